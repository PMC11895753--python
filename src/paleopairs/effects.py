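"""Ecological differences within species pairs and null-model effect sizes.

For every classified species pair, three absolute differences are computed:
ln body mass (Eltonian niche axis) and the two environmental-preference
axes pref1/pref2 (Grinnellian niche, inherited NMDS scores). Differences are
averaged per (biozone x pair type), and observed averages are compared to a
cross-biozone richness-preserving null: in each replicate every site in
every biozone is refilled with k distinct species drawn uniformly from the
pooled species list (k = the site's observed richness), after which the full
downstream pipeline (pair classification, species preferences, pair
differences, per-type summaries) is re-run on the randomised matrices. Site
richness and per-bin site counts are conserved exactly; species occupancy
totals are not (the null randomises species associations).

Effect sizes are Cohen's D, d = (mean observed - mean null) / sd(null),
where the null mean and sd are taken over the pooled pair-level null
differences for that cell, so that Cohen's conventional benchmarks apply:
|d| <= 0.2 small, |d| >= 0.8 large, medium otherwise. The per-replicate
cell means (``null_means``) are also returned, both for violin-style
reporting of the null and for the replicate-mean variant ``d_rep``
(a z-score-like statistic, expected to land mostly in (-2, 2) when the
observed data are themselves a draw from the null).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cooccur import CLS_LABELS, NullEngineConfig, classify_core
from .occurrences import BIOZONE_ORDER, OccurrenceMatrix

logger = logging.getLogger(__name__)

VARIABLES = ("mass", "pref1", "pref2")
CLASSIFICATIONS = ("aggregated", "segregated", "random")


def pair_differences(
    pairs: pd.DataFrame, traits: pd.DataFrame, prefs: pd.DataFrame
) -> pd.DataFrame:
    """Absolute trait and preference differences for classified pairs.

    ``pairs`` is the (possibly concatenated) output of classify_pairs;
    pairs whose species lack a trait or preference record are dropped with
    a logged count. Returns one row per pair with d_mass, d_pref1, d_pref2.
    """
    tr = traits.set_index("species_id")["ln_mass"]
    p1 = prefs.set_index("species_id")["pref1"]
    p2 = prefs.set_index("species_id")["pref2"]
    out = pairs[["species_i", "species_j", "biozone", "classification"]].copy()
    out["d_mass"] = (
        pairs["species_i"].map(tr).to_numpy() - pairs["species_j"].map(tr).to_numpy()
    )
    out["d_pref1"] = (
        pairs["species_i"].map(p1).to_numpy() - pairs["species_j"].map(p1).to_numpy()
    )
    out["d_pref2"] = (
        pairs["species_i"].map(p2).to_numpy() - pairs["species_j"].map(p2).to_numpy()
    )
    bad = out[["d_mass", "d_pref1", "d_pref2"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d pairs lacking traits or preferences", int(bad.sum()))
        out = out[~bad]
    for col in ("d_mass", "d_pref1", "d_pref2"):
        out[col] = out[col].abs()
    return out.reset_index(drop=True)


def summarize_types(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mean and median differences per (biozone x classification x variable).

    Cells with no pairs (e.g. a biozone with no segregated pairs) simply do
    not appear; downstream reporting marks them absent.
    """
    rows = []
    for (bz, cls), sub in diffs.groupby(["biozone", "classification"], sort=True):
        for var, col in zip(VARIABLES, ("d_mass", "d_pref1", "d_pref2")):
            vals = sub[col].to_numpy(dtype=float)
            rows.append(
                {
                    "biozone": bz,
                    "classification": cls,
                    "variable": var,
                    "mean_diff": float(np.mean(vals)),
                    "median_diff": float(np.median(vals)),
                    "n_pairs": len(vals),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(
            ["biozone", "classification", "variable"], ignore_index=True
        )
    return out


@dataclass
class EffectSize:
    observed_mean: float
    null_mean: float
    null_sd: float
    d: float
    magnitude: str
    n_null: int


def magnitude_label(d: float) -> str:
    """Cohen's benchmarks: |d| <= 0.2 small, |d| >= 0.8 large, else medium."""
    if abs(d) <= 0.2:
        return "small"
    if abs(d) >= 0.8:
        return "large"
    return "medium"


def cohens_d(observed_mean: float, null_values: np.ndarray) -> EffectSize:
    """Cohen's D of an observed mean against a null distribution:
    (observed - mean(null)) / sd(null), sample sd (n-1)."""
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) < 30:
        raise ValueError("need at least 30 null replicates for a stable effect size")
    mu = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1))
    if sd <= 0.0:
        raise ValueError("degenerate null (zero standard deviation)")
    d = (observed_mean - mu) / sd
    return EffectSize(float(observed_mean), mu, sd, float(d), magnitude_label(d), len(null_values))


@dataclass
class NullEnsemble:
    """Richness-preserving null distributions.

    ``rep_summaries``: one row per (replicate x biozone x classification x
    variable) with the replicate's mean/median difference and pair count.
    ``pooled``: pair-level null differences pooled across replicates,
    keyed by (biozone, classification, variable).
    """

    rep_summaries: pd.DataFrame
    pooled: dict[tuple[str, str, str], np.ndarray]
    n_reps: int
    seed: int

    def rep_means(self, biozone: str, classification: str, variable: str) -> np.ndarray:
        s = self.rep_summaries
        sel = (
            (s["biozone"] == biozone)
            & (s["classification"] == classification)
            & (s["variable"] == variable)
        )
        return s.loc[sel, "mean_diff"].to_numpy(dtype=float)


def _randomized_bins(
    richness: dict[str, np.ndarray], n_pool: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One null replicate: refill every site with k distinct species drawn
    uniformly from the pooled species list (k = observed site richness)."""
    out = {}
    for label, ks in richness.items():
        z = np.zeros((n_pool, len(ks)), dtype=np.int8)
        for c, k in enumerate(ks):
            z[rng.choice(n_pool, size=int(k), replace=False), c] = 1
        out[label] = z
    return out


def richness_preserving_null(
    mammal_matrices: dict[str, OccurrenceMatrix],
    site_habitats: pd.DataFrame,
    traits: pd.DataFrame,
    n_reps: int = 100,
    inner: NullEngineConfig | None = None,
    seed: int = 0,
    reclassify: bool = True,
    observed_pairs: dict[str, pd.DataFrame] | None = None,
) -> NullEnsemble:
    """Cross-biozone richness-preserving null for pair-type differences.

    Per replicate, sites in all biozones are refilled from the pooled
    species list, pair classification is re-run per biozone with the
    (reduced) ``inner`` co-occurrence null, preferences are recomputed from
    the randomised occupancies and the per-type difference summaries are
    recorded. Deterministic given ``seed``; replicate r uses the seed stream
    (seed, r) so n_reps can grow without changing earlier replicates.

    ``reclassify=False`` reuses the observed pair classifications
    (``observed_pairs`` required) and only recomputes preferences and
    differences — a cheaper variant.
    """
    if inner is None:
        inner = NullEngineConfig(n_null=200)
    bins = sorted(mammal_matrices, key=BIOZONE_ORDER.get)
    pool = sorted(set().union(*(mammal_matrices[b].species_ids for b in bins)))
    tr_map = traits.set_index("species_id")["ln_mass"]
    have_mass = [s in tr_map.index and np.isfinite(tr_map[s]) for s in pool]
    if not all(have_mass):
        dropped = [s for s, ok in zip(pool, have_mass) if not ok]
        logger.warning("null pool drops %d species lacking traits", len(dropped))
        pool = [s for s, ok in zip(pool, have_mass) if ok]
    n_pool = len(pool)
    mass = tr_map.loc[pool].to_numpy(dtype=float)

    richness = {b: mammal_matrices[b].col_totals for b in bins}
    max_k = max(int(r.max()) for r in richness.values())
    if n_pool < max_k:
        raise ValueError(
            f"pooled species count {n_pool} < maximum site richness {max_k}"
        )
    hab = site_habitats.set_index("mammal_site_id")
    scores = {
        b: hab.loc[mammal_matrices[b].site_ids, ["NMDS1", "NMDS2"]].to_numpy(dtype=float)
        for b in bins
    }

    if not reclassify:
        if observed_pairs is None:
            raise ValueError("observed_pairs required when reclassify=False")
        pool_index = {s: i for i, s in enumerate(pool)}
        fixed = {
            b: (
                observed_pairs[b]["species_i"].map(pool_index).to_numpy(),
                observed_pairs[b]["species_j"].map(pool_index).to_numpy(),
                observed_pairs[b]["classification"].to_numpy(),
            )
            for b in bins
        }

    sum_rows: list[dict] = []
    pooled_acc: dict[tuple[str, str, str], list[np.ndarray]] = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        zbins = _randomized_bins(richness, n_pool, rng)

        # preferences from the randomised occupancies, pooled across bins
        occ_all = np.hstack([zbins[b] for b in bins]).astype(np.float64)
        sc_all = np.vstack([scores[b] for b in bins])
        n_sites_sp = occ_all.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pref = (occ_all @ sc_all) / n_sites_sp[:, None]

        for b in bins:
            z = zbins[b]
            present = z.sum(axis=1) >= 1
            idx = np.nonzero(present)[0]
            if reclassify:
                sub = z[present]
                core = classify_core(
                    sub,
                    inner.replace(seed=int(rng.integers(2**31))),
                )
                gi = idx[core["i"]]
                gj = idx[core["j"]]
                cls = CLS_LABELS[core["cls"]]
            else:
                gi, gj, cls = fixed[b]
                keep = present[gi] & present[gj]
                gi, gj, cls = gi[keep], gj[keep], cls[keep]
            d_mass = np.abs(mass[gi] - mass[gj])
            d_p1 = np.abs(pref[gi, 0] - pref[gj, 0])
            d_p2 = np.abs(pref[gi, 1] - pref[gj, 1])
            for label in CLASSIFICATIONS:
                mask = cls == label
                n_cell = int(mask.sum())
                for var, vals in zip(VARIABLES, (d_mass, d_p1, d_p2)):
                    if n_cell == 0:
                        continue
                    v = vals[mask]
                    sum_rows.append(
                        {
                            "rep": rep,
                            "biozone": b,
                            "classification": label,
                            "variable": var,
                            "mean_diff": float(v.mean()),
                            "median_diff": float(np.median(v)),
                            "n_pairs": n_cell,
                        }
                    )
                    pooled_acc.setdefault((b, label, var), []).append(v)

    pooled = {k: np.concatenate(v) for k, v in pooled_acc.items()}
    return NullEnsemble(
        rep_summaries=pd.DataFrame(sum_rows), pooled=pooled, n_reps=n_reps, seed=seed
    )


def effect_table(
    observed_diffs: pd.DataFrame,
    null: NullEnsemble,
    biozones: list[str] | None = None,
) -> pd.DataFrame:
    """Effect sizes of observed pair-type differences against the null.

    One row per (biozone x classification x variable). Cells absent from
    the observed data (e.g. no segregated pairs in a bin) are marked
    ``absent`` and carry no effect size. ``d`` is Cohen's D against the
    pooled pair-level null; ``d_median`` is its median-based analogue;
    ``d_rep`` standardises by the spread of replicate-level null means.
    """
    if biozones is None:
        biozones = sorted(
            set(observed_diffs["biozone"]) | {k[0] for k in null.pooled},
            key=lambda b: BIOZONE_ORDER.get(b, 99),
        )
    obs = summarize_types(observed_diffs).set_index(
        ["biozone", "classification", "variable"]
    )
    rows = []
    for bz in biozones:
        for cls in CLASSIFICATIONS:
            for var in VARIABLES:
                key = (bz, cls, var)
                row: dict = {"biozone": bz, "classification": cls, "variable": var}
                pooled = null.pooled.get(key)
                if key not in obs.index or pooled is None or len(pooled) < 30:
                    row.update(
                        n_pairs=0, observed_mean=np.nan, observed_median=np.nan,
                        null_n=0 if pooled is None else len(pooled),
                        null_mean=np.nan, null_sd=np.nan, d=np.nan,
                        d_median=np.nan, d_rep=np.nan,
                        magnitude="absent", absent=True,
                    )
                    rows.append(row)
                    continue
                o = obs.loc[key]
                es = cohens_d(float(o["mean_diff"]), pooled)
                d_median = (float(o["median_diff"]) - float(np.median(pooled))) / es.null_sd
                reps = null.rep_means(bz, cls, var)
                if len(reps) >= 2 and np.std(reps, ddof=1) > 0:
                    d_rep = (es.observed_mean - float(np.mean(reps))) / float(
                        np.std(reps, ddof=1)
                    )
                else:
                    d_rep = np.nan
                row.update(
                    n_pairs=int(o["n_pairs"]),
                    observed_mean=es.observed_mean,
                    observed_median=float(o["median_diff"]),
                    null_n=len(pooled),
                    null_mean=es.null_mean,
                    null_sd=es.null_sd,
                    d=es.d,
                    d_median=float(d_median),
                    d_rep=float(d_rep),
                    magnitude=es.magnitude,
                    absent=False,
                )
                rows.append(row)
    return pd.DataFrame(rows)
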