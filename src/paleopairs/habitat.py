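"""Habitat (Grinnellian niche) assignment from palynofloral ordination.

Each mammal site inherits the two NMDS scores of its geographically closest
contemporaneous palynofloral site (great-circle distance on a sphere of
radius 6371 km; ties broken toward the lexicographically smallest floral
site id). A species' environmental preference is the unweighted mean of the
inherited scores over every mammal site it occupies, pooled across all
biozones (time-transgressive: occurrences in every bin inform one
preference per species). Per-bin preference distributions are summarised
(mean, median and a configurable dispersion statistic) for either all taxa
present in the bin or only taxa first occurring there, and compared between
bins with a Kruskal-Wallis omnibus test plus pairwise two-sided
Mann-Whitney U tests under Bonferroni correction (a classical one-way ANOVA
is available behind a flag).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .occurrences import BIOZONE_ORDER, OccurrenceMatrix, Site, first_occurrence_bin
from .ordination import OrdinationResult

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    if (np.abs(lat1) > 90).any() or (np.abs(lat2) > 90).any():
        raise ValueError("latitude out of [-90, 90]")
    if (np.abs(lon1) > 180).any() or (np.abs(lon2) > 180).any():
        raise ValueError("longitude out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def match_sites(
    mammal_sites: list[Site],
    floral_sites: list[Site],
    ordination: OrdinationResult,
) -> pd.DataFrame:
    """Nearest contemporaneous palynofloral site for every mammal site.

    Returns a frame (mammal_site_id, matched_floral_site_id, distance_km,
    NMDS1, NMDS2, biozone). Matching is restricted to floral sites of the
    same biozone; a nearer floral site in a different bin is never used.
    """
    mammal_sites = [s for s in mammal_sites if s.kind == "mammal"]
    floral_sites = [s for s in floral_sites if s.kind == "palynofloral"]
    score_idx = {sid: i for i, sid in enumerate(ordination.site_ids)}
    missing = [s.site_id for s in floral_sites if s.site_id not in score_idx]
    if missing:
        raise ValueError(f"floral sites missing from ordination: {missing[:5]}")

    by_bin: dict[str, list[Site]] = {}
    for s in floral_sites:
        by_bin.setdefault(s.biozone, []).append(s)
    for sites in by_bin.values():
        sites.sort(key=lambda s: s.site_id)  # argmin then breaks ties lexicographically

    rows = []
    for ms in sorted(mammal_sites, key=lambda s: s.site_id):
        cands = by_bin.get(ms.biozone)
        if not cands:
            raise ValueError(f"no contemporaneous palynofloral site for biozone {ms.biozone!r}")
        dists = haversine_km(
            ms.lat, ms.lon,
            np.array([c.lat for c in cands]), np.array([c.lon for c in cands]),
        )
        dists = np.atleast_1d(dists)
        # ties (within a millimetre) resolve to the lexicographically
        # smallest floral site id; cands are already sorted by id
        j = int(np.nonzero(dists <= dists.min() + 1e-6)[0][0])
        fl = cands[j]
        sc = ordination.scores[score_idx[fl.site_id]]
        rows.append(
            {
                "mammal_site_id": ms.site_id,
                "matched_floral_site_id": fl.site_id,
                "distance_km": float(dists[j]),
                "NMDS1": float(sc[0]),
                "NMDS2": float(sc[1]),
                "biozone": ms.biozone,
            }
        )
    return pd.DataFrame(rows)


def species_preferences(
    mammal_matrices: dict[str, OccurrenceMatrix],
    site_habitats: pd.DataFrame,
) -> pd.DataFrame:
    """Time-transgressive species environmental preferences.

    Unweighted mean of inherited (NMDS1, NMDS2) over the union of occupied
    mammal sites across all biozones; each occupied site counts once.
    Returns (species_id, pref1, pref2, n_sites).
    """
    occ = pd.concat(
        [m.to_long() for m in mammal_matrices.values()], ignore_index=True
    ).drop_duplicates()
    merged = occ.merge(
        site_habitats[["mammal_site_id", "NMDS1", "NMDS2"]],
        left_on="site_id", right_on="mammal_site_id", how="left",
    )
    unmatched = merged["NMDS1"].isna()
    if unmatched.any():
        bad = merged.loc[unmatched, "site_id"].unique()
        raise ValueError(f"mammal sites without habitat scores: {list(bad[:5])}")
    prefs = (
        merged.groupby("species_id")
        .agg(pref1=("NMDS1", "mean"), pref2=("NMDS2", "mean"), n_sites=("site_id", "size"))
        .reset_index()
        .sort_values("species_id", ignore_index=True)
    )
    return prefs


def _dispersion(x: np.ndarray, stat: str) -> float:
    if len(x) < 2:
        return 0.0
    if stat == "variance":
        return float(np.var(x, ddof=1))
    if stat == "range":
        return float(np.max(x) - np.min(x))
    raise ValueError(f"unknown dispersion statistic {stat!r}")


def bin_preference_summaries(
    prefs: pd.DataFrame,
    mammal_matrices: dict[str, OccurrenceMatrix],
    subset: str = "all_taxa",
    dispersion_stat: str = "variance",
) -> pd.DataFrame:
    """Per-biozone summary of species preferences.

    ``subset='all_taxa'`` uses every species present in the bin;
    ``subset='first_occurrences'`` only species whose oldest occurrence is
    in that bin. Dispersion is the sample variance (n-1) or the range.
    """
    if subset not in ("all_taxa", "first_occurrences"):
        raise ValueError(f"unknown subset {subset!r}")
    pref_idx = prefs.set_index("species_id")
    rows = []
    for label in sorted(mammal_matrices, key=BIOZONE_ORDER.get):
        m = mammal_matrices[label]
        present = [s for s, t in zip(m.species_ids, m.row_totals) if t >= 1]
        if subset == "first_occurrences":
            present = [
                s for s in present if first_occurrence_bin(s, mammal_matrices) == label
            ]
        present = [s for s in present if s in pref_idx.index]
        if not present:
            rows.append({"biozone": label, "subset": subset, "n_species": 0,
                         "absent": True})
            continue
        p1 = pref_idx.loc[present, "pref1"].to_numpy(dtype=float)
        p2 = pref_idx.loc[present, "pref2"].to_numpy(dtype=float)
        rows.append(
            {
                "biozone": label,
                "subset": subset,
                "n_species": len(present),
                "absent": False,
                "mean1": float(np.mean(p1)),
                "mean2": float(np.mean(p2)),
                "median1": float(np.median(p1)),
                "median2": float(np.median(p2)),
                "dispersion1": _dispersion(p1, dispersion_stat),
                "dispersion2": _dispersion(p2, dispersion_stat),
                "dispersion_stat": dispersion_stat,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BetweenBinTests:
    variable: str
    method: str  # 'kruskal' or 'anova'
    statistic: float
    p: float
    pairwise: pd.DataFrame  # bin_a, bin_b, statistic, p_raw, p_bonferroni


def between_bin_tests(
    groups: dict[str, np.ndarray],
    variable: str = "value",
    method: str = "kruskal",
) -> BetweenBinTests:
    """Omnibus + pairwise comparison of a per-species variable between bins.

    Default omnibus is Kruskal-Wallis with pairwise two-sided Mann-Whitney U
    tests (Bonferroni-corrected); ``method='anova'`` swaps the omnibus for a
    classical one-way ANOVA. Groups that are identical everywhere (all
    values tied) yield p = 1 by convention.
    """
    labels = sorted(groups, key=lambda b: BIOZONE_ORDER.get(b, 99))
    if len(labels) < 2:
        raise ValueError("need at least 2 bins")
    arrays = [np.asarray(groups[b], dtype=float) for b in labels]
    for b, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"bin {b!r} has fewer than 2 species")

    pooled = np.concatenate(arrays)
    all_tied = np.all(pooled == pooled[0])
    if all_tied:
        stat, p = 0.0, 1.0
    elif method == "kruskal":
        stat, p = stats.kruskal(*arrays)
    elif method == "anova":
        stat, p = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown method {method!r}")

    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], dtype=float), np.asarray(groups[b], dtype=float)
        both = np.concatenate([xa, xb])
        if np.all(both == both[0]):
            u, p_ab = len(xa) * len(xb) / 2.0, 1.0
        else:
            u, p_ab = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
                "bin_a": a,
                "bin_b": b,
                "statistic": float(u),
                "p_raw": float(p_ab),
                "p_bonferroni": min(1.0, float(p_ab) * len(pairs)),
            }
        )
    return BetweenBinTests(
        variable=variable, method=method, statistic=float(stat), p=float(p),
        pairwise=pd.DataFrame(rows),
    )
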