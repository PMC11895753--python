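"""End-to-end orchestration: one config in, every output table out.

Stage order: floral ordination -> PERMANOVA -> site matching -> species
preferences -> per-bin pair classification -> pair census -> pair
differences -> per-type summaries -> richness-preserving null -> effect
table -> between-bin preference tests. Every stage is a pure function of
(inputs, config, seed); a master seed fans out to per-stage seeds via fixed
offsets so stages can be re-run in isolation. All tables carry a header
comment with the package version, config hash and master seed, and a JSON
manifest records the config echo, seeds, stage timings and row counts.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cooccur import NullEngineConfig, classify_pairs, pair_census
from .effects import effect_table, pair_differences, richness_preserving_null
from .habitat import between_bin_tests, bin_preference_summaries, match_sites, species_preferences
from .occurrences import BIOZONE_ORDER, Dataset, load_dataset, pooled_matrix, validate_dataset
from .ordination import jaccard_distances, nmds, permanova

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
SEED_OFFSETS = {"nmds": 11, "permanova": 23, "pairs": 37, "null": 53}


@dataclass
class RunConfig:
    sites: str
    mammals: str
    flora: str
    traits: str
    outdir: str = "results"
    metric: str = "jaccard"
    nmds_restarts: int = 50
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-7
    n_perm: int = 10000
    n_null: int = 1000
    alpha: float = 0.05
    n_reps: int = 100
    inner_null: int = 200
    reclassify: bool = True
    dispersion: str = "variance"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunReport:
    outdir: Path
    manifest: dict = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, header: str) -> int:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return len(df)


def run_all(cfg: RunConfig, dataset: Dataset | None = None) -> RunReport:
    """Execute the full analysis; returns the output directory and manifest.

    Output tables are byte-identical across reruns of the same config
    (timings live only in the manifest).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    header = f"# paleopairs {__version__} config_hash={h} seed={cfg.seed}\n"
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": h,
        "seeds": {k: cfg.seed + v for k, v in SEED_OFFSETS.items()},
        "stages": {},
        "rows": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(rows: int | None = None):
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
            if rows is not None:
                manifest["rows"][name] = rows

        return done

    if dataset is None:
        dataset = load_dataset(cfg.sites, cfg.mammals, cfg.flora, cfg.traits)
    report = validate_dataset(dataset)
    if report.fatal:
        raise RuntimeError(
            f"validation failed: biozones without palynofloral sites: "
            f"{report.bins_without_flora}"
        )

    done = stage("ordination")
    flora_pooled = pooled_matrix(dataset.floral_matrices)
    dist = jaccard_distances(flora_pooled, metric=cfg.metric)
    ordn = nmds(
        dist,
        n_restarts=cfg.nmds_restarts,
        max_iter=cfg.nmds_max_iter,
        tol=cfg.nmds_tol,
        seed=cfg.seed + SEED_OFFSETS["nmds"],
    )
    site_bins = {
        s.site_id: s.biozone for s in dataset.sites if s.kind == "palynofloral"
    }
    scores = ordn.to_frame()
    scores.insert(1, "biozone", scores["site_id"].map(site_bins))
    scores["stress"] = ordn.stress
    done(_write_table(scores, out / "ordination_scores.csv", header))

    done = stage("permanova")
    groups = [site_bins[s] for s in dist.site_ids]
    perm = permanova(dist, groups, n_perm=cfg.n_perm, seed=cfg.seed + SEED_OFFSETS["permanova"])
    perm_rows = pd.concat(
        [
            pd.DataFrame(
                [{"group_a": "overall", "group_b": "", "F": perm.F,
                  "p_raw": perm.p, "p_bonferroni": perm.p}]
            ),
            perm.pairwise,
        ],
        ignore_index=True,
    )
    done(_write_table(perm_rows, out / "permanova.csv", header))

    done = stage("habitat_matching")
    habitats = match_sites(dataset.sites, dataset.sites, ordn)
    done(_write_table(habitats, out / "site_habitats.csv", header))

    done = stage("preferences")
    prefs = species_preferences(dataset.mammal_matrices, habitats)
    done(_write_table(prefs, out / "species_preferences.csv", header))

    done = stage("classification")
    pairs = {}
    for label in sorted(dataset.mammal_matrices, key=BIOZONE_ORDER.get):
        cfg_bin = NullEngineConfig(
            n_null=cfg.n_null,
            alpha=cfg.alpha,
            seed=cfg.seed + SEED_OFFSETS["pairs"] + BIOZONE_ORDER[label],
        )
        pairs[label] = classify_pairs(dataset.mammal_matrices[label], cfg_bin)
    all_pairs = pd.concat(pairs.values(), ignore_index=True)
    _write_table(all_pairs, out / "pair_classifications.csv", header)
    census = pair_census(pairs)
    done(_write_table(census, out / "pair_census.csv", header))

    done = stage("differences")
    diffs = pair_differences(all_pairs, dataset.traits, prefs)
    _write_table(diffs, out / "pair_differences.csv", header)
    from .effects import summarize_types

    done(_write_table(summarize_types(diffs), out / "type_summaries.csv", header))

    done = stage("null_model")
    null = richness_preserving_null(
        dataset.mammal_matrices,
        habitats,
        dataset.traits,
        n_reps=cfg.n_reps,
        inner=NullEngineConfig(n_null=cfg.inner_null, alpha=cfg.alpha),
        seed=cfg.seed + SEED_OFFSETS["null"],
        reclassify=cfg.reclassify,
        observed_pairs=None if cfg.reclassify else pairs,
    )
    _write_table(null.rep_summaries, out / "null_means.csv", header)
    effects = effect_table(diffs, null)
    done(_write_table(effects, out / "effect_sizes.csv", header))

    done = stage("preference_summaries")
    summaries = pd.concat(
        [
            bin_preference_summaries(
                prefs, dataset.mammal_matrices, subset=sub, dispersion_stat=cfg.dispersion
            )
            for sub in ("all_taxa", "first_occurrences")
        ],
        ignore_index=True,
    )
    _write_table(summaries, out / "bin_preference_summaries.csv", header)

    pref_idx = prefs.set_index("species_id")
    test_rows = []
    for axis in ("pref1", "pref2"):
        groups_by_bin = {}
        for label, m in dataset.mammal_matrices.items():
            present = [s for s in m.species_ids if s in pref_idx.index]
            groups_by_bin[label] = pref_idx.loc[present, axis].to_numpy()
        t = between_bin_tests(groups_by_bin, variable=axis)
        test_rows.append(
            {"variable": axis, "scope": "omnibus", "method": t.method,
             "statistic": t.statistic, "p_raw": t.p, "p_bonferroni": t.p}
        )
        for r in t.pairwise.itertuples():
            test_rows.append(
                {"variable": axis, "scope": f"{r.bin_a} vs {r.bin_b}",
                 "method": "mannwhitney", "statistic": r.statistic,
                 "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni}
            )
    done(_write_table(pd.DataFrame(test_rows), out / "between_bin_tests.csv", header))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunReport(outdir=out, manifest=manifest)
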