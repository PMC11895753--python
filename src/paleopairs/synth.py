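"""Synthetic community datasets with known ground truth.

Generates complete datasets with the statistical structure the analysis
assumes: three ordered biozones; ~30 palynofloral sites whose taxon
compositions form bin-level clusters (taxon pools turn over between bins);
mammal sites placed near floral sites so nearest-neighbour habitat matching
is meaningful; log-normal body masses; and occupancy driven by a single
latent 1-D habitat gradient shared by flora and mammals — site habitat
values set floral composition (gaussian taxon response curves around
per-taxon optima) and, when ``habitat_filter_strength > 0``, decay mammal
occupancy with the squared distance between site habitat and a species'
habitat centre, scaled by its breadth. Optionally, species pairs with known
aggregated or segregated structure are planted on top of the probabilistic
occupancy, for parameter-recovery tests.

Default shapes mirror the study system: 173 mammal species on 126 mammal
sites (36/48/42 per bin), 30 palynofloral sites (8/13/9 per bin), site
coordinates inside a ~200 km box in the Bighorn Basin.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .occurrences import (
    BIOZONES,
    Dataset,
    OccurrenceMatrix,
    Site,
    write_occurrences,
    write_sites,
    write_traits,
)

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    """Generator settings; defaults give a study-shaped dataset."""

    floral_sites_per_bin: tuple[int, int, int] = (8, 13, 9)
    n_floral_taxa_pool: int = 120
    bin_pool_size: int = 50
    floral_turnover: float = 0.7  # fraction of each bin's pool replaced
    floral_inclusion: float = 0.55  # peak per-taxon inclusion probability
    floral_niche_width: float = 1.0

    mammal_sites_per_bin: tuple[int, int, int] = (36, 48, 42)
    n_mammal_species: int = 173
    #: optional imposed temporal ranges: species per bin-level pool, with
    #: consecutive pools sharing (1 - mammal_turnover) of their species.
    #: None (default) lets turnover emerge from habitat filtering alone:
    #: under a nonzero filter strength, species whose habitat centre
    #: matches one bin's habitat concentrate their occurrences there, which
    #: reproduces the strong extinction/immigration turnover of the study
    #: interval without a second mechanism.
    mammal_bin_pool: int | None = None
    mammal_turnover: float = 0.5
    mass_log_mean: float = 6.0  # ln grams
    mass_log_sd: float = 2.0
    base_occupancy: float = 0.15  # mean per-species site-occupancy rate
    #: Beta concentration of per-species occupancy rates around
    #: base_occupancy; None draws every species at exactly base_occupancy
    #: (the exchangeable regime used for null-model calibration).
    occupancy_concentration: float | None = 12.0

    habitat_filter_strength: float = 1.0  # 0 = neutral occupancy
    n_planted_aggregated: int = 0
    n_planted_segregated: int = 0
    planted_agg_fill: float = 0.4  # target shared-site fraction per bin
    planted_seg_fill: float = 0.75  # per-site presence prob on own half

    #: mammal localities are spatially clumped: per bin, mammal sites are
    #: placed around only this many distinct palynofloral parents, so
    #: nearest-site matching resolves to a handful of floral localities
    #: (the study system matched 126 mammal sites to five floral sites,
    #: 2/2/1 per bin).
    mammal_parent_sites_per_bin: tuple[int, int, int] = (2, 2, 1)

    coord_box: tuple[float, float, float, float] = (44.0, 45.8, -109.5, -107.7)
    habitat_bin_means: tuple[float, float, float] = (-1.0, 1.0, 0.0)
    habitat_site_sd: float = 0.35
    mammal_coord_jitter: float = 0.03  # degrees around the parent floral site

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floral_turnover <= 1.0:
            raise ValueError("floral_turnover must lie in [0, 1]")
        n_new = round(self.floral_turnover * self.bin_pool_size)
        if self.bin_pool_size + 2 * n_new > self.n_floral_taxa_pool:
            raise ValueError(
                "taxon pool too small for the requested per-bin pools and turnover"
            )
        if min(self.floral_sites_per_bin) < 1 or min(self.mammal_sites_per_bin) < 1:
            raise ValueError("every biozone needs at least one site")
        if self.n_mammal_species < 1:
            raise ValueError("need at least one species")
        if 2 * (self.n_planted_aggregated + self.n_planted_segregated) > self.n_mammal_species:
            raise ValueError("more planted pairs than species allow")
        if self.mammal_bin_pool is not None:
            if not 0.0 <= self.mammal_turnover <= 1.0:
                raise ValueError("mammal_turnover must lie in [0, 1]")
            n_new = round(self.mammal_turnover * self.mammal_bin_pool)
            if self.mammal_bin_pool + 2 * n_new > self.n_mammal_species:
                raise ValueError(
                    "species pool too small for the requested per-bin pools and turnover"
                )
        if not 0.0 < self.base_occupancy < 1.0:
            raise ValueError("base_occupancy must lie in (0, 1)")

    @property
    def n_mammal_sites(self) -> int:
        return sum(self.mammal_sites_per_bin)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests; never an input
    to the analysis pipeline."""

    species: pd.DataFrame  # species_id, center, breadth, base_rate
    planted_pairs: pd.DataFrame  # species_i, species_j, intended
    sites: pd.DataFrame  # site_id, biozone, kind, habitat
    taxa: pd.DataFrame = field(default_factory=pd.DataFrame)  # taxon_id, optimum


def _turnover_pools(m: int, turnover: float, rng: np.random.Generator) -> list[list[int]]:
    """Three bin-level pools of size m over ids 0..m+2*round(turnover*m);
    consecutive pools share (1 - turnover) of their members."""
    n_new = round(turnover * m)
    pools = [list(range(m))]
    next_fresh = m
    for _ in range(1, 3):
        prev = pools[-1]
        kept = sorted(rng.choice(len(prev), size=m - n_new, replace=False))
        pool = [prev[i] for i in kept] + list(range(next_fresh, next_fresh + n_new))
        next_fresh += n_new
        pools.append(pool)
    return pools


def _bin_pools(cfg: SynthConfig, rng: np.random.Generator) -> list[list[int]]:
    return _turnover_pools(cfg.bin_pool_size, cfg.floral_turnover, rng)


def generate_flora(
    cfg: SynthConfig,
) -> tuple[dict[str, OccurrenceMatrix], list[Site], pd.DataFrame, pd.DataFrame]:
    """Palynofloral matrices, sites, per-site latent habitat and taxon optima."""
    root = np.random.SeedSequence((cfg.seed, 0))
    rng = np.random.default_rng(root)
    pools = _bin_pools(cfg, rng)

    optima: dict[int, float] = {}
    for b, pool in enumerate(pools):
        for t in pool:
            if t not in optima:
                optima[t] = float(rng.normal(cfg.habitat_bin_means[b], 0.6))

    lat0, lat1, lon0, lon1 = cfg.coord_box
    sites: list[Site] = []
    hab_rows = []
    matrices: dict[str, OccurrenceMatrix] = {}
    for b, label in enumerate(BIOZONES):
        n_sites = cfg.floral_sites_per_bin[b]
        pool = pools[b]
        opts = np.array([optima[t] for t in pool])
        site_ids = [f"F{label}_{i:02d}" for i in range(n_sites)]
        habitats = cfg.habitat_bin_means[b] + rng.normal(0.0, cfg.habitat_site_sd, n_sites)
        lats = rng.uniform(lat0, lat1, n_sites)
        lons = rng.uniform(lon0, lon1, n_sites)
        cells = np.zeros((len(pool), n_sites), dtype=np.int8)
        for j in range(n_sites):
            p = cfg.floral_inclusion * np.exp(
                -((habitats[j] - opts) ** 2) / (2.0 * cfg.floral_niche_width**2)
            )
            draw = rng.random(len(pool)) < p
            if draw.sum() < 3:  # a pollen sample is never taxon-free
                draw[np.argsort(p)[-3:]] = True
            cells[:, j] = draw
        taxa_ids = [f"T{t:03d}" for t in pool]
        order = np.argsort(taxa_ids)
        m = OccurrenceMatrix(
            [taxa_ids[i] for i in order], site_ids, cells[order], label
        ).validated()
        matrices[label] = m
        for sid, la, lo, h in zip(site_ids, lats, lons, habitats):
            sites.append(Site(sid, float(la), float(lo), label, "palynofloral"))
            hab_rows.append({"site_id": sid, "biozone": label, "kind": "palynofloral",
                             "habitat": float(h)})
    taxa_df = pd.DataFrame(
        {"taxon_id": [f"T{t:03d}" for t in sorted(optima)],
         "optimum": [optima[t] for t in sorted(optima)]}
    )
    return matrices, sites, pd.DataFrame(hab_rows), taxa_df


def generate_mammals(
    cfg: SynthConfig,
    floral_sites: list[Site],
    floral_habitats: pd.DataFrame,
) -> tuple[dict[str, OccurrenceMatrix], list[Site], pd.DataFrame, GroundTruth]:
    """Mammal matrices, sites, trait table and ground truth."""
    ss = np.random.SeedSequence((cfg.seed, 1))
    rng_params, rng_sites, rng_occ, rng_plant = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    S = cfg.n_mammal_species
    width = max(3, int(math.ceil(math.log10(max(S, 2)))))
    species = [f"sp{i:0{width}d}" for i in range(S)]

    centers = rng_params.normal(0.0, 1.0, S)
    breadths = rng_params.uniform(0.6, 1.4, S)
    ln_mass = rng_params.normal(cfg.mass_log_mean, cfg.mass_log_sd, S)
    # per-species occupancy rates around the configured mean; the draw is
    # always consumed so the stream stays aligned across configurations
    kappa = cfg.occupancy_concentration
    raw = rng_params.beta(
        (kappa or 1.0) * cfg.base_occupancy,
        (kappa or 1.0) * (1.0 - cfg.base_occupancy),
        S,
    )
    base_rate = raw if kappa is not None else np.full(S, cfg.base_occupancy)

    # temporal ranges: which species can occur in which bin
    allowed = np.ones((S, 3), dtype=bool)
    if cfg.mammal_bin_pool is not None:
        allowed[:] = False
        for b, pool in enumerate(
            _turnover_pools(cfg.mammal_bin_pool, cfg.mammal_turnover, rng_params)
        ):
            allowed[pool, b] = True
        # species beyond the pooled range ids never occur; they stay in the
        # trait table but are dropped by per-bin validation
    n_planted_sp = 2 * (cfg.n_planted_aggregated + cfg.n_planted_segregated)
    if n_planted_sp:
        allowed[S - n_planted_sp:, :] = True  # planted pairs span all bins

    hab_by_floral = floral_habitats.set_index("site_id")["habitat"]
    floral_by_bin: dict[str, list[Site]] = {}
    for s in floral_sites:
        floral_by_bin.setdefault(s.biozone, []).append(s)

    sites: list[Site] = []
    site_rows = []
    bin_site_ids: dict[str, list[str]] = {}
    bin_habitats: dict[str, np.ndarray] = {}
    for b, label in enumerate(BIOZONES):
        n_sites = cfg.mammal_sites_per_bin[b]
        n_parents = min(cfg.mammal_parent_sites_per_bin[b], len(floral_by_bin[label]))
        parent_pool = rng_sites.choice(len(floral_by_bin[label]), size=n_parents,
                                       replace=False)
        parents = parent_pool[rng_sites.integers(0, n_parents, n_sites)]
        ids, habs = [], []
        for j in range(n_sites):
            parent = floral_by_bin[label][int(parents[j])]
            sid = f"M{label}_{j:03d}"
            lat = float(np.clip(parent.lat + rng_sites.normal(0, cfg.mammal_coord_jitter), -90, 90))
            lon = float(np.clip(parent.lon + rng_sites.normal(0, cfg.mammal_coord_jitter), -180, 180))
            h = float(hab_by_floral[parent.site_id] + rng_sites.normal(0, 0.1))
            sites.append(Site(sid, lat, lon, label, "mammal"))
            site_rows.append({"site_id": sid, "biozone": label, "kind": "mammal",
                              "habitat": h})
            ids.append(sid)
            habs.append(h)
        bin_site_ids[label] = ids
        bin_habitats[label] = np.array(habs)

    # occupancy: one uniform draw per (species, site); the habitat filter is
    # normalised per species and bin so the expected occupancy stays at the
    # species' base rate for every filter strength
    # occupancy: the habitat filter is normalised per species across ALL
    # sites (its occurrence budget is global), so under strong filtering a
    # species concentrates its occurrences in the bins whose habitat
    # matches its centre — turnover emerges from the gradient itself
    h_all = np.concatenate([bin_habitats[label] for label in BIOZONES])
    mask_all = np.concatenate(
        [np.repeat(allowed[:, b][:, None], len(bin_habitats[label]), axis=1)
         for b, label in enumerate(BIOZONES)],
        axis=1,
    )
    f = np.exp(
        -cfg.habitat_filter_strength
        * (h_all[None, :] - centers[:, None]) ** 2
        / breadths[:, None] ** 2
    )
    f = np.where(mask_all, f, 0.0)
    denom = f.mean(axis=1, keepdims=True)
    denom[denom <= 0] = 1.0
    p_all = np.clip(base_rate[:, None] * f / denom, 0.0, 0.9)
    u_all = rng_occ.random(p_all.shape)
    occ_all = (u_all < p_all).astype(np.int8)
    occupancy: dict[str, np.ndarray] = {}
    offset = 0
    for label in BIOZONES:
        n = len(bin_habitats[label])
        occupancy[label] = occ_all[:, offset:offset + n].copy()
        offset += n

    # planted pairs override whole rows, consuming only the planting stream,
    # so occupancy of non-planted species is invariant to the pair counts
    planted = []
    tail = S
    for intent, n_pairs in (
        ("aggregated", cfg.n_planted_aggregated),
        ("segregated", cfg.n_planted_segregated),
    ):
        for _ in range(n_pairs):
            i, j = tail - 2, tail - 1
            tail -= 2
            planted.append((species[i], species[j], intent, i, j))
    for sp_i, sp_j, intent, i, j in planted:
        for label in BIOZONES:
            occ = occupancy[label]
            n_sites = occ.shape[1]
            if intent == "aggregated":
                union = (occ[i] | occ[j]).astype(bool)
                target = max(2, int(round(cfg.planted_agg_fill * n_sites)))
                deficit = target - int(union.sum())
                if deficit > 0:
                    absent = np.nonzero(~union)[0]
                    add = rng_plant.choice(len(absent), size=min(deficit, len(absent)),
                                           replace=False)
                    union[absent[add]] = True
                occ[i] = occ[j] = union.astype(np.int8)
            else:
                half = n_sites // 2
                row_i = np.zeros(n_sites, dtype=np.int8)
                row_j = np.zeros(n_sites, dtype=np.int8)
                row_i[:half] = rng_plant.random(half) < cfg.planted_seg_fill
                row_j[half:] = rng_plant.random(n_sites - half) < cfg.planted_seg_fill
                if row_i.sum() == 0:
                    row_i[0] = 1
                if row_j.sum() == 0:
                    row_j[-1] = 1
                occ[i] = row_i
                occ[j] = row_j

    matrices: dict[str, OccurrenceMatrix] = {}
    for b, label in enumerate(BIOZONES):
        occ = occupancy[label]
        # a fossil site always yields at least one taxon (of the bin's pool)
        cand = np.nonzero(allowed[:, b])[0]
        best = int(cand[np.argmax(base_rate[cand])])
        for c in np.nonzero(occ.sum(axis=0) == 0)[0]:
            occ[best, c] = 1
        matrices[label] = OccurrenceMatrix(
            species, bin_site_ids[label], occ, label
        ).validated()

    traits = pd.DataFrame({"species_id": species, "ln_mass": ln_mass}).sort_values(
        "species_id", ignore_index=True
    )
    truth = GroundTruth(
        species=pd.DataFrame(
            {"species_id": species, "center": centers, "breadth": breadths,
             "base_rate": base_rate,
             **{f"in_{lbl}": allowed[:, b] for b, lbl in enumerate(BIOZONES)}}
        ),
        planted_pairs=pd.DataFrame(
            [(a, b, t) for a, b, t, _, _ in planted],
            columns=["species_i", "species_j", "intended"],
        ),
        sites=pd.DataFrame(site_rows),
    )
    return matrices, sites, traits, truth


def generate_dataset(cfg: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Full synthetic dataset (flora + mammals + traits) with ground truth."""
    floral_matrices, floral_sites, floral_hab, taxa = generate_flora(cfg)
    mammal_matrices, mammal_sites, traits, truth = generate_mammals(
        cfg, floral_sites, floral_hab
    )
    truth.sites = pd.concat([floral_hab, truth.sites], ignore_index=True)
    truth.taxa = taxa
    ds = Dataset(
        sites=floral_sites + mammal_sites,
        mammal_matrices=mammal_matrices,
        floral_matrices=floral_matrices,
        traits=traits,
    )
    return ds, truth


def write_dataset(ds: Dataset, truth: GroundTruth, directory: str | Path) -> None:
    """Write the dataset in the canonical CSV formats plus ground-truth
    files (the latter are never inputs to the pipeline)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_sites(ds.sites, d / "sites.csv")
    write_occurrences(ds.mammal_matrices, d / "mammal_occurrences.csv")
    write_occurrences(ds.floral_matrices, d / "floral_occurrences.csv")
    write_traits(ds.traits, d / "traits.csv")
    truth.species.to_csv(d / "ground_truth_species.csv", index=False)
    truth.planted_pairs.to_csv(d / "ground_truth_pairs.csv", index=False)
    truth.sites.to_csv(d / "ground_truth_sites.csv", index=False)
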