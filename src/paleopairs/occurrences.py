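"""Occurrence data model, validation and file I/O.

The analysis operates on binary species-by-site presence/absence matrices,
one per biozone (time bin). Species are rows and sites are columns, so a
species' occupancy is its row total R_i. Three ordered North American Land
Mammal Age biozones are recognised: the Clarkforkian 3 (Cf3, oldest), the
Wasatchian 0 (Wa0, spanning the PETM) and the combined Wasatchian 1-2
(Wa1_2). Sites come in two kinds, ``mammal`` and ``palynofloral``, and carry
decimal-degree coordinates used for nearest-neighbour habitat matching.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Biozone labels in stratigraphic order (oldest first).
BIOZONES: tuple[str, ...] = ("Cf3", "Wa0", "Wa1_2")
BIOZONE_ORDER: dict[str, int] = {b: i for i, b in enumerate(BIOZONES)}
#: Approximate age spans, annotation only (never used in computation).
BIOZONE_AGES: dict[str, str] = {
    "Cf3": "ca. 56.2-55.8 Ma",
    "Wa0": "ca. 55.8-55.7 Ma",
    "Wa1_2": "ca. 55.7-54.8 Ma",
}
SITE_KINDS: tuple[str, ...] = ("mammal", "palynofloral")


@dataclass(frozen=True)
class Site:
    """A fossil locality with coordinates, biozone and kind."""

    site_id: str
    lat: float
    lon: float
    biozone: str
    kind: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.site_id!r}: latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"site {self.site_id!r}: longitude {self.lon} out of [-180, 180]")
        if self.biozone not in BIOZONE_ORDER:
            raise ValueError(f"site {self.site_id!r}: unknown biozone {self.biozone!r}")
        if self.kind not in SITE_KINDS:
            raise ValueError(f"site {self.site_id!r}: unknown kind {self.kind!r}")


@dataclass
class OccurrenceMatrix:
    """Binary species-by-site matrix for one biozone.

    ``cells[i, j] == 1`` iff species ``species_ids[i]`` occurs at site
    ``site_ids[j]``. Rows and columns are kept in lexicographic order by the
    readers so matrix construction is deterministic.
    """

    species_ids: list[str]
    site_ids: list[str]
    cells: np.ndarray
    biozone: str

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be 2-D")
        if self.cells.shape != (len(self.species_ids), len(self.site_ids)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.site_ids)} sites"
            )
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary (0/1)")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species_ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site_ids")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def row_totals(self) -> np.ndarray:
        """Occupancy R_i of each species (number of occupied sites)."""
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Richness of each site (number of species present)."""
        return self.cells.sum(axis=0)

    def copy(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(
            list(self.species_ids), list(self.site_ids), self.cells.copy(), self.biozone
        )

    def validated(self) -> "OccurrenceMatrix":
        """Drop empty rows and columns (logged), returning a new matrix."""
        rt = self.row_totals
        ct = self.col_totals
        keep_r = rt >= 1
        keep_c = ct >= 1
        if keep_r.all() and keep_c.all():
            return self.copy()
        dropped_sp = [s for s, k in zip(self.species_ids, keep_r) if not k]
        dropped_si = [s for s, k in zip(self.site_ids, keep_c) if not k]
        if dropped_sp:
            logger.warning("%s: dropping %d empty species rows: %s",
                           self.biozone, len(dropped_sp), dropped_sp[:10])
        if dropped_si:
            logger.warning("%s: dropping %d empty site columns: %s",
                           self.biozone, len(dropped_si), dropped_si[:10])
        return OccurrenceMatrix(
            [s for s, k in zip(self.species_ids, keep_r) if k],
            [s for s, k in zip(self.site_ids, keep_c) if k],
            self.cells[np.ix_(keep_r, keep_c)],
            self.biozone,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.species_ids, columns=self.site_ids)

    def to_long(self) -> pd.DataFrame:
        """Long-format (species_id, site_id) table of presences."""
        rows, cols = np.nonzero(self.cells)
        return pd.DataFrame(
            {
                "species_id": np.asarray(self.species_ids, dtype=object)[rows],
                "site_id": np.asarray(self.site_ids, dtype=object)[cols],
            }
        )


@dataclass
class Dataset:
    """All inputs to a run: sites, per-biozone matrices and the trait table."""

    sites: list[Site]
    mammal_matrices: dict[str, OccurrenceMatrix]
    floral_matrices: dict[str, OccurrenceMatrix]
    traits: pd.DataFrame  # columns: species_id, ln_mass

    def sites_of_kind(self, kind: str) -> list[Site]:
        return [s for s in self.sites if s.kind == kind]


@dataclass
class ValidationReport:
    """Report-only consistency check; downstream stages refuse fatal reports."""

    dropped_species: dict[str, list[str]] = field(default_factory=dict)
    dropped_sites: dict[str, list[str]] = field(default_factory=dict)
    missing_traits: list[str] = field(default_factory=list)
    bins_without_flora: list[str] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return bool(self.bins_without_flora)

    @property
    def empty(self) -> bool:
        return not (
            self.dropped_species or self.dropped_sites
            or self.missing_traits or self.bins_without_flora
        )


def read_sites(path: str | Path) -> list[Site]:
    """Read the site metadata CSV (site_id, lat, lon, biozone, kind)."""
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "lat", "lon", "biozone", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty site table")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"{path}: duplicate site_ids {dups[:5]}")
    return [
        Site(r.site_id, float(r.lat), float(r.lon), r.biozone, r.kind)
        for r in df.itertuples()
    ]


def _matrices_from_records(
    df: pd.DataFrame, sites: list[Site], kind: str
) -> dict[str, OccurrenceMatrix]:
    site_map = {s.site_id: s for s in sites if s.kind == kind}
    unknown = ~df["site_id"].isin(site_map)
    if unknown.any():
        row = df.index[unknown][0]
        raise ValueError(
            f"record {row}: site_id {df.loc[row, 'site_id']!r} not a known {kind} site"
        )
    df = df.drop_duplicates(["species_id", "site_id"])
    df = df.assign(biozone=df["site_id"].map(lambda s: site_map[s].biozone))
    out: dict[str, OccurrenceMatrix] = {}
    for bin_label, sub in df.groupby("biozone"):
        sp = sorted(sub["species_id"].unique())
        si = sorted(sub["site_id"].unique())
        cells = np.zeros((len(sp), len(si)), dtype=np.int8)
        spi = {s: i for i, s in enumerate(sp)}
        sii = {s: i for i, s in enumerate(si)}
        for r in sub.itertuples():
            cells[spi[r.species_id], sii[r.site_id]] = 1
        out[bin_label] = OccurrenceMatrix(sp, si, cells, bin_label).validated()
    return out


def read_occurrences(
    path: str | Path, sites: list[Site], kind: str
) -> dict[str, OccurrenceMatrix]:
    """Read a long-format occurrence CSV (species_id, site_id) into one
    binary matrix per biozone. Duplicate records collapse to one presence;
    rows and columns are sorted lexicographically."""
    df = pd.read_csv(path, dtype=str)
    for col in ("species_id", "site_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: empty occurrence table")
    return _matrices_from_records(df[["species_id", "site_id"]], sites, kind)


def read_wide_occurrences(
    path: str | Path, sites: list[Site], kind: str
) -> dict[str, OccurrenceMatrix]:
    """Convenience reader for a wide site-by-species CSV (first column
    site_id, remaining columns species with 0/1 cells); same post-conditions
    as :func:`read_occurrences`."""
    df = pd.read_csv(path, dtype={"site_id": str}).set_index("site_id")
    long = df.stack().reset_index()
    long.columns = ["site_id", "species_id", "present"]
    long = long[long["present"].astype(int) == 1]
    if long.empty:
        raise ValueError(f"{path}: no presences in wide table")
    return _matrices_from_records(long[["species_id", "site_id"]], sites, kind)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read the trait CSV (species_id, ln_mass_g) into a (species_id,
    ln_mass) frame. Masses are natural-log grams."""
    df = pd.read_csv(path, dtype={"species_id": str})
    for col in ("species_id", "ln_mass_g"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["species_id"].duplicated().any():
        raise ValueError(f"{path}: more than one record for some species")
    out = df.rename(columns={"ln_mass_g": "ln_mass"})[["species_id", "ln_mass"]]
    if not np.isfinite(out["ln_mass"]).all():
        raise ValueError(f"{path}: non-finite ln_mass values")
    return out.sort_values("species_id", ignore_index=True)


def write_matrix(m: OccurrenceMatrix, path: str | Path) -> None:
    """Write one matrix as a wide CSV; exact round-trip with read_matrix."""
    m.to_frame().to_csv(path, index_label="species_id")


def read_matrix(path: str | Path, biozone: str) -> OccurrenceMatrix:
    df = pd.read_csv(path, index_col="species_id")
    return OccurrenceMatrix(
        [str(s) for s in df.index], [str(s) for s in df.columns],
        df.to_numpy(dtype=np.int8), biozone,
    )


def write_sites(sites: list[Site], path: str | Path) -> None:
    pd.DataFrame(
        [(s.site_id, s.lat, s.lon, s.biozone, s.kind) for s in sites],
        columns=["site_id", "lat", "lon", "biozone", "kind"],
    ).to_csv(path, index=False)


def write_occurrences(matrices: dict[str, OccurrenceMatrix], path: str | Path) -> None:
    """Write per-biozone matrices as one long-format CSV."""
    parts = [matrices[b].to_long() for b in sorted(matrices, key=BIOZONE_ORDER.get)]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename(columns={"ln_mass": "ln_mass_g"}).to_csv(path, index=False)


def load_dataset(
    sites_path: str | Path,
    mammal_path: str | Path,
    floral_path: str | Path,
    traits_path: str | Path,
) -> Dataset:
    sites = read_sites(sites_path)
    return Dataset(
        sites=sites,
        mammal_matrices=read_occurrences(mammal_path, sites, "mammal"),
        floral_matrices=read_occurrences(floral_path, sites, "palynofloral"),
        traits=read_traits(traits_path),
    )


def validate_dataset(d: Dataset) -> ValidationReport:
    """Consistency report: empty rows/columns that validation would drop,
    species lacking trait records, and mammal biozones without any
    contemporaneous palynofloral site (fatal for habitat assignment)."""
    rep = ValidationReport()
    for label, m in d.mammal_matrices.items():
        rt, ct = m.row_totals, m.col_totals
        dr = [s for s, t in zip(m.species_ids, rt) if t == 0]
        dc = [s for s, t in zip(m.site_ids, ct) if t == 0]
        if dr:
            rep.dropped_species[label] = dr
        if dc:
            rep.dropped_sites[label] = dc
    trait_sp = set(d.traits["species_id"])
    seen = set()
    for m in d.mammal_matrices.values():
        seen.update(m.species_ids)
    rep.missing_traits = sorted(seen - trait_sp)
    floral_bins = {s.biozone for s in d.sites if s.kind == "palynofloral"}
    rep.bins_without_flora = sorted(
        (set(d.mammal_matrices) - floral_bins), key=BIOZONE_ORDER.get
    )
    return rep


def first_occurrence_bin(
    species_id: str, mammal_matrices: dict[str, OccurrenceMatrix]
) -> str:
    """Oldest biozone in which the species has at least one occurrence."""
    for label in sorted(mammal_matrices, key=BIOZONE_ORDER.get):
        m = mammal_matrices[label]
        if species_id in m.species_ids:
            i = m.species_ids.index(species_id)
            if m.row_totals[i] >= 1:
                return label
    raise ValueError(f"species {species_id!r} occurs in no biozone")


def pooled_matrix(matrices: dict[str, OccurrenceMatrix], label: str = "pooled") -> OccurrenceMatrix:
    """Union matrix over all biozones (species union x concatenated sites).

    Site columns keep their per-biozone identity (site ids are unique across
    bins), ordered by biozone then lexicographically.
    """
    species = sorted(set().union(*(m.species_ids for m in matrices.values())))
    spi = {s: i for i, s in enumerate(species)}
    site_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for b in sorted(matrices, key=BIOZONE_ORDER.get):
        m = matrices[b]
        block = np.zeros((len(species), m.n_sites), dtype=np.int8)
        idx = [spi[s] for s in m.species_ids]
        block[idx, :] = m.cells
        blocks.append(block)
        site_ids.extend(m.site_ids)
    return OccurrenceMatrix(species, site_ids, np.hstack(blocks), label)
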