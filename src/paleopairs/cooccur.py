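"""Pairwise co-occurrence analysis (scaled C-scores and fixed-fixed nulls).

For a species pair (i, j) with occupancies R_i, R_j and D shared sites, the
scaled C-score is

    C_ij = (R_i - D) (R_j - D) / (R_i R_j)

ranging from 0.0 (complete aggregation: identical site sets) to 1.0
(complete segregation: disjoint site sets). Significance is assessed against
a fixed-fixed null: the observed matrix is randomised by sequential 2x2
checkerboard swaps, which preserve every row and column total exactly, and
the null distribution of each pair's C-score is accumulated along a single
thinned chain. Because row totals are invariant along the chain, a pair's
C-score is a strictly decreasing function of D, so null-tail counts are
computed exactly on the integer shared-site counts.

p-values use add-one Monte-Carlo counting (the observed matrix counts as one
realisation of its own null), two one-sided tests per pair:
``p_agg = (1 + #{null C <= obs}) / (1 + n_null)`` and symmetrically for
segregation. A pair is aggregated if p_agg <= alpha, segregated if
p_seg <= alpha, random otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class NullEngineConfig:
    """Settings for the swap-null engine.

    burn_in_swaps / thin_swaps count *attempted* swaps and default to
    10x and 1x the number of presences in the matrix respectively.
    n_null below ~100 gives too coarse a p-value lattice for inference and
    is warned about.
    """

    n_null: int = 1000
    burn_in_swaps: int | None = None
    thin_swaps: int | None = None
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.n_null < 100:
            logger.warning("n_null=%d is small; p-values will be coarse", self.n_null)
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    def replace(self, **kw) -> "NullEngineConfig":
        d = dict(n_null=self.n_null, burn_in_swaps=self.burn_in_swaps,
                 thin_swaps=self.thin_swaps, seed=self.seed, alpha=self.alpha)
        d.update(kw)
        return NullEngineConfig(**d)


def c_score(r_i: int, r_j: int, d: int) -> float:
    """Scaled C-score (R_i - D)(R_j - D) / (R_i R_j); symmetric in i, j."""
    if r_i < 1 or r_j < 1:
        raise ValueError("row totals must be >= 1")
    if d < 0 or d > min(r_i, r_j):
        raise ValueError(f"shared-site count D={d} outside [0, min(R_i, R_j)]")
    return (r_i - d) * (r_j - d) / (r_i * r_j)


def _rows_as_lists(cells: np.ndarray) -> list[list[int]]:
    return [list(map(int, row)) for row in cells]


def _attempt_swaps(
    rows: list[list[int]],
    n_attempts: int,
    rng: np.random.Generator,
    max_accept: int | None = None,
) -> int:
    """Run ``n_attempts`` proposed checkerboard swaps in place; returns the
    number accepted (stopping early once ``max_accept`` swaps succeed, if
    given). Proposals draw two rows and two columns uniformly; the 2x2
    submatrix is swapped iff it is a checkerboard, which conserves all
    marginals. The proposal kernel is symmetric, so the chain's stationary
    distribution is uniform over matrices with the observed marginals."""
    n_r = len(rows)
    n_c = len(rows[0]) if n_r else 0
    if n_r < 2 or n_c < 2 or n_attempts <= 0:
        return 0
    rs = rng.integers(0, n_r, size=2 * n_attempts).tolist()
    cs = rng.integers(0, n_c, size=2 * n_attempts).tolist()
    accepted = 0
    k2 = 0
    for _ in range(n_attempts):
        r1 = rs[k2]
        r2 = rs[k2 + 1]
        c1 = cs[k2]
        c2 = cs[k2 + 1]
        k2 += 2
        if r1 == r2 or c1 == c2:
            continue
        a = rows[r1]
        b = rows[r2]
        x11 = a[c1]
        x22 = b[c2]
        if x11 != x22:
            continue
        x12 = a[c2]
        if x12 != b[c1] or x11 == x12:
            continue
        a[c1] = x12
        a[c2] = x11
        b[c1] = x11
        b[c2] = x12
        accepted += 1
        if max_accept is not None and accepted >= max_accept:
            break
    return accepted


def swap_null_matrix(m: OccurrenceMatrix, n_swaps: int, seed: int) -> OccurrenceMatrix:
    """Return a randomised copy of ``m`` after ``n_swaps`` *accepted*
    checkerboard swaps (marginals conserved exactly; deterministic given
    seed). A matrix with no swappable checkerboard (e.g. a single row or
    column) is returned unchanged with a logged note."""
    if m.n_species < 2 or m.n_sites < 2:
        logger.info("%s: no checkerboards possible; returning matrix unchanged", m.biozone)
        return m.copy()
    rng = np.random.default_rng(seed)
    rows = _rows_as_lists(m.cells)
    remaining = n_swaps
    attempts_left = max(10_000, 500 * max(n_swaps, 1))
    block = max(64, 4 * n_swaps)
    while remaining > 0 and attempts_left > 0:
        n = min(block, attempts_left)
        got = _attempt_swaps(rows, n, rng, max_accept=remaining)
        attempts_left -= n
        remaining -= got
    if remaining > 0:
        logger.info(
            "%s: attempt budget exhausted with %d/%d swaps accepted "
            "(matrix may admit no checkerboard)", m.biozone, n_swaps - remaining, n_swaps
        )
    return OccurrenceMatrix(
        list(m.species_ids), list(m.site_ids),
        np.array(rows, dtype=np.int8), m.biozone,
    )


#: integer codes used by the array-level classifier
CLS_LABELS = np.array(["random", "aggregated", "segregated"], dtype=object)


def classify_core(cells: np.ndarray, cfg: NullEngineConfig) -> dict[str, np.ndarray]:
    """Array-level pair classification for a validated binary matrix.

    Returns upper-triangle pair arrays: row indices ``i``/``j``, occupancy
    ``R_i``/``R_j``, shared-site counts ``D``, ``c_score``, ``p_agg``,
    ``p_seg`` and integer ``cls`` codes (0 random, 1 aggregated,
    2 segregated). Used directly by the richness-preserving null, which
    reclassifies thousands of randomised matrices.
    """
    cells = np.asarray(cells, dtype=np.int8)
    S, T = cells.shape
    if S < 2 or T < 2:
        raise ValueError("need at least 2 species and 2 sites to classify pairs")
    r = cells.sum(axis=1).astype(np.int64)
    if (r < 1).any() or (cells.sum(axis=0) < 1).any():
        raise ValueError("matrix must be validated (no empty rows/columns)")

    x0 = cells.astype(np.float32)
    d_obs = np.rint(x0 @ x0.T).astype(np.int32)
    presences = int(cells.sum())
    burn = cfg.burn_in_swaps if cfg.burn_in_swaps is not None else 10 * presences
    thin = cfg.thin_swaps if cfg.thin_swaps is not None else presences

    rng = np.random.default_rng(cfg.seed)
    rows = _rows_as_lists(cells)
    _attempt_swaps(rows, burn, rng)

    ge = np.zeros((S, S), dtype=np.int32)  # null D >= observed D (aggregation tail)
    le = np.zeros((S, S), dtype=np.int32)  # null D <= observed D (segregation tail)
    for _ in range(cfg.n_null):
        _attempt_swaps(rows, thin, rng)
        x = np.asarray(rows, dtype=np.float32)
        d_null = np.rint(x @ x.T).astype(np.int32)
        ge += d_null >= d_obs
        le += d_null <= d_obs

    iu = np.triu_indices(S, k=1)
    r_i = r[iu[0]]
    r_j = r[iu[1]]
    d = d_obs[iu].astype(np.int64)
    # C-score is strictly decreasing in D at fixed marginals, so the null
    # tail counts on D are exact tail counts on the C-score.
    c = (r_i - d) * (r_j - d) / (r_i * r_j)
    p_agg = (1.0 + ge[iu]) / (1.0 + cfg.n_null)
    p_seg = (1.0 + le[iu]) / (1.0 + cfg.n_null)

    agg = p_agg <= cfg.alpha
    seg = p_seg <= cfg.alpha
    cls = np.zeros(len(d), dtype=np.int8)
    cls[agg & ~seg] = 1
    cls[seg & ~agg] = 2
    both = agg & seg
    if both.any():
        # degenerate nulls: the smaller p wins; exact ties stay random
        cls[both & (p_agg < p_seg)] = 1
        cls[both & (p_seg < p_agg)] = 2
        n_tied = int((both & (p_agg == p_seg)).sum())
        if n_tied:
            logger.info("%d pairs significant in both tails with tied p; "
                        "classified random", n_tied)
    return {
        "i": iu[0], "j": iu[1], "R_i": r_i, "R_j": r_j, "D": d,
        "c_score": c, "p_agg": p_agg, "p_seg": p_seg, "cls": cls,
    }


def classify_pairs(m: OccurrenceMatrix, cfg: NullEngineConfig) -> pd.DataFrame:
    """Classify every unordered species pair of one biozone's matrix.

    Returns a DataFrame with one row per pair (species_i < species_j
    lexicographically): R_i, R_j, D, c_score, p_agg, p_seg, classification,
    biozone. Deterministic given ``cfg.seed``.
    """
    core = classify_core(m.cells, cfg)
    sp = np.asarray(m.species_ids, dtype=object)
    sp_i, sp_j = sp[core["i"]], sp[core["j"]]
    r_i, r_j = core["R_i"].copy(), core["R_j"].copy()
    flip = sp_i > sp_j  # keep species_i < species_j even for unsorted input
    sp_i[flip], sp_j[flip] = sp_j[flip], sp_i[flip].copy()
    r_i[flip], r_j[flip] = r_j[flip], r_i[flip].copy()
    return pd.DataFrame(
        {
            "species_i": sp_i,
            "species_j": sp_j,
            "R_i": r_i,
            "R_j": r_j,
            "D": core["D"],
            "c_score": core["c_score"],
            "p_agg": core["p_agg"],
            "p_seg": core["p_seg"],
            "classification": CLS_LABELS[core["cls"]],
            "biozone": m.biozone,
        }
    )


def pair_census(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of aggregated / segregated / random pairs per biozone
    (total_significant = aggregated + segregated)."""
    from .occurrences import BIOZONE_ORDER

    rows = []
    for label in sorted(results, key=lambda b: BIOZONE_ORDER.get(b, 99)):
        df = results[label]
        counts = df["classification"].value_counts()
        n_agg = int(counts.get("aggregated", 0))
        n_seg = int(counts.get("segregated", 0))
        n_rand = int(counts.get("random", 0))
        rows.append(
            {
                "biozone": label,
                "aggregated": n_agg,
                "segregated": n_seg,
                "random": n_rand,
                "total_significant": n_agg + n_seg,
                "total_pairs": len(df),
            }
        )
    return pd.DataFrame(rows)
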