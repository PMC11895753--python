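"""Palynofloral ordination: composition distances, NMDS and PERMANOVA.

Palynofloral site compositions (binary taxon lists) are compared with the
Jaccard distance 1 - |A∩B| / |A∪B| (or, as a replicate analysis, the cosine
distance 1 - D / sqrt(R_s R_t) on binary vectors). The distance matrix is
embedded in two dimensions by nonmetric multidimensional scaling minimising
Kruskal stress-1, and compositional differences among biozones are tested
with a distance-based PERMANOVA (pseudo-F, label-permutation p-values,
pairwise comparisons Bonferroni-corrected).

Axis orientation convention: NMDS solutions are determined only up to
rotation and reflection, so the best configuration is centred, rotated to
its principal axes, and each axis is sign-fixed so that the lexicographically
smallest site id (with a non-negligible score) scores non-negative. Any
downstream per-axis quantity is therefore deterministic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .occurrences import OccurrenceMatrix

logger = logging.getLogger(__name__)

#: Conventional interpretability limit for Kruskal stress-1.
STRESS_LIMIT = 0.2

METRICS = ("jaccard", "cosine")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over sites with zero diagonal."""

    site_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match site_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if self.metric == "jaccard" and (self.values > 1.0 + 1e-12).any():
            raise ValueError("jaccard distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def jaccard_distances(m: OccurrenceMatrix, metric: str = "jaccard") -> DistanceMatrix:
    """Distance matrix over the sites (columns) of a composition matrix.

    ``metric='jaccard'`` gives 1 - |A∩B|/|A∪B| on taxon sets;
    ``metric='cosine'`` gives 1 - D/sqrt(R_s R_t) on the binary vectors.
    Every site must contain at least one taxon.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = m.cells.T.astype(bool)  # sites x taxa
    empties = [s for s, k in zip(m.site_ids, x.any(axis=1)) if not k]
    if empties:
        raise ValueError(f"sites with empty composition: {empties[:5]}")
    vals = squareform(pdist(x, metric=metric))
    return DistanceMatrix(list(m.site_ids), vals, metric)


@dataclass
class OrdinationResult:
    site_ids: list[str]
    scores: np.ndarray  # (n_sites, n_dims), centred, principal-axis rotated
    stress: float  # Kruskal stress-1
    n_restarts_used: int
    seed: int

    @property
    def stress_ok(self) -> bool:
        return self.stress < STRESS_LIMIT

    def to_frame(self) -> pd.DataFrame:
        cols = {f"NMDS{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"site_id": self.site_ids, **cols})


def _orient(scores: np.ndarray, site_ids: list[str]) -> np.ndarray:
    """Centre, rotate to principal axes and sign-fix each axis."""
    x = scores - scores.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    order = np.argsort(np.asarray(site_ids, dtype=object))
    for ax in range(x.shape[1]):
        for i in order:
            if abs(x[i, ax]) > 1e-12:
                if x[i, ax] < 0:
                    x[:, ax] = -x[:, ax]
                break
    return x


def _pav_disparities(ranks: np.ndarray, dist: np.ndarray, ir: IsotonicRegression) -> np.ndarray:
    """Monotone-regression disparities for the current configuration.

    Kruskal's primary tie approach: pairs are ordered by dissimilarity rank
    with ties broken by the current configuration distances, so tied
    dissimilarities impose no order constraint among themselves.
    """
    order = np.lexsort((dist, ranks))
    m = len(dist)
    fitted = ir.fit_transform(np.arange(m, dtype=float), dist[order])
    dhat = np.empty(m)
    dhat[order] = fitted
    return dhat


def _smacof_nonmetric(
    ranks: np.ndarray, n: int, n_dims: int, max_iter: int, tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One SMACOF run from a random start; returns (scores, stress-1).

    The dissimilarities enter only through their ranks, so the whole
    trajectory — and hence the stress — is invariant to any strictly
    increasing transform of the input distances.
    """
    iu = np.triu_indices(n, k=1)
    ir = IsotonicRegression()
    x = rng.uniform(size=(n, n_dims))
    dist_mat = squareform(pdist(x))
    old = None
    stress1 = np.inf
    for _ in range(max_iter):
        dist = dist_mat[iu]
        dhat = _pav_disparities(ranks, dist, ir)
        # fix the disparity scale (Guttman transform is scale-coupled)
        dhat = dhat * np.sqrt(len(dhat) / (dhat**2).sum())
        full = np.zeros((n, n))
        full[iu] = dhat
        full = full + full.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_mat > 0, full / np.where(dist_mat > 0, dist_mat, 1.0), 0.0)
        b = -ratio
        b[np.diag_indices(n)] += ratio.sum(axis=1)
        x = (b @ x) / n
        dist_mat = squareform(pdist(x))
        dist = dist_mat[iu]
        stress1 = float(np.sqrt(((dist - dhat) ** 2).sum() / (dist**2).sum()))
        if old is not None and old - stress1 < tol:
            break
        old = stress1
    return x, stress1


def nmds(
    d: DistanceMatrix,
    n_dims: int = 2,
    n_restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Nonmetric MDS minimising Kruskal stress-1 (monotone regression on
    ranks, primary tie handling), best of ``n_restarts`` random
    initialisations; deterministic given ``seed``. Sites are processed in a
    canonical (lexicographic) order internally, so the result is invariant
    to the input ordering; stress depends on the dissimilarities only
    through their ranks, so any strictly increasing transform of the input
    leaves it unchanged."""
    if d.n < 4:
        raise ValueError("need at least 4 sites for a 2-D ordination")
    if np.allclose(d.condensed(), 0.0):
        raise ValueError("degenerate: all sites identical (all-zero distances)")

    canon = np.argsort(np.asarray(d.site_ids, dtype=object))
    vals = d.values[np.ix_(canon, canon)]
    iu = np.triu_indices(d.n, k=1)
    # tied dissimilarities share a rank (so tie handling is well defined)
    cond = vals[iu]
    order = np.argsort(cond, kind="stable")
    tie_rank = np.empty(len(cond))
    r = 0
    for k, idx in enumerate(order):
        if k > 0 and cond[idx] != cond[order[k - 1]]:
            r = k
        tie_rank[idx] = r
    ranks = tie_rank

    best_stress = np.inf
    best_scores = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        scores, stress = _smacof_nonmetric(ranks, d.n, n_dims, max_iter, tol, rng)
        if stress < best_stress:
            best_stress = stress
            best_scores = scores

    inverse = np.empty_like(canon)
    inverse[canon] = np.arange(d.n)
    sorted_ids = [d.site_ids[i] for i in canon]
    oriented = _orient(best_scores, sorted_ids)[inverse]
    return OrdinationResult(
        site_ids=list(d.site_ids),
        scores=oriented,
        stress=float(best_stress),
        n_restarts_used=n_restarts,
        seed=seed,
    )


@dataclass
class PermanovaResult:
    grouping: list[str]
    F: float
    p: float
    n_perm: int
    pairwise: pd.DataFrame  # group_a, group_b, F, p_raw, p_bonferroni


def _pseudo_f(d2: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> float:
    """Distance-based pseudo-F from squared distances and a one-hot group
    matrix: (SS_between/(k-1)) / (SS_within/(n-k))."""
    n = d2.shape[0]
    k = onehot.shape[1]
    ss_total = d2.sum() / (2.0 * n)
    within_by_group = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / (2.0 * counts)
    ss_within = within_by_group.sum()
    ss_between = ss_total - ss_within
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def _one_test(d2: np.ndarray, codes: np.ndarray, k: int,
              n_perm: int, rng: np.random.Generator) -> tuple[float, float]:
    counts = np.bincount(codes, minlength=k).astype(float)
    onehot = np.zeros((len(codes), k))
    onehot[np.arange(len(codes)), codes] = 1.0
    f_obs = _pseudo_f(d2, onehot, counts)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        if _pseudo_f(d2, onehot[perm], counts) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return f_obs, p


def permanova(
    d: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA on a distance matrix with whole-site label permutation.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Pairwise two-group tests
    are run for every group pair and Bonferroni-corrected by the number of
    pairwise tests. Every group needs >= 2 members.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != d.n:
        raise ValueError("one group label per site required")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    small = labels[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 sites: {list(small)}")

    d2 = d.values**2
    rng = np.random.default_rng(seed)
    f_obs, p = _one_test(d2, codes, k, n_perm, rng)

    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    rows = []
    for idx, (a, b) in enumerate(pairs):
        mask = (groups == a) | (groups == b)
        sub2 = d2[np.ix_(mask, mask)]
        sub_codes = (groups[mask] == b).astype(int)
        rng_pair = np.random.default_rng([seed, idx])
        f_ab, p_ab = _one_test(sub2, sub_codes, 2, n_perm, rng_pair)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": f_ab,
                "p_raw": p_ab,
                "p_bonferroni": min(1.0, p_ab * len(pairs)),
            }
        )
    return PermanovaResult(
        grouping=list(groups), F=float(f_obs), p=float(p),
        n_perm=n_perm, pairwise=pd.DataFrame(rows),
    )
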