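"""Condition-level functional network inference from c-Fos density cohorts.

Within one condition, two regions are functionally connected when their
densities covary across animals.  The pipeline is:

1. pairwise Spearman rank correlation across animals for every unordered
   region pair (pairwise-complete observations),
2. two-sided p-value per pair - by full permutation enumeration at small n
   (exact at the study's n = 8, where 8! = 40,320 rank assignments are
   enumerable) or by the t-distribution approximation at larger n,
3. significance thresholding at p < alpha (both signs kept as edges),
4. Fisher z-transform z = atanh(rho) of the significant *positive*
   coefficients as the edge connectivity strength.

No multiple-testing correction is applied by default (uncorrected p < 0.05
across the 435 default-atlas pairs); Benjamini-Hochberg is available as an
opt-in flag on :func:`threshold_network`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, NamedTuple

import numpy as np
from scipy import stats

from .atlas import Atlas, CohortTable

logger = logging.getLogger("cfosnet")

__all__ = [
    "CorrelationResult",
    "FunctionalNetwork",
    "Edge",
    "UndefinedCorrelationError",
    "spearman_pair",
    "correlation_matrix",
    "fisher_z",
    "threshold_network",
    "all_pairs_z",
]

PValueMethod = Literal["exact", "t_approx", "auto"]

#: largest n for which "auto" enumerates all n! rank assignments
EXACT_N_MAX = 9

_CLAMP = 1.0 - 1e-7


class UndefinedCorrelationError(ValueError):
    """A Spearman coefficient is undefined (constant input after pairwise
    deletion).  Callers computing full matrices record the pair as undefined
    rather than propagating."""


class Edge(NamedTuple):
    """One significant correlation: region pair, coefficient, p, sign."""

    region_i: str
    region_j: str
    rho: float
    p: float
    sign: int  # +1 / -1


# ---------------------------------------------------------------------------
# Spearman correlation with exact permutation p-values
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) integer array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@lru_cache(maxsize=8)
def _null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! equally likely untied rank assignments.

    For tie-free data the permutation null of Spearman's rho depends only on
    n, so the full two-sided null distribution is tabulated once per n and
    shared by every pair - this is what makes exact p-values at n = 8
    affordable across 435 pairs and hundreds of simulated cohorts.
    """
    base = np.arange(1, n + 1, dtype=np.int64)
    perms = base[_permutation_indices(n)]
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.sort(np.abs(rho))


def _exact_p_no_ties(rho: float, n: int) -> float:
    null = _null_abs_rho(n)
    idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float((null.size - idx) / null.size)


def _exact_p_with_ties(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Enumerate permutations of the observed (tied) rank vector ry."""
    n = rx.size
    perms = ry[_permutation_indices(n).astype(np.intp)]
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = math.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
    rho_null = pc @ rxc / denom
    return float((np.abs(rho_null) >= abs(rho_obs) - 1e-12).mean())


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_pair(
    x: np.ndarray, y: np.ndarray, method: PValueMethod = "auto"
) -> tuple[float, float, int]:
    """Spearman correlation between two density vectors.

    Pairs where either value is missing (NaN) are dropped first; ranks use
    the average-rank convention for ties.

    Parameters
    ----------
    x, y : array-like
        Density vectors of equal length (one entry per animal).
    method : {"exact", "t_approx", "auto"}
        Two-sided p-value method.  ``exact`` enumerates all n! rank
        assignments (permuting the observed, possibly tied, ranks);
        ``t_approx`` uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df;
        ``auto`` (default) selects ``exact`` for n <= 9.

    Returns
    -------
    (rho, p, n) : float, float, int
        Coefficient, two-sided p-value, and number of complete pairs used.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant after pairwise deletion.
    ValueError
        If fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete observation pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: Spearman rho undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ties = np.unique(rx).size < n or np.unique(ry).size < n
    if ties:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        # tie-free: exact rank-difference formula (integer arithmetic)
        d2 = float(((rx - ry) ** 2).sum())
        rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    rho = max(-1.0, min(1.0, rho))

    if method not in ("exact", "t_approx", "auto"):
        raise ValueError(f"unknown p-value method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        p = _exact_p_with_ties(rx, ry, rho) if ties else _exact_p_no_ties(rho, n)
    else:
        p = _t_approx_p(rho, n)
    return rho, p, n


# ---------------------------------------------------------------------------
# Full correlation matrices
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho / p-value matrices for one cohort.

    The diagonal is NaN by construction (a region's correlation with itself
    is not an edge); undefined pairs (constant input) are NaN in both
    matrices with ``n_pairs`` still recording the sample size.
    """

    atlas: Atlas = field(repr=False)
    rho: np.ndarray
    pvals: np.ndarray
    n_pairs: np.ndarray
    method: str
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("rho", "pvals", "n_pairs"):
            m = getattr(self, name)
            if m.shape != (len(self.atlas), len(self.atlas)):
                raise ValueError(f"{name} has shape {m.shape}, atlas has {len(self.atlas)}")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"{name} matrix must be symmetric")
        defined = ~np.isnan(self.rho)
        np.fill_diagonal(defined, False)
        if np.any(np.abs(self.rho[defined]) > 1 + 1e-12):
            raise ValueError("|rho| must be <= 1")
        if np.any(np.isnan(self.pvals[defined])):
            raise ValueError("p must be defined wherever rho is defined")

    def n_defined_pairs(self) -> int:
        iu = np.triu_indices(len(self.atlas), k=1)
        return int((~np.isnan(self.rho[iu])).sum())


def correlation_matrix(
    cohort: CohortTable, method: PValueMethod = "auto"
) -> CorrelationResult:
    """Pairwise Spearman correlation across animals for every region pair.

    Missing densities are handled by pairwise-complete deletion: each pair
    uses every animal with data for both regions, and ``n_pairs`` records
    the effective sample size.  Pairs whose correlation is undefined
    (constant region, or < 3 complete observations) are recorded as NaN
    with a logged warning, never as silent zeros.
    """
    if cohort.n_animals < 3:
        raise ValueError(f"need >= 3 animals for inference, got {cohort.n_animals}")
    X = cohort.densities
    d = X.shape[1]
    rho = np.full((d, d), np.nan)
    pvals = np.full((d, d), np.nan)
    n_pairs = np.zeros((d, d), dtype=int)
    codes = cohort.atlas.codes

    complete = not np.any(np.isnan(X))
    if complete:
        # rank once per column; rho for all pairs in one shot
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        constant = np.ptp(X, axis=0) == 0
        n = X.shape[0]
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(ranks, rowvar=False)
        # tie-free column pairs: exact rank-difference formula instead
        tie_free = np.array([np.unique(ranks[:, k]).size == n for k in range(d)])
        if np.any(tie_free):
            G = ranks.T @ ranks
            S = n * (n + 1) * (2 * n + 1) / 6.0  # sum of squared tie-free ranks
            rho_exact = 1.0 - 6.0 * (2.0 * S - 2.0 * G) / (n * (n * n - 1))
            C = np.where(np.outer(tie_free, tie_free), rho_exact, C)
        C = np.clip(C, -1.0, 1.0)
        use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
        any_ties = not bool(tie_free.all())
        for i in range(d):
            for j in range(i + 1, d):
                n_pairs[i, j] = n_pairs[j, i] = n
                if constant[i] or constant[j]:
                    logger.warning(
                        "undefined correlation (constant region): %s - %s",
                        codes[i], codes[j],
                    )
                    continue
                r = float(C[i, j])
                if use_exact:
                    if any_ties and not (tie_free[i] and tie_free[j]):
                        p = _exact_p_with_ties(ranks[:, i], ranks[:, j], r)
                    else:
                        p = _exact_p_no_ties(r, n)
                else:
                    p = _t_approx_p(r, n)
                rho[i, j] = rho[j, i] = r
                pvals[i, j] = pvals[j, i] = p
    else:
        for i in range(d):
            for j in range(i + 1, d):
                try:
                    r, p, n = spearman_pair(X[:, i], X[:, j], method=method)
                except (UndefinedCorrelationError, ValueError) as exc:
                    keep = ~(np.isnan(X[:, i]) | np.isnan(X[:, j]))
                    n_pairs[i, j] = n_pairs[j, i] = int(keep.sum())
                    logger.warning(
                        "undefined correlation %s - %s: %s", codes[i], codes[j], exc
                    )
                    continue
                rho[i, j] = rho[j, i] = r
                pvals[i, j] = pvals[j, i] = p
                n_pairs[i, j] = n_pairs[j, i] = n

    method_label = method
    if method == "auto":
        nmax = int(n_pairs.max()) if n_pairs.size else 0
        method_label = "exact" if nmax <= EXACT_N_MAX else "t_approx"
    return CorrelationResult(
        atlas=cohort.atlas,
        rho=rho,
        pvals=pvals,
        n_pairs=n_pairs,
        method=method_label,
        condition=cohort.condition,
    )


# ---------------------------------------------------------------------------
# Fisher z and thresholding
# ---------------------------------------------------------------------------


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform z = atanh(rho), the edge connectivity strength.

    Coefficients of exactly +/-1 are clamped to +/-(1 - 1e-7) before the
    transform (and the clamp logged); |rho| > 1 is an error.
    """
    arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(arr[~np.isnan(arr)]) > 1 + 1e-12):
        raise ValueError("|rho| must be <= 1")
    clipped = np.clip(arr, -_CLAMP, _CLAMP)
    n_clamped = int((np.abs(arr[~np.isnan(arr)]) > _CLAMP).sum())
    if n_clamped:
        logger.info("fisher_z: clamped %d coefficient(s) at |rho|=1", n_clamped)
    z = np.arctanh(clipped)
    return float(z) if np.isscalar(rho) or arr.ndim == 0 else z


@dataclass
class FunctionalNetwork:
    """Significance-thresholded signed network for one condition.

    ``edges`` holds every pair with p < alpha, both signs; ``z_weights`` is
    the symmetric non-negative matrix of Fisher-z strengths, populated only
    for significant *positive* edges (zero elsewhere, zero diagonal) - the
    weighted graph all graph metrics are computed on.
    """

    atlas: Atlas = field(repr=False)
    edges: list[Edge]
    z_weights: np.ndarray
    alpha: float
    condition: str = ""

    def __post_init__(self) -> None:
        d = len(self.atlas)
        if self.z_weights.shape != (d, d):
            raise ValueError("z_weights shape mismatch with atlas")
        if not np.allclose(self.z_weights, self.z_weights.T):
            raise ValueError("z_weights must be symmetric")
        if np.any(np.diag(self.z_weights) != 0):
            raise ValueError("z_weights diagonal must be zero")
        if np.any(self.z_weights < 0):
            raise ValueError("z_weights must be non-negative")
        for e in self.edges:
            if not e.p < self.alpha:
                raise ValueError(f"edge {e} fails p < alpha={self.alpha}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((e.region_i, e.region_j)) for e in self.edges}


def threshold_network(
    corr: CorrelationResult,
    atlas: Atlas | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> FunctionalNetwork:
    """Threshold a correlation matrix into the condition functional network.

    Edges are the pairs with (strictly) p < ``alpha``, both positive and
    negative; Fisher-z weights are assigned to positive edges only.  With
    ``fdr=True`` the p-values are Benjamini-Hochberg adjusted across all
    defined pairs before thresholding (off by default).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    atlas = atlas if atlas is not None else corr.atlas
    d = len(atlas)
    pvals = corr.pvals.copy()
    if fdr:
        iu = np.triu_indices(d, k=1)
        flat = pvals[iu]
        defined = ~np.isnan(flat)
        adj = flat.copy()
        adj[defined] = stats.false_discovery_control(flat[defined], method="bh")
        pvals = np.full_like(pvals, np.nan)
        pvals[iu] = adj
        pvals = np.where(np.isnan(pvals), pvals.T, pvals)

    edges: list[Edge] = []
    z_weights = np.zeros((d, d))
    codes = atlas.codes
    for i in range(d):
        for j in range(i + 1, d):
            p = pvals[i, j]
            r = corr.rho[i, j]
            if np.isnan(p) or np.isnan(r) or not p < alpha:
                continue
            sign = 1 if r > 0 else -1
            edges.append(Edge(codes[i], codes[j], float(r), float(p), sign))
            if sign > 0:
                z = float(fisher_z(r))
                z_weights[i, j] = z_weights[j, i] = z
    return FunctionalNetwork(
        atlas=atlas,
        edges=edges,
        z_weights=z_weights,
        alpha=alpha,
        condition=corr.condition,
    )


def all_pairs_z(corr: CorrelationResult) -> np.ndarray:
    """Fisher-z connectivity strength for ALL region pairs (no threshold).

    Returns atanh(rho) for every unordered pair in atlas (upper-triangle)
    order - 435 values for the default atlas - both signs included and no
    significance filter, as used by the total-connectivity contrast between
    conditions.  Undefined pairs are excluded with a logged warning.
    """
    d = len(corr.atlas)
    iu = np.triu_indices(d, k=1)
    rho = corr.rho[iu]
    defined = ~np.isnan(rho)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning("all_pairs_z: excluding %d undefined pair(s)", n_undef)
    return np.asarray(fisher_z(rho[defined]), dtype=float)
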