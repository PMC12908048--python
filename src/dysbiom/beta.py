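"""Beta diversity: Bray–Curtis distances, PCoA, PERMANOVA and BETADISPER.

PERMANOVA follows the one-factor distance decomposition

    SS_total  = (1/n) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = (SS_between / (k-1)) / (SS_within / (n-k)),   R^2 = SS_between/SS_total

with the permutation p-value using the add-one convention
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never 0. When the number
of distinct label assignments is small (<= ``max_exact``) the permutation
distribution is enumerated exactly and p is the exact tail proportion.

BETADISPER embeds the distance matrix by PCoA (negative eigenvalues retained:
axes with negative eigenvalues contribute *negatively* to squared distances,
the standard correction), computes each sample's distance to its group
centroid (spatial median by default, mean by flag), and permutes group
membership of those dispersion distances under a one-way F statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import AbundanceTable, DistanceMatrix, ValidationError

__all__ = [
    "PermTestResult",
    "Ordination",
    "bray_curtis",
    "pcoa",
    "permanova",
    "betadisper",
]

_EIG_TOL = 1e-9


@dataclass
class PermTestResult:
    statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str
    exact: bool = False


@dataclass
class Ordination:
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # length k, descending (may be negative)
    proportion_explained: np.ndarray  # length k


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC(x, y) = sum|x-y| / sum(x+y)."""
    vals = table.values
    if (vals.sum(axis=1) <= 0).any():
        raise ValidationError("all-zero row in abundance table")
    d = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, metric="braycurtis")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _gower_eig(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the double-centered -D^2/2 matrix, descending."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa(dm: DistanceMatrix, k: int | None = None) -> Ordination:
    """Principal-coordinates analysis.

    ``coordinates`` holds the first ``k`` axes; ``eigenvalues`` always holds
    the full spectrum so negative eigenvalues (non-Euclidean distance
    matrices) are reported, never silently dropped. ``proportion_explained``
    is relative to the sum of positive eigenvalues.
    """
    n = dm.n_samples
    if k is None:
        k = n - 1
    if not (0 < k < n):
        raise ValidationError(f"k must satisfy 0 < k < n (k={k}, n={n})")
    eigvals, eigvecs = _gower_eig(dm.values)
    pos = np.clip(eigvals, 0.0, None)
    coords = eigvecs * np.sqrt(pos)[None, :]
    total_pos = pos.sum()
    prop = pos / total_pos if total_pos > 0 else np.zeros_like(pos)
    return Ordination(coords[:, :k], eigvals, prop)


def _corrected_embedding(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real- and imaginary-axis coordinates for a possibly non-Euclidean dm."""
    eigvals, eigvecs = _gower_eig(d)
    scale = eigvals.max() if eigvals.size else 1.0
    tol = _EIG_TOL * max(scale, 1.0)
    real = eigvecs[:, eigvals > tol] * np.sqrt(eigvals[eigvals > tol])[None, :]
    imag = eigvecs[:, eigvals < -tol] * np.sqrt(-eigvals[eigvals < -tol])[None, :]
    return real, imag


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _check_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups (constant labels)")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(groups[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValidationError(f"each group needs >= 2 samples; too small: {small}")
    return codes, sizes


def _pseudo_f(d2: np.ndarray, code_rows: np.ndarray, k: int, ss_total: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pseudo-F over rows of group codes (each row one labelling)."""
    n = d2.shape[0]
    ss_within = np.zeros(code_rows.shape[0])
    for g in range(k):
        b = (code_rows == g).astype(float)
        n_g = b[0].sum()  # group sizes fixed across permutations
        ss_within += np.einsum("pi,ij,pj->p", b, d2, b) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - k)
    numer = ss_between / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = numer / denom
    f = np.where(denom <= 1e-300, np.where(np.abs(numer) <= 1e-12, 0.0, np.inf), f)
    return f, ss_between


def _enumerate_assignments(codes: np.ndarray, sizes: np.ndarray) -> np.ndarray | None:
    """All distinct label assignments, or None if there are too many."""
    n = codes.size
    k = sizes.size
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    if total > 10_000:
        return None
    if k == 2:
        n1 = int(sizes[1])
        rows = np.zeros((total, n), dtype=np.int8)
        for r, idx in enumerate(combinations(range(n), n1)):
            rows[r, list(idx)] = 1
        return rows

    rows = []

    def assign(positions: tuple[int, ...], row: np.ndarray, g: int) -> None:
        if g == k - 1:
            row = row.copy()
            row[list(positions)] = g
            rows.append(row)
            return
        for chosen in combinations(positions, int(sizes[g])):
            nxt = row.copy()
            nxt[list(chosen)] = g
            assign(tuple(p for p in positions if p not in chosen), nxt, g + 1)

    assign(tuple(range(n)), np.zeros(n, dtype=np.int8), 0)
    return np.array(rows, dtype=np.int8)


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    max_exact: int = 10_000,
) -> PermTestResult:
    """One-factor PERMANOVA on a distance matrix.

    Exact enumeration of all distinct assignments is used automatically when
    their number is at most ``max_exact``; otherwise ``n_perm`` Monte-Carlo
    label permutations with the add-one p-value convention. Ties
    (F_perm == F_obs) count toward p.
    """
    codes, sizes = _check_groups(labels)
    k = sizes.size
    n = dm.n_samples
    if codes.size != n:
        raise ValidationError("labels length does not match distance matrix")
    d2 = dm.values**2
    ss_total = d2.sum() / (2.0 * n)

    f_obs_arr, ssb = _pseudo_f(d2, codes[None, :], k, ss_total)
    f_obs = float(f_obs_arr[0])
    r2 = float(ssb[0] / ss_total) if ss_total > 0 else 0.0

    if ss_total <= 1e-300:  # all samples identical: degenerate, documented
        return PermTestResult(0.0, 0.0, 1.0, 0, seed, "permanova", exact=True)

    exact_rows = None
    total_assignments = math.factorial(n)
    for s in sizes:
        total_assignments //= math.factorial(int(s))
    if total_assignments <= max_exact:
        exact_rows = _enumerate_assignments(codes, sizes)
    if exact_rows is not None:
        f_perm, _ = _pseudo_f(d2, exact_rows, k, ss_total)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return PermTestResult(f_obs, r2, p, exact_rows.shape[0], seed, "permanova", exact=True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm, _ = _pseudo_f(d2, perms, k, ss_total)
    p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
    return PermTestResult(f_obs, r2, p, n_perm, seed, "permanova", exact=False)


# ---------------------------------------------------------------------------
# BETADISPER
# ---------------------------------------------------------------------------

def _spatial_median(x: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    y = x.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(x - y, axis=1)
        if (dist < 1e-12).any():
            # median coincides with a data point
            return x[dist.argmin()].copy()
        w = 1.0 / dist
        y_new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol * (1 + np.linalg.norm(y)):
            return y_new
        y = y_new
    return y


def _anova_f(values: np.ndarray, code_rows: np.ndarray, k: int) -> np.ndarray:
    """Vectorised one-way ANOVA F over rows of group codes."""
    n = values.size
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    ssw = np.zeros(code_rows.shape[0])
    for g in range(k):
        b = code_rows == g
        n_g = b[0].sum()
        group_sums = b @ values
        group_sq = b @ (values**2)
        ssw += group_sq - group_sums**2 / n_g
    ssb = sst - ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(ssw <= 1e-300, np.where(np.abs(ssb) <= 1e-12, 0.0, np.inf), f)


def dispersion_distances(dm: DistanceMatrix, labels, centroid: str = "median") -> np.ndarray:
    """Per-sample distance to its group centroid in the corrected PCoA space.

    ``centroid="median"`` uses the spatial median on the real axes (imaginary
    axes use the group mean); ``centroid="centroid"`` uses the mean on both.
    Squared distances are real-part minus imaginary-part contributions,
    clipped at 0.
    """
    if centroid not in ("median", "centroid"):
        raise ValidationError(f"centroid must be 'median' or 'centroid', got {centroid!r}")
    codes, _ = _check_groups(labels)
    real, imag = _corrected_embedding(dm.values)
    dist2 = np.zeros(dm.n_samples)
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        if centroid == "median" and real.shape[1] > 0:
            c_real = _spatial_median(real[idx])
        else:
            c_real = real[idx].mean(axis=0) if real.shape[1] else np.zeros(0)
        c_imag = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d2 = np.zeros(idx.size)
        if real.shape[1]:
            d2 += ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            d2 -= ((imag[idx] - c_imag) ** 2).sum(axis=1)
        dist2[idx] = np.clip(d2, 0.0, None)
    return np.sqrt(dist2)


def betadisper(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
    centroid: str = "median",
) -> PermTestResult:
    """Permutation test for homogeneity of multivariate group dispersions.

    Dispersion distances are computed once under the observed grouping; the
    permutation scheme then shuffles group membership of those distances
    (the standard residual-permutation convention).
    """
    codes, sizes = _check_groups(labels)
    k = sizes.size
    n = dm.n_samples
    z = dispersion_distances(dm, labels, centroid=centroid)

    f_obs = float(_anova_f(z, codes[None, :], k)[0])
    grand = z.mean()
    sst = ((z - grand) ** 2).sum()
    ssw = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum() for g in range(k))
    r2 = float((sst - ssw) / sst) if sst > 0 else 0.0

    if sst <= 1e-300:
        return PermTestResult(0.0, 0.0, 1.0, 0, seed, "betadisper", exact=True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _anova_f(z, perms, k)
    p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + n_perm))
    return PermTestResult(f_obs, r2, p, n_perm, seed, "betadisper", exact=False)
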