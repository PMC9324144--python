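"""Distance, ordination, group testing and rank correlation.

Bray–Curtis dissimilarity on the transformed relative-abundance matrix is the
common currency: it feeds the non-metric multidimensional scaling (NMDS)
ordination, the PERMANOVA group test, and the randomization null models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from sklearn.manifold import smacof

from .data_model import ValidationError, add_one_p_value
from .preprocess import ProcessedMatrix

# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity 1 - 2 sum(min(x, y)) / (sum x + sum y).

    0 means identical composition, 1 no shared species. Scale-invariant under
    common rescaling of both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric Bray–Curtis dissimilarities with a zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValidationError("Bray-Curtis entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def distance_matrix(pm: ProcessedMatrix) -> DistanceMatrix:
    """Pairwise Bray–Curtis over the rows of the transformed matrix."""
    values = pm.values.values
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    d = cdist(values, values, metric="braycurtis")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=pm.sample_ids, d=d)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Best-of-restarts NMDS solution.

    Coordinates are centered and rotated to principal axes; ``stress`` is
    Kruskal stress-1 of the returned (best) solution and ``restart_stresses``
    records every restart so the minimum can be audited.
    """

    coords: pd.DataFrame
    stress: float
    k: int
    restarts: int
    seed: int
    converged: bool = True
    restart_stresses: list[float] = field(default_factory=list)


def _classical_mds_init(d: np.ndarray, k: int) -> np.ndarray:
    """Principal-coordinates (classical metric scaling) start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    return coords @ vt.T


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 over ``restarts`` starts.

    The first start is the classical-scaling configuration of the dissimilarity
    matrix; remaining starts are random, all driven by ``seed``. The lowest
    stress solution is returned, centered and rotated to principal axes.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    stresses: list[float] = []
    any_nonconverged = False
    for r in range(restarts):
        if r == 0:
            init = _classical_mds_init(dm.d, k)
        else:
            init = rng.standard_normal((dm.n, k))
        coords, stress, n_iter = smacof(
            dm.d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            return_n_iter=True,
        )
        stresses.append(float(stress))
        if n_iter >= max_iter:
            any_nonconverged = True
        if stress < best_stress:
            best_stress, best_coords = float(stress), coords
    coords = _principal_axes(best_coords)
    axis_names = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coords=pd.DataFrame(coords, index=dm.ids, columns=axis_names),
        stress=best_stress,
        k=k,
        restarts=restarts,
        seed=seed,
        converged=not any_nonconverged,
        restart_stresses=stresses,
    )


def orient_axes(ordination: OrdinationResult, covariate: pd.Series) -> OrdinationResult:
    """Fix the arbitrary sign of NMDS1 to correlate positively with ``covariate``.

    The conventional orientation puts warm-affinity (Mediterranean/Lusitanian)
    dominated samples at positive NMDS1.
    """
    cov = covariate.reindex(ordination.coords.index).astype(float)
    rho, _ = spearman(ordination.coords["NMDS1"].values, cov.values)
    coords = ordination.coords.copy()
    if rho < 0:
        coords["NMDS1"] = -coords["NMDS1"]
    return OrdinationResult(
        coords=coords,
        stress=ordination.stress,
        k=ordination.k,
        restarts=ordination.restarts,
        seed=ordination.seed,
        converged=ordination.converged,
        restart_stresses=ordination.restart_stresses,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    permutations: int
    df_among: int
    df_within: int
    seed: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return float((ss_among / df_among) / (ss_within / df_within)) if ss_within > 0 else np.inf


def permanova(
    dm: DistanceMatrix,
    groups: pd.Series | dict | list,
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation-based multivariate ANOVA on a distance matrix.

    SS_total = sum of squared distances / N over all pairs; SS_within sums the
    analogous per-group terms; the pseudo-F ratio is tested by permuting group
    labels, with p = (b + 1) / (B + 1).
    """
    if isinstance(groups, pd.Series):
        labels = groups.reindex(dm.ids).values
    elif isinstance(groups, dict):
        labels = np.array([groups[i] for i in dm.ids])
    else:
        labels = np.asarray(groups)
        if len(labels) != dm.n:
            raise ValidationError("groups length != number of samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(counts < 2)]
        raise ValidationError(f"groups with < 2 samples: {small}")
    d2 = dm.d ** 2
    observed = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    null = np.empty(permutations)
    for b in range(permutations):
        null[b] = _pseudo_f(d2, rng.permutation(codes), len(uniq))
    p = add_one_p_value(observed, null, tail="greater")
    return PermanovaResult(
        pseudo_F=observed,
        p_value=p,
        permutations=permutations,
        df_among=len(uniq) - 1,
        df_within=dm.n - len(uniq),
        seed=seed,
    )


def permanova_exhaustive_p(dm: DistanceMatrix, groups: list) -> float:
    """Exact p over all distinct label permutations (small instances only)."""
    labels = np.asarray(groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    d2 = dm.d ** 2
    observed = _pseudo_f(d2, codes, len(uniq))
    n = dm.n
    if math.factorial(n) > 50_000:
        raise ValidationError("too many permutations for exhaustive enumeration")
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        f = _pseudo_f(d2, codes[list(perm)], len(uniq))
        total += 1
        if f >= observed - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho as Pearson correlation of mid-ranks, with its p-value.

    Ties receive average (mid) ranks. The p-value is two-sided: exact by full
    permutation enumeration for n <= 9, otherwise the t approximation
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValidationError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        count = 0
        total = 0
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum())
        for perm in itertools.permutations(ry):
            ryp = np.asarray(perm)
            ry_c = ryp - ryp.mean()
            r = float(rx_c @ ry_c / (denom * np.sqrt((ry_c ** 2).sum())))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return rho, p


__all__ = [
    "bray_curtis",
    "DistanceMatrix",
    "distance_matrix",
    "OrdinationResult",
    "nmds",
    "orient_axes",
    "PermanovaResult",
    "permanova",
    "permanova_exhaustive_p",
    "spearman",
]
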