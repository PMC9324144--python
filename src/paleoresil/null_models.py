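"""Randomization null models for between-interval assemblage comparison.

Two Monte-Carlo procedures test the null hypothesis that the samples of two
time intervals came from one homogeneous system:

* :func:`bc_permutation_test` — the observed mean between-interval Bray–Curtis
  dissimilarity is compared against a null built by pooling every specimen of
  the compared intervals and reassigning them, without replacement, into
  synthetic samples that keep the exact per-sample sizes and interval labels
  of the real data.

* :func:`pooled_abundance_envelope` — per-species totals pooled within each
  interval are compared against multinomial resampling from the pooled
  species-abundance distribution into the observed sample structure, yielding
  one simulated (interval A, interval B) abundance pair per species per
  iteration; the envelope of those pairs is the null region, and Spearman rank
  correlation of the observed totals measures abundance-structure agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import (
    CommunityMatrix,
    NullTestResult,
    SampleMetadata,
    ValidationError,
    add_one_p_value,
)
from .multivariate import spearman

DEFAULT_ITERATIONS = 1000


def _transform_rows(counts: np.ndarray, kind: str) -> np.ndarray:
    """Row-wise relative abundance followed by the chosen transform (fast path)."""
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValidationError("empty sample encountered during transform")
    rel = counts / totals
    if kind == "fourth_root":
        return rel ** 0.25
    if kind == "log1p":
        return np.log1p(rel)
    if kind == "wisconsin":
        colmax = rel.max(axis=0, keepdims=True)
        colmax = np.where(colmax == 0, 1.0, colmax)
        v = rel / colmax
        return v / v.sum(axis=1, keepdims=True)
    if kind == "none":
        return rel
    raise ValidationError(f"unknown transform {kind!r}")


def _interval_blocks(
    cm: CommunityMatrix, meta: SampleMetadata, intervals: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Stack counts for the given intervals; return (matrix, sizes, block lengths)."""
    blocks = []
    lens = []
    for iv in intervals:
        ids = [s for s in cm.sample_ids if s in meta.samples_in(iv)]
        if not ids:
            raise ValidationError(f"interval {iv!r} has no retained samples")
        blocks.append(cm.counts.loc[ids].values)
        lens.append(len(ids))
    mat = np.vstack(blocks)
    sizes = mat.sum(axis=1)
    return mat, sizes, lens


def _mean_between(values: np.ndarray, n_a: int) -> float:
    d = cdist(values[:n_a], values[n_a:], metric="braycurtis")
    return float(d.mean())


def mean_between_bc(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    a: str,
    b: str,
    transform_kind: str = "fourth_root",
) -> float:
    """Mean Bray–Curtis over all |a| x |b| between-interval sample pairs.

    The transform (relative abundance + ``transform_kind``) is applied to the
    union of the two intervals' samples, mirroring the ordination matrix.
    """
    mat, _, lens = _interval_blocks(cm, meta, (a, b))
    values = _transform_rows(mat, transform_kind)
    return _mean_between(values, lens[0])


def bc_permutation_test(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    a: str,
    b: str,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    transform_kind: str = "fourth_root",
    pool_scope: str = "pair",
    tail: str = "greater",
) -> NullTestResult:
    """Size-preserving specimen-permutation test of mean between-interval BC.

    Every iteration pools the specimens (as a multiset of species identities)
    of the samples in scope, permutes them without replacement into synthetic
    samples with exactly the original per-sample sizes and interval labels,
    re-applies the transform, and records the mean between-interval BC. The
    default one-sided alternative ("greater") asks whether the observed
    intervals are more dissimilar than expected from one homogeneous system.

    ``pool_scope="pair"`` (default) pools the two compared intervals only;
    ``"all"`` pools every sample of every interval in the metadata while still
    scoring only the a-vs-b comparison.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if not cm.is_integer():
        raise ValidationError(
            "counts must be integers (run resolve_valves first) for specimen pooling"
        )
    if pool_scope == "pair":
        scope: tuple[str, ...] = (a, b)
    elif pool_scope == "all":
        ordered = [iv for iv in ("LIG", "LG", "CIG") if len(meta.samples_in(iv)) > 0]
        scope = tuple([a, b] + [iv for iv in ordered if iv not in (a, b)])
    else:
        raise ValidationError(f"unknown pool_scope {pool_scope!r}")

    mat, sizes, lens = _interval_blocks(cm, meta, scope)
    n_a = lens[0]
    n_ab = lens[0] + lens[1]
    observed = _mean_between(_transform_rows(mat[:n_ab], transform_kind), n_a)

    counts_int = mat.astype(np.int64)
    pooled = counts_int.sum(axis=0)
    labels = np.repeat(np.arange(len(pooled)), pooled)
    split_points = np.cumsum(sizes.astype(np.int64))[:-1]
    n_species = len(pooled)

    rng = np.random.default_rng(seed)
    null = np.empty(iterations)
    for it in range(iterations):
        shuffled = rng.permutation(labels)
        rows = [
            np.bincount(chunk, minlength=n_species)
            for chunk in np.split(shuffled, split_points)
        ]
        synth = np.asarray(rows, dtype=float)[:n_ab]
        present = synth.sum(axis=0) > 0
        values = _transform_rows(synth[:, present], transform_kind)
        null[it] = _mean_between(values, n_a)

    p = add_one_p_value(observed, null, tail=tail)
    return NullTestResult(
        observed=observed,
        null_values=null,
        p_value=p,
        iterations=iterations,
        seed=seed,
        tail=tail,
    )


@dataclass
class AbundanceComparison:
    """Observed vs multinomial-null per-species pooled totals for two intervals.

    ``observed_pairs`` is indexed by species with columns named after the two
    intervals; ``null_pairs`` has shape (iterations, n_species, 2) in the same
    species order. ``rho_observed`` is the Spearman rank correlation of the
    observed totals over all species present in the union (zeros included).
    """

    species_ids: list[str]
    observed_pairs: pd.DataFrame
    null_pairs: np.ndarray
    rho_observed: float
    p_rho: float
    iterations: int
    seed: int
    intervals: tuple[str, str]

    def null_pairs_long(self) -> pd.DataFrame:
        """Long-format (species, iteration, x, y) table of the null envelope."""
        it, s, _ = self.null_pairs.shape
        return pd.DataFrame(
            {
                "species_id": np.tile(self.species_ids, it),
                "iteration": np.repeat(np.arange(it), s),
                "x": self.null_pairs[:, :, 0].ravel(),
                "y": self.null_pairs[:, :, 1].ravel(),
            }
        )

    def coverage_fraction(self, level: float = 0.95) -> float:
        """Fraction of species whose observed pair sits inside the central
        ``level`` envelope of its simulated pairs (both coordinates)."""
        lo = (1.0 - level) / 2.0
        qlo = np.quantile(self.null_pairs, lo, axis=0)
        qhi = np.quantile(self.null_pairs, 1.0 - lo, axis=0)
        obs = self.observed_pairs.values
        inside = (obs >= qlo) & (obs <= qhi)
        return float(inside.all(axis=1).mean())


def pooled_abundance_envelope(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    a: str,
    b: str,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> AbundanceComparison:
    """Multinomial resampling envelope for pooled per-species totals.

    The pooled relative species-abundance distribution over both intervals
    defines the homogeneous-system null. Each iteration redraws every original
    sample as a multinomial of its observed size from that distribution and
    totals the draws per interval, giving one simulated (a, b) abundance pair
    per species. Interval grand totals are conserved exactly by construction.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    if not cm.is_integer():
        raise ValidationError("counts must be integers for specimen resampling")
    mat, sizes, lens = _interval_blocks(cm, meta, (a, b))
    n_a = lens[0]
    pooled = mat.sum(axis=0)
    pi = pooled / pooled.sum()
    sizes = sizes.astype(np.int64)

    rng = np.random.default_rng(seed)
    n_species = mat.shape[1]
    null_pairs = np.empty((iterations, n_species, 2))
    for it in range(iterations):
        draws = rng.multinomial(sizes, pi)
        null_pairs[it, :, 0] = draws[:n_a].sum(axis=0)
        null_pairs[it, :, 1] = draws[n_a:].sum(axis=0)

    obs_a = mat[:n_a].sum(axis=0)
    obs_b = mat[n_a:].sum(axis=0)
    try:
        rho, p_rho = spearman(obs_a, obs_b)
    except ValidationError:
        # fewer than 3 species, or tied ranks throughout: rho is undefined but
        # the null envelope itself is still well-formed
        rho, p_rho = float("nan"), float("nan")
    observed = pd.DataFrame({a: obs_a, b: obs_b}, index=cm.species_ids)
    return AbundanceComparison(
        species_ids=cm.species_ids,
        observed_pairs=observed,
        null_pairs=null_pairs,
        rho_observed=rho,
        p_rho=p_rho,
        iterations=iterations,
        seed=seed,
        intervals=(a, b),
    )
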