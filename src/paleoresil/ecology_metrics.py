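"""Diversity, dominance, biogeographic and bathymetric descriptors.

Sample-standardized richness uses the analytic hypergeometric rarefaction
expectation; dominance is the share of the most abundant species; biogeographic
profiles pool specimens per interval over the four affinity classes; depth
estimation follows the weighted-averaging approach of paleo-bathymetry transfer
functions: each species gets a preferred depth (abundance-weighted mean depth
of its census records) and each sample the abundance-weighted mean of its
species' preferred depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_model import (
    BIOGEO_CLASSES,
    BathymetryCensus,
    CommunityMatrix,
    SampleMetadata,
    SpeciesTraits,
    ValidationError,
    logger,
)

# ---------------------------------------------------------------------------
# Rarefaction and dominance
# ---------------------------------------------------------------------------


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, n: int) -> float:
    """Expected species count in a random subsample of ``n`` specimens.

    Analytic hypergeometric expectation
    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], with N the sample total.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if n < 1:
        raise ValidationError("subsample size must be >= 1")
    if n > N:
        raise ValidationError(f"subsample size {n} exceeds sample total {int(N)}")
    # C(N - N_i, n) is zero when N - N_i < n
    terms = np.zeros(len(counts))
    feasible = (N - counts) >= n
    if feasible.any():
        terms[feasible] = np.exp(
            _log_choose(N - counts[feasible], n) - _log_choose(np.array(N), n)
        )
    return float(np.sum(1.0 - terms))


def dominance(counts) -> float:
    """Share of the single most abundant species."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("dominance undefined for an empty sample")
    return float(counts.max() / total)


# ---------------------------------------------------------------------------
# Biogeographic profiles
# ---------------------------------------------------------------------------


@dataclass
class BiogeoProfile:
    """Fraction of an interval's pooled specimens in each affinity class."""

    interval: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"biogeo proportions sum to {total}, not 1")


def biogeo_profile(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    traits: SpeciesTraits,
    interval: str,
) -> BiogeoProfile:
    """Pool specimens over the interval's samples; fraction per affinity class."""
    traits.check_covers(cm.species_ids)
    ids = [s for s in cm.sample_ids if s in meta.samples_in(interval)]
    if not ids:
        raise ValidationError(f"no samples in interval {interval!r}")
    totals = cm.counts.loc[ids].sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValidationError(f"no specimens in interval {interval!r}")
    props = {}
    for cls in BIOGEO_CLASSES:
        members = [sp for sp in cm.species_ids if traits.table.loc[sp, "biogeo_class"] == cls]
        props[cls] = float(totals[members].sum() / grand)
    return BiogeoProfile(interval=interval, proportions=props)


def warm_affinity_fraction(
    counts_row: pd.Series, traits: SpeciesTraits, classes: tuple[str, ...] = ("MED/LUS", "WAF")
) -> float:
    """Per-sample fraction of specimens in warm-affinity classes (default
    Mediterranean/Lusitanian + West African), the covariate correlated with
    the first ordination axis."""
    total = counts_row.sum()
    if total <= 0:
        raise ValidationError("empty sample")
    members = [
        sp
        for sp in counts_row.index
        if traits.table.loc[sp, "biogeo_class"] in classes
    ]
    return float(counts_row[members].sum() / total)


# ---------------------------------------------------------------------------
# Top-k rank overlap
# ---------------------------------------------------------------------------


def interval_rank_series(cm: CommunityMatrix, meta: SampleMetadata, interval: str) -> pd.Series:
    """Species ranked 1..S by pooled abundance within an interval.

    Descending abundance; ties broken by species id lexicographic order.
    Species absent from the interval get no rank (NaN).
    """
    ids = [s for s in cm.sample_ids if s in meta.samples_in(interval)]
    totals = cm.counts.loc[ids].sum(axis=0)
    present = totals[totals > 0]
    order = sorted(present.index, key=lambda sp: (-present[sp], sp))
    ranks = pd.Series(np.nan, index=cm.species_ids, dtype=float)
    for r, sp in enumerate(order, start=1):
        ranks[sp] = r
    return ranks


def overlap_from_ranks(ranks_in_b, k: int) -> int:
    """Count of interval-A top-k species whose rank in B is also <= k.

    ``ranks_in_b`` holds, for each of A's top-k species, its abundance rank in
    interval B, with NaN/None/"absent" for species missing from B — the shape
    of a printed rank table.
    """
    n = 0
    for r in ranks_in_b:
        if r is None or (isinstance(r, str) and r.lower() == "absent"):
            continue
        if isinstance(r, float) and np.isnan(r):
            continue
        if float(r) <= k:
            n += 1
    return n


def topk_overlap(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    a: str,
    b: str,
    k: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Overlap of the two intervals' top-k most abundant species.

    Returns the overlap count and a rank table listing each of A's top-k
    species with its abundance rank in both intervals ("absent" when missing
    from B).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranks_a = interval_rank_series(cm, meta, a)
    ranks_b = interval_rank_series(cm, meta, b)
    n_present = int(ranks_a.notna().sum())
    if n_present < k:
        logger.warning(
            "interval %s has only %d species with nonzero abundance (< k=%d)",
            a, n_present, k,
        )
        k_eff = n_present
    else:
        k_eff = k
    top_a = ranks_a[ranks_a <= k_eff].sort_values().index.tolist()
    rows = []
    for sp in top_a:
        rb = ranks_b[sp]
        rows.append(
            {
                "species_id": sp,
                f"rank_{a}": int(ranks_a[sp]),
                f"rank_{b}": "absent" if np.isnan(rb) else int(rb),
            }
        )
    table = pd.DataFrame(rows)
    overlap = overlap_from_ranks([ranks_b[sp] for sp in top_a], k)
    return overlap, table


# ---------------------------------------------------------------------------
# Weighted-averaging bathymetry
# ---------------------------------------------------------------------------


@dataclass
class DepthEstimate:
    sample_id: str
    depth_m: float
    coverage: float  # fraction of specimens belonging to species with census data


def species_preferred_depth(
    census: BathymetryCensus, species_id: str, live_only: bool = False
) -> float:
    """Abundance-weighted mean depth of a species' census records.

    Live and dead abundances are combined by default (``live_only`` restricts
    the weighting to living individuals).
    """
    rec = census.records[census.records["species_id"] == species_id]
    if len(rec) == 0:
        raise ValidationError(f"no census records for species {species_id!r}")
    weights = rec["live_abundance"] if live_only else rec["live_abundance"] + rec["dead_abundance"]
    weights = weights.astype(float)
    if weights.sum() <= 0:
        raise ValidationError(f"zero total census abundance for species {species_id!r}")
    return float(np.average(rec["depth_m"].astype(float), weights=weights))


def preferred_depths(census: BathymetryCensus, live_only: bool = False) -> pd.Series:
    """Preferred depth for every species present in the census."""
    return pd.Series(
        {
            sp: species_preferred_depth(census, sp, live_only=live_only)
            for sp in census.species_ids
        },
        name="preferred_depth_m",
    )


def sample_depth(counts_row: pd.Series, depths: pd.Series) -> DepthEstimate:
    """Abundance-weighted mean of constituent species' preferred depths.

    Species without census coverage are excluded and the weights renormalized;
    ``coverage`` reports the specimen fraction that contributed.
    """
    total = float(counts_row.sum())
    if total <= 0:
        raise ValidationError("empty sample")
    covered = [sp for sp in counts_row.index if sp in depths.index and counts_row[sp] > 0]
    covered_total = float(counts_row[covered].sum())
    if covered_total <= 0:
        raise ValidationError("no specimens with bathymetric coverage; no estimate")
    est = float(
        np.average(depths[covered].astype(float), weights=counts_row[covered].astype(float))
    )
    return DepthEstimate(
        sample_id=str(counts_row.name),
        depth_m=est,
        coverage=covered_total / total,
    )


def sample_depths(cm: CommunityMatrix, depths: pd.Series) -> pd.DataFrame:
    """Depth estimates for every sample with nonzero coverage."""
    rows = []
    for sid in cm.sample_ids:
        try:
            d = sample_depth(cm.counts.loc[sid], depths)
        except ValidationError:
            logger.warning("sample %s has no bathymetric coverage; skipped", sid)
            continue
        rows.append({"sample_id": sid, "depth_m": d.depth_m, "coverage": d.coverage})
    return pd.DataFrame(rows).set_index("sample_id")
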