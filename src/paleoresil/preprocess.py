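"""Data-selection and transformation rules producing the analysis-ready matrix.

The selection protocol, applied in a fixed single pass:

1. valve resolution — isolated bivalve valve counts are halved (one valve
   still implies one individual, so halves round up);
2. habitat exclusion — freshwater and terrestrial species are removed;
3. sample-size threshold — samples with fewer than ``min_n`` (default 25;
   sensitivity 60) marine specimens are removed;
4. rare-species removal (multivariate analyses only) — species present in a
   single retained sample are dropped, once, with no fixpoint iteration;
5. transformation — per-sample relative abundances, then a fourth-root
   transform by default to damp hyperabundant taxa (log1p and Wisconsin
   double-relativization are sensitivity options).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ELEMENTS,
    CommunityMatrix,
    SampleMetadata,
    SpeciesTraits,
    ValidationError,
    logger,
)

TRANSFORMS = ("fourth_root", "log1p", "wisconsin", "none")

DEFAULT_MIN_N = 25
SENSITIVITY_MIN_N = 60


@dataclass
class ProcessedMatrix:
    """Filtered, transformed relative-abundance matrix ready for ordination.

    ``values`` holds the transformed entries; ``relabund`` the per-sample
    relative abundances they were derived from (rows sum to 1). ``provenance``
    records every filter applied and what it removed.
    """

    values: pd.DataFrame
    relabund: pd.DataFrame
    transform: str
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance, indent=2))


def resolve_valves(raw: CommunityMatrix, element_info: pd.DataFrame | None = None) -> CommunityMatrix:
    """Convert isolated-valve counts to individuals: ceil(valves / 2).

    Cells labelled ``whole`` are unchanged. With no element information the
    whole matrix is treated as whole-individual counts and only checked for
    integrality.
    """
    element = element_info if element_info is not None else raw.element
    counts = raw.counts.copy()
    if element is None:
        if not raw.is_integer():
            raise ValidationError(
                "non-integer counts with no element labels; cannot resolve valves"
            )
        return CommunityMatrix(counts)
    element = element.reindex(index=counts.index, columns=counts.columns).fillna("whole")
    bad = set(np.unique(element.values.astype(str))) - set(ELEMENTS)
    if bad:
        raise ValidationError(f"unknown element labels: {sorted(bad)}")
    is_valve = element.values == "valve"
    v = counts.values
    v = np.where(is_valve, np.ceil(v / 2.0), v)
    if not np.all(v == np.floor(v)):
        raise ValidationError("whole-individual counts must be integers")
    return CommunityMatrix(pd.DataFrame(v, index=counts.index, columns=counts.columns))


def filter_samples(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    traits: SpeciesTraits,
    min_n: int = DEFAULT_MIN_N,
    provenance: dict | None = None,
) -> CommunityMatrix:
    """Drop non-marine species, then samples with fewer than ``min_n`` specimens.

    The threshold is evaluated on the marine specimen total (the analysis
    universe), not the raw total, and "at least min_n" is inclusive.
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    meta.check_covers(cm)
    traits.check_covers(cm.species_ids)

    marine = [s for s in cm.species_ids if s in traits.marine_species()]
    dropped_species = [s for s in cm.species_ids if s not in marine]
    out = cm.select_species(marine)

    totals = out.sample_totals
    keep = totals[totals >= min_n].index.tolist()
    dropped_samples = [s for s in out.sample_ids if s not in keep]
    if not keep:
        raise ValidationError("no samples survive filtering")
    out = out.select_samples(keep)

    if provenance is not None:
        provenance["habitat_exclusion"] = {
            "dropped_species": dropped_species,
            "rule": "habitat != marine",
        }
        provenance["sample_threshold"] = {
            "min_n": min_n,
            "counted_on": "marine specimens after habitat exclusion",
            "dropped_samples": dropped_samples,
        }
    logger.info(
        "filter_samples: dropped %d non-marine species, %d samples below n=%d",
        len(dropped_species), len(dropped_samples), min_n,
    )
    return out


def drop_rare_species(cm: CommunityMatrix, provenance: dict | None = None) -> CommunityMatrix:
    """Remove species occurring (present, regardless of abundance) in <=1 sample.

    Applied once; sample thresholds are deliberately not re-checked afterwards,
    so sample sizes stay interpretable.
    """
    presence = (cm.counts.values > 0).sum(axis=0)
    keep = [sp for sp, n in zip(cm.species_ids, presence) if n >= 2]
    dropped = [sp for sp, n in zip(cm.species_ids, presence) if n < 2]
    out = cm.select_species(keep)
    if provenance is not None:
        provenance["rare_species_removal"] = {
            "rule": "present in <= 1 sample",
            "dropped_species": dropped,
        }
    logger.info("drop_rare_species: dropped %d singleton-occurrence species", len(dropped))
    return out


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise ValidationError(f"samples with zero specimens: {empty}")
    return counts.div(totals, axis=0)


def transform(
    cm: CommunityMatrix,
    kind: str = "fourth_root",
    provenance: dict | None = None,
) -> ProcessedMatrix:
    """Convert to per-sample relative abundances and apply ``kind``.

    fourth_root: x ** 0.25 — the default, damping hyperabundant taxa.
    log1p: ln(1 + x). wisconsin: divide each species by its column maximum,
    then each sample by its row total. none: relative abundances unchanged.
    """
    if kind not in TRANSFORMS:
        raise ValidationError(f"unknown transform {kind!r}; expected one of {TRANSFORMS}")
    relabund = to_relative_abundance(cm.counts)
    if kind == "fourth_root":
        values = relabund ** 0.25
    elif kind == "log1p":
        values = np.log1p(relabund)
    elif kind == "wisconsin":
        colmax = relabund.max(axis=0)
        colmax = colmax.replace(0.0, 1.0)  # all-zero species contribute nothing
        v = relabund.div(colmax, axis=1)
        values = v.div(v.sum(axis=1), axis=0)
    else:
        values = relabund.copy()
    prov = dict(provenance) if provenance else {}
    prov["transform"] = kind
    return ProcessedMatrix(values=values, relabund=relabund, transform=kind, provenance=prov)


def prepare_multivariate_matrix(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    traits: SpeciesTraits,
    min_n: int = DEFAULT_MIN_N,
    kind: str = "fourth_root",
) -> ProcessedMatrix:
    """Full single-pass protocol: habitat exclusion -> min-n -> rare removal -> transform."""
    provenance: dict = {}
    filtered = filter_samples(cm, meta, traits, min_n=min_n, provenance=provenance)
    filtered = drop_rare_species(filtered, provenance=provenance)
    return transform(filtered, kind=kind, provenance=provenance)
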