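"""Core data containers and delimited-text I/O for the pipeline.

The central object is a :class:`CommunityMatrix` — a samples x species table of
specimen counts — accompanied by per-sample metadata (time interval, core,
environment), per-species traits (biogeographic affinity, habitat), and a
bathymetric census of living/death-assemblage records used for weighted-average
depth estimation. All containers validate their invariants on construction and
round-trip exactly through plain CSV/TSV.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("paleoresil")

#: The three time-interval groups compared throughout the analysis:
#: last interglacial, last late glacial, current interglacial.
INTERVALS = ("LIG", "LG", "CIG")

#: Biogeographic affinity classes, ordered warm -> cold-tolerant:
#: Mediterranean/Lusitanian endemics, West African-reaching, Boreal-reaching,
#: cosmopolitan (West African through Boreal).
BIOGEO_CLASSES = ("MED/LUS", "WAF", "BOR", "COS")

HABITATS = ("marine", "freshwater", "terrestrial")

ELEMENTS = ("whole", "valve")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


class ParseError(ValidationError):
    """A cell of an input table could not be parsed."""


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Samples x species specimen counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by sample id, columns by species id, non-negative numeric
        values. Counts may be fractional only transiently (isolated bivalve
        valves before valve resolution); analysis routines require integers.
    element : pandas.DataFrame, optional
        Same shape as ``counts``; entries ``"whole"`` or ``"valve"`` marking
        whether a cell tallies whole individuals or isolated valves.
    """

    counts: pd.DataFrame
    element: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated species ids: {dupes}")
        try:
            c = c.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric count value: {exc}") from exc
        if c.isna().any().any():
            c = c.fillna(0.0)
        if (c.values < 0).any():
            i, j = np.argwhere(c.values < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[i]!r}, species {c.columns[j]!r}"
            )
        self.counts = c
        if self.element is not None:
            bad = set(np.unique(self.element.values.astype(str))) - set(ELEMENTS) - {"nan", ""}
            if bad:
                raise ValidationError(f"unknown element labels: {sorted(bad)}")

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_totals(self) -> pd.Series:
        """Per-sample specimen totals (the N_s preserved by permutation nulls)."""
        return self.counts.sum(axis=1)

    @property
    def total_specimens(self) -> float:
        return float(self.counts.values.sum())

    def is_integer(self) -> bool:
        v = self.counts.values
        return bool(np.all(v == np.floor(v)))

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityMatrix":
        el = self.element.loc[sample_ids] if self.element is not None else None
        return CommunityMatrix(self.counts.loc[sample_ids], el)

    def select_species(self, species_ids: Sequence[str]) -> "CommunityMatrix":
        el = self.element[species_ids] if self.element is not None else None
        return CommunityMatrix(self.counts[list(species_ids)], el)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample interval/core/environment labels.

    ``table`` is indexed by sample id with columns ``interval`` (one of
    LIG/LG/CIG), ``core_id``, ``environment`` and optional ``volume_dm3``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicated sample ids in metadata")
        missing = {"interval", "core_id", "environment"} - set(t.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        bad = set(t["interval"].unique()) - set(INTERVALS)
        if bad:
            raise ValidationError(
                f"unknown interval labels {sorted(bad)}; expected one of {INTERVALS}"
            )

    def interval_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "interval"])

    def samples_in(self, interval: str) -> list[str]:
        if interval not in INTERVALS:
            raise ValidationError(f"unknown interval {interval!r}")
        return list(self.table.index[self.table["interval"] == interval])

    def check_covers(self, cm: CommunityMatrix) -> None:
        """Every sample in ``cm`` must have exactly one metadata row."""
        missing = [s for s in cm.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------------
# SpeciesTraits
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTraits:
    """Per-species biogeographic affinity class and habitat flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicated species ids in traits")
        missing = {"biogeo_class", "habitat"} - set(t.columns)
        if missing:
            raise ValidationError(f"traits missing columns: {sorted(missing)}")
        bad = set(t["biogeo_class"].unique()) - set(BIOGEO_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown biogeo_class labels {sorted(bad)}; expected {BIOGEO_CLASSES}"
            )
        bad = set(t["habitat"].unique()) - set(HABITATS)
        if bad:
            raise ValidationError(f"unknown habitat labels {sorted(bad)}")

    def check_covers(self, species: Iterable[str]) -> None:
        missing = [s for s in species if s not in self.table.index]
        if missing:
            raise ValidationError(f"species without trait rows: {missing}")

    def marine_species(self) -> list[str]:
        return list(self.table.index[self.table["habitat"] == "marine"])

    def species_of_class(self, biogeo_class: str) -> list[str]:
        return list(self.table.index[self.table["biogeo_class"] == biogeo_class])


# ---------------------------------------------------------------------------
# BathymetryCensus
# ---------------------------------------------------------------------------


@dataclass
class BathymetryCensus:
    """Census records of (species, depth in metres, live/dead abundance)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        missing = {"species_id", "depth_m", "live_abundance", "dead_abundance"} - set(r.columns)
        if missing:
            raise ValidationError(f"census missing columns: {sorted(missing)}")
        depth = r["depth_m"].astype(float)
        if not np.isfinite(depth).all():
            raise ValidationError("non-finite depth in census")
        if (depth < 0).any():
            bad = r.loc[depth < 0, "species_id"].tolist()
            raise ValidationError(f"negative depth for species {bad}")
        if ((r["live_abundance"] < 0) | (r["dead_abundance"] < 0)).any():
            raise ValidationError("negative abundance in census")

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.records["species_id"].unique())


# ---------------------------------------------------------------------------
# NullTestResult
# ---------------------------------------------------------------------------


@dataclass
class NullTestResult:
    """Outcome of a Monte-Carlo randomization test.

    The p-value follows the add-one rule p = (1 + b) / (iterations + 1) where
    b counts null values at least as extreme as the observed statistic, so the
    smallest reportable p with 1000 iterations is ~.001.
    """

    observed: float
    null_values: np.ndarray
    p_value: float
    iterations: int
    seed: int
    tail: str

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.iterations:
            raise ValidationError("null_values length != iterations")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        if self.tail not in ("greater", "less", "two-sided"):
            raise ValidationError(f"unknown tail {self.tail!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["null_values"] = [float(v) for v in self.null_values]
        return d


def add_one_p_value(observed: float, null_values: np.ndarray, tail: str) -> float:
    """Randomization p-value with the (b + 1) / (B + 1) rule."""
    null_values = np.asarray(null_values, dtype=float)
    B = len(null_values)
    if tail == "greater":
        b = int(np.sum(null_values >= observed))
    elif tail == "less":
        b = int(np.sum(null_values <= observed))
    elif tail == "two-sided":
        center = float(np.mean(null_values))
        b = int(np.sum(np.abs(null_values - center) >= abs(observed - center)))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (b + 1) / (B + 1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_community_matrix(path: str | Path, dialect: str = "wide") -> CommunityMatrix:
    """Read a community matrix from delimited text.

    ``dialect="wide"`` expects species ids in the header row and sample ids in
    the first column. ``dialect="long"`` expects occurrence triplets with
    columns ``sample_id,species_id,count`` and an optional ``element`` column
    (``whole``/``valve``); triplets are pivoted to wide with missing cells as 0.
    """
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ParseError(
                    f"non-numeric count at sample {df.index[bad.argmax()]!r}, "
                    f"species {col!r} in {path.name}"
                )
            df[col] = coerced
        return CommunityMatrix(df.fillna(0.0))
    if dialect == "long":
        df = pd.read_csv(path, sep=sep, dtype={0: str})
        required = {"sample_id", "species_id", "count"}
        if not required <= set(df.columns):
            raise ParseError(f"long dialect needs columns {sorted(required)}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["species_id"] = df["species_id"].astype(str)
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            row = df.loc[counts.isna()].iloc[0]
            raise ParseError(
                f"non-numeric count for ({row['sample_id']}, {row['species_id']})"
            )
        df["count"] = counts
        dup = df.duplicated(subset=["sample_id", "species_id"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicated occurrence ({row['sample_id']}, {row['species_id']})"
            )
        # preserve first-appearance order of samples and species, as read
        sample_order = df["sample_id"].drop_duplicates().tolist()
        species_order = df["species_id"].drop_duplicates().tolist()
        wide = (
            df.pivot(index="sample_id", columns="species_id", values="count")
            .reindex(index=sample_order, columns=species_order)
            .fillna(0.0)
        )
        wide.index.name = None
        wide.columns.name = None
        element = None
        if "element" in df.columns:
            element = (
                df.pivot(index="sample_id", columns="species_id", values="element")
                .reindex(index=sample_order, columns=species_order)
                .fillna("whole")
            )
            element.index.name = None
            element.columns.name = None
        return CommunityMatrix(wide, element)
    raise ValidationError(f"unknown dialect {dialect!r}")


def write_community_matrix(cm: CommunityMatrix, path: str | Path) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError("metadata needs a sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(Path(path), index_label="sample_id")


def read_traits(path: str | Path) -> SpeciesTraits:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), dtype=str)
    if "species_id" not in df.columns:
        raise ParseError("traits need a species_id column")
    missing = df["species_id"][df.get("biogeo_class", pd.Series(dtype=str)).isna()]
    if len(missing):
        raise ValidationError(f"species missing biogeo_class: {missing.tolist()}")
    return SpeciesTraits(df.set_index("species_id"))


def write_traits(traits: SpeciesTraits, path: str | Path) -> None:
    traits.table.to_csv(Path(path), index_label="species_id")


def read_bathymetry_census(path: str | Path) -> BathymetryCensus:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)))
    rename = {"species": "species_id", "live": "live_abundance", "dead": "dead_abundance"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    census = BathymetryCensus(df)
    keep = (df["live_abundance"] + df["dead_abundance"]) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-abundance census records", n_dropped)
    return BathymetryCensus(df.loc[keep].reset_index(drop=True))


def write_bathymetry_census(census: BathymetryCensus, path: str | Path) -> None:
    census.records.to_csv(Path(path), index=False)
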