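"""End-to-end orchestration: ingest -> preprocess -> ordination -> null models
-> per-sample metrics -> scenario call, with a reproducible run manifest.

A single master seed deterministically spawns per-stage seeds (via
``numpy.random.SeedSequence``), so each stage can be re-run independently and
an identical configuration always produces an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (
    INTERVALS,
    CommunityMatrix,
    SampleMetadata,
    SpeciesTraits,
    ValidationError,
    read_bathymetry_census,
    read_community_matrix,
    read_sample_metadata,
    read_traits,
)
from .ecology_metrics import (
    biogeo_profile,
    dominance,
    preferred_depths,
    rarefied_richness,
    sample_depths,
    topk_overlap,
    warm_affinity_fraction,
)
from .multivariate import (
    OrdinationResult,
    distance_matrix,
    nmds,
    orient_axes,
    permanova,
    spearman,
)
from .null_models import bc_permutation_test, mean_between_bc, pooled_abundance_envelope
from .preprocess import (
    DEFAULT_MIN_N,
    filter_samples,
    drop_rare_species,
    resolve_valves,
    transform,
)
from .scenario import DEFAULT_ALPHA, classify_pattern

logger = logging.getLogger("paleoresil")

#: The three pairwise interval comparisons, interglacial pair first.
PAIRWISE = (("CIG", "LIG"), ("CIG", "LG"), ("LIG", "LG"))


@dataclass
class RunConfig:
    """Configuration of one full analysis run; defaults are the study settings
    (minimum 25 specimens, fourth-root transform, 2-D NMDS, 1000 iterations,
    alpha .05)."""

    community_path: str = ""
    metadata_path: str = ""
    traits_path: str = ""
    census_path: str = ""
    dialect: str = "wide"
    min_n: int = DEFAULT_MIN_N
    transform_kind: str = "fourth_root"
    nmds_k: int = 2
    nmds_restarts: int = 20
    iterations: int = 1000
    permutations: int = 999
    alpha: float = DEFAULT_ALPHA
    rarefaction_levels: tuple[int, ...] = (25, 60)
    top_k: int = 10
    seed: int = 0
    output_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "rarefaction_levels" in data:
            data["rarefaction_levels"] = tuple(data["rarefaction_levels"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rarefaction_levels"] = list(self.rarefaction_levels)
        return d


def _stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage seeds spawned deterministically from the master seed."""
    stages = ("nmds", "permanova", "bc_test_0", "bc_test_1", "bc_test_2",
              "envelope_0", "envelope_1", "envelope_2")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(stages))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for name, child in zip(stages, children)
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_analysis(
    cm: CommunityMatrix,
    meta: SampleMetadata,
    traits: SpeciesTraits,
    census=None,
    config: RunConfig | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; return a results dict.

    Stages: valve resolution (if element labels present) -> habitat / min-n
    filtering -> rare-species removal -> transform -> distances -> NMDS ->
    PERMANOVA -> three pairwise BC permutation tests -> three pooled-abundance
    envelopes -> per-sample metrics -> scenario classification.
    """
    cfg = config or RunConfig()
    seeds = _stage_seeds(cfg.seed)
    results: dict = {"config": cfg.to_dict(), "stage_seeds": seeds}

    # --- preprocess ---------------------------------------------------------
    cm = resolve_valves(cm)
    provenance: dict = {}
    filtered = filter_samples(cm, meta, traits, min_n=cfg.min_n, provenance=provenance)
    mv = drop_rare_species(filtered, provenance=provenance)
    pm = transform(mv, kind=cfg.transform_kind, provenance=provenance)
    results["provenance"] = pm.provenance
    results["n_samples_retained"] = mv.n_samples
    results["n_species_retained"] = mv.n_species

    retained_intervals = {
        iv: [s for s in mv.sample_ids if s in meta.samples_in(iv)] for iv in INTERVALS
    }
    for iv, ids in retained_intervals.items():
        if len(ids) < 2:
            raise ValidationError(f"interval {iv!r} retains {len(ids)} samples (< 2)")

    # --- multivariate -------------------------------------------------------
    dm = distance_matrix(pm)
    ordination = nmds(
        dm, k=cfg.nmds_k, restarts=cfg.nmds_restarts, seed=seeds["nmds"]
    )
    warm = pd.Series(
        {
            sid: warm_affinity_fraction(filtered.counts.loc[sid], traits)
            for sid in mv.sample_ids
        }
    )
    ordination = orient_axes(ordination, warm)
    results["nmds_stress"] = ordination.stress
    results["ordination"] = ordination

    groups = {s: meta.interval_of(s) for s in dm.ids}
    perma = permanova(dm, groups, permutations=cfg.permutations, seed=seeds["permanova"])
    results["permanova"] = perma

    # --- null models (on the filtered integer matrix, NMDS species set) -----
    bc_tests = {}
    envelopes = {}
    for i, (a, b) in enumerate(PAIRWISE):
        bc_tests[f"{a}-{b}"] = bc_permutation_test(
            mv, meta, a, b,
            iterations=cfg.iterations,
            seed=seeds[f"bc_test_{i}"],
            transform_kind=cfg.transform_kind,
        )
        envelopes[f"{a}-{b}"] = pooled_abundance_envelope(
            filtered, meta, a, b,
            iterations=cfg.iterations,
            seed=seeds[f"envelope_{i}"],
        )
    results["bc_tests"] = bc_tests
    results["envelopes"] = envelopes
    results["mean_bc"] = {
        f"{a}-{b}": mean_between_bc(mv, meta, a, b, cfg.transform_kind)
        for a, b in PAIRWISE
    }

    # --- per-sample metrics -------------------------------------------------
    metrics = pd.DataFrame(index=pd.Index(mv.sample_ids, name="sample_id"))
    metrics["interval"] = [meta.interval_of(s) for s in mv.sample_ids]
    metrics["n_specimens"] = filtered.sample_totals.loc[mv.sample_ids]
    metrics["dominance"] = [
        dominance(filtered.counts.loc[s].values) for s in mv.sample_ids
    ]
    metrics["warm_fraction"] = warm
    for level in cfg.rarefaction_levels:
        col = []
        for s in mv.sample_ids:
            counts = filtered.counts.loc[s].values
            col.append(
                rarefied_richness(counts, level) if counts.sum() >= level else np.nan
            )
        metrics[f"richness_rarefied_{level}"] = col
    if census is not None:
        depths = preferred_depths(census)
        depth_df = sample_depths(filtered, depths)
        metrics = metrics.join(depth_df)
    results["sample_metrics"] = metrics

    results["biogeo_profiles"] = {
        iv: biogeo_profile(filtered, meta, traits, iv) for iv in INTERVALS
    }
    overlap_tables = {}
    overlaps = {}
    for a, b in (("CIG", "LIG"), ("CIG", "LG")):
        overlaps[f"{a}-{b}"], overlap_tables[f"{a}-{b}"] = topk_overlap(
            filtered, meta, a, b, k=cfg.top_k
        )
    results["topk_overlap"] = overlaps
    results["rank_tables"] = overlap_tables

    # --- scenario -----------------------------------------------------------
    rho_evidence = {
        "rho_interglacial": (
            envelopes["CIG-LIG"].rho_observed, envelopes["CIG-LIG"].p_rho
        ),
        "rho_glacial_1": (envelopes["CIG-LG"].rho_observed, envelopes["CIG-LG"].p_rho),
        "rho_glacial_2": (envelopes["LIG-LG"].rho_observed, envelopes["LIG-LG"].p_rho),
    }
    call = classify_pattern(
        p_interglacial=bc_tests["CIG-LIG"].p_value,
        p_glacial_1=bc_tests["CIG-LG"].p_value,
        p_glacial_2=bc_tests["LIG-LG"].p_value,
        alpha=cfg.alpha,
        rho_evidence=rho_evidence,
        permanova_p=perma.p_value,
    )
    results["scenario"] = call
    return results


def correlate_ordination(
    ordination: OrdinationResult, metrics: pd.DataFrame, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Spearman correlation of each NMDS axis against per-sample covariates
    (rarefied richness, warm-affinity specimen fraction, depth estimate)."""
    if covariates is None:
        covariates = [
            c
            for c in metrics.columns
            if c.startswith("richness_rarefied_") or c in ("warm_fraction", "depth_m")
        ]
    missing = [s for s in ordination.coords.index if s not in metrics.index]
    if missing:
        raise ValidationError(f"metrics missing samples: {missing[:5]}")
    rows = []
    for axis in ordination.coords.columns:
        for cov in covariates:
            joined = pd.concat(
                [ordination.coords[axis], metrics[cov]], axis=1, join="inner"
            ).dropna()
            rho, p = spearman(joined.iloc[:, 0].values, joined.iloc[:, 1].values)
            rows.append({"axis": axis, "covariate": cov, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-based run with manifest
# ---------------------------------------------------------------------------


def _manifest_hash(manifest: dict) -> str:
    text = json.dumps(manifest, sort_keys=True, default=_json_default)
    return hashlib.sha256(text.encode()).hexdigest()


def run(config: RunConfig) -> Path:
    """Load inputs per ``config``, run the analysis, write every artifact and a
    manifest to the output directory. Returns the output directory path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cm = read_community_matrix(config.community_path, dialect=config.dialect)
    meta = read_sample_metadata(config.metadata_path)
    traits = read_traits(config.traits_path)
    census = (
        read_bathymetry_census(config.census_path) if config.census_path else None
    )

    results = run_analysis(cm, meta, traits, census=census, config=config)

    files: dict[str, str] = {}

    def _save_df(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def _save_json(obj, name: str) -> None:
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, default=_json_default))
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    ordination = results["ordination"]
    _save_df(ordination.coords, "nmds_coords.csv", index_label="sample_id")
    _save_json(
        {
            "stress": ordination.stress,
            "k": ordination.k,
            "restarts": ordination.restarts,
            "seed": ordination.seed,
            "converged": ordination.converged,
        },
        "nmds_stress.json",
    )
    _save_df(results["sample_metrics"], "sample_metrics.csv")
    perma = results["permanova"]
    _save_json(dataclasses.asdict(perma), "permanova.json")
    _save_json(results["provenance"], "provenance.json")
    for key, test in results["bc_tests"].items():
        _save_json(test.to_dict(), f"bc_test_{key}.json")
    for key, env in results["envelopes"].items():
        _save_df(env.null_pairs_long(), f"envelope_{key}.csv", index=False)
        _save_json(
            {
                "intervals": list(env.intervals),
                "rho_observed": env.rho_observed,
                "p_rho": env.p_rho,
                "iterations": env.iterations,
                "seed": env.seed,
            },
            f"envelope_{key}.json",
        )
    for key, table in results["rank_tables"].items():
        _save_df(table, f"rank_table_{key}.csv", index=False)
    _save_json(
        {iv: prof.proportions for iv, prof in results["biogeo_profiles"].items()},
        "biogeo_profiles.json",
    )
    results["scenario"].to_json(outdir / "scenario.json")
    files["scenario.json"] = hashlib.sha256((outdir / "scenario.json").read_bytes()).hexdigest()

    corr = correlate_ordination(ordination, results["sample_metrics"])
    _save_df(corr, "ordination_correlations.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": results["stage_seeds"],
        "n_samples_retained": results["n_samples_retained"],
        "n_species_retained": results["n_species_retained"],
        "scenario_label": results["scenario"].label,
        "files": files,
    }
    manifest["manifest_hash"] = _manifest_hash(manifest)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    logger.info("run complete: %s (scenario=%s)", outdir, results["scenario"].label)
    return outdir
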