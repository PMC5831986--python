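"""End-to-end orchestration: simulate -> genotype -> process assays -> associate.

Runs the stages in a fixed order, writes every stage output plus a run
manifest (config hash, seed, input/output checksums, per-stage row counts),
and aborts with a recorded partial manifest when a stage fails.  A pure
in-memory variant (:func:`analyze_cohort`) supports replicate studies such
as the generator's calibration report without touching the filesystem.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay_processing as ap
from . import association_analysis as aa
from . import prt_genotyping as prt
from . import synthetic_cohort as sc

logger = logging.getLogger(__name__)

#: Variables entering the pairwise correlation matrix, in output order.
DEFAULT_VARIABLES = (
    "weighted_mean_cn",
    "hbd2_norm_pg_per_ug",
    "kill_per_protein",
    "gestational_age_days",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records completed stages."""

    def __init__(self, message: str, manifest: "RunManifest | None" = None):
        super().__init__(message)
        self.manifest = manifest


@dataclass
class PipelineConfig:
    out_dir: str | Path = "pipeline_out"
    simulate: bool = True
    seed: int = 0
    sim_config: sc.SimulationConfig | None = None
    peaks_file: str | Path | None = None
    panel_file: str | Path | None = None
    assays_file: str | Path | None = None
    metadata_file: str | Path | None = None
    support: tuple[int, int] = prt.DEFAULT_SUPPORT
    min_channels: int = 2
    pool: str = "assay"
    lod_pg_ml: float = 16.0
    kill_floor_policy: str = "allow_negative"
    variables: tuple[str, ...] = DEFAULT_VARIABLES


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    stages_completed: list[str] = field(default_factory=list)
    row_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages_completed": self.stages_completed,
                    "row_counts": self.row_counts,
                    "input_checksums": self.input_checksums,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "simulate": config.simulate,
            "seed": config.seed,
            "support": list(config.support),
            "min_channels": config.min_channels,
            "pool": config.pool,
            "lod_pg_ml": config.lod_pg_ml,
            "kill_floor_policy": config.kill_floor_policy,
            "variables": list(config.variables),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def merge_cohort(
    calls: pd.DataFrame, assays: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Merge genotype calls, processed assays and metadata on sample_id."""
    df = metadata.merge(calls, on="sample_id", how="left").merge(
        assays, on="sample_id", how="left"
    )
    return df


def analyze_cohort(
    peaks: pd.DataFrame,
    panel: pd.DataFrame,
    assays: pd.DataFrame,
    metadata: pd.DataFrame,
    support: tuple[int, int] = prt.DEFAULT_SUPPORT,
    min_channels: int = 2,
    pool: str = "assay",
    assay_config: ap.AssayConfig | None = None,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
) -> dict:
    """Run genotyping, assay processing and associations in memory.

    Returns a dict with the calls frame, processed assays, merged cohort,
    exclusion result, correlation results (all-comers + strata) and group
    comparisons.
    """
    measurements, _ = prt.parse_peak_table(peaks)
    ref_panel = prt.parse_reference_panel(panel)
    model = prt.fit_calibration(ref_panel, support=support)
    calls = prt.genotype_cohort(
        measurements, model, min_channels=min_channels, pool=pool
    )
    calls_df = prt.calls_to_frame(calls)
    processed = ap.process_assay_table(assays, assay_config or ap.AssayConfig())
    cohort = merge_cohort(calls_df, processed, metadata)
    excl = aa.apply_exclusions(cohort)
    correlations, scatter = aa.pairwise_matrix(excl.all_comers, variables)
    strat, strat_scatter = aa.stratified_correlations(
        excl.outcome_set, variables
    )
    comparisons = [
        c
        for v in variables
        if v != "gestational_age_days"
        for c in [aa.compare_groups(excl.outcome_set, v)]
        if c is not None
    ]
    return {
        "calibration": model,
        "calls": calls_df,
        "assays": processed,
        "cohort": cohort,
        "exclusions": excl,
        "correlations": correlations,
        "stratified": strat,
        "scatter": {**scatter, **strat_scatter},
        "comparisons": comparisons,
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline to disk, returning the manifest.

    Raises PipelineError (carrying the partial manifest) on stage failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    manifest_path = out / "manifest.json"

    def fail(stage: str, msg: str):
        manifest.to_json(manifest_path)
        raise PipelineError(f"stage {stage}: {msg}", manifest)

    # Stage 1: inputs (simulate or load).
    if config.simulate:
        sim_cfg = config.sim_config or sc.default_config()
        cohort = sc.simulate_cohort(sim_cfg, seed=config.seed)
        paths = cohort.write(out / "inputs")
        peaks_file, panel_file = paths["peaks"], paths["panel"]
        assays_file, metadata_file = paths["assays"], paths["metadata"]
    else:
        peaks_file = config.peaks_file
        panel_file = config.panel_file
        assays_file = config.assays_file
        metadata_file = config.metadata_file
    for name, p in (
        ("peaks", peaks_file), ("panel", panel_file),
        ("assays", assays_file), ("metadata", metadata_file),
    ):
        if p is None or not Path(p).exists():
            fail("inputs", f"missing {name} file: {p}")
        manifest.input_checksums[name] = _sha256(Path(p))
    manifest.stages_completed.append("inputs")

    # Stage 2: genotyping.
    try:
        measurements, report = prt.parse_peak_table(peaks_file)
        ref_panel = prt.parse_reference_panel(panel_file)
        model = prt.fit_calibration(ref_panel, support=config.support)
        calls = prt.genotype_cohort(
            measurements, model,
            min_channels=config.min_channels, pool=config.pool,
        )
        calls_df = prt.calls_to_frame(calls)
    except (prt.PeakTableFormatError, prt.CalibrationError) as e:
        fail("genotype", str(e))
    n_called = int(calls_df["ml_integer_cn"].notna().sum())
    manifest.row_counts["genotype"] = {
        "rows_read": report.rows_read,
        "rows_unusable": report.flagged,
        "samples": len(calls_df),
        "called": n_called,
        "typing_failures": len(calls_df) - n_called,
    }
    calls_path = out / "calls.csv"
    calls_df.to_csv(calls_path, index=False, float_format="%.10g")
    model.to_json(out / "calibration.json")
    manifest.outputs["calls"] = _sha256(calls_path)
    manifest.outputs["calibration"] = _sha256(out / "calibration.json")
    manifest.stages_completed.append("genotype")

    # Stage 3: assay processing.
    assay_cfg = ap.AssayConfig(
        lod_pg_ml=config.lod_pg_ml, kill_floor_policy=config.kill_floor_policy
    )
    try:
        processed = ap.process_assay_table(assays_file, assay_cfg)
    except (ap.AssayInputError, FileNotFoundError) as e:
        fail("process-assays", str(e))
    manifest.row_counts["assays"] = {
        "samples": len(processed),
        "censored": int(processed["hbd2_censored"].sum()),
    }
    assays_path = out / "assays_processed.csv"
    processed.to_csv(assays_path, index=False, float_format="%.10g")
    manifest.outputs["assays_processed"] = _sha256(assays_path)
    manifest.stages_completed.append("process-assays")

    # Stage 4: association analysis.
    metadata = pd.read_csv(metadata_file)
    cohort_df = merge_cohort(calls_df, processed, metadata)
    missing = [v for v in config.variables if v not in cohort_df.columns]
    if missing:
        fail("associate", f"merged cohort is missing column(s): {', '.join(missing)}")
    excl = aa.apply_exclusions(cohort_df)
    correlations, scatter = aa.pairwise_matrix(excl.all_comers, config.variables)
    strat, strat_scatter = aa.stratified_correlations(
        excl.outcome_set, config.variables
    )
    comparisons = [
        c
        for v in config.variables
        if v != "gestational_age_days"
        for c in [aa.compare_groups(excl.outcome_set, v)]
        if c is not None
    ]
    manifest.row_counts["associate"] = {
        "cohort": len(cohort_df),
        "all_comers": len(excl.all_comers),
        "outcome_set": len(excl.outcome_set),
        "excluded_pre_sampling": len(cohort_df) - len(excl.all_comers),
        "correlations": len(correlations) + len(strat),
    }

    corr_path = out / "correlations.csv"
    aa.correlations_to_frame(list(correlations) + list(strat)).to_csv(
        corr_path, index=False, float_format="%.10g"
    )
    audit_path = out / "exclusions_audit.csv"
    excl.audit.to_csv(audit_path, index=False)
    comp_path = out / "group_comparisons.csv"
    pd.DataFrame(
        [
            {
                "variable": c.variable, "group_a": c.group_a, "group_b": c.group_b,
                "n_a": c.n_a, "n_b": c.n_b, "U": c.u_statistic,
                "p_value": c.p_value, "median_a": c.median_a,
                "median_b": c.median_b, "method": c.method,
            }
            for c in comparisons
        ]
    ).to_csv(comp_path, index=False, float_format="%.10g")
    scatter_path = out / "scatter_matrix.json"
    with open(scatter_path, "w") as fh:
        json.dump({**scatter, **strat_scatter}, fh)
    for name, p in (
        ("correlations", corr_path), ("exclusions_audit", audit_path),
        ("group_comparisons", comp_path), ("scatter_matrix", scatter_path),
    ):
        manifest.outputs[name] = _sha256(p)
    manifest.stages_completed.append("associate")

    manifest.to_json(manifest_path)
    logger.info("pipeline complete: %d stages, outputs in %s",
                len(manifest.stages_completed), out)
    return manifest


def _rho_lookup(results, pairs: dict[str, tuple[str, str]]) -> dict[str, float]:
    out = {}
    for label, (vx, vy) in pairs.items():
        for r in results:
            if {r.var_x, r.var_y} == {vx, vy}:
                out[label] = r.rho
                break
        else:
            out[label] = math.nan
    return out


#: Map from the generator's target_rho keys to merged-cohort column pairs.
RHO_PAIRS = {
    "cn~hbd2": ("weighted_mean_cn", "hbd2_norm_pg_per_ug"),
    "ga~hbd2": ("gestational_age_days", "hbd2_norm_pg_per_ug"),
    "hbd2~kill": ("hbd2_norm_pg_per_ug", "kill_per_protein"),
    "cn~kill": ("weighted_mean_cn", "kill_per_protein"),
}


def replicate_summary(
    config: sc.SimulationConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Simulate replicate cohorts, run the full pipeline in memory on each,
    and summarise the emergent statistics against the configured targets.

    This backs the generator's calibration report: mean and 95% CI of the
    Spearman rho for each variable pair, medians of the analysis variables,
    the censored fraction and the typing-failure rate.
    """
    cfg = config or sc.default_config()
    rows = []
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_replicates)]
    for rep_seed in child_seeds:
        cohort = sc.simulate_cohort(cfg, seed=rep_seed)
        res = analyze_cohort(
            cohort.peaks, cohort.panel, cohort.assays, cohort.metadata,
            assay_config=ap.AssayConfig(lod_pg_ml=cfg.lod_pg_ml),
        )
        rhos = _rho_lookup(res["correlations"], RHO_PAIRS)
        merged = res["cohort"]
        calls = res["calls"]
        rows.append(
            {
                **rhos,
                "median_hbd2": float(merged["hbd2_norm_pg_per_ug"].median()),
                "median_kill": float(merged["kill_per_protein"].median()),
                "censor_fraction": float(merged["hbd2_censored"].mean()),
                "typing_failure_rate": float(
                    calls["ml_integer_cn"].isna().mean()
                ),
            }
        )
    df = pd.DataFrame(rows)
    summary: dict = {"n_replicates": n_replicates, "per_replicate": df}
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        half = 1.96 * float(np.std(vals, ddof=1)) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        summary[col] = {"mean": mean, "ci95": (mean - half, mean + half)}
    sign_ok = (
        (df["cn~hbd2"] > 0) & (df["ga~hbd2"] < 0)
        & (df["hbd2~kill"] > 0) & (df["cn~kill"] > 0)
    )
    summary["sign_pattern_fraction"] = float(sign_ok.mean())
    summary["targets"] = dict(cfg.target_rho)
    return summary
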