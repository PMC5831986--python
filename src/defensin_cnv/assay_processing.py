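"""Processing of ELISA, total-protein and bactericidal kill-assay readings.

Derives the two analysis variables used downstream:

* HBD2 concentration normalised to total protein (pg/ug).  ELISA readings
  below the lower limit of detection (LOD, default 16 pg/ml) — whether
  reported as a sub-LOD number or as an "ND" (not detected) token — are
  substituted by LOD/sqrt(2), the conventional single-value imputation for
  left-censored biomarker data, and flagged.  Censoring is applied before
  protein normalisation, and the censored flag propagates to every derived
  variable.

* Protein-normalised bactericidal activity (%kill per ug total protein).
  Survival of the bacterial inoculum in plain HEPES buffer defines 100%, so
  %kill = 100 * (1 - cfu_test / cfu_control) from the triplicate means.
  Normalisation divides %kill by the total protein concentration (ug/ml) of
  the sample: with a fixed assay volume the per-aliquot protein mass differs
  from the concentration only by a constant factor, which cancels from every
  rank-based statistic, and the concentration basis keeps %kill values on
  the percent scale at which replicate noise is small relative to signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens accepted in the hbd2 column for "undetectable".
ND_TOKENS = {"ND", "nd", "N.D.", "<LOD"}

ASSAY_TABLE_COLUMNS = (
    "sample_id",
    "hbd2_pg_ml",
    "total_protein_ug_ml",
    "cfu_test_1",
    "cfu_test_2",
    "cfu_test_3",
    "cfu_control_1",
    "cfu_control_2",
    "cfu_control_3",
)


class AssayInputError(ValueError):
    """An assay reading violates the input contract (e.g. negative value)."""


@dataclass(frozen=True)
class AssayConfig:
    """Constants of the assay pipeline.

    lod_pg_ml: ELISA lower limit of detection.
    substitution_divisor: censored readings become lod/divisor (sqrt(2)).
    inoculum_cfu_ml: nominal bacterial input of the kill assay.
    assay_volume_ml: volume of sample aliquot in the kill assay (recorded
        for unit bookkeeping; %kill/ug divides by the protein concentration).
    kill_floor_policy: 'allow_negative' keeps growth-over-control as negative
        %kill (rank statistics downstream are unaffected); 'clip_to_zero'
        floors at 0 and flags GROWTH_OBSERVED.
    cv_flag_threshold: triplicate coefficient of variation above which the
        replicate set is QC-flagged.
    """

    lod_pg_ml: float = 16.0
    substitution_divisor: float = math.sqrt(2)
    inoculum_cfu_ml: float = 1e5
    assay_volume_ml: float = 0.050
    kill_floor_policy: str = "allow_negative"
    cv_flag_threshold: float = 0.30

    def __post_init__(self):
        if self.lod_pg_ml <= 0:
            raise AssayInputError("lod_pg_ml must be > 0")
        if self.kill_floor_policy not in ("allow_negative", "clip_to_zero"):
            raise AssayInputError(
                f"unknown kill_floor_policy {self.kill_floor_policy!r}"
            )

    @property
    def substitution_value(self) -> float:
        return self.lod_pg_ml / self.substitution_divisor


@dataclass
class SampleAssays:
    """Per-sample processed assay variables."""

    sample_id: str
    hbd2_raw_pg_ml: float | None          # None = reported undetectable
    hbd2_censored: bool
    hbd2_pg_ml: float                     # post-substitution
    total_protein_ug_ml: float
    hbd2_norm_pg_per_ug: float | None
    cfu_test_mean: float | None
    cfu_control_mean: float | None
    percent_kill: float | None
    kill_per_protein: float | None
    qc_flags: set[str] = field(default_factory=set)


def substitute_below_lod(
    reading: float | None, config: AssayConfig
) -> tuple[float, bool]:
    """Apply LOD/sqrt(2) substitution to one ELISA reading.

    ``reading`` is a non-negative concentration or None for "undetectable".
    Returns (value, censored).  Idempotent: the substituted value itself is
    below the LOD only when lod/sqrt(2) < lod, and re-substitution maps it to
    the same value.
    """
    if reading is None or (isinstance(reading, float) and math.isnan(reading)):
        return config.substitution_value, True
    if reading < 0:
        raise AssayInputError(f"negative ELISA reading {reading!r}")
    if reading < config.lod_pg_ml:
        return config.substitution_value, True
    return float(reading), False


def normalize_to_protein(value: float, total_protein: float) -> float | None:
    """Divide a per-ml quantity by total protein; pg/ml over ug/ml gives pg/ug.

    Returns None when total_protein is non-positive (the sample is flagged by
    the caller and the normalised value withheld).
    """
    if not (total_protein > 0):
        return None
    return value / total_protein


def aggregate_triplicates(
    replicates: Sequence[float], cv_threshold: float = 0.30
) -> tuple[float | None, float | None, set[str]]:
    """Mean and coefficient of variation of replicate cfu/ml quantifications.

    Requires at least 2 usable (finite, non-negative) replicates; returns
    (mean, cv, flags) with REPLICATES_INSUFFICIENT or HIGH_CV flags.
    """
    vals = np.asarray(
        [r for r in replicates if r is not None and math.isfinite(r)], dtype=float
    )
    if (vals < 0).any():
        raise AssayInputError("negative cfu replicate")
    flags: set[str] = set()
    if len(vals) < 2:
        flags.add("REPLICATES_INSUFFICIENT")
        return None, None, flags
    mean = float(np.mean(vals))
    cv = float(np.std(vals, ddof=1) / mean) if mean > 0 else math.inf
    if cv > cv_threshold:
        flags.add("HIGH_CV")
    return mean, cv, flags


def percent_kill(
    cfu_test: float, cfu_control: float, policy: str = "allow_negative"
) -> tuple[float | None, set[str]]:
    """Bactericidal %kill with the buffer control defined as 100% survival.

    %kill = 100 * (1 - cfu_test/cfu_control).  A failed control
    (cfu_control <= 0) yields no value.  Negative values (net growth) are
    kept under 'allow_negative' or floored at 0 with a GROWTH_OBSERVED flag
    under 'clip_to_zero'.
    """
    flags: set[str] = set()
    if not (cfu_control > 0):
        flags.add("CONTROL_FAILURE")
        return None, flags
    pk = 100.0 * (1.0 - cfu_test / cfu_control)
    if pk < 0:
        flags.add("GROWTH_OBSERVED")
        if policy == "clip_to_zero":
            pk = 0.0
    return pk, flags


def _parse_hbd2_field(raw) -> float | None:
    if isinstance(raw, str):
        token = raw.strip()
        if token in ND_TOKENS:
            return None
        return float(token)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    return float(raw)


def process_sample(
    sample_id: str,
    hbd2_raw,
    total_protein_ug_ml: float,
    cfu_test: Sequence[float],
    cfu_control: Sequence[float],
    config: AssayConfig | None = None,
) -> SampleAssays:
    """Run the full censor -> normalise -> kill-statistic chain for one sample."""
    config = config or AssayConfig()
    raw = _parse_hbd2_field(hbd2_raw)
    hbd2, censored = substitute_below_lod(raw, config)

    flags: set[str] = set()
    if censored:
        flags.add("HBD2_CENSORED")

    hbd2_norm = normalize_to_protein(hbd2, total_protein_ug_ml)
    if hbd2_norm is None:
        flags.add("PROTEIN_NONPOSITIVE")

    test_mean, test_cv, f1 = aggregate_triplicates(cfu_test, config.cv_flag_threshold)
    ctrl_mean, ctrl_cv, f2 = aggregate_triplicates(
        cfu_control, config.cv_flag_threshold
    )
    flags |= {f"TEST_{x}" for x in f1} | {f"CONTROL_{x}" for x in f2}

    pk: float | None = None
    kpp: float | None = None
    if test_mean is not None and ctrl_mean is not None:
        pk, f3 = percent_kill(test_mean, ctrl_mean, config.kill_floor_policy)
        flags |= f3
        if pk is not None:
            kpp = normalize_to_protein(pk, total_protein_ug_ml)
            if kpp is None:
                flags.add("PROTEIN_NONPOSITIVE")

    return SampleAssays(
        sample_id=sample_id,
        hbd2_raw_pg_ml=raw,
        hbd2_censored=censored,
        hbd2_pg_ml=hbd2,
        total_protein_ug_ml=float(total_protein_ug_ml),
        hbd2_norm_pg_per_ug=hbd2_norm,
        cfu_test_mean=test_mean,
        cfu_control_mean=ctrl_mean,
        percent_kill=pk,
        kill_per_protein=kpp,
        qc_flags=flags,
    )


def process_assay_table(source, config: AssayConfig | None = None) -> pd.DataFrame:
    """Process an assays CSV (or DataFrame) into the analysis variables.

    Expected columns: sample_id, hbd2_pg_ml (number or ND token),
    total_protein_ug_ml, cfu_test_1..3, cfu_control_1..3.
    """
    config = config or AssayConfig()
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in ASSAY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AssayInputError(
            f"assay table is missing required column(s): {', '.join(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        s = process_sample(
            str(row.sample_id),
            row.hbd2_pg_ml,
            float(row.total_protein_ug_ml),
            [row.cfu_test_1, row.cfu_test_2, row.cfu_test_3],
            [row.cfu_control_1, row.cfu_control_2, row.cfu_control_3],
            config,
        )
        records.append(
            {
                "sample_id": s.sample_id,
                "hbd2_pg_ml": s.hbd2_pg_ml,
                "hbd2_censored": s.hbd2_censored,
                "hbd2_norm_pg_per_ug": s.hbd2_norm_pg_per_ug,
                "total_protein_ug_ml": s.total_protein_ug_ml,
                "percent_kill": s.percent_kill,
                "kill_per_protein": s.kill_per_protein,
                "qc_flags": ";".join(sorted(s.qc_flags)),
            }
        )
    out = pd.DataFrame.from_records(records)
    n_cens = int(out["hbd2_censored"].sum())
    logger.info(
        "assays: %d samples processed, %d HBD2 readings censored at %.4f pg/ml",
        len(out), n_cens, config.substitution_value,
    )
    return out
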