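"""Paralogue-ratio-test (PRT) copy-number genotyping.

A PRT co-amplifies a test locus inside a copy-number-variable region and a
reference locus outside it with shared primers, so the ratio of the two
capillary-electrophoresis peak areas is (up to assay-specific scale and
offset) proportional to the diploid copy number.  This module turns peak-area
tables into integer copy-number calls in three steps:

1. *Calibration* — per fluorescence channel (assay x dye), ordinary least
   squares of the reference-panel ratios on their known integer copy numbers;
   the fitted line is inverted to map cohort ratios onto the copy-number
   scale, and the dispersion of the calibrated reference estimates around
   their known integers provides a per-channel standard deviation.
2. *Pooling* — dye channels belonging to one assay are averaged into a single
   per-assay estimate (sd scaled by 1/sqrt(#channels)); assays are then pooled
   by an inverse-variance-weighted mean into a continuous copy number.
3. *Maximum-likelihood integer calling* — assuming independent Gaussian
   errors per assay estimate, the integer k in the supported range that
   maximises the joint likelihood is called, with a normalised likelihood
   weight L(k*)/sum_k L(k) reported as the call confidence.

The module is deliberately agnostic about which PRT assays are used; the
default channel set matches a beta-defensin triplex PRT (107A and HSPD21 with
two dyes each, plus a third single-dye assay).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Diploid copy-number support for the beta-defensin CNV locus.
DEFAULT_SUPPORT: tuple[int, int] = (1, 12)

#: Floor applied to per-estimate standard deviations before likelihood
#: evaluation, in copy units.  Prevents degenerate (delta-like) likelihoods
#: from noise-free calibration panels.
SD_FLOOR: float = 1e-3

#: Confidence below which a call is flagged LOW_CONFIDENCE (still emitted).
LOW_CONFIDENCE_THRESHOLD: float = 0.60

PEAK_TABLE_COLUMNS = ("sample_id", "assay", "dye", "test_area", "reference_area")


class PeakTableFormatError(ValueError):
    """A peak-area or reference-panel table violates the input contract."""


class CalibrationError(RuntimeError):
    """Regression calibration failed (no usable channel)."""


@dataclass(frozen=True)
class PRTMeasurement:
    """One calibration-channel observation: peak areas at test and reference loci."""

    sample_id: str
    assay: str
    dye: str
    test_area: float
    reference_area: float

    @property
    def ratio(self) -> float:
        """Test/reference peak-area ratio; NaN when the measurement is unusable."""
        if not self.usable:
            return math.nan
        return self.test_area / self.reference_area

    @property
    def usable(self) -> bool:
        """Both peak areas strictly positive and finite."""
        return (
            math.isfinite(self.test_area)
            and math.isfinite(self.reference_area)
            and self.test_area > 0
            and self.reference_area > 0
        )

    @property
    def channel(self) -> tuple[str, str]:
        return (self.assay, self.dye)


@dataclass
class ParseReport:
    rows_read: int
    usable: int
    flagged: int


@dataclass
class ReferencePanel:
    """Samples of known integer copy number used to calibrate each channel."""

    known_cn: dict[str, int]
    measurements: list[PRTMeasurement]

    def validate(self, support: tuple[int, int] = DEFAULT_SUPPORT) -> None:
        lo, hi = support
        for sid, cn in self.known_cn.items():
            if not (isinstance(cn, (int, np.integer)) and lo <= cn <= hi):
                raise PeakTableFormatError(
                    f"reference sample {sid!r}: known_cn {cn!r} is not an "
                    f"integer in the supported range {lo}..{hi}"
                )


@dataclass
class ChannelCalibration:
    """Fitted linear map ratio = slope * copy_number + intercept for one channel."""

    assay: str
    dye: str
    slope: float
    intercept: float
    residual_sd: float
    n_ref: int
    failed: bool = False
    message: str = ""


@dataclass
class CalibrationModel:
    channels: dict[tuple[str, str], ChannelCalibration]
    support: tuple[int, int] = DEFAULT_SUPPORT

    def channel(self, assay: str, dye: str) -> ChannelCalibration | None:
        return self.channels.get((assay, dye))

    def to_dict(self) -> dict:
        return {
            "support": list(self.support),
            "channels": [
                {
                    "assay": c.assay,
                    "dye": c.dye,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "residual_sd": c.residual_sd,
                    "n_ref": c.n_ref,
                    "failed": c.failed,
                    "message": c.message,
                }
                for c in self.channels.values()
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class ChannelEstimate:
    """Calibrated continuous copy-number estimate from a single channel."""

    assay: str
    dye: str
    estimate: float
    sd: float
    out_of_support: bool


@dataclass
class CopyNumberCall:
    sample_id: str
    channel_estimates: dict[tuple[str, str], ChannelEstimate]
    assay_estimates: dict[str, tuple[float, float]]
    weighted_mean_cn: float | None
    ml_integer_cn: int | None
    confidence: float | None
    qc_flags: set[str] = field(default_factory=set)


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PeakTableFormatError(
            f"{what} is missing required column(s): {', '.join(missing)}"
        )


def parse_peak_table(source) -> tuple[list[PRTMeasurement], ParseReport]:
    """Parse a peak-area CSV (or DataFrame) into measurements.

    Rows with missing or non-positive peak areas are retained but flagged
    unusable; duplicated (sample_id, assay, dye) rows are an error because a
    channel can contribute at most one observation per sample.
    """
    df = _read_table(source)
    _require_columns(df, PEAK_TABLE_COLUMNS, "peak table")

    keys = df[["sample_id", "assay", "dye"]].astype(str)
    dup_mask = keys.duplicated(keep=False)
    if dup_mask.any():
        dups = sorted(set(map(tuple, keys[dup_mask].itertuples(index=False))))
        raise PeakTableFormatError(
            "duplicate (sample_id, assay, dye) rows: "
            + "; ".join(str(d) for d in dups[:20])
        )

    measurements: list[PRTMeasurement] = []
    usable = 0
    for row in df.itertuples(index=False):
        m = PRTMeasurement(
            sample_id=str(row.sample_id),
            assay=str(row.assay),
            dye=str(row.dye),
            test_area=float(row.test_area) if pd.notna(row.test_area) else math.nan,
            reference_area=float(row.reference_area)
            if pd.notna(row.reference_area)
            else math.nan,
        )
        if m.usable:
            usable += 1
        measurements.append(m)

    report = ParseReport(
        rows_read=len(measurements), usable=usable, flagged=len(measurements) - usable
    )
    logger.info(
        "peak table: %d rows read, %d usable, %d flagged unusable",
        report.rows_read,
        report.usable,
        report.flagged,
    )
    return measurements, report


def parse_reference_panel(source) -> ReferencePanel:
    """Parse a reference-panel CSV: peak-table columns plus integer known_cn."""
    df = _read_table(source)
    _require_columns(df, PEAK_TABLE_COLUMNS + ("known_cn",), "reference panel")
    measurements, _ = parse_peak_table(df[list(PEAK_TABLE_COLUMNS)])
    known: dict[str, int] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        cn = row.known_cn
        if float(cn) != int(cn):
            raise PeakTableFormatError(
                f"reference sample {sid!r}: known_cn {cn!r} is not an integer"
            )
        cn = int(cn)
        if sid in known and known[sid] != cn:
            raise PeakTableFormatError(
                f"reference sample {sid!r} has conflicting known_cn values"
            )
        known[sid] = cn
    panel = ReferencePanel(known_cn=known, measurements=measurements)
    return panel


def fit_calibration(
    panel: ReferencePanel,
    support: tuple[int, int] = DEFAULT_SUPPORT,
    min_residual_df: int = 3,
) -> CalibrationModel:
    """Fit the per-channel linear map from copy number to peak-area ratio.

    The regression is oriented with ratio as the response (ratio ~ known_cn)
    and inverted later for prediction.  ``residual_sd`` is the standard
    deviation (ddof=1) of the calibrated estimates (ratio - intercept)/slope
    minus the known integers; channels with fewer than ``min_residual_df``
    residual degrees of freedom fall back to the residual dispersion pooled
    across all non-failed channels.

    Raises
    ------
    CalibrationError
        If no channel yields a usable calibration (slope > 0).
    """
    panel.validate(support)
    by_channel: dict[tuple[str, str], list[PRTMeasurement]] = {}
    for m in panel.measurements:
        by_channel.setdefault(m.channel, []).append(m)

    channels: dict[tuple[str, str], ChannelCalibration] = {}
    residual_pools: dict[tuple[str, str], np.ndarray] = {}

    for key, ms in sorted(by_channel.items()):
        assay, dye = key
        usable = [m for m in ms if m.usable and m.sample_id in panel.known_cn]
        cns = np.array([panel.known_cn[m.sample_id] for m in usable], dtype=float)
        ratios = np.array([m.ratio for m in usable], dtype=float)
        if len(np.unique(cns)) < 2:
            channels[key] = ChannelCalibration(
                assay, dye, math.nan, math.nan, math.nan, len(usable),
                failed=True,
                message="fewer than 2 distinct known copy numbers",
            )
            logger.warning("channel %s/%s: calibration failed (%s)", assay, dye,
                           channels[key].message)
            continue
        fit = stats.linregress(cns, ratios)
        if not (fit.slope > 0):
            channels[key] = ChannelCalibration(
                assay, dye, fit.slope, fit.intercept, math.nan, len(usable),
                failed=True,
                message=f"non-positive slope {fit.slope:.4g}",
            )
            logger.warning("channel %s/%s: calibration failed (%s)", assay, dye,
                           channels[key].message)
            continue
        calibrated = (ratios - fit.intercept) / fit.slope
        residuals = calibrated - cns
        sd = float(np.std(residuals, ddof=1)) if len(residuals) >= 2 else math.nan
        channels[key] = ChannelCalibration(
            assay, dye, float(fit.slope), float(fit.intercept), sd, len(usable)
        )
        residual_pools[key] = residuals

    ok = [c for c in channels.values() if not c.failed]
    if not ok:
        raise CalibrationError("calibration failed for every channel")

    # Pooled residual sd across channels, for channels with too few residual df.
    all_res = np.concatenate([r for r in residual_pools.values()]) if residual_pools else np.array([])
    total_df = sum(max(len(r) - 2, 0) for r in residual_pools.values())
    pooled_sd = (
        float(np.sqrt(sum(float(r @ r) for r in residual_pools.values()) / total_df))
        if total_df > 0
        else float(np.std(all_res, ddof=1)) if len(all_res) >= 2 else 0.0
    )
    for key, cal in channels.items():
        if cal.failed:
            continue
        df_res = cal.n_ref - 2
        if df_res < min_residual_df or not math.isfinite(cal.residual_sd):
            cal.residual_sd = pooled_sd

    return CalibrationModel(channels=channels, support=support)


def apply_calibration(
    model: CalibrationModel, m: PRTMeasurement
) -> ChannelEstimate | None:
    """Map one measurement onto the copy-number scale via its channel calibration.

    Returns None (with a logged warning) when the channel calibration is
    absent or failed, or the measurement is unusable.  Estimates outside
    [support_min - 1, support_max + 1] are flagged out-of-support but retained.
    """
    cal = model.channel(m.assay, m.dye)
    if cal is None or cal.failed:
        logger.warning(
            "sample %s: no calibration for channel %s/%s; estimate omitted",
            m.sample_id, m.assay, m.dye,
        )
        return None
    if not m.usable:
        return None
    estimate = (m.ratio - cal.intercept) / cal.slope
    lo, hi = model.support
    out = not (lo - 1 <= estimate <= hi + 1)
    return ChannelEstimate(
        assay=m.assay, dye=m.dye, estimate=float(estimate),
        sd=float(cal.residual_sd), out_of_support=out,
    )


def call_integer_cn(
    estimates: Sequence[float],
    sds: Sequence[float],
    support: tuple[int, int] = DEFAULT_SUPPORT,
    sd_floor: float = SD_FLOOR,
) -> tuple[int, float]:
    """Maximum-likelihood integer copy number from pooled continuous estimates.

    Under independent Gaussian errors, log L(k) = sum_i [-log(sd_i sqrt(2 pi))
    - (x_i - k)^2 / (2 sd_i^2)] is maximised over the integer support; ties go
    to the smaller integer.  The confidence is the normalised likelihood
    weight L(k*)/sum_k L(k), evaluated with max-subtraction for stability.
    """
    x = np.asarray(estimates, dtype=float)
    s = np.maximum(np.asarray(sds, dtype=float), sd_floor)
    if x.size == 0 or x.size != s.size:
        raise ValueError("estimates and sds must be equal-length and non-empty")
    lo, hi = support
    ks = np.arange(lo, hi + 1, dtype=float)
    # loglik[j] over integers; constant term kept so L is a proper density product
    const = -np.sum(np.log(s * math.sqrt(2 * math.pi)))
    sq = -((x[None, :] - ks[:, None]) ** 2) / (2 * s[None, :] ** 2)
    loglik = const + sq.sum(axis=1)
    best = int(np.argmax(loglik))  # first (= smallest k) on ties
    lik = np.exp(loglik - loglik[best])
    confidence = float(lik[best] / lik.sum())
    return int(ks[best]), confidence


def weighted_mean_cn(estimates: Sequence[float], sds: Sequence[float],
                     sd_floor: float = SD_FLOOR) -> float:
    """Inverse-variance-weighted mean of continuous copy-number estimates."""
    x = np.asarray(estimates, dtype=float)
    s = np.maximum(np.asarray(sds, dtype=float), sd_floor)
    w = 1.0 / s**2
    return float(np.sum(w * x) / np.sum(w))


def _aggregate_assays(
    channel_estimates: Iterable[ChannelEstimate],
) -> dict[str, tuple[float, float]]:
    """Average dye channels within an assay; sd of the mean = sqrt(sum sd^2)/n."""
    by_assay: dict[str, list[ChannelEstimate]] = {}
    for ce in channel_estimates:
        by_assay.setdefault(ce.assay, []).append(ce)
    out: dict[str, tuple[float, float]] = {}
    for assay, ces in sorted(by_assay.items()):
        n = len(ces)
        est = float(np.mean([c.estimate for c in ces]))
        sd = float(np.sqrt(sum(c.sd**2 for c in ces)) / n)
        out[assay] = (est, sd)
    return out


def genotype_sample(
    sample_id: str,
    measurements: Sequence[PRTMeasurement],
    model: CalibrationModel,
    min_channels: int = 2,
    pool: str = "assay",
    sd_floor: float = SD_FLOOR,
    low_confidence: float = LOW_CONFIDENCE_THRESHOLD,
) -> CopyNumberCall:
    """Genotype one sample from its channel measurements.

    ``pool='assay'`` (default) averages dye channels within an assay before
    pooling, so a triplex PRT contributes three pooled estimates;
    ``pool='channel'`` pools the raw channels directly.
    """
    channel_estimates: dict[tuple[str, str], ChannelEstimate] = {}
    for m in measurements:
        ce = apply_calibration(model, m)
        if ce is not None:
            channel_estimates[m.channel] = ce

    if pool == "assay":
        pooled = _aggregate_assays(channel_estimates.values())
    elif pool == "channel":
        pooled = {
            f"{a}/{d}": (ce.estimate, ce.sd)
            for (a, d), ce in sorted(channel_estimates.items())
        }
    else:
        raise ValueError(f"unknown pooling mode {pool!r}")

    flags: set[str] = set()
    if any(ce.out_of_support for ce in channel_estimates.values()):
        flags.add("OUT_OF_SUPPORT")

    if len(pooled) < min_channels:
        flags.add("TOO_FEW_CHANNELS")
        return CopyNumberCall(
            sample_id=sample_id,
            channel_estimates=channel_estimates,
            assay_estimates=pooled,
            weighted_mean_cn=None,
            ml_integer_cn=None,
            confidence=None,
            qc_flags=flags,
        )

    ests = [e for e, _ in pooled.values()]
    sds = [s for _, s in pooled.values()]
    wmean = weighted_mean_cn(ests, sds, sd_floor=sd_floor)
    ml, conf = call_integer_cn(ests, sds, support=model.support, sd_floor=sd_floor)
    if conf < low_confidence:
        flags.add("LOW_CONFIDENCE")
    return CopyNumberCall(
        sample_id=sample_id,
        channel_estimates=channel_estimates,
        assay_estimates=pooled,
        weighted_mean_cn=wmean,
        ml_integer_cn=ml,
        confidence=conf,
        qc_flags=flags,
    )


def genotype_cohort(
    measurements: Sequence[PRTMeasurement],
    model: CalibrationModel,
    min_channels: int = 2,
    pool: str = "assay",
) -> list[CopyNumberCall]:
    """Genotype every sample in a parsed peak table."""
    by_sample: dict[str, list[PRTMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)
    return [
        genotype_sample(sid, ms, model, min_channels=min_channels, pool=pool)
        for sid, ms in sorted(by_sample.items())
    ]


def calls_to_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    """Tabulate calls for the calls CSV output."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "weighted_mean_cn": [c.weighted_mean_cn for c in calls],
            "ml_integer_cn": [
                c.ml_integer_cn if c.ml_integer_cn is not None else pd.NA
                for c in calls
            ],
            "confidence": [c.confidence for c in calls],
            "qc_flags": [";".join(sorted(c.qc_flags)) for c in calls],
        }
    ).astype({"ml_integer_cn": "Int64"})
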