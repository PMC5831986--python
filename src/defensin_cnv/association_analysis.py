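"""Rank-based association analysis of the merged cohort.

Pairwise Spearman correlations among copy number, normalised HBD2, protein-
normalised bactericidal activity and gestational age at sampling; cohort
exclusion rules with an audit trail; term/preterm stratification; and a
Mann-Whitney two-group comparison.

Spearman's rho is computed as the Pearson correlation of mid-ranks (average
ranks for ties).  The two-sided p-value uses exact permutation enumeration
for n <= 9 when neither variable has ties, and otherwise the t approximation
t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of freedom.  The
method actually used is recorded on every result.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Largest n for which the exact permutation p-value is enumerated (no ties).
EXACT_SPEARMAN_N_MAX = 9

#: Largest group size min(n1, n2) for which Mann-Whitney uses an exact p.
EXACT_MW_MIN_N_MAX = 8

#: Cap on C(n1+n2, n1) for full-assignment Mann-Whitney enumeration
#: (the enumeration handles ties; beyond the cap a tie-free exact method or
#: the tie-corrected normal approximation is used).
MW_ENUMERATION_CAP = 200_000

EXCLUSION_FLAG_COLUMNS = (
    "pre_sampling_progesterone",
    "post_sampling_cerclage",
    "post_sampling_progesterone",
)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    rho: float
    p_value: float
    stratum: str = "all"
    method_note: str = ""


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    method: str


@dataclass
class ExclusionResult:
    all_comers: pd.DataFrame
    outcome_set: pd.DataFrame
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p by full enumeration (tie-free ranks).

    With ties absent, rho for a permutation is 1 - 6*sum(d^2)/(n(n^2-1)),
    a strictly decreasing function of sum(d^2), so tail counting can be done
    on the d^2 statistic.
    """
    n = len(rx)
    denom = n * (n**2 - 1)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    ry_sorted = np.sort(ry)
    rx = np.asarray(rx)
    for perm in itertools.permutations(ry_sorted):
        d = rx - np.asarray(perm)
        rho = 1.0 - 6.0 * float(d @ d) / denom
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_n_max: int = EXACT_SPEARMAN_N_MAX,
) -> SpearmanResult | None:
    """Spearman rank correlation with pairwise-complete handling.

    Returns None (logged) for n < 3 or when either variable is constant
    after pairwise-complete filtering.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        logger.info("spearman: only %d complete pairs, no result", n)
        return None
    rx, ry = _midranks(xv), _midranks(yv)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        logger.warning("spearman: constant input, correlation undefined")
        return SpearmanResult(math.nan, math.nan, n, "CONSTANT_INPUT")

    rho = float(np.corrcoef(rx, ry)[0, 1])

    has_ties = len(np.unique(xv)) < n or len(np.unique(yv)) < n
    if n <= exact_n_max and not has_ties:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
        method = "t_approximation"
    if has_ties:
        method += ";midranks_ties"
    return SpearmanResult(rho=rho, p_value=min(p, 1.0), n=n, method=method)


def _mw_u_from_ranks(pooled_ranks: np.ndarray, idx_a: Sequence[int], n_a: int) -> float:
    r_a = float(np.sum(pooled_ranks[list(idx_a)]))
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Exact by full enumeration of group assignments when C(n1+n2, n1) is small
    enough (handles ties; identical groups give p = 1); exact via the
    tie-free distribution when min(n) is small and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (U of group a, p, method).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = _mw_u_from_ranks(ranks, range(n_a), n_a)

    n = n_a + n_b
    if min(n_a, n_b) <= EXACT_MW_MIN_N_MAX and comb(n, n_a) <= MW_ENUMERATION_CAP:
        # Full enumeration of which pooled observations form group a.
        u_low = min(u_a, n_a * n_b - u_a)
        u_high = n_a * n_b - u_low
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            u = _mw_u_from_ranks(ranks, idx, n_a)
            if u <= u_low + 1e-9 or u >= u_high - 1e-9:
                count += 1
            total += 1
        return u_a, min(count / total, 1.0), "exact_enumeration"
    has_ties = len(np.unique(pooled)) < n
    if min(n_a, n_b) <= EXACT_MW_MIN_N_MAX and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact_distribution"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "normal_approx_tie_corrected"


def pairwise_matrix(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    stratum: str = "all",
    min_n: int = 3,
) -> tuple[list[CorrelationResult], dict[str, dict[str, list[float]]]]:
    """Spearman correlations for every unordered variable pair.

    Returns the results plus scatterplot-matrix data: for each pair a dict
    with the pairwise-complete x and y value lists, keyed "var_x~var_y".
    """
    unknown = [v for v in variables if v not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown variable(s): {', '.join(unknown)}")
    results: list[CorrelationResult] = []
    scatter: dict[str, dict[str, list[float]]] = {}
    for vx, vy in itertools.combinations(variables, 2):
        xv, yv = _pairwise_complete(cohort[vx], cohort[vy])
        key = f"{vx}~{vy}"
        if len(xv) < min_n:
            logger.info("pair %s in stratum %s: n=%d < %d, not emitted",
                        key, stratum, len(xv), min_n)
            continue
        res = spearman(xv, yv)
        if res is None or math.isnan(res.rho):
            continue
        results.append(
            CorrelationResult(
                var_x=vx, var_y=vy, n=res.n, rho=res.rho,
                p_value=res.p_value, stratum=stratum, method_note=res.method,
            )
        )
        scatter[key] = {"x": xv.tolist(), "y": yv.tolist()}
    return results, scatter


def apply_exclusions(cohort: pd.DataFrame) -> ExclusionResult:
    """Split the cohort into the two analysis sets with an audit trail.

    * all-comers set: everyone except women who started progesterone before
      sampling (never analysable).
    * outcome-analysis set: additionally excludes treatment to prevent
      preterm birth given after sampling (cerclage, progesterone) and
      pregnancies ending in miscarriage or termination.
    """
    for col in EXCLUSION_FLAG_COLUMNS:
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing exclusion flag column {col!r}")

    audit_rows: list[dict] = []

    pre = cohort["pre_sampling_progesterone"].astype(bool)
    for sid in cohort.loc[pre, "sample_id"]:
        audit_rows.append({"sample_id": sid, "rule": "pre_sampling_progesterone",
                           "excluded_from": "all"})
    all_comers = cohort.loc[~pre].copy()

    outcome = all_comers["outcome"].astype(str) if "outcome" in all_comers else None
    drop = pd.Series(False, index=all_comers.index)
    rules = [
        ("post_sampling_cerclage", all_comers["post_sampling_cerclage"].astype(bool)),
        ("post_sampling_progesterone",
         all_comers["post_sampling_progesterone"].astype(bool)),
    ]
    if outcome is not None:
        rules.append(("miscarriage", outcome == "miscarriage"))
        rules.append(("termination", outcome == "termination"))
    for rule, mask in rules:
        for sid in all_comers.loc[mask, "sample_id"]:
            audit_rows.append({"sample_id": sid, "rule": rule,
                               "excluded_from": "outcome_set"})
        drop |= mask
    outcome_set = all_comers.loc[~drop].copy()

    audit = pd.DataFrame(audit_rows, columns=["sample_id", "rule", "excluded_from"])
    logger.info(
        "exclusions: %d in, %d all-comers, %d outcome set (%d audit entries)",
        len(cohort), len(all_comers), len(outcome_set), len(audit),
    )
    if outcome_set.empty:
        logger.warning("exclusions left an empty outcome-analysis set")
    return ExclusionResult(all_comers=all_comers, outcome_set=outcome_set, audit=audit)


def stratified_correlations(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome_col: str = "outcome",
    strata: Sequence[str] = ("term", "preterm"),
    min_n: int = 3,
) -> tuple[list[CorrelationResult], dict[str, dict[str, list[float]]]]:
    """Run the pairwise matrix within each outcome stratum.

    Strata below ``min_n`` are reported with an UNDERPOWERED method note and
    NaN statistics rather than silently suppressed, and strata large enough
    to compute but small (n < 30) carry an UNDERPOWERED note alongside the
    p-value method.
    """
    results: list[CorrelationResult] = []
    scatter: dict[str, dict[str, list[float]]] = {}
    for stratum in strata:
        sub = cohort.loc[cohort[outcome_col].astype(str) == stratum]
        if len(sub) < min_n:
            for vx, vy in itertools.combinations(variables, 2):
                results.append(
                    CorrelationResult(
                        var_x=vx, var_y=vy, n=len(sub), rho=math.nan,
                        p_value=math.nan, stratum=stratum,
                        method_note="UNDERPOWERED;n<3",
                    )
                )
            continue
        res, sc = pairwise_matrix(sub, variables, stratum=stratum, min_n=min_n)
        if len(sub) < 30:
            res = [
                CorrelationResult(
                    var_x=r.var_x, var_y=r.var_y, n=r.n, rho=r.rho,
                    p_value=r.p_value, stratum=r.stratum,
                    method_note=r.method_note + ";UNDERPOWERED",
                )
                for r in res
            ]
        results.extend(res)
        scatter.update({f"{stratum}:{k}": v for k, v in sc.items()})
    return results, scatter


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "outcome",
    group_labels: tuple[str, str] = ("term", "preterm"),
) -> GroupComparison | None:
    """Mann-Whitney comparison of one variable between two outcome groups."""
    la, lb = group_labels
    a = cohort.loc[cohort[group_col].astype(str) == la, variable].dropna().to_numpy()
    b = cohort.loc[cohort[group_col].astype(str) == lb, variable].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        logger.info("compare_groups %s: an empty group, no result", variable)
        return None
    u, p, method = mann_whitney(a, b)
    return GroupComparison(
        variable=variable, group_a=la, group_b=lb, n_a=len(a), n_b=len(b),
        u_statistic=u, p_value=p,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        method=method,
    )


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "var_x": [r.var_x for r in results],
            "var_y": [r.var_y for r in results],
            "n": [r.n for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "method_note": [r.method_note for r in results],
        }
    )
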