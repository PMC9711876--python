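"""Clinical endpoints: responder classification, biomarker stratification,
survival analysis, correlations, and the small trial formulas.

Responders are patients with a PSA decline of at least 50% or a tumor-volume
decrease of at least 30% at the landmark visit (thresholds inclusive, OR
rule). Biomarker stratification is strict (> cutoff) on the activity score.
Survival uses the Kaplan-Meier product-limit estimator and the two-group
log-rank test; at tied times, events are processed before censorings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

PSA_RESPONSE_PCT = -50.0
VOLUME_RESPONSE_PCT = -30.0

#: Column dictionary for the per-patient clinical table (CSV; optional
#: columns may be absent or empty).
CLINICAL_COLUMNS = {
    "patient_id": "unique patient label",
    "psa_pre": "baseline serum PSA, ng/mL (> 0)",
    "psa_on": "on-treatment serum PSA, ng/mL",
    "tumor_volume_pre": "baseline tumor volume, mm^3 (optional)",
    "tumor_volume_on": "on-treatment tumor volume, mm^3 (optional)",
    "rpfs_months": "radiographic progression-free survival time, months",
    "rpfs_event": "1 = progression event, 0 = censored",
    "os_months": "overall survival time, months",
    "os_event": "1 = death, 0 = censored",
    "arawm_score": "per-patient AR activity score in [0, 1] (optional)",
    "myc_hscore_pre": "baseline MYC H-score (optional)",
    "myc_hscore_on": "on-treatment MYC H-score (optional)",
    "ki67_hscore_pre": "baseline Ki-67 H-score (optional)",
    "ki67_hscore_on": "on-treatment Ki-67 H-score (optional)",
    "ar_od_pre": "baseline total AR OD (optional)",
    "ar_od_on": "on-treatment total AR OD (optional)",
    "nc_ratio_pre": "baseline AR N:C ratio (optional)",
    "nc_ratio_on": "on-treatment AR N:C ratio (optional)",
}


def read_clinical_table(path) -> pd.DataFrame:
    """Read the per-patient CSV; empty cells stay as missing (NaN)."""
    frame = pd.read_csv(path)
    if "patient_id" not in frame.columns:
        raise ValueError("clinical table needs a 'patient_id' column")
    return frame


# ---------------------------------------------------------------------------
# endpoint primitives


def percent_change(pre: float, on: float) -> float:
    """100 * (on - pre) / pre; baseline must be positive."""
    if not pre > 0:
        raise ValueError(f"baseline must be > 0, got {pre}")
    return 100.0 * (on - pre) / pre


def classify_response(
    psa_pre: float,
    psa_on: float,
    tumor_volume_pre: float | None = None,
    tumor_volume_on: float | None = None,
) -> tuple[bool, bool]:
    """Responder call: PSA decline >= 50% OR volume decrease >= 30%.

    Returns ``(responder, volume_used)``; when volume is unavailable the
    classification is PSA-only and ``volume_used`` is False.
    """
    psa_pct = percent_change(psa_pre, psa_on)
    responder = psa_pct <= PSA_RESPONSE_PCT
    volume_used = False
    has_vol = (
        tumor_volume_pre is not None and tumor_volume_on is not None
        and not (pd.isna(tumor_volume_pre) or pd.isna(tumor_volume_on))
    )
    if has_vol:
        volume_used = True
        if percent_change(tumor_volume_pre, tumor_volume_on) <= VOLUME_RESPONSE_PCT:
            responder = True
    else:
        logger.debug("volume unavailable; PSA-only response classification")
    return bool(responder), volume_used


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate with risk-table counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit survival estimate (censored leave the risk set after
    their time; at ties, events precede censorings)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table[kmf.event_table["removed"] > 0]
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if int(ea.sum()) + int(eb.sum()) == 0:
        raise ValueError("log-rank undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# group comparisons and correlations


def paired_and_group_tests(x, y, mode: str) -> tuple[float, float]:
    """Two-tailed comparisons: ``paired`` t, ``welch`` t, or ``chi2`` on a
    2x2 proportion table (x = (successes_a, n_a), y = (successes_b, n_b))."""
    if mode == "paired":
        a, b = np.asarray(x, float), np.asarray(y, float)
        if a.size != b.size:
            raise ValueError("paired mode needs equal-length vectors")
        if a.size < 2:
            raise ValueError("need n >= 2 pairs")
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
    elif mode == "welch":
        a, b = np.asarray(x, float), np.asarray(y, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per group")
        t, p = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "chi2":
        (sa, na), (sb, nb) = x, y
        if min(na, nb) < 1:
            raise ValueError("empty group in proportion test")
        table = np.array([[sa, na - sa], [sb, nb - sb]], dtype=float)
        if table.min() < 0:
            raise ValueError("successes exceed group size")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(t), float(p)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Optional Benjamini-Hochberg adjustment (reported p-values are
    unadjusted by default; call this explicitly when screening many tests)."""
    if method != "bh":
        raise ValueError(f"unsupported adjustment {method!r}")
    return stats.false_discovery_control(np.asarray(pvalues, float))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p (t transform, n - 2 df)."""
    a, b = np.asarray(x, float), np.asarray(y, float)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# trial formulas


def tumor_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Caliper tumor volume 0.5236 * L * W * H (mm^3); 0.5236 is pi/6 to 4
    decimals, i.e. the ellipsoid approximation."""
    if min(length_mm, width_mm, height_mm) <= 0:
        raise ValueError("caliper dimensions must be positive")
    return 0.5236 * length_mm * width_mm * height_mm


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """qPCR fold change 2**(-ddCt) with dCt = Ct_target - Ct_reference."""
    cts = [ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl]
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def predicted_population_response(
    prevalence_pct: float, conditional_response_pct: float
) -> float:
    """Population response rate = prevalence x conditional response, as a
    percent rounded half-up to one decimal (e.g. 36.5 x 70 -> 25.6)."""
    for v in (prevalence_pct, conditional_response_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must be in [0, 100]")
    raw = Decimal(str(prevalence_pct)) * Decimal(str(conditional_response_pct)) / Decimal(100)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# stratified endpoint summary


@dataclass
class StratificationResult:
    """Endpoint comparison between biomarker-high and -low strata."""

    cutoff: float
    high: pd.DataFrame
    low: pd.DataFrame
    responder_proportions: dict = field(default_factory=dict)
    response_chi2: tuple[float, float] | None = None
    percent_change_psa: dict = field(default_factory=dict)
    km: dict = field(default_factory=dict)  # endpoint -> {stratum: SurvivalCurve}
    logrank: dict = field(default_factory=dict)  # endpoint -> (stat, p)
    warnings: list[str] = field(default_factory=list)


def _responders(frame: pd.DataFrame) -> pd.Series:
    out = {}
    for _, row in frame.iterrows():
        resp, _ = classify_response(
            row["psa_pre"], row["psa_on"],
            row.get("tumor_volume_pre"), row.get("tumor_volume_on"),
        )
        out[row["patient_id"]] = resp
    return pd.Series(out)


def stratify_by_biomarker(
    records: pd.DataFrame,
    scores: pd.Series | None = None,
    cutoff: float = 0.6,
) -> StratificationResult:
    """Split patients at score > cutoff (strict) and compare endpoints.

    ``records`` follows CLINICAL_COLUMNS; scores come from the
    ``arawm_score`` column unless supplied separately (indexed by
    patient_id). Survival endpoints (rPFS, OS) are compared by Kaplan-Meier
    and log-rank when both strata are populated; otherwise comparisons are
    skipped with a warning.
    """
    frame = records.copy()
    if scores is not None:
        frame["arawm_score"] = frame["patient_id"].map(scores)
    if "arawm_score" not in frame.columns or frame["arawm_score"].isna().any():
        raise ValueError("every stratified record needs a score")
    is_high = frame["arawm_score"] > cutoff
    result = StratificationResult(cutoff=cutoff, high=frame[is_high], low=frame[~is_high])
    for name, sub in (("high", result.high), ("low", result.low)):
        if len(sub):
            resp = _responders(sub)
            result.responder_proportions[name] = float(resp.mean())
            result.percent_change_psa[name] = [
                percent_change(p, o) for p, o in zip(sub["psa_pre"], sub["psa_on"])
            ]
    if len(result.high) == 0 or len(result.low) == 0:
        msg = "all records fall in one stratum; comparisons skipped"
        logger.warning(msg)
        result.warnings.append(msg)
        return result
    n_hi, n_lo = len(result.high), len(result.low)
    k_hi = int(round(result.responder_proportions["high"] * n_hi))
    k_lo = int(round(result.responder_proportions["low"] * n_lo))
    result.response_chi2 = paired_and_group_tests((k_hi, n_hi), (k_lo, n_lo), mode="chi2")
    for endpoint in ("rpfs", "os"):
        tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
        if tcol not in frame.columns or frame[tcol].isna().any():
            continue
        curves = {}
        for name, sub in (("high", result.high), ("low", result.low)):
            curves[name] = km_estimate(sub[tcol].to_numpy(), sub[ecol].to_numpy(dtype=bool))
        result.km[endpoint] = curves
        try:
            result.logrank[endpoint] = logrank_test(
                result.high[tcol], result.high[ecol].astype(bool),
                result.low[tcol], result.low[ecol].astype(bool),
            )
        except ValueError as exc:
            result.warnings.append(f"{endpoint}: log-rank skipped ({exc})")
    return result
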