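"""Case-control diagnostic accuracy statistics for session-level alerting.

Sessions with an annotated significant deterioration are *cases*, an
equal number without are *controls*.  A case counts as a true positive
when at least one alert falls inside the detection window before its
event (24 h usual, 72 h exploratory); a control counts as a false
positive when it alerts at all.  From the resulting 2x2 table:

* sensitivity/specificity carry exact (Clopper-Pearson) binomial CIs;
* PPV/NPV are computed at a fixed prevalence pi via

      PPV = se*pi / (se*pi + (1-sp)(1-pi))
      NPV = sp*(1-pi) / ((1-se)*pi + sp*(1-pi))

  with logit-transformed confidence intervals (Mercaldo's method);
* paired method comparisons use McNemar's test on discordant pairs
  (continuity-corrected chi-square, exact binomial when discordants are
  few);
* warning times summarise first qualifying alert to event, in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EvaluationConfig:
    detection_window_hours: float = 72.0
    prevalence: float = 0.056
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.detection_window_hours <= 0:
            raise ValueError("detection window must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class AccuracyEstimates:
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: float
    ppv_ci: tuple[float, float]
    npv: float
    npv_ci: tuple[float, float]
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if np.isnan(v):  # degenerate test: predictive value undefined
                continue
            lo, hi = getattr(self, name + "_ci")
            if not (0 <= v <= 1 and 0 <= lo <= hi <= 1):
                raise ValueError(f"{name} estimate/CI outside [0, 1] or unordered")


@dataclass(frozen=True)
class WarningTimeSummary:
    """Hours from first qualifying alert to the event, over detected events."""

    n: int
    total: float
    mean: float
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if self.n > 0:
            if not self.min <= self.q1 <= self.median <= self.q3 <= self.max:
                raise ValueError("quartiles out of order")
            if abs(self.mean - self.total / self.n) > 1e-9:
                raise ValueError("mean must equal total/n")


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion x/n."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n, n > 0")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def predictive_values(se: float, sp: float, prevalence: float) -> tuple[float, float]:
    """PPV and NPV at a fixed prevalence (Bayes' rule on se/sp).

    A degenerate test (always positive / always negative) leaves one
    predictive value undefined; NaN is returned for it.
    """
    pi = np.float64(prevalence)
    se = np.float64(se)
    sp = np.float64(sp)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
        npv = sp * (1 - pi) / ((1 - se) * pi + sp * (1 - pi))
    return float(ppv), float(npv)


def _logit_ci(point: float, var_logit: float, level: float) -> tuple[float, float]:
    if np.isnan(point):
        return (float("nan"), float("nan"))
    if point <= 0.0 or point >= 1.0 or not np.isfinite(var_logit):
        return (max(point, 0.0), min(point, 1.0)) if point in (0.0, 1.0) else (0.0, 1.0)
    z = stats.norm.ppf(0.5 + level / 2)
    logit = np.log(point / (1 - point))
    lo, hi = logit - z * np.sqrt(var_logit), logit + z * np.sqrt(var_logit)
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    return float(expit(lo)), float(expit(hi))


def mercaldo_ci(
    table: ContingencyTable, prevalence: float, level: float = 0.95
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Logit-transformed CIs for prevalence-fixed PPV and NPV.

    Delta-method variances of logit(PPV)/logit(NPV) in terms of the
    binomial variances of the sensitivity and specificity estimates.
    """
    n1, n0 = table.n_cases, table.n_controls
    se = np.float64(table.tp) / n1
    sp = np.float64(table.tn) / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        # boundary estimates (se or sp of 0/1) yield infinite logit
        # variance; the CI then degenerates to the whole unit interval
        var_ppv = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
        var_npv = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
    ppv, npv = predictive_values(se, sp, prevalence)
    return _logit_ci(ppv, var_ppv, level), _logit_ci(npv, var_npv, level)


def classify_sessions(
    case_alert_minutes: dict[str, list[int]],
    control_alert_minutes: dict[str, list[int]],
    event_minutes: dict[str, int],
    cfg: EvaluationConfig | None = None,
) -> ContingencyTable:
    """Session-level 2x2 table under the study's alert-accounting rule.

    A case is a true positive iff any alert starts within
    ``detection_window_hours`` before (and up to) its event minute; a
    control is a false positive iff it has any alert at all.
    """
    cfg = cfg or EvaluationConfig()
    window = cfg.detection_window_hours * 60.0
    tp = fn = fp = tn = 0
    for sid, alerts in case_alert_minutes.items():
        if sid not in event_minutes:
            raise ValueError(f"case session {sid!r} has no event time")
        ev = event_minutes[sid]
        hit = any(ev - window <= a <= ev for a in alerts)
        tp += hit
        fn += not hit
    for sid, alerts in control_alert_minutes.items():
        fp += bool(alerts)
        tn += not alerts
    return ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)


def accuracy(table: ContingencyTable, cfg: EvaluationConfig | None = None) -> AccuracyEstimates:
    """Sensitivity/specificity with exact CIs; PPV/NPV at fixed prevalence."""
    cfg = cfg or EvaluationConfig()
    if table.n_cases == 0:
        raise ValueError("sensitivity undefined: no case sessions")
    if table.n_controls == 0:
        raise ValueError("specificity undefined: no control sessions")
    se = table.tp / table.n_cases
    sp = table.tn / table.n_controls
    ppv, npv = predictive_values(se, sp, cfg.prevalence)
    ppv_ci, npv_ci = mercaldo_ci(table, cfg.prevalence, cfg.ci_level)
    return AccuracyEstimates(
        sensitivity=se,
        sensitivity_ci=clopper_pearson(table.tp, table.n_cases, cfg.ci_level),
        specificity=sp,
        specificity_ci=clopper_pearson(table.tn, table.n_controls, cfg.ci_level),
        ppv=ppv,
        ppv_ci=ppv_ci,
        npv=npv,
        npv_ci=npv_ci,
        prevalence=cfg.prevalence,
    )


@dataclass(frozen=True)
class PairedComparison:
    difference: float
    difference_ci: tuple[float, float]
    discordant: tuple[int, int]
    statistic: float | None
    p_value: float
    exact: bool


def mcnemar_test(b: int, c: int, exact_below: int = 25) -> tuple[float | None, float, bool]:
    """McNemar's test on discordant counts (b: A-only, c: B-only).

    Continuity-corrected chi-square; exact two-sided binomial when the
    discordant total is below ``exact_below``.  Returns
    ``(statistic, p, used_exact)``.
    """
    n_disc = b + c
    if n_disc == 0:
        return None, 1.0, True
    if n_disc < exact_below:
        p = 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5)
        if b == c:
            p = 1.0
        return None, float(min(p, 1.0)), True
    statistic = (abs(b - c) - 1) ** 2 / n_disc
    return float(statistic), float(stats.chi2.sf(statistic, df=1)), False


def compare_paired(
    flags_a: np.ndarray, flags_b: np.ndarray, level: float = 0.95
) -> PairedComparison:
    """Paired difference in a detection proportion (B minus A) + McNemar.

    ``flags_a``/``flags_b`` are per-session booleans for the two methods
    on the *same* sessions (e.g. cases for sensitivity, controls for
    specificity, detected vs not).  The difference CI is the paired Wald
    interval on discordant counts.
    """
    a = np.asarray(flags_a, dtype=bool)
    b_arr = np.asarray(flags_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired flag arrays must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("no paired sessions")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    diff = (c - b) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(b + c - (b - c) ** 2 / n, 0.0)) / n
    statistic, p, exact = mcnemar_test(b, c)
    return PairedComparison(
        difference=float(diff),
        difference_ci=(float(diff - half), float(diff + half)),
        discordant=(b, c),
        statistic=statistic,
        p_value=p,
        exact=exact,
    )


def summarize_warning_times(times_hours: list[float] | np.ndarray) -> WarningTimeSummary:
    """Five-number-plus-mean summary (inclusive linear quartiles)."""
    t = np.sort(np.asarray(times_hours, dtype=float))
    if len(t) == 0:
        return WarningTimeSummary(0, 0.0, float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), float("nan"))
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    return WarningTimeSummary(
        n=len(t),
        total=float(t.sum()),
        mean=float(t.sum() / len(t)),
        min=float(t[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(t[-1]),
    )


def warning_times(
    alert_minutes: dict[str, list[int]],
    event_minutes: dict[str, int],
    cfg: EvaluationConfig | None = None,
) -> WarningTimeSummary:
    """Hours from first qualifying alert to event, over detected cases only.

    Cases with no alert inside the detection window are excluded (their
    count shows in the reduced ``n``).
    """
    cfg = cfg or EvaluationConfig()
    window = cfg.detection_window_hours * 60.0
    times = []
    for sid, ev in event_minutes.items():
        qualifying = [a for a in alert_minutes.get(sid, []) if ev - window <= a <= ev]
        if qualifying:
            times.append((ev - min(qualifying)) / 60.0)
    return summarize_warning_times(times)
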