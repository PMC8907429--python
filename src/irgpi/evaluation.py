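"""Evaluation of a fitted or published pair-index score.

Covers the classification side (ROC with the maximum-Youden cutoff and a
confusion summary: low scores are expected in responders) and the survival
side (Kaplan-Meier curves, log-rank comparison, a binary-covariate Cox
hazard ratio with Breslow tie handling, an exhaustive OS-driven cutpoint
scan, and fixed-effect inverse-variance meta-analysis of per-cohort hazard
ratios with the I-squared heterogeneity statistic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_core import IrgpiError, SurvivalRecord, clinical_frame
from .screening import logrank_test, DegenerateTestError

logger = logging.getLogger("irgpi")

_DIRECTIONS = ("low_is_positive", "high_is_positive")


def _as_series(scores) -> pd.Series:
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    return pd.Series(dict(scores), dtype=float)


# ---------------------------------------------------------------------------
# ROC / Youden / confusion
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    direction: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_and_youden(
    scores, labels, direction: str = "low_is_positive"
) -> RocResult:
    """ROC analysis of a score against binary responder labels.

    With the default ``low_is_positive`` direction a sample is predicted
    positive (responder) when its score is <= the threshold.  Thresholds are
    midpoints between consecutive distinct scores plus -inf/+inf sentinels;
    AUC is the trapezoidal area under (1 - specificity, sensitivity); the
    Youden cutoff maximizes J = sensitivity + specificity - 1, ties broken
    toward higher sensitivity then lower threshold.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    s = _as_series(scores)
    y = pd.Series(labels).reindex(s.index)
    if y.isna().any():
        missing = y.index[y.isna()].tolist()
        raise IrgpiError(f"labels missing for scored samples: {missing[:10]}")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise IrgpiError("both classes must be present for ROC analysis")

    vals = s.to_numpy(dtype=float)
    if direction == "high_is_positive":
        vals = -vals
    pos = y.to_numpy()
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos

    distinct = np.unique(vals)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred_pos = vals <= thr
        tp = int((pred_pos & pos).sum())
        tn = int((~pred_pos & ~pos).sum())
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg

    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    j = sens + spec - 1.0
    best = np.lexsort((thresholds, -sens, -j))[0]
    youden_j = float(j[best])
    cutoff = float(thresholds[best])
    if direction == "high_is_positive":
        cutoff = -cutoff
    return RocResult(
        thresholds=thresholds if direction == "low_is_positive" else -thresholds[::-1],
        sensitivity=sens if direction == "low_is_positive" else sens[::-1],
        specificity=spec if direction == "low_is_positive" else spec[::-1],
        auc=auc,
        youden_cutoff=cutoff,
        youden_j=youden_j,
        direction=direction,
    )


@dataclass
class ConfusionSummary:
    tp: int
    fn: int
    tn: int
    fp: int
    orr_low: float | None = None
    orr_high: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        """Percent of true positives among positives, one-decimal rounding."""
        return round(100.0 * self.tp / (self.tp + self.fn), 1)

    @property
    def specificity(self) -> float:
        return round(100.0 * self.tn / (self.tn + self.fp), 1)

    @property
    def accuracy(self) -> float:
        return round(100.0 * (self.tp + self.tn) / self.n, 1)

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "ConfusionSummary":
        return cls(tp=tp, fn=fn, tn=tn, fp=fp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tp": [self.tp], "fn": [self.fn], "tn": [self.tn], "fp": [self.fp],
                "sensitivity_pct": [self.sensitivity],
                "specificity_pct": [self.specificity],
                "accuracy_pct": [self.accuracy],
                "orr_low": [self.orr_low], "orr_high": [self.orr_high],
            }
        )


def classify_and_confuse(
    scores, cutoff: float, labels, direction: str = "low_is_positive"
) -> ConfusionSummary:
    """Split samples at a fixed cutoff and tabulate against responder labels.

    The low-score group (score <= cutoff) is predicted responder under the
    default direction.  ``orr_low`` / ``orr_high`` report the observed
    responder fraction within each score group.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s = _as_series(scores)
    y = pd.Series(labels).reindex(s.index).astype(bool)
    low = (s <= cutoff).to_numpy()
    pos = y.to_numpy()
    pred_pos = low if direction == "low_is_positive" else ~low
    tp = int((pred_pos & pos).sum())
    fn = int((~pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    fp = int((pred_pos & ~pos).sum())
    orr_low = float(pos[low].mean()) if low.any() else None
    orr_high = float(pos[~low].mean()) if (~low).any() else None
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp, orr_low=orr_low, orr_high=orr_high)


# ---------------------------------------------------------------------------
# survival comparison
# ---------------------------------------------------------------------------


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns a frame with columns time, n_at_risk, n_events, survival; one row
    per distinct event/censoring time, survival evaluated just after each
    time.  Tied events at one time form a single step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table[kmf.event_table.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "n_at_risk": table["at_risk"].to_numpy(dtype=int),
            "n_events": table["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def median_survival(curve: pd.DataFrame) -> float | None:
    """First time at which the KM curve reaches 0.5 or below; None if never."""
    hit = curve[curve["survival"] <= 0.5]
    if hit.empty:
        return None
    return float(hit["time"].iloc[0])


@dataclass
class CoxBinaryFit:
    log_hr: float
    se: float
    capped: bool = False  # True when the likelihood was monotone (HR unbounded)

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci(self) -> tuple[float, float]:
        z = 1.959963984540054
        with np.errstate(over="ignore"):  # capped fits can overflow to inf
            lo = float(np.exp(self.log_hr - z * self.se))
            hi = float(np.exp(self.log_hr + z * self.se))
        return lo, hi


def cox_binary_breslow(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray,
    max_iter: int = 100, tol: float = 1e-10, cap: float | None = None,
) -> CoxBinaryFit:
    """Cox proportional-hazards fit for one binary covariate, Breslow ties.

    Newton-Raphson on the Breslow partial likelihood; with a single 0/1
    covariate the score and information reduce to sums over distinct event
    times of the at-risk group counts.  Returns the log hazard ratio
    (group 1 vs group 0) and its Wald standard error.

    When the likelihood is monotone (the MLE diverges, e.g. every high-group
    subject fails before the low group), the fit raises unless ``cap`` is
    given, in which case the coefficient is clamped at ``+-cap`` and the
    result flagged ``capped`` -- the hazard ratio is then a lower bound, not
    an estimate.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups, int)
    if (g == 0).all() or (g == 1).all():
        raise DegenerateTestError("only one group present")
    if not e.any():
        raise DegenerateTestError("no events observed")
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]

    event_times = np.unique(t[e == 1])
    # risk-set composition at each event time
    n1_list, n0_list, d_list, d1_list = [], [], [], []
    idx, n = 0, len(t)
    n1_at_risk, n0_at_risk = int(g.sum()), int((1 - g).sum())
    for tau in event_times:
        while idx < n and t[idx] < tau:
            n1_at_risk -= g[idx]
            n0_at_risk -= 1 - g[idx]
            idx += 1
        at_tau = t == tau
        d_list.append(int(e[at_tau].sum()))
        d1_list.append(int(e[at_tau & (g == 1)].sum()))
        n1_list.append(n1_at_risk)
        n0_list.append(n0_at_risk)
    n1a = np.array(n1_list, float)
    n0a = np.array(n0_list, float)
    d = np.array(d_list, float)
    d1 = np.array(d1_list, float)

    beta = 0.0
    for _ in range(max_iter):
        w = n1a * math.exp(beta)
        denom = n0a + w
        mu = w / denom
        score = float((d1 - d * mu).sum())
        info = float((d * mu * (1 - mu)).sum())
        if info <= 0:
            raise DegenerateTestError("Cox information is zero")
        # damp the Newton step: the partial likelihood is concave but a full
        # step can overshoot badly when the effect is strong
        step = float(np.clip(score / info, -1.0, 1.0))
        beta += step
        if abs(beta) > 20:
            if cap is None:
                raise IrgpiError("Cox fit diverged (monotone likelihood / separation)")
            logger.warning(
                "binary Cox likelihood is monotone; log-HR capped at %+g "
                "(hazard ratio unbounded)", math.copysign(cap, beta),
            )
            beta = math.copysign(cap, beta)
            capped = True
            break
        if abs(step) < tol:
            capped = False
            break
    else:
        capped = False
    w = n1a * math.exp(beta)
    mu = w / (n0a + w)
    info = float((d * mu * (1 - mu)).sum())
    if info <= 0:
        raise DegenerateTestError("Cox information is zero at the solution")
    return CoxBinaryFit(log_hr=beta, se=1.0 / math.sqrt(info), capped=capped)


@dataclass
class SurvivalComparison:
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    log_hr: float
    log_hr_se: float
    median_low: float | None
    median_high: float | None
    n_low: int
    n_high: int


def compare_survival(
    scores,
    clinical: Sequence[SurvivalRecord],
    cutoff: float,
    endpoint: str = "os",
) -> SurvivalComparison:
    """Kaplan-Meier + log-rank + Cox comparison of score-low vs score-high groups.

    The high group (score > cutoff) is the Cox covariate-1 group, so the
    hazard ratio reads as the hazard of high-score relative to low-score
    patients (expected > 1 when high scores confer poor survival).
    """
    s = _as_series(scores)
    clin = clinical_frame(clinical)
    if endpoint == "pfs":
        clin = clin.dropna(subset=["pfs_time", "pfs_event"])
        time_col, event_col = "pfs_time", "pfs_event"
    elif endpoint == "os":
        time_col, event_col = "os_time", "os_event"
    else:
        raise ValueError("endpoint must be 'os' or 'pfs'")
    shared = [i for i in s.index if i in clin.index]
    if not shared:
        raise IrgpiError("no overlap between scores and clinical records")
    s = s.loc[shared]
    times = clin.loc[shared, time_col].to_numpy(float)
    events = clin.loc[shared, event_col].to_numpy(int)
    high = (s > cutoff).to_numpy()
    if not high.any() or high.all():
        raise IrgpiError("cutoff produces an empty group")
    chi2, p = logrank_test(times, events, high.astype(int))
    fit = cox_binary_breslow(times, events, high.astype(int), cap=20.0)
    low_curve = km_curve(times[~high], events[~high])
    high_curve = km_curve(times[high], events[high])
    return SurvivalComparison(
        km_low=low_curve,
        km_high=high_curve,
        logrank_chi2=chi2,
        logrank_p=p,
        hazard_ratio=fit.hr,
        hr_ci=fit.ci,
        log_hr=fit.log_hr,
        log_hr_se=fit.se,
        median_low=median_survival(low_curve),
        median_high=median_survival(high_curve),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
    )


def os_driven_cutpoint(
    scores,
    clinical: Sequence[SurvivalRecord],
    min_group_fraction: float = 0.10,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive log-rank scan for the score cutoff best separating OS.

    Scans every admissible split between consecutive distinct score values
    (both groups at least ceil(min_group_fraction * n) samples) and returns
    the cutoff with minimal log-rank p, the p itself, and the full scan
    table.  The minimal p is optimism-biased (no multiple-splits correction
    is applied); treat it as a cutpoint chooser, not a valid significance
    level.
    """
    s = _as_series(scores)
    clin = clinical_frame(clinical)
    shared = [i for i in s.index if i in clin.index]
    if len(shared) < 20:
        raise IrgpiError("need at least 20 subjects with OS for a cutpoint scan")
    s = s.loc[shared]
    times = clin.loc[shared, "os_time"].to_numpy(float)
    events = clin.loc[shared, "os_event"].to_numpy(int)
    n = len(s)
    min_size = math.ceil(min_group_fraction * n)
    vals = s.to_numpy(float)
    distinct = np.unique(vals)
    rows = []
    for cut in distinct[:-1]:  # split: low <= cut < high
        high = vals > cut
        n_high = int(high.sum())
        if n_high < min_size or n - n_high < min_size:
            continue
        try:
            chi2, p = logrank_test(times, events, high.astype(int))
        except DegenerateTestError:
            chi2, p = 0.0, 1.0
        rows.append((float(cut), n - n_high, n_high, chi2, p))
    if not rows:
        raise IrgpiError("no admissible cutoff under the minimum-group constraint")
    scan = pd.DataFrame(rows, columns=["cutoff", "n_low", "n_high", "chi_square", "p_value"])
    best = scan.sort_values(["p_value", "cutoff"], kind="stable").iloc[0]
    logger.info(
        "OS cutpoint scan: best cutoff %.4g with log-rank p %.3g "
        "(minimal-p selection is optimism-biased)",
        best["cutoff"], best["p_value"],
    )
    return float(best["cutoff"]), float(best["p_value"]), scan


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    study_log_hr: np.ndarray
    study_se: np.ndarray
    pooled_log_hr: float
    pooled_se: float
    q_statistic: float
    i_squared: float
    heterogeneity_p: float
    study_names: list[str] = field(default_factory=list)

    @property
    def pooled_hr(self) -> float:
        return math.exp(self.pooled_log_hr)

    @property
    def pooled_hr_ci(self) -> tuple[float, float]:
        z = 1.959963984540054
        return (
            math.exp(self.pooled_log_hr - z * self.pooled_se),
            math.exp(self.pooled_log_hr + z * self.pooled_se),
        )

    def to_frame(self) -> pd.DataFrame:
        names = self.study_names or [f"study{i+1}" for i in range(len(self.study_log_hr))]
        rows = pd.DataFrame(
            {
                "study": names,
                "log_hr": self.study_log_hr,
                "se": self.study_se,
                "hr": np.exp(self.study_log_hr),
            }
        )
        pooled = pd.DataFrame(
            {
                "study": ["pooled (fixed effect)"],
                "log_hr": [self.pooled_log_hr],
                "se": [self.pooled_se],
                "hr": [self.pooled_hr],
            }
        )
        return pd.concat([rows, pooled], ignore_index=True)


def meta_fixed_effect(
    studies: Sequence[tuple[float, float]], names: Sequence[str] | None = None
) -> MetaResult:
    """Fixed-effect inverse-variance pooling of per-study log hazard ratios.

    Weights w_i = 1/se_i^2; pooled = sum(w x)/sum(w) with SE = 1/sqrt(sum w);
    Cochran's Q = sum w (x - pooled)^2 on k-1 df; I^2 = max(0, (Q - df)/Q) * 100.
    """
    if not studies:
        raise ValueError("need at least one study")
    x = np.array([s[0] for s in studies], float)
    se = np.array([s[1] for s in studies], float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float((w * x).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    q = float((w * (x - pooled) ** 2).sum())
    df = len(studies) - 1
    if df > 0 and q > 0:
        i2 = max(0.0, (q - df) / q) * 100.0
        het_p = float(stats.chi2.sf(q, df))
    else:
        i2 = 0.0
        het_p = 1.0
    return MetaResult(
        study_log_hr=x,
        study_se=se,
        pooled_log_hr=pooled,
        pooled_se=pooled_se,
        q_statistic=q,
        i_squared=i2,
        heterogeneity_p=het_p,
        study_names=list(names) if names is not None else [],
    )
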