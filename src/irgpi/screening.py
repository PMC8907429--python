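"""Univariate survival screening of gene pairs.

Each candidate pair splits the meta cohort into its score-0 and score-1
groups; a two-group log-rank test measures the association of that split
with overall survival, and Benjamini-Hochberg control of the false discovery
rate selects the candidate pairs (default q < 0.001) that enter the
multivariate signature fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import IrgpiError, SurvivalRecord, clinical_frame
from .pairing import GenePair, PairIndicatorMatrix

logger = logging.getLogger("irgpi")


class DegenerateTestError(IrgpiError):
    """Log-rank test undefined: one group empty, no events, or zero variance."""


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time t, with n_j subjects at risk in group j and
    d_j observed events (d = d_0 + d_1, n = n_0 + n_1), the observed-minus-
    expected contribution for group 1 is d_1 - d * n_1 / n with hypergeometric
    variance d * (n_1/n) * (1 - n_1/n) * (n - d) / (n - 1).  The statistic
    (O - E)^2 / V is referred to chi-square with 1 df.

    Returns ``(chi_square, p_value)``.  Raises :class:`DegenerateTestError`
    when only one group is present, no events occur, or the variance is zero.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=int)
    if t.shape != e.shape or t.shape != g.shape:
        raise ValueError("times, events and groups must have equal length")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("groups must be coded 0/1")
    if (g == 0).all() or (g == 1).all():
        raise DegenerateTestError("only one group present")
    if not e.any():
        raise DegenerateTestError("no events observed")

    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n_total = len(t)
    n1_total = int(g.sum())

    event_times = np.unique(t[e == 1])
    # subjects at risk just before time tau: those with t >= tau
    o_minus_e = 0.0
    var = 0.0
    idx = 0  # first subject with t >= current tau (times sorted ascending)
    n_at_risk = n_total
    n1_at_risk = n1_total
    for tau in event_times:
        while idx < n_total and t[idx] < tau:
            n_at_risk -= 1
            n1_at_risk -= g[idx]
            idx += 1
        at_tau = (t == tau)
        d = int(e[at_tau].sum())
        d1 = int(e[at_tau & (g == 1)].sum())
        n = n_at_risk
        n1 = n1_at_risk
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        raise DegenerateTestError("log-rank variance is zero")
    chi_square = o_minus_e**2 / var
    p_value = float(stats.chi2.sf(chi_square, df=1))
    return float(chi_square), max(p_value, np.finfo(float).tiny)


def univariate_cox_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> tuple[float, float]:
    """Wald test from a univariate Cox fit on the binary group indicator.

    Asymptotically equivalent to the log-rank score test for a binary
    covariate; provided as an optional screening mode.
    """
    from .evaluation import cox_binary_breslow

    fit = cox_binary_breslow(np.asarray(times, float), np.asarray(events, int),
                             np.asarray(groups, int))
    z = fit.log_hr / fit.se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z**2), max(p, np.finfo(float).tiny)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class ScreeningResult:
    """Per-pair log-rank screening table.

    ``table`` columns: pair_label (index), chi_square, p_value, fdr, n0, n1,
    degenerate (pairs constant in the analyzed cohort carry p = 1 and a flag).
    """

    table: pd.DataFrame
    pairs: list[GenePair]
    endpoint: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="pair")


def screen_pairs(
    indicators: PairIndicatorMatrix,
    clinical: Sequence[SurvivalRecord],
    endpoint: str = "os",
    method: str = "logrank",
) -> ScreeningResult:
    """One survival test per pair, groups defined by the pair's 0/1 score.

    Pairs whose indicator is constant among the analyzed samples (possible
    after subsetting) are reported with p = 1 and flagged rather than
    dropped, keeping the result aligned with the pair list.
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError("endpoint must be 'os' or 'pfs'")
    if method not in ("logrank", "cox"):
        raise ValueError("method must be 'logrank' or 'cox'")
    clin = clinical_frame(clinical)
    if endpoint == "pfs":
        clin = clin.dropna(subset=["pfs_time", "pfs_event"])
        time_col, event_col = "pfs_time", "pfs_event"
    else:
        time_col, event_col = "os_time", "os_event"
    shared = [s for s in indicators.sample_ids if s in clin.index]
    if not shared:
        raise IrgpiError("no overlap between indicator samples and clinical records")
    times = clin.loc[shared, time_col].to_numpy(dtype=float)
    events = clin.loc[shared, event_col].to_numpy(dtype=int)
    scores = indicators.data[shared].to_numpy()

    test = logrank_test if method == "logrank" else univariate_cox_test
    rows = []
    n_degenerate = 0
    for i, pair in enumerate(indicators.pairs):
        groups = scores[i]
        n1 = int(groups.sum())
        n0 = len(groups) - n1
        try:
            chi, p = test(times, events, groups)
            degenerate = False
        except DegenerateTestError:
            chi, p = 0.0, 1.0
            degenerate = True
            n_degenerate += 1
        rows.append((pair.label, chi, p, n0, n1, degenerate))
    if n_degenerate:
        logger.info("screening: %d pair(s) degenerate in this cohort (p set to 1)",
                    n_degenerate)
    table = pd.DataFrame(
        rows, columns=["pair", "chi_square", "p_value", "n0", "n1", "degenerate"]
    ).set_index("pair")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table = table[["chi_square", "p_value", "fdr", "n0", "n1", "degenerate"]]
    return ScreeningResult(table, list(indicators.pairs), endpoint)


def select_candidates(
    result: ScreeningResult, fdr_threshold: float = 0.001
) -> list[GenePair]:
    """Pairs with FDR strictly below the threshold, sorted by (fdr, label)."""
    by_label = {p.label: p for p in result.pairs}
    hits = result.table[result.table["fdr"] < fdr_threshold]
    ordered = hits.sort_values(["fdr", "pair"], kind="stable")
    selected = [by_label[l] for l in ordered.index]
    if not selected:
        logger.warning("screening selected no candidate pairs at FDR < %g", fdr_threshold)
    return selected
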