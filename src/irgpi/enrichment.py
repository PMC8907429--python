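"""Single-sample gene-set enrichment and between-group feature comparison.

The per-sample enrichment score is the rank-weighted running-sum integral
(Barbie-style ssGSEA): genes are ranked within a sample, the ranked list is
walked from the top accumulating the weighted in-set fraction minus the
uniform out-of-set fraction, and the score is the sum of the running
differences.  Scores depend only on within-sample gene ranks, matching the
rank-based philosophy of the rest of the pipeline.

Group comparisons (e.g. score-high vs score-low tumors) use the two-sided
Wilcoxon rank-sum test with normal approximation and tie correction,
Benjamini-Hochberg adjusted across features in batch mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, GeneSetCollection, IrgpiError
from .screening import bh_fdr

logger = logging.getLogger("irgpi")


@dataclass
class EnrichmentScores:
    scores: pd.DataFrame  # gene sets x samples
    alpha: float
    normalized: bool

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="gene_set")


def _sample_scores(
    expr_col: np.ndarray,
    genes: np.ndarray,
    set_masks: dict[str, np.ndarray],
    alpha: float,
) -> dict[str, float]:
    # ranks ascending (1 = lowest expression, N = highest); average ranks for ties
    ranks = stats.rankdata(expr_col, method="average")
    # walk order: descending expression, gene symbol as the deterministic tie-break
    order = np.lexsort((genes, -expr_col))
    ranks_o = ranks[order]
    weights = np.abs(ranks_o) ** alpha
    out: dict[str, float] = {}
    n = len(genes)
    for name, mask in set_masks.items():
        in_set = mask[order]
        w_in = np.where(in_set, weights, 0.0)
        p_in = np.cumsum(w_in)
        total_in = p_in[-1]
        p_out = np.cumsum(~in_set) / (n - in_set.sum())
        out[name] = float(np.sum(p_in / total_in - p_out))
    return out


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> EnrichmentScores:
    """Rank-weighted running-sum enrichment score per (gene set, sample).

    ``alpha`` is the rank-weight exponent (0.25 by convention; 0 gives pure,
    unweighted ranks).  Sets sharing fewer than 2 genes with the matrix are
    skipped with a warning; a set covering every gene is an error (the
    out-of-set walk is undefined).  With ``normalize`` the whole score matrix
    is divided by its global (max - min).
    """
    genes = np.asarray(expr.gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    masks: dict[str, np.ndarray] = {}
    for name, members in sets:
        hit = [gene_index[g] for g in members if g in gene_index]
        if len(hit) < 2:
            logger.warning("gene set %r shares <2 genes with the matrix; skipped", name)
            continue
        if len(hit) == len(genes):
            raise IrgpiError(f"gene set {name!r} covers every gene; score undefined")
        mask = np.zeros(len(genes), dtype=bool)
        mask[hit] = True
        masks[name] = mask
    if not masks:
        raise IrgpiError("no usable gene sets after overlap filtering")

    values = expr.data.to_numpy(dtype=float)
    cols = {}
    for j, sample in enumerate(expr.sample_ids):
        cols[sample] = _sample_scores(values[:, j], genes, masks, alpha)
    scores = pd.DataFrame(cols)
    scores = scores.loc[list(masks)]  # stable set order
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return EnrichmentScores(scores, alpha=alpha, normalized=normalize)


@dataclass
class GroupComparison:
    """Per-feature Wilcoxon rank-sum comparison of high vs low groups."""

    table: pd.DataFrame  # feature (index), median_high, median_low, statistic, p_value, fdr, flag

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def compare_feature_by_group(
    feature: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon rank-sum (normal approximation, tie-corrected).

    ``groups`` maps sample id -> "high"/"low".  Returns (U statistic of the
    high group, p-value, constant_flag); a constant feature is reported with
    p = 1 and the flag set.
    """
    f = pd.Series(dict(feature)) if not isinstance(feature, pd.Series) else feature
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    shared = f.index.intersection(g.index)
    f, g = f.loc[shared].astype(float), g.loc[shared]
    hi = f[g == "high"].to_numpy()
    lo = f[g == "low"].to_numpy()
    if len(hi) < 3 or len(lo) < 3:
        raise IrgpiError("both groups need at least 3 samples")
    if np.unique(np.concatenate([hi, lo])).size == 1:
        return float(len(hi) * len(lo) / 2.0), 1.0, True
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue), False


def compare_features_by_group(
    features: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> GroupComparison:
    """Batch comparison of many per-sample features (rows) between groups,
    with BH adjustment across features."""
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    rows = []
    for name, values in features.iterrows():
        stat, p, flag = compare_feature_by_group(values, g)
        shared = values.index.intersection(g.index)
        v = values.loc[shared]
        rows.append(
            (
                name,
                float(v[g.loc[shared] == "high"].median()),
                float(v[g.loc[shared] == "low"].median()),
                stat,
                p,
                flag,
            )
        )
    table = pd.DataFrame(
        rows, columns=["feature", "median_high", "median_low", "statistic", "p_value", "constant"]
    ).set_index("feature")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table = table[["median_high", "median_low", "statistic", "p_value", "fdr", "constant"]]
    return GroupComparison(table)
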