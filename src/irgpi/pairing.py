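"""Gene-pair indicator construction and the constant-pair filter.

A gene pair ``A|B`` scores 1 in a sample iff A's expression strictly exceeds
B's in that sample, else 0 (ties score 0).  Because the score depends only on
the within-sample ordering of two genes, indicator matrices are invariant
under any per-sample strictly increasing transform of expression -- the
property that lets cohorts profiled on different platforms be concatenated
into one meta cohort without normalization.

Pairs that are nearly constant (same score in over 80% of samples in any
cohort) carry no survival-splitting information and are removed before
screening.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, ValidationError


@dataclass(frozen=True, order=True)
class GenePair:
    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"pair genes must differ: {self.gene_a!r}")

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    @classmethod
    def from_label(cls, label: str) -> "GenePair":
        a, sep, b = label.partition("|")
        if not sep or not a or not b:
            raise ValidationError(f"malformed pair label {label!r}; expected 'A|B'")
        return cls(a, b)

    def __str__(self) -> str:
        return self.label


@dataclass
class PairIndicatorMatrix:
    """Binary pair scores: rows are pair labels, columns sample ids, cells 0/1."""

    data: pd.DataFrame
    pairs: list[GenePair]
    cohort_label: str = ""

    def __post_init__(self) -> None:
        labels = [p.label for p in self.pairs]
        if len(set(labels)) != len(labels):
            raise ValidationError("pairs are not unique by label")
        if list(self.data.index) != labels:
            raise ValidationError("data index does not match pair labels")
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValidationError("pair scores must all be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def pair_labels(self) -> list[str]:
        return list(self.data.index)

    def subset_pairs(self, labels: Sequence[str]) -> "PairIndicatorMatrix":
        by_label = {p.label: p for p in self.pairs}
        missing = [l for l in labels if l not in by_label]
        if missing:
            raise ValidationError(f"pairs absent from matrix: {missing[:10]}")
        return PairIndicatorMatrix(
            self.data.loc[list(labels)], [by_label[l] for l in labels], self.cohort_label
        )


def enumerate_candidate_pairs(
    genes: Sequence[str], orientation: str = "canonical"
) -> list[GenePair]:
    """All candidate pairs over a gene universe.

    ``canonical``: one pair per unordered couple, lexicographically smaller
    symbol first (n(n-1)/2 pairs).  ``both``: all ordered pairs (n(n-1)) --
    redundant, since B|A is the exact complement of A|B, but kept for
    fidelity experiments.
    """
    uniq = sorted(set(genes))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 distinct genes to form pairs")
    if orientation == "canonical":
        return [GenePair(a, b) for a, b in itertools.combinations(uniq, 2)]
    if orientation == "both":
        return [GenePair(a, b) for a, b in itertools.permutations(uniq, 2)]
    raise ValueError(f"unknown orientation {orientation!r}")


def compute_pair_indicators(
    expr: ExpressionMatrix, pairs: Sequence[GenePair]
) -> PairIndicatorMatrix:
    """Score every pair in every sample: 1 iff expr(gene_a) > expr(gene_b), strictly."""
    pairs = list(pairs)
    genes = set(expr.gene_ids)
    missing = sorted({g for p in pairs for g in (p.gene_a, p.gene_b)} - genes)
    if missing:
        raise ValidationError(f"pair genes absent from expression matrix: {missing[:20]}")
    a_vals = expr.data.loc[[p.gene_a for p in pairs]].to_numpy()
    b_vals = expr.data.loc[[p.gene_b for p in pairs]].to_numpy()
    scores = (a_vals > b_vals).astype(np.int8)
    df = pd.DataFrame(scores, index=[p.label for p in pairs], columns=expr.data.columns)
    return PairIndicatorMatrix(df, pairs, expr.cohort_label)


def concat_indicator_matrices(
    matrices: Sequence[PairIndicatorMatrix], cohort_label: str = "meta"
) -> PairIndicatorMatrix:
    """Concatenate cohorts sharing a pair list into one meta-cohort matrix.

    Well-defined with no renormalization because the scores are rank-based.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    ref = matrices[0].pair_labels
    for m in matrices[1:]:
        if m.pair_labels != ref:
            raise ValidationError("indicator matrices do not share the same pair list")
    all_samples = list(itertools.chain.from_iterable(m.sample_ids for m in matrices))
    if len(set(all_samples)) != len(all_samples):
        raise ValidationError("sample ids collide across cohorts; cannot merge")
    df = pd.concat([m.data for m in matrices], axis=1)
    return PairIndicatorMatrix(df, list(matrices[0].pairs), cohort_label)


def _score_frequencies(
    expr_list: Sequence[ExpressionMatrix],
    pairs: Sequence[GenePair],
    block_size: int,
) -> np.ndarray:
    """Per (cohort, pair) frequency of score 1, computed in pair blocks so the
    full pairs-x-samples matrix is never resident.  Output is independent of
    block size."""
    freq = np.empty((len(expr_list), len(pairs)))
    for start in range(0, len(pairs), block_size):
        block = list(pairs[start : start + block_size])
        for ci, expr in enumerate(expr_list):
            ind = compute_pair_indicators(expr, block)
            freq[ci, start : start + len(block)] = ind.data.to_numpy().mean(axis=1)
    return freq


def filter_constant_pairs(
    matrices: Sequence[PairIndicatorMatrix], threshold: float = 0.80
) -> list[GenePair]:
    """Drop near-constant pairs; return the pairs kept.

    A pair is dropped iff, in at least one cohort, its score is 0 or 1 in
    strictly more than ``threshold`` of the samples ("over 80%").  A pair
    scoring exactly the threshold fraction is kept.
    """
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must be in (0.5, 1]")
    if not matrices:
        raise ValueError("no matrices given")
    ref = matrices[0].pair_labels
    for m in matrices[1:]:
        if m.pair_labels != ref:
            raise ValidationError("indicator matrices do not share the same pair list")
    keep = np.ones(len(ref), dtype=bool)
    for m in matrices:
        freq1 = m.data.to_numpy().mean(axis=1)
        keep &= ~((freq1 > threshold) | ((1.0 - freq1) > threshold))
    return [p for p, k in zip(matrices[0].pairs, keep) if k]


def filter_constant_pairs_streaming(
    expr_list: Sequence[ExpressionMatrix],
    pairs: Sequence[GenePair],
    threshold: float = 0.80,
    block_size: int = 50_000,
) -> list[GenePair]:
    """Constant-pair filter computed directly from expression, in pair blocks.

    Equivalent to building the full indicator matrices and calling
    :func:`filter_constant_pairs`, but memory-bounded for large pair universes
    (~650k canonical pairs over ~1100 genes)."""
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must be in (0.5, 1]")
    pairs = list(pairs)
    freq = _score_frequencies(expr_list, pairs, block_size)
    dropped = (freq > threshold) | ((1.0 - freq) > threshold)
    keep = ~dropped.any(axis=0)
    return [p for p, k in zip(pairs, keep) if k]


def write_pair_list(pairs: Iterable[GenePair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(p.label + "\n")


def read_pair_list(path) -> list[GenePair]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(GenePair.from_label(line))
    return out


def write_indicator_matrix(matrix: PairIndicatorMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="pair")


def read_indicator_matrix(path, cohort_label: str = "") -> PairIndicatorMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pairs = [GenePair.from_label(l) for l in df.index]
    return PairIndicatorMatrix(df.astype(np.int8), pairs, cohort_label)
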