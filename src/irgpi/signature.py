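"""Fitting and applying the weighted pair-index signature.

The index for a sample is a weighted sum of binary pair scores,

    index(s) = sum_i score_i(s) * coefficient_i,

with coefficients estimated by Cox proportional-hazards regression on the
candidate pairs surviving univariate screening.  Because candidate sets are
typically much larger than the event count, the default fit is two-stage:
an L1-penalized Cox partial likelihood (glmnet-style lasso path) with the
penalty chosen by k-fold cross-validated partial-likelihood deviance selects
a sparse pair set, then an unpenalized multivariate Cox refit on the selected
pairs yields the final coefficients.  Higher index values indicate higher
hazard and a lower chance of responding to checkpoint blockade.

A published 31-pair melanoma signature ships with the package
(:func:`load_bundled_signature`) so cohorts can be scored without refitting.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_core import ExpressionMatrix, IrgpiError, SurvivalRecord, ValidationError, clinical_frame
from .pairing import GenePair, PairIndicatorMatrix, compute_pair_indicators

logger = logging.getLogger("irgpi")

_BUNDLED_RESOURCE = "published_signature.tsv"
_BUNDLED_SHA256 = "4a8ec18de15c744978e2a4ff6441e0373ab053396396805db6ea78e66dfd7c79"


class EmptySelectionError(IrgpiError):
    """The penalized stage selected no pairs (e.g. pure-noise candidates)."""


@dataclass
class SignatureModel:
    """Ordered gene pairs with Cox coefficients."""

    entries: list[tuple[GenePair, float]]
    name: str = "signature"
    provenance: str = "fitted"  # or "bundled"

    def __post_init__(self) -> None:
        labels = [p.label for p, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("signature pair labels must be unique")
        for p, c in self.entries:
            if not np.isfinite(c) or c == 0:
                raise ValidationError(f"coefficient for {p.label} must be finite and non-zero")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.entries])

    @property
    def genes(self) -> list[str]:
        """Distinct gene symbols, in first-appearance order."""
        seen: dict[str, None] = {}
        for p, _ in self.entries:
            seen.setdefault(p.gene_a, None)
            seen.setdefault(p.gene_b, None)
        return list(seen)

    def score_bounds(self) -> tuple[float, float]:
        """Analytic (min, max) of the index over all 0/1 indicator vectors."""
        c = self.coefficients
        return float(np.minimum(c, 0).sum()), float(np.maximum(c, 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [p.gene_a for p, _ in self.entries],
                "gene_b": [p.gene_b for p, _ in self.entries],
                "coefficient": [c for _, c in self.entries],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tcoefficient\n")
            for _, row in df.iterrows():
                fh.write(f"{row['gene_a']}\t{row['gene_b']}\t{row['coefficient']!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None,
                 provenance: str = "fitted") -> "SignatureModel":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        for col in ("gene_a", "gene_b", "coefficient"):
            if col not in df.columns:
                raise IrgpiError(f"{path}: missing column {col!r}")
        entries = [
            (GenePair(str(r.gene_a).strip(), str(r.gene_b).strip()), float(r.coefficient))
            for r in df.itertuples()
        ]
        return cls(entries, name=name or Path(path).stem, provenance=provenance)


def load_bundled_signature() -> SignatureModel:
    """The packaged published 31-pair melanoma signature, coefficients verbatim.

    The file checksum is verified at load time; several genes recur across
    pairs (IDO1, IRF1, EGF, IL1R1, IL11, PRF1, HMOX1), exactly as published.
    """
    data = resources.files("irgpi.data").joinpath(_BUNDLED_RESOURCE).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _BUNDLED_SHA256:
        raise IrgpiError("bundled signature data corrupted (checksum mismatch)")
    df = pd.read_csv(pd.io.common.BytesIO(data), sep="\t", dtype={"gene_a": str, "gene_b": str})
    entries = [
        (GenePair(r.gene_a, r.gene_b), float(r.coefficient)) for r in df.itertuples()
    ]
    return SignatureModel(entries, name="published-melanoma-31", provenance="bundled")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Options for :func:`fit_signature`.

    mode: "auto" (unpenalized when candidates <= events/5, else lasso+refit),
    "lasso_refit", or "unpenalized".  The cross-validation fold assignment is
    driven by ``seed`` (required) so fitted signatures are reproducible.
    """

    seed: int
    mode: str = "auto"
    n_folds: int = 10
    n_alphas: int = 50
    alpha_min_ratio: float = 0.01
    max_coef: float = 10.0  # |coef| above this flags separation; pair dropped

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "lasso_refit", "unpenalized"):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible fits")


def _partial_loglik(beta: np.ndarray, X: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Breslow log partial likelihood at fixed beta (used for CV deviance)."""
    eta = X @ beta
    order = np.argsort(-t, kind="stable")  # descending time
    eta_o, t_o, e_o = eta[order], t[order], e[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # risk set for time t_o[i] = all with time >= t_o[i] = indices [0, j)
        denom = log_cum[j - 1]
        ev = e_o[i:j] == 1
        ll += float(eta_o[i:j][ev].sum() - ev.sum() * denom)
        i = j
    return ll


def _cv_choose_alpha(
    X: np.ndarray, t: np.ndarray, e: np.ndarray, alphas: np.ndarray,
    n_folds: int, seed: int,
) -> float:
    """Pick the lasso penalty maximizing mean held-out partial log-likelihood."""
    rng = np.random.default_rng(seed)
    n = len(t)
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    held_out = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for k in range(n_folds):
        train = folds != k
        test = ~train
        if e[train].sum() < 2 or test.sum() < 2:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train], y[train])
        fitted_alphas = list(est.alphas_)
        for ai, alpha in enumerate(alphas):
            if alpha not in fitted_alphas:
                continue
            beta = est.coef_[:, fitted_alphas.index(alpha)]
            # V&VH-style CV deviance: full-data minus train-only partial loglik
            ll_full = _partial_loglik(beta, X, t, e)
            ll_train = _partial_loglik(beta, X[train], t[train], e[train])
            held_out[ai] += ll_full - ll_train
            counts[ai] += 1
    valid = counts > 0
    if not valid.any():
        raise IrgpiError("cross-validation failed on every fold")
    mean_ll = np.where(valid, held_out / np.maximum(counts, 1), -np.inf)
    return float(alphas[int(np.argmax(mean_ll))])


def _refit_unpenalized(
    ind: pd.DataFrame, t: np.ndarray, e: np.ndarray, labels: list[str], max_coef: float
) -> dict[str, float]:
    """Unpenalized multivariate Cox on the selected pairs; drops separating pairs."""
    current = list(labels)
    while current:
        df = pd.DataFrame(ind[current].to_numpy(), columns=current)
        df["time"] = t
        df["event"] = e
        cph = CoxPHFitter(penalizer=0.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise IrgpiError(f"multivariate Cox refit failed to converge: {err}") from err
        coefs = cph.params_
        worst = coefs.abs().idxmax()
        if abs(coefs[worst]) > max_coef:
            logger.warning("dropping pair %s (|coef| %.2f suggests separation); refitting",
                           worst, abs(coefs[worst]))
            current.remove(worst)
            continue
        return {l: float(coefs[l]) for l in current}
    raise EmptySelectionError("all selected pairs dropped during refit")


def fit_signature(
    indicators: PairIndicatorMatrix,
    clinical: Sequence[SurvivalRecord],
    config: FitConfig,
    name: str = "fitted-signature",
) -> SignatureModel:
    """Fit the pair-index signature on candidate pairs against overall survival.

    ``indicators`` should already be restricted to the screened candidate
    pairs.  Pairs constant among the analyzed samples are dropped up front.
    Raises :class:`EmptySelectionError` when the penalized stage keeps
    nothing (a defined outcome on pure-noise candidates).
    """
    clin = clinical_frame(clinical)
    shared = [s for s in indicators.sample_ids if s in clin.index]
    if len(shared) < 10:
        raise IrgpiError("too few samples with clinical records to fit")
    t = clin.loc[shared, "os_time"].to_numpy(float)
    e = clin.loc[shared, "os_event"].to_numpy(int)
    n_events = int(e.sum())
    if n_events < 10:
        raise IrgpiError(f"need >= 10 events to fit a signature (got {n_events})")
    if len(indicators.pairs) < 2:
        raise IrgpiError("need at least 2 candidate pairs")

    ind = indicators.data[shared].T.astype(float)  # samples x pairs
    keep = ind.columns[(ind.nunique(axis=0) > 1)]
    dropped = len(ind.columns) - len(keep)
    if dropped:
        logger.info("fit: dropped %d pair(s) constant in the fitting cohort", dropped)
    ind = ind[keep]
    if ind.shape[1] < 2:
        raise IrgpiError("fewer than 2 non-constant candidate pairs")

    mode = config.mode
    if mode == "auto":
        mode = "unpenalized" if ind.shape[1] <= n_events / 5 else "lasso_refit"
        logger.info("fit: auto mode resolved to %s (%d candidates, %d events)",
                    mode, ind.shape[1], n_events)

    if mode == "lasso_refit":
        X = ind.to_numpy()
        y = Surv.from_arrays(event=e.astype(bool), time=t)
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=config.n_alphas,
            alpha_min_ratio=config.alpha_min_ratio, fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path.fit(X, y)
        alphas = np.asarray(path.alphas_)
        best_alpha = _cv_choose_alpha(X, t, e, alphas, config.n_folds, config.seed)
        beta = path.coef_[:, list(path.alphas_).index(best_alpha)]
        selected = [l for l, b in zip(ind.columns, beta) if b != 0]
        logger.info("fit: lasso at alpha %.4g selected %d pair(s)", best_alpha, len(selected))
        if not selected:
            raise EmptySelectionError(
                f"lasso selected no pairs at CV-chosen penalty {best_alpha:.4g}"
            )
    else:
        selected = list(ind.columns)

    coef_map = _refit_unpenalized(ind, t, e, selected, config.max_coef)
    by_label = {p.label: p for p in indicators.pairs}
    entries = [(by_label[l], c) for l, c in coef_map.items() if c != 0]
    if not entries:
        raise EmptySelectionError("refit produced no non-zero coefficients")
    return SignatureModel(entries, name=name, provenance="fitted")


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """Per-sample index scores."""

    scores: pd.Series  # index: sample_id, values: float
    signature_name: str = ""

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValidationError("duplicate sample ids in score table")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("scores must be finite")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tirgpi\n")
            for sid, v in self.scores.items():
                fh.write(f"{sid}\t{float(v)!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(pd.Series(df["irgpi"].to_numpy(float), index=df["sample_id"]),
                   signature_name=Path(path).stem)


def compute_irgpi(
    indicators: PairIndicatorMatrix,
    model: SignatureModel,
    missing_policy: str = "error",
) -> ScoreTable:
    """Weighted sum of pair scores: index(s) = sum_i score_i(s) * coefficient_i.

    With ``missing_policy="drop_pair"`` model pairs absent from the indicator
    matrix are excluded from the sum -- the resulting scores are NOT
    comparable to cutoffs derived from the full signature, and a prominent
    warning says so.
    """
    if missing_policy not in ("error", "drop_pair"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    available = set(indicators.pair_labels)
    usable = [(p, c) for p, c in model.entries if p.label in available]
    missing = [p.label for p, _ in model.entries if p.label not in available]
    if missing:
        if missing_policy == "error":
            raise IrgpiError(f"model pairs not scoreable: {missing}")
        logger.warning(
            "WARNING: %d of %d signature pair(s) dropped (%s); scores are NOT "
            "comparable to cutoffs published for the full signature",
            len(missing), len(model), ", ".join(missing[:5]),
        )
    if not usable:
        raise IrgpiError("no scoreable signature pairs")
    labels = [p.label for p, _ in usable]
    coefs = np.array([c for _, c in usable])
    # canonical memory layout so the dot product rounds identically no matter
    # how the indicator frame was assembled (exact rank-invariance relies on it)
    matrix = np.ascontiguousarray(indicators.data.loc[labels].to_numpy(dtype=float))
    scores = matrix.T @ coefs
    return ScoreTable(
        pd.Series(scores, index=pd.Index(indicators.sample_ids, name="sample_id")),
        signature_name=model.name,
    )


def score_cohort_from_expression(
    expr: ExpressionMatrix,
    model: SignatureModel,
    missing_policy: str = "error",
) -> ScoreTable:
    """Score a cohort directly from expression: build indicators for exactly
    the model's pairs, then apply :func:`compute_irgpi`.

    Platform-invariant by construction (only within-sample gene order is
    used); with ``drop_pair`` pairs whose genes are absent are skipped with
    the same comparability warning.
    """
    genes = set(expr.gene_ids)
    scoreable = [p for p in model.pairs if p.gene_a in genes and p.gene_b in genes]
    missing = [p.label for p in model.pairs if p not in scoreable]
    if missing and missing_policy == "error":
        missing_genes = sorted(
            {g for p in model.pairs for g in (p.gene_a, p.gene_b) if g not in genes}
        )
        raise IrgpiError(f"expression matrix lacks signature genes: {missing_genes}")
    if not scoreable:
        raise IrgpiError("no signature pair has both genes in the expression matrix")
    ind = compute_pair_indicators(expr, scoreable)
    return compute_irgpi(ind, model, missing_policy=missing_policy)
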