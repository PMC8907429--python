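"""Synthetic multi-cohort immunotherapy data with a planted pair signature.

The generator emulates the statistical structure the pipeline assumes:
several expression cohorts profiled on different "platforms" (per-cohort
strictly increasing distortions of the same latent values), a planted set of
gene pairs whose weighted indicator sum drives both a proportional-hazards
survival model and a logistic response model, and independent right-
censoring.  The generative model, in full:

1. latent expression: per-sample gene values g ~ lognormal(mu_gene, sigma),
   with gene-level means drawn once per run;
2. a latent binary class per sample (responder-like with probability
   ``responder_fraction``) orients every planted pair: the pair indicator is
   set to its class-consistent orientation with probability
   1 - ``pair_flip_probability`` (by swapping the two genes' values within
   the sample when needed), so indicators correlate with class by a known,
   analytic amount;
3. latent index L(s) = sum_i coefficient_i * indicator_i(s), centered at its
   median; negative coefficients mark responder-up pairs, so responders get
   lower L;
4. survival: OS time ~ exponential with hazard
   baseline_hazard * exp(beta_surv * L), censored by an independent
   exponential whose rate is calibrated so the expected censoring fraction
   equals ``censoring_rate``; PFS uses twice the OS hazard;
5. reported RECIST response: responder with probability
   logistic(-beta_resp * L), responders split CR/PR, non-responders SD/PD;
6. platform effect: each cohort's expression passes through its own strictly
   increasing transform (identity, square, log1p or positive-slope affine),
   which by construction leaves every pair indicator unchanged.

All randomness flows from one root seed through named substreams, so equal
seeds give byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    Cohort,
    ExpressionMatrix,
    SurvivalRecord,
    ValidationError,
    write_clinical,
    write_expression_matrix,
)
from .pairing import GenePair
from .signature import SignatureModel

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "square": lambda x: x**2,
    "log1p": lambda x: np.log1p(x),
    "affine": lambda x: 3.0 * x + 7.0,
}

#: default planted pair coefficients (sign convention: positive = hazard-up,
#: indicator 1 expected in non-responders)
_DEFAULT_COEFS = (1.0, -0.8, 0.9, -0.7, 0.6, -1.0, 0.8, -0.6, 0.7, -0.9)


def default_planted_pairs(n_genes: int) -> list[tuple[GenePair, float]]:
    """Ten disjoint pairs over the first twenty genes of the universe."""
    if n_genes < 2 * len(_DEFAULT_COEFS):
        raise ValidationError("gene universe too small for the default planted pairs")
    pairs = []
    for i, c in enumerate(_DEFAULT_COEFS):
        a = f"G{2 * i + 1:04d}"
        b = f"G{2 * i + 2:04d}"
        pairs.append((GenePair(a, b), c))
    return pairs


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror a three-cohort anti-PD-1 discovery setting: cohort sizes
    (41, 28, 51), responder fraction 0.44, exponential baseline hazard
    ln(2)/25 per month (median OS 25 months at the index median), 40%
    censoring, and a strong planted signal (5% indicator flips, unit
    log-hazard per index unit).
    """

    seed: int
    n_genes: int = 200
    n_samples: tuple[int, ...] = (41, 28, 51)
    planted_pairs: list[tuple[GenePair, float]] | None = None
    responder_fraction: float = 0.44
    pair_flip_probability: float = 0.05
    baseline_hazard: float = math.log(2) / 25.0  # events / month
    censoring_rate: float = 0.40
    beta_surv: float = 1.0
    beta_resp: float = 2.0
    platform_transforms: tuple[str, ...] = ("identity", "square", "log1p")
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.planted_pairs is None:
            self.planted_pairs = default_planted_pairs(self.n_genes)
        if not 0 < self.responder_fraction < 1:
            raise ValidationError("responder_fraction must be in (0,1)")
        if not 0 < self.pair_flip_probability <= 0.5:
            raise ValidationError("pair_flip_probability must be in (0, 0.5]")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0,1)")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        universe = set(self.gene_ids)
        planted_genes: list[str] = []
        for p, c in self.planted_pairs:
            if c == 0 or not np.isfinite(c):
                raise ValidationError(f"planted coefficient for {p.label} must be non-zero")
            planted_genes += [p.gene_a, p.gene_b]
        if len(set(planted_genes)) != len(planted_genes):
            raise ValidationError("planted pairs must use disjoint genes")
        outside = sorted(set(planted_genes) - universe)
        if outside:
            raise ValidationError(f"planted genes outside the gene universe: {outside}")
        for name in self.platform_transforms:
            if name not in _TRANSFORMS:
                raise ValidationError(
                    f"unknown platform transform {name!r}; choices: {sorted(_TRANSFORMS)}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def n_cohorts(self) -> int:
        return len(self.n_samples)


@dataclass
class SyntheticTruth:
    """Ground truth written alongside every generated bundle."""

    signature: SignatureModel
    latent_index: pd.Series  # centered L per sample
    latent_class: pd.Series  # the orientation-driving binary class
    responder: pd.Series  # reported responder labels (CR/PR)
    censoring_rate_empirical: float
    params: dict


@dataclass
class SyntheticCohortBundle:
    cohorts: list[Cohort]
    truth: SyntheticTruth
    config: SimulationConfig


def _calibrate_censoring(hazards: np.ndarray, target: float) -> float:
    """Rate c of an independent exponential censor with mean P(censor) = target.

    For exponential event time with hazard h and censor rate c,
    P(censored) = c / (c + h); solve mean over samples by bisection.
    """
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        frac = float(np.mean(mid / (mid + hazards)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate(config: SimulationConfig) -> SyntheticCohortBundle:
    """Draw a full multi-cohort bundle from the documented generative model."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(6)
    rng_expr, rng_class, rng_swap, rng_surv, rng_cens, rng_resp = (
        np.random.default_rng(s) for s in streams
    )

    genes = config.gene_ids
    n_total = int(sum(config.n_samples))
    sample_ids: list[str] = []
    cohort_of: list[int] = []
    for ci, n in enumerate(config.n_samples):
        for j in range(n):
            sample_ids.append(f"synth{ci + 1}_s{j + 1:03d}")
            cohort_of.append(ci)

    mu_gene = rng_expr.normal(2.0, 1.0, size=config.n_genes)
    values = np.exp(
        rng_expr.normal(mu_gene[:, None], config.sigma, size=(config.n_genes, n_total))
    )
    gene_row = {g: i for i, g in enumerate(genes)}

    z = rng_class.random(n_total) < config.responder_fraction  # latent class

    planted = config.planted_pairs or []
    indicators = np.zeros((len(planted), n_total), dtype=np.int8)
    for pi, (pair, coef) in enumerate(planted):
        ia, ib = gene_row[pair.gene_a], gene_row[pair.gene_b]
        # class-consistent orientation: responders carry indicator 1 only on
        # hazard-lowering (negative-coefficient) pairs
        desired = np.where(z, coef < 0, coef >= 0)
        flips = rng_swap.random(n_total) < config.pair_flip_probability
        desired = desired ^ flips
        current = values[ia] > values[ib]
        swap = current != desired
        a_vals = values[ia].copy()
        values[ia, swap] = values[ib, swap]
        values[ib, swap] = a_vals[swap]
        indicators[pi] = (values[ia] > values[ib]).astype(np.int8)

    coefs = np.array([c for _, c in planted])
    latent = indicators.T @ coefs if len(planted) else np.zeros(n_total)
    latent = latent - float(np.median(latent))

    hazards = config.baseline_hazard * np.exp(config.beta_surv * latent)
    os_event_time = rng_surv.exponential(1.0 / hazards)
    pfs_event_time = rng_surv.exponential(1.0 / (2.0 * hazards))
    c_rate = _calibrate_censoring(hazards, config.censoring_rate)
    if c_rate > 0:
        os_censor = rng_cens.exponential(1.0 / c_rate, size=n_total)
        pfs_censor = rng_cens.exponential(1.0 / (2.0 * c_rate), size=n_total)
    else:
        os_censor = np.full(n_total, np.inf)
        pfs_censor = np.full(n_total, np.inf)
    os_time = np.minimum(os_event_time, os_censor)
    os_event = (os_event_time <= os_censor).astype(int)
    pfs_time = np.minimum(pfs_event_time, pfs_censor)
    pfs_event = (pfs_event_time <= pfs_censor).astype(int)

    p_resp = 1.0 / (1.0 + np.exp(config.beta_resp * latent))
    responder = rng_resp.random(n_total) < p_resp
    cr_draw = rng_resp.random(n_total)
    response = np.where(
        responder,
        np.where(cr_draw < 0.15, "CR", "PR"),
        np.where(cr_draw < 0.35, "SD", "PD"),
    )

    cohorts: list[Cohort] = []
    offset = 0
    sample_index = pd.Index(sample_ids, name="sample_id")
    for ci, n in enumerate(config.n_samples):
        cols = slice(offset, offset + n)
        transform = _TRANSFORMS[
            config.platform_transforms[ci % len(config.platform_transforms)]
        ]
        expr_values = transform(values[:, cols])
        expr = ExpressionMatrix(
            pd.DataFrame(expr_values, index=genes, columns=sample_ids[cols]),
            cohort_label=f"synth{ci + 1}",
        )
        clinical = [
            SurvivalRecord(
                sample_id=sample_ids[offset + j],
                os_time=float(os_time[offset + j]),
                os_event=int(os_event[offset + j]),
                pfs_time=float(pfs_time[offset + j]),
                pfs_event=int(pfs_event[offset + j]),
                response=str(response[offset + j]),
            )
            for j in range(n)
        ]
        cohorts.append(Cohort(expr, clinical, name=f"synth{ci + 1}"))
        offset += n

    truth = SyntheticTruth(
        signature=SignatureModel(
            [(p, float(c)) for p, c in planted], name="planted", provenance="fitted"
        ),
        latent_index=pd.Series(latent, index=sample_index),
        latent_class=pd.Series(z.astype(int), index=sample_index),
        responder=pd.Series(responder, index=sample_index),
        censoring_rate_empirical=float(1.0 - np.mean(os_event)),
        params={
            "seed": config.seed,
            "n_genes": config.n_genes,
            "n_samples": list(config.n_samples),
            "responder_fraction": config.responder_fraction,
            "pair_flip_probability": config.pair_flip_probability,
            "baseline_hazard": config.baseline_hazard,
            "censoring_rate": config.censoring_rate,
            "censoring_rate_calibrated": c_rate,
            "beta_surv": config.beta_surv,
            "beta_resp": config.beta_resp,
            "platform_transforms": list(config.platform_transforms),
        },
    )
    return SyntheticCohortBundle(cohorts, truth, config)


def write_bundle(bundle: SyntheticCohortBundle, directory: str | Path) -> list[Path]:
    """Write per-cohort expression/clinical TSVs and a truth JSON.

    Output is byte-identical for equal seeds and round-trips exactly through
    the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for cohort in bundle.cohorts:
        expr_path = directory / f"{cohort.name}_expression.tsv"
        clin_path = directory / f"{cohort.name}_clinical.tsv"
        write_expression_matrix(cohort.expression, expr_path)
        write_clinical(cohort.clinical, clin_path)
        written += [expr_path, clin_path]
    truth = bundle.truth
    truth_obj = {
        "planted_signature": [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "coefficient": c}
            for p, c in truth.signature.entries
        ],
        "latent_index": {k: float(v) for k, v in truth.latent_index.items()},
        "latent_class": {k: int(v) for k, v in truth.latent_class.items()},
        "responder": {k: bool(v) for k, v in truth.responder.items()},
        "censoring_rate_empirical": truth.censoring_rate_empirical,
        "params": truth.params,
    }
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth_obj, indent=1, sort_keys=True) + "\n")
    written.append(truth_path)
    return written


def load_bundle_cohorts(directory: str | Path) -> list[Cohort]:
    """Re-load the cohorts of a written bundle via the package readers."""
    from .io_core import read_clinical, read_expression_matrix

    directory = Path(directory)
    cohorts = []
    for expr_path in sorted(directory.glob("*_expression.tsv")):
        name = expr_path.name.removesuffix("_expression.tsv")
        expr = read_expression_matrix(expr_path, cohort_label=name)
        clinical = read_clinical(directory / f"{name}_clinical.tsv")
        cohorts.append(Cohort(expr, clinical, name=name))
    return cohorts
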