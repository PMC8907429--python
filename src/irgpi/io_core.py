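"""Domain containers and text-format I/O shared by every pipeline stage.

The pipeline operates on bulk gene-expression matrices (genes x samples,
arbitrary units -- only within-sample rank order is ever used), clinical
tables with right-censored overall/progression-free survival and RECIST
response codes, and GMT gene-set collections.

Conventions (fixed package-wide):

* gene identifiers are HGNC-style symbols, matched case-sensitively after
  trimming whitespace; aliases are not resolved,
* survival times are in months; event code 1 means the event occurred,
* duplicated gene rows are resolved by keeping the row with the highest
  mean expression (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("irgpi")

RESPONSE_CODES = ("CR", "PR", "SD", "PD")
RESPONDER_CODES = frozenset({"CR", "PR"})

#: cell values treated as missing when reading expression matrices
_NA_MARKERS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null", "None"}


class IrgpiError(Exception):
    """Base class for all package errors."""


class ParseError(IrgpiError):
    """A file could not be parsed (malformed cell, bad schema, ...)."""


class ValidationError(IrgpiError):
    """An in-memory object violates a documented invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values, genes in rows and samples in columns.

    Units are arbitrary: every downstream consumer uses only the within-sample
    ordering of genes, so FPKM, TPM, counts or microarray intensities are all
    acceptable and never converted.
    """

    data: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("expression data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains missing/non-finite values")
        if values.size and (values < 0).any():
            raise ValidationError("expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.cohort_label)


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: OS (required), PFS and RECIST response (optional)."""

    sample_id: str
    os_time: float
    os_event: int
    pfs_time: float | None = None
    pfs_event: int | None = None
    response: str | None = None

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValidationError(f"{self.sample_id}: os_time must be > 0")
        if self.os_event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: os_event must be 0 or 1")
        if (self.pfs_time is None) != (self.pfs_event is None):
            raise ValidationError(f"{self.sample_id}: pfs_time and pfs_event must come together")
        if self.pfs_time is not None and self.pfs_time <= 0:
            raise ValidationError(f"{self.sample_id}: pfs_time must be > 0")
        if self.pfs_event is not None and self.pfs_event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: pfs_event must be 0 or 1")
        if self.response is not None and self.response not in RESPONSE_CODES:
            raise ValidationError(
                f"{self.sample_id}: unknown response code {self.response!r}; "
                f"expected one of {RESPONSE_CODES}"
            )

    @property
    def responder(self) -> bool | None:
        """True for CR/PR, False for SD/PD, None when the label is absent."""
        if self.response is None:
            return None
        return self.response in RESPONDER_CODES


@dataclass
class Cohort:
    """An expression matrix together with clinical records for (a subset of) its samples."""

    expression: ExpressionMatrix
    clinical: list[SurvivalRecord]
    name: str = ""

    def __post_init__(self) -> None:
        expr_samples = set(self.expression.sample_ids)
        clin_ids = [r.sample_id for r in self.clinical]
        if len(set(clin_ids)) != len(clin_ids):
            raise ValidationError(f"cohort {self.name}: duplicate clinical sample ids")
        extra = sorted(set(clin_ids) - expr_samples)
        if extra:
            raise ValidationError(
                f"cohort {self.name}: clinical records without expression: {extra[:10]}"
            )
        unmatched = expr_samples - set(clin_ids)
        if unmatched:
            logger.warning(
                "cohort %s: %d expression sample(s) lack clinical rows",
                self.name, len(unmatched),
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


@dataclass
class GeneSetCollection:
    """Named gene sets (a parsed GMT file)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_matrix(
    path: str | Path,
    missing_policy: str = "error",
    cohort_label: str | None = None,
) -> ExpressionMatrix:
    """Read a genes-x-samples expression table (TSV or CSV).

    First column holds gene symbols, the header row sample ids.  Duplicate
    gene symbols are resolved by keeping the row with the highest mean
    expression.  ``missing_policy`` is ``"error"`` (reject files with missing
    cells) or ``"drop_gene"`` (drop any gene row containing a missing cell).
    """
    path = Path(path)
    if missing_policy not in ("error", "drop_gene"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_na = cells.isin(_NA_MARKERS).to_numpy()
        # exact float() conversion: round-trips repr-formatted values bitwise
        values = np.full(len(cells), np.nan)
        for i, (cell, na) in enumerate(zip(cells.to_numpy(), is_na)):
            if na:
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} "
                    f"at gene {raw.index[i]!r}, sample {col!r}"
                ) from None
        numeric[col] = values

    has_missing = numeric.isna().any(axis=1)
    if has_missing.any():
        if missing_policy == "error":
            gene = numeric.index[has_missing.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: missing value(s), first at gene {gene!r}")
        logger.info("%s: dropped %d gene(s) with missing values", path, int(has_missing.sum()))
        numeric = numeric.loc[~has_missing]

    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = numeric.iloc[order]
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        # restore the original first-occurrence row order
        numeric = deduped.loc[numeric.index.drop_duplicates()]
        logger.info("%s: resolved duplicate gene symbols by highest mean expression", path)

    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric, cohort_label or path.stem)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV; floats round-trip exactly (repr format)."""
    df = expr.data
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(df.columns) + "\n")
        values = df.to_numpy()
        for i, gene in enumerate(df.index):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in values[i]) + "\n")


_CLINICAL_COLS = ("sample_id", "os_time", "os_event", "pfs_time", "pfs_event", "response")


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical table (TSV/CSV) into validated survival records.

    Required columns: sample_id, os_time, os_event.  Optional: pfs_time,
    pfs_event, response (RECIST: CR/PR/SD/PD).  Rows with os_time <= 0 are
    rejected and counted in the log; an unknown response code is an error.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    records: list[SurvivalRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        os_time = float(row["os_time"])
        if os_time <= 0:
            n_rejected += 1
            continue
        response = row.get("response")
        if response is not None and (pd.isna(response) or str(response).strip() == ""):
            response = None
        if response is not None:
            response = str(response).strip()
            if response not in RESPONSE_CODES:
                raise ParseError(
                    f"{path}: unknown response code {response!r} for sample "
                    f"{row['sample_id']!r}; expected one of {RESPONSE_CODES}"
                )
        pfs_time = row.get("pfs_time")
        pfs_event = row.get("pfs_event")
        pfs_missing = pfs_time is None or pd.isna(pfs_time)
        records.append(
            SurvivalRecord(
                sample_id=str(row["sample_id"]).strip(),
                os_time=os_time,
                os_event=int(row["os_event"]),
                pfs_time=None if pfs_missing else float(pfs_time),
                pfs_event=None if pfs_missing else int(pfs_event),
                response=response,
            )
        )
    if n_rejected:
        logger.warning("%s: rejected %d record(s) with non-positive os_time", path, n_rejected)
    return records


def write_clinical(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "os_time": repr(float(r.os_time)),
                "os_event": r.os_event,
                "pfs_time": "" if r.pfs_time is None else repr(float(r.pfs_time)),
                "pfs_event": "" if r.pfs_event is None else r.pfs_event,
                "response": r.response or "",
            }
        )
    pd.DataFrame(rows, columns=list(_CLINICAL_COLS)).to_csv(path, sep="\t", index=False)


def clinical_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Records as a DataFrame indexed by sample_id (responder: boolean or NaN)."""
    df = pd.DataFrame(
        {
            "os_time": [r.os_time for r in records],
            "os_event": [r.os_event for r in records],
            "pfs_time": [r.pfs_time for r in records],
            "pfs_event": [r.pfs_event for r in records],
            "response": [r.response for r in records],
            "responder": [r.responder for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0].strip()
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored; order preserved, deduplicated."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                seen.setdefault(g, None)
    return list(seen)


def intersect_genes(
    cohorts: Sequence[Cohort | ExpressionMatrix],
    gene_list: Iterable[str] | None = None,
) -> list[str]:
    """Sorted intersection of gene ids across cohorts, optionally pre-intersected
    with a curated gene list (e.g. an ImmPort-style immune-gene list)."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    common: set[str] | None = None
    for c in cohorts:
        expr = c.expression if isinstance(c, Cohort) else c
        genes = set(expr.gene_ids)
        common = genes if common is None else common & genes
    assert common is not None
    if gene_list is not None:
        supplied = {g.strip() for g in gene_list}
        unmatched = supplied - common
        if unmatched:
            logger.info("%d supplied gene(s) not shared by all cohorts", len(unmatched))
        common &= supplied
    if not common:
        raise ValidationError("gene intersection across cohorts is empty")
    return sorted(common)
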