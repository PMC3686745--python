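"""Expression-matrix input and probe-level preprocessing.

Reads genes x samples expression tables (plain TSV or the GEO series-matrix
dialect), attaches per-sample condition labels, collapses a many-to-many
probe/gene map to a one-to-one matrix, and splits samples by condition.

Preprocessing policy (deterministic, logged):

* rows containing any missing value are dropped and counted;
* probes mapping to more than one gene are dropped;
* among the probes of a gene, the probe with maximal row variance is kept
  (ties broken by smallest probe id).

Expression values of retained rows are passed through untouched — no
re-normalisation, no log transform.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import LabelingError, ParseError

log = logging.getLogger(__name__)

_GEO_TABLE_BEGIN = "!series_matrix_table_begin"
_GEO_TABLE_END = "!series_matrix_table_end"


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample condition labels.

    ``values`` is indexed by gene (or probe) id with one column per sample;
    ``conditions`` maps every sample id to exactly one condition label.
    """

    values: pd.DataFrame
    conditions: dict[str, str]
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicated row ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicated sample column headers: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise LabelingError(f"samples without a condition label: {missing[:5]}")
        # keep only labels for samples actually present
        self.conditions = {s: self.conditions[s] for s in self.values.columns}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ProbeGeneMap:
    """Many-to-many probe -> gene map (input side of probe collapsing)."""

    probe_to_genes: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ProbeGeneMap":
        out: dict[str, set[str]] = {}
        for probe, gene in pairs:
            out.setdefault(str(probe), set()).add(str(gene))
        return cls({p: frozenset(g) for p, g in out.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        if df.shape[1] < 2:
            raise ParseError(f"{path}: probe map needs 2 columns (probe, gene)")
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _extract_table_lines(raw_lines: list[str]) -> list[tuple[int, str]]:
    """Return (original line number, line) pairs for the data table.

    Handles the GEO series-matrix dialect: lines starting with "!" are
    metadata; if begin/end markers are present, only the block between them
    is the table.
    """
    numbered = [(i + 1, ln) for i, ln in enumerate(raw_lines)]
    lowered = [ln.strip().lower() for ln in raw_lines]
    if _GEO_TABLE_BEGIN in lowered:
        start = lowered.index(_GEO_TABLE_BEGIN)
        end = lowered.index(_GEO_TABLE_END) if _GEO_TABLE_END in lowered else len(raw_lines)
        numbered = numbered[start + 1 : end]
    return [(n, ln) for n, ln in numbered if ln.strip() and not ln.startswith("!")]


def load_expression(path: str | Path, sample_conditions: Mapping[str, str]) -> ExpressionMatrix:
    """Read a rectangular genes x samples TSV and label its samples.

    The first row holds sample ids, the first column probe/gene ids. Rows
    with any missing value are dropped and counted in
    ``ExpressionMatrix.n_dropped_missing``. Ragged rows raise
    :class:`ParseError` naming the offending line; samples absent from
    ``sample_conditions`` raise :class:`LabelingError`.
    """
    path = Path(path)
    table = _extract_table_lines(path.read_text().splitlines())
    if not table:
        raise ParseError(f"{path}: no data table found")
    header_fields = [f.strip('"') for f in table[0][1].split("\t")[1:]]
    dup_headers = {h for h in header_fields if header_fields.count(h) > 1}
    if dup_headers:
        raise ParseError(
            f"{path}: duplicated sample column headers: {sorted(dup_headers)}"
        )
    width = table[0][1].count("\t") + 1
    for lineno, line in table[1:]:
        n_fields = line.count("\t") + 1
        if n_fields != width:
            raise ParseError(
                f"{path}: ragged row at line {lineno} ({n_fields} fields, expected {width})"
            )
    df = pd.read_csv(
        io.StringIO("\n".join(ln for _, ln in table)),
        sep="\t",
        index_col=0,
        quotechar='"',
    )
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]

    unknown = [s for s in df.columns if s not in sample_conditions]
    if unknown:
        raise LabelingError(f"{path}: sample ids without condition label: {unknown}")

    complete = ~df.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    df = df.loc[complete]
    log.info(
        "loaded %s: %d genes x %d samples (%d incomplete rows dropped)",
        path.name, df.shape[0], df.shape[1], n_dropped,
    )
    return ExpressionMatrix(
        values=df.astype(float),
        conditions={s: sample_conditions[s] for s in df.columns},
        n_dropped_missing=n_dropped,
    )


def load_condition_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample id, condition label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: label table needs 2 columns (sample, condition)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def collapse_probes(expr: ExpressionMatrix, pmap: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    Probes mapping to more than one gene are dropped; among the remaining
    probes of a gene the one with maximal row variance is kept (ties by
    smallest probe id). Retained rows keep their original values bit for
    bit, reindexed by gene id, in the order of the retained probes.
    Idempotent: a matrix that is already one probe per gene (under an
    identity-extended map) passes through unchanged.
    """
    missing = [p for p in expr.gene_ids if p not in pmap.probe_to_genes]
    if missing:
        raise LabelingError(f"probes absent from probe/gene map: {missing[:5]}")

    multi = [p for p in expr.gene_ids if len(pmap.probe_to_genes[p]) > 1]
    single = [p for p in expr.gene_ids if len(pmap.probe_to_genes[p]) == 1]

    variances = expr.values.var(axis=1, ddof=0)
    by_gene: dict[str, list[str]] = {}
    for probe in single:
        (gene,) = pmap.probe_to_genes[probe]
        by_gene.setdefault(gene, []).append(probe)

    chosen: dict[str, str] = {
        gene: min(probes, key=lambda p: (-variances[p], p))
        for gene, probes in by_gene.items()
    }
    if not chosen:
        raise ParseError("probe collapsing produced an empty matrix")

    order = {p: i for i, p in enumerate(expr.gene_ids)}
    genes_sorted = sorted(chosen, key=lambda g: order[chosen[g]])
    probes_kept = [chosen[g] for g in genes_sorted]

    values = expr.values.loc[probes_kept].copy()
    values.index = pd.Index(genes_sorted, name=expr.values.index.name)

    n_collapsed = sum(len(v) - 1 for v in by_gene.values())
    log.info(
        "collapse_probes: %d multi-gene probes dropped, %d probes collapsed "
        "by max-variance, %d genes retained",
        len(multi), n_collapsed, len(genes_sorted),
    )
    return ExpressionMatrix(values=values, conditions=dict(expr.conditions))


def split_by_condition(expr: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition samples into one matrix per condition label.

    Every condition must have at least two samples (a Pearson correlation
    across samples is undefined otherwise).
    """
    groups: dict[str, list[str]] = {}
    for sample in expr.sample_ids:
        groups.setdefault(expr.conditions[sample], []).append(sample)
    thin = {c: len(s) for c, s in groups.items() if len(s) < 2}
    if thin:
        raise LabelingError(f"conditions with fewer than 2 samples: {thin}")
    return {
        cond: ExpressionMatrix(
            values=expr.values[samples].copy(),
            conditions={s: cond for s in samples},
        )
        for cond, samples in groups.items()
    }
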