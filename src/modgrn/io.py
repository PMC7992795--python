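"""Readers, writers and in-memory containers for the formats the toolkit speaks.

All downstream stages consume only the types defined here.  The internal
orientation of expression data is fixed as samples × genes; file dialects
that store genes in rows are transposed at the boundary.  Edge lists follow
the three-column benchmark dialect ``regulator<TAB>target<TAB>{0,1}`` (the
label column is optional; label-0 rows are kept as known negatives).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GoldStandardNetwork",
    "ModuleSet",
    "ScoredEdgeList",
    "read_expression_matrix",
    "read_edge_list",
    "read_module_file",
    "write_edge_list",
    "write_module_file",
    "write_ranked_edges",
]

#: decimal places used when serialising scores; chosen so that
#: write→read round-trips preserve ranks exactly.
SCORE_DECIMALS = 12


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix, samples in rows, genes in columns."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_samples, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} columns"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} rows"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class GoldStandardNetwork:
    """Directed reference network: positive edges plus optional annotations.

    ``known_negatives`` holds ordered pairs explicitly labelled 0 in a
    three-column edge file; evaluation can restrict the negative universe
    to them instead of treating every unlisted pair as a negative.
    """

    edges: set[tuple[str, str]]
    gene_universe: set[str]
    tf_set: set[str] | None = None
    known_negatives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop in gold standard: {reg}")
            if reg not in self.gene_universe or tgt not in self.gene_universe:
                raise ValueError(f"edge ({reg}, {tgt}) endpoint outside gene universe")

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.edges}

    def targets_of(self, regulator: str) -> set[str]:
        return {t for r, t in self.edges if r == regulator}

    def regulators_of(self, gene: str) -> set[str]:
        return {r for r, t in self.edges if t == gene}


@dataclass
class ModuleSet:
    """Ordered collection of possibly-overlapping gene modules."""

    modules: list[set[str]]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.modules = [set(m) for m in self.modules]
        if any(len(m) == 0 for m in self.modules):
            raise ValueError("empty module in ModuleSet")
        if self.labels is not None and len(self.labels) != len(self.modules):
            raise ValueError("labels length does not match number of modules")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def gene_to_modules(self) -> dict[str, set[int]]:
        """Map each gene to the indices of the modules containing it."""
        out: dict[str, set[int]] = {}
        for k, module in enumerate(self.modules):
            for g in module:
                out.setdefault(g, set()).add(k)
        return out

    @property
    def all_genes(self) -> set[str]:
        return set().union(*self.modules) if self.modules else set()


@dataclass
class ScoredEdgeList:
    """Directed (regulator, target, score) triples from one inference block.

    ``provenance`` tags the origin: ``intra:<module label>`` for a module's
    boosted-tree scores or ``inter`` for the cross-module ridge scores.
    """

    records: list[tuple[str, str, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str, float]] = []
        for reg, tgt, score in self.records:
            if reg == tgt:
                raise ValueError(f"self-edge ({reg}) in scored edge list")
            pair = (reg, tgt)
            if pair in seen:
                raise ValueError(f"duplicate pair {pair} in scored edge list")
            if score < 0:
                raise ValueError(f"negative score for {pair}: {score}")
            seen.add(pair)
            clean.append((str(reg), str(tgt), float(score)))
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.records}

    def sorted_records(self) -> list[tuple[str, str, float]]:
        """Records sorted by score descending, ties broken lexicographically."""
        return sorted(self.records, key=lambda rec: (-rec[2], rec[0], rec[1]))


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_matrix(
    path: str | Path,
    genes_in_rows: bool = False,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a delimited expression matrix (one header row, one ID column).

    The delimiter is auto-detected between tab and comma.  With
    ``genes_in_rows`` the file stores genes as rows and is transposed so the
    returned matrix is always samples × genes.  Missing cells are a load
    error unless ``impute_missing`` zero-fills them (logged).
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    if not genes_in_rows:
        # pandas silently mangles duplicate header names; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = _duplicates(header)
        if dupes:
            raise ValueError(f"duplicate gene ids in {path.name}: {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if genes_in_rows:
        df = df.T
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value {bad[col].iloc[0]!r} in column {col!r}, "
                    f"row {bad.index[0]!r} of {path.name}"
                )
        df = df.astype(float)
    if df.isna().any().any():
        if not impute_missing:
            raise ValueError(f"missing values in {path.name}; pass impute_missing=True to zero-fill")
        n_missing = int(df.isna().sum().sum())
        logger.info("imputing %d missing cells to zero in %s", n_missing, path.name)
        df = df.fillna(0.0)
    matrix = ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )
    logger.info(
        "loaded expression matrix %s: %d samples x %d genes",
        path.name, matrix.n_samples, matrix.n_genes,
    )
    return matrix


def read_edge_list(path: str | Path) -> GoldStandardNetwork:
    """Parse a 2- or 3-column delimited edge list into a gold standard.

    Rows of a 3-column file carry a 0/1 label; label-1 rows become edges and
    label-0 rows are recorded as known negatives.  A 2-column file lists
    positive edges only.  Self-loop rows are skipped with a warning;
    malformed rows raise with their line number.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = re.split(r"[\t,]", line) if ("\t" in line or "," in line) else line.split()
            if len(fields) not in (2, 3):
                raise ValueError(f"{path.name}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
            reg, tgt = fields[0].strip(), fields[1].strip()
            if not reg or not tgt:
                raise ValueError(f"{path.name}:{lineno}: empty gene id")
            if reg == tgt:
                logger.warning("%s:%d: skipping self-loop (%s, %s)", path.name, lineno, reg, tgt)
                universe.update((reg,))
                continue
            universe.update((reg, tgt))
            if len(fields) == 3:
                label = fields[2].strip()
                if label not in ("0", "1"):
                    raise ValueError(f"{path.name}:{lineno}: label must be 0 or 1, got {label!r}")
                if label == "1":
                    edges.add((reg, tgt))
                else:
                    negatives.add((reg, tgt))
            else:
                edges.add((reg, tgt))
    return GoldStandardNetwork(
        edges=edges,
        gene_universe=universe,
        tf_set={r for r, _ in edges} or None,
        known_negatives=negatives,
    )


_LABEL_RE = re.compile(r"^(module|mod|m)[\s_-]?\d+$", re.IGNORECASE)


def read_module_file(path: str | Path, has_labels: bool | None = None) -> ModuleSet:
    """Read one module per line, whitespace- or tab-separated gene IDs.

    A leading token is treated as a module label when ``has_labels`` is
    True, or (in auto mode) when it contains internal whitespace or looks
    like ``module 3`` / ``m1``.  Empty lines are skipped; a line that
    parses to an empty module is an error.
    """
    path = Path(path)
    modules: list[set[str]] = []
    labels: list[str] = []
    any_label = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")] if "\t" in line else line.split()
            fields = [f for f in fields if f]
            label = None
            if fields and (
                has_labels
                or (has_labels is None and (" " in fields[0] or _LABEL_RE.match(fields[0])))
            ):
                label = fields[0]
                fields = fields[1:]
                any_label = True
            if not fields:
                raise ValueError(f"{path.name}:{lineno}: empty module")
            modules.append(set(fields))
            labels.append(label if label is not None else f"module {len(modules)}")
    return ModuleSet(modules=modules, labels=labels if any_label else None)


def write_module_file(modules: ModuleSet, path: str | Path) -> None:
    """Write one module per line: optional label, then sorted gene IDs, tab-separated."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, module in enumerate(modules.modules):
            label = modules.labels[k] if modules.labels else None
            fields = ([label] if label else []) + sorted(module)
            fh.write("\t".join(fields) + "\n")


def write_edge_list(gold: GoldStandardNetwork, path: str | Path) -> None:
    """Write a gold standard as 3-column TSV (positives 1, known negatives 0)."""
    path = Path(path)
    with open(path, "w") as fh:
        for reg, tgt in sorted(gold.edges):
            fh.write(f"{reg}\t{tgt}\t1\n")
        for reg, tgt in sorted(gold.known_negatives):
            fh.write(f"{reg}\t{tgt}\t0\n")


def write_ranked_edges(records: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    """Write ``regulator<TAB>target<TAB>score`` sorted by descending score.

    Scores are written with fixed decimal precision so repeated reads
    reproduce the ranking byte-for-byte.
    """
    path = Path(path)
    ordered = sorted(records, key=lambda rec: (-rec[2], rec[0], rec[1]))
    with open(path, "w") as fh:
        for reg, tgt, score in ordered:
            fh.write(f"{reg}\t{tgt}\t{score:.{SCORE_DECIMALS}f}\n")
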