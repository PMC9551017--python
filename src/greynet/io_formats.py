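"""Readers and writers for every file the tool touches.

Time-series expression tables come in two dialects:

``dream4``
    The layout used by the public DREAM4 in-silico challenge
    distribution: tab-separated, a header row ``Time<TAB>G1<TAB>G2...``,
    one row per timepoint with genes as columns, and blank lines
    separating replicate time-series blocks.  Loaded tables are
    transposed to the internal genes x timepoints layout.
``plain``
    Genes as rows: first column is the gene id, remaining columns are
    the ordered timepoints; a single block.

Gold standards, ranked-edge lists, TF lists and probe-to-gene maps are
simple tab-separated files; see the individual functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Structural problem in an input file (ragged rows, bad header)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates an invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Gene-labelled expression values over ordered timepoints.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, shared by every replicate block.
    blocks : list of ndarray
        One ``(m, n_b)`` float matrix per replicate time series; rows
        follow ``gene_ids``, columns are ordered timepoints.
    timepoints : list of ndarray
        Numeric time labels per block, same length as the block's
        column count.
    """

    gene_ids: list[str]
    blocks: list[np.ndarray]
    timepoints: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if not self.blocks:
            raise ValidationError("ExpressionTable needs at least one block")
        m = len(self.gene_ids)
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        if not self.timepoints:
            self.timepoints = [np.arange(b.shape[1], dtype=float) for b in self.blocks]
        self.timepoints = [np.asarray(t, dtype=float) for t in self.timepoints]
        for i, (b, t) in enumerate(zip(self.blocks, self.timepoints)):
            if b.ndim != 2 or b.shape[0] != m:
                raise ValidationError(
                    f"block {i} has shape {b.shape}, expected ({m}, n)"
                )
            if b.shape[1] < 3:
                raise ValidationError(
                    f"block {i} has {b.shape[1]} timepoints; at least 3 required"
                )
            if len(t) != b.shape[1]:
                raise ValidationError(f"block {i}: timepoint labels do not match")
            if not np.all(np.isfinite(b)):
                raise ValidationError(f"block {i} contains NaN/Inf values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise ValidationError(f"unknown gene id: {gene_id!r}") from None

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionTable":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionTable(
            gene_ids=list(gene_ids),
            blocks=[b[idx] for b in self.blocks],
            timepoints=[t.copy() for t in self.timepoints],
        )


@dataclass
class GoldStandard:
    """Directed positive edges plus the implied negative universe.

    Every ordered gene pair without a self-loop belongs to the
    universe; pairs absent from ``edges`` are negatives, following the
    DREAM4 gold-standard convention.
    """

    edges: set[tuple[str, str]]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        known = set(self.gene_ids)
        bad = sorted({g for e in self.edges for g in e if g not in known})
        if bad:
            raise ValidationError(f"gold-standard ids not in expression table: {bad}")
        selfs = sorted(e for e in self.edges if e[0] == e[1])
        if selfs:
            raise ValidationError(f"self-edges not allowed: {selfs}")

    @property
    def universe(self) -> list[tuple[str, str]]:
        return [
            (a, b) for a in self.gene_ids for b in self.gene_ids if a != b
        ]

    @property
    def n_positives(self) -> int:
        return len(self.edges)

    @property
    def n_negatives(self) -> int:
        m = len(self.gene_ids)
        return m * (m - 1) - len(self.edges)


@dataclass
class RankedEdgeList:
    """Rows of ``(regulator, target, score)`` sorted by descending score.

    Ties are broken by (regulator, target) lexicographic order so that
    serialisation is deterministic.
    """

    rows: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for reg, tgt, s in self.rows:
            if reg == tgt:
                raise ValidationError(f"self-edge in ranking: {reg}")
            if not np.isfinite(s):
                raise ValidationError(f"non-finite score for ({reg}, {tgt})")
        pairs = [(r, t) for r, t, _ in self.rows]
        if len(pairs) != len(set(pairs)):
            raise ValidationError("duplicate (regulator, target) pairs in ranking")
        self.rows = sorted(self.rows, key=lambda r: (-r[2], r[0], r[1]))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


ProbeMap = dict  # probe_id -> gene_symbol; many probes may share a gene


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_float(token: str, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ValidationError(
            f"line {lineno}: non-numeric cell {token!r}"
        ) from None
    if not np.isfinite(v):
        raise ValidationError(f"line {lineno}: missing/non-finite value {token!r}")
    return v


def read_timeseries_tsv(path: str | Path, dialect: str = "dream4") -> ExpressionTable:
    """Load a time-series expression table.

    Parameters
    ----------
    path : path-like
        Tab-separated input file.
    dialect : {"dream4", "plain"}
        File layout; see the module docstring.
    """
    path = Path(path)
    if dialect not in ("dream4", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text().splitlines()
    if dialect == "plain":
        return _read_plain(lines)
    return _read_dream4(lines)


def _read_dream4(lines: list[str]) -> ExpressionTable:
    header = None
    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    times: list[np.ndarray] = []
    cur_rows: list[list[float]] = []
    cur_times: list[float] = []

    def flush() -> None:
        nonlocal cur_rows, cur_times
        if cur_rows:
            blocks.append(np.array(cur_rows, dtype=float).T)  # genes x time
            times.append(np.array(cur_times, dtype=float))
            cur_rows, cur_times = [], []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        fields = line.split("\t")
        if header is None:
            if fields[0].strip().lower() != "time":
                raise FormatError(
                    f"line {lineno}: dream4 header must start with 'Time', "
                    f"got {fields[0]!r}"
                )
            gene_ids = [f.strip() for f in fields[1:]]
            if not gene_ids:
                raise FormatError(f"line {lineno}: header names no genes")
            if len(gene_ids) != len(set(gene_ids)):
                raise ValidationError(f"line {lineno}: duplicate gene names in header")
            header = fields
            continue
        if fields[0].strip().lower() == "time":  # repeated header between blocks
            if [f.strip() for f in fields[1:]] != gene_ids:
                raise FormatError(f"line {lineno}: block header disagrees with first")
            flush()
            continue
        if len(fields) != len(gene_ids) + 1:
            raise FormatError(
                f"line {lineno}: expected {len(gene_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        cur_times.append(_parse_float(fields[0], lineno))
        cur_rows.append([_parse_float(f, lineno) for f in fields[1:]])
    flush()
    if header is None:
        raise FormatError("empty file: no header row")
    return ExpressionTable(gene_ids=gene_ids, blocks=blocks, timepoints=times)


def _read_plain(lines: list[str]) -> ExpressionTable:
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    width = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if width is None:
            width = len(fields)
            if width < 4:  # id + >=3 timepoints
                raise FormatError(
                    f"line {lineno}: need a gene id and at least 3 timepoints"
                )
        elif len(fields) != width:
            raise FormatError(
                f"line {lineno}: expected {width} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        rows.append([_parse_float(f, lineno) for f in fields[1:]])
    if not rows:
        raise FormatError("empty file")
    return ExpressionTable(gene_ids=gene_ids, blocks=[np.array(rows, dtype=float)])


def read_gold_standard(path: str | Path, gene_ids: Sequence[str]) -> GoldStandard:
    """Load a ``regulator<TAB>target[<TAB>label]`` edge list.

    Rows with label 1 (or no label) are positives; label 0 rows are
    ignored (they are part of the negative universe anyway).
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    known = set(gene_ids)
    unknown: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise FormatError(f"line {lineno}: expected 2 or 3 fields")
        reg, tgt = fields[0].strip(), fields[1].strip()
        label = fields[2].strip() if len(fields) == 3 else "1"
        if label not in ("0", "1"):
            raise ValidationError(f"line {lineno}: label must be 0 or 1, got {label!r}")
        for g in (reg, tgt):
            if g not in known:
                unknown.add(g)
        if reg == tgt:
            raise ValidationError(f"line {lineno}: self-edge {reg!r}")
        if label == "1":
            edges.add((reg, tgt))
    if unknown:
        raise ValidationError(
            f"gold-standard ids not in expression table: {sorted(unknown)}"
        )
    return GoldStandard(edges=edges, gene_ids=list(gene_ids))


def read_tf_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored; order preserved."""
    ids = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate ids in TF list")
    return ids


def read_probe_map(path: str | Path) -> ProbeMap:
    """``probe_id<TAB>gene_symbol`` rows; a gene may own many probes."""
    mapping: ProbeMap = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 fields")
        probe, gene = fields[0].strip(), fields[1].strip()
        if probe in mapping:
            raise ValidationError(f"line {lineno}: duplicate probe {probe!r}")
        mapping[probe] = gene
    return mapping


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_edge_ranking(ranked: RankedEdgeList, path: str | Path) -> None:
    """Write ``regulator<TAB>target<TAB>score`` rows, best first."""
    path = Path(path)
    with path.open("w") as fh:
        for reg, tgt, score in ranked:
            fh.write(f"{reg}\t{tgt}\t{score:.10g}\n")


def write_timeseries_tsv(
    table: ExpressionTable, path: str | Path, dialect: str = "dream4"
) -> None:
    """Serialise an ExpressionTable; inverse of :func:`read_timeseries_tsv`."""
    path = Path(path)
    if dialect == "dream4":
        with path.open("w") as fh:
            fh.write("Time\t" + "\t".join(table.gene_ids) + "\n")
            for bi, (block, tvals) in enumerate(zip(table.blocks, table.timepoints)):
                if bi > 0:
                    fh.write("\n")
                for j in range(block.shape[1]):
                    cells = "\t".join(f"{block[i, j]:.10g}" for i in range(block.shape[0]))
                    fh.write(f"{tvals[j]:.10g}\t{cells}\n")
    elif dialect == "plain":
        if table.n_blocks != 1:
            raise ValueError("plain dialect holds a single block")
        block = table.blocks[0]
        with path.open("w") as fh:
            for i, g in enumerate(table.gene_ids):
                cells = "\t".join(f"{v:.10g}" for v in block[i])
                fh.write(f"{g}\t{cells}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for reg, tgt in sorted(gold.edges):
            fh.write(f"{reg}\t{tgt}\t1\n")


# ---------------------------------------------------------------------------
# microarray probe collapse
# ---------------------------------------------------------------------------


def collapse_probes_by_iqr(
    probe_table: pd.DataFrame, probe_map: ProbeMap
) -> pd.DataFrame:
    """Collapse a probes x samples matrix to one row per gene symbol.

    For genes measured by several probesets, the probeset with the
    largest interquartile range of expression across samples (Q3 - Q1,
    linear-interpolation quantiles) is kept; ties go to the
    lexicographically smaller probe id.
    """
    unmapped = sorted(set(probe_table.index) - set(probe_map))
    if unmapped:
        raise ValidationError(f"probes missing from map: {unmapped}")
    iqr = probe_table.quantile(0.75, axis=1, interpolation="linear") - probe_table.quantile(
        0.25, axis=1, interpolation="linear"
    )
    chosen: dict[str, str] = {}
    for probe in sorted(probe_table.index):
        gene = probe_map[probe]
        if gene not in chosen or iqr[probe] > iqr[chosen[gene]]:
            chosen[gene] = probe
    out = probe_table.loc[[chosen[g] for g in sorted(chosen)]].copy()
    out.index = sorted(chosen)
    return out
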