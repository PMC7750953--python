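"""Readers and writers for the toolkit's interchange formats.

Everything is plain TSV ('\\t' delimiter, '.' decimal separator, no quoting),
matching the conventions of public regulatory-network releases; gzip input is
accepted transparently on read.  Edge lists are 3 columns
(regulator, gene, weight), expression matrices have a gene-ID first column
and a sample-ID header, cooperativity matrices are dense with an ID header
row and column, gene sets use the standard GMT layout
(name, description, members...).
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .datatypes import (
    CooperativityNetwork,
    ExpressionMatrix,
    RegulatoryNetwork,
)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "write_expression",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "read_id_list",
    "write_metadata",
]

_FLOAT_FMT = "%.17g"  # 17 significant digits: exact binary64 round-trip


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line:
                yield lineno, line.split("\t")


def read_edge_list(
    path: str | Path,
    header: bool = False,
    mirna_ids: list[str] | None = None,
) -> RegulatoryNetwork:
    """Read a regulator<TAB>gene<TAB>weight edge list into a dense network.

    IDs are ordered by first appearance; pairs absent from the file get
    weight 0.  Duplicate (regulator, gene) pairs and malformed rows raise
    with the offending line number.
    """
    regs: dict[str, int] = {}
    genes: dict[str, int] = {}
    triples: list[tuple[int, int, float]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _lines(path):
        if header and lineno == 1:
            continue
        if len(fields) != 3:
            raise ValueError(
                f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        r, g, w = fields
        try:
            weight = float(w)
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric weight {w!r}") from None
        if (r, g) in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate edge ({r}, {g})")
        seen.add((r, g))
        triples.append((regs.setdefault(r, len(regs)), genes.setdefault(g, len(genes)), weight))
    if not triples:
        raise ValueError(f"{path}: empty edge list")
    W = np.zeros((len(regs), len(genes)))
    for i, j, w in triples:
        W[i, j] = w
    mask = None
    if mirna_ids is not None:
        flagged = set(mirna_ids)
        mask = np.array([r in flagged for r in regs])
    return RegulatoryNetwork(list(regs), list(genes), W, mask)


def write_edge_list(
    net: RegulatoryNetwork,
    path: str | Path,
    header: bool = False,
    keep_zeros: bool = True,
) -> None:
    """Write a network as a canonical edge list (row-major edge order)."""
    with open(path, "w") as fh:
        if header:
            fh.write("regulator\tgene\tweight\n")
        for i, r in enumerate(net.regulators):
            for j, g in enumerate(net.genes):
                w = net.weights[i, j]
                if keep_zeros or w != 0:
                    fh.write(f"{r}\t{g}\t{_FLOAT_FMT % w}\n")


def read_expression(path: str | Path, tissue_label: str = "") -> ExpressionMatrix:
    """Read a genes-by-samples TSV (gene IDs first column, sample header)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values, tissue_label
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.samples) + "\n")
        for g, row in zip(expr.genes, expr.values):
            fh.write(g + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path: str | Path) -> CooperativityNetwork:
    """Read a dense symmetric matrix with an ID header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if ids != [str(x) for x in df.columns]:
        raise ValueError(f"{path}: row and column ID headers differ")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError(f"{path}: matrix is not symmetric")
    return CooperativityNetwork(ids, values)


def write_matrix(net: CooperativityNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(net.regulators) + "\n")
        for r, row in zip(net.regulators, net.values):
            fh.write(r + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def write_network_matrix(net: RegulatoryNetwork, path: str | Path) -> None:
    """Dense regulator-by-gene matrix TSV with ID headers."""
    with open(path, "w") as fh:
        fh.write("regulator\t" + "\t".join(net.genes) + "\n")
        for r, row in zip(net.regulators, net.weights):
            fh.write(r + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: name<TAB>description<TAB>member...  per line."""
    sets: dict[str, list[str]] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT rows need name, description and >= 1 member"
            )
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate gene set {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_id_list(path: str | Path) -> list[str]:
    """One ID per line; blank lines ignored; duplicates rejected."""
    ids: list[str] = []
    for lineno, fields in _lines(path):
        if len(fields) != 1:
            raise ValueError(f"{path}: line {lineno}: expected a single ID per line")
        if fields[0] in ids:
            raise ValueError(f"{path}: line {lineno}: duplicate ID {fields[0]!r}")
        ids.append(fields[0])
    return ids


def write_metadata(path: str | Path, **fields) -> None:
    """JSON sidecar recording the parameters and outcome of a run."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
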