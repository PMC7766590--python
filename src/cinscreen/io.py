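"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats handled here:

* gene x sample count matrices and two-column group-label tables (TSV),
* ortholog mapping tables (TSV, repeated source rows for one-to-many),
* GCT 1.2 score matrices (perturbagen libraries),
* GMT gene-set collections and ``*_UP`` / ``*_DN`` signature pairs,
* the simplified ``$``-delimited adverse-event report dialect
  (DEMO/DRUG/REAC tables).

Everything is UTF-8 text; writers are deterministic so that identical
inputs serialize byte-identically.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_signature_gmt",
    "write_signature_gmt",
    "read_delim_table",
    "write_delim_table",
    "read_synonym_tsv",
    "write_synonym_tsv",
]

FAERS_DELIM = "$"

# ---------------------------------------------------------------------------
# counts / labels / orthologs (TSV)
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_counts_tsv(path: str | Path, genes: Sequence[str], samples: Sequence[str], counts: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(counts), index=list(genes), columns=list(samples))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> group table (no header requirement: header 'sample\\tgroup' accepted)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if len(df) and df.iloc[0, 0] == "sample":
        df = df.iloc[1:]
    return dict(zip(df["sample"], df["group"]))


def write_labels_tsv(path: str | Path, group_of: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in group_of.items():
            fh.write(f"{sample}\t{group}\n")


def read_ortholog_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read (source_symbol, human_symbol) pairs; repeated sources encode one-to-many."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "source_symbol" and i == 1:
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_ortholog_tsv(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source_symbol\thuman_symbol\n")
        for src, dst in pairs:
            fh.write(f"{src}\t{dst}\n")


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix as a row-id x column-id DataFrame.

    Row descriptions (the ``Description`` column) are preserved in
    ``df.attrs["description"]``.
    """
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed dimension line")
        nrow, ncol = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.shape != (nrow, ncol + 1):
        raise ValueError(f"{path}: dimension line says {nrow}x{ncol}, body is {df.shape[0]}x{df.shape[1] - 1}")
    desc = df.iloc[:, 0]
    out = df.iloc[:, 1:].astype(float)
    out.attrs["description"] = dict(zip(df.index, desc))
    return out


def write_gct(path: str | Path, matrix: pd.DataFrame, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for name, row in matrix.iterrows():
            desc = descriptions.get(name, "na")
            fh.write(str(name) + "\t" + str(desc) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, description and >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]], description: str = "na") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(genes) + "\n")


def read_signature_gmt(path: str | Path) -> tuple[str, set[str], set[str]]:
    """Read a two-line ``<name>_UP`` / ``<name>_DN`` GMT signature pair."""
    sets = read_gmt(path)
    ups = {n[:-3]: v for n, v in sets.items() if n.endswith("_UP")}
    dns = {n[:-3]: v for n, v in sets.items() if n.endswith("_DN")}
    common = sorted(set(ups) & set(dns))
    if not common:
        raise ValueError(f"{path}: no matching *_UP / *_DN pair found")
    name = common[0]
    return name, set(ups[name]), set(dns[name])


def write_signature_gmt(path: str | Path, name: str, up: Iterable[str], down: Iterable[str]) -> None:
    write_gmt(path, {f"{name}_UP": sorted(up), f"{name}_DN": sorted(down)})


# ---------------------------------------------------------------------------
# $-delimited report dialect (DEMO / DRUG / REAC)
# ---------------------------------------------------------------------------


def read_delim_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a ``$``-delimited table, enforcing the expected header and row arity.

    Raises ``ValueError`` with the offending line number on malformed input.
    """
    rows: list[list[str]] = []
    ncol = len(columns)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=FAERS_DELIM)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}:1: empty file, expected header {FAERS_DELIM.join(columns)}")
        if [h.strip().lower() for h in header] != [c.lower() for c in columns]:
            raise ValueError(f"{path}:1: expected header {FAERS_DELIM.join(columns)}, got {FAERS_DELIM.join(header)}")
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise ValueError(f"{path}:{i}: expected {ncol} fields, got {len(row)}")
            rows.append(row)
    return pd.DataFrame(rows, columns=list(columns))


def write_delim_table(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(FAERS_DELIM.join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(FAERS_DELIM.join(str(v) for v in row) + "\n")


def read_synonym_tsv(path: str | Path) -> dict[str, str]:
    """Read a verbatim-drug-string -> ATC level-5 code table."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            table[parts[0]] = parts[1]
    return table


def write_synonym_tsv(path: str | Path, table: Mapping[str, str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for verbatim, atc in table.items():
            fh.write(f"{verbatim}\t{atc}\n")
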