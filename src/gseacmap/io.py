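"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects: GMT (MSigDB flavour), GCT v1.2, tab-separated tables with a header
row for counts / metadata / stage outputs, JSON for the final report. All
files are UTF-8, tab separated, "." decimal, "\\n" line endings. Floats are
written with ``repr`` so that write → read → write is byte-identical for
files produced by this package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, SignatureReference
from .errors import FormatError, ValidationError


def _fmt(v: float) -> str:
    return repr(float(v))


# ---------------------------------------------------------------------------
# count matrix + condition map
# ---------------------------------------------------------------------------

def read_conditions(path: str | Path) -> dict[str, str]:
    """Read a two-column sample → condition TSV (header: sample, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "condition"]:
        raise FormatError(f"{path}: expected header 'sample\\tcondition'")
    return dict(zip(df["sample"], df["condition"]))


def write_conditions(conditions: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tcondition\n")
        for s, c in conditions.items():
            fh.write(f"{s}\t{c}\n")


def read_counts(path: str | Path, conditions: Mapping[str, str]) -> CountMatrix:
    """Read a gene × sample count TSV (first column gene ids, header row).

    Every sample in the file must appear in *conditions*; cells must be
    nonnegative integers; duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise FormatError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    for s in samples:
        if s not in conditions:
            raise FormatError(f"{path}: sample {s!r} absent from condition map")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac = values != np.floor(values)
        if np.any(frac) or np.any(~np.isfinite(values)):
            i, j = np.argwhere(frac | ~np.isfinite(values))[0]
            raise FormatError(
                f"{path}: non-integer count at gene {genes[i]!r}, sample {samples[j]!r}"
            )
        values = values.astype(np.int64)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {genes[i]!r}, sample {samples[j]!r}"
        )
    try:
        return CountMatrix(genes, samples, {s: conditions[s] for s in samples}, values)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(cm.samples) + "\n")
        for i, g in enumerate(cm.genes):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in cm.counts[i]) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name, description, then >= 1 gene id."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write sets in collection order, members sorted lexicographically."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# GCT v1.2 signature matrix + instance metadata
# ---------------------------------------------------------------------------

def read_gct(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a GCT v1.2 matrix; returns (row ids, column ids, values)."""
    with open(path, "r", encoding="utf-8") as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise FormatError(f"{path}: expected '#1.2' header, got {version!r}")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed dimension line") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 + n_cols or header[0] != "Name":
            raise FormatError(
                f"{path}: header declares {len(header) - 2} columns, expected {n_cols}"
            )
        columns = header[2:]
        rows: list[str] = []
        values = np.empty((n_rows, n_cols), dtype=float)
        filled = 0
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 + n_cols:
                raise FormatError(f"{path}:{lineno}: expected {2 + n_cols} fields")
            if filled >= n_rows:
                raise FormatError(f"{path}: more data rows than the declared {n_rows}")
            rows.append(fields[0])
            values[filled] = [float(v) for v in fields[2:]]
            filled += 1
        if filled != n_rows:
            raise FormatError(f"{path}: found {filled} data rows, header declares {n_rows}")
    return rows, columns, values


def write_gct(rows: list[str], columns: list[str], values: np.ndarray, path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(rows)}\t{len(columns)}\n")
        fh.write("Name\tDescription\t" + "\t".join(columns) + "\n")
        for i, r in enumerate(rows):
            desc = descriptions.get(r, "na") if descriptions else "na"
            fh.write(r + "\t" + desc + "\t" + "\t".join(_fmt(v) for v in values[i]) + "\n")


def read_reference(matrix_path: str | Path, meta_path: str | Path) -> SignatureReference:
    """Assemble a compound-signature reference from a GCT matrix and metadata TSV.

    Metadata columns: instance_id, compound, moa_class, cell_line; instance
    ids must exactly match the matrix columns.
    """
    genes, instances, values = read_gct(matrix_path)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"instance_id", "compound", "moa_class", "cell_line"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{meta_path}: missing metadata columns {sorted(missing)}")
    meta = meta.set_index("instance_id")
    absent = [i for i in instances if i not in meta.index]
    if absent:
        raise FormatError(f"{meta_path}: instance(s) without metadata: {absent[:5]}")
    try:
        return SignatureReference(genes, instances, values, meta)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_reference(ref: SignatureReference, matrix_path: str | Path,
                    meta_path: str | Path) -> None:
    write_gct(ref.genes, ref.instances, ref.values, matrix_path)
    with open(meta_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\tcompound\tmoa_class\tcell_line\n")
        for inst in ref.instances:
            row = ref.meta.loc[inst]
            fh.write(f"{inst}\t{row['compound']}\t{row['moa_class']}\t{row['cell_line']}\n")


# ---------------------------------------------------------------------------
# stage tables and the final report
# ---------------------------------------------------------------------------

def write_de_table(de, path: str | Path) -> None:
    """Write a DeTable as TSV (gene, logFC, avg_expr, s2, t, df_total, p, fdr[, status])."""
    write_table(de.table, path, index_label="gene")


def read_de_table(path: str | Path):
    """Read a DE TSV back into a DeTable (EB hyperparameters not preserved)."""
    from .containers import DeTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DeTable(df, float("nan"), float("nan"))



def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a stage-output DataFrame as TSV with canonical float formatting."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=index_label is not None,
               index_label=index_label, lineterminator="\n")


def write_json_report(obj: dict, path: str | Path) -> None:
    """Serialise a report deterministically (sorted keys, canonical floats)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
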