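"""Readers and writers for the standard flat formats the pipeline touches.

Classic tab-separated OTU tables (QIIME-style, with or without the
``#OTU ID`` header), BIOM (v1.0 JSON and v2.1 HDF5), Newick trees,
two-column taxonomy files and tab-separated metadata/environment tables.
All writers emit tab-separated UTF-8 with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import (
    EnvMatrix,
    Lineage,
    OtuTable,
    SampleFrame,
    TaxonomyMap,
    ValidationError,
    check_tree,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_env",
    "write_env",
    "write_table",
]


def read_otu_table(path: str | Path, format: str = "classic_tsv") -> OtuTable:
    """Load an OTU x sample count table.

    ``classic_tsv``: first column is the OTU id (header ``#OTU ID`` or any
    bare label), remaining columns one per sample, integer cells.
    ``biom``: BIOM v1.0 (JSON) or v2.1 (HDF5), auto-detected.
    """
    path = Path(path)
    if format == "classic_tsv":
        return _read_classic_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown OTU table format {format!r}")


def _read_classic_tsv(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # skip any leading comment lines except the "#OTU ID" header itself
    while lines and lines[0].startswith("#") and "OTU ID" not in lines[0]:
        lines.pop(0)
    if not lines:
        raise ValidationError(f"{path}: empty OTU table")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    for r, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValidationError(
                f"{path}: row {r} has {len(cells)} cells, expected {len(header)}"
            )
        otu_ids.append(cells[0])
        row = []
        for c, cell in enumerate(cells[1:], start=1):
            try:
                val = int(float(cell)) if float(cell) == int(float(cell)) else None
            except ValueError:
                val = None
            if val is None:
                raise ValidationError(
                    f"{path}: non-integer cell at row {r} (OTU {cells[0]!r}), "
                    f"column {c} (sample {sample_ids[c - 1]!r}): {cell!r}"
                )
            if val < 0:
                raise ValidationError(
                    f"{path}: negative count at row {r} (OTU {cells[0]!r}), "
                    f"column {c} (sample {sample_ids[c - 1]!r}): {cell!r}"
                )
            row.append(val)
        rows.append(row)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(sample_ids)), int)
    return OtuTable(otu_ids, sample_ids, counts)


def _read_biom(path: Path) -> OtuTable:
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_json(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "dense":
        counts[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    return OtuTable(otu_ids, sample_ids, counts)


def _read_biom_hdf5(path: Path) -> OtuTable:
    import h5py

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    counts = np.zeros((len(otu_ids), len(sample_ids)))
    for i in range(len(otu_ids)):
        sl = slice(indptr[i], indptr[i + 1])
        counts[i, indices[sl]] = data[sl]
    return OtuTable(otu_ids, sample_ids, counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t", encoding="utf-8")


def read_metadata(path: str | Path) -> SampleFrame:
    """Load sample metadata: sample_id, site_id, reach, flow_order, campaign."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in SampleFrame.REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: metadata missing required columns: {missing}")
    return SampleFrame(df)


def write_metadata(frames: SampleFrame, path: str | Path) -> None:
    frames.frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Two-column tab-separated file: otu_id, semicolon-delimited lineage."""
    lineages: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}: line {n} has no lineage column")
            otu_id, lineage = parts[0], parts[1]
            if otu_id in lineages:
                raise ValidationError(f"{path}: duplicate otu_id {otu_id!r} at line {n}")
            lineages[otu_id] = Lineage.from_string(lineage)
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#otu_id\tlineage\n")
        for otu_id, lin in taxonomy.lineages.items():
            fh.write(f"{otu_id}\t{lin.to_string()}\n")


def read_tree(path: str | Path) -> TreeNode:
    """Rooted Newick tree with branch lengths; validated on load."""
    # underscores in unquoted labels are literal here (QIIME convention),
    # not spaces as in strict newick
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    return check_tree(tree)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_env(path: str | Path) -> EnvMatrix:
    """Sample x variable table; first column is the sample id.

    A variable named like ``temperature (°C)`` keeps its unit annotation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    units = {}
    for col in df.columns:
        if "(" in col and col.endswith(")"):
            name, unit = col[:-1].rsplit("(", 1)
            units[name.strip()] = unit.strip()
    return EnvMatrix(df, units)


def write_env(env: EnvMatrix, path: str | Path) -> None:
    df = env.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", encoding="utf-8")


def write_table(result: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as tab-separated UTF-8 with a header row."""
    result.to_csv(path, sep="\t", index=index, encoding="utf-8")
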