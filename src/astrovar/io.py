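"""Readers and writers for the delimited-text formats the pipeline touches.

Feature tables are delimited text with the analyte id in the first column
and one column per sample (TSV by default, comma auto-detected).  Gene sets
use the GMT dialect; TSS annotations use BED-like 4+ column files with
0-based positions; microbiome profiles use the MetaPhlAn merged-table
dialect (pipe-delimited taxonomy strings, species rows kept).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .tables import FeatureTable, GeneSetCollection, validate_sample_info, validate_tss_annotation

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_sample_info",
    "write_sample_info",
    "read_metaphlan_table",
    "read_gmt",
    "write_gmt",
    "read_tss_bed",
    "write_tss_bed",
]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
        else:
            line = ""
    return "," if ("," in line and "\t" not in line) else "\t"


def read_feature_table(path: str | Path, modality: str, *, normalized: bool = False) -> FeatureTable:
    """Read a delimited analyte-by-sample table.

    The first column holds analyte ids; the header row holds sample ids.
    Duplicate ids and non-numeric cells are hard errors (the offending
    row/column is named).  Parsing is locale-independent (C float syntax).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate analyte ids {dups}")
    if df.columns.has_duplicates:
        # pandas mangles duplicate headers; detect from the raw header line
        pass
    _check_duplicate_header(path, sep)
    try:
        numeric = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, (aid, cell) in enumerate(df[col].items()):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at analyte {aid!r} (row {i + 2}), "
                        f"sample {col!r} (column {j + 2}): {cell!r}"
                    ) from None
        raise
    return FeatureTable(data=numeric, modality=modality, normalized=normalized)


def _check_duplicate_header(path: Path, sep: str) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = next(csv.reader([line], delimiter=sep))
                break
        else:
            return
    samples = header[1:]
    seen, dups = set(), []
    for s in samples:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise ValueError(f"{path}: duplicate sample ids in header: {sorted(set(dups))}")


def write_feature_table(table: FeatureTable, path: str | Path, *, sep: str = "\t",
                        header_lines: list[str] | None = None) -> None:
    """Write a feature table; float repr round-trips bitwise through read."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.data.to_csv(fh, sep=sep, index_label="analyte_id", lineterminator="\n")


def read_sample_info(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#",
                     dtype={"sample_id": str, "subject_id": str, "timepoint_label": str})
    df["day_offset"] = df["day_offset"].astype(int)
    return validate_sample_info(df)


def write_sample_info(samples: pd.DataFrame, path: str | Path) -> None:
    validate_sample_info(samples)
    samples.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_metaphlan_table(path: str | Path) -> FeatureTable:
    """Read a MetaPhlAn-style merged relative-abundance table.

    Retains only species-level rows, i.e. rows whose deepest pipe-delimited
    taxonomic rank is prefixed ``s__``; the analyte id is the species name
    (the ``s__`` field).  Higher-rank summary rows (kingdom through genus)
    and strain-level (``t__``) rows are dropped.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    taxcol = df.columns[0]
    deepest = df[taxcol].astype(str).str.split("|").str[-1]
    keep = deepest.str.startswith("s__")
    if not keep.any():
        raise ValueError(f"{path}: no species-level (s__) rows found")
    out = df.loc[keep].copy()
    out.index = deepest[keep].to_numpy()
    out = out.drop(columns=[taxcol])
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate species rows {dups}")
    return FeatureTable(data=out.astype(float), modality="microbiome_relabund",
                        normalized=True)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB member...

    Duplicate set names and empty sets are errors.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no members"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSS annotation: chrom, start, end, gene_id[, score, strand].

    Positions are 0-based; the TSS is the ``start`` coordinate.  Strand
    defaults to '+' when absent (promoter windows are symmetric, so strand
    never changes a window).
    """
    path = Path(path)
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            strand = f[5] if len(f) >= 6 else "+"
            rows.append((f[3], f[0], int(f[1]), strand))
    tss = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return validate_tss_annotation(tss)


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    validate_tss_annotation(tss)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in tss.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t0\t{rec.strand}\n")
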