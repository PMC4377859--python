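"""Readers and writers for the package's tabular dialects.

Counts travel as TSV with the gene ID in the first column and one column
per sample, the header encoding ``model:condition:replicate``; gene lengths
as a two-column TSV; gene sets as GMT (set name, description, then member
IDs, tab-separated); the tissue atlas as an expression TSV plus a
tissue-to-class map; promoter hits as a TSV mirroring the hits-in-submitted
/ hits-on-genome column pair.  All outputs start with a ``#`` header
comment carrying the tool version so runs are diffable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import PromoterHitTable, TissueAtlas
from .crossmodel import ConcordanceTable
from .gsea import GeneSet
from .quantify import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_lengths",
    "write_lengths",
    "read_gmt",
    "write_gmt",
    "read_atlas",
    "write_atlas",
    "read_promoter_hits",
    "write_promoter_hits",
    "write_table",
    "read_table",
]

_HEADER = f"# isletkit {__version__}\n"


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write any result table as commented TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_lengths(lengths: pd.Series, path) -> None:
    df = pd.DataFrame({"gene": lengths.index, "length": lengths.to_numpy()})
    write_table(df, path)


def read_lengths(path) -> pd.Series:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: lengths file needs two columns (gene, length)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="length")
    if (s <= 0).any():
        gene = s.index[s <= 0][0]
        raise ValueError(f"{path}: non-positive length for gene {gene!r}")
    return s


def write_counts(counts: CountMatrix, path) -> None:
    df = counts.counts.copy()
    df.insert(0, "gene", df.index)
    write_table(df, path)


def read_counts(path, lengths_path) -> CountMatrix:
    """Parse a counts TSV plus lengths TSV into a validated CountMatrix.

    Headers must encode ``model:condition:replicate``; counts must be
    non-negative integers (errors cite the offending row and column) and
    every gene needs a length.
    """
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: counts file needs a gene column plus samples")
    gene_col = df.columns[0]
    genes = pd.Index(df[gene_col], name="gene")
    if genes.duplicated().any():
        dup = genes[genes.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene {dup!r}")
    sample_cols = list(df.columns[1:])
    meta = []
    for col in sample_cols:
        parts = col.split(":")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: sample column {col!r} must encode model:condition:replicate"
            )
        meta.append(parts)
    counts = pd.DataFrame(index=genes)
    for col in sample_cols:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() | (num != np.floor(num.fillna(0))) | (num < 0)
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: invalid count {raw.iloc[i]!r} at gene {genes[i]!r}, column {col!r}"
            )
        counts[col] = num.astype(np.int64).to_numpy()
    lengths = read_lengths(lengths_path)
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"{lengths_path}: no length for gene {missing[0]!r}")
    samples = pd.DataFrame(meta, index=sample_cols, columns=["model", "condition", "replicate"])
    return CountMatrix(counts=counts, samples=samples, lengths=lengths)


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *map(str, gs.members)]) + "\n")


def read_gmt(path) -> list:
    """Parse a GMT file; duplicate members are dropped with a warning."""
    sets: list = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) != len(members):
            warnings.warn(
                f"{path}:{lineno}: set {name!r} has duplicate members; deduplicated",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, description=desc, members=tuple(uniq)))
    return sets


def write_atlas(atlas: TissueAtlas, expr_path, class_path) -> None:
    df = atlas.expression.copy()
    df.insert(0, "gene", df.index)
    write_table(df, expr_path)
    cmap = pd.DataFrame({"tissue": atlas.tissue_class.index, "class": atlas.tissue_class.to_numpy()})
    write_table(cmap, class_path)


def read_atlas(expr_path, class_path) -> TissueAtlas:
    df = _read_tsv(expr_path)
    expr = df.set_index(df.columns[0])
    cmap = _read_tsv(class_path)
    tissue_class = pd.Series(cmap["class"].to_numpy(), index=cmap["tissue"], name="class")
    return TissueAtlas(expression=expr, tissue_class=tissue_class)


def write_promoter_hits(table: PromoterHitTable, path) -> None:
    df = table.hits.copy()
    df["n_submitted"] = table.n_submitted
    df["genome_promoters"] = table.genome_promoters
    write_table(df, path)


def read_promoter_hits(path) -> PromoterHitTable:
    df = _read_tsv(path)
    for col in ("tf", "hits_submitted", "hits_genome", "n_submitted", "genome_promoters"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PromoterHitTable(
        hits=df[["tf", "hits_submitted", "hits_genome"]].copy(),
        n_submitted=int(df["n_submitted"].iloc[0]),
        genome_promoters=int(df["genome_promoters"].iloc[0]),
    )


def write_concordance(table: ConcordanceTable, path) -> None:
    df = table.to_frame()
    df.insert(0, "gene", df.index)
    write_table(df, path)


def write_heatmap_tsv(matrix: pd.DataFrame, mask: pd.DataFrame, path) -> None:
    """Serialize the heat-map matrix; absent cells become the string 'absent'."""
    out = matrix.round(6).astype(object)
    out[mask] = "absent"
    out.insert(0, "gene", out.index)
    write_table(out, path)
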