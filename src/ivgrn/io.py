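"""Readers and writers for the plain-text formats the pipeline touches.

All tabular inputs are TSV. Expression and dosage matrices are samples x
columns with a header row of gene/variant IDs and the sample ID in the
first column. Networks are written twice: a human-readable edge list
(regulator, target, value) and a matrix-market style triplet file; a
read of either reproduces the edge set exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    BootstrapSummary,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    RegulatoryNetwork,
    VariantInfo,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes",
    "read_annotation",
    "write_annotation",
    "read_covariates",
    "write_network",
    "read_network_edges",
    "read_network",
    "read_bootstrap_summary",
]


def _read_matrix_tsv(path, what: str) -> pd.DataFrame:
    path = Path(path)
    # check the raw header: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"{path}: no samples (empty file)")
    cols = header.split("\t")[1:]
    dup_cols = sorted({c for c in cols if cols.count(c) > 1})
    if dup_cols:
        raise ValueError(f"{path}: duplicate {what} IDs in header: {dup_cols}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no samples (empty file)") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    dup_rows = df.index[df.index.duplicated()].tolist()
    if dup_rows:
        raise ValueError(f"{path}: duplicate sample IDs: {sorted(set(dup_rows))}")
    return df


def _to_numeric(df: pd.DataFrame, path, na_values=("NA", "NaN", "nan", "")) -> np.ndarray:
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        cleaned = raw.where(~raw.isin(na_values), np.nan)
        try:
            values[:, j] = pd.to_numeric(cleaned, errors="raise")
        except (ValueError, TypeError):
            bad = cleaned[pd.to_numeric(cleaned, errors="coerce").isna() & cleaned.notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at row {row!r}, column {col!r}"
            ) from None
    return values


def read_expression(path) -> ExpressionMatrix:
    """Read a samples x genes TSV (header = gene IDs, first column = sample IDs)."""
    df = _read_matrix_tsv(path, "gene")
    values = _to_numeric(df, path)
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


_RAW_META_COLS = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}


def _read_dosage(path) -> pd.DataFrame:
    """Read a dosage TSV; a PLINK ``.raw`` (recode A) file is accepted too."""
    df = _read_matrix_tsv(path, "variant")
    if str(path).endswith(".raw") or df.columns[:1].isin(["IID"]).any():
        # PLINK .raw: whitespace-separated, FID IID PAT MAT SEX PHENOTYPE then SNP_ALT
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        df = df.set_index("IID")
        df = df.drop(columns=[c for c in _RAW_META_COLS if c in df.columns], errors="ignore")
        df.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in df.columns]
    return df


def read_genotypes(path, variant_table) -> GenotypeMatrix:
    """Read a dosage matrix and its companion variant table.

    Dosage entries must be 0/1/2/NA. The variant table is a TSV with
    columns id, chrom, pos, ref, alt, aligned to the dosage columns by
    order; a mismatch in count is a hard error.
    """
    df = _read_dosage(path)
    values = _to_numeric(df, path)
    finite = values[np.isfinite(values)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(f"{path}: dosage value {bad[0]!r} outside {{0,1,2,NA}}")
    vt = pd.read_csv(variant_table, sep="\t", dtype=str)
    required = {"id", "chrom", "pos"}
    if not required.issubset(vt.columns):
        raise ValueError(f"{variant_table}: variant table needs columns {sorted(required)}")
    if len(vt) != values.shape[1]:
        raise ValueError(
            f"variant table has {len(vt)} rows but dosage file has "
            f"{values.shape[1]} variant columns"
        )
    variants = [
        VariantInfo(
            id=row["id"],
            chromosome=row["chrom"],
            position=int(row["pos"]),
            ref=row.get("ref", "N") or "N",
            alt=row.get("alt", "N") or "N",
        )
        for _, row in vt.iterrows()
    ]
    return GenotypeMatrix(values, variants, list(df.index))


def write_genotypes(g: GenotypeMatrix, dosage_path, variant_path) -> None:
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.variant_ids)
    # keep integral dosages readable as integers
    df.to_csv(dosage_path, sep="\t", index_label="sample_id", na_rep="NA",
              float_format="%.10g")
    vt = pd.DataFrame(
        {
            "id": [v.id for v in g.variants],
            "chrom": [v.chromosome for v in g.variants],
            "pos": [v.position for v in g.variants],
            "ref": [v.ref for v in g.variants],
            "alt": [v.alt for v in g.variants],
        }
    )
    vt.to_csv(variant_path, sep="\t", index=False)


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    return [
        GeneAnnotation(row["gene_id"], row["chrom"], int(row["start"]), int(row["end"]))
        for _, row in df.iterrows()
    ]


def write_annotation(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chromosome for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate TSV (first column sample_id); dtypes are inferred."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    return df


def write_network(net, path_prefix) -> tuple[str, str]:
    """Write a network or bootstrap summary as edge list + triplet file.

    ``path_prefix`` may be a directory-less prefix; two files are written:
    ``<prefix>.edges.tsv`` (regulator, target, value) and
    ``<prefix>.triplets.tsv`` (row, col, value with a shape header).
    Returns the two paths.
    """
    prefix = str(path_prefix)
    parent = os.path.dirname(prefix)
    if parent and not os.path.isdir(parent):
        raise FileNotFoundError(f"unwritable path: directory {parent!r} does not exist")
    edge_path = prefix + ".edges.tsv"
    trip_path = prefix + ".triplets.tsv"

    if isinstance(net, RegulatoryNetwork):
        value_name = "coefficient"
        coo = net.coefficients.tocoo()
        extra = ""
    elif isinstance(net, BootstrapSummary):
        value_name = "frequency"
        coo = sp.coo_matrix(net.frequency)
        extra = f"# n_bootstraps\t{net.n_bootstraps}\n"
    else:
        raise TypeError(f"cannot serialize {type(net).__name__}")

    with open(edge_path, "w") as fh:
        fh.write(f"regulator\ttarget\t{value_name}\n")
        for reg, tgt, val in net.edges():
            fh.write(f"{reg}\t{tgt}\t{float(val)!r}\n")

    with open(trip_path, "w") as fh:
        fh.write(f"# shape\t{net.n_genes}\t{net.n_genes}\n")
        fh.write(extra)
        fh.write("# genes\t" + "\t".join(net.gene_ids) + "\n")
        fh.write("row\tcol\tvalue\n")
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            fh.write(f"{coo.row[k]}\t{coo.col[k]}\t{float(coo.data[k])!r}\n")
    return edge_path, trip_path


def read_network_edges(edge_path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(edge_path, sep="\t", dtype={0: str, 1: str})
    return sorted((str(r), str(t), float(v)) for r, t, v in df.itertuples(index=False))


def _read_triplets(trip_path):
    meta = {}
    with open(trip_path) as fh:
        lines = fh.readlines()
    body_start = 0
    genes = None
    for k, line in enumerate(lines):
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "genes":
                genes = parts[1:]
            else:
                meta[parts[0]] = parts[1:]
            body_start = k + 1
        else:
            break
    p = int(meta["shape"][0])
    if genes is None or len(genes) != p:
        raise ValueError(f"{trip_path}: missing or inconsistent gene list header")
    rows, cols, vals = [], [], []
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        i, j, v = line.split("\t")
        rows.append(int(i))
        cols.append(int(j))
        vals.append(float(v))
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(p, p))
    return mat, genes, meta


def read_network(trip_path) -> RegulatoryNetwork:
    mat, genes, _ = _read_triplets(trip_path)
    return RegulatoryNetwork(mat, genes)


def read_bootstrap_summary(trip_path) -> BootstrapSummary:
    mat, genes, meta = _read_triplets(trip_path)
    B = int(meta["n_bootstraps"][0])
    counts = np.rint(mat.toarray() * B).astype(np.int64)
    return BootstrapSummary(counts, B, genes)
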