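"""Readers and writers shared by all pipeline stages.

Counts travel as gene x sample TSV (header row = sample ids) or as
MatrixMarket coordinate files with sidecar ``.rows``/``.cols`` name files.
The gene->chromosome map is a two-column TSV (``gene_id``,
``chromosome_id``); sample metadata is CSV with columns
``sample_id,ploidy,site,cohort,dam``. All tables are UTF-8 with headers;
chromosome ids are opaque strings (no "chr" prefix or ordering assumed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ploidyscreen.pairing import PAIR_COLUMNS, validate_sample_table

logger = logging.getLogger(__name__)


def _validate_count_values(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    values = df.to_numpy()
    bad = ~(np.isfinite(values) & (values >= 0) & (values == np.floor(values)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"count matrix entry for gene {df.index[r]!r}, sample {df.columns[c]!r} "
            f"is not a nonnegative integer: {values[r, c]!r}"
        )
    return df.astype(np.int64)


def read_counts(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a count matrix from TSV or MatrixMarket (+ name sidecars).

    ``fmt`` is inferred from the suffix (``.mtx`` -> MatrixMarket) when not
    given. Negative or non-integer entries are rejected with their
    location; duplicate ids are rejected.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
        df.columns.name = "sample_id"
    elif fmt == "mtx":
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        genes = Path(f"{path}.rows").read_text().split()
        samples = Path(f"{path}.cols").read_text().split()
        df = pd.DataFrame(
            matrix,
            index=pd.Index(genes, name="gene_id"),
            columns=pd.Index(samples, name="sample_id"),
        )
    else:
        raise ValueError(f"unknown counts format {fmt!r}; use 'tsv' or 'mtx'")
    return _validate_count_values(df)


def write_counts(counts: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a count matrix; inverse of :func:`read_counts`."""
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.to_numpy()))
        Path(f"{path}.rows").write_text("\n".join(counts.index) + "\n")
        Path(f"{path}.cols").write_text("\n".join(counts.columns) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}; use 'tsv' or 'mtx'")


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    """Write a real-valued gene x sample matrix (e.g. log-CPM) as TSV."""
    values.rename_axis("gene_id").to_csv(Path(path), sep="\t")


def read_genemap(path: str | Path) -> pd.Series:
    """Read the two-column gene -> chromosome TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chromosome_id"):
        if col not in df.columns:
            raise ValueError(f"gene map missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in gene map: {dup!r}")
    return df.set_index("gene_id")["chromosome_id"]


def write_genemap(genemap: pd.Series, path: str | Path) -> None:
    genemap.rename("chromosome_id").rename_axis("gene_id").to_csv(Path(path), sep="\t")


def genemap_from_gff3(path: str | Path, feature_type: str = "gene") -> pd.Series:
    """Build a gene -> chromosome map from GFF3 gene lines.

    Uses the record's seqid as the chromosome and its ``ID`` (or
    ``gene_id``) attribute as the gene id; a ``gene:`` prefix on the ID is
    stripped.
    """
    records: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature_type:
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"GFF3 {feature_type} line without ID attribute: {line!r}")
            gene_id = gene_id.removeprefix("gene:")
            if gene_id in records:
                raise ValueError(f"duplicate gene id in GFF3: {gene_id!r}")
            records[gene_id] = fields[0]
    return pd.Series(records, name="chromosome_id").rename_axis("gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata CSV and validate the ploidy levels."""
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("sample table missing required column 'sample_id'")
    return validate_sample_table(df.set_index("sample_id"))


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample_id").to_csv(Path(path))


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing required column(s): {sorted(missing)}")
    return df


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(Path(path), sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.rename_axis("sample_id").to_csv(Path(path), sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def align_to_genemap(counts: pd.DataFrame, genemap: pd.Series) -> pd.DataFrame:
    """Report and exclude genes absent from the chromosome map.

    Unmapped genes stay usable for PCA/shift but cannot enter the
    chromosome-level screen; the count of exclusions is logged.
    """
    unmapped = counts.index.difference(genemap.index)
    if len(unmapped):
        logger.info("%d gene(s) absent from the gene map; excluded", len(unmapped))
    return counts.loc[counts.index.intersection(genemap.index)]
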