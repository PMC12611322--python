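"""Plain-text I/O: Matrix Market matrices with features/barcodes
companions, CSV metadata and well tables.

The on-disk layout mirrors the common single-cell convention: each modality
is a features x barcodes sparse Matrix Market file next to ``features.tsv``
and ``barcodes.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import MultimodalDataset, WellRecord, wells_from_frame, wells_to_frame

__all__ = ["write_multimodal", "read_multimodal", "write_wells", "read_wells"]

_RNA_PREFIX = "rna"
_ADT_PREFIX = "adt"


def _write_modality(outdir: Path, prefix: str, counts: np.ndarray, feature_names) -> None:
    spio.mmwrite(outdir / f"{prefix}_matrix.mtx", sparse.csr_matrix(counts.T))
    pd.Series(list(feature_names)).to_csv(
        outdir / f"{prefix}_features.tsv", sep="\t", index=False, header=False
    )


def write_multimodal(dataset: MultimodalDataset, outdir) -> None:
    """Write a dataset as MTX + TSV companions + CSV metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_modality(outdir, _RNA_PREFIX, dataset.rna_counts, dataset.gene_names)
    _write_modality(outdir, _ADT_PREFIX, dataset.adt_counts, dataset.adt_names)
    pd.Series(dataset.barcodes).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    dataset.cell_meta.to_csv(outdir / "cell_meta.csv")
    dataset.gene_meta.to_csv(outdir / "gene_meta.csv")


def read_multimodal(indir) -> MultimodalDataset:
    """Read a dataset written by :func:`write_multimodal`."""
    indir = Path(indir)
    rna = np.asarray(spio.mmread(indir / f"{_RNA_PREFIX}_matrix.mtx").todense()).T
    adt = np.asarray(spio.mmread(indir / f"{_ADT_PREFIX}_matrix.mtx").todense()).T
    adt_names = (
        pd.read_csv(indir / f"{_ADT_PREFIX}_features.tsv", sep="\t", header=None)[0]
        .astype(str)
        .tolist()
    )
    cell_meta = pd.read_csv(indir / "cell_meta.csv", index_col=0)
    gene_meta = pd.read_csv(indir / "gene_meta.csv", index_col=0)
    return MultimodalDataset(
        rna_counts=rna.astype(np.int64),
        adt_counts=adt.astype(np.int64),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        adt_names=adt_names,
    )


def write_wells(wells: list[WellRecord], path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def read_wells(path) -> list[WellRecord]:
    return wells_from_frame(pd.read_csv(path))
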