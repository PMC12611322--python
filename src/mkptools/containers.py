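"""Shared in-memory containers for multimodal single-cell data, clonal
well tables, and flow-style event tables.

The central object is :class:`MultimodalDataset`, a paired RNA/ADT count
container with per-cell and per-gene metadata, mirroring what a CITE-seq
experiment delivers after alignment and UMI counting: an integer cell x gene
RNA matrix, an integer cell x ADT surface-protein matrix, the lineage
reporter label of each cell (GFP = passed through a Flk2+ state, Tom = did
not), and curation flags for each gene (membrane-bound, antibody available,
blocklist category).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Blocklist categories a gene may carry (technical-bias genes removed
#: from DEG lists downstream).
BLOCKLIST_CATEGORIES = ("none", "mito", "ribo", "malat1")

#: Reserved population label identifying counting-bead events in a
#: :class:`FlowEventTable`.
BEAD_LABEL = "beads"


@dataclass
class MultimodalDataset:
    """Paired RNA/ADT count matrices with aligned cell and gene metadata.

    Attributes
    ----------
    rna_counts : (n_cells, n_genes) int array
    adt_counts : (n_cells, n_adts) int array
    cell_meta : DataFrame indexed by barcode with columns
        ``biosample``, ``condition``, ``reporter`` (GFP/Tom),
        ``subtype`` (ground-truth class) and ``rna_celltype``
        (the RNA-based annotation taken as an input label).
    gene_meta : DataFrame indexed by gene name with columns
        ``membrane_flag``, ``antibody_flag``, ``blocklist_category``.
    adt_names : ADT (surface marker) names, one per ADT column.
    """

    rna_counts: np.ndarray
    adt_counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    adt_names: Sequence[str]

    def __post_init__(self) -> None:
        self.rna_counts = np.asarray(self.rna_counts)
        self.adt_counts = np.asarray(self.adt_counts)
        n = self.rna_counts.shape[0]
        if self.adt_counts.shape[0] != n or len(self.cell_meta) != n:
            raise ValueError("cell dimension mismatch between matrices and cell_meta")
        if self.rna_counts.shape[1] != len(self.gene_meta):
            raise ValueError("gene dimension mismatch between rna_counts and gene_meta")
        if self.adt_counts.shape[1] != len(self.adt_names):
            raise ValueError("ADT dimension mismatch between adt_counts and adt_names")
        if self.cell_meta.index.duplicated().any():
            raise ValueError("cell barcodes must be unique")
        if (self.rna_counts < 0).any() or (self.adt_counts < 0).any():
            raise ValueError("count matrices must be nonnegative")
        bad = set(self.gene_meta["blocklist_category"]) - set(BLOCKLIST_CATEGORIES)
        if bad:
            raise ValueError(f"unknown blocklist categories: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.rna_counts.shape[0]

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def rna_frame(self) -> pd.DataFrame:
        """RNA counts as a cells x genes DataFrame."""
        return pd.DataFrame(self.rna_counts, index=self.barcodes, columns=self.gene_names)

    def adt_frame(self) -> pd.DataFrame:
        """ADT counts as a cells x markers DataFrame."""
        return pd.DataFrame(self.adt_counts, index=self.barcodes, columns=list(self.adt_names))

    def to_anndata(self):
        """Package as an AnnData (RNA in ``X``, ADT counts in ``obsm['adt']``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.rna_counts.astype(np.float32),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )
        adata.obsm["adt"] = self.adt_counts.astype(np.float32)
        adata.uns["adt_names"] = list(self.adt_names)
        return adata


@dataclass(frozen=True)
class WellRecord:
    """Outcome of one single-HSC (or MPP2) culture well.

    ``n_mkp`` counts phenotypic MkPs detected in the well at readout and
    splits exactly into canonical (``n_cmkp``) and noncanonical
    (``n_ncmkp``) subtypes.
    """

    well_id: str
    source_cell_class: str
    age_group: str
    n_live: int
    n_mkp: int
    n_cmkp: int
    n_ncmkp: int

    def __post_init__(self) -> None:
        for name in ("n_live", "n_mkp", "n_cmkp", "n_ncmkp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_cmkp + self.n_ncmkp != self.n_mkp:
            raise ValueError("n_cmkp + n_ncmkp must equal n_mkp")
        if self.n_mkp > self.n_live:
            raise ValueError("n_mkp cannot exceed n_live")


def wells_to_frame(wells: Sequence[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [w.well_id for w in wells],
            "source_cell_class": [w.source_cell_class for w in wells],
            "age_group": [w.age_group for w in wells],
            "n_live": [w.n_live for w in wells],
            "n_mkp": [w.n_mkp for w in wells],
            "n_cmkp": [w.n_cmkp for w in wells],
            "n_ncmkp": [w.n_ncmkp for w in wells],
        }
    )


def wells_from_frame(df: pd.DataFrame) -> list[WellRecord]:
    return [
        WellRecord(
            well_id=str(r.well_id),
            source_cell_class=str(r.source_cell_class),
            age_group=str(r.age_group),
            n_live=int(r.n_live),
            n_mkp=int(r.n_mkp),
            n_cmkp=int(r.n_cmkp),
            n_ncmkp=int(r.n_ncmkp),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class FlowEventTable:
    """Per-event flow-cytometry-style table with spiked counting beads.

    ``events`` has one row per acquired event, a ``population`` column and
    one column per fluorescence channel.  Bead events carry the reserved
    population label :data:`BEAD_LABEL` and support absolute quantification
    from the known ``beads_added``.
    """

    events: pd.DataFrame
    beads_added: int
    sample_volume_ul: float | None = None
    background_mfi: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "population" not in self.events.columns:
            raise ValueError("events must have a 'population' column")
        channels = self.events.drop(columns="population")
        if not np.isfinite(channels.to_numpy(dtype=float)).all():
            raise ValueError("channel intensities must be finite")
        if self.beads_added <= 0:
            raise ValueError("beads_added must be positive")

    @property
    def channels(self) -> list[str]:
        return [c for c in self.events.columns if c != "population"]

    def population_events(self, population: str) -> pd.DataFrame:
        return self.events[self.events["population"] == population]

    def n_events(self, population: str) -> int:
        return int((self.events["population"] == population).sum())

    @property
    def n_bead_events(self) -> int:
        return self.n_events(BEAD_LABEL)
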