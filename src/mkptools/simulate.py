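"""Synthetic multimodal single-cell data, clonal well tables, and
flow-style event tables.

The generator emulates the statistical structure the downstream analysis
assumes so the whole pipeline runs without external data:

- RNA counts are negative-binomial with per-gene base abundances, per-cell
  library-size factors, and planted per-group log2 fold changes; a fixed
  small set of mitochondrial / ribosomal / Malat1 genes is always present
  so the blocklist filters are exercised, and the ``Cd48`` / ``F11r``
  marker genes have subtype-dependent expression so the RNA-only gate is
  meaningful.
- ADT counts are generated by sampling per-cell target values on the CLR
  scale (per-ADT, per-subtype Gaussian modes, e.g. a bimodal CD48) and
  numerically inverting the CLR map per cell, so gating thresholds defined
  on the normalized scale are controlled directly.
- The lineage reporter (GFP/Tom) is assigned from the true subtype with a
  configurable concordance, emulating near- but not perfect correspondence
  between lineage label and surface phenotype.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import FlowEventTable, MultimodalDataset, WellRecord, BEAD_LABEL

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "default_adt_modes",
    "generate_multimodal",
    "generate_wells",
    "generate_flow_sample",
    "generate_pseudobulk_counts",
]

#: Fixed technical-bias genes always present in generated data.
BLOCKLIST_GENES = {
    "mt-Co1": ("mito", 20.0),
    "mt-Nd1": ("mito", 15.0),
    "mt-Cytb": ("mito", 12.0),
    "Rps19": ("ribo", 18.0),
    "Rpl13a": ("ribo", 15.0),
    "Rps6": ("ribo", 12.0),
    "Rpl32": ("ribo", 10.0),
    "Malat1": ("malat1", 30.0),
}

#: Subtype-dependent mean expression of the RNA-gate marker genes.
MARKER_GENE_MEANS = {
    "Cd48": {"cMkP": 6.0, "ncMkP": 0.05, "MyPro": 3.0},
    "F11r": {"cMkP": 0.05, "ncMkP": 5.0, "MyPro": 0.05},
}


@dataclass(frozen=True)
class PlantedEffect:
    """A planted differential-expression effect.

    Cells whose condition or subtype equals ``contrast[1]`` have the
    gene's mean multiplied by ``2**log2fc``; ``contrast[0]`` is the
    unchanged reference group.
    """

    gene: str
    contrast: tuple[str, str]
    log2fc: float


def default_adt_modes(
    subtypes: Sequence[str] = ("cMkP", "ncMkP", "MyPro"),
) -> dict[str, dict[str, tuple[float, float]]]:
    """Default per-ADT, per-subtype (mean, sd) modes on the CLR scale.

    CD48 is strongly bimodal between subtypes (the gating marker); the
    MkP-defining markers (CD117 high, Sca1 low, CD150/CD41 high) place
    cMkP/ncMkP cells inside the manual MkP gate while MyPro cells fail the
    CD150/CD41 gate; CD9/CD49b carry milder subtype differences; lineage
    markers are uniformly low.
    """
    table = {
        "CD48": {"cMkP": (1.9, 0.2), "ncMkP": (0.3, 0.1), "MyPro": (1.5, 0.3)},
        "Sca1": {"cMkP": (0.3, 0.15), "ncMkP": (0.3, 0.15), "MyPro": (0.3, 0.15)},
        "CD117": {"cMkP": (1.6, 0.2), "ncMkP": (1.6, 0.2), "MyPro": (1.6, 0.2)},
        "CD150": {"cMkP": (1.2, 0.2), "ncMkP": (1.2, 0.2), "MyPro": (0.2, 0.1)},
        "CD41": {"cMkP": (1.3, 0.2), "ncMkP": (1.3, 0.2), "MyPro": (0.3, 0.15)},
        "CD9": {"cMkP": (0.5, 0.15), "ncMkP": (1.0, 0.2), "MyPro": (0.5, 0.15)},
        "CD105": {"cMkP": (0.6, 0.2), "ncMkP": (0.9, 0.2), "MyPro": (0.6, 0.2)},
        "CD49b": {"cMkP": (0.4, 0.15), "ncMkP": (0.7, 0.15), "MyPro": (0.4, 0.15)},
        "CD4": {"cMkP": (0.15, 0.08), "ncMkP": (0.15, 0.08), "MyPro": (0.15, 0.08)},
        "B220": {"cMkP": (0.15, 0.08), "ncMkP": (0.15, 0.08), "MyPro": (0.15, 0.08)},
        "CD3": {"cMkP": (0.15, 0.08), "ncMkP": (0.15, 0.08), "MyPro": (0.15, 0.08)},
        "Gr1": {"cMkP": (0.15, 0.08), "ncMkP": (0.15, 0.08), "MyPro": (0.15, 0.08)},
        "Ter119": {"cMkP": (0.15, 0.08), "ncMkP": (0.15, 0.08), "MyPro": (0.15, 0.08)},
    }
    return {
        adt: {s: modes[s] for s in subtypes if s in modes}
        for adt, modes in table.items()
    }


def _default_subtype_fractions() -> dict[str, dict[str, float]]:
    # ncMkPs are rare in young mice and expand with age.
    return {
        "young": {"cMkP": 0.80, "ncMkP": 0.10, "MyPro": 0.10},
        "old": {"cMkP": 0.50, "ncMkP": 0.35, "MyPro": 0.15},
    }


@dataclass
class SimConfig:
    """Configuration of the multimodal generator."""

    n_cells: int = 2000
    n_genes: int = 300
    n_biosamples_per_condition: int = 4
    conditions: tuple[str, ...] = ("young", "old")
    condition_weights: tuple[float, ...] | None = None
    subtype_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_subtype_fractions
    )
    planted_degs: tuple[PlantedEffect, ...] = ()
    adt_modes: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=default_adt_modes
    )
    nb_dispersion: float = 0.1
    reporter_concordance: float = 0.95
    library_size_sd: float = 0.3
    seed: int = 0

    @property
    def n_adts(self) -> int:
        return len(self.adt_modes)

    @property
    def subtypes(self) -> list[str]:
        seen: list[str] = []
        for fracs in self.subtype_fractions.values():
            for s in fracs:
                if s not in seen:
                    seen.append(s)
        return seen

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if self.n_biosamples_per_condition <= 0:
            raise ValueError("n_biosamples_per_condition must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.reporter_concordance <= 1.0:
            raise ValueError("reporter_concordance must be in [0, 1]")
        for cond in self.conditions:
            if cond not in self.subtype_fractions:
                raise ValueError(f"no subtype fractions for condition {cond!r}")
            fracs = self.subtype_fractions[cond]
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9 or any(f < 0 for f in fracs.values()):
                raise ValueError(
                    f"subtype fractions for {cond!r} must be nonnegative and sum to 1"
                )
            for adt, modes in self.adt_modes.items():
                for s in fracs:
                    if s not in modes:
                        raise ValueError(f"ADT {adt!r} has no mode for subtype {s!r}")

    def to_yaml(self, path) -> None:
        payload = {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_biosamples_per_condition": self.n_biosamples_per_condition,
            "conditions": list(self.conditions),
            "condition_weights": list(self.condition_weights)
            if self.condition_weights
            else None,
            "subtype_fractions": {
                c: dict(f) for c, f in self.subtype_fractions.items()
            },
            "planted_degs": [
                {"gene": p.gene, "contrast": list(p.contrast), "log2fc": p.log2fc}
                for p in self.planted_degs
            ],
            "adt_modes": {
                a: {s: list(m) for s, m in modes.items()}
                for a, modes in self.adt_modes.items()
            },
            "nb_dispersion": self.nb_dispersion,
            "reporter_concordance": self.reporter_concordance,
            "library_size_sd": self.library_size_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        planted = tuple(
            PlantedEffect(p["gene"], tuple(p["contrast"]), float(p["log2fc"]))
            for p in payload.pop("planted_degs", [])
        )
        adt_modes = {
            a: {s: tuple(m) for s, m in modes.items()}
            for a, modes in payload.pop("adt_modes", {}).items()
        }
        weights = payload.pop("condition_weights", None)
        return cls(
            planted_degs=planted,
            adt_modes=adt_modes or default_adt_modes(),
            conditions=tuple(payload.pop("conditions")),
            condition_weights=tuple(weights) if weights else None,
            **payload,
        )


def _invert_clr_targets(z: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Integer ADT counts whose CLR values approximate the targets ``z``.

    Solves the per-cell fixed point g = exp(mean over features of
    log1p(g * (e^z - 1))) by fixed-point iteration (the map is a
    contraction in log g when enough targets are dim), then rounds counts
    to integers.  The scale is capped at 1e6 as a safeguard for target
    vectors that are bright on nearly every feature, where no finite
    fixed point exists and the requested CLR profile is unrepresentable.
    """
    n_cells, p = z.shape
    ez = np.expm1(np.maximum(z, 0.0))
    g = np.full(n_cells, 20.0)
    for _ in range(max_iter):
        x = g[:, None] * ez
        log_g_new = np.where(x > 0, np.log1p(x), 0.0).sum(axis=1) / p
        g_new = np.minimum(np.exp(log_g_new), 1e6)
        if np.max(np.abs(np.log(g_new) - np.log(np.maximum(g, 1e-300)))) < tol:
            g = g_new
            break
        g = g_new
    return np.rint(g[:, None] * ez).astype(np.int64)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_multimodal(config: SimConfig) -> MultimodalDataset:
    """Generate a paired RNA/ADT dataset per the configuration.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells

    weights = (
        np.asarray(config.condition_weights, dtype=float)
        if config.condition_weights
        else np.full(len(config.conditions), 1.0 / len(config.conditions))
    )
    condition = rng.choice(config.conditions, size=n, p=weights / weights.sum())
    replicate = rng.integers(0, config.n_biosamples_per_condition, size=n)
    biosample = np.array([f"{c}_s{r + 1}" for c, r in zip(condition, replicate)])

    subtype = np.empty(n, dtype=object)
    for cond in config.conditions:
        sel = condition == cond
        fracs = config.subtype_fractions[cond]
        names = list(fracs)
        probs = np.array([fracs[s] for s in names], dtype=float)
        subtype[sel] = rng.choice(names, size=int(sel.sum()), p=probs / probs.sum())

    base_reporter = np.where(subtype == "ncMkP", "Tom", "GFP")
    flip = rng.random(n) > config.reporter_concordance
    reporter = np.where(
        flip, np.where(base_reporter == "GFP", "Tom", "GFP"), base_reporter
    )
    rna_celltype = np.where(np.isin(subtype, ["cMkP", "ncMkP"]), "MkP", subtype)

    # --- gene metadata and base means ---------------------------------
    special = list(MARKER_GENE_MEANS) + list(BLOCKLIST_GENES)
    n_generic = max(config.n_genes - len(special), 0)
    generic = [f"Gene{i + 1:04d}" for i in range(n_generic)]
    gene_names = special + generic
    blocklist = [
        BLOCKLIST_GENES[g][0] if g in BLOCKLIST_GENES else "none" for g in gene_names
    ]
    membrane = rng.random(len(gene_names)) < 0.3
    antibody = membrane & (rng.random(len(gene_names)) < 0.6)
    for marker in MARKER_GENE_MEANS:
        i = gene_names.index(marker)
        membrane[i] = True
        antibody[i] = True
    gene_meta = pd.DataFrame(
        {
            "membrane_flag": membrane,
            "antibody_flag": antibody,
            "blocklist_category": blocklist,
        },
        index=pd.Index(gene_names, name="gene"),
    )

    base = np.empty(len(gene_names))
    base[len(special):] = rng.lognormal(mean=np.log(2.0), sigma=1.0, size=n_generic)
    for j, g in enumerate(special):
        base[j] = BLOCKLIST_GENES[g][1] if g in BLOCKLIST_GENES else 1.0

    lib = rng.lognormal(mean=0.0, sigma=config.library_size_sd, size=n)
    mu = np.outer(lib, base)
    for marker, means in MARKER_GENE_MEANS.items():
        j = gene_names.index(marker)
        per_cell = np.array([means.get(s, 0.05) for s in subtype])
        mu[:, j] = lib * per_cell
    for effect in config.planted_degs:
        if effect.gene not in gene_names:
            raise ValueError(f"planted gene {effect.gene!r} not in gene set")
        j = gene_names.index(effect.gene)
        affected = (condition == effect.contrast[1]) | (subtype == effect.contrast[1])
        mu[affected, j] *= 2.0**effect.log2fc

    rna_counts = _nb_draw(rng, mu, config.nb_dispersion)

    # --- ADT counts via CLR-target inversion --------------------------
    adt_names = list(config.adt_modes)
    mean_mat = np.empty((n, len(adt_names)))
    sd_mat = np.empty_like(mean_mat)
    for k, adt in enumerate(adt_names):
        modes = config.adt_modes[adt]
        mean_mat[:, k] = [modes[s][0] for s in subtype]
        sd_mat[:, k] = [modes[s][1] for s in subtype]
    targets = np.maximum(rng.normal(mean_mat, sd_mat), 0.0)
    adt_counts = _invert_clr_targets(targets)

    barcodes = pd.Index([f"cell{i + 1:05d}-1" for i in range(n)], name="barcode")
    cell_meta = pd.DataFrame(
        {
            "biosample": biosample,
            "condition": condition,
            "reporter": reporter,
            "subtype": subtype,
            "rna_celltype": rna_celltype,
        },
        index=barcodes,
    )
    return MultimodalDataset(
        rna_counts=rna_counts,
        adt_counts=adt_counts,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
        adt_names=adt_names,
    )


def generate_wells(
    model: str,
    p_ncmkp: float,
    well_sizes,
    n_wells: int,
    seed: int = 0,
    *,
    source_cell_class: str = "HSC",
    age_group: str = "old",
    mkp_generation_rate: float = 1.0,
) -> list[WellRecord]:
    """Generate single-HSC well outcomes under a commitment model.

    ``model='strict_restriction'``: each well's MkPs are all one subtype;
    the well-level subtype is Bernoulli(``p_ncmkp``).
    ``model='independent'``: each MkP commits i.i.d. Bernoulli(``p_ncmkp``).

    ``well_sizes`` is a scalar (all wells equal), a sequence of length
    ``n_wells``, or a pool to sample from.  ``mkp_generation_rate`` sets
    the fraction of wells producing any MkPs at all (others read out with
    ``n_mkp = 0``).
    """
    if model not in ("strict_restriction", "independent"):
        raise ValueError(f"unknown model: {model!r}")
    if not 0.0 <= p_ncmkp <= 1.0:
        raise ValueError("p_ncmkp must be in [0, 1]")
    if not 0.0 < mkp_generation_rate <= 1.0:
        raise ValueError("mkp_generation_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)

    sizes = np.asarray(well_sizes)
    if sizes.ndim == 0:
        sizes = np.full(n_wells, int(sizes))
    elif sizes.size == n_wells:
        sizes = sizes.astype(int)
    else:
        sizes = rng.choice(sizes.astype(int), size=n_wells, replace=True)
    if (sizes < 0).any():
        raise ValueError("well sizes must be nonnegative")
    productive = rng.random(n_wells) < mkp_generation_rate
    sizes = np.where(productive, sizes, 0)

    wells = []
    for i, size in enumerate(sizes):
        size = int(size)
        if size == 0:
            n_nc = 0
        elif model == "strict_restriction":
            n_nc = size if rng.random() < p_ncmkp else 0
        else:
            n_nc = int(rng.binomial(size, p_ncmkp))
        n_live = size + int(rng.poisson(30))
        wells.append(
            WellRecord(
                well_id=f"well{i + 1:04d}",
                source_cell_class=source_cell_class,
                age_group=age_group,
                n_live=n_live,
                n_mkp=size,
                n_cmkp=size - n_nc,
                n_ncmkp=n_nc,
            )
        )
    return wells


def generate_flow_sample(
    populations: Mapping[str, Mapping],
    n_bead_events: int,
    beads_added: int,
    *,
    sample_volume_ul: float | None = None,
    background_mfi: Mapping[str, float] | None = None,
    seed: int = 0,
) -> FlowEventTable:
    """Generate a flow-style event table with spiked counting beads.

    ``populations`` maps a population label to ``{"n_events": int,
    "channels": {channel: (median, lognormal_sigma)}}``; channel
    intensities are lognormal around the given median.  Channels missing
    from a population are filled with zeros.  Bead events get a bright,
    tight lognormal signal on every channel.
    """
    if BEAD_LABEL in populations:
        raise ValueError(f"population label {BEAD_LABEL!r} is reserved for beads")
    rng = np.random.default_rng(seed)
    channels: list[str] = []
    for spec in populations.values():
        for ch in spec.get("channels", {}):
            if ch not in channels:
                channels.append(ch)

    frames = []
    for label, spec in populations.items():
        n_events = int(spec["n_events"])
        data = {"population": [label] * n_events}
        for ch in channels:
            if ch in spec.get("channels", {}):
                median, sigma = spec["channels"][ch]
                data[ch] = rng.lognormal(mean=np.log(median), sigma=sigma, size=n_events)
            else:
                data[ch] = np.zeros(n_events)
        frames.append(pd.DataFrame(data))
    bead_data = {"population": [BEAD_LABEL] * n_bead_events}
    for ch in channels:
        bead_data[ch] = rng.lognormal(mean=np.log(5e4), sigma=0.05, size=n_bead_events)
    frames.append(pd.DataFrame(bead_data))

    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return FlowEventTable(
        events=events,
        beads_added=beads_added,
        sample_volume_ul=sample_volume_ul,
        background_mfi=dict(background_mfi or {}),
    )


def generate_pseudobulk_counts(
    n_genes: int = 2000,
    n_per_group: int = 4,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    n_planted: int = 0,
    planted_log2fc: float = 3.0,
    depth_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Sample-level NB count table for differential-engine calibration.

    Two conditions ``A`` (reference) and ``B`` with ``n_per_group``
    samples each; the first ``n_planted`` genes have condition-B means
    multiplied by ``2**planted_log2fc`` (reference mean ``base_mean``).
    Per-sample depth factors are lognormal with ``depth_sd``.

    Returns ``(counts, condition, true_log2fc)``.
    """
    rng = np.random.default_rng(seed)
    m = 2 * n_per_group
    depth = rng.lognormal(0.0, depth_sd, size=m)
    condition = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group,
        index=[f"s{i + 1}" for i in range(m)],
    )
    truth = pd.Series(0.0, index=[f"g{j + 1}" for j in range(n_genes)])
    truth.iloc[:n_planted] = planted_log2fc

    mu = np.full((m, n_genes), base_mean)
    is_b = (condition == "B").to_numpy()
    mu[np.ix_(is_b, np.arange(n_planted))] *= 2.0**planted_log2fc
    mu *= depth[:, None]
    counts = _nb_draw(rng, mu, dispersion)
    frame = pd.DataFrame(counts.T, index=truth.index, columns=condition.index)
    return frame, condition, truth
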