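"""Marker gating: mixture-model thresholds, manual protein gates, RNA gate.

Positivity for CD48 on the CLR scale is decided by a two-component
univariate Gaussian mixture fitted to the marker's normalized values among
RNA-annotated MkPs; the positive/negative threshold is the midpoint of the
two component means.  Manual protein gates reproduce the hierarchical
flow-style scheme: myeloid progenitors (MyPro) are Sca1-low / CD117-high,
MkPs are MyPro cells with CD150 and CD41 above threshold, and MkPs split
into canonical (CD48 >= tau) vs noncanonical (CD48 < tau) subtypes.  The
RNA-only gate classifies MkPs by Cd48/F11r transcript positivity instead,
excluding double-positive and double-negative cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .containers import MultimodalDataset
from .normalize import clr_normalize_matrix

__all__ = [
    "GMMFit",
    "fit_gmm2",
    "GateConfig",
    "apply_protein_gates",
    "rna_gate",
    "annotate_schemes",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GMMFit:
    """Two-component 1-D Gaussian mixture, components sorted by mean.

    ``threshold`` is the midpoint of the two component means and is the
    positivity cutoff used for gating.  ``log_likelihoods`` records the
    total log-likelihood after every EM iteration (non-decreasing).
    """

    mean_lo: float
    mean_hi: float
    sd_lo: float
    sd_hi: float
    weight_lo: float
    weight_hi: float
    threshold: float
    n_iter: int
    converged: bool
    log_likelihoods: tuple[float, ...] = field(repr=False, default=())

    @property
    def means(self) -> tuple[float, float]:
        return (self.mean_lo, self.mean_hi)


def fit_gmm2(
    values,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    sd_floor: float = 1e-6,
) -> GMMFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialization is deterministic: component means at the 25th/75th
    percentiles of the data, equal weights, both standard deviations at
    half the sample standard deviation.  Convergence is declared when the
    change in total log-likelihood falls below ``tol``.

    Raises
    ------
    ValueError
        For fewer than 10 finite values or degenerate (constant) input.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite values to fit a mixture")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: values have zero spread")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:  # heavy ties at the quartiles
        mu = np.array([x.min(), x.max()], dtype=float)
    sd = np.full(2, max(x.std() / 2.0, sd_floor))
    w = np.array([0.5, 0.5])

    loglik_path: list[float] = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step: responsibilities in log space for stability
        logp = (
            np.log(w)[None, :]
            - np.log(sd)[None, :]
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        loglik_path.append(loglik)
        r = np.exp(logp - lse[:, None])

        # M step
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        w = nk / x.size

        if loglik - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = loglik

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    return GMMFit(
        mean_lo=float(mu[0]),
        mean_hi=float(mu[1]),
        sd_lo=float(sd[0]),
        sd_hi=float(sd[1]),
        weight_lo=float(w[0]),
        weight_hi=float(w[1]),
        threshold=float((mu[0] + mu[1]) / 2.0),
        n_iter=n_iter,
        converged=converged,
        log_likelihoods=tuple(loglik_path),
    )


@dataclass(frozen=True)
class GateConfig:
    """Named per-marker inequality thresholds for the protein gate tree.

    Boundary conventions follow the printed rules: the MyPro/MkP gates use
    strict inequalities, CD48 positivity is inclusive at the threshold.
    ``markers`` maps gate roles to the ADT column names in the data.
    """

    sca1_max: float = 0.71
    cd117_min: float = 1.0
    cd150_min: float = 0.45
    cd41_min: float = 0.6
    cd48_threshold: float = 1.1
    markers: Mapping[str, str] = field(
        default_factory=lambda: {
            "sca1": "Sca1",
            "cd117": "CD117",
            "cd150": "CD150",
            "cd41": "CD41",
            "cd48": "CD48",
        }
    )

    def with_threshold(self, tau: float) -> "GateConfig":
        """Copy of this config with the CD48 split set to ``tau``."""
        return replace(self, cd48_threshold=float(tau))

    def to_yaml(self, path) -> None:
        payload = {
            "thresholds": {
                "sca1_max": self.sca1_max,
                "cd117_min": self.cd117_min,
                "cd150_min": self.cd150_min,
                "cd41_min": self.cd41_min,
                "cd48_threshold": self.cd48_threshold,
            },
            "markers": dict(self.markers),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GateConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        thresholds = payload.get("thresholds", {})
        return cls(markers=payload.get("markers", cls().markers), **thresholds)


def apply_protein_gates(adt_clr: pd.DataFrame, config: GateConfig) -> pd.Series:
    """Label each cell from CLR-normalized ADT values.

    Returns a Series over the input index with values ``cMkP``, ``ncMkP``,
    ``MyPro`` (passes the myeloid-progenitor gate but not the MkP gate) or
    ``unlabeled``.
    """
    missing = [m for m in config.markers.values() if m not in adt_clr.columns]
    if missing:
        raise KeyError(f"gated ADT columns missing from matrix: {missing}")

    sca1 = adt_clr[config.markers["sca1"]]
    cd117 = adt_clr[config.markers["cd117"]]
    cd150 = adt_clr[config.markers["cd150"]]
    cd41 = adt_clr[config.markers["cd41"]]
    cd48 = adt_clr[config.markers["cd48"]]

    mypro = (sca1 < config.sca1_max) & (cd117 > config.cd117_min)
    mkp = mypro & (cd150 > config.cd150_min) & (cd41 > config.cd41_min)
    cmkp = mkp & (cd48 >= config.cd48_threshold)

    labels = pd.Series("unlabeled", index=adt_clr.index, dtype=object)
    labels[mypro] = "MyPro"
    labels[mkp & ~cmkp] = "ncMkP"
    labels[cmkp] = "cMkP"
    return labels


def rna_gate(cd48_expr, f11r_expr, index=None) -> pd.Series:
    """Classify MkPs by Cd48/F11r transcript positivity (expression > 0).

    Returns per-cell ``cMkP_RNA`` (Cd48+ F11r-), ``ncMkP_RNA``
    (Cd48- F11r+), ``excluded_double_positive`` or
    ``excluded_double_negative``.
    """
    cd48 = np.asarray(cd48_expr, dtype=float)
    f11r = np.asarray(f11r_expr, dtype=float)
    if cd48.shape != f11r.shape:
        raise ValueError("cd48 and f11r vectors must have equal length")
    if (cd48 < 0).any() or (f11r < 0).any():
        raise ValueError("expression values must be nonnegative")
    cd48_pos = cd48 > 0
    f11r_pos = f11r > 0
    out = np.where(
        cd48_pos & ~f11r_pos,
        "cMkP_RNA",
        np.where(
            ~cd48_pos & f11r_pos,
            "ncMkP_RNA",
            np.where(cd48_pos & f11r_pos, "excluded_double_positive", "excluded_double_negative"),
        ),
    )
    if index is None and isinstance(cd48_expr, pd.Series):
        index = cd48_expr.index
    return pd.Series(out, index=index)


def _collapse_reporter(label: str) -> str:
    # Cells still carrying Tom protein after the genetic switch count as GFP.
    return "GFP" if "GFP" in label else "Tom"


def annotate_schemes(
    dataset: MultimodalDataset,
    *,
    gate_config: GateConfig | None = None,
    tau: float | None = None,
    adt_clr: pd.DataFrame | None = None,
    cd48_gene: str = "Cd48",
    f11r_gene: str = "F11r",
) -> pd.DataFrame:
    """Build the four per-barcode MkP subtype annotations.

    Columns of the returned table (indexed by barcode):

    - ``rna_reporter``: RNA-annotated MkPs labeled by lineage reporter
      (GFP -> cMkP-like, Tom -> ncMkP-like); the reference scheme.
    - ``rna_protein``: RNA-annotated MkPs split by CD48 CLR value at
      ``tau``.
    - ``protein_only``: full manual protein gate tree, no RNA input.
    - ``rna_only``: RNA-annotated MkPs split by Cd48/F11r transcripts,
      with exclusion reasons for double-positive/negative cells.

    If ``tau`` is None it is derived by fitting the two-component mixture
    to CD48 CLR values among RNA-annotated MkPs.
    """
    gate_config = gate_config or GateConfig()
    if adt_clr is None:
        adt_clr = clr_normalize_matrix(dataset.adt_frame())

    is_rna_mkp = (dataset.cell_meta["rna_celltype"] == "MkP").to_numpy()
    cd48_col = gate_config.markers["cd48"]
    if tau is None:
        tau = fit_gmm2(adt_clr.loc[is_rna_mkp, cd48_col]).threshold
    gate_config = gate_config.with_threshold(tau)

    out = pd.DataFrame(index=dataset.barcodes)
    reporter = dataset.cell_meta["reporter"].map(_collapse_reporter)
    out["rna_reporter"] = np.where(
        is_rna_mkp, np.where(reporter == "GFP", "cMkP", "ncMkP"), pd.NA
    )
    out["rna_protein"] = np.where(
        is_rna_mkp, np.where(adt_clr[cd48_col] >= tau, "cMkP", "ncMkP"), pd.NA
    )
    out["protein_only"] = apply_protein_gates(adt_clr, gate_config)

    rna = dataset.rna_frame()
    rna_calls = rna_gate(rna[cd48_gene], rna[f11r_gene])
    out["rna_only"] = np.where(is_rna_mkp, rna_calls, pd.NA)
    out.attrs["cd48_threshold"] = float(tau)
    return out
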