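"""Per-cell centered log-ratio (CLR) normalization of ADT counts.

Raw antibody-derived-tag (ADT) counts are compositional: each cell's totals
are dominated by staining efficiency and sequencing depth, so counts are
normalized within each cell before any gating.  The variant implemented here
works on a cell's count vector ``x_1..x_p`` (``p`` = total number of ADT
features) as:

    s = sum over nonzero x_j of ln(x_j + 1)
    g = exp(s / p)
    z_j = ln(1 + x_j / g)

i.e. the per-cell geometric-mean-style scale ``g`` is built from the
offset logs of the *nonzero* elements but averaged over the *total* feature
count, and the final variance-stabilizing log is applied as ``log1p`` so
that zero counts map exactly to zero on the normalized scale.  This differs
from the textbook CLR (which would average over nonzero features only and
log the ratio directly); the dialect can be switched per call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["clr_normalize_cell", "clr_normalize_matrix"]


def _cell_scale(x: np.ndarray, denominator: str) -> float:
    """Per-cell normalization scale g."""
    nonzero = x[x > 0]
    s = float(np.log1p(nonzero).sum())
    if denominator == "total":
        p = x.size
    elif denominator == "nonzero":
        p = max(nonzero.size, 1)
    else:
        raise ValueError(f"unknown denominator convention: {denominator!r}")
    return float(np.exp(s / p))


def clr_normalize_cell(
    counts, *, denominator: str = "total", final_log: str = "log1p"
) -> np.ndarray:
    """CLR-normalize one cell's ADT count vector.

    Parameters
    ----------
    counts
        Nonnegative integer (or real) counts, one entry per ADT feature.
    denominator
        ``"total"`` (default) divides the nonzero log-sum by the total
        feature count ``p``; ``"nonzero"`` divides by the number of nonzero
        features (textbook CLR dialect).
    final_log
        ``"log1p"`` (default) returns ``ln(1 + x/g)`` so zeros stay zero;
        ``"log"`` returns ``ln(x/g)`` with zeros mapped to ``-inf``.

    Returns
    -------
    ndarray of the same length on the normalized scale.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("counts must be a nonempty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("counts must be finite")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    g = _cell_scale(x, denominator)
    ratio = x / g
    if final_log == "log1p":
        return np.log1p(ratio)
    if final_log == "log":
        with np.errstate(divide="ignore"):
            return np.log(ratio)
    raise ValueError(f"unknown final_log convention: {final_log!r}")


def clr_normalize_matrix(
    adt_counts, *, denominator: str = "total", final_log: str = "log1p"
):
    """Row-wise CLR normalization of a cells x ADT count matrix.

    Accepts an ndarray or DataFrame; a DataFrame round-trips its index and
    columns.  Each row (cell) is normalized independently.
    """
    if isinstance(adt_counts, pd.DataFrame):
        values = adt_counts.to_numpy(dtype=float)
        out = clr_normalize_matrix(values, denominator=denominator, final_log=final_log)
        return pd.DataFrame(out, index=adt_counts.index, columns=adt_counts.columns)

    x = np.asarray(adt_counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("adt_counts must be 2-D (cells x features)")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    nonzero_logsum = np.where(x > 0, np.log1p(x), 0.0).sum(axis=1)
    if denominator == "total":
        p = np.full(x.shape[0], x.shape[1], dtype=float)
    elif denominator == "nonzero":
        p = np.maximum((x > 0).sum(axis=1), 1).astype(float)
    else:
        raise ValueError(f"unknown denominator convention: {denominator!r}")
    g = np.exp(nonzero_logsum / p)
    ratio = x / g[:, None]
    if final_log == "log1p":
        return np.log1p(ratio)
    if final_log == "log":
        with np.errstate(divide="ignore"):
            return np.log(ratio)
    raise ValueError(f"unknown final_log convention: {final_log!r}")
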