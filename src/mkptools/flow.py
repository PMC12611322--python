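"""Flow-cytometry-style quantification utilities.

Absolute cell counts from spiked counting beads (a known number of beads is
added to the sample, so cells = events_pop * beads_added / bead_events),
background-subtracted median fluorescence intensity (MFI), donor chimerism
(baseline-subtracted donor fraction), and activation-kinetics area under
the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BEAD_LABEL, FlowEventTable

__all__ = [
    "AbsoluteCount",
    "absolute_count",
    "chimerism",
    "kinetics_auc",
    "background_subtracted_mfi",
    "QuantResult",
    "quantify_population",
]


@dataclass(frozen=True)
class AbsoluteCount:
    count: float
    per_ul: float | None = None


def absolute_count(
    events_pop: int,
    events_beads: int,
    beads_added: int,
    volume_ul: float | None = None,
) -> AbsoluteCount:
    """Bead-ratio absolute count: ``events_pop * beads_added / events_beads``.

    With a known sample volume the concentration per microliter is also
    returned.
    """
    if events_beads <= 0:
        raise ValueError("no bead events acquired; absolute count undefined")
    if beads_added <= 0:
        raise ValueError("beads_added must be positive")
    if events_pop < 0:
        raise ValueError("events_pop must be nonnegative")
    count = events_pop * beads_added / events_beads
    per_ul = count / volume_ul if volume_ul else None
    return AbsoluteCount(count=count, per_ul=per_ul)


def chimerism(freq_test: float, freq_baseline: float) -> float:
    """Baseline-subtracted donor fraction, floored at zero."""
    for f in (freq_test, freq_baseline):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    return max(freq_test - freq_baseline, 0.0)


def kinetics_auc(timestamps, intensities) -> float:
    """Trapezoidal area under an activation-kinetics trace.

    Timestamps (seconds) must be strictly increasing; no smoothing or
    resampling is applied.
    """
    t = np.asarray(timestamps, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size:
        raise ValueError("timestamps and intensities must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    return float(np.trapezoid(y, t))


def background_subtracted_mfi(intensities, background: float = 0.0) -> float:
    """Median channel intensity minus background (may be negative)."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty population: MFI undefined")
    return float(np.median(x) - background)


@dataclass(frozen=True)
class QuantResult:
    """Quantification of one population within an event table."""

    population: str
    frequency: float
    count: float
    per_ul: float | None
    mfi: float | None


def quantify_population(
    table: FlowEventTable,
    population: str,
    channel: str | None = None,
    parent: str | None = None,
) -> QuantResult:
    """Frequency-of-parent, bead-based absolute count, and optional MFI.

    ``parent`` restricts the frequency denominator to another population;
    by default all non-bead events are the parent.  ``channel`` selects the
    intensity channel for the background-subtracted MFI (background taken
    from the table's ``background_mfi`` map, defaulting to 0).
    """
    events = table.events
    is_bead = events["population"] == BEAD_LABEL
    n_pop = table.n_events(population)
    if parent is None:
        n_parent = int((~is_bead).sum())
    else:
        n_parent = table.n_events(parent)
    frequency = n_pop / n_parent if n_parent else float("nan")

    counts = absolute_count(
        n_pop, table.n_bead_events, table.beads_added, table.sample_volume_ul
    )
    mfi = None
    if channel is not None:
        pop_events = table.population_events(population)
        mfi = background_subtracted_mfi(
            pop_events[channel], float(table.background_mfi.get(channel, 0.0))
        )
    return QuantResult(
        population=population,
        frequency=frequency,
        count=counts.count,
        per_ul=counts.per_ul,
        mfi=mfi,
    )
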