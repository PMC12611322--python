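"""Marker-candidate triage and cross-annotation concordance.

Candidate surface markers are genes supported by differential-expression
evidence (bulk and/or pseudobulk single-cell, at strict and/or relaxed
thresholds) and/or differential ADT scores, restricted to genes predicted
to be membrane-bound with a commercially available antibody.  Candidates
are then validated by flow cytometry: a usable marker must separate the
two populations by at least a two-fold background-subtracted MFI
difference.

Annotation schemes are compared per barcode: for each reference class
(e.g. GFP+ vs Tom+ lineage label) the capture rate is the fraction of its
barcodes that the test annotation assigns to the mapped class (cMkP vs
ncMkP).  DEG lists from different annotation schemes are compared by Venn
region counts and pairwise Jaccard similarity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .differential import ADT_CUTOFFS, filter_degs, select_adt_candidates

__all__ = [
    "intersect_candidates",
    "MFIResult",
    "mfi_fold_change",
    "ConcordanceReport",
    "capture_rate",
    "deg_overlap",
]


def intersect_candidates(
    bulk_degs: pd.DataFrame | None,
    sc_degs: pd.DataFrame | None,
    adt_scores: pd.DataFrame | None,
    gene_meta: pd.DataFrame,
    *,
    adt_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join DEG and ADT evidence into a candidate-marker table.

    Parameters
    ----------
    bulk_degs, sc_degs
        Full differential-expression tables (as from ``nb_wald_test``,
        indexed by gene); each is filtered here at both the strict and the
        relaxed thresholds to set the evidence flags.  Either may be None.
    adt_scores
        ADT score table (as from ``score_adt_table``); restrictive and
        relaxed cutoffs set the remaining flags.  May be None.
    gene_meta
        Indexed by gene with boolean ``membrane_flag`` and
        ``antibody_flag`` curation columns.
    adt_to_gene
        Optional ADT name -> gene name mapping (defaults to identity).

    Returns
    -------
    DataFrame indexed by gene with the six evidence flags, the curation
    flags, ``direction`` ('A' = enriched in the first/reference-like group)
    and ``n_evidence``.  Only genes with both curation flags and at least
    one evidence flag are candidates.
    """
    if gene_meta.index.duplicated().any():
        raise ValueError("gene_meta index contains duplicate gene names")

    evidence: dict[str, pd.DataFrame] = {}
    for prefix, table, kind in (("bulk", bulk_degs, "bulk"), ("sc", sc_degs, "sc")):
        if table is None:
            continue
        if table.index.duplicated().any():
            raise ValueError(f"{prefix} DEG table contains duplicate gene names")
        for mode in ("strict", "relaxed"):
            kept = filter_degs(table, mode, kind)
            evidence[f"{prefix}_{mode}"] = pd.DataFrame(
                {"sign": np.sign(kept["log2FC"])}, index=kept.index
            )
    if adt_scores is not None:
        mapping = adt_to_gene or {}
        renamed = adt_scores.rename(index=lambda a: mapping.get(a, a))
        if renamed.index.duplicated().any():
            raise ValueError("ADT names collide after mapping to gene namespace")
        for cut in ("restrictive", "relaxed"):
            kept = select_adt_candidates(renamed, cutoff=cut)
            evidence[f"adt_{cut}"] = pd.DataFrame(
                {"sign": np.sign(kept["score"])}, index=kept.index
            )

    genes = sorted(set().union(*(set(e.index) for e in evidence.values()))) if evidence else []
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    signs = pd.DataFrame(index=table.index)
    for flag in ("bulk_strict", "bulk_relaxed", "sc_strict", "sc_relaxed",
                 "adt_restrictive", "adt_relaxed"):
        if flag in evidence:
            table[flag] = table.index.isin(evidence[flag].index)
            signs[flag] = evidence[flag]["sign"].reindex(table.index)
        else:
            table[flag] = False
            signs[flag] = np.nan

    flags = gene_meta.reindex(table.index)
    table["membrane_flag"] = flags["membrane_flag"].fillna(False).astype(bool)
    table["antibody_flag"] = flags["antibody_flag"].fillna(False).astype(bool)
    mean_sign = signs.mean(axis=1, skipna=True)
    table["direction"] = np.where(mean_sign >= 0, "A", "B")
    table["n_evidence"] = table[
        ["bulk_strict", "bulk_relaxed", "sc_strict", "sc_relaxed",
         "adt_restrictive", "adt_relaxed"]
    ].sum(axis=1)
    candidates = table[
        table["membrane_flag"] & table["antibody_flag"] & (table["n_evidence"] > 0)
    ]
    candidates.attrs["shared_bulk_sc_relaxed"] = sorted(
        set(evidence.get("bulk_relaxed", pd.DataFrame()).index)
        & set(evidence.get("sc_relaxed", pd.DataFrame()).index)
    )
    return candidates


@dataclass(frozen=True)
class MFIResult:
    """Background-subtracted MFI fold change and the two-fold criterion."""

    fold_change: float
    passed: bool
    undefined: bool = False


def mfi_fold_change(
    mfi_a: float,
    mfi_b: float,
    background_a: float = 0.0,
    background_b: float = 0.0,
    min_fold: float = 2.0,
) -> MFIResult:
    """Fold change of background-subtracted MFIs, pass when >= two-fold
    separation in either direction.

    A nonpositive background-subtracted denominator makes the ratio
    undefined; the result is flagged rather than raised, as this happens
    routinely for unstained controls.
    """
    num = mfi_a - background_a
    den = mfi_b - background_b
    if den <= 0 or num <= 0:
        return MFIResult(fold_change=float("nan"), passed=False, undefined=True)
    fc = num / den
    return MFIResult(fold_change=fc, passed=max(fc, 1.0 / fc) >= min_fold)


@dataclass
class ConcordanceReport:
    """Per-class capture rates and the full confusion table."""

    capture_rates: dict[str, float]
    confusion: pd.DataFrame
    n_evaluable: int
    n_unmatched: int
    class_map: dict[str, str] = field(default_factory=dict)


def capture_rate(
    reference: pd.Series,
    test: pd.Series,
    class_map: Mapping[str, str],
) -> ConcordanceReport:
    """How often a cell lands in the "correct" bin across annotations.

    Parameters
    ----------
    reference, test
        Per-barcode labels; aligned on their index.  Barcodes present in
        only one series, or with missing labels, are excluded and counted
        as unmatched.
    class_map
        Reference class -> matching test class (e.g. GFP -> cMkP).

    Returns
    -------
    ConcordanceReport with, per reference class, the fraction of its
    barcodes whose test label equals the mapped class.
    """
    ref = pd.Series(reference)
    tst = pd.Series(test)
    joined = pd.concat([ref.rename("ref"), tst.rename("test")], axis=1, join="outer")
    evaluable = joined.dropna()
    evaluable = evaluable[evaluable["ref"].isin(class_map.keys())]
    n_unmatched = len(joined) - len(evaluable)

    confusion = pd.crosstab(evaluable["ref"], evaluable["test"], dropna=False)
    rates = {}
    for ref_class, test_class in class_map.items():
        members = evaluable["ref"] == ref_class
        total = int(members.sum())
        if total == 0:
            rates[ref_class] = float("nan")
        else:
            rates[ref_class] = float((evaluable.loc[members, "test"] == test_class).sum() / total)
    return ConcordanceReport(
        capture_rates=rates,
        confusion=confusion,
        n_evaluable=int(len(evaluable)),
        n_unmatched=int(n_unmatched),
        class_map=dict(class_map),
    )


def deg_overlap(deg_sets: Mapping[str, Iterable]) -> dict:
    """Venn region counts and pairwise Jaccard for 2+ DEG sets.

    Returns ``{"regions": {membership-tuple: count}, "jaccard": DataFrame,
    "sizes": {name: size}}`` where each region key is the tuple of set
    names an element belongs to (exclusive regions, as drawn in a Venn
    diagram).
    """
    sets = {name: set(s) for name, s in deg_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 DEG sets")
    names = list(sets)

    regions: dict[tuple[str, ...], int] = {}
    universe = set().union(*sets.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)

    jac = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        union = sets[a] | sets[b]
        j = len(sets[a] & sets[b]) / len(union) if union else float("nan")
        jac.loc[a, b] = jac.loc[b, a] = j
    return {
        "regions": regions,
        "jaccard": jac,
        "sizes": {n: len(sets[n]) for n in names},
        "universe_size": len(universe),
    }
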