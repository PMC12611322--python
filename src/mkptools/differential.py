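"""Pseudobulk negative-binomial differential expression and ADT scoring.

Single-cell counts are aggregated into pseudobulk samples (summing cells
within each biosample x condition), normalized with median-of-ratios size
factors, and tested gene-by-gene with a two-group negative-binomial GLM and
a Wald test on the condition coefficient.  This is a deliberately compact
DESeq2-style engine: gene-wise dispersions come from a Cox-Reid-style
degrees-of-freedom-adjusted method of moments (no dispersion-trend or MAP
shrinkage), the GLM is fitted by iteratively reweighted least squares, and
p values are Benjamini-Hochberg adjusted.  Because group sizes are small
(typically 3-5 replicates), the Wald statistic is referred to a
t distribution with (n_samples - 2) degrees of freedom rather than the
normal; with plug-in moment dispersions this keeps the nominal 5% test
close to its size.

DEG lists are then filtered the way candidate surface markers were triaged:
blocklisted genes (mitochondrial, ribosomal, Malat1) and genes with no
adjusted p value are removed, genes at-or-below an abundance floor in both
conditions are removed (floor 50 for bulk RNAseq, 5 for pseudobulk
single-cell), and either a strict (|log2FC| >= 2.5 and padj < 0.01) or a
relaxed (log2FC >= 1.5 OR padj < 0.1) threshold is applied.

Surface-protein (ADT) group differences are scored with either a
tie-corrected Wilcoxon rank-sum z or the overestimated-variance t statistic
(both group variances divided by the first group's size), and candidates
are selected at a restrictive (|score| >= 10) or relaxed (|score| >= 5)
cutoff after removing lineage and MkP-defining markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pseudobulk_aggregate",
    "size_factors",
    "nb_wald_test",
    "compute_base_mean",
    "filter_degs",
    "ADTScore",
    "adt_score",
    "score_adt_table",
    "select_adt_candidates",
    "LINEAGE_MARKERS",
    "MKP_DEFINING_MARKERS",
    "ADT_CUTOFFS",
    "ABUNDANCE_FLOORS",
]

#: Mature-lineage ADT markers excluded from candidate scoring.
LINEAGE_MARKERS = frozenset(
    {"CD3", "CD4", "CD5", "CD8a", "CD11b", "Gr1", "B220", "Ter119"}
)
#: Markers that define the MkP gate itself, excluded from candidate scoring.
MKP_DEFINING_MARKERS = frozenset({"CD117", "cKit", "Sca1", "CD150", "CD41"})

ADT_CUTOFFS = {"restrictive": 10.0, "relaxed": 5.0}
ABUNDANCE_FLOORS = {"bulk": 50.0, "sc": 5.0}

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CAP = 20.0


def pseudobulk_aggregate(
    rna_counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
    group_keys: Sequence[str] = ("biosample", "condition"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum single-cell counts into one pseudobulk sample per group.

    Parameters
    ----------
    rna_counts
        Cells x genes count DataFrame (index = barcodes).
    cell_meta
        Per-cell metadata aligned on barcode, containing ``group_keys``.
    group_keys
        Metadata columns whose joint levels define the samples.

    Returns
    -------
    (counts, sample_meta)
        ``counts`` is genes x samples with integer sums; ``sample_meta``
        maps each sample id back to its group-key values.  Groups with no
        cells are dropped with a warning.
    """
    meta = cell_meta.loc[rna_counts.index, list(group_keys)]
    grouped = rna_counts.groupby([meta[k] for k in group_keys], observed=False).sum()
    empty = grouped.sum(axis=1) == 0
    n_cells = rna_counts.groupby([meta[k] for k in group_keys], observed=False).size()
    missing = n_cells[n_cells == 0]
    if len(missing) or empty.any():
        dropped = set(missing.index) | set(grouped.index[empty & (n_cells == 0)])
        if dropped:
            warnings.warn(f"dropping empty pseudobulk groups: {sorted(map(str, dropped))}")
    grouped = grouped[n_cells > 0]

    if isinstance(grouped.index, pd.MultiIndex):
        sample_ids = ["|".join(map(str, key)) for key in grouped.index]
        sample_meta = pd.DataFrame(
            list(grouped.index), columns=list(group_keys), index=sample_ids
        )
    else:
        sample_ids = [str(k) for k in grouped.index]
        sample_meta = pd.DataFrame({group_keys[0]: grouped.index}, index=sample_ids)
    counts = grouped.T
    counts.columns = sample_ids
    sample_meta["n_cells"] = n_cells[n_cells > 0].to_numpy()
    return counts, sample_meta


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column).

    The reference is the per-gene geometric mean across samples, computed
    over genes with no zero count in any sample; each sample's factor is
    the median ratio of its counts to that reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene is nonzero in all samples; cannot compute size factors")
    sub = x[all_positive]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _gene_dispersions(y: np.ndarray, groups: np.ndarray, inv_sf_mean: float) -> np.ndarray:
    """DoF-adjusted method-of-moments NB dispersion per gene.

    ``y`` is samples x genes on the normalized scale.  Residual variance is
    pooled within groups with ``m - 2`` degrees of freedom (the Cox-Reid
    style adjustment for the two fitted means), the Poisson component
    ``mean(1/s) * mu`` is subtracted, and the result is floored/capped.
    """
    m = y.shape[0]
    resid = np.empty_like(y)
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] = y[sel] - y[sel].mean(axis=0, keepdims=True)
    s2 = (resid**2).sum(axis=0) / max(m - 2, 1)
    mu = y.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - inv_sf_mean * mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    return np.clip(alpha, _DISPERSION_FLOOR, _DISPERSION_CAP)


def nb_wald_test(
    counts: pd.DataFrame,
    condition: Mapping[str, str] | pd.Series,
    *,
    reference: str | None = None,
    blocklist: Mapping[str, str] | pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-condition negative-binomial Wald differential expression.

    Parameters
    ----------
    counts
        Genes x samples integer count table (pseudobulk or bulk).
    condition
        Sample -> condition label; exactly two conditions, each with >= 2
        replicates.
    reference
        The baseline condition; ``log2FC`` is (other / reference).
        Defaults to the lexicographically first condition.
    blocklist
        Optional gene -> blocklist category, copied onto the output.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2FC``, ``pvalue``,
    ``padj``, ``baseMean``, ``baseMean_<reference>``, ``baseMean_<other>``,
    ``dispersion``, ``blocklist_category``.  All-zero genes get log2FC 0
    and missing p/padj; genes whose fit degenerates get missing padj.
    """
    cond = pd.Series(condition).loc[counts.columns]
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    if reference is None:
        reference = levels[0]
    other = [lv for lv in levels if lv != reference][0]
    if (cond == reference).sum() < 2 or (cond == other).sum() < 2:
        raise ValueError("need >= 2 replicates per condition")

    sf = size_factors(counts)
    K = counts.to_numpy(dtype=float).T  # samples x genes
    s = sf.to_numpy()
    y = K / s[:, None]
    design = (cond == other).to_numpy(dtype=float)  # 0 = reference, 1 = other
    m = K.shape[0]

    alpha = _gene_dispersions(y, design, float(np.mean(1.0 / s)))

    # IRLS for log mu = b0 + b1 * design + log s
    eps = 1e-8
    mean_ref = np.maximum(y[design == 0].mean(axis=0), eps)
    mean_oth = np.maximum(y[design == 1].mean(axis=0), eps)
    b0 = np.log(mean_ref)
    b1 = np.log(mean_oth) - b0
    log_s = np.log(s)[:, None]
    xcol = design[:, None]

    se_b1 = np.full(K.shape[1], np.nan)
    ok = np.ones(K.shape[1], dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + xcol * b1[None, :] + log_s
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[None, :] * mu)
        z = (eta - log_s) + (K - mu) / mu
        sw = w.sum(axis=0)
        swx = (w * xcol).sum(axis=0)
        swxx = swx  # design is 0/1 so x^2 == x
        swz = (w * z).sum(axis=0)
        swxz = (w * xcol * z).sum(axis=0)
        det = sw * swxx - swx**2
        good = det > 1e-12
        ok &= good
        det_safe = np.where(good, det, 1.0)
        nb0 = (swxx * swz - swx * swxz) / det_safe
        nb1 = (sw * swxz - swx * swz) / det_safe
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0 = np.where(good, nb0, b0)
        b1 = np.where(good, nb1, b1)
        se_b1 = np.where(good, np.sqrt(np.maximum(sw / det_safe, 0.0)), np.nan)
        if np.nanmax(np.where(good, delta, 0.0)) < tol:
            break

    all_zero = K.sum(axis=0) == 0
    log2fc = b1 / np.log(2.0)
    log2fc[all_zero] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = b1 / se_b1
    df_resid = max(m - 2, 1)
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=df_resid)
    pvalue[all_zero | ~ok | ~np.isfinite(wald)] = np.nan

    padj = np.full_like(pvalue, np.nan)
    valid = np.isfinite(pvalue)
    if valid.any():
        padj[valid] = multipletests(pvalue[valid], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "baseMean": y.mean(axis=0),
            f"baseMean_{reference}": y[design == 0].mean(axis=0),
            f"baseMean_{other}": y[design == 1].mean(axis=0),
            "dispersion": alpha,
        },
        index=counts.index,
    )
    out.attrs["reference"] = reference
    out.attrs["other"] = other
    if blocklist is not None:
        out["blocklist_category"] = pd.Series(blocklist).reindex(counts.index).fillna("none")
    else:
        out["blocklist_category"] = "none"
    return out


def compute_base_mean(
    counts: pd.DataFrame,
    members: Iterable[str],
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene mean of size-factor-normalized counts within a condition.

    ``members`` are the sample columns belonging to the condition; unknown
    members raise.  ``factors`` defaults to median-of-ratios size factors
    computed on the full table.
    """
    members = list(members)
    if not members:
        raise ValueError("condition has no members")
    unknown = [c for c in members if c not in counts.columns]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    if factors is None:
        factors = size_factors(counts)
    normalized = counts[members] / factors.loc[members]
    return normalized.mean(axis=1).rename("baseMean")


def filter_degs(
    records: pd.DataFrame,
    mode: str,
    data_kind: str,
    *,
    base_mean_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Apply the candidate-marker DEG filters.

    Removes blocklisted genes (mito/ribo/Malat1), genes with no adjusted
    p value, and genes whose per-condition baseMean is at or below the
    abundance floor in BOTH conditions (50 for ``data_kind='bulk'``, 5 for
    ``'sc'``), then keeps genes passing the threshold rule:

    - ``mode='strict'``:  |log2FC| >= 2.5  AND  padj < 0.01
    - ``mode='relaxed'``: |log2FC| >= 1.5  OR   padj < 0.1
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode: {mode!r}")
    if data_kind not in ABUNDANCE_FLOORS:
        raise ValueError(f"unknown data_kind: {data_kind!r}")
    floor = ABUNDANCE_FLOORS[data_kind]

    df = records.copy()
    if "blocklist_category" in df.columns:
        df = df[df["blocklist_category"].fillna("none") == "none"]
    df = df[df["padj"].notna()]

    if base_mean_columns is None:
        base_mean_columns = [
            c for c in df.columns if c.startswith("baseMean_")
        ]
    if len(base_mean_columns) == 2:
        bm = df[list(base_mean_columns)]
        df = df[~(bm <= floor).all(axis=1)]
    elif base_mean_columns:
        raise ValueError("expected exactly two per-condition baseMean columns")

    absfc = df["log2FC"].abs()
    if mode == "strict":
        keep = (absfc >= 2.5) & (df["padj"] < 0.01)
    else:
        keep = (absfc >= 1.5) | (df["padj"] < 0.1)
    return df[keep]


@dataclass(frozen=True)
class ADTScore:
    """Signed standardized group-difference statistic for one ADT."""

    name: str
    score: float
    method: str
    excluded: bool = False


def _wilcoxon_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected normal-approximation rank-sum z (positive when A > B)."""
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = ranks[:n1].sum()
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValueError("zero rank variance (all values tied); score undefined")
    return float((r_a - expected) / np.sqrt(var))


def _ttest_overestim_var(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample t with both group variances divided by the first group's
    size (deliberately overestimating the second group's standard error)."""
    n1 = a.size
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    denom = np.sqrt(va / n1 + vb / n1)
    if denom == 0:
        raise ValueError("zero combined variance; score undefined")
    return float((a.mean() - b.mean()) / denom)


def adt_score(group_a, group_b, method: str = "wilcoxon", name: str = "") -> ADTScore:
    """Score one ADT's difference between two cell groups.

    ``method`` is ``'wilcoxon'`` (tie-corrected standardized rank-sum,
    positive when group A's values are larger) or ``'ttest_overestim_var'``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if method == "wilcoxon":
        score = _wilcoxon_z(a, b)
    elif method == "ttest_overestim_var":
        score = _ttest_overestim_var(a, b)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return ADTScore(name=name, score=score, method=method)


def score_adt_table(
    adt_values: pd.DataFrame,
    group_labels: pd.Series,
    group_a: str,
    group_b: str,
    method: str = "wilcoxon",
    exclusions: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Score every ADT column between two labeled cell groups.

    Returns a DataFrame indexed by ADT name with ``score``, ``method`` and
    ``excluded`` (lineage / MkP-defining markers are flagged but still
    scored, mirroring how they are shown-but-not-selected).
    """
    if exclusions is None:
        exclusions = LINEAGE_MARKERS | MKP_DEFINING_MARKERS
    labels = group_labels.loc[adt_values.index]
    a_idx = labels == group_a
    b_idx = labels == group_b
    rows = []
    for marker in adt_values.columns:
        rec = adt_score(
            adt_values.loc[a_idx, marker],
            adt_values.loc[b_idx, marker],
            method=method,
            name=marker,
        )
        rows.append(
            {
                "score": rec.score,
                "method": rec.method,
                "excluded": marker in exclusions,
            }
        )
    return pd.DataFrame(rows, index=list(adt_values.columns))


def select_adt_candidates(
    scores: pd.DataFrame,
    cutoff: str | float = "restrictive",
    exclusions: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Keep ADTs with |score| at or above the cutoff, minus excluded markers.

    ``cutoff`` is ``'restrictive'`` (10), ``'relaxed'`` (5) or a number.
    The returned table adds ``direction``: ``'A'`` when the score is
    positive (enriched in the first group), else ``'B'``.
    """
    if isinstance(cutoff, str):
        if cutoff not in ADT_CUTOFFS:
            raise ValueError(f"unknown cutoff: {cutoff!r}")
        cutoff = ADT_CUTOFFS[cutoff]
    df = scores.copy()
    if exclusions is not None:
        df["excluded"] = df.get("excluded", False) | df.index.isin(list(exclusions))
    elif "excluded" not in df.columns:
        df["excluded"] = False
    kept = df[(~df["excluded"]) & (df["score"].abs() >= float(cutoff))].copy()
    kept["direction"] = np.where(kept["score"] > 0, "A", "B")
    return kept
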