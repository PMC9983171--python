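"""Enhancer-to-gene linkage and coupling statistics.

Peaks are assigned to the gene with the nearest TSS on the same chromosome
(ties: lower TSS coordinate, then lexicographic gene id).  On top of the
linkage table live the coupling analyses: per-category paired Wilcoxon tests of
nearby-gene expression, a Monte-Carlo permutation control against random gene
sets, a per-gene enhancer-burden regression, the %-enhancer-loss binning, and
the gene-centric view of enhancer acetylation fold changes.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval
from .diffquant import bh_adjust

__all__ = [
    "nearest_tss",
    "distance_filter",
    "category_expression_test",
    "permutation_control_test",
    "enhancer_burden_fit",
    "enhancer_loss_binning",
    "gene_centric_acetylation_fc",
]


def nearest_tss(
    peaks: list[GenomicInterval], genes: list[GeneModel]
) -> pd.DataFrame:
    """Link every peak to the gene whose TSS is nearest its midpoint.

    Returns a DataFrame indexed like ``peaks`` (positional, or by peak name
    when all peaks are named) with columns ``gene_id`` and ``distance``
    (signed, midpoint minus TSS).  Ties break to the lower TSS coordinate,
    then the lexicographically smaller gene id.  Peaks on chromosomes without
    any gene are dropped with a warning.
    """
    if not genes:
        raise ValueError("empty gene list")
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for c in per_chrom:
        per_chrom[c].sort()  # by TSS then gene_id: the tie-break order
        # genes sharing a TSS can only resolve to the first id; drop the rest
        per_chrom[c] = [
            item
            for i, item in enumerate(per_chrom[c])
            if i == 0 or item[0] != per_chrom[c][i - 1][0]
        ]

    rows = []
    dropped = 0
    named = all(p.name is not None for p in peaks) and len(
        {p.name for p in peaks}
    ) == len(peaks)
    for i, iv in enumerate(peaks):
        cand = per_chrom.get(iv.chrom)
        if not cand:
            dropped += 1
            continue
        mid = iv.midpoint
        tss_arr = np.array([t for t, _ in cand])
        j = int(np.searchsorted(tss_arr, mid))
        best = None
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(cand):
                d = abs(mid - cand[k][0])
                key = (d, cand[k][0], cand[k][1])
                if best is None or key < best[0]:
                    best = (key, k)
        tss, gid = cand[best[1]]
        rows.append(
            {
                "peak": iv.name if named else i,
                "gene_id": gid,
                "distance": mid - tss,
            }
        )
    if dropped:
        warnings.warn(f"{dropped} peak(s) on chromosomes without genes were dropped")
    if not rows:
        return pd.DataFrame(columns=["gene_id", "distance"]).rename_axis("peak")
    return pd.DataFrame(rows).set_index("peak")


def distance_filter(linkage: pd.DataFrame, max_bp: int = 10_000) -> pd.DataFrame:
    """Keep links with |distance| <= ``max_bp``."""
    return linkage[linkage["distance"].abs() <= max_bp]


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank; exact null for n <= 25 (no ties/zeros),
    normal approximation with continuity correction above."""
    d = x - y
    if np.allclose(d, 0):
        return 0.0, 1.0
    n = np.count_nonzero(d)
    method = "exact" if n <= 25 and not _has_tied_magnitudes(d) else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided", method=method,
        correction=(method == "approx"),
    )
    return float(res.statistic), float(res.pvalue)


def _has_tied_magnitudes(d: np.ndarray) -> bool:
    mags = np.abs(d[d != 0])
    return np.unique(mags).size < mags.size


def category_expression_test(
    linkage: pd.DataFrame,
    expression: pd.DataFrame,
    categories: pd.Series,
    comparisons: list[tuple[str, str]],
    min_genes: int = 5,
    paired: bool = True,
) -> pd.DataFrame:
    """Test nearby-gene expression between sample classes, per peak category.

    ``expression`` is genes x sample-class Log2CPM (class names are columns);
    ``categories`` labels each peak in ``linkage``.  For each (category,
    comparison) the genes linked by peaks of that category are deduplicated and
    tested with a paired Wilcoxon signed-rank (``paired=False`` switches to the
    unpaired rank-sum).  BH correction spans the whole family of tests.
    Categories mapping to fewer than ``min_genes`` genes are skipped with a
    warning.
    """
    rows = []
    for cat in pd.unique(categories):
        peak_ids = categories.index[categories == cat]
        genes = (
            linkage.loc[linkage.index.intersection(peak_ids), "gene_id"]
            .drop_duplicates()
            .tolist()
        )
        genes = [g for g in genes if g in expression.index]
        if len(genes) < min_genes:
            warnings.warn(f"category {cat!r}: only {len(genes)} genes, skipped")
            continue
        sub = expression.loc[genes]
        for a, b in comparisons:
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if paired:
                stat, p = _paired_wilcoxon(y, x)
            else:
                res = stats.mannwhitneyu(y, x, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "category": cat,
                    "comparison": f"{b}-vs-{a}",
                    "n_genes": len(genes),
                    "statistic": stat,
                    "pvalue": p,
                    "median_diff": float(np.median(y - x)),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def permutation_control_test(
    state_gene_values: np.ndarray,
    all_gene_values: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo permutation p-value of a gene set against an all-genes control.

    The observed Mann-Whitney U of the state set against all genes is compared
    with the U of random same-size draws (without replacement) from all genes:
    the two-sided empirical p is the fraction of draws whose deviation of U
    from its null mean is at least as extreme as the observed deviation.  All
    ``C(n, k)`` draws are enumerated when there are no more than ``n_perm`` of
    them, making the toy-size case exact.
    """
    state = np.asarray(state_gene_values, dtype=float)
    allv = np.asarray(all_gene_values, dtype=float)
    if state.size < 2:
        raise ValueError("state set must contain at least 2 genes")
    if state.size < 3:
        warnings.warn("state set smaller than 3 genes; p-value is very coarse")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value resolution")
    # membership check on values: every state value must be available in allv
    pool = list(allv)
    for v in state:
        try:
            pool.remove(v)
        except ValueError:
            raise ValueError("state set values are not a subset of all-gene values")

    def u_stat(x: np.ndarray) -> float:
        return float(
            stats.mannwhitneyu(x, allv, alternative="two-sided").statistic
        )

    mu = state.size * allv.size / 2.0
    obs_dev = abs(u_stat(state) - mu)

    k, n = state.size, allv.size
    if math.comb(n, k) <= n_perm:
        draws = [allv[list(c)] for c in combinations(range(n), k)]
    else:
        rng = np.random.default_rng(seed)
        draws = [rng.choice(allv, size=k, replace=False) for _ in range(n_perm)]
    devs = np.array([abs(u_stat(np.asarray(d)) - mu) for d in draws])
    return float(np.mean(devs >= obs_dev - 1e-12))


def enhancer_burden_fit(
    dependent_enhancer_count: np.ndarray,
    gene_log2fc: np.ndarray,
) -> dict:
    """OLS fit of gene log2FC (DKO/WT) on the number of MLL3/4-dependent
    enhancers linked to the gene; returns slope, 95% CI and p-value."""
    import statsmodels.api as sm

    x = np.asarray(dependent_enhancer_count, dtype=float)
    y = np.asarray(gene_log2fc, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two genes")
    if np.var(x) == 0:
        raise ValueError("enhancer counts have zero variance; slope is undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = fit.conf_int()[1]
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "pvalue": float(fit.pvalues[1]),
        "n": int(x.size),
    }


_LOSS_BINS = [
    ("0", lambda p: p == 0),
    ("(0,25]", lambda p: 0 < p <= 25),
    ("(25,50]", lambda p: 25 < p <= 50),
    ("(50,75]", lambda p: 50 < p <= 75),
    ("(75,100]", lambda p: 75 < p <= 100),
]


def enhancer_loss_binning(
    pct_dependent: np.ndarray,
    gene_log2fc: np.ndarray,
) -> pd.DataFrame:
    """Bin genes by the percentage of their enhancers that are MLL3/4-dependent
    and summarise the expression fold change per bin.

    Bins: {0, (0,25], (25,50], (50,75], (75,100]}%.  Each non-zero bin is
    compared with the 0% bin by a two-sided rank-sum test, BH-corrected.
    """
    pct = np.asarray(pct_dependent, dtype=float)
    y = np.asarray(gene_log2fc, dtype=float)
    rows = []
    ref = y[pct == 0]
    pvals = []
    for name, member in _LOSS_BINS:
        sel = np.array([member(p) for p in pct])
        vals = y[sel]
        row = {
            "bin": name,
            "n": int(sel.sum()),
            "median": float(np.median(vals)) if sel.any() else np.nan,
            "q1": float(np.quantile(vals, 0.25)) if sel.any() else np.nan,
            "q3": float(np.quantile(vals, 0.75)) if sel.any() else np.nan,
        }
        if name == "0" or not sel.any() or ref.size == 0:
            row["pvalue"] = np.nan
        else:
            row["pvalue"] = float(
                stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue
            )
            pvals.append(row["pvalue"])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("bin")
    tested = out["pvalue"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out


def gene_centric_acetylation_fc(
    gene_classes: pd.DataFrame,
    linkage: pd.DataFrame,
    k27_log2fc: pd.Series,
    transition: str = "formative",
) -> dict:
    """Enhancer H3K27ac fold-change distributions for dependent vs independent
    gene classes.

    ``gene_classes`` comes from :func:`enhdyn.classify.classify_genes`;
    ``linkage`` maps peaks (the H3K4me1+/H3K27ac+ enhancer set) to genes;
    ``k27_log2fc`` is the per-peak H3K27ac log2 fold change to compare (e.g.,
    formative/naive in DKO).  Returns the two distributions, their medians and
    a rank-sum p-value; a class with no linked enhancers is skipped with a
    warning.
    """
    out: dict = {"transition": transition}
    dists = {}
    for dep in ("dependent", "independent"):
        gene_set = set(
            gene_classes.index[
                (gene_classes["transition"] == transition)
                & (gene_classes["mll34"] == dep)
            ]
        )
        peak_ids = linkage.index[linkage["gene_id"].isin(gene_set)]
        vals = k27_log2fc.reindex(peak_ids).dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"gene class {dep!r}: no linked enhancers, skipped")
            continue
        dists[dep] = vals
        out[f"{dep}_median"] = float(np.median(vals))
        out[f"{dep}_n"] = int(vals.size)
    out["distributions"] = dists
    if len(dists) == 2:
        out["pvalue"] = float(
            stats.mannwhitneyu(
                dists["dependent"], dists["independent"], alternative="two-sided"
            ).pvalue
        )
    return out
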