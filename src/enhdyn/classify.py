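"""Peak and gene category logic.

Peaks are labelled along independent axes:

- *dynamics* (WT formative vs naive): ``formative`` / ``naive`` for peaks that
  significantly gain / lose the mark during the transition, ``shared`` for
  peaks confidently unchanged, ``unclassified`` in between;
- *dependency* on MLL3/4 (DKO vs WT): ``dependent`` if the mark drops more
  than 2-fold in either state, ``independent`` if it drops less than ~1.6-fold
  in both, ``intermediate`` otherwise;
- *feature class*: ``Promoter`` (midpoint within a window of a TSS),
  ``Distal`` (intergenic or intronic) or ``Other``;
- *joint* behaviour of a co-located second mark: gain / lose / maintain /
  never.

Genes get the analogous transition labels plus an MLL3/4-dependency call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval

__all__ = [
    "Thresholds",
    "categorize_dynamics",
    "categorize_dependency",
    "annotate_features",
    "overlap_filter",
    "joint_mark_categories",
    "classify_genes",
]


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs.

    Dynamic peaks: FDR < ``fdr_dyn`` and |log2FC| > ``lfc_dyn``; shared peaks:
    FDR > ``fdr_shared`` and |log2FC| < ``lfc_shared``.  Dependency: DKO/WT
    log2FC below ``dep_lfc`` in either state is dependent, above ``indep_lfc``
    in both states is independent.
    """

    fdr_dyn: float = 0.05
    lfc_dyn: float = 1.0
    fdr_shared: float = 0.1
    lfc_shared: float = 0.7
    dep_lfc: float = -1.0
    indep_lfc: float = -0.7
    overlap_frac: float = 0.75
    promoter_window_bp: int = 1000

    def __post_init__(self) -> None:
        if not self.dep_lfc < self.indep_lfc <= 0:
            raise ValueError("require dep_lfc < indep_lfc <= 0")
        if not 0 < self.overlap_frac <= 1:
            raise ValueError("overlap_frac must be in (0, 1]")


def categorize_dynamics(
    diff: pd.DataFrame, t: Thresholds = Thresholds()
) -> pd.Series:
    """Dynamics labels from a WT formative-vs-naive differential result."""
    fdr = diff["fdr"].to_numpy()
    lfc = diff["log2fc"].to_numpy()
    labels = np.full(len(diff), "unclassified", dtype=object)
    labels[(fdr < t.fdr_dyn) & (lfc > t.lfc_dyn)] = "formative"
    labels[(fdr < t.fdr_dyn) & (lfc < -t.lfc_dyn)] = "naive"
    labels[(fdr > t.fdr_shared) & (np.abs(lfc) < t.lfc_shared)] = "shared"
    return pd.Series(labels, index=diff.index, name="dynamics")


def categorize_dependency(
    lfc_naive_dko_wt: np.ndarray | pd.Series,
    lfc_form_dko_wt: np.ndarray | pd.Series,
    t: Thresholds = Thresholds(),
) -> pd.Series | np.ndarray:
    """MLL3/4-dependency from DKO/WT log2 fold changes in each state.

    ``dependent`` if either state's log2FC < ``dep_lfc``; ``independent`` if
    both are > ``indep_lfc``; ``intermediate`` otherwise.
    """
    ln = np.asarray(lfc_naive_dko_wt, dtype=float)
    lf = np.asarray(lfc_form_dko_wt, dtype=float)
    labels = np.full(ln.shape, "intermediate", dtype=object)
    labels[(ln > t.indep_lfc) & (lf > t.indep_lfc)] = "independent"
    labels[(ln < t.dep_lfc) | (lf < t.dep_lfc)] = "dependent"
    if isinstance(lfc_naive_dko_wt, pd.Series):
        return pd.Series(labels, index=lfc_naive_dko_wt.index, name="dependency")
    return labels


def annotate_features(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    t: Thresholds = Thresholds(),
    exons: list[GenomicInterval] | None = None,
) -> pd.Series:
    """Feature class per peak: Promoter / Distal / Other.

    A peak is Promoter when its midpoint lies within ``promoter_window_bp`` of
    any TSS.  Otherwise, with full gene structure (``exons`` given) a midpoint
    in an exon is Other and everything else (intergenic or intronic) Distal;
    with BED6-only genes the fallback is: inside a gene body -> Other, outside
    all gene bodies -> Distal.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    bodies_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        bodies_by_chrom.setdefault(g.chrom, []).append(
            (g.interval.start, g.interval.end)
        )
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if exons is not None:
        for iv in exons:
            exon_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def in_any(pos: int, spans: list[tuple[int, int]]) -> bool:
        return any(s <= pos < e for s, e in spans)

    labels = []
    for iv in peaks:
        mid = iv.midpoint
        tss = tss_by_chrom.get(iv.chrom)
        if tss is not None and tss.size:
            j = np.searchsorted(tss, mid)
            near = min(
                abs(mid - int(tss[k])) for k in (j - 1, j) if 0 <= k < tss.size
            )
            if near <= t.promoter_window_bp:
                labels.append("Promoter")
                continue
        if exons is not None:
            labels.append("Other" if in_any(mid, exon_by_chrom.get(iv.chrom, [])) else "Distal")
        else:
            labels.append(
                "Other" if in_any(mid, bodies_by_chrom.get(iv.chrom, [])) else "Distal"
            )
    return pd.Series(labels, name="feature")


def _overlap_pairs(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """All (i, j, overlap_bp) pairs with positive overlap, via a sweep."""
    out = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for c in by_chrom:
        by_chrom[c].sort()
    for i, iv in enumerate(a):
        cand = by_chrom.get(iv.chrom, [])
        starts = np.array([x[0] for x in cand])
        ends = np.array([x[1] for x in cand])
        if not starts.size:
            continue
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        for k in range(lo, hi):
            ov = min(iv.end, cand[k][1]) - max(iv.start, cand[k][0])
            if ov > 0:
                out.append((i, cand[k][2], ov))
    return out


def overlap_filter(
    peaks_a: list[GenomicInterval],
    peaks_b: list[GenomicInterval],
    frac: float = 0.75,
    measure_on: str = "B",
) -> list[GenomicInterval]:
    """Subset of A overlapping B by at least ``frac`` of the B peak's width.

    ``measure_on='A'`` measures the fraction on the A peak instead (sensitivity
    analysis).
    """
    keep = set()
    for i, j, ov in _overlap_pairs(peaks_a, peaks_b):
        denom = peaks_b[j].width if measure_on == "B" else peaks_a[i].width
        if ov >= frac * denom:
            keep.add(i)
    return [iv for i, iv in enumerate(peaks_a) if i in keep]


def joint_mark_categories(
    k4_peaks: list[GenomicInterval],
    k27_peaks: list[GenomicInterval],
    k27_dynamics: pd.Series | list[str],
) -> pd.Series:
    """Per-H3K4me1-peak label of co-located H3K27ac behaviour.

    Any-overlap (>=1 bp) association; when a K4 peak overlaps several K27
    peaks, the largest overlap wins.  The overlapping K27 peak's dynamics map
    formative -> ``gain``, naive -> ``lose``, shared or unclassified ->
    ``maintain``; no overlapping K27 peak -> ``never``.
    """
    dyn = list(k27_dynamics)
    best: dict[int, tuple[int, int]] = {}
    for i, j, ov in _overlap_pairs(k4_peaks, k27_peaks):
        if i not in best or ov > best[i][1]:
            best[i] = (j, ov)
    mapping = {"formative": "gain", "naive": "lose", "shared": "maintain",
               "unclassified": "maintain"}
    labels = []
    for i in range(len(k4_peaks)):
        if i in best:
            labels.append(mapping[dyn[best[i][0]]])
        else:
            labels.append("never")
    return pd.Series(labels, name="joint")


def classify_genes(
    wt_dge: pd.DataFrame,
    dko_naive_dge: pd.DataFrame,
    dko_form_dge: pd.DataFrame,
    naive_log2cpm_fc: pd.Series,
    t: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Transition classes and MLL3/4-dependency per gene.

    ``transition``: formative (WT formative/naive padj < fdr_dyn, log2FC >
    lfc_dyn), naive (log2FC < -lfc_dyn) or none.  A formative gene is MLL3/4
    ``dependent`` when DKO-vs-WT formative is significantly down *and* the gene
    has no pre-existing naive defect (naive Log2CPM DKO/WT > ``dep_lfc``);
    naive genes use the mirrored rule on the naive-state comparison.
    """
    genes = wt_dge.index
    res = pd.DataFrame(index=genes)
    sig = wt_dge["fdr"] < t.fdr_dyn
    res["transition"] = "none"
    res.loc[sig & (wt_dge["log2fc"] > t.lfc_dyn), "transition"] = "formative"
    res.loc[sig & (wt_dge["log2fc"] < -t.lfc_dyn), "transition"] = "naive"

    dko_form = dko_form_dge.reindex(genes)
    dko_naive = dko_naive_dge.reindex(genes)
    form_down = (dko_form["fdr"] < t.fdr_dyn) & (dko_form["log2fc"] < 0)
    naive_down = (dko_naive["fdr"] < t.fdr_dyn) & (dko_naive["log2fc"] < 0)
    no_naive_defect = naive_log2cpm_fc.reindex(genes) > t.dep_lfc

    res["mll34"] = "independent"
    res.loc[
        (res["transition"] == "formative") & form_down & no_naive_defect, "mll34"
    ] = "dependent"
    res.loc[(res["transition"] == "naive") & naive_down, "mll34"] = "dependent"
    res.loc[res["transition"] == "none", "mll34"] = "not_applicable"
    return res
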