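"""End-to-end orchestration of the enhancer analysis stages.

These helpers wire the library modules into the standard flow
``simulate -> callpeaks -> diff -> classify -> link -> states -> report`` and
are what the command-line interface and the acceptance analyses run.  Each
function is a thin composition of the module APIs; no statistics live here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import chromstates as cs
from . import classify as cl
from . import diffquant as dq
from . import linkage as lk
from . import synthetic as syn
from .core_io import GeneModel, GenomicInterval, SignalTrack
from .peakcall import PeakSet, call_peaks

__all__ = [
    "mark_category_table",
    "expression_log2cpm",
    "gene_dge",
    "evaluate_peak_calls",
    "decoupling_analysis",
    "track_bin_counts",
    "segment_condition",
    "run_end_to_end",
]


def mark_category_table(
    counts: "dq.CountMatrix",
    thresholds: cl.Thresholds = cl.Thresholds(),
    method: str = "nb_wald",
    seed: int = 0,
) -> pd.DataFrame:
    """Dynamics and dependency labels for one mark's count matrix.

    Runs three differential tests (WT formative vs naive; DKO vs WT within
    each state), each TMM-normalized within its contrast, and applies the
    category cutoffs.
    """
    groups = {
        (g, c): counts.samples_where(genotype=g, condition=c)
        for g in syn.GENOTYPES
        for c in syn.CONDITIONS
    }
    d_wt = dq.differential_test(
        counts, groups[("WT", "naive")], groups[("WT", "formative")],
        method=method, seed=seed,
    )
    d_naive = dq.differential_test(
        counts, groups[("WT", "naive")], groups[("DKO", "naive")],
        method=method, seed=seed,
    )
    d_form = dq.differential_test(
        counts, groups[("WT", "formative")], groups[("DKO", "formative")],
        method=method, seed=seed,
    )
    table = pd.DataFrame(
        {
            "log2fc_wt": d_wt["log2fc"],
            "fdr_wt": d_wt["fdr"],
            "lfc_naive_dko_wt": d_naive["log2fc"],
            "lfc_form_dko_wt": d_form["log2fc"],
            "fdr_naive_dko_wt": d_naive["fdr"],
            "fdr_form_dko_wt": d_form["fdr"],
        }
    )
    table["dynamics"] = cl.categorize_dynamics(d_wt, thresholds)
    table["dependency"] = cl.categorize_dependency(
        table["lfc_naive_dko_wt"], table["lfc_form_dko_wt"], thresholds
    )
    return table


def expression_log2cpm(expr: "dq.CountMatrix") -> pd.DataFrame:
    """Per-gene Log2CPM averaged over replicates of each genotype x condition
    class (TMM-normalized; columns like ``WT_naive``)."""
    tmm = dq.tmm_factors(expr)
    eff_lib = expr.lib_size * tmm
    log2cpm = np.log2(expr.counts.div(eff_lib, axis=1) * 1e6 + 1.0)
    cols = {}
    for g in syn.GENOTYPES:
        for c in syn.CONDITIONS:
            samples = expr.samples_where(genotype=g, condition=c)
            cols[f"{g}_{c}"] = log2cpm[samples].mean(axis=1)
    return pd.DataFrame(cols)


def gene_dge(
    expr: "dq.CountMatrix",
    thresholds: cl.Thresholds = cl.Thresholds(),
    method: str = "nb_wald",
    seed: int = 0,
) -> dict:
    """WT transition and DKO-vs-WT DGE plus gene classes.

    Genes are first filtered to CPM > 1 in at least two samples; library sizes
    stay fixed at their pre-filter values.
    """
    expr = dq.cpm_filter(expr)
    groups = {
        (g, c): expr.samples_where(genotype=g, condition=c)
        for g in syn.GENOTYPES
        for c in syn.CONDITIONS
    }
    wt = dq.differential_test(
        expr, groups[("WT", "naive")], groups[("WT", "formative")],
        method=method, seed=seed,
    )
    dko_naive = dq.differential_test(
        expr, groups[("WT", "naive")], groups[("DKO", "naive")],
        method=method, seed=seed,
    )
    dko_form = dq.differential_test(
        expr, groups[("WT", "formative")], groups[("DKO", "formative")],
        method=method, seed=seed,
    )
    lc = expression_log2cpm(expr)
    naive_fc = lc["DKO_naive"] - lc["WT_naive"]
    classes = cl.classify_genes(wt, dko_naive, dko_form, naive_fc, thresholds)
    return {
        "wt": wt,
        "dko_naive": dko_naive,
        "dko_form": dko_form,
        "log2cpm": lc,
        "classes": classes,
    }


def evaluate_peak_calls(
    called: PeakSet,
    truth: pd.DataFrame,
    mark: str,
    genotype: str,
    condition: str,
    config: syn.SimConfig,
) -> dict:
    """Recall over fully-marked planted enhancers and precision over called
    peaks (a call is correct when it overlaps any enhancer carrying signal in
    that sample class)."""
    full, any_signal = [], []
    for _, row in truth.iterrows():
        e = syn.planted_log2_enrichment(row, mark, genotype, condition, config)
        iv = GenomicInterval(row["chrom"], row["start"], row["end"])
        if e >= config.base_log2_enrichment:
            full.append(iv)
        if e > 0:
            any_signal.append(iv)
    called_ivs = called.intervals()
    hit = set()
    for i, _, _ in cl._overlap_pairs(full, called_ivs):
        hit.add(i)
    recall = len(hit) / len(full) if full else float("nan")
    tp = {j for _, j, _ in cl._overlap_pairs(any_signal, called_ivs)}
    precision = len(tp) / len(called_ivs) if called_ivs else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_called": len(called_ivs),
        "n_true_full": len(full),
    }


def decoupling_analysis(
    truth: pd.DataFrame,
    genes: list[GeneModel],
    k27_counts: "dq.CountMatrix",
    expr: "dq.CountMatrix",
    thresholds: cl.Thresholds = cl.Thresholds(),
    seed: int = 0,
) -> dict:
    """Chromatin-vs-transcription coupling at dependent formative enhancers.

    Chromatin side: paired Wilcoxon on per-enhancer H3K27ac Log2CPM (WT vs DKO,
    formative state) over the planted dependent formative enhancer set.
    Expression side: the category expression test of nearby genes (DKO vs WT
    formative Log2CPM).  Returns both BH-corrected p-values.
    """
    sel = (
        (truth["dynamics"] == "formative")
        & (truth["dep_H3K27ac"] == "dependent")
        & truth["has_H3K27ac"]
    )
    dep_ids = truth.index[sel]
    # chromatin: per-peak H3K27ac log2cpm, WT vs DKO formative
    tmm = dq.tmm_factors(k27_counts)
    eff_lib = k27_counts.lib_size * tmm
    log2cpm = np.log2(k27_counts.counts.div(eff_lib, axis=1) * 1e6 + 1.0)
    wt_f = log2cpm[k27_counts.samples_where(genotype="WT", condition="formative")].mean(axis=1)
    dko_f = log2cpm[k27_counts.samples_where(genotype="DKO", condition="formative")].mean(axis=1)
    stat, chrom_p = lk._paired_wilcoxon(
        dko_f.loc[dep_ids].to_numpy(), wt_f.loc[dep_ids].to_numpy()
    )
    # expression: genes near those peaks
    peaks = [
        GenomicInterval(row["chrom"], row["start"], row["end"], name=eid)
        for eid, row in truth.iterrows()
    ]
    link = lk.nearest_tss(peaks, genes)
    categories = pd.Series("other", index=truth.index, name="category")
    categories.loc[dep_ids] = "dependent_formative"
    expr_classes = expression_log2cpm(expr)
    tests = lk.category_expression_test(
        link,
        expr_classes,
        categories,
        comparisons=[("WT_formative", "DKO_formative")],
    )
    row = tests[tests["category"] == "dependent_formative"].iloc[0]
    return {
        "chromatin_pvalue": chrom_p,
        "chromatin_median_lfc": float((dko_f - wt_f).loc[dep_ids].median()),
        "expression_pvalue": float(row["fdr"]),
        "expression_median_diff": float(row["median_diff"]),
        "n_enhancers": int(sel.sum()),
        "n_genes": int(row["n_genes"]),
    }


# -- chromatin states over synthetic tracks --------------------------------

def track_bin_counts(
    track: SignalTrack, bin_size: int, extents: dict[str, int]
) -> dict[str, np.ndarray]:
    """Reconstruct integer per-bin fragment counts from a CPM-scaled track.

    The smallest positive record value is the single-fragment coverage level;
    together with that record's width it gives the per-fragment area quantum,
    and bin integrals divided by it recover counts.  Assumes the track was
    laid down in uniform-width records (as the simulator writes them).
    """
    quantum = None
    for _, s, e, v in track.iter_records():
        if quantum is None or v < quantum[0]:
            quantum = (v, (e - s) * v)
    sums = track.bin_sums(bin_size, extents)
    if quantum is None:
        return {c: np.zeros_like(a, dtype=np.int64) for c, a in sums.items()}
    return {c: np.rint(a / quantum[1]).astype(np.int64) for c, a in sums.items()}


def segment_condition(
    tracks: dict[tuple[str, str, str], SignalTrack],
    condition: str,
    config: syn.SimConfig,
    bin_size: int = 1000,
    pcut: float = 1e-4,
    hmm: bool = False,
    seed: int = 0,
) -> tuple[cs.BinarizedMatrix, cs.StateSegmentation]:
    """Binarize the four mark/genotype tracks of one condition and segment.

    Track order (MSB first): H3K4me1 WT, H3K4me1 DKO, H3K27ac WT, H3K27ac DKO.
    The Poisson background rate is estimated from the matched IgG control.
    """
    extents = {c: config.chrom_length for c in config.chrom_names}
    order = [
        ("H3K4me1", "WT"), ("H3K4me1", "DKO"), ("H3K27ac", "WT"), ("H3K27ac", "DKO"),
    ]
    binarized: dict[str, list[np.ndarray]] = {c: [] for c in config.chrom_names}
    for mark, genotype in order:
        counts = track_bin_counts(tracks[(mark, genotype, condition)], bin_size, extents)
        igg = track_bin_counts(tracks[("IgG", genotype, condition)], bin_size, extents)
        lam = float(np.mean(np.concatenate([igg[c] for c in config.chrom_names])))
        for c in config.chrom_names:
            binarized[c].append(cs.binarize(counts[c], lam=lam, pcut=pcut))
    b = cs.BinarizedMatrix(
        {c: np.column_stack(v) for c, v in binarized.items()},
        track_names=[f"{m}_{g}" for m, g in order],
        bin_size=bin_size,
    )
    if hmm:
        params, _ = cs.hmm_fit(b, n_states=16, seed=seed)
        seg = cs.hmm_decode(b, params, mode="posterior")
    else:
        seg = cs.combinatorial_states(b)
    return b, seg


# -- full pipeline ---------------------------------------------------------

def run_end_to_end(
    config: syn.SimConfig,
    outdir: str | Path,
    method: str = "nb_wald",
    make_plots: bool = True,
) -> dict:
    """Simulate a dataset and run every stage, writing report tables.

    Returns a summary dict with the per-stage results; writes TSVs (and small
    SVG figures) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = cl.Thresholds()
    data = syn.write_dataset(config, outdir / "data")
    truth, genes, tracks = data["truth"], data["genes"], data["tracks"]

    # peak calling against matched IgG
    peak_eval = {}
    peaksets = {}
    for mark in syn.MARKS:
        for genotype, condition in (("WT", "naive"), ("WT", "formative")):
            ps = call_peaks(
                tracks[(mark, genotype, condition)],
                control=tracks[("IgG", genotype, condition)],
                alpha=0.05,
                sample_id=f"{mark}_{genotype}_{condition}",
            )
            peaksets[(mark, genotype, condition)] = ps
            peak_eval[f"{mark}_{genotype}_{condition}"] = evaluate_peak_calls(
                ps, truth, mark, genotype, condition, config
            )
    union = {
        mark: dq.union_peaks(
            [peaksets[(mark, "WT", c)] for c in syn.CONDITIONS]
        )
        for mark in syn.MARKS
    }

    # differential + classification per mark on the replicate count matrices
    tables = {}
    for mark in syn.MARKS:
        tables[mark] = mark_category_table(
            data["counts"][mark], thresholds, method=method
        )
        tables[mark].to_csv(outdir / f"categories_{mark}.tsv", sep="\t")

    # feature annotation and joint-mark categories on the planted peak set
    peaks = [
        GenomicInterval(row["chrom"], row["start"], row["end"], name=eid)
        for eid, row in truth.iterrows()
    ]
    features = cl.annotate_features(peaks, genes, thresholds)
    k27_mask = truth["has_H3K27ac"].to_numpy()
    k27_peaks = [p for p, m in zip(peaks, k27_mask) if m]
    k27_dyn = tables["H3K27ac"]["dynamics"].loc[[p.name for p in k27_peaks]]
    joint = cl.joint_mark_categories(peaks, k27_peaks, list(k27_dyn))

    # linkage and coupling statistics
    link = lk.nearest_tss(peaks, genes)
    dge = gene_dge(data["expression"], thresholds, method=method)
    expr_lfc_form = dge["log2cpm"]["DKO_formative"] - dge["log2cpm"]["WT_formative"]

    dep_k27 = tables["H3K27ac"]["dependency"] == "dependent"
    burden = (
        link.assign(dep=dep_k27.reindex(link.index).fillna(False).to_numpy())
        .groupby("gene_id")
        .agg(n_dep=("dep", "sum"), n_total=("dep", "size"))
    )
    burden["gene_lfc"] = expr_lfc_form.reindex(burden.index).to_numpy()
    burden = burden.dropna()
    fit = lk.enhancer_burden_fit(
        burden["n_dep"].to_numpy(), burden["gene_lfc"].to_numpy()
    )
    loss_bins = lk.enhancer_loss_binning(
        (100.0 * burden["n_dep"] / burden["n_total"]).to_numpy(),
        burden["gene_lfc"].to_numpy(),
    )
    loss_bins.to_csv(outdir / "enhancer_loss_bins.tsv", sep="\t")
    # gene-centric view: H3K27ac change at enhancers of dependent vs
    # independent formative genes (K4me1+/K27ac+ set)
    k27_link = link[truth["has_H3K27ac"].reindex(link.index).fillna(False)]
    gene_centric = lk.gene_centric_acetylation_fc(
        dge["classes"],
        k27_link,
        tables["H3K27ac"]["lfc_form_dko_wt"],
    )
    decoupling = decoupling_analysis(
        truth, genes, data["counts"]["H3K27ac"], data["expression"], thresholds
    )

    # chromatin states (formative condition)
    b, seg = segment_condition(tracks, "formative", config)
    atac = [
        GenomicInterval(row["chrom"], row["start"], row["end"])
        for _, row in truth[truth["has_ATAC"]].iterrows()
    ]
    state_tests = cs.state_expression_test(
        seg, atac, genes, expr_lfc_form, seed=config.seed
    )
    state_tests.to_csv(outdir / "state_expression_tests.tsv", sep="\t", index=False)

    summary = pd.DataFrame(peak_eval).T
    summary.to_csv(outdir / "peak_call_evaluation.tsv", sep="\t")
    if make_plots:
        _report_plots(burden, fit, outdir)

    return {
        "truth": truth,
        "genes": genes,
        "peak_eval": peak_eval,
        "union_peaks": union,
        "tables": tables,
        "features": features,
        "joint": joint,
        "linkage": link,
        "dge": dge,
        "burden_fit": fit,
        "loss_bins": loss_bins,
        "gene_centric": gene_centric,
        "decoupling": decoupling,
        "state_tests": state_tests,
    }


def _report_plots(burden: pd.DataFrame, fit: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(burden["n_dep"], burden["gene_lfc"], s=4, alpha=0.4)
    xs = np.array(sorted(burden["n_dep"].unique()))
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, color="tab:blue")
    ax.set_xlabel("MLL3/4-dependent enhancers per gene")
    ax.set_ylabel("gene log2FC DKO/WT (formative)")
    fig.tight_layout()
    fig.savefig(outdir / "enhancer_burden.svg")
    plt.close(fig)
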