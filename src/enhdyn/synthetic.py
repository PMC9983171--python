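"""Miniature genome simulator with planted enhancer ground truth.

The generator builds a desk-scale genome (default two 5 Mb chromosomes) with
non-overlapping genes and intergenic enhancers, then plants the structures the
pipeline is meant to recover:

- *dynamics*: each enhancer is naive-, formative-enriched or shared between
  the two pluripotency states (the enriched state carries the mark at the base
  enrichment, the other state two log2 units lower by default);
- *dependency*: per mark, an enhancer either loses the mark in the MLL3/4
  double knockout (planted DKO/WT log2 fold change -2) or keeps it;
- *marks*: every enhancer carries H3K4me1; subsets also carry H3K27ac and/or
  open chromatin (ATAC);
- *coupling*: each enhancer is linked to its nearest-TSS gene, and the
  coupling strength ``kappa`` in [0, 1] sets what fraction of a gene's
  DKO/WT expression fold change is explained by the acetylation change at its
  coupled enhancers (``kappa = 0`` decouples chromatin from transcription).

Signal tracks are Poisson counts on fixed-width bins, CPM-scaled; per-enhancer
fragment counts and per-gene expression counts are negative binomial.  All
randomness flows from a single seeded generator, so outputs are byte-identical
given a seed.
"""

from __future__ import annotations

import bisect
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    GeneModel,
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_genes_bed,
    write_table,
)
from .diffquant import CountMatrix

__all__ = ["SimConfig", "generate_truth", "simulate_tracks", "simulate_counts",
           "simulate_expression", "write_dataset", "MARKS", "GENOTYPES", "CONDITIONS"]

MARKS = ("H3K4me1", "H3K27ac")
GENOTYPES = ("WT", "DKO")
CONDITIONS = ("naive", "formative")


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Effect sizes are log2: ``dynamics_log2fc`` separates the enriched from the
    depleted state of a dynamic enhancer, ``dependency_log2fc`` is the planted
    DKO/WT change at dependent sites, ``base_log2_enrichment`` the marked
    enhancer level over background (3 = 8x).  ``background_rate`` is background
    fragments per bp at nominal depth; ``kappa`` the chromatin-transcription
    coupling strength.
    """

    seed: int = 1
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_enhancers: int = 2000
    n_genes: int = 1000
    enhancer_width: int = 1000
    gene_length_min: int = 1000
    gene_length_max: int = 4000
    prop_naive: float = 0.25
    prop_formative: float = 0.25
    prop_shared: float = 0.5
    prop_dependent: float = 0.3
    prop_k27ac: float = 0.7
    prop_atac: float = 0.8
    base_log2_enrichment: float = 3.0
    dynamics_log2fc: float = 2.0
    dependency_log2fc: float = -2.0
    nb_dispersion: float = 0.02
    depth: float = 1e6
    background_rate: float = 0.003
    track_bin: int = 100
    kappa: float = 1.0
    coupling_prob: float = 1.0
    n_replicates: int = 2
    tss_margin: int = 1500

    def __post_init__(self) -> None:
        props = self.prop_naive + self.prop_formative + self.prop_shared
        if abs(props - 1.0) > 1e-9:
            raise ValueError("dynamics proportions must sum to 1")
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# -- ground truth ----------------------------------------------------------

def generate_truth(config: SimConfig) -> tuple[pd.DataFrame, list[GeneModel]]:
    """Place genes and enhancers and draw all ground-truth labels.

    Returns the truth table (one row per enhancer) and the gene models.
    Enhancers are non-overlapping, intergenic, and at least ``tss_margin`` bp
    from any TSS, so every planted enhancer is distal by construction.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    enhancers = _place_enhancers(config, genes, rng)
    n = len(enhancers)

    dynamics = rng.choice(
        ["naive", "formative", "shared"],
        size=n,
        p=[config.prop_naive, config.prop_formative, config.prop_shared],
    )
    dep_k4 = np.where(rng.random(n) < config.prop_dependent, "dependent", "independent")
    dep_k27 = np.where(rng.random(n) < config.prop_dependent, "dependent", "independent")
    has_k27 = rng.random(n) < config.prop_k27ac
    has_atac = rng.random(n) < config.prop_atac
    coupled = rng.random(n) < config.coupling_prob

    # nearest-TSS linkage by construction (inline brute force, same tie-break
    # as the linkage module: distance, then TSS coordinate, then gene id)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    linked, distances = [], []
    for iv in enhancers:
        mid = iv.midpoint
        best = min(
            ((abs(mid - t), t, gid) for t, gid in tss_by_chrom.get(iv.chrom, [])),
            default=None,
        )
        linked.append(best[2] if best else None)
        distances.append(mid - best[1] if best else np.nan)

    truth = pd.DataFrame(
        {
            "enhancer_id": [f"enh_{i:05d}" for i in range(n)],
            "chrom": [iv.chrom for iv in enhancers],
            "start": [iv.start for iv in enhancers],
            "end": [iv.end for iv in enhancers],
            "dynamics": dynamics,
            "dep_H3K4me1": dep_k4,
            "dep_H3K27ac": dep_k27,
            "has_H3K27ac": has_k27,
            "has_ATAC": has_atac,
            "gene_id": linked,
            "tss_distance": distances,
            "coupled": coupled,
        }
    ).set_index("enhancer_id")
    return truth, genes


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}
    genes = []
    attempts = 0
    i = 0
    while i < config.n_genes:
        attempts += 1
        if attempts > config.n_genes * 500:
            raise ValueError("genome too small for requested gene count")
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        start = int(rng.integers(0, config.chrom_length - length))
        if _conflicts(placed[chrom], start - 200, start + length + 200):
            continue
        bisect.insort(placed[chrom], (start, start + length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                f"gene_{i:04d}",
                GenomicInterval(chrom, start, start + length, strand=strand),
            )
        )
        i += 1
    return genes


def _place_enhancers(
    config: SimConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[GenomicInterval]:
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}
    for g in genes:
        iv = g.interval
        bisect.insort(
            blocked[iv.chrom],
            (iv.start - config.tss_margin, iv.end + config.tss_margin),
        )
    gap = 2 * config.track_bin
    enhancers = []
    attempts = 0
    w = config.enhancer_width
    while len(enhancers) < config.n_enhancers:
        attempts += 1
        if attempts > config.n_enhancers * 500:
            raise ValueError("genome too small for requested enhancer count")
        chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(gap, config.chrom_length - w - gap))
        if _conflicts(blocked[chrom], start - gap, start + w + gap):
            continue
        bisect.insort(blocked[chrom], (start, start + w))
        enhancers.append(GenomicInterval(chrom, start, start + w))
    enhancers.sort(key=lambda iv: (iv.chrom, iv.start))
    return enhancers


def _conflicts(spans: list[tuple[int, int]], start: int, end: int) -> bool:
    i = bisect.bisect_left(spans, (start, start))
    for j in (i - 1, i):
        if 0 <= j < len(spans) and spans[j][0] < end and start < spans[j][1]:
            return True
    return False


# -- planted enrichment ----------------------------------------------------

def planted_log2_enrichment(
    row: pd.Series, mark: str, genotype: str, condition: str, config: SimConfig
) -> float:
    """Planted log2 enrichment over background for one enhancer and sample
    class; 0 when the enhancer does not carry the mark."""
    if mark == "H3K27ac" and not row["has_H3K27ac"]:
        return 0.0
    if mark == "IgG":
        return 0.0
    base = config.base_log2_enrichment
    if row["dynamics"] == "shared":
        e = base
    elif row["dynamics"] == condition:
        e = base
    else:
        e = base - config.dynamics_log2fc
    if genotype == "DKO" and row[f"dep_{mark}"] == "dependent":
        e = max(e + config.dependency_log2fc, 0.0)
    return e


# -- signal tracks ---------------------------------------------------------

def simulate_tracks(
    truth: pd.DataFrame, config: SimConfig
) -> dict[tuple[str, str, str], SignalTrack]:
    """One CPM-scaled coverage track per (mark, genotype, condition), pooled
    across replicates, plus a matched background-only IgG control per
    (genotype, condition)."""
    rng = np.random.default_rng(config.seed + 1)
    bin_w = config.track_bin
    n_bins = config.chrom_length // bin_w
    lam_bg = config.background_rate * bin_w
    tracks: dict[tuple[str, str, str], SignalTrack] = {}
    for mark in MARKS + ("IgG",):
        for genotype in GENOTYPES:
            for condition in CONDITIONS:
                lam = {c: np.full(n_bins, lam_bg) for c in config.chrom_names}
                if mark != "IgG":
                    for _, row in truth.iterrows():
                        e = planted_log2_enrichment(row, mark, genotype, condition, config)
                        if e > 0:
                            b0 = row["start"] // bin_w
                            b1 = (row["end"] + bin_w - 1) // bin_w
                            lam[row["chrom"]][b0:b1] = lam_bg * 2.0**e
                records = []
                total = 0.0
                chrom_counts = {}
                for chrom in config.chrom_names:
                    counts = rng.poisson(lam[chrom])
                    chrom_counts[chrom] = counts
                    total += counts.sum()
                scale = 1e6 / total if total else 1.0
                for chrom in config.chrom_names:
                    counts = chrom_counts[chrom]
                    for b in np.flatnonzero(counts):
                        records.append(
                            (chrom, b * bin_w, (b + 1) * bin_w, counts[b] * scale)
                        )
                tracks[(mark, genotype, condition)] = SignalTrack.from_records(records)
    return tracks


# -- count matrices --------------------------------------------------------

def _sample_names(mark: str, config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    names, meta = [], []
    for genotype in GENOTYPES:
        for condition in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                names.append(f"{mark}_{genotype}_{condition}_r{rep}")
                meta.append(
                    {"sample": names[-1], "genotype": genotype,
                     "condition": condition, "replicate": rep}
                )
    return names, pd.DataFrame(meta).set_index("sample")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig, mark: str = "H3K4me1"
) -> CountMatrix:
    """Negative-binomial per-enhancer fragment counts for one mark across all
    genotype x condition x replicate samples.

    The expected count of enhancer *e* in a sample is
    ``depth_s * width * 2^enrichment / genome_length`` (background mass spread
    uniformly over the genome), with per-sample depths jittered around the
    configured depth.
    """
    rng = np.random.default_rng(config.seed + 2 + MARKS.index(mark))
    names, meta = _sample_names(mark, config)
    widths = (truth["end"] - truth["start"]).to_numpy(dtype=float)
    cols = {}
    libs = {}
    for name in names:
        genotype, condition = meta.loc[name, "genotype"], meta.loc[name, "condition"]
        depth = config.depth * float(rng.lognormal(0.0, 0.1))
        libs[name] = depth
        enrich = np.array(
            [
                planted_log2_enrichment(row, mark, genotype, condition, config)
                for _, row in truth.iterrows()
            ]
        )
        mean = depth * widths * 2.0**enrich / config.genome_length
        cols[name] = _nb_sample(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=truth.index)
    meta["lib_size"] = pd.Series(libs)
    # library size is the sample's total sequencing depth (the genome-wide
    # mapped-read count), not the in-peak sum: CPM is a whole-library scale
    return CountMatrix(counts, meta=meta, lib_size=pd.Series(libs).round())


def gene_effects(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Planted per-gene log2 effects: the WT transition effect and the
    acetylation-driven DKO/WT effect per condition (before scaling by kappa).

    Only enhancers *active* in a condition (at full base enrichment in WT,
    i.e. dynamics matching the condition or shared) couple to the gene in that
    condition: an enhancer drives expression where it is on.
    """
    sign = {"formative": 1.0, "naive": -1.0, "shared": 0.0}
    rows = {}
    for gid, grp in truth[truth["coupled"]].groupby("gene_id"):
        dyn = float(np.mean([sign[d] for d in grp["dynamics"]]))
        acet = {}
        k27 = grp[grp["has_H3K27ac"]]
        for condition in CONDITIONS:
            active = k27[k27["dynamics"].isin([condition, "shared"])]
            if len(active):
                deltas = [
                    planted_log2_enrichment(row, "H3K27ac", "DKO", condition, config)
                    - planted_log2_enrichment(row, "H3K27ac", "WT", condition, config)
                    for _, row in active.iterrows()
                ]
                acet[condition] = float(np.mean(deltas))
            else:
                acet[condition] = 0.0
        rows[gid] = {
            "wt_transition_lfc": dyn * config.dynamics_log2fc,
            "dko_acet_lfc_naive": acet["naive"],
            "dko_acet_lfc_formative": acet["formative"],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_expression(
    truth: pd.DataFrame, genes: list[GeneModel], config: SimConfig
) -> CountMatrix:
    """Gene x sample expression counts with enhancer-coupled genotype effects.

    A gene's DKO/WT log2 fold change in a condition is ``kappa`` times the mean
    planted H3K27ac log2 change of its coupled enhancers in that condition,
    plus NB noise; ``kappa = 0`` makes expression independent of enhancer
    state.
    """
    rng = np.random.default_rng(config.seed + 10)
    names, meta = _sample_names("rna", config)
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.lognormal(np.log(300.0), 1.0, size=len(gene_ids))
    effects = gene_effects(truth, config).reindex(gene_ids).fillna(0.0)
    wt_lfc = effects["wt_transition_lfc"].to_numpy()
    cols = {}
    for name in names:
        genotype, condition = meta.loc[name, "genotype"], meta.loc[name, "condition"]
        depth = config.depth * float(rng.lognormal(0.0, 0.1))
        log2_mean = np.log2(baseline / baseline.sum())
        if condition == "formative":
            log2_mean = log2_mean + wt_lfc
        if genotype == "DKO":
            log2_mean = log2_mean + config.kappa * effects[
                f"dko_acet_lfc_{condition}"
            ].to_numpy()
        mean = depth * 2.0**log2_mean / np.sum(2.0**log2_mean)
        cols[name] = _nb_sample(rng, mean, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=gene_ids)
    return CountMatrix(counts, meta=meta)


# -- dataset writer --------------------------------------------------------

def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Generate the full synthetic dataset and write it as plain-text files.

    Writes bedGraph tracks, the true-enhancer BED (truth labels in the name
    field), an ATAC peak BED, BED6 genes, per-mark count matrices, the
    expression matrix, sample sheets, the truth table and the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, genes = generate_truth(config)
    tracks = simulate_tracks(truth, config)
    for (mark, genotype, condition), track in tracks.items():
        write_bedgraph(track, outdir / f"{mark}_{genotype}_{condition}.bedgraph")
    enh_bed = [
        GenomicInterval(
            row["chrom"], row["start"], row["end"],
            name=f"{eid}|{row['dynamics']}|{row['dep_H3K4me1']}|{row['dep_H3K27ac']}",
        )
        for eid, row in truth.iterrows()
    ]
    write_bed(enh_bed, outdir / "true_enhancers.bed")
    atac = [
        GenomicInterval(row["chrom"], row["start"], row["end"], name=eid)
        for eid, row in truth[truth["has_ATAC"]].iterrows()
    ]
    write_bed(atac, outdir / "atac_peaks.bed")
    write_genes_bed(genes, outdir / "genes.bed")
    counts = {}
    for mark in MARKS:
        cm = simulate_counts(truth, config, mark)
        counts[mark] = cm
        write_table(cm.counts, outdir / f"counts_{mark}.tsv")
        cm.meta.to_csv(outdir / f"samples_{mark}.tsv", sep="\t")
    expr = simulate_expression(truth, genes, config)
    write_table(expr.counts, outdir / "expression.tsv")
    expr.meta.to_csv(outdir / "samples_rna.tsv", sep="\t")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    config.to_yaml(outdir / "config.yaml")
    return {"truth": truth, "genes": genes, "tracks": tracks,
            "counts": counts, "expression": expr}
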