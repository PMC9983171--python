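"""Chromatin-state segmentation over binarized histone-mark tracks.

The genome is tiled into fixed-width bins (default 200 bp); each track is
binarized against a Poisson background model.  With K tracks (here H3K4me1 and
H3K27ac in WT and DKO, so K = 4) the 2^K = 16 possible presence/absence
combinations are the chromatin states.  Two segmenters are provided: a direct
combinatorial assignment (the default -- with binary tracks and a saturated
state space the combinations *are* the states) and a hidden Markov model with
independent Bernoulli emissions per track, trained by Baum-Welch.

Forward/backward uses per-step scaling constants, which is algebraically
identical to log-domain arithmetic and underflow-free for arbitrarily long
sequences; Viterbi runs in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval

__all__ = [
    "BinarizedMatrix",
    "HMMParams",
    "StateSegmentation",
    "binarize",
    "combinatorial_states",
    "hmm_fit",
    "hmm_decode",
    "state_expression_test",
]

_EPS = 1e-6


@dataclass
class BinarizedMatrix:
    """Per-chromosome (n_bins x K) binary matrices for K ordered tracks."""

    data: dict[str, np.ndarray]
    track_names: list[str]
    bin_size: int = 200

    def __post_init__(self) -> None:
        k = len(self.track_names)
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.uint8)
            if arr.ndim != 2 or arr.shape[1] != k:
                raise ValueError(f"{chrom}: expected (n_bins, {k}) matrix")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{chrom}: entries must be 0/1")
            self.data[chrom] = arr

    @property
    def n_tracks(self) -> int:
        return len(self.track_names)

    def stacked(self) -> np.ndarray:
        return np.vstack([self.data[c] for c in sorted(self.data)])


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and per-track Bernoulli
    emission probabilities of the chromatin-state HMM."""

    pi: np.ndarray
    transition: np.ndarray
    emission: np.ndarray  # (n_states, n_tracks)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if not np.allclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")

    @property
    def n_states(self) -> int:
        return self.pi.size


@dataclass
class StateSegmentation:
    """Per-bin state assignment (1-based ids) and merged same-state runs."""

    states: dict[str, np.ndarray]
    bin_size: int
    n_states: int

    def intervals(self) -> list[GenomicInterval]:
        """Same-state runs as intervals, state id in the name field."""
        out = []
        for chrom in sorted(self.states):
            s = self.states[chrom]
            if not s.size:
                continue
            breaks = np.flatnonzero(np.diff(s)) + 1
            edges = np.concatenate([[0], breaks, [s.size]])
            for b0, b1 in zip(edges[:-1], edges[1:]):
                out.append(
                    GenomicInterval(
                        chrom,
                        int(b0 * self.bin_size),
                        int(b1 * self.bin_size),
                        name=str(int(s[b0])),
                    )
                )
        return out

    def state_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_states, dtype=np.int64)
        for s in self.states.values():
            counts += np.bincount(s - 1, minlength=self.n_states)
        return counts


# -- binarization ----------------------------------------------------------

def binarize(
    bin_counts: np.ndarray,
    lam: float | None = None,
    pcut: float = 1e-4,
) -> np.ndarray:
    """Poisson-tail binarization of per-bin counts.

    A bin is called present (1) iff the upper-tail probability
    ``P(X >= count | lam)`` is below ``pcut``; ``lam`` defaults to the
    genome-wide mean count per bin.
    """
    counts = np.asarray(bin_counts, dtype=float)
    if lam is None:
        lam = float(counts.mean())
    if lam <= 0:
        raise ValueError("background rate lambda must be positive")
    tail = stats.poisson.sf(counts - 1, lam)  # P(X >= count)
    return (tail < pcut).astype(np.uint8)


# -- combinatorial assignment ----------------------------------------------

def combinatorial_states(b: BinarizedMatrix) -> StateSegmentation:
    """State id = 1 + the binary encoding of the bin's track vector (first
    track is the most significant bit)."""
    k = b.n_tracks
    weights = 2 ** np.arange(k - 1, -1, -1)
    states = {
        chrom: (arr @ weights + 1).astype(np.int64) for chrom, arr in b.data.items()
    }
    return StateSegmentation(states=states, bin_size=b.bin_size, n_states=2**k)


# -- Bernoulli-emission HMM ------------------------------------------------

def _log_emission(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    E = np.clip(emission, _EPS, 1 - _EPS)
    return X @ np.log(E).T + (1 - X) @ np.log(1 - E).T  # (T, S)


def _forward_backward(
    X: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.  Returns (alpha_hat, beta_hat, scales, loglik)."""
    logB = _log_emission(X, params.emission)
    # per-row shift keeps the scaled recursion well conditioned
    shift = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - shift)
    T, S = B.shape
    A = params.transition
    alpha = np.empty((T, S))
    c = np.empty(T)
    a0 = params.pi * B[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, S))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    loglik = float(np.sum(np.log(c)) + shift.sum())
    return alpha, beta, c, loglik


def forward_loglik(b: BinarizedMatrix, params: HMMParams) -> float:
    """Total log-likelihood of the binarized data under the model (sequences =
    chromosomes, assumed independent)."""
    return sum(
        _forward_backward(b.data[c].astype(float), params)[3] for c in sorted(b.data)
    )


def hmm_fit(
    b: BinarizedMatrix,
    n_states: int = 16,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[HMMParams, list[float]]:
    """Baum-Welch fit of the Bernoulli-emission HMM.

    Emissions are initialised from the empirical per-track frequencies,
    perturbed per state by the seeded RNG; the log-likelihood is non-decreasing
    over iterations and fitting stops when the improvement falls below ``tol``
    (absolute) or ``max_iter`` is reached.  Returns the parameters and the
    log-likelihood trace.
    """
    seqs = [b.data[c].astype(float) for c in sorted(b.data)]
    X_all = np.vstack(seqs)
    if X_all.sum() == 0:
        raise ValueError("all-zero binarized matrix; nothing to segment")
    n_distinct = len({tuple(row) for row in X_all[: min(len(X_all), 50_000)]})
    if n_distinct < n_states:
        warnings.warn(
            f"only {n_distinct} distinct observation vectors for {n_states} states"
        )
    rng = np.random.default_rng(seed)
    freq = X_all.mean(axis=0)
    emission = np.clip(
        freq + rng.uniform(-0.25, 0.25, size=(n_states, b.n_tracks)), 0.05, 0.95
    )
    pi = np.full(n_states, 1.0 / n_states)
    transition = np.full((n_states, n_states), 0.1 / max(1, n_states - 1))
    np.fill_diagonal(transition, 0.9)
    transition /= transition.sum(axis=1, keepdims=True)
    params = HMMParams(pi, transition, emission)

    trace: list[float] = []
    for _ in range(max_iter):
        loglik = 0.0
        pi_acc = np.zeros(n_states)
        xi_acc = np.zeros((n_states, n_states))
        gnum = np.zeros((n_states, b.n_tracks))
        gden = np.zeros(n_states)
        for X in seqs:
            alpha, beta, c, ll = _forward_backward(X, params)
            loglik += ll
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            pi_acc += gamma[0]
            logB = _log_emission(X, params.emission)
            B = np.exp(logB - logB.max(axis=1, keepdims=True))
            w = B[1:] * beta[1:] / c[1:, None]
            xi_acc += params.transition * (alpha[:-1].T @ w)
            gnum += gamma.T @ X
            gden += gamma.sum(axis=0)
        trace.append(loglik)
        new = HMMParams(
            pi=pi_acc / pi_acc.sum(),
            transition=xi_acc / xi_acc.sum(axis=1, keepdims=True),
            emission=np.clip(gnum / gden[:, None], _EPS, 1 - _EPS),
        )
        params = new
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    return params, trace


def hmm_decode(
    b: BinarizedMatrix, params: HMMParams, mode: str = "posterior"
) -> StateSegmentation:
    """Decode a state path per chromosome.

    ``viterbi`` returns the jointly most probable path; ``posterior`` the
    per-bin argmax of the forward-backward posterior.
    """
    if mode not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decode mode {mode!r}")
    states = {}
    for chrom, arr in b.data.items():
        X = arr.astype(float)
        if mode == "posterior":
            alpha, beta, _, _ = _forward_backward(X, params)
            gamma = alpha * beta
            states[chrom] = np.argmax(gamma, axis=1).astype(np.int64) + 1
        else:
            states[chrom] = _viterbi(X, params) + 1
    return StateSegmentation(states=states, bin_size=b.bin_size, n_states=params.n_states)


def _viterbi(X: np.ndarray, params: HMMParams) -> np.ndarray:
    logB = _log_emission(X, params.emission)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logpi = np.log(params.pi)
    T, S = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(S)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# -- state-level expression test -------------------------------------------

def state_expression_test(
    seg: StateSegmentation,
    atac_peaks: list[GenomicInterval],
    genes: list[GeneModel],
    gene_values: pd.Series,
    emission: np.ndarray | None = None,
    overlap_frac: float = 0.75,
    n_perm: int = 1000,
    seed: int = 0,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Per-state permutation test of nearest-TSS gene expression changes.

    Segmentation intervals are restricted to distal accessible chromatin
    (>= ``overlap_frac`` of a WT ATAC peak covered, and not a promoter), mapped
    to nearest TSSs, and each state's (deduplicated) gene set is tested against
    the all-genes control with the Monte-Carlo Mann-Whitney permutation test;
    BH correction across states.  States whose tracks show no mark emission
    (state 1 in the combinatorial encoding, or an HMM state with all emission
    probabilities below 0.1) are excluded, as are states with fewer than
    ``min_sites`` distal sites.
    """
    from .classify import Thresholds, annotate_features, overlap_filter
    from .diffquant import bh_adjust
    from .linkage import nearest_tss, permutation_control_test

    if emission is None:
        excluded = {1}
    else:
        excluded = {
            s + 1 for s in range(emission.shape[0]) if (emission[s] < 0.1).all()
        }
    all_values = gene_values.dropna().to_numpy()
    rows = []
    ivs = seg.intervals()
    features = annotate_features([iv for iv in ivs], genes, Thresholds(overlap_frac=overlap_frac))
    distal = [iv for iv, f in zip(ivs, features) if f == "Distal"]
    for state in range(1, seg.n_states + 1):
        if state in excluded:
            continue
        state_ivs = [iv for iv in distal if int(iv.name) == state]
        state_ivs = overlap_filter(state_ivs, atac_peaks, frac=overlap_frac)
        if len(state_ivs) < min_sites:
            continue
        link = nearest_tss(state_ivs, genes)
        gene_ids = link["gene_id"].drop_duplicates()
        vals = gene_values.reindex(gene_ids).dropna().to_numpy()
        if vals.size < 3:
            continue
        p = permutation_control_test(
            vals, all_values, n_perm=n_perm, seed=seed + state
        )
        rows.append(
            {
                "state": state,
                "n_sites": len(state_ivs),
                "n_genes": int(vals.size),
                "median_value": float(np.median(vals)),
                "median_all": float(np.median(all_values)),
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out
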