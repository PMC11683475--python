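"""Chromatin-state segmentation from binarized ATAC / H3K4me3 / H3K27ac tracks.

The genome is cut into fixed bins (200 bp), each mark is binarized against a
Poisson background (a bin is "on" when its count is in the extreme
``p < 1e-4`` tail of Poisson(genome-wide mean)), and a K-state hidden Markov
model with independent-Bernoulli emissions is trained by Baum-Welch on the
concatenation of all tissues — one shared model, decoded per tissue by
posterior maximum. With three marks, six states capture the informative
combinations: active/weak promoter (TssA/TssW), strong/weak active enhancer
(EnhA/EnhAW), ATAC island (accessible only), and quiescent (Quies).

`BernoulliHMM` / `HMMResults` follow the statsmodels fit/results idiom; the
module-level functions (`binarize_track`, `train_hmm`, `decode_states`, ...)
are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, merge_intervals
from .io import GeneModel, SignalTrack

__all__ = [
    "MARKS",
    "STATE_LABELS",
    "binarize_track",
    "BinaryMarks",
    "BernoulliHMM",
    "HMMResults",
    "Segmentation",
    "train_hmm",
    "decode_states",
    "label_states",
    "state_coverage",
    "tss_profile",
    "merge_nonredundant",
    "call_tissue_specific",
    "variability_curve",
]

MARKS = ("ATAC", "H3K4me3", "H3K27ac")
STATE_LABELS = ("TssA", "TssW", "EnhA", "EnhAW", "ATAC_Is", "Quies")


# ---------------------------------------------------------------------------
# Binarization

def binarize_track(track: SignalTrack, p_threshold: float = 1e-4) -> dict[str, np.ndarray]:
    """Poisson-background binarization of one count track.

    lambda is the genome-wide mean bin count; a bin becomes 1 iff
    P(X >= count | Poisson(lambda)) < p_threshold. An all-zero track yields
    all zeros with a warning (degenerate background).
    """
    counts = track.concatenated()
    if (counts < 0).any():
        raise ValueError("count track has negative values")
    lam = counts.mean()
    if lam == 0:
        warnings.warn("all-zero track: binarization degenerate, returning zeros")
        return {c: np.zeros(track.n_bins(c), dtype=np.int8) for c in track.chroms}
    out = {}
    for chrom in track.chroms:
        v = track.values[chrom]
        tail = stats.poisson.sf(v - 1, lam)  # P(X >= v)
        out[chrom] = (tail < p_threshold).astype(np.int8)
    return out


@dataclass
class BinaryMarks:
    """Bins x marks 0/1 matrices for one tissue, per chromosome."""

    values: dict[str, np.ndarray]  # chrom -> (n_bins, n_marks)
    bin_size: int = 200
    marks: tuple[str, ...] = MARKS

    def __post_init__(self):
        for chrom, m in self.values.items():
            if m.ndim != 2 or m.shape[1] != len(self.marks):
                raise ValueError(f"{chrom}: expected (bins, {len(self.marks)}) matrix")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{chrom}: entries must be 0/1")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    @classmethod
    def from_tracks(cls, tracks: dict[str, SignalTrack],
                    p_threshold: float = 1e-4,
                    marks: tuple[str, ...] = MARKS) -> "BinaryMarks":
        binned = {m: binarize_track(tracks[m], p_threshold) for m in marks}
        chroms = binned[marks[0]].keys()
        values = {c: np.column_stack([binned[m][c] for m in marks]) for c in chroms}
        bs = tracks[marks[0]].bin_size
        return cls(values, bin_size=bs, marks=marks)


# ---------------------------------------------------------------------------
# HMM internals (scaled forward-backward, Baum-Welch E-step)

@njit(cache=True)
def _forward_backward(startprob, transmat, frame_prob):
    """Scaled forward-backward. Returns (log-likelihood, gamma, summed xi)."""
    T, K = frame_prob.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)
    for k in range(K):
        alpha[0, k] = startprob[k] * frame_prob[0, k]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = s * frame_prob[t, j]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += transmat[i, j] * frame_prob[t + 1, j] * beta[t + 1, j]
            beta[t, i] = s / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += (alpha[t, i] * transmat[i, j]
                             * frame_prob[t + 1, j] * beta[t + 1, j] / c[t + 1])
    ll = np.log(c).sum()
    return ll, gamma, xi


_EPS = 1e-10


def _frame_prob(x: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """Per-bin likelihood under each state's independent-Bernoulli emissions."""
    e = np.clip(emissions, _EPS, 1 - _EPS)
    # one of 2^M patterns per bin: evaluate each pattern once
    M = x.shape[1]
    codes = (x @ (1 << np.arange(M))).astype(np.int64)
    pat = ((np.arange(1 << M)[:, None] >> np.arange(M)) & 1)  # (2^M, M)
    logp = pat @ np.log(e).T + (1 - pat) @ np.log1p(-e).T  # (2^M, K)
    return np.exp(logp)[codes]


class BernoulliHMM:
    """K-state HMM with per-mark independent Bernoulli emissions.

    One model is trained on the concatenation of all tissues' binarized
    sequences (each chromosome of each tissue is its own sequence) and later
    decoded per tissue. Best of `n_restarts` random initializations by
    log-likelihood; training stops when the log-likelihood improves by less
    than `tol` or after `max_iter` Baum-Welch sweeps.
    """

    def __init__(self, n_states: int = 6, n_restarts: int = 5, tol: float = 1e-4,
                 max_iter: int = 500, seed: int | None = None):
        if n_states < 2:
            raise ValueError("need K >= 2 states")
        self.n_states = n_states
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, data: Sequence[BinaryMarks]) -> "HMMResults":
        if len(data) == 0:
            raise ValueError("no tissues to train on")
        marks = data[0].marks
        seqs = [bm.values[c].astype(np.float64) for bm in data for c in bm.chroms]
        n_patterns = len({tuple(row) for s in seqs for row in np.unique(s, axis=0)})
        if self.n_states > n_patterns:
            warnings.warn(f"K={self.n_states} exceeds the {n_patterns} distinct "
                          "emission patterns observed; states may collapse")
        rng = np.random.default_rng(self.seed)
        best = None
        for _ in range(self.n_restarts):
            params, ll, history = self._baum_welch(seqs, rng)
            if best is None or ll > best[1]:
                best = (params, ll, history)
        (startprob, transmat, emissions), ll, history = best
        return HMMResults(self, startprob, transmat, emissions, marks,
                          log_likelihood=ll, ll_history=history)

    def _baum_welch(self, seqs, rng):
        K, M = self.n_states, seqs[0].shape[1]
        emissions = rng.uniform(0.05, 0.95, size=(K, M))
        transmat = np.full((K, K), 0.1 / max(K - 1, 1)) + np.eye(K) * (0.9 - 0.1 / max(K - 1, 1))
        transmat += rng.uniform(0, 0.02, size=(K, K))
        transmat /= transmat.sum(axis=1, keepdims=True)
        startprob = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        history: list[float] = []
        for _ in range(self.max_iter):
            ll = 0.0
            xi_sum = np.zeros((K, K))
            start_sum = np.zeros(K)
            gamma_sum = np.zeros(K)
            gx_sum = np.zeros((K, M))
            for x in seqs:
                fp = _frame_prob(x, emissions)
                ll_s, gamma, xi = _forward_backward(startprob, transmat, fp)
                ll += ll_s
                xi_sum += xi
                start_sum += gamma[0]
                gamma_sum += gamma.sum(axis=0)
                gx_sum += gamma.T @ x
            history.append(ll)
            if ll < prev_ll - 1e-6:
                raise AssertionError(
                    f"Baum-Welch log-likelihood decreased: {prev_ll} -> {ll}")
            if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            startprob = start_sum / start_sum.sum()
            transmat = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), _EPS, None)
            emissions = gx_sum / np.clip(gamma_sum[:, None], _EPS, None)
        return (startprob, transmat, emissions), history[-1], history


@dataclass
class HMMResults:
    """Trained chromatin-state model: parameters, labels, decoding."""

    model: BernoulliHMM
    startprob: np.ndarray
    transmat: np.ndarray
    emissions: np.ndarray  # (K, M): P(mark on | state)
    marks: tuple[str, ...]
    log_likelihood: float
    ll_history: list[float] = field(default_factory=list)
    _labels: list[str] | None = None

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def state_labels(self) -> list[str]:
        if self._labels is None:
            self._labels = label_states(self.emissions, self.marks)
        return self._labels

    def decode(self, marks: BinaryMarks, method: str = "posterior") -> "Segmentation":
        """Per-bin state assignment; posterior maximum by default, Viterbi optional."""
        states = {}
        for chrom in marks.chroms:
            x = marks.values[chrom].astype(np.float64)
            fp = _frame_prob(x, self.emissions)
            if method == "posterior":
                _, gamma, _ = _forward_backward(self.startprob, self.transmat, fp)
                states[chrom] = gamma.argmax(axis=1).astype(np.int32)
            elif method == "viterbi":
                states[chrom] = _viterbi(self.startprob, self.transmat, fp)
            else:
                raise ValueError(f"unknown decoding method {method!r}")
        return Segmentation(states, marks.bin_size, labels=self.state_labels)

    def score(self, marks: BinaryMarks) -> float:
        """Log-likelihood of one tissue's binarized sequence."""
        ll = 0.0
        for chrom in marks.chroms:
            fp = _frame_prob(marks.values[chrom].astype(np.float64), self.emissions)
            ll += _forward_backward(self.startprob, self.transmat, fp)[0]
        return ll

    def summary(self) -> str:
        lines = ["Bernoulli-emission chromatin-state HMM", "=" * 47,
                 f"states: {self.n_states}   marks: {', '.join(self.marks)}",
                 f"log-likelihood: {self.log_likelihood:.2f} "
                 f"({len(self.ll_history)} EM iterations)", "",
                 "state  label     " + "  ".join(f"{m:>8s}" for m in self.marks)]
        for k in range(self.n_states):
            lines.append(f"{k:>5d}  {self.state_labels[k]:<8s}"
                         + "  ".join(f"{self.emissions[k, m]:8.3f}"
                                     for m in range(len(self.marks))))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "emissions": self.emissions.tolist(),
            "marks": list(self.marks),
            "labels": self.state_labels,
            "log_likelihood": self.log_likelihood,
        }


@njit(cache=True)
def _viterbi(startprob, transmat, frame_prob):
    T, K = frame_prob.shape
    logd = np.log(startprob + 1e-300) + np.log(frame_prob[0] + 1e-300)
    back = np.zeros((T, K), dtype=np.int32)
    logT = np.log(transmat + 1e-300)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best, arg = -1e308, 0
            for i in range(K):
                v = logd[i] + logT[i, j]
                if v > best:
                    best, arg = v, i
            new[j] = best + np.log(frame_prob[t, j] + 1e-300)
            back[t, j] = arg
        logd = new
    path = np.empty(T, dtype=np.int32)
    path[T - 1] = np.argmax(logd)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Segmentation and derived summaries

@dataclass
class Segmentation:
    """Per-bin state ids for one tissue plus label metadata."""

    states: dict[str, np.ndarray]  # chrom -> int per bin
    bin_size: int
    labels: list[str] | None = None

    @property
    def chroms(self) -> list[str]:
        return sorted(self.states)

    def state_intervals(self, state: int | str) -> IntervalSet:
        """Merged genomic intervals occupied by one state (id or label)."""
        if isinstance(state, str):
            if self.labels is None:
                raise ValueError("segmentation carries no labels")
            state = self.labels.index(state)
        ivs = []
        for chrom in self.chroms:
            s = self.states[chrom]
            hits = np.flatnonzero(s == state)
            if len(hits) == 0:
                continue
            breaks = np.flatnonzero(np.diff(hits) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(hits) - 1]))
            for a, b in zip(starts, ends):
                ivs.append(GenomicInterval(chrom, int(hits[a]) * self.bin_size,
                                           (int(hits[b]) + 1) * self.bin_size))
        return IntervalSet(ivs)


def train_hmm(data: Sequence[BinaryMarks], n_states: int = 6, n_restarts: int = 5,
              seed: int | None = None, **kwargs) -> HMMResults:
    return BernoulliHMM(n_states, n_restarts, seed=seed, **kwargs).fit(data)


def decode_states(result: HMMResults, marks: BinaryMarks,
                  method: str = "posterior") -> Segmentation:
    return result.decode(marks, method=method)


def label_states(emissions: np.ndarray, marks: tuple[str, ...] = MARKS) -> list[str]:
    """Rule-based labels from emission probabilities.

    With (ATAC, H3K4me3, H3K27ac) emission rows, in priority order:
    K4 >= 0.5 and K27ac >= 0.5 -> TssA; K4 >= 0.5 -> TssW; ATAC >= 0.5 and
    K27ac >= 0.5 -> EnhA; 0.2 <= K27ac < 0.5 -> EnhAW; ATAC >= 0.5 alone ->
    ATAC_Is; else Quies. Duplicate labels for a 6-state model are resolved
    by a best-match assignment to label prototypes (largest margin wins),
    with a warning.
    """
    emissions = np.asarray(emissions, dtype=float)
    ia, ik4, ik27 = (marks.index(m) for m in MARKS)

    def rule(row) -> str:
        atac, k4, k27 = row[ia], row[ik4], row[ik27]
        if k4 >= 0.5 and k27 >= 0.5:
            return "TssA"
        if k4 >= 0.5:
            return "TssW"
        if atac >= 0.5 and k27 >= 0.5:
            return "EnhA"
        if 0.2 <= k27 < 0.5:
            return "EnhAW"
        if atac >= 0.5:
            return "ATAC_Is"
        return "Quies"

    labels = [rule(row) for row in emissions]
    if len(labels) == len(set(labels)):
        return labels
    if emissions.shape[0] != len(STATE_LABELS):
        # non-6-state models keep duplicates, disambiguated by suffix
        warnings.warn("duplicate state labels; appending indices")
        seen: dict[str, int] = {}
        out = []
        for lab in labels:
            seen[lab] = seen.get(lab, 0) + 1
            out.append(lab if seen[lab] == 1 else f"{lab}.{seen[lab]}")
        return out
    warnings.warn("duplicate state labels; resolving by prototype assignment")
    prototypes = {
        "TssA": (0.9, 0.9, 0.9), "TssW": (0.5, 0.9, 0.1), "EnhA": (0.9, 0.05, 0.9),
        "EnhAW": (0.5, 0.05, 0.35), "ATAC_Is": (0.9, 0.05, 0.05),
        "Quies": (0.05, 0.05, 0.05),
    }
    from scipy.optimize import linear_sum_assignment

    order = [ia, ik4, ik27]
    cost = np.array([[np.sum((emissions[k, order] - np.array(prototypes[lab])) ** 2)
                      for lab in STATE_LABELS] for k in range(len(STATE_LABELS))])
    rows, cols = linear_sum_assignment(cost)
    out = [""] * len(STATE_LABELS)
    for r, c in zip(rows, cols):
        out[r] = STATE_LABELS[c]
    return out


def state_coverage(seg: Segmentation) -> pd.Series:
    """Fraction of binned genome assigned to each state (sums to 1)."""
    n_states = (seg.labels and len(seg.labels)) or int(
        max(s.max() for s in seg.states.values())) + 1
    counts = np.zeros(n_states)
    for s in seg.states.values():
        counts += np.bincount(s, minlength=n_states)
    frac = counts / counts.sum()
    index = seg.labels if seg.labels else list(range(n_states))
    return pd.Series(frac, index=index, name="coverage")


def tss_profile(values: dict[str, np.ndarray], bin_size: int,
                genes: Sequence[GeneModel], flank: int = 2000) -> pd.DataFrame:
    """Strand-aware average of a binned per-bin value around gene TSSs.

    `values` is any per-bin vector per chromosome (a mark track, or a 0/1
    indicator of one chromatin state). Genes whose window leaves the
    chromosome are skipped. Returns offsets (bp, TSS-centred) and means.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    half = flank // bin_size
    rows = []
    for g in genes:
        if g.chrom not in values:
            continue
        v = values[g.chrom]
        b = (g.tss - 1) // bin_size
        if b - half < 0 or b + half >= len(v):
            continue
        win = v[b - half: b + half + 1].astype(float)
        if g.strand == "-":
            win = win[::-1]
        rows.append(win)
    if not rows:
        raise ValueError("no gene window fits inside the genome")
    mean = np.mean(rows, axis=0)
    offsets = (np.arange(-half, half + 1)) * bin_size
    return pd.DataFrame({"offset": offsets, "mean": mean, "n_genes": len(rows)})


def merge_nonredundant(per_tissue: dict[str, IntervalSet]) -> IntervalSet:
    """Union of one state's intervals across tissues, merged when overlapping
    or book-ended (bedtools-merge semantics)."""
    ivs = [iv for s in per_tissue.values() for iv in s]
    return IntervalSet(merge_intervals(ivs))


def call_tissue_specific(nonredundant: IntervalSet,
                         per_tissue: dict[str, IntervalSet]) -> pd.DataFrame:
    """Presence matrix of nonredundant elements across tissues.

    Presence is >= 1 bp of overlap. Adds element length, the number of
    tissues carrying the element, and a category: 'specific' (exactly one
    tissue; `tissue` names it), 'common' (all tissues), else 'shared'.
    """
    tissues = list(per_tissue)
    if len(tissues) < 2:
        raise ValueError("tissue-specificity needs >= 2 tissues")
    elements = list(nonredundant.merged())
    data = {}
    for t in tissues:
        starts_ends = per_tissue[t]
        pres = np.zeros(len(elements), dtype=int)
        for i, iv in enumerate(elements):
            s, e = starts_ends.arrays(iv.chrom)
            pres[i] = int(np.any((s < iv.end) & (e > iv.start)))
        data[t] = pres
    df = pd.DataFrame(data, index=[f"{iv.chrom}:{iv.start}-{iv.end}" for iv in elements])
    n_tissues = df.sum(axis=1)
    df["length"] = [iv.length for iv in elements]
    df["n_tissues"] = n_tissues
    df["category"] = np.where(n_tissues == 1, "specific",
                              np.where(n_tissues == len(tissues), "common", "shared"))
    df["tissue"] = [
        tissues[int(np.argmax([data[t][i] for t in tissues]))] if n == 1 else None
        for i, n in enumerate(n_tissues)
    ]
    return df


def variability_curve(presence: pd.DataFrame, n_tissues: int | None = None
                      ) -> tuple[pd.Series, int]:
    """Cumulative bp fraction of elements present in <= k tissues.

    Input is the frame from `call_tissue_specific` (needs `n_tissues` and
    `length` columns). Returns (f(k) for k = 1..n, min k with f(k) >= 0.75).
    f is non-decreasing with f(n) = 1; a small summary k means the state is
    highly tissue-variable.
    """
    if n_tissues is None:
        n_tissues = int(presence["n_tissues"].max())
    total = presence["length"].sum()
    if total == 0:
        raise ValueError("empty presence matrix")
    f = pd.Series(
        [presence.loc[presence["n_tissues"] <= k, "length"].sum() / total
         for k in range(1, n_tissues + 1)],
        index=pd.RangeIndex(1, n_tissues + 1, name="k"), name="cum_fraction",
    )
    summary = int(f.index[np.argmax(f.to_numpy() >= 0.75)]) if (f >= 0.75).any() else n_tissues
    return f, summary
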