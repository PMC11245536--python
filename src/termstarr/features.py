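"""Sequence-composition and motif analytics.

Links terminator sequence to measured strength: GC content and windowed
base-composition correlations, the full 4^k k-mer occurrence matrix and
per-system k-mer strength rankings, PWM motif scanning with min-max
normalized log-odds scores, and the rank-sum significance machinery.

k-mer counting is single-stranded (RNA-sense): terminators act at the RNA
level, so reverse complements are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqlib import BASES

MATCH_THRESHOLD = 0.85
PWM_FLOOR = 1e-4

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def gc_content(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def bin_equal_size(values: Mapping[str, float], n_bins: int) -> dict[str, int]:
    """Quantile bins of approximately equal size; bin 0 holds the lowest values.

    Ties in value are broken deterministically by key so that bin sizes differ
    by at most one whenever the values are distinct.
    """
    if n_bins > len(set(values.values())):
        raise ValueError("n_bins exceeds the number of distinct values")
    ordered = sorted(values, key=lambda k: (values[k], k))
    n = len(ordered)
    assignment = {}
    for i, key in enumerate(ordered):
        assignment[key] = min(i * n_bins // n, n_bins - 1)
    return assignment


def _onehot_stack(sequences: Sequence[str]) -> np.ndarray:
    """(N, L) uint8 base-index array for equal-length sequences."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), lengths.pop())
    idx = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[ord(b)] = i
    out = idx[arr]
    if (out < 0).any():
        raise ValueError("non-ACGT characters in sequences")
    return out.astype(np.uint8)


@dataclass
class WindowCorrelationProfile:
    """Pearson r between strength and windowed base content.

    ``r[base_index, start]`` for 0-based window starts; NaN marks windows with
    zero-variance composition (undefined correlation, never coerced to 0).
    """

    window_width: int
    r: np.ndarray  # (4, L - width + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, base in enumerate(BASES):
            for start in range(self.r.shape[1]):
                rows.append({"base": base, "start": start + 1,
                             "r": self.r[bi, start]})
        return pd.DataFrame(rows)


def windowed_composition_correlation(sequences: Sequence[str],
                                     strengths: Sequence[float],
                                     width: int = 10) -> WindowCorrelationProfile:
    """Correlate per-window base fractions with strength at every start."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    idx = _onehot_stack(sequences)
    y = np.asarray(strengths, dtype=float)
    if len(y) != len(sequences):
        raise ValueError("strengths length mismatch")
    n, L = idx.shape
    n_windows = L - width + 1
    r = np.full((4, n_windows), np.nan)
    y_c = y - y.mean()
    y_ss = (y_c**2).sum()
    for bi in range(4):
        ind = (idx == bi).astype(float)
        csum = np.concatenate([np.zeros((n, 1)), np.cumsum(ind, axis=1)], axis=1)
        frac = (csum[:, width:] - csum[:, :-width]) / width  # (n, n_windows)
        x_c = frac - frac.mean(axis=0)
        x_ss = (x_c**2).sum(axis=0)
        valid = (x_ss > 0) & (y_ss > 0)
        num = (x_c * y_c[:, None]).sum(axis=0)
        r[bi, valid] = num[valid] / np.sqrt(x_ss[valid] * y_ss)
    return WindowCorrelationProfile(window_width=width, r=r)


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------

def kmer_universe(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (ACGT) order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


@dataclass
class KmerMatrix:
    ids: list[str]
    k: int
    counts: np.ndarray  # (n_sequences, 4^k)

    @property
    def columns(self) -> list[str]:
        return kmer_universe(self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.columns)


def count_kmers(sequences: Sequence[str], k: int = 6,
                ids: Sequence[str] | None = None) -> KmerMatrix:
    """Overlapping forward-strand k-mer counts for each sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = _onehot_stack(sequences).astype(np.int64)
    n, L = idx.shape
    if L < k:
        raise ValueError("sequences shorter than k")
    # rolling base-4 encoding of every k-mer start
    codes = np.zeros((n, L - k + 1), dtype=np.int64)
    for j in range(k):
        codes += idx[:, j:L - k + 1 + j] * 4 ** (k - 1 - j)
    counts = np.zeros((n, 4**k), dtype=np.int64)
    for i in range(n):
        counts[i] = np.bincount(codes[i], minlength=4**k)
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(n)]
    return KmerMatrix(ids=ids, k=k, counts=counts)


def kmer_strength_ranks(matrix: KmerMatrix,
                        strengths: Mapping[str, Sequence[float]]):
    """Per-system k-mer rank lists and cross-system rank conservation.

    For each system, every k-mer is scored by the Pearson correlation between
    its per-sequence count and strength; rank 1 is the most positively
    correlated k-mer.  Constant k-mer columns are excluded.  Returns
    ``(ranks_frame, spearman_rho, divergence_frame)`` where the divergence
    frame lists k-mers by largest cross-system rank difference (only computed
    when exactly two systems are given).
    """
    systems = list(strengths)
    X = matrix.counts.astype(float)
    x_c = X - X.mean(axis=0)
    x_ss = (x_c**2).sum(axis=0)
    variable = x_ss > 0
    kmers = np.array(matrix.columns)

    cols = {}
    for system in systems:
        y = np.asarray(strengths[system], dtype=float)
        if len(y) < 3:
            raise ValueError("need >= 3 sequences")
        y_c = y - y.mean()
        y_ss = (y_c**2).sum()
        r = np.full(X.shape[1], np.nan)
        r[variable] = (x_c[:, variable] * y_c[:, None]).sum(axis=0) / np.sqrt(
            x_ss[variable] * y_ss)
        cols[system] = r

    df = pd.DataFrame({"kmer": kmers[variable]})
    for system in systems:
        r = cols[system][variable]
        df[f"r_{system}"] = r
        # rank 1 = most positive correlation
        df[f"rank_{system}"] = (-df[f"r_{system}"]).rank(method="first").astype(int)

    rho = None
    divergence = None
    if len(systems) == 2:
        a, b = systems
        rho = float(stats.spearmanr(df[f"rank_{a}"], df[f"rank_{b}"]).statistic)
        df["rank_diff"] = df[f"rank_{a}"] - df[f"rank_{b}"]
        divergence = df.reindex(
            df["rank_diff"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return df, rho, divergence


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """A probability-matrix motif with a background for log-odds scoring."""

    name: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    background: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("motif matrix rows must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, PWM_FLOOR)
        return np.log2(p / self.background)

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       pseudo: float = 0.0) -> "MotifModel":
        consensus = consensus.upper().replace("U", "T")
        mat = np.full((len(consensus), 4), pseudo / 3 if pseudo else 0.0)
        for i, b in enumerate(consensus):
            mat[i] = pseudo / 3 if pseudo else 0.0
            mat[i, _BASE_INDEX[b]] = 1.0 - pseudo
        return cls(name, mat)


def scan_motif(sequence: str, motif: MotifModel,
               threshold: float = MATCH_THRESHOLD):
    """Best normalized log-odds motif score over all offsets.

    The maximum score over offsets is normalized so the weakest possible
    sequence scores 0 and the consensus scores 1; a sequence is a match when
    the normalized score reaches ``threshold`` (default 0.85).

    Returns ``(normalized_max_score, best_offset_0based, is_match)``.
    """
    lo = motif.log_odds()
    w = motif.width
    if len(sequence) < w:
        raise ValueError("motif wider than sequence")
    seq_idx = _onehot_stack([sequence.upper().replace("U", "T")])[0]
    scores = np.array([
        lo[np.arange(w), seq_idx[i:i + w]].sum()
        for i in range(len(sequence) - w + 1)
    ])
    min_possible = lo.min(axis=1).sum()
    max_possible = lo.max(axis=1).sum()
    if max_possible == min_possible:
        raise ValueError("degenerate motif: constant score")
    norm = (scores - min_possible) / (max_possible - min_possible)
    best = int(np.argmax(norm))
    return float(norm[best]), best, bool(norm[best] >= threshold)


def motif_positional_profile(sequences: Sequence[str], motif: MotifModel,
                             threshold: float = MATCH_THRESHOLD) -> np.ndarray:
    """Fraction of sequences with a motif match starting at each offset."""
    lo = motif.log_odds()
    w = motif.width
    idx = _onehot_stack([s.upper().replace("U", "T") for s in sequences])
    n, L = idx.shape
    min_possible = lo.min(axis=1).sum()
    max_possible = lo.max(axis=1).sum()
    profile = np.zeros(L - w + 1)
    for start in range(L - w + 1):
        s = np.zeros(n)
        for j in range(w):
            s += lo[j, idx[:, start + j]]
        norm = (s - min_possible) / (max_possible - min_possible)
        profile[start] = (norm >= threshold).mean()
    return profile


def group_compare(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution for small tie-free groups (both n <= 25), normal
    approximation with tie correction otherwise.  Returns the rank-sum
    statistic W of the first group and the two-sided p value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    w = float(res.statistic + len(a) * (len(a) + 1) / 2)  # U -> rank sum of a
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# MEME minimal format IO
# ---------------------------------------------------------------------------

def read_meme(path) -> list[MotifModel]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        pwm = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out.append(MotifModel(m.name, pwm))
    return out


def write_meme(motif_models: Iterable[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motif_models:
            fh.write(f"MOTIF {m.name}\n")
            # large nsites so count-based parsers keep full precision
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 1000000 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
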