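"""Cleavage/polyadenylation-site calling from 3'-end reads.

Reads are poly-A trimmed, assigned to designed library members by unique
prefix matching (the designed insert plus 52 nt of plasmid backbone), and
deduplicated on (terminator, UMI).  Per terminator, the histogram of unique
molecule lengths is scanned for local maxima; the cleavage probability is the
fraction of unique molecules cleaved within the 170-nt insert (length < 171)
rather than reading through into the backbone.

A molecule cut at the designed cleavage site has length 150: read length is
the 1-based length of the retained prefix, so "cleavage position" and length
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqlib import BASES, TERMINATOR_LENGTH, TerminatorRecord
from .synthio import BACKBONE_LENGTH

MIN_SUPPORTING_READS = 20
SECONDARY_THRESHOLD = 0.30
MIN_SITE_FRACTION = 0.05
MIN_SEPARATION = 5
SMOOTH_WINDOW = 3
PEAK_FLANK = 2          # raw-count site fraction measured within +-2 nt
DESIGNED_WINDOW = 5     # "position 150 +- 5 bp" classification interval
MAX_MISMATCH = 2


@dataclass(frozen=True)
class ThreePrimeRead:
    sequence: str
    umi: str

    def __post_init__(self):
        if len(self.umi) != 8:
            raise ValueError("UMI must be 8 nt")


@dataclass
class Site:
    position: int      # 1-based molecule length at the peak
    fraction: float    # raw-count fraction within +-PEAK_FLANK of the peak
    rank: int          # 1 = primary


@dataclass
class CleavageProfile:
    terminator_id: str
    length_histogram: dict[int, int]
    total_unique: int
    sites: list[Site] = field(default_factory=list)
    cleavage_probability: float | None = None

    @property
    def primary_site(self) -> Site | None:
        return self.sites[0] if self.sites else None


# ---------------------------------------------------------------------------
# read processing
# ---------------------------------------------------------------------------

def trim_polya(read: str, min_tail: int = 5, mismatch_per10: int = 1,
               anchor: int = 10) -> str:
    """Remove the maximal 3'-terminal poly-A run.

    A tail must be at least ``min_tail`` long, begin with a clean A run of
    ``anchor`` bases (or its full length, if shorter), and may contain at most
    ``mismatch_per10`` non-A bases per 10 tail bases beyond that anchor.
    Returns the read with the longest valid tail removed.
    """
    n = len(read)
    for i in range(n - min_tail + 1):
        tail = read[i:]
        head = tail[: min(anchor, len(tail))]
        if head != "A" * len(head):
            continue
        non_a = sum(1 for b in tail if b != "A")
        if non_a <= (len(tail) // 10) * mismatch_per10:
            return read[:i]
    return read


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    arr = np.zeros((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = np.frombuffer(s[:length].encode(), dtype=np.uint8)
    return arr


def assign_reads(reads: Sequence[str], library: Sequence[TerminatorRecord],
                 backbone: str, max_mismatch: int = MAX_MISMATCH,
                 chunk: int = 512) -> list[tuple[str, int] | None]:
    """Assign poly-A-trimmed reads to library members by prefix matching.

    Each read is compared against the prefix of every terminator sequence
    extended with the plasmid backbone; the unique best hit with at most
    ``max_mismatch`` Hamming mismatches wins, and its cleavage length is the
    trimmed read length.  Reads whose best hit is tied between two or more
    references are left unassigned (ambiguity rejection).
    """
    refs = [rec.sequence + backbone for rec in library]
    ids = [rec.terminator_id for rec in library]
    max_len = max(len(r) for r in refs)
    ref_arr = _encode(refs, max_len)
    ref_lens = np.array([len(r) for r in refs])

    results: list[tuple[str, int] | None] = [None] * len(reads)
    order = np.argsort([len(r) for r in reads], kind="stable")
    by_len: dict[int, list[int]] = {}
    for i in order:
        by_len.setdefault(len(reads[i]), []).append(i)

    for L, idxs in by_len.items():
        if L == 0 or L > max_len:
            continue
        valid_refs = np.where(ref_lens >= L)[0]
        if valid_refs.size == 0:
            continue
        sub = ref_arr[valid_refs, :L]
        for c0 in range(0, len(idxs), chunk):
            batch = idxs[c0:c0 + chunk]
            reads_arr = _encode([reads[i] for i in batch], L)
            mm = (reads_arr[:, None, :] != sub[None, :, :]).sum(axis=2)
            best = mm.min(axis=1)
            for row, i in enumerate(batch):
                if best[row] > max_mismatch:
                    continue
                hits = np.where(mm[row] == best[row])[0]
                if len(hits) != 1:
                    continue
                results[i] = (ids[valid_refs[hits[0]]], L)
    return results


def dedup_umi(assigned: Iterable[tuple[str, str, int]]) -> list[tuple[str, str, int]]:
    """Collapse PCR duplicates: one molecule per (terminator, UMI) pair.

    Input triples are (terminator_id, umi, cleavage_length).  Distinct lengths
    sharing a UMI collapse to the modal length; ties go to the shortest.
    """
    groups: dict[tuple[str, str], dict[int, int]] = {}
    for tid, umi, length in assigned:
        groups.setdefault((tid, umi), {})
        groups[(tid, umi)][length] = groups[(tid, umi)].get(length, 0) + 1
    out = []
    for (tid, umi), lengths in groups.items():
        modal = min(lengths, key=lambda L: (-lengths[L], L))
        out.append((tid, umi, modal))
    return out


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def call_sites(histogram: Mapping[int, int],
               secondary_threshold: float = SECONDARY_THRESHOLD,
               min_site_fraction: float = MIN_SITE_FRACTION,
               min_separation: int = MIN_SEPARATION,
               smooth_window: int = SMOOTH_WINDOW) -> list[Site]:
    """Call cleavage sites as local maxima of the read-length distribution.

    The histogram is smoothed with a centered moving average before locating
    local maxima; candidate peaks closer than ``min_separation`` to a
    stronger peak are suppressed, and a site's fraction is the raw-count
    share within +-2 nt of the peak.  Sites are returned by decreasing
    fraction; rank 1 is the primary site.
    """
    if not histogram:
        raise ValueError("empty length histogram")
    total = sum(histogram.values())
    max_len = max(histogram)
    counts = np.zeros(max_len + smooth_window + PEAK_FLANK + 2)
    for L, c in histogram.items():
        if L < 1:
            raise ValueError("read lengths must be >= 1")
        counts[L] = c
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts, kernel, mode="same")

    # local maxima of the smoothed curve, each snapped to the raw-count
    # argmax within the smoothing half-window so the reported position is an
    # observed read length
    half = smooth_window // 2
    snapped: dict[int, float] = {}
    for pos in range(1, max_len + 1):
        if smoothed[pos] <= 0:
            continue
        if smoothed[pos] >= smoothed[pos - 1] and smoothed[pos] >= smoothed[pos + 1]:
            lo = max(1, pos - half)
            hi = min(max_len, pos + half)
            local = counts[lo:hi + 1]
            peak = lo + int(np.argmax(local))
            if counts[peak] <= 0:
                continue
            flo, fhi = max(1, peak - PEAK_FLANK), peak + PEAK_FLANK
            snapped[peak] = counts[flo:fhi + 1].sum() / total

    # stronger peaks win within the separation radius; ties break by raw
    # count at the peak, then by position, for determinism
    candidates = sorted(snapped.items(),
                        key=lambda t: (-t[1], -counts[t[0]], t[0]))
    sites: list[Site] = []
    for pos, frac in candidates:
        if frac < min_site_fraction:
            continue
        if any(abs(pos - s.position) < min_separation for s in sites):
            continue
        sites.append(Site(position=pos, fraction=float(frac), rank=0))
    sites.sort(key=lambda s: (-s.fraction, s.position))
    for r, s in enumerate(sites, start=1):
        s.rank = r
    return sites


def cleavage_probability(histogram: Mapping[int, int],
                         insert_length: int = TERMINATOR_LENGTH) -> float:
    """Fraction of unique molecules cleaved within the insert (length < 171)."""
    total = sum(histogram.values())
    if total == 0:
        raise ValueError("empty length histogram")
    cleaved = sum(c for L, c in histogram.items() if L <= insert_length)
    return cleaved / total


def build_profiles(molecules: Iterable[tuple[str, str, int]],
                   min_reads: int = MIN_SUPPORTING_READS,
                   **call_kwargs) -> dict[str, CleavageProfile]:
    """Per-terminator profiles from deduplicated molecules.

    Terminators with fewer than ``min_reads`` unique molecules are discarded.
    """
    hists: dict[str, dict[int, int]] = {}
    for tid, _umi, length in molecules:
        hists.setdefault(tid, {})
        hists[tid][length] = hists[tid].get(length, 0) + 1
    profiles = {}
    for tid, hist in hists.items():
        total = sum(hist.values())
        if total < min_reads:
            continue
        prof = CleavageProfile(terminator_id=tid, length_histogram=hist,
                               total_unique=total)
        prof.sites = call_sites(hist, **call_kwargs)
        prof.cleavage_probability = cleavage_probability(hist)
        profiles[tid] = prof
    return profiles


def run_pipeline(reads: Sequence[tuple[str, str]], library: Sequence[TerminatorRecord],
                 backbone: str, min_reads: int = MIN_SUPPORTING_READS,
                 max_mismatch: int = MAX_MISMATCH) -> dict[str, CleavageProfile]:
    """Full 3'-end pipeline: trim, assign, deduplicate, call sites."""
    trimmed = [trim_polya(seq) for seq, _ in reads]
    assignments = assign_reads(trimmed, library, backbone, max_mismatch=max_mismatch)
    triples = [
        (a[0], umi, a[1])
        for a, (_, umi) in zip(assignments, reads)
        if a is not None
    ]
    molecules = dedup_umi(triples)
    return build_profiles(molecules, min_reads=min_reads)


# ---------------------------------------------------------------------------
# classification and context
# ---------------------------------------------------------------------------

CLASSIFICATION_FLAGS = (
    "site_at_150pm5", "primary_at_150pm5", "multiple_sites",
    "strong_secondary", "tDNA_only",
)


def classify_profile(profile: CleavageProfile,
                     designed_position: int = 150,
                     window: int = DESIGNED_WINDOW,
                     secondary_threshold: float = SECONDARY_THRESHOLD,
                     insert_length: int = TERMINATOR_LENGTH) -> dict[str, bool]:
    """Five-way cleavage-pattern flags for one terminator.

    A site counts as "at the designed position" when it lies within the
    inclusive interval [145, 155]; "tDNA only" means every called site is in
    the backbone (length > 170).
    """
    lo, hi = designed_position - window, designed_position + window
    sites = profile.sites
    return {
        "site_at_150pm5": any(lo <= s.position <= hi for s in sites),
        "primary_at_150pm5": bool(sites) and lo <= sites[0].position <= hi,
        "multiple_sites": len(sites) >= 2,
        "strong_secondary": any(
            s.fraction >= secondary_threshold for s in sites[1:]
        ),
        "tDNA_only": bool(sites) and all(s.position > insert_length for s in sites),
    }


def classify_profiles(profiles: Mapping[str, CleavageProfile],
                      groups: Mapping[str, str] | None = None,
                      **kwargs) -> pd.DataFrame:
    """Per-group counts and percentages of the five cleavage-pattern flags."""
    rows = []
    for tid, prof in profiles.items():
        flags = classify_profile(prof, **kwargs)
        flags["terminator_id"] = tid
        flags["group"] = groups.get(tid, "all") if groups else "all"
        rows.append(flags)
    df = pd.DataFrame(rows)
    out = []
    for group, grp in df.groupby("group"):
        row = {"group": group, "n": len(grp)}
        for flag in CLASSIFICATION_FLAGS:
            row[flag] = int(grp[flag].sum())
            row[f"{flag}_pct"] = 100.0 * grp[flag].mean()
        out.append(row)
    return pd.DataFrame(out)


def site_context(profiles: Mapping[str, CleavageProfile],
                 sequences: Mapping[str, str], window: int = 10,
                 which: str = "all", backbone: str = ""):
    """Base-frequency matrix around called cleavage sites.

    The window covers ``window // 2`` positions up to and including the site
    base plus ``window - window // 2`` positions downstream (for the default
    10: site positions -4..+5 relative to the cut base).  Sites whose window
    would run off the available sequence are skipped and counted.

    Returns ``(freq_matrix (window, 4), n_sites_used, n_skipped)``.
    """
    upstream = window // 2
    counts = np.zeros((window, 4))
    used = skipped = 0
    base_index = {b: i for i, b in enumerate(BASES)}
    for tid, prof in profiles.items():
        seq = sequences.get(tid)
        if seq is None:
            continue
        full = seq + backbone
        for site in prof.sites:
            if which == "primary" and site.rank != 1:
                continue
            if which == "secondary" and site.rank == 1:
                continue
            start = site.position - upstream  # 1-based window start
            stop = start + window - 1
            if start < 1 or stop > len(full):
                skipped += 1
                continue
            for off, b in enumerate(full[start - 1:stop]):
                counts[off, base_index[b]] += 1
            used += 1
    freqs = counts / counts.sum(axis=1, keepdims=True) if used else counts
    return freqs, used, skipped


def profiles_frame(profiles: Mapping[str, CleavageProfile]) -> pd.DataFrame:
    rows = []
    for tid, prof in profiles.items():
        for s in prof.sites:
            rows.append({
                "terminator_id": tid, "position": s.position,
                "fraction": s.fraction, "rank": s.rank,
                "total_unique": prof.total_unique,
                "cleavage_probability": prof.cleavage_probability,
            })
    return pd.DataFrame(rows)
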