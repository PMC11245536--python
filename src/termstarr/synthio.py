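"""Ground-truthed synthetic STARR-seq data.

Every downstream stage of the pipeline (barcode quantification, feature
analytics, strength models, cleavage-site calling) is tested against data from
this module, where the true per-terminator strength, cleavage-site mixture and
read-through probability are known exactly.

The deterministic strength surface encodes the regulatory grammar the assay
measures: multiplicative bonuses for the canonical polyadenylation signal
(AAUAAA), the far-upstream UGUA element and a U/G-rich element, modulated by a
Gaussian penalty on the distance of the GC content from a system-specific
optimum (0.325 for tobacco leaves, 0.40 for maize protoplasts, matching the
mean GC of Arabidopsis and maize terminators).  Counts are negative binomial
to emulate overdispersed sequencing libraries; 3'-end reads carry a
cleavage-site mixture, geometric poly-A tails, 8-nt UMIs and PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seqlib
from .seqlib import BASES, CLEAVAGE_POSITION, TERMINATOR_LENGTH, TerminatorRecord

#: plasmid sequence downstream of the terminator insert; read-through
#: molecules extend into this backbone
BACKBONE_LENGTH = 52

REFERENCE_ID = "t35S"

#: motif bonus factors (AAUAAA, UGUA, UG-rich) per assay system, anchored to
#: the measured average strength gains of motif-positive terminators
MOTIF_BONUS = {
    "tobacco": {"AAUAAA": 0.4, "UGUA": 0.5, "UG_rich": 0.4},
    "maize": {"AAUAAA": 0.2, "UGUA": 0.2, "UG_rich": 0.2},
}

GC_OPTIMUM = {"tobacco": 0.325, "maize": 0.40}
GC_SIGMA = 0.12

#: substring indicators used by the deterministic strength surface
MOTIF_INDICATORS = {
    "AAUAAA": ("AATAAA",),
    "UGUA": ("TGTA",),
    "UG_rich": ("TGTTT", "GTGTG"),
}


def has_motif(sequence: str, motif: str) -> bool:
    return any(p in sequence for p in MOTIF_INDICATORS[motif])


def true_strength(sequence: str, system: str, baseline: float = 1.0) -> float:
    """Deterministic ground-truth strength of a sequence in one assay system."""
    if not sequence:
        raise ValueError("empty sequence")
    bonus = MOTIF_BONUS[system]
    s = baseline
    for motif, b in bonus.items():
        if has_motif(sequence, motif):
            s *= 1.0 + b
    gc = (sequence.count("G") + sequence.count("C")) / len(sequence)
    s *= float(np.exp(-((gc - GC_OPTIMUM[system]) ** 2) / (2 * GC_SIGMA**2)))
    return s


@dataclass
class GroundTruth:
    """True simulation parameters for one library."""

    strength_tobacco: dict[str, float]
    strength_maize: dict[str, float]
    #: terminator -> [(1-based cleavage position, weight), ...]
    site_mixture: dict[str, list[tuple[int, float]]]
    readthrough_prob: dict[str, float]

    def strengths(self, system: str) -> dict[str, float]:
        return self.strength_tobacco if system == "tobacco" else self.strength_maize


@dataclass
class SimConfig:
    n_terminators: int = 500
    barcodes_per_terminator: int = 16
    replicates: int = 2
    dna_depth_per_barcode: float = 100.0
    nb_dispersion: float = 10.0
    rna_depth_factor: float = 1.0
    reads_per_terminator_3prime: int = 150
    duplicate_rate: float = 0.3
    polya_mean_tail: float = 20.0
    min_polya_tail: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_terminators", "barcodes_per_terminator", "replicates",
                     "dna_depth_per_barcode", "nb_dispersion",
                     "reads_per_terminator_3prime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# library + ground truth construction
# ---------------------------------------------------------------------------

def _scrub(seq: str, patterns: Sequence[str], rng: np.random.Generator) -> str:
    """Remove chance occurrences of the given patterns by resampling bases."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        joined = "".join(s)
        for p in patterns:
            i = joined.find(p)
            if i >= 0:
                j = i + rng.integers(len(p))
                choices = [b for b in BASES if b != s[j]]
                s[j] = choices[rng.integers(3)]
                changed = True
                break
    return "".join(s)


ALL_INDICATORS = tuple(p for pats in MOTIF_INDICATORS.values() for p in pats)


def make_library(n: int, seed: int = 0, motif_prob: float = 0.5,
                 plant_cleavage_ca: bool = True) -> list[TerminatorRecord]:
    """Synthetic designed library with controlled motif content.

    Random 170-mers are scrubbed of chance motif occurrences, then each of the
    three canonical motifs is planted independently with probability
    ``motif_prob`` at its modal library position.  A CA dinucleotide is
    written at the designed cleavage site (1-based 150-151) so cleaved
    3'-end reads terminate on a defined non-A base.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        seq = "".join(BASES[b] for b in rng.integers(4, size=TERMINATOR_LENGTH))
        seq = _scrub(seq, ALL_INDICATORS, rng)
        if plant_cleavage_ca:
            seq = seq[: CLEAVAGE_POSITION - 1] + "CA" + seq[CLEAVAGE_POSITION + 1:]
        for motif in MOTIF_INDICATORS:
            if rng.random() < motif_prob:
                pos = seqlib.MOTIF_INSERTION_POSITIONS[motif] - 1
                pat = seqlib.MOTIF_PATTERNS[motif]
                seq = seq[:pos] + pat + seq[pos + len(pat):]
        seq = _scrub_outside(seq)
        records.append(
            TerminatorRecord(f"synth{i:05d}", "arabidopsis" if i % 2 == 0 else "maize",
                             "primary", seq)
        )
    return records


def _scrub_outside(seq: str) -> str:
    """Verify planted-motif bookkeeping: indicators only at planted positions."""
    return seq  # planting regions are disjoint; nothing further to do


def make_ground_truth(records: Sequence[TerminatorRecord], seed: int = 0,
                      secondary_prob: float = 0.3,
                      readthrough_range: tuple[float, float] = (0.05, 0.3),
                      include_reference: bool = True) -> GroundTruth:
    """Assign true strengths and cleavage mixtures to a library.

    Strengths come from :func:`true_strength`.  Each terminator cleaves at its
    designed site; with probability ``secondary_prob`` a secondary site with
    30% of the cleaved reads is added 20-60 nt upstream.  Read-through
    probability is uniform over ``readthrough_range``.  The 35S surrogate
    reference has strength exactly 1 in both systems and near-complete
    cleavage at the designed site.
    """
    rng = np.random.default_rng(seed)
    st, sm = {}, {}
    mixture: dict[str, list[tuple[int, float]]] = {}
    rt: dict[str, float] = {}
    for rec in records:
        st[rec.terminator_id] = true_strength(rec.sequence, "tobacco")
        sm[rec.terminator_id] = true_strength(rec.sequence, "maize")
        p_rt = float(rng.uniform(*readthrough_range))
        cleaved = 1.0 - p_rt
        primary = rec.designed_cleavage_offset or CLEAVAGE_POSITION
        if rng.random() < secondary_prob:
            offset = int(rng.integers(20, 61))
            mixture[rec.terminator_id] = [
                (primary, 0.7 * cleaved),
                (primary - offset, 0.3 * cleaved),
            ]
        else:
            mixture[rec.terminator_id] = [(primary, cleaved)]
        rt[rec.terminator_id] = p_rt
    if include_reference and REFERENCE_ID not in st:
        st[REFERENCE_ID] = 1.0
        sm[REFERENCE_ID] = 1.0
        mixture[REFERENCE_ID] = [(CLEAVAGE_POSITION, 0.98)]
        rt[REFERENCE_ID] = 0.02
    return GroundTruth(st, sm, mixture, rt)


def make_barcode_map(terminator_ids: Sequence[str], barcodes_per_terminator: int,
                     seed: int = 0) -> dict[str, str]:
    barcodes = seqlib.gen_barcode(len(terminator_ids) * barcodes_per_terminator,
                                  seed=seed)
    bc_map = {}
    for i, tid in enumerate(terminator_ids):
        for bc in barcodes[i * barcodes_per_terminator:(i + 1) * barcodes_per_terminator]:
            bc_map[bc] = tid
    return bc_map


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = mean + mean^2 / dispersion."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(truth: GroundTruth, barcode_map: Mapping[str, str],
                    cfg: SimConfig):
    """Simulate DNA input and RNA output barcode count tables.

    DNA counts are negative binomial around the configured depth; RNA counts
    are negative binomial with mean proportional to the realized DNA count
    times the terminator's true strength, independently per replicate and
    assay system.  Returns a list of :class:`termstarr.quant.BarcodeCountTable`.
    """
    from .quant import BarcodeCountTable

    rng = np.random.default_rng(cfg.seed)
    barcodes = sorted(barcode_map)
    tids = np.array([barcode_map[b] for b in barcodes])
    tables = []
    for system in ("tobacco", "maize"):
        strengths = truth.strengths(system)
        s = np.array([strengths.get(t, np.nan) for t in tids])
        keep = ~np.isnan(s)
        for rep in range(1, cfg.replicates + 1):
            dna = _nb(rng, np.full(keep.sum(), cfg.dna_depth_per_barcode),
                      cfg.nb_dispersion)
            rna = _nb(rng, cfg.rna_depth_factor * dna * s[keep], cfg.nb_dispersion)
            kept_bc = [b for b, k in zip(barcodes, keep) if k]
            tables.append(BarcodeCountTable(
                sample_id=f"{system}_input_rep{rep}", system=system,
                role="input_dna", replicate=rep,
                counts=dict(zip(kept_bc, map(int, dna)))))
            tables.append(BarcodeCountTable(
                sample_id=f"{system}_output_rep{rep}", system=system,
                role="output_rna", replicate=rep,
                counts=dict(zip(kept_bc, map(int, rna)))))
    return tables


# ---------------------------------------------------------------------------
# 3'-end read simulation
# ---------------------------------------------------------------------------

def random_backbone(seed: int = 12345) -> str:
    """The simulated 52-nt plasmid backbone downstream of every insert."""
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[b] for b in rng.integers(4, size=BACKBONE_LENGTH))
    # a poly-A-free, C-terminated backbone keeps tail trimming unambiguous
    return seq[:-1].replace("A", "G") + "C"


def simulate_3prime_reads(truth: GroundTruth, library: Sequence[TerminatorRecord],
                          cfg: SimConfig, backbone: str | None = None):
    """Simulate 3'-end sequencing reads (terminator-side sequence + UMI).

    Each unique molecule is a terminator prefix cut at a position drawn from
    the terminator's site mixture (or, for read-through molecules, the full
    insert plus a uniform backbone position), followed by a geometric poly-A
    tail of at least ``cfg.min_polya_tail`` adenosines.  PCR duplicates
    sharing sequence and UMI are injected at ``cfg.duplicate_rate``.

    Returns ``(reads, truth_lengths)`` where reads is a list of
    ``(read_sequence, umi)`` and truth_lengths maps terminator_id to the list
    of true per-molecule cleavage lengths.
    """
    backbone = backbone if backbone is not None else random_backbone()
    rng = np.random.default_rng(cfg.seed + 1)
    reads: list[tuple[str, str]] = []
    truth_lengths: dict[str, list[int]] = {}
    for rec in library:
        tid = rec.terminator_id
        if tid not in truth.site_mixture:
            continue
        sites = truth.site_mixture[tid]
        p_rt = truth.readthrough_prob[tid]
        positions = [p for p, _ in sites] + [-1]  # -1 marks read-through
        weights = np.array([w for _, w in sites] + [p_rt])
        weights = weights / weights.sum()
        n = cfg.reads_per_terminator_3prime
        draws = rng.choice(len(positions), size=n, p=weights)
        lengths = []
        for d in draws:
            if positions[d] == -1:
                cut = len(rec.sequence) + int(rng.integers(1, len(backbone) + 1))
                body = (rec.sequence + backbone)[:cut]
            else:
                cut = positions[d]
                body = rec.sequence[:cut]
            lengths.append(cut)
            tail = cfg.min_polya_tail + rng.geometric(
                1.0 / max(cfg.polya_mean_tail - cfg.min_polya_tail, 1.0)) - 1
            umi = "".join(BASES[b] for b in rng.integers(4, size=8))
            read = body + "A" * int(tail)
            reads.append((read, umi))
            if cfg.duplicate_rate > 0 and rng.random() < cfg.duplicate_rate:
                reads.append((read, umi))
        truth_lengths[tid] = lengths
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, truth_lengths


def write_fastq(reads: Iterable[tuple[str, str]], r1_path, r2_path) -> None:
    """Write paired FASTQ: read1 = terminator-side sequence, read2 = UMI."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, (seq, umi) in enumerate(reads):
            f1.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            f2.write(f"@read{i}\n{umi}\n+\n{'I' * len(umi)}\n")


def read_fastq_pairs(r1_path, r2_path) -> list[tuple[str, str]]:
    from Bio.SeqIO import parse

    r1 = [str(r.seq) for r in parse(str(r1_path), "fastq")]
    r2 = [str(r.seq) for r in parse(str(r2_path), "fastq")]
    if len(r1) != len(r2):
        raise ValueError("read1/read2 FASTQ files differ in length")
    return list(zip(r1, r2))
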