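"""Terminator library construction.

A terminator is defined as the 170-nt sequence spanning 150 nt upstream of a
cleavage and polyadenylation site plus the 20 nt beginning at the site, using
the half-open window convention ``[site - 150, site + 20)``.  With this
convention the first base of the cleavage dinucleotide sits at 1-based
position 150 of the designed sequence.

Sequences are stored in the DNA alphabet; RNA motifs (AAUAAA, UGUA, ...) are
matched via the U<->T equivalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: designed terminator length and 1-based cleavage position within it
TERMINATOR_LENGTH = 170
CLEAVAGE_POSITION = 150
UPSTREAM = 150
DOWNSTREAM = 20

#: per-species library composition (number of designed members per category)
LIBRARY_COMPOSITION = {
    "arabidopsis": {"primary": 18450, "secondary": 2325, "annotation_end": 3754},
    "maize": {"primary": 25685, "secondary": 4407},
    "control": {
        "cds_control": 589 * 2,          # coding-sequence negatives per species
        "global_random": 200 * 2,
        "positional_random": 1000 * 2,
        "gc_random": 200 * 5,            # one set per GC level
        "reference_terminator": 4,       # 35S, Ag7, NOS, MAS
    },
}

#: GC levels of the randomized GC-content series
GC_RANDOM_LEVELS = (0.3, 0.4, 0.5, 0.6, 0.7)

#: full-length reference (non-plant) terminator lengths
REFERENCE_LENGTHS = {"t35S": 204, "tAg7": 208, "tMAS": 253, "tNOS": 253}

SECONDARY_SUPPORT_THRESHOLD = 0.30

#: canonical cleavage/polyadenylation motifs, DNA spelling
MOTIF_PATTERNS = {"AAUAAA": "AATAAA", "UGUA": "TGTA", "UG_rich": "TGTTGTTTGT"}

#: default 1-based insertion start positions for motif-addition variants:
#: the polyadenylation signal ends ~20 nt upstream of the cleavage site, the
#: UGUA element sits 30-40 nt upstream, the U/G-rich element between the
#: polyadenylation signal and the cleavage site.
MOTIF_INSERTION_POSITIONS = {"AAUAAA": 125, "UGUA": 112, "UG_rich": 131}

#: mutated motif variant series used to break a motif in place (DNA spelling);
#: the polyadenylation-signal series is deduplicated.
MOTIF_MUTANTS = {
    "AAUAAA": ("ACTCAA", "ACTAAA"),
    "UGUA": ("TGCA", "CGTA", "TCTA"),
}

BARCODE_V = "ACG"
BARCODE_REPEATS = 6  # VNN repeats -> 18-nt barcode


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CleavageSiteAnnotation:
    """A cleavage/polyadenylation site on a reference sequence.

    ``position`` is the 0-based coordinate of the first base of the cleavage
    dinucleotide on the forward strand of ``reference_id``.
    """

    gene_id: str
    reference_id: str
    position: int
    strand: str = "+"
    support_fraction: float | None = None
    origin: str = "experimental_primary"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.origin not in {"experimental_primary", "experimental_secondary", "annotation_end"}:
            raise ValueError(f"invalid origin {self.origin!r}")
        if self.origin.startswith("experimental") and self.support_fraction is None:
            raise ValueError("experimental sites require a support_fraction")


@dataclass(frozen=True)
class TerminatorRecord:
    """One designed library member."""

    terminator_id: str
    species: str
    category: str
    sequence: str
    designed_cleavage_offset: int | None = CLEAVAGE_POSITION

    def __post_init__(self):
        if set(self.sequence) - set(BASES):
            raise ValueError(f"{self.terminator_id}: non-ACGT characters in sequence")
        if self.category != "reference_terminator" and len(self.sequence) != TERMINATOR_LENGTH:
            raise ValueError(
                f"{self.terminator_id}: designed sequences must be {TERMINATOR_LENGTH} nt, "
                f"got {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MotifSpec:
    name: str
    pattern: str | np.ndarray
    insertion_position: int | None = None

    def __post_init__(self):
        if isinstance(self.pattern, np.ndarray):
            if not np.allclose(self.pattern.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("probability matrix rows must sum to 1")


def design_summary() -> pd.DataFrame:
    """Per-species, per-category member counts of the designed library.

    Returns a tidy frame with columns species/category/n and the totals the
    library was synthesized at (24,529 Arabidopsis and 30,092 maize
    terminator sequences plus controls).
    """
    rows = [
        {"species": sp, "category": cat, "n": n}
        for sp, cats in LIBRARY_COMPOSITION.items()
        for cat, n in cats.items()
    ]
    return pd.DataFrame(rows)


def species_totals() -> dict[str, int]:
    """Total designed terminator count per plant species."""
    return {
        sp: int(sum(cats.values()))
        for sp, cats in LIBRARY_COMPOSITION.items()
        if sp != "control"
    }


# ---------------------------------------------------------------------------
# window extraction and site selection
# ---------------------------------------------------------------------------

def extract_terminator_window(reference: str, site: CleavageSiteAnnotation) -> str:
    """Extract the 170-nt terminator window around a cleavage site.

    On the plus strand the window is ``reference[position-150 : position+20)``.
    Minus-strand sites are handled by extracting from the reverse complement,
    so the output always reads 5'->3' with the cleavage base at 1-based
    position 150.
    """
    if site.strand == "-":
        flipped = CleavageSiteAnnotation(
            gene_id=site.gene_id,
            reference_id=site.reference_id,
            position=len(reference) - 1 - site.position,
            strand="+",
            support_fraction=site.support_fraction,
            origin=site.origin,
        )
        return extract_terminator_window(reverse_complement(reference), flipped)

    start = site.position - UPSTREAM
    stop = site.position + DOWNSTREAM
    if start < 0:
        raise ValueError(
            f"site {site.gene_id}: window starts {-start} nt before the reference"
        )
    if stop > len(reference):
        raise ValueError(
            f"site {site.gene_id}: window ends {stop - len(reference)} nt past the reference"
        )
    return reference[start:stop].upper()


def select_sites(site_table: Iterable[CleavageSiteAnnotation]) -> list[CleavageSiteAnnotation]:
    """Apply the library site-selection rule.

    Keeps every experimentally determined primary site, secondary sites
    supported by >= 30% of a gene's reads, and annotation-derived 3'-UTR ends
    only for genes with no experimental site.
    """
    sites = list(site_table)
    by_gene: dict[str, list[CleavageSiteAnnotation]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)

    kept: list[CleavageSiteAnnotation] = []
    for s in sites:
        if s.origin == "experimental_primary":
            kept.append(s)
        elif s.origin == "experimental_secondary":
            if s.support_fraction is not None and s.support_fraction >= SECONDARY_SUPPORT_THRESHOLD:
                gene_sites = by_gene[s.gene_id]
                if not any(g.origin == "experimental_primary" for g in gene_sites):
                    warnings.warn(
                        f"gene {s.gene_id} has a secondary site but no primary site",
                        stacklevel=2,
                    )
                kept.append(s)
        elif s.origin == "annotation_end":
            if not any(g.origin.startswith("experimental") for g in by_gene[s.gene_id]):
                kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# randomized control sequences
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, probs: np.ndarray, n: int, length: int) -> list[str]:
    idx = rng.choice(4, size=(n, length), p=probs) if probs.ndim == 1 else None
    if idx is None:  # positional frequencies: one categorical draw per column
        cum = np.cumsum(probs, axis=1)
        u = rng.random((n, probs.shape[0]))
        idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in idx]


def gen_global_random(base_freqs, length: int = TERMINATOR_LENGTH, n: int = 200,
                      seed: int = 0) -> list[str]:
    """Random sequences with i.i.d. positions drawn from global base frequencies."""
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0, atol=1e-6):
        raise ValueError("base_freqs must be a 4-vector summing to 1")
    rng = np.random.default_rng(seed)
    return _draw(rng, freqs / freqs.sum(), n, length)


def gen_positional_random(pos_freqs, n: int = 1000, seed: int = 0) -> list[str]:
    """Random sequences drawn per position from a (length x 4) frequency matrix."""
    mat = np.asarray(pos_freqs, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("pos_freqs must be an (L, 4) matrix")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pos_freqs rows must sum to 1")
    rng = np.random.default_rng(seed)
    return _draw(rng, mat / mat.sum(axis=1, keepdims=True), n, mat.shape[0])


def gen_gc_random(gc: float, length: int = TERMINATOR_LENGTH, n: int = 200,
                  seed: int = 0) -> list[str]:
    """Random sequences at a target GC content (P(G)=P(C)=gc/2)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return gen_global_random(freqs, length=length, n=n, seed=seed)


def positional_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """Per-position base-frequency matrix (L x 4, columns in ACGT order)."""
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), -1
    )
    mat = np.stack([(arr == ord(b)).mean(axis=0) for b in BASES], axis=1)
    return mat


# ---------------------------------------------------------------------------
# motif-addition and motif-mutation variants
# ---------------------------------------------------------------------------

def build_motif_variants(base: str, motifs: Iterable[str] = ("AAUAAA", "UGUA", "UG_rich"),
                         positions: Mapping[str, int] | None = None) -> list[TerminatorRecord]:
    """All motif-combination variants of a motif-less base sequence.

    Every variant carries a CA dinucleotide written at 1-based positions
    150-151 (the designed cleavage site) and each subset of the requested
    motifs written at its modal library position.  Returns ``2^|motifs|``
    records, including the motif-less CA-only baseline.
    """
    motifs = list(motifs)
    positions = dict(MOTIF_INSERTION_POSITIONS, **(positions or {}))
    if len(base) != TERMINATOR_LENGTH:
        raise ValueError(f"base must be {TERMINATOR_LENGTH} nt")
    clashes = [m for m in motifs if MOTIF_PATTERNS[m] in base]
    if base[CLEAVAGE_POSITION - 1 : CLEAVAGE_POSITION + 1] == "CA":
        clashes.append("CA@150")
    if clashes:
        raise ValueError(f"base sequence already contains: {', '.join(clashes)}")

    def write_at(seq: str, pos1: int, sub: str) -> str:
        i = pos1 - 1
        return seq[:i] + sub + seq[i + len(sub):]

    baseline = write_at(base, CLEAVAGE_POSITION, "CA")
    records = []
    for mask in range(2 ** len(motifs)):
        subset = [m for j, m in enumerate(motifs) if mask >> j & 1]
        seq = baseline
        for m in subset:
            seq = write_at(seq, positions[m], MOTIF_PATTERNS[m])
        name = "+".join(subset) if subset else "none"
        records.append(
            TerminatorRecord(
                terminator_id=f"motif_{name}",
                species="control",
                category="motif_variant",
                sequence=seq,
            )
        )
    return records


def mutate_motif(sequence: str, motif: str) -> list[str]:
    """Replace the single occurrence of a motif with its mutated variants."""
    if motif not in MOTIF_MUTANTS:
        raise ValueError(f"no mutant series for motif {motif!r}")
    pattern = MOTIF_PATTERNS[motif]
    count = sequence.count(pattern)
    if count != 1:
        raise ValueError(
            f"sequence must contain exactly one {pattern} occurrence, found {count}"
        )
    i = sequence.index(pattern)
    return [
        sequence[:i] + variant + sequence[i + len(pattern):]
        for variant in MOTIF_MUTANTS[motif]
    ]


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def gen_barcode(n: int, seed: int = 0, repeats: int = BARCODE_REPEATS) -> list[str]:
    """Unique random barcodes matching the repeating VNN pattern (V = A/C/G)."""
    if n <= 0:
        raise ValueError("n must be positive")
    space = (3 * 4 * 4) ** repeats
    if n > space:
        raise ValueError(f"requested {n} barcodes but pattern space is {space}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        k = n - len(out)
        v = rng.choice(list(BARCODE_V), size=(k, repeats))
        n1 = rng.choice(list(BASES), size=(k, repeats))
        n2 = rng.choice(list(BASES), size=(k, repeats))
        for a, b, c in zip(v, n1, n2):
            bc = "".join(x + y + z for x, y, z in zip(a, b, c))
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def read_sites_tsv(path: str | Path) -> list[CleavageSiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        sf = getattr(row, "support_fraction", None)
        sites.append(
            CleavageSiteAnnotation(
                gene_id=str(row.gene_id),
                reference_id=str(row.reference_id),
                position=int(row.position),
                strand=str(row.strand),
                support_fraction=None if sf is None or pd.isna(sf) else float(sf),
                origin=str(row.origin),
            )
        )
    return sites


def write_library_fasta(records: Iterable[TerminatorRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqs = [
        SeqRecord(Seq(r.sequence), id=r.terminator_id,
                  description=f"{r.species} {r.category}")
        for r in records
    ]
    seqio_write(seqs, str(path), "fasta")


def read_library_fasta(path: str | Path,
                       manifest: pd.DataFrame | None = None) -> list[TerminatorRecord]:
    from Bio.SeqIO import parse as seqio_parse

    meta = {}
    if manifest is not None:
        meta = {
            str(r.terminator_id): (str(r.species), str(r.category),
                                   int(r.designed_cleavage_offset))
            for r in manifest.itertuples(index=False)
        }
    records = []
    for rec in seqio_parse(str(path), "fasta"):
        species, category, offset = meta.get(
            rec.id, ("control", "reference_terminator", CLEAVAGE_POSITION)
        )
        if rec.id not in meta and rec.description != rec.id:
            parts = rec.description.split()
            if len(parts) >= 3:
                species, category = parts[1], parts[2]
        records.append(
            TerminatorRecord(rec.id, species, category, str(rec.seq).upper(),
                             designed_cleavage_offset=offset)
        )
    return records


def write_manifest(records: Iterable[TerminatorRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "terminator_id": r.terminator_id,
                "species": r.species,
                "category": r.category,
                "designed_cleavage_offset": r.designed_cleavage_offset,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_barcode_map(barcode_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(barcode_map.items()), columns=["barcode", "terminator_id"]
    ).to_csv(path, sep="\t", index=False)


def read_barcode_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["barcode"].astype(str), df["terminator_id"].astype(str)))
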