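"""Barcode counts -> normalized terminator strengths.

Terminator strength is the enrichment of a construct's barcodes in the RNA
output over the DNA input, normalized to the enrichment of the 35S reference
terminator:

    S(t) = [ (out_t / out_total) / (in_t / in_total) ]  /  S(reference)

computed per assay system and replicate on barcode counts aggregated per
terminator after a minimum-read filter.  The species-specificity score psi is
the difference between min-max-normalized log2 strengths in the two systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_READS = 5


@dataclass
class BarcodeCountTable:
    """Per-sample barcode read counts (DNA input or RNA output)."""

    sample_id: str
    system: str
    role: str
    replicate: int
    counts: dict[str, int]

    def __post_init__(self):
        if self.role not in {"input_dna", "output_rna"}:
            raise ValueError(f"invalid role {self.role!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative counts")
        if self.counts and sum(self.counts.values()) == 0:
            raise ValueError(f"sample {self.sample_id} has zero total counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def filter_barcodes(table: BarcodeCountTable,
                    min_reads: int = DEFAULT_MIN_READS) -> BarcodeCountTable:
    """Drop barcodes with fewer than ``min_reads`` reads in this sample."""
    kept = {b: c for b, c in table.counts.items() if c >= min_reads}
    if table.counts and not kept:
        raise ValueError(f"sample {table.sample_id}: all barcodes below {min_reads} reads")
    return BarcodeCountTable(table.sample_id, table.system, table.role,
                             table.replicate, kept)


def _aggregate(table: BarcodeCountTable, barcode_map: Mapping[str, str]) -> dict[str, int]:
    agg: dict[str, int] = {}
    for bc, c in table.counts.items():
        tid = barcode_map.get(bc)
        if tid is not None:
            agg[tid] = agg.get(tid, 0) + c
    return agg


def compute_strength(input_table: BarcodeCountTable, output_table: BarcodeCountTable,
                     barcode_map: Mapping[str, str], reference_id: str) -> dict[str, float]:
    """Normalized RNA/DNA enrichment per terminator, scaled to the reference.

    A barcode contributes only if it survived filtering in both the input and
    the output sample.  Terminators absent from either sample are dropped.
    """
    shared = set(input_table.counts) & set(output_table.counts)
    in_counts = _aggregate(
        BarcodeCountTable(input_table.sample_id, input_table.system,
                          input_table.role, input_table.replicate,
                          {b: input_table.counts[b] for b in shared}),
        barcode_map)
    out_counts = _aggregate(
        BarcodeCountTable(output_table.sample_id, output_table.system,
                          output_table.role, output_table.replicate,
                          {b: output_table.counts[b] for b in shared}),
        barcode_map)

    in_total = sum(in_counts.values())
    out_total = sum(out_counts.values())
    if in_total == 0 or out_total == 0:
        raise ValueError("no overlapping barcodes between input and output")

    raw: dict[str, float] = {}
    for tid in set(in_counts) & set(out_counts):
        if in_counts[tid] == 0:
            warnings.warn(f"terminator {tid} has zero input counts; dropped",
                          stacklevel=2)
            continue
        if out_counts[tid] == 0:
            continue
        raw[tid] = (out_counts[tid] / out_total) / (in_counts[tid] / in_total)

    if reference_id not in raw:
        raise ValueError(f"reference terminator {reference_id!r} missing or unquantifiable")
    ref = raw[reference_id]
    return {tid: s / ref for tid, s in raw.items()}


def quantify(tables: Iterable[BarcodeCountTable], barcode_map: Mapping[str, str],
             reference_id: str, min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Full quantification: filter, pair input/output, strengths per replicate.

    Returns a tidy frame with columns terminator_id/system/replicate/strength.
    """
    by_key: dict[tuple[str, int, str], BarcodeCountTable] = {}
    for t in tables:
        by_key[(t.system, t.replicate, t.role)] = filter_barcodes(t, min_reads)

    rows = []
    for (system, rep) in sorted({(s, r) for s, r, _ in by_key}):
        inp = by_key.get((system, rep, "input_dna"))
        out = by_key.get((system, rep, "output_rna"))
        if inp is None or out is None:
            continue
        for tid, s in compute_strength(inp, out, barcode_map, reference_id).items():
            rows.append({"terminator_id": tid, "system": system,
                         "replicate": rep, "strength": s})
    return pd.DataFrame(rows)


def average_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Average linear strengths over replicates, per system.

    Terminators missing in any replicate of a system are dropped for that
    system (data not present in both replicates are excluded).  Returns
    columns terminator_id/system/strength/log2_strength.
    """
    out = []
    for system, grp in per_replicate.groupby("system"):
        n_reps = grp["replicate"].nunique()
        if n_reps < 2:
            raise ValueError(f"system {system}: need >= 2 replicates, got {n_reps}")
        counts = grp.groupby("terminator_id")["replicate"].nunique()
        complete = counts[counts == n_reps].index
        mean = (grp[grp["terminator_id"].isin(complete)]
                .groupby("terminator_id")["strength"].mean())
        out.append(pd.DataFrame({
            "terminator_id": mean.index,
            "system": system,
            "strength": mean.values,
            "log2_strength": np.log2(mean.values),
        }))
    return pd.concat(out, ignore_index=True)


def compute_psi(strength_tobacco: Mapping[str, float],
                strength_maize: Mapping[str, float]) -> dict[str, float]:
    """Species-specificity score psi per terminator.

    log2 strengths are min-max normalized to [0, 1] within each system over
    the shared terminator set; psi = normalized tobacco - normalized maize,
    so +1 is maximally tobacco-specific and -1 maximally maize-specific.
    """
    shared = sorted(set(strength_tobacco) & set(strength_maize))
    if not shared:
        raise ValueError("no terminators shared between systems")
    psi = {}
    norm = {}
    for name, strengths in (("tobacco", strength_tobacco), ("maize", strength_maize)):
        vals = np.log2([strengths[t] for t in shared])
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError(f"degenerate strength range in {name}")
        norm[name] = (vals - lo) / (hi - lo)
    for i, t in enumerate(shared):
        psi[t] = float(norm["tobacco"][i] - norm["maize"][i])
    return psi


def rank_specific(psi: Mapping[str, float], species_labels: Mapping[str, str],
                  fraction: float = 0.10) -> tuple[set[str], set[str]]:
    """Species-specific terminator sets.

    Tobacco-specific = top ``fraction`` of Arabidopsis terminators by psi
    (highest); maize-specific = top ``fraction`` of maize terminators by -psi
    (lowest psi).  Ties break by terminator_id for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    def top(species: str, reverse: bool) -> set[str]:
        members = sorted(
            (t for t in psi if species_labels.get(t) == species),
            key=lambda t: ((-psi[t]) if reverse else psi[t], t),
        )
        k = max(1, int(round(fraction * len(members)))) if members else 0
        if fraction == 1.0:
            k = len(members)
        return set(members[:k])

    return top("arabidopsis", reverse=True), top("maize", reverse=False)


def strength_maps(averaged: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Split an averaged strength frame into per-system id->strength maps."""
    return {
        system: dict(zip(grp["terminator_id"], grp["strength"]))
        for system, grp in averaged.groupby("system")
    }


def write_strength_table(averaged: pd.DataFrame, psi: Mapping[str, float] | None,
                         path) -> None:
    df = averaged.copy()
    if psi is not None:
        df["psi"] = df["terminator_id"].map(psi)
    df.to_csv(path, sep="\t", index=False)
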