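"""Composition metrics and wildtype-vs-optimized comparison statistics.

These are the per-construct columns of the standard comparison report for
an optimization run: ORF length, GC percentage, CAI, CpG/UpA dinucleotide
counts and the number and fraction of codons altered between a wildtype
coding sequence and its synonymous optimized counterpart.

Coordinates are 0-based half-open throughout; reported percentages are
rounded half-up to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .alphabet import clean_dna
from .codon_model import CodingSequence, CodonUsageTable, RelativeAdaptiveness, cai

__all__ = [
    "MetricReport",
    "PairComparison",
    "DinucleotideStats",
    "ComparisonError",
    "gc_content",
    "windowed_gc",
    "dinucleotide_stats",
    "codons_altered",
    "differing_codon_positions",
    "verify_synonymous",
    "metric_report",
    "percent_half_up",
]


class ComparisonError(ValueError):
    """Sequences cannot be compared codon-wise (frame or length mismatch)."""


@dataclass(frozen=True)
class MetricReport:
    id: str
    length_bp: int
    gc_percent: float
    cai: float
    cpg_count: int
    upa_count: int
    cpg_obs_exp: float


@dataclass(frozen=True)
class PairComparison:
    codons_altered_n: int
    codons_altered_percent: int
    synonymous: bool


@dataclass(frozen=True)
class DinucleotideStats:
    cpg_count: int
    upa_count: int
    cpg_obs_exp: float


def percent_half_up(numerator: int, denominator: int) -> int:
    """round(100 * numerator / denominator), half-up, in exact integer arithmetic."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * numerator + denominator) // (2 * denominator)


def gc_content(nt: str) -> float:
    """GC percentage: 100 * (G + C) / length."""
    s = clean_dna(nt, context="gc_content")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def windowed_gc(nt: str, window: int, step: int | None = None) -> list[tuple[int, float]]:
    """GC percentage over half-open windows ``[start, start+window)``.

    ``step`` defaults to ``window`` (non-overlapping tiling); a trailing
    partial window is dropped.
    """
    s = clean_dna(nt, context="windowed_gc")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > len(s):
        raise ValueError(f"window {window} exceeds sequence length {len(s)}")
    if step is None:
        step = window
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    out = []
    for start in range(0, len(s) - window + 1, step):
        chunk = s[start : start + window]
        out.append((start, 100.0 * (chunk.count("G") + chunk.count("C")) / window))
    return out


def dinucleotide_stats(nt: str) -> DinucleotideStats:
    """Overlapping CpG ("CG") and UpA ("TA" at DNA level) dinucleotide counts.

    The CpG observed/expected ratio is count * length / (nC * nG); it is
    reported as 0.0 when the sequence lacks C or G entirely.
    """
    s = clean_dna(nt, context="dinucleotide_stats")
    if len(s) < 2:
        raise ValueError("need at least 2 nucleotides")
    # two-letter motifs with distinct letters cannot overlap themselves, so
    # str.count (non-overlapping) already yields the overlapping-scan count
    cpg = s.count("CG")
    upa = s.count("TA")
    n_c, n_g = s.count("C"), s.count("G")
    obs_exp = (cpg * len(s) / (n_c * n_g)) if n_c and n_g else 0.0
    return DinucleotideStats(cpg_count=cpg, upa_count=upa, cpg_obs_exp=obs_exp)


def _as_cds(seq: Union[CodingSequence, str], id: str) -> CodingSequence:
    return seq if isinstance(seq, CodingSequence) else CodingSequence.from_nt(seq, id=id)


def differing_codon_positions(
    wt: Union[CodingSequence, str], opt: Union[CodingSequence, str]
) -> list[int]:
    a, b = _as_cds(wt, "wt"), _as_cds(opt, "opt")
    ca, cb = a.codons, b.codons
    if len(ca) != len(cb):
        raise ComparisonError(
            f"codon counts differ: {a.id} has {len(ca)}, {b.id} has {len(cb)}"
        )
    return [i for i, (x, y) in enumerate(zip(ca, cb)) if x != y]


def codons_altered(
    wt: Union[CodingSequence, str], opt: Union[CodingSequence, str]
) -> PairComparison:
    """Count codon positions whose triplets differ between two in-frame ORFs."""
    a, b = _as_cds(wt, "wt"), _as_cds(opt, "opt")
    diffs = differing_codon_positions(a, b)
    n_codons = len(a.codons)
    return PairComparison(
        codons_altered_n=len(diffs),
        codons_altered_percent=percent_half_up(len(diffs), n_codons),
        synonymous=a.aa == b.aa,
    )


def verify_synonymous(
    wt: Union[CodingSequence, str], opt: Union[CodingSequence, str]
) -> bool:
    """True iff both ORFs translate to the identical protein, codon for codon."""
    a, b = _as_cds(wt, "wt"), _as_cds(opt, "opt")
    if len(a.nt) != len(b.nt):
        raise ComparisonError(
            f"frame mismatch: {a.id} is {len(a.nt)} bp, {b.id} is {len(b.nt)} bp"
        )
    return a.aa == b.aa


def metric_report(
    seq: Union[CodingSequence, str],
    table: Union[CodonUsageTable, RelativeAdaptiveness],
) -> MetricReport:
    cds = _as_cds(seq, "seq")
    dn = dinucleotide_stats(cds.nt)
    return MetricReport(
        id=cds.id,
        length_bp=cds.length_bp,
        gc_percent=gc_content(cds.nt),
        cai=cai(cds, table),
        cpg_count=dn.cpg_count,
        upa_count=dn.upa_count,
        cpg_obs_exp=dn.cpg_obs_exp,
    )
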