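"""Silent-mutation divergence analytics for siRNA rescue experiments.

A sequence-optimized transgene differs from the wildtype coding sequence
only by synonymous ("silent") substitutions, so an siRNA that matches the
wildtype transcript perfectly can leave the optimized transcript
untouched.  These helpers quantify that divergence: where a given guide
aligns best in each sequence, how many mismatches it accumulates, and
which wildtype k-mers have diverged enough in the optimized copy to act
as rescue-compatible siRNA target sites.

Mismatch counting is ungapped Hamming distance at aligned offsets; the
siRNA/target duplex tolerates no gaps in this context.  Position-dependent
(seed-region) weighting is a noted extension point, not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from .alphabet import clean_dna
from .codon_model import CodingSequence

__all__ = [
    "SirnaQuery",
    "RescueVerdict",
    "RescueSite",
    "DEFAULT_RESCUE_MISMATCHES",
    "sirna_divergence",
    "enumerate_rescue_sites",
]

#: minimum mismatches in the optimized sequence for a site to count as
#: escaping the knockdown (conservative default, configurable)
DEFAULT_RESCUE_MISMATCHES = 4


@dataclass(frozen=True)
class SirnaQuery:
    """Sense-strand representation of an siRNA target site (typically 19-23 nt)."""

    guide: str
    name: str = "sirna"

    def __post_init__(self) -> None:
        object.__setattr__(self, "guide", clean_dna(self.guide, context=self.name))
        if len(self.guide) < 15:
            raise ValueError(f"{self.name}: guide shorter than 15 nt")


@dataclass(frozen=True)
class RescueVerdict:
    best_wt: tuple[int, int]  # (position, mismatches)
    best_opt: tuple[int, int]
    rescue_compatible: bool


@dataclass(frozen=True)
class RescueSite:
    position: int
    wt_kmer: str
    mismatches: int


def _nt_of(seq: Union[CodingSequence, str], context: str) -> str:
    if isinstance(seq, CodingSequence):
        return seq.nt
    return clean_dna(seq, context=context)


def _best_ungapped(target: str, guide: str) -> tuple[int, int]:
    """Offset minimizing Hamming mismatches; earliest position wins ties."""
    k = len(guide)
    if k > len(target):
        raise ValueError(f"query ({k} nt) longer than sequence ({len(target)} nt)")
    best_pos, best_mm = 0, k + 1
    for pos in range(len(target) - k + 1):
        mm = 0
        window = target[pos : pos + k]
        for a, b in zip(window, guide):
            if a != b:
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_pos, best_mm = pos, mm
            if mm == 0:
                break
    return best_pos, best_mm


def sirna_divergence(
    wt: Union[CodingSequence, str],
    opt: Union[CodingSequence, str],
    query: SirnaQuery,
    min_mismatch: int = DEFAULT_RESCUE_MISMATCHES,
) -> RescueVerdict:
    """Best ungapped match of the guide in each sequence and the verdict.

    ``rescue_compatible`` means the guide hits the wildtype perfectly while
    the optimized sequence diverges by at least ``min_mismatch`` bases at
    its own best-matching offset - i.e. the optimized transgene should
    escape an siRNA that silences the wildtype.
    """
    wt_nt = _nt_of(wt, "wt")
    opt_nt = _nt_of(opt, "opt")
    best_wt = _best_ungapped(wt_nt, query.guide)
    best_opt = _best_ungapped(opt_nt, query.guide)
    return RescueVerdict(
        best_wt=best_wt,
        best_opt=best_opt,
        rescue_compatible=(best_wt[1] == 0 and best_opt[1] >= min_mismatch),
    )


def enumerate_rescue_sites(
    wt: Union[CodingSequence, str],
    opt: Union[CodingSequence, str],
    k: int = 21,
    min_mismatch: int = DEFAULT_RESCUE_MISMATCHES,
) -> list[RescueSite]:
    """All wildtype k-mers whose aligned optimized window differs enough.

    The two sequences must be the same length (a synonymous wt/opt pair);
    for each 0-based start, the wildtype k-mer is compared position-wise
    with the optimized window at the same offset.  Sites reaching
    ``min_mismatch`` mismatches are candidate siRNA targets whose knockdown
    the optimized gene escapes.
    """
    wt_nt = _nt_of(wt, "wt")
    opt_nt = _nt_of(opt, "opt")
    if len(wt_nt) != len(opt_nt):
        raise ValueError(
            f"sequences differ in length ({len(wt_nt)} vs {len(opt_nt)} nt)"
        )
    if not 1 <= k <= len(wt_nt):
        raise ValueError(f"k must be in [1, {len(wt_nt)}], got {k}")
    sites = []
    for pos in range(len(wt_nt) - k + 1):
        mm = sum(1 for a, b in zip(wt_nt[pos : pos + k], opt_nt[pos : pos + k]) if a != b)
        if mm >= min_mismatch:
            sites.append(RescueSite(position=pos, wt_kmer=wt_nt[pos : pos + k], mismatches=mm))
    return sites
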