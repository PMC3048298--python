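"""Detection of deleterious sequence features a transgene should avoid.

Covers the motif-shaped optimization parameters: intragenic poly(A)
signals, AU-rich destabilizing elements and other user-supplied IUPAC
motifs; cryptic splice donor/acceptor sites; direct repeats; and
hairpin-forming inverted repeats as a deterministic proxy for stable RNA
secondary structure.

The splice-site and hairpin models are deliberately simple, fully
deterministic rules (consensus position weights, exact inverted repeats
with a GC bonus) rather than trained or thermodynamic models; see the
methods note for their rationale and limits.  Internal ribosome entry
sites have no workable published model and are supported only as
user-supplied motif entries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .alphabet import clean_dna, revcomp

__all__ = [
    "IUPAC",
    "PatternError",
    "MotifEntry",
    "MotifLibrary",
    "FeatureHit",
    "SpliceSiteModel",
    "default_motif_library",
    "load_motif_library",
    "scan_motifs",
    "score_splice_sites",
    "find_direct_repeats",
    "find_hairpins",
    "hits_to_bed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class PatternError(ValueError):
    """An IUPAC motif pattern contains an invalid symbol."""


@dataclass(frozen=True)
class FeatureHit:
    """One detected feature, 0-based half-open on the scanned sequence."""

    kind: str  # motif | donor_splice | acceptor_splice | polyA | ARE | repeat | hairpin
    name: str
    start: int
    end: int
    strand: str = "+"
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MotifEntry:
    name: str
    pattern: str
    penalty: float = 1.0
    hard: bool = False
    kind: str = "motif"

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad or not self.pattern:
            raise PatternError(f"{self.name}: invalid IUPAC symbols {sorted(bad)}")
        if self.penalty < 0:
            raise ValueError(f"{self.name}: penalty must be >= 0")


@dataclass(frozen=True)
class MotifLibrary:
    entries: tuple[MotifEntry, ...] = ()
    strand_mode: str = "sense-only"  # or "both"

    def __post_init__(self) -> None:
        if self.strand_mode not in ("sense-only", "both"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def hard_entries(self) -> tuple[MotifEntry, ...]:
        return tuple(e for e in self.entries if e.hard)

    @property
    def soft_entries(self) -> tuple[MotifEntry, ...]:
        return tuple(e for e in self.entries if not e.hard)


def default_motif_library() -> MotifLibrary:
    """Poly(A) signals (hard), ARE pentamer and long A/T runs (soft).

    UpA dinucleotides are handled as a composition term by the optimizer,
    not as motifs.
    """
    return MotifLibrary(
        entries=(
            MotifEntry("polyA_AATAAA", "AATAAA", penalty=1.0, hard=True, kind="polyA"),
            MotifEntry("polyA_ATTAAA", "ATTAAA", penalty=1.0, hard=True, kind="polyA"),
            MotifEntry("ARE_ATTTA", "ATTTA", penalty=0.5, hard=False, kind="ARE"),
            MotifEntry("AT_run_7", "WWWWWWW", penalty=0.25, hard=False, kind="motif"),
        ),
        strand_mode="sense-only",
    )


def load_motif_library(path: str | Path) -> MotifLibrary:
    """Read a motif library from a YAML config.

    Layout::

        strand_mode: sense-only
        motifs:
          - {name: polyA_AATAAA, pattern: AATAAA, penalty: 1.0, hard: true}
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    entries = tuple(
        MotifEntry(
            name=str(m["name"]),
            pattern=str(m["pattern"]),
            penalty=float(m.get("penalty", 1.0)),
            hard=bool(m.get("hard", False)),
            kind=str(m.get("kind", "motif")),
        )
        for m in doc.get("motifs", [])
    )
    return MotifLibrary(entries=entries, strand_mode=doc.get("strand_mode", "sense-only"))


@lru_cache(maxsize=512)
def _compile_iupac(pattern: str) -> re.Pattern[str]:
    parts = []
    for ch in pattern.upper():
        allowed = IUPAC.get(ch)
        if allowed is None:
            raise PatternError(f"invalid IUPAC symbol {ch!r} in {pattern!r}")
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def _scan_one_strand(nt: str, entry: MotifEntry, strand: str, length: int) -> list[FeatureHit]:
    hits = []
    for m in _compile_iupac(entry.pattern).finditer(nt):
        start, end = m.start(), m.start() + len(entry.pattern)
        if strand == "-":
            start, end = length - end, length - start
        hits.append(
            FeatureHit(kind=entry.kind, name=entry.name, start=start, end=end,
                       strand=strand, score=entry.penalty)
        )
    return hits


def scan_motifs(nt: str, lib: MotifLibrary) -> list[FeatureHit]:
    """All (possibly overlapping) IUPAC motif matches; optionally both strands.

    Reverse-strand hits are reported in forward coordinates with strand "-".
    """
    s = clean_dna(nt, context="scan_motifs")
    hits: list[FeatureHit] = []
    for entry in lib.entries:
        hits.extend(_scan_one_strand(s, entry, "+", len(s)))
        if lib.strand_mode == "both":
            hits.extend(_scan_one_strand(revcomp(s), entry, "-", len(s)))
    return sorted(hits, key=lambda h: (h.start, h.end, h.name, h.strand))


# ---------------------------------------------------------------------------
# cryptic splice sites

@dataclass(frozen=True)
class SpliceSiteModel:
    """Deterministic consensus models for cryptic donor and acceptor sites.

    The donor is a 9-mer spanning the last 3 exonic and first 6 intronic
    positions of the canonical MAG|GTRAGT consensus, scored by per-position
    match weights; the invariant GT dinucleotide carries the dominant
    weight, so the literal consensus attains the maximum score.  Acceptors
    are AG dinucleotides immediately preceded by a pyrimidine-rich tract.
    """

    donor_consensus: str = "MAGGTRAGT"
    donor_weights: tuple[float, ...] = (1, 1, 1, 3, 3, 1, 1, 1, 1)
    donor_threshold: float = 0.75  # fraction of the maximum attainable score
    acceptor_tract_len: int = 10
    acceptor_min_pyr_frac: float = 0.8

    def __post_init__(self) -> None:
        if len(self.donor_consensus) != len(self.donor_weights):
            raise ValueError("donor consensus and weights must have equal length")
        bad = set(self.donor_consensus.upper()) - set(IUPAC)
        if bad:
            raise PatternError(f"donor consensus: invalid symbols {sorted(bad)}")

    @property
    def donor_sets(self) -> tuple[frozenset[str], ...]:
        return _donor_sets_cached(self.donor_consensus.upper())

    @property
    def donor_max_score(self) -> float:
        return float(sum(self.donor_weights))


@lru_cache(maxsize=64)
def _donor_sets_cached(consensus: str) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(IUPAC[ch]) for ch in consensus)


def score_splice_sites(nt: str, model: SpliceSiteModel | None = None) -> list[FeatureHit]:
    """Donor and acceptor candidate sites at or above the model thresholds.

    Hit scores are normalized: donor = consensus score / maximum, acceptor =
    pyrimidine fraction of the tract.
    """
    s = clean_dna(nt, context="score_splice_sites")
    model = model or SpliceSiteModel()
    hits: list[FeatureHit] = []

    sets = model.donor_sets
    weights = model.donor_weights
    max_score = model.donor_max_score
    span = len(model.donor_consensus)
    exon_offset = model.donor_consensus.upper().find("GT")  # GT position inside the 9-mer
    pos = s.find("GT")
    while pos != -1:
        start = pos - exon_offset
        if start >= 0 and start + span <= len(s):
            window = s[start : start + span]
            score = sum(w for base, allowed, w in zip(window, sets, weights) if base in allowed)
            if score / max_score >= model.donor_threshold:
                hits.append(
                    FeatureHit(kind="donor_splice", name="donor", start=start,
                               end=start + span, score=score / max_score)
                )
        pos = s.find("GT", pos + 1)

    tract = model.acceptor_tract_len
    pos = s.find("AG")
    while pos != -1:
        if pos >= tract:
            t = s[pos - tract : pos]
            frac = (t.count("C") + t.count("T")) / tract
            if frac >= model.acceptor_min_pyr_frac:
                hits.append(
                    FeatureHit(kind="acceptor_splice", name="acceptor",
                               start=pos - tract, end=pos + 2, score=frac)
                )
        pos = s.find("AG", pos + 1)

    return sorted(hits, key=lambda h: (h.start, h.end, h.kind))


# ---------------------------------------------------------------------------
# direct repeats

def find_direct_repeats(nt: str, min_len: int = 8) -> list[FeatureHit]:
    """Maximal exact direct repeats of length >= ``min_len``.

    A substring is reported when it occurs at two or more distinct positions
    and is not contained in any longer substring that also repeats; every
    occurrence yields one hit.  Equivalent to brute-force enumeration of all
    repeated substrings.
    """
    s = clean_dna(nt, context="find_direct_repeats")
    if min_len < 4:
        raise ValueError(f"min_len must be >= 4, got {min_len}")
    if min_len > len(s):
        return []

    # level-by-level extension: only positions inside repeated k-mers can
    # start repeated (k+1)-mers
    levels: dict[int, dict[str, list[int]]] = {}
    groups: dict[str, list[int]] = {}
    for i in range(len(s) - min_len + 1):
        groups.setdefault(s[i : i + min_len], []).append(i)
    k = min_len
    while True:
        repeated = {sub: pos for sub, pos in groups.items() if len(pos) >= 2}
        if not repeated:
            break
        levels[k] = repeated
        nxt: dict[str, list[int]] = {}
        for sub, positions in repeated.items():
            for i in positions:
                if i + k < len(s):
                    nxt.setdefault(s[i : i + k + 1], []).append(i)
        groups = nxt
        k += 1

    hits: list[FeatureHit] = []
    for k, repeated in levels.items():
        longer = levels.get(k + 1, {})
        shadowed = {u[:-1] for u in longer} | {u[1:] for u in longer}
        for sub, positions in repeated.items():
            if sub in shadowed:
                continue
            for i in positions:
                hits.append(
                    FeatureHit(kind="repeat", name=sub, start=i, end=i + k, score=float(k))
                )
    return sorted(hits, key=lambda h: (h.start, h.end, h.name))


# ---------------------------------------------------------------------------
# hairpins (inverted repeats)

_PAIR_SCORE = {"A": 1.0, "T": 1.0, "G": 2.0, "C": 2.0}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_hairpins(
    nt: str, min_stem: int = 8, loop_range: tuple[int, int] = (3, 30)
) -> list[FeatureHit]:
    """Exact inverted repeats able to fold into a hairpin.

    For every putative loop (position and length within ``loop_range``) the
    flanking bases are extended outward while Watson-Crick complementary;
    stems of at least ``min_stem`` pairs are reported, spanning the full
    stem-loop-stem interval.  Score = 2 per GC pair + 1 per AT pair, a crude
    stability proxy in lieu of thermodynamic folding.  Hits contained in a
    larger reported hairpin are suppressed.
    """
    s = clean_dna(nt, context="find_hairpins")
    if min_stem < 4:
        raise ValueError(f"min_stem must be >= 4, got {min_stem}")
    loop_min, loop_max = loop_range
    if not (0 < loop_min <= loop_max):
        raise ValueError(f"bad loop_range {loop_range!r}")

    n = len(s)
    if n < 2 * min_stem + loop_min:
        return []
    rc = revcomp(s)

    # index every min_stem-mer; for loop start p the innermost min_stem
    # pairs match a downstream start q iff revcomp(s[p-min_stem:p]) (a slice
    # of rc) equals s[q:q+min_stem]
    index: dict[str, list[int]] = {}
    for j in range(n - min_stem + 1):
        index.setdefault(s[j : j + min_stem], []).append(j)

    raw: list[FeatureHit] = []
    for p in range(min_stem, n):  # p = first loop position (stem1 ends at p-1)
        seed_rc = rc[n - p : n - p + min_stem]
        positions = index.get(seed_rc)
        if not positions:
            continue
        for q in positions:  # q = first base after the loop
            loop = q - p
            if loop < loop_min:
                continue
            if loop > loop_max:
                break
            k = min_stem
            while p - k - 1 >= 0 and q + k < n and _COMP[s[p - k - 1]] == s[q + k]:
                k += 1
            stem1 = s[p - k : p]
            score = k + stem1.count("G") + stem1.count("C")
            raw.append(
                FeatureHit(kind="hairpin", name=f"stem{k}_loop{loop}",
                           start=p - k, end=q + k, score=float(score))
            )

    # drop hits nested inside a larger hairpin hit
    raw.sort(key=lambda h: (h.start, -h.end, -h.score))
    kept: list[FeatureHit] = []
    for h in raw:
        if any(o.start <= h.start and h.end <= o.end and o is not h for o in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.end))


def hits_to_bed(hits: Iterable[FeatureHit], seq_id: str = "seq") -> str:
    """BED-like TSV (0-based half-open): seq, start, end, name, score, strand, kind."""
    lines = [
        f"{seq_id}\t{h.start}\t{h.end}\t{h.name}\t{h.score:g}\t{h.strand}\t{h.kind}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
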