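"""Codon usage tables, relative adaptiveness, CAI and optimal back-translation.

The codon adaptation index (CAI) of a coding sequence is the geometric mean
of the relative adaptiveness values of its codons.  The relative
adaptiveness w(c) of a codon is the frequency of c in a reference codon
usage table divided by the frequency of the most frequent codon encoding
the same amino acid, so the optimal codon of every synonymous family has
w = 1.0 and a CAI of 1.0 marks a sequence built entirely from optimal
codons.

A genome-wide human codon usage table (per-thousand frequencies, standard
genetic code) is bundled as the default reference; any Kazusa-style or
two-column table can be loaded in its place.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .alphabet import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    BASES,
    CODON_TO_AA,
    CODONS,
    SINGLE_CODON_AAS,
    STANDARD_CODE_ID,
    STOP_CODONS,
    AlphabetError,
    clean_dna,
    translate,
)

__all__ = [
    "CodonUsageTable",
    "RelativeAdaptiveness",
    "CodingSequence",
    "CodonTableFormatError",
    "DegenerateFamilyError",
    "UndefinedCaiError",
    "load_codon_table",
    "load_human_table",
    "relative_adaptiveness",
    "cai",
    "back_translate_optimal",
]

#: floor substituted for w = 0 codons inside the CAI geometric mean, so a
#: single unused codon cannot collapse the whole index to zero
ZERO_W_FLOOR = 0.01


class CodonTableFormatError(ValueError):
    """A codon usage table file could not be parsed or validated."""


class DegenerateFamilyError(ValueError):
    """Every codon of a synonymous family has zero frequency."""


class UndefinedCaiError(ValueError):
    """CAI requested for a sequence with no countable codons."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon frequencies for one expression system.

    Frequencies may be on any scale (counts, per-thousand or fractions);
    relative adaptiveness only depends on within-family ratios.
    """

    frequencies: Mapping[str, float]
    species_label: str = ""
    genetic_code_id: int = STANDARD_CODE_ID

    def __post_init__(self) -> None:
        if self.genetic_code_id != STANDARD_CODE_ID:
            raise CodonTableFormatError(
                f"only the standard genetic code (id {STANDARD_CODE_ID}) is supported"
            )
        keys = set(self.frequencies)
        if keys != set(CODONS):
            missing = sorted(set(CODONS) - keys)
            extra = sorted(keys - set(CODONS))
            raise CodonTableFormatError(
                f"table must list all 64 codons exactly; missing={missing} extra={extra}"
            )
        for c, f in self.frequencies.items():
            if not (f >= 0):
                raise CodonTableFormatError(f"codon {c}: negative or invalid frequency {f!r}")
        for aa in AMINO_ACIDS:
            if all(self.frequencies[c] == 0 for c in AA_TO_CODONS[aa]):
                raise DegenerateFamilyError(
                    f"amino acid {aa}: all synonymous codons have zero frequency"
                )

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, float], species_label: str = "", fill: float = 0.0
    ) -> "CodonUsageTable":
        """Build a table from a partial codon->value mapping, padding absent codons.

        Every synonymous family must still end up with one non-zero codon.
        """
        freqs = {c: float(fill) for c in CODONS}
        for codon, value in counts.items():
            key = codon.upper().replace("U", "T")
            if key not in freqs:
                raise CodonTableFormatError(f"unknown codon {codon!r}")
            freqs[key] = float(value)
        return cls(frequencies=freqs, species_label=species_label)

    def family(self, aa: str) -> dict[str, float]:
        return {c: self.frequencies[c] for c in AA_TO_CODONS[aa]}

    def optimal_codon(self, aa: str) -> str:
        """Most frequent codon of the family; lexicographic tie-break."""
        fam = AA_TO_CODONS[aa]
        return max(fam, key=lambda c: (self.frequencies[c], _lex_key(c)))


def _lex_key(codon: str) -> tuple[int, ...]:
    # negated character ranks so that max() prefers the lexicographically
    # *smallest* codon on frequency ties
    return tuple(-ord(ch) for ch in codon)


@dataclass(frozen=True)
class RelativeAdaptiveness:
    """Per-codon w values in [0, 1]; the optimal codon of each family is 1.0."""

    w: Mapping[str, float]
    species_label: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame coding sequence and its translation.

    ``nt`` never carries the terminal stop codon: a single trailing stop in
    the input is trimmed and remembered in ``stop_codon`` so that lengths
    and codon statistics refer to amino-acid-coding positions only.
    """

    id: str
    nt: str
    aa: str
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if len(self.nt) != 3 * len(self.aa):
            raise ValueError(
                f"{self.id}: nt length {len(self.nt)} does not match {len(self.aa)} residues"
            )

    @classmethod
    def from_nt(cls, nt: str, id: str = "seq") -> "CodingSequence":
        s = clean_dna(nt, context=id)
        if len(s) % 3:
            raise AlphabetError(f"{id}: length {len(s)} is not a multiple of 3")
        aa = translate(s)
        stop: str | None = None
        if aa.endswith("*"):
            stop = s[-3:]
            s, aa = s[:-3], aa[:-1]
        if "*" in aa:
            pos = aa.index("*")
            raise AlphabetError(f"{id}: internal stop codon at codon {pos}")
        if not aa:
            raise AlphabetError(f"{id}: no coding codons")
        return cls(id=id, nt=s, aa=aa, stop_codon=stop)

    @property
    def includes_stop(self) -> bool:
        return self.stop_codon is not None

    @property
    def full_nt(self) -> str:
        return self.nt + (self.stop_codon or "")

    @property
    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    @property
    def length_bp(self) -> int:
        return len(self.nt)


# ---------------------------------------------------------------------------
# table parsing

_KAZUSA_ENTRY = re.compile(
    r"([ACGTUacgtu]{3})\s+(\d+(?:\.\d+)?)(?:\s*\(\s*(\d+(?:\.\d+)?)\s*\))?"
)


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0]


def _norm_codon(tok: str, lineno: int) -> str:
    codon = tok.upper().replace("U", "T")
    if len(codon) != 3 or set(codon) - set(BASES):
        raise CodonTableFormatError(f"line {lineno}: invalid codon {tok!r}")
    return codon


def _parse_two_column(text: str) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise CodonTableFormatError(
                f"line {lineno}: expected 'CODON value', got {raw.strip()!r}"
            )
        codon = _norm_codon(tokens[0], lineno)
        try:
            value = float(tokens[1])
        except ValueError:
            raise CodonTableFormatError(
                f"line {lineno}: unparseable frequency {tokens[1]!r}"
            ) from None
        if codon in freqs:
            raise CodonTableFormatError(f"line {lineno}: duplicate codon {codon}")
        freqs[codon] = value
    return freqs


def _parse_kazusa(text: str) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        consumed = 0
        for m in _KAZUSA_ENTRY.finditer(line):
            gap = line[consumed : m.start()]
            if gap.strip():
                raise CodonTableFormatError(
                    f"line {lineno}: unparseable text {gap.strip()!r}"
                )
            consumed = m.end()
            codon = _norm_codon(m.group(1), lineno)
            if codon in freqs:
                raise CodonTableFormatError(f"line {lineno}: duplicate codon {codon}")
            freqs[codon] = float(m.group(2))
        tail = line[consumed:]
        if tail.strip() or consumed == 0:
            raise CodonTableFormatError(
                f"line {lineno}: unparseable text {tail.strip() or line!r}"
            )
    return freqs


def load_codon_table(
    path: Union[str, Path],
    dialect: str = "auto",
    species_label: str | None = None,
) -> CodonUsageTable:
    """Load a codon usage table file.

    Two dialects are supported: ``two-column`` (one ``CODON value`` pair per
    line) and ``kazusa`` (the Kazusa-style text grid of ``codon freq(count)``
    entries, several per line, RNA or DNA alphabet).  ``auto`` picks
    ``two-column`` when every data line carries exactly two tokens.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        data_lines = [
            ln for ln in (_strip_comment(l).strip() for l in text.splitlines()) if ln
        ]
        if data_lines and all(len(ln.split()) == 2 for ln in data_lines):
            dialect = "two-column"
        else:
            dialect = "kazusa"
    if dialect == "two-column":
        freqs = _parse_two_column(text)
    elif dialect in ("kazusa", "kazusa-text"):
        freqs = _parse_kazusa(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = sorted(set(CODONS) - set(freqs))
    if missing:
        raise CodonTableFormatError(f"{path.name}: missing codons {missing}")
    return CodonUsageTable(
        frequencies=freqs,
        species_label=species_label if species_label is not None else path.stem,
    )


def load_human_table() -> CodonUsageTable:
    """The bundled genome-wide human codon usage table (per-thousand)."""
    ref = resources.files("codonopt.data").joinpath("human_codon_usage.txt")
    freqs = _parse_kazusa(ref.read_text())
    return CodonUsageTable(frequencies=freqs, species_label="Homo sapiens (genome-wide)")


# ---------------------------------------------------------------------------
# relative adaptiveness and CAI

def relative_adaptiveness(table: CodonUsageTable) -> RelativeAdaptiveness:
    """w(c) = f(c) / max synonymous f, per amino-acid family (stops excluded)."""
    w: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        fam = AA_TO_CODONS[aa]
        m = max(table.frequencies[c] for c in fam)
        if m <= 0:
            raise DegenerateFamilyError(f"amino acid {aa}: zero-frequency family")
        for c in fam:
            w[c] = table.frequencies[c] / m
    return RelativeAdaptiveness(w=w, species_label=table.species_label)


def _as_coding_sequence(seq: Union[CodingSequence, str], id: str = "seq") -> CodingSequence:
    if isinstance(seq, CodingSequence):
        return seq
    return CodingSequence.from_nt(seq, id=id)


def cai(
    seq: Union[CodingSequence, str],
    table: Union[CodonUsageTable, RelativeAdaptiveness],
    exclude_single_codon_families: bool = False,
    zero_w_floor: float = ZERO_W_FLOOR,
) -> float:
    """Codon adaptation index: geometric mean of w over counted codons.

    The terminal stop codon is never counted.  Codons with w = 0 in the
    reference table enter the product at ``zero_w_floor``.  Single-codon
    families (Met, Trp) contribute factors of exactly 1.0 and are counted
    unless ``exclude_single_codon_families`` asks for the variant CAI that
    drops them.
    """
    cds = _as_coding_sequence(seq)
    adapt = table if isinstance(table, RelativeAdaptiveness) else relative_adaptiveness(table)
    log_sum = 0.0
    n = 0
    for codon in cds.codons:
        if exclude_single_codon_families and CODON_TO_AA[codon] in SINGLE_CODON_AAS:
            continue
        w = adapt.w[codon]
        if w <= 0:
            w = zero_w_floor
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise UndefinedCaiError(f"{cds.id}: no countable codons for CAI")
    return math.exp(log_sum / n)


def back_translate_optimal(
    aa: str, table: CodonUsageTable, seq_id: str = "optimal"
) -> CodingSequence:
    """Encode every residue with its most frequent synonymous codon.

    The result has CAI = 1.0 by construction.  A single trailing ``*`` is
    honoured by attaching the table's most frequent stop codon.
    """
    if not aa:
        raise AlphabetError("empty protein sequence")
    protein = aa.upper()
    stop: str | None = None
    if protein.endswith("*"):
        protein = protein[:-1]
        stop = max(STOP_CODONS, key=lambda c: (table.frequencies[c], _lex_key(c)))
    bad = set(protein) - set(AMINO_ACIDS)
    if bad or not protein:
        raise AlphabetError(f"unknown residue symbols {sorted(bad)}")
    nt = "".join(table.optimal_codon(res) for res in protein)
    return CodingSequence(id=seq_id, nt=nt, aa=protein, stop_codon=stop)
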