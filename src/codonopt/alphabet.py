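"""DNA alphabet and standard genetic code helpers shared across the package.

All sequences handled here are plain ``str`` over the DNA alphabet ACGT;
mRNA-level features (UpA dinucleotides, AU-rich elements) are expressed at
the DNA level (TA, ATTTA).  The genetic code is the standard nuclear code
(NCBI translation table 1), taken from Biopython's codon table data.
"""

from __future__ import annotations

from Bio.Data import CodonTable as _bio_codon_table

BASES = "ACGT"
STANDARD_CODE_ID = 1

_STD = _bio_codon_table.unambiguous_dna_by_id[STANDARD_CODE_ID]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: all 64 codons in lexicographic order
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS = tuple(sorted(_STD.stop_codons))

#: codon -> one-letter amino acid, with "*" for the three stop codons
CODON_TO_AA = {c: _STD.forward_table.get(c, "*") for c in CODONS}

_aa_to_codons: dict[str, list[str]] = {}
for _c in CODONS:
    _aa = CODON_TO_AA[_c]
    if _aa != "*":
        _aa_to_codons.setdefault(_aa, []).append(_c)
#: amino acid -> synonymous codon family (lexicographically sorted)
AA_TO_CODONS = {aa: tuple(sorted(cs)) for aa, cs in _aa_to_codons.items()}
AMINO_ACIDS = tuple(sorted(AA_TO_CODONS))
SINGLE_CODON_AAS = frozenset(a for a, cs in AA_TO_CODONS.items() if len(cs) == 1)


class AlphabetError(ValueError):
    """Raised for sequences or symbols outside the expected alphabet."""


def clean_dna(nt: str, *, context: str = "sequence") -> str:
    """Uppercase ``nt`` and verify it is non-empty and strictly ACGT."""
    if not isinstance(nt, str):
        raise AlphabetError(f"{context}: expected a string, got {type(nt).__name__}")
    s = nt.upper()
    if not s:
        raise AlphabetError(f"{context}: empty sequence")
    bad = set(s) - set(BASES)
    if bad:
        raise AlphabetError(f"{context}: non-ACGT symbols {sorted(bad)}")
    return s


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate an in-frame DNA string; stop codons become ``*``."""
    if len(nt) % 3:
        raise AlphabetError(f"length {len(nt)} is not a multiple of 3")
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt), 3))
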