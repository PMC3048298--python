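"""FASTA I/O, wt/opt pairing, comparison reports, expression-ratio summaries
and synthetic ORF fixture generation.

The comparison report reproduces the column set used to characterize
wildtype versus sequence-optimized construct panels: ORF length, CAI and
GC% of both variants, and the number and percentage of codons altered.
A reference panel of 50 human genes with these published metrics is
bundled for consistency checks and ratio statistics.
"""

from __future__ import annotations

import math
import random
import statistics
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_TO_CODONS, AMINO_ACIDS, CODON_TO_AA, clean_dna
from .codon_model import CodingSequence, CodonUsageTable, cai, relative_adaptiveness
from .seq_metrics import (
    codons_altered,
    differing_codon_positions,
    gc_content,
    percent_half_up,
)

__all__ = [
    "FastaFormatError",
    "ExpressionRatioRecord",
    "RatioSummary",
    "read_fasta",
    "write_fasta",
    "pair_records",
    "table1_report",
    "summarize_ratios",
    "load_reference_panel",
    "panel_percent_consistency",
    "generate_fixture_orf",
    "mutate_synonymous",
]

#: ratio substituted for "only the optimized construct expressed" records
#: when computing the median opt/wt expression ratio
ONLY_OPT_MEDIAN_RATIO = 2.0

#: a relative expression change of at least 10% counts as a real difference
DEFAULT_IMPROVEMENT_MARGIN = 0.10


class FastaFormatError(ValueError):
    pass


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    Duplicate ids and empty sequences are format errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} is empty")
        records.append((rec.id, seq))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: Union[str, Path], wrap: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            s = seq.upper()
            for i in range(0, len(s), wrap):
                fh.write(s[i : i + wrap] + "\n")


def pair_records(
    records: Sequence[tuple[str, str]],
    wt_suffix: str = "_wt",
    opt_suffix: str = "_opt",
) -> tuple[list[tuple[CodingSequence, CodingSequence]], list[str]]:
    """Pair wildtype/optimized records by a shared base id and suffix rule.

    Returns (pairs, unpaired ids).  Pairs are ordered by base id so the
    result is independent of input order.  A pair whose translations differ
    is kept but triggers a loud warning listing the differing codon
    positions.
    """
    by_base: dict[str, dict[str, str]] = {}
    unpaired: list[str] = []
    for rec_id, seq in records:
        if rec_id.endswith(wt_suffix):
            by_base.setdefault(rec_id[: -len(wt_suffix)], {})["wt"] = seq
        elif rec_id.endswith(opt_suffix):
            by_base.setdefault(rec_id[: -len(opt_suffix)], {})["opt"] = seq
        else:
            unpaired.append(rec_id)

    pairs = []
    for base in sorted(by_base):
        slot = by_base[base]
        if "wt" not in slot or "opt" not in slot:
            unpaired.append(base + (wt_suffix if "wt" in slot else opt_suffix))
            continue
        wt = CodingSequence.from_nt(slot["wt"], id=base + wt_suffix)
        opt = CodingSequence.from_nt(slot["opt"], id=base + opt_suffix)
        if wt.aa != opt.aa:
            diffs = differing_codon_positions(wt, opt) if len(wt.nt) == len(opt.nt) else []
            warnings.warn(
                f"pair {base!r} is NOT synonymous; differing codon positions: "
                f"{[i for i in diffs if CODON_TO_AA[wt.codons[i]] != CODON_TO_AA[opt.codons[i]]] or 'length mismatch'}",
                stacklevel=2,
            )
        pairs.append((wt, opt))
    return pairs, sorted(unpaired)


def table1_report(
    pairs: Sequence[tuple[CodingSequence, CodingSequence]],
    table: CodonUsageTable,
) -> pd.DataFrame:
    """Per-pair comparison metrics: length, CAI, GC% and codons altered."""
    adapt = relative_adaptiveness(table)
    rows = []
    for wt, opt in pairs:
        cmp = codons_altered(wt, opt)
        rows.append(
            {
                "id": wt.id.removesuffix("_wt") if wt.id.endswith("_wt") else wt.id,
                "length_bp": wt.length_bp,
                "cai_wt": round(cai(wt, adapt), 2),
                "cai_opt": round(cai(opt, adapt), 2),
                "gc_wt_pct": percent_half_up(
                    wt.nt.count("G") + wt.nt.count("C"), wt.length_bp
                ),
                "gc_opt_pct": percent_half_up(
                    opt.nt.count("G") + opt.nt.count("C"), opt.length_bp
                ),
                "codons_altered_n": cmp.codons_altered_n,
                "codons_altered_pct": cmp.codons_altered_percent,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression ratio summaries

@dataclass(frozen=True)
class ExpressionRatioRecord:
    """Mean optimized/wildtype expression ratio for one construct pair.

    ``only_opt`` marks pairs where the wildtype produced no detectable
    expression, so a numeric ratio does not exist.
    """

    id: str
    ratio: float | None = None
    only_opt: bool = False
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.only_opt:
            if self.ratio is not None:
                raise ValueError(f"{self.id}: only_opt excludes a numeric ratio")
        else:
            if self.ratio is None or not self.ratio > 0:
                raise ValueError(f"{self.id}: ratio must be positive, got {self.ratio!r}")


@dataclass(frozen=True)
class RatioSummary:
    median_opt_over_wt: float
    pct_opt_gt_wt: float
    counts: dict[str, int]  # improved / equal / worse
    n: int


def _coerce_ratio_record(item, idx: int) -> ExpressionRatioRecord:
    if isinstance(item, ExpressionRatioRecord):
        return item
    if isinstance(item, str) and item == "only_opt":
        return ExpressionRatioRecord(id=f"r{idx}", only_opt=True)
    return ExpressionRatioRecord(id=f"r{idx}", ratio=float(item))


def summarize_ratios(
    records: Sequence,
    improvement_margin: float = DEFAULT_IMPROVEMENT_MARGIN,
    only_opt_ratio: float = ONLY_OPT_MEDIAN_RATIO,
) -> RatioSummary:
    """Median opt/wt ratio and improved/equal/worse counts.

    Records may be :class:`ExpressionRatioRecord`, numbers, or the string
    ``"only_opt"``.  only_opt records enter the median at ``only_opt_ratio``
    (the published convention sets them to 2) and always count as improved.
    A numeric ratio >= 1 + margin is improved, <= 1 - margin worse,
    otherwise equal.
    """
    if not records:
        raise ValueError("empty record list")
    recs = [_coerce_ratio_record(r, i) for i, r in enumerate(records)]
    values = [only_opt_ratio if r.only_opt else r.ratio for r in recs]
    counts = {"improved": 0, "equal": 0, "worse": 0}
    for r in recs:
        if r.only_opt or r.ratio >= 1 + improvement_margin:
            counts["improved"] += 1
        elif r.ratio <= 1 - improvement_margin:
            counts["worse"] += 1
        else:
            counts["equal"] += 1
    return RatioSummary(
        median_opt_over_wt=float(statistics.median(values)),
        pct_opt_gt_wt=100.0 * counts["improved"] / len(recs),
        counts=counts,
        n=len(recs),
    )


# ---------------------------------------------------------------------------
# bundled reference panel

def load_reference_panel() -> pd.DataFrame:
    """The bundled 50-gene wildtype/optimized construct comparison panel.

    Published per-construct metrics (ORF length, CAI, GC%, codons altered,
    relative expression) from a large-scale human autologous-expression
    study; ``expression_ratio`` is numeric or the string ``only_opt``.
    """
    ref = resources.files("codonopt.data").joinpath("expression_panel.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def panel_ratio_records(panel: pd.DataFrame) -> list[ExpressionRatioRecord]:
    """Expression-ratio records of a reference panel DataFrame."""
    out = []
    for row in panel.itertuples():
        if str(row.expression_ratio) == "only_opt":
            out.append(
                ExpressionRatioRecord(id=row.symbol, only_opt=True,
                                      class_label=row.protein_class)
            )
        else:
            out.append(
                ExpressionRatioRecord(id=row.symbol, ratio=float(row.expression_ratio),
                                      class_label=row.protein_class)
            )
    return out


def panel_percent_consistency(panel: pd.DataFrame) -> pd.DataFrame:
    """Re-derive codons-altered percentages from n and ORF length.

    Only rows whose printed length is divisible by 3 are checkable; the
    returned frame carries the recomputed percentage and a match flag
    against the printed value.
    """
    rows = []
    for row in panel.itertuples():
        if row.length_bp % 3:
            continue
        n_codons = row.length_bp // 3
        recomputed = percent_half_up(int(row.codons_altered_n), n_codons)
        rows.append(
            {
                "symbol": row.symbol,
                "n_codons": n_codons,
                "codons_altered_n": int(row.codons_altered_n),
                "printed_pct": int(row.codons_altered_pct),
                "recomputed_pct": recomputed,
                "match": recomputed == int(row.codons_altered_pct),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixtures

def generate_fixture_orf(
    aa_length: int,
    table: CodonUsageTable,
    gc_bias: float = 0.0,
    seed: int = 0,
    seq_id: str | None = None,
) -> CodingSequence:
    """A reproducible random ORF with usage-weighted codon sampling.

    The protein starts with Met followed by uniformly random residues; each
    codon is drawn with probability proportional to its table frequency
    tilted by ``exp(gc_bias * GC(codon))``, so negative ``gc_bias`` emulates
    AT-rich, poorly adapted wildtype genes and positive values GC-rich ones.
    """
    if aa_length < 1:
        raise ValueError("aa_length must be >= 1")
    rng = random.Random(seed)
    aa = "M" + "".join(rng.choices(AMINO_ACIDS, k=aa_length - 1))
    max_f = max(table.frequencies.values())
    codons = []
    for res in aa:
        fam = AA_TO_CODONS[res]
        weights = [
            (table.frequencies[c] / max_f + 0.02)
            * math.exp(gc_bias * (c.count("G") + c.count("C")))
            for c in fam
        ]
        codons.append(rng.choices(fam, weights=weights)[0])
    return CodingSequence(
        id=seq_id or f"fixture_{aa_length}aa_seed{seed}",
        nt="".join(codons),
        aa=aa,
    )


def mutate_synonymous(
    seq: CodingSequence, fraction: float, seed: int = 0
) -> CodingSequence:
    """Synonymously mutate about ``fraction`` of the mutable codons.

    Codons from single-codon families (Met, Trp) are immutable; each other
    codon is replaced by a uniformly chosen different synonymous codon with
    probability ``fraction``.  Translation is preserved exactly.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = random.Random(seed)
    out = []
    for codon in seq.codons:
        fam = AA_TO_CODONS[CODON_TO_AA[codon]]
        if len(fam) > 1 and rng.random() < fraction:
            out.append(rng.choice([c for c in fam if c != codon]))
        else:
            out.append(codon)
    return CodingSequence(
        id=seq.id + "_mut", nt="".join(out), aa=seq.aa, stop_codon=seq.stop_codon
    )
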