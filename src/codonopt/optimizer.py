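"""Quality-function scoring and the unidirectional sliding-window search.

The optimizer rewrites a coding sequence (or back-translates a protein)
codon by codon, 5' to 3'.  At each step a variation window of a few codons
is enumerated exhaustively over the synonymous codons of its residues;
every candidate (already-fixed prefix + window) is scored with a weighted
quality function covering codon usage, GC deviation from a target,
CpG/UpA dinucleotides, deleterious motifs, cryptic splice sites, direct
repeats and hairpins.  The first codon of the best candidate's window is
committed and the window shifts one codon towards the 3' end; at the
terminus the whole remaining window is committed.

Everything is deterministic: candidates are enumerated in lexicographic
order and score ties keep the lexicographically smallest window, so two
runs on identical input produce byte-identical output.

Candidates that would introduce a *new* occurrence of a hard-constraint
motif are rejected outright; occurrences already present in the fixed
prefix do not disqualify (this prevents deadlock once a motif has been
flagged unavoidable).  When every synonymous choice in a window carries
the motif, the best-scoring candidate is accepted anyway and the run is
flagged as carrying an unavoidable hard-constraint hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence, Union

import yaml

from .alphabet import AA_TO_CODONS, AMINO_ACIDS, AlphabetError
from .codon_model import (
    CodingSequence,
    CodonUsageTable,
    RelativeAdaptiveness,
    relative_adaptiveness,
)
from .feature_scan import (
    FeatureHit,
    MotifEntry,
    MotifLibrary,
    SpliceSiteModel,
    default_motif_library,
    find_direct_repeats,
    find_hairpins,
    scan_motifs,
    score_splice_sites,
    _compile_iupac,
)
from .seq_metrics import MetricReport, PairComparison, codons_altered, metric_report

__all__ = [
    "WEIGHT_KEYS",
    "QualityConfig",
    "OptimizationResult",
    "EnumerationCapError",
    "SizeError",
    "load_quality_config",
    "score_candidate",
    "optimize",
    "brute_force_optimize",
]

WEIGHT_KEYS = (
    "codon_usage",
    "gc_deviation",
    "cpg_reward",
    "upa_penalty",
    "motif_penalty",
    "splice_penalty",
    "repeat_penalty",
    "hairpin_penalty",
)

# declared, configurable stand-ins; the published comparison panel's CAI and
# GC bands of optimized constructs are the calibration surface
DEFAULT_WEIGHTS = {
    "codon_usage": 1.0,
    "gc_deviation": 0.02,
    "cpg_reward": 0.01,
    "upa_penalty": 0.02,
    "motif_penalty": 0.5,
    "splice_penalty": 0.25,
    "repeat_penalty": 0.25,
    "hairpin_penalty": 0.25,
}


class EnumerationCapError(ValueError):
    """A window would require more candidates than the configured cap."""


class SizeError(ValueError):
    """Brute-force enumeration bound exceeded."""


def _default_hard_constraints() -> tuple[MotifEntry, ...]:
    return default_motif_library().hard_entries


@dataclass(frozen=True)
class QualityConfig:
    """Weights, targets and hard constraints for the sliding-window search.

    ``gc_target_percent`` defaults to 60, the midpoint of the GC band that
    optimized mammalian transgenes typically land in.  The 5' ramp doubles
    the codon-usage weight over the first 15 codons so that bad codons are
    avoided most strictly near the start of translation.
    """

    window_codons: int = 5
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    gc_target_percent: float = 60.0
    gc_window_nt: int = 60
    lookback_nt: int = 60
    five_prime_ramp_codons: int = 15
    five_prime_ramp_multiplier: float = 2.0
    min_codon_w: float = 0.1
    enumeration_cap: int = 100_000
    hard_constraints: tuple[MotifEntry, ...] = field(
        default_factory=_default_hard_constraints
    )
    repeat_min_len: int = 8
    hairpin_min_stem: int = 8
    hairpin_loop_range: tuple[int, int] = (3, 30)

    def __post_init__(self) -> None:
        if self.window_codons < 1:
            raise ValueError("window_codons must be >= 1")
        if not 0 <= self.min_codon_w < 1:
            raise ValueError("min_codon_w must be in [0, 1)")
        if not 0 <= self.gc_target_percent <= 100:
            raise ValueError("gc_target_percent must be in [0, 100]")
        if self.five_prime_ramp_multiplier < 1:
            raise ValueError("five_prime_ramp_multiplier must be >= 1")
        unknown = set(self.weights) - set(WEIGHT_KEYS)
        if unknown:
            raise ValueError(f"unknown weight terms {sorted(unknown)}")
        merged = {k: 0.0 for k in WEIGHT_KEYS}
        merged.update(self.weights)
        for k, v in merged.items():
            if v < 0:
                raise ValueError(f"weight {k} must be >= 0, got {v}")
        object.__setattr__(self, "weights", merged)
        object.__setattr__(self, "hard_constraints", tuple(self.hard_constraints))

    @classmethod
    def usage_only(cls, **overrides) -> "QualityConfig":
        """Codon usage as the single active term; no hard constraints."""
        kw = dict(
            weights={"codon_usage": 1.0},
            hard_constraints=(),
            min_codon_w=0.0,
        )
        kw.update(overrides)
        return cls(**kw)


def load_quality_config(path: str | Path) -> QualityConfig:
    """Read a :class:`QualityConfig` from a YAML file.

    Recognized keys mirror the dataclass fields; ``hard_constraints`` is a
    list of motif entries ``{name, pattern, penalty}``.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    for key in (
        "window_codons", "weights", "gc_target_percent", "gc_window_nt",
        "lookback_nt", "five_prime_ramp_codons", "five_prime_ramp_multiplier",
        "min_codon_w", "enumeration_cap", "repeat_min_len", "hairpin_min_stem",
    ):
        if key in doc:
            kw[key] = doc[key]
    if "hairpin_loop_range" in doc:
        kw["hairpin_loop_range"] = tuple(doc["hairpin_loop_range"])
    if "hard_constraints" in doc:
        kw["hard_constraints"] = tuple(
            MotifEntry(
                name=str(m["name"]),
                pattern=str(m["pattern"]),
                penalty=float(m.get("penalty", 1.0)),
                hard=True,
                kind=str(m.get("kind", "motif")),
            )
            for m in doc["hard_constraints"]
        )
    return QualityConfig(**kw)


@dataclass(frozen=True)
class OptimizationResult:
    input: Union[CodingSequence, str]
    output: CodingSequence
    score_trace: tuple[tuple[int, int, float], ...]  # (window start codon, candidates, best score)
    report_after: MetricReport
    report_before: MetricReport | None = None
    comparison: PairComparison | None = None
    unavoidable_hits: tuple[FeatureHit, ...] = ()

    @property
    def unavoidable(self) -> bool:
        return bool(self.unavoidable_hits)


# ---------------------------------------------------------------------------
# scoring

def _count_new_hard(ctx: str, prefix_len: int, hard: Sequence[MotifEntry]) -> tuple[int, float]:
    """Occurrences of hard motifs in ctx; 'new' = extending past the prefix."""
    n_new = 0
    pen = 0.0
    for entry in hard:
        rx = _compile_iupac(entry.pattern)
        plen = len(entry.pattern)
        for m in rx.finditer(ctx):
            pen += entry.penalty
            if m.start() + plen > prefix_len:
                n_new += 1
    return n_new, pen


def _score_parts(
    prefix_tail: str,
    window_nt: str,
    position: int,
    cfg: QualityConfig,
    adapt: RelativeAdaptiveness,
    lib: MotifLibrary | None,
    splice: SpliceSiteModel | None,
) -> tuple[float, int]:
    """Weighted quality score of prefix_tail+window and the count of newly
    introduced hard-constraint occurrences."""
    w = cfg.weights
    ctx = prefix_tail + window_nt
    score = 0.0

    if w["codon_usage"]:
        vals = [
            adapt.w[window_nt[i : i + 3]] for i in range(0, len(window_nt), 3)
        ]
        mult = (
            cfg.five_prime_ramp_multiplier
            if position < cfg.five_prime_ramp_codons
            else 1.0
        )
        score += w["codon_usage"] * mult * (sum(vals) / len(vals))

    if w["gc_deviation"]:
        region = ctx[-cfg.gc_window_nt :] if cfg.gc_window_nt else ctx
        gc = 100.0 * (region.count("G") + region.count("C")) / len(region)
        score -= w["gc_deviation"] * abs(gc - cfg.gc_target_percent)

    if w["cpg_reward"]:
        score += w["cpg_reward"] * ctx.count("CG")
    if w["upa_penalty"]:
        score -= w["upa_penalty"] * ctx.count("TA")

    if w["motif_penalty"] and lib is not None and lib.soft_entries:
        soft = MotifLibrary(entries=lib.soft_entries, strand_mode=lib.strand_mode)
        score -= w["motif_penalty"] * sum(h.score for h in scan_motifs(ctx, soft))

    if w["splice_penalty"] and splice is not None:
        score -= w["splice_penalty"] * len(score_splice_sites(ctx, splice))

    if w["repeat_penalty"]:
        score -= w["repeat_penalty"] * len(
            find_direct_repeats(ctx, min_len=cfg.repeat_min_len)
        )

    if w["hairpin_penalty"]:
        score -= w["hairpin_penalty"] * len(
            find_hairpins(ctx, min_stem=cfg.hairpin_min_stem,
                          loop_range=cfg.hairpin_loop_range)
        )

    n_new_hard = 0
    if cfg.hard_constraints:
        n_new_hard, hard_pen = _count_new_hard(ctx, len(prefix_tail), cfg.hard_constraints)
        if w["motif_penalty"]:
            score -= w["motif_penalty"] * hard_pen

    return score, n_new_hard


def score_candidate(
    prefix: str,
    window_nt: str,
    position: int,
    cfg: QualityConfig,
    adapt: RelativeAdaptiveness,
    lib: MotifLibrary | None = None,
    splice: SpliceSiteModel | None = None,
) -> float:
    """Quality score of one candidate; -inf when it introduces a new
    hard-constraint motif occurrence absent from the fixed prefix."""
    if len(prefix) % 3 or len(window_nt) % 3 or not window_nt:
        raise ValueError("prefix and window must be non-degenerate and in frame")
    tail = prefix[-cfg.lookback_nt :] if cfg.lookback_nt else prefix
    score, n_hard = _score_parts(tail, window_nt, position, cfg, adapt, lib, splice)
    return -math.inf if n_hard else score


# ---------------------------------------------------------------------------
# candidate enumeration

def _codon_families(
    aa: str, adapt: RelativeAdaptiveness, cfg: QualityConfig
) -> list[tuple[str, ...]]:
    """Per-residue candidate codons, pruned at min_codon_w (>= 1 kept)."""
    fams = []
    for res in aa:
        codons = AA_TO_CODONS.get(res)
        if codons is None:
            raise AlphabetError(f"unknown residue symbol {res!r}")
        kept = tuple(c for c in codons if adapt.w[c] >= cfg.min_codon_w)
        if not kept:
            kept = (max(codons, key=lambda c: adapt.w[c]),)
        fams.append(kept)
    return fams


def _best_candidate(
    fams: Sequence[tuple[str, ...]],
    prefix_tail: str,
    position: int,
    cfg: QualityConfig,
    adapt: RelativeAdaptiveness,
    lib: MotifLibrary | None,
    splice: SpliceSiteModel | None,
) -> tuple[str, float, bool, int]:
    """Best window over the lexicographic product of ``fams``.

    Feasible candidates (no new hard-constraint occurrence) always beat
    infeasible ones; among infeasible ones, fewer new occurrences win.
    Strict comparison over the lexicographically ordered enumeration makes
    the tie-break the smallest window string.  Returns (window, score,
    feasible, n_candidates).
    """
    best_key: tuple | None = None
    best_window = ""
    best_score = -math.inf
    best_feasible = False
    n = 0
    for combo in product(*fams):
        window = "".join(combo)
        score, n_hard = _score_parts(
            prefix_tail, window, position, cfg, adapt, lib, splice
        )
        key = (1, score) if n_hard == 0 else (0, -n_hard, score)
        if best_key is None or key > best_key:
            best_key, best_window, best_score, best_feasible = (
                key, window, score, n_hard == 0
            )
        n += 1
    return best_window, best_score, best_feasible, n


def _hard_library(cfg: QualityConfig) -> MotifLibrary | None:
    if not cfg.hard_constraints:
        return None
    return MotifLibrary(entries=cfg.hard_constraints, strand_mode="sense-only")


def optimize(
    input: Union[CodingSequence, str],
    table: CodonUsageTable,
    cfg: QualityConfig | None = None,
    lib: MotifLibrary | None = None,
    splice: SpliceSiteModel | None = None,
    seq_id: str | None = None,
) -> OptimizationResult:
    """Sliding-window optimization of a protein or coding sequence.

    ``input`` may be a protein string or a :class:`CodingSequence`; a CDS is
    reduced to its translation and the result additionally carries the
    before-metrics and the codon-level comparison.  ``lib`` supplies soft
    scored motifs (default library when omitted); hard constraints live in
    ``cfg.hard_constraints``.
    """
    cfg = cfg or QualityConfig()
    if lib is None:
        lib = default_motif_library()
    if splice is None and cfg.weights["splice_penalty"]:
        splice = SpliceSiteModel()

    if isinstance(input, CodingSequence):
        aa = input.aa
        out_id = seq_id or f"{input.id}_opt"
    else:
        aa = str(input).upper().rstrip("*")
        bad = set(aa) - set(AMINO_ACIDS)
        if bad or not aa:
            raise AlphabetError(f"invalid protein sequence (bad symbols {sorted(bad)})")
        out_id = seq_id or "optimized"

    adapt = relative_adaptiveness(table)
    families = _codon_families(aa, adapt, cfg)
    n_res = len(aa)

    fixed: list[str] = []
    trace: list[tuple[int, int, float]] = []
    unavoidable_positions: list[int] = []
    i = 0
    while i < n_res:
        wlen = min(cfg.window_codons, n_res - i)
        fams = families[i : i + wlen]
        n_comb = math.prod(len(f) for f in fams)
        if n_comb > cfg.enumeration_cap:
            raise EnumerationCapError(
                f"window at codon {i} needs {n_comb} candidates "
                f"(cap {cfg.enumeration_cap}); reduce window_codons or raise min_codon_w"
            )
        prefix = "".join(fixed)
        tail = prefix[-cfg.lookback_nt :] if cfg.lookback_nt else prefix
        window, score, feasible, n_eval = _best_candidate(
            fams, tail, i, cfg, adapt, lib, splice
        )
        if not feasible:
            unavoidable_positions.append(i)
        trace.append((i, n_eval, score))
        if i + wlen >= n_res:
            fixed.extend(window[j : j + 3] for j in range(0, len(window), 3))
            i = n_res
        else:
            fixed.append(window[:3])
            i += 1

    out_nt = "".join(fixed)
    output = CodingSequence(id=out_id, nt=out_nt, aa=aa)

    unavoidable_hits: tuple[FeatureHit, ...] = ()
    hard_lib = _hard_library(cfg)
    if hard_lib is not None:
        unavoidable_hits = tuple(scan_motifs(out_nt, hard_lib))

    report_before = None
    comparison = None
    if isinstance(input, CodingSequence):
        report_before = metric_report(input, table)
        comparison = codons_altered(input, output)

    return OptimizationResult(
        input=input,
        output=output,
        score_trace=tuple(trace),
        report_after=metric_report(output, table),
        report_before=report_before,
        comparison=comparison,
        unavoidable_hits=unavoidable_hits,
    )


def brute_force_optimize(
    aa: str,
    table: CodonUsageTable,
    cfg: QualityConfig | None = None,
    lib: MotifLibrary | None = None,
    splice: SpliceSiteModel | None = None,
    max_residues: int = 8,
    max_combinations: int = 10_000_000,
) -> tuple[str, float]:
    """Global optimum of the quality function over a tiny peptide.

    Enumerates every synonymous encoding of ``aa`` (same per-residue codon
    pruning as :func:`optimize`), scores each complete sequence with the
    identical quality function and returns the best (ties resolved to the
    lexicographically smallest sequence).  Serves as the exhaustive oracle
    for the sliding-window search.
    """
    cfg = cfg or QualityConfig()
    if lib is None:
        lib = default_motif_library()
    if splice is None and cfg.weights["splice_penalty"]:
        splice = SpliceSiteModel()
    aa = str(aa).upper().rstrip("*")
    if len(aa) > max_residues:
        raise SizeError(f"{len(aa)} residues exceeds brute-force bound {max_residues}")
    adapt = relative_adaptiveness(table)
    fams = _codon_families(aa, adapt, cfg)
    n_comb = math.prod(len(f) for f in fams)
    if n_comb > max_combinations:
        raise SizeError(f"{n_comb} combinations exceed bound {max_combinations}")
    window, score, feasible, _ = _best_candidate(fams, "", 0, cfg, adapt, lib, splice)
    return window, score
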