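"""Quality-function scoring and the sliding-window search."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonopt.alphabet import AMINO_ACIDS, translate
from codonopt.codon_model import back_translate_optimal, cai, relative_adaptiveness
from codonopt.feature_scan import MotifEntry, MotifLibrary, default_motif_library
from codonopt.io_report import generate_fixture_orf
from codonopt.optimizer import (
    EnumerationCapError,
    QualityConfig,
    brute_force_optimize,
    optimize,
    score_candidate,
)
from codonopt.seq_metrics import gc_content, verify_synonymous
from conftest import make_table

EMPTY_LIB = MotifLibrary()


def usage_cfg(**kw):
    return QualityConfig.usage_only(**kw)


# ---------------------------------------------------------------------------
# scoring

def test_usage_only_window_of_optimal_codons_scores_ramped_one(human_table):
    adapt = relative_adaptiveness(human_table)
    cfg = usage_cfg()
    nt = back_translate_optimal("KLVE", human_table).nt
    # inside the 5' ramp the usage term is doubled
    assert score_candidate("", nt, 0, cfg, adapt, EMPTY_LIB) == pytest.approx(
        cfg.five_prime_ramp_multiplier
    )
    assert score_candidate("", nt, 50, cfg, adapt, EMPTY_LIB) == pytest.approx(1.0)


def test_usage_monotonicity(human_table):
    adapt = relative_adaptiveness(human_table)
    cfg = usage_cfg()
    hi = score_candidate("", "ATGCTG", 20, cfg, adapt, EMPTY_LIB)  # M + optimal Leu
    lo = score_candidate("", "ATGCTC", 20, cfg, adapt, EMPTY_LIB)  # M + w~0.49 Leu
    assert hi > lo


def test_new_hard_motif_rejected(human_table):
    adapt = relative_adaptiveness(human_table)
    cfg = QualityConfig()  # default hard constraints include AATAAA
    assert score_candidate("", "AATAAA", 0, cfg, adapt, EMPTY_LIB) == -math.inf


def test_preexisting_hard_motif_in_prefix_tolerated(human_table):
    adapt = relative_adaptiveness(human_table)
    cfg = QualityConfig()
    # motif entirely inside the fixed prefix: candidate not disqualified
    score = score_candidate("AATAAAGGG", "ATGCTG", 3, cfg, adapt, EMPTY_LIB)
    assert math.isfinite(score)


# ---------------------------------------------------------------------------
# optimization

def test_no_synonymous_freedom(human_table):
    res = optimize("MW", human_table)
    assert res.output.nt == "ATGTGG"


def test_usage_only_equals_optimal_backtranslation(human_table):
    cfg = usage_cfg()
    rng = random.Random(7)
    for _ in range(6):
        aa = "M" + "".join(rng.choices(AMINO_ACIDS, k=30))
        res = optimize(aa, human_table, cfg=cfg, lib=EMPTY_LIB)
        assert res.output.nt == back_translate_optimal(aa, human_table).nt
        assert cai(res.output, human_table) == pytest.approx(1.0)


def test_usage_only_equivalence_any_window(human_table):
    aa = "MLSRKGAVE"
    for window in (1, 2, 3, 7):
        res = optimize(aa, human_table, cfg=usage_cfg(window_codons=window), lib=EMPTY_LIB)
        assert res.output.nt == back_translate_optimal(aa, human_table).nt


def _oracle_configs():
    return [
        usage_cfg(window_codons=5),
        QualityConfig(
            window_codons=5,
            weights={"codon_usage": 1.0, "gc_deviation": 0.05},
            gc_target_percent=40.0,
            hard_constraints=(),
            min_codon_w=0.0,
        ),
        QualityConfig(
            window_codons=5,
            weights={"codon_usage": 1.0, "motif_penalty": 0.5},
            hard_constraints=(
                MotifEntry("polyA_AATAAA", "AATAAA", hard=True, kind="polyA"),
                MotifEntry("polyA_ATTAAA", "ATTAAA", hard=True, kind="polyA"),
            ),
            min_codon_w=0.0,
        ),
    ]


def test_sliding_window_matches_brute_force(human_table):
    """Window covering the whole peptide must find the global optimum."""
    rng = random.Random(11)
    peptides = ["".join(rng.choices(AMINO_ACIDS, k=5)) for _ in range(20)]
    for cfg in _oracle_configs():
        for aa in peptides:
            res = optimize(aa, human_table, cfg=cfg, lib=EMPTY_LIB)
            nt, score = brute_force_optimize(aa, human_table, cfg=cfg, lib=EMPTY_LIB)
            assert res.output.nt == nt
            assert res.score_trace[-1][2] == pytest.approx(score)


def test_determinism(human_table):
    orf = generate_fixture_orf(40, human_table, gc_bias=-0.5, seed=3)
    r1 = optimize(orf, human_table)
    r2 = optimize(orf, human_table)
    assert r1.output.nt == r2.output.nt
    assert r1.score_trace == r2.score_trace


@settings(max_examples=8)
@given(aa=st.text(alphabet="".join(AMINO_ACIDS), min_size=1, max_size=18))
def test_translation_preserved_under_default_config(human_table, aa):
    res = optimize(aa, human_table)
    assert translate(res.output.nt) == aa


def test_cds_input_reports_comparison(human_table):
    orf = generate_fixture_orf(30, human_table, gc_bias=-0.8, seed=5)
    res = optimize(orf, human_table)
    assert res.report_before is not None
    assert res.comparison is not None and res.comparison.synonymous
    assert verify_synonymous(orf, res.output)


# ---------------------------------------------------------------------------
# hard constraints

AAT_RICH = {"AAT": 30.0, "AAC": 10.0, "AAA": 30.0, "AAG": 10.0}


def test_avoidable_polya_site_removed():
    """With AAT/AAA as the favoured codons the naive choice spells AATAAA;
    the optimizer must pick suboptimal codons instead."""
    table = make_table(AAT_RICH)
    cfg = QualityConfig(
        weights={"codon_usage": 1.0, "motif_penalty": 0.5},
        hard_constraints=default_motif_library().hard_entries,
        min_codon_w=0.0,
    )
    for aa in ("MNKNK", "MKNKN", "MNKLVNK"):
        res = optimize(aa, table, cfg=cfg, lib=EMPTY_LIB)
        assert "AATAAA" not in res.output.nt
        assert "ATTAAA" not in res.output.nt
        assert not res.unavoidable
        assert translate(res.output.nt) == aa
    # sanity: the constraint actually bites for this table
    naive = back_translate_optimal("MNKNK", table).nt
    assert "AATAAA" in naive


def test_forced_motif_flagged_unavoidable(human_table):
    cfg = QualityConfig(
        weights={"codon_usage": 1.0, "motif_penalty": 0.5},
        hard_constraints=(MotifEntry("WW", "TGGTGG", hard=True),),
    )
    res = optimize("MWW", human_table, cfg=cfg, lib=EMPTY_LIB)
    assert res.unavoidable
    assert [h.name for h in res.unavoidable_hits] == ["WW"]
    assert translate(res.output.nt) == "MWW"


def test_enumeration_cap_error(human_table):
    with pytest.raises(EnumerationCapError, match="window"):
        optimize("MLLLLLLLL", human_table,
                 cfg=usage_cfg(window_codons=8, enumeration_cap=100), lib=EMPTY_LIB)


# ---------------------------------------------------------------------------
# GC behaviour and the published bands

def test_gc_term_can_only_lower_gc_when_target_below(human_table):
    plain = usage_cfg(window_codons=3)
    pulled = QualityConfig(
        window_codons=3,
        weights={"codon_usage": 1.0, "gc_deviation": 0.05},
        gc_target_percent=30.0,
        hard_constraints=(),
        min_codon_w=0.0,
    )
    for seed in range(5):
        orf = generate_fixture_orf(40, human_table, seed=seed)
        gc_plain = gc_content(optimize(orf.aa, human_table, cfg=plain, lib=EMPTY_LIB).output.nt)
        gc_pulled = gc_content(optimize(orf.aa, human_table, cfg=pulled, lib=EMPTY_LIB).output.nt)
        assert gc_pulled <= gc_plain + 1e-9


def test_default_config_reaches_published_bands(human_table):
    """Optimized synthetic wildtype ORFs must land in the CAI >= 0.95 and
    GC 55-70% bands reported for optimized human constructs."""
    for seed in range(4):
        wt = generate_fixture_orf(60, human_table, gc_bias=-0.8, seed=seed)
        res = optimize(wt, human_table)
        assert res.report_after.cai >= 0.95
        assert 55.0 <= res.report_after.gc_percent <= 70.0
        assert res.comparison.synonymous


# ---------------------------------------------------------------------------
# brute force oracle itself

def test_brute_force_trivial_cases(human_table):
    nt, _ = brute_force_optimize("MW", human_table, cfg=usage_cfg(), lib=EMPTY_LIB)
    assert nt == "ATGTGG"
    table = make_table({"GCT": 30.0, "GCC": 10.0, "GCA": 5.0, "GCG": 5.0})
    nt, _ = brute_force_optimize("MA", table, cfg=usage_cfg(), lib=EMPTY_LIB)
    assert nt == "ATGGCT"


def test_brute_force_size_bound(human_table):
    from codonopt.optimizer import SizeError

    with pytest.raises(SizeError):
        brute_force_optimize("MLLLLLLLLL", human_table, cfg=usage_cfg(), lib=EMPTY_LIB)
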