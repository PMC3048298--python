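"""Motif scanning, splice-site models, direct repeats and hairpins."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonopt.alphabet import revcomp
from codonopt.feature_scan import (
    IUPAC,
    MotifEntry,
    MotifLibrary,
    PatternError,
    SpliceSiteModel,
    default_motif_library,
    find_direct_repeats,
    find_hairpins,
    hits_to_bed,
    scan_motifs,
    score_splice_sites,
)

POLYA_LIB = MotifLibrary(entries=(MotifEntry("polyA", "AATAAA", hard=True, kind="polyA"),))


# ---------------------------------------------------------------------------
# motif scanning

def test_motif_free_sequence():
    assert scan_motifs("CCCGGG" * 10, POLYA_LIB) == []


def test_polya_hit_coordinates():
    hits = scan_motifs("GGAATAAAGG", POLYA_LIB)
    assert [(h.start, h.end, h.kind) for h in hits] == [(2, 8, "polyA")]


def test_are_pentamer_hit():
    lib = MotifLibrary(entries=(MotifEntry("ARE", "ATTTA", kind="ARE"),))
    hits = scan_motifs("GATTTAG", lib)
    assert [(h.start, h.end) for h in hits] == [(1, 6)]


def test_overlapping_matches_reported():
    lib = MotifLibrary(entries=(MotifEntry("atrun", "WWWWWWW"),))
    hits = scan_motifs("A" * 9 + "GGG", lib)
    assert [(h.start, h.end) for h in hits] == [(0, 7), (1, 8), (2, 9)]


def test_invalid_iupac_symbol_rejected():
    with pytest.raises(PatternError):
        MotifEntry("bad", "AXT")


@given(s=st.text(alphabet="ACGT", min_size=10, max_size=80))
def test_both_strand_scan_rc_invariant(s):
    lib = MotifLibrary(
        entries=(MotifEntry("polyA", "AATAAA"), MotifEntry("ARE", "ATTTA")),
        strand_mode="both",
    )
    flip = {"+": "-", "-": "+"}
    fwd = {
        (h.name, len(s) - h.end, len(s) - h.start, flip[h.strand])
        for h in scan_motifs(s, lib)
    }
    rev = {(h.name, h.start, h.end, h.strand) for h in scan_motifs(revcomp(s), lib)}
    assert fwd == rev


@given(s=st.text(alphabet="ACGT", min_size=6, max_size=80))
def test_every_hit_rechecks_against_its_pattern(s):
    lib = default_motif_library()
    patterns = {e.name: e.pattern for e in lib.entries}
    for h in scan_motifs(s, lib):
        pat = patterns[h.name]
        sub = s[h.start : h.end]
        assert len(sub) == len(pat)
        assert all(base in IUPAC[sym] for base, sym in zip(sub, pat))


# ---------------------------------------------------------------------------
# splice sites

def test_no_sites_in_homopolymer():
    assert score_splice_sites("A" * 50) == []


def test_literal_donor_consensus_is_maximal_hit():
    s = "CCCCC" + "AAGGTAAGT" + "CCCCC"
    hits = [h for h in score_splice_sites(s) if h.kind == "donor_splice"]
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == (5, 14)
    assert hits[0].score == pytest.approx(1.0)


def test_weak_gt_context_below_threshold():
    # GT present but the surrounding context matches almost nowhere
    assert score_splice_sites("CCCCGTCCCCCC") == []


def test_acceptor_polypyrimidine_tract():
    hits = score_splice_sites("TTTTTTTTTTTTAG")
    assert [(h.kind, h.start, h.end) for h in hits] == [("acceptor_splice", 2, 14)]
    assert hits[0].score == pytest.approx(1.0)


def test_acceptor_requires_pyrimidine_fraction():
    # 10-nt tract with 4 purines: fraction 0.6 < 0.8
    assert score_splice_sites("TTAGATAGTTAG"[:10] + "AG") == []


def test_donor_consensus_invariant_score_maximal():
    model = SpliceSiteModel()
    literal = "CAGGTAAGT"  # M->C, R->A instantiation of the consensus
    hits = score_splice_sites(literal, model)
    donors = [h for h in hits if h.kind == "donor_splice"]
    assert donors and donors[0].score == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# direct repeats

def _repeat_oracle(s, min_len):
    """O(L^2) enumeration of maximal repeated substrings."""
    by_len = {}
    for k in range(min_len, len(s) + 1):
        for i in range(len(s) - k + 1):
            sub = s[i : i + k]
            pos = [j for j in range(len(s) - k + 1) if s[j : j + k] == sub]
            if len(pos) >= 2:
                by_len.setdefault(k, {})[sub] = pos
    out = set()
    for k, subs in by_len.items():
        longer = by_len.get(k + 1, {})
        for sub, pos in subs.items():
            if any(sub in u for u in longer):
                continue
            out.update((i, i + k, sub) for i in pos)
    return out


def test_acgt_doublet():
    hits = find_direct_repeats("ACGTACGT", min_len=4)
    assert {(h.start, h.end, h.name) for h in hits} == {(0, 4, "ACGT"), (4, 8, "ACGT")}


def test_unique_kmer_sequence_empty():
    assert find_direct_repeats("ACGTTGCAAC", min_len=4) == []


def test_min_len_longer_than_sequence():
    assert find_direct_repeats("ACGT", min_len=8) == []


@given(s=st.text(alphabet="ACG", min_size=8, max_size=60),
       min_len=st.integers(4, 6))
def test_repeats_match_brute_force(s, min_len):
    got = {(h.start, h.end, h.name) for h in find_direct_repeats(s, min_len=min_len)}
    assert got == _repeat_oracle(s, min_len)


# ---------------------------------------------------------------------------
# hairpins

def _hairpin_oracle(s, min_stem, loop_range):
    """Loop-first triple scan with maximal outward extension, then dedupe."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    raw = set()
    for p in range(1, len(s)):
        for loop in range(loop_range[0], loop_range[1] + 1):
            q = p + loop
            if q >= len(s):
                break
            k = 0
            while p - k - 1 >= 0 and q + k < len(s) and comp[s[p - k - 1]] == s[q + k]:
                k += 1
            if k >= min_stem:
                raw.add((p - k, q + k))
    return {
        iv for iv in raw
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in raw)
    }


def test_hairpin_example():
    hits = find_hairpins("GGGGCAAAAGCCCC", min_stem=4, loop_range=(4, 4))
    assert [(h.start, h.end, h.score) for h in hits] == [(0, 14, 10.0)]


def test_homopolymer_has_no_hairpin():
    assert find_hairpins("A" * 60, min_stem=4, loop_range=(3, 30)) == []


def test_hairpin_stem_rechecks():
    s = "TTGCAGCGGT" + "AAAA" + "ACCGCTGCAA" + "GGGG"
    hits = find_hairpins(s, min_stem=6, loop_range=(3, 10))
    assert hits
    for h in hits:
        k = int(re.match(r"stem(\d+)", h.name).group(1))
        assert s[h.start : h.start + k] == revcomp(s[h.end - k : h.end])


@given(s=st.text(alphabet="ACGT", min_size=12, max_size=60),
       min_stem=st.integers(4, 5))
def test_hairpins_match_brute_force(s, min_stem):
    got = {(h.start, h.end) for h in find_hairpins(s, min_stem=min_stem, loop_range=(3, 8))}
    assert got == _hairpin_oracle(s, min_stem, (3, 8))


def test_bed_export_format():
    hits = find_direct_repeats("ACGTACGT", min_len=4)
    bed = hits_to_bed(hits, seq_id="chrX")
    lines = bed.strip().split("\n")
    assert lines[0].split("\t")[:4] == ["chrX", "0", "4", "ACGT"]
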