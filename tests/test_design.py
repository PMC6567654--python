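"""Guide-design pipeline: candidate discovery, filters, ranking, off-target
enumeration and library optimization."""

import numpy as np
import pytest

from cpf1kit import design as D
from cpf1kit import synthetic
from cpf1kit.encodings import reverse_complement

GUIDE = "TTTA" + "ACGTGACGTTACAGGCATACGAT"  # GC 11/23, no polyT


def test_single_plus_strand_site():
    seq = "TTTA" + "A" * 23
    sites = D.find_candidate_sites(seq, "x")
    plus = [s for s in sites if s.strand == "+"]
    assert len(plus) == 1
    assert (plus[0].start, plus[0].end) == (0, 27)
    assert plus[0].sequence == seq


def test_minus_strand_site_via_reverse_complement():
    seq = reverse_complement("TTTA" + "ACGTGACGTTACAGGCATACGAT")
    sites = D.find_candidate_sites(seq, "x")
    minus = [s for s in sites if s.strand == "-"]
    assert len(minus) == 1
    assert minus[0].sequence == "TTTA" + "ACGTGACGTTACAGGCATACGAT"
    assert reverse_complement(seq[minus[0].start : minus[0].end]) == minus[0].sequence


def test_no_sites_without_pam_on_either_strand():
    assert D.find_candidate_sites("ACG" * 20, "x") == []


def test_sites_with_n_skipped():
    seq = "TTTA" + "A" * 11 + "N" + "A" * 11 + "C" * 30
    assert all("N" not in s.sequence for s in D.find_candidate_sites(seq, "x"))


def test_candidate_counts_strand_symmetric(rng):
    """Oracle: a sequence and its reverse complement have identical
    candidate counts with swapped strands."""
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = D.find_candidate_sites(seq, "x")
        rev = D.find_candidate_sites(reverse_complement(seq), "x")
        assert len(fwd) == len(rev)
        assert sorted(s.sequence for s in fwd) == sorted(s.sequence for s in rev)


def test_candidates_revalidate_coordinates(rng):
    seq = "".join(rng.choice(list("ACGT"), size=800))
    for s in D.find_candidate_sites(seq, "x"):
        assert s.end - s.start == 27
        assert s.sequence.startswith("TTT")
        if s.strand == "+":
            assert seq[s.start : s.end] == s.sequence
        else:
            assert reverse_complement(seq[s.start : s.end]) == s.sequence


def _site(proto, start=0, strand="+"):
    return D.CandidateSite(name="x", start=start, end=start + 27,
                           strand=strand, sequence="TTTA" + proto)


def test_filters_gc_and_polyt():
    log = []
    low_gc = _site("A" * 23, start=0)
    boundary = _site("G" * 7 + "A" * 16, start=50)  # 7/23 = 0.3043 -> retained
    high_gc = _site("G" * 17 + "A" * 6, start=100)  # 17/23 = 0.739 -> removed
    polyt = _site("ACGTTTTACG" + "G" * 9 + "ACGA"[:4], start=150)
    kept = D.apply_filters([low_gc, boundary, high_gc, polyt], removal_log=log)
    assert kept == [boundary]
    reasons = dict(log)
    assert "polyT" in reasons[polyt.site_id]
    assert "gc" in reasons[low_gc.site_id]


def test_filters_idempotent(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    sites = D.find_candidate_sites(seq, "x")
    once = D.apply_filters(sites)
    twice = D.apply_filters(once)
    assert once == twice


def test_rank_and_retain_counts(activity_results, rng):
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    sites = D.apply_filters(D.find_candidate_sites(seq, "x"))
    clf = activity_results.classifier
    n = len(sites)
    kept = D.rank_and_retain(sites, clf, retain_frac=0.10)
    assert len(kept) == int(np.ceil(0.10 * n))
    assert all(k.activity_score is not None for k in kept)
    scores = [k.activity_score for k in kept]
    assert scores == sorted(scores, reverse=True)
    # floor of one survivor
    assert len(D.rank_and_retain(sites[:1], clf, retain_frac=0.10)) == 1
    # invariant to input order
    shuffled = list(sites)
    rng.shuffle(shuffled)
    kept2 = D.rank_and_retain(shuffled, clf, retain_frac=0.10)
    assert [k.site_id for k in kept] == [k.site_id for k in kept2]


def _naive_off_target_scan(guide, genome, max_mismatch):
    """Quadratic re-scan oracle: check every window on both strands."""
    hits = []
    L = len(genome)
    for start in range(L - 26):
        window = genome[start : start + 27]
        for strand, site in (("+", window), ("-", reverse_complement(window))):
            if not site.startswith("TTT") or "N" in site:
                continue
            mm = sum(a != b for a, b in zip(site[4:], guide.protospacer))
            if mm > max_mismatch:
                continue
            if (start, strand) == (guide.start, guide.strand):
                continue
            hits.append((start, strand, mm))
    return sorted(hits)


def test_enumeration_agrees_with_naive_rescan(rng):
    # plant an exact copy so the guide itself exists in the genome
    genome, truth = synthetic.simulate_genome(
        3000, [(GUIDE, 1, 0), (GUIDE, 3, 2)], seed=9)
    guide = next(s for s in D.find_candidate_sites(genome, "x")
                 if s.protospacer == GUIDE[4:])
    for max_mm in (0, 2, 4):
        hits = D.enumerate_off_targets(guide, {"x": genome}, max_mm)
        got = sorted((h.start, h.strand, h.mismatch_count) for h in hits)
        assert got == _naive_off_target_scan(guide, genome, max_mm)


def test_planted_copies_recovered_at_exact_mismatch_threshold():
    genome, truth = synthetic.simulate_genome(
        20000, [(GUIDE, 1, 0), (GUIDE, 3, 2)], seed=15)
    guide = next(s for s in D.find_candidate_sites(genome, "x")
                 if s.protospacer == GUIDE[4:])
    assert len(D.enumerate_off_targets(guide, {"x": genome}, 1)) == 0
    hits = D.enumerate_off_targets(guide, {"x": genome}, 2)
    planted = {(t["start"], t["strand"]) for t in truth if t["n_mismatches"] == 2}
    assert {(h.start, h.strand) for h in hits} == planted
    assert all(h.mismatch_count == 2 for h in hits)


def test_hit_count_invariant_under_genome_reverse_complement():
    genome, _ = synthetic.simulate_genome(
        10000, [(GUIDE, 1, 0), (GUIDE, 2, 3)], seed=16)
    guide = next(s for s in D.find_candidate_sites(genome, "x")
                 if s.protospacer == GUIDE[4:])
    rc = reverse_complement(genome)
    guide_rc = next(s for s in D.find_candidate_sites(rc, "x")
                    if s.protospacer == GUIDE[4:])
    n_fwd = len(D.enumerate_off_targets(guide, {"x": genome}, 3))
    n_rev = len(D.enumerate_off_targets(guide_rc, {"x": rc}, 3))
    assert n_fwd == n_rev


def test_specificity_score_counts(offtarget_results):
    clf = offtarget_results.classifier
    guide = _site("ACGTGACGTTACAGGCATACGAT")
    assert D.specificity_score(guide, [], clf) == (0, 1.0, [])
    # an exact duplicate counts as high activity by definition
    dup = D.OffTargetHit(name="x", start=100, end=127, strand="+",
                         sequence=guide.sequence, mismatch_count=0,
                         mismatch_positions=())
    n_high, score, scored = D.specificity_score(guide, [dup], clf)
    assert n_high == 1 and score == 0.5
    assert scored[0].predicted_score is not None


def test_specificity_region_ordering(offtarget_results):
    """A promiscuous-region mismatch should score higher than the same
    count of seed-region mismatches, as planted by the generator."""
    clf = offtarget_results.classifier
    guide = _site("ACGTGACGTTACAGGCATACGAT")

    def hit_with_mismatch(pos):  # 1-based site position
        seq = list(guide.sequence)
        seq[pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos - 1]]
        return D.OffTargetHit(name="x", start=200, end=227, strand="+",
                              sequence="".join(seq), mismatch_count=1,
                              mismatch_positions=(pos,))

    _, _, scored = D.specificity_score(
        guide, [hit_with_mismatch(7), hit_with_mismatch(26)], clf)
    seed_hit, prom_hit = scored
    assert prom_hit.predicted_score > seed_hit.predicted_score


def test_design_library_end_to_end(activity_results, offtarget_results):
    genome, _ = synthetic.simulate_genome(20000, [], seed=30)
    lib = D.design_library({"g": genome}, activity_results.classifier,
                           offtarget_results.classifier, n_guides=10,
                           max_mismatch=2)
    assert len(lib.guides) == 10
    assert lib.n_candidates >= lib.n_filtered >= lib.n_retained
    # ranking invariant: n_high non-decreasing; activity non-increasing
    # within equal n_high
    for a, b, na, nb in zip(lib.guides, lib.guides[1:],
                            lib.n_high_offtargets, lib.n_high_offtargets[1:]):
        assert na <= nb
        if na == nb:
            assert a.activity_score >= b.activity_score
    # determinism
    lib2 = D.design_library({"g": genome}, activity_results.classifier,
                            offtarget_results.classifier, n_guides=10,
                            max_mismatch=2)
    assert lib.frame().equals(lib2.frame())
    bed = lib.to_bed().splitlines()
    assert len(bed) == 10 and bed[0].split("\t")[5] in "+-"


def test_design_library_warns_when_short(activity_results, offtarget_results):
    genome, _ = synthetic.simulate_genome(1000, [(GUIDE, 1, 0)], seed=31)
    lib = D.design_library({"g": genome}, activity_results.classifier,
                           offtarget_results.classifier, n_guides=50,
                           retain_frac=1.0, max_mismatch=0)
    assert len(lib.guides) < 50
    assert lib.warning is not None
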