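from __future__ import annotations

import pytest

from clovermark.ssr import (
    SsrLocus,
    SsrParams,
    canonical_rotation,
    find_perfect_runs,
    merge_complex,
    primer_feasible,
    primitive_motif,
    ssr_summary,
    wallace_tm,
)

from tests.oracles import brute_force_ssr


def loci_tuples(loci):
    return [(lc.start, lc.end, lc.motif, lc.repeats) for lc in loci]


class TestThresholds:
    def test_monomer_at_threshold_found_below_not(self):
        flank_l, flank_r = "GCTGC", "CGTCG"
        hit = find_perfect_runs(flank_l + "A" * 12 + flank_r)
        assert loci_tuples(hit) == [(6, 17, "A", 12)]
        assert find_perfect_runs(flank_l + "A" * 11 + flank_r) == []

    def test_trimer_found_dimer_below_threshold_not(self):
        assert loci_tuples(find_perfect_runs("TT" + "AGC" * 4 + "GA")) == [
            (3, 14, "AGC", 4)
        ]
        assert find_perfect_runs("GC" + "AT" * 5 + "GC") == []

    def test_tetramer_span_reported_as_primitive_dimer(self):
        # ATAT x 3 is AT x 6: primitivity forces the smaller period
        assert loci_tuples(find_perfect_runs("GC" + "ATAT" * 3 + "GC")) == [
            (3, 14, "AT", 6)
        ]

    def test_run_containing_n_is_split(self):
        seq = "A" * 12 + "N" + "A" * 12
        found = loci_tuples(find_perfect_runs(seq))
        assert found == [(1, 12, "A", 12), (14, 25, "A", 12)]

    def test_motif_reported_as_smallest_rotation(self):
        found = find_perfect_runs("TT" + "GAC" * 4 + "TT")
        assert found[0].motif == "ACG"


def test_primitive_and_rotation_helpers():
    assert primitive_motif("AAB")
    assert not primitive_motif("ATAT")
    assert canonical_rotation("GAC") == "ACG"


class TestMergeComplex:
    def test_nearby_runs_merge_with_components(self):
        seq = "GC" + "AAG" * 4 + "TCG" + "CTT" * 5 + "GC"
        simple = find_perfect_runs(seq)
        assert len(simple) == 2
        gap = simple[1].start - simple[0].end - 1
        assert gap == 3  # brute-force pairwise gap check
        merged = merge_complex(simple)
        assert len(merged) == 1
        (cx,) = merged
        assert cx.klass == "complex"
        assert len(cx.components) == 2
        assert (cx.start, cx.end) == (simple[0].start, simple[1].end)

    def test_distant_runs_stay_simple(self):
        spacer = "GACTGCAGTCAGATCGGACTGCAGTCAGATCGGACTGCAGTCAGATCGGA"
        seq = "GC" + "AAG" * 4 + spacer + "CTT" * 5 + "GC"
        simple = find_perfect_runs(seq)
        assert len(simple) == 2
        assert merge_complex(simple) == simple

    def test_single_run_unchanged(self):
        seq = "GC" + "AAG" * 4 + "GC"
        simple = find_perfect_runs(seq)
        assert merge_complex(simple) == simple


class TestOracleEquivalence:
    @pytest.mark.parametrize("alphabet", ["ACGT", "AC", "ACGTN"])
    def test_matches_brute_force_on_fuzzed_sequences(self, alphabet, rng):
        relaxed = SsrParams(min_repeats={1: 6, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2})
        for _ in range(60):
            n = int(rng.integers(20, 300))
            seq = "".join(rng.choice(list(alphabet), size=n))
            got = loci_tuples(find_perfect_runs(seq, relaxed))
            expected = [
                (s, e, m, r) for s, e, m, r in
                ((c[0], c[1], c[2], c[3]) for c in brute_force_ssr(seq, relaxed.min_repeats))
            ]
            assert got == expected, seq

    def test_default_thresholds_on_repeat_rich_sequences(self, rng):
        params = SsrParams()
        motifs = ["A", "AT", "AAG", "ACGT", "AACGT", "ACGCTT"]
        for _ in range(40):
            pieces = []
            for _ in range(int(rng.integers(1, 5))):
                motif = motifs[int(rng.integers(0, len(motifs)))]
                reps = int(rng.integers(2, 15))
                pieces.append(motif * reps)
                pieces.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 12)))))
            seq = "".join(pieces)
            got = loci_tuples(find_perfect_runs(seq, params))
            expected = [(c[0], c[1], c[2], c[3]) for c in brute_force_ssr(seq, params.min_repeats)]
            assert got == expected, seq


class TestInvariants:
    def test_resolved_loci_never_overlap(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("AC"), size=120))
            loci = find_perfect_runs(seq, SsrParams(min_repeats={1: 4, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2}))
            for a, b in zip(loci, loci[1:]):
                assert a.end < b.start

    def test_self_concatenation_doubles_interior_loci(self):
        seq = "GGCGTC" + "AAG" * 4 + "TGCACG"
        single = find_perfect_runs(seq)
        double = find_perfect_runs(seq + seq)
        assert len(double) == 2 * len(single)


class TestPrimerFeasible:
    def _centered_locus(self, rng):
        # balanced-GC flanks around a trinucleotide repeat in a 500-bp sequence
        flank = "".join(rng.choice(list("ACGT"), size=244))
        seq = flank + "AAG" * 4 + "".join(rng.choice(list("ACGT"), size=244))
        locus = find_perfect_runs(seq)[0]
        return seq, locus

    def test_centered_locus_feasible_with_product_in_range(self, rng):
        seq, locus = self._centered_locus(rng)
        design = primer_feasible(seq, locus)
        assert design.feasible
        assert 100 <= design.product_len <= 350
        assert abs(design.tm_left - 55) <= 3 and abs(design.tm_right - 55) <= 3
        # windows flank the locus
        assert design.left[1] < locus.start and design.right[0] > locus.end

    def test_matches_exhaustive_search_optimum(self, rng):
        seq, locus = self._centered_locus(rng)
        design = primer_feasible(seq, locus)
        best = None
        for a in range(1, locus.start):
            for la in range(18, 25):
                b = a + la - 1
                if b > locus.start - 1:
                    continue
                w = seq[a - 1 : b]
                tml = wallace_tm(w.count("A") + w.count("T"), w.count("G") + w.count("C")) if la <= 20 else 64.9 + 41 * ((w.count("G") + w.count("C")) - 16.4) / la
                if abs(tml - 55) > 3:
                    continue
                for ra in range(locus.end + 1, len(seq) + 1):
                    for lr in range(18, 25):
                        rb = ra + lr - 1
                        if rb > len(seq):
                            continue
                        prod = rb - a + 1
                        if not 100 <= prod <= 350:
                            continue
                        w2 = seq[ra - 1 : rb]
                        tmr = wallace_tm(w2.count("A") + w2.count("T"), w2.count("G") + w2.count("C")) if lr <= 20 else 64.9 + 41 * ((w2.count("G") + w2.count("C")) - 16.4) / lr
                        if abs(tmr - 55) > 3:
                            continue
                        key = (abs(tml - 55) + abs(tmr - 55), prod)
                        if best is None or key < best:
                            best = key
        assert best is not None
        assert design.feasible
        assert (abs(design.tm_left - 55) + abs(design.tm_right - 55), design.product_len) == pytest.approx(best)

    def test_insufficient_flank(self):
        seq = "GCGC" + "AAG" * 4 + "GC" * 22
        locus = find_perfect_runs(seq)[0]
        design = primer_feasible(seq, locus)
        assert not design.feasible
        assert design.reason == "insufficient flank"

    def test_all_at_flanks_fail_tm(self):
        seq = "AT" * 60 + "AAG" * 4 + "TA" * 60
        locus = SsrLocus("s", 121, 132, "AAG", 4, "tri")
        design = primer_feasible(seq, locus)
        assert not design.feasible


class TestSummary:
    def test_zero_loci_reports_na_not_error(self):
        summary = ssr_summary([], total_cds_bp=1000, n_sequences=5)
        assert summary.n_loci == 0
        assert summary.density_bp_per_marker is None
        assert summary.designable_pct is None

    def test_counts_density_and_multiplicity(self):
        loci = [
            SsrLocus("s1", 1, 12, "A", 12, "mono", primer_designable=True),
            SsrLocus("s1", 50, 61, "AAG", 4, "tri", primer_designable=True),
            SsrLocus("s2", 10, 21, "AAG", 4, "tri", primer_designable=False),
        ]
        summary = ssr_summary(loci, total_cds_bp=24_000, n_sequences=4)
        assert summary.class_counts["tri"] == 2
        assert summary.n_designable == 2
        assert summary.designable_pct == 66.7
        assert summary.sequences_with_locus_pct == 50.0
        assert summary.density_bp_per_marker == 12_000.0
        assert summary.multiplicity_histogram == {1: 1, 2: 1}
        # mono locus of span 12 preserves frame; it is the only non-tri simple locus
        assert summary.frame_preserving_pct == 100.0
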