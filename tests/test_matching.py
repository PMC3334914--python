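"""Ungapped best-site search, categories, 3'-anchored profiles, amplicons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from primerscope import (
    DegeneratePrimer,
    MismatchCategory,
    best_site,
    categorize,
    iupac_match,
    positional_profile,
    predict_amplicon,
    reverse_complement,
)
from primerscope.iupac import EXPANSIONS, IUPAC_CODES
from primerscope.matching import PrimerSiteHit

# brute-force oracle: naive sliding window with set-intersection matching
_PAIR_MATCH = {
    (a, b): bool(EXPANSIONS[a] & EXPANSIONS[b])
    for a, b in itertools.product(IUPAC_CODES, repeat=2)
}


def naive_min_hamming(primer_seq: str, target: str) -> int:
    L = len(primer_seq)
    best = L + 1
    for off in range(len(target) - L + 1):
        mm = sum(
            1 for a, b in zip(target[off : off + L], primer_seq)
            if not _PAIR_MATCH[(a, b)]
        )
        best = min(best, mm)
    return best


def _fwd(seq, name="P"):
    return DegeneratePrimer(name, seq, "forward")


def _rev(seq, name="Q"):
    return DegeneratePrimer(name, seq, "reverse")


class TestIupacMatchExamples:
    @pytest.mark.parametrize(
        "t,p,expected", [("A", "N", True), ("G", "R", True), ("C", "R", False)]
    )
    def test_examples(self, t, p, expected):
        assert iupac_match(t, p) is expected


class TestBestSite:
    def test_exact_substring_hits_with_zero_mismatches(self):
        hit = best_site(_fwd("CGTA"), "AACGTATT")
        assert (hit.offset, hit.mismatch_count) == (2, 0)
        assert hit.footprint == "CGTA"

    def test_all_offsets_equal_ties_break_to_smallest_offset(self):
        hit = best_site(_fwd("AAAA"), "TTTTTTT")
        assert (hit.offset, hit.mismatch_count) == (0, 4)

    def test_reverse_primer_searches_its_reverse_complement(self):
        # reverse primer 5'-CGGT-3' anneals where the sense strand reads ACCG
        hit = best_site(_rev("CGGT"), "TTACCGTT")
        assert (hit.offset, hit.mismatch_count) == (2, 0)
        assert hit.footprint == "ACCG"

    def test_target_shorter_than_primer_is_an_error(self):
        with pytest.raises(ValueError):
            best_site(_fwd("ACGTACGT"), "ACG")

    def test_match_flags_are_indexed_from_the_3_prime_end(self):
        # footprint CGTA vs primer CGTT: sense mismatch at footprint index 3,
        # which is the forward primer's 3' terminus (position 1)
        hit = best_site(_fwd("CGTT"), "AACGTAAA")
        assert hit.mismatch_count == 1
        assert hit.match_flags[0] is False
        assert all(hit.match_flags[1:])

    def test_reverse_primer_flags_anchor_at_footprint_left_edge(self):
        # rev primer TACG anneals where sense reads CGTA; mutate the sense
        # base under the primer's 3' end (leftmost footprint base)
        hit = best_site(_rev("TACG"), "AAGGTAAA")
        assert hit.mismatch_count == 1
        assert hit.match_flags[0] is False

    @settings(derandomize=True, max_examples=150)
    @given(st.data())
    def test_agrees_with_naive_minimum_hamming_oracle(self, data):
        primer = data.draw(st.text(alphabet=IUPAC_CODES, min_size=4, max_size=12))
        target = data.draw(st.text(alphabet=IUPAC_CODES, min_size=12, max_size=120))
        assert best_site(_fwd(primer), target).mismatch_count == \
            naive_min_hamming(primer, target)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_invariant_under_reverse_complementing_both(self, data):
        primer = data.draw(st.text(alphabet=IUPAC_CODES, min_size=4, max_size=12))
        target = data.draw(st.text(alphabet="ACGT", min_size=15, max_size=80))
        a = best_site(_fwd(primer), target).mismatch_count
        b = best_site(_fwd(reverse_complement(primer)),
                      reverse_complement(target)).mismatch_count
        assert a == b


class TestCategorize:
    @pytest.mark.parametrize(
        "mm,expected",
        [(0, MismatchCategory.NO_MISMATCH), (1, MismatchCategory.ONE_MISMATCH),
         (2, MismatchCategory.TWO_OR_MORE), (7, MismatchCategory.TWO_OR_MORE)],
    )
    def test_thresholds(self, mm, expected):
        assert categorize(mm) is expected

    def test_accepts_hits(self):
        hit = best_site(_fwd("ACGT"), "ACGT")
        assert categorize(hit) is MismatchCategory.NO_MISMATCH


class TestPositionalProfile:
    def test_perfect_targets_give_unit_match_fraction(self):
        p = _fwd("ACGTACGTACGT")
        hits = [best_site(p, "TT" + p.sequence + "GG") for _ in range(5)]
        prof = positional_profile(p, hits)
        assert prof.match_fraction == (1.0,) * 12
        assert prof.flagged_positions() == ()

    def test_empty_hit_list_is_an_error(self):
        with pytest.raises(ValueError):
            positional_profile(_fwd("ACGT"), [])

    def test_planted_3prime_substitutions_are_flagged_at_planted_rate(self):
        """Mutating 3' positions 3 and 7 in most targets flags exactly those."""
        rng = np.random.default_rng(42)
        primer = _fwd("ACGTACGTACGTACGTACGT")  # 20-mer, concrete
        L = len(primer.sequence)
        hits = []
        n = 200
        for _ in range(n):
            site = list(primer.sequence)
            for pos in (3, 7):  # from the 3' end
                if rng.random() < 0.8:
                    i = L - pos
                    site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
            target = "GG" + "".join(site) + "AA"
            hits.append(best_site(primer, target))
        prof = positional_profile(primer, hits)
        assert prof.flagged_positions() == (3, 7)
        for pos in (3, 7):
            assert prof.match_fraction[pos - 1] == pytest.approx(0.2, abs=0.1)

    def test_match_fraction_complements_false_flag_fraction(self):
        rng = np.random.default_rng(1)
        primer = _fwd("RCGTWCGTACGT")
        hits = []
        for _ in range(50):
            t = "".join(rng.choice(list("ACGT"), size=40))
            hits.append(best_site(primer, t))
        prof = positional_profile(primer, hits)
        for p in range(len(primer.sequence)):
            false_frac = sum(1 for h in hits if not h.match_flags[p]) / len(hits)
            assert prof.match_fraction[p] == pytest.approx(1 - false_frac)

    def test_base_counts_sum_to_number_of_hits(self):
        primer = _fwd("ACGTACGT")
        rng = np.random.default_rng(2)
        hits = [best_site(primer, "".join(rng.choice(list("ACGT"), size=30)))
                for _ in range(20)]
        prof = positional_profile(primer, hits)
        assert all(sum(row) == 20 for row in prof.base_counts)

    def test_reverse_primer_profile_reads_primer_strand(self):
        # sense footprint ACCG = revcomp of primer CGGT: perfect match,
        # observed bases on the primer strand must equal the primer itself
        q = _rev("CGGT")
        hits = [best_site(q, "TTACCGTT")]
        prof = positional_profile(q, hits)
        assert prof.match_fraction == (1.0, 1.0, 1.0, 1.0)
        # 3'->5' of CGGT is TGGC; counts must put each observation there
        obs = []
        for row in prof.base_counts:
            (idx,) = [i for i, c in enumerate(row) if c]
            obs.append("ACGT"[idx])
        assert "".join(obs) == "TGGC"


class TestPredictAmplicon:
    def _hit(self, offset, seq, name, orientation, tid="t"):
        return PrimerSiteHit(
            target_id=tid, primer_name=name, orientation=orientation,
            offset=offset, footprint=seq, mismatch_count=0,
            match_flags=(True,) * len(seq),
        )

    def test_adjacent_footprints_give_zero_insert(self):
        f = self._hit(0, "A" * 20, "F", "forward")
        r = self._hit(20, "A" * 20, "R", "reverse")
        pred = predict_amplicon(f, r)
        assert pred.insert_length == 0
        assert pred.total_length == 40

    def test_insert_arithmetic(self):
        f = self._hit(10, "A" * 20, "F", "forward")
        r = self._hit(530, "A" * 20, "R", "reverse")
        pred = predict_amplicon(f, r)
        assert pred.insert_length == 500
        assert pred.total_length == 540

    def test_overlapping_footprints_are_an_error(self):
        f = self._hit(10, "A" * 20, "F", "forward")
        r = self._hit(15, "A" * 20, "R", "reverse")
        with pytest.raises(ValueError, match="no amplifiable orientation"):
            predict_amplicon(f, r)

    def test_mismatched_targets_are_an_error(self):
        f = self._hit(0, "AAAA", "F", "forward", tid="t1")
        r = self._hit(10, "AAAA", "R", "reverse", tid="t2")
        with pytest.raises(ValueError):
            predict_amplicon(f, r)


def test_category_counts_partition_any_cohort(small_dataset, small_records):
    from primerscope import excise_all, screen_targets

    genes = excise_all(small_records)
    out = screen_targets(
        [small_dataset.forward_primer, small_dataset.reverse_primer],
        genes, rank=-1,
    )
    frame = out.table.frame
    for p in ("SYNF", "SYNR"):
        counts = sum(frame[f"{p}:{c}:count"]
                     for c in ("no_mismatch", "one_mismatch", "two_or_more"))
        assert (counts == frame["n"]).all()
        pcts = sum(frame[f"{p}:{c}:pct"]
                   for c in ("no_mismatch", "one_mismatch", "two_or_more"))
        assert np.allclose(pcts, 100.0, atol=0.02)
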