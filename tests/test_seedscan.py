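"""Duplex alignment, free energy, seed rules, and UTR scanning."""

import math

import numpy as np
import pytest
from oracle_align import best_local_score

from mirswitch.core_io import SequenceRecord, ValidationError
from mirswitch.seedscan import (
    PairClass,
    align_duplex,
    duplex_energy,
    reverse_complement,
    scan_utr,
    seed_rule_class,
    count_predicted_targets,
)
from mirswitch.simulate import LET7C, _site_sequence


def make_utr(seq: str, name: str = "tx") -> SequenceRecord:
    return SequenceRecord(name, seq, "utr3")


class TestAlignDuplex:
    def test_perfect_complement_all_wc_no_gaps(self, let7c):
        aln = align_duplex(let7c, reverse_complement(LET7C))
        assert aln.score == 215.0  # 7 seed pairs * 5 * 4 + 15 pairs * 5
        assert all(c.pair_class == PairClass.WC for c in aln.columns)
        assert aln.n_gaps == 0
        assert len(aln.columns) == len(LET7C)

    @pytest.mark.parametrize("pos, scale", [(5, 4.0), (15, 1.0)])
    def test_single_mismatch_costs_eight_times_scale(self, pos, scale):
        # a WC->mismatch flip loses the +5 match and incurs the -3 penalty,
        # both multiplied by the position's seed scaling
        site = list(reverse_complement(LET7C))
        L = len(LET7C)
        idx = L - pos  # site index opposite miRNA position `pos`
        orig = site[idx]
        site[idx] = {"A": "C", "C": "A", "G": "A", "U": "C"}[orig]
        aln = align_duplex(LET7C, "".join(site))
        assert aln.score == 215.0 - 8.0 * scale

    def test_antiparallel_invariant(self, let7c):
        aln = align_duplex(let7c, reverse_complement(LET7C))
        mpos = [c.mirna_pos for c in aln.columns]
        upos = [c.utr_pos for c in aln.columns]
        assert mpos == sorted(mpos)
        assert upos == sorted(upos, reverse=True)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            align_duplex("ACGUACGUACGUACGUACGU", "")

    def test_matches_exhaustive_enumeration(self, rng):
        alphabet = np.array(list("ACGU"))
        for _ in range(25):
            m = "".join(rng.choice(alphabet, size=rng.integers(4, 9)))
            w = "".join(rng.choice(alphabet, size=rng.integers(6, 13)))
            expected = best_local_score(m, w)
            aln = align_duplex(m, w)
            got = 0.0 if aln is None else aln.score
            assert got == pytest.approx(expected, abs=1e-9), (m, w)


class TestDuplexEnergy:
    def test_single_pair_positive(self):
        aln = align_duplex("ACGUACGUACGUACGUAC", "GGGGUGGGG")
        # only one WC pairing region is possible; energy must exceed zero when
        # a single pair carries no stacks
        single = [c for c in aln.columns if c.pair_class == PairClass.WC]
        if len(single) == 1:
            assert duplex_energy(aln) > 0

    def test_au_only_helix_fails_energy_gate(self):
        m = "AUAUAUAUAUAUAUAUAUAU"  # 20-nt, pairs an AU-only helix
        aln = align_duplex(m, reverse_complement(m[:6]))
        dg = duplex_energy(aln)
        assert dg > -16.0  # weak all-AU stacking cannot reach the gate

    def test_perfect_let7c_duplex_is_stable(self, let7c):
        aln = align_duplex(let7c, reverse_complement(LET7C))
        assert duplex_energy(aln) < -20.0

    def test_summation_matches_independent_walk(self, let7c):
        # independent re-summation from the stack table over the pair list
        from mirswitch import _stacks

        aln = align_duplex(let7c, reverse_complement(LET7C))
        pairs = [(c.mirna_base, c.utr_base) for c in aln.columns]
        expected = _stacks.INITIATION
        for p1, p2 in zip(pairs, pairs[1:]):
            expected += _stacks.stack_energy(p1, p2)
        for end in (pairs[0], pairs[-1]):
            if end not in (("G", "C"), ("C", "G")):
                expected += _stacks.TERMINAL_AU_GU
        assert duplex_energy(aln) == pytest.approx(expected, abs=1e-9)

    def test_interruption_penalty_applied_once_per_run(self, rng):
        # class-B planted site: one mismatch at miRNA position 8 splits the
        # helix into two segments -> exactly one +3.0 interruption
        site = _site_sequence(LET7C, "B", 0, rng)
        aln_b = align_duplex(LET7C, site)
        aln_a = align_duplex(LET7C, reverse_complement(LET7C))
        segments_a = duplex_energy(aln_a)
        segments_b = duplex_energy(aln_b)
        assert segments_b > segments_a  # losing stacks + penalty destabilizes
        assert segments_b < -16.0  # but a near-full duplex still passes


class TestSeedRules:
    def test_seed_heptamer_is_class_a(self, let7c):
        # CUACCUC = reverse complement of let-7c nt 2-8 (GAGGUAG)
        assert reverse_complement(LET7C[1:8]) == "CUACCUC"
        aln = align_duplex(let7c, reverse_complement(LET7C))
        assert seed_rule_class(aln, let7c) == "A"

    def test_class_b_with_wobble_at_15(self, let7c, rng):
        site = list(reverse_complement(LET7C))
        L = len(LET7C)
        # break position 8 (G -> A keeps neither WC nor G:U possible with C)
        site[L - 8] = "A"
        # wobble at miRNA position 15 (G) -> target U
        assert LET7C[14] == "G"
        site[L - 15] = "U"
        aln = align_duplex(let7c, "".join(site))
        assert seed_rule_class(aln, let7c) == "B"

    def test_mismatch_in_seed_and_no_3p_pairing_is_none(self, let7c):
        site = list(reverse_complement(LET7C))
        L = len(LET7C)
        site[L - 5] = "A"  # breaks seed position 5 (G:C -> G:A)
        for k in range(13, 17):  # destroy the 13-16 span
            site[L - k] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[L - k]]
        aln = align_duplex(let7c, "".join(site))
        assert seed_rule_class(aln, let7c) == "NONE"

    def test_wobble_scope_3p_rejects_seed_wobble(self, let7c):
        site = list(reverse_complement(LET7C))
        L = len(LET7C)
        site[L - 8] = "A"  # not class A
        # wobble inside nt 2-7: position 4 is G -> target U
        assert LET7C[3] == "G"
        site[L - 4] = "U"
        aln = align_duplex(let7c, "".join(site))
        assert seed_rule_class(aln, let7c, wobble_scope="both") == "B"
        assert seed_rule_class(aln, let7c, wobble_scope="3p") == "NONE"


class TestScanUtr:
    def _random_utr_with_site(self, rng, site, length=500, name="tx1"):
        seq = list(rng.choice(list("ACGU"), size=length))
        start = int(rng.integers(0, length - len(site) + 1))
        seq[start : start + len(site)] = list(site)
        return make_utr("".join(seq), name), start

    def test_planted_perfect_site_recovered(self, let7c, rng):
        site = reverse_complement(LET7C)
        utr, start = self._random_utr_with_site(rng, site)
        found = scan_utr(let7c, utr)
        planted = [s for s in found if s.window.start == start]
        assert len(planted) == 1
        s = planted[0]
        assert s.seed_class == "A" and s.score > 130 and s.energy < -16
        assert (s.window.start, s.window.end) == (start, start + len(site))

    def test_short_utr_returns_empty(self, let7c):
        assert scan_utr(let7c, make_utr("ACGUAC")) == []

    def test_threshold_monotonicity(self, let7c, rng):
        utr, _ = self._random_utr_with_site(rng, reverse_complement(LET7C))
        loose = scan_utr(let7c, utr, score_threshold=-math.inf, energy_threshold=math.inf)
        tight = scan_utr(let7c, utr, score_threshold=150.0, energy_threshold=-20.0)
        loose_keys = {(s.window.start, s.window.end) for s in loose}
        assert all((s.window.start, s.window.end) in loose_keys for s in tight)
        assert len(tight) <= len(loose)

    def test_disabled_thresholds_return_all_seed_classified(self, let7c, rng):
        # every reported site still carries class A or B even with gates off
        utr, _ = self._random_utr_with_site(rng, reverse_complement(LET7C))
        for s in scan_utr(let7c, utr, score_threshold=-math.inf, energy_threshold=math.inf):
            assert s.seed_class in ("A", "B")

    def test_sense_antisense_orientation(self, let7c, rng):
        utr, _ = self._random_utr_with_site(rng, reverse_complement(LET7C))
        antisense = make_utr(reverse_complement(utr.sequence), "rc")
        assert not any(
            s.seed_class == "A"
            for s in scan_utr(let7c, antisense, score_threshold=-math.inf,
                              energy_threshold=math.inf)
        )

    def test_class_invariant_under_flanking_context(self, let7c, rng):
        site = reverse_complement(LET7C)
        for _ in range(3):
            utr, start = self._random_utr_with_site(rng, site)
            found = [s for s in scan_utr(let7c, utr) if s.window.start == start]
            assert len(found) == 1 and found[0].seed_class == "A"

    def test_sites_sorted_and_non_overlapping(self, let7c, rng):
        site = reverse_complement(LET7C)
        seq = list(rng.choice(list("ACGU"), size=600))
        seq[50 : 50 + len(site)] = list(site)
        seq[300 : 300 + len(site)] = list(site)
        found = scan_utr(let7c, make_utr("".join(seq)))
        starts = [s.window.start for s in found]
        assert starts == sorted(starts)
        for s1, s2 in zip(found, found[1:]):
            assert s1.window.end <= s2.window.start


class TestCountPredictedTargets:
    def test_multi_category_gene_counts_in_each(self, let7c, rng):
        site = reverse_complement(LET7C)
        seq = list(rng.choice(list("ACGU"), size=300))
        seq[10 : 10 + len(site)] = list(site)
        seq[100 : 100 + len(site)] = list(site)
        utr = make_utr("".join(seq), "g1")
        table = count_predicted_targets(
            [let7c], [utr], {"g1": ["lipid metabolism", "carbohydrate metabolism"]}
        )
        assert table.loc["gga-let-7c", "lipid metabolism"] == 1
        assert table.loc["gga-let-7c", "carbohydrate metabolism"] == 1

    def test_no_sites_all_zero(self, let7c, rng):
        utr = make_utr("".join(rng.choice(list("AC"), size=200)), "g1")
        table = count_predicted_targets([let7c], [utr], {"g1": ["lipid metabolism"]})
        assert (table.to_numpy() == 0).all()
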