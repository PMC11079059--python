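"""Alignment, region extraction, positional profiles and clone reports."""

import math

import numpy as np
import pytest

from vhhseq import (
    align_to_reference,
    clone_report,
    cluster_exact,
    extract_region,
    position_profile,
    rank_mutations,
    reference_region_fraction,
)
from vhhseq.simulate import ClonePool, MutagenesisModel, mutate_pool

from _oracles import affine_alignment_score, classify_substitution
from conftest import random_dna


def substitute(seq, pos, base):
    assert seq[pos] != base
    return seq[:pos] + base + seq[pos + 1 :]


class TestAlignToReference:
    def test_identity_alignment(self, ref):
        aln = align_to_reference(ref.sequence, ref)
        assert aln.is_identity and aln.score == len(ref.sequence)

    def test_single_substitution_located(self, ref):
        query = substitute(ref.sequence, 150, {"A": "C"}.get(ref.sequence[150], "A"))
        aln = align_to_reference(query, ref)
        assert len(aln.substitutions) == 1
        pos, r, q = aln.substitutions[0]
        assert pos == 150 and r == ref.sequence[150] and q == query[150]

    def test_single_deletion_located(self, ref):
        query = ref.sequence[:100] + ref.sequence[101:]
        aln = align_to_reference(query, ref)
        assert len(aln.deletions) == 1 and not aln.substitutions

    def test_score_matches_exhaustive_dp(self, rng):
        """Aligner score equals the brute-force Gotoh DP on small pairs."""
        for _ in range(150):
            x = random_dna(rng, int(rng.integers(1, 13)))
            y = random_dna(rng, int(rng.integers(1, 13)))
            assert align_to_reference(y, x).score == affine_alignment_score(x, y)

    def test_empty_query_rejected(self, ref):
        with pytest.raises(ValueError, match="empty query"):
            align_to_reference("", ref)


class TestExtractRegion:
    def test_identity_query_returns_reference_region(self, ref):
        aln = align_to_reference(ref.sequence, ref)
        extract = extract_region(aln, "CDR3", ref)
        assert extract.sequence == ref.region_nt("CDR3") and not extract.has_gap

    def test_substitution_inside_region(self, ref):
        start, _ = ref.region("CDR3")
        query = substitute(ref.sequence, start + 4,
                           {"A": "C"}.get(ref.sequence[start + 4], "A"))
        aln = align_to_reference(query, ref)
        extract = extract_region(aln, "CDR3", ref)
        region = ref.region_nt("CDR3")
        assert extract.sequence != region
        assert [i for i, (a, b) in enumerate(zip(extract.sequence, region)) if a != b] == [4]

    def test_deletion_inside_region_flagged(self, ref):
        start, _ = ref.region("CDR3")
        query = ref.sequence[: start + 3] + ref.sequence[start + 4 :]
        aln = align_to_reference(query, ref)
        assert extract_region(aln, "CDR3", ref).has_gap

    def test_unknown_region_rejected(self, ref):
        aln = align_to_reference(ref.sequence, ref)
        with pytest.raises(KeyError, match="unknown region"):
            extract_region(aln, "CDR9", ref)

    def test_planted_mutations_recovered_from_simulated_clones(self, ref):
        """Extracted CDR3s agree with simulator truth for mutated clones."""
        pool, events = mutate_pool(
            ClonePool({ref.sequence: 1}), ref,
            MutagenesisModel(per_base_rate_per_round=0.005, seed=77),
            return_events=True,
        )
        # rebuild the expected sequence from the event log
        expected = list(ref.sequence)
        for e in sorted(events, key=lambda e: e.round):
            expected[e.position] = e.new_base
        expected = "".join(expected)
        (observed,) = pool.clones
        assert observed == expected
        start, end = ref.region("CDR3")
        aln = align_to_reference(observed, ref)
        assert extract_region(aln, "CDR3", ref).sequence == expected[start:end]


class TestPositionProfile:
    def test_uniform_reference_pool(self, ref):
        profile = position_profile([ref.sequence] * 5, "CDR3", ref)
        assert np.all(profile.pid == 100.0)
        assert profile.region_mean_pid == 100.0
        assert np.allclose(profile.information_bits, 2.0)

    def test_two_equal_symbols_give_one_bit(self, ref):
        start, _ = ref.region("CDR3")
        alt = substitute(ref.sequence, start, "T")
        profile = position_profile([ref.sequence, alt], "CDR3", ref)
        assert profile.pid[0] == 50.0
        assert profile.information_bits[0] == pytest.approx(1.0)

    def test_hand_built_counts(self, ref):
        start, _ = ref.region("CDR3")
        pool = (
            [ref.sequence] * 14
            + [substitute(ref.sequence, start, "A")] * 4
            + [substitute(ref.sequence, start, "G")] * 2
        )
        profile = position_profile(pool, "CDR3", ref)
        assert profile.frequencies.loc[1, "C"] == pytest.approx(70.0)
        assert profile.frequencies.loc[1, "A"] == pytest.approx(20.0)
        assert profile.frequencies.loc[1, "G"] == pytest.approx(10.0)
        assert profile.pid[0] == pytest.approx(70.0)

    def test_frequencies_sum_to_100(self, ref, rng):
        pool = mutate_pool(
            ClonePool({ref.sequence: 200}), ref,
            MutagenesisModel(per_base_rate_per_round=0.02, seed=5),
        )
        profile = position_profile(pool.clones, "CDR3", ref)
        sums = profile.frequencies.sum(axis=1).to_numpy()
        assert np.allclose(sums, 100.0)
        # PID + non-reference mass = 100 at every position
        non_ref = sums - profile.pid
        assert np.allclose(profile.pid + non_ref, 100.0)

    def test_cluster_vs_read_denominator(self, ref):
        start, _ = ref.region("CDR3")
        alt = substitute(ref.sequence, start, "T")
        pool = {ref.sequence: 9, alt: 1}
        by_reads = position_profile(pool, "CDR3", ref, denominator="reads")
        by_clusters = position_profile(pool, "CDR3", ref, denominator="clusters")
        assert by_reads.pid[0] == pytest.approx(90.0)
        assert by_clusters.pid[0] == pytest.approx(50.0)

    def test_ambiguous_mass_reported_separately(self, ref):
        start, _ = ref.region("CDR3")
        pool = [ref.sequence, substitute(ref.sequence, start, "N")]
        profile = position_profile(pool, "CDR3", ref)
        assert profile.ambiguous_pct[0] == pytest.approx(50.0)
        assert profile.pid[0] == pytest.approx(50.0)
        # bits computed on canonical mass only: single symbol -> maximal
        assert profile.information_bits[0] == pytest.approx(2.0)

    def test_empty_pool_rejected(self, ref):
        with pytest.raises(ValueError, match="empty pool"):
            position_profile([], "CDR3", ref)


class TestRankMutations:
    def test_zero_mutation_pool_empty(self, ref):
        profile = position_profile([ref.sequence] * 3, "CDR3", ref)
        assert rank_mutations(profile) == []

    def test_known_frequencies_in_order(self, ref):
        start, _ = ref.region("CDR3")
        pool = (
            [ref.sequence] * 94
            + [substitute(ref.sequence, start, "T")] * 3
            + [substitute(ref.sequence, start + 7, "A")] * 2
            + [substitute(ref.sequence, start + 13, "T")] * 1
        )
        top = rank_mutations(position_profile(pool, "CDR3", ref), top_k=3)
        assert [(m.position, m.observed_symbol, m.frequency_pct) for m in top] == [
            (1, "T", 3.0),
            (8, "A", 2.0),
            (14, "T", 1.0),
        ]

    def test_matches_exhaustive_enumeration(self, ref, rng):
        pool = mutate_pool(
            ClonePool({ref.sequence: 300}), ref,
            MutagenesisModel(per_base_rate_per_round=0.02, seed=9),
        )
        profile = position_profile(pool.clones, "CDR3", ref)
        ranked = rank_mutations(profile, top_k=1000)
        # oracle: enumerate every non-reference canonical cell and sort
        cells = []
        region = ref.region_nt("CDR3")
        for i, position in enumerate(profile.frequencies.index):
            for symbol in "ACGT":
                if symbol == region[i]:
                    continue
                f = round(float(profile.frequencies.loc[position, symbol]), 2)
                if f > 0:
                    cells.append((-f, int(position), symbol))
        cells.sort()
        assert [(m.position, m.observed_symbol) for m in ranked] == [
            (p, s) for _, p, s in cells
        ]


class TestCloneReport:
    def test_reference_clone_has_empty_report(self, ref):
        assert clone_report(ref.sequence, ref) == []

    def test_planted_synonymous_g_to_a_in_fr2(self, ref):
        # FR2 glutamine codon CAG -> CAA is synonymous and a transition
        start, end = ref.region("FR2")
        pos = next(
            p for p in range(start, end)
            if ref.sequence[p] == "G" and (p - ref.frame_offset) % 3 == 2
            and ref.sequence[p - 2 : p + 1] == "CAG"
        )
        report = clone_report(substitute(ref.sequence, pos, "A"), ref)
        assert len(report) == 1
        (m,) = report
        assert m.region == "FR2"
        assert m.mutation_class == "transition"
        assert m.synonymous is True
        assert (m.ref_codon, m.observed_codon) == ("CAG", "CAA")

    def test_three_planted_mutations_all_annotated(self, ref):
        q = ref.sequence
        targets = [(80, "CDR1"), (120, "FR2"), (300, "CDR3")]
        for pos, _ in targets:
            q = substitute(q, pos, {"A": "C"}.get(q[pos], "A"))
        report = clone_report(q, ref)
        assert [(m.nt_position - 1, m.region) for m in report] == targets
        for m in report:
            assert m.mutation_class == classify_substitution(
                m.ref_symbol, m.observed_symbol
            )

    def test_matches_simulator_event_log(self, ref):
        """Substitution-only simulated clones reproduce the planted list."""
        pool, events = mutate_pool(
            ClonePool({ref.sequence: 40}), ref,
            MutagenesisModel(per_base_rate_per_round=0.004, seed=13),
            return_events=True,
        )
        # keep clones from copies whose sites were hit at most once
        per_copy: dict[int, list] = {}
        for e in events:
            per_copy.setdefault(e.copy_index, []).append(e)
        copies = sorted(per_copy)
        for copy_index in copies[:10]:
            evs = per_copy[copy_index]
            if len({e.position for e in evs}) != len(evs):
                continue
            seq = list(ref.sequence)
            for e in evs:
                seq[e.position] = e.new_base
            report = clone_report("".join(seq), ref)
            assert {(m.nt_position - 1, m.observed_symbol) for m in report} == {
                (e.position, e.new_base) for e in evs
            }


class TestReferenceRegionFraction:
    def test_no_matches(self, ref):
        start, _ = ref.region("CDR3")
        pool = [substitute(ref.sequence, start, "T")] * 4
        assert reference_region_fraction(pool, "CDR3", ref) == 0.0

    def test_hand_counts(self, ref):
        start, _ = ref.region("CDR3")
        pool = {ref.sequence: 3, substitute(ref.sequence, start, "T"): 1}
        assert reference_region_fraction(pool, "CDR3", ref) == pytest.approx(75.0)

    def test_ambiguous_counts_as_non_matching(self, ref):
        start, _ = ref.region("CDR3")
        pool = [ref.sequence, substitute(ref.sequence, start, "N")]
        assert reference_region_fraction(pool, "CDR3", ref) == pytest.approx(50.0)
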