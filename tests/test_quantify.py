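import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanotype.io import AlignmentRecord
from nanotype.quantify import (
    UNMAPPED_GENE,
    collapse_genes,
    fractional_counts,
    quantify_sample,
    read_n50,
    tpm_normalize,
)
from nanotype.simulate import simulate_paf
from nanotype.io import read_paf
from tests.conftest import brute_force_fractional_counts, brute_force_n50


def rec(read, target, score, length=200):
    return AlignmentRecord(read, length, target, score)


class TestFractionalCounts:
    def test_unique_alignment_gets_full_count(self):
        assert fractional_counts([rec("r1", "T1", 100)]) == {"T1": 1.0}

    def test_equal_split_among_best_score_ties(self):
        counts = fractional_counts(
            [rec("r1", "T1", 100), rec("r1", "T2", 100), rec("r1", "T3", 40)]
        )
        assert counts == {"T1": 0.5, "T2": 0.5}

    def test_hand_summed_mixture(self):
        counts = fractional_counts(
            [
                rec("r1", "T1", 90),
                rec("r2", "T1", 80),
                rec("r3", "T1", 70),
                rec("r3", "T2", 70),
            ]
        )
        assert counts == {"T1": 2.5, "T2": 0.5}

    def test_empty_input(self):
        assert fractional_counts([]) == {}

    def test_weighted_split_proportional_to_score(self):
        counts = fractional_counts(
            [rec("r1", "T1", 100), rec("r1", "T2", 300)], weighted=True
        )
        assert counts == pytest.approx({"T1": 0.25, "T2": 0.75})

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 9),   # read index
                st.integers(0, 4),   # target index
                st.integers(0, 50),  # score
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_conservation_permutation_and_oracle(self, triples):
        """Each read contributes total weight 1; record order is irrelevant;
        the result equals a brute-force per-read enumeration oracle."""
        records = [rec(f"r{i}", f"T{j}", s) for i, j, s in triples]
        counts = fractional_counts(records)
        n_reads = len({r.read_id for r in records})
        assert sum(counts.values()) == pytest.approx(n_reads, abs=1e-9)

        shuffled = records[::-1]
        assert fractional_counts(shuffled) == counts

        oracle = brute_force_fractional_counts(records)
        assert set(counts) == set(oracle)
        for t in counts:
            assert counts[t] == pytest.approx(oracle[t], abs=1e-12)


class TestTpmNormalize:
    def test_single_transcript_takes_the_million(self):
        assert tpm_normalize({"T1": 1.0}) == {"T1": 1e6}

    def test_proportional_without_length_term(self):
        tpm = tpm_normalize({"T1": 3.0, "T2": 1.0})
        assert tpm == pytest.approx({"T1": 750000.0, "T2": 250000.0})

    def test_length_normalization_equalizes_per_base_rates(self):
        tpm = tpm_normalize(
            {"T1": 2.0, "T2": 1.0}, lengths={"T1": 200, "T2": 100}, length_normalize=True
        )
        assert tpm == pytest.approx({"T1": 500000.0, "T2": 500000.0})

    def test_all_zero_counts_give_all_zero_tpm(self):
        assert tpm_normalize({"T1": 0.0, "T2": 0.0}) == {"T1": 0.0, "T2": 0.0}

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize({"T1": -1.0})


class TestCollapseGenes:
    def test_sums_members_of_one_gene(self, t2g_two_genes):
        assert collapse_genes({"T1a": 10.0, "T1b": 5.0}, t2g_two_genes) == {"G1": 15.0}

    def test_distinct_genes_pass_through(self, t2g_two_genes):
        out = collapse_genes({"T1a": 7.0, "T2a": 3.0}, t2g_two_genes)
        assert out == {"G1": 7.0, "G2": 3.0}

    def test_unknown_transcript_routed_to_unmapped_bucket(self, t2g_two_genes):
        with pytest.warns(UserWarning, match="__unmapped__"):
            out = collapse_genes({"T1a": 6.0, "Tx": 4.0}, t2g_two_genes)
        assert out == {"G1": 6.0, UNMAPPED_GENE: 4.0}
        assert sum(out.values()) == pytest.approx(10.0)


class TestReadN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([100], 100), ([2, 3, 5], 5), ([1, 1, 1, 1], 1), ([10, 10, 10, 1], 10)],
    )
    def test_known_values(self, lengths, expected):
        assert read_n50(lengths) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            read_n50([])

    def test_matches_threshold_scan_oracle(self):
        rng = random.Random(7)
        for _ in range(100):
            lengths = [rng.randint(1, 2000) for _ in range(rng.randint(1, 1000))]
            assert read_n50(lengths) == brute_force_n50(lengths)


class TestQuantifySample:
    def test_recovers_hand_computed_tpm(self, t2g_two_genes):
        # 10 reads: 6 unique to T1a, 2 unique to T2a, 2 tied between T1a/T2a
        records = []
        for i in range(6):
            records.append(rec(f"u{i}", "T1a", 100))
        for i in range(2):
            records.append(rec(f"v{i}", "T2a", 100))
        for i in range(2):
            records += [rec(f"w{i}", "T1a", 80), rec(f"w{i}", "T2a", 80)]
        profile = quantify_sample(records, t2g_two_genes)
        assert profile.n_aligned == 10
        assert profile.transcript_tpm["T1a"] == pytest.approx(7 / 10 * 1e6)
        assert profile.gene_tpm["G2"] == pytest.approx(3 / 10 * 1e6)
        assert sum(profile.gene_tpm.values()) == pytest.approx(1e6, rel=1e-6)

    def test_zero_alignments(self, t2g_two_genes):
        profile = quantify_sample([], t2g_two_genes)
        assert profile.n_aligned == 0
        assert profile.transcript_tpm == {} and profile.gene_tpm == {}

    def test_single_transcript_fixture(self, t2g_two_genes):
        profile = quantify_sample([rec("r1", "T1a", 50)], t2g_two_genes)
        assert profile.transcript_tpm == {"T1a": 1e6}

    def test_reads_with_only_secondary_alignments_still_count(self, t2g_two_genes):
        records = [AlignmentRecord("r1", 200, "T1a", 90, is_primary=False)]
        profile = quantify_sample(records, t2g_two_genes)
        assert profile.n_aligned == 1
        assert profile.transcript_tpm == {"T1a": 1e6}

    def test_total_reads_summary_drives_alignment_rate(self, t2g_two_genes):
        profile = quantify_sample([rec("r1", "T1a", 50)], t2g_two_genes, total_reads=4)
        assert profile.n_reads == 4 and profile.n_aligned == 1
        assert profile.alignment_rate == pytest.approx(0.25)

    def test_simulated_paf_without_multimapping_recovers_truth(self):
        transcripts = {"T1": 600, "T2": 800, "T3": 400}
        paf_text, truth = simulate_paf(40, transcripts, multimap_fraction=0.0, seed=5)
        counts = fractional_counts(read_paf(paf_text.splitlines()))
        assert counts == pytest.approx(truth)
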