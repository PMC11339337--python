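import numpy as np
import pandas as pd
import pytest

from nanotype.config import RunConfig
from nanotype.evaluate import confusion, grouped_loocv, tier_report
from nanotype.model import PredictionResult
from nanotype.simulate import CohortSpec, simulate_cohort


def result(sample_id, called, p):
    probs = {called: p, "other": 1 - p}
    return PredictionResult(sample_id, probs, called, p, tier="high" if p > 0.8 else "low")


class TestTierReport:
    def test_all_confident_and_correct(self):
        results = [result(f"s{i}", "A", 0.9) for i in range(4)]
        truths = {f"s{i}": "A" for i in range(4)}
        table = tier_report(results, truths)
        for t in (0.5, 0.6, 0.8):
            assert table[t] == {"coverage": 1.0, "accuracy": 1.0}

    def test_mixed_confidence(self):
        results = [result("s0", "A", 0.85), result("s1", "A", 0.55)]
        truths = {"s0": "A", "s1": "B"}
        table = tier_report(results, truths)
        assert table[0.8] == {"coverage": 0.5, "accuracy": 1.0}
        assert table[0.5] == {"coverage": 1.0, "accuracy": 0.5}

    def test_threshold_is_strict(self):
        results = [result("s0", "A", 0.8)]
        table = tier_report(results, {"s0": "A"})
        assert table[0.8]["coverage"] == 0.0
        assert table[0.8]["accuracy"] is None

    def test_coverage_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        results = [result(f"s{i}", "A", float(p)) for i, p in enumerate(rng.uniform(0.3, 1.0, 30))]
        truths = {r.sample_id: "A" for r in results}
        table = tier_report(results, truths)
        coverages = [table[t]["coverage"] for t in (0.5, 0.6, 0.8)]
        assert coverages == sorted(coverages, reverse=True)

    def test_empty_results_error(self):
        with pytest.raises(ValueError):
            tier_report([], {})


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        results = [result("s0", "A", 0.9), result("s1", "B", 0.9)]
        mat = confusion(results, {"s0": "A", "s1": "B"})
        assert mat.loc["A", "A"] == 1 and mat.loc["B", "B"] == 1
        assert mat.to_numpy().sum() == 2

    def test_single_error_lands_off_diagonal(self):
        results = [result(f"a{i}", "A", 0.9) for i in range(9)] + [result("a9", "B", 0.9)]
        truths = {r.sample_id: "A" for r in results}
        mat = confusion(results, truths, classes=["A", "B"])
        assert mat.loc["A", "A"] == 9 and mat.loc["A", "B"] == 1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            confusion([], {})


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = CohortSpec(
        n_classes=2, samples_per_class=3, n_genes=200, n_signature_genes=10,
        library_size=10_000, seed=6,
    )
    return simulate_cohort(spec)


class TestGroupedLoocv:
    def test_every_sample_predicted_once(self, tiny_cohort):
        report = grouped_loocv(tiny_cohort)
        assert len(report.results) == tiny_cohort.n_samples
        assert all(len(f.train_samples) == tiny_cohort.n_samples - 1 for f in report.folds)

    def test_overall_accuracy_equals_confusion_trace(self, tiny_cohort):
        report = grouped_loocv(tiny_cohort)
        trace = np.trace(report.confusion_matrix.to_numpy())
        assert report.overall_accuracy == pytest.approx(trace / len(report.results))

    def test_replicates_excluded_from_each_others_folds(self):
        spec = CohortSpec(
            n_classes=2, samples_per_class=4, n_genes=200, n_signature_genes=10,
            library_size=10_000, replicate_rate=1.0, seed=7,
        )
        m = simulate_cohort(spec)
        report = grouped_loocv(m)
        groups = m.groups
        for fold in report.folds:
            twins = [s for s in m.samples if groups[s] == fold.group_id and s != fold.sample_id]
            assert twins, "replicate_rate=1 should give every sample a twin"
            assert not set(twins) & set(fold.train_samples)
            assert fold.group_id not in fold.train_groups

    def test_naive_mode_keeps_twins_in_training(self):
        spec = CohortSpec(
            n_classes=2, samples_per_class=4, n_genes=200, n_signature_genes=10,
            library_size=10_000, replicate_rate=1.0, seed=7,
        )
        m = simulate_cohort(spec)
        report = grouped_loocv(m, grouped=False)
        fold = report.folds[0]
        twins = [s for s in m.samples if m.groups[s] == fold.group_id and s != fold.sample_id]
        assert set(twins) <= set(fold.train_samples)

    def test_fold_skipped_when_class_collapses(self):
        spec = CohortSpec(
            n_classes=2, samples_per_class=3, n_genes=200, n_signature_genes=10,
            library_size=10_000, seed=8,
        )
        m = simulate_cohort(spec)
        # put both typeB spares in one group so removing it leaves typeB with 1 sample
        groups = m.groups.copy()
        b_samples = [s for s in m.samples if m.labels[s] == "typeB"]
        groups[b_samples[0]] = "shared"
        groups[b_samples[1]] = "shared"
        m2 = m.with_labels(m.labels)
        m2.groups = groups
        report = grouped_loocv(m2)
        skipped_ids = {s for s, _ in report.skipped}
        assert skipped_ids == {b_samples[0], b_samples[1]}

    def test_single_class_is_error(self, tiny_cohort):
        only_a = tiny_cohort.subset_samples(
            [s for s in tiny_cohort.samples if tiny_cohort.labels[s] == "typeA"]
        )
        with pytest.raises(ValueError, match="2 classes"):
            grouped_loocv(only_a)

    def test_train_only_filter_fitted_without_test_sample(self, tiny_cohort):
        from nanotype.matrix import filter_genes

        report = grouped_loocv(tiny_cohort, config=RunConfig(filter_scope="train_only"))
        fold = report.folds[0]
        expected = filter_genes(
            tiny_cohort.subset_samples(list(fold.train_samples)), 0.01
        ).genes
        assert list(fold.gene_set) == expected
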