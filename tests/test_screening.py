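"""ROC uncertainty ranges and the hierarchical screening cascade."""

import numpy as np
import pytest

from olivescreen.chromatograms import FingerprintMatrix
from olivescreen.screening import (
    ScreeningConfig,
    UncertaintyRange,
    decide_binary,
    fit_screening_model,
    roc_from_cv,
    screen,
    uncertainty_range,
)
from olivescreen.simulate import simulate_dataset

POS = np.array([0.6, 0.7, 0.9])
NEG = np.array([0.2, 0.5, 0.65])
PV6 = np.concatenate([POS, NEG])
LAB6 = np.array([True, True, True, False, False, False])


def oracle_range(pv, labels):
    """Exhaustive cutoff scan: largest cutoff with sensitivity 1 and the
    boundary above which specificity is 1."""
    pv = np.asarray(pv, float)
    pos = pv[labels]
    neg = pv[~labels]
    candidates = np.unique(pv)
    sens_one = [c for c in candidates if (pos >= c).all()]
    lower = max(sens_one)
    # specificity counts PV < cutoff, so spec = 1 for any cutoff > max(neg)
    upper = max(neg)
    return lower, upper


class TestRoc:
    def test_counting_example(self):
        roc = roc_from_cv(PV6, LAB6)
        cut = {c: i for i, c in enumerate(roc.cutoffs)}
        # brute-force counting over the six values: at 0.65 only two of the
        # three positives are >= the cutoff, and the 0.65 negative is not
        # counted by specificity (which counts PV strictly below the cutoff)
        assert roc.sensitivity[cut[0.65]] == pytest.approx(2 / 3)
        assert roc.specificity[cut[0.65]] == pytest.approx(2 / 3)
        # sensitivity is 1 at and below the smallest positive PV
        assert roc.sensitivity[cut[0.6]] == 1.0
        assert roc.specificity[cut[0.9]] == 1.0

    def test_perfect_separation(self):
        roc = roc_from_cv(np.array([0.9, 0.1]), np.array([True, False]))
        i = int(np.argmin(np.abs(roc.cutoffs - 0.5)))
        # at the cutoff between the classes both rates are 1
        mid = (roc.cutoffs > 0.1) & (roc.cutoffs <= 0.9)
        assert np.any((roc.sensitivity == 1) & (roc.specificity == 1))

    def test_monotone_by_construction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pv = rng.normal(0.5, 0.3, 15)
            lab = rng.integers(0, 2, 15).astype(bool)
            if lab.all() or not lab.any():
                continue
            roc = roc_from_cv(pv, lab)
            assert np.all(np.diff(roc.sensitivity) <= 1e-12)
            assert np.all(np.diff(roc.specificity) >= -1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_from_cv(np.array([0.1, 0.2]), np.array([True, True]))


class TestUncertaintyRange:
    def test_example_thresholds(self):
        rng = uncertainty_range(PV6, LAB6)
        assert rng.lower == 0.6
        assert rng.upper == 0.65
        assert not rng.empty

    def test_perfect_separation_midpoint(self):
        rng = uncertainty_range(np.array([0.8, 0.9, 0.1, 0.2]),
                                np.array([True, True, False, False]))
        assert rng.empty
        assert rng.single_threshold == pytest.approx(0.5)

    def test_matches_exhaustive_scan_on_random_sets(self):
        """Property: thresholds equal an exhaustive cutoff-scan oracle."""
        for seed in range(100):
            rg = np.random.default_rng(seed)
            n = int(rg.integers(4, 21))
            pv = np.round(rg.normal(0.5, 0.25, n), 3)
            lab = rg.integers(0, 2, n).astype(bool)
            if lab.all() or not lab.any():
                continue
            rng = uncertainty_range(pv, lab)
            lo, up = oracle_range(pv, lab)
            assert rng.lower == lo
            assert rng.upper == up
            if not rng.empty:
                assert np.all(pv[lab] >= rng.lower)
                assert np.all(pv[~lab] <= rng.upper)


class TestDecideBinary:
    # thresholds from the published full EVOO/non-EVOO model
    RANGE = UncertaintyRange(lower=0.354, upper=0.752)

    @pytest.mark.parametrize("pv, expected", [
        (0.80, "positive"),
        (0.354, "uncertain"),
        (0.752, "uncertain"),
        (0.5, "uncertain"),
        (0.30, "negative"),
    ])
    def test_rule_application(self, pv, expected):
        assert decide_binary(pv, self.RANGE) == expected

    def test_empty_range_midpoint_rule(self):
        rng = UncertaintyRange(lower=0.6, upper=0.4)  # empty, midpoint 0.5
        assert rng.single_threshold == pytest.approx(0.5)
        assert decide_binary(0.5, rng) == "positive"   # >= convention
        assert decide_binary(0.4999, rng) == "negative"

    def test_widening_never_decreases_uncertain(self):
        rng0 = UncertaintyRange(0.4, 0.6)
        wide = UncertaintyRange(0.35, 0.65)
        pvs = np.linspace(0, 1, 101)
        d0 = [decide_binary(p, rng0) for p in pvs]
        d1 = [decide_binary(p, wide) for p in pvs]
        assert sum(d == "uncertain" for d in d1) >= sum(
            d == "uncertain" for d in d0)
        for a, b in zip(d0, d1):
            if b != "uncertain":
                assert a == b  # widening only converts assignments to deferrals


@pytest.fixture(scope="module")
def fitted(small_dataset_module):
    matrix, truths = small_dataset_module
    cats = [t.category for t in truths]
    cfg = ScreeningConfig(n_permutations=3, seed=7)
    return fit_screening_model(matrix, cats, cfg), matrix, truths


@pytest.fixture(scope="module")
def small_dataset_module():
    from olivescreen.align import align_batched
    matrix, truths = simulate_dataset(36, 30, 24, n_batches=2, seed=42)
    aligned, _ = align_batched(matrix, n_intervals=50)
    return aligned, truths


class TestFitScreeningModel:
    def test_training_assignments_all_correct(self, fitted):
        """Assigned training out-of-fold PVs are never misclassified."""
        model, matrix, truths = fitted
        cats = np.array([t.category for t in truths])
        oof = model.diagnostics1.cv.oof_at_chosen
        y = cats == "EVOO"
        for pv, truth in zip(oof, y):
            d = decide_binary(float(pv), model.range1)
            if d == "positive":
                assert truth
            elif d == "negative":
                assert not truth

    def test_model2_trained_on_non_evoo_subset(self, fitted):
        model, matrix, truths = fitted
        cat_of = {t.sample_id: t.category for t in truths}
        assert set(model.model2.training_ids) == {
            t.sample_id for t in truths if t.category != "EVOO"}
        assert set(model.model2.training_ids) < set(model.model1.training_ids)

    def test_diagnostics_clean_on_separable_data(self, fitted):
        model, *_ = fitted
        assert not model.diagnostics1.q2_flag
        assert not model.diagnostics2.q2_flag
        assert not model.diagnostics1.anova_flag

    def test_shuffled_labels_flagged(self, small_dataset_module):
        matrix, truths = small_dataset_module
        rng = np.random.default_rng(3)
        cats = rng.permutation([t.category for t in truths])
        cfg = ScreeningConfig(n_permutations=5, seed=1)
        model = fit_screening_model(matrix, list(cats), cfg)
        assert model.diagnostics1.q2_flag

    def test_missing_category_rejected(self, small_dataset_module):
        matrix, truths = small_dataset_module
        cats = ["EVOO" if t.category == "VOO" else t.category for t in truths]
        with pytest.raises(ValueError, match="VOO"):
            fit_screening_model(matrix, cats)


class TestScreen:
    def test_cascade_rules_and_partition(self, fitted):
        model, matrix, truths = fitted
        decisions = screen(model, matrix)
        assert len(decisions) == matrix.n_samples
        n_unc = sum(d.outcome == "UNCERTAIN" for d in decisions)
        n_assigned = sum(d.outcome != "UNCERTAIN" for d in decisions)
        assert n_unc + n_assigned == matrix.n_samples
        for d in decisions:
            if d.outcome == "EVOO" or d.deferred_at == "model1":
                assert d.pv2 is None
                if d.outcome == "EVOO":
                    assert d.pv1 > model.range1.upper or (
                        model.range1.empty
                        and d.pv1 >= model.range1.single_threshold)
            if d.outcome == "VOO":
                assert d.pv2 is not None
                assert d.pv2 < model.range2.lower or (
                    model.range2.empty
                    and d.pv2 < model.range2.single_threshold)

    def test_grid_mismatch_rejected(self, fitted):
        model, matrix, _ = fitted
        other = FingerprintMatrix(
            sample_ids=["x"],
            rt_axis=np.linspace(0, 1, 10),
            values=np.ones((1, 10)),
        )
        with pytest.raises(ValueError, match="grid"):
            screen(model, other)

    def test_json_round_trip_preserves_decisions(self, fitted, tmp_path):
        model, matrix, _ = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        from olivescreen.screening import HierarchicalScreeningModel
        loaded = HierarchicalScreeningModel.from_json(path)
        d1 = screen(model, matrix)
        d2 = screen(loaded, matrix)
        assert [(d.sample_id, d.outcome) for d in d1] == \
               [(d.sample_id, d.outcome) for d in d2]
        np.testing.assert_allclose([d.pv1 for d in d1], [d.pv1 for d in d2],
                                   atol=1e-12)
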