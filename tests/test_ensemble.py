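"""IQR-trimmed averaging, calibration, AUROC and Shapley attribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmvar.ensemble import (
    EnsemblePredictor,
    calibrate_fpr_threshold,
    compute_auroc,
    exact_shapley,
    iqr_trimmed_mean,
    positional_attribution,
    scan_proteome,
)
from conftest import StubModel


def brute_force_iqr_mean(values):
    """Independent trimmed-mean oracle with hand-rolled interpolated quartiles."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return v[lo] * (1 - frac) + v[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    iqr = q3 - q1
    kept = [x for x in v if q1 - 1.5 * iqr <= x <= q3 + 1.5 * iqr]
    return sum(kept) / len(kept)


class TestIQRTrimmedMean:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([0.8] * 10, 0.8),  # constant input
            ([0.9] * 9 + [0.0], 0.9),  # collapsed quartiles exclude the outlier
            ([0.4, 0.5, 0.6], 0.5),  # nothing outside the bounds
            ([0.42], 0.42),  # single score
        ],
    )
    def test_examples(self, scores, expected):
        assert iqr_trimmed_mean(scores) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iqr_trimmed_mean([])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        worst = 0.0
        for _ in range(10_000):
            v = rng.random(10)
            worst = max(worst, abs(iqr_trimmed_mean(v) - brute_force_iqr_mean(v)))
        assert worst < 1e-12

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_result_within_input_range(self, values):
        out = iqr_trimmed_mean(values)
        assert min(values) - 1e-12 <= out <= max(values) + 1e-12


class TestEnsembleScoring:
    def test_constant_stubs_pass_through(self, stub_ensemble, toy_protein):
        assert stub_ensemble.predict_site(
            toy_protein, 4, "phosphorylation"
        ) == pytest.approx(0.7)

    def test_outlier_member_excluded(self, toy_protein):
        ens = EnsemblePredictor(
            models=[StubModel(0.9) for _ in range(9)] + [StubModel(0.0)]
        )
        assert ens.predict_site(toy_protein, 4, "phosphorylation") == pytest.approx(0.9)

    def test_residue_mismatch_rejected(self, stub_ensemble, toy_protein):
        with pytest.raises(ValueError, match="target residue"):
            stub_ensemble.predict_site(toy_protein, 1, "phosphorylation")  # M

    def test_each_member_uses_its_own_window_length(self, toy_protein):
        seen = []

        def record_rule(peptide):
            seen.append(len(peptide))
            return 0.5

        ens = EnsemblePredictor(
            models=[
                StubModel(window_len=7, rule=record_rule),
                StubModel(window_len=11, rule=record_rule),
            ]
        )
        ens.predict_site(toy_protein, 4, "phosphorylation")
        assert sorted(seen) == [7, 11]


class TestScan:
    def test_row_per_target_residue(self, stub_ensemble, toy_protein):
        rows = scan_proteome(stub_ensemble, [toy_protein], "phosphorylation")
        expected = sum(toy_protein.sequence.count(a) for a in "STY")
        assert len(rows) == expected

    def test_no_target_residues_empty(self, stub_ensemble):
        from ptmvar.seqcore import ProteinRecord

        rows = scan_proteome(
            stub_ensemble, [ProteinRecord("p", "AAAGGG")], "phosphorylation"
        )
        assert rows == []

    def test_high_confidence_nested_in_positive(self, toy_protein):
        rng = np.random.default_rng(0)
        ens = EnsemblePredictor(
            models=[StubModel(rule=lambda p: float(rng.random()))],
            high_conf_threshold=0.8,
        )
        rows = scan_proteome(ens, [toy_protein], "phosphorylation")
        for row in rows:
            if row["class"] == "high_confidence":
                assert row["probability"] >= 0.5


class TestCalibration:
    def test_enumerated_example(self):
        scores = [0.005 * i for i in range(1, 201)]
        assert calibrate_fpr_threshold(scores, 0.01) == pytest.approx(0.990)

    def test_all_zero_scores(self):
        assert calibrate_fpr_threshold([0.0] * 50) == 0.0

    def test_fpr_one_returns_minimum(self):
        assert calibrate_fpr_threshold([0.3, 0.7, 0.1], 1.0) == pytest.approx(0.1)

    def test_achieved_fpr_below_requested(self):
        rng = np.random.default_rng(5)
        scores = rng.random(500)
        t = calibrate_fpr_threshold(scores, 0.05)
        assert np.mean(scores > t) <= 0.05


class TestAUROC:
    def test_perfect_separation(self):
        assert compute_auroc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auroc([0.5] * 5, [0.5] * 5) == 0.5

    def test_enumerated_pairs(self):
        # pairs: (.9>.5),(.9>.1),(.4<.5),(.4>.1) -> 3/4
        assert compute_auroc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        pos, neg = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        a = compute_auroc(pos, neg)
        b = compute_auroc(np.exp(pos), np.exp(neg))
        assert a == pytest.approx(b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([], [0.1])


class TestAttribution:
    @staticmethod
    def _linear_stub(seed=3, n=7):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(n, 22)) * 0.8

        def predict(batch):
            batch = np.asarray(batch)
            return 1.0 / (1.0 + np.exp(-np.sum(batch * W, axis=(1, 2))))

        return predict

    def test_monte_carlo_matches_exact_enumeration(self):
        predict = self._linear_stub()
        mc, residual = positional_attribution(predict, "ACDNGSW", 2000, seed=0)
        exact = exact_shapley(predict, "ACDNGSW")
        assert np.abs(mc - exact).max() < 0.02
        assert residual < 1e-9  # efficiency holds exactly per permutation

    def test_center_only_model_concentrates_mass(self):
        def center_stub(batch):
            return np.asarray(batch)[:, 3, :].sum(axis=1)

        contrib, _ = positional_attribution(center_stub, "ACDNGSW", 200, seed=1)
        assert abs(contrib[3]) / np.abs(contrib).sum() >= 0.95

    def test_baseline_window_all_zero(self):
        predict = self._linear_stub()
        contrib, residual = positional_attribution(predict, "XXXXXXX", 20, seed=0)
        assert np.abs(contrib).max() == 0.0 and residual == 0.0

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            positional_attribution(self._linear_stub(), "ACDNGSW", 0)
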