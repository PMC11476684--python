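"""GMM marker gating, co-occurrence classes, confusion matrices, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemux.gating import (
    CooccurrenceClass,
    GmmGate,
    assign_classes,
    call_markers,
    class_precision,
    confusion_by_class,
    fit_gate,
    fit_gates,
    interaction_enrichment,
)
from hemux.panel import MarkerPanel


def sample_mixture(rng, n=5000, mu=(0.0, 3.0), sd=(1.0, 1.0), pi1=0.3):
    lab = rng.uniform(size=n) < pi1
    return np.where(lab, rng.normal(mu[1], sd[1], n), rng.normal(mu[0], sd[0], n)), lab


class TestGmmGate:
    def test_recovers_planted_mixture_against_bayes_oracle(self, rng):
        v, _ = sample_mixture(rng)
        gate = fit_gate(v, seed=0)
        assert 0.25 <= gate.weights_[1] <= 0.35
        # oracle: classify with the generating parameters
        bayes = 0.3 * stats.norm.pdf(v, 3, 1) >= 0.7 * stats.norm.pdf(v, 0, 1)
        assert gate.predict(v).mean() == pytest.approx(bayes.mean(), abs=0.05)
        assert gate.means_[0] < gate.threshold_ < gate.means_[1]

    def test_identical_values_degenerate_zero_positives(self):
        gate = fit_gate(np.full(100, 2.5), seed=0)
        assert gate.degenerate_
        assert gate.predict(np.full(100, 2.5)).sum() == 0

    def test_threshold_shift_equivariance(self, rng):
        v, _ = sample_mixture(rng)
        g0 = fit_gate(v, seed=0)
        g1 = fit_gate(v + 7.0, seed=0)
        assert g1.threshold_ - g0.threshold_ == pytest.approx(7.0, abs=1e-6)
        assert np.array_equal(g1.predict(v + 7.0), g0.predict(v))

    def test_refit_idempotent(self, rng):
        v, _ = sample_mixture(rng)
        assert fit_gate(v, seed=3).threshold_ == fit_gate(v, seed=3).threshold_

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_gate(np.arange(10.0))

    def test_calls_are_threshold_monotone(self, rng):
        v, _ = sample_mixture(rng)
        gate = fit_gate(v, seed=0)
        calls = gate.predict(v)
        order = np.argsort(v)
        # once positive, always positive for larger values
        assert np.all(np.diff(calls[order].astype(int)) >= 0)

    def test_overlapping_components_flagged_degenerate(self, rng):
        v = rng.normal(0, 1, 500)  # single component: means collapse
        gate = GmmGate(min_separation=0.5, random_state=0).fit(v)
        if gate.degenerate_:
            assert gate.predict(v).sum() == 0


class TestCallMarkers:
    PANEL = MarkerPanel(("A", "B"))

    def _tiles(self, rng, n=120):
        va, _ = sample_mixture(rng, n=n)
        vb, _ = sample_mixture(rng, n=n)
        return pd.DataFrame(
            {"slide_id": "s1", "A_z": va, "B_z": vb}
        )

    def test_boundary_values_straddle_threshold(self, rng):
        tiles = self._tiles(rng)
        gates = fit_gates(tiles, self.PANEL, seed=0)
        t = gates[("s1", "A")].threshold_
        probe = pd.DataFrame(
            {"slide_id": "s1", "A_z": [t - 1e-9, t], "B_z": [0.0, 0.0]}
        )
        calls = call_markers(probe, gates, self.PANEL)
        assert not calls["A"][0] and calls["A"][1]

    def test_matches_elementwise_thresholding(self, rng):
        tiles = self._tiles(rng)
        gates = fit_gates(tiles, self.PANEL, seed=0)
        calls = call_markers(tiles, gates, self.PANEL)
        for name in self.PANEL.names:
            expected = tiles[f"{name}_z"].to_numpy() >= gates[("s1", name)].threshold_
            np.testing.assert_array_equal(calls[name], expected)

    def test_degenerate_gate_gives_all_negative_column(self, rng):
        tiles = self._tiles(rng)
        tiles["B_z"] = 1.0
        gates = fit_gates(tiles, self.PANEL, seed=0)
        calls = call_markers(tiles, gates, self.PANEL)
        assert calls["B"].sum() == 0

    def test_missing_gate_is_error(self, rng):
        tiles = self._tiles(rng)
        with pytest.raises(KeyError, match="B"):
            call_markers(tiles, {("s1", "A"): fit_gate(tiles["A_z"], 0)}, self.PANEL)


CLS_A = CooccurrenceClass("A+", ("A",))
CLS_AB = CooccurrenceClass("A+/B+", ("A", "B"))


def calls_frame(a, b, slide="s1"):
    return pd.DataFrame({"slide_id": slide, "A": a, "B": b})


class TestConfusion:
    def test_perfect_predictions_identity_matrix(self):
        calls = calls_frame([1, 1, 0, 0], [1, 0, 1, 0])
        cm = confusion_by_class(calls, calls, (CLS_A, CLS_AB))
        np.testing.assert_allclose(np.asarray(cm), np.eye(3))

    def test_ten_tile_hand_count(self):
        # true: 4 A+B+, 3 A+ only, 3 none;
        # predictions miscall one A+B+ as A+, one none as A+
        true = calls_frame(
            [1, 1, 1, 1, 1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        )
        pred = calls_frame(
            [1, 1, 1, 1, 1, 1, 1, 1, 0, 0], [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        )
        cm = confusion_by_class(true, pred, (CLS_A, CLS_AB))
        # predicted A+: tiles 3..7 -> true classes: A+B+ x1, A+ x3, none x1
        assert cm.loc["A+", "A+"] == pytest.approx(3 / 5)
        assert cm.loc["A+/B+", "A+"] == pytest.approx(1 / 5)
        assert cm.loc["none", "A+"] == pytest.approx(1 / 5)
        assert cm.loc["A+/B+", "A+/B+"] == pytest.approx(1.0)
        assert cm.loc["none", "none"] == pytest.approx(1.0)

    def test_columns_sum_to_one(self, rng):
        true = calls_frame(rng.integers(0, 2, 200), rng.integers(0, 2, 200))
        pred = calls_frame(rng.integers(0, 2, 200), rng.integers(0, 2, 200))
        cm = confusion_by_class(true, pred, (CLS_A, CLS_AB))
        sums = np.asarray(cm).sum(axis=0)
        ok = ~np.isnan(sums)
        np.testing.assert_allclose(sums[ok], 1.0, atol=1e-12)

    def test_empty_predicted_class_undefined(self):
        true = calls_frame([1, 0], [1, 0])
        pred = calls_frame([0, 0], [0, 0])
        cm = confusion_by_class(true, pred, (CLS_A, CLS_AB))
        assert cm["A+"].isna().all()

    def test_largest_matching_class_wins(self):
        calls = calls_frame([1], [1])
        labels = assign_classes(calls, (CLS_A, CLS_AB))
        assert labels[0] == "A+/B+"

    def test_precision_bounds_and_perfection(self, rng):
        true = calls_frame(rng.integers(0, 2, 100), rng.integers(0, 2, 100))
        noisy = calls_frame(
            true["A"] ^ (rng.uniform(size=100) < 0.2),
            true["B"] ^ (rng.uniform(size=100) < 0.2),
        )
        for cls in (CLS_A, CLS_AB):
            assert class_precision(true, true, cls) == 1.0
            p = class_precision(true, noisy, cls)
            assert 0.0 <= p <= 1.0


class TestEnrichment:
    def _planted(self, seed, p_int=0.6, p_non=0.3, n_slides=10, n_tiles=500):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_slides):
            n_i = n_tiles // 5
            inter = np.r_[np.ones(n_i, bool), np.zeros(n_tiles - n_i, bool)]
            ctx = np.r_[
                rng.uniform(size=n_i) < p_int,
                rng.uniform(size=n_tiles - n_i) < p_non,
            ]
            rows.append(
                pd.DataFrame(
                    {"slide_id": f"s{s}", "PD1": inter, "PDL1": inter, "CD45": ctx}
                )
            )
        return pd.concat(rows, ignore_index=True)

    @staticmethod
    def permutation_oracle(calls, n_shuffles=10_000, seed=0):
        """Sign-flip permutation test on per-slide differences."""
        diffs = []
        for _, sub in calls.groupby("slide_id"):
            inter = sub["PD1"].to_numpy() & sub["PDL1"].to_numpy()
            ctx = sub["CD45"].to_numpy()
            diffs.append(ctx[inter].mean() - ctx[~inter].mean())
        diffs = np.array(diffs)
        rng = np.random.default_rng(seed)
        obs = diffs.mean()
        flips = rng.choice([-1.0, 1.0], size=(n_shuffles, diffs.size))
        perm = (flips * diffs).mean(axis=1)
        return (1 + np.sum(perm >= obs)) / (1 + n_shuffles)

    def test_planted_enrichment_detected_and_agrees_with_permutation(self):
        calls = self._planted(seed=0)
        res = interaction_enrichment(calls, ("PD1", "PDL1"), ("CD45",))["CD45"]
        assert res.p is not None and res.p < 0.01
        p_perm = self.permutation_oracle(calls)
        assert (res.p < 0.01) == (p_perm < 0.01)

    def test_one_sided_directions_complementary(self):
        calls = self._planted(seed=1)
        pe = interaction_enrichment(calls, ("PD1", "PDL1"), ("CD45",))["CD45"].p
        pd_ = interaction_enrichment(
            calls, ("PD1", "PDL1"), ("CD45",), direction="depletion"
        )["CD45"].p
        assert pe + pd_ == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_differences_degenerate(self):
        rows = []
        for s in range(5):
            rows.append(
                pd.DataFrame(
                    {
                        "slide_id": f"s{s}",
                        "PD1": [True] * 4 + [False] * 4,
                        "PDL1": [True] * 4 + [False] * 4,
                        "CD45": [True, False] * 4,
                    }
                )
            )
        res = interaction_enrichment(
            pd.concat(rows, ignore_index=True), ("PD1", "PDL1"), ("CD45",)
        )["CD45"]
        assert res.degenerate and res.p is None

    def test_slides_without_interactions_dropped_then_error(self):
        calls = self._planted(seed=2, n_slides=3)
        calls.loc[calls["slide_id"] != "s0", ["PD1"]] = False
        with pytest.raises(ValueError, match=">= 3 slides"):
            interaction_enrichment(calls, ("PD1", "PDL1"), ("CD45",))

    def test_reported_proportions_match_hand_computation(self):
        calls = self._planted(seed=3, n_slides=3)
        res = interaction_enrichment(
            calls, ("PD1", "PDL1"), ("CD45",), min_slides=3
        )["CD45"]
        sub = calls[calls["slide_id"] == "s0"]
        inter = sub["PD1"] & sub["PDL1"]
        assert res.per_slide_interacting["s0"] == pytest.approx(
            sub["CD45"][inter].mean()
        )
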