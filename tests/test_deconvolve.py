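import numpy as np
import pytest

from exoalign.deconvolve import (
    CrosslinkMatrix,
    EMConfig,
    EMTrace,
    TagDistributionModel,
    compare_conditions,
    em_fit,
    quantify,
    tag_likelihood,
)
from exoalign.synthgen import sample_composite

MODEL = TagDistributionModel()


class TestTagLikelihood:
    def test_plus_strand_mode_at_mu_minus_six(self):
        mu, L = 100, 200
        peak = tag_likelihood((mu - 6, "+"), mu, MODEL, L)
        for delta in (1, 2, 5, 10):
            assert peak > tag_likelihood((mu - 6 + delta, "+"), mu, MODEL, L)
            assert peak > tag_likelihood((mu - 6 - delta, "+"), mu, MODEL, L)

    def test_symmetry_about_strand_mode(self):
        mu, L = 100, 200
        for delta in (1, 3, 7):
            assert tag_likelihood((mu - 6 + delta, "+"), mu, MODEL, L) == pytest.approx(
                tag_likelihood((mu - 6 - delta, "+"), mu, MODEL, L)
            )

    def test_strand_mirror(self):
        mu, L = 90, 200
        for col in (70, 84, 96, 110):
            assert tag_likelihood((col, "+"), mu, MODEL, L) == pytest.approx(
                tag_likelihood((2 * mu - col, "-"), mu, MODEL, L)
            )

    def test_normalised_over_span(self):
        L = 150
        p = MODEL.prob_grid(L, np.array([75]), 0)
        assert p.sum() == pytest.approx(1.0)


class TestEmFit:
    def test_single_crosslink_recovered(self, rng):
        w = {"a": sample_composite(rng, 250, [100], [1.0], 1000)}
        comps = em_fit(w, EMConfig(alpha=20))
        assert len(comps) == 1
        assert abs(comps[0].mu - 100) <= 2
        assert comps[0].pi["a"] == pytest.approx(1.0)

    def test_two_crosslinks_30bp_apart(self, rng):
        w = {"a": sample_composite(rng, 250, [100, 130], [0.5, 0.5], 1000)}
        comps = em_fit(w, EMConfig(alpha=20))
        assert len(comps) == 2
        for c in comps:
            assert 0.4 <= c.pi["a"] <= 0.6
        assert abs(comps[0].mu - 100) <= 2 and abs(comps[1].mu - 130) <= 2

    def test_alpha_zero_is_maximum_likelihood(self, rng):
        w = {"a": sample_composite(rng, 200, [80, 120], [0.6, 0.4], 800)}
        comps = em_fit(w, EMConfig(alpha=0.0))
        # no truncation: every surviving component keeps positive weight and
        # weights stay on the simplex
        assert all(c.pi["a"] > 0 for c in comps)
        assert sum(c.pi["a"] for c in comps) == pytest.approx(1.0, abs=1e-9)
        # weights equal the relative responsibility masses (pure ML update)
        # (pi comes from the final M-step, N from one further E-step, so the
        # two agree only up to the convergence tolerance scale)
        total = sum(c.N["a"] for c in comps)
        for c in comps:
            assert c.pi["a"] == pytest.approx(c.N["a"] / total, abs=1e-3)

    def test_pi_sums_to_one_every_iteration(self, rng):
        w = {
            "a": sample_composite(rng, 200, [60, 140], [0.7, 0.3], 600),
            "b": sample_composite(rng, 200, [60, 140], [0.2, 0.8], 600),
        }
        trace = EMTrace()
        em_fit(w, EMConfig(alpha=10), trace=trace)
        assert trace.iterations
        for it in trace.iterations:
            for s in it["pi_sums"]:
                assert s == pytest.approx(1.0, abs=1e-9)

    def test_log_posterior_nondecreasing_at_fixed_active_set(self, rng):
        w = {
            "a": sample_composite(rng, 200, [60, 140], [0.7, 0.3], 600),
            "b": sample_composite(rng, 200, [60, 140], [0.2, 0.8], 600),
        }
        trace = EMTrace()
        em_fit(w, EMConfig(alpha=10), trace=trace)
        its = trace.iterations
        for prev, cur in zip(its, its[1:]):
            if prev["mus"] == cur["mus"] and prev["support"] == cur["support"]:
                assert cur["logpost"] >= prev["logpost"] - 1e-6 * abs(prev["logpost"])

    def test_alpha_monotonicity(self, rng):
        w = {"a": sample_composite(rng, 300, [80, 150, 220], [0.5, 0.3, 0.2], 900,
                                   background_rate=0.2)}
        counts = []
        for alpha in (0.0, 5.0, 20.0, 80.0, 200.0):
            counts.append(len(em_fit(w, EMConfig(alpha=alpha))))
        assert counts == sorted(counts, reverse=True)

    def test_all_eliminated_keeps_best_component(self, rng):
        w = {"a": sample_composite(rng, 150, [70], [1.0], 30)}
        comps = em_fit(w, EMConfig(alpha=1e6))
        assert len(comps) == 1
        assert abs(comps[0].mu - 70) <= 5

    def test_positions_shared_across_experiments(self, rng):
        # a shallow experiment (below alpha) cannot anchor its own component;
        # its tags are quantified at the position anchored by the deep one
        w = {
            "a": sample_composite(rng, 200, [100], [1.0], 800),
            "b": sample_composite(rng, 200, [103], [1.0], 10),
        }
        comps = em_fit(w, EMConfig(alpha=15))
        assert len(comps) == 1
        assert abs(comps[0].mu - 100) <= 2
        m = quantify(comps, w)
        assert m.normalized[m.experiments.index("b"), 0] == pytest.approx(1.0)

    def test_no_tags_fatal(self):
        with pytest.raises(ValueError, match="no tags"):
            em_fit({"a": np.zeros((2, 100))}, EMConfig())


class TestQuantify:
    def test_single_component_row_is_one(self, rng):
        w = {"a": sample_composite(rng, 200, [100], [1.0], 500)}
        comps = em_fit(w, EMConfig(alpha=20))
        m = quantify(comps, w)
        assert m.normalized.shape == (1, 1)
        assert m.normalized[0, 0] == pytest.approx(1.0)

    def test_distant_experiment_gets_no_strength(self, rng):
        w = {
            "near": sample_composite(rng, 400, [100, 300], [0.5, 0.5], 800),
            "far": sample_composite(rng, 400, [300], [1.0], 800),
        }
        comps = em_fit(w, EMConfig(alpha=20))
        m = quantify(comps, w)
        j100 = m.positions.index(min(m.positions, key=lambda p: abs(p - 100)))
        assert m.normalized[m.experiments.index("far"), j100] < 0.01

    def test_three_protein_recovery(self, rng):
        truth = {"A": [0.8, 0.2], "B": [0.2, 0.8], "C": [0.5, 0.5]}
        w = {k: sample_composite(rng, 300, [120, 180], v, 1500) for k, v in truth.items()}
        comps = em_fit(w, EMConfig(alpha=30))
        m = quantify(comps, w)
        assert len(m.positions) == 2
        for name, expect in truth.items():
            row = m.normalized[m.experiments.index(name)]
            assert np.allclose(row, expect, atol=0.05)

    def test_zero_tag_experiment_flagged(self, rng):
        w = {
            "a": sample_composite(rng, 200, [100], [1.0], 500),
            "empty": np.zeros((2, 200)),
        }
        comps = em_fit(w, EMConfig(alpha=20))
        m = quantify(comps, w)
        assert "empty" in m.zero_rows
        assert m.normalized[m.experiments.index("empty")].sum() == 0

    def test_raw_strengths_conserve_tags(self, rng):
        w = {"a": sample_composite(rng, 200, [90, 140], [0.5, 0.5], 600)}
        comps = em_fit(w, EMConfig(alpha=20))
        m = quantify(comps, w)
        assert m.raw.sum() == pytest.approx(w["a"].sum())


class TestCompareConditions:
    def make_matrix(self, norm):
        norm = np.asarray(norm, dtype=float)
        return CrosslinkMatrix(
            experiments=[f"e{i}" for i in range(norm.shape[0])],
            positions=list(range(norm.shape[1])),
            raw=norm.copy(),
            normalized=norm,
        )

    def test_identical_matrices_give_zero(self):
        m = self.make_matrix([[0.7, 0.3], [0.4, 0.6]])
        fold = compare_conditions(m, m)
        assert np.allclose(fold.to_numpy(), 0.0)

    def test_shift_produces_opposite_signs(self):
        m1 = self.make_matrix([[0.8, 0.2]])
        m2 = self.make_matrix([[0.4, 0.6]])
        fold = compare_conditions(m1, m2).to_numpy()
        assert fold[0, 0] < 0 < fold[0, 1]

    def test_mismatched_positions_fatal(self):
        m1 = self.make_matrix([[1.0]])
        m2 = self.make_matrix([[0.5, 0.5]])
        with pytest.raises(ValueError, match="positions"):
            compare_conditions(m1, m2)
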