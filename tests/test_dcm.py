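import numpy as np
import pytest

from attnflow.containers import ALL_VISUAL, build_block_design
from attnflow.dcm import (
    DCMPriors,
    DCMSpec,
    HemoParams,
    NeuralParams,
    effective_strength,
    fit_dcm,
    integrate_dcm,
    posterior_edge_test,
)
from attnflow.synthetic import (
    NoiseSpec,
    default_neural_truth,
    noise_sd_for_snr,
    simulate_dcm_bold,
    standard_design,
)


def _single_region_spec():
    return DCMSpec(
        regions=("r",),
        a_mask=np.zeros((1, 1), bool),
        b_masks={},
        c_masks={"Same": np.ones(1, bool)},
    )


def _two_region_spec():
    a = np.array([[False, False], [True, False]])  # coupling r1 -> r2
    return DCMSpec(
        regions=("r1", "r2"),
        a_mask=a,
        b_masks={},
        c_masks={"Same": np.array([True, False])},
    )


class TestIntegrate:
    def test_silent_input_gives_zero_output(self, gen_spec, hemo):
        design = build_block_design(0, 16, 12, [], tr=2.0, microtime_bins=8)
        # pad the run to a nonzero length with no events
        design = build_block_design(1, 0.125, 27.875, ["Same"], tr=2.0,
                                    microtime_bins=16)
        n = gen_spec.n_regions
        neural = NeuralParams(
            -0.5 * np.eye(n),
            {"Same": np.zeros((n, n))},
            {ALL_VISUAL: np.zeros(n)},  # C = 0: input never enters
        )
        ts = integrate_dcm(gen_spec, neural, hemo, design)
        assert np.allclose(ts.data, 0.0, atol=1e-12)

    def test_impulse_response_peaks_4_to_7_s(self, hemo):
        spec = _single_region_spec()
        design = build_block_design(1, 0.5, 39.5, ["Same"], tr=0.5,
                                    microtime_bins=16)
        neural = NeuralParams(np.array([[-0.5]]), {}, {"Same": np.array([1.0])})
        ts = integrate_dcm(spec, neural, hemo, design)
        t_peak = ts.times[np.argmax(ts.data[0])]
        assert 4.0 <= t_peak <= 7.0

    def test_downstream_region_peaks_later(self, hemo):
        spec = _two_region_spec()
        design = build_block_design(1, 1.0, 39.0, ["Same"], tr=0.5,
                                    microtime_bins=16)
        A = np.array([[-0.5, 0.0], [0.4, -0.5]])
        neural = NeuralParams(A, {}, {"Same": np.array([1.0, 0.0])})
        ts = integrate_dcm(spec, neural, hemo, design)
        assert ts.times[np.argmax(ts.data[1])] > ts.times[np.argmax(ts.data[0])]

    def test_near_linear_regime_halving_c_halves_peak(self, hemo):
        spec = _single_region_spec()
        design = build_block_design(1, 2.0, 38.0, ["Same"], tr=0.5,
                                    microtime_bins=16)
        peaks = []
        for c in (0.02, 0.01):
            neural = NeuralParams(np.array([[-0.5]]), {}, {"Same": np.array([c])})
            peaks.append(integrate_dcm(spec, neural, hemo, design).data.max())
        assert peaks[0] / peaks[1] == pytest.approx(2.0, rel=0.05)

    def test_refining_microtime_changes_output_below_1pc_rms(
        self, gen_spec, truth_params, hemo
    ):
        coarse = integrate_dcm(gen_spec, truth_params, hemo,
                               standard_design(microtime_bins=16))
        fine = integrate_dcm(gen_spec, truth_params, hemo,
                             standard_design(microtime_bins=32))
        rms = np.sqrt(np.mean((coarse.data - fine.data) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(fine.data**2))

    def test_divergence_raises_with_region_name(self, hemo):
        spec = _single_region_spec()
        design = build_block_design(1, 16.0, 12.0, ["Same"], tr=2.0,
                                    microtime_bins=16)
        neural = NeuralParams.__new__(NeuralParams)  # bypass diag check
        object.__setattr__(neural, "A", np.array([[0.8]]))
        object.__setattr__(neural, "B", {})
        object.__setattr__(neural, "C", {"Same": np.array([5.0])})
        from attnflow.dcm import IntegrationDivergedError

        with pytest.raises(IntegrationDivergedError):
            integrate_dcm(spec, neural, hemo, design)

    def test_params_outside_masks_rejected(self, gen_spec, hemo, fast_design):
        n = gen_spec.n_regions
        bad_b = {"Same": np.ones((n, n))}
        neural = NeuralParams(-0.5 * np.eye(n), bad_b, {ALL_VISUAL: np.ones(n)})
        with pytest.raises(ValueError):
            integrate_dcm(gen_spec, neural, hemo, fast_design)


class TestSimulateVsIntegrate:
    def test_noiseless_simulation_equals_forward_model_exactly(
        self, gen_spec, truth_params, hemo, fast_design
    ):
        clean = integrate_dcm(gen_spec, truth_params, hemo, fast_design)
        sim = simulate_dcm_bold(gen_spec, truth_params, hemo, fast_design,
                                NoiseSpec(sd=0.0), seed=0)
        assert np.array_equal(sim.data, 100.0 + clean.data)

    def test_no_input_rests_at_baseline(self, hemo):
        spec = _single_region_spec()
        design = build_block_design(2, 8.0, 8.0, ["Same", "Same"], tr=2.0,
                                    microtime_bins=8)
        neural = NeuralParams(np.array([[-0.5]]), {}, {"Same": np.array([0.0])})
        sim = simulate_dcm_bold(spec, neural, hemo, design, NoiseSpec(0.0), seed=0)
        assert np.allclose(sim.data, 100.0)

    def test_unstable_dynamics_flagged_not_raised(self, hemo):
        spec = DCMSpec(
            regions=("a", "b"),
            a_mask=np.array([[False, True], [True, False]]),
            b_masks={},
            c_masks={"Same": np.array([True, False])},
        )
        A = np.array([[-0.1, 0.5], [0.5, -0.1]])  # positive eigenvalue
        neural = NeuralParams(A, {}, {"Same": np.array([0.001, 0.0])})
        design = build_block_design(1, 2.0, 26.0, ["Same"], tr=2.0,
                                    microtime_bins=8)
        sim = simulate_dcm_bold(spec, neural, hemo, design, NoiseSpec(0.0), seed=0)
        assert sim.meta.get("unstable_A") is True


class TestFitDcm:
    def test_zero_variance_prior_clamps_parameter(self, gen_spec, truth_params,
                                                  hemo, fast_design):
        sim = simulate_dcm_bold(gen_spec, truth_params, hemo, fast_design,
                                NoiseSpec(sd=1.0), seed=2)
        label = "b:Same:IFJ->IMT+"
        priors = DCMPriors(overrides={label: (0.1, 0.0)})
        fit = fit_dcm(sim.copy_with(sim.data - 100.0), gen_spec, fast_design,
                      priors=priors, options={"max_iter": 8})
        assert fit.posterior_mean(label) == 0.1
        assert fit.posterior_sd(label) == 0.0

    def test_high_snr_recovery_of_modulatory_weight(self, gen_spec, hemo,
                                                    fast_design):
        """b = 0.4 Hz recovered within +-0.2 Hz from one high-SNR subject."""
        truth = default_neural_truth(gen_spec, b_value=0.4)
        clean = simulate_dcm_bold(gen_spec, truth, hemo, fast_design,
                                  NoiseSpec(sd=0.0), seed=0)
        sd = noise_sd_for_snr(clean.copy_with(clean.data - 100.0), 4.0)
        sim = simulate_dcm_bold(gen_spec, truth, hemo, fast_design,
                                NoiseSpec(sd=sd), seed=5)
        fit = fit_dcm(sim.copy_with(sim.data - 100.0), gen_spec, fast_design)
        b_hat = fit.modulatory_mean("Same", ("IFJ", "IMT+"))
        assert abs(b_hat - 0.4) <= 0.2
        assert fit.converged
        # free energy is finite and the trace ends near its maximum
        assert np.isfinite(fit.free_energy)

    def test_generating_model_beats_pruned_model_on_strong_data(
        self, feedback_space, hemo, fast_design
    ):
        """F favors the generating structure over one lacking the true
        modulated edge for most subjects."""
        gen = feedback_space.spec("3")
        wrong = feedback_space.spec("1")  # modulation on IPS instead
        truth = default_neural_truth(gen, b_value=0.6)
        clean = simulate_dcm_bold(gen, truth, hemo, fast_design,
                                  NoiseSpec(0.0), seed=0)
        sd = noise_sd_for_snr(clean.copy_with(clean.data - 100.0), 4.0)
        wins = 0
        n_subj = 5
        for s in range(n_subj):
            sim = simulate_dcm_bold(gen, truth, hemo, fast_design,
                                    NoiseSpec(sd=sd), seed=10 + s)
            d = sim.copy_with(sim.data - 100.0)
            f_gen = fit_dcm(d, gen, fast_design).free_energy
            f_wrong = fit_dcm(d, wrong, fast_design).free_energy
            wins += f_gen > f_wrong
        assert wins >= 4  # >= 80% of subjects

    def test_region_mismatch_rejected(self, gen_spec, fast_design, rng):
        from attnflow.containers import TimeSeriesSet

        ts = TimeSeriesSet(("x", "y"), rng.standard_normal((2, fast_design.n_scans)),
                           2.0)
        with pytest.raises(ValueError):
            fit_dcm(ts, gen_spec, fast_design)


class TestEffectiveStrength:
    def _fit_stub(self, gen_spec):
        from attnflow.dcm import DCMFit, _param_layout

        layout = _param_layout(gen_spec)
        labels = tuple(lb for _, lb, _ in layout)
        theta = np.zeros(len(labels))
        theta[labels.index("a:IFJ->IMT+")] = 0.2
        theta[labels.index("b:Same:IFJ->IMT+")] = 0.3
        return DCMFit(
            spec=gen_spec, param_labels=labels, theta=theta,
            cov=np.eye(len(labels)) * 1e-4, free_energy=0.0,
            sigma2=np.ones(gen_spec.n_regions), predicted=np.zeros((1, 1)),
            converged=True, n_iter=1,
        )

    def test_additivity_of_intrinsic_and_modulatory(self, gen_spec):
        fit = self._fit_stub(gen_spec)
        s = effective_strength(fit, ("IFJ", "IMT+"), "Same")
        assert s == pytest.approx(0.2 + 0.3)

    def test_zero_modulation_equals_intrinsic(self, gen_spec):
        fit = self._fit_stub(gen_spec)
        fit.theta[fit.param_labels.index("b:Same:IFJ->IMT+")] = 0.0
        assert effective_strength(fit, ("IFJ", "IMT+"), "Same") == pytest.approx(0.2)

    def test_absent_edge_rejected(self, gen_spec):
        fit = self._fit_stub(gen_spec)
        with pytest.raises(ValueError):
            effective_strength(fit, ("IFJ", "IFJ"), "Same")

    def test_edge_test_equals_one_sample_t(self, gen_spec):
        fits = []
        for v in (0.1, 0.4, 0.3, 0.2):
            f = self._fit_stub(gen_spec)
            f.theta[f.param_labels.index("b:Same:IFJ->IMT+")] = v
            fits.append(f)
        res = posterior_edge_test(fits, ("IFJ", "IMT+"), "Same")
        from attnflow.stats import one_sample_t

        ref = one_sample_t([0.1, 0.4, 0.3, 0.2])
        assert res.statistic == pytest.approx(ref.statistic)

    def test_all_zero_modulations_give_t_zero(self, gen_spec):
        fits = [self._fit_stub(gen_spec) for _ in range(3)]
        for f in fits:
            f.theta[f.param_labels.index("b:Same:IFJ->IMT+")] = 0.0
        res = posterior_edge_test(fits, ("IFJ", "IMT+"), "Same")
        assert res.statistic == 0.0
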