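"""CRLB machinery and coordinate-descent search: oracle checks and
scaling identities."""

import numpy as np
import pytest

from pcaslopt.kinetics import PerfusionState, casl_signal
from pcaslopt.optimizer import (
    ATTPrior,
    OptimizerConfig,
    expected_cbf_sd,
    fisher_information,
    optimize_protocol,
    protocol_cost,
)
from pcaslopt.protocols import ProtocolSpec, timepoint_arrays
from pcaslopt.simulator import NoiseModel, simulate
from pcaslopt.inference import fit_dataset

TOY = ProtocolSpec("seq_multi_ld", [1.0, 1.2, 1.4], [0.3, 0.8, 1.3])


class TestAttPrior:
    def test_taper_and_normalization(self):
        prior = ATTPrior()
        x, w = prior.grid, prior.weights
        assert x[0] == pytest.approx(0.2) and x[-1] == pytest.approx(2.3)
        assert w.sum() == pytest.approx(1.0)
        core = (x >= 0.5) & (x <= 2.0)
        assert np.allclose(w[core], w[core][0])  # flat core
        assert w[0] == 0.0 and w[-1] == 0.0
        # linear ramp halfway up the taper
        i = np.argmin(np.abs(x - 0.35))
        assert w[i] / w[core][0] == pytest.approx(0.5, abs=0.01)


class TestFisherInformation:
    def test_singular_beyond_all_timepoints(self, params):
        lds, plds, _ = timepoint_arrays(TOY)
        late = float((lds + plds).max()) + 0.1
        f = fisher_information(TOY, PerfusionState(50.0, late), params)
        assert np.allclose(f, 0.0)

    def test_noise_scaling(self, params):
        s = PerfusionState(50.0, 1.0)
        f1 = fisher_information(TOY, s, params)
        f2 = fisher_information(TOY, s, params.with_noise(2 * params.noise_sd))
        assert np.allclose(f2, f1 / 4.0)

    def test_matches_numerical_jacobian(self, params):
        """Independent oracle: assemble F from finite-difference Jacobians."""
        s = PerfusionState(50.0, 1.0)
        lds, plds, scales = timepoint_arrays(TOY)
        h = 1e-6
        jc = (casl_signal(s.cbf + h, s.att, lds, plds, params)
              - casl_signal(s.cbf - h, s.att, lds, plds, params)) / (2 * h)
        ja = (casl_signal(s.cbf, s.att + h, lds, plds, params)
              - casl_signal(s.cbf, s.att - h, lds, plds, params)) / (2 * h)
        j = np.stack([jc, ja], axis=1)
        w = np.diag(1.0 / (params.noise_sd * scales) ** 2)
        expected = j.T @ w @ j
        got = fisher_information(TOY, s, params)
        assert np.allclose(got, expected, rtol=1e-4)


class TestExpectedCbfSd:
    def test_single_pld_flat_across_att(self, protocols):
        att = np.linspace(0.5, 2.0, 31)
        sd = expected_cbf_sd(protocols["single_pld"], att)
        assert np.allclose(sd, sd[0])

    def test_scan_time_scaling(self, protocols):
        p = protocols["seq_single_ld"]
        full = expected_cbf_sd(p, 1.0, OptimizerConfig(scan_time=300))
        half = expected_cbf_sd(p, 1.0, OptimizerConfig(scan_time=150))
        assert half == pytest.approx(np.sqrt(2) * full, rel=1e-12)

    def test_matches_monte_carlo_fit_sd(self, params):
        """Asymptotic CRLB attainment: the sample SD of high-SNR fits of one
        average matches the predicted SD within 5%."""
        p = ProtocolSpec("seq_multi_ld", [1.8, 1.8], [0.6, 1.6])
        noise = NoiseModel(sigma0=1.3e-4)  # high SNR keeps the fit linear
        quiet = params.with_noise(noise.sigma0)
        ds = simulate(p, 50.0, np.array([1.0]), noise, replicas=10_000, seed=5)
        fits = fit_dataset(ds, params=quiet)
        cfg = OptimizerConfig()
        one_ave = 300.0 / (2 * (1.8 + 0.6 + 0.638) + 2 * (1.8 + 1.6 + 0.638))
        predicted = expected_cbf_sd(p, 1.0, cfg, quiet) * np.sqrt(one_ave)
        assert np.std(fits.cbf_mean) == pytest.approx(predicted, rel=0.05)


class TestProtocolCost:
    def test_uniform_weights_reduce_to_plain_mean(self, params):
        prior = ATTPrior(att_min=0.5, att_max=2.0, step=0.01, taper=0.0)
        cost = protocol_cost(TOY, prior, params=params)
        var = expected_cbf_sd(TOY, prior.grid, params=params) ** 2
        assert cost == pytest.approx(var.mean(), rel=1e-12)

    def test_linear_in_noise_variance(self, params):
        # prior restricted to the well-conditioned range so the singular cap
        # never binds and the pure scaling identity is visible
        prior = ATTPrior(att_min=0.5, att_max=1.5, step=0.01, taper=0.0)
        c1 = protocol_cost(TOY, prior, params=params)
        c2 = protocol_cost(TOY, prior,
                           params=params.with_noise(3 * params.noise_sd))
        assert c2 == pytest.approx(9 * c1, rel=1e-6)

    def test_decimated_grid_agreement(self, protocols, params):
        # a densely sampled protocol keeps the integrand smooth, so a 10x
        # coarser ATT grid changes the cost negligibly
        p = protocols["seq_single_ld"]
        c_fine = protocol_cost(p, ATTPrior(step=0.001), params=params)
        c_coarse = protocol_cost(p, ATTPrior(step=0.010), params=params)
        assert c_coarse == pytest.approx(c_fine, rel=0.005)

    def test_all_singular_is_infinite_with_warning(self, params):
        p = ProtocolSpec("seq_single_ld", [0.2], [0.075])  # ld+pld < all ATTs
        prior = ATTPrior(att_min=1.0, att_max=2.0, taper=0.0, step=0.01)
        with pytest.warns(RuntimeWarning):
            assert protocol_cost(p, prior, params=params) == np.inf


COARSE = OptimizerConfig(pld_min=0.1, pld_max=2.3, pld_step=0.1,
                         ld_step=0.1, nt_max=2)
COARSE_PRIOR = ATTPrior(step=0.005)


class TestOptimizeProtocol:
    def test_trace_non_increasing(self):
        res = optimize_protocol("seq_single_ld", COARSE, COARSE_PRIOR, seed=0)
        trace = np.array(res.trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_exhaustive_equivalence_two_plds(self, params):
        """Coordinate descent equals brute force on the coarsened 2-PLD
        problem."""
        res = optimize_protocol("seq_single_ld", COARSE, COARSE_PRIOR,
                                params, seed=0)
        best = (np.inf, None)
        grid = COARSE.pld_grid
        for i, p1 in enumerate(grid):
            for p2 in grid[i:]:
                spec = ProtocolSpec("seq_single_ld", [COARSE.ld_max],
                                    [float(p1), float(p2)])
                c = protocol_cost(spec, COARSE_PRIOR, COARSE, params)
                if c < best[0]:
                    best = (c, (float(p1), float(p2)))
        assert res.cost == pytest.approx(best[0], rel=1e-9)
        if len(res.spec.plds) == 2:
            assert tuple(res.spec.plds) == pytest.approx(best[1])

    def test_emitted_timings_on_grid_and_in_bounds(self):
        res = optimize_protocol("had_t1adj",
                                OptimizerConfig(pld_step=0.1, ld_step=0.1,
                                                encoding_sizes=(3,)),
                                ATTPrior(step=0.01), seed=0)
        lds, plds, _ = timepoint_arrays(res.spec)
        assert np.all(plds >= 0.075 - 1e-9)
        assert float(min(res.spec.lds)) >= 0.1 - 1e-9
        assert float(max(res.spec.lds)) <= 1.8 + 1e-9
        # final PLD lands on its grid
        final = float(res.spec.plds[0])
        assert np.min(np.abs(OptimizerConfig(pld_step=0.1).pld_grid - final)) < 1e-9

    def test_longer_scan_never_costs_more(self):
        short = optimize_protocol(
            "seq_single_ld",
            OptimizerConfig(pld_step=0.2, nt_max=2, scan_time=300),
            COARSE_PRIOR, seed=0)
        long = optimize_protocol(
            "seq_single_ld",
            OptimizerConfig(pld_step=0.2, nt_max=2, scan_time=600),
            COARSE_PRIOR, seed=0)
        assert long.cost <= short.cost + 1e-12
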