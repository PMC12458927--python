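"""Two-state HMM segmentation and dwell-time summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from burstlab.hmm import (
    BurstHMM,
    StateSequence,
    dwell_cdf,
    extract_dwells,
    fit_hmm,
)


class TestFit:
    def test_noiseless_two_level_trace_is_decoded_exactly(self):
        rng = np.random.default_rng(0)
        states = (rng.random(400) < 0.3).astype(int)
        trace = np.where(states == 1, 10.0, 2.0) + rng.normal(0, 1e-3, 400)
        m = BurstHMM(random_state=0).fit([trace])
        assert m.means_[0] == pytest.approx(2.0, abs=0.01)
        assert m.means_[1] == pytest.approx(10.0, abs=0.01)
        assert np.array_equal(m.predict(trace), states)

    def test_active_is_always_the_higher_mean_state(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            states = (rng.random(300) < 0.5).astype(int)
            trace = states * 8.0 + rng.normal(0, 0.5, 300)
            m = BurstHMM(random_state=seed, init="kmeans").fit([trace])
            assert m.means_[1] > m.means_[0]

    def test_zero_variance_traces_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_hmm([np.full(50, 3.0)])

    def test_transition_dwells_recover_sampled_chain_kinetics(self, telegraph_traces):
        """Fitted transitions match the telegraph chain observed at the frame interval.

        Sampling a continuous-time two-state process every dt produces the
        discrete chain P = expm(Q dt); dwells shorter than dt are invisible,
        so apparent mean dwells follow P, not 1/k directly.
        """
        from scipy.linalg import expm

        table, traces, params = telegraph_traces
        m = BurstHMM(random_state=0).fit(table)
        dwells = m.mean_dwell_minutes(dt=params.dt)
        q = np.array([[-params.k_on, params.k_on], [params.k_off, -params.k_off]])
        p = expm(q * params.dt / 60.0)
        expect_inactive = 1 / (1 - p[0, 0]) * params.dt / 60.0
        expect_active = 1 / (1 - p[1, 1]) * params.dt / 60.0
        assert dwells["active"] == pytest.approx(expect_active, rel=0.10)
        assert dwells["inactive"] == pytest.approx(expect_inactive, rel=0.10)

    def test_fit_reproducible_for_fixed_seed(self, telegraph_traces):
        table, _, _ = telegraph_traces
        m1 = BurstHMM(random_state=3).fit(table)
        m2 = BurstHMM(random_state=3).fit(table)
        assert np.allclose(m1.means_, m2.means_)
        assert np.allclose(m1.transmat_, m2.transmat_)


def brute_force_viterbi(trace, means, sds, transmat, startprob):
    """Exhaustive maximum-probability path over all 2^n state sequences."""
    n = len(trace)
    best_lp, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=n):
        lp = np.log(startprob[path[0]])
        for t in range(n):
            s = path[t]
            lp += -0.5 * ((trace[t] - means[s]) / sds[s]) ** 2 - np.log(sds[s])
            if t:
                lp += np.log(transmat[path[t - 1], s])
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


class TestDecode:
    def test_all_low_trace_is_all_inactive(self):
        rng = np.random.default_rng(2)
        train = np.concatenate([np.zeros(100), np.full(100, 5.0)]) + rng.normal(0, 0.1, 200)
        m = BurstHMM(random_state=0).fit([train])
        low = rng.normal(0, 0.1, 50)
        assert not m.predict(low).any()

    def test_viterbi_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(3)
        train = np.concatenate([np.zeros(150), np.full(150, 5.0)]) + rng.normal(0, 0.4, 300)
        m = BurstHMM(random_state=0).fit([train])
        trace = np.array([0.1, 4.9, 0.2, 5.1, -0.1, 5.0, 0.0, 4.8])
        expected = brute_force_viterbi(trace, m.means_, m.sds_, m.transmat_, m.startprob_)
        assert np.array_equal(m.predict(trace), expected)

    def test_posteriors_normalize_and_track_states(self):
        rng = np.random.default_rng(4)
        # alternating blocks so both transition directions are represented
        train = np.tile(np.r_[np.zeros(20), np.full(20, 6.0)], 10) + rng.normal(0, 0.3, 400)
        m = BurstHMM(random_state=0).fit([train])
        seq = m.decode(np.array([0.0, 6.0, 6.0, 0.0]))
        assert np.all((seq.posterior_active >= 0) & (seq.posterior_active <= 1))
        assert np.allclose(seq.posterior_active[[1, 2]], 1.0, atol=1e-3)
        assert np.allclose(seq.posterior_active[[0, 3]], 0.0, atol=1e-3)

    def test_decoding_invariant_to_affine_rescaling_when_refit(self, telegraph_traces):
        table, traces, _ = telegraph_traces
        arrays = [tr.intensity for tr in traces[:10]]
        m1 = BurstHMM(random_state=0).fit(arrays)
        scaled = [3.0 * a + 50.0 for a in arrays]
        m2 = BurstHMM(random_state=0).fit(scaled)
        for a, b in zip(arrays, scaled):
            assert np.array_equal(m1.predict(a), m2.predict(b))


class TestDwells:
    def test_interior_active_run_in_minutes(self):
        s = np.array([0, 1, 1, 1, 1, 0])
        d = extract_dwells(s, dt=100.0)
        assert len(d.active_dwells) == 1
        # 4 frames x 100 s = 400 s = 6.67 min
        assert d.active_dwells[0] == pytest.approx(400 / 60)
        assert d.n_censored_excluded == 2  # both boundary OFF runs

    def test_boundary_runs_are_censored(self):
        d = extract_dwells(np.array([1, 1, 0, 0, 1, 1]), dt=100.0)
        assert len(d.active_dwells) == 0
        assert len(d.inactive_dwells) == 1
        assert d.n_censored_excluded == 2

    def test_constant_trace_contributes_only_censored_runs(self):
        d = extract_dwells(np.ones(10, dtype=int), dt=100.0)
        assert d.n_censored_excluded == 1
        assert len(d.active_dwells) == len(d.inactive_dwells) == 0

    def test_run_lengths_conserve_total_frames(self, telegraph_traces):
        _, traces, _ = telegraph_traces
        from burstlab.hmm import _runs

        for tr in traces[:10]:
            runs = _runs(tr.states)
            assert sum(length for _, _, length in runs) == len(tr.states)

    def test_decoded_dwell_medians_track_truth(self, telegraph_traces):
        table, traces, params = telegraph_traces
        m = BurstHMM(random_state=0).fit(table)
        decoded = [m.decode(tr.intensity) for tr in traces]
        est = extract_dwells(decoded, dt=params.dt)
        truth = extract_dwells([tr.states for tr in traces], dt=params.dt)
        assert est.median_active == pytest.approx(truth.median_active, rel=0.10)
        assert est.median_inactive == pytest.approx(truth.median_inactive, rel=0.10)


class TestDwellCdf:
    def test_single_dwell_step(self):
        cdf = dwell_cdf([5.0])
        assert list(cdf["duration_min"]) == [5.0]
        assert list(cdf["cdf"]) == [1.0]

    def test_counting(self):
        cdf = dwell_cdf([2.0, 4.0, 4.0, 8.0])
        at4 = cdf.loc[cdf["duration_min"] == 4.0, "cdf"].item()
        assert at4 == pytest.approx(0.75)

    def test_exponential_sample_matches_closed_form(self):
        rng = np.random.default_rng(5)
        scale = 6.67
        sample = rng.exponential(scale, 10_000)
        cdf = dwell_cdf(sample)
        theory = 1 - np.exp(-cdf["duration_min"] / scale)
        assert np.max(np.abs(cdf["cdf"] - theory)) < 0.02

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            dwell_cdf([])
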