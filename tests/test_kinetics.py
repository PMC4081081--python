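import numpy as np
import pytest
from scipy import stats

from gqfold.kinetics import (
    DwellRecord,
    FlowOnsetError,
    StatePath,
    assign_states,
    collect_dwells,
    detect_flow_onset,
    estimate_rates,
    initial_folding_rate,
)
from gqfold.registry import get_params
from gqfold.simulate import (
    _gillespie,
    ctmc_equilibrium,
    simulate_flow_experiment,
    simulate_population,
)
from gqfold.traces import FretSeries, Trace, compute_fret, select_window

CENTERS = {"UF": 0.25, "P": 0.55, "AP": 0.75}


def _series(values, dt=0.1):
    values = np.asarray(values, float)
    return FretSeries("m0", dt, values, np.ones(values.size, bool),
                      window=(0, values.size))


class TestAssignStates:
    def test_constant_parallel(self):
        path = assign_states(_series(np.full(50, 0.55)), CENTERS)
        assert (path.states == 1).all()

    def test_staircase(self):
        values = np.concatenate([np.full(10, 0.25), np.full(10, 0.55), np.full(10, 0.75)])
        path = assign_states(_series(values), CENTERS)
        assert (path.states[:10] == 0).all()
        assert (path.states[10:20] == 1).all()
        assert (path.states[20:] == 2).all()

    def test_thresholds_at_midpoints(self):
        # 0.40 and 0.65 are the decision boundaries for these centers
        path = assign_states(_series([0.39] * 5 + [0.41] * 5), CENTERS)
        assert (path.states[:5] == 0).all()
        assert (path.states[5:] == 1).all()

    def test_short_sojourn_merged_into_longer_neighbor(self):
        values = np.concatenate([np.full(10, 0.55), np.full(1, 0.75), np.full(4, 0.25)])
        path = assign_states(_series(values), CENTERS, min_dwell=2)
        # the single AP frame joins the 10-frame P dwell, not the 4-frame UF
        assert (path.states[:11] == 1).all()
        assert (path.states[11:] == 0).all()

    def test_unordered_centers_rejected(self):
        with pytest.raises(ValueError):
            assign_states(_series([0.5]), {"UF": 0.5, "P": 0.4, "AP": 0.8})

    def test_frame_accuracy_on_noisy_traces(self, params_333):
        traces = simulate_population(params_333, 100, 600, seed=2,
                                     mode="dynamic", bleach_rate=0.005)
        num = den = 0
        for trace in traces:
            series = select_window(trace)
            if series.excluded:
                continue
            path = assign_states(series, params_333.centers)
            lo, hi = series.window
            truth = trace.state_path[lo:hi][series.valid[lo:hi]]
            num += int((path.states == truth).sum())
            den += truth.size
        assert num / den >= 0.95


class TestCollectDwells:
    def test_flanks_censored(self):
        values = np.concatenate([np.full(5, 0.25), np.full(10, 0.55), np.full(5, 0.75)])
        path = assign_states(_series(values), CENTERS)
        dwells = collect_dwells([path])
        completed = [d for d in dwells if not d.censored]
        assert len(completed) == 1
        assert completed[0].state == "P"
        assert completed[0].duration == pytest.approx(1.0)
        assert completed[0].transition == "P_AP"

    def test_single_state_no_completed_dwells(self):
        path = assign_states(_series(np.full(30, 0.55)), CENTERS)
        dwells = collect_dwells([path])
        assert all(d.censored for d in dwells)

    def test_simulated_dwell_mean(self):
        # 2000 completed P dwells at exit rate 0.3/s -> mean 1/0.3 within 3 SE
        rng = np.random.default_rng(31)
        durations = []
        from gqfold.registry import RateMatrix

        rates = RateMatrix(P_AP=0.15, P_U=0.15, AP_P=0.3, AP_U=0.3, U_P=0.3, U_AP=0.3)
        while len(durations) < 2000:
            times, states = _gillespie(rates, 1, 0.0, 2000.0, rng)
            for i in range(1, len(times) - 1):
                if states[i] == 1:
                    durations.append(times[i + 1] - times[i])
        mean = np.mean(durations[:2000])
        se = (1 / 0.3) / np.sqrt(2000)
        assert mean == pytest.approx(1 / 0.3, abs=3 * se)

    def test_censoring_preserves_exponential_law(self):
        # dropping first/last sojourns must not distort the dwell law
        rng = np.random.default_rng(37)
        p = get_params("333")
        q = p.rates.generator()
        dwells = {0: [], 1: [], 2: []}
        for _ in range(60):
            times, states = _gillespie(p.rates, 1, 0.0, 1000.0, rng)
            for i in range(1, len(times) - 1):  # censor flanks
                dwells[states[i]].append(times[i + 1] - times[i])
        for code in (0, 1, 2):
            exit_rate = -q[code, code]
            ks = stats.kstest(dwells[code], "expon", args=(0, 1 / exit_rate))
            assert ks.pvalue > 0.01


class TestEstimateRates:
    def test_even_branch_split(self):
        # all P dwells exactly 2 s, exits half to AP and half to U
        dwells = []
        for i in range(20):
            dwells.append(DwellRecord("P", 2.0, "P_AP" if i % 2 else "P_U", f"m{i}"))
        est = estimate_rates(dwells, dt=0.0)
        assert est.rates["P_AP"].rate == pytest.approx(0.25)
        assert est.rates["P_U"].rate == pytest.approx(0.25)

    def test_insufficient_dwells_reported_missing(self):
        dwells = [DwellRecord("P", 1.0, "P_AP", "m0")] * 3
        est = estimate_rates(dwells, dt=0.1)
        assert "P_AP" not in est.rates
        assert est.missing["P_AP"] == 3

    def test_six_rate_recovery_333(self, params_333):
        # 200 molecules x 600 frames at the generator truth
        traces = simulate_population(params_333, 200, 600, seed=1,
                                     mode="dynamic", bleach_rate=0.005)
        paths = []
        for trace in traces:
            series = select_window(trace)
            if not series.excluded:
                paths.append(assign_states(series, params_333.centers))
        est = estimate_rates(collect_dwells(paths), 0.1)
        truth = params_333.rates.as_dict()
        assert set(est.rates) == set(truth)
        for label, r in est.rates.items():
            assert r.rate == pytest.approx(truth[label], rel=0.15), label

    def test_rates_mostly_in_expected_range(self, params_333):
        # most exchange rates for the dynamic construct lie in 0.1-0.2/s
        traces = simulate_population(params_333, 150, 600, seed=4,
                                     mode="dynamic", bleach_rate=0.005)
        paths = [
            assign_states(select_window(t), params_333.centers)
            for t in traces if not select_window(t).excluded
        ]
        est = estimate_rates(collect_dwells(paths), 0.1)
        in_range = sum(1 for r in est.rates.values() if 0.08 <= r.rate <= 0.22)
        assert in_range >= 4

    def test_equilibrium_consistency(self, params_333):
        traces = simulate_population(params_333, 200, 600, seed=1,
                                     mode="dynamic", bleach_rate=0.005)
        paths = [
            assign_states(select_window(t), params_333.centers)
            for t in traces if not select_window(t).excluded
        ]
        est = estimate_rates(collect_dwells(paths), 0.1)
        eq_est = ctmc_equilibrium(est.as_rate_matrix())
        eq_truth = ctmc_equilibrium(params_333.rates)
        for state in eq_truth:
            assert abs(eq_est[state] - eq_truth[state]) <= 0.05

    def test_dt_half_correction_removes_discretization_bias(self):
        # observed dwell spans are frame counts (ceil), inflating the mean
        # by ~dt/2; 50 replicates at truth 0.15/s
        rate, dt = 0.15, 0.1
        rng = np.random.default_rng(51)
        with_corr, without_corr = [], []
        for _ in range(50):
            true_dwells = rng.exponential(1 / rate, 5000)
            observed = np.ceil(true_dwells / dt) * dt
            dwells = [
                DwellRecord("P", d, "P_AP" if i % 2 else "P_U", "m")
                for i, d in enumerate(observed)
            ]
            est = estimate_rates(dwells, dt=dt)
            with_corr.append(est.rates["P_AP"].rate + est.rates["P_U"].rate)
            est0 = estimate_rates(dwells, dt=0.0)
            without_corr.append(est0.rates["P_AP"].rate + est0.rates["P_U"].rate)
        assert np.mean(with_corr) == pytest.approx(rate, rel=0.05)
        # frame-count durations overestimate the dwell by ~dt/2, so the
        # uncorrected rate is biased LOW by ~dt/2 * rate^2
        bias = rate - np.mean(without_corr)
        assert bias > 0
        assert bias == pytest.approx(dt / 2 * rate**2, rel=0.5)


class TestDetectFlowOnset:
    def test_manifest_onset_returned(self):
        trace = Trace("m0", 0.1, np.full(100, 500.0), np.full(100, 500.0),
                      flow_onset_frame=50)
        assert detect_flow_onset(trace) == 50

    def test_changepoint_fallback(self):
        rng = np.random.default_rng(3)
        acceptor = np.concatenate([np.full(80, 250.0), np.full(120, 550.0)])
        acceptor = acceptor + rng.normal(0, 30, 200)
        donor = 1000.0 - acceptor
        trace = Trace("m0", 0.1, donor, acceptor)
        assert abs(detect_flow_onset(trace) - 80) <= 2

    def test_no_jump_is_error(self):
        rng = np.random.default_rng(4)
        donor = np.full(100, 500.0) + rng.normal(0, 10, 100)
        trace = Trace("m0", 0.1, donor, 1000.0 - donor)
        with pytest.raises(FlowOnsetError):
            detect_flow_onset(trace)


class TestInitialFoldingRate:
    def _flow_trace(self, onset, latency_frames, n=300, first="P"):
        level = 0.55 if first == "P" else 0.75
        e = np.full(n, 0.25)
        e[onset + latency_frames :] = level
        acceptor = 1000.0 * e
        return Trace("m0", 0.1, 1000.0 - acceptor, acceptor,
                     flow_onset_frame=onset)

    def test_uniform_latency(self):
        traces = [self._flow_trace(50, 5) for _ in range(25)]
        result = initial_folding_rate(traces, CENTERS)
        assert result.rate == pytest.approx(2.0)
        assert result.n_censored == 0
        assert result.first_state_tally["P"] == 25

    def test_recovery_133(self):
        p = get_params("133")
        rng = np.random.default_rng(6)
        traces = [
            simulate_flow_experiment(p, 50, 20.0, 0.1, rng, molecule_id=f"m{i}")
            for i in range(200)
        ]
        result = initial_folding_rate(traces, p.centers)
        assert result.rate == pytest.approx(p.initial_folding_rate, rel=0.15)

    def test_433_folds_first_into_antiparallel(self):
        p = get_params("433")
        rng = np.random.default_rng(8)
        traces = [
            simulate_flow_experiment(p, 50, 30.0, 0.1, rng, molecule_id=f"m{i}")
            for i in range(100)
        ]
        result = initial_folding_rate(traces, p.centers)
        total = sum(result.first_state_tally.values())
        assert result.first_state_tally["AP"] / total > 0.90

    def test_censored_molecules_counted(self):
        folded = [self._flow_trace(50, 5) for _ in range(25)]
        never = Trace("never", 0.1, np.full(300, 750.0), np.full(300, 250.0),
                      flow_onset_frame=50)
        result = initial_folding_rate(folded + [never], CENTERS)
        assert result.n_censored == 1
        assert result.n_folded == 25

    def test_too_few_molecules(self):
        traces = [self._flow_trace(50, 5) for _ in range(5)]
        with pytest.raises(ValueError, match="need >="):
            initial_folding_rate(traces, CENTERS)
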