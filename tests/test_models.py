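"""Model-layer tests: closed forms, simulators and their invariants.

Expected numbers marked as oracle values were frozen from high-accuracy
numerical integration of the governing ODEs (independent of the simulator
code paths under test, which are exercised against them here).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoconsort import models as M

GRID = np.linspace(0.0, 12.0, 481)


class TestLightProgram:
    def test_on_time_accounting_is_exact(self):
        prog = M.LightProgram(((0.0, 0.5, 1.0), (1.0, 1.5, 0.5)))
        assert prog.total_on_time() == pytest.approx(0.75)
        assert prog.on_time_between(0.25, 1.25) == pytest.approx(0.375)
        assert prog.u(0.25) == 1.0 and prog.u(0.75) == 0.0

    @pytest.mark.parametrize(
        "segments",
        [
            ((0.0, 0.0, 1.0),),  # empty segment
            ((0.0, 1.0, 1.5),),  # u > 1
            ((0.0, 1.0, 1.0), (0.5, 2.0, 1.0)),  # overlap
            ((-1.0, 1.0, 1.0),),  # negative start
        ],
    )
    def test_invalid_programs_rejected(self, segments):
        with pytest.raises(M.ValidationError):
            M.LightProgram(segments)

    def test_duty_cycle_realization_on_at_cycle_start(self):
        prog = M.LightProgram.from_duty_cycles([0.5, 0.0, 1.0], 2.0, 0.5)
        assert prog.segments == ((2.0, 2.25, 1.0), (3.0, 3.5, 1.0))


class TestClosedForm:
    def test_identity_at_zero_exposure(self):
        assert M.closed_form_fraction(3.3, 0.0, 0.3) == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "k,on_time,f0,expected",
        [
            (1.2, 4.0, 0.0, 0.99177),  # oracle: integration of df=k(1-f)
            (1.2, 0.5, 0.0, 0.45119),  # oracle: one 30-min pulse
            (1.2, 3.0, 0.0, 0.97268),  # oracle: 180-min pulse
        ],
    )
    def test_matches_integration_oracle(self, k, on_time, f0, expected):
        assert M.closed_form_fraction(k, on_time, f0) == pytest.approx(
            expected, abs=1e-5
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": -0.1, "on_time_h": 1.0},
            {"k": 1.0, "on_time_h": -1.0},
            {"k": 1.0, "on_time_h": 1.0, "f0": 1.5},
        ],
    )
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(M.ValidationError):
            M.closed_form_fraction(**kwargs)


class TestDifferentiation:
    def test_dark_program_holds_initial_fraction(self, default_diff):
        tr = M.simulate_differentiation(
            default_diff, M.LightProgram.dark(), 0.2, GRID
        )
        assert np.allclose(tr["f"], 0.2, atol=1e-12)

    def test_split_pulses_equal_single_pulse(self, default_diff):
        # two 2-h pulses 6 h apart behave like one 4-h pulse (no memory)
        prog = M.LightProgram(((0.0, 2.0, 1.0), (8.0, 10.0, 1.0)))
        tr = M.simulate_differentiation(default_diff, prog, 0.0, GRID)
        assert tr["f"][-1] == pytest.approx(
            M.closed_form_fraction(1.2, 4.0), abs=1e-6
        )

    def test_four_hour_pulse_exceeds_99_percent(self, default_diff):
        tr = M.simulate_differentiation(
            default_diff, M.LightProgram.single_pulse(4.0), 0.0, GRID
        )
        assert tr["f"][-1] > 0.99

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        k=st.floats(0.1, 5.0),
        widths=st.lists(st.floats(0.1, 1.5), min_size=1, max_size=4),
        gap=st.floats(0.2, 2.0),
        f0=st.floats(0.0, 0.9),
    )
    def test_memoryless_and_monotone(self, k, widths, gap, f0):
        """Final fraction depends only on total ON time; f never decreases."""
        segs, t = [], 0.0
        for w in widths:
            segs.append((t, t + w, 1.0))
            t += w + gap
        prog = M.LightProgram(tuple(segs))
        grid = np.linspace(0.0, t + 1.0, 200)
        tr = M.simulate_differentiation(M.DiffParams(k=k), prog, f0, grid)
        assert np.all(np.diff(tr["f"]) >= -1e-9)
        assert tr["f"][-1] == pytest.approx(
            M.closed_form_fraction(k, prog.total_on_time(), f0), abs=1e-6
        )

    def test_repeated_pulses_recombine_constant_share_per_pulse(self):
        """Each pulse converts the same share 1 - exp(-k*width) of the
        remaining non-differentiated pool, regardless of prior exposure."""
        k, width = 1.2, 0.5
        segs = tuple((6.0 * i, 6.0 * i + width, 1.0) for i in range(4))
        grid = np.linspace(0.0, 24.0, 2401)
        tr = M.simulate_differentiation(
            M.DiffParams(k=k), M.LightProgram(segs), 0.0, grid
        )
        expected = 1.0 - np.exp(-k * width)
        for i in range(4):
            before = np.interp(6.0 * i, grid, tr["f"])
            after = np.interp(6.0 * i + width, grid, tr["f"])
            share = (after - before) / (1.0 - before)
            assert share == pytest.approx(expected, abs=1e-6)


class TestTwoReactor:
    def test_phi_zero_reduces_to_plain_model(self):
        params = M.TwoReactorParams(phi=0.0)
        tr = M.simulate_two_reactor(params, M.LightProgram.dark(), 0.5, GRID)
        assert np.allclose(tr["f"], 0.5, atol=1e-12)

    def test_steady_state_is_k_over_k_plus_phi(self):
        tr = M.simulate_two_reactor(
            M.TwoReactorParams(),
            M.LightProgram.constant(1.0, 60.0),
            0.0,
            np.linspace(0.0, 60.0, 601),
        )
        assert tr["f"][-1] == pytest.approx(1.2 / 1.4, abs=1e-5)

    def test_dark_decay_half_life(self):
        # with u=0, lam=0 the fraction decays at rate phi: ln2/0.2 = 3.4657 h
        tr = M.simulate_two_reactor(
            M.TwoReactorParams(),
            M.LightProgram.dark(),
            0.8,
            np.linspace(0.0, 3.4657, 100),
        )
        assert tr["f"][-1] == pytest.approx(0.4, abs=1e-4)


class TestGaudi:
    def test_dark_no_leak_is_balanced_turnover(self):
        p = M.GaudiParams(lam=0.0)
        tr = M.simulate_gaudi(
            p, M.LightProgram.dark(), M.GaudiState(1, 0, 0, 0), GRID
        )
        assert np.allclose(tr["n"], 1.0, atol=1e-9)
        assert np.allclose(tr["dilution_rate_per_h"], p.mu, atol=1e-9)

    def test_neutral_limit_recovers_plain_differentiation(self):
        """With no death/escape and arrested cells growing at mu, the live
        differentiated fraction follows the one-parameter model."""
        p = M.GaudiParams(lam=0.0, mu_d=0.4, gamma_x=0.0, gamma_e=0.0)
        prog = M.LightProgram.single_pulse(1.0)
        tr = M.simulate_gaudi(p, prog, M.GaudiState(1, 0, 0, 0), GRID)
        ref = M.simulate_differentiation(
            M.DiffParams(k=p.k, lam=0.0), prog, 0.0, GRID
        )
        assert np.allclose(tr["live_diff_fraction"], ref["f"], atol=1e-7)

    def test_growth_collapses_under_continuous_light(self, default_gaudi):
        tr = M.simulate_gaudi(
            default_gaudi,
            M.LightProgram.constant(1.0, 12.0),
            M.GaudiState(1, 0, 0, 0),
            GRID,
        )
        mask = (tr.time_h >= 8.0) & (tr.time_h <= 12.0)
        assert tr["dilution_rate_per_h"][mask].mean() < 0.04

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        pulse=st.floats(0.2, 3.0),
        n0=st.floats(0.2, 1.0),
        d0=st.floats(0.0, 0.5),
    )
    def test_total_conserved_and_dilution_bounded(
        self, default_gaudi, pulse, n0, d0
    ):
        s0 = M.GaudiState(n0, d0, 0.0, 0.0)
        tr = M.simulate_gaudi(
            default_gaudi,
            M.LightProgram.single_pulse(pulse),
            s0,
            np.linspace(0.0, 20.0, 201),
        )
        assert np.max(np.abs(tr["total"] - s0.total)) / s0.total < 1e-8
        assert tr["dilution_rate_per_h"].min() >= -1e-12
        assert tr["dilution_rate_per_h"].max() <= default_gaudi.mu + 1e-9
        assert min(tr["n"].min(), tr["d"].min(), tr["e"].min(), tr["x"].min()) >= 0


class TestMultiCassette:
    def test_symmetric_rates_give_symmetric_singles(self):
        tr = M.simulate_multicassette(
            M.MultiCassetteParams(1.2, 1.2),
            M.LightProgram.single_pulse(2.0),
            M.MultiCassetteState(),
            GRID,
        )
        assert np.allclose(tr["f_CbarN"], tr["f_CNbar"], atol=1e-9)
        total = tr["f_CN"] + tr["f_CbarN"] + tr["f_CNbar"] + tr["f_CbarNbar"]
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_half_recombined_gives_quarter_fractions(self):
        fr = M.MultiCassetteState(0.5, 0.5).fractions()
        assert all(v == pytest.approx(0.25) for v in fr.values())

    def test_long_light_absorbs_into_double_recombinant(self):
        tr = M.simulate_multicassette(
            M.MultiCassetteParams(),
            M.LightProgram.constant(1.0, 12.0),
            M.MultiCassetteState(),
            GRID,
        )
        assert tr["f_CbarNbar"][-1] > 0.999

    def test_sequential_rates_suppress_slow_only_species(self):
        # kN 5x slower: at the time pC reaches 0.99 the N-only species is
        # (1-0.99)*(1-exp(-0.24*3.838)) ~ 0.0060 (oracle: direct integration)
        t_star = 3.838
        tr = M.simulate_multicassette(
            M.MultiCassetteParams(1.2, 0.24),
            M.LightProgram.constant(1.0, t_star),
            M.MultiCassetteState(),
            np.linspace(0.0, t_star, 200),
        )
        assert tr["f_CNbar"][-1] == pytest.approx(0.0060, abs=2e-4)

    def test_marginal_equals_single_cassette_model(self):
        prog = M.LightProgram(((0.0, 0.5, 1.0), (6.0, 6.5, 1.0)))
        grid = np.linspace(0.0, 10.0, 201)
        tr = M.simulate_multicassette(
            M.MultiCassetteParams(kC=0.7, kN=0.2), prog,
            M.MultiCassetteState(), grid,
        )
        ref = M.simulate_differentiation(
            M.DiffParams(k=0.7, lam=0.0), prog, 0.0, grid
        )
        assert np.allclose(tr["pC"], ref["f"], atol=1e-7)


class TestObservationDelay:
    def test_zero_delay_is_identity(self):
        tr = M.Trajectory(GRID, {"f": np.sin(GRID / 4.0) ** 2})
        out = M.apply_observation_delay(tr, 0.0)
        assert np.allclose(out["f"], tr["f"])

    def test_step_shifts_by_delay(self):
        t = np.linspace(0.0, 4.0, 401)
        step = (t >= 1.0).astype(float)
        out = M.apply_observation_delay(M.Trajectory(t, {"f": step}), 60.0)
        assert out.value_at(1.99, "f") == 0.0
        assert out.value_at(2.01, "f") == 1.0

    def test_constant_unchanged_and_negative_rejected(self):
        tr = M.Trajectory(GRID, {"f": np.full_like(GRID, 0.7)})
        assert np.allclose(M.apply_observation_delay(tr, 500.0)["f"], 0.7)
        with pytest.raises(M.ValidationError):
            M.apply_observation_delay(tr, -1.0)
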