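"""Core reaction system: right-hand side, simulator, and conservation checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radscav.model import (
    DosingScheme,
    ModelConfig,
    RateConstants,
    SpeciesState,
    Trajectory,
    quasi_steady_radical,
    radical_balance_residual,
    rhs,
    simulate,
)

K = RateConstants()


class TestRhs:
    def test_null_state_gives_null_derivatives(self):
        d = rhs(SpeciesState(), K)
        assert all(v == 0.0 for v in d.values())

    def test_aaph_only_generation(self):
        d = rhs(SpeciesState(C_A=10000.0), K)
        assert d["C_A"] == pytest.approx(-1.26e-2)
        assert d["C_R"] == pytest.approx(+2.52e-2)
        assert d["C_C"] == d["C_CM"] == 0.0

    def test_radical_derivative_vanishes_at_quasi_steady_level(self):
        state = SpeciesState(C_A=10000.0, C_R=6.0577e-7)
        d = rhs(state, K)
        # generation 2.52e-2 balances elimination k_el*C_R
        assert abs(d["C_R"]) < 1e-5 * 2.52e-2

    def test_release_rate_feeds_curcumin(self):
        d = rhs(SpeciesState(), K, release_rate=0.5)
        assert d["C_C"] == 0.5

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rhs(SpeciesState(), K, release_rate=-1.0)
        with pytest.raises(ValueError):
            SpeciesState(C_A=-1.0)
        with pytest.raises(ValueError):
            RateConstants(k_C=-5.0)


class TestQuasiSteadyRadical:
    def test_no_initiator_means_no_radicals(self):
        assert quasi_steady_radical(SpeciesState(), K) == 0.0

    @pytest.mark.parametrize(
        "state, expected",
        [
            (SpeciesState(C_A=10000.0), 2.52e-2 / 4.16e4),
            (SpeciesState(C_A=10000.0, C_C=225.0), 2.52e-2 / (4.16e4 + 200.0 * 225.0)),
        ],
    )
    def test_algebraic_balance(self, state, expected):
        assert quasi_steady_radical(state, RateConstants(k_C=200.0)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_denominator_raises(self):
        k0 = RateConstants(k_A=1.26e-6, k_el=0.0, k_C=0.0, k_CM=0.0)
        with pytest.raises(ZeroDivisionError):
            quasi_steady_radical(SpeciesState(C_A=1.0), k0)


@pytest.mark.parametrize("mode", ["full-stiff", "quasi-steady-radical"])
class TestSimulate:
    def test_zero_initial_state_stays_zero(self, mode, minute_grid):
        traj = simulate(ModelConfig(mode=mode), t_eval=minute_grid)
        for arr in (traj.C_A, traj.C_R, traj.C_C, traj.C_CM):
            assert np.all(arr == 0.0)

    def test_aaph_matches_closed_form(self, mode, aaph_10mM_state, minute_grid):
        traj = simulate(
            ModelConfig(initial_state=aaph_10mM_state, mode=mode), t_eval=minute_grid
        )
        expected = 10000.0 * np.exp(-1.26e-6 * traj.time)
        assert np.max(np.abs(traj.C_A - expected) / expected) < 1e-6
        assert traj.C_A[-1] == pytest.approx(9981.9, abs=0.1)

    def test_balance_residual_small(self, mode, free_curcumin_config):
        cfg = ModelConfig(
            rate_constants=free_curcumin_config.rate_constants,
            initial_state=free_curcumin_config.initial_state,
            mode=mode,
        )
        traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0))
        assert radical_balance_residual(traj, cfg.rate_constants) < 1e-4

    def test_slow_species_non_increasing_without_dosing(self, mode):
        cfg = ModelConfig(
            initial_state=SpeciesState(C_A=10000.0, C_C=50.0, C_CM=20.0), mode=mode
        )
        traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0))
        eps = 1e-9
        assert np.all(np.diff(traj.C_A) <= eps)
        assert np.all(np.diff(traj.C_C) <= eps)
        assert np.all(np.diff(traj.C_CM) <= eps)
        assert traj.C_R.min() >= 0.0 and traj.C_C.min() >= 0.0


def test_radical_relaxes_to_quasi_steady_level(aaph_10mM_state):
    """After ten radical half-lives the stiff solution tracks the algebraic level."""
    cfg = ModelConfig(initial_state=aaph_10mM_state, mode="full-stiff")
    ten_half_lives = 10.0 * np.log(2.0) / K.k_el  # ≈ 1.7e-4 min
    t_eval = np.array([0.0, ten_half_lives, 1e-3, 1.0, 10.0, 100.0, 1440.0])
    traj = simulate(cfg, t_eval=t_eval)
    for i in range(1, len(t_eval)):
        qss = quasi_steady_radical(traj.state_at(i), K)
        assert abs(traj.C_R[i] - qss) / qss < 5e-3


def test_modes_agree_on_curcumin_and_balance(free_curcumin_config, minute_grid):
    """Stiff integration and the quasi-steady shortcut must tell the same story."""
    qssa = simulate(free_curcumin_config, t_eval=minute_grid)
    full = simulate(
        ModelConfig(
            rate_constants=free_curcumin_config.rate_constants,
            initial_state=free_curcumin_config.initial_state,
            mode="full-stiff",
        ),
        t_eval=minute_grid,
    )
    assert np.max(np.abs(qssa.C_C - full.C_C) / full.C_C) < 1e-3
    r_q = radical_balance_residual(qssa, free_curcumin_config.rate_constants)
    r_f = radical_balance_residual(full, free_curcumin_config.rate_constants)
    assert abs(r_q - r_f) < 1e-4


def test_kC_zero_keeps_curcumin_constant():
    cfg = ModelConfig(
        rate_constants=RateConstants(k_C=0.0),
        initial_state=SpeciesState(C_A=10000.0),
        dosing=DosingScheme.bolus(135.7),
        mode="quasi-steady-radical",
    )
    traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0))
    assert np.all(traj.C_C == pytest.approx(135.7, rel=1e-12))


def test_bolus_is_an_instantaneous_jump():
    cfg = ModelConfig(
        rate_constants=RateConstants(k_C=200.0),
        initial_state=SpeciesState(C_A=10000.0),
        dosing=DosingScheme.bolus(50.0, time_min=100.0),
        mode="quasi-steady-radical",
    )
    traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0))
    i = np.searchsorted(traj.time, 100.0)
    assert traj.C_C[i - 1] == 0.0
    # the first grid point after the dose is one minute later, so a tiny
    # amount has already been consumed
    assert 49.9 < traj.C_C[i + 1] <= 50.0
    # AAPH decay is untouched by dosing
    assert traj.C_A[-1] == pytest.approx(10000.0 * np.exp(-1.26e-6 * 1440.0), rel=1e-9)


def test_constant_rate_delivery_accumulates():
    cfg = ModelConfig(
        rate_constants=RateConstants(k_C=0.0),
        initial_state=SpeciesState(),
        dosing=DosingScheme.constant_rate(0.1, 1440.0),
        mode="quasi-steady-radical",
    )
    traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0))
    assert traj.C_C[-1] == pytest.approx(144.0, rel=1e-9)


def test_literal_generation_form_produces_no_radicals(aaph_10mM_state):
    """The literal C_R-proportional source with C_R(0)=0 never ignites."""
    for mode in ("full-stiff", "quasi-steady-radical"):
        cfg = ModelConfig(
            initial_state=aaph_10mM_state, mode=mode, literal_radical_generation=True
        )
        traj = simulate(cfg, t_eval=np.array([0.0, 720.0, 1440.0]))
        assert np.all(traj.C_R == 0.0)


def test_dosing_scheme_validation():
    with pytest.raises(ValueError):
        DosingScheme(rate_segments=((0.0, 100.0, "curcumin", 0.1),
                                    (50.0, 150.0, "curcumin", 0.1)))
    with pytest.raises(ValueError):
        DosingScheme(boluses=((0.0, "radical", 1.0),))
    with pytest.raises(ValueError):
        ModelConfig(dosing=DosingScheme.bolus(10.0, time_min=2000.0), horizon=1440.0)


def test_trajectory_csv_round_trip(tmp_path, free_curcumin_config):
    traj = simulate(free_curcumin_config, t_eval=np.arange(0.0, 1441.0, 120.0))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    assert path.read_text().splitlines()[0] == "time_min,C_A_uM,C_R_uM,C_C_uM,C_CM_uM"
    back = Trajectory.from_csv(path)
    np.testing.assert_allclose(back.C_C, traj.C_C, rtol=1e-6)
    np.testing.assert_allclose(back.time, traj.time)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    dose=st.floats(1.0, 500.0),
    k_C=st.floats(1.0, 2000.0),
    aaph=st.floats(100.0, 100000.0),
)
def test_simulation_invariants_hold_across_conditions(dose, k_C, aaph):
    """Non-negativity, AAPH closed form and mass balance for arbitrary scenarios."""
    cfg = ModelConfig(
        rate_constants=RateConstants(k_C=k_C),
        initial_state=SpeciesState(C_A=aaph, C_C=dose),
        mode="quasi-steady-radical",
    )
    traj = simulate(cfg, t_eval=np.arange(0.0, 1441.0, 10.0))
    assert traj.C_C.min() >= 0.0 and traj.C_R.min() >= 0.0
    expected = aaph * np.exp(-1.26e-6 * traj.time)
    assert np.max(np.abs(traj.C_A - expected) / expected) < 1e-6
    assert radical_balance_residual(traj, cfg.rate_constants) < 1e-4
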