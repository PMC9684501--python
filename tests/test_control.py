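"""OGY control: linearization, marginal lines, gain region, controlled orbits."""

import math

import numpy as np
import pandas as pd
import pytest

from hollingmap import (
    GainPair,
    MarginalLineLabel,
    ModelParams,
    State,
    closed_loop,
    control_phase_sweep,
    control_setup,
    controlled_orbit,
    marginal_lines,
    orbit,
    stable_gain_interval,
)
from conftest import random_valid_params


@pytest.fixture
def setup3(example3_control):
    return control_setup(example3_control)


def test_setup_linearization(setup3):
    J = setup3.J
    assert J.j11 == pytest.approx(-2.375, rel=1e-8)
    assert J.j12 == pytest.approx(-0.125, rel=1e-8)
    assert J.j21 == pytest.approx(7.875, rel=1e-8)
    assert J.j22 == pytest.approx(1.0, rel=1e-8)
    assert setup3.phi_c == pytest.approx(-4.810702355, rel=1e-8)
    assert setup3.Cvec[0] == 0.0
    assert setup3.rank == 2


def test_setup_line_scale_products(setup3):
    # the rho coefficients of the printed marginal lines
    assert abs(setup3.J.j12 * setup3.phi_c) == pytest.approx(0.6013377944, rel=1e-8)
    assert abs(setup3.J.j11 * setup3.phi_c) == pytest.approx(11.42541809, rel=1e-8)


def test_phi_matches_finite_difference(rng):
    # phi is d(second map component)/dc at the target fixed point
    delta = 1e-6
    for p in random_valid_params(rng, 20):
        setup = control_setup(p)
        x, y = setup.target

        def g(c):
            pc = p.replace(c=c)
            from hollingmap import step

            return step(pc, State(x, y)).y

        numeric = (g(p.c + delta) - g(p.c - delta)) / (2 * delta)
        assert numeric == pytest.approx(setup.phi_c, rel=1e-6)


def test_closed_loop_zero_gains_is_uncontrolled(setup3):
    Jc, cp = closed_loop(setup3, GainPair(0.0, 0.0))
    assert Jc == setup3.J
    assert cp.T == pytest.approx(-1.375, rel=1e-8)
    assert cp.D == pytest.approx(-1.390625, rel=1e-8)


def test_closed_loop_polynomial_gain_dependence(setup3):
    # R^2 + (1.375 - 4.810702355 rho2) R - 1.390625
    #     - 11.42541809 rho2 + 0.6013377944 rho1
    for rho1, rho2 in [(0.3, -0.1), (1.55, 0.05), (2.0, 0.2)]:
        _, cp = closed_loop(setup3, GainPair(rho1, rho2))
        assert -cp.T == pytest.approx(1.375 - 4.810702355 * rho2, rel=1e-8)
        assert cp.D == pytest.approx(
            -1.390625 - 11.42541809 * rho2 + 0.6013377944 * rho1, rel=1e-8
        )


def test_marginal_lines_match_printed_forms(setup3):
    lines = {line.label: line for line in marginal_lines(setup3)}
    flip = lines[MarginalLineLabel.H1_FLIP]
    det = lines[MarginalLineLabel.H2_DET]
    fold = lines[MarginalLineLabel.H3_FOLD]
    # H1: 0.6013377944 rho1 = 1.765625 + 6.614715735 rho2
    assert flip.alpha == pytest.approx(0.6013377944, rel=1e-8)
    assert flip.beta == pytest.approx(-6.614715735, rel=1e-8)
    assert flip.gamma == pytest.approx(-1.765625, rel=1e-8)
    # H2: 11.42541809 rho2 + 2.390625 = 0.6013377944 rho1
    assert det.alpha == pytest.approx(0.6013377944, rel=1e-8)
    assert det.beta == pytest.approx(-11.42541809, rel=1e-8)
    assert det.gamma == pytest.approx(-2.390625, rel=1e-8)
    # H3: 16.23612044 rho2 = 0.6013377944 rho1 + 0.984375
    assert fold.alpha == pytest.approx(0.6013377944, rel=1e-8)
    assert fold.beta == pytest.approx(-16.23612044, rel=1e-8)
    assert fold.gamma == pytest.approx(0.984375, rel=1e-8)


def test_gain_interval_endpoint_roots(setup3):
    report = stable_gain_interval(setup3, 1.55)
    assert report.rho2_fold_root == pytest.approx(0.1180361151, rel=1e-8)
    assert report.rho2_flip_root == pytest.approx(-0.1260146999, rel=1e-8)


def test_jury_set_boundaries_lie_on_marginal_lines(setup3):
    report = stable_gain_interval(setup3, 1.55)
    lines = {line.label: line for line in marginal_lines(setup3)}
    lo, hi = report.jury_interval
    # each exact-boundary point sits on exactly one marginal line
    assert abs(lines[MarginalLineLabel.H2_DET](1.55, lo)) < 1e-8
    assert abs(lines[MarginalLineLabel.H1_FLIP](1.55, hi)) < 1e-8


def test_jury_set_matches_eigenvalue_oracle(setup3):
    report = stable_gain_interval(setup3, 1.55)
    lo, hi = report.jury_interval
    for rho2 in np.arange(-0.16, 0.15, 1e-3):
        _, cp = closed_loop(setup3, GainPair(1.55, float(rho2)))
        sr = max(abs(r) for r in cp.eigenvalues)
        if lo + 1e-6 < rho2 < hi - 1e-6:
            assert sr < 1
        elif rho2 < lo - 1e-6 or rho2 > hi + 1e-6:
            assert sr >= 1


def test_jury_set_subset_of_stable_spectral_radius(setup3, rng):
    tested = 0
    for _ in range(1000):
        rho1 = rng.uniform(-1.0, 5.0)
        rho2 = rng.uniform(-0.3, 0.4)
        report = stable_gain_interval(setup3, rho1)
        if report.jury_interval is None:
            continue
        lo, hi = report.jury_interval
        if not (lo + 1e-9 < rho2 < hi - 1e-9):
            continue
        tested += 1
        _, cp = closed_loop(setup3, GainPair(rho1, rho2))
        assert max(abs(r) for r in cp.eigenvalues) < 1.0
    assert tested >= 20


def test_printed_interval_differs_from_jury_set(setup3):
    # the determinant condition cuts into the printed endpoint interval
    report = stable_gain_interval(setup3, 1.55)
    assert not report.matches_endpoints
    assert report.jury_interval[0] == pytest.approx(report.rho2_det_root)


def test_controlled_orbit_zero_gains_matches_uncontrolled(setup3, example3_control):
    init = State(0.3, 9.0)
    a = controlled_orbit(setup3, GainPair(0.0, 0.0), init, 50)
    b = orbit(example3_control, init, 50)
    np.testing.assert_array_equal(a, b)


def test_fixed_point_is_stationary_under_control(setup3):
    pts = controlled_orbit(setup3, GainPair(1.55, -0.127), setup3.target, 10)
    np.testing.assert_allclose(pts, np.tile(setup3.target, (10, 1)), atol=1e-9)


def test_controlled_convergence_with_stable_gains(setup3):
    init = State(setup3.target.x + 1e-3, setup3.target.y + 1e-3)
    pts = controlled_orbit(setup3, GainPair(1.55, -0.127), init, 1, transient=5000)
    dist = math.hypot(pts[-1, 0] - setup3.target.x, pts[-1, 1] - setup3.target.y)
    assert dist < 1e-6


def test_control_amplitude_clamp(example3_control):
    # with delta=0 effective c is pinned at c0: control acts as if off
    setup_off = control_setup(example3_control, delta=1e-12)
    init = State(0.3, 9.0)
    a = controlled_orbit(setup_off, GainPair(1.55, -0.127), init, 8)
    b = orbit(example3_control, init, 8)
    np.testing.assert_allclose(a, b, atol=1e-8)


def test_control_phase_sweep_structure(setup3):
    init = State(setup3.target.x + 1e-3, setup3.target.y + 1e-3)
    grid = [-0.127, -0.08, 0.02, 0.25]
    frame = control_phase_sweep(setup3, 1.55, grid, init, n_keep=40, transient=6000)
    by = dict(tuple(frame.groupby("rho2")))
    # inside the Jury-stable set: single-point attractor
    inside = by[-0.127]
    assert not inside["diverged"].any()
    assert len(np.unique(np.round(inside["x"], 6))) == 1
    # outside: multi-point attractor or recorded divergence, sweep continued
    outside = by[-0.08]
    assert len(np.unique(np.round(outside["x"], 6))) >= 2
    assert by[0.25]["diverged"].all()


def test_control_phase_sweep_empty_and_deterministic(setup3):
    init = State(setup3.target.x + 1e-3, setup3.target.y + 1e-3)
    assert control_phase_sweep(setup3, 1.55, [], init).empty
    a = control_phase_sweep(setup3, 1.55, [0.0, 0.1], init, n_keep=10, transient=50)
    b = control_phase_sweep(setup3, 1.55, [0.0, 0.1], init, n_keep=10, transient=50)
    pd.testing.assert_frame_equal(a, b)


def test_uncontrollable_when_interior_absent():
    with pytest.raises(ValueError):
        control_setup(ModelParams(1.0, 0.5, 0.1, 1.0, 1.0), c0=0.6)
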