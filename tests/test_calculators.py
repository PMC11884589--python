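"""Potential-contract tests: Morse analytics, gradient consistency,
Müller–Brown stationary points against a grid+Newton oracle, adapter parsing."""

import stat
import sys

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rpskit.calculators import (
    CalculatorError,
    CalculatorFailure,
    ExternalEngine,
    MorseCluster,
    MorseClusterParams,
    MuellerBrown,
    UnsupportedElementError,
    mueller_brown_energy,
)
from rpskit.core import Geometry

from conftest import H2_PARAMS, random_geometry


class TestMorseDimer:
    def test_energy_at_minimum_is_minus_D(self, h2_morse):
        g = Geometry.from_symbols(
            ("H", "H"), np.array([[0.0, 0, 0], [H2_PARAMS["r0"], 0, 0]])
        )
        e, f = h2_morse.evaluate(g)
        assert e == pytest.approx(-H2_PARAMS["D"], abs=1e-12)
        assert np.abs(f).max() <= 1e-8

    def test_dissociation_limit_zero(self, h2_morse):
        g = Geometry.from_symbols(("H", "H"), np.array([[0.0, 0, 0], [100.0, 0, 0]]))
        e, _ = h2_morse.evaluate(g)
        assert abs(e) < 1e-6

    def test_unsupported_element_raises(self, h2_morse):
        g = Geometry.from_symbols(("O", "O"), np.array([[0.0, 0, 0], [1.2, 0, 0]]))
        with pytest.raises(UnsupportedElementError):
            h2_morse.evaluate(g)

    def test_repeated_evaluation_bitwise_identical(self, morse, ht_reactant):
        e1, f1 = morse.evaluate(ht_reactant)
        e2, f2 = morse.evaluate(ht_reactant)
        assert e1 == e2
        assert np.array_equal(f1, f2)


class TestGradientConsistency:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_forces_match_finite_differences(self, seed):
        model = MorseCluster()
        rng = np.random.default_rng(seed)
        symbols = rng.choice(["O", "H", "N", "C"], size=4).tolist()
        g = random_geometry(rng, symbols)
        _, forces = model.evaluate(g)
        h = 1e-4
        for i in range(g.n_atoms):
            for k in range(3):
                p = np.array(g.positions)
                p[i, k] += h
                ep, _ = model.evaluate(g.with_positions(p))
                p[i, k] -= 2 * h
                em, _ = model.evaluate(g.with_positions(p))
                assert -(ep - em) / (2 * h) == pytest.approx(forces[i, k], abs=1e-4, rel=1e-6)

    def test_translation_invariance(self, morse):
        rng = np.random.default_rng(7)
        g = random_geometry(rng, ["O", "H", "N", "C", "H"])
        e0, f0 = morse.evaluate(g)
        shifted = g.with_positions(g.positions + np.array([1.7, -3.1, 0.4]))
        e1, f1 = morse.evaluate(shifted)
        assert abs(e1 - e0) < 1e-10
        assert np.abs(f0.sum(axis=0)).max() < 1e-8


class TestMorseParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            MorseClusterParams({("H", "H"): (-1.0, 1.0, 1.0)})

    def test_pair_lookup_symmetric(self, morse):
        assert morse.params.lookup("O", "H") == morse.params.lookup("H", "O")


def newton_refine(x, y, steps=50):
    """Independent Newton refinement on the analytic surface using numeric
    derivatives of the energy only."""
    h = 1e-6
    for _ in range(steps):
        E = mueller_brown_energy
        gx = (E(x + h, y) - E(x - h, y)) / (2 * h)
        gy = (E(x, y + h) - E(x, y - h)) / (2 * h)
        hxx = (E(x + h, y) - 2 * E(x, y) + E(x - h, y)) / h**2
        hyy = (E(x, y + h) - 2 * E(x, y) + E(x, y - h)) / h**2
        hxy = (
            E(x + h, y + h) - E(x + h, y - h) - E(x - h, y + h) + E(x - h, y - h)
        ) / (4 * h**2)
        H = np.array([[hxx, hxy], [hxy, hyy]])
        step = np.linalg.solve(H, [gx, gy])
        x, y = x - step[0], y - step[1]
        if np.hypot(gx, gy) < 1e-10:
            break
    return x, y


def grid_stationary_points():
    """Grid scan + Newton refinement oracle for Müller–Brown fixed points."""
    pts = []
    for x0 in np.linspace(-1.6, 1.2, 29):
        for y0 in np.linspace(-0.3, 2.0, 24):
            try:
                x, y = newton_refine(x0, y0)
            except np.linalg.LinAlgError:
                continue
            if not (-2 < x < 1.5 and -0.5 < y < 2.5):
                continue
            h = 1e-6
            E = mueller_brown_energy
            gx = (E(x + h, y) - E(x - h, y)) / (2 * h)
            gy = (E(x, y + h) - E(x, y - h)) / (2 * h)
            if np.hypot(gx, gy) > 1e-6:  # Newton did not actually converge
                continue
            if not any(np.hypot(x - a, y - b) < 1e-4 for a, b in pts):
                pts.append((x, y))
    return pts


def hessian_signature(x, y):
    h = 1e-5
    E = mueller_brown_energy
    hxx = (E(x + h, y) - 2 * E(x, y) + E(x - h, y)) / h**2
    hyy = (E(x, y + h) - 2 * E(x, y) + E(x, y - h)) / h**2
    hxy = (
        E(x + h, y + h) - E(x + h, y - h) - E(x - h, y + h) + E(x - h, y - h)
    ) / (4 * h**2)
    eig = np.linalg.eigvalsh(np.array([[hxx, hxy], [hxy, hyy]]))
    return int(np.sum(eig < 0))


class TestMuellerBrown:
    @pytest.fixture(scope="class")
    def oracle_points(self):
        pts = grid_stationary_points()
        minima = [p for p in pts if hessian_signature(*p) == 0]
        saddles = [p for p in pts if hessian_signature(*p) == 1]
        return minima, saddles

    def test_oracle_finds_three_minima_two_saddles(self, oracle_points):
        minima, saddles = oracle_points
        assert len(minima) == 3
        assert len(saddles) == 2

    def test_global_minimum_location_and_energy(self, oracle_points):
        minima, _ = oracle_points
        x, y = min(minima, key=lambda p: mueller_brown_energy(*p))
        assert (x, y) == pytest.approx((-0.558, 1.442), abs=1e-3)
        assert mueller_brown_energy(x, y) == pytest.approx(-146.70, abs=0.01)

    def test_second_minimum(self, oracle_points):
        minima, _ = oracle_points
        target = min(minima, key=lambda p: abs(p[0] - 0.623))
        assert target == pytest.approx((0.623, 0.028), abs=1e-3)
        assert mueller_brown_energy(*target) == pytest.approx(-108.17, abs=0.01)

    def test_highest_saddle(self, oracle_points):
        _, saddles = oracle_points
        s = max(saddles, key=lambda p: mueller_brown_energy(*p))
        assert s == pytest.approx((-0.822, 0.624), abs=1e-3)
        assert mueller_brown_energy(*s) == pytest.approx(-40.66, abs=0.01)

    def test_geometry_interface_forces_match_gradient(self, mueller_brown):
        g = MuellerBrown.geometry(0.1, 0.7)
        e, f = mueller_brown.evaluate(g)
        h = 1e-6
        gx = (mueller_brown_energy(0.1 + h, 0.7) - mueller_brown_energy(0.1 - h, 0.7)) / (2 * h)
        assert f[0, 0] == pytest.approx(-gx, abs=1e-4)
        assert f[0, 2] == 0.0
        assert e == pytest.approx(mueller_brown_energy(0.1, 0.7))


def make_stub(tmp_path, body: str) -> str:
    script = tmp_path / "engine.py"
    script.write_text(f"#!/usr/bin/env python\n{body}\n")
    script.chmod(script.stat().st_mode | stat.S_IEXEC)
    return str(script)


class TestExternalEngine:
    def engine(self, tmp_path, body):
        return ExternalEngine([sys.executable, make_stub(tmp_path, body)], name="stub")

    def test_roundtrip_through_parser(self, tmp_path):
        eng = self.engine(
            tmp_path,
            "print('energy -3.25')\n"
            "print('force 0.1 -0.2 0.0')\nprint('force -0.1 0.2 0.0')",
        )
        g = Geometry.from_symbols(("H", "H"), np.array([[0.0, 0, 0], [0.8, 0, 0]]))
        e, f = eng.evaluate(g)
        assert e == pytest.approx(-3.25)
        np.testing.assert_allclose(f, [[0.1, -0.2, 0.0], [-0.1, 0.2, 0.0]])

    def test_malformed_output_is_parse_error(self, tmp_path):
        eng = self.engine(tmp_path, "print('energy not-a-number')")
        g = Geometry.from_symbols(("H",), np.zeros((1, 3)))
        with pytest.raises(CalculatorError):
            eng.evaluate(g)

    def test_nan_energy_is_calculator_failure(self, tmp_path):
        eng = self.engine(
            tmp_path, "print('energy nan')\nprint('force 0 0 0')"
        )
        g = Geometry.from_symbols(("H",), np.zeros((1, 3)))
        with pytest.raises(CalculatorFailure):
            eng.evaluate(g)

    def test_missing_binary_reported(self):
        eng = ExternalEngine(["/no/such/engine"], name="ghost")
        g = Geometry.from_symbols(("H",), np.zeros((1, 3)))
        with pytest.raises(CalculatorError, match="not found"):
            eng.evaluate(g)
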