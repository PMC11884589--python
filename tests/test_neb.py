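"""Band interpolation, projected forces, CI-NEB saddle convergence and the
cumulative-Fmax harvesting bookkeeping."""

import numpy as np
import pytest

from rpskit.calculators import HarmonicBowl, MuellerBrown, MUELLER_BROWN_MINIMA
from rpskit.core import Geometry
from rpskit.filters import validate_ts
from rpskit.neb import (
    Band,
    HarvestState,
    NEBParams,
    interpolate_band,
    neb_forces,
    run_neb,
)


class FlatSurface(HarmonicBowl):
    """Zero-force surface for tangent/spring cancellation checks."""

    name = "flat"

    def _evaluate(self, positions, symbols):
        return 0.0, np.zeros_like(positions)


def line_geometry(x):
    return Geometry.from_symbols(("H",), np.array([[x, 0.0, 0.0]]))


class TestInterpolateBand:
    def test_three_images_midpoint(self, water):
        other = water.with_positions(water.positions + np.array([1.0, 0, 0]))
        band = interpolate_band(water, other, n_images=3, method="linear")
        np.testing.assert_allclose(
            band.images[1].positions, 0.5 * (water.positions + other.positions)
        )

    @pytest.mark.parametrize("method", ["linear", "idpp"])
    def test_endpoints_returned_unmodified(self, water, method):
        other = water.with_positions(water.positions + np.array([1.0, 0, 0]))
        band = interpolate_band(water, other, n_images=6, method=method)
        assert band.images[0] is water
        assert band.images[-1] is other

    def test_mismatched_atom_lists_rejected(self, water):
        dimer = Geometry.from_symbols(("H", "H"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError):
            interpolate_band(water, dimer, n_images=5)

    def test_idpp_tracks_distance_profile_better_than_linear(self, ht_reactant):
        # swing the H around: straight Cartesian interpolation distorts the
        # O–H distance, the pair-distance objective should not be worse
        rot = ht_reactant.positions.copy()
        c, s = np.cos(1.2), np.sin(1.2)
        rot[1] = rot[0] + np.array(
            [
                c * (rot[1, 0] - rot[0, 0]) - s * (rot[1, 1] - rot[0, 1]),
                s * (rot[1, 0] - rot[0, 0]) + c * (rot[1, 1] - rot[0, 1]),
                0.0,
            ]
        )
        end = ht_reactant.with_positions(rot)

        def objective(band):
            total = 0.0
            dr = np.linalg.norm(
                ht_reactant.positions[:, None] - ht_reactant.positions[None, :], axis=-1
            )
            dp = np.linalg.norm(end.positions[:, None] - end.positions[None, :], axis=-1)
            m = band.n_images
            for k in range(1, m - 1):
                t = k / (m - 1)
                target = (1 - t) * dr + t * dp
                pos = band.images[k].positions
                d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
                iu = np.triu_indices(pos.shape[0], 1)
                total += np.sum((d[iu] - target[iu]) ** 2 / target[iu] ** 4)
            return total

        lin = interpolate_band(ht_reactant, end, n_images=8, method="linear")
        idpp = interpolate_band(ht_reactant, end, n_images=8, method="idpp")
        assert objective(idpp) <= objective(lin) + 1e-12


class TestNebForces:
    def test_flat_surface_equally_spaced_zero(self):
        images = [line_geometry(x) for x in np.linspace(0, 3, 5)]
        band = Band(images=images)
        forces = neb_forces(band, FlatSurface())
        for f in forces:
            assert np.abs(f).max() <= 1e-10

    def test_tangent_points_to_higher_neighbor(self):
        from rpskit.neb import _improved_tangent

        r = [np.array([[float(x), 0, 0]]) for x in range(3)]
        tau = _improved_tangent(r[0], r[1], r[2], 0.0, 1.0, 2.0)
        np.testing.assert_allclose(tau, [[1.0, 0, 0]])  # uphill chain: r_next − r_here
        tau = _improved_tangent(r[0], r[1], r[2], 2.0, 1.0, 0.0)
        np.testing.assert_allclose(tau, [[1.0, 0, 0]])  # downhill chain: r_here − r_prev

    def test_spring_force_restores_spacing(self):
        # unequal spacing on a flat surface: only the spring term survives
        images = [line_geometry(x) for x in (0.0, 0.5, 3.0)]
        band = Band(images=images, spring_k=0.1)
        forces = neb_forces(band, FlatSurface())
        # |r2-r1| - |r1-r0| = 2.0 → spring force 0.2 along +x
        assert forces[1][0, 0] == pytest.approx(0.2)


class TestRunNeb:
    def test_already_converged_zero_iterations(self):
        images = [line_geometry(x) for x in np.linspace(0, 2, 4)]
        band = Band(images=images)
        band, harvest = run_neb(band, FlatSurface(), fmax_tol=0.05)
        assert band.converged
        assert len(band.trace) == 1  # only the initial evaluation
        assert len(harvest.harvested) == 1  # just the final band

    def test_endpoints_bitwise_constant(self, mueller_brown):
        r = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[0])
        p = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[2])
        band = interpolate_band(r, p, n_images=8, method="linear")
        band, _ = run_neb(band, mueller_brown, fmax_tol=0.05, max_steps=1500)
        np.testing.assert_array_equal(band.images[0].positions, r.positions)
        np.testing.assert_array_equal(band.images[-1].positions, p.positions)

    def test_climbing_image_converges_to_saddle(self, mueller_brown):
        r = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[0])
        p = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[2])
        band = interpolate_band(r, p, n_images=10, method="linear")
        band, _ = run_neb(band, mueller_brown, fmax_tol=0.05, max_steps=2000)
        assert band.converged
        e = band.energies
        k = 1 + int(np.argmax(e[1:-1]))
        # grid+Newton oracle saddle (computed in test_calculators oracle):
        assert e[k] == pytest.approx(-40.6648, abs=1e-2)
        assert band.images[k].positions[0, :2] == pytest.approx(
            (-0.8220, 0.6243), abs=5e-2
        )
        assert validate_ts(band.images[k], mueller_brown).accepted

    def test_images_lie_on_dense_mep_oracle(self, mueller_brown):
        """Converged band images sit on the steepest-descent path from the
        saddle (the true MEP), traced independently of the band code."""
        from rpskit.calculators import mueller_brown_gradient

        # dense MEP oracle: descend from just off the connecting saddle
        saddle = np.array([0.2124865821, 0.2929883251])
        h = 1e-5
        gxx = (mueller_brown_gradient(*(saddle + [h, 0]))[0] - mueller_brown_gradient(*(saddle - [h, 0]))[0]) / (2 * h)
        gyy = (mueller_brown_gradient(*(saddle + [0, h]))[1] - mueller_brown_gradient(*(saddle - [0, h]))[1]) / (2 * h)
        gxy = (mueller_brown_gradient(*(saddle + [0, h]))[0] - mueller_brown_gradient(*(saddle - [0, h]))[0]) / (2 * h)
        evals, evecs = np.linalg.eigh(np.array([[gxx, gxy], [gxy, gyy]]))
        unstable = evecs[:, int(np.argmin(evals))]
        mep = [saddle.copy()]
        for sign in (+1.0, -1.0):
            x = saddle + sign * 1e-3 * unstable
            for _ in range(200_000):
                g = np.array(mueller_brown_gradient(*x))
                if np.linalg.norm(g) < 1e-6:
                    break
                x = x - 1e-4 * g / max(np.linalg.norm(g), 1.0)
                mep.append(x.copy())
        mep = np.array(mep)

        r = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[1])
        p = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[2])
        band = interpolate_band(r, p, n_images=12, method="linear")
        band, _ = run_neb(band, mueller_brown, fmax_tol=0.02, max_steps=3000)
        assert band.converged
        for img in band.images[1:-1]:
            pt = img.positions[0, :2]
            dist = np.min(np.linalg.norm(mep - pt, axis=1))
            assert dist <= 0.05


class TestHarvesting:
    def test_trace_arithmetic_example(self):
        state = HarvestState(threshold=0.1)
        images = [line_geometry(x) for x in (0.0, 1.0, 2.0)]
        hits = [
            state.record(it, fm, images)
            for it, fm in enumerate((0.06, 0.06, 0.03, 0.08), start=1)
        ]
        assert hits == [False, True, False, True]
        assert [it for it, _ in state.harvested] == [2, 4]
        assert state.accumulator == 0.0

    def test_accumulator_bounds_between_harvests(self):
        rng = np.random.default_rng(23)
        state = HarvestState(threshold=0.1)
        images = [line_geometry(0.0)] * 3
        for it in range(200):
            state.record(it, float(rng.uniform(0, 0.05)), images)
            assert 0.0 <= state.accumulator < state.threshold

    def test_summed_fmax_between_harvests_at_least_threshold(self, mueller_brown):
        r = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[0])
        p = MuellerBrown.geometry(*MUELLER_BROWN_MINIMA[2])
        band = interpolate_band(r, p, n_images=8, method="linear")
        harvest = HarvestState(threshold=0.1)
        band, harvest = run_neb(
            band, mueller_brown, fmax_tol=0.05, max_steps=1500, harvest=harvest
        )
        fmax_by_iter = {it: fm for it, (fm, _) in enumerate(band.trace)}
        stamps = [it for it, _ in harvest.harvested[:-1]]  # exclude the final band
        prev = 0
        for stamp in stamps:
            window = [fmax_by_iter[i] for i in range(prev + 1, stamp + 1)]
            assert sum(window) >= harvest.threshold - 1e-12
            prev = stamp
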