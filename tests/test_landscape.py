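"""Trajectory alignment, surface interpolation, and barrier extraction."""

import json

import numpy as np
import pytest

import epiland as el
from epiland.attractors import UNASSIGNED, find_fixed_points, stable_points
from epiland.errors import ConfigurationError, NoSharedBoundaryError
from epiland.experiments import attractor_aliases
from epiland.landscape import (
    GridSpec,
    align,
    barrier_height,
    build_trajectory_fan,
    elevation_at,
    interpolate_surface,
)


class TestTrajectoryFan:
    def test_tristable_fan_covers_three_basins(self, tristable, tristable_fps):
        grid = GridSpec(0.0, 25.0, 0.0, 25.0, 41, 41)
        fan = build_trajectory_fan(tristable, grid, fixed_points=tristable_fps)
        assert not fan.excluded
        assert set(np.unique(fan.labels)) == {0, 1, 2}

    def test_single_start_at_attractor(self, tristable, tristable_fps):
        grid = GridSpec(10.0, 10.0, 10.0, 10.0, 1, 1)
        fan = build_trajectory_fan(tristable, grid, fixed_points=tristable_fps)
        traj = fan.trajectories[0]
        assert len(traj) == 1
        assert traj.drop == 0.0
        aligned = align(fan)
        assert aligned.offsets == {1: 0.0}

    def test_grid_refinement_preserves_labels(self, bistable, bistable_fps):
        coarse = build_trajectory_fan(
            bistable, GridSpec.for_params(bistable, n=21), fixed_points=bistable_fps)
        fine = build_trajectory_fan(
            bistable, GridSpec.for_params(bistable, n=41), fixed_points=bistable_fps)
        # The 41-grid contains every 21-grid start at doubled indices.
        assert np.array_equal(coarse.labels, fine.labels[::2, ::2])

    def test_basin_map_export(self, tmp_path, bistable_landscape):
        fan, _, _ = bistable_landscape
        path = tmp_path / "basins.csv"
        fan.basin_map_to_csv(path)
        assert path.read_text().splitlines()[0] == "x,y,basin"


class TestAlign:
    def test_terminal_elevation_equals_offset(self, tristable_landscape):
        _, aligned, _ = tristable_landscape
        for traj in aligned.fan.trajectories:
            if traj is None:
                continue
            terminal = aligned.offsets[traj.basin] + traj.elevation()[-1]
            assert terminal == pytest.approx(aligned.offsets[traj.basin], abs=1e-9)

    def test_symmetric_attractors_level(self, tristable_landscape):
        # x <-> y symmetry: the two differentiated attractors sit at equal
        # elevation, and the deepest sits at 0.
        _, aligned, _ = tristable_landscape
        offs = aligned.offsets
        assert offs[0] == pytest.approx(offs[2], abs=1e-6)
        assert min(offs.values()) == 0.0

    def test_bistable_ridge_above_both_valleys(self, bistable_landscape):
        _, aligned, surface = bistable_landscape
        for a, b in ((0, 1), (1, 0)):
            assert barrier_height(surface, a, b) > 0.05

    def test_residuals_shrink_under_grid_refinement(self, tristable, tristable_fps):
        med = {}
        for n in (21, 81):
            fan = build_trajectory_fan(
                tristable, GridSpec.for_params(tristable, n=n),
                fixed_points=tristable_fps)
            med[n] = np.median(np.abs(align(fan).residuals()))
        assert med[81] <= med[21]

    def test_disconnected_basins_raise(self, bistable, bistable_fps):
        # If every start pair bridging two basins is lost (e.g. to
        # non-convergence), the basins cannot be levelled against each other.
        import copy

        grid = GridSpec.for_params(bistable, n=9)
        fan = build_trajectory_fan(bistable, grid, fixed_points=bistable_fps)
        broken = copy.deepcopy(fan)
        lab = broken.labels
        vdiff = lab[:-1, :] != lab[1:, :]
        hdiff = lab[:, :-1] != lab[:, 1:]
        boundary = np.zeros_like(lab, dtype=bool)
        boundary[:-1, :] |= vdiff
        boundary[1:, :] |= vdiff
        boundary[:, :-1] |= hdiff
        boundary[:, 1:] |= hdiff
        for j, i in zip(*np.nonzero(boundary)):
            broken.labels[j, i] = UNASSIGNED
            broken.trajectories[j * grid.nx + i] = None
        with pytest.raises(el.errors.AlignmentError, match="unreachable"):
            align(broken)


class TestSurface:
    def test_minima_coincide_with_attractors(self, bistable_landscape,
                                             tristable_landscape):
        for fan, _, surface in (bistable_landscape, tristable_landscape):
            minima = surface.significant_minima()
            stable = fan.stable_points
            assert len(minima) == len(stable)
            cell = np.hypot(surface.x[1] - surface.x[0], surface.y[1] - surface.y[0])
            for fp in stable:
                d = min(np.hypot(mx - fp.x, my - fp.y) for mx, my, _, _ in minima)
                assert d <= cell

    def test_value_at_attractor_matches_offset(self, tristable_landscape):
        _, aligned, surface = tristable_landscape
        for label, (x, y) in surface.attractor_locations.items():
            v = surface.value_at((x, y))
            assert v == pytest.approx(surface.attractor_elevations[label], abs=0.3)

    def test_surface_non_increasing_along_flow(self, tristable, tristable_landscape):
        _, _, surface = tristable_landscape
        z_range = np.nanmax(surface.z) - np.nanmin(surface.z)
        for start in ((3.0, 22.0), (20.0, 18.0), (6.0, 1.0)):
            traj = el.integrate(start, tristable)
            vals = np.array([surface.value_at((x, y))
                             for x, y in zip(traj.x, traj.y)])
            vals = vals[np.isfinite(vals)]
            climbs = np.diff(vals)
            assert climbs.max(initial=0.0) <= 0.01 * z_range

    def test_symmetric_surface(self, tristable_landscape):
        _, _, surface = tristable_landscape
        both = surface.valid & surface.valid.T
        diff = np.abs(surface.z - surface.z.T)[both]
        z_range = np.nanmax(surface.z) - np.nanmin(surface.z)
        assert diff.max() <= 1e-6 * z_range

    def test_attractors_barely_move_with_hill_coefficient(self, tristable):
        # Steepening the sigmoids reshapes elevations, not state locations.
        lo = el.find_fixed_points(tristable.replace(n_H=2.0), seed=1, n_starts=600)
        hi = stable_points(el.find_fixed_points(tristable.replace(n_H=10.0), seed=1))
        locs_lo = [fp.location for fp in lo]
        sep = min(np.hypot(a.x - b.x, a.y - b.y)
                  for a in hi for b in hi if a.label != b.label)
        for fp in hi:
            d = min(np.hypot(fp.x - x, fp.y - y) for x, y in locs_lo)
            assert d < 0.1 * sep

    def test_exports(self, tmp_path, bistable_landscape):
        _, _, surface = bistable_landscape
        surface.to_csv(tmp_path / "surface.csv")
        surface.to_json(tmp_path / "surface.json")
        surface.basin_to_csv(tmp_path / "surface_basins.csv")
        assert (tmp_path / "surface.csv").read_text().splitlines()[0] == \
            "x,y,elevation,valid"
        mesh = json.loads((tmp_path / "surface.json").read_text())
        assert len(mesh["elevation"]) == len(mesh["y"])
        assert set(mesh["attractor_elevations"]) == {"0", "1"}


class TestBarriers:
    def test_symmetric_barriers_equal(self, tristable_landscape):
        _, _, surface = tristable_landscape
        assert barrier_height(surface, 0, 1) == pytest.approx(
            barrier_height(surface, 2, 1), rel=1e-6)
        assert barrier_height(surface, 1, 0) == pytest.approx(
            barrier_height(surface, 1, 2), rel=1e-6)

    def test_escape_barrier_exceeds_entry_barrier_for_deep_valley(
            self, tristable_landscape):
        _, _, surface = tristable_landscape
        # The differentiated valleys are deeper than the progenitor's, so
        # escaping them costs more than entering.
        assert barrier_height(surface, 0, 1) > barrier_height(surface, 1, 0)

    def test_differentiated_basins_share_no_boundary(self, tristable_landscape):
        _, _, surface = tristable_landscape
        with pytest.raises(NoSharedBoundaryError) as exc:
            barrier_height(surface, 0, 2)
        assert exc.value.intermediates == [1]

    def test_barriers_grow_with_ultrasensitivity(self, tristable):
        # Raising n_H makes the ridges higher relative to the valleys.
        heights = []
        for nh in (3.0, 4.0, 10.0):
            p = tristable.replace(n_H=nh)
            fps = find_fixed_points(p, seed=1)
            fan = build_trajectory_fan(p, GridSpec.for_params(p, n=41),
                                       fixed_points=fps)
            surface = interpolate_surface(align(fan))
            aliases = attractor_aliases(stable_points(fps))
            by_alias = {v: k for k, v in aliases.items()}
            heights.append(barrier_height(surface, by_alias["B"], by_alias["C"]))
        assert heights[0] < heights[1] < heights[2]

    def test_invalid_queries(self, bistable_landscape):
        _, _, surface = bistable_landscape
        with pytest.raises(ConfigurationError):
            barrier_height(surface, 0, 0)
        with pytest.raises(ConfigurationError):
            barrier_height(surface, 0, 7)

    def test_single_basin_has_no_barrier(self):
        p = el.CircuitParams(B_X=0.2, B_Y=0.2)
        fps = find_fixed_points(p, seed=0)
        fan = build_trajectory_fan(p, GridSpec(0, 1, 0, 1, 11, 11),
                                   fixed_points=fps)
        surface = interpolate_surface(align(fan), nx=51, ny=51)
        with pytest.raises(ConfigurationError):
            barrier_height(surface, 0, 1)


class TestElevationAt:
    def test_exact_on_sample(self, tristable_landscape):
        _, aligned, _ = tristable_landscape
        k = len(aligned.elevations) // 3
        pt = aligned.points[k]
        assert elevation_at(aligned, pt) == pytest.approx(aligned.elevations[k])

    def test_agrees_with_surface_interpolation(self, tristable_landscape):
        _, aligned, surface = tristable_landscape
        z_range = np.nanmax(surface.z) - np.nanmin(surface.z)
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(200):
            pt = tuple(rng.uniform(2, 22, 2))
            a = elevation_at(aligned, pt)
            b = surface.value_at(pt)
            if np.isfinite(a) and np.isfinite(b):
                diffs.append(abs(a - b))
        diffs = np.asarray(diffs)
        assert np.median(diffs) < 0.01 * z_range
        assert np.percentile(diffs, 95) < 0.03 * z_range

    def test_monotone_along_trajectory(self, tristable, tristable_landscape):
        _, aligned, surface = tristable_landscape
        z_range = np.nanmax(surface.z) - np.nanmin(surface.z)
        traj = el.integrate((4.0, 21.0), tristable)
        vals = np.array([elevation_at(aligned, (x, y))
                         for x, y in zip(traj.x, traj.y)])
        vals = vals[np.isfinite(vals)]
        # The two-nearest-sample rule is coarser than the triangulated
        # surface, so its transient overshoots are allowed twice the slack.
        assert np.diff(vals).max(initial=0.0) <= 0.02 * z_range

    def test_outside_support_is_masked(self, tristable_landscape):
        _, aligned, _ = tristable_landscape
        assert np.isnan(elevation_at(aligned, (1e3, 1e3)))


def test_raising_basal_expression_deepens_the_fed_attractor(tristable):
    """Raising B_Y lowers the y-dominated attractor A relative to B."""
    deltas = {}
    for by in (0.0, 4.0):
        p = tristable.replace(B_Y=by)
        fps = find_fixed_points(p, seed=1)
        fan = build_trajectory_fan(p, GridSpec.for_params(p, n=41),
                                   fixed_points=fps)
        surface = interpolate_surface(align(fan))
        aliases = attractor_aliases(stable_points(fps))
        by_alias = {v: k for k, v in aliases.items()}
        deltas[by] = (surface.attractor_elevations[by_alias["A"]]
                      - surface.attractor_elevations[by_alias["B"]])
    assert deltas[0.0] == pytest.approx(0.0, abs=1e-6)
    assert deltas[4.0] < deltas[0.0] - 1.0
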