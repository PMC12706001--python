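"""Occupancy grids, overflow statistics and contact maps."""

import numpy as np
import pytest

from dyn2lattice import (
    OVERFLOW,
    assign_site,
    contact_map,
    diff_contact_map,
    leading_head_fraction,
    occupancy,
    overflow_proportion,
)
from dyn2lattice.analysis import ContactMap
from dyn2lattice.bead_model import BeadModel, ModelValidationError
from dyn2lattice.engine import Trajectory
from dyn2lattice.synthetic import gen_random_walk_trajectories, square_grid


def _traj(coms, steps=None, position_id=2, digest="d"):
    coms = np.asarray(coms, dtype=float)
    if steps is None:
        steps = np.arange(1, len(coms) + 1, dtype=np.int64)
    return Trajectory(
        metadata={"tail_state": "Y", "position_id": position_id, "seed": 0,
                  "params_digest": digest},
        steps=np.asarray(steps, dtype=np.int64),
        com_low=coms,
    )


GRID = square_grid(spacing=1.0)


def oracle_assign(com, grid):
    """Independent capture-region + nearest-center implementation."""
    a = float(np.dot(com, grid.axial_direction))
    l = float(np.dot(com, grid.lateral_direction))
    ac = grid.site_centers @ grid.axial_direction
    lc = grid.site_centers @ grid.lateral_direction
    if a < ac.min() - grid.margin_axial or a > ac.max() + grid.margin_axial:
        return OVERFLOW
    if l < lc.min() - grid.margin_lateral or l > lc.max() + grid.margin_lateral:
        return OVERFLOW
    if com[2] - grid.surface_z > grid.detach_height:
        return OVERFLOW
    best, best_d = None, np.inf
    for r in range(3):
        for c in range(3):
            d = (ac[r, c] - a) ** 2 + (lc[r, c] - l) ** 2
            if d < best_d - 1e-15:
                best, best_d = (r, c), d
    return best


class TestAssignSite:
    def test_center_maps_to_center(self):
        assert assign_site(GRID.site_centers[1, 1], GRID) == (1, 1)

    def test_far_point_overflows(self):
        assert assign_site([30.0, 0.0, 0.0], GRID) == OVERFLOW

    def test_detachment_height_overflows(self):
        com = GRID.site_centers[1, 1] + np.array([0, 0, 10.0])
        assert assign_site(com, GRID) == OVERFLOW

    def test_matches_brute_force_on_random_points(self, rng):
        pts = rng.uniform(-3, 3, (1000, 3))
        pts[:, 2] = rng.uniform(-1, 8, 1000)
        for p in pts:
            assert assign_site(p, GRID) == oracle_assign(p, GRID)


class TestOccupancy:
    def test_stationary_trajectory_all_mass_at_center(self):
        t = _traj(np.tile(GRID.site_centers[1, 1], (50, 1)))
        res = occupancy([t], GRID, burn_in=0)
        assert res.summed_grid[1, 1] == pytest.approx(1.0)
        assert res.overflow_percent == 0.0

    def test_hand_built_three_site_visit(self):
        coms = [GRID.site_centers[1, 1], GRID.site_centers[1, 2],
                GRID.site_centers[2, 1]]
        res = occupancy([_traj(coms)], GRID, burn_in=0)
        for site in [(1, 1), (1, 2), (2, 1)]:
            assert res.summed_grid[site] == pytest.approx(1 / 3)

    def test_burn_in_frame_bookkeeping_full_protocol(self):
        """3×10⁷ steps with the first 5×10⁶ excluded at uniform stride:
        exactly 5/6 of the frames are retained."""
        stride = 10_000
        steps = np.arange(stride, 30_000_000 + 1, stride)
        coms = np.tile(GRID.site_centers[1, 1], (len(steps), 1))
        res = occupancy([_traj(coms, steps=steps)], GRID, burn_in=5_000_000)
        assert res.frames_used / len(steps) == pytest.approx(5 / 6)

    def test_short_trajectory_excluded_with_warning(self, caplog):
        good = _traj(np.tile(GRID.site_centers[1, 1], (50, 1)))
        short = _traj([GRID.site_centers[1, 1]], steps=[1])
        res = occupancy([good, short], GRID, burn_in=10)
        assert res.n_trajectories == 1

    def test_mixed_digests_rejected(self):
        a = _traj(np.tile(GRID.site_centers[1, 1], (5, 1)), digest="a")
        b = _traj(np.tile(GRID.site_centers[1, 1], (5, 1)), digest="b")
        with pytest.raises(ModelValidationError):
            occupancy([a, b], GRID, burn_in=0)

    def test_non_escaping_mass_sums_to_one(self, rng):
        coms = rng.uniform(-0.4, 0.4, (100, 3))
        coms[:, 2] = 0.0
        res = occupancy([_traj(coms)], GRID, burn_in=0)
        assert res.summed_grid.sum() == pytest.approx(1.0)


class TestOverflowProportion:
    def test_all_stationary_zero(self):
        trajs = [_traj(np.tile(GRID.site_centers[1, 1], (20, 1)))
                 for _ in range(5)]
        pct, _ = overflow_proportion(trajs, GRID)
        assert pct == 0.0

    def test_three_of_twenty_escape(self):
        stay = np.tile(GRID.site_centers[1, 1], (20, 1))
        gone = stay.copy()
        gone[10:] = [25.0, 0, 0]
        trajs = [_traj(stay) for _ in range(17)] + [_traj(gone) for _ in range(3)]
        pct, (lo, hi) = overflow_proportion(trajs, GRID)
        assert pct == pytest.approx(15.0)
        assert lo <= 15.0 <= hi

    def test_monotone_in_shrinking_margin(self, rng):
        walks = gen_random_walk_trajectories(n=100, n_frames=100, step_sd=0.3,
                                             absorbing_bound=np.inf, seed=3)
        pcts = []
        for spacing in (1.6, 1.2, 0.8, 0.4):
            grid = square_grid(spacing=spacing)
            pcts.append(overflow_proportion(walks, grid)[0])
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ModelValidationError):
            overflow_proportion([], GRID)

    def test_matches_markov_chain_absorption_oracle(self):
        """Gaussian random walks with a square absorbing boundary: the
        observed overflow fraction sits inside the binomial CI around
        the transition-matrix absorption probability (the x/y components
        are independent, so 2-D survival is the 1-D survival squared)."""
        n, n_frames, sd, bound = 500, 120, 0.22, 1.5
        walks = gen_random_walk_trajectories(n=n, n_frames=n_frames, step_sd=sd,
                                             absorbing_bound=bound, seed=9)
        grid = square_grid(spacing=2 * bound / 3)
        pct, _ = overflow_proportion(walks, grid)

        m = 801
        x = np.linspace(-bound, bound, m)
        dx = x[1] - x[0]
        kernel = np.exp(-((x[:, None] - x[None, :]) ** 2) / (2 * sd**2)) \
            / (sd * np.sqrt(2 * np.pi)) * dx
        p = np.zeros(m)
        p[m // 2] = 1.0
        for _ in range(n_frames):
            p = kernel @ p
        survive_1d = p.sum()
        p_escape = 100 * (1 - survive_1d**2)
        se = 100 * np.sqrt(p_escape / 100 * (1 - p_escape / 100) / n)
        assert abs(pct - p_escape) < 3 * se + 0.5


class TestContactMap:
    def _full_traj(self, frames, model):
        frames = np.asarray(frames, dtype=float)
        return Trajectory(
            metadata={"params_digest": "d"},
            steps=np.arange(1, len(frames) + 1, dtype=np.int64),
            com_low=frames.mean(axis=1),
            full_steps=np.arange(1, len(frames) + 1, dtype=np.int64),
            full_positions=frames,
            mobile_idx=np.arange(model.n_beads),
            base_positions=model.positions.copy(),
            model=model,
        )

    def _model(self, n):
        return BeadModel(
            chain_id=["M"] * (n // 2) + ["T"] * (n - n // 2),
            residue_index=np.arange(1, n + 1, dtype=np.int64),
            residue_name=["LYS"] * (n // 2) + ["GLU"] * (n - n // 2),
            positions=np.zeros((n, 3)),
            charges=np.zeros(n),
            group=["mtbd_low"] * (n // 2) + ["tail"] * (n - n // 2),
        )

    def test_distant_selections_zero_map(self):
        model = self._model(4)
        frames = np.tile([[0, 0, 0], [0.5, 0, 0], [5, 0, 0], [5.5, 0, 0]],
                         (10, 1, 1))
        traj = self._full_traj(frames, model)
        cm = contact_map(traj, [0, 1], [2, 3], cutoff=1.0)
        assert cm.counts.sum() == 0

    def test_pair_within_cutoff_counts_frames(self):
        model = self._model(2)
        frames = np.tile([[0, 0, 0], [0.9, 0, 0]], (10, 1, 1))
        traj = self._full_traj(frames, model)
        cm = contact_map(traj, [0], [1], cutoff=1.0)
        assert cm.counts[0, 0] == 10

    def test_matches_brute_force_on_toy_trajectory(self, rng):
        model = self._model(6)
        frames = rng.uniform(0, 2.0, (5, 6, 3))
        traj = self._full_traj(frames, model)
        cm = contact_map(traj, [0, 1, 2], [3, 4, 5], cutoff=1.0)
        for ri, i in enumerate([0, 1, 2]):
            for ci, j in enumerate([3, 4, 5]):
                expected = sum(
                    np.linalg.norm(fr[i] - fr[j]) <= 1.0 for fr in frames
                )
                assert cm.counts[ri, ci] == expected

    def test_frame_order_invariance(self, rng):
        model = self._model(4)
        frames = rng.uniform(0, 1.5, (8, 4, 3))
        t1 = self._full_traj(frames, model)
        t2 = self._full_traj(frames[::-1], model)
        c1 = contact_map(t1, [0, 1], [2, 3])
        c2 = contact_map(t2, [0, 1], [2, 3])
        np.testing.assert_array_equal(c1.counts, c2.counts)

    def test_empty_selection_rejected(self):
        model = self._model(4)
        traj = self._full_traj(np.zeros((1, 4, 3)) + np.arange(4)[None, :, None],
                               model)
        with pytest.raises(ModelValidationError):
            contact_map(traj, [], [2, 3])


class TestDiffContactMap:
    def _cm(self, counts, rows, cols, n_frames=10):
        return ContactMap(rows=list(rows), cols=list(cols),
                          counts=np.asarray(counts), n_frames=n_frames,
                          cutoff=1.0)

    def test_identical_maps_zero_delta(self):
        cm = self._cm([[3, 1], [0, 2]], ["K1", "K2"], ["E1", "E2"])
        d = diff_contact_map(cm, cm)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_swap_negates(self):
        a = self._cm([[3, 1], [0, 2]], ["K1", "K2"], ["E1", "E2"])
        b = self._cm([[1, 1], [4, 0]], ["K1", "K2"], ["E1", "E2"])
        d1 = diff_contact_map(a, b)
        d2 = diff_contact_map(b, a)
        np.testing.assert_allclose(d1.delta, -d2.delta)

    def test_terminal_tyr_column_dropped(self):
        y = self._cm([[3, 1, 2]], ["K1"], ["E450", "Y451", "E423"])
        dy = self._cm([[5, 1]], ["K1"], ["E450", "E423"])
        d = diff_contact_map(dy, y, terminal_label="Y451")
        assert d.cols == ["E450", "E423"]
        np.testing.assert_allclose(d.delta, [[0.2, -0.1]])

    def test_other_label_mismatch_rejected(self):
        y = self._cm([[3]], ["K1"], ["E450"])
        dy = self._cm([[5]], ["K1"], ["E999"])
        with pytest.raises(ModelValidationError):
            diff_contact_map(dy, y, terminal_label="Y451")


class TestLeadingHeadFraction:
    def _two_head(self, low_x, high_x):
        n = len(low_x)
        t = _traj(np.column_stack([low_x, np.zeros(n), np.zeros(n)]))
        t.com_high = np.column_stack([high_x, np.zeros(n), np.zeros(n)])
        return t

    def test_always_ahead(self):
        t = self._two_head([2, 2, 2], [1, 1, 1])
        assert leading_head_fraction(t, [1, 0, 0]) == 1.0

    def test_hand_built_three_of_four(self):
        t = self._two_head([2, 2, 0, 2], [1, 1, 1, 1])
        assert leading_head_fraction(t, [1, 0, 0]) == 0.75

    def test_symmetric_walk_near_half(self, rng):
        """Single-walk occupation follows the arcsine law (broad), but
        the mean over many symmetric walks is 1/2."""
        fracs = []
        for _ in range(300):
            x = np.cumsum(rng.normal(0, 1, 300))
            t = self._two_head(x, np.zeros(300))
            fracs.append(leading_head_fraction(t, [1, 0, 0]))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.06)

    def test_missing_high_series_rejected(self):
        t = _traj([[0, 0, 0]])
        with pytest.raises(ModelValidationError):
            leading_head_fraction(t, [1, 0, 0])
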