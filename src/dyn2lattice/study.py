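"""High-level reduced-scale study drivers.

The reduced campaign is the desk-scale version of the full simulation
protocol: 2 tail states × 3 initial positions × ``n_seeds`` seeds at
10⁵ steps per run (the full protocol is 20 seeds × 3×10⁷ steps), on the
packaged toy motor and 4-PF × 3-dimer lattice.  It preserves the
protocol's structure — burn-in fraction, per-position accounting,
trajectory-level overflow — while staying runnable on one CPU in
minutes.
"""

from __future__ import annotations

import numpy as np

from .analysis import OVERFLOW, _site_series, occupancy, overflow_proportion
from .engine import run_campaign
from .lattice import SiteGrid
from .params import ForceField
from .synthetic import campaign_grid, scaled_params


def reduced_campaign(base_seed: int = 0, n_seeds: int = 10,
                     states=("Y", "dY"), positions=(1, 2, 3),
                     params=None, ff: ForceField | None = None,
                     store_full_stride: int = 0, progress: bool = False):
    """Run the reduced two-state campaign; returns (trajectories,
    manifest, grid)."""
    params = params or scaled_params()
    trajs, manifest = run_campaign(
        states=states, positions=positions, n_seeds=n_seeds, params=params,
        ff=ff, base_seed=base_seed, store_full_stride=store_full_stride,
        progress=progress,
    )
    return trajs, manifest, campaign_grid()


def overflow_flags(trajs, grid: SiteGrid, burn_in: int):
    """Per-trajectory overflow indicator (any post-burn-in frame out)."""
    return np.array([
        any(lab == OVERFLOW for lab in _site_series(t, grid, burn_in))
        for t in trajs
    ])


def campaign_summary(trajs, grid: SiteGrid, burn_in: int,
                     n_boot: int = 2000, seed: int = 0) -> dict:
    """Per-state occupancy and overflow statistics plus the one-sided
    bootstrap test that detyrosination raises the overflow proportion.

    Returns a dict with, per state: the OccupancyResult, the overflow
    percentage and its bootstrap CI, and the summed center-site (1, 1)
    occupancy; plus ``p_overflow_dY_gt_Y``, the bootstrap p-value for
    the one-sided comparison.
    """
    by_state = {}
    for state in sorted({t.metadata["tail_state"] for t in trajs}):
        sub = [t for t in trajs if t.metadata["tail_state"] == state]
        occ = occupancy(sub, grid, burn_in=burn_in)
        pct, ci = overflow_proportion(sub, grid, burn_in=burn_in, seed=seed)
        # center residence over ALL post-burn-in frames (absorbed overflow
        # frames count in the denominator): the direct "tended to stay at
        # (1, 1)" statistic, free of survivor bias
        residence = float(occ.summed_grid[1, 1]) * occ.frames_used \
            / max(occ.frames_total, 1)
        by_state[state] = {
            "occupancy": occ,
            "overflow_percent": pct,
            "overflow_ci": ci,
            "center_occupancy": residence,
            "center_occupancy_non_overflow": float(occ.summed_grid[1, 1]),
            "n_trajectories": len(sub),
        }
    out = {"states": by_state}
    if {"Y", "dY"} <= set(by_state):
        f_y = overflow_flags([t for t in trajs if t.metadata["tail_state"] == "Y"],
                             grid, burn_in)
        f_dy = overflow_flags([t for t in trajs if t.metadata["tail_state"] == "dY"],
                              grid, burn_in)
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            diffs[b] = rng.choice(f_dy, f_dy.size).mean() \
                - rng.choice(f_y, f_y.size).mean()
        # one-sided: P(resampled difference <= 0); +1 smoothing keeps
        # the p-value away from an over-confident zero
        out["p_overflow_dY_gt_Y"] = float((np.sum(diffs <= 0) + 1) / (n_boot + 1))
        out["overflow_difference"] = float(f_dy.mean() - f_y.mean()) * 100.0
    return out
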