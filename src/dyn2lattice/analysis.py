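"""Trajectory statistics: occupancy heatmaps, overflow, contact maps.

The mobile MTBD's center of geometry is assigned per frame to one of the
3×3 binding sites (Voronoi cells clipped to the grid rectangle extended
by half a site spacing per axis, plus a detachment bound on height above
the lattice surface).  A trajectory counts as *overflow* if any
post-burn-in frame leaves the capture region; overflow is absorbing
(frames after the first exit are excluded from grid mass), and the
overflow proportion is the percentage of trajectories that ever
overflow.  Contact maps accumulate, per residue pair, the number of
frames in which the minimum bead–bead distance is within the cutoff
(1.0 nm); differential maps subtract per-frame-normalized Y frequencies
from dY frequencies, so positive entries mean more contact upon
detyrosination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bead_model import BeadModel, ModelValidationError, residue_label
from .engine import Trajectory
from .lattice import SiteGrid

logger = logging.getLogger(__name__)

OVERFLOW = "overflow"


@dataclass
class OccupancyResult:
    """3×3 site-occupancy frequencies plus the overflow percentage."""

    per_position_grid: dict          # position_id -> (3, 3) fractions
    summed_grid: np.ndarray          # (3, 3) fractions over all positions
    overflow_percent: float
    overflow_ci: tuple | None
    n_trajectories: int
    frames_used: int
    frames_total: int


@dataclass
class ContactMap:
    rows: list                       # MTBD residue labels, e.g. K2996
    cols: list                       # tubulin residue labels, e.g. E411
    counts: np.ndarray               # (rows, cols) accumulated contact events
    n_frames: int
    cutoff: float

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / max(self.n_frames, 1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.rows, columns=self.cols)


@dataclass
class DiffContactMap:
    rows: list
    cols: list
    delta: np.ndarray                # freq(dY) − freq(Y)
    annotations: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.delta, index=self.rows, columns=self.cols)


# ----------------------------------------------------------------------
def assign_site(com, grid: SiteGrid):
    """Map a COM (nm) to its (row, col) site, or OVERFLOW.

    The capture region is the grid bounding rectangle in the
    axial/lateral plane extended by the per-axis margins, bounded in
    height by ``detach_height`` above the lattice surface.  Within the
    region the nearest site center (axial/lateral distance) wins; exact
    ties break toward the lower (row, col) index.
    """
    com = np.asarray(com, dtype=float)
    centers = grid.site_centers
    ax = grid.axial_direction
    lat = grid.lateral_direction
    a = float(np.dot(com, ax))
    l = float(np.dot(com, lat))
    a_c = centers @ ax
    l_c = centers @ lat
    if not (a_c.min() - grid.margin_axial <= a <= a_c.max() + grid.margin_axial):
        return OVERFLOW
    if not (l_c.min() - grid.margin_lateral <= l <= l_c.max() + grid.margin_lateral):
        return OVERFLOW
    height = float(com[2]) - grid.surface_z
    if height > grid.detach_height:
        return OVERFLOW
    d2 = (a_c - a) ** 2 + (l_c - l) ** 2
    flat = int(np.argmin(d2))   # argmin returns the first (lowest) index on ties
    return (flat // 3, flat % 3)


def _site_series(traj: Trajectory, grid: SiteGrid, burn_in: int):
    """Per-frame site labels after burn-in, absorbing at first overflow."""
    mask = traj.steps > burn_in
    labels = []
    overflowed = False
    for com in traj.com_low[mask]:
        if overflowed:
            labels.append(OVERFLOW)
            continue
        site = assign_site(com, grid)
        if site == OVERFLOW:
            overflowed = True
        labels.append(site)
    return labels


def occupancy(trajs, grid: SiteGrid, burn_in: int) -> OccupancyResult:
    """Accumulate per-position and summed 3×3 frequency grids.

    Frames at steps ≤ ``burn_in`` are excluded.  Grids are normalized
    over the retained frames of non-overflow segments; overflow mass is
    reported separately as a percentage of trajectories.  Trajectories
    shorter than the burn-in are excluded with a warning.
    """
    if not trajs:
        raise ModelValidationError("no trajectories")
    digests = {t.metadata.get("params_digest") for t in trajs}
    if len(digests) > 1:
        raise ModelValidationError("trajectories have mixed params digests")
    kept = []
    for t in trajs:
        if t.steps[-1] <= burn_in:
            logger.warning("trajectory shorter than burn-in excluded")
            continue
        kept.append(t)
    if not kept:
        raise ModelValidationError("all trajectories shorter than burn-in")

    per_pos_counts = {}
    total = np.zeros((3, 3))
    frames_used = 0
    frames_total = 0
    n_overflow = 0
    for t in kept:
        labels = _site_series(t, grid, burn_in)
        frames_total += len(labels)
        pos_id = t.metadata.get("position_id")
        g = per_pos_counts.setdefault(pos_id, np.zeros((3, 3)))
        hit = False
        for lab in labels:
            if lab == OVERFLOW:
                hit = True
                continue
            g[lab] += 1
            total[lab] += 1
            frames_used += 1
        if hit:
            n_overflow += 1
    per_position = {
        k: (v / v.sum() if v.sum() > 0 else v) for k, v in per_pos_counts.items()
    }
    summed = total / total.sum() if total.sum() > 0 else total
    return OccupancyResult(
        per_position_grid=per_position,
        summed_grid=summed,
        overflow_percent=100.0 * n_overflow / len(kept),
        overflow_ci=None,
        n_trajectories=len(kept),
        frames_used=frames_used,
        frames_total=frames_total,
    )


def overflow_proportion(trajs, grid: SiteGrid, burn_in: int = 0,
                        n_boot: int = 1000, ci: float = 0.95, seed: int = 0):
    """Percentage of trajectories that ever leave the capture region
    after burn-in, with a percentile bootstrap CI over trajectories.

    Returns ``(percent, (lo, hi))``.
    """
    if not trajs:
        raise ModelValidationError("no trajectories")
    flags = np.array([
        any(lab == OVERFLOW for lab in _site_series(t, grid, burn_in))
        for t in trajs
    ])
    pct = 100.0 * flags.mean()
    rng = np.random.default_rng(seed)
    n = len(flags)
    boots = 100.0 * rng.choice(flags, size=(n_boot, n), replace=True).mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return pct, (float(lo), float(hi))


# ----------------------------------------------------------------------
def _residue_groups(model: BeadModel, bead_idx):
    """Group bead indices by residue identity, aggregating the copies of
    a residue across chains (the maps are residue-level: one row/column
    per residue label, as E411 or K2996, regardless of which tubulin
    copy is contacted)."""
    order = {}
    for i in bead_idx:
        key = (model.residue_name[i], int(model.residue_index[i]))
        order.setdefault(key, []).append(int(i))
    labels = [residue_label(name, ri) for (name, ri) in order]
    return labels, list(order.values())


def contact_map(traj: Trajectory, mtbd_selection, tubulin_selection,
                cutoff: float = 1.0) -> ContactMap:
    """Accumulate residue-pair contacts over full-bead frames.

    A contact event is a frame in which the minimum bead–bead distance
    between the two residues is ≤ ``cutoff`` (nm).  Requires a
    trajectory stored with full bead positions.
    """
    if traj.full_positions is None or traj.model is None:
        raise ModelValidationError("trajectory lacks full-bead frames")
    mtbd_selection = np.asarray(mtbd_selection, dtype=int)
    tubulin_selection = np.asarray(tubulin_selection, dtype=int)
    if mtbd_selection.size == 0 or tubulin_selection.size == 0:
        raise ModelValidationError("empty selection")
    model = traj.model
    rows, row_beads = _residue_groups(model, mtbd_selection)
    cols, col_beads = _residue_groups(model, tubulin_selection)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    pos_full = traj.base_positions.copy()
    mob = traj.mobile_idx
    for frame in traj.full_positions:
        pos_full[mob] = frame
        for ri, rb in enumerate(row_beads):
            p_r = pos_full[rb]
            for ci, cb in enumerate(col_beads):
                d = np.linalg.norm(p_r[:, None, :] - pos_full[cb][None, :, :], axis=2)
                if d.min() <= cutoff:
                    counts[ri, ci] += 1
    return ContactMap(rows=rows, cols=cols, counts=counts,
                      n_frames=len(traj.full_positions), cutoff=cutoff)


def merge_contact_maps(maps) -> ContactMap:
    """Sum contact maps with identical labels (e.g. across seeds)."""
    first = maps[0]
    for m in maps[1:]:
        if m.rows != first.rows or m.cols != first.cols:
            raise ModelValidationError("contact maps have mismatched labels")
    return ContactMap(
        rows=first.rows, cols=first.cols,
        counts=np.sum([m.counts for m in maps], axis=0),
        n_frames=int(np.sum([m.n_frames for m in maps])),
        cutoff=first.cutoff,
    )


def diff_contact_map(map_dY: ContactMap, map_Y: ContactMap,
                     terminal_label: str | None = None,
                     annotations: dict | None = None) -> DiffContactMap:
    """Per-frame-normalized difference freq(dY) − freq(Y).

    The terminal-tyrosine row/column (absent in the dY condition) is
    dropped from the Y map before subtraction when ``terminal_label``
    is given (e.g. ``"Y451"``); any other label mismatch is an error.
    Positive entries mean more contact upon detyrosination.
    """
    fy = map_Y.frequencies
    fd = map_dY.frequencies
    rows_y, cols_y = list(map_Y.rows), list(map_Y.cols)
    rows_d, cols_d = list(map_dY.rows), list(map_dY.cols)

    def _align(labels_a, labels_b):
        sa, sb = set(labels_a), set(labels_b)
        extra = (sa - sb) | (sb - sa)
        for lab in extra:
            if terminal_label is None or lab != terminal_label:
                raise ModelValidationError(
                    f"label mismatch beyond terminal TYR: {lab!r}")
        shared = [lab for lab in labels_a if lab in sb]
        return shared

    rows = _align(rows_d, rows_y)
    cols = _align(cols_d, cols_y)
    ry = [rows_y.index(r) for r in rows]
    cy = [cols_y.index(c) for c in cols]
    rd = [rows_d.index(r) for r in rows]
    cd = [cols_d.index(c) for c in cols]
    delta = fd[np.ix_(rd, cd)] - fy[np.ix_(ry, cy)]
    return DiffContactMap(rows=rows, cols=cols, delta=delta,
                          annotations=dict(annotations or {}))


def leading_head_fraction(traj: Trajectory, axis, burn_in: int = 0) -> float:
    """Fraction of post-burn-in frames in which the mobile low-affinity
    head is ahead of the fixed high-affinity head along ``axis`` (the
    minus-end / movement direction)."""
    if traj.com_high is None:
        raise ModelValidationError("trajectory lacks the high-affinity COM series")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    mask = traj.steps > burn_in
    if not mask.any():
        raise ModelValidationError("no frames after burn-in")
    a_low = traj.com_low[mask] @ axis
    a_high = traj.com_high[mask] @ axis
    return float(np.mean(a_low > a_high))
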