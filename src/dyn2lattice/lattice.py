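"""Idealized tubulin-lattice and dimer-placement geometry.

The simulated system mirrors a small patch of microtubule wall: four
straight parallel protofilaments (PFs) of three αβ-tubulin dimers each,
with B-lattice stagger, every α-tubulin carrying a flexible, glutamate-
rich C-terminal tail (E-hook) that can be tyrosinated (Y, ends in Tyr)
or detyrosinated (dY, terminal Tyr removed so the exposed Glu carries
both its side-chain charge and the free carboxylate).

Geometry defaults (all config-overridable): 8.2 nm axial rise per dimer,
5.2 nm lateral PF spacing, 0.92 nm B-lattice stagger, straight PFs (no
supertwist or curvature).  Coordinate convention is right-handed with
the axial direction (+x) pointing toward the microtubule minus end —
the direction of dynein movement — the lateral direction +y, and the
outward surface normal +z.  Residue indexing is 1-based as in the PDB;
the α-tubulin tail occupies indices ending at 451 (the terminal Tyr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bead_model import (
    AA1TO3,
    BeadModel,
    ModelValidationError,
    assign_charges,
)

logger = logging.getLogger(__name__)

#: α-tubulin C-terminal tail default: the disordered E-hook proper (the
#: last 12 residues of the α-tubulin sequence, ending at Tyr451); the
#: upstream C-terminal residues belong to helix H12 and stay in the
#: rigid body.
DEFAULT_TAIL_SEQUENCE = "AEGAGEGEGEEY"
TAIL_END_INDEX = 451


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform bead shell of ``n`` points."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class LatticeSpec:
    """Builder parameters for the idealized CG tubulin lattice."""

    n_pf: int = 4
    n_dimers_per_pf: int = 3
    axial_rise_per_dimer: float = 8.2   # nm
    lateral_spacing: float = 5.2        # nm
    stagger: float = 0.92               # nm, B-lattice offset between PFs
    beads_per_monomer: int = 20
    monomer_radius: float = 2.0         # nm
    tail_sequence: str = DEFAULT_TAIL_SEQUENCE
    tail_state: str = "Y"
    tail_bond_length: float = 0.38      # nm, Cα–Cα virtual bond

    def validate(self) -> "LatticeSpec":
        if self.n_pf < 1 or self.n_dimers_per_pf < 1:
            raise ModelValidationError("n_pf and n_dimers_per_pf must be >= 1")
        if self.axial_rise_per_dimer <= 0 or self.lateral_spacing <= 0:
            raise ModelValidationError("spacings must be > 0")
        if self.beads_per_monomer < 1 or self.monomer_radius <= 0:
            raise ModelValidationError("monomer body parameters must be positive")
        if not self.tail_sequence:
            raise ModelValidationError("tail_sequence must be non-empty")
        if self.tail_state not in ("Y", "dY"):
            raise ModelValidationError("tail_state must be 'Y' or 'dY'")
        bad = [a for a in self.tail_sequence if a not in AA1TO3]
        if bad:
            raise ModelValidationError(f"unknown amino acids in tail: {bad}")
        return self


@dataclass
class SiteGrid:
    """3×3 grid of dynein binding sites, (row, col) with center (1, 1).

    Rows run laterally (one row per PF), columns axially (one column per
    tubulin dimer).  ``axial_direction`` points toward the minus end.
    The capture region is the Voronoi cell of each center clipped to the
    grid bounding rectangle extended by half a site spacing per axis,
    with a detachment bound on height above the lattice surface.
    """

    site_centers: np.ndarray            # (3, 3, 3) nm
    axial_direction: np.ndarray         # unit vector
    lateral_direction: np.ndarray       # unit vector
    margin_axial: float                 # nm
    margin_lateral: float               # nm
    surface_z: float                    # nm, top of the tubulin bodies
    detach_height: float = 6.0          # nm above surface_z counts as detached

    @property
    def margin(self) -> float:
        """Mean capture half-width beyond the outer site centers, nm."""
        return 0.5 * (self.margin_axial + self.margin_lateral)

    def validate(self) -> "SiteGrid":
        a, l = self.axial_direction, self.lateral_direction
        if abs(np.dot(a, l)) > 1e-9:
            raise ModelValidationError("axial and lateral directions must be orthogonal")
        for v in (a, l):
            if abs(np.linalg.norm(v) - 1) > 1e-9:
                raise ModelValidationError("grid directions must be unit vectors")
        return self


@dataclass
class PlacementSpec:
    """Initial placement of the high-affinity head relative to the
    low-affinity head on the neighboring PF: 1 = backward (trailing),
    2 = lateral (zero axial offset), 3 = forward (leading, one site
    toward the minus end), mirroring the cryo-ET configuration classes."""

    position_id: int = 2

    #: axial site offset of the high-affinity head, in units of the dimer rise
    OFFSETS = {1: -1, 2: 0, 3: +1}

    def validate(self) -> "PlacementSpec":
        if self.position_id not in (1, 2, 3):
            raise ModelValidationError("position_id must be 1, 2 or 3")
        return self

    @property
    def axial_offset_sites(self) -> int:
        return self.OFFSETS[self.position_id]


# ----------------------------------------------------------------------
def _monomer(kind: str, chain: str, center: np.ndarray, spec: LatticeSpec) -> BeadModel:
    """One rigid tubulin monomer body as a bead shell.

    For α-tubulin the topmost (outward-facing) bead is the H12/C-terminal
    tail attachment point (index 430) and the next three outward beads are
    the acidic surface residues E411/E420/E423 that line the dynein
    binding site.
    """
    n = spec.beads_per_monomer
    shell = _fibonacci_sphere(n, spec.monomer_radius) + center
    order = np.argsort(-shell[:, 2])  # outward-most first
    names = ["GLY"] * n
    resid = [0] * n
    if kind == "alpha":
        special = [("GLY", 430), ("GLU", 411), ("GLU", 420), ("GLU", 423)]
        for rank, (nm_, ri) in enumerate(special[: min(4, n)]):
            names[order[rank]] = nm_
            resid[order[rank]] = ri
    filler = 1
    for i in range(n):
        if resid[i] == 0:
            resid[i] = filler
            filler += 1
    group = "alpha_tubulin" if kind == "alpha" else "beta_tubulin"
    bonds = np.zeros((0, 2), dtype=np.int64)  # rigid body: no backbone springs
    return BeadModel(
        chain_id=[chain] * n,
        residue_index=np.asarray(resid, dtype=np.int64),
        residue_name=names,
        positions=shell,
        charges=np.zeros(n),
        group=[group] * n,
        bonds=bonds,
    )


def _attach_tail(model: BeadModel, chain: str, spec: LatticeSpec) -> BeadModel:
    """Append the flexible E-hook chain to an α-tubulin monomer model."""
    seq = spec.tail_sequence
    candidates = [i for i in model.chain_beads(chain) if model.residue_index[i] == 430]
    if not candidates:
        raise ModelValidationError(f"chain {chain!r} has no tail attachment bead")
    attach = model.positions[candidates[0]]
    # Initial conformation: the E-hook arches from the α-tubulin crest
    # toward the adjacent dynein binding site (+x), as in the docked
    # MTBD–tubulin complex where the C-terminal tail lies against the
    # MTBD rim.  Native contacts of the placed complex are computed from
    # this conformation, so the terminal tyrosine is part of the native
    # interface of the tyrosinated lattice.
    n = len(seq)
    # two straight segments: up and sideways off the crest, then over
    # toward the binding-site rim, skirting the motor body laterally
    seg1 = np.array([0.3, 2.4, 0.8])
    seg2 = np.array([2.4, -0.35, -0.3])
    l1, l2 = np.linalg.norm(seg1), np.linalg.norm(seg2)
    n1 = max(1, min(n, round(n * l1 / (l1 + l2))))
    dirs = [seg1 / l1] * n1 + [seg2 / l2] * (n - n1)
    start = TAIL_END_INDEX - len(seq) + 1
    n0 = model.n_beads
    pos = np.empty((n, 3))
    p = attach.copy()
    for k in range(n):
        p = p + dirs[k] * spec.tail_bond_length
        pos[k] = p
    tail = BeadModel(
        chain_id=[chain] * len(seq),
        residue_index=np.arange(start, start + len(seq), dtype=np.int64),
        residue_name=[AA1TO3[a] for a in seq],
        positions=pos,
        charges=np.zeros(len(seq)),
        group=["tail"] * len(seq),
    )
    out = BeadModel(
        chain_id=list(model.chain_id) + list(tail.chain_id),
        residue_index=np.concatenate([model.residue_index, tail.residue_index]),
        residue_name=list(model.residue_name) + list(tail.residue_name),
        positions=np.vstack([model.positions, tail.positions]),
        charges=np.concatenate([model.charges, tail.charges]),
        group=list(model.group) + list(tail.group),
        bonds=model.bonds.copy(),
        native_contacts=model.native_contacts.copy(),
        native_r0=model.native_r0.copy(),
        tethers=model.tethers.copy(),
        tether_r0=model.tether_r0.copy(),
    )
    attach_idx = [i for i in out.chain_beads(chain) if out.residue_index[i] == 430][0]
    new_bonds = [[attach_idx, n0]] + [[n0 + k, n0 + k + 1] for k in range(len(seq) - 1)]
    out.bonds = np.vstack([out.bonds, np.asarray(new_bonds, dtype=np.int64)])
    return out


def build_lattice(spec: LatticeSpec) -> BeadModel:
    """Construct the idealized CG tubulin lattice (deterministic).

    Returns ``n_pf × n_dimers_per_pf`` tubulin dimers, each α-tubulin
    carrying a flexible tail of ``spec.tail_sequence`` in the requested
    tyrosination state, with charges assigned.
    """
    spec.validate()
    parts = []
    half = spec.axial_rise_per_dimer / 2.0
    for p in range(spec.n_pf):
        for d in range(spec.n_dimers_per_pf):
            x = d * spec.axial_rise_per_dimer + p * spec.stagger
            y = p * spec.lateral_spacing
            alpha = _monomer("alpha", f"A{p}.{d}", np.array([x, y, 0.0]), spec)
            alpha = _attach_tail(alpha, f"A{p}.{d}", spec)
            beta = _monomer("beta", f"B{p}.{d}", np.array([x + half, y, 0.0]), spec)
            parts.extend([alpha, beta])
    model = assign_charges(BeadModel.concat(parts)).validate()
    if spec.tail_state == "dY":
        model = set_tyrosination(model, "dY")
    return model


# ----------------------------------------------------------------------
def set_tyrosination(model: BeadModel, state: str, chains=None) -> BeadModel:
    """Set the tyrosination state of the selected tail chains.

    ``state='dY'`` removes the final residue of each selected tail iff it
    is TYR and moves the free-carboxylate −1 to the newly exposed
    terminal residue (via charge reassignment).  ``state='Y'`` is the
    identity on already-tyrosinated tails; applying it to a tail that
    does not end in Tyr only logs a warning (residues are never added).
    Applying 'dY' to a tail not ending in TYR is an explicit error.
    """
    if state not in ("Y", "dY"):
        raise ModelValidationError("state must be 'Y' or 'dY'")
    if chains is None:
        chains = sorted({model.chain_id[i] for i in model.group_beads("tail")})
    out = model.copy()
    drop = []
    for chain in chains:
        idx = out.chain_beads(chain)
        if idx.size == 0:
            raise ModelValidationError(f"no beads on chain {chain!r}")
        cterm = int(idx[np.argmax(out.residue_index[idx])])
        is_tyr = out.residue_name[cterm] == "TYR"
        if state == "Y":
            if not is_tyr:
                logger.warning(
                    "chain %s already detyrosinated; set_tyrosination('Y') is a no-op",
                    chain,
                )
            continue
        if not is_tyr:
            raise ModelValidationError(
                f"chain {chain!r} C-terminal residue is "
                f"{out.residue_name[cterm]}, not TYR: cannot detyrosinate"
            )
        drop.append(cterm)
    if not drop:
        return out
    keep = np.ones(out.n_beads, dtype=bool)
    keep[drop] = False
    remap = -np.ones(out.n_beads, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))

    def _filter_pairs(pairs, aux=None):
        if len(pairs) == 0:
            return pairs, aux
        ok = keep[pairs[:, 0]] & keep[pairs[:, 1]]
        new = remap[pairs[ok]]
        return new, (aux[ok] if aux is not None else None)

    bonds, _ = _filter_pairs(out.bonds)
    contacts, r0 = _filter_pairs(out.native_contacts, out.native_r0)
    tethers, tr0 = _filter_pairs(out.tethers, out.tether_r0)
    trimmed = BeadModel(
        chain_id=[c for c, k in zip(out.chain_id, keep) if k],
        residue_index=out.residue_index[keep],
        residue_name=[r for r, k in zip(out.residue_name, keep) if k],
        positions=out.positions[keep],
        charges=out.charges[keep],
        group=[g for g, k in zip(out.group, keep) if k],
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        native_contacts=np.asarray(contacts, dtype=np.int64).reshape(-1, 2),
        native_r0=r0 if r0 is not None else np.zeros(0),
        tethers=np.asarray(tethers, dtype=np.int64).reshape(-1, 2),
        tether_r0=tr0 if tr0 is not None else np.zeros(0),
    )
    return assign_charges(trimmed)


# ----------------------------------------------------------------------
def make_site_grid(
    spec: LatticeSpec,
    pf_center: int = 1,
    dimer_center: int = 1,
    face_gap: float = 0.7,
    detach_height: float = 6.0,
) -> SiteGrid:
    """Binding-site grid over the 3×3 patch centered at
    (``pf_center``, ``dimer_center``).

    Each site center sits over the intradimer (α–β) interface at the
    height where the motor's MTBD face rests when bound
    (``surface + face_gap``).
    """
    spec.validate()
    if not (1 <= pf_center <= spec.n_pf - 1) and spec.n_pf > 1:
        raise ModelValidationError("pf_center must leave room for one PF on each side")
    centers = np.zeros((3, 3, 3))
    z = spec.monomer_radius + face_gap
    for r in range(3):
        p = pf_center - 1 + r
        for c in range(3):
            d = dimer_center - 1 + c
            x = d * spec.axial_rise_per_dimer + p * spec.stagger \
                + spec.axial_rise_per_dimer / 4.0
            centers[r, c] = (x, p * spec.lateral_spacing, z)
    return SiteGrid(
        site_centers=centers,
        axial_direction=np.array([1.0, 0.0, 0.0]),
        lateral_direction=np.array([0.0, 1.0, 0.0]),
        margin_axial=spec.axial_rise_per_dimer / 2.0,
        margin_lateral=spec.lateral_spacing / 2.0,
        surface_z=spec.monomer_radius,
        detach_height=detach_height,
    ).validate()


def place_dimer(
    lattice: BeadModel,
    motor_low: BeadModel,
    motor_high: BeadModel,
    placement: PlacementSpec,
    grid: SiteGrid,
    go_cutoff: float = 1.3,
    body_cutoff: float = 1.5,
    tether_r0: float = 6.0,
) -> BeadModel:
    """Insert the two-headed motor onto the lattice.

    The low-affinity MTBD center of geometry is placed at grid site
    (1, 1); the high-affinity MTBD goes on the adjacent PF (the next row)
    at axial site offset −1/0/+1 for positions 1/2/3.  Native (Gō)
    contacts are recorded between the low-affinity face and nearby
    lattice beads at their placed distances; the heads are linked by a
    soft tether between their outward-most beads.  Lattice coordinates
    are never modified.
    """
    placement.validate()
    grid.validate()
    pfs = {c for c in lattice.chains() if c.startswith("A")}
    n_pf = len({c.split(".")[0] for c in pfs})
    n_dim = len({c.split(".")[1] for c in pfs})
    if n_pf < 2 or n_dim < 3:
        raise ModelValidationError("lattice must have >= 2 PFs and >= 3 dimers per PF")

    def _moved(head: BeadModel, face_group: str, target: np.ndarray) -> BeadModel:
        out = head.copy()
        out.positions = out.positions + (target - out.group_com(face_group))
        return out

    low_target = grid.site_centers[1, 1]
    col = 1 + placement.axial_offset_sites
    if not (0 <= col <= 2):
        raise ModelValidationError("placement falls outside the 3x3 grid")
    high_target = grid.site_centers[2, col]
    low = _moved(motor_low, "mtbd_low", low_target)
    high = _moved(motor_high, "mtbd_high", high_target)

    system = BeadModel.concat([lattice, low, high])

    # Gō contacts of the docked complex, per head: motor beads against
    # tubulin-body beads (within body_cutoff) and against the resolved
    # terminal stretch of the E-hook — the last three residues, E-E-Y on
    # a tyrosinated lattice — within go_cutoff.  The terminal tyrosine is
    # therefore part of the native interface; detyrosination
    # (set_tyrosination on the assembled system) deletes that residue
    # and every contact it participates in, while the upstream E-hook
    # stays disordered and purely nonbonded.  Pairs closer than the
    # excluded-volume contact distance stay EV-only.
    n_lat = lattice.n_beads
    lat_idx = np.arange(n_lat)
    is_tail = np.array([g == "tail" for g in system.group[:n_lat]])
    anchor = is_tail & (np.asarray(system.residue_index[:n_lat]) >= TAIL_END_INDEX - 2)
    cutoffs = np.where(is_tail, np.where(anchor, go_cutoff, 0.0), body_cutoff)
    for chain_ids in (sorted({motor_low.chain_id[0]}), sorted({motor_high.chain_id[0]})):
        head_idx = np.concatenate([system.chain_beads(c) for c in chain_ids])
        d = np.linalg.norm(
            system.positions[head_idx][:, None, :]
            - system.positions[lat_idx][None, :, :], axis=2,
        )
        fi, bi = np.nonzero((d < cutoffs[None, :]) & (d >= 0.7))
        if fi.size:
            pairs = np.column_stack([head_idx[fi], lat_idx[bi]]).astype(np.int64)
            system.native_contacts = np.vstack([system.native_contacts, pairs])
            system.native_r0 = np.concatenate([system.native_r0, d[fi, bi]])

    # soft dimerization tether between the outward-most bead of each head
    def _top(chain_ids):
        idx = np.concatenate([system.chain_beads(c) for c in chain_ids])
        return int(idx[np.argmax(system.positions[idx, 2])])

    low_chains = sorted({motor_low.chain_id[0]})
    high_chains = sorted({motor_high.chain_id[0]})
    t = np.array([[_top(low_chains), _top(high_chains)]], dtype=np.int64)
    system.tethers = np.vstack([system.tethers, t])
    system.tether_r0 = np.concatenate([system.tether_r0, [tether_r0]])
    return system.validate()
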