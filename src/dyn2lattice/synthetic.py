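"""Synthetic-data generators with embedded ground truth.

Every pipeline input can be generated here deterministically (pure
function of parameters and seed): the two-headed toy motor, assembled
lattice+motor systems, tomogram head annotations with Poisson linear
densities and known configuration-class proportions, peptide-spectrum
match (PSM) tables with known tyrosinated/detyrosinated/glutamylated
fractions, and analytic random-walk COM trajectories for
occupancy/overflow tests.

The toy motor mimics the low-affinity dynein-2 MTBD at reduced scale: a
quasi-spherical 20-bead rigid body whose lattice-facing cap carries the
basic residues seen at the MTBD–tubulin interface (K2996, R3007, R3041,
R3044, K3077, K3080, R3081); the remaining surface is neutral,
matching dynein-2's comparatively neutral binding face.
"""

from __future__ import annotations

import numpy as np

from .bead_model import BeadModel, ModelValidationError
from .engine import Trajectory
from .lattice import (
    LatticeSpec,
    PlacementSpec,
    SiteGrid,
    _fibonacci_sphere,
    build_lattice,
    make_site_grid,
    place_dimer,
)
from .params import ForceField, SimParams
from .quantify import Head, PSMRecord, TomoAnnotation

#: α-tubulin C-terminal reference (ends at the terminal Tyr); the two
#: C-terminal tryptic peptides are its 21- and 29-residue suffixes.
REFERENCE_TAIL = "EDLAALEKDFEEVGAESAEGAGEGEGEEY"

#: internal tryptic decoy peptides (α-tubulin internal sequences)
INTERNAL_PEPTIDES = ("AVLVDLEPGTMDSVR", "QLFHPEQLITGK", "IHFPLATYAPVISAEK")

#: default MTBD face: (residue name, residue index, charge)
DEFAULT_FACE = (
    ("LYS", 2996, +1),
    ("ARG", 3007, +1),
    ("SER", 3036, 0),
    ("ARG", 3041, +1),
    ("ARG", 3044, +1),
    ("LYS", 3077, +1),
    ("LYS", 3080, +1),
    ("ARG", 3081, +1),
)


# ======================================================================
# toy motor & assembled systems
# ======================================================================

def gen_toy_motor(
    n_body_beads: int = 20,
    face_charges=None,
    tether_length: float = 6.0,
    seed: int = 0,
    radius: float = 1.5,
):
    """Two-headed toy motor: returns ``(low_head, high_head)``.

    Each head is a rigid quasi-spherical shell of ``n_body_beads`` beads
    (radius nm) whose bottom cap is the MTBD binding face.  Face bead
    charges follow ``face_charges`` (default: the basic MTBD residues
    above); charges must be in {−1, 0, +1}.  The tether rest length is
    recorded for ``place_dimer``.  Same seed → identical coordinates.
    """
    if n_body_beads < 4:
        raise ModelValidationError("n_body_beads must be >= 4")
    if face_charges is None:
        face = list(DEFAULT_FACE)
    else:
        face = []
        for k, q in enumerate(face_charges):
            if q not in (-1, 0, 1):
                raise ModelValidationError(f"invalid face charge {q!r}")
            name = {1: "LYS", 0: "SER", -1: "GLU"}[q]
            face.append((name, 3001 + k, q))
    n_face = min(len(face), n_body_beads)
    face = face[:n_face]

    rng = np.random.default_rng(seed)
    shell = _fibonacci_sphere(n_body_beads, radius)
    shell = shell + rng.normal(0.0, 0.02, shell.shape)   # bead-scale jitter
    order = np.argsort(shell[:, 2])                       # bottom cap first

    names = ["GLY"] * n_body_beads
    resid = np.zeros(n_body_beads, dtype=np.int64)
    charges = np.zeros(n_body_beads)
    groups = ["motor_body"] * n_body_beads
    for rank, (name, ri, q) in enumerate(face):
        i = order[rank]
        names[i] = name
        resid[i] = ri
        charges[i] = q
        groups[i] = "FACE"
    filler = 1
    for i in range(n_body_beads):
        if resid[i] == 0:
            resid[i] = filler
            filler += 1

    def _head(chain: str, face_group: str) -> BeadModel:
        return BeadModel(
            chain_id=[chain] * n_body_beads,
            residue_index=resid.copy(),
            residue_name=list(names),
            positions=shell.copy(),
            charges=charges.copy(),
            group=[face_group if g == "FACE" else g for g in groups],
        ).validate()

    low = _head("ML", "mtbd_low")
    high = _head("MH", "mtbd_high")
    low.tether_hint = tether_length  # informational; place_dimer sets the spring
    return low, high


def assemble_toy_system(
    state: str = "Y",
    position: int = 2,
    lattice_spec: LatticeSpec | None = None,
    ff: ForceField | None = None,
    n_body_beads: int = 20,
    motor_seed: int = 0,
) -> BeadModel:
    """Lattice + placed toy dimer for one tail state and initial position."""
    from .lattice import set_tyrosination

    ff = ff or ForceField()
    spec = lattice_spec or LatticeSpec()
    # the native complex is always defined on the tyrosinated lattice;
    # detyrosination edits the assembled system (removing the terminal
    # tyrosine and every native contact it participates in)
    spec = LatticeSpec(**{**spec.__dict__, "tail_state": "Y"})
    lattice = build_lattice(spec)
    grid = make_site_grid(spec)
    low, high = gen_toy_motor(n_body_beads=n_body_beads, seed=motor_seed,
                              tether_length=ff.tether_r0)
    system = place_dimer(lattice, low, high, PlacementSpec(position_id=position),
                         grid, tether_r0=ff.tether_r0)
    if state == "dY":
        system = set_tyrosination(system, "dY")
    return system


def campaign_grid(lattice_spec: LatticeSpec | None = None) -> SiteGrid:
    """The site grid matching :func:`assemble_toy_system`'s lattice."""
    return make_site_grid(lattice_spec or LatticeSpec())


def scaled_params(seed: int = 0) -> SimParams:
    """Reduced-scale campaign protocol: 10⁵ steps per run, the first
    ~1/6 excluded as burn-in (as in the full protocol), 100-step frame
    stride."""
    return SimParams(n_steps=100_000, burn_in_steps=17_000,
                     output_stride=100, seed=seed)


def synthetic_mtbd_pair(rmsd_target_angstrom: float = 1.1, seed: int = 7):
    """Synthetic stand-in pair of MTBD Cα traces with a known optimal RMSD.

    Returns ``(model_a, model_b)``: two 164-residue Cα bead models
    numbered with the dynein-2 (2962–3125) and dynein-1 (3266–3429)
    MTBD ranges.  ``model_b`` equals ``model_a`` plus a deformation
    field that is orthogonal to all rigid-body modes (zero net
    translation and zero net infinitesimal rotation) and scaled to the
    requested RMSD, then an arbitrary rigid motion.  The minimal
    least-squares RMSD between them is therefore the target value to
    within second-order corrections (≪ 0.01 Å).

    This is a synthetic geometry fixture, not real dynein coordinates.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    n = 164
    # smooth helix-like Cα trace, nm
    t = np.arange(n)
    trace = np.column_stack([
        0.23 * np.cos(t * 1.75) + 0.015 * t,
        0.23 * np.sin(t * 1.75) + 0.4 * np.sin(t / 25.0),
        0.15 * t - 0.3 * np.cos(t / 18.0),
    ])
    centered = trace - trace.mean(axis=0)
    disp = rng.normal(size=(n, 3))
    # project out rigid-body modes: translations and rotations about COM
    disp -= disp.mean(axis=0)
    basis = np.zeros((3, n, 3))
    for k, ax in enumerate(np.eye(3)):
        basis[k] = np.cross(np.broadcast_to(ax, (n, 3)), centered)
    for _ in range(3):  # orthogonalize twice for numerical cleanliness
        for k in range(3):
            b = basis[k].ravel()
            disp -= (disp.ravel() @ b) / (b @ b) * basis[k]
        disp -= disp.mean(axis=0)
    target_nm = rmsd_target_angstrom / 10.0
    disp *= target_nm / np.sqrt((disp**2).sum() / n)
    deformed = centered + disp
    rot = Rotation.from_euler("zyx", [35.0, -20.0, 50.0], degrees=True)
    deformed = deformed @ rot.as_matrix().T + np.array([3.0, -2.0, 5.0])

    def _model(pos, chain, start):
        return BeadModel(
            chain_id=[chain] * n,
            residue_index=np.arange(start, start + n, dtype=np.int64),
            residue_name=["ALA"] * n,
            positions=pos,
            charges=np.zeros(n),
            group=["motor_body"] * n,
            bonds=np.column_stack([np.arange(n - 1), np.arange(1, n)]).astype(np.int64),
        ).validate()

    return _model(centered, "A", 2962), _model(deformed, "B", 3266)


# ======================================================================
# tomogram annotations
# ======================================================================

def _place_dimer_heads(cls, center, axis_dir, normal, rng,
                       lateral_sep=5.2, axial_sep=8.2):
    """Head coordinates realizing one configuration class.

    Classes 1/3 put the right head (axis × normal) one dimer ahead /
    behind; class 2 side by side; 'other' laterally coincident."""
    right = np.cross(axis_dir, normal)
    if cls == "other":
        p1 = center + axis_dir * 2.0 + rng.normal(0, 0.15, 3)
        p2 = center - axis_dir * 2.0 + rng.normal(0, 0.15, 3)
        return p1, p2
    off = {1: +axial_sep, 2: 0.0, 3: -axial_sep}[cls]
    p_right = center + right * (lateral_sep / 2) + axis_dir * (off / 2)
    p_left = center - right * (lateral_sep / 2) - axis_dir * (off / 2)
    p_right = p_right + rng.normal(0, 0.3, 3)
    p_left = p_left + rng.normal(0, 0.3, 3)
    return p_right, p_left


def gen_tomo_annotations(
    n_doublets: int = 24,
    axis_length_nm: float = 1000.0,
    rate_A: float = 3.0,
    rate_B: float = 1.0,
    config_probs=(0.163, 0.256, 0.302, 0.279),
    seed: int = 0,
):
    """Synthetic doublet annotations with known ground truth.

    Head counts per tubule are Poisson(rate × length/100); heads come in
    dimer pairs (odd counts leave one unpaired head) whose geometry
    realizes a configuration class sampled from ``config_probs``
    (classes 1, 2, 3, other), so the geometric classifier recovers the
    sampled labels.  Defaults emulate the experimental scale (~900 heads
    over 24 doublets, A-tubule enriched).
    """
    if rate_A < 0 or rate_B < 0:
        raise ModelValidationError("rates must be >= 0")
    probs = np.asarray(config_probs, dtype=float)
    if probs.size != 4 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ModelValidationError("config_probs must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    classes = np.array([1, 2, 3, "other"], dtype=object)
    out = []
    for d in range(n_doublets):
        axis = np.array([[0.0, 0.0, 0.0], [axis_length_nm, 0.0, 0.0]])
        axis_dir = np.array([1.0, 0.0, 0.0])
        heads, normals, labels = [], {}, []
        hid = 0
        did = 0
        for tubule, rate in (("A", rate_A), ("B", rate_B)):
            n_heads = rng.poisson(rate * axis_length_nm / 100.0)
            y_side = 12.0 if tubule == "A" else -12.0
            for _ in range(n_heads // 2):
                cls = classes[rng.choice(4, p=probs)]
                s = rng.uniform(0.05, 0.95) * axis_length_nm
                theta = rng.uniform(0, 2 * np.pi)
                normal = np.array([0.0, np.cos(theta), np.sin(theta)])
                center = np.array([s, y_side, 0.0]) + normal * 10.0
                p1, p2 = _place_dimer_heads(cls, center, axis_dir, normal, rng)
                heads.append(Head(hid, p1, tubule, did))
                heads.append(Head(hid + 1, p2, tubule, did))
                normals[did] = normal
                labels.append(cls if cls == "other" else int(cls))
                hid += 2
                did += 1
            if n_heads % 2:
                s = rng.uniform(0.05, 0.95) * axis_length_nm
                heads.append(Head(hid, np.array([s, y_side, 10.0]), tubule, None))
                hid += 1
        out.append(TomoAnnotation(
            doublet_id=f"synthetic_doublet_{d:02d}",
            axis=axis,
            heads=heads,
            dimer_normals=normals,
            ground_truth={
                "rate_A": rate_A, "rate_B": rate_B,
                "config_probs": probs.tolist(),
                "labels": [str(x) for x in labels],
            },
        ).validate())
    return out


def reference_configuration_annotations(seed: int = 12345):
    """Deterministic 43-dimer annotation set over five doublets with the
    experimentally observed class composition 7 : 11 : 13 : 12
    (Configurations 1 : 2 : 3 : other)."""
    rng = np.random.default_rng(seed)
    composition = [1] * 7 + [2] * 11 + [3] * 13 + ["other"] * 12
    perm = rng.permutation(len(composition))
    composition = [composition[i] for i in perm]
    per_doublet = [9, 9, 9, 8, 8]
    out = []
    k = 0
    for d, n_dim in enumerate(per_doublet):
        axis = np.array([[0.0, 0.0, 0.0], [600.0, 0.0, 0.0]])
        axis_dir = np.array([1.0, 0.0, 0.0])
        heads, normals = [], {}
        for j in range(n_dim):
            cls = composition[k]
            k += 1
            s = 600.0 * (j + 1) / (n_dim + 1)
            theta = rng.uniform(0, 2 * np.pi)
            normal = np.array([0.0, np.cos(theta), np.sin(theta)])
            center = np.array([s, 12.0, 0.0]) + normal * 10.0
            p1, p2 = _place_dimer_heads(cls, center, axis_dir, normal, rng)
            heads.append(Head(2 * j, p1, "A", j))
            heads.append(Head(2 * j + 1, p2, "A", j))
            normals[j] = normal
        out.append(TomoAnnotation(
            doublet_id=f"synthetic_ref43_{d}",
            axis=axis, heads=heads, dimer_normals=normals,
            ground_truth={"composition": "7:11:13:12"},
        ).validate())
    return out


# ======================================================================
# PSM tables
# ======================================================================

def gen_psm_table(
    frac_Y: float = 0.337,
    frac_glu: float = 0.0635,
    n_records: int = 10_000,
    reference_tail: str = REFERENCE_TAIL,
    seed: int = 0,
    internal_fraction: float = 0.25,
):
    """Synthetic PSM records at known tyrosination/glutamylation levels.

    ``n_records`` C-terminal records are drawn tyrosinated with
    probability ``frac_Y`` (peptides are true suffixes of the reference
    tail, with or without the terminal Tyr); internal decoy records are
    appended at ``internal_fraction`` of ``n_records``; every record
    carries the glutamylation flag with probability ``frac_glu``.
    """
    for name, v in (("frac_Y", frac_Y), ("frac_glu", frac_glu)):
        if not (0.0 <= v <= 1.0):
            raise ModelValidationError(f"{name} must be within [0, 1]")
    rng = np.random.default_rng(seed)
    suffix_lengths = (21, len(reference_tail))
    records = []
    for _ in range(n_records):
        tyr = rng.random() < frac_Y
        ln = int(rng.choice(suffix_lengths))
        pep = reference_tail[-ln:]
        if not tyr:
            pep = pep[:-1]
        mods = frozenset({"glutamylation"}) if rng.random() < frac_glu else frozenset()
        records.append(PSMRecord(peptide=pep, count=1.0, mods=mods))
    for _ in range(int(round(internal_fraction * n_records))):
        pep = INTERNAL_PEPTIDES[int(rng.integers(len(INTERNAL_PEPTIDES)))]
        mods = frozenset({"glutamylation"}) if rng.random() < frac_glu else frozenset()
        records.append(PSMRecord(peptide=pep, count=1.0, mods=mods))
    return records


def psm_table_to_csv(records, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "count": [r.count for r in records],
            "mods": [";".join(sorted(r.mods)) for r in records],
        }
    ).to_csv(path, index=False)


def psm_table_from_csv(path):
    import pandas as pd

    df = pd.read_csv(path, keep_default_na=False)
    return [
        PSMRecord(
            peptide=str(row.peptide),
            count=float(row.count),
            mods=frozenset(m for m in str(row.mods).split(";") if m),
        )
        for row in df.itertuples()
    ]


# ======================================================================
# analytic random-walk trajectories
# ======================================================================

def square_grid(spacing: float = 1.0, z: float = 0.0) -> SiteGrid:
    """3×3 grid with equal axial/lateral spacing centered at the origin
    (for the analytic random-walk fixtures)."""
    centers = np.zeros((3, 3, 3))
    for r in range(3):
        for c in range(3):
            centers[r, c] = ((c - 1) * spacing, (r - 1) * spacing, z)
    return SiteGrid(
        site_centers=centers,
        axial_direction=np.array([1.0, 0.0, 0.0]),
        lateral_direction=np.array([0.0, 1.0, 0.0]),
        margin_axial=spacing / 2.0,
        margin_lateral=spacing / 2.0,
        surface_z=z,
        detach_height=6.0,
    ).validate()


def gen_random_walk_trajectories(
    n: int = 500,
    n_frames: int = 200,
    step_sd: float = 0.25,
    absorbing_bound: float = 1.5,
    seed: int = 0,
):
    """Isotropic Gaussian COM random walks from the grid center.

    A walk is absorbed (flagged overflow) the first frame its max-norm
    displacement exceeds ``absorbing_bound``; it then stays outside.
    The matching grid is ``square_grid(spacing = 2·bound/3)`` so the
    capture region is exactly ``|x|,|y| ≤ bound``.
    """
    if n < 1:
        raise ModelValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for w in range(n):
        steps = rng.normal(0.0, step_sd, (n_frames, 2)) if step_sd > 0 \
            else np.zeros((n_frames, 2))
        xy = np.cumsum(steps, axis=0)
        absorbed = np.flatnonzero(np.abs(xy).max(axis=1) > absorbing_bound)
        if absorbed.size:
            first = absorbed[0]
            xy[first + 1:] = xy[first]
        com = np.column_stack([xy, np.zeros(n_frames)])
        out.append(Trajectory(
            metadata={"tail_state": "synthetic", "position_id": 2,
                      "seed": seed + w, "params_digest": "synthetic-walk"},
            steps=np.arange(1, n_frames + 1, dtype=np.int64),
            com_low=com,
        ).validate())
    return out
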