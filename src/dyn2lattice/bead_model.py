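"""One-bead-per-residue coarse-grained model container.

A :class:`BeadModel` holds positions (nm), per-bead charges (elementary
charges), chain/residue bookkeeping, sequential backbone bonds, native
(Gō) contacts, and soft inter-chain tethers.  It is the common currency
between the lattice/motor builders, the Langevin engine and the
trajectory statistics.

Charge convention: ASP/GLU carry −1, LYS/ARG +1, everything else
(including HIS at neutral pH) 0; each chain's C-terminal bead carries one
extra −1 for the free carboxylate.  Detyrosination therefore moves the
terminal −1 onto the exposed glutamate (side chain −1 plus carboxylate
−1) without changing the net tail charge by more than the removed
residue — the charge *position* changes, which is the mechanism the
simulations probe.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

GROUPS = frozenset(
    {
        "alpha_tubulin",
        "beta_tubulin",
        "tail",
        "mtbd_low",
        "mtbd_high",
        "motor_body",
        "tether",
    }
)

#: side-chain charge at neutral pH per 3-letter residue code
RESIDUE_CHARGE = {
    "ALA": 0, "ARG": +1, "ASN": 0, "ASP": -1, "CYS": 0,
    "GLN": 0, "GLU": -1, "GLY": 0, "HIS": 0, "ILE": 0,
    "LEU": 0, "LYS": +1, "MET": 0, "PHE": 0, "PRO": 0,
    "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
}

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3TO1 = {v: k for k, v in AA1TO3.items()}


class ModelValidationError(ValueError):
    """Raised when a BeadModel or builder spec violates an invariant."""


@dataclass
class BeadModel:
    """Columnar one-bead-per-residue model.

    Attributes
    ----------
    chain_id, residue_index, residue_name, group
        Per-bead annotations; ``(chain_id, residue_index)`` is unique.
    positions
        (N, 3) float array, nm.
    charges
        (N,) float array, elementary charges.
    bonds
        (B, 2) int array of bead indices; sequential backbone springs,
        always within one chain.
    native_contacts
        (C, 2) int array of bead indices plus (C,) native distances, nm.
    tethers
        (T, 2) int array of bead indices plus (T,) rest lengths, nm; soft
        inter-chain springs (the dimerization proxy between motor heads).
    """

    chain_id: list
    residue_index: np.ndarray
    residue_name: list
    positions: np.ndarray
    charges: np.ndarray
    group: list
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    native_contacts: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    native_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    tethers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    tether_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def validate(self) -> "BeadModel":
        n = self.n_beads
        if not (len(self.chain_id) == len(self.residue_index) == len(self.residue_name)
                == len(self.group) == len(self.charges) == n):
            raise ModelValidationError("inconsistent per-bead array lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ModelValidationError("non-finite bead positions")
        if len(set(zip(self.chain_id, map(int, self.residue_index)))) != n:
            raise ModelValidationError("(chain_id, residue_index) pairs not unique")
        for g in set(self.group):
            if g not in GROUPS:
                raise ModelValidationError(f"unknown bead group {g!r}")
        if self.native_r0.size and not np.all(self.native_r0 > 0):
            raise ModelValidationError("native distances must be > 0")
        for i, j in self.bonds:
            if self.chain_id[i] != self.chain_id[j]:
                raise ModelValidationError(f"bond {i}-{j} crosses chains")
        return self

    def copy(self) -> "BeadModel":
        return BeadModel(
            chain_id=list(self.chain_id),
            residue_index=self.residue_index.copy(),
            residue_name=list(self.residue_name),
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            group=list(self.group),
            bonds=self.bonds.copy(),
            native_contacts=self.native_contacts.copy(),
            native_r0=self.native_r0.copy(),
            tethers=self.tethers.copy(),
            tether_r0=self.tether_r0.copy(),
        )

    def chains(self) -> list:
        seen = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_beads(self, chain: str) -> np.ndarray:
        return np.flatnonzero(np.array([c == chain for c in self.chain_id]))

    def group_beads(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.array([g == group for g in self.group]))

    def group_com(self, group: str) -> np.ndarray:
        """Unweighted center of geometry of a bead group."""
        idx = self.group_beads(group)
        if idx.size == 0:
            raise ModelValidationError(f"no beads in group {group!r}")
        return self.positions[idx].mean(axis=0)

    # ------------------------------------------------------------------
    @staticmethod
    def concat(models: list) -> "BeadModel":
        """Merge models; chain_ids must be disjoint.  Bead indices of later
        models are shifted; bonds/contacts/tethers are remapped."""
        chains = [c for m in models for c in m.chains()]
        if len(chains) != len(set(chains)):
            raise ModelValidationError("duplicate chain ids in concat")
        offs, off = [], 0
        for m in models:
            offs.append(off)
            off += m.n_beads
        return BeadModel(
            chain_id=[c for m in models for c in m.chain_id],
            residue_index=np.concatenate([m.residue_index for m in models]),
            residue_name=[r for m in models for r in m.residue_name],
            positions=np.vstack([m.positions for m in models]),
            charges=np.concatenate([m.charges for m in models]),
            group=[g for m in models for g in m.group],
            bonds=np.vstack([m.bonds + o for m, o in zip(models, offs)]).astype(np.int64),
            native_contacts=np.vstack(
                [m.native_contacts + o for m, o in zip(models, offs)]
            ).astype(np.int64),
            native_r0=np.concatenate([m.native_r0 for m in models]),
            tethers=np.vstack([m.tethers + o for m, o in zip(models, offs)]).astype(np.int64),
            tether_r0=np.concatenate([m.tether_r0 for m in models]),
        )

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "chain_id": list(self.chain_id),
            "residue_index": self.residue_index.tolist(),
            "residue_name": list(self.residue_name),
            "positions": self.positions.tolist(),
            "charges": self.charges.tolist(),
            "group": list(self.group),
            "bonds": self.bonds.tolist(),
            "native_contacts": self.native_contacts.tolist(),
            "native_r0": self.native_r0.tolist(),
            "tethers": self.tethers.tolist(),
            "tether_r0": self.tether_r0.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(source) -> "BeadModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return BeadModel(
            chain_id=doc["chain_id"],
            residue_index=np.asarray(doc["residue_index"], dtype=np.int64),
            residue_name=doc["residue_name"],
            positions=np.asarray(doc["positions"], dtype=float),
            charges=np.asarray(doc["charges"], dtype=float),
            group=doc["group"],
            bonds=np.asarray(doc["bonds"], dtype=np.int64).reshape(-1, 2),
            native_contacts=np.asarray(doc["native_contacts"], dtype=np.int64).reshape(-1, 2),
            native_r0=np.asarray(doc["native_r0"], dtype=float),
            tethers=np.asarray(doc["tethers"], dtype=np.int64).reshape(-1, 2),
            tether_r0=np.asarray(doc["tether_r0"], dtype=float),
        )

    def to_pdb(self, path) -> None:
        """Write one CA pseudo-atom per bead (positions nm → Å, charge in
        the B-factor column) for visualization."""
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = self.n_beads
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(self.positions, dtype=np.float32) * 10.0
        # PDB chain ids are short; map long internal ids onto A, B, ...
        uniq = self.chains()
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
        cmap = {c: alphabet[i % len(alphabet)] for i, c in enumerate(uniq)}
        arr.chain_id = np.array([cmap[c] for c in self.chain_id])
        arr.res_id = self.residue_index.astype(int)
        arr.res_name = np.array(self.residue_name)
        arr.atom_name = np.array(["CA"] * n)
        arr.element = np.array(["C"] * n)
        arr.set_annotation("b_factor", self.charges.astype(float))
        pdb = PDBFile()
        pdb.set_structure(arr)
        pdb.write(path)


# ----------------------------------------------------------------------
def assign_charges(model: BeadModel) -> BeadModel:
    """Assign per-bead charges from residue identity.

    ASP/GLU → −1, LYS/ARG → +1, all others (including HIS) → 0, plus one
    extra −1 on each chain's C-terminal bead (free carboxylate).
    Idempotent: charges are recomputed from residue names, never
    incremented.
    """
    out = model.copy()
    unknown = [
        (i, rn) for i, rn in enumerate(out.residue_name) if rn not in RESIDUE_CHARGE
    ]
    if unknown:
        raise ModelValidationError(
            "unknown residue codes on beads: "
            + ", ".join(f"#{i}={rn}" for i, rn in unknown[:10])
        )
    q = np.array([RESIDUE_CHARGE[rn] for rn in out.residue_name], dtype=float)
    for chain in out.chains():
        idx = out.chain_beads(chain)
        cterm = idx[np.argmax(out.residue_index[idx])]
        q[cterm] -= 1.0
    out.charges = q
    return out


def residue_label(residue_name: str, residue_index: int) -> str:
    """Field-style residue label, e.g. ('GLU', 411) → 'E411'."""
    return f"{AA3TO1.get(residue_name, 'X')}{int(residue_index)}"
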