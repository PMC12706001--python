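"""Simulation parameters, force-field constants and closed-form energies.

Unit system ("engine units"): length nm, energy kcal/mol, bead mass 1,
time τ = nm·√(mass / (kcal/mol)).  kB = 1.9872041e-3 kcal/(mol·K), so
kBT ≈ 0.596 kcal/mol at 300 K.  The friction coefficient is an opaque
engine-unit value (per unit mass per τ).

The nonbonded model is a simplified structure-based force field:
uniform-ε Gaussian wells on the native binding interface (the form the
published atomic-interaction-based CG force fields use for contacts),
Debye–Hückel screened electrostatics for the charged beads (implicit
solvent, relative dielectric 78, ionic strength 0.1 M, 300 K by
default), and a shifted r⁻¹² excluded-volume repulsion that also
supplies the hard core of native pairs.  The classic 12–10 Gō pair
potential is provided as :func:`go_contact_energy` for analysis and
cross-checks.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

KB = 1.9872041e-3          # kcal/mol/K
_E_CHARGE = 1.602176634e-19     # C
_EPS0 = 8.8541878128e-12        # F/m
_KB_SI = 1.380649e-23           # J/K
_NA = 6.02214076e23             # 1/mol


class ParameterError(ValueError):
    pass


def bjerrum_length(temperature: float, dielectric: float) -> float:
    """Bjerrum length λ_B = e²/(4π ε₀ ε_r kB T), in nm."""
    if temperature <= 0 or dielectric <= 0:
        raise ParameterError("temperature and dielectric must be > 0")
    lb_m = _E_CHARGE**2 / (4 * math.pi * _EPS0 * dielectric * _KB_SI * temperature)
    return lb_m * 1e9


def debye_length(ionic_strength: float, temperature: float, dielectric: float) -> float:
    """Debye screening length λ_D = √(ε ε₀ kB T / (2 NA e² I)), in nm.

    ``ionic_strength`` in mol/L; returns ``inf`` at zero ionic strength.
    """
    if ionic_strength < 0:
        raise ParameterError("ionic_strength must be >= 0")
    if ionic_strength == 0:
        return math.inf
    lb = bjerrum_length(temperature, dielectric)        # nm
    n_tot = 2.0 * ionic_strength * _NA * 1e3 * 1e-27    # ions / nm^3
    kappa2 = 4 * math.pi * lb * n_tot
    return 1.0 / math.sqrt(kappa2)


@dataclass
class SimParams:
    """Protocol parameters.  Defaults are the full-protocol values:
    300 K, ε_r 78, 0.1 M, friction 2.0, 3×10⁷ steps with the first
    5×10⁶ excluded as burn-in.  Reduced-scale campaigns override
    ``n_steps``/``burn_in_steps``/``output_stride``."""

    temperature: float = 300.0       # K
    dielectric: float = 78.0
    ionic_strength: float = 0.1      # mol/L
    friction: float = 2.0            # engine units (per mass per τ)
    n_steps: int = 30_000_000
    burn_in_steps: int = 5_000_000
    timestep: float = 0.05           # τ
    seed: int = 0
    output_stride: int = 100         # steps per saved frame

    def validate(self) -> "SimParams":
        if self.temperature < 0:
            raise ParameterError("temperature must be >= 0")
        if self.dielectric <= 0:
            raise ParameterError("dielectric must be > 0")
        if self.ionic_strength < 0:
            raise ParameterError("ionic_strength must be >= 0")
        if not (self.n_steps > self.burn_in_steps >= 0):
            raise ParameterError("need n_steps > burn_in_steps >= 0")
        if self.output_stride < 1:
            raise ParameterError("output_stride must be >= 1")
        if self.timestep <= 0:
            raise ParameterError("timestep must be > 0")
        return self

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def bjerrum_length(self) -> float:
        return bjerrum_length(self.temperature, self.dielectric)

    @property
    def debye_length(self) -> float:
        return debye_length(self.ionic_strength, self.temperature, self.dielectric)


@dataclass
class ForceField:
    """Force-field constants (energies kcal/mol, lengths nm).

    ``go_epsilon`` sets the depth of each native 12–10 contact; the
    default puts the whole low-affinity binding interface a few kBT deep
    so thermal escape is rare but observable on 10⁵-step runs.
    ``restraint_k`` pins the high-affinity head (a translation-only
    rigid body, like the low-affinity head).
    """

    bead_mass: float = 5.0
    #: engine-units per CafeMol friction unit: the protocol's friction is
    #: quoted in CafeMol units, whose physical mapping is not published;
    #: effective damping is friction × friction_scale per τ
    friction_scale: float = 0.15
    go_epsilon: float = 1.2
    #: width of the Gaussian native-contact wells used by the engine, nm
    contact_width: float = 0.25
    excluded_sigma: float = 0.6
    excluded_epsilon: float = 2.0
    excluded_cutoff_factor: float = 2.0  # cutoff = factor * sigma
    bond_k: float = 100.0
    angle_k: float = 2.0
    angle_cos0: float = -0.64            # cos(130°), gentle chain stiffness
    tether_k: float = 0.2
    tether_r0: float = 6.0
    restraint_k: float = 25.0
    elec_cutoff: float = 3.0             # nm (~3 Debye lengths at 0.1 M)
    box_bound_factor: float = 10.0       # abort bound, × lattice extent

    def validate(self) -> "ForceField":
        for name in ("go_epsilon", "excluded_epsilon", "bond_k", "angle_k",
                     "tether_k", "restraint_k"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.excluded_sigma <= 0 or self.elec_cutoff <= 0:
            raise ParameterError("lengths must be > 0")
        if self.bead_mass <= 0:
            raise ParameterError("bead_mass must be > 0")
        return self

    @property
    def excluded_cutoff(self) -> float:
        return self.excluded_cutoff_factor * self.excluded_sigma


def params_digest(params: SimParams, ff: ForceField) -> str:
    """Stable digest of every physical parameter, for trajectory metadata."""
    doc = {"params": asdict(params), "ff": asdict(ff)}
    doc["params"].pop("seed", None)
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# closed-form pair energies (array-friendly)

def debye_huckel_energy(qi, qj, r, params: SimParams):
    """Screened Coulomb energy kBT·λ_B·qi·qj·exp(−r/λ_D)/r, kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("r must be > 0")
    lb = params.bjerrum_length
    ld = params.debye_length
    screen = np.exp(-r / ld) if math.isfinite(ld) else 1.0
    out = params.kT * lb * np.asarray(qi) * np.asarray(qj) * screen / r
    return out if out.shape else float(out)


def go_contact_energy(r, r0, eps):
    """12–10 Gō potential U = ε(5(r0/r)¹² − 6(r0/r)¹⁰); minimum −ε at r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(np.asarray(r0) <= 0):
        raise ParameterError("r and r0 must be > 0")
    s = np.asarray(r0) / r
    out = eps * (5.0 * s**12 - 6.0 * s**10)
    return out if out.shape else float(out)


def gaussian_contact_energy(r, r0, eps, width):
    """Gaussian native-contact well U = −ε·exp(−(r−r0)²/2w²) — the form
    the engine applies to native contacts (bounded force; the hard core
    comes from the excluded-volume term)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or np.any(np.asarray(r0) <= 0) or width <= 0:
        raise ParameterError("r, r0 and width must be > 0")
    out = -eps * np.exp(-((r - np.asarray(r0)) ** 2) / (2.0 * width**2))
    return out if out.shape else float(out)


def excluded_volume_energy(r, sigma, eps, cutoff=None):
    """Purely repulsive shifted r⁻¹²: ε((σ/r)¹² − (σ/rc)¹²) for r < rc,
    0 beyond; continuous at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("r must be > 0")
    if cutoff is None:
        cutoff = 2.0 * sigma
    shift = (sigma / cutoff) ** 12
    out = np.where(r < cutoff, eps * ((sigma / r) ** 12 - shift), 0.0)
    return out if out.shape else float(out)
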