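"""Non-simulation quantifications: tomogram head densities, dimer
configuration classes, C-terminal peptide tyrosination fractions and
co-pelleting band statistics.

Conventions
-----------
*Configuration classes.*  Looking along the direction of movement (the
minus-end direction) with the microtubule surface below the motor (the
outward normal pointing up at the observer's feet), ``right_dir =
axis_dir × outward_normal``.  The head with the larger projection onto
``right_dir`` is the right head; if the axial offset between the two
heads is within tolerance they are side by side (Configuration 2),
otherwise the right head leading gives Configuration 1 and trailing
gives Configuration 3.  Mirroring across the axial–normal plane swaps
1 ↔ 3.

*Tyrosination fractions.*  A peptide is classified against the
α-tubulin C-terminal reference sequence: a suffix-anchored match ending
at the terminal Tyr is *tyrosinated*; a match ending exactly one
residue short (at the penultimate Glu) is *detyrosinated*; anything
else is an internal peptide.  The tyrosinated/detyrosinated fractions
are computed over C-terminal peptide-spectrum matches only; the
glutamylated fraction over all records.

*Rounding.*  Percentages round half-up to one decimal; protofilament
equivalents round half-up to integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .bead_model import ModelValidationError

CONFIG_CLASSES = (1, 2, 3, "other")


class QuantificationError(ValueError):
    pass


def _round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ======================================================================
# domain records
# ======================================================================

@dataclass
class Head:
    head_id: int
    position: np.ndarray          # nm
    tubule: str                   # "A" or "B"
    dimer_id: int | None = None


@dataclass
class TomoAnnotation:
    """Annotated doublet: axis polyline (ordered toward the minus end),
    heads with tubule assignment, and per-dimer outward normals."""

    doublet_id: str
    axis: np.ndarray                      # (k, 3) nm, polarity = order
    heads: list = field(default_factory=list)
    dimer_normals: dict = field(default_factory=dict)   # dimer_id -> unit 3-vec
    ground_truth: dict = field(default_factory=dict)

    def validate(self) -> "TomoAnnotation":
        if len(self.axis) < 2:
            raise QuantificationError("axis needs >= 2 points")
        axis = np.asarray(self.axis, dtype=float)
        for h in self.heads:
            d = _point_axis_distance(np.asarray(h.position, float), axis)
            if d >= 60.0:
                raise QuantificationError(
                    f"head {h.head_id} is {d:.0f} nm from the axis (>= 60)")
        dimers = {}
        for h in self.heads:
            if h.dimer_id is not None:
                dimers.setdefault(h.dimer_id, []).append(h)
        for did, hh in dimers.items():
            if len(hh) != 2:
                raise QuantificationError(f"dimer {did} has {len(hh)} heads, not 2")
        return self

    @property
    def axis_length(self) -> float:
        axis = np.asarray(self.axis, dtype=float)
        return float(np.linalg.norm(np.diff(axis, axis=0), axis=1).sum())

    @property
    def axis_direction(self) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        v = axis[-1] - axis[0]
        return v / np.linalg.norm(v)

    def dimers(self) -> dict:
        out = {}
        for h in self.heads:
            if h.dimer_id is not None:
                out.setdefault(h.dimer_id, []).append(h)
        return {k: v for k, v in out.items() if len(v) == 2}

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "doublet_id": self.doublet_id,
            "axis": np.asarray(self.axis, float).tolist(),
            "heads": [
                {"head_id": h.head_id, "position": np.asarray(h.position, float).tolist(),
                 "tubule": h.tubule, "dimer_id": h.dimer_id}
                for h in self.heads
            ],
            "dimer_normals": {str(k): np.asarray(v, float).tolist()
                              for k, v in self.dimer_normals.items()},
            "ground_truth": self.ground_truth,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(source) -> "TomoAnnotation":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return TomoAnnotation(
            doublet_id=doc["doublet_id"],
            axis=np.asarray(doc["axis"], float),
            heads=[Head(head_id=h["head_id"], position=np.asarray(h["position"], float),
                        tubule=h["tubule"], dimer_id=h["dimer_id"])
                   for h in doc["heads"]],
            dimer_normals={int(k): np.asarray(v, float)
                           for k, v in doc.get("dimer_normals", {}).items()},
            ground_truth=doc.get("ground_truth", {}),
        ).validate()


@dataclass
class PSMRecord:
    peptide: str
    count: float = 1.0
    mods: frozenset = frozenset()

    def validate(self) -> "PSMRecord":
        if not self.peptide:
            raise QuantificationError("empty peptide")
        if self.count < 0:
            raise QuantificationError("count must be >= 0")
        return self


@dataclass
class DensityStats:
    densities_a: np.ndarray
    densities_b: np.ndarray
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float


def _point_axis_distance(p, axis):
    """Distance from a point to a polyline (segment-wise)."""
    best = np.inf
    for a, b in zip(axis[:-1], axis[1:]):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    return best


# ======================================================================
# densities & group comparison
# ======================================================================

#: accessible protofilaments per tubule: A1 and A10–A13 of the 13
#: A-tubule PFs are occluded (8 accessible); all 10 B-tubule PFs are free
ACCESSIBLE_PF = {"A": (8, 13), "B": (10, 10)}


def head_density(ann: TomoAnnotation, accessible_correction: bool = False):
    """Heads per 100 nm of axis length, per tubule: (density_A, density_B).

    With ``accessible_correction`` the densities are rescaled to the
    accessible protofilaments only (× total/accessible per tubule);
    uncorrected densities are the default report.
    """
    length = ann.axis_length
    if length <= 0:
        raise QuantificationError("zero-length axis")
    n_a = sum(1 for h in ann.heads if h.tubule == "A")
    n_b = sum(1 for h in ann.heads if h.tubule == "B")
    da, db = 100.0 * n_a / length, 100.0 * n_b / length
    if accessible_correction:
        da *= ACCESSIBLE_PF["A"][1] / ACCESSIBLE_PF["A"][0]
        db *= ACCESSIBLE_PF["B"][1] / ACCESSIBLE_PF["B"][0]
    return da, db


def compare_groups(a, b, welch: bool = False) -> DensityStats:
    """Two-sided unpaired Student t test (equal-variance by default,
    Welch by flag), with group means and SDs."""
    import warnings as _warnings

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise QuantificationError("need >= 2 values per group")
    with _warnings.catch_warnings():
        # identical constant groups are a legitimate input (t=0, p=1);
        # scipy warns about the zero-variance moment computation
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # identical constant groups: no separation
        t, p = 0.0, 1.0
    return DensityStats(
        densities_a=a, densities_b=b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        t=t, df=float(df), p=p,
    )


# ======================================================================
# dimer configuration classes
# ======================================================================

def classify_configuration(head_low, head_partner, axis_dir, outward_normal,
                           axial_tol: float = 4.0,
                           lateral_tol: float = 1.0):
    """Classify a two-headed geometry into Configuration 1/2/3/other.

    ``axis_dir`` points toward the minus end (direction of movement),
    ``outward_normal`` radially outward; both unit vectors.  The default
    axial tolerance of 4 nm (half a tubulin dimer repeat) defines "side
    by side"; heads laterally coincident within ``lateral_tol`` are
    degenerate → "other".
    """
    axis_dir = np.asarray(axis_dir, dtype=float)
    outward_normal = np.asarray(outward_normal, dtype=float)
    for v in (axis_dir, outward_normal):
        if np.linalg.norm(v) == 0:
            raise QuantificationError("zero-length direction vector")
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    outward_normal = outward_normal / np.linalg.norm(outward_normal)
    p1 = np.asarray(head_low, dtype=float)
    p2 = np.asarray(head_partner, dtype=float)
    if np.allclose(p1, p2):
        raise QuantificationError("heads coincide")
    right = np.cross(axis_dir, outward_normal)
    lat1, lat2 = float(p1 @ right), float(p2 @ right)
    if abs(lat1 - lat2) <= lateral_tol:
        return "other"
    right_head, left_head = (p1, p2) if lat1 > lat2 else (p2, p1)
    axial_offset = float((right_head - left_head) @ axis_dir)
    if abs(axial_offset) <= axial_tol:
        return 2
    return 1 if axial_offset > 0 else 3


def config_proportions(labels) -> dict:
    """Per-class percentages (100 × count / total), rounded half-up to
    one decimal; every class is reported even at zero."""
    labels = list(labels)
    if not labels:
        raise QuantificationError("no labels")
    total = len(labels)
    out = {}
    for cls in CONFIG_CLASSES:
        out[cls] = _round_half_up(100.0 * labels.count(cls) / total, 1)
    return out


def classify_dimers(ann: TomoAnnotation, axial_tol: float = 4.0) -> list:
    """Classify every complete dimer in an annotation set."""
    axis_dir = ann.axis_direction
    labels = []
    for did, (h1, h2) in sorted(ann.dimers().items()):
        normal = ann.dimer_normals.get(did)
        if normal is None:
            raise QuantificationError(f"dimer {did} lacks an outward normal")
        labels.append(classify_configuration(
            h1.position, h2.position, axis_dir, normal, axial_tol=axial_tol))
    return labels


# ======================================================================
# MS peptide classification
# ======================================================================

def classify_ct_peptide(peptide: str, reference_tail: str) -> str:
    """'tyrosinated' | 'detyrosinated' | 'internal' (see module docs)."""
    if not peptide or not reference_tail:
        raise QuantificationError("empty peptide or reference tail")
    if not reference_tail.endswith("Y"):
        raise QuantificationError("reference tail must end in Y")
    if reference_tail.endswith(peptide):
        return "tyrosinated"
    if reference_tail[:-1].endswith(peptide):
        return "detyrosinated"
    return "internal"


def ptm_fractions(records, reference_tail: str):
    """(tyrosinated %, detyrosinated %, glutamylated %) over PSM records.

    Y/dY fractions are weighted by spectral count over C-terminal
    records only; the glutamylated fraction is over all records.
    Percentages are rounded half-up to one decimal.
    """
    records = [r.validate() for r in records]
    if not records:
        raise QuantificationError("no records")
    w_y = w_dy = 0.0
    w_glu = w_all = 0.0
    for r in records:
        cls = classify_ct_peptide(r.peptide, reference_tail)
        if cls == "tyrosinated":
            w_y += r.count
        elif cls == "detyrosinated":
            w_dy += r.count
        w_all += r.count
        if "glutamylation" in r.mods:
            w_glu += r.count
    ct = w_y + w_dy
    if ct == 0:
        raise QuantificationError("no C-terminal records for Y/dY fractions")
    return (
        _round_half_up(100.0 * w_y / ct, 1),
        _round_half_up(100.0 * w_dy / ct, 1),
        _round_half_up(100.0 * w_glu / w_all, 2),
    )


def pf_equivalents(fraction: float, total_pf: int = 23) -> int:
    """Map a tubulin-pool percentage onto whole protofilaments of the
    doublet (13 A-tubule + 10 B-tubule = 23 by default), half-up."""
    if not (0.0 <= fraction <= 100.0):
        raise QuantificationError("fraction must be within [0, 100]")
    if total_pf < 1:
        raise QuantificationError("total_pf must be >= 1")
    return int(_round_half_up(fraction / 100.0 * total_pf, 0))


# ======================================================================
# co-pelleting bands
# ======================================================================

def binding_fraction(ppt_intensity: float, sup_intensity: float) -> float:
    """Bound fraction ppt/(ppt+sup) from band intensities."""
    if ppt_intensity < 0 or sup_intensity < 0:
        raise QuantificationError("intensities must be >= 0")
    total = ppt_intensity + sup_intensity
    if total == 0:
        raise QuantificationError("both intensities are zero")
    return ppt_intensity / total


def pelleting_stats(bands_a, bands_b, welch: bool = False) -> DensityStats:
    """Replicate bound fractions per construct ((ppt, sup) pairs) and
    the unpaired t test between constructs."""
    fa = [binding_fraction(p, s) for p, s in bands_a]
    fb = [binding_fraction(p, s) for p, s in bands_b]
    return compare_groups(fa, fb, welch=welch)
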