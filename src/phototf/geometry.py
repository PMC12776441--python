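"""Photoreactivity geometry of dipyrimidine steps in DNA structures.

Parameters follow the standard rigid-base description of nucleic acid
geometry: a reference frame is fitted to each base by least-squares
superposition of an idealized planar base onto the observed ring atoms, and
relative placements (shift/slide/rise, tilt/roll/twist for steps;
shear/stretch/stagger, buckle/propeller/opening for pairs) are read off in
the symmetric mid-frame. On top of these, the module measures the
photodimer-specific distances: d22 (between the C5-C6 bond midpoints of
adjacent pyrimidines, the bond pair fused in a CPD) and d64 (from the 5'
pyrimidine C5 to the 3' base's O4/N4, the atoms joined through the
oxetane/azetidine intermediate of 6-4 PP formation), the projected ring
stacking overlap, the interbase angle sqrt(propeller^2 + buckle^2), and the
Altona-Sundaralingam sugar pseudorotation phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import gemmi
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon

__all__ = [
    "StructureModel",
    "Residue",
    "BaseFrame",
    "SugarPucker",
    "DipyrimidineGeometry",
    "load_structure",
    "confidence_filter",
    "d22",
    "d64",
    "fit_base_frame",
    "pair_parameters",
    "step_parameters",
    "interbase_angle",
    "stacking_overlap",
    "phase_from_torsions",
    "pseudorotation",
    "dipyrimidine_geometry",
    "compare_states",
    "STANDARD_BASES",
]

log = logging.getLogger(__name__)

#: Idealized planar base geometries (ring + key exocyclic atoms) expressed in
#: the standard base reference frame (origin on the pairing axis, y toward
#: the backbone, z normal to the base plane). Used only as the template for
#: least-squares frame fitting.
STANDARD_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0), "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0), "C4": (-1.267, 3.124, 0.0),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0), "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0), "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0), "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.135, 0.0),
        "O2": (-2.562, 2.608, 0.0), "N3": (-0.298, 2.407, 0.0),
        "C4": (0.994, 2.897, 0.0), "O4": (1.944, 2.119, 0.0),
        "C5": (1.106, 4.338, 0.0), "C7": (2.466, 4.961, 0.0),
        "C6": (-0.024, 5.057, 0.0),
    },
}

PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")

_DNA_NAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
              "A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}

PUCKER_LABELS = ["C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
                 "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo"]


@dataclass
class Residue:
    """One nucleotide: base letter, atom coordinates, per-atom confidence."""

    chain: str
    index: int
    name: str
    base: str
    atoms: dict[str, np.ndarray]
    confidence: dict[str, float] = field(default_factory=dict)

    @property
    def mean_confidence(self) -> float:
        vals = list(self.confidence.values())
        return float(np.mean(vals)) if vals else float("nan")

    def xyz(self, atom: str) -> np.ndarray:
        if atom not in self.atoms:
            raise KeyError(f"{self.chain}/{self.name}{self.index}: missing atom {atom}")
        return self.atoms[atom]

    @property
    def is_pyrimidine(self) -> bool:
        return self.base in ("C", "T", "U")

    @property
    def ring_atoms(self) -> tuple[str, ...]:
        return PYRIMIDINE_RING if self.is_pyrimidine else PURINE_RING


@dataclass
class StructureModel:
    """Parsed structure: DNA chains (residues ordered 5'->3') by chain name."""

    structure_id: str
    dna_chains: dict[str, list[Residue]]

    def all_residues(self) -> list[Residue]:
        return [r for chain in self.dna_chains.values() for r in chain]


def load_structure(path: str | Path) -> StructureModel:
    """Read an mmCIF or PDB file; keep DNA chains; confidence from B-factor."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for i, res in enumerate(chain):
            base = _DNA_NAMES.get(res.name.strip().upper())
            if base is None:
                continue
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            conf = {a.name: float(a.b_iso) for a in res}
            residues.append(Residue(chain.name, res.seqid.num, res.name, base,
                                    atoms, conf))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"{path}: no DNA chain found")
    for name, residues in chains.items():
        for r in residues:
            missing = [a for a in r.ring_atoms if a not in r.atoms]
            if missing:
                log.warning("%s chain %s %s%d: missing ring atoms %s",
                            path, name, r.name, r.index, missing)
    return StructureModel(Path(path).stem, chains)


def confidence_filter(model: StructureModel, min_mean_plddt: float = 70.0,
                      trim_bp: int = 3) -> tuple[bool, list[Residue]]:
    """Trim chain termini, then require confident predictions throughout.

    The first and last ``trim_bp`` residues of every DNA chain are removed
    from the analysis set; the structure fails if any retained residue's
    mean per-atom confidence is below ``min_mean_plddt``.
    """
    retained: list[Residue] = []
    for residues in model.dna_chains.values():
        core = residues[trim_bp:len(residues) - trim_bp] if trim_bp else residues
        retained.extend(core)
    ok = all(r.mean_confidence >= min_mean_plddt for r in retained)
    return ok, retained


# -- distances -----------------------------------------------------------


def d22(res5: Residue, res3: Residue) -> float:
    """Distance (A) between the C5-C6 bond midpoints of adjacent pyrimidines."""
    for r in (res5, res3):
        if not r.is_pyrimidine:
            raise ValueError(f"{r.name}{r.index} is not a pyrimidine")
    m5 = (res5.xyz("C5") + res5.xyz("C6")) / 2
    m3 = (res3.xyz("C5") + res3.xyz("C6")) / 2
    return float(np.linalg.norm(m5 - m3))


def d64(res5: Residue, res3: Residue) -> float:
    """Distance (A) from the 5' pyrimidine C5 to the 3' base's O4 (T) or N4 (C)."""
    if not res5.is_pyrimidine:
        raise ValueError(f"{res5.name}{res5.index} is not a pyrimidine")
    acceptor = "O4" if res3.base in ("T", "U") else "N4"
    return float(np.linalg.norm(res5.xyz("C5") - res3.xyz(acceptor)))


# -- reference frames ----------------------------------------------------


class BaseFrame(NamedTuple):
    """Right-handed orthonormal frame fitted to one base."""

    origin: np.ndarray   # (3,)
    axes: np.ndarray     # (3, 3), columns are x, y, z
    rmsd: float = 0.0


def fit_base_frame(residue: Residue) -> BaseFrame:
    """Least-squares rigid superposition of the standard base onto the residue.

    Only ring atoms present in both the residue and the standard geometry are
    used; the rotation is proper (no reflection). Returns the transformed
    standard frame and the fit RMSD.
    """
    std = STANDARD_BASES[residue.base if residue.base != "U" else "C"]
    names = [a for a in residue.ring_atoms if a in residue.atoms and a in std]
    if len(names) < 3:
        raise ValueError(f"{residue.name}{residue.index}: fewer than 3 usable ring atoms")
    P = np.array([std[a] for a in names])           # standard
    Q = np.array([residue.atoms[a] for a in names])  # observed
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise ValueError(f"{residue.name}{residue.index}: degenerate ring atoms")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    origin = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((Q0 - (R @ P0.T).T) ** 2, axis=1))))
    return BaseFrame(origin, R, rmsd)


def _rot(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


class RelativeParams(NamedTuple):
    translation: tuple[float, float, float]  # along mid-frame x, y, z (A)
    rotation: tuple[float, float, float]     # about mid-frame x, y, z (deg)
    mid_frame: BaseFrame


def _relative_params(f1: BaseFrame, f2: BaseFrame) -> RelativeParams:
    """Symmetric mid-frame decomposition of the placement of f2 relative to f1.

    The z-axes are brought into coincidence by rotating each frame halfway
    about their common hinge; the remaining rotation about the shared z is
    the twist-like angle, and the hinge phase splits the bending angle into
    the x-like and y-like components. Translations are the components of the
    origin displacement in the mid-frame.
    """
    R1, R2 = f1.axes, f2.axes
    z1, z2 = R1[:, 2], R2[:, 2]
    cr = np.cross(z1, z2)
    ncr = float(np.linalg.norm(cr))
    if ncr < 1e-12:
        gamma = 0.0 if float(np.dot(z1, z2)) > 0 else math.pi
        hinge = R1[:, 0]  # arbitrary in-plane axis (degenerate hinge)
        if gamma == 0.0:
            R1p, R2p = R1, R2
        else:
            R1p = _rot(hinge, +gamma / 2) @ R1
            R2p = _rot(hinge, -gamma / 2) @ R2
    else:
        hinge = cr / ncr
        gamma = math.atan2(ncr, float(np.dot(z1, z2)))
        R1p = _rot(hinge, +gamma / 2) @ R1
        R2p = _rot(hinge, -gamma / 2) @ R2
    zm = R1p[:, 2]
    x1, x2 = R1p[:, 0], R2p[:, 0]
    twist = math.atan2(float(np.dot(np.cross(x1, x2), zm)), float(np.dot(x1, x2)))
    xs = x1 + x2
    if np.linalg.norm(xs) < 1e-9:  # twist ~ 180 deg: bisector undefined
        xm = x1
    else:
        xm = xs / np.linalg.norm(xs)
    xm = xm - zm * np.dot(xm, zm)
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    Rm = np.column_stack([xm, ym, zm])
    om = (f1.origin + f2.origin) / 2
    disp = Rm.T @ (f2.origin - f1.origin)
    if gamma == 0.0:
        rx = ry = 0.0
    else:
        phi = math.atan2(float(np.dot(np.cross(hinge, ym), zm)),
                         float(np.dot(hinge, ym)))
        ry = gamma * math.cos(phi)   # roll-like, about mid-frame y
        rx = gamma * math.sin(phi)   # tilt-like, about mid-frame x
    return RelativeParams(
        (float(disp[0]), float(disp[1]), float(disp[2])),
        (math.degrees(rx), math.degrees(ry), math.degrees(twist)),
        BaseFrame(om, Rm))


class StepParams(NamedTuple):
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    mid_frame: BaseFrame


def step_parameters(f1: BaseFrame, f2: BaseFrame) -> StepParams:
    """shift/slide/rise (A) and tilt/roll/twist (deg) between successive frames."""
    rel = _relative_params(f1, f2)
    return StepParams(*rel.translation, *rel.rotation, rel.mid_frame)


class PairParams(NamedTuple):
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float
    pair_frame: BaseFrame


def pair_parameters(frame_a: BaseFrame, frame_b: BaseFrame,
                    misorientation_tol_deg: float = 90.0) -> PairParams:
    """Intra-pair parameters; the second base's frame is flipped (anti-parallel).

    Raises if, after the flip, the z-axes (or x-axes about the shared z) are
    misoriented by more than ``misorientation_tol_deg`` -- not a plausible
    base pair.
    """
    flip = np.diag([1.0, -1.0, -1.0])
    fb = BaseFrame(frame_b.origin, frame_b.axes @ flip)
    bend = math.degrees(math.acos(np.clip(
        float(np.dot(frame_a.axes[:, 2], fb.axes[:, 2])), -1.0, 1.0)))
    rel = _relative_params(fb, frame_a)
    if bend > misorientation_tol_deg or abs(rel.rotation[2]) > misorientation_tol_deg:
        raise ValueError(f"pair frames misoriented (bend {bend:.1f} deg, "
                         f"opening {rel.rotation[2]:.1f} deg)")
    return PairParams(*rel.translation, *rel.rotation, rel.mid_frame)


def interbase_angle(propeller: float, buckle: float) -> float:
    """sqrt(propeller^2 + buckle^2), in degrees."""
    return float(math.hypot(propeller, buckle))


# -- stacking ------------------------------------------------------------


def _ring_polygon_2d(coords: np.ndarray, origin: np.ndarray,
                     ex: np.ndarray, ey: np.ndarray, normal: np.ndarray) -> Polygon:
    proj = coords - np.outer((coords - origin) @ normal, normal)
    pts = np.column_stack([(proj - origin) @ ex, (proj - origin) @ ey])
    return Polygon(pts)


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(c)
    return Vt[2]


def stacking_overlap(res5, res3) -> float | None:
    """Overlap area (A^2) of the six-membered rings projected on the mean plane.

    The mean plane normal is the normalized sum of the two base-plane
    normals (oriented consistently), anchored at the midpoint of the ring
    centroids. Near-perpendicular bases (normal sum ~ 0) are flagged by
    returning None. Accepts Residues or raw (6, 3) ring-coordinate arrays.
    """
    def ring_coords(r):
        if isinstance(r, Residue):
            return np.array([r.xyz(a) for a in PYRIMIDINE_RING]) if r.is_pyrimidine \
                else np.array([r.xyz(a) for a in ("N1", "C2", "N3", "C4", "C5", "C6")])
        return np.asarray(r, dtype=float)

    A = ring_coords(res5)
    B = ring_coords(res3)
    n1 = _plane_normal(A)
    n2 = _plane_normal(B)
    if abs(float(np.dot(n1, n2))) < 0.2:  # planes > ~78 degrees apart
        log.warning("stacking_overlap: near-perpendicular bases, no value")
        return None
    if np.dot(n1, n2) < 0:
        n2 = -n2
    normal = (n1 + n2) / np.linalg.norm(n1 + n2)
    origin = (A.mean(axis=0) + B.mean(axis=0)) / 2
    ex = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(ex) < 1e-6:
        ex = np.cross(normal, [0.0, 1.0, 0.0])
    ex /= np.linalg.norm(ex)
    ey = np.cross(normal, ex)
    pa = _ring_polygon_2d(A, origin, ex, ey, normal)
    pb = _ring_polygon_2d(B, origin, ex, ey, normal)
    return float(pa.intersection(pb).area)


# -- sugar pucker --------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention (cis = 0)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    return math.degrees(math.atan2(y, x))


class SugarPucker(NamedTuple):
    nu: tuple[float, float, float, float, float]
    phase: float        # pseudorotation phase P, degrees in [0, 360)
    amplitude: float    # tau_m, degrees
    label: str


def phase_from_torsions(nus) -> SugarPucker:
    """Altona-Sundaralingam phase from the five endocyclic torsions (deg).

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin36 + sin72)); the
    quadrant follows the signs of numerator and nu2 (atan2); amplitude
    tau_m = nu2 / cos P; the label is the 36-degree window containing P
    (P=0 -> C3'-endo, [144, 180) -> C2'-endo). nu2 ~ 0 is resolved from the
    numerator sign (flagged by a warning).
    """
    nu0, nu1, nu2, nu3, nu4 = (float(v) for v in nus)
    num = (nu4 + nu1) - (nu3 + nu0)
    den = 2.0 * nu2 * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
    if abs(nu2) < 1e-9:
        log.warning("pseudorotation: nu2 ~ 0, quadrant from the numerator sign")
        P = 90.0 if num >= 0 else 270.0
        amplitude = abs(num) / (2 * (math.sin(math.radians(36)) + math.sin(math.radians(72))))
    else:
        P = math.degrees(math.atan2(num, den)) % 360.0
        amplitude = nu2 / math.cos(math.radians(P))
    label = PUCKER_LABELS[int(P // 36) % 10]
    return SugarPucker((nu0, nu1, nu2, nu3, nu4), float(P), float(amplitude), label)


def pseudorotation(residue: Residue) -> SugarPucker:
    """Sugar ring pseudorotation phase and pucker label of one nucleotide."""
    a = {name: residue.xyz(name) for name in SUGAR_ATOMS}
    nu0 = _dihedral(a["C4'"], a["O4'"], a["C1'"], a["C2'"])
    nu1 = _dihedral(a["O4'"], a["C1'"], a["C2'"], a["C3'"])
    nu2 = _dihedral(a["C1'"], a["C2'"], a["C3'"], a["C4'"])
    nu3 = _dihedral(a["C2'"], a["C3'"], a["C4'"], a["O4'"])
    nu4 = _dihedral(a["C3'"], a["C4'"], a["O4'"], a["C1'"])
    return phase_from_torsions((nu0, nu1, nu2, nu3, nu4))


# -- assembled per-step geometry ----------------------------------------


@dataclass
class DipyrimidineGeometry:
    """The structural parameter ensemble for one dipyrimidine step."""

    structure_id: str
    state: str              # bound / unbound
    step: str               # e.g. "TT"
    d22: float | None = None
    d64: float | None = None
    overlap: float | None = None
    shift: float | None = None
    slide: float | None = None
    rise: float | None = None
    interbase_angle: float | None = None
    propeller: float | None = None
    buckle: float | None = None
    pucker5: SugarPucker | None = None
    pucker3: SugarPucker | None = None

    def as_dict(self) -> dict:
        d = {"structure_id": self.structure_id, "state": self.state, "step": self.step,
             "d22": self.d22, "d64": self.d64, "overlap": self.overlap,
             "shift": self.shift, "slide": self.slide, "rise": self.rise,
             "interbase_angle": self.interbase_angle,
             "propeller": self.propeller, "buckle": self.buckle,
             "phase5": self.pucker5.phase if self.pucker5 else None,
             "phase3": self.pucker3.phase if self.pucker3 else None,
             "pucker5": self.pucker5.label if self.pucker5 else None,
             "pucker3": self.pucker3.label if self.pucker3 else None}
        return d


def dipyrimidine_geometry(res5: Residue, res3: Residue,
                          partner5: Residue | None = None,
                          partner3: Residue | None = None,
                          structure_id: str = "", state: str = "") -> DipyrimidineGeometry:
    """All photoreactivity parameters for one dipyrimidine step.

    Step shift/slide are computed between pair mid-frames when the paired
    residues are supplied, else between the two base frames (flagged by a
    log message). Propeller/buckle (and hence the interbase angle) need the
    partners; the reported values are the means over the two pairs.
    """
    geom = DipyrimidineGeometry(structure_id, state, res5.base + res3.base)
    geom.d22 = d22(res5, res3)
    geom.d64 = d64(res5, res3)
    geom.overlap = stacking_overlap(res5, res3)
    f5 = fit_base_frame(res5)
    f3 = fit_base_frame(res3)
    if partner5 is not None and partner3 is not None:
        p5 = pair_parameters(f5, fit_base_frame(partner5))
        p3 = pair_parameters(f3, fit_base_frame(partner3))
        step = step_parameters(p5.pair_frame, p3.pair_frame)
        geom.propeller = (p5.propeller + p3.propeller) / 2
        geom.buckle = (p5.buckle + p3.buckle) / 2
        geom.interbase_angle = (interbase_angle(p5.propeller, p5.buckle)
                                + interbase_angle(p3.propeller, p3.buckle)) / 2
    else:
        log.info("dipyrimidine_geometry: no partner residues; step parameters "
                 "from base frames")
        step = step_parameters(f5, f3)
    geom.shift, geom.slide, geom.rise = step.shift, step.slide, step.rise
    try:
        geom.pucker5 = pseudorotation(res5)
        geom.pucker3 = pseudorotation(res3)
    except KeyError:
        log.info("dipyrimidine_geometry: sugar atoms missing, no pucker")
    return geom


def compare_states(bound: list[DipyrimidineGeometry],
                   unbound: list[DipyrimidineGeometry],
                   thresholds: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Per-parameter bound/unbound comparison: medians, fold change, MW p.

    ``thresholds`` maps parameter name to a (low, high) reactive range;
    parameters whose bound median falls inside the range are flagged.
    Parameters missing in either state are excluded (logged).
    """
    if len(bound) < 3 or len(unbound) < 3:
        raise ValueError("need >= 3 structures per state")
    params = ["d22", "d64", "overlap", "shift", "slide", "rise",
              "interbase_angle", "propeller", "buckle"]
    rows = []
    for p in params:
        bv = np.array([getattr(g, p) for g in bound if getattr(g, p) is not None],
                      dtype=float)
        uv = np.array([getattr(g, p) for g in unbound if getattr(g, p) is not None],
                      dtype=float)
        if len(bv) < 3 or len(uv) < 3:
            log.info("compare_states: parameter %s missing in a state, excluded", p)
            continue
        mb, mu = float(np.median(bv)), float(np.median(uv))
        fold = mb / mu if mu != 0 else np.nan
        if np.array_equal(np.sort(bv), np.sort(uv)):
            pval = 1.0
            u = len(bv) * len(uv) / 2.0
        else:
            res = stats.mannwhitneyu(bv, uv, alternative="two-sided")
            u, pval = float(res.statistic), float(res.pvalue)
        in_range = False
        if thresholds and p in thresholds:
            lo, hi = thresholds[p]
            if lo > hi:
                raise ValueError(f"threshold range for {p} is not well-ordered")
            in_range = lo <= mb <= hi
        rows.append({"parameter": p, "median_bound": mb, "median_unbound": mu,
                     "fold_change": fold, "U": u, "p": pval,
                     "reactive_flag": in_range})
    return pd.DataFrame(rows)


def select_prediction_sites(siteset, genome, n: int = 20, length: int = 20) -> list[str]:
    """Top-scoring non-redundant binding-site sequences for structure prediction.

    Each sequence is ``length`` bp, centered at the motif center, read on the
    motif strand; duplicates are removed keeping the best-scoring instance.
    """
    from .genome import revcomp
    ranked = siteset.sorted_by_score()
    centers = ranked.centers
    seqs: list[str] = []
    seen: set[str] = set()
    half = length // 2
    for r, c in zip(ranked.sites.itertuples(), centers):
        lo, hi = int(c) - half, int(c) - half + length
        if lo < 0 or hi > genome.lengths[r.chrom]:
            continue
        seq = genome.sequence(r.chrom, lo, hi)
        if r.strand == "-":
            seq = revcomp(seq)
        if seq in seen:
            continue
        seen.add(seq)
        seqs.append(seq)
        if len(seqs) >= n:
            break
    return seqs
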