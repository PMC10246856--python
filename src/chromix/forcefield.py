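"""Bead-spring force field: bonds, bending, Lennard-Jones pairs, confinement.

The model energy is

    U_tot = U_spring + U_bend + U_LJ + U_nucleus

with harmonic bonds of rest length sigma, a cosine bending term
U = k_bend * sum(1 - cos theta) whose stiffness sets the persistence length
(k_bend = l_p * k_B T / sigma), a truncated 12-6 Lennard-Jones pair term with
a type-pair interaction matrix, and a harmonic wall representing the
hard-core repulsion of the nuclear envelope.  A spherical indenter used by
the compression protocol applies an inward force K*(r - R)^2.

Interaction types are EU, HET, LAMIN plus the effective type LAD (an
euchromatic bead carrying the lamina-associated-domain flag); only the
LAMIN-LAD entry distinguishes LAD from plain EU beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels
from ._kernels import PAIR_BY_TYPE
from .model_core import EU, HET, LAMIN, PolymerSystem

__all__ = [
    "ForceField",
    "SingularGeometryError",
    "spring_energy_forces",
    "bending_energy_forces",
    "pair_lj_energy_forces",
    "confinement_energy_forces",
    "indenter_force",
    "total_energy",
    "effective_type_index",
    "WCA_CUTOFF",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)  # purely repulsive truncation
ATTRACTIVE_CUTOFF = 2.5

TYPE_LABELS = ["EU", "HET", "LAMIN", "LAD"]
_LABEL_TO_IDX = {l: i for i, l in enumerate(TYPE_LABELS)}
LAD = 3  # effective type index of a LAD-flagged euchromatic bead


class SingularGeometryError(ValueError):
    """Coincident bonded beads or a zero-length bond in an angle."""


def effective_type_index(bead_type: np.ndarray, lad_flag: np.ndarray) -> np.ndarray:
    """Map (bead_type, lad_flag) to the 4-type interaction index.

    LAD status only matters for euchromatic beads (LAD annotation exists
    only in euchromatin), so a HET bead keeps its HET index regardless of
    the flag.
    """
    idx = np.asarray(bead_type, dtype=np.int64).copy()
    lad = np.asarray(lad_flag, dtype=bool)
    idx[(idx == EU) & lad] = LAD
    return idx


def _symmetric_matrix(default: float) -> np.ndarray:
    return np.full((4, 4), float(default))


@dataclass
class ForceField:
    """Parameter container for the polymer force field (reduced units)."""

    k_spring: float = 100.0    # k_BT / sigma^2; keeps bond fluctuations < 0.1 sigma
    k_bend: float = 5.0        # k_BT; = l_p/sigma, so 5 for l_p = 5 beads
    eps_matrix: np.ndarray = None     # (4,4) in k_BT
    cutoff_matrix: np.ndarray = None  # (4,4) in sigma
    lj_shifted: bool = False
    wall_strength: float = 200.0      # k_BT / sigma^2

    def __post_init__(self):
        if self.eps_matrix is None:
            self.eps_matrix = _symmetric_matrix(0.0)
        if self.cutoff_matrix is None:
            self.cutoff_matrix = _symmetric_matrix(WCA_CUTOFF)
        self.eps_matrix = np.asarray(self.eps_matrix, dtype=np.float64)
        self.cutoff_matrix = np.asarray(self.cutoff_matrix, dtype=np.float64)
        self.validate()

    def validate(self):
        if self.eps_matrix.shape != (4, 4) or self.cutoff_matrix.shape != (4, 4):
            raise ValueError("interaction matrices must be 4x4 (EU/HET/LAMIN/LAD)")
        if not np.allclose(self.eps_matrix, self.eps_matrix.T):
            raise ValueError("eps_matrix must be symmetric")
        if not np.allclose(self.cutoff_matrix, self.cutoff_matrix.T):
            raise ValueError("cutoff_matrix must be symmetric")
        if np.any(self.eps_matrix < 0):
            raise ValueError("epsilon values must be non-negative")
        if np.any(self.cutoff_matrix < WCA_CUTOFF - 1e-9):
            raise ValueError(f"cutoffs must be >= 2^(1/6) sigma ({WCA_CUTOFF:.4f})")

    @property
    def max_cutoff(self) -> float:
        active = self.eps_matrix > 0
        if not active.any():
            return 0.0
        return float(self.cutoff_matrix[active].max())

    def set_pair(self, type_a: str, type_b: str, eps: float, cutoff: float = None):
        ia, ib = _LABEL_TO_IDX[type_a], _LABEL_TO_IDX[type_b]
        self.eps_matrix[ia, ib] = self.eps_matrix[ib, ia] = float(eps)
        if cutoff is not None:
            self.cutoff_matrix[ia, ib] = self.cutoff_matrix[ib, ia] = float(cutoff)
        self.validate()

    @classmethod
    def homopolymer(cls, epsilon: float, k_bend: float = 5.0,
                    cutoff: float = ATTRACTIVE_CUTOFF, **kw) -> "ForceField":
        """Uniform self-attraction epsilon among all chromatin beads.

        epsilon = 0 gives a phantom chain (no pair interactions at all);
        a purely repulsive chain is epsilon > 0 with cutoff 2^(1/6) sigma.
        """
        ff = cls(k_bend=k_bend, **kw)
        for a in ("EU", "HET", "LAD"):
            for b in ("EU", "HET", "LAD"):
                ff.set_pair(a, b, epsilon, cutoff)
        return ff

    @classmethod
    def block_copolymer(cls, eps_ee: float = 0.25, eps_hh: float = 0.5,
                        lamin_lad_eps: float = 0.0, k_bend: float = 5.0,
                        **kw) -> "ForceField":
        """Euchromatin/heterochromatin copolymer interactions.

        EU-EU and LAD-involving chromatin pairs attract with eps_ee, HET-HET
        with eps_hh; EU-HET pairs are purely repulsive (excluded volume
        only).  lamin_lad_eps > 0 adds the lamina tether: LAMIN beads
        attract LAD-flagged beads with a 2.5 sigma cutoff and repel
        everything else.
        """
        ff = cls(k_bend=k_bend, **kw)
        for a, b in (("EU", "EU"), ("EU", "LAD"), ("LAD", "LAD")):
            ff.set_pair(a, b, eps_ee, ATTRACTIVE_CUTOFF)
        ff.set_pair("HET", "HET", eps_hh, ATTRACTIVE_CUTOFF)
        # EU-HET: excluded volume only
        ff.set_pair("EU", "HET", 1.0, WCA_CUTOFF)
        ff.set_pair("LAD", "HET", 1.0, WCA_CUTOFF)
        # lamin shell: repulsive to all chromatin, attractive to LADs if asked
        for t in ("EU", "HET", "LAMIN"):
            ff.set_pair("LAMIN", t, 1.0, WCA_CUTOFF)
        if lamin_lad_eps > 0:
            ff.set_pair("LAMIN", "LAD", lamin_lad_eps, ATTRACTIVE_CUTOFF)
        else:
            ff.set_pair("LAMIN", "LAD", 1.0, WCA_CUTOFF)
        return ff

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path):
        pairs = []
        for a in range(4):
            for b in range(a, 4):
                pairs.append([
                    TYPE_LABELS[a], TYPE_LABELS[b],
                    float(self.eps_matrix[a, b]),
                    float(self.cutoff_matrix[a, b]),
                ])
        doc = {
            "k_spring": float(self.k_spring),
            "k_bend": float(self.k_bend),
            "lj_shifted": bool(self.lj_shifted),
            "wall_strength": float(self.wall_strength),
            "pairs": pairs,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        ff = cls(
            k_spring=float(doc.get("k_spring", 100.0)),
            k_bend=float(doc.get("k_bend", 5.0)),
            lj_shifted=bool(doc.get("lj_shifted", False)),
            wall_strength=float(doc.get("wall_strength", 200.0)),
        )
        for a, b, eps, cut in doc.get("pairs", []):
            ff.set_pair(a, b, float(eps), float(cut))
        return ff


# --------------------------------------------------------------------------
# per-term operations (thin wrappers over the jitted kernels)
# --------------------------------------------------------------------------

def _as_pos(positions):
    return np.ascontiguousarray(positions, dtype=np.float64)


def spring_energy_forces(positions, bonds, k_spring):
    """Harmonic bond energy and forces; rest length sigma = 1."""
    pos = _as_pos(positions)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    forces = np.zeros_like(pos)
    e, ok = _kernels.spring_forces(pos, bonds, float(k_spring), forces)
    if not ok:
        raise SingularGeometryError("coincident bonded beads (zero bond length)")
    return e, forces


def bending_energy_forces(positions, angle_triples, k_bend):
    """Cosine bending energy U = k_bend * sum(1 - cos theta) and forces."""
    pos = _as_pos(positions)
    triples = np.asarray(angle_triples, dtype=np.int64).reshape(-1, 3)
    forces = np.zeros_like(pos)
    e, ok = _kernels.bending_forces(pos, triples, float(k_bend), forces)
    if not ok:
        raise SingularGeometryError("zero-length bond inside an angle triple")
    return e, forces


def pair_lj_energy_forces(positions, bead_types, eps_matrix, cutoff_matrix,
                          neighbor_list, lad_flag=None, lj_shifted=False,
                          chain_id=None):
    """Truncated LJ energy and forces over a candidate pair list.

    ``neighbor_list`` is a (pair_i, pair_j) tuple, e.g. from
    :func:`chromix.dynamics.build_neighbor_list`; bonded pairs must already
    be excluded from it.  Forces below r = 0.5 sigma are capped (overlapping
    start configurations); the count of capped interactions is not returned
    here but is logged during dynamics.
    """
    pos = _as_pos(positions)
    bead_types = np.asarray(bead_types, dtype=np.int64)
    if lad_flag is None:
        lad_flag = np.zeros(len(bead_types), dtype=bool)
    type_idx = effective_type_index(bead_types, lad_flag)
    if chain_id is None:
        chain_id = np.zeros(len(bead_types), dtype=np.int32)
    pair_i, pair_j = neighbor_list
    forces = np.zeros_like(pos)
    e, _ncap = _kernels.lj_pair_forces(
        pos, np.asarray(pair_i, np.int64), np.asarray(pair_j, np.int64),
        type_idx, np.asarray(chain_id, np.int32),
        np.asarray(eps_matrix, np.float64), np.asarray(cutoff_matrix, np.float64),
        lj_shifted, PAIR_BY_TYPE, 0.0, 0.0, 0.0, 0.0,
        _kernels.FORCE_CAP, forces,
    )
    return e, forces


def confinement_energy_forces(positions, Rc, wall_strength, mobile_mask=None):
    """Harmonic wall beyond |r| = Rc - sigma/2; zero inside."""
    if not math.isfinite(Rc):
        raise ValueError("confinement radius must be finite")
    pos = _as_pos(positions)
    if mobile_mask is None:
        mobile_mask = np.ones(len(pos), dtype=bool)
    forces = np.zeros_like(pos)
    e = _kernels.wall_forces(pos, np.asarray(mobile_mask, bool), float(Rc),
                             float(wall_strength), forces)
    return e, forces


def indenter_force(positions, K_indent, R_indent, mobile_mask=None):
    """Inward radial force of magnitude K*(r - R)^2 outside the indenter."""
    if not R_indent > 0:
        raise ValueError("R_indent must be positive")
    pos = _as_pos(positions)
    if mobile_mask is None:
        mobile_mask = np.ones(len(pos), dtype=bool)
    forces = np.zeros_like(pos)
    _kernels.indenter_forces(pos, np.asarray(mobile_mask, bool),
                             float(K_indent), float(R_indent), forces)
    return forces


def total_energy(system: PolymerSystem, forcefield: ForceField, neighbor_list):
    """Per-term and total energy of a system under a force field.

    Returns a dict with keys spring/bend/lj/wall/indenter/total; the
    indenter term is zero here (it only acts during compression and its
    work is reported separately by the compression protocol).
    """
    e_spring, _ = spring_energy_forces(system.positions, system.bonds,
                                       forcefield.k_spring)
    e_bend, _ = bending_energy_forces(system.positions, system.angle_triples,
                                      forcefield.k_bend)
    e_lj, _ = pair_lj_energy_forces(
        system.positions, system.bead_type, forcefield.eps_matrix,
        forcefield.cutoff_matrix, neighbor_list, lad_flag=system.lad_flag,
        lj_shifted=forcefield.lj_shifted, chain_id=system.chain_id,
    )
    e_wall = 0.0
    if math.isfinite(system.confinement_radius):
        e_wall, _ = confinement_energy_forces(
            system.positions, system.confinement_radius,
            forcefield.wall_strength, system.mobile_mask,
        )
    terms = {
        "spring": e_spring,
        "bend": e_bend,
        "lj": e_lj,
        "wall": e_wall,
        "indenter": 0.0,
    }
    terms["total"] = sum(terms.values())
    return terms
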