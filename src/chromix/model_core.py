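"""Domain types and reduced-unit conventions.

Simulation quantities are expressed in reduced units: lengths in bead
diameters (sigma), energies in units of the thermal energy k_B*T, and times
in the Brownian time tau -- the time a free bead needs to diffuse its own
diameter.  :class:`UnitSystem` is the single place where these reduced units
are mapped onto metres and seconds; everything else in the package is
agnostic of the physical scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import yaml

__all__ = [
    "EU",
    "HET",
    "LAMIN",
    "BOLTZMANN_SI",
    "SECONDS_PER_YEAR",
    "GenomeSpec",
    "UnitSystem",
    "PolymerSystem",
    "ScalingFit",
    "brownian_time",
    "convert_sim_time",
    "volume_fraction",
    "confinement_radius_from_phi",
]

# Bead type codes used throughout the kernels.
EU = 0      # euchromatin: open, weakly self-attractive chromatin
HET = 1     # heterochromatin: compact, strongly self-attractive chromatin
LAMIN = 2   # immobile lamin bead on the nuclear shell

BOLTZMANN_SI = 1.380649e-23  # J/K (exact, SI 2019)
SECONDS_PER_YEAR = 3.1557e7  # Julian year


class InvalidUnitsError(ValueError):
    """A physical unit parameter is non-positive or otherwise unusable."""


@dataclass
class GenomeSpec:
    """Chain lengths and per-bead annotations defining a polymer genome.

    Parameters
    ----------
    chain_names : list of str
        One label per chain (e.g. ``["Chr2", "Chr3", "Chr4", "ChrX"]``).
    chain_lengths : list of int
        Beads per chain; every entry must be >= 2 unless the system is a
        collection of disconnected beads (``disconnected=True``).
    bead_class : ndarray of int
        Per-bead chromatin class over the concatenated chains (EU or HET).
    lad_flag : ndarray of bool
        Per-bead lamina-associated-domain flag.
    bp_per_bead : int
        Basepairs of DNA represented by one bead (default 5000).
    """

    chain_names: list
    chain_lengths: list
    bead_class: np.ndarray = None
    lad_flag: np.ndarray = None
    bp_per_bead: int = 5000
    disconnected: bool = False

    def __post_init__(self):
        self.chain_lengths = [int(x) for x in self.chain_lengths]
        if len(self.chain_names) != len(self.chain_lengths):
            raise ValueError("chain_names and chain_lengths must align")
        if any(l < 1 for l in self.chain_lengths):
            raise ValueError("chain lengths must be positive")
        if not self.disconnected and any(l < 2 for l in self.chain_lengths):
            raise ValueError(
                "chain lengths must be >= 2 (or declare disconnected=True)"
            )
        n = self.n_beads
        if self.bead_class is None:
            self.bead_class = np.full(n, EU, dtype=np.int8)
        else:
            self.bead_class = np.asarray(self.bead_class, dtype=np.int8)
        if self.lad_flag is None:
            self.lad_flag = np.zeros(n, dtype=bool)
        else:
            self.lad_flag = np.asarray(self.lad_flag, dtype=bool)
        if self.bead_class.shape != (n,) or self.lad_flag.shape != (n,):
            raise ValueError("annotation arrays must match total bead count")

    @property
    def n_beads(self) -> int:
        return int(sum(self.chain_lengths))

    @property
    def n_chains(self) -> int:
        return len(self.chain_lengths)

    @property
    def chain_offsets(self) -> np.ndarray:
        """Start index of each chain plus the terminal bead count."""
        return np.concatenate([[0], np.cumsum(self.chain_lengths)]).astype(np.int64)

    def chain_id(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.chain_lengths).astype(np.int32)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path, annotation_path=None):
        """Write the chain table as YAML and per-bead annotation as TSV."""
        doc = {
            "chains": [
                {"name": n, "beads": int(l)}
                for n, l in zip(self.chain_names, self.chain_lengths)
            ],
            "bp_per_bead": int(self.bp_per_bead),
            "disconnected": bool(self.disconnected),
        }
        if annotation_path is not None:
            doc["annotation"] = str(annotation_path)
            self._write_annotation(annotation_path)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def _write_annotation(self, path):
        # BED-like: chrom, start_bead, end_bead (half-open, 0-based), class, lad
        offs = self.chain_offsets
        cls = np.where(self.bead_class == HET, "HET", "EU")
        with open(path, "w") as fh:
            for c, name in enumerate(self.chain_names):
                lo, hi = offs[c], offs[c + 1]
                i = lo
                while i < hi:
                    j = i
                    while (
                        j + 1 < hi
                        and cls[j + 1] == cls[i]
                        and self.lad_flag[j + 1] == self.lad_flag[i]
                    ):
                        j += 1
                    fh.write(
                        f"{name}\t{i - lo}\t{j + 1 - lo}\t{cls[i]}\t"
                        f"{int(self.lad_flag[i])}\n"
                    )
                    i = j + 1

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        names = [c["name"] for c in doc["chains"]]
        lengths = [int(c["beads"]) for c in doc["chains"]]
        spec = cls(
            names,
            lengths,
            bp_per_bead=int(doc.get("bp_per_bead", 5000)),
            disconnected=bool(doc.get("disconnected", False)),
        )
        ann = doc.get("annotation")
        if ann:
            spec._read_annotation(ann)
        return spec

    def _read_annotation(self, path):
        offs = self.chain_offsets
        name_to_chain = {n: i for i, n in enumerate(self.chain_names)}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, lo, hi, klass, lad = line.split("\t")
                c = name_to_chain[chrom]
                sl = slice(offs[c] + int(lo), offs[c] + int(hi))
                self.bead_class[sl] = HET if klass == "HET" else EU
                self.lad_flag[sl] = bool(int(lad))


@dataclass
class UnitSystem:
    """Physical-unit mapping for the reduced simulation units.

    tau (the Brownian time) is always recomputed from the current fields,
    never cached, so mutating sigma/eta/T keeps the mapping consistent.
    """

    sigma_m: float = 30e-9   # bead diameter [m]
    eta_Pa_s: float = 1e-3   # nucleoplasm viscosity [Pa s] (~water)
    T_K: float = 310.0       # absolute temperature [K]

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not (self.sigma_m > 0 and self.eta_Pa_s > 0 and self.T_K > 0):
            raise InvalidUnitsError("sigma, eta and T must all be positive")

    @property
    def tau_s(self) -> float:
        """Brownian time 3*pi*eta*sigma^3 / (k_B T) in seconds."""
        return brownian_time(self)

    def to_dict(self):
        return {
            "sigma_m": self.sigma_m,
            "eta_Pa_s": self.eta_Pa_s,
            "T_K": self.T_K,
            "tau_s": self.tau_s,
        }


def brownian_time(units: UnitSystem) -> float:
    """Time for a bead to diffuse its own diameter, in seconds.

    Stokes friction zeta = 3*pi*eta*sigma and D = k_B T / zeta give
    tau = sigma^2/D = 3*pi*eta*sigma^3/(k_B T).  For a 30 nm bead in water
    at 310 K this is 59.5 us, i.e. 60 us to the nearest 10 us.
    """
    units.validate()
    return 3.0 * math.pi * units.eta_Pa_s * units.sigma_m ** 3 / (
        BOLTZMANN_SI * units.T_K
    )


_TIME_UNITS = {
    "s": 1.0,
    "seconds": 1.0,
    "min": 60.0,
    "minutes": 60.0,
    "h": 3600.0,
    "hours": 3600.0,
    "days": 86400.0,
    "years": SECONDS_PER_YEAR,
}


def convert_sim_time(t_tau: float, units: UnitSystem, target_unit: str = "s") -> float:
    """Convert a duration given in Brownian times to a physical unit.

    ``target_unit`` is one of s/min/h/days/years (year = Julian year,
    3.1557e7 s).
    """
    if t_tau < 0:
        raise ValueError("t_tau must be non-negative")
    try:
        denom = _TIME_UNITS[target_unit]
    except KeyError:
        raise ValueError(
            f"unknown target_unit {target_unit!r}; choose from {sorted(_TIME_UNITS)}"
        ) from None
    return t_tau * brownian_time(units) / denom


def volume_fraction(n_beads: int, Rc: float) -> float:
    """Fraction of the confining sphere volume occupied by beads.

    phi = N * (sigma/2)^3 / Rc^3 with Rc in sigma units; the 4/3*pi factors
    of the bead and confinement volumes cancel.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if not Rc > 0:
        raise ValueError("Rc must be positive")
    return n_beads / (8.0 * Rc ** 3)


def confinement_radius_from_phi(n_beads: int, phi: float) -> int:
    """Smallest integer confinement radius (sigma) for a nominal phi.

    Inverts the volume-fraction relation and takes the ceiling,
    Rc = ceil((N/phi)^(1/3) / 2).  The realized volume fraction
    ``volume_fraction(n_beads, Rc)`` is therefore at most the nominal one.
    """
    if not (0 < phi <= 1):
        raise ValueError("phi must lie in (0, 1]")
    raw = (n_beads / phi) ** (1.0 / 3.0) / 2.0
    # guard against ceil(x + ulp) overshooting an exact integer result
    return int(math.ceil(raw - 1e-9))


@dataclass
class PolymerSystem:
    """Bead positions, topology and confinement of one simulated system."""

    positions: np.ndarray            # (N, 3) in sigma
    chain_id: np.ndarray             # (N,) int
    bead_type: np.ndarray = None     # (N,) int: EU/HET/LAMIN
    lad_flag: np.ndarray = None      # (N,) bool
    velocities: np.ndarray = None    # (N, 3)
    bonds: np.ndarray = None         # (B, 2) int pairs, consecutive beads
    angle_triples: np.ndarray = None  # (A, 3) int consecutive triples
    confinement_radius: float = math.inf   # sigma; inf = unconfined
    mobile_mask: np.ndarray = None   # (N,) bool; lamin beads immobile

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        n = self.positions.shape[0]
        self.chain_id = np.asarray(self.chain_id, dtype=np.int32)
        if self.bead_type is None:
            self.bead_type = np.full(n, EU, dtype=np.int8)
        self.bead_type = np.asarray(self.bead_type, dtype=np.int8)
        if self.lad_flag is None:
            self.lad_flag = np.zeros(n, dtype=bool)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.bonds is None:
            self.bonds = _bonds_from_chain_id(self.chain_id)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if self.angle_triples is None:
            self.angle_triples = _angles_from_chain_id(self.chain_id)
        self.angle_triples = np.asarray(self.angle_triples, dtype=np.int64).reshape(-1, 3)
        if self.mobile_mask is None:
            self.mobile_mask = self.bead_type != LAMIN
        self.mobile_mask = np.asarray(self.mobile_mask, dtype=bool)
        if np.any(self.mobile_mask[self.bead_type == LAMIN]):
            raise ValueError("lamin beads must be immobile")
        self.validate_topology()

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    def chain_offsets(self) -> np.ndarray:
        """Start indices of the mobile chains (terminal count appended).

        Lamin shell beads, if present, are appended after all chains and are
        not part of any chain block.
        """
        mobile_chains = self.chain_id[self.bead_type != LAMIN]
        counts = np.bincount(mobile_chains)
        return np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def validate_topology(self):
        if len(self.bonds):
            a, b = self.bonds[:, 0], self.bonds[:, 1]
            if np.any(self.chain_id[a] != self.chain_id[b]):
                raise ValueError("bonds must join beads of the same chain")
            if np.any(np.abs(a - b) != 1):
                raise ValueError("bonds must join consecutive beads")

    def copy(self) -> "PolymerSystem":
        return PolymerSystem(
            positions=self.positions.copy(),
            chain_id=self.chain_id.copy(),
            bead_type=self.bead_type.copy(),
            lad_flag=self.lad_flag.copy(),
            velocities=self.velocities.copy(),
            bonds=self.bonds.copy(),
            angle_triples=self.angle_triples.copy(),
            confinement_radius=self.confinement_radius,
            mobile_mask=self.mobile_mask.copy(),
        )


def _bonds_from_chain_id(chain_id: np.ndarray) -> np.ndarray:
    n = len(chain_id)
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    i = np.arange(n - 1)
    same = chain_id[i] == chain_id[i + 1]
    return np.stack([i[same], i[same] + 1], axis=1).astype(np.int64)


def _angles_from_chain_id(chain_id: np.ndarray) -> np.ndarray:
    n = len(chain_id)
    if n < 3:
        return np.empty((0, 3), dtype=np.int64)
    i = np.arange(n - 2)
    same = (chain_id[i] == chain_id[i + 1]) & (chain_id[i] == chain_id[i + 2])
    return np.stack([i[same], i[same] + 1, i[same] + 2], axis=1).astype(np.int64)


@dataclass
class ScalingFit:
    """Result of a power-law fit y ~ prefactor * x^(+-exponent)."""

    exponent: float
    prefactor: float
    window: tuple
    r_squared: float
    breakpoint: float = None
    second_exponent: float = None

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("fit window must satisfy lo < hi")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.breakpoint is not None and not (lo <= self.breakpoint <= hi):
            raise ValueError("breakpoint must lie inside the fit window")

    def to_dict(self) -> dict:
        """JSON-ready record of the fit."""
        return {
            "exponent": self.exponent,
            "prefactor": self.prefactor,
            "window": [self.window[0], self.window[1]],
            "r_squared": self.r_squared,
            "breakpoint": self.breakpoint,
            "second_exponent": self.second_exponent,
        }
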