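"""Reduced torsional model of an Ala -> Gly side-chain mutation.

The system is a nine-bead stand-in for the backbone atoms around the
central residue of a KXK tripeptide: a rigid bead chain (fixed bond
lengths and angles) with two torsional degrees of freedom, the backbone
dihedrals phi2 and psi2 of the central residue.  The side-chain bead
(``CB``, a united-atom CH3) is alchemically coupled: at lambda = 0 it is
fully interacting (alanine-like), at lambda = 1 it is a dummy atom with
no nonbonded parameters (glycine-like).  Its 1,4 nonbonded interactions
with the previous carbonyl carbon, the amide hydrogen, the carbonyl
oxygen and the next amide nitrogen dominate the phi2/psi2 barriers at
lambda = 0; the torsional potential-energy terms themselves contribute
barriers of about 1 kJ/mol only.

Nonbonded interactions use a Beutler-style softcore form.  For a
perturbed pair the Lennard-Jones energy is

    U(r, lam) = (1-lam)^n [ C12_A/D_A^2 - C6_A/D_A ]
              +     lam^n [ C12_B/D_B^2 - C6_B/D_B ]

    D_A = alpha_vdw lam^2 (C12_A/C6_A) + r^6
    D_B = alpha_vdw (1-lam)^2 (C12_B/C6_B) + r^6

so the softening radius of each state grows as that state is switched
off; alpha_vdw is dimensionless because the C12/C6 ratio carries nm^6.
Electrostatics (Coulomb plus reaction field) soften the squared
distance by alpha_crf lam^2 (units nm^2) in the same two-branch
scheme.  At the endpoints both reduce exactly to the plain pair
energies of the corresponding end state.  Unperturbed pairs (identical
A- and B-state parameters) are evaluated with the plain potentials and
contribute nothing to dU/dlambda.

Units throughout: kJ/mol, nm, degrees (IUPAC torsion convention,
wrapped to [-180, 180)), elementary charges, kelvin.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ._kernels import (FELEC, KB, VARIANT_EXTRA_EXCL, VARIANT_REFERENCE,
                       VARIANT_STANDARD, batch_energy_kernel, dudl_kernel,
                       energy_kernel, place_kernel)

__all__ = [
    "Bead", "ZRow", "ToyTopology", "SoftcoreParams", "RFParams",
    "TorsionState", "build_toy_mutation", "place_beads", "measure_torsions",
    "softcore_lj", "softcore_rf", "potential_energy", "dU_dlambda",
    "reference_softcore", "topology_to_yaml", "topology_from_yaml",
    "KB", "FELEC",
]

_VARIANTS = {
    "standard": VARIANT_STANDARD,
    "extra_exclusions": VARIANT_EXTRA_EXCL,
    "reference_R": VARIANT_REFERENCE,
}


def wrap_deg(x):
    """Wrap angle(s) in degrees into [-180, 180)."""
    return np.asarray(x, dtype=float) - 360.0 * np.floor(
        (np.asarray(x, dtype=float) + 180.0) / 360.0)


@dataclass(frozen=True)
class Bead:
    """One interaction site with A-state and B-state nonbonded parameters.

    ``lj_A``/``lj_B`` are (C12 [kJ/mol nm^12], C6 [kJ/mol nm^6]) tuples;
    a dummy state has both zero and zero charge.
    """
    index: int
    name: str
    lj_A: tuple[float, float]
    lj_B: tuple[float, float]
    charge_A: float
    charge_B: float
    is_perturbed: bool = False

    def __post_init__(self):
        for c12, c6 in (self.lj_A, self.lj_B):
            if c12 < 0 or c6 < 0:
                raise ValueError("LJ coefficients must be non-negative")


@dataclass(frozen=True)
class ZRow:
    """Internal-coordinate placement record for one bead.

    ``dof`` is the torsion DOF index driving the dihedral (or -1 for a
    geometry-fixed dihedral); the actual dihedral placed is
    ``angles[dof] + dihedral_deg``.
    """
    parent: int
    angle_ref: int
    torsion_ref: int
    bond: float
    angle_deg: float
    dof: int
    dihedral_deg: float


@dataclass(frozen=True)
class SoftcoreParams:
    """Softcore softness parameters.

    alpha_vdw : dimensionless LJ softness (0.5 default; 1.0 is the
        "softer" protocol variant; 1.51 is the one-step-perturbation
        reference state).
    alpha_crf : nm^2, electrostatic softness.
    n_power : integer exponent of the overall (1-lam)^n / lam^n scaling.
    """
    alpha_vdw: float = 0.5
    alpha_crf: float = 0.5
    n_power: int = 1

    def __post_init__(self):
        if self.alpha_vdw < 0 or self.alpha_crf < 0:
            raise ValueError("softcore alphas must be >= 0")
        if self.n_power < 1:
            raise ValueError("n_power must be >= 1")


def reference_softcore(alpha_vdw: float = 1.51) -> SoftcoreParams:
    """Softcore parameters of the unphysical OSP reference state."""
    return SoftcoreParams(alpha_vdw=alpha_vdw, alpha_crf=0.0)


@dataclass(frozen=True)
class RFParams:
    """Reaction-field electrostatics: relative dielectric and cutoff."""
    eps_rf: float = 61.0
    cutoff: float = 1.4

    def __post_init__(self):
        if self.eps_rf <= 1:
            raise ValueError("eps_rf must exceed 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def crf(self) -> float:
        """Reaction-field constant C_rf = 2(eps-1)/(2 eps + 1)."""
        return 2.0 * (self.eps_rf - 1.0) / (2.0 * self.eps_rf + 1.0)


@dataclass(frozen=True)
class TorsionState:
    """A point in torsion space; angles in degrees in [-180, 180)."""
    angles: np.ndarray

    def __init__(self, angles):
        object.__setattr__(self, "angles", wrap_deg(np.atleast_1d(angles)))

    def shifted(self, dof: int, delta_deg: float) -> "TorsionState":
        a = self.angles.copy()
        a[dof] += delta_deg
        return TorsionState(a)


@dataclass
class ToyTopology:
    """The perturbed molecular model (beads, rigid geometry, torsions)."""
    beads: list[Bead]
    zmat: list[ZRow]
    torsion_dofs: list[tuple[tuple[int, int, int, int], str]]
    torsion_terms: list[tuple[int, float, int, float]]  # (dof, k, m, delta_deg)
    exclusions: set[tuple[int, int]]
    extra_exclusions: set[tuple[int, int]]
    rf: RFParams = field(default_factory=RFParams)
    temperature_K: float = 298.0
    _tables: "TopologyTables" = field(default=None, init=False, repr=False,
                                      compare=False)

    @property
    def n_dof(self) -> int:
        return len(self.torsion_dofs)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def kT(self) -> float:
        return KB * self.temperature_K

    @property
    def bond_lengths(self) -> dict[tuple[int, int], float]:
        return {tuple(sorted((i, z.parent))): z.bond
                for i, z in enumerate(self.zmat) if i > 0}

    @property
    def bond_angles(self) -> dict[tuple[int, int, int], float]:
        return {(i, z.parent, z.angle_ref): z.angle_deg
                for i, z in enumerate(self.zmat) if i > 1}

    @property
    def perturbed_index(self) -> int:
        return next(b.index for b in self.beads if b.is_perturbed)

    def tables(self) -> "TopologyTables":
        if self._tables is None:
            self._tables = TopologyTables(self)
        return self._tables


class TopologyTables:
    """Packed plain-array view of a topology for the numba kernels."""

    def __init__(self, top: ToyTopology):
        n = top.n_beads
        self.zp = np.full((n, 3), -1, dtype=np.int64)
        self.zgeom = np.zeros((n, 4))
        for i, z in enumerate(top.zmat):
            if i == 0:
                continue
            self.zp[i] = (z.parent, z.angle_ref, z.torsion_ref)
            self.zgeom[i] = (z.bond, math.radians(z.angle_deg),
                             float(z.dof), math.radians(z.dihedral_deg))
        pairs = [(i, j) for i, j in itertools.combinations(range(n), 2)
                 if (i, j) not in top.exclusions]
        m = len(pairs)
        self.pi = np.array([p[0] for p in pairs], dtype=np.int64)
        self.pj = np.array([p[1] for p in pairs], dtype=np.int64)
        self.c12A = np.zeros(m)
        self.c6A = np.zeros(m)
        self.c12B = np.zeros(m)
        self.c6B = np.zeros(m)
        self.qqA = np.zeros(m)
        self.qqB = np.zeros(m)
        self.pert = np.zeros(m, dtype=np.bool_)
        self.xexcl = np.zeros(m, dtype=np.bool_)
        for k, (i, j) in enumerate(pairs):
            bi, bj = top.beads[i], top.beads[j]
            self.c12A[k] = math.sqrt(bi.lj_A[0] * bj.lj_A[0])
            self.c6A[k] = math.sqrt(bi.lj_A[1] * bj.lj_A[1])
            self.c12B[k] = math.sqrt(bi.lj_B[0] * bj.lj_B[0])
            self.c6B[k] = math.sqrt(bi.lj_B[1] * bj.lj_B[1])
            self.qqA[k] = bi.charge_A * bj.charge_A
            self.qqB[k] = bi.charge_B * bj.charge_B
            self.pert[k] = (bi.lj_A != bi.lj_B or bj.lj_A != bj.lj_B
                            or bi.charge_A != bi.charge_B
                            or bj.charge_A != bj.charge_B)
            self.xexcl[k] = (i, j) in top.extra_exclusions
        with np.errstate(divide="ignore", invalid="ignore"):
            self.c126A = np.where(self.c6A > 0, self.c12A / np.maximum(self.c6A, 1e-300), 0.0)
            self.c126B = np.where(self.c6B > 0, self.c12B / np.maximum(self.c6B, 1e-300), 0.0)
        self.crf = top.rf.crf
        self.rc = top.rf.cutoff

    def energy_args(self):
        return (self.zp, self.zgeom, self.pi, self.pj, self.c12A, self.c6A,
                self.c12B, self.c6B, self.c126A, self.c126B, self.qqA,
                self.qqB, self.pert, self.xexcl)


# ---------------------------------------------------------------------------
# default model parameters
# ---------------------------------------------------------------------------

#: GROMOS-flavoured united-atom LJ coefficients (C12 [kJ/mol nm^12],
#: C6 [kJ/mol nm^6]) and partial charges for the backbone fragment.
DEFAULT_CONFIG: dict = {
    "temperature_K": 298.0,
    "eps_rf": 61.0,
    "rf_cutoff": 1.4,
    # per-bead (C12, C6): bare carbonyl C, carbonyl O, amide N,
    # amide H (tiny core so no pair can collapse), CH1 alpha carbon,
    # CH3 side chain
    "lj": {
        "C": (4.937e-6, 2.340e-3),
        "O": (4.500e-6, 2.262e-3),
        "N": (8.134e-6, 2.480e-3),
        "H": (1.500e-8, 8.000e-5),
        "CA": (9.700e-5, 6.068e-3),
        "CB": (4.797e-5, 9.614e-3),
    },
    "charges": {
        "C1": 0.38, "O1": -0.38, "N": -0.28, "H": 0.28,
        "CA": 0.0, "CB": 0.0, "C": 0.38, "O": -0.38, "N2": -0.28,
    },
    # side-chain bead at state A; override to emulate a smaller
    # united-atom type (e.g. CH2)
    "side_chain_lj": None,
    # torsional terms k (1 + cos(m phi - delta)); barrier 2k = 1 kJ/mol
    "torsion_k": 0.5,
    "torsion_m": 3,
    # fixed dihedral offset of CB from C around the N-CA axis
    "cb_offset_deg": -122.0,
    # bond angles (deg) by placed bead name
    "bond_angles": {
        "CA": 122.0, "O1": 123.0, "H": 119.0, "C": 111.0,
        "CB": 110.0, "O": 121.0, "N2": 119.0,
    },
}

_BEAD_NAMES = ["C1", "N", "CA", "O1", "H", "C", "CB", "O", "N2"]
_BEAD_TYPES = {"C1": "C", "N": "N", "CA": "CA", "O1": "O", "H": "H",
               "C": "C", "CB": "CB", "O": "O", "N2": "N"}
IDX = {n: i for i, n in enumerate(_BEAD_NAMES)}


def build_toy_mutation(config: dict | None = None, **overrides) -> ToyTopology:
    """Build the default two-torsion Ala -> Gly toy topology.

    The topology has exactly two torsional DOFs (phi2, psi2) and one
    perturbed side-chain bead ``CB`` (CH3 at state A, dummy at state B)
    whose four 1,4 neighbours are the previous carbonyl carbon, the
    amide hydrogen, the carbonyl oxygen and the next amide nitrogen.
    ``config``/keyword overrides update :data:`DEFAULT_CONFIG`.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    cfg.update(overrides)
    lj = dict(DEFAULT_CONFIG["lj"])
    lj.update(cfg.get("lj", {}))
    q = dict(DEFAULT_CONFIG["charges"])
    q.update(cfg.get("charges", {}))
    cb_lj = cfg.get("side_chain_lj") or lj["CB"]

    beads = []
    for name in _BEAD_NAMES:
        params = cb_lj if name == "CB" else lj[_BEAD_TYPES[name]]
        pert = name == "CB"
        beads.append(Bead(
            index=IDX[name], name=name,
            lj_A=tuple(params),
            lj_B=(0.0, 0.0) if pert else tuple(params),
            charge_A=q[name],
            charge_B=0.0 if pert else q[name],
            is_perturbed=pert,
        ))

    off = cfg["cb_offset_deg"]
    ang = dict(DEFAULT_CONFIG["bond_angles"])
    ang.update(cfg.get("bond_angles", {}))
    zmat = [
        ZRow(-1, -1, -1, 0.0, 0.0, -1, 0.0),            # C1 at origin
        ZRow(IDX["C1"], -1, -1, 0.133, 0.0, -1, 0.0),   # N
        ZRow(IDX["N"], IDX["C1"], -1, 0.147, ang["CA"], -1, 0.0),       # CA
        ZRow(IDX["C1"], IDX["N"], IDX["CA"], 0.123, ang["O1"], -1, 0.0),  # O1 cis CA
        ZRow(IDX["N"], IDX["C1"], IDX["O1"], 0.100, ang["H"], -1, 180.0),  # H
        ZRow(IDX["CA"], IDX["N"], IDX["C1"], 0.153, ang["C"], 0, 0.0),   # C: phi2
        ZRow(IDX["CA"], IDX["N"], IDX["C1"], 0.153, ang["CB"], 0, off),  # CB
        ZRow(IDX["C"], IDX["CA"], IDX["N"], 0.123, ang["O"], 1, 180.0),  # O
        ZRow(IDX["C"], IDX["CA"], IDX["N"], 0.133, ang["N2"], 1, 0.0),   # N2: psi2
    ]

    bonds = {tuple(sorted((i, z.parent))) for i, z in enumerate(zmat) if i > 0}
    neigh = {i: set() for i in range(len(beads))}
    for i, j in bonds:
        neigh[i].add(j)
        neigh[j].add(i)
    excl = set(bonds)
    for c in neigh:                       # 1,3 pairs via a common centre
        for i in neigh[c]:
            for j in neigh[c]:
                if i < j:
                    excl.add((i, j))
    cb = IDX["CB"]
    extra = {tuple(sorted((cb, IDX[x]))) for x in ("C1", "H", "O", "N2")}
    if extra & excl:
        raise ValueError("1,4 pairs of the side-chain bead must not be excluded")

    k, m = float(cfg["torsion_k"]), int(cfg["torsion_m"])
    top = ToyTopology(
        beads=beads,
        zmat=zmat,
        torsion_dofs=[((IDX["C1"], IDX["N"], IDX["CA"], IDX["C"]), "phi2"),
                      ((IDX["N"], IDX["CA"], IDX["C"], IDX["N2"]), "psi2")],
        torsion_terms=[(0, k, m, 0.0), (1, k, m, 0.0)],
        exclusions=excl,
        extra_exclusions=extra,
        rf=RFParams(eps_rf=cfg["eps_rf"], cutoff=cfg["rf_cutoff"]),
        temperature_K=float(cfg["temperature_K"]),
    )
    _check_no_overlap(top)
    return top


def _check_no_overlap(top: ToyTopology, scan_deg: float = 15.0,
                      r_min: float = 0.02) -> None:
    """Reject geometries where a nonbonded pair distance can reach zero."""
    t = top.tables()
    grid = np.arange(-180.0, 180.0, scan_deg)
    worst = np.inf
    for ang in itertools.product(grid, repeat=top.n_dof):
        c = place_kernel(t.zp, t.zgeom, np.array(ang, dtype=float))
        d = np.linalg.norm(c[t.pi] - c[t.pj], axis=1)
        worst = min(worst, d.min())
    if worst < r_min:
        raise ValueError(
            f"fixed geometry allows a nonbonded pair distance of {worst:.4f} nm"
            " (overlapping beads)")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def place_beads(top: ToyTopology, s: TorsionState) -> np.ndarray:
    """Deterministic Cartesian coordinates (nm) for a torsion state."""
    ang = np.atleast_1d(np.asarray(s.angles if isinstance(s, TorsionState)
                                   else s, dtype=float))
    if ang.shape[0] != top.n_dof:
        raise ValueError("state has wrong number of torsions")
    t = top.tables()
    return place_kernel(t.zp, t.zgeom, ang)


def dihedral_deg(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(wrap_deg(math.degrees(math.atan2(y, x))))


def measure_torsions(top: ToyTopology, coords: np.ndarray) -> np.ndarray:
    """Recompute the torsion DOF values (degrees) from coordinates."""
    out = np.empty(top.n_dof)
    for k, (quad, _label) in enumerate(top.torsion_dofs):
        i, j, l, m = quad
        out[k] = dihedral_deg(coords[i], coords[j], coords[l], coords[m])
    return out


# ---------------------------------------------------------------------------
# pair potentials (reference scalar implementations)
# ---------------------------------------------------------------------------

def softcore_lj(r: float, C12_A: float, C6_A: float, C12_B: float,
                C6_B: float, lam: float, sc: SoftcoreParams) -> float:
    """Softcore Lennard-Jones pair energy (kJ/mol) at coupling ``lam``."""
    if r < 0:
        raise ValueError("negative distance")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda outside [0, 1]")
    r6 = r ** 6
    u = 0.0
    if C12_A or C6_A:
        dA = sc.alpha_vdw * lam ** 2 * (C12_A / C6_A if C6_A else 0.0) + r6
        u += (1.0 - lam) ** sc.n_power * (C12_A / dA - C6_A) / dA
    if C12_B or C6_B:
        dB = sc.alpha_vdw * (1.0 - lam) ** 2 * (C12_B / C6_B if C6_B else 0.0) + r6
        u += lam ** sc.n_power * (C12_B / dB - C6_B) / dB
    return u


def softcore_rf(r: float, q_i: float, q_j: float, lam: float,
                sc: SoftcoreParams, rf: RFParams,
                qB_i: float = 0.0, qB_j: float = 0.0) -> float:
    """Softcore Coulomb + reaction-field pair energy (kJ/mol).

    ``q_i, q_j`` are the A-state charges (vanishing as lam -> 1);
    ``qB_i, qB_j`` the B-state charges (appearing), zero by default.
    """
    if r < 0:
        raise ValueError("negative distance")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda outside [0, 1]")
    crf = rf.crf
    rc3 = rf.cutoff ** 3
    cst = (1.0 - 0.5 * crf) / rf.cutoff
    u = 0.0
    qqA = q_i * q_j
    qqB = qB_i * qB_j
    if qqA:
        s = sc.alpha_crf * lam ** 2 + r ** 2
        u += (1.0 - lam) ** sc.n_power * FELEC * qqA * (
            1.0 / math.sqrt(s) - 0.5 * crf * s / rc3 - cst)
    if qqB:
        s = sc.alpha_crf * (1.0 - lam) ** 2 + r ** 2
        u += lam ** sc.n_power * FELEC * qqB * (
            1.0 / math.sqrt(s) - 0.5 * crf * s / rc3 - cst)
    return u


# ---------------------------------------------------------------------------
# system energies
# ---------------------------------------------------------------------------

def _variant_code(variant: str) -> int:
    try:
        return _VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown Hamiltonian variant {variant!r}") from None


def potential_energy(top: ToyTopology, s, lam: float,
                     sc: SoftcoreParams | None = None,
                     variant: str = "standard"):
    """Total potential energy and its components.

    Returns ``(U_total, components)`` with components a dict holding the
    ``torsional``, ``lj`` and ``rf`` contributions (kJ/mol).  The
    ``reference_R`` variant ignores ``lam`` and evaluates the fixed
    softcore reference Hamiltonian (pass ``reference_softcore()`` as
    ``sc``).
    """
    sc = sc or SoftcoreParams()
    ang = np.atleast_1d(np.asarray(
        s.angles if isinstance(s, TorsionState) else s, dtype=float))
    t = top.tables()
    u_t, u_lj, u_rf = energy_kernel(
        *t.energy_args(), *_torsion_arrays(top), ang, float(lam),
        sc.alpha_vdw, sc.alpha_crf, sc.n_power, t.crf, t.rc,
        _variant_code(variant))
    total = u_t + u_lj + u_rf
    if not np.isfinite(total):
        raise FloatingPointError(
            "non-finite potential energy; softcore settings are broken")
    return total, {"torsional": u_t, "lj": u_lj, "rf": u_rf}


def dU_dlambda(top: ToyTopology, s, lam: float,
               sc: SoftcoreParams | None = None,
               variant: str = "standard") -> float:
    """Analytic dU/dlambda of the softcore pair terms (kJ/mol)."""
    sc = sc or SoftcoreParams()
    ang = np.atleast_1d(np.asarray(
        s.angles if isinstance(s, TorsionState) else s, dtype=float))
    t = top.tables()
    val = dudl_kernel(*t.energy_args(), *_torsion_arrays(top), ang,
                      float(lam), sc.alpha_vdw, sc.alpha_crf, sc.n_power,
                      t.crf, t.rc, _variant_code(variant))
    if not np.isfinite(val):
        raise FloatingPointError("non-finite dU/dlambda")
    return float(val)


def batch_energy(top: ToyTopology, states_deg: np.ndarray, lam: float,
                 sc: SoftcoreParams, variant: str = "standard",
                 want_dudl: bool = False):
    """Vectorised U (and optionally dU/dl) over an (n, n_dof) array."""
    t = top.tables()
    U, D = batch_energy_kernel(
        *t.energy_args(), *_torsion_arrays(top),
        np.ascontiguousarray(states_deg, dtype=float), float(lam),
        sc.alpha_vdw, sc.alpha_crf, sc.n_power, t.crf, t.rc,
        _variant_code(variant), want_dudl)
    return (U, D) if want_dudl else U


def _torsion_arrays(top: ToyTopology):
    terms = top.torsion_terms
    return (np.array([t[0] for t in terms], dtype=np.int64),
            np.array([t[1] for t in terms]),
            np.array([float(t[2]) for t in terms]),
            np.array([math.radians(t[3]) for t in terms]))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def topology_to_yaml(top: ToyTopology) -> str:
    """Serialize a topology to canonical YAML."""
    doc = {
        "temperature_K": top.temperature_K,
        "reaction_field": {"eps_rf": top.rf.eps_rf, "cutoff": top.rf.cutoff},
        "beads": [{
            "index": b.index, "name": b.name,
            "lj_A": list(b.lj_A), "lj_B": list(b.lj_B),
            "charge_A": b.charge_A, "charge_B": b.charge_B,
            "is_perturbed": b.is_perturbed,
        } for b in top.beads],
        "zmat": [{
            "parent": z.parent, "angle_ref": z.angle_ref,
            "torsion_ref": z.torsion_ref, "bond": z.bond,
            "angle_deg": z.angle_deg, "dof": z.dof,
            "dihedral_deg": z.dihedral_deg,
        } for z in top.zmat],
        "torsion_dofs": [{"quad": list(q), "label": lab}
                         for q, lab in top.torsion_dofs],
        "torsion_terms": [list(t) for t in top.torsion_terms],
        "exclusions": sorted(list(p) for p in top.exclusions),
        "extra_exclusions": sorted(list(p) for p in top.extra_exclusions),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def topology_from_yaml(text: str) -> ToyTopology:
    doc = yaml.safe_load(text)
    return ToyTopology(
        beads=[Bead(index=b["index"], name=b["name"],
                    lj_A=tuple(b["lj_A"]), lj_B=tuple(b["lj_B"]),
                    charge_A=b["charge_A"], charge_B=b["charge_B"],
                    is_perturbed=b["is_perturbed"]) for b in doc["beads"]],
        zmat=[ZRow(**z) for z in doc["zmat"]],
        torsion_dofs=[(tuple(d["quad"]), d["label"])
                      for d in doc["torsion_dofs"]],
        torsion_terms=[(int(t[0]), float(t[1]), int(t[2]), float(t[3]))
                       for t in doc["torsion_terms"]],
        exclusions={tuple(p) for p in doc["exclusions"]},
        extra_exclusions={tuple(p) for p in doc["extra_exclusions"]},
        rf=RFParams(**doc["reaction_field"]),
        temperature_K=doc["temperature_K"],
    )
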