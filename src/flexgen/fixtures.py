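"""Synthetic two-conformation test proteins.

Builds an idealized hinged peptide — two α-helical arms joined by a
three-residue loop — in two conformations that differ only by a rigid
rotation of the second arm about the hinge, plus synthetic pockets
(one bridging the hinge cleft, plus surface decoys) and a fake modulator
atom cluster.  Everything is deterministic given the seed, so the whole
pipeline is testable without downloading structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .perturbation import Pocket
from .structure_io import Atom, Structure

__all__ = ["HingeSpec", "make_hinge_pair", "make_pockets",
           "make_modulator_atoms"]

# Ideal backbone internal coordinates (lengths Å, angles deg).
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
LOOP_PHI_PSI = (-80.0, 130.0)  # generic/coil region

_ONE_TO_THREE = {"A": "ALA", "L": "LEU", "K": "LYS", "E": "GLU"}


@dataclass(frozen=True)
class HingeSpec:
    n_res_per_arm: int = 11
    hinge_angle_a: float = 15.0
    hinge_angle_b: float = 85.0
    sequence: str = ""    # auto-generated KALE pattern when empty
    seed: int = 0

    def __post_init__(self):
        if self.n_res_per_arm < 5:
            raise ValueError("need at least 5 residues per arm")
        for ang in (self.hinge_angle_a, self.hinge_angle_b):
            if not 0 < ang < 180:
                raise ValueError("hinge angles must lie in (0, 180) degrees")

    @property
    def n_res(self) -> int:
        return 2 * self.n_res_per_arm + 3

    def full_sequence(self) -> str:
        if self.sequence:
            if len(self.sequence) != self.n_res:
                raise ValueError("sequence length must be 2*arm + 3")
            bad = set(self.sequence) - set(_ONE_TO_THREE)
            if bad:
                raise ValueError(f"unsupported residue letters: {bad}")
            return self.sequence
        arm = ("KALE" * (self.n_res_per_arm // 4 + 1))[:self.n_res_per_arm]
        return arm + "AAA" + arm


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          r: float, theta: float, chi: float) -> np.ndarray:
    """Place atom D from A-B-C with bond r, angle B-C-D, torsion A-B-C-D."""
    theta = math.radians(theta)
    chi = math.radians(chi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-r * math.cos(theta),
                        r * math.sin(theta) * math.cos(chi),
                        r * math.sin(theta) * math.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_sidechain(res_name: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray) -> list[tuple[str, np.ndarray]]:
    if res_name == "GLY":
        return []
    # improper placement of CB gives the L configuration
    cb = _nerf(c, n, ca, 1.53, 110.6, 122.6)
    out = [("CB", cb)]
    if res_name == "ALA":
        return out
    chi1 = -65.0
    cg = _nerf(n, ca, cb, 1.53, 114.0, chi1)
    if res_name == "LEU":
        out += [("CG", cg),
                ("CD1", _nerf(ca, cb, cg, 1.52, 110.7, 175.0)),
                ("CD2", _nerf(ca, cb, cg, 1.52, 110.7, 55.0))]
    elif res_name == "LYS":
        cd = _nerf(ca, cb, cg, 1.52, 111.0, 180.0)
        ce = _nerf(cb, cg, cd, 1.52, 111.0, 180.0)
        nz = _nerf(cg, cd, ce, 1.49, 111.0, 180.0)
        out += [("CG", cg), ("CD", cd), ("CE", ce), ("NZ", nz)]
    elif res_name == "GLU":
        cd = _nerf(ca, cb, cg, 1.52, 112.0, 180.0)
        oe1 = _nerf(cb, cg, cd, 1.25, 118.0, 0.0)
        oe2 = _nerf(cb, cg, cd, 1.25, 118.0, 180.0)
        out += [("CG", cg), ("CD", cd), ("OE1", oe1), ("OE2", oe2)]
    else:
        raise ValueError(f"no side-chain template for {res_name}")
    return out


def _build_peptide(seq3: list[str], phi_psi: list[tuple[float, float]]
                   ) -> list[tuple[int, str, np.ndarray]]:
    """All heavy atoms of a chain from per-residue (phi, psi); omega trans."""
    atoms: list[tuple[int, str, np.ndarray]] = []
    n_prev = np.array([0.0, 0.0, 0.0])
    ca_prev = np.array([BOND_N_CA, 0.0, 0.0])
    th = math.radians(180.0 - ANGLE_N_CA_C)
    c_prev = ca_prev + BOND_CA_C * np.array([math.cos(th), math.sin(th), 0.0])
    for i, res in enumerate(seq3):
        phi, psi = phi_psi[i]
        if i == 0:
            n_i, ca_i, c_i = n_prev, ca_prev, c_prev
        else:
            n_i = _nerf(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N,
                        phi_psi[i - 1][1])
            ca_i = _nerf(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            c_i = _nerf(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        o_i = _nerf(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms.append((i, "N", n_i))
        atoms.append((i, "CA", ca_i))
        atoms.append((i, "C", c_i))
        atoms.append((i, "O", o_i))
        for name, xyz in _build_sidechain(res, n_i, ca_i, c_i):
            atoms.append((i, name, xyz))
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i
    return atoms


def _to_structure(atoms: list[tuple[int, str, np.ndarray]],
                  seq3: list[str], title: str) -> Structure:
    out = []
    for serial, (ri, name, xyz) in enumerate(atoms, start=1):
        out.append(Atom(serial=serial, name=name, element=name[0],
                        residue_name=seq3[ri], residue_index=ri,
                        chain_id="A", coords=np.asarray(xyz, dtype=float),
                        res_seq=ri + 1))
    return Structure(out, title=title)


def make_hinge_pair(spec: HingeSpec) -> tuple[Structure, Structure]:
    """Two conformations of the hinged peptide with identical rosters.

    The base chain is built once; each conformation rotates the second arm
    rigidly about an axis through the backbone N of its first residue, so
    all bond lengths are preserved exactly and only the hinge angle differs.
    The axis runs along the first arm's helix axis, so the second arm swings
    azimuthally around the first — intermediate angles bring the arms closer
    than in either end state, which makes the two states distinct basins of
    the derived constraint set rather than ends of a flat continuum.
    """
    seq = spec.full_sequence()
    seq3 = [_ONE_TO_THREE[c] for c in seq]
    n_arm = spec.n_res_per_arm
    phi_psi = ([HELIX_PHI_PSI] * n_arm + [LOOP_PHI_PSI] * 3
               + [HELIX_PHI_PSI] * n_arm)
    base = _build_peptide(seq3, phi_psi)

    arm2_start = n_arm + 3
    by_key = {(ri, name): xyz for ri, name, xyz in base}
    pivot = by_key[(arm2_start, "N")]
    axis = by_key[(n_arm - 1, "CA")] - by_key[(0, "CA")]
    axis /= np.linalg.norm(axis)

    def _conformation(angle_deg: float, label: str) -> Structure:
        rot = Rotation.from_rotvec(math.radians(angle_deg) * axis)
        atoms = []
        for ri, name, xyz in base:
            if ri >= arm2_start and not (ri == arm2_start and name == "N"):
                xyz = rot.apply(xyz - pivot) + pivot
            atoms.append((ri, name, xyz))
        return _to_structure(atoms, seq3, f"hinge peptide ({label})")

    return (_conformation(spec.hinge_angle_a, "state A"),
            _conformation(spec.hinge_angle_b, "state B"))


def _arm_atom_coords(s: Structure, spec: HingeSpec, arm: int) -> np.ndarray:
    n_arm = spec.n_res_per_arm
    lo, hi = (0, n_arm) if arm == 1 else (n_arm + 3, spec.n_res)
    return np.array([a.coords for a in s.atoms if lo <= a.residue_index < hi])


def make_pockets(pair: tuple[Structure, Structure], spec: HingeSpec,
                 n_decoys: int = 3, seed: int = 0) -> list[Pocket]:
    """One hinge-bridging pocket plus ``n_decoys`` single-arm surface decoys.

    All volumes clear the 13 Å³ filter; pocket 1 (largest volume) is the
    bridging one.  Point clouds are 150-point uniform balls of radius 2.5 Å.
    """
    s = pair[0]
    rng = np.random.default_rng(seed)
    n_arm = spec.n_res_per_arm
    ca = {a.residue_index: a.coords for a in s.atoms if a.name == "CA"}
    centroid = s.coords.mean(axis=0)

    def _ball(center: np.ndarray, radius: float = 2.5,
              n_points: int = 150) -> np.ndarray:
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        radii = radius * rng.random(n_points) ** (1.0 / 3.0)
        return center + pts * radii[:, None]

    # bridging pocket: between the hinge-proximal ends of the two arms
    c1 = np.mean([ca[i] for i in range(n_arm - 3, n_arm)], axis=0)
    c2 = np.mean([ca[i] for i in range(n_arm + 3, n_arm + 6)], axis=0)
    bridge_center = 0.5 * (c1 + c2)
    pockets = [Pocket(id=1, center=bridge_center,
                      points=_ball(bridge_center), volume=100.0)]

    # decoys anchored at the distal ends of the arms, pushed outward
    anchors = [1, spec.n_res - 2, 3, spec.n_res - 4, 5, spec.n_res - 6]
    for k in range(n_decoys):
        anchor = ca[anchors[k % len(anchors)]]
        outward = anchor - centroid
        outward /= np.linalg.norm(outward)
        center = anchor + 6.0 * outward
        pockets.append(Pocket(id=k + 2, center=center,
                              points=_ball(center), volume=90.0 - 10.0 * k))
    return pockets


def make_modulator_atoms(pocket: Pocket) -> np.ndarray:
    """A compact 10-atom pseudo-ligand centred on the pocket (diameter < 4 Å)."""
    offsets = np.array([
        [0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [-1.2, 0.0, 0.0],
        [0.0, 1.2, 0.0], [0.0, -1.2, 0.0], [0.0, 0.0, 1.2],
        [0.0, 0.0, -1.2], [0.8, 0.8, 0.8], [-0.8, -0.8, 0.8],
        [0.8, -0.8, -0.8],
    ])
    return np.asarray(pocket.center, dtype=float) + offsets
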