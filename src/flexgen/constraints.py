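"""Interaction classification and distance-constraint generation.

Every atom pair of a structure is assigned exactly one of 15 interaction
types (covalent bond, bond angle, ring, four flavours of 1-4 dihedral pair,
secondary structure, salt bridge, hydrogen bond, two hydrophobic shells, and
the generic remainder), each with a fixed tolerance.  Pairs get the
lowest-numbered type whose criterion they satisfy.  Bounds for a pair at
observed distance d are d ± wb * tolerance, combined across the two input
conformations by interval union, and the vastly more numerous generic pairs
are subsampled to roughly 20 per atom.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from ._templates import (
    DOUBLE_BOND_CENTRAL, NEGATIVE_GROUP, POSITIVE_GROUP, RING_ATOMS,
    SIDE_CHAIN_BONDS, STANDARD_RESIDUES, VDW_RADII,
    acceptor_atoms, donor_atoms,
)
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "TOLERANCES", "TYPE_NAMES", "InteractionType", "Constraint",
    "ConstraintSet", "classify_pairs", "make_bounds", "combine_bounds",
    "build_constraint_set", "subsample_other_pairs", "build_topology",
]

#: Constraint tolerance (Å) per interaction type code.
TOLERANCES: dict[int, float] = {
    1: 0.02, 2: 0.05, 3: 0.1, 4: 0.1, 5: 0.1, 6: 0.2, 7: 0.4, 8: 0.3,
    9: 0.4, 10: 0.5, 11: 0.75, 12: 0.5, 13: 0.5, 14: 1.0, 15: 5.0,
}

TYPE_NAMES: dict[int, str] = {
    1: "covalent bond", 2: "bond angle", 3: "ring",
    4: "double bond 1-4", 5: "omega 1-4", 6: "tight phi/psi 1-4",
    7: "loose phi/psi 1-4", 8: "other phi/psi 1-4", 9: "other 1-4",
    10: "secondary structure", 11: "salt bridge", 12: "hydrogen bond",
    13: "tight hydrophobic", 14: "loose hydrophobic", 15: "all other pairs",
}

GENERIC = 15

#: Distance cutoffs used by the distance-based criteria (Å).
SALT_BRIDGE_CUTOFF = 4.0
HBOND_DONOR_ACCEPTOR_CUTOFF = 3.5
HBOND_MIN_ANGLE_DEG = 90.0
PEPTIDE_BOND_CUTOFF = 1.8
DISULFIDE_CUTOFF = 2.5


@dataclass(frozen=True)
class InteractionType:
    code: int
    name: str = ""
    tolerance: float = 0.0

    def __post_init__(self):
        if self.code not in TOLERANCES:
            raise ValueError(f"unknown interaction type code {self.code}")
        object.__setattr__(self, "name", TYPE_NAMES[self.code])
        object.__setattr__(self, "tolerance", TOLERANCES[self.code])


class Constraint(NamedTuple):
    i: int
    j: int
    lower: float
    upper: float
    itype: int


@dataclass
class ConstraintSet:
    """All constraints for one embedding run, stored as flat arrays."""

    n_atoms: int
    wb: float
    seed: int
    i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lower: np.ndarray = field(default_factory=lambda: np.empty(0))
    upper: np.ndarray = field(default_factory=lambda: np.empty(0))
    itype: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len({len(self.i), len(self.j), len(self.lower),
                len(self.upper), len(self.itype)}) != 1:
            raise ValueError("constraint arrays have inconsistent lengths")
        if len(self.i):
            if self.i.min() < 0 or max(self.i.max(), self.j.max()) >= self.n_atoms:
                raise ValueError("constraint indices out of range")
            if np.any(self.i >= self.j):
                raise ValueError("constraints must have i < j")
            if np.any(self.lower <= 0) or np.any(self.lower > self.upper):
                raise ValueError("require 0 < lower <= upper")
            pairs = self.i * self.n_atoms + self.j
            if len(np.unique(pairs)) != len(pairs):
                raise ValueError("duplicate atom pair in constraint set")

    def __len__(self) -> int:
        return len(self.i)

    def __iter__(self) -> Iterator[Constraint]:
        for k in range(len(self.i)):
            yield Constraint(int(self.i[k]), int(self.j[k]),
                             float(self.lower[k]), float(self.upper[k]),
                             int(self.itype[k]))

    @property
    def constraints(self) -> list[Constraint]:
        return list(self)

    def type_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.itype, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def extended(self, extra: list[Constraint], n_atoms: int | None = None
                 ) -> "ConstraintSet":
        """New set with additional constraints (e.g. modulator pseudo-atoms)."""
        n = n_atoms if n_atoms is not None else self.n_atoms
        ei = np.array([c.i for c in extra], dtype=np.int64)
        ej = np.array([c.j for c in extra], dtype=np.int64)
        return ConstraintSet(
            n_atoms=n, wb=self.wb, seed=self.seed,
            i=np.concatenate([self.i, ei]),
            j=np.concatenate([self.j, ej]),
            lower=np.concatenate([self.lower, [c.lower for c in extra]]),
            upper=np.concatenate([self.upper, [c.upper for c in extra]]),
            itype=np.concatenate([self.itype,
                                  np.array([c.itype for c in extra],
                                           dtype=np.int64)]))

    # TSV round trip: header comment carries n_atoms / wb / seed.
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_atoms={self.n_atoms}\twb={self.wb}\tseed={self.seed}\n")
            fh.write("i\tj\tlower\tupper\ttype_code\n")
            for c in self:
                fh.write(f"{c.i}\t{c.j}\t{c.lower:.6f}\t{c.upper:.6f}\t{c.itype}\n")

    @classmethod
    def from_tsv(cls, path) -> "ConstraintSet":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing metadata header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            fh.readline()  # column names
            rows = [line.split("\t") for line in fh if line.strip()]
        return cls(
            n_atoms=int(meta["n_atoms"]), wb=float(meta["wb"]),
            seed=int(meta["seed"]),
            i=np.array([int(r[0]) for r in rows], dtype=np.int64),
            j=np.array([int(r[1]) for r in rows], dtype=np.int64),
            lower=np.array([float(r[2]) for r in rows]),
            upper=np.array([float(r[3]) for r in rows]),
            itype=np.array([int(r[4]) for r in rows], dtype=np.int64))


# --- covalent topology -----------------------------------------------------

def build_topology(s: Structure) -> set[tuple[int, int]]:
    """Covalent bonds (i < j) from residue templates plus peptide and
    disulfide bonds detected by distance."""
    bonds: set[tuple[int, int]] = set()
    index: dict[tuple[int, str], int] = {}
    for k, a in enumerate(s.atoms):
        index[(a.residue_index, a.name)] = k

    residues = s.residues()
    res_names = [r[3] for r in residues]
    unknown = {n for n in res_names if n not in STANDARD_RESIDUES}
    if unknown:
        warnings.warn(f"unknown residues treated generically: {sorted(unknown)}")

    def _add(i: int | None, j: int | None) -> None:
        if i is not None and j is not None and i != j:
            bonds.add((min(i, j), max(i, j)))

    for ri, name in enumerate(res_names):
        tmpl = SIDE_CHAIN_BONDS.get(name, ())
        for a_name, b_name in (("N", "CA"), ("CA", "C"), ("C", "O"),
                               ("C", "OXT"), *tmpl):
            _add(index.get((ri, a_name)), index.get((ri, b_name)))

    # inter-residue peptide bonds: C(i)-N(i+1) within cutoff, same chain
    chain_of = {a.residue_index: a.chain_id for a in s.atoms}
    for ri in range(len(residues) - 1):
        if chain_of.get(ri) != chain_of.get(ri + 1):
            continue
        ci = index.get((ri, "C"))
        nj = index.get((ri + 1, "N"))
        if ci is not None and nj is not None:
            d = np.linalg.norm(s.atoms[ci].coords - s.atoms[nj].coords)
            if d < PEPTIDE_BOND_CUTOFF:
                _add(ci, nj)

    # disulfides
    sgs = [k for k, a in enumerate(s.atoms)
           if a.name == "SG" and a.residue_name == "CYS"]
    for x in range(len(sgs)):
        for y in range(x + 1, len(sgs)):
            d = np.linalg.norm(s.atoms[sgs[x]].coords - s.atoms[sgs[y]].coords)
            if d < DISULFIDE_CUTOFF:
                _add(sgs[x], sgs[y])
    return bonds


def _segments(sec_struct: list[str]) -> list[int]:
    """Per-residue segment id; -1 for coil, otherwise contiguous H/E runs."""
    seg = [-1] * len(sec_struct)
    cur = -1
    for i, lab in enumerate(sec_struct):
        if lab in ("H", "E"):
            if i == 0 or sec_struct[i - 1] != lab:
                cur += 1
            seg[i] = cur
    return seg


def _classify_specific(s: Structure) -> dict[tuple[int, int], int]:
    """Map pair -> interaction code for all specific (type 1-14) pairs.

    Types are assigned in ascending order; a pair keeps the first (lowest)
    matching code.
    """
    if len(s.sec_struct) != s.n_residues:
        raise ValueError("structure needs sec_struct assigned "
                         "(call assign_secondary_structure first)")
    atoms = s.atoms
    coords = s.coords
    assigned: dict[tuple[int, int], int] = {}

    def _claim(i: int, j: int, code: int) -> None:
        if i > j:
            i, j = j, i
        prev = assigned.get((i, j))
        if prev is None or code < prev:
            assigned[(i, j)] = code

    bonds = build_topology(s)
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)

    # 1: covalent bonds
    for i, j in bonds:
        _claim(i, j, 1)

    # 2: bond angles (shared bonded neighbour)
    for center, nbrs in neighbors.items():
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                if (min(nbrs[x], nbrs[y]), max(nbrs[x], nbrs[y])) not in bonds:
                    _claim(nbrs[x], nbrs[y], 2)

    # 3: ring systems (template membership, per residue)
    ring_members: dict[int, list[int]] = {}
    for k, a in enumerate(atoms):
        ring = RING_ATOMS.get(a.residue_name)
        if ring and a.name in ring:
            ring_members.setdefault(a.residue_index, []).append(k)
    for members in ring_members.values():
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                _claim(members[x], members[y], 3)

    # 4-9: 1-4 dihedral pairs, classified by the central bond
    seg = _segments(s.sec_struct)
    res_name = {a.residue_index: a.residue_name for a in atoms}
    omega_bonds = set()
    phi_psi_bonds = set()
    for i, j in bonds:
        ai, aj = atoms[i], atoms[j]
        names = {ai.name, aj.name}
        if ai.residue_index != aj.residue_index and names == {"C", "N"}:
            omega_bonds.add((i, j))
        elif ai.residue_index == aj.residue_index and names in ({"N", "CA"},
                                                                {"CA", "C"}):
            phi_psi_bonds.add((i, j))

    def _double_bond(i: int, j: int) -> bool:
        ai, aj = atoms[i], atoms[j]
        if ai.residue_index != aj.residue_index:
            return False
        central = DOUBLE_BOND_CENTRAL.get(ai.residue_name, frozenset())
        return ((ai.name, aj.name) in central or (aj.name, ai.name) in central)

    for b, c in bonds:
        if (b, c) in omega_bonds:
            code_bc = 5
        elif _double_bond(b, c):
            code_bc = 4
        elif (b, c) in phi_psi_bonds:
            code_bc = 0  # resolved per end-pair below
        else:
            code_bc = 9
        for a_idx in neighbors.get(b, ()):
            if a_idx == c:
                continue
            for d_idx in neighbors.get(c, ()):
                if d_idx == b or d_idx == a_idx:
                    continue
                code = code_bc
                if code == 0:
                    r1 = atoms[a_idx].residue_index
                    r2 = atoms[d_idx].residue_index
                    n1, n2 = res_name[r1], res_name[r2]
                    same_seg = seg[r1] != -1 and seg[r1] == seg[r2]
                    if "PRO" in (n1, n2) or same_seg:
                        code = 6
                    elif "GLY" in (n1, n2) or (s.sec_struct[r1] == "C"
                                               and s.sec_struct[r2] == "C"):
                        code = 7
                    else:
                        code = 8
                _claim(a_idx, d_idx, code)

    # 10: backbone pairs within one helix/strand segment, <= 4 residues apart
    backbone = [k for k, a in enumerate(atoms)
                if a.name in ("N", "CA", "C", "O")]
    by_seg: dict[int, list[int]] = {}
    for k in backbone:
        sg = seg[atoms[k].residue_index]
        if sg != -1:
            by_seg.setdefault(sg, []).append(k)
    for members in by_seg.values():
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                i, j = members[x], members[y]
                if abs(atoms[i].residue_index - atoms[j].residue_index) <= 4:
                    _claim(i, j, 10)

    # 11: salt bridges (opposite charges < 4 Å)
    def _group_atoms(table: dict[str, frozenset[str]]) -> list[int]:
        out = []
        for k, a in enumerate(atoms):
            if a.name in table.get(a.residue_name, frozenset()) \
                    or a.name in table.get("*", frozenset()):
                out.append(k)
        return out

    pos = _group_atoms(POSITIVE_GROUP)
    neg = _group_atoms(NEGATIVE_GROUP)
    if pos and neg:
        tree_neg = cKDTree(coords[neg])
        for p in pos:
            for hit in tree_neg.query_ball_point(coords[p], SALT_BRIDGE_CUTOFF):
                n_idx = neg[hit]
                d = np.linalg.norm(coords[p] - coords[n_idx])
                if d < SALT_BRIDGE_CUTOFF:
                    _claim(p, n_idx, 11)

    # 12: hydrogen bonds on heavy atoms: donor-acceptor <= 3.5 Å and
    # antecedent-donor-acceptor angle >= 90 deg (hydrogens are stripped).
    donors = [k for k, a in enumerate(atoms) if a.name in donor_atoms(a.residue_name)]
    acceptors = [k for k, a in enumerate(atoms)
                 if a.name in acceptor_atoms(a.residue_name)]
    if donors and acceptors:
        tree_acc = cKDTree(coords[acceptors])
        for dk in donors:
            antecedents = neighbors.get(dk, ())
            for hit in tree_acc.query_ball_point(coords[dk],
                                                 HBOND_DONOR_ACCEPTOR_CUTOFF):
                ak = acceptors[hit]
                if ak == dk or (min(dk, ak), max(dk, ak)) in bonds:
                    continue
                da = coords[ak] - coords[dk]
                ok_angle = False
                for ant in antecedents:
                    v = coords[ant] - coords[dk]
                    cosang = np.dot(v, da) / (np.linalg.norm(v)
                                              * np.linalg.norm(da) + 1e-12)
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) \
                            >= HBOND_MIN_ANGLE_DEG:
                        ok_angle = True
                        break
                if ok_angle:
                    _claim(dk, ak, 12)

    # 13/14: hydrophobic shells; carbon atoms only (H stripped)
    carbons = [k for k, a in enumerate(atoms) if a.element == "C"]
    if carbons:
        r_c = VDW_RADII["C"]
        tree_c = cKDTree(coords[carbons])
        for x, y in tree_c.query_pairs(2 * r_c + 1.0):
            i, j = carbons[x], carbons[y]
            d = np.linalg.norm(coords[i] - coords[j])
            if d < 2 * r_c + 0.5:
                _claim(i, j, 13)
            elif d < 2 * r_c + 1.0:
                _claim(i, j, 14)

    return assigned


def classify_pairs(s: Structure) -> dict[tuple[int, int], InteractionType]:
    """Interaction type for EVERY atom pair (generic pairs included).

    O(n^2) in atoms; intended for small structures and tests.  Pipeline code
    uses the sparse specific classification internally.
    """
    specific = _classify_specific(s)
    n = len(s.atoms)
    out: dict[tuple[int, int], InteractionType] = {}
    for i in range(n):
        for j in range(i + 1, n):
            out[(i, j)] = InteractionType(specific.get((i, j), GENERIC))
    return out


# --- bound generation ------------------------------------------------------

def make_bounds(d: float, itype: InteractionType | int, wb: float
                ) -> tuple[float, float]:
    """Bounds (d - wb*t, d + wb*t); lower clamped to 0.5*d if non-positive."""
    if d <= 0:
        raise ValueError("distance must be positive")
    if not 0 <= wb <= 1:
        raise ValueError("wb must be in [0, 1]")
    t = itype.tolerance if isinstance(itype, InteractionType) \
        else TOLERANCES[int(itype)]
    lower = d - wb * t
    if lower <= 0:
        lower = 0.5 * d
    return (lower, d + wb * t)


def combine_bounds(c1: Constraint, c2: Constraint) -> Constraint:
    """Union interval of two constraints on the same pair."""
    if (c1.i, c1.j) != (c2.i, c2.j):
        raise ValueError("cannot combine constraints for different atom pairs")
    return Constraint(c1.i, c1.j,
                      min(c1.lower, c2.lower), max(c1.upper, c2.upper),
                      min(c1.itype, c2.itype))


def subsample_other_pairs(pairs: np.ndarray, n_atoms: int, seed: int
                          ) -> np.ndarray:
    """Independently retain each generic pair with p = min(1, 20*n/|pairs|).

    ``pairs`` is an (m, 2) index array; returns the retained subset in order.
    """
    pairs = np.asarray(pairs)
    m = len(pairs)
    if m == 0:
        return pairs
    p = min(1.0, 20.0 * n_atoms / m)
    if p >= 1.0:
        return pairs
    rng = np.random.default_rng(seed)
    return pairs[rng.random(m) < p]


def build_constraint_set(a: Structure, b: Structure, wb: float, seed: int = 0
                         ) -> ConstraintSet:
    """Classify pairs in both conformations, build and combine bounds.

    Pairs generic (type 15) in BOTH structures are subsampled to an expected
    20 per atom; any pair specific in either structure is always kept.
    """
    if len(a) != len(b):
        raise ValueError("structures must share one atom roster "
                         "(run intersect_atoms first)")
    n = len(a)
    spec_a = _classify_specific(a)
    spec_b = _classify_specific(b)
    specific_pairs = sorted(set(spec_a) | set(spec_b))

    iu, ju = np.triu_indices(n, k=1)
    all_pairs = np.column_stack([iu, ju])
    if specific_pairs:
        spec_flat = np.array([i * n + j for i, j in specific_pairs])
        mask = np.isin(iu * n + ju, spec_flat)
        generic_pairs = all_pairs[~mask]
    else:
        generic_pairs = all_pairs
    kept_generic = subsample_other_pairs(generic_pairs, n, seed)

    pi = np.concatenate([np.array([p[0] for p in specific_pairs], dtype=np.int64),
                         kept_generic[:, 0]]) if specific_pairs \
        else kept_generic[:, 0].astype(np.int64)
    pj = np.concatenate([np.array([p[1] for p in specific_pairs], dtype=np.int64),
                         kept_generic[:, 1]]) if specific_pairs \
        else kept_generic[:, 1].astype(np.int64)

    code_a = np.full(len(pi), GENERIC, dtype=np.int64)
    code_b = np.full(len(pi), GENERIC, dtype=np.int64)
    for k, pair in enumerate(specific_pairs):
        code_a[k] = spec_a.get(pair, GENERIC)
        code_b[k] = spec_b.get(pair, GENERIC)

    xa, xb = a.coords, b.coords
    da = np.linalg.norm(xa[pi] - xa[pj], axis=1)
    db = np.linalg.norm(xb[pi] - xb[pj], axis=1)
    tol = np.vectorize(TOLERANCES.get)(code_a).astype(float)
    tol_b = np.vectorize(TOLERANCES.get)(code_b).astype(float)

    lo_a = da - wb * tol
    lo_a = np.where(lo_a <= 0, 0.5 * da, lo_a)
    lo_b = db - wb * tol_b
    lo_b = np.where(lo_b <= 0, 0.5 * db, lo_b)
    lower = np.minimum(lo_a, lo_b)
    upper = np.maximum(da + wb * tol, db + wb * tol_b)
    itype = np.minimum(code_a, code_b)

    order = np.lexsort((pj, pi))
    cs = ConstraintSet(n_atoms=n, wb=wb, seed=seed,
                       i=pi[order], j=pj[order],
                       lower=lower[order], upper=upper[order],
                       itype=itype[order])
    logger.info("constraint set: %d constraints for %d atoms (%s)",
                len(cs), n,
                ", ".join(f"t{c}={v}" for c, v in sorted(cs.type_counts().items())))
    return cs
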