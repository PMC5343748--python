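"""PDB structure and ensemble I/O.

Reading is backed by Biopython's :class:`Bio.PDB.PDBParser`; the rest of the
package works on the lightweight :class:`Atom`/:class:`Structure`/
:class:`Ensemble` types defined here.  Atom order is canonicalised to
(chain, residue number + insertion code, PDB atom-name order) so that two
structures of the same protein can be compared index-by-index after
:func:`intersect_atoms`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from ._templates import atom_sort_rank

__all__ = [
    "Atom", "Structure", "Ensemble", "StructureError",
    "read_structure", "strip_non_protein", "intersect_atoms",
    "assign_secondary_structure", "write_ensemble", "read_ensemble",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised for malformed or incompatible structure input."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom: identity plus coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int      # 0-based sequential index over the roster
    chain_id: str
    coords: np.ndarray      # shape (3,), Å
    res_seq: int = 0        # author residue number, output only
    icode: str = ""         # insertion code, output only
    het: bool = False

    def key(self) -> tuple:
        """Identity key used to match atoms between two structures."""
        return (self.chain_id, self.res_seq, self.icode,
                self.residue_name, self.name)


@dataclass
class Structure:
    """An ordered list of atoms for one conformation."""

    atoms: list[Atom]
    title: str = ""
    sec_struct: list[str] = field(default_factory=list)  # per residue, H/E/C

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        atoms = [replace(a, coords=np.asarray(c, dtype=float))
                 for a, c in zip(self.atoms, coords, strict=True)]
        return Structure(atoms, self.title, list(self.sec_struct))

    def residues(self) -> list[tuple]:
        """Unique residues in roster order: (chain, res_seq, icode, name)."""
        seen: dict[tuple, tuple] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.res_seq, a.icode),
                            (a.chain_id, a.res_seq, a.icode, a.residue_name))
        return list(seen.values())

    @property
    def n_residues(self) -> int:
        return len(self.residues())

    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms)
                         if a.name == "CA"], dtype=int)

    def atom_index(self, chain_id: str, res_seq: int, name: str,
                   icode: str = "") -> int:
        for i, a in enumerate(self.atoms):
            if (a.chain_id == chain_id and a.res_seq == res_seq
                    and a.icode == icode and a.name == name):
                return i
        raise KeyError((chain_id, res_seq, icode, name))


@dataclass
class Ensemble:
    """Models sharing one atom roster, with per-model error scores."""

    roster: Structure
    models: list[np.ndarray]
    error_scores: list[float] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        n = len(self.roster)
        for m in self.models:
            if m.shape != (n, 3):
                raise StructureError(
                    f"model shape {m.shape} != roster size ({n}, 3)")
        if not self.error_scores:
            self.error_scores = [0.0] * len(self.models)
        if len(self.error_scores) != len(self.models):
            raise StructureError("error_scores length != number of models")

    def __len__(self) -> int:
        return len(self.models)


def _canonical_sort(atoms: list[Atom]) -> list[Atom]:
    atoms = sorted(atoms, key=lambda a: (
        a.chain_id, a.res_seq, a.icode,
        atom_sort_rank(a.residue_name, a.name)))
    return _reindex(atoms)


def _reindex(atoms: list[Atom]) -> list[Atom]:
    """Renumber residue_index sequentially over the (sorted) atom list."""
    out: list[Atom] = []
    idx = -1
    prev = None
    for a in atoms:
        rid = (a.chain_id, a.res_seq, a.icode)
        if rid != prev:
            idx += 1
            prev = rid
        out.append(replace(a, residue_index=idx))
    return out


def read_structure(path, model_index: int = 0) -> Structure:
    """Read one model from a PDB file into a canonical-order Structure.

    Alternate locations collapse to the highest-occupancy conformer
    (ties keep the first encountered).  HETATM records are kept and flagged;
    use :func:`strip_non_protein` to drop them.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            bio = parser.get_structure("s", str(path))
        except FileNotFoundError:
            raise
        except Exception as exc:  # malformed file
            raise StructureError(f"cannot parse PDB file {path}: {exc}")
    models = list(bio.get_models())
    if not models:
        raise StructureError(f"no models in {path}")
    if not 0 <= model_index < len(models):
        raise StructureError(
            f"model_index {model_index} out of range (file has {len(models)})")
    model = models[model_index]

    atoms: list[Atom] = []
    n_atom_records = 0
    for chain in model:
        for res in chain:
            hetfield, res_seq, icode = res.id
            het = hetfield.strip() != ""
            if not het:
                n_atom_records += 1
            for at in res.get_atoms():  # disordered atoms yield selected child
                element = (at.element or "").strip().upper()
                atoms.append(Atom(
                    serial=at.serial_number or 0,
                    name=at.get_name().strip(),
                    element=element,
                    residue_name=res.get_resname().strip(),
                    residue_index=0,
                    chain_id=chain.id if chain.id.strip() else "A",
                    coords=np.asarray(at.coord, dtype=float),
                    res_seq=res_seq,
                    icode=icode.strip(),
                    het=het,
                ))
    if n_atom_records == 0:
        raise StructureError(f"no ATOM records in {path}")
    for a in atoms:
        if not np.all(np.isfinite(a.coords)):
            raise StructureError(f"non-finite coordinates for atom {a.key()}")
    return Structure(_canonical_sort(atoms), title=str(path))


def strip_non_protein(s: Structure) -> Structure:
    """Drop HETATM-derived atoms, waters and all hydrogens; reindex."""
    kept = [a for a in s.atoms
            if not a.het
            and a.residue_name not in _WATER_NAMES
            and a.element not in ("H", "D")]
    return Structure(_reindex(kept), s.title, [])


def intersect_atoms(a: Structure, b: Structure) -> tuple[Structure, Structure]:
    """Restrict both structures to their common atoms, in identical order.

    Atoms are matched on (chain, residue number + insertion code, residue
    name, atom name).  Raises on an empty intersection.
    """
    keys_a = {at.key(): at for at in a.atoms}
    keys_b = {at.key(): at for at in b.atoms}
    if len(keys_a) != len(a.atoms) or len(keys_b) != len(b.atoms):
        raise StructureError("duplicate atom keys within one structure")
    common = set(keys_a) & set(keys_b)
    if not common:
        raise StructureError("no atoms in common between the two structures")
    out_a = _canonical_sort([keys_a[k] for k in common])
    out_b = _canonical_sort([keys_b[k] for k in common])
    return (Structure(out_a, a.title, []), Structure(out_b, b.title, []))


# --- secondary structure ---------------------------------------------------

_DSSP_TO_HEC = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def _parse_dssp(path) -> dict[tuple[str, int, str], str]:
    """Parse a classic DSSP output file to {(chain, resnum, icode): H/E/C}."""
    out: dict[tuple[str, int, str], str] = {}
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":  # chain break
                continue
            try:
                res_seq = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip()
            chain = line[11].strip() or "A"
            code = line[16].strip()
            out[(chain, res_seq, icode)] = _DSSP_TO_HEC.get(code, "C")
    if not out:
        raise StructureError(f"no residue records found in DSSP file {path}")
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(s: Structure) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None at chain termini or missing atoms."""
    res_atoms: dict[int, dict[str, np.ndarray]] = {}
    res_chain: dict[int, str] = {}
    for a in s.atoms:
        if a.name in ("N", "CA", "C"):
            res_atoms.setdefault(a.residue_index, {})[a.name] = a.coords
            res_chain[a.residue_index] = a.chain_id
    n_res = s.n_residues
    out: list[tuple[float | None, float | None]] = []
    for i in range(n_res):
        cur = res_atoms.get(i, {})
        prv = res_atoms.get(i - 1, {})
        nxt = res_atoms.get(i + 1, {})
        phi = psi = None
        same_prev = res_chain.get(i - 1) == res_chain.get(i)
        same_next = res_chain.get(i + 1) == res_chain.get(i)
        if same_prev and "C" in prv and all(k in cur for k in ("N", "CA", "C")):
            phi = _dihedral(prv["C"], cur["N"], cur["CA"], cur["C"])
        if same_next and "N" in nxt and all(k in cur for k in ("N", "CA", "C")):
            psi = _dihedral(cur["N"], cur["CA"], cur["C"], nxt["N"])
        out.append((phi, psi))
    return out


def _fallback_secondary_structure(s: Structure) -> list[str]:
    """Torsion-window assignment used when no DSSP file is supplied.

    Helix: phi in [-100, -30] and psi in [-80, -5] for >= 4 consecutive
    residues.  Strand: phi in [-180, -90] and psi in [90, 180] or
    [-180, -170] for >= 3 consecutive residues.  Everything else is coil.
    """
    dihed = backbone_dihedrals(s)
    n = len(dihed)
    helix_ok = [phi is not None and psi is not None
                and -100 <= phi <= -30 and -80 <= psi <= -5
                for phi, psi in dihed]
    strand_ok = [phi is not None and psi is not None
                 and -180 <= phi <= -90
                 and (90 <= psi <= 180 or -180 <= psi <= -170)
                 for phi, psi in dihed]
    labels = ["C"] * n

    def _mark(ok: list[bool], min_run: int, label: str) -> None:
        i = 0
        while i < n:
            if ok[i] and labels[i] == "C":
                j = i
                while j < n and ok[j] and labels[j] == "C":
                    j += 1
                if j - i >= min_run:
                    for k in range(i, j):
                        labels[k] = label
                i = j
            else:
                i += 1

    _mark(helix_ok, 4, "H")
    _mark(strand_ok, 3, "E")
    return labels


def assign_secondary_structure(s: Structure, dssp_path=None) -> Structure:
    """Fill per-residue H/E/C labels from a DSSP file or the torsion fallback.

    DSSP codes collapse as H,G,I -> H; E,B -> E; everything else -> C.
    Raises if the DSSP file does not cover every residue of ``s``.
    """
    if dssp_path is None:
        labels = _fallback_secondary_structure(s)
    else:
        table = _parse_dssp(dssp_path)
        labels = []
        missing = []
        for chain, res_seq, icode, _name in s.residues():
            key = (chain, res_seq, icode)
            if key not in table:
                missing.append(key)
            else:
                labels.append(table[key])
        if missing:
            raise StructureError(
                f"DSSP file does not cover residues: {missing[:10]}"
                + ("..." if len(missing) > 10 else ""))
    return Structure(list(s.atoms), s.title, labels)


# --- writing ---------------------------------------------------------------

def _format_atom_line(a: Atom, serial: int, x: float, y: float, z: float) -> str:
    name = a.name
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    record = "HETATM" if a.het else "ATOM  "
    return (f"{record}{serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.res_seq:4d}{a.icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")


def write_structure(s: Structure, path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms, start=1):
            fh.write(_format_atom_line(a, i, *a.coords) + "\n")
        fh.write("END\n")


def write_ensemble(e: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    if len(e) == 0:
        raise StructureError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        for m, coords in enumerate(e.models, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (a, xyz) in enumerate(zip(e.roster.atoms, coords), start=1):
                fh.write(_format_atom_line(a, i, *xyz) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_ensemble(path, roster: Structure | None = None) -> Ensemble:
    """Read a multi-model PDB back into an Ensemble."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio = parser.get_structure("e", str(path))
    models = list(bio.get_models())
    if not models:
        raise StructureError(f"no models in {path}")
    structures = [read_structure(path, model_index=i)
                  for i in range(len(models))]
    if roster is None:
        roster = structures[0]
    return Ensemble(roster=roster,
                    models=[s.coords for s in structures])
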