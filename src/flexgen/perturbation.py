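"""Pocket perturbation: simulated modulators and allosteric pocket ranking.

A candidate pocket is represented by 120 pseudo-atom points.  Each point is
tethered to every protein atom within 7 Å by a tight (±0.1 Å) distance
constraint, the ensemble is regenerated with the augmented constraint set,
and pockets are ranked by how far the perturbation moves the ensemble
average (Cα RMSD, largest shift first).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .analysis import average_structure, iterative_align, rmsd
from .constraints import Constraint, ConstraintSet
from .spe import SPEParams, generate_ensemble
from .structure_io import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "Pocket", "PerturbationResult", "filter_pockets", "sample_pocket_points",
    "ball_points", "modulator_constraints", "perturb_and_rank",
    "is_allosteric_pocket", "N_MODULATOR_POINTS", "MODULATOR_CUTOFF",
    "MODULATOR_TOLERANCE", "VOLUME_CUTOFF", "MAX_POCKETS",
    "ALLOSTERIC_DISTANCE",
]

N_MODULATOR_POINTS = 120      # pseudo-atoms per simulated modulator
MODULATOR_CUTOFF = 7.0        # Å, point-to-protein constraint reach
MODULATOR_TOLERANCE = 0.1     # Å, half-width of modulator constraints
VOLUME_CUTOFF = 13.0          # Å^3, pockets must exceed this to be tried
MAX_POCKETS = 8               # at most this many pockets per protein
ALLOSTERIC_DISTANCE = 6.0     # Å, pocket-center-to-modulator validation


@dataclass
class Pocket:
    id: int
    center: np.ndarray
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    volume: float = 0.0


@dataclass
class PerturbationResult:
    pocket_id: int
    shift_rmsd: float
    rank: int = 0
    n_constraints: int = 0
    perturbed_ensemble: Ensemble | None = None


def filter_pockets(pockets: list[Pocket]) -> list[Pocket]:
    """Pockets strictly larger than the volume cutoff, largest first, capped."""
    selected = sorted((p for p in pockets if p.volume > VOLUME_CUTOFF),
                      key=lambda p: (-p.volume, p.id))
    if not selected:
        warnings.warn("no pockets pass the volume filter")
    return selected[:MAX_POCKETS]


def sample_pocket_points(p: Pocket, n: int = N_MODULATOR_POINTS,
                         seed: int = 0) -> np.ndarray:
    """Draw exactly ``n`` pocket points: without replacement when enough are
    available, otherwise resampled with replacement."""
    pts = np.asarray(p.points, dtype=float)
    if len(pts) == 0:
        raise ValueError(f"pocket {p.id} has no points")
    rng = np.random.default_rng(seed)
    replace = len(pts) < n
    idx = rng.choice(len(pts), size=n, replace=replace)
    return pts[idx]


def ball_points(center: np.ndarray, spacing: float = 1.2,
                n: int = N_MODULATOR_POINTS) -> np.ndarray:
    """The ``n`` cubic-lattice points (given spacing) closest to ``center``.

    Equivalent to intersecting the lattice with the smallest ball holding
    ``n`` points; ties at the boundary shell break deterministically by
    lattice coordinate.
    """
    center = np.asarray(center, dtype=float)
    k = 1
    while (2 * k + 1) ** 3 < 4 * n:
        k += 1
    axis = np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * spacing
    r2 = np.sum(lattice ** 2, axis=1)
    order = np.lexsort((lattice[:, 2], lattice[:, 1], lattice[:, 0], r2))
    return lattice[order[:n]] + center


def modulator_constraints(points: np.ndarray, s: Structure,
                          roster_offset: int | None = None,
                          internal: bool = True) -> list[Constraint]:
    """Constraints anchoring modulator pseudo-atoms to the protein.

    Each point is constrained at ±0.1 Å to every protein atom within 7 Å.
    With ``internal`` the point cloud is additionally made quasi-rigid by
    constraining all point-point distances, so the simulated modulator moves
    as a body rather than dissolving into the protein.
    """
    points = np.asarray(points, dtype=float)
    offset = roster_offset if roster_offset is not None else len(s)
    coords = s.coords
    tree = cKDTree(coords)
    out: list[Constraint] = []
    tol = MODULATOR_TOLERANCE
    for k, pt in enumerate(points):
        hits = tree.query_ball_point(pt, MODULATOR_CUTOFF)
        if not hits:
            warnings.warn(f"modulator point {k} has no protein atom "
                          f"within {MODULATOR_CUTOFF} Å")
        for a_idx in sorted(hits):
            d = float(np.linalg.norm(coords[a_idx] - pt))
            out.append(Constraint(a_idx, offset + k,
                                  max(d - tol, 0.5 * d), d + tol, 15))
    if internal:
        for a in range(len(points)):
            for b in range(a + 1, len(points)):
                d = float(np.linalg.norm(points[a] - points[b]))
                if d <= 0:
                    continue
                out.append(Constraint(offset + a, offset + b,
                                      max(d - tol, 0.5 * d), d + tol, 15))
    return out


def is_allosteric_pocket(p: Pocket, modulator_atoms: np.ndarray,
                         cutoff: float = ALLOSTERIC_DISTANCE) -> bool:
    """True when the pocket center lies within ``cutoff`` of any modulator
    atom (the validation criterion for a known modulator)."""
    atoms = np.asarray(modulator_atoms, dtype=float)
    if atoms.size == 0:
        raise ValueError("empty modulator atom list")
    return bool(np.min(np.linalg.norm(atoms - p.center, axis=1)) <= cutoff)


def perturbed_ensemble(pocket: Pocket, structure: Structure,
                       base_cs: ConstraintSet, n_models: int,
                       params: SPEParams, seed: int = 0,
                       internal: bool = True,
                       points: np.ndarray | None = None
                       ) -> tuple[Ensemble, int]:
    """Generate an ensemble with one pocket's modulator constraints added."""
    if points is None:
        points = sample_pocket_points(pocket, seed=seed)
    extra = modulator_constraints(points, structure, internal=internal)
    cs = base_cs.extended(extra, n_atoms=base_cs.n_atoms + len(points))
    ens = generate_ensemble(cs, n_models, structure, params,
                            n_protein=len(structure))
    return ens, len(extra)


def write_pockets_tsv(pockets: list[Pocket], path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tpocket_id\tvolume\n")
        for p in pockets:
            for pt in p.points:
                fh.write(f"{pt[0]:.3f}\t{pt[1]:.3f}\t{pt[2]:.3f}"
                         f"\t{p.id}\t{p.volume:.2f}\n")


def read_pockets_tsv(path) -> list[Pocket]:
    """Read pockets from a TSV of (x, y, z, pocket_id, volume) rows.

    The pocket center is the mean of its points.
    """
    groups: dict[int, list[list[float]]] = {}
    volumes: dict[int, float] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["x", "y", "z"]:
            raise ValueError("expected columns x, y, z, pocket_id, volume")
        for line in fh:
            if not line.strip():
                continue
            x, y, z, pid, vol = line.split("\t")
            groups.setdefault(int(pid), []).append([float(x), float(y), float(z)])
            volumes[int(pid)] = float(vol)
    return [Pocket(id=pid, points=np.array(pts),
                   center=np.mean(pts, axis=0), volume=volumes[pid])
            for pid, pts in sorted(groups.items())]


def read_pocket_points_pdb(path, pocket_id: int = 1,
                           volume: float = 0.0) -> Pocket:
    """Read a pocket-point cloud from a PDB-like file (one pocket per file).

    Only the coordinate columns of ATOM/HETATM records are used, so output
    from any grid pocket finder works.
    """
    pts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                pts.append([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
    if not pts:
        raise ValueError(f"no coordinate records in {path}")
    pts = np.array(pts)
    return Pocket(id=pocket_id, points=pts, center=pts.mean(axis=0),
                  volume=volume)


def perturb_and_rank(a: Structure, b: Structure, pockets: list[Pocket],
                     base_cs: ConstraintSet, n_models: int,
                     params: SPEParams, seed: int = 0,
                     internal: bool = True,
                     keep_ensembles: bool = False,
                     unperturbed: Ensemble | None = None
                     ) -> list[PerturbationResult]:
    """Perturb each pocket in turn and rank by ensemble-average shift.

    For every pocket, the pooled (unperturbed + perturbed) models are
    iteratively aligned into one frame; the Cα RMSD between the two
    ensemble averages is the pocket's shift.  Ranking is by descending
    shift, ties broken by pocket id.
    """
    if unperturbed is None:
        unperturbed = generate_ensemble(base_cs, n_models, a, params)
    ca = a.ca_indices()
    results: list[PerturbationResult] = []
    for p_idx, pocket in enumerate(pockets):
        ens, n_extra = perturbed_ensemble(
            pocket, a, base_cs, n_models, params,
            seed=seed * 1000 + p_idx, internal=internal)
        pooled = Ensemble(roster=a,
                          models=[*unperturbed.models, *ens.models])
        pooled = iterative_align(pooled)
        avg = average_structure(pooled)  # noqa: F841 (frame anchor)
        n_u = len(unperturbed)
        avg_u = np.mean(pooled.models[:n_u], axis=0)
        avg_p = np.mean(pooled.models[n_u:], axis=0)
        shift = rmsd(avg_u[ca], avg_p[ca])
        results.append(PerturbationResult(
            pocket_id=pocket.id, shift_rmsd=shift, n_constraints=n_extra,
            perturbed_ensemble=ens if keep_ensembles else None))
        logger.info("pocket %d: %d modulator constraints, shift %.3f Å",
                    pocket.id, n_extra, shift)
    order = sorted(range(len(results)),
                   key=lambda k: (-results[k].shift_rmsd, results[k].pocket_id))
    for rank, k in enumerate(order, start=1):
        results[k].rank = rank
    return results
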