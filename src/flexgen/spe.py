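"""Stochastic proximity embedding of a distance-constraint set.

Random starting coordinates are refined by repeatedly drawing a random
constraint and, when its current distance violates the interval, moving both
atoms along their difference vector toward the nearest violated bound.  The
learning rate decays linearly over cycles, annealing the system into a
self-consistent structure.  The hot loop is numba-compiled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .constraints import ConstraintSet
from .structure_io import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "SPEParams", "EmbeddingResult", "spe_embed", "error_score",
    "fix_chirality", "generate_ensemble", "planned_embeddings",
    "DISCARD_RATIO",
]

#: Over-generation factor: ceil(ratio * n) embeddings are run and the n with
#: the lowest error scores retained.
DISCARD_RATIO = 1.5

_EPS = 1e-9


@dataclass(frozen=True)
class SPEParams:
    """Embedding schedule.

    ``iterations_per_atom`` is the product of cycles C and steps-per-cycle S,
    with S = 50 C; each step performs one random constraint update per atom,
    so total updates scale with system size.
    """

    iterations_per_atom: int = 60_000
    steps_per_cycle_ratio: int = 50
    lambda_start: float = 2.0
    lambda_end: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.iterations_per_atom <= 0:
            raise ValueError("iterations_per_atom must be positive")
        if not self.lambda_start >= self.lambda_end > 0:
            raise ValueError("require lambda_start >= lambda_end > 0")
        # the update moves a pair by ~lambda * violation, so lambda > 2
        # overshoots by more than the violation itself and diverges
        if self.lambda_start > 2.0:
            raise ValueError("lambda_start > 2.0 is numerically unstable")

    @property
    def n_cycles(self) -> int:
        return math.ceil(math.sqrt(self.iterations_per_atom
                                   / self.steps_per_cycle_ratio))

    @property
    def steps_per_cycle(self) -> int:
        return self.steps_per_cycle_ratio * self.n_cycles


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    error_score: float
    mirrored: bool = False
    seed: int = 0


@njit(cache=True)
def _spe_core(x, lower, upper, ci, cj, n_cycles, steps_per_cycle,
              updates_per_step, lam0, lam1, seed):  # pragma: no cover
    np.random.seed(seed)
    n_con = ci.shape[0]
    for cycle in range(n_cycles):
        if n_cycles > 1:
            lam = lam0 + (lam1 - lam0) * (cycle / (n_cycles - 1))
        else:
            lam = lam1
        for _step in range(steps_per_cycle):
            for _u in range(updates_per_step):
                m = np.random.randint(n_con)
                i = ci[m]
                j = cj[m]
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d < lower[m]:
                    t = lower[m]
                elif d > upper[m]:
                    t = upper[m]
                else:
                    continue
                g = lam * 0.5 * (t - d) / (d + _EPS)
                x[i, 0] += g * dx
                x[i, 1] += g * dy
                x[i, 2] += g * dz
                x[j, 0] -= g * dx
                x[j, 1] -= g * dy
                x[j, 2] -= g * dz
    return x


def spe_embed(cs: ConstraintSet, params: SPEParams) -> EmbeddingResult:
    """Run one embedding; deterministic for a given ``params.seed``."""
    if len(cs) == 0:
        raise ValueError("cannot embed an empty constraint set")
    rng = np.random.default_rng(params.seed)
    side = cs.n_atoms ** (1.0 / 3.0) * 3.0
    x = (rng.random((cs.n_atoms, 3)) - 0.5) * side
    x = _spe_core(x, cs.lower, cs.upper, cs.i, cs.j,
                  params.n_cycles, params.steps_per_cycle, cs.n_atoms,
                  params.lambda_start, params.lambda_end,
                  int(params.seed) % (2 ** 32 - 1))
    return EmbeddingResult(coords=x, error_score=error_score(x, cs),
                           seed=params.seed)


def error_score(coords: np.ndarray, cs: ConstraintSet) -> float:
    """Sum of squared bound violations; zero iff every constraint holds."""
    d = np.linalg.norm(coords[cs.i] - coords[cs.j], axis=1)
    v = np.maximum(0.0, np.maximum(cs.lower - d, d - cs.upper))
    return float(np.sum(v * v))


def fix_chirality(coords: np.ndarray, reference: Structure | np.ndarray,
                  subset: np.ndarray | None = None
                  ) -> tuple[np.ndarray, bool]:
    """Mirror coordinates in the xy plane when the reflected superposition
    onto the reference fits better than the proper-rotation one.

    The optimal unconstrained orthogonal transform is found by SVD; a
    determinant of -1 means the embedding came out as the mirror image.
    """
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference)
    mob = np.asarray(coords, dtype=float)
    if subset is None:
        subset = np.arange(len(ref))
    a = mob[subset] - mob[subset].mean(axis=0)
    b = ref[subset] - ref[subset].mean(axis=0)
    h = a.T @ b
    u, _s, vt = np.linalg.svd(h)
    if np.linalg.det(u @ vt) < 0:
        out = mob.copy()
        out[:, 2] *= -1.0
        return out, True
    return mob.copy(), False


def planned_embeddings(n: int, ratio: float = DISCARD_RATIO) -> int:
    """Number of embeddings attempted for a final ensemble of ``n`` models."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.ceil(ratio * n)


def generate_ensemble(cs: ConstraintSet, n: int, reference: Structure,
                      params: SPEParams, n_protein: int | None = None
                      ) -> Ensemble:
    """Generate ``n`` structures: over-generate by the discard ratio, fix
    chirality against the reference, keep the lowest-error embeddings.

    When ``cs`` includes pseudo-atoms beyond the protein roster
    (``cs.n_atoms > len(reference)``), the pseudo-atom coordinates are
    dropped from the returned models; they participate in embedding and
    error scoring only.
    """
    n_prot = n_protein if n_protein is not None else len(reference)
    if cs.n_atoms < n_prot:
        raise ValueError("constraint set smaller than the protein roster")
    n_attempt = planned_embeddings(n)
    results: list[EmbeddingResult] = []
    subset = np.arange(n_prot)
    for idx in range(n_attempt):
        seed = params.seed * 10 ** 6 + idx
        res = spe_embed(cs, replace(params, seed=seed))
        fixed, mirrored = fix_chirality(res.coords[:, :], reference.coords,
                                        subset=subset)
        # re-embedding is not needed: mirroring preserves all distances
        results.append(EmbeddingResult(fixed, res.error_score, mirrored, seed))
    order = sorted(range(n_attempt), key=lambda k: results[k].error_score)
    kept = sorted(order[:n])  # deterministic: by seed index
    n_mirrored = sum(results[k].mirrored for k in kept)
    logger.info("generated %d/%d embeddings kept (max kept score %.4f, "
                "%d mirrored)", n, n_attempt,
                results[kept[-1]].error_score if kept else float("nan"),
                n_mirrored)
    return Ensemble(roster=reference,
                    models=[results[k].coords[:n_prot] for k in kept],
                    error_scores=[results[k].error_score for k in kept])
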