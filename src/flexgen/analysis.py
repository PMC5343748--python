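"""Ensemble alignment, averaging, PCA, fluctuation and RMSD analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Ensemble

__all__ = [
    "PCAResult", "kabsch_superpose", "iterative_align", "average_structure",
    "pca", "project", "rmsf", "rmsf_ratio", "pairwise_rmsd", "rmsd",
]


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD of already-superposed coordinate sets."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray,
                     subset: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Least-squares superposition with a proper rotation (det = +1).

    The fit is computed on ``subset`` (default: all atoms) and applied to the
    whole coordinate set; returns (transformed coords, subset RMSD).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if subset is None:
        subset = np.arange(len(ref))
    if len(subset) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    a = mobile[subset]
    b = ref[subset]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    # collinear subsets give a rank-<2 covariance: rotation underdetermined
    if np.linalg.matrix_rank(a - ca, tol=1e-8) < 2:
        raise ValueError("superposition subset is degenerate (collinear)")
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    out = (mobile - ca) @ r.T + cb
    return out, rmsd(out[subset], ref[subset])


def iterative_align(e: Ensemble, subset: np.ndarray | None = None,
                    tol: float = 1e-4, max_iter: int = 50) -> Ensemble:
    """Reference-free alignment: superpose onto model 0, then repeatedly
    realign everything onto the running centroid average until it is stable.
    """
    if len(e) < 2:
        raise ValueError("need at least 2 models to align")
    if subset is None:
        subset = e.roster.ca_indices()
        if len(subset) < 3:
            subset = np.arange(len(e.roster))
    models = [m.copy() for m in e.models]
    ref = models[0]
    models = [kabsch_superpose(m, ref, subset)[0] for m in models]
    avg = np.mean(models, axis=0)
    for _ in range(max_iter):
        models = [kabsch_superpose(m, avg, subset)[0] for m in models]
        new_avg = np.mean(models, axis=0)
        shift = rmsd(new_avg, avg)
        avg = new_avg
        if shift < tol:
            break
    return Ensemble(roster=e.roster, models=models,
                    error_scores=list(e.error_scores), aligned=True)


def average_structure(e: Ensemble) -> np.ndarray:
    """Centroid (per-atom mean) of an aligned ensemble."""
    if not e.aligned:
        raise ValueError("ensemble must be aligned before averaging")
    return np.mean(e.models, axis=0)


@dataclass
class PCAResult:
    mean: np.ndarray             # flattened (3*Nc,) Å
    eigenvalues: np.ndarray      # descending, Å^2
    eigenvectors: np.ndarray     # rows orthonormal, shape (3*Nc, 3*Nc)
    variance_fractions: np.ndarray
    atom_indices: np.ndarray     # roster indices the PCA was computed on


def pca(e: Ensemble, ca_only: bool = True) -> PCAResult:
    """Principal components of the coordinate covariance over the ensemble.

    The covariance is the ensemble average of coordinate deviations from the
    ensemble mean (population normalisation), computed on Cα atoms by
    default, then diagonalised.  Eigenvector signs are fixed so each
    vector's largest-magnitude entry is positive.
    """
    if not e.aligned:
        raise ValueError("ensemble must be aligned before PCA")
    if len(e) < 2:
        raise ValueError("need at least 2 models")
    idx = e.roster.ca_indices() if ca_only else np.arange(len(e.roster))
    x = np.array([m[idx].ravel() for m in e.models])  # (n_models, 3Nc)
    mean = x.mean(axis=0)
    dev = x - mean
    cov = dev.T @ dev / len(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are components
    for k in range(len(evecs)):
        if evecs[k, np.argmax(np.abs(evecs[k]))] < 0:
            evecs[k] = -evecs[k]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(mean=mean, eigenvalues=evals, eigenvectors=evecs,
                     variance_fractions=fractions, atom_indices=idx)


def project(coords: np.ndarray, p: PCAResult, component: int) -> float:
    """Projection of a structure (in the PCA frame) onto one component."""
    vec = np.asarray(coords)[p.atom_indices].ravel() - p.mean
    return float(vec @ p.eigenvectors[component])


def rmsf(e: Ensemble) -> np.ndarray:
    """Per-residue Cα mean square fluctuation (Å^2) of an aligned ensemble."""
    if not e.aligned:
        raise ValueError("ensemble must be aligned before RMSF")
    idx = e.roster.ca_indices()
    x = np.array([m[idx] for m in e.models])  # (n_models, Nc, 3)
    dev = x - x.mean(axis=0)
    return np.mean(np.sum(dev ** 2, axis=2), axis=0)


def rmsf_ratio(perturbed: Ensemble, reference: Ensemble,
               guard: float = 1e-12) -> np.ndarray:
    """Elementwise MSF(perturbed) / MSF(reference); NaN where the reference
    fluctuation is numerically zero."""
    if len(perturbed.roster) != len(reference.roster):
        raise ValueError("ensembles must share one residue roster")
    num = rmsf(perturbed)
    den = rmsf(reference)
    out = np.full_like(num, np.nan)
    ok = den >= guard
    out[ok] = num[ok] / den[ok]
    return out


def pairwise_rmsd(e: Ensemble) -> np.ndarray:
    """Cα RMSD matrix between aligned models (no re-superposition)."""
    idx = e.roster.ca_indices()
    n = len(e)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = rmsd(e.models[a][idx], e.models[b][idx])
    return out
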