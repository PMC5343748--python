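"""TM-score, ensemble spread fraction and automatic tolerance-weight choice.

The tolerance weight wb controls how far generated structures stray from the
two inputs.  It is selected by generating small trial ensembles at wb = 1.0,
0.9, ..., 0.0 and keeping the first value whose spread fraction — the share
of models strictly closer (by TM-score) to both inputs than the inputs are
to each other — reaches the target (0.9 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .analysis import kabsch_superpose
from .constraints import build_constraint_set
from .spe import SPEParams, generate_ensemble
from .structure_io import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = ["SpreadReport", "tm_score", "spread_fraction", "select_wb",
           "WB_SCHEDULE"]

#: wb search schedule, highest (widest spread) first.
WB_SCHEDULE: tuple[float, ...] = tuple(round(w, 1) for w in
                                       np.linspace(1.0, 0.0, 11))


@dataclass
class SpreadReport:
    wb: float
    f: float
    n_structures: int
    tm_ab: float

    def __post_init__(self):
        if not 0 <= self.f <= 1:
            raise ValueError("spread fraction must lie in [0, 1]")


def _d0(n_res: int) -> float:
    d0 = 1.24 * (n_res - 15) ** (1.0 / 3.0) - 1.8 if n_res > 15 else 0.5
    return max(d0, 0.5)


def tm_score(model: np.ndarray | Structure, ref: Structure,
             max_iter: int = 10, fragment_seeds: bool = True) -> float:
    """TM-score of ``model`` against ``ref`` on the shared Cα roster.

    Residue correspondence is identity (same protein), so no alignment
    search is needed.  The score is maximised over superpositions by
    iterative refinement from several seeds — the full chain plus
    contiguous fragments (halves, thirds, middle) — each refined by
    re-fitting on the residues currently within the distance threshold;
    the best score seen is returned.  Fragment seeds let the superposition
    lock onto a rigid core instead of compromising across a hinge.
    """
    ca = ref.ca_indices()
    if len(ca) < 3:
        raise ValueError("need at least 3 residues for a TM-score")
    mob = (model.coords if isinstance(model, Structure)
           else np.asarray(model, dtype=float))[ca]
    target = ref.coords[ca]
    n = len(ca)
    d0 = _d0(n)

    def _score(fitted: np.ndarray) -> float:
        d = np.linalg.norm(fitted - target, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    seeds = [np.arange(n)]
    if fragment_seeds:
        seeds += [np.arange(0, n // 2), np.arange(n // 2, n),
                  np.arange(n // 4, (3 * n) // 4),
                  np.arange(0, n // 3), np.arange(n // 3, (2 * n) // 3),
                  np.arange((2 * n) // 3, n)]
    best = 0.0
    for seed in seeds:
        if len(seed) < 3:
            continue
        try:
            fitted, _ = kabsch_superpose(mob, target, subset=seed)
        except ValueError:  # degenerate fragment
            continue
        best = max(best, _score(fitted))
        kept = seed
        for _ in range(max_iter):
            d = np.linalg.norm(fitted - target, axis=1)
            new_kept = np.where(d < max(d0, 3.0))[0]
            if len(new_kept) < 3 or np.array_equal(new_kept, kept):
                break
            kept = new_kept
            try:
                fitted, _ = kabsch_superpose(mob, target, subset=kept)
            except ValueError:  # kept set collapsed to a degenerate shape
                break
            best = max(best, _score(fitted))
    return best


def spread_fraction(e: Ensemble, a: Structure, b: Structure) -> SpreadReport:
    """Fraction of models strictly closer to both inputs than A and B are to
    each other: TM(S,A) > TM(B,A) and TM(S,B) > TM(A,B)."""
    if len(e) == 0:
        raise ValueError("empty ensemble")
    tm_ba = tm_score(b.coords, a)   # TM(B,A)
    tm_ab = tm_score(a.coords, b)   # TM(A,B)
    count = 0
    for m in e.models:
        if tm_score(m, a) > tm_ba and tm_score(m, b) > tm_ab:
            count += 1
    return SpreadReport(wb=getattr(e, "wb", float("nan")),
                        f=count / len(e), n_structures=len(e), tm_ab=tm_ab)


def select_wb(a: Structure, b: Structure, f_target: float = 0.9,
              n: int = 50, params: SPEParams | None = None,
              seed: int = 0) -> tuple[float, list[SpreadReport]]:
    """Walk the wb schedule and return the first wb whose trial ensemble
    reaches the target spread fraction, with the full search trace.

    Falls back to 0.0 (with a warning) if no wb qualifies.
    """
    params = params or SPEParams()
    trace: list[SpreadReport] = []
    for step, wb in enumerate(WB_SCHEDULE):
        cs = build_constraint_set(a, b, wb, seed=seed + step)
        ens = generate_ensemble(cs, n, a,
                                replace(params, seed=seed * 1000 + step))
        report = spread_fraction(ens, a, b)
        report.wb = wb
        trace.append(report)
        logger.info("wb search: wb=%.1f f=%.3f", wb, report.f)
        if report.f >= f_target:
            return wb, trace
    logger.warning("no wb in the schedule reached F >= %.2f; using 0.0",
                   f_target)
    return 0.0, trace
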