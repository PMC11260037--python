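"""Mate allocation under the five designs, pedigree kinship, and the
simulated-annealing optimizer for progeny inbreeding.

All designs produce a :class:`MatePlan` in which every dam appears exactly
once and sire usage is near-equal (dam counts per sire differ by at most
one), so the designs differ only in *which* dams a sire receives:

* ``random`` — dams shuffled and dealt to sires in blocks;
* ``assortative+`` / ``assortative-`` — sires and dams ranked by estimated
  breeding value; the top sire receives the top (``+``) or bottom (``-``)
  block of dams;
* ``min_inbreeding`` / ``max_inbreeding`` — the mean parental kinship over
  pairs (= mean expected progeny inbreeding F) is minimized/maximized by
  simulated annealing (Metropolis acceptance, geometric cooling).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_generator
from .errors import ConfigurationError, PedigreeError

DESIGNS = ("random", "assortative+", "assortative-", "min_inbreeding", "max_inbreeding")


@dataclass
class MatePlan:
    """Sire-dam pair allocation; one entry per dam."""

    design: str
    sires: np.ndarray        # sire id per pair
    dams: np.ndarray         # dam id per pair
    expected_F: np.ndarray | None = None  # parental kinship per pair
    objective: float | None = None        # mean expected progeny F (SA designs)
    trace: list = field(default_factory=list)  # (temperature, best objective) per sweep

    @property
    def pairs(self):
        return list(zip(self.sires.tolist(), self.dams.tolist()))

    def to_frame(self):
        """Pair table (sire, dam, expected_progeny_F) for CSV export."""
        import pandas as pd

        return pd.DataFrame({
            "sire": self.sires,
            "dam": self.dams,
            "expected_progeny_F": (self.expected_F if self.expected_F is not None
                                   else np.full(self.dams.size, np.nan)),
        })

    def validate(self, sire_pool, dam_pool) -> None:
        """Check dam coverage and sire balance invariants."""
        dam_pool = np.asarray(dam_pool)
        if sorted(self.dams.tolist()) != sorted(dam_pool.tolist()):
            raise ConfigurationError("plan does not cover every dam exactly once")
        counts = {s: 0 for s in np.asarray(sire_pool).tolist()}
        for s in self.sires.tolist():
            counts[s] += 1
        uses = list(counts.values())
        if max(uses) - min(uses) > 1:
            raise ConfigurationError("sire usage is not balanced")


def _balanced_slots(n_sires: int, n_dams: int) -> np.ndarray:
    """Slot index per dam: sizes differ by <= 1, larger blocks first."""
    base, rem = divmod(n_dams, n_sires)
    counts = np.full(n_sires, base)
    counts[:rem] += 1
    return np.repeat(np.arange(n_sires), counts)


def kinship_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Pedigree kinship by the tabular method.

    ``sire``/``dam`` give parent row indices (-1 = unknown) and must be
    sorted parents-before-offspring (a parent index >= its offspring's row is
    rejected, which also excludes cycles).  Returns K with K[i,i] =
    (1 + F_i)/2; the additive relationship matrix is 2K.
    """
    sire = np.asarray(sire, dtype=int)
    dam = np.asarray(dam, dtype=int)
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= i or d >= i:
            raise PedigreeError(f"animal {i} has a parent with row index >= {i}")
        if (s < 0) != (d < 0) and min(s, d) < -1:
            raise PedigreeError("parent indices must be >= -1")
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A / 2.0


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F_i = A_ii - 1 from the tabular relationship matrix."""
    K = kinship_matrix(sire, dam)
    return 2.0 * np.diag(K) - 1.0


def pair_random(sire_ids, dam_ids, rng=None) -> MatePlan:
    """Shuffle dams and deal them to (shuffled) sires in near-equal blocks."""
    rng = as_generator(rng)
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    if sire_ids.size < 1 or dam_ids.size < 1:
        raise ConfigurationError("need at least one sire and one dam")
    dams = rng.permutation(dam_ids)
    sires = rng.permutation(sire_ids)
    slots = _balanced_slots(sires.size, dams.size)
    return MatePlan("random", sires[slots], dams)


def pair_assortative(sire_ids, dam_ids, sire_ebv, dam_ebv, direction: str,
                     kinship=None) -> MatePlan:
    """Rank-match (positive) or rank-anti-match (negative) sires and dams
    on estimated breeding value.  Ties break by id (deterministic)."""
    if direction not in ("+", "-", "positive", "negative"):
        raise ConfigurationError(f"unknown assortative direction {direction!r}")
    positive = direction in ("+", "positive")
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    sire_ebv = np.asarray(sire_ebv, dtype=float)
    dam_ebv = np.asarray(dam_ebv, dtype=float)
    if sire_ebv.shape != sire_ids.shape or dam_ebv.shape != dam_ids.shape:
        raise ConfigurationError("every candidate needs an EBV")
    if np.any(~np.isfinite(sire_ebv)) or np.any(~np.isfinite(dam_ebv)):
        raise ConfigurationError("EBVs must be finite")
    s_order = np.lexsort((sire_ids, -sire_ebv))  # descending EBV, id tiebreak
    d_order = np.lexsort((dam_ids, -dam_ebv))
    if not positive:
        d_order = d_order[::-1]  # top sire gets the bottom block, ascending
    sires = sire_ids[s_order]
    dams = dam_ids[d_order]
    slots = _balanced_slots(sires.size, dams.size)
    design = "assortative+" if positive else "assortative-"
    return MatePlan(design, sires[slots], dams)


def pair_inbreeding_opt(sire_ids, dam_ids, kinship_sd: np.ndarray, objective: str,
                        rng=None, t0: float = 0.5, cooling: float = 0.9,
                        t_min: float = 1e-4, patience: int = 50,
                        moves_per_sweep: int | None = None) -> MatePlan:
    """Optimize mean expected progeny inbreeding by simulated annealing.

    ``kinship_sd[i, j]`` is the kinship between ``sire_ids[i]`` and
    ``dam_ids[j]`` (= the inbreeding F of their progeny).  The proposal move
    swaps the sires of two randomly chosen dams (feasibility-preserving:
    balance is never disturbed); a worsening move of size ``delta`` (on the
    summed objective) is accepted with probability exp(-delta/T).  The
    temperature starts at ``t0`` and is lowered by ``cooling`` after every
    sweep of ``moves_per_sweep`` proposals (default: one per dam).  Stops
    when T < ``t_min`` or after ``patience`` sweeps without improving the
    best-so-far allocation, which is what is returned.  ``objective='max'``
    minimizes the negated kinship.
    """
    if objective not in ("min", "max"):
        raise ConfigurationError("objective must be 'min' or 'max'")
    rng = as_generator(rng)
    sire_ids = np.asarray(sire_ids)
    dam_ids = np.asarray(dam_ids)
    kinship_sd = np.asarray(kinship_sd, dtype=float)
    n_s, n_d = sire_ids.size, dam_ids.size
    if n_s == 0 or n_d == 0:
        raise ConfigurationError("empty candidate set")
    if kinship_sd.shape != (n_s, n_d):
        raise ConfigurationError("kinship matrix shape must be (n_sires, n_dams)")
    sign = 1.0 if objective == "min" else -1.0
    cost = sign * kinship_sd
    slots = rng.permutation(_balanced_slots(n_s, n_d))
    cols = np.arange(n_d)
    cur = float(cost[slots, cols].sum())
    best = cur
    best_slots = slots.copy()
    n_moves = moves_per_sweep if moves_per_sweep is not None else n_d
    T = t0
    stale = 0
    trace = []
    while T >= t_min and stale <= patience:
        ii = rng.integers(0, n_d, size=n_moves)
        jj = rng.integers(0, n_d, size=n_moves)
        us = rng.random(size=n_moves)
        improved = False
        for i, j, u in zip(ii, jj, us):
            si, sj = slots[i], slots[j]
            if si == sj:
                continue
            delta = cost[sj, i] + cost[si, j] - cost[si, i] - cost[sj, j]
            if delta <= 0.0 or u < math.exp(-delta / T):
                slots[i], slots[j] = sj, si
                cur += delta
                if cur < best - 1e-12:
                    best = cur
                    best_slots[:] = slots
                    improved = True
        trace.append((T, sign * best / n_d))
        stale = 0 if improved else stale + 1
        T *= cooling
    expected_F = kinship_sd[best_slots, cols]
    design = "min_inbreeding" if objective == "min" else "max_inbreeding"
    return MatePlan(design, sire_ids[best_slots], dam_ids,
                    expected_F=expected_F, objective=float(expected_F.mean()),
                    trace=trace)


def make_plan(design: str, sire_ids, dam_ids, rng=None, sire_ebv=None,
              dam_ebv=None, kinship_sd=None, **anneal_kwargs) -> MatePlan:
    """Dispatch to the design-specific pairing routine."""
    if design == "random":
        return pair_random(sire_ids, dam_ids, rng)
    if design in ("assortative+", "assortative-"):
        return pair_assortative(sire_ids, dam_ids, sire_ebv, dam_ebv, design[-1])
    if design in ("min_inbreeding", "max_inbreeding"):
        return pair_inbreeding_opt(sire_ids, dam_ids, kinship_sd,
                                   design.split("_")[0], rng, **anneal_kwargs)
    raise ConfigurationError(f"unknown mating design {design!r}")
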