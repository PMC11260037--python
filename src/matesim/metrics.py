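"""Prediction accuracy, bias slope, LD r-squared, and replicate summaries.

* **accuracy** — Pearson correlation between true and genomic estimated
  breeding values (A_T in the reference set, A_V in the validation set).
* **bias slope** — OLS slope of TBV on GEBV; an unbiased predictor has
  expected slope 1.
* **LD** — r2 = D^2 / (f(A) f(a) f(B) f(b)) with D = f(AB) - f(A) f(B),
  counted over phased haplotypes, binned by map distance in the layout used
  for LD-decay tables: (0-0.05], (0.05-0.1], (0.1-0.2] ... (0.9-1], (1-2],
  (2-3], (3-4], (4-5] cM.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, UndefinedStatisticError
from .genome_trait import GenomeMap
from .popsim_historical import HaplotypePopulation

LD_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
                2.0, 3.0, 4.0, 5.0)


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.size < 3:
        raise ConfigurationError("need two equal-length vectors with >= 3 entries")
    if np.var(tbv) == 0.0 or np.var(gebv) == 0.0:
        raise UndefinedStatisticError("accuracy undefined: zero variance input")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def bias_slope(tbv: np.ndarray, gebv: np.ndarray) -> tuple[float, float]:
    """OLS slope of TBV regressed on GEBV, with its standard error."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.size < 3:
        raise ConfigurationError("need two equal-length vectors with >= 3 entries")
    if np.var(gebv) == 0.0:
        raise UndefinedStatisticError("bias slope undefined: GEBV has zero variance")
    res = scipy.stats.linregress(gebv, tbv)
    return float(res.slope), float(res.stderr)


def ld_r2_pair(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r2 between two loci from phased haplotype allele columns (0/1)."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("haplotype columns must be 1-D and equal length")
    fA, fB = a.mean(), b.mean()
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        raise UndefinedStatisticError("r2 undefined at a fixed locus")
    fAB = (a * b).mean()
    D = fAB - fA * fB
    return float(D * D / (fA * (1 - fA) * fB * (1 - fB)))


def _pairwise_r2(H: np.ndarray, positions: np.ndarray, max_dist: float):
    """All (distance, r2) pairs among segregating columns within max_dist.

    H is a (n_haplotypes, n_loci) 0/1 matrix.  Works offset-by-offset so the
    cost stays linear in the number of eligible pairs.
    """
    H = np.asarray(H, dtype=float)
    p = H.mean(axis=0)
    keep = (p > 0.0) & (p < 1.0)
    H = H[:, keep]
    pos = np.asarray(positions, dtype=float)[keep]
    p = p[keep]
    q = 1.0 - p
    m = pos.size
    dists, r2s = [], []
    for off in range(1, m):
        d = pos[off:] - pos[:-off]
        sel = d <= max_dist
        if not sel.any():
            break
        fAB = (H[:, :-off] * H[:, off:]).mean(axis=0)
        D = fAB - p[:-off] * p[off:]
        r2 = D * D / (p[:-off] * q[:-off] * p[off:] * q[off:])
        dists.append(d[sel])
        r2s.append(r2[sel])
    if not dists:
        return np.empty(0), np.empty(0)
    return np.concatenate(dists), np.concatenate(r2s)


def ld_table(pop, gmap: GenomeMap, bins=LD_BIN_EDGES, max_dist=None) -> pd.DataFrame:
    """Mean r2 and pair count per distance bin over a cohort's markers.

    ``pop`` may be a HaplotypePopulation or a raw (n, 2, L) haplotype array
    aligned with ``gmap``.  Monomorphic markers are excluded.  Bins are
    half-open (lo, hi]; empty bins report count 0 and NaN mean.
    """
    haps = pop.haplotypes if isinstance(pop, HaplotypePopulation) else np.asarray(pop)
    mk = gmap.marker_indices
    H = haps[:, :, mk].reshape(-1, mk.size)
    edges = np.asarray(bins, dtype=float)
    if max_dist is None:
        max_dist = float(edges[-1])
    d, r2 = _pairwise_r2(H, gmap.positions[mk], max_dist)
    which = np.searchsorted(edges, d, side="left") - 1  # (lo, hi] binning
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        n_pairs = int(sel.sum())
        rows.append({
            "bin_lo": edges[b],
            "bin_hi": edges[b + 1],
            "n_pairs": n_pairs,
            "mean_r2": float(r2[sel].mean()) if n_pairs else np.nan,
        })
    return pd.DataFrame(rows)


def mean_r2(pop, gmap: GenomeMap, max_dist: float = LD_BIN_EDGES[-1]) -> float:
    """Pair-weighted mean r2 over segregating marker pairs within max_dist."""
    haps = pop.haplotypes if isinstance(pop, HaplotypePopulation) else np.asarray(pop)
    mk = gmap.marker_indices
    H = haps[:, :, mk].reshape(-1, mk.size)
    _, r2 = _pairwise_r2(H, gmap.positions[mk], max_dist)
    if r2.size == 0:
        raise UndefinedStatisticError("no segregating marker pairs within range")
    return float(r2.mean())


def summarize_replicates(values) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(R)) over replicate statistics."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 1:
        raise ConfigurationError("need at least one replicate")
    if v.size == 1:
        warnings.warn("single replicate: standard error reported as 0", stacklevel=2)
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
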