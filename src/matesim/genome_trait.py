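"""Genome map, QTL effects, and the additive trait model.

The simulated genome is a single chromosome of ``length_cM`` centimorgans
carrying two kinds of bi-allelic loci:

* **markers** — observed by the predictor, placed on a regular grid
  ``i * length/m`` for ``i = 1..m``;
* **QTL** — unobserved causal loci at uniform random positions, whose
  allele-substitution effects sum to an individual's true breeding value
  (TBV).

QTL effect magnitudes follow a gamma distribution (shape 0.4 by default);
signs are assigned + or - with equal probability.  After genotypes exist for
a founder cohort, the effect vector is rescaled by a single constant so that
Var(TBV) = h2 * sigma_p2 in that cohort; phenotypes are then
``y = TBV + e`` with ``e ~ N(0, (1 - h2) * sigma_p2)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from ._rng import as_generator
from .errors import ConfigurationError, DegenerateTraitError

DEFAULT_GAMMA_SHAPE = 0.4


@dataclass(frozen=True)
class GenomeMap:
    """Positions (cM) and roles of all loci on one chromosome.

    ``positions`` is strictly increasing; ``is_qtl`` flags QTL loci, all
    other loci are markers.
    """

    length_cM: float
    positions: np.ndarray
    is_qtl: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        qtl = np.asarray(self.is_qtl, dtype=bool)
        if pos.ndim != 1 or pos.shape != qtl.shape:
            raise ConfigurationError("positions and is_qtl must be 1-D and aligned")
        if np.any(np.diff(pos) <= 0):
            raise ConfigurationError("locus positions must be strictly increasing")
        if pos.size and (pos[0] <= 0 or pos[-1] > self.length_cM):
            raise ConfigurationError("locus positions must lie in (0, length_cM]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "is_qtl", qtl)

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @cached_property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @cached_property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def n_markers(self) -> int:
        return self.marker_indices.size

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size

    @property
    def marker_pos(self) -> np.ndarray:
        return self.positions[self.marker_indices]

    @property
    def qtl_pos(self) -> np.ndarray:
        return self.positions[self.qtl_indices]

    def thin(self, n_markers: int, n_qtl: int, rng=None) -> tuple["GenomeMap", np.ndarray]:
        """Down-sample to ``n_markers`` grid-nearest markers and a random
        subset of ``n_qtl`` QTL.

        Returns the thinned map and the column indices into this map's locus
        axis, so haplotype matrices simulated on the dense map can be sliced
        to match.  Marginalising a neutral forward simulation over a locus
        subset is exact, which is what makes sharing one dense historical
        simulation across marker-density scenarios legitimate.
        """
        if n_markers > self.n_markers or n_qtl > self.n_qtl:
            raise ConfigurationError("cannot thin to more loci than available")
        rng = as_generator(rng)
        grid = np.arange(1, n_markers + 1) * (self.length_cM / n_markers)
        src = self.marker_pos
        nearest = np.searchsorted(src, grid)
        nearest = np.clip(nearest, 1, src.size - 1)
        left_closer = np.abs(grid - src[nearest - 1]) <= np.abs(grid - src[nearest])
        pick = np.where(left_closer, nearest - 1, nearest)
        pick = np.unique(pick)
        if pick.size != n_markers:
            raise ConfigurationError(
                "grid-nearest marker selection produced duplicates; "
                "source map too sparse for requested density"
            )
        marker_cols = self.marker_indices[pick]
        qtl_cols = rng.choice(self.qtl_indices, size=n_qtl, replace=False)
        cols = np.sort(np.concatenate([marker_cols, qtl_cols]))
        sub = GenomeMap(self.length_cM, self.positions[cols], self.is_qtl[cols])
        return sub, cols

    def to_frame(self) -> pd.DataFrame:
        """Locus table in an extended PLINK .map layout (+ role column)."""
        return pd.DataFrame(
            {
                "chrom": 1,
                "id": [f"{'qtl' if q else 'snp'}{i}" for i, q in enumerate(self.is_qtl)],
                "position_cM": self.positions,
                "role": np.where(self.is_qtl, "qtl", "marker"),
            }
        )

    def write_map(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_genome_map(n_markers: int, n_qtl: int, length_cM: float = 100.0, rng=None) -> GenomeMap:
    """Equally spaced markers plus uniformly placed QTL on one chromosome.

    Markers sit at ``i * length/m`` for ``i = 1..m``; QTL positions are drawn
    uniformly on (0, length], resampled on (measure-zero) collisions with a
    marker or another QTL so all positions are distinct.
    """
    if n_markers < 2 or n_qtl < 1:
        raise ConfigurationError("need n_markers >= 2 and n_qtl >= 1")
    if length_cM <= 0:
        raise ConfigurationError("length_cM must be positive")
    rng = as_generator(rng)
    marker_pos = np.arange(1, n_markers + 1) * (length_cM / n_markers)
    marker_pos[-1] = length_cM  # avoid accumulated float error at the end
    taken = set(marker_pos.tolist())
    qtl_pos = []
    while len(qtl_pos) < n_qtl:
        x = float(rng.uniform(0.0, length_cM))
        if x <= 0.0 or x in taken:
            continue
        taken.add(x)
        qtl_pos.append(x)
    positions = np.concatenate([marker_pos, qtl_pos])
    is_qtl = np.zeros(positions.size, dtype=bool)
    is_qtl[n_markers:] = True
    order = np.argsort(positions)
    return GenomeMap(length_cM, positions[order], is_qtl[order])


def sample_qtl_effects(n_qtl: int, shape: float = DEFAULT_GAMMA_SHAPE, rng=None) -> np.ndarray:
    """Signed allele-substitution effects: gamma(shape, scale=1) magnitudes,
    random +/- signs.

    The gamma scale is irrelevant because effects are later rescaled to hit
    the target genetic variance.
    """
    if n_qtl < 1:
        raise ConfigurationError("n_qtl must be >= 1")
    if shape <= 0:
        raise ConfigurationError("gamma shape must be positive")
    rng = as_generator(rng)
    magnitudes = rng.gamma(shape, 1.0, size=n_qtl)
    signs = rng.choice([-1.0, 1.0], size=n_qtl)
    return magnitudes * signs


@dataclass(frozen=True)
class TraitModel:
    """Scaled QTL effects plus the variance decomposition of the trait."""

    effects: np.ndarray  # per-QTL allele substitution effects, trait units
    h2: float
    sigma_p2: float = 1.0
    scale_factor: float = 1.0  # constant applied to the raw effects

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h2) * self.sigma_p2

    def breeding_values(self, qtl_dosages: np.ndarray) -> np.ndarray:
        """TBV = sum over QTL of dosage * effect."""
        return np.asarray(qtl_dosages, dtype=float) @ self.effects

    def phenotypes(self, tbv: np.ndarray, rng=None) -> np.ndarray:
        """y_i = TBV_i + e_i with e_i ~ N(0, sigma_e2), independent."""
        rng = as_generator(rng)
        tbv = np.asarray(tbv, dtype=float)
        if self.sigma_e2 == 0.0:
            return tbv.copy()
        return tbv + rng.normal(0.0, np.sqrt(self.sigma_e2), size=tbv.shape)


def scale_trait(founder_qtl_dosages: np.ndarray, raw_effects: np.ndarray,
                h2: float, sigma_p2: float = 1.0) -> TraitModel:
    """Rescale raw effects so Var(TBV) = h2 * sigma_p2 in the founder cohort.

    Variance is the population (ddof=0) variance over founders.  Raises
    :class:`DegenerateTraitError` when the raw TBV variance is zero (all QTL
    fixed), in which case the caller should resample QTL.
    """
    if not 0.0 < h2 <= 1.0:
        raise ConfigurationError("h2 must be in (0, 1]")
    if sigma_p2 <= 0:
        raise ConfigurationError("sigma_p2 must be positive")
    raw_effects = np.asarray(raw_effects, dtype=float)
    raw_tbv = np.asarray(founder_qtl_dosages, dtype=float) @ raw_effects
    v = float(np.var(raw_tbv))
    if v <= 0.0:
        raise DegenerateTraitError("raw TBV variance is zero in the founder cohort")
    c = float(np.sqrt(h2 * sigma_p2 / v))
    return TraitModel(effects=c * raw_effects, h2=float(h2),
                      sigma_p2=float(sigma_p2), scale_factor=c)
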