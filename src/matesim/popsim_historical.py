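"""Historical population: drift + mutation under a census-size schedule.

The historical phase emulates a population evolving to mutation-drift
equilibrium and then through a bottleneck that builds up linkage
disequilibrium: a constant founder cohort grows to a peak census and then
declines, with offspring each generation produced by uniting gametes from a
randomly drawn sire and dam (with replacement).

Meiosis uses the Haldane model: crossover count ~ Poisson(length in Morgans),
crossover positions uniform, no interference.  Mutation flips alleles (0<->1)
independently per locus per gamete.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._rng import as_generator
from .errors import ConfigurationError, SimulationError
from .genome_trait import GenomeMap

DEFAULT_MUTATION_RATE = 2.5e-5  # per locus per generation


@dataclass
class HaplotypePopulation:
    """Phased bi-allelic genotypes of one cohort.

    ``haplotypes`` has shape (n_individuals, 2, n_loci) with values in {0,1};
    locus ordering matches the :class:`GenomeMap` the cohort was simulated on.
    """

    haplotypes: np.ndarray
    is_male: np.ndarray
    generation: int = 0

    def __post_init__(self):
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.is_male = np.asarray(self.is_male, dtype=bool)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ConfigurationError("haplotypes must have shape (n, 2, L)")
        if self.is_male.shape[0] != self.haplotypes.shape[0]:
            raise ConfigurationError("is_male length must match n individuals")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def dosages(self, loci=None) -> np.ndarray:
        """0/1/2 genotype dosage matrix, optionally restricted to ``loci``."""
        d = self.haplotypes.sum(axis=1)
        return d if loci is None else d[:, loci]

    def subset_loci(self, cols) -> "HaplotypePopulation":
        return replace(self, haplotypes=self.haplotypes[:, :, cols])

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.is_male)

    def females(self) -> np.ndarray:
        return np.flatnonzero(~self.is_male)


@dataclass(frozen=True)
class SizeSchedule:
    """Census-size anchors with linear interpolation between them.

    Interpolated sizes are rounded to the nearest even integer (>= 2) so an
    even sex split is always possible.
    """

    anchors: tuple

    def __post_init__(self):
        gens = [g for g, _ in self.anchors]
        sizes = [s for _, s in self.anchors]
        if len(self.anchors) < 1 or gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ConfigurationError("anchor generations must be strictly increasing")
        if min(sizes) < 2:
            raise ConfigurationError("census sizes must be >= 2")

    @property
    def n_generations(self) -> int:
        return self.anchors[-1][0]

    def sizes(self) -> np.ndarray:
        """Census size for every generation 0..n_generations inclusive."""
        gens = np.array([g for g, _ in self.anchors], dtype=float)
        vals = np.array([s for _, s in self.anchors], dtype=float)
        t = np.arange(self.anchors[-1][0] + 1, dtype=float)
        interp = np.interp(t, gens, vals)
        even = 2 * np.rint(interp / 2.0)
        return np.maximum(2, even).astype(int)

    @classmethod
    def default(cls, scale: float = 1.0) -> "SizeSchedule":
        """1000 founders -> 10,000 at generation 1000 -> 4,000 at 2020,
        with generations and sizes shrunk proportionally for scale < 1."""
        def even(x):
            return max(2, int(2 * round(x / 2.0)))

        g1, g2 = max(1, round(1000 * scale)), max(2, round(2020 * scale))
        return cls(((0, even(1000 * scale)), (g1, even(10000 * scale)), (g2, even(4000 * scale))))


def make_gametes(parent_haps: np.ndarray, positions: np.ndarray, length_cM: float,
                 rng, mutation_rate: float = 0.0, chunk: int = 4096) -> np.ndarray:
    """One recombinant (and possibly mutated) gamete per parent row.

    ``parent_haps`` has shape (k, 2, L).  Crossover counts are
    Poisson(length_cM/100), positions uniform on (0, length_cM); the gamete
    copies alternating parental strands between crossovers starting from a
    random strand.  Each output allele then flips with prob ``mutation_rate``.
    """
    parent_haps = np.asarray(parent_haps)
    k, _, n_loci = parent_haps.shape
    positions = np.asarray(positions, dtype=float)
    out = np.empty((k, n_loci), dtype=np.uint8)
    morgans = length_cM / 100.0
    for lo in range(0, k, chunk):
        hi = min(lo + chunk, k)
        kk = hi - lo
        n_cx = rng.poisson(morgans, size=kk)
        start = rng.integers(0, 2, size=kk)
        kmax = int(n_cx.max()) if kk else 0
        if kmax == 0:
            strand = np.repeat(start[:, None], n_loci, axis=1)
        else:
            cx = rng.uniform(0.0, length_cM, size=(kk, kmax))
            cx[np.arange(kmax)[None, :] >= n_cx[:, None]] = np.inf
            crossed = (cx[:, :, None] < positions[None, None, :]).sum(axis=1)
            strand = (start[:, None] + crossed) & 1
        rows = np.arange(lo, hi)[:, None]
        out[lo:hi] = parent_haps[rows, strand, np.arange(n_loci)[None, :]]
    if mutation_rate > 0.0:
        total = out.size
        n_mut = rng.binomial(total, mutation_rate)
        if n_mut:
            # flip by XOR at random flat indices; the vanishing chance of a
            # duplicate index just cancels two flips
            idx = rng.integers(0, total, size=n_mut)
            flat = out.reshape(-1)
            np.bitwise_xor.at(flat, idx, 1)
    return out


def produce_offspring(parent_haps: np.ndarray, sire_idx: np.ndarray, dam_idx: np.ndarray,
                      positions: np.ndarray, length_cM: float, rng,
                      mutation_rate: float = 0.0) -> np.ndarray:
    """Unite one paternal and one maternal gamete per (sire, dam) pair."""
    paternal = make_gametes(parent_haps[sire_idx], positions, length_cM, rng, mutation_rate)
    maternal = make_gametes(parent_haps[dam_idx], positions, length_cM, rng, mutation_rate)
    return np.stack([paternal, maternal], axis=1)


def _assign_sexes(n: int, rng, n_males: int | None = None) -> np.ndarray:
    if n_males is None:
        n_males = n // 2
    if not 0 <= n_males <= n:
        raise ConfigurationError("invalid male count for cohort size")
    is_male = np.zeros(n, dtype=bool)
    is_male[:n_males] = True
    return rng.permutation(is_male)


def iterate_historical(gmap: GenomeMap, schedule: SizeSchedule,
                       mutation_rate: float = DEFAULT_MUTATION_RATE, rng=None,
                       final_sex_split: tuple[int, int] | None = None):
    """Yield every generation of the historical simulation in order.

    Founders start at allele frequency 0.5 per locus (maximal diversity; the
    long drift/mutation phase then shapes the equilibrium).  Each generation,
    every offspring gets a random sire and random dam drawn with replacement.
    ``final_sex_split`` fixes (n_males, n_females) of the last generation so a
    subsequent expansion phase can draw its sires and dams from it.
    """
    rng = as_generator(rng)
    sizes = schedule.sizes()
    if final_sex_split is not None:
        nm, nf = final_sex_split
        if nm + nf != sizes[-1]:
            raise ConfigurationError(
                f"final_sex_split {final_sex_split} must sum to the final census {sizes[-1]}"
            )
    founders = rng.integers(0, 2, size=(sizes[0], 2, gmap.n_loci), dtype=np.uint8)
    pop = HaplotypePopulation(founders, _assign_sexes(sizes[0], rng), generation=0)
    yield pop
    last = len(sizes) - 1
    for gen in range(1, len(sizes)):
        n_next = int(sizes[gen])
        males, females = pop.males(), pop.females()
        if males.size == 0 or females.size == 0:
            raise SimulationError(f"generation {gen - 1} lacks one sex")
        sires = rng.choice(males, size=n_next, replace=True)
        dams = rng.choice(females, size=n_next, replace=True)
        haps = produce_offspring(pop.haplotypes, sires, dams, gmap.positions,
                                 gmap.length_cM, rng, mutation_rate)
        nm = final_sex_split[0] if (final_sex_split and gen == last) else None
        pop = HaplotypePopulation(haps, _assign_sexes(n_next, rng, nm), generation=gen)
        yield pop


def simulate_historical(gmap: GenomeMap, schedule: SizeSchedule,
                        mutation_rate: float = DEFAULT_MUTATION_RATE, rng=None,
                        final_sex_split: tuple[int, int] | None = None) -> HaplotypePopulation:
    """Run the full schedule and return the final generation."""
    pop = None
    for pop in iterate_historical(gmap, schedule, mutation_rate, rng, final_sex_split):
        pass
    return pop


def write_plink(pop: HaplotypePopulation, gmap: GenomeMap, prefix) -> None:
    """Dump phased genotypes as a PLINK-style .ped/.map text pair.

    Alleles are coded 1/2; sample ids carry the generation index.  Intended
    for interoperability spot-checks, not for large cohorts.
    """
    from pathlib import Path

    prefix = Path(prefix)
    frame = gmap.to_frame()
    frame[["chrom", "id", "position_cM"]].assign(bp=0).to_csv(
        prefix.with_suffix(".map"), sep="\t", header=False, index=False)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(pop.n):
            sex = "1" if pop.is_male[i] else "2"
            sid = f"g{pop.generation}_i{i}"
            alleles = (pop.haplotypes[i] + 1).T.reshape(-1)
            fh.write(" ".join(["FAM0", sid, "0", "0", sex, "0",
                               *map(str, alleles)]) + "\n")


def segregating_loci(pop: HaplotypePopulation) -> np.ndarray:
    """Indices of loci with minor allele frequency > 0 in ``pop``."""
    p = pop.allele_frequencies()
    return np.flatnonzero((p > 0.0) & (p < 1.0))
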