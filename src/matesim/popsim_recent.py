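"""Expansion phase and the 10-generation recent population under a mating
design, with pedigree, inbreeding, TBV/phenotype bookkeeping and the
reference/validation split.

Phase layout (full-scale preset sizes in brackets):

* **expansion** — sires [500] and dams [3500] drawn at random from the last
  historical generation; each dam has ``litter`` [5] offspring per
  generation for [10] generations, the dam quota growing exponentially
  (factor litter/2) up to a configurable cap;
* **recent** — sires [50] and dams [3500] drawn from the expanded
  population found a new pedigree (F=0 base); ten further generations are
  bred under one of the five mating designs, replacements chosen at random
  among offspring.  Generations 3-9 are the phenotyped+genotyped reference
  set, generation 10 the genotyped-only validation set.

Pedigree inbreeding is tracked exactly by the kinship recursion: the kinship
of two offspring is the mean of their parents' four pairwise kinships, a
self-kinship is (1 + F)/2, and an offspring's F equals its parents' kinship.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator
from .errors import ConfigurationError, SimulationError
from .genome_trait import GenomeMap, TraitModel, scale_trait
from .mating import make_plan
from .popsim_historical import (DEFAULT_MUTATION_RATE, HaplotypePopulation,
                                produce_offspring)
from .prediction import estimate_ebv

RECENT_GENERATIONS = 10
REFERENCE_GENERATIONS = tuple(range(3, 10))
VALIDATION_GENERATION = 10


@dataclass
class Cohort:
    """One generation of the recent population."""

    generation: int
    ids: np.ndarray
    sire_id: np.ndarray   # global animal id, -1 for base animals
    dam_id: np.ndarray
    is_male: np.ndarray
    F: np.ndarray
    haplotypes: np.ndarray
    tbv: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return self.ids.size


@dataclass
class StudyPopulation:
    """All recent-phase cohorts plus trait model and set masks."""

    gmap: GenomeMap
    trait: TraitModel
    design: str
    cohorts: list
    reference_generations: tuple = REFERENCE_GENERATIONS
    validation_generation: int = VALIDATION_GENERATION

    def cohort(self, generation: int) -> Cohort:
        for c in self.cohorts:
            if c.generation == generation:
                return c
        raise KeyError(f"no cohort for generation {generation}")

    def _stacked(self, gens, attr):
        return np.concatenate([getattr(self.cohort(g), attr) for g in gens])

    def haplotypes(self, gens) -> np.ndarray:
        return np.concatenate([self.cohort(g).haplotypes for g in gens], axis=0)

    def marker_dosages(self, gens) -> np.ndarray:
        return self.haplotypes(gens).sum(axis=1)[:, self.gmap.marker_indices]

    def tbv(self, gens) -> np.ndarray:
        return self._stacked(gens, "tbv")

    def phenotypes(self, gens) -> np.ndarray:
        return self._stacked(gens, "y")

    def mean_inbreeding(self, generation: int) -> float:
        return float(self.cohort(generation).F.mean())

    def pedigree_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cohorts:
            rows.append(pd.DataFrame({
                "id": c.ids, "sire": c.sire_id, "dam": c.dam_id,
                "sex": np.where(c.is_male, "M", "F"),
                "generation": c.generation, "F": c.F,
            }))
        return pd.concat(rows, ignore_index=True)

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cohorts:
            rows.append(pd.DataFrame({"id": c.ids, "generation": c.generation,
                                      "y": c.y, "TBV": c.tbv}))
        return pd.concat(rows, ignore_index=True)


def _draw_founders(pop: HaplotypePopulation, n_sires: int, n_dams: int, rng):
    males, females = pop.males(), pop.females()
    if males.size < n_sires or females.size < n_dams:
        raise SimulationError(
            f"need {n_sires} males and {n_dams} females, have "
            f"{males.size} and {females.size}"
        )
    sires = rng.choice(males, size=n_sires, replace=False)
    dams = rng.choice(females, size=n_dams, replace=False)
    return sires, dams


def expand_population(hist: HaplotypePopulation, gmap: GenomeMap, n_sires: int,
                      n_dams: int, n_generations: int = 10, litter: int = 5,
                      rng=None, mutation_rate: float = DEFAULT_MUTATION_RATE,
                      dam_growth_cap: float = 2.0) -> HaplotypePopulation:
    """Random-mating growth phase between the historical bottleneck and the
    recent pedigree.

    Each generation every dam is mated to a randomly assigned sire and
    produces ``litter`` offspring (sex ~ Bernoulli(1/2)).  The dam quota
    grows by factor litter/2 per generation up to ``dam_growth_cap`` times
    the initial count; the sire quota keeps the initial sire:dam ratio.
    """
    rng = as_generator(rng)
    if n_generations < 0 or litter < 1:
        raise ConfigurationError("need n_generations >= 0 and litter >= 1")
    sire_idx, dam_idx = _draw_founders(hist, n_sires, n_dams, rng)
    founders_rows = np.concatenate([sire_idx, dam_idx])
    pop = HaplotypePopulation(
        hist.haplotypes[founders_rows],
        np.concatenate([np.ones(n_sires, bool), np.zeros(n_dams, bool)]),
        generation=0,
    )
    if n_generations == 0:
        return pop
    ratio = n_dams / n_sires
    quota = n_dams
    max_dams = int(round(dam_growth_cap * n_dams))
    cur_sires = np.arange(n_sires)
    cur_dams = np.arange(n_sires, n_sires + n_dams)
    for gen in range(1, n_generations + 1):
        sire_of_dam = cur_sires[rng.integers(0, cur_sires.size, size=cur_dams.size)]
        dam_rep = np.repeat(cur_dams, litter)
        sire_rep = np.repeat(sire_of_dam, litter)
        haps = produce_offspring(pop.haplotypes, sire_rep, dam_rep, gmap.positions,
                                 gmap.length_cM, rng, mutation_rate)
        is_male = rng.random(haps.shape[0]) < 0.5
        pop = HaplotypePopulation(haps, is_male, generation=gen)
        if gen == n_generations:
            break
        quota = min(max_dams, int(round(quota * litter / 2.0)))
        females = pop.females()
        males = pop.males()
        n_next_dams = min(quota, females.size)
        n_next_sires = min(max(1, int(round(n_next_dams / ratio))), males.size)
        if n_next_dams < 1 or n_next_sires < 1:
            raise SimulationError(f"expansion generation {gen} ran out of a sex")
        cur_dams = rng.choice(females, size=n_next_dams, replace=False)
        cur_sires = rng.choice(males, size=n_next_sires, replace=False)
    return pop


def _offspring_kinship(K_par: np.ndarray, sire_pos: np.ndarray,
                       dam_pos: np.ndarray) -> np.ndarray:
    """Pairwise kinship among same-generation offspring from parent kinships."""
    Kss = K_par[np.ix_(sire_pos, sire_pos)]
    Ksd = K_par[np.ix_(sire_pos, dam_pos)]
    Kds = K_par[np.ix_(dam_pos, sire_pos)]
    Kdd = K_par[np.ix_(dam_pos, dam_pos)]
    K = 0.25 * (Kss + Ksd + Kds + Kdd)
    # self-kinship overrides the cross formula on the diagonal
    F = K_par[sire_pos, dam_pos]
    np.fill_diagonal(K, 0.5 * (1.0 + F))
    return K


def simulate_recent(expanded: HaplotypePopulation, gmap: GenomeMap,
                    raw_effects: np.ndarray, h2: float, design: str,
                    n_sires: int, n_dams: int,
                    n_generations: int = RECENT_GENERATIONS, litter: int = 5,
                    sigma_p2: float = 1.0, rng=None,
                    mutation_rate: float = DEFAULT_MUTATION_RATE,
                    ebv_method: str = "phenotype",
                    anneal_kwargs: dict | None = None) -> StudyPopulation:
    """Breed ``n_generations`` generations under ``design`` and record
    everything needed for genomic prediction.

    The trait is scaled on the recent founder cohort (generation 0), so
    heritability holds where phenotypes are recorded.  Replacements (the
    next generation's ``n_sires`` + ``n_dams`` parents) are drawn at random
    among offspring, so differences between runs are attributable to the
    mating design rather than to selection.
    """
    rng = as_generator(rng)
    if design not in ("random", "assortative+", "assortative-",
                      "min_inbreeding", "max_inbreeding"):
        raise ConfigurationError(f"unknown mating design {design!r}")
    anneal_kwargs = anneal_kwargs or {}
    sire_rows, dam_rows = _draw_founders(expanded, n_sires, n_dams, rng)
    rows = np.concatenate([sire_rows, dam_rows])
    n_par = rows.size
    par_haps = expanded.haplotypes[rows]
    par_is_male = np.concatenate([np.ones(n_sires, bool), np.zeros(n_dams, bool)])

    qtl_cols = gmap.qtl_indices
    trait = scale_trait(par_haps.sum(axis=1)[:, qtl_cols], raw_effects, h2, sigma_p2)

    par_tbv = trait.breeding_values(par_haps.sum(axis=1)[:, qtl_cols])
    par_y = trait.phenotypes(par_tbv, rng)
    par_ids = np.arange(n_par)
    next_id = n_par
    K = 0.5 * np.eye(n_par)  # founders: unrelated, non-inbred

    cohorts = [Cohort(0, par_ids, np.full(n_par, -1), np.full(n_par, -1),
                      par_is_male, np.zeros(n_par), par_haps, par_tbv, par_y)]

    for gen in range(1, n_generations + 1):
        sire_pos = np.arange(n_sires)              # parents stored sires-first
        dam_pos = np.arange(n_sires, n_par)
        if design in ("assortative+", "assortative-"):
            ebv = estimate_ebv(par_y, h2, method=ebv_method)
            plan = make_plan(design, sire_pos, dam_pos, rng,
                             sire_ebv=ebv[sire_pos], dam_ebv=ebv[dam_pos])
        elif design in ("min_inbreeding", "max_inbreeding"):
            plan = make_plan(design, sire_pos, dam_pos, rng,
                             kinship_sd=K[np.ix_(sire_pos, dam_pos)],
                             **anneal_kwargs)
        else:
            plan = make_plan(design, sire_pos, dam_pos, rng)

        dam_rep = np.repeat(plan.dams, litter)
        sire_rep = np.repeat(plan.sires, litter)
        haps = produce_offspring(par_haps, sire_rep, dam_rep, gmap.positions,
                                 gmap.length_cM, rng, mutation_rate)
        n_off = haps.shape[0]
        off_F = K[sire_rep, dam_rep]
        off_tbv = trait.breeding_values(haps.sum(axis=1)[:, qtl_cols])
        off_y = trait.phenotypes(off_tbv, rng)
        off_is_male = rng.random(n_off) < 0.5
        off_ids = np.arange(next_id, next_id + n_off)
        next_id += n_off
        cohorts.append(Cohort(gen, off_ids, par_ids[sire_rep], par_ids[dam_rep],
                              off_is_male, off_F, haps, off_tbv, off_y))
        if gen == n_generations:
            break
        males = np.flatnonzero(off_is_male)
        females = np.flatnonzero(~off_is_male)
        if males.size < n_sires or females.size < n_dams:
            raise SimulationError(f"recent generation {gen}: offspring shortfall")
        new_sires = rng.choice(males, size=n_sires, replace=False)
        new_dams = rng.choice(females, size=n_dams, replace=False)
        sel = np.concatenate([new_sires, new_dams])
        K = _offspring_kinship(K, sire_rep[sel], dam_rep[sel])
        par_haps = haps[sel]
        par_y = off_y[sel]
        par_ids = off_ids[sel]
        par_is_male = off_is_male[sel]

    ref = tuple(g for g in REFERENCE_GENERATIONS if g < n_generations)
    return StudyPopulation(gmap, trait, design, cohorts,
                           reference_generations=ref,
                           validation_generation=n_generations)
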