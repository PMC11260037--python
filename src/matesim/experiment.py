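"""Scenario orchestration: one replicate end-to-end, scenarios, and grids.

A *scenario* is (marker count, QTL count, heritability, mating design) at a
given scale preset.  A replicate runs

    historical simulation -> expansion -> recent phase under the design
    -> RR-BLUP fit on the reference set (generations 3-9)
    -> GEBV for reference and validation -> accuracy / bias / LD metrics.

Seeding is fully deterministic: replicate streams come from
``SeedSequence([master_seed, replicate])`` and per-stage/per-scenario
children are spawned from it, so a (config, master seed) pair reproduces
results bit-for-bit.

Grids can share one dense historical+expansion simulation per replicate
across scenarios (markers thinned nearest-to-grid, QTL subset per
scenario); marginalising a neutral simulation over a locus subset is exact,
so density comparisons then share genetic background, as intended.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateTraitError
from .genome_trait import GenomeMap, build_genome_map, sample_qtl_effects
from .mating import DESIGNS
from .metrics import (LD_BIN_EDGES, accuracy, bias_slope, ld_table, mean_r2,
                      summarize_replicates)
from .popsim_historical import HaplotypePopulation, simulate_historical
from .popsim_recent import StudyPopulation, expand_population, simulate_recent
from .prediction import default_lambda, gebv, rrblup_fit
from .presets import ScalePreset, get_preset

logger = logging.getLogger("matesim")

SUPPORTED_MARKERS = (350, 650, 950)
SUPPORTED_QTL = (50, 150, 200)
SUPPORTED_H2 = (0.05, 0.30, 0.60)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the scenario grid."""

    n_markers: int = 650
    n_qtl: int = 50
    h2: float = 0.30
    design: str = "random"
    preset: str = "desk"
    length_cM: float = 100.0
    sigma_p2: float = 1.0
    gamma_shape: float = 0.4
    compute_ld: bool = False

    def __post_init__(self):
        if self.n_markers < 2 or self.n_qtl < 1:
            raise ConfigurationError("need n_markers >= 2, n_qtl >= 1")
        if not 0.0 < self.h2 <= 1.0:
            raise ConfigurationError("h2 must be in (0, 1]")
        if self.design not in DESIGNS:
            raise ConfigurationError(f"unknown design {self.design!r}")
        get_preset(self.preset)  # validates

    @property
    def scale(self) -> ScalePreset:
        return get_preset(self.preset)

    def label(self) -> str:
        return f"{self.design}/m{self.n_markers}/q{self.n_qtl}/h{self.h2:g}"


@dataclass
class ReplicateResult:
    """Per-replicate metrics for one scenario."""

    n_markers: int
    n_qtl: int
    h2: float
    design: str
    replicate: int
    a_t: float            # reference-set correlation(TBV, GEBV)
    a_v: float            # validation-set correlation
    b: float              # OLS slope of TBV on GEBV, reference+validation pooled
    b_se: float
    var_tbv_val: float    # TBV variance in the validation cohort
    mean_f_val: float     # mean pedigree inbreeding in the validation cohort
    n_reference: int
    n_validation: int
    mean_r2: float = np.nan  # mean marker-pair r2 (<= 5 cM) in the reference set

    def as_dict(self):
        return asdict(self)


def _simulate_base(cfg_markers: int, cfg_qtl: int, preset: ScalePreset,
                   length_cM: float, ss: np.random.SeedSequence):
    """Genome map + historical + expansion for one replicate."""
    r_map, r_hist, r_exp = [np.random.default_rng(c) for c in ss.spawn(3)]
    gmap = build_genome_map(cfg_markers, cfg_qtl, length_cM, r_map)
    hist = simulate_historical(gmap, preset.schedule, preset.mutation_rate,
                               r_hist, final_sex_split=preset.final_sex_split)
    expanded = expand_population(hist, gmap, preset.expand_sires,
                                 preset.expand_dams, preset.expand_generations,
                                 preset.litter, r_exp, preset.mutation_rate,
                                 preset.dam_growth_cap)
    return gmap, expanded


def _recent_and_score(cfg: ScenarioConfig, gmap: GenomeMap,
                      expanded: HaplotypePopulation, replicate: int,
                      ss: np.random.SeedSequence) -> ReplicateResult:
    preset = cfg.scale
    study = None
    for attempt, child in enumerate(ss.spawn(5)):
        rng = np.random.default_rng(child)
        raw = sample_qtl_effects(gmap.n_qtl, cfg.gamma_shape, rng)
        try:
            study = simulate_recent(expanded, gmap, raw, cfg.h2, cfg.design,
                                    preset.recent_sires, preset.recent_dams,
                                    preset.recent_generations, preset.litter,
                                    cfg.sigma_p2, rng, preset.mutation_rate)
            break
        except DegenerateTraitError:
            logger.warning("degenerate trait in %s rep %d (attempt %d); resampling",
                           cfg.label(), replicate, attempt)
    if study is None:
        raise DegenerateTraitError(f"could not scale a trait for {cfg.label()}")
    return score_study(study, cfg, replicate)


def score_study(study: StudyPopulation, cfg: ScenarioConfig,
                replicate: int = 0) -> ReplicateResult:
    """RR-BLUP fit on the reference set, GEBVs, and all metrics."""
    ref_g = study.reference_generations
    val_g = (study.validation_generation,)
    X_ref = study.marker_dosages(ref_g).astype(float)
    p = X_ref.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)  # markers fixed in the reference carry no signal
    X_ref = X_ref[:, keep]
    y_ref = study.phenotypes(ref_g)
    lam = default_lambda(cfg.h2, cfg.sigma_p2, p[keep]) if cfg.h2 < 1.0 else 1e-8
    fit = rrblup_fit(X_ref, y_ref, lam)
    X_val = study.marker_dosages(val_g).astype(float)[:, keep]
    tbv_ref, tbv_val = study.tbv(ref_g), study.tbv(val_g)
    g_ref, g_val = gebv(X_ref, fit), gebv(X_val, fit)
    slope, slope_se = bias_slope(np.concatenate([tbv_ref, tbv_val]),
                                 np.concatenate([g_ref, g_val]))
    r2 = np.nan
    if cfg.compute_ld:
        r2 = mean_r2(study.haplotypes(ref_g), study.gmap)
    val = study.cohort(study.validation_generation)
    return ReplicateResult(
        n_markers=cfg.n_markers, n_qtl=cfg.n_qtl, h2=cfg.h2, design=cfg.design,
        replicate=replicate,
        a_t=accuracy(tbv_ref, g_ref), a_v=accuracy(tbv_val, g_val),
        b=slope, b_se=slope_se,
        var_tbv_val=float(np.var(tbv_val)), mean_f_val=float(val.F.mean()),
        n_reference=y_ref.size, n_validation=tbv_val.size, mean_r2=r2,
    )


def run_replicate(cfg: ScenarioConfig, master_seed: int,
                  replicate: int = 0) -> ReplicateResult:
    """One scenario replicate from scratch (no sharing)."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    base_ss, recent_ss = ss.spawn(2)
    gmap, expanded = _simulate_base(cfg.n_markers, cfg.n_qtl, cfg.scale,
                                    cfg.length_cM, base_ss)
    return _recent_and_score(cfg, gmap, expanded, replicate, recent_ss)


def run_scenario(cfg: ScenarioConfig, master_seed: int,
                 n_replicates: int = 5) -> pd.DataFrame:
    """Independent replicates of one scenario; one row per replicate."""
    rows = [run_replicate(cfg, master_seed, r).as_dict()
            for r in range(n_replicates)]
    return pd.DataFrame(rows)


def run_grid(scenarios, preset, master_seed: int, n_replicates: int = 3,
             share_history: bool = True, compute_ld: bool = False) -> pd.DataFrame:
    """Run a list of (n_markers, n_qtl, h2, design) cells.

    With ``share_history`` (default) each replicate index simulates one dense
    historical+expansion base at the maximum marker/QTL density and thins it
    per scenario, so scenario comparisons share genetic background and the
    grid runs ~|scenarios| times cheaper.
    """
    preset = get_preset(preset)
    cfgs = [c if isinstance(c, ScenarioConfig)
            else ScenarioConfig(*c, preset=preset.name, compute_ld=compute_ld)
            for c in scenarios]
    cfgs = [ScenarioConfig(c.n_markers, c.n_qtl, c.h2, c.design, preset.name,
                           c.length_cM, c.sigma_p2, c.gamma_shape,
                           compute_ld or c.compute_ld) for c in cfgs]
    if not cfgs:
        raise ConfigurationError("empty scenario list")
    rows = []
    if not share_history:
        for c in cfgs:
            for r in range(n_replicates):
                rows.append(run_replicate(c, master_seed, r).as_dict())
        return pd.DataFrame(rows)
    m_max = max(c.n_markers for c in cfgs)
    q_max = max(c.n_qtl for c in cfgs)
    for r in range(n_replicates):
        ss = np.random.SeedSequence([int(master_seed), int(r)])
        base_ss, scen_parent = ss.spawn(2)
        dense_map, dense_exp = _simulate_base(m_max, q_max, preset, cfgs[0].length_cM,
                                              base_ss)
        for s_idx, (c, child) in enumerate(zip(cfgs, scen_parent.spawn(len(cfgs)))):
            thin_ss, recent_ss = child.spawn(2)
            gmap, cols = dense_map.thin(c.n_markers, c.n_qtl,
                                        np.random.default_rng(thin_ss))
            expanded = dense_exp.subset_loci(cols)
            res = _recent_and_score(c, gmap, expanded, r, recent_ss)
            rows.append(res.as_dict())
            logger.info("replicate %d scenario %s done", r, c.label())
    return pd.DataFrame(rows)


def full_grid_scenarios(design_list=DESIGNS, markers=SUPPORTED_MARKERS,
                        qtl=SUPPORTED_QTL, h2s=SUPPORTED_H2):
    """The full 3 x 3 x 3 x 5 scenario grid as (m, q, h2, design) tuples."""
    return [(m, q, h, d) for d in design_list
            for m, q, h in itertools.product(markers, qtl, h2s)]


def summarize(results: pd.DataFrame, by=("design", "n_markers", "n_qtl", "h2"),
              metrics_cols=("a_t", "a_v", "b")) -> pd.DataFrame:
    """Mean +/- SE per scenario cell, mirroring the results-table layout."""
    out = []
    for key, grp in results.groupby(list(by)):
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_replicates"] = len(grp)
        for col in metrics_cols:
            mean, se = summarize_replicates(grp[col].to_numpy())
            row[col] = mean
            row[f"{col}_se"] = se
        out.append(row)
    return pd.DataFrame(out)


def ld_decay_table(cfg: ScenarioConfig, master_seed: int, replicate: int = 0,
                   bins=LD_BIN_EDGES) -> pd.DataFrame:
    """Per-reference-generation LD bin table (LD-decay layout) for one run."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    base_ss, recent_ss = ss.spawn(2)
    gmap, expanded = _simulate_base(cfg.n_markers, cfg.n_qtl, cfg.scale,
                                    cfg.length_cM, base_ss)
    preset = cfg.scale
    rng = np.random.default_rng(recent_ss)
    raw = sample_qtl_effects(gmap.n_qtl, cfg.gamma_shape, rng)
    study = simulate_recent(expanded, gmap, raw, cfg.h2, cfg.design,
                            preset.recent_sires, preset.recent_dams,
                            preset.recent_generations, preset.litter,
                            cfg.sigma_p2, rng, preset.mutation_rate)
    tables = []
    for g in study.reference_generations:
        t = ld_table(study.cohort(g).haplotypes, gmap, bins)
        t.insert(0, "generation", g)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)
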