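"""End-to-end orchestration of the reservoir analysis.

Wires the modules together in the order the analysis runs on field data:
synthetic (or loaded) inputs -> mixing-polygon screening -> Bayesian diet
mixing -> community/group niche metrics -> between-period and
consecutive-pair trait-change partitions -> environment linkage
(PERMANOVA, collinearity/VIF screening, PLS path model).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import env_stats, niche_metrics, plspm_engine, preprocess, source_mixing
from .core_io import CommunitySnapshot, IsotopeSample, RunConfig, TrophicEnrichment
from .niche_metrics import EllipsePosterior, IsoPointSet
from .price_partition import PricePartition, price_partition, timeseries_partition
from .synthetic_data import (
    SyntheticBundle,
    SynthConfig,
    generate,
    period_mean_snapshots,
)


def pointset(consumers: list[IsotopeSample], label: str) -> IsoPointSet:
    pts = np.array([[c.d13C, c.d15N] for c in consumers])
    return IsoPointSet(label=label, points=pts)


def per_period_pointsets(
    consumers: list[IsotopeSample], periods: dict[_dt.date, str]
) -> dict[str, IsoPointSet]:
    out = {}
    for period in ("mixing", "stratification"):
        sel = [c for c in consumers if periods[c.date] == period]
        if sel:
            out[period] = pointset(sel, period)
    return out


def group_period_sea_b(
    consumers: list[IsotopeSample],
    periods: dict[_dt.date, str],
    groups: tuple[str, ...],
    seed: int = 0,
    n_draws: int = 1000,
) -> dict[str, dict[str, EllipsePosterior]]:
    """Per-group, per-period Bayesian standard ellipse areas."""
    out: dict[str, dict[str, EllipsePosterior]] = {}
    for period in ("mixing", "stratification"):
        out[period] = {}
        for g in groups:
            sel = [c for c in consumers if c.group_id == g and periods[c.date] == period]
            if len(sel) >= 3:
                out[period][g] = niche_metrics.sea_b(
                    pointset(sel, f"{g}_{period}"), n_draws=n_draws, seed=seed
                )
    return out


def niche_breadth_partition(
    bundle: SyntheticBundle, seed: int = 0, n_draws: int = 1000
) -> PricePartition:
    """Between-period partition of community niche breadth (z = group SEA_B).

    Uses each group's period-mean relative abundance and its posterior-mode
    SEA_B within the period as (q, z) in the two period-level snapshots.
    """
    gt = bundle.ground_truth
    periods = {d: p for d, p in zip(gt.dates, gt.periods)}
    seab = group_period_sea_b(
        bundle.consumers, periods, gt.config.groups, seed=seed, n_draws=n_draws
    )
    mix_snap, strat_snap = period_mean_snapshots(bundle)
    snaps = []
    for period, base in (("mixing", mix_snap), ("stratification", strat_snap)):
        entries = tuple(
            (g, q, seab[period][g].mode)
            for g, q, _ in base.entries
            if g in seab[period]
        )
        total_q = sum(q for _, q, _ in entries)
        entries = tuple((g, q / total_q, z) for g, q, z in entries)
        snaps.append(
            CommunitySnapshot(date=base.date, period=period, entries=entries)
        )
    return price_partition(snaps[0], snaps[1])


@dataclass(frozen=True)
class PipelineSummary:
    cwm_body_size_mixing: float
    cwm_body_size_stratification: float
    body_size_partition: PricePartition
    niche_partition: PricePartition
    sea_b_mixing: EllipsePosterior
    sea_b_stratification: EllipsePosterior
    permanova: env_stats.PermanovaResult
    diet_posterior_mixing: source_mixing.MixingPosterior
    diet_posterior_stratification: source_mixing.MixingPosterior
    n_excluded_mixing: int
    n_excluded_stratification: int
    timeseries_partitions: list[PricePartition]
    plspm: plspm_engine.PathModelResult


def run_synthetic_pipeline(
    seed: int = 0,
    cfg: SynthConfig | None = None,
    mcmc_iterations: int = 40_000,
    mcmc_burn_in: int = 8_000,
    mcmc_thinning: int = 20,
    polygon_iterations: int = 2000,
    sea_b_draws: int = 2000,
    n_permutations: int = 999,
) -> PipelineSummary:
    """Run the full analysis on one synthetic reservoir realization.

    Returns the principal quantities of the study design: period
    community-weighted mean body sizes, the taxa-sorting /
    intrataxonomic-variation / turnover partitions of body-size and
    niche-breadth change, per-period community SEA_B posteriors, the
    environmental PERMANOVA, the screened diet-mixing posteriors per
    period, and the PLS path model linking temperature, environment and
    community properties.
    """
    cfg = cfg or SynthConfig(seed=seed)
    bundle = generate(cfg)
    gt = bundle.ground_truth
    periods = {d: p for d, p in zip(gt.dates, gt.periods)}

    # community-weighted mean body size per period
    mix_snap, strat_snap = period_mean_snapshots(bundle)
    cwm_mix = preprocess.community_weighted_mean(mix_snap)
    cwm_strat = preprocess.community_weighted_mean(strat_snap)

    # between-period partitions
    body_part = price_partition(mix_snap, strat_snap)
    niche_part = niche_breadth_partition(bundle, seed=seed, n_draws=sea_b_draws // 2)

    # per-period community ellipses
    ps = per_period_pointsets(bundle.consumers, periods)
    seab_mix = niche_metrics.sea_b(ps["mixing"], n_draws=sea_b_draws, seed=seed)
    seab_strat = niche_metrics.sea_b(ps["stratification"], n_draws=sea_b_draws, seed=seed)

    # environmental PERMANOVA (period factor, standardized Euclidean)
    env_df = pd.DataFrame([r.variables for r in bundle.env])
    labels = np.array(gt.periods)
    perma = env_stats.permanova_one_factor(
        env_df.to_numpy(), labels, n_perm=n_permutations, seed=seed
    )

    # diet mixing per period, after polygon screening
    run_cfg = RunConfig(seed=seed)
    run_cfg.mcmc.iterations = mcmc_iterations
    run_cfg.mcmc.burn_in = mcmc_burn_in
    run_cfg.mcmc.thinning = mcmc_thinning
    tef = gt.config.tef
    posteriors = {}
    n_excluded = {}
    for period in ("mixing", "stratification"):
        cons = ps[period]
        screen = source_mixing.simulate_mixing_polygon(
            bundle.sources, tef, cons, n_iter=polygon_iterations, seed=seed
        )
        kept = IsoPointSet(label=period, points=cons.points[~screen.excluded])
        posteriors[period] = source_mixing.fit_mixing_model(
            kept, bundle.sources, tef, cfg=run_cfg
        )
        n_excluded[period] = screen.n_excluded

    ts_parts = timeseries_partition(bundle.snapshots)

    # PLS path model: temperature + physicochemistry + nutrients +
    # chlorophyll -> community body size (single-indicator response blocks)
    cwm_series = [preprocess.community_weighted_mean(s) for s in bundle.snapshots]
    plspm_df = env_df.copy()
    plspm_df["Zeu"] = [preprocess.euphotic_depth(v) for v in env_df["secchi"]]
    plspm_df["CO2aq"] = [
        preprocess.co2aq(d, t, p)
        for d, t, p in zip(env_df["DIC"], env_df["temperature"], env_df["pH"])
    ]
    plspm_df["body_size"] = cwm_series
    spec = plspm_engine.PathModelSpec(
        blocks={
            "temperature": ("temperature",),
            "physicochemical": ("Zeu", "EC", "CO2aq", "DO"),
            "nutrients": ("TN", "NOx_N", "TP", "DIC"),
            "chlorophyll": ("chl_a",),
            "body_size": ("body_size",),
        },
        paths=(
            ("temperature", "physicochemical"),
            ("temperature", "nutrients"),
            ("temperature", "chlorophyll"),
            ("physicochemical", "body_size"),
            ("nutrients", "body_size"),
            ("chlorophyll", "body_size"),
            ("temperature", "body_size"),
        ),
    )
    plspm_res, _ = plspm_engine.prune_and_refit(plspm_df, spec, loading_cutoff=0.7)

    return PipelineSummary(
        cwm_body_size_mixing=cwm_mix,
        cwm_body_size_stratification=cwm_strat,
        body_size_partition=body_part,
        niche_partition=niche_part,
        sea_b_mixing=seab_mix,
        sea_b_stratification=seab_strat,
        permanova=perma,
        diet_posterior_mixing=posteriors["mixing"],
        diet_posterior_stratification=posteriors["stratification"],
        n_excluded_mixing=n_excluded["mixing"],
        n_excluded_stratification=n_excluded["stratification"],
        timeseries_partitions=ts_parts,
        plspm=plspm_res,
    )
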