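"""Synthetic monomictic-reservoir dataset generator.

Emulates the statistical structure of a one-year, 20-day-cadence
zooplankton isotope survey of a subtropical reservoir: a cold fully-mixed
period followed by a warm stratified period, six zooplankton taxonomic
groups, and particulate-organic-matter (POM) food sources in three size
fractions from two depth layers.  The generator encodes the qualitative
effect directions such a system exhibits:

* surface temperature with distinct period means (defaults 18.97 degC
  mixing, 27.11 degC stratification),
* per-taxon body size declining with temperature for most groups
  (positive for small Cyclopidae, flat for Diaptomidae),
* relative abundances shifting toward small-bodied taxa as temperature
  rises (so taxa sorting dominates the community body-size change),
* per-taxon isotopic dispersion shrinking with temperature (so
  intrataxonomic variation dominates the niche-breadth change and the
  community ellipse is larger in the mixing period),
* consumer isotope values drawn from the diet-mixing likelihood given the
  date's true diet proportions and the trophic enrichment factor.

Every draw is a pure function of the configured seed; the ground-truth
record retains the noise-free generating values so that recovery tests
can compare pipeline estimates against the truth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    DEFAULT_GROUPS,
    CommunitySnapshot,
    EnvRecord,
    IsotopeSample,
    SourceSummary,
    TrophicEnrichment,
    ValidationError,
    env_to_frame,
    rng_for,
    snapshots_to_frame,
    write_results,
)
from .price_partition import PricePartition, price_partition

# default POM source signatures: (mean d13C, sd, mean d15N, sd)
DEFAULT_SOURCES: dict[str, tuple[float, float, float, float]] = {
    "pico_surface": (-30.5, 0.6, 3.5, 0.5),
    "nano_surface": (-27.0, 0.6, 4.8, 0.5),
    "micro_surface": (-23.5, 0.6, 6.0, 0.5),
    "pico_bottom": (-32.5, 0.6, 5.5, 0.5),
    "nano_bottom": (-29.0, 0.6, 6.8, 0.5),
    "micro_bottom": (-25.5, 0.6, 8.0, 0.5),
}

# community-level mean diet proportions per period (simplex, source order
# as DEFAULT_SOURCES): balanced pico/nano diet while mixed, surface
# pico-POM dominant under stratification
DEFAULT_DIET_MIXING = (0.17, 0.17, 0.12, 0.20, 0.18, 0.16)
DEFAULT_DIET_STRATIFICATION = (0.73, 0.10, 0.05, 0.05, 0.04, 0.03)

# per-group body size baseline (ug dry weight / individual) and slope vs
# temperature (ug per degC); sign pattern: declining with warming for
# Bosmina, Bosminopsis, other Cladocera and large Cyclopidae, increasing
# for small Cyclopidae, flat for Diaptomidae
DEFAULT_SIZE_BASELINE = (1.00, 0.80, 2.20, 1.20, 3.00, 2.50)
DEFAULT_SIZE_SLOPE = (-0.030, -0.025, -0.060, 0.030, -0.080, 0.0)

# abundance responsiveness on the log scale (positive: favoured when warm)
DEFAULT_ABUNDANCE_BASE = (0.30, 0.00, -0.20, 0.00, 0.20, -0.10)
DEFAULT_ABUNDANCE_SLOPE = (0.10, 0.10, -0.08, 0.12, -0.15, 0.0)

# small per-group offsets of the consumer cloud in isotope space
DEFAULT_GROUP_D13C_OFFSET = (-0.2, -0.1, 0.0, 0.1, 0.2, 0.15)
DEFAULT_GROUP_D15N_OFFSET = (-0.3, -0.3, 0.0, 0.3, 0.5, 0.4)


@dataclass(frozen=True)
class SynthConfig:
    n_dates: int = 21
    n_mixing_dates: int = 9
    cadence_days: int = 20
    start_date: _dt.date = _dt.date(2015, 11, 1)
    temp_mixing: float = 18.97
    temp_stratification: float = 27.11
    temp_noise_sd: float = 0.8
    groups: tuple[str, ...] = DEFAULT_GROUPS
    sources: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOURCES)
    )
    diet_mixing: tuple[float, ...] = DEFAULT_DIET_MIXING
    diet_stratification: tuple[float, ...] = DEFAULT_DIET_STRATIFICATION
    tef: TrophicEnrichment = field(default_factory=TrophicEnrichment)
    size_baseline: tuple[float, ...] = DEFAULT_SIZE_BASELINE
    size_slope: tuple[float, ...] = DEFAULT_SIZE_SLOPE
    size_noise_sd: float = 0.05
    abundance_base: tuple[float, ...] = DEFAULT_ABUNDANCE_BASE
    abundance_slope: tuple[float, ...] = DEFAULT_ABUNDANCE_SLOPE
    abundance_logit_noise_sd: float = 0.05
    # isotopic dispersion of each group's consumer cloud: shrinks with T so
    # the isotopic niche narrows from the mixing to the stratified period
    dispersion_cold: float = 1.30
    dispersion_warm: float = 0.65
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dates < 4:
            raise ValidationError("need n_dates >= 4")
        if not (0 < self.n_mixing_dates < self.n_dates):
            raise ValidationError("n_mixing_dates must split the series")
        for diet in (self.diet_mixing, self.diet_stratification):
            if len(diet) != len(self.sources):
                raise ValidationError("diet proportion length must match source count")
            if abs(sum(diet) - 1.0) > 1e-9 or any(p < 0 for p in diet):
                raise ValidationError("diet proportions must lie on the simplex")
        k = len(self.groups)
        for name in ("size_baseline", "size_slope", "abundance_base", "abundance_slope"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"{name} must have one entry per group")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free generating values alongside the realized (noisy) series."""

    config: SynthConfig
    dates: tuple[_dt.date, ...]
    periods: tuple[str, ...]
    temperature: np.ndarray            # (n_dates,) realized
    diet: np.ndarray                   # (n_dates, n_sources) true proportions
    q: np.ndarray                      # (n_dates, n_groups) realized abundances
    z_size_true: np.ndarray            # (n_dates, n_groups) noise-free body size
    z_size_realized: np.ndarray        # (n_dates, n_groups) noisy body size
    dispersion: np.ndarray             # (n_dates,) consumer isotope SD
    consumer_mean: np.ndarray          # (n_dates, 2) TEF-corrected diet mean


@dataclass(frozen=True)
class SyntheticBundle:
    consumers: list[IsotopeSample]
    sources: list[SourceSummary]
    snapshots: list[CommunitySnapshot]
    env: list[EnvRecord]
    ground_truth: GroundTruth


def _ramp(cfg: SynthConfig) -> np.ndarray:
    """Smooth 0->1 logistic transition centred on the period boundary."""
    i = np.arange(cfg.n_dates, dtype=float)
    return 1.0 / (1.0 + np.exp(-(i - cfg.n_mixing_dates + 0.5) / 1.2))


def generate(cfg: SynthConfig | None = None) -> SyntheticBundle:
    """Generate the full dataset bundle plus its ground-truth record."""
    cfg = cfg or SynthConfig()
    rng = rng_for(cfg.seed, "synth")
    n, k = cfg.n_dates, len(cfg.groups)
    dates = tuple(
        cfg.start_date + _dt.timedelta(days=cfg.cadence_days * i) for i in range(n)
    )
    mix_mask = np.arange(n) < cfg.n_mixing_dates
    periods = tuple("mixing" if m else "stratification" for m in mix_mask)

    # temperature: smooth two-period trajectory, recentred per period so the
    # realized period means equal the configured ones exactly
    s = _ramp(cfg)
    temp = cfg.temp_mixing + (cfg.temp_stratification - cfg.temp_mixing) * s
    temp = temp + rng.normal(0.0, cfg.temp_noise_sd, n)
    temp[mix_mask] += cfg.temp_mixing - temp[mix_mask].mean()
    temp[~mix_mask] += cfg.temp_stratification - temp[~mix_mask].mean()

    t_mid = 0.5 * (cfg.temp_mixing + cfg.temp_stratification)
    t_span = cfg.temp_stratification - cfg.temp_mixing

    # true diet proportions interpolate between the period-level vectors
    diet_mix = np.array(cfg.diet_mixing)
    diet_strat = np.array(cfg.diet_stratification)
    diet = (1 - s)[:, None] * diet_mix + s[:, None] * diet_strat
    diet /= diet.sum(axis=1, keepdims=True)

    # relative abundances: softmax of temperature-dependent log-weights
    logits = (
        np.array(cfg.abundance_base)[None, :]
        + np.array(cfg.abundance_slope)[None, :] * (temp - t_mid)[:, None]
        + rng.normal(0.0, cfg.abundance_logit_noise_sd, (n, k))
    )
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    q = w / w.sum(axis=1, keepdims=True)

    # body size: linear-in-temperature per taxon plus noise
    z_true = (
        np.array(cfg.size_baseline)[None, :]
        + np.array(cfg.size_slope)[None, :] * (temp - t_mid)[:, None]
    )
    z_real = np.clip(z_true + rng.normal(0.0, cfg.size_noise_sd, (n, k)), 0.01, None)

    # consumer isotope values from the mixing likelihood
    src_ids = list(cfg.sources)
    src_mu = np.array([[v[0], v[2]] for v in cfg.sources.values()])
    tef_mu = np.array([cfg.tef.mean_d13C, cfg.tef.mean_d15N])
    consumer_mean = diet @ src_mu + tef_mu
    frac = np.clip((temp - cfg.temp_mixing) / t_span, 0.0, 1.2)
    dispersion = cfg.dispersion_cold + (cfg.dispersion_warm - cfg.dispersion_cold) * frac

    off13 = np.array(DEFAULT_GROUP_D13C_OFFSET[:k]) if k <= 6 else np.zeros(k)
    off15 = np.array(DEFAULT_GROUP_D15N_OFFSET[:k]) if k <= 6 else np.zeros(k)
    consumers: list[IsotopeSample] = []
    for i, date in enumerate(dates):
        for gi, group in enumerate(cfg.groups):
            vals = rng.normal(
                loc=[consumer_mean[i, 0] + off13[gi], consumer_mean[i, 1] + off15[gi]],
                scale=dispersion[i],
                size=(cfg.n_replicates, 2),
            )
            cpct = rng.normal(45.0, 2.0, cfg.n_replicates)
            cn = rng.normal(5.0, 0.4, cfg.n_replicates)
            for r in range(cfg.n_replicates):
                consumers.append(
                    IsotopeSample(
                        sample_id=f"{group}_{date.isoformat()}_{r}",
                        group_id=group,
                        date=date,
                        d13C=float(vals[r, 0]),
                        d15N=float(vals[r, 1]),
                        c_percent=float(cpct[r]),
                        n_percent=float(cpct[r] / cn[r]),
                        cn_ratio=float(cn[r]),
                    )
                )

    sources = [
        SourceSummary(
            source_id=sid,
            mean_d13C=v[0],
            sd_d13C=v[1],
            mean_d15N=v[2],
            sd_d15N=v[3],
            n=3,
        )
        for sid, v in cfg.sources.items()
    ]

    snapshots = [
        CommunitySnapshot(
            date=dates[i],
            period=periods[i],
            entries=tuple(
                (cfg.groups[gi], float(q[i, gi]), float(z_real[i, gi]))
                for gi in range(k)
            ),
        )
        for i in range(n)
    ]

    env = _generate_env(cfg, rng, dates, temp, s)

    gt = GroundTruth(
        config=cfg,
        dates=dates,
        periods=periods,
        temperature=temp,
        diet=diet,
        q=q,
        z_size_true=z_true,
        z_size_realized=z_real,
        dispersion=dispersion,
        consumer_mean=consumer_mean,
    )
    return SyntheticBundle(
        consumers=consumers, sources=sources, snapshots=snapshots, env=env,
        ground_truth=gt,
    )


def _generate_env(
    cfg: SynthConfig,
    rng: np.random.Generator,
    dates: Sequence[_dt.date],
    temp: np.ndarray,
    s: np.ndarray,
) -> list[EnvRecord]:
    """Environmental series with period-dependent means and mild noise.

    Oxygen declines and chlorophyll rises with stratification; carbonate
    system variables stay near-neutral freshwater values.
    """
    n = len(dates)
    do = 9.0 - 2.5 * s + rng.normal(0, 0.4, n)
    ph = 7.2 + 0.2 * s + rng.normal(0, 0.1, n)
    dic = 11.0 + 1.5 * s + rng.normal(0, 0.5, n)
    secchi = 2.0 - 0.6 * s + rng.normal(0, 0.15, n)
    tn = 0.9 + 0.2 * s + rng.normal(0, 0.05, n)
    nox = 0.45 + 0.1 * s + rng.normal(0, 0.04, n)
    nh4 = 0.10 + 0.04 * s + rng.normal(0, 0.01, n)
    tp = 0.030 + 0.010 * s + rng.normal(0, 0.003, n)
    po4 = 0.012 + 0.004 * s + rng.normal(0, 0.001, n)
    chla = 5.0 + 6.0 * s + rng.normal(0, 0.8, n)
    ec = 110.0 + 15.0 * s + rng.normal(0, 4.0, n)
    precip = np.clip(rng.gamma(1.5, 30.0, n) * (0.6 + 0.8 * s), 0, None)
    records = []
    for i, date in enumerate(dates):
        records.append(
            EnvRecord(
                date=date,
                variables={
                    "temperature": float(temp[i]),
                    "DO": float(max(do[i], 0.5)),
                    "pH": float(ph[i]),
                    "DIC": float(max(dic[i], 1.0)),
                    "secchi": float(max(secchi[i], 0.3)),
                    "TN": float(max(tn[i], 0.05)),
                    "NOx_N": float(max(nox[i], 0.01)),
                    "NH4_N": float(max(nh4[i], 0.005)),
                    "TP": float(max(tp[i], 0.002)),
                    "PO4_P": float(max(po4[i], 0.001)),
                    "chl_a": float(max(chla[i], 0.2)),
                    "EC": float(ec[i]),
                    "precipitation": float(precip[i]),
                },
            )
        )
    return records


def expected_partitions(gt: GroundTruth) -> list[PricePartition]:
    """Noise-free body-size partitions for every consecutive date pair.

    Built from the generating (noise-free) trait values and the realized
    abundances; serves as the oracle against which pipeline partitions are
    compared with a tolerance scaled to the configured trait noise.
    """
    snaps = [
        CommunitySnapshot(
            date=gt.dates[i],
            period=gt.periods[i],
            entries=tuple(
                (g, float(gt.q[i, gi]), float(gt.z_size_true[i, gi]))
                for gi, g in enumerate(gt.config.groups)
            ),
        )
        for i in range(len(gt.dates))
    ]
    return [price_partition(a, b) for a, b in zip(snaps, snaps[1:])]


def period_mean_snapshots(bundle: SyntheticBundle) -> tuple[CommunitySnapshot, CommunitySnapshot]:
    """Per-period mean community snapshots (mean q renormalized, mean z).

    These are the inputs for the between-period trait-change partition,
    which uses the mean relative abundance and mean trait value of each
    group within each period.
    """
    groups = bundle.ground_truth.config.groups
    out = []
    for period in ("mixing", "stratification"):
        snaps = [s for s in bundle.snapshots if s.period == period]
        qbar = np.mean([[s.as_dict()[g][0] for g in groups] for s in snaps], axis=0)
        zbar = np.mean([[s.as_dict()[g][1] for g in groups] for s in snaps], axis=0)
        qbar = qbar / qbar.sum()
        out.append(
            CommunitySnapshot(
                date=snaps[-1].date,
                period=period,
                entries=tuple(
                    (g, float(qbar[i]), float(zbar[i])) for i, g in enumerate(groups)
                ),
            )
        )
    return out[0], out[1]


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSVs plus a ground-truth JSON into ``out_dir``."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    cons = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "group_id": c.group_id,
                "date": c.date.isoformat(), "d13C": c.d13C, "d15N": c.d15N,
                "c_percent": c.c_percent, "n_percent": c.n_percent,
                "cn_ratio": c.cn_ratio,
            }
            for c in bundle.consumers
        ]
    )
    paths["consumers"] = out_dir / "consumers.csv"
    cons.to_csv(paths["consumers"], index=False)

    src = pd.DataFrame(
        [
            {
                "source_id": s.source_id, "mean_d13C": s.mean_d13C,
                "sd_d13C": s.sd_d13C, "mean_d15N": s.mean_d15N,
                "sd_d15N": s.sd_d15N, "n": s.n,
            }
            for s in bundle.sources
        ]
    )
    paths["sources"] = out_dir / "sources.csv"
    src.to_csv(paths["sources"], index=False)

    paths["snapshots"] = out_dir / "snapshots.csv"
    snapshots_to_frame(bundle.snapshots).to_csv(paths["snapshots"], index=False)

    paths["env"] = out_dir / "env.csv"
    env_to_frame(bundle.env).to_csv(paths["env"], index=False)

    gt = bundle.ground_truth
    paths["ground_truth"] = out_dir / "ground_truth.json"
    write_results(
        {
            "seed": gt.config.seed,
            "dates": [d.isoformat() for d in gt.dates],
            "periods": list(gt.periods),
            "temperature": gt.temperature,
            "diet": gt.diet,
            "source_ids": list(gt.config.sources),
            "q": gt.q,
            "z_size_true": gt.z_size_true,
            "z_size_realized": gt.z_size_realized,
            "dispersion": gt.dispersion,
        },
        paths["ground_truth"],
    )
    return paths
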