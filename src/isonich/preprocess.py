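"""Pre-analysis corrections and standardizations.

Covers four independent steps that precede the niche and diet-mixing
analyses: (i) lipid-bias correction of consumer d13C from C:N ratios,
(ii) baseline standardization of consumer isotope values against the
retained food sources, (iii) derived environmental variables (dissolved
CO2 from the carbonate equilibrium, euphotic depth from Secchi depth),
and (iv) community-weighted trait means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_io import CommunitySnapshot, IsotopeSample, ValidationError, logger


@dataclass(frozen=True)
class LipidModel:
    """Linear-in-C:N lipid correction for d13C.

    mode="off" leaves d13C untouched.  mode="linear" adds
    ``intercept + slope * cn_ratio`` (per-mil).  Coefficients are supplied
    by configuration because published normalizations differ by taxon and
    lake; the correction never touches d15N.
    """

    mode: Literal["off", "linear"] = "off"
    intercept: float = 0.0
    slope: float = 0.0


@dataclass(frozen=True)
class BaselineSpec:
    """Per-axis baseline (mean, range) computed from retained food sources."""

    retained_sources: tuple[str, ...]
    mean_d13C: float
    range_d13C: float
    mean_d15N: float
    range_d15N: float

    def __post_init__(self) -> None:
        if self.range_d13C <= 0 or self.range_d15N <= 0:
            raise ValidationError("baseline range must be > 0 on every axis")


def lipid_correct(sample: IsotopeSample, model: LipidModel) -> float:
    """Return the lipid-corrected d13C for one sample.

    Raises ValidationError when mode="linear" and the sample has no C:N
    ratio (caller should exclude the sample and log it).
    """
    if model.mode == "off":
        return sample.d13C
    if sample.cn_ratio is None:
        raise ValidationError(
            f"sample {sample.sample_id}: C:N ratio required for lipid correction"
        )
    return sample.d13C + model.intercept + model.slope * sample.cn_ratio


def lipid_correct_all(
    samples: Sequence[IsotopeSample], model: LipidModel
) -> list[IsotopeSample]:
    """Apply the lipid correction to a batch, excluding samples without C:N."""
    out: list[IsotopeSample] = []
    excluded = 0
    for s in samples:
        try:
            out.append(replace(s, d13C=lipid_correct(s, model)))
        except ValidationError:
            excluded += 1
    if excluded:
        logger.info("lipid_correct_all excluded=%d (missing C:N)", excluded)
    return out


def select_baseline_sources(
    contributions: Mapping[str, Mapping[str, float]], cutoff: float = 0.12
) -> list[str]:
    """Retain sources contributing strictly more than ``cutoff`` in >= 1 period.

    ``contributions`` maps source_id -> {period: mean diet proportion}.
    The default cutoff (0.12) keeps only food sources that supply more
    than 12% of the diet in at least one hydrological period.
    """
    retained = [
        src
        for src, by_period in contributions.items()
        if any(p > cutoff for p in by_period.values())
    ]
    if not retained:
        raise ValidationError(
            f"no source exceeds the {cutoff:.0%} contribution cutoff; review the cutoff"
        )
    return retained


def make_baseline_spec(
    sources: Mapping[str, tuple[float, float]], retained: Sequence[str], axis: str = ""
) -> tuple[float, float]:
    """Pooled (mean, range) of the retained sources' means on one axis.

    ``sources`` maps source_id -> per-axis mean value; the range is the
    spread of the retained means.  Returns (mean, range).
    """
    vals = np.array([sources[s] for s in retained], dtype=float)
    rng = float(vals.max() - vals.min())
    return float(vals.mean()), rng


def baseline_standardize(
    values: np.ndarray, mean: float, value_range: float
) -> np.ndarray:
    """Standardize consumer values on one axis: (x - baseline mean) / baseline range.

    Puts both isotope axes on a common, dimensionless scale so that
    Euclidean niche metrics are comparable across dates with drifting
    source signatures.
    """
    if value_range <= 0:
        raise ValidationError("degenerate baseline: range must be > 0")
    return (np.asarray(values, dtype=float) - mean) / value_range


# -- carbonate equilibrium ---------------------------------------------------

# Freshwater dissociation constants of carbonic acid (Plummer & Busenberg
# 1982 fits, T in kelvin); valid 0-50 degC at infinite dilution.


def _log10_k1(t_kelvin: float) -> float:
    return (
        -356.3094
        - 0.06091964 * t_kelvin
        + 21834.37 / t_kelvin
        + 126.8339 * math.log10(t_kelvin)
        - 1_684_915.0 / t_kelvin**2
    )


def _log10_k2(t_kelvin: float) -> float:
    return (
        -107.8871
        - 0.03252849 * t_kelvin
        + 5151.79 / t_kelvin
        + 38.92561 * math.log10(t_kelvin)
        - 563_713.9 / t_kelvin**2
    )


def co2aq(dic_mg_l: float, temperature_c: float, ph: float) -> float:
    """Dissolved CO2 (umol/L) from DIC (mg C/L), temperature (degC) and pH.

    Uses the carbonate speciation fraction
    ``alpha0 = 1 / (1 + K1/[H+] + K1*K2/[H+]^2)`` with freshwater K1(T),
    K2(T); DIC in mg C/L is converted to umol/L via the molar mass of
    carbon (12.011 g/mol): ``DIC_umol = DIC_mg / 12.011 * 1000``.
    """
    if not (0 < ph < 14):
        raise ValidationError(f"pH out of range: {ph}")
    if dic_mg_l < 0:
        raise ValidationError(f"negative DIC: {dic_mg_l}")
    if not (0 < temperature_c < 40):
        raise ValidationError(f"temperature out of range: {temperature_c}")
    t_k = temperature_c + 273.15
    k1 = 10.0 ** _log10_k1(t_k)
    k2 = 10.0 ** _log10_k2(t_k)
    h = 10.0 ** (-ph)
    alpha0 = 1.0 / (1.0 + k1 / h + k1 * k2 / h**2)
    dic_umol = dic_mg_l / 12.011 * 1000.0
    return dic_umol * alpha0


def euphotic_depth(secchi_m: float) -> float:
    """Euphotic depth (m) estimated as 2.7 x the Secchi depth."""
    if secchi_m < 0:
        raise ValidationError(f"negative Secchi depth: {secchi_m}")
    return 2.7 * secchi_m


def community_weighted_mean(snapshot: CommunitySnapshot) -> float:
    """Community-weighted mean trait value, sum(q_i * z_i)."""
    if not snapshot.entries:
        raise ValidationError(f"snapshot {snapshot.date}: empty community")
    return float(sum(q * z for _, q, z in snapshot.entries))
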