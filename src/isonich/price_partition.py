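"""Price-equation partitioning of community trait change.

The change in a community-aggregated property z-bar = sum(q_i z_i) between
two snapshots is decomposed into three ecological processes:

* taxa sorting (TS) — shifts in relative abundance among the taxa shared
  by both snapshots,
* intrataxonomic variation (ITV) — within-taxon change of the trait value
  itself,
* taxa turnover (TT) — gain and loss of taxa between the snapshots.

The default pairing is the telescoping form

    TS  = sum_shared z_i (q_i' - q_i)
    ITV = sum_shared q_i' (z_i' - z_i)
    TT  = sum_gained q_i' z_i' - sum_lost q_i z_i

which sums exactly to the total change sum(q'z') - sum(qz).  An optional
three-term mode splits the shared-taxa change symmetrically into
TS = sum z_i dq_i, ITV = sum q_i dz_i and an abundance-trait covariation
term COV = sum dq_i dz_i; both modes conserve the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import spearmanr

from .core_io import CommunitySnapshot, EnvRecord, ValidationError


@dataclass(frozen=True)
class PricePartition:
    delta_total: float
    TS: float
    ITV: float
    TT: float
    COV: float | None = None           # populated only in three-term mode
    rel_TS: float | None = None        # percentages of |TS|+|ITV|(+|COV|)+|TT|
    rel_ITV: float | None = None
    rel_TT: float | None = None
    rel_COV: float | None = None
    degenerate: bool = False           # all components zero: shares undefined

    @property
    def components(self) -> dict[str, float]:
        out = {"TS": self.TS, "ITV": self.ITV, "TT": self.TT}
        if self.COV is not None:
            out["COV"] = self.COV
        return out


def _apply_rarity_threshold(
    snap: CommunitySnapshot, threshold: float
) -> dict[str, tuple[float, float]]:
    """Taxa at or below the rarity threshold are treated as absent (routed to TT)."""
    return {g: (q, z) for g, q, z in snap.entries if q > threshold}


def price_partition(
    c1: CommunitySnapshot,
    c2: CommunitySnapshot,
    mode: Literal["telescoping", "three_term"] = "telescoping",
    rarity_threshold: float = 0.0,
) -> PricePartition:
    """Partition the community change from snapshot c1 to c2.

    ``rarity_threshold`` > 0 routes taxa whose relative abundance does not
    exceed it to the turnover term (they are treated as absent from the
    shared set), mirroring analyses that fold rare taxa (< 3%) into
    turnover; off (0.0) by default.
    """
    d1 = _apply_rarity_threshold(c1, rarity_threshold)
    d2 = _apply_rarity_threshold(c2, rarity_threshold)
    for snap, d in ((c1, d1), (c2, d2)):
        for g, (q, z) in d.items():
            if q > 0 and not np.isfinite(z):
                raise ValidationError(f"snapshot {snap.date}: taxon {g} has no trait value")

    shared = sorted(set(d1) & set(d2))
    gained = sorted(set(d2) - set(d1))
    lost = sorted(set(d1) - set(d2))

    delta_total = sum(q * z for q, z in d2.values()) - sum(q * z for q, z in d1.values())

    if mode == "telescoping":
        ts = sum(d1[g][1] * (d2[g][0] - d1[g][0]) for g in shared)
        itv = sum(d2[g][0] * (d2[g][1] - d1[g][1]) for g in shared)
        cov = None
    elif mode == "three_term":
        ts = sum(d1[g][1] * (d2[g][0] - d1[g][0]) for g in shared)
        itv = sum(d1[g][0] * (d2[g][1] - d1[g][1]) for g in shared)
        cov = sum(
            (d2[g][0] - d1[g][0]) * (d2[g][1] - d1[g][1]) for g in shared
        )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    tt = sum(d2[g][0] * d2[g][1] for g in gained) - sum(
        d1[g][0] * d1[g][1] for g in lost
    )

    part = PricePartition(
        delta_total=float(delta_total),
        TS=float(ts),
        ITV=float(itv),
        TT=float(tt),
        COV=None if cov is None else float(cov),
    )
    return relative_contributions(part)


def relative_contributions(p: PricePartition) -> PricePartition:
    """Attach percentage contributions, rel_X = |X| / sum(|components|) * 100.

    Components may carry opposite signs, so shares use absolute
    magnitudes.  When every component is zero the shares are undefined and
    the partition is flagged degenerate.
    """
    comps = p.components
    total = sum(abs(v) for v in comps.values())
    if total == 0:
        return PricePartition(
            delta_total=p.delta_total, TS=p.TS, ITV=p.ITV, TT=p.TT, COV=p.COV,
            degenerate=True,
        )
    rel = {k: abs(v) / total * 100.0 for k, v in comps.items()}
    return PricePartition(
        delta_total=p.delta_total, TS=p.TS, ITV=p.ITV, TT=p.TT, COV=p.COV,
        rel_TS=rel["TS"], rel_ITV=rel["ITV"], rel_TT=rel["TT"],
        rel_COV=rel.get("COV"),
    )


def timeseries_partition(
    series: Sequence[CommunitySnapshot],
    mode: Literal["telescoping", "three_term"] = "telescoping",
    rarity_threshold: float = 0.0,
) -> list[PricePartition]:
    """Partition every consecutive pair of a date-ordered snapshot series."""
    if len(series) < 2:
        raise ValidationError("need >= 2 snapshots")
    dates = [s.date for s in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError("snapshot dates must be strictly increasing")
    return [
        price_partition(a, b, mode=mode, rarity_threshold=rarity_threshold)
        for a, b in zip(series, series[1:])
    ]


def link_contributions_env(
    partitions: Sequence[PricePartition],
    env: Sequence[EnvRecord],
) -> dict[tuple[str, str], dict[str, float | None]]:
    """Spearman correlation of component shares vs. environmental change.

    ``env`` must align with the snapshot series that produced
    ``partitions`` (one record per snapshot date); environmental deltas
    are taken over the same consecutive pairs.  Returns a mapping
    (component, variable) -> {rho, p, n}; cells with fewer than 4 usable
    pairs or a constant vector carry rho=None with a flag.
    """
    if len(env) != len(partitions) + 1:
        raise ValidationError(
            f"need {len(partitions) + 1} environmental records, got {len(env)}"
        )
    variables = sorted(set.intersection(*(set(r.variables) for r in env)))
    comp_series = {
        "rel_TS": np.array([p.rel_TS if not p.degenerate else np.nan for p in partitions]),
        "rel_ITV": np.array([p.rel_ITV if not p.degenerate else np.nan for p in partitions]),
        "rel_TT": np.array([p.rel_TT if not p.degenerate else np.nan for p in partitions]),
    }
    out: dict[tuple[str, str], dict[str, float | None]] = {}
    for var in variables:
        vals = np.array([r.variables[var] for r in env], dtype=float)
        dvals = np.diff(vals)
        for comp, cseries in comp_series.items():
            mask = np.isfinite(cseries) & np.isfinite(dvals)
            n = int(mask.sum())
            cell: dict[str, float | None] = {"n": n, "rho": None, "p": None,
                                             "insufficient": False}
            if n < 4:
                cell["insufficient"] = True
            else:
                a, b = cseries[mask], dvals[mask]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    cell["insufficient"] = True  # constant vector: rho undefined
                else:
                    rho, p = spearmanr(a, b)
                    cell["rho"], cell["p"] = float(rho), float(p)
            out[(comp, var)] = cell
    return out
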