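"""Domain types, file readers/writers, configuration and seeded RNG handling.

The package works on four kinds of tabular inputs: consumer isotope
replicates (one row per measured zooplankton sample), food-source isotope
summaries (mean/SD per isotope per particulate-organic-matter fraction),
community snapshots (per-date taxon relative abundance and trait value),
and environmental time series.  All dates are ISO-8601 text in files and
``datetime.date`` in memory.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("isonich")

#: The six taxonomic groups used by default throughout the package.
#: Cyclopidae are split by prosome length (small: 200-450 um, large: >=450 um).
DEFAULT_GROUPS: tuple[str, ...] = (
    "Bosmina",
    "Bosminopsis",
    "other_Cladocera",
    "small_Cyclopidae",
    "large_Cyclopidae",
    "Diaptomidae",
)


class SchemaError(ValueError):
    """A required column is missing or malformed in an input table."""


class ValidationError(ValueError):
    """An input value violates a documented precondition."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""

    def __init__(self, message: str, n: int | None = None):
        super().__init__(message)
        self.n = n


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeSample:
    """One consumer replicate: group, date, isotope values, elemental composition.

    d13C is per-mil vs VPDB; d15N per-mil vs air N2; c_percent / n_percent
    are % dry mass; cn_ratio is the (dimensionless) molar or mass C:N as
    supplied upstream.
    """

    sample_id: str
    group_id: str
    date: _dt.date
    d13C: float
    d15N: float
    c_percent: float | None = None
    n_percent: float | None = None
    cn_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d13C) and np.isfinite(self.d15N)):
            raise ValidationError(f"sample {self.sample_id}: non-finite isotope value")
        if self.cn_ratio is not None and self.cn_ratio <= 0:
            raise ValidationError(f"sample {self.sample_id}: cn_ratio must be > 0")


@dataclass(frozen=True)
class SourceSummary:
    """Per-source isotope mean/SD (e.g. pico/nano/micro-POM by layer)."""

    source_id: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.sd_d13C < 0 or self.sd_d15N < 0:
            raise ValidationError(f"source {self.source_id}: negative SD")
        if self.n < 1:
            raise ValidationError(f"source {self.source_id}: n must be >= 1")


@dataclass(frozen=True)
class TrophicEnrichment:
    """Trophic enrichment (fractionation) factors per isotope.

    Defaults are the widely used consumer-diet discrimination values:
    0.4 +/- 1.3 per-mil for d13C and 3.4 +/- 1.0 per-mil for d15N.
    """

    mean_d13C: float = 0.4
    sd_d13C: float = 1.3
    mean_d15N: float = 3.4
    sd_d15N: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_d13C < 0 or self.sd_d15N < 0:
            raise ValidationError("TEF SDs must be >= 0")


@dataclass(frozen=True)
class CommunitySnapshot:
    """Per-date community composition: (group_id, relative abundance q, trait z).

    q must be non-negative and sum to 1; ``period`` labels the hydrological
    regime ("mixing" or "stratification").
    """

    date: _dt.date
    period: str
    entries: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        qs = [q for _, q, _ in self.entries]
        if any(q < 0 for q in qs):
            raise ValidationError(f"snapshot {self.date}: negative abundance")
        if qs and abs(sum(qs) - 1.0) > 1e-9:
            raise ValidationError(
                f"snapshot {self.date}: abundances sum to {sum(qs)!r}, not 1"
            )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.entries)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {g: (q, z) for g, q, z in self.entries}


@dataclass(frozen=True)
class EnvRecord:
    """One date's environmental measurements (temperature, DO, pH, ...)."""

    date: _dt.date
    variables: Mapping[str, float]


@dataclass
class MCMCSettings:
    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 20
    chains: int = 4

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValidationError(
                f"iterations ({self.iterations}) must exceed burn_in ({self.burn_in})"
            )
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")


@dataclass
class Thresholds:
    source_contribution_cutoff: float = 0.12
    loading_cutoff: float = 0.7
    collinearity_cutoff: float = 0.7
    collinearity_p_cutoff: float = 0.05
    vif_cutoff: float = 10.0
    polygon_inclusion_cutoff: float = 0.05


@dataclass
class RunConfig:
    """Run-wide settings: seed, MCMC schedule, screening thresholds."""

    seed: int = 0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    thresholds: Thresholds = field(default_factory=Thresholds)
    groups: tuple[str, ...] = DEFAULT_GROUPS


# ---------------------------------------------------------------------------
# RNG handling
# ---------------------------------------------------------------------------


def rng_for(seed: int, *tags: str | int) -> np.random.Generator:
    """Derive an independent Generator from a base seed and stage tags.

    Every stochastic stage draws from its own stream so adding a stage
    never perturbs another stage's draws.
    """
    entropy = [int(seed)] + [
        t if isinstance(t, int) else int.from_bytes(t.encode(), "little") % (2**31)
        for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ISOTOPE_COLUMNS = {
    "sample_id": "sample_id",
    "group_id": "group_id",
    "date": "date",
    "d13C": "d13C",
    "d15N": "d15N",
    "c_percent": "c_percent",
    "n_percent": "n_percent",
    "cn_ratio": "cn_ratio",
}
_REQUIRED = ("sample_id", "group_id", "date", "d13C", "d15N")


def read_isotope_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[IsotopeSample]:
    """Read a consumer isotope CSV/TSV into IsotopeSample records.

    ``schema`` maps logical field names to column names in the file;
    unmapped fields default to their own name.  Rows with missing isotope
    values are skipped (the count is logged); a missing required column is
    a SchemaError naming the column.
    """
    path = Path(path)
    colmap = dict(_ISOTOPE_COLUMNS)
    if schema:
        colmap.update(schema)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for logical in _REQUIRED:
        if colmap[logical] not in df.columns:
            raise SchemaError(f"missing required column: {colmap[logical]!r}")

    samples: list[IsotopeSample] = []
    skipped = 0
    for i, row in df.iterrows():
        d13c, d15n = row[colmap["d13C"]], row[colmap["d15N"]]
        if pd.isna(pd.to_numeric(d13c, errors="coerce")) or pd.isna(
            pd.to_numeric(d15n, errors="coerce")
        ):
            skipped += 1
            continue
        try:
            date = _dt.date.fromisoformat(str(row[colmap["date"]]))
        except ValueError as exc:
            raise SchemaError(f"line {i + 2}: unparseable date {row[colmap['date']]!r}") from exc

        def _opt(logical: str) -> float | None:
            col = colmap[logical]
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        samples.append(
            IsotopeSample(
                sample_id=str(row[colmap["sample_id"]]),
                group_id=str(row[colmap["group_id"]]),
                date=date,
                d13C=float(d13c),
                d15N=float(d15n),
                c_percent=_opt("c_percent"),
                n_percent=_opt("n_percent"),
                cn_ratio=_opt("cn_ratio"),
            )
        )
    logger.info(
        "read_isotope_table path=%s rows=%d kept=%d skipped=%d",
        path, len(df), len(samples), skipped,
    )
    return samples


def read_source_table(path: str | Path) -> list[SourceSummary]:
    """Read a food-source summary CSV (source_id, mean/sd per isotope, n)."""
    df = pd.read_csv(path)
    for col in ("source_id", "mean_d13C", "sd_d13C", "mean_d15N", "sd_d15N"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    return [
        SourceSummary(
            source_id=str(r.source_id),
            mean_d13C=float(r.mean_d13C),
            sd_d13C=float(r.sd_d13C),
            mean_d15N=float(r.mean_d15N),
            sd_d15N=float(r.sd_d15N),
            n=int(getattr(r, "n", 1)),
        )
        for r in df.itertuples()
    ]


def read_snapshot_table(path: str | Path) -> list[CommunitySnapshot]:
    """Read community snapshots from a long CSV (date, period, group_id, q, z)."""
    df = pd.read_csv(path)
    for col in ("date", "period", "group_id", "q", "z"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    out = []
    for (date, period), sub in df.groupby(["date", "period"], sort=False):
        out.append(
            CommunitySnapshot(
                date=_dt.date.fromisoformat(str(date)),
                period=str(period),
                entries=tuple(
                    (str(r.group_id), float(r.q), float(r.z)) for r in sub.itertuples()
                ),
            )
        )
    out.sort(key=lambda s: s.date)
    return out


def read_env_table(path: str | Path) -> list[EnvRecord]:
    """Read an environmental time series CSV (date + one column per variable)."""
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise SchemaError("missing required column: 'date'")
    if df["date"].duplicated().any():
        raise ValidationError("duplicate dates in environmental series")
    records = []
    for _, row in df.iterrows():
        variables = {
            c: float(row[c]) for c in df.columns if c != "date" and not pd.isna(row[c])
        }
        records.append(EnvRecord(date=_dt.date.fromisoformat(str(row["date"])), variables=variables))
    records.sort(key=lambda r: r.date)
    return records


class _ResultEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, _dt.date):
            return o.isoformat()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_results(obj: Any, path: str | Path) -> None:
    """Write a result object to disk: DataFrames as CSV, everything else JSON.

    JSON output is round-trippable via :func:`read_results` for plain
    dataclasses, mappings and sequences.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        return
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_ResultEncoder, indent=2, allow_nan=True)


def read_results(path: str | Path) -> Any:
    """Read back a JSON result written by :func:`write_results`."""
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a RunConfig from YAML; absent keys take documented defaults.

    Defaults follow the standard schedule for the diet-mixing sampler:
    20,000 iterations, 2,000 burn-in, thinning interval 20.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    mcmc = MCMCSettings(**raw.get("mcmc", {}))
    thresholds = Thresholds(**raw.get("thresholds", {}))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        mcmc=mcmc,
        thresholds=thresholds,
        groups=tuple(raw.get("groups", DEFAULT_GROUPS)),
    )


def snapshots_to_frame(snaps: Iterable[CommunitySnapshot]) -> pd.DataFrame:
    """Flatten snapshots into a long DataFrame (date, period, group_id, q, z)."""
    rows = [
        {"date": s.date.isoformat(), "period": s.period, "group_id": g, "q": q, "z": z}
        for s in snaps
        for g, q, z in s.entries
    ]
    return pd.DataFrame(rows)


def env_to_frame(records: Sequence[EnvRecord]) -> pd.DataFrame:
    rows = [{"date": r.date.isoformat(), **r.variables} for r in records]
    return pd.DataFrame(rows)
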