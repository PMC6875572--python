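"""Partial least squares path modeling (PLS-PM) with reflective blocks.

Latent variables (e.g. "temperature", "nutrients", "physicochemistry",
"chlorophyll", "body size", "niche breadth") are estimated as weighted
composites of their indicator blocks by Lohmoller's alternating
outer/inner estimation; directed path coefficients among latents are then
ordinary least squares on the standardized latent scores.  All blocks are
reflective (mode A).  Model quality is summarized by per-endogenous R2,
per-block communality (mean squared loading) and the global
goodness-of-fit index GoF = sqrt(mean communality x mean R2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError, rng_for


@dataclass(frozen=True)
class PathModelSpec:
    """Blocks of indicators plus a directed acyclic inner model over latents."""

    blocks: Mapping[str, tuple[str, ...]]
    paths: tuple[tuple[str, str], ...]  # (source latent, target latent)
    scheme: Literal["centroid", "factorial", "path"] = "centroid"
    max_iter: int = 300
    tol: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", {k: tuple(v) for k, v in self.blocks.items()}
        )
        object.__setattr__(self, "paths", tuple((a, b) for a, b in self.paths))
        for name, cols in self.blocks.items():
            if not cols:
                raise ValidationError(f"block {name!r} is empty")
        for a, b in self.paths:
            if a not in self.blocks or b not in self.blocks:
                raise ValidationError(f"path {a}->{b} references an unknown block")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        order, seen, temp = [], set(), set()

        def visit(u: str) -> None:
            if u in seen:
                return
            if u in temp:
                raise ValidationError("inner path model contains a cycle")
            temp.add(u)
            for a, b in self.paths:
                if b == u:
                    visit(a)
            temp.discard(u)
            seen.add(u)
            order.append(u)

        for name in self.blocks:
            visit(name)
        return order

    def predecessors(self, latent: str) -> list[str]:
        return [a for a, b in self.paths if b == latent]

    def neighbours(self, latent: str) -> list[str]:
        return [b if a == latent else a for a, b in self.paths if latent in (a, b)]

    @property
    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]


@dataclass(frozen=True)
class PathModelResult:
    spec: PathModelSpec
    outer_weights: dict[str, np.ndarray]
    loadings: dict[str, dict[str, float]]            # block -> indicator -> loading
    scores: pd.DataFrame                             # samples x latents, unit variance
    path_coefficients: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    communality: dict[str, float]                    # per block
    gof: float
    n_iter: int
    bootstrap: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def edge_table(self, coefficient_display_cutoff: float = 0.0) -> pd.DataFrame:
        rows = []
        for (a, b), coef in self.path_coefficients.items():
            if abs(coef) < coefficient_display_cutoff:
                continue
            row = {"from": a, "to": b, "coefficient": coef}
            if (a, b) in self.bootstrap:
                row.update(self.bootstrap[(a, b)])
            rows.append(row)
        return pd.DataFrame(rows)


def _standardize(x: np.ndarray, names: Sequence[str]) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = names[int(np.argmax(sd == 0))]
        raise ValidationError(f"constant indicator: {bad!r}")
    return (x - mu) / sd


def fit_plspm(data: pd.DataFrame, spec: PathModelSpec) -> PathModelResult:
    """Fit the path model by alternating outer/inner estimation.

    Iterates until the largest outer-weight change is below ``spec.tol``.
    Latent scores are standardized to unit variance at every step and each
    latent is oriented so that its mean loading is positive, which makes
    the result deterministic given (data, spec).
    """
    data = data.dropna()
    n = len(data)
    blocks = list(spec.blocks)
    xs = {
        b: _standardize(data[list(spec.blocks[b])].to_numpy(dtype=float), spec.blocks[b])
        for b in blocks
    }
    weights = {b: np.ones(len(spec.blocks[b])) for b in blocks}

    def scores_from(w: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for b in blocks:
            y = xs[b] @ w[b]
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"degenerate latent score for block {b!r}")
            out[b] = y / sd
        return out

    y = scores_from(weights)
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        # inner approximation
        z = {}
        for b in blocks:
            nb = spec.neighbours(b)
            if not nb:
                z[b] = y[b]
                continue
            if spec.scheme == "centroid":
                e = {c: np.sign(np.corrcoef(y[b], y[c])[0, 1]) for c in nb}
            elif spec.scheme == "factorial":
                e = {c: np.corrcoef(y[b], y[c])[0, 1] for c in nb}
            else:  # path scheme
                preds = spec.predecessors(b)
                e = {}
                if preds:
                    xp = np.column_stack([y[c] for c in preds])
                    beta, *_ = np.linalg.lstsq(xp, y[b], rcond=None)
                    e.update(dict(zip(preds, beta)))
                for c in nb:
                    if c not in e:  # successors weighted by correlation
                        e[c] = np.corrcoef(y[b], y[c])[0, 1]
            z[b] = sum(e[c] * y[c] for c in nb)
        # outer update, mode A: weight_j proportional to cov(x_j, inner estimate)
        new_weights = {}
        for b in blocks:
            w = xs[b].T @ z[b] / (n - 1)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValidationError(f"all-zero outer weights for block {b!r}")
            new_weights[b] = w / norm
        delta = max(
            float(np.max(np.abs(new_weights[b] - weights[b]))) for b in blocks
        )
        weights = new_weights
        y = scores_from(weights)
        if delta < spec.tol:
            break
    else:
        raise ValidationError(
            f"PLS-PM did not converge in {spec.max_iter} iterations (last delta={delta:.3g})"
        )

    # orient each latent so its mean loading is positive
    loadings: dict[str, dict[str, float]] = {}
    for b in blocks:
        load = xs[b].T @ y[b] / (n - 1)
        if load.mean() < 0:
            weights[b] = -weights[b]
            y[b] = -y[b]
            load = -load
        loadings[b] = dict(zip(spec.blocks[b], map(float, load)))

    scores = pd.DataFrame({b: y[b] for b in blocks}, index=data.index)

    path_coefficients: dict[tuple[str, str], float] = {}
    r_squared: dict[str, float] = {}
    for b in spec.endogenous:
        preds = spec.predecessors(b)
        xp = np.column_stack([y[c] for c in preds])
        beta, *_ = np.linalg.lstsq(xp, y[b], rcond=None)
        fitted = xp @ beta
        r_squared[b] = float(1.0 - np.sum((y[b] - fitted) ** 2) / np.sum(y[b] ** 2))
        for c, coef in zip(preds, beta):
            path_coefficients[(c, b)] = float(coef)

    communality = {
        b: float(np.mean([v**2 for v in loadings[b].values()])) for b in blocks
    }
    all_sq_loadings = [v**2 for b in blocks for v in loadings[b].values()]
    mean_r2 = float(np.mean(list(r_squared.values()))) if r_squared else 0.0
    gof = float(np.sqrt(np.mean(all_sq_loadings) * mean_r2))

    return PathModelResult(
        spec=spec,
        outer_weights=weights,
        loadings=loadings,
        scores=scores,
        path_coefficients=path_coefficients,
        r_squared=r_squared,
        communality=communality,
        gof=gof,
        n_iter=n_iter,
    )


def prune_and_refit(
    data: pd.DataFrame, spec: PathModelSpec, loading_cutoff: float = 0.7
) -> tuple[PathModelResult, list[str]]:
    """Drop indicators with |loading| < cutoff from an initial fit, then refit.

    Blocks emptied by the pruning are removed from the inner model (with
    their edges); pruning an endogenous terminal block down to nothing is
    an error because the model would lose its response.
    """
    initial = fit_plspm(data, spec)
    dropped = [
        ind
        for b, loads in initial.loadings.items()
        for ind, l in loads.items()
        if abs(l) < loading_cutoff
    ]
    if not dropped:
        return initial, []
    new_blocks = {
        b: tuple(i for i in cols if i not in dropped)
        for b, cols in spec.blocks.items()
    }
    emptied = {b for b, cols in new_blocks.items() if not cols}
    terminal = {b for b in spec.blocks
                if spec.predecessors(b) and not any(a == b for a, _ in spec.paths)}
    if emptied & terminal:
        raise ValidationError(
            f"pruning removed every indicator of terminal block(s) {sorted(emptied & terminal)}"
        )
    new_paths = tuple(
        (a, b) for a, b in spec.paths if a not in emptied and b not in emptied
    )
    new_spec = replace(
        spec,
        blocks={b: cols for b, cols in new_blocks.items() if cols},
        paths=new_paths,
    )
    return fit_plspm(data, new_spec), dropped


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.10,
) -> dict[tuple[str, str], dict[str, float]]:
    """Bootstrap CIs and two-sided p-values for every path coefficient.

    Rows are resampled with replacement ``n_boot`` times and the model is
    refit on each resample; percentile (1 - alpha) CIs and a two-sided
    sign-based p-value are reported per path, with a significance flag at
    the given alpha (default 0.10).  Raises if more than 5% of resamples
    fail to fit.
    """
    point = fit_plspm(data, spec)
    rng = rng_for(seed, "plspm_bootstrap")
    draws: dict[tuple[str, str], list[float]] = {k: [] for k in point.path_coefficients}
    failures = 0
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = fit_plspm(data.iloc[idx].reset_index(drop=True), spec)
        except (ValidationError, np.linalg.LinAlgError):
            failures += 1
            continue
        for k in draws:
            draws[k].append(res.path_coefficients[k])
    if failures > 0.05 * n_boot:
        raise ValidationError(
            f"bootstrap failure rate {failures / n_boot:.1%} exceeds 5%"
        )
    out: dict[tuple[str, str], dict[str, float]] = {}
    for k, vals in draws.items():
        arr = np.array(vals)
        lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        frac_neg = float(np.mean(arr <= 0))
        frac_pos = float(np.mean(arr >= 0))
        p = min(1.0, 2 * min(frac_neg, frac_pos) + 2.0 / (len(arr) + 1))
        out[k] = {
            "coefficient": point.path_coefficients[k],
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": p,
            "significant": float(p < alpha),
        }
    return out
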