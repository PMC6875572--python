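"""Environment-side statistics.

One-factor PERMANOVA for testing multivariate environmental differences
between hydrological periods, plus the two predictor-screening steps used
before ordination/path modelling: greedy Spearman collinearity pruning
(|rho| > 0.7, p < 0.05) and iterative variance-inflation-factor filtering
(VIF < 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_io import ValidationError, logger, rng_for


@dataclass(frozen=True)
class PermanovaResult:
    r_squared: float      # SS_between / SS_total
    residual_r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _ss_within(d2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squared distances, sum over groups of SS_g / n_g."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss


def permanova_one_factor(
    data: np.ndarray,
    grouping: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> PermanovaResult:
    """Permutational MANOVA of a samples x variables matrix against one factor.

    Computes the Euclidean distance matrix (after optional per-column
    z-scoring), partitions the total sum of squared distances into
    between- and within-group parts, and derives the pseudo-F statistic

        F = (SS_between / (g - 1)) / (SS_within / (n - g)).

    The p-value is the fraction of label permutations (plus the observed
    labelling) with pseudo-F at least as large as observed.
    """
    data = np.asarray(data, dtype=float)
    grouping = np.asarray(grouping)
    groups = np.unique(grouping)
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if n_perm < 99:
        raise ValidationError("need >= 99 permutations")
    n, g = data.shape[0], len(groups)
    if standardize:
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd
    diff = data[:, None, :] - data[None, :, :]
    d2 = (diff**2).sum(-1)

    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    labels = grouping.copy()

    def pseudo_f(lab: np.ndarray) -> tuple[float, float]:
        ssw = _ss_within(d2, lab)
        ssb = ss_total - ssw
        return (ssb / (g - 1)) / (ssw / (n - g)) if ssw > 0 else np.inf, ssb

    f_obs, ssb_obs = pseudo_f(labels)
    rng = rng_for(seed, "permanova")
    count = 0
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(labels))
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    r2 = ssb_obs / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        r_squared=float(r2),
        residual_r_squared=float(1.0 - r2),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
    )


def permanova_table(
    df: pd.DataFrame, grouping: np.ndarray, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Marginal one-variable PERMANOVA per column (a per-variable R2/p table)."""
    rows = []
    for i, col in enumerate(df.columns):
        res = permanova_one_factor(
            df[[col]].to_numpy(), grouping, n_perm=n_perm, seed=seed + i
        )
        rows.append({"variable": col, "R2": res.r_squared, "p": res.p_value})
    return pd.DataFrame(rows)


def collinearity_prune(
    df: pd.DataFrame, rho_cutoff: float = 0.7, p_cutoff: float = 0.05
) -> tuple[list[str], dict[str, str]]:
    """Greedy Spearman collinearity pruning in column order.

    Columns are scanned in the DataFrame's order; a column is dropped when
    it correlates with an already-retained column at |rho| > rho_cutoff
    with p < p_cutoff.  Returns the retained columns and a map of each
    dropped column to the retained partner that triggered the drop.
    """
    if df.shape[1] < 2:
        raise ValidationError("need >= 2 variables")
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for col in df.columns:
        partner = None
        for kept in retained:
            rho, p = spearmanr(df[col], df[kept])
            if abs(rho) > rho_cutoff and p < p_cutoff:
                partner = kept
                break
        if partner is None:
            retained.append(col)
        else:
            dropped[col] = partner
    if len(retained) == 1:
        logger.warning("collinearity_prune: all variables mutually collinear; one survivor")
    logger.info("collinearity_prune retained=%d dropped=%d", len(retained), len(dropped))
    return retained, dropped


def vif(df: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R2_j).

    R2_j is from the OLS regression (with intercept) of column j on all
    other columns.  A single column has VIF 1 by convention; perfect
    multicollinearity yields inf.
    """
    x = df.to_numpy(dtype=float)
    n, k = x.shape
    out = {}
    for j, col in enumerate(df.columns):
        if k == 1:
            out[col] = 1.0
            continue
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(df: pd.DataFrame, cutoff: float = 10.0) -> tuple[list[str], pd.Series]:
    """Iteratively drop the largest-VIF column until every VIF < cutoff.

    Infinite VIFs (perfect multicollinearity) are dropped first.  Returns
    the retained columns and their final VIFs.
    """
    work = df.copy()
    while work.shape[1] > 1:
        v = vif(work)
        worst = v.idxmax()
        if v[worst] < cutoff:
            break
        work = work.drop(columns=[worst])
        logger.info("vif_filter dropped=%s vif=%.3g", worst, v[worst])
    return list(work.columns), vif(work)
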