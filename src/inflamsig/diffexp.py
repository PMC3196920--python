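"""Two-group differential expression for log2 expression matrices.

The test statistic is a plain two-sided two-sample t (pooled-variance
Student's t by default, Welch optional), corrected for multiple testing
with Storey q-values.  The fold-change significance threshold is not a
fixed constant but is calibrated on a panel of housekeeping genes: the
threshold is the smallest fold change that none of the housekeeping genes
exceeds in the same comparison, i.e. the maximum housekeeping fold change.
A gene is called differentially expressed when its q-value falls below the
FDR target *and* its fold change strictly exceeds the calibrated
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .io import ExpressionMatrix, GeneList, bundled_housekeeping_list

#: Column order of a differential-expression result table.
RESULT_COLUMNS = [
    "gene",
    "mean_a",
    "mean_b",
    "log_ratio",
    "fold_change",
    "direction",
    "t_stat",
    "p_value",
    "q_value",
    "call",
]


@dataclass
class DiffExpConfig:
    """Knobs of the differential-expression caller.

    q_threshold
        FDR target; a gene must have q below this to be called (default
        0.01, i.e. 1% false discovery rate).
    housekeeping_genes
        Panel used to calibrate the fold-change threshold; defaults to 14
        ribosomal/constitutive genes.
    t_variant
        ``"pooled"`` (Student) or ``"welch"``.
    fc_threshold_override
        Skip calibration and use this linear fold-change threshold.
    """

    q_threshold: float = 0.01
    housekeeping_genes: GeneList = field(default_factory=bundled_housekeeping_list)
    t_variant: str = "pooled"
    fc_threshold_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t variant {self.t_variant!r}")
        if self.fc_threshold_override is None and len(self.housekeeping_genes) == 0:
            raise ValueError("housekeeping list empty and no fc_threshold_override given")


def two_group_t(values_a, values_b, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test from the defining formulas.

    Degenerate case: when both groups have zero variance and equal means
    the statistic is 0 and p = 1 by convention; zero variance with
    unequal means gives p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = _t_matrix(a[None, :], b[None, :], variant)
    return float(t[0]), float(p[0])


def _t_matrix(a: np.ndarray, b: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t over (genes × samples) blocks."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, n1 + n2 - 2)
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    else:
        raise ValueError(f"unknown t variant {variant!r}")

    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero variance in both groups: equal means -> (0, 1); unequal -> (inf, 0)
    degenerate = se == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, p


def log_ratio_to_fc(log_ratio: float) -> tuple[float, str | None]:
    """Convert a log2 group-mean difference to (linear fold change, direction).

    Fold change is the magnitude ``2**|log_ratio|`` (always >= 1);
    direction is ``"up"``/``"down"`` by the sign of the log ratio, and
    ``None`` for a zero ratio.
    """
    lr = float(log_ratio)
    if not np.isfinite(lr):
        raise ValueError("log ratio must be finite")
    fc = float(2.0 ** abs(lr))
    direction = "up" if lr > 0 else ("down" if lr < 0 else None)
    return fc, direction


def qvalues(p_values, *, lambda_grid: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with spline-smoothed pi0 estimation.

    pi0 (the proportion of true nulls) is estimated as
    ``#{p > lambda} / (m (1 - lambda))`` on a lambda grid
    ``0, 0.05, ..., 0.90``, smoothed by a cubic smoothing spline and read
    off at the largest lambda, then clipped to (0, 1].  The q-value of a
    p-value is the minimum estimated FDR over all rejection thresholds at
    least as large:  ``q(i) = min_{p(j) >= p(i)} pi0 * m * p(j) / rank(j)``.
    The mapping p -> q is monotone and permutation-equivariant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need a 1-d vector of at least 2 p-values")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size

    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)
    pi0_hat = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid]
    )
    if np.all(pi0_hat == pi0_hat[0]):
        pi0 = pi0_hat[0]
    else:
        # cubic smoothing spline (~3 effective df), evaluated at max(lambda)
        spl = interpolate.UnivariateSpline(lambda_grid, pi0_hat, k=3)
        pi0 = float(spl(lambda_grid[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    fdr = pi0 * m * ranked / ranks
    # running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def estimate_pi0(p_values, *, lambda_grid: np.ndarray | None = None) -> float:
    """The spline-smoothed null-proportion estimate used by :func:`qvalues`."""
    p = np.asarray(p_values, dtype=float)
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9001, 0.05)
    pi0_hat = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid])
    if np.all(pi0_hat == pi0_hat[0]):
        pi0 = pi0_hat[0]
    else:
        spl = interpolate.UnivariateSpline(lambda_grid, pi0_hat, k=3)
        pi0 = float(spl(lambda_grid[-1]))
    return min(max(pi0, 1.0 / p.size), 1.0)


def housekeeping_threshold(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    housekeeping: GeneList | None = None,
) -> float:
    """Calibrate the fold-change threshold on housekeeping genes.

    Returns the maximum ``2**|log ratio|`` over the housekeeping genes
    found in the matrix — the lowest fold change not exceeded by any of
    them.  Differential calls must *strictly* exceed this value.
    Housekeeping genes missing from the matrix are skipped with a
    warning; finding none is a hard error.
    """
    if housekeeping is None:
        housekeeping = bundled_housekeeping_list()
    cols_a = expr.samples_in_group(group_a)
    cols_b = expr.samples_in_group(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    found = [g for g in housekeeping if g in expr.data.index]
    if not found:
        raise ValueError(
            f"none of the housekeeping genes found in matrix: {list(housekeeping)}"
        )
    if len(found) < len(housekeeping):
        missing = sorted(set(housekeeping) - set(found))
        warnings.warn(f"housekeeping genes not in matrix, skipped: {missing}", stacklevel=2)
    lr = (
        expr.data.loc[found, cols_a].mean(axis=1)
        - expr.data.loc[found, cols_b].mean(axis=1)
    )
    return float(np.max(2.0 ** np.abs(lr.to_numpy())))


def call_differential(
    results: pd.DataFrame, config: DiffExpConfig, fc_threshold: float
) -> pd.DataFrame:
    """Set the up/down/unchanged call on a result table.

    A gene is ``up`` when q < q_threshold, fold change strictly exceeds
    the threshold, and the log ratio is positive; ``down`` symmetrically;
    otherwise ``unchanged``.
    """
    out = results.copy()
    sig = (out["q_value"] < config.q_threshold) & (out["fold_change"] > fc_threshold)
    out["call"] = "unchanged"
    out.loc[sig & (out["direction"] == "up"), "call"] = "up"
    out.loc[sig & (out["direction"] == "down"), "call"] = "down"
    return out


def diffexp_table(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    config: DiffExpConfig | None = None,
    *,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """Full per-gene differential expression between two sample groups.

    Computes, per gene: group means, log ratio (mean_a − mean_b on the
    log2 scale), linear fold change, t statistic, p, Storey q, and the
    up/down/unchanged call against the housekeeping-calibrated (or
    overridden) fold-change threshold.  Returns a DataFrame with
    :data:`RESULT_COLUMNS`; the threshold used is stored in
    ``df.attrs["fc_threshold"]``.
    """
    config = config or DiffExpConfig()
    cols_a = expr.samples_in_group(group_a)
    cols_b = expr.samples_in_group(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    a = expr.data[cols_a].to_numpy()
    b = expr.data[cols_b].to_numpy()
    t, p = _t_matrix(a, b, config.t_variant)
    lr = a.mean(axis=1) - b.mean(axis=1)
    q = qvalues(p)

    res = pd.DataFrame(
        {
            "gene": expr.data.index,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "log_ratio": lr,
            "fold_change": 2.0 ** np.abs(lr),
            "direction": np.where(lr > 0, "up", np.where(lr < 0, "down", "")),
            "t_stat": t,
            "p_value": p,
            "q_value": q,
        }
    )
    if fc_threshold is None:
        if config.fc_threshold_override is not None:
            fc_threshold = config.fc_threshold_override
        else:
            fc_threshold = housekeeping_threshold(
                expr, group_a, group_b, config.housekeeping_genes
            )
    res = call_differential(res, config, fc_threshold)
    res.attrs["fc_threshold"] = fc_threshold
    res.attrs["comparison"] = (group_a, group_b)
    return res[RESULT_COLUMNS]


def write_results(results: pd.DataFrame, path) -> None:
    """Write a result table as TSV mirroring the published column layout."""
    results.to_csv(path, sep="\t", index=False)
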