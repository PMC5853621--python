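"""Group-level inference on metric tables.

Metric tables are tidy DataFrames with columns ``subject``, ``state``,
``metric``, ``value`` (one row per subject x state x metric), optionally
joined with per-subject covariates (``sex`` as a binary indicator, ``age``
in years).  Paired tests compare the two states of each subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "paired_t",
    "paired_permutation",
    "ks_normality",
    "fdr_adjust",
    "anova_two_way_repeated",
    "adjusted_correlation",
    "delta_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """A single statistical test outcome."""

    statistic: float
    p: float
    method: str
    n: int
    df: float | tuple[float, float] | None = None
    p_fdr: float | None = None
    extra: dict | None = None


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Classical paired t test on a - b differences (two-sided)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 3:
        raise ValueError("paired t needs n >= 3")
    d = a - b
    if np.allclose(d, 0):
        raise ValueError("all paired differences are zero")
    t, p = stats.ttest_rel(a, b)
    return TestResult(statistic=float(t), p=float(p), method="paired_t", n=n,
                      df=n - 1)


def paired_permutation(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Sign-flipping permutation test of the mean paired difference.

    Two-sided p with the add-one correction
    ``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``, so the smallest
    attainable p is ``1/(n_perm + 1)``.  Deterministic given ``seed``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 5:
        raise ValueError("paired permutation needs n >= 5")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d = a - b
    observed = d.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = (signs * d).mean(axis=1)
    p = (1 + np.count_nonzero(np.abs(null) >= abs(observed))) / (1 + n_perm)
    return TestResult(
        statistic=float(observed), p=float(p), method="paired_permutation",
        n=n, extra={"n_perm": n_perm},
    )


def ks_normality(values: np.ndarray) -> TestResult:
    """Composite normality check (Kolmogorov-Smirnov with estimated
    parameters, Lilliefors-calibrated p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("normality check needs n >= 5")
    if x.std() == 0:
        raise ValueError("zero-variance sample")
    stat, p = lilliefors(x, dist="norm")
    return TestResult(statistic=float(stat), p=float(p),
                      method="ks_normality", n=x.size)


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a fixed-lambda pi0 estimate."""
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / ((1 - lam) * m)) if m > 1 else 1.0
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = prev
    return q


def fdr_adjust(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-comparison adjustment: BH step-up or Storey q-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError("method must be 'bh' or 'storey'")


def anova_two_way_repeated(
    table: np.ndarray, reps: int
) -> dict[str, TestResult]:
    """Balanced two-way ANOVA with replication on a two-column design.

    ``table`` stacks the two region-class columns (e.g. Act and L-Act
    fractional modularity) over subject x state rows; consecutive groups of
    ``reps`` rows form the blocks of the other factor.  Returns the F tests
    for the column factor (region class) and the block x column interaction.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("table must have >= 2 columns")
    n_rows, n_cols = x.shape
    if reps < 2 or n_rows % reps:
        raise ValueError("reps must be >= 2 and divide the row count")
    n_blocks = n_rows // reps
    cells = x.reshape(n_blocks, reps, n_cols)  # block x replicate x column
    grand = x.mean()
    col_means = x.mean(axis=0)
    block_means = cells.mean(axis=(1, 2))
    cell_means = cells.mean(axis=1)  # block x column
    ss_col = n_rows * ((col_means - grand) ** 2).sum()
    ss_block = reps * n_cols * ((block_means - grand) ** 2).sum()
    ss_cells = reps * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_col - ss_block
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cells
    df_col = n_cols - 1
    df_block = n_blocks - 1
    df_inter = df_col * df_block
    df_err = n_blocks * n_cols * (reps - 1)
    if df_err < 1:
        raise ValueError("no error degrees of freedom (need reps >= 2)")
    ms_err = ss_err / df_err
    f_col = (ss_col / df_col) / ms_err
    out = {
        "column": TestResult(
            statistic=float(f_col),
            p=float(stats.f.sf(f_col, df_col, df_err)),
            method="anova2_column", n=x.size, df=(df_col, df_err),
        ),
    }
    if df_inter > 0:
        f_int = (ss_inter / df_inter) / ms_err
        out["interaction"] = TestResult(
            statistic=float(f_int),
            p=float(stats.f.sf(f_int, df_inter, df_err)),
            method="anova2_interaction", n=x.size, df=(df_inter, df_err),
        )
    return out


def adjusted_correlation(
    x: np.ndarray, y: np.ndarray, confounds: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation after removing confound contributions.

    Both vectors are residualised on ``[intercept | confounds]`` by OLS;
    the correlation of the residuals is tested with ``n - 2 - C`` degrees
    of freedom.  Rank-deficient confound columns are dropped with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if confounds is None or np.size(confounds) == 0:
        design = np.ones((n, 1))
        n_conf = 0
    else:
        conf = np.atleast_2d(np.asarray(confounds, dtype=float))
        if conf.shape[0] != n:
            conf = conf.T
        design = np.column_stack([np.ones(n), conf])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            logger.warning("rank-deficient confounds; dropping dependent columns")
            q, r = np.linalg.qr(design)
            keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r).max()
            design = design[:, keep]
        n_conf = design.shape[1] - 1
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    # a variable fully explained by the confounds has nothing left to correlate
    if rx.std() <= 1e-12 * max(x.std(), 1e-300) or ry.std() <= 1e-12 * max(
        y.std(), 1e-300
    ):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - n_conf
    if df < 1:
        raise ValueError("not enough observations for the adjusted correlation")
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_c * np.sqrt(df / (1 - r_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def delta_metrics(
    table: pd.DataFrame, task: str, rest: str = "rest"
) -> pd.DataFrame:
    """Per-subject task-minus-rest change scores for every metric.

    Subjects missing either state are dropped with a warning.  Returns a
    wide frame indexed by subject with one column per metric.
    """
    required = {"subject", "state", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"metric table needs columns {sorted(required)}")
    wide = table.pivot_table(
        index="subject", columns=["state", "metric"], values="value"
    )
    if task not in wide.columns.get_level_values(0):
        raise ValueError(f"state {task!r} not present in table")
    task_w, rest_w = wide[task], wide[rest]
    complete = task_w.notna().all(axis=1) & rest_w.notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d subject(s) without both states", (~complete).sum()
        )
    return (task_w - rest_w).loc[complete]
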