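"""Differential-expression calling for two-group expression matrices.

Two statistical routes are provided, matching common microarray practice:

* ``anova`` — per-gene one-way fixed-effects ANOVA (equivalent, for two
  groups, to the pooled-variance t test: F = t^2), thresholded on the raw
  p-value.
* ``fisher_bh`` — each gene is dichotomized at its overall median and the
  resulting 2x2 group-by-(above/below) table is tested with a two-sided
  Fisher exact test; p-values are Benjamini-Hochberg adjusted and the
  adjusted value is thresholded.

The median-split construction of the Fisher route is an interpretation:
callers with their own per-gene 2x2 tables can use
:func:`fisher_exact_two_sided` directly. Ties at the median fall in the
"below-or-equal" cell. Direction (up/down) is always taken from the sign of
(case mean - control mean), for both routes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")

#: Relative tolerance for the "pmf <= observed pmf" comparison in the
#: two-sided Fisher test; guards against float noise when enumerating
#: hypergeometric probabilities that are mathematically equal.
FISHER_REL_TOL = 1e-7

DEG_COLUMNS = ["gene", "direction", "p_value", "p_adjusted", "source"]


@dataclass
class GeneExpressionMatrix:
    """A normalized log-scale expression matrix with two-group labels.

    Parameters
    ----------
    values
        genes x samples DataFrame of log-scale expression values.
    sample_groups
        Mapping (Series or dict) sample id -> ``"case"`` / ``"control"``.
    platform_id
        Free-text label for the measurement platform.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    platform_id: str = "platform0"

    def __post_init__(self) -> None:
        if not isinstance(self.sample_groups, pd.Series):
            self.sample_groups = pd.Series(self.sample_groups)
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        bad = set(self.sample_groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.sample_groups == g).sum() == 0:
                raise ValueError(f"group {g!r} has no samples")
        if self.values.isna().any().any():
            raise ValueError(
                "expression matrix contains missing values; filter or drop "
                "incomplete genes before loading"
            )

    @property
    def case_columns(self) -> list:
        return list(self.sample_groups.index[self.sample_groups == "case"])

    @property
    def control_columns(self) -> list:
        return list(self.sample_groups.index[self.sample_groups == "control"])

    def to_tsv(self, values_path, groups_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene", float_format="%.10g")
        pd.DataFrame(
            {"sample": self.sample_groups.index, "group": self.sample_groups.values}
        ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path, groups_path, platform_id: str = "platform0"):
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t")
        sample_groups = pd.Series(groups["group"].values, index=groups["sample"].values)
        return cls(values=values, sample_groups=sample_groups, platform_id=platform_id)


def anova_pvalue(case_values, control_values) -> tuple[float, float]:
    """One-way fixed-effects ANOVA for two groups.

    Returns ``(F, p)`` with p from the upper tail of F(1, n-2). For two
    groups F equals the square of the pooled-variance t statistic.
    Degenerate inputs: both groups constant and equal -> ``(0.0, 1.0)``
    with a warning; both constant and different -> ``(inf, 0.0)``.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 values")
    F, p = _anova_arrays(case[None, :], control[None, :])
    return float(F[0]), float(p[0])


def _anova_arrays(case: np.ndarray, control: np.ndarray):
    """Vectorized two-group one-way ANOVA over rows (genes)."""
    n1, n2 = case.shape[1], control.shape[1]
    n = n1 + n2
    m1 = case.mean(axis=1)
    m2 = control.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((case - m1[:, None]) ** 2).sum(axis=1) + ((control - m2[:, None]) ** 2).sum(axis=1)
    df_w = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / df_w)
    p = np.empty_like(F)
    regular = ssw > 0
    p[regular] = stats.f.sf(F[regular], 1, df_w)
    # Both groups constant: F is 0/0 (equal means -> no evidence, p=1) or
    # x/0 (different means -> p -> 0 in the limit).
    degenerate = ~regular
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero within-group variance",
            RuntimeWarning,
            stacklevel=3,
        )
        equal = degenerate & (ssb == 0)
        F[equal] = 0.0
        p[equal] = 1.0
        diff = degenerate & (ssb > 0)
        F[diff] = np.inf
        p[diff] = 0.0
    return F, p


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test for the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums hypergeometric probabilities, over all
    tables with the observed margins, of tables whose probability does not
    exceed the observed table's (relative tolerance ``FISHER_REL_TOL``).
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(row1 + 1)
        - gammaln(support + 1)
        - gammaln(row1 - support + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - support + 1)
        - gammaln(n - row1 - col1 + support + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()  # exact unit mass; cancels accumulated float error
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1 + FISHER_REL_TOL)].sum()
    return float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, p_(i) is multiplied by m/i, monotonicity is enforced
    by a cumulative minimum from the largest rank, and values are capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


def min_p_across_platforms(tables) -> dict:
    """Merge per-platform gene -> p maps by taking the minimum per gene."""
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    merged: dict = {}
    for table in tables:
        for gene, p in table.items():
            if gene not in merged or p < merged[gene]:
                merged[gene] = p
    return merged


@dataclass
class DECallResult:
    """DEG table plus per-run bookkeeping counts."""

    table: pd.DataFrame
    n_tested: int
    n_degenerate: int = 0


def gene_pvalues(matrix: GeneExpressionMatrix, route: str = "anova") -> pd.Series:
    """Raw per-gene p-values for one route (used for platform merging)."""
    p, _, _ = _route_pvalues(matrix, route)
    return pd.Series(p, index=matrix.values.index)


def _route_pvalues(matrix: GeneExpressionMatrix, route: str):
    case = matrix.values[matrix.case_columns].to_numpy(dtype=float)
    control = matrix.values[matrix.control_columns].to_numpy(dtype=float)
    constant = np.ptp(np.hstack([case, control]), axis=1) == 0
    if route == "anova":
        _, p = _anova_arrays(case, control)
    elif route == "fisher_bh":
        values = np.hstack([case, control])
        medians = np.median(values, axis=1)
        # ties at the median count as "below-or-equal"
        ca = (case > medians[:, None]).sum(axis=1)
        cb = case.shape[1] - ca
        cc = (control > medians[:, None]).sum(axis=1)
        cd = control.shape[1] - cc
        p = np.array(
            [fisher_exact_two_sided(a, b, c, d) for a, b, c, d in zip(ca, cb, cc, cd)]
        )
    else:
        raise ValueError(f"unknown route {route!r}")
    p[constant] = 1.0  # constant genes can never be called
    direction = np.where(case.mean(axis=1) > control.mean(axis=1), "up", "down")
    return p, direction, constant


def call_degs(
    matrix: GeneExpressionMatrix,
    alpha: float = 0.05,
    route: str = "anova",
    p_override: pd.Series | None = None,
) -> DECallResult:
    """Call differentially expressed genes.

    The anova route thresholds the raw p-value at ``alpha``; the fisher_bh
    route thresholds the BH-adjusted p-value. ``p_override`` substitutes
    externally merged raw p-values (e.g. cross-platform minima) while
    directions are still read from this matrix.
    """
    p, direction, constant = _route_pvalues(matrix, route)
    if p_override is not None:
        p = p_override.loc[matrix.values.index].to_numpy(dtype=float)
    n_degenerate = int(constant.sum())
    if n_degenerate:
        logger.warning("%d constant gene(s) reported as non-significant", n_degenerate)
    p_adj = bh_adjust(np.clip(p, 1e-300, 1.0))
    called = (p_adj < alpha) if route == "fisher_bh" else (p < alpha)
    called &= ~constant
    table = pd.DataFrame(
        {
            "gene": matrix.values.index[called],
            "direction": direction[called],
            "p_value": p[called],
            "p_adjusted": p_adj[called],
            "source": "fisher" if route == "fisher_bh" else "anova",
        }
    ).sort_values(["p_value", "gene"], kind="stable", ignore_index=True)
    return DECallResult(table=table, n_tested=len(p), n_degenerate=n_degenerate)


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return table
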