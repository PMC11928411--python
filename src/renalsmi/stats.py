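"""Two-group small-n cohort statistics.

The analysis pipeline mirrors how small animal cohorts are analyzed in
practice: Shapiro-Wilk normality gating, natural-log transforms for the
skewed congestion variables, the exact Mann-Whitney test for two-group
comparisons (raw values; ranks are invariant under monotone transforms, so
the log policy cannot change these p-values), Pearson correlation on the
(possibly log) scale, and mean +- standard error reporting (SE = SD/sqrt(n)).

With 5 vs 9 subjects the exact Mann-Whitney null distribution has
C(14,5) = 2002 equally likely rank assignments, so the smallest two-sided
p-value is 2/2002 ~ 0.001 - only an exact (enumeration-based) test can
print it, which is why the exact method is the default in this regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

GROUPS = ("control", "HF")

#: right-skewed congestion variables conventionally log-transformed
DEFAULT_LOG_VARIABLES = ("cvp", "rmp", "ttp_medulla", "edema")

#: canonical per-subject columns (besides id/group)
COHORT_VARIABLES = (
    "cvp",
    "rmp",
    "ttp_cortex",
    "ttp_medulla",
    "irpi_interlobular",
    "irpi_interlobar",
    "irpi_combined",
    "edema",
)

#: default correlation panel: IRPI vs (log) congestion markers
CORRELATION_PANEL = (
    ("irpi_interlobular", "cvp"),
    ("irpi_interlobular", "rmp"),
    ("irpi_interlobular", "ttp_medulla"),
    ("irpi_interlobular", "edema"),
    ("irpi_interlobular", "ri"),
    ("irpi_interlobular", "vii"),
)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check group labels and return the table with a categorical group column."""
    if "group" not in table.columns:
        raise ValidationError("cohort table: missing 'group' column")
    bad = set(table["group"].unique()) - set(GROUPS)
    if bad:
        raise ValidationError(f"cohort table: unknown group labels {sorted(bad)}")
    for g in GROUPS:
        if not (table["group"] == g).any():
            raise ValidationError(f"cohort table: group '{g}' is empty")
    return table


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """Shapiro-Wilk gate: ("normal" | "non_normal", p-value)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValidationError(f"normality_gate: n must be in [3, 5000], got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("normality_gate: sample has zero variance")
    _, p = sps.shapiro(x)
    return ("non_normal" if p < alpha else "normal"), float(p)


def apply_log_policy(
    table: pd.DataFrame,
    variables: tuple[str, ...] | list[str] = DEFAULT_LOG_VARIABLES,
    alpha: float = 0.05,
    force: bool = False,
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Natural-log transform the listed variables that fail the normality gate.

    Returns a copy of the table plus per-variable transform flags. With
    ``force=True`` the gate is skipped and every listed variable is
    transformed. Nonpositive values under a
    requested log raise a validation error naming subject and variable.
    """
    out = table.copy()
    flags: dict[str, bool] = {}
    for var in variables:
        if var not in out.columns:
            continue
        x = out[var].to_numpy(dtype=float)
        do = force or normality_gate(x, alpha)[0] == "non_normal"
        if do:
            bad = np.flatnonzero(x <= 0)
            if bad.size:
                subj = (
                    out["id"].iloc[bad[0]] if "id" in out.columns else int(bad[0])
                )
                raise ValidationError(
                    f"log transform of '{var}': nonpositive value for subject "
                    f"{subj}"
                )
            out[var] = np.log(x)
        flags[var] = bool(do)
    return out, flags


def mann_whitney_exact(x, y) -> tuple[float, float, str]:
    """Mann-Whitney U of x vs y: (U, two-sided p, method).

    Exact p by full enumeration of rank assignments when n_x + n_y <= 20
    and the pooled sample is tie-free; otherwise the mid-rank normal
    approximation with tie correction. The two-sided p is
    min(1, 2*min(P(U <= u), P(U >= u))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney: both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= 20) and not ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue), method


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson R with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_corr: need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("pearson_corr: a variable has zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StatsReport:
    """Cohort summary: group comparisons and a correlation panel."""

    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    log_flags: dict[str, bool] = field(default_factory=dict)

    def to_csv(self, comparisons_path, correlations_path) -> None:
        self.comparisons.to_csv(comparisons_path, index=False)
        self.correlations.to_csv(correlations_path, index=False)


def summarize_cohort(
    table: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    log_variables: tuple[str, ...] = DEFAULT_LOG_VARIABLES,
    force_log: bool = True,
    correlation_panel=CORRELATION_PANEL,
) -> StatsReport:
    """Per-variable group mean +- SE with Mann-Whitney p, plus correlations.

    Comparisons run on raw values. Correlations involving a log-flagged
    variable use its natural log; the transform flag is recorded per pair.
    """
    table = validate_cohort(table)
    if variables is None:
        variables = tuple(
            v for v in COHORT_VARIABLES if v in table.columns
        ) + tuple(
            v
            for v in table.columns
            if v not in COHORT_VARIABLES
            and v not in ("id", "group")
            and pd.api.types.is_numeric_dtype(table[v])
        )

    logged, flags = apply_log_policy(
        table, [v for v in log_variables if v in table.columns], alpha, force=force_log
    )

    rows = []
    for var in variables:
        sub = table[["group", var]].dropna()
        xc = sub.loc[sub["group"] == "control", var].to_numpy(dtype=float)
        xh = sub.loc[sub["group"] == "HF", var].to_numpy(dtype=float)
        u, p, method = mann_whitney_exact(xc, xh)
        rows.append(
            {
                "variable": var,
                "mean_control": xc.mean(),
                "se_control": xc.std(ddof=1) / np.sqrt(xc.size),
                "n_control": xc.size,
                "mean_hf": xh.mean(),
                "se_hf": xh.std(ddof=1) / np.sqrt(xh.size),
                "n_hf": xh.size,
                "test": f"mann_whitney_{method}",
                "p": p,
                "log_transformed": bool(flags.get(var, False)),
            }
        )
    comparisons = pd.DataFrame(rows)

    corr_rows = []
    for xvar, yvar in correlation_panel:
        if xvar not in table.columns or yvar not in table.columns:
            continue
        src_x = logged if flags.get(xvar) else table
        src_y = logged if flags.get(yvar) else table
        sub = pd.DataFrame({"x": src_x[xvar], "y": src_y[yvar]}).dropna()
        if len(sub) < 3:
            continue
        r, p = pearson_corr(sub["x"], sub["y"])
        corr_rows.append(
            {
                "x": xvar,
                "y": yvar,
                "x_log": bool(flags.get(xvar, False)),
                "y_log": bool(flags.get(yvar, False)),
                "r": r,
                "p": p,
                "n": len(sub),
            }
        )
    correlations = pd.DataFrame(
        corr_rows, columns=["x", "y", "x_log", "y_log", "r", "p", "n"]
    )
    return StatsReport(comparisons=comparisons, correlations=correlations, log_flags=flags)
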