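"""Reference-database statistics over per-eye choroid measurements.

Covers the statistical layer of the reference database: subgroup summary
tables (mean/std/min/max by sex and origin, left and right eyes kept as
separate tables because fellow eyes of one animal are not independent), the
coefficient of variation, Pearson correlation panels among the 21 measures,
a two-way type-II ANOVA of sex and origin per thickness coefficient, and
Bonferroni-adjusted significance banding (nine tests per eye side).

The sample (n-1) standard deviation is used throughout, including the CV.
Eyes of unknown origin stay in summaries and correlations but are excluded
from the ANOVAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .io_formats import ChoroidRefError
from .morphometry import AREA_NAMES, MEASURE_COLUMNS, THICKNESS_NAMES, UMBO_NAMES

__all__ = [
    "SummaryStats",
    "AnovaResult",
    "SignificanceBand",
    "summarize",
    "coefficient_of_variation",
    "pearson_matrix",
    "table1_panels",
    "anova_two_way_type2",
    "bonferroni_band",
    "anova_battery",
]

#: Table 1b pairing: each thickness against its flanking area, plus the
#: nulla thickness against the four umbo measures.
CROSS_PANEL_PAIRS = [
    ("T1", "A1"), ("T2", "A2"), ("T3", "A3"), ("T4", "A4"),
    ("T6", "A5"), ("T7", "A6"), ("T8", "A7"), ("T9", "A8"),
    ("T5", "TUn"), ("T5", "TUt"), ("T5", "AUn"), ("T5", "AUt"),
]


class StatisticsError(ChoroidRefError):
    """Raised when a statistic's preconditions are not met."""


@dataclass(frozen=True)
class SummaryStats:
    """Per-group, per-measure summary: mean, std, min, max and optional CV%."""

    group: dict
    measure: str
    n: int
    mean: float
    std: float
    min: float
    max: float
    cv_pct: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    """Two-way (sex, origin) type-II ANOVA of one response.

    ``factors`` maps factor name to (sum of squares, df, F, p); the model
    has no interaction term, so residual df = n - 1 - df(sex) - df(origin).
    """

    response: str
    factors: dict[str, tuple[float, int, float, float]]
    residual_ss: float
    residual_df: int
    n: int
    side: str | None = None


@dataclass(frozen=True)
class SignificanceBand:
    """Bonferroni-banded significance of a raw p-value against m tests."""

    p: float
    m: int
    band: str  # "significant" | "weakly significant" | "not significant"

    @property
    def strict_threshold(self) -> float:
        return 0.01 / self.m

    @property
    def weak_threshold(self) -> float:
        return 0.05 / self.m


def summarize(
    table: pd.DataFrame,
    group_by: tuple[str, ...] = ("sex", "origin"),
    measures: tuple[str, ...] | None = None,
    include_cv: bool = False,
) -> list[SummaryStats]:
    """Summary statistics per (group x measure).

    Empty groups are omitted (with a warning); single-row groups report
    std 0.  Measures default to the full 21-column landmark set.
    """
    if table.empty:
        raise StatisticsError("cannot summarize an empty table")
    measures = measures or tuple(c for c in MEASURE_COLUMNS if c in table.columns)
    out: list[SummaryStats] = []
    grouped = table.groupby(list(group_by), observed=True) if group_by else [((), table)]
    for keys, sub in grouped:
        if sub.empty:  # pragma: no cover - pandas drops empty observed groups
            warnings.warn(f"empty group {keys!r} omitted from summary")
            continue
        if not isinstance(keys, tuple):
            keys = (keys,)
        group = dict(zip(group_by, keys))
        for m in measures:
            vals = sub[m].to_numpy(dtype=float)
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            mean = float(vals.mean())
            out.append(
                SummaryStats(
                    group=group,
                    measure=m,
                    n=len(vals),
                    mean=mean,
                    std=std,
                    min=float(vals.min()),
                    max=float(vals.max()),
                    cv_pct=(
                        coefficient_of_variation(vals)
                        if include_cv and len(vals) > 1 and mean > 0
                        else None
                    ),
                )
            )
    return out


def summary_frame(stats: list[SummaryStats]) -> pd.DataFrame:
    """Tidy DataFrame view of :func:`summarize` output."""
    rows = []
    for s in stats:
        row = dict(s.group)
        row.update(
            measure=s.measure, n=s.n, mean=s.mean, std=s.std, min=s.min, max=s.max
        )
        if s.cv_pct is not None:
            row["cv_pct"] = s.cv_pct
        rows.append(row)
    return pd.DataFrame(rows)


def coefficient_of_variation(values, decimals: int | None = 1) -> float:
    """CV as a percentage: 100 x sample standard deviation / mean.

    Requires at least two values and a positive mean; reported to one
    decimal by default (pass ``decimals=None`` for full precision).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise StatisticsError("CV needs at least two values")
    mean = vals.mean()
    if mean <= 0:
        raise StatisticsError("CV is undefined for a non-positive mean")
    cv = 100.0 * vals.std(ddof=1) / mean
    return float(round(cv, decimals)) if decimals is not None else float(cv)


def pearson_matrix(
    table: pd.DataFrame,
    vars_a: tuple[str, ...],
    vars_b: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Pearson correlation coefficients between two variable sets.

    Requires at least three complete rows.  Zero-variance variables yield
    NaN entries and a warning rather than a silent 0.
    """
    vars_b = vars_b or vars_a
    cols = list(dict.fromkeys([*vars_a, *vars_b]))
    data = table[cols].dropna()
    if len(data) < 3:
        raise StatisticsError("Pearson correlation needs at least 3 complete rows")
    x = data.to_numpy(dtype=float)
    centred = x - x.mean(axis=0)
    ss = (centred**2).sum(axis=0)
    degenerate = ss == 0
    if degenerate.any():
        warnings.warn(
            "zero-variance variable(s) "
            f"{[c for c, d in zip(cols, degenerate) if d]}: entries set to NaN"
        )
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred.T @ centred) / denom
    r[np.outer(degenerate, np.ones(len(cols), bool))] = np.nan
    r[np.outer(np.ones(len(cols), bool), degenerate)] = np.nan
    full = pd.DataFrame(r, index=cols, columns=cols)
    return full.loc[list(vars_a), list(vars_b)]


def table1_panels(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two published correlation panels.

    Panel (a): the 9x9 matrix among thickness coefficients; panel (b): each
    thickness against its flanking area plus T5 against the umbo measures,
    as a (var1, var2, r) frame.
    """
    matrix = pearson_matrix(table, THICKNESS_NAMES)
    pair_rows = []
    for a, b in CROSS_PANEL_PAIRS:
        r = pearson_matrix(table, (a,), (b,)).iat[0, 0]
        pair_rows.append({"var1": a, "var2": b, "r": float(r)})
    return matrix, pd.DataFrame(pair_rows)


def anova_two_way_type2(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("sex", "origin"),
    *,
    side: str | None = None,
    exclude_levels: dict[str, tuple[str, ...]] | None = None,
) -> AnovaResult:
    """Two-way ANOVA with type-II sums of squares and no interaction.

    Each factor's SS is the residual-SS reduction from adding it to the
    model already containing the other factor; F compares the factor mean
    square to the residual mean square of the full additive model.  Rows
    whose origin is "unknown" are dropped by default (they cannot be
    attributed to either origin group); a factor left with fewer than two
    observed levels, or a rank-deficient design, raises
    :class:`StatisticsError`.
    """
    if exclude_levels is None:
        exclude_levels = {"origin": ("unknown",)}
    data = table.copy()
    for factor, levels in exclude_levels.items():
        if factor in data.columns:
            data = data[~data[factor].isin(levels)]
    data = data.dropna(subset=[response, *factors])
    for factor in factors:
        n_levels = data[factor].nunique()
        if n_levels < 2:
            raise StatisticsError(
                f"factor {factor!r} has {n_levels} observed level(s); "
                "two-way ANOVA needs at least 2"
            )
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid <= 0 or np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise StatisticsError(
            f"rank-deficient design for response {response!r} (empty cell?)"
        )
    tab = anova_lm(fit, typ=2)
    factor_stats: dict[str, tuple[float, int, float, float]] = {}
    for factor in factors:
        row = tab.loc[f"C({factor})"]
        factor_stats[factor] = (
            float(row["sum_sq"]),
            int(row["df"]),
            float(row["F"]),
            float(row["PR(>F)"]),
        )
    resid = tab.loc["Residual"]
    return AnovaResult(
        response=response,
        factors=factor_stats,
        residual_ss=float(resid["sum_sq"]),
        residual_df=int(resid["df"]),
        n=int(len(data)),
        side=side,
    )


def bonferroni_band(p: float, m: int = 9) -> SignificanceBand:
    """Band a raw p-value after Bonferroni division of the alpha levels.

    With m tests per eye side, p < 0.01/m is "significant",
    0.01/m <= p < 0.05/m "weakly significant", and anything else
    "not significant".
    """
    if not (0 < p <= 1):
        raise StatisticsError(f"p-value must lie in (0, 1], got {p}")
    if m < 1:
        raise StatisticsError("number of tests m must be >= 1")
    if p < 0.01 / m:
        band = "significant"
    elif p < 0.05 / m:
        band = "weakly significant"
    else:
        band = "not significant"
    return SignificanceBand(p=float(p), m=int(m), band=band)


def anova_battery(
    table: pd.DataFrame,
    responses: tuple[str, ...] = THICKNESS_NAMES,
    *,
    side_column: str = "side",
    m_tests: int | None = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Run the per-side ANOVA battery and band every factor p-value.

    One two-way (sex, origin) ANOVA per response per eye side; the
    Bonferroni divisor defaults to the number of responses per side (nine).
    Returns a tidy frame: side, response, factor, sum_sq, df, F, p, band.
    With ``on_error="skip"``, sides whose design is degenerate (e.g. a
    subgroup with a single observed factor level) are logged and omitted
    instead of aborting the whole battery.
    """
    m = m_tests or len(responses)
    rows = []
    for side_value, sub in table.groupby(side_column):
        for response in responses:
            try:
                result = anova_two_way_type2(sub, response, side=str(side_value))
            except StatisticsError:
                if on_error == "skip":
                    warnings.warn(
                        f"ANOVA skipped for side={side_value} response={response}: "
                        "degenerate design"
                    )
                    continue
                raise
            for factor, (ss, df, f_stat, p) in result.factors.items():
                rows.append(
                    {
                        "side": side_value,
                        "response": response,
                        "factor": factor,
                        "sum_sq": ss,
                        "df": df,
                        "F": f_stat,
                        "p": p,
                        "band": bonferroni_band(p, m).band,
                    }
                )
    return pd.DataFrame(
        rows, columns=["side", "response", "factor", "sum_sq", "df", "F", "p",
                       "band"])
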