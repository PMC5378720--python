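"""Group-level statistics: age binning, composition, ANOVA, Tukey, Grubbs.

The comparative layer of the pipeline: per-donor per-subtype metrics are
aggregated into subtype composition percentages and compared across the four
donor age ranges (<30, 30-50, 50-70, >70 years) with a fixed-effects two-way
ANOVA (subtype x age group, with interaction), Tukey HSD post-hoc pairs and a
compact letter display, plus a single-outlier Grubbs screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientPointsError,
    InvalidSpecError,
    UnbalancedDesignError,
    UndefinedStatisticError,
)
from .reference import SOMA_LAYER

__all__ = [
    "AGE_GROUPS",
    "METRICS",
    "assign_age_group",
    "composition_percentages",
    "CompositionResult",
    "layer_share",
    "grubbs_test",
    "GrubbsResult",
    "two_way_anova",
    "AnovaResult",
    "EffectResult",
    "compact_letter_display",
    "decline_summary",
    "round_half_up",
]

#: Age-range bins, half-open: [0,30), [30,50), [50,70), [70,inf).
AGE_GROUPS: tuple[str, ...] = ("lt30", "30to50", "50to70", "gt70")

#: Closed vocabulary of study-table metrics.
METRICS: tuple[str, ...] = (
    "density_cells_per_mm2",
    "soma_equiv_diameter",
    "dendritic_area",
    "branch_points",
    "terminal_tips",
    "sholl_area",
    "nnri",
    "vdri",
    "di",
)


def assign_age_group(age_years: float) -> str:
    """Bin a donor age into the four study ranges (boundaries go up)."""
    if not (0.0 <= age_years <= 120.0):
        raise InvalidSpecError(f"age {age_years} outside [0, 120]")
    if age_years < 30:
        return "lt30"
    if age_years < 50:
        return "30to50"
    if age_years < 70:
        return "50to70"
    return "gt70"


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CompositionResult:
    """Subtype shares of total density, unrounded and as reported integers."""

    percent: dict
    percent_rounded: dict
    total_density: float


def composition_percentages(mean_densities) -> CompositionResult:
    """Each subtype's share of the summed density, in percent.

    Integer percentages use half-up rounding (the presentation convention);
    the unrounded values are retained and sum to exactly 100.
    """
    items = dict(mean_densities)
    if any(v < 0 for v in items.values()):
        raise InvalidSpecError("densities must be non-negative")
    total = float(sum(items.values()))
    if total <= 0:
        raise UndefinedStatisticError("composition undefined: zero total density")
    percent = {k: 100.0 * v / total for k, v in items.items()}
    return CompositionResult(
        percent=percent,
        percent_rounded={k: round_half_up(p) for k, p in percent.items()},
        total_density=total,
    )


def layer_share(mean_densities, layer: str = "GCL", layer_map=None) -> tuple[float, int]:
    """Share (unrounded %, rounded %) of total density whose somas sit in ``layer``."""
    layer_map = dict(SOMA_LAYER if layer_map is None else layer_map)
    comp = composition_percentages(mean_densities)
    share = sum(p for k, p in comp.percent.items() if layer_map.get(k) == layer)
    return share, round_half_up(share)


# ---------------------------------------------------------------------------
# Grubbs outlier test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrubbsResult:
    outlier_index: int | None
    statistic: float
    critical: float
    alpha: float
    n: int


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = stats.t.isf(alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x_i - mean| / SD is compared to the t-based critical value; at
    most one observation is flagged per invocation (repeated application to a
    reduced sample is the caller's explicit choice).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise InsufficientPointsError("Grubbs test needs at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return GrubbsResult(None, 0.0, grubbs_critical_value(n, alpha), alpha, n)
    dev = np.abs(values - values.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / sd)
    crit = grubbs_critical_value(n, alpha)
    return GrubbsResult(idx if g > crit else None, g, crit, alpha, n)


# ---------------------------------------------------------------------------
# two-way ANOVA with Tukey HSD and compact letter display
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectResult:
    name: str
    ss: float
    df: float
    F: float | None
    p: float | None


@dataclass(frozen=True)
class AnovaResult:
    effects: dict
    residual: EffectResult
    tukey: dict
    letters: dict
    alpha: float
    ss_type: int

    def significant(self, factor: str) -> bool:
        return self.effects[factor].p is not None and self.effects[factor].p < self.alpha


def compact_letter_display(levels, means, nonsig_pairs) -> dict:
    """Letters such that two levels share a letter iff their pair is non-significant.

    Implemented via maximal cliques of the non-significance graph; cliques are
    lettered in descending order of their mean response.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(nonsig_pairs)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -np.mean([means[l] for l in c]))
    letters = {l: [] for l in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for l in clique:
            letters[l].append(ch)
    return {l: "".join(sorted(v)) for l, v in letters.items()}


def _tukey_factor(df: pd.DataFrame, col: str, mse: float, df_resid: float, alpha: float):
    levels = sorted(df[col].unique(), key=str)
    means = {l: df.loc[df[col] == l, "y"].mean() for l in levels}
    ns = {l: int((df[col] == l).sum()) for l in levels}
    k = len(levels)
    rows = []
    nonsig = []
    for a in range(k):
        for b in range(a + 1, k):
            la, lb = levels[a], levels[b]
            diff = means[la] - means[lb]
            se = math.sqrt(mse / 2.0 * (1.0 / ns[la] + 1.0 / ns[lb]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_resid))
            sig = p < alpha
            if not sig:
                nonsig.append((la, lb))
            rows.append(dict(group1=la, group2=lb, meandiff=diff, p_adj=p, significant=sig))
    table = pd.DataFrame(rows)
    letters = compact_letter_display(levels, means, nonsig)
    return table, letters


def two_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    factors: tuple[str, str] = ("subtype", "age_group"),
    ss_type: int = 2,
    alpha: float = 0.05,
) -> AnovaResult:
    """Fixed-effects two-factor ANOVA with interaction, Tukey HSD and letters.

    Type-II sums of squares by default (appropriate for mildly unbalanced
    designs); ``ss_type=1`` gives sequential SS.  Empty factor cells raise
    :class:`UnbalancedDesignError` naming the cells; the interaction term
    requires at least two observations in some cell (positive residual df).
    Tukey–Kramer pairs use the model residual MSE and the studentized-range
    distribution; the letter display marks two levels with a shared letter
    exactly when their adjusted p >= alpha.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    for col in (response, fa, fb):
        if col not in data.columns:
            raise InvalidSpecError(f"column {col!r} missing from table")
    df = data[[response, fa, fb]].dropna().copy()
    df.columns = ["y", "A", "B"]
    df["A"] = df["A"].astype(str)
    df["B"] = df["B"].astype(str)
    for col, name in (("A", fa), ("B", fb)):
        if df[col].nunique() < 2:
            raise UnbalancedDesignError(f"factor {name!r} needs >=2 levels")
    counts = df.groupby(["A", "B"], sort=True).size()
    full = pd.MultiIndex.from_product([sorted(df["A"].unique()), sorted(df["B"].unique())])
    missing = full.difference(counts.index)
    if len(missing) > 0:
        cells = [f"({fa}={a}, {fb}={b})" for a, b in missing]
        raise UnbalancedDesignError(f"empty design cell(s): {', '.join(cells)}")
    n_cells = len(full)
    if len(df) - n_cells < 1:
        raise UnbalancedDesignError(
            "interaction model needs replicate observations (residual df would be 0)"
        )
    if ss_type not in (1, 2):
        raise InvalidSpecError("ss_type must be 1 or 2")

    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)
    name_map = {"C(A)": fa, "C(B)": fb, "C(A):C(B)": "interaction"}
    effects = {}
    for raw, name in name_map.items():
        row = tab.loc[raw]
        effects[name] = EffectResult(
            name=name, ss=float(row["sum_sq"]), df=float(row["df"]),
            F=float(row["F"]), p=float(row["PR(>F)"]),
        )
    resid = tab.loc["Residual"]
    residual = EffectResult("residual", float(resid["sum_sq"]), float(resid["df"]), None, None)

    mse = model.mse_resid
    tukey = {}
    letters = {}
    for col, name in (("A", fa), ("B", fb)):
        table, lett = _tukey_factor(df, col, mse, model.df_resid, alpha)
        tukey[name] = table
        letters[name] = lett
    return AnovaResult(effects=effects, residual=residual, tukey=tukey,
                       letters=letters, alpha=alpha, ss_type=ss_type)


def decline_summary(
    table: pd.DataFrame,
    metric: str,
    reference_group: str,
    target_group: str,
    group_col: str = "age_group",
    metric_col: str = "metric",
    value_col: str = "value",
) -> float:
    """Percent change of the target group mean below the reference group mean.

    100*(mean_ref - mean_target)/mean_ref: positive numbers are declines.
    """
    sub = table[table[metric_col] == metric] if metric_col in table.columns else table
    ref = sub.loc[sub[group_col] == reference_group, value_col]
    tgt = sub.loc[sub[group_col] == target_group, value_col]
    if len(ref) == 0 or len(tgt) == 0:
        raise InvalidSpecError(
            f"group(s) missing from table: {reference_group if len(ref) == 0 else target_group}"
        )
    m_ref = float(ref.mean())
    if m_ref == 0:
        raise UndefinedStatisticError("decline undefined: zero reference mean")
    return 100.0 * (m_ref - float(tgt.mean())) / m_ref
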