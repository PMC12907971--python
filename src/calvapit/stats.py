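"""Per-sample summaries and the assay's statistical layer.

Covers the quantities reported for the calvarial resorption assay: per-animal
pit count / total / mean resorbed volume, fold changes and percent decreases
between treatment means, two-way (treatment x sex) ANOVA with Tukey HSD post
hoc comparisons, within-treatment sex contrasts, and power-based sample-size
estimation for a two-sample t-test.

Balanced designs use the classical sums-of-squares decomposition computed
in-package (also exercised heavily by simulation tests); unbalanced designs
fall back to Type II sums of squares via statsmodels.  Tukey-adjusted
p-values come from the studentized range distribution.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pits import PitCandidate
from .volio import ResultsRow


# ---------------------------------------------------------------------------
# per-sample summaries and effect-size arithmetic


def summarize_sample(
    confirmed: Sequence[PitCandidate], voxel_size_um: float
) -> tuple[int, float, float]:
    """(pit_count, total_volume_um3, mean_pit_volume_um3) over confirmed
    pits; the mean is reported as 0 for a pit-free sample."""
    for c in confirmed:
        if c.status != "confirmed":
            raise ValueError(f"pit {c.pit_id} has status {c.status!r}, not confirmed")
    count = len(confirmed)
    total = float(sum(c.volume_um3 for c in confirmed))
    mean = total / count if count else 0.0
    return count, total, mean


def results_row(
    sample_id: str,
    treatment: str,
    sex: str,
    confirmed: Sequence[PitCandidate],
    voxel_size_um: float,
) -> ResultsRow:
    count, total, mean = summarize_sample(confirmed, voxel_size_um)
    return ResultsRow(sample_id, treatment, sex, count, total, mean)


def fold_change(numerator_mean: float, denominator_mean: float) -> float:
    """Ratio of group means (report at 1 decimal in summaries)."""
    if denominator_mean <= 0:
        raise ValueError("fold change requires a positive denominator mean")
    return numerator_mean / denominator_mean


def percent_decrease(reference_mean: float, treated_mean: float) -> float:
    """100 * (reference - treated) / reference."""
    if reference_mean <= 0:
        raise ValueError("percent decrease requires a positive reference mean")
    return 100.0 * (reference_mean - treated_mean) / reference_mean


# ---------------------------------------------------------------------------
# two-way ANOVA with Tukey post hoc


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    sum_sq: float
    df: int
    mean_sq: float
    F: float
    p: float


@dataclass(frozen=True)
class TukeyComparison:
    group_i: str
    group_j: str
    mean_diff: float
    adjusted_p: float


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[AnovaEffect, ...]
    residual_sum_sq: float
    residual_df: int
    tukey: tuple[TukeyComparison, ...]

    @property
    def residual_mean_sq(self) -> float:
        return self.residual_sum_sq / self.residual_df

    def effect(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def group_table(rows: Sequence[ResultsRow]) -> pd.DataFrame:
    """Animal-level table with treatment and sex factors plus the three
    outcome columns."""
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def _validate_design(table: pd.DataFrame, outcome: str, fa: str, fb: str) -> None:
    for col in (outcome, fa, fb):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    y = table[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome values must be finite")
    counts = table.groupby([fa, fb], observed=True).size().unstack(fill_value=0)
    if (counts.to_numpy() == 0).any():
        raise ValueError("every factor-level cell must contain at least one value")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("each factor needs at least 2 levels")


def _balanced_decomposition(
    table: pd.DataFrame, outcome: str, fa: str, fb: str
) -> tuple[dict[str, tuple[float, int]], float, int]:
    """Classical two-way crossed decomposition for balanced cells."""
    y = table[outcome].to_numpy(dtype=float)
    a = table[fa].to_numpy()
    b = table[fb].to_numpy()
    a_levels = np.unique(a)
    b_levels = np.unique(b)
    grand = y.mean()
    n = len(y)
    cell_mean = {}
    ss_res = 0.0
    for al in a_levels:
        for bl in b_levels:
            cell = y[(a == al) & (b == bl)]
            cell_mean[(al, bl)] = cell.mean()
            ss_res += float(((cell - cell.mean()) ** 2).sum())
    a_mean = {al: y[a == al].mean() for al in a_levels}
    b_mean = {bl: y[b == bl].mean() for bl in b_levels}
    m = n // (len(a_levels) * len(b_levels))  # per-cell count (balanced)
    ss_a = m * len(b_levels) * sum((a_mean[al] - grand) ** 2 for al in a_levels)
    ss_b = m * len(a_levels) * sum((b_mean[bl] - grand) ** 2 for bl in b_levels)
    ss_ab = m * sum(
        (cell_mean[(al, bl)] - a_mean[al] - b_mean[bl] + grand) ** 2
        for al in a_levels
        for bl in b_levels
    )
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_res = n - len(a_levels) * len(b_levels)
    effects = {
        fa: (float(ss_a), df_a),
        fb: (float(ss_b), df_b),
        f"{fa}:{fb}": (float(ss_ab), df_ab),
    }
    return effects, ss_res, df_res


def _type2_decomposition(
    table: pd.DataFrame, outcome: str, fa: str, fb: str
) -> tuple[dict[str, tuple[float, int]], float, int]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={outcome: "_y", fa: "_a", fb: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effects = {
        fa: (float(aov.loc["C(_a)", "sum_sq"]), int(aov.loc["C(_a)", "df"])),
        fb: (float(aov.loc["C(_b)", "sum_sq"]), int(aov.loc["C(_b)", "df"])),
        f"{fa}:{fb}": (
            float(aov.loc["C(_a):C(_b)", "sum_sq"]),
            int(aov.loc["C(_a):C(_b)", "df"]),
        ),
    }
    ss_res = float(aov.loc["Residual", "sum_sq"])
    df_res = int(aov.loc["Residual", "df"])
    return effects, ss_res, df_res


def tukey_hsd(
    group_means: Mapping[str, float],
    group_ns: Mapping[str, int],
    ms_residual: float,
    df_residual: int,
) -> list[TukeyComparison]:
    """All-pairs comparisons with studentized-range (Tukey–Kramer)
    adjusted p-values."""
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if len(group_means) < 2:
        raise ValueError("need at least 2 groups")
    if ms_residual <= 0:
        raise ValueError("zero residual variance: Tukey p undefined")
    names = list(group_means)
    k = len(names)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            diff = group_means[gi] - group_means[gj]
            se = math.sqrt(
                ms_residual / 2.0 * (1.0 / group_ns[gi] + 1.0 / group_ns[gj])
            )
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_residual))
            out.append(TukeyComparison(gi, gj, float(diff), min(max(p, 0.0), 1.0)))
    return out


def two_way_anova(
    table: pd.DataFrame,
    outcome: str,
    factor_a: str = "treatment",
    factor_b: str = "sex",
    tukey_factor: str | None = None,
) -> AnovaResult:
    """Two-way crossed ANOVA with interaction, F tests against the residual
    mean square, and Tukey HSD over the levels of ``tukey_factor``
    (default ``factor_a``).

    Balanced designs use the classical decomposition; unbalanced designs use
    Type II sums of squares (identical for balanced data).
    """
    _validate_design(table, outcome, factor_a, factor_b)
    counts = table.groupby([factor_a, factor_b], observed=True).size()
    balanced = counts.nunique() == 1
    if balanced:
        effects_ss, ss_res, df_res = _balanced_decomposition(
            table, outcome, factor_a, factor_b
        )
    else:
        effects_ss, ss_res, df_res = _type2_decomposition(
            table, outcome, factor_a, factor_b
        )
    if df_res < 1:
        raise ValueError("residual df < 1: design has no replication")
    ms_res = ss_res / df_res
    if ms_res <= 0:
        raise ValueError("zero residual variance: F test undefined")
    effects = []
    for name, (ss, df) in effects_ss.items():
        ms = ss / df
        f = ms / ms_res
        p = float(sps.f.sf(f, df, df_res))
        effects.append(AnovaEffect(name, ss, df, ms, f, p))

    tf = tukey_factor or factor_a
    groups = table.groupby(tf, observed=True)[outcome]
    comparisons = tukey_hsd(
        groups.mean().to_dict(),
        groups.size().to_dict(),
        ms_res,
        df_res,
    )
    return AnovaResult(tuple(effects), ss_res, df_res, tuple(comparisons))


@dataclass(frozen=True)
class SexContrast:
    treatment: str
    mean_male: float
    mean_female: float
    mean_diff: float  # male minus female
    adjusted_p: float


def sex_contrasts(
    table: pd.DataFrame,
    outcome: str,
    factor_a: str = "treatment",
    sex_col: str = "sex",
) -> list[SexContrast]:
    """Within-treatment male-vs-female comparisons of cell means, adjusted
    with the studentized range over all treatment-by-sex cell means (the
    family from which the within-treatment pairs are drawn)."""
    _validate_design(table, outcome, factor_a, sex_col)
    sexes = set(table[sex_col].unique())
    if not {"M", "F"} <= sexes:
        raise ValueError("both sexes must be present")
    res = two_way_anova(table, outcome, factor_a, sex_col)
    ms_res, df_res = res.residual_mean_sq, res.residual_df
    cells = table.groupby([factor_a, sex_col], observed=True)[outcome]
    means = cells.mean()
    ns = cells.size()
    k = len(means)  # family size: all cell means
    out = []
    for trt in table[factor_a].unique():
        m_m, m_f = means[(trt, "M")], means[(trt, "F")]
        se = math.sqrt(ms_res / 2.0 * (1.0 / ns[(trt, "M")] + 1.0 / ns[(trt, "F")]))
        diff = float(m_m - m_f)
        p = float(sps.studentized_range.sf(abs(diff) / se, k, df_res))
        out.append(SexContrast(str(trt), float(m_m), float(m_f), diff, min(p, 1.0)))
    return out


# ---------------------------------------------------------------------------
# power-based sample size


@dataclass(frozen=True)
class PowerSpec:
    """Two-sided two-sample t-test power specification: detect a
    ``pct_difference`` % shift from ``reference_mean`` given common ``sd``."""

    pct_difference: float
    reference_mean: float
    sd: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.pct_difference <= 0 or self.reference_mean <= 0 or self.sd <= 0:
            raise ValueError("pct_difference, reference_mean and sd must be positive")

    @property
    def effect_size(self) -> float:
        """Standardized difference delta / sd."""
        return self.pct_difference / 100.0 * self.reference_mean / self.sd


def sample_size_two_groups(spec: PowerSpec, max_n: int = 10**6) -> int:
    """Smallest per-group n whose exact (noncentral-t) two-sided two-sample
    t-test power reaches ``spec.power``.  Monotone non-increasing in the
    percent difference."""
    from statsmodels.stats.power import TTestIndPower

    solver = TTestIndPower()
    d = spec.effect_size
    for n in range(2, max_n + 1):
        if solver.power(effect_size=d, nobs1=n, alpha=spec.alpha, ratio=1.0) >= spec.power:
            return n
    raise ValueError("required sample size exceeds max_n; effect size too small")
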