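"""Cohort-level statistics: normality testing and the factor screen.

Each region's IO% sample is tested for normality (Shapiro-Wilk, Royston
algorithm) and screened for the influence of five categorical patient
factors — angle class, displacement distance, anterior bite situation,
age group and gender — with a general linear model.  The screen fits,
per region, an ordinary least-squares model with all five main effects
(no interactions; the small cohorts this mimics cannot support them)
and reports each factor's Type-III F-test p-value, producing a
5-factor x 8-region p-value grid.  With main effects only, Type III is
invariant to the factor coding; sum-to-zero contrasts are used.

No multiple-testing correction is applied across the grid cells,
matching how such screens are conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .regions import REGION_NAMES
from .synthetic_data import FACTOR_LEVELS

DEFAULT_ALPHA = 0.05

FACTOR_ORDER = tuple(FACTOR_LEVELS)  # angle_class, displacement, bite, age_group, gender


class DegenerateSampleError(ValueError):
    """Sample unusable for the requested test."""


class RankDeficiencyError(ValueError):
    """Aliased (confounded) factors make the model unidentifiable."""


def validate_study_table(table: pd.DataFrame, regions=REGION_NAMES) -> None:
    """Check factor levels and IO% ranges of a study table."""
    for factor, levels in FACTOR_LEVELS.items():
        if factor not in table:
            raise ValueError(f"study table missing factor column {factor!r}")
        bad = set(table[factor].unique()) - set(levels)
        if bad:
            raise ValueError(f"factor {factor!r} has unknown level(s) {sorted(bad)}")
    for region in regions:
        if region not in table:
            raise ValueError(f"study table missing region column {region!r}")
        vals = table[region].to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 100:
            raise ValueError(f"IO% out of [0, 100] in region {region!r}")


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    n = len(values)
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={n}")
    if np.ptp(values) == 0:
        raise DegenerateSampleError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


@dataclass
class FactorPGrid:
    """Type-III p-values for each (factor, region) cell."""

    pvalues: pd.DataFrame  # index: factors, columns: regions
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        vals = self.pvalues.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("p-values outside [0, 1]")

    @property
    def significant(self) -> pd.DataFrame:
        return self.pvalues < self.alpha

    def to_csv(self, path) -> None:
        out = self.pvalues.copy()
        out.insert(0, "factor", out.index)
        out.to_csv(path, index=False, float_format="%.6g")


def _check_aliasing(table: pd.DataFrame) -> None:
    """Raise naming a confounded factor pair, if any."""
    factors = list(FACTOR_ORDER)
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            a, b = factors[i], factors[j]
            ct = pd.crosstab(table[a], table[b]).to_numpy()
            used_a = (ct.sum(axis=1) > 0).sum()
            used_b = (ct.sum(axis=0) > 0).sum()
            if used_a < 2 or used_b < 2:
                continue
            # perfectly nested/confounded: one nonzero cell per row or column
            if ((ct > 0).sum(axis=1) <= 1).all() or ((ct > 0).sum(axis=0) <= 1).all():
                raise RankDeficiencyError(
                    f"factors {a!r} and {b!r} are aliased (perfectly confounded)"
                )


_FORMULA_RHS = " + ".join(f"C({f}, Sum)" for f in FACTOR_ORDER)


def glm_factor_screen(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    regions=REGION_NAMES,
) -> FactorPGrid:
    """Per-region main-effects GLM; Type-III F-test p per factor.

    Preconditions: every used factor level has >= 2 patients, and there
    are more observations than model parameters.  Aliased factor pairs
    raise :class:`RankDeficiencyError` naming the pair.
    """
    validate_study_table(table, regions=regions)
    n = len(table)
    n_params = 1 + sum(table[f].nunique() - 1 for f in FACTOR_ORDER)
    if n <= n_params:
        raise ValueError(
            f"insufficient observations: n={n} for {n_params} model parameters"
        )
    for factor in FACTOR_ORDER:
        counts = table[factor].value_counts()
        if counts.min() < 2:
            raise ValueError(
                f"factor {factor!r} has a level with fewer than 2 patients: "
                f"{counts.to_dict()}"
            )
    _check_aliasing(table)
    if n - n_params < 10:
        warnings.warn(
            f"residual degrees of freedom = {n - n_params} < 10; "
            "the factor screen has little power"
        )

    grid = {}
    for region in regions:
        df = table[[*FACTOR_ORDER]].copy()
        df["io"] = table[region].to_numpy(dtype=float)
        model = smf.ols(f"io ~ {_FORMULA_RHS}", data=df).fit()
        if model.df_resid < 1:
            raise ValueError(f"no residual degrees of freedom for region {region!r}")
        anova = sm.stats.anova_lm(model, typ=3)
        ps = {}
        for factor in FACTOR_ORDER:
            ps[factor] = float(anova.loc[f"C({factor}, Sum)", "PR(>F)"])
        grid[region] = ps
    pvalues = pd.DataFrame(grid).loc[list(FACTOR_ORDER), list(regions)]
    pvalues.index.name = "factor"
    return FactorPGrid(pvalues, alpha=alpha)


def box_summary(values: np.ndarray) -> dict:
    """Box-plot summary: quartiles (linear interpolation) + outlier flags.

    Outliers beyond 1.5 x IQR from the quartiles are "moderate", beyond
    3.0 x IQR "extreme" (the usual box-plot convention).
    """
    values = np.asarray(values, dtype=np.float64).reshape(-1)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise DegenerateSampleError("empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_m, hi_m = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_x, hi_x = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    outside = (values < lo_m) | (values > hi_m)
    extreme = (values < lo_x) | (values > hi_x)
    moderate = outside & ~extreme
    return {
        "n": int(len(values)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_lo": float(values[values >= lo_m].min()),
        "whisker_hi": float(values[values <= hi_m].max()),
        "moderate_outliers": sorted(float(v) for v in values[moderate]),
        "extreme_outliers": sorted(float(v) for v in values[extreme]),
    }


def cohort_report(
    table: pd.DataFrame,
    grid: FactorPGrid,
    out_dir: str | Path,
    plots: bool = False,
    regions=REGION_NAMES,
) -> dict:
    """Write per-region box-plot summaries and the p-value grid as CSV.

    Returns the summary mapping.  Empty region columns are omitted with
    a warning.  ``plots=True`` additionally renders IO% box plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries = {}
    kept = []
    for region in regions:
        vals = table[region].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"region {region!r} has no values; omitted from summary")
            continue
        summaries[region] = box_summary(vals)
        kept.append(region)
    rows = []
    for region in kept:
        s = summaries[region]
        rows.append(
            {
                "region": region,
                **{k: s[k] for k in ("n", "median", "q1", "q3", "iqr",
                                     "whisker_lo", "whisker_hi")},
                "n_moderate_outliers": len(s["moderate_outliers"]),
                "n_extreme_outliers": len(s["extreme_outliers"]),
            }
        )
    pd.DataFrame(rows).to_csv(out / "boxplot_summary.csv", index=False,
                              float_format="%.10g")
    grid.to_csv(out / "factor_pvalues.csv")
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4.5))
        ax.boxplot([table[r].dropna() for r in kept], tick_labels=kept)
        ax.set_ylabel("IO% (surface congruence within tolerance)")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(out / "io_boxplot.png", dpi=150)
        plt.close(fig)
    return summaries
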