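"""ROI-level group statistics: t-tests with BH-FDR and DTI ~ AI + CD regression.

The measurement table is tidy: one row per (animal, hemisphere, bregma
level, region) carrying the histology measures (AI: structure-tensor
anisotropy index; CD: cell density on the x1e-2 cells/um^2 scale) and the
DTI measures (FA; AD in x1e-3 mm^2/s).

Three analyses mirror the usual design of MRI--histology comparisons:

* per (level, region, hemisphere, measure), an unpaired two-sample t-test
  between groups (pooled-variance Student's t by default, Welch optional);
* Benjamini--Hochberg step-up FDR across each configurable family of
  p-values, reported as q-values, significance at q < 0.05;
* per region family (single regions and pooled sets of connected regions),
  an ordinary least-squares regression DTI ~ AI + CD with intercept, with
  coefficient t statistics, adjusted R^2 and model F, and the projection
  chi = beta_AI * AI + beta_CD * CD used for scatter reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUPS",
    "HEMISPHERES",
    "LEVELS",
    "REGIONS_BY_LEVEL",
    "REGION_FAMILIES",
    "StatsConfig",
    "GroupTestResult",
    "RegressionResult",
    "unpaired_t",
    "bh_fdr",
    "fit_dti_histology_regression",
    "chi_projection",
    "analyze_cohort",
]

GROUPS = ("sham", "mTBI")
HEMISPHERES = ("ipsilateral", "contralateral")
LEVELS = (1.08, -1.60, -3.60)
#: regions measured at each bregma level (ic and VPL only at the lesion level)
REGIONS_BY_LEVEL = {
    1.08: ("cc", "ec", "S1"),
    -1.60: ("cc", "ec", "S1"),
    -3.60: ("cc", "ec", "S1", "ic", "VPL"),
}
#: regression families per level: single regions plus pooled connected sets
REGION_FAMILIES = {
    1.08: [("cc",), ("ec",), ("S1",), ("cc", "ec")],
    -1.60: [("cc",), ("ec",), ("S1",), ("cc", "ec")],
    -3.60: [("cc",), ("ec",), ("S1",), ("ic",), ("VPL",),
            ("cc", "ec"), ("cc", "ec", "ic"), ("S1", "VPL")],
}

REQUIRED_COLUMNS = ("animal_id", "group", "hemisphere", "level", "region",
                    "AI", "CD", "FA", "AD")


@dataclass
class StatsConfig:
    """t-test variant, significance level and FDR family layout.

    ``fdr_families``: "per_measure" pools all t-tests of one measure (AI or
    CD) across levels/regions/hemispheres into one BH family and all
    regression p-values into another single family; "global" uses one family
    per analysis type regardless of measure.
    """

    welch: bool = False
    alpha: float = 0.05
    fdr_families: str = "per_measure"


@dataclass
class GroupTestResult:
    level: float
    region: str
    hemisphere: str
    measure: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p: float
    q: float = np.nan
    significant: bool = False


@dataclass
class RegressionResult:
    """OLS fit of one DTI measure on (AI, CD) over one region family."""

    level: float
    regions: tuple[str, ...]
    response: str
    beta_ai: float
    beta_cd: float
    intercept: float
    t_ai: float
    t_cd: float
    p_ai: float
    p_cd: float
    r2: float
    r2_adj: float
    f_stat: float
    p_model: float
    n: int
    q_ai: float = np.nan
    q_cd: float = np.nan
    q_model: float = np.nan


def unpaired_t(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p).

    Pooled-variance Student's t by default (df = nA + nB - 2); Welch's
    unequal-variance form when ``welch``. With zero pooled variance, t = 0
    for equal means and signed infinity (p = 0) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the input
    order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def fit_dti_histology_regression(
    records: pd.DataFrame,
    response: str,
    regions: tuple[str, ...] | list[str],
    level: float,
) -> RegressionResult:
    """OLS of ``response`` (FA or AD) on AI and CD over a region family.

    All records of the family enter: both hemispheres and both groups, one
    observation per (animal, hemisphere, region). CD is used on its x1e-2
    cells/um^2 scale so coefficients stay O(1).
    """
    regions = tuple(regions)
    sub = records[(records["level"] == level) & records["region"].isin(regions)]
    sub = sub.dropna(subset=["AI", "CD", response])
    if len(sub) < 4:
        raise ValueError(f"family {regions} at level {level}: fewer than 4 records")
    x = sub[["AI", "CD"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < 3:
        raise ValueError(f"collinear AI/CD in family {regions} at level {level}")
    model = sm.OLS(sub[response].to_numpy(dtype=float), sm.add_constant(x)).fit()
    return RegressionResult(
        level=level, regions=regions, response=response,
        intercept=float(model.params[0]),
        beta_ai=float(model.params[1]), beta_cd=float(model.params[2]),
        t_ai=float(model.tvalues[1]), t_cd=float(model.tvalues[2]),
        p_ai=float(model.pvalues[1]), p_cd=float(model.pvalues[2]),
        r2=float(model.rsquared), r2_adj=float(model.rsquared_adj),
        f_stat=float(model.fvalue), p_model=float(model.f_pvalue),
        n=int(model.nobs),
    )


def chi_projection(result: RegressionResult, ai, cd):
    """chi = beta_AI * AI + beta_CD * CD (no intercept), the fitted linear
    combination of the histology measures used on regression scatter axes."""
    return result.beta_ai * np.asarray(ai, dtype=float) + result.beta_cd * np.asarray(cd, dtype=float)


def _validate_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")
    bad_group = set(records["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown groups: {bad_group}")
    return records


def analyze_cohort(
    records: pd.DataFrame, cfg: StatsConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Produce the group-contrast and regression report tables for a cohort.

    Returns ``{"group_tests": ..., "regressions": ..., "chi": ...}``:
    per-contrast group means +- SD with t/p/q and a significance flag; the
    regression table over the region families; and per-record chi values for
    every fitted family.
    """
    cfg = cfg or StatsConfig()
    records = _validate_table(records)
    tests: list[GroupTestResult] = []
    for level in LEVELS:
        for region in REGIONS_BY_LEVEL[level]:
            for hemi in HEMISPHERES:
                sub = records[(records["level"] == level)
                              & (records["region"] == region)
                              & (records["hemisphere"] == hemi)]
                for measure in ("AI", "CD"):
                    a = sub.loc[sub["group"] == "sham", measure].dropna().to_numpy()
                    b = sub.loc[sub["group"] == "mTBI", measure].dropna().to_numpy()
                    if len(a) < 2 or len(b) < 2:
                        tests.append(GroupTestResult(
                            level, region, hemi, measure,
                            np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, np.nan))
                        continue
                    t, df, p = unpaired_t(a, b, welch=cfg.welch)
                    tests.append(GroupTestResult(
                        level, region, hemi, measure,
                        float(a.mean()), float(a.std(ddof=1)),
                        float(b.mean()), float(b.std(ddof=1)),
                        t, df, p))
    # FDR over the t-test p-values
    if cfg.fdr_families == "per_measure":
        family_key = lambda tr: tr.measure  # noqa: E731
    else:
        family_key = lambda tr: "ttest"  # noqa: E731
    for key in {family_key(tr) for tr in tests}:
        fam = [tr for tr in tests if family_key(tr) == key and np.isfinite(tr.p)]
        if not fam:
            continue
        qs = bh_fdr([tr.p for tr in fam])
        for tr, q in zip(fam, qs):
            tr.q = float(q)
            tr.significant = bool(q < cfg.alpha)

    regressions: list[RegressionResult] = []
    chi_rows: list[pd.DataFrame] = []
    for level in LEVELS:
        for family in REGION_FAMILIES[level]:
            for response in ("FA", "AD"):
                try:
                    rr = fit_dti_histology_regression(records, response, family, level)
                except ValueError:
                    continue
                regressions.append(rr)
                sub = records[(records["level"] == level)
                              & records["region"].isin(family)].dropna(
                                  subset=["AI", "CD", response])
                chi = chi_projection(rr, sub["AI"], sub["CD"])
                chi_rows.append(pd.DataFrame({
                    "level": level, "family": "+".join(family), "response": response,
                    "animal_id": sub["animal_id"].to_numpy(),
                    "group": sub["group"].to_numpy(),
                    "hemisphere": sub["hemisphere"].to_numpy(),
                    "region": sub["region"].to_numpy(),
                    "chi": chi,
                    "value": sub[response].to_numpy(),
                }))
    # one BH family over all regression p-values (coefficients and models)
    if regressions:
        flat = []
        for rr in regressions:
            flat.extend([rr.p_ai, rr.p_cd, rr.p_model])
        qs = bh_fdr(flat)
        for i, rr in enumerate(regressions):
            rr.q_ai, rr.q_cd, rr.q_model = (float(qs[3 * i]), float(qs[3 * i + 1]),
                                            float(qs[3 * i + 2]))

    group_df = pd.DataFrame([vars(tr) for tr in tests])
    reg_df = pd.DataFrame([
        {**{k: v for k, v in vars(rr).items() if k != "regions"},
         "family": "+".join(rr.regions)}
        for rr in regressions
    ])
    chi_df = (pd.concat(chi_rows, ignore_index=True)
              if chi_rows else pd.DataFrame())
    return {"group_tests": group_df, "regressions": reg_df, "chi": chi_df}
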