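"""Zonal inference: MANOVA, Bonferroni post-hoc comparisons, WE->MHU regression.

The omnibus question is whether the pillar scores differ across the six
zones.  A one-way MANOVA on the stacked pillar responses gives Pillai's
trace; per-pillar one-way F tests (between df = zones - 1, within df =
n - zones) are reported alongside, as is conventional for this design.
Pairwise zone contrasts use t statistics on the pooled within-group mean
square with a Bonferroni family of all C(zones, 2) pairs per pillar.
Regions missing any pillar score are excluded listwise, since the
multivariate test needs complete response vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.multivariate.manova import MANOVA

from .core import RegionRecord, ValidationError, registry_zones


@dataclass
class ZonalTestResult:
    pillar_id: str
    F: float
    df_between: int
    df_within: int
    p: float
    multivariate_stat: tuple[str, float, float] | None = None


@dataclass
class RegressionResult:
    intercept: float
    slope: float
    r_squared: float
    n: int


def _complete_cases(
    scores_wide: pd.DataFrame, registry: Sequence[RegionRecord]
) -> tuple[pd.DataFrame, pd.Series]:
    zones = registry_zones(registry)
    missing = [rid for rid in scores_wide.index if rid not in zones.index]
    if missing:
        raise ValidationError(f"regions not in registry: {missing[:5]}")
    complete = scores_wide.dropna(axis=0, how="any")
    return complete, zones.loc[complete.index]


def _check_group_sizes(zones: pd.Series) -> list[str]:
    counts = zones.value_counts()
    small = [z for z, n in counts.items() if n < 2]
    if small:
        raise ValidationError(
            f"zones with < 2 usable regions: {small} (cannot estimate "
            "within-zone variance)"
        )
    if len(counts) < 2:
        raise ValidationError("need at least 2 zones")
    return sorted(counts.index)


def zonal_manova(
    scores_wide: pd.DataFrame,
    registry: Sequence[RegionRecord],
    multivariate: bool = True,
) -> list[ZonalTestResult]:
    """Per-pillar one-way F tests across zones, plus Pillai's trace.

    Parameters
    ----------
    scores_wide : region x pillar score frame (NaN = undefined).
    registry : region records supplying the zone factor.
    multivariate : compute Pillai's trace for the joint test (attached to
        every returned row).  Turning it off skips the multivariate model;
        the univariate Fs are unaffected.
    """
    complete, zones = _complete_cases(scores_wide, registry)
    zone_levels = _check_group_sizes(zones)
    k = len(zone_levels)
    n = len(complete)

    results: list[ZonalTestResult] = []
    for pillar in complete.columns:
        groups = [
            complete.loc[zones == z, pillar].to_numpy(dtype=float)
            for z in zone_levels
        ]
        if all(np.ptp(g) == 0 for g in groups):
            raise ValidationError(
                f"pillar {pillar!r}: zero variance everywhere, F undefined"
            )
        F, p = stats.f_oneway(*groups)
        results.append(
            ZonalTestResult(
                pillar_id=pillar,
                F=float(F),
                df_between=k - 1,
                df_within=n - k,
                p=float(p),
            )
        )

    if multivariate:
        data = complete.copy()
        data.columns = [f"y{i}" for i in range(len(complete.columns))]
        data["zone"] = zones.values
        formula = " + ".join(data.columns[:-1]) + " ~ C(zone)"
        mv = MANOVA.from_formula(formula, data=data)
        tab = mv.mv_test().results["C(zone)"]["stat"]
        pillai = float(tab.loc["Pillai's trace", "Value"])
        pillai_p = float(tab.loc["Pillai's trace", "Pr > F"])
        for r in results:
            r.multivariate_stat = ("pillai", pillai, pillai_p)
    return results


def bonferroni_posthoc(
    scores_wide: pd.DataFrame,
    registry: Sequence[RegionRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise zone mean differences per pillar, Bonferroni-adjusted.

    The t statistic for a pair uses the pooled within-group mean square from
    the full one-way model (within df = n - zones), and the Bonferroni
    family is the C(zones, 2) pairs within each pillar.  ``mean_diff`` is
    mean(zone_a) - mean(zone_b) with pairs listed in lexicographic order, so
    a negative entry means zone_a underperforms zone_b.
    """
    complete, zones = _complete_cases(scores_wide, registry)
    zone_levels = _check_group_sizes(zones)
    k = len(zone_levels)
    n = len(complete)
    df_within = n - k
    n_pairs = k * (k - 1) // 2

    rows = []
    for pillar in complete.columns:
        s = complete[pillar]
        means = {z: float(s[zones == z].mean()) for z in zone_levels}
        counts = {z: int((zones == z).sum()) for z in zone_levels}
        ssw = sum(
            float(((s[zones == z] - means[z]) ** 2).sum()) for z in zone_levels
        )
        msw = ssw / df_within
        if msw == 0:
            raise ValidationError(
                f"pillar {pillar!r}: zero within-zone variance, t undefined"
            )
        for a, b in combinations(zone_levels, 2):
            diff = means[a] - means[b]
            se = math.sqrt(msw * (1.0 / counts[a] + 1.0 / counts[b]))
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), df_within)
            p_adj = min(1.0, n_pairs * p)
            rows.append(
                {
                    "pillar_id": pillar,
                    "zone_a": a,
                    "zone_b": b,
                    "mean_diff": diff,
                    "t": t,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return pd.DataFrame(rows)


class PillarRegressor(BaseEstimator, RegressorMixin):
    """Univariate least-squares regression of one pillar score on another.

    Defaults model maternal-healthcare utilisation as a linear function of
    women empowerment at region level: MHU = b * WE + a.  Fitted attributes
    follow scikit-learn conventions (``intercept_``, ``coef_``,
    ``r_squared_``, ``n_``).
    """

    def __init__(self, predictor: str = "WE", response: str = "MHU"):
        self.predictor = predictor
        self.response = response

    def fit(self, X, y=None) -> "PillarRegressor":
        """X: wide score frame containing the predictor and response columns,
        or a 2D array of predictor values with y the response."""
        if isinstance(X, pd.DataFrame) and y is None:
            sub = X[[self.predictor, self.response]].dropna()
            x = sub[self.predictor].to_numpy(dtype=float)
            yv = sub[self.response].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float).ravel()
            yv = np.asarray(y, dtype=float).ravel()
        if x.size < 3:
            raise ValidationError(
                f"need >= 3 complete observations, have {x.size}"
            )
        if np.ptp(x) == 0:
            raise ValidationError("zero variance in predictor; slope undefined")
        import statsmodels.api as sm

        model = sm.OLS(yv, sm.add_constant(x)).fit()
        self.intercept_ = float(model.params[0])
        self.coef_ = np.array([model.params[1]])
        self.slope_ = float(model.params[1])
        # a constant response has no variance to explain: R^2 = 0 by convention
        self.r_squared_ = float(model.rsquared) if np.ptp(yv) > 0 else 0.0
        self.n_ = int(x.size)
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            x = X[self.predictor].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.slope_ * x

    def result(self) -> RegressionResult:
        return RegressionResult(
            intercept=self.intercept_,
            slope=self.slope_,
            r_squared=self.r_squared_,
            n=self.n_,
        )


def fit_we_mhu_regression(
    scores_wide: pd.DataFrame,
    registry: Sequence[RegionRecord] | None = None,
) -> tuple[RegressionResult, pd.DataFrame]:
    """OLS fit of MHU on WE at region level.

    Returns the coefficients and a scatter-ready frame
    (region_id, zone, WE, MHU) for plotting, zone-coloured.
    """
    reg = PillarRegressor(predictor="WE", response="MHU").fit(scores_wide)
    scatter = scores_wide[["WE", "MHU"]].dropna().reset_index()
    scatter = scatter.rename(columns={scatter.columns[0]: "region_id"})
    if registry is not None:
        zones = registry_zones(registry)
        scatter.insert(1, "zone", scatter["region_id"].map(zones))
    return reg.result(), scatter


def results_frame(results: Sequence[ZonalTestResult]) -> pd.DataFrame:
    """Flatten ZonalTestResult rows to the output CSV schema."""
    rows = []
    for r in results:
        pillai, pillai_p = (math.nan, math.nan)
        if r.multivariate_stat is not None:
            _, pillai, pillai_p = r.multivariate_stat
        rows.append(
            {
                "pillar_id": r.pillar_id,
                "F": r.F,
                "df1": r.df_between,
                "df2": r.df_within,
                "p": r.p,
                "pillai": pillai,
                "pillai_p": pillai_p,
            }
        )
    return pd.DataFrame(rows)
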