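"""SPI dimension and pillar scoring.

The Statistical Performance Index is applied hierarchically: a dimension
score is the unweighted mean of its non-missing indicators, and a pillar
score is the (weight-normalised) mean of its defined dimension scores.
Missing indicators contribute nothing to the numerator and are excluded
from the denominator, so a score is the mean over whatever data a region
actually has; it is undefined (NaN) only when every contributing indicator
is missing.  In the default configuration each indicator is its own
dimension with weight 1, so the pillar score reduces to the plain mean of
the pillar's non-missing indicator values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import IndicatorTable, PillarConfig, ValidationError


def dimension_score(
    values: Sequence[tuple[float | None, bool]],
) -> tuple[float, int]:
    """Mean of the non-missing indicator values in one dimension.

    Parameters
    ----------
    values : sequence of (value, missing) pairs
        ``missing=True`` excludes the value from both numerator and
        denominator.

    Returns
    -------
    (score, n_effective) : score is NaN when every value is missing.
    """
    if not values:
        raise ValidationError("dimension with no indicators (misconfigured)")
    present = [v for v, missing in values if not missing]
    if not present:
        return (math.nan, 0)
    return (float(np.mean(present)), len(present))


def pillar_score(
    dim_scores: Sequence[tuple[float, float]],
    n_effectives: Sequence[int] | None = None,
) -> tuple[float, int]:
    """Weighted mean of defined dimension scores.

    Parameters
    ----------
    dim_scores : sequence of (score, weight)
        NaN scores mark undefined dimensions; they are dropped and the
        weight normaliser is the sum of weights over *defined* dimensions,
        which reduces to the plain defined-dimension mean when all weights
        are 1.
    n_effectives : optional per-dimension indicator counts
        Summed into the returned n_effective; defaults to 1 per defined
        dimension.

    Returns
    -------
    (score, n_effective) : score is NaN iff no dimension is defined.
    """
    if not dim_scores:
        raise ValidationError("pillar with no dimensions (misconfigured)")
    weights = [w for _, w in dim_scores]
    if any(w < 0 for w in weights):
        raise ValidationError("negative dimension weight")
    if all(w == 0 for w in weights):
        raise ValidationError("all dimension weights are zero")
    if n_effectives is None:
        n_effectives = [0 if math.isnan(s) else 1 for s, _ in dim_scores]
    num = 0.0
    den = 0.0
    n_eff = 0
    for (s, w), n_i in zip(dim_scores, n_effectives):
        if math.isnan(s):
            continue
        num += w * s
        den += w
        n_eff += n_i
    if den == 0.0 or n_eff == 0:
        return (math.nan, 0)
    return (num / den, n_eff)


class SPIScorer(BaseEstimator, TransformerMixin):
    """Compute per-region SPI pillar scores from an indicator table.

    A stateless transformer in the scikit-learn sense: ``fit`` validates the
    pillar configuration against the table's columns, ``transform`` returns a
    wide region x pillar score frame (NaN = undefined).  Use
    :meth:`score_table` for the long format carrying ``n_effective``.

    Parameters
    ----------
    config : PillarConfig
        Indicator-to-pillar assignment, dimension weights and polarity.
    """

    def __init__(self, config: PillarConfig | None = None):
        self.config = config

    def _table(self, X: IndicatorTable | pd.DataFrame) -> IndicatorTable:
        if isinstance(X, IndicatorTable):
            return X
        return IndicatorTable(values=X, missing_mask=X.isna())

    def fit(self, X: IndicatorTable | pd.DataFrame, y=None) -> "SPIScorer":
        if self.config is None:
            raise ValidationError("SPIScorer requires a PillarConfig")
        table = self._table(X)
        missing_cols = [
            ind for ind in self.config.all_indicators if ind not in table.values.columns
        ]
        if missing_cols:
            raise ValidationError(
                f"config references indicators absent from table: {missing_cols}"
            )
        self.pillars_ = list(self.config.pillars)
        self.feature_names_in_ = np.asarray(table.indicators, dtype=object)
        self.n_features_in_ = len(table.indicators)
        return self

    def transform(self, X: IndicatorTable | pd.DataFrame) -> pd.DataFrame:
        """Wide region x pillar frame of SPI pillar scores."""
        long = self.score_table(X)
        wide = long.pivot(index="region_id", columns="pillar_id", values="score")
        table = self._table(X)
        return wide.reindex(index=table.regions, columns=self.pillars_)

    def score_table(self, X: IndicatorTable | pd.DataFrame) -> pd.DataFrame:
        """Long-format scores: region_id, pillar_id, score, n_effective."""
        if not hasattr(self, "pillars_"):
            self.fit(X)
        table = self._table(X)
        config = self.config
        vals = table.values.to_numpy(dtype=float)
        mask = table.missing_mask.to_numpy(dtype=bool)
        col_ix = {c: j for j, c in enumerate(table.values.columns)}

        rows: list[tuple[str, str, float, int]] = []
        for pillar in config.pillars:
            dims = config.indicator_map[pillar]
            # per-dimension means under the excluded-denominator rule
            dim_means = np.full((vals.shape[0], len(dims)), np.nan)
            dim_neff = np.zeros((vals.shape[0], len(dims)), dtype=int)
            weights = np.array([config.weight(pillar, d) for d, _ in dims])
            for k, (dim_id, inds) in enumerate(dims):
                jj = [col_ix[i] for i in inds]
                sub = vals[:, jj].copy()
                for j_local, ind in enumerate(inds):
                    if config.polarity.get(ind, "direct") == "inverse":
                        sub[:, j_local] = 100.0 - sub[:, j_local]
                sub_mask = mask[:, jj]
                sub = np.where(sub_mask, 0.0, sub)
                counts = (~sub_mask).sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    means = np.where(counts > 0, sub.sum(axis=1) / counts, np.nan)
                dim_means[:, k] = means
                dim_neff[:, k] = counts
            defined = ~np.isnan(dim_means)
            w = np.where(defined, weights[None, :], 0.0)
            num = np.nansum(dim_means * w, axis=1)
            den = w.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pscore = np.where(den > 0, num / den, np.nan)
            neff = dim_neff.sum(axis=1)
            for r, rid in enumerate(table.regions):
                rows.append((rid, pillar, float(pscore[r]), int(neff[r])))
        df = pd.DataFrame(
            rows, columns=["region_id", "pillar_id", "score", "n_effective"]
        )
        return df.sort_values(["region_id", "pillar_id"], kind="stable").reset_index(
            drop=True
        )


def score_all(table: IndicatorTable, config: PillarConfig) -> pd.DataFrame:
    """One (region, pillar) score row per combination; see :class:`SPIScorer`."""
    return SPIScorer(config).fit(table).score_table(table)


def scores_wide(scores_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score table to a region x pillar frame."""
    return scores_long.pivot(index="region_id", columns="pillar_id", values="score")
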