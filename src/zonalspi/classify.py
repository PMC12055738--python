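"""Quartile classification of regions and zonal favourability scores.

Per pillar, regions are split into four performance classes at the 25th,
50th and 75th percentiles of the defined scores (Q1 = poor ... Q4 =
excellent).  A zone's favourability score for a pillar is the percentage of
its regions that land in Q3 or Q4:

    favourability(y, z) = 100 * (# regions of zone z in Q3 or Q4 for pillar y)
                              / (total # regions in zone z)

reported to one decimal, rounding halves away from zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rounding import round_half_away
from .core import RegionRecord, ValidationError, registry_zones

QUANTILE_LABELS: dict[str, str] = {
    "Q1": "poor",
    "Q2": "fair",
    "Q3": "good",
    "Q4": "excellent",
}


class QuantileClassifier(BaseEstimator, TransformerMixin):
    """Assign Q1-Q4 per pillar from percentile cutpoints of the scores.

    ``fit`` learns three ascending cutpoints per pillar (25th/50th/75th
    percentiles, numpy linear interpolation) unless explicit ``cutpoints``
    are supplied; ``transform`` bins scores with the half-open convention
    Q1: s <= c25, Q2: c25 < s <= c50, Q3: c50 < s <= c75, Q4: s > c75 —
    ties at a cutpoint fall to the lower class.  Undefined (NaN) scores
    receive no assignment.

    Parameters
    ----------
    cutpoints : optional mapping pillar -> (c25, c50, c75), or a single
        3-tuple applied to every pillar.  Supplied cutpoints are used
        verbatim, which lets any alternative binning be reproduced.
    """

    def __init__(
        self,
        cutpoints: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
    ):
        self.cutpoints = cutpoints

    @staticmethod
    def _check_ascending(cuts: Sequence[float], pillar: str) -> tuple[float, ...]:
        cuts = tuple(float(c) for c in cuts)
        if len(cuts) != 3 or not (cuts[0] <= cuts[1] <= cuts[2]):
            raise ValidationError(
                f"cutpoints for {pillar!r} must be three ascending values, got {cuts}"
            )
        return cuts

    def fit(self, X: pd.DataFrame, y=None) -> "QuantileClassifier":
        """X: wide region x pillar score frame (NaN = undefined)."""
        self.cutpoints_: dict[str, tuple[float, float, float]] = {}
        for pillar in X.columns:
            if self.cutpoints is not None:
                if isinstance(self.cutpoints, Mapping):
                    cuts = self.cutpoints[pillar]
                else:
                    cuts = self.cutpoints
                self.cutpoints_[pillar] = self._check_ascending(cuts, pillar)
                continue
            defined = X[pillar].dropna().to_numpy(dtype=float)
            if defined.size < 4:
                raise ValidationError(
                    f"pillar {pillar!r}: need >= 4 defined scores to estimate "
                    f"quartile cutpoints, have {defined.size}"
                )
            c25, c50, c75 = np.percentile(defined, [25, 50, 75])
            self.cutpoints_[pillar] = (float(c25), float(c50), float(c75))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Frame of 'Q1'..'Q4' strings aligned with X; NaN stays NaN."""
        out = pd.DataFrame(index=X.index, columns=X.columns, dtype=object)
        for pillar in X.columns:
            c25, c50, c75 = self.cutpoints_[pillar]
            s = X[pillar]
            labels = pd.Series(np.nan, index=s.index, dtype=object)
            labels[s <= c25] = "Q1"
            labels[(s > c25) & (s <= c50)] = "Q2"
            labels[(s > c50) & (s <= c75)] = "Q3"
            labels[s > c75] = "Q4"
            out[pillar] = labels
        return out


def assign_quantiles(
    scores: pd.DataFrame,
    cutpoints: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Long-format quartile assignments for a wide score frame.

    Returns columns region_id, pillar_id, quantile, label; regions with
    undefined scores are omitted.
    """
    clf = QuantileClassifier(cutpoints=cutpoints).fit(scores)
    wide = clf.transform(scores)
    long = (
        wide.rename_axis(index="region_id", columns="pillar_id")
        .stack()
        .rename("quantile")
        .reset_index()
    )
    long["label"] = long["quantile"].map(QUANTILE_LABELS)
    return long.sort_values(["region_id", "pillar_id"], kind="stable").reset_index(
        drop=True
    )


def favourability_score(
    assignments: pd.DataFrame,
    registry: Sequence[RegionRecord],
    pillar_id: str,
    zone: str,
) -> dict:
    """One favourability row: counts and the rounded percentage for a zone.

    The denominator is every region of the zone in the registry — including
    regions whose pillar score is undefined (they are still regions "in the
    zone"); only Q3/Q4 assignments count in the numerator.
    """
    zone_regions = [r.region_id for r in registry if r.zone == zone]
    n_total = len(zone_regions)
    if n_total == 0:
        raise ValidationError(f"zone {zone!r} has no regions in the registry")
    sub = assignments[
        (assignments["pillar_id"] == pillar_id)
        & (assignments["region_id"].isin(zone_regions))
    ]
    n_q34 = int(sub["quantile"].isin(["Q3", "Q4"]).sum())
    score = round_half_away(100.0 * n_q34 / n_total, 1)
    return {
        "zone": zone,
        "pillar_id": pillar_id,
        "n_total": n_total,
        "n_q34": n_q34,
        "score": score,
    }


def favourability_all(
    assignments: pd.DataFrame,
    registry: Sequence[RegionRecord],
    pillars: Sequence[str],
) -> pd.DataFrame:
    """One favourability row per (zone, pillar), zones in registry order."""
    zones: list[str] = []
    for r in registry:
        if r.zone not in zones:
            zones.append(r.zone)
    rows = [
        favourability_score(assignments, registry, pillar, zone)
        for zone in zones
        for pillar in pillars
    ]
    return pd.DataFrame(rows)


def quantile_occupancy(assignments: pd.DataFrame) -> pd.DataFrame:
    """National share of regions in each quartile per pillar (percent, 2 dp).

    Mirrors the nationwide occupancy summary (e.g. the share of all regions
    falling in the fourth quantile for a pillar).
    """
    rows = []
    for pillar, sub in assignments.groupby("pillar_id", sort=False):
        n = len(sub)
        for q in ("Q1", "Q2", "Q3", "Q4"):
            share = 100.0 * (sub["quantile"] == q).sum() / n if n else math.nan
            rows.append(
                {
                    "pillar_id": pillar,
                    "quantile": q,
                    "n": int((sub["quantile"] == q).sum()),
                    "share": round_half_away(share, 2),
                }
            )
    return pd.DataFrame(rows)


def favourability_pivot(fav: pd.DataFrame, pillars: Sequence[str]) -> pd.DataFrame:
    """Zone-per-row layout: n_total, per-pillar Q3+Q4 counts, per-pillar scores."""
    out = fav.pivot(index="zone", columns="pillar_id", values=["n_q34", "score"])
    n_total = fav.drop_duplicates("zone").set_index("zone")["n_total"]
    table = pd.DataFrame(index=out.index)
    table["n_total"] = n_total
    for p in pillars:
        table[f"n_q34_{p}"] = out[("n_q34", p)]
    for p in pillars:
        table[f"fav_{p}"] = out[("score", p)]
    return table.reset_index()
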