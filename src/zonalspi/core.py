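"""Domain types and CSV readers/writers for the zonal disparity pipeline.

The unit of analysis is a *region*: the urban or rural stratum of an Indian
state or union territory (e.g. ``u_Assam`` = urban Assam).  Regions belong to
one of the six Zonal Council zones (Central, East, North, Northeast, South,
West).  Indicator values are survey percentages on [0, 100]; missing cells are
carried explicitly in a boolean mask rather than coerced to a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ZONES: tuple[str, ...] = ("C", "E", "N", "NE", "S", "W")
RESIDENCES: tuple[str, ...] = ("urban", "rural")
PILLARS: tuple[str, ...] = ("MHU", "WE", "DC")

DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "."})


class ValidationError(ValueError):
    """Raised when an input file or configuration violates the data contract."""


@dataclass(frozen=True)
class RegionRecord:
    """One survey region: an urban/rural stratum of a state or UT."""

    region_id: str
    state: str
    zone: str
    residence: str

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValidationError(
                f"region {self.region_id!r}: unknown zone {self.zone!r}; "
                f"expected one of {ZONES}"
            )
        if self.residence not in RESIDENCES:
            raise ValidationError(
                f"region {self.region_id!r}: residence must be 'urban' or "
                f"'rural', got {self.residence!r}"
            )


@dataclass
class IndicatorTable:
    """Region x indicator percentage matrix with an explicit missing mask.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by region_id, columns by indicator_id.  Missing cells
        hold NaN.
    missing_mask : pandas.DataFrame
        Boolean frame aligned with ``values``; True marks a missing cell.
    survey_round : str
        Tag for the survey round the values come from (e.g. "NFHS-5").
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    survey_round: str = "NFHS-5"

    def __post_init__(self) -> None:
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError(
                "values and missing_mask shapes differ: "
                f"{self.values.shape} vs {self.missing_mask.shape}"
            )
        arr = self.values.to_numpy(dtype=float)
        mask = self.missing_mask.to_numpy(dtype=bool)
        present = arr[~mask]
        bad = present[(present < 0) | (present > 100)]
        if bad.size:
            raise ValidationError(
                f"indicator values outside [0, 100]: first offender {bad[0]!r}"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PillarConfig:
    """Assignment of indicators to pillars and dimensions, with weights.

    ``indicator_map`` maps each pillar to an ordered list of
    ``(dimension_id, [indicator_id, ...])`` pairs.  In the default analysis
    every indicator is its own dimension with weight 1, which reduces the
    pillar score to the unweighted mean of non-missing indicators.
    ``polarity`` marks indicators whose raw value is inverted (100 - x)
    before aggregation; the default is ``direct`` for every indicator.
    """

    pillars: list[str]
    indicator_map: dict[str, list[tuple[str, list[str]]]]
    dimension_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    polarity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pillar in self.pillars:
            dims = self.indicator_map.get(pillar, [])
            if not dims:
                raise ValidationError(f"pillar {pillar!r} has no dimensions")
            any_positive = False
            for dim_id, inds in dims:
                if not inds:
                    raise ValidationError(
                        f"dimension {dim_id!r} of pillar {pillar!r} has no indicators"
                    )
                w = self.dimension_weights.get((pillar, dim_id), 1.0)
                if w < 0:
                    raise ValidationError(
                        f"negative weight for dimension {dim_id!r} of {pillar!r}"
                    )
                if w > 0:
                    any_positive = True
                for ind in inds:
                    if ind in seen:
                        raise ValidationError(
                            f"indicator {ind!r} assigned to both "
                            f"{seen[ind]!r} and {pillar!r}"
                        )
                    seen[ind] = pillar
            if not any_positive:
                raise ValidationError(f"all dimension weights of {pillar!r} are zero")
        for ind, pol in self.polarity.items():
            if pol not in ("direct", "inverse"):
                raise ValidationError(
                    f"polarity for {ind!r} must be 'direct' or 'inverse', got {pol!r}"
                )

    def weight(self, pillar: str, dimension: str) -> float:
        return self.dimension_weights.get((pillar, dimension), 1.0)

    @property
    def all_indicators(self) -> list[str]:
        out: list[str] = []
        for pillar in self.pillars:
            for _, inds in self.indicator_map[pillar]:
                out.extend(inds)
        return out


def read_region_registry(path: str | Path) -> list[RegionRecord]:
    """Read a region registry CSV with columns region_id,state,zone,residence."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"region_id", "state", "zone", "residence"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"registry {path}: missing columns {sorted(required - set(df.columns))}"
        )
    records: list[RegionRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rid = row["region_id"]
        if rid in seen:
            raise ValidationError(f"registry {path}: duplicate region_id {rid!r}")
        seen.add(rid)
        try:
            records.append(
                RegionRecord(rid, row["state"], row["zone"], row["residence"])
            )
        except ValidationError as exc:
            raise ValidationError(f"registry {path}, row {i + 2}: {exc}") from exc
    return records


def write_region_registry(records: Sequence[RegionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.region_id, r.state, r.zone, r.residence) for r in records],
        columns=["region_id", "state", "zone", "residence"],
    ).to_csv(path, index=False)


def registry_zones(records: Sequence[RegionRecord]) -> pd.Series:
    """Zone of each region as a Series indexed by region_id."""
    return pd.Series(
        {r.region_id: r.zone for r in records}, name="zone", dtype="object"
    )


def read_indicator_table(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    survey_round: str = "NFHS-5",
) -> IndicatorTable:
    """Read a wide CSV (first column region_id, one column per indicator).

    Cells equal to any token in ``missing_tokens`` (after stripping) are
    treated as missing; everything else must parse as a number in [0, 100].
    """
    tokens = set(missing_tokens)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.columns[0] != "region_id":
        raise ValidationError(f"{path}: first column must be 'region_id'")
    raw = raw.set_index("region_id")
    values = pd.DataFrame(
        np.nan, index=raw.index, columns=raw.columns, dtype=float
    )
    mask = pd.DataFrame(False, index=raw.index, columns=raw.columns, dtype=bool)
    for col in raw.columns:
        for rid, cell in raw[col].items():
            cell = cell.strip()
            if cell in tokens:
                mask.loc[rid, col] = True
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: cell ({rid}, {col}) = {cell!r} is not numeric"
                ) from exc
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{path}: cell ({rid}, {col}) = {v} outside [0, 100]"
                )
            values.loc[rid, col] = v
    return IndicatorTable(values=values, missing_mask=mask, survey_round=survey_round)


def write_indicator_table(table: IndicatorTable, path: str | Path) -> None:
    """Write the wide CSV; missing cells become empty strings."""
    out = table.values.copy()
    out = out.where(~table.missing_mask, other=np.nan)
    out.index.name = "region_id"
    out.to_csv(path, na_rep="")


def read_pillar_config(path: str | Path) -> PillarConfig:
    """Read a YAML pillar configuration.

    Expected layout::

        pillars:
          MHU:
            dimensions:
              anc_first_trimester: [anc_first_trimester]
            weights:            # optional, default 1
              anc_first_trimester: 1.0
        polarity:               # optional, default direct
          some_indicator: inverse

    A dimension may also be given as a bare list of indicator ids under the
    pillar, in which case each indicator becomes its own dimension.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "pillars" not in doc:
        raise ValidationError(f"{path}: missing top-level 'pillars' key")
    pillars: list[str] = []
    indicator_map: dict[str, list[tuple[str, list[str]]]] = {}
    weights: dict[tuple[str, str], float] = {}
    for pillar, body in doc["pillars"].items():
        pillars.append(pillar)
        dims: list[tuple[str, list[str]]] = []
        if isinstance(body, list):
            # shorthand: each indicator is its own dimension
            dims = [(ind, [ind]) for ind in body]
        else:
            for dim_id, inds in (body.get("dimensions") or {}).items():
                if isinstance(inds, str):
                    inds = [inds]
                dims.append((dim_id, list(inds)))
            for dim_id, w in (body.get("weights") or {}).items():
                weights[(pillar, dim_id)] = float(w)
        indicator_map[pillar] = dims
    polarity = {k: str(v) for k, v in (doc.get("polarity") or {}).items()}
    return PillarConfig(
        pillars=pillars,
        indicator_map=indicator_map,
        dimension_weights=weights,
        polarity=polarity,
    )


def write_pillar_config(config: PillarConfig, path: str | Path) -> None:
    doc: dict = {"pillars": {}}
    for pillar in config.pillars:
        dims = {d: list(inds) for d, inds in config.indicator_map[pillar]}
        body: dict = {"dimensions": dims}
        ws = {
            d: config.dimension_weights[(pillar, d)]
            for d, _ in config.indicator_map[pillar]
            if (pillar, d) in config.dimension_weights
        }
        if ws:
            body["weights"] = ws
        doc["pillars"][pillar] = body
    if config.polarity:
        doc["polarity"] = dict(config.polarity)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write long-format pillar scores (region_id,pillar_id,score,n_effective).

    Undefined scores (NaN) are serialised as empty cells; no rounding.
    """
    if scores.empty:
        raise ValidationError("refusing to write an empty score table")
    cols = ["region_id", "pillar_id", "score", "n_effective"]
    scores[cols].to_csv(path, index=False, na_rep="")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["n_effective"] = df["n_effective"].astype(int)
    return df


def check_regions_resolve(
    table: IndicatorTable, registry: Sequence[RegionRecord]
) -> None:
    """Every region in the table must exist in the registry (hard error)."""
    known = {r.region_id for r in registry}
    unknown = [rid for rid in table.regions if rid not in known]
    if unknown:
        raise ValidationError(
            f"regions not present in registry: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
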