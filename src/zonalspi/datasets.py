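"""Small reference datasets used in examples and desk checks."""

from __future__ import annotations

import pandas as pd

from .core import PILLARS, RegionRecord

# Published zonal quartile counts for NFHS-5 (2019-21) regions of India:
# per zone, the total number of regions and the number landing in Q3 or Q4
# for each pillar (maternal healthcare utilisation, women empowerment,
# delivery care).  Zone totals sum to 71 regions.
ZONAL_QUANTILE_COUNTS: dict[str, dict] = {
    "C": {"n_total": 6, "MHU": 4, "WE": 1, "DC": 2},
    "E": {"n_total": 8, "MHU": 4, "WE": 3, "DC": 4},
    "N": {"n_total": 17, "MHU": 15, "WE": 13, "DC": 10},
    "NE": {"n_total": 16, "MHU": 5, "WE": 12, "DC": 9},
    "S": {"n_total": 16, "MHU": 16, "WE": 15, "DC": 16},
    "W": {"n_total": 8, "MHU": 8, "WE": 4, "DC": 5},
}


def zonal_quantile_counts() -> pd.DataFrame:
    """The published per-zone Q3+Q4 counts as a tidy frame."""
    rows = []
    for zone, body in ZONAL_QUANTILE_COUNTS.items():
        for pillar in PILLARS:
            rows.append(
                {
                    "zone": zone,
                    "pillar_id": pillar,
                    "n_total": body["n_total"],
                    "n_q34": body[pillar],
                }
            )
    return pd.DataFrame(rows)


def counts_registry() -> list[RegionRecord]:
    """A registry with the published zone totals (region ids are synthetic)."""
    records = []
    for zone, body in ZONAL_QUANTILE_COUNTS.items():
        for k in range(body["n_total"]):
            state = f"{zone}{k // 2 + 1:02d}"
            residence = "urban" if k % 2 == 0 else "rural"
            prefix = "u" if residence == "urban" else "r"
            records.append(RegionRecord(f"{prefix}_{state}", state, zone, residence))
    return records


def counts_as_assignments() -> tuple[pd.DataFrame, list[RegionRecord]]:
    """Expand the published counts into per-region quartile assignments.

    For each zone and pillar, the first ``n_q34`` regions are marked Q3 and
    the rest Q1 — which regions carry the Q3/Q4 labels does not affect the
    zonal favourability score, only the counts do.
    """
    registry = counts_registry()
    by_zone: dict[str, list[str]] = {}
    for r in registry:
        by_zone.setdefault(r.zone, []).append(r.region_id)
    rows = []
    for zone, body in ZONAL_QUANTILE_COUNTS.items():
        for pillar in PILLARS:
            for i, rid in enumerate(by_zone[zone]):
                q = "Q3" if i < body[pillar] else "Q1"
                rows.append({"region_id": rid, "pillar_id": pillar, "quantile": q})
    return pd.DataFrame(rows), registry
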