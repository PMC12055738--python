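"""Markdown report rendering from pipeline artifact CSVs.

Rendering is a pure function of the CSV artifacts: no statistic is ever
recomputed here, only formatted.  Percentages print at 1 decimal, mean
differences at 2, F statistics at 3, all rounding halves away from zero.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._rounding import round_half_away
from .core import ValidationError

ARTIFACTS = {
    "favourability": "favourability.csv",
    "inference": "inference.csv",
    "posthoc": "posthoc.csv",
    "regression": "regression.csv",
    "occupancy": "occupancy.csv",
}


def _fmt(x: float, nd: int) -> str:
    return f"{round_half_away(float(x), nd):.{nd}f}"


def _load(artifact_dir: Path, key: str) -> pd.DataFrame:
    path = artifact_dir / ARTIFACTS[key]
    if not path.exists():
        raise ValidationError(
            f"missing artifact {path.name}; rerun the {key!r} stage"
        )
    return pd.read_csv(path)


def render_report(artifact_dir: str | Path) -> str:
    """Assemble the zonal disparity report from a pipeline output directory."""
    d = Path(artifact_dir)
    fav = _load(d, "favourability")
    inf = _load(d, "inference")
    post = _load(d, "posthoc")
    reg = _load(d, "regression")
    occ = _load(d, "occupancy")

    pillars = list(dict.fromkeys(fav["pillar_id"]))
    lines: list[str] = ["# Zonal disparity report", ""]

    lines += ["## Favourability of zones", ""]
    header = (
        "| Zone | Total regions | "
        + " | ".join(f"Q3+Q4 {p}" for p in pillars)
        + " | "
        + " | ".join(f"Fav. {p} (%)" for p in pillars)
        + " |"
    )
    lines.append(header)
    lines.append("|" + "---|" * (2 + 2 * len(pillars)))
    for zone in dict.fromkeys(fav["zone"]):
        sub = fav[fav["zone"] == zone].set_index("pillar_id")
        n_total = int(sub["n_total"].iloc[0])
        counts = " | ".join(str(int(sub.loc[p, "n_q34"])) for p in pillars)
        scores = " | ".join(_fmt(sub.loc[p, "score"], 1) for p in pillars)
        lines.append(f"| {zone} | {n_total} | {counts} | {scores} |")
    lines.append("")

    lines += ["## National quartile occupancy (%)", ""]
    lines.append("| Pillar | Q1 | Q2 | Q3 | Q4 |")
    lines.append("|---|---|---|---|---|")
    for p in dict.fromkeys(occ["pillar_id"]):
        sub = occ[occ["pillar_id"] == p].set_index("quantile")
        cells = " | ".join(_fmt(sub.loc[q, "share"], 2) for q in ("Q1", "Q2", "Q3", "Q4"))
        lines.append(f"| {p} | {cells} |")
    lines.append("")

    lines += ["## Zonal variation (one-way F per pillar)", ""]
    lines.append("| Pillar | F | df | p |")
    lines.append("|---|---|---|---|")
    for _, r in inf.iterrows():
        lines.append(
            f"| {r['pillar_id']} | {_fmt(r['F'], 3)} | "
            f"({int(r['df1'])}, {int(r['df2'])}) | {r['p']:.3g} |"
        )
    if "pillai" in inf.columns and pd.notna(inf["pillai"]).any():
        pillai = inf["pillai"].dropna().iloc[0]
        pillai_p = inf["pillai_p"].dropna().iloc[0]
        lines.append("")
        lines.append(
            f"Multivariate test: Pillai's trace = {_fmt(pillai, 3)}, "
            f"p = {pillai_p:.3g}."
        )
    lines.append("")

    lines += ["## Bonferroni pairwise comparisons (significant pairs)", ""]
    sig = post[post["significant"]]
    if sig.empty:
        lines.append("none significant")
    else:
        lines.append("| Pillar | Zone | vs Zone | Mean difference | |")
        lines.append("|---|---|---|---|---|")
        for _, r in sig.iterrows():
            star = "**" if r["p_adj"] < 0.001 else "*"
            lines.append(
                f"| {r['pillar_id']} | {r['zone_a']} | {r['zone_b']} | "
                f"{_fmt(r['mean_diff'], 2)} | {star} |"
            )
        lines.append("")
        lines.append("\\* p < .05, \\*\\* p < .001 (Bonferroni-adjusted)")
    lines.append("")

    lines += ["## Regression of MHU on WE", ""]
    r = reg.iloc[0]
    lines.append(
        f"MHU = {_fmt(r['slope'], 3)} x WE + {_fmt(r['intercept'], 3)}, "
        f"R^2 = {_fmt(r['r_squared'], 3)}, n = {int(r['n'])}"
    )
    lines.append("")
    return "\n".join(lines)
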