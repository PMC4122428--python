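"""Human-readable markdown report over a pipeline results directory."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort_stats import OVERALL, days_to_years

_GROUP_TITLES = {
    "low": "Low risk",
    "increased": "Increased risk",
    "diabetes": "Diabetes",
    OVERALL: "Overall",
}
_ENDPOINT_TITLES = {
    "duration_days": "Duration of medication (days)",
    "interval_days": "Interval detection 5.7% to 6.5% (days)",
}


def _fmt(x, nd=1) -> str:
    if pd.isna(x):
        return "-"
    return f"{x:.{nd}f}"


def render_report(results_dir: str | Path, days_per_year: float = 365.0) -> str:
    """Render ledger, characteristics and endpoint tables as markdown.

    The endpoint table mirrors the published layout: per-group and overall
    mean/SE for the medication delay and the crossing interval, plus a
    years-equivalent row for the interval using ``days_per_year``.
    """
    results_dir = Path(results_dir)
    ledger = pd.read_csv(results_dir / "ledger.csv")
    table2 = pd.read_csv(results_dir / "table2.csv")

    lines = ["# Progression analysis report", "", "## Exclusion cascade", ""]
    lines += ["| stage | n |", "|---|---|"]
    lines += [f"| {r.stage} | {r.n} |" for r in ledger.itertuples()]

    groups = [g for g in _GROUP_TITLES if g in set(table2["group"])]
    lines += ["", "## Endpoints by risk group", ""]
    header = "| endpoint | stat | " + " | ".join(_GROUP_TITLES[g] for g in groups) + " | p |"
    lines += [header, "|" + "---|" * (len(groups) + 3)]
    for var, sub in table2.groupby("variable", sort=False):
        sub = sub.set_index("group")
        p = _fmt(sub["p"].iloc[0], 4)
        for stat in ("n", "mean", "se"):
            cells = [
                _fmt(sub.loc[g, stat], 0 if stat == "n" else 1) if g in sub.index else "-"
                for g in groups
            ]
            lines.append(
                f"| {_ENDPOINT_TITLES.get(var, var)} | {stat} | "
                + " | ".join(cells) + f" | {p if stat == 'n' else ''} |"
            )
        if var == "interval_days":
            years = [
                _fmt(days_to_years(sub.loc[g, "mean"], days_per_year, 2), 2)
                if g in sub.index and pd.notna(sub.loc[g, "mean"]) else "-"
                for g in groups
            ]
            lines.append(
                f"| {_ENDPOINT_TITLES[var]} | years | " + " | ".join(years) + " |  |"
            )

    t1_path = results_dir / "table1.csv"
    if t1_path.exists():
        table1 = pd.read_csv(t1_path)
        lines += ["", "## Baseline characteristics", ""]
        lines += ["| variable | stat | " + " | ".join(
            _GROUP_TITLES[g] for g in ("low", "increased", "diabetes")) + " | p |"]
        lines += ["|" + "---|" * 6]
        for r in table1.itertuples():
            lines.append(
                f"| {r.variable} | {r.stat} | {_fmt(r.low)} | {_fmt(r.increased)} "
                f"| {_fmt(r.diabetes)} | {_fmt(r.p, 4)} |"
            )
    empty = [g for g in ("low", "increased", "diabetes")
             if g in set(table2["group"]) and (table2.set_index("group").loc[g, "n"] == 0).any()]
    if empty:
        lines += ["", f"Note: empty group(s): {', '.join(empty)}."]
    return "\n".join(lines) + "\n"
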