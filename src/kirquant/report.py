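"""Assemble per-arm summary tables and the combined comparisons report.

Each analysis arm contributes one CSV: the ephys group table (per-cell
current densities and group summaries), the blot fold-change table, and the
per-cell trafficking table.  WT-vs-MT comparisons from all present arms are
pooled into a single comparisons CSV with deterministic column order, and
the seed/config provenance is echoed alongside so a rerun at the same seed
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .stats import GroupComparison

__all__ = ["build_report", "violin_plot"]

_COMPARISON_COLUMNS = ["arm", "metric", "groups", "n", "test", "statistic", "p_value", "stars"]


def build_report(
    out_dir: str | Path,
    ephys_cells: pd.DataFrame | None = None,
    ephys_groups: pd.DataFrame | None = None,
    blot_lanes: pd.DataFrame | None = None,
    cell_metrics: pd.DataFrame | None = None,
    comparisons: Mapping[tuple[str, str], GroupComparison] | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Write one CSV per present arm plus a combined comparisons CSV.

    ``comparisons`` maps (arm, metric) -> GroupComparison.  Absent arms are
    simply omitted; at least one arm must be present.  Returns the written
    tables keyed by file stem.
    """
    arms = {
        "ephys_cells": ephys_cells,
        "ephys_groups": ephys_groups,
        "blot_lanes": blot_lanes,
        "cell_metrics": cell_metrics,
    }
    present = {k: v for k, v in arms.items() if v is not None}
    if not present and not comparisons:
        raise ValueError("no analysis arm present; nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, pd.DataFrame] = {}
    for name, df in present.items():
        df = df.reset_index(drop=True)
        df.to_csv(out / f"{name}.csv", index=False)
        written[name] = df
    if comparisons:
        rows = []
        for (arm, metric), cmp in sorted(comparisons.items()):
            rows.append({"arm": arm, "metric": metric, **cmp.as_row()})
        cmp_df = pd.DataFrame(rows, columns=_COMPARISON_COLUMNS)
        cmp_df.to_csv(out / "comparisons.csv", index=False)
        written["comparisons"] = cmp_df
    provenance = {"seed": seed, "config": config or {}}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return written


def violin_plot(
    df: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    ylabel: str = "",
    path: str | Path | None = None,
):
    """Cosmetic per-group violin plot (SVG when ``path`` is given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(df[group_col].unique())
    data = [df.loc[df[group_col] == g, value_col].dropna().to_numpy() for g in groups]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 3.2))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_ylabel(ylabel or value_col)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
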