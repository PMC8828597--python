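"""SVG exports: radar plots of marker-panel ENFC and SUSP scatter plots.

Figures are presentation aids; the underlying CSVs carry the same numbers
and are the layout-independent record.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .susp import SuspDataset

__all__ = ["radar_panel", "susp_figure"]

#: Compartment axis labels in radar-plot order.
COMPARTMENT_ABBREV = {
    "adipose": "ADI",
    "cerebellum": "CEB",
    "heart": "HEA",
    "liver": "LIV",
    "right brain": "RiB",
    "brain": "BRA",
    "serum": "SER",
}


def radar_panel(
    panel_tables: list[pd.DataFrame], variable: str, path: str | Path
) -> Path:
    """Radar plot for one panel member: axes = compartments, one trace per
    comparison.

    ``panel_tables`` are outputs of :func:`lipidtraffic.abundance.panel_enfc`
    (one per comparison); missing ENFC values break the trace rather than
    being drawn as zero.
    """
    path = Path(path)
    compartments = sorted(
        {c for t in panel_tables for c in t["compartment"].unique()},
        key=lambda c: COMPARTMENT_ABBREV.get(c, c.upper()),
    )
    angles = [2 * math.pi * i / len(compartments) for i in range(len(compartments))]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    for table in panel_tables:
        sub = table[table["variable"] == variable].set_index("compartment")
        values = [
            sub["enfc"].get(c, np.nan) if c in sub.index else np.nan
            for c in compartments
        ]
        vals = [np.nan if pd.isna(v) else float(v) for v in values]
        comparison = table["comparison"].iloc[0] if len(table) else ""
        ax.plot(
            angles + angles[:1],
            vals + vals[:1],
            marker="o",
            label=str(comparison),
        )
    ax.set_xticks(angles)
    ax.set_xticklabels([COMPARTMENT_ABBREV.get(c, c.upper()) for c in compartments])
    ax.set_title(variable, pad=18)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path


def susp_figure(dataset: SuspDataset, path: str | Path) -> Path:
    """SUSP scatter: shared points in 2D, unique variables as axis rugs."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if dataset.shared_points:
        xs, ys = zip(*dataset.shared_points.values())
        ax.scatter(xs, ys, s=14, alpha=0.7, label="shared")
    if dataset.unique_x:
        ax.plot(
            list(dataset.unique_x.values()),
            [0] * len(dataset.unique_x),
            "|",
            color="tab:orange",
            markersize=12,
            label=f"unique to {dataset.comparison_x}",
        )
    if dataset.unique_y:
        ax.plot(
            [0] * len(dataset.unique_y),
            list(dataset.unique_y.values()),
            "_",
            color="tab:green",
            markersize=12,
            label=f"unique to {dataset.comparison_y}",
        )
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(f"ENFC {dataset.comparison_x}")
    ax.set_ylabel(f"ENFC {dataset.comparison_y}")
    ax.set_title(dataset.compartment)
    ax.legend(fontsize=8)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path
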