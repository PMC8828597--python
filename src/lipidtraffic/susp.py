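"""Shared and Unique Structures Plot (SUSP) data.

A SUSP contrasts two comparisons (e.g. NN vs NH and HH vs HN) through the
per-variable ENFC measured in one compartment.  Variables with a defined
ENFC in both comparisons form a 2D point cloud (shared); variables defined
in only one comparison are listed as unique to that side.  A lipid whose
abundance is programmed through sperm alone should shift in one comparison
but not the other, so the interesting structure is asymmetry of the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SuspDataset", "build_susp"]


@dataclass
class SuspDataset:
    """Per-variable ENFC in one compartment across two comparisons."""

    compartment: str
    comparison_x: str
    comparison_y: str
    shared_points: dict[str, tuple[float, float]] = field(default_factory=dict)
    unique_x: dict[str, float] = field(default_factory=dict)
    unique_y: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: variable, group (shared/unique_x/unique_y), x, y."""
        rows = []
        for v, (x, y) in sorted(self.shared_points.items()):
            rows.append({"variable": v, "group": "shared", "enfc_x": x, "enfc_y": y})
        for v, x in sorted(self.unique_x.items()):
            rows.append({"variable": v, "group": "unique_x", "enfc_x": x, "enfc_y": None})
        for v, y in sorted(self.unique_y.items()):
            rows.append({"variable": v, "group": "unique_y", "enfc_x": None, "enfc_y": y})
        df = pd.DataFrame(rows, columns=["variable", "group", "enfc_x", "enfc_y"])
        df.insert(0, "compartment", self.compartment)
        return df


def _defined(enfc_table: pd.DataFrame, compartment: str) -> dict[str, float]:
    sub = enfc_table[enfc_table["compartment"] == compartment]
    return {
        r["variable"]: float(r["enfc"])
        for _, r in sub.iterrows()
        if pd.notna(r["enfc"])
    }


def build_susp(
    enfc_x: pd.DataFrame,
    enfc_y: pd.DataFrame,
    compartment: str,
    comparison_x: str = "x",
    comparison_y: str = "y",
) -> SuspDataset:
    """Split variables into shared and comparison-unique ENFC points.

    ``enfc_x`` and ``enfc_y`` are long-format ENFC tables (from
    :func:`lipidtraffic.abundance.enfc_table`) for the two comparisons; both
    must cover ``compartment``.  A variable with a defined ENFC in both
    lands in ``shared_points``; one defined on a single side is unique to it.
    """
    for label, tab in (("first", enfc_x), ("second", enfc_y)):
        if compartment not in set(tab["compartment"]):
            raise ValueError(
                f"compartment {compartment!r} absent from the {label} ENFC table"
            )
    xs = _defined(enfc_x, compartment)
    ys = _defined(enfc_y, compartment)
    ds = SuspDataset(compartment, comparison_x, comparison_y)
    for v in sorted(set(xs) | set(ys)):
        if v in xs and v in ys:
            ds.shared_points[v] = (xs[v], ys[v])
        elif v in xs:
            ds.unique_x[v] = xs[v]
        else:
            ds.unique_y[v] = ys[v]
    return ds
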