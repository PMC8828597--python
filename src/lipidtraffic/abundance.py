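"""Abundance Analysis: margin change and error-normalised fold change.

For a lipid variable in one compartment, the experimental group E is
compared with the control group C through two descriptive dimensions:

* margin change  =  x̄_E − x̄_C                       (intensity units)
* ENFC  =  log10(x̄_E / x̄_C) / sqrt((a² + b²) / 2)    (dimensionless)

where x̄ is the group mean intensity and a, b are the relative errors of
the experimental and control groups.  Here a and b are coefficients of
variation (SD/mean): the CV is dimensionless, which keeps the denominator
commensurate with a log ratio and makes ENFC invariant to common rescaling
of the intensities.  SEM/mean is available as an alternative.

ENFC is undefined (reported as missing, with a reason) when either mean is
non-positive or both relative errors are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lipids import LipidVariable, parse_lipid_name
from .presence import AbundanceTable, PRESENCE_THRESHOLD

__all__ = [
    "GroupSummary",
    "MarkerPanel",
    "DNL_TG_PANEL",
    "DIETARY_TG_PANEL",
    "ABUNDANT_PC_PANEL",
    "BUNDLED_PANELS",
    "summarise_group",
    "margin_change",
    "enfc",
    "enfc_table",
    "panel_enfc",
    "normalise_per_mille",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean and relative error of one group's intensities for one variable."""

    mean: float
    relative_error: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.relative_error < 0:
            raise ValueError("group mean and relative error must be non-negative")


@dataclass(frozen=True)
class MarkerPanel:
    """A named panel of marker lipids with a shared biological origin."""

    name: str
    members: tuple[LipidVariable, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"marker panel {self.name!r} has no members")


def _panel(name: str, names: Sequence[str]) -> MarkerPanel:
    return MarkerPanel(name, tuple(parse_lipid_name(n) for n in names))


#: TGs synthesised de novo from carbohydrate: short, saturated species.
DNL_TG_PANEL = _panel("dnl_tg", ["TG(46:0)", "TG(46:1)", "TG(48:0)", "TG(48:1)"])
#: TGs tracking dietary fat intake: longer, unsaturated species.
DIETARY_TG_PANEL = _panel(
    "dietary_tg", ["TG(52:2)", "TG(54:4)", "TG(54:8)", "TG(56:7)"]
)
#: The most abundant membrane phosphatidylcholines.
ABUNDANT_PC_PANEL = _panel(
    "abundant_pc", ["PC(34:1)", "PC(34:2)", "PC(36:4)", "PC(38:4)"]
)

BUNDLED_PANELS: dict[str, MarkerPanel] = {
    p.name: p for p in (DNL_TG_PANEL, DIETARY_TG_PANEL, ABUNDANT_PC_PANEL)
}


def normalise_per_mille(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample's row to sum to 1000 (relative abundance, per mille).

    Samples with an all-zero row are left at zero.
    """
    values = table.values.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, values / totals * 1000.0, 0.0)
    return AbundanceTable(
        compartment=table.compartment,
        phenotype=table.phenotype,
        values=pd.DataFrame(
            scaled, index=table.values.index, columns=table.values.columns
        ),
        variables=list(table.variables),
        ionisation_mode=table.ionisation_mode,
    )


def summarise_group(
    intensities: Iterable[float], error_model: str = "cv"
) -> GroupSummary:
    """Mean and relative error (CV by default, SEM/mean as ``"sem"``)."""
    x = np.asarray(list(intensities), dtype=float)
    x = np.nan_to_num(x, nan=0.0)
    mean = float(x.mean())
    if mean <= 0:
        return GroupSummary(mean=max(mean, 0.0), relative_error=0.0)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if error_model == "cv":
        rel = sd / mean
    elif error_model == "sem":
        rel = sd / math.sqrt(x.size) / mean
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return GroupSummary(mean=mean, relative_error=rel)


def margin_change(experimental: GroupSummary, control: GroupSummary) -> float:
    """Difference of group means, x̄_E − x̄_C (intensity units)."""
    return experimental.mean - control.mean


def enfc(experimental: GroupSummary, control: GroupSummary) -> float:
    """Error-normalised fold change: log10(x̄_E/x̄_C) / sqrt((a²+b²)/2).

    Raises
    ------
    ValueError
        When either mean is non-positive or both relative errors are zero;
        tabulating callers catch this and report the variable as missing
        with the reason.
    """
    if experimental.mean <= 0 or control.mean <= 0:
        raise ValueError("ENFC undefined: non-positive group mean")
    a, b = experimental.relative_error, control.relative_error
    denom = math.sqrt((a * a + b * b) / 2.0)
    if denom == 0:
        raise ValueError("ENFC undefined: both relative errors are zero")
    return math.log10(experimental.mean / control.mean) / denom


def enfc_table(
    control_tables: Mapping[str, AbundanceTable],
    experimental_tables: Mapping[str, AbundanceTable],
    comparison: str = "",
    normalise: bool = True,
    require_presence: bool = True,
    presence_threshold: float = PRESENCE_THRESHOLD,
    error_model: str = "cv",
) -> pd.DataFrame:
    """Long-format ENFC table over all shared compartments and variables.

    Parameters
    ----------
    control_tables, experimental_tables:
        Per-compartment abundance tables for the two groups; the control
        group is always the denominator of the fold change.
    normalise:
        Apply per-mille relative-abundance normalisation per sample first.
    require_presence:
        Exclude variables failing the presence call in either group for
        the compartment (avoids ratios of noise); excluded and undefined
        variables appear with an empty ENFC and a ``reason``.

    Returns a DataFrame with columns: comparison, compartment, variable,
    lipid_class, mean_control, mean_experimental, rel_err_control,
    rel_err_experimental, margin_change, enfc, reason.
    """
    from .presence import call_presence  # local import to avoid cycle at module load

    rows = []
    compartments = [c for c in control_tables if c in experimental_tables]
    for comp in compartments:
        ct, et = control_tables[comp], experimental_tables[comp]
        if normalise:
            ct, et = normalise_per_mille(ct), normalise_per_mille(et)
        pres_c = call_presence(ct, presence_threshold) if require_presence else None
        pres_e = call_presence(et, presence_threshold) if require_presence else None
        var_map = {**et.variable_map(), **ct.variable_map()}
        shared = [n for n in ct.values.columns if n in set(et.values.columns)]
        for name in shared:
            var = var_map[name]
            cs = summarise_group(ct.values[name], error_model)
            es = summarise_group(et.values[name], error_model)
            reason = ""
            value: float | None = None
            if require_presence and not (
                pres_c.calls[(comp, name)] and pres_e.calls[(comp, name)]
            ):
                reason = "below presence threshold"
            else:
                try:
                    value = enfc(es, cs)
                except ValueError as e:
                    reason = str(e)
            rows.append(
                {
                    "comparison": comparison,
                    "compartment": comp,
                    "variable": name,
                    "lipid_class": var.lipid_class,
                    "mean_control": cs.mean,
                    "mean_experimental": es.mean,
                    "rel_err_control": cs.relative_error,
                    "rel_err_experimental": es.relative_error,
                    "margin_change": margin_change(es, cs),
                    "enfc": value,
                    "reason": reason,
                }
            )
    cols = [
        "comparison",
        "compartment",
        "variable",
        "lipid_class",
        "mean_control",
        "mean_experimental",
        "rel_err_control",
        "rel_err_experimental",
        "margin_change",
        "enfc",
        "reason",
    ]
    return pd.DataFrame(rows, columns=cols)


def panel_enfc(
    control_tables: Mapping[str, AbundanceTable],
    experimental_tables: Mapping[str, AbundanceTable],
    panel: MarkerPanel,
    comparison: str = "",
    **kwargs,
) -> pd.DataFrame:
    """ENFC for a marker panel: compartments x panel members.

    Panel members absent from the input tables appear as missing values
    (with reason ``"not measured"``) rather than being dropped, so the
    radar-plot axes stay comparable across comparisons.
    """
    full = enfc_table(
        control_tables, experimental_tables, comparison=comparison, **kwargs
    )
    member_names = [m.canonical_name for m in panel.members]
    compartments = [c for c in control_tables if c in experimental_tables]
    rows = []
    for comp in compartments:
        for name in member_names:
            hit = full[(full["compartment"] == comp) & (full["variable"] == name)]
            if hit.empty:
                rows.append(
                    {
                        "comparison": comparison,
                        "panel": panel.name,
                        "compartment": comp,
                        "variable": name,
                        "enfc": None,
                        "reason": "not measured",
                    }
                )
            else:
                r = hit.iloc[0]
                rows.append(
                    {
                        "comparison": comparison,
                        "panel": panel.name,
                        "compartment": comp,
                        "variable": name,
                        "enfc": r["enfc"],
                        "reason": r["reason"],
                    }
                )
    return pd.DataFrame(
        rows, columns=["comparison", "panel", "compartment", "variable", "enfc", "reason"]
    )
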