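"""Abundance tables and binary presence calls.

A lipid variable counts as *present* in a compartment for a phenotype group
when its signal is strictly positive in at least a threshold fraction of the
group's samples (default 0.66, applied literally as ``fraction >= 0.66``).
Presence is therefore invariant to any positive rescaling of intensities,
and missing cells are treated as non-detection (zero), the convention of
direct-infusion MS export tables; a strict mode rejects missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .lipids import LipidVariable, canonical_order, parse_headers

__all__ = [
    "AbundanceTable",
    "PresenceProfile",
    "PRESENCE_THRESHOLD",
    "call_presence",
    "read_abundance_csv",
]

#: Default presence threshold: present iff detected in >= 66% of samples.
PRESENCE_THRESHOLD = 0.66


@dataclass
class AbundanceTable:
    """A samples x variables intensity matrix for one compartment and group.

    ``values`` is a DataFrame indexed by sample identifier with one column
    per lipid variable (canonical name); ``variables`` carries the parsed
    identities in column order.
    """

    compartment: str
    phenotype: str
    values: pd.DataFrame
    variables: list[LipidVariable]
    ionisation_mode: str = "unspecified"

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError(
                f"abundance table {self.phenotype}/{self.compartment}: "
                "need at least one sample and one variable"
            )
        if len(self.variables) != self.values.shape[1]:
            raise ValueError("variables do not match value columns")
        names = [v.canonical_name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"duplicate lipid variables in {self.phenotype}/"
                f"{self.compartment}: {dupes}"
            )
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError(
                f"negative intensities in {self.phenotype}/{self.compartment}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def variable_map(self) -> dict[str, LipidVariable]:
        return {v.canonical_name: v for v in self.variables}


@dataclass
class PresenceProfile:
    """Binary presence calls for one phenotype across compartments.

    ``calls`` and ``detection_fraction`` are keyed by
    ``(compartment, canonical variable name)``; ``variables`` maps canonical
    names back to parsed identities.
    """

    phenotype: str
    threshold: float
    calls: dict[tuple[str, str], bool] = field(default_factory=dict)
    detection_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    variables: dict[str, LipidVariable] = field(default_factory=dict)
    compartments: list[str] = field(default_factory=list)

    def present_in(self, compartment: str, lipid_class: str | None = None) -> set[LipidVariable]:
        """Variables called present in a compartment, optionally by class."""
        out = set()
        for (comp, name), present in self.calls.items():
            if comp != compartment or not present:
                continue
            var = self.variables[name]
            if lipid_class is None or var.lipid_class == lipid_class:
                out.add(var)
        return out

    def presence_compartments(self, variable: LipidVariable) -> set[str]:
        """Compartments in which a variable is called present."""
        name = variable.canonical_name
        return {
            comp
            for (comp, n), present in self.calls.items()
            if n == name and present
        }

    def all_variables(self, lipid_class: str | None = None) -> list[LipidVariable]:
        vs = [
            v
            for v in self.variables.values()
            if lipid_class is None or v.lipid_class == lipid_class
        ]
        return canonical_order(vs)

    def merge(self, other: "PresenceProfile") -> "PresenceProfile":
        """Combine slices (e.g. per-compartment calls) of the same phenotype."""
        if other.phenotype != self.phenotype:
            raise ValueError(
                f"cannot merge profiles of {self.phenotype!r} and {other.phenotype!r}"
            )
        if other.threshold != self.threshold:
            raise ValueError("cannot merge profiles with different thresholds")
        merged = PresenceProfile(self.phenotype, self.threshold)
        merged.calls = {**self.calls, **other.calls}
        merged.detection_fraction = {
            **self.detection_fraction,
            **other.detection_fraction,
        }
        merged.variables = {**self.variables, **other.variables}
        merged.compartments = list(
            dict.fromkeys(self.compartments + other.compartments)
        )
        return merged


def call_presence(
    table: AbundanceTable,
    threshold: float = PRESENCE_THRESHOLD,
    strict_missing: bool = False,
) -> PresenceProfile:
    """Convert one abundance table into a presence-profile slice.

    A variable is present iff
    ``(# samples with value > 0) / (# samples) >= threshold``.

    Parameters
    ----------
    table:
        Validated samples x variables intensities.
    threshold:
        Fraction in (0, 1]; the default 0.66 is applied literally, so e.g.
        33/50 = 0.66 is present.
    strict_missing:
        When True, NaN cells raise instead of counting as non-detection.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    arr = table.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        if strict_missing:
            raise ValueError(
                f"missing cells in {table.phenotype}/{table.compartment} "
                "(strict_missing=True)"
            )
        arr = np.nan_to_num(arr, nan=0.0)
    fractions = (arr > 0).mean(axis=0)
    profile = PresenceProfile(table.phenotype, threshold)
    profile.compartments = [table.compartment]
    for var, frac in zip(table.variables, fractions):
        key = (table.compartment, var.canonical_name)
        profile.detection_fraction[key] = float(frac)
        profile.calls[key] = bool(frac >= threshold)
        profile.variables[var.canonical_name] = var
    return profile


def build_profile(
    tables: Iterable[AbundanceTable],
    threshold: float = PRESENCE_THRESHOLD,
    strict_missing: bool = False,
) -> PresenceProfile:
    """Presence profile for one phenotype from its per-compartment tables."""
    tables = list(tables)
    if not tables:
        raise ValueError("no abundance tables supplied")
    phenos = {t.phenotype for t in tables}
    if len(phenos) != 1:
        raise ValueError(f"tables span multiple phenotypes: {sorted(phenos)}")
    profile = call_presence(tables[0], threshold, strict_missing)
    for t in tables[1:]:
        profile = profile.merge(call_presence(t, threshold, strict_missing))
    return profile


def read_abundance_csv(
    path: str | Path,
    compartment: str,
    phenotype: str,
    ionisation_mode: str = "unspecified",
    sep: str | None = None,
) -> AbundanceTable:
    """Read a wide CSV/TSV abundance matrix.

    First column = sample identifier; remaining columns = lipid variable
    names in shorthand nomenclature.  The separator is sniffed from the file
    extension unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    variables = parse_headers(list(df.columns), ionisation_mode=ionisation_mode)
    df.columns = [v.canonical_name for v in variables]
    return AbundanceTable(
        compartment=compartment,
        phenotype=phenotype,
        values=df.astype(float),
        variables=variables,
        ionisation_mode=ionisation_mode,
    )
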