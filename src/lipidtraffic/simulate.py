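"""Synthetic multi-compartment lipidomics datasets with planted traffic.

The generator emulates a four-group direct-infusion MS study: per-group,
per-compartment wide tables of non-negative intensities whose presence
structure is planted by design.  Each lipid class carries a plan of A-type
(ubiquitous), B-type (edge-sharing), U-type (single-compartment) and
other-shared (non-adjacent) variables; each category has a core shared by
all phenotype groups plus per-group unique extras, which fixes the
between-group overlap exactly.  Intensities are lognormal with a
per-variable coefficient of variation in 0.1-0.5 (typical dispersion of
direct-infusion lipidomics); absent variables are exact zeros, matching
the strictly-positive-signal presence rule.  All randomness flows from one
integer seed; the planted ground truth is returned alongside the tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lipids import LipidVariable
from .network import CompartmentNetwork, MOUSE_ADULT
from .presence import AbundanceTable
from .traffic import Assignment, TrafficClassification, _direction_label

__all__ = [
    "CategoryPlan",
    "ClassPlan",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "default_study_spec",
    "write_dataset",
]

PHENOTYPES = ("NN", "NH", "HN", "HH")

#: Ionisation mode by class: glycerides, cholesteryl esters and SM are read
#: from positive-mode tables; PC/PE from negative-mode tables.
CLASS_MODE = {
    "TG": "positive",
    "DG": "positive",
    "MG": "positive",
    "CE": "positive",
    "SM": "positive",
    "Chol": "positive",
    "PC": "negative",
    "PE": "negative",
    "PS": "negative",
    "PI": "negative",
    "PG": "negative",
    "PA": "negative",
    "LPC": "negative",
    "LPE": "negative",
}

_BASE_CARBONS = {
    "TG": 40,
    "DG": 28,
    "MG": 14,
    "PC": 30,
    "PE": 32,
    "PS": 34,
    "PI": 34,
    "SM": 30,
    "CE": 14,
    "LPC": 14,
    "LPE": 16,
}


@dataclass(frozen=True)
class CategoryPlan:
    """Planted counts for one category of one class.

    ``shared`` variables are present (in this category) in every phenotype
    group; each group additionally gets ``extras[group]`` unique variables.
    The between-group overlap of the category lists is therefore exactly
    ``shared`` for every pair.
    """

    shared: int = 0
    extras: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shared < 0 or any(v < 0 for v in self.extras.values()):
            raise ValueError("planted counts must be non-negative")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], overlap: int
    ) -> "CategoryPlan":
        """Build from per-group totals and a pairwise overlap.

        Raises if ``overlap`` exceeds any group's total (infeasible design).
        """
        if counts and overlap > min(counts.values()):
            raise ValueError(
                f"planted overlap {overlap} exceeds the smallest category "
                f"count {min(counts.values())}"
            )
        if overlap < 0:
            raise ValueError("planted overlap must be non-negative")
        return cls(
            shared=overlap, extras={g: n - overlap for g, n in counts.items()}
        )

    def count(self, phenotype: str) -> int:
        return self.shared + self.extras.get(phenotype, 0)


@dataclass(frozen=True)
class ClassPlan:
    """Category plans for one lipid class (missing categories are empty)."""

    A: CategoryPlan = CategoryPlan()
    B: CategoryPlan = CategoryPlan()
    U: CategoryPlan = CategoryPlan()
    other_shared: CategoryPlan = CategoryPlan()

    def items(self):
        return (
            ("A", self.A),
            ("B", self.B),
            ("U", self.U),
            ("other-shared", self.other_shared),
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full design of a synthetic study."""

    network: CompartmentNetwork = MOUSE_ADULT
    phenotypes: tuple[str, ...] = PHENOTYPES
    n_samples_per_group: int = 8
    classes: Mapping[str, ClassPlan] = field(default_factory=dict)
    effect_sizes: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=dict
    )
    dropout: float = 0.0
    seed: int = 0
    cv_range: tuple[float, float] = (0.1, 0.5)
    base_abundance: float = 50.0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {self.dropout}")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        lo, hi = self.cv_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid CV range {self.cv_range}")

    def effect(self, phenotype: str, lipid_class: str) -> float:
        e = self.effect_sizes.get(phenotype, 1.0)
        if isinstance(e, Mapping):
            return float(e.get(lipid_class, 1.0))
        return float(e)


@dataclass
class SyntheticDataset:
    """Generated tables plus the planted ground truth."""

    spec: SyntheticSpec
    tables: dict[tuple[str, str], AbundanceTable]  # (phenotype, compartment)
    ground_truth: dict[str, TrafficClassification]  # phenotype -> classification

    def tables_for(self, phenotype: str) -> dict[str, AbundanceTable]:
        return {
            comp: t
            for (ph, comp), t in self.tables.items()
            if ph == phenotype
        }


def _species_namer(lipid_class: str):
    """Deterministic stream of distinct (carbons, double_bonds) per class."""
    base = _BASE_CARBONS.get(lipid_class, 30)

    def name(i: int) -> LipidVariable:
        c = base + 2 * (i // 7)
        d = i % 7
        return LipidVariable(
            raw_name=f"{lipid_class}({c}:{d})",
            lipid_class=lipid_class,
            carbons=c,
            double_bonds=d,
            ionisation_mode=CLASS_MODE.get(lipid_class, "unspecified"),
        )

    return name


def _plant_class(
    lipid_class: str,
    plan: ClassPlan,
    spec: SyntheticSpec,
) -> dict[str, list[Assignment]]:
    """Assign planted variables, presence compartments and categories.

    Returns phenotype -> assignments for this class.  Station/edge choices
    cycle deterministically through the network so every compartment and
    edge receives planted structure.
    """
    net = spec.network
    comps = list(net.compartments)
    edges = net.edge_list()
    nonadj = sorted(
        (a, b)
        for i, a in enumerate(comps)
        for b in comps[i + 1 :]
        if not net.adjacent(a, b)
    )
    namer = _species_namer(lipid_class)
    counter = 0
    out: dict[str, list[Assignment]] = {ph: [] for ph in spec.phenotypes}

    def presence_for(category: str, slot: int) -> tuple[frozenset[str], frozenset]:
        if category == "A":
            return frozenset(comps), frozenset()
        if category == "U":
            return frozenset({comps[slot % len(comps)]}), frozenset()
        if category == "B":
            edge = edges[slot % len(edges)]
            return frozenset(edge), frozenset({edge})
        if not nonadj:
            raise ValueError(
                "network has no non-adjacent compartment pair; cannot plant "
                "other-shared variables"
            )
        return frozenset(nonadj[slot % len(nonadj)]), frozenset()

    for category, cplan in plan.items():
        for s in range(cplan.shared):
            var = namer(counter)
            counter += 1
            present, edgeset = presence_for(category, s)
            for ph in spec.phenotypes:
                out[ph].append(
                    _assignment(var, category, present, edgeset, net)
                )
        for ph in spec.phenotypes:
            for s in range(cplan.extras.get(ph, 0)):
                var = namer(counter)
                counter += 1
                present, edgeset = presence_for(category, s)
                out[ph].append(
                    _assignment(var, category, present, edgeset, net)
                )
    return out


def _assignment(
    var: LipidVariable,
    category: str,
    present: frozenset[str],
    edgeset: frozenset,
    net: CompartmentNetwork,
) -> Assignment:
    direction = (
        _direction_label(net, edgeset) if category == "B" and edgeset else None
    )
    return Assignment(
        variable=var,
        category=category,
        compartments=present,
        edges=edgeset,
        direction=direction,
    )


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int):
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate abundance tables and planted ground truth from a design.

    Deterministic given ``spec.seed``.  With ``dropout == 0`` every planted
    variable is strictly positive in all samples of its presence
    compartments, so presence calling at any threshold recovers the planted
    design exactly; dropout > 0 zeroes individual cells at the given rate
    and makes recovery noisy by intent.
    """
    rng = np.random.default_rng(spec.seed)
    planted: dict[str, list[Assignment]] = {ph: [] for ph in spec.phenotypes}
    for lipid_class in sorted(spec.classes):
        per_ph = _plant_class(lipid_class, spec.classes[lipid_class], spec)
        for ph in spec.phenotypes:
            planted[ph].extend(per_ph[ph])

    # Variable panel per ionisation mode: every table in a mode shares the
    # same columns (as a real MS export does); unplanted cells are zeros.
    all_vars: dict[str, LipidVariable] = {}
    for assigns in planted.values():
        for a in assigns:
            all_vars.setdefault(a.variable.canonical_name, a.variable)
    panel = sorted(all_vars.values(), key=lambda v: v.sort_key)

    # Per (variable, compartment) base mean and per-variable CV, shared by
    # all phenotype groups so that unit effect sizes give ENFC ~ 0.
    lo, hi = spec.cv_range
    cvs = {
        v.canonical_name: float(rng.uniform(lo, hi)) for v in panel
    }
    base_means = {
        (v.canonical_name, comp): float(
            _lognormal(rng, spec.base_abundance, 1.0, 1)[0]
        )
        for v in panel
        for comp in spec.network.compartments
    }

    n = spec.n_samples_per_group
    tables: dict[tuple[str, str], AbundanceTable] = {}
    for ph in spec.phenotypes:
        present_at: dict[str, set[str]] = {}
        for a in planted[ph]:
            present_at.setdefault(a.variable.canonical_name, set()).update(
                a.compartments
            )
        for comp in spec.network.compartments:
            cols = {}
            for v in panel:
                name = v.canonical_name
                if comp in present_at.get(name, ()):
                    mean = base_means[(name, comp)] * spec.effect(
                        ph, v.lipid_class
                    )
                    values = _lognormal(rng, mean, cvs[name], n)
                    if spec.dropout > 0:
                        mask = rng.random(n) < spec.dropout
                        values = np.where(mask, 0.0, values)
                else:
                    values = np.zeros(n)
                cols[name] = values
            samples = [f"{ph}_{comp}_{i + 1}" for i in range(n)]
            df = pd.DataFrame(cols, index=samples)
            tables[(ph, comp)] = AbundanceTable(
                compartment=comp,
                phenotype=ph,
                values=df,
                variables=[all_vars[c] for c in df.columns],
            )

    truth = {
        ph: TrafficClassification(
            phenotype=ph,
            lipid_class=None,
            assignments={a.variable: a for a in planted[ph]},
        )
        for ph in spec.phenotypes
    }
    return SyntheticDataset(spec=spec, tables=tables, ground_truth=truth)


def default_study_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The bundled four-group mouse design.

    A-type core/extra counts for TG and PC reproduce the control-group
    list sizes and overlaps of the worked examples (TG 29:35 sharing 28;
    PC 32:23 sharing 21); B/U/other-shared counts and the remaining classes
    are set to magnitudes typical of a ~500-variable direct-infusion panel.
    """
    classes = {
        "TG": ClassPlan(
            A=CategoryPlan(28, {"NN": 1, "NH": 3, "HN": 4, "HH": 7}),
            B=CategoryPlan(55, {"NN": 8, "NH": 6, "HN": 7, "HH": 9}),
            U=CategoryPlan(12, {"NN": 4, "NH": 3, "HN": 5, "HH": 4}),
            other_shared=CategoryPlan(3, {"NN": 1, "NH": 0, "HN": 1, "HH": 1}),
        ),
        "PC": ClassPlan(
            A=CategoryPlan(21, {"NN": 11, "NH": 6, "HN": 4, "HH": 2}),
            B=CategoryPlan(48, {"NN": 6, "NH": 5, "HN": 6, "HH": 4}),
            U=CategoryPlan(10, {"NN": 3, "NH": 2, "HN": 3, "HH": 2}),
            other_shared=CategoryPlan(2, {"NN": 1, "NH": 1, "HN": 0, "HH": 1}),
        ),
        "SM": ClassPlan(
            A=CategoryPlan(14, {"NN": 2, "NH": 1, "HN": 2, "HH": 2}),
            B=CategoryPlan(24, {"NN": 4, "NH": 3, "HN": 3, "HH": 4}),
            U=CategoryPlan(6, {"NN": 2, "NH": 1, "HN": 2, "HH": 1}),
        ),
        "PE": ClassPlan(
            A=CategoryPlan(10, {"NN": 2, "NH": 2, "HN": 1, "HH": 2}),
            B=CategoryPlan(18, {"NN": 3, "NH": 2, "HN": 3, "HH": 2}),
            U=CategoryPlan(5, {"NN": 2, "NH": 1, "HN": 1, "HH": 2}),
        ),
        "DG": ClassPlan(
            A=CategoryPlan(6, {"NN": 1, "NH": 1, "HN": 1, "HH": 1}),
            B=CategoryPlan(10, {"NN": 2, "NH": 1, "HN": 2, "HH": 1}),
            U=CategoryPlan(4, {"NN": 1, "NH": 1, "HN": 1, "HH": 1}),
        ),
        "CE": ClassPlan(
            A=CategoryPlan(4, {"NN": 1, "NH": 0, "HN": 1, "HH": 1}),
            B=CategoryPlan(8, {"NN": 1, "NH": 2, "HN": 1, "HH": 2}),
            U=CategoryPlan(2, {"NN": 1, "NH": 1, "HN": 0, "HH": 1}),
        ),
    }
    kwargs = dict(classes=classes, seed=seed)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write per-group per-compartment CSVs plus a ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for (ph, comp), table in sorted(dataset.tables.items()):
        path = outdir / f"{ph}_{comp.replace(' ', '_')}.csv"
        table.values.to_csv(path, index_label="sample")
        written.append(path)
    truth = pd.concat(
        [c.to_frame() for _, c in sorted(dataset.ground_truth.items())],
        ignore_index=True,
    )
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    written.append(truth_path)
    return written
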