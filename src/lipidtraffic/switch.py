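"""Switch Analysis: Jaccard-Tanimoto comparison of binary presence lists.

Two phenotypes' presence (or category) lists are aligned over their union,
summarised by the Jaccard-Tanimoto coefficient J = |intersection| / |union|,
and given an exact p-value under a fixed-margins null: conditioned on the
two list sizes, the intersection size follows a hypergeometric law over the
aligned universe, and p = P(J_null <= J_observed).  Since J is strictly
increasing in the intersection size at fixed margins, this is the lower
hypergeometric tail — p near 0 means the lists share less than chance would
give (fully disjoint lists of substantial size give p ~ 0), and heavily
overlapping lists give large p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .lipids import LipidVariable, canonical_order

__all__ = [
    "AlignedLists",
    "ComparisonResult",
    "align_lists",
    "jaccard_tanimoto",
    "jtc_p_value",
    "compare_sets",
    "switch_report",
]


@dataclass(frozen=True)
class AlignedLists:
    """Two binary membership vectors over a canonically ordered universe."""

    universe: tuple[LipidVariable, ...]
    bits_control: tuple[int, ...]
    bits_experimental: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.universe)
        if len(self.bits_control) != n or len(self.bits_experimental) != n:
            raise ValueError("bit vectors must span the universe")
        for c, e in zip(self.bits_control, self.bits_experimental):
            if not (c or e):
                raise ValueError("aligned universe contains an all-zero column")

    @property
    def n_control(self) -> int:
        return sum(self.bits_control)

    @property
    def n_experimental(self) -> int:
        return sum(self.bits_experimental)

    @property
    def n_shared(self) -> int:
        return sum(
            c & e for c, e in zip(self.bits_control, self.bits_experimental)
        )


def align_lists(
    control: Iterable[LipidVariable], experimental: Iterable[LipidVariable]
) -> AlignedLists:
    """Align two variable sets over the canonical ordering of their union."""
    a, b = set(control), set(experimental)
    universe = tuple(canonical_order(a | b))
    return AlignedLists(
        universe=universe,
        bits_control=tuple(int(v in a) for v in universe),
        bits_experimental=tuple(int(v in b) for v in universe),
    )


def jaccard_tanimoto(aligned: AlignedLists) -> float:
    """J = |intersection| / |union| over the aligned universe."""
    union = len(aligned.universe)
    if union == 0:
        raise ValueError("Jaccard-Tanimoto coefficient undefined on empty universe")
    return aligned.n_shared / union


def _jtc_p(n_universe: int, n_a: int, n_b: int, k_obs: int) -> float:
    # At fixed margins J(k) = k / (n_a + n_b - k) is increasing in k, so
    # P(J <= J_obs) = P(K <= k_obs) with K ~ Hypergeom(N, n_a, n_b).
    return float(hypergeom.cdf(k_obs, n_universe, n_a, n_b))


def jtc_p_value(aligned: AlignedLists) -> float:
    """Exact lower-tail p-value for the observed J under the fixed-margins null.

    Null model: the two lists are placed uniformly at random over the aligned
    universe with their observed sizes fixed; the intersection size is then
    hypergeometric, and p = P(J_null <= J_observed) is an exact summation
    over all feasible intersection sizes.
    """
    n = len(aligned.universe)
    if n == 0:
        raise ValueError("p-value undefined on empty universe")
    return _jtc_p(n, aligned.n_control, aligned.n_experimental, aligned.n_shared)


@dataclass(frozen=True)
class ComparisonResult:
    """One Switch-Analysis comparison in one scope.

    ``scope`` identifies the slice compared: (lipid class, category,
    optional edge or compartment restriction).  The counts render in the
    "29:35" control:experimental style used in reports.
    """

    scope: tuple[str, str, str | None]
    comparison: str
    n_control: int
    n_experimental: int
    n_shared: int
    jtc: float
    p_value: float

    @property
    def ratio_text(self) -> str:
        return f"{self.n_control}:{self.n_experimental}"


def compare_sets(
    control: Iterable[LipidVariable],
    experimental: Iterable[LipidVariable],
    scope: tuple[str, str, str | None] = ("all", "all", None),
    comparison: str = "",
) -> ComparisonResult | None:
    """Align, compute J and p for two variable sets.

    Returns ``None`` on an empty union (nothing present on either side),
    which callers report as a missing scope rather than a zero.
    """
    aligned = align_lists(control, experimental)
    if not aligned.universe:
        return None
    return ComparisonResult(
        scope=scope,
        comparison=comparison,
        n_control=aligned.n_control,
        n_experimental=aligned.n_experimental,
        n_shared=aligned.n_shared,
        jtc=jaccard_tanimoto(aligned),
        p_value=jtc_p_value(aligned),
    )


def switch_report(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy report: one row per (scope, comparison); J and p to 2 d.p.

    Full precision is retained on the :class:`ComparisonResult` objects;
    rounding here matches the presentation convention of printed tables.
    """
    rows = []
    for r in results:
        lipid_class, category, where = r.scope
        rows.append(
            {
                "comparison": r.comparison,
                "lipid_class": lipid_class,
                "category": category,
                "scope": where or "",
                "n_control": r.n_control,
                "n_experimental": r.n_experimental,
                "ratio": r.ratio_text,
                "n_shared": r.n_shared,
                "J": round(r.jtc, 2),
                "p": round(r.p_value, 2),
            }
        )
    cols = [
        "comparison",
        "lipid_class",
        "category",
        "scope",
        "n_control",
        "n_experimental",
        "ratio",
        "n_shared",
        "J",
        "p",
    ]
    return pd.DataFrame(rows, columns=cols)


def switch_analysis(
    classification_control,
    classification_experimental,
    comparison: str,
    lipid_classes: Sequence[str],
    categories: Sequence[str] = ("A", "B", "U"),
    per_edge: bool = True,
) -> list[ComparisonResult]:
    """Full Switch Analysis between two phenotypes' classifications.

    For each lipid class and category, compares the variable lists of the
    two phenotypes; B-type lists are additionally compared per sharing
    edge and U-type lists per compartment when ``per_edge`` is set.
    """
    results: list[ComparisonResult] = []
    for cls in lipid_classes:
        for cat in categories:
            ctrl = {
                a.variable
                for a in classification_control.assignments.values()
                if a.category == cat and a.variable.lipid_class == cls
            }
            expt = {
                a.variable
                for a in classification_experimental.assignments.values()
                if a.category == cat and a.variable.lipid_class == cls
            }
            r = compare_sets(ctrl, expt, scope=(cls, cat, None), comparison=comparison)
            if r is not None:
                results.append(r)
            if not per_edge:
                continue
            if cat == "B":
                edges = set()
                for src in (classification_control, classification_experimental):
                    for a in src.assignments.values():
                        if a.category == "B" and a.variable.lipid_class == cls:
                            edges |= set(a.edges)
                for edge in sorted(edges):
                    label = "--".join(edge)
                    c_e = {
                        a.variable
                        for a in classification_control.assignments.values()
                        if a.category == cat
                        and a.variable.lipid_class == cls
                        and edge in a.edges
                    }
                    e_e = {
                        a.variable
                        for a in classification_experimental.assignments.values()
                        if a.category == cat
                        and a.variable.lipid_class == cls
                        and edge in a.edges
                    }
                    r = compare_sets(
                        c_e, e_e, scope=(cls, cat, label), comparison=comparison
                    )
                    if r is not None:
                        results.append(r)
            elif cat == "U":
                comps = set()
                for src in (classification_control, classification_experimental):
                    for a in src.assignments.values():
                        if a.category == "U" and a.variable.lipid_class == cls:
                            comps |= a.compartments
                for comp in sorted(comps):
                    c_u = {
                        a.variable
                        for a in classification_control.assignments.values()
                        if a.category == cat
                        and a.variable.lipid_class == cls
                        and comp in a.compartments
                    }
                    e_u = {
                        a.variable
                        for a in classification_experimental.assignments.values()
                        if a.category == cat
                        and a.variable.lipid_class == cls
                        and comp in a.compartments
                    }
                    r = compare_sets(
                        c_u, e_u, scope=(cls, cat, comp), comparison=comparison
                    )
                    if r is not None:
                        results.append(r)
    return results
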