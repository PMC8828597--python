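"""Traffic classification of lipid variables over the compartment network.

Each variable present somewhere in the network is assigned exactly one
category per phenotype:

* **A** — present in every compartment (ubiquitous),
* **U** — present in exactly one compartment (unique),
* **B** — present in two or more (but not all) compartments with at least
  one adjacent pair among them; all sharing edges are reported,
* **other-shared** — present in two or more non-adjacent compartments;
  flagged rather than dropped, since on a star topology this marks lipids
  seen in several termini but not the hub.

B-type variables additionally carry a direction label.  On a network with a
declared origin a B-lipid whose presence set includes the origin side of its
edges is labelled *unidirectional* (consistent with outbound traffic from
the origin); otherwise *bidirectional*.  The label is interpretive only and
never affects counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .lipids import LipidVariable, canonical_order
from .network import CompartmentNetwork
from .presence import PresenceProfile

__all__ = [
    "Assignment",
    "TrafficClassification",
    "GlycerideParentage",
    "classify_traffic",
    "count_ubiquitous",
    "assess_tg_derived_glycerides",
    "DEFAULT_FA_POOL",
]

CATEGORIES = ("A", "B", "U", "other-shared")


@dataclass(frozen=True)
class Assignment:
    """Category assignment for one variable in one phenotype."""

    variable: LipidVariable
    category: str
    compartments: frozenset[str]
    edges: frozenset[tuple[str, str]] = frozenset()  # B only, sorted pairs
    direction: str | None = None  # B only: unidirectional | bidirectional

    @property
    def unique_compartment(self) -> str | None:
        if self.category == "U":
            return next(iter(self.compartments))
        return None


@dataclass
class TrafficClassification:
    """All assignments for one phenotype (optionally class-restricted)."""

    phenotype: str
    lipid_class: str | None
    assignments: dict[LipidVariable, Assignment] = field(default_factory=dict)

    def of_category(self, category: str) -> list[Assignment]:
        out = [a for a in self.assignments.values() if a.category == category]
        order = {v: i for i, v in enumerate(canonical_order(a.variable for a in out))}
        return sorted(out, key=lambda a: order[a.variable])

    def variables_of(self, category: str) -> set[LipidVariable]:
        return {a.variable for a in self.assignments.values() if a.category == category}

    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in CATEGORIES}
        for a in self.assignments.values():
            c[a.category] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready table: one row per classified variable."""
        rows = []
        for a in sorted(
            self.assignments.values(), key=lambda a: a.variable.sort_key
        ):
            rows.append(
                {
                    "phenotype": self.phenotype,
                    "lipid_class": a.variable.lipid_class,
                    "variable": a.variable.canonical_name,
                    "category": a.category,
                    "compartments": ";".join(sorted(a.compartments)),
                    "edges": ";".join(
                        "--".join(e) for e in sorted(a.edges)
                    ),
                    "direction": a.direction or "",
                }
            )
        cols = [
            "phenotype",
            "lipid_class",
            "variable",
            "category",
            "compartments",
            "edges",
            "direction",
        ]
        return pd.DataFrame(rows, columns=cols)


def _direction_label(
    network: CompartmentNetwork, edges: frozenset[tuple[str, str]]
) -> str:
    """Uni- vs bidirectional label for a B-type sharing pattern.

    With a declared origin, an edge is on the outbound path when exactly one
    endpoint is nearer the origin (hop count on the graph); sharing confined
    to such edges reads as unidirectional outbound traffic.  Without an
    origin the pattern is labelled bidirectional.
    """
    if network.origin is None:
        return "bidirectional"
    dist = nx.single_source_shortest_path_length(network.graph, network.origin)
    for a, b in edges:
        if dist.get(a) == dist.get(b):
            return "bidirectional"
    return "unidirectional"


def classify_traffic(
    profile: PresenceProfile,
    network: CompartmentNetwork,
    lipid_class: str | None = None,
    strict_pairs_only: bool = False,
) -> TrafficClassification:
    """Assign A/U/B/other-shared categories to every present variable.

    Parameters
    ----------
    profile:
        Presence calls covering every network compartment.
    network:
        The compartment graph.
    lipid_class:
        Restrict to one class (e.g. ``"TG"``); ``None`` classifies all.
    strict_pairs_only:
        When True, B is restricted to variables present in *exactly two*
        (adjacent) compartments; multi-compartment adjacent patterns fall
        into other-shared.  Default False: any adjacent pair qualifies as B.
    """
    missing = [c for c in network.compartments if c not in profile.compartments]
    if missing:
        raise ValueError(
            f"presence profile for {profile.phenotype!r} lacks network "
            f"compartment(s): {missing}"
        )
    n_total = len(network.compartments)
    result = TrafficClassification(profile.phenotype, lipid_class)
    for var in profile.all_variables(lipid_class):
        comps = profile.presence_compartments(var) & set(network.compartments)
        if not comps:
            continue
        if len(comps) == n_total:
            result.assignments[var] = Assignment(var, "A", frozenset(comps))
            continue
        if len(comps) == 1:
            result.assignments[var] = Assignment(var, "U", frozenset(comps))
            continue
        shared_edges = frozenset(
            tuple(sorted((a, b)))
            for a in comps
            for b in comps
            if a < b and network.adjacent(a, b)
        )
        is_b = bool(shared_edges) and (len(comps) == 2 or not strict_pairs_only)
        if is_b:
            result.assignments[var] = Assignment(
                var,
                "B",
                frozenset(comps),
                edges=shared_edges,
                direction=_direction_label(network, shared_edges),
            )
        else:
            result.assignments[var] = Assignment(
                var, "other-shared", frozenset(comps), edges=shared_edges
            )
    return result


def count_ubiquitous(
    classification: TrafficClassification, lipid_class: str | None = None
) -> int:
    """Number of A-type (ubiquitous) variables, optionally by class."""
    return sum(
        1
        for a in classification.assignments.values()
        if a.category == "A"
        and (lipid_class is None or a.variable.lipid_class == lipid_class)
    )


#: Even-chain fatty acids commonly observed in mouse tissues, as
#: (carbons, double bonds).  User-overridable in glyceride assessment.
DEFAULT_FA_POOL: frozenset[tuple[int, int]] = frozenset(
    {
        (14, 0),
        (16, 0),
        (16, 1),
        (18, 0),
        (18, 1),
        (18, 2),
        (18, 3),
        (20, 4),
        (20, 5),
        (22, 6),
    }
)


@dataclass(frozen=True)
class GlycerideParentage:
    """Candidate and observed TG parents of a DG/MG in one compartment.

    A DG gains one fatty acid to become a TG; an MG gains two.  A candidate
    parent satisfies ``carbons = child + sum(FA carbons)`` and
    ``double_bonds = child + sum(FA double bonds)`` for fatty acids drawn
    from the configured pool.  Observed parents are the candidates called
    present in the same compartment.
    """

    child: LipidVariable
    compartment: str
    candidate_parents: frozenset[tuple[int, int]]  # TG (carbons, double bonds)
    observed_parents: frozenset[LipidVariable]


def _candidate_tg_compositions(
    child: LipidVariable, fa_pool: Iterable[tuple[int, int]]
) -> frozenset[tuple[int, int]]:
    pool = list(fa_pool)
    if child.lipid_class == "DG":
        combos = [(fa,) for fa in pool]
    elif child.lipid_class == "MG":
        combos = [
            (pool[i], pool[j]) for i in range(len(pool)) for j in range(i, len(pool))
        ]
    else:
        raise ValueError(f"{child.canonical_name}: not a DG or MG")
    out = set()
    for fas in combos:
        c = child.carbons + sum(fa[0] for fa in fas)
        d = child.double_bonds + sum(fa[1] for fa in fas)
        out.add((c, d))
    return frozenset(out)


def assess_tg_derived_glycerides(
    profile: PresenceProfile,
    fa_pool: Iterable[tuple[int, int]] = DEFAULT_FA_POOL,
) -> list[GlycerideParentage]:
    """TG parentage of every present DG/MG variable, per compartment.

    For each di-/monoglyceride present in a compartment, enumerates the TG
    compositions reachable by re-esterifying fatty acids from ``fa_pool``
    and reports which of those TGs are themselves present there — evidence
    that the glyceride could be TG-derived (lipolysis) locally.
    """
    fa_pool = frozenset(fa_pool)
    if not fa_pool:
        raise ValueError("fatty-acid pool must be non-empty")
    tg_by_comp: dict[str, dict[tuple[int, int], LipidVariable]] = {}
    for comp in profile.compartments:
        tg_by_comp[comp] = {
            (v.carbons, v.double_bonds): v for v in profile.present_in(comp, "TG")
        }
    results: list[GlycerideParentage] = []
    for comp in profile.compartments:
        children = profile.present_in(comp, "DG") | profile.present_in(comp, "MG")
        for child in canonical_order(children):
            candidates = _candidate_tg_compositions(child, fa_pool)
            observed = frozenset(
                tg_by_comp[comp][cd] for cd in candidates if cd in tg_by_comp[comp]
            )
            results.append(
                GlycerideParentage(
                    child=child,
                    compartment=comp,
                    candidate_parents=candidates,
                    observed_parents=observed,
                )
            )
    return results
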