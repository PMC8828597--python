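"""U/A/B traffic classification and TG-derived glyceride assessment."""

import itertools

import pytest

import lipidtraffic as lt
from lipidtraffic.network import MOUSE_ADULT, build_network
from lipidtraffic.presence import PresenceProfile
from lipidtraffic.traffic import (
    assess_tg_derived_glycerides,
    classify_traffic,
    count_ubiquitous,
)

from conftest import make_vars


def profile_from_sets(presence, phenotype="NN", network=MOUSE_ADULT):
    """Presence profile from {variable: set-of-compartments}."""
    p = PresenceProfile(phenotype, threshold=0.66)
    p.compartments = list(network.compartments)
    for var, comps in presence.items():
        p.variables[var.canonical_name] = var
        for c in network.compartments:
            key = (c, var.canonical_name)
            p.calls[key] = c in comps
            p.detection_fraction[key] = 1.0 if c in comps else 0.0
    return p


def brute_force_category(comps, network):
    """Direct re-derivation of the category from the presence set."""
    comps = set(comps)
    if comps == set(network.compartments):
        return "A"
    if len(comps) == 1:
        return "U"
    any_adjacent = any(
        network.adjacent(a, b) for a, b in itertools.combinations(sorted(comps), 2)
    )
    return "B" if any_adjacent else "other-shared"


def test_classification_examples():
    v_all, v_liver, v_edge = make_vars(3)
    profile = profile_from_sets(
        {
            v_all: set(MOUSE_ADULT.compartments),
            v_liver: {"liver"},
            v_edge: {"liver", "serum"},
        }
    )
    cls = classify_traffic(profile, MOUSE_ADULT)
    assert cls.assignments[v_all].category == "A"
    assert cls.assignments[v_liver].category == "U"
    assert cls.assignments[v_liver].unique_compartment == "liver"
    b = cls.assignments[v_edge]
    assert b.category == "B"
    assert b.edges == frozenset({("liver", "serum")})
    assert b.direction == "unidirectional"  # outbound from the liver origin


def test_non_adjacent_sharing_is_flagged_not_dropped():
    (v,) = make_vars(1)
    profile = profile_from_sets({v: {"heart", "adipose"}})  # two termini
    cls = classify_traffic(profile, MOUSE_ADULT)
    assert cls.assignments[v].category == "other-shared"


def test_hub_spanning_sharing_is_bidirectional():
    (v,) = make_vars(1)
    profile = profile_from_sets({v: {"liver", "serum", "heart"}})
    b = cls = classify_traffic(profile, MOUSE_ADULT).assignments[v]
    assert b.category == "B"
    assert b.edges == frozenset({("liver", "serum"), ("heart", "serum")})


def test_strict_pairs_only_mode():
    (v,) = make_vars(1)
    profile = profile_from_sets({v: {"liver", "serum", "heart"}})
    cls = classify_traffic(profile, MOUSE_ADULT, strict_pairs_only=True)
    assert cls.assignments[v].category == "other-shared"


def test_missing_compartment_raises():
    net = build_network(
        {"compartments": ["liver", "serum"], "edges": [["liver", "serum"]]}
    )
    p = PresenceProfile("NN", 0.66)
    p.compartments = ["liver"]
    with pytest.raises(ValueError, match="serum"):
        classify_traffic(p, net)


def test_brute_force_equivalence_over_all_presence_subsets():
    """Classification agrees with direct enumeration of every non-empty
    presence subset of the six-compartment network."""
    comps = list(MOUSE_ADULT.compartments)
    subsets = [
        set(s)
        for r in range(1, len(comps) + 1)
        for s in itertools.combinations(comps, r)
    ]
    variables = make_vars(len(subsets))
    profile = profile_from_sets(dict(zip(variables, subsets)))
    cls = classify_traffic(profile, MOUSE_ADULT)
    for var, comps_set in zip(variables, subsets):
        assert cls.assignments[var].category == brute_force_category(
            comps_set, MOUSE_ADULT
        ), comps_set
    # partition property over the same exhaustive profile
    counts = cls.counts()
    assert sum(counts.values()) == len(subsets)


def test_partition_property_on_synthetic_data(profiles, small_dataset):
    """|A|+|U|+|B|+|other-shared| equals the number of present variables."""
    for ph, profile in profiles.items():
        cls = classify_traffic(profile, small_dataset.spec.network)
        n_present = len(
            {
                name
                for (comp, name), present in profile.calls.items()
                if present
            }
        )
        assert sum(cls.counts().values()) == n_present


def test_count_ubiquitous(profiles, small_dataset):
    cls = classify_traffic(profiles["NN"], small_dataset.spec.network, "TG")
    planted = sum(
        1
        for a in small_dataset.ground_truth["NN"].assignments.values()
        if a.category == "A" and a.variable.lipid_class == "TG"
    )
    assert count_ubiquitous(cls) == planted == 29
    empty = classify_traffic(profiles["NN"], small_dataset.spec.network, "MG")
    assert count_ubiquitous(empty) == 0


def test_glyceride_parentage_arithmetic():
    """DG + one FA, MG + two FAs: composition sums define candidate TGs."""
    dg = lt.parse_lipid_name("DG(34:1)")
    tg50, tg52 = lt.parse_lipid_name("TG(50:1)"), lt.parse_lipid_name("TG(52:2)")
    profile = profile_from_sets(
        {dg: {"liver"}, tg50: {"liver"}, tg52: {"serum"}}
    )
    results = assess_tg_derived_glycerides(profile, fa_pool={(16, 0), (18, 1)})
    liver = [r for r in results if r.compartment == "liver" and r.child == dg]
    assert len(liver) == 1
    assert liver[0].candidate_parents == {(50, 1), (52, 2)}
    # TG(52:2) is present in serum, not liver: only TG(50:1) observed locally
    assert liver[0].observed_parents == frozenset({tg50})


def test_mg_parentage_and_empty_observed():
    mg = lt.parse_lipid_name("MG(18:1)")
    profile = profile_from_sets({mg: {"liver"}})
    results = assess_tg_derived_glycerides(profile, fa_pool={(16, 0)})
    hit = [r for r in results if r.child == mg][0]
    assert hit.candidate_parents == {(50, 1)}  # 18+16+16 : 1+0+0
    assert hit.observed_parents == frozenset()


def test_empty_fa_pool_rejected():
    profile = profile_from_sets({})
    with pytest.raises(ValueError, match="non-empty"):
        assess_tg_derived_glycerides(profile, fa_pool=set())
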