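"""Synthetic data generator: determinism, feasibility, planted recovery."""

import numpy as np
import pandas as pd
import pytest

import lipidtraffic as lt
from lipidtraffic.simulate import (
    CategoryPlan,
    ClassPlan,
    SyntheticSpec,
    default_study_spec,
    generate,
    write_dataset,
)


def small_spec(seed=0, **overrides):
    classes = {
        "TG": ClassPlan(
            A=CategoryPlan(5, {"NN": 2, "HH": 3}),
            B=CategoryPlan(4, {"NN": 1, "HH": 2}),
            U=CategoryPlan(3, {"NN": 1, "HH": 1}),
            other_shared=CategoryPlan(1, {"NN": 1, "HH": 0}),
        ),
    }
    kwargs = dict(
        classes=classes,
        phenotypes=("NN", "HH"),
        n_samples_per_group=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


def test_same_seed_identical_tables():
    d1, d2 = generate(small_spec(7)), generate(small_spec(7))
    for key in d1.tables:
        pd.testing.assert_frame_equal(d1.tables[key].values, d2.tables[key].values)


def test_different_seeds_differ():
    d1, d2 = generate(small_spec(7)), generate(small_spec(8))
    key = ("NN", "liver")
    assert not d1.tables[key].values.equals(d2.tables[key].values)


def test_infeasible_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        CategoryPlan.from_counts({"NN": 3, "HH": 5}, overlap=4)
    plan = CategoryPlan.from_counts({"NN": 29, "HH": 35}, overlap=28)
    assert plan.count("NN") == 29 and plan.count("HH") == 35


def test_invalid_rates_rejected():
    with pytest.raises(ValueError, match="dropout"):
        small_spec(dropout=1.0)
    with pytest.raises(ValueError):
        small_spec(n_samples_per_group=0)


def test_round_trip_recovery_exact():
    """With no dropout, classification recovers every planted assignment."""
    ds = generate(small_spec(3))
    for ph in ("NN", "HH"):
        profile = lt.build_profile(ds.tables_for(ph).values())
        cls = lt.classify_traffic(profile, ds.spec.network)
        truth = ds.ground_truth[ph]
        assert set(cls.assignments) == set(truth.assignments)
        for var, a in cls.assignments.items():
            t = truth.assignments[var]
            assert (a.category, a.compartments) == (t.category, t.compartments)


def test_planted_jtc_recovered():
    """The planted 29:35 / 28-shared A-type TG design yields J = 28/36."""
    spec = default_study_spec(seed=11, n_samples_per_group=3)
    ds = generate(spec)
    a = lt.classify_traffic(
        lt.build_profile(ds.tables_for("NN").values()), spec.network, "TG"
    ).variables_of("A")
    b = lt.classify_traffic(
        lt.build_profile(ds.tables_for("HH").values()), spec.network, "TG"
    ).variables_of("A")
    r = lt.compare_sets(a, b)
    assert (r.n_control, r.n_experimental, r.n_shared) == (29, 35, 28)
    assert r.jtc == pytest.approx(28 / 36)


def test_null_effects_give_near_zero_enfc():
    ds = generate(small_spec(5, n_samples_per_group=8))
    table = lt.enfc_table(
        ds.tables_for("NN"), ds.tables_for("HH"), normalise=False
    )
    defined = table["enfc"].dropna().astype(float)
    assert len(defined) > 0
    assert abs(defined.median()) < 0.6


def test_enfc_monotone_in_planted_effect():
    """Median ENFC of affected variables grows with the multiplicative
    effect; with effect 10 and small CV it is clearly positive."""
    medians = []
    for effect in (1.0, 3.0, 10.0):
        ds = generate(
            small_spec(
                9,
                n_samples_per_group=8,
                effect_sizes={"HH": effect},
                cv_range=(0.1, 0.2),
            )
        )
        table = lt.enfc_table(
            ds.tables_for("NN"), ds.tables_for("HH"), normalise=False
        )
        medians.append(float(table["enfc"].dropna().median()))
    assert medians[0] < medians[1] < medians[2]
    assert medians[2] > 1.0


def test_dropout_zeroes_cells():
    ds = generate(small_spec(2, dropout=0.4, n_samples_per_group=20))
    truth = ds.ground_truth["NN"]
    some_a = next(
        a for a in truth.assignments.values() if a.category == "A"
    )
    col = ds.tables[("NN", "liver")].values[some_a.variable.canonical_name]
    assert (col == 0).any() and (col > 0).any()


def test_write_dataset(tmp_path):
    ds = generate(small_spec(1))
    written = write_dataset(ds, tmp_path)
    assert (tmp_path / "ground_truth.csv").exists()
    # one file per (group, compartment) plus the ground truth
    assert len(written) == len(ds.tables) + 1
    loaded = lt.read_abundance_csv(tmp_path / "NN_liver.csv", "liver", "NN")
    assert np.allclose(
        loaded.values.to_numpy(), ds.tables[("NN", "liver")].values.to_numpy()
    )
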