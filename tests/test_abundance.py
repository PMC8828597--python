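"""Margin change, error-normalised fold change and marker panels."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lipidtraffic as lt
from lipidtraffic.abundance import (
    BUNDLED_PANELS,
    GroupSummary,
    enfc,
    enfc_table,
    margin_change,
    normalise_per_mille,
    panel_enfc,
    summarise_group,
)

MEANS = (0.1, 1.0, 10.0)
CVS = (0.1, 0.3, 0.5)


def test_margin_change_is_mean_difference():
    assert margin_change(GroupSummary(5, 0.1), GroupSummary(3, 0.1)) == 2
    assert margin_change(GroupSummary(4, 0.2), GroupSummary(4, 0.9)) == 0
    assert margin_change(GroupSummary(0, 0.0), GroupSummary(4, 0.1)) == -4


def test_enfc_worked_values():
    # log10(10/1) = 1 over sqrt((1+1)/2) = 1
    assert enfc(GroupSummary(10, 1.0), GroupSummary(1, 1.0)) == pytest.approx(1.0)
    assert enfc(GroupSummary(1, 1.0), GroupSummary(10, 1.0)) == pytest.approx(-1.0)
    assert enfc(GroupSummary(7, 0.3), GroupSummary(7, 0.5)) == 0.0


def test_enfc_undefined_cases():
    with pytest.raises(ValueError, match="non-positive"):
        enfc(GroupSummary(0, 0.1), GroupSummary(1, 0.1))
    with pytest.raises(ValueError, match="errors are zero"):
        enfc(GroupSummary(2, 0.0), GroupSummary(1, 0.0))


def test_enfc_grid_properties():
    """Antisymmetry, zero at equal means, scale invariance — exhaustively
    over the means x CVs grid."""
    for (me, mc), (a, b) in itertools.product(
        itertools.product(MEANS, MEANS), itertools.product(CVS, CVS)
    ):
        e, c = GroupSummary(me, a), GroupSummary(mc, b)
        v = enfc(e, c)
        # antisymmetry under swapping groups (errors travel with the groups)
        assert enfc(c, e) == pytest.approx(-enfc(e, c))
        if me == mc:
            assert v == 0.0
        for scale in (0.01, 1.0, 250.0):
            scaled = enfc(
                GroupSummary(me * scale, a), GroupSummary(mc * scale, b)
            )
            assert scaled == pytest.approx(v)


def test_summarise_group_cv_and_sem():
    x = [2.0, 4.0, 6.0]
    s = summarise_group(x)
    assert s.mean == pytest.approx(4.0)
    assert s.relative_error == pytest.approx(np.std(x, ddof=1) / 4.0)
    sem = summarise_group(x, error_model="sem")
    assert sem.relative_error == pytest.approx(s.relative_error / np.sqrt(3))
    assert summarise_group([0.0, 0.0]).mean == 0.0


def test_bundled_marker_panels():
    assert [m.canonical_name for m in BUNDLED_PANELS["dnl_tg"].members] == [
        "TG(46:0)",
        "TG(46:1)",
        "TG(48:0)",
        "TG(48:1)",
    ]
    assert [m.canonical_name for m in BUNDLED_PANELS["dietary_tg"].members] == [
        "TG(52:2)",
        "TG(54:4)",
        "TG(54:8)",
        "TG(56:7)",
    ]
    assert [m.canonical_name for m in BUNDLED_PANELS["abundant_pc"].members] == [
        "PC(34:1)",
        "PC(34:2)",
        "PC(36:4)",
        "PC(38:4)",
    ]


def test_per_mille_normalisation(small_dataset):
    table = small_dataset.tables[("NN", "liver")]
    scaled = normalise_per_mille(table)
    sums = scaled.values.sum(axis=1).to_numpy()
    assert np.allclose(sums[sums > 0], 1000.0)


def test_enfc_table_null_comparison(small_dataset):
    """With identical generative groups (unit effects), ENFC scatters
    around zero."""
    nn = small_dataset.tables_for("NN")
    hh = small_dataset.tables_for("HH")
    table = enfc_table(nn, hh, comparison="NN vs HH")
    defined = table["enfc"].dropna().astype(float)
    assert len(defined) > 50
    assert abs(defined.median()) < 0.5


def test_enfc_table_excludes_sub_threshold_variables(small_dataset):
    nn = small_dataset.tables_for("NN")
    hh = small_dataset.tables_for("HH")
    table = enfc_table(nn, hh)
    missing = table[table["reason"] == "below presence threshold"]
    assert len(missing) > 0
    assert missing["enfc"].isna().all()


def test_panel_enfc_shape_and_missing_members(small_dataset):
    nn = small_dataset.tables_for("NN")
    nh = small_dataset.tables_for("NH")
    out = panel_enfc(nn, nh, BUNDLED_PANELS["dnl_tg"], comparison="NN vs NH")
    n_comps = len(small_dataset.spec.network.compartments)
    assert len(out) == 4 * n_comps  # every member reported in every compartment
    assert set(out["variable"]) == {
        "TG(46:0)",
        "TG(46:1)",
        "TG(48:0)",
        "TG(48:1)",
    }
    # members never dropped: undefined cells carry a reason instead
    assert (out["enfc"].notna() | (out["reason"] != "")).all()
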