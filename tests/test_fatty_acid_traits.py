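"""Trait derivation: basis conversion, composites, indices, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fatscan import (atherogenic_index, composite_traits,
                     default_definitions, derive_traits, summary_stats,
                     to_fat_percent)
from fatscan.fatty_acid_traits import (ALL_TRAITS, FATTY_ACIDS,
                                       MCFA_TABLE1, LCFA_TABLE1)


def profile(**kwargs) -> pd.DataFrame:
    """One-animal profile over all 38 acids, zeros unless given."""
    row = {name: 0.0 for name in FATTY_ACIDS}
    row.update(kwargs)
    return pd.DataFrame([row])


def test_fat_percent_hand_arithmetic():
    p = profile(**{"14:0": 1.0, "16:0": 2.0, "18:0": 1.0})
    out = to_fat_percent(p)
    assert out.iloc[0]["14:0"] == pytest.approx(25.0)
    assert out.iloc[0]["16:0"] == pytest.approx(50.0)
    assert out.iloc[0]["18:0"] == pytest.approx(25.0)


def test_fat_percent_single_component_and_zero_error():
    assert to_fat_percent(profile(**{"16:0": 3.3})).iloc[0]["16:0"] == \
        pytest.approx(100.0)
    with pytest.raises(ValueError, match="all-zero"):
        to_fat_percent(profile())


@given(st.lists(st.floats(0.01, 1e4), min_size=3, max_size=8))
def test_fat_percent_closure_and_idempotence(weights):
    names = list(FATTY_ACIDS)[: len(weights)]
    p = pd.DataFrame([dict(zip(names, weights))])
    out = to_fat_percent(p)
    assert out.iloc[0].sum() == pytest.approx(100.0, abs=1e-9)
    # idempotent up to scale: composition unchanged
    pd.testing.assert_frame_equal(to_fat_percent(out), out)


def test_mcfa_lcfa_partition_sums_to_100():
    rng = np.random.default_rng(0)
    p = pd.DataFrame(rng.lognormal(size=(20, 38)), columns=list(FATTY_ACIDS))
    fp = to_fat_percent(p)
    comp = composite_traits(fp)
    assert set(MCFA_TABLE1) | set(LCFA_TABLE1) == set(FATTY_ACIDS)
    np.testing.assert_allclose(comp["MCFA"] + comp["LCFA"], 100.0,
                               atol=1e-9)


def test_sum_traits_hand_arithmetic():
    comp = composite_traits(profile(**{"10:0": 10.0, "20:0": 20.0}))
    assert comp.iloc[0]["SFA"] == pytest.approx(30.0)


def test_ratio_traits_scale_and_published_means():
    # a fat-percent profile matching the published 14:0/16:0 means
    p = profile(**{"14:0": 2.707, "16:0": 26.549,
                   "18:0": 100 - 2.707 - 26.549})
    comp = composite_traits(p)
    val = comp.iloc[0]["(14:0+16:0)/All"]
    assert val == pytest.approx(29.256, abs=1e-9)   # x100 of 0.29256
    assert abs(val - 29.257) < 0.01                 # published mean


def test_ratio_traits_na_on_beef_basis_and_zero_denominator():
    p = profile(**{"14:0": 1.0, "10:0": 2.0})
    beef = composite_traits(p, basis="beef")
    assert np.isnan(beef.iloc[0]["PUFA/SFA"])
    all_sat = composite_traits(profile(**{"10:0": 100.0}))
    assert all_sat.iloc[0]["PUFA/SFA"] == pytest.approx(0.0)
    no_sat = composite_traits(profile(**{"14:1": 100.0}))
    assert np.isnan(no_sat.iloc[0]["PUFA/SFA"])  # SFA == 0 -> NA


def test_atherogenic_index_published_and_hand_values():
    # published fat-percent means: MUFA into cis-9 18:1, PUFA into 18:2
    p = profile(**{"14:0": 2.707, "16:0": 26.549, "cis-9 18:1": 49.047,
                   "18:2": 5.674})
    ai = atherogenic_index(p).iloc[0]
    assert ai == pytest.approx(100 * (4 * 2.707 + 26.549) / 54.721,
                               abs=1e-9)
    assert ai == pytest.approx(68.31, abs=0.01)
    assert abs(ai - 68.728) / 68.728 < 0.01  # within 1% of published mean

    hand = atherogenic_index(profile(**{"14:0": 1.0, "16:0": 1.0,
                                        "cis-9 18:1": 5.0})).iloc[0]
    assert hand == pytest.approx(100.0)
    zero = atherogenic_index(profile(**{"cis-9 18:1": 5.0})).iloc[0]
    assert zero == pytest.approx(0.0)


def test_derive_traits_covers_all_49(small_sim):
    rng = np.random.default_rng(1)
    p = pd.DataFrame(rng.lognormal(size=(5, 38)), columns=list(FATTY_ACIDS))
    out = derive_traits(to_fat_percent(p))
    assert list(out.columns) == list(ALL_TRAITS)
    assert len(ALL_TRAITS) == 49


def test_composite_linearity():
    """Composite of the mean profile equals the mean of composites."""
    rng = np.random.default_rng(2)
    p = pd.DataFrame(rng.lognormal(size=(50, 38)), columns=list(FATTY_ACIDS))
    comp = composite_traits(p, basis="beef")
    mean_comp = composite_traits(
        pd.DataFrame([p.mean()]), basis="beef")
    for t in ("MCFA", "LCFA", "MUFA", "PUFA", "SFA", "n3", "n6"):
        assert mean_comp.iloc[0][t] == pytest.approx(comp[t].mean())


def test_summary_stats_published_and_hand_values():
    # published 16:0 fat-percent row: mean 26.549, SD 1.792 -> CV x100 6.7
    rng = np.random.default_rng(0)
    v = rng.normal(size=1000)
    v = (v - v.mean()) / v.std(ddof=1) * 1.792 + 26.549
    s = summary_stats(pd.DataFrame({"16:0": v})).iloc[0]
    assert round(s["CV_x100"], 1) == 6.7

    s2 = summary_stats(pd.DataFrame({"t": [1.0, 2.0, 3.0]})).iloc[0]
    assert (s2["mean"], s2["SD"], s2["CV_x100"]) == (2.0, 1.0, 50.0)

    s3 = summary_stats(pd.DataFrame({"t": [4.0, 4.0, 4.0]})).iloc[0]
    assert s3["SD"] == 0.0 and s3["CV_x100"] == 0.0

    s4 = summary_stats(pd.DataFrame({"t": [-1.0, 1.0]})).iloc[0]
    assert np.isnan(s4["CV_x100"])  # zero mean


def test_configurable_memberships():
    defs_text = default_definitions(mcfa="text", n3="text", n6="text")
    assert defs_text["MCFA"].members == ("12:0", "13:0")
    assert defs_text["n3"].members == ("18:3n3", "20:3n3")
    defs_def = default_definitions()
    assert "20:5" in defs_def["n3"].members
    assert "CLAc9t11" in defs_def["n6"].members
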