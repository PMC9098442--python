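"""Infant high-exposure intake and risk arithmetic: frozen expected cells."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenoquant.display import display_ratio, display_value, round_sig
from xenoquant.exposure import (
    assumed_concentration,
    build_assessment_table,
    class_cumulative_table,
    compat_ratio,
    cumulative_hubi,
    hubi,
    infant_guidance,
    load_assessment_inputs,
    moe,
    risk_ratio,
)
from xenoquant.types import Status


def _series(concs, statuses):
    return pd.DataFrame({"conc": concs, "status": statuses})


def test_assumed_concentration_rules():
    q, b = Status.quantified.value, Status.below_loq.value
    # everything below LOQ -> the LOQ itself
    assert assumed_concentration(_series([np.nan] * 3, [b] * 3), 0.40) == (0.40, "loq")
    # max over quantified
    res = _series([0.2, 6.4, np.nan], [q, q, b])
    assert assumed_concentration(res, 0.16) == (6.4, "max_quantified")
    assert assumed_concentration(_series([1.7], [q]), 0.1) == (1.7, "max_quantified")
    with pytest.raises(ValueError, match="empty"):
        assumed_concentration(_series([], []), 0.1)
    with pytest.raises(ValueError, match="no detections"):
        assumed_concentration(_series([np.nan], [Status.not_detected.value]), 0.1)


def test_hubi_reference_values():
    assert display_value(hubi(6.4)) == pytest.approx(1.1)
    assert display_value(hubi(0.042)) == pytest.approx(0.0070)
    assert hubi(0.0) == 0.0
    with pytest.raises(ValueError):
        hubi(1.0, bw=0)


def test_infant_correction_reference_values():
    assert display_value(infant_guidance(4.0)) == pytest.approx(1.3)
    assert display_value(infant_guidance(10.0)) == pytest.approx(3.3)
    assert display_value(infant_guidance(0.016)) == pytest.approx(0.0053)


def test_risk_ratio_reference_cells():
    # PFOA: (0.63/3) / (0.092/6) -> 14
    assert display_ratio(risk_ratio(infant_guidance(0.63), hubi(0.092))) == 14
    # propylparaben: (2000/3) / (16/6) -> 250
    assert display_ratio(risk_ratio(infant_guidance(2000), hubi(16))) == 250
    assert risk_ratio(1.0, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        risk_ratio(1.0, 0.0)


def test_moe_reference_cells_and_concern_flag():
    m, concern = moe(70, hubi(0.021))
    assert display_ratio(m) == 20_000 and concern is False
    m, concern = moe(480, hubi(0.042))
    assert display_ratio(m) == 68_571 and concern is False
    m, concern = moe(70, hubi(0.11))
    assert concern is True  # full precision 3818
    # compat mode reproduces the printed 3889 (divides display values)
    assert compat_ratio(70, hubi(0.11)) == 3889
    # boundary: exactly 10,000 is NOT of concern (strict <)
    assert moe(10_000.0, 1.0)[1] is False


def test_cumulative_bisphenols():
    c = cumulative_hubi([0.40, 0.028, 0.051])
    assert round_sig(c, 1) == pytest.approx(0.08)
    assert cumulative_hubi([0.40]) == hubi(0.40)
    # additivity before rounding
    assert cumulative_hubi([0.40, 0.028]) + cumulative_hubi([0.051]) == pytest.approx(
        cumulative_hubi([0.40, 0.028, 0.051]))
    with pytest.raises(ValueError):
        cumulative_hubi([])


REFERENCE_HUBI = {
    "Bisphenol A (BPA)": 0.067, "Bisphenol F (BPF)": 0.0047,
    "Bisphenol S (BPS)": 0.0085, "Mono-n-butyl phthalate (MBP)": 1.1,
    "Perfluorooctanoic acid (PFOA)": 0.015,
    "Perfluorooctanesulfonic acid (PFOS)": 0.0080, "Prochloraz": 0.014,
    "8-prenylnaringenin": 0.038, "Daidzein": 0.023, "Enterolactone": 0.028,
    "Glycitein": 0.0018, "Isoxanthohumol": 0.013, "Resveratrol": 0.050,
    "Xanthohumol": 0.037, "Alternariol": 0.085, "Benzophenone 1": 0.0065,
    "Benzophenone 2": 0.0033, "Butylparaben (BP)": 0.0060,
    "Ethylparaben (EP)": 0.022, "Methylparaben (MP)": 3.8,
    "Propylparaben (PP)": 2.7, "Anisodamine": 0.0052,
    "Jacobine-N-oxide": 0.018, "Riddelliin-N-oxide": 0.0035,
    "Scopolamine": 0.000067, "PhIP": 0.0070,
}

RATIO_CELLS = {  # frozen expected ratio/MoE display cells
    "Bisphenol A (BPA)": 20, "Perfluorooctanoic acid (PFOA)": 14,
    "Perfluorooctanesulfonic acid (PFOS)": 26, "Prochloraz": 2439,
    "Benzophenone 1": 1538, "Butylparaben (BP)": 111_111,
    "Ethylparaben (EP)": 153_846, "Methylparaben (MP)": 870,
    "Propylparaben (PP)": 250, "Riddelliin-N-oxide": 20_000, "PhIP": 68_571,
}


def test_full_table_reproduces_expected_hubi_cells():
    df = build_assessment_table(entries=load_assessment_inputs())
    got = dict(zip(df["analyte"], df["hubi_display"]))
    for name, want in REFERENCE_HUBI.items():
        assert got[name] == pytest.approx(want), name


def test_full_precision_ratios_match_expected_cells():
    """At least 9 of the 11 expected ratio/MoE cells match the full-precision
    convention; the remainder match the display-rounded one."""
    df = build_assessment_table(entries=load_assessment_inputs()).set_index("analyte")
    full_hits, either_hits = 0, 0
    for name, want in RATIO_CELLS.items():
        row = df.loc[name]
        full = row["ratio_display"] if pd.notna(row["ratio_display"]) else row["moe_display"]
        compat = row["ratio_compat"] if pd.notna(row["ratio_compat"]) else row["moe_compat"]
        full_hits += full == want
        either_hits += (full == want) or (compat == want)
    assert full_hits >= 9
    assert either_hits == len(RATIO_CELLS)


def test_guidance_less_analytes_have_hubi_only():
    df = build_assessment_table(entries=load_assessment_inputs()).set_index("analyte")
    row = df.loc["Daidzein"]
    assert row["guidance_kind"] == "none"
    assert pd.isna(row["ratio"]) and pd.isna(row["moe"])
    assert row["hubi"] > 0


def test_class_cumulative_table_bisphenols():
    df = build_assessment_table(entries=load_assessment_inputs())
    cum = class_cumulative_table(df[df["analyte"].str.startswith("Bisphenol")
                                    | (df["analyte"] == "Mono-n-butyl phthalate (MBP)")])
    plast = cum.set_index("chemical_class").loc["plasticizer"]
    # bisphenols + MBP share the class; restrict to the three bisphenols
    bps = df[df["analyte"].str.startswith("Bisphenol")]
    assert round_sig(cumulative_hubi(bps["assumed_conc"]), 1) == pytest.approx(0.08)


def test_assessment_round_trips_through_file(tmp_path):
    from xenoquant.io import write_table

    df = build_assessment_table(entries=load_assessment_inputs())
    path = tmp_path / "assess.csv"
    write_table(df, path)
    back = pd.read_csv(path)
    rebuilt = build_assessment_table(entries=[
        {"name": r["analyte"], "chemical_class": r["chemical_class"],
         "assumed_conc": r["assumed_conc"], "assumed_from": r["assumed_from"],
         "guidance": ({"kind": r["guidance_kind"], "value": r["guidance_adult"]}
                      if r["guidance_kind"] != "none" else None)}
        for _, r in back.iterrows()
    ])
    pd.testing.assert_series_equal(rebuilt["hubi"], df["hubi"])
    pd.testing.assert_series_equal(rebuilt["ratio"], df["ratio"])


@settings(max_examples=100, deadline=None)
@given(conc=st.floats(1e-6, 1e4), bw=st.floats(0.5, 100), k=st.floats(1.1, 10))
def test_hubi_linear_in_conc_inverse_in_bw(conc, bw, k):
    assert hubi(k * conc, bw=bw) == pytest.approx(k * hubi(conc, bw=bw))
    assert hubi(conc, bw=k * bw) == pytest.approx(hubi(conc, bw=bw) / k)


@settings(max_examples=100, deadline=None)
@given(h=st.floats(1e-6, 1e3), k=st.floats(1.01, 100))
def test_ratio_and_moe_strictly_decreasing_in_hubi(h, k):
    assert risk_ratio(1.0, k * h) < risk_ratio(1.0, h)
    assert moe(70.0, k * h)[0] < moe(70.0, h)[0]
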