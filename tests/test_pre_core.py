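"""PRE ratios, error propagation, two-point Γ₂, profiles, ΔI, groups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premap.pre_core import (
    BleachedPeakError,
    annotate_groups,
    build_pre_profile,
    delta_I,
    gamma2_two_point,
    intensity_ratio,
    ratio_uncertainty,
)
from premap.synthetic import two_point_intensities
from conftest import make_table


class TestIntensityRatio:
    @pytest.mark.parametrize(
        "i_dia,i_para,c,expected",
        [(100, 100, 1.0, 1.0), (100, 50, 1.0, 2.0), (100, 50, 0.8, 2.5)],
    )
    def test_values(self, i_dia, i_para, c, expected):
        assert intensity_ratio(i_dia, i_para, c) == pytest.approx(expected)

    def test_nonpositive_para_is_bleached_candidate(self):
        with pytest.raises(BleachedPeakError):
            intensity_ratio(100.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        k=st.floats(1e-3, 1e3),
        a=st.floats(1.0, 1e5),
        b=st.floats(1.0, 1e5),
        c=st.floats(0.5, 2.0),
    )
    def test_homogeneity(self, k, a, b, c):
        # scaling both intensities by k leaves the ratio unchanged
        assert intensity_ratio(k * a, k * b, c) == pytest.approx(
            intensity_ratio(a, b, c), rel=1e-12
        )


class TestRatioUncertainty:
    def test_zero_sigmas_give_zero(self):
        assert ratio_uncertainty(100, 0, 50, 0) == 0.0

    def test_scale_invariance_of_relative_uncertainty(self):
        r1 = ratio_uncertainty(100, 5, 50, 5) / intensity_ratio(100, 50)
        r2 = ratio_uncertainty(200, 10, 100, 10) / intensity_ratio(200, 100)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_matches_monte_carlo(self):
        # independent MC propagation of the ratio, fixed seed
        rng = np.random.default_rng(42)
        i_dia, s_dia, i_para, s_para = 100.0, 5.0, 50.0, 5.0
        draws = (rng.normal(i_dia, s_dia, 100_000)
                 / rng.normal(i_para, s_para, 100_000))
        mc = draws.std(ddof=1)
        assert ratio_uncertainty(i_dia, s_dia, i_para, s_para) == pytest.approx(
            mc, rel=0.05
        )


class TestGamma2TwoPoint:
    def test_identical_decay_gives_zero(self):
        rec = gamma2_two_point(800, 400, 800, 400, 0.002, 0.010)
        assert rec.gamma2_per_s == pytest.approx(0.0, abs=1e-12)

    def test_exact_inverse_of_forward_model(self):
        ints = two_point_intensities(25.0, 0.002, 0.010)
        rec = gamma2_two_point(*ints, 0.002, 0.010)
        assert rec.gamma2_per_s == pytest.approx(25.0, abs=1e-10)
        assert not rec.is_lower_bound

    @settings(max_examples=100, derandomize=True)
    @given(
        gamma2=st.floats(0.0, 200.0),
        ta=st.floats(1e-4, 0.01),
        dt=st.floats(1e-4, 0.05),
        r2dia=st.floats(1.0, 60.0),
    )
    def test_inversion_property(self, gamma2, ta, dt, r2dia):
        ints = two_point_intensities(gamma2, ta, ta + dt, r2_dia_per_s=r2dia)
        rec = gamma2_two_point(*ints, ta, ta + dt)
        assert rec.gamma2_per_s == pytest.approx(gamma2, abs=1e-9)

    def test_below_noise_floor_is_lower_bound(self):
        ipa, ipb, ida, idb = two_point_intensities(150.0, 0.002, 0.010)
        floor = ipb * 2  # Tb paramagnetic point has sunk below the noise
        rec = gamma2_two_point(ipa, ipb, ida, idb, 0.002, 0.010, noise_floor=floor)
        assert rec.is_lower_bound
        # bound computed at the floor is below the (unknowable) true rate
        assert rec.gamma2_per_s < 150.0

    def test_sigma_propagation_positive(self):
        ints = two_point_intensities(25.0, 0.002, 0.010)
        rec = gamma2_two_point(*ints, 0.002, 0.010, sigmas=(5, 5, 5, 5))
        assert rec.sigma_gamma2_per_s > 0


class TestBuildPreProfile:
    def test_identical_tables_all_unity(self, dia_meta, para_meta):
        rows = [(20, "V20-g1", 1000.0, 10.0), (197, "V197-g1", 900.0, 10.0)]
        prof = build_pre_profile(make_table(dia_meta, rows), make_table(para_meta, rows))
        assert np.allclose(prof.df["i_ratio"], 1.0)
        assert not prof.df["bleached"].any()

    def test_concentration_correction_from_meta(self, dia_meta, para_meta):
        from dataclasses import replace
        rows = [(20, "V20-g1", 1000.0, 10.0)]
        para_meta2 = replace(para_meta, protein_conc_uM=160.0)  # c = 0.8
        prof = build_pre_profile(make_table(dia_meta, rows), make_table(para_meta2, rows))
        assert prof.df.loc[0, "i_ratio"] == pytest.approx(1 / 0.8)
        assert prof.df.loc[0, "c_correction"] == pytest.approx(0.8)

    def test_sub_threshold_peak_flagged_bleached(self, dia_meta, para_meta):
        dia = make_table(dia_meta, [(211, "V211-g1", 1000.0, 10.0)])
        para = make_table(para_meta, [(211, "V211-g1", 5.0, 10.0)])  # 0.5 σ
        prof = build_pre_profile(dia, para, bleach_snr_threshold=3.0)
        rec = prof.df.iloc[0]
        assert rec["bleached"] and rec["is_lower_bound"]
        # lower bound computed at the 3σ floor, not at the noise-level value
        assert rec["i_ratio"] == pytest.approx(1000.0 / 30.0)

    def test_missing_para_key_reported_bleached(self, dia_meta, para_meta):
        dia = make_table(dia_meta, [(20, "V20-g1", 1000.0, 10.0),
                                    (31, "I31-d1", 1000.0, 10.0)])
        para = make_table(para_meta, [(20, "V20-g1", 500.0, 10.0)])
        prof = build_pre_profile(dia, para)
        row = prof.df[prof.df["residue_index"] == 31].iloc[0]
        assert row["bleached"] and row["is_lower_bound"]

    def test_no_record_loss(self, simple_pair):
        dia, para = simple_pair
        prof = build_pre_profile(dia, para)
        assert set(zip(prof.df["residue_index"], prof.df["methyl_id"])) == dia.keys()
        assert not prof.df.duplicated(["residue_index", "methyl_id"]).any()


class TestDeltaI:
    def test_identical_profiles_zero(self, simple_pair):
        dia, para = simple_pair
        prof = build_pre_profile(dia, para)
        di = delta_I(prof, prof)
        assert np.allclose(di["delta_i"], 0.0)

    def test_planted_difference_with_mc_sigma(self, dia_meta, para_meta):
        # profile a: ratio 5.2 at V197; profile b: ratio 2.1
        dia_a = make_table(dia_meta, [(197, "V197-g1", 1040.0, 10.0)])
        para_a = make_table(para_meta, [(197, "V197-g1", 200.0, 10.0)])
        dia_b = make_table(dia_meta, [(197, "V197-g1", 1050.0, 10.0)])
        para_b = make_table(para_meta, [(197, "V197-g1", 500.0, 10.0)])
        pa, pb = build_pre_profile(dia_a, para_a), build_pre_profile(dia_b, para_b)
        di = delta_I(pa, pb)
        assert di.loc[0, "delta_i"] == pytest.approx(5.2 - 2.1)
        rng = np.random.default_rng(7)
        n = 100_000
        mc = (rng.normal(1040, 10, n) / rng.normal(200, 10, n)
              - rng.normal(1050, 10, n) / rng.normal(500, 10, n)).std(ddof=1)
        assert di.loc[0, "sigma_delta_i"] == pytest.approx(mc, rel=0.05)

    def test_antisymmetry(self, dia_meta, para_meta):
        dia = make_table(dia_meta, [(20, "V20-g1", 1000.0, 10.0),
                                    (197, "V197-g1", 1000.0, 10.0)])
        para_a = make_table(para_meta, [(20, "V20-g1", 400.0, 10.0),
                                        (197, "V197-g1", 250.0, 10.0)])
        para_b = make_table(para_meta, [(20, "V20-g1", 900.0, 10.0),
                                        (197, "V197-g1", 700.0, 10.0)])
        pa, pb = build_pre_profile(dia, para_a), build_pre_profile(dia, para_b)
        ab, ba = delta_I(pa, pb), delta_I(pb, pa)
        assert np.allclose(ab["delta_i"], -ba["delta_i"])

    def test_bleached_side_gives_sign_only(self, dia_meta, para_meta):
        dia = make_table(dia_meta, [(211, "V211-g1", 1000.0, 10.0)])
        para_bleached = make_table(para_meta, [(211, "V211-g1", 5.0, 10.0)])
        para_modest = make_table(para_meta, [(211, "V211-g1", 700.0, 10.0)])
        pa = build_pre_profile(dia, para_bleached)
        pb = build_pre_profile(dia, para_modest)
        di = delta_I(pa, pb)
        assert bool(di.loc[0, "sign_only"]) and di.loc[0, "sign"] == 1

    def test_disjoint_profiles_error(self, dia_meta, para_meta):
        dia_a = make_table(dia_meta, [(20, "V20-g1", 1.0, 0.1)])
        dia_b = make_table(dia_meta, [(31, "I31-d1", 1.0, 0.1)])
        pa = build_pre_profile(dia_a, make_table(para_meta, [(20, "V20-g1", 1.0, 0.1)]))
        pb = build_pre_profile(dia_b, make_table(para_meta, [(31, "I31-d1", 1.0, 0.1)]))
        with pytest.raises(ValueError, match="share no"):
            delta_I(pa, pb)


class TestGroups:
    def test_default_config_labels(self, dia_meta, para_meta):
        rows = [(197, "V197-g1", 1.0, 0.1), (225, "I225-d1", 1.0, 0.1),
                (50, "L50-d1", 1.0, 0.1)]
        prof = annotate_groups(
            build_pre_profile(make_table(dia_meta, rows), make_table(para_meta, rows))
        )
        by_res = prof.df.set_index("residue_index")["group"]
        assert by_res[197] == "distal_group2"
        assert by_res[225] == "proximal_group1"
        assert by_res[50] == "unassigned"

    def test_empty_config_all_unassigned(self, simple_pair):
        dia, para = simple_pair
        prof = annotate_groups(build_pre_profile(dia, para), {})
        assert (prof.df["group"] == "unassigned").all()

    def test_overlapping_lists_rejected(self, simple_pair):
        dia, para = simple_pair
        with pytest.raises(ValueError, match="197"):
            annotate_groups(build_pre_profile(dia, para),
                            {"g1": (197,), "g2": (197, 20)})
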