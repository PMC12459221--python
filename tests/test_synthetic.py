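"""Forward-model generators: determinism, closure, planted-parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from premap.md_distances import close_fraction, distance_series
from premap.pre_core import build_pre_profile, gamma2_two_point
from premap.spre import build_phi_profile
from premap.synthetic import (
    DEFAULT_EVOLUTION_TIME_S,
    LoopEnsembleModel,
    SurfaceChargeModel,
    default_pre_scale_K,
    gamma2_from_ensemble,
    generate_pre_tables,
    generate_snapshots,
    generate_spre_tables,
    two_point_intensities,
)


def probe(res=197, methyl="V197-g1", xyz=(0.0, 0.0, 0.0)):
    return {(res, methyl): np.array(xyz, dtype=float)}


class TestGamma2FromEnsemble:
    def test_single_member_closed_form(self):
        m = LoopEnsembleModel(members=[[10.0, 0, 0]], weights=[1.0],
                              probe_sites=probe(), pre_scale_K=1e6)
        assert gamma2_from_ensemble(m, (197, "V197-g1")) == pytest.approx(1.0)

    def test_degenerate_mixture_equals_single(self):
        m1 = LoopEnsembleModel(members=[[12.0, 0, 0]], weights=[1.0],
                               probe_sites=probe())
        m2 = LoopEnsembleModel(members=[[12.0, 0, 0], [12.0, 0, 0]],
                               weights=[0.5, 0.5], probe_sites=probe())
        key = (197, "V197-g1")
        assert gamma2_from_ensemble(m1, key) == pytest.approx(
            gamma2_from_ensemble(m2, key), rel=1e-12)

    def test_mixture_matches_weighted_closed_form(self):
        m = LoopEnsembleModel(members=[[10.0, 0, 0], [40.0, 0, 0]],
                              weights=[0.08, 0.92], probe_sites=probe())
        expected = m.pre_scale_K * (0.08 * 10.0**-6 + 0.92 * 40.0**-6)
        assert gamma2_from_ensemble(m, (197, "V197-g1")) == pytest.approx(
            expected, rel=1e-12)

    def test_monotone_in_distance(self):
        key = (197, "V197-g1")
        g = [gamma2_from_ensemble(
                LoopEnsembleModel(members=[[r, 0, 0]], weights=[1.0],
                                  probe_sites=probe()), key)
             for r in (8.0, 12.0, 20.0, 30.0)]
        assert all(a > b for a, b in zip(g, g[1:]))

    def test_label_clash_raises(self):
        m = LoopEnsembleModel(members=[[0.0, 0, 0]], weights=[1.0],
                              probe_sites=probe())
        with pytest.raises(ValueError, match="coincides"):
            gamma2_from_ensemble(m, (197, "V197-g1"))


class TestGeneratePreTables:
    def two_pop_model(self, noise=0.0):
        return LoopEnsembleModel(
            members=[[0.0, 0, 0], [28.0, 21.0, 0]], weights=[0.08, 0.92],
            probe_sites={(197, "V197-g1"): np.array([12.0, 0.0, 0.0]),
                         (20, "V20-g1"): np.array([0.0, 18.0, 0.0]),
                         (237, "I237-d1"): np.array([40.0, -20.0, 0.0])},
            noise_sigma=noise)

    def test_noiseless_zero_pre_gives_unit_ratios(self):
        m = LoopEnsembleModel(members=[[500.0, 0, 0]], weights=[1.0],
                              probe_sites=probe(), pre_scale_K=1e-6, noise_sigma=0.0)
        dia, para, _ = generate_pre_tables(m, seed=0)
        prof = build_pre_profile(dia, para)
        assert np.allclose(prof.df["i_ratio"], 1.0, atol=1e-9)

    def test_noiseless_recovery_of_planted_ratios(self):
        dia, para, truth = generate_pre_tables(self.two_pop_model(), c_true=0.85, seed=0)
        prof = build_pre_profile(dia, para)
        merged = prof.df.merge(truth, on=["residue_index", "methyl_id"])
        assert np.allclose(merged["i_ratio"], merged["ratio_true"], rtol=1e-12)

    def test_planted_excursion_site_has_max_ratio(self):
        dia, para, truth = generate_pre_tables(self.two_pop_model(noise=5.0), seed=1)
        prof = build_pre_profile(dia, para)
        top = prof.df.loc[prof.df["i_ratio"].idxmax(), "methyl_id"]
        assert top == truth.loc[truth["ratio_true"].idxmax(), "methyl_id"]

    def test_seed_determinism(self):
        m = self.two_pop_model(noise=20.0)
        a = generate_pre_tables(m, seed=3)
        b = generate_pre_tables(m, seed=3)
        assert a[0].df.equals(b[0].df) and a[1].df.equals(b[1].df)

    def test_detection_ceiling(self):
        # beyond 25 Å the planted attenuation is within 3σ of no PRE at the
        # default calibration, i.e. indistinguishable from ratio 1
        m = LoopEnsembleModel(members=[[0.0, 0, 0]], weights=[1.0],
                              probe_sites={(1, "X1-m1"): np.array([30.0, 0.0, 0.0])},
                              noise_sigma=20.0)
        dia, para, truth = generate_pre_tables(m, seed=2)
        prof = build_pre_profile(dia, para)
        rec = prof.df.iloc[0]
        assert abs(rec["i_ratio"] - 1.0) < 3 * rec["sigma_ratio"]
        # while at 15 Å the PRE is well resolved
        m2 = LoopEnsembleModel(members=[[0.0, 0, 0]], weights=[1.0],
                               probe_sites={(1, "X1-m1"): np.array([15.0, 0.0, 0.0])},
                               noise_sigma=20.0)
        dia2, para2, _ = generate_pre_tables(m2, seed=2)
        rec2 = build_pre_profile(dia2, para2).df.iloc[0]
        assert rec2["i_ratio"] - 1.0 > 3 * rec2["sigma_ratio"]

    def test_gamma2_closure_through_two_point(self):
        # planted ensemble Γ₂ recovered through the full two-point pathway
        truth = self.two_pop_model()
        for key in truth.probe_sites:
            g2 = gamma2_from_ensemble(truth, key)
            ints = two_point_intensities(g2, 0.002, 0.010)
            rec = gamma2_two_point(*ints, 0.002, 0.010)
            assert rec.gamma2_per_s == pytest.approx(g2, abs=1e-9)


class TestGenerateSpreTables:
    def test_zero_psi_zero_phi(self):
        model = SurfaceChargeModel(psi={i: 0.0 for i in range(5)}, noise_sigma=0.0)
        dia, plus, minus, _ = generate_spre_tables(model, seed=0)
        prof = build_phi_profile(dia, plus, minus)
        assert np.allclose(prof.df["phi"], 0.0, atol=1e-9)

    def test_positive_psi_recovers_positive_phi(self):
        model = SurfaceChargeModel(psi={10: 1.5, 11: 0.0}, noise_sigma=0.0)
        dia, plus, minus, _ = generate_spre_tables(model, seed=0)
        prof = build_phi_profile(dia, plus, minus)
        by_res = prof.df.set_index("residue_index")["phi"]
        assert by_res[10] > 0 and by_res[11] == pytest.approx(0.0, abs=1e-9)

    def test_rank_correlation_at_low_noise(self):
        psi = {i: v for i, v in enumerate(np.linspace(-2, 2, 30))}
        model = SurfaceChargeModel(psi=psi, noise_sigma=20.0)  # σ/I = 0.02
        dia, plus, minus, truth = generate_spre_tables(model, seed=4)
        prof = build_phi_profile(dia, plus, minus)
        merged = prof.df.merge(truth, on="residue_index")
        rho = spearmanr(merged["psi"], merged["phi"]).statistic
        assert rho >= 0.9

    def test_determinism(self):
        model = SurfaceChargeModel(psi={1: 0.5, 2: -0.5})
        a = generate_spre_tables(model, seed=9)
        b = generate_spre_tables(model, seed=9)
        for ta, tb in zip(a[:3], b[:3]):
            assert ta.df.equals(tb.df)


class TestGenerateSnapshots:
    def test_extreme_fractions_exact(self):
        for f, expected in ((0.0, 0.0), (1.0, 1.0)):
            snaps, _ = generate_snapshots(n_frames=25, f_close_inter=f, seed=12)
            census = distance_series(snaps)
            assert close_fraction(census, "inter") == expected

    def test_intra_always_beyond_floor(self):
        snaps, _ = generate_snapshots(n_frames=50, f_close_inter=0.5, seed=13)
        census = distance_series(snaps)
        sub = census.records[census.records["klass"] == "intra"]
        assert (sub["distance_A"] > 25.0).all()

    def test_census_measures_planted_distances(self):
        snaps, truth = generate_snapshots(n_frames=20, f_close_inter=0.3, seed=14)
        census = distance_series(snaps)
        wide = census.records.pivot(index="frame", columns="chain_pair",
                                    values="distance_A")
        for pair, col in (("A->A", "d_AA"), ("A->B", "d_AB"),
                          ("B->A", "d_BA"), ("B->B", "d_BB")):
            assert np.allclose(wide[pair], truth[col], atol=1e-9)

    def test_binomial_recovery(self):
        f = 0.08
        snaps, truth = generate_snapshots(n_frames=600, f_close_inter=f, seed=15)
        census = distance_series(snaps)
        n = 1200  # two inter pairs per frame
        bound = 2 * np.sqrt(f * (1 - f) / n)
        assert abs(close_fraction(census, "inter") - f) <= bound

    def test_determinism(self):
        a, ta = generate_snapshots(n_frames=10, f_close_inter=0.2, seed=16)
        b, tb = generate_snapshots(n_frames=10, f_close_inter=0.2, seed=16)
        assert a.df.equals(b.df) and ta.equals(tb)

    def test_disjoint_range_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            generate_snapshots(n_frames=2, close_range=(5, 30), far_range=(25, 45))
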