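"""Synthetic survey generator: calibration, determinism, statistical structure."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from codmix.markerpanel import gst
from codmix.synthio import (GeneratorConfig, gen_otoliths, gen_reference_freqs,
                            gen_reference_genotypes, gen_station_metadata,
                            gen_survey, generate_all, mixture_probability)


class TestReferenceFreqs:
    def test_zero_target_gives_identical_populations(self):
        cfg = GeneratorConfig(seed=1, mean_gst_target=0.0)
        freqs = gen_reference_freqs(cfg)
        assert (freqs["p_fjord"] == freqs["p_northsea"]).all()
        assert all(gst(r.p_fjord, r.p_northsea) == 0.0
                   for r in freqs.itertuples())

    def test_default_target_realized(self):
        cfg = GeneratorConfig(seed=1)
        freqs = gen_reference_freqs(cfg)
        assert len(freqs) == 26
        mean_gst = np.mean([gst(r.p_fjord, r.p_northsea)
                            for r in freqs.itertuples()])
        assert 0.15 <= mean_gst <= 0.25

    def test_single_locus_symmetric_pair_identity(self):
        """G_ST 0.64 at a centred pair means a frequency gap of 0.8
        (e.g. 0.1 vs 0.9)."""
        cfg = GeneratorConfig(seed=2, n_loci=1, mean_gst_target=0.64)
        freqs = gen_reference_freqs(cfg)
        p1, p2 = freqs.loc[0, ["p_fjord", "p_northsea"]]
        assert gst(p1, p2) == pytest.approx(0.64, abs=1e-9)
        assert abs(p1 - p2) == pytest.approx(0.8, abs=0.12)  # near-centred midpoint

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(mean_gst_target=1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(mean_gst_target=0.99)

    def test_frequencies_strictly_internal(self):
        cfg = GeneratorConfig(seed=3, mean_gst_target=0.9)
        freqs = gen_reference_freqs(cfg)
        for col in ("p_fjord", "p_northsea"):
            assert ((freqs[col] > 0) & (freqs[col] < 1)).all()


class TestReferenceGenotypes:
    def test_fixed_locus_all_homozygous(self):
        freqs = pd.DataFrame({"locus_id": ["a"], "p_fjord": [1.0],
                              "p_northsea": [1.0]})
        g_f, g_n = gen_reference_genotypes(freqs, 20, GeneratorConfig(seed=1))
        assert (g_f["a"] == 2.0).all() and (g_n["a"] == 2.0).all()

    def test_sample_frequencies_near_generating_truth(self):
        cfg = GeneratorConfig(seed=4)
        freqs = gen_reference_freqs(cfg)
        g_f, _ = gen_reference_genotypes(freqs, 300, cfg)
        p_hat = g_f.mean(axis=0) / 2.0
        p = freqs.set_index("locus_id")["p_fjord"]
        se = np.sqrt(p * (1 - p) / (2 * 300))
        assert (np.abs(p_hat - p) <= 4 * se).all()

    def test_full_missingness(self):
        cfg = GeneratorConfig(seed=1, missing_rate=1.0)
        freqs = gen_reference_freqs(cfg)
        g_f, g_n = gen_reference_genotypes(freqs, 10, cfg)
        assert g_f.isna().all().all() and g_n.isna().all().all()

    def test_hwe_within_populations(self):
        """Generated reference genotypes follow Hardy-Weinberg proportions:
        an exact test at alpha=0.001 passes at >= 99% of loci over seeds."""
        def hwe_exact_p(n_aa, n_ab, n_bb):
            # exact conditional distribution of heterozygote count
            n = n_aa + n_ab + n_bb
            na = 2 * n_aa + n_ab
            probs = {}
            for het in range(na % 2, min(na, 2 * n - na) + 1, 2):
                hom_a = (na - het) // 2
                hom_b = n - hom_a - het
                if hom_b < 0:
                    continue
                from scipy.special import gammaln
                lp = (gammaln(n + 1) - gammaln(hom_a + 1) - gammaln(het + 1)
                      - gammaln(hom_b + 1) + het * np.log(2)
                      + gammaln(na + 1) + gammaln(2 * n - na + 1) - gammaln(2 * n + 1))
                probs[het] = np.exp(lp)
            tot = sum(probs.values())
            p_obs = probs[n_ab] / tot
            return sum(v for v in probs.values() if v / tot <= p_obs / tot + 1e-12) / tot

        n_pass = n_tot = 0
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed, n_ref_per_pop=100)
            freqs = gen_reference_freqs(cfg)
            for g in gen_reference_genotypes(freqs, 100, cfg):
                for locus in g.columns:
                    counts = g[locus].value_counts()
                    n_bb, n_ab, n_aa = (int(counts.get(k, 0)) for k in (0.0, 1.0, 2.0))
                    p = hwe_exact_p(n_aa, n_ab, n_bb)
                    n_tot += 1
                    n_pass += p > 0.001
        assert n_pass / n_tot >= 0.99


class TestStations:
    def test_one_station_per_region_when_equal(self):
        cfg = GeneratorConfig(seed=1, n_stations=15, n_regions=15)
        st = gen_station_metadata(cfg)
        assert st["region"].nunique() == 15
        assert st["region"].value_counts().max() == 1

    def test_distances_span_survey_gradient(self):
        st = gen_station_metadata(GeneratorConfig(seed=1))
        assert st["distance_m"].min() == 0.0
        assert st["distance_m"].max() >= 20000.0
        assert st["distance_m"].between(0, 25000).all()

    def test_covariates_valid(self):
        st = gen_station_metadata(GeneratorConfig(seed=2))
        assert (st["wave_exposure"] > 0).all()
        assert set(st["veg_type"]) <= {"eelgrass", "macroalgae"}
        assert st["veg_cover"].isin([1, 2, 3, 4, 5]).all()

    def test_deterministic(self):
        cfg = GeneratorConfig(seed=5)
        pd.testing.assert_frame_equal(gen_station_metadata(cfg),
                                      gen_station_metadata(cfg))

    def test_fewer_stations_than_regions_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_stations=5, n_regions=15)


class TestSurvey:
    def test_pure_northsea_limit(self):
        cfg = GeneratorConfig(seed=1, mixture_intercept=1.0, mixture_slope=0.0,
                              n_stations=10, n_regions=5, haul_rate=1.0,
                              years=(2000,))
        stations = gen_station_metadata(cfg)
        freqs = gen_reference_freqs(cfg)
        survey, _ = gen_survey(cfg, stations, freqs)
        # clamping caps the probability at 0.99
        assert (survey["ecotype_true"] == "northsea").mean() > 0.95

    def test_mixture_probability_clamped(self):
        cfg = GeneratorConfig(seed=1, mixture_intercept=0.55)
        p = mixture_probability(cfg, np.array([0.0, 1e6]))
        assert p[0] == pytest.approx(0.55)
        assert p[1] == 0.01

    def test_origin_length_difference_matches_truth(self, default_bundle):
        """Within-haul mean log-length difference (North Sea - fjord) is the
        generating origin effect plus its wave-exposure/vegetation
        interactions at the haul's covariates."""
        sv = default_bundle["survey"]
        truth = default_bundle["config"].lmm_truth
        sv = sv.assign(log_len=np.log(sv["length_cm"]))
        expected = (truth["co_northsea"]
                    + truth["we_co"] * np.log(sv["wave_exposure"])
                    + truth["vt_co"] * (sv["veg_type"] == "macroalgae"))
        adj = sv["log_len"] - np.where(sv["ecotype_true"] == "northsea",
                                       expected, 0.0)
        hauls = sv.assign(adj=adj).groupby(["station", "year"])
        diffs = []
        weights = []
        for _, h in hauls:
            ns = h[h["ecotype_true"] == "northsea"]["adj"]
            fj = h[h["ecotype_true"] == "fjord"]["adj"]
            if len(ns) >= 2 and len(fj) >= 2:
                diffs.append(ns.mean() - fj.mean())
                weights.append(2.0 / (1.0 / len(ns) + 1.0 / len(fj)))
        mean_diff = np.average(diffs, weights=weights)
        # adjusted difference should vanish up to Monte Carlo error
        assert abs(mean_diff) < 0.02

    def test_survey_determinism(self, small_config):
        b1 = generate_all(small_config)
        b2 = generate_all(small_config)
        pd.testing.assert_frame_equal(b1["survey"], b2["survey"])
        pd.testing.assert_frame_equal(b1["genotypes"], b2["genotypes"])

    def test_region_variance_share_near_8_percent(self):
        """Empirical region-effect variance over total is ~8% at defaults."""
        shares = []
        for seed in (1, 2, 3):
            cfg = GeneratorConfig(seed=seed, n_stations=60, n_regions=15,
                                  haul_rate=0.3)
            sv = generate_all(cfg)["survey"]
            truth = cfg.lmm_truth
            eta = (truth["intercept"]
                   + sv["year"].map(truth["year"]).fillna(0.0)
                   + truth["we"] * np.log(sv["wave_exposure"])
                   + truth["vt_macroalgae"] * (sv["veg_type"] == "macroalgae")
                   + truth["vc"] * sv["veg_cover"]
                   + (sv["ecotype_true"] == "northsea")
                   * (truth["co_northsea"]
                      + truth["we_co"] * np.log(sv["wave_exposure"])
                      + truth["vt_co"] * (sv["veg_type"] == "macroalgae")))
            resid = np.log(sv["length_cm"]) - eta
            region_means = resid.groupby(sv["region"]).mean()
            var_region = region_means.var(ddof=1)
            var_within = resid.groupby(sv["region"]).var(ddof=1).mean()
            shares.append(var_region / (var_region + var_within))
        assert np.mean(shares) == pytest.approx(0.08, abs=0.04)


class TestMixtureCalibration:
    def test_assignment_recovers_pooled_fraction(self):
        """With strongly divergent references, the assignment stage's pooled
        North-Sea fraction is within 0.03 of the generator's expectation."""
        from codmix.assign import ReferencePanel, assign_cohort

        cfg = GeneratorConfig(seed=13, mean_gst_target=0.6, n_stations=40,
                              n_regions=8, haul_rate=0.3)
        b = generate_all(cfg)
        panel = ReferencePanel.from_genotypes(b["ref_genotypes"], b["ref_labels"])
        table, _ = assign_cohort(b["genotypes"], panel)
        assigned = table[table["label"] != "unassigned"]
        frac = (assigned["label"] == "northsea").mean()
        expected = b["survey"]["p_ns_true"].mean()
        assert abs(frac - expected) <= 0.03


class TestOtolithGenerator:
    def test_length_identity(self):
        cfg = GeneratorConfig(seed=2)
        fish, _ = gen_otoliths(5, [dt.date(2015, 9, 23)], cfg)
        for r in fish.itertuples(index=False):
            assert r.length_capture_mm == pytest.approx(
                4.5 + r.growth_target_mm_day * r.age_days_true)

    def test_growth_targets_in_range(self):
        cfg = GeneratorConfig(seed=2)
        fish, _ = gen_otoliths(30, [dt.date(2015, 9, 21)], cfg)
        assert fish["growth_target_mm_day"].between(0.46, 0.86).all()

    def test_hatch_dates_in_window(self):
        cfg = GeneratorConfig(seed=2)
        fish, _ = gen_otoliths(30, [dt.date(2015, 9, 21)], cfg)
        lo, hi = cfg.hatch_window
        assert ((fish["hatch_date_true"] >= lo) & (fish["hatch_date_true"] <= hi)).all()

    def test_radius_identity(self):
        cfg = GeneratorConfig(seed=2)
        fish, inc = gen_otoliths(5, [dt.date(2015, 9, 21)], cfg)
        for r in fish.itertuples(index=False):
            s = inc[inc["fish_id"] == r.fish_id]["increment_width_um"].sum()
            assert r.o_capture_um == pytest.approx(9.0 + s, abs=1e-6)
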