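"""Generator correctness: input models, compartment solutions, noise, phantoms
and cohort statistics, each checked against an independent closed form or a
Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from petkin import core, synthetic as syn
from petkin.errors import ConfigurationError, ContractError


class TestAif:
    def test_zero_amplitude_curve_is_zero(self):
        p = syn.AifParams(amplitudes=(0.0, 0.0, 0.0))
        t = np.linspace(0, 60, 50)
        assert np.all(p(t) == 0)
        assert p.peak_value == 0

    def test_single_exponential_e_folding(self):
        # one e-folding time after the peak the curve equals A1/e
        p = syn.AifParams(peak_time=1.0, amplitudes=(10.0, 0.0, 0.0),
                          decay_rates=(0.5, 1.0, 2.0))
        val = p(np.array([1.0 + 1.0 / 0.5]))[0]
        assert val == pytest.approx(10.0 / np.e, abs=1e-9)

    def test_arterial_sampling_times(self, aif):
        tac = syn.simulate_aif(aif, core.ARTERIAL_SAMPLE_TIMES)
        assert len(tac) == 25
        assert np.all(tac.activity >= 0)

    def test_continuity_at_peak(self, aif):
        eps = 1e-9
        lo, hi = aif(np.array([aif.peak_time - eps, aif.peak_time + eps]))
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_cum_integral_matches_quadrature(self, aif):
        from scipy.integrate import quad
        for t_end in (0.7, 5.0, 42.0):
            num, _ = quad(lambda s: float(aif(np.array([s]))[0]), 0, t_end,
                          limit=200)
            assert aif.cum_integral(np.array([t_end]))[0] == pytest.approx(
                num, rel=1e-8)

    def test_nonincreasing_times_rejected(self, aif):
        with pytest.raises(ContractError):
            syn.simulate_aif(aif, np.array([0.0, 2.0, 1.0]))


class TestParentFraction:
    def test_starts_at_one(self, hill):
        assert syn.parent_fraction(hill, np.array([0.0]))[0] == 1.0

    def test_half_metabolized_at_60min(self, hill):
        assert hill(60.0) == pytest.approx(0.50, abs=0.02)

    def test_no_metabolism_limit(self):
        p = syn.HillParams(a=0.0)
        assert np.all(p(np.linspace(0, 120, 50)) == 1.0)

    def test_negative_time_rejected(self, hill):
        with pytest.raises(ContractError):
            hill(np.array([-1.0]))

    @given(a=st.floats(0, 1), b=st.floats(0.1, 5), c=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, a, b, c):
        p = syn.HillParams(a=a, b=b, c=c)
        t = np.linspace(0, 120, 200)
        f = p(t)
        assert np.all((f >= 1 - a - 1e-12) & (f <= 1 + 1e-12))
        assert np.all(np.diff(f) <= 1e-12)


def _oracle_1tcm(K1, k2, aif, t):
    """Independent closed-form 1TCM convolution for the ramp+tri-exp input."""
    t = np.asarray(t, dtype=float)
    tp, m = aif.peak_time, aif.peak_value / aif.peak_time
    out = np.zeros_like(t)
    pre = t <= tp
    out[pre] = m * (t[pre] / k2 - (1 - np.exp(-k2 * t[pre])) / k2 ** 2)
    u = t[~pre] - tp
    ramp_tp = m * (tp / k2 - (1 - np.exp(-k2 * tp)) / k2 ** 2)
    tail = np.zeros_like(u)
    for a, lam in zip(aif.amplitudes, aif.decay_rates):
        tail += a * (np.exp(-lam * u) - np.exp(-k2 * u)) / (k2 - lam)
    out[~pre] = ramp_tp * np.exp(-k2 * u) + tail
    return K1 * out


class TestTwoTissueModel:
    def test_zero_input_zero_tissue(self, schedule):
        p = syn.AifParams(amplitudes=(0.0, 0.0, 0.0))
        tac = syn.simulate_2tcm(syn.TcmParams(K1=0.1, k2=0.05), p, schedule)
        assert np.all(tac.activity == 0)

    def test_matches_independent_1tcm_convolution(self, aif):
        """The general 2TCM solution collapses to the separately derived
        1TCM closed form when k3 = k4 = 0 (machine-precision agreement)."""
        t = np.linspace(0.01, 60, 400)
        mine = syn.tissue_curve(syn.TcmParams(K1=0.12, k2=0.17), aif, t)
        oracle = _oracle_1tcm(0.12, 0.17, aif, t)
        assert np.max(np.abs(mine - oracle)) < 1e-6

    def test_linearity_in_k1(self, aif, schedule):
        base = syn.simulate_2tcm(syn.TcmParams(K1=0.15, k2=0.2, k3=0.1, k4=0.1),
                                 aif, schedule)
        dbl = syn.simulate_2tcm(syn.TcmParams(K1=0.30, k2=0.2, k3=0.1, k4=0.1),
                                aif, schedule)
        assert np.allclose(dbl.activity, 2 * base.activity, rtol=1e-9)

    def test_logan_recovers_1tcm_vt(self, aif, schedule):
        from petkin.kinetics import logan_vt
        tcm = syn.TcmParams(K1=0.1, k2=0.05)
        tac = syn.simulate_2tcm(tcm, aif, schedule)
        res = logan_vt(tac, aif, t_star=10)
        assert res.vt == pytest.approx(2.0, rel=0.01)

    def test_sampled_input_agrees_with_analytic(self, aif, schedule):
        """Piecewise-linear convolution path vs the closed-form path."""
        fine = np.linspace(0.0, 60.0, 6001)[1:]
        sampled = core.TimeActivityCurve(fine, aif(fine))   # model stripped
        tcm = syn.TcmParams(K1=0.2, k2=0.2, k3=0.15, k4=0.1)
        a = syn.simulate_2tcm(tcm, aif, schedule)
        b = syn.simulate_2tcm(tcm, sampled, schedule)
        assert np.allclose(a.activity, b.activity, rtol=2e-3, atol=1e-3)

    def test_input_not_covering_schedule(self, aif, schedule):
        short = core.TimeActivityCurve(np.linspace(0.1, 30, 50),
                                       aif(np.linspace(0.1, 30, 50)))
        with pytest.raises(Exception):
            syn.simulate_2tcm(syn.TcmParams(K1=0.1, k2=0.1), short, schedule)


class TestNoise:
    def test_zero_noise_identity(self, aif, schedule):
        tac = syn.simulate_2tcm(syn.TcmParams(K1=0.3, k2=0.25), aif, schedule)
        out = syn.add_tac_noise(tac, schedule, 0.0, seed=1)
        assert np.array_equal(out.activity, tac.activity)

    def test_seed_determinism(self, aif, schedule):
        tac = syn.simulate_2tcm(syn.TcmParams(K1=0.3, k2=0.25), aif, schedule)
        a = syn.add_tac_noise(tac, schedule, 0.05, seed=42)
        b = syn.add_tac_noise(tac, schedule, 0.05, seed=42)
        assert np.array_equal(a.activity, b.activity)

    def test_last_frame_sd_matches_nominal(self, aif, schedule):
        """Monte-Carlo check of the variance model at the last frame."""
        tac = syn.simulate_2tcm(syn.TcmParams(K1=0.3, k2=0.25, k3=0.15, k4=0.15),
                                aif, schedule)
        last = np.array([syn.add_tac_noise(tac, schedule, 0.05, seed=s).activity[-1]
                         for s in range(1000)])
        nominal = 0.05 * tac.activity[-1]
        assert np.std(last) == pytest.approx(nominal, rel=0.15)


class TestPhantom:
    def test_noiseless_voxels_equal_regional_tac(self, noiseless_phantom, atlas,
                                                 regional_params, aif, schedule):
        tac = syn.simulate_2tcm(regional_params["thalamus_P"], aif, schedule)
        vox = noiseless_phantom.voxels[atlas.mask("thalamus_P")]
        assert np.allclose(vox, tac.activity[None, :])

    def test_background_voxels_zero(self, noiseless_phantom, atlas):
        assert np.all(noiseless_phantom.voxels[atlas.labels == 0] == 0)

    def test_missing_region_params(self, atlas, aif, schedule, regional_params):
        incomplete = {k: v for k, v in regional_params.items() if k != "medulla"}
        with pytest.raises(ConfigurationError):
            syn.build_phantom(atlas, incomplete, aif, schedule, 0.0, seed=0)

    def test_reference_region_must_have_k3_zero(self, atlas, aif, schedule,
                                                regional_params):
        bad = dict(regional_params)
        bad["cerebellum"] = syn.TcmParams(K1=0.3, k2=0.25, k3=0.1, k4=0.1)
        with pytest.raises(ConfigurationError):
            syn.build_phantom(atlas, bad, aif, schedule, 0.0, seed=0)

    def test_two_seeds_same_regional_means(self, atlas, regional_params, aif,
                                           schedule):
        a = syn.build_phantom(atlas, regional_params, aif, schedule, 0.05, seed=1)
        b = syn.build_phantom(atlas, regional_params, aif, schedule, 0.05, seed=2)
        assert not np.array_equal(a.voxels, b.voxels)
        m = atlas.mask("thalamus_P")
        assert a.voxels[m].mean() == pytest.approx(b.voxels[m].mean(), rel=0.02)


class TestGroundTruthIdentity:
    def test_dvr_bpnd_identity_on_parameter_tables(self):
        """Configured DVR truth = Vt/Vt_ref and BPnd = DVR - 1 exactly."""
        ref = syn.tcm_for_bpnd(0.0)
        for bp in (0.0, 0.3, 1.0, 1.6):
            p = syn.tcm_for_bpnd(bp)
            dvr = p.vt / ref.vt
            assert dvr == pytest.approx(1.0 + bp, rel=1e-12)
            assert p.bpnd == pytest.approx(dvr - 1.0, rel=1e-12)


class TestCohort:
    def test_study_size(self, atlas):
        d = syn.generate_cohort(syn.CohortSpec(), atlas, image_mode="none")
        sexes = [r.sex for r in d.records]
        assert len(d.records) == 21
        assert sexes.count("F") == 10 and sexes.count("M") == 11

    def test_seed_determinism(self, atlas):
        a = syn.generate_cohort(syn.CohortSpec(seed=5), atlas, image_mode="none")
        b = syn.generate_cohort(syn.CohortSpec(seed=5), atlas, image_mode="none")
        assert a.truth.equals(b.truth)
        assert [r.baq_total for r in a.records] == [r.baq_total for r in b.records]

    def test_male_female_shift_except_right_hypothalamus(self):
        means = syn.default_region_means()
        for region, (f, m) in means.items():
            if region == "hypothalamus_R":
                assert f > m
            elif region != "cerebellum":
                assert m > f

    def test_unsatisfiable_r2_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.TraitLink("baq_total", "amygdala_L", "positive", 1.0)

    def _sample_r2(self, spec, atlas, trait, region):
        d = syn.generate_cohort(spec, atlas, image_mode="none")
        piv = d.truth.pivot(index="subject", columns="region",
                            values="bpnd_truth")
        cols = [c for c in piv.columns if c == region or
                (region not in piv.columns and c.startswith(region))]
        x = piv[cols].mean(axis=1)
        y = {r.id: (r.baq_total if trait == "baq_total" else r.tci[trait])
             for r in d.records}
        y = np.array([y[s] for s in piv.index])
        return stats.linregress(x.to_numpy(), y).rvalue ** 2

    def test_target_r2_calibration(self, atlas):
        """n=200 cohorts with target R2 = 0.8 land inside the Monte-Carlo
        90 percent band of the bivariate-normal sampling distribution."""
        rng = np.random.default_rng(0)
        rho = np.sqrt(0.8)
        r2s = []
        for _ in range(2000):
            z = rng.standard_normal((200, 2))
            x, y = z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
            r2s.append(stats.pearsonr(x, y)[0] ** 2)
        lo, hi = np.quantile(r2s, [0.05, 0.95])
        link = syn.TraitLink("baq_total", "amygdala_L", "positive", 0.8)
        spec = syn.CohortSpec(n_female=100, n_male=100, trait_links=(link,),
                              seed=11)
        r2 = self._sample_r2(spec, atlas, "baq_total", "amygdala_L")
        assert lo <= r2 <= hi

    def test_null_link_uncorrelated(self, atlas):
        spec = syn.CohortSpec(n_female=100, n_male=100, trait_links=(), seed=3)
        r2 = self._sample_r2(spec, atlas, "baq_total", "amygdala_L")
        n = 200
        r = np.sqrt(r2)
        t = r * np.sqrt((n - 2) / (1 - r2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert p > 0.01

    def test_negative_direction_link(self, atlas):
        link = syn.TraitLink("cooperativeness", "thalamus", "negative", 0.71)
        spec = syn.CohortSpec(n_female=100, n_male=100, trait_links=(link,),
                              seed=9)
        d = syn.generate_cohort(spec, atlas, image_mode="none")
        piv = d.truth.pivot(index="subject", columns="region",
                            values="bpnd_truth")
        x = piv[[c for c in piv.columns if c.startswith("thalamus")]].mean(axis=1)
        y = {r.id: r.tci["cooperativeness"] for r in d.records}
        y = np.array([y[s] for s in piv.index])
        assert stats.pearsonr(x.to_numpy(), y)[0] < -0.6
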