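import numpy as np
import pytest
from scipy import stats

from ecdysis import coupling, preprocess, synthetic, timefreq as tf
from ecdysis.core import CCAP_ALPHA, CCAP_BETA, MN_REGION, Experiment, NeuronID, Trace

from conftest import make_trace, sine_trace


def nid(kind, side, seg=None):
    return NeuronID(kind, side, seg)


class TestClassifyPair:
    def test_contralateral_same_segment(self):
        cls = coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(CCAP_ALPHA, "R", 2))
        assert cls.category == "contralateral" and cls.group == "C"

    def test_ipsilateral_two_segments_apart(self):
        cls = coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(CCAP_ALPHA, "L", 4))
        assert cls.category == "ipsilateral"
        assert cls.seg_distance == 2 and cls.group == "I3"

    def test_other_pair(self):
        cls = coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(CCAP_ALPHA, "R", 3))
        assert cls.category == "other" and cls.group == "O"

    def test_same_hemisegment_alpha_beta_is_i1(self):
        cls = coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(CCAP_BETA, "L", 2))
        assert cls.group == "I1"

    def test_identical_ids_rejected(self):
        with pytest.raises(ValueError):
            coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(CCAP_ALPHA, "L", 2))

    def test_motoneuron_rejected(self):
        with pytest.raises(ValueError):
            coupling.classify_pair(nid(CCAP_ALPHA, "L", 2), nid(MN_REGION, "R"))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert coupling.pearson(x, x) == pytest.approx(1.0)
        assert coupling.pearson(x, -x) == pytest.approx(-1.0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(0)
        assert abs(coupling.pearson(rng.normal(size=10**4), rng.normal(size=10**4))) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            coupling.pearson(np.ones(5), np.arange(5.0))


class TestGroupCorrelations:
    def test_identical_traces_r_one_in_all_domains(self):
        t = 2.5 * np.arange(1000)
        v = np.abs(np.sin(2 * np.pi * t / 100)) * np.exp(-(((t - 1200) / 500) ** 2))
        traces = [
            Trace(nid(CCAP_ALPHA, "L", 1), t, v, 2.5),
            Trace(nid(CCAP_ALPHA, "R", 1), t, v, 2.5),
        ]
        exp = Experiment(traces=traces)
        for domain in ("time", "tf_amplitude", "tf_amp_phase"):
            out = coupling.group_correlations(exp, domain)
            assert out["C"][0] == pytest.approx(1.0, abs=1e-9)

    def test_envelope_vs_phase_contrast(self, preprocessed_experiment):
        """Shared envelope with random phases: amplitude correlations are
        high while amplitude+phase correlations collapse."""
        exp, _ = preprocessed_experiment
        ccap = Experiment(traces=[tr for tr in exp.traces if tr.id.is_ccap])
        r_amp = np.concatenate(list(coupling.group_correlations(ccap, "tf_amplitude").values()))
        r_ap = np.concatenate(list(coupling.group_correlations(ccap, "tf_amp_phase").values()))
        assert np.median(r_amp) > 0.5
        assert np.median(r_amp) - np.median(r_ap) > 0.3

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        t = 2.5 * np.arange(2000)
        traces = [
            Trace(nid(CCAP_ALPHA, "L", 1), t, rng.normal(size=2000), 2.5),
            Trace(nid(CCAP_ALPHA, "R", 1), t, rng.normal(size=2000), 2.5),
        ]
        out = coupling.group_correlations(Experiment(traces=traces), "time")
        assert abs(out["C"][0]) < 0.1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        t = 2.5 * np.arange(800)
        v1, v2 = rng.random(800), rng.random(800)
        def exp_of(a, b):
            return Experiment(traces=[
                Trace(nid(CCAP_ALPHA, "L", 1), t, a * v1 + b, 2.5),
                Trace(nid(CCAP_ALPHA, "R", 1), t, a * v2 + b, 2.5),
            ])
        r1 = coupling.group_correlations(exp_of(1.0, 0.0), "time")["C"][0]
        r2 = coupling.group_correlations(exp_of(3.5, 2.0), "time")["C"][0]
        assert r1 == pytest.approx(r2, abs=1e-9)
        # tf domain: offsets leak only through the soft cone-of-influence
        # boundary (zero padding); the residual is bounded and small
        r1 = coupling.group_correlations(exp_of(1.0, 0.0), "tf_amplitude")["C"][0]
        r2 = coupling.group_correlations(exp_of(3.5, 2.0), "tf_amplitude")["C"][0]
        assert r1 == pytest.approx(r2, abs=0.02)


class TestSlidingCorrelation:
    def test_identical_and_inverted(self):
        t = 2.5 * np.arange(400)
        v = np.sin(2 * np.pi * t / 33) + 0.1 * np.random.default_rng(0).normal(size=400)
        left = make_trace(v, side="L")
        ok = slice(30, -30)
        r_same = coupling.sliding_correlation(left, make_trace(v, side="R"))
        r_inv = coupling.sliding_correlation(left, make_trace(-v, side="R"))
        np.testing.assert_allclose(r_same[ok], 1.0, atol=1e-9)
        np.testing.assert_allclose(r_inv[ok], -1.0, atol=1e-9)

    def test_antiphase_sines_negative(self):
        left = sine_trace(33, 1000, side="L")
        right = sine_trace(33, 1000, phase=np.pi, side="R")
        r = coupling.sliding_correlation(left, right)
        interior = r[40:-40]
        assert np.nanmax(interior) < -0.95

    def test_window_exceeding_span_rejected(self):
        with pytest.raises(ValueError):
            coupling.sliding_correlation(
                sine_trace(33, 50), sine_trace(33, 50), window=100.0
            )


class TestPhaseDifference:
    def test_identical_zero(self):
        L = sine_trace(33, 600, side="L")
        R = sine_trace(33, 600, side="R")
        assert coupling.phase_difference(L, R, 33.0).angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_antiphase_180(self):
        L = sine_trace(33, 600, side="L")
        R = sine_trace(33, 600, phase=np.pi, side="R")
        assert coupling.phase_difference(L, R, 33.0).angle_deg == pytest.approx(180.0, abs=1.0)

    def test_quarter_lag_90(self):
        period = 33.0
        t = 2.5 * np.arange(240)
        L = make_trace(np.sin(2 * np.pi * t / period), side="L")
        R = make_trace(np.sin(2 * np.pi * (t - period / 4) / period), side="R")
        assert coupling.phase_difference(L, R, period).angle_deg == pytest.approx(90.0, abs=2.0)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        t = 2.5 * np.arange(400)
        L = make_trace(np.sin(2 * np.pi * t / 40) + 0.1 * rng.normal(size=400), side="L")
        R = make_trace(np.sin(2 * np.pi * t / 40 + 1.1) + 0.1 * rng.normal(size=400), side="R")
        a = coupling.phase_difference(L, R, 40.0).angle_deg
        b = coupling.phase_difference(R, L, 40.0).angle_deg
        assert (a + b) % 360.0 == pytest.approx(0.0, abs=1e-6) or (a + b) % 360.0 == pytest.approx(360.0, abs=1e-6)


class TestMnAmplitude:
    def test_zero_signal(self):
        tr = sine_trace(33, 600).with_values(np.zeros(240))
        assert np.allclose(coupling.mn_amplitude(tr, 33.0), 0.0)

    def test_linearity_in_amplitude(self):
        tr1 = sine_trace(33, 600, amplitude=1.0)
        tr2 = sine_trace(33, 600, amplitude=2.0)
        a1 = coupling.mn_amplitude(tr1, 33.0)
        a2 = coupling.mn_amplitude(tr2, 33.0)
        interior = slice(40, -40)
        np.testing.assert_allclose(a2[interior] / a1[interior], 2.0, rtol=1e-9)

    def test_gated_sine_tracks_gate(self):
        t = 2.5 * np.arange(480)
        gate = ((t > 300) & (t < 700)) | ((t > 850) & (t < 1050))
        tr = make_trace(gate * np.sin(2 * np.pi * t / 33))
        amp = coupling.mn_amplitude(tr, 33.0)
        assert amp[(t > 400) & (t < 600)].min() > 3 * amp[(t > 100) & (t < 250)].max()


@pytest.fixture(scope="module")
def experiments():
    out = []
    for seed in (1, 2, 3):
        exp, _ = synthetic.gen_experiment(synthetic.SynthParams(seed=seed))
        out.append(Experiment(
            traces=[preprocess.preprocess_trace(tr) for tr in exp.traces],
            label=exp.label,
        ))
    return out


class TestCcapMnCoupling:
    def test_gated_synthetic_significant(self, experiments):
        null = coupling.cross_experiment_null(experiments)
        rs, p = coupling.ccap_mn_correlations(experiments[0], null_rs=null)
        assert np.median(rs) > 0.4
        assert p < 0.05

    def test_block_shuffled_amplitude_not_significant(self, experiments):
        exp = experiments[0]
        null = coupling.cross_experiment_null(experiments)
        left = preprocess.side_average(exp, "L")
        right = preprocess.side_average(exp, "R")
        diff = preprocess.mn_difference(left, right)
        sg = tf.cwt_morlet(diff, 25, 50)
        period = tf.dominant_period(tf.mean_spectrum(sg))
        amp = coupling.mn_amplitude(diff, period)
        rng = np.random.default_rng(0)
        blocks = np.array_split(amp, 12)
        rng.shuffle(blocks)
        shuffled = np.concatenate(blocks)
        rs = [coupling.pearson(tr.v, shuffled) for tr in exp.select(kind=CCAP_ALPHA)]
        assert coupling.mw_u_test(rs, null) > 0.05

    def test_alpha_equal_to_amplitude_gives_r_one(self, experiments):
        exp = experiments[0]
        left = preprocess.side_average(exp, "L")
        right = preprocess.side_average(exp, "R")
        diff = preprocess.mn_difference(left, right)
        amp = coupling.mn_amplitude(diff, 33.0)
        fake = Trace(nid(CCAP_ALPHA, "L", 1), diff.t, amp, diff.dt)
        fake_exp = Experiment(traces=[fake] + exp.select(kind=MN_REGION))
        rs, _ = coupling.ccap_mn_correlations(fake_exp, period=33.0)
        assert rs[0] == pytest.approx(1.0, abs=1e-9)


class TestMWUTest:
    def test_separated_samples_significant(self):
        within = [0.8, 0.85, 0.9, 0.95, 0.99]
        null = [0.1, 0.2, 0.15, 0.05, 0.12]
        p = coupling.mw_u_test(within, null)
        # exact enumeration: U = 25 of 25, one-sided p = 1/C(10,5)
        assert p == pytest.approx(1 / 252, rel=1e-6)

    def test_identical_samples_near_half(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        assert coupling.mw_u_test(list(x), list(x)) == pytest.approx(0.5, abs=0.06)

    def test_single_tie_is_conservative(self):
        # a 1-vs-1 tie carries no evidence; the standard U test returns the
        # conservative p = 1 for the one-sided alternative
        assert coupling.mw_u_test([1.0], [1.0]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            coupling.mw_u_test([], [0.1])
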