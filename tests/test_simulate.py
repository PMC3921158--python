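import numpy as np
import pytest

from plinet.connectivity import cluster_means, connectivity_matrix
from plinet.preprocess import BAND_BY_NAME, bandpass, instantaneous_phase, \
    make_epochs
from plinet.simulate import (BandComponent, CouplingSpec, GroupTemplate,
                             MixingMatrix, SimulationConfig, apply_mixing,
                             control_like_template, fxs_like_template,
                             generate_cohort, generate_recording, subject_seed)


def _pair_pli(recording, band="beta", n_epochs=1, epoch_length=4096):
    filtered = bandpass(recording, BAND_BY_NAME[band])
    ep = make_epochs(filtered, n_epochs, epoch_length)
    phases = [instantaneous_phase(e, ep.channels) for e in ep.epochs]
    return connectivity_matrix(phases).values[0, 1]


class TestConfigValidation:
    def test_label_count_mismatch(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=3, channel_labels=("a", "b"))

    def test_bad_rates_and_durations(self):
        with pytest.raises(ValueError):
            SimulationConfig(sampling_rate=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration=-1.0)

    def test_too_short_for_epochs(self):
        cfg = SimulationConfig(duration=10.0)
        with pytest.raises(ValueError, match="fewer"):
            cfg.check_epochable()

    def test_unknown_coupling_channel(self, beta_pair_config):
        bad = CouplingSpec(("Fz", "XX"), "beta", np.pi / 4, 1.0)
        with pytest.raises(ValueError, match="XX"):
            generate_recording(beta_pair_config, [bad], seed=0)
        with pytest.raises(ValueError, match="unknown"):
            GroupTemplate("g", beta_pair_config, (bad,))

    def test_coupling_spec_invariants(self):
        with pytest.raises(ValueError):
            CouplingSpec(("a", "a"), "theta", 0.5, 0.5)
        with pytest.raises(ValueError):
            CouplingSpec(("a", "b"), "theta", 0.5, 1.5)
        with pytest.raises(ValueError):
            CouplingSpec(("a", "b"), "theta", 4.0, 0.5)


class TestGenerateRecording:
    def test_seed_determinism(self, beta_pair_config):
        c = [CouplingSpec(("Fz", "Pz"), "beta", np.pi / 4, 0.5)]
        a = generate_recording(beta_pair_config, c, seed=7)
        b = generate_recording(beta_pair_config, c, seed=7)
        assert np.array_equal(a.data, b.data)
        c2 = generate_recording(beta_pair_config, c, seed=8)
        assert not np.array_equal(a.data, c2.data)

    def test_full_strength_zero_diffusion_locks_at_lag(self):
        # constant pi/4 lag: every phase-difference sign is identical, so
        # the PLI of the extracted phases is exactly 1
        comps = (BandComponent("beta", 20.0, phase_sigma=0.0, freq_spread=4.0),)
        cfg = SimulationConfig(
            n_channels=2, channel_labels=("Fz", "Pz"), duration=9.0,
            band_components=comps, noise_amplitude=0.0)
        coupling = [CouplingSpec(("Fz", "Pz"), "beta", np.pi / 4, 1.0)]
        rec = generate_recording(cfg, coupling, seed=3)
        ep = make_epochs(rec, 1, 4096)  # single narrowband component:
        phases = [instantaneous_phase(e, ep.channels) for e in ep.epochs]
        assert connectivity_matrix(phases).values[0, 1] == 1.0

    def test_uncoupled_pair_pli_near_zero(self, beta_pair_config):
        # phase-difference signs of independent oscillators average out
        vals = [_pair_pli(generate_recording(beta_pair_config, [], seed=s))
                for s in range(100)]
        assert np.mean(vals) < 0.1

    def test_pli_monotone_in_coupling_strength(self, beta_pair_config):
        means = []
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            c = [CouplingSpec(("Fz", "Pz"), "beta", np.pi / 4, s)]
            vals = [_pair_pli(generate_recording(beta_pair_config, c, seed=k))
                    for k in range(20)]
            means.append(np.mean(vals))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
        assert means[-1] > 0.9 > means[0]


class TestApplyMixing:
    def test_identity_is_exact(self, beta_pair_config):
        rec = generate_recording(beta_pair_config, [], seed=0)
        out = apply_mixing(rec, MixingMatrix(np.eye(2)))
        assert np.array_equal(out.data, rec.data)

    def test_composition_equals_product(self, beta_pair_config, rng):
        rec = generate_recording(beta_pair_config, [], seed=0)
        a = rng.standard_normal((2, 2))
        b = rng.standard_normal((2, 2))
        seq = apply_mixing(apply_mixing(rec, MixingMatrix(a)), MixingMatrix(b))
        combined = apply_mixing(rec, MixingMatrix(b @ a))
        assert np.allclose(seq.data, combined.data, atol=1e-12)

    def test_dimension_mismatch(self, beta_pair_config):
        rec = generate_recording(beta_pair_config, [], seed=0)
        with pytest.raises(ValueError, match="channels"):
            apply_mixing(rec, MixingMatrix(np.eye(3)))

    def test_duplicated_channels_have_zero_pli(self, beta_pair_config):
        rec = generate_recording(beta_pair_config, [], seed=1)
        dup = apply_mixing(rec, MixingMatrix(np.array([[1.0, 0.0], [1.0, 0.0]])))
        assert _pair_pli(dup) == 0.0

    def test_zero_lag_mixing_spurious_correlation_not_pli(self, beta_pair_config):
        # the classic volume-conduction scenario: strong amplitude
        # correlation between mixtures, but no consistent nonzero lag
        mix = MixingMatrix(np.array([[0.7, 0.3], [0.3, 0.7]]))
        plis, corrs = [], []
        for s in range(20):
            rec = generate_recording(beta_pair_config, [], seed=200 + s)
            mixed = apply_mixing(rec, mix)
            filtered = bandpass(mixed, BAND_BY_NAME["beta"])
            plis.append(_pair_pli(mixed))
            corrs.append(np.corrcoef(filtered.data)[0, 1])
        assert np.mean(plis) < 0.1
        assert np.mean(corrs) > 0.5


class TestCohorts:
    def test_empty_cohort(self):
        assert generate_cohort(fxs_like_template(), control_like_template(),
                               0, seed=1) == []

    def test_subject_seeds_stable(self):
        assert subject_seed(5, 0, 3) == subject_seed(5, 0, 3)
        assert subject_seed(5, 0, 3) != subject_seed(5, 1, 3)

    def test_cohort_determinism_and_labels(self, beta_pair_config):
        tpl_a = GroupTemplate("a", beta_pair_config)
        tpl_b = GroupTemplate("b", beta_pair_config)
        c1 = generate_cohort(tpl_a, tpl_b, 2, seed=9)
        c2 = generate_cohort(tpl_a, tpl_b, 2, seed=9)
        assert [s.group for s in c1] == ["a", "a", "b", "b"]
        for s1, s2 in zip(c1, c2):
            assert s1.subject_id == s2.subject_id
            assert np.array_equal(s1.recording.data, s2.recording.data)

    def test_theta_long_range_direction_recovered(self):
        """The FXS-like template yields higher long-range theta PLI in
        nearly every replicate cohort."""
        short = SimulationConfig(duration=9.0)
        fxs = fxs_like_template(short)
        ctl = control_like_template(short)
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            cohort = generate_cohort(fxs, ctl, 2, seed=3000 + rep)
            means = {}
            for s in cohort:
                filtered = bandpass(s.recording, BAND_BY_NAME["theta"])
                ep = make_epochs(filtered, 1, 4096)
                phases = [instantaneous_phase(e, ep.channels) for e in ep.epochs]
                lr = cluster_means(connectivity_matrix(phases)).long_range
                means.setdefault(s.group, []).append(lr)
            wins += np.mean(means["fxs_like"]) > np.mean(means["control_like"])
        assert wins >= 0.9 * n_rep
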