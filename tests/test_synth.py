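"""Synthetic-data generator: planted time courses, volumes, and I/O."""

import numpy as np
import pytest

from specseg.design import AcquisitionDesign
from specseg.freq import spearman_spt, spectrum
from specseg.synth import (
    CsfArtifact,
    Harmonic2,
    MotionCoupled,
    OffFrequency,
    PlantedComponent,
    SptLocked,
    WhiteNoise,
    gaussian_blob_map,
    make_timecourse,
    one_over_f_noise,
    synthesize,
    write_dataset,
)


class TestMakeTimecourse:
    # a periodically sampled cosine has repeated values whose float-level
    # near-ties rank arbitrarily, so +/-1 holds to ~1e-3 rather than exactly
    def test_same_phase_cosines_rank_correlate_perfectly(self, jittered_design):
        a = make_timecourse(SptLocked(37.0, 1.0), jittered_design, 0.0, 0)
        b = make_timecourse(SptLocked(37.0, 0.3), jittered_design, 0.0, 1)
        r, _ = spearman_spt(a, b)
        assert r == pytest.approx(1.0, abs=5e-3)

    def test_antiphase_gives_minus_one(self, jittered_design):
        a = make_timecourse(SptLocked(37.0, 1.0), jittered_design, 0.0, 0)
        b = make_timecourse(SptLocked(217.0, 1.0), jittered_design, 0.0, 0)
        r, _ = spearman_spt(a, b)
        assert r == pytest.approx(-1.0, abs=5e-3)

    def test_noiseless_amplitude_and_phase_recovered_exactly(self, jittered_design):
        """Planted spectral parameters at the stimulus bin survive to machine
        precision through the generator (IC-21-like parameters)."""
        tc = make_timecourse(SptLocked(-56.5, 0.145), jittered_design, 0.0, 0)
        res = spectrum(tc, jittered_design.acq_interval)
        k = jittered_design.fundamental_bin
        assert res.amplitude_at(k) == pytest.approx(0.145, abs=1e-12)
        assert res.phase_at(k) == pytest.approx(-56.5, abs=1e-9)

    def test_harmonic2_lands_on_second_harmonic_bin(self, jittered_design):
        tc = make_timecourse(Harmonic2(70.4, 0.04), jittered_design, 0.0, 0)
        res = spectrum(tc, jittered_design.acq_interval)
        assert res.peak_bin == jittered_design.harmonic2_bin

    def test_off_frequency_must_avoid_stimulus_bins(self, jittered_design):
        with pytest.raises(ValueError):
            make_timecourse(OffFrequency(0.01471), jittered_design, 0.0, 0)

    def test_unknown_spec_kind_rejected(self, jittered_design):
        with pytest.raises(ValueError):
            make_timecourse(object(), jittered_design, 0.0, 0)

    def test_negative_noise_rejected(self, jittered_design):
        with pytest.raises(ValueError):
            make_timecourse(WhiteNoise(), jittered_design, -1.0, 0)

    def test_length_is_total_volumes(self, jittered_design):
        tc = make_timecourse(MotionCoupled(3), jittered_design, 0.5, 0)
        assert tc.size == jittered_design.total_volumes == 306


class TestSpatial:
    def test_blob_nonnegative_after_threshold(self):
        m = gaussian_blob_map((12, 12, 8), (6, 6, 4), 2.0)
        assert np.all(m >= 0)
        assert m.max() > 1.0

    def test_one_over_f_concentrates_low_frequencies(self, rng):
        x = one_over_f_noise(306, 1.0, rng)
        amp = np.abs(np.fft.rfft(x))
        assert amp[1:20].sum() > amp[100:120].sum()
        assert x.std() == pytest.approx(1.0)


def tiny_components(shape):
    gm_map = gaussian_blob_map(shape, (8, 4, 3), 1.5)
    csf_map = np.zeros(shape)
    csf_map[0, 4, 2] = 2.0
    return [
        PlantedComponent("aud", gm_map, SptLocked(-40.0, 1.0), "stimulus-activated"),
        PlantedComponent("csf", csf_map, CsfArtifact(1.0), "noise"),
    ]


class TestSynthesize:
    SHAPE = (12, 8, 6)

    def test_zero_components_pure_noise(self, jittered_design):
        ds = synthesize(jittered_design, [], subject_count=2, noise_sd=1.0, seed=0,
                        shape=self.SHAPE)
        assert abs(ds.volumes[0].mean()) < 0.01
        assert ds.volumes[0].shape == self.SHAPE + (306,)

    def test_planted_component_maximises_voxel_correlation(self, jittered_design):
        comps = tiny_components(self.SHAPE)
        ds = synthesize(jittered_design, comps, subject_count=1, noise_sd=0.3,
                        seed=0, shape=self.SHAPE)
        tc = ds.timecourses["aud"]
        vol = ds.volumes[0].reshape(-1, 306)
        tc_c = tc - tc.mean()
        v_c = vol - vol.mean(axis=1, keepdims=True)
        corr = (v_c @ tc_c) / (
            np.linalg.norm(v_c, axis=1) * np.linalg.norm(tc_c) + 1e-12
        )
        best = np.unravel_index(np.argmax(corr), self.SHAPE)
        support = comps[0].spatial_map > 0
        assert support[best]

    def test_subject_count_and_t_dimension(self, jittered_design):
        ds = synthesize(jittered_design, [], subject_count=3, noise_sd=1.0,
                        seed=0, shape=self.SHAPE)
        assert ds.n_subjects == 3
        assert all(v.shape[-1] == 306 for v in ds.volumes)
        assert all(m.shape == (306, 6) for m in ds.motion)

    def test_seed_reproducibility_bit_identical(self, jittered_design):
        kw = dict(subject_count=2, noise_sd=0.7, seed=42, shape=self.SHAPE)
        a = synthesize(jittered_design, tiny_components(self.SHAPE), **kw)
        b = synthesize(jittered_design, tiny_components(self.SHAPE), **kw)
        for va, vb in zip(a.volumes, b.volumes):
            assert np.array_equal(va, vb)
        for ma, mb in zip(a.motion, b.motion):
            assert np.array_equal(ma, mb)

    def test_map_shape_mismatch_rejected(self, jittered_design):
        bad = [
            PlantedComponent(
                "bad", gaussian_blob_map((4, 4, 4), (2, 2, 2), 1.0),
                SptLocked(0.0, 1.0), "stimulus-activated",
            )
        ]
        with pytest.raises(ValueError, match="shape"):
            synthesize(jittered_design, bad, subject_count=1, shape=self.SHAPE)

    def test_csf_artifact_confined_to_mask(self, jittered_design):
        comps = tiny_components(self.SHAPE)
        ds = synthesize(jittered_design, comps, subject_count=1, noise_sd=0.0,
                        seed=0, shape=self.SHAPE)
        assert ds.csf_mask[0, 4, 2]

    def test_motion_coupled_trace(self, jittered_design):
        m = gaussian_blob_map(self.SHAPE, (4, 4, 3), 1.2)
        comps = [PlantedComponent("mot", m, MotionCoupled(1), "noise")]
        ds = synthesize(jittered_design, comps, subject_count=1, noise_sd=0.1,
                        seed=0, shape=self.SHAPE)
        tc = ds.timecourses["mot"]
        corrs = [abs(np.corrcoef(tc, ds.motion[0][:, j])[0, 1]) for j in range(6)]
        assert np.argmax(corrs) == 1

    def test_write_dataset_roundtrip(self, jittered_design, tmp_path):
        import nibabel as nib
        import pandas as pd

        ds = synthesize(jittered_design, tiny_components(self.SHAPE),
                        subject_count=1, noise_sd=0.5, seed=0, shape=self.SHAPE)
        write_dataset(ds, tmp_path)
        img = nib.load(tmp_path / "sub-01_bold.nii")
        assert img.shape == self.SHAPE + (306,)
        motion = np.loadtxt(tmp_path / "sub-01_motion.txt")
        assert motion.shape == (306, 6)
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert set(truth["component_id"]) == {"aud", "csf"}
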