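"""Block-paradigm timing, boxcar construction, and SPT spectral anchors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specseg.design import (
    AcquisitionDesign,
    HRFParams,
    build_boxcar,
    build_spt,
    double_gamma_hrf,
    fundamental_frequency,
    load_design,
    phase_to_seconds,
    save_design,
    save_spt,
    second_harmonic_frequency,
)

DT = 0.1


class TestAcquisitionDesign:
    def test_reference_dimensions(self, jittered_design):
        d = jittered_design
        assert d.total_volumes == d.n_runs * d.volumes_per_run == 306
        assert d.run_duration == 272.0
        assert d.nyquist_hz == 0.0625

    def test_off_durations_within_range(self, jittered_design):
        for run in jittered_design.off_durations:
            assert all(30.0 <= off <= 36.0 for off in run)

    def test_invalid_off_duration_rejected(self):
        offs = tuple(tuple([29.0, 34.0, 34.0, 34.0]) if r == 0 else (34.0,) * 4 for r in range(9))
        with pytest.raises(ValueError, match="off duration"):
            AcquisitionDesign(off_durations=offs)

    def test_config_roundtrip(self, jittered_design, tmp_path):
        path = tmp_path / "design.cfg"
        save_design(jittered_design, path)
        loaded = load_design(path)
        assert loaded == jittered_design


class TestBoxcar:
    def test_first_on_block_at_zero_delay(self, design):
        box = build_boxcar(design, 0, DT)  # run 0 has delay 0
        t = np.arange(box.size) * DT
        assert np.all(box[(t >= 0) & (t < 32.0)] == 1.0)
        assert box[int(32.0 / DT)] == 0.0

    def test_delay_shifts_onset(self, design):
        box = build_boxcar(design, 2, DT)  # run 2 has delay 6 s
        t = np.arange(box.size) * DT
        assert np.all(box[t < 6.0] == 0.0)
        assert box[int(6.0 / DT)] == 1.0

    def test_exactly_cycles_per_run_on_blocks(self, jittered_design):
        box = build_boxcar(jittered_design, 4, DT)
        onsets = np.sum(np.diff(np.concatenate([[0.0], box])) > 0)
        assert onsets == jittered_design.cycles_per_run

    def test_zero_on_duration_gives_all_zero(self):
        d = AcquisitionDesign(on_duration=0.0)
        assert not build_boxcar(d, 0, DT).any()

    def test_run_index_out_of_range(self, design):
        with pytest.raises(IndexError):
            build_boxcar(design, design.n_runs, DT)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_on_time_conserved_under_jitter(self, seed):
        """Total on-time and cycle count are invariant to the jitter draw."""
        d = AcquisitionDesign.jittered(seed)
        total_on = sum(build_boxcar(d, r, DT).sum() * DT for r in range(d.n_runs))
        expected = d.n_runs * d.cycles_per_run * d.on_duration
        assert total_on == pytest.approx(expected, rel=1e-6)


class TestFrequencies:
    def test_fundamental_of_reference_design(self, jittered_design):
        assert fundamental_frequency(jittered_design) == 0.01471

    def test_second_harmonic_bin_arithmetic(self, jittered_design):
        # bin 72 of the 306-point grid at 8 s sampling: 72/2448
        assert second_harmonic_frequency(jittered_design) == round(72 / 2448, 5)
        assert second_harmonic_frequency(jittered_design) == 0.02941

    def test_single_cycle_gives_lowest_nonzero_bin(self):
        d = AcquisitionDesign(n_runs=1, cycles_per_run=1, volumes_per_run=34)
        assert fundamental_frequency(d) == round(1 / (34 * 8.0), 5)

    def test_zero_cycles_error(self):
        d = AcquisitionDesign(cycles_per_run=0)
        with pytest.raises(ValueError):
            fundamental_frequency(d)

    def test_n_fft_must_match(self, design):
        with pytest.raises(ValueError):
            fundamental_frequency(design, n_fft=128)

    def test_phase_to_seconds(self):
        assert phase_to_seconds(12.8, 68.0) == pytest.approx(2.4, abs=0.05)


class TestSPT:
    def test_length_and_per_run_zscore(self, spt, jittered_design):
        assert spt.n == jittered_design.total_volumes
        per_run = spt.samples.reshape(jittered_design.n_runs, -1)
        assert np.allclose(per_run.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(per_run.std(axis=1), 1.0, atol=1e-12)

    def test_periodogram_peak_at_fundamental(self, spt, jittered_design):
        amp = np.abs(np.fft.rfft(spt.samples))
        amp[0] = 0.0
        assert np.argmax(amp) == jittered_design.fundamental_bin
        assert spt.fundamental_hz == fundamental_frequency(jittered_design)

    def test_fundamental_on_fft_grid(self, spt):
        # reported value is the grid frequency k/(N*dt) at printing precision
        k = round(spt.fundamental_hz * spt.n * spt.acq_interval)
        grid_freq = k / (spt.n * spt.acq_interval)
        assert abs(spt.fundamental_hz - grid_freq) < 0.5e-5
        assert k == spt.fundamental_bin == 36

    def test_impulse_boxcar_identity_hrf_subsamples(self):
        """An 8 s on-block with a delta-like HRF subsamples to an impulse."""
        d = AcquisitionDesign(
            n_runs=1,
            cycles_per_run=1,
            volumes_per_run=34,
            on_duration=8.0,
            off_durations=((30.0,),),
            onset_delays=(0.0,),
        )
        hrf = HRFParams(duration=0.2)
        w = build_spt(d, hrf)
        peak = int(np.argmax(w.samples))
        assert peak <= 1  # impulse lands on the first or second acquisition
        rest = np.delete(w.samples, peak)
        assert np.allclose(rest, rest[0], atol=1e-9)

    def test_hrf_unit_peak_and_undershoot(self):
        h = double_gamma_hrf()
        assert h.max() == pytest.approx(1.0)
        assert h.min() < 0.0  # undershoot present

    def test_spt_tsv_export(self, spt, tmp_path):
        path = tmp_path / "spt.tsv"
        save_spt(spt, path)
        data = np.loadtxt(path, skiprows=1)
        assert data.shape == (spt.n, 2)
        assert np.allclose(data[:, 1], spt.samples)
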