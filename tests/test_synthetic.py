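"""Generator contracts: protocols, the viscoelastic simulator against the
Zener closed form, layered images, and cohort coupling."""

import math

import numpy as np
import pytest
from scipy import stats as sstats

from afshear.dma import phase_shift
from afshear.synthetic import (
    generate_cohort,
    generate_lamellae_image,
    make_dma_protocol,
    make_ssa_protocol,
    simulate_response,
    zener_storage_loss,
)
from afshear.types import CohortConfig, Geometry, GroupConfig, LamellaeParams, ViscoParams
from afshear.waveform import final_period, to_stress_strain

GEO = Geometry()


class TestProtocols:
    @pytest.mark.parametrize("strain,amp", [(10.0, 0.5), (40.0, 2.0)])
    def test_strain_to_amplitude(self, strain, amp):
        prot = make_dma_protocol(strain, GEO)
        assert prot.segments[0].label == "precondition"
        assert prot.segments[0].cycles == 20
        assert prot.segments[0].frequency_hz == 1.0
        for seg in prot.segments[1:]:
            assert seg.amplitude_mm == pytest.approx(amp)
            assert seg.cycles == 5

    def test_zero_strain_is_flat(self):
        prot = make_dma_protocol(0.0, GEO)
        _, disp, _ = prot.waveform()
        assert np.all(disp == 0.0)

    def test_unsupported_strain_rejected(self):
        with pytest.raises(ValueError, match="unsupported strain"):
            make_dma_protocol(25.0, GEO)

    def test_ssa_staircase_levels(self):
        prot = make_ssa_protocol(10.0, 2.5, 1200.0, GEO)
        holds = [s for s in prot.segments if s.label.endswith("-hold")]
        assert len(holds) == 4
        _, disp, spans = prot.waveform()
        levels = []
        for label, start, end in spans:
            if label.endswith("-hold"):
                levels.append(disp[end - 1] / GEO.height_mm)
        assert np.allclose(levels, [0.025, 0.05, 0.075, 0.10])

    def test_ssa_40pct_variant(self):
        prot = make_ssa_protocol(40.0, 10.0, 300.0, GEO)
        holds = [s for s in prot.segments if s.label.endswith("-hold")]
        assert len(holds) == 4
        assert holds[0].hold_s == 300.0

    def test_ssa_single_step(self):
        prot = make_ssa_protocol(2.5, 2.5, 60.0, GEO)
        assert sum(s.label.endswith("-hold") for s in prot.segments) == 1

    def test_ssa_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="whole multiple"):
            make_ssa_protocol(10.0, 3.0, 60.0, GEO)

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError, match="sampling rate"):
            make_dma_protocol(10.0, GEO, sampling_rate_hz=20.0)


class TestSimulator:
    def test_zero_amplitude_zero_load(self):
        prot = make_dma_protocol(0.0, GEO)
        params = ViscoParams(g_eq_kpa=80.0, noise_sd_n=0.0)
        rec = simulate_response(params, prot, GEO)
        assert np.allclose(rec.load_n, 0.0)

    def test_pure_elastic_no_phase_lag(self):
        params = ViscoParams(g_eq_kpa=80.0, noise_sd_n=0.0)
        rec = simulate_response(params, make_dma_protocol(10.0, GEO), GEO)
        expected = 80.0 * rec.displacement_mm / GEO.height_mm * GEO.area_mm2 / 1000.0
        assert np.allclose(rec.load_n, expected)
        window = final_period(rec, rec.segment("0.1Hz"))
        tan_d, _ = phase_shift(window, 0.1)
        assert tan_d == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("freq", [0.01, 0.1, 1.0])
    def test_zener_closed_form_all_frequencies(self, zener_params, zener_dma_record, freq):
        window = final_period(zener_dma_record, zener_dma_record.segment(f"{freq:g}Hz"))
        tan_d, _ = phase_shift(window, freq)
        gp, gpp = zener_storage_loss(zener_params, freq)
        assert tan_d == pytest.approx(gpp / gp, rel=0.01)

    def test_relaxation_monotone_after_ramp(self):
        params = ViscoParams(g_eq_kpa=50.0, branches=((30.0, 10.0),), noise_sd_n=0.0)
        prot = make_ssa_protocol(2.5, 2.5, 120.0, GEO, sampling_rate_hz=50.0)
        rec = simulate_response(params, prot, GEO)
        hold = rec.segment("step1-hold")
        load = rec.load_n[hold.start : hold.end]
        assert np.all(np.diff(load) <= 1e-12)

    def test_dynamic_modulus_increases_with_frequency(self, zener_dma_record):
        mags = []
        for freq in (0.01, 0.1, 1.0):
            window = final_period(zener_dma_record, zener_dma_record.segment(f"{freq:g}Hz"))
            tr = to_stress_strain(window)
            mags.append(np.ptp(tr.stress_kpa) / np.ptp(tr.strain))
        assert mags[0] < mags[1] < mags[2]

    def test_seeded_reproducibility(self):
        params = ViscoParams(g_eq_kpa=80.0, branches=((20.0, 5.0),), noise_sd_n=0.01, seed=7)
        prot = make_dma_protocol(10.0, GEO)
        a = simulate_response(params, prot, GEO)
        b = simulate_response(params, prot, GEO)
        assert np.array_equal(a.load_n, b.load_n)


class TestLamellaeImages:
    def test_flat_noiseless_bands_are_piecewise_constant(self):
        params = LamellaeParams(
            mean_thickness_um=30 * 10.23,
            sd_thickness_um=0.0,
            undulation_amplitude_um=0.0,
            bright_dark_contrast=1.0,
            speckle_shape=math.inf,
            image_size_px=440,
        )
        synth = generate_lamellae_image(params, seed=0)
        assert set(np.unique(synth.image)) == {0.0, 1.0}
        for b in synth.boundaries:
            assert np.ptp(b) == pytest.approx(0.0)
        rows = [b[0] for b in synth.boundaries]
        assert np.allclose(np.diff(rows), 30.0)
        assert np.allclose(synth.layer_thickness_um, 30 * 10.23)

    def test_tilt_preserves_perpendicular_thickness(self):
        params = LamellaeParams(
            mean_thickness_um=300.0,
            sd_thickness_um=0.0,
            undulation_amplitude_um=0.0,
            tilt_deg=10.0,
            speckle_shape=math.inf,
            image_size_px=440,
        )
        synth = generate_lamellae_image(params, seed=0)
        # vertical spacing between boundaries is thickness / cos(tilt)
        b0, b1 = synth.boundaries[0], synth.boundaries[1]
        vert = np.mean(b1 - b0) * params.pixel_size_xy_um
        assert vert * math.cos(math.radians(10.0)) == pytest.approx(300.0, rel=1e-6)
        assert np.allclose(synth.layer_thickness_um, 300.0)

    def test_speckle_cv_matches_gamma_law(self, rng):
        shape = 4.0
        params = LamellaeParams(
            mean_thickness_um=3000.0,  # one huge band: pure speckle statistics
            sd_thickness_um=0.0,
            undulation_amplitude_um=0.0,
            bright_dark_contrast=0.5,
            speckle_shape=shape,
            image_size_px=440,
        )
        synth = generate_lamellae_image(params, rng)
        mask = synth.bright_mask
        band = synth.image[mask] if mask.sum() > mask.size / 2 else synth.image[~mask]
        cv = np.std(band) / np.mean(band)
        assert cv == pytest.approx(1.0 / math.sqrt(shape), rel=0.02)

    def test_unresolvable_thickness_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            LamellaeParams(mean_thickness_um=15.0)

    def test_seeded_reproducibility(self):
        params = LamellaeParams()
        a = generate_lamellae_image(params, seed=3)
        b = generate_lamellae_image(params, seed=3)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.all_boundary_rows, b.all_boundary_rows)


class TestCohort:
    def _config(self, rho, n, seed=0, stratified=False):
        g = GroupConfig(
            label="ctl", n=n, g1_mean_kpa=83.0, g1_sd_kpa=41.3,
            g2_mean_kpa=226.2, g2_sd_kpa=81.9,
            thickness_mean_um=324.67, thickness_sd_um=26.76,
        )
        return CohortConfig(groups=(g,), rank_rho=rho, seed=seed, stratified=stratified)

    def test_zero_coupling_near_zero_spearman(self):
        samples = generate_cohort(self._config(0.0, 400, seed=5))
        g1 = [s for s in samples if s.orientation == "G1"]
        r = sstats.spearmanr(
            [s.true_g_eq_kpa for s in g1], [s.true_thickness_um for s in g1]
        ).statistic
        assert abs(r) < 0.12

    def test_strong_negative_coupling_sign_recovered(self):
        negatives = 0
        n_seeds = 60
        for seed in range(n_seeds):
            samples = generate_cohort(self._config(-0.9, 40, seed=seed))
            g1 = [s for s in samples if s.orientation == "G1"]
            r = sstats.spearmanr(
                [s.true_g_eq_kpa for s in g1], [s.true_thickness_um for s in g1]
            ).statistic
            negatives += r < 0
        assert negatives / n_seeds > 0.95

    def test_cohort_means_approach_configured_values(self):
        samples = generate_cohort(self._config(-0.7, 2000, seed=2))
        g1 = np.array([s.true_g_eq_kpa for s in samples if s.orientation == "G1"])
        th = np.array([s.true_thickness_um for s in samples if s.orientation == "G1"])
        # floor truncation shifts the modulus mean up slightly (< 3%)
        assert np.mean(g1) == pytest.approx(83.0, rel=0.04)
        assert np.mean(th) == pytest.approx(324.67, rel=0.02)

    def test_seeded_reproducibility(self):
        a = generate_cohort(self._config(-0.7, 10, seed=9, stratified=True))
        b = generate_cohort(self._config(-0.7, 10, seed=9, stratified=True))
        assert [s.true_g_eq_kpa for s in a] == [s.true_g_eq_kpa for s in b]
        assert [s.true_thickness_um for s in a] == [s.true_thickness_um for s in b]
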