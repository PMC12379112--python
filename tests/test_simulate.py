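"""Simulator ground truth, determinism, and pipeline recovery."""

import math

import numpy as np
import pytest

from orbin.calib import BUILTIN_ANCHORS, shot_noise_sigma, to_air_scale
from orbin.counts import IT_AT_CEILING, TICXIT_OUT_OF_BAND, IntegrationWindow, select_window
from orbin.ratios import acquisition_ratio, delta_vs_standard, integrate_ratio, pair_and_reduce
from orbin.simulate import (
    AIR_15R,
    SimConfig,
    SimConfigError,
    config_for_collected,
    default_scenario,
    inject_anomalies,
    simulate_acquisition,
    simulate_sequence,
)


def trapped_cfg(glycine, collected=2e5, duration=40.0, **kw):
    base = SimConfig(fragment=glycine, mode="trapped", duration_s=duration, **kw)
    return config_for_collected(base, collected)


class TestSimulateAcquisition:
    def test_deterministic_under_seed(self, glycine):
        cfg = trapped_cfg(glycine)
        a1, t1 = simulate_acquisition(cfg, rng=11)
        a2, t2 = simulate_acquisition(cfg, rng=11)
        assert t1.realized_major == t2.realized_major
        assert all(
            p1.mz == p2.mz and p1.signal == p2.signal
            for s1, s2 in zip(a1.scans, a2.scans)
            for p1, p2 in zip(s1.peaks, s2.peaks)
        )

    def test_true_ratio_follows_delta(self, glycine):
        from dataclasses import replace

        cfg = replace(trapped_cfg(glycine, collected=1e5), true_delta_air=100.0)
        _, truth = simulate_acquisition(cfg, rng=0)
        assert truth.true_ratio == pytest.approx(AIR_15R * 1.1, rel=1e-12)

    def test_count_conservation(self, glycine):
        """Expected collected ions match the configured total; realized
        counts sit within Poisson fluctuation of it."""
        collected = 3e5
        cfg = trapped_cfg(glycine, collected=collected, duration=60.0)
        _, truth = simulate_acquisition(cfg, rng=3)
        assert truth.expected_collected == pytest.approx(collected, rel=1e-6)
        total = truth.realized_major + truth.realized_minor
        assert abs(total - collected) < 4 * math.sqrt(collected)

    def test_pipeline_recovers_realized_counts(self, glycine):
        """Inverting the intensity relation and re-converting is lossless."""
        cfg = trapped_cfg(glycine, collected=2e5, mass_jitter_ppm=0.0,
                          include_13c=False)
        acq, truth = simulate_acquisition(cfg, rng=5)
        window = IntegrationWindow(1, len(acq))
        result = integrate_ratio(acq, window, cfg.settings)
        assert result.counts_major == pytest.approx(truth.realized_major, rel=1e-6)
        assert result.counts_minor == pytest.approx(truth.realized_minor, rel=1e-6)

    def test_null_recovery(self, glycine):
        """A sample at the standard's composition reads 0 within 3 sigma."""
        cfg = trapped_cfg(glycine, collected=1e6, duration=120.0)
        sample = acquisition_ratio(simulate_acquisition(cfg, rng=21)[0], cfg.settings)
        standard = acquisition_ratio(simulate_acquisition(cfg, rng=22)[0], cfg.settings)
        delta = delta_vs_standard(sample.ratio, standard.ratio)
        sigma = math.sqrt(
            shot_noise_sigma(sample.counts_major, sample.counts_minor).sigma_delta ** 2
            + shot_noise_sigma(standard.counts_major, standard.counts_minor).sigma_delta ** 2
        )
        assert abs(delta) < 3 * sigma

    def test_injection_times_respect_ceiling(self, glycine):
        cfg = trapped_cfg(glycine)
        acq, _ = simulate_acquisition(cfg, rng=0)
        assert all(s.injection_time <= cfg.max_it_ms for s in acq.scans)

    def test_infeasible_total_rejected(self, glycine):
        cfg = SimConfig(fragment=glycine, duration_s=4.0, total_analyte_ions=1e12)
        with pytest.raises(SimConfigError):
            simulate_acquisition(cfg, rng=0)

    def test_excessive_flux_hits_it_quantum(self, glycine):
        cfg = config_for_collected(
            SimConfig(fragment=glycine, duration_s=4.0, scan_period_s=0.4,
                      decay_constant_s=None, min_it_ms=50.0),
            1.9e6,
        )
        with pytest.raises(SimConfigError, match="quantum"):
            simulate_acquisition(cfg, rng=0)

    def test_trapped_mode_multiplies_scan_count(self, glycine):
        trapped = SimConfig(fragment=glycine, mode="trapped")
        direct = SimConfig(fragment=glycine, mode="direct")
        assert trapped.n_scans >= 10 * direct.n_scans

    def test_direct_mode_tails_pinned_at_ceiling(self, glycine):
        """With analyte-dominated flux, Gaussian tails saturate AGC and are
        excluded from the window."""
        cfg = SimConfig(
            fragment=glycine, mode="direct", duration_s=30.0,
            total_analyte_ions=1.2e7, background_flux=0.0,
        )
        acq, _ = simulate_acquisition(cfg, rng=9)
        window = select_window(acq)
        reasons = {r for _, r in window.excluded_scans}
        assert IT_AT_CEILING in reasons
        assert window.end_scan - window.start_scan + 1 < len(acq)


class TestPrecisionLaw:
    def test_pipeline_sd_tracks_shot_noise(self, glycine):
        """Full simulate-and-reduce sample-vs-standard deltas spread at the
        shot-noise floor (which budgets both measurements' counting noise)."""
        cfg = trapped_cfg(glycine, collected=4e5, duration=30.0)
        deltas, sigmas = [], []
        for seed in range(60):
            sample_acq, _ = simulate_acquisition(cfg, rng=100 + seed)
            standard_acq, _ = simulate_acquisition(cfg, rng=10_100 + seed)
            sample = acquisition_ratio(sample_acq, cfg.settings)
            standard = acquisition_ratio(standard_acq, cfg.settings)
            deltas.append(delta_vs_standard(sample.ratio, standard.ratio))
            sigmas.append(
                shot_noise_sigma(sample.counts_major, sample.counts_minor).sigma_delta
            )
        sd = float(np.std(deltas, ddof=1))
        predicted = float(np.mean(sigmas))
        # 60 replicates: sd of sd ~ 9%; allow 3 sigma
        assert sd == pytest.approx(predicted, rel=0.30)


class TestSimulateSequence:
    def test_layout_and_determinism(self, glycine):
        sample = trapped_cfg(glycine, collected=5e4, duration=8.0)
        standard = sample
        seq, truths = simulate_sequence(sample, standard, 5, 6, seed=3)
        assert len(seq) == 11
        roles = [a.role for a in seq]
        assert roles[0] == roles[-1] == "standard"
        assert roles.count("sample") == 5
        seq2, _ = simulate_sequence(sample, standard, 5, 6, seed=3)
        assert [a.scans[0].tic for a in seq] == [a.scans[0].tic for a in seq2]

    def test_end_to_end_recovery_on_air_scale(self, glycine):
        """Processing a simulated sequence recovers the true delta15N_Air."""
        anchor = BUILTIN_ANCHORS["alpha-AIB"]
        true_air = 183.5
        sample, standard = default_scenario(
            "alpha-AIB", "trapped", delta_air_sample=true_air,
            delta_air_standard=anchor.delta_air, collected_ions=2e6,
            duration_s=120.0,
        )
        seq, _ = simulate_sequence(sample, standard, 5, 6, seed=17)
        result = pair_and_reduce(seq)["alpha-AIB"]
        recovered = to_air_scale(result.delta_vs_standard, anchor)
        # the pooled standard mean is shared by all replicates, so its
        # counting error propagates alongside the replicate SE
        n_std = 6
        combined = result.sd * math.sqrt(1 / result.n + 1 / n_std)
        assert recovered == pytest.approx(true_air, abs=3 * combined)


class TestInjectAnomalies:
    def test_ceiling_scan_excluded(self, glycine):
        cfg = trapped_cfg(glycine, collected=1e5)
        acq, _ = simulate_acquisition(cfg, rng=1)
        acq = inject_anomalies(acq, ceiling_scans=[7])
        window = select_window(acq)
        assert (7, IT_AT_CEILING) in window.excluded_scans

    def test_tic_spike_excluded(self, glycine):
        cfg = trapped_cfg(glycine, collected=1e5)
        acq, _ = simulate_acquisition(cfg, rng=1)
        acq = inject_anomalies(acq, tic_spike_scans=[40], spike_factor=1.3)
        window = select_window(acq, tic_it_band=0.20)
        assert (40, TICXIT_OUT_OF_BAND) in window.excluded_scans

    def test_empty_spec_is_identity(self, glycine):
        cfg = trapped_cfg(glycine, collected=1e5)
        acq, _ = simulate_acquisition(cfg, rng=1)
        same = inject_anomalies(acq)
        assert all(
            a.tic == b.tic and a.injection_time == b.injection_time
            for a, b in zip(acq.scans, same.scans)
        )

    def test_unknown_scan_index_rejected(self, glycine):
        cfg = trapped_cfg(glycine, collected=1e5)
        acq, _ = simulate_acquisition(cfg, rng=1)
        with pytest.raises(IndexError):
            inject_anomalies(acq, ceiling_scans=[10_000])
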