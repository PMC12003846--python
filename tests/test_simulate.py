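import numpy as np
import pytest

from fmriscrub.connectivity import fc_profile
from fmriscrub.metrics import compute_fd, compute_sdvars, compute_tsnr
from fmriscrub.simulate import (
    SimulationConfig,
    SyntheticTruth,
    simulate_dataset,
    simulate_motion,
    simulate_scan,
    simulate_volumes,
)


def quiet_config(**kw):
    defaults = dict(n_scans=3, n_roi=8, frames=60, seed=9)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateMotion:
    def test_all_zero_when_quiet(self):
        cfg = quiet_config(spike_rate=0.0, baseline_scale_mm=0.0)
        trace = simulate_motion(cfg, 0)
        assert np.all(trace.params == 0)
        assert np.all(compute_fd(trace).fd == 0)

    def test_deterministic(self):
        cfg = quiet_config()
        t1 = simulate_motion(cfg, 2)
        t2 = simulate_motion(cfg, 2)
        np.testing.assert_array_equal(t1.params, t2.params)

    def test_scans_differ(self):
        cfg = quiet_config()
        t1 = simulate_motion(cfg, 0)
        t2 = simulate_motion(cfg, 1)
        assert not np.array_equal(t1.params, t2.params)

    def test_event_rate_matches_closed_form(self):
        # with no baseline, FD crossings of 1.5 mm are thinned events:
        # E[# crossings] = spike_rate * P(Exp(amp) > 1.5)
        rate, amp, thr = 10.0, 3.0, 1.5
        expected = rate * np.exp(-thr / amp)
        counts = []
        for seed in range(200):
            cfg = SimulationConfig(
                n_scans=1, n_roi=8, frames=144, seed=seed,
                spike_rate=rate, spike_amp_mm=amp,
                baseline_scale_mm=0.0, motion_var=0.0,
            )
            fd = compute_fd(simulate_motion(cfg, 0), cfg.radius_mm).fd
            counts.append(int((fd > thr).sum()))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 1e-9


class TestSimulateScan:
    def test_fc_consistency_without_contamination(self):
        cfg = quiet_config(
            artifact_gain=0.0, ga_effect=0.0, sex_effect=0.0,
            tissue_gain=0.0, noise_sd=0.0,
        )
        ds = simulate_dataset(cfg)
        truth_fc = ds.truth.latent_fc

        def frob(frames):
            c = quiet_config(
                frames=frames, artifact_gain=0.0, ga_effect=0.0,
                sex_effect=0.0, tissue_gain=0.0, noise_sd=0.0,
            )
            bold, _ = simulate_scan(c, ds.truth, simulate_motion(c, 0), ds.scans[0].record, 0)
            emp = np.corrcoef(bold.data, rowvar=False)
            return np.linalg.norm(emp - truth_fc)

        assert frob(5000) < frob(100)

    def test_artifact_induces_distance_dependent_fc_bias(self):
        # mean FC difference (high-FD minus low-FD scans) decreases with distance
        diffs, dists = [], None
        for seed in range(100):
            cfg = SimulationConfig(
                n_scans=2, n_roi=12, frames=120, seed=seed,
                ga_effect=0.0, sex_effect=0.0, motion_var=0.0,
                artifact_gain=1.5, spike_rate=12,
            )
            ds = simulate_dataset(cfg)
            pairs = None
            fcs, fd_aves = [], []
            for i, b in enumerate(ds.scans):
                fd = compute_fd(b.motion, cfg.radius_mm)
                fd_aves.append(fd.fd.mean())
                prof = fc_profile(np.corrcoef(b.bold.data, rowvar=False))
                fcs.append(prof.values)
                pairs = prof.pair_index
            hi, lo = np.argmax(fd_aves), np.argmin(fd_aves)
            diffs.append(np.asarray(fcs[hi]) - np.asarray(fcs[lo]))
            d = ds.geometry.pairwise_distances()
            dists = d[pairs[:, 0], pairs[:, 1]]
        mean_diff = np.mean(diffs, axis=0)
        # short-range bias positive, slope vs distance negative
        near = mean_diff[dists < np.median(dists)].mean()
        slope = np.corrcoef(dists, mean_diff)[0, 1]
        assert near > 0
        assert slope < 0

    def test_sex_effect_detectable_on_planted_edges(self):
        wins = 0
        n_trials = 60
        for seed in range(n_trials):
            cfg = SimulationConfig(
                n_scans=16, n_roi=10, frames=200, seed=seed,
                artifact_gain=0.0, ga_effect=0.0, sex_effect=0.4,
                tissue_gain=0.0, noise_sd=0.2, motion_var=0.0,
            )
            ds = simulate_dataset(cfg)
            sex = np.array([r.sex == "M" for r in (s.record for s in ds.scans)])
            profs = np.array(
                [fc_profile(np.corrcoef(s.bold.data, rowvar=False)).values for s in ds.scans]
            )
            pairs = fc_profile(np.zeros((10, 10))).pair_index
            edge_ids = {tuple(e): i for i, e in enumerate(pairs)}
            planted = [edge_ids[tuple(e)] for e in ds.truth.sex_edges]
            rng = np.random.default_rng(seed)
            rand = rng.choice(profs.shape[1], size=len(planted), replace=False)

            def tstat(cols):
                a, b = profs[np.ix_(sex, cols)], profs[np.ix_(~sex, cols)]
                num = a.mean() - b.mean()
                den = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
                return abs(num / den)

            wins += tstat(planted) > tstat(rand)
        assert wins / n_trials >= 0.90


class TestSimulateDataset:
    def test_profile_length_200_roi(self):
        cfg = SimulationConfig(n_scans=1, n_roi=200, frames=40, seed=0)
        ds = simulate_dataset(cfg)
        prof = fc_profile(np.corrcoef(ds.scans[0].bold.data, rowvar=False))
        assert prof.n_edges == 19900

    def test_minimal_dataset_round_trips(self, tmp_path):
        cfg = SimulationConfig(n_scans=2, n_roi=3, frames=50, seed=4)
        ds = simulate_dataset(cfg)
        ds.write(tmp_path)
        from fmriscrub.pipeline import load_scan_bundles

        bundles, geom = load_scan_bundles(tmp_path, cfg.tr_seconds)
        assert len(bundles) == 2
        np.testing.assert_array_equal(geom.centroids, ds.geometry.centroids)
        np.testing.assert_array_equal(bundles[0].bold.data, ds.scans[0].bold.data)

    def test_byte_identical_outputs_same_seed(self, tmp_path):
        cfg = quiet_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg).write(d1)
        simulate_dataset(quiet_config()).write(d2)
        for f1 in sorted(d1.iterdir()):
            assert (d2 / f1.name).read_bytes() == f1.read_bytes()

    def test_truth_invariants(self):
        ds = simulate_dataset(quiet_config())
        C = ds.truth.latent_fc
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.linalg.eigvalsh(C).min() > -1e-9
        ga = {tuple(e) for e in ds.truth.ga_edges}
        sx = {tuple(e) for e in ds.truth.sex_edges}
        assert not ga & sx

    def test_sex_balanced_ga_in_window(self):
        cfg = quiet_config(n_scans=10)
        ds = simulate_dataset(cfg)
        sexes = [s.record.sex for s in ds.scans]
        assert abs(sexes.count("M") - sexes.count("F")) <= 1
        lo, hi = cfg.ga_window
        assert all(lo <= s.record.ga_weeks <= hi for s in ds.scans)

    def test_non_psd_truth_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(ValueError, match="positive semi-definite"):
            SyntheticTruth(latent_fc=C, ga_edges=np.zeros((0, 2)), sex_edges=np.zeros((0, 2)))


class TestSimulateVolumes:
    def test_quiet_volumes_zero_sdvars(self):
        cfg = quiet_config(
            spike_rate=0.0, baseline_scale_mm=0.0, noise_sd=0.0, volume_signal_amp=0.0
        )
        vols = simulate_volumes(cfg, simulate_motion(cfg, 0), 0)
        assert np.all(compute_sdvars(vols).sdvars == 0)

    def test_masks_present_and_consistent(self):
        cfg = quiet_config()
        vols = simulate_volumes(cfg, simulate_motion(cfg, 0), 0)
        for name in ("brain", "gray", "white", "csf", "seed"):
            assert name in vols.masks
        assert vols.masks["seed"].sum() > 0
        assert np.all(vols.masks["gray"] | ~vols.masks["gray"])
        assert not (vols.masks["gray"] & vols.masks["white"]).any()

    def test_known_jump_hand_computed_sdvars(self):
        # inject one global jump of size J on frame k into quiet volumes:
        # sdvars[k] = J / grand_mean over gray voxels
        cfg = quiet_config(
            spike_rate=0.0, baseline_scale_mm=0.0, noise_sd=0.0, volume_signal_amp=0.0
        )
        vols = simulate_volumes(cfg, simulate_motion(cfg, 0), 0)
        J, k = 5.0, 7
        gray = vols.masks["gray"]
        base = vols.data[gray][0, 0]  # constant baseline
        vols.data[gray, k:] += J
        dv = compute_sdvars(vols)
        grand_mean = base + J * (vols.frames - k) / vols.frames
        assert dv.sdvars[k] == pytest.approx(J / grand_mean)
        assert dv.sdvars[k + 1] == pytest.approx(0.0, abs=1e-12)

    def test_tsnr_matches_generating_process(self):
        cfg = quiet_config(
            frames=1000, spike_rate=0.0, baseline_scale_mm=0.0,
            noise_sd=2.0, volume_signal_amp=0.0,
        )
        vols = simulate_volumes(cfg, simulate_motion(cfg, 0), 0)
        t = compute_tsnr(vols)
        assert t.mean_tsnr == pytest.approx(100.0 / 2.0, rel=0.10)

    def test_higher_motion_lower_tsnr(self):
        # rank correlation between injected FD load and mean tSNR is negative
        fd_aves, tsnrs = [], []
        for i in range(50):
            cfg = SimulationConfig(
                n_scans=1, n_roi=8, frames=80, seed=1000 + i,
                noise_sd=1.0, motion_var=0.8,
            )
            motion = simulate_motion(cfg, 0)
            fd_aves.append(compute_fd(motion, cfg.radius_mm).fd.mean())
            tsnrs.append(compute_tsnr(simulate_volumes(cfg, motion, 0)).mean_tsnr)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(fd_aves, tsnrs)
        assert rho < 0
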