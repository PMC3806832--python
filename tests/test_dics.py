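import numpy as np
import pytest

from ictalnet import dics
from ictalnet import simulate as sim
from ictalnet.spectral import EEGSegment, estimate_csd

from _oracles import brute_force_power_map


def _random_csd(rng, n):
    X = rng.standard_normal((n, 3 * n)) + 1j * rng.standard_normal((n, 3 * n))
    C = X @ X.conj().T / (3 * n)
    return 0.5 * (C + C.conj().T)


@pytest.fixture(scope="module")
def star_segment(leadfield_fn, montage32):
    return sim.simulate_scalp_eeg(sim.star_scenario(snr_db=10, seed=0),
                                  leadfield_fn, montage32, 60.0, 200.0)


@pytest.fixture(scope="module")
def star_filters(star_segment, leadfield):
    csd = estimate_csd(star_segment, (16.0, 20.0))
    return dics.compute_spatial_filters(leadfield, csd), csd


class TestSpatialFilters:
    def test_unit_gain_everywhere(self, star_filters, leadfield):
        filt, _ = star_filters
        dev = np.abs(np.einsum("vae,veb->vab", filt.filters,
                               leadfield.matrices) - np.eye(3))
        assert dev.max() < 1e-8

    def test_high_alpha_approaches_pseudoinverse(self, leadfield, rng):
        """With white-noise CSD and huge regularization the LCMV filter tends
        to the Moore-Penrose solution of the lead field."""
        E = len(leadfield.montage)
        C = np.eye(E)
        filt = dics.compute_spatial_filters(
            leadfield, C, dics.DICSConfig(alpha=1000.0))
        v = 123
        L = leadfield.matrices[v]
        pinv = np.linalg.pinv(L)
        assert np.allclose(filt.filters[v], pinv, rtol=1e-6, atol=1e-9)

    def test_channel_permutation_equivariance(self, leadfield, star_filters):
        filt, csd = star_filters
        E = len(leadfield.montage)
        perm = np.random.default_rng(0).permutation(E)
        from ictalnet.forward import ElectrodeMontage, LeadField
        mont_p = ElectrodeMontage(
            labels=tuple(np.array(leadfield.montage.labels)[perm]),
            positions=leadfield.montage.positions[perm])
        lf_p = LeadField(grid=leadfield.grid, montage=mont_p,
                         model=leadfield.model,
                         matrices=leadfield.matrices[:, perm, :],
                         tol=leadfield.tol)
        C = filt.csd_matrix
        C_p = C[np.ix_(perm, perm)]
        filt_p = dics.compute_spatial_filters(lf_p, C_p)
        p1 = dics.power_map(filt, C).values
        p2 = dics.power_map(filt_p, C_p).values
        assert np.allclose(p1, p2, rtol=1e-9)

    def test_singular_csd_reported(self, leadfield):
        E = len(leadfield.montage)
        C = np.zeros((E, E))
        with pytest.raises(Exception, match="cond|singular"):
            dics.compute_spatial_filters(leadfield, C)


class TestPowerMap:
    def test_localizes_single_dipole(self, leadfield, leadfield_fn,
                                     montage32, grid5):
        scen = sim.SourceScenario((sim.DEFAULT_POSITIONS[0],),
                                  (sim.DEFAULT_ORIENTATIONS[0],),
                                  snr_db=10, seed=0)
        seg = sim.simulate_scalp_eeg(scen, leadfield_fn, montage32, 10.0,
                                     200.0)
        csd = estimate_csd(seg, (16.0, 20.0))
        filt = dics.compute_spatial_filters(leadfield, csd)
        peak = int(np.argmax(dics.power_map(filt, csd).values))
        true_node = grid5.nearest_node(sim.DEFAULT_POSITIONS[0])
        err = np.linalg.norm(grid5.nodes[peak] - grid5.nodes[true_node])
        assert err <= 0.005 + 1e-9

    def test_noise_map_has_no_focal_peak(self, leadfield, montage32):
        """Depth-normalized power of source-free noise is spatially flat."""
        rec, _ = sim.make_ictal_recording(seizure_times=None, fs=200.0,
                                          montage=montage32, seed=3,
                                          duration=60.0)
        csd = estimate_csd(rec, (16.0, 20.0))
        filt = dics.compute_spatial_filters(leadfield, csd)
        pm = dics.power_map(filt, csd).values
        noise_gain = np.einsum("vae,vae->v", filt.filters, filt.filters)
        nai = pm / noise_gain
        assert nai.max() < 3.0 * np.median(nai)

    def test_linearity_in_csd(self, star_filters):
        filt, _ = star_filters
        C = filt.csd_matrix
        p1 = dics.power_map(filt, C).values
        p2 = dics.power_map(filt, 3.5 * C).values
        assert np.allclose(p2, 3.5 * p1, rtol=1e-10)

    def test_matches_brute_force_oracle(self, coarse_leadfield, rng):
        """Vectorized beamformer equals the per-voxel generic-solver route."""
        E = len(coarse_leadfield.montage)
        C = _random_csd(rng, E)
        cfg = dics.DICSConfig()
        filt = dics.compute_spatial_filters(coarse_leadfield, C, cfg)
        fast = dics.power_map(filt, C).values
        slow = brute_force_power_map(coarse_leadfield, C, cfg.alpha)
        assert np.allclose(fast, slow, rtol=1e-8, atol=1e-12 * slow.max())

    def test_dominant_orientation_power_is_maximal(self, star_filters, rng):
        filt, _ = star_filters
        C = filt.csd_matrix
        H = np.einsum("vae,ef,vbf->vab", filt.filters, C,
                      np.conj(filt.filters))
        vals = dics.power_map(filt, C).values
        for v in rng.integers(0, filt.n_nodes, 20):
            q = rng.standard_normal(3)
            q /= np.linalg.norm(q)
            fixed = np.real(q @ H[v] @ q)
            assert vals[v] >= fixed - 1e-12 * abs(fixed)


class TestCoherenceMap:
    def test_values_in_unit_interval(self, star_filters, rng):
        filt, _ = star_filters
        for _ in range(20):
            C = _random_csd(rng, filt.reduced.shape[1])
            cm = dics.coherence_map(filt, C, reference_node=500)
            assert cm.values.min() >= 0.0 and cm.values.max() <= 1.0

    def test_reference_suppressed(self, star_filters):
        filt, csd = star_filters
        ref = int(np.argmax(dics.power_map(filt, csd).values))
        cm = dics.coherence_map(filt, csd, ref)
        assert cm.values[ref] < 1e-6

    def test_coupled_partner_recovered(self, leadfield, leadfield_fn,
                                       montage32, grid5):
        scen = sim.SourceScenario(
            sim.DEFAULT_POSITIONS[:2], sim.DEFAULT_ORIENTATIONS[:2],
            coupling_graph=((0, 1, 0.7),), snr_db=10, seed=0,
            innovation_scales=(2.0, 1.0))
        seg = sim.simulate_scalp_eeg(scen, leadfield_fn, montage32, 60.0,
                                     200.0)
        csd = estimate_csd(seg, (16.0, 20.0))
        filt = dics.compute_spatial_filters(leadfield, csd)
        ref = int(np.argmax(dics.power_map(filt, csd).values))
        cm = dics.coherence_map(filt, csd, ref)
        masked = cm.values.copy()
        masked[np.linalg.norm(grid5.nodes - grid5.nodes[ref], axis=1)
               < 0.02] = -np.inf
        peak = int(np.argmax(masked))
        partner = grid5.nearest_node(sim.DEFAULT_POSITIONS[1])
        assert np.linalg.norm(grid5.nodes[peak] - grid5.nodes[partner]) \
            <= 0.005 + 1e-9

    def test_bad_reference_rejected(self, star_filters):
        filt, csd = star_filters
        with pytest.raises(ValueError, match="grid"):
            dics.coherence_map(filt, csd, reference_node=10 ** 7)


class TestSurrogates:
    def test_shuffle_preserves_samples(self, rng):
        seg = EEGSegment(rng.standard_normal((3, 1000)), 200.0)
        out = dics.shuffle_windows(seg, np.random.default_rng(0))
        for ch in range(3):
            assert np.allclose(np.sort(out.data[ch]),
                               np.sort(seg.data[ch]))
        assert not np.allclose(out.data, seg.data)

    def test_joint_shuffle_keeps_channels_aligned(self, rng):
        seg = EEGSegment(rng.standard_normal((3, 1000)), 200.0)
        out = dics.shuffle_windows(seg, np.random.default_rng(0), joint=True)
        # the inter-channel relation at every sample is preserved
        ratio = out.data[0] / out.data[1]
        orig = seg.data[0] / seg.data[1]
        assert np.allclose(np.sort(ratio), np.sort(orig))

    def test_threshold_deterministic_for_seed(self, leadfield, montage32,
                                              rng):
        seg = EEGSegment(rng.standard_normal((32, 1200)), 200.0, montage32)
        cfg = dics.DICSConfig(n_permutations=5)

        def build(s):
            c = estimate_csd(s, (10.0, 30.0))
            f = dics.compute_spatial_filters(leadfield, c, cfg)
            return dics.power_map(f, c).values

        t1 = dics.surrogate_threshold(seg, build, cfg,
                                      np.random.default_rng(7))
        t2 = dics.surrogate_threshold(seg, build, cfg,
                                      np.random.default_rng(7))
        assert np.array_equal(t1, t2)

    def test_builder_failure_propagates_permutation(self, rng):
        seg = EEGSegment(rng.standard_normal((3, 1000)), 200.0)

        def bad_builder(s):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="permutation 0"):
            dics.surrogate_threshold(seg, bad_builder,
                                     dics.DICSConfig(n_permutations=2),
                                     np.random.default_rng(0))


class TestNetworkSearch:
    def test_star_network_recovered(self, leadfield, leadfield_fn, montage32,
                                    grid5):
        seg = sim.simulate_scalp_eeg(sim.star_scenario(snr_db=10, seed=1),
                                     leadfield_fn, montage32, 60.0, 200.0)
        cfg = dics.DICSConfig(n_permutations=20)
        net, filt, csd = dics.find_coherent_network(seg, leadfield,
                                                    (16.0, 20.0), cfg, seed=1)
        assert len(net) == 3
        truth = [grid5.nodes[grid5.nearest_node(p)]
                 for p in sim.DEFAULT_POSITIONS]
        for coord in net.coordinates:
            err = min(np.linalg.norm(coord - t) for t in truth)
            assert err <= 0.005 + 1e-9
        assert net.source_maps[0] == "power"
        assert not net.weak_primary

    def test_baseline_gives_weak_singleton(self, leadfield, montage32):
        rec, _ = sim.make_ictal_recording(seizure_times=None, fs=200.0,
                                          montage=montage32, seed=2,
                                          duration=40.0)
        cfg = dics.DICSConfig(n_permutations=10)
        net, _, _ = dics.find_coherent_network(rec, leadfield, (16.0, 20.0),
                                               cfg, seed=2)
        assert len(net) == 1
        assert net.weak_primary

    def test_max_sources_one_skips_coherence(self, leadfield, star_segment):
        cfg = dics.DICSConfig(n_permutations=5, max_sources=1)
        net, filt, csd = dics.find_coherent_network(
            star_segment, leadfield, (16.0, 20.0), cfg, seed=0)
        assert len(net) == 1
        pm = dics.power_map(filt, csd)
        assert net.node_indices[0] == int(np.argmax(pm.values))


class TestExtraction:
    def test_noise_free_source_recovered(self, leadfield, leadfield_fn,
                                         montage32, grid5):
        scen = sim.SourceScenario((sim.DEFAULT_POSITIONS[0],),
                                  (sim.DEFAULT_ORIENTATIONS[0],),
                                  snr_db=np.inf, seed=0)
        rng0 = np.random.default_rng(0)
        src = sim.simulate_coupled_sources(scen, 2000, 200.0, rng=rng0)
        seg = sim.simulate_scalp_eeg(scen, leadfield_fn, montage32, 10.0,
                                     200.0, rng=np.random.default_rng(0))
        csd = estimate_csd(seg, (16.0, 20.0))
        filt = dics.compute_spatial_filters(leadfield, csd)
        node = grid5.nearest_node(sim.DEFAULT_POSITIONS[0])
        out = dics.extract_source_timeseries(seg, filt, [node])
        r = np.corrcoef(out[0], src[0])[0, 1]
        assert abs(r) >= 0.99

    def test_crosstalk_suppressed(self, leadfield, leadfield_fn, montage32,
                                  grid5):
        scen = sim.SourceScenario(
            sim.DEFAULT_POSITIONS[:2], sim.DEFAULT_ORIENTATIONS[:2],
            snr_db=np.inf, seed=5)
        rng0 = np.random.default_rng(5)
        src = sim.simulate_coupled_sources(scen, 2000, 200.0, rng=rng0)
        seg = sim.simulate_scalp_eeg(scen, leadfield_fn, montage32, 10.0,
                                     200.0, rng=np.random.default_rng(5))
        csd = estimate_csd(seg, (16.0, 20.0))
        filt = dics.compute_spatial_filters(leadfield, csd)
        nodes = [grid5.nearest_node(p) for p in scen.source_positions]
        out = dics.extract_source_timeseries(seg, filt, nodes)
        cross = abs(np.corrcoef(out[0], src[1])[0, 1])
        assert cross < 0.3

    def test_zero_data_zero_output(self, star_filters, montage32):
        filt, _ = star_filters
        seg = EEGSegment(np.zeros((32, 1000)), 200.0, montage32)
        out = dics.extract_source_timeseries(seg, filt, [5, 10],
                                             band=(16.0, 20.0))
        assert np.allclose(out, 0.0)

    def test_invalid_band_rejected(self, star_filters, montage32, rng):
        filt, _ = star_filters
        seg = EEGSegment(rng.standard_normal((32, 1000)), 200.0, montage32)
        with pytest.raises(ValueError, match="fs"):
            dics.extract_source_timeseries(seg, filt, [3], band=(16., 150.))


class TestExports:
    def test_nifti_and_csv(self, leadfield, star_filters, tmp_path):
        import nibabel as nib
        import pandas as pd

        filt, csd = star_filters
        pm = dics.power_map(filt, csd)
        dics.map_to_nifti(pm.values, leadfield, tmp_path / "p.nii.gz")
        img = nib.load(str(tmp_path / "p.nii.gz"))
        vol = np.asarray(img.dataobj)
        assert np.nanmax(vol) == pytest.approx(pm.values.max(), rel=1e-6)
        assert img.affine[0, 0] == pytest.approx(5.0)  # mm voxels
        dics.map_to_csv(pm.values, leadfield, tmp_path / "p.csv")
        df = pd.read_csv(tmp_path / "p.csv")
        assert len(df) == len(leadfield.grid)

    def test_network_json(self, leadfield, star_segment, tmp_path):
        cfg = dics.DICSConfig(n_permutations=5, max_sources=2)
        net, _, _ = dics.find_coherent_network(star_segment, leadfield,
                                               (16.0, 20.0), cfg, seed=0)
        import json
        text = dics.network_to_json(net, tmp_path / "net.json")
        payload = json.loads(text)
        assert len(payload["nodes"]) == len(net)
        assert payload["nodes"][0]["map"] == "power"
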