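"""Self-validation studies on synthetic ground truth.

Each function runs one quantitative check of the pipeline on data from the
synthetic generator — forward-model agreement, beamformer algebra,
localization and coherent-source recovery, surrogate calibration, RPDC
asymptotics, order selection, end-to-end flow classification, and
determinism — and returns the measured quantity.  The test suite asserts
them; the acceptance script reports them.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from . import connectivity as conn
from . import dics
from . import simulate as sim
from .forward import (HeadModel, SourceGrid, compute_leadfield,
                      homogeneous_sphere_potential, make_leadfield_fn,
                      multilayer_potential, standard_1010_montage)
from .pipeline import AnalysisConfig, analyze_phase
from .spectral import estimate_csd

__all__ = [
    "forward_oracle_error",
    "unit_gain_deviation",
    "localization_hit_rate",
    "coherence_recovery",
    "surrogate_false_positive_rate",
    "pdc_normalization_deviation",
    "rpdc_null_mean",
    "classification_rate",
    "aic_order_recovery_rate",
    "determinism_check",
]

BAND = (16.0, 20.0)


def _study_leadfield(n_electrodes: int = 32, voxel_size: float = 0.005):
    model = HeadModel()
    montage = standard_1010_montage(n_electrodes, model)
    grid = SourceGrid.for_model(model, voxel_size)
    return compute_leadfield(grid, montage, model), montage, model


def forward_oracle_error(n_configs: int = 100, seed: int = 0) -> float:
    """Max relative error of the multilayer solver against the closed-form
    homogeneous-sphere potential when all conductivities are equal."""
    rng = np.random.default_rng(seed)
    R, sig = 0.092, 0.33
    model = HeadModel(conductivities=(sig,) * 5)
    worst = 0.0
    for _ in range(n_configs):
        while True:
            p = rng.uniform(-0.066, 0.066, 3)
            if np.linalg.norm(p) < 0.066:
                break
        mom = rng.normal(size=3) * 1e-8
        e = rng.normal(size=3)
        e = e / np.linalg.norm(e) * R
        v1 = multilayer_potential(p, mom, e, model, tol=1e-10)[0]
        v2 = homogeneous_sphere_potential(p, mom, e, R, sig)[0]
        worst = max(worst, abs(v1 - v2) / max(abs(v2), 1e-30))
    return float(worst)


def unit_gain_deviation(leadfield=None, seed: int = 0) -> float:
    """Max |A(r) L(r) - I| over a whole source grid (>= 3000 voxels)."""
    if leadfield is None:
        leadfield, _, _ = _study_leadfield(voxel_size=0.0075)
    rng = np.random.default_rng(seed)
    E = len(leadfield.montage)
    X = rng.standard_normal((E, 4 * E))
    C = X @ X.T / (4 * E)
    filt = dics.compute_spatial_filters(leadfield, C)
    dev = np.abs(np.einsum("vae,veb->vab", filt.filters,
                           leadfield.matrices) - np.eye(3))
    return float(dev.max())


def localization_hit_rate(n_seeds: int = 20, snr_db: float = 10.0,
                          seed: int = 0, leadfield=None,
                          montage=None, model=None) -> float:
    """Fraction of runs with the power-map peak within one voxel of a single
    simulated dipole (32 electrodes, alpha = 0.001, 5 mm grid)."""
    if leadfield is None:
        leadfield, montage, model = _study_leadfield()
    lffn = make_leadfield_fn(montage, model)
    grid = leadfield.grid
    true_node = grid.nearest_node(sim.DEFAULT_POSITIONS[0])
    hits = 0
    base = np.random.SeedSequence(seed)
    for child in base.spawn(n_seeds):
        rng = np.random.default_rng(child)
        scen = sim.SourceScenario((sim.DEFAULT_POSITIONS[0],),
                                  (sim.DEFAULT_ORIENTATIONS[0],),
                                  band=BAND, snr_db=snr_db)
        seg = sim.simulate_scalp_eeg(scen, lffn, montage, 10.0, 200.0,
                                     rng=rng)
        csd = estimate_csd(seg, BAND)
        filt = dics.compute_spatial_filters(leadfield, csd)
        peak = int(np.argmax(dics.power_map(filt, csd).values))
        err = np.linalg.norm(grid.nodes[peak] - grid.nodes[true_node])
        hits += err <= grid.voxel_size + 1e-9
    return hits / n_seeds


def coherence_recovery(n_seeds: int = 20, snr_db: float = 10.0,
                       duration: float = 60.0, seed: int = 0,
                       leadfield=None, montage=None, model=None) -> dict:
    """Two coupled sources: coherence-map peak within one voxel of the
    second source with the primary as reference, and the map value at the
    projected-out reference (should sit below any meaningful threshold)."""
    if leadfield is None:
        leadfield, montage, model = _study_leadfield()
    lffn = make_leadfield_fn(montage, model)
    grid = leadfield.grid
    partner = grid.nearest_node(sim.DEFAULT_POSITIONS[1])
    hits = 0
    ref_vals = []
    base = np.random.SeedSequence([seed, 1])
    for child in base.spawn(n_seeds):
        rng = np.random.default_rng(child)
        scen = sim.SourceScenario(
            sim.DEFAULT_POSITIONS[:2], sim.DEFAULT_ORIENTATIONS[:2],
            coupling_graph=((0, 1, sim.DEFAULT_STRENGTH),), band=BAND,
            snr_db=snr_db, innovation_scales=(2.0, 1.0))
        seg = sim.simulate_scalp_eeg(scen, lffn, montage, duration, 200.0,
                                     rng=rng)
        csd = estimate_csd(seg, BAND)
        filt = dics.compute_spatial_filters(leadfield, csd)
        ref = int(np.argmax(dics.power_map(filt, csd).values))
        cm = dics.coherence_map(filt, csd, ref)
        ref_vals.append(float(cm.values[ref]))
        masked = cm.values.copy()
        masked[np.linalg.norm(grid.nodes - grid.nodes[ref], axis=1)
               < 4 * grid.voxel_size] = -np.inf
        peak = int(np.argmax(masked))
        err = np.linalg.norm(grid.nodes[peak] - grid.nodes[partner])
        hits += err <= grid.voxel_size + 1e-9
    return {"hit_rate": hits / n_seeds,
            "max_reference_coherence": float(np.max(ref_vals))}


def surrogate_false_positive_rate(n_runs: int = 3, n_permutations: int = 100,
                                  seed: int = 0, leadfield=None,
                                  montage=None, model=None) -> float:
    """Fraction of voxels of a source-free noise recording whose power map
    exceeds the 99th-percentile window-shuffle surrogate threshold."""
    if leadfield is None:
        leadfield, montage, model = _study_leadfield()
    cfg = dics.DICSConfig(n_permutations=n_permutations)
    fracs = []
    for k in range(n_runs):
        rec, _ = sim.make_ictal_recording(seizure_times=None, fs=200.0,
                                          montage=montage, model=model,
                                          seed=seed + k, duration=30.0)
        csd = estimate_csd(rec, BAND)
        filt = dics.compute_spatial_filters(leadfield, csd, cfg)
        pmap = dics.power_map(filt, csd).values

        def build(s):
            c = estimate_csd(s, BAND)
            return dics.power_map(filt, c).values

        thr = dics.surrogate_threshold(rec, build, cfg,
                                       np.random.default_rng(seed + k))
        fracs.append(float(np.mean(pmap > thr)))
    return float(np.mean(fracs))


def pdc_normalization_deviation(n_models: int = 10, seed: int = 0) -> float:
    """Max deviation of sum_i |PDC_ij|^2 from one over random stable models."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    made = 0
    while made < n_models:
        m = int(rng.integers(2, 5))
        p = int(rng.integers(1, 4))
        A = rng.normal(scale=0.25, size=(p, m, m))
        if sim.companion_spectral_radius(A) >= 0.98:
            continue
        made += 1
        model = conn.MVARModel(order=p, coefficients=A, sigma=np.eye(m),
                               xtx_inv=np.eye(m * p), n_samples=1000,
                               fs=200.0)
        pdc = conn.compute_pdc(model, np.linspace(0.5, 99.0, 31))
        worst = max(worst, float(np.abs((pdc ** 2).sum(axis=1) - 1.0).max()))
    return worst


def rpdc_null_mean(n_fits: int = 200, n_samples: int = 1000,
                   seed: int = 0) -> float:
    """Mean of n*lambda over null (uncoupled white-noise) fits; the
    asymptotic law is chi-squared with 2 degrees of freedom (mean 2)."""
    vals = []
    base = np.random.SeedSequence([seed, 6])
    for child in base.spawn(n_fits):
        x = np.random.default_rng(child).standard_normal((2, n_samples))
        model = conn.fit_mvar(x, 3, fs=200.0)
        lam = conn.compute_rpdc(model, [10.0, 30.0, 60.0])
        vals.extend(model.n_samples * lam[:, 0, 1])
        vals.extend(model.n_samples * lam[:, 1, 0])
    return float(np.mean(vals))


def classification_rate(topology: str, n_seeds: int = 20,
                        snr_db: float = 10.0, duration: float = 60.0,
                        seed: int = 0, leadfield=None, montage=None,
                        model=None, n_permutations: int = 20) -> float:
    """End-to-end flow-pattern recovery rate for one scenario topology.

    Simulates scalp EEG of the star-out or ring scenario, runs the full
    chain (coherent-network search, source extraction, MVAR/RPDC with the
    rank-rule bootstrap, flow classification) and scores the fraction of
    seeds classified as the generating topology.
    """
    if leadfield is None:
        leadfield, montage, model = _study_leadfield()
    lffn = make_leadfield_fn(montage, model)
    maker = {"star_out": sim.star_scenario, "cycle": sim.cycle_scenario}
    want = {"star_out": "star_out", "cycle": "circular"}[topology]
    cfg = dics.DICSConfig(n_permutations=n_permutations)
    correct = 0
    base = np.random.SeedSequence([seed, 2 if topology == "star_out" else 3])
    for k, child in enumerate(base.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        scen = maker[topology](snr_db=snr_db, seed=seed + k)
        seg = sim.simulate_scalp_eeg(scen, lffn, montage, duration, 200.0,
                                     rng=rng)
        net, filt, _ = dics.find_coherent_network(seg, leadfield, BAND, cfg,
                                                  seed=rng)
        if len(net) < 2:
            continue
        series = dics.extract_source_timeseries(seg, filt, net.node_indices)
        series, fs_dec = conn.decimate_for_band(series, 200.0, BAND)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = conn.bootstrap_rpdc_null(series, fs_dec, BAND, rule="rank",
                                           seed=rng, p_max=10)
        dn = conn.build_directed_network(
            res, [str(i) for i in net.node_indices],
            coordinates=net.coordinates, primary=0,
            min_fraction_of_max=0.4, drop_isolated=True)
        correct += dn.topology_class == want
    return correct / n_seeds


def aic_order_recovery_rate(n_seeds: int = 20, n_samples: int = 5000,
                            true_order: int = 3, seed: int = 0) -> float:
    """Fraction of VAR(3) simulations whose AIC-selected order is 3."""
    A = np.zeros((3, 3, 3))
    A[0] = np.diag([0.5, 0.4, 0.5])
    A[1] = np.diag([-0.3, -0.2, -0.3])
    A[2] = np.diag([0.3, 0.35, 0.3])
    A[2, 1, 0] = 0.25
    hits = 0
    base = np.random.SeedSequence([seed, 4])
    for child in base.spawn(n_seeds):
        rng = np.random.default_rng(child)
        n, burn, m = n_samples, 300, 3
        x = np.zeros((n + burn, m))
        e = rng.standard_normal((n + burn, m))
        for t in range(3, n + burn):
            x[t] = e[t] + sum(A[k] @ x[t - 1 - k] for k in range(3))
        sig = x[burn:].T
        sig = sig - sig.mean(axis=1, keepdims=True)
        hits += conn.select_order_aic(sig, 10) == true_order
    return hits / n_seeds


def determinism_check(seed: int = 0, leadfield=None, montage=None,
                      model=None) -> bool:
    """Same seed twice: bit-identical maps, thresholds, and reports."""
    if leadfield is None:
        leadfield, montage, model = _study_leadfield()
    lffn = make_leadfield_fn(montage, model)
    rec, _ = sim.make_ictal_recording(
        sim.star_scenario(snr_db=10, seed=seed),
        sim.cycle_scenario(snr_db=10, seed=seed),
        seizure_times=(30.0, 70.0), fs=200.0, montage=montage,
        leadfield_fn=lffn, seed=seed, middle_start=40.0)
    cfg = AnalysisConfig(t_onset=30.0, t_offset=70.0,
                         dics=dics.DICSConfig(n_permutations=10), seed=seed)

    def run():
        rep = analyze_phase(rec, 30.0, 70.0, "onset", leadfield, cfg)
        csd = estimate_csd(rec.slice_samples(int(25 * 200), int(35 * 200)),
                           BAND)
        filt = dics.compute_spatial_filters(leadfield, csd, cfg.dics)
        pmap = dics.power_map(filt, csd).values

        def build(s):
            c = estimate_csd(s, BAND)
            return dics.power_map(filt, c).values

        thr = dics.surrogate_threshold(
            rec.slice_samples(int(25 * 200), int(35 * 200)), build, cfg.dics,
            np.random.default_rng(seed))
        return (json.dumps(rep.summary(), sort_keys=True), pmap, thr)

    r1, p1, t1 = run()
    r2, p2, t2 = run()
    return bool(r1 == r2 and np.array_equal(p1, p2)
                and np.array_equal(t1, t2))
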