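"""Synthetic ictal-EEG generator with known source-level ground truth.

Band-limited oscillatory dipole sources are generated by a stable vector
autoregressive (VAR) process whose directed-coupling graph is prescribed:
each source is a damped AR(2) resonator in its analysis band, and an edge
j -> i adds delayed taps of source j to the update equation of source i.
Tap amplitudes are normalized so that an edge's ``strength`` is the loop
gain it contributes at the resonance frequency (dimensionless; a directed
ring is stable iff the product of its strengths is below one).

Sources are projected to scalp electrodes through the concentric-sphere
forward model and white sensor noise is added at a prescribed SNR, giving
recordings on which every downstream stage has a known answer: a star-out
coupling graph emulates seizure onset (activity propagating from the primary
focus), a directed ring emulates the middle of the seizure (activity
circulating through the network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .forward import HeadModel, ElectrodeMontage, SourceGrid, make_leadfield_fn
from .spectral import EEGSegment

__all__ = [
    "SourceScenario",
    "IctalAnnotation",
    "scenario_var_coefficients",
    "companion_spectral_radius",
    "simulate_coupled_sources",
    "simulate_scalp_eeg",
    "make_ictal_recording",
    "star_scenario",
    "cycle_scenario",
    "baseline_scenario",
]

# default simulated sampling rate (Hz); the recording hardware this emulates
# runs at 2000 Hz, but the generator is rate-agnostic and 200 Hz keeps the
# routine problem sizes small
DEFAULT_FS = 200.0
DEFAULT_BAND = (16.0, 20.0)
DEFAULT_SNR_DB = 5.0
DEFAULT_STRENGTH = 0.7
VAR_ORDER = 5
STABILITY_MARGIN = 0.999
# dipole moment scale (A*m) applied to the unit-variance source series
MOMENT_SCALE = 2e-8

# three well-separated template source positions (m), multiples of the 5 mm
# grid spacing so localization error has an unambiguous zero
DEFAULT_POSITIONS = (
    (-0.040, -0.020, 0.025),   # left temporal-ish (primary)
    (0.040, 0.030, 0.010),     # right frontal-ish
    (0.000, -0.045, 0.040),    # midline parietal-ish
)
DEFAULT_ORIENTATIONS = (
    (0.0, 0.6, 0.8),
    (0.0, 0.0, 1.0),
    (1.0, 0.0, 0.0),
)
# relative cross-coupling tap shape over lags 1..3; sums to zero so coupling
# carries no DC gain
COUPLING_TAP_SHAPE = (1.0, -0.5, -0.5)


@dataclass(frozen=True)
class SourceScenario:
    """Ground-truth configuration of coupled dipole sources.

    ``coupling_graph`` is a tuple of ``(src, dst, strength)`` triples; the
    strength is the resonant loop gain of the edge (see module docstring).
    """

    source_positions: tuple
    source_orientations: tuple
    coupling_graph: tuple = ()
    band: tuple = DEFAULT_BAND
    topology_label: str = "none"
    snr_db: float = DEFAULT_SNR_DB
    seed: int = 0
    # per-source innovation std; the seizure-onset (primary) source is
    # typically the strongest, so star presets boost it
    innovation_scales: tuple | None = None

    def __post_init__(self):
        pos = np.asarray(self.source_positions, float)
        ori = np.asarray(self.source_orientations, float)
        if len(self.source_positions) == 0:
            pos = pos.reshape(0, 3)
            ori = ori.reshape(0, 3)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != ori.shape:
            raise ValueError("positions/orientations must be matching (m, 3)")
        inner = HeadModel().inner_radius
        if pos.size and np.any(np.linalg.norm(pos, axis=1) >= inner):
            raise ValueError(
                "all source positions must be strictly inside the innermost "
                f"shell (radius {inner} m)")
        if ori.size:
            norms = np.linalg.norm(ori, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("orientations must be unit-norm within 1e-9")
        m = pos.shape[0]
        for (s, d, c) in self.coupling_graph:
            if not (0 <= s < m and 0 <= d < m) or s == d:
                raise ValueError(f"invalid edge ({s}, {d})")
            float(c)
        f_lo, f_hi = self.band
        if not 0 < f_lo < f_hi:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if self.topology_label not in {"star_out", "cycle", "none"}:
            raise ValueError("topology_label must be star_out, cycle or none")
        if self.innovation_scales is not None:
            scales = np.asarray(self.innovation_scales, float)
            if scales.shape != (m,) or np.any(scales <= 0):
                raise ValueError("innovation_scales must be m positive values")

    @property
    def n_sources(self) -> int:
        return len(self.source_positions)


def _default_sources(n: int):
    return (tuple(DEFAULT_POSITIONS[:n]), tuple(DEFAULT_ORIENTATIONS[:n]))


def star_scenario(strength: float = DEFAULT_STRENGTH,
                  snr_db: float = DEFAULT_SNR_DB,
                  band: tuple = DEFAULT_BAND, seed: int = 0) -> SourceScenario:
    """Three sources; the primary drives the other two (seizure onset)."""
    pos, ori = _default_sources(3)
    return SourceScenario(pos, ori,
                          coupling_graph=((0, 1, strength), (0, 2, strength)),
                          band=band, topology_label="star_out",
                          snr_db=snr_db, seed=seed,
                          innovation_scales=(2.0, 1.0, 1.0))


def cycle_scenario(strength: float = DEFAULT_STRENGTH,
                   snr_db: float = DEFAULT_SNR_DB,
                   band: tuple = DEFAULT_BAND, seed: int = 0) -> SourceScenario:
    """Three sources coupled in a directed ring (mid-seizure perpetuation)."""
    pos, ori = _default_sources(3)
    return SourceScenario(pos, ori,
                          coupling_graph=((0, 1, strength), (1, 2, strength),
                                          (2, 0, strength)),
                          band=band, topology_label="cycle",
                          snr_db=snr_db, seed=seed)


def baseline_scenario(snr_db: float = DEFAULT_SNR_DB,
                      band: tuple = DEFAULT_BAND, seed: int = 0) -> SourceScenario:
    """No active sources: sensor noise only."""
    return SourceScenario((), (), coupling_graph=(), band=band,
                          topology_label="none", snr_db=snr_db, seed=seed)


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (``coeffs``: (p, m, m))."""
    p, m, _ = coeffs.shape
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.abs(np.linalg.eigvals(comp)).max())


def scenario_var_coefficients(scenario: SourceScenario,
                              fs: float = DEFAULT_FS) -> np.ndarray:
    """VAR(p) coefficient matrices realizing the scenario's coupling graph.

    Diagonal terms are AR(2) resonators at the band centre with pole radius
    set by the band width; cross terms are zero-DC tap triples at lags 1..3
    normalized so each edge contributes its ``strength`` as resonant loop
    gain.  Raises if the assembled process is unstable.
    """
    f_lo, f_hi = scenario.band
    if f_hi >= fs / 2:
        raise ValueError(f"band {scenario.band} outside (0, {fs / 2}) Hz")
    m = scenario.n_sources
    fc = 0.5 * (f_lo + f_hi)
    rho = 1.0 - np.pi * (f_hi - f_lo) / fs
    if rho <= 0:
        raise ValueError("band too wide for this sampling rate")
    theta = 2.0 * np.pi * fc / fs
    A = np.zeros((VAR_ORDER, m, m))
    for i in range(m):
        A[0, i, i] = 2.0 * rho * np.cos(theta)
        A[1, i, i] = -rho ** 2
    if m == 0:
        return A
    # resonator gain at fc and raw tap gain at fc, used for normalization
    z = np.exp(-1j * theta)
    g_osc = 1.0 / abs(1.0 - A[0, 0, 0] * z - A[1, 0, 0] * z ** 2)
    shape = np.asarray(COUPLING_TAP_SHAPE)
    h_fc = abs(sum(b * z ** (k + 1) for k, b in enumerate(shape)))
    for (s, d, c) in scenario.coupling_graph:
        taps = (float(c) / (g_osc * h_fc)) * shape
        A[:3, d, s] += taps
    radius = companion_spectral_radius(A)
    if radius >= STABILITY_MARGIN:
        raise ValueError(
            f"unstable coupling graph: companion spectral radius "
            f"{radius:.4f} >= {STABILITY_MARGIN}")
    return A


def simulate_coupled_sources(scenario: SourceScenario, n_samples: int,
                             fs: float = DEFAULT_FS,
                             rng: np.random.Generator | None = None,
                             burn_in: int = 1000) -> np.ndarray:
    """Generate the source time series (n_sources x n_samples), zero-mean.

    The VAR process is driven by unit-variance Gaussian innovations; an
    initial ``burn_in`` stretch is discarded so the output is (approximately)
    stationary from the first sample.
    """
    A = scenario_var_coefficients(scenario, fs)
    m = scenario.n_sources
    if m == 0:
        return np.zeros((0, n_samples))
    p = A.shape[0]
    if n_samples < 10 * p:
        raise ValueError(f"need at least {10 * p} samples")
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    total = n_samples + burn_in
    e = rng.standard_normal((total, m))
    if scenario.innovation_scales is not None:
        e = e * np.asarray(scenario.innovation_scales, float)
    x = np.zeros((total, m))
    for t in range(p, total):
        acc = e[t]
        for k in range(p):
            acc = acc + A[k] @ x[t - 1 - k]
        x[t] = acc
    out = x[burn_in:].T
    return out - out.mean(axis=1, keepdims=True)


def _sensor_noise(rng, n_channels, n_samples, std, spatial_corr=0.0,
                  positions=None):
    """White Gaussian sensor noise; optionally spatially correlated."""
    noise = rng.standard_normal((n_channels, n_samples)) * std
    if spatial_corr > 0:
        if positions is None:
            raise ValueError("spatially correlated noise needs positions")
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        K = np.exp(-d / spatial_corr)
        L = np.linalg.cholesky(K + 1e-12 * np.eye(n_channels))
        noise = L @ noise
    return noise


def simulate_scalp_eeg(scenario: SourceScenario, leadfield_fn,
                       montage: ElectrodeMontage, duration: float,
                       fs: float = DEFAULT_FS,
                       rng: np.random.Generator | None = None,
                       noise_spatial_corr: float = 0.0,
                       return_parts: bool = False):
    """Project the scenario's sources to scalp electrodes and add noise.

    EEG(t) = sum_s L(pos_s, ori_s) * moment * source_s(t) + noise, with the
    white Gaussian sensor noise scaled so the channel-averaged SNR equals
    ``scenario.snr_db``; the output is average-referenced, in microvolts.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    n_samples = int(round(duration * fs))
    sources = simulate_coupled_sources(scenario, n_samples, fs, rng=rng)
    n_ch = len(montage)
    signal = np.zeros((n_ch, n_samples))
    for s in range(scenario.n_sources):
        gain = leadfield_fn(scenario.source_positions[s],
                            np.asarray(scenario.source_orientations[s]) *
                            MOMENT_SCALE)
        signal += np.outer(gain, sources[s])
    signal *= 1e6    # V -> microvolts
    p_sig = float(np.mean(signal ** 2))
    if np.isinf(scenario.snr_db):
        noise = np.zeros_like(signal)
    else:
        if p_sig == 0.0:
            raise ValueError(
                "cannot scale noise by SNR for a source-free scenario; "
                "use make_ictal_recording with an explicit noise level")
        std = np.sqrt(p_sig / 10.0 ** (scenario.snr_db / 10.0))
        noise = _sensor_noise(rng, n_ch, n_samples, std,
                              noise_spatial_corr, montage.positions)
    data = signal + noise
    data = data - data.mean(axis=0, keepdims=True)
    seg = EEGSegment(data=data, fs=fs, montage=montage, t0=0.0)
    if return_parts:
        return seg, signal, noise
    return seg


@dataclass
class IctalAnnotation:
    """Ground truth attached to a simulated recording."""

    fs: float
    duration: float
    t_onset: float | None
    t_offset: float | None
    t_middle_start: float | None
    noise_std_uv: float
    phases: list = field(default_factory=list)
    # each phase: {label, t_start, t_end, topology, band, positions,
    #             orientations, coupling_graph}
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "IctalAnnotation":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "IctalAnnotation":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def phase(self, label: str) -> dict:
        for ph in self.phases:
            if ph["label"] == label:
                return ph
        raise KeyError(label)


def _phase_record(label, t_start, t_end, scenario: SourceScenario) -> dict:
    return {
        "label": label,
        "t_start": t_start,
        "t_end": t_end,
        "topology": scenario.topology_label,
        "band": list(scenario.band),
        "positions": [list(p) for p in scenario.source_positions],
        "orientations": [list(o) for o in scenario.source_orientations],
        "coupling_graph": [list(e) for e in scenario.coupling_graph],
    }


def make_ictal_recording(onset_scenario: SourceScenario | None = None,
                         middle_scenario: SourceScenario | None = None,
                         seizure_times: tuple | None = (30.0, 70.0),
                         duration: float | None = None,
                         fs: float = DEFAULT_FS,
                         montage: ElectrodeMontage | None = None,
                         model: HeadModel | None = None,
                         leadfield_fn=None,
                         seed: int = 0,
                         snap_to_grid: bool = True,
                         voxel_size: float = 0.005,
                         middle_start: float | None = None):
    """Simulate a full recording: pre-ictal baseline, onset, middle phase.

    The onset scenario is active on [t_on, middle_start) and the middle
    scenario on [middle_start, t_off); ``middle_start`` defaults to the
    seizure midpoint.  Note that the 10 s mid-seizure analysis window is
    centred on the midpoint, so with the default switch time it straddles
    the regime change; pass e.g. ``middle_start = t_on + 10`` for a window
    of pure mid-seizure dynamics.  Sensor noise is continuous over the whole
    recording, scaled so the onset phase reaches the onset scenario's SNR.
    With ``seizure_times=None`` a baseline-only (pure noise) recording is
    produced.

    Returns ``(EEGSegment, IctalAnnotation)``.
    """
    model = model or HeadModel()
    if montage is None:
        from .forward import standard_1010_montage
        montage = standard_1010_montage(32, model)
    if leadfield_fn is None:
        leadfield_fn = make_leadfield_fn(montage, model)
    rng = np.random.default_rng(seed)
    if seizure_times is None:
        duration = duration or 60.0
        n = int(round(duration * fs))
        base = baseline_scenario(seed=seed)
        noise_std = 1.0   # microvolts, arbitrary reference level
        data = _sensor_noise(rng, len(montage), n, noise_std)
        data -= data.mean(axis=0, keepdims=True)
        ann = IctalAnnotation(fs=fs, duration=duration, t_onset=None,
                              t_offset=None, t_middle_start=None,
                              noise_std_uv=noise_std,
                              phases=[_phase_record("baseline", 0.0,
                                                    duration, base)],
                              seed=seed)
        return EEGSegment(data, fs, montage, 0.0, "baseline"), ann

    t_on, t_off = seizure_times
    if t_on < 10.0:
        raise ValueError("seizure onset must be at least 10 s into the recording")
    if t_off <= t_on:
        raise ValueError("t_off must exceed t_on")
    onset_scenario = onset_scenario or star_scenario(seed=seed)
    middle_scenario = middle_scenario or cycle_scenario(
        snr_db=onset_scenario.snr_db, band=onset_scenario.band, seed=seed)
    if snap_to_grid:
        grid = SourceGrid.for_model(model, voxel_size)
        onset_scenario = _snap_scenario(onset_scenario, grid)
        middle_scenario = _snap_scenario(middle_scenario, grid)
    duration = duration or (t_off + 10.0)
    if t_off > duration:
        raise ValueError("seizure extends past the end of the recording")
    n_total = int(round(duration * fs))
    t_mid = 0.5 * (t_on + t_off) if middle_start is None else float(middle_start)
    if not t_on < t_mid < t_off:
        raise ValueError("middle_start must lie inside the seizure")
    i_on, i_mid, i_off = (int(np.floor(t * fs)) for t in (t_on, t_mid, t_off))

    signal = np.zeros((len(montage), n_total))
    for scen, lo, hi in ((onset_scenario, i_on, i_mid),
                         (middle_scenario, i_mid, i_off)):
        _, sig, _ = simulate_scalp_eeg(
            scen, leadfield_fn, montage, (hi - lo) / fs, fs, rng=rng,
            return_parts=True)
        signal[:, lo:hi] = sig
    # noise level from the onset-phase signal power and onset SNR
    p_sig = float(np.mean(signal[:, i_on:i_mid] ** 2))
    noise_std = np.sqrt(p_sig / 10.0 ** (onset_scenario.snr_db / 10.0))
    noise = _sensor_noise(rng, len(montage), n_total, noise_std)
    data = signal + noise
    data -= data.mean(axis=0, keepdims=True)
    ann = IctalAnnotation(
        fs=fs, duration=duration, t_onset=t_on, t_offset=t_off,
        t_middle_start=t_mid, noise_std_uv=float(noise_std),
        phases=[
            _phase_record("baseline", 0.0, t_on, baseline_scenario(seed=seed)),
            _phase_record("onset", t_on, t_mid, onset_scenario),
            _phase_record("middle", t_mid, t_off, middle_scenario),
        ],
        seed=seed)
    return EEGSegment(data, fs, montage, 0.0, "other"), ann


def _snap_scenario(scenario: SourceScenario, grid: SourceGrid) -> SourceScenario:
    pos = tuple(tuple(grid.snap(p)) for p in scenario.source_positions)
    return SourceScenario(pos, scenario.source_orientations,
                          scenario.coupling_graph, scenario.band,
                          scenario.topology_label, scenario.snr_db,
                          scenario.seed, scenario.innovation_scales)
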