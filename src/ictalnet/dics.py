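"""DICS beamforming: spatial filters, power/coherence maps, source networks.

The beamformer is the linearly constrained minimum-variance (LCMV) filter in
the frequency domain: at every grid node r with lead field L(r), the filter
A(r) = (L' Cr^-1 L)^-1 L' Cr^-1 passes a dipole at r with unit gain while
minimizing output power, where Cr is the real part of the band-averaged
cross-spectral density with diagonal (Tikhonov) regularization
alpha * mean(diag).  Power maps take the dominant-orientation output power;
coherence maps relate every node to a reference source whose own sensor-space
contribution has been deflated out of the CSD, so that the reference's
trivial self-coherence of one cannot dominate the map.

Significance of a map is assessed against surrogates built by shuffling
one-second windows of the segment independently per channel, which preserves
channel spectra but destroys inter-channel coherence; the per-voxel
threshold is a high percentile (default 99) of the surrogate map values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .spectral import (CrossSpectrum, EEGSegment, band_average_csd,
                       estimate_csd)

__all__ = [
    "DICSConfig",
    "SpatialFilter",
    "PowerMap",
    "CoherenceMap",
    "CoherentNetwork",
    "compute_spatial_filters",
    "power_map",
    "coherence_map",
    "surrogate_threshold",
    "find_coherent_network",
    "extract_source_timeseries",
    "shuffle_windows",
    "map_to_nifti",
    "map_to_csv",
    "network_to_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DICSConfig:
    """Beamformer and surrogate-test settings."""

    alpha: float = 0.001              # regularization, relative to mean power
    voxel_size: float = 0.005         # m
    n_permutations: int = 100
    threshold_percentile: float = 99.0
    max_sources: int = 8
    min_node_separation_voxels: float = 4.0
    surrogate_window_s: float = 1.0
    joint_shuffle: bool = False       # shuffle windows jointly across channels
    # dimension of the residual signal subspace used by the sequential
    # source scan; 3 accommodates up to three further coherent dipoles
    scan_subspace_rank: int = 3
    # a CSD eigenvalue counts as a source when it exceeds this multiple of
    # the median eigenvalue (the sensor-noise floor); caps the number of
    # network iterations
    source_count_eigenvalue_ratio: float = 10.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 50.0 < self.threshold_percentile < 100.0:
            raise ValueError("threshold_percentile must be in (50, 100)")
        if self.n_permutations < 1 or self.max_sources < 1:
            raise ValueError("n_permutations and max_sources must be >= 1")


@dataclass
class SpatialFilter:
    """Per-node LCMV filters derived from one band-averaged CSD."""

    filters: np.ndarray        # (V, 3, E) unit-gain vector filters
    orientations: np.ndarray   # (V, 3) dominant dipole orientation
    reduced: np.ndarray        # (V, E) dominant-orientation filters
    csd_matrix: np.ndarray     # (E, E) complex band-averaged CSD
    leadfield: LeadField
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.filters.shape[0]

    def node_topography(self, node: int) -> np.ndarray:
        """Sensor-space pattern of the node's dominant-orientation dipole."""
        return self.leadfield.matrices[node] @ self.orientations[node]


@dataclass
class PowerMap:
    values: np.ndarray                 # (V,) >= 0
    band: tuple
    threshold: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.values < -1e-12 * max(self.values.max(), 1e-300)):
            raise ValueError("power map must be non-negative")
        self.values = np.maximum(self.values, 0.0)


@dataclass
class CoherenceMap:
    values: np.ndarray                 # (V,) in [0, 1]
    band: tuple
    reference_node: int
    projected_out: tuple = ()
    threshold: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass
class CoherentNetwork:
    """Ordered list of accepted coherent sources."""

    node_indices: list
    coordinates: np.ndarray            # (k, 3)
    statistics: list                   # acceptance statistic per node
    thresholds: list
    source_maps: list                  # "power" or ("coherence", ref_index)
    weak_primary: bool = False

    def __len__(self) -> int:
        return len(self.node_indices)


def _band_matrix(csd) -> np.ndarray:
    if isinstance(csd, CrossSpectrum):
        return band_average_csd(csd)
    C = np.asarray(csd, complex)
    return 0.5 * (C + C.conj().T)


def compute_spatial_filters(leadfield: LeadField, csd,
                            config: DICSConfig = DICSConfig()) -> SpatialFilter:
    """Unit-gain LCMV filters for every grid node.

    The inverse is taken of Cr = Re(C) + alpha * mean(diag(Re C)) * I; the
    real part carries the zero-lag field structure used for localization.
    The dominant orientation at each node is the leading eigenvector of the
    3x3 real output matrix A Re(C) A'.
    """
    C = _band_matrix(csd)
    E = C.shape[0]
    L = leadfield.matrices                      # (V, E, 3)
    if L.shape[1] != E:
        raise ValueError("lead field and CSD have different channel counts")
    Cr = C.real + config.alpha * np.mean(np.diag(C.real)) * np.eye(E)
    cond = np.linalg.cond(Cr)
    if not np.isfinite(cond) or cond > 1e13:
        raise np.linalg.LinAlgError(
            f"regularized CSD is numerically singular (cond={cond:.3g}); "
            f"increase alpha")
    Ci = np.linalg.inv(Cr)
    Ci = 0.5 * (Ci + Ci.T)
    T = np.einsum("ef,vfa->vea", Ci, L)         # (V, E, 3)
    G = np.einsum("vea,veb->vab", L, T)         # (V, 3, 3)
    A = np.linalg.solve(G, np.swapaxes(T, 1, 2))  # (V, 3, E)
    M = np.einsum("vae,ef,vbf->vab", A, C.real, A)
    M = 0.5 * (M + np.swapaxes(M, 1, 2))
    _, vecs = np.linalg.eigh(M)
    u = vecs[:, :, -1]                          # leading eigenvector
    # deterministic sign: largest-magnitude component positive
    idx = np.argmax(np.abs(u), axis=1)
    sign = np.sign(u[np.arange(len(u)), idx])
    sign[sign == 0] = 1.0
    u = u * sign[:, None]
    reduced = np.einsum("va,vae->ve", u, A)
    return SpatialFilter(filters=A, orientations=u, reduced=reduced,
                         csd_matrix=C, leadfield=leadfield,
                         alpha=config.alpha)


def power_map(filters: SpatialFilter, csd, band: tuple = (0.0, 0.0)) -> PowerMap:
    """Source power per voxel: largest eigenvalue of A(r) C A(r)^H."""
    C = _band_matrix(csd)
    H = np.einsum("vae,ef,vbf->vab", filters.filters, C,
                  np.conj(filters.filters))
    H = 0.5 * (H + np.conj(np.swapaxes(H, 1, 2)))
    vals = np.linalg.eigvalsh(H)[:, -1].real
    return PowerMap(values=vals, band=tuple(band))


def _source_projector(filters: SpatialFilter, node: int,
                      neighborhood: bool = False,
                      max_rank: int = 8) -> np.ndarray:
    """Projector removing one source's sensor-space contribution.

    Orthogonal signal-space projection onto the complement of the node's
    three-column lead field: P = I - Q Q', Q an orthonormal basis of
    span(L(r)).  A dipole at the node is removed exactly, for any
    orientation, with no noise amplification (P is an orthogonal projector);
    signals of well-separated sources lose only the small fraction of their
    topography lying in that low-dimensional subspace.

    With ``neighborhood`` the subspace is built from the lead fields of the
    node and its immediate grid neighbours (dominant ``max_rank`` singular
    directions), so a source whose accepted node is off by a voxel is still
    removed essentially completely — otherwise its residue re-enters
    residual-power maps as a spurious remote "ghost" source.
    """
    lf = filters.leadfield
    if neighborhood:
        Q = _neighborhood_basis(lf, node, max_rank)
    else:
        Q, _ = np.linalg.qr(lf.matrices[node])
    return np.eye(Q.shape[0]) - Q @ Q.T


def _oblique_projector(filters: SpatialFilter, node: int) -> np.ndarray:
    """P = I - l w / (w l): remove the node's beamformed signal estimate.

    Applied to the data, subtracts the node's unit-gain source estimate
    rendered through its dominant-orientation topography; w_v P strips
    exactly the deterministic leakage gain (w_v l) of that source from every
    voxel filter, and the node's own series w P x vanishes identically.
    Complements :func:`_source_projector`: the oblique form gives the exact
    per-voxel leakage correction coherence maps need, the orthogonal form
    the orientation-free removal that residual scans need.
    """
    l = filters.node_topography(node)
    w = filters.reduced[node]
    gain = float(w @ l)
    if abs(gain) < 1e-12:
        raise ValueError("degenerate source projector (w l = 0)")
    return np.eye(len(l)) - np.outer(l, w) / gain


def _neighborhood_basis(leadfield: LeadField, node: int,
                        max_rank: int = 8) -> np.ndarray:
    """Dominant singular directions of the lead fields around a node."""
    d = np.linalg.norm(leadfield.grid.nodes - leadfield.grid.nodes[node],
                       axis=1)
    sel = np.flatnonzero(d <= 1.6 * leadfield.grid.voxel_size)
    L = np.concatenate([leadfield.matrices[i] for i in sel], axis=1)
    U, s, _ = np.linalg.svd(L, full_matrices=False)
    rank = min(max_rank, int(np.sum(s > 1e-6 * s[0])))
    return U[:, :rank]


def coherence_map(filters: SpatialFilter, csd, reference_node: int,
                  project_out: tuple = (),
                  band: tuple = (0.0, 0.0)) -> CoherenceMap:
    """Coherence of every voxel with a reference source.

    Per voxel v the map is |S_vr|^2 / (S_vv * S_rr) on beamformed source
    spectra.  The reference is projected out of the cross-spectral matrix on
    the voxel side (see :func:`_source_projector`): leakage of the reference
    signal into other voxels' filters is removed, so the map is ~0 at the
    reference itself and in its halo, while genuine coherence of other
    regions with the reference signal survives.  Sources in ``project_out``
    (accepted earlier in the iterative network search) are removed from both
    sides first.  Values are in [0, 1] by the Cauchy-Schwarz inequality.
    """
    if isinstance(csd, CrossSpectrum):
        stack = csd.csd
    else:
        stack = np.asarray(csd, complex)
        if stack.ndim == 2:
            stack = stack[None]
    V = filters.n_nodes
    if not 0 <= reference_node < V:
        raise ValueError("reference node outside the grid")
    P = np.eye(stack.shape[1])
    for node in project_out:
        P = _oblique_projector(filters, node) @ P
    P = _oblique_projector(filters, reference_node) @ P
    w_r = filters.reduced[reference_node].astype(complex)
    W = filters.reduced.astype(complex)
    vals = np.zeros(V)
    # per-bin magnitude-squared coherence, averaged across the band: the
    # cross-spectral phase of lag-coupled oscillators rotates quickly across
    # a resonance, so complex band-averaging before normalization would
    # cancel genuine coherence
    for Cf in stack:
        s_rr = np.real(w_r @ Cf @ np.conj(w_r))
        if s_rr <= 0:
            raise ValueError("reference auto-spectrum is non-positive")
        PC = P @ Cf                                      # voxel-side projection
        num = np.abs(W @ (PC @ np.conj(w_r))) ** 2       # (V,)
        PCP = PC @ P.conj().T
        den = np.einsum("ve,ef,vf->v", W, PCP, np.conj(W)).real
        den = np.maximum(den, 0.0)
        good = den > 1e-15 * max(float(den.max()), 1e-300)
        bin_vals = np.zeros(V)
        bin_vals[good] = num[good] / (den[good] * s_rr)
        vals += np.clip(bin_vals, 0.0, 1.0)
    vals /= stack.shape[0]
    # the map is undefined at the reference itself: after its dipole is
    # projected out, the voxel's residual is leakage of *other* coherent
    # activity, so its coherence with the reference says nothing about a
    # source at that location; blank the immediate neighbourhood
    grid = filters.leadfield.grid
    for node in (reference_node, *project_out):
        near = np.linalg.norm(grid.nodes - grid.nodes[node], axis=1) \
            < 2.0 * grid.voxel_size
        vals[near] = 0.0
    return CoherenceMap(values=np.clip(vals, 0.0, 1.0), band=tuple(band),
                        reference_node=int(reference_node),
                        projected_out=tuple(project_out))


def window_fourier(segment: EEGSegment, band, window_s: float = 1.0,
                   overlap: float = 0.5):
    """Per-window Fourier coefficients on the band's bins.

    Returns ``(frequencies, coeffs)`` with ``coeffs`` of shape
    (n_windows, n_channels, n_bins); averaging the windows' outer products
    reproduces the Welch CSD up to a scale that cancels in coherence.
    """
    from scipy import signal as sps

    f_lo, f_hi = (band.f_lo, band.f_hi) if hasattr(band, "f_lo") else band
    fs = segment.fs
    nperseg = int(round(window_s * fs))
    step = nperseg - int(nperseg * overlap)
    data = segment.data - segment.data.mean(axis=1, keepdims=True)
    starts = np.arange(0, segment.n_samples - nperseg + 1, step)
    if len(starts) < 2:
        raise ValueError("segment too short: need at least 2 windows")
    win = sps.get_window("hann", nperseg)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    sel = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
    if sel.size == 0:
        raise ValueError("no frequency bins inside the band")
    coeffs = np.stack([np.fft.rfft(data[:, s:s + nperseg] * win,
                                   axis=1)[:, sel] for s in starts])
    return freqs[sel], coeffs


def coherence_stage(segment: EEGSegment, filters: SpatialFilter,
                    reference_node: int, project_out: tuple,
                    band, config: DICSConfig,
                    rng: np.random.Generator,
                    search_mask: np.ndarray | None = None,
                    return_surrogates: bool = False) -> tuple:
    """Observed coherence map plus reference-permutation thresholds.

    The observed map matches :func:`coherence_map` (per-bin magnitude-squared
    coherence of every voxel with the reference source, leakage projected
    out, averaged over band bins).  The null permutes the *reference
    source's* analysis windows against the intact voxel signals: this
    destroys exactly the voxel-reference dependence under test while
    preserving the narrowband spectra and the spatial structure of the data
    on both sides — a sensor-level shuffle would instead replace the
    recording with spatially unstructured activity whose beamformed
    coherence noise grossly overstates the null.

    Returns ``(values, thr_voxel, thr_max)``: the per-voxel percentile
    threshold and the family-wise threshold (the same percentile of the
    per-permutation map maxima over ``search_mask``), which calibrates the
    accept/reject decision for the map's argmax.
    """
    # non-overlapping windows: with overlap, a permuted reference window
    # landing next to its original position still shares half its samples
    # with the voxel windows, which inflates the null.  The coherence floor
    # of a K-window estimate is ~2/K, so short segments use windows small
    # enough for K >= 20, bounded below by the band's frequency resolution.
    f_lo, f_hi = (band.f_lo, band.f_hi) if hasattr(band, "f_lo") else band
    win_s = min(config.surrogate_window_s, segment.duration / 3.0)
    if segment.duration / win_s < 20:
        win_s = max(segment.duration / 20.0, 1.0 / max(f_hi - f_lo, 1e-6))
        win_s = min(win_s, segment.duration / 3.0)
    freqs, Y = window_fourier(segment, band, win_s, overlap=0.0)
    P = np.eye(Y.shape[1])
    for node in (*project_out, reference_node):
        P = _oblique_projector(filters, node) @ P
    Wp = filters.reduced @ P.T                        # (V, E), voxel side
    w_r = filters.reduced[reference_node]
    a_v = np.einsum("ve,kef->vkf", Wp, Y)             # (V, K, F)
    a_r = np.einsum("e,kef->kf", w_r, Y)              # (K, F)
    s_vv = np.sum(np.abs(a_v) ** 2, axis=1)           # (V, F)
    s_rr = np.sum(np.abs(a_r) ** 2, axis=0)           # (F,)
    if np.any(s_rr <= 0):
        raise ValueError("reference auto-spectrum is non-positive")
    den = np.maximum(s_vv * s_rr[None, :], 1e-300)

    def msc(perm=None):
        ar = a_r if perm is None else a_r[perm]
        s_vr = np.einsum("vkf,kf->vf", a_v, np.conj(ar))
        return np.mean(np.clip(np.abs(s_vr) ** 2 / den, 0.0, 1.0), axis=1)

    values = msc()
    k = Y.shape[0]
    sur = np.stack([msc(rng.permutation(k))
                    for _ in range(config.n_permutations)])
    if return_surrogates:
        return values, sur
    thr_voxel = np.percentile(sur, config.threshold_percentile, axis=0)
    region = sur if search_mask is None else sur[:, search_mask]
    thr_max = float(np.percentile(region.max(axis=1),
                                  config.threshold_percentile))
    return values, thr_voxel, thr_max


def shuffle_windows(segment: EEGSegment, rng: np.random.Generator,
                    window_s: float = 1.0,
                    joint: bool = False) -> EEGSegment:
    """Surrogate segment: permute fixed-length windows, per channel.

    Per-channel shuffling preserves each channel's spectrum but destroys
    inter-channel coherence (the null of "no coherent source"); ``joint``
    shuffling permutes the same window order in every channel instead,
    destroying only nonstationarity.
    """
    w = int(round(window_s * segment.fs))
    n = segment.n_samples
    k = n // w
    if k < 3:
        w = max(n // 3, 1)
        k = n // w
        logger.info("segment shorter than 3 surrogate windows; "
                    "window shrunk to %d samples", w)
    data = segment.data.copy()
    if joint:
        perm = rng.permutation(k)
        idx = (perm[:, None] * w + np.arange(w)).ravel()
        data[:, :k * w] = data[:, idx]
    else:
        for ch in range(segment.n_channels):
            perm = rng.permutation(k)
            idx = (perm[:, None] * w + np.arange(w)).ravel()
            data[ch, :k * w] = data[ch, idx]
    return EEGSegment(data, segment.fs, segment.montage, segment.t0,
                      segment.phase_label)


def surrogate_threshold(segment: EEGSegment, map_builder,
                        config: DICSConfig = DICSConfig(),
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Per-voxel significance threshold from window-shuffled surrogates.

    ``map_builder(segment) -> (V,) values`` is re-run on each of
    ``config.n_permutations`` surrogates; the threshold is the per-voxel
    ``config.threshold_percentile`` percentile of the surrogate values.
    Deterministic for a fixed rng/seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sur = np.empty((config.n_permutations, 0))
    maps = []
    for perm in range(config.n_permutations):
        shuffled = shuffle_windows(segment, rng, config.surrogate_window_s,
                                   joint=config.joint_shuffle)
        try:
            maps.append(np.asarray(map_builder(shuffled)))
        except Exception as exc:
            raise RuntimeError(
                f"surrogate map computation failed at permutation {perm}"
            ) from exc
    sur = np.stack(maps)
    return np.percentile(sur, config.threshold_percentile, axis=0)


def find_coherent_network(segment: EEGSegment, leadfield: LeadField, band,
                          config: DICSConfig = DICSConfig(),
                          seed: int | np.random.Generator = 0,
                          csd_kwargs: dict | None = None) -> tuple:
    """Iterative identification of the coherent source network.

    1. the power-map maximum is the primary source (the strongest source in
    the band defines the reference region; it is accepted without a
    significance gate); 2. candidate sources are proposed by a projected
    subspace-correlation scan of the residual CSD: with the accepted
    sources' lead fields projected out of both the CSD and the scanning
    lead fields, the candidate is the node whose (projected) lead-field
    subspace best correlates with the dominant residual signal subspace —
    the sequential-scan construction that keeps already-found sources from
    re-entering and localizes the next active region exactly even though
    plain coherence maps are scale-invariant and peak ambiguously on
    leakage mixtures; 3. the candidate is accepted if its coherence with any
    accepted source exceeds the percentile of the reference-permutation
    null (max-over-references statistic, identically formed under the
    null); 4. repeat until a candidate fails the coherence test or
    ``max_sources`` is reached.  Accepted nodes are kept at least
    ``min_node_separation_voxels`` apart.  A primary with no significant
    coherent partner is flagged weak.

    Returns ``(CoherentNetwork, SpatialFilter, CrossSpectrum)``.
    """
    csd_kwargs = dict(csd_kwargs or {})
    csd_kwargs.setdefault("window_s",
                          min(1.0, segment.duration / 2.0))
    band_t = (band.f_lo, band.f_hi) if hasattr(band, "f_lo") else tuple(band)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    csd = estimate_csd(segment, band_t, **csd_kwargs)
    filters = compute_spatial_filters(leadfield, csd, config)
    nodes = leadfield.grid.nodes
    C = _band_matrix(csd)

    pmap = power_map(filters, csd, band_t)
    primary = int(np.argmax(pmap.values))
    accepted = [primary]
    stats = [float(pmap.values[primary])]
    thresholds = [None]
    source_maps = ["power"]
    min_sep = config.min_node_separation_voxels * config.voxel_size
    # coherent-subspace dimension: eigenvalues above the noise floor
    eigs = np.linalg.eigvalsh(C)
    n_dominant = int(np.sum(eigs > config.source_count_eigenvalue_ratio *
                            np.median(eigs)))
    n_target = min(config.max_sources, max(1, n_dominant))

    while len(accepted) < n_target:
        mask = np.ones(len(nodes), bool)
        for node in accepted:
            mask &= np.linalg.norm(nodes - nodes[node], axis=1) >= min_sep
        if not mask.any():
            break
        P = np.eye(C.shape[0])
        for node in accepted:
            P = _source_projector(filters, node) @ P
        C_res = P @ C @ P.conj().T
        w_eig, V_eig = np.linalg.eigh(0.5 * (C_res + C_res.conj().T))
        Us = V_eig[:, -config.scan_subspace_rank:]
        PL = np.einsum("ef,vfa->vea", P, leadfield.matrices)
        Qv, _ = np.linalg.qr(PL)
        M = np.einsum("vea,ek->vak", Qv.conj(), Us)
        subcorr = np.linalg.svd(M, compute_uv=False)[:, 0]
        cand = int(np.argmax(np.where(mask, subcorr, -np.inf)))
        # acceptance statistic: the candidate's strongest coherence with any
        # accepted source (in a star-like network a new region may cohere
        # with the primary but only weakly with the last accepted one); the
        # null takes the same max over references per permutation, so the
        # combined test stays calibrated
        vals_by_ref, sur_by_ref = [], []
        for ref in reversed(accepted):
            proj = tuple(n for n in accepted if n != ref)
            v, s = coherence_stage(segment, filters, ref, proj, band_t,
                                   config, rng, return_surrogates=True)
            vals_by_ref.append(v)
            sur_by_ref.append(s)
        vals = np.max(vals_by_ref, axis=0)
        sur = np.max(sur_by_ref, axis=0)
        thr_voxel = np.percentile(sur, config.threshold_percentile, axis=0)
        if vals[cand] <= thr_voxel[cand]:
            break
        best_ref = list(reversed(accepted))[
            int(np.argmax([v[cand] for v in vals_by_ref]))]
        accepted.append(cand)
        stats.append(float(vals[cand]))
        thresholds.append(float(thr_voxel[cand]))
        source_maps.append(("coherence", best_ref))

    net = CoherentNetwork(node_indices=accepted,
                          coordinates=nodes[accepted].copy(),
                          statistics=stats, thresholds=thresholds,
                          source_maps=source_maps,
                          weak_primary=(len(accepted) == 1
                                        and config.max_sources > 1
                                        and n_dominant <= 1))
    return net, filters, csd


def extract_source_timeseries(segment: EEGSegment, filters: SpatialFilter,
                              node_indices, band=None,
                              joint_nulling: bool = True) -> np.ndarray:
    """Source waveforms: unit-gain spatial filters applied to the EEG.

    Returns (n_nodes, n_samples), zero-mean.  With ``joint_nulling`` the
    weights are the jointly constrained minimum-variance solution over the
    nodes' dominant-orientation topographies (W [l_1 .. l_k] = I), which
    zeroes the cross-talk between the extracted series — essential before
    directed-connectivity modelling, where leakage of one source into
    another's series masquerades as (often reversed) causality.  Otherwise
    each node's own reduced filter is used.

    With ``band`` given, a zero-phase fourth-order Butterworth band-pass is
    applied first; leave it ``None`` when the series feed causal (MVAR/RPDC)
    modelling — filtering, and in particular zero-phase filtering, erases
    the lagged structure that directed-influence measures rest on, so the
    band is then expressed only through the frequencies at which the spectra
    are evaluated.
    """
    from scipy import signal as sps

    data = segment.data - segment.data.mean(axis=0, keepdims=True)
    if band is not None:
        f_lo, f_hi = (band.f_lo, band.f_hi) if hasattr(band, "f_lo") else band
        nyq = segment.fs / 2.0
        if not 0 < f_lo < f_hi < nyq:
            raise ValueError(
                f"band ({f_lo}, {f_hi}) Hz is unstable/undefined at "
                f"fs={segment.fs} Hz")
        sos = sps.butter(4, [f_lo / nyq, f_hi / nyq], btype="bandpass",
                         output="sos")
        if not np.allclose(data, 0.0):
            data = sps.sosfiltfilt(sos, data, axis=1)
    nodes = list(node_indices)
    if joint_nulling and len(nodes) > 1:
        C = filters.csd_matrix.real
        Cr = C + filters.alpha * np.mean(np.diag(C)) * np.eye(C.shape[0])
        Ci = np.linalg.inv(Cr)
        # per-node minimum-variance weights with unit gain on the node's
        # topography and explicit nulls on the *neighbourhood* lead-field
        # subspace of every other node, so cross-talk stays suppressed even
        # when an accepted node is off the true source by a voxel
        rows = []
        for i, ni in enumerate(nodes):
            cols = [filters.node_topography(ni)[:, None]]
            for j, nj in enumerate(nodes):
                if j != i:
                    cols.append(_neighborhood_basis(filters.leadfield, nj))
            G = np.concatenate(cols, axis=1)
            e = np.zeros(G.shape[1])
            e[0] = 1.0
            w = Ci @ G @ np.linalg.solve(G.T @ Ci @ G, e)
            rows.append(w)
        W = np.stack(rows)
    else:
        W = filters.reduced[nodes]
    out = W @ data
    return out - out.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def map_to_nifti(values: np.ndarray, leadfield: LeadField, path) -> None:
    """Write a voxel map as a NIfTI volume on the source grid (mm affine)."""
    import nibabel as nib

    grid = leadfield.grid
    ijk = grid.ijk - grid.ijk.min(axis=0)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vol[tuple(ijk.T)] = values
    vox_mm = grid.voxel_size * 1000.0
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    affine[:3, 3] = grid.ijk.min(axis=0) * vox_mm
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def map_to_csv(values: np.ndarray, leadfield: LeadField, path,
               threshold: np.ndarray | None = None) -> None:
    import pandas as pd

    grid = leadfield.grid
    df = pd.DataFrame({
        "x_m": grid.nodes[:, 0], "y_m": grid.nodes[:, 1],
        "z_m": grid.nodes[:, 2], "value": values,
    })
    if threshold is not None:
        df["threshold"] = threshold
    df.to_csv(path, index=False)


def network_to_json(net: CoherentNetwork, path=None) -> str:
    payload = {
        "weak_primary": net.weak_primary,
        "nodes": [
            {
                "index": int(idx),
                "coordinates_m": [float(v) for v in net.coordinates[i]],
                "statistic": net.statistics[i],
                "threshold": net.thresholds[i],
                "map": (net.source_maps[i] if isinstance(net.source_maps[i], str)
                        else list(net.source_maps[i])),
            }
            for i, idx in enumerate(net.node_indices)
        ],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
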