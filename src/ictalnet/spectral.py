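"""Segment selection, leading-frequency identification, and cross-spectra.

The analysis frequency band of a seizure is taken from the global field
power (GFP) spectrum of the selected segment: the frequency with maximal
across-channel power is the leading frequency.  Cross-spectral densities are
Welch-averaged with a Hann taper and feed the frequency-domain beamformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGSegment",
    "BandSelection",
    "CrossSpectrum",
    "select_onset_segment",
    "select_middle_segment",
    "leading_frequency_band",
    "estimate_csd",
    "band_average_csd",
    "compare_band_selections",
]

# search range (Hz) for the leading frequency: excludes DC drift and line noise
GFP_SEARCH_RANGE = (0.5, 45.0)
SHORT_SEIZURE_S = 3.0


@dataclass
class EEGSegment:
    """A channels x samples chunk of EEG (microvolts) with its clock context."""

    data: np.ndarray
    fs: float
    montage: object = None          # ElectrodeMontage or None
    t0: float = 0.0                 # start time on the recording clock (s)
    phase_label: str = "other"      # onset | middle | baseline | other

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.montage is not None and len(self.montage) != self.data.shape[0]:
            raise ValueError("channel count does not match montage")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def slice_samples(self, start: int, stop: int, phase_label: str = "other"):
        if start < 0 or stop > self.n_samples:
            raise ValueError(
                f"requested samples [{start}, {stop}) exceed recording "
                f"bounds [0, {self.n_samples})"
            )
        return EEGSegment(self.data[:, start:stop], self.fs, self.montage,
                          self.t0 + start / self.fs, phase_label)


@dataclass(frozen=True)
class BandSelection:
    """Analysis band around the leading (GFP-maximal) frequency."""

    f_lo: float
    f_hi: float
    leading_frequency: float
    gfp_frequencies: np.ndarray = None
    gfp_spectrum: np.ndarray = None

    def __post_init__(self):
        if not (0 < self.f_lo <= self.leading_frequency <= self.f_hi):
            raise ValueError("band must satisfy 0 < f_lo <= leading <= f_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


@dataclass
class CrossSpectrum:
    """Hermitian channel x channel cross-spectral density per frequency bin."""

    frequencies: np.ndarray   # (F,)
    csd: np.ndarray           # (F, n, n) complex
    n_segments_averaged: int
    taper: str = "hann"

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        self.csd = np.asarray(self.csd, complex)
        herm = np.abs(self.csd - np.conj(np.swapaxes(self.csd, 1, 2)))
        scale = max(np.abs(self.csd).max(), 1e-300)
        if herm.max() > 1e-10 * scale:
            raise ValueError("cross-spectral matrices are not Hermitian")
        diags = np.diagonal(self.csd, axis1=1, axis2=2)
        if np.any(diags.real < -1e-12 * scale):
            raise ValueError("auto-spectra must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]


def _window_samples(t_start: float, t_stop: float, fs: float) -> tuple:
    """Half-open sample interval [floor(t_start*fs), floor(t_stop*fs))."""
    return int(np.floor(t_start * fs)), int(np.floor(t_stop * fs))


def select_onset_segment(recording: EEGSegment, t_onset: float,
                         seizure_duration: float) -> EEGSegment:
    """Cut the seizure-onset analysis window.

    The window spans 5 s before to 5 s after onset; for very short seizures
    (< 3 s) a 1 s window centred on the onset is used instead.
    """
    if seizure_duration < SHORT_SEIZURE_S:
        start, stop = _window_samples(t_onset - 0.5, t_onset + 0.5,
                                      recording.fs)
    else:
        start, stop = _window_samples(t_onset - 5.0, t_onset + 5.0,
                                      recording.fs)
    return recording.slice_samples(start, stop, phase_label="onset")


def select_middle_segment(recording: EEGSegment, t_onset: float,
                          t_offset: float) -> EEGSegment:
    """Cut the mid-seizure analysis window.

    A 10 s window centred on the midpoint between onset and offset (1 s for
    seizures shorter than 3 s).  Overlap with the onset window is an error:
    the two analysis segments must be disjoint.
    """
    if t_offset <= t_onset:
        raise ValueError("t_offset must exceed t_onset")
    duration = t_offset - t_onset
    center = 0.5 * (t_onset + t_offset)
    half = 0.5 if duration < SHORT_SEIZURE_S else 5.0
    start, stop = _window_samples(center - half, center + half, recording.fs)
    onset_seg = select_onset_segment(recording, t_onset, duration)
    o_start = int(np.floor(onset_seg.t0 * recording.fs))
    o_stop = o_start + onset_seg.n_samples
    overlap = min(stop, o_stop) - max(start, o_start)
    if overlap > 0 and duration < SHORT_SEIZURE_S:
        # the 1 s windows of a very short seizure cannot both be centred;
        # slide the middle window right so the segments stay disjoint
        start, stop = o_stop, o_stop + (stop - start)
        overlap = 0
    if overlap > 0:
        raise ValueError(
            f"middle window samples [{start}, {stop}) overlap the onset "
            f"window [{o_start}, {o_stop}) by {overlap} samples"
        )
    return recording.slice_samples(start, stop, phase_label="middle")


def _gfp_spectrum(segment: EEGSegment, window_s: float = 1.0,
                  overlap: float = 0.5):
    """Across-channel sum of Welch power spectra of average-referenced data."""
    data = segment.data - segment.data.mean(axis=0, keepdims=True)
    nperseg = min(int(round(window_s * segment.fs)), segment.n_samples)
    freqs, psd = sps.welch(data, fs=segment.fs, window="hann",
                           nperseg=nperseg,
                           noverlap=int(nperseg * overlap), axis=-1)
    return freqs, psd.sum(axis=0)


def leading_frequency_band(segment: EEGSegment, band_half_width: float = 2.0,
                           search_range: tuple = GFP_SEARCH_RANGE,
                           window_s: float = 1.0) -> BandSelection:
    """Band around the frequency of maximal global field power.

    The GFP spectrum is the across-channel sum of Welch power estimates of
    the average-referenced segment; the leading frequency is its argmax over
    ``search_range`` and the band extends ``band_half_width`` Hz either side,
    clipped to the search range.
    """
    if segment.duration < 1.0:
        raise ValueError("segment must be at least 1 s long")
    if np.allclose(segment.data, 0.0):
        raise ValueError("segment is identically zero; no leading frequency")
    freqs, gfp = _gfp_spectrum(segment, window_s=window_s)
    lo, hi = search_range
    mask = (freqs >= lo) & (freqs <= min(hi, segment.fs / 2 - 1e-9))
    if not mask.any():
        raise ValueError("no frequency bins inside the search range")
    leading = float(freqs[mask][np.argmax(gfp[mask])])
    return BandSelection(
        f_lo=max(lo, leading - band_half_width),
        f_hi=min(hi, leading + band_half_width),
        leading_frequency=leading,
        gfp_frequencies=freqs, gfp_spectrum=gfp,
    )


def estimate_csd(segment: EEGSegment, band, window_s: float = 1.0,
                 overlap: float = 0.5, demean: bool = True) -> CrossSpectrum:
    """Welch cross-spectral density on the bins inside ``band``.

    Hann-tapered windows of ``window_s`` seconds with fractional ``overlap``
    are Fourier transformed; the CSD at each retained bin is the average of
    the outer products of the windowed Fourier coefficients (density
    scaling), Hermitian by construction.

    ``band`` is a BandSelection or an ``(f_lo, f_hi)`` pair.
    """
    f_lo, f_hi = (band.f_lo, band.f_hi) if hasattr(band, "f_lo") else band
    fs = segment.fs
    if not 0 < f_lo <= f_hi < fs / 2:
        raise ValueError("band must lie inside (0, fs/2)")
    nperseg = int(round(window_s * fs))
    step = nperseg - int(nperseg * overlap)
    if segment.n_samples < nperseg + step:
        raise ValueError("segment too short: need at least 2 Welch windows")
    data = segment.data
    if demean:
        data = data - data.mean(axis=1, keepdims=True)
    starts = np.arange(0, segment.n_samples - nperseg + 1, step)
    win = sps.get_window("hann", nperseg)
    scale = 1.0 / (fs * (win ** 2).sum())
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    sel = np.flatnonzero((freqs >= f_lo) & (freqs <= f_hi))
    if sel.size == 0:
        raise ValueError(
            f"no frequency bins inside [{f_lo}, {f_hi}] Hz at resolution "
            f"{fs / nperseg:.3g} Hz; use a longer analysis window"
        )
    n = segment.n_channels
    acc = np.zeros((sel.size, n, n), complex)
    for s0 in starts:
        chunk = data[:, s0:s0 + nperseg] * win
        spec = np.fft.rfft(chunk, axis=1)[:, sel]          # (n, F)
        acc += np.einsum("af,bf->fab", spec, np.conj(spec))
    acc *= scale / len(starts)
    # one-sided density: double non-DC/non-Nyquist bins, as scipy does
    full_bins = (freqs[sel] > 0) & (freqs[sel] < fs / 2)
    acc[full_bins] *= 2.0
    acc = 0.5 * (acc + np.conj(np.swapaxes(acc, 1, 2)))    # enforce symmetry
    return CrossSpectrum(frequencies=freqs[sel], csd=acc,
                         n_segments_averaged=len(starts))


def band_average_csd(csd: CrossSpectrum) -> np.ndarray:
    """Average the CSD over its frequency bins to one Hermitian matrix."""
    C = csd.csd.mean(axis=0)
    return 0.5 * (C + C.conj().T)


def compare_band_selections(selections) -> dict:
    """Consistency summary of leading frequencies across several recordings.

    Helper mirroring the clinical practice of confirming that the leading
    frequency is stable across evaluated seizures before fixing the band.
    """
    leads = np.array([s.leading_frequency for s in selections], float)
    return {
        "leading_frequencies": leads.tolist(),
        "spread_hz": float(leads.max() - leads.min()) if leads.size else 0.0,
        "consistent_within_2hz": bool(leads.size and
                                      leads.max() - leads.min() <= 2.0),
    }
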