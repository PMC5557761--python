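"""Time-resolved spectral analysis of multichannel EEG.

Pipeline stage 1: a recording (channels x samples) is converted into a
short-time Fourier tensor, then into per-window cross-spectral density
(CSD) matrices, and finally into the non-negative 3-way amplitude
spectral density (ASD) tensor (space x frequency x time) that the
PARAFAC stages decompose.

Conventions
-----------
* Hann tapers use the periodic convention, so the mean of the squared
  taper values is exactly 3/8 = 0.375 and the one-sided cross-spectrum
  normalization is ``2 / (0.375 * df)``.
* Windows are laid out independently inside each concatenated segment,
  starting at the segment's first sample; no window straddles a
  segment boundary.
* Frequency band endpoints are inclusive: 5-15 Hz at df = 0.2 Hz gives
  51 bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "StftTensor",
    "CrossSpectrumSet",
    "SpectralTensor",
    "stft",
    "cross_spectral_density",
    "amplitude_spectrum",
    "hann_taper",
]


@dataclass
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Samples per second.
    channel_names : list of str
    channel_positions : ndarray, shape (n_channels, 3)
        Meters, head frame: origin at sphere center, +x right,
        +y anterior, +z superior.
    segment_boundaries : ndarray of int
        Sample indices of the interior edges between concatenated
        segments (e.g. the four eyes-closed periods of one session).
        May be empty for a single contiguous recording.
    reference : str
        Reference tag; the pipeline expects "average".
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray
    segment_boundaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    reference: str = "average"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.channel_positions.shape != (self.n_channels, 3):
            raise ValueError("channel_positions must be (n_channels, 3)")
        b = np.asarray(self.segment_boundaries, dtype=int)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= self.n_samples):
            raise ValueError("segment boundaries must be strictly increasing, inside (0, n_samples)")
        self.segment_boundaries = b

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def segments(self) -> list[tuple[int, int]]:
        """(start, stop) sample index pairs of the concatenated segments."""
        edges = np.concatenate(([0], self.segment_boundaries, [self.n_samples]))
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def apply_average_reference(self) -> "EEGRecording":
        """Return a copy re-referenced to the common average."""
        return EEGRecording(
            data=self.data - self.data.mean(axis=0, keepdims=True),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions.copy(),
            segment_boundaries=self.segment_boundaries.copy(),
            reference="average",
        )


@dataclass
class StftTensor:
    """Complex STFT values, channels x frequencies x windows."""

    values: np.ndarray
    freqs: np.ndarray
    window_length_samples: int
    window_centers: np.ndarray
    sampling_rate: float
    taper: str = "hann"
    overlap: float = 0.5

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if len(self.freqs) > 1 else np.nan

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]

    def taper_samples(self) -> np.ndarray:
        if self.taper != "hann":
            raise ValueError(f"unknown taper {self.taper!r}")
        return hann_taper(self.window_length_samples)


@dataclass
class CrossSpectrumSet:
    """Per-(frequency, window) Hermitian cross-spectral density matrices.

    ``values`` has shape (n_freqs, n_windows, n_channels, n_channels)
    in microvolts^2 per Hz; the diagonal is the per-channel one-sided
    power spectral density.
    """

    values: np.ndarray
    freqs: np.ndarray
    window_centers: np.ndarray
    normalization: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


@dataclass
class SpectralTensor:
    """Non-negative 3-way amplitude-spectrum tensor, space x frequency x time.

    ``space_kind`` is "sensor" for channel-space ASD and "source" for
    the ASD of LORETA source estimates. Sensor units are microvolts per
    sqrt(Hz).
    """

    values: np.ndarray
    freqs: np.ndarray
    window_centers: np.ndarray
    space_kind: str = "sensor"
    units: str = "uV/sqrt(Hz)"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SpectralTensor values must be 3-way (space x freq x time)")
        if self.values.shape[1] != len(self.freqs):
            raise ValueError("frequency axis inconsistent with freqs metadata")
        if self.values.shape[2] != len(self.window_centers):
            raise ValueError("time axis inconsistent with window_centers metadata")
        if self.values.min() < 0:
            raise ValueError("SpectralTensor values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def hann_taper(length: int) -> np.ndarray:
    """Periodic Hann window of the given length.

    The periodic convention, ``0.5 * (1 - cos(2*pi*n/L))``, makes the
    mean of the squared taper exactly 0.375 for any length, which is
    the constant entering the cross-spectrum normalization.
    """
    if length < 2:
        raise ValueError("taper length must be >= 2")
    n = np.arange(length)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / length))


def stft(
    recording: EEGRecording,
    window_seconds: float = 5.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (5.0, 15.0),
    reject_amplitude: float | None = None,
) -> StftTensor:
    """Segment-respecting short-time Fourier transform of a recording.

    Each concatenated segment is covered by Hann-tapered windows of
    ``window_seconds`` with the given fractional overlap, starting at
    the segment's first sample; trailing samples that do not fill a
    window are dropped, and segments shorter than one window are
    skipped with a warning. DFT values are scaled by 1/L and restricted
    to frequency bins inside ``band`` (endpoints inclusive); the
    frequency resolution is 1/window_seconds.

    Parameters
    ----------
    reject_amplitude : float, optional
        If given, windows containing any sample whose absolute value
        exceeds this threshold (microvolts) are dropped. This is a
        crude stand-in for artifact-segment screening.
    """
    fs = recording.sampling_rate
    L_float = fs * window_seconds
    L = int(round(L_float))
    if abs(L_float - L) > 1e-9:
        raise ValueError("sampling_rate * window_seconds must be an integer number of samples")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    f_lo, f_hi = band
    nyquist = fs / 2.0
    if f_lo < 0 or f_hi > nyquist or f_lo >= f_hi:
        raise ValueError(f"band {band} outside [0, Nyquist={nyquist}]")

    hop = int(round(L * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop < 1 sample")

    taper = hann_taper(L)
    all_freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    keep = (all_freqs >= f_lo - 1e-9) & (all_freqs <= f_hi + 1e-9)
    freqs = all_freqs[keep]

    starts: list[int] = []
    for seg_start, seg_stop in recording.segments():
        if seg_stop - seg_start < L:
            warnings.warn(
                f"segment [{seg_start}, {seg_stop}) shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        s = seg_start
        while s + L <= seg_stop:
            starts.append(s)
            s += hop
    if not starts:
        raise ValueError("no segment long enough for a single STFT window")

    if reject_amplitude is not None:
        kept_starts = [
            s for s in starts if np.abs(recording.data[:, s : s + L]).max() <= reject_amplitude
        ]
        n_dropped = len(starts) - len(kept_starts)
        if n_dropped:
            logger.info("amplitude screen dropped %d of %d windows", n_dropped, len(starts))
        if not kept_starts:
            raise ValueError("amplitude screening removed every window")
        starts = kept_starts

    starts_arr = np.asarray(starts, dtype=int)
    # (n_windows, n_channels, L) stack of tapered windows
    segs = np.stack([recording.data[:, s : s + L] for s in starts_arr], axis=0)
    spec = np.fft.rfft(segs * taper[None, None, :], axis=2)[:, :, keep] / L
    # absolute-time phase reference: each window's DFT carries the phase
    # factor of its start sample so phases are comparable across windows
    phase = np.exp(-2j * np.pi * np.outer(starts_arr / fs, freqs))
    spec = spec * phase[:, None, :]

    values = np.transpose(spec, (1, 2, 0))  # channels x freqs x windows
    centers = starts_arr + L // 2
    return StftTensor(
        values=values,
        freqs=freqs,
        window_length_samples=L,
        window_centers=centers,
        sampling_rate=fs,
        taper="hann",
        overlap=overlap,
    )


def cross_spectral_density(stft_tensor: StftTensor) -> CrossSpectrumSet:
    """One-sided cross-spectral density matrices from an STFT tensor.

    For each (frequency, window) pair the CSD is the outer product of
    the channel vector with its conjugate, scaled by
    ``2 / (mean(W^2) * df)`` where W are the actual taper samples
    (0.375 for the periodic Hann taper). The factor 2 folds negative
    frequencies into the one-sided spectrum; the analysis band excludes
    DC and Nyquist so it applies uniformly.
    """
    if stft_tensor.n_windows == 0:
        raise ValueError("empty STFT tensor")
    taper = stft_tensor.taper_samples()
    mean_sq = float(np.mean(taper**2))
    norm = 2.0 / (mean_sq * stft_tensor.df)
    phi = stft_tensor.values  # channels x freqs x windows
    values = norm * np.einsum("mft,nft->ftmn", phi, np.conj(phi))
    return CrossSpectrumSet(
        values=values,
        freqs=stft_tensor.freqs.copy(),
        window_centers=stft_tensor.window_centers.copy(),
        normalization=norm,
    )


def amplitude_spectrum(csd: CrossSpectrumSet) -> SpectralTensor:
    """Amplitude spectral density: square root of the CSD diagonal.

    Returns a (channels x frequencies x windows) non-negative tensor.
    Diagonal entries slightly negative from round-off (>= -1e-9) are
    clamped to zero; anything more negative raises, since the diagonal
    of a Hermitian outer-product form must be non-negative.
    """
    diag = np.diagonal(csd.values, axis1=2, axis2=3)  # (f, t, ch)
    if np.abs(diag.imag).max(initial=0.0) > 1e-9 * max(diag.real.max(initial=0.0), 1.0):
        raise ValueError("CSD diagonal has a non-negligible imaginary part")
    diag = diag.real
    if diag.min(initial=0.0) < -1e-9:
        raise ValueError(f"negative CSD diagonal ({diag.min():.3e}): inconsistent input")
    values = np.sqrt(np.clip(diag, 0.0, None))
    return SpectralTensor(
        values=np.transpose(values, (2, 0, 1)),
        freqs=csd.freqs.copy(),
        window_centers=csd.window_centers.copy(),
        space_kind="sensor",
        units="uV/sqrt(Hz)",
    )


def amplitude_spectrum_from_stft(stft_tensor: StftTensor) -> SpectralTensor:
    """Sensor ASD computed directly from the STFT, bypassing the full CSD.

    Identical to ``amplitude_spectrum(cross_spectral_density(stft))``
    because the CSD diagonal is ``norm * |phi|^2``; avoids materializing
    n_channels^2 matrices for long recordings.
    """
    taper = stft_tensor.taper_samples()
    norm = 2.0 / (float(np.mean(taper**2)) * stft_tensor.df)
    values = np.sqrt(norm) * np.abs(stft_tensor.values)
    return SpectralTensor(
        values=values,
        freqs=stft_tensor.freqs.copy(),
        window_centers=stft_tensor.window_centers.copy(),
        space_kind="sensor",
        units="uV/sqrt(Hz)",
    )
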