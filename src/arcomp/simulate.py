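"""Synthetic resting-state EEG with a known alpha-component structure.

Every downstream stage (spectral analysis, source imaging, the
two-stage PARAFAC, group statistics) is tested against recordings
generated here, because no public recordings with known component
structure exist. A recording is a sum of

* one oscillatory cortical patch per alpha component: band-pass
  filtered Gaussian noise (Gaussian spectral profile of configurable
  peak frequency and FWHM) modulated by an independently fluctuating
  non-negative envelope (rectified low-pass Gaussian noise), placed on
  a compact Gaussian patch of the source grid and projected through the
  lead field;
* a 1/f background from many weak diffuse sources, so the background is
  spatially correlated like real EEG;
* white sensor noise.

The returned :class:`GroundTruth` holds the frequency, source-space,
channel-space and temporal profile of each patch on the analysis grids,
which is what recovered PARAFAC loadings are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .headmodel import LeadFieldModel
from .spectral import EEGRecording, SpectralTensor

__all__ = [
    "SourcePatchSpec",
    "NoiseSpec",
    "SimulationScenario",
    "GroundTruth",
    "simulate_recording",
    "simulate_tensor",
    "default_two_arc_scenario",
    "single_arc_scenario",
    "artifact_scenario",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SourcePatchSpec:
    """One oscillatory cortical patch.

    ``center`` must lie on the source shell; ``radius`` is the Gaussian
    spatial extent (m); the spectral profile is Gaussian around
    ``peak_frequency`` with FWHM ``bandwidth``; the amplitude envelope
    has the given mean (microvolts at the patch center) and fluctuates
    on ``envelope_timescale`` seconds.
    """

    center: tuple[float, float, float]
    radius: float
    peak_frequency: float
    bandwidth: float
    envelope_mean: float
    envelope_timescale: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")
        if self.envelope_mean <= 0:
            raise ValueError("envelope mean must be positive")
        if self.peak_frequency <= 0 or self.bandwidth <= 0:
            raise ValueError("peak frequency and bandwidth must be positive")


@dataclass
class NoiseSpec:
    """Background and sensor noise levels.

    ``background_exponent`` is the 1/f power-law exponent of the
    diffuse background sources; ``background_amplitude`` their RMS
    source amplitude (microvolts each); ``sensor_noise_sd`` the white
    sensor noise standard deviation (microvolts).
    """

    background_exponent: float = 1.0
    background_amplitude: float = 2.0
    n_background_sources: int = 100
    sensor_noise_sd: float = 1.5


@dataclass
class SimulationScenario:
    patches: list[SourcePatchSpec]
    n_channels: int = 62
    sampling_rate: float = 500.0
    duration: float = 240.0
    segment_boundaries: tuple[float, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    store_waveforms: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        b = np.asarray(self.segment_boundaries, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= self.duration):
            raise ValueError("segment boundaries must be increasing, inside (0, duration)")


@dataclass
class GroundTruth:
    """Known per-patch profiles on the analysis grids.

    ``true_spatial_profiles`` are source-grid weights (max 1 at the
    patch center); ``true_channel_profiles`` equal the absolute value
    of the lead field applied to the source profile;
    ``true_temporal_profiles`` are the per-window RMS of each patch's
    envelope at the STFT window layout. ``loadings`` (simulate_tensor
    only) holds the exact drawn factor matrices.
    """

    labels: list[str]
    true_frequency_profiles: np.ndarray
    true_spatial_profiles: np.ndarray
    true_channel_profiles: np.ndarray | None
    true_temporal_profiles: np.ndarray
    freqs: np.ndarray
    window_centers: np.ndarray
    loadings: dict[str, np.ndarray] | None = None
    source_waveforms: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("true_frequency_profiles", "true_spatial_profiles", "true_temporal_profiles"):
            arr = getattr(self, name)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{name} must be non-negative")


def _window_layout(
    n_samples: int,
    boundaries: np.ndarray,
    fs: float,
    window_seconds: float,
    overlap: float,
) -> tuple[np.ndarray, int]:
    """Window start indices matching the STFT layout, and the length L."""
    L = int(round(fs * window_seconds))
    hop = int(round(L * (1.0 - overlap)))
    edges = np.concatenate(([0], boundaries, [n_samples]))
    starts = []
    for a, b in zip(edges[:-1], edges[1:]):
        s = int(a)
        while s + L <= b:
            starts.append(s)
            s += hop
    return np.asarray(starts, dtype=int), L


def _bandpassed_noise(
    rng: np.random.Generator, n: int, fs: float, f0: float, fwhm: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise with a Gaussian amplitude spectrum."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sd = fwhm / _FWHM_TO_SD
    mask = np.exp(-0.5 * ((freqs - f0) / sd) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * mask, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _envelope(rng: np.random.Generator, n: int, fs: float, timescale: float, mean: float) -> np.ndarray:
    """Rectified low-pass Gaussian noise, scaled to the requested mean."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    fc = 1.0 / timescale
    mask = np.exp(-0.5 * (freqs / fc) ** 2)
    env = np.abs(np.fft.irfft(np.fft.rfft(white) * mask, n))
    m = env.mean()
    return env * (mean / m) if m > 0 else np.full(n, mean)


def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(coeffs, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_recording(
    scenario: SimulationScenario,
    leadfield: LeadFieldModel,
    window_seconds: float = 5.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (5.0, 15.0),
) -> tuple[EEGRecording, GroundTruth]:
    """Generate a recording and its ground truth from a scenario.

    The STFT parameters are only used to lay out the frequency grid and
    window centers on which the ground-truth profiles are tabulated;
    they should match the downstream analysis settings.
    """
    if leadfield.n_channels != scenario.n_channels:
        raise ValueError("lead field channel count does not match the scenario")
    fs = scenario.sampling_rate
    n = int(round(scenario.duration * fs))
    L = int(round(fs * window_seconds))
    if n < L:
        raise ValueError("duration shorter than one STFT window")
    grid = leadfield.grid
    shell_r = grid.radius
    rng = np.random.default_rng(scenario.seed)

    boundaries = np.round(np.asarray(scenario.segment_boundaries) * fs).astype(int)
    starts, L = _window_layout(n, boundaries, fs, window_seconds, overlap)
    window_centers = starts + L // 2
    all_freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    freqs = all_freqs[(all_freqs >= band[0] - 1e-9) & (all_freqs <= band[1] + 1e-9)]

    data = np.zeros((scenario.n_channels, n))
    n_p = len(scenario.patches)
    freq_profiles = np.zeros((n_p, len(freqs)))
    spatial_profiles = np.zeros((n_p, grid.n_sources))
    channel_profiles = np.zeros((n_p, scenario.n_channels))
    temporal_profiles = np.zeros((n_p, len(starts)))
    waveforms = np.zeros((n_p, n)) if scenario.store_waveforms else None
    labels = []

    for p, patch in enumerate(scenario.patches):
        center = np.asarray(patch.center, dtype=float)
        if abs(np.linalg.norm(center) - shell_r) > 0.02 * shell_r:
            raise ValueError(
                f"patch {patch.label!r} center is off the source shell "
                f"(|c|={np.linalg.norm(center):.4f} m, shell={shell_r:.4f} m)"
            )
        osc = _bandpassed_noise(rng, n, fs, patch.peak_frequency, patch.bandwidth)
        env = _envelope(rng, n, fs, patch.envelope_timescale, patch.envelope_mean)
        x = env * osc  # microvolts at the patch center
        d = np.linalg.norm(grid.coords - center, axis=1)
        w = np.exp(-0.5 * (d / patch.radius) ** 2)
        topo = leadfield.gain @ w
        data += np.outer(topo, x)
        if waveforms is not None:
            waveforms[p] = x

        sd = patch.bandwidth / _FWHM_TO_SD
        fp = np.exp(-0.5 * ((freqs - patch.peak_frequency) / sd) ** 2)
        freq_profiles[p] = fp / fp.max() if fp.max() > 0 else fp
        spatial_profiles[p] = w
        channel_profiles[p] = np.abs(topo)
        seg_rms = np.sqrt(
            np.mean(np.stack([env[s : s + L] for s in starts]) ** 2, axis=1)
        )
        temporal_profiles[p] = seg_rms
        labels.append(patch.label or f"patch{p + 1}")

    noise = scenario.noise
    if noise.n_background_sources > 0 and noise.background_amplitude > 0:
        # on grids smaller than the requested count, every point hosts one
        n_bg = min(noise.n_background_sources, grid.n_sources)
        idx = rng.choice(grid.n_sources, size=n_bg, replace=False)
        bg = np.stack(
            [
                noise.background_amplitude
                * _one_over_f_noise(rng, n, fs, noise.background_exponent)
                for _ in idx
            ]
        )
        data += leadfield.gain[:, idx] @ bg
    if noise.sensor_noise_sd > 0:
        data += noise.sensor_noise_sd * rng.standard_normal(data.shape)

    names = leadfield.channel_names or [f"E{k + 1:02d}" for k in range(scenario.n_channels)]
    recording = EEGRecording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        channel_positions=leadfield.channel_positions.copy(),
        segment_boundaries=boundaries,
        reference="average",
    )
    truth = GroundTruth(
        labels=labels,
        true_frequency_profiles=freq_profiles,
        true_spatial_profiles=spatial_profiles,
        true_channel_profiles=channel_profiles,
        true_temporal_profiles=temporal_profiles,
        freqs=freqs,
        window_centers=window_centers,
        source_waveforms=waveforms,
    )
    return recording, truth


def simulate_tensor(
    K: int,
    dims: tuple[int, int, int],
    noise_sd: float,
    seed: int | None = None,
) -> tuple[SpectralTensor, GroundTruth]:
    """Exact K-component trilinear tensor plus optional Gaussian noise.

    ``dims`` is (n_space, n_freq, n_time); loadings are drawn uniform
    non-negative and stored exactly in the ground truth, so recovery
    can be checked component by component.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if min(dims) < K:
        raise ValueError("every dimension must be >= K")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_space, n_freq, n_time = dims
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, 1.0, size=(n_space, K))
    F = rng.uniform(0.0, 1.0, size=(n_freq, K))
    T = rng.uniform(0.0, 1.0, size=(n_time, K))
    values = np.einsum("sk,fk,tk->sft", S, F, T)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None)
    tensor = SpectralTensor(
        values=values,
        freqs=np.arange(n_freq, dtype=float),
        window_centers=np.arange(n_time),
        space_kind="sensor",
        units="a.u.",
    )
    truth = GroundTruth(
        labels=[f"component{k + 1}" for k in range(K)],
        true_frequency_profiles=F.T.copy(),
        true_spatial_profiles=S.T.copy(),
        true_channel_profiles=None,
        true_temporal_profiles=T.T.copy(),
        freqs=tensor.freqs.copy(),
        window_centers=tensor.window_centers.copy(),
        loadings={"space": S, "frequency": F, "time": T},
    )
    return tensor, truth


def _shell_point(direction: tuple[float, float, float], radius: float) -> tuple[float, float, float]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d) * radius
    return (float(d[0]), float(d[1]), float(d[2]))


def default_two_arc_scenario(
    seed: int = 0,
    duration: float = 240.0,
    shell_radius: float = 0.92 * 0.087,
    store_waveforms: bool = False,
) -> SimulationScenario:
    """Two-component study conditions: a 10.4 Hz occipito-parietal patch
    and a 9.4 Hz left occipito-temporal patch with independent
    envelopes, four equal eyes-closed segments, 62 channels at 500 Hz.

    Amplitudes are set so the posterior alpha peak stands 3-10x above
    the 1/f background, i.e. recoverable but not trivial.
    """
    patches = [
        SourcePatchSpec(
            center=_shell_point((0.0, -0.55, 0.83), shell_radius),
            radius=0.025,
            peak_frequency=10.4,
            bandwidth=1.0,
            envelope_mean=0.6,
            envelope_timescale=8.0,
            label="ARC1-like",
        ),
        SourcePatchSpec(
            center=_shell_point((-0.60, -0.75, 0.20), shell_radius),
            radius=0.022,
            peak_frequency=9.4,
            bandwidth=1.2,
            envelope_mean=0.5,
            envelope_timescale=8.0,
            label="ARC2-like",
        ),
    ]
    n_seg = 4
    return SimulationScenario(
        patches=patches,
        n_channels=62,
        sampling_rate=500.0,
        duration=duration,
        segment_boundaries=tuple(duration * k / n_seg for k in range(1, n_seg)),
        noise=NoiseSpec(),
        seed=seed,
        store_waveforms=store_waveforms,
    )


def single_arc_scenario(seed: int = 0, duration: float = 240.0) -> SimulationScenario:
    """One occipito-parietal 10.2 Hz component only."""
    sc = default_two_arc_scenario(seed=seed, duration=duration)
    sc.patches = [sc.patches[0]]
    sc.patches[0].peak_frequency = 10.2
    return sc


def artifact_scenario(seed: int = 0, duration: float = 240.0) -> SimulationScenario:
    """Two alpha patches plus a frontal broadband patch emulating an
    eye/muscle artifact, used to exercise noise-component rejection."""
    sc = default_two_arc_scenario(seed=seed, duration=duration)
    shell_radius = np.linalg.norm(sc.patches[0].center)
    sc.patches.append(
        SourcePatchSpec(
            center=_shell_point((0.0, 0.95, 0.30), shell_radius),
            radius=0.03,
            peak_frequency=10.0,
            bandwidth=14.0,  # spectrally flat across the analysis band
            envelope_mean=0.7,
            envelope_timescale=6.0,
            label="frontal-artifact",
        )
    )
    return sc


def pooled_posterior_spectrum(
    recording: EEGRecording,
    window_seconds: float = 5.0,
    band: tuple[float, float] = (5.0, 15.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude spectrum over posterior channels (diagnostic helper).

    Returns (freqs, mean ASD over posterior channels and windows).
    """
    from .spectral import amplitude_spectrum_from_stft, stft

    asd = amplitude_spectrum_from_stft(
        stft(recording, window_seconds=window_seconds, band=band)
    )
    posterior = recording.channel_positions[:, 1] < 0
    return asd.freqs, asd.values[posterior].mean(axis=(0, 2))
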