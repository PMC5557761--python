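"""Per-subject two-stage decomposition pipeline.

Stage order: STFT -> cross-spectra -> sensor amplitude-spectrum tensor
-> model-order selection by core consistency -> sensor-space
non-negative PARAFAC -> rejection of noise components (flat spectrum or
non-posterior topography) -> LORETA source amplitude spectrum ->
source-space PARAFAC with the frequency and temporal modes held fixed
at the retained sensor estimates -> labeling of the surviving alpha
components (highest peak frequency = ARC1, lowest = ARC2).

Exposed statsmodels-style: :class:`ArcDecomposition` is built from a
recording and a :class:`~arcomp.config.RunConfig`; ``fit()`` returns an
:class:`ArcDecompositionResults` carrying every intermediate model, the
labeled components, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .headmodel import HeadModel, LeadFieldModel, build_leadfield
from .inverse import InverseOperator, loreta_inverse, source_amplitude_spectrum_from_stft
from .parafac import Parafac, ParafacResults, select_num_components
from .spectral import (
    EEGRecording,
    SpectralTensor,
    amplitude_spectrum,
    cross_spectral_density,
    stft,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArcComponent",
    "ArcDecomposition",
    "ArcDecompositionResults",
    "decompose_subject",
    "reject_noise_components",
    "label_components",
    "spectral_flatness",
]


def spectral_flatness(loading: np.ndarray) -> float:
    """Geometric over arithmetic mean of a non-negative spectral profile.

    1 for a flat profile, near 0 for a single-bin peak. A tiny floor
    (1e-12 of the maximum) keeps the geometric mean defined when bins
    are exactly zero.
    """
    x = np.asarray(loading, dtype=float)
    if x.min() < 0:
        raise ValueError("flatness is defined for non-negative profiles")
    m = x.max()
    if m == 0:
        return 1.0
    x = np.clip(x, 1e-12 * m, None)
    return float(np.exp(np.mean(np.log(x))) / np.mean(x))


@dataclass
class ArcComponent:
    """One labeled alpha-rhythm component.

    All loading vectors are max-normalized (maximum exactly 1).
    ``posterior_fraction`` is the share of spatial loading mass inside
    the posterior mask of the corresponding space.
    """

    label: str
    peak_frequency: float
    frequency_loading: np.ndarray
    sensor_loading: np.ndarray
    source_loading: np.ndarray | None
    temporal_loading: np.ndarray
    spectral_flatness: float
    posterior_fraction: float
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frequency_loading", "sensor_loading", "temporal_loading"):
            v = getattr(self, name)
            if v.max() > 0 and abs(v.max() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be max-normalized")


def _max_normalize(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else v.copy()


def reject_noise_components(
    results: ParafacResults,
    posterior_mask: np.ndarray,
    flatness_max: float = 0.7,
    posterior_min: float = 0.5,
) -> tuple[ParafacResults, pd.DataFrame]:
    """Drop components with flat spectra or non-posterior topography.

    A component is rejected when the spectral flatness of its frequency
    loading exceeds ``flatness_max`` OR when the fraction of its
    spatial loading mass inside ``posterior_mask`` falls below
    ``posterior_min``. Returns the reduced model (components
    re-indexed) and a per-component decision table.
    """
    if posterior_mask.shape[0] != results.B.shape[0]:
        raise ValueError("posterior mask does not match the spatial dimension")
    rows = []
    keep = []
    for k in range(results.K):
        flat = spectral_flatness(results.A[:, k])
        b = results.B[:, k]
        total = b.sum()
        post = float(b[posterior_mask].sum() / total) if total > 0 else 0.0
        rejected = flat > flatness_max or post < posterior_min
        rows.append(
            {
                "component": k + 1,
                "flatness": flat,
                "posterior_fraction": post,
                "rejected": rejected,
            }
        )
        if not rejected:
            keep.append(k)
    table = pd.DataFrame(rows).set_index("component")
    if not keep:
        raise ValueError("all components rejected: decomposition is invalid")
    if len(keep) < results.K:
        logger.info("rejected %d of %d components as noise", results.K - len(keep), results.K)
    return results.subset(keep), table


def label_components(components: list[ArcComponent]) -> list[ArcComponent]:
    """Assign ARC labels by peak frequency.

    Two retained components: higher peak -> ARC1, lower -> ARC2. Three:
    the two higher-frequency ones -> ARC1a / ARC1b (the ARC1 class),
    the lowest -> ARC2. One: "unclassified" (a single component cannot
    be placed in the two-component scheme). More than three: the three
    frequency-ordered labels are assigned and the rest stay
    "unclassified". Ties in peak frequency are broken by larger
    component magnitude.
    """
    if not components:
        raise ValueError("no components to label")
    order = sorted(
        range(len(components)),
        key=lambda i: (-components[i].peak_frequency, -components[i].magnitude),
    )
    n = len(components)
    if n == 1:
        components[0].label = "unclassified"
        return components
    if n == 2:
        names = ["ARC1", "ARC2"]
    else:
        names = ["ARC1a", "ARC1b", "ARC2"] + ["unclassified"] * (n - 3)
    for rank, idx in enumerate(order):
        components[idx].label = names[rank]
    return components


@dataclass
class ArcDecompositionResults:
    """Everything the per-subject pipeline produced."""

    config: RunConfig
    sensor_model: ParafacResults
    sensor_model_full: ParafacResults
    source_model: ParafacResults
    components: list[ArcComponent]
    selection_table: pd.DataFrame
    rejection_table: pd.DataFrame
    sensor_tensor: SpectralTensor
    source_tensor: SpectralTensor
    inverse: InverseOperator
    leadfield: LeadFieldModel
    n_components_selected: int
    window_centers: np.ndarray = field(default_factory=lambda: np.array([]))

    def component_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "peak_frequency_hz": c.peak_frequency,
                "spectral_flatness": c.spectral_flatness,
                "posterior_fraction": c.posterior_fraction,
                "magnitude": c.magnitude,
            }
            for c in self.components
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Alpha-component decomposition",
            "=" * 40,
            f"selected components: {self.n_components_selected} "
            f"(core-consistency threshold {self.config.corcondia_threshold}%)",
            f"retained after noise rejection: {len(self.components)}",
            f"sensor fit: {self.sensor_model_full.fit:.4f}  "
            f"source fit: {self.source_model.fit:.4f}",
            "",
            self.component_table().to_string(index=False),
        ]
        return "\n".join(lines)


class ArcDecomposition:
    """Two-stage alpha-component decomposition of one recording.

    Parameters
    ----------
    recording : EEGRecording
    config : RunConfig, optional
    leadfield : LeadFieldModel, optional
        Reuse a precomputed lead field (must match the recording's
        channel positions); built from the config otherwise.
    """

    def __init__(
        self,
        recording: EEGRecording,
        config: RunConfig | None = None,
        leadfield: LeadFieldModel | None = None,
    ):
        self.recording = recording
        self.config = config or RunConfig()
        if leadfield is None:
            head = HeadModel(self.config.shell_radii, self.config.conductivities)
            leadfield = build_leadfield(
                recording.channel_positions,
                n_sources=self.config.n_sources,
                head=head,
                channel_names=recording.channel_names,
                source_depth_fraction=self.config.source_depth_fraction,
            )
        if leadfield.n_channels != recording.n_channels:
            raise ValueError("lead field does not match the recording's channel count")
        self.leadfield = leadfield

    def fit(self, seed: int | None = None) -> ArcDecompositionResults:
        """Run every stage; the seed (default: config.seed) drives the
        PARAFAC multi-starts."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        ss_select, ss_source = ss.spawn(2)

        rec = self.recording
        if rec.reference != "average":
            rec = rec.apply_average_reference()
        stft_tensor = stft(
            rec,
            window_seconds=cfg.window_seconds,
            overlap=cfg.overlap,
            band=cfg.band,
            reject_amplitude=cfg.reject_amplitude,
        )
        csd = cross_spectral_density(stft_tensor)
        sensor_asd = amplitude_spectrum(csd)
        del csd

        K, selection_table, per_k_models = select_num_components(
            sensor_asd,
            K_max=cfg.K_max,
            threshold=cfg.corcondia_threshold,
            n_starts=cfg.n_starts,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            seed=ss_select,
            return_models=True,
        )
        sensor_full = per_k_models[K]

        sensor_posterior = rec.channel_positions[:, 1] < 0
        sensor_model, rejection_table = reject_noise_components(
            sensor_full,
            sensor_posterior,
            flatness_max=cfg.flatness_max,
            posterior_min=cfg.posterior_min,
        )

        inverse = loreta_inverse(self.leadfield, alpha=cfg.alpha, method=cfg.inverse_method)
        source_asd = source_amplitude_spectrum_from_stft(inverse, stft_tensor)

        source_fit = Parafac(
            source_asd,
            sensor_model.K,
            fixed={"frequency": sensor_model.A, "time": sensor_model.C},
        ).fit(
            n_starts=cfg.n_starts,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            seed=ss_source,
        )

        source_posterior = self.leadfield.grid.posterior_mask()
        freqs = sensor_asd.freqs
        components = []
        for k in range(sensor_model.K):
            a = sensor_model.A[:, k]
            b_src = source_fit.B[:, k]
            total = b_src.sum()
            post = float(b_src[source_posterior].sum() / total) if total > 0 else 0.0
            components.append(
                ArcComponent(
                    label="unclassified",
                    peak_frequency=float(freqs[np.argmax(a)]),
                    frequency_loading=_max_normalize(a),
                    sensor_loading=_max_normalize(sensor_model.B[:, k]),
                    source_loading=_max_normalize(b_src),
                    temporal_loading=_max_normalize(sensor_model.C[:, k]),
                    spectral_flatness=spectral_flatness(a),
                    posterior_fraction=post,
                    magnitude=float(np.linalg.norm(a)),
                )
            )
        components = label_components(components)

        return ArcDecompositionResults(
            config=cfg,
            sensor_model=sensor_model,
            sensor_model_full=sensor_full,
            source_model=source_fit,
            components=components,
            selection_table=selection_table,
            rejection_table=rejection_table,
            sensor_tensor=sensor_asd,
            source_tensor=source_asd,
            inverse=inverse,
            leadfield=self.leadfield,
            n_components_selected=K,
            window_centers=stft_tensor.window_centers.copy(),
        )


def decompose_subject(
    recording: EEGRecording,
    config: RunConfig | None = None,
    leadfield: LeadFieldModel | None = None,
    seed: int | None = None,
) -> ArcDecompositionResults:
    """Functional wrapper around :class:`ArcDecomposition`."""
    return ArcDecomposition(recording, config=config, leadfield=leadfield).fit(seed=seed)
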