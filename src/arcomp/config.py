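"""Run configuration: every tunable pipeline parameter with defaults.

Defaults mirror the analysis constants of the method: 5 s Hann windows
with 50% overlap over the extended 5-15 Hz alpha band (df = 0.2 Hz,
51 bins at 500 Hz), 387 sources, core-consistency threshold 90%, 5000
permutations with a 99th-percentile cluster-forming threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # spectral analysis
    window_seconds: float = 5.0
    overlap: float = 0.5
    band: tuple[float, float] = (5.0, 15.0)
    reject_amplitude: float | None = 100.0  # microvolts; None disables screening

    # head model / source imaging
    n_sources: int = 387
    shell_radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    source_depth_fraction: float = 0.92
    inverse_method: str = "loreta"
    alpha: float | None = None  # None -> 0.05 x mean eigenvalue rule

    # PARAFAC
    K_max: int = 6
    corcondia_threshold: float = 90.0
    n_starts: int = 10
    tol: float = 1e-8
    max_iter: int = 2000

    # noise-component rejection
    flatness_max: float = 0.7
    posterior_min: float = 0.5

    # group statistics
    n_perm: int = 5000
    cluster_pct: float = 99.0

    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.band = tuple(float(x) for x in self.band)
        self.shell_radii = tuple(float(x) for x in self.shell_radii)
        self.conductivities = tuple(float(x) for x in self.conductivities)
        self.validate()

    def validate(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.band[0] >= self.band[1] or self.band[0] < 0:
            raise ValueError("band must be an increasing non-negative pair")
        if self.n_sources < 10:
            raise ValueError("n_sources must be >= 10")
        if self.K_max < 1:
            raise ValueError("K_max must be >= 1")
        if not 0 <= self.corcondia_threshold <= 100:
            raise ValueError("corcondia_threshold must be in [0, 100]")
        if not 0 <= self.flatness_max <= 1:
            raise ValueError("flatness_max must be in [0, 1]")
        if not 0 <= self.posterior_min <= 1:
            raise ValueError("posterior_min must be in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 50 <= self.cluster_pct < 100:
            raise ValueError("cluster_pct must be in [50, 100)")
        if self.inverse_method not in ("loreta", "minimum-norm"):
            raise ValueError("inverse_method must be 'loreta' or 'minimum-norm'")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["shell_radii"] = list(self.shell_radii)
        d["conductivities"] = list(self.conductivities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if hasattr(path_or_text, "read"):
            d = yaml.safe_load(path_or_text.read())
        else:
            try:
                with open(path_or_text) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)

    def content_hash(self) -> str:
        """Stable digest of the full configuration, logged with each run."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
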