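"""Spherical head model, source grid, and analytic lead field.

The forward model is a 3-shell concentric-sphere volume conductor
(brain / skull / scalp) with radial dipoles on a quasi-uniform
Fibonacci lattice just beneath the innermost (brain) shell. The scalp
potential of a radial dipole in the innermost layer is the classical
Legendre series; the per-degree radial transfer coefficients are
obtained by solving the interface conditions of the layered conductor
exactly, so the gain matrix is analytic up to series truncation.

Default geometry: shell radii 0.087 / 0.092 / 0.100 m with
conductivities 0.33 / 0.0042 / 0.33 S/m (brain, skull, scalp), sources
at 92% of the brain radius. The gain is common-average referenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import legval

__all__ = [
    "HeadModel",
    "SourceGrid",
    "LeadFieldModel",
    "build_leadfield",
    "build_source_grid",
    "fibonacci_sphere",
    "default_channel_positions",
    "radial_transfer_coefficients",
]

DEFAULT_RADII = (0.087, 0.092, 0.100)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


@dataclass(frozen=True)
class HeadModel:
    """3-shell concentric spherical conductor (radii in m, conductivities in S/m)."""

    radii: tuple[float, float, float] = DEFAULT_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("shell radii must be positive and strictly increasing")
        if np.any(np.asarray(self.conductivities) <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    @property
    def brain_radius(self) -> float:
        return self.radii[0]


@dataclass
class SourceGrid:
    """Quasi-uniform dipole grid on a spherical shell with adjacency and labels.

    ``adjacency`` pairs points closer than ``r_adj = 1.3 x`` the median
    nearest-neighbor distance; ``region_labels`` are geometric sector
    names standing in for anatomical parcels.
    """

    coords: np.ndarray
    adjacency_pairs: np.ndarray
    region_labels: np.ndarray
    r_adj: float

    def __post_init__(self) -> None:
        pairs = np.asarray(self.adjacency_pairs, dtype=int)
        if pairs.size and np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("adjacency contains self-pairs")
        self.adjacency_pairs = pairs

    @property
    def n_sources(self) -> int:
        return self.coords.shape[0]

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.coords, axis=1).mean())

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-point arrays of neighbor indices (symmetric)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_sources)]
        for i, j in self.adjacency_pairs:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.asarray(sorted(x), dtype=int) for x in nbrs]

    def posterior_mask(self) -> np.ndarray:
        """Posterior sector: y < 0 in the head frame (+y anterior)."""
        return self.coords[:, 1] < 0.0

    def region_mask(self, label: str) -> np.ndarray:
        return self.region_labels == label


@dataclass
class LeadFieldModel:
    """Gain matrix (channels x sources) for radial dipoles plus its geometry.

    The gain is unitless: the analytic 3-shell potentials are rescaled
    so the largest absolute entry is 1, i.e. a unit-amplitude source
    produces at most 1 microvolt at the best-coupled sensor.
    ``gain_scale`` is the factor by which the raw analytic potentials
    were divided (useful for checking against the series solution).
    """

    gain: np.ndarray
    grid: SourceGrid
    head: HeadModel
    channel_positions: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    gain_scale: float = 1.0

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite values")
        if self.gain.shape != (self.channel_positions.shape[0], self.grid.n_sources):
            raise ValueError("gain shape inconsistent with channels/sources")
        if np.any(np.linalg.norm(self.gain, axis=0) == 0):
            raise ValueError("gain has an all-zero source column")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform lattice of n points on a sphere (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def fibonacci_cap(n: int, radius: float, z_min_fraction: float) -> np.ndarray:
    """Quasi-uniform lattice on the spherical cap z/r >= z_min_fraction."""
    i = np.arange(n)
    z = z_min_fraction + (1.0 - z_min_fraction) * (2.0 * i + 1.0) / (2.0 * n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def default_channel_positions(
    n_channels: int = 62,
    outer_radius: float = DEFAULT_RADII[2],
    z_min_fraction: float = -0.35,
) -> tuple[np.ndarray, list[str]]:
    """Quasi-uniform electrode layout on the upper scalp cap.

    Points are placed by a golden-angle spiral over the spherical cap
    z/R >= z_min_fraction, emulating a whole-head montage whose lowest
    ring sits below the ears. Names are synthetic ("E01", ...).
    """
    pts = fibonacci_cap(n_channels, outer_radius, z_min_fraction)
    names = [f"E{k + 1:02d}" for k in range(n_channels)]
    return pts, names


def _sector_labels(coords: np.ndarray) -> np.ndarray:
    """Geometric sector labels standing in for anatomical parcels."""
    r = np.linalg.norm(coords, axis=1)
    y = coords[:, 1] / r
    z = coords[:, 2] / r
    labels = np.empty(coords.shape[0], dtype=object)
    posterior = y < 0.0
    labels[posterior & (z >= 0.25)] = "occipito-parietal"
    labels[posterior & (z < 0.25)] = "occipito-temporal"
    labels[~posterior & (y >= 0.25)] = "frontal"
    labels[~posterior & (y < 0.25)] = "central"
    return labels.astype(str)


def build_source_grid(
    n_sources: int = 387,
    radius: float | None = None,
    head: HeadModel | None = None,
    source_depth_fraction: float = 0.92,
    adjacency_factor: float = 1.3,
    z_min_fraction: float = -0.2,
) -> SourceGrid:
    """Quasi-uniform source grid on a shell inside the brain compartment.

    The lattice covers the cap z/r >= z_min_fraction rather than the
    full sphere: cortical gray matter does not extend to the skull
    base, and sources far outside the electrode coverage would be
    unlocalizable in principle.
    """
    if n_sources < 10:
        raise ValueError("need at least 10 sources")
    head = head or HeadModel()
    if radius is None:
        radius = source_depth_fraction * head.brain_radius
    coords = fibonacci_cap(n_sources, radius, z_min_fraction)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    r_adj = adjacency_factor * float(np.median(nn))
    ii, jj = np.nonzero(d < r_adj)
    pairs = np.column_stack([ii[ii < jj], jj[ii < jj]])
    grid = SourceGrid(
        coords=coords,
        adjacency_pairs=pairs,
        region_labels=_sector_labels(coords),
        r_adj=r_adj,
    )
    counts = np.zeros(n_sources, dtype=int)
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    if np.any(counts == 0):
        raise ValueError("isolated grid point: adjacency radius too small for this density")
    return grid


def radial_transfer_coefficients(
    source_radius: float,
    head: HeadModel,
    n_terms: int = 200,
) -> np.ndarray:
    """Per-degree Legendre coefficients of the scalp potential of a
    unit radial dipole at the given radius inside a 3-shell sphere.

    For each degree n the potential in layer j is
    ``A_j r^n + B_j r^-(n+1)`` (plus the free-space dipole term in the
    innermost layer). Continuity of potential and of radial current at
    the two interfaces, and zero radial current at the scalp surface,
    give a 5x5 linear system whose solution yields the surface
    coefficient ``A_3 R^n + B_3 R^-(n+1)``. The scalp potential at
    angular distance gamma from the dipole axis is then
    ``sum_n coef[n] P_n(cos gamma)`` (coef[0] = 0).

    The free-space radial-dipole expansion used is
    ``V_p(r, theta) = 1/(4 pi s1) * sum_n n b^(n-1) r^-(n+1) P_n``.
    """
    if not 0 < source_radius < head.radii[0]:
        raise ValueError("source must lie strictly inside the innermost shell")
    # Solve in radius-normalized units (outer radius = 1) so that powers of
    # the radii stay of order (b/R)^n instead of overflowing a double at
    # high degree; the coefficient of degree n scales as R^-2 overall.
    scale = head.radii[2]
    b = source_radius / scale
    r1, r2, R = (r / scale for r in head.radii)
    s1, s2, s3 = head.conductivities
    c = 1.0 / (4.0 * np.pi * s1)
    coefs = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        src_v = c * n * b ** (n - 1)  # coefficient of r^-(n+1) source term in layer 1
        # potential continuity at r1
        M[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -src_v * r1 ** -(n + 1)
        # current continuity at r1: s * dV/dr
        M[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0.0,
            0.0,
        ]
        rhs[1] = s1 * (n + 1) * src_v * r1 ** -(n + 2)
        # potential continuity at r2
        M[2] = [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # current continuity at r2
        M[3] = [
            0.0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # zero radial current at the scalp surface
        M[4] = [0.0, 0.0, 0.0, n * R ** (n - 1), -(n + 1) * R ** -(n + 2)]
        sol = np.linalg.solve(M, rhs)
        A3, B3 = sol[3], sol[4]
        coefs[n] = (A3 * R**n + B3 * R ** -(n + 1)) / scale**2
    return coefs


def build_leadfield(
    positions: np.ndarray,
    n_sources: int = 387,
    head: HeadModel | None = None,
    channel_names: list[str] | None = None,
    source_depth_fraction: float = 0.92,
    n_terms: int = 200,
    grid: SourceGrid | None = None,
) -> LeadFieldModel:
    """Analytic 3-shell lead field for radial dipoles, common-average referenced.

    Parameters
    ----------
    positions : ndarray (n_channels, 3)
        Electrode coordinates; must lie within 10% of the outer shell.
    n_sources : int
        Size of the quasi-uniform source lattice (ignored if ``grid``
        is given).
    """
    head = head or HeadModel()
    positions = np.asarray(positions, dtype=float)
    radii = np.linalg.norm(positions, axis=1)
    if np.any(np.abs(radii - head.outer_radius) > 0.1 * head.outer_radius):
        raise ValueError("channel positions deviate more than 10% from the outer shell")
    if grid is None:
        grid = build_source_grid(n_sources, head=head, source_depth_fraction=source_depth_fraction)
    coefs = radial_transfer_coefficients(grid.radius, head, n_terms=n_terms)
    # cosine of the angle between each electrode and each source
    u_ch = positions / radii[:, None]
    u_src = grid.coords / np.linalg.norm(grid.coords, axis=1)[:, None]
    cosg = np.clip(u_ch @ u_src.T, -1.0, 1.0)
    gain = legval(cosg, coefs)
    gain = gain - gain.mean(axis=0, keepdims=True)  # common-average reference
    scale = float(np.abs(gain).max())
    return LeadFieldModel(
        gain=gain / scale,
        grid=grid,
        head=head,
        channel_positions=positions,
        channel_names=list(channel_names) if channel_names else [],
        gain_scale=scale,
    )
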