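"""Synthetic phantoms, full imaging scenarios, and abstract test systems.

Sparse fluorescent inclusions are modelled as 2D disks (the planar analogue of
the spherical targets used in small-animal studies) rasterised onto the
imaging grid.  ``make_scenario`` wires the full pipeline — grid, homogeneous
optical properties, boundary-inset point sources, boundary detectors,
sensitivity matrix, ground truth and noisy measurements — into one
reproducible bundle.  ``make_random_system`` produces abstract systems with a
controlled singular-value profile for solver unit tests independent of the
optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidParameterError, ShapeError
from .forward import (
    ImagingGrid,
    OpticalProperties,
    ORGAN_PROPERTIES,
    SensitivityMatrix,
    SourceSpec,
    assemble_sensitivity_matrix,
    simulate_measurements,
)

__all__ = [
    "DiskTarget",
    "PhantomSpec",
    "ScenarioConfig",
    "ScenarioBundle",
    "rasterize_phantom",
    "perimeter_sources",
    "make_scenario",
    "make_random_system",
    "two_target_config",
    "three_target_config",
]


@dataclass(frozen=True)
class DiskTarget:
    """A uniform fluorescent disk: centre (mm), radius (mm), intensity (a.u.)."""

    center: tuple[float, float]
    radius: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius}")
        if self.intensity <= 0:
            raise InvalidParameterError(f"intensity must be > 0, got {self.intensity}")


@dataclass(frozen=True)
class PhantomSpec:
    """A list of disk targets embedded in an imaging grid."""

    targets: tuple[DiskTarget, ...]
    grid: ImagingGrid

    def __post_init__(self) -> None:
        for t in self.targets:
            if not self.grid.contains(t.center):
                raise InvalidParameterError(
                    f"target centre {t.center} lies outside the {self.grid.extent} mm domain"
                )


def rasterize_phantom(spec: PhantomSpec) -> np.ndarray:
    """Nodal ground-truth vector: each node sums the intensities of the disks
    containing it (boundary inclusive); nodes outside every disk get 0."""
    coords = spec.grid.node_coordinates()
    x = np.zeros(spec.grid.n_nodes)
    for t in spec.targets:
        d2 = (coords[:, 0] - t.center[0]) ** 2 + (coords[:, 1] - t.center[1]) ** 2
        x[d2 <= t.radius**2] += t.intensity
    return x


def perimeter_sources(
    grid: ImagingGrid, depth: float, count: int, amplitude: float = 1.0
) -> list[SourceSpec]:
    """``count`` point sources equally spaced along the rectangle inset by
    ``depth`` (mm) from the domain boundary — one transport mean free path
    beneath the surface when depth = 1/mu_sx'."""
    if count < 1:
        raise InvalidParameterError(f"count must be >= 1, got {count}")
    ex, ey = grid.extent
    if not (0 < depth < min(ex, ey) / 2):
        raise InvalidParameterError(
            f"depth {depth} mm must be inside (0, {min(ex, ey) / 2}) for this domain"
        )
    x0, y0 = grid.origin[0] + depth, grid.origin[1] + depth
    w, h = ex - 2 * depth, ey - 2 * depth
    perim = 2 * (w + h)
    sources = []
    for i in range(count):
        t = (i / count) * perim
        if t < w:
            pos = (x0 + t, y0)
        elif t < w + h:
            pos = (x0 + w, y0 + (t - w))
        elif t < 2 * w + h:
            pos = (x0 + w - (t - w - h), y0 + h)
        else:
            pos = (x0, y0 + h - (t - 2 * w - h))
        # Snap to the nearest grid node so the delta deposition is unambiguous.
        sources.append(SourceSpec(position=grid.node_position(grid.nearest_node(pos)), amplitude=amplitude))
    return sources


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic imaging experiment.

    Defaults: 20 mm x 20 mm domain on a 32 x 32 grid (spacing 20/31 mm),
    homogeneous muscle optics, 5 sources one transport mean free path inside
    the boundary, detectors on every boundary node, 1% relative Gaussian
    measurement noise.
    """

    nx: int = 32
    ny: int = 32
    domain_size: float = 20.0  # mm along x; y scales with ny
    optical: OpticalProperties = field(default_factory=lambda: ORGAN_PROPERTIES["muscle"])
    robin_coefficient: float = 1.0
    n_sources: int = 5
    source_depth: float | None = None  # mm; None -> 1/mu_sx'
    targets: tuple[DiskTarget, ...] = (DiskTarget(center=(12.9, 9.9), radius=1.5),)
    noise_level: float = 0.01
    seed: int = 0

    def build_grid(self) -> ImagingGrid:
        spacing = self.domain_size / (self.nx - 1)
        return ImagingGrid(
            nx=self.nx, ny=self.ny, spacing=spacing, robin_coefficient=self.robin_coefficient
        )


def two_target_config(**overrides) -> ScenarioConfig:
    """Two 1 mm disks at (13, 12) and (13, 6) mm in the default domain."""
    targets = (
        DiskTarget(center=(13.0, 12.0), radius=1.0),
        DiskTarget(center=(13.0, 6.0), radius=1.0),
    )
    return ScenarioConfig(targets=targets, **overrides)


def three_target_config(**overrides) -> ScenarioConfig:
    """Three 1 mm disks at (11, 10), (14, 14) and (13, 6) mm."""
    targets = (
        DiskTarget(center=(11.0, 10.0), radius=1.0),
        DiskTarget(center=(14.0, 14.0), radius=1.0),
        DiskTarget(center=(13.0, 6.0), radius=1.0),
    )
    return ScenarioConfig(targets=targets, **overrides)


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything a reconstruction needs, fully determined by (config, seed)."""

    A: SensitivityMatrix
    x_true: np.ndarray
    phi_m: np.ndarray
    noise_level: float
    seed: int
    provenance: dict


def make_scenario(config: ScenarioConfig | None = None) -> ScenarioBundle:
    """Simulate a complete synthetic experiment from a scenario configuration."""
    config = config or ScenarioConfig()
    grid = config.build_grid()
    depth = (
        config.source_depth
        if config.source_depth is not None
        else config.optical.transport_mean_free_path
    )
    sources = perimeter_sources(grid, depth=depth, count=config.n_sources)
    detectors = grid.boundary_positions()
    A = assemble_sensitivity_matrix(grid, config.optical, sources, detectors)
    x_true = rasterize_phantom(PhantomSpec(targets=config.targets, grid=grid))
    phi_m = simulate_measurements(A, x_true, config.noise_level, config.seed)
    provenance = asdict(config)
    provenance["n_detectors"] = int(detectors.shape[0])
    provenance["source_positions"] = [s.position for s in sources]
    return ScenarioBundle(
        A=A,
        x_true=x_true,
        phi_m=phi_m,
        noise_level=config.noise_level,
        seed=config.seed,
        provenance=provenance,
    )


def make_random_system(
    M: int,
    N: int,
    condition_profile: str = "flat",
    seed: int = 0,
    support_size: int | None = None,
    decay: float = 0.7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random M x N system with controlled singular-value decay and a sparse
    nonnegative ground truth; measurements are exactly consistent.

    condition_profile: "flat" (all singular values 1, near-orthogonal rows) or
    "geometric" (sigma_i = decay**i, increasingly ill-conditioned).
    """
    if M < 1 or N < 1:
        raise ShapeError(f"M and N must be >= 1, got {M}, {N}")
    if condition_profile not in ("flat", "geometric"):
        raise InvalidParameterError(
            f"condition_profile must be 'flat' or 'geometric', got {condition_profile!r}"
        )
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(M, N))
    U, _, Vt = np.linalg.svd(G, full_matrices=False)
    r = min(M, N)
    s = np.ones(r) if condition_profile == "flat" else decay ** np.arange(r)
    A = (U * s) @ Vt

    if N == 1:
        x_true = np.array([abs(rng.normal()) + 0.5])
    else:
        k = support_size if support_size is not None else max(1, round(0.05 * N))
        k = min(k, N)
        support = rng.choice(N, size=k, replace=False)
        x_true = np.zeros(N)
        x_true[support] = rng.uniform(0.5, 1.5, size=k)
    phi_m = A @ x_true
    return A, x_true, phi_m
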