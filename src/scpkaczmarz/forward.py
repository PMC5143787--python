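"""Diffusion-approximation forward model on a 2D structured grid.

Photon transport at the excitation and emission wavelengths is modelled by two
coupled elliptic diffusion equations,

    -div(D_x grad Phi_x) + mu_ax Phi_x = Theta * delta(r - r_s),
    -div(D_m grad Phi_m) + mu_am Phi_m = Phi_x * x,

with the Robin boundary condition Phi + 2*kappa*D dPhi/dn = 0, where
D = 1/(3*(mu_a + mu_s')) is the diffusion coefficient and x is the unknown
fluorescent yield per node.  The equations are discretised with a symmetric
node-centred finite-volume scheme (5-point stencil, half cells on the
boundary), which yields a symmetric positive-definite M-matrix and hence a
strictly positive field for any nonnegative nonzero source.

Eliminating Phi_m gives the linear measurement model phi_m = A x, where row
(s, d) of the sensitivity matrix A is the Born product of the excitation
field of source s and the emission-wavelength adjoint field of detector d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    InvalidParameterError,
    LayoutError,
    NumericalError,
    ShapeError,
)

__all__ = [
    "OpticalProperties",
    "ORGAN_PROPERTIES",
    "ImagingGrid",
    "SourceSpec",
    "Field",
    "SensitivityMatrix",
    "diffusion_coefficient",
    "solve_diffusion_field",
    "assemble_sensitivity_matrix",
    "simulate_measurements",
]


def diffusion_coefficient(mu_a: float, mu_s_prime: float) -> float:
    """Diffusion coefficient D = 1 / (3 * (mu_a + mu_s')) in mm.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1, > 0.
    mu_s_prime : float
        Reduced scattering coefficient (1 - g) * mu_s, mm^-1, > 0.
    """
    if mu_a <= 0 or mu_s_prime <= 0:
        raise InvalidParameterError(
            f"optical coefficients must be > 0, got mu_a={mu_a}, mu_s'={mu_s_prime}"
        )
    return 1.0 / (3.0 * (mu_a + mu_s_prime))


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical coefficients at the excitation and emission wavelengths.

    All coefficients in mm^-1; reduced scattering (1-g)*mu_s is stored directly.
    """

    mu_ax: float
    mu_am: float
    mu_sx_prime: float
    mu_sm_prime: float

    def __post_init__(self) -> None:
        for name in ("mu_ax", "mu_am", "mu_sx_prime", "mu_sm_prime"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def diffusion_x(self) -> float:
        """Diffusion coefficient at the excitation wavelength, mm."""
        return diffusion_coefficient(self.mu_ax, self.mu_sx_prime)

    @property
    def diffusion_m(self) -> float:
        """Diffusion coefficient at the emission wavelength, mm."""
        return diffusion_coefficient(self.mu_am, self.mu_sm_prime)

    @property
    def transport_mean_free_path(self) -> float:
        """1 / mu_sx', mm — the depth at which boundary sources are placed."""
        return 1.0 / self.mu_sx_prime


#: Mouse-organ optical coefficients (mu_ax, mu_am, mu_sx', mu_sm', mm^-1), used
#: as scalar fixtures for homogeneous domains.
ORGAN_PROPERTIES: dict[str, OpticalProperties] = {
    "muscle": OpticalProperties(0.0052, 0.0068, 1.08, 1.03),
    "heart": OpticalProperties(0.0083, 0.0104, 1.01, 0.99),
    "lungs": OpticalProperties(0.0133, 0.0203, 1.97, 1.95),
    "liver": OpticalProperties(0.0329, 0.0176, 0.70, 0.65),
    "kidneys": OpticalProperties(0.0660, 0.0380, 2.25, 2.02),
    "stomach": OpticalProperties(0.0114, 0.0070, 1.74, 1.36),
}


@dataclass(frozen=True)
class ImagingGrid:
    """Node-centred rectangular grid; nodes enumerated row-major (index = iy*nx + ix).

    Coordinates are in mm; node (ix, iy) sits at origin + (ix, iy) * spacing.
    ``robin_coefficient`` is the boundary-mismatch factor kappa in the Robin
    condition Phi + 2*kappa*D dPhi/dn = 0 (kappa = 1 for index matching).
    """

    nx: int
    ny: int
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    robin_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise InvalidParameterError(f"grid must be at least 3x3, got {self.nx}x{self.ny}")
        if self.spacing <= 0:
            raise InvalidParameterError(f"spacing must be > 0, got {self.spacing}")
        if self.robin_coefficient <= 0:
            raise InvalidParameterError(
                f"robin_coefficient must be > 0, got {self.robin_coefficient}"
            )

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float]:
        """Physical domain size (mm) along x and y."""
        return ((self.nx - 1) * self.spacing, (self.ny - 1) * self.spacing)

    def node_index(self, ix: int, iy: int) -> int:
        return iy * self.nx + ix

    def node_position(self, j: int) -> tuple[float, float]:
        iy, ix = divmod(j, self.nx)
        return (self.origin[0] + ix * self.spacing, self.origin[1] + iy * self.spacing)

    def node_coordinates(self) -> np.ndarray:
        """(N, 2) array of physical node positions, row-major order."""
        xs = self.origin[0] + np.arange(self.nx) * self.spacing
        ys = self.origin[1] + np.arange(self.ny) * self.spacing
        gx, gy = np.meshgrid(xs, ys)  # gy varies along rows -> row-major flatten
        return np.column_stack([gx.ravel(), gy.ravel()])

    def boundary_mask(self) -> np.ndarray:
        """Boolean mask of length N, True for nodes on the domain boundary."""
        ix = np.arange(self.n_nodes) % self.nx
        iy = np.arange(self.n_nodes) // self.nx
        return (ix == 0) | (ix == self.nx - 1) | (iy == 0) | (iy == self.ny - 1)

    def boundary_positions(self) -> np.ndarray:
        """(n_boundary, 2) physical positions of boundary nodes, row-major order."""
        return self.node_coordinates()[self.boundary_mask()]

    def contains(self, position: tuple[float, float]) -> bool:
        x, y = position
        ex, ey = self.extent
        return (
            self.origin[0] <= x <= self.origin[0] + ex
            and self.origin[1] <= y <= self.origin[1] + ey
        )

    def nearest_node(self, position: tuple[float, float]) -> int:
        """Index of the grid node closest to a physical position."""
        ix = int(round((position[0] - self.origin[0]) / self.spacing))
        iy = int(round((position[1] - self.origin[1]) / self.spacing))
        ix = min(max(ix, 0), self.nx - 1)
        iy = min(max(iy, 0), self.ny - 1)
        return self.node_index(ix, iy)


@dataclass(frozen=True)
class SourceSpec:
    """Isotropic point source Theta * delta(r - position)."""

    position: tuple[float, float]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise InvalidParameterError(f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class Field:
    """Photon density Phi at every grid node (row-major), tagged by wavelength."""

    values: np.ndarray
    wavelength_tag: str  # "excitation" or "emission"


def assemble_operator(grid: ImagingGrid, mu_a: float, D: float) -> sp.csr_matrix:
    """Symmetric finite-volume discretisation of -div(D grad .) + mu_a with Robin BC.

    Boundary nodes own half cells (quarter cells at corners); the Robin condition
    Phi + 2*kappa*D dPhi/dn = 0 contributes facelen * Phi / (2*kappa) on each
    boundary face.  The result is a symmetric positive-definite M-matrix.
    """
    if mu_a <= 0 or D <= 0:
        raise InvalidParameterError(f"mu_a and D must be > 0, got mu_a={mu_a}, D={D}")
    nx, ny, h = grid.nx, grid.ny, grid.spacing
    kappa = grid.robin_coefficient

    # Cell widths: half width for boundary rows/columns.
    wx = np.full(nx, h)
    wx[0] = wx[-1] = h / 2.0
    wy = np.full(ny, h)
    wy[0] = wy[-1] = h / 2.0

    N = nx * ny
    diag = np.zeros(N)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    ix = np.arange(N) % nx
    iy = np.arange(N) // nx
    area = wx[ix] * wy[iy]
    diag += mu_a * area

    # Horizontal interfaces between (ix, iy) and (ix+1, iy): face length wy[iy].
    left = np.where(ix < nx - 1)[0]
    right = left + 1
    c = D * wy[iy[left]] / h
    diag[left] += c
    diag[right] += c
    rows.append(left)
    cols.append(right)
    vals.append(-c)
    rows.append(right)
    cols.append(left)
    vals.append(-c)

    # Vertical interfaces between (ix, iy) and (ix, iy+1): face length wx[ix].
    bottom = np.where(iy < ny - 1)[0]
    top = bottom + nx
    c = D * wx[ix[bottom]] / h
    diag[bottom] += c
    diag[top] += c
    rows.append(bottom)
    cols.append(top)
    vals.append(-c)
    rows.append(top)
    cols.append(bottom)
    vals.append(-c)

    # Robin boundary faces: flux out = Phi/(2*kappa) per unit face length.
    for mask, facelen in (
        (ix == 0, wy[iy]),
        (ix == nx - 1, wy[iy]),
        (iy == 0, wx[ix]),
        (iy == ny - 1, wx[ix]),
    ):
        diag[mask] += facelen[mask] / (2.0 * kappa)

    idx = np.arange(N)
    rows.append(idx)
    cols.append(idx)
    vals.append(diag)
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    )
    return K.tocsr()


def _point_source_rhs(grid: ImagingGrid, source: SourceSpec) -> np.ndarray:
    """Integrated right-hand side for Theta * delta(r - r_s).

    The delta carries total mass Theta, deposited on the nearest grid node
    (equivalently, nodal source density Theta / spacing^2 over a nominal cell).
    """
    if not grid.contains(source.position):
        raise LayoutError(f"source position {source.position} lies outside the domain")
    b = np.zeros(grid.n_nodes)
    b[grid.nearest_node(source.position)] = source.amplitude
    return b


def solve_diffusion_field(
    grid: ImagingGrid, mu_a: float, D: float, source: SourceSpec
) -> Field:
    """Solve -div(D grad Phi) + mu_a Phi = Theta delta(r - r_s) with Robin BC.

    Returns the photon-density field on all grid nodes.  The discrete operator
    is an M-matrix, so the field is strictly positive for Theta > 0.
    """
    K = assemble_operator(grid, mu_a, D)
    b = _point_source_rhs(grid, source)
    try:
        phi = spla.spsolve(K, b)
    except Exception as exc:  # pragma: no cover - cannot occur for valid inputs
        raise NumericalError(f"diffusion solve failed: {exc}") from exc
    if not np.all(np.isfinite(phi)):  # pragma: no cover - guard only
        raise NumericalError("diffusion solve produced non-finite values")
    return Field(values=phi, wavelength_tag="excitation")


@dataclass(frozen=True)
class SensitivityMatrix:
    """M x N forward matrix A mapping nodal fluorescent yield to measurements.

    ``row_index[i]`` is the (source, detector) pair of row i (source-major);
    columns follow the grid's row-major node order.
    """

    entries: np.ndarray
    row_index: list[tuple[int, int]] = field(repr=False)
    grid: ImagingGrid | None = None

    @property
    def n_measurements(self) -> int:
        return self.entries.shape[0]

    @property
    def n_unknowns(self) -> int:
        return self.entries.shape[1]


def _detector_nodes(grid: ImagingGrid, detectors) -> list[int]:
    boundary = grid.boundary_mask()
    nodes = []
    tol = 1e-6 * grid.spacing
    for k, pos in enumerate(detectors):
        j = grid.nearest_node(tuple(pos))
        px, py = grid.node_position(j)
        if abs(px - pos[0]) > tol or abs(py - pos[1]) > tol:
            raise LayoutError(f"detector {k} at {tuple(pos)} does not coincide with a grid node")
        if not boundary[j]:
            raise LayoutError(f"detector {k} at {tuple(pos)} is not on a boundary node")
        nodes.append(j)
    return nodes


def assemble_sensitivity_matrix(
    grid: ImagingGrid,
    props: OpticalProperties,
    sources: list[SourceSpec],
    detectors,
) -> SensitivityMatrix:
    """Assemble the Born sensitivity matrix A.

    Row (s, d) has entries A[(s,d), j] = Phi_x^s(r_j) * G_m^d(r_j) * spacing^2,
    where Phi_x^s is the excitation field of source s and G_m^d is the
    emission-wavelength adjoint field driven by a unit source at detector d.
    Rows are ordered source-major with detectors in input order.
    """
    if len(sources) == 0 or len(detectors) == 0:
        raise LayoutError("need at least one source and one detector")
    det_nodes = _detector_nodes(grid, detectors)

    Kx = assemble_operator(grid, props.mu_ax, props.diffusion_x)
    Km = assemble_operator(grid, props.mu_am, props.diffusion_m)
    lu_x = spla.splu(Kx.tocsc())
    lu_m = spla.splu(Km.tocsc())

    phi_x = np.column_stack(
        [lu_x.solve(_point_source_rhs(grid, s)) for s in sources]
    )  # N x S
    G = np.zeros((grid.n_nodes, len(det_nodes)))
    for k, j in enumerate(det_nodes):
        e = np.zeros(grid.n_nodes)
        e[j] = 1.0
        G[:, k] = lu_m.solve(e)

    h2 = grid.spacing**2
    rows = []
    row_index = []
    for s in range(len(sources)):
        for d in range(len(det_nodes)):
            rows.append(phi_x[:, s] * G[:, d] * h2)
            row_index.append((s, d))
    A = np.vstack(rows)
    return SensitivityMatrix(entries=A, row_index=row_index, grid=grid)


def simulate_measurements(
    A: SensitivityMatrix | np.ndarray,
    x_true: np.ndarray,
    noise_level: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Noisy boundary measurements phi_m = A x_true + e.

    The noise e is zero-mean Gaussian with standard deviation
    noise_level * mean(|A x_true|), reproducible from ``seed``.  With a zero
    signal the noise scale is zero by this convention, so the result is exactly
    the zero vector.
    """
    mat = A.entries if isinstance(A, SensitivityMatrix) else np.asarray(A)
    x_true = np.asarray(x_true, dtype=float)
    if x_true.shape != (mat.shape[1],):
        raise ShapeError(
            f"x_true has shape {x_true.shape}, expected ({mat.shape[1]},) to match A"
        )
    if noise_level < 0:
        raise InvalidParameterError(f"noise_level must be >= 0, got {noise_level}")
    clean = mat @ x_true
    sigma = noise_level * np.mean(np.abs(clean))
    rng = np.random.default_rng(seed)
    return clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
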