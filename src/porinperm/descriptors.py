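"""Conformer-ensemble molecular descriptors for porin permeation scoring.

Four physical descriptors drive the permeability score of a compound
through a general porin:

* **net charge** ``Q`` — nearest integer to the partial-charge sum;
* **total dipole moment** — point-charge dipole, Debye, averaged over
  conformers;
* **transversal dipole moment** ``D`` — the dipole component perpendicular
  to the molecule's main inertia axis (its long axis), the part that
  couples to the porin's transversal electric field;
* **minimal projection area (MPA)** — the smallest shadow the molecule can
  cast (union of atomic vdW disks) over all viewing directions, with its
  standard deviation across conformers measuring flexibility.

The MPA estimator rasterises the projected union of disks on a regular
grid, searches a quasi-uniform Fibonacci hemisphere of directions and
refines the best direction with golden-section line searches in the local
tangent plane.  A Monte-Carlo hit-or-miss estimator of the same projected
area is provided purely as a stochastic cross-check of the raster method;
the pipeline never uses it.

For net-charged species the dipole is origin dependent; this module fixes
the origin at the center of mass, consistent with the inertia-frame
decomposition used for the transversal component.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .ensembles import ConformerEnsemble

__all__ = [
    "EA_TO_DEBYE",
    "DescriptorSet",
    "DescriptorSettings",
    "net_charge",
    "dipole_vector",
    "main_inertia_axis",
    "transversal_dipole",
    "projection_area",
    "projection_area_monte_carlo",
    "fibonacci_hemisphere",
    "minimal_projection_area",
    "ensemble_descriptors",
    "ConformerDescriptorCalculator",
]

#: Conversion factor 1 e*angstrom = 4.80320 Debye.
EA_TO_DEBYE = 4.80320

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_INV_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DescriptorSet:
    """Scored molecular descriptors of one compound (ensemble means)."""

    compound_id: str
    net_charge: int
    total_dipole_mean: float  # Debye
    transversal_dipole_mean: float  # Debye
    mpa_mean: float  # A^2
    mpa_sd: float  # A^2, population normalisation
    alogp: float

    def __post_init__(self) -> None:
        if self.mpa_mean <= 0:
            raise ValueError("mpa_mean must be positive")
        if self.mpa_sd < 0:
            raise ValueError("mpa_sd must be non-negative")
        if not (
            self.total_dipole_mean >= self.transversal_dipole_mean - 1e-9
            and self.transversal_dipole_mean >= -1e-12
        ):
            raise ValueError(
                "require total_dipole_mean >= transversal_dipole_mean >= 0"
            )


@dataclass
class DescriptorSettings:
    """Tunables of the MPA search: direction count, raster step, refinement."""

    n_directions: int = 256
    grid_resolution: float = 0.1  # angstrom
    refine: bool = True

    def __post_init__(self) -> None:
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")


# ---------------------------------------------------------------------------
# charge and dipole


def net_charge(ensemble: ConformerEnsemble) -> int:
    """Formal net charge: nearest integer to the partial-charge sum.

    The ensemble validates on construction that the sum is within 0.01 e of
    an integer, so this is exact for any valid ensemble.
    """
    return ensemble.formal_charge


def center_of_mass(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    return masses @ positions / masses.sum()


def dipole_vector(
    positions: np.ndarray,
    charges: np.ndarray,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Point-charge dipole ``mu = sum_i q_i (r_i - origin)`` in Debye.

    For neutral species the dipole is origin independent.  For net-charged
    species it is not, and the origin is taken at the center of mass when
    ``masses`` is given (geometric centroid otherwise) so that the dipole
    lives in the same frame as the inertia decomposition.
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must have shape (n_atoms, 3)")
    if positions.shape[0] == 0:
        raise ValueError("empty atom list")
    if charges.shape != (positions.shape[0],):
        raise ValueError("charges length must match positions")
    if masses is not None:
        origin = center_of_mass(positions, masses)
    else:
        origin = positions.mean(axis=0)
    return EA_TO_DEBYE * (charges @ (positions - origin))


def main_inertia_axis(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Unit vector of the molecule's long axis.

    Eigenvector of the mass-weighted inertia tensor (about the center of
    mass) with the smallest eigenvalue: mass far from an axis contributes
    to the moment about it, so the smallest moment belongs to the axis of
    elongation.  Sign convention: the first component larger than 1e-12 in
    magnitude is made positive.  For degenerate smallest eigenvalues the
    lexicographically smallest sign-fixed eigenvector is returned — a
    deterministic tie-break for symmetric molecules where any in-plane
    axis would do.
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("need at least two atoms to define an inertia axis")
    centered = positions - center_of_mass(positions, masses)
    extent = float(np.abs(centered).max())
    if extent < 1e-9:
        raise ValueError("degenerate geometry: all atoms coincide")
    r2 = np.einsum("ij,ij->i", centered, centered)
    # I = sum_i m_i (|r_i|^2 I3 - r_i r_i^T)
    tensor = np.eye(3) * float(masses @ r2) - np.einsum(
        "i,ij,ik->jk", masses, centered, centered
    )
    eigvals, eigvecs = np.linalg.eigh(tensor)
    scale = max(abs(eigvals[-1]), 1e-300)
    candidates = [
        _fix_sign(eigvecs[:, k])
        for k in range(3)
        if eigvals[k] - eigvals[0] <= 1e-8 * scale
    ]
    candidates.sort(key=lambda v: tuple(np.round(v, 12)))
    return candidates[0]


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    for component in vec:
        if abs(component) > 1e-12:
            return vec if component > 0 else -vec
    return vec


def transversal_dipole(dipole: np.ndarray, axis: np.ndarray) -> float:
    """Magnitude of the dipole component perpendicular to ``axis`` (Debye).

    Satisfies the Pythagorean identity
    ``transversal^2 + (mu . axis)^2 = |mu|^2``.
    """
    dipole = np.asarray(dipole, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"axis must be a unit vector; |axis| = {norm:.12f}")
    perpendicular = dipole - (dipole @ axis) * axis
    return float(np.linalg.norm(perpendicular))


# ---------------------------------------------------------------------------
# projection areas


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (u, v) of the plane normal to ``direction``."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(direction)))] = 1.0
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def _projected_disks(
    positions: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    u, v = _plane_basis(direction)
    return np.column_stack((positions @ u, positions @ v))


def projection_area(
    positions: np.ndarray,
    radii: np.ndarray,
    direction: np.ndarray,
    resolution: float = 0.1,
) -> float:
    """Area (A^2) of the union of atomic vdW disks projected along ``direction``.

    The projection plane is rasterised with square cells of side
    ``resolution``; a cell counts if its center falls inside any disk.  The
    estimate converges to the exact union area as the resolution shrinks.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    pts = _projected_disks(positions, direction)
    rmax = float(radii.max())
    lo = pts.min(axis=0) - rmax - resolution
    hi = pts.max(axis=0) + rmax + resolution
    nx = int(np.ceil((hi[0] - lo[0]) / resolution))
    ny = int(np.ceil((hi[1] - lo[1]) / resolution))
    xs = lo[0] + (np.arange(nx) + 0.5) * resolution
    ys = lo[1] + (np.arange(ny) + 0.5) * resolution
    mask = np.zeros((nx, ny), dtype=bool)
    for (px, py), radius in zip(pts, radii):
        i0 = max(int((px - radius - lo[0]) / resolution) - 1, 0)
        i1 = min(int((px + radius - lo[0]) / resolution) + 2, nx)
        j0 = max(int((py - radius - lo[1]) / resolution) - 1, 0)
        j1 = min(int((py + radius - lo[1]) / resolution) + 2, ny)
        dx2 = (xs[i0:i1] - px) ** 2
        dy2 = (ys[j0:j1] - py) ** 2
        mask[i0:i1, j0:j1] |= dx2[:, None] + dy2[None, :] <= radius * radius
    return float(mask.sum()) * resolution * resolution


def projection_area_monte_carlo(
    positions: np.ndarray,
    radii: np.ndarray,
    direction: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Hit-or-miss Monte-Carlo estimate of the projected union-of-disks area.

    Stochastic reference estimator used only to cross-validate the raster
    method; it plays no role in descriptor computation.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    direction = np.asarray(direction, dtype=float)
    pts = _projected_disks(positions, direction)
    rmax = float(radii.max())
    lo = pts.min(axis=0) - rmax
    hi = pts.max(axis=0) + rmax
    box_area = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    hits = 0
    r2 = radii**2
    chunk = 200_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        samples = rng.uniform(lo, hi, size=(m, 2))
        d2 = (
            (samples[:, None, 0] - pts[None, :, 0]) ** 2
            + (samples[:, None, 1] - pts[None, :, 1]) ** 2
        )
        hits += int(np.any(d2 <= r2[None, :], axis=1).sum())
        remaining -= m
    return box_area * hits / n_samples


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions on the upper hemisphere, shape (n, 3).

    Projection areas are antipodally symmetric, so a hemisphere covers all
    distinct viewing directions.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    z = (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def _golden_section(fn, lo: float, hi: float, n_iter: int = 16) -> float:
    """Argmin of a unimodal-ish 1D function on [lo, hi] by golden section."""
    a, b = lo, hi
    c = b - _INV_GOLDEN * (b - a)
    d = a + _INV_GOLDEN * (b - a)
    fc, fd = fn(c), fn(d)
    for _ in range(n_iter):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INV_GOLDEN * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INV_GOLDEN * (b - a)
            fd = fn(d)
    return (a + b) / 2.0


def minimal_projection_area(
    positions: np.ndarray,
    radii: np.ndarray,
    n_directions: int = 256,
    resolution: float = 0.1,
    refine: bool = True,
) -> tuple[float, np.ndarray]:
    """Minimal projection area (A^2) and the minimising direction.

    Scans a Fibonacci hemisphere of ``n_directions`` directions, then (if
    ``refine``) polishes the best direction with alternating golden-section
    line searches along the two tangent-plane angles, with a search window
    matched to the lattice spacing.  The returned MPA never exceeds the
    projected area along any probed direction.
    """
    directions = fibonacci_hemisphere(n_directions)
    areas = [
        projection_area(positions, radii, d, resolution) for d in directions
    ]
    best_idx = int(np.argmin(areas))
    best_area = areas[best_idx]
    best_dir = directions[best_idx]
    if refine and n_directions > 1:
        window = 2.0 * np.sqrt(2.0 / n_directions)  # ~2x lattice spacing, rad
        for _ in range(2):
            u, v = _plane_basis(best_dir)
            for tangent in (u, v):

                def along(theta: float, t=tangent, d0=best_dir) -> float:
                    cand = np.cos(theta) * d0 + np.sin(theta) * t
                    return projection_area(positions, radii, cand, resolution)

                theta_best = _golden_section(along, -window, window)
                cand_dir = (
                    np.cos(theta_best) * best_dir
                    + np.sin(theta_best) * tangent
                )
                cand_dir /= np.linalg.norm(cand_dir)
                cand_area = projection_area(
                    positions, radii, cand_dir, resolution
                )
                if cand_area < best_area:
                    best_area, best_dir = cand_area, cand_dir
            window /= 2.0
    return best_area, best_dir


# ---------------------------------------------------------------------------
# ensemble aggregation


def ensemble_descriptors(
    ensemble: ConformerEnsemble,
    alogp: float,
    settings: DescriptorSettings | None = None,
) -> DescriptorSet:
    """Aggregate per-conformer dipoles and MPAs into a :class:`DescriptorSet`.

    Total and transversal dipoles and the MPA are computed per conformer;
    the descriptor set stores their means and the population standard
    deviation of the MPA (zero for a single conformer).  ``alogp`` is an
    externally supplied hydrophobicity and is copied through.
    """
    settings = settings or DescriptorSettings()
    totals, transversals, mpas = [], [], []
    for conf in ensemble.positions:
        mu = dipole_vector(conf, ensemble.charges, ensemble.masses)
        totals.append(float(np.linalg.norm(mu)))
        axis = main_inertia_axis(conf, ensemble.masses)
        transversals.append(transversal_dipole(mu, axis))
        mpa, _ = minimal_projection_area(
            conf,
            ensemble.radii,
            n_directions=settings.n_directions,
            resolution=settings.grid_resolution,
            refine=settings.refine,
        )
        mpas.append(mpa)
    mpas_arr = np.asarray(mpas)
    return DescriptorSet(
        compound_id=ensemble.compound_id,
        net_charge=net_charge(ensemble),
        total_dipole_mean=float(np.mean(totals)),
        transversal_dipole_mean=float(np.mean(transversals)),
        mpa_mean=float(mpas_arr.mean()),
        mpa_sd=float(mpas_arr.std(ddof=0)),
        alogp=float(alogp),
    )


class ConformerDescriptorCalculator(BaseEstimator):
    """Stateless transformer turning conformer ensembles into a descriptor table.

    Follows the scikit-learn estimator protocol (``get_params`` /
    ``set_params``; ``fit`` is a no-op) so descriptor settings can be tuned
    inside pipelines and grid searches.
    """

    def __init__(
        self,
        n_directions: int = 256,
        grid_resolution: float = 0.1,
        refine: bool = True,
    ):
        self.n_directions = n_directions
        self.grid_resolution = grid_resolution
        self.refine = refine

    def fit(self, X=None, y=None):  # noqa: N803 - sklearn signature
        return self

    def transform(self, ensembles, alogp=None):
        """Compute descriptors for an iterable of ensembles.

        Parameters
        ----------
        ensembles:
            Iterable of :class:`ConformerEnsemble`.
        alogp:
            Mapping ``compound_id -> alogp``; missing ids get NaN.

        Returns
        -------
        pandas.DataFrame
            One row per compound with the canonical descriptor columns.
        """
        import pandas as pd

        settings = DescriptorSettings(
            n_directions=self.n_directions,
            grid_resolution=self.grid_resolution,
            refine=self.refine,
        )
        alogp = alogp or {}
        rows = []
        for ens in ensembles:
            d = ensemble_descriptors(
                ens, alogp.get(ens.compound_id, float("nan")), settings
            )
            rows.append(
                {
                    "id": d.compound_id,
                    "net_charge": d.net_charge,
                    "total_dipole": d.total_dipole_mean,
                    "transversal_dipole": d.transversal_dipole_mean,
                    "mpa_mean": d.mpa_mean,
                    "mpa_sd": d.mpa_sd,
                    "alogp": d.alogp,
                }
            )
        return pd.DataFrame(rows)
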