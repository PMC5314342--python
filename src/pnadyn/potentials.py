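"""Analytic benchmark potentials with quadrature free-energy oracles.

These low-dimensional potentials validate the metadynamics engine: a
particle evolving on them has an exactly computable (by quadrature)
free-energy surface against which hills-based reconstruction and
reweighting are checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB

__all__ = [
    "AnalyticPotential",
    "DoubleWell1D",
    "DoubleWell2D",
    "ParticleSystem",
    "fes_by_quadrature",
]


class AnalyticPotential:
    """Scalar potential on 1 or 2 coordinates, confining at the domain
    boundaries, with an analytic gradient."""

    dimension: int = 1
    #: suggested domain per dimension, nm
    domain: tuple[tuple[float, float], ...] = ((-1.0, 1.0),)

    def energy(self, s: np.ndarray) -> np.ndarray:
        """Energy (kJ/mol) at points s of shape (..., dimension)."""
        raise NotImplementedError

    def gradient(self, s: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class DoubleWell1D(AnalyticPotential):
    """Quartic double well with an optional linear tilt:

        U(x) = h ((x/a)^2 - 1)^2 + c x

    Wells near +-a (nm), barrier height h (kJ/mol) at x=0 for c=0; the
    tilt c (kJ/mol/nm) makes the basins inequivalent.
    """

    h: float = 10.0
    a: float = 0.05
    c: float = 0.0

    def __post_init__(self):
        self.dimension = 1
        w = 2.5 * self.a
        self.domain = ((-w, w),)

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        x = s[..., 0]
        return self.h * ((x / self.a) ** 2 - 1.0) ** 2 + self.c * x

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        x = s[..., 0]
        g = np.empty_like(s)
        g[..., 0] = 4.0 * self.h * x * ((x / self.a) ** 2 - 1.0) / self.a**2 \
            + self.c
        return g


@dataclass
class DoubleWell2D(AnalyticPotential):
    """Two wells along x, harmonic confinement along y, optional tilt:

        U(x, y) = h ((x/a)^2 - 1)^2 + c x + ky/2 y^2
    """

    h: float = 10.0
    a: float = 0.05
    c: float = 0.0
    ky: float = 2000.0

    def __post_init__(self):
        self.dimension = 2
        w = 2.5 * self.a
        wy = 3.0 * np.sqrt(2.494 / self.ky) + 0.02
        self.domain = ((-w, w), (-wy, wy))

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        return (self.h * ((x / self.a) ** 2 - 1.0) ** 2 + self.c * x
                + 0.5 * self.ky * y**2)

    def gradient(self, s):
        s = np.asarray(s, dtype=float)
        x, y = s[..., 0], s[..., 1]
        g = np.empty_like(s)
        g[..., 0] = 4.0 * self.h * x * ((x / self.a) ** 2 - 1.0) / self.a**2 \
            + self.c
        g[..., 1] = self.ky * y
        return g


class ParticleSystem:
    """A single Langevin particle on an analytic potential, exposing the
    same interface as the coarse-grained systems (masses, initial,
    energy_forces).  Unused Cartesian axes are harmonically confined."""

    _CONFINE_K = 100.0

    def __init__(self, potential: AnalyticPotential, mass: float = 1.0,
                 dt: float = 0.002, friction: float = 5.0,
                 start: np.ndarray | None = None):
        from types import SimpleNamespace
        from .core import Conformation

        self.potential = potential
        self.masses = np.array([mass])
        self.params = SimpleNamespace(dt_integration=dt, friction=friction)
        x0 = np.zeros((1, 3))
        if start is None:
            # left well for a double well, origin otherwise
            if hasattr(potential, "a"):
                x0[0, 0] = -potential.a
        else:
            x0[0, :potential.dimension] = np.asarray(start, dtype=float)
        self.initial = Conformation(x0)

    @property
    def n_sites(self) -> int:
        return 1

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_forces(coords)[0]

    def energy_forces(self, coords: np.ndarray):
        d = self.potential.dimension
        s = coords[0, :d]
        e = float(self.potential.energy(s))
        g = self.potential.gradient(s)
        forces = np.zeros_like(coords)
        forces[0, :d] = -g
        rest = coords[0, d:]
        e += 0.5 * self._CONFINE_K * float(np.sum(rest**2))
        forces[0, d:] = -self._CONFINE_K * rest
        return e, forces


def fes_by_quadrature(potential: AnalyticPotential, temperature: float,
                      edges: list[np.ndarray], refine: int = 32):
    """Reference free-energy surface by direct quadrature.

    For each grid cell, F = -kT ln of the Boltzmann integral of
    exp(-U/kT) restricted to the cell (midpoint rule on a refine-fold
    subdivision), min-normalized to 0.  Returns an FESGrid.
    """
    from .metad import FESGrid  # local import to avoid a cycle

    kT = KB * temperature
    edges = [np.asarray(e, dtype=float) for e in edges]
    if len(edges) != potential.dimension:
        raise ValueError("edge list does not match potential dimension")

    def cell_points(e):
        # refine midpoints inside every cell
        widths = np.diff(e)
        offs = (np.arange(refine) + 0.5) / refine
        pts = e[:-1, None] + widths[:, None] * offs[None, :]
        return pts, widths

    if potential.dimension == 1:
        pts, widths = cell_points(edges[0])
        U = potential.energy(pts[..., None])
        z = np.exp(-U / kT).mean(axis=1) * widths
    else:
        ptsx, wx = cell_points(edges[0])
        ptsy, wy = cell_points(edges[1])
        nx, ny = len(wx), len(wy)
        z = np.empty((nx, ny))
        grid_y = ptsy.reshape(ny, refine)
        for i in range(nx):
            X = np.repeat(ptsx[i], grid_y.size).reshape(refine, ny, refine)
            Y = np.broadcast_to(grid_y[None, :, :], X.shape)
            U = potential.energy(np.stack([X, Y], axis=-1))
            z[i] = np.exp(-U / kT).mean(axis=(0, 2)) * wx[i] * wy
    with np.errstate(divide="ignore"):
        F = -kT * np.log(z)
    F -= F.min()
    return FESGrid(edges=edges, values=F, units="kJ/mol")
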