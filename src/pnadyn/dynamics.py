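"""Langevin dynamics for coarse-grained systems.

The integrator is BAOAB splitting (velocity half-kick, half-drift,
Ornstein-Uhlenbeck velocity update, half-drift, half-kick), which samples
the canonical ensemble accurately at moderate time steps.  With zero
friction and zero temperature the scheme reduces to velocity Verlet, used
for the energy-conservation checks.  All randomness flows from a single
integer seed through ``numpy.random.default_rng``; identical seeds give
bitwise-identical trajectories.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import KB
from .core import Conformation, Trajectory

__all__ = ["simulate", "minimize_conformation", "SimulationDiverged"]


class SimulationDiverged(RuntimeError):
    """Raised when coordinates become non-finite during integration."""


def simulate(system, steps: int, temperature: float, seed: int = 0,
             stride: int = 10, start: Conformation | None = None,
             dt: float | None = None, friction: float | None = None,
             bias_force: Callable[[np.ndarray, int], np.ndarray] | None = None,
             callback: Callable[[int, np.ndarray], None] | None = None,
             log_energies: bool = False) -> Trajectory:
    """Run Langevin dynamics and return the stored-frame trajectory.

    Parameters
    ----------
    system:
        Anything with ``masses``, ``initial`` and ``energy_forces``.
    steps:
        Number of integration steps (> 0).
    temperature:
        Thermostat temperature, K.  Zero disables the noise.
    stride:
        Store every ``stride``-th frame (frame 0 included).
    bias_force:
        Optional callable ``(coords, step) -> forces`` added to the
        physical forces (metadynamics hook).
    callback:
        Optional observer called as ``callback(step, coords)`` after each
        step, before frame storage.
    """
    if steps <= 0:
        raise ValueError("steps must be positive")
    params = getattr(system, "params", None)
    if dt is None:
        dt = params.dt_integration if params is not None else 0.01
    if friction is None:
        friction = params.friction if params is not None else 2.0
    x = (start or system.initial).coordinates.copy()
    m = np.asarray(system.masses, dtype=float)[:, None]
    rng = np.random.default_rng(seed)
    v = np.zeros_like(x)
    if temperature > 0:
        v = rng.normal(size=x.shape) * np.sqrt(KB * temperature / m)

    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(max(1.0 - c1 * c1, 0.0) * KB * temperature / m)
    else:
        c1, c2 = 1.0, np.zeros_like(m)

    e, f = system.energy_forces(x)
    if bias_force is not None:
        f = f + bias_force(x, 0)
    frames = [Conformation(x.copy())]
    energies = [(0.5 * float(np.sum(m * v * v)), e)] if log_energies else None
    for step in range(1, steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        if friction > 0:
            v = c1 * v + c2 * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        e, f = system.energy_forces(x)
        if bias_force is not None:
            f = f + bias_force(x, step)
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(x)):
            raise SimulationDiverged(
                f"non-finite coordinates/forces at step {step} "
                f"(t = {step * dt:.3f} ps, T = {temperature} K)")
        v += 0.5 * dt * f / m
        if callback is not None:
            callback(step, x)
        if step % stride == 0:
            frames.append(Conformation(x.copy()))
            if log_energies:
                energies.append((0.5 * float(np.sum(m * v * v)), e))
    return Trajectory(frames=frames, dt=stride * dt,
                      temperature=temperature, seed=seed,
                      energies=(np.asarray(energies)
                                if log_energies else None))


def minimize_conformation(system, conf: Conformation | None = None,
                          maxiter: int = 500) -> Conformation:
    """Local energy minimization (L-BFGS-B on the flattened coordinates)."""
    x0 = (conf or system.initial).coordinates
    shape = x0.shape

    def fg(z):
        e, f = system.energy_forces(z.reshape(shape))
        return e, -f.ravel()

    res = _scipy_minimize(fg, x0.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter})
    return Conformation(res.x.reshape(shape))
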