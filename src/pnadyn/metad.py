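"""Well-tempered metadynamics: hills bookkeeping, bias evaluation,
free-energy reconstruction and reweighting.

A Gaussian hill of height W and per-CV width sigma is deposited every
tau ps at the instantaneous CV position s.  In the well-tempered scheme
the height decays with the bias already accumulated there,

    W_k = W0 exp(-V(s_k, t_k) / (kB DeltaT)),   DeltaT = (gamma - 1) T,

so hills never exceed W0 and shrink at revisited points.  At convergence
the bias tends to -(1 - 1/gamma) F(s), hence the free-energy estimate

    F(s) = -(gamma / (gamma - 1)) V(s, t_end),

min-normalized to zero.

Reweighting onto arbitrary target CVs uses per-frame weights

    w_t  propto  exp(+[V(s_t, t) - c(t)] / kB T)

with the time-dependent offset c(t) computed from the running free-energy
estimate on the biased-CV grid,

    c(t) = kB T ln [ int exp(-F_t/kBT) / int exp(-(F_t + V_t)/kBT) ],

followed by a weighted histogram of the target CVs and
F = -kB T ln(histogram), min-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, KJ_PER_KCAL
from .core import Conformation, Trajectory
from .cvs import CollectiveVariable, CVRecord

__all__ = [
    "Hill",
    "MetadParams",
    "FESGrid",
    "bias_value",
    "bias_gradient",
    "deposit",
    "run_wtmetad",
    "fes_from_hills",
    "reweight",
    "reweight_weights",
    "convert_units",
]

#: hills are truncated beyond this many sigmas (error < 3e-18 W0 per hill)
HILL_CUTOFF_SIGMA = 9.0


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: center and width per CV, height in kJ/mol."""

    time: float
    center: tuple[float, ...]
    sigma: tuple[float, ...]
    height: float

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma):
            raise ValueError("hill widths must be positive")
        if self.height <= 0:
            raise ValueError("hill height must be positive")


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered metadynamics parameters.

    Defaults follow the production protocol for the strand systems: initial
    height 2.5 kJ/mol, widths 0.01 (nm for HT, dimensionless for Stk),
    deposition every 1 ps, bias factor 30.
    """

    w0: float = 2.5
    sigma: tuple[float, ...] = (0.01, 0.01)
    stride_ps: float = 1.0
    gamma: float = 30.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.gamma <= 1:
            raise ValueError("bias factor gamma must exceed 1")
        if self.w0 < 0:
            raise ValueError("initial hill height must be non-negative")
        if self.stride_ps <= 0:
            raise ValueError("deposition stride must be positive")

    @property
    def delta_T(self) -> float:
        return (self.gamma - 1.0) * self.temperature

    @property
    def kT(self) -> float:
        return KB * self.temperature


def _hill_arrays(hills):
    c = np.array([h.center for h in hills], dtype=float)
    s = np.array([h.sigma for h in hills], dtype=float)
    w = np.array([h.height for h in hills], dtype=float)
    return c, s, w


def bias_value(hills, s) -> float | np.ndarray:
    """Total bias V(s) = sum_k W_k exp(-sum_d (s_d - c_kd)^2 / 2 sigma_d^2).

    ``s`` may be a single point (length-d) or an array (..., d).
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    scalar_in = s.ndim == 1
    pts = s[None, :] if scalar_in else s.reshape(-1, s.shape[-1])
    if len(hills) == 0:
        out = np.zeros(pts.shape[0])
    else:
        c, sig, w = _hill_arrays(hills)
        qmax = 0.5 * HILL_CUTOFF_SIGMA**2
        out = np.empty(pts.shape[0])
        block = max(1, 2_000_000 // max(len(hills), 1))
        for lo in range(0, pts.shape[0], block):
            z = (pts[lo:lo + block, None, :] - c[None, :, :]) / sig[None, :, :]
            q = 0.5 * np.sum(z * z, axis=-1)
            out[lo:lo + block] = np.sum(
                np.where(q < qmax, w[None, :] * np.exp(-np.minimum(q, qmax)),
                         0.0), axis=1)
    if scalar_in:
        return float(out[0])
    return out.reshape(s.shape[:-1])


def bias_gradient(hills, s) -> np.ndarray:
    """Analytic gradient of the bias at a single point s (per-CV)."""
    s = np.asarray(s, dtype=float)
    if len(hills) == 0:
        return np.zeros_like(s)
    c, sig, w = _hill_arrays(hills)
    z = (s[None, :] - c) / sig
    q = 0.5 * np.sum(z * z, axis=-1)
    g = w * np.exp(-np.minimum(q, 700.0))
    return -np.sum(g[:, None] * z / sig, axis=0)


def deposit(hills: list[Hill], s, params: MetadParams,
            time: float = 0.0) -> Hill:
    """Deposit a well-tempered hill at s and append it to ``hills``."""
    v = bias_value(hills, s)
    w = params.w0 * np.exp(-v / (KB * params.delta_T))
    hill = Hill(time=time, center=tuple(np.atleast_1d(s)),
                sigma=tuple(params.sigma), height=float(w))
    hills.append(hill)
    return hill


@dataclass
class FESGrid:
    """Free energy on a regular cell-centered grid over 1 or 2 CVs,
    min-normalized to 0."""

    edges: list[np.ndarray]
    values: np.ndarray
    units: str = "kJ/mol"

    def __post_init__(self):
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        self.values = np.asarray(self.values, dtype=float)
        expect = tuple(len(e) - 1 for e in self.edges)
        if self.values.shape != expect:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{expect}")

    @property
    def dimension(self) -> int:
        return len(self.edges)

    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    def mesh(self) -> np.ndarray:
        """Cell-center points, shape grid_shape + (d,)."""
        cs = self.centers()
        if self.dimension == 1:
            return cs[0][:, None]
        X, Y = np.meshgrid(cs[0], cs[1], indexing="ij")
        return np.stack([X, Y], axis=-1)

    def normalized(self) -> "FESGrid":
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("FES has no finite values")
        return FESGrid(self.edges, self.values - self.values[finite].min(),
                       self.units)


def default_grid(lo: float, hi: float, bins: int = 200) -> np.ndarray:
    return np.linspace(lo, hi, bins + 1)


def fes_from_hills(hills, edges, params: MetadParams,
                   average_fraction: float = 0.0) -> FESGrid:
    """Free energy from the deposited bias: F = -(gamma/(gamma-1)) V,
    min-normalized to 0.  Empty hills give a flat zero grid.

    With ``average_fraction`` > 0 the running final-bias estimate is
    averaged over the trailing fraction of depositions, which suppresses
    the O(kBT) late-time fluctuation of the plain final-bias form; the
    average reduces to a per-hill reweighting of the Gaussian sum.
    """
    shape = tuple(len(np.asarray(e)) - 1 for e in edges)
    grid = FESGrid(edges=list(edges), values=np.zeros(shape))
    K = len(hills)
    if K == 0:
        return grid
    pts = grid.mesh()
    if average_fraction > 0.0:
        from dataclasses import replace as _replace

        j0 = max(int(np.floor(K * (1.0 - average_fraction))), 0)
        n_avg = K - j0
        # mean over j in (j0, K] of V_j = sum_k w_k g_k with
        # w_k = #(j >= max(k, j0+1)) / n_avg
        scaled = [_replace(h, height=h.height
                           * (K - max(k + 1, j0 + 1) + 1) / n_avg)
                  for k, h in enumerate(hills)]
        v = bias_value(scaled, pts)
    else:
        v = bias_value(hills, pts)
    fac = params.gamma / (params.gamma - 1.0)
    grid.values = -fac * v
    return grid.normalized()


def convert_units(fes: FESGrid, to: str) -> FESGrid:
    """Convert an FES between kJ/mol and kcal/mol (factor 4.184 exactly)."""
    if to not in ("kJ/mol", "kcal/mol"):
        raise ValueError(f"unknown unit {to!r}")
    if to == fes.units:
        return FESGrid(fes.edges, fes.values.copy(), fes.units)
    factor = 1.0 / KJ_PER_KCAL if to == "kcal/mol" else KJ_PER_KCAL
    return FESGrid(fes.edges, fes.values * factor, to)


# ---------------------------------------------------------------------------
# biased dynamics


def run_wtmetad(system, cvs: list[CollectiveVariable], params: MetadParams,
                steps: int, seed: int = 0, stride: int = 10,
                dt: float | None = None, friction: float | None = None):
    """Well-tempered metadynamics on a system, biasing the given CVs.

    Returns ``(trajectory, hills, records)`` where records hold one
    CVRecord per stored frame with the instantaneous bias.  Hills are
    deposited every ``round(stride_ps / dt)`` integration steps.
    """
    from .dynamics import simulate

    sys_params = getattr(system, "params", None)
    if dt is None:
        dt = sys_params.dt_integration if sys_params is not None else 0.01
    dep_stride = max(1, int(round(params.stride_ps / dt)))

    hills: list[Hill] = []
    records: list[CVRecord] = []
    names = [cv.name for cv in cvs]
    state = {"s": None, "v": 0.0}
    d = len(cvs)
    sig = np.asarray(params.sigma[:d], dtype=float)
    inv2sig2 = 1.0 / (2.0 * sig * sig)
    kbdT = KB * params.delta_T
    qmax = 0.5 * HILL_CUTOFF_SIGMA**2
    # growing hill arrays, kept in sync with the hills list for speed
    cap = 1024
    c_arr = np.empty((cap, d))
    w_arr = np.empty(cap)

    def eval_bias(s):
        """(V, dV/ds) against the cached hill arrays."""
        k = len(hills)
        if k == 0:
            return 0.0, np.zeros(d)
        z = (s[None, :] - c_arr[:k]) * inv2sig2[None, :]
        q = np.einsum("kd,kd->k", s[None, :] - c_arr[:k], z)
        g = np.where(q < qmax, w_arr[:k] * np.exp(-np.minimum(q, qmax)), 0.0)
        v = float(g.sum())
        dv = -2.0 * np.einsum("k,kd->d", g, z)
        return v, dv

    def bias_force(coords, step):
        nonlocal c_arr, w_arr
        vals = np.empty(d)
        grads = []
        for i, cv in enumerate(cvs):
            vals[i], g = cv.value_and_gradient(coords)
            grads.append(g)
        if params.w0 > 0 and step > 0 and step % dep_stride == 0:
            v_here = eval_bias(vals)[0]
            w = params.w0 * np.exp(-v_here / kbdT)
            k = len(hills)
            if k >= c_arr.shape[0]:
                c_arr = np.concatenate([c_arr, np.empty_like(c_arr)])
                w_arr = np.concatenate([w_arr, np.empty_like(w_arr)])
            c_arr[k] = vals
            w_arr[k] = w
            hills.append(Hill(time=step * dt, center=tuple(vals),
                              sigma=tuple(sig), height=float(w)))
        state["s"] = vals
        v, dvds = eval_bias(vals)
        state["v"] = v
        f = np.zeros_like(coords)
        for i, g in enumerate(grads):
            if dvds[i] != 0.0:
                f -= dvds[i] * g
        if not np.all(np.isfinite(f)):
            raise RuntimeError(
                f"non-finite bias force at step {step}, CVs {vals}")
        return f

    def observer(step, coords):
        if step % stride == 0:
            records.append(CVRecord(
                time=step * dt,
                values=dict(zip(names, map(float, state["s"]))),
                bias=state["v"]))

    # frame 0 record (simulate's callback starts at step 1)
    x0 = system.initial.coordinates
    vals0 = {cv.name: cv.value(x0) for cv in cvs}
    records.append(CVRecord(time=0.0, values=vals0, bias=0.0))

    traj = simulate(system, steps=steps, temperature=params.temperature,
                    seed=seed, stride=stride, dt=dt, friction=friction,
                    bias_force=bias_force, callback=observer)
    return traj, hills, records


# ---------------------------------------------------------------------------
# reweighting


def _running_offsets(hills, frame_times, bias_edges, params: MetadParams):
    """c(t) at each frame time, from the running hills-based FES on the
    biased-CV grid (c is stepwise constant between depositions)."""
    kT = params.kT
    fac = params.gamma / (params.gamma - 1.0)
    shape_grid = FESGrid(edges=list(bias_edges),
                         values=np.zeros(tuple(len(np.asarray(e)) - 1
                                               for e in bias_edges)))
    pts = shape_grid.mesh()
    flat_pts = pts.reshape(-1, pts.shape[-1])
    V = np.zeros(flat_pts.shape[0])
    c_of_t = np.empty(len(frame_times))
    times = np.asarray(frame_times, dtype=float)

    def offset():
        F = -fac * V
        F = F - F.min()
        num = np.exp(-F / kT).sum()
        den = np.exp(-(F + V - V.max()) / kT).sum()
        # den carries exp(V.max()/kT) factored out:
        return kT * (np.log(num) - np.log(den)) + V.max()

    k = 0
    hlist = sorted(hills, key=lambda h: h.time)
    cur = offset()
    for i, t in enumerate(times):
        while k < len(hlist) and hlist[k].time <= t:
            h = hlist[k]
            z = (flat_pts - np.asarray(h.center)) / np.asarray(h.sigma)
            V += h.height * np.exp(-np.minimum(0.5 * np.sum(z * z, -1), 700.0))
            k += 1
            cur = None
        if cur is None:
            cur = offset()
        c_of_t[i] = cur
    return c_of_t


def reweight_weights(frame_times, frame_bias, hills, bias_edges,
                     params: MetadParams) -> np.ndarray:
    """Normalized per-frame reweighting weights w_t.

    ``frame_bias`` is the logged instantaneous bias V(s_t, t) per frame.
    """
    frame_bias = np.asarray(frame_bias, dtype=float)
    if len(hills) == 0 or params.w0 == 0:
        w = np.ones_like(frame_bias)
        return w / w.sum()
    c = _running_offsets(hills, frame_times, bias_edges, params)
    logw = (frame_bias - c) / params.kT
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w * w))


def reweight(frame_times, frame_bias, hills, bias_edges,
             params: MetadParams, targets, target_edges,
             min_ess: float = 10.0) -> FESGrid:
    """Reweighted free energy of arbitrary target CVs.

    ``targets`` is (n_frames, d) target-CV values per stored frame.
    Warns (via ``warnings``) when the effective sample size falls below
    ``min_ess``.
    """
    import warnings

    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    w = reweight_weights(frame_times, frame_bias, hills, bias_edges, params)
    if effective_sample_size(w) < min_ess:
        warnings.warn("degenerate reweighting weights: effective sample "
                      f"size {effective_sample_size(w):.1f} < {min_ess}")
    edges = [np.asarray(e, dtype=float) for e in target_edges]
    hist, _ = np.histogramdd(targets, bins=edges, weights=w)
    with np.errstate(divide="ignore"):
        F = -params.kT * np.log(hist)
    grid = FESGrid(edges=edges, values=F)
    return grid.normalized()
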