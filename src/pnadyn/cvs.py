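"""Collective variables for strand conformational analysis.

Implements the head-to-tail distance (HT) between first- and last-monomer
centers of mass, a base-stacking score built from a rational switching
function of the base-plane centroid distance times the squared cosine of
the angle between the base-plane normals, its sequential (SStk) and
non-sequential (NStk) decomposition, a coordination-style smooth contact
count, and signed dihedral angles.

All CVs are differentiable in the coordinates; value-and-gradient forms
are provided because the same functions serve both as analysis observables
and as biasing targets (and, for stacking, as the attractive part of the
coarse-grained force field).

The per-pair stacking score is

    s_ij = f(d_ij) * cos^2(theta_ij)

with d_ij the distance between base-plane centroids, theta_ij the angle
between the (unoriented) plane normals and f the rational switch

    f(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m),   m > n even,

which is 1 at r=0, n/m at r=r0 (continuous limit) and decays to 0.
cos^2 rather than |cos| keeps the score face-agnostic and differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import Conformation, StrandTopology, DuplexTopology, Trajectory

__all__ = [
    "SwitchingParams",
    "CVRecord",
    "rational_switch",
    "ht_distance",
    "pair_stacking",
    "stk",
    "sstk",
    "nstk",
    "coordination",
    "dihedral",
    "cv_series",
    "CollectiveVariable",
    "HeadTailCV",
    "StackingCV",
    "CoordinateCV",
    "stacking_batch",
    "DEFAULT_STACK_SWITCH",
    "DEFAULT_COORD_SWITCH",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function.

    r0 in nm; n, m even integers with m > n so the function decreases
    monotonically from 1 (r=0) through n/m (r=r0) to 0 (r -> inf).
    """

    r0: float = 0.4
    n: int = 6
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n % 2 or self.m % 2:
            raise ValueError("n and m must be even")
        if self.m <= self.n:
            raise ValueError("m must exceed n")


#: stacking dialect: well inside the switch at base contact (< 0.3 nm)
DEFAULT_STACK_SWITCH = SwitchingParams(r0=0.4, n=6, m=12)
#: coordination (H-bond proxy) dialect
DEFAULT_COORD_SWITCH = SwitchingParams(r0=0.3, n=6, m=12)

_SINGULAR_HALFWIDTH = 1e-7


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (avoids np.cross call overhead)."""
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _rownorm(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("...i,...i->...", a, a))


def scatter_add(g: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    """Accumulate contrib rows into g at (possibly repeated) site indices.

    bincount-based: substantially faster than np.add.at for the small,
    dense index sets that arise here.
    """
    flat = idx.ravel()
    c = contrib.reshape(-1, 3)
    n = g.shape[0]
    for k in range(3):
        g[:, k] += np.bincount(flat, weights=c[:, k], minlength=n)


def rational_switch(r, params: SwitchingParams, deriv: bool = False):
    """Rational switch f(r) (and optionally df/dr) for scalar or array r.

    The removable singularity at r = r0 is filled with the continuous
    limit n/m and its limiting slope (n/m)(n-m)/(2 r0).
    """
    r = np.asarray(r, dtype=float)
    # far beyond the switch both value and slope vanish; clipping avoids
    # overflow in the high powers for fully separated strands
    x = np.minimum(r / params.r0, 1e3)
    n, m = params.n, params.m
    xn = x**n
    xm = x**m
    u = 1.0 - xn
    v = 1.0 - xm
    near = np.abs(x - 1.0) < _SINGULAR_HALFWIDTH
    safe_v = np.where(near, 1.0, v)
    f = np.where(near, n / m, u / safe_v)
    if not deriv:
        return f if f.ndim else float(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        du = -n * x ** (n - 1)
        dv = -m * x ** (m - 1)
        dfdx = np.where(near,
                        (n / m) * (n - m) / 2.0,
                        (du * safe_v - u * dv) / safe_v**2)
    dfdr = dfdx / params.r0
    if f.ndim:
        return f, dfdr
    return float(f), float(dfdr)


@dataclass
class CVRecord:
    """One stored frame's CV values (plus optional instantaneous bias)."""

    time: float
    values: dict[str, float]
    bias: float | None = None


# ---------------------------------------------------------------------------
# head-to-tail distance


def _monomer_com(coords: np.ndarray, sites: Sequence[int],
                 masses: np.ndarray | None = None) -> np.ndarray:
    pts = coords[list(sites)]
    if masses is None:
        return pts.mean(axis=0)
    w = masses[list(sites)]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def ht_distance(conf: Conformation, topo: StrandTopology,
                masses: np.ndarray | None = None) -> float:
    """Distance (nm) between the centers of mass of the first and last
    monomers of a strand."""
    if topo.length < 2:
        raise ValueError("head-to-tail distance needs at least 2 monomers")
    c0 = _monomer_com(conf.coordinates, topo.monomer_sites(0), masses)
    c1 = _monomer_com(conf.coordinates,
                      topo.monomer_sites(topo.length - 1), masses)
    return float(np.linalg.norm(c1 - c0))


# ---------------------------------------------------------------------------
# stacking


def _plane_normals(coords: np.ndarray, trips: np.ndarray):
    """Centroids, unit normals and the raw cross products of base-plane
    triplets.  trips: (P, 3) integer site indices."""
    p1 = coords[trips[:, 0]]
    p2 = coords[trips[:, 1]]
    p3 = coords[trips[:, 2]]
    cent = (p1 + p2 + p3) / 3.0
    a = p2 - p1
    b = p3 - p1
    u = _cross(a, b)
    return cent, a, b, u, _rownorm(u)


def stacking_batch(coords: np.ndarray, trips_i: np.ndarray,
                   trips_j: np.ndarray, params: SwitchingParams,
                   grad: bool = False,
                   weights: np.ndarray | None = None):
    """Vectorized per-pair stacking scores s_ij (and the gradient of the
    weighted sum w . s with respect to all coordinates).

    Used both by the stacking CVs (weights=1) and by the stacking energy
    term of the coarse-grained model (weights=-epsilon).  Degenerate
    (collinear) triplets raise in the plain-value path; the gradient path
    clamps the normal length to stay finite under dynamics.
    """
    trips_i = np.asarray(trips_i, dtype=int)
    trips_j = np.asarray(trips_j, dtype=int)
    ci, ai, bi, ui, uin = _plane_normals(coords, trips_i)
    cj, aj, bj, uj, ujn = _plane_normals(coords, trips_j)
    if grad:
        uin = np.maximum(uin, 1e-10)
        ujn = np.maximum(ujn, 1e-10)
    elif np.any(uin < 1e-12) or np.any(ujn < 1e-12):
        raise ValueError("degenerate (collinear) base-plane triplet")
    ni = ui / uin[:, None]
    nj = uj / ujn[:, None]
    delta = ci - cj
    d = _rownorm(delta)
    d_safe = np.maximum(d, 1e-12)
    c = np.einsum("ij,ij->i", ni, nj)
    if not grad:
        f = rational_switch(d, params)
        return np.atleast_1d(f) * c**2

    f, fp = rational_switch(d, params, deriv=True)
    f = np.atleast_1d(f)
    fp = np.atleast_1d(fp)
    s = f * c**2
    w = np.ones_like(s) if weights is None else np.asarray(weights, float)

    g = np.zeros_like(coords)
    # distance part: d(w s)/dcent_i = w f'(d) c^2 * delta/d, split 1/3 each
    gc = (w * fp * c**2 / d_safe)[:, None] * delta / 3.0
    # orientation part: d(w s)/dc = 2 w f c; chain through unit normals
    dsdc = 2.0 * w * f * c
    gui = dsdc[:, None] * (nj - c[:, None] * ni) / uin[:, None]
    guj = dsdc[:, None] * (ni - c[:, None] * nj) / ujn[:, None]
    # u = a x b:  dE/da = b x g_u,  dE/db = g_u x a
    dEda_i = _cross(bi, gui)
    dEdb_i = _cross(gui, ai)
    dEda_j = _cross(bj, guj)
    dEdb_j = _cross(guj, aj)
    idx = np.concatenate([trips_i, trips_j], axis=1)  # (P, 6)
    contrib = np.stack([
        gc - dEda_i - dEdb_i,
        gc + dEda_i,
        gc + dEdb_i,
        -gc - dEda_j - dEdb_j,
        -gc + dEda_j,
        -gc + dEdb_j,
    ], axis=1)  # (P, 6, 3)
    scatter_add(g, idx, contrib)
    return s, g


def _strand_triplets(topo: StrandTopology) -> np.ndarray:
    return np.array([topo.plane_triplet(i) for i in range(topo.length)],
                    dtype=int)


def _pair_lists(L: int, which: str) -> tuple[np.ndarray, np.ndarray]:
    if which == "sstk":
        ii = np.arange(L - 1)
        jj = ii + 1
    elif which == "nstk":
        ii, jj = np.triu_indices(L, k=2)
    else:  # all unordered pairs, sequential included
        ii, jj = np.triu_indices(L, k=1)
    return ii, jj


def pair_stacking(conf: Conformation, topo: StrandTopology, i: int, j: int,
                  params: SwitchingParams = DEFAULT_STACK_SWITCH) -> float:
    """Stacking score of bases i and j of one strand, in [0, 1]."""
    if i == j:
        raise ValueError("pair_stacking requires i != j")
    trips = _strand_triplets(topo)
    s = stacking_batch(conf.coordinates, trips[[i]], trips[[j]], params)
    return float(s[0])


def _stk_sum(conf: Conformation, topo: StrandTopology, which: str,
             params: SwitchingParams) -> float:
    if topo.length < 2:
        raise ValueError("stacking sums need at least 2 bases")
    trips = _strand_triplets(topo)
    ii, jj = _pair_lists(topo.length, which)
    if len(ii) == 0:
        return 0.0
    s = stacking_batch(conf.coordinates, trips[ii], trips[jj], params)
    return float(s.sum())


def stk(conf, topo, params: SwitchingParams = DEFAULT_STACK_SWITCH) -> float:
    """Total stacking: sum of s_ij over all unordered base pairs."""
    return _stk_sum(conf, topo, "stk", params)


def sstk(conf, topo, params: SwitchingParams = DEFAULT_STACK_SWITCH) -> float:
    """Sequential stacking: sum over (i, i+1) pairs only."""
    return _stk_sum(conf, topo, "sstk", params)


def nstk(conf, topo, params: SwitchingParams = DEFAULT_STACK_SWITCH) -> float:
    """Non-sequential stacking: stk - sstk, summed directly over |i-j|>=2."""
    return _stk_sum(conf, topo, "nstk", params)


# ---------------------------------------------------------------------------
# coordination


def coordination(conf: Conformation, site_pairs: Sequence[tuple[int, int]],
                 params: SwitchingParams = DEFAULT_COORD_SWITCH) -> float:
    """Smooth contact count: sum of the rational switch of inter-site
    distance over a list of site pairs."""
    pairs = np.asarray(site_pairs, dtype=int)
    if pairs.size == 0:
        raise ValueError("empty site-pair list")
    delta = conf.coordinates[pairs[:, 0]] - conf.coordinates[pairs[:, 1]]
    d = np.linalg.norm(delta, axis=1)
    return float(np.sum(rational_switch(d, params)))


# ---------------------------------------------------------------------------
# dihedral


def dihedral(conf: Conformation, sites: Sequence[int]) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) over four sites,
    IUPAC convention (cis = 0)."""
    if len(sites) != 4:
        raise ValueError("dihedral needs exactly four sites")
    p = conf.coordinates[list(sites)]
    b0 = p[0] - p[1]
    b1 = p[2] - p[1]
    b2 = p[3] - p[2]
    n1 = np.linalg.norm(b1)
    if n1 < 1e-12:
        raise ValueError("degenerate dihedral: coincident central sites")
    b1u = b1 / n1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise ValueError("degenerate dihedral: collinear sites")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# CV objects (value + gradient) for biasing


class CollectiveVariable:
    """A differentiable scalar function of the full coordinate array."""

    name: str = "cv"

    def value(self, coords: np.ndarray) -> float:
        raise NotImplementedError

    def value_and_gradient(self, coords: np.ndarray):
        raise NotImplementedError


class HeadTailCV(CollectiveVariable):
    """Head-to-tail monomer center-of-mass distance of one strand."""

    def __init__(self, topo: StrandTopology, name: str = "ht"):
        if topo.length < 2:
            raise ValueError("head-to-tail distance needs >= 2 monomers")
        self.topo = topo
        self.name = name
        self._head = np.array(topo.monomer_sites(0), dtype=int)
        self._tail = np.array(topo.monomer_sites(topo.length - 1), dtype=int)

    def value(self, coords: np.ndarray) -> float:
        delta = coords[self._tail].mean(0) - coords[self._head].mean(0)
        return float(np.linalg.norm(delta))

    def value_and_gradient(self, coords: np.ndarray):
        delta = coords[self._tail].mean(0) - coords[self._head].mean(0)
        d = float(np.linalg.norm(delta))
        g = np.zeros_like(coords)
        if d > 1e-12:
            e = delta / d
            g[self._tail] += e / len(self._tail)
            g[self._head] -= e / len(self._head)
        return d, g


class StackingCV(CollectiveVariable):
    """Stk, SStk or NStk of one strand as a biasable CV."""

    def __init__(self, topo: StrandTopology, which: str = "stk",
                 params: SwitchingParams = DEFAULT_STACK_SWITCH,
                 name: str | None = None):
        if which not in ("stk", "sstk", "nstk"):
            raise ValueError(f"unknown stacking mode {which!r}")
        self.topo = topo
        self.which = which
        self.params = params
        self.name = name or which
        trips = _strand_triplets(topo)
        ii, jj = _pair_lists(topo.length, which)
        self._ti = trips[ii]
        self._tj = trips[jj]

    def value(self, coords: np.ndarray) -> float:
        s = stacking_batch(coords, self._ti, self._tj, self.params)
        return float(s.sum())

    def value_and_gradient(self, coords: np.ndarray):
        s, g = stacking_batch(coords, self._ti, self._tj, self.params,
                              grad=True)
        return float(s.sum()), g


class CoordinateCV(CollectiveVariable):
    """One Cartesian coordinate of one site — the identity CV used when
    biasing a particle on an analytic benchmark potential."""

    def __init__(self, site: int = 0, axis: int = 0, name: str | None = None):
        self.site = site
        self.axis = axis
        self.name = name or f"x{axis}"

    def value(self, coords: np.ndarray) -> float:
        return float(coords[self.site, self.axis])

    def value_and_gradient(self, coords: np.ndarray):
        g = np.zeros_like(coords)
        g[self.site, self.axis] = 1.0
        return float(coords[self.site, self.axis]), g


# ---------------------------------------------------------------------------
# time series


def cv_series(traj: Trajectory,
              cvs: dict[str, Callable[[Conformation], float]]) -> list[CVRecord]:
    """Evaluate named CV callables on every stored frame.

    Deterministic: one record per frame, names in the given order.
    """
    if len(set(cvs)) != len(cvs):
        raise ValueError("duplicate CV names")
    out = []
    for k, frame in enumerate(traj.frames):
        out.append(CVRecord(time=k * traj.dt,
                            values={name: float(fn(frame))
                                    for name, fn in cvs.items()}))
    return out
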