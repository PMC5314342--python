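"""Coarse-grained strand and duplex systems.

Each monomer is four beads: one backbone bead and a rigid-ish triplet of
sites spanning the aromatic base plane.  The effective potential has

* harmonic bonds along the backbone and within each monomer (attaching the
  base triangle to its backbone bead),
* a stacking attraction between bases of the same strand, using the same
  switch-times-cos^2 form as the stacking CV (single source of geometric
  truth) scaled by a well depth,
* for duplexes, a Watson-Crick pairing attraction between base-plane
  centroids of mapped pairs, scaled by the pair's H-bond multiplicity
  (3 for G:C, 2 for A:U), so a G:C contact is 3/2 as deep as an A:U one,
* soft excluded volume between backbone beads and between base centroids,
* optionally a backbone torsional bias toward the ideal-helix dihedral,
  standing in for the helical pre-organization induced by a gamma-carbon
  backbone substituent; zero bias strength recovers the unmodified model
  exactly.

Solvent and electrostatics are implicit in the effective well depths; all
parameters are in reduced units (nm, ps, kJ/mol, amu).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (Conformation, DuplexTopology, StrandTopology,
                   build_strand, SITES_PER_MONOMER)
from .cvs import (SwitchingParams, rational_switch, stacking_batch,
                  dihedral, scatter_add, _cross, _rownorm)

__all__ = [
    "CoarseModelParams",
    "WatsonCrickPairing",
    "CGSystem",
    "make_ss_system",
    "make_duplex_system",
    "make_distorted_duplex",
    "ideal_helix_conformation",
    "ideal_duplex_conformation",
    "random_coil_conformation",
    "hb_site_pairs",
]


@dataclass(frozen=True)
class CoarseModelParams:
    """Force-field and geometry parameters of the coarse-grained model.

    Energies kJ/mol, lengths nm, times ps, masses amu.  The defaults were
    tuned once so that the hexamer duplex is stable near 300 K and
    dissociates on the accessible timescale in the 340-400 K scan window;
    they are model conditions, not fitted quantities.
    """

    #: harmonic bond stiffness, kJ/mol/nm^2
    bond_k: float = 1000.0
    #: base-plane triangle rigidity, kJ/mol/nm^2
    plane_k: float = 2000.0
    #: stacking well depth per fully stacked pair, kJ/mol
    stack_eps: float = 6.0
    stack_switch: SwitchingParams = field(
        default_factory=lambda: SwitchingParams(r0=0.4, n=6, m=12))
    #: pairing well depth per canonical H-bond, kJ/mol
    hb_eps: float = 2.5
    #: nearest-neighbour pairing cooperativity (zipper coupling), kJ/mol
    coop_J: float = 8.0
    hb_switch: SwitchingParams = field(
        default_factory=lambda: SwitchingParams(r0=0.35, n=6, m=12))
    #: soft excluded volume (harmonic for r < sigma)
    ev_k: float = 200.0
    ev_sigma_backbone: float = 0.40
    ev_sigma_base: float = 0.25
    #: torsional bias strength kappa_gamma, kJ/mol (gamma-PNA only)
    gamma_bias_k: float = 25.0
    #: gamma base-orientation bias (normal-along-chain), kJ/mol
    gamma_orient_k: float = 10.0
    #: gamma sequential-stacking well deepening, kJ/mol per (i, i+1) pair
    gamma_stack_bonus: float = 5.0
    #: bias target; None = the ideal-helix backbone dihedral
    gamma_target_deg: float | None = None
    #: Langevin friction, 1/ps
    friction: float = 2.0
    #: integration step, ps
    dt_integration: float = 0.04
    #: per-site mass, amu
    mass: float = 25.0
    # ideal helix geometry
    helix_rise: float = 0.40
    helix_twist_deg: float = 20.0
    r_backbone: float = 0.45
    r_base: float = 0.14
    plane_radius: float = 0.08

    def __post_init__(self):
        for name in ("bond_k", "plane_k", "stack_eps", "hb_eps", "ev_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gamma_bias_k < 0:
            raise ValueError("gamma_bias_k must be non-negative")


# ---------------------------------------------------------------------------
# force-field terms


class HarmonicBonds:
    def __init__(self, pairs, k, r0):
        self.pairs = np.asarray(pairs, dtype=int)
        self.k = np.asarray(k, dtype=float)
        self.r0 = np.asarray(r0, dtype=float)

    def energy_forces(self, coords, forces=None):
        delta = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        d = _rownorm(delta)
        dev = d - self.r0
        e = 0.5 * float(np.sum(self.k * dev**2))
        if forces is None:
            return e
        g = (self.k * dev / np.maximum(d, 1e-12))[:, None] * delta
        scatter_add(forces, self.pairs, np.stack([-g, g], axis=1))
        return e


class StackingTerm:
    """E = -eps * sum s_ij over listed same-strand base pairs."""

    def __init__(self, trips_i, trips_j, eps, switch):
        self.trips_i = np.asarray(trips_i, dtype=int)
        self.trips_j = np.asarray(trips_j, dtype=int)
        self.eps = float(eps)
        self.switch = switch

    def energy_forces(self, coords, forces=None):
        if forces is None:
            s = stacking_batch(coords, self.trips_i, self.trips_j,
                               self.switch, grad=True)[0]
            return -self.eps * float(s.sum())
        s, g = stacking_batch(coords, self.trips_i, self.trips_j,
                              self.switch, grad=True)
        forces += self.eps * g
        return -self.eps * float(s.sum())


class PairingTerm:
    """Watson-Crick pairing: E = -sum_p w_p * f(d_p) with d_p the distance
    between the paired bases' plane centroids and w_p = eps_hb * hbonds."""

    def __init__(self, trips_a, trips_b, weights, switch):
        self.trips_a = np.asarray(trips_a, dtype=int)
        self.trips_b = np.asarray(trips_b, dtype=int)
        self.weights = np.asarray(weights, dtype=float)
        self.switch = switch

    def centroid_distances(self, coords):
        ca = coords[self.trips_a].mean(axis=1)
        cb = coords[self.trips_b].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=1)

    def energy_forces(self, coords, forces=None):
        ca = coords[self.trips_a].mean(axis=1)
        cb = coords[self.trips_b].mean(axis=1)
        delta = ca - cb
        d = _rownorm(delta)
        f, fp = rational_switch(d, self.switch, deriv=True)
        f = np.atleast_1d(f)
        fp = np.atleast_1d(fp)
        e = -float(np.sum(self.weights * f))
        if forces is None:
            return e
        # force = -dE/dx; dE/dcent_a = -w f'(d) delta/d
        g = (self.weights * fp / np.maximum(d, 1e-12))[:, None] * delta / 3.0
        idx = np.concatenate([self.trips_a, self.trips_b], axis=1)
        contrib = np.stack([g, g, g, -g, -g, -g], axis=1)
        scatter_add(forces, idx, contrib)
        return e


class WatsonCrickPairing(PairingTerm):
    """Fused pairing + nearest-neighbour cooperativity: one switch
    evaluation serves both E = -sum w_p f(d_p) and the zipper coupling
    -J sum f(d_i) f(d_{i+1})."""

    def __init__(self, trips_a, trips_b, weights, J, switch):
        super().__init__(trips_a, trips_b, weights, switch)
        self.J = float(J)

    def energy_forces(self, coords, forces=None):
        ca = coords[self.trips_a].mean(axis=1)
        cb = coords[self.trips_b].mean(axis=1)
        delta = ca - cb
        d = _rownorm(delta)
        f, fp = rational_switch(d, self.switch, deriv=True)
        f = np.atleast_1d(f)
        fp = np.atleast_1d(fp)
        e = -float(np.sum(self.weights * f))
        neigh = np.zeros_like(f)
        if self.J != 0.0 and len(f) >= 2:
            e -= self.J * float(np.sum(f[:-1] * f[1:]))
            neigh[:-1] += f[1:]
            neigh[1:] += f[:-1]
        if forces is None:
            return e
        coef = self.weights + self.J * neigh
        g = (coef * fp / np.maximum(d, 1e-12))[:, None] * delta / 3.0
        idx = np.concatenate([self.trips_a, self.trips_b], axis=1)
        scatter_add(forces, idx, np.stack([g, g, g, -g, -g, -g], axis=1))
        return e


class PairingCooperativity:
    """Nearest-neighbour zipper coupling between adjacent Watson-Crick
    pairs: E = -J * sum_i f(d_i) f(d_{i+1}) with f the pairing switch.

    A central pair partakes in two coupling terms, a terminal pair in one,
    which is what makes duplex ends fray first.
    """

    def __init__(self, trips_a, trips_b, J, switch):
        # trips ordered along the duplex
        self.trips_a = np.asarray(trips_a, dtype=int)
        self.trips_b = np.asarray(trips_b, dtype=int)
        self.J = float(J)
        self.switch = switch

    def energy_forces(self, coords, forces=None):
        if self.J == 0.0 or len(self.trips_a) < 2:
            return 0.0
        ca = coords[self.trips_a].mean(axis=1)
        cb = coords[self.trips_b].mean(axis=1)
        delta = ca - cb
        d = _rownorm(delta)
        f, fp = rational_switch(d, self.switch, deriv=True)
        f = np.atleast_1d(f)
        fp = np.atleast_1d(fp)
        e = -self.J * float(np.sum(f[:-1] * f[1:]))
        if forces is None:
            return e
        neigh = np.zeros_like(f)
        neigh[:-1] += f[1:]
        neigh[1:] += f[:-1]
        # dE/dd_i = -J * (f_{i-1} + f_{i+1}) * f'(d_i)
        g = (self.J * neigh * fp / np.maximum(d, 1e-12))[:, None] \
            * delta / 3.0
        idx = np.concatenate([self.trips_a, self.trips_b], axis=1)
        scatter_add(forces, idx, np.stack([g, g, g, -g, -g, -g], axis=1))
        return e


class BaseOrientationBias:
    """Aligns base-plane normals with the local backbone tangent:
    E = kappa * sum_i (1 - (n_i . t_i)^2) with t_i the unit vector from
    backbone bead i to bead i+1.

    Part of the gamma-modification stand-in: the substituent restricts
    rotation about the backbone-base linker, pre-organizing bases into
    the stacked helical arrangement (normals along the helix axis).
    """

    def __init__(self, trips, bb_from, bb_to, kappa):
        self.trips = np.asarray(trips, dtype=int)
        self.bb_from = np.asarray(bb_from, dtype=int)
        self.bb_to = np.asarray(bb_to, dtype=int)
        self.kappa = float(kappa)

    def energy_forces(self, coords, forces=None):
        if self.kappa == 0.0 or len(self.trips) == 0:
            return 0.0
        p1 = coords[self.trips[:, 0]]
        p2 = coords[self.trips[:, 1]]
        p3 = coords[self.trips[:, 2]]
        a = p2 - p1
        b = p3 - p1
        u = _cross(a, b)
        un = np.maximum(_rownorm(u), 1e-10)
        nhat = u / un[:, None]
        tv = coords[self.bb_to] - coords[self.bb_from]
        tn = np.maximum(_rownorm(tv), 1e-10)
        that = tv / tn[:, None]
        c = np.einsum("ij,ij->i", nhat, that)
        e = self.kappa * float(np.sum(1.0 - c**2))
        if forces is None:
            return e
        coef = -2.0 * self.kappa * c
        # through the plane normal
        gu = coef[:, None] * (that - c[:, None] * nhat) / un[:, None]
        dEda = _cross(b, gu)
        dEdb = _cross(gu, a)
        scatter_add(forces, self.trips,
                    np.stack([dEda + dEdb, -dEda, -dEdb], axis=1))
        # through the tangent
        gt = coef[:, None] * (nhat - c[:, None] * that) / tn[:, None]
        scatter_add(forces, np.stack([self.bb_to, self.bb_from], axis=1),
                    np.stack([-gt, gt], axis=1))
        return e


class SoftSphere:
    """Soft harmonic repulsion between listed site pairs:
    E = k/2 (sigma - r)^2 for r < sigma."""

    def __init__(self, pairs, k, sigma):
        self.pairs = np.asarray(pairs, dtype=int)
        self.k = float(k)
        self.sigma = float(sigma)

    def energy_forces(self, coords, forces=None):
        if len(self.pairs) == 0:
            return 0.0
        delta = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        d = _rownorm(delta)
        overlap = np.maximum(self.sigma - d, 0.0)
        e = 0.5 * self.k * float(np.sum(overlap**2))
        if forces is None:
            return e
        act = overlap > 0
        if np.any(act):
            g = (self.k * overlap[act] / np.maximum(d[act], 1e-12))[:, None] \
                * delta[act]
            scatter_add(forces, self.pairs[act],
                        np.stack([g, -g], axis=1))
        return e


class CentroidSoftSphere:
    """Soft repulsion between base-plane centroids of listed base pairs."""

    def __init__(self, trips_i, trips_j, k, sigma):
        self.trips_i = np.asarray(trips_i, dtype=int)
        self.trips_j = np.asarray(trips_j, dtype=int)
        self.k = float(k)
        self.sigma = float(sigma)

    def energy_forces(self, coords, forces=None):
        if len(self.trips_i) == 0:
            return 0.0
        ci = coords[self.trips_i].mean(axis=1)
        cj = coords[self.trips_j].mean(axis=1)
        delta = ci - cj
        d = _rownorm(delta)
        overlap = np.maximum(self.sigma - d, 0.0)
        e = 0.5 * self.k * float(np.sum(overlap**2))
        if forces is None:
            return e
        act = overlap > 0
        if np.any(act):
            g = (self.k * overlap[act] / np.maximum(d[act], 1e-12))[:, None] \
                * delta[act] / 3.0
            idx = np.concatenate([self.trips_i[act], self.trips_j[act]],
                                 axis=1)
            scatter_add(forces, idx, np.stack([g, g, g, -g, -g, -g], axis=1))
        return e


class TorsionBias:
    """E = kappa * (1 - cos(phi - phi0)) over listed backbone dihedrals."""

    def __init__(self, quads, kappa, phi0_deg):
        self.quads = np.asarray(quads, dtype=int)
        self.kappa = float(kappa)
        self.phi0 = np.radians(float(phi0_deg))

    def energy_forces(self, coords, forces=None):
        if self.kappa == 0.0 or len(self.quads) == 0:
            return 0.0
        p0 = coords[self.quads[:, 0]]
        p1 = coords[self.quads[:, 1]]
        p2 = coords[self.quads[:, 2]]
        p3 = coords[self.quads[:, 3]]
        b1 = p1 - p0
        b2 = p2 - p1
        b3 = p3 - p2
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        b2n = _rownorm(b2)
        m1 = _cross(n1, b2 / b2n[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        # IUPAC convention (cis = 0), consistent with cvs.dihedral
        phi = np.arctan2(y, -x)
        e = self.kappa * float(np.sum(1.0 - np.cos(phi - self.phi0)))
        if forces is None:
            return e
        dEdphi = self.kappa * np.sin(phi - self.phi0)
        n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-14)
        n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-14)
        dphi_dp0 = -(b2n / n1sq)[:, None] * n1
        dphi_dp3 = (b2n / n2sq)[:, None] * n2
        c12 = np.sum(b1 * b2, axis=1) / b2n**2
        c32 = np.sum(b3 * b2, axis=1) / b2n**2
        dphi_dp1 = -(1.0 + c12)[:, None] * dphi_dp0 \
            + c32[:, None] * dphi_dp3
        dphi_dp2 = c12[:, None] * dphi_dp0 \
            - (1.0 + c32)[:, None] * dphi_dp3
        contrib = np.stack([dphi_dp0, dphi_dp1, dphi_dp2, dphi_dp3], axis=1)
        scatter_add(forces, self.quads, -dEdphi[:, None, None] * contrib)
        return e


# ---------------------------------------------------------------------------
# system


@dataclass
class CGSystem:
    """A coarse-grained system: topology, force-field terms, masses and a
    reference (ideal) starting conformation."""

    topology: StrandTopology | DuplexTopology
    params: CoarseModelParams
    terms: list
    masses: np.ndarray
    initial: Conformation

    @property
    def n_sites(self) -> int:
        return self.initial.n_sites

    def energy(self, coords: np.ndarray) -> float:
        return float(sum(t.energy_forces(coords) for t in self.terms))

    def energy_forces(self, coords: np.ndarray):
        forces = np.zeros_like(coords)
        e = float(sum(t.energy_forces(coords, forces) for t in self.terms))
        return e, forces


# ---------------------------------------------------------------------------
# ideal geometry


def _monomer_sites_ideal(angle, z, params: CoarseModelParams, flip: bool):
    """Four sites of one monomer: backbone bead at r_backbone, base-plane
    triplet around the base center at r_base, plane normal along the helix
    axis.  ``flip`` mirrors across the axis for the second strand."""
    a = angle + (np.pi if flip else 0.0)
    ca, sa = np.cos(a), np.sin(a)
    bb = np.array([params.r_backbone * ca, params.r_backbone * sa, z])
    cent = np.array([params.r_base * ca, params.r_base * sa, z])
    rho = params.plane_radius
    trip = [cent + rho * np.array([np.cos(a + t), np.sin(a + t), 0.0])
            for t in np.radians([0.0, 120.0, 240.0])]
    return [bb, *trip]


def ideal_helix_conformation(topo: StrandTopology, params: CoarseModelParams,
                             twist_deg: float | None = None) -> Conformation:
    """Ideal single-strand helix (the duplex-derived starting geometry)."""
    twist = np.radians(params.helix_twist_deg if twist_deg is None
                       else twist_deg)
    coords = np.zeros((topo.n_sites, 3))
    for i in range(topo.length):
        sites = _monomer_sites_ideal(i * twist, i * params.helix_rise,
                                     params, flip=False)
        for k, s in enumerate(topo.monomer_sites(i)):
            coords[s - topo.site_offset] = sites[k]
    return Conformation(coords)


def ideal_duplex_conformation(duplex: DuplexTopology,
                              params: CoarseModelParams,
                              twist_deg: float = 0.0) -> Conformation:
    """Ideal antiparallel duplex: pair i of the map shares height i*rise
    and angle i*twist; the RNA partner sits mirrored across the axis.

    The default is an untwisted (achiral) ladder: a twisted duplex is
    chiral, and chirality couples to the unzipping direction, imprinting a
    positional bias on per-pair fraying statistics that masks sequence
    effects.  Single strands keep their helical twist."""
    twist = np.radians(twist_deg)
    coords = np.zeros((duplex.n_sites, 3))
    for p, (ia, ib) in enumerate(duplex.pair_map):
        z = p * params.helix_rise
        ang = p * twist
        for topo, idx, flip in ((duplex.strand_a, ia, False),
                                (duplex.strand_b, ib, True)):
            sites = _monomer_sites_ideal(ang, z, params, flip)
            for k, s in enumerate(topo.monomer_sites(idx)):
                coords[s] = sites[k]
    return Conformation(coords)


def random_coil_conformation(topo: StrandTopology, params: CoarseModelParams,
                             seed: int = 0) -> Conformation:
    """Self-avoiding random walk of backbone beads (rejection on overlap)
    with randomly oriented bases."""
    rng = np.random.default_rng(seed)
    step = _backbone_bond_length(params)
    bb = [np.zeros(3)]
    for _ in range(topo.length - 1):
        for _attempt in range(1000):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = bb[-1] + v
            if all(np.linalg.norm(cand - p) >= params.ev_sigma_backbone * 0.9
                   for p in bb[:-1]) or len(bb) < 2:
                bb.append(cand)
                break
        else:
            raise RuntimeError("self-avoiding walk failed")
    coords = np.zeros((topo.n_sites, 3))
    for i in range(topo.length):
        base_dir = rng.normal(size=3)
        base_dir /= np.linalg.norm(base_dir)
        cent = bb[i] + (params.r_backbone - params.r_base) * base_dir
        # random orthonormal frame in the base plane
        ref = rng.normal(size=3)
        e1 = np.cross(base_dir, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(base_dir, e1)
        rho = params.plane_radius
        sites = topo.monomer_sites(i)
        coords[sites[0]] = bb[i]
        for k, t in enumerate(np.radians([0.0, 120.0, 240.0])):
            coords[sites[k + 1]] = cent + rho * (np.cos(t) * e1
                                                 + np.sin(t) * e2)
    return Conformation(coords)


def _backbone_bond_length(params: CoarseModelParams) -> float:
    twist = np.radians(params.helix_twist_deg)
    chord = 2.0 * params.r_backbone * np.sin(twist / 2.0)
    return float(np.hypot(chord, params.helix_rise))


def _ideal_backbone_dihedral(params: CoarseModelParams) -> float:
    """Backbone dihedral (degrees) of four consecutive beads of the ideal
    helix — the gamma-bias target when none is given."""
    twist = np.radians(params.helix_twist_deg)
    pts = np.array([[params.r_backbone * np.cos(i * twist),
                     params.r_backbone * np.sin(i * twist),
                     i * params.helix_rise] for i in range(4)])
    return dihedral(Conformation(pts), [0, 1, 2, 3])


# ---------------------------------------------------------------------------
# term assembly


def _collect_strand(acc: dict, topo: StrandTopology,
                    params: CoarseModelParams, kind: str):
    """Append one strand's bonded, stacking, excluded-volume and (gamma)
    torsion interactions to the accumulator.  Bond rest lengths come from
    the ideal helix so the ideal geometry is a near-minimum of the bonded
    part."""
    L = topo.length
    off = topo.site_offset
    ref = ideal_helix_conformation(
        StrandTopology(kind="pna", sequence=topo.sequence.replace("U", "T")),
        params)
    refc = ref.coordinates

    def add_bond(a, b, k):
        acc["bond_pairs"].append((a, b))
        acc["bond_k"].append(k)
        acc["bond_r0"].append(
            float(np.linalg.norm(refc[b - off] - refc[a - off])))

    for i in range(L - 1):
        add_bond(topo.backbone_site(i), topo.backbone_site(i + 1),
                 params.bond_k)
    for i in range(L):
        s = topo.monomer_sites(i)
        for t in s[1:]:
            add_bond(s[0], t, params.bond_k)
        for a, b in ((s[1], s[2]), (s[2], s[3]), (s[3], s[1])):
            add_bond(a, b, params.plane_k)

    trips = np.array([topo.plane_triplet(i) for i in range(L)], dtype=int)
    ii, jj = np.triu_indices(L, k=1)
    acc["stack_i"].append(trips[ii])
    acc["stack_j"].append(trips[jj])
    bb = [topo.backbone_site(i) for i in range(L)]
    acc["ev_pairs"] += [(bb[i], bb[j]) for i in range(L)
                        for j in range(i + 2, L)]
    acc["cev_i"].append(trips[ii])
    acc["cev_j"].append(trips[jj])
    if kind == "gamma_pna" and L >= 4 and params.gamma_bias_k > 0:
        target = (params.gamma_target_deg
                  if params.gamma_target_deg is not None
                  else _ideal_backbone_dihedral(params))
        acc["torsions"].append(
            TorsionBias([(bb[i], bb[i + 1], bb[i + 2], bb[i + 3])
                         for i in range(L - 3)],
                        params.gamma_bias_k, target))
    if kind == "gamma_pna" and L >= 2 and params.gamma_orient_k > 0:
        acc["torsions"].append(BaseOrientationBias(
            trips[:-1], bb[:-1], bb[1:], params.gamma_orient_k))
    if kind == "gamma_pna" and L >= 2 and params.gamma_stack_bonus > 0:
        # the modification deepens the effective sequential stacking well
        acc["torsions"].append(StackingTerm(
            trips[:-1], trips[1:], params.gamma_stack_bonus,
            params.stack_switch))
    return trips


def _new_acc() -> dict:
    return {"bond_pairs": [], "bond_k": [], "bond_r0": [],
            "stack_i": [], "stack_j": [], "ev_pairs": [],
            "cev_i": [], "cev_j": [], "torsions": []}


def _acc_to_terms(acc: dict, params: CoarseModelParams) -> list:
    terms = [
        HarmonicBonds(acc["bond_pairs"], acc["bond_k"], acc["bond_r0"]),
        StackingTerm(np.concatenate(acc["stack_i"]),
                     np.concatenate(acc["stack_j"]),
                     params.stack_eps, params.stack_switch),
        SoftSphere(acc["ev_pairs"], params.ev_k, params.ev_sigma_backbone),
        CentroidSoftSphere(np.concatenate(acc["cev_i"]),
                           np.concatenate(acc["cev_j"]),
                           params.ev_k, params.ev_sigma_base),
    ]
    return terms + acc["torsions"]


def make_ss_system(seq: str, kind: str = "pna",
                   params: CoarseModelParams | None = None) -> CGSystem:
    """Single-strand coarse-grained system (PNA or gamma-PNA) started from
    an ideal helix."""
    if kind not in ("pna", "gamma_pna"):
        raise ValueError(f"single-strand kind must be pna/gamma_pna, "
                         f"got {kind!r}")
    params = params or CoarseModelParams()
    topo = build_strand(seq, kind)
    acc = _new_acc()
    _collect_strand(acc, topo, params, kind)
    masses = np.full(topo.n_sites, params.mass)
    init = ideal_helix_conformation(topo, params)
    return CGSystem(topology=topo, params=params,
                    terms=_acc_to_terms(acc, params),
                    masses=masses, initial=init)


def make_duplex_system(duplex: DuplexTopology,
                       params: CoarseModelParams | None = None) -> CGSystem:
    """Duplex system: both strands' intra-strand interactions plus
    Watson-Crick pairing terms weighted by H-bond multiplicity and
    cross-strand excluded volume."""
    params = params or CoarseModelParams()
    acc = _new_acc()
    trips_a = _collect_strand(acc, duplex.strand_a, params,
                              duplex.strand_a.kind)
    trips_b = _collect_strand(acc, duplex.strand_b, params,
                              duplex.strand_b.kind)

    # cross-strand excluded volume: backbones, and bases that are not
    # Watson-Crick partners
    La, Lb = duplex.strand_a.length, duplex.strand_b.length
    bba = [duplex.strand_a.backbone_site(i) for i in range(La)]
    bbb = [duplex.strand_b.backbone_site(i) for i in range(Lb)]
    acc["ev_pairs"] += [(a, b) for a in bba for b in bbb]
    paired = set(duplex.pair_map)
    cross_i = [trips_a[ia] for ia in range(La) for ib in range(Lb)
               if (ia, ib) not in paired]
    cross_j = [trips_b[ib] for ia in range(La) for ib in range(Lb)
               if (ia, ib) not in paired]
    acc["cev_i"].append(np.array(cross_i, dtype=int).reshape(-1, 3))
    acc["cev_j"].append(np.array(cross_j, dtype=int).reshape(-1, 3))

    terms = _acc_to_terms(acc, params)
    pa = np.array([trips_a[ia] for ia, _ in duplex.pair_map])
    pb = np.array([trips_b[ib] for _, ib in duplex.pair_map])
    weights = np.array([params.hb_eps * duplex.pair_hbond_count(i)
                        for i in range(duplex.n_pairs)])
    terms.append(WatsonCrickPairing(pa, pb, weights, params.coop_J,
                                    params.hb_switch))

    masses = np.full(duplex.n_sites, params.mass)
    init = ideal_duplex_conformation(duplex, params)
    return CGSystem(topology=duplex, params=params, terms=terms,
                    masses=masses, initial=init)


def hb_site_pairs(duplex: DuplexTopology, pair_index: int):
    """The 3x3 cross pairs of base-plane sites of one Watson-Crick pair,
    used for the per-pair coordination (H-bond proxy) CV."""
    ia, ib = duplex.pair_map[pair_index]
    ta = duplex.strand_a.plane_triplet(ia)
    tb = duplex.strand_b.plane_triplet(ib)
    return [(a, b) for a in ta for b in tb]


# ---------------------------------------------------------------------------
# distorted duplex scenarios


def _rigid_rotate(coords, sites, pivot, axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
    coords[sites] = (coords[sites] - pivot) @ R.T + pivot


def _strand_sites(topo: StrandTopology):
    return np.arange(topo.site_offset, topo.site_offset + topo.n_sites)


def make_distorted_duplex(system: CGSystem, scenario: int,
                          seed: int = 0) -> Conformation:
    """Distorted starting conformations for re-annealing runs.

    1: fan-opened about the C-terminal-side pair (only that pair in
       contact); 2: fan-opened about the N-terminal-side pair; 3: strands
       uniformly separated to 0.50-0.60 nm between paired base centers,
       bases facing; 4: strands crossed at the duplex center, termini
       separated; 5: both strands fully stretched with random base
       orientations and a shifted register, approached and energy-
       minimized (no native pair in contact).
    """
    duplex = system.topology
    if not isinstance(duplex, DuplexTopology):
        raise ValueError("make_distorted_duplex needs a duplex system")
    if scenario not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown scenario {scenario}")
    params = system.params
    n = duplex.n_pairs
    sites_b = _strand_sites(duplex.strand_b)

    if scenario in (1, 2):
        conf = ideal_duplex_conformation(duplex, params, twist_deg=0.0)
        coords = conf.coordinates
        pivot_pair = n - 1 if scenario == 1 else 0
        ia, ib = duplex.pair_map[pivot_pair]
        ca = coords[list(duplex.strand_a.plane_triplet(ia))].mean(0)
        cb = coords[list(duplex.strand_b.plane_triplet(ib))].mean(0)
        pivot = 0.5 * (ca + cb)
        # open about the axis perpendicular to both the helix axis (z)
        # and the pairing direction (x): rotate strand B about y
        _rigid_rotate(coords, sites_b, pivot, (0.0, 1.0, 0.0),
                      110.0 if scenario == 1 else -110.0)
        return Conformation(coords)

    if scenario == 3:
        conf = ideal_duplex_conformation(duplex, params, twist_deg=0.0)
        coords = conf.coordinates
        # untwisted ladder: every pair axis is x; push strand B out so the
        # base-center separation is 0.55 nm
        target = 0.50
        current = 2.0 * params.r_base
        coords[sites_b, 0] -= (target - current)
        return Conformation(coords)

    if scenario == 4:
        conf = ideal_duplex_conformation(duplex, params, twist_deg=0.0)
        coords = conf.coordinates
        zc = 0.5 * (n - 1) * params.helix_rise
        pivot = np.array([0.0, 0.0, zc])
        # cross the strands: rotate strand B about the pairing direction
        _rigid_rotate(coords, sites_b, pivot, (1.0, 0.0, 0.0), 90.0)
        return Conformation(coords)

    # scenario 5: stretched strands, random bases, shifted register,
    # approached and minimized
    from .dynamics import minimize_conformation

    rng = np.random.default_rng(seed)
    coords = np.zeros((duplex.n_sites, 3))
    stretch = 1.35 * _backbone_bond_length(params)
    gap = 0.8

    def lay_strand(topo, y, z_shift, reverse):
        L = topo.length
        for i in range(L):
            t = (L - 1 - i) if reverse else i
            bb = np.array([0.0, y, z_shift + t * stretch])
            base_dir = rng.normal(size=3)
            base_dir /= np.linalg.norm(base_dir)
            cent = bb + (params.r_backbone - params.r_base) * base_dir
            ref = rng.normal(size=3)
            e1 = np.cross(base_dir, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(base_dir, e1)
            s = topo.monomer_sites(i)
            coords[s[0]] = bb
            for k, th in enumerate(np.radians([0.0, 120.0, 240.0])):
                coords[s[k + 1]] = cent + params.plane_radius * (
                    np.cos(th) * e1 + np.sin(th) * e2)

    # register shifted by nearly the full strand length: only non-native
    # contacts are possible at the approach interface
    lay_strand(duplex.strand_a, 0.0, 0.0, reverse=False)
    lay_strand(duplex.strand_b, gap, n * stretch, reverse=True)
    conf = Conformation(coords)
    return minimize_conformation(system, conf, maxiter=150)
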