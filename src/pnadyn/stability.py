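"""Duplex melting and re-annealing analysis.

The observable is a per-base-pair coordination number — a smooth H-bond
proxy: the rational-switch contact count over the 3x3 cross pairs of the
two bases' plane sites — tracked along a trajectory and normalized by its
value in the fully formed duplex.  A pair is *persistently formed* when
its normalized coordination stays above theta_on for m consecutive stored
frames; the duplex is *completely disrupted* at the earliest time from
which every pair stays below theta_off for at least the persistence
window (persistence filtering suppresses single-frame flickers).

The pre-break profile averages each pair's normalized coordination over a
window immediately before disruption — the per-pair contribution to
duplex stability just before it falls apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import Conformation, DuplexTopology, Trajectory
from .cvs import SwitchingParams, rational_switch, DEFAULT_COORD_SWITCH
from .systems import CGSystem, hb_site_pairs, ideal_duplex_conformation, \
    make_distorted_duplex
from .dynamics import simulate

__all__ = [
    "PairingSeries",
    "MeltResult",
    "AnnealResult",
    "pairing_series",
    "pairing_fraction",
    "detect_disruption",
    "prebreak_profile",
    "melt_scan",
    "anneal_run",
]

#: defaults for persistence filtering (fractions of the fully-formed
#: reference coordination; m in stored frames)
THETA_ON = 0.5
THETA_OFF = 0.2
PERSISTENCE_FRAMES = 5


@dataclass
class PairingSeries:
    """Per-base-pair coordination time series.

    values[t, p] is the raw coordination of pair p at stored frame t;
    reference[p] its value in the fully formed duplex.  Labels are
    "PNAbase:RNAbase" in pair order from the PNA N-terminus.
    """

    times: np.ndarray
    values: np.ndarray
    labels: list[str]
    reference: np.ndarray
    theta_on: float = THETA_ON
    theta_off: float = THETA_OFF
    m_frames: int = PERSISTENCE_FRAMES

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.values.shape != (len(self.times), len(self.labels)):
            raise ValueError("values shape does not match times/labels")
        if np.any(self.values < 0) or np.any(self.reference <= 0):
            raise ValueError("coordination values must be non-negative "
                             "with positive reference")

    @property
    def n_pairs(self) -> int:
        return len(self.labels)

    def normalized(self) -> np.ndarray:
        return self.values / self.reference[None, :]

    def _frame_index(self, t: float) -> int:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside series "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))

    def persistent_formed(self, theta_on: float | None = None,
                          m: int | None = None) -> np.ndarray:
        """Boolean [t, p]: pair p has stayed above theta_on for the m
        stored frames ending at t (False for t < m-1)."""
        th = self.theta_on if theta_on is None else theta_on
        m = self.m_frames if m is None else m
        formed = (self.normalized() > th).astype(int)
        out = np.zeros_like(formed, dtype=bool)
        if len(self.times) >= m:
            csum = np.cumsum(np.vstack([np.zeros((1, self.n_pairs), int),
                                        formed]), axis=0)
            win = csum[m:] - csum[:-m]
            out[m - 1:] = win == m
        return out


def pairing_series(traj: Trajectory, duplex: DuplexTopology,
                   switch: SwitchingParams = DEFAULT_COORD_SWITCH,
                   reference: Conformation | None = None,
                   ref_params=None, **kwargs) -> PairingSeries:
    """Per-pair coordination along a trajectory.

    The reference (fully formed) coordination comes from an ideal duplex
    conformation unless one is supplied.
    """
    pair_sites = [np.asarray(hb_site_pairs(duplex, p), dtype=int)
                  for p in range(duplex.n_pairs)]
    ia = np.stack([ps[:, 0] for ps in pair_sites])  # (P, 9)
    ib = np.stack([ps[:, 1] for ps in pair_sites])
    X = traj.coordinates()  # (F, N, 3)
    delta = X[:, ia] - X[:, ib]  # (F, P, 9, 3)
    d = np.linalg.norm(delta, axis=-1)
    vals = rational_switch(d, switch).sum(axis=-1)  # (F, P)

    if reference is None:
        if ref_params is None:
            raise ValueError("need a reference conformation or model "
                             "parameters to build one")
        reference = ideal_duplex_conformation(duplex, ref_params)
    rd = np.linalg.norm(reference.coordinates[ia]
                        - reference.coordinates[ib], axis=-1)
    ref = rational_switch(rd, switch).sum(axis=-1)
    return PairingSeries(times=traj.times, values=vals,
                         labels=duplex.pair_labels(), reference=ref,
                         **kwargs)


def pairing_fraction(series: PairingSeries, t: float) -> float:
    """Fraction of base pairs persistently formed at time t, in [0, 1]."""
    idx = series._frame_index(t)
    pf = series.persistent_formed()
    return float(pf[idx].sum() / series.n_pairs)


def detect_disruption(series: PairingSeries,
                      theta_off: float | None = None,
                      persistence: int | None = None) -> float | None:
    """Earliest time after which every pair stays below theta_off for at
    least the persistence window; None if the duplex never breaks."""
    th = series.theta_off if theta_off is None else theta_off
    m = series.m_frames if persistence is None else persistence
    below = np.all(series.normalized() < th, axis=1).astype(int)
    if len(below) < m:
        return None
    csum = np.concatenate([[0], np.cumsum(below)])
    win = csum[m:] - csum[:-m]
    hits = np.nonzero(win == m)[0]
    if len(hits) == 0:
        return None
    return float(series.times[hits[0]])


def prebreak_profile(series: PairingSeries, t_disrupt: float,
                     window: float) -> np.ndarray:
    """Per-pair time-averaged normalized coordination over the window
    before disruption, clipped to [0, 1].

    Shrinks the window with a warning when disruption happens earlier
    than one full window into the series.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t0 = t_disrupt - window
    if t0 < series.times[0]:
        warnings.warn("disruption earlier than the averaging window; "
                      "shrinking window")
        t0 = series.times[0]
    mask = (series.times >= t0 - 1e-9) & (series.times <= t_disrupt + 1e-9)
    if not mask.any():
        raise ValueError("empty pre-break window")
    prof = series.normalized()[mask].mean(axis=0)
    return np.clip(prof, 0.0, 1.0)


@dataclass
class MeltResult:
    """One melting run: disruption time (None if the duplex survived) and
    the per-pair pre-break H-bonding fraction."""

    temperature: float
    seed: int
    disruption_time: float | None
    profile: np.ndarray | None
    window: float

    def __post_init__(self):
        if self.profile is not None:
            self.profile = np.asarray(self.profile, dtype=float)
            if np.any(self.profile < 0) or np.any(self.profile > 1):
                raise ValueError("profile fractions must lie in [0, 1]")


@dataclass
class AnnealResult:
    """One re-annealing run from a distorted start."""

    scenario: int
    seed: int
    outcome: Literal["full", "partial", "none"]
    time_to_anneal: float | None
    nucleation_pair: int | None
    final_fraction: float

    def __post_init__(self):
        if self.outcome == "full" and self.time_to_anneal is None:
            raise ValueError("outcome 'full' requires time_to_anneal")


def melt_scan(system: CGSystem, temperatures: Sequence[float],
              seeds: Sequence[int], steps: int = 30000, stride: int = 20,
              window: float | None = None,
              switch: SwitchingParams = DEFAULT_COORD_SWITCH):
    """Thermal dissociation scan: one run per (temperature, seed).

    Returns ``(results, average_profile)`` where the average is taken
    over runs with a detected disruption, each weighted equally.  Raises
    when no run disrupts (advise longer runs or higher temperatures).
    The default pre-break window is a fixed fraction (one quarter) of the
    trajectory span, preserving the window-to-dissociation-timescale
    ratio of the original protocol.
    """
    duplex = system.topology
    results: list[MeltResult] = []
    profiles = []
    for T in temperatures:
        for seed in seeds:
            traj = simulate(system, steps=steps, temperature=T, seed=seed,
                            stride=stride)
            series = pairing_series(traj, duplex, switch=switch,
                                    ref_params=system.params)
            t_d = detect_disruption(series)
            win = window if window is not None else 0.25 * traj.times[-1]
            if t_d is None:
                results.append(MeltResult(T, seed, None, None, win))
                continue
            prof = prebreak_profile(series, t_d, win)
            results.append(MeltResult(T, seed, t_d, prof, win))
            profiles.append(prof)
    if not profiles:
        raise RuntimeError(
            "no run reached complete disruption: increase steps or "
            "temperatures")
    return results, np.mean(profiles, axis=0)


def anneal_run(system: CGSystem, scenario: int, steps: int = 40000,
               seed: int = 0, temperature: float = 300.0,
               stride: int = 20, theta_full: float = 0.9,
               switch: SwitchingParams = DEFAULT_COORD_SWITCH) -> AnnealResult:
    """Re-annealing run from one distorted-duplex scenario.

    Outcome is "full" when the persistent pairing fraction reaches
    theta_full and stays there for the persistence window before the
    budget ends; "partial" when some but not all pairs end persistently
    formed; "none" otherwise.  The nucleation pair is the first pair to
    become persistently formed.
    """
    duplex = system.topology
    start = make_distorted_duplex(system, scenario, seed=seed)
    traj = simulate(system, steps=steps, temperature=temperature,
                    seed=seed + 1_000_000, stride=stride, start=start)
    series = pairing_series(traj, duplex, switch=switch,
                            ref_params=system.params)
    pf = series.persistent_formed()
    frac = pf.sum(axis=1) / series.n_pairs

    first_formed = None
    nucleation = None
    for p in range(series.n_pairs):
        hits = np.nonzero(pf[:, p])[0]
        if len(hits) and (first_formed is None or hits[0] < first_formed):
            first_formed = hits[0]
            nucleation = p

    m = series.m_frames
    full_frames = np.nonzero(frac >= theta_full)[0]
    time_full = None
    if len(full_frames):
        # sustained: theta_full held for m consecutive frames
        ok = (frac >= theta_full).astype(int)
        csum = np.concatenate([[0], np.cumsum(ok)])
        win = csum[m:] - csum[:-m]
        hits = np.nonzero(win == m)[0]
        if len(hits):
            time_full = float(series.times[hits[0]])
    final = float(frac[-1])
    if time_full is not None:
        outcome = "full"
    elif final > 0:
        outcome = "partial"
    else:
        outcome = "none"
    return AnnealResult(scenario=scenario, seed=seed, outcome=outcome,
                        time_to_anneal=time_full, nucleation_pair=nucleation,
                        final_fraction=final)
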