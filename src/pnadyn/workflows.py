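"""End-to-end study workflows.

Each function reproduces one of the package's studies at desk scale and
returns plain dictionaries / DataFrames that the analysis scripts, the
test suite and the acceptance script all share:

* ``benchmark_double_well_1d`` / ``_2d`` — well-tempered metadynamics and
  reweighting validated against quadrature oracles on analytic potentials.
* ``melt_study`` — thermal dissociation scan of the PNA:RNA hexamer with
  per-pair pre-break H-bonding statistics (end fraying, half asymmetry).
* ``anneal_study`` — re-annealing of the five distorted-duplex scenarios.
* ``preorganization_study`` — reweighted population shift of the
  gamma-modified single strand toward stacked-extended conformations.

Problem sizes default to runs that finish in minutes on one CPU; they are
deliberately far below the original atomistic protocol and are chosen for
statistical adequacy, not quantitative correspondence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .constants import KB
from .core import build_duplex
from .cvs import HeadTailCV, StackingCV, CoordinateCV
from .metad import (MetadParams, run_wtmetad, fes_from_hills, reweight,
                    reweight_weights)
from .potentials import (DoubleWell1D, DoubleWell2D, ParticleSystem,
                         fes_by_quadrature)
from .stability import melt_scan, anneal_run
from .systems import CoarseModelParams, make_duplex_system, make_ss_system

__all__ = [
    "benchmark_double_well_1d",
    "benchmark_double_well_2d",
    "melt_study",
    "anneal_study",
    "preorganization_study",
    "PRODUCTION_METAD",
]

#: the production biasing protocol: 2.5 kJ/mol hills, widths 0.01 (nm on
#: HT, dimensionless on Stk), deposited every ps, bias factor 30
PRODUCTION_METAD = dict(w0=2.5, sigma=(0.01, 0.01), stride_ps=1.0,
                        gamma=30.0)

PNA_SEQ = "GAACTC"
RNA_SEQ = "GAGTTC"


def _basin_delta_f(values: np.ndarray, centers: np.ndarray,
                   kT: float) -> float:
    """Free-energy difference between the x>=0 and x<0 basins from a
    min-normalized FES (Boltzmann-integrated, robust to bin noise)."""
    F = np.where(np.isfinite(values), values, np.inf)
    w = np.exp(-F / kT)
    if values.ndim == 2:
        w = w.sum(axis=1)
    return float(-kT * np.log(w[centers >= 0].sum() / w[centers < 0].sum()))


def benchmark_double_well_1d(seed: int = 1, steps: int = 800_000,
                             temperature: float = 300.0) -> dict:
    """WT-metadynamics on a tilted 1D double well vs the quadrature oracle.

    Returns the basin free-energy difference from the hills-reconstructed
    FES, the oracle value, and their discrepancy in units of kB T.
    """
    kT = KB * temperature
    pot = DoubleWell1D(h=10.0, a=0.05, c=25.0)
    system = ParticleSystem(pot, mass=10.0, dt=0.002, friction=10.0)
    params = MetadParams(w0=2.5, sigma=(0.01,), stride_ps=1.0, gamma=30.0,
                         temperature=temperature)
    edges = [np.linspace(-0.125, 0.125, 201)]
    oracle = fes_by_quadrature(pot, temperature, edges)
    _, hills, _ = run_wtmetad(system, [CoordinateCV(0, 0, "x")], params,
                              steps=steps, seed=seed, stride=100)
    fes = fes_from_hills(hills, edges, params)
    xc = fes.centers()[0]
    df_metad = _basin_delta_f(fes.values, xc, kT)
    df_oracle = _basin_delta_f(oracle.values, xc, kT)
    return {"delta_f_metad": df_metad, "delta_f_oracle": df_oracle,
            "error_kT": abs(df_metad - df_oracle) / kT,
            "n_hills": len(hills), "max_hill_height": max(
                h.height for h in hills)}


def benchmark_double_well_2d(seed: int = 7, steps: int = 1_000_000,
                             temperature: float = 300.0) -> dict:
    """Reweighting on a 2D two-well potential vs the quadrature oracle.

    Checks (a) the reweighted 2D basin free-energy difference against the
    oracle and (b) the reweighted marginal of the biased CV against the
    hills-based FES, both in kB T.
    """
    kT = KB * temperature
    pot = DoubleWell2D(h=10.0, a=0.05, c=25.0, ky=2000.0)
    system = ParticleSystem(pot, mass=10.0, dt=0.002, friction=10.0)
    params = MetadParams(w0=2.5, sigma=(0.01, 0.01), stride_ps=1.0,
                         gamma=30.0, temperature=temperature)
    ex = np.linspace(-0.125, 0.125, 51)
    ey = np.linspace(-0.12, 0.12, 25)
    oracle = fes_by_quadrature(pot, temperature, [ex, ey])
    cvs = [CoordinateCV(0, 0, "x"), CoordinateCV(0, 1, "y")]
    _, hills, recs = run_wtmetad(system, cvs, params, steps=steps,
                                 seed=seed, stride=25)
    times = [r.time for r in recs]
    bias = [r.bias for r in recs]
    targets = np.array([[r.values["x"], r.values["y"]] for r in recs])
    rw = reweight(times, bias, hills, [ex, ey], params, targets, [ex, ey])
    xc = rw.centers()[0]
    df_rw = _basin_delta_f(rw.values, xc, kT)
    df_oracle = _basin_delta_f(oracle.values, xc, kT)

    weights = reweight_weights(times, bias, hills, [ex, ey], params)
    hist, _ = np.histogram(targets[:, 0], bins=ex, weights=weights)
    with np.errstate(divide="ignore"):
        f_marg = -kT * np.log(hist)
    f_marg -= f_marg[np.isfinite(f_marg)].min()
    params_1d = MetadParams(w0=2.5, sigma=(0.01,), stride_ps=1.0,
                            gamma=30.0, temperature=temperature)
    # trailing-average estimator: the plain final-bias form fluctuates
    # by O(kBT) at run end, beyond the self-consistency tolerance
    fes_hills = fes_from_hills(hills, [ex], params_1d,
                               average_fraction=0.5)
    df_marg = _basin_delta_f(f_marg, xc, kT)
    df_hills = _basin_delta_f(fes_hills.values, xc, kT)
    return {"delta_f_reweight_2d": df_rw, "delta_f_oracle": df_oracle,
            "error_2d_kT": abs(df_rw - df_oracle) / kT,
            "delta_f_marginal": df_marg, "delta_f_hills": df_hills,
            "error_marginal_kT": abs(df_marg - df_hills) / kT}


def melt_study(temperatures=(360.0, 380.0, 400.0), seeds=range(1, 8),
               steps: int = 20_000,
               model: CoarseModelParams | None = None) -> dict:
    """Thermal dissociation scan of the GAACTC:RNA hexamer duplex.

    Returns per-run results, the average pre-break profile over disrupted
    runs (and the same excluding the highest temperature), the central /
    terminal and C-half / N-half means and one-sided paired-test p-values.
    """
    system = make_duplex_system(build_duplex(PNA_SEQ, RNA_SEQ), model)
    results, avg = melt_scan(system, temperatures, seeds, steps=steps)
    disrupted = [r for r in results if r.disruption_time is not None]
    profiles = np.array([r.profile for r in disrupted])
    t_hi = max(temperatures)
    prof_lo = np.array([r.profile for r in disrupted
                        if r.temperature != t_hi])
    central = profiles[:, [2, 3]].mean(axis=1)
    terminal = profiles[:, [0, 5]].mean(axis=1)
    c_half = profiles[:, 3:].mean(axis=1)
    n_half = profiles[:, :3].mean(axis=1)
    p_fray = _stats.ttest_rel(central, terminal,
                              alternative="greater").pvalue
    p_half = _stats.ttest_rel(c_half, n_half, alternative="greater").pvalue
    return {
        "results": results,
        "n_runs": len(results),
        "n_disrupted": len(disrupted),
        "average_profile": avg,
        "average_profile_excl_hottest": (prof_lo.mean(axis=0)
                                         if len(prof_lo) else None),
        "central_mean": float(central.mean()),
        "terminal_mean": float(terminal.mean()),
        "p_central_gt_terminal": float(p_fray),
        "c_half_mean": float(c_half.mean()),
        "n_half_mean": float(n_half.mean()),
        "p_c_half_gt_n_half": float(p_half),
    }


def anneal_study(scenarios=(1, 2, 3, 4, 5), seeds=range(1, 11),
                 steps: int = 10_000,
                 model: CoarseModelParams | None = None) -> dict:
    """Re-annealing of the five distorted-duplex scenarios.

    Returns the per-run table and a per-scenario summary: outcome counts,
    median time-to-anneal among full runs, and the fraction of runs
    nucleating at a central pair (2 or 3).
    """
    system = make_duplex_system(build_duplex(PNA_SEQ, RNA_SEQ), model)
    rows = []
    for sc in scenarios:
        for seed in seeds:
            r = anneal_run(system, sc, steps=steps, seed=seed)
            rows.append({"scenario": sc, "seed": seed, "outcome": r.outcome,
                         "time_to_anneal": r.time_to_anneal,
                         "nucleation_pair": r.nucleation_pair,
                         "final_fraction": r.final_fraction})
    table = pd.DataFrame(rows)
    summary = {}
    for sc in scenarios:
        sub = table[table.scenario == sc]
        full = sub[sub.outcome == "full"]
        summary[sc] = {
            "n_full": int((sub.outcome == "full").sum()),
            "n_partial": int((sub.outcome == "partial").sum()),
            "n_none": int((sub.outcome == "none").sum()),
            "median_time_full": (float(full.time_to_anneal.median())
                                 if len(full) else None),
            "central_nucleation_fraction": float(
                sub.nucleation_pair.isin([2, 3]).mean()),
        }
    return {"table": table, "summary": summary}


#: stacked-extended region of the (HT, SStk) plane: head-to-tail distance
#: beyond 1.2 nm with sequential stacking above 1.5
PREORG_REGION = {"ht_min": 1.2, "sstk_min": 1.5}


def preorganization_study(seeds=(11, 12, 13), steps: int = 30_000,
                          seq: str = PNA_SEQ,
                          model: CoarseModelParams | None = None,
                          temperature: float = 300.0) -> dict:
    """Reweighted population mass in the stacked-extended region for the
    unmodified vs the gamma-modified single strand, at matched seeds.

    Each strand runs well-tempered metadynamics biasing (HT, Stk) with the
    production protocol; frames are reweighted and the unbiased population
    mass with HT > ht_min and SStk > sstk_min is accumulated.
    """
    params = MetadParams(temperature=temperature, **PRODUCTION_METAD)
    masses: dict[str, list[float]] = {}
    for kind in ("pna", "gamma_pna"):
        masses[kind] = []
        for seed in seeds:
            system = make_ss_system(seq, kind, model)
            ht = HeadTailCV(system.topology)
            stk = StackingCV(system.topology, "stk")
            sstk = StackingCV(system.topology, "sstk")
            traj, hills, recs = run_wtmetad(system, [ht, stk], params,
                                            steps=steps, seed=seed,
                                            stride=25)
            times = [r.time for r in recs]
            bias = [r.bias for r in recs]
            hvals = np.array([r.values["ht"] for r in recs])
            svals = np.array([r.values["stk"] for r in recs])
            eh = np.linspace(0.0, max(2.5, hvals.max() + 0.1), 81)
            es = np.linspace(0.0, max(4.5, svals.max() + 0.1), 81)
            w = reweight_weights(times, bias, hills, [eh, es], params)
            X = traj.coordinates()
            ss = np.array([sstk.value(x) for x in X])
            mask = (hvals > PREORG_REGION["ht_min"]) \
                & (ss > PREORG_REGION["sstk_min"])
            masses[kind].append(float(w[mask].sum()))
    pna = np.array(masses["pna"])
    gamma = np.array(masses["gamma_pna"])
    return {"mass_pna": pna, "mass_gamma": gamma,
            "mean_pna": float(pna.mean()), "mean_gamma": float(gamma.mean()),
            "pairwise_increase": bool(np.all(gamma > pna)),
            "mean_ratio": float(gamma.mean() / pna.mean())}
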