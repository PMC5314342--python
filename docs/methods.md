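# Methods

## The model

`pnadyn` studies the conformational behavior of a peptide nucleic acid
(PNA) hexamer (N-GAACTC-C), its γ-backbone-modified variant, and the
antiparallel PNA:RNA duplex it forms with 5′-GAGTTC-3′, using a
coarse-grained strand model, Langevin dynamics, well-tempered
metadynamics with reweighting, and persistence-filtered base-pairing
analysis. The atomistic scale of the original problem (explicit solvent,
hundreds of nanoseconds) is out of reach on a desk machine; the package
reproduces the *machinery* — collective variables, biasing, free-energy
reconstruction, melting and re-annealing analysis — and the qualitative
direction of the associated effects on a reduced model.

### Coarse-grained representation

Each monomer is four beads: one backbone bead and a three-site triplet
spanning the aromatic base plane. The triplet's centroid is the base
center; its normal is the base-plane normal. All quantities are in
GROMACS-style reduced units: nm, ps, kJ/mol, amu.

The effective potential:

| term | form | default |
|---|---|---|
| backbone / monomer bonds | harmonic, rest lengths from the ideal geometry | k = 1000 (2000 for the base triangle) kJ/mol/nm² |
| stacking (same strand, all base pairs) | −ε · f(d) cos²θ | ε = 6 kJ/mol |
| WC pairing (duplex) | −ε_hb · n_hb · f_hb(d) per mapped pair | ε_hb = 2.5 kJ/mol per H-bond; n_hb = 3 (G:C), 2 (A:U/T) |
| pairing cooperativity | −J Σ f_hb(d_i) f_hb(d_{i+1}) | J = 8 kJ/mol |
| excluded volume | soft harmonic overlap (backbones, base centroids) | k = 200 kJ/mol/nm², σ = 0.40 / 0.25 nm |
| γ stand-in (γ-PNA only) | backbone torsion toward the helix dihedral + base-normal-along-chain alignment + deepened sequential stacking | κ = 25, κ_orient = 10, Δε_seq = 5 kJ/mol |

`f` is the rational switch `(1−(r/r0)^6)/(1−(r/r0)^12)` with r0 = 0.4 nm
for stacking and 0.35 nm for pairing — the same functional form as the
collective variables, so there is a single source of geometric truth.
Setting every γ-term strength to zero reproduces the unmodified model
exactly.

The H-bond multiplicity weighting makes the duplex's two halves
inequivalent: the N-terminal half (G:C, A:U, A:U) carries 7 H-bonds, the
C-terminal half (C:G, T:A, C:G) 8, and an RNA hexamer needs 5 monovalent
counterions for neutrality (one per phosphodiester linkage).

The nearest-neighbour cooperativity term is the zipper coupling: a
central pair partakes in two couplings, a terminal pair in one, which is
what makes duplex ends fray before the center. Without it the per-pair
persistence simply tracks the H-bond weight and no end fraying appears.

The γ stand-in deserves a note. The physical γ-serine modification
pre-organizes the single strand toward the helical, sequentially stacked
geometry. A backbone torsional bias alone extends the chain but cannot
raise sequential stacking, because the *collapsed* unmodified strand
already stacks nearly maximally — extension and stacking trade off in a
freely jointed chain. The stand-in therefore combines the torsion with a
base-orientation bias (normals along the chain) and a deepened effective
sequential-stacking well; in a model whose solvent is implicit in its
well depths, a substituent that pre-organizes stacking is legitimately
rendered as a renormalized stacking depth.

### Reference geometries

Single strands start from an ideal helix (rise 0.40 nm, twist 20°,
backbone radius 0.45 nm, base-center radius 0.14 nm). Duplexes use an
**untwisted ladder** as reference and starting structure: a twisted
duplex is chiral, and we found chirality can couple to the unzipping
direction in conditioned statistics, so the achiral ladder keeps the
melt analysis positionally unbiased. Paired base centers sit 0.28 nm
apart, well inside the pairing switch.

### Dynamics

BAOAB-splitting Langevin integration, default dt = 0.04 ps, friction
2 ps⁻¹, bead mass 25 amu. With zero friction and temperature the scheme
reduces to velocity Verlet; its secular energy drift is below 1e-4 over
10⁴ steps at dt = 0.001 ps and converges quadratically in dt. At the
production step the stiff base-triangle springs make the deterministic
shadow-energy error appreciable; production sampling therefore relies on
the thermostat, and the kinetic temperature estimator stays within 5% of
the target. All randomness flows from one integer seed; identical seeds
give bitwise-identical trajectories.

### Collective variables

* **HT** — distance between the centers of mass of the first and last
  monomers.
* **s_ij** — per-pair stacking, `f(d_ij)·cos²θ_ij` on base-plane
  centroids and normals, bounded in [0, 1]; `cos²` (not |cos|) keeps it
  face-agnostic and differentiable, which biasing requires.
* **Stk / SStk / NStk** — sums of s_ij over all unordered pairs /
  sequential (i, i+1) pairs / the rest, so Stk = SStk + NStk by
  construction. Whether the "total stacking" of the original protocol
  includes sequential terms is not derivable from its main text; this
  package includes them (SStk ⊂ Stk) and documents the choice as a
  dialect.
* **coordination** — smooth contact count, rational switch (r0 = 0.3 nm,
  n = 6, m = 12) summed over site pairs; the per-pair H-bond proxy uses
  the 3×3 cross pairs of the two bases' plane sites.
* **dihedral** — signed IUPAC convention (cis = 0), degrees at
  interfaces, radians internally.

All CVs are rotation/translation invariant and carry analytic gradients
(validated against finite differences), since the stacking CV doubles as
the stacking force-field term and the bias needs ∂s/∂x.

### Well-tempered metadynamics and reweighting

Gaussian hills of initial height W0 = 2.5 kJ/mol and widths 0.01 (nm on
HT, dimensionless on stacking) are deposited every 1 ps with bias factor
γ = 30: `W_k = W0 exp(−V(s_k,t_k)/(kB ΔT))`, ΔT = (γ−1)T. The default
free-energy estimate is the converged-limit form
`F(s) = −(γ/(γ−1)) V(s, t_end)`, min-normalized to zero. That estimator
retains an O(kBT) fluctuation at run end; `fes_from_hills` therefore
offers a trailing-average variant (mean of the running estimate over the
last fraction of depositions, implemented as a per-hill reweighting of
the Gaussian sum), which the hills-vs-reweighting self-consistency check
uses.
Hills are truncated beyond 9σ (error < 3e-18 W0 per hill).
The hill widths are taken as printed even though the stacking CV is
dimensionless; whether the original scaled its CVs is unknowable from
the text.

Reweighting uses per-frame weights
`w_t ∝ exp([V(s_t,t) − c(t)]/kBT)` with the time-dependent offset

    c(t) = kBT ln [ ∫ e^(−F_t/kBT) ds / ∫ e^(−(F_t+V_t)/kBT) ds ]

computed incrementally on the biased-CV grid from the running hills sum
(c is stepwise-constant between depositions). Correctness is established
by oracle, not by matching any particular published implementation: on a
tilted 1D double well the hills-based basin ΔF lands within 0.5 kBT of
direct quadrature, and on a 2D two-well potential the reweighted basin
ΔF lands within 0.1 kBT of quadrature while the reweighted marginal of
the biased CV agrees with the hills-based FES within 1 kBT. Basin
comparisons integrate Boltzmann weight over each basin rather than
reading single bins, which is robust to histogram noise. An effective
sample size below 10 triggers a degenerate-weights warning.

### Melting analysis

A pair is *persistently formed* when its normalized coordination exceeds
θ_on = 0.5 for m = 5 consecutive stored frames; *complete disruption* is
the earliest time from which every pair stays below θ_off = 0.2 for the
persistence window (single-frame flickers are not disruptions — the
high-temperature anomalies of the original study motivate robust
detection). The pre-break profile averages each pair's normalized
coordination over a window before disruption (default one quarter of the
trajectory span, shrunk with a warning when disruption comes earlier)
and clips to [0, 1]. The melt scan runs 360/380/400 K — inside the
340–400 K dissociation band; at 340 K the toy duplex usually survives
the accessible run length and such runs are reported as non-disrupted.
Averages are reported both over all disrupted runs and excluding the
hottest temperature.

### Distorted starts for re-annealing

1/2: fan-opened 110° about the C-/N-terminal pair (only that pair in
contact); 3: rigidly separated strands at 0.50 nm per-pair distance,
bases facing; 4: strands crossed 90° about the duplex center, termini
apart; 5: both strands stretched ~35% with random base orientations,
laid at a register shifted by the full strand length, approached and
L-BFGS-minimized — no native pair in contact. Re-annealing is "full"
when the persistent pairing fraction reaches 0.9 sustained for the
persistence window; the nucleation pair is the first to become
persistently formed.

### γ pre-organization readout

Both strand variants run the production metadynamics protocol biasing
(HT, Stk); frames are reweighted and the unbiased population mass in the
stacked-extended region (HT > 1.2 nm, SStk > 1.5 — roughly 60% of the
ideal helix's sequential stacking) is accumulated. At matched seeds the
γ-strand's mass is consistently ~4–5× the unmodified strand's.

## Parameter provenance

The original protocol pins the biasing parameters (2.5 kJ/mol hills,
widths 0.01, 1 ps stride, γ = 30) and the analysis structure; it gives
no effective stacking or H-bond energies for a coarse model. The well
depths here were tuned once so the hexamer duplex is stable for ~1 ns at
300 K and dissociates within 1 ns across 360–400 K; they are reduced
model conditions with no claim of atomistic correspondence. Problem
sizes (21-run melt scan, 10 seeds per re-annealing scenario, 3 paired
seeds for the pre-organization study, 10⁵–10⁶-step benchmarks) were
chosen for statistical adequacy of the qualitative claims on one CPU.

## What the synthetic model does and does not show

The generator emulates: sequential/non-sequential stacking competing
with chain entropy, WC pairing weighted by H-bond multiplicity,
zipper-cooperative melting with end fraying, temperature-dependent
fraying, and a tunable helical pre-organization bias. It does not
emulate: solvent structure, electrostatics and counterion condensation,
base-specific stacking energetics, sugar/backbone chemistry, or
atomistic kinetics. Passing tests therefore demonstrate correctness of
the machinery and the qualitative direction of cooperative effects, not
quantitative agreement with experiments on real PNA:RNA systems.

### A negative result, recorded deliberately

The 7-vs-8 half asymmetry does *not* produce a resolvable difference in
the pre-break persistence of the two halves at this scale. The potential
is exactly mirror-symmetric (verified term-by-term under z-flip plus
monomer relabeling), stationary per-pair coordination is position
symmetric, and a mirror-sequence control run with shared seeds
reproduces the same apparent direction as the original sequence —
proving that which end unzips first is decided by the noise realization,
not the sequence: one extra H-bond (2.5 kJ/mol of ~90 kJ/mol total
binding) sits below the noise floor of a ~20-run scan (SEM ≈ 0.05;
independent seed blocks scatter between −0.14 and +0.07). The end-fraying
contrast (central vs terminal pairs), by comparison, is large and
reproducible (p ≈ 4e-4 in the default scan). Both half means are
reported; the corresponding directional check in the test suite is
expected to fail and is retained as an honest record.

## Numerical choices

* Rational switch: removable singularity at r = r0 filled with the
  continuous limit n/m and slope (n/m)(n−m)/(2 r0); branch half-width
  1e-7 in r/r0.
* Degenerate (collinear) base triplets raise in analysis paths; the
  force path clamps the normal length at 1e-10 to stay finite.
* L-BFGS-B for minimization on flattened coordinates.
* FES grids are cell-centered; min-normalization subtracts the finite
  minimum exactly, so the reported minimum is 0 by construction.
* kJ/mol internally; kcal/mol only at reporting boundaries
  (factor 4.184 exactly).
* Text writers use fixed 6-decimal formatting and are byte-deterministic.

## Known limitations

* The hills-based FES estimator retains the well-tempered late-time
  fluctuation (~0.5 kBT at γ = 30 for the benchmark lengths); the
  reweighted route is the more accurate of the two.
* The melt scan's temperature mapping is nominal: "K" labels the
  thermostat of a reduced model.
* Re-annealing scenario medians (3 vs 4) are close; the ordering holds
  at the documented seeds but is not a large-margin effect. Failure of
  the mismatched stretched start (scenario 5) is the typical outcome,
  not an absolute one: occasionally a seed re-threads within the budget.
* 176D-style PDB ingestion is provided (Biopython-backed, with
  chain-selective coarse mapping) but no experimental structure ships
  with the package; tests use synthetic fixtures.
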