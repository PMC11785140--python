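# Methods

`loopscape` implements the standard trajectory-to-kinetics analysis chain
used to map slow conformational switching in proteins — in particular the
kind of two-to-three-state activation-loop equilibrium seen in kinases such
as CK1 — together with a synthetic-dynamics layer that makes every stage of
the chain testable against exact ground truth.

## The model

The analysis assumes the system's long-time dynamics are well described by
a discrete-state Markov chain observed through geometric features. The
chain is:

1. **Featurization** (`trajfeat`). Cartesian trajectories are reduced to
   scalar collective variables: pairwise distances between atoms or
   residue-group centroids (Å), backbone φ/ψ dihedrals (degrees, IUPAC
   sign convention, range (−180°, 180°]), RMSD after optimal least-squares
   (Kabsch) superposition, and per-atom RMSF.
2. **tICA** (`tica`). Given feature series x_t, time-lagged independent
   component analysis solves the generalized eigenproblem
   C_τ v = λ (C_0 + εI) v, where C_0 and C_τ are the instantaneous and
   lag-τ covariances. Eigenvectors with eigenvalues near 1 are the slowest
   collective coordinates (TICs); for data generated by a reversible
   Markov chain, the leading eigenvalue approaches λ₂(T)^τ.
3. **Discretization** (`msmcore.cluster_microstates`). k-means (k-means++
   initialization, fixed seed) partitions TIC space into k microstates.
4. **Counting and trimming**. Sliding-window transition counts at lag τ
   (every frame a window start, never across trajectory boundaries),
   restricted to the largest strongly connected component of the count
   graph. Strong (not weak) connectivity is required because the
   reversible maximum-likelihood estimator needs an irreducible chain.
5. **Reversible MSM** (`msmcore.estimate_reversible_T`). The transition
   matrix maximizing the likelihood Π T_ij^{c_ij} under detailed balance,
   found by the standard fixed-point iteration on the symmetric variables
   x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j); the stationary distribution π
   is the normalized row sum of x. Convergence: max relative change
   < 10⁻¹⁰, cap 10⁵ iterations (non-convergence warns with the residual).
   Every returned model satisfies max|π_i T_ij − π_j T_ji| < 10⁻⁸.
6. **Validation**. Implied timescales t_i(τ) = −τΔt/ln λ_i(τ) (nonpositive
   eigenvalues are discarded with a warning), and a Chapman–Kolmogorov
   test comparing metastable-set persistence under T(τ)^k against a model
   re-estimated at lag kτ.
7. **Coarse-graining** (`msmcore.pcca`). PCCA+-style memberships from the
   top-m right eigenvectors via the inner-simplex vertex search: the m most
   spectrally extreme microstates act as vertices and every state is
   expressed as a convex combination. Tiny negative entries produced by
   the linear solve are clipped to zero and rows renormalized, so the
   membership matrix is exactly row-stochastic and nonnegative.
8. **Kinetics** (`msmcore.mfpt`, `compute_kinetics`). Metastable
   populations are crisp sums of π (membership-weighted sums are available
   as an option). MFPTs solve the first-step system h = 0 on the target,
   h_i = τΔt + Σ_j T_ij h_j elsewhere, averaged over the source with
   π-weights restricted to the source; reported in physical time via the
   frame interval, with a configurable scale to ns/μs.
9. **Landscape** (`landscape`). The free-energy surface on (TIC 1, TIC 2)
   is F = −kT ln(weighted histogram / max), with per-frame weights
   π(microstate)/count(microstate) so the surface reflects equilibrium
   populations rather than raw sampling; a raw-histogram mode is also
   provided since either convention is common. Basin comparisons use the
   integrated basin energy −kT·ln Σ exp(−F/kT), whose differences equal
   −kT·ln(population ratios). The dihedral-sign/state association uses
   Cramér's V on the 2×m contingency table with a block-permutation null
   (block length = model lag) so the p-value respects frame
   autocorrelation.

## The synthetic generator

Because μs-scale MD ensembles cannot be regenerated at analysis time, the
`synthdyn` module supplies two surrogates with exact ground truth:

* **Hidden metastable chain.** The default fixture has 9 microstates in 3
  blocks, built reversible-by-construction from a symmetric edge-weight
  matrix: within-block hop probability ≈ 0.1 per neighbour (0.2 total),
  block-pair couplings 0.004/0.002/0.001 per state pair (two orders of
  magnitude slower), and block weights 1.0/2.0/0.7 giving populations
  ≈ 0.27/0.54/0.19. Emissions are 5-dimensional Gaussians — the scale of a
  small set of informative pairwise distances — with block centres ~6 sd
  apart and within-block offsets ~3 sd. The slow eigenvalues (0.984,
  0.979) put inter-block MFPTs at roughly 90–340 steps, so ensembles of
  10 × 50 000 steps contain hundreds of transitions: enough to recover
  populations to ±0.03 and MFPTs to ±10%, which is what the test suite
  demands. The `exchange_scale` knob multiplies the block couplings and
  emulates a barrier-lowering mutation; scaling by 2.5 reduces every exact
  inter-block MFPT by ×2.45.
* **Overdamped Langevin diffusion** on a sum of inverted Gaussian wells in
  2-d, integrated by Euler–Maruyama (default dt = 10⁻³). This is the
  continuous analog of loop switching with tunable barriers; the sampler
  is validated by equipartition and a χ² Boltzmann check on a deep well
  (depth 100–400 kT wells are harmonic to < 1%).
* **Pseudo-structure emission** maps hidden state paths to Cartesian
  frames (per-state reference coordinates + isotropic jitter), so the
  file-based featurization path (PDB/DCD and a plain-text array dialect)
  is exercised end to end.

Randomness: each generator call consumes one documented PCG64 stream;
multi-trajectory ensembles use `SeedSequence.spawn` children so
trajectories are independent yet bit-reproducible from a single integer
seed.

What the surrogates do *not* emulate: real force-field energetics,
anisotropic/correlated feature noise, slow drifts or non-Markovian memory
from unresolved degrees of freedom, and periodic-boundary artifacts.
Passing the recovery tests therefore shows the estimators are correct and
well-conditioned at realistic signal-to-noise, not that any particular MD
ensemble is converged.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| tICA lag | 5 frames | near the fixture's within-block relaxation (−1/ln 0.69 ≈ 2.7 frames); slow modes remain > 0.9 |
| tICA shrinkage ε | 10⁻⁶·tr(C0)/dim | guards rank deficiency without biasing the slow spectrum |
| retained TICs | smallest n with Σλ² ≥ 0.95 (min 2) | kinetic-variance criterion; 2 mirrors the usual 2-d landscape view |
| k (microstates) | 9 | matches the fixture; real data typically needs 10²–10³ |
| MSM lag | 5 frames | implied timescales are flat (±15%) for lags 2–25 on the fixture |
| m (metastable states) | largest relative spectral gap; override to 3 | the gap rule is standard; 3 mirrors a three-basin landscape |
| MLE tol / max_iter | 10⁻¹⁰ relative / 10⁵ | fixed point is monotone in likelihood; tolerance well below statistical error |
| FES binning | 80×80 over 1st–99th percentile | robust to outliers; consistency checks use full range |
| voxel size (occupancy) | 1.0 Å | typical heavy-atom resolution for pocket maps |
| contact cutoff | 4.0 Å | conventional heavy-atom contact distance |

Degenerate inputs: absorbing chains are rejected by the stationary solver
(degenerate unit eigenvalue); empty histogram bins are masked, never −∞;
an empty dihedral sign class returns score 0 with a warning; Langevin
divergence beyond the domain bound aborts with a diagnostic; k-means ties
and PCCA vertex ties resolve deterministically for a fixed seed.

The Chapman–Kolmogorov error bands are 3× binomial standard errors with
the observation count divided by the lag factor k: sliding windows at lag
kτ overlap k-fold relative to the estimation lag, so raw counts overstate
the number of independent observations. This keeps the bands honest on
exactly-Markovian data while leaving order-of-magnitude headroom for
detecting genuinely non-Markovian (lumped hidden-state) input.

## Design choices made where the design was open

* **Association statistic** for the dihedral/loop-state analysis: Cramér's
  V, because it is bounded on [0, 1] and valid for 2×m tables; "moderate
  correlation" claims in the literature rarely name a statistic.
* **Populations** are reported from crisp (argmax) assignments by default;
  membership weighting is exposed because published population figures
  rarely state which convention was used.
* **Reversibility is always enforced** in estimation. Protein
  conformational exchange at equilibrium obeys detailed balance, and the
  reversible estimator halves the variance of π.
* **Strong connectivity** defines the active set, as required for the
  reversible MLE; disconnected sampling shows up as a shrunken active set
  in the run manifest rather than being silently patched.
* **Time units**: MFPTs are in frame-interval units times a configurable
  `time_scale`, since absolute μs values depend entirely on the saving
  interval of the source trajectories.

## Problem sizes

The validation suite and the reproduction script use 10 trajectories ×
5·10⁴ steps of the 9-state fixture (5·10⁵ frames, 5 features), 10⁵-step
single chains for spectral checks, 10⁵-frame Monte-Carlo oracles for RMSF
and first-passage statistics, and 1.5–3×10⁵-step Langevin runs. These
sizes keep every quantity's statistical error several times smaller than
the tolerance it is tested against while completing in minutes on one CPU.

## Known limitations

* No periodic-boundary imaging: inputs must be whole-molecule.
* No error bars on MSM quantities (no Bayesian sampling of transition
  matrices); recovery tolerances are validated empirically on synthetic
  ground truth instead.
* PCCA+ here uses the inner-simplex vertex search without the subsequent
  constrained optimization refinement; on well-separated spectra (the
  intended regime) the two agree, but memberships can be suboptimal when
  the spectral gap is weak — a degeneracy warning is emitted in that case.
* k-means microstates are spherical in TIC space; strongly anisotropic
  basins may need larger k.
* The CLI's `featurize` stage computes distance features only; dihedral
  and RMSD features are available through the library API.
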