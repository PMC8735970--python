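# Methods

`selectorswitch` models the maintenance of ASE neuron identity in
*C. elegans* as a stochastic bistable switch built on the terminal selector
CHE-1: CHE-1 activates its own gene (*che-1*) and several hundred target
genes, and the stability of this self-sustaining ("ON") expression state
against molecular noise is the quantity of interest.  This note records the
models, the parameter derivations, the numerical choices, and the known
limitations.

## Reaction networks

All variants share the expression backbone: the single *che-1* promoter
transcribes mRNA M at rate `fM` while productively bound, M decays at `bM`,
is translated at `fC` per transcript, and **free** CHE-1 protein C decays at
`bC` — promoter-bound CHE-1 is protected from degradation, which is what the
mass-action equations imply when the decay term carries the free pool only
(and which makes the derived `bC = fC·M/C_free` reproduce the measured
value).  CHE-1 binds any promoter at the diffusion-limited, volume-scaled
rate `fO`, and unbinds its own promoter at `bO` and the `NT` identical
target promoters at `bT`.  Target promoters are lumped into a single bound
counter; this is exact because they share both rate constants.

* `noncoop` — CHE-1 activates *che-1* as a monomer.  The deterministic
  system has two fixed points: the ON state and the origin.  The origin is a
  boundary equilibrium: deterministically repelling (one mRNA suffices to
  re-ignite the switch) but stochastically absorbing once every molecule is
  gone — we tag it "half-stable".
* `coop` — two CHE-1 molecules bind sequentially (`b1`, `b2`); only the
  doubly bound promoter transcribes.  This genuinely bistable system has a
  stable OFF state and an unstable intermediate point.
* `hd1a/b`, `hd2a/b` — a homeodomain co-factor H binds the *che-1* promoter
  at `fO_H`.  In model 1, H and CHE-1 stabilize each other on the promoter
  (dissociation from the joint complex at `bO_s << bO`) and both the
  CHE-1-bound and joint complexes transcribe; in model 2, the H-bound
  promoter transcribes at `fM_H` independently of CHE-1.  `a` variants hold
  free H clamped at `H0` (constitutive expression); `b` variants produce H
  from CHE-1 at `fH` and decay it at `bH`.  `H0` defaults to the
  production/decay balance of the matching `b` variant at the ON-state
  CHE-1 level (`round(fH·C_ss/bH)` ≈ 6000 at full scale), so promoter
  occupancies match between the paired variants.
* Optional add-ons: a reporter target promoter (binds like any target,
  makes its own mRNA at `fP`, decays at `bP`) for depletion panels, and a
  FRAP mode that mirrors every protein channel for a bleached pool which
  binds, unbinds, transcribes, and decays like the visible pool but is
  never produced.

Protocols are piecewise-constant parameter overrides (depletion = raised
`bC` in a window; transient induction = basal transcription `fM0` switched
on in a window; motif deletion = `fO_C` zero throughout) plus instantaneous
bleach events.  Simulation steps never cross an override boundary.

## Parameter derivation

Measured observables (ASER neuron): 900 CHE-1 proteins and 7 *che-1* mRNAs
per cell at steady state, a 20-minute mRNA mean lifetime, an 83 ± 20 minute
protein half-life from FRAP, binding-site cross section σ = 0.01 µm,
D = 1 µm²/s, nuclear volume 4 µm³, and NT = 500 or 1000 target promoters.

The chain is: `fO = 4πσD/V_C = 0.0314 → 0.03 s⁻¹` (the one-significant-
figure presentation is applied before deriving dependent rates, matching the
published derivation); `bM = 1/τ_mRNA = 1/1200 s⁻¹` (used unrounded — the
printed 0.00083 is its two-figure presentation, and deriving from the
rounded value misses the stable-switch `fM`); the conservation equation
`C_free + NT·θ_T + θ_O = 900` is solved for the free pool (strictly
increasing in `C_free`, Brent to 1e-12), giving the promoter occupancy
`θ_O = fO·C_free/(fO·C_free + bO)`; then `fM = bM·M_ss/θ_O` and
`bC = fC·M_ss/C_free`.  With the measured `fC` this reproduces the
published parameter tables to within their rounding (2%).

`calibrate_protein_rates_to_frap` closes the loop when `fC` is not given:
it finds the `(fC, bC)` pair that satisfies the steady state and makes the
two-pool deterministic FRAP recovery half-time match the target.  In the
two-pool model the visible total relaxes at `b_eff = bC·C_free/C_total`
(free and bound pools exchange quickly and only the free pool decays).  At
the published stable-switch pair this model gives a ≈56-minute half-time,
not 83 minutes; the original fitting protocol is under-specified, so the
operation's contract is self-consistency (round trip to ≤1%), not
reproduction of the printed pair.

## Stochastic simulation

The SSA is the exact direct method, jitted with numba: propensities are
mass-action products over at most two distinct reactant species (promoter
complements such as the free-promoter count are explicit species, which
keeps every channel bimolecular with simple counts).  Trajectories are
sampled on a uniform grid; absorbing states persist to the horizon.  Every
ensemble member derives an independent sub-seed from SHA-256 of (master
seed, indices), below 2³¹, so ensembles are reproducible and
order-independent.  Typical throughput is ~10⁷ events/s; the full-scale
unstable switch generates ~2×10⁴ events per simulated second.

The OFF criterion is explicit: zero total CHE-1 (free plus all bound) and
zero mRNA — absorbing in the non-cooperative model without basal
transcription.

## Forward flux sampling

Order parameter: total CHE-1 protein, decreasing toward OFF (the natural
choice given that transition-path panels plot occupancies against protein
level).  Interfaces are descending protein thresholds ending at the OFF
boundary (which additionally requires zero mRNA).  The first interface is
placed from pilot excursion statistics so that ~5–10% of excursions below
the pilot boundary (basin mean minus one step) reach it; subsequent
interfaces descend by a fixed step (default 20 molecules at full scale; the
interface count is clamped to [20, 35] by adjusting the step only when
necessary, and the adjustment is logged).  The basin-return boundary λ_A
sits one interface step above the first interface; the flux stage counts
first crossings after re-arming at λ_A, and shots terminate at the next
interface or at λ_A, which keeps direct FFS affordable — the rate estimate
is invariant to the λ_A choice as long as both stages use the same
boundary.  No pruning.  The lifetime is `τ = 1/(Φ₀·Πp_i)` with the error
from the delta method on log τ (Poisson flux count plus per-stage binomial
variances).  A stage with zero successes substitutes the `1/trials` upper
bound for `p_i` and flags the result as a lifetime lower bound.

Transition-path statistics are accumulated time-weighted per shot
(promoter occupancy, bound-target count, mRNA, binned by total protein) and
composed along branch ancestries; complete ON→OFF paths are weighted
equally.  When no complete path exists at the configured budget — the
situation at strongly stable parameters, where the *che-1* promoter simply
never empties — partial paths down to the deepest sampled interface can be
requested explicitly for occupancy profiling.

## Deterministic analysis

Fixed points reduce to a one-dimensional root problem in free CHE-1: at a
fixed point the binding sub-network is at equilibrium given `C` (solved in
closed form, or as a 4-state stationary distribution for the co-factor
model), mRNA balances production, and the residual is the free-protein
balance `fC·M(C) − bC·C`.  Roots are bracketed on a log grid (400 points)
and polished by Brent.  Stability comes from the Jacobian of the full
mass-action system restricted to the reduced manifold — the promoter
ledgers are exactly conserved, so the unreduced Jacobian always carries
structural zero eigenvalues that would mask the physical ones.

The required-lifetime bound treats spontaneous OFF switches as a Poisson
process: the fraction of animals losing the state within lifetime T stays
below φ iff the mean ON lifetime exceeds `T/(−ln(1−φ))` (`log1p` is used;
at φ = 10⁻⁶ naive evaluation loses four digits).  With φ = 10⁻⁶ and T = 2
weeks the bound evaluates to ≈3.8×10⁴ years; the figure of 2.3×10⁵ years
that circulates for this quantity does not follow from the stated formula,
and we implement the formula as written.

## Quantification fits

* **mRNA chase** — counts are normalized by
  `n(t) = (N(t) − N_control)/(N_HS − N_control)` and fitted with a decaying
  exponential, plateau fixed at zero.  The full pipeline
  (`fit_decay_chase`) fits with a free amplitude, so the rate depends only
  on the curve shape and not on noise in the two normalization references,
  and bootstraps animals within every group (control and each time point),
  renormalizing per resample; 95% percentile intervals.  With 10 animals
  per time point and 4 time points the interval covers the truth in ≈92%
  of synthetic replicates — the small-sample optimism of the bootstrap, not
  a defect of the estimator (whose bias is <3%).
* **FRAP** — per-trace nonlinear least squares of
  `R(t) = f/b + (x₀ − f/b)·e^{−bt}`; the population half-life is the mean
  of the per-trace `ln2/b`.
* **Protein counting** — `(I_cell/I_bath)·c_bath·V·0.6022` molecules, with
  the ellipsoid nuclear volume `V = (4/3)πxyz` from the measured radii
  (a flag converts diameters).
* **Spot counting** — Gaussian convolution, thresholding, connected
  components, and splitting of components that contain several 3-D regional
  maxima at least `min_separation` voxels apart.  The default threshold is
  the smoothed-stack median plus 5 robust standard deviations (the "manual
  threshold" of the original procedure made explicit and logged per run);
  components below 4 voxels are discarded as shot noise, and a 2-voxel
  border is excluded because reflect-padding inflates smoothed-noise
  variance at the stack faces while real spots always carry a PSF-sized
  interior margin.
* **Chemotaxis index** — `(n_on − n_off)/(n_on + n_off)`.

## Synthetic data

Generators are bit-reproducible functions of (parameters, seed) and always
store their ground truth.  The chase generator emulates the heat-shock
design: baseline 6 mRNAs, induction to 24, time points ~17 minutes apart,
10 animals per point, Poisson counting noise, plus an uninduced control
group.  The FRAP generator bleaches to 20% of the plateau and samples every
20 minutes for 3 hours with Gaussian intensity noise (σ = 0.03 of the
plateau).  The smFISH generator places 3-D Gaussian spots (σ ≈ 1–1.3
voxels) on a flat background with Gaussian read noise at rejection-sampled
positions honoring a minimum separation.  None of these emulate
autofluorescence, spot-intensity heterogeneity, camera-specific noise, or
cell-segmentation ambiguity, so passing round trips demonstrate estimator
correctness under the stated noise model, not robustness to every
real-data artifact.

## Problem sizes and presets

Stochastic analyses run at two presets.  `full` uses the measured
copy numbers (900 proteins, NT = 500); at these sizes stable-switch
lifetimes reach years and a lifetime scan is an overnight-to-days
computation.  `smoke` scales copy numbers and nuclear volume to one tenth
(fO ×10, so concentrations and promoter occupancies are preserved; the
mRNA count stays at its measured ~7), with reduced trial counts; every
qualitative signature of the full model — preferential-binding stability,
transition-path occupancy profiles, depletion resilience, the HD-TF
contract — reproduces at this scale in minutes, and the test suite runs
there.  The scaled HD-TF depletion uses a 10-fold (not 50-fold) `bC`
increase so the depleted absolute copy number (~7 molecules) matches the
full-scale depth.  The scaled fixture is also where FFS is validated
head-to-head against brute-force mean first-passage times, which is
feasible precisely because the scaled switch flips in ~10⁴ seconds of
simulated time.

## Known limitations

* Mean-field promoter occupancies in the deterministic analysis; no
  chromatin states, no spatial effects, single *che-1* promoter copy.
* The FRAP calibration's two-pool model assumes fast binding exchange
  relative to protein turnover; it is exact in that regime only.
* FFS transition-path averages weight complete paths equally (uniform
  ancestor sampling with replacement); per-branch reweighting beyond this
  is not implemented.
* The lifetime error bar assumes independent stages; correlations between
  stored configurations at successive interfaces are ignored, as in
  standard direct FFS practice.
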