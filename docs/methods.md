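# Methods

`ionpull` studies how multiple ions cross a narrow channel pore by combining
two complementary free-energy routes over the same model system: a
non-equilibrium route (step-wise harmonic pulling analysed with Jarzynski's
equality) and an equilibrium route (umbrella sampling analysed with WHAM).
The model system is a Brownian-dynamics stand-in for a bacterial
sodium-channel selectivity filter, built so that the qualitative physics of
potassium block — a pass-by ion pair wedged side-by-side in the filter,
stable only under an inward applied force — is reproducible at desk scale.

## Units and conventions

Lengths in Å, times in ps, energies in kcal/mol; k_B = 0.0019872
kcal/mol/K and T = 300 K unless stated (k_BT = 0.5962 kcal/mol).  The pore
axis is z; z increases in the inward direction (extracellular side at
negative z).  The filter spans z ≈ −15 Å (outer serine ring) to −5 Å
(inner threonine ring).  Conversions to electrophysiological units use
1 eV = 23.0605 kcal/mol per elementary charge and 1 kcal/mol/Å = 69.48 pN.

## The model landscape

A `LandscapeSpec` is a sum of analytic terms with analytic gradients
(verified against central differences at 1e-4 Å to better than 1e-3
relative error):

* **Axial features** — Gaussians U = depth·exp(−(z−c)²/2w²) per ion.
  Negative depths are binding sites, positive ones barriers.
* **Lateral confinement** — ½·k_lat·(x²+y²) toward the pore axis.  The
  presets use k_lat = 2.0 kcal/mol/Å², a thermal half-width of ~0.5 Å,
  i.e. a pore a few Å across, matching a selectivity filter much narrower
  than the ions' hydration shells.
* **Screened pair repulsion** — V(r) = A·exp(−r/ℓ)/r with A = 20 kcal·Å/mol
  and ℓ = 3 Å (water screening is implicit), soft-core clamped below
  r = 1 Å so the energy (and hence the force, which is zero inside the
  core) stays finite.  Two confined ions at the same z can only avoid each
  other laterally; relaxing the lateral coordinate, the same-z penalty is
  ≈ 4 kcal/mol above the staggered (Δz ≈ 3 Å) arrangement.  This is what
  makes "knock-on" (single-file) passage the default and "pass-by"
  (side-by-side) passage special.
* **Coordination features** — pair terms
  depth·exp(−(z̄−z_c)²/2w²)·exp(−Δz²/2t²) active only when two ions are
  near the same z (Δz within the tolerance t).  These model a
  hydrogen-bonded coordination cage that can hold an ion *pair*; they are
  what distinguishes the potassium-like from the sodium-like species.

### Presets

Both species share the channel skeleton: a broad attractive filter region
centred at z = −10, a narrow "turnstile" binding site at z = −5.5 on the
cavity side that holds one ion at a time and keeps an exiting pair in
single file, a wide vestibule well outside the entrance (z = −18) and a
wide cavity well inside (z = −1).  The two wide terminal wells let an
arriving or leaving pair spread out along z, the model's stand-in for
bulk-like solvation outside the filter.

The **Na-like** preset has no coordination features.  Its reduced two-ion
surface U₂(z1, z2) (axial terms plus the laterally relaxed repulsion) has
only off-diagonal knock-on minima and no same-z minima — two sodium-like
ions cross staggered by ~3 Å in either direction.

The **K-like** preset weakens the single-ion binding (broad well −0.5
kcal/mol) and adds two same-z coordination wells on the pass-by diagonal:

* **X** at z̄ = −10 (depth −11, width 1.6, gate tolerance 0.5 Å): the
  global minimum of the two-ion surface, a deep pair site sealed behind a
  narrow same-z gate — a staggered pair passing by cannot fall in.
* **Y** at z̄ = −13.25 (depth −6.5, width 0.9, gate tolerance 1.2 Å): a
  shallower minimum at the filter entrance with a wide gate — a doorway
  onto the diagonal.

The preset geometry was tuned for topology, not to match any particular
all-atom energy value: the analytic K-like surface must show exactly two same-z minima
with X global and Y shallower, and the Na-like surface none (checked
directly by the minima finder on the analytic surface, and again on the
WHAM reconstruction).  One deliberate departure from a strictly thermal
block: X's escape barrier is several k_BT rather than ~1 k_BT, because a
k_BT-scale trap produces no detectable occupancy signature at desk-scale
sampling with the fixed detection thresholds below.  The block is
therefore somewhat stickier here than a marginal minimum, while the work
to break it (5–10 kcal/mol, see below) stays on the experimentally
relevant scale of tens-of-mV breaking potentials.

### Why the block is one-way

Pulled inward, a pair starts compressed (both ions fed to the filter mouth
at the same z), enters the Y doorway, slides along the diagonal into X and
wedges there; the shared restraint center λ pushes both ions to the same
point and holds the pair on the diagonal.  Pulled outward, the pair
arrives staggered (turnstile plus repulsion), cannot cross X's narrow
gate, passes Y only transiently, and decompresses into the vestibule — no
block, and little extra work.

## Dynamics

Overdamped Langevin (Euler–Maruyama): each coordinate advances by
(D/k_BT)·F·dt plus Gaussian noise of variance 2·D·dt.  Defaults
D = 0.2 Å²/ps per species (the order of bulk ion diffusivities; the
effective in-filter diffusivity of a real channel is unknown, so this is a
stand-in) and dt = 0.01 ps (0.005 ps under stiff biases), subject to the
stability bound k_max·D·dt/k_BT < 0.1, which aborts a run before it
starts rather than mid-flight.  Validation: stationary variance in a
harmonic trap equals k_BT/k within 5%, a flat potential samples uniformly
(chi-square on independent walkers), and −k_BT·ln(histogram) recovers a
2 kcal/mol test well to better than 0.1 kcal/mol at 10⁶ frames (depth read
off a least-squares fit of the recovered profile).

Randomness is counter-based: stream j under master seed s uses
`SeedSequence(s, spawn_key=(j,))`, so replica sets are order-independent
and every result is bit-reproducible from (spec, config, seed).

## Step-wise pulling and Jarzynski analysis

All ions share one harmonic restraint U = ½k_lat(x²+y²) + ½k_ax(z−λ)² with
k_ax = 0.6 kcal/mol/Å² by default (a 2 Å lateral excursion costs 1.2
kcal/mol ≈ 2 k_BT).  λ moves in 1.0 Å increments: inward −20 → −2 Å (19
steps), outward 4.5 → −17.5 Å (23 steps).  Each increment is an
instantaneous switch at frozen coordinates; its work is the restraint
energy jump ΔW = Σ_ions ½k_ax[(z−λ')² − (z−λ)²] (lateral terms cancel),
followed by a relaxation period τ.  Relaxation times map the conventional
nanosecond-scale values onto simulator time through a single factor of
1/100 — Brownian ions on a smooth landscape decorrelate about two orders
of magnitude faster than ions in an explicit filter — giving τ = 5 ps
(fast) and τ = 30 ps (slow, the default for the asymmetry studies).

Per λ-switch, the work samples over replicas form a distribution and
ΔF = −k_BT·ln[(1/Q)Σ exp(−W_q/k_BT)] (overflow-safe log-sum-exp).  This
per-step form assumes the relaxation re-equilibrates the system at each
λ — the reason τ must be several restraint relaxation times k_BT/(D·k_ax)
(≈ 5 ps at k_ax = 0.6).  The per-step uncertainty is
[σ²_W/Q + σ⁴_W(k_BT)⁻²/2(Q−1)]^½ and accumulates across steps in
quadrature, ignoring step-to-step correlations.  Profiles ΔF(λ) are
anchored at 0 at the schedule origin.

Per-ion components use the total-work exponential weights
w_q ∝ exp(−ΔW_q/k_BT) applied to each ion's work, with the fluctuation
part of the total estimate shared equally:
ΔF_j = ⟨ΔW_j⟩_w + (ΔF − ⟨ΔW⟩_w)/N.  This makes components sum to the
total exactly at every λ; an independent per-ion exponential average is
available behind a flag but does not decompose exactly.

Estimator checks: a degenerate distribution returns its value; Gaussian
work returns μ − σ²/2k_BT; the estimate never exceeds the sample mean
(Jensen); a flat landscape returns ΔF = 0 within twice the reported
uncertainty at 50 replicas × 10 steps.  For the flat-landscape null check
a soft spring (k_ax = 0.3) keeps σ_W below k_BT; wider work distributions
make the exponential average noticeably skewed at Q = 50.

## Umbrella sampling and WHAM

Windows bias z of one ion (1D) or (z1, z2) of a pair (2D) with
k_umb = 10 kcal/mol/Å²; a warning fires when √(k_BT/k_umb) < spacing/2.
All windows run as one vectorized walker batch.  WHAM iterates

    P(ξ) ∝ Σ_k h_k(ξ) / Σ_k N_k exp[(f_k − U_k(ξ))/k_BT],
    f_k = −k_BT ln Σ_ξ P(ξ) exp(−U_k(ξ)/k_BT)

in log space until max|Δf_k| < 1e-7 kcal/mol (default cap 1e5 iterations;
hitting the cap, or a window-overlap graph that is disconnected — which
leaves relative offsets undetermined — flags the result non-converged).
Unsampled bins stay masked; the PMF is −k_BT·ln P with its sampled
minimum at zero.  Recovery checks: a single unbiased window returns
−k_BT·ln h exactly; a flat landscape reconstructs flat to < 0.15 kcal/mol;
an asymmetric double well is recovered to < 0.25 kcal/mol RMSE with 19
windows × 2×10⁴ frames; the solution is invariant to window order,
uniform count doubling, and constant bias offsets (gauge).

Feature extraction on 2D grids: local minima are bins below all eight
neighbours (complete unmasked neighbourhoods only, so grid-boundary bins
never qualify), kept when their prominence — bottleneck saddle toward any
deeper minimum, minus their own value — exceeds `min_depth` (default 0.3
kcal/mol); the deepest is global.  Paths are bottleneck-optimal on the
8-connected grid (Dijkstra on the minimax cost, ties broken by path
length then lexicographic node order, for determinism), labelled
knock-on-like, pass-by-like or mixed by whether |z1−z2| exceeds the
same-z tolerance along the way.  A pair configuration is "pass-by" iff
|z1−z2| ≤ δ (boundary inclusive), δ = 1.0 Å by default.

## Stiff-spring equivalence

With k_ax = 20 kcal/mol/Å², Δλ = 0.125 Å and 256 replicas on a known 1D
landscape, the Jarzynski profile and the WHAM PMF of the same landscape
agree to ≲ 0.15 kcal/mol RMSE (tolerance 0.3) after removing the additive
offset — the two free-energy routes coincide in the stiff-spring limit.
The fine Δλ keeps the per-switch work distribution narrow (σ_W ≈ 0.9
kcal/mol); coarser switching biases the exponential average at this Q.

## Trajectory analytics

* **Axial histograms** per ion; counts conserve frames.
* **Pair density** over (z1, z2) for a designated pair, optionally
  symmetrized under ion relabelling.
* **Block detection**: counts inside the diagonal band |z1−z2| ≤ δ (1.0 Å)
  are pooled per diagonal position; the candidate region is the longest
  contiguous run of positions holding at least 10% of the peak position
  count (a full-width-style region definition); a block is detected when
  the run's pooled occupancy reaches θ_occ = 0.2 of all frames.  θ_occ is
  an artifact parameter (blocking areas are conventionally read off a
  density plot by eye) and the same thresholds are applied to both pulling
  directions when testing asymmetry.
* **Shared solvent**: a solvent point is shared when it lies within the
  instantaneous ion–ion distance r12 of *both* ions (the lens where the
  two spheres overlap; the union reading is rejected because the sites are
  "between" the ions).  Per-step averages use the final 5/6 of each
  relaxation window.
* **Asymmetry summary**: per-direction maximum cumulative work over the
  filter span, and the block-escape work — the rise from the lowest ΔF
  inside the block region (λ ∈ [−15, −10]) to the highest ΔF before the
  first subsequent local minimum along the pulling direction.  A dip only
  terminates that search if the profile rises again by > 0.75 kcal/mol
  (≈ 1.25 k_BT); smaller wiggles at Q ≈ 64 are sampling noise, not
  metastable states.

On the K-like preset with matched protocols (τ = 30 ps, 64 replicas) the
block is detected inward and not outward at identical thresholds, with an
inward blocking extent of ~3 Å; the inward escape work is 5–8 kcal/mol
against 1–3 kcal/mol outward, a ≥ 2σ separation across the seeds
examined.  The Na-like preset detects no block in either direction.  The
inward escape work corresponds to breaking potentials of roughly 80–120 mV
for three charges.

## Problem sizes

The shipped analyses run minutes on one CPU: pulling studies use 32–64
replicas of 2-ion systems over 19–23 steps of 30 ps; umbrella studies use
19–25 windows × 2×10⁴ frames (1D) or 121 windows × 4×10³ frames (2D);
simulator validation uses 10⁵–10⁶ recorded frames pooled over independent
walkers.  These sizes were chosen so that every stochastic tolerance above
is met with margin at typical seeds.

## What the synthetic generator does and does not emulate

It emulates: diffusive multi-ion motion on species-dependent landscapes
with screened repulsion and lateral confinement; pass-by versus knock-on
pair topology; harmonic stepped pulling with relaxation; point solvent for
shared-water counting.  It does not emulate: explicit water, protein
flexibility, electrostatics beyond the screened pair term, ion-specific
dehydration energetics, or the absolute kcal/mol values of any
all-atom landscape.  Passing tests therefore demonstrate that the
*estimators and detectors* behave correctly on landscapes with the right
topology — not that the model reproduces a specific channel's energetics.

## Known limitations

* Step-to-step correlations are ignored in profile uncertainties.
* Per-step Jarzynski estimates assume re-equilibration within τ; the
  cumulative-work form (exact for any τ but far noisier) is not the
  default.
* The effective diffusion constant in a real filter is unknown; D is a
  stand-in and the time mapping (1/100) is a convention, so simulated
  times should be read in units of the restraint relaxation time.
* Block detection thresholds (δ, θ_occ, the 10% region definition) are
  artifact parameters; conclusions are only meaningful when the same
  thresholds are applied to the conditions being compared.
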