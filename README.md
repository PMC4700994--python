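# ionpull

Free-energy analysis of multi-ion permeation through a narrow channel
pore: step-wise harmonic pulling with Jarzynski reweighting, umbrella
sampling with WHAM, and the trajectory analytics needed to characterise a
potassium-type block — all over a Brownian-dynamics model of a
sodium-channel selectivity filter.

## The problem

Bacterial voltage-gated sodium channels conduct Na⁺ in both directions but
pass K⁺ essentially only outward.  The proposed mechanism is a *block
state*: under an inward driving force, two K⁺ ions end up side by side at
the same axial position ("pass-by" configuration) and wedge against the
filter walls, while Na⁺ ions file through staggered in a loose "knock-on"
chain.  Crucially, the block lives in a minimum of the *equilibrium*
two-ion free-energy landscape that only becomes kinetically decisive under
an applied force — so equilibrium landscapes alone miss it, and
non-equilibrium pulling alone cannot place it on the landscape.  This
package is for computational biophysicists who want both routes over one
system, with estimators and detectors that are each validated against
exact oracles.

Two free-energy routes share the machinery:

* **Non-equilibrium**: all ions carry one harmonic restraint
  U = ½k(x² + y²) + ½k(z − λ)²; λ advances in 1 Å steps, each an
  instantaneous switch (work ΔW = Σ ½k[(z−λ')² − (z−λ)²]) followed by a
  relaxation time τ.  Jarzynski's equality,
  exp(−ΔF/k_BT) = ⟨exp(−W/k_BT)⟩, turns the per-step work distributions
  into a "useful work" profile ΔF(λ) with per-ion components and the
  uncertainty [σ²_W/Q + σ⁴_W(k_BT)⁻²/2(Q−1)]^½.
* **Equilibrium**: overlapping harmonic umbrella windows in z (one ion) or
  (z₁, z₂) (an ion pair), recombined by the self-consistent WHAM
  equations into a 1D/2D PMF, from which local minima (the pass-by minima
  X and Y), their prominences, and bottleneck-optimal permeation pathways
  are extracted.

In the stiff-spring limit the two routes coincide, and the package tests
that they do.

## Worked example

Matched inward and outward pulling of a potassium-like ion pair
(τ = 30 ps, 64 replicas per direction), with block detection at identical
thresholds and the block-escape work from the Jarzynski profiles:

```python
import ionpull as ip
from ionpull.protocols import asymmetry_study

study = asymmetry_study(ip.k_like_preset(), seed=7, n_replicas=64)
blk_in, blk_out = study["block_inward"], study["block_outward"]
rep = study["asymmetry"]
print(f"inward block:  detected={blk_in.detected}  "
      f"extent={blk_in.extent:.1f} A  occupancy={blk_in.occupancy:.2f}")
print(f"outward block: detected={blk_out.detected}  "
      f"occupancy={blk_out.occupancy:.2f}")
print(f"escape work: inward {rep.inward_escape_work:.1f} +/- {rep.inward_escape_err:.1f}, "
      f"outward {rep.outward_escape_work:.1f} +/- {rep.outward_escape_err:.1f} kcal/mol")
print(f"equivalent breaking potential: "
      f"{abs(ip.energy_to_potential(rep.inward_escape_work, 3)):.0f} mV (3 charges)")
```

prints

```
inward block:  detected=True  extent=3.0 A  occupancy=0.30
outward block: detected=False  occupancy=0.14
escape work: inward 6.4 +/- 0.9, outward 2.3 +/- 1.0 kcal/mol
equivalent breaking potential: 92 mV (3 charges)
```

Reading this: pulled inward, the pair spends 30% of all frames in a ~3 Å
stretch of the same-z diagonal — the block — and needs ~6 kcal/mol of
extra work to break out of it, the equivalent of roughly a −90 mV membrane
potential acting on three charges; pulled outward under the same detector
thresholds no block forms and the pair leaves almost freely.  The
sodium-like preset (`ip.na_like_preset()`) detects no block in either
direction.

The same stages are scriptable from the shell (`ionpull pull`,
`ionpull jarzynski`, `ionpull umbrella`, `ionpull wham`,
`ionpull analyze`, `ionpull convert`), reading a YAML run configuration
and writing plain-text trajectories, work ledgers, PMF grids and JSON
reports; every output embeds the resolved configuration digest so a run
can be reproduced bit-identically from its own files.

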