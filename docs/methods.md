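# Methods

## Rate-theory chain

All bimolecular rate constants are handled in M⁻¹s⁻¹ and converted to the
per-nucleus volume units used by the simulations (µm³ s⁻¹, i.e. molecules
per µm³) with `k × 10¹⁵ / N_A`, `N_A = 6.022×10²³`.  Lengths are stored in
nm and converted to µm inside the diffusion formulas; site separations are
in bp (0.34 nm/bp where a physical length is needed).

The chain runs: free-protein diffusion limit → activation-limited rate
(Collins–Kimball partition of the measured association constant) →
bound-protein diffusion limit → effective second-end capture constant
(harmonic composition) → looping local concentration → synapsis rate
`k2 = k1′·j_M`.  The activation-limited rate is a molecular property, so
the crowded-nucleus chain reuses the dilute-solution value; recomposing it
with the crowded diffusion limit yields the in vivo first-end constant.
The equation groupings were fixed by requiring that the chain reproduce
every derived constant of both shipped parameter presets to two
significant figures, which is also the tolerance used throughout the test
suite (5% relative), since the reference values are printed rounded.

Physical inputs (shipped as `presets/in_vitro.yaml`, `presets/in_vivo.yaml`):
persistence length 50 nm; reaction radius 2.5 nm; protein diffusion 61
(dilute) / 15 (crowded) µm²/s; segmental DNA diffusion 27 / 5×10⁻⁴ µm²/s;
measured specific association 3.8×10⁸ M⁻¹s⁻¹; end separation 1287 bp.

## Invasion models

State is molecule counts in a single well-mixed nucleus (default 500 fl,
diploid 3×10⁹ bp genome giving 6×10⁹ non-specific sites).  Because the two
transposon ends are identical, end-level species are collapsed to
unordered transposon pools (both-free / singly-occupied / doubly-occupied
/ synapsed) with statistical factors 2 on first binding and on
dissociation from the doubly-occupied state; the collapse halves the state
count with identical dynamics.  Non-specific sites are held at constant
excess: only the ratio k₋₀/k₀ matters, as it sets the free fraction of
transposase (7.0×10⁻⁴ with the default constants).

Kinetic defaults (all overridable per scenario): k₀ = 9.9×10⁶ M⁻¹s⁻¹,
k₋₀ = 139 s⁻¹, k₁ = 3.8×10⁸ M⁻¹s⁻¹, k₋₁ = 1.2×10⁻² s⁻¹, k₂ = 12.7 s⁻¹
(derived), k₋₂ = 10⁻¹⁰ s⁻¹ (synapsis is irreversible once the first nick
is possible), k₃ = 1.4×10⁻³ s⁻¹.  Crowded-nucleus presets override
k₀ = 5×10⁶, k₁ = 1.9×10⁸ and k₂ = 4.5×10⁻⁴ (the figure-level preset value;
the derivation chain itself gives 4.3×10⁻⁴, the difference being rounding
of intermediates).  Allosteric presets replace the idealized synapsis and
end-dissociation rates with the experimental estimates k₂ = 9.6×10⁻⁵ s⁻¹,
k₋₁ = 5.8×10⁻⁴ s⁻¹ (dilute) and k₂ = 3.4×10⁻⁹ s⁻¹ (crowded; consistent
with scaling the dilute estimate by the ideal-chain crowding penalty).
One source prints the allosteric k₋₁ as 5.8×10⁴ s⁻¹; that value would give
sub-millisecond end residence and contradicts the measured 20-minute
dissociation half-time, so it is treated as a sign typo for 5.8×10⁻⁴.

Expression is instantaneous: total transposase is algebraically slaved to
`expression_per_copy × N` (500 dimers per copy in the dimeric models,
1000 monomers in the monomeric ones), implemented as a production flux
proportional to dN/dt.  The conservation residual is checked at every
stored trajectory point.

**Copy-number coupling.**  A matured synapse converts one copy into
`efficiency` copies.  In the deterministic equations this is treated as
geometric compounding: the net flux into N is `ln(efficiency)·k₃·P`, the
completing transposon re-enters the unbound pool with its gained siblings,
and its transposase returns to the free pool.  The logarithmic form makes
the steady occlusion-buffered rate proportional to log₂(efficiency) —
scaled to 1 at efficiency 2 the curve is `y = ln(x)/ln 2 = 1.4427·ln(x)` —
so efficiency 1 is exact stasis, an efficiency of 1.5 costs roughly half
the rate, and efficiencies below 1 give constant-rate copy loss.  The
per-event expectation form `(efficiency−1)` was considered and rejected:
it predicts scaled steady rates equal to `x−1`, which is inconsistent with
the logarithmic efficiency–rate relationship this model family exhibits.
The stochastic oracle realises the same flux as a Bernoulli(|ln e|) copy
gain (or loss) per completion, so ODE and oracle agree in expectation by
construction.  Efficiency is restricted to (0, e] — 2 is the biological
maximum anyway.

**Variant hooks.**  A cis-acting fraction *f* of expression forms a
private per-copy pool; its completion propensity is solved from the
stationary distribution of the single-copy binding/synapsis cycle at the
fixed private concentration, and added per copy.  The private pool is
buffered by non-specific chromatin binding exactly like the bulk pool
(omitting that buffer would make a 99%-cis element *faster* than the
unregulated baseline, inverting the intended comparison).  A trans-acting
inhibitor of potency κ scales effective expression — bulk and cis alike —
by 1/(1+κ): inhibitor and transposase are co-expressed, so the suppression
is copy-number independent; applying it to the bulk pool only would leave
the near-saturating private pool untouched and the combined cis+inhibitor
strategy ineffective, contrary to its observed behaviour.  A secondary
inhibitory binding site (association `multiplier × k₁`, dissociation k₋₁)
splits every pool by secondary-site occupancy and blocks the synapsis flux
while occupied; multiplier 0 reduces exactly to the baseline.  The DEO
model implements the simplified scheme in which only free monomers
dimerize; monomers and inactive dimers exchange with the non-specific pool
at the same constants, and the dimerization constant defaults to k₁ but is
an independent parameter (the steady-rate invariance under end-association
scaling holds when dimerization is held fixed).

## Simulation engine

`solve_ivp` with LSODA at rtol 10⁻⁸, atol 10⁻⁶ counts (halving the
tolerances moves endpoints by <10⁻⁸ relative); BDF is retried
automatically on the rare stiffness failure.  Output is 400 points on a
logarithmic grid (linear for established-state scans); a terminal event
caps runaway copy numbers at 10¹² and trajectories record whether they
were truncated.  Scenario time spans are the smallest in which each
scenario's regime diagnostic converges and are recorded in the registry.

"Rate of transposition" means dN/dt; the per-copy rate is the completion
flux divided by N.  The steady-state rate is the least-squares slope of
N(t) over the trailing half-window, flagged steady when the slope change
between the window's halves is below 1% per doubling of N.  Regime
classification compares the relative variation of dN/dt against that of
d ln N/dt over the trailing window (both invariant to rescaling time or
copy number), with explicit negative-growth and lag rules.

The efficiency scan starts each run from an established invasion (200
copies, binding pre-equilibrated by fixed-point partition of transposase
among free, non-specific and end-bound pools): steady *decay* rates for
efficiencies below 1 are only defined from an established state, since
from a single copy the element simply dwindles to zero.  Fixed-copy-number
comparisons (expression, genome size, volume, affinity scans) integrate to
a terminal event at the target copy number and evaluate the flux there.

## Synthetic data

Measurement noise is multiplicative lognormal with unit mean (gel, EMSA
and colony-count signals are positive with roughly proportional error);
the CV defaults (10% for gels/EMSA, 20% for colony counts) are package
conventions, not measured values.  Colony counts can be Poisson-sampled on
top.  Every generator takes an integer seed (numpy `default_rng`) and is
byte-reproducible; the truth parameters ride along in the dataset record.

The gel time course integrates the test-tube reaction (molar units, no
genome, no expression) with binding pre-equilibrated before time zero,
emulating the pre-incubation stage before the catalytic metal ion starts
catalysis.  At the optimal ratio of one dimer per transposon the initial
assortment is ¼ unbound / ½ singly-occupied / ¼ doubly-occupied, so only
half the substrate can react at first and the quarter-consumption time
approximates the synapsis half-time ln 2/k₂ (redistribution of occluding
dimers makes the simulated value ~15% faster than that identity).

The stochastic oracle is an exact event-driven (Gillespie) simulation of
the naked-end-capture network on small instances (≤50 copies, ≤10⁴
transposase molecules; larger systems are refused with guidance).  It is
used to validate the ODE species trajectories within 3 standard errors of
200-run ensemble means, with and without non-specific exchange and with
and without copy-number growth.

## What the synthetic data do and do not show

The generators emulate the *form* of the measurements (first-order decay,
pseudo-first-order consumption, inverse power law) under the package's own
noise model.  Passing recovery tests therefore demonstrates estimator
consistency — the pipeline returns what generated the data — not that real
gels or colony assays obey lognormal noise, and not that the biological
ground truth equals the preset constants.  Real data add baseline and
quantification artefacts, partial transposase activity and plasmid
topology effects that are outside this model.

## Known limitations

* A single well-mixed nucleus: no chromatin state, no spatial structure,
  no cell cycle; "efficiency" compresses replication timing and donor-site
  repair into one number.
* Non-specific sites never saturate; above ~10⁷ copies (≥5×10⁹ expressed
  dimers) that assumption weakens exactly where the dilute-solution
  occlusion landmark lies.  The landmark computed here (~4×10⁵ copies for
  50% per-copy inhibition) is accordingly an in-model statement; analytic
  estimates put it at the same order, but reference accounts of this
  quantity disagree internally by an order of magnitude.
* The continuous ODE treats copy number as a real variable; below ~10
  copies the stochastic oracle, not the ODE, is the right tool.
* The DEO model is the simplified only-free-monomers-dimerize scheme; the
  full state graph with mixed monomer/dimer species on partially assembled
  complexes is documented but not integrated.
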