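# Methods

## The model

`presyn` simulates competitive blockade of presynaptic T-type (Ca_v_3.1-like)
calcium channels by a small-molecule antagonist, and its downstream effect on
synaptic-vesicle release.  The synapse is three compartments — an
extracellular region (4.63 µm³), the pre-synapse (0.21 µm³) and an inert
post-synapse (0.15 µm³) — coupled by reactive faces of the presynaptic
membrane.  Five processes act on nine species:

| reaction | meaning | rate constant |
|---|---|---|
| Ca_out + A → Ca_pre | calcium transport through an open channel | k₁ = 1.0×10⁸ M⁻¹s⁻¹ |
| M + A → E | drug irreversibly blocks a channel | k₂ ∈ {0.5×10⁶ … 1.0×10⁸} M⁻¹s⁻¹ |
| Ca_pre + V → D | calcium–vesicle complex formation | k₃ = 1.0×10⁷ M⁻¹s⁻¹ |
| Ca_pre + P → Ca_out | extrusion by calcium pumps | k₄ = 1.0×10⁷ M⁻¹s⁻¹ |
| D_pre → D_released | complex escape through the active face | first-order surrogate |

Binding is irreversible throughout: neither a calcium ion in transit nor a
bound drug molecule leaves a channel, so blocked channels absorb.  Channels
and pumps sit on membrane sub-faces at 10⁴ µm⁻²; their copy numbers are
density × face area.  Diffusion coefficients: Ca²⁺ 6×10⁻⁶, drug 1×10⁻⁶,
vesicles 1.2×10⁻⁶, complexes 1×10⁻⁶ cm²/s.  Initial copy numbers: 3,000
Ca²⁺ and 0/500/1,500 drug molecules uniform in the extracellular region.

Two engines share this parameterisation:

* **well-mixed** — exact Gillespie (direct-method) SSA over mass-action
  propensities, with a deterministic mean-field ODE integrator as the
  large-copy-number oracle.  The direct method is affordable here (≲10⁴
  particles, five reaction channels, ~2×10⁴ events per 0.2 s run).
* **spatial** — Brownian-dynamics Monte Carlo with explicit particle
  positions in axis-aligned boxes holding exactly the compartment volumes.
  Per-axis displacements are N(0, 2·D·dt); walls reflect except the reactive
  faces.  Surface-hit acceptance probabilities are calibrated from the
  one-sided diffusive wall flux, p = k̂·√(π·dt/D)/A_tile, so the dilute
  reaction-limited regime reproduces the configured rate constant (enforced
  by test against the SSA).  The Ca–vesicle volume reaction uses a Doi
  scheme: pairs within a 10 nm binding radius react with probability
  k̂·dt/V_radius, valid because k₃ is ~5,000× below its Smoluchowski limit.
  Per-event probabilities are capped at 0.2; larger values raise an error
  instructing a smaller dt (at k₂ = 10⁸ M⁻¹s⁻¹ the drug's face probability
  requires dt ≲ 0.4 µs).

## Delivery-limited face kinetics

In the spatial engine, reaction at the channel face requires diffusion to a
small membrane patch.  When intrinsic binding is fast, this transport step —
not the rate constant — limits the flux, and it throttles the drug (D =
1×10⁻⁶ cm²/s) six times harder than Ca²⁺.  The well-mixed engine captures
the same physics without positions through a Collins–Kimball series
resistance: the conductance of each face reaction is

    G = ( 1/(n_free·k̂) + 1/(4·D·a) )⁻¹ ,

the harmonic combination of intrinsic binding and diffusive delivery to an
absorbing disk of the face's radius a.  Propensities become
n_ligand·G/V, i.e. plain mass action damped by 1/(1 + n_free·k̂/(4Da)).
This correction (config flag `transport_limited`, default on) is what lets a
non-spatial engine reproduce the spatial model's drug/calcium competition;
switching it off recovers textbook mass action.  A direct measurement of
the influx rate in the particle engine agrees with the corrected conductance
to within ~6% (the residual reflects the disk idealisation of a square
face on a finite box).

## Channel mode

The influx reaction can be read two ways: the channel is *consumed* by the
transport (permanently occupied by its calcium ion) or acts *catalytically*
(stays open, only the drug retires it).  Both are implemented
(`channel_mode`).  The default is **catalytic**, for a structural reason
found during calibration: in consumed mode the drug's share of channels is
pinned to the instantaneous flux ratio, which forces the bound-drug count
and the release deficit apart by ~30% no matter how the free knobs are set.
In catalytic mode, full blockade of a sub-1,500 channel population
reproduces both the bound-drug plateau (~750) and the released-complex
deficit, as well as the strongly superlinear effect of drug count (500 drug
molecules cannot block all channels; 1,500 can).

## Calibration of unprinted parameters

Four quantities needed by the model are not part of the published
parameterisation and act as calibration knobs.  They were fitted once, by
least squares of the mean-field ODE against the published released-complex
counts over the full drug × k₂ grid (two query times) plus the bound-drug
count, and then frozen as package defaults:

| knob | default | role |
|---|---|---|
| channel face area | 0.0755 µm² (755 channels) | influx conductance; bound-drug plateau |
| pump face area | 0.001 µm² (10 pumps) | extrusion flux (negligible at this setting) |
| vesicle count | 3,000 | capture rate and release ceiling |
| release rate | 17 s⁻¹ | active-face escape surrogate; late-time rise |

The calibrated model reproduces the six headline quantities (released-count
reduction ~26%, bound drug ~700, k₂ sensitivities ~4%/~25%, and the two
strongest-blockade released counts) to within ~7% in the mean field.  The
pump face calibrates to near zero: on a 0.2 s horizon with k₄ = 10⁷ M⁻¹s⁻¹,
extrusion must be ≪ vesicle capture for the observed counts, so pumps are
present but kinetically negligible at the defaults.

## Stochastic protocol

The published counts come from single simulation runs; this package treats
single stochastic runs as unacceptable evidence and reports replicate means
± sd (default 10 replicates; the bundled result script uses 200).
Per-condition seeds derive from SHA-256 of (base seed, drug count, k₂), so a
sweep is reproducible and independent of execution order.  Trajectories are
sampled on a 1 ms grid over 0.2 s.

Problem sizes used by the test-suite and result script: the headline grid
runs the SSA at full scale (3,000 Ca²⁺, 200 replicates per condition, ~80 s
total).  Spatial-engine validations run scaled-down systems (200–2,000
particles, 4–15 ms horizons): a reaction-limited box against the SSA oracle
(5% tolerance), a 30× diffusion speed-up against the SSA within Monte Carlo
error, an Einstein-relation check on step statistics, and dt-halving
stability.  Full-scale spatial runs of the 0.2 s protocol are supported but
take hours in this implementation and are not part of the default suites.

## Screening evaluation

ROC/AUC over actives vs decoys follows the ranking convention of empirical
docking scores (higher = better).  Ties receive half credit, making the AUC
identical to the normalised Mann–Whitney U; tests enforce exact agreement
with a brute-force pairwise count.  The synthetic score generator draws
actives from N(µ, 1) and decoys from N(0, 1), giving the closed-form
AUC = Φ(µ/√2) used as the convergence oracle — the Gaussian model is chosen
for that closed form, not as a claim about real score distributions.  The
real screening campaign's AUC depends on an external docking program and
compound library and is out of scope.

## Trajectory metrics

RMSD uses proper Kabsch superposition (SVD via scipy's rotation solver,
det = +1 enforced); RMSF superposes all frames on an iteratively refined
mean structure first, so rigid-body motion never counts as fluctuation.
SASA is Shrake–Rupley on a golden-spiral point lattice (default 960 points;
≥92 enforced); exactly coincident atoms are deduplicated rather than
mutually buried.  Hydrogen bonds use the conventional geometric criterion,
3.5 Å donor–acceptor and 30° H–D–A, both exposed as parameters.  PCA
eigendecomposes the aligned-coordinate covariance; the free-energy landscape
is ΔG = −k_B·T·ln(P/P_max) over a 2-D histogram of the first two
projections at 300 K in kJ/mol, with unoccupied bins unbounded.  All
metrics are validated against closed-form fixtures generated by
`presyn.synth`; published MD observables require production trajectories
from an MD engine and are not validation surfaces here.

## Numerical notes and limitations

* SSA sampling records the state immediately before each grid time; fixed
  seeds give bit-identical trajectories.
* The ODE integrator (LSODA, rtol 10⁻⁹) self-checks by re-integration at
  tightened tolerance.
* SASA is rotation-invariant only to its lattice discretisation (≲1% at
  960 points); PCA/RMSF superposition leaks a ≲0.1% variance sliver into
  rigid-body directions for small atom counts.
* The spatial engine folds once at reflections (valid for step σ ≪ box),
  resolves at most one reaction per particle per step, and treats released
  complexes as inert once in the extracellular box.  The active-face escape
  has no unique well-mixed analogue; cross-engine comparisons therefore pool
  formed complexes (D_pre + D_released).
* Compartment shapes are boxes with the correct volumes; the published
  surface meshes are not available, which is precisely why face areas are
  calibration knobs rather than inputs.
* No calcium buffering, channel gating, membrane potential, organelle
  obstacles or cooperative multi-calcium fusion.
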