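# Methods

This note documents the models implemented in `ethmig`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical decisions a user should know about.

## Units

Dynamics run internally in (amu, Å, fs); interfaces use atomic units for
momenta, eV for energies, fs for times and Å for distances.  All conversion
factors are derived from scipy's CODATA constants
(ħ²-free: k = e²/4πε₀ = 14.3996 eV·Å, 1 hartree = 27.2114 eV,
1 amu = 1822.888 mₑ).  Fragment-ion masses are integer amu: the experiment
this pipeline serves separates species by nominal mass-to-charge, so
isotope-resolved masses would add nothing.

## Ethanol geometry

One hard-coded anti (trans) conformer built from standard bond lengths
(r(C–O) = 1.43 Å, r(C–C) = 1.52 Å, r(O–H) = 0.97 Å, r(C–H) = 1.09 Å) with
tetrahedral angles, role labels (O, C_α, C_β, hydroxyl/α/β hydrogens).  Real
samples contain two low-lying conformers; conformer-level differences are
not analyzed here, so a single conformer keeps the geometry a fixed, fully
specified input.  The `conformer` argument exists as a configuration stub.

## Coulomb-explosion simulator

Fragments are unit point charges at the centers of mass of the fragment
atom groups in the intact geometry.  Propagation is velocity Verlet under
pairwise Coulomb forces with a base timestep of 0.05 fs.  Two numerical
choices matter:

* **Separation-scaled timestep.**  The step grows as
  `dt = dt0 · (r_min/3 Å)^1.5`, capped at 25 fs, where `r_min` is the
  closest pair distance.  Forces decay as 1/r², so the integration error per
  step shrinks faster than the step grows; measured total-energy drift stays
  below ~2·10⁻³ % of the released energy over a full explosion, orders of
  magnitude inside the 0.1% tolerance asserted by the tests.  A fixed 0.05 fs
  step would need ~10⁶ steps per event to reach the asymptote.
* **Asymptote criterion.**  Propagation stops when the residual pairwise
  potential is below 0.1% of the accumulated kinetic energy (hard cap 50 ps
  of simulated time).  The reported KER is the kinetic energy at
  termination, so it underestimates the true asymptotic KER by at most the
  0.1% residual (≈0.4% at the cap for the slowest, 10 Å two-body case, still
  inside the 0.5% oracle tolerance).

Orientation is sampled uniformly over SO(3) via normalized Gaussian
quaternions from a seeded generator; all ensembles are reproducible from
their seed.

### Sequential breakups

The triple coincidence H⁺ + H₂O⁺ + C₂H₃⁺ is fed by three two-step
mechanisms, simulated as: (1) two-body explosion of the dication from rest;
(2) at an ionization delay `t_ionize`, the intermediate fragment gains one
charge and splits into two daughters placed along an isotropically random
direction with the center of mass and momentum preserved and zero internal
velocity; (3) three-body propagation to the asymptote.

| process | first fragment | intermediate | daughters | daughter separation |
| --- | --- | --- | --- | --- |
| seq_i | C₂H₃⁺ | H₃O⁺ | H⁺ + H₂O⁺ | 3.0 Å |
| seq_ii | H₂O⁺ | C₂H₄⁺ | H⁺ + C₂H₃⁺ | 3.0 Å |
| seq_iii | H⁺ | C₂H₅O⁺ | H₂O⁺ + C₂H₃⁺ | 2.5 Å |

The daughter separations are **effective charge-site distances**, not
bond lengths.  A bare point-charge split at the covalent H–O distance
(~1 Å) would release ~14 eV into the late proton and push every mechanism
into the upper Dalitz region, which contradicts both the measured KER scale
of these channels (the observed bands span roughly 0–5 and 5–13 eV) and the
qualitative mechanism signature (proton-first events high on the Dalitz
plot, heavy-fragment-first events low).  Point charges at covalent distances
systematically overestimate the energy release of small molecular ions; the
defaults above keep the step-2 release at a few eV, consistent with those
bands.  They are configuration values on `BreakupProcess`, not constants.

With these defaults the simulator reproduces the expected mechanism
signatures: mean y_d(seq_iii) ≈ 0.29 against ≈ 0.08 for seq_i/seq_ii, and
total KER is monotonically non-increasing in `t_ionize` (the longer the
intermediate flies before the second ionization, the less residual Coulomb
repulsion remains).

`t_ionize` is drawn from an exponential distribution (default mean 200 fs) —
a memoryless stand-in for the probe-arrival statistics.

## Kinematics conventions

* **Newton frame.**  The reference fragment (C₂H₃⁺) is rotated onto +x; the
  event plane is spanned by the reference and the "upper" fragment (H₂O⁺)
  momenta; the "lower" fragment's (H⁺) out-of-plane component is folded into
  its signed in-plane transverse component by projection.  Reflections are
  allowed so the upper/lower convention always holds.  For
  momentum-conserving events the lower fragment lands in the lower half
  automatically.
* **Dalitz coordinates.**  x_d = (E(C₂H₃⁺) − E(H₂O⁺))/(√3·KER),
  y_d = E(H⁺)/KER − 1/3.  Any momentum-conserving three-body event maps into
  y_d ∈ [−1/3, 2/3]; the map is scale invariant in the energies.
* **Gates.**  All interval gates are half-open [low, high); the proton
  momentum split assigns the boundary value (default 20 a.u.) to the high
  side.

## Spectrometer model

A single uniform extraction region (default 20 V/cm over 0.10 m, detector
radius 60 mm, t0 = 0): L = (p_z/m)t + (qE/2m)t², x = (p_x/m)t, y = (p_y/m)t.
The inverse is algebraically exact, so forward→inverse round trips are
limited only by floating point (~10⁻¹³ relative).  No drift tube, lenses,
magnetic field or multi-hit dead time: one region suffices to make the
TOF ↔ momentum chain testable end to end, and all dimensions are
configurable.

TOF windows for species assignment are the exact TOF roots at
p_z = ±p_max (default 150 a.u., covering every momentum that occurs at the
KER scales of these channels).  The shift is asymmetric: ions launched away
from the detector turn around and arrive later than p/(qE) would suggest.

## Channel identification

For each laser shot, every channel whose member species' TOF windows can be
matched one-to-one to distinct hits is evaluated by reconstructing the
momenta under those species hypotheses; the event is accepted only if
|Σp| is below the channel threshold (default 10 a.u.).  Neighbouring-mass
ions (OH⁺/H₂O⁺/H₃O⁺ at m = 17/18/19) have overlapping TOF windows, and a
pair mis-read with a neighbour's masses shifts |Σp| by only ΔmL/t ≈ 4–8 a.u.
— inside the gate.  A fixed-priority first-match rule would therefore
misassign essentially all SHM events to DHM; instead the gate-passing
channel with the **smallest |Σp|** wins (priority TRIPLE > DHM > SHM > NHM
breaks exact ties).  On noiseless synthetic streams true assignments have
|Σp| ~ 10⁻⁹ a.u. and always win; measured recovery is 100% with ≤0.8% of
false pairs slipping through.

## Trajectory criteria

* A hydrogen has migrated when d(H, O) drops below 1 Å **for the first
  time**; the original hydroxyl hydrogen (d(H,O) < 1 Å in frame 0) is
  excluded, so H₂O⁺ formation requires one detected migration and H₃O⁺ two.
* Migration origin (α vs β) is the carbon nearest the hydrogen in frame 0.
* The C–O bond is broken when d(O, C_α) exceeds 3 Å, C_α being the carbon
  nearest O in frame 0.
* The DHM "formation time" used for yield counting is the **second**
  crossing time — the event that completes the H₃O⁺ species.  (The first
  crossing would date the species before it exists.)
* Final channels come from the last frame's bond graph: bond iff
  distance < 1.2 × (sum of covalent radii; H 0.31, C 0.76, O 0.66 Å).
* Crossing detection is exact to one frame on scripted trajectories and
  invariant under global rotation/translation; same-frame ties break by
  atom index.

Yield curves are cumulative counts of the channel-defining times; theory
curves are scaled to match a normalized experimental yield at 1 ps
(nearest grid point), where the curves have saturated.  The saturating
exponential fit A·(1 − exp(−t/τ)) in `delay.fit_saturation_time` is a
convenience estimator of the migration clock, not part of the scaling
procedure.

## Synthetic data generator

The generator encodes the statistical structure the analysis is designed to
extract, with every quantity recorded as ground truth.

**Event streams.**  Per delay bin (default 50 fs bins, −1 to +1 ps, 3000
pulse pairs per bin) each pulse pair yields an event with probability 0.45;
5% of events are single-pulse background.  A destined channel is drawn with
delay-independent branching (NHM 0.30 / SHM 0.30 / DHM 0.35) and a migration
completion time T from an exponential clock (mean 300 fs for SHM and DHM,
250 fs for NHM, scaled by 10 eV/E_internal so that hotter ions migrate
faster).  If the probe arrives before T the event appears in the
no-migration precursor channel; otherwise in its migration channel,
exploding as two point charges from R(t) = R₀ + v·(|t| − T) with
R₀ = 4.1 Å and v = 0.015 Å/fs.  R₀ is calibrated so the KER at the moment
of migration (14.4/4.1 ≈ 3.5 eV) sits at the top of the channel's KER gate
and the whole post-migration feature stays inside the gate out to the
largest delays — this is what makes the gated, pulse-pair-normalized yield
directly proportional to P(T ≤ t).  Background events form a
delay-independent KER band (Gaussian, 5.0 ± 0.4 eV), outside every
migration gate, mimicking single-pulse contamination.  Two-body momenta use
the closed-form Coulomb solution |p| = √(2μ·KER) back-to-back along a random
direction — exact for two point charges from rest, and cross-checked against
the numerical propagator in the tests.  SHM and DHM share the same default
time constant; their branching is genuinely delay independent, which is the
construction under which the channel-ratio flatness test is meaningful.

**Trajectory ensembles.**  Scripted 9-atom geometry time series (default
2 fs frames to 3 ps; the analysis is exact to one frame, so finer sampling
would only cost memory).  For DHM trajectories the first migration time is
exponential (mean 150 fs) truncated below 400 fs and the second is
400 fs + exponential (mean 600 fs): the two draws are independent **and**
always ordered, so the detected (first, second) pair is exactly independent.
(Ordering two iid exponentials would induce corr(min, max) ≈ 0.45 — an
artifact of sorting, not of the physics being emulated.)  The C–O break time
is t₂ + 40 fs + N(0, 5 fs): the concerted second-migration/C–O-break
mechanism.  Migration origins are sampled 50/50 between C_α and C_β,
independently per migration.  Hydrogens travel radially toward O so that
d(H,O) crosses 1 Å exactly at the sampled time (the approach speed adapts so
the ramp never starts before frame 0); the O-bearing group separates along
the C→O axis so d(C_α,O) crosses 3 Å at the sampled break time.  Static
per-atom jitter (σ = 0.01 Å) and a random global rotation are applied.

**What the generator does not emulate:** detector resolution and dead time
(TOF/position jitter is off by default), random-coincidence backgrounds
beyond simple mispaired fragments, intensity-dependent ionization physics,
anharmonic vibrational motion, and any electronic-structure realism in the
trajectories — the scripted paths have the right event times and final
fragments, not the right forces.  Passing tests therefore demonstrate that
the **analysis** is correct and unbiased on data with known structure; they
say nothing about whether real ethanol ions behave this way.

## Parameter-recovery estimators

The migration time constant is fitted from the gated normalized yield with
A·(1 − exp(−t/τ)) by weighted least squares (Poisson weights).  Positive and
negative delay branches are analyzed independently; when the generator's
clock is branch independent (the default) the fit pools both branches
against |t|, doubling the statistics.  With the default stream (~14,000
gated DHM events over both branches) the estimator is unbiased with a ~4%
standard error.

Correlations (second vs first migration, C–O break vs second migration) are
ordinary least squares with Pearson r, reported with n; correlations with
fewer than 3 complete pairs or zero variance are reported absent.

## Known limitations

* Point charges at centers of mass ignore charge distribution and covalent
  binding, so absolute simulated KERs for concerted explosions run ~50%
  above measured values; orderings and delay trends are the meaningful
  outputs, and the effective separations are exposed as configuration.
* The single-region spectrometer cannot reproduce instrument-specific
  acceptance or resolution effects.
* The event-stream model collapses the precursor dynamics into one
  exponential clock per channel; real cation dynamics have richer structure
  (several internal energies, conformers, intermediate plateaus).
* Only the anti conformer of ethanol is used.
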