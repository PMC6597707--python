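# ethmig

Coulomb-explosion imaging analysis of single and double hydrogen migration
in ethanol ions.

When an ultrashort laser pulse ionizes ethanol (C₂H₅OH), hydrogen atoms can
migrate from the carbon backbone to the hydroxyl group before the molecule
falls apart.  In a pump-probe coincidence experiment the migration shows up
as distinct two-body fragmentation channels of the dication —

* **NHM** (no migration): OH⁺ + C₂H₅⁺
* **SHM** (single migration): H₂O⁺ + C₂H₄⁺
* **DHM** (double migration): H₃O⁺ + C₂H₃⁺

— plus the triple coincidence H⁺ + H₂O⁺ + C₂H₃⁺ from the trication, whose
energy sharing distinguishes which fragment was ejected first.  This package
implements the full analysis chain for that kind of measurement and for the
molecular-dynamics trajectories that accompany it, together with a synthetic
generator that emulates both data families with known ground truth.

## What's inside

| module | role |
| --- | --- |
| `ethmig.units` | constants, fragment-ion catalogue, ethanol geometry |
| `ethmig.explosion` | classical point-charge Coulomb explosions, concerted and sequential (velocity Verlet, propagated to the asymptote) |
| `ethmig.kinematics` | per-event observables: kinetic energies, KER, Newton-frame momenta, Dalitz coordinates `x_d = (E(C₂H₃⁺) − E(H₂O⁺))/(√3·KER)`, `y_d = E(H⁺)/KER − 1/3` |
| `ethmig.spectrometer` | idealized single-field ion spectrometer: momentum → (TOF, position) and its exact inverse |
| `ethmig.coincidence` | PIPICO maps, TOF-window species assignment, momentum-conservation gating |
| `ethmig.trajectory` | migration (d(H,O) < 1 Å, first crossing) and C–O break (d(C,O) > 3 Å) criteria, fragment identification, yield curves, migration-time correlations |
| `ethmig.delay` | KER-vs-delay maps, pulse-pair-normalized yields, saturation-time fits, channel-ratio flatness |
| `ethmig.synthetic` | ground-truth generator for event streams and scripted AIMD-like trajectory ensembles |
| `ethmig.cli` | `ethmig` command with simulate/analyze/report subcommands |

## Worked example

Simulate the three sequential breakup mechanisms of the triple channel and
locate them on the Dalitz plot, then recover the double-migration time
constant from a synthetic pump-probe stream:

```python
import numpy as np
from ethmig import explosion, kinematics, synthetic, coincidence, delay
from ethmig.units import get_species

for proc in ("seq_i", "seq_ii", "seq_iii"):
    events = explosion.simulate_process_ensemble(proc, 150, seed=1)
    y = []
    for ev in events:
        E = {s: kinematics.kinetic_energy(p, get_species(s).mass)
             for s, p in zip(ev.species, ev.momenta_au)}
        y.append(kinematics.dalitz_coordinates(
            E["C2H3+"], E["H2O+"], E["H+"]).y_d)
    print(f"{proc}: mean y_d = {np.mean(y):+.3f}  mean KER = "
          f"{np.mean([e.ker_eV for e in events]):.1f} eV")

config = synthetic.GeneratorConfig(pulse_pairs_per_bin=1000)
hits, truth = synthetic.generate_event_stream(config, seed=1)
events, stats = coincidence.assign_channels(hits)
scan = delay.yield_vs_delay(
    events["DHM"], coincidence.CHANNEL_BY_NAME["DHM"],
    pulse_pairs=config.pulse_pairs_per_bin,
    delay_edges_fs=config.delay_edges_fs)
fit = delay.fit_saturation_time(scan, "both")
print(f"DHM yield saturation: tau = {fit['tau_fs']:.0f} +- "
      f"{fit['tau_err_fs']:.0f} fs "
      f"(generator: {config.effective_tau('DHM'):.0f} fs)")
```

Output:

```
seq_i: mean y_d = +0.078  mean KER = 15.4 eV
seq_ii: mean y_d = +0.083  mean KER = 14.3 eV
seq_iii: mean y_d = +0.287  mean KER = 15.8 eV
DHM yield saturation: tau = 324 +- 26 fs (generator: 300 fs)
```

Reading it: `seq_iii` ejects the proton first, so the proton carries most of
the released energy and those events sit high on the Dalitz plot
(mean y_d ≈ 0.29, the upper part of the allowed region, y_d ∈ [−1/3, 2/3]);
when a heavy fragment leaves first (`seq_i`, `seq_ii`) the late proton shares
far less and the events sit low.  The second block generates a full synthetic
coincidence stream, reconstructs fragment momenta from detector hits, gates
channels on momentum conservation and KER, and fits the normalized DHM yield
with A·(1 − exp(−t/τ)): the fitted τ agrees with the generator's migration
clock within its statistical uncertainty.

The same steps are available from the shell:

```
ethmig simulate-events --seed 1 --outdir out
ethmig analyze-events --hits out/hits.csv --outdir out
ethmig simulate-dalitz --seed 1 --n-per-process 500 --outdir out
ethmig simulate-trajectories --seed 1 --outdir out --write-xyz
ethmig analyze-trajectories --xyz-dir out/xyz --dt-fs 2.0 --outdir out
```

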