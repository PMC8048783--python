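# p450kit

Analytics for cytochrome P450 compound I reactivity, steroid binding
and catalysis. The package bundles the bespoke computations used to
study the regioselectivity of a steroid-hydroxylating P450
monooxygenase (such as CYP154C5 and its active-site mutants):

- **NAC scoring** — frame-by-frame classification of near-attack
  conformations of abstractable substrate hydrogens relative to the
  compound I ferryl oxygen over MD-style trajectories, per-site NAC
  percentages, shortest-distance traces over equivalent hydrogens, and
  nearest-water traces with H-bond flags (water intrusion drives
  uncoupling).
- **Tight-binding titrations** — type-I spin-shift difference signals
  ΔA = A(386) − A(420) fitted with the quadratic tight-binding
  (Morrison) equation to obtain K_D at enzyme-comparable concentrations,
  with principled `no_shift` / `upper_bound_only` flags and high-spin
  fraction estimation by spectral unmixing.
- **Kinetics** — turnover numbers from the steepest substrate-consumption
  window, coupling efficiency (substrate converted per NADH consumed),
  and Beer–Lambert helpers for NADH, cytochrome c and CO-difference
  P450 quantification.
- **Structure comparison** — Cα mapping, Kabsch superposition, Cα RMSD
  and cross-complex ligand-atom correspondences for P450–steroid
  crystal structures.
- **Synthetic data** — seeded generators for every input above with
  recorded ground truth, so the whole pipeline is testable without any
  external data.

The core statistic: a frame is a near-attack conformation (NAC) for a
hydroxylation site when any of its equivalent hydrogens satisfies
d(H···O) < d_vdW(H,O) and |θ(C–H···O) − θ_ref| ≤ 20°; the per-site NAC
percentage over a trajectory predicts which carbon the ferryl oxygen
can attack. K_D comes from
ΔA(L) = ΔA_max·[(E+L+K_D) − √((E+L+K_D)² − 4EL)]/(2E).
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from p450kit.synthgen import (ReactiveTrajectorySpec, SiteSpec, TitrationSpec,
                              gen_reactive_trajectory, gen_titration)
from p450kit.reactivity import nac_percentages
from p450kit.binding import fit_tight_binding

gen = gen_reactive_trajectory(ReactiveTrajectorySpec(
    n_frames=5000,
    sites=(SiteSpec("16a", 1, 0.22), SiteSpec("21", 3, 0.07)),
    seed=11,
    water_schedule=((1000, 1100, 1.9),),
))
result = nac_percentages(gen.trajectory, gen.criterion)
print(result.to_frame().to_string(index=False))

series, truth = gen_titration(TitrationSpec(kd_nM=209.0, delta_A_max=0.10, seed=11))
fit = fit_tight_binding(series)
print(fit.summary(), "| status:", fit.status)
```

prints

```
site  nac_frames  total_frames  nac_percent
 16a        1138          5000        22.76
  21         371          5000         7.42
K_D = 213 +/- 9.3 nM | status: ok
```

The trajectory generator planted NAC geometry in 22 % of frames for the
one-hydrogen 16α site and 7 % for the three-hydrogen C21 methyl site
(plus a scheduled water approach to 1.9 Å in frames 1000–1100); the
classifier recovers those frame counts exactly, since the planted
labels are ground truth. The titration was simulated at E = 3 μM with
1 % noise from a true K_D of 209 nM; the tight-binding fit recovers it
within its standard error.

## Command line

Each stage is also a config-driven subcommand producing CSV artifacts
and a run-metadata file; identical config + seed give byte-identical
outputs:

```bash
p450kit synth      --config run.yaml --out-dir out/   # synthetic trajectory + truth
p450kit reactivity --config run.yaml --out-dir out/   # NAC summary, distance/water traces
p450kit binding    --config run.yaml --out-dir out/   # tight-binding fit report
p450kit kinetics   --config run.yaml --out-dir out/   # TON / coupling report
p450kit compare    --config run.yaml --out-dir out/   # Calpha RMSD table
p450kit report     out/*.csv --out-dir out/           # merged markdown summary
```

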