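# Methods

This note documents the models and procedures implemented in `p450kit`,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results.

## Near-attack-conformation (NAC) scoring

The first chemical step of a P450 hydroxylation is abstraction of a
substrate hydrogen by the ferryl oxygen of the compound I intermediate
(Fe(IV)=O, porphyrin cation radical). A trajectory frame is counted as a
near-attack conformation for a candidate hydroxylation site when **any**
of the site's chemically equivalent hydrogens simultaneously satisfies

- a distance test: d(H···O) < `d_max`, and
- an angle test: |θ(C–H···O) − `theta_ref`| ≤ `theta_tol`,

where the angle vertex is the hydrogen. The per-site NAC percentage is
100 × (NAC frames) / (total frames).

Defaults and rationale:

| parameter   | default | unit | rationale |
|-------------|---------|------|-----------|
| `d_max`     | 2.72    | Å    | Bondi van-der-Waals contact distance r(O) + r(H) = 1.52 + 1.20 |
| `theta_ref` | 180     | deg  | near-linear C–H···O geometry of hydrogen abstraction; the appropriate value depends on the quantum-chemical transition-state model, so it is a first-class argument |
| `theta_tol` | 20      | deg  | conventional NAC angular tolerance |

Choices worth stating explicitly:

- Equivalent hydrogens (e.g. the three C21 methyl hydrogens of a
  pregnane side chain) combine by *any-satisfies* for classification and
  by *minimum distance* for traces; the reported (d, θ) of a frame
  belong to the hydrogen closest to the acceptor, with ties broken by
  lowest roster index for determinism.
- One angle is scored (C–H···O). Additional angle constraints (e.g.
  Fe–O–H) are deliberately out of scope; the criterion object is the
  extension point.
- Geometry is evaluated on every stored frame. Trajectories sampled at
  different rates are compared on whatever frames they contain.
- Secondary oxidation sites (12β, 17) need no special casing: they are
  ordinary `SiteDefinition`s.

## Water intrusion and hydrogen bonding

Water access to the ferryl oxygen promotes uncoupling (the oxidase
shunt: the activated oxygen dissipates to water instead of oxidising
substrate). The nearest-water trace reports, per frame, the minimum
O(water)···O(ferryl) distance and the arg-min water. The H-bond flag
requires d ≤ 3.5 Å (O···O) and, when the water's hydrogens are present
in the roster, an O–H···O angle ≥ 120°; waters without explicit
hydrogens are judged on distance alone. Both thresholds are standard
geometric H-bond criteria, configurable, and echoed in output metadata
because no single convention is universal.

## Superposition, RMSD, RMSF

Rigid superposition minimises RMSD over proper rotations and
translations via the SVD of the cross-covariance matrix, with a
determinant guard so a reflection is never returned. The test suite
cross-checks it against an independently implemented quaternion
eigenvalue method.

RMSF is computed about the trajectory-mean position of each atom (not
frame 1), after optionally superposing every frame onto frame 1 over a
fit set (typically protein atoms) so that rigid-body drift does not
inflate substrate mobility. For isotropic Gaussian jitter of per-axis
σ the expected RMSF is σ√3, which the tests use as a closed form.

Structure comparison pairs Cα atoms by (chain, residue number) —
appropriate for one protein crystallised repeatedly — rather than by
sequence alignment. Only blank/'A' alternate locations are kept.
Waters are excluded; the heme never enters the RMSD. Ligand positions
are compared *after* protein superposition, so statements like "C15 of
one steroid occupies the position of C16 of another" are distances in
the common frame.

## Tight-binding (Morrison) titration analysis

Substrate binding displaces the heme iron's sixth (water) ligand and
shifts the Soret band from ~420 nm (low spin) towards ~390 nm (high
spin). The titration signal is ΔA = A(386) − A(420) (probe pair
configurable; 390/420 available). Because K_D is comparable to the
enzyme concentration E, ΔA versus total ligand L follows the quadratic
tight-binding equation

ΔA(L) = ΔA_max · [(E + L + K_D) − √((E + L + K_D)² − 4·E·L)] / (2E),

exact in the stoichiometric limit K_D = 0 where it reduces to
ΔA_max·min(L, E)/E, and converging to the Langmuir hyperbola for
K_D ≫ E. Fitting is weighted least squares profiled over K_D (the
amplitude has a closed-form optimum at fixed K_D), both parameters
constrained non-negative, internally in μM with K_D reported in nM.

Status flags:

- `no_shift` — max |ΔA| below a noise floor (3× the replicate SD at
  L = 0 when replicates exist, else 0.005 AU).
- `upper_bound_only` — the 95 % profile-likelihood interval
  (Δχ² ≤ 3.84) extends to K_D = 0. When K_D ≪ E the titration only
  bounds K_D from above, and the fit reports the 95 % upper limit in the
  "< X nM" convention rather than an unidentifiable point estimate.

Identifiability judgement needs a noise scale even for noiseless input;
the residual variance is floored at 0.5 % of the fitted amplitude, a
realistic spectrophotometer precision. Replicate measurements at the
same ligand concentration are averaged before fitting and their spread
feeds the weights.

High-spin content of a partially shifted sample is estimated by
non-negative least-squares unmixing of the sample onto low-spin and
high-spin basis spectra, returning a_HS/(a_LS + a_HS). Linear unmixing
is this package's choice of estimator; other conventions (peak-height
ratios) exist.

## Turnover number and coupling efficiency

TON (μmol substrate consumed · μmol P450⁻¹ · min⁻¹) is evaluated over
the contiguous sample window (spanning at least `window_min`, default
120 min, matching a "highest rate within the first 2–3 h" protocol)
whose least-squares slope of substrate vs time is steepest; sliding-
window regression is used instead of two-point differences for
robustness to sampling noise. A non-negative best slope clamps TON to 0
with a `no_consumption` flag. The window discretisation bounds the
recovery error by TON·(Δt/window).

Coupling efficiency is 100 × (substrate converted)/(NADH consumed);
values above 100 % are flagged as stoichiometrically implausible, not
rejected. Beer–Lambert helpers use ϵ(NADH, 340 nm) = 6.22 mM⁻¹cm⁻¹,
ϵ(reduced cytochrome c) = 19.1 mM⁻¹cm⁻¹ for the electron-transfer-chain
activity assay read at 550 nm (the ϵ subscript conventions for this
assay vary between sources; the value is configurable), and
ϵ = 91 mM⁻¹cm⁻¹ for the 450−490 nm CO-difference quantification of P450
(Omura–Sato convention, configurable).

## Synthetic-data generators

All generators are pure functions of their spec including the seed
(`numpy.random.default_rng`); repeat calls are bitwise identical. They
exist so every stage can be verified against *recorded* ground truth
rather than distributional expectations.

- **Reactive trajectories.** Each frame/site is NAC with the site's
  target probability; the drawn label is recorded. Planted hydrogens
  sample d ∈ [1.8 Å, d_max·(1−margin)] and θ within
  theta_ref ± theta_tol·(1−margin); all other hydrogens violate *both*
  criteria by at least the margin (default 10 %), so no atom lies inside
  the threshold band and classification is margin-robust to
  floating-point noise. Default site fractions used in examples (22 %
  and 7 % for a one-hydrogen and a three-hydrogen site) are realistic
  magnitudes for a well-packed P450–steroid complex. Waters are parked
  beyond 7 Å — the behaviour of a tight, water-excluding active site —
  except during scheduled approach windows, where one O–H bond points at
  the acceptor so that sub-3.5 Å approaches register as H-bonds.
- **Titrations.** Model curve times (1 + ε), ε ~ N(0, σ_rel), on a
  12-point 0–150 μM grid at E = 3 μM in duplicate — a standard type-I
  titration design; 1 % relative noise reflects duplicate
  spectrophotometry.
- **Time courses.** Substrate is flat outside the planted window and
  declines at TON·[P450] inside it; the NADH trace consumes
  100/coupling μM NADH per μM substrate. TON, coupling and the NADH
  budget are jointly overdetermined, so when a finite `nadh0` is given
  the course is truncated where NADH runs out (the endpoint-extraction
  design of a coupling assay); otherwise the initial NADH is set to what
  the course consumes.
- **Structure pairs.** Cα perturbations are rescaled iteratively until
  the *minimised* RMSD matches the target within 0.1 %, then a random
  rigid motion is applied; planted ligand offsets go through the inverse
  of the actual optimal superposition so the post-alignment distance is
  exact.

What the generators do **not** emulate: physical dynamics (no force
field, no correlated motion, no Boltzmann ensemble), realistic spectral
baselines or scattering drift, substrate depletion curvature within the
steep phase, or crystallographic error models. Passing tests therefore
demonstrate the correctness of the *computations* on data with known
truth — not that any particular enzyme shows a given NAC percentage or
K_D; those are empirical questions for real trajectories and spectra.

## Problem sizes and numerical choices

Recovery experiments in the test and acceptance suites use 10 000-frame
trajectories, 100-seed titration ensembles, 50-seed time-course
ensembles, 20 000-frame RMSF checks and 100-residue structure pairs —
sizes at which the estimators' statistical error is well below the
asserted tolerances. Distance ties are broken by lowest roster index;
arccos arguments are clipped to [−1, 1]; the quadratic discriminant is
clipped at 0; degenerate geometry (zero-length angle arms, < 3
superposition points, linearly dependent unmixing bases) raises typed
errors rather than returning NaN.

## Known limitations

- PDB and the package's own frame-table dialect only; no binary
  trajectory formats (DCD/XTC/TRR) and no mmCIF.
- Cα mapping assumes shared residue numbering; divergent constructs
  would need a sequence alignment, which is out of scope.
- One scored angle per site; multi-angle NAC definitions require
  extending the criterion.
- The tight-binding fit assumes a single binding site and no
  cooperativity (no Hill model).
- Comparison against deposited crystal structures requires the
  coordinates locally or a network fetch; no structural data ships with
  the package.
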