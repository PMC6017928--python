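# Methods

This note records the models implemented, the defaults and why, the design
choices made where the procedure was genuinely open, and what the synthetic
data do and do not establish.

## Reduction potentials (`redox_thermo`)

**Model.** Free energies of the neutral nitroaromatic and its radical anion
(hartree, as produced by a vibrational analysis at the optimized geometry)
enter an isodesmic one-electron exchange against a reference couple,
nitrobenzene by default:

    dG_rxn = G(Ar, anion) + G(ref, neutral) − G(Ar, neutral) − G(ref, anion)

Because the electron count is identical on both sides, systematic errors of
the level of theory largely cancel. The Nernst relation E = −dG/nF converts
to a potential; working in eV per electron makes F cancel, so the only
constant used is 1 hartree = 27.2114 eV. The scale is anchored to
E°′ = −0.486 V vs NHE for nitrobenzene at pH 7.

**Calibration.** Gas-phase computed values overestimate the spread of
aqueous potentials (no dielectric stabilization of the anion), so a linear
calibration against experimental values is fitted. The regression is
ordinary least squares of E_comp on E_exp, reported in the parameterization
E_comp = slope·(E_exp + offset) with offset = intercept/slope; this form is
unique and its inverse E_cal = E_comp/slope − offset is the map applied to
new compounds. Whether the historical convention regresses computed on
experimental or vice versa is ambiguous; computed-on-experimental is chosen
because the published parameterization is written that way, and the
mean absolute deviation after calibration (`mad_after`) is reported so the
choice is auditable. For noise-free collinear input `mad_after` is zero to
solver tolerance, and it equals mean(|OLS residual|)/|slope| exactly.

**Conformers.** If several free-energy records share a (compound, state)
pair, the minimum-G record is used — the retention rule of a Monte-Carlo
conformer search that keeps only the lowest-energy conformation.

**π-system size.** The compound table carries a user-supplied count of
atoms bearing conjugated p-orbitals. The documented helper convention is:
aromatic ring atoms plus directly conjugated substituent atoms (nitro N and
both O, carbonyl C and O, nitrile C and N); nitrobenzene counts 9. Any
consistent convention works — the field is descriptive, not computed.

## Kinetics (`kinetics`)

**Initial velocities.** The early-trace window defaults to the first 10 %
of points (minimum 4). A curvature guard shrinks the window while the
quadratic term of a 2nd-order fit contributes more than 5 % of the linear
change across it — conventional initial-rate practice; the window fraction
and tolerance are parameters. The velocity is
(|slope| − |baseline slope|)/(ε·ℓ), floored at zero; the baseline subtracts
uncoupled NAD(P)H oxidation recorded before substrate addition.

**Michaelis–Menten.** v/[E]₀ vs [S] is fitted to the hyperbola by
unweighted nonlinear least squares (`scipy.optimize.curve_fit`) with
positivity bounds, initialized from a Hanes–Woolf linearization (S/v vs S),
which is robust for saturating designs. An optional 1/v weighting flag
provides relative-error weighting. Standard errors are asymptotic; the
error of k_cat/K_M propagates the parameter covariance. The fit is
invariant to input order, to unit-consistent rescaling of [S], and scales
k_cat linearly with a common velocity factor (all tested).

**Hammett.** Base-10 logarithms throughout (the standard of physical
organic chemistry). The normalized relation log₁₀(Yᵢ/Y₀) = ρσ has no
intercept, so normalized mode fits through the origin and reports the
uncentered R²; a free-intercept mode regresses log₁₀(Yᵢ) on σ for series
reported without normalization. Exactly one parent (σ = 0) is required in
normalized mode. A small dictionary of literature para σ constants
(`SIGMA_PARA`, Hansch/Leo/Taft values) ships for convenience; analyses take
arbitrary user-supplied σ.

## Titration (`titration`)

The Nernst slope constant is fixed at 0.0592 V (25 °C). The oxidized dye
concentration comes from A521 alone (reduced phenosafranine is colorless
there); the enzyme's oxidized fraction comes from A454 after subtracting
the oxidized dye's ε₄₅₄ contribution, normalized between explicit
fully-oxidized and fully-reduced enzyme endpoint absorbances. Endpoint
normalization is used instead of an absolute enzyme extinction coefficient
because the endpoints are the only quantities the procedure defines; they
must be supplied (asymptotes or recorded extremes — the caller decides).
Points where either couple is outside 2–98 % oxidized (configurable) are
excluded from the log-log fit to avoid logarithmic blow-up; the counts of
used and excluded points are reported. Equilibrium at every recorded point
is assumed (mediated slow reduction); no kinetic model of the reductant
system is attempted. E°_e = E°_d + intercept·0.0592/n_e.

## Products (`products`)

Stage deltas from the parent nitro compound are fixed composition changes:
nitroso −O (−16 Da nominal), hydroxylamine −O+2H (−14), amine −2O+2H (−30).
Exactly one nitro group is transformed per call; regioselectivity on
polynitro compounds is outside mass arithmetic. Ion m/z are reported as
nominal mass ±1 for protonated/deprotonated species — for these compounds
the monoisotopic arithmetic rounds to the same integers (asserted in
tests against pyteomics as an independent mass oracle). The detection
policy encodes the screen's sensitivity: yields above 1 % are detected,
non-detection bounds the yield below 0.5 %, and the band between is
indeterminate.

## Structure (`structure`)

**SASA.** Sphere-point sampling on each atom's probe-expanded radius
(probe 1.4 Å, 960 points by default) with a deterministic Fibonacci
lattice — no RNG, so results are bit-stable. Neighbor candidates come from
a k-d tree. The estimator matches the closed-form isolated-sphere and
two-sphere spherical-cap areas within sampling tolerance and an independent
Shrake–Rupley implementation (biotite) within 2 % on the same radii;
convergence with point count is tested at 60/240/960.

**Radii.** A documented per-element van der Waals table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20 Å, …); unknown elements fall back to 1.8 Å with a
warning. Hydrogens are excluded by default (the crystal structures of
interest lack them); a flag includes them. Published per-dimer buried areas
computed with other radii sets are therefore reproducible only to within a
few percent, which is why the buried-area check on a deposited dimer allows
radii-set slack beyond the reported ±300 Å² spread.

**Buried interface.** ASA of chain A alone, chain B alone, and the AB
complex; buried = (ASA(A)+ASA(B)−ASA(AB))/2 and buried fraction
100·buried/ASA(A). Chains are taken as deposited; biological-assembly
reconstruction from symmetry operators is out of scope — supply a two-chain
file. The report is symmetric under chain swap and the buried area falls
monotonically to zero as the chains are rigidly separated (tested).

**CPK volume.** Union-of-spheres volume by occupancy counting on a regular
grid (0.2 Å default spacing) over the bounding box; matches the sphere and
two-sphere lens closed forms within 1 %.

**Parsing.** gemmi reads PDB/mmCIF; first model only, waters and hetero
residues excluded by default, and for alternate locations the
highest-occupancy conformer is kept (selected explicitly, per atom-name
group).

## Synthetic data (`synth_data`)

Each generator is a pure function of (seed, parameters): fixed seed gives
bit-identical output, and each generator owns an independent RNG stream so
adding one never perturbs another's fixtures. Noise models follow the
measurements: additive Gaussian for potentials and absorbances,
multiplicative lognormal for strictly positive rates.

Defaults are the study conditions of the analyses they feed: calibration
pairs on the line slope 4.67 / offset 0.379 V over −0.6…−0.2 V; rate data
with k_cat = 10 s⁻¹, K_M = 100 µM over the 13 µM–0.5 mM saturation range;
Hammett series with ρ = 3.1 over a σ grid from methoxy to nitro; titrations
with an enzyme midpoint of −190 mV against the −252 mV two-electron dye at
18 µM, endpoint absorbances 0.50/0.05 AU, swept over a potential grid
bracketing both midpoints; toy dimers as mirrored Gaussian atom clusters at
a set centroid separation, writable as valid PDB with byte-stable output.

**What passing tests show — and don't.** The generators emulate the
statistical structure the analyses assume (Nernst equilibrium, hyperbolic
saturation, log-linear substituent dependence, homoscedastic or
multiplicative noise). Real traces add instrument drift, mediator
non-equilibrium, substrate inhibition, σ-scale ambiguity for strongly
interacting substituents, and crystallographic artifacts — none of which
are simulated. Parameter-recovery results therefore validate the
estimators, not the experimental designs.

## Problem sizes and numerical choices

Recovery suites use 20–50 seeded replicates at the stated noise levels
(σ = 0.02–0.03 V for potentials, 5–10 % for rates, 0.005 AU for
absorbances), sample sizes of 8–41 points per dataset, and toy structures
of 25–50 atoms; these sizes give stable means while keeping the full suite
fast on one CPU. Degenerate inputs (zero x-variance, all-identical [S],
missing parent, equal titration endpoints, fewer than 3 interior points,
zero-width potential grids, nonpositive radii/probes/spacings) raise
`ValueError` with a message naming the problem rather than returning NaN.

## Known limitations

- The calibration's regression direction (computed-on-experimental) is a
  convention; with scatter the two directions differ slightly.
- The titration analysis models two couples only; a one-electron
  semiquinone intermediate would bend the log-log line and is not modeled.
- Buried-area values depend on the radii set and sampling density at the
  few-percent level; cross-software agreement should not be expected to be
  exact.
- The mass arithmetic reduces exactly one nitro group per call and does not
  predict isotope envelopes or fragmentation.
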