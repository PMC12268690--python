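# Methods

`stepkin` re-implements, as a tested library, the model chain behind a
step-growth kinetics study of anhydrous theophylline (Form II, orthorhombic
Pna2₁) growing from n-octanol: solubility thermodynamics, step-velocity
kinetics and its anisotropy on the (200) face, kink-energy accounting from
the lattice bond chains, 2D-nucleation-limited morphology control, and
kinetic Monte Carlo (KMC) realizations of the proposed mechanisms,
including groove self-healing.  A synthetic-data module stands in for the
AFM and spectroscopy measurements so every stage is testable offline.

## Thermodynamics (`stepkin.thermo`)

The driving force for crystallization is Δμ/kBT = ln(C/Ce).  The
crystallization equilibrium constant is Kcryst = Ce⁻¹ on the molarity
scale with unit activity coefficients (reasonable for a neutral solute at
millimolar concentrations in an organic solvent), so ΔG°(T) = RT ln Ce and
van 't Hoff's law ∂lnCe/∂(1/T) = ΔH°/R yields (ΔH°, ΔS°) from ordinary
least squares of ln Ce on 1/T (inverse-variance weights optional when the
points carry uncertainties; the data give no weighting scheme, so
unweighted is the default).  All energies are molar (J/mol, gas constant
R); crystallization quantities keep their negative signs.  Temperatures
are kelvin, with an explicit-unit converter (`kelvin(x, "C")`) and no
autodetection.

The equilibrium kink density of a step is 2/[exp(ω/kBT)+2] with ω the kink
energy.  This is exactly the restricted solid-on-solid (RSOS) result:
height differences between neighboring edge sites take the three values
{−1, 0, +1} with Boltzmann weights e^{−ω|d|/kBT}, and a kink is any d ≠ 0.
The density therefore lies in (0, 2/3], and the zero-entropy alternating
configuration (two molecules, two vacancies, repeating) has exactly 0.5
kinks per site while entropic configurations cap near 0.3.

**2D-nucleation barrier.**  The barrier is often quoted as ΔG*₂D = πΩhγ²/Δμ,
which is dimensionally consistent only if γ is an energy per unit riser
*area*.  This package fixes γ as an energy per unit step *length* (J/m) —
the convention of the classical disk-nucleus derivation — and implements
ΔG*₂D = πΩγ²/(hΔμ), which is the identical quantity under
γ_area = γ_length/h.  The choice is prominent here and in the docstring
because the two conventions silently differ by h².

## Cell arithmetic (`stepkin.cell`)

Only the cell/formula subset of CIF is read (via gemmi); loops, symmetry
and reflections are ignored.  Volume uses the general triclinic formula;
density is Z·Fw/(N_A·V); atomic weights are pinned (IUPAC 2021, five
significant figures).  Two cells coexist in the source data: the 100 K
single-crystal cell (a = 24.2655 Å) and the room-temperature AFM repeat
|a| = 2.413 nm.  Step heights on (200) are room-temperature observables,
so the AFM value is the default for the full/half step-height classes
(2.413 / 1.2065 nm; the half-cell sub-steps are glide-related and grow at
the same velocity).

## Step tracking (`stepkin.tracking`)

Height maps are plain-text grids; profiles are sampled bilinearly
(scipy `map_coordinates`) at ≤ 1 px spacing.  Terraces are found by greedy
piecewise-constant segmentation (a new terrace opens when a sample departs
from the running mean by more than `tol`, earliest-position tie-break);
risers between terrace medians are classified full/half/unclassified
against the unit height within `tol`, which must stay below a quarter unit
so the classes cannot overlap.  Tracking follows the detection nearest the
previous position within a gate; a lost or ambiguous step is a hard error
naming the frame.  Velocity is the OLS slope of displacement vs time,
positive toward the reference point.  Step positions are not localized
sub-pixel (pixel quantization, not noise, limits noiseless recovery — about
1–2 % at 4 nm pixels) and drift correction is off by default; both are
assumptions the original measurement chain leaves unspecified.

The velocity-independence claim (same v across step-height classes and
inter-step distances, the signature of direct incorporation from solution)
is tested with a seeded permutation test (10⁴ permutations, between-group
sum of squares statistic) rather than a named parametric test: few AFM
estimates, no distributional assumptions.

## Kinetic laws (`stepkin.kinetics`)

All laws use σ' = C/Ce − 1 as the regressor, pinning v(Ce) = 0:
`linear_bcf` (v = βσ'), `power_law` (v = βσ'^m, m ≥ 1, multi-start
nonlinear least squares), and `quadratic_kink_limited` (m = 2).  The
analytic v(C) of the 1D row-nucleation models is not committed to; the
free-exponent law is an explicit surrogate.  Models are ranked by AICc
with ties toward the lower order; when velocity uncertainties are present
both the fits and the AICc use inverse-variance-weighted residuals, so the
comparison stays coherent under multiplicative noise.  The absorbance
screen fits Beer–Lambert against a monomer–dimer model (mass balance
M + 2KM² = C solved in closed form) and declares "monomeric" when the
linear model wins — the situation over 1–20 mM, where the spectra scale
linearly.

## Bond-chain kink accounting (`stepkin.bonds`)

The (200) plane is a rectangular lattice with π–π stacking along [010],
the N–H···N hydrogen-bond chain on the [011] diagonal, a pooled in-plane
van der Waals contact along [001], and out-of-plane vdW tracked only for
the enthalpy sum (default multiplicity 4 — two neighbors in each adjacent
plane — a modeling choice that only affects how calibration distributes
the remainder).  The four-kink creation cost is enumerated explicitly on a
half-plane occupancy (extract an edge molecule, reattach at an intact
distant segment; bonds to the underlying plane cancel), not hard-coded:
for a [001]-advancing step the net is two π–π bonds; for a [010]-advancing
step the strong bonds break once and restore once, leaving two in-plane
vdW contacts.  The lattice enthalpy is −½ Σ energy × multiplicity, the
half-sum-of-bonds constraint against the measured ΔH°.  No numeric bond
energies ship as defaults — none are individually quantified — so schemes
are user inputs or outputs of `calibrate_scheme`, which solves the
[010]-kink and enthalpy constraints and spreads the underdetermined
remainder uniformly over the out-of-plane slots.

## Kinetic Monte Carlo (`stepkin.kmc`)

Both engines are rejection-free (n-fold way): per-site rates, exponential
waiting times, linear-scan event selection (at ≤ 512 edge sites and ≤ 128²
surface sites a compiled linear scan beats tree bookkeeping and cannot
accumulate partial-sum drift), numba-compiled kernels, and numpy-MT19937
seeding recorded in every result.  Identical config + seed reproduces
results bit-for-bit.

**Rate laws.**  Every move satisfies detailed balance — the forward/backward
ratio equals the Boltzmann factor of the grand-potential change — and this
is audited exhaustively over the rate catalog before every run (failure is
fatal).  Two laws are offered: `glauber`, ν/(1+e^{βΔΦ}), whose rates are
bounded by the attempt frequency and which keeps the high-kink-energy
equilibrium measurements efficient (with the textbook splitting, a freshly
attached adatom detaches at rate ∝ e^{+2βω}, so at ω = 20 kJ/mol nearly
every event is a futile attach/detach pair); and `split`, attachment
∝ C/Ce with detachment ∝ e^{−ΔE/RT}, the conventional choice, used where
the event currency itself should reflect the attempt/failure structure
(kinetic-order curves and healing transients below).

**Step edge.**  The RSOS restriction (|Δh| ≤ 1) is chosen deliberately:
its equilibrium kink density is exactly 2/[e^{βω}+2], the closed form used
throughout, whereas unrestricted SOS gives 2/[e^{βω}+1].  Boundary
topology matters and is a config switch:

* `free` ends sample the exact three-state product measure over height
  differences, so the time-averaged kink density can be validated against
  the closed form at any edge length.  A periodic ring instead pins the
  winding number ΣΔh = 0, forcing kinks into bulk pairs and suppressing
  the density by orders of magnitude once the expected kink number per
  edge drops below one (at ω = 20 kJ/mol and 128 sites, ~30×).
* `periodic` models an isolated infinite step with no boundary kink
  sources — the right geometry for v(C) curves, because free ends act as
  permanent kinks and linearize growth at any ω.

Kink density is time-averaged after a burn-in (default 25 % of events)
with batch-means standard errors (16 batches); velocity is net attachments
per site per unit time.

**Kinetic-order regimes.**  On a kink-rich edge (low ω) the velocity is
carried by pre-existing kinks and v(C) is quasi-first-order.  On a
kink-poor ring the step grows by 1D nucleation of new rows: an adatom
(rate ∝ S per site) must be rescued by a neighbor (∝ S) before it detaches
(∝ e^{2βω}), after which the kink pair random-walks to row completion, so
v ∝ e^{−2βω}(S² − 1).  That superlinearity is only expressed once the
quadratic term competes with the linear one, i.e. at saturation ratios of
order 2 and above; within a narrow near-equilibrium window (C/Ce ≤ 1.5)
the curvature of (S²−1) is numerically indistinguishable from a straight
line at any realistic event budget.  The order-selection experiments
therefore scan S ∈ [1.5, 4] with the split law (ω = 2 kJ/mol for the
linear regime, 12 kJ/mol for the superlinear one; 20 kJ/mol is exercised
at equilibrium, where it is measurable, but its velocity at low S is
~e^{−2βω} ≈ 10⁻⁷ ν and cannot be resolved at desk scale).

**Surface lattice gas.**  One (200) monolayer with occupancy dynamics;
bonds along [010] (π chain), [001] (in-plane vdW) and the [011] diagonal
(H-bond chain); periodic boundaries.  The configured Δμ is measured from
solid–solution coexistence: by particle–hole symmetry the gas coexists at
bare chemical potential −(E₀₁₀+E₀₀₁+E₀₁₁), and the kernel offsets by that
amount, so at Δμ = 0 a flat interface neither grows nor dissolves and an
isolated molecule in the open region is penalized by the full bond sum.  A
step edge running along direction **u** makes kinks by paying the bonds
*along* **u**: edges along [001] are kink-rich (cheap E₀₀₁), edges along
[010] kink-poor (expensive E₀₁₀) — the same anisotropy the bond-chain
ledger derives.

**Groove healing.**  `etch_groove` clears a centered band spanning the
lattice (depth is restricted to 1: the engine is a monolayer; the original
observation is morphological/in-plane).  Healing runs regrow the etched
lattice at Δμ = RT ln(18/13.5) ≈ 0.71 kJ/mol (the 18 mM healing solution
over the 13.5 mM solubility).  Grooves elongated along [001] heal by
advance of kink-rich walls and refill essentially completely; grooves
along [010] heal by kink-poor walls, lag far behind at the matched event
budget, and leave connected never-refilled clusters — reported as
`void_count`, this package's quantitative stand-in for the qualitative
"voids and crevices".  The anisotropy is asserted as a paired-seed
ordering (same Δμ, events, and seed for both orientations), never as exact
void geometry.  Default experiment: 64×64 lattice, bonds
(E₀₁₀, E₀₀₁, E₀₁₁) = (10, 2, 4) kJ/mol — a synthetic hierarchy with the π
chain strongest, not measured values — width-8 grooves, 15 000 events,
split law.

## Morphology (`stepkin.morphology`)

Face growth rate: birth-and-spread,
R = A·h·(Δμ/kBT)^{5/6}·e^{−ΔG*₂D/3kBT}, with a mononuclear alternative
(R = A·h·e^{−ΔG*₂D/kBT}) behind a flag — the barrier argument alone does
not decide between them, so both are exposed.  The habit aspect is
R(010)/R(001); above a configurable threshold (default 5, purely a
reporting convention) the crystal is classed needle/ribbon (elongated
along [010]), else isometric sheet.  With γ(001) > γ(010) and equal
prefactors the aspect is monotone decreasing in C — the mechanism as a
property of the closed form.  `demo_faces()` is a clearly synthetic
parameterization (γ(001) = 6.5 pJ/m, γ(010) = 1.1 pJ/m, h = c and b
respectively, Ω = V/Z = 193.4 ų): the γ values are chosen, by closed-form
calibration, to put the ribbon→sheet crossover at ≈ 17 mM for
Ce = 13.5 mM, inside the experimentally bracketed 14.5–20 mM window.  No
measured γ exists for this system.

## Synthetic data (`stepkin.synth`)

Every generator is a pure function of (parameters, seed) — reruns are
bit-identical — and emits a ground-truth manifest for recovery tests.
Noise models: multiplicative lognormal for concentration-like quantities,
additive Gaussian for heights and velocities (the study reports only sd
error bars, so these are the simplest adequate choices).  Defaults mimic
the study scales: Ce from (ΔH°, ΔS°) = (−20.5 kJ/mol, −34 J/mol/K) at the
10–27 °C equilibration temperatures; v(C) grids over 14–20 mM above
13.5 mM; risers only in the {2.413, 1.2065} nm classes; UV series 1–20 mM.
What the generators do *not* emulate: AFM tip convolution, scanner drift
nonlinearity, image bow/flattening artifacts, spectral band shapes, or any
instrument physics — so green recovery tests certify the analysis chain on
idealized data, not robustness to real instrument artifacts.

## Statistical conventions in the tests

Recovery tests use nominal-coverage checks (95 % t-intervals covered in at
least 88 % of 200 seeded replicates, binomially slack), model
identification ≥ 90 % correct at 5 % noise and n = 8, KMC observables
within 3 batch-means SEs of closed forms, and paired-seed orderings
(≥ 9/10) for the healing anisotropy.  Problem sizes — 128-site edges,
(0.15–3)·10⁶ events per KMC point, 64×64 surfaces, 200-replicate fit
studies — were chosen so the full suite completes on a single CPU in a few
minutes while keeping each criterion's statistical power well above its
threshold.

## Known limitations

* Bond energies are never predicted; all numeric schemes are inputs or
  calibration outputs (quantum-chemical evaluation is explicitly out of
  scope).
* The KMC step engine supplies solute uniformly (direct incorporation);
  the surface-diffusion supply mode exists only as the analytic contrast
  in the discussion, not as a second engine.
* The surface model is one monolayer; multilayer groove depth, thermal
  etch physics and 2D nucleation at crystal edges are not simulated.
* Non-ideal activity, hydrate equilibria and solubility prediction from
  structure are out of scope.
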