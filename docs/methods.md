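# Methods

## Model

The package computes the bulk refractive-index change produced by a 1:1
binding event from the linearized Clausius–Mossotti (CM) relation.

**Exact relation.** (n² − 1)/(n² + 2) = (4π/3) Σ N·α, with N in molecules/Å³
and α in Å³. `cm_refractive_index` solves this exactly
(n = √((1 + 2S)/(1 − S)) for S < 1) and raises for unphysical sums S ≥ 1.

**Linearization.** The derivative of the exact solution with respect to the
polarizability-density sum at the operating point n₀ is

    k = (2π/9) (n₀² + 2)² / n₀

(`cm_k`; 2π at n₀ = 1, 7.4709 at n₀ = 1.333). Binding changes the sum by
N·Δα where N is the product number density, so Δn = k·N·Δα. The
linearization is excellent in the regime of interest: at Δn ~ 10⁻⁴ the
second-order correction is below one part in 10³ (the unit tests verify
agreement with a finite difference of the exact relation to 10⁻⁶ relative).

**Γ parameterization.** The product's polarizability cannot be computed from
the unbound partners, so it enters as the ratio
Γ = α_P,total / (α_R,total + α_L,total), giving

    Δn = k · C · N_A · 10⁻²⁷ · (α_R,total + α_L,total) · (Γ − 1),

linear in C and in (Γ − 1); the inversion Γ(Δn) is closed-form
(`gamma_from_measured_dn`) and exact to round-off. Only the *product*
concentration enters — unbound material contributes identically before and
after binding and cancels. A helper (`product_concentration`) solves the
standard 1:1 equilibrium quadratic for callers who only know totals and a
K_d; that conversion is a convenience outside the core model.

Bracketing Γ from data: solvent-dependent spreads of a protein's refractive
increment bound plausible Γ values via `gamma_from_dndc_ratio`
(ratio of two dn/dc values); literature spreads for single proteins span
roughly 0.56–1.77, and a 10–20% excess of measured dn/dc over
composition-based predictions corresponds to Γ ≈ 1.1–1.2 from solvation
alone.

## Polarizability bookkeeping

Dry solute polarizabilities are strictly additive:

* **Proteins** — sum of per-residue contributions (in-chain residues, i.e.
  the water of each peptide bond is already condensed out; one water is added
  back in the molar mass only). Additivity makes the value
  permutation-invariant and linear under concatenation, which the property
  tests exploit.
* **Small molecules** — sum of per-atom contributions over the elemental
  composition (Hill-notation formulas are parsed in-package). No bond-order
  or conjugation corrections: aromatic systems are underestimated by
  ~10–20%, a bias far smaller than the solvation-shell term in every
  supported scenario.
* **Monatomic ions** — tabulated free-ion literature values.

**Atomic constants.** The shipped atom table converts classic sodium-D
atomic refraction increments to polarizabilities (α = 3R/(4πN_A)): H 0.436,
C 0.959, N 0.921, O 0.650, S 3.050 Å³. This compilation was chosen because
it reproduces the shell-water benchmark (H₂O → 1.52 Å³ against the 1.5 Å³
reference) — average-atom compilations overshoot water by ~40%.

**Residue constants.** Residue contributions are *derived from the same
atomic table* applied to each residue's elemental formula and frozen into
`data/residues.tsv` (mean 11.1 Å³/residue). The originally intended
literature per-residue table was not reproducible offline with confidence;
because shell polarizability exceeds dry protein polarizability ~20-fold at
40 Å shells, swapping residue tables of plausible magnitude moves the
worked-example predictions by under 5%.

Nonstandard residue codes (X, B, Z, U…) are rejected by default; an explicit
`on_nonstandard="mean"` opt-in substitutes the mean residue value, since
silent substitution would bias α_R.

## Solvation shells

The solute is a sphere. Its anhydrous volume is m·psv/N_A with partial
specific volume psv defaulting to 0.73 mL/g (standard for proteins, and a
good small-molecule approximation: benzenesulfonamide's crystal density
~1.37 g/mL implies psv ≈ 0.73); monatomic ions use their tabulated ionic
radius instead. The shell is the spherical layer of thickness t outside the
effective radius r:

    V_shell = (4π/3)((r + t)³ − r³),
    N_water = V_shell / 25 Å³,   α_shell = N_water × 1.5 Å³.

N_water stays real-valued — the shell is a continuum estimate and rounding
would break layer additivity (V(r, t₁+t₂) = V(r, t₁) + V(r+t₁, t₂), a tested
invariant). The per-shell-water polarizability (1.5 Å³) and water volume
(25 Å³) give every shell a polarizability density of 0.06, independent of
geometry.

**Shell-size convention.** "Shell size" is read as *thickness outward from
the solute surface*; this reading reproduces the desk benchmark (50 kDa,
psv 0.73 → 60.6 nm³ anhydrous, radius 24.4 Å; +4 nm → 1056.5 nm³ of shell,
~17× the protein volume). The source literature for that benchmark quotes a
"diameter" of 2.4 nm alongside a 58 nm³ volume — mutually inconsistent
(58 nm³ is a sphere of *radius* 2.4 nm); we follow the volume. A
`convention="total_radius"` mode (shell size = outer radius) exists for
sensitivity analysis.

**Ligand shells** are included in the unbound total by default, each built on
the ligand's own geometry; `include_ligand_shell=False` removes it. The
default matters: in the sulfonamide/carbonic-anhydrase example, inverting
the measured Δn = −1.4 × 10⁻⁵ RIU at 50 nM has *no* physical solution
(Γ < 0) without the ligand shell, and gives Γ ≈ 0.19 with it.

**Γ scope.** Γ multiplies the *solvated* totals by default
(`gamma_scope="solvated"`), treating shell reorganisation as part of the
binding-induced polarizability change; `gamma_scope="dry"` restricts Γ to
dry polarizabilities (shells assumed to cancel) for sensitivity analysis.

## Synthetic fixtures — what a green test does and does not establish

The two bundled FASTA fixtures are **synthetic stand-ins**, flagged as such
in filename and header: random sequences with vertebrate-average amino-acid
frequencies constrained to the lengths and molar masses of the proteins they
emulate (recoverin-like: 201 aa, 23 200.7 g/mol; carbonic-anhydrase-II-like:
260 aa, 29 252.8 g/mol). Downstream physics sees a sequence only through its
molar mass (→ radius → shell volume) and its dry α (→ a ~4% sliver of the
solvated total at 40 Å), so the worked-example tests validate the *model
arithmetic at realistic scale*, not any property of the real proteins'
specific sequences. Real sequences can be supplied as FASTA paths anywhere a
fixture name is accepted.

Equally, the generator does not emulate: nonspherical shapes, sequence-
specific hydration, charge-state effects beyond tabulated ion values, or
frequency dependence of α. A green worked-example test establishes that the
CM pipeline reproduces the published signal *magnitudes within a factor of
two* under the stated geometric conventions — the remaining gap (~1.4×) is
attributable to the source's unstated effective α totals, and is visible in
the inverse problem as Γ ≈ 0.19 recovered where ≈ 0.42 was reported (both
correspond to the same measured Δn; the polarizability deficits 1 − Γ agree
within a factor of 1.4).

## Numerical choices

* All internal lengths in Å, volumes in Å³, concentrations in mol/L;
  the only unit conversion is N_A·10⁻²⁷ (mol/L → molecules/Å³).
* N_A = 6.02214076 × 10²³ (exact SI).
* No iterative solvers anywhere: the forward map is bilinear and the
  inversion closed-form; the exact CM solve is algebraic.
* Degenerate inputs: zero shell thickness gives a zero shell; zero
  concentration predicts Δn = 0 but refuses inversion
  (`DegenerateInversionError`); CM sums ≥ 1 raise rather than return a
  complex index.
* CSV output uses 6-significant-digit scientific notation; JSON retains
  full precision. Identical inputs produce byte-identical outputs.

## Known limitations

* Additive polarizabilities ignore conformer, anisotropy and bond effects;
  the product's α is never predicted, only parameterized via Γ.
* The shell is a single averaged entity — no radial dielectric profile and
  no distinction between first-shell and outer-shell water.
* Spherical geometry throughout; elongated or disc-like solutes will have
  their shell volumes misestimated at small thicknesses.
* The instrument map is the scalar ρ = β·χ·C; no optics are modelled.
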