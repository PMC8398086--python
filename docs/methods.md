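# Methods

## The inference chain

The package treats a fluorescence titration as the primary observable: a
protein solution at fixed concentration, temperature and pH is titrated
with a quencher/ligand at concentrations [Q]₀ = 0 < [Q]₁ < … (default
{0, 2, 4, 6, 8, 10}×10⁻⁶ mol/L), and the emission spectrum is recorded at
each point over 300–450 nm. The peak intensity of the [Q] = 0 spectrum is
F₀; each subsequent peak is F.

**Peak extraction.** Spectra are smoothed with a centered moving average of
half-width 2 nm (default; the raw data carry no stated noise treatment, so
a minimal symmetric smoother was chosen), then the maximum is refined by a
three-point parabola through the smoothed neighbours. Exact ties resolve
to the lowest wavelength; a maximum on the grid edge is returned unrefined
and flagged. Peak *amplitude*, not integrated area, feeds the fits — this
matches single-wavelength reading practice; an area mode is deliberately
out of scope. Intensities are never renormalized: every downstream model
uses the ratio F₀/F, so units cancel. No inner-filter correction is
applied (none is standard for this assay at these absorbances); blank
(buffer) spectra, when present, are subtracted point-wise first.

**Stern–Volmer stage.** F₀/F is regressed on [Q] by ordinary least squares
with a *free* intercept. The textbook law forces the intercept to 1; the
free intercept is reported as a diagnostic that exposes normalization or
blank-handling faults, and a constrained mode
(`constrained_intercept=True`) replicates the literal one-parameter law.
K_sv is the slope, K_q = K_sv/τ₀ with τ₀ = 10⁻⁸ s (the standard biomolecule
fluorescence lifetime), and the mechanism is classified against the
diffusion-limited maximum 2.0×10¹⁰ L mol⁻¹ s⁻¹: above → static, below →
dynamic, within one standard error of the boundary → indeterminate (the
boundary band is this package's choice; real data rarely sit on it).

**Double-log stage.** log₁₀((F₀−F)/F) is regressed on log₁₀[Q] (base-10
logs, as conventional for this plot; the van't Hoff stage uses natural
logs). The slope is the apparent site number n, the intercept 10-exponent
is K_b, and the [Q] = 0 point is excluded (it defines F₀ and is singular
under the transform). Any F ≥ F₀ at nonzero [Q] is an error naming the
offending concentration.

**Thermodynamic stage.** ln K_b is regressed on 1/T: ΔH = −R·slope,
ΔS = R·intercept, R = 8.314 J mol⁻¹ K⁻¹. ΔH is carried in kJ/mol and ΔS in
J mol⁻¹ K⁻¹ (the units these quantities are conventionally printed in);
all internal arithmetic is done in J to avoid kJ/J mixing, and
ΔG(T) = ΔH − TΔS/1000 kJ/mol. Published tables in this literature
sometimes print ΔG values equal to −TΔS alone — a unit slip this explicit
harmonization is designed to prevent. The sign rules (ΔH<0, ΔS>0 →
electrostatic; >0,>0 → hydrophobic; <0,<0 → H-bond/van der Waals) use
strict inequalities; a zero maps to *unclassified* rather than guessing.
The default fit is unweighted (appropriate to 2–4 temperature points); a
weighted mode accepts per-point weights. Two points give the exact line
with undefined standard errors (NaN).

**Docking conversion.** K_d = exp(E_b/(R′T)) with
R′ = 1.987207×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K by default — the
convention docking engines use to print a dissociation constant next to a
score. The map is strictly increasing and multiplicative in E_b. Scores
near −7.5 kcal/mol give K_d ≈ 3×10⁻⁶ mol/L; some published pose tables
carry a 10⁻⁷ scale header with mantissas that actually match the 10⁻⁵
scale under this formula — the formula, not the header, is implemented.

## Synthetic data: what it emulates and what it does not

Each generator inverts the closed-form law its downstream fitter assumes:

- `generate_emission_titration` produces Gaussian emission peaks (default
  σ = 25 nm — chosen to look spectrum-like; irrelevant to the fits, which
  use peak amplitude) centered at 337 nm (pH 7.4) or 334 nm (pH 2.0), with
  amplitude F₀/(1 + K_sv[Q]) (Stern–Volmer mode) or F₀/(1 + K_b[Q]ⁿ)
  (double-log mode), plus optional additive Gaussian noise under an
  explicit seed. Peak position does not shift with concentration
  (amplitude-only quenching). Noiseless output is bit-reproducible and
  seed-independent.
- `generate_kb_series` evaluates K_b(T) = exp(−ΔH/RT + ΔS/R) exactly, so
  the van't Hoff round trip recovers (ΔH, ΔS) to ≤10⁻⁹ relative.
- `build_ideal_chain` places a poly-alanine backbone (N, H, CA, C, O) by
  internal-to-Cartesian construction with standard geometry (N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, N–H 1.01 Å; angles 111.2°/
  116.2°/121.7°) at any uniform (φ, ψ, ω); `make_antiparallel_sheet`
  pairs two extended strands (φ = −139°, ψ = 135°) at 4.85 Å spacing with
  a 1.15 Å registry shift calibrated once against the H-bond energy
  criterion; `make_hbond_fixture` realizes an exact donor–acceptor
  distance and D–H···A angle; `apply_rigid_motion` adds Euler rotations,
  translations and seeded jitter.

Passing tests on these inputs demonstrate that the estimators invert their
models exactly and that the structural metrics satisfy their geometric
invariants. They do **not** demonstrate robustness to real-spectrum
pathologies (baseline drift, inner-filter effects, scattering, spectral
shifts on binding) or reproduce any published trajectory-scale observable
(RMSD drift magnitudes, H-bond counts from engine-internal criteria,
secondary-structure changes of an undeposited model) — those depend on
data that was never deposited.

Two internal consistencies of published parameter tables are worth noting.
First, a (K_sv) value and a (K_b, n) pair with n far from 1 cannot describe
the same titration: at micromolar [Q], K_b[Q]ⁿ with n ≈ 1.6 predicts
negligible quenching while K_sv[Q] predicts ~30%. Synthetic series
therefore use one law at a time. Second, the double-log intercept sits
~5.5 decades outside the sampled log₁₀[Q] range, so K_b is severely
noise-amplified: at 1% spectral noise the median K_b error is ~80% even
though K_sv's is ~1% and n's is ~9%. The noise-robustness suite asserts
the 5% median for K_sv and a frozen seeded band for the double-log fit;
small printed uncertainties on K_b in this assay imply heavy replicate
averaging or fitting of pre-averaged data.

## Structural metrics

**RMSD.** Atoms are matched by (chain, residue index, name) over {N, CA,
C}; superposition is the closed-form Kabsch solution (covariance SVD with
a determinant guard against reflections). Trajectory series are computed
against frame 0. Coordinates are orthogonal Å; no periodic imaging.

**Hydrogen bonds.** Geometric criteria: d(D···A) ≤ 3.5 Å and, when the
donor hydrogen is present, ∠(D–H···A) ≥ 120°; donors are N/O with a
covalently attached H (≤1.25 Å, same residue), acceptors are O atoms plus
N atoms with lone-pair capacity by name table. Files without hydrogens
fall back to a distance-only heavy-atom mode, flagged by a null angle.
These thresholds are configuration-exposed; engine-internal energy
criteria used by MD packages are *not* reproduced, so absolute counts are
not comparable across tools.

**Secondary structure.** A simplified Kabsch–Sander scheme: backbone
H-bonds scored by the electrostatic dipole model
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bond iff
E < −0.5. Amide hydrogens are reconstructed geometrically (1.01 Å from N,
opposite the bisector of its covalent bonds) when absent. Helix = runs of
two consecutive i→i+4 bonds (marking residues i+1…i+4; 3₁₀/π are folded
into H), sheet = parallel/antiparallel bridge patterns, turn = i→i+3 bonds
outside helices, coil = remainder — the four classes a typical MD analysis
reports. Chains under 5 residues are all-coil with a warning. Fractions
close exactly to 100 on the coil share.

**Ramachandran.** Terminal residues (undefined φ or ψ) are skipped and
tallied. The four-level region map is an owned, versioned rectangle grid
(`data/rama_map.json`), deliberately coarse: it contains the canonical α
and β basins as core, graded expansions as additional/generous, and a
point-symmetric widened map for glycine. It is *not* a reproduction of any
validation server's contour set, so percentages are self-consistent under
this map but not comparable to published validation reports.

## Numerical and design choices

- All linear fits are OLS via `scipy.stats.linregress` (or closed form
  where constrained); no iterative optimization anywhere, so noiseless
  recovery is exact to rounding and every result is deterministic.
- PDB I/O is delegated to biotite (fixed-column, MODEL-delimited; first
  altloc kept; HETATM retained and flagged); titration files are
  long-format UTF-8 CSV with header
  `wavelength_nm,intensity,quencher_conc_M,temperature_K,pH` and a `-1`
  sentinel concentration for buffer-blank rows.
- Every random-number consumer takes an explicit seed; there is no hidden
  global state.
- The pipeline's structured JSON report is the source of truth (full
  precision, input SHA-256 hashes, version stamp); rendered tables are
  derived, rounded views.

## Known limitations

Single-wavelength peak reading only (no area mode); no modified
Stern–Volmer (Lehrer) or time-resolved analysis; no inner-filter or
photobleaching correction; no curved van't Hoff (ΔCp); H-bond and
secondary-structure criteria are geometric stand-ins for engine-internal
energy definitions; the Ramachandran map is coarse by design. Problem
sizes throughout (≤20-residue fixtures, 6-point titrations, ≤200-replicate
noise studies) are desk-scale choices that keep the full suite under a few
seconds while exercising every code path.
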