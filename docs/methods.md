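# Methods

## Scope and model

`polyrisk` covers the post-CSP half of a polymorph risk assessment: it takes
per-candidate energies (and, where present, crystal structures) as inputs and
produces a ranked free-energy landscape, powder-pattern-based identifications,
disorder corrections, and risk statistics. It performs no structure
generation, no force-field or quantum-mechanical energetics, and no phonon
calculations — those are upstream producers of its input tables.

## Crystal structures and density

Structures are modeled as a unit cell (a, b, c in Å; α, β, γ in degrees), a
space-group operator list, and asymmetric-unit sites with occupancies. CIF
syntax is handled by gemmi; both the modern `_space_group_symop_operation_xyz`
and the legacy `_symmetry_equiv_pos_as_xyz` loops are accepted, and
symbol-only files are resolved through gemmi's full Hermann–Mauguin table
(P1, P2₁, C2, P2₁2₁2₁ and the rest). Cell volume uses the triclinic
expression V = abc·√(1−cos²α−cos²β−cos²γ+2cosαcosβcosγ); density is
ρ = Z·M/(N_A·V) with N_A = 6.02214076×10²³ mol⁻¹ and atomic masses from an
embedded IUPAC-2021 table (common organic elements; gemmi supplies the rest).
When a molecular formula is declared it takes precedence over the site list,
so models with missing hydrogens yield the correct density. Density is
computed from whatever cell the input carries; no thermal-expansion
correction is attempted.

Symmetry expansion maps every site by every operator, wraps into [0,1), and
merges images of the same source site within 0.01 fractional units
(minimum-image metric), which collapses special positions. Sites sharing a
`disorder_group` tag are treated as alternative positions of one fragment and
must have occupancies closing to 1 ± 0.01.

## Powder-pattern simulation

Reflections are enumerated inside the d-spacing sphere of the requested 2θ
window via per-axis index bounds h ≤ a/d_min (exact for the axial families,
conservative otherwise), with 1/d² = h·G*·h from the reciprocal metric
tensor. |F|² is the kinematic sum Σ oⱼfⱼ(sinθ/λ)e^{2πi h·xⱼ} over the
expanded cell, with 4-term Cromer–Mann (IT92) form factors for any tabulated
element and a constant-Z fallback model. Reflections coinciding in 2θ within
1e-4° merge, accumulating multiplicity; merged intensity is Σ LP·|F|² with
LP = (1+cos²2θ)/(sin²θcosθ). Peaks are area-normalized pseudo-Voigt
(mixing η between Gaussian and Lorentzian), evaluated on the full grid so the
long Lorentzian tails are not truncated, and the pattern maximum is scaled
to 100. Defaults are typical laboratory conditions: Cu Kα₁ 1.5406 Å, 3–40°
2θ, 0.02° step, 0.1° FWHM, η = 0.5. No Kα₂ doublet, preferred orientation,
or Debye–Waller damping: the downstream consumer is a correlation score
dominated by peak positions. Structures with no observable reflection in
the window produce a flat zero pattern with a warning rather than an error,
so that one degenerate candidate cannot abort a ranking run.

## Pattern similarity and ranking

Two patterns on a common uniform grid are compared by the weighted
cross-correlation S = Σ_r w(r)c_pq(r)/√(Σw·c_pp·Σw·c_qq) with the triangular
weight w(r) = max(0, 1−|r|/l) sampled at integer grid offsets. S is symmetric,
scale-invariant, 1 exactly for proportional curves, and in the delta-peak
limit two peaks Δ apart score 1−Δ/l; for Gaussian peaks of finite width the
exact value is (1−Δ/l)/(1−E|r|/l) with E|r| the mean absolute offset of the
peak autocorrelation — both closed forms are asserted in the tests. With
l equal to the grid step the score reduces to the cosine similarity of the
two intensity vectors. The default half-width l = 1.5° 2θ follows the
conventional choice in the cross-correlation matching literature and absorbs
zero-point error and modest cell-parameter discrepancies; the zero shift is
deliberately not refined during scoring, keeping the score a pure function
of the two curves.

Preprocessing resamples by linear interpolation, removes a polynomial
baseline, clips negatives, and scales to unit area. The baseline is an
*iteratively clamped* least-squares fit: after each fit, only points at or
below the current polynomial are retained and the fit repeated until stable.
A plain least-squares polynomial through a peaked curve would sit well above
the background (a degree-0 fit is the mean), distorting background-free
patterns; the clamped fit converges onto the smooth background exactly when
the background is itself polynomial of the chosen degree. The degree should
match the background complexity of the data; the matching studies in the
test suite use degree 2 against quadratic synthetic backgrounds.

`rank_candidates` simulates every candidate at the experimental wavelength
and range, preprocesses both sides identically, and sorts by descending
score with lexicographic tie-breaks; a candidate whose simulation fails is
kept with score NaN at the bottom rather than silently dropped.

## Disorder

The isolated-site model Boltzmann-populates each disordered fragment's
configurations independently: occupancies pᵢ ∝ dᵢe^{−gᵢ/RT} (computed with a
max-shift; R = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹) and stabilization
ΔF = min(g) + RT·ln Σdᵢe^{−(gᵢ−min g)/RT} ≥ 0, reported as a positive
magnitude and subtracted from the entry's free energy. Per-configuration
energies are *inputs* — in practice they come from electronic-structure
calculations on ordered models. Independence makes the joint partition
function factorize, so per-site corrections add; this is verified against a
brute-force enumeration of all joint configurations for up to three sites.
Interacting disordered groups (e.g. a Z′ = 4 structure whose disordered
fragments touch) violate independence and are out of scope by design. The
two-configuration inverse, Δg = −RT·ln(p₂/p₁), turns refined occupancies
into an energy gap: a 58/42 split at 298 K corresponds to 0.800 kJ/mol, a
56/44 split at 300 K to 0.602 kJ/mol.

## Landscape assembly and error bars

Free energies are per molecule in kJ/mol at a reporting temperature of
300 K. Entries with explicit F_vib get F = E_latt + F_vib and σ = σ_base;
the remainder get the unweighted mean F_vib of the explicit subset (at least
two required) and σ = √(σ_base² + sd(F_vib)²), where sd is the sample
standard deviation (n−1) of the explicit values — the spread of the
vibrational term is exactly the extra uncertainty the uniform shift
introduces. Relative energies are measured from the minimum; ranking ties
break by higher density, then id, for deterministic output. σ_base defaults
to 1.9 kJ/mol, the value consistent with the probability pair below.
Structures outside the generation space (e.g. high-Z′ forms optimized
independently) enter as ordinary externally supplied entries.

## Risk statistics

Treating a pairwise computed gap ΔF as Gaussian with standard error σ, the
probability that the challenger is actually more stable is Φ(−ΔF/σ). σ is
applied directly to the pairwise difference — no additional √2 inflation —
because that is the only reading under which a single σ reproduces the
canonical 3.89 → 2.0% and 5.51 → 0.2% pair (both imply σ ≈ 1.89–1.91 kJ/mol);
by default the larger of the two entries' error bars is used. The solubility
fold is exp(ΔF/RT) with the gap taken from the assembled (and, when
supplied, disorder-corrected) free energies; its inverse RT·ln(ratio)
converts measured solubility ratios into experimental gap estimates.
Severity is a two-condition rule: *severe* when the challenger is both
plausible (p ≥ p_threshold, default 0.05) and costly (fold > tolerance_fold,
default 1.05 — a near-saturated solution formulation tolerates only minor
loss); *moderate* when exactly one condition holds; *low* otherwise. Both
thresholds are exposed as configuration.

## Synthetic study conditions

The generators stand in for the expensive upstream producers:

* **Toy crystals** — random cells (edges 4–30 Å, free angles 80–120°,
  constrained to the crystal system) in P1, P2₁, C2 or P2₁2₁2₁ with up to 20
  light atoms (C/N/O/S) at general positions. They are not molecules; they
  exist to give the diffraction and matching stages realistic peak
  complexity.
* **Candidate landscapes** — true relative free energies with exponential
  spacing (default scale 2 kJ/mol) above a global minimum, matching the
  dense-above-minimum shape of predicted landscapes; observed lattice
  energies carry Gaussian noise of σ (`noise_sigma`), per-candidate
  vibrational terms scatter with the same σ around a mean of −3 kJ/mol, and
  only the lowest-energy subset reports them explicitly. At zero noise the
  assembled landscape reproduces the truth exactly; at σ = 1.9 the rank
  inversion rate for a 3.89 kJ/mol true gap matches Φ(−3.89/(1.9√2)) for two
  independently noisy energies, verified by Monte Carlo.
* **Noisy patterns** — clean simulation, then a zero-point shift (default
  0.02°), a polynomial background, and multiplicative Gaussian noise
  (default 5%), clipped at zero. These are the conditions of the matcher
  self-identification study: 20 candidates, 100 seeded trials, ≥95 top-1
  hits required.
* **Disorder ensembles** — 2–3 configurations per site with gaps uniform in
  [0, gap_scale].

All generators are pure functions of (seed, parameters); substreams are
drawn from `default_rng([seed, stream_counter])` so adding a fixture never
perturbs existing ones.

What passing these tests shows — and does not: the pipeline arithmetic,
ranking behaviour and statistical calibration are exercised end to end, but
toy crystals have no molecular form factor structure, no preferred
orientation, and no instrument aberrations beyond those injected, so
matching performance on real laboratory data will be lower and
preprocessing choices matter more.

## Numerical choices and problem sizes

Boltzmann weights use max-shifted exponentials / `logsumexp`; reflections
merge at 1e-4° 2θ; symmetry images merge at 0.01 fractional units;
reflection-box bounds are floor(edge/d_min) per axis; similarity offsets
stop where the triangular weight reaches zero. The acceptance script runs
the matcher statistic at 40 seeded trials and the test suite at 100; the
Monte-Carlo σ-recovery checks use 10⁵ draws (within 3 binomial standard
errors) and 2000 seeded landscape pairs. The full suite runs in well under
a minute of CPU on one core.

## Known limitations

* Kinematic intensities only; no Rietveld/Pawley refinement, so the
  similarity score is a screening statistic, not a structure solution.
* The isolated-site disorder model cannot describe interacting disordered
  fragments; such structures need explicit ensemble treatments.
* Severity classification is a deliberately simple two-threshold rule;
  nucleation and growth kinetics — the reason a predicted stable form may
  never appear — are not modeled.
* The uniform F_vib shift assumes the explicit subset is representative of
  the rest of the landscape; a biased subset biases both the shift and its
  error bar.
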