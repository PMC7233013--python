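# Methods

## Problem and model

A still two-color diffraction image records two superimposed patterns of
one microcrystal, taken by an XFEL pulse pair at photon energies E₁ and
E₂ (defaults 7 and 9 keV). Given prior unit-cell parameters, indexing
means finding the proper rotation U carrying the crystal-fixed
reciprocal basis B into the laboratory frame, such that as many observed
peaks as possible coincide with reciprocal-lattice nodes on one of the
two Ewald spheres.

Conventions, pinned once and used consistently:

* crystallographic reciprocal metric, |k| = 1/λ without 2π, so a d Å
  resolution cutoff is |q| ≤ 1/d Å⁻¹;
* laboratory frame: beam along +z, detector plane at z = distance, fast
  axis +x, slow axis +y; pixels 0-based with centres on integers; beam
  centre defaults to the panel centre (719.5, 719.5);
* B in the Busing–Levy orientation (a* along x, b* in the x–y plane).
  Only U·B is physical; the fixed convention makes serialized solutions
  and tests well defined. B is validated against gemmi's reciprocal-cell
  computation in the test suite;
* Euler angles are intrinsic z–y–x ("ZYX"); orientation errors are
  reported both as the rotation angle of U_est·U_trueᵀ and per Euler
  angle;
* nearest-integer rounding is half-away-from-zero (ties are measure-zero
  since matching requires a residual ≤ 0.25).

## Search

**Reference table.** All reflections of the prior cell to d_min = 5 Å
(both Friedel mates; P1, no symmetry reduction) are enumerated — 12,316
for the default triclinic cell. An entry is an unordered reflection pair
described by (len_a ≤ len_b, angle); pairs within 10° of collinearity are
excluded (`min_angle_sep`) because they produce numerically unstable
rotations. At realistic cutoffs the pair set (~7.6×10⁷) is far too large
to materialize, so the table stores the reflection list sorted by vector
length and generates matching entries lazily per query via binary search
on both length windows plus a vectorized angle filter; a query is
provably identical to a linear scan over all pairs (tested against one).
Explicit materialization and pair serialization are guarded by a
5×10⁶-entry cap.

**Seed pairs.** Peak pairs are ranked by the sum of the two peaks' sort
key (SNR by default; intensity and radial-distance "resolution" keys are
supported) with a lexicographic peak-index tie-break, and the top
`n_pairs = 5` are tried. Ranking is a property of peaks, not colors, so
both per-color searches share the same pair list. Only peaks whose
reciprocal-vector length lies within the table's resolution range under
*both* wavelengths are eligible for seeding: a peak outside the table
under one hypothesis can never produce a table hit there, and spending
the fixed pair budget on such peaks is what makes sparse-budget indexing
fail. Peaks of any resolution still participate in scoring.

**Candidates and scoring.** For each seed pair and each wavelength the
observed triple is matched against the table; every hit (including the
swapped assignment when the two lengths are within tolerance of each
other) yields a rotation by aligning right-handed orthonormal triads
built from (v₁, v₁×v₂, v₁×(v₁×v₂)) of the observed and reference pairs
— proper by construction. All candidates from both per-color searches
are pooled and scored with the two-color score (matched = min of the two
per-color residuals ≤ δ = 0.25); pooling costs at most 2× and removes
the failure mode where the correct rotation is second-best under a
single color. Ties on S break by smaller summed residual over matched
peaks, then earlier seed-pair rank, then query order — the search is
fully deterministic and invariant to peak relabeling up to exact ties.
A solution is accepted when S ≥ max(6, ⌈0.4·n_peaks⌉); the floor of 6
prevents two-peak self-matches from "indexing" noise (a 60-peak
no-lattice null model stays below threshold in the tests).

**Color assignment.** With residual pair (e₁, e₂) per peak,
p₁ = e₂/(e₁+e₂) and p₂ = 1−p₁; both-zero residuals give 0.5/0.5. A
matched peak is assigned to the color with probability > 0.5; equal
residuals or unmatched peaks stay unassigned (probabilities still
reported). The inverse-residual share is the simplest form that is
normalized, monotone (smaller residual → larger probability) and
symmetric under color exchange.

**Refinement.** The final rotation minimizes
f(U) = Σ_{i∈G₁} ‖h_f,i(λ₁) − h_int,i‖² + Σ_{i∈G₂} ‖h_f,i(λ₂) − h_int,i‖²
over rotations only (the prior cell is trusted and held fixed), with
integer targets frozen at their values under the unrefined U₀ and U
parametrized as an axis-angle perturbation composed with U₀ — exactly
orthonormal at every evaluation (scipy BFGS, gtol 1e-12). If the
optimizer fails to improve, U₀ is returned with a non-converged flag;
the objective never increases, and if re-scoring at the refined rotation
ever lost matched peaks the driver falls back to U₀. Unassigned peaks
are excluded from refinement.

## Simulator

The generator is purely geometric, matching what an indexing test needs:
reciprocal-lattice points are spheres of fixed radius r; a reflection is
excited under a color when its rotated lattice point lies within r of
that color's Ewald sphere surface; excited points are snapped radially
onto the sphere (the detector records where the sphere cuts the spot)
and projected to real-valued pixel coordinates; spots off the panel are
dropped. Structure factors, partiality, mosaicity, background and
detector noise are deliberately absent, and all peaks carry
intensity = SNR = 1. An optional Gaussian pixel jitter (default 0)
supports noise studies. Each pattern keeps its ground truth: U_true,
per-peak color, Miller index, and a dual-excitable flag for reflections
within r of both spheres (inherently color-ambiguous; ~1–3% of peaks at
7/9 keV).

Defaults are the validation study's conditions: triclinic cell
a=64.3, b=72.0, c=89.2 Å, α=110.6°, β=107.5°, γ=85.8° (PDB 5m2t, P1);
1440×1440 panel, 100 µm pixels, 0.1 m distance; energies 7 and 9 keV.
Simulated spots extend to d_min = 3.0 Å while the indexing table stops
at 5 Å — deliberately different, so the search must cope with peaks it
cannot look up. The sphere radius default is r = 3×10⁻⁴ Å⁻¹: the
expected excited count per color is Σ r/|q| over reflections in range
(the Ewald-band fraction of the orientation sphere), ≈ 68 for the
default cell before detector clipping, i.e. patterns with some tens of
peaks per color — typical of sparse SFX stills and cheap enough that the
whole 100-pattern study indexes in ~2 minutes. The snap also bounds the
simulation's intrinsic residuals: ≤ |a_max|·r ≈ 0.027 per fractional
index component and ≲ r/|q| in pair angle, comfortably inside δ = 0.25
and the 1° angle tolerance for all but the very lowest-resolution pairs.

Because positions are exact up to the Ewald snap, passing tests show the
search, scoring, classification and refinement are correct — they say
nothing about robustness to centroiding error, indexing of weak/split
peaks, or intensity pathologies of real detectors (the pixel-jitter
knob exists for such studies but is not part of the validation).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| δ (`delta`) | 0.25 | — | max fractional-index deviation for a match |
| `n_pairs` | 5 | — | seed peak pairs tried per pattern |
| `sort_key` | snr | — | pair ranking key (snr / intensity / resolution) |
| `tol_len` | 0.0025 | Å⁻¹ | table length tolerance (printed value is dimensionally a reciprocal length) |
| `tol_angle` | 1.0 | deg | table angle tolerance |
| `min_angle_sep` | 10 | deg | collinearity guard on table pairs |
| `min_score` | max(6, 0.4·N) | peaks | acceptance threshold |
| table `d_min` | 5.0 | Å | reference-table resolution cutoff |
| sim `d_min` | 3.0 | Å | simulated-spot resolution cutoff |
| `sphere_radius` | 3×10⁻⁴ | Å⁻¹ | lattice-point radius (sets peak density) |

## Validation scale

The reference study indexes 100 simulated patterns (seed 42) with
default parameters — every pattern indexes with orientation error well
below 0.1° and the median per-Euler-angle error is ~0.003°. A 20-pattern
study at 9/9.1 keV (1% separation) also indexes fully; there the two
spheres nearly coincide, most peaks are dual-excitable and color
classification is intentionally uninformative. Exhaustive-search
equivalence is checked on a cubic 10 Å toy cell (32 reflections, 496
pair entries) where brute force over every pair/entry/assignment is
affordable; orientation comparisons there are made modulo the cubic
lattice's 24 proper point-group rotations.

## Known limitations

* Single flat panel, no tilts or multi-panel geometry refinement.
* One lattice per pattern; no multi-crystal deconvolution.
* P1 reference only: no systematic absences, no resolution of lattice-
  symmetry indexing ambiguities.
* The prior cell is an input and is never refined.
* Peak-pair ranking on constant-SNR input degrades to index order; real
  peak lists with informative SNR rank better.
* At small energy separations the two hypotheses become degenerate:
  orientations index fine but per-peak color probabilities hover near
  0.5 by construction.
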