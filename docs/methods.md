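# Methods

## Model and frame

The valve section is planar.  The anterior annular hinge is the origin, the
posterior hinge sits at `(MAD, 0)` and y grows toward the apex.  Each
leaflet is an inextensible Euler elastica clamped horizontally at its hinge
and loaded only at the free edge by its chorda; there is no distributed
(pressure) load — the model represents the intra-operative state, not the
pressurised systolic valve.  The closed-form solution is parametrised by
the free-edge tangent angle `θ_l` and the load inclination `α` (from the
apical axis); the elliptic modulus convention is the SciPy parameter
`m = k²` throughout, and every elliptic-function identity used is covered
by quadrature and ODE-shooting oracle tests.

Chordae tilt *away* from the valve midline (`arg(m−b) = π/2 ± α`): this is
the tethering geometry of laterally/apically displaced papillary muscles,
and it is the only sign convention under which the preoperative
interpapillary distance (44.6 mm) can exceed the annular diameter (41 mm)
without the papillary muscles crossing sides.  Chordae are tension-only;
a slack chorda (`λ < 1`) transmits no force and is flagged.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `l_a, l_p` | 18, 13 | mm | leaflet lengths |
| `B` | 500 | mN·mm² | leaflet bending stiffness |
| `c1, c2` | 352.4, 0.1907 | mN/mm², – | Fung chorda constants |
| `A_ref` | 0.197 | mm² | chorda reference cross-section |
| `MAD_pre` | 41 | mm | annular diameter (case study) |
| `IPD_pre` | 44.6 | mm | end-diastolic interpapillary distance |
| `TH_pre`, `TH_opt` | 12.4, 6.8 | mm | tenting height, target coaptation height |
| `δ_a, δ_p` | 32.6°, 56.8° | – | leaflet angles |
| `h_a, h_p` | 45, 35 | mm | annulus-to-papillary-head heights (case study) |

With these chorda constants the initial tangent modulus `c1·c2 ≈ 67
mN/mm²` is soft, so physiologically large preoperative stretches (the
posterior chorda reaches `λ ≈ 2.1` at the reference case) are intrinsic to
the parameter set, not a solver artefact.

## Preoperative identification

Chorda inclinations are drawn uniformly on (1°, 60°); for each draw the
end-slope is the Brent root of the congruence `y_l = x_l·tan δ` (the tip
deflection grows monotonically with the end-slope, giving a single
bracketed sign change), and a draw is accepted when both tip depths fall
within `TH ± ΔTH` and the papillary distance within `IPD ± ΔIPD`.  Window
half-widths default to the reported cohort spreads (0.13 and 0.39 mm) and
are configurable.

Two structural facts about the reference measurement set matter:

1. **The tenting window is geometrically unreachable.**  On the δ-ray the
   tip depth is `chord·sin δ ≤ l·sin δ` = 9.70 mm (anterior) and 10.88 mm
   (posterior), both below `TH − ΔTH` = 12.27 mm.  The identification
   therefore offers a `mode="best"` that returns the compatibility-optimal
   configuration (tips as deep as the geometry allows, papillary distance
   inside its window) and records the residual window miss; `accept_first`
   mode raises with a closest-miss report, as a strict reading demands.
   Every reference-case analysis in this package uses `mode="best"`.

2. **The asymmetric identification is underdetermined.**  Tip depth is
   nearly independent of the chorda inclination, so the tenting window
   exerts no selection and a single interpapillary-distance equation cannot
   pin two angles: any point of a one-parameter family passes.  The
   reference analyses therefore impose symmetric tethering — one shared
   inclination for both chordae (`symmetric=True`), the study condition the
   model is built for.  Asymmetric identification remains available, with
   the caveat that recovered per-chorda stresses are then seed-dependent.

Finalisation computes the loads from the elastica (`P = Bω²/l²`), the
stretches from node equilibrium (Brent on a bracket grown geometrically;
the Fung stress is exponential and the load term linear, so the root is
unique), and the chordae reference lengths by pull-back.

## Postoperative solves

For a fixed PM-displacement orientation pair the seven-equation system
collapses exactly: coaptation pins the end-slope given the inclination,
equilibrium pins the stretch given the leaflet load, congruency then
places the papillary head — leaving one scalar orientation-match equation
per side, solved by grid scan plus Brent (the anterior side decouples; the
posterior is solved conditional on the shared coaptation abscissa).  Every
reported solution is re-verified against the full scaled residual vector
(components scaled by `c1`, `MAD_pre` and radians; sup-norm reported, with
`1e-8` as the acceptance threshold).

**Orientation optimisation.**  The orientations `(ζ_a, ζ_p)` are sampled
uniformly on `[−2, 2]²` — negative values move a papillary head toward the
annulus, which is the direction an approximation that reverses apical
tethering must take.  The objective is the worst chorda nominal stress
(`objective="max"`; `"sum"` available).  The stress landscape over the
orientations is nearly flat (tens of draws lie within a few percent of the
minimum while the implied papillary positions range over centimetres), so
the reported argmin of a finite random search would be noise; among draws
within 2% of the best objective the solution of smallest total papillary
displacement is returned.  The parsimony tie-break reflects the surgical
concern that disproportionate displacements load the papillary roots and
ventricular wall, and it makes the reported geometry reproducible across
seeds (the five-seed spread of every reported quantity is under 1 mm).

**Annuloplasty alone.**  With the papillary muscles held at their
preoperative positions, each leaflet can only move along its
tethered-equilibrium branch, and the scalar equilibrium residual at the
target coaptation height is positive for *every* inclination: annular
restriction alone cannot bring the tips to `TH_opt`.  The solver instead
drives both tips to the common depth of maximal reach — the limiting side
sits at its branch fold (located by bisection), the other side matches its
depth — leaving a horizontal coaptation gap that is reported as an
outcome.  At that configuration both chordae are at their maximal
tethering stretch, so the stress and stretch ratios exceed 1, and the
residual tenting above the target expresses the recurrence risk of
isolated annuloplasty under severe tethering.

**Complete approximation.**  Both papillary heads share one orientation ζ,
the unknown balancing the added prescribed-distance equation (solved by a
scan-plus-Brent root in ζ).  Because each head must keep its equilibrium
distance `λ·L_c` from the coapted tip, the achievable distance is bounded
below; at the reference case the floor is ≈16.4 mm, so the conventional
10-mm prescription is unreachable there (it is honoured to `1e-8` on
geometries with lower-set papillary heads).  `solve_scenario` raises by
default; `compare_scenarios` substitutes the nearest achievable distance
and records the substitution.

## Synthetic cohort

`generate_cohort` draws each measurement independently from a truncated
normal around the reference means/spreads (angles in degrees at the
boundary), truncated at plausibility bounds; model constants carry zero
spread.  It emulates between-patient variability of the echocardiographic
measurements only — not intra-patient measurement error, covariance
between measurements, or asymmetric-tethering phenotypes — so passing
recovery tests demonstrate identifiability of the model under its own
generating process, not robustness to real imaging noise.

## Numerical choices

* Elliptic functions: `scipy.special` (`ellipk/ellipkinc/ellipeinc/ellipj`),
  parameter `m = k²`.
* Zero-load degeneracy: below `ω = 1e-6` the parametric shape is 0/0 and
  the analytic straight-rod limit is returned (round-off in `φ_α ≈ π/2`
  leaves `ω ~ 1e-8` for a truly unloaded beam, hence the threshold).
* Scalar roots: Brent with `xtol` between 1e-13 and 1e-14; grid scans use
  81–160 points, with bracket hints carried between neighbouring
  inclinations for speed (the hint path falls back to a full scan).
* Root moments are reported as magnitudes; only ratios are used.
* Determinism: every stochastic routine takes a seed and uses
  `numpy.random.default_rng`; identical inputs and seeds give bit-identical
  outputs.

## Problem sizes

The reference analyses use 1 500 identification draws, 200 orientation
draws per optimisation and five seeds per reported quantity (medians);
the synthetic-recovery study uses 50 patients.  A full five-seed
reference-case reproduction takes roughly half a minute on one CPU.

## Known limitations

* 2D kinematics; no systolic pressure on the leaflets, no leaflet contact
  beyond the tip-height constraint, single effective chorda per leaflet,
  no commissural chordae, no annular saddle shape.
* The printed reference tenting height is unreachable under the printed
  leaflet lengths and angles (see above); reference-case results therefore
  correspond to the deepest compatible tenting (~9.4/10.0 mm), and
  quantities that inherit the preoperative bending state (notably the
  anterior root-moment reduction, ~32% here) sit below what a deeper,
  internally consistent preoperative state would give.
* Chordae are elastic; no viscoelasticity, damage or rupture criterion.
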