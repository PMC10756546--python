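# Methods

## Scope and model

The package models **diacyl glycerophospholipids** of seven head-group
classes (PC, PE, PME, PDME, PI, PG, PS). Lyso- and ether species,
double-bond positions/geometry, sn-stereochemistry, isotopic fine structure
and multiply charged ions are out of scope. A fatty acyl chain is described
only by carbons and double-bond equivalents (DBE); because DBE counts rings
as well as double bonds, the structural feasibility guard
`DBE <= carbons - 2` can be relaxed per call (`strict=False`) for exotic
chains.

All mass arithmetic uses a single table of monoisotopic atomic masses
(CODATA/IUPAC; deuterium included for the d70 internal standard), and every
ion m/z is **electron-corrected**: the phosphocholine fragment computes to
184.0733 rather than the 184.0739 one obtains ignoring the electron. This
correction is required to match diagnostic masses quoted at 4 decimals.

Adduct conventions: ESI+ [M+H]⁺ for PC/PE/PME/PDME/PS and [M+NH4]⁺ for PI
and PG (the ammonium-acetate mobile phase promotes ammonium adducts for the
acidic classes, and their positive-mode neutral-loss masses — 277.0563 =
inositol phosphate + NH3, 189.0402 = glycerophosphate + NH3 — are only
consistent with the ammonium adduct); ESI− [M+HCOO]⁻ for PC and [M−H]⁻
otherwise. The per-class choice is overridable.

The closed-form neutral formulas (PC(C:D) → C_{C+8}H_{2C−2D+16}NO8P, etc.)
are verified in the test suite against an independent additive assembly:
glycerol + phosphoric acid + head alcohol + two fatty acids minus one water
per ester/phosphoester bond.

## Identification procedure

A species is confirmed only when every stage passes:

1. ESI+ MS² class assignment (PC fragment ion; head-group neutral loss for
   the rest), candidates ranked by matched-fragment intensity.
2. Sum composition by exhaustive scan of the (total carbons, total DBE)
   grid — defaults C ∈ [20, 70], D ∈ [0, 16] — against the ESI+ precursor.
3. Co-eluting ESI− precursor of the same neutral species.
4. The negative-mode class rule where the class has one (PC, PI, PS). PE,
   PME, PDME and PG have no negative-mode diagnostic and confirm on
   precursor plus acyl evidence alone.
5. At least one acyl pair summing to the composition with both carboxylate
   anions observed in ESI− MS² (acyl space defaults: carbons ∈ [12, 40],
   DBE ∈ [0, 10], covering 12:0–36:8). The more intense anion is assigned
   sn-2 (ties go to the longer chain — a documented arbitrary tie-break).

Rejections are returned as data with machine-readable reasons, never
raised. Species confirmed without any matching acyl pair are rejected by
default; setting `require_acyl_pairs=False` keeps them as
"sum-composition-only" entries instead (they are then excluded from
fatty-acid-level statistics).

Co-eluting isomers are integrated as one chromatographic peak, so an
annotation carries *all* consistent acyl pairs; wherever a statistic needs
per-pair abundances, the species percentage is apportioned across pairs by
the intensity of each pair's more abundant acyl fragment.

## Tolerances and pairing

The original peak integration was done in vendor software that publishes no
tolerances, so these are engineering defaults, all exposed as config keys:

| parameter       | default | unit | role |
| --------------- | ------- | ---- | ---- |
| `ms1_ppm`       | 5       | ppm  | precursor matching (both polarities) |
| `ms2_ppm`       | 10      | ppm  | fragment/neutral-loss/acyl-anion matching |
| `rt_tol_min`    | 0.1     | min  | cross-polarity co-elution window |
| `pair_mass_ppm` | 2×ms1   | ppm  | implied-neutral-mass agreement when pairing |

Cross-polarity pairing is greedy nearest-RT matching under the constraint
that the neutral masses implied by adduct removal agree; since *two*
measurements each within `ms1_ppm` of the same truth can disagree by up to
twice that, the pairing window defaults to `2 × ms1_ppm`. Each feature is
used at most once; unpaired features are reported, not dropped.

Retention times are in minutes; the observed IPL elution window
(3.5–9 min) is a sanity warning, never a filter.

## Quantification

Quantification is relative to the d70-PC(36:0) internal standard (mass
shift +70·(²H−¹H) ≈ +70.439 Da), located in the positive run by accurate
mass. Class-matched standards: PC(16:0)→PC; PE(16:0)→PE, PME, PDME;
PG(16:0)→PG, PI; PS(16:0)→PS.

Calibration series span 0.1 pg/mL–10 µg/mL in quadruplicate. Per level,
replicate area ratios pass an **iterative two-sided Grubbs test**
(α = 0.05; critical value ((N−1)/√N)·√(t²/(N−2+t²)) with t the upper
α/(2N) Student-t quantile at N−2 df), one removal per pass, never reducing
a level below three replicates; the survivors are averaged. Level means are
expected monotone in concentration; violations warn but do not abort.

For each sample ratio the **five nearest levels** are selected (ties toward
the lower concentration), preferring a bracketing window: if the nearest
five end up one-sided while the ratio lies inside the calibrated range —
which happens routinely on log-spaced levels — the farthest selected level
is swapped for the nearest level on the missing side. The concentration is
the ordinary least-squares line through those five points inverted at the
sample ratio (a 1/x-weighted fit is available via
`calibration_fit="weighted_1_over_x"`); negative predictions floor at zero
with a flag, ratios outside the calibrated range flag extrapolation.

Note on the Grubbs test at quadruplicate level: with N = 4 the Grubbs
statistic is bounded by 1.5 while the α = 0.05 critical value is 1.4813, so
power against moderate (≈5σ) outliers is intrinsically low; the test
protects mainly against gross excursions. This is a property of the test at
small N, not of the implementation.

Blank subtraction removes the mean process-blank concentration per species,
flooring at zero and dropping species fully explained by the blank.
Because tissue masses are unavailable, everything downstream uses
**percentage distributions** per sample (summing to 100 within 1e−9);
Grubbs is never applied to biological replicates.

The GC-MS free-fatty-acid ingestion converts (FA token, area, IS area) rows
to SFA/MUFA/PUFA percentages of the total lipid extract using one response
factor per saturation class (mirroring calibration with one saturated, one
monounsaturated and one polyunsaturated reference acid) and the deuterated
18:0 released from the internal standard for drift correction.

## Composition statistics

* **Grouping**: within each class, species are binned LMW/MMW/HMW by
  neutral mass and LDU/MDU/HDU by total DBE. The published per-class
  boundaries live in supplementary tables that are not reproduced here, so
  defaults are the tertiles of the distinct values observed per class, with
  an injection point for explicit boundaries. Classes with fewer than three
  distinct values collapse to a single group.
* **PCA**: column-centred SVD of the percentage matrix (scaling optional),
  via scikit-learn — the one deliberately "library" step in the statistics
  chain.
* **Seasonal ratios**: per species, mean percentage over samples in month
  group A divided by mean over group B (means over samples, not pooled
  totals — an assumption, documented here). Species absent on one side are
  flagged one-sided, never imputed. `ratios(A,B)` is the element-wise
  reciprocal of `ratios(B,A)`.
* **Ternary SFA/MUFA/PUFA**: each species splits its percentage equally
  over its two acyl positions; multi-pair species are apportioned by
  more-abundant-acyl intensity; chains bin as SFA (0 DBE), MUFA (1),
  PUFA (≥2).
* **Indices**: mean unsaturation per fatty acid is
  Σ pctᵢ·(Dᵢ/2) / Σ pctᵢ over a class' species (DBE per chain weighted by
  relative abundance); EPA%/DHA% are the class percentages of species
  carrying ≥1 chain of 20:5 / 22:6, apportioned for multi-pair species and
  normalised over pair-resolved species.
* **Reference overlap**: per-class sum-formula counts, intersection and
  summed percentage coverage on each side against any user-supplied
  (species, pct) table.

## Synthetic data

The generator emulates what matters to the pipeline about a krill
digestive-organ lipidome and nothing more:

* class draw weighted 59:27:13:11:7:6:4
  (PC:PE:PDME:PI:PME:PG:PS), matching the observed sum-formula diversity;
* acyl pairs from a pool of 17 chains weighted toward 20:5, 18:1, 22:6 and
  16:0, including the very-long-chain PUFAs 26:6, 28:8 and 36:8; the more
  unsaturated chain is placed at sn-2;
* log-normal baseline concentrations (median ≈ 0.1 µg/mL, σ_log = 1,
  clipped to the calibrated range);
* an optional condition effect multiplying species in the upper mass or DBE
  tertile by a factor (default 2) in January/March digestive-gland samples —
  the summer high-MW/high-unsaturation shift;
* rendering with per-peak Gaussian m/z error (default σ = 2 ppm, typical
  of a well-calibrated Orbitrap), RT jitter (σ = 0.02 min) around
  class-level retention times inside 3.5–9 min, log-normal area noise
  (CV = 5%), decoy features kept ≥15 ppm (3× the MS1 tolerance) from every
  theoretical species m/z, the internal standard in the positive run, and
  process blanks carrying only IS and decoys;
* calibration series with linear response, multiplicative noise and
  optionally planted outliers at a stated σ-multiple.

It does **not** model chromatographic peak shapes, isotope envelopes,
in-source fragmentation, co-isolation chimeras, matrix effects or
class-dependent ionisation efficiencies. Passing round-trip tests therefore
demonstrates correctness of the identification and quantification logic
under controlled noise, not instrument-level robustness.

Determinism: a fixed seed yields byte-identical study directories and
pipeline outputs (all randomness flows through seeded numpy generators;
TSVs are written at 10 significant digits, which preserves sub-ppm mass
precision through round trips).

A note on recovery at the default noise level: confirmation requires both
polarities' precursors to fall within the 5 ppm gate independently, so with
iid 2 ppm Gaussian error per measurement the expected species recovery is
P(|N(0,2)| ≤ 5)² ≈ 97.5%, with zero false species (decoys are excluded by
construction and the grid has no near-degenerate neighbours at 5 ppm).
Noiseless rendering is recovered completely; at 20 ppm error the pipeline
collapses, as it should.

## Problem sizes used in the shipped tests

Simulated studies in the test suite use 10–40 species, 1–4 replicates per
month × organ cell and 20 seeds for the noise-sweep round trips; these
sizes give stable statistics for every directional and distributional
assertion while keeping the suite fast.

## Known limitations

* Local five-point OLS inversion is a minimal reading of "five calibration
  levels were chosen"; on log-spaced levels the fit is dominated by the
  upper selected level, so relative errors grow mid-decade.
* The sn-2 assignment from fragment intensity is a heuristic that depends
  on collision settings; it is recorded as evidence, not structure.
* Tertile grouping boundaries are a stand-in for published per-class
  boundaries; inject explicit breakpoints to reproduce a specific scheme.
* mzML ingestion is not included; the TSV feature-table dialect is the
  native interface and an adapter producing `Feature` objects is the
  intended extension point.
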