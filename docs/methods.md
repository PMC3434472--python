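# Methods

This note documents the modelling and numerical conventions of the
package: what the synthetic generator produces and why, which statistical
definitions are pinned where the assay literature leaves a choice open,
and the known limitations.

## 1. Experimental design and blinding

`cresstex.design` builds the crossed design: per (lab, day) there are
2 treatments × 3 internal replicates = 6 extract groups, each examined in
6 glass-plate replicates (36 treatment plates), plus 7 open
reference-standard slots — 43 scheduled plates per day.  The default shape
(7 LBI days + 8 BRAD days) gives 540 treatment plates; discarding 5 leaves
535 usable.

Coding assigns the day's extract groups the opaque codes "1"–"6"; the
processing order equals the code number because extracts are handled in
code sequence.  Two randomization schemes are provided:

* `manual_emulated` — a plain uniform permutation of the codes per day.
  This deliberately allows order/treatment imbalance, the failure mode the
  processing-order diagnostic exists to catch.
* `balanced` — alternates two complementary order patterns across days so
  the per-lab mean processing order is exactly equal between truth groups.
  The balance is exact only for even day counts per lab; an odd count
  leaves a one-day remainder that no pattern pair can cancel.

Blinding is structural, not cosmetic: coding moves the truth labels into a
private map, the public design table and every file the analysis stage
writes carry only codes, and `decode` validates the entire supplied key
against the private map before revealing anything (all-or-nothing; a
tampered key changes nothing).

Potency arithmetic uses the 1 : 9 step (factor 0.1 per step).  Nominal
molarity is `dilution × reference_concentration / molar_mass` with the
reference concentration defaulting to 1000 g/L of pure source — the single
assumption that reproduces both the 8.4·10⁻³⁰ M (tin, 118.71 g/mol, 30
steps) and 2.9·10⁻²⁴ M (lactose, 342.30 g/mol, 24 steps) figures.

## 2. Synthetic crystallograms

The renderer (`cresstex.synthesis`) is a stylised branching-walk texture
generator, not a physical model of CuCl₂ dendrite growth; the analysis
layer uses plates only as texture carriers, so what matters is the
statistical structure:

* **Dendritic skeleton.**  Random-walk branches radiate from one
  off-centre nucleus, with anchored side branchlets and a 45 %-amplitude
  taper.  Deposit amplitudes are *bipolar* (ridges brighten, interstitial
  shadows darken) and **exactly sign-balanced** — amplitudes are drawn in
  ± pairs for the main branches, the branchlets (mirrored across the ±
  parent halves) and the rim branches.  A binomial sign draw would leave a
  net skew of order √n branches, which would swamp the deliberate
  asymmetry channel below.
* **Roughness channel.**  Fine Gaussian noise with relative amplitude
  ρ = 1 + day effect + evaporation coupling + order drift + lab offset +
  plate noise.  ρ is a *structural* parameter (a contrast ratio), so it
  survives the global grey normalisation that discards absolute mean/SD.
  The gradient-sensitive variables (inertia, inverse difference moment,
  entropy/energy, the sum/difference statistics) read this channel, which
  is what ties them to evaporation time (group II behaviour).
* **Asymmetry channel.**  Soft bright droplets (Gaussian blobs, σ = 0.9 px)
  in the centre zone (r < 65 %).  One log-normal plate-level strength
  scales all of a plate's droplets, so the odd-moment variables
  (cluster_shade, diagonal_moment) co-vary across plates — the group I
  pair.  Because blobs are smooth, they add high-grey-level mass with
  small pixel-to-pixel gradients and therefore stay out of the roughness
  variables: the two variable groups are separated *by construction of the
  image physics*, not by post-hoc labelling.
* **Treatment signal**, two spatial components mirroring the assay's
  localisation findings: verum amplifies the centre droplets (the
  amplification is mostly variance-neutral — droplet count falls as
  1/√boost while amplitude rises with boost — because a fully
  variance-coupled boost would leak into every region through the global
  normalisation), and verum applies a reproducible contrast gain in the
  70–90 % annulus plus a day-modulated gain in 50–70 % (the
  day × treatment interaction).
* **Peripheral crystallisations.**  Rim-anchored inward branches appear
  when the evaporation time exceeds its threshold (default 19 h), with
  count proportional to the excess.
* **Evaporation times** are drawn per day (LBI 14.25 ± 0.75 h uniform,
  BRAD 21.5 ± 4.5 h uniform; replicate SD 0.15 h), reproducing the two
  labs' reported per-day ranges with the day effect dominating the
  replicate effect.

Determinism: every random quantity comes from a `SeedSequence` keyed by
(study seed, lab, day, processing order, plate replicate) — a plate's
pixels are a pure function of its own identity, insensitive to unrelated
design edits, and whole-study generation is bit-reproducible.

### A note on global normalisation

Gaussian normalisation pins the whole-disc mean and SD.  Any local
contrast gain therefore reappears with the opposite sign everywhere else
("normalisation shadow").  Consequences built into the package's
validation: spatial localisation is tested on *signed* standardized
verum−control differences (the annulus component is positive only in
70–90 % and negative elsewhere; the centre component is positive and
largest inside 70 %), not on raw F magnitudes, which the shadow inflates
in every region.

## 3. Image preparation and GLCM conventions

* Grey conversion: equal-weight RGB mean, rounded.
* Gaussian normalisation: linear mean/SD standardization to (127.5, 32)
  within the disc, clipped to [0, 255] and re-quantized (idempotent up to
  one grey level).  A histogram variant (rank mapping onto Gaussian
  quantiles) is available behind `normalize: histogram`.
* ROIs are annuli in percent of the disc radius; the boundary convention
  is half-open (inner inclusive) with a closed outer boundary at 100 %, so
  the four standard segments partition the disc pixel-exactly.
* GLCMs accumulate pixel pairs over the four standard directions and both
  orientations (symmetric) at displacement 1, **counting a pair only when
  both endpoints lie in the ROI mask** — annulus statistics are exact at
  segment boundaries.  Counts are integer until the final normalisation.
  Grey rebinning (levels < 256) is uniform-width floor assignment.
* The 15 feature formulas are pinned in `cresstex.texture`'s module
  docstring (natural logarithms, 0·log 0 ≡ 0, correlation ≡ 0 at zero
  marginal variance, kappa ≡ 1 at Pe = 1).  `diagonal_moment` is defined
  as Σ √|i−j| (i+j−μx−μy) p — an odd-moment form chosen so it co-varies
  with cluster_shade rather than with inertia, matching the assay's
  empirical grouping; `kappa` is the chance-corrected diagonal agreement
  (P0 − Pe)/(1 − Pe).

## 4. Statistics

* **Factorial ANOVA** uses effects (Sum) coding with partial
  (Type-III-style) sums of squares, so the mild imbalance left by plate
  discards is handled; on balanced data this reduces to the classical
  decomposition.  Constant responses report SS = 0, p = 1 instead of
  failing a whole run; saturated models (no residual degrees of freedom)
  and inestimable effects (empty cells) raise informative errors.
* **Holm correction** is applied over the whole main-table family
  (7 effects × 15 variables = 105 tests, the conservative
  independent-tests assumption).
* **Variable grouping**: connected components of the between-plate
  correlation graph thresholded at |r| ≥ 0.6; components are labelled
  evaporation-linked ("II") when their median |r| with evaporation time
  reaches 0.46, otherwise "I"; singletons are "intermediate".
* **Processing-order diagnostic**: control-group values are normalised to
  their day mean (ratio by default, subtraction as an option), pooled
  across days, and tested by one-way ANOVA on the order factor 1–6.  The
  **correction** subtracts the least-squares linear order component
  (grand mean preserved; idempotent; refitted slope numerically zero).
* **LSD post-hoc** contrasts use the omnibus model's residual mean square
  and residual degrees of freedom.

## 5. Validation experiments (`cresstex.calibration`)

All four experiments run the *full* pipeline (design → blinding →
rendering → normalisation → GLCM → ANOVA) on reduced studies (128-px
plates, single lab, 4–6 days, 2 plate replicates, 64 grey levels — sizes
chosen by this package for desk-scale runtime, not taken from the assay):

1. **Type-I calibration** — 500 null studies; the treatment rejection rate
   at α = 0.05 must lie within 3 binomial SE of 0.05.
2. **Effect recovery** — treatment effects 0.1/0.2/0.4; the median
   treatment F in the annulus component's home region grows monotonically,
   and the signed standardized differences localise both components as
   described in §2.
3. **Order machinery** — injected drifts 0–0.2 per order unit; the
   diagnostic's power exceeds 0.8 at the largest slope, and after linear
   correction the refitted slope is ≤ 10⁻¹⁰ with the rejection rate back
   at nominal.
4. **Grouping** — plates pooled across 8 effect-bearing studies (the
   sampling noise of a correlation on one small study is comparable to the
   0.6/0.46 thresholds themselves; pooling brings the SE to ~0.04):
   cluster_shade/diagonal_moment correlate ≥ 0.6 with each other and
   < 0.46 with evaporation time, while the roughness block's median
   evaporation correlation exceeds 0.46.

Independent oracles back the deterministic layers: a brute-force
double-loop GLCM with literal-formula (fsum) features, and a
projection-matrix least-squares ANOVA with explicit sum-coded design
matrices (`tests/_oracles.py`).

## 6. Limitations

* The renderer is not crystal-growth physics; effect magnitudes are free
  parameters, so validation is *recovery of injected truth*, never
  reproduction of the original assay's F statistics or p-values.
* The exact "Gaussian normalisation" of the original scanner pipeline is
  unspecified; both implemented variants are flagged in run provenance.
* `diagonal_moment` and `kappa` definitions are declared choices (the
  source framework's formulas are not public); they are validated by the
  grouping behaviour only.
* Whole-plate treatment tests on single small synthetic studies are
  conservative because of the normalisation shadow (§2); detection there
  relies on the per-ROI tables and pooled experiments.
* The balanced randomization scheme is exact only for even day counts per
  lab.
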