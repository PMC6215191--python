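# Methods

This note documents the statistical model behind `cyanoval`, the choices
made where the conventional protocol leaves room, and what the synthetic
generator does and does not emulate.

## The measurement model

Every computation runs on a tidy table of instrument observations
(`analyte_id, sample_type, nominal_conc, day, replicate, response,
youden_combo`). Concentrations are in µg L⁻¹ of spiking solution; in the
emulated design 1 mL of solution is spiked onto ≈1 g of fresh leaf, so
µg L⁻¹ and ng g⁻¹ fresh weight are numerically identical and no unit
conversion is ever computed — the equivalence is documentation only.

The response model is linear: `y = a + b·c`, with a matrix-specific slope
`b_matrix = b_solvent · ratio`. All downstream statistics are computed on
back-calculated concentrations `(y − a)/b_matrix`, never on raw areas,
except the blank statistics, which the LOD/LOQ convention defines in
signal space first (`Y = Ȳ_blank + n·S_blank`) and converts afterwards.

## Calibration and linearity

* Unweighted OLS (`scipy.stats.linregress`); weighted or robust fits are
  deliberately out of scope — the protocol being modelled reports single
  unweighted equations per analyte.
* Huber plot: the response factor uses the **mean** of replicate responses
  per level before ratioing (one point per concentration), the target is
  the **median** factor across levels, and the band is ±5 % (configurable).
  The plot's pass is scale-invariant by construction.
* Lack of fit: SS_res = SS_pure-error + SS_lack-of-fit is an identity the
  test suite checks to 1e−8 relative. Degrees of freedom always follow the
  data actually supplied: 12 levels × 3 replicates gives (10, 24) and an
  F criterion of ≈2.25. Validation reports in this field sometimes quote
  the much weaker (10, 2) bound of 19.4; that value is reproduced as a
  quantile computation in the tests, never hard-coded as the criterion.
* Degenerate inputs: MS_pe = 0 with MS_lof = 0 yields F = 0 (pass);
  MS_pe = 0 with MS_lof > 0 yields F = ∞ (fail). No replication at any
  level is a design error, not a silent skip.

## Sensitivity

LOD = max(0, (Ȳ + 3S − a)/b), LOQ with 10S; the max(0, ·) clamp is applied
because concentrations are physical. Blank statistics use the n−1 SD.
Whether "blank signal" means raw area or back-computed concentration is
ambiguous in practice; the implementation works in raw-signal space and
inverts afterwards, the order the defining equation states. The identity
LOQ − LOD = 7·S_blank/b holds exactly away from the clamp and is tested.

## Matrix effect

Computed from the slope ratio of two full calibrations
(ME% = 100·(b_m − b_s)/b_s), not from a signal ratio at a single level: a
per-analyte single number spanning the whole curve forces the slope-ratio
convention. Bands: |ME| < 10 negligible, 10–20 mild, > 20 strong.

## Precision components

Balanced one-way ANOVA with day as the random factor. Two conventions
coexist in the literature for the reported "between-day" figure; this
package follows the one its reference table is internally consistent with:

* `s_b_paper = √MS_between` — the reported S_B;
* `s_b_component = √max(0, (MS_b − MS_w)/r)` — the day variance component;

both are exposed. S_IP = √(MS_w + max(0,(MS_b − MS_w)/r)), truncating a
negative day component at zero (the standard convention for one-way random
effects). Consistency check: reconstructing S_IP from every reference
(S_w, S_B) pair with r = 3 reproduces the reported values within ±0.01 —
11 of 12 rows agree at 2 decimals exactly; the MC-YR 5 µg L⁻¹ row
recomputes to 0.47 against a printed 0.46, inside rounding tolerance.

%RSD_IP divides by the **mean measured** concentration, not the nominal
spike: only that convention makes the reference RSDs jointly consistent
with the reported recovery ranges. Unbalanced layouts are rejected rather
than approximated, since the component formulas assume balance.

## Robustness

The design is a full 2³ factorial (8 runs, 3 factors), not the classical
7-factor Youden screen. The factor-level time settings attached to the
combination labels are metadata; the sign coding drives the statistics.
The t construction is the one point where the conventional protocol is
underdetermined, so it is stated explicitly: the error SD is the sample SD
of the nine precision measurements (3 days × 3 replicates) at the 20
µg L⁻¹ robustness level, giving 8 degrees of freedom and t_crit = 2.306,
and SE(D) = s·√(2/4) since D is a difference of two 4-run means. A
10⁴-replicate null simulation in the test suite confirms the construction
has type-I error 0.05 ± 0.01 at 8 df. The error-SD source is configurable
through the function arguments.

## The synthetic generator

Noise is placed on the **concentration scale** and pushed through the
linear response map, so estimated components are directly interpretable in
µg L⁻¹. Per level, a spiked measurement is
`L·recovery + δ_day + ε`, with `δ_day ~ N(0, σ_day)` shared by all
replicates of a day and `ε ~ N(0, σ_w)` independent — the classic one-way
random-effects layout, chosen because days are the dominant variation
source in intra-laboratory studies. Replicates are treated as independent
spikes within a day.

Default parameters reproduce the reference study's statistics:

* slopes/intercepts are the reference regression equations, used as the
  solvent curves, with matrix slope ratios 1.0423 / 1.1717 / 0.8768 /
  0.8860 (MC-LR, MC-RR, MC-YR, CYN);
* σ_w per level is the reference S_w; σ_day = √max(0,(S_B² − S_w²)/3);
* recovery fractions derive from the reference RSDs (mean measured =
  S_IP/RSD), e.g. 0.409/0.928/0.887 for MC-RR at 5/20/50 µg L⁻¹;
* blank mean/SD are chosen so the noiseless pipeline lands on the
  reference LOD/LOQ through the matrix curve;
* calibration standards get their own concentration-proportional noise,
  with CV set by the reference r² via 1 − r² = cv²·E[L²]/Var(L) over the
  12-level grid (0.8–2.6 % depending on analyte) — reusing the full
  extraction-level S_w would misstate r² by an order of magnitude, because
  calibration standards are direct extract spikes that skip the extraction
  chain.

Determinism: one global seed is split into per-analyte, per-stage
substreams (`numpy` `SeedSequence.spawn`), so a fixed seed gives
byte-identical tables and any stage re-run in isolation reproduces itself.

### What the generator does not emulate

No chromatographic peak shapes, carryover, heteroscedastic *response*
noise, calibration drift, or correlated extraction batches; replicate
independence within a day is assumed rather than known. Passing tests
therefore demonstrate that the statistics are computed correctly under the
stated variance structure — not that real extracts satisfy that structure.

One tension is intrinsic and worth knowing: a reference-faithful r² of
≈0.999 over 0.2–75 µg L⁻¹ requires roughly proportional noise, but the
lack-of-fit F test assumes homoscedastic pure error, so on simulated
bundles the LoF test rejects ≈12 % of the time per analyte even though the
generating model is exactly linear — and the ±5 % Huber band sits close to
the intercept-induced offset at the 0.2 µg L⁻¹ level for the low-slope
analytes. Occasional linearity "failures" on default bundles are therefore
expected sampling behaviour, not bugs; no homoscedastic noise level can
reproduce the reference r² while keeping the bottom calibration level
inside the Huber band.

## Problem sizes

Defaults are the study's own: 12 calibration levels × 3 replicates, 10
blanks, 3 days × 3 replicates × 3 levels, 8 Youden runs — 468 records for
four analytes. The stochastic acceptance computation averages 500
simulated precision studies; the variance-component recovery test averages
eight 200-day studies to pin the Monte-Carlo error of the day-component
estimate near 2 %; the type-I-error simulation uses 10⁴ null designs.

## Reporting

Reports carry full-precision numbers plus a `printed` sub-object rounded
to 2 decimals for comparison tooling. Provenance records SHA-256 digests
of the input table and effective config (no timestamps — identical inputs
must give byte-identical reports). Blocks whose inputs are missing are
marked `"not assessed (missing data)"`; overall verdicts are derivable
from the blocks alone.
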