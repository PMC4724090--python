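# Methods

This note records the models implemented in `radbio`, the defaults and the
reasoning behind the genuinely open design choices, and what the synthetic
cohort does and does not establish about real planning data.

## Dose-volume histograms

A DVH is stored either differentially (fractional volume per dose bin,
bins half-open `[e_i, e_{i+1})`, volumes attached to bin centers) or
cumulatively (fraction receiving at least each bin-edge dose). Volumes are
kept as fractions of the structure volume because every response formula
consumes fractional `v_i`; absolute cc values are recovered through the
optional `total_volume_cc` only where a constraint needs them. Bin edges
start at 0 Gy and are strictly increasing; min/max dose are reported at
bin-edge resolution with no extrapolation beyond the recorded bins.
`dose_at_volume` / `volume_at_dose` interpolate linearly on the cumulative
curve, and on flat segments `dose_at_volume` returns the highest dose
still meeting the requested coverage. Both metrics are exactly linear
under a uniform scaling of the dose axis — a property the synthetic
generator exploits to normalize D95% without iteration.

The default DVH resolution used by the generator is 0.1 Gy; it is
configurable (`CohortSpec.bin_width_gy`). Clinical exports rarely state
their internal histogram resolution, so metric agreement is only ever
asserted to within one bin width.

`dvh_from_dose_list` builds an *exact* DVH from an explicit voxel dose
list by giving each distinct dose its own narrow bin centred on the dose
(zero-volume filler bins pad the gaps). This makes volume-weighted
statistics on the DVH identical to brute-force per-voxel computation to
floating-point accuracy, which is how the oracle tests are constructed.

## Fractionation correction

All responses are evaluated on the 2-Gy-fraction equivalent dose
`EQD2 = D (1 + d/(α/β)) / (1 + 2/(α/β))`. Two readings of `d` are needed
in practice:

* **Per-bin DVH correction** — each bin's dose is assumed delivered evenly
  over all `n` fractions, so `d_i = D_i / n`. The map is a monotone
  increasing function of `D`, so it is applied to the bin *edges*; volumes
  carry over unchanged, conserving mass exactly on a non-uniform output
  grid.
* **Scalar dose differences** — a difference between two plans' D95%
  values is converted at the *nominal prescription* dose per fraction
  (12 Gy here), not at the difference divided by `n`; this is the only
  reading under which the published 6.5 Gy → 11.9 Gy conversion holds.

Tumor corrections use α/β = 10 Gy. Every NTCP parameter set carries its
own α/β (lung 1.3 or 3 Gy, heart 2.5 Gy, esophagus 10 or 3 Gy depending
on the model family), so the same organ DVH may be corrected several
times onto different effective-dose scales within one evaluation. No
high-dose LQ modifications (LQ-L, universal survival curve) are applied;
the validity of plain LQ at 12 Gy per fraction is a recognised open issue
in the field, and results at such fraction sizes should be read with that
caveat.

## Tumor control probability

The Poisson-LQ (Källman) form `P(D) = 2^(−exp(e·γ·(1 − D/D₅₀)))` is used
for the uniform-dose response. It satisfies `P(D₅₀) = ½` exactly and `γ`
is the normalized slope at the steepest point, matching the semantics of
the published parameter tables. The response form sits behind a named
registry (`RESPONSE_FUNCTIONS`) so alternative Poisson-type closed forms
can be added without touching call sites.

DVH aggregation uses the voxel-independence product
`TCP = Π_i P(D_i)^{v_i}`, the standard assumption when the vendor's exact
reduction rule is not documented. A mean-dose ("eud") reduction is
provided behind a method switch for cross-checks; the product rule is the
default. Probabilities are clipped to `[1e-12, 1 − 1e-12]` before
logarithms — the clip prevents underflow at very low doses and is
documented here rather than silent.

Bundled tumor parameter sets: D₅₀ = 74.5 Gy / γ = 3.5 (24-month local
control, EQD2-converted fit), 72.0 / 2.0 and 84.5 / 1.5 (24- and 30-month
local control from conventionally fractionated NSCLC data, physical dose
taken as EQD2 because those plans used 1.8–2 Gy fractions).

## Normal-tissue complication probability

**LKB**: `NTCP = Φ(t)`, `t = (EUD − D₅₀)/(m·D₅₀)`, with the generalized
equivalent uniform dose `EUD = (Σ_i v_i·D_i^{1/n})^n` (`n = 1` mean dose,
`n → 0` max dose). The probit is evaluated through the closed-form normal
CDF and cross-checked in the tests against numerical quadrature of the
probit integrand to 1e-7. The EUD power mean is computed in log space
(log-sum-exp), which keeps small `n` (serial organs) from overflowing
`D^{1/n}`. Lung pneumonitis sets: (30.5, 1, 0.3), (30.8, 0.99, 0.37) and
(24.5, 0.87, 0.18) for (D₅₀, n, m); the middle set is bundled at both
α/β = 1.3 and 3 Gy, the other two at 1.3 Gy. Esophagitis (51.0, 0.44,
0.32, α/β 10) and pericarditis (60.6, 0.64, 0.13, α/β 2.5) complete the
LKB table.

**Relative seriality**: `NTCP = [1 − Π_i (1 − P(D_i)^s)^{v_i}]^{1/s}`
with `P` the Poisson-LQ response of the organ's (D₅₀, γ). A uniform dose
at D₅₀ yields 0.5 for any `s`, and `s = 1` collapses to the plain
response — both are test anchors. Bundled sets: spinal-cord
myelitis/necrosis (68.6, 1.9, s = 4.0, α/β 3) and esophageal stricture
(68.6, 2.8, s = 3.4, α/β 3).

## Constraint checking

The rule table encodes the institutional SBRT criteria: max point dose
below 30 Gy (cord), 38 Gy (heart), 35 Gy (esophagus); absolute volume
receiving at least 32 Gy below 15 cc (heart), at least 19.5 Gy below 5 cc
(esophagus); and bilateral-lung-minus-ITV volume at 13.5 / 12.5 Gy below
1000 / 1500 cc. All inequalities are strict, following the `<` notation
of the source table, so boundary equality fails. A rule whose structure
or total volume is missing is reported `not_evaluable`, never silently
passed.

## Cohort statistics

Paired deltas are defined reference − recalculated, so positive means the
reference plan reports the higher value. Summaries are medians with
(min, max) ranges stratified by tumor location. Group comparisons use the
Kruskal-Wallis rank test with tie-corrected H; the p-value comes from the
χ² approximation, replaced by exact enumeration of all group assignments
when the pooled sample is ≤ 10 (small-sample regime where the
approximation is poorest). An all-tied input returns H = 0, p = 1 by
convention. The test is applied unpaired, as cited in the source
analysis; for genuinely paired plan data this is statistically
conservative at best, and the limitation is deliberate fidelity rather
than endorsement. Trend screens use Spearman rank correlation with a
seeded 10 000-draw permutation p-value; a constant covariate is reported
as undefined rather than zero.

## Synthetic cohort

The generator emulates the *metric* structure of a 28-patient paired
cohort (19 peripheral / 9 central tumors; PTV volumes 15.3–107.3 cc
peripheral, 19.0–144.9 cc central; 60 Gy in 5 fractions):

* The reference PTV DVH is a logistic fall-off whose steepness is set by
  requiring 95 % coverage at the prescription and ~0.5 % residual
  coverage at a maximum dose drawn from 63.7–73.2 Gy, then dose-rescaled
  so D95% equals 60 Gy *exactly* (the rescale is exact because the D95%
  lookup is linear in dose). The cold head of the curve is flattened so
  minimum PTV doses fall in a clinically plausible low-50s Gy band.
* The recalculated PTV DVH is the reference under a uniform monotone dose
  contraction lowering D95% by a draw from the per-location difference
  ranges (peripheral 0.3–6.5 Gy, central 0.6–4.4 Gy). The draw is uniform
  by default — the published summaries give only median and range, and
  uniform is the minimal assumption — with a triangular option whose mode
  sits at the published medians (1.7 / 1.0 Gy).
* OAR DVHs are truncated exponentials rescaled to a drawn mean dose, with
  dose caps below the constraint ceilings so generated plans pass the
  rule table by construction; the recalculated OAR differs by a small
  multiplicative dose perturbation (±2 % default). The mean-lung-dose
  range of 3–8 Gy is **invented**: no MLD values are published for this
  setting, and the default was chosen once as a plausible lung-SBRT band.
* One seed drives the cohort; each patient uses a substream spawned from
  (seed, patient index), so records are reproducible under reordering.
  Location assignment is deterministic from `fraction_peripheral`.

What passing the cohort-level tests shows: the pipeline propagates
coverage differences into TCP differences with the right sign and
ordering, and leaves low-dose lung NTCP essentially unchanged, under DVHs
whose summary metrics match the published ranges. What it does not show:
anything about real AAA/AXB physics (lateral scatter in low-density
media, dose-to-medium vs dose-to-water), about DVH shapes of real plans,
or about absolute TCP/NTCP calibration — the synthetic D95% differences
are drawn uniformly over the published ranges, so their *median* sits
higher than the published (skewed) medians, and absolute ΔTCP medians are
correspondingly larger. Only directions, orderings and bounds are
asserted.

## Numerical choices and degenerate inputs

* Differential volumes must be non-negative and sum to at most 1;
  response computations additionally require normalisation to 1 within
  1e-6 and raise otherwise.
* Cumulative curves must be non-increasing, start at 1 and end ≥ 0;
  conversion drops any unrecorded mass above the last edge (bounded by
  the validator).
* Probability clipping at `[1e-12, 1 − 1e-12]` before products/logs.
* `dose_at_volume` rejects fractions outside (0, 1]; `volume_at_dose`
  returns 0 above the last recorded edge.
* Empty structures (zero total volume) are a validation error, not a
  silent zero.
* Default problem sizes: the test suite and reproduction script use the
  28-patient default cohort at 0.1 Gy bins — small enough to run in
  seconds while matching the published cohort's size.

## Known limitations

* Plain LQ at 12 Gy per fraction likely overestimates fractionation
  effects; no high-dose correction is offered.
* The vendor biological-evaluation module's exact DVH reduction is
  undocumented; the product rule is an assumption, made explicit and
  swappable.
* Unpaired Kruskal-Wallis on paired data (see above).
* The synthetic generator reproduces metric ranges, not dose-calculation
  physics; conclusions about real algorithm differences require real
  paired plans, which the I/O layer (CSV schema, Eclipse-style text
  export) can ingest directly.
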