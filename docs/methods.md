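# Methods

## Scope and model

The package implements the Worldwide Bioclimatic Classification System
(WBCS) of Rivas-Martínez as a deterministic threshold hierarchy over
per-cell monthly climatologies, plus the comparison machinery for
classified grids from successive time slices.  There is no statistical
estimation anywhere: the "model" is a fixed, versioned rule table, and
the scientific content lies in computing the bioclimatic indices
exactly as defined and applying the rules in the canonical order.

### Input convention

A cell is 12 monthly mean daily-minimum temperatures, 12 monthly mean
daily-maximum temperatures (°C) and 12 monthly precipitation totals
(mm), Jan→Dec, with latitude, longitude and elevation.  Monthly mean
temperature is `Ti = (tmin_i + tmax_i)/2`.  The summer quarter is
June–August in the northern hemisphere and December–February in the
southern one, resolved by the sign of the latitude; the winter quarter
is its opposite.  No water-year option exists.

### Indices

All Table-style WBCS quantities are computed per cell: `T`, `Tmax`,
`Tmin`, the coldest month's `M` and `m` (earliest month on ties),
positive temperature `Tp` (tenths of °C) and its summer restriction
`Tps`, `Ic = Tmax − Tmin`, `It = (T + m + M)·10`, precipitation totals
`P`, `Pp` (months with `Ti > 0`), quarter sums `Ps/Pw/Pps/Ppw`, the
warmest/coldest six-month sums `Pss/Psw` and the warmest-four-month
windows `Pcm1/Pcm2/Pcm3`.  Windowed quantities use contiguous calendar
windows with wrap-around, selected by the extremal `Σ Ti` (or `Σ P`
for the driest quarter), ties broken towards the earliest start month.
The ombrothermic family divides positive precipitation by positive
temperature in tenths, scaled by 10: `Io = 10·Pp/Tp`, monthly `Iosi`,
`Ios2` over the warmest contiguous two-month sub-window of the summer
quarter, `Iosc3` over the quarter, `Iosc4` adding the immediately
preceding month, and `Iod2` over the two driest months (not necessarily
contiguous) of the driest contiguous quarter.  Cells with `Tp = 0`
carry `Io = NaN` and are routed explicitly by the classifier; no ratio
is ever formed with a zero denominator.

### Summer aridity (mediterraneity)

A summer is arid when `Ios2 ≤ 2.0` and the drought is not compensated.
Compensation fires when `Iosc3 > 2.0`, or when `Iosc4 > 2.0` in cells
that are not annually dry.  The annual-dryness gate on the `Iosc4`
branch is not printed in full in the source literature available to
this package; we gate it at `Io ≥ 3.6`, the WBCS dry/subhumid boundary,
on the reasoning that a pre-summer wet month should not rescue a cell
whose year as a whole is already dry-steppic.  All four gates are
ruleset parameters (`summer_aridity:` block) and can be overridden.

### Thermicity compensation and the 200-m reduction

`Itc = It + C(Ic)` with a stepwise-linear `C`: zero on the neutral band
`Ic ∈ [8, 18)`, negative with increasing weight towards extreme
oceanicity (tranche factors 10/20/40 per degree below 8), positive with
factors 5 then 15 per degree above 18, flat at +120 beyond `Ic = 28`.
The flat tail is inconsequential in practice because thermotypes of
cells with `Ic ≥ 21` are dispatched to the `Tp` tables.  For
macrobioclimate identification, monthly temperatures are first shifted
by `0.6 °C per 100 m × (elevation − 200)/100` and `T`, `M`, `Itc`, `Tp`
recomputed ("reduced to 200 m"); a cell at exactly 200 m is untouched.
Both the coefficient and the reference height are ruleset parameters.

### The ruleset

Every threshold lives in `src/wbcs/data/wbcs_ruleset.yaml`
(version `wbcs-2011-transcription-1.0`), a transcription of the
published WBCS synopsis: the 18-row continentality table, macro-level
`Tp` bands (polar < 380, boreal < 720, in tenths of °C, on the reduced
values; tropical gated at |lat| < 23.5°), bioclimate `Io` bands
(mediterranean hyperdesertic < 0.2 ≤ desertic < 1.0 ≤ xeric < 2.0 ≤
pluviseasonal; temperate/boreal xeric < 3.6) with the
oceanic/continental split at `Ic = 21` and hyperoceanic below 11,
thermotype `Itc` and `Tp` belts per macrobioclimate, and the shared
ombrotype scale (0.2, 0.4, 1.0, 2.0, 3.6, 6.0, 12.0, 24.0).  Interval
semantics are uniform: lower-closed, upper-open, final interval
upper-closed, so a value printed as the shared endpoint of two rows
(e.g. `Ic = 37`) belongs to the upper row.  Loading validates that
every interval list tiles its domain without gaps; classification never
hard-codes a number.

Cells in the gelid belt (`Tp < 100`) take the supersnowy ombrotype, as
the ombrothermic ratio is not meaningful there; with an undefined `Io`
a cell's bioclimate takes the wettest band of its macrobioclimate.
Tropical and polar branches are carried for completeness but are not
exercised by the mid-latitude fixtures.

### Classification order and dual routes

Per cell: indices → 200-m reduction → continentality →
macrobioclimate → bioclimate → variant (steppic tested before
submediterranean, normal otherwise) → thermotype (unreduced `Itc`/`Tp`)
→ ombrotype → isobioclimate `"<bioclimate> <thermotype> <ombrotype>"`.
Two independent code paths exist on purpose: a loop-based brute-force
route (`indices_cell` + `classify_cell`) and the vectorised production
route (`compute_indices` + `classify_grid`); the test suite asserts
exact agreement on every fixture and on random climatologies.

## Change analysis

Area tables count cells per class and period; percentages are
`count/n·100` rounded half-up (two decimals by default) and the
gain/loss column is final-period minus first-period percent, taken on
the rounded values.  Stability is the fraction of cells keeping one
class through every period; its complement is the change fraction.
Trend summaries sum the per-class deltas over declared groupings: warm
belts (infra-/thermo-/meso-), cold belts (the rest), mountain
thermotypes {Ote, Cte, Obo, Cbo, Gel}, mountain ombrotypes
{Hum, Hhu, Uhh, Ssnw}, continental bioclimates and the arid ombrotypes
{Uha, Har, Sar}.  Because "aridification" admits two readings, both are
computed: the grouped area delta of the arid ombrotypes, and the
per-cell fraction whose ombrotype moved drier between the first and
last period (likewise warmer-thermotype and more-continental
fractions).

Diversity loss uses as baseline the union of classes observed in *any*
period, with "disappeared" = baseline classes absent from the final
period; this is the only definition under which a class observed solely
in the middle period counts as lost, which matches how the loss
percentages in the source tables reconcile with their own class counts.

The isobioclimate catalog numbers all codes observed across the
supplied periods from 1, ordered by bioclimate (ruleset order),
thermotype warmest-first, ombrotype driest-first; re-running with the
periods permuted, or appending a period with no new codes, leaves the
numbering unchanged.

## Synthetic climatology

`SyntheticGridSpec` defaults encode the study conditions the pipeline
is meant for: 4569 cells on a 0.22° lattice over roughly 40.5–55.5 °N /
46.5–87.2 °E, ~590.9 km² per cell, three 25-year periods.  Monthly
temperature is a July-peaked sinusoid around an annual mean of 10 °C at
43 °N, lapsed 0.55 °C per degree northward and 0.6 °C per 100 m of
elevation, with a per-cell amplitude of 17 ± 2 °C so that plain cells
land overwhelmingly in the eucontinental band (Ic 28–46); tmin/tmax
are the monthly mean ∓/± a fixed 5 °C diurnal half-range.  Annual
precipitation rises from 110 mm at the southern edge to 380 mm at the
northern edge, times an orographic factor (+0.9 per km of elevation,
capped at 3 km); its monthly shape goes from near-uniform in the south
(aridity there is driven by summer heat, which keeps the steppic
`Ps ≥ Pw` condition satisfiable) to markedly summer-peaked in the north
(suppressing mediterraneity, so the north classifies temperate), with
mountains shifted further towards summer rain.  Eight percent of cells
are mountains (1200–3500 m), placed preferentially in the east/
south-east.  Period deltas warm summer more than winter
((0,0), (+1.2,+1.8), (+2.2,+3.2) °C) with precipitation scales
(1.0, 1.0, 0.98), emulating a high-emission mid-century trajectory
with near-stable precipitation.  Gaussian noise (σ = 0.3 °C monthly,
5 % multiplicative on precipitation) is seeded; a single integer seed
fully determines all output.

What the generator does *not* emulate: spatial autocorrelation beyond
the smooth gradients, realistic coastlines or orography, interannual
variability, and the exact class proportions of any real territory.
Passing tests on synthetic grids therefore demonstrate the correctness
and invariances of the index computations and of the rule hierarchy —
not agreement with any particular observed climatology.

`branch_fixtures` builds a 21-cell noiseless grid directly from ruleset
interval midpoints using a two-level monthly profile (a six-month warm
plateau sized to hit the target `Tp` and `Ic` exactly, precipitation
placed either away from the summer quarter, to force uncompensated
summer aridity, or mostly inside it, to suppress it, and elevation
solved so the 200-m-reduced `Tp` lands in the desired macrobioclimate
band).  The fixtures cover the 10 bioclimates, 11 thermotypes,
10 ombrotypes, 3 variants and 4 continentality subtypes reported for
strongly continental mid-latitude territories, verify themselves
against the classifier at build time, and are stable under ±1e−6
perturbations because every target sits mid-interval.

## Numerical choices and degenerate inputs

- Ties (coldest month, extremal windows, warmest summer pair, wettest
  month of the driest quarter) always resolve to the earliest
  candidate, identically in both code routes.
- `Tp = 0` ⇒ `Io` undefined (NaN), never infinity; the classifier
  branches explicitly (wettest bioclimate band, gelid thermotype,
  supersnowy ombrotype).  NaN comparisons are masked, never relied on.
- Negative `Ic` and values below a table's domain raise; values above
  the last finite bound clamp into the final (upper-closed) interval.
- Percent rounding is decimal half-up, not banker's rounding, to match
  conventional table formatting; counts are exact integers.
- Classification is pure: identical input bits give identical labels.

## Problem sizes

The default test suite runs at reduced sizes (fixtures of 21 cells,
synthetic grids of 150–400 cells) chosen because the classifier is
exactly scale-free — every property holds per cell — while the
acceptance script and the runtime check exercise the full
3 × 4569-cell study size, which classifies in well under a second on
one CPU.

## Known limitations

- The ruleset is a transcription of the published WBCS synopsis; a few
  rarely exercised belts (polar thermotypes, tropical bioclimates) are
  carried as placeholders for completeness and should be re-checked
  against the primary reference before use in those zones.
- Sub-monthly structure (frost days, precipitation intensity) is
  outside the WBCS inputs and hence out of scope.
- The `Iosc4` annual-dryness gate (`Io ≥ 3.6`) is a documented
  interpretation; territories near that boundary may flip between
  mediterranean and temperate under a different gate.
- No bias correction, downscaling or reprojection is performed; inputs
  are classified as given.
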