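# Methods

## The reporting cascade and its generative model

`hmisdq` treats a routine HMIS as a five-stage cascade per (facility,
indicator, month): true client events → register rows → tally marks →
facility monthly report → district report copy → DHIS2 entry. The
simulator draws true counts and then applies, stage by stage, the error
processes that field reviews of paper-based systems describe.

**True events.** Counts are Poisson with mean `mean_monthly_volume`,
resolvable per (service area, facility level). Poisson was chosen for
simplicity; configurable over-dispersion is a non-goal. The typical preset
scales a per-service-area base volume (OPD 200/month at a dispensary, down
to 15 for labour-and-delivery) by a level multiplier (health centre ×2.5,
hospital ×6).

**Recording.** The register captures each event independently with
probability 1 − `p_register_miss`; the tally sheet with
1 − `p_tally_miss`, plus Poisson over-marking at `tally_overmark_rate`
extra marks per true event. Both are binomial thinnings, so pooled ratios
recover 1/(1 − p) analytically — the basis of the parameter-recovery
tests.

**Compilation.** Each monthly report is compiled in one of three modes
drawn from `compile_mode_probs`: a copy of the tally totals, a register
recount, or an inflated guess (register recount × `report_inflation_factor`,
rounded half away from zero — counts must be integers and the rule must be
fixed for determinism). The error-free configuration compiles from tally
totals, so that with only register thinning active, Diff1 and Diff2 both
equal 1/(1 − p_register_miss).

**Transmission and entry.** The district copy equals the facility report
unless lost (`p_transmission_loss`). Before DHIS2 entry the value may be
revised (× `correction_factor` with probability `p_district_correction` —
an *undocumented* correction, visible only as Diff4/Diff5 ≠ 1) and may
suffer a keystroke error (`p_entry_error`: one decimal digit replaced by a
uniformly different one).

**Tool absence.** With probabilities `p_*_absent`, a register, tally sheet
or report form cannot be located for a (facility, service area, month).
Absence masks what the review team sees; it does not change the values
propagating downstream — reports routinely exist without locatable
register or tally support. The exceptions are structural: an absent
facility report suppresses the district copy and DHIS2 entry, and a
transmission loss suppresses both district and DHIS2.

**Granularity of draws.** Monthly decisions — tool absence, compile mode,
transmission loss, district correction — are drawn once per (facility,
service area, month), because registers, tally sheets and reports are
physical per-service-area monthly artefacts; event-level noise (misses,
over-marks, keystrokes) is drawn per indicator row.

**Seeding.** One global seed expands into per-facility substreams keyed by
a CRC32 of the facility id, with disjoint stream tags for true events, the
journey and register rows. Adding facilities therefore never reshuffles
the draws of existing ones, and identical (seed, params) give bit-identical
datasets.

## Metrics

**Availability.** A tool-month counts as observed when at least one row
for that (tool, facility, service area, month) is present. Rates are
computed per facility first, then summarised across facilities per stratum
(median, p25, p75, range = p75 − p25). The quantile convention is linear
interpolation between closest order statistics (`numpy.percentile`'s
default), exposed as a `method` argument since no single convention is
universal. Units with zero expected tool-months are excluded with a logged
warning. Display rounding is one decimal for rates; internal computation
is unrounded.

**Availability categories.** low [0, 25), average [25, 50), high [50, 75],
very high (75, 100]. The published scheme leaves the 25/50/75 boundaries
ambiguous; this closure assigns each boundary to the band above it except
75, which stays in *high* because *very high* is defined strictly above
75. The four bands exactly partition [0, 100].

**Completeness.** Blank means the empty string after whitespace trimming.
Code comparison is case-sensitive, deliberately: a lone `N` means "yes"
(Ndiyo) under the Kiswahili convention and "no" under English usage, so
case must be preserved rather than normalised away. One conditional rule
ships by default — severity is required only when a diagnosis is recorded
— expressed as a `required_if` reference to a sibling field.
Invalid-value checks apply to any non-blank value regardless of
requiredness. A row is adherent iff it has no violations.

**Accuracy.** Each DR is the ratio of pooled sums over the
facility-months where *both* sources are present (pairwise-complete
pooling); absence is never imputed as zero. Pooled sums, rather than means
of per-row ratios, are robust to zero-count months and match the recount
semantics of register audits; they also make stratified results exactly
recombinable (yearly sums add to the pooled total). Degenerate cases are
flagged, not silently categorised: 0/0 → `undefined_0_over_0` (excluded
from category tallies, still counted in `n_pairs`), positive/0 →
`infinite_over` (categorised as extremely over-represented), no
pairwise-complete rows → `no_pairwise_rows` with `n_pairs = 0`.

**Match categories.** matched [0.95, 1.05]; moderately matched
[0.75, 0.95) ∪ (1.05, 1.25]; moderately under [0.5, 0.75); moderately over
(1.25, 1.5]; highly under [0, 0.5); highly over (1.5, 2]; extremely over
(2, ∞). The published intervals double-assign 0.75 and leave 0.5
unassigned; this closure gives 0.75 to moderately-matched and 0.5 to
moderately-under, making the seven bands an exact partition of [0, ∞).
Reported DRs are rounded to two decimals in outputs only.

**Transmission-phase pairs.** Diff3–Diff5 are assigned as district/facility
copy, DHIS2/district copy and DHIS2/facility copy: the three ordered pairs
spanning exactly the transmission segment, which separates documented
corrections (visible in Diff3) from undocumented ones (Diff4/Diff5).

## Default study conditions

The default roster is 115 facilities in 11 districts (5 urban, 6 rural),
with 67 dispensaries, 36 health centres and 12 hospitals; ownership is 81
government / 23 faith-based / 11 private (a typical public-sector-dominated
mix; level totals are matched exactly, labels shuffled). Service-area
offers are Bernoulli at the observed facility shares (OPD 114/115, IPD
43/115, …), with OPD forced on if a draw would leave a facility offering
nothing. The catalogue holds 34 indicators (OPD 5, IPD 4, ANC 8, PNC 6,
LnD 2, FP 6, PITC 3) with age-split and complexity flags. The review
window is 2014-01 to 2017-09 (45 months); the detailed-review subset is
the fixed 12 months 2014-10..12, 2015-07..09, 2016-04..06, 2017-01..03 —
four quarters at equal six-month spacing.

The `typical` preset (register miss 0.35, tally miss 0.15, over-marking
0.05, compile modes 0.6/0.2/0.2 with inflation ×3, absences 0.09/0.25/0.13,
transmission loss 0.35, correction 0.15 × 1.2, entry error 0.02) is
*illustrative*: no field study publishes its error phenomena as generative
rates, so these were set once to reproduce the qualitative regime —
registers the best-kept tool, tally sheets the worst, reports
over-represented several-fold in bad compile draws, about a third of
reports unlocatable at district, and a stable transmission phase with a
small undocumented-correction signal (Diff4 ≈ 1.04 > Diff3 = 1).

## What the synthetic data does and does not show

The generator reproduces the *structure* of a reporting cascade — paired
sources, presence patterns, pooled-ratio signatures — so passing tests
demonstrate that the metrics measure what they claim and recover known
parameters. It does not emulate longitudinal client identity, seasonality,
clinically coherent diagnoses, inter-indicator correlation, or
facility-specific behaviour drift; conclusions about any real system
require real extracts, which the I/O layer accepts as long-format CSV.

## Numerical choices and degenerate inputs

Half-away-from-zero rounding wherever a factor produces a non-integer;
keystroke errors clip implicitly at zero (a digit substitution of a
nonnegative integer stays nonnegative); empty count sets and empty
summaries raise rather than return NaN; malformed CSVs are rejected with
row-numbered diagnostics (unknown source label, non-binary presence flag,
negative or fractional value, value without presence). Test problem sizes
were chosen as the smallest with enough Monte-Carlo resolution for
3-standard-error recovery checks (≥ 1,000 pairs for ratio recovery,
≥ 10,000 rows for rate recovery).

## Known limitations

Error processes are independent across facilities and months — no
contagion of bad practice, no improvement trends (the year-on-year
improvement a real system shows would enter through time-varying
parameters, which the dataclass does not yet support). District
corrections are multiplicative and unsigned. Timeliness (submission dates)
is out of scope: the data model records presence, not dates.
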