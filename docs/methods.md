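# Methods

## Pipeline model

The package models the chain from a targeted GC-MS/MS measurement to a
population-level inhalation risk statement.

**Quantification.** Each record is one compound in one physically separated
cigarette part (tobacco, filter tip, or one flavor capsule), extracted in
acetone (25 mL for a 0.25 g tobacco/filter aliquot, 10 mL for a whole
capsule). The extract level `L` (ng/mL) read off the calibration curve is
converted to a matrix concentration `L × dilution × V / W` (ng/g) and then
to a per-part content `concentration × W / 1000` (µg); the weight cancels,
so contents are robust to aliquot-weight uncertainty. Extracts whose level
falls above the calibration range are modelled as re-analyzed after decade
dilution, with the dilution factor restored multiplicatively — linear in the
level, which is exactly what re-injection of a diluted extract does.

**Censoring.** Every measurement carries a three-way status: `quantified`
(level ≥ LOQ), `below_loq` (LOD ≤ level < LOQ) or `not_detected`, and this
distinction survives CSV round-trips as a literal status column. For
exposure estimation, below-LOQ records are substituted by the LOQ-equivalent
content (the LOQ level pushed through the two unit equations at dilution 1)
— a deliberately conservative upper-bounding convention — while non-detects
contribute zero and compounds detected in no product at all are excluded
from exposure estimation entirely. Substitution is monotone: it can only
raise totals, means and maxima (property-tested).

**Aggregation.** Per-cigarette totals sum tobacco + filter tip + every
capsule; cigarettes with two capsules sum both, which is why the maximum
per-cigarette total can exceed the sum of single-part maxima across a study.
The average can be taken over detecting cigarettes only (default) or over
all cigarettes: the published summary averages cannot be reconstructed
unambiguously from the published per-part tables, so the denominator is an
explicit, configurable policy rather than a hard-coded guess.

**Exposure.** `EC = C·N·ED·EF / (IR·AT) / 1000` mg/m³ assumes complete
transfer of the flavor load to the mainstream smoke (no pyrolysis,
mouth-spill, or filter-retention corrections — a deliberate overestimate in
the absence of transfer data). Defaults describe an adult Korean smoker:

| parameter | symbol | default | unit | origin |
|---|---|---|---|---|
| cigarettes per day | N | 13.2 | 1/day | national health survey average |
| smoking onset age | — | 13.2 | years | survey average |
| life expectancy | — | 82.7 | years | 2018 national statistic |
| exposure duration | ED | 69.5 | years | life expectancy − onset |
| exposure frequency | EF | 365 | days/year | daily smoking |
| inhalation rate | IR | 14.25 | m³/day | adult long-term average |
| averaging time | AT | 25,367.5 | days | ED × 365 |

AT is carried in **days**. Exposure-equation write-ups sometimes label AT in
hours, but the defining relation AT = ED × 365 and the published value
25,367.5 are in days, and only the day convention makes ED·EF/AT
dimensionless (= 1 under the defaults, so EC reduces to C·N/IR µg/m³). The
µg→mg division by 1000 happens at the EC step because contents are carried
in µg and exposures reported in mg/m³.

**Risk.** RCR = EC / DNEL, using long-term systemic inhalation DNELs for the
general population (the most conservative chronic choice). Compounds without
a registered DNEL are skipped — there is nothing to characterize against.
Report rendering fixes exposures at five decimal places and RCRs at two
significant figures in scientific notation, so rendered tables are
bit-comparable.

**Rounding artifacts in published anchors.** When validating against a
published risk table, only rows whose printed content, exposure and RCR are
mutually consistent at printed precision are used as anchors. Rows computed
from unrounded intermediates break at printed precision (e.g. a printed
exposure of 0.00005 mg/m³ against a DNEL of 1.74 yields RCR 2.9 × 10⁻⁵, not
the printed 2.6 × 10⁻⁵, because the true exposure behind it was ≈0.000046).
The acceptance tests document these rows as rounding artifacts instead of
forcing agreement.

## Method validation

Calibration is unweighted OLS with a free intercept — the simplest model
consistent with a reported R² criterion — gated at R² > 0.999. LOD and LOQ
are 3× and 10× baseline noise divided by slope, so LOQ/LOD ≡ 10/3; for
tobacco and filter-tip matrices the same construction on a spiked blank
gives the MDL. The baseline noise is a user-supplied scalar (RMS of a blank
baseline): chromatogram processing is out of scope. Recovery is
100 × measured/spiked per spike level (acceptable ≈ 80–110%), precision is
the sample-SD RSD gated at < 10%. The mg/kg ↔ percent conversion
(1 mg/kg = 0.0001%) supports checks against leave-on cosmetic limits
(0.0002%).

## Comparison battery

Contents are right-skewed and heavily censored, so group comparisons are
rank-based. A Shapiro–Wilk gateway (delegated to scipy) motivates the
nonparametric route. Kruskal–Wallis (tie-corrected, chi-square p) compares
the three parts; an all-equal sample is defined to give H = 0, p = 1.
Dunn's post hoc z-tests on pooled mean ranks carry the Σ(t³−t)/(12(N−1))
tie correction and Bonferroni multiplication by k(k−1)/2 capped at 1
(implemented in-package; no established implementation is available in the
dependency set). Mann–Whitney U compares capsule against non-capsule
cigarettes, using the exact null distribution when min(n, m) ≤ 8 without
ties and the tie/continuity-corrected normal approximation otherwise — a
deterministic, documented switch. By default the tests rank detected values
only, matching detected-only summary semantics; substituted LOQ values can
be included instead. All tests are validated against brute-force
enumeration or hand-computed rank formulas, not against published
statistics: the per-cigarette raw data behind those were never released.

PCA uses unit-variance scaling with non-detects encoded as 0 before scaling
(a non-detect has no defined content; zero is the natural fingerprint
encoding and matches common chemometric practice), with constant columns
left centered only.

## Synthetic study generator

The generator emulates the study design: 24 non-capsule and 30 capsule
cigarettes, 40% of capsule cigarettes carrying two capsules (42 capsules in
total — the published capsule count over 30 capsule cigarettes implies 12
two-capsule products). Contents are log-normal per compound × part ×
cigarette class, parameterized by moment matching (σ² = ln(1 + CV²),
µ = ln(mean) − σ²/2) from the published class-wise means, SDs and detection
counts. The class-aware design matters: pooled per-part distributions mix
two very different classes (e.g. tobacco menthol: ≈0.75 µg in non-capsule vs
≈337 µg in capsule cigarettes), and a single log-normal fit to the pooled
moments would need σ ≈ 3, making distributional functionals practically
inestimable at any realistic study size. Cells observed once, or with a
printed SD of zero, get a small default CV (0.2) instead of a degenerate
law.

Instrument levels are back-computed from contents (level = content × 1000 /
volume), censored against the per-matrix LOD/LOQ and decade-diluted when
above the calibration range, so generated tables exercise the same
validation and quantification code paths as real data. The whole-capsule
sample weight defaults to 0.021 g, back-derived from the published
mg/kg-vs-µg pair for methyl eugenol in capsules (1.0 mg/kg ↔ 0.02 µg;
15.0 mg/kg ↔ 0.32 µg); contents are weight-independent, so this only
affects reported matrix concentrations.

Because censoring is part of the generative law, the config implies
closed-form *observables*: the detectable frequency p·(1 − F(LOD-content))
and the LOQ-truncated quantified mean E[X | X ≥ LOQ-content]
(`cell_observables`). Parameter-recovery tests compare empirical values to
these implied observables on a 10,000-cigarette study, restricted a priori
to cells whose predicted 3σ Monte-Carlo error fits inside the 5% band —
an estimability screen computed from the configuration alone.

What the generator does **not** emulate: brand-level correlation between
compounds (cells are sampled independently, so real covariance structure —
e.g. menthol-heavy brands being heavy in the capsule *and* the filter — is
only partly reproduced through the class split), per-brand capsule counts,
recipe-driven multimodality, instrument drift, or chromatographic
interferences. Passing tests therefore demonstrate that the pipeline
arithmetic, censoring policy and statistics behave correctly on
study-shaped data; they do not validate the log-normal assumption against
real cigarettes.

Per-compound detection limits are not published (only method-wide ranges),
so the bundled limit table is a synthetic stand-in spanning those ranges,
clearly labelled, and overridable by users with their own validated limits.

## Numerical and interface choices

- CSVs are UTF-8, comma-separated, `.` decimal, one record per (cigarette,
  part, capsule index, compound); floats are written at full precision and
  read back with round-trip parsing, so `read(write(x)) == x` exactly.
- Record invariants are enforced at construction (pydantic/dataclass
  validation) and again against the compound's matrix limits when reading
  tables; errors cite 1-based file line numbers.
- CAS registry numbers are check-digit validated.
- Degenerate inputs fail loudly: empty groups, constant calibration
  responses, zero-mean RSD, onset age ≥ life expectancy, nonpositive DNEL,
  duplicate (cigarette, part, capsule, compound) rows.
- Test problem sizes: the null-calibration simulation uses 10,000
  Kruskal–Wallis draws on three groups of 20; parameter recovery uses a
  10,000-cigarette study; enumeration oracles cover all instances up to 10
  observations. These sizes give comfortable Monte-Carlo margins for the
  bands they check.

## Known limitations

- The exposure model's complete-transfer assumption overstates systemic
  dose by design; RCRs are upper bounds under the stated smoking pattern.
- LOQ substitution biases means upward for heavily censored compounds; the
  substitution-free detected-only summaries are reported alongside.
- The averaging-denominator ambiguity (detected vs all cigarettes) changes
  average-content RCRs by the detection-rate factor; both policies are
  exposed, neither is claimed authoritative.
- Published pairwise "mean difference" columns in post hoc tables use an
  unstated standardization; the package reports raw mean-rank differences
  and z statistics instead and does not attempt to match those numbers.
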