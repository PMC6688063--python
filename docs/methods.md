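# Methods

## The filtering model

The pipeline judges one unit of evidence at a time: a `(site, individual,
caller)` record carrying brain and blood ref/alt read counts harmonized from
that caller's VCF dialect. The seven criteria (depth ≥ 50× in both tissues of
the pair; ≥ 5 brain alt reads; AAF < 20% in both tissues; brain/blood AAF
ratio outside [0.8, 1.2]; exact-test p < 0.05; non-recurrence across the
cohort; ≥ 3-of-4 caller consensus) encode three distinct error models:

* **germline leakage** — a heterozygote sits near AAF 0.5 in both tissues;
  the 20% AAF ceiling removes it regardless of capture imbalance, because
  both tissues would have to be deflated below 20% simultaneously;
* **shared artifacts** — mapping or capture errors appear at similar
  frequency in both libraries; the ratio window and the exact test both
  target this, the test adding depth-awareness at very low counts;
* **caller-private noise** — each caller's model fabricates its own
  low-frequency candidates; consensus voting suppresses these without any
  per-caller tuning, which is why caller FILTER values are recorded but never
  used to reject (rare variants at ~700× fall outside the callers' tuned
  regime, and their default filters mark most true rare events).

All criteria are evaluated on every record, with no short-circuiting, so the
verdict table doubles as an attrition audit. Tie handling follows the
criteria as stated: "minimum 5" is ≥ 5, "< 20%" and "p < 0.05" are strict,
and the ratio exclusion window is the closed interval [0.8, 1.2]. A blood AAF
of exactly 0 gives ratio +∞, which passes criterion iv: absence in blood is
the strongest somatic evidence, and the window exists to remove *shared*
signal. A 0/0 ratio is undefined and fails (it cannot arise after criterion
ii anyway).

### Exact test convention

Criterion v is a Fisher exact test on the 2×2 table [[brain_alt, brain_ref],
[blood_alt, blood_ref]], computed by enumerating the hypergeometric support.
The default sidedness is the minimum-likelihood two-sided convention (sum of
all tables, with the observed margins, whose point probability does not
exceed the observed one within relative tolerance 1e−7). This choice is
deliberate: on the bundled reference counts, the "double the one-sided p"
convention would push two sites (chr2:128054946, chr8:27316070) to p ≈ 0.06
and reject them, whereas the minimum-likelihood convention — which is also
what `scipy.stats.fisher_exact` and R's `fisher.test` implement — passes all
eleven. A one-sided brain-enrichment alternative is available via
`FilterThresholds(fisher_sidedness="one_sided_brain_enriched")`. The p-value
is clamped to (0, 1]. No multiple-testing correction is applied, matching
the fixed per-site α of the original design.

### Recurrence

"Recurrent" is read as: the same SNV passes criteria i–v in more than one
individual (`recurrence_max_individuals=1`, configurable). Recurrence is
counted on criteria-i–v-passing verdicts *before* consensus; a recurrent key
fails criterion vi in every individual. A true somatic event is private to
one person, so cross-individual recurrence at ultra-deep coverage flags a
position-specific systematic artifact.

### Consensus

Support = number of callers whose full verdict (i–vi) passes. ≥ 4 ⇒
`tissue_specific`, ≥ 3 ⇒ `possible`, else `rejected`. Classification is
monotone in support by construction.

## VCF harmonization

Count extraction per dialect uses each caller's canonical fields: the AD
(ref, alt) allelic-depth pair for the MuTect callers and the uniform
synthetic dialect; RD/AD for Varscan2; tier-1 base counts (`AU`/`CU`/`GU`/
`TU`) for Strelka2. Tumor/normal columns are identified by sample name
(BRAIN/TUMOR vs BLOOD/NORMAL, case-insensitive), overridable explicitly.
Multiallelic records and indels are skipped and counted, not split — the
analysis is SNV-only and the MuTect comment exclusion flags triallelic sites
regardless. Internally all positions are 1-based; BED masks are 0-based
half-open, converted only at the mask boundary (a call at position *p* is
masked iff some interval satisfies start ≤ *p*−1 < end). Comment matching is
case-insensitive substring with spaces and underscores interchangeable,
since caller versions vary in formatting.

Note on printed AAFs: a few published table cells are not equal to
alt/(ref+alt) of their own printed counts (e.g. one MuTect2 row printing
1.2% where the counts give 1.4%), presumably because a caller-reported
frequency was printed. The datasets module therefore exposes both the
printed and the count-derived values; the pipeline always derives AAF from
counts.

## ddPCR quantification

Copies per droplet per channel: λ = −ln(1 − p̂) with p̂ = positives/accepted
over wells merged by summing droplet counts. Saturation (p̂ = 1) raises an
error advising dilution rather than returning a censored value. Fractional
abundance FA = λ_m/(λ_m + λ_w); its 95% CI comes from the delta method,
var(λ̂) ≈ p̂/(N(1−p̂)) per channel propagated to the ratio and clipped to
[0, 1]. The instrument vendor's CI algorithm is proprietary, so the CI is
asserted by calibration rather than equality: at the validated assay's scale
(true FA 0.39%, ~45,700 copies in two wells) the interval covers the truth
in ≈ 94% of 1000 seeded replicates. Droplet volume defaults to 0.85 nL (the
QX200 partition volume; the conversion to copies/µL is linear so any
calibrated value can be substituted). "1 in X" is round-half-away-from-zero
of 1/FA, which reproduces all printed reference values (256, 943, 1031).
Mass arithmetic uses 6.6 pg per diploid genome (truncating division for
whole cells, e.g. 4 µg → 606,060 cells) and 3.3 pg per haploid genome;
instrument-reported "total haploid copies" are measured quantities and are
not recomputed from mass (the reference values differ from the mass-derived
expectation by ~0.04%).

## The synthetic cohort generator

The generator emulates the *statistical* structure of the study, not its
reads:

* **cohort**: 14 pairs by default (4 EOAD, 4 LOAD, 6 controls — the retained
  pairs of the original design);
* **depth**: per-individual mean ~ Normal(698, 23·√14) (the published
  mean ± SEM of coverage, converted to an across-individual SD), then
  per-site negative binomial with CV 0.15 around that mean, floor 1;
* **somatic variants**: 2 per AD individual by default (11 variants across 5
  AD pairs ≈ 2), uniform true AAF in [0.004, 0.03], blood AAF exactly 0,
  positions unique cohort-wide (somatic events are private; colliding plants
  would be eaten by the recurrence criterion);
* **germline heterozygotes**: 60 per individual drawn from a shared
  polymorphic-position panel (~human heterozygosity, one het per ~1.7 kb,
  over the default 100 kb region), true AAF 0.5 in both tissues;
* **capture allelic imbalance**: a per-site gamma factor *b* with mean 1 and
  SD `imbalance_strength` (default 0.5) multiplies the alt allele's capture
  efficiency in brain: p′ = b·p/(b·p + 1 − p). Because p′ is concave in *b*,
  a unit-mean factor still deflates the mean brain AAF (Jensen), reproducing
  the reference-ward brain imbalance seen in capture libraries (blood 30–40%
  het AAFs reading ~20% in brain in the tail). The distribution's shape is a
  modeling choice; only its qualitative effect is asserted.
* **noise**: independent per-read error (default 2×10⁻⁴) adds alt reads in
  unaffected tissue; strand structure is not modeled (strand-bias handling
  belongs to the callers, which are out of scope);
* **callers**: each detects a site with a logistic probability in the
  realized brain alt count (midpoints near the 5-read floor: 4.5–9 reads),
  never reports alt-free sites, fabricates private false positives at a
  per-Mb rate (ordered MuTect2 > Varscan2 > Strelka2 > MuTect1 to mirror the
  relative raw-call yields of the four callers) with 3–8 alt reads, and
  injects FILTER comments (benign ones like `t_lod_fstar` frequently,
  excludable ones like `clustered_events` rarely). Profiles are configurable
  and are not claimed to match the real callers quantitatively.

The default region is 100 kb — a deliberate scale-down of the 2.86 Mb
capture design chosen so the full generate→emulate→filter→evaluate chain
runs in seconds; the full size is one parameter away. Everything is
deterministic under `seed` (position allocation, per-individual draws and
per-caller draws use separate spawned streams).

**What passing tests show — and don't.** The synthetic tests establish that
the filter logic is correct against known truth: noise-free perfect-caller
runs recover exactly the detectable planted set; germline heterozygotes are
rejected by the AAF ceiling in > 99.9% of deep sites; planted AAFs are
re-estimated with unit slope; single-caller candidates dominate consensus
candidates under defaulted false-positive profiles. They do not establish
sensitivity or FDR on real tissue, where error modes (FFPE-like damage,
mapping artifacts, strand bias, index hopping) are structured rather than
independent per read, and where the callers' true sensitivity curves are
unknown. Recovery numbers from the generator are calibration checks, not
performance claims.

### Recovery metrics

A planted somatic site counts as *detectable* iff its realized counts pass
criteria i–iii; sensitivity is computed over detectable sites only (an
undetectable plant is a statement about sampling, not about the pipeline)
and is undefined (None) when no plant is detectable. FDR is the fraction of
possible/tissue-specific calls not matching a planted somatic site, 0 when
there are no positive calls.

## Numerical and degenerate-input choices

* AAF at zero total depth is an error, not 0 — callers cannot emit such
  records, and silence would hide upstream corruption.
* Candidate tables format AAF as percent with one decimal (matching the
  reference table layout) but round-trip the integer counts losslessly.
* BED masks are merged at load; an interval with start ≥ end is a format
  error naming the line. Chromosome names absent from the mask produce a
  warning and no masking for those calls (naming-convention mismatches are
  surfaced, never guessed).
* The hypergeometric enumeration runs on the full support of the observed
  margins; at 700× with ≤ ~20 alt reads the support has ≤ ~21 points, so
  exactness costs nothing.

## Known limitations

* Consensus assumes the four call sets are independent given truth; real
  callers share the alignment, so their errors correlate and 3-of-4 support
  is weaker evidence than the synthetic model implies.
* The recurrence rule with threshold 1 is aggressive for true hotspots; it
  is configurable but defaults to the strictest reading.
* The ddPCR CI is a large-count normal approximation; with very few positive
  droplets (near the 3-droplet QC floor) its coverage degrades, which is why
  the QC verdict travels with every quantification result.
* The generator plants at most one variant class per position and does not
  simulate indels, multiallelic sites, or read-level artifacts.
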