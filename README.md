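# somatosift

Detection of rare tissue-specific somatic single-nucleotide variants (SNVs)
from paired ultra-deep targeted sequencing, plus droplet digital PCR (ddPCR)
rare-event quantification.

## The problem

Post-zygotic (mosaic) mutations can be confined to one tissue — e.g. present
in a fraction of temporal-cortex cells of an Alzheimer disease patient but
absent from the same person's blood. At ~700× bulk coverage such variants sit
at 0.4–3% alternative allele frequency (AAF), below the operating point of
somatic callers tuned for ~100× tumor/normal data: their default filters
discard most true rare events, while raw call sets are dominated by
caller-specific false positives. `somatosift` implements the downstream
strategy that deals with both: keep *all* raw calls from four callers
(MuTect1, MuTect2, Strelka2, Varscan2, run with brain as "tumor" and blood as
"normal"), harmonize them, apply one explicit paired somatic filter, and
demand cross-caller consensus.

For one individual's site with brain counts (ref *b_r*, alt *b_a*) and blood
counts (*n_r*, *n_a*), with AAF = alt/(ref+alt), a call passes when:

1. depth ≥ 50× in both tissues;
2. *b_a* ≥ 5;
3. AAF < 20% in both tissues (removes germline heterozygotes);
4. AAF_brain/AAF_blood ∉ [0.8, 1.2] (removes shared signal; the ratio is +∞
   when the blood AAF is 0, which passes);
5. Fisher's exact test on [[*b_a*, *b_r*], [*n_a*, *n_r*]] gives p < 0.05
   (minimum-likelihood two-sided convention by default);
6. the site is not recurrent across individuals (recurrence across the
   cohort marks a systematic artifact);
7. consensus: ≥ 3 of 4 callers ⇒ *possible* tissue-specific variant,
   4 of 4 ⇒ *tissue-specific*.

Records carrying the MuTect comments `clustered events`, `poor mapping
region`, `nearby gap`, `triallelic sites` or `strand artifact` and sites in
segmental-duplication regions (BED mask) are excluded up front; all other
caller FILTER values are recorded but never used to reject.

Validation-side, the ddPCR module implements merged-well rare-event Poisson
quantification: λ = −ln(1 − positives/accepted) copies per droplet per
channel, fractional abundance FA = λ_mut/(λ_mut + λ_wt) with a delta-method
95% CI, acceptance QC (≥3 positive droplets, ≥10,000 accepted droplets per
well, ≥10 ng input) and copy/mass arithmetic (6.6 pg per diploid genome).

Because raw sequencing data for such cohorts are typically not shareable, the
package ships a synthetic paired-cohort generator (`somatosift.synthetic`)
that emulates the study design — negative-binomial ultra-deep depth, rare
brain-confined somatic variants, germline heterozygotes with capture allelic
imbalance, sequencing noise, and per-caller sensitivity/false-positive
profiles — with a ground-truth table, so the whole pipeline is testable and
calibratable end to end.

## Worked example

The package bundles the published validation cohort (11 brain-specific SNVs
with per-caller brain/blood counts). Running the filter + consensus over it:

```python
import somatosift as ss
from somatosift.datasets import reported_callsets, individual_groups
from somatosift.report import summarize

results, summary = ss.run_pipeline(reported_callsets())
for r in results:
    print(f"{str(r.key):>24}  {r.individual:>6}  "
          f"{r.classification:<15} {len(r.supporting_callers)}/4")
print(summary["classes"])
print(summarize(results, individual_groups()))
```

prints

```
       chr1:207351003C>A     1/2  possible        3/4
       chr1:207461994C>T   19/20  tissue_specific 4/4
       chr1:207550332T>C   27/28  possible        3/4
       chr1:227069718G>T   27/28  possible        3/4
       chr2:128054946G>T   25/26  possible        3/4
        chr8:27316070C>A   11/12  possible        3/4
      chr11:121250381G>T   25/26  possible        3/4
      chr11:121363100C>A   11/12  possible        3/4
      chr11:121401561A>G   27/28  possible        3/4
       chr21:27421506G>T   11/12  possible        3/4
       chr21:27489758G>A   11/12  possible        3/4
{'tissue_specific': 1, 'possible': 10, 'rejected': 0}
         tissue_specific  possible  rejected  candidates
group
EOAD                   0         9         0           9
LOAD                   1         1         0           2
control                0         0         0           0
```

i.e. one SNV (chr1:207461994C>T, upstream of *CD55*) is supported by all four
callers and classified tissue-specific; the ten others are possible
tissue-specific variants with 3/4 support; nine candidates are in early-onset
and two in late-onset patients, none in controls.

A ddPCR assay of two merged wells at that variant's scale:

```python
from somatosift import ddpcr

assay = ddpcr.DdpcrAssay(
    "brain_19_20",
    [ddpcr.DdpcrWell("A1", 16000, 90, 12000),
     ddpcr.DdpcrWell("A2", 15500, 88, 11800)],
    input_mass_ng=151,
)
q = ddpcr.quantify(assay)
```

yields `FA = 0.40% (95% CI 0.34–0.46), 1 in 250, ~44,600 total copies, QC
pass` — a mutant allele carried by roughly 1 in 250 haploid genomes.

## Command line

```sh
somatosift simulate --config sim.yaml --seed 42 --out synthetic/
somatosift filter   --cohort synthetic/cohort.yaml --segdup mask.bed \
                    --out candidates.tsv --log run.log
somatosift evaluate --results candidates.tsv --truth synthetic/counts.tsv
somatosift ddpcr    --wells wells.csv --out quant.tsv
somatosift report   --results candidates.tsv --cohort synthetic/cohort.yaml \
                    --out summary.tsv
```

`cohort.yaml` maps individuals (with EOAD/LOAD/control group labels) to
per-caller VCF paths; thresholds are overridable there or by flags.

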