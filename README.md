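# iciqtl

Host-genetics analysis of immune-checkpoint-inhibitor (ICI) response in
mouse tumor models. The package quantifies per-animal response to anti-PD-1
therapy from serial tumor-volume measurements, estimates how heritable that
response is across a Collaborative-Cross-derived strain panel, maps the
responsible loci over founder haplotypes (including epistatic interactions),
and computes tumor-microenvironment statistics that discriminate responders
from non-responders. A synthetic-study generator with planted ground truth
makes every stage testable end to end.

## Who it is for

Groups running syngeneic immunotherapy studies across genetically diverse
hosts — CC or CC-derived F1 panels (CCF1), or backcross designs in which
each mouse is genetically unique (CCF1N1) — who need a reproducible pipeline
from caliper measurements to QTL calls and microenvironment biomarkers.

## The statistics at the core

**Rate-based tumor/control (RTC).** Tumor volume is assumed to grow
exponentially, so a line is fit to log10 volume against day for each tumor,
using measurements from the first dosing day onward and above the detection
limit. The per-mouse response statistic is

    RTC_i = 10^((b_i − μ_C) · 21)

where `b_i` is mouse *i*'s slope and `μ_C` the mean slope of the same line's
isotype-control arm: the fold-change in volume after 21 days relative to the
control-arm expectation. RTC < 1 means inhibition. Tumors that grew once and
regressed below detection receive the arm-wise 10th-quantile slope; tumors
that never grew (CR\*) are handled by an exact-binomial enrichment test per
line whose Z-score is blended with the line's mean log RTC (weights 20/80)
into a combined response trait.

**Broad-sense heritability.** Per-mouse RTC is rank-based inverse-normal
transformed and decomposed by one-way ANOVA on strain:

    H² = MS_strain / (MS_strain + (n̄ − 1) · MS_resid)

with `n̄` the mean per-strain sample size. Significance comes from shuffling
strain labels; confidence intervals from a two-stage cluster bootstrap.

**QTL scans.** For CCF1 panels, the per-line phenotype is regressed at every
marker on the eight founder-dosage columns (Haley–Knott-style), with
`LOD = (N/2)·log10(RSS₀/RSS₁)`. For CCF1N1 mice, a binary ancestry indicator
per marker is used — Gaussian LOD for quantitative traits, and for the
binary complete-responder (CR) trait a logistic LOD computed in closed form
from the two genotype-group response fractions. Genome-wide thresholds are
the empirical 95th percentile of the permutation max-LOD (1000 permutations,
α = 0.05). Epistasis between mapped loci is tested by logistic-regression
likelihood-ratio tests of additive vs interactive models.

**Microenvironment statistics.** Spot-level spatial colocalization of cell
types (markers of both types detected in the same Ptprc⁺ spot), tested by
shuffling the spot-to-sample assignment; the Cxcl9/Spp1 CPM ratio compared
across groups by rank-sum tests; and an MHC heterozygosity score — the
fraction of MHC-interval SNVs at which a line's CC-derived founder allele
differs from its inbred partner strain.

## Worked example

Simulate a 24-line CCF1 study with one planted response QTL (founder B at
marker `c2m16`, slope effect −0.05 on the treated arm) plus a spatial spot
table whose responder samples have 4× the CTL–macrophage co-occurrence, and
run the pipeline:

```sh
iciqtl simulate --scenario scenario.yaml --outdir sim --seed 1
iciqtl rtc   --input sim/growth.tsv --out rtc.tsv --seed 1
iciqtl herit --input rtc.tsv --config config.yaml --out herit.tsv --seed 1
iciqtl scan  --design ccf1 --trait mean_log_rtc --input rtc_lines.tsv \
             --dosages sim/dosages.tsv --config config.yaml \
             --out scan.tsv --seed 1
iciqtl coloc --spots sim/spots.tsv --n-perm 2000 --out coloc.tsv --seed 1
```

which prints:

```
seed=1 h2=0.6450 p=< 0.0005 wrote herit.tsv
seed=1 peak=c2m16 lod=23.977 threshold=9.274 wrote scan.tsv
seed=1 diff=0.1809 p=< 0.0005 wrote coloc.tsv
```

Reading the output: ICI response is strongly heritable in this panel
(H² = 0.65, no permuted dataset reached the observed value in 2000
shuffles); the genome scan's peak lands exactly on the planted marker
`c2m16` with LOD 24.0, far above the 1000-permutation genome-wide threshold
of 9.3; and responder tumors show an 18-percentage-point higher fraction of
immune spots with CTL–macrophage colocalization (permutation p < 5 × 10⁻⁴).
Every stage writes a TSV payload plus a `.meta.json` sidecar recording
parameters and seed; identical inputs, config and seed reproduce the
payloads byte for byte.

## Layout

- `src/iciqtl/config.py`, `io.py`, `cli.py` — study configuration, domain
  containers, TSV/JSON I/O, and the `iciqtl` command-line pipeline
- `src/iciqtl/growth.py` — slope fitting, RTC, response classes, CR* test
- `src/iciqtl/heritability.py` — rankZ, ANOVA H², permutation/bootstrap
- `src/iciqtl/qtl.py` — founder-dosage and binary-marker scans, permutation
  thresholds, epistasis LRT, rank-sum comparisons
- `src/iciqtl/tme.py` — colocalization, expression ratio, MHC heterozygosity
- `src/iciqtl/simulate.py` — genomes, crosses, growth, counts, spots
- `docs/methods.md` — models, assumptions, parameter choices, limitations
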