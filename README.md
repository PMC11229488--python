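# phbreak

Breakpoint analysis for t(9;22)-type genomic fusions — the translocation
that fuses *BCR* (chromosome 22) to *ABL1* (chromosome 9) and produces the
Philadelphia chromosome of chronic myeloid leukemia (CML) and
*BCR::ABL1*-positive acute lymphoblastic leukemia (ALL).

The package is written for researchers who map genomic (DNA-level) fusion
breakpoints in patient cohorts and want a tested, self-contained toolkit
for the downstream analyses:

* **simulate** translocation cohorts with exact per-patient ground truth
  (breakpoint densities per breakpoint cluster region, junction-mechanism
  mixture, reciprocal-fusion balance, junction-spanning reads);
* **call** breakpoints from junction-spanning reads by deterministic
  split-read alignment against the two partner references;
* **classify** junction primary structure into the non-homologous end
  joining (NHEJ) signatures — microhomology, blunt join, untemplated
  insertion;
* **stats** — chi-squared uniformity tests, two-sample Kolmogorov–Smirnov
  comparisons (e.g. CML vs ALL), single-covariate logistic screens;
* **reciprocal** — deletion/duplication arithmetic between the forward
  (*BCR::ABL1*) and reciprocal (*ABL1::BCR*) junctions of each patient;
* **motifs** — IUPAC and RSS (heptamer/spacer/nonamer) scanning with a
  permutation test of breakpoint–motif proximity;
* **report** — a static JSON + HTML cohort report.

## The junction decomposition at the core

Given a fusion sequence *F* spanning a junction and the two partner
references, let

* *p* = length of the maximal prefix of *F* matching partner A contiguously
  from its aligned start, and
* *s* = length of the maximal suffix of *F* matching partner B contiguously
  to its aligned end.

Then

| condition       | call          | detail                                   |
|-----------------|---------------|------------------------------------------|
| *p* + *s* = \|*F*\| | blunt         | no shared, no untemplated bases          |
| *p* + *s* > \|*F*\| | microhomology | *h* = *p* + *s* − \|*F*\| shared bases; *h* + 1 equivalent crossovers |
| *p* + *s* < \|*F*\| | insertion     | ins = *F*[*p* : \|*F*\| − *s*], the unique minimal insert |

Canonical breakpoints are reported under the **leftmost rule** (the
crossover is placed at the 5′-most equivalent position), matching common
structural-variant normalization. The split-read caller applies the same
decomposition per read, clusters canonicalized votes within ±3 bases,
builds a per-column-majority consensus junction and classifies it.

Reciprocal balance uses the convention that adjacency is balance: with both
genes plus-strand, `delta22 = pos22_rec − pos22_fwd − 1` and
`delta9 = pos9_fwd − pos9_rec − 1`; positive deltas are bases lost from both
derivatives (deletion), negative deltas bases present on both
(duplication).

The shipped region catalog carries the GRCh38 breakpoint cluster regions:
minor *BCR* chr22:23,180,958−23,254,000; Major *BCR*
chr22:23,289,491−23,292,664; micro *BCR* chr22:23,311,732−23,313,035;
*ABL1* chr9:130,699,582−130,855,101.

## Worked example

```python
from phbreak import (SimParams, make_toy_reference, simulate_cohort,
                     classify_cohort, ks_compare, cohort_reciprocal_report)

ref = make_toy_reference(seed=1)
res = simulate_cohort(SimParams(n_patients=500, seed=7), ref)

summary = classify_cohort(res.records, res.refs["chr22"], res.refs["chr9"])
print(summary.fractions)       # mechanism mixture over 500 junctions
print(summary.mh_len_median)   # homology length median

t = res.truth
ks = ks_compare(t.loc[t.group == "CML", "pos9"], t.loc[t.group == "ALL", "pos9"])
print(ks.statistic, ks.p_value)

print(cohort_reciprocal_report(res.records))
```

prints (abridged):

```
{'microhomology': 0.498, 'blunt': 0.384, 'insertion': 0.118}
1.0
0.3 2.59e-10
{'n_paired': 500, 'n_perfectly_balanced': 53, 'n_within_1bp_both': 65,
 'pct_within_100bp_22': 87.0, 'pct_within_100bp_9': 86.2, ...}
```

Reading: at the default mixture roughly half of the simulated junctions
carry short homologies (median 1 bp), ~38% are blunt and ~12% carry a short
untemplated insert; the CML- and ALL-analog breakpoint distributions in the
ABL1-analog region differ strongly (D = 0.30, p ≈ 2.6e-10, n = 220 + 280);
and most reciprocal pairs are balanced to within 100 bp on both genes, with
a small tail of large (>10 kbp) deletions/duplications.

The same pipeline is available from the shell:

```sh
phbreak simulate --seed 7 --n-patients 500 --reads --out sim/
phbreak call --reads sim/reads.fastq --refs sim/refs.fasta --out calls/
phbreak classify --cohort sim/cohort.tsv --refs sim/refs.fasta --out cls/
phbreak stats --cohort sim/cohort.tsv --test ks --region ABL1 \
        --group-by diagnosis --catalog sim/catalog.tsv --out st/
phbreak reciprocal --cohort sim/cohort.tsv --out rec/
phbreak motifs --refs sim/refs.fasta --chrom chr9 --cohort sim/cohort.tsv --out mot/
phbreak report --stage junction_fractions=cls/junction_summary.json \
        --stage reciprocal_counts=rec/reciprocal_report.json --out rep/
```

Real cohort tables (tab-separated, 1-based inclusive coordinates, columns
`patient_id  diagnosis  age_years  sex  locus  pos22  pos9
pos22_reciprocal  pos9_reciprocal  junction_seq`; a `column_map` argument
accommodates other layouts) can be ingested with
`phbreak.read_cohort_table` against the GRCh38 catalog.

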