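# embryoedit

Amplicon genotyping, reading-frame allele classification and stop-codon
guide design for CRISPR knockout experiments in early embryos.

## The problem

Gene-ablation studies in non-model mammals (cattle, rabbit) generate
knockout embryos either with the conventional Cas9 nuclease — random
indels from NHEJ repair of a double-strand break — or with a cytosine base
editor (CBE/BE3), which converts a C·G pair to T·A inside a protospacer
window and can turn CAA/CAG/CGA/TGG codons into stops without cutting DNA.
Because editing happens after the first cleavage divisions, each embryo is
a *mosaic* of up to several alleles, and Sanger traces with mixed peaks
cannot resolve them; the practical readout is deep sequencing of a short
PCR amplicon over the target site.

`embryoedit` packages that workflow end to end:

* **genotyping** — reads are aligned to the WT amplicon with an affine-gap
  glocal aligner, per-read edits are left-normalized (VCF convention) and
  restricted to the CRISPR editing region with a base-quality filter,
  identical edit lists are pooled into alleles above explicit support
  thresholds, and each embryo is called from its allele classes;
* **classification** — the frame rule: an allele whose net coding change is
  not a multiple of three is a frameshift knockout (`KO_frameshift`); a
  multiple-of-three change is in-frame (`IF`) unless it gains a premature
  stop; a codon-to-stop substitution is `KO_stop`. Embryos are `WT`
  (no edited allele), `IF` (≥ 1 ORF-conserving allele among ≥ 1 edited),
  `KO` (only ORF-disrupting alleles) under the nuclease scheme, and
  `WT` / `Hz` / `KO` under the base-editor scheme;
* **design** — exhaustive enumeration of protospacers (both strands, NGG
  PAM) whose window C→T edits install a premature in-frame stop, with
  per-isoform truncation fractions, bystander-edit accounting and an
  alternative-start escape flag; plus frameshift outcome annotation
  (identical N-terminal prefix, percent identity vs each isoform) for
  nuclease guides;
* **statistics** — editing efficiency (edited / genotyped) and KO-generation
  efficiency under both denominator conventions (KO / edited and
  KO / genotyped), and two-proportion comparisons (Pearson χ² when all
  expected counts ≥ 5, otherwise Fisher's exact test);
* **simulation** — a seeded generator of mosaic embryo cohorts and
  error-bearing FASTQ reads, including named cohort fixtures whose genotype
  compositions match published TEAD4-knockout embryo counts.

## Worked example

Simulate the rabbit day-5 base-editor cohort (10 embryos: 8 knockouts and
2 heterozygotes, 200 reads each) and genotype it:

```bash
$ embryoedit simulate --cohort rabbit-D5 --seed 7 --outdir sim
simulated 10 embryos x 200 reads (cohort=rabbit-D5, seed=7) -> sim

$ embryoedit genotype --fastq-dir sim --config sim/config.json --outdir out
...
summary: {'n_genotyped': 10, 'n_wt': 0, 'n_if': 0, 'n_hz': 2, 'n_ko': 8,
          'n_edited': 10, 'n_no_call': 0, 'edit_efficiency_pct': 100.0,
          'ko_of_edited_pct': 80.0, 'ko_of_total_pct': 80.0}

$ head -4 out/genotypes.tsv
embryo_id       call  n_alleles  classes       support_fractions  n_reads  n_passing
rabbit-D5-hz00  Hz    2          KO_stop,WT    0.505,0.495        200      200
rabbit-D5-hz01  Hz    2          WT,KO_stop    0.510,0.490        200      200
rabbit-D5-ko00  KO    1          KO_stop       1.000              200      200
```

All ten embryos are edited and eight carry only stop alleles
(`ko_of_total_pct` = 80%); the two heterozygotes show the WT and the
CAG→TAG allele at ~50/50 read support, as planted. Comparing blastocyst
development between an injected and a control group (10/12 vs 9/11):

```bash
$ embryoedit stats 10 12 9 11
{"statistic": null, "p_value": 1.0, "method": "fisher"}
```

The same machinery is available as a library:

```python
from embryoedit import paper_cohorts, run_cohort

bundle = paper_cohorts(seed=1)["bovine-D8"]
results, summary = run_cohort(bundle)
print(summary.as_dict()["edit_efficiency_pct"])   # 93.9  (31/33 edited)
print(summary.as_dict()["ko_of_edited_pct"])      # 45.2  (14/31 KO)
```

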