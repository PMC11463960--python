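# Methods

## Scope and model

`embryoedit` models the genotyping of CRISPR-injected embryos from deep
sequencing of one PCR amplicon per target. An embryo is treated as a finite
mixture of alleles (it is a few-cell mosaic at injection time, so one to
four alleles are expected and no ploidy prior is imposed). An allele is an
ordered set of edits on the amplicon plus strand; the biological question —
is the gene ablated? — reduces to the reading-frame consequence of those
edits on the annotated CDS segments of the amplicon.

### Frame rule

For an allele with edits restricted to coding sequence, let d be the net
coding-length change (inserted coding bases minus deleted coding bases).

* d mod 3 ≠ 0 → `KO_frameshift`: every codon downstream of the edit is
  read out of frame.
* d mod 3 = 0 and the edited sequence gains a premature in-frame stop →
  `KO_stop` (this covers the base-editor CAG→TAG strategy and in-frame
  indels that insert a stop codon).
* d mod 3 = 0 otherwise → `IF` (edited, ORF conserved).
* no coding edit → `WT` (non-coding edits are noted but do not change the
  class).

Embryo calls per scheme: **nuclease** — WT (no edited allele), KO (every
allele ORF-disrupting), IF otherwise (≥ 1 edited allele and ≥ 1 allele,
edited or not, conserving the ORF; an unedited WT allele therefore rescues
an embryo to IF, keeping KO = "only KO alleles" exact). **base editor** —
WT (no stop allele), KO (only stop alleles), Hz (mixture). The base-editor
scheme has no IF category: an edited allele without a stop (a missense
bystander-only outcome) does not make the embryo a knockout and is folded
into the non-KO side of the call; the simulator never plants such alleles.

## Alignment

Reads are aligned to the WT amplicon with a three-state Gotoh dynamic
program: match +2, mismatch −3, and affine gaps where a gap of length L
costs `gap_open + L·gap_extend` = −(5 + L). The alignment is glocal: the
read must be consumed end to end, while unaligned reference flanks are
free, which is the correct shape for amplicon reads that may carry
insertions past the reference length. Rows are computed with NumPy; the
within-row insertion-state dependency is resolved exactly with a running
maximum (`gap_open + max_k(H[k] − k·gap_extend) + j·gap_extend`), so no
band or heuristic is involved — the score provably equals the plain DP,
and the test suite checks that equality against an independent brute-force
implementation on a thousand random instances. Tie-breaks are fixed
(diagonal over reference gap over read gap); gap placement is then
canonicalized by left-normalization, so tie-break choices cannot affect
downstream calls. All-N reads are flagged unalignable.

## Edit calling and the editing region

Edits are extracted from the alignment walk. Indels are left-normalized
(VCF convention) before any region test, so region membership is
placement-invariant in homopolymers. The "editing region" restricts calls
to where the enzyme can act: cut site ± 10 bp for nuclease experiments
(covers NHEJ indel spread without capturing distal artifacts) and the
base-editing window footprint ± 2 bp for base-editor experiments; both
are configurable. An edit is kept when its normalized footprint *overlaps*
the region (insertions are given a two-base footprint spanning their
flanks so boundary insertions remain testable).

Quality control: substitutions require Phred ≥ 20 at the mismatched base
(bases the simulator corrupts carry Q12, real pipelines carry the
sequencer's estimate), and reads with more than 10% low-quality bases are
dropped from the denominator. These thresholds are declared conventions,
not values fitted to any dataset.

## Allele reconstruction

Reads with identical (possibly empty) edit lists are pooled into candidate
alleles. A candidate is reported when it has ≥ 5 supporting reads *and*
≥ 10% of passing reads; the WT allele competes under the same thresholds,
and reported fractions are renormalized. The thresholds are a sequencing
noise floor, not a ploidy prior: any number of alleles above the floor is
reported. Raising the fraction threshold can only shrink the reported set
(tested as a monotonicity property). An embryo with no passing reads, or
none above threshold, is a `no-call` and is excluded from cohort
denominators with its count reported.

## Protein impact and guide design

Mutant proteins are predicted by projecting amplicon edits onto the full
transcript CDS, translating in the WT frame to the first stop. Two
homology metrics are reported because they answer different questions:
the identical N-terminal prefix length (how much of the WT sequence a
truncated product retains) and global-alignment percent identity with the
denominator fixed at the WT isoform length (so truncations score low even
when their prefix matches perfectly). Epitope retention classifies a
1-based WT residue interval as full/partial/none by positional identity —
a proxy for whether an antibody raised against that immunogen would still
detect the mutant product.

The stop-guide designer enumerates every 20-mer with a matching PAM on
both strands and applies C→T to *all* window cytosines on the protospacer
strand (positions 4–8, PAM-distal, by default). The all-C model is the
worst-case bystander assumption and the design-relevant one for a
processive deaminase; a `single_c` optimistic mode is available. Stop
codons reachable by C edits are CAA→TAA, CAG→TAG, CGA→TGA on the sense
strand and TGG→TGA/TAG/TAA through antisense edits (G→A on the sense
strand); these follow from the genetic code. Candidates whose stop
coincides with the WT stop produce no truncation and are not reported.
Ranking is ascending in the maximum truncation fraction (truncated
length / isoform length) across isoforms — earlier stops first — and a
candidate whose stop falls at or upstream of an isoform's alternative
start is flagged as an escape risk: that isoform would still be produced
intact. Isoform start offsets are recognized for C-terminal-suffix
isoforms (alternative downstream starts); isoforms that are not suffixes
of the canonical protein, or lack an initial methionine, are skipped.

Nuclease guides are annotated by applying 1-bp and 2-bp insertion
archetypes at the blunt cut (3 bp 5′ of the PAM, between protospacer
positions 17|18) and reporting the maximum identical prefix and percent
identity across both frameshift phases and all isoforms.

## Simulator

The generator emulates exactly the structure the genotyper assumes:
single-end, full-amplicon reads drawn from an embryo's allele mixture by
its fractions, then corrupted by independent per-base substitution errors
(default 0.002) and uniformly placed single-base indel errors (default
1e-4, a typical Illumina scale). Error-free bases get Q37, error-injected
bases Q12. A fixed configuration (including seed) yields byte-identical
FASTQ output; per-embryo streams use spawned child seeds so cohorts are
reproducible embryo by embryo.

The named cohort fixtures (`paper_cohorts`) encode published embryo
counts: bovine D8 (33 embryos: 2 WT / 17 IF / 14 KO), bovine D12
(45: 0/22/23), bovine E14 (26: 3/10/13) and rabbit D5 (10: 8 KO / 2 Hz).
IF and KO embryos cycle through mixture patterns of one to four alleles
built from canonical archetypes (3-bp in-frame insertion, 1-bp insertion,
1- and 2-bp deletions at the cut; CAG→TAG conversion for the rabbit), with
minimum planted fractions of 0.25 so every allele sits well above the
support floor at 200 reads per embryo.

What the simulator does **not** model: PCR chimeras and amplification
bias, position-dependent Illumina error profiles, paired-end overlap,
UMI structure, large structural deletions spanning a primer, and
cell-sampling noise in the allele fractions. Passing the planted-truth
tests therefore shows the pipeline's logic is correct under its stated
error model, not that real miSeq data would be error-free; on real data
the support thresholds and region filter carry the corresponding load.

## Synthetic reference fixtures

The frozen fixtures in `fixtures.py` are synthetic stand-ins for real
loci, engineered so that the arithmetic of the published worked examples
holds in miniature: the rabbit-style transcript is 360 codons with the
targetable CAG at codon 162 (stop there truncates to 162 aa = 45% of
protein length) and carries an internal ATG at codon 100 as an
alternative-start isoform; the bovine-style transcript is 500 codons with
the cut at the codon-110 boundary and early stops engineered in both
shifted frames, so frameshift archetypes retain an identical prefix of
exactly 110 aa (22% identity). Real-accession analyses run through the
same code paths by supplying FASTA inputs to the `design` command.

## Numerical and interface choices

* Coordinates are 0-based half-open on the amplicon plus strand; a guide's
  `start` is its 5′ end on its own strand; cut offset default 3.
* Percentages are kept at one decimal in machine outputs; displayed
  summaries round to integers.
* χ² is used without continuity correction when all expected counts are
  ≥ 5 (a `continuity` flag enables Yates), Fisher's exact (two-sided)
  otherwise.
* KO-generation efficiency is reported under both denominators
  (`ko_of_edited_pct`, `ko_of_total_pct`) since both conventions appear in
  practice.
* Simulated problem sizes in the test suite (200 reads/embryo, cohorts of
  10–45 embryos, 260-bp amplicons) match the fixture definitions; the
  alignment-oracle cross-checks use 1,000 random pairs up to 30 bp, where
  the brute-force DP is exact and fast.

## Known limitations

* The genotyper assumes one amplicon per run; multi-locus experiments need
  one run per target.
* Alleles are defined by edits inside the editing region only; a real
  large deletion removing a primer site would present as allele dropout,
  which the model cannot see.
* Hz calls come from allele sets, not chromatogram deconvolution; Sanger
  trace parsing is out of scope.
* The designer scores neither editing efficiency nor off-targets; it
  enumerates and ranks by truncation only.
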