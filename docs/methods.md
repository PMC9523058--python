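# Methods

## Genetic code tables and translation

Translation tables come from the NCBI registry (via Biopython). Table 15
is table 11 with a single change — TAG encodes glutamine instead of stop —
which the loader verifies at construction. Start-codon sets are
deliberately narrower than NCBI's permissive lists: code 11 uses
{ATG, GTG, TTG} (the three common bacterial initiators; NCBI's seven-codon
list inflates spurious ORFs), and code 15 uses {ATG} only, since
alternative initiators have not been observed for this code. Codons
containing N translate to X and never act as starts or stops. Translation
offers three stop policies (`truncate`, `error`, `readthrough`).

## ORF prediction and gene selection

Gene calling is a deterministic maximal-ORF scan: in each of the six
reading frames, every stop-to-stop interval yields at most one ORF,
running from its first (most upstream) start codon to the terminating stop
(or to the contig edge, flagged accordingly). The first-start rule
maximises ORF length and therefore the coding-density contrast between
codes. The default length floor is 30 residues. There is no coding
statistic, RBS model or start-site scoring, so absolute gene inventories
differ from a trained gene finder's; the code-assignment rule only compares
the two codes under the *same* caller, which preserves the contrast.

A raw six-frame scan emits heavily overlapping calls. Before density
comparison the pipeline applies a greedy one-gene-per-locus selection:
ORFs are taken longest-first, discarding any that overlaps an
already-selected ORF on the same contig (ties broken by coordinates, so
the step is deterministic). This is the structural analogue of a gene
finder reporting one gene per locus and is what makes coding density a
meaningful per-contig quantity here.

Circular contigs are linearised (no origin-spanning ORFs); the topology
flag is retained for reporting. Coordinates are 0-based half-open
internally and 1-based inclusive in GFF3; minus-strand genes store
forward-axis coordinates and read their protein from the reverse
complement.

## Coding density and code assignment

Coding density is the summed length of all (selected) genes divided by
contig length; overlapping spans would be counted with multiplicity (a
per-base union density is available as a diagnostic, and the two coincide
after selection). The assignment rule works in absolute percentage points
of density gain: contigs of 5–100 kb are assigned to code 15 when the gain
strictly exceeds 10 points, contigs of ≥ 100 kb when it exceeds 5 points.
A relative-increase variant (`mode="relative"`) is provided as a
configuration switch because "increase of greater than 10 %" admits both
readings; the absolute reading is the default since coding density is
itself a percentage and the size tiers suggest additive thresholds.
Contigs under 5 kb return `indeterminate` rather than silently defaulting
to code 11.

## GC skew

Skew is (G−C)/(G+C) over sliding windows (default 1000 nt window, 10 nt
step, both configurable; windows with G+C = 0 score 0). The cumulative
skew's global minimum marks the replication origin and its maximum the
terminus, under the convention that the leading strand is G-rich. The
defaults are conventions of the skew-analysis tools in common use, not
measured values. On a circular genome the origin may be found at either
contig edge; distances to it should be evaluated circularly.

## Search database

The layered database contains: one record per code-11 gene, one per
code-15 gene, one per code-15 gene with a non-empty upstream extension,
plus auxiliary proteomes (e.g. a host reference) and contaminants supplied
as FASTA, and one reversed decoy per target (`DECOY_` prefix;
whole-protein reversal preserves length and residue composition exactly).
Record ids carry provenance (`source|gene_id|extN`) and survive a FASTA
round trip.

Upstream extensions append at most 30 residues of in-frame sequence
upstream of the annotated start, stopping at the nearest upstream TAA or
TGA or the contig edge. TAG is *not* a boundary — under code 15 it reads
through as Q — so the boundary set is exactly {TAA, TGA}. Extended records
are separate entries, so peptide evidence upstream of the annotated start
is distinguishable by parent id. Whether ATGs inside the extension should
seed alternative N-termini is left unmodelled.

## Digestion and masses

Trypsin cleaves after K or R but not before P. Full-specific peptides have
both termini at cleavage sites or protein ends; semi-specific digestion
additionally emits peptides with exactly one conformant terminus. Missed
cleavages are cleavage sites strictly inside the peptide (default cap 3).
Default length bounds are 6–50 residues — a conventional search window,
not a measured value — and are plain parameters. Monoisotopic residue
masses come from pyteomics; carbamidomethylation (+57.02 Da) is applied to
every cysteine unconditionally and methionine oxidation (+15.99 Da) is the
default variable modification, at most three per peptide. Fragment-ion
generation and PTM localisation are out of scope.

## Target–decoy FDR

FDR is estimated at the peptide level: PSMs collapse to the best-scoring
entry per sequence, entries are ranked by score, the FDR at rank k is
(decoys at or above k)/(targets at or above k), q-values are the running
minimum from the bottom, and targets with q ≤ 0.01 are accepted. A peptide
matching both a target and its own reversed decoy counts as target. This
is the classical concatenated-search estimator; engines with fused decoy
schemes (e.g. PEAKS' decoy fusion) estimate the same quantity differently,
so accepted sets will not be identical across engines at the same nominal
threshold. With zero decoys present all q-values are 0 and a warning is
emitted.

## Codon-level mapping and evidence classes

Each accepted peptide is located in its parent record(s) (one alignment
per occurrence), and each residue is assigned its 3-nt genomic span using
the gene's coordinates, strand and extension offset. The literal genomic
codon is looked up for every residue; positions whose codon is TAG are the
candidate recoding observations, and an alignment is rejected if its
residues contradict the genomic translation.

Classes per peptide:

- **code15-exclusive** — a substring of no standard-code target record
  (code-11 phage records, auxiliary and contaminant proteins); otherwise
  **shared**. I and L are distinct in this check by default (database
  sequences are in-silico translations); tag matching, by contrast, always
  treats I/L as equivalent because de novo sequencing cannot distinguish
  them.
- **stop-readthrough** — at least one residue sits on a genomic TAG with at
  least one residue on each side within the peptide.
- **start-readthrough** — the peptide's genomic span covers the start codon
  of a same-strand, same-frame code-11 gene with at least one residue on
  each side of it.

A recoding event aggregates, per TAG codon, all supporting peptides; a
hard assertion guarantees no event is ever emitted at a non-TAG codon or
for a residue other than Q.

## De novo corroboration

A tag must pass ALC > 50 % and share a contiguous stretch of ≥ 6 residues
with the peptide (longest-common-stretch, I=L). For a recoded position the
recoded Q and up to two flanking residues on each side (clipped at the tag
ends) must each exceed 90 % local confidence. The flank width of 2 is a
design choice — "several flanking residues" is not otherwise quantified —
and is configurable. The manual-validation step that a human analyst would
perform on spectra is replaced by this explicit rule set; that replacement
is deliberate and documented here.

## Synthetic data generator

The generator emulates the genome and measurement structure the analysis
assumes. One linear contig holds two equal halves: the first carries
code-15 genes (in-frame TAGs encoding Q), the second standard code-11
genes; the halves form two replichores with opposed GC skew (leading
strand G-rich, skew 0.2). The composition is AT-rich (GC 0.34), matching
the phages being emulated; this also gives shifted and reverse frames a
realistic stop-codon supply, which is what makes wrong-code annotation
fragment rather than re-tile the recoded half. Genes are 350–550 codons,
separated by 30–90 nt gaps, all on the forward strand (strand handling is
exercised by dedicated fixtures); each gene is preceded by an in-frame TAA
and a short non-start spacer, so the first-start rule recovers planted
genes exactly and upstream-extension boundary cases occur naturally.
Recoded genes carry Poisson(12) in-frame TAGs (~2.7 % of codons, with ≥ 1
enforced), in the range reported for TAG-recoded gut-phage genes.

PSMs follow an abstract Gaussian score model (only rank order matters to
the FDR stage): correct identifications are tryptic peptides of the true
proteome sampled at rate 0.3 with scores N(30, 5); incorrect ones carry
shuffled sequences with scores N(15, 5) and land in target or decoy space
with probability 1/2 each — the competition structure of a concatenated
search, under which the decoy count is an unbiased estimate of the
incorrect-target count and the classical estimator is calibrated. The
noise fraction defaults to 0.4. Peptides covering recoded positions
receive matching de novo tags with high per-residue confidence
(92–99.5 %) with probability 0.8, low confidence (55–88 %) otherwise.

What the generator does **not** emulate: real spectra and their chimeras,
codon-usage bias beyond explicit TAG placement, ribosome-binding signals,
overlapping genes, sequencing errors, or strain mixtures. Passing tests
therefore demonstrate the correctness and calibration of the decision
rules under the stated structural assumptions, not search-engine behaviour
on real spectra.

## Problem sizes and numerical choices

The default study runs on a 99 kb contig (just under the 100 kb rule
boundary, so the 5–100 kb tier applies) with 30 recoded and 30 standard
genes; a 150 kb variant exercises the ≥ 100 kb tier. The full synthetic
pipeline completes in well under a minute on one CPU. Ties in ORF
selection and FDR ranking are broken by fixed lexicographic keys, so every
stage is deterministic given the seed; the staged CLI subcommands and the
composed run produce byte-identical outputs.

## Known limitations

- The ORF caller's absolute densities are not comparable to a trained gene
  finder's; only the between-code contrast is meaningful.
- Only TAG→Q (code 15) is detected; the table registry accepts other
  codes, but no assignment rule is implemented for, e.g., TGA→W.
- Protein-level FDR (picked-pair or otherwise) and quantification are not
  implemented; detection requires one unique peptide per gene.
- Contigs under 5 kb are never assigned; genuinely recoded short contigs
  will be reported `indeterminate`.
- The cumulative-skew extrema assume a single origin/terminus pair;
  genomes without bidirectional replication will yield arbitrary extrema.
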