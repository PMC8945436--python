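# Methods

## The question and the model

Canonical animal miRNA targeting is defined by perfect Watson–Crick pairing
of the seed — mature positions 2–7 (6-mer) or 2–8 (7-mer) — to a site in a
3'UTR. A miRNA whose seed contains a CG dinucleotide faces a peculiar
evolutionary problem: in mammalian genomes the cytosine of a CpG is
methylation-prone and hypermutable (deamination of 5-methyl-C to T), so the
CG half-site in *target* UTRs decays quickly, while the miRNA locus itself is
conserved. The hypothesis this package operationalizes is that such miRNAs
carry an alternative target class: sites with one extra nucleotide bulged,
on the target side, between the C and G that pair the seed's G and C. The
pipeline finds both classes and tests the bulge class with five independent
lines of evidence: cross-species conservation, population mutation burden,
expression anticorrelation, transfection response, and CLASH chimeric reads.

Seed length defaults to 7 (positions 2–8); the shipped table of
vertebrate-conserved miRNAs is classified with the 7-mer convention (one of
its CG seeds carries the dimer at positions 6–7, which a 6-mer seed would
miss). Length 6 is available everywhere via the `seed_len` parameter.

## Site classes and search

* **seed** — the exact reverse complement of the seed (DNA alphabet),
  searched on the UTR sense strand only; overlapping occurrences all count;
  `N` never matches.
* **cg_bulge** — for every CG occurrence in the seed-match pattern, the four
  patterns with A/C/G/T inserted between that C and G (deduplicated).
* **random_bulge** (control) — one base inserted at a uniformly random
  *interior* point of the seed-match pattern that is not a CG gap. End
  insertions are excluded by design: they would leave the perfect match
  intact as a substring, making the "control" a canonical site. Note that
  interior insertions can still coincide with other classes (duplicating a
  base next to a run recreates the perfect site; inserting into the CG gap
  of a C/G run can equal a cg_bulge string); such sites are kept and flagged
  `also_seed_site` rather than silently dropped.

Per-miRNA "target number" counts distinct genes with at least one site
(per-occurrence counts are also reported). When a gene has several UTR
isoforms only the longest is ingested.

## Conservation

Sites are projected through MAF alignment blocks by reference-column lookup,
with stitching across blocks whose reference coordinates are contiguous.
A species missing from a covering block, or fully gapped under the site, is
excluded from that site's denominator; a site not fully covered by blocks is
excluded entirely (both logged, never scored 0). The conservation rate is
the number of species, reference included, in which the site is intact.
Intactness has two modes: `exact` (the projected subsequence equals the site
pattern — default for seed sites) and `pattern` (the subsequence contains
*any* same-class pattern for the same seed — default for bulge classes,
since a bulge site conserved with a different bulged base is biologically
the same class). Class comparisons use two-sided rank-sum tests on the
per-site rates; groups under 3 observations are skipped with a warning.

## Mutation burden and spectra

Variants (biallelic SNVs with folded minor allele frequencies) are assigned
to regions by half-open interval lookup and classified CpG/non-CpG from
their ±1 context, strand-symmetrically (ref C followed by G, or ref G
preceded by C); C→T on the CpG strand or G→A on its complement is flagged as
deamination. MAFs are binned left-open/right-closed with default upper
edges 0.001, 0.005, 0.01, 0.05, 0.1, 0.5. Normalization against the neutral
yardstick is `raw × 1000 / (n_synonymous × gene_length)`; the two normalizers
are standard, their algebraic combination (product denominator, ×1000 scale)
is this package's modeling choice and is configurable in the sense that the
exact rationals are always available. For pooled profiles the gene length is
the mean over pooled genes.

Two statistics are deliberately separated. The two-sample KS test
(`compare_profiles`, per-variant MAF samples by default, per-bin values
optionally) compares spectrum *shape*. A rate multiplier on CpG sites
changes *burden*, not shape, so directionality questions (are UTR CpGs more
mutable than miRNA-locus CpGs?) use `compare_burden`: conditional on the
total CpG mutation count, the count in one region class is binomial with
probability proportional to its CpG site-count exposure — an exact test that
is well calibrated at the study's exposures.

## Expression and transfection

Spearman correlation is computed as rank-transform-then-Pearson with average
ranks for ties and pairwise-complete handling of missing samples (≥3
overlapping samples required per gene). The null is empirical: random gene
sets of the target-set size drawn 1000 times (default) from the expressed
genes, *excluding* predicted targets of the same miRNA — the exclusion is a
design choice to avoid null contamination and can be toggled. Transfection
tests are one-sided Mann–Whitney in the hypothesized direction (down after
over-expression, up after knock-down); the direction is the hypothesis, so
two-sided testing would be anti-conservative bookkeeping. Overlap between
target and control sets is removed from the control with a warning.

## Duplex free energy

An intermolecular-only nearest-neighbor model, adequate for seed-region
duplexes (the default scores the seed against the site plus 3 flanking nt):
matched positions must be Watson–Crick or (by default) G:U pairs; helix
stability comes from stack free energies (37 °C, kcal/mol) shipped in
`data/nn_stacks.tsv` — the 16 Watson–Crick stacks carry published
nearest-neighbor values, stacks involving a G:U pair carry a uniform −0.6
placeholder (a documented simplification; the file is swappable); loop
penalties are affine (bulge 3.8 + 0.5/nt, internal loop 4.0 + 0.5/nt).
A single-nucleotide bulge follows the standard convention that the stack
across it is retained (`bulge_init + closing stack`). The empty pairing has
energy 0; tie-breaks are lower energy, then fewer bulges, then the 5'-most
pairing. The dynamic program is verified against exhaustive pairing
enumeration for short strands.

A consequence worth stating plainly: under this position-blind bulge rule a
CG-gap bulge and a random-gap bulge of the same seed cost the same, and on
the actual pattern sets random-gap duplexes are, if anything, slightly
*more* stable (an end-adjacent bulge can be absorbed by dropping a terminal
pair, and duplicating a base recreates the perfect site). The package
therefore reports the three-class energy comparison without asserting a
CG-vs-random ordering; an observed stability gap between those classes in
real data would reflect sequence context beyond a neutral nearest-neighbor
model, e.g. full-length hybridization against genomic flanks.

## CLASH chimeras

Reads are split against the mature catalog (miRNA-first order by default,
≥16 nt matched, ≤1 mismatch for sequencing error; equal best matches are
ambiguous and left unassigned — unassignable reads are data, not errors).
Interaction classification applies a fixed precedence to reads satisfying
several patterns: canonical seed > CG bulge > G:U wobble > single mismatch >
other bulge > unclassified. A wobble window pairs with ≥1 G:U and no
mismatch; a mismatch window has exactly one non-pairing position and every
other position Watson–Crick (windows mixing wobbles and a mismatch fall
through — they are not near-canonical sites). Two nulls: *shuffle* permutes
target parts across miRNA assignments (breaks pairing, keeps marginals);
*scramble* permutes each target part's nucleotides (keeps length and
composition). Scrambled parts are re-searched for class patterns directly;
this estimates the same combinatorial background as remapping scrambled
reads to a genome, without requiring an aligner — the package's one
intentional procedural substitution, and its classification-based background
is what the enrichment fold is measured against. The headline ratio
aggregates CG bulge + wobble + mismatch + other bulge as "non-canonical".

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of (parameters, rng seed) and emits its
planted truth for closed-loop tests. Emulated: planted site positions per
class; i.i.d. per-species site retention (seed/bulge 0.7 vs control 0.3 by
default) on top of 10% background divergence; CpG deamination at
`base_rate × multiplier` in UTRs vs `base_rate` in miRNA loci (defaults
0.006 and 10, giving roughly a thousand variants at the default cohort
size) with a rare-dominated MAF law (90% below 0.001); Gaussian-copula
rank coupling for Spearman-targeted expression (seed −0.6, bulge −0.35,
12 samples); ±0.4 log-unit transfection shifts over 0.5-sd noise; and exact
(largest-remainder) chimera class mixtures whose reads are built with the
classifier itself as constructive oracle. Not emulated: phylogeny (species
are independent retention draws, not a tree), sequencing error, real base
composition (uniform background by default; a CpG-depleted mode with
observed/expected ≈ 0.25 is available because background CG frequency
drives bulge-search specificity), and genome-scale target counts. Passing
recovery tests therefore demonstrates that the *analysis* detects these
planted structures at realistic effect sizes and sample sizes — not that
real data contain them.

## Problem sizes and numerical choices

The end-to-end synthetic study defaults to: 150 genes × 500 nt UTRs,
23 species, 200 planted sites per class, ~1000 variants over the UTRs plus a
60-locus miRNA panel at pre-miRNA scale (80 nt) so the burden test has real
exposure on both sides, 100 genes per expression group against a 1000-draw
null, 100 duplexes per energy class, and 300 chimeric reads at a
30/50/20 canonical/CG-bulge/background mixture. One replicate runs in about
a second; the recovery check (every planted ordering at p < 0.01) holds
in ≥95 of 100 replicates. Calibration scenarios use the same machinery with
null parameters; the exact-test discreteness of the binomial burden test and
two-sample KS is kept mild by choosing exposures/sample sizes where the
attainable level is close to nominal (e.g. KS at 150 per group).

Degenerate inputs are contracts, not surprises: empty FASTA, ragged MAF
blocks, missing reference rows, MAFs outside (0, 0.5], zero synonymous
counts, empty statistical groups, and mixtures not summing to 1 all raise
typed errors; sub-minimum group sizes warn and skip.

## Known limitations

Intactness of a "homologous site" is pattern-based, not alignment-aware
phylogenetics — no branch lengths, no PhyloP/PhastCons weighting. The
consequence annotator is minimal (synthetic truth supplies synonymous counts
directly). The duplex model makes no claim of parity with full secondary-
structure predictors. Table-level display conventions (ratios truncated to
4 decimals, group means truncated to integers) reproduce the curated table's
own printing and are display-only; exact fractions are always emitted.
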