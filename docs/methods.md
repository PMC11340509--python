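# Methods

This note documents the models, conventions and numerical choices behind
`kaspanel`, in the order the pipeline applies them.

## Data model and conventions

External formats (VCF, GFF3) are 1-based with closed intervals; every
internal interval is 0-based half-open, and conversion happens only in
`io_formats`. Genotypes are unordered diploid allele pairs with phase
discarded — dikaryotic fungal strains are genotyped diploid-like, so
heterozygous/homozygous calls carry meaning, but allele order does not.
A half-missing call (`./0`) is normalised to fully missing.

GATK-style site annotations (QD, MQ, FS, MQRankSum, ReadPosRankSum) that
are absent from a record stay "absent": they are never imputed and never
trigger a filter. *AverageQ* — the mean per-site genotyping quality — is
taken as the mean per-sample FORMAT GQ over non-missing calls when GQ is
present, else the site QUAL; the choice is visible in the code and is
deliberate, since "average quality" has no single standard definition.

## Synthetic panel generator

The generator emulates the shape of a resequenced germplasm collection:
by default 60 accessions in 5 subpopulations, 5,000 biallelic SNPs over
three 200 kb contigs, 25 triallelic spike-ins, 5% of biallelic sites with
one deliberately failing hard-filter annotation, 2% uniformly missing
calls, and 2 accessions that are exact clones of others (the hard case
for fingerprinting, and the reason identification efficiency saturates
below 1 on the full panel).

The population model is Balding–Nichols: each locus draws an ancestral
alternate-allele frequency p ~ Uniform(0.05, 0.5); each subpopulation
draws its own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F the
fixation index (default 0.3), and genotypes are Binomial(2, p_sub) draws.
F → 0 degenerates to a panmictic population. This is the simplest
F-model that yields tunable subpopulation differentiation detectable by
PCA and trees. The random genome is tiled to roughly 40% with multi-exon
genes on both strands carrying short UTR stubs, so every annotation class
occurs; CDS lengths are trimmed to multiples of three.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: linkage disequilibrium (sites are
independent), the transition/transversion bias of real mutation spectra
(alternate bases are drawn uniformly, so simulated Ts/Tv ≈ 0.5 rather
than the 3–4 typical of fungal resequencing), depth/quality correlation
with genotype error, segmental duplication (flank uniqueness is almost
never violated in random sequence), and selection.

## Filter cascade

Five per-locus predicates applied in sequence; because each is a pure
predicate (conservation is judged against the *full* pre-filter variant
set, and PIC against the full matrix), the survivor set is independent of
stage order — a property the tests assert. Comparators are strict exactly
as configured: FS = 60.0 survives, MAF = 0.05 fails. Multiallelic loci
pass the early stages and fall only at the biallelic ("double-allele")
criterion; they are never split into pseudo-biallelic records.

Conservation is judged against all called variants, including ones other
stages later remove, because a primer region must be variant-free
regardless of the neighbouring variant's quality.

Flank uniqueness extracts the ±100 bp window around each SNP and scans
the genome (both strands) with exact 31-mer seeds; every distinct seeded
placement is evaluated ungapped over the full window and the locus is
dropped when a non-self placement reaches ≥ 90% identity over ≥ 100
aligned bases. Exact seeding means diverged repeats with no shared 31-mer
escape detection; the thresholds and seed size are configuration fields
of `FilterThresholds`.

## Annotation

Region precedence when a SNP overlaps several features or genes:
CDS > UTR/exon-noncoding > intron > upstream > downstream > intergenic,
remaining ties broken by lexicographically smallest gene id, so every
locus gets exactly one deterministic label. Upstream/downstream are
strand-aware 2 kb windows (upstream of a minus-strand gene lies at larger
coordinates). Coding effects substitute the alternate base into the
affected codon (complemented for minus-strand genes) and translate with
the standard code; "stop loss" is the substitution reading of a
terminal-codon change, since only SNPs (not indels) are in scope. A gene
whose CDS length is not a multiple of three is skipped with a warning.
Tests verify effect calls against an oracle that re-translates the whole
protein from an edited genome copy.

## Diversity statistics

All indices are computed from non-missing calls only. He uses the
uncorrected 1 − ∑p² (no small-sample factor), which makes He and Nei's H
identical by construction — matching how the index pair is conventionally
reported for such panels. PIC is Botstein's

PIC = 1 − ∑ᵢ pᵢ² − ∑ᵢ<ⱼ 2 pᵢ² pⱼ²

with the sums over the *alleles* of the locus; the bound PIC ≤ He holds
on the whole frequency simplex and is fuzz-tested. The MAF of a
multiallelic locus is the frequency of its second-most-frequent allele.

Pairwise distance is one minus the allele-sharing (IBS) proportion: per
locus the multiset intersection of the two allele pairs divided by two
(AA vs AA → 1, AA vs AG → ½, AG vs GT → ½, AA vs GG → 0), averaged with
pairwise deletion of missing calls; a pair with no comparable locus is an
error rather than a silent zero.

Neighbor joining follows Saitou–Nei with the standard Q-criterion and
branch-length updates. Negative branch lengths are clamped to zero with
the deficit transferred to the sister edge, preserving path lengths. On
additive matrices the reconstruction is exact; tests verify patristic
distances against 100 random generating trees and cross-check against an
independent NJ implementation.

PCA encodes genotypes as alternate-allele dosage {0, 1, 2}, imputes
missing dosages to the column mean (the standard simple choice for
genotype PCA), mean-centres columns and takes the SVD; variance fractions
cover all components and sum to one.

## Core collection

Objective: mean entry-to-nearest-entry distance of the selected subset —
one of the standard core-collection objectives, favouring cores whose
members are mutually far apart, which also makes co-selecting a clone
pair (distance 0) maximally unattractive. Search: greedy max-min
completion from a seed pair, then steepest-ascent single-swap local
search to a local optimum; the search is restarted from the farthest
pairs (all pairs on panels of ≤ 16 accessions, the top 8 otherwise) and
the best result kept, with all ties broken on accession id order so a
fixed input yields a fixed core. On small instances this attains the
exhaustive-search optimum (asserted against a brute-force oracle); at
panel scale it is a heuristic for an NP-hard problem. Evaluation reports
mean Na, Ne, I, Ho, He, PIC, Nei's H for core and full panel, their
ratios, and pooled allele coverage — also restricted to alleles observed
at least twice, since singleton private alleles are frequently
unrecoverable at small ratios.

The 5%–95% (step 5) sampling-ratio sweep is available as
`core_collection.ratio_sweep` / `kaspanel core-collection --sweep`; the
default single ratio is 30%, the point at which such panels typically
reach near-complete allele coverage.

## KASP design

Primer cores are 18–30 nt; the two allele-specific forwards sit on the
plus strand and 3′-terminate exactly at the SNP, one per allele, with
their universal FAM/VIC tails prepended verbatim. Constraints (GC < 60%,
Tm ∈ [55, 61] °C) are enforced on the *untailed* cores — the tails are
universal and identical across assays — and each forward's 5′ end is
extended independently from the minimum length until its core passes, so
the two forwards may differ in length. The common reverse is the first
(closest to the SNP, then shortest) minus-strand window that meets all
constraints within the 120 bp amplicon budget — a deterministic first-fit
rule rather than penalty optimisation. Any candidate footprint covering
another known variant is rejected when `forbid_variants_under_primers`
is set (the default). Failures carry their binding constraint
(`variant_under_primer`, `no_forward_primer`, `no_reverse_site`, `edge`).

Melting temperature is nearest-neighbor thermodynamics with the
SantaLucia unified parameter set at 50 mM monovalent salt and 200 nM
primer (computed via Biopython's `Tm_NN`); the test suite re-derives it
by hand-summing the published ΔH/ΔS table. Secondary-structure screening
(hairpins, dimers) is out of scope.

The published 12-assay *G. frondosa* core panel ships as package data for
structural validation. Note that several of its assays are designed on
the minus strand, so their forwards 3′-terminate in the *complement* of
the listed allele pair; the validator accepts both orientations.

## Core marker set and fingerprints

A marker distinguishes an accession pair when both calls are present and
the unordered genotypes differ; missing never distinguishes, so
fingerprints remain valid under assay dropout. Identification efficiency
is the fraction of all C(n,2) pairs distinguished by at least one marker
of the set. Candidate screening keeps designed, in-region (default CDS)
markers with missing rate ≤ 0.10 and MAF ≥ 0.20, prefers PIC ≥ 0.30
(falling back to ≥ 0.20 when too few pass), ranks by PIC, enforces a
minimum spacing per contig, and truncates to 50.

Minimal fully-discriminating subset selection is set cover, hence
NP-hard; the selector is greedy maximum coverage (ties to higher PIC,
then genomic position) followed by a pruning loop that removes any marker
whose removal preserves the achieved coverage, yielding a
superset-minimal set within the classical greedy bound of the optimum
(both verified against an exhaustive oracle at test scale). Pairs no
candidate can resolve — clone accessions — are reported, not fatal. The
saturation curve records cumulative efficiency in greedy order.

The fingerprint table codes each cell as `X/Y` (alleles alphabetical) or
`.`; the uniqueness report groups accessions by the distinguishability
relation (not raw string equality), so "all rows unique" holds exactly
when identification efficiency is 1. An optional grid rendering colours
homozygote classes (A/A green, C/C yellow, T/T blue, G/G purple),
heterozygotes grey and missing white.

## Orchestration and determinism

`pipeline.run` executes simulate/load → filter → annotate → stats/tree/
PCA → core collection → KASP design → screen → core markers →
fingerprint from one config, validates inputs before any stage runs, and
writes a manifest with SHA-256 checksums of every artifact. One root seed
drives everything; each stochastic stage derives its own stream by stable
hashing (CRC-32) of the stage name, so adding a stage never perturbs
earlier randomness, and two same-seed runs are byte-identical (asserted
end to end in the tests). NJ, tree and PCA run on the "high-quality" SNP
set (hard + quality criteria, without the KASP-specific conservation /
uniqueness / PIC stages), mirroring how population structure is normally
computed on all high-quality sites rather than assay-eligible ones.

## Problem sizes and limitations

Default test and demonstration sizes — 60 accessions, ~5,000 SNPs,
600 kb of genome — were chosen as the smallest panel that exercises every
stage with comfortable statistical margins (e.g. ~2,000 post-conservation
sites, 50 candidates, clone pairs present). Known limitations: no
linkage or recombination model; exact-seed uniqueness scanning misses
diverged repeats; the NJ implementation targets panel-scale taxa counts
(quadratic memory); no indel, CNV or structural-variant support; and
fluorescence-cluster genotype calling (the wet-lab half of KASP
genotyping) is out of scope.
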