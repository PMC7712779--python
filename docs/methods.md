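# Methods

## Scope and model

The package reconstructs, at desk scale, an annotation-and-quantification
workflow for insect antimicrobial-peptide (AMP) gene families. Its central
objects are a curated **gene catalogue** (one record per locus: family,
scaffold placement or `Unplaced`, exon blocks, CDS, assembly-gap flags,
member transcripts) and an **expression matrix** (genes × runs of
exact-match hit counts with within-family percentages and hits/Gb). Five
AMP classes are modelled; the class definitions are purely architectural,
so classification is deterministic given a protein sequence and a set of
domain profiles.

## Classification rules and their parameters

**Signal peptide.** Kyte–Doolittle hydropathy over the first 25 residues;
a core is any run of windows of width 8 with mean ≥ 1.6. Cleavage is placed
at the first small residue (A/G/S/C/T) after the first qualifying window,
searched within positions 15–30 (small residues before position 15 are
ignored — signal peptides shorter than 15 aa are not credible, and this
keeps single polar substitutions inside the hydrophobic stretch from
truncating the call). If no small residue occurs in range, cleavage falls
back to the core end clamped to [15, 30]. This is a heuristic stand-in for
a trained predictor; it is adequate for the strongly hydrophobic signals of
these families and is exercised as such.

**Glx-rich segment.** The *longest* substring with Q+E density ≥ 0.6,
ties to the smaller start; reported only if ≥ 71 aa. The density threshold
operationalises "mainly glutamines and glutamic acids", and the length
floor the "> 70 residues" class boundary; 0.6 cleanly separates the
blattellicin panel (Glx tracks of density ~0.9) from attacin-like proteins
(scattered Q/E). Implementation reduces the density constraint to a
prefix-sum problem (weights `indicator − t`; the longest window ending at
*j* starts at the earliest prefix minimum ≤ P[j]); an O(n²) enumeration
oracle checks it exactly in the tests. Note the maximal window may extend
beyond a dense core through dilute flanks — that is a property of the
definition, shared by implementation and oracle.

**Family domains.** Per-family position-frequency profiles built from the
bundled panel's domain blocks (pseudocount 0.5), scanned as ungapped
log-odds sums against a uniform background. The reporting threshold is
half the weakest training-sequence score, floored at 10 bits. A margin of
only a couple of bits below the weakest trainer would reject paralogs that
have drifted a few percent from the family consensus (each substituted
column costs ~4–6 bits), so the threshold is placed far below the training
scores but far above cross-family and shuffled-decoy scores (which are
strongly negative); the tests require zero cross-family hits on the panel
and < 1% decoy hits. Externally supplied domain-hit tables (e.g. real
profile-HMM output) bypass the scan entirely.

**Class assignment.** defensin ⟺ defensin domain + exactly 6 mature-region
cysteines; drosomycin ⟺ gamma-thionin + 8; termicin ⟺ toxin-like domain;
blattellicin ⟺ attacin domain + qualifying Glx segment + length > 200 aa;
attacin-like ⟺ attacin domain, no qualifying Glx segment, length 100–130.
Cysteines are counted after the predicted signal because the signals are
cysteine-free and precursor counts would be unstable.

## Curation rules

Placement chains maximal exact anchor matches (≥ 31 nt) colinearly per
scaffold/strand (weighted-interval DP on covered transcript bases); a
transcript is placed at ≥ 90% anchor coverage. Chain gaps on the scaffold
are annotated as introns (GT..AG checked) unless they overlap an N-run
(≥ 10 N), which sets an assembly-gap flag instead. Anchors are exact, so a
single mismatch splits a block; splice boundaries are therefore precise
only when exon ends do not coincidentally match intron bases — a known
limitation relative to splice-aware aligners.

Pair resolution: *isoform* requires an identical CDS and an overlapping
placement on the same scaffold; *paralog* follows from distinct loci
(identical CDS included — placement outranks sequence identity) or from
≥ 3 total mRNA differences; otherwise *allele*. Differences are counted
from a global affine-gap alignment (match 2 / mismatch −1 / open −5 /
extend −0.5): substitutions per site, each gap run once. Affine costs are
essential — unit-cost edit scripts scatter a 9-nt deletion into several
cost-equivalent fragments and would inflate the count. The ≥ 3 threshold
is a judgement call anchored to the catalogue's own decisions (2
differences → alleles; 7 + indels → distinct genes); intermediate cases
(3–5 differences, unplaced) are resolved as paralogs and flagged in the
decision log.

Tandem splitting: after grouping, any additional exact occurrence of a
group's CDS on its scaffold that no transcript placement claims becomes an
extra gene record — this is how one annotated mRNA spanning two
near-identical copies yields two genes. Naming is deterministic: families
in fixed order (defensin, termicin, drosomycin, attacin-like,
blattellicin), genes numbered by scaffold id then coordinate, unplaced
last.

## Expression estimation

Reads are optionally filtered first: exact adapter-prefix trimming at the
3′ end (≥ 8 nt overlap), then mean Phred ≥ 20 and length ≥ 100 nt.

**Diagnostic windows.** Within a family, a window of fixed length (150 nt)
at a fixed CDS offset identifies a gene iff no other family member carries
the identical substring; `best_offset` searches all offsets exhaustively
and returns the smallest offset maximising the number of uniquely
identified genes. Discrimination is exact identity, matching the
100%-coverage/100%-identity counting downstream; genes with identical
windows are reported as merged rows (`g3+5`), never silently pooled. A
read counts at most once per window, on either strand (the counting is
orientation-blind; libraries with strand information lose that information
here, stated deliberately).

**Whole-CDS screen.** A read hits a CDS when an exact 31-mer seed extends
ungapped along its diagonal to ≥ 100 matched positions at ≥ 95% identity;
counts are capped at 5000 per query per run (capped cells flagged). The
identity/coverage rule replaces a database e-value cutoff, which has no
meaning without a database-size context; 10% divergence between paralogs
is comfortably rejected while error-free reads from the query gene always
pass. Seeds are sampled every 10 positions, which cannot miss any
qualifying error-free stretch (any ≥ 100-nt exact region contains an
aligned seed at some sampled offset) and misses mismatch-riddled borderline
alignments only in the same spirit as any seeded aligner.

Normalisations: hits/Gb = count / run size in gigabases (doubling the run
size halves it exactly); optional division by CDS length; within-family
percentages sum to 100 per run unless the family total is zero, which is
reported as NA.

## Phylogeny preparation

Attacin-family alignments are trimmed to the concatenation of the 22
N-terminal columns (20-aa signal + 2 residues, the second a proline) and
the 81-column attacin block — 103 sites on the bundled panel. Distances
are p-distances after complete deletion of gap-containing columns. Trees
are neighbor-joining (scikit-bio; negative branch lengths clipped to 0)
with midpoint rooting; support is the fraction of column-resampled NJ
replicates containing each bipartition, with values below 0.5 masked on
output. Maximum-likelihood inference and model selection are deliberately
out of scope; NJ on p-distances is the reproducible stand-in and topology
statements are treated qualitatively.

## Protein metrics

pI is found by bisecting the Henderson–Hasselbalch net-charge curve on
pH ∈ [0, 14] to an interval below 10⁻⁶ (interval convergence, not charge
convergence: curves with many weak acids are nearly flat near zero). The
default pKa set is EMBOSS (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1, termini 8.6/3.6) and is swappable. pI is computed on the full
precursor including the signal peptide. "Positively charged" means K+R
(H excluded) in all composition percentages.

## The bundled panel and the synthetic generator

The gene *table* shipped in `data/table1.tsv` is the published 39-gene
catalogue (names, products, lengths, domains, placements). The *sequences*
behind it are synthetic, constructed so that every architectural and
counting constraint of the published set holds exactly: per-gene CDS and
protein lengths; signal peptides of 18–22 aa (termicins 1–19); 6/8
conserved cysteines; the termicin trio differing at a single site (S/A at
position 13, with four polymorphic CDS sites coverable by one 150-nt
window); defensin windows at CDS 41–190 pairwise distinct except
defensin_g3/g5; attacin-like proteins at ~20% K+R; blattellicins > 200 aa
with Glx tracks > 70 aa, ~13% K+R and anionic pI. The five genes the
assembly lacks are given divergent mRNAs (randomised UTRs plus densely
spaced synonymous differences) so that no 31-nt anchor chain reaches 90%
coverage against their siblings' loci — the synthetic analogue of "the
sequence was not detected in any scaffold". Being synthetic, the panel
reproduces the *structure* of the real gene set, not its residues: tests
that pass on it validate the machinery and the decision rules, not any
biological claim about real sequences; its attacin-like proteins, for
instance, are more basic than their real counterparts.

The generator (`synthetic_data`) derives paralogs from one panel ancestor
per family by guarded codon-wise substitution (per-codon probability
1 − (1 − r)³ for per-site rate r): start/stop, signal codons and cysteine
codons are never touched, and substitutions never create a stop or a new
cysteine — mirroring the conservation the real families show and keeping
the class architecture intact up to r ≈ 0.05. Reads default to 301 nt
(the read length of the sequencing run the study profiled), uniform
positions and strands, independent per-base errors, and qualities drawn
from a clamped rounded normal (mean 36, sd 3, range [2, 41]) — enough
structure to exercise the Q20 filter, with no attempt to model real
Illumina error or quality profiles, coverage bias, PCR duplicates or
stranded library chemistry. Parameter-recovery results on these reads
therefore bound what the counting machinery can do under ideal sampling,
not what real libraries deliver.

## Problem sizes

Default test and acceptance runs use families of 2–4 genes, read sets of
2×10⁴–10⁵ reads, 500-protein Glx-oracle sweeps, 1000 window/read counting
pairs, 50 random 6-leaf additive trees and 100-peptide pI sweeps — sizes
chosen so each check is statistically meaningful (e.g. binomial error on
2×10⁴ reads is ~0.6 points at 75/25) while the whole suite stays desk-
scale.

## Known limitations

- The profile scan is ungapped; an indel inside a domain fragments its
  score (profile-HMM alignment is the upgrade path, via the external
  hit-table input).
- Exact-anchor placement has no splice-site model; intron boundaries can
  shift when exon termini match intron bases by chance.
- The e-value-to-identity translation in the CDS screen is a calibration
  choice; absolute hit counts are comparable within this package only.
- Allele/paralog resolution for unplaced pairs at 3–5 differences rests on
  the ≥ 3 threshold, which published decisions bracket but do not pin.
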