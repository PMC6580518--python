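# Methods

This note documents the models and procedures implemented in `hsfkit`, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## The survey workflow

Genome-wide surveys of the heat shock transcription factor (Hsf) family
follow a standard chain: candidate identification by protein homology
against known Hsfs, verification of the family-defining domain architecture
(an N-terminal DNA-binding domain, DBD, followed by the bipartite HR-A/B
coiled-coil oligomerization region), classification into classes A/B/C,
phylogeny-based subclass assignment, chromosomal distribution and
duplication analysis (in bread wheat, across the A/B/D subgenomes of the
allohexaploid genome), orthology-projected interaction networks, and
expression profiling. `hsfkit` implements each stage as a library module
with a thin CLI, and ships a seeded generator that emits a miniature
hexaploid dataset with a complete ground-truth manifest so the whole chain
can be validated end to end.

## Homology screen

Candidates are identified by optimal local alignment (Smith–Waterman with
affine gaps, computed by Biopython's `PairwiseAligner`) against a set of
known Hsf query proteins. Scoring defaults to BLOSUM62 with gap open 11 /
extend 1; significance uses the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with the standard gapped constants λ = 0.267, K = 0.041.
A protein passes when some query alignment has E ≤ 1e−5 and aligned-region
identity ≥ 50% (identity is computed over aligned columns, gaps included —
the aligned-region reading of the threshold). Passing proteins whose gene
models overlap on the same scaffold are collapsed to the longest protein
(redundant isoforms at one locus), ties broken by identifier.

EST support counts each expressed-sequence tag whose best infix alignment
into a CDS (edlib edit distance) reaches 95% identity at ≥ 100 bp. Because
homoeologous copies share high CDS identity, the pipeline tallies support
by assigning each EST to its single best-matching CDS (the parent gene
always wins at higher identity); a gene with zero assigned ESTs is flagged
"unsupported", never removed.

## Domain architecture

**DBD.** A position-weight profile scan: the packaged profile is a
synthetic consensus (94 residues, match probability 0.75 against a 0.05
background) constructed in-package as a composition-plausible stand-in for
a plant-Hsf DBD seed alignment; the generator plants instances of this same
profile, which keeps recovery tests closed-world. The best window above a
log-odds threshold of 100 is reported (well-conserved instances score
~180–250; unrelated sequence scores far below zero, and the empirical
false-positive rate on shuffled planted proteins is below 1%).

**HR-A/B coiled-coil.** A COILS-style windowed heptad model: every
28-residue window is scored in all seven registers as the mean log
propensity ratio of its residues at core (a/d) versus non-core positions,
using a packaged propensity table (hydrophobics favored at a/d, proline
strongly penalized everywhere). Residues inherit their best covering-window
score; runs above 0.2 merged across gaps ≤ 3 and at least 14 residues long
become coarse segments. Window scans blur boundaries by up to a window
width, which would corrupt the classification criterion, so the
architecture step refines them: the first chain of segments after the DBD
(joined across gaps ≤ 30, the span of a class-A insertion) fixes the
region and its best register; within it, per-residue log propensities
smoothed over 7 residues define runs, whose starts snap to the nearest
favorable core slot (up to one heptad back) and whose ends complete the
final heptad. Runs closer than 4 residues are rejoined and runs shorter
than two heptads are discarded as polar noise. The two highest-scoring
runs are HR-A and HR-B; the insertion is the gap strictly between them
(a single run means a compact region, insertion 0). Segments that bleed
backward over the DBD end are clipped, not discarded — otherwise short
linkers lose their HR-A entirely.

**Signal motifs.** Threshold-free patterns generalized from published
instances: NLS = ≥ 3 K/R in a 4–6 residue window (anywhere); NES = an
8–11 residue window with ≥ 3 large hydrophobics (L/I/V/M/F) of which ≥ 2
are leucines; AHA = an 8–10 residue window with ≥ 1 aromatic (W/F/Y),
≥ 1 large hydrophobic (L/I/V) and ≥ 2 acidic (D/E) residues. NES and AHA
are restricted to the C-terminal half, where the export and activator
elements reside. The hydrophobic requirement for AHA is ≥ 1 (not ≥ 2)
because published AHA instances such as DSFWEQFLCA contain exactly one
L/I/V; likewise the NES rule is windowed rather than a fixed-spacing
regular expression because published NES instances (e.g. LTEQMGLL) are too
short for the classical spacing pattern.

## Classification

The class call uses the HR-A/B insertion length as the primary criterion:
insertions of about 21 residues define class A, about 7 class C, and none
class B. The decision boundaries ≥ 15 → A, 4–14 → C, ≤ 3 → B bracket the
nominal sizes with midpoint cuts. The DBD-to-HR-A/B linker length
(class A: 9–39, B: 50–78, C: 14–49 residues) is a secondary consistency
check: a linker outside its class range raises `LINKER_OUT_OF_RANGE` but
never overrides the insertion-based call, since published tables contain
C-type genes whose printed spans imply linkers outside the stated C range.
Subclass labels (A1–A8, B1/B2/B4, C1/C2) are assigned only phylogenetically
(nearest labeled reference), never by thresholds.

## Phylogeny

Trees are built from the conserved N-proximal region (DBD start through
HR-A/B end). Distances are Poisson-corrected, d = −ln(1 − p), with
pairwise deletion (columns gapped in either row are dropped per pair);
p = 1 raises a saturation error except inside bootstrap replicates, where
it is clamped just below 1 (column resampling can transiently saturate a
fine pair). Trees are built by Saitou–Nei neighbor joining with
deterministic tie-breaking (smallest index pair) and negative branch
lengths clamped to zero. Bootstrap support resamples alignment columns
with replacement; support is the percentage of replicate trees containing
each bipartition of the full-alignment tree. Unlabeled leaves receive the
subclass of the nearest labeled leaf by patristic distance (ties: smaller
distance, then lexicographic reference id).

Multiple alignment is an input contract (any aligner may produce the
fixed-width matrix). The pipeline uses `mafft --auto` when the executable
is available and otherwise falls back to a built-in center-star progressive
aligner. The center-star construction is only adequate for closely related
sets: projecting two close sequences through a distant center can place
their residues in different columns and inflate their apparent distance,
which is why it is the fallback rather than the default.

## Genome organization

Homoeologs are detected per homoeologous chromosome group (1–7): candidate
pairs are mutual best hits (by alignment score) between subgenomes that
also pass the strict duplication rule — aligned identity > 80% **and**
alignment coverage > 80% of the longer gene. Triangulated triads (all
three cross-subgenome edges) are preferred over pairs; every gene joins at
most one group, and the accounting identity
3·triads + 2·pairs + singletons = family size holds for every grouping.

Duplicate gene pairs are all unordered pairs passing the same strict
80/80 rule, excluding pairs inside one homoeolog group. A duplication that
predates homoeolog divergence necessarily links every member of the two
descendant groups pairwise (each member is within a few percent identity
of its group's ancestor), so the pair list is collapsed to one
representative pair per group pair (highest identity) for reporting; the
mode is `same_chromosome` when both genes carry an identical chromosome
token, else `segmental`. Link tables are exported as Circos-style plain
text, one record per homoeolog or duplication relation.

## Network projection and enrichment

Family genes map to a reference proteome by reciprocal best hit under the
same E ≤ 1e−5 / identity ≥ 50% thresholds; each mapped gene inherits the
undirected interaction edges of its ortholog (self-loops dropped, edges
deduplicated; the mean degree is computed over mapped genes only). Term
enrichment of the interacting set is the exact upper-tail hypergeometric
probability (scipy) with Benjamini–Hochberg adjustment (statsmodels;
Bonferroni available), significant at q ≤ 0.01.

## Expression

FPKM matrices transform as log2(FPKM + 1); the pseudo-count of 1 preserves
zero ↦ zero. qPCR quantification is the Livak method: per condition,
replicate-paired ΔCt = Ct(target) − Ct(reference); ΔΔCt =
mean(ΔCt_treated) − mean(ΔCt_control); fold = 2^−ΔΔCt. Significance is a
two-sided Welch test on the replicate ΔCt values (α = 0.05), with the
convention that identical zero-variance groups give p = 1; Student's t can
be substituted. Reference-gene subtraction makes the fold change invariant
to any constant shift applied to one condition's cycle thresholds.

## The synthetic data generator

The generator's defaults are the study conditions: 78 family genes
(38 class A, 16 B, 24 C) organized into 17 triads, 7 pairs and 13
singletons across chromosome groups 1–7 and subgenomes A/B/D; 3
same-chromosome and 14 segmental duplicate pairs; 11 + 11 decoys; ESTs for
all but 2 genes; 15 genes with planted orthologs carrying 420 interaction
edges (mean 28 per mapped gene); and 13 qPCR genes with planted fold
changes (8 up, 5 down) under control/treated conditions with 3 replicates
and 0.05-cycle noise.

Sequences are built hierarchically: one fresh template per class (leader,
DBD instance sampled from the packaged profile at 0.9 match, linker drawn
uniformly from the class range out of a no-coil alphabet, two 4-heptad HR
blocks with the class-specific insertion — 21/7/0 residues, heptad-phase
preserving, proline at its core slots — and a tail carrying the planted
NLS/NES/AHA motifs); group ancestors derive from their class template at
12% divergence (fresh linker per group), duplicate-target ancestors from
their source group's ancestor at 4.5% (linker retained), members from
their group ancestor at 5%, and queries from the class templates at 20%.
All divergence is planted as an exact substitution count, not a Bernoulli
rate, so identity thresholds are met with deterministic margins at any
seed: homoeologs ≈ 90% identity > duplicates ≈ 86% > the 80% rule >
unrelated same-class genes ≈ 73% > members vs queries ≈ 65% > the 50%
screen threshold > decoy remnant DBDs ≈ 33%. Substitutions at HR core
slots are conservative (among L/I/V/M/F), linker substitutions stay within
the no-coil alphabet, and planted signal motifs and insertions are masked
from mutation, so manifest coordinates remain exact. Decoys either lack
the DBD entirely (coil plus background) or carry a diverged remnant DBD at
35% consensus match — below both the screen identity threshold and the
profile-scan threshold — emulating distant winged-helix proteins; their
remaining sequence avoids coil-forming residues. CDS sequences are random
reverse-translations; ESTs are exact substrings of the CDS (150–400 bp).
All randomness flows from a single integer seed through one generator
(expression tables use an independent child stream so they can be
regenerated without the proteome), and a fixed seed reproduces every
output byte for byte.

What the generator does **not** emulate: realistic codon usage or GC
content, indels (planted coordinates stay exact by construction), intron
sequences or exon structure beyond counts, genome-scale data volumes,
pseudogenes, partial gene models, or assembly artifacts. Passing recovery
tests therefore demonstrates that the pipeline's logic is correct under
its stated assumptions — not that the scanners' thresholds are optimal for
real proteomes, where domain divergence is not closed-world.

## Problem sizes and numerical choices

The recovery suite runs at about 100 proteins of roughly 300–550 residues
(78 family members plus 22 decoys), with all-pairs alignment cached so
each protein pair is aligned once. Bootstrap analyses in the tests and the
acceptance script use 200 replicates on the ~115-taxon family tree; the
pipeline default remains 1000. pI is found by bisection on the net-charge
curve (Bjellqvist pKa set, packaged and swappable) to 0.001 pH; molecular
weights use average residue masses plus one water, in kDa. Coordinates
are 1-based inclusive everywhere. The pI bisection is validated against a
1e−4-step grid search, local alignment against exhaustive enumeration of
order-preserving pairings (linear gap costs), the hypergeometric tail
against subset enumeration, and neighbor joining against exact recovery of
random additive trees and an independent implementation.

## Known limitations

- The DBD profile and coil propensity table are synthetic, closed-world
  artifacts; applying the scanners to real proteomes would require a
  profile built from a curated seed alignment and re-tuned thresholds.
- The measured insertion length carries ±3-residue smoothing slack on
  degraded (non-planted) coils; the class bands absorb this by design.
- Duplication detection reports group-collapsed representative pairs;
  tandem-array annotation (intervening-gene counts) is available as an
  off-by-default mode annotation, never a pass/fail filter.
- The center-star fallback aligner degrades on diverse families (see
  above); use mafft or supply a pre-computed alignment where possible.
- EST assignment is strand-naive (ESTs are generated forward-stranded).
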