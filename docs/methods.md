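# Methods

This note records the models, conventions and design decisions behind
`mitochar`, in the spirit of a package's statistical/algorithmic
documentation. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and the circular closure

All coordinates are 1-based inclusive, matching how mitogenome
annotations are printed; conversion to 0-based half-open happens only at
I/O edges. Features spanning the circular origin are split at read time
into two sub-spans sharing a gene id.

For consecutive genes `(a, b)` in start order (strand ignored — published
architecture tallies run on the single mixed-strand order):

* overlap = `a.end − b.start + 1` when positive;
* spacer = `b.start − a.end − 1` when positive;
* exact adjacency otherwise.

The circle is closed from the last gene back to the first using the
**declared** genome length: `spacer = L − last.end + first.start − 1`.
Consequence for the bundled MN564936 annotation: the annotation stops at
16,518 while the declared length is 16,815, so the unannotated 297-bp
tail becomes the closing spacer. The source annotation prints this
interval as 296 bp; we follow the arithmetic, expose the interval as
`closing_spacer` in the report, and tests accept ±1 bp on this single
documented case. Whether the tail is control-region continuation or a
pseudo-control region is not decidable from the annotation; we expose it
as unannotated sequence and do not guess.

Report totals use the occupancy definition — overlap bp is the coverage
excess `Σ lengths − covered positions`, spacer bp the uncovered
positions — which coincides with the pairwise definition whenever no
feature nests inside another, and keeps the circular conservation
identity `Σ lengths − overlap_bp + spacer_bp = L` exact even with nested
features (which are additionally flagged). Class-length totals do **not**
deduplicate overlaps: each gene contributes `end − start + 1`, the
convention used when tables report per-class totals. Because of the
overlaps, the per-class totals of a dense annotation can exceed published
"coding proportion" figures computed by other means; we report the
table-derived values and both spacer fractions (vs. genome length and
vs. last annotated coordinate) rather than reconciling externally printed
percentages.

## Composition and skew

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C); both are
scale-invariant so counts, fractions and percentages are interchangeable.
N (and any ambiguity code) is tallied separately and excluded from the
skew denominators, keeping skews defined on draft sequences. Per-gene
composition is computed on the coding (sense) strand — published gene
rows rarely state the strand; this is our documented assumption. Reports
round to 2 decimals by default (3 reproduces finer printed skews); full
precision is kept internally.

## Codon usage

Stop/start typing and translation use the vertebrate mitochondrial code
(NCBI transl_table=2; stops TAA, TAG, AGA, AGG). A gene length ≡ 1
(mod 3) with a trailing T is typed `T--`, ≡ 2 with trailing TA is `TA-`
(incomplete stops completed to UAA by polyadenylation); any other
remainder content is flagged annotation-inconsistent rather than
guessed. Internal stops warn but do not abort, so provisional annotations
remain analysable.

RSCU families come in two partitions. The default, `standard`, groups
codons by standard-nuclear-code amino acid (Leu 6, Ser 6, Arg 6 including
AGA/AGG, one 3-codon stop family): this is the grouping produced by the
common codon-usage software that published mitogenome tables descend
from, and the published 64-codon table bundled here is arithmetically
consistent only with it. The `mito` partition groups by transl_table=2
(Arg 4; stops UAA/UAG/AGA/AGG; Trp UGA+UGG; Met AUA+AUG) for users who
want code-faithful families. Counts include every complete triplet
(terminal complete stops included unless `include_stops=False`);
incomplete stops contribute nothing; codons containing N are skipped and
logged. Report rounding is 2 dp, half-up.

## tRNA cloverleaf folding

The fold is a constrained template search, not thermodynamic folding.
Template bounds: acceptor stem 6–7 pairs, DHU stem 3–4, anticodon stem
4–5 with a fixed 7-nt loop centred on the anticodon, TΨC stem 4–5,
acceptor→DHU linker 1–3 nt, DHU→anticodon linker 0–2 nt, D-loop 4–12 nt,
T-loop 5–9 nt, variable loop 3–23 nt, 0–4 unpaired 3′ nt, 0–1 unpaired 5′
nt. Every placement satisfying these bounds is enumerated; pairs score
+2 (Watson–Crick), +1 (G·U wobble; G/T in the DNA reading), −1
(otherwise), and the argmax is returned. A placement must form at least
15 WC/G·U pairs, else a no-cloverleaf error is raised. The tie-break is
fully deterministic: most WC+G·U pairs, then shortest variable loop, then
leftmost acceptor start, then lexicographic layout parameters. When the
annotated anticodon is supplied, placements are first restricted to those
centring it; if none exists, the search falls back to the unconstrained
space. Scoring weights and stem bounds are this package's choices, tuned
for structural agreement on well-formed tRNAs, not for replicating any
external predictor's scores; per-arm censuses on real accessions are
therefore soft targets. Following the field's descriptive convention, the
census counts every non-WC apposition as a "mismatch" and subclasses G·U
wobbles.

## Supermatrix preparation and topology checks

Alignment and Bayesian MCMC are delegated to external tools; this module
is pre/post-processing only. Per-gene blocks must already be equal-length
across taxa (an alignment-required error points to an external aligner
otherwise); genes concatenate in the canonical order nad1, nad2, cox1,
cox2, atp8, atp6, cox3, nad3, nad4l, nad4, nad5, cob, nad6, with missing
genes padded by `?`. "Removing missing parts" is interpreted as deleting
every column holding a missing/gap symbol in any taxon, behind a flag.
The emitted NEXUS encodes nst=6 rates=invgamma (GTR+G+I), 4 chains,
ngen=400000, samplefreq=100, burninfrac=0.25 — all overridable. Topology
assertions treat the tree as outgroup-rooted; a nested group passes iff
its leaves form a clade, genus names expanding to all matching leaves;
node supports are stored as generic supports regardless of how a source
labels them (posterior probabilities vs. bootstrap).

## Synthetic-genome generator

The generator's defaults are the study conditions of the bundled
reference: the exact MN564936 gene order, lengths, strands and
coordinates (hence 9 overlaps/32 bp, 22 spacers, 7 adjacencies on a
16,815-bp circle), its start/stop typing (GTG start for cox1; incomplete
stops on nad1, cox3, nad4), whole-genome base frequencies
(A .3006, C .3145, G .1478, T .2371), the published 64-codon counts as
PCG sampling weights, and 24 planted G·U wobble pairs distributed
8/6/3/7 over acceptor/DHU/anticodon/TΨC arms of the 22 tRNAs.

Emission order is: background sequence from the base frequencies, then
rRNA/control-region/PCG features, then tRNAs, so tRNA stems win overlap
conflicts; where a 1-bp gene overlap would break a tRNA's terminal stem
pair, the unshared partner base is adjusted to complement the shared
base — as in real overlapping tRNAs, the shared base serves both genes.
PCG codons are sampled from the weight vector restricted to the 60
non-stop codons of the mito code; planted starts/stops override the
terminal triplets. The `TruthRecord` is re-derived from the *emitted*
sequence by deliberately naive tallies (character counts, triplet
slicing, planted stem positions), so it always describes the genome
actually returned, including planted values perturbed inside overlap
regions (e.g. a PCG stop overwritten by a downstream tRNA is recorded as
such).

Synthetic tRNAs are built for identifiability, not sequence realism:
stems sit at the template maxima, loop/linker bases are drawn from
{A, C} (unpairable against each other), stem-boundary positions carry
A·A blockers, stem bases avoid repeats within distance two, and G·U
pairs are planted at interior stem positions only. This makes the
planted layout the essentially unique argmax of the fold search; a small
residual of equal-score relocations remains, which is why
planted-census recovery is asserted as a ≥95% rate rather than
exactly. Codon sampling necessarily excludes the four mito stop
triplets, which leaves a small negative AT-skew in coding sequence even
under uniform codon weights; the near-zero-skew symmetry check therefore
uses a non-coding gene plan. Taxon sets derive from one root genome by
i.i.d. per-site substitutions (rate ≤ 0.3, indel-free so genes stay
length-matched). One seeded RNG stream drives everything; identical
seeds give byte-identical output.

What passing on synthetic data does **not** show: real annotations have
ambiguous gene boundaries, heteroplasmy/Ns, loop sequences that can pair
spuriously, and tRNAs diverging from the canonical cloverleaf (notably
truncated DHU arms in some mito tRNAs); per-arm census agreement with
annotator-derived figures on real accessions is expected only
approximately.

## Problem sizes and numerical conventions in the test suite

The suite runs entirely offline: the published annotation/codon tables
are desk inputs, and everything else is generated. Sweeps use 100 seeded
genomes for end-to-end truth recovery, 12 for genome-embedded fold
censuses (264 tRNAs), 100–120 standalone tRNAs for recovery rates, 60
fuzzed feature sets (≤50 features) for the occupancy oracle and
conservation identity, and 10 random 10-leaf trees (all 3-subsets) for
the clade oracle; brute-force fold enumeration is checked on a handful of
≤80-nt sequences. Ratio comparisons use 1e−9 absolute tolerance; discrete
quantities are exact. Report rounding is half-up at 2 dp (skews also
shown at 3 dp where finer published precision exists).

## Known limitations

* No de novo annotation: gene calls are inputs.
* The folder's fixed 7-nt anticodon loop and stem bounds cannot express
  every real mitochondrial tRNA geometry.
* NEXUS parsing is limited to the dialect this package writes; taxon
  labels containing spaces are written with underscores and read back
  literally.
* Origin-spanning genes are handled as split parts in architecture
  accounting, but codon extraction across the origin assumes the split
  parts are provided in order.
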