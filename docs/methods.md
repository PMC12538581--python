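# Methods

## Model and assumptions

`phagesite` treats machine-learning promoter prediction scores as a proxy for
promoter strength: a prediction is a probability-like value *s* ∈ [0, 1]
attached to a motif footprint on one strand. The working hypothesis is that
the expression a payload experiences downstream of an intergenic stretch
scales with the density and strength of predicted promoters in that stretch.
This ignores transcription factors, RNA secondary structure, RNAP kinetics,
promoter bidirectionality beyond per-strand bookkeeping, and phage-encoded
polymerases — all of which can make individual loci deviate substantially
from the prediction. The pipeline is a ranking heuristic, not an expression
model.

### Coordinates

Everything internal is 0-based half-open on the forward strand. GenBank
input (1-based inclusive) is converted on read; BED output stays 0-based
half-open, GFF3 is emitted 1-based inclusive. Minus-strand positions in
prediction tables are given 1-based on the reverse-complement frame and are
reflected into forward coordinates on read, so that writing and re-reading a
table is the identity.

### Split genes and interior genes

A gene annotated as a multi-part `join` (typically a locus interrupted by an
intron-encoded homing endonuclease) is collapsed to the hull of its parts.
Genes fully nested inside such a hull are flagged *interior*: they remain as
annotation but create no intergenic boundary, so no insertion site can fall
between the parts of the interrupted locus. Genes that only partially
overlap a hull do break intergenic space. Coverage union is used for
overlapping same-strand annotations; overlap is never an error.

### Intergenic regions

Core spans are the maximal intervals not covered by any non-interior gene
body. Terminal spans before the first and after the last gene are kept for
linear genomes (the default); for circular genomes the two terminal spans
fuse into one wrap-around region. Zero-width cores between abutting genes
are kept (their extended span is still a valid search window); zero-width
spans at the genome edges are dropped. Each core is widened by the extension
E = 50 bp (default) into the flanking genes, clamped to genome bounds.

## Scoring

The weighting is fixed to w(s) = exp(s): strictly increasing, convex, and
w(0) = 1, so one promoter of score 0.921 yields a cumulative region score of
exp(0.921) = 2.5119 ≈ 2.51. The score threshold (default 0.5) is applied
when predictions are read or scanned, *before* weighting. One IPR is formed
per (region, strand); the region itself is the cluster — no sub-region
splitting is performed. A prediction whose footprint lies inside two
overlapping extended regions (possible when a gene is shorter than 2E) is
assigned to the region whose core midpoint is nearest the footprint
midpoint, and the assignment is logged. Ranking sorts by descending score
with ties broken by smaller span start, making output order deterministic.

### Built-in PWM scanner

So the pipeline runs without any external predictor, a two-box σ70 consensus
scanner is included: position weight matrices for TTGACA (−35) and TATAAT
(−10) with consensus-base probability 0.8 (off-consensus 0.2/3), spacer 15–19
bp, scored by summed log-odds against a uniform background. Every
(position, spacer) placement is scored independently on both strands. The
log-odds sum x is mapped to [0, 1] by a logistic 1/(1 + exp(−(x − 7)/1)):
the exact consensus (x ≈ 13.96) scores ≈ 0.999 and a typical random window
(E[x] ≈ −8.4) scores ≈ 10⁻⁷, keeping built-in scores commensurate with
external probability scores. Ambiguous bases (N) contribute zero log-odds.
The constants live in `PwmModel` and round-trip through a key-value text
file.

## Site selection

For each ranked IPR the first gene whose 5′ boundary lies at/after the IPR
hull in the IPR's reading direction *and* whose strand matches the IPR is
selected; there is no distance cap by default (a configurable cap exists).
IPRs with no such gene are skipped, and a gene is used at most once, by the
highest-ranking IPR that reaches it. The insertion point is the base
immediately past the selected gene's stop: `end` for + genes, `start` for −
genes. With a temporal-class table the top `per_class` (default 1) sites per
class are returned, in the table's class order; classes with no candidate
produce a warning, not an error.

## Donor design

Arms default to 400 bp and shrink toward the 200 bp minimum only when (a)
the genome edge forces it (below 200 bp is a hard error) or (b) a full-length
gene whose product annotation matches the avoid keywords ("hypothetical",
"unknown") would be wholly contained in the arm — a best-effort rule; if
avoidance would push the arm under 200 bp the long arm is kept and a warning
issued.

The duplication rule quantifies "preserve the downstream RBS" as follows:
with intergenic distance d from the selected gene's stop to the next gene's
start (in reading direction), if d < 20 the last (20 − d) bases of the
selected gene are appended after the cassette, restoring a full 20 bp of
native upstream context for the downstream gene. The trigger (20 bp) is
fixed by the design input; the duplicated *length* (20 − d) is this
package's documented reading of "the required bases" — the symmetric choice
that makes the post-edit 20 bp window bit-identical to the reference, which
the in-silico verification asserts.

Minus-strand designs are handled entirely in the forward frame: the cassette
is reverse-complemented and the duplicated bases are the gene's first
(20 − d) forward bases, which sit adjacent to the cassette on its upstream
side. This construction makes donor design an exact mirror: designing on the
reverse-complemented genome yields the reverse complement of the forward
donor (asserted as a property test).

`apply_edit_in_silico` verifies both arms base-by-base against the
reference, inserts the cassette (+ duplicated context), shifts downstream
annotations and adds a feature for the payload. Every original CDS must be
retrievable verbatim from the recombinant; a gene spanning the insertion
point (possible only with overlapping annotations) is flagged with a warning
as disrupted.

## Synthetic data

The generator emulates what the pipeline assumes about real phage genomes:
non-overlapping genes (800–1600 bp) separated by intergenic gaps
(180–320 bp) on a 30 kb genome at 35% GC (typical of *Staphylococcus*
phages), with operon-like strand runs by default (strand flips with
probability 0.25; `plus`, `alternating` and `random` patterns are
available). Planted clusters write σ70 consensus motifs (TTGACA + 17 bp +
TATAAT) into chosen intergenic cores and emit matching predictions whose
scores are drawn from a normal truncated to [0, 1] — simple, and sufficient
to produce the strong right-skew toward 1 seen in real predictor output.
Temporal classes are assigned as contiguous thirds of the *gene order*
rather than of raw genome coordinates: an unannotated tail would otherwise
leave a class empty, and gene-order thirds preserve the intended
early/middle/late block structure. All randomness flows from the single
config seed; identical seeds give byte-identical genomes, tables and
classes.

What the generator does **not** emulate: realistic codon statistics or gene
content, false-positive predictions outside planted regions, predictor
noise correlated with sequence composition, and validated-promoter ground
truth. Passing the recovery tests therefore shows the scoring and ranking
machinery is correct and stable under score noise — not that the upstream
predictor's scores track real promoter strength.

## Problem sizes and numerical choices

The oracle-equivalence suite uses 200 random genomes of 5–50 kb with up to
40 genes against a per-base coverage-mask oracle; cluster recovery uses 200
seeded simulations of the default 30 kb genome; both complete in seconds.
Scores are compared exactly (sums of exponentials of identical floats);
reported tables round to 4 decimals. Ties in ranking break on span start;
ties in region assignment break on first (leftmost) region. Degenerate
inputs: a genome fully tiled by genes yields an empty region list (not an
error); a sequence shorter than the minimal motif+spacer span yields no
scanner hits; an empty payload is rejected.

## Known limitations

- Circular-genome handling is implemented for region extraction
  (wrap-around region) but promoter assignment and donor design assume the
  insertion neighbourhood does not cross the origin.
- Multi-record (segmented) genomes, de novo gene calling and annotation
  correction are out of scope.
- Additive effects of multiple IPRs upstream of the same gene are not
  modeled; each IPR competes independently in the ranking.
- Temporal classes are consumed as an input table, never computed from
  expression data.
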