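# Methods

`mircnn` identifies plant miRNAs from small RNA-seq data by combining a
classical precursor-discovery pipeline with a small convolutional network
that classifies candidate hairpins from their raw sequence, secondary
structure and read-coverage signal. This note documents the model, the
defaults, and the design choices where the design was genuinely open.

## Discovery pipeline

**Read handling.** Input reads are assumed adapter-trimmed. They are
collapsed to unique sequences with counts, normalized to DNA (U→T, upper
case), and restricted to the canonical plant miRNA length range of 20–24
nt. Reads containing N are dropped (exact-match mapping cannot place
them); there is no quality filter in the core pipeline.

**Mapping.** Mature miRNA reads are genome-templated, so mapping is exact
and full-length on both strands, seeded by a k-mer index (k = 12) and
verified by string comparison. This removes any aligner dependency and is
deliberately mismatch-free; sequencing errors are therefore invisible to
the pipeline (see Limitations). Reads with more than 20 placements are
discarded as repeat-derived. Mapped loci are clustered per chromosome and
strand with a maximum gap of 100 nt, chosen so that the mature and star
reads of one precursor — at most ~200 nt apart, since plant precursors
are typically 100–200 nt — always co-cluster, while neighboring loci
separated by longer spacers do not.

**Window excision.** The most abundant read of a cluster is the putative
mature. Windows of 100, 150 and 200 nt are excised with three anchorings
(mature near the window 5' end with a 15-nt flank, centered, near the 3'
end), because the mature can sit on either precursor arm and the true
precursor extent is unknown. Windows are clipped to chromosome bounds and
kept only if still ≥ 100 nt. Ties between equally good windows resolve to
the shortest window and then to the window placing the mature closest to
the transcript 5' end — a deliberately strand-symmetric rule, so the same
locus planted on either strand yields the identical candidate.

**Folding.** The built-in folder maximizes the number of nested base
pairs (Nussinov dynamic program, numba-accelerated) over the pair set
{AU, UA, GC, CG, GU, UG} with a minimum hairpin loop of 3 nt. Base-pair
maximization was chosen over a thermodynamic model because it is
dependency-free and admits an exact brute-force enumeration oracle, which
the test suite exercises exhaustively at small lengths. The traceback is
deterministic: a position is left unpaired whenever an optimal structure
allows it, otherwise it pairs with its smallest feasible partner.
`fold()` is the single extension point — any callable returning the same
structure object (e.g. wrapping an energy-minimizing folder) can replace
it throughout the pipeline. Pair probabilities, suboptimal ensembles and
pseudoknots are out of scope.

**Hairpin decision.** A candidate passes when (a) the region spanning the
mature and its pairing partners closes exactly one terminal loop (a
multiloop with two or more branch stems between mature and partner region
fails; a single stem nested inside the connecting loop merely re-roots
the terminal loop and passes), (b) at least 60% of mature bases are
paired, and (c) every mature partner lies on one side of the mature span.
The 60% threshold is a configurable operationalization; no published
number exists for it. One candidate survives per cluster.

**Duplex annotation.** The star span is the mirror of the mature's
pairing partners shifted by the canonical Dicer 2-nt 3' overhang. Duplex
bookkeeping undoes that shift, so a perfect inverted repeat scores zero
mismatches. A candidate is rule-labeled miRNA when the duplex has at most
5 mismatched mature positions, at most 3 nucleotides in mature-side
asymmetric bulges, no secondary stem (a duplex base pairing away from its
expected arm), no internal loop longer than 5 nt, and when the reads
within the padded (±3 nt) mature/star spans carry at least 75% of the
locus read count. The 75% precise-processing rule and the 5-nt large-loop
cutoff are our operationalizations of the community criteria, which state
budgets for mismatches and bulges but not positional bookkeeping; both
are configurable. Mature positions unpaired beyond the first/last paired
base count as mismatches but not as bulges (no opposite-arm evidence).
`match_known` scores candidates against a reference set of mature miRNAs
by ungapped identity over all alignment offsets; strictly more than 18
identical bases marks a candidate as a known miRNA.

## Matrix encoding

Each candidate becomes a 7 × 200 matrix: rows 1–4 one-hot nucleotide
identity (A, U, C, G), rows 5–6 a structure code per column ([1,0]
paired, [0,1] unpaired, [0.5,0.5] for padding/gap columns), row 7 read
coverage normalized by the count of the locus's most abundant read, with
overlaps resolved by the per-position maximum. The structure code uses
two rows so that the scalar codes 1/0/0.5 appear verbatim while the
matrix height stays fixed; the width of 200 covers the longest window and
shorter precursors are right-padded. Height 7 and width 200 also make the
network's shape chain land on a valid final feature map. The encoding is
lossless for sequence and pairing state (a decode round-trip is tested)
and invariant to read order and to rescaling all counts.

## Network and training

The classifier is a LeNet-style stack: 2×2 convolution with 20 filters →
ReLU → 2×2 max pooling → 2×2 convolution with 60 filters → ReLU → 2×2 max
pooling → fully connected 500 units (identity activation) → fully
connected 2 units → softmax. Stride is 1 for convolutions, pooling is
non-overlapping, and no padding is used, giving the shape chain
1×7×200 → 20×6×199 → 20×3×99 → 60×2×98 → 60×1×49 → 2940 → 500 → 2.

Training minimizes the negative log likelihood with AdaDelta (ρ = 0.95,
ε = 1e-6 — the optimizer's customary defaults), Xavier-uniform
initialization, and dropout after each hidden layer at training time
only. The dropout coefficient of 0.9 is read as the **retain**
probability (drop 0.1), the convention of the JVM deep-learning framework
family this architecture is usually configured in; the opposite reading
would drop 90% of activations and cripple training. Epochs (15) and batch
size (32) are package defaults chosen so the network converges on the
simulated corpus in minutes on one CPU; both are configurable. All layers
are implemented directly in numpy (im2col convolution, analytic
gradients); the forward kernels are verified against naive-loop oracles
and the backward pass against finite differences during development.

**Evaluation protocol.** Stratified five-fold cross-validation with a
single user seed driving fold assignment, initialization, oversampling,
batch order and dropout masks, making runs bit-for-bit reproducible. The
minority class is oversampled with replacement to exact 1:1 parity inside
each training split only — held-out folds are never resampled, the
leakage-free ordering. Reported metrics (accuracy, precision, recall, F1
from the confusion counts) are the unweighted mean of per-fold values;
pooled counts are carried alongside. Ratios with vanishing denominators
are reported as NaN with a warning, never silently 0. The positive class
is called at p(miRNA) ≥ 0.5, ties to miRNA.

## Synthetic data

The simulator plants two locus classes on toy chromosomes separated by
~150–200 nt random spacers (always wider than the clustering gap):

* **miRNA loci** — fold-back precursors of 100–200 nt: a lower stem, the
  mature/star duplex with 0–4 designed mismatches of which at most 2 are
  nucleotides in one asymmetric bulge, a 3–8 bp upper stem, and a 4–15 nt
  terminal loop; mature on either arm, strand random. Reads form two
  sharp stacks — mature ~4:1 over star — with 90% of reads matching the
  designed 5' ends exactly and the rest jittered by 1–3 nt. Per-locus
  depth is 30–120 reads.
* **siRNA-like loci** — the hard negative class: inverted repeats that
  fold into hairpins just as well, but carrying 8–16 dispersed reads with
  heterogeneous 5' ends, so they fail the precise-processing rule rather
  than the structure filter.

Two constructions make the generator's guarantees hold by construction
rather than statistically. First, every designed-unpaired element
(terminal loop, mismatch columns, bulges, tails) is an adenosine run, the
upper stem is G/C-only, and neighbors of mismatch columns are forced to
G/C: under the AU/GC/GU pair set no designed-unpaired base can then pair
with anything nearby, so the max-pairing folder has no equal-score
alternative around the duplex and recovers the designed structure — the
annotation module reads the designed mismatch and bulge counts straight
off the fold. Second, siRNA arms carry symmetric imperfection columns
every ~12 nt, so no ≥20-nt arm read is a perfect reverse complement of
the opposite arm; without this, arm reads exact-map back onto the other
strand and create phantom single-read loci that masquerade as miRNAs
(a failure mode real inverted repeats genuinely exhibit).

What the simulator does **not** emulate: sequencing error (off by
default; exact mapping would silently drop erroneous reads), realistic
expression distributions across loci and tissues, genome-scale repeat
structure and multi-mapping ambiguity, polycistronic precursors, and
thermodynamically-weighted structure ensembles. Passing the simulated
experiments therefore demonstrates that the pipeline's stages compose
correctly and that the network can exploit the intended read-pattern and
structure signal; it does not measure performance on real libraries,
where precursor structure and read stacks are noisier than anything the
generator produces.

## Problem sizes and numerical choices

The discovery experiment uses 20 miRNA + 60 siRNA loci; the
classification experiment uses 400 miRNA + 1,200 siRNA loci (the 3:1
negative:positive imbalance typical of hairpin-forming loci in real
training data), yielding ~1,300–1,350 labeled candidates after the
pipeline, trained for 15 epochs per fold. These sizes were chosen as the
package's standard desk-scale study; they run in a few minutes on one
CPU. Further defaults: seed k = 12, max 20 placements per read,
clustering gap 100 nt, window set {100, 150, 200} with 15-nt mature
flanks, minimum hairpin loop 3 nt, mature-pairing threshold 0.6, duplex
read fraction 0.75 with ±3 nt span padding.

## Known limitations

Exact matching cannot place reads with sequencing errors or SNPs;
base-pair maximization over-pairs relative to thermodynamic folding and
has degenerate ties on repetitive sequence (resolved deterministically
but arbitrarily); multi-branched precursors and polycistrons are rejected
by the single-terminal-loop rule; the rule-based labels used for training
inherit every operationalization above, so a CNN trained on them can at
best reproduce those rules' view of the data; and cross-validation on
simulated loci measures pipeline-internal consistency, not accuracy on
real libraries.
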