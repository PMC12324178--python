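# Methods

## Read model and label grammar

A library layout is an ordered list of elements, each of one kind:
`fixed_sequence` (adapters; literal ACGT string), `random_fixed_length`
(CBC, UMI), `homopolymer` (polyT; one base identity plus a length range),
`variable_length` (the cDNA insert), and the implicit terminal `RANDOM`
flank. The shipped 10x 3′ v3 layout is
`ADAPTER5 · CBC(16) · UMI(12) · POLYT(10–60) · CDNA(100–500) · ADAPTER3`;
the adapter literals are the Read-1 primer suffix and a TSO-like sequence.
Layout files are 3-column tab-delimited text (`label  kind  spec`),
round-trippable through `parse_layout`/`serialize_layout`.

The layout doubles as a grammar over per-base labels. After run-length
aggregation and smoothing, a read is

* **valid** if its segment labels, with terminal `RANDOM` flanks of any
  length stripped, equal the element order forward (`+`) or reversed (`-`,
  the reverse-complemented molecule — element labels are invariant under
  reverse complement, so the reversed *order* is the complete signature);
* a **concatemer** if they parse as K ≥ 2 back-to-back fragment orders,
  each independently oriented. At `FWD|REV` and `REV|FWD` junctions the two
  adjacent identical element labels merge into a single run, so the parser
  allows one segment to serve as the last element of one fragment and the
  first of the next; fragment boundaries inside such shared segments are
  placed at the segment midpoint. Internal `RANDOM` runs of at most 30 bp
  are tolerated at junctions only (configurable);
* **invalid** otherwise.

Smoothing absorbs segments sandwiched between two segments of one same
label when they are shorter than the island tolerance (25 bp; two passes,
since a merge can expose a new sandwich). Per-base classifiers flicker and
occasionally hallucinate short elements inside longer runs; the absorption
scale is safe because in every legal structure the only same-label sandwich
filling is a merged double-adapter junction run (>= ~44 bp for these
adapters) — real elements never sit between two same-label neighbours.
Terminal flank zones are stripped robustly for the same reason: the largest
terminal run whose innermost segment is RANDOM and whose non-RANDOM members
are all <= 25 bp is treated as flank, since flank bases are random and any
short element call inside them is noise. A long element bordering the flank
(a real adapter) ends the zone and is preserved.

## Simulator

Reads are assembled element by element (CBCs drawn from a configurable cell
pool sampled from the whitelist, UMIs and inserts uniform random, polyT
length uniform in its range), reverse-complemented with probability
`orientation_mix` (default 0.5), and bracketed by uniform-random flanks of
0–70 bp. Concatemer artifacts join 2–3 independently sampled molecules
end-to-end with no spacer, flanked only at the outer termini; the eight
supported patterns enumerate the orientation sequences of Table-1-style
chimeras (`FWD_FWD` through `REV_REV_FWD`).

Errors are i.i.d. per base: with `p_ins` (0.05) a uniform-random base is
inserted before a base, inheriting its label so label runs stay contiguous;
the base itself is deleted with `p_del` (0.0613) or substituted to a
uniformly random *different* base with `p_sub` (0.05). Expected
post-injection length is `L (1 + p_ins − p_del)`; a Monte-Carlo test pins
this. Truth fragment spans are carried through injection by an explicit
coordinate map. The deletion default is 0.0613; some descriptions of this
error profile round it to 0.06, and the rate is a plain config field so
either is reproducible.

What the simulator does **not** model: homopolymer-length-dependent or
quality-conditioned error (real ONT error is not i.i.d.), base-composition
bias, real cDNA sequence content (inserts are uniform random, so the model
cannot exploit transcript sequence statistics — if anything this makes the
labeling task harder than on real data, since only the fixed elements and
global structure are informative), truncated or adapter-less molecules
beyond the concatemer patterns. Passing benchmarks therefore demonstrates
that the architecture recovers structure under heavy i.i.d. noise, not that
it transfers to any particular real run.

Whitelists are synthesized as unique uniform-random 16-mers. Real
chemistries ship curated lists; for correction benchmarks what matters is
the pairwise-distance distribution, which random barcodes reproduce.

## Network

Tokens (A,C,G,T,N → 1…5; 0 = pad) are embedded (dim 8 by default), passed
through a stack of same-padded Conv1D+ReLU layers (default one layer, 48
filters, kernel 7), a stack of bidirectional LSTMs (default one layer, 32
units per direction), and a time-distributed dense layer producing
per-base emission scores. Heads: softmax with masked categorical
cross-entropy, or a linear-chain CRF (transition matrix plus start/end
scores) trained by exact negative log-likelihood via forward–backward and
decoded by Viterbi. Optimization is Adam with global-norm gradient
clipping (5.0).

The implementation is plain NumPy with explicit backward passes (the LSTM
backward recurrence is a numba kernel; arrays are time-major so each
timestep touches contiguous memory). Correctness is enforced by
finite-difference gradient checks for both heads and by a
Viterbi-vs-exhaustive-enumeration oracle. Activations are masked after the
embedding and every conv layer and the recurrence freezes state at padded
steps, so padding is exactly inert: duplicating a batch with extra pad
columns leaves losses and predictions bit-comparable, and predictions are
independent of batch composition (tested).

Batching: reads are length-sorted and batches are sized so that
`batch_size × longest_member ≤ token budget` (training default 65,536
tokens; inference follows the same rule against the chunk's budget). The
pad class (id 0) is excluded from loss and metrics. All randomness
(simulation, initialization, shuffling, dropout) flows from explicit seeds;
training is bit-reproducible on CPU (tested).

## Reference training recipe

The reference models are deliberately small — CPU-trainable in minutes —
and are trained on a 50,000-read simulated set at the default error rates,
85% canonical / 15% artifacts across all eight patterns, both orientations.
Artifacts must be present in training so the CRF's transition matrix
learns the junction transitions (e.g. ADAPTER3→ADAPTER5) that concatemer
decoding requires. The fast softmax model trains two passes (Adam,
lr 0.01 then 0.003); the CRF variant warm-starts from the fast model's
encoder and fine-tunes one pass at lr 0.004, which is enough to fit its
transition parameters. Dropout is off for these small models (they
underfit rather than overfit at this scale).

## Annotation modes

`CRF` mode Viterbi-labels every read. `HYB` mode labels everything with
the fast softmax model and reprocesses through the CRF model those reads
that are structurally invalid **or** whose least-confident segment (mean
softmax probability over the segment) falls below 0.9. Both the predicate
and the threshold are package choices — "ambiguous" admits several
reasonable operationalizations — and are exposed as parameters.

## Demultiplexing

The observed CBC is cut from the read as a window padded by 4 bp on each
side of its annotated coordinates; reverse-oriented reads are
reverse-complemented before comparison because whitelists are defined on
the forward chemistry. Correction aligns each whitelist barcode as an
*infix* of the window (edlib HW mode, banded at the threshold): a unique
nearest entry within 2 edits assigns the read; a tie is ambiguous; anything
farther is unmatched. The infix window matters because boundary placement
under indel noise is irreducibly fuzzy by a base or two — insertions at an
element boundary make even the ground-truth boundary ambiguous — and
exact-segment global distance would charge every boundary shift as edits,
roughly tripling the apparent barcode error. With the window, only edits
inside the barcode count. ``correct_barcode`` itself retains plain global
Levenshtein semantics (unique argmin within the threshold) and is tested
against a dynamic-programming oracle and an exhaustive scan.
The production corrector uses an exact-match fast path plus a pigeonhole
substring prefilter (each whitelist barcode split into `max_dist + 1`
pieces; any entry within `max_dist` edits must contain one piece verbatim),
and is tested equal to the exhaustive scan.

## Duplicate marking

Within each (reference, strand, cell) partition, reads chain into candidate
sets by single linkage on |Δstart| ≤ 10 **and** |Δend| ≤ 10; "similar
coordinates" could also be read as anchored windows, so the single-linkage
choice is pinned by an all-pairs brute-force oracle test. Within a
candidate set UMIs cluster by single linkage at edit distance ≤ 2; each
cluster of ≥ 2 keeps one representative (highest MAPQ, then smallest start,
then lexicographically smallest read id) and the rest get the 0x400 flag
and a shared `UG:i` group tag. Only primary alignments with CB/UB tags
participate; others pass through unchanged with a warning.

## Benchmark definitions and problem sizes

All headline quantities are recomputed from scratch by
`scripts/acceptance.py` at the package's reference scale, chosen so the
full benchmark trains and evaluates in minutes on one CPU core:

* **Structural-filtering accuracy** — 20,000 held-out canonical plus 2,000
  artifact reads; a read scores when `status == valid` matches its ground
  truth. Reported per annotation mode; the script's single value is the
  lower of the two.
* **Demultiplexing efficiency** — fraction of structurally valid reads
  (hybrid mode) whose observed CBC receives a unique whitelist assignment
  at distance ≤ 2, whether or not it is the generating barcode; the
  truth-correct fraction is logged alongside.
* **Sub-fragment recovery** — 2,000 fresh artifact reads spanning all eight
  patterns; a true sub-fragment is recovered when the CRF concatemer call
  contains an unused sub-span with the same orientation and Jaccard overlap
  ≥ 0.75. Classification-level recovery (fragment count, orientations and
  approximate boundaries), not base-exact splitting.

## Known limitations

* The i.i.d. error model understates structured ONT error; boundary
  placement on real homopolymer-rich reads will be noisier than measured
  here.
* The CRF enforces pairwise transition preferences, not the full grammar;
  the grammar validator downstream is what guarantees structural calls.
* Expected demultiplexing efficiency is bounded by the error model: at the
  default rates a 16 bp barcode carries Binomial(16, 0.161) ≈ 2.6 expected
  edits, so only ≈ 55–60% of reads can lie within distance 2 of any
  barcode; see the benchmark output for the measured value.
* `dedup` consumes any coordinate-sorted BAM with CB/UB tags but considers
  primary alignments only; supplementary-alignment rescue is out of scope.
* Thread parameters are accepted for interface stability; this
  implementation is single-process.
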