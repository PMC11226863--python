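# Methods

## Sequence primitives

The standard genetic code (table 1) is built from Biopython's codon table;
synonymous families are stored sorted lexicographically so every
iteration, tie-break and tokenization order is deterministic. Alternative
codes can be supplied as a `GeneticCode` instance; there is no NCBI
table-id machinery and ambiguity codes are rejected rather than guessed.

**CAI.** Relative adaptiveness is w(c) = f(c) / max over the family, with
frequencies normalized over all 64 codons. The geometric mean runs over
the *coding* codons of a sequence: a trailing stop is excluded, and
single-codon families are included (their w = 1 cannot lower the product
but does enter the length normalization — the convention used by the
EMBOSS `cai` program). Codons never observed in the reference corpus get
a pseudo-count of 0.5 before normalization so CAI is always finite; the
constant is `seqcore.ZERO_COUNT_FLOOR`. Usage tables are serialized as
counts per million, which keeps the pseudo-count floor negligible on a
write/read round trip.

**One-codon optimization.** Each residue maps to its family's most
frequent codon; ties break to the lexicographically smallest codon so runs
are reproducible across platforms. Two identities follow directly from the
definitions and are enforced as universally quantified tests: the
optimized sequence translates back exactly, and its CAI against the
optimizing table is exactly 1.

## Corpus construction

`filter_by_tpm` keeps records with TPM **strictly greater** than the
threshold (default 5). CAI and minimum-free-energy bounds are optional;
an MFE bound requires a folding backend (the `RNAfold` adapter) and its
absence is a raised error, never a silent pass. `mix_jcat` replaces the
CDS of a uniformly sampled round(p·n) subset with one-codon optimized
sequences; the shipped admixture series (0, 0.1, 0.25, 0.5) is this
package's default preset. All sampling flows through explicitly passed
seeded generators — no global random state anywhere in the package.

## The synthetic generator

Desk-scale experiments run on synthetic corpora that emulate a set of
highly expressed coding sequences:

* proteins are uniform over the 20 letters, lengths uniform in a range
  (default 30–60 codons);
* the synonymous choice for each residue follows a **planted** per-family
  categorical distribution. The default planted table draws each family's
  distribution from a Dirichlet with concentration α = 0.1, i.e. strongly
  biased families whose modal codon carries ≈ 0.8 of the family mass.
  Strong bias is the regime characteristic of highly expressed
  transcripts, and it is also what makes recovery measurable: argmax
  decoding necessarily concentrates on conditional modes, so a corpus
  with weak planted bias cannot be matched closely in pooled usage by
  *any* deterministic decoder;
* first-order context: with probability `pair_dependence` the choice is
  drawn instead from the planted distribution tilted by a factor e^κ
  (κ = 1) toward codons whose first base repeats the previous codon's
  third base — a minimal, learnable stand-in for bicodon preference;
* `deterministic_rule` replaces sampling with a fixed function of the
  previous residue: codon index = alphabet rank of the previous amino
  acid modulo family size (first position: the lexicographically first
  codon). This makes perfect decoding achievable, isolating the
  model/curriculum question from irreducible sampling noise.

What the generator does **not** emulate: real length distributions, amino
acid composition, GC-content constraints, secondary-structure selection,
or higher-order (beyond first-order) codon context. Passing the recovery
tests therefore shows the architecture and curriculum can extract planted
usage and pair preferences from data of this shape — not that the model
matches biological corpora.

## Architecture

Both streams are embedded with learned token embeddings plus a **shared**
learned absolute position embedding (the two streams index the same
residue positions). Each of the `n_blocks` encoder blocks applies, with a
residual connection and post-layer-norm around every sublayer:

1. self-attention within the amino-acid stream;
2. self-attention within the codon stream (the codon side mirrors the
   amino-acid side block-for-block);
3. cross-attention — queries from the amino-acid stream, keys *and*
   values from the codon stream — updating the amino-acid stream;
4. a position-wise feed-forward (GELU) on each stream.

The codon head reads the amino-acid stream's final states (the query
positions are the ones that must emit codons); the amino-acid head reads
the codon stream's final states. PAD key positions are masked out of every
attention; changing token content at PAD positions provably cannot change
outputs at real positions (tested).

Whole-sequence hiding is implemented at the embedding output: a hidden row
of the codon stream becomes exactly the zero tensor (token *and* position
contributions), not a learned MASK embedding, so inference-time input is a
true zero placeholder. With all-zero keys and values, cross-attention
degenerates gracefully (uniform attention over zero values plus residual).

The network and its backward passes are written in NumPy (float64):
dense, layer-norm, multi-head attention and embedding layers each carry an
explicit `backward`. The full composite gradient is verified against
central differences in the test suite (relative tolerance 1e-4 at
ε = 1e-6). The closed-form parameter count
(vocab + position embeddings, 3 attention modules + 5 layer norms +
2 feed-forwards per block, 2 heads) is asserted against the framework
count.

**Presets.** `ModelConfig.tiny()`: embed 64, 2 blocks, 4 heads,
feed-forward 128 — the desk-scale configuration used by every experiment
here. `ModelConfig.large()` (embed 256, 6 blocks, 8 heads) is provided for
real corpora; both are this package's own choices.

## Training

Masked-LM objective: mean cross-entropy over labelled codon positions plus
mean cross-entropy over labelled amino-acid positions, equally weighted.
Visible rows are supervised only at masked token positions (default rate
0.15 per stream, the conventional masked-LM rate; masked tokens are always
replaced by MASK — no 80/10/10 split, a deliberate simplification).
Hidden rows are supervised at **every** real position.

The hiding curriculum is
`fraction(e) = 0` for `e ≤ warmup`, else
`min(1, increment · ⌈(e − warmup)/step⌉)`, and exactly 1 for
`e > full_mask_epoch`. With the standard constants (warmup 15, step 15,
increment 0.05, full at 300) this yields 0 through epoch 15, 5% at epochs
16–30, 95% at epoch 300 and 100% beyond it; the boundary arithmetic is
fixed by this formula, and the function is monotone by construction. The
schedule is fully parametric; `CurriculumSchedule.compressed()` (warmup 1,
step 1, increment 0.2, full at 6) preserves the shape at desk scale.

Optimization is Adam with fixed learning rate (default 1e-3). The
per-epoch RNG is forked from `(seed, epoch)`, so training is bitwise
reproducible on one device and a checkpoint-resumed run reproduces the
straight run's history exactly (optimizer moments are checkpointed).
The hidden-row fraction applies per batch ("5% of the codon sequences in
each batch"), rounded to the nearest row count.

**Desk-scale preset.** `TrainConfig.compressed()` uses batch size 8 and
learning rate 3e-3: 25 epochs over 500 short sequences give only a few
hundred optimizer steps, and the default 1e-3/16 leaves the tiny model far
from convergence within that budget. The larger step size is stable at
this model size (float64, post-norm) and brings the deterministic-rule
study to its ceiling.

## Evaluation

Decoding is one forward pass with the codon stream hidden plus
position-wise argmax; no iterative refill. `constrain=True` restricts each
position's argmax to the residue's synonymous family, making 100%
amino-acid fidelity a construction-time guarantee (tested on untrained
models); unconstrained decoding reports amino-acid fidelity separately,
since accuracy-vs-reference alone cannot distinguish synonymous from
non-synonymous errors.

Per-sequence codon accuracy is summarized across sequences by the
**median**. Usage vectors are pooled codon frequencies (64, lexicographic
order); bicodon vectors count ordered adjacent pairs within sequences only
(4096); both normalized to sum 1 and compared to the training corpus by
Pearson correlation. MFE is an adapter around an external `RNAfold`
executable; per-sequence failures are recorded, never fatal, and an absent
backend is a detectable condition.

## Desk-scale studies and their sizes

* **Accuracy study**: 500 training / 100 held-out deterministic-rule
  sequences (30–60 codons), tiny preset, compressed curriculum, 25
  epochs. Median held-out accuracy reaches 100% (≈96% of sequences decode
  perfectly); ≈2 minutes on one CPU core.
* **Usage-recovery study**: planted α = 0.1 table, `pair_dependence`
   0.5, same corpus sizes, compressed curriculum run for 40 epochs
  (the few extra minutes buy convergence margin on unlucky seeds).
  Decoded-set vs training-corpus PCC ≥ 0.95 (usage) and ≥ 0.90 (bicodon)
  across three seeds; ≈4 minutes per seed.

## Known limitations

* Argmax decoding is deterministic; it cannot reproduce the *within*-
  context entropy of a stochastic corpus, only its conditional modes.
  Sampling decoders would trade accuracy for usage diversity.
* The NumPy implementation is single-device and CPU-bound; it is sized
  for corpora of hundreds to thousands of short sequences, not
  transcriptome scale.
* Learned absolute positions cap sequence length at `max_len`; longer
  proteins require a larger preset, there is no length extrapolation.
* Tissue-specific corpora, genome downloads and identifier mapping are
  out of scope; corpora enter as FASTA (+ optional TPM TSV).
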