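# Methods

## Model

RNA design is treated as a constraint satisfaction problem over motifs.
A design space S = (m_1, …, m_k) is an ordered list of motifs, each a
pair of a sequence constraint fragment over {A, C, G, U, ?} and a
structure constraint fragment over {., (, ), ?}; the two-character token
`?*` marks a region unconstrained in both channels and of arbitrary
length. Objectives are relations over the concatenated assignment:

* hard constraints — every concrete symbol must be matched exactly by
  the candidate (sequence channel) and by its predicted structure
  (structure channel);
* the folding relation — the predicted structure of the designed
  sequence must satisfy the concrete structure symbols, with the
  predictor treated as a parameter (ViennaRNA MFE by default, MEA or
  the bundled Nussinov folder as alternatives);
* scalar objectives — GC content with a tolerance band, or plug-in
  scores through the adapter transforms described below.

Structure constraints are *not* required to be balanced. A lone bracket
constrains a position to be paired without naming the partner; the pair
table used internally matches brackets by stack discipline and leaves
unmatched brackets partnerless.

### Task sampling

A variable-length space is interpreted as a family of fixed-length
tasks. Sampling first draws the total length uniformly from the
feasible interval (lower bound clamped to the number of fixed tokens),
then splits the surplus across the `?*` regions uniformly over weak
compositions (stars and bars), so every split, including empty regions,
is equally likely. No distribution over compositions is canonical for
this problem; the uniform choice maximises structural diversity at
every sampled length and is isolated in one function. All randomness
flows through an injected seeded generator — there is no module-level
random state anywhere in the package.

IUPAC degenerate codes are accepted in motif sequence parts so that
published motif notation (e.g. a GNRA tetraloop) can be pasted
verbatim. They survive parsing and rendering but are relaxed to `?`
when a fixed-length task is instantiated: generation treats them as
free positions, and a caller who needs them enforced can filter
candidates against the original motif.

## The decision process

One episode designs one candidate. The task is encoded by indexing the
(sequence, structure) symbol pair at each position as `4·s + t` with
sequence order A, C, G, U, ? and structure order ., (, ), ? (20 pair
symbols), plus a padding symbol (#, #) with index 20; κ pads are
prepended and appended. The observation at step t is the (2κ+1)-gram
centred on the t-th unconstrained sequence position. Parameters:

| parameter | meaning | default |
| --- | --- | --- |
| κ (`state_radius`) | observation half-width | 16 |
| σ (`include_actions_in_state`) | placed nucleotides replace wildcards in later observations | on |
| `action_semantics` | place Watson–Crick pairs at matched brackets | on |
| α | reward shaping exponent | 1.0 |
| β, γ | structure / GC loss weights | 1.0, 1.0 |
| ε (`gc_tolerance`) | GC tolerance band (fraction) | 0.01 |
| `restart_interval` | wall-clock weight reset period (s) | 1800 |

Design decisions the formulation leaves open, fixed here:

* visit order is left to right over unconstrained sequence positions;
  a partner auto-filled by a pair action is removed from the order;
* actions map 0→A, 1→G, 2→C, 3→U; the pair action writes the
  complement (A↔U, G↔C) at the partner site;
* when the matched partner of an opening bracket is sequence-
  constrained, only the current position is written — constrained
  positions are never overwritten, so the hard sequence constraints
  hold by construction at the end of every episode;
* with σ on, observations are recomputed from the task plus the fills,
  making the observation a pure function of (task, fills).

The reward is computed only at the terminal step: the full sequence is
folded and scored (1 − L/|ω̄|)^α where L counts violated structure
constraints, or the weighted structure+GC form clipped at zero when the
weighted loss exceeds one.

## Policy and training

The policy maps the observation window to a distribution over the four
actions: symbol embedding (size 8) → optional 1-D convolutions (default
one layer, kernel 3, 8 channels) → optional LSTM layers (default 1,
hidden size equal to its input width; forget-gate bias initialised to
1) → dense layers (default one of 32 units) → linear head and softmax.
The network is implemented directly in NumPy with hand-written
backpropagation; the test suite verifies the gradients against central
finite differences for conv/LSTM/dense configurations.

Training is synchronous minibatch REINFORCE: trajectories are collected
for `batch_size` episodes (default 32), advantages are episode reward
minus an exponential moving-average baseline (decay 0.99), an entropy
bonus (weight 5·10⁻³) discourages premature collapse, the global
gradient norm is clipped at 5, and parameters are updated with Adam
(learning rate 10⁻³). Updates are deliberately synchronous — an
asynchronous scheme would be faster on many cores but makes runs
irreproducible; with a fixed seed every training run and design stream
is bit-reproducible.

During design the agent keeps updating between episodes (adaptation)
and resets its weights to the stored initial values whenever
`restart_interval` elapses, which escapes adaptation dead ends in long
runs. Two refinement steps polish near-solutions:

* local improvement: when 1–5 structure constraints are violated, all
  nucleotide assignments to the free positions within one position of a
  violation are enumerated (at most 6 positions, nearest first) and the
  assignment with minimal structure loss is kept;
* GC improvement (active when a GC target is set): greedy single-
  nucleotide mutations at free positions toward the target, each step
  choosing the mutation with the smallest structure-loss increase,
  until the tolerance is met or no mutation helps.

Both steps only touch unconstrained positions. The 5-mismatch gate and
the enumeration caps are this package's choices; they bound the number
of extra folds per candidate.

## Structure distance

Besides the positional Hamming loss, a Weisfeiler–Lehman distance
between secondary structures is provided. Each structure becomes a
graph with positions as nodes (labelled by their structure symbol) and
backbone plus matched-pair edges. Labels are refined for h rounds
(default 2) by hashing each label with the sorted multiset of neighbour
labels; the feature vector counts every label over all rounds. The
distance is 1 − cosine(ψ(G₁), ψ(G₂)). A raw dot product grows
unboundedly with structure length, so the cosine normalisation is used
to keep the distance in [0, 1] with d(s, s) = 0; this normalisation is
a deliberate choice and is pinned by tests against an independent
oracle implementation.

## Plug-in objectives

External scorers attach through two transforms: covariance-model
bitscores are used directly with −200 substituted when the scorer
reports no match (so a non-matching candidate is strongly penalised but
finite), and RNA–RNA interaction energies E (negative is better) are
mapped to (−E)³ to reward low-energy complexes steeply. The scorers
themselves (alignment/search executables) are outside the package;
only the reward contracts are implemented.

## Synthetic training corpus

The corpus generator emulates a database-derived training set without
any download: uniform-random sequences with lengths drawn from one of
three regimes — short (50–200 nt), long (200–450 nt), mixed (50–450 nt)
— folded by the configured engine. The short/long/mixed split mirrors
training sets restricted to ≤200 nt, ≥200 nt, and unrestricted lengths;
the 450 nt cap and 50 nt floor keep desk-scale folding affordable and
are configuration, not dogma. What the generator does **not** emulate:
the base composition, conservation patterns and structural classes of
natural RNA families. Passing tests therefore demonstrate the
correctness of the machinery and learnability of synthetic design
tasks, not performance on natural-RNA benchmarks.

Masking turns a (sequence, structure) pair into a training task:

1. draw a part count uniformly from {0, …, 5} and mask that many
   non-overlapping structure intervals, each of length up to 20% of the
   total (interval positions and lengths uniform; overlapping draws are
   retried a bounded number of times, so occasionally fewer parts are
   placed). Zero parts is deliberately included so pure
   inverse-folding tasks (fully masked sequence, complete structure)
   arise naturally;
2. mask the sequence exactly where the structure remained unmasked —
   the alternating-constraints pattern, under which no position is
   constrained in both channels;
3. with probability 0.2 a sample instead receives independent random
   sequence masking (each position masked with probability 0.5,
   structure masking kept as drawn), emulating design from arbitrary
   mixed motifs. The within-sample density of 0.5 is this package's
   choice.

## The riboswitch protocol

The riboswitch experiment designs transcription-regulating theophylline
riboswitch constructs: TCT8-4 aptamer + spacer (6–20 nt) + a 10–21 nt
region complementary to the aptamer 3'-end (forming the terminator
hairpin) + an 8-U stretch. The design-space record bundled here is a
**synthetic reconstruction** built from that published construction
protocol (see `synthetic_riboswitch_definition`): the sequence channel
fixes the 42-nt aptamer, the reverse complement of its 3' decamer and
the U-tail, with `?*` regions between them (total length 66–91 nt); the
structure channel requires the aptamer's core hairpin (positions
12–26), a 10-bp terminator helix (aptamer 3' decamer paired with the
fixed complement) and an unpaired U-stretch. Two printed properties of
the original space are reproduced exactly by this reconstruction: the
length bounds (aptamer + 24 to aptamer + 49) and the analytic
GC-content margins, 26/91 = 0.29 to 57/91 = 0.63 after rounding.

The motif language carries only global length bounds, so the rendered
design space lets the surplus length split freely between the spacer
and the complement extension; the random-baseline sampler enforces the
per-region bounds of the protocol, while the agent explores the relaxed
space.

Validity of a candidate is the conjunction of the hard sequence
constraints and the structure constraints of the design space
instantiated at the candidate's region lengths, applied to the MFE
fold; per-criterion outcomes are logged. Library reports count unique
structures by exact dot-bracket equality, both over the valid
candidates (`unique_structures`, the diversity of the designed library)
and over all candidates (`unique_structures_all`). The valid-only count
is the headline number: a library overview describes the constructs
that pass the design criteria, and under the reconstruction it is the
quantity consistent with the published library statistics, while the
all-candidates count is ~2.5× larger.

`gc_bounds` is analytic: concrete nucleotides contribute fixed GC,
every free position can be A/U or G/C, and both extremes are attained
at the maximal total length; no sampling is involved.

## Problem sizes and tolerances

The acceptance script builds one 50,000-candidate random library (the
published library size, used for the diversity count) plus four
10,000-candidate libraries for the valid fraction, whose binomial
standard error at 10,000 is already below 0.5 points. The agent
comparison trains for 1,500 episodes and designs 2,000 candidates with
adaptation and local improvement — a deliberately small policy
(embedding 6, one dense layer of 32, κ = 8) which is enough to beat the
random baseline by a wide margin at this scale. Full-scale training
budgets would be needed to claim the published absolute agent numbers;
the desk-scale check is monotone (agent > baseline), and the observed
agent valid fractions at this scale happen to land close to the
published full-scale value.

Numerical details: the Nussinov folder maximises canonical pairs
(Watson–Crick + GU wobble, minimum hairpin 3) with deterministic
tie-breaks (prefer unpaired, then the earliest pairing partner); note
the episode pair action places only Watson–Crick pairs while the folder
also scores GU — a documented asymmetry matching biological pairing.
Softmax logits are max-shifted before exponentiation; probabilities are
floored at 10⁻¹² inside logs.

## Known limitations

* No pseudoknots, no multi-target structures, no partition-function
  objectives.
* The bundled corpus is synthetic; results on it do not transfer
  quantitatively to natural RNA families.
* The riboswitch design-space record is a reconstruction; quantities
  that depend on its exact structure channel (validity fraction,
  structure diversity) are reproduced at the few-percent level, not
  bit-exactly.
* Training is single-process and CPU-bound by design; no GPU path.
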