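# rnadesign

Motif-based RNA design: a wildcard constraint language for RNA
sequence/structure design spaces, and a reinforcement-learning designer
that fills the unconstrained positions to produce libraries of
variable-length candidates with desired properties.

## Who this is for

RNA engineers who start from fragments with known function — an aptamer,
a tetraloop, a terminator — and need many candidate constructs around
those fragments rather than one solution to a rigid, fixed-length
inverse-folding task. `rnadesign` lets you write down *what you know*
(sequence and structure constraints at individual positions, regions of
entirely unknown length and composition) and ask for as many candidates
as you want, scored against configurable objectives.

## The design-space language

A design space is a pair of constraint strings over

* sequence symbols `A C G U`, the wildcard `?` (any nucleotide) and
  `?*` (an unconstrained region of arbitrary, possibly zero, length);
  IUPAC degenerate codes (`N`, `R`, ...) are accepted and treated as
  unconstrained during generation,
* structure symbols `.` (unpaired), `(`/`)` (paired) with the same two
  wildcards. Brackets need not be balanced: a lone `(` demands a paired
  position without naming its partner.

For example, a stem of unspecified length carrying a GNRA tetraloop,
with free flanking regions:

```
sequence: ?*?GNRA??*
structure: ?*(....)?*
```

Formally the space is an ordered list of motifs m_i = (φ̂_i, ω̂_i); each
motif carries a sequence variable and a structure variable, and
objectives are relations over the concatenated assignment — hard
positional constraints, the folding relation F(φ) = ω (MFE or MEA
prediction), GC content, or plug-in scores. A solution is any
variable-length candidate that satisfies all attached objectives, so a
single run yields a focused library rather than a point solution.

## The designer

Generation is episodic: a fixed-length task τ = (φ̄, ω̄) is sampled from
the design space (total length uniform within the bounds, surplus split
uniformly over the variable regions), and a policy network fills the
unconstrained sequence positions left to right. The observation at step
t is the (2κ+1)-gram of the numerically encoded task centred on the
t-th unconstrained position; actions place a nucleotide, or a
Watson–Crick pair when the position is a matched opening bracket. At
the terminal step the sequence is folded and rewarded with

  R_T = (1 − L_ω̄ / |ω̄|)^α,

where L_ω̄ counts violated structure constraints, optionally combined
with a GC-content loss: R_T = (1 − (β·L_ω̄/|ω̄| + γ·L_GC))^α, clipped to
zero. The policy (embedding → optional 1-D convolutions → optional LSTM
→ dense softmax head, implemented in NumPy with manual gradients) is
trained by minibatch REINFORCE on masked tasks derived from a corpus,
keeps adapting during design, and periodically restarts from its
initial weights. Near-solutions are polished by an exhaustive local
improvement step and a greedy GC improvement step.

## Worked example

```bash
cat > gnra.txt <<'EOF'
sequence: ?*?GNRA??*
structure: ?*(....)?*
EOF
rnadesign design --input-file gnra.txt -n 5 --min-len 12 --max-len 30 \
    --seed 7 --out gnra_run
```

prints `5 candidates written to gnra_run.fasta / gnra_run.tsv (3 solved)`
and the sidecar table

```
id      sequence                        structure                       length  gc      score_solved  score_structure
cand_0  UUAGUAUUGGGGGCACGAAAGUAACAACG   ........(..(..((....))..)..).   29      0.4483  1             1
cand_1  CCCAAACAGAUAGUCUCCAGCGAAAGC     ...................((....))     27      0.5185  1             1
cand_2  AGAAAAAGUCCCCA                  ..............                  14      0.4286  0             0.857143
cand_3  AGAUACCGGCAACGUUCAAUCA          .(((..((....))....))).          22      0.4545  1             1
cand_4  CCGGAAUGCGUAAGAAAGC             .......((........))             19      0.5263  0             0.947368
```

Each row is one sampled task solved in a single episode: candidates have
different lengths, every one contains the GNRA motif, `score_structure`
is the normalised structure reward (1 means every structure constraint
of the sampled task is met by the MFE fold) and `score_solved` flags
candidates satisfying all hard constraints. A manifest
(`gnra_run.manifest.yaml`) records the full configuration, seed and
engine so the run can be reproduced exactly.

The riboswitch protocol — a theophylline aptamer, a 6–20 nt spacer, a
10–21 nt region complementary to the aptamer 3'-end (the terminator
hairpin) and an 8-U tail — is available as a subcommand:

```bash
rnadesign riboswitch --n 10000 --seeds 2 --method baseline --report rs.tsv
```

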