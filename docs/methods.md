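# Methods

This note documents the model behind `seqforge`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Problem formulation

A design is a pair `z = (s, b)`: a DNA sequence `s` over {A,C,G,T} and an
ordered partition `b` of `[0, len(s))` into contiguous blocks, each block
to be synthesized as one fragment. Edits to `s` are restricted to
synonymous codon substitutions inside annotated CDSs, so every design
encodes exactly the proteins of the input; edits to `b` are restricted by
the synthesizable fragment bounds `l_min ≤ l(block) ≤ l_max`. All
objectives are minimized; design `u` dominates `v` when `u` is no worse
in every objective and strictly better in at least one. The result of a
run is (an approximation of) the Pareto set of this problem, not a single
design.

Coordinates are 0-based half-open everywhere in memory; GenBank's 1-based
inclusive locations are converted at the I/O boundary. Minus-strand CDSs
are reverse-complemented before codon-level work and written back in
place, which keeps every operator strand-agnostic. Ambiguity codes are
rejected at load time, since the objectives and operators are defined
only over the four-letter alphabet. Circular sequences and non-standard
genetic codes are out of scope.

## Objectives and their bounds

| objective | form | ideal | nadir |
|---|---|---|---|
| gc | Σ_blocks \|T_GC − GC(b)\| | 0 | heuristic (below) |
| codon_usage | Σ_codons (Q(aa(c)) − q(c)) | 0 | all codons at the rarest synonym |
| block_variance | population variance of block lengths | 0 | (l_max − l_min)²/4 |
| block_count | number of blocks | ⌈L/l_max⌉ | ⌊L/l_min⌋ |

In the codon-usage objective, `q(c)` is the *reference-table* frequency
of the codon chosen in the design, not its empirical frequency within
the design; this is the only reading under which the objective is zero
exactly when every codon is its family's most frequent synonym and
maximal when all rare codons are used. Stop codons and the initial
codon carry no penalty and are never recoded.

The GC nadir has no closed form, so it is estimated heuristically: every
CDS codon is replaced by the synonym whose own GC fraction is farthest
from `T_GC` (ties broken lexicographically), the sequence is split into
the maximum admissible number of blocks (⌊L/l_min⌋, near-equal lengths),
and the objective is evaluated. Because this is a heuristic, a design
exceeding it is possible in principle; the normalization treats it as an
estimate, and hypervolume clips front points into the box. The
block-count bounds apply ceiling/floor to the real-valued length ratios
since counts are integers.

## Edit operators

Each operator maps a valid design to a new valid design and edits one
thing only — one CDS, or one block boundary — which keeps the pool
diverse rather than converging on a single greedy rewrite.

* **GC recoding** walks over one randomly chosen CDS, repeatedly picking
  a random codon that can move GC in the needed direction and swapping it
  for its family's highest- (or lowest-) GC synonym. The walk stops when
  the CDS GC is within half a codon (1.5 nt) of the target, when no
  synonym improves, or when any further move would push the total drift
  beyond `sigma_gc` of the CDS's starting GC. The drift cap deliberately
  limits each application, trading convergence speed for design
  diversity. One subtlety: the directionality is "use high-GC synonyms
  while below target, low-GC while above" — the semantically coherent
  reading of the operator's purpose; an inverted branch would walk away
  from the target and never terminate meaningfully. A move/miss budget of
  10× the codon count guarantees termination in all cases.
* **Codon recoding** recodes each codon of one random CDS to the modal
  synonym of the usage table, independently with probability `sigma_c`.
* **Block split** cuts one random block at a uniformly chosen admissible
  point on the `sigma_b` grid (both parts within bounds); **block join**
  merges a random adjacent pair, re-splitting on the grid when the merge
  would exceed `l_max` (the count is unchanged but the boundary moves).

One operator is applied per clone per iteration, drawn uniformly from the
operators relevant to the configured objectives: block operators always,
the GC (codon) operator only when the GC (codon-usage) objective is
active. Operators returning an unmodified copy keep the cached objective
vector, so no-op edits cost no re-evaluation.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| n / T_max / m | 100 / 200 / 100 | pool size, iterations, archive capacity |
| l_min, l_max | 500, 3000 nt | synthesizable fragment bounds |
| sigma_gc | 0.05 | max GC drift (absolute fraction) per GC-operator call |
| sigma_c | 0.25 | per-codon recoding probability |
| sigma_b | 100 nt | block boundary grid step |
| t_gc | 0.55 | target GC fraction |
| overlap | 40 nt | Gibson overlap on exported fragments |

`sigma_gc` is an absolute GC-fraction difference (0.05 = 5 percentage
points). These are package defaults chosen as typical of current
synthesis constraints and operator step sizes, configurable per run.

## Selection and the archive

Survivors are chosen from the union of parents and offspring by
domination-count rank (number of solutions dominating each candidate),
then by crowding distance within each rank group, with infinite distance
for the per-objective extremes — the standard elitist convention that
preserves front spread. Normalization uses the running per-objective
extremes observed so far in the run, maintained incrementally. Ties
break by insertion order (stable sort) so a fixed seed reproduces runs
bit-for-bit.

The archive holds every non-dominated solution encountered, up to
capacity `m`; beyond capacity, the most crowded members are evicted. It
is updated with all 2n evaluated solutions each iteration, so
non-dominated designs that selection discards for crowding reasons are
still returned to the user. The initial pool clones the input sequence
with independent random partitions (target mean block length uniform in
`[l_min, l_max]`, boundaries jittered on the `sigma_b` grid), which
seeds the block objectives with diversity at iteration 0.

## Quality metrics

The hypervolume of a front within the ideal–nadir box is the measure of
the box region weakly dominated by at least one front member — the
volume between the front and the nadir — computed exactly by a sweep in
two dimensions and recursive slicing along the last objective in three
or more. Normalized hypervolume divides by the box volume, so `NV` lies
in [0,1], equals 1 for a front at the ideal point and 0 at the nadir.
This orientation is the one under which "NV near 1 = near-optimal
trade-offs" holds; measuring from the ideal instead would invert the
scale. Degenerate boxes (an objective whose ideal equals its nadir) are
rejected rather than silently scored.

The approximate global Pareto set is the non-dominated union of fronts
from independent runs/settings. `r_theta` is the fraction of that union
a single setting recovered (membership by exact objective-vector
equality), divided by `min(|union|, pool size)`: the pool-size floor
lets a setting score 1 even when the union is larger than any single
pool could hold. The exact normalization is an interpretation fixed by
this package and documented here because reasonable alternatives exist.

## Synthetic benchmark

The generator emulates modular constructs: `num_tus` transcription
units, each promoter + CDS + terminator. Promoter/terminator lengths are
Poisson(500 bp); CDS lengths are Poisson(250) codons (the scale of an
average bacterial gene), including the ATG start and single stop that
GenBank CDS conventions require; each component's GC target is an
independent Beta(150·0.55, 150·0.45) draw (mean 0.55, sd ≈ 0.04). A
5-TU construct is therefore ~8.75 kb in expectation. Regulatory sequence
is per-base Bernoulli in GC; CDS synonyms are drawn with an exponential
tilt on codon GC calibrated by root-finding so the expected GC matches
the component target within the genetic code's achievable range.
Usage tables for benchmark runs are random (uniform weights per
amino-acid family, normalized, seeded).

What this does *not* emulate: organism-specific codon usage bias. A
random usage table has compositionally unbiased modal codons (mean codon
GC near 0.5), so recoding toward modal codons barely conflicts with a
55% GC target, and on the P4 problem (GC + codon usage + block count)
the optimizer reaches near-zero codon-usage values while holding GC —
mean NV ≈ 0.98 in the bundled study. Against a real organism's table,
whose preferred codons are systematically GC- or AT-skewed, the
codon/GC trade-off is materially harder and NV should be expected to
drop; benchmark results on P4 are therefore optimistic relative to real
transplantation tasks. Real regulatory elements (promoter motifs,
terminator hairpins, RBSs), repeats and synthesis-hostile local features
are likewise absent, so passing the benchmark says nothing about
sequence manufacturability screens beyond GC windows.

## Numerical and degenerate-input choices

* GC computations use integer G/C counts over prefix sums; objective
  vectors are cached per solution and never recomputed for unedited
  clones.
* Usage tables must contain all 61 sense codons with family sums within
  1e-6 of 1; modal/rarest synonyms break frequency ties lexicographically
  so tables with tied frequencies are still deterministic.
* A split (join) that admits no grid cut returns the design unchanged
  rather than violating bounds; sequences shorter than `l_min` are
  rejected at pool initialization.
* Crowding distance treats a zero-span objective as contributing nothing;
  fronts of ≤2 points are all-extreme (infinite distance).
* Empty sequences, non-codon-multiple CDSs, stop-codon recoding requests
  and mismatched objective-vector lengths raise errors rather than
  propagating nonsense.

## Study scale

The bundled quality study (tests and `scripts/acceptance.py`) uses 3
constructs of 5 TUs × 3 seeds per problem with n=100, T_max=200, m=100 —
the same optimizer settings as the full-size experiments this package's
benchmark emulates, with the construct count and replication chosen to
keep a complete study in the low minutes on one CPU. Means over 9–18
runs are stable to ~0.01 NV across master seeds.

## Known limitations

* The GC nadir is heuristic, so NV values are comparable within a fixed
  bound estimate but not across different bound procedures.
* Exact hypervolume by slicing is practical for the k ≤ 3 problems used
  here (and exact at any k); large fronts in k ≥ 4 would need a
  dedicated algorithm (WFG/HSO) out of scope for this package.
* `r_theta` compares objective vectors exactly; two designs differing
  only in sequence but identical in objectives count once.
* The optimizer offers no constraint handling beyond operator
  feasibility, no adaptive operator scheduling and no parallel
  populations.
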