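# Methods

## Connection model

Residue positions are 1-based everywhere in the public interface. A window
of half-width `w ≥ 0` around a center `c` covers positions `c−w … c+w`
(`2w+1` slots, slot `w` being the center).

**Bipartite templates** are ordered, duplicate-free offset sets
`{(a, b)}`; realizing one at a central pair `(p, q)` yields connections
`(p+a, q+b)` in template order. The built-ins are:

* `patch(w)`: all `|a|, |b| ≤ w`, lexicographic order, `t = (2w+1)²`;
* `memconp`: a fixed 25-offset set encoding face-to-face helix packing
  (kept verbatim in its canonical printed order; it is centrosymmetric
  under `(a, b) → (−a, −b)`);
* `cross(w)`: `(a, 0)` and `(0, b)` arms, `t = 4w+1`.

**Unipartite templates** are ordered pairs of distinct window slots; the
`complete` template is all `(2w)(2w+1)` ordered pairs of distinct slots,
sorted by `(slot_i, slot_j)`. Ordered (rather than unordered) pairs are
used because the connection `(i, j)` and its reverse occupy different
feature columns for positionally ordered windows; the closed-form count
`(2w)(2w+1)` is exactly the ordered, non-self pair count of `2w+1` slots.

### Boundary and degeneracy policy

A connection end outside `1 … L` is *kept* as a placeholder (`None` in
memory, `-` in TSV) rather than dropped, so the realized list always has
the template-determined length — feature matrices then have fixed width
regardless of where the center sits, which is what downstream ML models
need. A realized bipartite connection whose two ends resolve to the same
residue (possible only when the central pair is closer than the offset
span) is emitted fully placeholdered: a residue is never connected to
itself. The placeholder feature value defaults to 0.0 (neutral under
summation) and is user-settable.

## Feature assignment

The score matrix is a hash table keyed on the unordered pair `(i, j)`,
`i < j`; access is symmetric, the diagonal and absent pairs read 0.0, and
negative scores pass through unchanged. One lookup is O(1), so assigning
features to `n` centers under a fixed template costs O(n) lookups — the
matrix object counts its lookups so scaling can be asserted on operation
counts instead of wall-clock time, which is hardware-independent.

Two routes share one contract. `assign_hash` generates each center's
connections on the fly and never materializes a whole-corpus connection
object. `assign_materialized` first builds the full 3D object (centers ×
connections × 2 ends) and then performs the same lookups; it exists as the
reference/cross-check route, and the element-wise equality of the two is a
defining, tested property.

The score-file reader accepts the 3-column `i j score` dialect and the
5+-column `i aa_i j aa_j score…` dialect (auto-detected by column count;
score column selectable). Duplicate pairs keep the last value with a
warning; out-of-range or self pairs are errors.

## cumuCC

For a matrix over `L` residues and a threshold `ratio`:

* `k = min(max(1, ⌊ratio·L⌋), L(L−1)/2)`;
* the `k` highest-scoring *unordered pairs are selected globally*, ranking
  over all `L(L−1)/2` pairs with absent entries at 0.0 (this matters when
  scores are negative), ties broken by ascending `(i, j)`;
* `CC_R` = sum of selected-pair scores over pairs containing `R`;
* `c` = (sum of all pair scores) / (L(L−1)/2), i.e. the matrix mean with
  the diagonal excluded; `c = 0` is an error (undefined normalization);
* `cumuCC(R) = CC_R / c`.

Global selection is the default because that is how the score is consumed
as an interaction-site feature; a per-residue variant (each residue sums
its own `k` highest partner scores) is available behind the
`per_residue=True` flag. Useful identities, all tested: positive scale
invariance (`λ > 0` rescales selection, `CC_R` and `c` alike),
`Σ_R CC_R = 2 × (sum of selected scores)`, and the constant-matrix closed
form (scores count selected pairs containing the residue).

## Topology

Region codes follow the structure-based annotation convention: H, B, C, I,
L, F, U, 1, 2. Structure placement cannot distinguish the cytoplasmic from
the extracellular membrane side, so `redistribute_nontm` stacks the
annotation against a sequence-predicted topology (inside/outside/TM
segments). Policy choices:

* only codes 1, 2, L and U are relabeled; membrane-associated codes
  (H, B, F, I, C) pass through verbatim;
* relabeling is per-segment by **residue-majority** overlap with the
  predicted inside/outside segments; a tie or no overlap yields `unknown`.
  Majority-by-residue was chosen over first-overlap or midpoint rules as
  the conservative option when a predicted boundary bisects a structural
  segment; boundaries themselves are never moved.

`per_residue_topology` expands segments to a length-`L` label vector
(uncovered → U; overlaps resolved last-in-document-order with a warning).
QC criteria are all optional; a record missing a field that a set
criterion tests fails with `missing:<field>`, which makes adding criteria
monotone — a tested invariant.

## Mapping

Structure-derived and FASTA sequences are aligned globally (match +1,
mismatch −1, gap open −2, gap extend −1; fixed defaults, configurable).
Identity scoring, not a substitution matrix: both sequences come from the
same protein, so a mismatch flags an artifact, not homology. Aligned
identical columns become map entries; aligned mismatches are mapped but
flagged; gap columns go to the unmapped lists. Among equal-scoring
alignments the aligner's first traceback is taken, which is deterministic
for fixed inputs and scores.

One inherent limit: when a deletion boundary falls inside a run of
repeated letters, the deleted positions are not identifiable from the
strings — any alignment maps the survivors to an equal-letter placement
that may be shifted within the run. Recovery tests therefore draw
*identifiable* deletions (boundary letters differing on both sides); this
is a property of alignment-based mapping itself, not of the
implementation.

## Synthetic fixtures

The generator emulates the input ecosystem at desk scale: random sequences
over the 20-letter alphabet; dense symmetric score files with uniform(0,1)
background and an optional fraction (default 5%) of "contact" pairs spiked
around a higher mean (default 1.5, uniform half-width 0.1); topology
annotations alternating side (3–11 residues) / TM helix (15–25 residues,
the physical span of a membrane-crossing α-helix) / opposite side; a
predicted topology derived from the annotation (side1 → inside, side2 →
outside, H → TM) with a per-segment corruption probability (default 0);
and a QC table with randomized method/resolution/helix statistics. One
seed drives everything and regeneration is byte-identical.

What the fixtures do *not* emulate: the heavy-tailed, position-correlated
structure of real coevolutionary matrices, insertion codes and
heteroatoms in structure numbering, multi-chain topology interplay, and
biological-assembly reconstruction. Passing tests therefore demonstrate
the combinatorial and numerical contracts of the pipeline, not predictive
performance on real proteins.

## Problem sizes and numerics

Default verification sizes: dual-route equivalence over 100 seeded
configurations with `L ∈ 20…80` and 15 centers each; lookup scaling on
100–1600 interior, well-separated centers at `L = 80` (separation ≥ 5 so
patch windows neither truncate nor overlap and each connection costs
exactly one lookup); mapping recovery over 50 trials with `L ∈ 50…300`
and up to 3 deletions of 1–7 residues; topology recovery on five
150-residue proteins; QC monotonicity on 200 records. Counting-formula
checks run exhaustively for `w ∈ 0…5` and `L ∈ 2…200`. Exact equality is
asserted where the quantity is discrete (counts, dual-route values, which
are the same lookups in a different order); float comparisons use relative
tolerances around 1e-9–1e-12.
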