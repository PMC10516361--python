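# resconn

Residue–residue connection graphs and fast coevolutionary feature
assignment for transmembrane-protein machine learning, with the supporting
plumbing such pipelines need: membrane-topology parsing and relabeling,
structure↔sequence residue mapping, and metadata-based quality control.

## Who this is for

Contact-map and interaction-site predictors for membrane proteins are
usually trained on features read off a residue-pair score matrix (e.g.
coevolutionary couplings from FreeContact/EVfold-style programs). For every
residue or residue pair of interest, the feature vector collects the scores
of the *connections* in its sequence neighborhood — and for a protein of
length `L` there are `L(L−1)/2` pairs, so how those connections are built
and looked up dominates the cost of feature engineering. `resconn` provides
that layer as a library plus a thin CLI.

## The model

A sequence of length `L` is a vertex set `{v_1 … v_L}`. Around a central
residue (or each member of a central pair) a window of half-width `w`
spans `2w+1` positions.

* **Local connections (LocRRCs)** join two residues inside one window.
  The default *complete* unipartite template connects every ordered pair of
  distinct window slots: `(2w)(2w+1)` connections per residue.
* **Global connections (GlobRRCs)** join a residue near one member of a
  central pair `(p, q)` to a residue near the other. A bipartite template
  is a set of integer offsets `(a, b)`; each offset realizes the connection
  `(p+a, q+b)`. Built-in templates:
  * `patch` — the full `(2w+1)×(2w+1)` square of the contact map around
    the pair (`t = (2w+1)²` edges);
  * `memconp` — a fixed 25-offset pattern for face-to-face helix packing
    (offsets step by 1, 3 and 4 positions, the contact periodicity of an
    α-helix);
  * `cross` — the central row plus central column (`t = 4w+1`);
  * custom templates from a two-column text file.

Connections running past the sequence ends are kept as placeholders, so
every feature row has a fixed, template-determined width.

Scores live in a hash table keyed on the unordered residue pair, so one
lookup is O(1) and assigning features to `n` centers under a fixed template
takes O(n) lookups. The direct route (`assign_hash`) generates each
center's connections on the fly; a reference route (`assign_materialized`)
builds the full centers × connections × 2 object first and must agree
element-wise.

The per-residue **cumulative correlation coefficient** is

```
cumuCC(R) = CC_R / c
```

where `CC_R` sums the globally top-`k` pair scores over the pairs
containing residue `R` (`k = ⌊ratio·L⌋`, ties broken by ascending pair
index) and `c` is the mean score over all `L(L−1)/2` pairs. It measures how
much of the strongest coupling signal a residue carries, a standard feature
for interaction-site prediction.

The topology module parses region-annotated XML (TMDET/PDBTM-style codes:
H helix, B strand, C coil, I inside, L loop, F interfacial, 1/2 membrane
sides), relabels the ambiguous non-TM segments as cytoplasmic/extracellular
by residue-majority vote against a sequence-predicted topology, and filters
structure metadata (method, resolution, length, TM-helix count/lengths).
The mapping module aligns a structure-derived sequence against its full
FASTA sequence (global alignment, match +1 / mismatch −1 / gap open −2 /
extend −1) and returns a bidirectional residue-number map.

## Worked example

A toy 4-residue protein with pair scores `(1,2)=4, (1,3)=3, (2,3)=2` and
0.5 elsewhere, scored with the top `k = ⌊0.5·L⌋ = 2` pairs:

```
$ printf '1 2 4\n1 3 3\n2 3 2\n1 4 0.5\n2 4 0.5\n3 4 0.5\n' > toy.scores
$ resconn cumucc -m toy.scores -L 4 -r 0.5
# k_used=2	c=1.75
residue	cumucc
1	4
2	2.28571
3	1.71429
4	0
```

The two selected pairs are (1,2) and (1,3), so the raw sums are
`CC = [7, 4, 3, 0]`; dividing by the matrix mean `c = 10.5/6 = 1.75` gives
the printed scores. Realizing a patch template at the pair (10, 40):

```
$ resconn globrrc -L 100 -p 10 40 -g patch -w 1
center	edge	i	j
10,40	0	9	39
10,40	1	9	40
...            # 9 connections: t = (2·1+1)² = 9
```

Other subcommands: `pairs`, `locrrc`, `assign` (hash or materialized
route), `topo-parse`, `topo-redistribute`, `qc`, `map`, and `fixtures`
(seeded synthetic bundles — sequences, score files, topology XML, predicted
topology, QC table — for offline testing).

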