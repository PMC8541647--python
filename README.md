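# nrpslink

Linking nonribosomal peptide (NRP) structures to the biosynthetic gene
clusters (BGCs) that produce them.

Nonribosomal peptides — a major class of microbial natural products that
includes many antibiotics and siderophores — are assembled by modular
NRPS enzymes, one residue per module. Genome mining finds thousands of
candidate NRPS clusters whose products are unknown, while compound
databases hold thousands of peptides whose producers are unknown.
`nrpslink` connects the two sides: it turns a peptide's monomer graph
into candidate linear monomer sequences, turns a cluster's module
annotations into candidate assembly-line monomer sequences, scores all
pairs with a probabilistic log-odds global alignment, and reports
ranked and reciprocal-best matches. It is aimed at natural-product
researchers doing dereplication or producer identification from
annotated genomes and structure databases.

## The model

Both sides are reduced to sequences of *monomers*. A structure-side
monomer is `(a, m, e)`: core residue `a` from an extended alphabet
`Ā = A ∪ {⌀}` (`⌀` stands for any unsupported residue, and two `⌀`
are never equal), methylation `m ∈ {−1, +1}` and stereochemistry
`e ∈ {−1, 0, +1}` (L / undetermined / D). A gene-side monomer is
`(s, a, m, e)` with a substrate-prediction specificity score
`s ∈ [0..100]`, discretized into five levels (with `s = 0` a reserved
"unreliable" level).

For a global alignment `(NRP′, BGC′)` of the two sequences, the score
is the log-odds ratio

```
Score = log P(NRP′ | BGC′) − log P(NRP | NULL)
```

where `NULL` is an equal-length sequence of completely undefined
modules `M̄ = (0, ⌀, 0, 0)`. Columns are independent and factor into
residue, methylation and stereo terms:

* residue: `P(a_nrp | s, a_bgc) = PmatchA(level(s))` on a match, else
  `(1 − PmatchA) · PA(a_nrp) / (1 − PA(a_bgc))`;
* methylation/stereo: match and mismatch probabilities keyed by the
  structure-side state, falling back to background frequencies
  `PM` / `PE` when the gene side is undefined; an undetermined
  structure-side `e` contributes exactly 0;
* indels: insertions cost `Pinsertion · PA(a) · PM(m) · PE(e)`;
  deletions cost a uniform `Pdeletion`.

The optimal alignment is computed with Needleman–Wunsch (natural
logarithms; linear gap costs). All probabilities are learned as plain
event frequencies from a structure corpus and curated alignments, with
bootstrap resampling for uncertainty.

Around the scoring core, the pipeline linearizes monomer graphs
(tailoring bonds removed, Hamiltonian traversal per backbone component,
every ring opening of a cycle, component permutations for
non-collinear/iterative synthesis), reconstructs assembly lines
(module→monomer conversion, stutter and iterative-reuse strip variants,
splitting of over-merged clusters, consistency-constrained strip
ordering driven by CS/TE/COM domains) and filters matches reciprocally.

## Worked example

Everything runs on synthetic fixtures with planted ground truth, so no
downloads are needed:

```
nrpslink fixtures --n-pairs 3 --n-decoys 10 --length 7 --seed 11 --out demo/fix
nrpslink match --graphs demo/fix/monomer_graphs.json \
               --bgcs demo/fix/bgc_annotations.json \
               --out demo/run --min-score 6.0
nrpslink eval-fdr --results demo/run/combined_report.tsv \
                  --truth demo/fix/truth.tsv --out demo/fdr.tsv
```

The match step prints

```
3 matches, 3 in the combined report
```

and `demo/run/combined_report.tsv` contains the reciprocal-best pairs:

```
score	compound_id	genome_id	bgc_id	candidate_index	line_index
22.266380	compound1	genome1	bgc1	0	0
21.702885	compound2	genome2	bgc2	0	0
15.284542	compound0	genome0	bgc0	0	0
```

Each planted compound is recovered as the reciprocal best hit of its
planted cluster, with scores well above the default reporting threshold
of 6.0; the per-genome report renders the underlying alignments, e.g.

```
   gly[s=95] m-1/e-1     gly m-1/e-1      match     -1.514  (-0.223, -0.598, -0.693)
   arg[s=99] m-1/e+1     arg m-1/e+1      match     -2.207  (-0.223, -0.598, -1.386)
   ...
  score = 15.2845 (null logP = -34.8577)
```

A positive score means the cluster explains the peptide much better
than an uninformed null cluster would; the FDR table (`demo/fdr.tsv`)
shows all three identifications are correct at every list prefix
(FDR = 0).

## Input formats

* **Monomer graphs** (stand-in for retro-biosynthesis output): JSON,
  `{id, nodes: [{id, residue, supported, methylated, stereo}], edges:
  [{from, to, bond}]}`.
* **BGC annotations** (stand-in for genome-mining output): JSON,
  `{genome_id, bgcs: [{bgc_id, genes: [{gene_id, start, end, strand,
  modules: [[{kind, predictions?}]]}]}]}` with 1-based inclusive
  coordinates; A-domain predictions carry Stachelhaus and SVM scores.
* **Curated alignments**: TSV, one column pair per row, gaps as `-`.
* **Scoring parameters**: flat YAML written at full float precision;
  **residue alphabet**: one name per line (TSV). Defaults for both ship
  with the package.
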