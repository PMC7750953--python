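# pumanet

Message-passing inference of genome-wide miRNA–target gene regulatory
networks, with the downstream analyses used to interpret collections of such
networks across tissues.

## The problem

microRNAs (miRNAs) repress messenger RNAs by binding their 3′ UTRs, and most
human protein-coding genes carry conserved miRNA binding sites.  Sequence-based
target-prediction resources disagree substantially with each other and with
actual regulation: predicted targets are often not repressed, and real targets
are sometimes missed entirely.  `pumanet` implements PUMA (PANDA Using
MicroRNA Associations), which treats a target-prediction network as a *prior*
and refines it by message passing against the co-expression of the putative
target genes, producing complete bipartite networks whose edge weights behave
like z-scores — down-weighting predicted edges with no expression support and
*learning* edges absent from the prior.

It is aimed at computational biologists who have (i) a regulator→gene prior
edge list, (ii) one expression matrix per tissue or condition, and (iii)
optionally gene sets for functional interpretation.

## The model

Three normalized networks exchange messages: the evolving regulatory network
**W** (m regulators × n genes), regulator cooperativity **P** (m × m, identity
for miRNA-only runs) and target co-expression **C** (n × n, Pearson).  All
similarities use the continuous Tanimoto kernel

    T(x, y) = x·y / sqrt(‖x‖² + ‖y‖² − |x·y|).

Each iteration computes a responsibility R = T(P, Wᵀ) and an availability
A = T(W, C), forms the candidate Ŵ = (R + A)/2, measures the hamming distance
h = mean|W − Ŵ|, and applies the convex update W ← (1−α)W + αŴ; P and C are
updated toward the self-similarity of W's rows and columns.  The defining
miRNA modification: cooperativity rows/columns of miRNA regulators are reset
to their prior after every iteration, because sequence-based miRNA priors
carry no cooperativity evidence.  With no miRNAs flagged the engine is the
plain transcription-factor scheme (PANDA mode), bit for bit.

Downstream, for a collection of per-tissue networks:

* tissue-specificity of an edge: `s_ij(t) = (w_ij(t) − med_t′ w_ij) / IQR_t′ w_ij`,
  with `s > 2` marking a tissue-specific edge and the multiplicity
  `m_ij = Σ_t [s_ij(t) > 2]`;
* miRNA expression specificity from per-tissue sample medians against the
  pooled median/IQR;
* pre-ranked permutation GSEA over each miRNA's *targeting profile* (the
  per-gene specificity scores), summarized as `−log10(FDR) · sign(ES)`;
* fast-greedy (Clauset–Newman–Moore) communities over the bipartite graph of
  significant (FDR < 0.001, ES > 0.65) miRNA/tissue–gene-set associations,
  compared across collections with the Jaccard index.

A first-class synthetic-data module generates two discordant binary priors and
multi-tissue expression with planted, optionally tissue-restricted
co-expression modules, so the whole pipeline is testable with known ground
truth and no downloads.

## Worked example

```sh
python examples/01_infer_network.py
```

```
converged: True after 573 iterations (final h = 9.92e-04)

strongest refined edges (regulator -> gene, weight, planted?):
  miR001 -> g015    6.21  True
  miR001 -> g008    6.21  True
  miR016 -> g037    6.21  False
  ...

planted-edge AUROC: 0.903 (how well refined weights rank planted edges above background)
AUROC for planted edges withheld from the prior: 0.797 (the 'learn new edges' property)
```

The run refines a simulated 20-miRNA × 60-gene prior against one tissue's
expression until the hamming distance falls below 10⁻³.  Edge weights are
z-score-like: the strongest edges mix planted regulation and strong prior
edges, and the AUROC lines quantify how well the refined weights recover the
planted structure — including edges deliberately withheld from the prior,
which can only be found through co-expression.  `examples/02–04` continue the
same dataset through tissue-specificity scoring (84% of planted
tissue-restricted edges reach s > 2 in their active tissue), targeting-profile
enrichment (the planted module of miR004 in tissue2 gets ES = 1.0 and signed
score ≈ 3) and community detection (two planted association blocks recovered
at Q = 0.5).

The same functionality is exposed as a thin CLI:

```sh
puma simulate --config cfg.yaml --out sim/
puma run --prior sim/priorA.tsv --expression sim/expression_tissue0.tsv \
         --mirna sim/mirnas.txt --out network.tsv
puma specificity --networks nets/ --out scores.tsv --multiplicity mult.tsv
```

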