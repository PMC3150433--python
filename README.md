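# degenkit

Codon-degeneracy recoding and signal dissection for concatenated
protein-coding supermatrices.

## The problem

In deep-level phylogenetics of protein-coding genes, synonymous
substitutions saturate quickly and carry taxon-specific base-composition
bias, so they can lend strong bootstrap support to wrong groupings while
contributing little genuine signal about ancient divergences.
Nonsynonymous change is slower and far less compositionally biased. A
family of character-coding devices separates the two signals without
discarding alignments:

- **degen1** recodes every codon as the maximally degenerate IUPAC
  codon of its synonymous family — His `CAT`/`CAC` → `CAY`, all six Leu
  codons → `YTN`, all six Arg codons → `MGN`, serine's two boxes kept
  apart as `TCN` and `AGY` — so that only nonsynonymous differences
  remain informative. After recoding, the only determinate
  third-position symbol left is the `G` of `ATG` (Met) and `TGG` (Trp).
- **nt1/nt2/nt3** split columns by codon position;
  **LRall1**/**noLRall1** split first positions by whether any taxon's
  codon can encode leucine or arginine (the only amino acids with
  synonymous change at position 1). **noLRall1nt2** (= noLRall1 + nt2)
  concentrates nonsynonymous change; its exact complement
  **LRall1nt3** concentrates synonymous change.
- **nt3_4foldsynon** keeps third positions of strictly fourfold codons
  (Ala, Gly, Pro, Thr, Val) and degenerates everything else to `N`,
  isolating purely synonymous change.

Around these codings the package provides: NEXUS/FASTA/PHYLIP matrix
I/O with CHARSET and exclusion-mask handling, seeded column shuffling
and complementary fractional splits, bipartition-level comparison of
bootstrap analyses against a reference topology, a per-gene
phylogenetic-utility score

    U = (G / (L x 10^-3)) * (T / (T - m))

(G = reference nodes recovered at BP >= 75%, L = fragment length in nt,
m = taxa with entirely missing data, T = total taxa), per-taxon base
composition with Euclidean-distance dendrograms, a shared-indel screen
("high quality" = identical bounds across >= 2 taxa, no staggered
ends), and a seeded simulator that generates in-frame codon alignments
with known tree, synonymous:nonsynonymous rate ratio and
group-structured third-position bias.

## Worked example

```python
from degenkit.synthgen import default_spec, simulate_alignment
from degenkit.charsets import build_named_set
from degenkit.degeneracy import degen1_codon, degen1_matrix

spec = default_spec(n_taxa=12, seed=11, n_fragments=4, n_codons=30, biased=False)
m = simulate_alignment(spec)
print(m)
print(degen1_codon("CAT"), degen1_codon("TTA"))
a = build_named_set(m, "noLRall1nt2")
b = build_named_set(m, "LRall1nt3")
print(a.n_cols, b.n_cols, a.n_cols + b.n_cols == m.n_cols)
```

prints

```
NucMatrix(12 taxa x 360 cols, 4 charsets, 0 excluded)
CAY YTN
210 150 True
```

i.e. a 12-taxon, 360-column in-frame matrix in which the
mostly-nonsynonymous subset (210 columns) and the synonymous-enriched
subset (150 columns) exactly reconstitute the matrix, and the two
textbook degen1 recodings. The same operations are available from the
shell:

```sh
degenkit degen1 in.nex out.nex
degenkit subset --name noLRall1nt2 in.nex out.nex
degenkit split --fractions 0.5,0.5 --seed 7 --replicates 5 in.nex outdir/
degenkit compare --ref ref.nwk --cand cand.nwk
degenkit indels in.nex --min-taxa 2
```

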