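# startalign

Alignment-evidence prediction of prokaryotic gene starts (translation
initiation sites).

Ab initio gene finders agree almost perfectly on prokaryotic gene 3′
ends but disagree on 5′ ends (start codons) for a substantial fraction
of genes, because upstream signals (Shine–Dalgarno RBSs, leaderless
transcription, non-canonical motifs) vary widely between clades.
`startalign` takes the orthogonal route: it infers the start of a gene
from the pattern of evolutionary conservation in a multiple alignment
of homologous, *unannotated* syntenic sequences — no RBS or promoter
model, no existing start annotations.  It is written for
bioinformaticians who need an independent evidence stream for gene 5′
ends: annotation curators, comparative genomicists, and anyone
benchmarking ab initio gene finders.

## Method

For a query gene (3′ end given; 3′-end prediction is considered solved)
the gene is extended in-frame upstream to its **LORF** — the longest
open-reading frame, reaching back to the nearest in-frame stop — so
that every plausible start codon (ATG/GTG/TTG) lies in one sequence.
Homologous LORFs are then filtered and aligned:

1. **Target selection.** Homologs whose protein alignment covers ≤ 80%
   of either sequence are dropped.  Pairwise evolutionary distances are
   computed under the Kimura two-parameter model,

   d_AB = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

   with P and Q the transition and transversion fractions of the
   codon-back-mapped nucleotide alignment.  Targets outside
   d_AB ∈ [0.1, 0.5] to the query are discarded (too close is
   redundant, too distant disrupts the alignment), mutually redundant
   targets (d_AB < 0.1 to a kept target) are removed, and at most 50
   targets are sampled.  Queries ending up with fewer than 10 targets
   are declined (coverage loss, not an error).
2. **Dual-layer MSA.** A protein MSA of the translated LORFs is
   back-mapped codon-by-codon to a nucleotide layer (each residue
   column expands to its source codon, each gap to three gaps), giving
   exact column ↔ sequence coordinate maps.
3. **Start selection** by the first applicable of three steps:
   - **A** — find the leftmost conserved amino-acid block
     (S_blk(i, r=10) > 0.5, an ordered-pair identity score); if exactly
     one start candidate lies strictly upstream of it, predict it.
   - **B** — if the LORF overlaps (or nearly abuts) the upstream
     same-strand gene, score candidates within 9 nt of that gene's 3′
     end with the candidate conservation score
     S5′(i, x) = (1/N) Σ_j (G(i,j,x) − P(i,j)), where G = 1 iff a
     target carries ATG/GTG/TTG within x = 2 codons of the candidate
     column and P = 1 penalises a synonymous non-start Val/Leu codon at
     the column; predict the best candidate if S5′ > 0.5.
   - **C** — screen candidates 5′→3′ for the first with S5′ > 0.5,
     then re-check the 30 nt downstream: a higher-scoring downstream
     candidate wins unless a conserved block separates the two.

   Conservation of an overlap configuration itself is quantified by
   DC(x, f) = (1/N) Σ_n I{x − f ≤ D(n) ≤ x + f}, the fraction of family
   members whose signed upstream-gene distance D(n) lies within f nt of
   the modal distance x.
4. **Agreement combiner.** Predictions can be intersected with an
   independent ab initio annotation, keeping exactly the genes where
   both streams name the same start; since the streams err
   independently, the combined error rate scales with the product of
   the individual rates.  Prediction sets are scored 3′-anchored:
   Acc = 100·M5/M3, Err = 100 − Acc, Covr = 100·M3/|G|.

Because the published genome-scale benchmarks require clade-wide
sequence databases, the package ships a first-class synthetic family
generator (`startalign.synthsim`) that inverts the K80 model: families
with known true starts, controlled Kimura distances, tunable
conservation contrast, decoy upstream start codons and −4/−1 nt
upstream-gene overlaps.  All tests and the acceptance script run
offline on it.

## Worked example

```
$ startalign simulate demo/family --seed 7
$ startalign predict demo/family demo/pred
$ cat demo/pred/predictions.gff3
##gff-version 3
query	startalign	CDS	91	456	.	+	0	start_step=C;s5=1.0000
```

The generator placed the true start 90 nt into the LORF (1-based 91);
the pipeline kept all 20 targets, found a decoy GTG at offset 51 with
S5′ = 0.15 (unsupported by the targets) and the true ATG at offset 90
with S5′ = 1.0, and selected it at step C.  The evidence table shows
both candidates:

```
$ head -3 demo/pred/candidate_scores.tsv
seq_offset	codon	msa_column	s5	n_support	n_penalty	s_blk_from_here
51	GTG	51	0.15	5	2	0.179
90	ATG	90	1.0	20	0	0.2195
$ startalign evaluate demo/pred/predictions.gff3 demo/family/truth.gff3
{
 "n_reference": 1,
 "M3": 1,
 "M5": 1,
 "Acc": 100.0,
 "Err": 0.0,
 "Covr": 100.0
}
```

Acc/Err/Covr are the 3′-anchored metrics above: the single predicted
gene matches the truth by both ends.  Overlap families reproduce the
conserved −4 nt overlap statistic:

```
$ startalign simulate demo/ov --seed 11 --overlap-mode minus4 --overlap-jitter-sd 1.0
$ startalign stats demo/ov
{
 "n_targets": 20,
 "kimura_min": 0.12461390385755318,
 "kimura_max": 0.24709625208071564,
 "kimura_mean": 0.19152865634061547,
 "intergenic_mode": -4,
 "dc": 1.0
}
```

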