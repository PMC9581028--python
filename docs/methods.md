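# Methods

## Model and procedure

`startalign` treats prokaryotic gene-start prediction as a
change-point problem on a multiple alignment: downstream of a true
translation initiation site, purifying selection keeps homologous
sequences conserved at the protein level; upstream of it (inside the
LORF's 5′ extension) the sequence is effectively unconstrained.  The
pipeline runs in four stages — LORF extraction, target selection,
dual-layer alignment, three-step start selection — each exposed as a
library module and orchestrated by the CLI.

Assumptions the method inherits and that we make explicit:

* The gene's 3′ end (reading frame) is correct as given; only the 5′
  end is inferred.
* Start codons are ATG, GTG or TTG.  Rarer initiators (ATT, CTG) are
  excluded deliberately: the candidate conservation score enumerates
  exactly these three codons, and admitting others would change the
  penalty structure.  Translation uses NCBI table 11 throughout.
* Homologs are syntenic and colinear over the gene; frameshifts within
  targets are out of scope.
* Real upstream genes on the same strand end at annotated positions
  supplied by the caller (e.g. from an ab initio annotation); the
  method never infers them.

## Scores and their parameters

All parameters live in `ScoringConfig`; defaults below are the
method's operating point and are used by every test.

| parameter | default | meaning |
|---|---|---|
| `block_len_aa` (r) | 10 aa | conserved-block length |
| `t_blk` | 0.5 | block conservation threshold (majority vote) |
| `t_5prime` | 0.5 | candidate conservation threshold |
| `neigh_codons` (x) | 2 codons (6 nt) | candidate neighborhood half-width |
| `overlap_window_nt` | 9 nt | step-B search window at the upstream 3′ end |
| `downstream_recheck_nt` | 30 nt | step C-2 window |
| `dc_margin` (f) | 3 nt | overlap-conservation margin |
| `kimura_min` / `kimura_max` | 0.1 / 0.5 | target distance window |
| `coverage_min` | 0.8 | pairwise protein-alignment coverage |
| `min_targets` / `max_targets` | 10 / 50 | alignment size bounds |

Numerical choices worth knowing:

* **Block score normalisation.**  S_blk is implemented exactly as
  printed, 1/(r·(N−1)²) over ordered row pairs, which makes its
  maximum N/(N−1) (slightly above 1).  Whether (N−1)² is a variant of
  N(N−1) is genuinely ambiguous, so a `blk_norm="pair_count"` switch
  provides the 1/(r·N·(N−1)) normalisation for sensitivity analysis;
  the default threshold 0.5 applies to the printed form.  N here is
  the total number of rows including the query; in S5′, N is the
  number of target rows (the query does not vote for its own
  candidate).
* **Gap/ambiguity handling.**  Columns with a gap or ambiguity letter
  in either row are excluded from Kimura P/Q counts; ambiguous
  residues never match in S_blk; codons containing ambiguity letters
  are never start candidates; a target row whose LORF does not reach a
  candidate column contributes G = 0, P = 0 to S5′.
* **Undefined distances.**  d_AB is undefined (returned as `None`,
  never 0 or ∞) when (1−2P−Q) ≤ 0 or (1−2Q) ≤ 0; such targets are
  rejected with reason `undefined_distance`.
* **Tie-breaks.**  Equal candidate scores resolve to the most upstream
  (5′-most) candidate; modal-distance ties in DC resolve to the
  smallest |x|, then the most negative x.
* **Step C-2 "otherwise" branch.**  When no downstream candidate
  clears t5′, the C-1 candidate u is predicted; the block condition
  only arbitrates between u and a qualifying downstream d.  This
  reading is pinned by the trace tests.
* **Step-B trigger.**  B is attempted when the upstream gene's 3′ end
  lies downstream of, or within 10 nt upstream of, the LORF 5′ end
  (`overlap_proximity_nt`), matching the observation that conserved
  overlap configurations involve overlaps or very short (< 10 nt)
  intergenic gaps.  Distances in step B are measured in query sequence
  offsets, which coincide with alignment-column distances wherever the
  query row is ungapped and remain well defined for 3′ ends upstream
  of the LORF.
* **Redundancy removal order.**  The removal rule ("two targets closer
  than kimura_min to each other are redundant") does not prescribe
  which member to drop; we scan kept targets in ascending
  distance-to-query order and drop later ones within `kimura_min` of
  an already-kept target — deterministic, and biased toward the set
  closest to the query.  Target–target distances are computed only in
  this pass (composed through the query alignment); a full distance
  matrix is available separately for diagnostics.
* **Filter/sample order.**  Distance filtering runs before the
  50-target sampling cap (`sample_order="filter_first"`): sampling
  first can discard the only in-window targets.  The alternative order
  is available as a config switch.
* **Coordinates.**  0-based half-open internally; GFF3 I/O converts to
  1-based inclusive.  A `LorfRecord.nt` includes the terminal stop
  codon; its `aa` and both MSA layers cover only the codons preceding
  it.  `upstream_gene_end_offset` is exclusive (one past the upstream
  gene's last nucleotide), so the signed intergenic distance is
  `gene_start_offset − upstream_gene_end_offset` and a −4 nt overlap
  (ATGA-style) gives D = −4.

## What the synthetic generator emulates — and what it does not

`synthsim` builds star-topology families: the query is the ancestor and
each target evolves independently under per-site K80 substitution run
at the exact model transition probabilities, so the Kimura estimator
applied to (ancestor, target) is consistent for the nominal branch
length.  The ancestral LORF is laid out as
`[upstream noise | true start | variable N-terminus | conserved coding | stop]`.

Deliberate realism features (all `FamilySpec` fields):

* **Conservation contrast.**  Coding codons evolve at
  `sub_rate_coding = 0.22` subs/site versus `sub_rate_upstream = 0.66`
  upstream (3× contrast), and additionally under purifying selection:
  nonsynonymous proposals are accepted with probability
  `dn_ds = 0.1`.  Without the selection step, codon-level substitution
  noise erases the protein-level conserved blocks that steps A and C-2
  depend on; real gene families at nucleotide distances 0.1–0.5 remain
  strongly conserved in amino-acid space, and dN/dS ≈ 0.1 is typical
  of conserved bacterial genes.
* **N-terminal hypervariability.**  The first `nterm_variable_aa = 10`
  codons after the true start evolve at the fast rate, mirroring the
  well-known variability of protein N-termini (the r = 10 block length
  itself excludes the N-terminal region).  This places the leftmost
  conserved block downstream of the start codon — the geometry the
  block-based steps assume.
* **Truth preservation.**  The true start codon stays within
  {ATG, GTG, TTG} (it may wobble ATG→GTG, as real starts do) and no
  in-frame stop ever appears before the terminal stop, so every target
  remains a valid LORF with the same true start.
* **Controlled candidates.**  Ancestral upstream and N-terminal codons
  exclude start-like codons, so the query's upstream candidates are
  exactly the planted decoys (`decoy_upstream_starts`); targets are
  free to drift start-like codons in and out, which is the noise S5′
  has to tolerate.
* **Distance placement.**  Per-target rate scale factors are drawn
  uniformly from `rate_scale_range = (0.7, 1.6)` and the realised
  query–target Kimura distance is verified post hoc against
  `dist_window = (0.1, 0.5)`, resampling (bounded retries) on failure.
* **Overlap families.**  `overlap_mode` plants upstream-gene 3′ ends
  at D = −4, −1 or a custom signed distance, jittered per target by a
  rounded normal with `overlap_jitter_sd` nt.

Not emulated — and therefore not certified by passing tests: realistic
phylogenies (star topology only, so target–target distances are sums
of branch lengths), indels (gold alignments are colinear; the external
aligner adapter exists but alignment error is untested), codon-usage
bias, GC-content gradients, horizontal transfer, genuine RBS/promoter
signal (irrelevant to the method but present in real upstream
regions), and annotation errors in the upstream-gene context supplied
to step B.  Recovery rates measured on these families (≈ 96–99% over
200 families) characterise the score logic under the stated contrast,
not performance on real genomes.

## Problem sizes

The defaults used by the test suite and the acceptance script —
families of 20 targets with 120-codon genes and 90 nt upstream
extensions, 200 families for recovery, 25 for the overlap statistic,
2,000 genes for the combiner experiment, 500 random alignments and
1,000 random (P, Q) pairs for the oracle checks — were chosen so the
whole suite certifies every property in well under a minute per check
on a single CPU while keeping binomial uncertainties small relative to
the thresholds being asserted (e.g. the 95% recovery bound has a
standard error of ≈ 1.3 percentage points at n = 200).

## Known limitations

* Step A's "single candidate strictly upstream of the leftmost
  conserved block" can, in principle, select a spurious upstream
  candidate when the detected block extends upstream of the true start
  (the 0.5 threshold admits windows with up to ~half noise columns);
  in our families the variable N-terminus keeps the block downstream
  of the start and the configuration does not arise.  On real data
  this is mitigated by the same biology.
* The combiner assumes independent error processes; correlated errors
  (e.g. both predictors misled by the same decoy) inflate the combined
  error above the product estimate.
* Declined predictions (too few in-window targets, no candidate above
  threshold) are reported, not imputed; genome-scale coverage depends
  entirely on homolog availability in the caller's database.
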