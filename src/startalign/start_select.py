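"""Three-step (A/B/C) gene-start selection over a dual-layer MSA.

Scores
------
* Block conservation  S_blk(i, r) = 1/(r (N-1)^2) * sum_{m != n} sum_{j in J(i,r)} H(m,n,j)
  over ordered row pairs, where J(i, r) is the set of r alignment columns
  at/after i with no gap in the query row and H = 1 iff rows m and n carry
  the same unambiguous residue at column j.  A block scoring above
  t_blk = 0.5 (majority vote) is conserved.  As printed this normalisation
  tops out near N/(N-1); a pair-count variant 1/(r N (N-1)) is available
  for sensitivity analysis.
* Candidate conservation  S5'(i, x) = 1/N * sum_j (G(i,j,x) - P(i,j)) over
  the N target rows: G = 1 iff an ATG/GTG/TTG occurs among the row's
  frame-0 codons within x codons of the candidate column, and P = 1 iff
  the row's codon at the candidate column encodes Val/Leu through a
  non-start codon.
* Intergenic-distance conservation  DC(x, f) = fraction of rows whose
  signed upstream-gene distance D(n) falls within x +/- f, where x is the
  modal distance (ties: smallest |x|, then most negative).

Steps
-----
A: if the leftmost conserved block exists and exactly one query start
candidate lies strictly upstream of it, predict that candidate (its own
conservation is not required).  B (only with upstream-gene context): best
candidate within 9 nt of the upstream gene's 3' end whose S5' clears
t5' = 0.5.  C: scan candidates 5'->3' for the first clearing t5' (= u),
then re-check the 30 nt downstream for a higher-scoring candidate d —
predicted unless a conserved block (any length up to r) separates u from d.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .msa_layer import DualMsa, column_window
from .seqmodel import (
    LorfRecord,
    NONSTART_VL_CODONS,
    START_CODONS,
    ScoringConfig,
    StartCandidate,
)

_AA_AMBIG = frozenset({"X", "-", "*"})


@dataclass
class BlockScore:
    aa_col: int
    r: int
    score: float
    conserved: bool


@dataclass
class CandidateScore:
    candidate: StartCandidate
    s5: float
    n_support: int   # rows with a start-capable codon in the neighborhood
    n_penalty: int   # rows with a synonymous non-start codon at the column


@dataclass
class OverlapStats:
    distances: list[int]
    mode_x: int
    f: int
    dc: float


@dataclass
class StartPrediction:
    query_offset: Optional[int]
    step: str  # 'A' | 'B' | 'C' | 'none'
    scores: dict = field(default_factory=dict)
    n_targets: int = 0
    reason: str = ""

    @property
    def made(self) -> bool:
        return self.step != "none"


# ---------------------------------------------------------------------------
# Scores

def block_conservation_score(
    msa: DualMsa, aa_col: int, r: int, cfg: Optional[ScoringConfig] = None
) -> Optional[BlockScore]:
    """S_blk at ``aa_col`` over the r query-ungapped columns from there.

    Returns None when fewer than r query-ungapped columns remain (the
    block is not evaluable).
    """
    cfg = cfg or ScoringConfig()
    cols = msa.query_ungapped_cols(start=aa_col)[:r]
    if len(cols) < r:
        return None
    n = msa.n_seqs
    matches = 0
    for j in cols:
        counts = Counter(
            msa.aa_rows[m][j] for m in range(n) if msa.aa_rows[m][j] not in _AA_AMBIG
        )
        matches += sum(c * (c - 1) for c in counts.values())  # ordered pairs
    denom = r * (n - 1) ** 2 if cfg.blk_norm == "printed" else r * n * (n - 1)
    score = matches / denom
    return BlockScore(aa_col=aa_col, r=r, score=score, conserved=score > cfg.t_blk)


def find_leftmost_conserved_block(
    msa: DualMsa, cfg: ScoringConfig, start_col: int = 0
) -> Optional[BlockScore]:
    """First (leftmost) query-ungapped column whose r-block clears t_blk."""
    for c in msa.query_ungapped_cols(start=start_col):
        blk = block_conservation_score(msa, c, cfg.block_len_aa, cfg)
        if blk is None:
            return None  # too close to the 3' end for any further block
        if blk.conserved:
            return blk
    return None


def candidate_score_s5(
    msa: DualMsa, candidate: StartCandidate, cfg: ScoringConfig
) -> CandidateScore:
    """S5' of a query start candidate over the target rows.

    Target rows whose LORF does not reach the candidate column (gap
    codons throughout the window) contribute G = 0, P = 0.
    """
    if candidate.msa_column is None:
        raise ValueError("candidate has no msa_column; build the DualMsa first")
    windows = column_window(msa, candidate.msa_column, 3 * cfg.neigh_codons)
    center_aa = candidate.msa_column // 3
    support = penalty = 0
    for r in range(msa.n_seqs):
        if r == msa.query_index:
            continue
        codons = windows[r]
        if any(codon in START_CODONS for _, codon in codons):
            support += 1
        center = msa.codon_at(r, center_aa)
        if center in NONSTART_VL_CODONS:
            penalty += 1
    n = msa.n_targets
    s5 = (support - penalty) / n if n else 0.0
    return CandidateScore(candidate=candidate, s5=s5, n_support=support, n_penalty=penalty)


def intergenic_conservation_dc(distances: Sequence[int], f: int) -> OverlapStats:
    """Modal signed intergenic distance and its conservation DC(x, f)."""
    if not distances:
        raise ValueError("need at least one distance")
    counts = Counter(distances)
    # highest count; ties -> smallest |x|, then most negative
    mode_x = min(counts, key=lambda x: (-counts[x], abs(x), x))
    within = sum(1 for d in distances if mode_x - f <= d <= mode_x + f)
    return OverlapStats(
        distances=list(distances), mode_x=mode_x, f=f, dc=within / len(distances)
    )


def overlap_stats_for_records(
    records: Iterable[LorfRecord], f: int = 3
) -> Optional[OverlapStats]:
    """DC over the records that carry both a start and an upstream 3' end."""
    ds = [r.intergenic_distance for r in records if r.intergenic_distance is not None]
    if not ds:
        return None
    return intergenic_conservation_dc(ds, f)


# ---------------------------------------------------------------------------
# Steps

def step_a(msa: DualMsa, cfg: ScoringConfig) -> Optional[StartPrediction]:
    """Predict when a single candidate sits strictly upstream of the
    leftmost conserved block; zero or several candidates fall through."""
    blk = find_leftmost_conserved_block(msa, cfg)
    if blk is None:
        return None
    upstream = [c for c in msa.query_candidates if c.aa_col < blk.aa_col]
    if len(upstream) != 1:
        return None
    cand = upstream[0]
    return StartPrediction(
        query_offset=cand.seq_offset,
        step="A",
        scores={"s_blk": blk.score, "block_aa_col": blk.aa_col},
        n_targets=msa.n_targets,
    )


def step_b(
    msa: DualMsa, upstream_gene_end_offset: int, cfg: ScoringConfig
) -> Optional[StartPrediction]:
    """Predict the best-scoring candidate near the upstream gene's 3' end.

    Candidates within ``overlap_window_nt`` of the 3' end (distances in
    query nt offsets) are scored with S5'; the best one is predicted when
    it clears t5', ties resolving to the most upstream candidate.
    """
    in_window = [
        c
        for c in msa.query_candidates
        if abs(c.seq_offset - upstream_gene_end_offset) <= cfg.overlap_window_nt
    ]
    if not in_window:
        return None
    scored = [candidate_score_s5(msa, c, cfg) for c in in_window]
    best = max(scored, key=lambda s: (s.s5, -s.candidate.seq_offset))
    if best.s5 > cfg.t_5prime:
        return StartPrediction(
            query_offset=best.candidate.seq_offset,
            step="B",
            scores={"s5": best.s5},
            n_targets=msa.n_targets,
        )
    return None


def _conserved_block_between(
    msa: DualMsa, aa_lo: int, aa_hi: int, cfg: ScoringConfig
) -> bool:
    """Any conserved block (length 1..r) whose columns lie strictly
    between aa columns ``aa_lo`` and ``aa_hi``."""
    inner = [c for c in msa.query_ungapped_cols(start=aa_lo + 1) if c < aa_hi]
    for i, anchor in enumerate(inner):
        avail = len(inner) - i
        for length in range(1, min(cfg.block_len_aa, avail) + 1):
            blk = block_conservation_score(msa, anchor, length, cfg)
            # restrict to columns inside the gap: the helper walks the
            # query-ungapped columns, which inside `inner` are contiguous
            if blk is not None and inner[i + length - 1] < aa_hi and blk.conserved:
                return True
    return False


def step_c(msa: DualMsa, cfg: ScoringConfig) -> StartPrediction:
    """General case: 5'->3' screening with a downstream re-check.

    C-1: candidates upstream of the leftmost conserved block (all of
    them when no block exists) are screened 5'->3'; the first with
    S5' > t5' is the provisional start u.  None qualifying -> declined.
    C-2: among candidates within ``downstream_recheck_nt`` downstream of
    u, the one with maximal S5' (d) replaces u when it clears t5' and no
    conserved block of any length up to r separates u from d.
    """
    blk = find_leftmost_conserved_block(msa, cfg)
    candidates = msa.query_candidates
    if blk is not None:
        candidates = [c for c in candidates if c.aa_col < blk.aa_col]
    u_score: Optional[CandidateScore] = None
    for cand in sorted(candidates, key=lambda c: c.seq_offset):
        sc = candidate_score_s5(msa, cand, cfg)
        if sc.s5 > cfg.t_5prime:
            u_score = sc
            break
    if u_score is None:
        return StartPrediction(
            query_offset=None, step="none", n_targets=msa.n_targets,
            reason="no_candidate_above_threshold",
        )
    u = u_score.candidate
    downstream = [
        c
        for c in msa.query_candidates
        if 0 < c.seq_offset - u.seq_offset <= cfg.downstream_recheck_nt
    ]
    chosen, scores = u, {"s5": u_score.s5}
    if downstream:
        d_scores = [candidate_score_s5(msa, c, cfg) for c in downstream]
        d_best = max(d_scores, key=lambda s: (s.s5, -s.candidate.seq_offset))
        if d_best.s5 > cfg.t_5prime:
            sep = _conserved_block_between(
                msa,
                msa.aa_col_of_offset(msa.query_index, u.seq_offset),
                msa.aa_col_of_offset(msa.query_index, d_best.candidate.seq_offset),
                cfg,
            )
            if not sep:
                chosen = d_best.candidate
                scores = {"s5": d_best.s5, "s5_upstream": u_score.s5}
            else:
                scores = {"s5": u_score.s5, "s5_downstream": d_best.s5}
    return StartPrediction(
        query_offset=chosen.seq_offset, step="C", scores=scores,
        n_targets=msa.n_targets,
    )


def predict_start(
    msa: DualMsa,
    upstream_gene_end_offset: Optional[int] = None,
    cfg: Optional[ScoringConfig] = None,
) -> StartPrediction:
    """Dispatch the three steps for one query.

    With upstream-gene context indicating overlap or near-abutment (3'
    end downstream of, or within ``overlap_proximity_nt`` upstream of,
    the LORF 5' end), B is tried before C; otherwise A then C.  Queries
    with fewer than ``min_targets`` targets are declined.
    """
    cfg = cfg or ScoringConfig()
    cfg.validate()
    if msa.n_targets < cfg.min_targets:
        return StartPrediction(
            query_offset=None, step="none", n_targets=msa.n_targets,
            reason="too_few_targets",
        )
    overlapish = (
        upstream_gene_end_offset is not None
        and upstream_gene_end_offset > -cfg.overlap_proximity_nt
    )
    if overlapish:
        pred = step_b(msa, upstream_gene_end_offset, cfg)
        if pred is not None:
            return pred
        return step_c(msa, cfg)
    pred = step_a(msa, cfg)
    if pred is not None:
        return pred
    return step_c(msa, cfg)


def candidate_score_table(msa: DualMsa, cfg: ScoringConfig):
    """Per-candidate evidence rows (for the tab-separated score dump)."""
    import pandas as pd

    rows = []
    for cand in msa.query_candidates:
        sc = candidate_score_s5(msa, cand, cfg)
        blk = block_conservation_score(msa, cand.aa_col, cfg.block_len_aa, cfg)
        rows.append(
            {
                "seq_offset": cand.seq_offset,
                "codon": cand.codon,
                "msa_column": cand.msa_column,
                "s5": sc.s5,
                "n_support": sc.n_support,
                "n_penalty": sc.n_penalty,
                "s_blk_from_here": None if blk is None else blk.score,
            }
        )
    return pd.DataFrame(rows)
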