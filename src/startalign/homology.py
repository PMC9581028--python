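"""Target-set construction: coverage filtering, Kimura-2P distances,
distance-window selection, redundancy removal and capped sampling.

Raw homologs arrive as (target LORF, query/target protein pairwise
alignment) pairs from a pluggable search provider — the repository ships
a fixture provider reading the tab-separated relation tables written by
:mod:`startalign.synthsim`; an external protein-search tool can be
wrapped with the same contract.  Evolutionary distances are computed on
nucleotide pairwise alignments obtained by codon back-mapping of the
protein alignment (no realignment): for closely related sequences a
local, protein-guided alignment already yields accurate distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqmodel import LorfRecord, ScoringConfig, read_fasta_lorfs

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_ACGT = frozenset("ACGT")

# Rejection-reason codes, in pipeline order.
REASONS = (
    "low_coverage",
    "undefined_distance",
    "too_close",
    "too_far",
    "redundant",
    "sampled_out",
)


@dataclass
class PairwiseDistanceStats:
    """Transition/transversion composition of one pairwise nt alignment."""

    aligned_positions: int
    P: float  # transition fraction (A<->G, C<->T)
    Q: float  # transversion fraction (all other mismatches)

    @property
    def defined(self) -> bool:
        return (
            self.aligned_positions > 0
            and (1.0 - 2.0 * self.P - self.Q) > 0.0
            and (1.0 - 2.0 * self.Q) > 0.0
        )


def transition_transversion_fractions(
    row_a: str, row_b: str
) -> PairwiseDistanceStats:
    """P and Q over the columns with an unambiguous nucleotide in both rows.

    Columns containing a gap or ambiguity letter in either row are
    excluded from ``aligned_positions``.
    """
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    n = ts = tv = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a not in _ACGT or b not in _ACGT:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return PairwiseDistanceStats(aligned_positions=0, P=0.0, Q=0.0)
    return PairwiseDistanceStats(aligned_positions=n, P=ts / n, Q=tv / n)


def kimura_distance(stats: PairwiseDistanceStats) -> Optional[float]:
    """Kimura two-parameter distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    Returns None (never 0 or inf) when the alignment is empty or the
    logarithm's argument is non-positive (distance saturated).
    """
    if stats.aligned_positions == 0 or not stats.defined:
        return None
    arg = (1.0 - 2.0 * stats.P - stats.Q) * math.sqrt(1.0 - 2.0 * stats.Q)
    return -0.5 * math.log(arg)


@dataclass
class RawTarget:
    """A homolog as delivered by a search provider: the target LORF plus
    its protein pairwise alignment with the query (two gapped rows)."""

    record: LorfRecord
    aln_query_aa: str
    aln_target_aa: str
    coverage_query: Optional[float] = None
    coverage_target: Optional[float] = None


@dataclass
class TargetRelation:
    """Audit entry for one raw target through the selection pipeline."""

    target_id: str
    coverage_query: float
    coverage_target: float
    dist_to_query: PairwiseDistanceStats
    d_ab: Optional[float]
    kept: bool
    reason: Optional[str] = None  # set iff not kept


def backmap_pairwise_nt(
    query: LorfRecord, target: RawTarget
) -> tuple[str, str]:
    """Expand a protein pairwise alignment to codon-resolved nt rows."""
    rows = []
    for rec, aln in (
        (query, target.aln_query_aa),
        (target.record, target.aln_target_aa),
    ):
        if aln.replace("-", "") != rec.aa:
            raise ValueError(
                f"{rec.id}: aligned protein row does not ungap to the record's aa"
            )
        out, pos = [], 0
        for ch in aln:
            if ch == "-":
                out.append("---")
            else:
                out.append(rec.coding_nt[3 * pos : 3 * pos + 3])
                pos += 1
        rows.append("".join(out))
    return rows[0], rows[1]


def _coverages(target: RawTarget, query: LorfRecord) -> tuple[float, float]:
    if target.coverage_query is not None and target.coverage_target is not None:
        return target.coverage_query, target.coverage_target
    both = sum(
        1
        for a, b in zip(target.aln_query_aa, target.aln_target_aa)
        if a != "-" and b != "-"
    )
    return both / len(query.aa), both / len(target.record.aa)


def query_target_distance(
    query: LorfRecord, target: RawTarget
) -> tuple[PairwiseDistanceStats, Optional[float]]:
    nt_q, nt_t = backmap_pairwise_nt(query, target)
    stats = transition_transversion_fractions(nt_q, nt_t)
    return stats, kimura_distance(stats)


def _target_target_distance(
    query: LorfRecord, a: RawTarget, b: RawTarget
) -> Optional[float]:
    """Distance between two targets via composition through the query.

    Columns where both targets align a residue to the same query residue
    define a (local) pairwise alignment of the two targets.
    """

    def query_pos_to_codon(t: RawTarget) -> dict[int, str]:
        m: dict[int, str] = {}
        qpos = tpos = 0
        for qa, ta in zip(t.aln_query_aa, t.aln_target_aa):
            if qa != "-" and ta != "-":
                m[qpos] = t.record.coding_nt[3 * tpos : 3 * tpos + 3]
            if qa != "-":
                qpos += 1
            if ta != "-":
                tpos += 1
        return m

    ma, mb = query_pos_to_codon(a), query_pos_to_codon(b)
    shared = sorted(set(ma) & set(mb))
    if not shared:
        return None
    row_a = "".join(ma[p] for p in shared)
    row_b = "".join(mb[p] for p in shared)
    return kimura_distance(transition_transversion_fractions(row_a, row_b))


def select_targets(
    query: LorfRecord,
    raw_targets: Sequence[RawTarget],
    cfg: ScoringConfig,
) -> tuple[list[RawTarget], list[TargetRelation]]:
    """Run the target-selection pipeline and return kept targets + audit.

    Pipeline (default order): (1) drop alignments covering <= coverage_min
    of either protein; (2) Kimura distance to the query from the
    back-mapped nt alignment; (3) window [kimura_min, kimura_max], with
    undefined distances dropped; (4) greedy redundancy pass in ascending
    distance-to-query order, dropping any target closer than kimura_min
    to an already-kept one; (5) uniform sampling down to max_targets with
    cfg.rng_seed.  Every input receives exactly one reason code or kept.
    """
    cfg.validate()
    relations: dict[int, TargetRelation] = {}
    stage: list[tuple[int, RawTarget, PairwiseDistanceStats, float]] = []

    sampled_out_idx: set[int] = set()
    indices = list(range(len(raw_targets)))
    if cfg.sample_order == "sample_first" and len(indices) > cfg.max_targets:
        rng = np.random.default_rng(cfg.rng_seed)
        keep = set(rng.choice(len(indices), size=cfg.max_targets, replace=False).tolist())
        sampled_out_idx = set(indices) - keep

    for i, t in enumerate(raw_targets):
        cov_q, cov_t = _coverages(t, query)
        stats, d = query_target_distance(query, t)

        def rel(kept: bool, reason: Optional[str] = None) -> TargetRelation:
            return TargetRelation(
                target_id=t.record.id,
                coverage_query=cov_q,
                coverage_target=cov_t,
                dist_to_query=stats,
                d_ab=d,
                kept=kept,
                reason=reason,
            )

        if i in sampled_out_idx:
            relations[i] = rel(False, "sampled_out")
        elif cov_q <= cfg.coverage_min or cov_t <= cfg.coverage_min:
            relations[i] = rel(False, "low_coverage")
        elif d is None:
            relations[i] = rel(False, "undefined_distance")
        elif d < cfg.kimura_min:
            relations[i] = rel(False, "too_close")
        elif d > cfg.kimura_max:
            relations[i] = rel(False, "too_far")
        else:
            relations[i] = rel(True)
            stage.append((i, t, stats, d))

    # Redundancy: ascending distance to the query, so the set closest to
    # the query is retained deterministically.
    stage.sort(key=lambda item: (item[3], item[1].record.id))
    kept_stage: list[tuple[int, RawTarget, PairwiseDistanceStats, float]] = []
    for item in stage:
        redundant = False
        for kept_item in kept_stage:
            d_tt = _target_target_distance(query, item[1], kept_item[1])
            if d_tt is not None and d_tt < cfg.kimura_min:
                redundant = True
                break
        if redundant:
            relations[item[0]].kept = False
            relations[item[0]].reason = "redundant"
        else:
            kept_stage.append(item)

    if cfg.sample_order == "filter_first" and len(kept_stage) > cfg.max_targets:
        rng = np.random.default_rng(cfg.rng_seed)
        chosen = set(
            rng.choice(len(kept_stage), size=cfg.max_targets, replace=False).tolist()
        )
        for j, item in enumerate(kept_stage):
            if j not in chosen:
                relations[item[0]].kept = False
                relations[item[0]].reason = "sampled_out"
        kept_stage = [item for j, item in enumerate(kept_stage) if j in chosen]

    kept_stage.sort(key=lambda item: item[0])  # restore input order
    kept = [item[1] for item in kept_stage]
    audit = [relations[i] for i in range(len(raw_targets))]
    return kept, audit


def distance_matrix(
    query: LorfRecord, targets: Sequence[RawTarget]
) -> pd.DataFrame:
    """Full query/target-target Kimura distance matrix (diagnostics)."""
    names = [query.id] + [t.record.id for t in targets]
    n = len(names)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 0.0)
    for i, t in enumerate(targets, start=1):
        _, d = query_target_distance(query, t)
        mat[0, i] = mat[i, 0] = np.nan if d is None else d
    for i in range(1, n):
        for j in range(i + 1, n):
            d = _target_target_distance(query, targets[i - 1], targets[j - 1])
            mat[i, j] = mat[j, i] = np.nan if d is None else d
    return pd.DataFrame(mat, index=names, columns=names)


def relations_table(audit: Sequence[TargetRelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": [r.target_id for r in audit],
            "coverage_query": [r.coverage_query for r in audit],
            "coverage_target": [r.coverage_target for r in audit],
            "P": [r.dist_to_query.P for r in audit],
            "Q": [r.dist_to_query.Q for r in audit],
            "d_ab": [r.d_ab for r in audit],
            "kept": [r.kept for r in audit],
            "reason": [r.reason or "" for r in audit],
        }
    )


# ---------------------------------------------------------------------------
# Fixture search provider

def load_fixture_family(
    directory,
) -> tuple[LorfRecord, list[RawTarget]]:
    """Read a family bundle: query.fasta, targets.fasta, relations.tsv.

    The relation table carries one row per target: ``target_id``, the two
    aligned protein rows, and the two coverage fractions.  This is the
    offline stand-in for an external homology-search adapter.
    """
    directory = Path(directory)
    query = read_fasta_lorfs(directory / "query.fasta")[0]
    targets = {r.id: r for r in read_fasta_lorfs(directory / "targets.fasta")}
    table = pd.read_csv(directory / "relations.tsv", sep="\t", dtype=str)
    raw = []
    for _, row in table.iterrows():
        rec = targets[row["target_id"]]
        raw.append(
            RawTarget(
                record=rec,
                aln_query_aa=row["aln_query_aa"],
                aln_target_aa=row["aln_target_aa"],
                coverage_query=float(row["coverage_query"]),
                coverage_target=float(row["coverage_target"]),
            )
        )
    return query, raw
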