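"""Shared fixtures: hand-built dual MSAs, synthetic families, and
independent brute-force score oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from startalign.msa_layer import DualMsa, backmap_to_nucleotide
from startalign.seqmodel import LorfRecord, START_CODONS

# Codons with pairwise-distinct amino acids, none of them Met/Val/Leu,
# none a stop: column i of a "noise block" can give every row a different
# residue, so those columns contribute zero to any identity score.
DISTINCT_AA_CODONS = [
    "GCT",  # A
    "TGT",  # C
    "GAT",  # D
    "GAA",  # E
    "TTT",  # F
    "GGT",  # G
    "CAT",  # H
    "ATT",  # I
    "AAA",  # K
    "AAT",  # N
    "CCT",  # P
    "CAA",  # Q
    "CGT",  # R
    "TCT",  # S
    "ACT",  # T
    "TGG",  # W
    "TAT",  # Y
]


def msa_from_codons(codon_rows: list[list[str]], query_index: int = 0) -> DualMsa:
    """Build a gap-free DualMsa from per-row codon lists (stop appended)."""
    records = [
        LorfRecord(id=f"row{i}", nt="".join(codons) + "TAA")
        for i, codons in enumerate(codon_rows)
    ]
    aa_rows = [r.aa for r in records]
    return backmap_to_nucleotide(aa_rows, records, query_index=query_index)


def noise_column(n_rows: int, skip: int | None = None) -> list[str]:
    """One codon per row, all encoding different amino acids."""
    assert n_rows <= len(DISTINCT_AA_CODONS)
    col = DISTINCT_AA_CODONS[:n_rows]
    if skip is not None:
        col = col[:skip] + col[skip + 1 :] + [col[skip]]
    return col


def build_columns(columns: list[list[str]]) -> list[list[str]]:
    """Transpose a column-major codon layout into codon rows."""
    n_rows = len(columns[0])
    return [[col[r] for col in columns] for r in range(n_rows)]


# ---------------------------------------------------------------------------
# Independent brute-force oracles (never reuse package internals)

def brute_block_score(
    aa_rows: list[str], query_index: int, aa_col: int, r: int
) -> float | None:
    """Triple-loop evaluation of the block identity score, as printed."""
    n = len(aa_rows)
    cols, c = [], aa_col
    while len(cols) < r and c < len(aa_rows[query_index]):
        if aa_rows[query_index][c] != "-":
            cols.append(c)
        c += 1
    if len(cols) < r:
        return None
    total = 0
    for m in range(n):
        for k in range(n):
            if m == k:
                continue
            for j in cols:
                a, b = aa_rows[m][j], aa_rows[k][j]
                if a == b and a not in "-X*":
                    total += 1
    return total / (r * (n - 1) ** 2)


def brute_s5(
    nt_rows: list[str], query_index: int, candidate_nt_col: int, x_codons: int
) -> float:
    """Direct evaluation of the candidate conservation score."""
    nonstart_vl = {"GTA", "GTC", "GTT", "CTA", "CTC", "CTG", "CTT", "TTA"}
    center_aa = candidate_nt_col // 3
    total = 0
    n_targets = len(nt_rows) - 1
    for r, row in enumerate(nt_rows):
        if r == query_index:
            continue
        g = 0
        for c in range(center_aa - x_codons, center_aa + x_codons + 1):
            if 0 <= c < len(row) // 3 and row[3 * c : 3 * c + 3] in START_CODONS:
                g = 1
        p = 1 if row[3 * center_aa : 3 * center_aa + 3] in nonstart_vl else 0
        total += g - p
    return total / n_targets


def brute_dc(distances: list[int], f: int) -> tuple[int, float]:
    """Mode (ties: smallest |x|, then most negative) and DC(x, f)."""
    best = None
    for x in set(distances):
        key = (-distances.count(x), abs(x), x)
        if best is None or key < best[0]:
            best = (key, x)
    x = best[1]
    dc = sum(1 for d in distances if x - f <= d <= x + f) / len(distances)
    return x, dc


def random_dual_msa(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    gap_prob: float = 0.2,
    start_codon_prob: float = 0.2,
) -> DualMsa:
    """A random gapped dual-layer MSA (query row kept gap-free)."""
    import itertools

    sense = [
        c
        for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
        if c not in ("TAA", "TAG", "TGA")
    ]
    aa_rows, records = [], []
    for r in range(n_rows):
        codons = []
        for c in range(n_cols):
            if r != 0 and rng.random() < gap_prob:
                codons.append(None)
            elif rng.random() < start_codon_prob:
                codons.append(str(rng.choice(START_CODONS)))
            else:
                codons.append(str(rng.choice(sense)))
        # avoid all-gap rows
        if all(x is None for x in codons):
            codons[int(rng.integers(n_cols))] = str(rng.choice(sense))
        rec = LorfRecord(
            id=f"r{r}", nt="".join(c for c in codons if c) + "TAA"
        )
        records.append(rec)
        pos = 0
        row = []
        for c in codons:
            if c is None:
                row.append("-")
            else:
                row.append(rec.aa[pos])
                pos += 1
        aa_rows.append("".join(row))
    return backmap_to_nucleotide(aa_rows, records, query_index=0)


@pytest.fixture(scope="session")
def plain_family():
    from startalign.synthsim import FamilySpec, simulate_family

    return simulate_family(FamilySpec(seed=7))


@pytest.fixture(scope="session")
def overlap_family():
    from startalign.synthsim import FamilySpec, simulate_family

    return simulate_family(
        FamilySpec(seed=11, overlap_mode="minus4", overlap_jitter_sd=1.0)
    )


@pytest.fixture(scope="session")
def family_msa(plain_family):
    from startalign.homology import select_targets
    from startalign.msa_layer import GoldAligner, build_protein_msa
    from startalign.seqmodel import ScoringConfig

    kept, _ = select_targets(
        plain_family.query, plain_family.raw_targets(), ScoringConfig()
    )
    records = [plain_family.query] + [t.record for t in kept]
    rows = build_protein_msa(records, GoldAligner(plain_family.gold_aa))
    return backmap_to_nucleotide(rows, records, query_index=0)
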