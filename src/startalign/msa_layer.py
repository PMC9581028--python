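"""Dual-layer multiple alignment: protein MSA plus its codon-resolved
nucleotide back-mapping, with exact column <-> sequence coordinate maps.

The protein aligner is an adapter.  Offline, families come with gold
alignments (stored rows, or trivially colinear synthetic families); an
external progressive aligner (mafft) can be wrapped when present on
PATH.  The nucleotide layer is strictly protein-guided: each amino-acid
column expands to its source codon or to three gap characters, so no
nucleotide realignment ever happens.
"""

from __future__ import annotations

import io
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

from Bio import AlignIO, SeqIO

from .seqmodel import (
    LorfRecord,
    NONSTART_VL_CODONS,
    START_CODONS,
    StartCandidate,
    list_start_candidates,
    write_fasta,
)


class AlignerAdapter(Protocol):
    def align(self, records: Sequence[LorfRecord]) -> list[str]: ...


class GoldAligner:
    """Fixture passthrough: returns pre-computed aligned rows byte-for-byte."""

    def __init__(self, rows_by_id: dict[str, str]):
        self.rows_by_id = dict(rows_by_id)

    def align(self, records: Sequence[LorfRecord]) -> list[str]:
        try:
            return [self.rows_by_id[r.id] for r in records]
        except KeyError as e:
            raise ValueError(f"gold alignment missing row for {e.args[0]!r}") from None


class ColinearAligner:
    """Gap-free alignment of equal-length proteins (indel-free families)."""

    def align(self, records: Sequence[LorfRecord]) -> list[str]:
        lengths = {len(r.aa) for r in records}
        if len(lengths) != 1:
            raise ValueError(
                f"colinear alignment requires equal protein lengths, got {sorted(lengths)}"
            )
        return [r.aa for r in records]


class MafftAligner:
    """External progressive-aligner adapter (mafft)."""

    def __init__(self, executable: str = "mafft", extra_args: Sequence[str] = ()):
        self.executable = executable
        self.extra_args = list(extra_args)

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def align(self, records: Sequence[LorfRecord]) -> list[str]:
        if not self.available():
            raise RuntimeError(f"{self.executable!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "in.fasta"
            write_fasta(fasta, [(r.id, r.aa) for r in records])
            proc = subprocess.run(
                [self.executable, "--quiet", "--amino", *self.extra_args, str(fasta)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"{self.executable} failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
            aligned = {
                rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(io.StringIO(proc.stdout), "fasta")
            }
        return [aligned[r.id] for r in records]


def build_protein_msa(
    records: Sequence[LorfRecord], aligner: AlignerAdapter
) -> list[str]:
    """Aligned aa rows in input order; validated against the inputs."""
    if len(records) < 2:
        raise ValueError("an alignment needs at least two records")
    rows = aligner.align(records)
    if len(rows) != len(records):
        raise ValueError("aligner returned wrong number of rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("aligned rows differ in length")
    for rec, row in zip(records, rows):
        if row.replace("-", "") != rec.aa:
            raise ValueError(f"{rec.id}: aligned row does not ungap to its protein")
    return rows


@dataclass
class DualMsa:
    """Protein MSA and its codon-expanded nucleotide layer.

    ``col_maps[row][aa_col]`` is the 0-based codon index in that record's
    coding sequence, or None at a gap; nucleotide column ``3*aa_col`` is
    the codon's first base.  ``start_marks[row]`` are the row's start
    candidates lifted to alignment columns.
    """

    records: list[LorfRecord]
    aa_rows: list[str]
    nt_rows: list[str]
    query_index: int = 0
    col_maps: list[list[Optional[int]]] = field(default_factory=list)
    start_marks: list[list[StartCandidate]] = field(default_factory=list)

    @property
    def n_seqs(self) -> int:
        return len(self.aa_rows)

    @property
    def n_targets(self) -> int:
        return self.n_seqs - 1

    @property
    def n_cols(self) -> int:
        return len(self.aa_rows[0])

    @property
    def query(self) -> LorfRecord:
        return self.records[self.query_index]

    @property
    def query_candidates(self) -> list[StartCandidate]:
        return self.start_marks[self.query_index]

    def aa_col_of_offset(self, row: int, seq_offset: int) -> int:
        """Alignment column holding codon ``seq_offset//3`` of a row."""
        codon_idx = seq_offset // 3
        m = self.col_maps[row]
        for col, idx in enumerate(m):
            if idx == codon_idx:
                return col
        raise ValueError(f"offset {seq_offset} not aligned in row {row}")

    def codon_at(self, row: int, aa_col: int) -> Optional[str]:
        """Codon of ``row`` at an aa column, or None at a gap."""
        codon = self.nt_rows[row][3 * aa_col : 3 * aa_col + 3]
        return None if codon == "---" else codon

    def query_offset_of_col(self, aa_col: int) -> Optional[int]:
        idx = self.col_maps[self.query_index][aa_col]
        return None if idx is None else 3 * idx

    def query_ungapped_cols(self, start: int = 0) -> list[int]:
        m = self.col_maps[self.query_index]
        return [c for c in range(start, self.n_cols) if m[c] is not None]


def backmap_to_nucleotide(
    aa_rows: Sequence[str],
    records: Sequence[LorfRecord],
    query_index: int = 0,
) -> DualMsa:
    """Expand a protein MSA to the dual-layer representation."""
    nt_rows: list[str] = []
    col_maps: list[list[Optional[int]]] = []
    for rec, row in zip(records, aa_rows):
        if row.replace("-", "") != rec.aa:
            raise ValueError(f"{rec.id}: aa row does not match record")
        if len(rec.coding_nt) != 3 * len(rec.aa):
            raise ValueError(f"{rec.id}: aa/nt length mismatch")
        chunks: list[str] = []
        cmap: list[Optional[int]] = []
        pos = 0
        for ch in row:
            if ch == "-":
                chunks.append("---")
                cmap.append(None)
            else:
                chunks.append(rec.coding_nt[3 * pos : 3 * pos + 3])
                cmap.append(pos)
                pos += 1
        nt_rows.append("".join(chunks))
        col_maps.append(cmap)

    msa = DualMsa(
        records=list(records),
        aa_rows=list(aa_rows),
        nt_rows=nt_rows,
        query_index=query_index,
        col_maps=col_maps,
    )
    marks: list[list[StartCandidate]] = []
    for r, rec in enumerate(records):
        row_marks = []
        # invert the column map once per row
        inv = {idx: col for col, idx in enumerate(col_maps[r]) if idx is not None}
        for cand in list_start_candidates(rec):
            cand.msa_column = 3 * inv[cand.seq_offset // 3]
            row_marks.append(cand)
        marks.append(row_marks)
    msa.start_marks = marks
    return msa


def column_window(
    msa: DualMsa, center_col: int, half_width_nt: int
) -> list[list[tuple[int, str]]]:
    """Per-row frame-0 codons whose first nt column lies within
    +/-half_width_nt of ``center_col`` (a frame-0 nt column of the query
    row); gap codons are skipped.  Returns ``[(aa_col, codon), ...]`` per
    row."""
    if center_col % 3:
        raise ValueError("center_col must be a frame-0 nucleotide column")
    center_aa = center_col // 3
    if not 0 <= center_aa < msa.n_cols:
        raise ValueError(f"center_col {center_col} out of range")
    if msa.col_maps[msa.query_index][center_aa] is None:
        raise ValueError("center_col is a gap in the query row")
    lo = max(0, (center_col - half_width_nt + 2) // 3)
    hi = min(msa.n_cols - 1, (center_col + half_width_nt) // 3)
    out = []
    for r in range(msa.n_seqs):
        row = []
        for c in range(lo, hi + 1):
            codon = msa.codon_at(r, c)
            if codon is not None:
                row.append((c, codon))
        out.append(row)
    return out


def gap_fraction_report(msa: DualMsa) -> list[float]:
    """Per-aa-column gap fraction (diagnostic for distant-target noise)."""
    out = []
    for c in range(msa.n_cols):
        gaps = sum(1 for row in msa.aa_rows if row[c] == "-")
        out.append(gaps / msa.n_seqs)
    return out


# ---------------------------------------------------------------------------
# Aligned FASTA I/O and display

def write_aligned_fasta(path, names: Sequence[str], rows: Sequence[str]) -> None:
    write_fasta(path, list(zip(names, rows)))


def read_aligned_fasta(path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def render_msa(
    msa: DualMsa,
    ref_offset: Optional[int] = None,
    selected_offset: Optional[int] = None,
) -> str:
    """Text view of the protein layer with start-codon semantics.

    Uppercase M/V/L mark residues coded by the start-capable codons
    ATG/GTG/TTG; lowercase v/l mark valine/leucine from synonymous
    non-start codons.  '#ref' / '#selected' marker rows flag the
    annotated and the chosen start columns of the query.
    """

    def marker_row(offset: Optional[int], label: str) -> str:
        if offset is None:
            return ""
        col = msa.aa_col_of_offset(msa.query_index, offset)
        return " " * col + "*" + " " * (msa.n_cols - col - 1) + f"  {label}\n"

    lines = [marker_row(ref_offset, "#ref"), marker_row(selected_offset, "#selected")]
    width = max(len(r.id) for r in msa.records) + 2
    for r, rec in enumerate(msa.records):
        chars = []
        for c in range(msa.n_cols):
            aa = msa.aa_rows[r][c]
            codon = msa.codon_at(r, c)
            if codon in NONSTART_VL_CODONS:
                aa = aa.lower()
            elif codon in START_CODONS:
                aa = aa.upper()
            chars.append(aa)
        lines.append(rec.id.ljust(width) + "".join(chars) + "\n")
    return "".join(line for line in lines if line)
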