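"""Core domain types and genetic-code utilities.

Everything downstream of homology search works on LORFs: a gene's
open-reading frame extended in-frame upstream to the nearest stop codon,
so that every plausible start codon (ATG/GTG/TTG) of the gene is contained
in one sequence.  This module owns LORF extraction, translation (NCBI
table 11), start-candidate enumeration and the scoring configuration
shared by the whole pipeline.

Coordinate conventions: 0-based, half-open everywhere internally; GFF3
I/O (see :mod:`startalign.integrate_eval`) converts to 1-based inclusive.
A ``LorfRecord``'s ``nt`` runs from the LORF's first codon through its
terminal stop codon; ``aa`` is the translation of the codons preceding
that stop.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

# NCBI translation table 11 (bacteria/archaea/plastid).
_TABLE = unambiguous_dna_by_id[11]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))  # TAA, TAG, TGA

#: Valine/leucine codons that cannot act as starts; used by the candidate
#: conservation penalty and by the display layer (lowercase v/l).
NONSTART_VL_CODONS = frozenset(
    {"GTA", "GTC", "GTT", "CTA", "CTC", "CTG", "CTT", "TTA"}
)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon with table 11; ambiguity/partial codons give 'X'."""
    codon = codon.upper()
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table.get(codon, "X")


def translate(nt: str) -> str:
    """Codon-by-codon table-11 translation of an in-frame sequence."""
    if len(nt) % 3:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    return "".join(translate_codon(nt[i : i + 3]) for i in range(0, len(nt), 3))


@dataclass
class LorfRecord:
    """A query or target LORF on its sense strand.

    ``nt`` begins at the LORF's first codon and ends with the gene's stop
    codon; no in-frame stop occurs before that final codon.  ``aa`` is the
    translation of ``nt`` without the terminal stop.
    """

    id: str
    nt: str
    aa: str = ""
    gene_start_offset: Optional[int] = None
    #: Exclusive 0-based offset (possibly negative, i.e. upstream of the
    #: LORF) of the nearest same-strand upstream gene's 3' end, one past
    #: its last nucleotide.  ``gene_start_offset - upstream_gene_end_offset``
    #: is the signed intergenic distance D (negative = overlap).
    upstream_gene_end_offset: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.nt = self.nt.upper()
        if not self.aa:
            self.aa = translate(self.coding_nt)
        self.aa = self.aa.upper()

    @property
    def coding_nt(self) -> str:
        """``nt`` without the terminal stop codon (the MSA substrate)."""
        return self.nt[:-3]

    def codon(self, offset: int) -> str:
        return self.nt[offset : offset + 3]

    def validate(self) -> None:
        if len(self.nt) % 3 or len(self.nt) < 6:
            raise ValueError(f"{self.id}: nt length {len(self.nt)} invalid")
        if self.nt[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: final codon is not a stop codon")
        for i in range(0, len(self.nt) - 3, 3):
            if self.nt[i : i + 3] in STOP_CODONS:
                raise ValueError(f"{self.id}: in-frame stop before final codon")
        if self.aa != translate(self.coding_nt):
            raise ValueError(f"{self.id}: aa does not match translation of nt")
        if self.gene_start_offset is not None:
            g = self.gene_start_offset
            if g % 3 or not 0 <= g < len(self.nt) - 3:
                raise ValueError(f"{self.id}: gene_start_offset {g} invalid")
            if self.codon(g) not in START_CODONS:
                raise ValueError(
                    f"{self.id}: codon at gene_start_offset is {self.codon(g)}"
                )

    @property
    def intergenic_distance(self) -> Optional[int]:
        """Signed distance D from the upstream gene's 3' end to the start."""
        if self.gene_start_offset is None or self.upstream_gene_end_offset is None:
            return None
        return self.gene_start_offset - self.upstream_gene_end_offset


@dataclass
class StartCandidate:
    """A frame-0 ATG/GTG/TTG codon of a LorfRecord.

    ``msa_column`` is the first nucleotide-layer column of the codon once
    the record sits in a DualMsa (None until then); ``aa_col`` is the
    matching amino-acid-layer column.
    """

    seq_offset: int
    codon: str
    msa_column: Optional[int] = None

    @property
    def aa_col(self) -> Optional[int]:
        return None if self.msa_column is None else self.msa_column // 3


@dataclass
class ScoringConfig:
    """Tunable parameters of the whole prediction pipeline.

    Defaults are the method's operating point: r=10 aa blocks with a 0.5
    majority-vote conservation threshold, candidate threshold t5'=0.5 with
    a +/-2-codon (6 nt) neighborhood, a 9 nt search window at the upstream
    gene's 3' end, a 30 nt downstream re-check, Kimura window [0.1, 0.5],
    80% pairwise coverage, and 10..50 targets per alignment.
    """

    block_len_aa: int = 10            # r
    t_blk: float = 0.5
    t_5prime: float = 0.5             # t5'
    neigh_codons: int = 2             # x (6 nt)
    overlap_window_nt: int = 9
    downstream_recheck_nt: int = 30
    dc_margin: int = 3                # f
    kimura_min: float = 0.1
    kimura_max: float = 0.5
    coverage_min: float = 0.8
    max_targets: int = 50             # N_max
    min_targets: int = 10
    rng_seed: int = 0
    #: Eq-as-printed normalisation 1/(r (N-1)^2) ("printed") or the
    #: ordered-pair count 1/(r N (N-1)) ("pair_count").
    blk_norm: str = "printed"
    #: Pipeline order for the sampling cap: filter distances first, then
    #: sample ("filter_first"), or sample the raw set first ("sample_first").
    sample_order: str = "filter_first"
    #: Step B is attempted when the upstream gene's 3' end lies downstream
    #: of, or within this many nt upstream of, the LORF 5' end.
    overlap_proximity_nt: int = 10

    def validate(self) -> None:
        if not (0 < self.t_blk <= 1 and 0 < self.t_5prime <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        if not self.kimura_min < self.kimura_max:
            raise ValueError("kimura_min must be < kimura_max")
        if self.min_targets > self.max_targets:
            raise ValueError("min_targets must be <= max_targets")
        for name in (
            "block_len_aa",
            "neigh_codons",
            "overlap_window_nt",
            "downstream_recheck_nt",
        ):
            if getattr(self, name) < 0 or (
                name in ("block_len_aa", "overlap_window_nt") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.blk_norm not in ("printed", "pair_count"):
            raise ValueError("blk_norm must be 'printed' or 'pair_count'")
        if self.sample_order not in ("filter_first", "sample_first"):
            raise ValueError("sample_order must be 'filter_first' or 'sample_first'")

    def replace(self, **kw) -> "ScoringConfig":
        return replace(self, **kw)


def extract_lorf(
    seq: str,
    gene_end: int,
    strand: str = "+",
    annotated_start: Optional[int] = None,
    record_id: str = "lorf",
) -> LorfRecord:
    """Extend a gene upstream to its LORF.

    ``gene_end`` is the 0-based exclusive 3' coordinate of the gene on the
    sense strand (for '-' genes, coordinates refer to the
    reverse-complemented sequence), whose last codon must be a stop.  The
    LORF runs from the first codon after the nearest upstream in-frame
    stop (or the in-frame sequence edge) through that terminal stop.
    ``annotated_start`` (sense-strand, 0-based) is recorded relative to
    the LORF when given.
    """
    if strand == "-":
        sense = reverse_complement(seq)
        return extract_lorf(
            sense,
            gene_end,
            "+",
            annotated_start=annotated_start,
            record_id=record_id,
        )
    if strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = seq.upper()
    if not 3 <= gene_end <= len(seq):
        raise ValueError(f"gene_end {gene_end} out of range")
    if seq[gene_end - 3 : gene_end] not in STOP_CODONS:
        raise ValueError(f"no stop codon ending at {gene_end}")
    lo = gene_end - 3
    while lo - 3 >= 0 and seq[lo - 3 : lo] not in STOP_CODONS:
        lo -= 3
    if lo == gene_end - 3:
        raise ValueError("LORF shorter than one codon")
    start_off = None
    if annotated_start is not None:
        if annotated_start < lo or (annotated_start - lo) % 3:
            raise ValueError(
                f"annotated_start {annotated_start} not in-frame within LORF [{lo}, {gene_end})"
            )
        start_off = annotated_start - lo
    rec = LorfRecord(
        id=record_id, nt=seq[lo:gene_end], gene_start_offset=start_off,
        source=f"extracted[{lo}:{gene_end}]+",
    )
    rec.validate()
    return rec


def list_start_candidates(lorf: LorfRecord) -> list[StartCandidate]:
    """All frame-0 ATG/GTG/TTG codons of the LORF, 5'->3'.

    The terminal stop codon position is excluded; codons containing
    ambiguity letters are never candidates.
    """
    out = []
    for off in range(0, len(lorf.nt) - 3, 3):
        codon = lorf.nt[off : off + 3]
        if codon in START_CODONS:
            out.append(StartCandidate(seq_offset=off, codon=codon))
    return out


# ---------------------------------------------------------------------------
# FASTA I/O

def _open_maybe_gz(path: Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta_lorfs(path) -> list[LorfRecord]:
    """Read LORF nucleotide records from (possibly gzipped) FASTA."""
    records = []
    seen: set[str] = set()
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(LorfRecord(id=rec.id, nt=str(rec.seq), source=str(path)))
    return records


def write_fasta(path, records: Sequence[tuple[str, str]]) -> None:
    with _open_maybe_gz(Path(path), "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
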