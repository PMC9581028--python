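"""Synthetic homologous-LORF families with known true starts.

A family is a star topology: an ancestral LORF (the query) and n targets
independently evolved from it under a Kimura two-parameter (K80)
substitution process, with no indels, so the gold alignment is the
trivial colinear one.  The ancestor is laid out as

    [upstream noise | true start | variable N-terminus | conserved coding | stop]

and three features of real gene families are emulated deliberately:

* conservation contrast — the coding region evolves at a lower
  substitution rate than the upstream region, and additionally under
  purifying selection (nonsynonymous proposals accepted with probability
  ``dn_ds``), because the conserved amino-acid blocks the start-selection
  logic keys on only exist when protein sequence, not just nucleotide
  sequence, is conserved;
* N-terminal hypervariability — the first ``nterm_variable_aa`` codons
  after the true start evolve at the fast (upstream) rate, as real
  protein N-termini are poorly conserved; the conserved block therefore
  begins downstream of the start codon, as the block-based steps assume;
* truth preservation — the true start codon stays start-capable
  (ATG/GTG/TTG) and no in-frame stop ever appears upstream of the
  terminal stop, so every target remains a valid LORF with the same true
  start offset.

Ancestral upstream and N-terminal codons exclude ATG/GTG/TTG, so the
query's upstream start candidates are exactly the planted decoys.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .homology import (
    RawTarget,
    kimura_distance,
    transition_transversion_fractions,
)
from .seqmodel import (
    LorfRecord,
    START_CODONS,
    STOP_CODONS,
    translate_codon,
    write_fasta,
)

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}

_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]
_NONSTART_SENSE_CODONS = [c for c in _SENSE_CODONS if c not in START_CODONS]


def k80_expected_pq(rate: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Expected transition/transversion fractions of a K80 process run to
    ``rate`` expected substitutions per site.

    ``ts_tv_ratio`` is the instantaneous transition rate over the total
    transversion rate (the small-time P/Q ratio).  The Kimura distance
    estimator applied to (P, Q) returns ``rate`` exactly, which is what
    makes the generator the model's inverse.
    """
    if not 0 < rate:
        raise ValueError("rate must be positive")
    rho = ts_tv_ratio
    beta_t = rate / (2.0 * (rho + 1.0))
    alpha_t = rate * rho / (rho + 1.0)
    p = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    q = 0.5 - 0.5 * np.exp(-4.0 * beta_t)
    return float(p), float(q)


def _mutate_sites(
    encoded: np.ndarray, p: float, q: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised per-site K80 draw on a base-encoded (0..3) array."""
    u = rng.random(encoded.shape[0])
    pick = rng.integers(0, 2, size=encoded.shape[0])
    out = encoded.copy()
    ts = u < p
    tv = (~ts) & (u < p + q)
    # transitions: A<->G, C<->T  (encoding A=0 C=1 G=2 T=3)
    out[ts] = (encoded[ts] + 2) % 4
    # transversions: purine -> {C,T}, pyrimidine -> {A,G}
    out[tv] = ((encoded[tv] + 1) % 2) + 2 * pick[tv]
    return out


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_B2I[b] for b in seq), dtype=np.int8, count=len(seq))


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def evolve_k80(
    seq: str,
    rate: float,
    ts_tv_ratio: float,
    rng: np.random.Generator,
    forbid_frame0_stops: bool = False,
    preserve_start_at: Optional[int] = None,
    max_codon_tries: int = 50,
) -> str:
    """Evolve a sequence under per-site independent K80 substitution.

    Length is preserved; no indels.  With ``forbid_frame0_stops`` any
    frame-0 codon mutated into a stop is rejected and resampled (the
    ancestral codon is restored if resampling keeps failing); with
    ``preserve_start_at`` the codon at that offset must stay in
    {ATG, GTG, TTG}.
    """
    if rate == 0:
        return seq
    if rate >= 0.75:
        raise ValueError("rate must be < 0.75 expected substitutions/site")
    p, q = k80_expected_pq(rate, ts_tv_ratio)
    enc = _encode(seq)
    out = _mutate_sites(enc, p, q, rng)

    def resample_codon(i: int, ok) -> None:
        for _ in range(max_codon_tries):
            if ok(_decode(out[i : i + 3])):
                return
            out[i : i + 3] = _mutate_sites(enc[i : i + 3], p, q, rng)
        out[i : i + 3] = enc[i : i + 3]  # revert to ancestral

    if forbid_frame0_stops:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            if preserve_start_at is not None and i == preserve_start_at:
                continue
            resample_codon(i, lambda c: c not in STOP_CODONS)
    if preserve_start_at is not None:
        resample_codon(preserve_start_at, lambda c: c in START_CODONS)
    return _decode(out)


def _evolve_coding(
    codons: Sequence[str],
    rate: float,
    ts_tv_ratio: float,
    dn_ds: float,
    rng: np.random.Generator,
) -> list[str]:
    """Codon-wise K80 with purifying selection.

    Site substitutions are proposed from the K80 process and applied one
    at a time; a proposal creating a stop codon is discarded, and a
    nonsynonymous proposal is accepted only with probability ``dn_ds``.
    """
    p, q = k80_expected_pq(rate, ts_tv_ratio)
    out = []
    for codon in codons:
        current = codon
        enc = _encode(codon)
        proposed = _mutate_sites(enc, p, q, rng)
        for site in range(3):
            if proposed[site] == enc[site]:
                continue
            trial = current[:site] + _BASES[proposed[site]] + current[site + 1 :]
            if trial in STOP_CODONS:
                continue
            if translate_codon(trial) != translate_codon(current):
                if rng.random() >= dn_ds:
                    continue
            current = trial
        out.append(current)
    return out


@dataclass
class FamilySpec:
    """Declarative description of one synthetic family.

    Rates are expected substitutions/site along one query-to-target
    branch.  ``rate_scale_range`` draws a per-target factor so pairwise
    query-target Kimura distances spread over ``dist_window``; a target
    whose realised distance falls outside the window is resampled
    (bounded retries), keeping the spec declarative.
    """

    n_targets: int = 20
    coding_len_aa: int = 120          # codons after the true start, excl. stop
    upstream_len_nt: int = 90
    sub_rate_coding: float = 0.22
    sub_rate_upstream: float = 0.66
    ts_tv_ratio: float = 2.0
    decoy_upstream_starts: int = 1
    overlap_mode: str | int = "none"  # none | minus4 | minus1 | custom D (int)
    overlap_jitter_sd: float = 0.0
    seed: int = 0
    dn_ds: float = 0.1
    nterm_variable_aa: int = 10
    rate_scale_range: tuple[float, float] = (0.7, 1.6)
    dist_window: tuple[float, float] = (0.1, 0.5)
    max_retries_per_target: int = 20

    def validate(self) -> None:
        if self.upstream_len_nt % 3:
            raise ValueError("upstream_len_nt must be a multiple of 3")
        for r in (self.sub_rate_coding, self.sub_rate_upstream):
            if not 0 < r < 0.75:
                raise ValueError("substitution rates must lie in (0, 0.75)")
        if self.nterm_variable_aa >= self.coding_len_aa:
            raise ValueError("nterm_variable_aa must be < coding_len_aa")
        if self.decoy_upstream_starts > self.upstream_len_nt // 3:
            raise ValueError(
                f"upstream region ({self.upstream_len_nt} nt) too short for "
                f"{self.decoy_upstream_starts} decoy starts"
            )
        if self.n_targets < 1:
            raise ValueError("n_targets must be positive")
        if isinstance(self.overlap_mode, str) and self.overlap_mode not in (
            "none",
            "minus4",
            "minus1",
        ):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


@dataclass
class FamilyTruth:
    true_start_offset: int
    decoy_offsets: list[int]
    target_distances: dict[str, float]
    intergenic: dict[str, int] = field(default_factory=dict)


@dataclass
class Family:
    spec: FamilySpec
    query: LorfRecord
    targets: list[LorfRecord]
    gold_aa: dict[str, str]
    truth: FamilyTruth

    def raw_targets(self) -> list[RawTarget]:
        """Targets with their (colinear) protein pairwise alignments."""
        return [
            RawTarget(
                record=t,
                aln_query_aa=self.query.aa,
                aln_target_aa=t.aa,
                coverage_query=1.0,
                coverage_target=1.0,
            )
            for t in self.targets
        ]


def _overlap_d(mode: str | int) -> Optional[int]:
    if mode == "none":
        return None
    if mode == "minus4":
        return -4
    if mode == "minus1":
        return -1
    return int(mode)


def simulate_family(spec: FamilySpec) -> Family:
    """Build a family: ancestor query, evolved targets, gold alignment, truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_up = spec.upstream_len_nt // 3
    up_codons = list(rng.choice(_NONSTART_SENSE_CODONS, size=n_up))
    decoy_slots = sorted(
        rng.choice(n_up, size=spec.decoy_upstream_starts, replace=False).tolist()
    )
    for slot in decoy_slots:
        up_codons[slot] = str(rng.choice(START_CODONS))
    nterm = list(rng.choice(_NONSTART_SENSE_CODONS, size=spec.nterm_variable_aa))
    n_core = spec.coding_len_aa - spec.nterm_variable_aa
    core = list(rng.choice(_SENSE_CODONS, size=n_core))
    stop = str(rng.choice(STOP_CODONS))

    true_start = spec.upstream_len_nt
    ancestor = "".join(up_codons) + "ATG" + "".join(nterm) + "".join(core) + stop

    d_overlap = _overlap_d(spec.overlap_mode)
    query = LorfRecord(
        id="query",
        nt=ancestor,
        gene_start_offset=true_start,
        upstream_gene_end_offset=None if d_overlap is None else true_start - d_overlap,
        source="synthsim:ancestor",
    )
    query.validate()

    fast_len = true_start + 3 + 3 * spec.nterm_variable_aa  # upstream+start+N-term
    targets: list[LorfRecord] = []
    distances: dict[str, float] = {}
    intergenic: dict[str, int] = {}
    lo, hi = spec.dist_window
    for i in range(spec.n_targets):
        for attempt in range(spec.max_retries_per_target):
            scale = rng.uniform(*spec.rate_scale_range)
            rate_up = min(spec.sub_rate_upstream * scale, 0.74)
            rate_cod = spec.sub_rate_coding * scale
            fast = evolve_k80(
                ancestor[:fast_len],
                rate_up,
                spec.ts_tv_ratio,
                rng,
                forbid_frame0_stops=True,
                preserve_start_at=true_start,
            )
            core_codons = [
                ancestor[j : j + 3] for j in range(fast_len, len(ancestor) - 3, 3)
            ]
            slow = "".join(
                _evolve_coding(core_codons, rate_cod, spec.ts_tv_ratio, spec.dn_ds, rng)
            )
            nt = fast + slow + stop
            stats = transition_transversion_fractions(ancestor, nt)
            d = kimura_distance(stats)
            if d is not None and lo <= d <= hi:
                break
        else:
            raise RuntimeError(
                f"could not place target {i} inside Kimura window {spec.dist_window} "
                f"after {spec.max_retries_per_target} attempts"
            )
        tid = f"t{i:03d}"
        up_end = None
        if d_overlap is not None:
            jitter = (
                int(round(rng.normal(0.0, spec.overlap_jitter_sd)))
                if spec.overlap_jitter_sd > 0
                else 0
            )
            up_end = true_start - d_overlap + jitter
            intergenic[tid] = true_start - up_end
        rec = LorfRecord(
            id=tid,
            nt=nt,
            gene_start_offset=true_start,
            upstream_gene_end_offset=up_end,
            source=f"synthsim:seed={spec.seed}",
        )
        rec.validate()
        targets.append(rec)
        distances[tid] = d

    gold = {query.id: query.aa, **{t.id: t.aa for t in targets}}
    truth = FamilyTruth(
        true_start_offset=true_start,
        decoy_offsets=[3 * s for s in decoy_slots],
        target_distances=distances,
        intergenic=intergenic,
    )
    return Family(spec=spec, query=query, targets=targets, gold_aa=gold, truth=truth)


# ---------------------------------------------------------------------------
# Fixture bundles

def write_fixture_bundle(family: Family, directory) -> None:
    """Emit a family as plain-text files consumable by the pipeline.

    query.fasta / targets.fasta (nt LORFs), aligned_aa.fasta /
    aligned_nt.fasta (gold alignment, both layers), relations.tsv (the
    fixture search-provider table) and truth.gff3 + meta.json (ground
    truth and record metadata).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    q, ts = family.query, family.targets
    write_fasta(directory / "query.fasta", [(q.id, q.nt)])
    write_fasta(directory / "targets.fasta", [(t.id, t.nt) for t in ts])
    names = [q.id] + [t.id for t in ts]
    write_fasta(
        directory / "aligned_aa.fasta", [(n, family.gold_aa[n]) for n in names]
    )
    nt_by_id = {q.id: q.coding_nt, **{t.id: t.coding_nt for t in ts}}
    write_fasta(directory / "aligned_nt.fasta", [(n, nt_by_id[n]) for n in names])

    with open(directory / "relations.tsv", "w") as fh:
        fh.write(
            "target_id\taln_query_aa\taln_target_aa\tcoverage_query\tcoverage_target\n"
        )
        for rt in family.raw_targets():
            fh.write(
                f"{rt.record.id}\t{rt.aln_query_aa}\t{rt.aln_target_aa}\t"
                f"{rt.coverage_query}\t{rt.coverage_target}\n"
            )

    with open(directory / "truth.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            "\t".join(
                [
                    q.id,
                    "synthsim",
                    "CDS",
                    str(family.truth.true_start_offset + 1),
                    str(len(q.nt)),
                    ".",
                    "+",
                    "0",
                    "ID=true_gene",
                ]
            )
            + "\n"
        )

    meta = {
        "spec": asdict(family.spec),
        "truth": asdict(family.truth),
        "gene_start_offset": {
            r.id: r.gene_start_offset for r in [q, *ts]
        },
        "upstream_gene_end_offset": {
            r.id: r.upstream_gene_end_offset for r in [q, *ts]
        },
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_fixture_bundle(directory) -> Family:
    """Round-trip reader for :func:`write_fixture_bundle` output."""
    from .homology import load_fixture_family
    from .msa_layer import read_aligned_fasta

    directory = Path(directory)
    query, raw = load_fixture_family(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    spec_d = meta["spec"]
    for key in ("rate_scale_range", "dist_window"):
        spec_d[key] = tuple(spec_d[key])
    spec = FamilySpec(**spec_d)
    starts = meta["gene_start_offset"]
    ends = meta["upstream_gene_end_offset"]
    query.gene_start_offset = starts.get(query.id)
    query.upstream_gene_end_offset = ends.get(query.id)
    targets = []
    for rt in raw:
        rt.record.gene_start_offset = starts.get(rt.record.id)
        rt.record.upstream_gene_end_offset = ends.get(rt.record.id)
        targets.append(rt.record)
    truth_d = meta["truth"]
    truth = FamilyTruth(
        true_start_offset=truth_d["true_start_offset"],
        decoy_offsets=list(truth_d["decoy_offsets"]),
        target_distances=dict(truth_d["target_distances"]),
        intergenic={k: int(v) for k, v in truth_d["intergenic"].items()},
    )
    gold = read_aligned_fasta(directory / "aligned_aa.fasta")
    return Family(spec=spec, query=query, targets=targets, gold_aa=gold, truth=truth)
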