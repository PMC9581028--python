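"""Agreement combiner and gene-start evaluation metrics.

Gene identity is 3'-anchored: prokaryotic 3' ends (reading frames) are
considered solved, so two calls describe the same gene iff they share
(seq_id, strand, 3' end).  The combiner keeps exactly the calls made at
the same 5' position by two independent predictors — an error then
requires both to make the same mistake, so the expected combined error
rate is proportional to the product of the individual error rates.

Metrics over a reference set G and prediction set S:
    M3 = |{s in S : 3' key in G}|,  M5 = |{those also matching 5'}|
    Acc = 100 * M5 / M3,  Err = 100 - Acc,  Covr = 100 * M3 / |G|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneCall:
    """One gene call in genome coordinates (1-based inclusive, GFF-style)."""

    seq_id: str
    strand: str  # '+' | '-'
    start: int   # leftmost genome coordinate
    end: int     # rightmost genome coordinate
    attributes: tuple = ()  # extra GFF attributes, as (key, value) pairs

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def three_prime_key(self) -> tuple[str, str, int]:
        """Strand-aware gene identity: the 3' end is `end` on '+', `start` on '-'."""
        return (self.seq_id, self.strand, self.end if self.strand == "+" else self.start)

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class EvaluationReport:
    n_reference: int
    m3: int
    m5: int

    @property
    def acc(self) -> Optional[float]:
        return None if self.m3 == 0 else 100.0 * self.m5 / self.m3

    @property
    def err(self) -> Optional[float]:
        return None if self.acc is None else 100.0 - self.acc

    @property
    def covr(self) -> float:
        return 100.0 * self.m3 / self.n_reference

    def as_dict(self) -> dict:
        rnd = lambda v: None if v is None else round(v, 2)
        return {
            "n_reference": self.n_reference,
            "M3": self.m3,
            "M5": self.m5,
            "Acc": rnd(self.acc),
            "Err": rnd(self.err),
            "Covr": rnd(self.covr),
        }


def _keyed(calls: Iterable[GeneCall], label: str) -> dict:
    out = {}
    for call in calls:
        k = call.three_prime_key
        if k in out:
            raise ValueError(f"duplicate 3' key {k} in {label} set")
        out[k] = call
    return out


def combine_agreement(
    pred_a: Iterable[GeneCall], pred_b: Iterable[GeneCall]
) -> list[GeneCall]:
    """Calls present in both sets with identical 5' starts.

    Genes present in only one set, or with differing starts, are excluded
    (coverage loss by design).  Duplicate 3' keys within a set are input
    errors.
    """
    a = _keyed(pred_a, "first")
    b = _keyed(pred_b, "second")
    out = []
    for k in a:
        if k in b and a[k].five_prime == b[k].five_prime:
            out.append(a[k])
    return sorted(out, key=lambda c: (c.seq_id, c.start, c.end, c.strand))


def evaluate(
    pred: Iterable[GeneCall], reference: Iterable[GeneCall]
) -> EvaluationReport:
    ref = _keyed(reference, "reference")
    if not ref:
        raise ValueError("reference set is empty")
    prd = _keyed(pred, "prediction")
    m3 = m5 = 0
    for k, call in prd.items():
        if k in ref:
            m3 += 1
            if call.five_prime == ref[k].five_prime:
                m5 += 1
    return EvaluationReport(n_reference=len(ref), m3=m3, m5=m5)


def difference_report(
    set1: Iterable[GeneCall],
    set2: Iterable[GeneCall],
    strata: Optional[dict] = None,
) -> pd.DataFrame:
    """Percentage of shared-3'-key genes whose 5' starts differ, per stratum.

    ``strata`` maps a 3' key to a stratum label (e.g. the producing step
    or a GC bin); unkeyed genes fall into stratum 'all' when strata is
    None, else 'unstratified'.  Empty strata keep their row with n=0 and
    a not-applicable percentage.
    """
    a = _keyed(set1, "first")
    b = _keyed(set2, "second")
    shared = [k for k in a if k in b]
    rows: dict[str, list[int]] = {}
    if strata:
        for label in set(strata.values()):
            rows[str(label)] = [0, 0]
    else:
        rows["all"] = [0, 0]
    for k in shared:
        label = "all" if strata is None else str(strata.get(k, "unstratified"))
        rows.setdefault(label, [0, 0])
        rows[label][0] += 1
        if a[k].five_prime != b[k].five_prime:
            rows[label][1] += 1
    table = []
    for label in sorted(rows):
        n, diff = rows[label]
        table.append(
            {
                "stratum": label,
                "n_shared_3prime": n,
                "n_diff_5prime": diff,
                "pct_diff": round(100.0 * diff / n, 2) if n else None,
            }
        )
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# GFF3 I/O

_GFF_COLS = (
    "seqid source type start end score strand frame attributes".split()
)


def write_gff3(path, calls: Sequence[GeneCall], source: str = "startalign") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            attrs = ";".join(f"{k}={v}" for k, v in c.attributes) or "."
            fh.write(
                "\t".join(
                    [
                        c.seq_id,
                        source,
                        "CDS",
                        str(c.start),
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path, feature_type: str = "CDS") -> list[GeneCall]:
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []  # header-only file: no calls
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    calls = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        attrs = tuple(
            (k, ",".join(v)) for k, v in feat.attributes.items() if k != "ID"
        )
        calls.append(
            GeneCall(
                seq_id=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                attributes=attrs,
            )
        )
    return calls
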