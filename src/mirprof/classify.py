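"""Sequential hierarchical read assignment and RPM normalization.

Each size-filtered read is mapped against the reference tiers in order —
(1) rRNA/tRNA decoys, (2) miRNA precursors, (3) genome — and assigned to the
first tier where it has at least one hit; reads hitting no tier are
unmapped.  Matching is ungapped (Hamming), sense-strand only, with a
configurable substitution budget: reads are at most 40 nt and the references
are stored as transcripts, so gapped or reverse-strand alignment adds
nothing here.

Multi-mapping policy: within the miRNA tier a read counts once for the
category but increments every precursor it hits, so reads of a mature arm
shared by two loci (the miR-196a situation) appear in both per-locus counts.
Feature counts therefore need not sum to the category count.

RPM (reads per million mapped reads) divides feature counts by the total
reference-mapped read count; whether rRNA/tRNA reads belong in that
denominator is genuinely ambiguous in practice, so it is a flag
(``exclude_decoys``, default off: decoys count as mapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .references import ReferenceSet

Hit = tuple[str, int, int, int]  # (reference_id, start, end, mismatches)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    category: str  # rRNA_tRNA | miRNA | genome | unmapped
    hits: tuple[Hit, ...]

    def __post_init__(self) -> None:
        if (self.category == "unmapped") != (len(self.hits) == 0):
            raise ValueError("unmapped iff no hits")


@dataclass
class CategoryCounts:
    total_reads: int
    by_category: dict[str, int]
    by_feature: dict[str, int]  # per-precursor counts within the miRNA tier


@dataclass
class NormalizedCounts:
    rpm: dict[str, float]
    denominator: int


def length_filter(
    reads: list[tuple[str, str]], min_len: int = 10, max_len: int = 40
) -> list[tuple[str, str]]:
    """Keep reads with min_len <= length <= max_len (inclusive), preserving order."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [(rid, seq) for rid, seq in reads if min_len <= len(seq) <= max_len]


def match_read(
    read: str, reference: str, max_mismatches: int = 0
) -> list[tuple[int, int, int]]:
    """All ungapped occurrences of ``read`` in ``reference`` with at most
    ``max_mismatches`` substitutions, as (start, end, mismatches) in 0-based
    half-open coordinates, sorted by start.  Sense strand only."""
    m = len(read)
    if m < 1:
        raise ValueError("read must be non-empty")
    n = len(reference)
    if m > n:
        return []
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
    mism = (windows != q).sum(axis=1)
    starts = np.nonzero(mism <= max_mismatches)[0]
    return [(int(s), int(s) + m, int(mism[s])) for s in starts]


def _tier_hits(
    seq: str, tier: list[tuple[str, str]], max_mismatches: int
) -> tuple[Hit, ...]:
    hits: list[Hit] = []
    for ref_id, ref_seq in tier:
        for start, end, mm in match_read(seq, ref_seq, max_mismatches):
            hits.append((ref_id, start, end, mm))
    return tuple(hits)


def assign_reads(
    reads: list[tuple[str, str]],
    refs: ReferenceSet,
    max_mismatches: int = 1,
) -> list[ReadAssignment]:
    """Assign each read to the first tier it hits (decoys, then precursors,
    then genome); within the hit tier every hitting reference is recorded.

    Raises on duplicate read ids (they would make truth-table joins
    ambiguous).  Identical sequences are resolved once and cached.
    """
    ids = [rid for rid, _ in reads]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate read ids")

    tiers = (
        ("rRNA_tRNA", list(refs.decoys)),
        ("miRNA", [(p.id, p.sequence) for p in refs.precursors]),
        ("genome", list(refs.genome)),
    )
    cache: dict[str, tuple[str, tuple[Hit, ...]]] = {}
    out: list[ReadAssignment] = []
    for rid, seq in reads:
        if seq not in cache:
            resolved = ("unmapped", ())
            for category, tier in tiers:
                hits = _tier_hits(seq, tier, max_mismatches)
                if hits:
                    resolved = (category, hits)
                    break
            cache[seq] = resolved
        category, hits = cache[seq]
        out.append(ReadAssignment(read_id=rid, category=category, hits=hits))
    return out


def category_counts(assignments: list[ReadAssignment]) -> CategoryCounts:
    by_category = {"rRNA_tRNA": 0, "miRNA": 0, "genome": 0, "unmapped": 0}
    by_feature: dict[str, int] = {}
    for a in assignments:
        by_category[a.category] += 1
        if a.category == "miRNA":
            for ref_id in {h[0] for h in a.hits}:
                by_feature[ref_id] = by_feature.get(ref_id, 0) + 1
    return CategoryCounts(
        total_reads=len(assignments), by_category=by_category, by_feature=by_feature
    )


def rpm_normalize(
    counts: CategoryCounts, exclude_decoys: bool = False
) -> NormalizedCounts:
    """Per-feature reads-per-million over the total reference-mapped reads.

    ``exclude_decoys`` drops the rRNA/tRNA tier from the denominator."""
    denominator = counts.total_reads - counts.by_category["unmapped"]
    if exclude_decoys:
        denominator -= counts.by_category["rRNA_tRNA"]
    if denominator <= 0:
        raise ValueError("no reference-mapped reads: RPM denominator is zero")
    rpm = {f: 1e6 * c / denominator for f, c in counts.by_feature.items()}
    return NormalizedCounts(rpm=rpm, denominator=denominator)


# --------------------------------------------------------------------- I/O

def assignments_to_frame(assignments: list[ReadAssignment]) -> pd.DataFrame:
    """One row per hit; unmapped reads carry empty hit fields."""
    rows = []
    for a in assignments:
        if not a.hits:
            rows.append((a.read_id, a.category, "", "", "", ""))
        for ref_id, start, end, mm in a.hits:
            rows.append((a.read_id, a.category, ref_id, start, end, mm))
    return pd.DataFrame(
        rows,
        columns=["read_id", "category", "reference_id", "start", "end", "mismatches"],
    )


def write_assignments(assignments: list[ReadAssignment], path: str | Path) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[ReadAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"reference_id": str})
    out: list[ReadAssignment] = []
    for rid, grp in df.groupby("read_id", sort=False):
        category = grp["category"].iloc[0]
        hits: list[Hit] = []
        for row in grp.itertuples(index=False):
            if isinstance(row.reference_id, str) and row.reference_id:
                hits.append(
                    (row.reference_id, int(row.start), int(row.end), int(row.mismatches))
                )
        out.append(ReadAssignment(read_id=str(rid), category=category, hits=tuple(hits)))
    return out


def counts_to_frame(counts: CategoryCounts) -> pd.DataFrame:
    rows = [("category", cat, n) for cat, n in counts.by_category.items()]
    rows += [("feature", f, n) for f, n in sorted(counts.by_feature.items())]
    return pd.DataFrame(rows, columns=["level", "name", "count"])


def rpm_to_frame(norm: NormalizedCounts) -> pd.DataFrame:
    return pd.DataFrame(
        [(f, r, norm.denominator) for f, r in sorted(norm.rpm.items())],
        columns=["feature", "rpm", "denominator"],
    )
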