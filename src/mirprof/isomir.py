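"""IsomiR classification by signed end offsets and size-spectrum comparison.

An isomiR is keyed by its precursor, its 5'/3' end positions relative to the
canonical mature boundaries, and its sequence:

    off5 = read_start - mature_start   (positive = 5'-truncated)
    off3 = read_end   - mature_end     (positive = 3'-extended)

so the canonical mature form is (+0, +0), written with an explicit sign as
"+0" — matching the convention in which the mature start site is position
+0.  End truncation at both ends reads as (+, -).  Only mature-overlapping
(5'-arm) hits enter a locus spectrum; hits elsewhere on the hairpin are
reported separately rather than forced into the mature coordinate frame.

The group comparison is deliberately descriptive (RPM means, modal lengths,
mean offsets, a qualitative call); inferential testing lives in
:mod:`mirprof.stats`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import ReadAssignment
from .references import PrecursorRecord, ReferenceSet


def offset_label(off: int) -> str:
    """Signed position label: 0 -> '+0', -1 -> '-1', 2 -> '+2'."""
    return f"{off:+d}"


@dataclass(frozen=True)
class IsomiRRecord:
    precursor_id: str
    sequence: str
    off5: int
    off3: int
    length: int
    count: int
    rpm: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("isomiR length must be >= 1")

    @property
    def label(self) -> str:
        return offset_label(self.off5)


@dataclass
class SizeSpectrum:
    """Percentage-by-length table for one locus in one sample."""

    locus: str
    sample: str
    percent: dict[int, float]  # length (nt) -> percent of locus reads


@dataclass
class SpectrumComparison:
    locus: str
    rpm_a: float
    rpm_b: float
    rpm_ratio: float | None
    modal_length_a: int
    modal_length_b: int
    mean_off5_a: float
    mean_off3_a: float
    mean_off5_b: float
    mean_off3_b: float
    call_a: str
    call_b: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_isomir(
    hit: tuple[str, int, int],
    annotation: PrecursorRecord,
    sequence: str,
    count: int = 1,
    rpm: float = 0.0,
) -> IsomiRRecord:
    """Turn one precursor hit into an isomiR record with signed end offsets."""
    precursor_id, start, end = hit
    if precursor_id != annotation.id:
        raise ValueError(f"hit precursor {precursor_id} != annotation {annotation.id}")
    if not (0 <= start < end <= len(annotation.sequence)):
        raise ValueError(f"hit [{start},{end}) outside precursor {precursor_id}")
    off5 = start - annotation.mature_start
    off3 = end - annotation.mature_end
    return IsomiRRecord(
        precursor_id=precursor_id,
        sequence=sequence,
        off5=off5,
        off3=off3,
        length=end - start,
        count=count,
        rpm=rpm,
    )


def _overlaps_mature(start: int, end: int, ann: PrecursorRecord) -> bool:
    return start < ann.mature_end and end > ann.mature_start


def profile_isomirs(
    assignments: list[ReadAssignment],
    reads: list[tuple[str, str]],
    refs: ReferenceSet,
    denominator: int,
) -> tuple[list[IsomiRRecord], list[IsomiRRecord]]:
    """Aggregate miRNA-tier hits into isomiR records.

    Returns ``(mature_arm, other_arm)``: records for mature-overlapping hits
    and, separately, records for hits elsewhere on the hairpin (e.g. 3'-arm
    products without a canonical annotation).  Counts collapse by
    (precursor, off5, off3, sequence); RPM uses the supplied mapped-read
    denominator.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    seq_by_id = dict(reads)
    mature: dict[tuple, int] = defaultdict(int)
    other: dict[tuple, int] = defaultdict(int)
    for a in assignments:
        if a.category != "miRNA":
            continue
        seq = seq_by_id[a.read_id]
        for ref_id, start, end, _mm in a.hits:
            ann = refs.precursor(ref_id)
            key = (ref_id, start, end, seq)
            if _overlaps_mature(start, end, ann):
                mature[key] += 1
            else:
                other[key] += 1

    def build(bucket: dict[tuple, int]) -> list[IsomiRRecord]:
        records = []
        for (ref_id, start, end, seq), n in bucket.items():
            records.append(
                classify_isomir(
                    (ref_id, start, end),
                    refs.precursor(ref_id),
                    seq,
                    count=n,
                    rpm=1e6 * n / denominator,
                )
            )
        records.sort(key=lambda r: (r.precursor_id, -r.count, r.off5, r.off3, r.sequence))
        return records

    return build(mature), build(other)


def size_spectrum(records: list[IsomiRRecord], sample: str = "") -> SizeSpectrum:
    """Percentage size distribution for one locus: percent of locus reads at
    each attained length.  Percentages sum to 100."""
    if not records:
        raise ValueError("cannot build a spectrum from zero records")
    loci = {r.precursor_id for r in records}
    if len(loci) != 1:
        raise ValueError(f"records span multiple loci: {sorted(loci)}")
    total = sum(r.count for r in records)
    by_len: dict[int, int] = defaultdict(int)
    for r in records:
        by_len[r.length] += r.count
    percent = {L: 100.0 * n / total for L, n in sorted(by_len.items())}
    return SizeSpectrum(locus=loci.pop(), sample=sample, percent=percent)


def dominant_isomir(records: list[IsomiRRecord]) -> tuple[int, int, int]:
    """(length, off5, off3) of the most abundant isomiR.  Ties break toward
    the smaller |off5|+|off3|, then the smaller off5."""
    if not records:
        raise ValueError("no records")
    pooled: dict[tuple[int, int], int] = defaultdict(int)
    for r in records:
        pooled[(r.off5, r.off3)] += r.count
    lengths = {(r.off5, r.off3): r.length for r in records}
    best = max(
        pooled.items(),
        key=lambda kv: (kv[1], -(abs(kv[0][0]) + abs(kv[0][1])), -kv[0][0]),
    )[0]
    return lengths[best], best[0], best[1]


def truncation_stats(records: list[IsomiRRecord]) -> tuple[float, float]:
    """Count-weighted mean 5' and 3' offsets — positive mean_off5 and negative
    mean_off3 quantify truncation at both ends."""
    if not records:
        raise ValueError("no records")
    total = sum(r.count for r in records)
    mean5 = sum(r.off5 * r.count for r in records) / total
    mean3 = sum(r.off3 * r.count for r in records) / total
    return mean5, mean3


def _qualitative_call(off5: int, off3: int) -> str:
    if off5 == 0 and off3 == 0:
        return "canonical-dominant"
    if 1 <= off5 <= 2 and -2 <= off3 <= -1:
        return "truncated"
    return "indeterminate"


def _locus_records(sample: list[IsomiRRecord], locus: str) -> list[IsomiRRecord]:
    return [r for r in sample if r.precursor_id == locus]


def compare_groups(
    samples_a: list[list[IsomiRRecord]],
    samples_b: list[list[IsomiRRecord]],
    locus: str,
) -> SpectrumComparison:
    """Descriptive two-group comparison at one locus.

    Group RPM is the unweighted mean of per-sample summed locus RPM (each
    sample is already depth-normalized); modal lengths and mean offsets come
    from counts pooled within each group.
    """
    if not samples_a or not samples_b:
        raise ValueError("each group needs at least one sample")
    per_a = [_locus_records(s, locus) for s in samples_a]
    per_b = [_locus_records(s, locus) for s in samples_b]
    if not any(per_a) and not any(per_b):
        raise ValueError(f"locus {locus!r} absent from every sample")

    rpm_a = sum(sum(r.rpm for r in recs) for recs in per_a) / len(per_a)
    rpm_b = sum(sum(r.rpm for r in recs) for recs in per_b) / len(per_b)
    pooled_a = [r for recs in per_a for r in recs]
    pooled_b = [r for recs in per_b for r in recs]
    len_a, o5a, o3a = dominant_isomir(pooled_a)
    len_b, o5b, o3b = dominant_isomir(pooled_b)
    m5a, m3a = truncation_stats(pooled_a)
    m5b, m3b = truncation_stats(pooled_b)
    return SpectrumComparison(
        locus=locus,
        rpm_a=rpm_a,
        rpm_b=rpm_b,
        rpm_ratio=(rpm_a / rpm_b) if rpm_b > 0 else None,
        modal_length_a=len_a,
        modal_length_b=len_b,
        mean_off5_a=m5a,
        mean_off3_a=m3a,
        mean_off5_b=m5b,
        mean_off3_b=m3b,
        call_a=_qualitative_call(o5a, o3a),
        call_b=_qualitative_call(o5b, o3b),
    )


# --------------------------------------------------------------------- I/O

def isomirs_to_frame(records: list[IsomiRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.precursor_id, r.sequence, r.off5, r.off3, r.length, r.count, r.rpm, r.label)
            for r in records
        ],
        columns=["precursor_id", "sequence", "off5", "off3", "length", "count", "rpm", "label"],
    )


def write_isomirs(records: list[IsomiRRecord], path: str | Path) -> None:
    isomirs_to_frame(records).to_csv(path, sep="\t", index=False)


def read_isomirs(path: str | Path) -> list[IsomiRRecord]:
    df = pd.read_csv(path, sep="\t")
    cols = ["precursor_id", "sequence", "off5", "off3", "length", "count", "rpm"]
    return [
        IsomiRRecord(
            precursor_id=pid,
            sequence=seq,
            off5=int(o5),
            off3=int(o3),
            length=int(length),
            count=int(n),
            rpm=float(rpm),
        )
        for pid, seq, o5, o3, length, n, rpm in df[cols].itertuples(index=False, name=None)
    ]


def spectrum_to_frame(spectrum: SizeSpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        [(spectrum.locus, spectrum.sample, L, p) for L, p in spectrum.percent.items()],
        columns=["precursor_id", "sample", "length", "percent"],
    )
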