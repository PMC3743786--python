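"""Reference sequence sets for small-RNA read classification.

Reads are assigned against three tiers in order: contaminant rRNA/tRNA
decoys, miRNA precursor hairpins carrying a mature-arm annotation, and a
genomic background contig.  Two of the precursors embed an identical mature
5'-arm sequence at distinct loci, mirroring the two-locus arrangement of
miR-196a (mir-196a-1 on chr17, mir-196a-2 on chr12) whose mature 5p products
are indistinguishable at the read level.

Coordinate conventions: genomic spans written in ``source_locus`` strings are
1-based inclusive (UCSC style); all in-memory coordinates are 0-based
half-open.  Minus-strand loci are stored already reverse-complemented, i.e.
every stored sequence is the 5'->3' transcript, so no strand arithmetic is
needed downstream.  RNA sequences are stored DNA-encoded (U -> T).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_VALID_SEQ = re.compile(r"^[ACGT]+$")

#: Mature miR-196a-5p (miRBase MIMAT0000226), DNA-encoded.
MATURE_MIR196A = "TAGGTAGTTTCATGTTGTTGGG"

#: Genomic spans of the two human miR-196a precursor loci (GRCh37).
MIR196A1_LOCUS = "chr17:46709852-46709921[-]"
MIR196A2_LOCUS = "chr12:54385522-54385631[+]"

MIR196A1_ID = "mir-196a-1-like"
MIR196A2_ID = "mir-196a-2-like"


def locus_span_length(locus: str) -> int:
    """Length in bases of a 1-based inclusive span such as ``chr17:100-169[-]``."""
    m = re.match(r"^[^:]+:(\d+)-(\d+)", locus)
    if m is None:
        raise ValueError(f"unparsable locus string: {locus!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise ValueError(f"span end precedes start in {locus!r}")
    return end - start + 1


def _check_seq(seq: str, what: str) -> None:
    if not _VALID_SEQ.match(seq):
        raise ValueError(f"{what}: sequence must be non-empty uppercase over ACGT")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrecursorRecord:
    """A precursor hairpin with its canonical mature-arm interval.

    ``mature_start``/``mature_end`` delimit the canonical mature miRNA within
    the precursor, 0-based half-open.  The interval is the origin for the
    signed 5'/3' isomiR offsets computed downstream.
    """

    id: str
    sequence: str
    mature_start: int
    mature_end: int
    source_locus: str | None = None

    def __post_init__(self) -> None:
        _check_seq(self.sequence, f"precursor {self.id}")
        if not (0 <= self.mature_start < self.mature_end <= len(self.sequence)):
            raise ValueError(
                f"precursor {self.id}: mature interval "
                f"[{self.mature_start},{self.mature_end}) outside sequence"
            )
        mlen = self.mature_end - self.mature_start
        if not (18 <= mlen <= 26):
            raise ValueError(f"precursor {self.id}: mature length {mlen} outside [18,26]")

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


@dataclass
class ReferenceSet:
    """Decoy, precursor, and genome sequences — the three classification tiers."""

    decoys: list[tuple[str, str]]
    precursors: list[PrecursorRecord]
    genome: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids: list[str] = []
        for rid, seq in self.decoys + self.genome:
            _check_seq(seq, f"record {rid}")
            ids.append(rid)
        ids.extend(p.id for p in self.precursors)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record ids in reference set")

    def precursor(self, precursor_id: str) -> PrecursorRecord:
        for p in self.precursors:
            if p.id == precursor_id:
                return p
        raise KeyError(precursor_id)

    @property
    def annotations(self) -> pd.DataFrame:
        """Precursor annotation table (0-based half-open mature intervals)."""
        return pd.DataFrame(
            [
                {
                    "precursor_id": p.id,
                    "mature_start": p.mature_start,
                    "mature_end": p.mature_end,
                    "source_locus": p.source_locus or "",
                }
                for p in self.precursors
            ]
        )

    def all_sequences(self) -> list[tuple[str, str]]:
        return (
            list(self.decoys)
            + [(p.id, p.sequence) for p in self.precursors]
            + list(self.genome)
        )

    # ------------------------------------------------------------------ I/O

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write decoys.fa / precursors.fa / genome.fa / precursors.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "decoys": outdir / "decoys.fa",
            "precursors": outdir / "precursors.fa",
            "genome": outdir / "genome.fa",
            "annotations": outdir / "precursors.tsv",
        }
        _write_fasta(self.decoys, paths["decoys"])
        _write_fasta([(p.id, p.sequence) for p in self.precursors], paths["precursors"])
        _write_fasta(self.genome, paths["genome"])
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, refdir: str | Path) -> "ReferenceSet":
        refdir = Path(refdir)
        decoys = _read_fasta(refdir / "decoys.fa")
        genome = _read_fasta(refdir / "genome.fa")
        seqs = dict(_read_fasta(refdir / "precursors.fa"))
        ann = pd.read_csv(refdir / "precursors.tsv", sep="\t", dtype={"source_locus": str})
        precursors = []
        for row in ann.itertuples(index=False):
            locus = row.source_locus if isinstance(row.source_locus, str) and row.source_locus else None
            precursors.append(
                PrecursorRecord(
                    id=row.precursor_id,
                    sequence=seqs[row.precursor_id],
                    mature_start=int(row.mature_start),
                    mature_end=int(row.mature_end),
                    source_locus=locus,
                )
            )
        return cls(decoys=decoys, precursors=precursors, genome=genome)

    def to_fasta(self) -> str:
        """All records as one FASTA string (stable order: decoys, precursors, genome)."""
        buf = io.StringIO()
        SeqIO.write(
            (SeqRecord(Seq(s), id=i, description="") for i, s in self.all_sequences()),
            buf,
            "fasta",
        )
        return buf.getvalue()


def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, n)])


def _hairpin(rng: np.random.Generator, total_len: int, mature: str, mature_start: int) -> str:
    """Assemble a hairpin-like precursor: 5' flank, mature arm, loop, then a
    3' arm that is (approximately) the reverse complement of the 5' arm."""
    flank5 = _random_seq(rng, mature_start)
    remaining = total_len - mature_start - len(mature)
    if remaining < 0:
        raise ValueError("precursor too short for mature placement")
    loop_len = min(12, remaining)
    loop = _random_seq(rng, loop_len)
    arm3_len = remaining - loop_len
    arm3 = reverse_complement(flank5 + mature)[:arm3_len]
    if len(arm3) < arm3_len:
        arm3 += _random_seq(rng, arm3_len - len(arm3))
    return flank5 + mature + loop + arm3


def make_reference_set(
    seed: int,
    n_decoys: int = 6,
    n_extra_precursors: int = 8,
    genome_length: int = 5000,
) -> ReferenceSet:
    """Build a seeded reference set for the three-tier classifier.

    The set always contains two precursors embedding the identical mature
    miR-196a-5p sequence: a 70-nt hairpin modeled on the chr17 locus and a
    110-nt hairpin modeled on the chr12 locus (lengths are the 1-based
    inclusive span lengths of the printed coordinates).  ``n_extra_precursors``
    random hairpins with random mature intervals, ``n_decoys`` rRNA/tRNA-like
    decoys, and one background contig complete the set.

    Deterministic for a fixed seed.
    """
    if genome_length < 100:
        raise ValueError("genome_length must be >= 100")
    if n_decoys < 0 or n_extra_precursors < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)

    len1 = locus_span_length(MIR196A1_LOCUS)  # 70
    len2 = locus_span_length(MIR196A2_LOCUS)  # 110
    precursors = [
        PrecursorRecord(
            id=MIR196A1_ID,
            sequence=_hairpin(rng, len1, MATURE_MIR196A, mature_start=4),
            mature_start=4,
            mature_end=4 + len(MATURE_MIR196A),
            source_locus=MIR196A1_LOCUS,
        ),
        PrecursorRecord(
            id=MIR196A2_ID,
            sequence=_hairpin(rng, len2, MATURE_MIR196A, mature_start=22),
            mature_start=22,
            mature_end=22 + len(MATURE_MIR196A),
            source_locus=MIR196A2_LOCUS,
        ),
    ]
    for k in range(n_extra_precursors):
        total = int(rng.integers(60, 111))
        mlen = int(rng.integers(19, 25))
        # keep >=2 nt of flank on both sides so +/-1..2 end shifts stay inside
        mstart = int(rng.integers(3, total - mlen - 3))
        mature = _random_seq(rng, mlen)
        precursors.append(
            PrecursorRecord(
                id=f"pre-{k + 1}",
                sequence=_hairpin(rng, total, mature, mature_start=mstart),
                mature_start=mstart,
                mature_end=mstart + mlen,
            )
        )

    decoys = []
    for k in range(n_decoys):
        kind = "rRNA" if k % 2 == 0 else "tRNA"
        decoys.append((f"decoy_{kind}_{k + 1}", _random_seq(rng, int(rng.integers(80, 301)))))

    genome = [("chrBG", _random_seq(rng, genome_length))]
    return ReferenceSet(decoys=decoys, precursors=precursors, genome=genome)
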