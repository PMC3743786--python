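"""Seeded small-RNA read simulation with cleavage-offset structure.

A library is a mixture of four read categories: rRNA/tRNA contaminants,
miRNA-derived reads, genomic background fragments, and unmappable reads.
miRNA reads are precursor substrings whose 5'/3' ends are drawn from a
:class:`CleavageProfile` — signed offsets relative to the canonical mature
boundaries.  The two shipped presets encode the qualitative contrast between
laryngeal-cancer-like libraries (Drosha/Dicer cleavage peaked at the
canonical miRBase boundaries, higher miRNA load) and non-cancer-like
libraries (isomiRs truncated by 1-2 nt at both ends, lower miRNA load).

Sequencing errors are independent per-base substitutions; indels and
non-templated additions are out of scope.  Reads are assumed
adapter-trimmed, and every emitted read has length in [10, 40] nt (offset
draws that would leave this window, or an empty read, are rejected and
redrawn).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .references import ALPHABET, ReferenceSet

#: Category order used throughout (mixture tuples, counts tables).
CATEGORIES = ("rRNA_tRNA", "miRNA", "genome", "unmapped")

READ_LEN_MIN = 10
READ_LEN_MAX = 40

# length range for decoy/genome/unmapped fragments; long enough that chance
# cross-tier matches are astronomically unlikely
_NONMIR_LEN = (18, 31)  # half-open for rng.integers

_PROB_TOL = 1e-9


def _check_table(table: dict[int, float], name: str) -> dict[int, float]:
    if not table:
        raise ValueError(f"{name}: empty probability table")
    for off, p in table.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}[{off}] = {p} outside [0,1]")
    if abs(sum(table.values()) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name}: probabilities must sum to 1")
    return dict(sorted(table.items()))


@dataclass(frozen=True)
class CleavageProfile:
    """Generative model for one library: end-offset tables, category mixture,
    and per-base substitution error rate.

    ``p5``/``p3`` map signed offsets (read_start - mature_start and
    read_end - mature_end, in precursor coordinates) to probabilities.
    ``category_mix`` gives probabilities over ``CATEGORIES``.
    """

    p5: dict[int, float]
    p3: dict[int, float]
    category_mix: tuple[float, float, float, float]
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p5", _check_table(self.p5, "p5"))
        object.__setattr__(self, "p3", _check_table(self.p3, "p3"))
        if len(self.category_mix) != len(CATEGORIES):
            raise ValueError("category_mix needs one probability per category")
        for p in self.category_mix:
            if not (0.0 <= p <= 1.0):
                raise ValueError("category_mix probabilities must lie in [0,1]")
        if abs(sum(self.category_mix) - 1.0) > _PROB_TOL:
            raise ValueError("category_mix must sum to 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must lie in [0,1)")

    @property
    def mirna_fraction(self) -> float:
        return self.category_mix[CATEGORIES.index("miRNA")]

    def expected_offsets(self) -> tuple[float, float]:
        """Expectations (E[off5], E[off3]) of the two offset tables."""
        e5 = sum(k * p for k, p in self.p5.items())
        e3 = sum(k * p for k, p in self.p3.items())
        return e5, e3


def cancer_profile(error_rate: float = 0.01) -> CleavageProfile:
    """Cancer-like preset: cleavage mass concentrated at the canonical
    boundaries (joint probability of the exact canonical form ~0.74) and a
    high miRNA mixing fraction.  The offset probabilities are presets — the
    qualitative pattern (canonical-dominant) is what is modeled."""
    return CleavageProfile(
        p5={0: 0.86, 1: 0.06, -1: 0.05, 2: 0.03},
        p3={0: 0.86, -1: 0.06, 1: 0.05, -2: 0.03},
        category_mix=(0.25, 0.55, 0.15, 0.05),
        error_rate=error_rate,
    )


def noncancer_profile(error_rate: float = 0.01) -> CleavageProfile:
    """Non-cancer-like preset: modal cleavage truncated by 1-2 nt at both
    ends (modal read 2-4 nt shorter than canonical) and a lower miRNA mixing
    fraction.  Offset probabilities are presets."""
    return CleavageProfile(
        p5={1: 0.40, 2: 0.28, 0: 0.18, 3: 0.08, -1: 0.06},
        p3={-1: 0.40, -2: 0.28, 0: 0.18, -3: 0.08, 1: 0.06},
        category_mix=(0.40, 0.35, 0.20, 0.05),
        error_rate=error_rate,
    )


TRUTH_COLUMNS = ("read_id", "category", "precursor_id", "off5", "off3")


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    hit = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hit.size == 0:
        return seq
    chars = list(seq)
    for i in hit:
        alts = [b for b in ALPHABET if b != chars[i]]
        chars[i] = alts[int(rng.integers(3))]
    return "".join(chars)


def simulate_reads(
    refs: ReferenceSet,
    profile: CleavageProfile,
    n_reads: int,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw a seeded read library and its ground-truth table.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence)`` and ``truth`` has columns
    ``read_id, category, precursor_id, off5, off3`` (offsets only for miRNA
    reads).  Deterministic for a fixed seed; rejected draws (offsets leaving
    the precursor or the [10, 40] nt window, unmapped candidates colliding
    with a reference) are redrawn, consuming further generator state.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    categories = rng.choice(len(CATEGORIES), size=n_reads, p=list(profile.category_mix))

    off5_vals = np.array(list(profile.p5.keys()))
    off5_probs = np.array(list(profile.p5.values()))
    off3_vals = np.array(list(profile.p3.keys()))
    off3_probs = np.array(list(profile.p3.values()))

    all_ref_text = "#".join(seq for _, seq in refs.all_sequences())
    width = len(str(n_reads))
    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []

    for i in range(n_reads):
        rid = f"r{i + 1:0{width}d}"
        cat = CATEGORIES[categories[i]]
        precursor_id, off5, off3 = "", None, None

        if cat == "miRNA":
            for _ in range(1000):
                p = refs.precursors[int(rng.integers(len(refs.precursors)))]
                o5 = int(off5_vals[rng.choice(len(off5_vals), p=off5_probs)])
                o3 = int(off3_vals[rng.choice(len(off3_vals), p=off3_probs)])
                start = p.mature_start + o5
                end = p.mature_end + o3
                if 0 <= start < end <= len(p.sequence) and READ_LEN_MIN <= end - start <= READ_LEN_MAX:
                    break
            else:  # pragma: no cover - profile grossly inconsistent with refs
                raise RuntimeError("could not draw a valid miRNA read in 1000 attempts")
            seq = _mutate(p.sequence[start:end], rng, profile.error_rate)
            precursor_id, off5, off3 = p.id, o5, o3
        elif cat == "rRNA_tRNA":
            src = refs.decoys[int(rng.integers(len(refs.decoys)))][1]
            length = int(rng.integers(*_NONMIR_LEN))
            length = min(length, len(src))
            start = int(rng.integers(0, len(src) - length + 1))
            seq = _mutate(src[start : start + length], rng, profile.error_rate)
        elif cat == "genome":
            src = refs.genome[int(rng.integers(len(refs.genome)))][1]
            length = int(rng.integers(*_NONMIR_LEN))
            start = int(rng.integers(0, len(src) - length + 1))
            seq = _mutate(src[start : start + length], rng, profile.error_rate)
        else:  # unmapped
            while True:
                length = int(rng.integers(*_NONMIR_LEN))
                seq = "".join(np.array(list(ALPHABET))[rng.integers(0, 4, length)])
                if seq not in all_ref_text:
                    break

        reads.append((rid, seq))
        truth_rows.append((rid, cat, precursor_id, off5, off3))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return reads, truth


# --------------------------------------------------------------------- I/O

def reads_to_fastq(reads: list[tuple[str, str]]) -> str:
    """Render reads as FASTQ text with a uniform dummy quality of 'I'."""
    buf = io.StringIO()
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, buf, "fastq")
    return buf.getvalue()


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text(reads_to_fastq(reads))


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Load reads from FASTQ or FASTA (by extension; .fq/.fastq -> FASTQ)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, na_rep="")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["precursor_id"] = df["precursor_id"].fillna("")
    return df
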