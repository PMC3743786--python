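"""End-to-end pipeline: simulate -> classify -> profile -> compare.

A run is described by a flat key-value config (YAML mapping, all keys
optional except ``seed``).  The same config and seed always yield
byte-identical outputs; per-sample seeds are derived deterministically from
the run seed.  Outputs are TSV/JSON files plus a run manifest recording the
config hash and per-stage files with their row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    assign_reads,
    category_counts,
    counts_to_frame,
    length_filter,
    rpm_normalize,
    rpm_to_frame,
    write_assignments,
)
from .isomir import (
    compare_groups,
    profile_isomirs,
    size_spectrum,
    spectrum_to_frame,
    write_isomirs,
)
from .references import MIR196A1_ID, MIR196A2_ID, make_reference_set
from .simulate import cancer_profile, noncancer_profile, simulate_reads, write_fastq, write_truth

log = logging.getLogger("mirprof")

_MAX_SEED = 2**31 - 1


@dataclass
class RunConfig:
    seed: int
    n_decoys: int = 6
    n_extra_precursors: int = 8
    genome_length: int = 5000
    n_cancer_samples: int = 2
    n_noncancer_samples: int = 3
    n_reads: int = 50000
    error_rate: float = 0.01
    max_mismatches: int = 1
    min_len: int = 10
    max_len: int = 40
    exclude_decoys_from_denominator: bool = False
    alpha: float = 0.05
    min_fold: float = 2.0

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    """Raised with the complete list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


_INT_KEYS = {
    "seed", "n_decoys", "n_extra_precursors", "genome_length",
    "n_cancer_samples", "n_noncancer_samples", "n_reads",
    "max_mismatches", "min_len", "max_len",
}
_FLOAT_KEYS = {"error_rate", "alpha", "min_fold"}
_BOOL_KEYS = {"exclude_decoys_from_denominator"}
_ALL_KEYS = _INT_KEYS | _FLOAT_KEYS | _BOOL_KEYS


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a config mapping or YAML file.

    All violations are collected and reported together in a
    :class:`ConfigError`, not just the first one found.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a flat key-value mapping"])

    violations = [f"unknown key: {k}" for k in raw if k not in _ALL_KEYS]
    if "seed" not in raw:
        violations.append("seed is required")

    values: dict = {}
    for k, v in raw.items():
        if k in _INT_KEYS:
            if isinstance(v, bool) or not isinstance(v, int):
                violations.append(f"{k} must be an integer (got {v!r})")
                continue
        elif k in _FLOAT_KEYS:
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                violations.append(f"{k} must be a number (got {v!r})")
                continue
            v = float(v)
        elif k in _BOOL_KEYS:
            if not isinstance(v, bool):
                violations.append(f"{k} must be true/false (got {v!r})")
                continue
        else:
            continue
        values[k] = v

    def chk(cond: bool, msg: str) -> None:
        if not cond:
            violations.append(msg)

    # range checks run on whatever parsed cleanly so all violations surface at once
    if "seed" in values:
        chk(0 <= values["seed"] <= _MAX_SEED, "seed must lie in [0, 2^31-1]")
    for k in ("n_decoys", "n_extra_precursors"):
        if k in values:
            chk(values[k] >= 0, f"{k} must be >= 0")
    if "genome_length" in values:
        chk(values["genome_length"] >= 100, "genome_length must be >= 100")
    for k in ("n_cancer_samples", "n_noncancer_samples", "n_reads"):
        if k in values:
            chk(values[k] >= 1, f"{k} must be >= 1")
    if "error_rate" in values:
        chk(0.0 <= values["error_rate"] < 1.0, "error_rate must lie in [0, 1)")
    if "max_mismatches" in values:
        chk(values["max_mismatches"] >= 0, "max_mismatches must be >= 0")
    if "alpha" in values:
        chk(0.0 < values["alpha"] < 1.0, "alpha must lie in (0, 1)")
    if "min_fold" in values:
        chk(values["min_fold"] >= 1.0, "min_fold must be >= 1")
    min_len = values.get("min_len", RunConfig.min_len)
    max_len = values.get("max_len", RunConfig.max_len)
    chk(min_len <= max_len, "min_len must be <= max_len")
    chk(min_len >= 1, "min_len must be >= 1")

    if violations:
        raise ConfigError(violations)
    return RunConfig(**values)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    config: dict
    stages: dict[str, dict[str, dict]] = field(default_factory=dict)

    def record(self, stage: str, name: str, path: Path) -> None:
        if not path.exists() or path.stat().st_size == 0:
            raise RuntimeError(f"stage {stage}: output {path} missing or empty")
        rows = sum(1 for _ in open(path)) if path.suffix in {".tsv", ".fastq", ".fa"} else None
        self.stages.setdefault(stage, {})[name] = {
            "path": str(path),
            "rows": rows,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def derive_sample_seed(seed: int, index: int) -> int:
    """Deterministic per-sample seed, kept below 2^31."""
    h = hashlib.sha256(f"{seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % _MAX_SEED


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunManifest:
    """Run simulate -> classify -> profile -> compare for a two-group
    synthetic experiment (cancer-like vs non-cancer-like libraries) and
    write all stage outputs plus a manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), config=asdict(config)
    )

    # ---- simulate
    stage = "simulate"
    try:
        log.info("[%s] seed=%d building references", stage, config.seed)
        refs = make_reference_set(
            config.seed,
            n_decoys=config.n_decoys,
            n_extra_precursors=config.n_extra_precursors,
            genome_length=config.genome_length,
        )
        refdir = outdir / "refs"
        for name, path in refs.write(refdir).items():
            manifest.record(stage, f"refs/{name}", path)

        groups = {"cancer": [], "noncancer": []}
        profiles = {
            "cancer": cancer_profile(error_rate=config.error_rate),
            "noncancer": noncancer_profile(error_rate=config.error_rate),
        }
        n_by_group = {
            "cancer": config.n_cancer_samples,
            "noncancer": config.n_noncancer_samples,
        }
        idx = 0
        sample_data = {}
        for group in ("cancer", "noncancer"):
            for k in range(n_by_group[group]):
                name = f"{group}_{k + 1}"
                sseed = derive_sample_seed(config.seed, idx)
                idx += 1
                log.info("[%s] sample %s seed=%d n_reads=%d", stage, name, sseed, config.n_reads)
                reads, truth = simulate_reads(refs, profiles[group], config.n_reads, sseed)
                sdir = outdir / name
                sdir.mkdir(exist_ok=True)
                write_fastq(reads, sdir / "reads.fastq")
                write_truth(truth, sdir / "truth.tsv")
                manifest.record(stage, f"{name}/reads", sdir / "reads.fastq")
                manifest.record(stage, f"{name}/truth", sdir / "truth.tsv")
                groups[group].append(name)
                sample_data[name] = (reads, sdir)
    except Exception as exc:  # noqa: BLE001 - re-raise stage-attributed
        raise StageError(stage, exc) from exc

    # ---- classify + profile
    stage = "classify"
    sample_records = {}
    try:
        for name, (reads, sdir) in sample_data.items():
            kept = length_filter(reads, config.min_len, config.max_len)
            assignments = assign_reads(kept, refs, max_mismatches=config.max_mismatches)
            counts = category_counts(assignments)
            norm = rpm_normalize(counts, exclude_decoys=config.exclude_decoys_from_denominator)
            write_assignments(assignments, sdir / "assignments.tsv")
            counts_to_frame(counts).to_csv(sdir / "counts.tsv", sep="\t", index=False)
            rpm_to_frame(norm).to_csv(sdir / "rpm.tsv", sep="\t", index=False)
            for fname in ("assignments", "counts", "rpm"):
                manifest.record(stage, f"{name}/{fname}", sdir / f"{fname}.tsv")

            mature, other = profile_isomirs(assignments, kept, refs, norm.denominator)
            write_isomirs(mature, sdir / "isomirs.tsv")
            if other:
                write_isomirs(other, sdir / "isomirs_other_arm.tsv")
            manifest.record("profile", f"{name}/isomirs", sdir / "isomirs.tsv")
            spectra = []
            for locus in (MIR196A1_ID, MIR196A2_ID):
                recs = [r for r in mature if r.precursor_id == locus]
                if recs:
                    spectra.append(spectrum_to_frame(size_spectrum(recs, sample=name)))
            if spectra:
                pd.concat(spectra).to_csv(sdir / "spectrum.tsv", sep="\t", index=False)
                manifest.record("profile", f"{name}/spectrum", sdir / "spectrum.tsv")
            sample_records[name] = mature
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- compare
    stage = "compare"
    try:
        report = {}
        for locus in (MIR196A1_ID, MIR196A2_ID):
            cmp = compare_groups(
                [sample_records[s] for s in groups["cancer"]],
                [sample_records[s] for s in groups["noncancer"]],
                locus,
            )
            report[locus] = cmp.to_dict()
        cmp_path = outdir / "comparison.json"
        cmp_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest.record(stage, "comparison", cmp_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "manifest.json")
    return manifest
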