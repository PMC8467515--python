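"""End-to-end orchestration: trim -> collapse -> profile -> call -> report.

A run consumes a FASTQ plus a 5.8S-bearing reference, executes every
stage deterministically under the configured seed, and writes a report
(length profile, dominance table, window fractions, ladder table, ratio
estimate) together with a manifest listing the configuration snapshot,
input checksums and a sha256 for every produced file.  Re-running the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from . import classify, length_profile, sequence_io
from .mapper import ReferenceFeatureSet
from .references import synthetic_precursor


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    fastq: str
    reference_fasta: str | None = None   # None -> bundled synthetic precursor
    reference_features: str | None = None
    species: str = "human"
    accession: str | None = None
    adapter3: str | None = None          # None -> TrimConfig default
    min_insert: int = 8
    max_insert: int = 30
    min_overlap: int = 8
    max_mismatch_rate: float = 0.1
    allow_mismatches: int = 0
    dominance_lengths: tuple[int, ...] = (12, 13)
    n_bootstrap: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "dominance_lengths" in data:
            data["dominance_lengths"] = tuple(data["dominance_lengths"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> tuple[dict, dict]:
    """Execute all stages; returns (report, manifest) and writes both.

    An empty input yields an empty report with warnings rather than an
    error; a genuine stage failure raises PipelineError carrying the
    partial manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    warnings_: list[str] = []
    manifest: dict[str, Any] = {
        "tool": "dorna",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
        "log": log,
    }

    def stage(name: str):
        log.append(f"stage:{name}")

    try:
        stage("reference")
        if config.reference_fasta is not None:
            refs = ReferenceFeatureSet.from_fasta(config.reference_fasta, config.reference_features)
            manifest["inputs"]["reference_fasta"] = _sha256(Path(config.reference_fasta))
        else:
            refs = synthetic_precursor(config.species)
        accession = config.accession or next(iter(refs.records))
        anchor = classify.derive_anchor(refs, accession)
    except Exception as exc:  # noqa: BLE001 - structured reporting
        raise PipelineError("reference", str(exc), manifest) from exc

    try:
        stage("trim")
        fastq = Path(config.fastq)
        manifest["inputs"]["fastq"] = _sha256(fastq)
        trim_cfg = sequence_io.TrimConfig(
            **({"adapter3": config.adapter3} if config.adapter3 else {}),
            min_overlap=config.min_overlap, max_mismatch_rate=config.max_mismatch_rate,
            min_insert=config.min_insert, max_insert=config.max_insert)
        inserts = []
        rejections: dict[str, int] = {}
        n_input = 0
        for read in sequence_io.read_fastq(fastq):
            n_input += 1
            result = sequence_io.trim_adapter(read, trim_cfg)
            if result.accepted:
                inserts.append(result.insert)
            else:
                rejections[result.reason] = rejections.get(result.reason, 0) + 1
        if n_input == 0:
            warnings_.append("input FASTQ contains no reads")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("trim", str(exc), manifest) from exc

    try:
        stage("collapse")
        uniques = sequence_io.collapse_reads(inserts)
        total_trimmed = sum(u.count for u in uniques)
        if uniques:
            uniques = sequence_io.rpm_normalize(uniques)
        sequence_io.write_collapsed_tsv(
            uniques, outdir / "collapsed.tsv",
            metadata={"rpm_denominator": total_trimmed, "seed": config.seed})
    except Exception as exc:
        raise PipelineError("collapse", str(exc), manifest) from exc

    report: dict[str, Any] = {
        "n_input_reads": n_input,
        "n_trimmed_reads": total_trimmed,
        "trim_rejections": rejections,
        "warnings": warnings_,
    }

    try:
        stage("profile")
        if uniques:
            profile = length_profile.length_histogram(uniques)
            length_profile.write_profile_tsv(profile, outdir / "profile.tsv")
            report["length_profile"] = {str(k): {"reads": b.reads, "rpm": round(b.rpm, 4),
                                                 "n_unique": b.n_unique}
                                        for k, b in profile.per_length.items()}
            report["window_fraction_12_13"] = length_profile.window_fraction(profile, {12, 13})
            dominance = []
            for length in config.dominance_lengths:
                dominance.extend(length_profile.dominant_sequences(uniques, length, k=3))
            length_profile.write_dominance_tsv(dominance, outdir / "dominance.tsv")
            report["dominance"] = [asdict(d) for d in dominance]
            report["two_sequence_share"] = length_profile.two_sequence_share(uniques)
        else:
            warnings_.append("no reads survived trimming; profile skipped")
            report["length_profile"] = {}
    except Exception as exc:
        raise PipelineError("profile", str(exc), manifest) from exc

    try:
        stage("call")
        ladder = classify.tabulate_ladder(uniques, anchor, allow_mismatches=config.allow_mismatches)
        classify.write_ladder_tsv(ladder, outdir / "ladder.tsv")
        c_count, d_count = classify.ratio_from_ladder(ladder)
        report["anchor"] = {"accession": anchor.accession, "core": anchor.core_sequence,
                            "c_variant": anchor.c_variant_sequence}
        report["family_counts"] = {"c_dorna": c_count, "dorna": d_count}
        if d_count >= 1:
            est = classify.estimate_ratio(c_count, d_count, n_bootstrap=config.n_bootstrap,
                                          seed=config.seed)
            report["ratio"] = {"estimate": est.ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
                               "n_bootstrap": est.n_bootstrap, "seed": est.seed}
        else:
            warnings_.append("no doRNA core reads; ratio undefined")
            report["ratio"] = None
    except Exception as exc:
        raise PipelineError("call", str(exc), manifest) from exc

    stage("report")
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for produced in sorted(outdir.glob("*.tsv")) + [report_path]:
        manifest["outputs"][produced.name] = _sha256(produced)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report, manifest
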