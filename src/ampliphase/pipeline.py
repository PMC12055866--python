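"""End-to-end pipeline: configuration, stage orchestration and reports.

A run executes simulate (optional, when no FASTQ is supplied) -> align ->
genotype -> pair concordance -> exhaustive phasing -> star naming, writes
every intermediate in a standard text format (FASTA, FASTQ, SAM, VCF,
TSV, JSON) and produces a deterministic JSON report.  One seed governs
the whole run; stage-local seeds are derived by stable hashing of
(seed, stage name) so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .align import Scoring, align_reads, coverage_profile, export_sam
from .amplicon import (
    AmpliconReference,
    build_default_reference,
    write_fasta,
    write_snp_catalog,
)
from .genotype import (
    GenotypeCall,
    call_genotypes,
    extract_alleles,
    read_stats,
    write_stats,
    write_vcf,
)
from .phasing import (
    all_pair_concordances,
    distance_decay,
    estimate_hybrid_rate,
    phase_diplotype,
)
from .simulate import (
    PcrConfig,
    ReadModel,
    read_fastq,
    simulate_pcr,
    simulate_reads,
    write_fastq,
    write_truth,
)
from .star import DEFAULT_STAR_TABLE, assign_star, name_diplotype


class PipelineError(RuntimeError):
    pass


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of a full run."""

    sample: str = "sample"
    seed: int = 0
    reference_seed: int = 1
    diplotype: tuple[str, str] = ("*A1", "*B1b")
    input_ng: float = 20.0
    cycles: int = 40
    efficiency0: float = 0.30
    chimera_rate0: float = 0.5
    capacity: int = 100_000
    n_reads: int = 2000
    error_sub: float = 0.05
    error_ins: float = 0.01
    error_del: float = 0.01
    trunc_prob: float = 0.654
    trunc_max: int = 897
    min_len: int = 50
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    min_identity: float = 0.6
    band: int = 64
    min_coverage: int = 20
    fastq: str | None = None  # align this file instead of simulating

    def pcr_config(self) -> PcrConfig:
        return PcrConfig(
            n0_per_haplotype=PcrConfig.n0_for_ng(self.input_ng),
            cycles=self.cycles,
            efficiency0=self.efficiency0,
            chimera_rate0=self.chimera_rate0,
            capacity=self.capacity,
            seed=stage_seed(self.seed, "pcr"),
        )

    def read_model(self) -> ReadModel:
        return ReadModel(
            self.error_sub, self.error_ins, self.error_del,
            self.trunc_prob, self.trunc_max, self.min_len,
        )

    def scoring(self) -> Scoring:
        return Scoring(
            self.match, self.mismatch, self.gap_open, self.gap_extend,
            self.min_identity, self.band,
        )

    def haplotypes(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        haps = []
        for item in self.diplotype:
            if item.startswith("*"):
                if item not in DEFAULT_STAR_TABLE:
                    raise PipelineError(f"unknown star allele {item!r}")
                haps.append(DEFAULT_STAR_TABLE[item])
            else:
                haps.append(tuple(item.split(",")))
        return haps[0], haps[1]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["diplotype"] = list(self.diplotype)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "diplotype" in kwargs:
            kwargs["diplotype"] = tuple(kwargs["diplotype"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the full pipeline; returns the report dict (and writes all
    intermediates when ``outdir`` is given)."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    reference = _stage(
        "reference", lambda: build_default_reference(config.reference_seed)
    )
    if out is not None:
        write_fasta(reference, out / "reference.fasta")
        write_snp_catalog(reference.snps, out / "snps.tsv")

    truths = None
    pool = None
    if config.fastq is not None:
        path = Path(config.fastq)
        if not path.exists():
            raise PipelineError(f"stage reads: FASTQ not found: {path}")
        reads = _stage("reads", lambda: read_fastq(path))
    else:
        pool = _stage(
            "pcr", lambda: simulate_pcr(
                config.haplotypes(), config.pcr_config(), length=len(reference)
            )
        )
        reads, truths = _stage(
            "reads", lambda: simulate_reads(
                pool, reference, config.n_reads, config.read_model(),
                seed=stage_seed(config.seed, "reads"),
            )
        )
        if out is not None:
            write_fastq(reads, out / "reads.fastq")
            write_truth(truths, out / "truth.tsv")

    records = _stage(
        "align", lambda: align_reads(reads, reference, config.scoring())
    )
    if out is not None:
        export_sam(records, reads, reference, out / "alignments.sam")

    stats = _stage(
        "stats", lambda: read_stats(reads, records, len(reference), config.sample)
    )
    table = _stage(
        "extract", lambda: extract_alleles(records, reads, reference)
    )
    calls = _stage(
        "genotype", lambda: call_genotypes(table, reference, config.min_coverage)
    )
    if out is not None:
        write_vcf(calls, reference, out / "genotypes.vcf")
        write_stats([stats], out / "stats.tsv")

    results = _stage(
        "concordance", lambda: all_pair_concordances(table, calls, reference)
    )
    decay_df, summary = (None, None)
    estimate = None
    if any(r.valid for r in results):
        decay_df, summary = _stage(
            "concordance", lambda: distance_decay(results)
        )
        try:
            estimate = estimate_hybrid_rate(results)
        except ValueError:
            estimate = None
    if out is not None and decay_df is not None:
        decay_df.to_csv(out / "pairs.tsv", sep="\t", index=False)

    dip = _stage("phase", lambda: phase_diplotype(table, calls, reference))
    star_1 = _stage("star", lambda: assign_star(dip.haplotype_1))
    star_2 = _stage("star", lambda: assign_star(dip.haplotype_2))
    dip_name = _stage(
        "star", lambda: name_diplotype(dip.haplotype_1, dip.haplotype_2)
    )

    report: dict[str, Any] = {
        "tool": {"name": "ampliphase", "version": __version__},
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
        },
        "sample": config.sample,
        "read_stats": dataclasses.asdict(stats),
        "pool": None
        if pool is None
        else {
            "size": len(pool),
            "chimeric_fraction": pool.chimeric_fraction,
        },
        "genotypes": [
            {
                "snp_id": c.snp_id,
                "coverage": c.coverage,
                "counts": dict(sorted(c.counts.items())),
                "retained": list(c.retained_alleles),
                "zygosity": c.zygosity,
                "discarded_reads": c.discarded_reads,
                "flags": list(c.flags),
            }
            for c in calls
        ],
        "pair_decay": None
        if decay_df is None
        else decay_df.to_dict(orient="records"),
        "decay_summary": summary,
        "hybrid_estimate": None
        if estimate is None
        else {
            "error_floor": estimate.error_floor,
            "per_bp_rate": estimate.per_bp_rate,
        },
        "diplotype": {
            "haplotype_1": list(dip.haplotype_1),
            "haplotype_2": list(dip.haplotype_2),
            "n_het_sites": dip.n_het_sites,
            "score": dip.score,
            "n_reads_consistent": dip.n_reads_consistent,
            "ties": dip.ties,
            "flags": list(dip.flags),
            "star_1": star_1,
            "star_2": star_2,
            "name": dip_name,
        },
    }
    if out is not None:
        (out / "report.json").write_bytes(report_json(report))
        (out / "diplotype.json").write_text(
            json.dumps(report["diplotype"], indent=2, sort_keys=True) + "\n"
        )
    return report


def report_json(report: Mapping[str, Any]) -> bytes:
    return (json.dumps(report, indent=2, sort_keys=True) + "\n").encode()


def make_fixtures(outdir: str | Path, seed: int = 1) -> PipelineConfig:
    """Write a miniature deterministic dataset (reference FASTA, 200-read
    FASTQ, truth TSV, expected report JSON) for tests and demos."""
    config = PipelineConfig(
        sample="fixture",
        seed=seed,
        diplotype=("*A1", "*B1b"),
        cycles=30,
        chimera_rate0=0.3,
        n_reads=200,
    )
    run_pipeline(config, outdir)
    config.to_yaml(Path(outdir) / "config.yaml")
    return config
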