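"""End-to-end orchestration: phases 1-4 over a whole run.

The pipeline takes either raw multiplexed reads (FASTA/FASTQ plus a
barcode map) or pre-demultiplexed per-sample libraries, then runs
sequence combination and stepwise clustering per sample and the
cross-sample post-processing once, writing all module outputs under
one directory.  One global seed derives per-sample seeds by stable
hashing of sample ids, so adding a sample never perturbs the results
of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import combine, postprocess, seqprep, stepwise
from .seqprep import SampleLibrary
from .stepwise import ClusterSet, STCParams

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything influencing a pipeline run; echoed into the run log."""

    # input: either raw reads + barcodes, or a directory of per-sample
    # libraries (*.tsv sequence-count tables or *.fasta read files)
    reads_path: str | None = None
    barcode_map_path: str | None = None
    fwd_primer: str | None = None
    rev_primer: str | None = None
    library_dir: str | None = None
    out_dir: str | None = None

    # phase 1
    max_barcode_mismatch: int = 0
    min_length: int = 200
    min_library_size: int = 80
    subsample_cap: int = 1000

    # phases 2-4
    expected_len: int = 213
    strict_combine: bool = False
    theta: float = 1 / 22
    delta: float = 4.0
    gamma_start: float | str = stepwise.AUTO
    gamma_step: float = 1.0
    gamma_end: float = 97.0
    replicates: int = 100
    epsilon: int = 3
    min_dropped_reads: int = 3
    chimera_max_mismatch: int = 0
    length_screen: bool = False
    seed: int = 0

    def stc_params(self, seed: int | None = None) -> STCParams:
        return STCParams(
            theta=self.theta,
            delta=self.delta,
            gamma_start=self.gamma_start,
            gamma_step=self.gamma_step,
            gamma_end=self.gamma_end,
            replicates=self.replicates,
            epsilon=self.epsilon,
            min_dropped_reads=self.min_dropped_reads,
            expected_len=self.expected_len,
            seed=self.seed if seed is None else seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def sample_seed(global_seed: int, sample_id: str) -> int:
    """Stable per-sample seed below 2**31."""
    return (zlib.crc32(sample_id.encode()) ^ (global_seed & 0x7FFFFFFF)) % (2**31)


@dataclass
class PipelineResult:
    libraries: dict[str, SampleLibrary]  # post-filter/subsampling input
    combined: dict[str, SampleLibrary]  # after phase-2 combination
    clustersets: dict[str, ClusterSet]
    genotypes: list[postprocess.Genotype]
    allele_catalog: pd.DataFrame
    chimera_report: pd.DataFrame
    genotype_matrix: pd.DataFrame
    allele_ids: list[tuple[str, str]]
    diagnostics: dict
    combine_records: dict[str, list[combine.CombineRecord]] = field(
        default_factory=dict
    )
    prep_report: seqprep.PrepReport | None = None
    removed_by_length: list[tuple[str, str]] = field(default_factory=list)
    not_genotyped: list[str] = field(default_factory=list)


def _load_library_dir(path: Path) -> dict[str, SampleLibrary]:
    libs: dict[str, SampleLibrary] = {}
    for f in sorted(path.iterdir()):
        if f.suffix == ".tsv":
            libs[f.stem] = SampleLibrary.from_tsv(f)
        elif f.suffix in (".fa", ".fasta", ".fna"):
            libs[f.stem] = SampleLibrary.from_fasta(f)
    if not libs:
        raise FileNotFoundError(f"no per-sample libraries found under {path}")
    return libs


def run_from_libraries(
    libs: Mapping[str, SampleLibrary],
    config: PipelineConfig,
    prep_report: seqprep.PrepReport | None = None,
) -> PipelineResult:
    """Run phases 1 (filtering/subsampling only) through 4 on in-memory
    sample libraries."""
    all_ids = sorted(libs)
    kept = seqprep.filter_min_library(dict(libs), config.min_library_size)
    not_genotyped = [sid for sid in all_ids if sid not in kept]
    prepared: dict[str, SampleLibrary] = {}
    for sid in sorted(kept):
        prepared[sid] = seqprep.subsample_library(
            kept[sid], config.subsample_cap, seed=sample_seed(config.seed, sid)
        )

    clustersets: dict[str, ClusterSet] = {}
    combined_libs: dict[str, SampleLibrary] = {}
    combine_records: dict[str, list[combine.CombineRecord]] = {}
    for sid, lib in prepared.items():
        combined, recs = combine.combine_library(
            lib, config.expected_len, strict=config.strict_combine
        )
        combined_libs[sid] = combined
        combine_records[sid] = recs
        params = config.stc_params(seed=sample_seed(config.seed, sid))
        clustersets[sid] = stepwise.run_stc(combined, params)
        logger.info(
            "sample %s: %d good, %d small clusters",
            sid,
            len(clustersets[sid].good),
            len(clustersets[sid].small),
        )

    genotypes, catalog = postprocess.promote_dropped(
        clustersets,
        epsilon=config.epsilon,
        min_dropped_reads=config.min_dropped_reads,
    )
    genotypes, chimera_report = postprocess.classify_chimeras(
        genotypes, max_mismatch=config.chimera_max_mismatch
    )
    genotypes, removed = postprocess.length_screen(
        genotypes, config.expected_len, enabled=config.length_screen
    )
    diag = postprocess.diagnostics(genotypes, clustersets)
    matrix, allele_ids = postprocess.assemble_outputs(genotypes)
    return PipelineResult(
        libraries=prepared,
        combined=combined_libs,
        clustersets=clustersets,
        genotypes=genotypes,
        allele_catalog=catalog,
        chimera_report=chimera_report,
        genotype_matrix=matrix,
        allele_ids=allele_ids,
        diagnostics=diag,
        combine_records=combine_records,
        prep_report=prep_report,
        removed_by_length=removed,
        not_genotyped=not_genotyped,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from files and write all outputs."""
    prep_report = None
    if config.reads_path:
        if not (config.barcode_map_path and config.fwd_primer and config.rev_primer):
            raise ValueError(
                "raw-read input needs barcode_map_path, fwd_primer and rev_primer"
            )
        reads = seqprep.parse_reads(config.reads_path)
        barcodes = seqprep.BarcodeMap.from_tsv(config.barcode_map_path)
        libs, prep_report = seqprep.demultiplex(
            reads,
            barcodes,
            config.fwd_primer,
            config.rev_primer,
            max_barcode_mismatch=config.max_barcode_mismatch,
            min_length=config.min_length,
        )
    elif config.library_dir:
        libs = _load_library_dir(Path(config.library_dir))
    else:
        raise ValueError("config must set reads_path or library_dir")

    result = run_from_libraries(libs, config, prep_report=prep_report)
    if config.out_dir:
        write_outputs(result, config, Path(config.out_dir))
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.echo(), fh, sort_keys=True)
    result.genotype_matrix.to_csv(out / "genotype_matrix.tsv", sep="\t")
    postprocess.write_allele_fasta(result.allele_ids, out / "alleles.fasta")
    result.allele_catalog.to_csv(out / "allele_catalog.tsv", sep="\t", index=False)
    result.chimera_report.to_csv(out / "chimera_report.tsv", sep="\t", index=False)
    result.diagnostics["samples"].to_csv(
        out / "sample_summary.tsv", sep="\t", index=False
    )
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(
            {
                "drop_rate_vs_cluster_size": result.diagnostics[
                    "drop_rate_vs_cluster_size"
                ],
                "library_size_vs_allele_count": result.diagnostics[
                    "library_size_vs_allele_count"
                ],
                "not_genotyped": result.not_genotyped,
                "removed_by_length": result.removed_by_length,
            },
            fh,
            indent=2,
        )
    clusters_dir = out / "clusters"
    clusters_dir.mkdir(exist_ok=True)
    for sid, cs in result.clustersets.items():
        cs.round_log_tsv(clusters_dir / f"{sid}.rounds.tsv")
        cs.cluster_tsv(clusters_dir / f"{sid}.clusters.tsv")
    combine.records_to_tsv(
        (
            (sid, rec)
            for sid in sorted(result.combine_records)
            for rec in result.combine_records[sid]
        ),
        out / "combined_pairs.tsv",
    )
    if result.prep_report is not None:
        result.prep_report.to_tsv(out / "prep_report.tsv")
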