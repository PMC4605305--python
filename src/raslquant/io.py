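"""Readers, writers, pipeline configuration and the end-to-end runner.

All tables are plain TSV with a header line; reports and the run manifest
are JSON. FASTQ reading goes through Biopython (gzip transparent); writing
emits standard 4-line records.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .types import Genotype, ProbeEvent, SampleSpec, Stimulation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (id, sequence, quality) records as 4-line FASTQ; returns the
    number of reads written. ``.gz`` suffix enables gzip compression."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file (optionally gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


# ---------------------------------------------------------------- tables

def write_probe_library(library: list[ProbeEvent], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(e) for e in library],
        columns=["event_id", "gene_symbol", "long_junction_seq",
                 "short_junction_seq", "long_is_inclusion"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_library(path: str | Path) -> list[ProbeEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_symbol": str})
    return [
        ProbeEvent(
            event_id=r.event_id,
            gene_symbol=r.gene_symbol,
            long_junction_seq=r.long_junction_seq,
            short_junction_seq=r.short_junction_seq,
            long_is_inclusion=bool(r.long_is_inclusion),
        )
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: list[SampleSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype.value,
                "stimulation": s.stimulation.value,
                "replicate": s.replicate,
                "barcode": s.barcode,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return [
        SampleSpec(
            genotype=Genotype(r.genotype),
            stimulation=Stimulation(r.stimulation),
            replicate=int(r.replicate),
            barcode=r.barcode,
        )
        for r in df.itertuples(index=False)
    ]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_count_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"event_id": str, "sample_id": str, "long_count": int, "short_count": int},
    )


def read_means_table(path: str | Path) -> pd.DataFrame:
    """Read a wide condition-mean PSI table indexed by event_id."""
    return pd.read_csv(path, sep="\t", dtype={"event_id": str}).set_index("event_id")


# ---------------------------------------------------------------- config

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; mirrors the YAML config file."""

    out_dir: str
    reads: str | None = None
    library: str | None = None
    samples: str | None = None
    # simulation fallback when no reads are supplied
    n_events: int = 200
    mean_depth: float = 1000.0
    dispersion: float = 10.0
    replicates: int = 3
    read_error_rate: float = 0.0
    # analysis thresholds
    min_mean_reads: float = 10.0
    methods_delta: float = 10.0
    stim_delta: float = 9.0
    rescue: float = 0.6
    alpha: float = 0.05
    margin: float = 5.0
    max_mismatches: int = 1
    criterion: str = "methods"
    magnitude_only: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_mean_reads", "methods_delta", "stim_delta", "rescue", "margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.criterion not in ("methods", "results"):
            raise ValueError("criterion must be 'methods' or 'results'")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------- runner

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute count -> filter -> PSI -> delta/test -> call (-> antagonism)
    and write every intermediate table plus a run manifest.

    Inputs come from ``config.reads``/``library``/``samples`` when given;
    otherwise a fully synthetic experiment is simulated at the configured
    depth and seed. Returns the manifest dict.
    """
    from . import counting, event_calling, quantification, synthetic_data

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    stage = "inputs"
    try:
        if config.reads is not None:
            if config.library is None or config.samples is None:
                raise ValueError("reads input requires --library and --samples")
            library = read_probe_library(config.library)
            samples = read_samples(config.samples)
            reads: Iterable = read_fastq(config.reads)
        else:
            logger.info("no reads supplied; simulating %d events", config.n_events)
            library = synthetic_data.make_probe_library(config.n_events, seed=config.seed)
            samples = synthetic_data.make_samples(
                synthetic_data.default_conditions(),
                replicates=config.replicates,
                seed=config.seed,
            )
            conditions = sorted({s.condition for s in samples})
            true_psi = synthetic_data.random_true_psi(
                config.n_events, conditions, seed=config.seed,
                event_ids=[e.event_id for e in library],
            )
            from .types import SimulationConfig

            sim = SimulationConfig(
                true_psi=true_psi,
                mean_depth=config.mean_depth,
                dispersion=config.dispersion,
                replicates_per_condition=config.replicates,
                seed=config.seed,
                read_error_rate=config.read_error_rate,
            )
            sim_counts = synthetic_data.simulate_counts(sim, samples)
            write_probe_library(library, out / "library.tsv")
            write_samples(samples, out / "samples.tsv")
            write_table(true_psi.reset_index(), out / "true_psi.tsv")
            write_fastq(
                synthetic_data.emit_reads(sim_counts, library, samples, sim),
                out / "reads.fastq",
            )
            reads = read_fastq(out / "reads.fastq")

        stage = "count"
        logger.info("counting reads")
        counts, report = counting.demultiplex_and_count(
            reads, library, samples, max_mismatches=config.max_mismatches
        )
        write_table(counts, out / "counts.tsv")
        (out / "counting_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["stages"]["count"] = {
            "rows": len(counts), "n_assigned": report.n_assigned,
            "n_reads_total": report.n_reads_total,
        }

        stage = "filter"
        filtered = quantification.filter_low_coverage(counts, config.min_mean_reads)
        write_table(filtered, out / "counts_filtered.tsv")
        manifest["stages"]["filter"] = {
            "rows": len(filtered),
            "events": int(filtered["event_id"].nunique()),
        }

        stage = "psi"
        psi = quantification.compute_psi(filtered, samples)
        write_table(psi.replicates, out / "psi_replicates.tsv")
        write_table(psi.condition_means, out / "psi_condition_means.tsv")
        manifest["stages"]["psi"] = {"rows": len(psi.replicates)}

        stage = "delta"
        dp = quantification.delta_psi(psi, event_calling.WT_S, event_calling.PSF_KD_S)
        write_table(dp, out / "delta_psi.tsv")
        manifest["stages"]["delta"] = {"rows": len(dp)}

        stage = "call"
        means = psi.means_wide()
        pvals = dp.set_index("event_id")["p_value"]
        if config.criterion == "methods":
            calls = event_calling.call_psf_dependent_methods(
                means, pvals, delta_threshold=config.methods_delta,
                alpha=config.alpha, magnitude_only=config.magnitude_only,
            )
            pass_col = "passes_methods_criterion"
        else:
            calls = event_calling.call_psf_dependent_results(
                means, pvals, stim_threshold=config.stim_delta,
                rescue_threshold=config.rescue, alpha=config.alpha,
                magnitude_only=config.magnitude_only,
            )
            pass_col = "passes_results_criterion"
        write_table(calls, out / "event_calls.tsv")
        manifest["stages"]["call"] = {
            "rows": len(calls),
            "n_passing": int(calls[pass_col].sum()),
            "criterion": config.criterion,
        }

        if event_calling.TRAP150_KD_U in means.columns:
            stage = "antagonism"
            ant = event_calling.classify_antagonism(means, margin=config.margin)
            write_table(ant, out / "antagonism_calls.tsv")
            manifest["stages"]["antagonism"] = {
                "rows": len(ant),
                "labels": ant["label"].value_counts().to_dict(),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
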