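"""Synthetic RASL-Seq data generation.

Builds probe libraries, sample sheets, ground-truth PSI matrices, replicate
count tables and raw barcoded reads with the statistical structure the
downstream analysis assumes, so every stage of the pipeline can be tested
without external sequencing data. Also ships the packaged reference set of
39 PSF-dependent, PMA-induced splicing events (condition-mean PSI for
WT-unstimulated, WT-stimulated and PSF-knockdown-stimulated JSL1 cells).
"""

from __future__ import annotations

import importlib.resources
import itertools
from collections.abc import Iterator, Sequence

import numpy as np
import pandas as pd

from .types import (
    DNA_ALPHABET,
    Genotype,
    ProbeEvent,
    SampleSpec,
    SimulationConfig,
    Stimulation,
)

DEFAULT_JUNCTION_LENGTH = 40  # 20 nt probe on each side of the junction
DEFAULT_BARCODE_LENGTH = 8

_BASES = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


def _random_unique_seqs(n: int, length: int, rng: np.random.Generator,
                        taken: set[str] | None = None) -> list[str]:
    """Draw ``n`` distinct random DNA strings not colliding with ``taken``."""
    seen: set[str] = set() if taken is None else set(taken)
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out) + 8, length))
        for row in _BASES[batch]:
            seq = row.tobytes().decode()
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    break
    return out


def make_probe_library(
    n_events: int,
    seed: int,
    junction_length: int = DEFAULT_JUNCTION_LENGTH,
    event_ids: Sequence[str] | None = None,
    gene_symbols: Sequence[str] | None = None,
) -> list[ProbeEvent]:
    """Generate a probe library of ``n_events`` cassette-exon events.

    Junction sequences are random DNA of ``junction_length`` nt, unique
    across the whole library (long and short pooled), mimicking a probe set
    designed against distinct splice junctions. Deterministic given ``seed``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if event_ids is not None and len(event_ids) != n_events:
        raise ValueError("event_ids length must equal n_events")
    rng = np.random.default_rng(seed)
    seqs = _random_unique_seqs(2 * n_events, junction_length, rng)
    events = []
    for i in range(n_events):
        eid = event_ids[i] if event_ids is not None else f"EV{i:05d}"
        sym = gene_symbols[i] if gene_symbols is not None else eid
        events.append(
            ProbeEvent(
                event_id=eid,
                gene_symbol=sym,
                long_junction_seq=seqs[2 * i],
                short_junction_seq=seqs[2 * i + 1],
                long_is_inclusion=True,
            )
        )
    if len({e.event_id for e in events}) != n_events:
        raise ValueError("event_ids must be unique")
    return events


def make_samples(
    conditions: Sequence[tuple[Genotype, Stimulation]],
    replicates: int = 3,
    seed: int = 0,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
) -> list[SampleSpec]:
    """Build a sample sheet with unique equal-length barcodes."""
    n = len(conditions) * replicates
    rng = np.random.default_rng(seed)
    barcodes = _random_unique_seqs(n, barcode_length, rng)
    samples = []
    for i, ((gt, stim), rep) in enumerate(
        itertools.product(conditions, range(1, replicates + 1))
    ):
        samples.append(SampleSpec(gt, stim, rep, barcodes[i]))
    return samples


def default_conditions() -> list[tuple[Genotype, Stimulation]]:
    """The three screen conditions: WT unstimulated, WT stimulated,
    PSF-KD stimulated."""
    return [
        (Genotype.WT, Stimulation.UNSTIMULATED),
        (Genotype.WT, Stimulation.STIMULATED),
        (Genotype.PSF_KD, Stimulation.STIMULATED),
    ]


def random_true_psi(
    n_events: int,
    conditions: Sequence[str],
    seed: int,
    event_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth PSI matrix.

    Values are Beta(0.5, 0.5) x 100, reproducing the U-shaped distribution
    of cassette-exon inclusion seen in real transcriptomes (most exons near
    constitutively included or skipped, fewer intermediate).
    """
    rng = np.random.default_rng(seed)
    if event_ids is None:
        event_ids = [f"EV{i:05d}" for i in range(n_events)]
    vals = 100.0 * rng.beta(0.5, 0.5, size=(n_events, len(conditions)))
    return pd.DataFrame(vals, index=pd.Index(event_ids, name="event_id"),
                        columns=list(conditions))


def simulate_counts(config: SimulationConfig, samples: Sequence[SampleSpec]) -> pd.DataFrame:
    """Draw a per event x sample long/short count table.

    Totals are negative binomial with mean ``config.mean_depth`` and shape
    ``config.dispersion`` (Poisson when the shape is infinite); the long
    count is binomial from the total at true_psi/100 for the sample's
    condition. Deterministic given ``config.seed``.
    """
    for s in samples:
        if s.condition not in config.true_psi.columns:
            raise ValueError(
                f"sample {s.sample_id}: condition {s.condition} has no "
                "column in true_psi"
            )
    rng = np.random.default_rng(config.seed)
    event_ids = list(config.true_psi.index)
    n = len(event_ids)
    rows = []
    for s in samples:
        p = config.true_psi[s.condition].to_numpy(dtype=float) / 100.0
        if np.isinf(config.dispersion):
            totals = rng.poisson(config.mean_depth, size=n)
        else:
            k = config.dispersion
            totals = rng.negative_binomial(k, k / (k + config.mean_depth), size=n)
        longs = rng.binomial(totals, p)
        rows.append(
            pd.DataFrame(
                {
                    "event_id": event_ids,
                    "sample_id": s.sample_id,
                    "long_count": longs,
                    "short_count": totals - longs,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["event_id", "sample_id"], ignore_index=True)


# fixed placeholder quality; the analysis never reads quality scores
_QUAL_CHAR = "I"


def emit_reads(
    count_table: pd.DataFrame,
    library: Sequence[ProbeEvent],
    samples: Sequence[SampleSpec],
    config: SimulationConfig,
) -> Iterator[tuple[str, str, str]]:
    """Yield FASTQ records (id, sequence, quality) for every counted
    ligation product.

    Each read is the sample barcode followed by the event's long or short
    junction sequence, with per-base substitution noise at
    ``config.read_error_rate``. The read multiset per (event, sample,
    isoform) has exactly the cardinality of the count-table entry.
    """
    by_id = {e.event_id: e for e in library}
    bc = {s.sample_id: s.barcode for s in samples}
    unknown = set(count_table["event_id"]) - set(by_id)
    if unknown:
        raise KeyError(f"count table references unknown event ids: {sorted(unknown)[:5]}")
    # independent error stream so count draws are unaffected by the error rate
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EAD]))
    err = config.read_error_rate
    i = 0
    for row in count_table.itertuples(index=False):
        ev = by_id[row.event_id]
        barcode = bc[row.sample_id]
        for seq, count in (
            (ev.long_junction_seq, int(row.long_count)),
            (ev.short_junction_seq, int(row.short_count)),
        ):
            full = barcode + seq
            qual = _QUAL_CHAR * len(full)
            for _ in range(count):
                read = full
                if err > 0.0:
                    read = _mutate(full, err, rng)
                yield (f"read{i:09d}", read, qual)
                i += 1


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        choices = [b for b in DNA_ALPHABET if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


def psf_dependent_events() -> pd.DataFrame:
    """Load the packaged reference set of 39 PSF-dependent splicing events.

    Returns condition-mean PSI (columns WT_U, WT_S, PSF_KD_S, integer
    percentages as published) indexed by event_id, with a gene_symbol
    column. Two distinct events share the symbol SNHG3-RCC1 and are
    disambiguated as SNHG3-RCC1.a / SNHG3-RCC1.b in table order.
    """
    ref = importlib.resources.files("raslquant.data") / "psf_dependent_events.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_symbol": str})
    return df.set_index("event_id")
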