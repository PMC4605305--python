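"""Demultiplexing and junction-read counting.

Assigns each read to a sample by exact barcode prefix match, then to a
library junction (and hence to one isoform of one event) by nearest
Hamming match within a mismatch budget. Ambiguous matches — two library
junctions tied at the minimum distance — are discarded, a conservative
rule for short inline probes.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CountingReport, ProbeEvent, SampleSpec

logger = logging.getLogger(__name__)


def _junction_matrix(junctions: list[str]) -> np.ndarray:
    return np.frombuffer("".join(junctions).encode(), dtype=np.uint8).reshape(
        len(junctions), -1
    )


def demultiplex_and_count(
    reads: Iterable[tuple[str, str, str] | tuple[str, str] | str],
    library: Sequence[ProbeEvent],
    samples: Sequence[SampleSpec],
    max_mismatches: int = 1,
) -> tuple[pd.DataFrame, CountingReport]:
    """Count long/short junction reads per event per sample.

    ``reads`` yields FASTQ-like records: plain sequence strings or
    (id, seq[, qual]) tuples. Returns a dense count table (every
    event x sample present, zeros where unobserved; columns event_id,
    sample_id, long_count, short_count) and a :class:`CountingReport`
    whose categories partition the input reads.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    bc_lens = {len(s.barcode) for s in samples}
    if len(bc_lens) > 1:
        raise ValueError("sample barcodes must be equal-length")
    j_lens = {len(e.long_junction_seq) for e in library} | {
        len(e.short_junction_seq) for e in library
    }
    if len(j_lens) > 1:
        raise ValueError("junction sequences must be equal-length")
    bc_len = bc_lens.pop() if bc_lens else 0
    j_len = j_lens.pop() if j_lens else 0

    barcode_to_sample = {s.barcode: s.sample_id for s in samples}
    if len(barcode_to_sample) != len(samples):
        raise ValueError("sample barcodes must be unique")

    junctions: list[str] = []
    targets: list[tuple[str, bool]] = []  # (event_id, is_long)
    for e in library:
        junctions.append(e.long_junction_seq)
        targets.append((e.event_id, True))
        junctions.append(e.short_junction_seq)
        targets.append((e.event_id, False))
    if len(set(junctions)) != len(junctions):
        raise ValueError("junction sequences must be unique across the library")
    exact = {seq: tgt for seq, tgt in zip(junctions, targets)}
    jmat = _junction_matrix(junctions) if max_mismatches > 0 else None

    counts: Counter[tuple[str, str, bool]] = Counter()
    report = CountingReport()
    per_sample: Counter[str] = Counter()
    short_read_warned = False

    for rec in reads:
        seq = rec if isinstance(rec, str) else rec[1]
        report.n_reads_total += 1
        if len(seq) < bc_len:
            report.n_unassigned_barcode += 1
            continue
        sample_id = barcode_to_sample.get(seq[:bc_len])
        if sample_id is None:
            report.n_unassigned_barcode += 1
            continue
        if len(seq) < bc_len + j_len:
            if not short_read_warned:
                logger.warning(
                    "read shorter than barcode+junction length; counting as unassigned"
                )
                short_read_warned = True
            report.n_unassigned_junction += 1
            continue
        region = seq[bc_len : bc_len + j_len]
        target = exact.get(region)
        if target is None and jmat is not None:
            rv = np.frombuffer(region.encode(), dtype=np.uint8)
            dists = (jmat != rv).sum(axis=1)
            dmin = int(dists.min())
            if dmin <= max_mismatches and int((dists == dmin).sum()) == 1:
                target = targets[int(dists.argmin())]
        if target is None:
            report.n_unassigned_junction += 1
            continue
        event_id, is_long = target
        counts[(event_id, sample_id, is_long)] += 1
        per_sample[sample_id] += 1
        report.n_assigned += 1

    report.per_sample_assigned = {s.sample_id: per_sample.get(s.sample_id, 0)
                                  for s in samples}

    event_ids = [e.event_id for e in library]
    sample_ids = [s.sample_id for s in samples]
    rows = [
        {
            "event_id": eid,
            "sample_id": sid,
            "long_count": counts.get((eid, sid, True), 0),
            "short_count": counts.get((eid, sid, False), 0),
        }
        for eid in event_ids
        for sid in sample_ids
    ]
    table = pd.DataFrame(rows, columns=["event_id", "sample_id", "long_count", "short_count"])
    table = table.sort_values(["event_id", "sample_id"], ignore_index=True)
    return table, report
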