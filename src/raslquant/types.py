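"""Core domain types for RASL-Seq splicing quantification.

A RASL-Seq assay interrogates each cassette-exon splicing event with two
ligation probe pairs: one spanning the exon-inclusion (long isoform)
junction and one spanning the exon-skipping (short isoform) junction.
Sequencing reads are the sample barcode followed by the ligated junction
sequence, so every read votes for one isoform of one event in one sample.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"

_VALID_SEQ = re.compile(r"^[ACGT]+$")


class Genotype(str, enum.Enum):
    WT = "WT"
    PSF_KD = "PSF_KD"
    TRAP150_KD = "TRAP150_KD"


class Stimulation(str, enum.Enum):
    UNSTIMULATED = "U"
    STIMULATED = "S"


@dataclass(frozen=True)
class ProbeEvent:
    """One interrogated cassette-exon event and its two junction probes.

    ``long_junction_seq`` / ``short_junction_seq`` are the concatenated
    upstream+downstream probe sequences (DNA alphabet, conventionally
    20 nt + 20 nt). ``long_is_inclusion`` records which junction reports
    the longest (exon-included) isoform; PSI is always the long-isoform
    read fraction.
    """

    event_id: str
    gene_symbol: str
    long_junction_seq: str
    short_junction_seq: str
    long_is_inclusion: bool = True

    def __post_init__(self) -> None:
        for seq in (self.long_junction_seq, self.short_junction_seq):
            if not _VALID_SEQ.match(seq):
                raise ValueError(
                    f"event {self.event_id}: junction sequence must be "
                    f"non-empty A/C/G/T, got {seq!r}"
                )
        if self.long_junction_seq == self.short_junction_seq:
            raise ValueError(
                f"event {self.event_id}: long and short junction "
                "sequences must differ"
            )


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing sample: genotype x stimulation x replicate, with its
    inline barcode."""

    genotype: Genotype
    stimulation: Stimulation
    replicate: int
    barcode: str

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if not _VALID_SEQ.match(self.barcode):
            raise ValueError(f"barcode must be non-empty A/C/G/T, got {self.barcode!r}")

    @property
    def condition(self) -> str:
        """Condition label, e.g. ``WT_S`` or ``PSF_KD_S``."""
        return f"{self.genotype.value}_{self.stimulation.value}"

    @property
    def sample_id(self) -> str:
        return f"{self.condition}_rep{self.replicate}"


def condition_of(sample_id: str) -> str:
    """Strip the replicate suffix from a sample id (``WT_S_rep2`` -> ``WT_S``)."""
    return re.sub(r"_rep\d+$", "", sample_id)


@dataclass
class SimulationConfig:
    """Parameters of the count-generating model.

    Per event x sample the total read count is negative binomial with mean
    ``mean_depth`` and shape ``dispersion`` (variance mu + mu^2/dispersion;
    ``dispersion = inf`` gives Poisson). The long-isoform count is binomial
    from the total at probability true_psi/100.

    ``true_psi`` is an event x condition DataFrame of inclusion percentages
    in [0, 100]; its index defines the simulated event set.
    """

    true_psi: pd.DataFrame
    mean_depth: float = 1000.0
    dispersion: float = 10.0
    replicates_per_condition: int = 3
    seed: int = 0
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        psi = np.asarray(self.true_psi, dtype=float)
        if psi.size and ((psi < 0) | (psi > 100)).any():
            raise ValueError("true_psi values must lie in [0, 100]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (use inf for Poisson)")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate must lie in [0, 1]")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")

    @property
    def n_events(self) -> int:
        return len(self.true_psi)


@dataclass
class CountingReport:
    """Read-assignment accounting for one demultiplex-and-count run."""

    n_reads_total: int = 0
    n_assigned: int = 0
    n_unassigned_barcode: int = 0
    n_unassigned_junction: int = 0
    per_sample_assigned: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_reads_total": self.n_reads_total,
            "n_assigned": self.n_assigned,
            "n_unassigned_barcode": self.n_unassigned_barcode,
            "n_unassigned_junction": self.n_unassigned_junction,
            "per_sample_assigned": dict(self.per_sample_assigned),
        }


@dataclass
class PsiTable:
    """Per-replicate PSI values plus condition means.

    ``replicates``: columns event_id, sample_id, condition, long_count,
    short_count, total_count, psi (NaN where total_count == 0).
    ``condition_means``: columns event_id, condition, mean_psi,
    n_replicates_used; the mean is over replicates with defined PSI only.
    """

    replicates: pd.DataFrame
    condition_means: pd.DataFrame

    def means_wide(self) -> pd.DataFrame:
        """Event x condition matrix of mean PSI (index event_id)."""
        return self.condition_means.pivot(
            index="event_id", columns="condition", values="mean_psi"
        ).rename_axis(columns=None)
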