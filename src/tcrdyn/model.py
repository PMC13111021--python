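"""Core in-memory containers for repertoire samples and cohort records.

A *clonotype* is a unique rearrangement defined by its CDR3 nucleotide
sequence together with V and J gene usage; the amino-acid sequence is
derived by translation and is shared by synonymous rearrangements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

TIMEPOINTS = ("T1", "T2", "T3")
RESPONSES = ("PR", "SD", "PD", "NE")

#: responses that constitute disease control (RECIST 1.1 PR or SD)
DISEASE_CONTROL_RESPONSES = frozenset({"PR", "SD"})


@dataclass(frozen=True)
class Clonotype:
    """One collapsed rearrangement: nt/aa CDR3, V and J genes, read count."""

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    j_gene: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"clonotype count must be >= 1, got {self.count}")

    @property
    def key(self) -> tuple[str, str, str]:
        """Identity key: (CDR3 nt, V gene, J gene)."""
        return (self.cdr3_nt, self.v_gene, self.j_gene)


@dataclass
class RepertoireSample:
    """One patient x time-point repertoire: collapsed clonotypes plus provenance.

    ``discarded_reads`` records the read mass removed because the junction
    was unproductive (out of frame or containing a stop codon), so that
    parsing stays lossless for counts: depth + discarded = input total.
    """

    clonotypes: list[Clonotype]
    patient_id: Optional[str] = None
    timepoint: Optional[str] = None
    discarded_reads: int = 0
    source: Optional[str] = None

    @property
    def depth(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id or 'sample'}_{self.timepoint or 'NA'}"

    def counts(self) -> np.ndarray:
        return np.asarray([c.count for c in self.clonotypes], dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        depth = self.depth
        if depth == 0:
            raise ValueError("sample has zero depth; frequencies undefined")
        return self.counts() / depth


@dataclass(frozen=True)
class ConvergentGroup:
    """A (V gene, CDR3 amino acid) class encoded by >= 2 distinct nt sequences."""

    v_gene: str
    cdr3_aa: str
    members: frozenset[str]
    aggregate_count: int
    aggregate_frequency: float

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a convergent group needs >= 2 distinct nt members")
        if not 0.0 <= self.aggregate_frequency <= 1.0:
            raise ValueError("aggregate_frequency outside [0, 1]")


@dataclass
class SampleMetrics:
    """Per-sample summary: diversity, evenness, convergence, richness, depth.

    ``evenness`` is NaN when the sample holds <= 1 clonotype (Pielou's J is
    undefined at S = 1).
    """

    patient_id: str
    timepoint: str
    group: Optional[str]
    depth: int
    unique_clones: int
    shannon: float
    evenness: float
    convergence: float


@dataclass
class DeltaMetrics:
    """Per-patient T1 -> T2 change in unique clone count."""

    patient_id: str
    group: Optional[str]
    pre_clones: int
    post_clones: int
    delta_clones: int
    percent_decline: float


@dataclass
class PatientRecord:
    patient_id: str
    response: str
    os_days: float
    event: int
    sample_paths: dict[str, Path] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(
                f"response {self.response!r} not in {sorted(RESPONSES)}"
            )
        if self.os_days < 0:
            raise ValueError(f"os_days must be >= 0, got {self.os_days}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")

    @property
    def group(self) -> Optional[str]:
        """DCG iff response is PR or SD; PD for progression; None for NE."""
        if self.response in DISEASE_CONTROL_RESPONSES:
            return "DCG"
        if self.response == "PD":
            return "PD"
        return None


@dataclass
class CohortManifest:
    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def by_id(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)
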