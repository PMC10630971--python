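"""In-memory cohort containers shared by the generator, the readers and the pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid
from .grid import StructureSet

__all__ = ["Patient", "Cohort", "array_hash"]


def array_hash(arr: np.ndarray) -> str:
    """sha256 of an array's raw bytes (dtype and shape included)."""
    h = hashlib.sha256()
    h.update(str(arr.dtype).encode())
    h.update(str(arr.shape).encode())
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


@dataclass
class Patient:
    """Reference plan plus per-fraction evaluations for one patient."""

    patient_id: str
    reference: StructureSet
    reference_dose: DoseGrid
    fractions: list[tuple[StructureSet, DoseGrid]] = field(default_factory=list)

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)


@dataclass
class Cohort:
    patients: list[Patient]
    manifest: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_evaluation_records(self) -> int:
        return sum(p.n_fractions for p in self.patients)
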