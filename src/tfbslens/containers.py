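"""Shared lightweight containers: sequence records and labeled instance sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import is_dna, is_protein


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record with a declared molecule type.

    DNA sequences must be plain uppercase ACGT (ambiguity codes are rejected
    because records feed the scoring functions); proteins must use the 20
    standard amino acids.
    """

    id: str
    sequence: str
    moltype: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.moltype == "dna":
            if not is_dna(self.sequence):
                raise ValueError(f"record {self.id!r}: not a plain ACGT DNA sequence")
        elif self.moltype == "protein":
            if not is_protein(self.sequence):
                raise ValueError(f"record {self.id!r}: not a standard protein sequence")
        else:
            raise ValueError(f"record {self.id!r}: unknown moltype {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Instance:
    """One labeled DNA segment; label 1 = verified binding site, 0 = background."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"instance {self.id!r}: label must be 0 or 1")
        if not is_dna(self.sequence):
            raise ValueError(f"instance {self.id!r}: not a plain ACGT sequence")


@dataclass
class InstanceSet:
    """A balanced positive/negative instance set, optionally with features.

    ``features`` (when attached by :func:`tfbslens.features.featurize`) is a
    DataFrame aligned row-for-row with ``instances``, holding the canonical
    feature block (sequence score if a PWM was available, 38 structure
    attributes, evolution score).
    """

    set_id: str
    instances: list[Instance] = field(default_factory=list)
    features: pd.DataFrame | None = None

    @property
    def sequences(self) -> list[str]:
        return [inst.sequence for inst in self.instances]

    @property
    def labels(self) -> list[int]:
        return [inst.label for inst in self.instances]

    @property
    def positives(self) -> list[Instance]:
        return [inst for inst in self.instances if inst.label == 1]

    @property
    def negatives(self) -> list[Instance]:
        return [inst for inst in self.instances if inst.label == 0]

    def __len__(self) -> int:
        return len(self.instances)

    def is_balanced(self) -> bool:
        return len(self.positives) == len(self.negatives)
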