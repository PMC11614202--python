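"""Bag containers shared across the pipeline.

A *bag* is one virus represented by an ordered list of instances. Before
featurization an instance carries a raw sequence (a protein fragment or a
CDS); after featurization the bag additionally holds an ``(M, d)`` feature
matrix whose rows align with the instance list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Instance", "VirusBag"]


@dataclass(frozen=True)
class Instance:
    """Provenance of one bag member.

    ``fragment_index`` is 0 for unsplit proteins and for CDS instances; for
    split proteins it numbers the 1022-residue fragments left to right.
    """

    protein_id: str
    fragment_index: int = 0
    sequence: str | None = None


@dataclass
class VirusBag:
    """One virus as an ordered set of instances with an optional label.

    Parameters
    ----------
    virus_id
        Identifier of the virus (taxid or accession).
    instances
        Ordered provenance records, one per instance.
    features
        ``(M, d)`` float matrix, row ``m`` belonging to ``instances[m]``;
        ``None`` for a raw-sequence skeleton.
    label
        ``0``/``1`` for binary tasks, a class index for multi-class tasks,
        or ``None`` at prediction time.
    """

    virus_id: str
    instances: list[Instance] = field(default_factory=list)
    features: np.ndarray | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError(f"bag {self.virus_id!r} has no instances")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.ndim != 2 or self.features.shape[0] != len(self.instances):
                raise ValueError(
                    f"bag {self.virus_id!r}: feature matrix shape "
                    f"{self.features.shape} does not match {len(self.instances)} instances"
                )

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def dim(self) -> int:
        if self.features is None:
            raise ValueError(f"bag {self.virus_id!r} is not featurized")
        return self.features.shape[1]
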