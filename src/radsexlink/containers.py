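"""Shared in-memory containers used across the pipeline.

The two containers here are deliberately thin wrappers around pandas objects:
a read-depth matrix with per-sample sex labels, and a marker catalogue mapping
locus ids to nucleotide sequences. Everything downstream (screening, pseudo-SNP
encoding, linkage mapping) operates on these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_VALID_SEXES = {MALE, FEMALE, UNKNOWN}


@dataclass
class DepthMatrix:
    """Loci x samples integer read counts plus a sex label per sample.

    ``counts`` is indexed by locus id with one column per sample id;
    ``sexes`` maps sample id -> 'male' | 'female' | 'unknown'.
    """

    counts: pd.DataFrame
    sexes: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.sexes = pd.Series(self.sexes, dtype=object)
        missing = [s for s in self.counts.columns if s not in self.sexes.index]
        if missing:
            raise ValueError(f"samples without sex labels: {missing[:5]}")
        bad = set(self.sexes) - _VALID_SEXES
        if bad:
            raise ValueError(f"invalid sex labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def loci(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of_sex(self, sex: str) -> list[str]:
        return [s for s in self.counts.columns if self.sexes[s] == sex]

    @property
    def males(self) -> list[str]:
        return self.samples_of_sex(MALE)

    @property
    def females(self) -> list[str]:
        return self.samples_of_sex(FEMALE)

    def subset_loci(self, loci) -> "DepthMatrix":
        return DepthMatrix(self.counts.loc[list(loci)], self.sexes)


@dataclass
class MarkerCatalog:
    """Ordered locus id -> nucleotide sequence mapping (RAD marker catalogue)."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, locus: str) -> bool:
        return locus in self.sequences

    def __getitem__(self, locus: str) -> str:
        return self.sequences[locus]

    def ids(self) -> list[str]:
        return list(self.sequences)

    def items(self):
        return self.sequences.items()
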