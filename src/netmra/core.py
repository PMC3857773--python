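"""Core in-memory containers shared across the pipeline.

All gene and sample identifiers are opaque strings: no probe/symbol
mapping is performed anywhere in the package, so synthetic and imported
data live in a single identifier space.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("netmra")


class ValidationError(ValueError):
    """An input violated a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized (log-scale recommended) expression.

    Invariants: unique gene and sample ids, finite values, shape consistent
    with the id lists. Values are kept as a float64 ndarray; ``to_frame``
    gives a labeled pandas view.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene id in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample id in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class GeneSet:
    """A named gene collection (regulon, signature, ...).

    ``members`` preserves insertion order (GMT round-trips are exact) but
    membership semantics are set-like.
    """

    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(str(m))
        self.members = list(seen)

    def as_set(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class MotifModel:
    """Position frequency matrix over the DNA alphabet A, C, G, T.

    ``counts`` is a 4 x L non-negative matrix; row order is fixed A, C, G, T.
    """

    motif_id: str
    counts: np.ndarray

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError("motif counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValidationError("motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValidationError("motif counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValidationError("every motif column needs a positive total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass
class SurvivalTable:
    """Right-censored time-to-event records with one real covariate."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariate: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.covariate = np.asarray(self.covariate, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.time) == len(self.event) == len(self.covariate) == n):
            raise ValidationError("survival table columns have unequal lengths")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValidationError("survival times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValidationError("event indicator must be 0 or 1")
        if np.any(~np.isfinite(self.covariate)):
            raise ValidationError("missing covariate value in survival table")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask: np.ndarray) -> "SurvivalTable":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return SurvivalTable(ids, self.time[mask], self.event[mask], self.covariate[mask])
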