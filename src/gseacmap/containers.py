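"""In-memory containers passed between pipeline stages.

Gene identifiers are matched as exact, case-sensitive strings everywhere in
the package; no symbol/alias mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

CONDITIONS = ("control", "treated")


@dataclass
class CountMatrix:
    """Raw gene × sample read counts with a condition label per sample.

    ``counts`` is an integer array of shape ``(n_genes, n_samples)``; gene
    order is preserved from the source file. The two-group design requires
    at least two samples per condition for variance estimation.
    """

    genes: list[str]
    samples: list[str]
    conditions: dict[str, str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g in seen:
                    raise ValidationError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValidationError(
                    f"non-integer count at gene {self.genes[bad[0]]!r}, "
                    f"sample {self.samples[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}"
            )
        for s in self.samples:
            if s not in self.conditions:
                raise ValidationError(f"sample {s!r} missing from condition map")
            if self.conditions[s] not in CONDITIONS:
                raise ValidationError(
                    f"condition for sample {s!r} must be one of {CONDITIONS}"
                )

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of (control, treated) samples."""
        ctrl = np.array([i for i, s in enumerate(self.samples) if self.conditions[s] == "control"])
        trt = np.array([i for i, s in enumerate(self.samples) if self.conditions[s] == "treated"])
        return ctrl, trt

    def validate_design(self) -> None:
        ctrl, trt = self.group_indices()
        if len(ctrl) < 2 or len(trt) < 2:
            raise ValidationError("need >= 2 samples per condition")
        if np.any(self.library_sizes == 0):
            raise ValidationError("all-zero sample column")


@dataclass
class NormalizedMatrix:
    """TMM-scaled log2-CPM expression with optional precision weights.

    ``logcpm[g, s] = log2((c + 0.5) / (L_s + 1) * 1e6)`` with effective
    library size ``L_s = column_sum * tmm_factor``.
    """

    genes: list[str]
    samples: list[str]
    conditions: dict[str, str]
    logcpm: np.ndarray
    factors: np.ndarray
    effective_lib_sizes: np.ndarray
    weights: Optional[np.ndarray] = None

    def group_indices(self) -> tuple[np.ndarray, np.ndarray]:
        ctrl = np.array([i for i, s in enumerate(self.samples) if self.conditions[s] == "control"])
        trt = np.array([i for i, s in enumerate(self.samples) if self.conditions[s] == "treated"])
        return ctrl, trt


@dataclass
class DeTable:
    """Per-gene differential-expression results plus shared EB hyperparameters.

    ``table`` columns: logFC, avg_expr, s2, t, df_total, p, fdr, status
    (index = gene id). ``d0``/``s0_2`` are the empirical-Bayes prior degrees
    of freedom and prior variance shared by all genes (``d0`` may be inf).
    """

    table: pd.DataFrame
    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        required = {"logFC", "avg_expr", "s2", "t", "df_total", "p", "fdr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DeTable missing columns: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def counts(self) -> dict[str, int]:
        """Number of up / down / total differentially expressed genes."""
        if "status" not in self.table.columns:
            raise ValidationError("status not assigned; run filter_degs first")
        status = self.table["status"]
        up = int((status == "up").sum())
        down = int((status == "down").sum())
        return {"up": up, "down": down, "total": up + down}


@dataclass
class GeneSetCollection:
    """Named gene sets (membership deduplicated) with descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(m) for name, m in self.sets.items()}

    def restrict(self, universe: Iterable[str], min_size: int, max_size: int) -> "GeneSetCollection":
        """Intersect every set with *universe*; drop sets outside the size bounds."""
        uni = frozenset(universe)
        kept: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            inter = members & uni
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})


@dataclass
class SignatureReference:
    """Compound-signature reference: genes × instances z-scores with metadata.

    ``values`` holds the signatures as given (z-score convention);
    ``ranks`` is derived per instance with 1 = highest value (ties broken by
    gene order, so each column is a permutation of 1..n_genes). ``meta`` is
    indexed by instance id with columns compound, moa_class, cell_line.
    """

    genes: list[str]
    instances: list[str]
    values: np.ndarray
    meta: pd.DataFrame
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.instances)):
            raise ValidationError(
                f"reference values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.instances)} instances"
            )
        for col in ("compound", "moa_class", "cell_line"):
            if col not in self.meta.columns:
                raise ValidationError(f"reference metadata missing column {col!r}")
        missing = [i for i in self.instances if i not in self.meta.index]
        if missing:
            raise ValidationError(f"instance(s) without metadata: {missing[:5]}")
        self.meta = self.meta.loc[self.instances]
        # rank 1 = highest z; stable tie-break on gene order keeps each
        # column an exact permutation of 1..G
        order = np.argsort(-self.values, axis=0, kind="stable")
        ranks = np.empty_like(order)
        g = self.values.shape[0]
        rows = np.arange(g)[:, None]
        np.put_along_axis(ranks, order, np.broadcast_to(rows + 1, order.shape), axis=0)
        self.ranks = ranks

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def universe(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class QuerySignature:
    """Up/down tag sets queried against the reference."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if not self.up or not self.down:
            raise ValidationError("query needs both tails")
        if self.up & self.down:
            raise ValidationError("up and down tag sets overlap")

    def restrict(self, universe: Iterable[str]) -> tuple["QuerySignature", int]:
        """Drop genes absent from *universe*; return (restricted, n_dropped)."""
        uni = frozenset(universe)
        up = self.up & uni
        down = self.down & uni
        dropped = len(self.up) + len(self.down) - len(up) - len(down)
        return QuerySignature(up, down), dropped
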