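"""Pipeline configuration.

All thresholds default to the study settings so a bare run reproduces the
published analysis conditions: differential expression at fold change > 2 and
BH FDR < 0.05; GSEA at nominal p < 0.05 and FDR q < 0.25 with weighting
exponent 1 and 1000 gene-label permutations; connectivity hits taken from the
scaled-score window [95, 100] capped at the top 10 compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Thresholds and knobs shared across the pipeline stages.

    Attributes
    ----------
    fc_threshold:
        Fold-change cutoff for calling a gene differentially expressed; the
        filter is strict on ``|log2FC| > log2(fc_threshold)``.
    de_fdr:
        Benjamini–Hochberg q-value cutoff for differential expression.
    gsea_p, gsea_fdr:
        Nominal permutation p and FDR q cutoffs for calling a gene set
        enriched.
    gsea_exponent:
        Weighting exponent of the running-sum statistic (0 = classic
        Kolmogorov–Smirnov, 1 = standard weighted form).
    n_perm:
        Gene-label permutations for the GSEA null.
    score_window:
        Inclusive ``[low, high]`` window on the scaled connectivity score
        (range −100..100) from which hit compounds are taken.
    top_k:
        Maximum number of hit compounds retained.
    class_fraction:
        Fraction of a mechanism-of-action class's hit compounds that must
        share a pathway for it to enter the class pathway set.
    min_set_size, max_set_size:
        Gene-set size bounds after restriction to the ranked universe.
    n_sig:
        Tag-set size used when deriving top/bottom gene sets from a hit
        compound's signature (over-representation mode).
    use_voom_weights:
        Enable per-observation precision weights from the mean–variance
        trend; default off (trend-free log-CPM + empirical Bayes).
    seed:
        Master RNG seed; every stochastic step derives its stream from it.
    """

    fc_threshold: float = 2.0
    de_fdr: float = 0.05
    gsea_p: float = 0.05
    gsea_fdr: float = 0.25
    gsea_exponent: float = 1.0
    n_perm: int = 1000
    score_window: tuple[float, float] = (95.0, 100.0)
    top_k: int = 10
    class_fraction: float = 0.5
    min_set_size: int = 5
    max_set_size: int = 500
    n_sig: int = 150
    use_voom_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.score_window = tuple(float(v) for v in self.score_window)  # type: ignore[assignment]
        for name in ("fc_threshold", "de_fdr", "gsea_p", "gsea_fdr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.gsea_exponent < 0:
            raise ValidationError("gsea_exponent must be >= 0")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        lo, hi = self.score_window
        if not (-100.0 <= lo <= hi <= 100.0):
            raise ValidationError("score_window must satisfy -100 <= low <= high <= 100")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not (0.0 < self.class_fraction <= 1.0):
            raise ValidationError("class_fraction must lie in (0, 1]")
        if not (1 <= self.min_set_size <= self.max_set_size):
            raise ValidationError("need 1 <= min_set_size <= max_set_size")
        if self.n_sig < 1:
            raise ValidationError("n_sig must be >= 1")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_window"] = list(self.score_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a flat key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
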