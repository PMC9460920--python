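"""Pathway-set integration: per-class enrichment of hit signatures and the
intersection with the experiment's own enriched pathways.

The distinctive final step of the pipeline: each hit compound's extracted
signature is subjected to the same preranked GSEA as the experiment (an
over-representation mode on the top/bottom tag sets is available as a
flag); a mechanism-of-action class's pathway set contains every pathway
enriched in at least ``class_fraction`` of the class's hit compounds; and
the high-confidence prediction is the intersection of all class sets with
the experiment's enriched pathways, reported together with the full Venn
membership so alternative intersection readings can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .containers import GeneSetCollection
from .de import bh_adjust
from .errors import ValidationError
from .gsea import GseaResult, RankedList, permutation_stats


@dataclass
class ClassPathwaySet:
    """Pathways enriched in a mechanism-of-action class's hit compounds."""

    moa_class: str
    compounds: list[str]
    per_compound: dict[str, dict[str, str]]        # compound -> {pathway: direction}
    class_set: dict[str, dict] = field(default_factory=dict)
    # class_set: pathway -> {"fraction": float in (0,1], "direction": up/down}

    def pathways(self) -> set[str]:
        return set(self.class_set)


def _ora_enriched(top: frozenset[str], bottom: frozenset[str],
                  genesets: GeneSetCollection, universe: list[str],
                  config: PipelineConfig) -> dict[str, str]:
    """Hypergeometric over-representation of a signature's top/bottom tails.

    A pathway is called for the tail with the smaller BH-adjusted upper
    hypergeometric p, at the de_fdr threshold.
    """
    n_uni = len(universe)
    uni = frozenset(universe)
    names, p_up, p_down = [], [], []
    for name, members in genesets.sets.items():
        m = members & uni
        if not (config.min_set_size <= len(m) <= config.max_set_size):
            continue
        names.append(name)
        k_up = len(m & top)
        k_down = len(m & bottom)
        p_up.append(stats.hypergeom.sf(k_up - 1, n_uni, len(m), len(top)))
        p_down.append(stats.hypergeom.sf(k_down - 1, n_uni, len(m), len(bottom)))
    if not names:
        return {}
    q_up = bh_adjust(np.asarray(p_up))
    q_down = bh_adjust(np.asarray(p_down))
    out: dict[str, str] = {}
    for i, name in enumerate(names):
        if q_up[i] < config.de_fdr and q_up[i] <= q_down[i]:
            out[name] = "up"
        elif q_down[i] < config.de_fdr:
            out[name] = "down"
    return out


def class_pathways(hit_signatures: dict[str, dict], genesets: GeneSetCollection,
                   config: PipelineConfig, method: str = "gsea",
                   rng: np.random.Generator | None = None) -> list[ClassPathwaySet]:
    """Per-class pathway sets from the hit compounds' extracted signatures.

    ``hit_signatures`` is the mapping produced by
    :func:`gseacmap.connectivity.extract_hit_signatures`. Classes with zero
    hits are simply absent. ``method`` is ``"gsea"`` (preranked, same
    thresholds as the experiment) or ``"ora"`` (hypergeometric on the
    top/bottom tag sets).
    """
    if not genesets.sets:
        raise ValidationError("empty gene-set collection")
    if not hit_signatures:
        raise ValidationError("no hit signatures supplied")
    if method not in ("gsea", "ora"):
        raise ValidationError(f"unknown enrichment method {method!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    by_class: dict[str, list[str]] = {}
    for compound, sig in hit_signatures.items():
        by_class.setdefault(sig["moa_class"], []).append(compound)

    out: list[ClassPathwaySet] = []
    for moa_class in sorted(by_class):
        members = sorted(by_class[moa_class])
        per_compound: dict[str, dict[str, str]] = {}
        for compound in members:
            sig = hit_signatures[compound]
            if method == "gsea":
                res = permutation_stats(sig["ranked"], genesets, config, rng=rng)
                per_compound[compound] = res.enriched_sets()
            else:
                ranked: RankedList = sig["ranked"]
                per_compound[compound] = _ora_enriched(
                    sig["top"], sig["bottom"], genesets, ranked.genes, config)
        class_set = aggregate_class_set(per_compound, config.class_fraction)
        out.append(ClassPathwaySet(moa_class, members, per_compound, class_set))
    return out


def aggregate_class_set(per_compound: dict[str, dict[str, str]],
                        class_fraction: float) -> dict[str, dict]:
    """Majority-style rule: keep pathways enriched in >= class_fraction of
    the class's compounds; direction by majority vote (ties -> up)."""
    n = len(per_compound)
    tally: dict[str, list[str]] = {}
    for enriched in per_compound.values():
        for pathway, direction in enriched.items():
            tally.setdefault(pathway, []).append(direction)
    class_set: dict[str, dict] = {}
    for pathway, directions in sorted(tally.items()):
        fraction = len(directions) / n
        if fraction >= class_fraction:
            n_up = sum(1 for d in directions if d == "up")
            class_set[pathway] = {
                "fraction": fraction,
                "direction": "up" if n_up * 2 >= len(directions) else "down",
            }
    return class_set


@dataclass
class IntegrationReport:
    """Final integration product: extract pathways, class sets, Venn, prediction."""

    extract_pathways: dict[str, str]            # pathway -> direction
    class_sets: list[ClassPathwaySet]
    venn_membership: dict[str, list[str]]       # pathway -> sorted group names
    region_counts: dict[str, int]               # "extract&class01" -> count
    predicted: list[dict]                       # {pathway, direction, flag}
    config: dict = field(default_factory=dict)
    seed: int | None = None
    notices: list[str] = field(default_factory=list)

    def predicted_pathways(self) -> set[str]:
        return {p["pathway"] for p in self.predicted}

    def to_dict(self) -> dict:
        return {
            "extract_pathways": dict(sorted(self.extract_pathways.items())),
            "class_sets": [
                {
                    "moa_class": cs.moa_class,
                    "compounds": cs.compounds,
                    "class_set": {k: cs.class_set[k] for k in sorted(cs.class_set)},
                    "per_compound": {c: dict(sorted(e.items()))
                                     for c, e in sorted(cs.per_compound.items())},
                }
                for cs in self.class_sets
            ],
            "venn_membership": {k: v for k, v in sorted(self.venn_membership.items())},
            "region_counts": dict(sorted(self.region_counts.items())),
            "predicted": self.predicted,
            "config": self.config,
            "seed": self.seed,
            "notices": self.notices,
        }


def overlap_pathways(extract: GseaResult,
                     classes: list[ClassPathwaySet],
                     config: PipelineConfig | None = None) -> IntegrationReport:
    """Venn regions over {extract} ∪ class sets; predicted = total intersection."""
    if not classes:
        raise ValidationError("need at least one class pathway set")
    groups: dict[str, set[str]] = {"extract": set(extract.enriched_sets())}
    for cs in classes:
        groups[cs.moa_class] = cs.pathways()
    union = set().union(*groups.values())

    membership: dict[str, list[str]] = {}
    for pathway in sorted(union):
        membership[pathway] = sorted(g for g, s in groups.items() if pathway in s)

    region_counts: dict[str, int] = {}
    names = sorted(groups)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = "&".join(combo)
            combo_set = set(combo)
            region_counts[key] = sum(
                1 for p, m in membership.items() if set(m) == combo_set)

    predicted_names = set.intersection(*groups.values())
    extract_dirs = extract.enriched_sets()
    predicted = [{"pathway": p, "direction": extract_dirs[p], "flag": ""}
                 for p in sorted(predicted_names)]
    return IntegrationReport(
        extract_pathways=extract_dirs,
        class_sets=classes,
        venn_membership=membership,
        region_counts=region_counts,
        predicted=predicted,
        config=config.to_dict() if config else {},
        seed=config.seed if config else None,
    )


def direction_annotate(report: IntegrationReport,
                       extract: GseaResult) -> IntegrationReport:
    """Label each predicted pathway with the extract's direction and flag
    extract-vs-class direction conflicts as compensatory candidates.

    A pathway whose extract direction disagrees with the majority direction
    across the class sets is flagged ``"compensatory-candidate"`` — the
    transcriptional change may compensate for, rather than reflect, the
    functional effect.
    """
    extract_dirs = extract.enriched_sets()
    for entry in report.predicted:
        pathway = entry["pathway"]
        entry["direction"] = extract_dirs.get(pathway, entry["direction"])
        class_dirs = [cs.class_set[pathway]["direction"]
                      for cs in report.class_sets if pathway in cs.class_set]
        if class_dirs:
            n_up = sum(1 for d in class_dirs if d == "up")
            n_down = len(class_dirs) - n_up
            if n_up != n_down:
                majority = "up" if n_up > n_down else "down"
                if majority != entry["direction"]:
                    entry["flag"] = "compensatory-candidate"
    return report
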