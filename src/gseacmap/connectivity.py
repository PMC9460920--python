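"""Connectivity-map scoring of an up/down query signature.

Each reference instance is a genome-wide ranking (1 = most up-regulated by
the perturbagen). For a tag set of t query genes with sorted rank positions
V(1) <= ... <= V(t) in an instance of N genes, the Kolmogorov–Smirnov
statistic is

    a = max_j ( j/t − V(j)/N ),   b = max_j ( V(j)/N − (j−1)/t )
    ks = a if a > b else −b

The raw connectivity of an instance is ``s = ks_up − ks_down`` when the two
statistics disagree in sign and 0 otherwise; scores are scaled to
``c = 100 · s / max_i |s_i|`` so the best-matching instance attains ±100.
Hit compounds are those whose best-instance score falls inside the
configured window (default [95, 100], both ends inclusive), ranked
descending and truncated to ``top_k``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import DeTable, QuerySignature, SignatureReference
from .errors import ValidationError
from .gsea import RankedList

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityTable:
    """Per-instance KS statistics and scaled scores, plus compound summaries.

    ``instances`` columns: instance, compound, moa_class, cell_line, ks_up,
    ks_down, s, score. ``compounds`` columns: compound, moa_class,
    cell_line, score (best instance), median_score, best_instance.
    """

    instances: pd.DataFrame
    compounds: pd.DataFrame
    n_dropped_query_genes: int = 0


@dataclass
class HitSet:
    """Selected hit compounds grouped by mechanism-of-action class."""

    hits: pd.DataFrame  # compound, moa_class, score, best_instance
    by_class: dict[str, list[str]] = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        return list(self.hits["compound"])

    def to_dict(self) -> dict:
        return {
            "hits": [
                {"compound": r.compound, "moa_class": r.moa_class,
                 "score": float(r.score), "best_instance": r.best_instance}
                for r in self.hits.itertuples()
            ],
            "by_class": {k: list(v) for k, v in self.by_class.items()},
        }


def make_query(de: DeTable, config: PipelineConfig,
               n_sig: int | None = None) -> QuerySignature:
    """Build the up/down query from a status-filtered DE table.

    With ``n_sig`` set, each tail is capped at the n_sig genes of largest
    |moderated t|; by default all DEGs are used. Both tails must be
    nonempty.
    """
    if "status" not in de.table.columns:
        raise ValidationError("DE table has no status column; run filter_degs first")
    tbl = de.table
    up = tbl[tbl["status"] == "up"]
    down = tbl[tbl["status"] == "down"]
    if len(up) == 0 or len(down) == 0:
        raise ValidationError("query needs both tails")
    if n_sig is not None:
        up = up.reindex(up["t"].abs().sort_values(ascending=False).index[:n_sig])
        down = down.reindex(down["t"].abs().sort_values(ascending=False).index[:n_sig])
    return QuerySignature(frozenset(up.index), frozenset(down.index))


def ks_statistic(tag_ranks: np.ndarray, n: int) -> float:
    """Two-sided KS statistic of a tag set's rank positions in a ranking of n genes.

    ``tag_ranks`` are the 1-based rank positions (values drawn from a
    permutation of 1..n) of the tag genes in one reference instance.
    """
    v = np.sort(np.asarray(tag_ranks, dtype=float))
    t = len(v)
    if t == 0:
        raise ValidationError("empty tag set")
    j = np.arange(1, t + 1)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a > b else -b


def connectivity_scores(reference: SignatureReference,
                        query: QuerySignature) -> ConnectivityTable:
    """Score every reference instance against the query's up/down tag sets."""
    if reference.n_instances == 0:
        raise ValidationError("empty reference")
    restricted, dropped = query.restrict(reference.universe())
    if dropped:
        logger.info("connectivity: dropped %d query genes absent from the reference", dropped)
    gene_idx = {g: i for i, g in enumerate(reference.genes)}
    up_idx = np.array([gene_idx[g] for g in sorted(restricted.up)])
    down_idx = np.array([gene_idx[g] for g in sorted(restricted.down)])
    n = len(reference.genes)

    ks_up = np.empty(reference.n_instances)
    ks_down = np.empty(reference.n_instances)
    for i in range(reference.n_instances):
        col = reference.ranks[:, i]
        ks_up[i] = ks_statistic(col[up_idx], n)
        ks_down[i] = ks_statistic(col[down_idx], n)

    s = np.where(np.sign(ks_up) == np.sign(ks_down), 0.0, ks_up - ks_down)
    max_abs = np.max(np.abs(s))
    score = 100.0 * s / max_abs if max_abs > 0 else np.zeros_like(s)

    inst = pd.DataFrame(
        {
            "instance": reference.instances,
            "compound": reference.meta["compound"].to_numpy(),
            "moa_class": reference.meta["moa_class"].to_numpy(),
            "cell_line": reference.meta["cell_line"].to_numpy(),
            "ks_up": ks_up,
            "ks_down": ks_down,
            "s": s,
            "score": score,
        }
    )
    # compound level: best (max) instance score, median for diagnostics
    rows = []
    for compound, grp in inst.groupby("compound", sort=True):
        best = grp.loc[grp["score"].idxmax()]
        rows.append(
            {
                "compound": compound,
                "moa_class": best["moa_class"],
                "cell_line": best["cell_line"],
                "score": float(grp["score"].max()),
                "median_score": float(grp["score"].median()),
                "best_instance": best["instance"],
            }
        )
    compounds = pd.DataFrame(rows).sort_values(
        ["score", "compound"], ascending=[False, True]).reset_index(drop=True)
    return ConnectivityTable(inst, compounds, dropped)


def select_hits(table: ConnectivityTable, config: PipelineConfig) -> HitSet:
    """Compounds inside the score window, descending, truncated to top_k."""
    if len(table.compounds) == 0:
        raise ValidationError("empty connectivity table")
    lo, hi = config.score_window
    sel = table.compounds[(table.compounds["score"] >= lo) & (table.compounds["score"] <= hi)]
    sel = sel.sort_values(["score", "compound"], ascending=[False, True]).head(config.top_k)
    if len(sel) == 0:
        logger.info("connectivity: no compounds inside score window [%s, %s]", lo, hi)
    by_class: dict[str, list[str]] = {}
    for r in sel.itertuples():
        by_class.setdefault(r.moa_class, []).append(r.compound)
    return HitSet(sel.reset_index(drop=True)[
        ["compound", "moa_class", "score", "best_instance"]], by_class)


def extract_hit_signatures(reference: SignatureReference, hits: HitSet,
                           n_sig: int = 150) -> dict[str, dict]:
    """Per hit compound: the best instance's signature as a ranked list.

    Returns ``{compound: {"ranked": RankedList, "moa_class": str,
    "top": set, "bottom": set, "instance": str}}`` where top/bottom are the
    n_sig highest/lowest genes of the instance (for over-representation
    use). The ranked list is a permutation of the reference universe,
    ordered by descending z-score.
    """
    if len(hits.hits) == 0:
        raise ValidationError("no hits to extract")
    inst_idx = {inst: i for i, inst in enumerate(reference.instances)}
    out: dict[str, dict] = {}
    for r in hits.hits.itertuples():
        if r.best_instance not in inst_idx:
            raise ValidationError(f"hit instance {r.best_instance!r} not in reference")
        i = inst_idx[r.best_instance]
        values = reference.values[:, i]
        order = np.argsort(reference.ranks[:, i], kind="stable")  # rank 1 first
        genes = [reference.genes[k] for k in order]
        ranked = RankedList(genes, values[order])
        out[r.compound] = {
            "ranked": ranked,
            "moa_class": r.moa_class,
            "instance": r.best_instance,
            "top": frozenset(genes[:n_sig]),
            "bottom": frozenset(genes[-n_sig:]),
        }
    return out
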