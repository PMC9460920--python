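"""Preranked gene set enrichment analysis (GSEA).

Genes are ranked by signed log2 fold change (descending). For a gene set S
with N_h members inside the ranked universe of N genes, a running sum walks
the list, incrementing by ``|r_i|^p / sum_{hits} |r_j|^p`` at members and
decrementing by ``1 / (N - N_h)`` at non-members; the enrichment score (ES)
is the signed maximal deviation from zero. Significance comes from a
gene-label permutation null: random same-size gene subsets (one shared
label permutation per round, preserving inter-set correlation), with the
normalized ES (NES) formed against the matching-sign null mean and FDR q
computed by the ratio-of-tails over the pooled normalized null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import DeTable, GeneSetCollection
from .errors import ValidationError

_MIN_STABLE_NULL = 10  # matching-sign null draws below this → flagged unstable


@dataclass
class RankedList:
    """Gene ids ordered by descending score, with the scores and a tie count."""

    genes: list[str]
    scores: np.ndarray
    n_tied: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must have equal length")
        if len(self.genes) < 2:
            raise ValidationError("ranked list needs >= 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list has duplicate gene ids")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.genes)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genes)}
        pos = sorted(idx[g] for g in members if g in idx)
        return np.asarray(pos, dtype=np.int64)


@dataclass
class GseaResult:
    """Per-set enrichment table plus the run's global settings.

    ``table`` columns: size, es, nes, p, q, direction, enriched, unstable
    (index = set name; nes/q are NaN for sets whose matching-sign null was
    empty — those are excluded from the FDR computation).
    """

    table: pd.DataFrame
    n_perm: int
    exponent: float
    seed: int | None = None
    collection_names: tuple[str, ...] = field(default_factory=tuple)

    def enriched_sets(self) -> dict[str, str]:
        """Names of enriched sets mapped to their direction ('up'/'down')."""
        sel = self.table[self.table["enriched"]]
        return dict(zip(sel.index, sel["direction"]))


def rank_genes(de: DeTable) -> RankedList:
    """Rank all genes by descending log2FC; ties by smaller p, then id."""
    if len(de.table) == 0:
        raise ValidationError("empty DE table")
    tbl = de.table
    order = sorted(range(len(tbl)),
                   key=lambda i: (-tbl["logFC"].iloc[i], tbl["p"].iloc[i], tbl.index[i]))
    genes = [str(tbl.index[i]) for i in order]
    scores = tbl["logFC"].to_numpy()[order]
    n_tied = int(pd.Series(scores).duplicated(keep=False).sum())
    return RankedList(genes, scores, n_tied)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(ranked: RankedList, members: Iterable[str],
                     exponent: float = 1.0) -> tuple[float, np.ndarray, np.ndarray]:
    """ES of one gene set: (score, running profile of length N, hit indices).

    The profile value at index i is the running sum after processing the
    gene at rank i; the ES is the profile value of maximal absolute
    deviation (positive preferred on exact ties).
    """
    pos = ranked.positions(members)
    n = ranked.n
    if len(pos) == 0:
        raise ValidationError("gene set empty after restriction to the ranked universe")
    if len(pos) == n:
        raise ValidationError("gene set covers the whole universe; miss penalty undefined")
    absw = np.abs(ranked.scores) ** exponent
    w = absw[pos]
    denom = w.sum()
    if denom == 0:
        w = np.ones_like(w)  # all-zero scores degenerate to unweighted hits
        denom = w.sum()
    delta = np.full(n, -1.0 / (n - len(pos)))
    delta[pos] = w / denom
    profile = np.cumsum(delta)
    mx, mn = float(profile.max()), float(profile.min())
    # signed maximal deviation; positive preferred on an exact magnitude tie
    es = mx if mx >= -mn else mn
    return es, profile, pos


def _batch_es(sorted_pos: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Vectorised ES for many same-size hit-position vectors.

    ``sorted_pos``: (m, k) ascending 0-based hit positions; ``absw``: the
    |score|^p vector of the ranked list. Evaluates the running sum only at
    the hit positions (its local extrema) rather than along the full list.
    """
    m, k = sorted_pos.shape
    miss = 1.0 / (n - k)
    w = absw[sorted_pos]
    denom = w.sum(axis=1)
    zero = denom == 0
    if np.any(zero):
        w[zero] = 1.0
        denom[zero] = k
    h = np.cumsum(w, axis=1) / denom[:, None]
    jj = np.arange(1, k + 1)
    drop = (sorted_pos + 1 - jj) * miss  # misses accumulated before each hit
    after = h - drop
    before = np.concatenate([np.zeros((m, 1)), h[:, :-1]], axis=1) - drop
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

def permutation_stats(ranked: RankedList, collection: GeneSetCollection,
                      config: PipelineConfig,
                      rng: np.random.Generator | None = None) -> GseaResult:
    """Permutation p, NES and ratio-of-tails FDR q for every retained set.

    The collection is first restricted to the ranked universe and to sizes
    within [min_set_size, max_set_size]. The null uses ``n_perm`` shared
    gene-label permutations; the one-sided p on the observed sign is
    ``(1 + #exceedances) / (1 + n_perm)``. A set whose matching-sign null
    is empty gets NaN NES/q and is excluded from the FDR pool; fewer than
    10 matching-sign draws flags the set unstable.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    restricted = collection.restrict(ranked.genes, config.min_set_size, config.max_set_size)
    if not restricted.sets:
        raise ValidationError("no gene sets retained after universe/size restriction")
    n = ranked.n
    absw = np.abs(ranked.scores) ** config.gsea_exponent
    n_perm = config.n_perm

    # one shared label permutation per round: perm[i, g] = permuted position
    # of the gene at rank g, so each set's null keeps inter-set structure
    perm = np.argsort(rng.random((n_perm, n)), axis=1)

    names = restricted.names()
    es_obs = np.empty(len(names))
    sizes = np.empty(len(names), dtype=int)
    null_es: list[np.ndarray] = []
    for i, name in enumerate(names):
        pos = ranked.positions(restricted.sets[name])
        sizes[i] = len(pos)
        es_obs[i] = _batch_es(pos[None, :], absw, n)[0]
        null_pos = np.sort(perm[:, pos], axis=1)
        null_es.append(_batch_es(null_pos, absw, n))

    nes = np.full(len(names), np.nan)
    p_perm = np.ones(len(names))
    unstable = np.zeros(len(names), dtype=bool)
    null_nes_pool: list[np.ndarray] = []
    for i in range(len(names)):
        null = null_es[i]
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan
        es = es_obs[i]
        if es > 0:
            p_perm[i] = (1 + np.sum(pos_null >= es)) / (1 + n_perm)
            nes[i] = es / mean_pos if len(pos_null) else np.nan
            unstable[i] = len(pos_null) < _MIN_STABLE_NULL
        elif es < 0:
            p_perm[i] = (1 + np.sum(neg_null <= es)) / (1 + n_perm)
            nes[i] = es / mean_neg if len(neg_null) else np.nan
            unstable[i] = len(neg_null) < _MIN_STABLE_NULL
        else:
            p_perm[i] = 1.0
            nes[i] = 0.0
        pool = np.concatenate([
            pos_null / mean_pos if len(pos_null) else np.empty(0),
            neg_null / mean_neg if len(neg_null) else np.empty(0),
        ])
        null_nes_pool.append(pool)

    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    q = _fdr_ratio_of_tails(nes, pooled)

    enriched = (p_perm < config.gsea_p) & (q < config.gsea_fdr) & np.isfinite(nes)
    direction = np.where(es_obs >= 0, "up", "down")
    table = pd.DataFrame(
        {
            "size": sizes,
            "es": es_obs,
            "nes": nes,
            "p": p_perm,
            "q": q,
            "direction": direction,
            "enriched": enriched,
            "unstable": unstable,
        },
        index=pd.Index(names, name="set"),
    )
    return GseaResult(table, n_perm, config.gsea_exponent, config.seed,
                      tuple(sorted(collection.sets)))


def _fdr_ratio_of_tails(nes: np.ndarray, pooled_null: np.ndarray) -> np.ndarray:
    """GSEA ratio-of-tails FDR on the pooled normalized null, clipped to [0,1]."""
    q = np.full_like(nes, np.nan, dtype=float)
    finite = np.isfinite(nes)
    pos_null = pooled_null[pooled_null >= 0]
    neg_null = pooled_null[pooled_null < 0]
    obs_pos = nes[finite & (nes >= 0)]
    obs_neg = nes[finite & (nes < 0)]
    for i, v in enumerate(nes):
        if not np.isfinite(v):
            continue
        if v >= 0:
            num = np.mean(pos_null >= v) if len(pos_null) else 0.0
            den = np.mean(obs_pos >= v) if len(obs_pos) else 1.0
        else:
            num = np.mean(neg_null <= v) if len(neg_null) else 0.0
            den = np.mean(obs_neg <= v) if len(obs_neg) else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


# ---------------------------------------------------------------------------
# run comparison (e.g. two cell lines)
# ---------------------------------------------------------------------------

def compare_runs(result_a: GseaResult, result_b: GseaResult) -> dict:
    """Overlap of enriched sets between two runs of the same collection.

    Returns sets enriched only in a / only in b / in both, split by
    direction, plus the Jaccard index of the enriched sets (defined as 1.0
    when both runs call nothing enriched).
    """
    if result_a.collection_names != result_b.collection_names:
        raise ValidationError("results come from different gene-set collections")
    ea, eb = result_a.enriched_sets(), result_b.enriched_sets()
    sa, sb = set(ea), set(eb)
    union = sa | sb
    jaccard = 1.0 if not union else len(sa & sb) / len(union)

    def _split(names: set[str], dirs: dict[str, str]) -> dict[str, list[str]]:
        return {
            "up": sorted(n for n in names if dirs.get(n) == "up"),
            "down": sorted(n for n in names if dirs.get(n) == "down"),
        }

    both = sa & sb
    return {
        "a_only": _split(sa - sb, ea),
        "b_only": _split(sb - sa, eb),
        "both": _split(both, ea),
        "both_discordant": sorted(n for n in both if ea[n] != eb[n]),
        "jaccard": jaccard,
    }
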