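"""End-to-end pipeline: DE → preranked GSEA → connectivity → integration.

``run_pipeline`` chains the four stages in order, writes one TSV per stage
plus a single JSON report, and is byte-deterministic: the same seed and
inputs always produce identical report bytes. Any stage failure is
re-raised as :class:`~gseacmap.errors.StageError` with the stage name
attached.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .connectivity import (connectivity_scores, extract_hit_signatures,
                           make_query, select_hits)
from .containers import CountMatrix, GeneSetCollection, SignatureReference
from .de import run_de
from .errors import PipelineError, StageError
from .gsea import permutation_stats, rank_genes
from .integrate import (IntegrationReport, class_pathways, direction_annotate,
                        overlap_pathways)

logger = logging.getLogger(__name__)


def _stage(name: str):
    """Context manager attributing errors and logging wall time per stage."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.2fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            if isinstance(exc, (PipelineError, ValueError)):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, counts: CountMatrix,
                 genesets: GeneSetCollection, reference: SignatureReference,
                 out_dir: str | Path | None = None,
                 enrichment_method: str = "gsea") -> IntegrationReport:
    """Execute all stages and return the annotated integration report.

    When ``out_dir`` is given, writes per-stage TSVs (``de_table.tsv``,
    ``gsea_extract.tsv``, ``connectivity_instances.tsv``,
    ``connectivity_compounds.tsv``, ``venn_membership.tsv``) and the JSON
    report (``integration_report.json``, ``hits.json``).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("deg"):
        de = run_de(counts, config)
        if out is not None:
            io.write_de_table(de, out / "de_table.tsv")

    with _stage("gsea"):
        ranked = rank_genes(de)
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
        extract_gsea = permutation_stats(ranked, genesets, config, rng=rng)
        if out is not None:
            io.write_table(extract_gsea.table, out / "gsea_extract.tsv", index_label="set")

    with _stage("connectivity"):
        if reference.n_instances == 0:
            raise StageError("connectivity", "empty reference")
        query = make_query(de, config)
        conn = connectivity_scores(reference, query)
        hits = select_hits(conn, config)
        if out is not None:
            io.write_table(conn.instances, out / "connectivity_instances.tsv")
            io.write_table(conn.compounds, out / "connectivity_compounds.tsv")
            io.write_json_report(hits.to_dict(), out / "hits.json")

    with _stage("integration"):
        if len(hits.hits) == 0:
            report = IntegrationReport(
                extract_pathways=extract_gsea.enriched_sets(),
                class_sets=[], venn_membership={}, region_counts={},
                predicted=[], config=config.to_dict(), seed=config.seed,
                notices=["no connectivity hits inside the score window"],
            )
        else:
            signatures = extract_hit_signatures(reference, hits, n_sig=config.n_sig)
            rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
            classes = class_pathways(signatures, genesets, config,
                                     method=enrichment_method, rng=rng)
            report = overlap_pathways(extract_gsea, classes, config)
            report = direction_annotate(report, extract_gsea)
        if out is not None:
            io.write_json_report(report.to_dict(), out / "integration_report.json")
            _write_venn_tsv(report, out / "venn_membership.tsv")

    return report


def _write_venn_tsv(report: IntegrationReport, path: Path) -> None:
    groups = ["extract"] + [cs.moa_class for cs in report.class_sets]
    rows = []
    for pathway, member_of in sorted(report.venn_membership.items()):
        row = {"pathway": pathway}
        for g in groups:
            row[g] = int(g in member_of)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["pathway"] + groups)
    io.write_table(df, path)
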