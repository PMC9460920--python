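"""Synthetic data with planted truth for every pipeline stage.

Three coupled generators emulate the study design end to end without any
external download:

* :func:`generate_experiment` — negative-binomial counts for a treated vs.
  control two-arm design (the cell-culture extract-treatment setting), with
  log-normal gene base means, per-sample library-size factors, and planted
  log2 fold changes on a chosen fraction of genes (half up, half down).
* :func:`generate_genesets` — a hallmark-like collection of named gene sets
  in which designated "affected" sets carry the planted DE genes.
* :func:`generate_reference` — a compound-signature reference whose
  instances are z-score vectors built from per-class planted gene-set
  programs plus Gaussian noise; one designated *matched* class additionally
  receives the experiment's planted DE direction, so connectivity
  self-recovery is testable.

All three derive the same planted truth deterministically from the seed in
:class:`SimConfig`, so they can be called independently and still agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, SignatureReference
from .de import bh_adjust
from .errors import ValidationError


@dataclass
class SimConfig:
    """Study conditions for the synthetic scenario.

    Counts: ``n_genes`` genes, ``n_reps`` replicates per arm, negative
    binomial with variance ``mu + dispersion * mu^2`` (dispersion constant
    across genes), base means log-normal on the natural-log scale, library
    factors uniform in [0.5, 2]. Effects: ``fraction_de`` of genes get
    ``±effect_logfc`` (half up, half down). Gene sets: ``n_sets`` sets with
    sizes in ``[set_size_min, set_size_max]``; ``n_affected_sets`` carry the
    DE genes, of which ``n_shared_programs`` are also planted in every
    compound class. Reference: ``n_compounds`` assigned round-robin to
    ``n_classes`` classes, ``instances_per_compound`` instances each;
    planted set members get ``±signature_effect`` z-units plus
    ``N(0, signature_noise_sd)`` noise.
    """

    n_genes: int = 2000
    n_reps: int = 3
    nb_dispersion: float = 0.1
    base_mean_log_mu: float = 5.0
    base_mean_log_sigma: float = 1.0
    n_sets: int = 50
    set_size_min: int = 15
    set_size_max: int = 200
    effect_logfc: float = 2.0
    fraction_de: float = 0.05
    n_affected_sets: int = 4
    n_shared_programs: int = 1
    programs_per_class: int = 2
    n_compounds: int = 15
    instances_per_compound: int = 2
    n_classes: int = 3
    signature_effect: float = 3.0
    signature_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_reps", "n_sets", "n_compounds",
                     "instances_per_compound", "n_classes", "programs_per_class"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not (0.0 <= self.fraction_de < 1.0):
            raise ValidationError("fraction_de must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not (1 <= self.set_size_min <= self.set_size_max <= self.n_genes):
            raise ValidationError("need 1 <= set_size_min <= set_size_max <= n_genes")
        if self.n_classes > self.n_compounds:
            raise ValidationError("more classes than compounds")
        if self.n_shared_programs > self.n_affected_sets:
            raise ValidationError("shared programs must be among the affected sets")
        if self.n_affected_sets + self.n_classes * self.programs_per_class > self.n_sets:
            raise ValidationError("not enough gene sets for the requested programs")
        if self.signature_noise_sd < 0:
            raise ValidationError("signature_noise_sd must be >= 0")

    @property
    def n_de(self) -> int:
        return int(round(self.fraction_de * self.n_genes))


@dataclass
class SimTruth:
    """Planted ground truth shared by the three generators."""

    de_genes: dict[str, float]                 # gene -> planted log2FC
    affected_sets: dict[str, float]            # set name -> mean planted |log2FC|
    class_programs: dict[str, dict[str, int]]  # class -> {set name: sign}
    shared_programs: list[str]                 # sets planted in extract AND all classes
    matched_class: str
    set_de_assignment: dict[str, list[str]]    # affected set -> its DE genes
    null_flag: bool = False


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _set_names(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _class_names(n: int) -> list[str]:
    return [f"class{i + 1:02d}" for i in range(n)]


def _plan_truth(config: SimConfig) -> SimTruth:
    """Derive the planted truth deterministically from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    genes = _gene_ids(config.n_genes)
    set_names = _set_names(config.n_sets)
    classes = _class_names(config.n_classes)

    if config.fraction_de > 0 and config.n_de < 1:
        raise ValidationError("fraction_de * n_genes < 1: no DE gene can be planted")

    null_flag = config.n_de == 0
    de_genes: dict[str, float] = {}
    affected: dict[str, float] = {}
    assignment: dict[str, list[str]] = {}
    shared: list[str] = []
    used_sets: list[str] = []

    if not null_flag:
        chosen = rng.choice(config.n_genes, size=config.n_de, replace=False)
        n_up = math.ceil(config.n_de / 2)
        for k, gi in enumerate(chosen):
            de_genes[genes[gi]] = config.effect_logfc if k < n_up else -config.effect_logfc
        up_genes = [genes[gi] for gi in chosen[:n_up]]
        down_genes = [genes[gi] for gi in chosen[n_up:]]

        n_aff = min(config.n_affected_sets, config.n_de)
        n_aff_up = max(1, math.ceil(n_aff / 2))
        n_aff_down = max(1, n_aff - n_aff_up) if down_genes else 0
        aff_names = [str(s) for s in
                     rng.choice(set_names, size=n_aff_up + n_aff_down, replace=False)]
        used_sets = list(aff_names)
        up_sets = aff_names[:n_aff_up]
        down_sets = aff_names[n_aff_up:]
        for i, g in enumerate(up_genes):
            assignment.setdefault(up_sets[i % len(up_sets)], []).append(g)
        for i, g in enumerate(down_genes):
            if down_sets:
                assignment.setdefault(down_sets[i % len(down_sets)], []).append(g)
        for name, members in assignment.items():
            affected[name] = float(np.mean([abs(de_genes[g]) for g in members]))
        shared = up_sets[: config.n_shared_programs]

    # exclusive per-class programs come from sets carrying no planted DE signal
    free = [s for s in set_names if s not in used_sets]
    class_programs: dict[str, dict[str, int]] = {}
    for c in classes:
        programs: dict[str, int] = {s: 1 for s in shared}
        n_excl = config.programs_per_class
        picked = [free.pop(0) for _ in range(min(n_excl, len(free)))]
        for k, s in enumerate(picked):
            programs[s] = 1 if (k + rng.integers(0, 2)) % 2 == 0 else -1
        class_programs[c] = programs

    return SimTruth(de_genes, affected, class_programs, shared, classes[0],
                    assignment, null_flag)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_experiment(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial treated/control counts with planted fold changes."""
    truth = _plan_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    genes = _gene_ids(config.n_genes)
    samples = [f"ctrl{i + 1}" for i in range(config.n_reps)] + \
              [f"trt{i + 1}" for i in range(config.n_reps)]
    conditions = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}

    base = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma,
                         size=config.n_genes)
    lib_factor = rng.uniform(0.5, 2.0, size=len(samples))
    fc = np.ones(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, lfc in truth.de_genes.items():
        fc[gene_pos[g]] = 2.0 ** lfc

    mu = base[:, None] * lib_factor[None, :]
    mu[:, config.n_reps:] *= fc[:, None]  # planted effects in treated arm only

    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    # an all-zero sample column is astronomically unlikely at these means,
    # but the downstream invariant requires it never happens
    while np.any(counts.sum(axis=0) == 0):  # pragma: no cover
        counts = rng.negative_binomial(r, p)
    return CountMatrix(genes, samples, conditions, counts), truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_genesets(config: SimConfig) -> GeneSetCollection:
    """Hallmark-like synthetic collection; affected sets contain their DE genes.

    Null (unaffected) sets are drawn uniformly from the genes carrying no
    planted effect, so they stay signal-free by construction; overlap among
    sets is allowed.
    """
    truth = _plan_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 303]))
    genes = _gene_ids(config.n_genes)
    non_de = [g for g in genes if g not in truth.de_genes]
    if config.set_size_max > len(genes):
        raise ValidationError("set size exceeds gene universe")

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for name in _set_names(config.n_sets):
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        planted = truth.set_de_assignment.get(name, [])
        size = max(size, len(planted))
        # fill only from signal-free genes; cap at the available pool
        n_fill = min(size - len(planted), len(non_de))
        fill = rng.choice(len(non_de), size=n_fill, replace=False)
        members = frozenset(planted) | frozenset(non_de[i] for i in fill)
        sets[name] = members
        descriptions[name] = "synthetic_planted" if planted else "synthetic_null"
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# compound-signature reference
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig,
                       genesets: GeneSetCollection) -> tuple[SignatureReference, SimTruth]:
    """Reference instances = class planted programs + noise (z-score scale).

    Compounds are assigned round-robin to classes; every instance of a
    class receives ``sign * signature_effect`` on the members of each of
    the class's program sets. Instances of the *matched* class additionally
    receive the experiment's planted DE direction. Gaussian noise with
    ``signature_noise_sd`` is added everywhere.
    """
    truth = _plan_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 404]))
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    classes = _class_names(config.n_classes)

    for c, programs in truth.class_programs.items():
        for s in programs:
            if s not in genesets.sets:
                raise ValidationError(f"class program {s!r} missing from collection")

    compounds = [f"CPD{i + 1:03d}" for i in range(config.n_compounds)]
    compound_class = {cpd: classes[i % config.n_classes] for i, cpd in enumerate(compounds)}

    instances: list[str] = []
    meta_rows: list[dict] = []
    columns: list[np.ndarray] = []
    for ci, cpd in enumerate(compounds):
        cls = compound_class[cpd]
        base = np.zeros(config.n_genes)
        for s, sign in truth.class_programs[cls].items():
            idx = [gene_pos[g] for g in genesets.sets[s]]
            base[idx] += sign * config.signature_effect
        if cls == truth.matched_class and not truth.null_flag:
            for g, lfc in truth.de_genes.items():
                base[gene_pos[g]] += config.signature_effect * (1 if lfc > 0 else -1)
        for k in range(config.instances_per_compound):
            inst = f"{cpd}_r{k + 1}"
            noise = rng.normal(0.0, config.signature_noise_sd, size=config.n_genes) \
                if config.signature_noise_sd > 0 else 0.0
            columns.append(base + noise)
            instances.append(inst)
            meta_rows.append({
                "instance_id": inst,
                "compound": cpd,
                "moa_class": cls,
                "cell_line": "CL1" if k % 2 == 0 else "CL2",
            })

    values = np.column_stack(columns)
    meta = pd.DataFrame(meta_rows).set_index("instance_id")
    return SignatureReference(genes, instances, values, meta), truth


def generate_scenario(config: SimConfig):
    """Convenience: (counts, gene sets, reference, truth) from one config."""
    counts, truth = generate_experiment(config)
    genesets = generate_genesets(config)
    reference, _ = generate_reference(config, genesets)
    return counts, genesets, reference, truth


# ---------------------------------------------------------------------------
# synthetic stand-in for the published supplementary DEG table
# ---------------------------------------------------------------------------

def synthetic_supplement_degs(n_up: int = 601, n_down: int = 730,
                              n_ns: int = 11000, seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a published supplementary expression table.

    The real supplementary table is not redistributable, so this generator
    emulates its reported composition: ``n_up`` genes with log2FC > 1 at
    small p, ``n_down`` with log2FC < −1, and ``n_ns`` non-significant
    genes, including genes that fail only one of the two filters (large
    fold change at large p; tiny p at sub-threshold fold change). BH
    q-values are computed over the whole table, so applying the standard
    filter (|log2FC| > 1 and q < 0.05) recovers exactly the planted split
    for any seed.

    Returns a DataFrame with columns gene, logFC, avg_expr, t, p, fdr.
    """
    rng = np.random.default_rng(seed)
    total = n_up + n_down + n_ns
    genes = [f"GENE{i + 1:05d}" for i in range(total)]

    logfc = np.empty(total)
    p = np.empty(total)
    logfc[:n_up] = rng.uniform(1.05, 6.0, n_up)
    logfc[n_up:n_up + n_down] = rng.uniform(-6.0, -1.05, n_down)
    p[:n_up + n_down] = 10.0 ** rng.uniform(-20.0, -6.0, n_up + n_down)

    # non-significant block: mostly flat genes, plus the two one-filter-only
    # failure modes a real table contains
    ns = slice(n_up + n_down, total)
    n_bigfc = n_ns // 10        # large fold change, not significant
    n_smallp = n_ns // 20       # significant p, sub-threshold fold change
    n_flat = n_ns - n_bigfc - n_smallp
    logfc_ns = np.concatenate([
        rng.uniform(0.0, 0.95, n_flat) * rng.choice([-1, 1], n_flat),
        rng.uniform(1.05, 3.0, n_bigfc) * rng.choice([-1, 1], n_bigfc),
        rng.uniform(0.0, 0.95, n_smallp) * rng.choice([-1, 1], n_smallp),
    ])
    p_ns = np.concatenate([
        rng.uniform(0.05, 1.0, n_flat),
        rng.uniform(0.3, 1.0, n_bigfc),
        10.0 ** rng.uniform(-12.0, -7.0, n_smallp),
    ])
    logfc[ns] = logfc_ns
    p[ns] = p_ns

    fdr = bh_adjust(p)
    avg = rng.lognormal(3.0, 1.0, total)
    t = np.sign(logfc) * -np.log10(np.maximum(p, 1e-300))
    df = pd.DataFrame({
        "gene": genes,
        "logFC": logfc,
        "avg_expr": avg,
        "s2": rng.lognormal(-2.0, 0.5, total),
        "t": t,
        "df_total": np.full(total, 6.0),
        "p": p,
        "fdr": fdr,
    })
    return df
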