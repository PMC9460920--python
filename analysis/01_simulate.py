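#!/usr/bin/env python
"""Generate the study's synthetic inputs and write them to disk.

Produces a treated-vs-control count matrix with planted fold changes, a
hallmark-like gene-set collection carrying those genes, and a compound-
signature reference in which one mechanism class matches the planted
perturbation. Full-size data files go to scratch/data/ (regenerable from
the seed); a small summary of the planted truth goes to results/.
"""

from pathlib import Path

from gseacmap import SimConfig, generate_scenario, io

SEED = 1

def main() -> None:
    sim = SimConfig(seed=SEED)
    counts, genesets, reference, truth = generate_scenario(sim)

    data = Path("scratch/data")
    data.mkdir(parents=True, exist_ok=True)
    io.write_counts(counts, data / "counts.tsv")
    io.write_conditions(counts.conditions, data / "conditions.tsv")
    io.write_gmt(genesets, data / "genesets.gmt")
    io.write_reference(reference, data / "reference.gct", data / "reference_meta.tsv")

    out = Path("results")
    out.mkdir(exist_ok=True)
    io.write_json_report(
        {
            "seed": SEED,
            "n_genes": sim.n_genes,
            "n_de_planted": len(truth.de_genes),
            "affected_sets": truth.affected_sets,
            "shared_programs": truth.shared_programs,
            "class_programs": truth.class_programs,
            "matched_class": truth.matched_class,
        },
        out / "sim_truth_summary.json",
    )
    print(f"scenario (seed {SEED}): {counts.counts.shape[0]} genes x "
          f"{counts.counts.shape[1]} samples, {len(genesets.sets)} gene sets, "
          f"{reference.n_instances} reference instances")
    print(f"planted: {len(truth.de_genes)} DE genes in sets "
          f"{sorted(truth.affected_sets)}; shared program {truth.shared_programs} "
          f"matched to class {truth.matched_class!r}")
    print("wrote scratch/data/{counts,conditions,genesets,reference*} and "
          "results/sim_truth_summary.json")


if __name__ == "__main__":
    main()
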