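#!/usr/bin/env python
"""Simulate the default multi-omics cohort and write it to results/data/.

2000 genes across three ESC states (2iL reference, SL, EPI) plus the two
single-inhibitor withdrawal cultures (CHL, PDL): RNA-seq and footprint
counts (2 replicates), a censored protein layer (3 replicates), transcript
sequences with planted AU-rich elements, and 50k footprint alignments.
"""

from pathlib import Path

from ribobuffer import io, synthdata as sd

SEED = 1
N_GENES = 2000
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = sd.generate_gene_specs(N_GENES, seed=SEED)
    sim = sd.SimulationConfig(n_genes=N_GENES, seed=SEED)
    design = sd.ExperimentDesign(conditions=("2iL", "SL", "EPI", "CHL", "PDL"))
    rna, rfp = sd.simulate_counts(specs, design, sim)
    wclasses = sd.assign_withdrawal_classes(specs, seed=SEED)
    proteins = sd.simulate_proteins(specs, design, sim, withdrawal_classes=wclasses)
    transcripts = sd.simulate_transcripts(specs, seed=SEED)
    weights = {s.gene_id: float(2.0**s.base_log2_cpm) for s in specs}
    footprints = sd.simulate_footprints(transcripts, weights, 50_000, seed=SEED)

    io.write_counts(rna, OUT / "rna_counts.tsv", OUT / "rna_meta.tsv")
    io.write_counts(rfp, OUT / "rfp_counts.tsv", OUT / "rfp_meta.tsv")
    io.write_proteins(
        proteins, OUT / "protein_log2.tsv", OUT / "protein_meta.tsv",
        OUT / "protein_map.tsv",
    )
    io.write_transcripts_fasta(transcripts, OUT / "transcripts.fasta")
    io.write_footprints(footprints, OUT / "footprints.tsv")
    io.write_gene_specs(specs, OUT / "ground_truth.tsv")
    with open(OUT / "withdrawal_classes.tsv", "w") as fh:
        fh.write("gene_id\tclass\n")
        for gene, cls in sorted(wclasses.items()):
            fh.write(f"{gene}\t{cls}\n")

    n_modes = {m: sum(s.mode == m for s in specs) for m in sd.MODES}
    print(f"wrote cohort to {OUT}")
    print(f"planted modes: {n_modes}")
    print(f"protein groups mapping to 2 genes: "
          f"{sum(len(g) == 2 for g in proteins.gene_map.values())}")


if __name__ == "__main__":
    main()
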