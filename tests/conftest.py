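"""Shared fixtures: a small toy cohort and the default 2000-gene cohort with
its full downstream analysis, computed once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from ribobuffer import diffte, integrate, proteo, synthdata as sd


@pytest.fixture(scope="session")
def toy_specs():
    return sd.generate_gene_specs(60, seed=3)


@pytest.fixture(scope="session")
def toy_transcripts(toy_specs):
    return sd.simulate_transcripts(toy_specs, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 2000-gene synthetic cohort plus its SL-vs-2iL analysis."""
    seed = 1
    specs = sd.generate_gene_specs(2000, seed=seed)
    sim = sd.SimulationConfig(n_genes=2000, seed=seed)
    design = sd.ExperimentDesign()
    rna, rfp = sd.simulate_counts(specs, design, sim)
    proteins = sd.simulate_proteins(specs, design, sim)
    te = diffte.differential_te(rna, rfp, "2iL", "SL")
    filtered = proteo.filter_reproducible(proteins)
    imputed = proteo.impute_missing(filtered, proteo.ImputationConfig(seed=seed))
    prot = proteo.differential_protein(imputed, "2iL", "SL")
    triplets = integrate.assemble_triplets(
        te["log2fc_rna"], te["log2fc_rfp"], prot["log2fc"], proteins.gene_map
    )
    by_mode: dict[str, set] = {}
    for s in specs:
        by_mode.setdefault(s.mode, set()).add(s.gene_id)
    return {
        "seed": seed,
        "specs": specs,
        "by_mode": by_mode,
        "design": design,
        "sim": sim,
        "rna": rna,
        "rfp": rfp,
        "proteins": proteins,
        "te": te,
        "imputed": imputed,
        "prot": prot,
        "triplets": triplets,
    }
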