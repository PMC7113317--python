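"""End-to-end orchestration: simulate -> QC -> differential TE -> proteomics
-> integration -> enrichment, from one config, into one output bundle.

Every stage writes its table under the output directory with a config-hash
comment line; ``summary.json`` aggregates category counts and percentages
(the synthetic analogue of a three-state study's headline decomposition).
All randomness flows from ``config.seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffte, integrate, io, proteo, riboqc, seqfeat, setstats, synthdata

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Thresholds", "load_config", "run_pipeline"]


@dataclass(frozen=True)
class Thresholds:
    te_fdr: float = 0.1
    te_fc: float = 1.5
    prot_fdr: float = 0.05
    prot_fc: float = 3.0
    rna_fc: float = 2.0
    rfp_fc: float = 2.0
    buffer_prot_fc: float = 2.0
    withdrawal_fc: float = 2.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    n_genes: int = 2000
    conditions: tuple[str, ...] = ("2iL", "SL", "EPI")
    include_withdrawal: bool = True
    n_footprints: int = 50_000
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    dispersion: float = 0.02
    protein_sigma: float = 0.25
    censor_quantile: float = 0.10

    @property
    def reference(self) -> str:
        return self.conditions[0]


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON (keys mirror the dataclass)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    thr = Thresholds(**data.pop("thresholds", {}))
    if "conditions" in data:
        data["conditions"] = tuple(data["conditions"])
    try:
        return PipelineConfig(thresholds=thr, **data)
    except TypeError as exc:
        raise ValueError(f"bad config section: {exc}") from exc


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a synthetic cohort and write the report bundle.

    Returns the summary dictionary that is also written to ``summary.json``.
    """
    t0 = time.perf_counter()
    out = io.ensure_dir(outdir)
    cfg_hash = _config_hash(config)
    thr = config.thresholds
    ref = config.reference
    alts = [c for c in config.conditions[1:]]
    if len(alts) < 2:
        raise ValueError("need a reference plus >= 2 alternative conditions")

    def stage(name: str) -> None:
        logger.info("stage %-12s %.1fs", name, time.perf_counter() - t0)

    # --- simulate -----------------------------------------------------
    specs = synthdata.generate_gene_specs(config.n_genes, seed=config.seed)
    sim = synthdata.SimulationConfig(
        n_genes=config.n_genes,
        dispersion=config.dispersion,
        protein_sigma=config.protein_sigma,
        censor_quantile=config.censor_quantile,
        seed=config.seed,
    )
    conditions = tuple(config.conditions) + (
        ("CHL", "PDL") if config.include_withdrawal else ()
    )
    design = synthdata.ExperimentDesign(conditions=conditions)
    rna, rfp = synthdata.simulate_counts(specs, design, sim)
    wclasses = (
        synthdata.assign_withdrawal_classes(specs, seed=config.seed)
        if config.include_withdrawal
        else {}
    )
    proteins = synthdata.simulate_proteins(
        specs, design, sim, withdrawal_classes=wclasses
    )
    transcripts = synthdata.simulate_transcripts(specs, seed=config.seed)
    weights = {s.gene_id: float(2.0**s.base_log2_cpm) for s in specs}
    footprints = synthdata.simulate_footprints(
        transcripts, weights, config.n_footprints, seed=config.seed
    )
    io.write_gene_specs(specs, out / "ground_truth.tsv")
    stage("simulate")

    # --- ribosome-profiling QC ---------------------------------------
    hist = riboqc.estimate_psite_offset(footprints, transcripts)
    _write_tsv(
        pd.DataFrame(
            sorted(hist.offsets.items()), columns=["offset", "count"]
        ).set_index("offset"),
        out / "psite_offsets.tsv",
        cfg_hash,
    )
    profiles = riboqc.metagene_profile(footprints, transcripts)
    meta_rows = [
        {"region": p.region, "bin_index": i, "mean_coverage": v}
        for p in profiles
        for i, v in enumerate(p.values)
    ]
    _write_tsv(pd.DataFrame(meta_rows), out / "metagene.tsv", cfg_hash, index=False)
    cds_counts = riboqc.count_cds_reads(footprints, transcripts)
    mean_cov = {p.region: float(np.mean(p.values)) if p.values.size else 0.0 for p in profiles}
    qc_summary = {
        "modal_offsets": hist.modes,
        "n_reads_in_window": hist.total,
        "cds_assigned_reads": int(sum(cds_counts.values())),
        "mean_bin_coverage": mean_cov,
    }
    stage("riboqc")

    # --- differential TE ----------------------------------------------
    te_cfg = diffte.DiffTEConfig(fdr_max=thr.te_fdr, fc_min=thr.te_fc)
    te_results = {
        alt: diffte.differential_te(rna, rfp, ref, alt, te_cfg) for alt in alts[:2]
    }
    for alt, res in te_results.items():
        _write_tsv(res, out / f"te_{alt}_vs_{ref}.tsv", cfg_hash)
    sets = diffte.partition_te_sets(
        te_results[alts[0]], te_results[alts[1]], labels=(alts[0], alts[1])
    )
    if len(sets["table"]):
        _write_tsv(sets["table"], out / "te_sets.tsv", cfg_hash)
    te_summary = {
        "n_tested": {alt: int(len(res)) for alt, res in te_results.items()},
        "n_called": {alt: int(res["called"].sum()) for alt, res in te_results.items()},
        f"{alts[0]}_only": len(sets[f"{alts[0]}_only"]),
        f"{alts[1]}_only": len(sets[f"{alts[1]}_only"]),
        "common": len(sets["common"]),
    }
    stage("diffte")

    # --- proteomics ----------------------------------------------------
    filtered = proteo.filter_reproducible(proteins)
    imputed = proteo.impute_missing(
        filtered, proteo.ImputationConfig(seed=config.seed)
    )
    prot_results = {
        alt: proteo.differential_protein(
            imputed, ref, alt, fc_min=thr.prot_fc, fdr_max=thr.prot_fdr
        )
        for alt in alts[:2]
    }
    for alt, res in prot_results.items():
        _write_tsv(res, out / f"protein_{alt}_vs_{ref}.tsv", cfg_hash)
    detection = proteo.detection_matrix(filtered, list(config.conditions))
    patterns = proteo.state_exclusive_proteins(detection)
    full = tuple(sorted(config.conditions))
    exclusive = {
        "+".join(pat): len(prots) for pat, prots in sorted(patterns.items()) if pat != full
    }
    prot_summary = {
        "n_quantified": int(len(filtered.intensities)),
        "n_called": {alt: int(res["called"].sum()) for alt, res in prot_results.items()},
        "n_state_exclusive": int(sum(exclusive.values())),
        "exclusive_patterns": exclusive,
    }
    stage("proteo")

    # --- integration ----------------------------------------------------
    triplets = {}
    mode_calls = {}
    buffered = {}
    for alt in alts[:2]:
        res = te_results[alt]
        trip = integrate.assemble_triplets(
            res["log2fc_rna"],
            res["log2fc_rfp"],
            prot_results[alt]["log2fc"],
            proteins.gene_map,
        )
        triplets[alt] = trip
        called_pgs = prot_results[alt].index[prot_results[alt]["called"]]
        called_genes = {
            proteins.gene_map[pg][0]
            for pg in called_pgs
            if len(proteins.gene_map[pg]) == 1
        }
        mode_calls[alt] = integrate.classify_regulatory_mode(
            trip,
            called_genes,
            {"protein_fc": thr.prot_fc, "rna_fc": thr.rna_fc, "rfp_fc": thr.rfp_fc},
        )
        buffered[alt] = integrate.detect_buffering(res, trip, thr.buffer_prot_fc)
        _write_tsv(trip, out / f"triplets_{alt}_vs_{ref}.tsv", cfg_hash)
        if len(mode_calls[alt]):
            _write_tsv(mode_calls[alt], out / f"modes_{alt}_vs_{ref}.tsv", cfg_hash)
    all_modes = pd.concat([m for m in mode_calls.values() if len(m)])
    mode_counts = all_modes["mode"].value_counts().to_dict() if len(all_modes) else {}
    total_modes = max(1, sum(mode_counts.values()))
    corr = integrate.layer_correlations(triplets[alts[0]])
    _write_tsv(corr, out / "layer_correlations.tsv", cfg_hash)
    buffered_union = sorted(set().union(*buffered.values()))
    _write_tsv(
        pd.DataFrame({"gene_id": buffered_union}),
        out / "buffered_genes.tsv",
        cfg_hash,
        index=False,
    )
    integration_summary = {
        "n_triplets": {alt: int(len(t)) for alt, t in triplets.items()},
        "mode_counts": {k: int(v) for k, v in sorted(mode_counts.items())},
        "mode_percent": {
            k: round(100.0 * v / total_modes, 1) for k, v in sorted(mode_counts.items())
        },
        "n_buffered": {alt: len(b) for alt, b in buffered.items()},
        "n_buffered_union": len(buffered_union),
    }
    stage("integrate")

    # --- inhibitor withdrawal ------------------------------------------
    if config.include_withdrawal:
        withdrawal_tables = {
            culture: proteo.differential_protein(
                imputed, ref, culture, fc_min=thr.withdrawal_fc, fdr_max=thr.prot_fdr
            )
            for culture in ("CHL", "PDL")
        }
        called_union = sorted(
            set(prot_results[alts[0]].index[prot_results[alts[0]]["called"]])
            | set(prot_results[alts[1]].index[prot_results[alts[1]]["called"]])
        )
        ref_fc = prot_results[alts[0]]["log2fc"].reindex(called_union)
        fallback = prot_results[alts[1]]["log2fc"].reindex(called_union)
        ref_fc = ref_fc.fillna(fallback)
        classes = integrate.classify_inhibitor_dependency(
            ref_fc,
            withdrawal_tables["CHL"],
            withdrawal_tables["PDL"],
            fc_min=thr.withdrawal_fc,
            fdr_max=thr.prot_fdr,
        )
        _write_tsv(classes, out / "inhibitor_classes.tsv", cfg_hash)
        class_counts = classes["class"].value_counts().to_dict()
        withdrawal_summary = {
            "n_classified": int(len(classes)),
            "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
        }
    else:
        withdrawal_summary = {"n_classified": 0, "class_counts": {}}
    stage("withdrawal")

    # --- UTR features / ARE enrichment ---------------------------------
    composition = seqfeat.sequence_composition(transcripts)
    _write_tsv(composition, out / "utr_composition.tsv", cfg_hash, index=False)
    utr3 = {t.gene_id: t.utr3 for t in transcripts}
    are_counts = seqfeat.scan_exact_motif(utr3)
    hit_genes = {g for g, n in are_counts.items() if n > 0}
    primary = te_results[alts[0]]
    background = set(primary.index)
    query = set(
        primary.index[(primary["called"]) & (primary["direction"] == "higher_in_ref")]
    )
    if query:
        are_enr = seqfeat.motif_presence_enrichment(hit_genes, query, background)
        are_summary = {
            "n_query": are_enr.n,
            "query_hit_fraction": round(are_enr.k / max(1, are_enr.n), 3),
            "background_hit_fraction": round(are_enr.K / are_enr.N, 3),
            "p": are_enr.p,
        }
    else:
        are_summary = {"n_query": 0}
    stage("seqfeat")

    # --- planted-set enrichment (synthetic term sets) -------------------
    universe = set(triplets[alts[0]].index)
    by_mode: dict[str, set] = {}
    for s in specs:
        by_mode.setdefault(f"planted_{s.mode}", set()).add(s.gene_id)
    called_genes_union = set()
    for alt in alts[:2]:
        called_genes_union |= set(mode_calls[alt].index) if len(mode_calls[alt]) else set()
    enr = setstats.gene_set_enrichment(
        called_genes_union & universe, by_mode, universe, min_term_size=6
    )
    _write_tsv(
        pd.DataFrame([vars(r) for r in enr]).set_index("term_id"),
        out / "set_enrichment.tsv",
        cfg_hash,
    )
    enrichment_summary = {
        r.term_id: {"k": r.k, "K": r.K, "p": r.p, "fdr": r.fdr} for r in enr
    }
    stage("enrich")

    summary = {
        "config_hash": cfg_hash,
        "qc": qc_summary,
        "differential_te": te_summary,
        "proteome": prot_summary,
        "integration": integration_summary,
        "inhibitor_withdrawal": withdrawal_summary,
        "are_enrichment": are_summary,
        "set_enrichment": enrichment_summary,
        "correlations": {
            "rna_rfp": float(corr.loc["log2fc_rna", "log2fc_rfp"]),
            "rna_protein": float(corr.loc["log2fc_rna", "log2fc_protein"]),
            "delta_te_protein": float(corr.loc["delta_te", "log2fc_protein"]),
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return summary
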