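"""Cross-layer integration of RNA, ribosome-footprint and protein changes.

Joins per-gene log2 fold changes across the three layers into triplets
(unique gene–protein assignment required), then:

* decomposes differential protein expression into regulatory modes —
  transcriptional (RNA fold change > 2, concordant with protein),
  translational (RFP > 2-fold, RNA < 2-fold, concordant), post-translational
  (RNA and RFP both < 2-fold) — plus an explicit ``unclassified`` bucket;
* detects translational buffering: differential-TE genes whose TE change
  opposes the RNA change while protein stays within 2-fold;
* classifies inhibitor-withdrawal dependency (CP / 2i / P / C) from
  single-inhibitor cultures;
* reports Pearson correlations between layer fold changes.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "assemble_triplets",
    "classify_regulatory_mode",
    "detect_buffering",
    "classify_inhibitor_dependency",
    "layer_correlations",
    "DEFAULT_MODE_THRESHOLDS",
]

DEFAULT_MODE_THRESHOLDS: dict[str, float] = {"protein_fc": 3.0, "rna_fc": 2.0, "rfp_fc": 2.0}


def assemble_triplets(
    rna_fc: Mapping[str, float] | pd.Series,
    rfp_fc: Mapping[str, float] | pd.Series,
    protein_fc: Mapping[str, float] | pd.Series,
    gene_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Join the three layers into one row per uniquely assigned gene.

    ``protein_fc`` is keyed by protein group; ``gene_map`` links groups to
    gene ids.  Groups mapping to more than one gene are dropped (unique
    assignment), as are genes missing from any layer.  Two protein groups
    resolving to the same gene is a duplicate-row error.
    """
    rna = pd.Series(rna_fc, dtype=float)
    rfp = pd.Series(rfp_fc, dtype=float)
    if rna.index.has_duplicates or rfp.index.has_duplicates:
        raise ValueError("duplicate gene rows within a layer")
    prot_by_gene: dict[str, float] = {}
    for pg, fc in pd.Series(protein_fc, dtype=float).items():
        genes = gene_map.get(pg, ())
        if len(genes) != 1:
            continue  # ambiguous protein group: not uniquely assigned
        gene = genes[0]
        if gene in prot_by_gene:
            raise ValueError(f"duplicate gene rows within the protein layer: {gene!r}")
        prot_by_gene[gene] = float(fc)
    genes = sorted(set(rna.index) & set(rfp.index) & set(prot_by_gene))
    df = pd.DataFrame(
        {
            "log2fc_rna": rna.loc[genes],
            "log2fc_rfp": rfp.loc[genes],
            "log2fc_protein": [prot_by_gene[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df = df.dropna()
    df["delta_te"] = df["log2fc_rfp"] - df["log2fc_rna"]
    return df


def classify_regulatory_mode(
    triplets: pd.DataFrame,
    protein_called: Sequence[str] | set[str],
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Attribute each protein-differential gene's change to a regulatory mode.

    With absolute fold changes F = 2^|log2fc|:

    * ``transcriptional``  iff F_rna > rna_fc and sign(rna) == sign(protein)
    * else ``translational`` iff F_rfp > rfp_fc and F_rna < rna_fc and
      sign(rfp) == sign(protein)
    * else ``post_translational`` iff F_rna < rna_fc and F_rfp < rfp_fc
    * else ``unclassified``

    The sign-concordance requirement prevents attributing a protein increase
    to a transcript decrease.  Genes absent from the triplet table are
    skipped with a warning.
    """
    thr = dict(DEFAULT_MODE_THRESHOLDS)
    if thresholds is not None:
        thr.update(thresholds)
    rows = []
    for gene in sorted(set(protein_called)):
        if gene not in triplets.index:
            logger.warning("gene %s is protein-differential but has no triplet row", gene)
            continue
        row = triplets.loc[gene]
        f_rna = 2 ** abs(row["log2fc_rna"])
        f_rfp = 2 ** abs(row["log2fc_rfp"])
        s_rna = np.sign(row["log2fc_rna"])
        s_rfp = np.sign(row["log2fc_rfp"])
        s_prot = np.sign(row["log2fc_protein"])
        if f_rna > thr["rna_fc"] and s_rna == s_prot:
            mode = "transcriptional"
        elif f_rfp > thr["rfp_fc"] and f_rna < thr["rna_fc"] and s_rfp == s_prot:
            mode = "translational"
        elif f_rna < thr["rna_fc"] and f_rfp < thr["rfp_fc"]:
            mode = "post_translational"
        else:
            mode = "unclassified"
        rows.append(
            {
                "gene_id": gene,
                "mode": mode,
                "log2fc_rna": row["log2fc_rna"],
                "log2fc_rfp": row["log2fc_rfp"],
                "log2fc_protein": row["log2fc_protein"],
            }
        )
    out = pd.DataFrame(rows)
    return out.set_index("gene_id") if len(rows) else out


def detect_buffering(
    te_results: pd.DataFrame,
    triplets: pd.DataFrame,
    protein_fc_max: float = 2.0,
) -> set[str]:
    """Translationally buffered genes.

    A gene is buffered iff it is called differentially translated, its
    protein change stays below ``protein_fc_max`` (absolute fold change), and
    its TE change opposes a non-zero RNA change.
    """
    called = set(te_results.index[te_results["called"]])
    buffered = set()
    for gene in called & set(triplets.index):
        row = triplets.loc[gene]
        if 2 ** abs(row["log2fc_protein"]) >= protein_fc_max:
            continue
        if row["log2fc_rna"] == 0:
            continue
        if np.sign(row["delta_te"]) == -np.sign(row["log2fc_rna"]):
            buffered.add(gene)
    return buffered


def classify_inhibitor_dependency(
    reference_fc: Mapping[str, float] | pd.Series,
    chl_table: pd.DataFrame,
    pdl_table: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Classify each differential protein's dependence on the two inhibitors.

    ``reference_fc``: log2 protein fold change SL(or EPI)-vs-2iL for the
    proteins differential between those steady states.  ``chl_table`` /
    ``pdl_table``: per-protein log2fc and fdr for the single-inhibitor
    cultures vs 2iL (CHL = MEK inhibitor PD withdrawn; PDL = GSK3 inhibitor
    CH withdrawn).  A protein *responds* in a culture when the change is
    significant (fdr < fdr_max), exceeds ``fc_min``-fold, and points in the
    steady-state direction.

    Classes: ``P`` responds only when PD is withdrawn; ``C`` only when CH is
    withdrawn; ``2i`` in both; ``CP`` in neither (both inhibitors must go to
    reproduce the SL/EPI pattern).  Proteins missing a withdrawal
    measurement are labeled ``none`` with a warning.
    """
    ref = pd.Series(reference_fc, dtype=float)
    rows = []
    for protein, fc_ref in ref.items():
        responses = {}
        missing = False
        for label, table in (("CHL", chl_table), ("PDL", pdl_table)):
            if protein not in table.index:
                missing = True
                break
            entry = table.loc[protein]
            responses[label] = bool(
                entry["fdr"] < fdr_max
                and 2 ** abs(entry["log2fc"]) > fc_min
                and np.sign(entry["log2fc"]) == np.sign(fc_ref)
            )
        if missing:
            logger.warning("protein %s lacks a withdrawal measurement", protein)
            cls = "none"
        else:
            r_chl, r_pdl = responses["CHL"], responses["PDL"]
            if r_chl and r_pdl:
                cls = "2i"
            elif r_chl:
                cls = "P"
            elif r_pdl:
                cls = "C"
            else:
                cls = "CP"
        rows.append({"protein_id": protein, "class": cls})
    return pd.DataFrame(rows).set_index("protein_id")


_CORR_COLUMNS = ["log2fc_rna", "log2fc_rfp", "log2fc_protein", "delta_te"]


def layer_correlations(triplets: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between the layer fold changes and the TE
    change; zero-variance vectors yield NaN off-diagonal, diagonal is 1."""
    if len(triplets) < 3:
        raise ValueError("need >= 3 genes for correlations")
    sub = triplets[_CORR_COLUMNS].astype(float)
    mat = pd.DataFrame(np.nan, index=_CORR_COLUMNS, columns=_CORR_COLUMNS)
    values = sub.values
    sd = values.std(axis=0)
    for i, a in enumerate(_CORR_COLUMNS):
        for j, b in enumerate(_CORR_COLUMNS):
            if i == j:
                mat.iloc[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                mat.iloc[i, j] = float(np.corrcoef(values[:, i], values[:, j])[0, 1])
    return mat
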