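"""Readers/writers for the package's plain-text interchange formats.

* counts: TSV, first column ``gene_id``, one column per sample; sidecar
  metadata TSV (sample, condition, layer, replicate)
* proteins: TSV of log2 intensities with ``NA`` for missing + sidecar meta
* transcripts: FASTA, header ``>gene_id|u5=<len>|cds=<len>|u3=<len>``,
  RNA alphabet
* footprints: 6-column BED-like TSV (transcript_id, start, end, read_id,
  length, strand), 0-based half-open, sense strand only
* motifs: MEME minimal format (RNA alphabet)
* gene specs: TSV of the planted ground truth (for test harnesses)
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqfeat import MotifPWM
from .synthdata import (
    CountMatrix,
    FootprintAlignment,
    GeneSpec,
    ProteinMatrix,
    TranscriptModel,
)

__all__ = [
    "write_counts",
    "read_counts",
    "write_proteins",
    "read_proteins",
    "write_transcripts_fasta",
    "read_transcripts_fasta",
    "write_footprints",
    "read_footprints",
    "write_gene_specs",
    "read_gene_specs",
    "read_meme",
    "write_meme",
]


# --- counts ---------------------------------------------------------------


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.meta.to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    return CountMatrix(counts, meta)


# --- proteins -------------------------------------------------------------


def write_proteins(pm: ProteinMatrix, matrix_path, meta_path, map_path) -> None:
    pm.intensities.to_csv(matrix_path, sep="\t", na_rep="NA")
    pm.meta.to_csv(meta_path, sep="\t", index=False)
    rows = [(pg, ";".join(genes)) for pg, genes in pm.gene_map.items()]
    pd.DataFrame(rows, columns=["protein_group_id", "gene_ids"]).to_csv(
        map_path, sep="\t", index=False
    )


def read_proteins(matrix_path, meta_path, map_path) -> ProteinMatrix:
    intensities = pd.read_csv(
        matrix_path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True
    )
    meta = pd.read_csv(meta_path, sep="\t")
    gm = pd.read_csv(map_path, sep="\t")
    gene_map = {
        row.protein_group_id: tuple(str(row.gene_ids).split(";"))
        for row in gm.itertuples()
    }
    return ProteinMatrix(intensities, gene_map, meta)


# --- transcripts ----------------------------------------------------------


def write_transcripts_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=f"{t.gene_id}|u5={len(t.utr5)}|cds={len(t.cds)}|u3={len(t.utr3)}",
            description="",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts_fasta(path) -> list[TranscriptModel]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        gene_id = fields[0]
        lens = dict(f.split("=", 1) for f in fields[1:])
        try:
            n5, nc, n3 = int(lens["u5"]), int(lens["cds"]), int(lens["u3"])
        except KeyError as exc:
            raise ValueError(f"FASTA header {rec.id!r} lacks field {exc}") from exc
        seq = str(rec.seq).upper().replace("T", "U")
        if len(seq) != n5 + nc + n3:
            raise ValueError(f"{gene_id}: sequence length does not match header")
        out.append(TranscriptModel(gene_id, seq[:n5], seq[n5 : n5 + nc], seq[n5 + nc :]))
    return out


# --- footprints -----------------------------------------------------------

_FP_COLUMNS = ["transcript_id", "start", "end", "read_id", "length", "strand"]


def write_footprints(reads: Sequence[FootprintAlignment], path) -> None:
    rows = [(r.transcript_id, r.start, r.end, r.read_id, r.length, "+") for r in reads]
    pd.DataFrame(rows, columns=_FP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_footprints(path) -> list[FootprintAlignment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_FP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"footprint TSV missing columns {sorted(missing)}")
    return [
        FootprintAlignment(str(r.read_id), str(r.transcript_id), int(r.start), int(r.length))
        for r in df.itertuples()
    ]


# --- gene specs -----------------------------------------------------------


def write_gene_specs(specs: Sequence[GeneSpec], path) -> None:
    pd.DataFrame([vars(s) for s in specs]).to_csv(path, sep="\t", index=False)


def read_gene_specs(path) -> list[GeneSpec]:
    # keep_default_na=False: the mode "null" is a value, not a missing cell
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False, na_values=[], float_precision="round_trip"
    )
    return [
        GeneSpec(
            gene_id=str(r.gene_id),
            mode=str(r.mode),
            base_log2_cpm=float(r.base_log2_cpm),
            rna_shift=float(r.rna_shift),
            te_shift=float(r.te_shift),
            protein_shift=float(r.protein_shift),
            has_are=str(r.has_are) in ("True", "true", "1"),
        )
        for r in df.itertuples()
    ]


# --- MEME minimal ---------------------------------------------------------


def read_meme(path) -> list[MotifPWM]:
    """Parse MEME minimal format into position-probability matrices.

    Accepts ACGT or ACGU alphabets; matrices are returned over ACGU order.
    """
    motifs: list[MotifPWM] = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append(MotifPWM(name, np.array(rows)))
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif{len(motifs)}"
                rows, expecting = [], 0
            elif line.startswith("letter-probability matrix"):
                expecting = -1  # read numeric rows until a non-numeric line
            elif expecting == -1 and line:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    expecting = 0
                    continue
                if len(vals) != 4:
                    raise ValueError(f"PWM row with {len(vals)} columns in {name}")
                total = sum(vals)
                if not 0.99 < total < 1.01:
                    raise ValueError(f"PWM row sums to {total} in {name}")
                rows.append([v / total for v in vals])  # absorb print rounding
    if name is not None and rows:
        motifs.append(MotifPWM(name, np.array(rows)))
    return motifs


def write_meme(motifs: Sequence[MotifPWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.matrix.shape[0]}\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
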