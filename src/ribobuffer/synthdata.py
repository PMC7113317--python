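"""Synthetic multi-omics generator with planted regulatory ground truth.

Emulates a three-layer (RNA-seq, ribosome footprints, label-free proteome)
experiment over mouse ESC culture states — ground-state 2iL (reference),
serum/LIF (SL) and primed epiblast-like (EPI), optionally with
single-inhibitor withdrawal cultures (CHL = MEK inhibitor withdrawn,
PDL = GSK3 inhibitor withdrawn).

Every gene carries a planted regulatory mode:

``transcriptional``
    RNA shifts; TE constant; protein follows RNA.
``translational``
    RNA constant; TE shifts; protein follows TE.
``buffered``
    RNA and TE shift in opposite directions by the same magnitude; protein
    constant (translational buffering).
``post_translational``
    RNA and TE constant; protein shifts.
``null``
    Nothing shifts.

Counts are negative binomial with var = mu + phi * mu^2; protein
log2 intensities are normal with left-censored, missing-not-at-random
dropout; transcripts have structured 5'UTR/CDS/3'UTR with controllable AU
content and optionally a planted AU-rich element (UAUUUAU); footprints are
placed with a fixed P-site geometry (5' end 12 nt upstream of the decoded
codon) plus an initiation-pause component and a small UTR background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "MODES",
    "WITHDRAWAL_CLASSES",
    "GeneSpec",
    "ExperimentDesign",
    "SimulationConfig",
    "TranscriptModel",
    "UtrConfig",
    "PsiteGeometry",
    "FootprintAlignment",
    "CountMatrix",
    "ProteinMatrix",
    "generate_gene_specs",
    "assign_withdrawal_classes",
    "simulate_counts",
    "simulate_proteins",
    "simulate_transcripts",
    "simulate_footprints",
    "DEFAULT_MODE_FRACTIONS",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_ARE_ENRICHMENT",
    "ARE_MOTIF",
]

MODES = ("transcriptional", "translational", "buffered", "post_translational", "null")
WITHDRAWAL_CLASSES = ("CP", "2i", "P", "C")

ARE_MOTIF = "UAUUUAU"

#: Default planted composition.  Chosen so the protein-differential subset
#: decomposes roughly 74% transcriptional / 7% translational / 19%
#: post-translational, and buffering dominates differential-TE genes.
DEFAULT_MODE_FRACTIONS: dict[str, float] = {
    "null": 0.60,
    "transcriptional": 0.20,
    "buffered": 0.13,
    "post_translational": 0.05,
    "translational": 0.02,
}

#: Planted |log2 shift| per mode: 2 for protein-level drivers, 1.5 for
#: buffering.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "transcriptional": 2.0,
    "translational": 2.0,
    "post_translational": 2.0,
    "buffered": 1.5,
    "null": 0.0,
}

#: Fraction of genes per mode carrying a planted AU-rich element in the
#: 3'UTR; buffered genes are ARE-enriched, everything else sits at background.
DEFAULT_ARE_ENRICHMENT: dict[str, float] = {
    "buffered": 0.60,
    "transcriptional": 0.25,
    "translational": 0.25,
    "post_translational": 0.25,
    "null": 0.25,
}

DEFAULT_WITHDRAWAL_FRACTIONS: dict[str, float] = {
    "CP": 0.60,
    "2i": 0.20,
    "P": 0.10,
    "C": 0.10,
}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneSpec:
    """Planted ground truth for one gene.

    Shifts are log2 units, condition vs reference.  Mode invariants are
    enforced at construction.
    """

    gene_id: str
    mode: str
    base_log2_cpm: float
    rna_shift: float
    te_shift: float
    protein_shift: float
    has_are: bool

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown regulatory mode {self.mode!r}")
        r, t, p = self.rna_shift, self.te_shift, self.protein_shift
        ok = {
            "buffered": t == -r and p == 0 and r != 0,
            "transcriptional": t == 0 and p == r,
            "translational": r == 0 and p == t,
            "post_translational": r == 0 and t == 0 and p != 0,
            "null": r == 0 and t == 0 and p == 0,
        }[self.mode]
        if not ok:
            raise ValueError(
                f"{self.gene_id}: shifts ({r}, {t}, {p}) violate mode {self.mode!r}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditions and replicate structure; the reference condition is first.

    RNA/RFP layers use two biological replicates per condition, the proteome
    uses biological triplicates, mirroring the study layout this generator
    emulates.
    """

    conditions: tuple[str, ...] = ("2iL", "SL", "EPI")
    n_rna_reps: int = 2
    n_rfp_reps: int = 2
    n_prot_reps: int = 3
    library_depths: Mapping[str, int] = field(default_factory=dict)
    default_depth: int = 5_000_000

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("at least one (reference) condition is required")
        if self.n_rna_reps < 2 or self.n_rfp_reps < 2:
            raise ValueError("RNA and RFP layers need >= 2 replicates")
        if self.n_prot_reps < 3:
            raise ValueError("protein layer needs >= 3 replicates")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    def samples(self, layer: str) -> list[tuple[str, str, int]]:
        """(sample_id, condition, replicate) triples for one layer."""
        n = {"rna": self.n_rna_reps, "rfp": self.n_rfp_reps, "prot": self.n_prot_reps}[
            layer
        ]
        return [
            (f"{cond}_{layer}_rep{i + 1}", cond, i + 1)
            for cond in self.conditions
            for i in range(n)
        ]

    def depth(self, sample_id: str) -> int:
        return int(self.library_depths.get(sample_id, self.default_depth))


@dataclass(frozen=True)
class SimulationConfig:
    """Dials of the generator.

    ``dispersion`` is the NB dispersion phi in var = mu + phi mu^2;
    ``protein_sigma`` the log2 replicate noise of the proteome;
    ``censor_quantile`` the per-sample intensity quantile below which values
    are eligible for missingness (each eligible cell drops out with
    probability 0.8 — left censoring, missing-not-at-random).
    """

    n_genes: int = 2000
    mode_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_FRACTIONS)
    )
    dispersion: float = 0.02
    protein_sigma: float = 0.25
    censor_quantile: float = 0.10
    rfp_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mode_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode fractions sum to {total}, expected 1")
        for mode in self.mode_fractions:
            if mode not in MODES:
                raise ValueError(f"unknown mode key {mode!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.censor_quantile < 1):
            raise ValueError("censor_quantile must lie in [0, 1)")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript in transcript coordinates (0-based, half-open).

    The translation initiation site (TIS) is the first nucleotide of the
    AUG, at position ``len(utr5)``.
    """

    gene_id: str
    utr5: str
    cds: str
    utr3: str

    def __post_init__(self) -> None:
        seq = self.utr5 + self.cds + self.utr3
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"{self.gene_id}: non-ACGU residues {sorted(bad)}")
        if not self.cds.startswith("AUG"):
            raise ValueError(f"{self.gene_id}: CDS does not start with AUG")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.cds[-3:] not in ("UAA", "UAG", "UGA"):
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")

    @property
    def tis(self) -> int:
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass(frozen=True)
class UtrConfig:
    """Length ranges (nt, inclusive) and AU content of simulated transcripts."""

    utr5_len: tuple[int, int] = (60, 200)
    cds_len: tuple[int, int] = (300, 1800)
    utr3_len: tuple[int, int] = (150, 600)
    utr3_au: float = 0.60
    utr5_au: float = 0.50

    def __post_init__(self) -> None:
        for lo, hi in (self.utr5_len, self.cds_len, self.utr3_len):
            if lo < 0 or hi < lo:
                raise ValueError("invalid length range")
        if self.cds_len[1] < 9:
            raise ValueError("CDS range must allow start + >=1 codon + stop")
        if not (0 < self.utr3_au < 1 and 0 < self.utr5_au < 1):
            raise ValueError("AU content must lie in (0, 1)")


@dataclass(frozen=True)
class PsiteGeometry:
    """Footprint geometry: 5' end sits ``offset`` nt upstream of the decoded
    codon; read lengths uniform on [min_len, max_len]."""

    offset: int = 12
    min_len: int = 28
    max_len: int = 32
    utr_background: float = 0.03
    init_peak: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("invalid read-length range")
        if not (0 <= self.utr_background < 1 and 0 <= self.init_peak <= 1):
            raise ValueError("fractions must lie in [0, 1)")


@dataclass(frozen=True)
class FootprintAlignment:
    """A sense-strand footprint alignment in transcript coordinates."""

    read_id: str
    transcript_id: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class CountMatrix:
    """genes x samples integer counts for one layer plus sample metadata.

    ``meta`` columns: sample, condition, layer, replicate.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def samples_for(self, condition: str) -> list[str]:
        return list(self.meta.loc[self.meta["condition"] == condition, "sample"])


@dataclass
class ProteinMatrix:
    """protein group x sample log2 intensities with explicit missingness.

    Missing cells are NaN; ``gene_map`` links each protein group to >= 1 gene
    ids (groups mapping to more than one gene exercise the unique-assignment
    filter downstream).
    """

    intensities: pd.DataFrame
    gene_map: dict[str, tuple[str, ...]]
    meta: pd.DataFrame

    def samples_for(self, condition: str) -> list[str]:
        return list(self.meta.loc[self.meta["condition"] == condition, "sample"])


# ---------------------------------------------------------------------------
# operations


def _largest_remainder(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Apportion n into integer counts by largest remainder, deterministic."""
    items = sorted(fractions.items())
    raw = [(mode, n * frac) for mode, frac in items]
    counts = {mode: int(np.floor(x)) for mode, x in raw}
    short = n - sum(counts.values())
    remainders = sorted(
        ((x - np.floor(x), mode) for mode, x in raw), key=lambda t: (-t[0], t[1])
    )
    for _, mode in remainders[:short]:
        counts[mode] += 1
    return counts


def generate_gene_specs(
    n_genes: int,
    mode_fractions: Mapping[str, float] | None = None,
    effect_sizes: Mapping[str, float] | None = None,
    are_enrichment: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[GeneSpec]:
    """Plant ground truth: exactly round(n * fraction) genes per mode
    (largest-remainder rounding), random shift signs, mode-dependent ARE
    planting.  Deterministic for a fixed seed."""
    fractions = dict(DEFAULT_MODE_FRACTIONS if mode_fractions is None else mode_fractions)
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode fractions sum to {total}, expected 1")
    for mode in fractions:
        if mode not in MODES:
            raise ValueError(f"unknown mode key {mode!r}")
    sizes = dict(DEFAULT_EFFECT_SIZES)
    if effect_sizes is not None:
        sizes.update(effect_sizes)
    are = dict(DEFAULT_ARE_ENRICHMENT)
    if are_enrichment is not None:
        are.update(are_enrichment)
    for value in sizes.values():
        if not np.isfinite(value):
            raise ValueError("effect sizes must be finite")

    rng = substream(seed, "gene_specs")
    counts = _largest_remainder(n_genes, fractions)
    modes = [m for m in sorted(counts) for _ in range(counts[m])]
    rng.shuffle(modes)

    width = max(4, len(str(max(n_genes - 1, 0))))
    specs: list[GeneSpec] = []
    for i, mode in enumerate(modes):
        base = float(rng.normal(7.0, 1.5))
        sign = float(rng.choice([-1.0, 1.0]))
        size = float(sizes.get(mode, 0.0))
        shift = sign * size
        if mode == "transcriptional":
            r, t, p = shift, 0.0, shift
        elif mode == "translational":
            r, t, p = 0.0, shift, shift
        elif mode == "buffered":
            r, t, p = shift, -shift, 0.0
        elif mode == "post_translational":
            r, t, p = 0.0, 0.0, shift
        else:
            r = t = p = 0.0
        has_are = bool(rng.random() < are.get(mode, 0.0))
        specs.append(
            GeneSpec(
                gene_id=f"g{i:0{width}d}",
                mode=mode,
                base_log2_cpm=base,
                rna_shift=r,
                te_shift=t,
                protein_shift=p,
                has_are=has_are,
            )
        )
    return specs


def assign_withdrawal_classes(
    specs: Sequence[GeneSpec],
    fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Assign an inhibitor-withdrawal dependency class to each protein-shifted
    gene.

    The class states which single-inhibitor culture reproduces the gene's
    SL/EPI-like protein change: ``P`` responds when the MEK inhibitor (PD) is
    withdrawn (CHL culture), ``C`` when the GSK3 inhibitor (CH) is withdrawn
    (PDL culture), ``2i`` in either, ``CP`` only when both are withdrawn.
    """
    fracs = dict(DEFAULT_WITHDRAWAL_FRACTIONS if fractions is None else fractions)
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("withdrawal class fractions must sum to 1")
    rng = substream(seed, "withdrawal_classes")
    shifted = [s.gene_id for s in specs if s.protein_shift != 0]
    counts = _largest_remainder(len(shifted), fracs)
    labels = [c for c in sorted(counts) for _ in range(counts[c])]
    rng.shuffle(labels)
    return dict(zip(shifted, labels))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) via Gamma–Poisson; phi = 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


_WITHDRAWAL_CONDITIONS = {"CHL": ("P", "2i"), "PDL": ("C", "2i")}


def _protein_shift_for(
    spec: GeneSpec, condition: str, reference: str, withdrawal_classes: Mapping[str, str]
) -> float:
    if condition == reference:
        return 0.0
    if condition in _WITHDRAWAL_CONDITIONS:
        cls = withdrawal_classes.get(spec.gene_id)
        responds = cls in _WITHDRAWAL_CONDITIONS[condition]
        return spec.protein_shift if responds else 0.0
    return spec.protein_shift


def simulate_counts(
    specs: Sequence[GeneSpec],
    design: ExperimentDesign,
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw RNA and footprint count matrices.

    RNA mean for gene g in sample s is ``2^(base + rna_shift * I[s not ref])``
    scaled so the column's expected total equals the library depth; the RFP
    mean multiplies in ``2^(te_shift * I[s not ref]) * rfp_scale``.  Withdrawal
    cultures (CHL/PDL) carry the full condition shift on the RNA/TE layers.
    """
    genes = [s.gene_id for s in specs]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in specs")
    base = np.array([s.base_log2_cpm for s in specs])
    rna_shift = np.array([s.rna_shift for s in specs])
    te_shift = np.array([s.te_shift for s in specs])
    ref = design.reference
    rng = substream(config.seed, "counts")

    layers: dict[str, pd.DataFrame] = {}
    metas: dict[str, pd.DataFrame] = {}
    for layer in ("rna", "rfp"):
        cols = {}
        meta_rows = []
        for sample_id, cond, rep in design.samples(layer):
            non_ref = cond != ref
            rel = np.exp2(base + rna_shift * non_ref)
            mean = rel / rel.sum() * design.depth(sample_id)
            if layer == "rfp":
                mean = mean * np.exp2(te_shift * non_ref) * config.rfp_scale
            cols[sample_id] = _nb_draw(rng, mean, config.dispersion)
            meta_rows.append((sample_id, cond, layer, rep))
        layers[layer] = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        metas[layer] = pd.DataFrame(
            meta_rows, columns=["sample", "condition", "layer", "replicate"]
        )
    return (
        CountMatrix(layers["rna"], metas["rna"]),
        CountMatrix(layers["rfp"], metas["rfp"]),
    )


def simulate_proteins(
    specs: Sequence[GeneSpec],
    design: ExperimentDesign,
    config: SimulationConfig,
    ambiguous_fraction: float = 0.05,
    withdrawal_classes: Mapping[str, str] | None = None,
    base_offset: float = 16.0,
) -> ProteinMatrix:
    """Draw a censored log-normal protein layer.

    log2 intensity = base + protein_shift * I[condition != ref] + N(0, sigma).
    Within each sample the cells below the ``censor_quantile`` intensity
    quantile go missing with probability 0.8 (left censoring).  A fraction of
    protein groups is mapped to two genes to exercise the unique-assignment
    filter.  Withdrawal cultures (CHL/PDL) receive the protein shift only for
    genes whose planted withdrawal class responds in that culture.
    """
    if config.censor_quantile >= 1:
        raise ValueError("censor_quantile must be < 1")
    if not (0 <= ambiguous_fraction < 1):
        raise ValueError("ambiguous_fraction must lie in [0, 1)")
    wc = withdrawal_classes or {}
    rng = substream(config.seed, "proteins")
    genes = [s.gene_id for s in specs]
    samples = design.samples("prot")

    values = np.empty((len(specs), len(samples)))
    for j, (sample_id, cond, _rep) in enumerate(samples):
        shifts = np.array(
            [_protein_shift_for(s, cond, design.reference, wc) for s in specs]
        )
        mu = np.array([s.base_log2_cpm for s in specs]) + base_offset + shifts
        values[:, j] = mu + rng.normal(0.0, config.protein_sigma, size=len(specs))

    # left-censoring: per sample, lowest-quantile cells drop out w.p. 0.8
    if config.censor_quantile > 0:
        for j in range(values.shape[1]):
            cutoff = np.quantile(values[:, j], config.censor_quantile)
            eligible = values[:, j] <= cutoff
            drop = eligible & (rng.random(len(specs)) < 0.8)
            values[drop, j] = np.nan

    n_ambig = int(round(ambiguous_fraction * len(specs)))
    ambig_idx = set(rng.choice(len(specs), size=n_ambig, replace=False).tolist())
    gene_map: dict[str, tuple[str, ...]] = {}
    pg_ids = []
    for i, gene in enumerate(genes):
        pg = f"PG_{gene}"
        pg_ids.append(pg)
        if i in ambig_idx and len(genes) > 1:
            partner = genes[(i + 1 + int(rng.integers(len(genes) - 1))) % len(genes)]
            if partner == gene:
                partner = genes[(i + 1) % len(genes)]
            gene_map[pg] = (gene, partner)
        else:
            gene_map[pg] = (gene,)

    intensities = pd.DataFrame(
        values,
        index=pd.Index(pg_ids, name="protein_group_id"),
        columns=[s for s, _, _ in samples],
    )
    meta = pd.DataFrame(
        [(s, c, "prot", r) for s, c, r in samples],
        columns=["sample", "condition", "layer", "replicate"],
    )
    return ProteinMatrix(intensities, gene_map, meta)


_STOPS = ("UAA", "UAG", "UGA")
_NT = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, n: int, au: float) -> str:
    p = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])
    return "".join(rng.choice(_NT, size=n, p=p)) if n else ""


def _random_cds(rng: np.random.Generator, n_nt: int) -> str:
    """AUG + random non-stop codons + one stop; n_nt divisible by 3."""
    n_mid = n_nt // 3 - 2
    codons = []
    while len(codons) < n_mid:
        c = "".join(rng.choice(_NT, size=3))
        if c not in _STOPS:
            codons.append(c)
    stop = _STOPS[int(rng.integers(3))]
    return "AUG" + "".join(codons) + stop


def simulate_transcripts(
    specs: Sequence[GeneSpec],
    utr_config: UtrConfig | None = None,
    seed: int = 0,
) -> list[TranscriptModel]:
    """Emit one transcript model per gene.

    CDS lengths are drawn within the configured range and snapped to a
    multiple of 3; genes with ``has_are`` get at least one UAUUUAU heptamer
    planted in the 3'UTR.
    """
    cfg = utr_config or UtrConfig()
    rng = substream(seed, "transcripts")
    if cfg.utr3_len[0] < len(ARE_MOTIF) and any(s.has_are for s in specs):
        raise ValueError("3'UTR too short to plant the ARE heptamer")
    out = []
    for spec in specs:
        n5 = int(rng.integers(cfg.utr5_len[0], cfg.utr5_len[1] + 1))
        n3 = int(rng.integers(cfg.utr3_len[0], cfg.utr3_len[1] + 1))
        nc = int(rng.integers(cfg.cds_len[0], cfg.cds_len[1] + 1))
        nc = max(9, nc - nc % 3)
        utr5 = _random_seq(rng, n5, cfg.utr5_au)
        utr3 = _random_seq(rng, n3, cfg.utr3_au)
        if spec.has_are:
            pos = int(rng.integers(0, n3 - len(ARE_MOTIF) + 1))
            utr3 = utr3[:pos] + ARE_MOTIF + utr3[pos + len(ARE_MOTIF):]
        out.append(TranscriptModel(spec.gene_id, utr5, _random_cds(rng, nc), utr3))
    return out


def simulate_footprints(
    transcripts: Sequence[TranscriptModel],
    te_weights: Mapping[str, float],
    n_reads: int,
    geometry: PsiteGeometry | None = None,
    seed: int = 0,
) -> list[FootprintAlignment]:
    """Place ``n_reads`` footprints across transcripts, multinomial per gene
    with probability proportional to ``te_weights``.

    In-CDS reads decode a codon (the start codon with probability
    ``init_peak`` — the initiation pause — otherwise a uniform CDS codon) and
    have their 5' end ``offset`` nt upstream of it; a small ``utr_background``
    fraction lands uniformly in the UTRs.
    """
    geom = geometry or PsiteGeometry()
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if not transcripts:
        if n_reads > 0:
            raise ValueError("no transcripts to place reads on")
        return []
    rng = substream(seed, "footprints")
    tx = list(transcripts)
    w = np.array([float(te_weights.get(t.gene_id, 0.0)) for t in tx])
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    per_gene = rng.multinomial(n_reads, w / w.sum())

    reads: list[FootprintAlignment] = []
    rid = 0
    for t, n in zip(tx, per_gene):
        if n == 0:
            continue
        lengths = rng.integers(geom.min_len, geom.max_len + 1, size=n)
        in_utr = rng.random(n) < geom.utr_background
        at_init = rng.random(n) < geom.init_peak
        n_codons = len(t.cds) // 3
        for k in range(int(n)):
            length = int(lengths[k])
            if in_utr[k]:
                # uniform 5' end over UTR positions, clipped so the read fits
                utr_pos = list(range(0, t.tis)) + list(range(t.cds_end, t.length))
                start = int(utr_pos[int(rng.integers(len(utr_pos)))])
                start = min(start, max(0, t.length - length))
            else:
                codon_idx = 0 if at_init[k] else int(rng.integers(n_codons))
                codon_pos = t.tis + 3 * codon_idx
                start = codon_pos - geom.offset
                start = min(max(start, 0), max(0, t.length - length))
            reads.append(FootprintAlignment(f"r{rid:07d}", t.gene_id, start, length))
            rid += 1
    return reads
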