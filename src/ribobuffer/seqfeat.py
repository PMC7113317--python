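"""UTR/CDS sequence features and motif scanning.

Length, %GC and %AU per transcript region; exact (overlapping) scans for the
AU-rich element UAUUUAU on the sense strand; PWM scanning with a
relative-score threshold (hit iff log-odds >= threshold x the PWM's maximal
achievable log-odds); Wilcoxon rank-sum comparisons of feature
distributions (exact enumeration at small n); and hypergeometric motif
presence enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .setstats import EnrichmentResult, hypergeometric_tail
from .synthdata import ARE_MOTIF, TranscriptModel

__all__ = [
    "MotifPWM",
    "sequence_composition",
    "scan_exact_motif",
    "scan_pwm",
    "compare_distributions",
    "motif_presence_enrichment",
    "ARE_MOTIF",
]

_ALPHABET = "ACGU"
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class MotifPWM:
    """Position probability matrix over ACGU with a background distribution.

    Zeros are replaced by a pseudo-probability of 1e-3 (rows renormalized)
    before taking log-odds, so the score stays finite.
    """

    motif_id: str
    matrix: np.ndarray  # (length, 4) probabilities, ACGU order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be >= 0")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("PWM rows must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", np.asarray(self.background, float))

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.matrix, 1e-3)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p: float = 0.97) -> "MotifPWM":
        """A sharp PWM giving probability ``p`` to each consensus base."""
        m = np.full((len(consensus), 4), (1 - p) / 3)
        for i, c in enumerate(consensus):
            m[i, _INDEX[c]] = p
        return cls(motif_id, m)


def _check_rna(seq: str, name: str = "sequence") -> None:
    for i, c in enumerate(seq):
        if c not in _INDEX:
            raise ValueError(f"{name}: non-ACGU character {c!r} at position {i}")


def sequence_composition(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Length, GC fraction and AU fraction per transcript region."""
    rows = []
    for t in transcripts:
        for region, seq in (("utr5", t.utr5), ("cds", t.cds), ("utr3", t.utr3)):
            _check_rna(seq, f"{t.gene_id}/{region}")
            n = len(seq)
            gc = (seq.count("G") + seq.count("C")) / n if n else 0.0
            au = (seq.count("A") + seq.count("U")) / n if n else 0.0
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "region": region,
                    "length": n,
                    "gc_fraction": gc,
                    "au_fraction": au,
                }
            )
    return pd.DataFrame(rows)


def scan_exact_motif(
    sequences: Mapping[str, str] | Sequence[str],
    motif: str = ARE_MOTIF,
) -> dict[str, int] | list[int]:
    """Count all (possibly overlapping) occurrences of ``motif`` on the given
    strand of each sequence."""
    if not motif:
        raise ValueError("motif must be non-empty")
    _check_rna(motif, "motif")

    def _count(seq: str) -> int:
        return sum(
            1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
        )

    if isinstance(sequences, Mapping):
        return {name: _count(seq) for name, seq in sequences.items()}
    return [_count(seq) for seq in sequences]


def scan_pwm(
    sequences: Mapping[str, str] | Sequence[str],
    pwm: MotifPWM,
    rel_threshold: float = 0.9,
) -> dict[str, list[tuple[int, float]]] | list[list[tuple[int, float]]]:
    """Positive-strand PWM scan.

    Scores every position with the log-odds of the PWM against its
    background; a hit is any position whose score reaches ``rel_threshold``
    times the PWM's maximum achievable log-odds.  Sequences shorter than the
    motif yield no hits.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    lods = pwm.log_odds()
    cutoff = rel_threshold * pwm.max_score

    def _scan(seq: str) -> list[tuple[int, float]]:
        hits = []
        L = pwm.length
        for i in range(len(seq) - L + 1):
            score = sum(lods[j, _INDEX[seq[i + j]]] for j in range(L))
            if score >= cutoff:
                hits.append((i, float(score)))
        return hits

    if isinstance(sequences, Mapping):
        return {name: _scan(seq) for name, seq in sequences.items()}
    return [_scan(seq) for seq in sequences]


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann–Whitney p by enumeration of all label
    assignments of the pooled sample (midranks for ties).

    Two-sided p = P(|U - mn/2| >= |u_obs - mn/2|), which is valid for
    arbitrary tie patterns.
    """
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    center = na * (n - na) / 2
    dev = abs(u_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        if abs(u - center) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_distributions(values_a: Iterable[float], values_b: Iterable[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when n_a + n_b <= 12; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= 12:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def motif_presence_enrichment(
    hit_genes: set,
    query_set: set,
    background_set: set,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of motif-bearing genes in a query
    set against a background universe."""
    background = set(background_set)
    query = set(query_set)
    if not query <= background:
        raise ValueError("query is not a subset of the background")
    hits = set(hit_genes) & background
    k = len(hits & query)
    K = len(hits)
    n = len(query)
    N = len(background)
    p = hypergeometric_tail(k, K, n, N)
    return EnrichmentResult("motif_presence", k, K, n, N, p, p)
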