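"""Label-free proteomics statistics.

Mirrors the standard Perseus-style workflow for MaxQuant LFQ output:
keep proteins reproducibly quantified (>= 3 valid values in at least one
condition), impute remaining missing values from a down-shifted normal
(per-sample mean − 1.8 sd, width 0.3 sd — left-censored intensities sit
below the detection limit), then call differential proteins with a
two-sample t-test at BH FDR < 0.05 and fold change >= 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .setstats import bh_adjust
from .synthdata import ProteinMatrix

__all__ = [
    "ImputationConfig",
    "filter_reproducible",
    "impute_missing",
    "differential_protein",
    "detection_matrix",
    "state_exclusive_proteins",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Down-shifted normal imputation parameters (in per-sample sd units)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0
    min_observed_per_sample: int = 2

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")


def filter_reproducible(pm: ProteinMatrix, min_valid: int = 3) -> ProteinMatrix:
    """Keep proteins with >= ``min_valid`` non-missing values in at least one
    condition."""
    conditions = pm.meta["condition"].unique()
    keep = pd.Series(False, index=pm.intensities.index)
    for cond in conditions:
        cols = pm.samples_for(cond)
        keep |= pm.intensities[cols].notna().sum(axis=1) >= min_valid
    kept = pm.intensities.loc[keep]
    gene_map = {pg: pm.gene_map[pg] for pg in kept.index}
    return ProteinMatrix(kept, gene_map, pm.meta.copy())


def impute_missing(pm: ProteinMatrix, config: ImputationConfig | None = None) -> ProteinMatrix:
    """Replace missing cells, per sample, with draws from
    Normal(mu_hat − downshift * sd_hat, (width * sd_hat)^2), where mu_hat and
    sd_hat come from that sample's observed values.  Observed cells are never
    altered; the draw stream is keyed by (seed, sample) so results are
    deterministic and independent of which other samples exist."""
    cfg = config or ImputationConfig()
    out = pm.intensities.copy()
    for col in out.columns:
        missing = out[col].isna()
        if not missing.any():
            continue
        observed = out[col].dropna()
        if len(observed) < cfg.min_observed_per_sample:
            raise ValueError(
                f"sample {col!r} has {len(observed)} observed values, "
                f"need >= {cfg.min_observed_per_sample}"
            )
        mu, sd = float(observed.mean()), float(observed.std(ddof=1))
        rng = substream(cfg.seed, f"impute:{col}")
        out.loc[missing, col] = rng.normal(
            mu - cfg.downshift * sd, cfg.width * sd, size=int(missing.sum())
        )
    return ProteinMatrix(out, dict(pm.gene_map), pm.meta.copy())


def differential_protein(
    pm: ProteinMatrix,
    cond_a: str,
    cond_b: str,
    fc_min: float = 3.0,
    fdr_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per protein on log2 intensities, ``cond_b`` vs
    ``cond_a``; called iff BH FDR < ``fdr_max`` and 2^|log2fc| >= ``fc_min``.

    Requires a fully imputed matrix (raises if missing values remain) and
    >= 3 replicates per condition.  Student's pooled-variance t by default;
    ``welch=True`` switches to unequal variances.
    """
    cols_a, cols_b = pm.samples_for(cond_a), pm.samples_for(cond_b)
    for cond, cols in ((cond_a, cols_a), (cond_b, cols_b)):
        if len(cols) < 3:
            raise ValueError(f"condition {cond!r} has < 3 protein replicates")
    sub = pm.intensities[cols_a + cols_b]
    if sub.isna().any().any():
        raise ValueError("missing values present: impute before testing")
    a = pm.intensities[cols_a].values
    b = pm.intensities[cols_b].values
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    fdr = bh_adjust(p)
    called = (fdr < fdr_max) & (np.exp2(np.abs(log2fc)) >= fc_min)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "fdr": fdr, "called": called},
        index=pm.intensities.index,
    )


def detection_matrix(
    pm: ProteinMatrix, conditions: list[str] | None = None, min_valid: int = 3
) -> pd.DataFrame:
    """protein x condition boolean: detected iff >= ``min_valid`` observed
    replicates in that condition."""
    conditions = conditions or list(pd.unique(pm.meta["condition"]))
    out = {}
    for cond in conditions:
        cols = pm.samples_for(cond)
        out[cond] = pm.intensities[cols].notna().sum(axis=1) >= min_valid
    return pd.DataFrame(out)


def state_exclusive_proteins(detection: pd.DataFrame) -> dict[tuple[str, ...], set[str]]:
    """Group proteins by their detection pattern over the conditions.

    Keys are sorted tuples of the conditions in which the protein is
    detected; "exclusive" proteins are those whose pattern is a strict
    non-empty subset of all conditions (the full pattern is also returned,
    under the all-conditions key, for completeness).  Undetected proteins are
    omitted.
    """
    patterns: dict[tuple[str, ...], set[str]] = {}
    conds = list(detection.columns)
    for protein, row in detection.iterrows():
        pattern = tuple(sorted(c for c in conds if row[c]))
        if not pattern:
            continue
        patterns.setdefault(pattern, set()).add(protein)
    return patterns
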