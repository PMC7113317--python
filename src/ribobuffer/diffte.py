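"""Normalization, expression filtering and differential translation efficiency.

Translation efficiency (TE) is the ratio of library-size-normalized
footprint abundance to normalized mRNA abundance.  Differential TE between
two conditions is tested with a delta-method z statistic on

    delta_te = log2FC(RFP) - log2FC(RNA),

where the variance of each log2 condition mean is approximated from the
negative-binomial mean–variance relation,

    Var(log2 mu_hat) ~= (1/ln 2)^2 * (1/mu + phi(mu)) / n_reps,

with a mean–dispersion trend phi(mu) estimated by method of moments on the
replicates, binned by mean and monotonised (pool-adjacent-violators).  Genes
are called differentially translated at BH FDR < 0.1 and fold change > 1.5,
after requiring > 50 normalized RNA reads and > 25 normalized RFP reads in
every replicate of at least one compared condition and a mean raw count
>= 50 in both layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .setstats import bh_adjust
from .synthdata import CountMatrix

__all__ = [
    "NormalizationConfig",
    "DiffTEConfig",
    "normalize",
    "filter_expressed",
    "compute_te",
    "differential_te",
    "partition_te_sets",
]

_LN2_SQ_INV = 1.0 / math.log(2) ** 2


@dataclass(frozen=True)
class NormalizationConfig:
    method: str = "cpm"  # "cpm" | "median_of_ratios"
    pseudocount: float = 0.5  # CPM units, used for fold changes

    def __post_init__(self) -> None:
        if self.method not in ("cpm", "median_of_ratios"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class DiffTEConfig:
    normalization: NormalizationConfig = NormalizationConfig()
    rna_min: float = 50.0
    rfp_min: float = 25.0
    min_mean_count: float = 50.0
    fdr_max: float = 0.1
    fc_min: float = 1.5
    n_dispersion_bins: int = 20


def normalize(counts: pd.DataFrame, config: NormalizationConfig | None = None) -> pd.DataFrame:
    """Library-size normalization of a genes x samples count matrix.

    ``cpm``: count * 1e6 / column sum.  ``median_of_ratios``: DESeq-style —
    each sample divided by its size factor, the median over genes of
    count / geometric-mean reference row (genes with a zero anywhere are
    excluded from the reference).
    """
    config = config or NormalizationConfig()
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column: {zero.index[0]!r}")
    if config.method == "cpm":
        return counts * 1e6 / colsums
    log_counts = np.log(counts.where(counts > 0))
    ref = log_counts.mean(axis=1)  # log geometric mean; NaN if any zero
    usable = ref.notna()
    if not usable.any():
        raise ValueError("no gene without zeros for median-of-ratios reference")
    ratios = np.log(counts.loc[usable]).sub(ref[usable], axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    return counts / size_factors


def filter_expressed(
    rna_norm: pd.DataFrame,
    rfp_norm: pd.DataFrame,
    rna_meta: pd.DataFrame,
    rfp_meta: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    rna_min: float = 50.0,
    rfp_min: float = 25.0,
) -> set[str]:
    """Expression filter for one comparison.

    A gene is kept iff its normalized RNA value exceeds ``rna_min`` in every
    replicate of at least one of the two compared conditions, and likewise
    its normalized RFP value exceeds ``rfp_min`` (strict inequalities).
    """
    if not rna_norm.index.equals(rfp_norm.index):
        raise ValueError("RNA and RFP matrices have mismatched gene sets")

    def _passes(norm: pd.DataFrame, meta: pd.DataFrame, minimum: float) -> pd.Series:
        ok = pd.Series(False, index=norm.index)
        for cond in (cond_a, cond_b):
            cols = meta.loc[meta["condition"] == cond, "sample"]
            if len(cols) == 0:
                raise ValueError(f"condition {cond!r} absent from metadata")
            ok |= (norm[list(cols)] > minimum).all(axis=1)
        return ok

    keep = _passes(rna_norm, rna_meta, rna_min) & _passes(rfp_norm, rfp_meta, rfp_min)
    return set(rna_norm.index[keep])


def compute_te(
    rfp_norm: pd.DataFrame,
    rna_norm: pd.DataFrame,
    rfp_meta: pd.DataFrame,
    rna_meta: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene TE = (rfp + c) / (rna + c), samples paired by
    (condition, replicate); columns named ``{condition}_rep{n}``."""
    key = lambda m: {  # noqa: E731
        (r.condition, r.replicate): r.sample for r in m.itertuples()
    }
    rna_by, rfp_by = key(rna_meta), key(rfp_meta)
    pairs = sorted(set(rna_by) & set(rfp_by))
    if set(rna_by) != set(rfp_by):
        raise ValueError("unpaired samples between RNA and RFP layers")
    te = {}
    for cond, rep in pairs:
        te[f"{cond}_rep{rep}"] = (rfp_norm[rfp_by[(cond, rep)]] + pseudocount) / (
            rna_norm[rna_by[(cond, rep)]] + pseudocount
        )
    return pd.DataFrame(te, index=rna_norm.index)


def _pava_nonincreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, monotone non-increasing."""
    y = -np.asarray(y, dtype=float)
    blocks = [[v, wt, 1] for v, wt in zip(y, w)]  # mean, weight, size
    merged: list[list[float]] = []
    for b in blocks:
        merged.append(list(b))
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            v2, w2, n2 = merged.pop()
            v1, w1, n1 = merged.pop()
            wsum = w1 + w2
            merged.append([(v1 * w1 + v2 * w2) / wsum, wsum, n1 + n2])
    fit = np.concatenate([[v] * int(n) for v, _, n in merged])
    return -fit


def _dispersion_trend(
    counts: pd.DataFrame, groups: list[list[str]], n_bins: int
) -> "_Trend":
    """Method-of-moments NB dispersion, binned by mean, monotone-smoothed.

    For each gene and replicate group with mean m and variance s^2,
    phi_hat = (s^2 - m) / m^2; per-bin means over genes (the per-gene
    estimate has few degrees of freedom, and its median — unlike its mean —
    is badly biased low) are monotonised (dispersion non-increasing in mean)
    and linearly interpolated in log-mean.
    """
    means, phis = [], []
    for cols in groups:
        sub = counts[cols].values.astype(float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        means.append(m[ok])
        phis.append((v[ok] - m[ok]) / m[ok] ** 2)
    mean_all = np.concatenate(means)
    phi_all = np.concatenate(phis)
    if mean_all.size == 0:
        return _Trend(np.array([0.0]), np.array([0.0]))
    logm = np.log(mean_all)
    qs = np.quantile(logm, np.linspace(0, 1, min(n_bins, max(2, mean_all.size)) + 1))
    qs[-1] += 1e-9
    centers, medians, weights = [], [], []
    for lo, hi in zip(qs[:-1], qs[1:]):
        mask = (logm >= lo) & (logm < hi)
        if mask.sum() < 3:
            continue
        centers.append(logm[mask].mean())
        medians.append(phi_all[mask].mean())
        weights.append(mask.sum())
    if not centers:
        phi = max(float(np.mean(phi_all)), 0.0)
        return _Trend(np.array([0.0]), np.array([phi]))
    fit = _pava_nonincreasing(np.array(medians), np.array(weights, dtype=float))
    return _Trend(np.array(centers), np.clip(fit, 0.0, None))


@dataclass(frozen=True)
class _Trend:
    log_means: np.ndarray
    phis: np.ndarray

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        logm = np.log(np.maximum(np.asarray(mean, dtype=float), 1e-12))
        return np.interp(logm, self.log_means, self.phis)


def differential_te(
    rna: CountMatrix,
    rfp: CountMatrix,
    cond_a: str,
    cond_b: str,
    config: DiffTEConfig | None = None,
) -> pd.DataFrame:
    """Differential TE between ``cond_b`` and ``cond_a`` (reference).

    Returns one row per tested gene with columns log2fc_rna, log2fc_rfp,
    delta_te, se, z, p, fdr, called, direction.  ``direction`` is
    ``higher_in_ref`` when TE drops in ``cond_b`` relative to ``cond_a``.
    """
    cfg = config or DiffTEConfig()
    layers = {"rna": rna, "rfp": rfp}
    cols: dict[tuple[str, str], list[str]] = {}
    for name, cm in layers.items():
        for cond in (cond_a, cond_b):
            cs = cm.samples_for(cond)
            if not cs:
                raise ValueError(f"condition {cond!r} absent from {name} layer")
            if len(cs) < 2:
                raise ValueError(f"condition {cond!r} has < 2 {name} replicates")
            cols[(name, cond)] = cs

    norm = {
        name: normalize(cm.counts, cfg.normalization) for name, cm in layers.items()
    }
    keep = filter_expressed(
        norm["rna"], norm["rfp"], rna.meta, rfp.meta, cond_a, cond_b,
        cfg.rna_min, cfg.rfp_min,
    )
    compared = {
        name: cols[(name, cond_a)] + cols[(name, cond_b)] for name in layers
    }
    mean_ok = pd.Series(True, index=rna.counts.index)
    for name, cm in layers.items():
        mean_ok &= cm.counts[compared[name]].mean(axis=1) >= cfg.min_mean_count
    tested = sorted(keep & set(rna.counts.index[mean_ok]))
    if not tested:
        return pd.DataFrame(
            columns=[
                "gene_id", "log2fc_rna", "log2fc_rfp", "delta_te",
                "se", "z", "p", "fdr", "called", "direction",
            ]
        ).set_index("gene_id")

    trends = {
        name: _dispersion_trend(
            cm.counts, [cols[(name, cond_a)], cols[(name, cond_b)]],
            cfg.n_dispersion_bins,
        )
        for name, cm in layers.items()
    }

    c = cfg.normalization.pseudocount
    fc: dict[str, np.ndarray] = {}
    var: dict[str, np.ndarray] = {}
    for name, cm in layers.items():
        fcs, vars_ = [], []
        for cond in (cond_a, cond_b):
            cs = cols[(name, cond)]
            raw_mean = cm.counts.loc[tested, cs].mean(axis=1).values
            norm_mean = norm[name].loc[tested, cs].mean(axis=1).values
            phi = trends[name](raw_mean)
            vars_.append(
                _LN2_SQ_INV * (1.0 / np.maximum(raw_mean, 1e-12) + phi) / len(cs)
            )
            fcs.append(np.log2(norm_mean + c))
        fc[name] = fcs[1] - fcs[0]
        var[name] = vars_[0] + vars_[1]

    delta = fc["rfp"] - fc["rna"]
    se = np.sqrt(var["rna"] + var["rfp"])
    z = delta / se
    p = 2 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(p)
    called = (fdr < cfg.fdr_max) & (np.exp2(np.abs(delta)) > cfg.fc_min)
    direction = np.where(delta < 0, "higher_in_ref", "higher_in_alt")
    return pd.DataFrame(
        {
            "log2fc_rna": fc["rna"],
            "log2fc_rfp": fc["rfp"],
            "delta_te": delta,
            "se": se,
            "z": z,
            "p": p,
            "fdr": fdr,
            "called": called,
            "direction": direction,
        },
        index=pd.Index(tested, name="gene_id"),
    )


def partition_te_sets(
    results_a: pd.DataFrame, results_b: pd.DataFrame, labels: tuple[str, str] = ("SL", "EPI")
) -> dict[str, object]:
    """Partition called genes from two comparisons against a common reference
    into {label_a}_only / {label_b}_only / common, with per-comparison TE
    direction annotations."""
    called_a = set(results_a.index[results_a["called"]])
    called_b = set(results_b.index[results_b["called"]])
    common = called_a & called_b
    la, lb = labels
    sets = {
        f"{la}_only": called_a - called_b,
        f"{lb}_only": called_b - called_a,
        "common": common,
    }
    rows = []
    for gene in sorted(called_a | called_b):
        member = (
            "common" if gene in common else (f"{la}_only" if gene in called_a else f"{lb}_only")
        )
        rows.append(
            {
                "gene_id": gene,
                "set": member,
                f"direction_{la}": results_a["direction"].get(gene, ""),
                f"direction_{lb}": results_b["direction"].get(gene, ""),
            }
        )
    sets["table"] = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
    return sets
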