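"""Alpha-diversity estimators and rarefaction curves for OTU count vectors.

Implements the indices conventionally reported for amplicon surveys of
fermented foods: observed richness, Shannon, Gini-Simpson, the Chao1 and
ACE richness estimators, and Good's coverage, plus analytic (hypergeometric
expectation) and subsampling rarefaction curves. Estimator dialects:

- Shannon supports base 2 (default) and e.
- Simpson is reported as 1 - dominance (higher = more diverse); the
  plugin variant is 1 - sum p_i^2, the unbiased variant
  1 - sum n_i (n_i - 1) / (N (N - 1)).
- Chao1 defaults to the bias-corrected form S_obs + F1 (F1-1) / (2 (F2+1));
  the classic form S_obs + F1^2 / (2 F2) falls back to bias-corrected when
  F2 = 0.
- ACE partitions OTUs at a rare/abundant cutoff (default count <= 10) and
  falls back to Chao1 (with a warning) when every rare OTU is a singleton.

Analytic rarefaction evaluates E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n))
with binomial coefficients in log space, so curves at realistic sequencing
depths do not overflow.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import StageDesign

__all__ = [
    "observed_otus",
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "rarefaction_curve",
    "alpha_diversity_table",
    "stage_summary",
]


def _clean(counts) -> np.ndarray:
    a = np.asarray(counts)
    if a.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(a < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(np.equal(np.mod(a, 1), 0)):
        raise ValueError("counts must be integers")
    return a.astype(np.int64)


def _require_positive_total(a: np.ndarray) -> int:
    n = int(a.sum())
    if n <= 0:
        raise ValueError("diversity undefined for an all-zero sample")
    return n


def observed_otus(counts) -> int:
    """Number of OTUs with count > 0 (sobs)."""
    return int(np.count_nonzero(_clean(counts)))


def shannon(counts, base: float = 2) -> float:
    """Shannon entropy -sum p_i log_base p_i over OTUs with p_i > 0."""
    a = _clean(counts)
    n = _require_positive_total(a)
    p = a[a > 0] / n
    return float(-(p * (np.log(p) / np.log(base))).sum())


def simpson(counts, variant: str = "plugin") -> float:
    """Gini-Simpson diversity, 1 - dominance.

    plugin: 1 - sum p_i^2; unbiased: 1 - sum n_i (n_i - 1) / (N (N - 1)).
    """
    a = _clean(counts)
    n = _require_positive_total(a)
    if variant == "plugin":
        p = a / n
        return float(1.0 - (p**2).sum())
    if variant == "unbiased":
        if n < 2:
            raise ValueError("unbiased Simpson needs a total of at least 2")
        return float(1.0 - (a * (a - 1)).sum() / (n * (n - 1)))
    raise ValueError("variant must be 'plugin' or 'unbiased'")


def chao1(counts, variant: str = "bias_corrected") -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    a = _clean(counts)
    _require_positive_total(a)
    s_obs = int(np.count_nonzero(a))
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    if variant == "bias_corrected" or (variant == "classic" and f2 == 0):
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if variant == "classic":
        return s_obs + f1**2 / (2.0 * f2)
    raise ValueError("variant must be 'bias_corrected' or 'classic'")


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    OTUs with count <= rare_cutoff form the rare group. With sample
    coverage C_ace = 1 - F1/N_rare and squared coefficient of variation
    gamma^2 (floored at 0):

        ACE = S_abund + S_rare / C_ace + F1 / C_ace * gamma^2

    When every rare OTU is a singleton (C_ace = 0) the estimator is
    undefined; Chao1 (bias-corrected) is returned with a warning.
    """
    a = _clean(counts)
    _require_positive_total(a)
    if rare_cutoff < 1:
        raise ValueError("rare_cutoff must be >= 1")
    rare = a[(a > 0) & (a <= rare_cutoff)]
    s_abund = int((a > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        warnings.warn(
            "all rare OTUs are singletons; ACE undefined, falling back to Chao1",
            stacklevel=2,
        )
        return chao1(a)
    c_ace = 1.0 - f1 / n_rare
    freqs = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    sum_term = float((i * (i - 1) * freqs).sum())
    gamma2 = max(
        s_rare * sum_term / (c_ace * n_rare * (n_rare - 1)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: chance the next read hits a seen OTU."""
    a = _clean(counts)
    n = _require_positive_total(a)
    f1 = int((a == 1).sum())
    return 1.0 - f1 / n


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(
    counts,
    depths,
    method: str = "analytic",
    n_rep: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected observed richness at subsampled depths (dilution curve).

    analytic: E[S(n)] = sum_i (1 - C(N - N_i, n) / C(N, n)), exact under
    subsampling without replacement. subsample: the mean sobs over
    ``n_rep`` random subsamples without replacement. Depths must be
    increasing and <= N. Returns a frame with columns depth, sobs.
    """
    a = _clean(counts)
    n_total = _require_positive_total(a)
    depths = [int(d) for d in depths]
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if any(b <= s for s, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    if depths and depths[-1] > n_total:
        raise ValueError(f"depth {depths[-1]} exceeds sample total {n_total}")

    pos = a[a > 0]
    if method == "analytic":
        log_cn = _log_comb(n_total, np.asarray(depths))
        sobs = []
        for j, d in enumerate(depths):
            rem = n_total - pos
            p_absent = np.zeros(len(pos))
            ok = rem >= d  # else the OTU cannot be missed at depth d
            p_absent[ok] = np.exp(_log_comb(rem[ok], d) - log_cn[j])
            sobs.append(float(np.sum(1.0 - p_absent)))
    elif method == "subsample":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(pos)), pos)
        sobs = []
        for d in depths:
            vals = [
                len(np.unique(rng.choice(pool, size=d, replace=False)))
                for _ in range(n_rep)
            ]
            sobs.append(float(np.mean(vals)))
    else:
        raise ValueError("method must be 'analytic' or 'subsample'")
    return pd.DataFrame({"depth": depths, "sobs": sobs})


def alpha_diversity_table(
    counts: pd.DataFrame,
    shannon_base: float = 2,
    simpson_variant: str = "plugin",
    chao1_variant: str = "bias_corrected",
    ace_rare_cutoff: int = 10,
) -> pd.DataFrame:
    """All indices for every sample column of an OTU x sample count table."""
    rows = {}
    for sample in counts.columns:
        v = counts[sample].to_numpy()
        rows[sample] = {
            "observed_otus": observed_otus(v),
            "shannon": shannon(v, base=shannon_base),
            "simpson": simpson(v, variant=simpson_variant),
            "chao1": chao1(v, variant=chao1_variant),
            "ace": ace(v, rare_cutoff=ace_rare_cutoff),
            "goods_coverage": goods_coverage(v),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def stage_summary(
    per_sample: pd.DataFrame, design: StageDesign | pd.DataFrame
) -> pd.DataFrame:
    """Per-stage mean and sd over replicates, in stage order.

    Matches the conventional "mean ± sd" presentation of alpha-diversity
    tables; sd is the sample standard deviation (ddof=1).
    """
    frame = design.to_frame() if isinstance(design, StageDesign) else design
    stages = frame.loc[per_sample.index, "stage"]
    grouped = per_sample.groupby(stages.values, sort=False)
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
    return out
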