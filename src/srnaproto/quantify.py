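"""Normalisation and differential expression for count matrices.

Libraries are made comparable by median-of-ratios size factors followed by
a generalised-log (glog) variance-stabilising transform, and two-group
differential expression is tested with an explicit negative-binomial
moment-based test: per-species dispersions are estimated by the method of
moments pooled within groups, and group means are compared with a Wald-type
statistic referred to a t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
ALPHA = 0.05
PSEUDOCOUNT = 0.5


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each species with a positive count in every library, the ratio of
    its count to its across-library geometric mean is formed; a library's
    factor is the median of these ratios. Species containing any zero are
    excluded from the median.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    counts = count_matrix.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no species has positive counts in every library; size factors "
            "are undefined — supply deeper libraries or a shared reference set"
        )
    logs = np.log(counts[all_positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def glog_transform(
    count_matrix: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Generalised-log transform of size-factor-normalised counts.

    value = log2(x + sqrt(x^2 + 1)) - 1 with x = count / factor. Finite at
    zero, strictly increasing, and asymptotically log2(x) for large x.
    """
    if factors is None:
        factors = size_factors(count_matrix)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    x = count_matrix.to_numpy(dtype=float) / factors.to_numpy(dtype=float)[None, :]
    values = np.log2(x + np.sqrt(x * x + 1.0)) - 1.0
    return pd.DataFrame(values, index=count_matrix.index, columns=count_matrix.columns)


@dataclass
class DEResult:
    """Per-species differential-expression table plus the inputs used."""

    table: pd.DataFrame  # columns: mean_a, mean_b, log2_fold_change, pvalue, padj
    size_factors: pd.Series
    groups: pd.Series
    alpha: float = ALPHA

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["padj"] < self.alpha]


def de_test(
    count_matrix: pd.DataFrame,
    group_labels: pd.Series | dict,
    factors: pd.Series | None = None,
    dispersion_floor: float = DISPERSION_FLOOR,
    prior_df: float = 10.0,
    alpha: float = ALPHA,
    pseudocount: float = PSEUDOCOUNT,
) -> DEResult:
    """Two-group negative-binomial test with moderated pooled dispersion.

    Counts are divided by size factors; for each species the NB dispersion
    is estimated by the method of moments from the within-group variances
    (pooled across the two groups), then shrunk toward the across-species
    median with ``prior_df`` pseudo-observations — per-species dispersions
    from two or three replicates are far too noisy to use raw. The
    difference of group means is tested with a Wald statistic whose variance
    follows the NB mean-variance relation at the pooled mean; p-values use a
    t reference with n_a + n_b - 2 + prior_df degrees of freedom (residual
    plus prior information) and are BH-adjusted across species. The
    moderated dispersion, floored at ``dispersion_floor``, is reported.
    """
    groups = pd.Series(group_labels)
    groups = groups.reindex(count_matrix.columns)
    if groups.isna().any():
        raise ValueError("every library needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 libraries to estimate variation")

    if factors is None:
        factors = size_factors(count_matrix)
    s = factors.to_numpy(dtype=float)
    y = count_matrix.to_numpy(dtype=float) / s[None, :]  # normalised counts

    ya, yb = y[:, mask_a], y[:, mask_b]
    qa, qb = ya.mean(axis=1), yb.mean(axis=1)
    q0 = (n_a * qa + n_b * qb) / (n_a + n_b)

    # method-of-moments dispersion, pooled within groups:
    # Var(k/s) = q * mean(1/s) + alpha * q^2  =>  alpha = (v - q*m) / q^2
    inv_s = 1.0 / s
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_terms = []
        for yg, mask, q in ((ya, mask_a, qa), (yb, mask_b, qb)):
            v = yg.var(axis=1, ddof=1)
            m = inv_s[mask].mean()
            a_g = np.where(q > 0, (v - q * m) / np.maximum(q, 1e-300) ** 2, 0.0)
            disp_terms.append(((mask.sum() - 1) * a_g, mask.sum() - 1))
        alpha_raw = np.nan_to_num(
            (disp_terms[0][0] + disp_terms[1][0])
            / (disp_terms[0][1] + disp_terms[1][1])
        )

    # shrink toward the across-species median dispersion
    residual_df = n_a + n_b - 2
    informative = np.isfinite(alpha_raw) & (q0 > 0)
    prior = float(np.median(alpha_raw[informative])) if informative.any() else 0.0
    alpha_mod = (prior_df * prior + residual_df * alpha_raw) / (prior_df + residual_df)
    dispersion = np.clip(alpha_mod, dispersion_floor, None)

    # Wald variance of (mean_a - mean_b) under the pooled null mean q0.
    # The moderated (possibly slightly negative) dispersion enters here —
    # clipping it upward would systematically inflate the variance and make
    # the test conservative; the floored value is what gets reported.
    poisson_part = q0 * inv_s[mask_a].sum() / n_a**2 + q0 * inv_s[mask_b].sum() / n_b**2
    nb_part = alpha_mod * q0**2 * (1.0 / n_a + 1.0 / n_b)
    variance = np.maximum(poisson_part + nb_part, 0.01 * poisson_part)
    se = np.sqrt(np.maximum(variance, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, (qa - qb) / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=residual_df + prior_df)
    pvals = np.minimum(pvals, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]

    lfc = np.log2((qa + pseudocount) / (qb + pseudocount))
    table = pd.DataFrame(
        {
            "mean_a": qa,
            "mean_b": qb,
            "log2_fold_change": lfc,
            "dispersion": dispersion,
            "pvalue": pvals,
            "padj": padj,
        },
        index=count_matrix.index,
    )
    return DEResult(table=table, size_factors=factors, groups=groups, alpha=alpha)


def fold_changes(
    count_matrix: pd.DataFrame,
    library_a: str,
    library_b: str,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """Per-species log2 fold-change between two libraries.

    Computed as log2((a + c) / (b + c)) on size-factor-normalised counts
    with pseudocount c, so species absent from one library stay finite.
    """
    for lib in (library_a, library_b):
        if lib not in count_matrix.columns:
            raise ValueError(f"library {lib!r} not in count matrix")
    if factors is None:
        factors = size_factors(count_matrix)
    a = count_matrix[library_a] / factors[library_a]
    b = count_matrix[library_b] / factors[library_b]
    return np.log2((a + pseudocount) / (b + pseudocount)).rename(
        f"log2({library_a}/{library_b})"
    )
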