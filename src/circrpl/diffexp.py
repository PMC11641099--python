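"""Expression filtering, normalization, PCA and NB Wald differential expression.

The count model for one circRNA *i* in sample *j* is

    K_ij ~ NB(mu_ij, alpha_i),   Var = mu + alpha * mu^2
    mu_ij = s_j * q_i * 2^(beta_i * x_j)

where ``s_j`` is the sample's size factor (by default the raw library size,
so normalized counts are junction reads *per sequenced read* and baseMeans
land around 1e-6), ``x_j`` is the condition indicator (1 for RPL) and
``beta_i`` is the log2 fold change.  The gene-wise dispersion ``alpha_i``
is estimated by method of moments on the two-group fit (with an n/(n-2)
degrees-of-freedom correction and a 1e-8 floor), ``beta_i`` by maximum
likelihood with Newton iterations, and its standard error from the observed
Fisher information.  The Wald statistic beta/SE is referred to the standard
normal; p-values are Benjamini-Hochberg adjusted per project.  No dispersion
shrinkage, outlier filtering or independent filtering is applied.

A circRNA is significant when padj < alpha_fdr and |log2FC| > lfc_cut
(strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_formats import CountMatrix

LN2 = math.log(2.0)
ALPHA_FLOOR = 1e-8


class DesignError(ValueError):
    """The sample layout cannot support the requested analysis."""


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------


def filter_expressed(
    cm: CountMatrix, min_count: int = 5, min_fraction: float = 0.5
) -> CountMatrix:
    """Keep circRNAs with >= min_count reads in >= ceil(min_fraction * n) samples."""
    n = cm.counts.shape[1]
    need = math.ceil(min_fraction * n)
    passing = (cm.counts >= min_count).sum(axis=1) >= need
    return CountMatrix(cm.counts.loc[passing], cm.samples)


def size_factors(samples: pd.DataFrame, counts: pd.DataFrame | None = None,
                 mode: str = "library_size") -> pd.Series:
    """Per-sample size factors.

    ``library_size`` uses the total sequenced reads from the sample sheet;
    ``median_of_ratios`` is the classical pseudo-reference alternative,
    offered for comparison.
    """
    if mode == "library_size":
        s = samples["library_size"].astype(float)
        if (s <= 0).any():
            raise ValueError("library_size must be positive for normalization")
        return s
    if mode == "median_of_ratios":
        if counts is None:
            raise ValueError("median_of_ratios needs the count matrix")
        logc = np.log(counts.replace(0, np.nan))
        ref = logc.mean(axis=1)
        ratios = logc.sub(ref, axis=0)
        return np.exp(ratios.median(axis=0, skipna=True))
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize(cm: CountMatrix, mode: str = "library_size"):
    """Return (normalized matrix, size factors)."""
    s = size_factors(cm.samples, cm.counts, mode)
    return cm.counts.div(s, axis=1), s


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def run_pca(
    cm: CountMatrix,
    n_components: int = 2,
    pseudocount: float = 1e-8,
    mode: str = "library_size",
):
    """PCA of samples on log2(normalized + pseudocount) expression.

    Returns (scores DataFrame samples x PCs, variance-explained fractions).
    Component signs are fixed so the largest-magnitude loading is positive.
    """
    norm, _ = normalize(cm, mode)
    if cm.counts.shape[1] < n_components:
        raise DesignError("fewer samples than requested components")
    x = np.log2(norm.to_numpy(dtype=float).T + pseudocount)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=cm.counts.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------


@dataclass
class DEResult:
    name: str
    baseMean: float
    log2FoldChange: float
    lfcSE: float
    stat: float
    pvalue: float
    padj: float = float("nan")
    significant: bool = False
    zero_group: bool = False


def _mom_moments(k: np.ndarray, s: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Numerator and denominator of the MoM dispersion for one feature.

    Residual second moments carry an n/(n-2) correction for the two
    estimated group means.
    """
    n = k.size
    mu = np.empty(n)
    for g in (0, 1):
        m = x == g
        mu[m] = s[m] * (k[m].sum() / s[m].sum()) if k[m].sum() > 0 else 0.0
    num = float((((k - mu) ** 2) - mu).sum())
    if n > 2:
        num *= n / (n - 2)
    return num, float((mu**2).sum())


def _mom_dispersion(k: np.ndarray, s: np.ndarray, x: np.ndarray) -> float:
    """Per-feature method-of-moments NB dispersion, floored at 1e-8."""
    num, den = _mom_moments(k, s, x)
    if den == 0:
        return ALPHA_FLOOR
    return max(num / den, ALPHA_FLOOR)


def _nb_fit(k: np.ndarray, s: np.ndarray, x: np.ndarray, alpha: float):
    """Fit log mu_j = log s_j + c + b*x_j by Newton-Raphson at fixed alpha.

    Returns (c, b, se_b, converged).  ``b`` is on the natural-log scale.
    """
    m0, m1 = x == 0, x == 1
    zero_group = k[m0].sum() == 0 or k[m1].sum() == 0
    mean0 = (k[m0].sum() + (0.5 if zero_group else 0.0)) / s[m0].sum()
    mean1 = (k[m1].sum() + (0.5 if zero_group else 0.0)) / s[m1].sum()
    c = math.log(mean0)
    b = math.log(mean1) - math.log(mean0)

    def info(c: float, b: float):
        eta = c + b * x
        mu = s * np.exp(eta)
        w = mu * (1.0 + alpha * k) / (1.0 + alpha * mu) ** 2
        g = (k - mu) / (1.0 + alpha * mu)
        grad = np.array([g.sum(), (g * x).sum()])
        h00 = w.sum()
        h01 = (w * x).sum()
        hess = np.array([[h00, h01], [h01, h01]])  # x is 0/1 so x^2 = x
        return grad, hess, mu

    converged = False
    if not zero_group:
        for _ in range(60):
            grad, hess, _mu = info(c, b)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                break
            # dampen huge steps to keep exp() in range
            norm = float(np.abs(step).max())
            if norm > 5.0:
                step *= 5.0 / norm
            c += step[0]
            b += step[1]
            if float(np.abs(grad).max()) < 1e-10:
                converged = True
                break
    _grad, hess, _mu = info(c, b)
    try:
        cov = np.linalg.inv(hess)
        se_b = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_b = float("nan")
    return c, b, se_b, zero_group


def nb_wald_de(
    cm: CountMatrix,
    condition: pd.Series | None = None,
    alpha_fdr: float = 0.05,
    lfc_cut: float = 0.58,
    names: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-circRNA NB Wald test of RPL vs control.

    Returns a DataFrame with baseMean, log2FoldChange, lfcSE, stat, pvalue,
    padj and a significance flag.  Rows that are all-zero in both groups are
    reported with p = 1 rather than dropped.
    """
    if condition is None:
        condition = cm.samples["condition"]
    condition = condition.reindex(cm.counts.columns)
    if condition.isna().any():
        raise DesignError("condition labels missing for some samples")
    x = (condition == "RPL").to_numpy(dtype=float)
    if (x == 1).sum() < 2 or (x == 0).sum() < 2:
        raise DesignError("need at least 2 samples per condition")
    counts = cm.counts.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(np.int64)
    s = cm.samples["library_size"].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValueError("library_size must be positive")

    # pooled MoM dispersion across all features: at these sample sizes the
    # per-feature estimate is noisy and often collapses to zero, which would
    # understate the Wald SE, so each feature's dispersion is floored at the
    # pooled value
    num_tot, den_tot = 0.0, 0.0
    for i in range(counts.shape[0]):
        num, den = _mom_moments(counts[i].astype(float), s, x)
        num_tot += num
        den_tot += den
    pooled_alpha = max(num_tot / den_tot, ALPHA_FLOOR) if den_tot > 0 else ALPHA_FLOOR

    rows = []
    ids = list(cm.counts.index)
    labels = list(names.reindex(cm.counts.index)) if names is not None else ids
    for i, rid in enumerate(ids):
        k = counts[i].astype(float)
        base_mean = float((k / s).mean())
        if k.sum() == 0:
            rows.append(
                DEResult(labels[i], 0.0, 0.0, float("nan"), 0.0, 1.0, zero_group=True)
            )
            continue
        alpha = max(_mom_dispersion(k, s, x), pooled_alpha)
        _c, b, se_b, zero_group = _nb_fit(k, s, x, alpha)
        lfc = b / LN2
        lfc_se = se_b / LN2
        if lfc_se > 0 and math.isfinite(lfc_se):
            z = lfc / lfc_se
            p = 2.0 * stats.norm.sf(abs(z))
        else:
            z, p = 0.0, 1.0
        rows.append(DEResult(labels[i], base_mean, lfc, lfc_se, z, p, zero_group=zero_group))

    pvals = np.array([r.pvalue for r in rows])
    padj = bh_adjust(pvals)
    for r, q in zip(rows, padj):
        r.padj = float(q)
        r.significant = bool(q < alpha_fdr and abs(r.log2FoldChange) > lfc_cut)
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "baseMean": r.baseMean,
                "log2FoldChange": r.log2FoldChange,
                "lfcSE": r.lfcSE,
                "stat": r.stat,
                "pvalue": r.pvalue,
                "padj": r.padj,
                "significant": r.significant,
                "zero_group": r.zero_group,
            }
            for r in rows
        ]
    )
    df.index = pd.Index(ids, name="bsj_id")
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")  # stable for ties
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Cross-tissue overlap
# ---------------------------------------------------------------------------


def cross_tissue_overlap(sets: dict[str, set]) -> pd.DataFrame:
    """Venn-style region counts: one row per nonempty membership pattern."""
    names = sorted(sets)
    tally: dict[tuple[int, ...], int] = {}
    for el in set().union(*sets.values()) if sets else set():
        pattern = tuple(int(el in sets[n]) for n in names)
        tally[pattern] = tally.get(pattern, 0) + 1
    rows = [
        {**{n: b for n, b in zip(names, pat)}, "count": cnt}
        for pat, cnt in sorted(tally.items(), reverse=True)
    ]
    return pd.DataFrame(rows, columns=names + ["count"])


def shared_de(sets: dict[str, set]) -> set:
    """Elements significant in at least two projects."""
    counts: dict = {}
    for s in sets.values():
        for el in s:
            counts[el] = counts.get(el, 0) + 1
    return {el for el, c in counts.items() if c >= 2}
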