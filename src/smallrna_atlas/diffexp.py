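"""Negative-binomial differential expression for small RNA count data.

Implements the classic NB exact-test workflow for two-condition count
matrices: median-of-ratios size factors, pooled method-of-moments
dispersion estimation with a fitted mean-dispersion trend (parametric
``alpha(q) = a1/q + a0`` or a local running-median trend) and *maximum*
sharing (each feature keeps the larger of its own estimate and the
fitted value), the exact conditional NB test on group count sums,
fold changes with ``+/-Inf`` when exactly one group mean is zero,
Benjamini-Hochberg adjustment, and the variance-stabilizing
transformation derived from the fitted dispersion trend.

The count model is NB with variance ``v = q + alpha * q**2`` on the
common scale ``q`` (counts divided by size factors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: dispersion floor: prevents degenerate NB distributions
DISPERSION_FLOOR = 1e-8


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Features x samples integer counts plus the sample design.

    ``design`` must carry ``sample_id`` and ``condition`` (case/control)
    columns; its row order defines nothing — samples are matched by id.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(self.design["sample_id"])
        if missing:
            raise ValueError(f"samples without a design row: {sorted(missing)}")

    @property
    def conditions(self) -> pd.Series:
        cond = self.design.set_index("sample_id")["condition"]
        return cond.reindex(self.counts.columns)


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

def count_reads(features: pd.DataFrame, alignments: pd.DataFrame,
                multimap_policy: str = "all",
                strandedness: str = "ignore") -> pd.Series:
    """Per-feature alignment counts for one sample.

    Every alignment record overlapping a feature adds one count (so a
    read with k alignment records can contribute k counts — the default
    policy keeps multi-mapped piRNA reads in the analysis).  An
    alignment overlapping several features adds 1 to each under
    ``multimap_policy="all"``; under ``"unique"`` it is counted only
    when it overlaps exactly one feature.
    """
    if len(features) == 0:
        raise ValueError("feature set is empty")
    if multimap_policy not in ("all", "unique"):
        raise ValueError(f"unknown multimap_policy {multimap_policy!r}")
    out = np.zeros(len(features), dtype=np.int64)
    feats = features.reset_index(drop=True)
    keys = ["chrom", "strand"] if strandedness == "same" else ["chrom"]
    for key, fgrp in feats.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        sel = alignments
        for col, val in zip(keys, key):
            sel = sel[sel[col] == val]
        if sel.empty:
            continue
        fs = fgrp["start"].to_numpy()
        fe = fgrp["end"].to_numpy()
        fpos = fgrp.index.to_numpy()
        order = np.argsort(fs, kind="stable")
        fs, fe, fpos = fs[order], fe[order], fpos[order]
        if np.all(fs[1:] >= fe[:-1]):
            # non-overlapping features: each read hits a contiguous run
            lo = np.searchsorted(fe, sel["start"].to_numpy(), side="right")
            hi = np.searchsorted(fs, sel["end"].to_numpy(), side="left")
            hi = np.maximum(hi, lo)
            if multimap_policy == "unique":
                one = hi - lo == 1
                np.add.at(out, fpos[lo[one]], 1)
            else:
                diff = np.zeros(len(fgrp) + 1, dtype=np.int64)
                np.add.at(diff, lo, 1)
                np.add.at(diff, hi, -1)
                out[fpos] += np.cumsum(diff[:-1])
        else:  # rare: overlapping features, quadratic fallback
            for rs, re_ in zip(sel["start"].to_numpy(), sel["end"].to_numpy()):
                hits = np.flatnonzero((fs < re_) & (rs < fe))
                if multimap_policy == "unique" and hits.size != 1:
                    continue
                out[fpos[hits]] += 1
    name_col = "name" if "name" in feats else None
    index = feats[name_col] if name_col else feats.index
    return pd.Series(out, index=pd.Index(index, name="feature"), name="count")


def count_matrix(features: pd.DataFrame,
                 reads_by_sample: dict[str, pd.DataFrame],
                 design: pd.DataFrame, multimap_policy: str = "all",
                 strandedness: str = "ignore") -> CountMatrix:
    """Assemble the features x samples count matrix for a design table."""
    cols = {}
    for sample_id in design["sample_id"]:
        cols[sample_id] = count_reads(features, reads_by_sample[sample_id],
                                      multimap_policy, strandedness)
    return CountMatrix(counts=pd.DataFrame(cols), design=design)


# --------------------------------------------------------------------------
# size factors
# --------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``s_j`` is the median over features (restricted to
    features with a positive geometric mean, i.e. nonzero in every
    sample) of ``count_ij / geomean_i``.  All-equal samples get
    ``s_j = 1`` exactly; a single sample gets ``s = 1``.
    """
    mat = counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    log_geomean = logc.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; filter the "
            "matrix before estimating size factors")
    ratios = np.exp(logc[usable] - log_geomean[usable, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


# --------------------------------------------------------------------------
# dispersion estimation
# --------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Raw, fitted and final (maximum-shared) per-feature dispersions.

    ``base_mean`` is the mean of normalized counts across all samples.
    ``coeffs`` holds (a0, a1) for the parametric fit ``alpha(q) = a1/q +
    a0``; the local fit keeps a log-log running-median trend.
    """

    raw: pd.Series
    fitted: pd.Series
    final: pd.Series
    base_mean: pd.Series
    fit_type: str
    coeffs: tuple[float, float] | None = None
    _local_logq: np.ndarray | None = None
    _local_logd: np.ndarray | None = None

    def dispersion_at(self, q) -> np.ndarray:
        """Fitted dispersion trend evaluated at mean normalized count q."""
        q = np.asarray(q, dtype=float)
        if self.fit_type == "parametric":
            a0, a1 = self.coeffs
            with np.errstate(divide="ignore"):
                out = np.where(q > 0, a1 / np.maximum(q, 1e-300) + a0, np.inf)
            return out
        logd = np.interp(np.log(np.maximum(q, 1e-300)),
                         self._local_logq, self._local_logd)
        return np.exp(logd)


def _parametric_fit(qbar: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Gamma-family GLM fit of disp ~ 1/qbar with identity link, with an
    ordinary least-squares fallback; coefficients clipped non-negative."""
    import warnings

    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(qbar), 1.0 / qbar])
    a0 = a1 = None
    try:
        with warnings.catch_warnings():
            # identity link on Gamma is the standard mean-dispersion fit
            warnings.simplefilter("ignore")
            model = sm.GLM(disp, X, family=sm.families.Gamma(
                sm.families.links.Identity()))
            start = np.maximum(np.linalg.lstsq(X, disp, rcond=None)[0], 1e-6)
            res = model.fit(start_params=start, maxiter=100)
        a0, a1 = res.params
        if not np.all(np.isfinite([a0, a1])):
            raise ValueError("non-finite GLM fit")
    except Exception:  # fall back to least squares
        a0, a1 = np.linalg.lstsq(X, disp, rcond=None)[0]
    return float(max(a0, 1e-12)), float(max(a1, 0.0))


def _local_fit(qbar: np.ndarray, disp: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Running-median trend of log dispersion vs log mean (window = 10 %
    of features, at least 5)."""
    order = np.argsort(qbar, kind="stable")
    lq = np.log(qbar[order])
    ld = np.log(np.maximum(disp[order], DISPERSION_FLOOR))
    n = len(lq)
    w = max(5, int(round(0.1 * n)))
    half = w // 2
    med = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        med[i] = np.median(ld[lo:hi])
    # collapse duplicate abscissae for interpolation
    uniq_lq, idx = np.unique(lq, return_index=True)
    return uniq_lq, med[idx]


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         conditions: pd.Series,
                         fit_type: str = "parametric") -> DispersionModel:
    """Pooled method-of-moments dispersions with maximum sharing.

    Raw per-feature dispersions pool within-condition variability across
    all conditions that have replicates; the mean-dispersion trend is
    fitted parametrically (``a1/q + a0``) or as a local running-median
    trend, and the final dispersion is ``max(raw, fitted)`` (maximum
    sharing), floored at a small positive value.  Negative raw estimates
    (sub-Poisson variability) are floored to 0 before sharing.
    """
    if fit_type not in ("parametric", "local"):
        raise ValueError(f"unknown fit_type {fit_type!r}")
    cond = conditions.reindex(counts.columns)
    counts_arr = counts.to_numpy(float)
    sf_arr = sf.reindex(counts.columns).to_numpy(float)
    norm = counts_arr / sf_arr

    replicated = [c for c in cond.unique()
                  if (cond == c).sum() >= 2]
    if not replicated:
        raise ValueError("no condition has >= 2 samples: dispersion cannot "
                         "be estimated without replication")
    used = cond.isin(replicated).to_numpy()
    m = int(used.sum())
    k = len(replicated)
    qbar = norm[:, used].mean(axis=1)

    ss = np.zeros(len(counts))
    for c in replicated:
        cols = (cond == c).to_numpy()
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    base_var = ss / (m - k)
    xi = np.mean(1.0 / sf_arr[used])
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (base_var - xi * qbar) / qbar ** 2
    raw = np.where(qbar > 0, raw, np.nan)
    raw_floored = np.maximum(np.nan_to_num(raw, nan=0.0), 0.0)

    fit_mask = (qbar > 0) & (raw_floored > 0)
    if fit_mask.sum() < 2:
        # essentially Poisson data: flat trend at the floor
        coeffs = (DISPERSION_FLOOR, 0.0)
        model = DispersionModel(
            raw=pd.Series(raw_floored, index=counts.index),
            fitted=pd.Series(DISPERSION_FLOOR, index=counts.index),
            final=pd.Series(np.maximum(raw_floored, DISPERSION_FLOOR),
                            index=counts.index),
            base_mean=pd.Series(norm.mean(axis=1), index=counts.index),
            fit_type="parametric", coeffs=coeffs)
        return model

    if fit_type == "parametric":
        a0, a1 = _parametric_fit(qbar[fit_mask], raw_floored[fit_mask])
        model = DispersionModel(
            raw=None, fitted=None, final=None, base_mean=None,
            fit_type="parametric", coeffs=(a0, a1))
    else:
        lq, ld = _local_fit(qbar[fit_mask], raw_floored[fit_mask])
        model = DispersionModel(
            raw=None, fitted=None, final=None, base_mean=None,
            fit_type="local", _local_logq=lq, _local_logd=ld)

    fitted = np.where(qbar > 0, model.dispersion_at(np.maximum(qbar, 1e-300)),
                      np.nan)
    fitted = np.nan_to_num(fitted, nan=DISPERSION_FLOOR, posinf=np.inf)
    final = np.maximum(np.maximum(raw_floored, np.minimum(fitted, 1e6)),
                       DISPERSION_FLOOR)
    model.raw = pd.Series(raw_floored, index=counts.index, name="raw")
    model.fitted = pd.Series(fitted, index=counts.index, name="fitted")
    model.final = pd.Series(final, index=counts.index, name="final")
    model.base_mean = pd.Series(norm.mean(axis=1), index=counts.index,
                                name="baseMean")
    return model


# --------------------------------------------------------------------------
# exact NB test
# --------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log PMF of an NB with given mean/variance (Poisson when var <= mu)."""
    if mu <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(k, mu)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    return stats.nbinom.logpmf(k, size, p)


def nbinom_exact_pvalue(k_a: int, k_b: int, s_a: float, s_b: float,
                        s2_a: float, s2_b: float, alpha: float) -> float:
    """Exact conditional NB test p-value for one feature.

    Conditions on the total ``K = k_a + k_b``: with the pooled rate
    ``q = K / (s_a + s_b)`` the group sums are modelled as independent
    NB variables with means ``q * s_g`` and variances ``q * s_g + alpha
    * q**2 * s2_g`` (``s_g``/``s2_g``: sum of size factors / of squared
    size factors in group g).  The p-value is the total probability of
    all splits ``(a, K - a)`` no more likely than the observed one,
    normalized by the probability of all splits.
    """
    K = k_a + k_b
    if K == 0:
        return 1.0
    q = K / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    var_a = mu_a + alpha * q * q * s2_a
    var_b = mu_b + alpha * q * q * s2_b
    ks = np.arange(K + 1)
    logps = _nb_logpmf(ks, mu_a, var_a) + _nb_logpmf(ks[::-1], mu_b, var_b)
    log_obs = logps[k_a]
    log_denom = logsumexp(logps)
    le = logps <= log_obs
    if not le.any():
        return 0.0
    log_num = logsumexp(logps[le])
    return float(min(np.exp(log_num - log_denom), 1.0))


def nbinom_test(counts: pd.DataFrame, sf: pd.Series,
                dispersions: pd.Series, conditions: pd.Series,
                case: str = "case", control: str = "control") -> pd.Series:
    """Exact NB test p-values for every feature.

    Features with zero counts in all samples get p = 1.  Swapping the
    case/control labels leaves the p-values unchanged (the test is
    exchangeable in the two groups).
    """
    cond = conditions.reindex(counts.columns)
    sf = sf.reindex(counts.columns)
    a_cols = (cond == case).to_numpy()
    b_cols = (cond == control).to_numpy()
    if a_cols.sum() == 0 or b_cols.sum() == 0:
        raise ValueError("both conditions must have at least one sample")
    missing = dispersions.reindex(counts.index).isna()
    if missing.any():
        raise ValueError(
            f"dispersion missing for {int(missing.sum())} tested features")
    arr = counts.to_numpy()
    s = sf.to_numpy(float)
    s_a, s_b = s[a_cols].sum(), s[b_cols].sum()
    s2_a, s2_b = (s[a_cols] ** 2).sum(), (s[b_cols] ** 2).sum()
    disp = dispersions.reindex(counts.index).to_numpy(float)
    pvals = np.ones(len(counts))
    for i in range(len(counts)):
        k_a = int(arr[i, a_cols].sum())
        k_b = int(arr[i, b_cols].sum())
        pvals[i] = nbinom_exact_pvalue(k_a, k_b, s_a, s_b, s2_a, s2_b,
                                       float(disp[i]))
    return pd.Series(pvals, index=counts.index, name="pvalue")


# --------------------------------------------------------------------------
# fold changes, adjustment, significance
# --------------------------------------------------------------------------

def fold_change(counts: pd.DataFrame, sf: pd.Series, conditions: pd.Series,
                case: str = "case", control: str = "control") -> pd.DataFrame:
    """Group means of normalized counts, baseMean and log2 fold change.

    log2FC is ``+Inf``/``-Inf`` when exactly one group mean is zero and
    NaN (missing) when both are zero.
    """
    cond = conditions.reindex(counts.columns)
    norm = counts.to_numpy(float) / sf.reindex(counts.columns).to_numpy(float)
    mean_case = norm[:, (cond == case).to_numpy()].mean(axis=1)
    mean_control = norm[:, (cond == control).to_numpy()].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(mean_case / mean_control)
    l2fc = np.where((mean_case == 0) & (mean_control == 0), np.nan, l2fc)
    return pd.DataFrame({
        "baseMean": norm.mean(axis=1),
        "mean_case": mean_case,
        "mean_control": mean_control,
        "log2FoldChange": l2fc,
    }, index=counts.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nbinom_de(cm: CountMatrix, fit_type: str = "parametric") -> pd.DataFrame:
    """Full differential-expression pass on a count matrix.

    Returns per-feature ``baseMean``, ``log2FoldChange`` (case vs
    control), ``pvalue`` and BH-``padj``.
    """
    sf = size_factors(cm.counts)
    cond = cm.conditions
    model = estimate_dispersions(cm.counts, sf, cond, fit_type=fit_type)
    pvals = nbinom_test(cm.counts, sf, model.final, cond)
    fc = fold_change(cm.counts, sf, cond)
    out = fc[["baseMean", "log2FoldChange"]].copy()
    out["pvalue"] = pvals
    out["padj"] = bh_adjust(pvals.to_numpy())
    return out


def filter_significant(results: pd.DataFrame, threshold: float = 1e-6,
                       on: str = "padj") -> pd.DataFrame:
    """Features with adjusted p strictly below the threshold, sorted by
    significance then by absolute fold change (infinite first)."""
    sig = results[results[on] < threshold].copy()
    sig["_absfc"] = sig["log2FoldChange"].abs()
    sig = sig.sort_values([on, "_absfc"], ascending=[True, False],
                          kind="stable").drop(columns="_absfc")
    return sig


# --------------------------------------------------------------------------
# variance-stabilizing transformation
# --------------------------------------------------------------------------

def vst(counts: pd.DataFrame, sf: pd.Series,
        model: DispersionModel) -> pd.DataFrame:
    """Variance-stabilizing transformation of normalized counts.

    The transform integrates ``1 / sqrt(q + alpha(q) q^2)`` along the
    fitted dispersion trend.  For the parametric trend ``alpha(q) = a1/q
    + a0`` (variance ``(1 + a1) q + a0 q^2``) the closed form is

        vst(q) = log2( (2 a0 q + b + 2 sqrt(a0 (a0 q^2 + b q))) / (4 a0) )

    with ``b = 1 + a1``; for large q this approaches ``log2 q`` plus a
    constant.  For the local trend the integral is evaluated by
    quadrature on a grid and rescaled so the upper range matches the
    log2 scale.
    """
    if model.fitted is None:
        raise ValueError("dispersion model has not been fitted")
    norm = counts.to_numpy(float) / sf.reindex(counts.columns).to_numpy(float)
    if model.fit_type == "parametric":
        a0, a1 = model.coeffs
        a0 = max(a0, 1e-12)
        b = 1.0 + a1
        q = norm
        inner = 2.0 * a0 * q + b + 2.0 * np.sqrt(a0 * (a0 * q * q + b * q))
        out = np.log2(inner / (4.0 * a0))
    else:
        qmax = max(norm.max(), 1.0)
        grid = np.linspace(0.0, np.sqrt(qmax), 2049) ** 2  # dense near 0
        alpha_g = model.dispersion_at(np.maximum(grid, 1e-12))
        with np.errstate(divide="ignore"):
            integrand = 1.0 / np.sqrt(grid + alpha_g * grid ** 2)
        integrand[0] = integrand[1]
        from scipy.integrate import cumulative_trapezoid
        u = cumulative_trapezoid(integrand, grid, initial=0.0)
        a_inf = float(model.dispersion_at(qmax))
        scale = np.sqrt(max(a_inf, 1e-12)) / np.log(2.0)
        offset = np.log2(qmax) - u[-1] * scale
        out = np.interp(norm, grid, u) * scale + offset
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)
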