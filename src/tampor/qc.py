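"""Quality-control and evaluation metrics for batch-corrected abundance.

All functions take **log2** matrices (features x samples) with ``NaN`` for
missing values. Inter-sample correlation metrics are meant to be applied on
the dimensionless ratio scale (naive ratio output, or corrected abundance
divided by its restored row medians — :meth:`CorrectionResult.ratio_matrix`),
where the inter-feature dynamic range has been removed by construction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "mean_sd_series",
    "MDSEmbedding",
    "classical_mds",
    "variance_explained",
    "pearson_corr",
    "bicor",
    "ReplicatePairReport",
    "replicate_pair_analysis",
    "CorrelationShift",
    "all_pair_correlation_shift",
    "differential_abundance",
]


def mean_sd_series(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean and sample SD (ddof=1) of log2 abundance, ranked by
    mean descending. Features with fewer than two present values are
    excluded (their count is logged)."""
    vals = log2_matrix.to_numpy(float)
    n = np.sum(~np.isnan(vals), axis=1)
    ok = n >= 2
    if (~ok).any():
        logger.warning("mean_sd_series: %d features with <2 present values excluded",
                       int((~ok).sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    out = pd.DataFrame(
        {"mean": mean[ok], "sd": sd[ok], "n_present": n[ok]},
        index=log2_matrix.index[ok],
    ).sort_values("mean", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class MDSEmbedding:
    """Classical (Torgerson) scaling of inter-sample distances."""

    coordinates: pd.DataFrame  # samples x dimensions, centered at the origin
    eigenvalues: np.ndarray


def _pairwise_complete_sqdist(vals: np.ndarray, columns) -> np.ndarray:
    """Squared Euclidean distances over pairwise-complete features, rescaled
    by total / shared feature counts to stay comparable under missingness."""
    n_feat, n_samp = vals.shape
    finite = (~np.isnan(vals)).astype(float)
    filled = np.where(np.isnan(vals), 0.0, vals)
    shared = finite.T @ finite
    if (shared < 1).any():
        i, j = np.argwhere((shared < 1) & ~np.eye(n_samp, dtype=bool))[0]
        raise ValueError(
            f"samples {columns[i]!r} and {columns[j]!r} share no present features"
        )
    part = (filled**2).T @ finite  # sum_f x_if^2 over features present in both
    d2 = part + part.T - 2 * filled.T @ filled
    d2 = np.maximum(d2, 0.0) * (n_feat / shared)
    np.fill_diagonal(d2, 0.0)
    return d2


def classical_mds(log2_matrix: pd.DataFrame, n_dims: int = 2) -> MDSEmbedding:
    """Embed samples by classical multidimensional scaling of Euclidean
    distances (pairwise-complete, shared-feature rescaled).

    Coordinates are centered at the origin; with complete data and a
    full-rank embedding the inter-sample distances are reproduced exactly.
    """
    n_samp = log2_matrix.shape[1]
    if n_dims > n_samp - 1:
        raise ValueError("n_dims must be <= n_samples - 1")
    d2 = _pairwise_complete_sqdist(log2_matrix.to_numpy(float), list(log2_matrix.columns))
    j = np.eye(n_samp) - np.ones((n_samp, n_samp)) / n_samp
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:n_dims], 0.0, None)
    lam[lam < 1e-12 * max(evals.max(), 0.0)] = 0.0  # numerical-noise modes
    coords = evecs[:, :n_dims] * np.sqrt(lam)[None, :]
    coords = coords - coords.mean(0)  # numerically exact centering
    return MDSEmbedding(
        coordinates=pd.DataFrame(
            coords,
            index=log2_matrix.columns,
            columns=[f"dim{i + 1}" for i in range(n_dims)],
        ),
        eigenvalues=evals,
    )


def _categorical_fraction(vals: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature one-way variance-component fraction (method of moments,
    truncated at zero) for one categorical factor."""
    levels = pd.unique(labels)
    n_feat = vals.shape[0]
    finite = ~np.isnan(vals)
    counts = np.zeros((n_feat, len(levels)))
    sums = np.zeros((n_feat, len(levels)))
    sqs = np.zeros((n_feat, len(levels)))
    for li, lev in enumerate(levels):
        sub = vals[:, labels == lev]
        fin = finite[:, labels == lev]
        counts[:, li] = fin.sum(1)
        sums[:, li] = np.where(fin, sub, 0.0).sum(1)
        sqs[:, li] = np.where(fin, sub**2, 0.0).sum(1)
    # drop levels with <1 present value per feature via masking
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    used = counts > 0
    k = used.sum(1)
    n_tot = counts.sum(1)
    grand = sums.sum(1) / n_tot
    ssb = np.nansum(counts * (means - grand[:, None]) ** 2, axis=1)
    ssw = np.nansum(sqs - counts * means**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / (k - 1)
        msw = ssw / (n_tot - k)
        n0 = (n_tot - (counts**2).sum(1) / n_tot) / (k - 1)
        sb = np.maximum(0.0, (msb - msw) / n0)
        frac = sb / (sb + msw)
    frac = np.where((k < 2) | (n_tot - k < 1), np.nan, frac)
    return frac


def _continuous_fraction(vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-feature squared Pearson correlation with a numeric trait."""
    out = np.full(vals.shape[0], np.nan)
    for i in range(vals.shape[0]):
        fin = ~np.isnan(vals[i]) & ~np.isnan(x)
        if fin.sum() < 3:
            continue
        xi, yi = x[fin], vals[i, fin]
        if np.std(xi) == 0 or np.std(yi) == 0:
            out[i] = 0.0
            continue
        out[i] = np.corrcoef(xi, yi)[0, 1] ** 2
    return out


def variance_explained(
    log2_matrix: pd.DataFrame, annotation: pd.DataFrame, factors
) -> pd.DataFrame:
    """Per-feature fraction of variance explained by each factor.

    Categorical factors are scored marginally (one at a time) by a one-way
    between/within variance-component decomposition (method of moments,
    truncated at zero); continuous traits by squared Pearson correlation.
    This is a deliberately simple approximation of mixed-model variance
    partitioning.

    Returns a DataFrame with one column per factor, a ``residual`` column
    (``1 - sum`` truncated at zero; fractions are rescaled to sum to one in
    the rare case marginal estimates exceed one) and a boolean ``constant``
    flag for features without variance (their fractions are zero).
    """
    ann = annotation.loc[list(log2_matrix.columns)]
    vals = log2_matrix.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        constant = np.nanstd(vals, axis=1) == 0
    out = {}
    for f in factors:
        col = ann[f]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            frac = _continuous_fraction(vals, col.to_numpy(float))
        else:
            labels = col.astype(str).to_numpy()
            lev_counts = pd.Series(labels).value_counts()
            if (lev_counts >= 2).sum() < 2:
                raise ValueError(
                    f"factor {f!r} needs >= 2 levels with >= 2 samples each"
                )
            frac = _categorical_fraction(vals, labels)
        out[f] = np.where(constant, 0.0, frac)
    table = pd.DataFrame(out, index=log2_matrix.index)
    total = table.sum(axis=1)
    over = total > 1
    if over.any():
        table.loc[over] = table.loc[over].div(total[over], axis=0)
    table["residual"] = np.where(constant, 0.0, np.maximum(0.0, 1.0 - table.sum(axis=1)))
    table["constant"] = constant
    return table


def pearson_corr(x, y) -> float:
    """Product-moment correlation over pairwise-complete values.

    Returns ``NaN`` (with a log note) when fewer than 3 pairs are present
    or either vector has zero variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fin = ~np.isnan(x) & ~np.isnan(y)
    if fin.sum() < 3:
        logger.warning("pearson_corr: <3 shared present values")
        return float("nan")
    xi, yi = x[fin], y[fin]
    if np.std(xi) == 0 or np.std(yi) == 0:
        logger.warning("pearson_corr: zero variance")
        return float("nan")
    return float(np.corrcoef(xi, yi)[0, 1])


def _biweight(v: np.ndarray) -> np.ndarray | None:
    """Tukey-biweight-deviation vector; None when the MAD is zero."""
    med = np.median(v)
    mad = np.median(np.abs(v - med))  # raw MAD, no 1.4826 scaling
    if mad == 0:
        return None
    u = (v - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    return (v - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation: a median/MAD-based robust correlation.

    Deviations from the median are down-weighted by Tukey's biweight
    ``w = (1 - u^2)^2`` for ``|u| < 1`` with ``u = (v - median) / (9 MAD)``
    (raw MAD); values beyond the window get zero weight.  Returns ``NaN``
    when the MAD of either vector is zero or fewer than 3 pairs exist.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fin = ~np.isnan(x) & ~np.isnan(y)
    if fin.sum() < 3:
        logger.warning("bicor: <3 shared present values")
        return float("nan")
    a = _biweight(x[fin])
    b = _biweight(y[fin])
    if a is None or b is None:
        logger.warning("bicor: zero MAD, correlation undefined")
        return float("nan")
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return float("nan")
    return float((a * b).sum() / denom)


def _corr_matrix(vals: np.ndarray, method: str) -> np.ndarray:
    """Sample x sample correlation matrix over features (complete-data fast
    path; falls back to pairwise loops when missing values are present)."""
    n = vals.shape[1]
    if not np.isnan(vals).any():
        if method == "pearson":
            return np.corrcoef(vals.T)
        xt = np.empty_like(vals)
        ok = np.ones(n, bool)
        for j in range(n):
            b = _biweight(vals[:, j])
            if b is None:
                ok[j] = False
                xt[:, j] = np.nan
            else:
                xt[:, j] = b / np.sqrt((b**2).sum())
        c = xt.T @ xt
        c[~ok, :] = np.nan
        c[:, ~ok] = np.nan
        return c
    fn = pearson_corr if method == "pearson" else bicor
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c[i, j] = c[j, i] = fn(vals[:, i], vals[:, j])
    return c


@dataclass
class ReplicatePairReport:
    """Before/after correlation comparison over technical replicate pairs."""

    per_pair: pd.DataFrame  # sample_a, sample_b, r_before, r_after, delta
    n_improved: int
    n_worsened: int
    n_unchanged: int
    mean_abs_delta_improved: float
    sem_abs_delta_improved: float
    mean_abs_delta_worsened: float
    sem_abs_delta_worsened: float
    t_statistic: float
    p_value: float  # one-tailed: |delta| improved > |delta| worsened
    excluded_pairs: list = field(default_factory=list)


def replicate_pair_analysis(
    before: pd.DataFrame, after: pd.DataFrame, pairs
) -> ReplicatePairReport:
    """Compare each replicate pair's Pearson correlation before vs after
    correction.

    ``pairs`` is an iterable of (sample_a, sample_b). Correlations use the
    features shared by both matrices (pairwise-complete). Pairs with fewer
    than 3 shared present values are excluded with a warning. The one-tailed
    Welch t-test asks whether the mean absolute gain of improved pairs
    exceeds the mean absolute loss of worsened pairs.
    """
    shared = before.index.intersection(after.index)
    rows = []
    excluded = []
    for a, b in pairs:
        if a not in before.columns or b not in before.columns:
            raise ValueError(f"pair ({a!r}, {b!r}) not found in matrices")
        rb = pearson_corr(before.loc[shared, a], before.loc[shared, b])
        ra = pearson_corr(after.loc[shared, a], after.loc[shared, b])
        if np.isnan(rb) or np.isnan(ra):
            warnings.warn(f"replicate pair ({a}, {b}) excluded: correlation undefined",
                          stacklevel=2)
            excluded.append((a, b))
            continue
        rows.append({"sample_a": a, "sample_b": b, "r_before": rb, "r_after": ra,
                     "delta": ra - rb})
    per_pair = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r_before",
                                           "r_after", "delta"])
    d = per_pair["delta"].to_numpy() if len(per_pair) else np.array([])
    up, down = d[d > 0], d[d < 0]
    if len(up) >= 2 and len(down) >= 2:
        tt = stats.ttest_ind(np.abs(up), np.abs(down), equal_var=False,
                             alternative="greater")
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    else:
        logger.warning("replicate_pair_analysis: t-test undefined "
                       "(needs >=2 improved and >=2 worsened pairs)")
        t_stat, p = float("nan"), float("nan")

    def _sem(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else float("nan")

    return ReplicatePairReport(
        per_pair=per_pair,
        n_improved=int((d > 0).sum()),
        n_worsened=int((d < 0).sum()),
        n_unchanged=int((d == 0).sum()),
        mean_abs_delta_improved=float(np.mean(np.abs(up))) if len(up) else float("nan"),
        sem_abs_delta_improved=_sem(np.abs(up)),
        mean_abs_delta_worsened=float(np.mean(np.abs(down))) if len(down) else float("nan"),
        sem_abs_delta_worsened=_sem(np.abs(down)),
        t_statistic=t_stat,
        p_value=p,
        excluded_pairs=excluded,
    )


@dataclass
class CorrelationShift:
    """Distribution of correlation changes over all non-replicate sample
    pairs."""

    deltas: pd.Series  # indexed by (sample_a, sample_b)
    mean_before: float
    mean_after: float
    mean_delta: float
    n_pairs: int


def all_pair_correlation_shift(
    before: pd.DataFrame,
    after: pd.DataFrame,
    method: str = "pearson",
    exclude_pairs=(),
) -> CorrelationShift:
    """Score every unordered non-replicate sample pair before vs after.

    ``exclude_pairs`` lists replicate pairs to drop; with ``n`` samples and
    ``r`` replicate pairs the result holds ``n (n-1) / 2 - r`` entries.
    """
    if method not in ("pearson", "bicor"):
        raise ValueError("method must be 'pearson' or 'bicor'")
    if list(before.columns) != list(after.columns):
        raise ValueError("before/after must hold the same samples in the same order")
    shared = before.index.intersection(after.index)
    cols = list(before.columns)
    cb = _corr_matrix(before.loc[shared].to_numpy(float), method)
    ca = _corr_matrix(after.loc[shared].to_numpy(float), method)
    excl = {frozenset(p) for p in exclude_pairs}
    names, db, da = [], [], []
    for i, j in itertools.combinations(range(len(cols)), 2):
        if frozenset((cols[i], cols[j])) in excl:
            continue
        names.append((cols[i], cols[j]))
        db.append(cb[i, j])
        da.append(ca[i, j])
    db, da = np.asarray(db), np.asarray(da)
    return CorrelationShift(
        deltas=pd.Series(da - db, index=pd.MultiIndex.from_tuples(names)),
        mean_before=float(np.nanmean(db)),
        mean_after=float(np.nanmean(da)),
        mean_delta=float(np.nanmean(da - db)),
        n_pairs=len(names),
    )


def differential_abundance(
    log2_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    group_a: str,
    group_b: str,
    trait: str = "group",
    exclude_gis: bool = True,
) -> pd.DataFrame:
    """Welch two-sample t-test per feature between two annotation groups.

    ``log2_fc`` is ``mean(group_a) - mean(group_b)`` of log2 values.
    Features with fewer than 2 present values in either group, or zero
    variance in both, are flagged untestable (``NaN`` statistics) and
    excluded from the Benjamini-Hochberg adjustment.
    """
    ann = annotation.loc[list(log2_matrix.columns)]
    mask = ann[trait].isin([group_a, group_b])
    if exclude_gis and "is_gis" in ann.columns:
        mask &= ~ann["is_gis"].astype(bool)
    sub = log2_matrix.loc[:, mask.to_numpy()]
    grp = ann.loc[mask.to_numpy(), trait]
    va = sub.loc[:, (grp == group_a).to_numpy()].to_numpy(float)
    vb = sub.loc[:, (grp == group_b).to_numpy()].to_numpy(float)
    na = (~np.isnan(va)).sum(1)
    nb = (~np.isnan(vb)).sum(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(va, axis=1), np.nanmean(vb, axis=1)
        sa2 = np.nanvar(va, axis=1, ddof=1)
        sb2 = np.nanvar(vb, axis=1, ddof=1)
    testable = (na >= 2) & (nb >= 2) & ((sa2 > 0) | (sb2 > 0))
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info("differential_abundance: %d features untestable", n_skip)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = sa2 / na + sb2 / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((sa2 / na) ** 2 / (na - 1) + (sb2 / nb) ** 2 / (nb - 1))
    p = np.full(len(t), np.nan)
    p[testable] = 2 * stats.t.sf(np.abs(t[testable]), df[testable])
    padj = np.full(len(t), np.nan)
    if testable.any():
        padj[testable] = multipletests(p[testable], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_fc": ma - mb,
            "t": np.where(testable, t, np.nan),
            "p_value": p,
            "p_adjusted": padj,
            "n_a": na,
            "n_b": nb,
            "testable": testable,
        },
        index=log2_matrix.index,
    )
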