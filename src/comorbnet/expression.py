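"""Expression processing: QC, TMM normalization, filtering and moderated DE.

The differential-expression model is an unweighted per-gene least-squares
fit of log2CPM on condition (case vs control) plus study indicators, with
empirical-Bayes variance moderation: residual variances s^2 with d degrees
of freedom are shrunk toward a prior s0^2 with prior degrees of freedom d0,

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

where (d0, s0^2) are estimated by moment-matching on log s^2 using
digamma/trigamma equations (the scaled-F model of moderated t statistics).
The moderated t is logFC / (s~ * sqrt(v)) on d0 + d degrees of freedom,
with Benjamini-Hochberg q-values; genes at q <= 0.05 are the sDEGs.

TMM (trimmed mean of M-values) between-sample factors follow the standard
doubly trimmed, precision-weighted mean of gene-wise log ratios against a
reference column, rescaled to geometric mean one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import AnalysisError, ConfigError, DifferentialProfile, ExpressionMatrix, SampleTable

log = logging.getLogger(__name__)

__all__ = [
    "bh_fdr",
    "qc_filter",
    "tmm_factors",
    "log2cpm",
    "normalize",
    "fit_de",
    "remove_batch",
    "fit_fdist_moments",
    "trigamma_inverse",
]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( n * p_(j) / j ), clipped to 1; order-preserving
    and element-wise >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    table: SampleTable,
    min_aligned: float = 70.0,
    min_cases: int = 3,
) -> SampleTable:
    """Drop poorly aligned samples, then inadequate whole studies.

    A sample is removed when its percent of reads aligned to the genome is
    below ``min_aligned``. A study is then removed entirely when fewer than
    ``min_cases`` of its case samples survive, or no control does.
    """
    md = table.metadata
    good = md["percent_aligned"] >= min_aligned
    n_dropped = int((~good).sum())
    if n_dropped:
        log.info("qc_filter: removed %d samples below %.1f%% aligned", n_dropped, min_aligned)
    md = md[good]

    keep_parts = []
    for study, grp in md.groupby("study", sort=False):
        n_case = int((grp["condition"] == "case").sum())
        n_ctrl = int((grp["condition"] == "control").sum())
        if n_case < min_cases or n_ctrl == 0:
            log.info(
                "qc_filter: removed study %s (%d cases, %d controls surviving)",
                study, n_case, n_ctrl,
            )
            continue
        keep_parts.append(grp)
    if not keep_parts:
        raise AnalysisError("no analyzable data: every sample or study removed by QC")
    md = pd.concat(keep_parts).reset_index(drop=True)
    return SampleTable(
        counts=table.counts[list(md["sample_id"])],
        metadata=md,
        truth=table.truth,
    )


# ---------------------------------------------------------------------------
# TMM + log2CPM
# ---------------------------------------------------------------------------

def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_logratio: float,
    trim_abs: float,
) -> float:
    """One sample's TMM factor against the reference column (unscaled)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        po, pr = obs / lib_obs, ref / lib_ref
        logR = np.log2(po / pr)
        absE = (np.log2(po) + np.log2(pr)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(logR) & np.isfinite(absE)
    if not fin.any():
        log.warning("tmm_factors: sample shares no co-expressed genes with reference; factor 1")
        return 1.0
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * trim_logratio) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * trim_abs) + 1
    hiS = n + 1 - loS
    rL, rS = _rank_average(logR), _rank_average(absE)
    keep = (rL >= loL) & (rL <= hiL) & (rS >= loS) & (rS <= hiS)
    if not keep.any():
        log.warning("tmm_factors: trimming removed all genes; factor 1")
        return 1.0
    f = np.nansum(logR[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_logratio: float = 0.3,
    trim_abs: float = 0.05,
) -> pd.Series:
    """TMM scaling factors, geometric mean one.

    The reference sample is the column whose 75th percentile of
    library-scaled counts is closest to the mean such percentile.
    """
    if counts.shape[1] < 2:
        raise ConfigError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ConfigError("zero library size")
    q75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_logratio, trim_abs)
            for j in range(x.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def log2cpm(
    counts: pd.DataFrame,
    norm_factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a depth-invariant prior count.

    Effective library sizes are lib * f_j. The prior is expressed on the
    CPM scale (``prior_count`` CPM-equivalents) and scaled to each sample's
    own effective library size, p_j = prior_count * L_j / 1e6, with the
    library size inflated by twice the prior. Because p_j is proportional
    to L_j alone, the transform is exactly invariant to rescaling any one
    sample's counts; at a balanced 1M-read library it reduces to the usual
    0.5 pseudo-count.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns).to_numpy()
    prior = prior_count * lib / 1e6
    vals = np.log2((x + prior[None, :]) / (lib + 2 * prior)[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def normalize(
    table: SampleTable,
    min_logcpm: float = 1.0,
    max_low_frac: float = 0.20,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """Within-sample log2CPM, low-expression filter, then TMM.

    Genes with log2CPM below ``min_logcpm`` in strictly more than
    ``max_low_frac`` of the samples are removed (computed on plain log2CPM,
    before between-sample normalization); library sizes are recomputed on
    the retained genes and TMM factors estimated on them; the returned
    matrix is log2CPM under the TMM-effective library sizes.
    """
    raw = log2cpm(table.counts, norm_factors=None, prior_count=prior_count)
    frac_low = (raw < min_logcpm).mean(axis=1)
    keep = frac_low <= max_low_frac
    if not keep.any():
        raise AnalysisError("no genes survive the low-expression filter")
    counts = table.counts.loc[keep]
    lib = counts.sum(axis=0)
    factors = tmm_factors(counts)
    values = log2cpm(counts, norm_factors=factors, prior_count=prior_count)
    return ExpressionMatrix(
        values=values,
        norm_factors=factors,
        lib_sizes=lib,
        metadata=table.metadata.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_fdist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Given gene-wise variances ``s2`` each on ``df`` residual degrees of
    freedom, returns (d0, s0^2): the prior degrees of freedom and prior
    variance such that s2/s0^2 ~ F(df, d0). Uses the log-variance mean and
    variance with digamma/trigamma corrections; d0 = inf when the observed
    spread of log s2 is no larger than the chi-square sampling spread.
    Genes with nonpositive variance are excluded.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise AnalysisError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2)
    e = z - special.psi(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.psi(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


# ---------------------------------------------------------------------------
# design matrices and DE
# ---------------------------------------------------------------------------

def _design_matrix(metadata: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + condition + covariate dummies, dropping aliased columns.

    Columns enter in a fixed order (condition first, then covariate levels
    sorted lexicographically) and a column is dropped when it does not
    increase the design rank. A drop of the condition column itself means
    case/control status is confounded with the covariates and is an error.
    """
    n = len(metadata)
    cond = (metadata["condition"] == "case").to_numpy(dtype=float)
    if cond.min() == cond.max():
        raise AnalysisError("need both cases and controls to fit a contrast")
    cols = [np.ones(n)]
    names = ["intercept"]
    candidates: list[tuple[str, np.ndarray]] = [("condition", cond)]
    for cov in covariates:
        levels = sorted(metadata[cov].unique())
        if len(levels) < 2:
            log.info("fit_de: covariate %r has a single level; dropped", cov)
            continue
        for lev in levels[1:]:  # first level is the reference
            candidates.append((f"{cov}[{lev}]", (metadata[cov] == lev).to_numpy(dtype=float)))
    # the contrast must not be expressible from the intercept and covariates
    cov_cols = [c for nme, c in candidates if nme != "condition"]
    base = np.column_stack([np.ones(n)] + cov_cols)
    if np.linalg.matrix_rank(np.column_stack([base, cond])) == np.linalg.matrix_rank(base):
        cov_names = [nme for nme, _ in candidates if nme != "condition"]
        raise AnalysisError(
            "condition is aliased with the design "
            f"({', '.join(cov_names) or 'intercept'}); contrast not estimable"
        )
    for name, col in candidates:
        trial = np.column_stack(cols + [col])
        if np.linalg.matrix_rank(trial) > len(cols):
            cols.append(col)
            names.append(name)
        else:
            log.info("fit_de: dropping aliased column %s", name)
    return np.column_stack(cols), names


def fit_de(
    expr: ExpressionMatrix,
    phenotype: str,
    covariates: tuple[str, ...] = ("study",),
    sdeg_threshold: float = 0.05,
    kind: str = "disease",
    family: str | None = None,
) -> DifferentialProfile:
    """Study-adjusted moderated differential expression for one phenotype."""
    X, names = _design_matrix(expr.metadata, covariates)
    Y = expr.values.to_numpy().T  # samples x genes
    n, p = X.shape
    d = n - p
    if d < 1:
        raise AnalysisError("no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / d
    xtx_inv = np.linalg.inv(X.T @ X)
    ci = names.index("condition")
    v = xtx_inv[ci, ci]
    logfc = beta[ci]

    d0, s02 = fit_fdist_moments(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore"):
        t = logfc / np.sqrt(s2_post * v)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    fdr = bh_fdr(pvals)
    tab = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "pvalue": pvals,
            "fdr": fdr,
            "sdeg": fdr <= sdeg_threshold,
        },
        index=expr.values.index,
    )
    return DifferentialProfile(
        phenotype=phenotype,
        table=tab,
        d0=float(d0),
        s02=float(s02),
        df_residual=float(d),
        kind=kind,
        family=family,
        sdeg_threshold=sdeg_threshold,
    )


def remove_batch(expr: ExpressionMatrix, batch: str = "study") -> ExpressionMatrix:
    """Regress out the batch component per gene, keeping the condition effect.

    Batches are deviation-coded (effects sum to zero across batches) so the
    subtracted component is centered; the output is only for clustering,
    never for differential expression.
    """
    md = expr.metadata
    levels = sorted(md[batch].unique())
    if len(levels) < 2:
        return ExpressionMatrix(
            values=expr.values.copy(),
            norm_factors=expr.norm_factors,
            lib_sizes=expr.lib_sizes,
            metadata=md,
        )
    cond = (md["condition"] == "case").to_numpy(dtype=float)
    n = len(md)
    batch_cols = []
    last = levels[-1]
    for lev in levels[:-1]:
        col = np.where(md[batch] == lev, 1.0, 0.0) - np.where(md[batch] == last, 1.0, 0.0)
        batch_cols.append(col)
    B = np.column_stack(batch_cols)
    X = np.column_stack([np.ones(n), cond, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # same aliasing rule as fit_de: the contrast must stay estimable
        others = np.column_stack([np.ones(n), B])
        if np.linalg.matrix_rank(np.column_stack([others, cond])) == np.linalg.matrix_rank(others):
            raise AnalysisError("condition is confounded with the batch (aliased)")
        raise AnalysisError("batch design is rank deficient")
    Y = expr.values.to_numpy().T
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    batch_part = B @ beta[2:, :]
    corrected = (Y - batch_part).T
    return ExpressionMatrix(
        values=pd.DataFrame(corrected, index=expr.values.index, columns=expr.values.columns),
        norm_factors=expr.norm_factors,
        lib_sizes=expr.lib_sizes,
        metadata=md,
    )


def subset_expression(expr: ExpressionMatrix, sample_ids: list[str]) -> ExpressionMatrix:
    """Column subset of an ExpressionMatrix (normalization kept as computed)."""
    ids = [s for s in expr.values.columns if s in set(sample_ids)]
    md = expr.metadata[expr.metadata["sample_id"].isin(set(ids))].reset_index(drop=True)
    return ExpressionMatrix(
        values=expr.values[list(md["sample_id"])],
        norm_factors=expr.norm_factors.loc[list(md["sample_id"])],
        lib_sizes=expr.lib_sizes.loc[list(md["sample_id"])],
        metadata=md,
    )
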