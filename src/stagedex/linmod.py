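"""Per-gene linear models with empirical-Bayes variance moderation.

Three design matrices are supported for a cohort of controls and four
cancer stages:

* ``baseline`` — intercept alpha (control mean) plus four stage
  indicators, so each stage coefficient is that stage's log fold-change
  versus control;
* ``cellmeans`` — one indicator per group and no intercept, so each
  coefficient is a group mean (the parameterization contrasts are applied
  to);
* ``numeric`` — intercept plus a single numeric stage covariate coded
  control=0, I=1, ..., IV=4, for ordered-trend detection.

Fitting is ordinary (or precision-weighted) least squares, batched over
genes. Moderation shrinks each gene's residual variance s^2 (df d)
toward a prior variance s0^2 (df d0) estimated across all genes by the
method of moments on log variances, yielding the posterior

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and t-statistics with d0 + d degrees of freedom. The optional
mean-variance precision weights fit a LOWESS trend of sqrt residual SD
against average expression and weight each observation by the predicted
variance at its fitted value, in the style of the voom transformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .groups import GROUP_CODES, GROUPS, STAGES, validate_group
from .ingest import ExpressionDataset

logger = logging.getLogger(__name__)

DESIGN_KINDS = ("baseline", "cellmeans", "numeric")

#: Residual-variance floor applied before moderation so a perfectly fit
#: gene cannot produce an infinite t-statistic while keeping its rank.
SIGMA2_FLOOR = 1e-12


class LinModError(ValueError):
    pass


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    columns: tuple[str, ...]
    kind: str

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]


def build_design(groups, kind: str) -> DesignMatrix:
    """Build the design matrix of the requested kind for the given labels."""
    if kind not in DESIGN_KINDS:
        raise LinModError(f"unknown design kind {kind!r}; expected one of {DESIGN_KINDS}")
    labels = [validate_group(str(g)) for g in groups]
    n = len(labels)
    if kind == "cellmeans":
        X = np.zeros((n, len(GROUPS)))
        for i, g in enumerate(labels):
            X[i, GROUP_CODES[g]] = 1.0
        return DesignMatrix(X, GROUPS, kind)
    if kind == "baseline":
        X = np.zeros((n, 1 + len(STAGES)))
        X[:, 0] = 1.0
        for i, g in enumerate(labels):
            if g != "control":
                X[i, 1 + STAGES.index(g)] = 1.0
        return DesignMatrix(X, ("intercept",) + STAGES, kind)
    # numeric: intercept + ordinal stage code
    X = np.column_stack([np.ones(n), [float(GROUP_CODES[g]) for g in labels]])
    return DesignMatrix(X, ("intercept", "stage_numeric"), kind)


@dataclass
class GeneFit:
    """Least-squares result for one gene (a view into the batched fit)."""

    gene: str
    coefficients: np.ndarray
    sigma2: float
    df_residual: float
    stdev_unscaled: np.ndarray
    fitted: np.ndarray


@dataclass
class GeneFitResults:
    """Batched per-gene least-squares fits under one design.

    ``coefficients`` is genes x p; ``cov_unscaled`` is the per-gene
    (X' W X)^-1 (shared p x p matrix when the fit is unweighted);
    ``stdev_unscaled`` holds the square roots of its diagonal, the scale
    factors multiplying the residual SD to give coefficient standard
    errors.
    """

    design: DesignMatrix
    gene_ids: pd.Index
    coefficients: np.ndarray
    sigma2: np.ndarray
    df_residual: np.ndarray
    stdev_unscaled: np.ndarray
    cov_unscaled: np.ndarray  # (p, p) shared, or (g, p, p) when weighted
    amean: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def weighted(self) -> bool:
        return self.cov_unscaled.ndim == 3

    def cov_for(self, g: int) -> np.ndarray:
        return self.cov_unscaled[g] if self.weighted else self.cov_unscaled

    def fitted_values(self) -> np.ndarray:
        """Fitted matrix, genes x samples."""
        return self.coefficients @ self.design.matrix.T

    def __getitem__(self, g: int) -> GeneFit:
        return GeneFit(
            gene=str(self.gene_ids[g]),
            coefficients=self.coefficients[g],
            sigma2=float(self.sigma2[g]),
            df_residual=float(self.df_residual[g]),
            stdev_unscaled=self.stdev_unscaled[g],
            fitted=self.coefficients[g] @ self.design.matrix.T,
        )

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coefficients, index=self.gene_ids, columns=self.design.columns)


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        culprits = [
            columns[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise LinModError(f"design matrix is rank deficient; collinear columns: {culprits}")


def fit_gene_models(
    dataset: ExpressionDataset,
    design: DesignMatrix,
    weights: np.ndarray | None = None,
) -> GeneFitResults:
    """Fit the design to every gene by (weighted) least squares.

    ``weights`` is an optional strictly positive genes x samples matrix of
    per-observation precision weights.
    """
    X = design.matrix
    Y = np.asarray(dataset.values, dtype=float)
    if X.shape[0] != Y.shape[1]:
        raise LinModError(
            f"design has {X.shape[0]} rows but dataset has {Y.shape[1]} samples"
        )
    _check_full_rank(X, design.columns)
    n, p = X.shape
    g = Y.shape[0]
    df = float(n - p)

    if weights is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = Y @ X @ xtx_inv
        resid = Y - coef @ X.T
        rss = np.einsum("gn,gn->g", resid, resid)
        cov_unscaled = xtx_inv
        stdev_unscaled = np.broadcast_to(np.sqrt(np.diag(xtx_inv)), (g, p)).copy()
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != Y.shape:
            raise LinModError(f"weights shape {W.shape} does not match data shape {Y.shape}")
        if np.any(W <= 0):
            raise LinModError("all precision weights must be strictly positive")
        xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
        xtwy = np.einsum("ni,gn->gi", X, W * Y)
        cov_unscaled = np.linalg.inv(xtwx)
        coef = np.einsum("gij,gj->gi", cov_unscaled, xtwy)
        resid = Y - coef @ X.T
        rss = np.einsum("gn,gn->g", W, resid**2)
        stdev_unscaled = np.sqrt(np.diagonal(cov_unscaled, axis1=1, axis2=2))

    sigma2 = rss / df if df > 0 else np.zeros(g)
    sigma2 = np.maximum(sigma2, 0.0)
    return GeneFitResults(
        design=design,
        gene_ids=dataset.gene_ids,
        coefficients=coef,
        sigma2=sigma2,
        df_residual=np.full(g, max(df, 0.0)),
        stdev_unscaled=stdev_unscaled,
        cov_unscaled=cov_unscaled,
        amean=Y.mean(axis=1),
    )


def estimate_meanvar_weights(
    dataset: ExpressionDataset, design: DesignMatrix, span: float = 0.5
) -> np.ndarray:
    """Mean-variance precision weights from an unweighted first pass.

    A LOWESS trend of sqrt residual SD versus average expression is
    fitted; each observation's weight is the predicted SD at its fitted
    value raised to the -4th power (i.e. the inverse of the predicted
    variance on the original scale). Falls back to unit weights with a
    warning when fewer than 10 genes are available.
    """
    Y = np.asarray(dataset.values, dtype=float)
    if dataset.n_genes < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend unfittable, using unit weights")
        return np.ones_like(Y)
    fit = fit_gene_models(dataset, design)
    sqrt_sd = np.sqrt(fit.sigma2) ** 0.5  # quarter-power of variance
    trend = lowess(sqrt_sd, fit.amean, frac=span, return_sorted=True)
    xs, ys = trend[:, 0], np.maximum(trend[:, 1], 1e-6)
    fitted = fit.fitted_values()
    predicted = np.interp(fitted, xs, ys)
    return predicted**-4.0


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise LinModError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regulation_status(stage_lfcs) -> str:
    """UP if all four stage lfcs are positive, DOWN if all negative, else MIXED."""
    lfc = np.asarray(stage_lfcs, dtype=float)
    if lfc.shape != (len(STAGES),):
        raise LinModError(f"expected {len(STAGES)} stage lfc values, got shape {lfc.shape}")
    if np.all(lfc > 0):
        return "UP"
    if np.all(lfc < 0):
        return "DOWN"
    return "MIXED"


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimate of (prior df d0, prior variance s0^2).

    Under the hierarchical model, s^2 * d / sigma_g^2 ~ ChiSquare(d) with
    sigma_g^2 scaled-inverse-chi-square(d0, s0^2), so log s^2 has a known
    mean and variance in terms of digamma/trigamma functions; matching the
    empirical moments of log s^2 identifies both hyperparameters.
    """
    ok = df > 0
    s2 = np.maximum(sigma2[ok], SIGMA2_FLOOR)
    d = df[ok]
    if s2.size < 2:
        raise LinModError("need at least 2 genes with positive residual df")
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.mean((e - e_mean) ** 2) * n / (n - 1) - np.mean(special.polygamma(1, d / 2.0))
    if e_var > 0:
        df_prior = 2.0 * _trigamma_inverse(e_var)
        s0 = np.exp(e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s0 = np.exp(e_mean)
    return float(df_prior), float(s0)


@dataclass
class ModeratedStats:
    """Moderated per-gene statistics under one design.

    ``t``/``p_t``/``adj_p_t`` are genes x coefficients; the F statistic
    jointly tests the coefficients named in ``f_tested``. BH adjustment is
    applied per statistic family across genes.
    """

    gene_ids: pd.Index
    columns: tuple[str, ...]
    df_prior: float
    var_prior: float
    var_post: np.ndarray
    df_total: np.ndarray
    t: np.ndarray
    p_t: np.ndarray
    adj_p_t: np.ndarray
    f: np.ndarray | None = None
    p_f: np.ndarray | None = None
    adj_p_f: np.ndarray | None = None
    f_tested: tuple[str, ...] = ()

    def frame(self) -> pd.DataFrame:
        out = {}
        for j, c in enumerate(self.columns):
            out[f"t_{c}"] = self.t[:, j]
            out[f"p_{c}"] = self.p_t[:, j]
            out[f"adj_p_{c}"] = self.adj_p_t[:, j]
        if self.f is not None:
            out["F"] = self.f
            out["p_F"] = self.p_f
            out["adj_p_F"] = self.adj_p_f
        return pd.DataFrame(out, index=self.gene_ids)


def _default_f_indices(design: DesignMatrix) -> list[int]:
    if design.kind == "baseline":
        return [design.columns.index(s) for s in STAGES]
    if design.kind == "numeric":
        return [design.columns.index("stage_numeric")]
    return []


def moderated_variance(
    sigma2: np.ndarray, df: np.ndarray, df_prior: float, var_prior: float
) -> np.ndarray:
    """Posterior variance s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s2 = np.maximum(sigma2, SIGMA2_FLOOR)
    if np.isinf(df_prior):
        return np.full_like(s2, var_prior)
    return (df_prior * var_prior + df * s2) / (df_prior + df)


def ebayes_moderate(
    fits: GeneFitResults,
    f_coefficients: list[int] | None = None,
    prior: tuple[float, float] | None = None,
) -> ModeratedStats:
    """Empirical-Bayes moderation of the per-gene fits.

    ``prior`` overrides the estimated (d0, s0^2) — useful for the
    closed-form limits d0=0 (ordinary statistics) and d0=inf (full
    shrinkage). ``f_coefficients`` selects the jointly tested columns for
    the moderated F (defaults to the stage indicators for the baseline
    design and the slope for the numeric design).
    """
    if np.all(fits.df_residual <= 0):
        raise LinModError("all residual degrees of freedom are zero; no variance information")
    sigma2 = np.maximum(fits.sigma2, SIGMA2_FLOOR)
    if prior is None:
        df_prior, var_prior = fit_variance_prior(sigma2, fits.df_residual)
    else:
        df_prior, var_prior = prior
    var_post = moderated_variance(sigma2, fits.df_residual, df_prior, var_prior)
    df_total = fits.df_residual + (0.0 if np.isinf(df_prior) else df_prior)

    se = fits.stdev_unscaled * np.sqrt(var_post)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.coefficients / se
    p_t = 2.0 * stats.t.sf(np.abs(t), df_total[:, None])
    adj_p_t = np.column_stack([adjust_bh(p_t[:, j]) for j in range(p_t.shape[1])])

    stats_out = ModeratedStats(
        gene_ids=fits.gene_ids,
        columns=fits.design.columns,
        df_prior=df_prior,
        var_prior=var_prior,
        var_post=var_post,
        df_total=df_total,
        t=t,
        p_t=p_t,
        adj_p_t=adj_p_t,
    )

    idx = _default_f_indices(fits.design) if f_coefficients is None else list(f_coefficients)
    if idx:
        k = len(idx)
        g = len(fits)
        quad = np.empty(g)
        if fits.weighted:
            for i in range(g):
                cov = fits.cov_unscaled[i][np.ix_(idx, idx)]
                b = fits.coefficients[i, idx]
                quad[i] = b @ np.linalg.solve(cov, b)
        else:
            cov = fits.cov_unscaled[np.ix_(idx, idx)]
            cov_inv = np.linalg.inv(cov)
            B = fits.coefficients[:, idx]
            quad = np.einsum("gi,ij,gj->g", B, cov_inv, B)
        f = quad / (k * var_post)
        p_f = stats.f.sf(f, k, df_total)
        stats_out.f = f
        stats_out.p_f = p_f
        stats_out.adj_p_f = adjust_bh(p_f)
        stats_out.f_tested = tuple(fits.design.columns[j] for j in idx)
    return stats_out


def results_table(fits: GeneFitResults, mod: ModeratedStats) -> pd.DataFrame:
    """Per-model results: coefficients, moderated statistics, regulation status.

    Regulation status (UP/DOWN/MIXED across stage lfcs) is reported for
    the baseline design, whose stage coefficients are lfcs vs control.
    """
    out = fits.coef_frame().join(mod.frame())
    if fits.design.kind == "baseline":
        stage_idx = [fits.design.columns.index(s) for s in STAGES]
        lfcs = fits.coefficients[:, stage_idx]
        out["regulation"] = [regulation_status(row) for row in lfcs]
    return out
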