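"""Crossed random-intercept linear mixed models for differential analysis.

The global model for a log2 response y (fluorescence or concentration) is

    y = analyte + tissue + condition + analyte:tissue + analyte:condition
        + (1 | plate:condition:tissue) + (1 | patient) + error

i.e. three fixed main effects with first-order analyte interactions (the
three-way interaction is deliberately excluded: the design is sparse and the
model would overfit), plus two crossed scalar random effects: one for the
plate-group (which plate a condition x tissue combination ran on) and one
for the patient (some patients contribute two tissues).  The reduced model
drops the condition main effect and its analyte interaction.

Estimation is profiled (RE)ML.  Writing V = sigma^2 (I + Z G Z') with Z the
stacked random-effect indicators and G the diagonal of variance *ratios*
gamma_k = sigma_k^2 / sigma^2, both the GLS fixed effects and the residual
variance have closed forms given gamma, so only the two ratios are optimized
(L-BFGS-B on log gamma, started from method-of-moments values).  All solves
go through a Cholesky factor of the q x q system Z'Z + G^{-1} (Woodbury),
so cost scales with the number of random levels, not observations.

Inference on fixed effects is by Wald chi-square quadratic forms on cell-
mean contrasts, with Holm's step-down adjustment across whole result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve
from statsmodels.stats.multitest import multipletests

from .plate_data import PlateDataset, aggregate_duplicates

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2 * np.pi))


class SingularDesignError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a mixed model on a plate dataset."""

    response: str = "log2_fluorescence"
    fixed_main: tuple = ("analyte", "tissue", "condition")
    fixed_interactions: tuple = ("analyte:tissue", "analyte:condition")
    random_intercepts: tuple = ("plate_group", "patient")

    def __post_init__(self):
        for inter in self.fixed_interactions:
            parts = inter.split(":")
            if not all(p in self.fixed_main for p in parts):
                raise ValueError(
                    f"interaction {inter} involves factors outside fixed_main"
                )
        if not self.random_intercepts:
            raise ValueError("at least one random grouping is required")


GLOBAL_SPEC = ModelSpec()
REDUCED_SPEC = ModelSpec(
    fixed_main=("analyte", "tissue"),
    fixed_interactions=("analyte:tissue",),
)


@dataclass
class ContrastResult:
    analyte: str | None
    contrast_label: str
    value: float
    chisq: float
    df: int
    p_raw: float
    p_holm: float | None = None


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class FixedDesign:
    """Treatment-coded fixed design with cell-mean row construction."""

    columns: list            # ("Intercept",) | (factor, level) | (f1,l1,f2,l2)
    levels: dict             # factor -> ordered level list (ref first)
    spec: ModelSpec

    @property
    def p(self) -> int:
        return len(self.columns)

    def cell_row(self, assignment: dict) -> np.ndarray:
        """Design row for a fixed-effects cell mean.

        ``assignment`` maps each factor either to a single level or to a
        sequence of levels to be averaged with equal weights (the adjusted-
        mean convention).
        """
        weights = {}
        for factor, lv in assignment.items():
            if isinstance(lv, (list, tuple, np.ndarray)):
                weights[factor] = {l: 1.0 / len(lv) for l in lv}
            else:
                weights[factor] = {lv: 1.0}
        row = np.zeros(self.p)
        for j, col in enumerate(self.columns):
            if col == ("Intercept",):
                row[j] = 1.0
            elif len(col) == 2:
                f, l = col
                row[j] = weights[f].get(l, 0.0)
            else:
                f1, l1, f2, l2 = col
                row[j] = weights[f1].get(l1, 0.0) * weights[f2].get(l2, 0.0)
        return row


def build_fixed_design(frame: pd.DataFrame, spec: ModelSpec,
                       reference: dict | None = None):
    """Build the treatment-coded fixed design matrix X.

    ``reference`` optionally picks the baseline level per factor (default:
    first in sorted order; for ``condition`` the level "Normal" is promoted
    to baseline when present).
    """
    reference = reference or {}
    levels = {}
    for f in spec.fixed_main:
        lv = sorted(frame[f].astype(str).unique())
        ref = reference.get(f)
        if ref is None and f == "condition" and "Normal" in lv:
            ref = "Normal"
        if ref is not None:
            lv.remove(ref)
            lv = [ref] + lv
        levels[f] = lv

    columns = [("Intercept",)]
    blocks = [np.ones((len(frame), 1))]
    ind = {}
    for f in spec.fixed_main:
        vals = frame[f].astype(str).to_numpy()
        mat = np.empty((len(frame), len(levels[f]) - 1))
        for k, l in enumerate(levels[f][1:]):
            mat[:, k] = vals == l
            columns.append((f, l))
        ind[f] = mat
        blocks.append(mat)
    for inter in spec.fixed_interactions:
        f1, f2 = inter.split(":")
        m1, m2 = ind[f1], ind[f2]
        mat = np.empty((len(frame), m1.shape[1] * m2.shape[1]))
        k = 0
        for i1, l1 in enumerate(levels[f1][1:]):
            for i2, l2 in enumerate(levels[f2][1:]):
                mat[:, k] = m1[:, i1] * m2[:, i2]
                columns.append((f1, l1, f2, l2))
                k += 1
        blocks.append(mat)
    X = np.hstack(blocks)
    return X, FixedDesign(columns=columns, levels=levels, spec=spec)


def model_frame(ds: PlateDataset, spec: ModelSpec,
                aggregate: bool = True) -> pd.DataFrame:
    """Long frame of sample responses ready for modelling.

    Duplicate wells are averaged by default (one observation per
    sample x analyte); rows without the requested response are dropped
    (this is where concentration censoring bites).
    """
    if aggregate:
        ds = aggregate_duplicates(ds)
    df = ds.samples().copy()
    if spec.response == "log2_fluorescence":
        df["y"] = np.log2(df["fluorescence"].astype(float))
    elif spec.response == "log2_concentration":
        df = df.dropna(subset=["concentration"])
        df = df[df["concentration"] > 0]
        df["y"] = np.log2(df["concentration"].astype(float))
    else:
        raise ValueError(f"unknown response {spec.response!r}")
    df["plate_group"] = (
        df["plate"].astype(str) + ":" + df["condition"].astype(str)
        + ":" + df["tissue"].astype(str)
    )
    df["patient"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)


def _random_indicators(frame: pd.DataFrame, groupings):
    Zs, sizes, level_maps = [], [], []
    for g in groupings:
        codes, lv = pd.factorize(frame[g].astype(str), sort=True)
        Z = sparse.csr_matrix(
            (np.ones(len(codes)), (np.arange(len(codes)), codes)),
            shape=(len(codes), len(lv)),
        )
        Zs.append(Z)
        sizes.append(len(lv))
        level_maps.append(list(lv))
    return sparse.hstack(Zs, format="csr"), sizes, level_maps


# ---------------------------------------------------------------------------
# (RE)ML machinery
# ---------------------------------------------------------------------------

class _ProfiledLikelihood:
    """Profiled (RE)ML criterion over variance ratios gamma."""

    def __init__(self, X, y, Z, sizes, method):
        self.X, self.y, self.Z = X, y, Z
        self.sizes = sizes
        self.method = method
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = np.asarray(Z.T @ X)
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        # rank check once, naming aliased columns via pivoted QR
        eigvals = np.linalg.eigvalsh(self.XtX)
        if eigvals[0] <= 1e-8 * max(eigvals[-1], 1.0):
            from scipy.linalg import qr
            _, r, piv = qr(X, mode="economic", pivoting=True)
            d = np.abs(np.diag(r))
            bad = piv[d < 1e-8 * d.max()]
            raise SingularDesignError(
                f"aliased fixed-effect columns at indices {sorted(bad)}"
            )

    def _gamma_vector(self, gammas):
        return np.repeat(np.asarray(gammas, dtype=float), self.sizes)

    def components(self, gammas):
        """Return (beta, sigma2, r'H^-1 r, logdet H, logdet X'H^-1X, XtHinvX)."""
        g = self._gamma_vector(gammas)
        A = self.ZtZ + np.diag(1.0 / g)
        cA = cho_factor(A, lower=True, check_finite=False)
        # W = A^{-1} Z'[X y]
        rhs = np.concatenate([self.ZtX, self.Zty[:, None]], axis=1)
        w = cho_solve(cA, rhs, check_finite=False)
        WX, Wy = w[:, :-1], w[:, -1]
        XtHX = self.XtX - self.ZtX.T @ WX
        XtHy = self.Xty - self.ZtX.T @ Wy
        ytHy = self.yty - float(self.Zty @ Wy)
        cX = cho_factor(XtHX, lower=True, check_finite=False)
        beta = cho_solve(cX, XtHy, check_finite=False)
        rss = ytHy - float(beta @ XtHy)
        rss = max(rss, 1e-300)
        logdetH = 2 * float(np.log(np.diag(cA[0])).sum()) + float(np.log(g).sum())
        logdetXtHX = 2 * float(np.log(np.diag(cX[0])).sum())
        return beta, rss, logdetH, logdetXtHX, XtHX

    def neg2loglik(self, gammas):
        beta, rss, logdetH, logdetXtHX, _ = self.components(gammas)
        n, p = self.n, self.p
        if self.method == "reml":
            sigma2 = rss / (n - p)
            return ((n - p) * (LOG2PI + np.log(sigma2)) + logdetH
                    + logdetXtHX + (n - p))
        sigma2 = rss / n
        return n * (LOG2PI + np.log(sigma2)) + logdetH + n


@dataclass
class LMMFit:
    """Fitted crossed random-intercept mixed model."""

    spec: ModelSpec
    design: FixedDesign
    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2: float
    variance_components: dict
    method: str
    neg2loglik: float
    aic: float
    bic: float
    n_obs: int
    fixed_df: int
    converged: bool = True
    frame: pd.DataFrame | None = field(default=None, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def loglik(self) -> float:
        return -0.5 * self.neg2loglik

    def coef_table(self) -> pd.DataFrame:
        names = ["Intercept" if c == ("Intercept",) else
                 ":".join(f"{c[i]}[{c[i + 1]}]" for i in range(0, len(c), 2))
                 for c in self.design.columns]
        se = np.sqrt(np.diag(self.vcov_beta))
        return pd.DataFrame({"coef": names, "estimate": self.beta, "se": se})


def _moment_start(X, y, frame, groupings):
    """Method-of-moments starting ratios from one-way residual decompositions."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tot = max(float(np.var(resid)), 1e-8)
    out = []
    for g in groupings:
        means = pd.Series(resid).groupby(frame[g].astype(str).to_numpy()).mean()
        between = float(np.var(means.to_numpy())) if len(means) > 1 else 0.0
        out.append(min(max(between / tot, 1e-3), 10.0))
    return out


def fit_lmm(ds_or_frame, spec: ModelSpec = GLOBAL_SPEC,
            method: str = "reml", aggregate: bool = True,
            reference: dict | None = None) -> LMMFit:
    """Fit the mixed model by profiled restricted (or full) maximum likelihood.

    Accepts a :class:`PlateDataset` or an already-prepared model frame.
    Raises :class:`SingularDesignError` for aliased fixed effects (run the
    estimability filter first); a variance ratio pinned at its lower bound
    produces a warning, not an error.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    frame = (ds_or_frame if isinstance(ds_or_frame, pd.DataFrame)
             else model_frame(ds_or_frame, spec, aggregate=aggregate))
    y = frame["y"].to_numpy(dtype=float)
    X, design = build_fixed_design(frame, spec, reference=reference)
    Z, sizes, _ = _random_indicators(frame, spec.random_intercepts)
    lik = _ProfiledLikelihood(X, y, Z, sizes, method)

    x0 = np.log(_moment_start(X, y, frame, spec.random_intercepts))
    bounds = [(np.log(1e-8), np.log(1e6))] * len(sizes)
    res = optimize.minimize(lambda lg: lik.neg2loglik(np.exp(lg)), x0,
                            method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-10, "gtol": 1e-8,
                                     "maxiter": 500})
    gammas = np.exp(res.x)
    pinned = gammas <= 1.5e-8
    if pinned.any():
        which = [spec.random_intercepts[i] for i in np.flatnonzero(pinned)]
        logger.warning("variance component(s) pinned at zero: %s", which)
        gammas = np.where(pinned, 0.0, gammas)

    beta, rss, logdetH, logdetXtHX, XtHX = lik.components(
        np.maximum(gammas, 1e-10))
    n, p = lik.n, lik.p
    denom = n - p if method == "reml" else n
    sigma2 = rss / denom
    vcov = sigma2 * np.linalg.inv(XtHX)
    vc = {g: float(sigma2 * gammas[i])
          for i, g in enumerate(spec.random_intercepts)}
    neg2 = float(lik.neg2loglik(np.maximum(gammas, 1e-10)))
    k = p + len(sizes) + 1
    aic = neg2 + 2 * k
    bic = neg2 + k * np.log(n)
    return LMMFit(spec=spec, design=design, beta=beta, vcov_beta=vcov,
                  sigma2=float(sigma2), variance_components=vc,
                  method=method, neg2loglik=neg2, aic=float(aic),
                  bic=float(bic), n_obs=n, fixed_df=p,
                  converged=bool(res.success), frame=frame)


def reml_criterion_dense(X, y, Z_dense, variances, sigma2, method="reml"):
    """Brute-force dense evaluation of the (RE)ML -2 log-likelihood.

    Builds V = sigma2 I + sum_k var_k Z_k Z_k' explicitly; independent
    oracle for the Woodbury implementation on small instances.
    """
    n, p = X.shape
    V = sigma2 * np.eye(n)
    for Zk, vk in zip(Z_dense, variances):
        V += vk * (Zk @ Zk.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    sign, logdetV = np.linalg.slogdet(V)
    if method == "reml":
        sign2, logdetXtViX = np.linalg.slogdet(XtViX)
        return (n - p) * LOG2PI + logdetV + logdetXtViX + quad
    return n * LOG2PI + logdetV + quad


def compare_models(ds: PlateDataset, reduced: ModelSpec, global_: ModelSpec,
                   aggregate: bool = True) -> dict:
    """Likelihood-ratio comparison of nested fixed-effect structures.

    Both models are refit by full ML (REML likelihoods are not comparable
    across fixed structures) on the same rows; reports AIC/BIC from the ML
    fits and the chi-square on the difference in fixed df.
    """
    red_terms = set(reduced.fixed_main) | set(reduced.fixed_interactions)
    glob_terms = set(global_.fixed_main) | set(global_.fixed_interactions)
    if not red_terms <= glob_terms:
        raise ValueError("reduced model terms are not nested in the global model")
    if reduced.random_intercepts != global_.random_intercepts:
        raise ValueError("random structures must match")
    if reduced.response != global_.response:
        raise ValueError("responses must match")
    frame = model_frame(ds, global_, aggregate=aggregate)
    fit_red = fit_lmm(frame, reduced, method="ml")
    fit_glob = fit_lmm(frame, global_, method="ml")
    chisq = max(fit_red.neg2loglik - fit_glob.neg2loglik, 0.0)
    df_diff = fit_glob.fixed_df - fit_red.fixed_df
    p = float(stats.chi2.sf(chisq, df_diff)) if df_diff > 0 else 1.0
    return {
        "aic": (fit_red.aic, fit_glob.aic),
        "bic": (fit_red.bic, fit_glob.bic),
        "df": (fit_red.fixed_df, fit_glob.fixed_df),
        "chisq": float(chisq),
        "df_diff": int(df_diff),
        "p": p,
    }


# ---------------------------------------------------------------------------
# Wald contrasts and adjusted means
# ---------------------------------------------------------------------------

def _other_factors(design: FixedDesign, factor: str):
    return [f for f in design.spec.fixed_main if f not in ("analyte", factor)]


def _mean_row(design: FixedDesign, analyte: str, factor: str, level):
    """Cell-mean row for (analyte, factor=level), equal-weight averaging the rest."""
    assignment = {"analyte": analyte, factor: level}
    for f in _other_factors(design, factor):
        assignment[f] = design.levels[f]
    return design.cell_row(assignment)


def wald_test(fit: LMMFit, L: np.ndarray):
    """Wald chi-square for the linear hypothesis L beta = 0."""
    L = np.atleast_2d(L)
    est = L @ fit.beta
    cov = L @ fit.vcov_beta @ L.T
    if np.linalg.matrix_rank(cov, tol=1e-10 * max(np.abs(cov).max(), 1e-30)) < L.shape[0]:
        raise SingularDesignError("contrast matrix is rank deficient")
    chisq = float(est @ np.linalg.solve(cov, est))
    df = L.shape[0]
    return max(chisq, 0.0), df, float(stats.chi2.sf(max(chisq, 0.0), df))


def omnibus_factor_test(fit: LMMFit, analyte: str, factor: str) -> ContrastResult:
    """Omnibus Wald test of any factor-level difference within an analyte.

    The hypothesis spans all level differences of ``factor`` at the given
    analyte's cell means (main effect plus analyte interaction), df =
    levels - 1; invariant to the coding reference.
    """
    if factor not in fit.design.levels:
        raise ValueError(f"{factor} is not a fixed factor of this model")
    levels = fit.design.levels[factor]
    base = _mean_row(fit.design, analyte, factor, levels[0])
    L = np.array([_mean_row(fit.design, analyte, factor, l) - base
                  for l in levels[1:]])
    chisq, df, p = wald_test(fit, L)
    return ContrastResult(analyte=analyte, contrast_label=f"{factor} omnibus",
                          value=float("nan"), chisq=chisq, df=df, p_raw=p)


def condition_contrast(fit: LMMFit, analyte: str, reference: str,
                       other: str) -> ContrastResult:
    """Single df-1 Wald contrast of two condition levels within an analyte.

    ``value`` is the adjusted log2 difference reference-minus-other, so a
    negative value means the analyte is higher in the ``other`` condition.
    A level contrasted against itself gives value 0, p = 1.
    """
    levels = fit.design.levels["condition"]
    for lv in (reference, other):
        if lv not in levels:
            raise ValueError(f"condition level {lv!r} not in design")
    L = (_mean_row(fit.design, analyte, "condition", reference)
         - _mean_row(fit.design, analyte, "condition", other))
    value = float(L @ fit.beta)
    var = float(L @ fit.vcov_beta @ L)
    chisq = value ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chisq, 1))
    return ContrastResult(analyte=analyte,
                          contrast_label=f"{reference}-{other}",
                          value=value, chisq=chisq, df=1, p_raw=p)


def pairwise_condition_contrasts(fit: LMMFit, analyte: str,
                                 reference: str = "Normal") -> list[ContrastResult]:
    """df-1 Wald contrasts of the reference condition against every other."""
    levels = fit.design.levels["condition"]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not in design")
    return [condition_contrast(fit, analyte, reference, other)
            for other in levels if other != reference]


def holm_adjust(p_raw) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def adjusted_means(fit: LMMFit, analyte: str, factor: str,
                   level: float = 0.95) -> pd.DataFrame:
    """Model-adjusted means per factor level with normal-quantile intervals.

    Levels of the remaining fixed factors are averaged with equal weights;
    the interval is estimate +/- z * SE from the fixed-effect covariance.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for lv in fit.design.levels[factor]:
        r = _mean_row(fit.design, analyte, factor, lv)
        est = float(r @ fit.beta)
        se = float(np.sqrt(r @ fit.vcov_beta @ r))
        rows.append({"analyte": analyte, factor: lv, "mean": est, "se": se,
                     "lower": est - z * se, "upper": est + z * se})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table builders (omnibus-per-analyte and pairwise-contrast tables)
# ---------------------------------------------------------------------------

def omnibus_table(fit: LMMFit, factor: str) -> pd.DataFrame:
    """Per-analyte omnibus chi-squares for a factor, Holm-adjusted family-wide."""
    rows = [omnibus_factor_test(fit, a, factor)
            for a in fit.design.levels["analyte"]]
    df = pd.DataFrame([{"analyte": r.analyte, "chisq": r.chisq, "df": r.df,
                        "p_raw": r.p_raw} for r in rows])
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def contrast_table(fit: LMMFit, reference: str = "Normal") -> pd.DataFrame:
    """All analyte x condition pairwise contrasts, Holm-adjusted family-wide."""
    rows = []
    for a in fit.design.levels["analyte"]:
        rows.extend(pairwise_condition_contrasts(fit, a, reference=reference))
    df = pd.DataFrame([{"analyte": r.analyte, "contrast": r.contrast_label,
                        "value": r.value, "chisq": r.chisq, "df": r.df,
                        "p_raw": r.p_raw} for r in rows])
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df
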