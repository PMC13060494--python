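"""Covariate-adjusted gene-based rare-variant association tests.

Implements score-based burden, SKAT, SKAT-O (minimum-p over a rho grid with
the one-dimensional integration adjustment), ACAT-V and ACAT-O on a
qualifying variant set, against a null model fitted once per trait.

The weighted chi-square mixture tail needed by SKAT is computed by
error-bounded characteristic-function inversion (Davies' method) with a
moment-matching fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from ._davies import DaviesFailure, qf_tail
from .consequence_masks import QualifyingVariantSet  # noqa: F401  (re-export; built upstream)
from .exceptions import (
    ConfigurationError,
    DegenerateSetError,
    FitError,
    InputError,
    PerfectSeparationError,
)

P_FLOOR = 1e-300
# Accuracy used by SKAT/SKAT-O internals (reference implementations use 1e-6);
# davies_pvalue itself defaults to 1e-9.
SKAT_DAVIES_ACC = 1e-6
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """Covariate-adjusted null fit supplying residuals and score variances.

    ``v`` holds per-sample working variances: mu*(1-mu) for a binary trait,
    the constant residual variance estimate for a quantitative trait. Score
    variances use the projection P = V - VX (X'VX)^-1 X'V.
    """

    kind: str  # "binary" | "quantitative"
    y: np.ndarray
    X: np.ndarray
    beta: np.ndarray
    mu: np.ndarray
    v: np.ndarray
    dropped_columns: list[int] = dc_field(default_factory=list)
    _xtvx_inv: np.ndarray = dc_field(default=None, repr=False)

    def __post_init__(self):
        if self._xtvx_inv is None:
            xtvx = self.X.T @ (self.v[:, None] * self.X)
            self._xtvx_inv = np.linalg.pinv(xtvx)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu

    def score_cross_product(self, G: np.ndarray) -> np.ndarray:
        """G' P G for a samples x variants matrix G (covariate-adjusted)."""
        G = np.asarray(G, dtype=float)
        VG = self.v[:, None] * G
        XtVG = self.X.T @ VG
        return G.T @ VG - XtVG.T @ (self._xtvx_inv @ XtVG)

    def score(self, G: np.ndarray) -> np.ndarray:
        """Score vector U_j = residuals' g_j."""
        return np.asarray(G, dtype=float).T @ self.residuals


def fit_null(
    y: np.ndarray,
    covariates: np.ndarray,
    kind: str = "binary",
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NullModel:
    """Fit the covariate-only null model.

    Binary traits use iteratively reweighted least squares for the logistic
    model, converged to score norm < ``tol``; quantitative traits use least
    squares. Rank-deficient covariate columns are dropped with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if len(y) != X.shape[0]:
        raise InputError("outcome and covariate row counts differ")
    if np.isnan(y).any() or np.isnan(X).any():
        raise InputError("missing values in outcome or covariates")
    if kind not in ("binary", "quantitative"):
        raise ConfigurationError(f"unknown trait kind {kind!r}")
    if kind == "binary" and not np.isin(y, (0.0, 1.0)).all():
        raise InputError("binary outcome must be coded 0/1")

    # Drop aliased columns via pivoted QR of the column-scaled design.
    dropped: list[int] = []
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, r = np.linalg.qr(X / norms)
    diag = np.abs(np.diag(r))
    keep = np.ones(X.shape[1], dtype=bool)
    if (diag < 1e-10 * max(diag.max(), 1.0)).any() or np.linalg.matrix_rank(X) < X.shape[1]:
        # Greedy: keep columns that increase rank.
        keep[:] = False
        cur = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) > cur.shape[1]:
                keep[j] = True
                cur = cand
            else:
                dropped.append(j)
        warnings.warn(f"dropping {len(dropped)} aliased covariate column(s): {dropped}")
    Xk = X[:, keep]

    if kind == "quantitative":
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        mu = Xk @ beta
        resid = y - mu
        dof = max(len(y) - Xk.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        v = np.full(len(y), sigma2)
        return NullModel("quantitative", y, Xk, beta, mu, v, dropped)

    # Logistic IRLS.
    beta = np.zeros(Xk.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Xk @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xk.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            break
        H = Xk.T @ (w[:, None] * Xk)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.abs(beta).max() > 50:
            raise PerfectSeparationError(
                "logistic null model diverged (probable perfect separation); "
                "consider a Firth/penalized fit"
            )
    else:
        if np.linalg.norm(Xk.T @ (y - mu)) >= math.sqrt(tol):
            raise FitError("logistic null model did not converge")
    eta = np.clip(Xk @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    v = mu * (1.0 - mu)
    return NullModel("binary", y, Xk, beta, mu, v, dropped)


# ---------------------------------------------------------------------------
# Chi-square mixture tails
# ---------------------------------------------------------------------------


def liu_pvalue(lambdas: np.ndarray, q: float) -> float:
    """Moment-matching (noncentral chi-square) tail approximation."""
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
        a = math.sqrt(dof)
    mu_q = c1
    sigma_q = math.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    x = t_star * math.sqrt(2 * (dof + 2 * delta)) + dof + delta
    return float(stats.ncx2.sf(x, dof, delta)) if delta > 0 else float(stats.chi2.sf(x, dof))


def davies_pvalue(
    lambdas: Sequence[float], q: float, acc: float = 1e-9, return_detail: bool = False
) -> float | tuple[float, bool]:
    """P(sum_k lambda_k * chi2_1 > q) by characteristic-function inversion.

    Uses Davies' error-bounded inversion (absolute accuracy ``acc``); a
    single-eigenvalue mixture is an exact chi-square tail. Falls back to the
    moment-matching approximation when the inversion fails or the result is
    below its own accuracy floor; the fallback is flagged in the detailed
    return.
    """
    lam = np.asarray(lambdas, dtype=float)
    if not np.all(np.isfinite(lam)) or not np.isfinite(q):
        raise InputError("non-finite input to davies_pvalue")
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0:
        raise DegenerateSetError("no positive eigenvalues in chi-square mixture")
    if q <= 0:
        return (1.0, False) if return_detail else 1.0

    fallback = False
    if lam.size == 1:
        p = float(stats.chi2.sf(q / lam[0], 1))
    else:
        try:
            p = qf_tail(lam, q, acc=acc)
            if p < max(acc, 1e-12):
                # Below the inversion's absolute accuracy; moment matching
                # is better behaved in the far tail.
                p = liu_pvalue(lam, q)
                fallback = True
        except DaviesFailure:
            p = liu_pvalue(lam, q)
            fallback = True
    p = float(min(max(p, P_FLOOR), 1.0))
    return (p, fallback) if return_detail else p


def _liu_params_mod(lambdas: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, sd, dof and noncentrality of the modified moment matching."""
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    return c1, math.sqrt(2 * c2), dof, delta


_GAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_nodes(n: int = 256, upper: float = 6.5) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0, upper] (cached)."""
    if n not in _GAUSS_CACHE:
        t, w = np.polynomial.legendre.leggauss(n)
        _GAUSS_CACHE[n] = (0.5 * upper * (t + 1.0), 0.5 * upper * w)
    return _GAUSS_CACHE[n]


def _mixture_quantile(lambdas: np.ndarray, p_upper: float) -> float:
    """Approximate upper quantile of the mixture via moment matching."""
    mu_q, sigma_q, dof, delta = _liu_params_mod(lambdas)
    q_chi = stats.ncx2.isf(p_upper, dof, delta) if delta > 0 else stats.chi2.isf(p_upper, dof)
    return float((q_chi - dof - delta) / math.sqrt(2 * (dof + 2 * delta)) * sigma_q + mu_q)


# ---------------------------------------------------------------------------
# Cauchy combination
# ---------------------------------------------------------------------------


def cauchy_combine(pvalues: Sequence[float], weights: Optional[Sequence[float]] = None) -> float:
    """Combine p-values with the Cauchy (tangent) transform.

    Very small p use the 1/(p*pi) tangent asymptote; p >= 0.999 use the
    mirrored asymptote to dodge cancellation near 1. Output floored at 1e-300.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InputError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]; floor zeros upstream")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        w = w / w.sum()
    t = np.empty_like(p)
    small = p < 1e-16
    large = p >= 0.999
    mid = ~(small | large)
    t[small] = 1.0 / (p[small] * math.pi)
    t[large] = -1.0 / (np.maximum(1.0 - p[large], 1e-300) * math.pi)
    t[mid] = np.tan((0.5 - p[mid]) * math.pi)
    tstat = float(np.sum(w * t))
    if tstat > 1e15:
        comb = 1.0 / (tstat * math.pi)
    else:
        comb = 0.5 - math.atan(tstat) / math.pi
    return float(min(max(comb, P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# Gene-level tests
# ---------------------------------------------------------------------------


@dataclass
class GeneTestResult:
    gene: str
    mask: str
    test: str
    statistic: float
    p: float
    n_variants: int
    n_carriers: int
    detail: dict = dc_field(default_factory=dict)


def _check_set(qset: QualifyingVariantSet, null: NullModel) -> np.ndarray:
    G = np.asarray(qset.genotypes, dtype=float)
    if G.shape[0] != len(null.y):
        raise InputError(
            f"qualifying set has {G.shape[0]} samples but null model has {len(null.y)}"
        )
    if G.shape[1] == 0:
        raise DegenerateSetError("empty qualifying set")
    return G


def burden_test(qset: QualifyingVariantSet, null: NullModel) -> GeneTestResult:
    """Score test on the weighted dosage sum; signed Z, two-sided p."""
    G = _check_set(qset, null)
    b = G @ qset.weights
    u = float(null.residuals @ b)
    var = float(null.score_cross_product(b[:, None])[0, 0])
    if var <= 0:
        raise DegenerateSetError(f"{qset.gene}/{qset.mask}: burden score variance is zero")
    z = u / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return GeneTestResult(
        qset.gene, qset.mask, "Burden", z, max(p, P_FLOOR), qset.n_variants, qset.n_carriers,
        detail={"direction": "risk" if z > 0 else "protective"},
    )


def _skat_core(qset: QualifyingVariantSet, null: NullModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Q statistic, per-variant scores, and the adjusted cross-product matrix."""
    G = _check_set(qset, null)
    Gw = G * qset.weights[None, :]
    scores = null.score(Gw)  # w_j * residual'g_j
    q = float(np.sum(scores**2))
    A = null.score_cross_product(Gw)  # Gw' P Gw
    return q, scores, A


def skat_test(qset: QualifyingVariantSet, null: NullModel) -> GeneTestResult:
    """Variance-component quadratic-form test (weighted chi-square mixture)."""
    q, _, A = _skat_core(qset, null)
    lam = np.linalg.eigvalsh((A + A.T) / 2.0)
    lam = lam[lam > max(lam.max(initial=0.0), 0.0) * 1e-10]
    if lam.size == 0:
        raise DegenerateSetError(f"{qset.gene}/{qset.mask}: SKAT kernel has no positive eigenvalue")
    p, fallback = davies_pvalue(lam, q, acc=SKAT_DAVIES_ACC, return_detail=True)
    return GeneTestResult(
        qset.gene, qset.mask, "SKAT", q, p, qset.n_variants, qset.n_carriers,
        detail={"liu_fallback": fallback},
    )


def skat_o_test(
    qset: QualifyingVariantSet,
    null: NullModel,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> GeneTestResult:
    """Optimal burden/SKAT combination over a rho grid (minimum-p procedure).

    Q_rho = (1-rho) * Q_SKAT + rho * Q_burden; per-rho p-values come from the
    corresponding chi-square mixtures, and the minimum over the grid is
    calibrated by one-dimensional integration over the burden component.
    """
    grid = sorted(set(float(r) for r in rho_grid))
    if not grid:
        raise ConfigurationError("empty rho grid")
    if any(r < 0 or r > 1 for r in grid):
        raise ConfigurationError("rho grid must lie in [0, 1]")

    if len(grid) == 1:
        rho = grid[0]
        base = burden_test(qset, null) if rho == 1.0 else (
            skat_test(qset, null) if rho == 0.0 else None
        )
        if base is None:
            raise ConfigurationError("single-point rho grid must be {0} or {1}")
        return GeneTestResult(
            qset.gene, qset.mask, "SKATO", rho, base.p, qset.n_variants, qset.n_carriers,
            detail={"rho": rho, "component_p": {str(rho): base.p}},
        )

    q_skat, scores, A = _skat_core(qset, null)
    m = A.shape[0]
    q_burden = float(np.sum(scores) ** 2)

    if m == 1:
        base = burden_test(qset, null)
        return GeneTestResult(
            qset.gene, qset.mask, "SKATO", 0.0, base.p, qset.n_variants, qset.n_carriers,
            detail={"rho": 1.0, "component_p": {"1": base.p}},
        )

    ones = np.ones(m)
    # Per-rho mixture eigenvalues via R_rho^{1/2} A R_rho^{1/2};
    # R_rho = (1-rho) I + rho 11' has sqrt a*J/m + b*(I - J/m).
    p_per_rho: dict[float, float] = {}
    lam_per_rho: dict[float, np.ndarray] = {}
    for rho in grid:
        q_rho = (1.0 - rho) * q_skat + rho * q_burden
        a = math.sqrt(1.0 - rho + rho * m)
        b = math.sqrt(1.0 - rho)
        P1 = np.outer(ones, ones) / m
        R_half = a * P1 + b * (np.eye(m) - P1)
        B = R_half @ A @ R_half
        lam = np.linalg.eigvalsh((B + B.T) / 2.0)
        lam = lam[lam > max(lam.max(initial=0.0), 0.0) * 1e-10]
        if lam.size == 0:
            raise DegenerateSetError(f"{qset.gene}/{qset.mask}: degenerate at rho={rho}")
        lam_per_rho[rho] = lam
        p_per_rho[rho] = davies_pvalue(lam, q_rho, acc=SKAT_DAVIES_ACC)

    min_p = min(p_per_rho.values())
    rho_min = min(p_per_rho, key=p_per_rho.get)

    # Decomposition of the mixture along the burden direction (all inner
    # products derive from A and s = A 1 / m).
    s = A @ ones / m
    zz = float(ones @ A @ ones) / m**2  # zbar' zbar
    if zz <= 0:
        p_final = min_p
    else:
        cof = s / zz
        A2 = A - np.outer(s, s) / zz  # kappa-part cross-product
        lam_k = np.linalg.eigvalsh((A2 + A2.T) / 2.0)
        lam_k = lam_k[lam_k > max(lam_k.max(initial=0.0), 0.0) * 1e-10]
        mu_q = float(np.sum(lam_k))
        extra_var = 4.0 * float(s @ A @ s - (s @ s) ** 2 / zz) / zz
        var_q = 2.0 * float(np.sum(lam_k**2)) + extra_var
        if lam_k.size == 0 or var_q <= 0:
            p_final = min_p
        else:
            kurt = 12.0 * float(np.sum(lam_k**4)) / max(float(np.sum(lam_k**2)) ** 2, 1e-300)
            df = 12.0 / kurt if kurt > 0 else 1e6
            taus = np.array(
                [(m**2 * r + (1.0 - r) * float(cof @ cof)) * zz for r in grid]
            )
            q_min = np.array([_mixture_quantile(lam_per_rho[r], min_p) for r in grid])
            one_minus = np.array([1.0 - min(r, 0.999) for r in grid])

            # integral over the chi2_1 burden component, substituting x = t^2
            # to remove the density singularity; vectorized Gauss-Legendre.
            t, wts = _gauss_nodes()
            x = t**2
            tmin = np.min((q_min[:, None] - np.outer(taus, x)) / one_minus[:, None], axis=0)
            tq = (tmin - mu_q) / math.sqrt(var_q) * math.sqrt(2.0 * df) + df
            cdf = np.where(tq > 0, special.gammainc(df / 2.0, np.maximum(tq, 0) / 2.0), 0.0)
            val = math.sqrt(2.0 / math.pi) * float(np.sum(wts * cdf * np.exp(-x / 2.0)))
            p_final = 1.0 - val
    # Standard guards: the adjusted p cannot beat the best component and the
    # Bonferroni bound over the grid caps it from above.
    p_final = float(min(max(p_final, min_p, P_FLOOR), min(min_p * len(grid), 1.0)))
    return GeneTestResult(
        qset.gene, qset.mask, "SKATO", rho_min, p_final, qset.n_variants, qset.n_carriers,
        detail={"rho": rho_min, "component_p": {str(r): p_per_rho[r] for r in grid}},
    )


def single_variant_score_pvalues(
    qset: QualifyingVariantSet, null: NullModel
) -> np.ndarray:
    """Two-sided score-test p-value per variant (unweighted dosage)."""
    G = _check_set(qset, null)
    u = null.score(G)
    var = np.diag(null.score_cross_product(G))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, u / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = np.nan
    return np.maximum(p, P_FLOOR)


def acat_v_test(
    qset: QualifyingVariantSet,
    null: NullModel,
    mac_collapse_threshold: int = 10,
) -> GeneTestResult:
    """Cauchy combination of per-variant score p-values.

    Variants with minor allele count at or below the collapse threshold are
    merged into a single burden component; combination weights are
    w_j^2 * MAF_j * (1 - MAF_j), with the collapsed component taking the mean
    weight of its members.
    """
    G = _check_set(qset, null)
    mac = np.minimum(G.sum(axis=0), 2 * G.shape[0] - G.sum(axis=0)).astype(int)
    common = mac > mac_collapse_threshold
    base_w = qset.weights**2 * qset.maf * (1.0 - qset.maf)

    pvals: list[float] = []
    wts: list[float] = []
    if common.any():
        sub = QualifyingVariantSet(
            qset.gene, qset.mask,
            np.ascontiguousarray(qset.genotypes[:, common]),
            [qset.variant_ids[j] for j in np.where(common)[0]],
            qset.maf[common], qset.weights[common],
        )
        pj = single_variant_score_pvalues(sub, null)
        for p, w in zip(pj, base_w[common]):
            if np.isfinite(p):
                pvals.append(float(p))
                wts.append(float(w))
    if (~common).any():
        rare = QualifyingVariantSet(
            qset.gene, qset.mask,
            np.ascontiguousarray(qset.genotypes[:, ~common]),
            [qset.variant_ids[j] for j in np.where(~common)[0]],
            qset.maf[~common], qset.weights[~common],
        )
        try:
            pvals.append(burden_test(rare, null).p)
            wts.append(float(base_w[~common].mean()))
        except DegenerateSetError:
            if not pvals:
                raise
    if not pvals:
        raise DegenerateSetError(f"{qset.gene}/{qset.mask}: no combinable ACAT-V components")
    p = cauchy_combine(pvals, wts)
    return GeneTestResult(
        qset.gene, qset.mask, "ACATV", float(len(pvals)), p, qset.n_variants, qset.n_carriers,
        detail={"n_components": len(pvals), "n_collapsed": int((~common).sum())},
    )


def acat_o_test(
    gene: str,
    mask: str,
    component_pvalues: Sequence[float],
    n_variants: int = 0,
    n_carriers: int = 0,
) -> GeneTestResult:
    """Equal-weight Cauchy combination of available component test p-values."""
    ps = [float(p) for p in component_pvalues if p is not None and np.isfinite(p)]
    if not ps:
        raise DegenerateSetError(f"{gene}/{mask}: no valid ACAT-O components")
    p = cauchy_combine(ps)
    return GeneTestResult(
        gene, mask, "ACATO", float(len(ps)), p, n_variants, n_carriers,
        detail={"n_components": len(ps)},
    )


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Family-wise significance threshold alpha / n_genes."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    return alpha / n_genes


TEST_NAMES = ("burden", "skat", "skato", "acatv", "acato")


def run_gene_tests(
    qset: QualifyingVariantSet,
    null: NullModel,
    tests: Sequence[str] = TEST_NAMES,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    mac_collapse_threshold: int = 10,
) -> list[GeneTestResult]:
    """Run the requested tests on one qualifying set.

    ACAT-O combines whichever of burden / SKAT / ACAT-V ran successfully.
    Degenerate individual tests are skipped (not fatal for the others).
    """
    tests = [t.lower() for t in tests]
    unknown = set(tests) - set(TEST_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown tests: {sorted(unknown)}")
    results: list[GeneTestResult] = []
    components: dict[str, float] = {}
    runner = {
        "burden": lambda: burden_test(qset, null),
        "skat": lambda: skat_test(qset, null),
        "skato": lambda: skat_o_test(qset, null, rho_grid),
        "acatv": lambda: acat_v_test(qset, null, mac_collapse_threshold),
    }
    wanted_components = set(tests) | ({"burden", "skat", "acatv"} if "acato" in tests else set())
    for name in ("burden", "skat", "skato", "acatv"):
        if name not in wanted_components:
            continue
        try:
            res = runner[name]()
        except DegenerateSetError:
            continue
        if name in tests:
            results.append(res)
        if name in ("burden", "skat", "acatv"):
            components[name] = res.p
    if "acato" in tests:
        try:
            results.append(
                acat_o_test(
                    qset.gene, qset.mask, list(components.values()),
                    qset.n_variants, qset.n_carriers,
                )
            )
        except DegenerateSetError:
            pass
    return results
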