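"""Per-variant association scans on inbred-line panels.

Two phenotype models are fitted per site:

* a **lognormal accelerated-failure-time model** for checkpointed
  time-to-death data: log T ~ N(x'b + u_line + u_exp, sigma^2), with deaths
  contributing the normal log-density of log t and 48-h survivors the log
  survival function.  The Gaussian "frailty" terms are random intercepts;
  variance components are estimated by maximizing the Laplace-approximated
  marginal likelihood.  The fixed design is Wolbachia * SNP.

* a **binomial logit mixed model** for 48-h alive/dead counts with one
  Gaussian random intercept per line, integrated by adaptive Gauss-Hermite
  quadrature.  The fixed design is Wolbachia + SNP (no interaction, no
  experiment term).

Sites enter a scan only after a two-by-two inclusion filter on the
(Wolbachia status x allele) line counts: tables where each allele occurs in
exactly one Wolbachia class are dropped as completely collinear, and tables
where fewer than three of the four cells hold at least five lines are
dropped as too sparse.

P-values are likelihood-ratio tests of the SNP terms against the reduced
model (Wald tests would also be defensible; the LRT is the documented
choice).  In genome scans the variance components are estimated once under
the no-SNP null and held fixed across sites, the standard two-step shortcut
for mixed-model GWAS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.stats import chi2

from .panel_io import (
    CENSOR_HOUR,
    CHECKPOINTS,
    MISSING,
    SURVIVAL_DEATH_COLS,
    BinomialTable,
    GenotypePanel,
    SurvivalTable,
)

logger = logging.getLogger("resistscan")

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryCounts:
    """Line counts of the 2x2 (Wolbachia status x allele) table."""

    n_wp_ref: int
    n_wp_alt: int
    n_wm_ref: int
    n_wm_alt: int

    def __post_init__(self) -> None:
        if min(self.n_wp_ref, self.n_wp_alt, self.n_wm_ref, self.n_wm_alt) < 0:
            raise ValueError("category counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_wp_ref + self.n_wp_alt + self.n_wm_ref + self.n_wm_alt

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_wp_ref, self.n_wp_alt, self.n_wm_ref, self.n_wm_alt)


def category_counts(genotypes: np.ndarray, wolbachia: np.ndarray) -> CategoryCounts:
    """Cross-tabulate observed calls against *Wolbachia* status.

    ``genotypes`` are per-line calls in {0, 1, -1}; missing calls are
    excluded from the table.
    """
    g = np.asarray(genotypes)
    w = np.asarray(wolbachia, dtype=bool)
    obs = g != MISSING
    return CategoryCounts(
        n_wp_ref=int(np.sum(obs & w & (g == 0))),
        n_wp_alt=int(np.sum(obs & w & (g == 1))),
        n_wm_ref=int(np.sum(obs & ~w & (g == 0))),
        n_wm_alt=int(np.sum(obs & ~w & (g == 1))),
    )


def site_passes_filter(counts: CategoryCounts, min_lines: int = 5, min_cells: int = 3
                       ) -> tuple[bool, str]:
    """SNP inclusion rule on the 2x2 Wolbachia-by-allele table.

    Fails with reason ``"collinear"`` when each observed allele occurs in
    exactly one Wolbachia class (the two nonzero cells lie in different rows
    and different columns, so allele identity and symbiont status are
    confounded), and with reason ``"sparse"`` when fewer than ``min_cells``
    cells hold at least ``min_lines`` lines.
    """
    a, b, c, d = counts.as_tuple()  # (W+ ref, W+ alt, W- ref, W- alt)
    nonzero = [x > 0 for x in (a, b, c, d)]
    if sum(nonzero) == 2:
        # diagonal patterns: {W+ ref, W- alt} or {W+ alt, W- ref}
        if (a > 0 and d > 0) or (b > 0 and c > 0):
            return False, "collinear"
    if sum(x >= min_lines for x in (a, b, c, d)) < min_cells:
        return False, "sparse"
    return True, "ok"


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class AssocFit:
    """Result of a per-site model fit."""

    coefficients: dict[str, float]
    se: dict[str, float]
    var_components: dict[str, float]
    loglik: float
    p_snp: float | None
    p_interaction: float | None
    lrt_snp: float | None = None
    lrt_interaction: float | None = None
    scale: float | None = None  # residual sigma of the AFT model
    converged: bool = True
    status: str = "ok"
    n_lines: int = 0


# ---------------------------------------------------------------------------
# Lognormal AFT with Gaussian random intercepts
# ---------------------------------------------------------------------------

_LOG_CENSOR = math.log(CENSOR_HOUR)
_LOG_CP = np.log(np.asarray(CHECKPOINTS))


@dataclass
class _AftData:
    """Survival data grouped into (line, experiment, vial) cells."""

    cell_line: np.ndarray  # (C,) index into `lines`
    cell_exp: np.ndarray  # (C,) index into experiments
    death_cell: np.ndarray  # flat death-entry -> cell index
    death_logt: np.ndarray  # flat death-entry log time
    death_count: np.ndarray  # flat death-entry count
    cens_count: np.ndarray  # (C,) censored flies per cell
    lines: list[str]
    n_exp: int
    wolbachia: np.ndarray  # (L,) bool

    @classmethod
    def from_table(cls, table: SurvivalTable, metadata: pd.DataFrame | None) -> "_AftData":
        df = table.data
        lines = list(pd.unique(df["line_id"]))
        line_index = {l: i for i, l in enumerate(lines)}
        exps = list(pd.unique(df["experiment_id"]))
        exp_index = {e: i for i, e in enumerate(exps)}
        cell_line = df["line_id"].map(line_index).to_numpy(dtype=int)
        cell_exp = df["experiment_id"].map(exp_index).to_numpy(dtype=int)
        deaths = df[SURVIVAL_DEATH_COLS].to_numpy(dtype=float)
        cens = df["n_start"].to_numpy(dtype=float) - deaths.sum(axis=1)
        cell_ids, cp_ids = np.nonzero(deaths > 0)
        if metadata is not None:
            wmap = dict(zip(metadata["line_id"], metadata["wolbachia"].astype(bool)))
            wolb = np.array([bool(wmap[l]) for l in lines])
        else:
            wolb = np.zeros(len(lines), dtype=bool)
        return cls(
            cell_line=cell_line,
            cell_exp=cell_exp,
            death_cell=cell_ids,
            death_logt=_LOG_CP[cp_ids],
            death_count=deaths[cell_ids, cp_ids],
            cens_count=cens,
            lines=lines,
            n_exp=len(exps),
            wolbachia=wolb,
        )

    def subset_lines(self, keep: np.ndarray) -> "_AftData":
        """Restrict to lines where ``keep`` (bool over self.lines) is true."""
        keep = np.asarray(keep, dtype=bool)
        new_idx = -np.ones(len(self.lines), dtype=int)
        kept = np.flatnonzero(keep)
        new_idx[kept] = np.arange(kept.size)
        cell_mask = keep[self.cell_line]
        cell_pos = -np.ones(cell_mask.size, dtype=int)
        cell_pos[cell_mask] = np.arange(int(cell_mask.sum()))
        death_mask = cell_mask[self.death_cell]
        return _AftData(
            cell_line=new_idx[self.cell_line[cell_mask]],
            cell_exp=self.cell_exp[cell_mask],
            death_cell=cell_pos[self.death_cell[death_mask]],
            death_logt=self.death_logt[death_mask],
            death_count=self.death_count[death_mask],
            cens_count=self.cens_count[cell_mask],
            lines=[self.lines[i] for i in kept],
            n_exp=self.n_exp,
            wolbachia=self.wolbachia[kept],
        )


def _aft_design(
    data: _AftData,
    snp: np.ndarray | None,
    include_wolbachia: bool,
    include_snp: bool,
    include_interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    """Cell-level fixed design matrix and term names."""
    w = data.wolbachia[data.cell_line].astype(float)
    cols = [np.ones(data.cell_line.size)]
    names = ["intercept"]
    if include_wolbachia:
        cols.append(w)
        names.append("wolbachia")
    if include_snp:
        g = snp[data.cell_line].astype(float)
        cols.append(g)
        names.append("snp")
        if include_interaction:
            cols.append(g * w)
            names.append("snp:wolbachia")
    return np.column_stack(cols), names


def _aft_newton(
    data: _AftData,
    X: np.ndarray,
    re_line: bool,
    re_exp: bool,
    s2_line: float,
    s2_exp: float,
    theta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict[str, Any]:
    """Maximize the penalized AFT log-likelihood by damped Newton.

    Parameter vector is (beta, u_line?, u_exp?, rho = log sigma).  Returns the
    mode, the full negative-definite Hessian and the Laplace-approximated
    marginal log-likelihood.
    """
    C = data.cell_line.size
    p = X.shape[1]
    L = len(data.lines) if re_line else 0
    E = data.n_exp if re_exp else 0
    dim = p + L + E + 1

    A = np.empty((C, p + L + E))
    A[:, :p] = X
    if L:
        Z = np.zeros((C, L))
        Z[np.arange(C), data.cell_line] = 1.0
        A[:, p : p + L] = Z
    if E:
        Z = np.zeros((C, E))
        Z[np.arange(C), data.cell_exp] = 1.0
        A[:, p + L :] = Z

    pen_diag = np.zeros(p + L + E)
    pen_const = 0.0
    if L:
        pen_diag[p : p + L] = 1.0 / s2_line
        pen_const -= 0.5 * L * math.log(2.0 * math.pi * s2_line)
    if E:
        pen_diag[p + L :] = 1.0 / s2_exp
        pen_const -= 0.5 * E * math.log(2.0 * math.pi * s2_exp)

    d_cell = data.death_cell
    d_logt = data.death_logt
    d_cnt = data.death_count
    m = data.cens_count
    cens_cells = np.flatnonzero(m > 0)
    m_c = m[cens_cells]
    n_deaths = float(d_cnt.sum())

    def pll(theta: np.ndarray) -> float:
        eta = A @ theta[:-1]
        rho = theta[-1]
        sigma = math.exp(rho)
        z = (d_logt - eta[d_cell]) / sigma
        ll = float(np.sum(d_cnt * (-rho - 0.5 * _LOG2PI - 0.5 * z * z)))
        if cens_cells.size:
            zc = (_LOG_CENSOR - eta[cens_cells]) / sigma
            ll += float(np.sum(m_c * special.log_ndtr(-zc)))
        u = theta[:-1]
        ll -= 0.5 * float(np.sum(pen_diag * u * u))
        return ll + pen_const

    def derivatives(theta: np.ndarray):
        eta = A @ theta[:-1]
        rho = theta[-1]
        sigma = math.exp(rho)
        z = (d_logt - eta[d_cell]) / sigma
        g_eta = np.bincount(d_cell, weights=d_cnt * z / sigma, minlength=C)
        h_eta = np.bincount(d_cell, weights=-d_cnt / sigma**2, minlength=C)
        c_eta = np.bincount(d_cell, weights=-2.0 * d_cnt * z / sigma, minlength=C)
        g_rho = float(np.sum(d_cnt * (z * z - 1.0)))
        h_rho = float(np.sum(-2.0 * d_cnt * z * z))
        if cens_cells.size:
            zc = (_LOG_CENSOR - eta[cens_cells]) / sigma
            lam = np.exp(-0.5 * zc * zc - 0.5 * _LOG2PI - special.log_ndtr(-zc))
            hz = lam * (lam - zc)  # positive curvature factor
            g_eta[cens_cells] += m_c * lam / sigma
            h_eta[cens_cells] += -m_c * hz / sigma**2
            c_eta[cens_cells] += m_c * (-zc * hz - lam) / sigma
            g_rho += float(np.sum(m_c * lam * zc))
            h_rho += float(np.sum(m_c * (-zc * zc * hz - lam * zc)))
        u = theta[:-1]
        grad = np.empty(dim)
        grad[:-1] = A.T @ g_eta - pen_diag * u
        grad[-1] = g_rho
        H = np.empty((dim, dim))
        H[:-1, :-1] = (A * h_eta[:, None]).T @ A
        H[np.arange(p + L + E), np.arange(p + L + E)] -= pen_diag
        cross = A.T @ c_eta
        H[:-1, -1] = cross
        H[-1, :-1] = cross
        H[-1, -1] = h_rho
        return grad, H

    if theta0 is None:
        theta = np.zeros(dim)
        # initialize intercept/scale from the death-time moments
        if n_deaths > 0:
            mu0 = float(np.sum(d_cnt * d_logt) / n_deaths)
            var0 = float(np.sum(d_cnt * (d_logt - mu0) ** 2) / n_deaths)
            theta[0] = mu0
            theta[-1] = 0.5 * math.log(max(var0, 1e-3))
        else:
            theta[0] = _LOG_CENSOR
            theta[-1] = math.log(0.5)
    else:
        theta = theta0.copy()

    from scipy.linalg import cho_factor, cho_solve

    f = pll(theta)
    converged = False
    eye = np.eye(dim)
    for _ in range(max_iter):
        grad, H = derivatives(theta)
        if float(np.max(np.abs(grad))) < tol * max(1.0, abs(f)):
            converged = True
            break
        # the Hessian need not be negative definite away from the mode;
        # ridge -H up to positive definiteness so the step is an ascent
        Hn = -H
        ridge = 0.0
        scale = float(np.max(np.abs(np.diag(Hn)))) + 1e-12
        while True:
            try:
                factor = cho_factor(Hn + ridge * eye, lower=True)
                step = cho_solve(factor, grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8 * scale)
        # backtracking line search (simple ascent condition)
        t = 1.0
        improved = False
        for _bt in range(50):
            cand = theta + t * step
            fc = pll(cand)
            if np.isfinite(fc) and fc > f:
                theta, f = cand, fc
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    grad, H = derivatives(theta)
    if not converged:
        converged = float(np.max(np.abs(grad))) < 1e-4 * max(1.0, abs(f))

    # Laplace marginal over the random intercepts
    q = L + E
    mll = f
    if q:
        H_uu = -H[p : p + q, p : p + q]
        sign, logdet = np.linalg.slogdet(H_uu)
        if sign <= 0:  # pragma: no cover - mode should be a maximum
            logdet = np.inf
        mll = f + 0.5 * q * _LOG2PI - 0.5 * logdet
    return {
        "theta": theta,
        "pll": f,
        "mll": float(mll),
        "H": H,
        "converged": bool(converged),
        "p": p,
        "L": L,
        "E": E,
    }


def _estimate_aft_vc(
    data: _AftData,
    X: np.ndarray,
    re_line: bool,
    re_exp: bool,
) -> tuple[float, float]:
    """Variance components maximizing the Laplace marginal likelihood."""
    state: dict[str, Any] = {"theta": None}

    def neg_mll(logs: np.ndarray) -> float:
        s2l = math.exp(logs[0]) if re_line else 0.0
        s2e = math.exp(logs[1]) if (re_exp and logs.size > 1) else 0.0
        fit = _aft_newton(
            data, X, re_line, re_exp,
            s2l if re_line else 1.0, s2e if re_exp else 1.0,
            theta0=state["theta"],
        )
        state["theta"] = fit["theta"]
        return -fit["mll"]

    if re_line and re_exp:
        res = optimize.minimize(
            neg_mll, x0=np.array([math.log(0.25), math.log(0.04)]),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 120},
        )
        return math.exp(res.x[0]), math.exp(res.x[1])
    if re_line or re_exp:
        res = optimize.minimize_scalar(
            lambda x: neg_mll(np.array([x])), bounds=(-10.0, 4.0), method="bounded",
            options={"xatol": 1e-3},
        )
        s2 = math.exp(res.x)
        return (s2, 0.0) if re_line else (0.0, s2)
    return 0.0, 0.0


def fit_lognormal_aft(
    survival: SurvivalTable,
    metadata: pd.DataFrame | None = None,
    snp: Mapping[str, int] | pd.Series | None = None,
    include_interaction: bool = True,
    random_effects: Sequence[str] = ("line", "experiment"),
    var_components: tuple[float, float] | None = None,
) -> AssocFit:
    """Fit the censored lognormal AFT association model for one site.

    The full fixed design is ``Wolbachia * SNP`` (interaction included by
    default); ``p_snp`` is a likelihood-ratio test of the SNP and interaction
    terms jointly against the Wolbachia-only reduced model, and
    ``p_interaction`` tests the interaction alone.  Lines with a missing
    genotype are excluded from the fit.

    ``var_components`` fixes ``(sigma2_line, sigma2_exp)``; when ``None``
    they are estimated by maximizing the Laplace marginal likelihood of the
    full model.
    """
    data = _AftData.from_table(survival, metadata)
    include_wolb = metadata is not None
    include_snp = snp is not None
    include_inter = include_interaction and include_wolb and include_snp

    g = None
    if include_snp:
        s = pd.Series(snp)
        g_full = np.array(
            [int(s.get(l, MISSING)) for l in data.lines], dtype=int
        )
        keep = g_full != MISSING
        if not keep.all():
            data = data.subset_lines(keep)
        g = g_full[keep.nonzero()[0]] if not keep.all() else g_full

    if data.death_count.sum() == 0:
        return AssocFit(
            coefficients={}, se={}, var_components={}, loglik=np.nan,
            p_snp=None, p_interaction=None, converged=False,
            status="no_events", n_lines=len(data.lines),
        )

    re_line = "line" in random_effects
    re_exp = "experiment" in random_effects

    X_full, names = _aft_design(data, g, include_wolb, include_snp, include_inter)
    if var_components is None:
        s2l, s2e = _estimate_aft_vc(data, X_full, re_line, re_exp)
    else:
        s2l, s2e = var_components
        re_line = re_line and s2l > 0
        re_exp = re_exp and s2e > 0

    full = _aft_newton(data, X_full, re_line, re_exp, max(s2l, 1e-12), max(s2e, 1e-12))

    p_snp = p_inter = lrt_snp = lrt_inter = None
    status = "ok" if full["converged"] else "nonconverged"
    if include_snp:
        X_red, _ = _aft_design(data, g, include_wolb, False, False)
        red = _aft_newton(data, X_red, re_line, re_exp, max(s2l, 1e-12), max(s2e, 1e-12))
        df_snp = 2 if include_inter else 1
        lrt_snp = max(2.0 * (full["mll"] - red["mll"]), 0.0)
        p_snp = float(chi2.sf(lrt_snp, df_snp))
        if include_inter:
            X_add, _ = _aft_design(data, g, include_wolb, True, False)
            add = _aft_newton(
                data, X_add, re_line, re_exp, max(s2l, 1e-12), max(s2e, 1e-12)
            )
            lrt_inter = max(2.0 * (full["mll"] - add["mll"]), 0.0)
            p_inter = float(chi2.sf(lrt_inter, 1))
        if not (full["converged"] and red["converged"]):
            status = "nonconverged"
        # complete separation: all carriers (or non-carriers) censored
        deaths_per_line = np.bincount(
            data.cell_line[data.death_cell],
            weights=data.death_count,
            minlength=len(data.lines),
        )
        for allele in (0, 1):
            sel = g == allele
            if sel.any() and deaths_per_line[sel].sum() == 0:
                status = "separation"

    theta = full["theta"]
    p = full["p"]
    coefs = dict(zip(names, theta[:p].tolist()))
    Hn = -full["H"]
    se: dict[str, float] = {}
    try:
        cov = np.linalg.inv(Hn)
        se = {nm: float(math.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        se = {nm: float("nan") for nm in names}

    return AssocFit(
        coefficients=coefs,
        se=se,
        var_components={"line": float(s2l), "experiment": float(s2e)},
        loglik=float(full["mll"]),
        p_snp=p_snp,
        p_interaction=p_inter,
        lrt_snp=lrt_snp,
        lrt_interaction=lrt_inter,
        scale=float(math.exp(theta[-1])),
        converged=bool(full["converged"]),
        status=status,
        n_lines=len(data.lines),
    )


# ---------------------------------------------------------------------------
# Binomial GLMM (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

@dataclass
class _BinData:
    """48-h mortality collapsed to per-line totals (covariates are per line)."""

    lines: list[str]
    dead: np.ndarray  # (L,)
    total: np.ndarray  # (L,)
    wolbachia: np.ndarray  # (L,) bool
    log_binom_const: float  # sum of per-vial binomial coefficients

    @classmethod
    def from_table(cls, table: BinomialTable, metadata: pd.DataFrame | None) -> "_BinData":
        df = table.data
        tot = df["alive_48"].to_numpy(float) + df["dead_48"].to_numpy(float)
        const = float(
            np.sum(
                special.gammaln(tot + 1)
                - special.gammaln(df["dead_48"].to_numpy(float) + 1)
                - special.gammaln(df["alive_48"].to_numpy(float) + 1)
            )
        )
        agg = df.groupby("line_id", sort=False).agg(
            dead=("dead_48", "sum"), alive=("alive_48", "sum")
        )
        lines = list(agg.index)
        if metadata is not None:
            wmap = dict(zip(metadata["line_id"], metadata["wolbachia"].astype(bool)))
            wolb = np.array([bool(wmap[l]) for l in lines])
        else:
            wolb = np.zeros(len(lines), dtype=bool)
        return cls(
            lines=lines,
            dead=agg["dead"].to_numpy(float),
            total=(agg["dead"] + agg["alive"]).to_numpy(float),
            wolbachia=wolb,
            log_binom_const=const,
        )

    def subset_lines(self, keep: np.ndarray) -> "_BinData":
        keep = np.asarray(keep, dtype=bool)
        return _BinData(
            lines=[l for l, k in zip(self.lines, keep) if k],
            dead=self.dead[keep],
            total=self.total[keep],
            wolbachia=self.wolbachia[keep],
            log_binom_const=self.log_binom_const,  # constant; irrelevant to LRT
        )


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _glmm_loglik(
    data: _BinData, eta: np.ndarray, sigma: float
) -> float:
    """Marginal log-likelihood, adaptive GHQ over the per-line intercept."""
    D, N = data.dead, data.total
    if sigma < 1e-8:
        p = special.expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = D * np.log(p) + (N - D) * np.log1p(-p)
        ll = np.where((D == 0) & (p == 0), 0.0, ll)
        ll = np.where((D == N) & (p == 1), 0.0, ll)
        return float(np.sum(ll)) + data.log_binom_const
    s2 = sigma * sigma
    # per-line mode of f(u) = D log p + (N-D) log(1-p) - u^2/(2 s2);
    # f is strictly concave, but raw Newton can overshoot and oscillate when
    # p saturates, so steps are clamped
    u = np.zeros_like(eta)
    for _ in range(80):
        p = special.expit(eta + u)
        g = D - N * p - u / s2
        h_pd = N * p * (1 - p) + 1.0 / s2
        step = np.clip(g / h_pd, -3.0, 3.0)
        u += step
        if float(np.max(np.abs(step))) < 1e-11:
            break
    p = special.expit(eta + u)
    tau = 1.0 / np.sqrt(N * p * (1 - p) + 1.0 / s2)
    # integral: sqrt(2) tau sum_q w_q e^{x_q^2} e^{f(u_q)}, f includes N(0,s2) density
    uq = u[:, None] + math.sqrt(2.0) * tau[:, None] * _GH_NODES[None, :]
    etaq = eta[:, None] + uq
    f = (
        D[:, None] * etaq
        - N[:, None] * np.logaddexp(0.0, etaq)
        - 0.5 * uq * uq / s2
        - 0.5 * math.log(2.0 * math.pi * s2)
    )
    t = np.log(_GH_WEIGHTS)[None, :] + _GH_NODES[None, :] ** 2 + f
    ll = 0.5 * math.log(2.0) + np.log(tau) + special.logsumexp(t, axis=1)
    return float(np.sum(ll)) + data.log_binom_const


def _glmm_design(
    data: _BinData, snp: np.ndarray | None, include_wolbachia: bool
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data.lines))]
    names = ["intercept"]
    if include_wolbachia:
        cols.append(data.wolbachia.astype(float))
        names.append("wolbachia")
    if snp is not None:
        cols.append(snp.astype(float))
        names.append("snp")
    return np.column_stack(cols), names


def _num_grad(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = eps
        g[i] = (f(x + e) - f(x - e)) / (2 * eps)
    return g


def _num_hess(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def _fit_glmm(
    data: _BinData,
    X: np.ndarray,
    sigma: float | None,
    beta0: np.ndarray | None = None,
) -> dict[str, Any]:
    """Maximize the GLMM likelihood; ``sigma=None`` estimates it too.

    Convergence is judged from the measured gradient at the optimum rather
    than the optimizer's own flag (finite-difference BFGS often reports
    spurious precision-loss failures at a perfectly good mode).
    """
    p = X.shape[1]

    if sigma is None:
        def nll(par: np.ndarray) -> float:
            return -_glmm_loglik(data, X @ par[:p], math.exp(par[p]))

        x0 = np.zeros(p + 1)
        if beta0 is not None:
            x0[:p] = beta0
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 3000})
        res2 = optimize.minimize(nll, res.x, method="BFGS",
                                 options={"gtol": 1e-5, "maxiter": 200})
        best = res2 if res2.fun <= res.fun else res
        grad = _num_grad(nll, best.x)
        tol = 1e-3 * max(1.0, abs(best.fun))
        # the sigma direction flattens near the boundary; judge beta only
        conv = bool(np.isfinite(best.fun) and np.max(np.abs(grad[:p])) < tol)
        return {"beta": best.x[:p], "sigma": math.exp(best.x[p]),
                "ll": -best.fun, "converged": conv}

    def nll_b(par: np.ndarray) -> float:
        return -_glmm_loglik(data, X @ par, sigma)

    x0 = beta0 if beta0 is not None else np.zeros(p)
    res = optimize.minimize(nll_b, x0, method="BFGS",
                            options={"gtol": 1e-5, "maxiter": 300})
    x, fx = res.x, float(res.fun)
    grad = _num_grad(nll_b, x)
    tol = 1e-3 * max(1.0, abs(fx))
    if not (np.isfinite(fx) and np.max(np.abs(grad)) < tol):
        res_nm = optimize.minimize(nll_b, x, method="Nelder-Mead",
                                   options={"xatol": 1e-6, "fatol": 1e-9,
                                            "maxiter": 2000})
        if res_nm.fun <= fx:
            x, fx = res_nm.x, float(res_nm.fun)
        grad = _num_grad(nll_b, x)
    # numeric Newton polish: BFGS with finite differences stops a touch
    # short of the mode, which matters for exact limiting-case identities
    for _ in range(3):
        H = _num_hess(nll_b, x)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        cand = x - step
        fc = float(nll_b(cand))
        if not np.isfinite(fc) or fc > fx + 1e-12:
            break
        x, fx = cand, fc
        grad = _num_grad(nll_b, x)
        if np.max(np.abs(step)) < 1e-10:
            break
    conv = bool(np.isfinite(fx) and np.max(np.abs(grad)) < tol)
    return {"beta": x, "sigma": sigma, "ll": -fx, "converged": conv}


def _glmm_beta_se(data: _BinData, X: np.ndarray, beta: np.ndarray, sigma: float
                  ) -> np.ndarray:
    """Standard errors from a central-difference observed information."""
    p = X.shape[1]
    h = 1e-4
    H = np.zeros((p, p))
    f0 = _glmm_loglik(data, X @ beta, sigma)
    for i in range(p):
        for j in range(i, p):
            bi, bj = np.zeros(p), np.zeros(p)
            bi[i] = h
            bj[j] = h
            fpp = _glmm_loglik(data, X @ (beta + bi + bj), sigma)
            fpm = _glmm_loglik(data, X @ (beta + bi - bj), sigma)
            fmp = _glmm_loglik(data, X @ (beta - bi + bj), sigma)
            fmm = _glmm_loglik(data, X @ (beta - bi - bj), sigma)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(-H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(p, np.nan)


def fit_binomial_glmm(
    binomial: BinomialTable,
    metadata: pd.DataFrame | None = None,
    snp: Mapping[str, int] | pd.Series | None = None,
    var_line: float | None = None,
) -> AssocFit:
    """Fit the binomial logit mixed model for one site.

    Fixed design ``Wolbachia + SNP`` with a Gaussian random intercept per
    line; the likelihood is integrated by 15-node adaptive Gauss-Hermite
    quadrature.  ``p_snp`` is a 1-df likelihood-ratio test against the
    Wolbachia-only reduced model.  ``var_line`` fixes sigma_line^2 (0 reduces
    the model to ordinary logistic regression); ``None`` estimates it.
    """
    data = _BinData.from_table(binomial, metadata)
    include_wolb = metadata is not None

    g = None
    if snp is not None:
        s = pd.Series(snp)
        g_full = np.array([int(s.get(l, MISSING)) for l in data.lines], dtype=int)
        keep = g_full != MISSING
        if not keep.all():
            data = data.subset_lines(keep)
        g = g_full[keep]

    sigma = None if var_line is None else math.sqrt(var_line)
    X_full, names = _glmm_design(data, g, include_wolb)
    full = _fit_glmm(data, X_full, sigma)

    p_snp = lrt_snp = None
    status = "ok" if full["converged"] else "nonconverged"
    if g is not None:
        X_red, _ = _glmm_design(data, None, include_wolb)
        red = _fit_glmm(data, X_red, sigma)
        lrt_snp = max(2.0 * (full["ll"] - red["ll"]), 0.0)
        p_snp = float(chi2.sf(lrt_snp, 1))
        if not red["converged"]:
            status = "nonconverged"
        # separation on the collapsed table
        for allele in (0, 1):
            sel = g == allele
            if sel.any() and (
                data.dead[sel].sum() == 0
                or data.dead[sel].sum() == data.total[sel].sum()
            ):
                status = "separation"

    beta = full["beta"]
    se_vals = _glmm_beta_se(data, X_full, beta, full["sigma"])
    return AssocFit(
        coefficients=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se_vals.tolist())),
        var_components={"line": float(full["sigma"] ** 2)},
        loglik=float(full["ll"]),
        p_snp=p_snp,
        p_interaction=None,
        lrt_snp=lrt_snp,
        converged=bool(full["converged"]),
        status=status,
        n_lines=len(data.lines),
    )


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

THRESHOLD_MARKS = (4.0, 5.0, 8.0)

_SCAN_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "n_Wp_ref", "n_Wp_alt", "n_Wm_ref", "n_Wm_alt",
    "beta_snp", "se_snp", "p_snp", "p_interaction",
    "minus_log10_p", "q_bh", "status",
]


@dataclass
class AssociationResult:
    """Per-variant scan output plus bookkeeping counts.

    ``table`` is Manhattan-ready: one row per site that passed the inclusion
    filter, sorted by position.  ``q_bh`` is a Benjamini-Hochberg q-value
    column provided as an extra convenience; the fixed -log10 p thresholds
    remain the primary bookkeeping.
    """

    table: pd.DataFrame
    model: str
    threshold_counts: dict[float, int] = field(default_factory=dict)
    n_sites_total: int = 0
    n_sites_tested: int = 0
    n_filtered: dict[str, int] = field(default_factory=dict)
    n_flagged: int = 0
    status: str = "ok"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def top_hit(self) -> pd.Series | None:
        ok = self.table.dropna(subset=["p_snp"])
        if ok.empty:
            return None
        return ok.loc[ok["p_snp"].idxmin()]


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-safe)."""
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def _empty_result(model: str, status: str) -> AssociationResult:
    return AssociationResult(
        table=pd.DataFrame(columns=_SCAN_COLUMNS),
        model=model,
        threshold_counts={t: 0 for t in THRESHOLD_MARKS},
        status=status,
    )


def gwas_scan(
    panel: GenotypePanel,
    phenotypes: SurvivalTable | BinomialTable,
    metadata: pd.DataFrame,
    model: Literal["survival", "binomial"] = "survival",
    compute_interaction: bool = True,
    var_components: tuple[float, float] | float | None = None,
) -> AssociationResult:
    """Genome-wide per-variant association scan.

    Applies the inclusion filter at every site, then fits the phenotype
    model.  Variance components are estimated once under the no-SNP null
    (on the full line set) and held fixed across sites; pass
    ``var_components`` to override.  Sites flagged non-converged or separated
    keep their row but carry NaN p-values and are excluded from the
    threshold bookkeeping.
    """
    pheno_lines = set(phenotypes.lines)
    meta = metadata[metadata["line_id"].isin(pheno_lines)]
    lines = [l for l in panel.lines if l in set(meta["line_id"])]
    if not lines:
        return _empty_result(model, "empty_subset")
    sub_panel = panel.take_lines(lines)
    meta = meta.set_index("line_id").loc[lines].reset_index()
    wolb = meta["wolbachia"].to_numpy(dtype=bool)

    if model == "survival":
        if not isinstance(phenotypes, SurvivalTable):
            raise TypeError("survival model requires a SurvivalTable")
        data_all = _AftData.from_table(phenotypes, meta)
        keep = np.array([l in set(lines) for l in data_all.lines])
        if not keep.all():
            data_all = data_all.subset_lines(keep)
        order = {l: i for i, l in enumerate(data_all.lines)}
        g_row = np.array([order[l] for l in lines])
        if var_components is None:
            X0, _ = _aft_design(data_all, None, True, False, False)
            s2l, s2e = _estimate_aft_vc(data_all, X0, True, True)
        else:
            s2l, s2e = var_components  # type: ignore[misc]
        fit_cache: dict[tuple[bytes, str], dict[str, Any]] = {}

        def fit_site(g_lines: np.ndarray) -> tuple[AssocFit | None, dict[str, float]]:
            g_data = np.full(len(data_all.lines), MISSING, dtype=int)
            g_data[g_row] = g_lines
            obs = g_data != MISSING
            d = data_all if obs.all() else data_all.subset_lines(obs)
            gg = g_data[obs]
            key = obs.tobytes()
            red = fit_cache.get((key, "red"))
            if red is None:
                X_red, _ = _aft_design(d, gg, True, False, False)
                red = _aft_newton(d, X_red, True, True, s2l, s2e)
                fit_cache[(key, "red")] = red
            X_full, names = _aft_design(d, gg, True, True, compute_interaction)
            theta0 = None
            if red["theta"] is not None:
                theta0 = np.zeros(X_full.shape[1] + red["L"] + red["E"] + 1)
                theta0[:2] = red["theta"][:2]
                theta0[X_full.shape[1]:] = red["theta"][2:]
            full = _aft_newton(d, X_full, True, True, s2l, s2e, theta0=theta0)
            df_snp = 2 if compute_interaction else 1
            lrt = max(2.0 * (full["mll"] - red["mll"]), 0.0)
            p_snp = float(chi2.sf(lrt, df_snp))
            p_int = np.nan
            if compute_interaction:
                X_add, _ = _aft_design(d, gg, True, True, False)
                theta0a = np.delete(full["theta"], 3)
                add = _aft_newton(d, X_add, True, True, s2l, s2e, theta0=theta0a)
                p_int = float(chi2.sf(max(2.0 * (full["mll"] - add["mll"]), 0.0), 1))
                conv = full["converged"] and red["converged"] and add["converged"]
            else:
                conv = full["converged"] and red["converged"]
            i_snp = 2  # (intercept, wolbachia, snp, ...)
            Hn = -full["H"]
            try:
                cov = np.linalg.inv(Hn)
                se_snp = float(math.sqrt(max(cov[i_snp, i_snp], 0.0)))
            except np.linalg.LinAlgError:  # pragma: no cover
                se_snp = float("nan")
            return None, {
                "beta_snp": float(full["theta"][i_snp]),
                "se_snp": se_snp,
                "p_snp": p_snp,
                "p_interaction": p_int,
                "converged": conv,
            }
    else:
        if not isinstance(phenotypes, BinomialTable):
            raise TypeError("binomial model requires a BinomialTable")
        bdata_all = _BinData.from_table(phenotypes, meta)
        keep = np.array([l in set(lines) for l in bdata_all.lines])
        if not keep.all():
            bdata_all = bdata_all.subset_lines(keep)
        order = {l: i for i, l in enumerate(bdata_all.lines)}
        g_row = np.array([order[l] for l in lines])
        if var_components is None:
            X0, _ = _glmm_design(bdata_all, None, True)
            null = _fit_glmm(bdata_all, X0, None)
            sigma0 = null["sigma"]
        else:
            vc = var_components
            sigma0 = math.sqrt(vc if np.isscalar(vc) else vc[0])  # type: ignore[arg-type]
        bfit_cache: dict[bytes, dict[str, Any]] = {}

        def fit_site(g_lines: np.ndarray) -> tuple[AssocFit | None, dict[str, float]]:
            g_data = np.full(len(bdata_all.lines), MISSING, dtype=int)
            g_data[g_row] = g_lines
            obs = g_data != MISSING
            d = bdata_all if obs.all() else bdata_all.subset_lines(obs)
            gg = g_data[obs].astype(float)
            key = obs.tobytes()
            red = bfit_cache.get(key)
            if red is None:
                X_red, _ = _glmm_design(d, None, True)
                red = _fit_glmm(d, X_red, sigma0)
                bfit_cache[key] = red
            X_full, _ = _glmm_design(d, gg, True)
            beta0 = np.append(red["beta"], 0.0)
            full = _fit_glmm(d, X_full, sigma0, beta0=beta0)
            lrt = max(2.0 * (full["ll"] - red["ll"]), 0.0)
            se = _glmm_beta_se(d, X_full, full["beta"], sigma0)
            return None, {
                "beta_snp": float(full["beta"][-1]),
                "se_snp": float(se[-1]),
                "p_snp": float(chi2.sf(lrt, 1)),
                "p_interaction": np.nan,
                "converged": full["converged"] and red["converged"],
            }

    rows = []
    n_filtered = {"collinear": 0, "sparse": 0}
    n_flagged = 0
    for j in range(sub_panel.n_variants):
        g = sub_panel.calls[:, j].astype(int)
        counts = category_counts(g, wolb)
        ok, reason = site_passes_filter(counts)
        if not ok:
            n_filtered[reason] += 1
            continue
        _, fit = fit_site(g)
        var = sub_panel.variants.iloc[j]
        status = "ok" if fit["converged"] else "nonconverged"
        if not fit["converged"]:
            n_flagged += 1
        p_val = fit["p_snp"] if fit["converged"] else np.nan
        rows.append(
            {
                "chrom": var["chrom"],
                "pos": int(var["pos"]),
                "ref": var["ref"],
                "alt": var["alt"],
                "n_Wp_ref": counts.n_wp_ref,
                "n_Wp_alt": counts.n_wp_alt,
                "n_Wm_ref": counts.n_wm_ref,
                "n_Wm_alt": counts.n_wm_alt,
                "beta_snp": fit["beta_snp"],
                "se_snp": fit["se_snp"],
                "p_snp": p_val,
                "p_interaction": fit["p_interaction"] if fit["converged"] else np.nan,
                "minus_log10_p": -np.log10(p_val) if p_val and p_val > 0 else (
                    np.inf if p_val == 0 else np.nan
                ),
                "status": status,
            }
        )
    table = pd.DataFrame(rows, columns=[c for c in _SCAN_COLUMNS if c != "q_bh"])
    if len(table):
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        table["q_bh"] = _bh_qvalues(table["p_snp"].to_numpy(dtype=float))
        table = table[_SCAN_COLUMNS]
    else:
        table = pd.DataFrame(columns=_SCAN_COLUMNS)
    mlp = table["minus_log10_p"].to_numpy(dtype=float) if len(table) else np.array([])
    counts_over = {t: int(np.nansum(mlp > t)) for t in THRESHOLD_MARKS}
    if n_flagged:
        logger.info("gwas_scan: %d sites flagged non-converged", n_flagged)
    logger.info(
        "gwas_scan(%s): tested %d sites (filtered: %s)", model, len(table), n_filtered
    )
    return AssociationResult(
        table=table,
        model=model,
        threshold_counts=counts_over,
        n_sites_total=sub_panel.n_variants,
        n_sites_tested=len(table),
        n_filtered=n_filtered,
        n_flagged=n_flagged,
    )


def infer_resistant_allele(
    panel: GenotypePanel,
    phenotypes: SurvivalTable | BinomialTable,
    metadata: pd.DataFrame,
    variant: tuple[str, int],
    model: Literal["survival", "binomial"],
) -> int:
    """Allele (0 or 1) associated with longer survival / lower mortality."""
    j = panel.site_index(*variant)
    g = pd.Series(panel.calls[:, j].astype(int), index=panel.lines)
    g = g[g != MISSING]
    if model == "survival":
        fit = fit_lognormal_aft(phenotypes, metadata, snp=g, include_interaction=False)
        beta = fit.coefficients.get("snp", 0.0)
        return 1 if beta > 0 else 0  # positive = longer log survival time
    fit = fit_binomial_glmm(phenotypes, metadata, snp=g)
    beta = fit.coefficients.get("snp", 0.0)
    return 1 if beta < 0 else 0  # negative = lower log-odds of death


def nested_scan(
    panel: GenotypePanel,
    phenotypes: SurvivalTable | BinomialTable,
    metadata: pd.DataFrame,
    top_variant: tuple[str, int],
    resistant_allele: int | None = None,
    model: Literal["survival", "binomial"] = "survival",
    mode: Literal["allele", "full_survival"] = "allele",
    **scan_kwargs: Any,
) -> AssociationResult:
    """Re-run the scan on lines lacking the top resistance allele.

    The default subset drops every line carrying ``resistant_allele`` at
    ``top_variant`` (inferred from the fitted effect sign when not given);
    lines with a missing genotype there are dropped too, with a log note.
    ``mode="full_survival"`` instead drops lines at 100% survival at 48 h,
    the alternative subset phrasing for this procedure.
    """
    if mode == "full_survival":
        from .panel_io import survival_proportion_48h

        props = survival_proportion_48h(phenotypes)
        drop = set(props.loc[props["mean"] >= 1.0, "line_id"])
        keep_lines = [l for l in panel.lines if l not in drop]
    else:
        if resistant_allele is None:
            resistant_allele = infer_resistant_allele(
                panel, phenotypes, metadata, top_variant, model
            )
        j = panel.site_index(*top_variant)
        g = panel.calls[:, j].astype(int)
        n_missing = int(np.sum(g == MISSING))
        if n_missing:
            logger.info(
                "nested_scan: dropping %d lines with missing genotype at %s:%d",
                n_missing, *top_variant,
            )
        keep = (g != MISSING) & (g != resistant_allele)
        keep_lines = [l for l, k in zip(panel.lines, keep) if k]

    if not keep_lines:
        return _empty_result(model, "empty_subset")

    sub_panel = panel.take_lines(keep_lines)
    keep_set = set(keep_lines)
    if isinstance(phenotypes, SurvivalTable):
        sub_pheno: SurvivalTable | BinomialTable = SurvivalTable(
            phenotypes.data[phenotypes.data["line_id"].isin(keep_set)]
        )
    else:
        sub_pheno = BinomialTable(
            phenotypes.data[phenotypes.data["line_id"].isin(keep_set)]
        )
    sub_meta = metadata[metadata["line_id"].isin(keep_set)]
    result = gwas_scan(sub_panel, sub_pheno, sub_meta, model=model, **scan_kwargs)
    if result.n_sites_tested == 0 and result.status == "ok":
        result.status = "no_sites_pass_filter"
    return result


def candidate_table(
    result: AssociationResult, threshold_p: float = 1e-4
) -> pd.DataFrame:
    """Candidate rows with p below threshold, ranked by p.

    The returned frame carries the -log10 p threshold bookkeeping counts in
    ``DataFrame.attrs["threshold_counts"]``.
    """
    t = result.table.dropna(subset=["p_snp"])
    cand = t[t["p_snp"] < threshold_p].sort_values("p_snp", kind="mergesort")
    cand = cand.reset_index(drop=True)
    mlp = t["minus_log10_p"].to_numpy(dtype=float)
    cand.attrs["threshold_counts"] = {
        thr: int(np.nansum(mlp > thr)) for thr in THRESHOLD_MARKS
    }
    return cand
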