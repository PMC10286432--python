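"""Exact Gaussian inference for the area-level smoothing models.

The observation model is Gaussian with *known* variance (the empirical-logit
summary ``y_L_j ~ N(eta_j, var_logit_j)``), so the latent field
``x = (fixed effects, v, u)`` is a Gaussian Markov random field conditional
on the precision hyperparameters ``theta`` and the Laplace step of INLA is
exact here.  Inference therefore reduces to:

1. for each ``theta``: a sparse constrained Gaussian solve giving the
   conditional posterior of ``x`` and a closed-form (constraint-corrected)
   log marginal likelihood;
2. numerical integration of ``theta`` over an adaptive grid on the
   log-precision scale, centred at the posterior mode;
3. grid-weighted Gaussian-mixture marginals for every latent component and
   every linear predictor ``eta_j``, including unsampled areas.

Sum-to-zero constraints ``A u = 0`` are imposed by conditioning by kriging.
Because the ICAR prior precision is singular exactly along the constrained
directions, the factored matrix is augmented with ``c A~' A~`` — this leaves
the constrained distribution (and the corrected marginal likelihood)
mathematically unchanged while making the factorization well posed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln

from .graph import AdjacencyGraph, IcarStructure, scale_icar
from .models import ModelSpec, design_matrix, fixed_effect_prior_precisions
from .survey import STATUS_UNSAMPLED

__all__ = [
    "GaussianSystem",
    "FitResult",
    "assemble_system",
    "constrain",
    "sample_constrained",
    "hyper_grid",
    "fit_model",
    "mixture_quantile",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class UBlock:
    """One structured (ICAR) block: scaled structure matrix in global coords."""

    name: str
    idx: np.ndarray            # area indices covered by the block
    R: sp.csr_matrix           # n_areas x n_areas, zero outside the block
    rank: int                  # n_block_areas - n_components_in_block
    log_gdet: float            # sum log positive eigenvalues of the block


@dataclass
class GaussianSystem:
    """Joint Gaussian model for one ModelSpec on one dataset.

    Latent layout: ``[fixed (p) | v (n) | u (n)]``; the v / u sections are
    absent when the corresponding block list is empty (used by toy systems
    in tests).  Observation precisions are fixed at ``1 / var_logit``.
    """

    area_ids: tuple
    X: np.ndarray
    fixed_names: list
    fixed_prec: np.ndarray
    v_blocks: list              # (name, idx array)
    u_blocks: list              # UBlock
    A_u: np.ndarray             # (k, n) constraint on u; k may be 0
    y: np.ndarray               # (n,) NaN where unobserved
    obs_var: np.ndarray         # (n,) NaN where unobserved
    priors: object              # Priors (gamma hyperprior parameters)
    spec: ModelSpec | None = None

    # derived quantities, built once in __post_init__
    def __post_init__(self):
        n = len(self.area_ids)
        p = self.X.shape[1]
        self.n_areas, self.p = n, p
        self.has_v = bool(self.v_blocks)
        self.has_u = bool(self.u_blocks)
        self.dim = p + n * (self.has_v + self.has_u)
        self.v_off = p
        self.u_off = p + (n if self.has_v else 0)
        self.theta_names = [f"log_tau_u:{b.name}" for b in self.u_blocks] + [
            f"log_tau_v:{name}" for name, _ in self.v_blocks
        ]
        self.n_theta = len(self.theta_names)

        obs = np.isfinite(self.y) & np.isfinite(self.obs_var)
        if np.any(obs & ~(self.obs_var > 0)):
            raise ValueError("non-positive observation variance")
        self.obs_mask = obs
        self.obs_idx = np.flatnonzero(obs)

        # incidence of eta_j = X_j beta + v_j + u_j for every area
        blocks = [sp.csr_matrix(self.X)]
        eye = sp.eye(n, format="csr")
        if self.has_v:
            blocks.append(eye)
        if self.has_u:
            blocks.append(eye)
        self.Z = sp.hstack(blocks, format="csr")
        self._Z_dense = self.Z.toarray()
        M = self.Z[self.obs_idx]
        d = 1.0 / self.obs_var[self.obs_idx]
        self._MtDM = (M.T @ sp.diags(d) @ M).tocsr()
        self._b = M.T @ (d * self.y[self.obs_idx])
        self._M = M
        self._d = d

        k = self.A_u.shape[0] if self.A_u is not None and self.has_u else 0
        self.n_constraints = k
        if k:
            At = np.zeros((self.dim, k))
            At[self.u_off : self.u_off + n, :] = self.A_u.T
            self._At = At
            if np.linalg.matrix_rank(self.A_u) < k:
                raise ValueError("constraint matrix is rank deficient")
        else:
            self._At = np.zeros((self.dim, 0))
        self._build_assembly_template()

    def _build_assembly_template(self):
        """Precompute an aligned sparsity pattern so Q(theta) assembly and the
        constraint augmentation are pure array arithmetic in the hot loop."""
        dim, n, p = self.dim, self.n_areas, self.p

        def embed(mat, off):
            m = sp.coo_matrix(mat)
            return sp.coo_matrix(
                (m.data, (m.row + off, m.col + off)), shape=(dim, dim)
            ).tocsr()

        const = [self._MtDM.tocsr()]
        if p:
            # fixed-effect prior precisions live on the leading diagonal
            const.append(embed(sp.diags(self.fixed_prec), 0))
        self._aug_scale = max(1.0, float(np.mean(np.abs(self._MtDM.diagonal())) or 1.0))
        if self.n_constraints:
            const.append(self._aug_scale * sp.csr_matrix(self._At @ self._At.T))
        variable = []
        for b in self.u_blocks:
            variable.append(embed(b.R, self.u_off))
        for name, idx in self.v_blocks:
            d = np.zeros(n)
            d[idx] = 1.0
            variable.append(embed(sp.diags(d), self.v_off))
        union = sum(abs(c) for c in const + variable).tocsc()
        union.sort_indices()
        self._pat_indices, self._pat_indptr = union.indices, union.indptr
        cols = np.repeat(np.arange(dim), np.diff(union.indptr))
        union_lin = cols.astype(np.int64) * dim + union.indices
        aligned = []
        for m in const + variable:
            mc = m.tocoo()
            mc.sum_duplicates()
            lin = mc.col.astype(np.int64) * dim + mc.row
            pos = np.searchsorted(union_lin, lin)
            if pos.size and (pos.max() >= union_lin.size or not np.array_equal(union_lin[pos], lin)):
                raise AssertionError("sparsity alignment failed")
            data = np.zeros(union_lin.size)
            data[pos] = mc.data
            aligned.append(data)
        n_const = len(const)
        self._const_data = np.sum(aligned[:n_const], axis=0)
        self._var_data = np.array(aligned[n_const:])
        self._marg_rhs = np.concatenate(
            [self._Z_dense.T, np.eye(dim)[:, :p]], axis=1
        )

    def _augmented_precision_csc(self, theta) -> sp.csc_matrix:
        """Q(theta) + c A'A on the precomputed pattern (fast path)."""
        taus = np.exp(np.clip(np.asarray(theta, dtype=float), -40.0, 40.0))
        data = self._const_data + taus @ self._var_data
        return sp.csc_matrix(
            (data, self._pat_indices, self._pat_indptr), shape=(self.dim, self.dim)
        )

    # -- precision assembly ------------------------------------------------
    def prior_precision(self, theta: np.ndarray) -> sp.csr_matrix:
        taus = np.exp(np.asarray(theta, dtype=float))
        tau_u = taus[: len(self.u_blocks)]
        tau_v = taus[len(self.u_blocks) :]
        n = self.n_areas
        diag = np.zeros(self.dim)
        diag[: self.p] = self.fixed_prec
        if self.has_v:
            for (name, idx), tv in zip(self.v_blocks, tau_v):
                diag[self.v_off + idx] = tv
        parts = []
        head = diag[: self.u_off]
        if head.size:
            parts.append(sp.diags(head))
        if self.has_u:
            parts.append(sum(tu * b.R for b, tu in zip(self.u_blocks, tau_u)))
        if len(parts) == 1:
            return sp.csr_matrix(parts[0])
        return sp.block_diag(parts, format="csr")

    def posterior_precision(self, theta: np.ndarray) -> sp.csr_matrix:
        return (self.prior_precision(theta) + self._MtDM).tocsr()

    # -- log densities -----------------------------------------------------
    def log_prior_field(self, theta: np.ndarray, x: np.ndarray) -> float:
        """Generalized log prior density of the latent field at x.

        Uses the rank / generalized-determinant convention for the singular
        ICAR blocks; constant (theta-independent) measure factors from the
        constraint geometry are irrelevant for grid weights and dropped.
        """
        taus = np.exp(np.asarray(theta, dtype=float))
        tau_u = taus[: len(self.u_blocks)]
        tau_v = taus[len(self.u_blocks) :]
        p = self.p
        out = 0.0
        gamma = x[:p]
        out += 0.5 * np.sum(np.log(self.fixed_prec) - _LOG2PI) - 0.5 * np.sum(
            self.fixed_prec * gamma**2
        )
        if self.has_v:
            v = x[self.v_off : self.v_off + self.n_areas]
            for (name, idx), tv in zip(self.v_blocks, tau_v):
                nb = len(idx)
                out += 0.5 * nb * (math.log(tv) - _LOG2PI) - 0.5 * tv * np.sum(v[idx] ** 2)
        if self.has_u:
            u = x[self.u_off :]
            for b, tu in zip(self.u_blocks, tau_u):
                quad = float(u @ (b.R @ u))
                out += 0.5 * (b.rank * math.log(tu) + b.log_gdet - b.rank * _LOG2PI)
                out -= 0.5 * tu * quad
        return float(out)

    def log_likelihood(self, x: np.ndarray) -> float:
        eta = self._M @ x
        r = self.y[self.obs_idx] - eta
        return float(-0.5 * np.sum(np.log(2.0 * np.pi / self._d) + self._d * r**2))

    def log_hyperprior(self, theta: np.ndarray) -> float:
        """Gamma(shape, rate) prior on each precision, on the log scale."""
        a = self.priors.precision_shape
        b = self.priors.precision_rate
        th = np.asarray(theta, dtype=float)
        return float(
            np.sum(a * th - b * np.exp(th)) + self.n_theta * (a * math.log(b) - gammaln(a))
        )


# ---------------------------------------------------------------------------
# constrained Gaussian algebra
# ---------------------------------------------------------------------------

def constrain(Q, b, A):
    """Constrained Gaussian ``x | Ax = 0`` for canonical ``N(Q^-1 b, Q^-1)``.

    Conditioning by kriging with sparse solves.  Because adding ``c A'A``
    to ``Q`` changes nothing on the constraint subspace, the factorization
    is performed on the augmented matrix, which also covers intrinsic priors
    whose null space is spanned by the constraint rows.

    Returns ``(mean_c, handle)`` where the handle carries the factorization
    and kriging pieces for variance deflation and log determinants.
    """
    Q = sp.csr_matrix(Q)
    dim = Q.shape[0]
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.size == 0:
        A = np.zeros((0, dim))
    k = A.shape[0]
    if k and np.linalg.matrix_rank(A) < k:
        raise ValueError("constraint matrix is rank deficient")
    if k:
        c = max(1.0, float(np.mean(np.abs(Q.diagonal()))))
        Qf = (Q + c * sp.csr_matrix(A.T @ A)).tocsc()
    else:
        Qf = Q.tocsc()
    lu = splu(Qf)
    logdet_Q = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    mu = lu.solve(np.asarray(b, dtype=float))
    if k:
        W = lu.solve(A.T)                    # Q^-1 A'
        S = A @ W                            # A Q^-1 A'
        S_chol = sla.cho_factor(S)
        mean_c = mu - W @ sla.cho_solve(S_chol, A @ mu)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(S_chol[0]))))
    else:
        W, S_chol, logdet_S = np.zeros((dim, 0)), None, 0.0
        mean_c = mu
    handle = _KrigingHandle(lu, A, W, S_chol, logdet_Q, logdet_S, dim)
    return mean_c, handle


@dataclass
class _KrigingHandle:
    lu: object
    A: np.ndarray
    W: np.ndarray
    S_chol: object
    logdet_Q: float
    logdet_S: float
    dim: int

    @property
    def k(self):
        return self.A.shape[0]

    def covariance(self) -> np.ndarray:
        """Dense constrained covariance (columns via sparse solves)."""
        Sigma = self.lu.solve(np.eye(self.dim))
        if self.k:
            Sigma = Sigma - self.W @ sla.cho_solve(self.S_chol, self.W.T)
        return Sigma

    def log_normalizer(self) -> float:
        """log density of the constrained Gaussian at its own mean.

        Equals ``-((dim-k)/2) log 2pi + (logdet Q + logdet S)/2`` and is
        invariant to the ``c A'A`` augmentation.
        """
        return -0.5 * (self.dim - self.k) * _LOG2PI + 0.5 * (self.logdet_Q + self.logdet_S)


def sample_constrained(Q, b, A, rng, n_draws: int) -> np.ndarray:
    """Draws from the constrained Gaussian (dense path, small systems).

    Unconstrained draws are corrected by kriging, so every draw satisfies
    ``A x = 0`` to solver precision.
    """
    mean_c, h = constrain(Q, b, A)
    Sigma = h.lu.solve(np.eye(h.dim))
    L = np.linalg.cholesky(0.5 * (Sigma + Sigma.T) + 1e-12 * np.eye(h.dim))
    x = mean_c[None, :] + (rng.standard_normal((n_draws, h.dim)) @ L.T)
    if h.k:
        resid = x @ h.A.T
        x = x - resid @ sla.cho_solve(h.S_chol, h.W.T)
    return x


# ---------------------------------------------------------------------------
# per-theta solve
# ---------------------------------------------------------------------------

@dataclass
class GridPoint:
    theta: np.ndarray
    log_marginal: float
    log_post: float
    mean: np.ndarray | None = None
    latent_sd: np.ndarray | None = None
    fixed_sd: np.ndarray | None = None
    eta_mean: np.ndarray | None = None
    eta_sd: np.ndarray | None = None


def _fast_constrain(system: GaussianSystem, theta) -> tuple[np.ndarray, _KrigingHandle]:
    """Constrained posterior solve on the precomputed sparsity template."""
    Qf = system._augmented_precision_csc(theta)
    lu = splu(Qf, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
    logdet_Q = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    mu = lu.solve(system._b)
    k = system.n_constraints
    A = system._At.T
    if k:
        W = lu.solve(system._At)
        S = A @ W
        S_chol = sla.cho_factor(S)
        mean_c = mu - W @ sla.cho_solve(S_chol, A @ mu)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(S_chol[0]))))
    else:
        W, S_chol, logdet_S, mean_c = np.zeros((system.dim, 0)), None, 0.0, mu
    return mean_c, _KrigingHandle(lu, A, W, S_chol, logdet_Q, logdet_S, system.dim)


def _solve_point(
    system: GaussianSystem, theta, marginals: bool = False, latent_sd: bool = False
) -> GridPoint:
    mean_c, h = _fast_constrain(system, theta)
    lml = (
        system.log_prior_field(theta, mean_c)
        + system.log_likelihood(mean_c)
        - h.log_normalizer()
    )
    gp = GridPoint(
        theta=np.asarray(theta, dtype=float),
        log_marginal=float(lml),
        log_post=float(lml + system.log_hyperprior(theta)),
    )
    if marginals:
        gp.mean = mean_c
        Zd = system._Z_dense
        n, p = Zd.shape[0], system.p
        T = h.lu.solve(system._marg_rhs)           # [Q^-1 Z' | Q^-1 e_1..e_p]
        var_eta = np.einsum("ij,ji->i", Zd, T[:, :n])
        var_fix = np.array([T[j, n + j] for j in range(p)])
        if h.k:
            Sinv = sla.cho_solve(h.S_chol, np.eye(h.k))
            ZW = Zd @ h.W
            var_eta = var_eta - np.einsum("ij,ij->i", ZW @ Sinv, ZW)
            Wf = h.W[:p]
            var_fix = var_fix - np.einsum("ij,ij->i", Wf @ Sinv, Wf)
        gp.eta_mean = system.Z @ mean_c
        gp.eta_sd = np.sqrt(np.maximum(var_eta, 0.0))
        gp.fixed_sd = np.sqrt(np.maximum(var_fix, 0.0))
        if latent_sd:
            Sigma = h.covariance()
            gp.latent_sd = np.sqrt(np.maximum(Sigma.diagonal(), 0.0))
    return gp


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

def _mode_search(system: GaussianSystem, theta0=None, gtol: float = 1e-8):
    d = system.n_theta
    x0 = np.full(d, 3.0) if theta0 is None else np.asarray(theta0, dtype=float)

    def neg(th):
        # keep log-precisions in a numerically safe box; quadratic pull-back
        thc = np.clip(th, -20.0, 20.0)
        penalty = 1e3 * float(np.sum((th - thc) ** 2))
        return -_solve_point(system, thc).log_post + penalty

    res = minimize(neg, x0, method="BFGS", options={"gtol": gtol, "maxiter": 200})
    res.x = np.clip(res.x, -20.0, 20.0)
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"hyperparameter mode search failed at {res.x!r}")
    return res.x, -res.fun


def _hessian(fun, x0, h: float = 0.05) -> np.ndarray:
    d = len(x0)
    H = np.zeros((d, d))
    f0 = fun(x0)
    for i in range(d):
        for j in range(i, d):
            ei, ej = np.zeros(d), np.zeros(d)
            ei[i], ej[j] = h, h
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej) - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * h**2)
    return H


def hyper_grid(
    system: GaussianSystem,
    theta0=None,
    step: float | None = None,
    cutoff: float = 5.0,
    max_points: int = 4000,
) -> list[GridPoint]:
    """Adaptive grid of hyperparameter points around the posterior mode.

    The grid lives on the log-precision scale, in standardized coordinates
    from the eigendecomposition of the negative Hessian at the mode; points
    are explored best-first and kept while their log posterior density is
    within ``cutoff`` of the mode.
    """
    d = system.n_theta
    if d == 0:
        return [_solve_point(system, np.zeros(0))]
    mode, lp_mode = _mode_search(system, theta0)
    if step is None:
        step = 0.5 if d <= 2 else 1.0
    H = -_hessian(lambda th: _solve_point(system, th).log_post, mode)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    # floor curvature: flat directions get a capped exploration scale
    sd = 1.0 / np.sqrt(np.maximum(w, 1.0 / 25.0))

    def theta_of(z):
        return mode + V @ (sd * step * np.asarray(z, dtype=float))

    max_steps = int(np.ceil(6.0 / step))  # never explore past ~6 posterior sds
    origin = tuple([0] * d)
    cache = {origin: _solve_point(system, theta_of(origin))}
    best = cache[origin].log_post
    heap = [(-cache[origin].log_post, origin)]
    accepted = []
    seen = {origin}
    while heap and len(accepted) < max_points:
        _, z = heapq.heappop(heap)
        gp = cache[z]
        best = max(best, gp.log_post)
        if gp.log_post < best - cutoff:
            continue
        accepted.append((z, gp))
        for i in range(d):
            for delta in (-1, 1):
                nz = tuple(z[j] + (delta if j == i else 0) for j in range(d))
                if nz in seen or abs(nz[i]) > max_steps:
                    continue
                seen.add(nz)
                ngp = _solve_point(system, theta_of(nz))
                cache[nz] = ngp
                if ngp.log_post >= best - cutoff:
                    heapq.heappush(heap, (-ngp.log_post, nz))
    return [gp for _, gp in accepted]


# ---------------------------------------------------------------------------
# posterior mixture
# ---------------------------------------------------------------------------

def mixture_quantile(means, sds, weights, q: float) -> float:
    """Quantile of a scalar Gaussian mixture by bisection on its CDF."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    means = np.asarray(means, dtype=float)
    sds = np.maximum(np.asarray(sds, dtype=float), 1e-300)
    w = np.asarray(weights, dtype=float)

    def cdf(x):
        return float(np.sum(w * norm.cdf((x - means) / sds))) - q

    lo = float(np.min(means - 10 * sds))
    hi = float(np.max(means + 10 * sds))
    return float(brentq(cdf, lo, hi, xtol=1e-10))


@dataclass
class FitResult:
    """Posterior summaries of one model fit.

    Latent marginals and linear predictors are grid-weighted Gaussian
    mixtures; fitted prevalences are transformations of the ``eta``
    mixtures through the inverse logit.
    """

    spec: ModelSpec
    area_ids: tuple
    statuses: np.ndarray
    summaries: pd.DataFrame
    latent_names: list
    theta_names: list
    grid_theta: np.ndarray      # (G, d)
    grid_log_post: np.ndarray   # (G,)
    weights: np.ndarray         # (G,) normalized
    point_latent_mean: np.ndarray   # (G, dim)
    point_fixed_sd: np.ndarray      # (G, p)
    point_eta_mean: np.ndarray      # (G, n)
    point_eta_sd: np.ndarray
    point_latent_sd: np.ndarray | None = None   # (G, dim), on request
    system: GaussianSystem = field(repr=False, default=None)

    # -- mixture moments ---------------------------------------------------
    @staticmethod
    def _mix(w, m, s):
        mean = w @ m
        var = w @ (s**2 + m**2) - mean**2
        return mean, np.sqrt(np.maximum(var, 0.0))

    @property
    def latent_mean(self):
        return self.weights @ self.point_latent_mean

    @property
    def latent_sd(self):
        if self.point_latent_sd is None:
            raise ValueError("fit was run without latent_sd=True")
        return self._mix(self.weights, self.point_latent_mean, self.point_latent_sd)[1]

    def fixed_effects(self) -> pd.DataFrame:
        """Posterior mean, sd and 95% interval of intercepts and slopes."""
        p = self.system.p
        m = self.point_latent_mean[:, :p]
        s = self.point_fixed_sd
        mean, sd = self._mix(self.weights, m, s)
        lo = [mixture_quantile(m[:, j], s[:, j], self.weights, 0.025) for j in range(p)]
        hi = [mixture_quantile(m[:, j], s[:, j], self.weights, 0.975) for j in range(p)]
        return pd.DataFrame(
            {"mean": mean, "sd": sd, "lower95": lo, "upper95": hi},
            index=self.system.fixed_names,
        )

    @property
    def eta_mean(self):
        return self._mix(self.weights, self.point_eta_mean, self.point_eta_sd)[0]

    @property
    def eta_sd(self):
        return self._mix(self.weights, self.point_eta_mean, self.point_eta_sd)[1]

    def eta_quantile(self, q: float) -> np.ndarray:
        return np.array(
            [
                mixture_quantile(self.point_eta_mean[:, j], self.point_eta_sd[:, j], self.weights, q)
                for j in range(self.point_eta_mean.shape[1])
            ]
        )

    # -- fitted prevalence -------------------------------------------------
    def sample_eta(self, n_draws: int = 5000, seed: int = 20150101) -> np.ndarray:
        """Draws (n_draws, n_areas) from the per-area eta mixtures."""
        rng = np.random.default_rng(seed)
        g = rng.choice(len(self.weights), size=n_draws, p=self.weights)
        z = rng.standard_normal((n_draws, self.point_eta_mean.shape[1]))
        return self.point_eta_mean[g] + self.point_eta_sd[g] * z

    def fitted_prevalence(self, method: str = "mc", n_draws: int = 5000, seed: int = 20150101):
        """Posterior mean of expit(eta) per area.

        ``mc`` (default): seeded Monte Carlo through expit.  ``ghq``:
        deterministic Gauss-Hermite quadrature over each mixture component.
        """
        if method == "mc":
            return expit(self.sample_eta(n_draws, seed)).mean(axis=0)
        if method == "ghq":
            t, om = np.polynomial.hermite_e.hermegauss(41)
            om = om / om.sum()
            vals = expit(
                self.point_eta_mean[:, :, None] + self.point_eta_sd[:, :, None] * t[None, None, :]
            )
            return np.einsum("g,gjq,q->j", self.weights, vals, om)
        raise ValueError(f"unknown method {method!r}")

    def prevalence_summary(
        self, n_draws: int = 5000, seed: int = 20150101, method: str = "mc"
    ) -> pd.DataFrame:
        """Per-area table: direct estimate, fitted mean, 95% interval, sd, status."""
        mean = self.fitted_prevalence(method=method, n_draws=n_draws, seed=seed)
        lo = expit(self.eta_quantile(0.025))
        hi = expit(self.eta_quantile(0.975))
        if method == "mc":
            sd = expit(self.sample_eta(n_draws, seed)).std(axis=0, ddof=1)
        else:
            t, om = np.polynomial.hermite_e.hermegauss(41)
            om = om / om.sum()
            vals = expit(
                self.point_eta_mean[:, :, None] + self.point_eta_sd[:, :, None] * t[None, None, :]
            )
            second = np.einsum("g,gjq,q->j", self.weights, vals**2, om)
            sd = np.sqrt(np.maximum(second - mean**2, 0.0))
        direct = self.summaries["p_hat"].reindex(list(self.area_ids)).to_numpy()
        return pd.DataFrame(
            {
                "area_id": list(self.area_ids),
                "direct": direct,
                "fitted_mean": mean,
                "lower95": lo,
                "upper95": hi,
                "sd": sd,
                "status": self.statuses,
            }
        ).set_index("area_id")

    def predict_unsampled(self, **kwargs) -> pd.DataFrame:
        """Fitted prevalences for areas carrying no likelihood contribution."""
        tab = self.prevalence_summary(**kwargs)
        return tab[tab["status"] == STATUS_UNSAMPLED]

    # -- hyperparameters ---------------------------------------------------
    def hyperparameter_summary(self) -> pd.DataFrame:
        taus = np.exp(self.grid_theta)
        rows = []
        for i, name in enumerate(self.theta_names):
            rows.append(
                {
                    "hyperparameter": name,
                    "mean_precision": float(self.weights @ taus[:, i]),
                    "mean_variance": float(self.weights @ (1.0 / taus[:, i])),
                }
            )
        return pd.DataFrame(rows).set_index("hyperparameter")

    # -- information criteria (delegated) ----------------------------------
    def dic(self, **kwargs):
        from .criteria import dic

        return dic(self, **kwargs)

    def waic(self, **kwargs):
        from .criteria import waic

        return waic(self, **kwargs)

    # -- export -------------------------------------------------------------
    def export_csv(self, path, **kwargs) -> None:
        self.prevalence_summary(**kwargs).to_csv(path)

    def export_geojson(self, path, geometries, **kwargs) -> None:
        """GeoJSON FeatureCollection with fitted summaries joined as properties."""
        import json

        from shapely.geometry import mapping

        tab = self.prevalence_summary(**kwargs)
        geoms = dict(geometries.items() if hasattr(geometries, "items") else geometries)
        feats = []
        for area, row in tab.iterrows():
            if area not in geoms:
                raise ValueError(f"no geometry for area {area!r}")
            props = {"area_id": area, **{k: (None if pd.isna(v) else v) for k, v in row.items()}}
            feats.append(
                {"type": "Feature", "properties": props, "geometry": mapping(geoms[area])}
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    # convenience: observed-area pieces used by the information criteria
    def observed_eta_moments(self):
        idx = self.system.obs_idx
        return (
            self.system.y[idx],
            self.system.obs_var[idx],
            self.point_eta_mean[:, idx],
            self.point_eta_sd[:, idx],
            self.weights,
        )


# ---------------------------------------------------------------------------
# assembly and top-level fit
# ---------------------------------------------------------------------------

def assemble_system(
    spec: ModelSpec,
    graph: AdjacencyGraph,
    summaries: pd.DataFrame,
    covariate_table: pd.DataFrame | None = None,
    icar: IcarStructure | None = None,
) -> GaussianSystem:
    """Build the joint Gaussian model for a spec on a dataset.

    For a single-region (variant V) spec, the graph and summaries are
    restricted to the requested component first.
    """
    if spec.variant == "V":
        graph, _ = graph.subgraph(spec.region)
        icar = None  # must be rebuilt on the subgraph
    if icar is None:
        icar = scale_icar(graph, mode=spec.scaling_mode, constraint_mode=spec.constraint_mode)
    if (icar.scaling_mode, icar.constraint_mode) != (spec.scaling_mode, spec.constraint_mode):
        raise ValueError("icar structure modes do not match the model spec")

    X, names = design_matrix(spec, graph, covariate_table)
    fixed_prec = fixed_effect_prior_precisions(spec, names)

    summaries = summaries.reindex(list(graph.area_ids))
    y = summaries["y_logit"].to_numpy(dtype=float)
    var = summaries["var_logit"].to_numpy(dtype=float)
    status = summaries["status"].fillna(STATUS_UNSAMPLED).to_numpy()
    unobs = status == STATUS_UNSAMPLED
    y = np.where(unobs, np.nan, y)
    var = np.where(unobs, np.nan, var)

    n = graph.n_areas
    all_idx = np.arange(n)
    comps = graph.components()
    ranks = icar.ranks()
    gdets = icar.log_generalized_determinants()
    R = icar.structure_matrix

    if spec.split_random_effects:
        u_blocks, v_blocks = [], []
        for c, idx in enumerate(comps):
            mask = np.zeros(n)
            mask[idx] = 1.0
            D = sp.diags(mask)
            # components are disconnected, so D R D is exactly R's block c
            u_blocks.append(
                UBlock(f"region{c}", idx, (D @ R @ D).tocsr(), int(ranks[c]), float(gdets[c]))
            )
            v_blocks.append((f"region{c}", idx))
    else:
        rank = int(ranks.sum())
        u_blocks = [UBlock("all", all_idx, R, rank, float(gdets.sum()))]
        v_blocks = [("all", all_idx)]

    return GaussianSystem(
        area_ids=graph.area_ids,
        X=X,
        fixed_names=names,
        fixed_prec=fixed_prec,
        v_blocks=v_blocks,
        u_blocks=u_blocks,
        A_u=icar.constraint_matrix,
        y=y,
        obs_var=var,
        priors=spec.priors,
        spec=spec,
    )


def fit_system(
    system: GaussianSystem,
    summaries: pd.DataFrame,
    grid: np.ndarray | None = None,
    latent_sd: bool = False,
    prune: float = 1e-10,
    **grid_kwargs,
) -> FitResult:
    """Run grid integration and mixture marginals on an assembled system.

    Grid points whose normalized weight falls below ``prune`` are dropped
    (and the weights renormalized) before the marginal solves.
    """
    if grid is not None:
        pts = [_solve_point(system, th) for th in np.atleast_2d(np.asarray(grid, dtype=float))]
    else:
        pts = hyper_grid(system, **grid_kwargs)
    lps = np.array([g.log_post for g in pts])
    w = np.exp(lps - lps.max())
    w /= w.sum()
    keep = w >= prune
    pts = [g for g, k in zip(pts, keep) if k]
    lps, w = lps[keep], w[keep]
    w = w / w.sum()
    full = [_solve_point(system, g.theta, marginals=True, latent_sd=latent_sd) for g in pts]
    statuses = summaries.reindex(list(system.area_ids))["status"].fillna(STATUS_UNSAMPLED).to_numpy()
    latent_names = (
        list(system.fixed_names)
        + ([f"v:{a}" for a in system.area_ids] if system.has_v else [])
        + ([f"u:{a}" for a in system.area_ids] if system.has_u else [])
    )
    return FitResult(
        spec=system.spec,
        area_ids=system.area_ids,
        statuses=statuses,
        summaries=summaries.reindex(list(system.area_ids)),
        latent_names=latent_names,
        theta_names=system.theta_names,
        grid_theta=np.array([g.theta for g in full]),
        grid_log_post=lps,
        weights=w,
        point_latent_mean=np.array([g.mean for g in full]),
        point_fixed_sd=np.array([g.fixed_sd for g in full]),
        point_eta_mean=np.array([g.eta_mean for g in full]),
        point_eta_sd=np.array([g.eta_sd for g in full]),
        point_latent_sd=np.array([g.latent_sd for g in full]) if latent_sd else None,
        system=system,
    )


def fit_model(
    spec: ModelSpec,
    graph: AdjacencyGraph,
    summaries: pd.DataFrame,
    covariate_table: pd.DataFrame | None = None,
    icar: IcarStructure | None = None,
    grid: np.ndarray | None = None,
    **grid_kwargs,
) -> FitResult:
    """Assemble and fit one model variant; the main entry point."""
    system = assemble_system(spec, graph, summaries, covariate_table, icar)
    if spec.variant == "V":
        summaries = summaries.reindex(list(system.area_ids))
    return fit_system(system, summaries, grid=grid, **grid_kwargs)
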