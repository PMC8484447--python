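"""Expression Variance and Evolution (EVE) phylogenetic ANOVA.

Gene expression is treated as a quantitative trait evolving along a species
tree under a stationary Ornstein-Uhlenbeck (OU) process with optimum
``theta``, drift variance ``sigma2`` and selection strength ``alpha``.
Individual-level measurements add independent within-species variance
expressed as a fraction ``beta`` of the evolutionary (stationary) variance
``v_evo = sigma2 / (2 * alpha)``.

Under these assumptions the vector of expression values across all
individuals is multivariate normal with mean ``theta`` and covariance

* ``v_evo * (1 + beta)`` on the diagonal,
* ``v_evo`` between two individuals of the same species,
* ``v_evo * exp(-alpha * d(s, s'))`` between individuals of species ``s``
  and ``s'`` at patristic distance ``d``.

``beta`` is the ratio of within-species expression variance to evolutionary
variance.  Genes whose gene-specific ``beta`` is *lower* than the shared
estimate (between-lineage variance dominates) are candidates for
lineage-specific expression shifts ("divergence"); genes with a *higher*
``beta`` show elevated within-species variability ("diversity").  The test
is a likelihood ratio of the gene-specific-``beta`` fit against the
shared-``beta`` fit, referred to a chi-square distribution with one degree
of freedom.

Likelihoods are profiled analytically over ``theta`` (GLS mean) and
``v_evo`` (scaled residual quadratic form), so numerical optimisation only
runs over ``log alpha`` and, in the free arm, ``log beta``.  This keeps the
maximisation two-dimensional, exactly scale-equivariant in ``theta``, and
fast enough to fit thousands of genes jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, eigh
from statsmodels.stats.multitest import multipletests

from .phylogeny import Phylogeny

__all__ = [
    "OUGeneParams",
    "SampleLayout",
    "GeneFit",
    "build_covariance",
    "loglik_gene",
    "fit_gene",
    "fit_shared_beta",
    "divergence_test",
]

# Box constraints for the optimiser, on the natural-log scale.
LOG_ALPHA_BOUNDS = (-8.0, 8.0)
LOG_BETA_BOUNDS = (-8.0, 8.0)
_DEGENERATE_VAR = 1e-10


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class OUGeneParams:
    """Per-gene OU parameters.

    theta
        Trait optimum (expression units).
    sigma2
        OU drift variance per unit branch length (> 0).
    alpha
        Selection strength per unit branch length (> 0).
    beta
        Ratio of within-species to evolutionary variance (>= 0).
    """

    theta: float
    sigma2: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @property
    def v_evo(self) -> float:
        """Stationary (evolutionary) variance sigma2 / (2 alpha)."""
        return self.sigma2 / (2.0 * self.alpha)

    @property
    def stationary_sd(self) -> float:
        return float(np.sqrt(self.v_evo))


@dataclass(frozen=True)
class SampleLayout:
    """Species assignment of each individual (column) in an expression matrix."""

    species: tuple[str, ...]
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.species) < 1:
            raise ValueError("layout must contain at least one individual")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.species):
            raise ValueError("sample_ids and species must have equal length")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def species_set(self) -> set[str]:
        return set(self.species)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.species:
            out[s] = out.get(s, 0) + 1
        return out

    @classmethod
    def from_metadata(
        cls, meta: pd.DataFrame, condition: str | None = None
    ) -> "SampleLayout":
        """Build a layout from a metadata table (sample_id, species, condition)."""
        df = meta
        if condition is not None:
            df = df[df["condition"] == condition]
        return cls(
            species=tuple(df["species"].tolist()),
            sample_ids=tuple(df["sample_id"].tolist()),
        )


@dataclass
class GeneFit:
    """Result of a single-gene likelihood maximisation."""

    params: OUGeneParams
    loglik: float
    converged: bool


# ----------------------------------------------------------------------
# Covariance and likelihood
# ----------------------------------------------------------------------
def _individual_distances(tree: Phylogeny, layout: SampleLayout) -> np.ndarray:
    """Patristic distance between the species of every pair of individuals."""
    missing = sorted(layout.species_set - set(tree.tips))
    if missing:
        raise ValueError(
            f"species not on tree: {missing}; tips are {list(tree.tips)}"
        )
    sp = list(dict.fromkeys(layout.species))
    D_sp = tree.distance_matrix(order=sp)
    idx = np.array([sp.index(s) for s in layout.species])
    return D_sp[np.ix_(idx, idx)]


def build_covariance(
    tree: Phylogeny, params: OUGeneParams, layout: SampleLayout
) -> np.ndarray:
    """Assemble the individual-level OU covariance matrix.

    Diagonal entries are ``v_evo * (1 + beta)``, same-species off-diagonals
    ``v_evo`` and cross-species entries ``v_evo * exp(-alpha * d)``.
    """
    D = _individual_distances(tree, layout)
    v = params.v_evo
    cov = v * np.exp(-params.alpha * D)
    cov[np.diag_indices_from(cov)] += v * params.beta
    # PD check; a tiny jitter covers exact beta == 0 with replicates
    try:
        cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(cov) / cov.shape[0]
        cov_j = cov + jitter * np.eye(cov.shape[0])
        try:
            cho_factor(cov_j, lower=True)
            return cov_j
        except np.linalg.LinAlgError:
            smallest = float(np.linalg.eigvalsh(cov).min())
            raise np.linalg.LinAlgError(
                "covariance not positive definite after jitter "
                f"(smallest eigenvalue {smallest:.3e})"
            ) from None
    return cov


def loglik_gene(
    y: np.ndarray,
    params: OUGeneParams,
    tree: Phylogeny,
    layout: SampleLayout,
) -> float:
    """Multivariate-normal log-density of one gene's expression vector.

    Mean is ``theta`` at every individual (stationary OU rooted at the
    optimum); covariance comes from :func:`build_covariance`.  Uses a
    Cholesky factorisation for numerical stability.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != layout.n:
        raise ValueError(
            f"expression vector length {y.size} != layout size {layout.n}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("expression vector contains non-finite values")
    cov = build_covariance(tree, params, layout)
    try:
        cf = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular covariance: {exc}") from exc
    r = y - params.theta
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n = layout.n
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


# ----------------------------------------------------------------------
# Profiled likelihood machinery
# ----------------------------------------------------------------------
def _profile_ll_chol(
    y: np.ndarray, D: np.ndarray, log_alpha: float, log_beta: float
) -> tuple[float, float, float]:
    """Log-likelihood maximised analytically over theta and v_evo.

    Returns ``(loglik, theta_hat, v_hat)`` at the given (log alpha,
    log beta); ``-inf`` if the correlation matrix is numerically singular.
    """
    alpha = np.exp(log_alpha)
    beta = np.exp(log_beta)
    n = len(y)
    C = np.exp(-alpha * D)
    C[np.diag_indices_from(C)] += beta
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    ones = np.ones(n)
    s1 = cho_solve(cf, ones)
    sy = cho_solve(cf, y)
    a = float(ones @ s1)
    b = float(ones @ sy)
    theta = b / a
    q = float(y @ sy) - b * b / a
    if not np.isfinite(q) or q <= 0:
        return -np.inf, theta, np.nan
    v = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * n * (np.log(2.0 * np.pi * v) + 1.0) - 0.5 * logdet
    return ll, theta, v


class _ProfileGrid:
    """Vectorised profiled log-likelihoods on a fixed log-alpha grid.

    Pre-computes, per grid alpha, the eigendecomposition of the correlation
    matrix ``R(alpha) = exp(-alpha * D)`` and the projections of every gene,
    so that the likelihood at any ``beta`` is a cheap vector operation:
    ``C = R + beta * I`` shares eigenvectors with ``R``.
    """

    def __init__(self, Y: np.ndarray, D: np.ndarray, log_alphas: np.ndarray):
        self.Y = Y
        self.n = Y.shape[1]
        self.log_alphas = log_alphas
        ones = np.ones(self.n)
        self._w = []
        self._Z = []
        self._u1 = []
        for la in log_alphas:
            R = np.exp(-np.exp(la) * D)
            w, U = eigh(R)
            self._w.append(np.maximum(w, 0.0))
            self._Z.append(Y @ U)
            self._u1.append(U.T @ ones)

    def loglik(self, log_beta: float) -> np.ndarray:
        """Profiled log-likelihood per (gene, grid alpha) at one beta."""
        beta = np.exp(log_beta)
        n = self.n
        G = self.Y.shape[0]
        out = np.full((G, len(self.log_alphas)), -np.inf)
        for k in range(len(self.log_alphas)):
            lam = self._w[k] + beta
            if lam.min() <= 0:
                continue
            iw = 1.0 / lam
            u1 = self._u1[k]
            Z = self._Z[k]
            a = float((u1 * u1) @ iw)
            b = Z @ (u1 * iw)
            q = (Z * Z) @ iw - b * b / a
            q = np.maximum(q, 1e-300)
            out[:, k] = (
                -0.5 * n * (np.log(2.0 * np.pi * q / n) + 1.0)
                - 0.5 * float(np.sum(np.log(lam)))
            )
        return out

    def max_over_alpha(self, log_beta: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene maximum over the alpha grid with parabolic refinement."""
        ll = self.loglik(log_beta)
        k = np.argmax(ll, axis=1)
        best = ll[np.arange(len(k)), k]
        interior = (k > 0) & (k < ll.shape[1] - 1)
        if np.any(interior):
            ki = k[interior]
            rows = np.where(interior)[0]
            lm = ll[rows, ki - 1]
            l0 = ll[rows, ki]
            lp = ll[rows, ki + 1]
            denom = 2.0 * l0 - lm - lp
            ok = denom > 0
            corr = np.zeros_like(l0)
            corr[ok] = (lp[ok] - lm[ok]) ** 2 / (8.0 * denom[ok])
            best[rows] += corr
        la = self.log_alphas[k]
        return best, la


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------
def _check_identifiable(layout: SampleLayout) -> None:
    counts = layout.counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 species to fit the OU model")
    if max(counts.values()) < 2:
        raise ValueError(
            "beta is unidentifiable without replicates: need >= 2 "
            "individuals in at least one species"
        )


def _degenerate_mask(Y: np.ndarray, layout: SampleLayout) -> np.ndarray:
    """Genes with ~zero variance or any species lacking 2 finite values."""
    finite = np.isfinite(Y)
    mask = np.zeros(Y.shape[0], dtype=bool)
    with np.errstate(invalid="ignore"):
        var = np.nanvar(np.where(finite, Y, np.nan), axis=1)
    mask |= ~np.isfinite(var) | (var < _DEGENERATE_VAR)
    species = np.array(layout.species)
    for s in set(layout.species):
        cols = species == s
        mask |= finite[:, cols].sum(axis=1) < 2
    return mask


def _params_from_profile(
    y: np.ndarray, D: np.ndarray, log_alpha: float, log_beta: float
) -> tuple[OUGeneParams, float]:
    ll, theta, v = _profile_ll_chol(y, D, log_alpha, log_beta)
    alpha = float(np.exp(log_alpha))
    v = max(float(v), 1e-300)
    return (
        OUGeneParams(
            theta=float(theta),
            sigma2=2.0 * alpha * v,
            alpha=alpha,
            beta=float(np.exp(log_beta)),
        ),
        ll,
    )


def _fit_fixed_beta(
    y: np.ndarray, D: np.ndarray, log_beta: float, la0: float
) -> tuple[float, float, bool]:
    """Maximise over log alpha at fixed beta. Returns (ll, log_alpha, ok)."""

    def nll(la):
        return -_profile_ll_chol(y, D, float(la), log_beta)[0]

    res = optimize.minimize_scalar(
        nll,
        bounds=LOG_ALPHA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-7},
    )
    best_ll = -res.fun
    best_la = float(res.x)
    ll0 = _profile_ll_chol(y, D, la0, log_beta)[0]
    if ll0 > best_ll:  # bounded search can miss a boundary basin
        best_ll, best_la = ll0, la0
    return best_ll, best_la, bool(res.success)


def _fit_free(
    y: np.ndarray, D: np.ndarray, starts: list[tuple[float, float]]
) -> tuple[float, float, float, bool]:
    """Maximise over (log alpha, log beta). Returns (ll, la, lb, ok)."""

    def nll(x):
        return -_profile_ll_chol(y, D, float(x[0]), float(x[1]))[0]

    best = (-np.inf, np.nan, np.nan, False)
    for la, lb in starts:
        res = optimize.minimize(
            nll,
            x0=np.array([la, lb]),
            method="L-BFGS-B",
            bounds=[LOG_ALPHA_BOUNDS, LOG_BETA_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-9},
        )
        if -res.fun > best[0]:
            best = (-res.fun, float(res.x[0]), float(res.x[1]), bool(res.success))
        ll_start = -nll([la, lb])
        if ll_start > best[0]:
            best = (ll_start, la, lb, True)
    return best


_COARSE_LOG_ALPHAS = np.linspace(*LOG_ALPHA_BOUNDS, 33)
_COARSE_LOG_BETAS = np.linspace(*LOG_BETA_BOUNDS, 33)
_SHARED_LOG_ALPHAS = np.linspace(*LOG_ALPHA_BOUNDS, 97)


def fit_gene(
    y: np.ndarray,
    tree: Phylogeny,
    layout: SampleLayout,
    fixed_beta: float | None = None,
) -> GeneFit:
    """Maximum-likelihood OU fit for one gene.

    With ``fixed_beta=None`` the within/evolutionary variance ratio ``beta``
    is a free parameter; otherwise it is pinned (the shared-``beta`` null
    arm of the divergence test).  ``theta`` and ``v_evo`` are profiled
    analytically; ``alpha`` (and ``beta``) are maximised numerically with
    multiple starts seeded from a coarse grid.
    """
    _check_identifiable(layout)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("expression vector contains non-finite values")
    if float(np.var(y)) < _DEGENERATE_VAR:
        params = OUGeneParams(
            theta=float(np.mean(y)), sigma2=1e-12, alpha=1.0,
            beta=np.exp(LOG_BETA_BOUNDS[0]) if fixed_beta is None else fixed_beta,
        )
        return GeneFit(params=params, loglik=np.nan, converged=False)
    D = _individual_distances(tree, layout)
    grid = _ProfileGrid(y[None, :], D, _COARSE_LOG_ALPHAS)

    if fixed_beta is not None:
        lb = float(np.log(fixed_beta))
        ll_grid = grid.loglik(lb)[0]
        la0 = _COARSE_LOG_ALPHAS[int(np.argmax(ll_grid))]
        ll, la, ok = _fit_fixed_beta(y, D, lb, la0)
        params, _ = _params_from_profile(y, D, la, lb)
        return GeneFit(params=params, loglik=ll, converged=ok)

    # free beta: seed from best coarse (alpha, beta) cell + two canonical starts
    best_cell = (-np.inf, 0.0, 0.0)
    for lbg in _COARSE_LOG_BETAS:
        ll_grid = grid.loglik(lbg)[0]
        k = int(np.argmax(ll_grid))
        if ll_grid[k] > best_cell[0]:
            best_cell = (ll_grid[k], _COARSE_LOG_ALPHAS[k], lbg)
    starts = [(best_cell[1], best_cell[2]), (0.0, 0.0)]
    ll, la, lb, ok = _fit_free(y, D, starts)
    params, _ = _params_from_profile(y, D, la, lb)
    return GeneFit(params=params, loglik=ll, converged=ok)


def fit_shared_beta(
    matrix: np.ndarray | pd.DataFrame,
    tree: Phylogeny,
    layout: SampleLayout,
) -> tuple[float, list[OUGeneParams]]:
    """Joint fit of one common ``beta`` across genes.

    Maximises the summed per-gene profiled log-likelihood with a single
    shared ``beta`` and gene-specific ``(theta, sigma2, alpha)``: an outer
    one-dimensional bounded search over ``log beta`` wrapping an inner
    vectorised per-gene profile over ``alpha``.
    """
    _check_identifiable(layout)
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != layout.n:
        raise ValueError("matrix must be genes x individuals matching layout")
    keep = ~_degenerate_mask(Y, layout)
    if keep.sum() < 1:
        raise ValueError("all genes are degenerate; cannot estimate shared beta")
    Yk = Y[keep]
    D = _individual_distances(tree, layout)
    grid = _ProfileGrid(Yk, D, _SHARED_LOG_ALPHAS)

    def neg_joint(log_beta):
        best, _ = grid.max_over_alpha(float(log_beta))
        return -float(best.sum())

    res = optimize.minimize_scalar(
        neg_joint, bounds=LOG_BETA_BOUNDS, method="bounded",
        options={"xatol": 1e-6},
    )
    lb_hat = float(res.x)
    beta_shared = float(np.exp(lb_hat))

    _, la_grid = grid.max_over_alpha(lb_hat)
    params: list[OUGeneParams] = []
    j = 0
    for g in range(Y.shape[0]):
        if not keep[g]:
            params.append(
                OUGeneParams(theta=float(np.nanmean(Y[g])), sigma2=1e-12,
                             alpha=1.0, beta=beta_shared)
            )
            continue
        _, la, _ = _fit_fixed_beta(Yk[j], D, lb_hat, float(la_grid[j]))
        p, _ = _params_from_profile(Yk[j], D, la, lb_hat)
        params.append(p)
        j += 1
    return beta_shared, params


def divergence_test(
    matrix: np.ndarray | pd.DataFrame,
    tree: Phylogeny,
    layout: SampleLayout,
    p_threshold: float = 0.05,
    beta_shared: float | None = None,
) -> pd.DataFrame:
    """Per-gene likelihood-ratio test of gene-specific vs shared ``beta``.

    For every gene the null arm re-optimises ``(theta, sigma2, alpha)`` with
    ``beta`` held at the joint shared estimate, the alternative arm frees
    ``beta``, and ``LRT = 2 * (loglik_free - loglik_shared)`` is referred to
    a chi-square distribution with 1 degree of freedom.  Genes with
    ``p < p_threshold`` are called ``divergence`` when the gene-specific
    ``beta`` falls below the shared value and ``diversity`` when above.

    Returns a table with one row per input gene: ``beta_i``,
    ``beta_shared``, both log-likelihoods, ``lrt``, ``pvalue``,
    Benjamini-Hochberg ``qvalue`` (reported, not used for calls), ``call``
    and flags.  Degenerate genes (near-zero variance, or a species with
    fewer than two finite values) are excluded from testing and flagged.
    """
    if isinstance(matrix, pd.DataFrame):
        gene_ids = list(matrix.index)
        Y = matrix.to_numpy(dtype=float)
    else:
        Y = np.asarray(matrix, dtype=float)
        gene_ids = [f"g{i}" for i in range(Y.shape[0])]
    _check_identifiable(layout)
    if Y.shape[1] != layout.n:
        raise ValueError("matrix columns must match layout individuals")

    degenerate = _degenerate_mask(Y, layout)
    n_genes = Y.shape[0]
    cols = {
        "beta_i": np.full(n_genes, np.nan),
        "beta_shared": np.full(n_genes, np.nan),
        "theta": np.full(n_genes, np.nan),
        "sigma2": np.full(n_genes, np.nan),
        "alpha": np.full(n_genes, np.nan),
        "loglik_null": np.full(n_genes, np.nan),
        "loglik_alt": np.full(n_genes, np.nan),
        "lrt": np.full(n_genes, np.nan),
        "pvalue": np.full(n_genes, np.nan),
        "qvalue": np.full(n_genes, np.nan),
        "call": np.array(["none"] * n_genes, dtype=object),
        "converged": np.zeros(n_genes, dtype=bool),
        "degenerate": degenerate.copy(),
    }
    if degenerate.all():
        warnings.warn(
            "all genes are degenerate (constant or under-replicated); "
            "returning an empty result table",
            RuntimeWarning,
        )
        return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    keep = ~degenerate
    Yk = Y[keep]
    if beta_shared is None:
        beta_shared, _ = fit_shared_beta(Yk, tree, layout)
    lb_hat = float(np.log(beta_shared))
    D = _individual_distances(tree, layout)
    grid = _ProfileGrid(Yk, D, _SHARED_LOG_ALPHAS)
    _, la_null = grid.max_over_alpha(lb_hat)
    # per-gene coarse free-beta starting cells
    best_free = np.full((Yk.shape[0], 3), -np.inf)
    for lbg in _COARSE_LOG_BETAS:
        ll = grid.loglik(lbg)
        k = np.argmax(ll, axis=1)
        v = ll[np.arange(len(k)), k]
        upd = v > best_free[:, 0]
        best_free[upd, 0] = v[upd]
        best_free[upd, 1] = _SHARED_LOG_ALPHAS[k[upd]]
        best_free[upd, 2] = lbg

    rows = np.where(keep)[0]
    for j, g in enumerate(rows):
        y = Yk[j]
        ll0, la0, ok0 = _fit_fixed_beta(y, D, lb_hat, float(la_null[j]))
        starts = [(la0, lb_hat), (float(best_free[j, 1]), float(best_free[j, 2]))]
        ll1, la1, lb1, ok1 = _fit_free(y, D, starts)
        if ll1 < ll0:  # free arm nests the null arm
            ll1, la1, lb1 = ll0, la0, lb_hat
        lrt = 2.0 * (ll1 - ll0)
        if lrt < -1e-6:
            raise RuntimeError(
                f"negative LRT ({lrt:.3e}) for gene {gene_ids[g]}: optimizer bug"
            )
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        params, _ = _params_from_profile(y, D, la1, lb1)
        beta_i = params.beta
        call = "none"
        if p < p_threshold:
            call = "divergence" if beta_i < beta_shared else "diversity"
        cols["beta_i"][g] = beta_i
        cols["beta_shared"][g] = beta_shared
        cols["theta"][g] = params.theta
        cols["sigma2"][g] = params.sigma2
        cols["alpha"][g] = params.alpha
        cols["loglik_null"][g] = ll0
        cols["loglik_alt"][g] = ll1
        cols["lrt"][g] = lrt
        cols["pvalue"][g] = p
        cols["call"][g] = call
        cols["converged"][g] = ok0 and ok1

    tested = np.isfinite(cols["pvalue"])
    if tested.any():
        cols["qvalue"][tested] = multipletests(
            cols["pvalue"][tested], method="fdr_bh"
        )[1]
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
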