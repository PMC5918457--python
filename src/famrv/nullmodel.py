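"""Polygenic null model and the quasi-likelihood score machinery.

The null model is Y = X beta + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I), where K is the covariance kernel (2*KCM for a
pedigree kinship matrix, or a GRM). Variance components are estimated by
restricted maximum likelihood. Because a single kernel is involved, REML
profiles exactly to a one-dimensional problem after one eigendecomposition
K = U D U^T: rotating by U^T diagonalizes the covariance, beta and
sigma_e^2 have closed forms given the ratio gamma = sigma_g^2/sigma_e^2,
and gamma is found by bounded scalar optimization of the restricted
log-likelihood. The decomposition can be shared across phenotypes on the
same kernel, which is what makes large calibration experiments cheap.

Binary phenotypes are fitted with the same working linear model on 0/1
outcomes; the resulting score tests remain valid under the null.

All gene-level tests consume a :class:`ScoreBlock`: the weighted score
vector S = W^{1/2} G^T P Y and its null covariance V = W^{1/2} G^T P G
W^{1/2}, where P is the REML projection
Sigma^{-1} - Sigma^{-1} X (X^T Sigma^{-1} X)^{-1} X^T Sigma^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import beta as beta_dist

from .datatypes import RelMatrix


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the evaluation trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class KernelEigen:
    """Cached eigendecomposition of a covariance kernel.

    Build once per kernel and pass to any number of
    :class:`FamilyNullModel` fits on the same subjects. An indefinite
    kernel (possible for a GRM) gets a 1e-6 ridge, then residual negative
    eigenvalues are clipped at zero.
    """

    def __init__(self, kernel: RelMatrix | np.ndarray, subject_order=None):
        if isinstance(kernel, RelMatrix):
            mat = kernel.kernel
            self.subject_order = list(kernel.subject_order)
            self.kind = kernel.kind
        else:
            mat = np.asarray(kernel, dtype=float)
            self.subject_order = list(subject_order) if subject_order is not None else None
            self.kind = "custom"
        d, U = np.linalg.eigh(mat)
        if d.min() < -1e-8 * max(1.0, abs(d.max())):
            d = d + 1e-6
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = mat.shape[0]

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A


@dataclass
class FamilyNullModel:
    """REML fit of the single-kernel polygenic null model.

    Parameters
    ----------
    kernel:
        A :class:`RelMatrix` or a precomputed :class:`KernelEigen`.
    gamma_bounds:
        Search interval for log(sigma_g^2/sigma_e^2).

    Fitted attributes (set by :meth:`fit`): ``beta_``, ``sigma_g2_``,
    ``sigma_e2_``, ``h2_``, ``resid_proj_`` (the projected residuals P Y),
    ``converged_``, ``reml_loglik_``.
    """

    kernel: KernelEigen | RelMatrix
    gamma_bounds: tuple[float, float] = (-18.0, 18.0)
    phenotype_kind: str = "continuous"
    _trace: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if isinstance(self.kernel, RelMatrix):
            self.kernel = KernelEigen(self.kernel)

    # -- internals ---------------------------------------------------------

    def _neg_restricted_ll(self, log_gamma, yt, Xt, d):
        gamma = np.exp(log_gamma)
        w = gamma * d + 1.0
        xtw = Xt / w[:, None]
        xwx = Xt.T @ xtw
        try:
            beta = np.linalg.solve(xwx, xtw.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        nc = len(yt) - Xt.shape[1]
        rss = float(r @ (r / w))
        if rss <= 0:
            return np.inf
        sigma_e2 = rss / nc
        sign, logdet_xwx = np.linalg.slogdet(xwx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (nc * np.log(sigma_e2) + np.log(w).sum() + logdet_xwx + nc)
        self._trace.append((float(log_gamma), float(-ll)))
        return -ll

    def _reml_gradient(self, log_gamma, yt, Xt, d):
        """d(restricted loglik)/d(log gamma), analytic."""
        gamma = np.exp(log_gamma)
        w = gamma * d + 1.0
        xtw = Xt / w[:, None]
        xwx = Xt.T @ xtw
        beta = np.linalg.solve(xwx, xtw.T @ yt)
        r = yt - Xt @ beta
        nc = len(yt) - Xt.shape[1]
        rw = r / w
        rss = float(r @ rw)
        sigma_e2 = rss / nc
        dw = d  # dw/dgamma
        # envelope theorem: beta is weighted-LS optimal, so no beta term
        d_rss = -float(rw @ (dw * rw))
        d_logdet_w = float((dw / w).sum())
        M = Xt * (dw / w ** 2)[:, None]
        d_logdet_x = -float(np.trace(np.linalg.solve(xwx, Xt.T @ M)))
        dll_dgamma = -0.5 * (nc * d_rss / rss + d_logdet_w + d_logdet_x)
        return dll_dgamma * gamma  # chain rule to log scale

    # -- public API --------------------------------------------------------

    def fit(self, y: np.ndarray, X: np.ndarray | None = None,
            add_intercept: bool = True) -> "FamilyNullModel":
        y = np.asarray(y, dtype=float)
        n = self.kernel.n
        if y.shape != (n,):
            raise ValueError(f"phenotype length {y.shape} != kernel size {n}")
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=float)
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
        # standardize nonconstant columns so the fit (and downstream score
        # tests) are invariant to covariate rescaling
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        X = X / scale
        self._X = X
        self._trace = []
        d, U = self.kernel.d, self.kernel.U
        yt = U.T @ y
        Xt = U.T @ X

        lo, hi = self.gamma_bounds
        res = optimize.minimize_scalar(
            self._neg_restricted_ll, bounds=(lo, hi), args=(yt, Xt, d),
            method="bounded", options={"xatol": 1e-10, "maxiter": 500},
        )
        if not res.success and not np.isfinite(res.fun):
            raise ConvergenceError("REML scalar optimization failed", self._trace)
        # compare against the sigma_g^2 = 0 boundary (gamma ~ 0)
        f_zero = self._neg_restricted_ll(lo - 30.0, yt, Xt, d)
        if f_zero <= res.fun:
            gamma = 0.0
            self.reml_loglik_ = -f_zero
        else:
            x = float(res.x)
            # polish by bisection on the analytic gradient; the optimum is
            # then a root of a freshly evaluated 1-D function, independent
            # of the optimizer's iterate history
            a, b = max(lo, x - 0.5), min(hi, x + 0.5)
            ga = self._reml_gradient(a, yt, Xt, d)
            gb = self._reml_gradient(b, yt, Xt, d)
            if ga > 0 > gb:
                for _ in range(80):
                    mid = 0.5 * (a + b)
                    if self._reml_gradient(mid, yt, Xt, d) > 0:
                        a = mid
                    else:
                        b = mid
                x = 0.5 * (a + b)
            gamma = float(np.exp(x))
            if x <= lo + 1e-6:
                gamma = 0.0
            self.reml_loglik_ = -self._neg_restricted_ll(x, yt, Xt, d)
        self.converged_ = True

        w = gamma * d + 1.0
        xtw = Xt / w[:, None]
        xwx = Xt.T @ xtw
        beta = np.linalg.solve(xwx, xtw.T @ yt)
        r = yt - Xt @ beta
        nc = n - X.shape[1]
        sigma_e2 = float(r @ (r / w)) / nc
        self.beta_ = beta / scale  # effects on the original covariate scale
        self.sigma_e2_ = sigma_e2
        self.sigma_g2_ = gamma * sigma_e2
        tot = self.sigma_g2_ + self.sigma_e2_
        self.h2_ = self.sigma_g2_ / tot if tot > 0 else 0.0
        self.gamma_ = gamma

        # projection pieces in rotated coordinates
        self._w_sigma = w * sigma_e2  # diag of rotated Sigma-hat
        self._Xt = Xt
        self._xwx_inv = np.linalg.inv(Xt.T @ (Xt / self._w_sigma[:, None]))
        self._yt = yt
        self._py_rot = self._project_rotated(yt[:, None])[:, 0]
        self.resid_proj_ = U @ self._py_rot
        return self

    def _project_rotated(self, Bt: np.ndarray) -> np.ndarray:
        """P applied to rotated columns: returns U^T P U Bt."""
        wb = Bt / self._w_sigma[:, None]
        xwb = self._Xt.T @ wb
        return wb - (self._Xt / self._w_sigma[:, None]) @ (self._xwx_inv @ xwb)

    def quad_forms(self, G: np.ndarray, rotated: bool = False):
        """(G^T P Y, G^T P G) for dosage columns G (subjects x variants).

        Pass ``rotated=True`` when G is already U^T-rotated (precomputed
        once per kernel for speed).
        """
        Gt = G if rotated else self.kernel.rotate(G)
        s = Gt.T @ self._py_rot
        PG = self._project_rotated(Gt)
        C = Gt.T @ PG
        return s, (C + C.T) / 2.0

    def summary(self) -> str:
        return (
            f"REML null model: sigma_g2={self.sigma_g2_:.6g} "
            f"sigma_e2={self.sigma_e2_:.6g} h2={self.h2_:.4f} "
            f"beta={np.array2string(self.beta_, precision=4)} "
            f"({self.phenotype_kind}, kernel={self.kernel.kind})"
        )

    # minimal get/set-params so the model composes with sklearn utilities
    def get_params(self, deep: bool = True) -> dict:
        return {"kernel": self.kernel, "gamma_bounds": self.gamma_bounds,
                "phenotype_kind": self.phenotype_kind}

    def set_params(self, **params) -> "FamilyNullModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def fit_null_model(phenotype: np.ndarray, covariates: np.ndarray | None,
                   kernel: RelMatrix | KernelEigen,
                   phenotype_kind: str = "continuous") -> FamilyNullModel:
    """Functional wrapper over :class:`FamilyNullModel`."""
    model = FamilyNullModel(kernel, phenotype_kind=phenotype_kind)
    return model.fit(phenotype, covariates)


# ---------------------------------------------------------------------------
# Variant weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightSpec:
    """Per-variant weight scheme for gene-level tests.

    ``beta`` (default a=1, b=25) up-weights rarer variants as in the SKAT
    lineage; ``uniform`` gives 1; ``madsen-browning`` gives
    1/sqrt(maf*(1-maf)).
    """

    scheme: str = "beta"
    a: float = 1.0
    b: float = 25.0

    def __call__(self, mafs: np.ndarray) -> np.ndarray:
        mafs = np.asarray(mafs, dtype=float)
        if self.scheme == "uniform":
            return np.ones_like(mafs)
        if self.scheme == "beta":
            return beta_dist.pdf(np.clip(mafs, 1e-12, 1.0), self.a, self.b)
        if self.scheme == "madsen-browning":
            p = np.clip(mafs, 1e-12, 1 - 1e-12)
            return 1.0 / np.sqrt(p * (1.0 - p))
        raise ValueError(f"unknown weight scheme {self.scheme!r}")


@dataclass
class ScoreBlock:
    """Weighted gene score vector and its null covariance.

    ``S = W^(1/2) G^T P Y`` and ``V = W^(1/2) G^T P G W^(1/2)``; the
    unweighted score ``raw_score = G^T P Y`` and covariance ``raw_cov``
    are retained for the variable-threshold test.
    """

    S: np.ndarray
    V: np.ndarray
    weights: np.ndarray
    raw_score: np.ndarray
    raw_cov: np.ndarray

    @property
    def n_variants(self) -> int:
        return self.S.size


def score_block(null_model: FamilyNullModel, gene_dosages: np.ndarray,
                weights: np.ndarray, rotated: bool = False) -> ScoreBlock:
    """Build the score block for one gene.

    ``gene_dosages`` are subjects x variants (missing already imputed);
    ``weights`` are strictly positive per-variant weights.
    """
    G = np.asarray(gene_dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(~np.isfinite(G)):
        raise ValueError("gene dosages contain missing values; impute first")
    s, C = null_model.quad_forms(G, rotated=rotated)
    sw = np.sqrt(w)
    S = sw * s
    V = (sw[:, None] * C) * sw[None, :]
    return ScoreBlock(S, (V + V.T) / 2.0, w, s, C)
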