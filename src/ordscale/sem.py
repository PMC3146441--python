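"""Ordinal factor models fitted to polychoric statistics.

The estimator is diagonally weighted least squares (DWLS): the free
parameters minimise

    F(theta) = sum_p (s_p - sigma_p(theta))^2 / Gamma_pp

over the stacked lower-triangle polychoric correlations s, with Gamma the
asymptotic covariance of s.  The test statistic is the scaled-and-shifted
("mean and variance adjusted") transform of n*F_hat referred to the model
degrees of freedom, and standard errors use the full-Gamma sandwich — the
combination that emulates the behaviour of the WLSMV estimator for
categorical indicators.  Supported structures: congeneric CFA with free
factor correlations, exploratory blocks (all loadings free, echelon
identification, geomin rotation applied afterwards), and orthogonal
bifactor models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, ncx2

from .polychoric import PolychoricResult, pair_order
from .rotation import align_to_target, rotate_geomin

__all__ = [
    "ModelSpec",
    "FactorSolution",
    "FitIndices",
    "ModificationIndex",
    "fit_model",
    "fit_exploratory",
    "fit_indices",
    "modification_indices",
    "scaled_difference_test",
    "one_factor_spec",
    "cfa_spec",
    "bifactor_spec",
    "exploratory_spec",
]

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Free/fixed structure of an ordinal factor model.

    ``pattern[i, k]`` is True where loading lambda_ik is free (fixed
    loadings are 0).  Identification is by unit factor variances throughout
    (delta parameterization; standardized output only).
    """

    pattern: np.ndarray
    factor_cov: str = "free"  # "free" or "orthogonal"
    residual_pairs: tuple = ()
    exploratory: bool = False
    general_col: int | None = None
    item_labels: tuple = ()
    factor_labels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "pattern", np.atleast_2d(np.asarray(self.pattern, bool)))
        object.__setattr__(
            self, "residual_pairs", tuple(tuple(sorted(p)) for p in self.residual_pairs)
        )
        if not self.item_labels:
            object.__setattr__(
                self, "item_labels", tuple(f"i{j + 1}" for j in range(self.pattern.shape[0]))
            )
        if not self.factor_labels:
            object.__setattr__(
                self, "factor_labels", tuple(f"f{k + 1}" for k in range(self.pattern.shape[1]))
            )
        self.validate()

    @property
    def n_items(self) -> int:
        return self.pattern.shape[0]

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]

    @property
    def n_free(self) -> int:
        n = int(self.pattern.sum()) + len(self.residual_pairs)
        if self.factor_cov == "free":
            K = self.n_factors
            n += K * (K - 1) // 2
        return n

    def validate(self) -> None:
        if self.factor_cov not in ("free", "orthogonal"):
            raise ValueError("factor_cov must be 'free' or 'orthogonal'")
        if np.any(self.pattern.sum(axis=1) == 0):
            bad = [self.item_labels[i] for i in np.where(self.pattern.sum(axis=1) == 0)[0]]
            raise ValueError(f"items {bad} load on no factor")
        if (self.exploratory or self.general_col is not None) and self.factor_cov != "orthogonal":
            raise ValueError("exploratory and bifactor structures require orthogonal factors")
        if not self.exploratory:
            per_factor = self.pattern.sum(axis=0)
            if np.any(per_factor[per_factor > 0] < 3):
                raise ValueError(
                    "confirmatory factors need at least three indicators for identification"
                )

    def to_yaml(self, path) -> None:
        payload = {
            "item_labels": list(self.item_labels),
            "factor_labels": list(self.factor_labels),
            "pattern": self.pattern.astype(int).tolist(),
            "factor_cov": self.factor_cov,
            "residual_pairs": [list(p) for p in self.residual_pairs],
            "exploratory": self.exploratory,
            "general_col": self.general_col,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            pattern=np.asarray(payload["pattern"], bool),
            factor_cov=payload.get("factor_cov", "free"),
            residual_pairs=tuple(tuple(p) for p in payload.get("residual_pairs", ())),
            exploratory=payload.get("exploratory", False),
            general_col=payload.get("general_col"),
            item_labels=tuple(payload.get("item_labels", ())),
            factor_labels=tuple(payload.get("factor_labels", ())),
        )

    def replace(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)


def one_factor_spec(item_labels) -> ModelSpec:
    J = len(item_labels)
    return ModelSpec(
        pattern=np.ones((J, 1), bool),
        factor_cov="orthogonal",
        item_labels=tuple(item_labels),
        factor_labels=("f1",),
    )


def cfa_spec(item_sets: dict, item_labels) -> ModelSpec:
    """Congeneric CFA: each item on exactly one factor, free correlations."""
    item_labels = tuple(item_labels)
    factors = tuple(item_sets)
    pattern = np.zeros((len(item_labels), len(factors)), bool)
    for k, fac in enumerate(factors):
        for item in item_sets[fac]:
            pattern[item_labels.index(item), k] = True
    return ModelSpec(
        pattern=pattern, factor_cov="free", item_labels=item_labels, factor_labels=factors
    )


def bifactor_spec(item_sets: dict, item_labels) -> ModelSpec:
    """General factor on every item plus one specific factor per item set."""
    item_labels = tuple(item_labels)
    factors = ("g",) + tuple(item_sets)
    pattern = np.zeros((len(item_labels), len(factors)), bool)
    pattern[:, 0] = True
    for k, fac in enumerate(item_sets, start=1):
        for item in item_sets[fac]:
            pattern[item_labels.index(item), k] = True
    return ModelSpec(
        pattern=pattern,
        factor_cov="orthogonal",
        general_col=0,
        item_labels=item_labels,
        factor_labels=factors,
    )


def exploratory_spec(n_items: int, n_factors: int, item_labels=None) -> ModelSpec:
    """All loadings free under echelon identification (K(K-1)/2 zeros)."""
    pattern = np.ones((n_items, n_factors), bool)
    for i in range(min(n_factors, n_items)):
        pattern[i, i + 1:] = False
    return ModelSpec(
        pattern=pattern,
        factor_cov="orthogonal",
        exploratory=True,
        item_labels=tuple(item_labels) if item_labels else (),
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitIndices:
    """Adjusted test statistic and derived approximate-fit indices."""

    T: float
    df: int
    rmsea: float
    rmsea_ci: tuple
    cfi: float
    tli: float
    baseline_T: float
    baseline_df: int
    n: int
    t_raw: float = field(repr=False, default=np.nan)
    trace_m: float = field(repr=False, default=np.nan)
    trace_m2: float = field(repr=False, default=np.nan)

    @property
    def p_value(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(chi2.sf(self.T, self.df))


@dataclass(frozen=True)
class FactorSolution:
    """Standardized estimates of an ordinal factor model."""

    spec: ModelSpec
    loadings: np.ndarray
    loadings_se: np.ndarray
    phi: np.ndarray
    phi_se: np.ndarray
    residual_corr: np.ndarray
    delta: np.ndarray
    heywood: np.ndarray
    thresholds: object
    converged: bool
    n_iter: int
    grad_norm: float
    se_approximate: bool = False
    # fit internals consumed by modification indices / bootstrap restarts
    params: np.ndarray = field(repr=False, default=None)
    f_min: float = field(repr=False, default=np.nan)
    _jac: np.ndarray = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)
    _gamma: np.ndarray = field(repr=False, default=None)
    _resid: np.ndarray = field(repr=False, default=None)
    _n: int = field(repr=False, default=0)
    _param_cov: np.ndarray = field(repr=False, default=None)

    @property
    def item_labels(self):
        return self.spec.item_labels

    @property
    def factor_labels(self):
        return self.spec.factor_labels

    def implied_correlations(self) -> np.ndarray:
        sigma = self.loadings @ self.phi @ self.loadings.T + self.residual_corr
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def loadings_ci(self, level: float = 0.95):
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return self.loadings - z * self.loadings_se, self.loadings + z * self.loadings_se

    def to_frame(self):
        import pandas as pd

        lo, hi = self.loadings_ci()
        rows = []
        for i, item in enumerate(self.item_labels):
            for k, fac in enumerate(self.factor_labels):
                if self.spec.pattern[i, k]:
                    rows.append(
                        {
                            "parameter": f"{item}~{fac}",
                            "estimate": self.loadings[i, k],
                            "se": self.loadings_se[i, k],
                            "ci_low": lo[i, k],
                            "ci_high": hi[i, k],
                        }
                    )
        for a in range(self.spec.n_factors):
            for b in range(a + 1, self.spec.n_factors):
                if self.spec.factor_cov == "free":
                    se = self.phi_se[a, b]
                    rows.append(
                        {
                            "parameter": f"{self.factor_labels[a]}~~{self.factor_labels[b]}",
                            "estimate": self.phi[a, b],
                            "se": se,
                            "ci_low": self.phi[a, b] - 1.959963984540054 * se,
                            "ci_high": self.phi[a, b] + 1.959963984540054 * se,
                        }
                    )
        for i, item in enumerate(self.item_labels):
            rows.append(
                {
                    "parameter": f"{item}~~{item}",
                    "estimate": self.delta[i],
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModificationIndex:
    """Score-test statistic for freeing one constrained parameter."""

    kind: str  # "loading" or "residual"
    label: str
    index: tuple
    mi: float
    epc: float


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

class _ParamMap:
    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.load_idx = [tuple(ix) for ix in np.argwhere(spec.pattern)]
        K = spec.n_factors
        self.phi_idx = (
            [(a, b) for a in range(K) for b in range(a + 1, K)]
            if spec.factor_cov == "free"
            else []
        )
        self.res_idx = list(spec.residual_pairs)
        self.n_load = len(self.load_idx)
        self.n_phi = len(self.phi_idx)
        self.n_res = len(self.res_idx)
        self.n_params = self.n_load + self.n_phi + self.n_res

    def unpack(self, params):
        spec = self.spec
        lam = np.zeros((spec.n_items, spec.n_factors))
        for v, (i, k) in zip(params[: self.n_load], self.load_idx):
            lam[i, k] = v
        phi = np.eye(spec.n_factors)
        for v, (a, b) in zip(params[self.n_load: self.n_load + self.n_phi], self.phi_idx):
            phi[a, b] = phi[b, a] = v
        theta = np.zeros((spec.n_items, spec.n_items))
        for v, (i, j) in zip(params[self.n_load + self.n_phi:], self.res_idx):
            theta[i, j] = theta[j, i] = v
        return lam, phi, theta

    def bounds(self):
        # standardized loadings are correlations with the latent response,
        # so they are constrained to (-1, 1); Heywood cases then surface as
        # negative uniqueness rather than runaway estimates
        return (
            [(-0.999, 0.999)] * self.n_load
            + [(-0.999, 0.999)] * self.n_phi
            + [(-0.999, 0.999)] * self.n_res
        )


def _sigma_and_jac(pm: _ParamMap, params, pairs):
    lam, phi, theta = pm.unpack(params)
    M = lam @ phi  # J x K
    sig_full = M @ lam.T
    sigma = np.array([sig_full[i, j] + theta[i, j] for i, j in pairs])
    jac = np.zeros((len(pairs), pm.n_params))
    for p, (i, j) in enumerate(pairs):
        for q, (a, c) in enumerate(pm.load_idx):
            v = 0.0
            if i == a:
                v += M[j, c]
            if j == a:
                v += M[i, c]
            jac[p, q] = v
        for q, (a, b) in enumerate(pm.phi_idx):
            jac[p, pm.n_load + q] = lam[i, a] * lam[j, b] + lam[i, b] * lam[j, a]
        for q, (a, b) in enumerate(pm.res_idx):
            if (min(i, j), max(i, j)) == (a, b):
                jac[p, pm.n_load + pm.n_phi + q] = 1.0
    return sigma, jac


def _start_values(spec: ModelSpec, pm: _ParamMap, R: np.ndarray):
    if spec.exploratory:
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1][: spec.n_factors]
        lam = vecs[:, order] * np.sqrt(np.maximum(vals[order], 1e-3))
        # rotate to echelon form: zeros above the diagonal of the first K rows
        K = spec.n_factors
        q, _ = np.linalg.qr(lam[:K].T)
        lam = lam @ q
        for k in range(K):
            if lam[k, k] < 0:
                lam[:, k] *= -1
        start_load = [lam[i, k] for i, k in pm.load_idx]
    else:
        start_load = []
        for i, k in pm.load_idx:
            if spec.general_col is not None:
                start_load.append(0.6 if k == spec.general_col else 0.3)
            else:
                start_load.append(0.6)
    return np.concatenate([start_load, [0.4] * pm.n_phi, [0.0] * pm.n_res])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(
    spec: ModelSpec,
    stats: PolychoricResult,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
    compute_fit: bool = True,
):
    """Fit an ordinal factor model by DWLS; returns (FactorSolution, FitIndices).

    ``stats.acov`` may be None, in which case unit weights are used (useful
    for fitting to an exact model-implied matrix).  ``compute_fit=False``
    skips the test statistic and fit indices (bootstrap replicates only need
    point estimates) and returns None in their place.
    """
    J = stats.n_items
    if spec.n_items != J:
        raise ValueError("model spec and statistics disagree on the number of items")
    pairs = pair_order(J)
    s = stats.lower_triangle()
    n = stats.n
    if stats.acov is not None:
        gamma = stats.acov * n  # asymptotic (per-observation) covariance of s
    else:
        gamma = np.eye(len(pairs))
    w = np.maximum(np.diag(gamma).copy(), _W_FLOOR)

    pm = _ParamMap(spec)
    if pm.n_params > len(pairs) and not spec.exploratory:
        raise ValueError("model has more free parameters than sample correlations")
    x0 = np.asarray(start, float) if start is not None else _start_values(spec, pm, stats.R)

    def objective(params):
        sigma, jac = _sigma_and_jac(pm, params, pairs)
        r = sigma - s
        f = float(np.sum(r * r / w))
        g = 2.0 * (jac.T @ (r / w))
        return f, g

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=pm.bounds(),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol},
    )
    sigma, jac = _sigma_and_jac(pm, res.x, pairs)
    resid = sigma - s
    grad_norm = float(np.linalg.norm(res.jac))
    converged = bool(res.success) or grad_norm < 1e-4
    if not converged:
        logger.warning("DWLS optimiser did not converge: %s (|g|=%.2e)", res.message, grad_norm)

    lam, phi, theta = pm.unpack(res.x)
    communality = np.einsum("ik,kl,il->i", lam, phi, lam)
    delta = 1.0 - communality
    heywood = delta < 0
    if heywood.any():
        logger.warning(
            "Heywood cases (negative uniqueness) for items %s",
            [spec.item_labels[i] for i in np.where(heywood)[0]],
        )

    # sandwich parameter covariance
    Winv_jac = jac / w[:, None]
    B = jac.T @ Winv_jac
    Binv = np.linalg.pinv(B)
    inner = Winv_jac.T @ gamma @ Winv_jac
    param_cov = Binv @ inner @ Binv / n
    param_se = np.sqrt(np.maximum(np.diag(param_cov), 0.0))

    load_se = np.full_like(lam, np.nan)
    for se, (i, k) in zip(param_se[: pm.n_load], pm.load_idx):
        load_se[i, k] = se
    phi_se = np.full_like(phi, np.nan)
    for se, (a, b) in zip(param_se[pm.n_load: pm.n_load + pm.n_phi], pm.phi_idx):
        phi_se[a, b] = phi_se[b, a] = se

    solution = FactorSolution(
        spec=spec,
        loadings=lam,
        loadings_se=load_se,
        phi=phi,
        phi_se=phi_se,
        residual_corr=theta,
        delta=delta,
        heywood=heywood,
        thresholds=stats.thresholds,
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        params=res.x.copy(),
        f_min=float(res.fun),
        _jac=jac,
        _w=w,
        _gamma=gamma,
        _resid=resid,
        _n=n,
        _param_cov=param_cov,
    )
    indices = None
    if compute_fit:
        T, df, t_raw, tr_m, tr_m2 = _test_statistics(resid, jac, w, gamma, n, pm.n_params)
        T_b, df_b, _, _ = baseline_statistics(stats)
        indices = replace(
            fit_indices(T, df, T_b, df_b, n), t_raw=t_raw, trace_m=tr_m, trace_m2=tr_m2
        )
    return solution, indices


def _adjusted_statistic(t_raw, M, df):
    """Scale-and-shift t_raw so its first two moments match chi-square(df)."""
    tr_m = float(np.trace(M))
    tr_m2 = float(np.trace(M @ M))
    if df <= 0 or tr_m2 <= 0:
        return max(t_raw, 0.0), tr_m, tr_m2
    a = np.sqrt(df / tr_m2)
    b = df - a * tr_m
    return max(a * t_raw + b, 0.0), tr_m, tr_m2


def _test_statistics(resid, jac, w, gamma, n, n_params):
    n_pairs = len(resid)
    df = n_pairs - n_params
    Winv = 1.0 / w
    t_raw = n * float(np.sum(resid * resid * Winv))
    if df > 0:
        Wj = jac * Winv[:, None]
        U = np.diag(Winv) - Wj @ np.linalg.pinv(jac.T @ Wj) @ Wj.T
        T, tr_m, tr_m2 = _adjusted_statistic(t_raw, U @ gamma, df)
    else:
        df = max(df, 0)
        T, tr_m, tr_m2 = max(t_raw, 0.0), np.nan, np.nan
    return T, df, t_raw, tr_m, tr_m2


def baseline_statistics(stats: PolychoricResult):
    """Mean/variance-adjusted statistic of the zero-correlation baseline model."""
    s = stats.lower_triangle()
    n = stats.n
    gamma = stats.acov * n if stats.acov is not None else np.eye(len(s))
    w = np.maximum(np.diag(gamma).copy(), _W_FLOOR)
    df = len(s)
    t_raw = n * float(np.sum(s * s / w))
    T, tr_m, tr_m2 = _adjusted_statistic(t_raw, np.diag(1.0 / w) @ gamma, df)
    return T, df, t_raw, tr_m


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def fit_indices(T: float, df: int, baseline_T: float, baseline_df: int, n: int) -> FitIndices:
    """RMSEA (with 90% noncentrality CI), CFI and TLI from adjusted statistics."""
    if n <= 1:
        raise ValueError("sample size must exceed 1")
    if df <= 0:
        return FitIndices(T=T, df=max(df, 0), rmsea=0.0, rmsea_ci=(0.0, 0.0), cfi=1.0,
                          tli=1.0, baseline_T=baseline_T, baseline_df=baseline_df, n=n)
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * n)))
    rmsea_ci = _rmsea_ci(T, df, n)
    num = max(T - df, 0.0)
    denom = max(baseline_T - baseline_df, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    base_ratio = baseline_T / baseline_df
    tli = 1.0 if base_ratio <= 1.0 else (base_ratio - T / df) / (base_ratio - 1.0)
    tli = min(tli, 1.0)
    return FitIndices(
        T=T, df=df, rmsea=rmsea, rmsea_ci=rmsea_ci, cfi=cfi, tli=tli,
        baseline_T=baseline_T, baseline_df=baseline_df, n=n,
    )


def _rmsea_ci(T, df, n, level=0.90):
    lo_q = 0.5 + level / 2  # 0.95
    hi_q = 0.5 - level / 2  # 0.05

    def nc_for(q):
        # noncentrality lambda with ncx2.cdf(T, df, lambda) == q
        if chi2.cdf(T, df) < q:
            return 0.0
        hi = max(T, 1.0)
        while ncx2.cdf(T, df, hi) > q:
            hi *= 2
            if hi > 1e7:
                break
        return brentq(lambda nc: ncx2.cdf(T, df, nc) - q, 0.0, hi, xtol=1e-8)

    nc_lo = nc_for(lo_q)
    nc_hi = nc_for(hi_q)
    return (float(np.sqrt(nc_lo / (df * n))), float(np.sqrt(nc_hi / (df * n))))


# ---------------------------------------------------------------------------
# Modification indices
# ---------------------------------------------------------------------------

def modification_indices(solution: FactorSolution, stats: PolychoricResult):
    """Univariate score-test MI and EPC for every constrained parameter.

    Candidates are fixed loadings (confirmatory specs only) and absent
    residual correlations.  The MI >= 10 screening threshold is a caller
    decision, not applied here.
    """
    spec = solution.spec
    if not solution.converged:
        raise ValueError("modification indices require a converged solution")
    J = spec.n_items
    pairs = pair_order(J)
    pm = _ParamMap(spec)
    w = solution._w
    resid = solution._resid
    n = solution._n

    candidates = []
    if not spec.exploratory:
        for i in range(J):
            for k in range(spec.n_factors):
                if not spec.pattern[i, k]:
                    candidates.append(("loading", (i, k)))
    existing = set(spec.residual_pairs)
    for i in range(J):
        for j in range(i + 1, J):
            if (i, j) not in existing:
                candidates.append(("residual", (i, j)))

    H_base = 2.0 * (solution._jac.T @ (solution._jac / w[:, None]))
    H_inv = np.linalg.pinv(H_base)
    out = []
    for kind, index in candidates:
        col = _candidate_column(solution, pm, pairs, kind, index)
        g_j = 2.0 * float(col @ (resid / w))
        h_jj = 2.0 * float(col @ (col / w))
        h_js = 2.0 * (solution._jac.T @ (col / w))
        c_jj = h_jj - float(h_js @ H_inv @ h_js)
        if c_jj <= 1e-10:
            logger.debug("singular information for candidate %s %s; skipped", kind, index)
            continue
        mi = n * g_j * g_j / (2.0 * c_jj)
        epc = -g_j / c_jj
        label = _candidate_label(spec, kind, index)
        out.append(ModificationIndex(kind=kind, label=label, index=index, mi=mi, epc=epc))
    out.sort(key=lambda m: -m.mi)
    return out


def _candidate_column(solution, pm, pairs, kind, index):
    lam, phi = solution.loadings, solution.phi
    M = lam @ phi
    col = np.zeros(len(pairs))
    if kind == "loading":
        a, c = index
        for p, (i, j) in enumerate(pairs):
            v = 0.0
            if i == a:
                v += M[j, c]
            if j == a:
                v += M[i, c]
            col[p] = v
    else:
        a, b = index
        for p, (i, j) in enumerate(pairs):
            if (min(i, j), max(i, j)) == (a, b):
                col[p] = 1.0
    return col


def _candidate_label(spec, kind, index):
    if kind == "loading":
        return f"{spec.item_labels[index[0]]}~{spec.factor_labels[index[1]]}"
    return f"{spec.item_labels[index[0]]}~~{spec.item_labels[index[1]]}"


# ---------------------------------------------------------------------------
# Scaled difference testing
# ---------------------------------------------------------------------------

def scaled_difference_test(full: FitIndices, nested: FitIndices):
    """Satorra-Bentler style scaled chi-square difference between nested fits.

    ``nested`` is the more constrained model (larger df).  Uses each model's
    mean-scaling factor tr(M)/df; a negative scaled statistic is reported as
    0 with a warning flag (a known pathology of the correction).

    Returns (statistic, df, p, negative_flag).
    """
    d_df = nested.df - full.df
    if d_df < 0:
        raise ValueError("'nested' must have more degrees of freedom than 'full'")
    if d_df == 0:
        return 0.0, 0, 1.0, False
    c_nested = nested.trace_m / nested.df
    c_full = full.trace_m / full.df if full.df > 0 else c_nested
    cd = (nested.df * c_nested - full.df * c_full) / d_df
    negative = False
    if cd <= 0:
        negative = True
        cd = abs(cd) if cd != 0 else 1.0
    stat = (nested.t_raw - full.t_raw) / cd
    if stat < 0:
        negative = True
        stat = 0.0
    p = float(chi2.sf(stat, d_df))
    return float(stat), int(d_df), p, negative


# ---------------------------------------------------------------------------
# Exploratory-within-confirmatory fitting
# ---------------------------------------------------------------------------

def fit_exploratory(
    stats: PolychoricResult,
    n_factors: int,
    eps: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    target: np.ndarray | None = None,
    compute_rotated_se: bool = False,
):
    """Fit an exploratory block and geomin-rotate it.

    Returns (solution, fit) where the solution carries the rotated loadings
    and oblique factor correlations.  Rotated-solution standard errors, when
    requested, are numeric delta-method propagations of the unrotated
    sandwich covariance through the rotation and are flagged approximate.
    """
    spec = exploratory_spec(stats.n_items, n_factors, stats.item_labels)
    solution, fi = fit_model(spec, stats, max_iter=2000)
    rot = rotate_geomin(
        solution.loadings, eps=eps, n_starts=n_starts, seed=seed, target=target
    )
    L, phi = rot.loadings, rot.phi

    load_se = np.full_like(L, np.nan)
    phi_se = np.full_like(phi, np.nan)
    if compute_rotated_se:
        load_se, phi_se = _rotated_se(solution, spec, eps, L, phi)

    rotated = replace(
        solution,
        loadings=L,
        phi=phi,
        loadings_se=load_se,
        phi_se=phi_se,
        delta=1.0 - np.einsum("ik,kl,il->i", L, phi, L),
        se_approximate=compute_rotated_se,
        spec=spec.replace(pattern=np.ones_like(spec.pattern), factor_cov="orthogonal"),
    )
    return rotated, fi


def _rotated_se(solution, spec, eps, L_base, phi_base, h: float = 1e-5):
    """Numeric delta-method SEs for the rotated solution (approximate)."""
    pm = _ParamMap(spec)
    base_params = solution.params
    n_out = L_base.size + phi_base.size

    def rotated_vec(params):
        lam, _, _ = pm.unpack(params)
        rot = rotate_geomin(lam, eps=eps, n_starts=1, target=L_base)
        return np.concatenate([rot.loadings.ravel(), rot.phi.ravel()])

    jac = np.zeros((n_out, pm.n_params))
    for q in range(pm.n_params):
        up = base_params.copy()
        up[q] += h
        dn = base_params.copy()
        dn[q] -= h
        jac[:, q] = (rotated_vec(up) - rotated_vec(dn)) / (2 * h)
    cov = jac @ solution._param_cov @ jac.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    load_se = se[: L_base.size].reshape(L_base.shape)
    phi_se = se[L_base.size:].reshape(phi_base.shape)
    return load_se, phi_se
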