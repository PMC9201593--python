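"""Maximum-likelihood path (mediation) modelling of observed variables.

A recursive path model over observed variables x is parameterized by path
coefficients B (B[i, j] multiplies variable j in the equation of variable i)
and a disturbance covariance Psi (diagonal by default; exogenous variances
on the diagonal, mediator residual covariances optionally freed). The
model-implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T

and estimation minimizes the ML discrepancy

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - k

over the free parameters, with S the unbiased sample covariance. At the
optimum, chi^2 = (n - 1) F is asymptotically central chi-square under the
true model with df = k(k+1)/2 - (number of free parameters). Fit indices:
RMSEA = sqrt(max(0, (chi2 - df) / (df (n-1)))) and AIC = chi2 + 2 q (the
relative-fit convention; the full-likelihood variant -2 lnL + 2 q is also
reported). Standardized coefficients rescale paths by the model-implied
standard deviations and are invariant under positive rescaling of columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModelSpec",
    "SEMFit",
    "build_mediation_spec",
    "parse_path_spec",
    "fit_ml",
    "rmsea",
    "aic",
    "scaling_invariance",
]


@dataclass(frozen=True)
class PathModelSpec:
    """Observed-variable path model: variables and directed paths."""

    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]
    free_residual_cov: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        used = {v for p in self.paths for v in p}
        missing = set(self.variables) - used
        if missing:
            raise ValueError(f"variables appear in no path: {sorted(missing)}")
        for src, dst in self.paths:
            if src == dst:
                raise ValueError(f"self-loop {src}->{dst}")
            if src not in self.variables or dst not in self.variables:
                raise ValueError(f"path {src}->{dst} uses an unknown variable")
        self._topological_order()  # raises on cycles

    def _topological_order(self) -> list[str]:
        indeg = {v: 0 for v in self.variables}
        for _, dst in self.paths:
            indeg[dst] += 1
        queue = [v for v in self.variables if indeg[v] == 0]
        order = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for src, dst in self.paths:
                if src == v:
                    indeg[dst] -= 1
                    if indeg[dst] == 0:
                        queue.append(dst)
        if len(order) != len(self.variables):
            raise ValueError("path graph contains a cycle")
        return order

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if any(dst == v for _, dst in self.paths)]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.variables if v not in self.endogenous]


def build_mediation_spec(
    input_var: str, mediators: list[str], output_var: str, free_mediator_cov: bool = False
) -> PathModelSpec:
    """Mediation topology: input -> each mediator -> output, plus the direct
    input -> output path. One mediator gives 3 paths, two give 5."""
    names = [input_var, *mediators, output_var]
    if len(set(names)) != len(names):
        raise ValueError("variable names must be distinct")
    paths = [(input_var, m) for m in mediators]
    paths += [(m, output_var) for m in mediators]
    paths.append((input_var, output_var))
    free_cov = ()
    if free_mediator_cov and len(mediators) == 2:
        free_cov = ((mediators[0], mediators[1]),)
    return PathModelSpec(tuple(names), tuple(paths), free_cov)


def parse_path_spec(dsl: str) -> PathModelSpec:
    """Parse a path DSL like ``"tpdc -> coh; coh -> su; tpdc -> su"``."""
    paths = []
    variables: list[str] = []
    for clause in dsl.split(";"):
        clause = clause.strip()
        if not clause:
            continue
        parts = [p.strip() for p in clause.split("->")]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"cannot parse path clause {clause!r}")
        paths.append((parts[0], parts[1]))
        for v in parts:
            if v not in variables:
                variables.append(v)
    return PathModelSpec(tuple(variables), tuple(paths))


@dataclass
class SEMFit:
    """Fitted path model with fit indices."""

    spec: PathModelSpec
    coefficients: dict[tuple[str, str], float]
    standardized: dict[tuple[str, str], float]
    std_errors: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    variances: dict[str, float]
    residual_covariances: dict[tuple[str, str], float]
    chi2: float
    df: int
    n: int
    n_free: int
    rmsea: float
    aic: float
    aic_deviance: float
    converged: bool
    implied_cov: pd.DataFrame = field(repr=False, default=None)


def _unpack(theta: np.ndarray, spec: PathModelSpec, idx: dict[str, int]):
    k = len(spec.variables)
    b = np.zeros((k, k))
    n_paths = len(spec.paths)
    for p, (src, dst) in enumerate(spec.paths):
        b[idx[dst], idx[src]] = theta[p]
    psi = np.zeros((k, k))
    for v_i, v in enumerate(spec.variables):
        psi[v_i, v_i] = theta[n_paths + v_i]
    for c, (v1, v2) in enumerate(spec.free_residual_cov):
        val = theta[n_paths + k + c]
        psi[idx[v1], idx[v2]] = psi[idx[v2], idx[v1]] = val
    return b, psi


def _implied(theta: np.ndarray, spec: PathModelSpec, idx: dict[str, int]) -> np.ndarray:
    b, psi = _unpack(theta, spec, idx)
    inv = np.linalg.inv(np.eye(b.shape[0]) - b)
    return inv @ psi @ inv.T


def _discrepancy(theta, spec, idx, s, logdet_s):
    sigma = _implied(theta, spec, idx)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10
    return logdet + float(np.trace(s @ np.linalg.inv(sigma))) - logdet_s - s.shape[0]


def _numerical_hessian(fun, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    q = theta.size
    h = np.zeros((q, q))
    steps = eps * np.maximum(1.0, np.abs(theta))
    for a in range(q):
        for b_i in range(a, q):
            ea = np.zeros(q)
            eb = np.zeros(q)
            ea[a] = steps[a]
            eb[b_i] = steps[b_i]
            val = (
                fun(theta + ea + eb) - fun(theta + ea - eb) - fun(theta - ea + eb) + fun(theta - ea - eb)
            ) / (4 * steps[a] * steps[b_i])
            h[a, b_i] = h[b_i, a] = val
    return h


def fit_ml(spec: PathModelSpec, data: pd.DataFrame) -> SEMFit:
    """Fit the path model by maximum likelihood.

    Requires complete columns for every model variable and n greater than
    the number of free parameters. Raises on a singular sample covariance or
    non-convergence (reporting the final gradient norm).
    """
    cols = list(spec.variables)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    frame = data[cols]
    if frame.isna().any().any():
        raise ValueError("data columns must be complete (no missing values)")
    n = len(frame)
    k = len(cols)
    idx = {v: i for i, v in enumerate(cols)}
    n_free = len(spec.paths) + k + len(spec.free_residual_cov)
    if n <= n_free:
        raise ValueError(f"n={n} must exceed the {n_free} free parameters")
    s_orig = frame.cov().to_numpy()
    sign, _ = np.linalg.slogdet(s_orig)
    if sign <= 0:
        raise ValueError("singular sample covariance")
    # optimize on the correlation scale: the fit is invariant under positive
    # column rescaling, and unit variances keep the problem well conditioned
    scales = np.sqrt(np.diag(s_orig))
    frame = frame / scales
    s = s_orig / np.outer(scales, scales)
    _, logdet_s = np.linalg.slogdet(s)

    # start values: equation-by-equation OLS (the ML solution for recursive
    # models with uncorrelated disturbances)
    theta0 = np.zeros(n_free)
    x_mat = frame.to_numpy()
    for v in spec.endogenous:
        preds = [src for src, dst in spec.paths if dst == v]
        xmat = x_mat[:, [idx[p] for p in preds]]
        beta, *_ = np.linalg.lstsq(
            np.column_stack([xmat, np.ones(n)]), x_mat[:, idx[v]], rcond=None
        )
        resid = x_mat[:, idx[v]] - np.column_stack([xmat, np.ones(n)]) @ beta
        for p_i, src in enumerate(preds):
            theta0[spec.paths.index((src, v))] = beta[p_i]
        theta0[len(spec.paths) + idx[v]] = resid.var(ddof=1)
    for v in spec.exogenous:
        theta0[len(spec.paths) + idx[v]] = s[idx[v], idx[v]]

    fun = lambda th: _discrepancy(th, spec, idx, s, logdet_s)  # noqa: E731
    bounds = [(None, None)] * len(spec.paths)
    bounds += [(1e-8, None)] * k
    bounds += [(None, None)] * len(spec.free_residual_cov)
    res = optimize.minimize(fun, theta0, method="L-BFGS-B", bounds=bounds)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not res.success and grad_norm > 1e-3:
        raise RuntimeError(f"ML fit did not converge (max |gradient| = {grad_norm:.2e})")
    theta = res.x

    chi2 = max(0.0, float((n - 1) * res.fun))
    df = k * (k + 1) // 2 - n_free
    if df < 0:
        raise ValueError("negative degrees of freedom: model over-parameterized")

    hess = _numerical_hessian(fun, theta)
    try:
        acov = (2.0 / (n - 1)) * np.linalg.pinv(hess)
        ses = np.sqrt(np.clip(np.diag(acov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(n_free, np.nan)

    sigma = _implied(theta, spec, idx)
    sds = np.sqrt(np.diag(sigma))
    coefficients, standardized, std_errors, p_values = {}, {}, {}, {}
    for p, (src, dst) in enumerate(spec.paths):
        back = scales[idx[dst]] / scales[idx[src]]  # undo the column rescaling
        coefficients[(src, dst)] = float(theta[p] * back)
        standardized[(src, dst)] = float(theta[p] * sds[idx[src]] / sds[idx[dst]])
        std_errors[(src, dst)] = float(ses[p] * back)
        z = theta[p] / ses[p] if ses[p] > 0 else np.inf
        p_values[(src, dst)] = float(2 * stats.norm.sf(abs(z)))
    variances = {
        v: float(theta[len(spec.paths) + idx[v]] * scales[idx[v]] ** 2) for v in cols
    }
    residual_covariances = {
        (v1, v2): float(theta[len(spec.paths) + k + c] * scales[idx[v1]] * scales[idx[v2]])
        for c, (v1, v2) in enumerate(spec.free_residual_cov)
    }

    # full-likelihood AIC variant: -2 lnL with the ML (1/n) sample covariance,
    # shifted back to the original column scales
    s_ml = s * (n - 1) / n
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    neg2lnl = n * (k * np.log(2 * np.pi) + logdet_m + float(np.trace(s_ml @ np.linalg.inv(sigma))))
    neg2lnl += 2 * n * float(np.sum(np.log(scales)))
    sigma_orig = sigma * np.outer(scales, scales)
    fit = SEMFit(
        spec=spec,
        coefficients=coefficients,
        standardized=standardized,
        std_errors=std_errors,
        p_values=p_values,
        variances=variances,
        residual_covariances=residual_covariances,
        chi2=chi2,
        df=df,
        n=n,
        n_free=n_free,
        rmsea=rmsea(chi2, df, n),
        aic=chi2 + 2 * n_free,
        aic_deviance=float(neg2lnl + 2 * n_free),
        converged=bool(res.success),
        implied_cov=pd.DataFrame(sigma_orig, index=cols, columns=cols),
    )
    return fit


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation; 0 for a saturated model."""
    if df < 0 or n < 2:
        raise ValueError("need df >= 0 and n >= 2")
    if df == 0:
        return 0.0
    return float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1)))))


def aic(fit: SEMFit) -> float:
    """Relative-fit AIC: chi-square plus twice the free parameter count."""
    return fit.chi2 + 2 * fit.n_free


def scaling_invariance(
    spec: PathModelSpec, data: pd.DataFrame, n_draws: int = 3, seed: int = 0
) -> float:
    """Maximum absolute change of any standardized coefficient under random
    positive rescaling of the data columns. Should be ~0 for a well-posed
    model (the "invariant under constant scaling" check); values far from 0
    indicate a scale-dependent, untrustworthy solution."""
    rng = np.random.default_rng(seed)
    base = fit_ml(spec, data).standardized
    worst = 0.0
    for _ in range(n_draws):
        scales = rng.uniform(0.2, 5.0, size=len(spec.variables))
        scaled = data[list(spec.variables)] * scales
        alt = fit_ml(spec, scaled).standardized
        worst = max(worst, max(abs(alt[p] - base[p]) for p in base))
    return worst
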