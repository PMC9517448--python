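"""Maximum-likelihood estimation of linear covariance-structure models.

A model is a recursive path diagram over observed variables and latent
factors: each latent is measured by ordered indicators (the first is the
*marker*, its loading fixed to 1 to set the latent's scale), directed
regressions connect observed/latent variables, and selected pairs of
residuals may covary.  Collecting all directed coefficients in ``A`` and
all residual (co)variances in ``S``, the model-implied covariance of the
observed variables is

    Sigma(theta) = P (I - A)^-1 S (I - A)^-T P^T

with ``P`` the selection of observed rows.  Estimation minimizes the
normal-theory ML discrepancy

    F(theta) = ln|Sigma| + tr(S_n Sigma^-1) - ln|S_n| - p

over the free parameters, where ``S_n`` is the sample covariance;
``n * F`` at the optimum is the chi-square model-fit statistic.

Negative residual variances (Heywood cases) are admitted but flagged:
they signal identification or specification trouble, and standard SEM
software reports rather than constrains them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "FitResult",
    "ModelError",
    "parse_model",
    "render_model",
    "count_free_parameters",
    "model_df",
    "param_names",
    "implied_covariance",
    "ml_discrepancy",
    "fit",
    "standard_errors",
    "standardized_solution",
    "standardized_standard_errors",
]

#: convergence requires the inf-norm of the discrepancy gradient below this
GRADIENT_TOL = 1e-6

MAX_ITER = 1000


class ModelError(ValueError):
    """Invalid model specification or unusable input matrices."""


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative path model.

    observed: ordered observed-variable names (fixes the Sigma layout)
    latents: (factor name, ordered indicators); indicator[0] is the marker
    regressions: (outcome, predictor) directed edges
    residual_covariances: unordered residual pairs, stored sorted
    exogenous_free: estimate variances and pairwise covariances of
        exogenous observed variables freely (rather than fixing them to
        their sample values)
    """

    observed: tuple[str, ...]
    latents: tuple[tuple[str, tuple[str, ...]], ...] = ()
    regressions: tuple[tuple[str, str], ...] = ()
    residual_covariances: tuple[tuple[str, str], ...] = ()
    exogenous_free: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "residual_covariances",
            tuple(_pair(*p) for p in self.residual_covariances),
        )
        self._validate()

    # -- structure queries --------------------------------------------------

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.latents)

    @property
    def all_vars(self) -> tuple[str, ...]:
        return self.observed + self.latent_names

    @property
    def directed_edges(self) -> tuple[tuple[str, str], ...]:
        """(head, tail) pairs: loadings (indicator <- latent) then paths."""
        edges = []
        for latent, indicators in self.latents:
            for ind in indicators:
                edges.append((ind, latent))
        edges.extend(self.regressions)
        return tuple(edges)

    @property
    def endogenous(self) -> tuple[str, ...]:
        heads = {h for h, _ in self.directed_edges}
        return tuple(v for v in self.all_vars if v in heads)

    @property
    def exogenous_observed(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.observed if v not in endo)

    def _validate(self) -> None:
        seen: set[str] = set()
        for v in self.observed:
            if v in seen:
                raise ModelError(f"duplicate variable name {v!r}")
            seen.add(v)
        for latent, indicators in self.latents:
            if latent in seen:
                raise ModelError(f"duplicate variable name {latent!r}")
            seen.add(latent)
            if len(indicators) < 2:
                raise ModelError(
                    f"latent {latent!r} has {len(indicators)} indicator(s); "
                    "at least 2 are required for identification"
                )
            for ind in indicators:
                if ind not in self.observed:
                    raise ModelError(
                        f"indicator {ind!r} of latent {latent!r} is not an "
                        "observed variable"
                    )
            if len(set(indicators)) != len(indicators):
                raise ModelError(f"latent {latent!r} repeats an indicator")
        names = set(self.all_vars)
        seen_edges: set[tuple[str, str]] = set()
        for outcome, predictor in self.regressions:
            for v in (outcome, predictor):
                if v not in names:
                    raise ModelError(f"regression references unknown name {v!r}")
            if (outcome, predictor) in seen_edges:
                raise ModelError(
                    f"duplicate regression {outcome!r} ~ {predictor!r}"
                )
            seen_edges.add((outcome, predictor))
        seen_pairs: set[tuple[str, str]] = set()
        for a, b in self.residual_covariances:
            for v in (a, b):
                if v not in names:
                    raise ModelError(f"residual covariance references {v!r}")
            if a == b:
                raise ModelError(f"residual covariance of {a!r} with itself")
            if (a, b) in seen_pairs:
                raise ModelError(f"duplicate residual covariance {a!r} ~~ {b!r}")
            seen_pairs.add((a, b))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over the directed-edge graph
        succ: dict[str, list[str]] = {v: [] for v in self.all_vars}
        indeg = {v: 0 for v in self.all_vars}
        for head, tail in self.directed_edges:
            succ[tail].append(head)
            indeg[head] += 1
        queue = [v for v, d in indeg.items() if d == 0]
        removed = 0
        while queue:
            v = queue.pop()
            removed += 1
            for w in succ[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if removed != len(self.all_vars):
            cyc = sorted(v for v, d in indeg.items() if d > 0)
            raise ModelError(f"structural graph contains a cycle among {cyc}")


def parse_model(text: str) -> ModelSpec:
    """Parse the plain-text model mini-syntax.

    One statement per line: ``F =~ a + b + c`` defines a latent with
    marker ``a``; ``y ~ x1 + x2`` defines regressions; ``a ~~ b`` a
    residual covariance; ``#`` starts a comment.  Observed-variable order
    is order of first appearance.
    """
    observed: list[str] = []
    latents: list[tuple[str, tuple[str, ...]]] = []
    regressions: list[tuple[str, str]] = []
    covariances: list[tuple[str, str]] = []
    latent_names: set[str] = set()

    def note_observed(name: str) -> None:
        if name not in latent_names and name not in observed:
            observed.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = (s.strip() for s in line.split(op, 1))
                break
        else:
            raise ModelError(f"line {lineno}: no operator in {raw.strip()!r}")
        if not lhs or not rhs:
            raise ModelError(f"line {lineno}: incomplete statement {raw.strip()!r}")
        rhs_names = [s.strip() for s in rhs.split("+")]
        if any(not s or " " in s for s in [lhs] + rhs_names):
            raise ModelError(f"line {lineno}: malformed name in {raw.strip()!r}")
        if op == "=~":
            if lhs in latent_names:
                raise ModelError(f"line {lineno}: latent {lhs!r} defined twice")
            if lhs in observed:
                raise ModelError(
                    f"line {lineno}: {lhs!r} already used as an observed variable"
                )
            latent_names.add(lhs)
            latents.append((lhs, tuple(rhs_names)))
            for name in rhs_names:
                note_observed(name)
        elif op == "~~":
            if len(rhs_names) != 1:
                raise ModelError(f"line {lineno}: '~~' takes exactly one pair")
            note_observed(lhs)
            note_observed(rhs_names[0])
            covariances.append(_pair(lhs, rhs_names[0]))
        else:
            note_observed(lhs)
            for name in rhs_names:
                note_observed(name)
                regressions.append((lhs, name))
    try:
        return ModelSpec(
            observed=tuple(observed),
            latents=tuple(latents),
            regressions=tuple(regressions),
            residual_covariances=tuple(covariances),
        )
    except ModelError as exc:
        raise ModelError(f"model text invalid: {exc}") from exc


def render_model(spec: ModelSpec) -> str:
    """Serialize a spec back to the mini-syntax (inverse of parse for
    specs whose observed order follows statement order)."""
    lines = []
    for latent, indicators in spec.latents:
        lines.append(f"{latent} =~ " + " + ".join(indicators))
    by_outcome: dict[str, list[str]] = {}
    for outcome, predictor in spec.regressions:
        by_outcome.setdefault(outcome, []).append(predictor)
    for outcome, preds in by_outcome.items():
        lines.append(f"{outcome} ~ " + " + ".join(preds))
    for a, b in spec.residual_covariances:
        lines.append(f"{a} ~~ {b}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

ParamKey = tuple[str, ...]  # ("loading", latent, ind) | ("path", out, pred)
#                             | ("var", name) | ("cov", a, b)


def param_names(spec: ModelSpec) -> list[ParamKey]:
    """Ordered free-parameter keys; defines the flat-vector layout."""
    keys: list[ParamKey] = []
    for latent, indicators in spec.latents:
        for ind in indicators[1:]:  # marker loading fixed to 1
            keys.append(("loading", latent, ind))
    for outcome, predictor in spec.regressions:
        keys.append(("path", outcome, predictor))
    for a, b in spec.residual_covariances:
        keys.append(("cov", a, b))
    exo = set(spec.exogenous_observed) if not spec.exogenous_free else set()
    for v in spec.all_vars:
        if v not in exo:
            keys.append(("var", v))
    if spec.exogenous_free:
        exo_obs = spec.exogenous_observed
        for i in range(len(exo_obs)):
            for j in range(i + 1, len(exo_obs)):
                keys.append(("cov", *_pair(exo_obs[i], exo_obs[j])))
    return keys


def count_free_parameters(spec: ModelSpec) -> int:
    return len(param_names(spec))


def model_df(spec: ModelSpec) -> int:
    """Degrees of freedom: distinct sample moments minus free parameters.
    Negative values flag an unidentified model."""
    p = len(spec.observed)
    return p * (p + 1) // 2 - count_free_parameters(spec)


@dataclass
class ParameterSet:
    """Loadings, paths and residual (co)variances, bijective with the
    flat optimization vector for a given spec (fixed marker loadings are
    not stored)."""

    loadings: dict[tuple[str, str], float] = field(default_factory=dict)
    paths: dict[tuple[str, str], float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    covariances: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, key: ParamKey) -> float:
        kind = key[0]
        if kind == "loading":
            return self.loadings[(key[1], key[2])]
        if kind == "path":
            return self.paths[(key[1], key[2])]
        if kind == "var":
            return self.variances[key[1]]
        if kind == "cov":
            return self.covariances[_pair(key[1], key[2])]
        raise KeyError(key)

    def set(self, key: ParamKey, value: float) -> None:
        kind = key[0]
        if kind == "loading":
            self.loadings[(key[1], key[2])] = value
        elif kind == "path":
            self.paths[(key[1], key[2])] = value
        elif kind == "var":
            self.variances[key[1]] = value
        elif kind == "cov":
            self.covariances[_pair(key[1], key[2])] = value
        else:
            raise KeyError(key)

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        return np.array([self.get(k) for k in param_names(spec)], dtype=float)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vector: np.ndarray) -> "ParameterSet":
        keys = param_names(spec)
        if len(vector) != len(keys):
            raise ModelError(
                f"vector length {len(vector)} != {len(keys)} free parameters"
            )
        ps = cls()
        for key, value in zip(keys, vector):
            ps.set(key, float(value))
        return ps

    def as_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (l, i), v in self.loadings.items():
            out[f"{l} =~ {i}"] = v
        for (o, p), v in self.paths.items():
            out[f"{o} ~ {p}"] = v
        for name, v in self.variances.items():
            out[f"var({name})"] = v
        for (a, b), v in self.covariances.items():
            out[f"{a} ~~ {b}"] = v
        return out


def format_param(key: ParamKey) -> str:
    kind = key[0]
    if kind == "loading":
        return f"{key[1]} =~ {key[2]}"
    if kind == "path":
        return f"{key[1]} ~ {key[2]}"
    if kind == "var":
        return f"var({key[1]})"
    return f"{key[1]} ~~ {key[2]}"


# --------------------------------------------------------------------------
# implied covariance and discrepancy
# --------------------------------------------------------------------------


def _build_matrices(
    spec: ModelSpec, params: ParameterSet, marker_fixed: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Directed-coefficient matrix A and residual-structure matrix S over
    all (observed + latent) variables.  With ``marker_fixed`` the first
    indicator's loading is pinned to 1; otherwise it is read from
    ``params`` (used for fully standardized parameterizations)."""
    t = len(spec.all_vars)
    idx = {v: i for i, v in enumerate(spec.all_vars)}
    A = np.zeros((t, t))
    S = np.zeros((t, t))
    for latent, indicators in spec.latents:
        if marker_fixed:
            A[idx[indicators[0]], idx[latent]] = 1.0
        else:
            A[idx[indicators[0]], idx[latent]] = params.loadings[
                (latent, indicators[0])
            ]
        for ind in indicators[1:]:
            A[idx[ind], idx[latent]] = params.loadings[(latent, ind)]
    for outcome, predictor in spec.regressions:
        A[idx[outcome], idx[predictor]] = params.paths[(outcome, predictor)]
    for v in spec.all_vars:
        S[idx[v], idx[v]] = params.variances[v]
    for (a, b), value in params.covariances.items():
        S[idx[a], idx[b]] = S[idx[b], idx[a]] = value
    return A, S


def implied_covariance(
    spec: ModelSpec, params: ParameterSet, marker_fixed: bool = True
) -> np.ndarray:
    """Model-implied covariance of the observed variables."""
    A, S = _build_matrices(spec, params, marker_fixed=marker_fixed)
    t = A.shape[0]
    try:
        B = linalg.solve(np.eye(t) - A, np.eye(t))
    except linalg.LinAlgError as exc:  # pragma: no cover - acyclicity prevents it
        raise ModelError("I - A is singular (cyclic or degenerate model)") from exc
    V = B @ S @ B.T
    p = len(spec.observed)
    sigma = V[:p, :p]
    return (sigma + sigma.T) / 2.0


def _logdet_chol(M: np.ndarray) -> tuple[float, np.ndarray]:
    """(log-determinant, Cholesky factor); raises ModelError if not PD."""
    try:
        c = linalg.cholesky(M, lower=True)
    except linalg.LinAlgError as exc:
        raise ModelError("matrix is not positive-definite") from exc
    return 2.0 * float(np.sum(np.log(np.diag(c)))), c


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory discrepancy ln|Sigma| + tr(S Sigma^-1) - ln|S| - p.

    Zero iff Sigma equals S; ``n * F`` is the chi-square statistic.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ModelError("S and Sigma must be square matrices of equal size")
    p = S.shape[0]
    logdet_s, _ = _logdet_chol(S)
    logdet_sig, c = _logdet_chol(Sigma)
    trace = float(np.trace(linalg.cho_solve((c, True), S)))
    return logdet_sig + trace - logdet_s - p


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged (or best-effort) ML solution for one model and sample."""

    spec: ModelSpec
    estimates: ParameterSet
    standard_errors: dict[ParamKey, float]
    z_values: dict[ParamKey, float]
    p_values: dict[ParamKey, float]
    standardized: ParameterSet
    discrepancy: float
    n: int
    df: int
    converged: bool
    iterations: int
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    acov: np.ndarray  # asymptotic covariance of the free-parameter vector
    heywood: list[str] = field(default_factory=list)

    @property
    def chi_square(self) -> float:
        return self.n * self.discrepancy

    def to_dict(self) -> dict:
        keys = param_names(self.spec)
        return {
            "observed": list(self.spec.observed),
            "df": self.df,
            "n": self.n,
            "discrepancy": self.discrepancy,
            "chi_square": self.chi_square,
            "converged": self.converged,
            "iterations": self.iterations,
            "heywood": self.heywood,
            "parameters": [
                {
                    "name": format_param(k),
                    "estimate": self.estimates.get(k),
                    "se": self.standard_errors.get(k, float("nan")),
                    "z": self.z_values.get(k, float("nan")),
                    "p": self.p_values.get(k, float("nan")),
                    "standardized": self.standardized.get(k),
                }
                for k in keys
            ],
        }


def _start_values(spec: ModelSpec, S: np.ndarray) -> ParameterSet:
    """Deterministic starting point: loadings from the reference-variable
    regression cov(indicator, marker)/var(marker) (sign-correct for
    negatively loading indicators), paths 0, residual variances at half
    the sample variances (marker's for latents), exogenous moments at
    their sample values."""
    obs_idx = {v: i for i, v in enumerate(spec.observed)}
    ps = ParameterSet()
    for latent, indicators in spec.latents:
        m = obs_idx[indicators[0]]
        for ind in indicators[1:]:
            ps.loadings[(latent, ind)] = float(S[obs_idx[ind], m] / S[m, m])
    for outcome, predictor in spec.regressions:
        ps.paths[(outcome, predictor)] = 0.0
    exo = set(spec.exogenous_observed)
    for v in spec.all_vars:
        if v in obs_idx:
            sv = float(S[obs_idx[v], obs_idx[v]])
            ps.variances[v] = sv if v in exo else 0.5 * sv
        else:
            marker = dict(spec.latents)[v][0]
            ps.variances[v] = 0.5 * float(S[obs_idx[marker], obs_idx[marker]])
    for a, b in spec.residual_covariances:
        ps.covariances[_pair(a, b)] = 0.0
    if spec.exogenous_free:
        exo_obs = spec.exogenous_observed
        for i in range(len(exo_obs)):
            for j in range(i + 1, len(exo_obs)):
                a, b = exo_obs[i], exo_obs[j]
                ps.covariances[_pair(a, b)] = float(S[obs_idx[a], obs_idx[b]])
    return ps


def _discrepancy_and_grad(
    theta: np.ndarray,
    spec: ModelSpec,
    S: np.ndarray,
    keys: list[ParamKey],
    theta0: np.ndarray,
) -> tuple[float, np.ndarray]:
    """F(theta) and its analytic gradient; a smooth pull-back penalty is
    returned where Sigma(theta) leaves the positive-definite cone."""
    params = ParameterSet.from_vector(spec, theta)
    if not spec.exogenous_free:
        _fill_exogenous_from_sample(spec, params, S)
    A, Smat = _build_matrices(spec, params)
    t = A.shape[0]
    p = len(spec.observed)
    B = linalg.solve(np.eye(t) - A, np.eye(t))
    V = B @ Smat @ B.T
    Sigma = (V[:p, :p] + V[:p, :p].T) / 2.0
    try:
        _, c = _logdet_chol(Sigma)
    except ModelError:
        diff = theta - theta0
        return 1e10 + float(diff @ diff), 2.0 * diff
    logdet_sig = 2.0 * float(np.sum(np.log(np.diag(c))))
    sign_s, logdet_s = np.linalg.slogdet(S)
    sigma_inv = linalg.cho_solve((c, True), np.eye(p))
    F = logdet_sig + float(np.sum(sigma_inv * S)) - logdet_s - p
    # dF = tr(W dSigma), W = Sigma^-1 - Sigma^-1 S Sigma^-1
    W = sigma_inv - sigma_inv @ S @ sigma_inv
    G = np.zeros((t, t))
    G[:p, :p] = W
    M = B.T @ G @ B        # gradient wrt S entries
    H = V @ G @ B          # gradient wrt A entries: 2 * H[tail, head]^T
    idx = {v: i for i, v in enumerate(spec.all_vars)}
    grad = np.empty(len(keys))
    for k, key in enumerate(keys):
        kind = key[0]
        if kind == "loading":
            i, j = idx[key[2]], idx[key[1]]
            grad[k] = 2.0 * H[j, i]
        elif kind == "path":
            i, j = idx[key[1]], idx[key[2]]
            grad[k] = 2.0 * H[j, i]
        elif kind == "var":
            i = idx[key[1]]
            grad[k] = M[i, i]
        else:  # cov
            i, j = idx[key[1]], idx[key[2]]
            grad[k] = 2.0 * M[i, j]
    return F, grad


def _sigma_derivatives(
    spec: ModelSpec, params: ParameterSet, keys: list[ParamKey]
) -> list[np.ndarray]:
    """dSigma/dtheta_k for each free parameter (observed block)."""
    A, Smat = _build_matrices(spec, params)
    t = A.shape[0]
    p = len(spec.observed)
    B = linalg.solve(np.eye(t) - A, np.eye(t))
    V = B @ Smat @ B.T
    idx = {v: i for i, v in enumerate(spec.all_vars)}
    derivs = []
    for key in keys:
        kind = key[0]
        if kind in ("loading", "path"):
            if kind == "loading":
                i, j = idx[key[2]], idx[key[1]]  # A[indicator, latent]
            else:
                i, j = idx[key[1]], idx[key[2]]  # A[outcome, predictor]
            T1 = np.outer(B[:, i], V[j, :])  # B E_ij V
            dV = T1 + T1.T
        elif kind == "var":
            i = idx[key[1]]
            dV = np.outer(B[:, i], B[:, i])
        else:
            i, j = idx[key[1]], idx[key[2]]
            T1 = np.outer(B[:, i], B[:, j])
            dV = T1 + T1.T
        derivs.append(dV[:p, :p])
    return derivs


def _fill_exogenous_from_sample(
    spec: ModelSpec, params: ParameterSet, S: np.ndarray
) -> None:
    """With exogenous_free=False the exogenous observed moments are not
    free parameters; pin them to their sample values."""
    obs_idx = {v: i for i, v in enumerate(spec.observed)}
    exo = spec.exogenous_observed
    for v in exo:
        params.variances[v] = float(S[obs_idx[v], obs_idx[v]])
    for i in range(len(exo)):
        for j in range(i + 1, len(exo)):
            a, b = exo[i], exo[j]
            params.covariances[_pair(a, b)] = float(S[obs_idx[a], obs_idx[b]])


def _as_sample_cov(
    data, spec: ModelSpec, cov, n, names
) -> tuple[np.ndarray, int]:
    if cov is not None:
        if n is None:
            raise ModelError("n must be given alongside a covariance matrix")
        S = np.asarray(cov, dtype=float)
        if names is not None:
            order = [list(names).index(v) for v in spec.observed]
            S = S[np.ix_(order, order)]
        return S, int(n)
    if data is None:
        raise ModelError("provide data or (cov, n)")
    if isinstance(data, pd.DataFrame):
        missing = [v for v in spec.observed if v not in data.columns]
        if missing:
            raise ModelError(f"data lacks model variables {missing}")
        X = data[list(spec.observed)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if names is not None:
            order = [list(names).index(v) for v in spec.observed]
            X = X[:, order]
        elif X.shape[1] != len(spec.observed):
            raise ModelError(
                f"data has {X.shape[1]} columns for {len(spec.observed)} "
                "observed variables and no names were given"
            )
    if np.isnan(X).any():
        raise ModelError("missing cells in the data matrix are not supported")
    n_obs = X.shape[0]
    return np.cov(X, rowvar=False, ddof=1), n_obs


def fit(
    spec: ModelSpec,
    data=None,
    *,
    cov: np.ndarray | None = None,
    n: int | None = None,
    names: Sequence[str] | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Estimate a model by minimizing the ML discrepancy.

    ``data`` is an n x p matrix or DataFrame over the model's observed
    variables; alternatively pass a sample covariance ``cov`` with its
    ``n``.  Optimization is quasi-Newton with analytic gradients from a
    deterministic starting point; a solution is flagged converged when
    the gradient inf-norm falls below ``GRADIENT_TOL``.
    """
    df = model_df(spec)
    if df < 0:
        raise ModelError(
            f"model has negative degrees of freedom ({df}): unidentified"
        )
    S, n_obs = _as_sample_cov(data, spec, cov, n, names)
    _logdet_chol(S)  # sample covariance must be PD
    p = len(spec.observed)
    if n_obs <= p:
        warnings.warn(
            f"sample size {n_obs} does not exceed the number of observed "
            f"variables {p}; estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )
    keys = param_names(spec)
    theta0 = _start_values(spec, S).to_vector(spec)

    res = optimize.minimize(
        _discrepancy_and_grad,
        theta0,
        args=(spec, S, keys, theta0),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": MAX_ITER},
    )
    iterations = int(res.nit)
    theta = res.x
    f_val, grad = _discrepancy_and_grad(theta, spec, S, keys, theta0)
    if np.max(np.abs(grad)) >= GRADIENT_TOL:
        # polish: limited-memory quasi-Newton handles the ill-conditioned
        # near-Heywood valleys where full BFGS stalls
        res2 = optimize.minimize(
            _discrepancy_and_grad,
            theta,
            args=(spec, S, keys, theta0),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-12},
        )
        iterations += int(res2.nit)
        f2, g2 = _discrepancy_and_grad(res2.x, spec, S, keys, theta0)
        if f2 <= f_val:
            theta, f_val, grad = res2.x, f2, g2
    if np.max(np.abs(grad)) >= GRADIENT_TOL:
        # last resort: simplex walk out of a flat spot, then BFGS again
        res3 = optimize.minimize(
            lambda th: _discrepancy_and_grad(th, spec, S, keys, theta0)[0],
            theta,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-12, "fatol": 1e-14},
        )
        res4 = optimize.minimize(
            _discrepancy_and_grad,
            res3.x,
            args=(spec, S, keys, theta0),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": MAX_ITER},
        )
        iterations += int(res3.nit) + int(res4.nit)
        f2, g2 = _discrepancy_and_grad(res4.x, spec, S, keys, theta0)
        if f2 <= f_val:
            theta, f_val, grad = res4.x, f2, g2
    converged = bool(np.max(np.abs(grad)) < GRADIENT_TOL and f_val < 1e9)

    estimates = ParameterSet.from_vector(spec, theta)
    if not spec.exogenous_free:
        _fill_exogenous_from_sample(spec, estimates, S)
    Sigma = implied_covariance(spec, estimates)
    discrepancy = max(float(f_val), 0.0)
    heywood = [v for v, val in estimates.variances.items() if val < 0]

    ses: dict[ParamKey, float] = {}
    zs: dict[ParamKey, float] = {}
    pvals: dict[ParamKey, float] = {}
    acov = np.full((len(keys), len(keys)), np.nan)
    if compute_se and converged:
        acov, ses, zs, pvals = _se_from_information(
            spec, estimates, keys, Sigma, n_obs
        )

    try:
        standardized = standardized_parameters(spec, estimates)
    except ModelError:
        standardized = ParameterSet()  # degenerate solution: no std. metric
        for key in keys:
            standardized.set(key, float("nan"))
        for v in spec.all_vars:
            standardized.variances.setdefault(v, float("nan"))
    return FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        z_values=zs,
        p_values=pvals,
        standardized=standardized,
        discrepancy=discrepancy,
        n=n_obs,
        df=df,
        converged=converged,
        iterations=iterations,
        sample_cov=S,
        implied_cov=Sigma,
        acov=acov,
        heywood=heywood,
    )


def expected_information(
    spec: ModelSpec, params: ParameterSet, n: int
) -> np.ndarray:
    """Expected (Fisher) information of n*F/2 at ``params``:
    I_jk = (n/2) tr(Sigma^-1 dSigma_j Sigma^-1 dSigma_k)."""
    keys = param_names(spec)
    Sigma = implied_covariance(spec, params)
    _, c = _logdet_chol(Sigma)
    sigma_inv = linalg.cho_solve((c, True), np.eye(Sigma.shape[0]))
    derivs = _sigma_derivatives(spec, params, keys)
    q = len(keys)
    left = [sigma_inv @ d for d in derivs]
    info = np.empty((q, q))
    for j in range(q):
        for k in range(j, q):
            val = (n / 2.0) * float(np.sum(left[j] * left[k].T))
            info[j, k] = info[k, j] = val
    return info


def _se_from_information(spec, estimates, keys, Sigma, n_obs):
    info = expected_information(spec, estimates, n_obs)
    ses: dict[ParamKey, float] = {}
    zs: dict[ParamKey, float] = {}
    pvals: dict[ParamKey, float] = {}
    try:
        acov = linalg.inv(info)
        diag = np.diag(acov)
        if np.any(diag < -1e-8):
            raise linalg.LinAlgError("negative variance estimate")
        for k, key in enumerate(keys):
            se = math.sqrt(max(diag[k], 0.0))
            ses[key] = se
            est = estimates.get(key)
            z = est / se if se > 0 else float("nan")
            zs[key] = z
            pvals[key] = 2.0 * stats.norm.sf(abs(z)) if se > 0 else float("nan")
    except linalg.LinAlgError:
        warnings.warn(
            "information matrix is singular; standard errors undefined",
            UserWarning,
            stacklevel=2,
        )
        acov = np.full((len(keys), len(keys)), np.nan)
        for key in keys:
            ses[key] = float("nan")
            zs[key] = float("nan")
            pvals[key] = float("nan")
    return acov, ses, zs, pvals


def standard_errors(result: FitResult) -> dict[ParamKey, float]:
    """SEs from the inverse expected information at the optimum."""
    if not result.converged:
        raise ModelError("standard errors require a converged solution")
    return dict(result.standard_errors)


# --------------------------------------------------------------------------
# standardized solution
# --------------------------------------------------------------------------


def standardized_parameters(spec: ModelSpec, params: ParameterSet) -> ParameterSet:
    """Rescale every coefficient to the unit-variance metric of the
    implied covariance (latent variances 1); marker loadings become free
    standardized values."""
    A, Smat = _build_matrices(spec, params)
    t = A.shape[0]
    B = linalg.solve(np.eye(t) - A, np.eye(t))
    V = B @ Smat @ B.T
    idx = {v: i for i, v in enumerate(spec.all_vars)}
    sd = np.sqrt(np.diag(V))
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        bad = [v for v in spec.all_vars if not (V[idx[v], idx[v]] > 0)]
        raise ModelError(f"zero or negative implied variance for {bad}")
    out = ParameterSet()
    for latent, indicators in spec.latents:
        for ind in indicators:  # marker included: standardized value is free
            raw = 1.0 if ind == indicators[0] else params.loadings[(latent, ind)]
            out.loadings[(latent, ind)] = raw * sd[idx[latent]] / sd[idx[ind]]
    for outcome, predictor in spec.regressions:
        out.paths[(outcome, predictor)] = (
            params.paths[(outcome, predictor)]
            * sd[idx[predictor]]
            / sd[idx[outcome]]
        )
    for v in spec.all_vars:
        out.variances[v] = params.variances[v] / (sd[idx[v]] ** 2)
    for (a, b), value in params.covariances.items():
        out.covariances[(a, b)] = value / (sd[idx[a]] * sd[idx[b]])
    return out


def standardized_solution(result: FitResult) -> ParameterSet:
    """Standardized estimates of a fitted model (all variables unit
    variance under the implied covariance)."""
    return standardized_parameters(result.spec, result.estimates)


def standardized_standard_errors(
    result: FitResult, step: float = 1e-6
) -> dict[ParamKey, float]:
    """Delta-method SEs of the standardized free parameters.

    The standardized solution is a smooth function of the free vector;
    its Jacobian is taken by central differences and propagated through
    the asymptotic covariance of the estimates.
    """
    if not result.converged or not np.all(np.isfinite(result.acov)):
        raise ModelError("standardized SEs require a converged solution with SEs")
    spec = result.spec
    keys = param_names(spec)
    theta = result.estimates.to_vector(spec)

    def std_vec(th: np.ndarray) -> np.ndarray:
        ps = standardized_parameters(spec, ParameterSet.from_vector(spec, th))
        return np.array([ps.get(k) for k in keys])

    q = len(keys)
    J = np.empty((q, q))
    for j in range(q):
        h = step * max(1.0, abs(theta[j]))
        e = np.zeros(q)
        e[j] = h
        J[:, j] = (std_vec(theta + e) - std_vec(theta - e)) / (2 * h)
    cov_std = J @ result.acov @ J.T
    return {
        key: math.sqrt(max(cov_std[k, k], 0.0)) for k, key in enumerate(keys)
    }
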