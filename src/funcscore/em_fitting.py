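"""Maximum-likelihood estimation of the latent-class model via EM.

The observed-data likelihood is a two-component mixture: for each row the
marginal density is ``pi * f1(y) + (1 - pi) * f0(y)`` with the factorized
class-conditional densities of :mod:`funcscore.annotation_model`.  The E-step
computes responsibilities (posterior class-1 probabilities under the current
parameters); the M-step has closed-form weighted-moment updates because the
emissions are Normal and Bernoulli.

Missing continuous values are handled by one of three policies:

* ``marginalize`` — missing cells drop out of the per-row product (the
  statistically clean choice under conditional independence);
* ``impute_neutral_zero`` — missing conservation scores are replaced by the
  neutral value 0 before fitting;
* ``complete_case`` — rows with any missing cell are removed before fitting.

Mixture components are exchangeable, so after fitting the functional class is
anchored as the one with the higher mean conservation signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .annotation_model import (
    BERNOULLI_CLAMP,
    VARIANCE_FLOOR,
    AnnotationMatrix,
    AnnotationSchema,
    ModelError,
    ModelParameters,
    class_log_densities,
    _posterior_from_log_densities,
)

MissingPolicy = Literal["marginalize", "impute_neutral_zero", "complete_case"]
InitStrategy = Literal["quantile_split", "random_responsibilities"]


@dataclass(frozen=True)
class EMConfig:
    max_iterations: int = 1000
    tolerance: float = 1e-8          # relative log-likelihood change
    n_restarts: int = 1
    seed: int = 0
    init_strategy: InitStrategy = "quantile_split"
    missing_policy: MissingPolicy = "marginalize"
    variance_floor: float = VARIANCE_FLOOR
    bernoulli_clamp: float = BERNOULLI_CLAMP

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ModelError("max_iterations must be >= 1")
        if not self.tolerance > 0:
            raise ModelError("tolerance must be positive")
        if self.n_restarts < 1:
            raise ModelError("n_restarts must be >= 1")
        if not (0.0 < self.bernoulli_clamp < 0.5):
            raise ModelError("bernoulli_clamp must lie in (0, 0.5)")
        if not self.variance_floor > 0:
            raise ModelError("variance_floor must be positive")


@dataclass
class EMResult:
    params: ModelParameters
    responsibilities: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int
    seed_used: int
    restart_index_selected: int
    config: EMConfig
    #: original row indices the fit used (differs from range(n) only under complete_case)
    row_indices: np.ndarray | None = None
    anchored_swap: bool = field(default=False)

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def metadata_text(self) -> str:
        """Plain-text run-metadata block written beside the parameter file."""
        lines = [
            "# funcscore EM run metadata",
            f"seed\t{self.seed_used}",
            f"restart_selected\t{self.restart_index_selected}",
            f"converged\t{self.converged}",
            f"n_iterations\t{self.n_iterations}",
            f"final_loglik\t{self.final_loglik!r}",
            f"anchored_swap\t{self.anchored_swap}",
            f"init_strategy\t{self.config.init_strategy}",
            f"missing_policy\t{self.config.missing_policy}",
            f"tolerance\t{self.config.tolerance!r}",
            f"max_iterations\t{self.config.max_iterations}",
            f"n_restarts\t{self.config.n_restarts}",
            "loglik_trace\t" + ",".join(repr(float(v)) for v in self.loglik_trace),
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize(matrix: AnnotationMatrix, schema: AnnotationSchema,
               config: EMConfig, seed: int | None = None) -> ModelParameters:
    """Deterministic starting parameters.

    ``quantile_split`` ranks rows by the mean of their standardized observed
    continuous values (conservation carries the strongest class signal) and
    seeds class 1 from the top 40%.  ``random_responsibilities`` draws soft
    weights uniform on (0.25, 0.75) and takes one M-step.
    """
    if matrix.n_rows < 10:
        raise ModelError("need at least 10 rows to initialize moment estimates")
    seed = config.seed if seed is None else seed
    if config.init_strategy == "random_responsibilities":
        rng = np.random.default_rng(seed)
        resp = rng.uniform(0.25, 0.75, size=matrix.n_rows)
        return m_step(matrix, resp, config=config)
    if config.init_strategy != "quantile_split":
        raise ModelError(f"unknown init strategy {config.init_strategy!r}")

    ci = schema.continuous_indices
    n = matrix.n_rows
    if ci.size:
        x = matrix.values[:, ci]
        obs = matrix.mask[:, ci]
        col_mean = np.array([x[obs[:, j], j].mean() if obs[:, j].any() else 0.0
                             for j in range(ci.size)])
        col_sd = np.array([x[obs[:, j], j].std() if obs[:, j].any() else 1.0
                           for j in range(ci.size)])
        col_sd = np.maximum(col_sd, config.variance_floor)
        z = np.where(obs, (x - col_mean) / col_sd, 0.0)
        denom = np.maximum(obs.sum(axis=1), 1)
        score = z.sum(axis=1) / denom
    else:
        # no continuous columns: rank by total binary signal instead
        score = matrix.values[:, schema.binary_indices].sum(axis=1)
    order = np.argsort(score, kind="stable")
    n_top = max(1, int(round(0.4 * n)))
    resp = np.zeros(n)
    resp[order[n - n_top:]] = 1.0
    params = m_step(matrix, resp, config=config)
    return params.with_pi(0.4)


# ---------------------------------------------------------------------------
# E and M steps
# ---------------------------------------------------------------------------

def e_step(matrix: AnnotationMatrix, params: ModelParameters,
           ) -> tuple[np.ndarray, float]:
    """Responsibilities ``P(Z=1 | row)`` and the observed-data log-likelihood."""
    log_f0, log_f1 = class_log_densities(matrix, params)
    resp = _posterior_from_log_densities(log_f0, log_f1, params.pi)
    pi = params.pi
    if pi <= 0.0:
        loglik = float(np.sum(log_f0))
    elif pi >= 1.0:
        loglik = float(np.sum(log_f1))
    else:
        loglik = float(np.sum(np.logaddexp(np.log(pi) + log_f1,
                                           np.log1p(-pi) + log_f0)))
    return resp, loglik


def m_step(matrix: AnnotationMatrix, responsibilities: np.ndarray,
           config: EMConfig | None = None) -> ModelParameters:
    """Closed-form weighted updates for the Normal and Bernoulli emissions.

    Missing continuous cells simply drop out of the weighted moments (the
    marginalize policy; the other policies transform the matrix up front).
    """
    config = config or EMConfig()
    w = np.asarray(responsibilities, dtype=float)
    if w.shape != (matrix.n_rows,):
        raise ModelError("responsibilities length must equal row count")
    if ((w < 0) | (w > 1)).any():
        raise ModelError("responsibilities must lie in [0, 1]")
    w1_sum = w.sum()
    w0_sum = (1.0 - w).sum()
    if w1_sum == 0.0 or w0_sum == 0.0:
        raise ModelError("empty class: all responsibilities are 0 or all are 1")
    schema = matrix.schema
    pi = float(w.mean())

    ci = schema.continuous_indices
    mu = {0: np.zeros(ci.size), 1: np.zeros(ci.size)}
    sd = {0: np.ones(ci.size), 1: np.ones(ci.size)}
    if ci.size:
        x = matrix.values[:, ci]
        obs = matrix.mask[:, ci]
        xs = np.where(obs, x, 0.0)
        for z, wz in ((1, w), (0, 1.0 - w)):
            wobs = obs * wz[:, None]
            tot = wobs.sum(axis=0)
            if (tot <= 0).any():
                raise ModelError("a class has zero weight on an observed continuous column")
            m = (wobs * xs).sum(axis=0) / tot
            var = (wobs * (xs - m) ** 2).sum(axis=0) / tot
            mu[z] = m
            sd[z] = np.maximum(np.sqrt(var), config.variance_floor)

    bi = schema.binary_indices
    p = {0: np.zeros(bi.size), 1: np.zeros(bi.size)}
    if bi.size:
        y = matrix.values[:, bi]
        p[1] = (w @ y) / w1_sum
        p[0] = ((1.0 - w) @ y) / w0_sum
        clamp = config.bernoulli_clamp
        p[1] = np.clip(p[1], clamp, 1.0 - clamp)
        p[0] = np.clip(p[0], clamp, 1.0 - clamp)

    return ModelParameters(schema=schema, pi=pi,
                           mu0=mu[0], sigma0=sd[0], mu1=mu[1], sigma1=sd[1],
                           p0=p[0], p1=p[1])


# ---------------------------------------------------------------------------
# Component anchoring
# ---------------------------------------------------------------------------

def swap_components(params: ModelParameters) -> ModelParameters:
    """Exchange the two mixture components (label switch)."""
    return replace(params, pi=1.0 - params.pi,
                   mu0=params.mu1.copy(), sigma0=params.sigma1.copy(),
                   mu1=params.mu0.copy(), sigma1=params.sigma0.copy(),
                   p0=params.p1.copy(), p1=params.p0.copy())


def anchor_functional_component(params: ModelParameters,
                                schema: AnnotationSchema | None = None,
                                ) -> tuple[ModelParameters, bool]:
    """Resolve mixture label switching: the functional class is the one with
    the higher mean conservation (continuous-annotation) signal.

    Returns ``(params, swapped)``.  Exact ties leave the labels unchanged and
    record a warning.
    """
    schema = schema or params.schema
    if schema.n_continuous == 0:
        return params, False
    delta = float(np.mean(params.mu1 - params.mu0))
    if delta < 0.0:
        return swap_components(params), True
    if delta == 0.0:
        warnings.warn("component anchoring is tied (mu1 == mu0 for all "
                      "continuous annotations); labels left unchanged",
                      stacklevel=2)
    return params, False


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------

def _apply_missing_policy(matrix: AnnotationMatrix, policy: MissingPolicy,
                          ) -> tuple[AnnotationMatrix, np.ndarray]:
    if policy == "marginalize":
        return matrix, np.arange(matrix.n_rows)
    if policy == "impute_neutral_zero":
        return matrix.impute_neutral_zero(), np.arange(matrix.n_rows)
    if policy == "complete_case":
        sub, idx = matrix.complete_cases()
        return sub, idx
    raise ModelError(f"unknown missing policy {policy!r}")


def fit(matrix: AnnotationMatrix, schema: AnnotationSchema | None = None,
        config: EMConfig | None = None,
        init_params: ModelParameters | None = None) -> EMResult:
    """Fit the mixture by EM with restarts; best final log-likelihood wins
    (ties go to the lowest restart index).

    The log-likelihood trace is non-decreasing up to floating-point slack;
    non-convergence within ``max_iterations`` is reported, not raised.
    ``init_params`` overrides the initializer (used e.g. to study label
    switching by starting from mirrored parameters).
    """
    config = config or EMConfig()
    schema = schema or matrix.schema
    if schema.names != matrix.schema.names:
        raise ModelError("schema does not match the annotation matrix")
    work, row_idx = _apply_missing_policy(matrix, config.missing_policy)
    if work.n_rows < 10:
        raise ModelError("need at least 10 rows to fit")

    best: tuple[float, int, ModelParameters, np.ndarray, list[float], bool, int] | None = None
    for r in range(config.n_restarts):
        restart_seed = int(config.seed) + r
        params = init_params if init_params is not None else initialize(
            work, schema, config, seed=restart_seed)
        trace: list[float] = []
        converged = False
        resp, loglik = e_step(work, params)
        trace.append(loglik)
        n_iter = 0
        for n_iter in range(1, config.max_iterations + 1):
            params = m_step(work, resp, config=config)
            resp, loglik = e_step(work, params)
            trace.append(loglik)
            prev = trace[-2]
            rel = abs(loglik - prev) / max(abs(prev), 1.0)
            if rel < config.tolerance:
                converged = True
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], r, params, resp, trace, converged, n_iter)

    _, r_sel, params, resp, trace, converged, n_iter = best
    params, swapped = anchor_functional_component(params, schema)
    if swapped:
        resp = 1.0 - resp
    return EMResult(params=params, responsibilities=resp,
                    loglik_trace=np.asarray(trace), converged=converged,
                    n_iterations=n_iter, seed_used=int(config.seed) + r_sel,
                    restart_index_selected=r_sel, config=config,
                    row_indices=row_idx, anchored_swap=swapped)
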