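"""MAP fitting of the HGF model space with Laplace model evidence.

Four models are fitted throughout the analysis:

====  ==============  =========================================
id    level-3 dynamics  perceptual parameters
====  ==============  =========================================
m1    standard          free (kappa2, omega2, mu2_0, mu3_0)
m1b   standard          fixed to an ideal Bayesian observer
m2    mean-reverting    free (+ m3)
m2b   mean-reverting    fixed to an ideal Bayesian observer
====  ==============  =========================================

All models share the response parameters (zeta, nu). Meta-volatility
theta is fixed to 0.5 and the drift rate phi3 to 0.1 to keep the number
of free parameters manageable. Estimation is done in an unconstrained
space (logit for the bounded kappa2 and zeta, identity elsewhere) with
Gaussian priors, maximised by quasi-Newton (L-BFGS-B) from multiple
seeded starts; the model evidence is the Laplace (free-energy style)
approximation at the MAP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .hgf import AgentParams, TrajectoryRejection, filter_beliefs, response_probabilities
from .task import SessionData

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "FitResult",
    "MODELS",
    "DEFAULT_PRIORS",
    "PARAM_BOUNDS",
    "FitFailure",
    "fit_map",
    "laplace_log_evidence",
    "ideal_observer_params",
    "sample_agent_params",
    "to_native",
    "to_estimation",
]

#: native-scale bounds of the bounded parameters (used for clipping
#: user-supplied generating values; the estimation-space transform keeps
#: fitted values strictly inside them)
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "kappa2": (1e-6, 1.0),
    "zeta": (1e-6, 1.0 - 1e-6),
}

_PENALTY = 1e12  # objective value for rejected (ill-posed) trajectories

PERCEPTUAL_PARAMS = ("kappa2", "omega2", "mu2_0", "mu3_0", "m3")
RESPONSE_PARAMS = ("zeta", "nu")


class FitFailure(RuntimeError):
    """All optimisation starts were rejected or failed to converge."""


@dataclass(frozen=True)
class Prior:
    mean: float
    var: float
    transform: str = "identity"  # or "logit" (scaled to (0,1))

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("prior variance must be positive")
        if self.transform not in ("identity", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors in estimation space, one per free parameter."""

    priors: dict[str, Prior]

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.priors

    def log_pdf(self, names, x_est) -> float:
        lp = 0.0
        for name, x in zip(names, x_est):
            p = self.priors[name]
            lp += -0.5 * (math.log(2 * math.pi * p.var) + (x - p.mean) ** 2 / p.var)
        return lp


#: Priors of the standard analysis, in estimation space:
#: (mean, variance), with kappa2 and zeta logit-transformed to (0, 1).
DEFAULT_PRIORS = PriorSpec(
    priors={
        "kappa2": Prior(0.0, 1.0, "logit"),
        "omega2": Prior(-2.0, 4.0),
        "mu2_0": Prior(0.0, 1.0),
        "mu3_0": Prior(1.0, 1.0),
        "zeta": Prior(0.0, 1.0, "logit"),
        "nu": Prior(math.log(48.0), 1.0),
        "m3": Prior(1.0, 1.0),
    }
)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def to_native(name: str, x: float, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Estimation space -> native parameter scale."""
    if priors[name].transform == "logit":
        return _sigmoid(x)
    return x


def to_estimation(name: str, p: float, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Native scale -> estimation space (inverse of :func:`to_native`)."""
    if priors[name].transform == "logit":
        p = min(max(p, 1e-12), 1 - 1e-12)
        return math.log(p / (1.0 - p))
    return p


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the 2x2 model space (level-3 dynamics x perceptual mode)."""

    name: str
    variant: str  # "standard" | "mean_reverting"
    perceptual_mode: str = "free"  # "free" | "ideal_fixed"
    theta: float = 0.5
    phi3: float = 0.1

    @property
    def perceptual_params(self) -> tuple[str, ...]:
        base = ["kappa2", "omega2", "mu2_0", "mu3_0"]
        if self.variant == "mean_reverting":
            base.append("m3")
        return tuple(base)

    @property
    def free_params(self) -> tuple[str, ...]:
        if self.perceptual_mode == "free":
            return self.perceptual_params + RESPONSE_PARAMS
        return RESPONSE_PARAMS

    def make_agent(self, free: dict[str, float], fixed_perceptual: dict[str, float] | None = None) -> AgentParams:
        vals = {"theta": self.theta, "phi3": self.phi3}
        if self.perceptual_mode == "ideal_fixed":
            if fixed_perceptual is None:
                raise ValueError(f"model {self.name} requires fixed perceptual values")
            vals.update(fixed_perceptual)
        vals.update(free)
        return AgentParams(**vals)


MODELS: dict[str, ModelSpec] = {
    "m1": ModelSpec("m1", "standard", "free"),
    "m1b": ModelSpec("m1b", "standard", "ideal_fixed"),
    "m2": ModelSpec("m2", "mean_reverting", "free"),
    "m2b": ModelSpec("m2b", "mean_reverting", "ideal_fixed"),
}


@dataclass
class FitResult:
    """MAP fit of one model to one session."""

    model: str
    param_names: tuple[str, ...]
    params_est: np.ndarray
    params_native: dict[str, float]
    log_joint: float
    hessian: np.ndarray
    lme: float
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "param_names": list(self.param_names),
            "params_est": [float(v) for v in self.params_est],
            "params_native": {k: float(v) for k, v in self.params_native.items()},
            "log_joint": float(self.log_joint),
            "lme": float(self.lme),
            "diagnostics": self.diagnostics,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _session_nll(agent: AgentParams, u, c, y, variant: str) -> float:
    """Negative Bernoulli log-likelihood of choices; penalty if ill-posed."""
    try:
        traj = filter_beliefs(agent, u, variant=variant)
    except TrajectoryRejection:
        return _PENALTY
    _, _, p = response_probabilities(traj.muhat1, traj.muhat3, c, agent.zeta, agent.nu)
    ll = float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))
    return -ll


def _input_surprise(agent: AgentParams, u, variant: str) -> float:
    """Cumulative surprise of the inputs alone, -sum log p(u(k) | muhat1(k))."""
    try:
        traj = filter_beliefs(agent, u, variant=variant)
    except TrajectoryRejection:
        return _PENALTY
    p = np.clip(traj.muhat1, 1e-12, 1 - 1e-12)
    u = np.asarray(u)
    return -float(np.sum(np.where(u == 1, np.log(p), np.log1p(-p))))


def _make_objective(session: SessionData, model: ModelSpec, priors: PriorSpec,
                    names: tuple[str, ...], fixed_perceptual: dict | None):
    u, c, y = session.u, session.c, session.y

    def neg_log_joint(x):
        free = {nm: to_native(nm, float(v), priors) for nm, v in zip(names, x)}
        try:
            agent = model.make_agent(free, fixed_perceptual)
        except ValueError:
            return _PENALTY
        nll = _session_nll(agent, u, c, y, model.variant)
        if nll >= _PENALTY:
            return _PENALTY
        return nll - priors.log_pdf(names, x)

    return neg_log_joint


def _multistart_minimize(fun, names, priors: PriorSpec, seed: int, n_starts: int,
                         max_iter: int, gtol: float):
    rng = np.random.default_rng(seed)
    means = np.array([priors[nm].mean for nm in names])
    sds = np.array([math.sqrt(priors[nm].var) for nm in names])
    starts = [means]
    tries = 0
    while len(starts) < n_starts and tries < 10 * n_starts:
        x0 = rng.normal(means, sds)
        tries += 1
        if fun(x0) < _PENALTY:
            starts.append(x0)
    best, n_rejected, records = None, 0, []
    for x0 in starts:
        if fun(x0) >= _PENALTY:
            n_rejected += 1
            continue
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-10},
        )
        records.append({"fun": float(res.fun), "nit": int(res.nit), "success": bool(res.success)})
        if res.fun < _PENALTY and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailure(f"all {len(starts)} starts rejected or failed ({n_rejected} rejected)")
    diagnostics = {
        "n_starts": len(starts),
        "n_rejected_starts": n_rejected,
        "starts": records,
        "converged": True,
        "nit": int(best.nit),
    }
    return best, diagnostics


def _finite_diff_hessian(fun, x, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            if i == j:
                f1, f2 = fun(x + ei), fun(x - ei)
                H[i, i] = (f1 - 2 * f0 + f2) / step**2
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step**2)
    return H


def _nearest_pd(H: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped positive-definite projection of a symmetric matrix."""
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    if np.all(w > 0):
        return Hs, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def laplace_log_evidence(log_joint: float, hessian: np.ndarray) -> tuple[float, bool]:
    """Laplace approximation of the log model evidence.

    LME = log_joint(MAP) + d/2 * log(2*pi) - 1/2 * log det(H), where H is
    the Hessian of the negative log joint at the MAP. A non-positive-
    definite Hessian is projected to the nearest PD matrix; the second
    return value flags when that regularisation was applied. With d = 0
    the evidence is the log joint itself.
    """
    hessian = np.atleast_2d(np.asarray(hessian, dtype=float))
    d = hessian.shape[0] if hessian.size else 0
    if d == 0:
        return float(log_joint), False
    H, regularised = _nearest_pd(hessian)
    sign, logdet = np.linalg.slogdet(H)
    return float(log_joint + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet), regularised


def fit_map(
    session: SessionData,
    model: ModelSpec | str,
    priors: PriorSpec = DEFAULT_PRIORS,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 500,
    gtol: float = 1e-6,
    fixed_perceptual: dict[str, float] | None = None,
) -> FitResult:
    """MAP-fit one model to one session.

    Maximises log p(y | theta) + log p(theta) in estimation space by
    quasi-Newton from ``n_starts`` seeded starts (the prior mean plus
    prior draws); parameter proposals whose trajectories are ill-posed
    score as rejected. For the ideal-observer models (m1b/m2b) the
    perceptual parameters are first optimised on the inputs alone via
    :func:`ideal_observer_params` (or passed via ``fixed_perceptual``).
    Returns the best local optimum with its Laplace log evidence.
    """
    model = MODELS[model] if isinstance(model, str) else model
    if session.y is None:
        raise ValueError("session has no choices to fit")
    if model.perceptual_mode == "ideal_fixed" and fixed_perceptual is None:
        fixed_perceptual = ideal_observer_params(session.u, model, priors)
    names = model.free_params
    fun = _make_objective(session, model, priors, names, fixed_perceptual)
    best, diagnostics = _multistart_minimize(fun, names, priors, seed, n_starts, max_iter, gtol)
    x = np.asarray(best.x, dtype=float)
    log_joint = -float(best.fun)
    H = _finite_diff_hessian(fun, x)
    lme, regularised = laplace_log_evidence(log_joint, H)
    diagnostics["hessian_regularised"] = regularised
    native = {nm: to_native(nm, float(v), priors) for nm, v in zip(names, x)}
    if fixed_perceptual:
        diagnostics["fixed_perceptual"] = {k: float(v) for k, v in fixed_perceptual.items()}
    return FitResult(
        model=model.name,
        param_names=names,
        params_est=x,
        params_native=native,
        log_joint=log_joint,
        hessian=H,
        lme=lme,
        diagnostics=diagnostics,
        seed=seed,
    )


def ideal_observer_params(
    u,
    model: ModelSpec | str,
    priors: PriorSpec = DEFAULT_PRIORS,
    n_starts: int = 5,
    max_iter: int = 500,
    gtol: float = 1e-6,
) -> dict[str, float]:
    """Perceptual parameters of an ideal Bayesian observer of the inputs.

    Minimises the cumulative input surprise
    ``-sum_k log p(u(k) | muhat1(k))`` plus the prior penalty, over the
    perceptual parameters only (no choice data enters). Deterministic
    given ``u`` and the configuration: the multistart seed is fixed.
    """
    model = MODELS[model] if isinstance(model, str) else model
    u = np.asarray(u, dtype=int)
    names = model.perceptual_params

    def fun(x):
        free = {nm: to_native(nm, float(v), priors) for nm, v in zip(names, x)}
        try:
            agent = model.make_agent(free, fixed_perceptual=None) if model.perceptual_mode == "free" \
                else AgentParams(theta=model.theta, phi3=model.phi3, **free)
        except ValueError:
            return _PENALTY
        s = _input_surprise(agent, u, model.variant)
        if s >= _PENALTY:
            return _PENALTY
        return s - priors.log_pdf(names, x)

    best, _ = _multistart_minimize(fun, names, priors, seed=0, n_starts=n_starts,
                                   max_iter=max_iter, gtol=gtol)
    return {nm: to_native(nm, float(v), priors) for nm, v in zip(names, best.x)}


def sample_agent_params(
    n: int,
    variant: str = "mean_reverting",
    rng: np.random.Generator | int = 0,
    priors: PriorSpec = DEFAULT_PRIORS,
    design=None,
    max_tries: int = 200,
) -> list[dict[str, float]]:
    """Draw generating parameter dicts from the priors (native scale).

    Samples each free parameter of the given variant from its Gaussian
    prior in estimation space and maps it to the native scale, so bounded
    parameters automatically respect their bounds. theta/phi3 stay at
    their fixed analysis values.

    When a :class:`~advicehgf.task.TaskDesign` is given, draws whose
    belief trajectories are ill-posed on an input sequence sampled from
    the design are rejected and redrawn — the synthetic analog of real
    cohorts, whose fitted parameters are well-posed by construction.
    """
    model = MODELS["m2" if variant == "mean_reverting" else "m1"]
    rng = np.random.default_rng(rng)
    out = []
    while len(out) < n:
        for _ in range(max_tries):
            p = {}
            for name in model.free_params:
                pr = priors[name]
                p[name] = to_native(name, rng.normal(pr.mean, math.sqrt(pr.var)), priors)
            if design is not None:
                from .task import sample_advice_outcomes

                inputs = sample_advice_outcomes(design, rng)
                try:
                    filter_beliefs(AgentParams(theta=model.theta, phi3=model.phi3, **p),
                                   inputs.u, variant=variant)
                except TrajectoryRejection:
                    continue
            break
        else:
            raise FitFailure(f"could not draw a well-posed agent in {max_tries} tries")
        out.append(p)
    return out
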