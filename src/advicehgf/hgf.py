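"""3-level binary Hierarchical Gaussian Filter and response model.

The perceptual model tracks three latent states: x1, the trial-wise
accuracy of the advice (binary); x2, the adviser's fidelity in log-odds;
and x3, the log-volatility of that fidelity. Beliefs are updated by
precision-weighted prediction errors: the level-2 posterior mean moves by
``delta1 / pi2`` where ``delta1 = u - s(mu2_prior)``, and the level-3
mean by the volatility prediction error of level 2 scaled by the
coupling ``kappa2``. The mean-reverting (AR1) variant additionally
drifts the level-3 prediction toward an equilibrium ``m3`` at rate
``phi3`` before each update, akin to a discrete-time Ornstein-Uhlenbeck
process.

The response model blends the predicted advice accuracy with the
non-social cue, ``b = zeta * muhat1 + (1 - zeta) * c``, and maps the
integrated belief through a power sigmoid with inverse temperature
``beta = exp(-muhat3 + nu)``: higher inferred volatility means noisier
choices, on top of the constant decision noise ``nu``.

The per-trial filter is a scalar recursion, deliberately written with
plain floats: a 153-trial pass costs ~0.1 ms, which is what makes the
multistart MAP fits and recovery studies cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import SessionData

__all__ = [
    "AgentParams",
    "BeliefTrajectory",
    "TrajectoryRejection",
    "VARIANTS",
    "filter_beliefs",
    "response_probabilities",
    "simulate_choices",
    "session_log_likelihood",
]

VARIANTS = ("standard", "mean_reverting")

#: clamp on the integrated belief before the decision sigmoid
B_EPS = 1e-8
#: clamp on choice probabilities entering the log-likelihood
P_EPS = 1e-12


class TrajectoryRejection(ValueError):
    """Ill-posed belief trajectory (non-positive posterior precision).

    The standard signal that a parameter vector has left the region where
    the variational HGF updates are well defined; the fitter treats such
    proposals as having zero posterior density.
    """

    def __init__(self, trial: int, message: str = "non-positive posterior precision"):
        self.trial = trial
        super().__init__(f"{message} at trial {trial}")


@dataclass(frozen=True)
class AgentParams:
    """Perceptual + response parameters of one agent.

    kappa2   coupling strength in (0, 1]; scales how strongly inferred
             volatility modulates fidelity learning (phasic learning).
    omega2   tonic evolution rate of fidelity (log-variance offset).
    theta    meta-volatility, the step variance at level 3 (fixed 0.5 in
             the standard analysis).
    mu2_0, mu3_0        initial belief means (fidelity log-odds; log-volatility).
    sigma2_0, sigma3_0  initial belief variances (fixed 1.0 by convention).
    phi3, m3 drift rate and equilibrium of the mean-reverting level-3
             variant (phi3 fixed 0.1; ignored by the standard variant).
    zeta     advice weight in (0, 1): relative reliance on the social cue.
    nu       decision noise offset; beta = exp(-muhat3 + nu).
    """

    kappa2: float = 0.5
    omega2: float = -2.0
    mu2_0: float = 0.0
    mu3_0: float = 1.0
    zeta: float = 0.5
    nu: float = math.log(48.0)
    m3: float = 1.0
    theta: float = 0.5
    phi3: float = 0.1
    sigma2_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa2 <= 1.0):
            raise ValueError(f"kappa2 must be in (0, 1], got {self.kappa2}")
        if not (0.0 < self.zeta < 1.0):
            raise ValueError(f"zeta must be in (0, 1), got {self.zeta}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not (0.0 <= self.phi3 <= 1.0):
            raise ValueError("phi3 must be in [0, 1]")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BeliefTrajectory:
    """Per-trial beliefs, precisions and prediction errors (trial k at
    index k-1). Response-model fields (b, beta, p_follow) are attached
    once cue and response parameters are known."""

    muhat1: np.ndarray
    muhat2: np.ndarray
    muhat3: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    sigma2: np.ndarray
    sigma3: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    b: np.ndarray | None = None
    beta: np.ndarray | None = None
    p_follow: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        d = {"trial": np.arange(1, self.n_trials + 1)}
        for name in ("muhat1", "muhat2", "muhat3", "mu2", "mu3", "sigma2",
                     "sigma3", "delta1", "delta2", "b", "beta", "p_follow"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_beliefs(params: AgentParams, u, variant: str = "standard") -> BeliefTrajectory:
    """Run the perceptual filter over a binary advice-accuracy sequence.

    Implements the variational update equations of the 3-level binary
    HGF. Per trial k (predictions first, then updates):

        muhat2 = mu2(k-1)                      muhat1 = s(muhat2)
        muhat3 = mu3(k-1) [+ phi3*(m3 - mu3(k-1)) if mean-reverting]
        pihat2 = 1 / (sigma2(k-1) + exp(kappa2*mu3(k-1) + omega2))
        pihat3 = 1 / (sigma3(k-1) + theta)
        delta1 = u(k) - muhat1
        pi2    = pihat2 + muhat1*(1 - muhat1)
        mu2(k) = muhat2 + delta1 / pi2
        delta2 = (sigma2(k) + (mu2(k) - muhat2)^2) * pihat2 - 1
        w2     = exp(kappa2*mu3(k-1) + omega2) * pihat2
        pi3    = pihat3 + kappa2^2/2 * w2 * (w2 + (2*w2 - 1)*delta2)
        mu3(k) = muhat3 + kappa2*w2/(2*pi3) * delta2

    Raises :class:`TrajectoryRejection` (with the 1-based offending
    trial) if any posterior precision is non-positive or the recursion
    overflows — the ill-posedness signal used to discard parameter
    proposals during fitting.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    mean_reverting = variant == "mean_reverting"
    ka, om, th = params.kappa2, params.omega2, params.theta
    ph, m3 = params.phi3, params.m3
    mu2, sig2 = params.mu2_0, params.sigma2_0
    mu3, sig3 = params.mu3_0, params.sigma3_0

    useq = [int(v) for v in u]
    n = len(useq)
    cols: list[list[float]] = [[0.0] * n for _ in range(9)]
    (MUHAT1, MUHAT2, MUHAT3, MU2, MU3, SIG2, SIG3, D1, D2) = range(9)

    for k, uk in enumerate(useq):
        try:
            muhat2 = mu2
            muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
            muhat3 = mu3 + ph * (m3 - mu3) if mean_reverting else mu3
            v2 = math.exp(ka * mu3 + om)
            pihat2 = 1.0 / (sig2 + v2)
            pihat3 = 1.0 / (sig3 + th)
            delta1 = uk - muhat1
            pi2 = pihat2 + muhat1 * (1.0 - muhat1)
            mu2 = muhat2 + delta1 / pi2
            sig2 = 1.0 / pi2
            delta2 = (sig2 + (mu2 - muhat2) ** 2) * pihat2 - 1.0
            w2 = v2 * pihat2
            pi3 = pihat3 + 0.5 * ka * ka * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
            if pi3 <= 0.0 or not math.isfinite(pi3):
                raise TrajectoryRejection(k + 1)
            mu3 = muhat3 + ka * w2 / (2.0 * pi3) * delta2
            sig3 = 1.0 / pi3
        except OverflowError:
            raise TrajectoryRejection(k + 1, "numerical overflow") from None
        row = (muhat1, muhat2, muhat3, mu2, mu3, sig2, sig3, delta1, delta2)
        for j in range(9):
            cols[j][k] = row[j]

    return BeliefTrajectory(
        muhat1=np.array(cols[MUHAT1]),
        muhat2=np.array(cols[MUHAT2]),
        muhat3=np.array(cols[MUHAT3]),
        mu2=np.array(cols[MU2]),
        mu3=np.array(cols[MU3]),
        sigma2=np.array(cols[SIG2]),
        sigma3=np.array(cols[SIG3]),
        delta1=np.array(cols[D1]),
        delta2=np.array(cols[D2]),
    )


def response_probabilities(muhat1, muhat3, c, zeta: float, nu: float):
    """Integrated belief, inverse temperature and follow probability.

    b = zeta*muhat1 + (1-zeta)*c (clamped to [1e-8, 1-1e-8]);
    beta = exp(-muhat3 + nu);
    p_follow = b^beta / (b^beta + (1-b)^beta), computed in log space.
    Returns (b, beta, p_follow) as float arrays.
    """
    muhat1 = np.asarray(muhat1, dtype=float)
    muhat3 = np.asarray(muhat3, dtype=float)
    c = np.asarray(c, dtype=float)
    b = zeta * muhat1 + (1.0 - zeta) * c
    b = np.clip(b, B_EPS, 1.0 - B_EPS)
    beta = np.exp(np.clip(-muhat3 + nu, -700.0, 700.0))
    # p = 1 / (1 + exp(beta * (log(1-b) - log b)))
    z = np.clip(beta * (np.log1p(-b) - np.log(b)), -700.0, 700.0)
    p = 1.0 / (1.0 + np.exp(z))
    p = np.clip(p, P_EPS, 1.0 - P_EPS)
    return b, beta, p


def attach_response(trajectory: BeliefTrajectory, c, zeta: float, nu: float) -> BeliefTrajectory:
    """Return a copy of ``trajectory`` with response-model fields filled."""
    b, beta, p = response_probabilities(trajectory.muhat1, trajectory.muhat3, c, zeta, nu)
    return replace(trajectory, b=b, beta=beta, p_follow=p)


def simulate_choices(
    params: AgentParams,
    u,
    c,
    variant: str = "standard",
    rng: np.random.Generator | int = 0,
    phase=None,
) -> SessionData:
    """Simulate one session: filter beliefs, then sample choices.

    y(k) ~ Bernoulli(p_follow(k)); the chosen option wins iff the choice
    agrees with the advice's accuracy (win = u when following, 1-u when
    going against). ``phase`` labels default to all-volatile if omitted.
    """
    u = np.asarray(u, dtype=int)
    c = np.asarray(c, dtype=float)
    if len(u) != len(c):
        raise ValueError("u and c must have equal length")
    rng = np.random.default_rng(rng)
    traj = filter_beliefs(params, u, variant=variant)
    _, _, p = response_probabilities(traj.muhat1, traj.muhat3, c, params.zeta, params.nu)
    y = (rng.random(len(u)) < p).astype(int)
    win = np.where(y == 1, u, 1 - u)
    phase = tuple(phase) if phase is not None else ("volatile",) * len(u)
    return SessionData(u=u, c=c, phase=phase, y=y, win=win)


def session_log_likelihood(params: AgentParams, session: SessionData, variant: str = "standard") -> float:
    """Bernoulli log-likelihood of the observed choices under the model."""
    if session.y is None:
        raise ValueError("session has no choices")
    traj = filter_beliefs(params, session.u, variant=variant)
    _, _, p = response_probabilities(traj.muhat1, traj.muhat3, session.c, params.zeta, params.nu)
    y = session.y
    return float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))
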