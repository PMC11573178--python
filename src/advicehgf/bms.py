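"""Random-effects Bayesian model selection (RFX-BMS).

Given a subjects x models matrix of log model evidences, the
random-effects scheme treats the model identity of each subject as drawn
from population frequencies r ~ Dirichlet(alpha) and estimates the
posterior over r by variational Bayes. Reported quantities:

* expected model frequencies ``f = E[r]``,
* exceedance probabilities ``EP_k = P(r_k > r_j for all j)``, estimated
  by Monte-Carlo sampling of the Dirichlet posterior,
* the Bayes omnibus risk ``BOR``, the posterior probability that model
  frequencies are all equal (differences arose by chance), from the free
  energies of the frequency model and the equal-frequency null,
* protected exceedance probabilities
  ``PEP = (1 - BOR) * EP + BOR / K``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["EvidenceMatrix", "BmsResult", "rfx_bms", "model_recovery_confusion"]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Log model evidences, one row per subject, one column per model."""

    lme: np.ndarray
    models: tuple[str, ...]

    def __post_init__(self) -> None:
        lme = np.atleast_2d(np.asarray(self.lme, dtype=float))
        object.__setattr__(self, "lme", lme)
        if lme.shape[1] != len(self.models):
            raise ValueError("column count does not match model labels")
        if lme.shape[1] < 1:
            raise ValueError("need at least one model")
        if not np.all(np.isfinite(lme)):
            raise ValueError("log evidences must be finite")

    @property
    def n_subjects(self) -> int:
        return self.lme.shape[0]

    @property
    def n_models(self) -> int:
        return self.lme.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.lme, columns=list(self.models)).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EvidenceMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(lme=df.to_numpy(float), models=tuple(df.columns))


@dataclass
class BmsResult:
    models: tuple[str, ...]
    alpha: np.ndarray           # Dirichlet posterior counts
    frequencies: np.ndarray     # expected model frequencies f
    exceedance: np.ndarray      # EP
    bor: float                  # Bayes omnibus risk
    protected_exceedance: np.ndarray  # PEP
    responsibilities: np.ndarray      # subjects x models posterior assignment
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "frequencies": self.frequencies.tolist(),
            "exceedance": self.exceedance.tolist(),
            "bor": float(self.bor),
            "protected_exceedance": self.protected_exceedance.tolist(),
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a_s, a0_s = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_s) - gammaln(alpha).sum()
        - gammaln(a0_s) + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_s))).sum()
    )


def _free_energy_rfx(lme: np.ndarray, g: np.ndarray, alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """Variational free energy of the random-effects frequency model."""
    dig = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = np.where(g > 0, g * np.log(g), 0.0).sum()
    return float((g * (lme + dig)).sum() - entropy - _dirichlet_kl(alpha, alpha0))


def _free_energy_null(lme: np.ndarray) -> float:
    """Log evidence of the fixed equal-frequency null model."""
    k = lme.shape[1]
    return float(logsumexp(lme - np.log(k), axis=1).sum())


def rfx_bms(
    evidence: EvidenceMatrix,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> BmsResult:
    """Variational random-effects BMS over an evidence matrix.

    Iterates subject responsibilities ``g_nk ∝ exp(lme_nk + digamma
    terms)`` against Dirichlet counts ``alpha = alpha0 + sum_n g_nk``
    until the counts converge, then samples the Dirichlet posterior for
    exceedance probabilities, computes the Bayes omnibus risk from the
    free-energy comparison with the equal-frequency null, and protects
    the exceedance probabilities accordingly.
    """
    lme = evidence.lme
    n, k = lme.shape
    if k < 2:
        raise ValueError("RFX-BMS needs at least two models")
    a0 = np.full(k, float(alpha0))
    alpha = a0.copy()
    for it in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(f"RFX-BMS did not converge in {max_iter} iterations (alpha={alpha})")

    f = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    ep = np.bincount(np.argmax(samples, axis=1), minlength=k) / n_samples

    f1 = _free_energy_rfx(lme, g, alpha, a0)
    f0 = _free_energy_null(lme)
    bor = float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))
    pep = (1.0 - bor) * ep + bor / k
    return BmsResult(
        models=evidence.models,
        alpha=alpha,
        frequencies=f,
        exceedance=ep,
        bor=bor,
        protected_exceedance=pep,
        responsibilities=g,
        diagnostics={"iterations": it + 1, "free_energy_rfx": f1, "free_energy_null": f0,
                     "n_samples": n_samples, "seed": seed},
    )


def model_recovery_confusion(
    evidence_by_generator: dict[str, list[EvidenceMatrix]],
    seed: int = 0,
    **bms_kwargs,
) -> pd.DataFrame:
    """Average-PEP confusion matrix for model recovery.

    ``evidence_by_generator`` maps each generating model's name to the
    list of evidence matrices (one per simulation run, subjects x fitted
    models). Entry (g, f) of the result is the protected exceedance
    probability of fitted model f on data generated by model g, averaged
    over runs; rows sum to 1.
    """
    rows = {}
    fitted: tuple[str, ...] | None = None
    for gen, mats in evidence_by_generator.items():
        if not mats:
            raise ValueError(f"no evidence matrices for generator {gen!r}")
        peps = []
        for i, mat in enumerate(mats):
            if fitted is None:
                fitted = mat.models
            elif mat.models != fitted:
                raise ValueError("inconsistent fitted-model labels across matrices")
            if mat.n_models == 1:  # degenerate single-model space
                peps.append(np.array([1.0]))
            else:
                res = rfx_bms(mat, seed=seed + i, **bms_kwargs)
                peps.append(res.protected_exceedance)
        rows[gen] = np.mean(peps, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(fitted))
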