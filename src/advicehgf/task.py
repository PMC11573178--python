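"""Synthetic social advice-taking task: designs, sessions, and cohorts.

The task is a binary lottery in which an on-screen adviser recommends one
of two options while a pie chart displays the options' true win
probabilities.  The adviser's fidelity (probability of giving accurate
advice) is stable and high for an initial block of trials and then
switches rapidly between helpful and misleading regimes.  This module
generates task designs with that structure, samples advice/outcome
sequences, and builds paired test-retest cohorts of HGF agents.

Trial indices are 1-based throughout (``probe_trials=[14, ...]`` refers
to the 14th trial); internally arrays are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskDesign",
    "SessionData",
    "CohortSpec",
    "ProbeResponse",
    "DEFAULT_SCHEDULE",
    "DEFAULT_CUE_SET",
    "make_task_design",
    "sample_advice_outcomes",
    "generate_retest_cohort",
    "generate_probe_responses",
]

#: Default block schedule: (length, fidelity) pairs. The first 35 trials
#: form the stable phase with consistently helpful advice; the remaining
#: 118 trials alternate between helpful and misleading regimes in short
#: blocks. The volatile-phase block boundaries approximate the intended
#: rapid-switching structure and are fully overridable via `blocks=`.
DEFAULT_SCHEDULE: tuple[tuple[int, float], ...] = (
    (35, 0.9),   # stable phase
    (15, 0.2),
    (15, 0.8),
    (12, 0.2),
    (12, 0.8),
    (10, 0.2),
    (10, 0.8),
    (12, 0.2),
    (12, 0.8),
    (20, 0.2),
)

#: Pie-chart win probabilities for the cue-favoured option, sampled
#: uniformly per trial. Spans weak to strong non-social evidence.
DEFAULT_CUE_SET: tuple[float, ...] = (0.55, 0.65, 0.75, 0.85)

DEFAULT_PROBE_TRIALS: tuple[int, ...] = (14, 49, 73, 99, 134)


class ConfigError(ValueError):
    """Raised when a schedule or cohort configuration is inconsistent."""


@dataclass(frozen=True)
class TaskDesign:
    """Trial-wise ground truth of one task run.

    Attributes
    ----------
    fidelity : per-trial probability that the advice is accurate
        (the true Bernoulli rate of the advice-accuracy state).
    cue_prob : per-trial win probability of the pie-chart-favoured option.
    phase : per-trial label, ``"stable"`` or ``"volatile"``; the stable
        phase is a contiguous prefix.
    probe_trials : 1-based trials on which an explicit fidelity report
        ("helpful" / "random" / "misleading") is collected.
    pre_task_probe : whether a report is also collected on trial 1,
        before any advice has been seen.
    """

    fidelity: np.ndarray
    cue_prob: np.ndarray
    phase: tuple[str, ...]
    probe_trials: tuple[int, ...] = DEFAULT_PROBE_TRIALS
    pre_task_probe: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "fidelity", np.asarray(self.fidelity, dtype=float))
        object.__setattr__(self, "cue_prob", np.asarray(self.cue_prob, dtype=float))
        n = len(self.fidelity)
        if not (len(self.cue_prob) == len(self.phase) == n):
            raise ConfigError("fidelity, cue_prob and phase must have equal length")
        if np.any((self.fidelity < 0) | (self.fidelity > 1)):
            raise ConfigError("fidelity outside [0, 1]")
        if np.any((self.cue_prob <= 0) | (self.cue_prob >= 1)):
            raise ConfigError("cue_prob outside (0, 1)")
        labels = set(self.phase)
        if not labels <= {"stable", "volatile"}:
            raise ConfigError(f"unknown phase labels: {labels - {'stable', 'volatile'}}")
        # stable phase must be a contiguous prefix
        stable = [p == "stable" for p in self.phase]
        if any(stable[i] and not all(stable[: i + 1]) for i in range(n)):
            raise ConfigError("stable phase must be a contiguous prefix")
        probes = list(self.probe_trials)
        if probes != sorted(set(probes)) or (probes and not (1 <= probes[0] and probes[-1] <= n)):
            raise ConfigError("probe_trials must be strictly increasing within [1, n_trials]")

    @property
    def n_trials(self) -> int:
        return len(self.fidelity)

    @property
    def stable_length(self) -> int:
        return sum(1 for p in self.phase if p == "stable")

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-trial representation (trial column 1-based)."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": list(self.phase),
                "fidelity": self.fidelity,
                "cue_prob": self.cue_prob,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, probe_trials=DEFAULT_PROBE_TRIALS, pre_task_probe=True) -> "TaskDesign":
        df = df.sort_values("trial")
        return cls(
            fidelity=df["fidelity"].to_numpy(float),
            cue_prob=df["cue_prob"].to_numpy(float),
            phase=tuple(df["phase"]),
            probe_trials=tuple(probe_trials),
            pre_task_probe=pre_task_probe,
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "TaskDesign":
        return cls.from_frame(pd.read_csv(path), **kw)


@dataclass
class SessionData:
    """One participant-session of the task.

    ``u`` is the binary advice-accuracy sequence the agent observes
    (1 = the advised option won), ``c`` the pie-chart win probability of
    the *advised* option (the non-social cue re-expressed on the advised
    colour), ``y`` the binary choices (1 = followed advice) and ``win``
    the realised outcomes of the chosen option. ``y`` and ``win`` may be
    None for input-only sessions that have not been played yet.
    """

    u: np.ndarray
    c: np.ndarray
    phase: tuple[str, ...]
    y: np.ndarray | None = None
    win: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=int)
        self.c = np.asarray(self.c, dtype=float)
        n = len(self.u)
        if not (len(self.c) == len(self.phase) == n):
            raise ConfigError("u, c and phase must have equal length")
        if not set(np.unique(self.u)) <= {0, 1}:
            raise ConfigError("u must be binary")
        if np.any((self.c <= 0) | (self.c >= 1)):
            raise ConfigError("c outside (0, 1)")
        for name in ("y", "win"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if len(v) != n or not set(np.unique(v)) <= {0, 1}:
                    raise ConfigError(f"{name} must be binary of length {n}")
                setattr(self, name, v)

    @property
    def n_trials(self) -> int:
        return len(self.u)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "trial": np.arange(1, self.n_trials + 1),
            "phase": list(self.phase),
            "u": self.u,
            "advised_cue_prob": self.c,
        }
        if self.y is not None:
            d["y"] = self.y
        if self.win is not None:
            d["win"] = self.win
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SessionData":
        df = df.sort_values("trial")
        return cls(
            u=df["u"].to_numpy(int),
            c=df["advised_cue_prob"].to_numpy(float),
            phase=tuple(df["phase"]),
            y=df["y"].to_numpy(int) if "y" in df else None,
            win=df["win"].to_numpy(int) if "win" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "SessionData":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ProbeResponse:
    """Explicit adviser-fidelity report at one probe trial."""

    trial: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in ("helpful", "random", "misleading"):
            raise ConfigError(f"unknown probe category {self.category!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a paired (test/retest) synthetic cohort.

    Session-1 generating parameters are drawn from ``param_distribution``
    (a mapping name -> (mean, sd) on the parameter's native scale, with
    bounded parameters re-clipped to their bounds); when the mapping is
    empty (the default) they are instead drawn from the analysis priors
    in estimation space, rejection-sampled to be well-posed on the
    design. Session-2 parameters
    are session-1 values plus ``Normal(practice_shift, within_subject_sd)``
    per parameter, re-clipped. With both perturbations zero the two
    sessions share generating parameters and differ only through decision
    noise.
    """

    n_subjects: int = 39
    param_distribution: dict[str, tuple[float, float]] = field(default_factory=dict)
    within_subject_sd: dict[str, float] = field(default_factory=dict)
    practice_shift: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        for name, sd in self.within_subject_sd.items():
            if sd < 0:
                raise ConfigError(f"within_subject_sd[{name}] < 0")
        for name, (_, sd) in self.param_distribution.items():
            if sd < 0:
                raise ConfigError(f"param sd for {name} < 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_subjects": self.n_subjects,
                    "param_distribution": self.param_distribution,
                    "within_subject_sd": self.within_subject_sd,
                    "practice_shift": self.practice_shift,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["param_distribution"] = {k: tuple(v) for k, v in d.get("param_distribution", {}).items()}
        return cls(**d)


def make_task_design(
    n_trials: int = 153,
    blocks: Sequence[tuple[int, float]] = DEFAULT_SCHEDULE,
    cue_set: Sequence[float] = DEFAULT_CUE_SET,
    probe_trials: Sequence[int] = DEFAULT_PROBE_TRIALS,
    pre_task_probe: bool = True,
    stable_fidelity_min: float = 0.7,
    rng: np.random.Generator | int | None = 0,
) -> TaskDesign:
    """Build a :class:`TaskDesign` from a block schedule.

    ``blocks`` is a sequence of ``(length, fidelity)`` pairs whose lengths
    must sum to ``n_trials``. The stable phase is the maximal prefix of
    blocks with fidelity >= ``stable_fidelity_min``; everything after is
    labelled volatile. Cue probabilities are sampled uniformly from
    ``cue_set`` (seeded; pass an int or Generator).

    The default schedule reproduces the canonical 153-trial design: a
    35-trial stable phase of consistently helpful advice followed by a
    118-trial volatile phase of alternating fidelity, with probes at
    trials 14, 49, 73, 99 and 134 plus a pre-task probe on trial 1.
    """
    blocks = [(int(n), float(f)) for n, f in blocks]
    if sum(n for n, _ in blocks) != n_trials:
        raise ConfigError(
            f"block lengths sum to {sum(n for n, _ in blocks)}, expected n_trials={n_trials}"
        )
    fidelity = np.concatenate([np.full(n, f) for n, f in blocks])
    phase: list[str] = []
    in_prefix = True
    for n, f in blocks:
        if in_prefix and f >= stable_fidelity_min:
            phase += ["stable"] * n
        else:
            in_prefix = False
            phase += ["volatile"] * n
    rng = np.random.default_rng(rng)
    cue_prob = rng.choice(np.asarray(cue_set, dtype=float), size=n_trials)
    return TaskDesign(
        fidelity=fidelity,
        cue_prob=cue_prob,
        phase=tuple(phase),
        probe_trials=tuple(int(t) for t in probe_trials),
        pre_task_probe=pre_task_probe,
    )


def sample_advice_outcomes(
    design: TaskDesign, rng: np.random.Generator | int
) -> SessionData:
    """Sample the input side of one session from a design.

    The lottery outcome is drawn first: the pie-chart-favoured option wins
    with probability ``cue_prob[t]``. The advice is then conditioned on
    the realised outcome — it points at the actual winner with probability
    ``fidelity[t]`` (so ``u[t] ~ Bernoulli(fidelity[t])`` marginally). The
    advised-option cue probability ``c[t]`` equals ``cue_prob[t]`` when
    the advice points at the favoured option and ``1 - cue_prob[t]``
    otherwise. Choices ``y``/``win`` are left unset (see
    :func:`advicehgf.hgf.simulate_choices`).
    """
    rng = np.random.default_rng(rng)
    n = design.n_trials
    u = (rng.random(n) < design.fidelity).astype(int)
    favoured_wins = (rng.random(n) < design.cue_prob).astype(int)
    # advice points at winner iff u=1; it is the favoured option iff
    # (winner favoured) == (advice accurate)
    advised_is_favoured = favoured_wins == u
    c = np.where(advised_is_favoured, design.cue_prob, 1.0 - design.cue_prob)
    return SessionData(u=u, c=c, phase=design.phase)


def _draw_params(spec: CohortSpec, rng: np.random.Generator, n: int | None = None) -> list[dict[str, float]]:
    from .fitting import PARAM_BOUNDS  # bounds shared with the fitter

    out = []
    for _ in range(n if n is not None else spec.n_subjects):
        p = {}
        for name, (mean, sd) in spec.param_distribution.items():
            lo, hi = PARAM_BOUNDS.get(name, (-np.inf, np.inf))
            p[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
        out.append(p)
    return out


def perturb_params(
    params: dict[str, float],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Session-2 generating parameters: additive practice shift plus
    within-subject noise, re-clipped to native bounds."""
    from .fitting import PARAM_BOUNDS

    out = dict(params)
    names = set(spec.within_subject_sd) | set(spec.practice_shift)
    for name in sorted(names):
        if name not in out:
            raise ConfigError(f"perturbation for unknown parameter {name!r}")
        shift = spec.practice_shift.get(name, 0.0)
        sd = spec.within_subject_sd.get(name, 0.0)
        lo, hi = PARAM_BOUNDS.get(name, (-np.inf, np.inf))
        out[name] = float(np.clip(out[name] + shift + (rng.normal(0.0, sd) if sd > 0 else 0.0), lo, hi))
    return out


def generate_retest_cohort(
    spec: CohortSpec,
    design: TaskDesign,
    variant: str = "mean_reverting",
):
    """Simulate a paired test-retest cohort of HGF agents.

    Returns a list of per-subject dicts with keys ``params1``, ``params2``
    (generating parameter dicts) and ``session1``, ``session2``
    (simulated :class:`SessionData` including choices). All randomness is
    driven by ``spec.seed``.
    """
    from .fitting import sample_agent_params
    from .hgf import AgentParams, TrajectoryRejection, simulate_choices

    rng = np.random.default_rng(spec.seed)

    def _draw_one():
        if spec.param_distribution:
            return _draw_params(spec, rng, 1)[0]
        # default: generating parameters drawn from the analysis priors,
        # rejection-sampled to be well-posed on the design
        return sample_agent_params(1, variant, rng, design=design)[0]

    def _play(p):
        # redraw inputs a few times if this agent is ill-posed on them
        for _ in range(20):
            inputs = sample_advice_outcomes(design, rng)
            try:
                return simulate_choices(AgentParams(**p), inputs.u, inputs.c,
                                        variant=variant, rng=rng, phase=design.phase)
            except TrajectoryRejection:
                continue
        return None

    cohort = []
    while len(cohort) < spec.n_subjects:
        for _ in range(50):  # redraw the subject if never well-posed
            p1 = _draw_one()
            s1 = _play(p1)
            if s1 is None:
                continue
            for _ in range(50):  # redraw the perturbation likewise
                p2 = perturb_params(p1, spec, rng)
                s2 = _play(p2)
                if s2 is not None:
                    break
            else:
                continue
            break
        else:
            raise ConfigError("could not generate a well-posed subject on this design")
        cohort.append({"params1": p1, "params2": p2, "session1": s1, "session2": s2})
    return cohort


def generate_probe_responses(
    trajectory, design: TaskDesign, tau: float = 0.5
) -> list[ProbeResponse]:
    """Map belief trajectories to explicit fidelity reports.

    At each probe trial the agent reports "helpful" if its predicted
    fidelity log-odds (the level-2 prediction) exceeds ``tau``,
    "misleading" if below ``-tau``, and "random" inside the dead zone.
    The pre-task probe (trial 1) uses the prior prediction before any
    input. ``tau`` defaults to 0.5 log-odds, a symmetric three-way
    partition around indifference.
    """
    muhat2 = np.asarray(trajectory.muhat2, dtype=float)
    probes = list(design.probe_trials)
    if design.pre_task_probe and 1 not in probes:
        probes = [1] + probes
    out = []
    for t in probes:
        if t > len(muhat2):
            raise IndexError(f"probe trial {t} beyond trajectory length {len(muhat2)}")
        m = muhat2[t - 1]
        if m > tau:
            cat = "helpful"
        elif m < -tau:
            cat = "misleading"
        else:
            cat = "random"
        out.append(ProbeResponse(trial=t, category=cat))
    return out
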