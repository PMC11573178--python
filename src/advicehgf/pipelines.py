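"""Orchestration of the four analyses over synthetic cohorts.

* parameter recovery: simulate sessions at known generating parameters,
  refit, and measure generating-vs-recovered agreement (ICC(A,1) and
  Pearson) per parameter, averaged over seeded runs — the upper bound on
  attainable test-retest reliability;
* model recovery: simulate under each model, fit all models, run
  RFX-BMS per run, average protected exceedance probabilities into a
  confusion matrix;
* test-retest reliability: fit each session of a paired cohort
  independently, compute behavioral measures, and assemble the
  reliability report (ICC/Pearson/paired tests after extreme-outlier
  screening) for 6 behavioral + 7 model measures;
* practice effects & face validity: paired-session shifts per measure,
  correlations between per-subject parameter changes and behavioral
  changes, probe-report cross-tabulations and the helpful-vs-misleading
  contrast of the fidelity belief.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import psychometrics as psy
from .bms import EvidenceMatrix, model_recovery_confusion
from .fitting import MODELS, FitFailure, ModelSpec, fit_map, ideal_observer_params, sample_agent_params
from .hgf import AgentParams, filter_beliefs, simulate_choices
from .task import CohortSpec, TaskDesign, generate_probe_responses, generate_retest_cohort, sample_advice_outcomes

__all__ = [
    "RecoveryReport",
    "ReliabilityReport",
    "run_parameter_recovery",
    "run_model_recovery",
    "run_test_retest",
    "run_practice_effects",
    "run_face_validity",
]


def _resolve(model: ModelSpec | str) -> ModelSpec:
    return MODELS[model] if isinstance(model, str) else model


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    # independent integer seeds per run, kept below 2**31
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)]


def _simulate_session(agent: AgentParams, design: TaskDesign, variant: str,
                      rng: np.random.Generator, max_tries: int = 10):
    """Simulate one session, redrawing inputs if the agent's trajectory
    is ill-posed on a particular advice sequence; None if it never is."""
    from .hgf import TrajectoryRejection

    for _ in range(max_tries):
        inputs = sample_advice_outcomes(design, rng)
        try:
            return simulate_choices(agent, inputs.u, inputs.c, variant=variant,
                                    rng=rng, phase=design.phase)
        except TrajectoryRejection:
            continue
    return None


def empirical_like_generating_params(
    design: TaskDesign,
    n_subjects: int = 39,
    model: ModelSpec | str = "m2",
    seed: int = 0,
    n_starts: int = 5,
) -> list[dict[str, float]]:
    """Generating parameter vectors for the recovery experiment.

    Mirrors the empirical procedure, which reuses fitted parameter
    estimates as generating values: a cohort is drawn from the priors,
    each agent plays one session of the design, the model is MAP-fitted
    once, and the fitted (prior-regularised) estimates become the
    generating values. Raw prior draws are intentionally not used here —
    they carry none of the shrinkage that fitted estimates have, which
    distorts generating-vs-recovered agreement.
    """
    model = _resolve(model)
    rng = np.random.default_rng(seed)
    draws = sample_agent_params(n_subjects, model.variant, rng, design=design)
    out = []
    for i, params in enumerate(draws):
        agent = AgentParams(theta=model.theta, phi3=model.phi3, **params)
        session = _simulate_session(agent, design, model.variant, rng)
        if session is None:  # pragma: no cover - draws are pre-validated
            raise FitFailure("agent never well-posed on this design")
        fit = fit_map(session, model, seed=seed + i, n_starts=n_starts)
        out.append(fit.params_native)
    return out


@dataclass
class RecoveryReport:
    """Generating-vs-recovered agreement per parameter."""

    per_run: pd.DataFrame   # columns: run, seed, param, icc, pearson
    summary: pd.DataFrame   # index: param; icc_mean, icc_se, pearson_mean, pearson_se
    n_runs: int
    seeds: list[int]
    n_fit_failures: int

    def icc(self, param: str) -> float:
        return float(self.summary.loc[param, "icc_mean"])

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "summary": self.summary.reset_index().to_dict(orient="records"),
                    "per_run": self.per_run.to_dict(orient="records"),
                    "n_runs": self.n_runs,
                    "seeds": self.seeds,
                    "n_fit_failures": self.n_fit_failures,
                },
                fh,
                indent=1,
            )


def run_parameter_recovery(
    generating_params: list[dict[str, float]],
    design: TaskDesign,
    model: ModelSpec | str = "m2",
    n_runs: int = 20,
    seed: int = 0,
    n_starts: int = 5,
) -> RecoveryReport:
    """Simulate-and-refit recovery of the free parameters.

    For each run, every generating agent plays one session of the design
    (fresh advice/outcome draws and fresh decision noise per run), the
    model is refit by MAP, and per-parameter ICC(A,1) and Pearson r
    between generating and recovered values are computed; runs are then
    averaged. Fit failures are excluded pairwise and counted.
    """
    model = _resolve(model)
    names = model.free_params
    seeds = _run_seeds(seed, n_runs)
    rows, n_fail = [], 0
    for run, run_seed in enumerate(seeds):
        rng = np.random.default_rng(run_seed)
        gen_vals: dict[str, list[float]] = {nm: [] for nm in names}
        rec_vals: dict[str, list[float]] = {nm: [] for nm in names}
        for params in generating_params:
            agent = AgentParams(theta=model.theta, phi3=model.phi3, **params)
            session = _simulate_session(agent, design, model.variant, rng)
            if session is None:
                n_fail += 1
                continue
            try:
                fit = fit_map(session, model, seed=run_seed, n_starts=n_starts)
            except FitFailure:
                n_fail += 1
                continue
            for nm in names:
                gen_vals[nm].append(params[nm])
                rec_vals[nm].append(fit.params_native[nm])
        for nm in names:
            g, r = np.asarray(gen_vals[nm]), np.asarray(rec_vals[nm])
            icc = psy.icc_a1(g, r).icc
            pear = float(stats.pearsonr(g, r).statistic)
            rows.append({"run": run, "seed": run_seed, "param": nm, "icc": icc, "pearson": pear})
    per_run = pd.DataFrame(rows)
    grp = per_run.groupby("param", sort=False)
    summary = pd.DataFrame(
        {
            "icc_mean": grp["icc"].mean(),
            "icc_se": grp["icc"].sem(ddof=1) if n_runs > 1 else 0.0,
            "pearson_mean": grp["pearson"].mean(),
            "pearson_se": grp["pearson"].sem(ddof=1) if n_runs > 1 else 0.0,
        }
    ).loc[list(names)]
    return RecoveryReport(per_run=per_run, summary=summary, n_runs=n_runs,
                          seeds=seeds, n_fit_failures=n_fail)


def run_model_recovery(
    design: TaskDesign,
    n_subjects: int = 39,
    models: tuple[str, ...] = ("m1", "m1b", "m2", "m2b"),
    n_runs: int = 20,
    seed: int = 0,
    n_starts: int = 5,
) -> pd.DataFrame:
    """PEP confusion matrix over the model space.

    For each generating model, simulates a cohort (parameters drawn from
    the priors; ideal-observer models get ideal perceptual parameters and
    prior-drawn response parameters), fits every model in the space to
    each session, runs RFX-BMS per run and averages the protected
    exceedance probabilities. Rows: generating model; columns: fitted.
    """
    seeds = _run_seeds(seed, n_runs)
    evidence: dict[str, list[EvidenceMatrix]] = {g: [] for g in models}
    for run_seed in seeds:
        rng = np.random.default_rng(run_seed)
        for gen_name in models:
            gen = MODELS[gen_name]
            draws = sample_agent_params(n_subjects, gen.variant, rng, design=design)
            lme = np.empty((n_subjects, len(models)))
            for i, params in enumerate(draws):
                if gen.perceptual_mode == "ideal_fixed":
                    inputs = sample_advice_outcomes(design, rng)
                    perc = ideal_observer_params(inputs.u, gen)
                    params = {**perc, "zeta": params["zeta"], "nu": params["nu"]}
                    agent = AgentParams(theta=gen.theta, phi3=gen.phi3, **params)
                    session = simulate_choices(agent, inputs.u, inputs.c, variant=gen.variant,
                                               rng=rng, phase=design.phase)
                else:
                    agent = AgentParams(theta=gen.theta, phi3=gen.phi3, **params)
                    session = _simulate_session(agent, design, gen.variant, rng)
                    if session is None:  # pragma: no cover - extremely rare after validation
                        raise FitFailure(f"agent drawn for {gen_name} never well-posed")
                io_cache: dict[str, dict[str, float]] = {}
                for j, fit_name in enumerate(models):
                    spec = MODELS[fit_name]
                    fixed = None
                    if spec.perceptual_mode == "ideal_fixed":
                        # one ideal-observer optimisation per session and variant
                        if spec.variant not in io_cache:
                            io_cache[spec.variant] = ideal_observer_params(session.u, spec)
                        fixed = io_cache[spec.variant]
                    lme[i, j] = fit_map(session, fit_name, seed=run_seed, n_starts=n_starts,
                                        fixed_perceptual=fixed).lme
            evidence[gen_name].append(EvidenceMatrix(lme=lme, models=models))
    return model_recovery_confusion(evidence, seed=seed)


_COMPUTATIONAL = ("mu2_0", "mu3_0", "m3", "kappa2", "omega2", "zeta", "nu")


@dataclass
class ReliabilityReport:
    """Per-measure reliability/practice-effect statistics plus the
    per-subject session measures they were computed from."""

    table: pd.DataFrame        # index: measure; icc, ci_low, ci_high, pearson, t, p, d, bf01, n, outliers_removed
    per_subject: pd.DataFrame  # columns: subject, session, <measures...>
    model: str
    n_dropped_fits: int = 0
    fits: list = field(default_factory=list, repr=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "model": self.model,
            "n_dropped_fits": self.n_dropped_fits,
            "measures": {
                m: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for m, row in self.table.to_dict(orient="index").items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _reliability_row(x, y):
    """ICC/Pearson/paired block for one measure after extreme-outlier
    screening (a pair is dropped if either session's value is flagged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    out = tukey_pair_mask(x[finite], y[finite])
    xk, yk = x[finite][~out], y[finite][~out]
    icc = psy.icc_a1(xk, yk)
    pear = float(stats.pearsonr(xk, yk).statistic)
    try:
        cmp_ = psy.paired_comparison(xk, yk)
        t, p, d, bf01 = cmp_.t, cmp_.p, cmp_.cohens_d, cmp_.bf01
    except ValueError:
        t = p = d = bf01 = float("nan")
    return {
        "icc": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high,
        "pearson": pear, "t": t, "p": p, "d": d, "bf01": bf01,
        "n": len(xk), "outliers_removed": int(out.sum()),
    }


def tukey_pair_mask(x, y) -> np.ndarray:
    """Pairs flagged as extreme outliers in either session."""
    return psy.tukey_extreme_outliers(x) | psy.tukey_extreme_outliers(y)


def run_test_retest(
    cohort: list[dict],
    model: ModelSpec | str = "m2",
    seed: int = 0,
    n_starts: int = 5,
    keep_fits: bool = False,
) -> ReliabilityReport:
    """Test-retest reliability of behavioral and computational measures.

    Fits the model to each subject's two sessions independently (same
    fixed priors), computes the six behavioral measures per session, and
    assembles per-measure ICC(A,1) with CI, Pearson's r and the paired
    t/BF01 block, after removing extreme-outlier pairs. Subjects whose
    fit fails in either session are dropped listwise.
    """
    model = _resolve(model)
    param_names = [p for p in _COMPUTATIONAL if p in model.free_params]
    rows, fits, n_dropped = [], [], 0
    for subj, entry in enumerate(cohort):
        rec = {}
        try:
            for s, key in enumerate(("session1", "session2"), start=1):
                session = entry[key]
                fit = fit_map(session, model, seed=seed + subj, n_starts=n_starts)
                meas = psy.behavioral_measures(session).to_dict()
                rec[s] = {"subject": subj, "session": s, **meas,
                          **{p: fit.params_native[p] for p in param_names}}
                if keep_fits:
                    fits.append(fit)
        except FitFailure:
            n_dropped += 1
            continue
        rows += [rec[1], rec[2]]
    per_subject = pd.DataFrame(rows)
    measures = list(psy.BEHAVIORAL_MEASURE_NAMES) + param_names
    s1 = per_subject[per_subject.session == 1].set_index("subject")
    s2 = per_subject[per_subject.session == 2].set_index("subject")
    table = pd.DataFrame({m: _reliability_row(s1[m], s2[m]) for m in measures}).T
    return ReliabilityReport(table=table, per_subject=per_subject,
                             model=model.name, n_dropped_fits=n_dropped, fits=fits)


def run_practice_effects(
    report: ReliabilityReport,
    behavioral: tuple[str, ...] = ("advice_taking_total", "advice_taking_stable", "win_stay"),
) -> dict:
    """Practice-effect tests and the parameter-vs-behaviour change map.

    Returns the per-measure paired-comparison table (already part of the
    reliability report) together with the Pearson correlation matrix of
    per-subject session-2-minus-session-1 changes: model parameters in
    rows, behavioral measures in columns, with the matching p values.
    """
    per = report.per_subject
    s1 = per[per.session == 1].set_index("subject")
    s2 = per[per.session == 2].set_index("subject")
    params = [p for p in _COMPUTATIONAL if p in per.columns]
    r = pd.DataFrame(index=params, columns=list(behavioral), dtype=float)
    pvals = r.copy()
    for p in params:
        dp = (s2[p] - s1[p]).to_numpy(float)
        for b in behavioral:
            db = (s2[b] - s1[b]).to_numpy(float)
            keep = np.isfinite(dp) & np.isfinite(db)
            res = stats.pearsonr(dp[keep], db[keep])
            r.loc[p, b] = res.statistic
            pvals.loc[p, b] = res.pvalue
    paired = report.table[["t", "p", "d", "bf01", "n"]].copy()
    return {"paired_tests": paired, "delta_correlations": r, "delta_pvalues": pvals}


def run_face_validity(
    cohort: list[dict],
    design: TaskDesign,
    model: ModelSpec | str = "m2",
    tau: float = 0.5,
    seed: int = 0,
    n_starts: int = 5,
    session_key: str = "session1",
    params_key: str = "params1",
    refit: bool = True,
) -> dict:
    """Face validity of the task and of the fidelity belief.

    Probe reports are produced by the generating agents' own belief
    trajectories (the synthetic analog of participants' explicit
    reports). Two checks follow: (i) a cross-tabulation of report
    category against the true adviser fidelity at each probe trial —
    the task manipulation should be visible in the reports; (ii) the
    model-derived fidelity belief (the level-2 prediction, recomputed
    from *refitted* parameters when ``refit=True``) grouped by report
    category, with a Welch t-test of helpful vs misleading probes.
    """
    model = _resolve(model)
    probe_rows = []
    mu2_by_cat: dict[str, list[float]] = {"helpful": [], "random": [], "misleading": []}
    for subj, entry in enumerate(cohort):
        session = entry[session_key]
        gen_agent = AgentParams(theta=model.theta, phi3=model.phi3, **entry[params_key])
        gen_traj = filter_beliefs(gen_agent, session.u, variant=model.variant)
        reports = generate_probe_responses(gen_traj, design, tau=tau)
        if refit:
            fit = fit_map(session, model, seed=seed + subj, n_starts=n_starts)
            agent = model.make_agent(fit.params_native,
                                     fit.diagnostics.get("fixed_perceptual"))
            traj = filter_beliefs(agent, session.u, variant=model.variant)
        else:
            traj = gen_traj
        for rep in reports:
            fid = float(design.fidelity[rep.trial - 1])
            probe_rows.append({"subject": subj, "trial": rep.trial,
                               "category": rep.category, "true_fidelity": fid})
            mu2_by_cat[rep.category].append(float(traj.muhat2[rep.trial - 1]))
    probes = pd.DataFrame(probe_rows)
    crosstab = pd.crosstab(probes["trial"], probes["category"])
    group_means = {k: (float(np.mean(v)) if v else float("nan")) for k, v in mu2_by_cat.items()}
    h, m = mu2_by_cat["helpful"], mu2_by_cat["misleading"]
    if len(h) >= 2 and len(m) >= 2:
        tt = stats.ttest_ind(h, m, equal_var=False)
        contrast = {"t": float(tt.statistic), "p": float(tt.pvalue),
                    "mean_helpful": group_means["helpful"],
                    "mean_misleading": group_means["misleading"],
                    "n_helpful": len(h), "n_misleading": len(m)}
    else:
        contrast = {"t": float("nan"), "p": float("nan"), **group_means,
                    "n_helpful": len(h), "n_misleading": len(m),
                    "note": "empty category group"}
    return {"probes": probes, "crosstab": crosstab,
            "mu2hat_group_means": group_means, "helpful_vs_misleading": contrast}
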