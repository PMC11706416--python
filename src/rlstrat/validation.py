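"""Generate-and-recover and posterior-predictive validation.

Parameter recovery: sample generating parameters from a documented
prior, simulate sessions, refit, and correlate recovered with generating
values (Spearman, rank-based so any monotone reporting scale gives the
same answer).  Posterior predictive: re-simulate each fitted session on
a fresh schedule of the same design and compare trial-history regression
coefficients and learning curves between source and simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import metrics, models, regressions, task
from .fitting import fit_cohort


@dataclass
class RecoveryReport:
    model: str
    correlations: pd.DataFrame       # parameter, rho, p, n
    scatter: pd.DataFrame            # session, parameter, generated, recovered
    n_sessions: int
    frac_converged: float
    valid: bool                      # False if < 50% of fits converged


@dataclass
class PredictiveReport:
    coefficients: pd.DataFrame       # session_id, term, source, simulated
    coefficient_correlations: pd.DataFrame  # term, r, p, n
    curves: pd.DataFrame             # session_id, origin, odor, bin, fraction_correct
    fits: pd.DataFrame = field(repr=False, default=None)


def recover(
    model: str | models.ModelSpec = models.WINNING_MODEL,
    prior: task.GroundTruthPrior | None = None,
    n_sessions: int = 30,
    session_spec: task.SessionSpec | None = None,
    n_starts: int = 20,
    seed: int | None = None,
) -> RecoveryReport:
    """Simulate -> refit -> Spearman-correlate per free parameter.

    Defaults mirror a desk-scale identifiability study: 30 set-size-2
    sessions of 400 trials.  Correlations use converged fits only; a
    degenerate generating distribution (zero variance) yields NaN rho,
    reported as such.
    """
    spec = models.get_model(model)
    prior = prior or task.GroundTruthPrior()
    session_spec = session_spec or task.SessionSpec(set_size=2, presentations_per_odor=200)
    if n_sessions < 2:
        raise ValueError("recovery needs at least 2 sessions")
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]

    truth = task.sample_ground_truth(prior, n_sessions, seed=seeds[0], model=spec)
    sessions = task.generate_sessions(n_sessions, session_spec, truth, model=spec, seed=seeds[1])
    fits = fit_cohort(sessions, [spec.name], n_starts=n_starts, seed=seeds[2])
    fits = fits.set_index("session_id")

    rows, scatter = [], []
    conv = fits["converged"].astype(bool)
    for j, pname in enumerate(spec.free):
        gen = np.array([truth[i][pname] for i in range(n_sessions)])
        rec = fits[pname].to_numpy(dtype=float)
        mask = conv.to_numpy() & np.isfinite(rec)
        for i in range(n_sessions):
            scatter.append({"session_id": fits.index[i], "parameter": pname,
                            "generated": gen[i], "recovered": rec[i],
                            "converged": bool(mask[i])})
        if mask.sum() < 3 or np.std(gen[mask]) == 0 or np.std(rec[mask]) == 0:
            rows.append({"parameter": pname, "rho": np.nan, "p": np.nan, "n": int(mask.sum())})
            continue
        rho, p = spearmanr(gen[mask], rec[mask])
        rows.append({"parameter": pname, "rho": float(rho), "p": float(p), "n": int(mask.sum())})
    frac = float(conv.mean())
    return RecoveryReport(
        model=spec.name,
        correlations=pd.DataFrame(rows),
        scatter=pd.DataFrame(scatter),
        n_sessions=n_sessions,
        frac_converged=frac,
        valid=frac >= 0.5,
    )


def posterior_predictive(
    fits: pd.DataFrame,
    source_sessions: pd.DataFrame,
    session_spec: task.SessionSpec | None = None,
    regression_id: int = 3,
    seed: int | None = None,
    reuse_schedule: bool = False,
) -> PredictiveReport:
    """Simulate each fitted session and compare regressions and curves.

    ``fits`` is a fit-cohort table (one row per session for one model).
    By default each session is re-simulated on a *fresh* schedule of the
    same design (testing the model rather than schedule memorization);
    ``reuse_schedule=True`` replays the source session's stimulus order.
    """
    session_spec = session_spec or task.SessionSpec(set_size=2, presentations_per_odor=200)
    ss = np.random.SeedSequence(seed)
    sim_frames = []
    for _, row in fits.iterrows():
        sid = row["session_id"]
        params = {k: float(row[k]) for k in models.PARAM_NAMES}
        child = ss.spawn(2)
        s_sched = int(child[0].generate_state(1)[0] % (2**31))
        s_agent = int(child[1].generate_state(1)[0] % (2**31))
        if reuse_schedule:
            src = source_sessions[source_sessions["session_id"] == sid].sort_values("trial_index")
            sched = task.StimulusSchedule(
                odor_ids=tuple(src["odor_id"]),
                correct_side=dict(zip(src["odor_id"], src["correct_side"])),
            )
        else:
            from dataclasses import replace
            sched = task.build_schedule(replace(session_spec, seed=s_sched))
        sim_frames.append(
            task.simulate_session(sched, params, row["model"], seed=s_agent, session_id=sid)
        )
    simulated = pd.concat(sim_frames, ignore_index=True)

    src_coef, _ = regressions.fit_sessions(source_sessions, [regression_id])
    sim_coef, _ = regressions.fit_sessions(simulated, [regression_id])
    merged = src_coef.merge(
        sim_coef, on=["session_id", "regression_id", "term"], suffixes=("_source", "_sim")
    )[["session_id", "term", "estimate_source", "estimate_sim"]]
    merged = merged.rename(columns={"estimate_source": "source", "estimate_sim": "simulated"})

    corr_rows = []
    for term, grp in merged.groupby("term"):
        x, y = grp["source"].to_numpy(), grp["simulated"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            corr_rows.append({"term": term, "r": np.nan, "p": np.nan, "n": int(ok.sum())})
            continue
        r, p = pearsonr(x[ok], y[ok])
        corr_rows.append({"term": term, "r": float(r), "p": float(p), "n": int(ok.sum())})

    src_curves, _ = metrics.session_metrics(source_sessions)
    sim_curves, _ = metrics.session_metrics(simulated)
    src_curves.insert(0, "origin", "source")
    sim_curves.insert(0, "origin", "simulated")
    return PredictiveReport(
        coefficients=merged,
        coefficient_correlations=pd.DataFrame(corr_rows),
        curves=pd.concat([src_curves, sim_curves], ignore_index=True),
        fits=fits,
    )
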