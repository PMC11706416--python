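"""End-to-end pipeline: simulate -> fit -> compare -> regress -> metrics -> validate.

A run is described by a :class:`RunConfig` (loadable from YAML), executed
into a single output directory with a JSON manifest recording per-stage
status, output files and SHA-256 hashes.  All randomness flows from the
single config seed through named substreams; a failed stage marks its
dependents skipped rather than crashing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, metrics, models, regressions, selection, task, validation
from .fitting import fit_cohort

log = logging.getLogger("rlstrat")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "rlstrat_run"
    sessions_csv: str | None = None      # if None, simulate instead
    simulate: bool = True
    n_sessions: int = 10
    set_size: int = 2
    presentations_per_odor: int = 200
    generating_model: str = models.WINNING_MODEL
    models: list[str] = field(default_factory=lambda: list(models.REGISTRY_NAMES))
    n_starts: int = 20
    regression_ids: list[int] = field(default_factory=lambda: list(regressions.REGRESSION_IDS))
    run_validation: bool = False
    recovery_sessions: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for m in [self.generating_model, *self.models]:
            models.get_model(m)  # raises ModelError on unknown names
        task.SessionSpec(set_size=self.set_size,
                         presentations_per_odor=self.presentations_per_odor)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _substream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"config": asdict(config), "stages": {}}
    state: dict = {}

    def stage(name: str, deps: list[str], fn):
        entry = {"status": "ok", "outputs": []}
        failed_dep = next(
            (d for d in deps if manifest["stages"].get(d, {}).get("status") != "ok"), None
        )
        if failed_dep is not None:
            entry["status"] = "skipped"
            entry["reason"] = f"dependency {failed_dep} failed"
            manifest["stages"][name] = entry
            log.info("stage %s skipped (%s failed)", name, failed_dep)
            return
        try:
            log.info("stage %s: start (seed substream %d)", name, _substream(config.seed, name))
            outputs = fn() or []
            entry["outputs"] = [
                {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in outputs
            ]
        except Exception as exc:  # recorded, not raised
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed:\n%s", name, traceback.format_exc())
        manifest["stages"][name] = entry

    def s_sessions():
        if config.sessions_csv:
            state["sessions"] = io.read_sessions(config.sessions_csv)
            return []
        spec = task.SessionSpec(set_size=config.set_size,
                                presentations_per_odor=config.presentations_per_odor)
        prior = task.GroundTruthPrior()
        params = task.sample_ground_truth(
            prior, config.n_sessions, seed=_substream(config.seed, "truth"),
            model=config.generating_model,
        )
        state["sessions"] = task.generate_sessions(
            config.n_sessions, spec, params, model=config.generating_model,
            seed=_substream(config.seed, "taskgen"),
        )
        truth = pd.DataFrame(params)
        truth.insert(0, "session_id", [f"sim{i}" for i in range(config.n_sessions)])
        truth.to_csv(out / "ground_truth.csv", index=False)
        io.write_sessions(state["sessions"], out / "sessions.csv")
        return [out / "sessions.csv", out / "ground_truth.csv"]

    def s_fit():
        state["fits"] = fit_cohort(
            state["sessions"], config.models, n_starts=config.n_starts,
            seed=_substream(config.seed, "fitting"),
        )
        state["fits"].to_csv(out / "fits.csv", index=False)
        return [out / "fits.csv"]

    def s_compare():
        ev = selection.evidence_from_fits(state["fits"], config.models)
        res = selection.group_bms(ev, seed=_substream(config.seed, "bms"))
        io.write_json(res.to_dict(), out / "bms.json")
        winners, mean_bic = selection.select_by_bic(state["fits"])
        pd.DataFrame({"winner": winners}).to_csv(out / "bic_winners.csv")
        mean_bic.to_frame().to_csv(out / "mean_bic.csv")
        return [out / "bms.json", out / "bic_winners.csv", out / "mean_bic.csv"]

    def s_regress():
        coef, crit = regressions.fit_sessions(state["sessions"], config.regression_ids)
        coef.to_csv(out / "coefficients.csv", index=False)
        crit.to_csv(out / "criteria.csv", index=False)
        return [out / "coefficients.csv", out / "criteria.csv"]

    def s_metrics():
        curves, splits = metrics.session_metrics(state["sessions"])
        curves.to_csv(out / "curves.csv", index=False)
        splits.to_csv(out / "splits.csv", index=False)
        return [out / "curves.csv", out / "splits.csv"]

    def s_validate():
        if not config.run_validation:
            return []
        rep = validation.recover(
            model=config.generating_model, n_sessions=config.recovery_sessions,
            n_starts=config.n_starts, seed=_substream(config.seed, "recovery"),
        )
        rep.correlations.to_csv(out / "recovery.csv", index=False)
        return [out / "recovery.csv"]

    stage("sessions", [], s_sessions)
    stage("fit", ["sessions"], s_fit)
    stage("compare", ["fit"], s_compare)
    stage("regress", ["sessions"], s_regress)
    stage("metrics", ["sessions"], s_metrics)
    stage("validate", [], s_validate)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.removeHandler(handler)
    handler.close()
    return manifest
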