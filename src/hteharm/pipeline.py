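"""Configuration-driven end-to-end pipeline with artifact provenance.

Wires the stages — simulate (optional), split selection, discretization,
forest, hypothesis distillation, Cox validation, blood-pressure mechanisms —
into one run that writes every intermediate artifact (CSV for tables, JSON
for structured results, YAML for configuration) plus a manifest with the
config hash and derived stage seeds.  A second run with an identical config
reproduces all result files byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prep
from .forest import ForestParams
from .io import baseline_summary, read_trial_table
from .mechanism import mechanism_contrast, summarize_pressures
from .model import HarmDiscovery
from .simulate import (
    SimConfig,
    TRUTH_COLUMNS,
    generate_adverse_events,
    generate_bp_trajectories,
    generate_cohort,
    write_simulation,
)
from .validation import adverse_event_cox

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either ``simulate`` holds a :class:`SimConfig`, or ``cohort_path`` (and
    optionally ``visits_path`` / ``adverse_events_path``) name existing CSVs.
    """

    simulate: SimConfig | None = None
    cohort_path: str | None = None
    visits_path: str | None = None
    adverse_events_path: str | None = None
    n_bins: int = 4
    n_split_candidates: int = 1000
    forest: ForestParams = field(default_factory=ForestParams)
    top_k: int = 5
    max_conditions: int = 3
    rank_by: str = "support"
    n_permutations: int = 1000
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    horizon: float | None = None
    ties: str = "breslow"
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.simulate is None and self.cohort_path is None:
            raise ValueError("config needs either a simulate block or a cohort_path")
        if self.simulate is None:
            for p in (self.cohort_path, self.visits_path, self.adverse_events_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
        for thr in (self.alpha, self.fdr_threshold):
            if not 0 < thr < 1:
                raise ValueError("alpha and fdr_threshold must be in (0, 1)")

    def to_yaml(self) -> str:
        # outdir is deliberately not serialized: the config describes the
        # analysis, so identical analyses hash identically wherever written
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        if self.simulate is not None:
            d["simulate"] = yaml.safe_load(self.simulate.to_yaml())
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "forest" in d and isinstance(d["forest"], dict):
            d["forest"] = ForestParams(**d["forest"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle.

    Returns ``{"results": HarmDiscoveryResults, "manifest": dict,
    "outdir": Path}``.  Stage failures abort with the stage name attached;
    artifacts written so far stay on disk next to a ``FAILED`` marker.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else Path(f"hteharm-run-{config.config_hash()}")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())

    stage = "setup"
    try:
        # -- data -----------------------------------------------------------
        visits = adverse = None
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            cohort_full = generate_cohort(sim)
            visits = generate_bp_trajectories(cohort_full, sim)
            adverse = generate_adverse_events(cohort_full, sim)
            write_simulation(outdir, cohort_full, visits, adverse, sim)
            cohort = cohort_full.drop(columns=list(TRUTH_COLUMNS))
        else:
            stage = "read"
            cohort = read_trial_table(config.cohort_path)
            if config.visits_path:
                visits = pd.read_csv(config.visits_path)
            if config.adverse_events_path:
                adverse = pd.read_csv(config.adverse_events_path)

        # -- discovery + validation ----------------------------------------
        stage = "fit"
        model = HarmDiscovery(
            cohort,
            n_bins=config.n_bins,
            n_split_candidates=config.n_split_candidates,
            forest_params=dataclasses.replace(config.forest),
            top_k=config.top_k,
            max_conditions=config.max_conditions,
            rank_by=config.rank_by,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            fdr_threshold=config.fdr_threshold,
            horizon=config.horizon,
            ties=config.ties,
            seed=config.seed,
        )
        log.info("fitting discovery pipeline (n=%d)", len(cohort))
        results = model.fit()

        stage = "write"
        results.split.labels.rename("partition").to_frame().assign(id=cohort["id"].to_numpy())[
            ["id", "partition"]
        ].to_csv(outdir / "split_assignment.csv", index=False)
        _write_json(
            outdir / "balance_report.json",
            {
                "selected_candidate": results.split.candidate,
                "selected_score": results.split.score,
                "n_candidates": results.n_candidates_scored,
                "smd": results.split.smd,
            },
        )
        _write_json(outdir / "cutpoints.json", results.cutpoints.to_dict())
        (outdir / "forest.json").write_text(results.forest.to_json())
        results.forest.leaf_census().to_csv(outdir / "leaf_census.csv", index=False)
        results.covariate_frequencies.to_csv(outdir / "covariate_frequency.csv", index=False)
        _write_json(outdir / "hypotheses.json", [h.to_dict() for h in results.hypotheses])
        _write_json(
            outdir / "validation_results.json",
            {
                "harm_fraction": results.harm_fraction,
                "n_leaves": results.forest.n_leaves,
                "hypotheses": [v.to_dict() for v in results.validations],
            },
        )
        baseline_summary(cohort, results.split.labels).to_csv(outdir / "baseline_table.csv", index=False)
        _table2(results).to_csv(outdir / "table2.csv", index=False)

        # -- mechanisms -----------------------------------------------------
        if visits is not None and len(visits) and results.hypotheses:
            stage = "mechanism"
            hyp = results.hypotheses[0]
            member = hyp.membership(results.test)
            traj = visits[visits["id"].isin(results.test["id"])]
            summarize_pressures(traj, results.test, member).to_csv(outdir / "pressure_summary.csv", index=False)
            contrasts = {
                q: mechanism_contrast(traj, results.test, member, quantity=q).to_dict()
                for q in ("map", "sbp", "dbp")
            }
            _write_json(outdir / "mechanism_contrasts.json", {"hypothesis": hyp.describe(), "contrasts": contrasts})
        if adverse is not None and len(adverse) and results.hypotheses:
            stage = "adverse_events"
            hyp = results.hypotheses[0]
            member = hyp.membership(results.test)
            test_ids = results.test["id"]
            ae = adverse[adverse["id"].isin(test_ids)]
            if ae["event_type"].nunique() and ae.shape[0]:
                try:
                    aec = adverse_event_cox(results.test, ae, member, event_type=ae["event_type"].iloc[0])
                    _write_json(
                        outdir / "adverse_event_results.json",
                        {
                            "hypothesis": hyp.describe(),
                            "subgroup": aec["subgroup"].to_dict() if aec["subgroup"] is not None else None,
                            "remainder": aec["remainder"].to_dict() if aec["remainder"] is not None else None,
                            "frequency": aec["frequency"].to_dict(),
                        },
                    )
                except ValueError as exc:
                    _write_json(outdir / "adverse_event_results.json", {"error": str(exc)})

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": {s: model._stage_seed(s) for s in ("split", "forest", "permutation")},
            "n_participants": int(len(cohort)),
            "artifacts": sorted({p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}),
            "package": "hteharm",
            "version": __import__("hteharm").__version__,
        }
        _write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {"results": results, "manifest": manifest, "outdir": outdir}


def _table2(results) -> pd.DataFrame:
    """Outcome-by-arm layout: overall, subgroup, remainder rows per hypothesis."""
    rows = []
    test = results.test
    for aname, aval in (("treated", 1), ("control", 0)):
        m = test["arm"] == aval
        rows.append(
            {
                "hypothesis": "",
                "group": "overall",
                "arm": aname,
                "n": int(m.sum()),
                "events": int(test.loc[m, "event"].sum()),
            }
        )
    for v in results.validations:
        for rec in v.frequency.table.to_dict(orient="records"):
            rec = {"hypothesis": v.hypothesis.describe(), **rec}
            if v.interaction is not None and v.interaction.converged and rec["group"] == "subgroup":
                if v.within_subgroup is not None and v.within_subgroup.converged:
                    rec["hr"] = v.within_subgroup.hr["treatment"]
                    rec["hr_ci_low"] = v.within_subgroup.ci_low["treatment"]
                    rec["hr_ci_high"] = v.within_subgroup.ci_high["treatment"]
                    rec["p"] = v.within_subgroup.p["treatment"]
            rows.append(rec)
    return pd.DataFrame(rows)
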