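"""End-to-end pipeline: simulate -> validate -> score -> compare -> regress -> rf.

Mirrors the cohort-analysis sequence: generate (or load) the two-table cohort,
validate every panel against the gating invariants, compute IMM-AGE scores,
compare scores across HC and trauma timepoints (ANOVA + Bonferroni), run the
univariate regressions (score vs age in HC; score vs ISS / IL6 / ICU stay in
trauma day 3), and rank sepsis-associated features with the random forest on
day-3 trauma samples.  Every artifact embeds the global seed and a config
hash; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .immage import ImmAgeConfig, compute_immage
from .io import cohort_summary, read_panels_frame, read_subjects_frame
from .phenotype import PhenotypePanel, validate_panel
from .sepsis import SepsisForestRanker, univariate_feature_tests
from .stats import anova_bonferroni, univariate_regression
from .synthetic import SimConfig, write_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_pipeline_config"]

STAGES = ("simulate", "validate", "immage", "compare", "regress", "rf")

#: default random-forest feature columns (subjects table + panel + score)
RF_DEFAULT_FEATURES = [
    "lymphocytes_1e9_per_L", "il6_pg_ml", "tnfa_pg_ml", "il10_pg_ml", "crp_mg_ml",
    "tcell_of_lymphs", "cd4_of_t", "cd8_of_t", "cd4_naive", "cd8_naive",
    "cd8_cd28neg", "cd8_senescent", "treg_of_cd4", "rte_of_naive_cd4",
    "immage_score",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "immflow_out"
    seed: int = 0
    #: simulate when set; otherwise subjects_path/panels_path must exist
    sim: SimConfig | None = field(default_factory=SimConfig)
    subjects_path: str | None = None
    panels_path: str | None = None
    immage: ImmAgeConfig = field(default_factory=ImmAgeConfig)
    #: random-forest block; set to None to skip the rf stage
    rf: dict | None = field(default_factory=lambda: {
        "n_trees": 500, "timepoint_day": 3, "features": RF_DEFAULT_FEATURES,
    })
    log_level: str = "INFO"


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline YAML (keys: out_dir, seed, sim, immage, rf, ...)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "out_dir" in raw:
        cfg.out_dir = raw["out_dir"]
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "subjects_path" in raw or "panels_path" in raw:
        cfg.subjects_path = raw.get("subjects_path")
        cfg.panels_path = raw.get("panels_path")
        cfg.sim = None
    if raw.get("sim") is not None:
        sim = dict(raw["sim"])
        for key in ("timepoints", "age_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg.sim = SimConfig(**sim)
    if "immage" in raw:
        cfg.immage = ImmAgeConfig(**{
            k: (tuple(v) if k == "features" else v) for k, v in raw["immage"].items()
        })
    if "rf" in raw:
        cfg.rf = raw["rf"]
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    d = dataclasses.asdict(cfg)
    d.pop("out_dir", None)  # where results land must not change what they are
    d.pop("log_level", None)
    blob = json.dumps(d, default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written to disk).

    Fails fast with :class:`PipelineError` naming the stage; artifacts written
    before the failure are retained next to a ``FAILED`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    manifest: dict = {
        "seed": config.seed, "config_hash": chash,
        "version": __version__, "stages": {}, "counts": {},
    }
    stage = "simulate"
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            subjects_path, panels_path = write_cohort(sim, out)
            manifest["stages"]["simulate"] = "completed"
        else:
            if not config.subjects_path or not config.panels_path:
                raise PipelineError("no sim block and no input table paths")
            subjects_path, panels_path = Path(config.subjects_path), Path(config.panels_path)
            manifest["stages"]["simulate"] = "skipped"
        subjects = read_subjects_frame(subjects_path)
        panels = read_panels_frame(panels_path)

        stage = "validate"
        freq_cols = [c for c in panels.columns if c != "subject_id"]
        n_violations = 0
        for _, row in panels.iterrows():
            p = PhenotypePanel(str(row["subject_id"]),
                               {c: float(row[c]) for c in freq_cols})
            n_violations += len(validate_panel(p))
        manifest["counts"]["panel_violations"] = n_violations
        manifest["counts"].update(cohort_summary(subjects))
        manifest["stages"]["validate"] = "completed"

        stage = "immage"
        result = compute_immage(panels, config.immage)
        scores = pd.DataFrame({"subject_id": result.scores.index,
                               "immage_score": result.scores.to_numpy()})
        meta = subjects[["subject_id", "group", "timepoint_day", "sepsis"]]
        scores = scores.merge(meta, on="subject_id", how="left")
        excluded = pd.DataFrame({"subject_id": result.excluded_ids})
        scores["excluded_flag"] = 0
        excluded["immage_score"] = np.nan
        excluded["excluded_flag"] = 1
        score_table = pd.concat([scores, excluded], ignore_index=True)
        score_table.to_csv(out / "scores.csv", index=False)
        _json_dump({
            "seed": config.seed, "config_hash": chash,
            "root_id": result.root_id,
            "eigenvalues": [float(v) for v in result.eigenvalues],
            "excluded_ids": result.excluded_ids,
            "trimmed_means": result.trimmed_means,
            "trimmed_sds": result.trimmed_sds,
            "config": dataclasses.asdict(result.config),
        }, out / "immage_diagnostics.json")
        manifest["counts"]["scored_samples"] = int(len(result.scores))
        manifest["counts"]["excluded_samples"] = len(result.excluded_ids)
        manifest["stages"]["immage"] = "completed"

        stage = "compare"
        merged = scores.dropna(subset=["immage_score"]).copy()
        merged["arm"] = np.where(
            merged["group"] == "HC", "HC",
            "day" + merged["timepoint_day"].fillna(-1).astype(int).astype(str),
        )
        arms = {
            name: grp["immage_score"].to_numpy()
            for name, grp in merged.groupby("arm") if len(grp) >= 2
        }
        rows = []
        if len(arms) >= 2:
            contrasts = [("HC", a) for a in sorted(arms) if a != "HC" and "HC" in arms]
            omnibus, posthoc = anova_bonferroni(arms, contrasts or None)
            rows.append({
                "contrast": "omnibus", "statistic_name": "F",
                "statistic": omnibus.statistic, "p_value": omnibus.p_value,
                "adjusted_p": np.nan,
            })
            for r in posthoc:
                rows.append({
                    "contrast": f"{r.groups[0]}_vs_{r.groups[1]}",
                    "statistic_name": "t", "statistic": r.statistic,
                    "p_value": r.p_value, "adjusted_p": r.adjusted_p,
                })
        pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)
        manifest["stages"]["compare"] = "completed"

        stage = "regress"
        sub = subjects.set_index("subject_id")
        merged = merged.set_index("subject_id")
        reg_rows = []

        def _reg(label, frame, xcol, ycol):
            d = frame[[xcol, ycol]].dropna()
            if len(d) >= 3 and d[xcol].nunique() > 1:
                r = univariate_regression(d[xcol], d[ycol])
                reg_rows.append({
                    "regression": label, "slope": r.slope, "intercept": r.intercept,
                    "r_squared": r.r_squared, "f_statistic": r.f_statistic,
                    "p_value": r.p_value, "n": r.n,
                })

        hc = merged[merged["group"] == "HC"].join(sub[["age_years"]])
        _reg("score_vs_age_HC", hc, "age_years", "immage_score")
        d3 = merged[(merged["group"] == "trauma") & (merged["timepoint_day"] == 3)]
        d3 = d3.join(sub[["iss", "il6_pg_ml", "icu_los_days"]])
        _reg("score_vs_iss_day3", d3, "iss", "immage_score")
        _reg("score_vs_il6_day3", d3, "il6_pg_ml", "immage_score")
        _reg("score_vs_icu_los_day3", d3, "icu_los_days", "immage_score")
        pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
        manifest["stages"]["regress"] = "completed"

        stage = "rf"
        if config.rf is None:
            manifest["stages"]["rf"] = "skipped"
        else:
            rf_cfg = dict(config.rf)
            day = rf_cfg.get("timepoint_day", 3)
            feats = rf_cfg.get("features", RF_DEFAULT_FEATURES)
            table = subjects.merge(panels, on="subject_id").merge(
                scores[["subject_id", "immage_score"]], on="subject_id", how="left"
            )
            table = table[(table["group"] == "trauma")
                          & (table["timepoint_day"] == day)]
            feats = [f for f in feats if f in table.columns]
            y = table["sepsis"].astype(float)
            keep = y.notna()
            X = table.loc[keep, feats]
            ranker = SepsisForestRanker(
                n_trees=int(rf_cfg.get("n_trees", 500)),
                mtry=rf_cfg.get("mtry"),
                stratified_bootstrap=bool(rf_cfg.get("stratified_bootstrap", False)),
                random_state=config.seed,
            ).fit(X, y[keep].astype(int))
            uni = univariate_feature_tests(X, y[keep].astype(bool))
            _json_dump({
                "seed": config.seed, "config_hash": chash,
                "timepoint_day": day,
                "ranking": ranker.ranking_,
                "mda": {k: float(v) for k, v in ranker.mda_.items()},
                "oob_accuracy": ranker.oob_accuracy_,
                "confusion": ranker.confusion_.tolist(),
                "n_dropped_missing": ranker.n_dropped_,
                "univariate_p": {k: float(v) for k, v in uni["p_value"].items()},
            }, out / "rf_result.json")
            manifest["stages"]["rf"] = "completed"
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    _json_dump(manifest, out / "manifest.json")
    return manifest
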