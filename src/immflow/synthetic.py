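"""Synthetic trauma / healthy-control cohort generator.

Emulates the structure of a severe-trauma immunophenotyping study: ~55 healthy
controls sampled once and ~57 trauma patients (inclusion ISS > 15) sampled at
days 3, 14, 28 and 60 post-hospitalisation, with gated T/B subset frequencies,
lymphocyte counts, serum cytokines and critical-illness scores.

Everything observable is driven by a single latent "immune age" per sample:
in controls it increases with chronological age plus noise; trauma adds a
positive latent offset that peaks at day 14 (the nadir of naive T cells).
Subset frequencies are compositional (Dirichlet / Beta draws whose means move
with the latent), cytokines are log-normal and right-skewed, elevated further
under sepsis, and sepsis labels come from a logistic model on the day-3
latent — so every downstream stage has planted, recoverable signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phenotype import SUBSET_NAMES, PhenotypePanel, SubjectRecord

__all__ = [
    "SimConfig",
    "ConfigError",
    "generate_cohort",
    "planted_truth",
    "cohort_frames",
    "write_cohort",
    "SUBJECTS_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# --- default feature model -------------------------------------------------
# Percent-scale intercept at latent z = 0 and slope (percentage points per
# latent unit).  Signs follow the immunosenescence gradient: naive pools and
# thymic output shrink, memory/senescent/regulatory pools expand.
_BASELINES: dict[str, float] = {
    "cd4_naive": 45.0, "cd4_cm": 25.0, "cd4_em": 20.0, "cd4_emra": 10.0,
    "cd8_naive": 35.0, "cd8_cm": 14.0, "cd8_em": 26.0, "cd8_emra": 25.0,
    "cd4_cd28neg": 8.0, "cd4_cd57pos": 6.0,
    "cd8_cd28neg": 25.0, "cd8_cd57pos": 20.0,
    "rte_of_naive_cd4": 20.0, "treg_of_cd4": 5.0,
    "b_naive": 60.0, "b_switched_mem": 25.0, "b_unswitched_mem": 10.0,
    "breg_of_b": 7.0,
    "tcell_of_lymphs": 70.0, "bcell_of_lymphs": 12.0,
    "cd4_of_t": 58.0, "cd8_of_t": 36.0,
}

_DEFAULT_SLOPES: dict[str, float] = {
    "cd4_naive": -12.0, "cd4_cm": 3.0, "cd4_em": 6.0, "cd4_emra": 3.0,
    "cd8_naive": -12.0, "cd8_cm": -1.0, "cd8_em": 6.0, "cd8_emra": 7.0,
    "cd4_cd28neg": 4.0, "cd4_cd57pos": 3.0,
    "cd8_cd28neg": 11.0, "cd8_cd57pos": 9.0,
    "rte_of_naive_cd4": -6.0, "treg_of_cd4": 1.8,
    "b_naive": -9.0, "b_switched_mem": 7.0, "b_unswitched_mem": 0.0,
    "breg_of_b": -1.5,
    "tcell_of_lymphs": -6.0, "bcell_of_lymphs": -0.5,
    "cd4_of_t": -4.0, "cd8_of_t": 4.0,
}

# Dirichlet/Beta precision (larger = tighter around the mean).
_DEFAULT_PRECISION: dict[str, float] = {
    "cd4_quartet": 150.0, "cd8_quartet": 150.0,
    "t_lineage_split": 150.0, "lymph_split": 150.0, "b_subsets": 120.0,
    "beta_default": 120.0,
}

# Latent offset added for trauma samples, peaking at day 14.
_DEFAULT_LATENT_OFFSETS: dict[int, float] = {3: 1.1, 14: 1.5, 28: 0.9, 60: 0.5}

# Multiplier on the lymphocyte-count median (nadir day 14, recovery by day 60).
_LYMPH_FACTORS: dict[int, float] = {3: 0.55, 14: 0.50, 28: 0.70, 60: 0.90}

# Cytokine medians for HC (pg/ml; CRP mg/ml) and trauma day multipliers.
_CYTO_HC_MEDIAN = {"il6": 4.0, "tnfa": 0.3, "il10": 2.0, "il8": 5.0, "crp": 2.0}
_CYTO_HC_SIGMA = 0.6
_CYTO_TRAUMA_SIGMA = 0.8
_CYTO_TRAUMA_FACTORS: dict[int, dict[str, float]] = {
    3: {"il6": 12.0, "tnfa": 5.0, "il10": 2.5, "il8": 3.0, "crp": 40.0},
    14: {"il6": 6.0, "tnfa": 4.0, "il10": 2.0, "il8": 2.5, "crp": 25.0},
    28: {"il6": 3.5, "tnfa": 3.0, "il10": 1.5, "il8": 2.0, "crp": 12.0},
    60: {"il6": 2.0, "tnfa": 2.0, "il10": 1.2, "il8": 1.5, "crp": 5.0},
}
_SEPSIS_CYTO_FACTORS = {"il6": 4.0, "tnfa": 3.0, "il10": 1.8, "il8": 1.5, "crp": 1.9}


@dataclass
class SimConfig:
    """Cohort-generator configuration (defaults emulate the study design)."""

    n_controls: int = 55
    n_trauma: int = 57
    timepoints: tuple[int, ...] = (3, 14, 28, 60)
    age_range: tuple[float, float] = (20.0, 85.0)
    sepsis_rate: float = 0.65
    #: slope of each feature mean against the latent (overrides defaults)
    latent_effect_sizes: dict[str, float] = field(default_factory=dict)
    #: additive shifts: feature -> {day: shift}; key "latent" shifts the
    #: latent itself (the primary trauma mechanism)
    trauma_offsets: dict[str, dict[int, float]] = field(
        default_factory=lambda: {"latent": dict(_DEFAULT_LATENT_OFFSETS)}
    )
    #: dispersion knobs: group/feature -> Dirichlet/Beta precision
    noise_scales: dict[str, float] = field(default_factory=dict)
    dropout_rate: float = 0.3
    #: probability any single panel frequency is missing (exercises the
    #: missing-value exclusion rule downstream)
    feature_missing_rate: float = 0.0
    latent_noise: float = 0.35
    sepsis_slope: float = 1.2
    male_fraction: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 1:
            raise ConfigError(f"n_controls must be >= 1, got {self.n_controls}")
        if self.n_trauma < 1:
            raise ConfigError(f"n_trauma must be >= 1, got {self.n_trauma}")
        if not (0.0 <= self.sepsis_rate <= 1.0):
            raise ConfigError(f"sepsis_rate must be in [0, 1], got {self.sepsis_rate}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not (0.0 <= self.feature_missing_rate < 1.0):
            raise ConfigError(
                f"feature_missing_rate must be in [0, 1), got {self.feature_missing_rate}"
            )
        tps = tuple(self.timepoints)
        if len(tps) == 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError(f"timepoints must be strictly increasing, got {tps}")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ConfigError(f"age_range must satisfy low < high, got {self.age_range}")

    # resolved lookups ------------------------------------------------------
    def slope(self, feature: str) -> float:
        return self.latent_effect_sizes.get(feature, _DEFAULT_SLOPES[feature])

    def precision(self, key: str) -> float:
        return self.noise_scales.get(
            key, _DEFAULT_PRECISION.get(key, _DEFAULT_PRECISION["beta_default"])
        )

    def feature_offset(self, feature: str, day: int) -> float:
        return self.trauma_offsets.get(feature, {}).get(day, 0.0)

    def latent_offset(self, day: int) -> float:
        return self.trauma_offsets.get("latent", {}).get(day, 0.0)


# --- low-level draws -------------------------------------------------------

def _beta_percent(rng: np.random.Generator, mean_pct: float, precision: float) -> float:
    mu = min(max(mean_pct / 100.0, 0.005), 0.97)
    return 100.0 * rng.beta(mu * precision, (1.0 - mu) * precision)


def _dirichlet_percent(
    rng: np.random.Generator, mean_pcts: Sequence[float], precision: float
) -> np.ndarray:
    m = np.clip(np.asarray(mean_pcts, dtype=float), 1.0, None)
    m = m / m.sum()
    return 100.0 * rng.dirichlet(m * precision)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(rng.normal(0.0, sigma)))


def _mean_pct(cfg: SimConfig, feature: str, z: float, day: int | None) -> float:
    m = _BASELINES[feature] + cfg.slope(feature) * z
    if day is not None:
        m += cfg.feature_offset(feature, day)
    return m


def _draw_panel(
    cfg: SimConfig, rng: np.random.Generator, z: float, day: int | None
) -> dict[str, float]:
    """One sample's full parent-relative frequency dictionary."""
    freqs: dict[str, float] = {}

    t, b, _ = _dirichlet_percent(
        rng,
        [_mean_pct(cfg, "tcell_of_lymphs", z, day),
         _mean_pct(cfg, "bcell_of_lymphs", z, day),
         100.0 - _BASELINES["tcell_of_lymphs"] - _BASELINES["bcell_of_lymphs"]],
        cfg.precision("lymph_split"),
    )
    freqs["tcell_of_lymphs"], freqs["bcell_of_lymphs"] = t, b

    cd4, cd8, _ = _dirichlet_percent(
        rng,
        [_mean_pct(cfg, "cd4_of_t", z, day), _mean_pct(cfg, "cd8_of_t", z, day),
         100.0 - _BASELINES["cd4_of_t"] - _BASELINES["cd8_of_t"]],
        cfg.precision("t_lineage_split"),
    )
    freqs["cd4_of_t"], freqs["cd8_of_t"] = cd4, cd8

    for lin in ("cd4", "cd8"):
        members = [f"{lin}_{s}" for s in ("naive", "cm", "em", "emra")]
        vals = _dirichlet_percent(
            rng, [_mean_pct(cfg, mname, z, day) for mname in members],
            cfg.precision(f"{lin}_quartet"),
        )
        freqs.update(zip(members, vals))

        cd28neg = _beta_percent(
            rng, _mean_pct(cfg, f"{lin}_cd28neg", z, day), cfg.precision(f"{lin}_cd28neg")
        )
        cd57pos = _beta_percent(
            rng, _mean_pct(cfg, f"{lin}_cd57pos", z, day), cfg.precision(f"{lin}_cd57pos")
        )
        overlap = rng.beta(24.0, 6.0)  # senescent gate covers ~80% of the overlap bound
        freqs[f"{lin}_cd28neg"] = cd28neg
        freqs[f"{lin}_cd57pos"] = cd57pos
        freqs[f"{lin}_senescent"] = overlap * min(cd28neg, cd57pos)

    freqs["rte_of_naive_cd4"] = _beta_percent(
        rng, _mean_pct(cfg, "rte_of_naive_cd4", z, day), cfg.precision("rte_of_naive_cd4")
    )
    freqs["treg_of_cd4"] = _beta_percent(
        rng, _mean_pct(cfg, "treg_of_cd4", z, day), cfg.precision("treg_of_cd4")
    )

    b_members = ["b_naive", "b_switched_mem", "b_unswitched_mem"]
    b_means = [_mean_pct(cfg, mname, z, day) for mname in b_members]
    vals = _dirichlet_percent(
        rng, b_means + [max(100.0 - sum(b_means), 2.0)], cfg.precision("b_subsets")
    )
    freqs.update(zip(b_members, vals[:3]))
    freqs["breg_of_b"] = _beta_percent(
        rng, _mean_pct(cfg, "breg_of_b", z, day), cfg.precision("breg_of_b")
    )

    if cfg.feature_missing_rate > 0:
        for name in list(freqs):
            if rng.random() < cfg.feature_missing_rate:
                freqs[name] = float("nan")
    return freqs


def _draw_cytokines(
    rng: np.random.Generator, day: int | None, sepsis: bool
) -> dict[str, float]:
    out = {}
    fac = _CYTO_TRAUMA_FACTORS.get(day, _CYTO_TRAUMA_FACTORS[3]) if day is not None else {}
    for name, med in _CYTO_HC_MEDIAN.items():
        if day is None:
            out[name] = _lognormal(rng, med, _CYTO_HC_SIGMA)
        else:
            m = med * fac.get(name, 1.0)
            if sepsis:
                m *= _SEPSIS_CYTO_FACTORS[name]
            out[name] = _lognormal(rng, m, _CYTO_TRAUMA_SIGMA)
    return out


def _age_component(cfg: SimConfig, age: float) -> float:
    lo, hi = cfg.age_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return (age - mid) / half


# --- cohort assembly -------------------------------------------------------

def _simulate(cfg: SimConfig):
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_controls + cfg.n_trauma)

    records: list[SubjectRecord] = []
    panels: list[PhenotypePanel] = []
    latent: dict[str, float] = {}

    for i in range(cfg.n_controls):
        rng = np.random.default_rng(children[i])
        sid = f"HC{i:03d}"
        age = float(rng.uniform(*cfg.age_range))
        z = _age_component(cfg, age) + rng.normal(0.0, cfg.latent_noise)
        sex = "M" if rng.random() < cfg.male_fraction else "F"
        lymph = _lognormal(rng, 1.8, 0.25)
        records.append(SubjectRecord(
            subject_id=sid, group="HC", age=age, sex=sex,
            lymphocyte_count=lymph, cytokines=_draw_cytokines(rng, None, False),
        ))
        panels.append(PhenotypePanel(sid, _draw_panel(cfg, rng, z, None)))
        latent[sid] = z

    days = tuple(int(d) for d in cfg.timepoints)
    for j in range(cfg.n_trauma):
        rng = np.random.default_rng(children[cfg.n_controls + j])
        base = f"TR{j:03d}"
        age = float(rng.uniform(*cfg.age_range))
        z_age = _age_component(cfg, age) + rng.normal(0.0, cfg.latent_noise)
        sex = "M" if rng.random() < cfg.male_fraction else "F"

        z_by_day = {d: z_age + cfg.latent_offset(d) for d in days}
        z3 = z_by_day[days[0]]
        # logistic sepsis model on the earliest-timepoint latent, centred so
        # that the marginal rate tracks sepsis_rate
        if cfg.sepsis_rate <= 0.0:
            sepsis = False
        elif cfg.sepsis_rate >= 1.0:
            sepsis = True
        else:
            eta = math.log(cfg.sepsis_rate / (1.0 - cfg.sepsis_rate))
            p = 1.0 / (1.0 + math.exp(-(eta + cfg.sepsis_slope * (z3 - cfg.latent_offset(days[0])))))
            sepsis = bool(rng.random() < p)

        iss = float(np.clip(round(16.0 + rng.gamma(2.0, 5.0)), 16, 75))
        niss = float(np.clip(round(iss + abs(rng.normal(7.0, 4.0))), iss, 75))
        apache2 = float(np.clip(round(12.0 + 4.5 * z3 + 4.0 * sepsis + rng.normal(0, 4)), 0, 71))
        sofa = float(np.clip(round(3.5 + 2.0 * z3 + 2.5 * sepsis + rng.normal(0, 2)), 0, 24))
        saps2 = float(np.clip(round(30.0 + 8.0 * z3 + 9.0 * sepsis + rng.normal(0, 8)), 0, 163))
        icu_los = _lognormal(rng, 5.0 + 10.0 * sepsis, 0.6)
        vent = _lognormal(rng, 3.0 + 8.0 * sepsis, 0.7)
        hosp = _lognormal(rng, 25.0 + 35.0 * sepsis, 0.5)

        # completely-at-random missed visits after the first timepoint
        retained = [days[0]] + [d for d in days[1:] if rng.random() >= cfg.dropout_rate]

        for d in days:  # draw in fixed order so retention does not shift streams
            z = z_by_day[d]
            lymph = _lognormal(rng, 1.8 * _LYMPH_FACTORS.get(d, 0.7), 0.3)
            cyto = _draw_cytokines(rng, d, sepsis)
            freqs = _draw_panel(cfg, rng, z, d)
            if d not in retained:
                continue
            sid = f"{base}_D{d:02d}"
            records.append(SubjectRecord(
                subject_id=sid, group="trauma", timepoint_day=d, age=age, sex=sex,
                iss=iss, niss=niss, apache2=apache2, sofa=sofa, saps2=saps2,
                sepsis=sepsis, icu_los=icu_los, hospital_los=hosp,
                ventilator_days=vent, lymphocyte_count=lymph, cytokines=cyto,
            ))
            panels.append(PhenotypePanel(sid, freqs))
            latent[sid] = z

    return records, panels, latent


def generate_cohort(config: SimConfig) -> tuple[list[SubjectRecord], list[PhenotypePanel]]:
    """Generate one cohort (deterministic given ``config.seed``)."""
    records, panels, _ = _simulate(config)
    return records, panels


def planted_truth(config: SimConfig) -> dict[str, float]:
    """The latent immune-age value actually used for each generated sample."""
    _, _, latent = _simulate(config)
    return latent


# --- tabular output --------------------------------------------------------

SUBJECTS_COLUMNS = [
    "subject_id", "group", "timepoint_day", "age_years", "sex",
    "iss", "niss", "apache2", "sofa", "saps2", "sepsis",
    "icu_los_days", "hospital_los_days", "ventilator_days",
    "lymphocytes_1e9_per_L", "il6_pg_ml", "tnfa_pg_ml", "il10_pg_ml",
    "il8_pg_ml", "crp_mg_ml",
]


def cohort_frames(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort as the published two-table layout (subjects, panels)."""
    records, panels = generate_cohort(config)
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "group": r.group,
            "timepoint_day": r.timepoint_day, "age_years": r.age, "sex": r.sex,
            "iss": r.iss, "niss": r.niss, "apache2": r.apache2, "sofa": r.sofa,
            "saps2": r.saps2,
            "sepsis": (None if r.sepsis is None else int(r.sepsis)),
            "icu_los_days": r.icu_los, "hospital_los_days": r.hospital_los,
            "ventilator_days": r.ventilator_days,
            "lymphocytes_1e9_per_L": r.lymphocyte_count,
            "il6_pg_ml": r.cytokines.get("il6"), "tnfa_pg_ml": r.cytokines.get("tnfa"),
            "il10_pg_ml": r.cytokines.get("il10"), "il8_pg_ml": r.cytokines.get("il8"),
            "crp_mg_ml": r.cytokines.get("crp"),
        })
    subjects = pd.DataFrame(rows, columns=SUBJECTS_COLUMNS)
    panel_rows = [{"subject_id": p.subject_id, **p.frequencies} for p in panels]
    panels_df = pd.DataFrame(panel_rows, columns=["subject_id", *SUBSET_NAMES])
    return subjects, panels_df


def write_cohort(config: SimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write subjects.csv and panels.csv (UTF-8, comma-separated, header row)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, panels = cohort_frames(config)
    sp, pp = out / "subjects.csv", out / "panels.csv"
    subjects.to_csv(sp, index=False)
    panels.to_csv(pp, index=False)
    return sp, pp


def default_config(**overrides) -> SimConfig:
    """Study-structure defaults with keyword overrides."""
    return replace(SimConfig(), **overrides)
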