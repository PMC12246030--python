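"""Synthetic prescription-register generator with a known ground truth.

Real prescription registers cannot be redistributed, so every pipeline stage
is exercised on data from a latent multistate prescription-behaviour model:

* patients initiate a drug class at a uniformly drawn index day within a
  multi-year entry window and are followed to an administrative study end;
* while *adherent* they refill: each fill dispenses a drawn days-of-supply,
  and the next fill is scheduled at supply exhaustion plus a drawn gap
  (negative gaps = early refills that stockpile supply; an occasional long
  gap models irregular use);
* adherence ends at a latent discontinuation time drawn from an exponential
  whose rate is scaled by covariate effects (sex, age band, BMI class);
  discontinued patients may reinitiate at a constant rate, starting a new
  refill cycle;
* at any refill the patient may switch to a different drug (code/category)
  within the class;
* death and emigration end all activity.

Only the fill stream and person table are observable; the latent event times
are returned in a :class:`GroundTruthLog` so that episode construction and
the competing-risks estimators can be validated against the truth.  The
observable discontinuation day (last supply end plus grace) deliberately
differs from the latent decision time — the same measurement problem that
makes real-world persistence estimates sensitive to the grace period.

The module also provides direct samplers for constant-hazard competing-risks
data and for the Fine–Gray sub-distribution model, used in estimator
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

_INF = float("inf")


def _default_category_codes() -> dict[str, list[str]]:
    # GLP-1 receptor agonist-like class: two named categories and a residual
    # "other" category containing several codes so other->other switches exist
    return {
        "semaglutide": ["A10BJ06"],
        "liraglutide": ["A10BJ02"],
        "other": ["A10BJ01", "A10BJ03", "A10BJ05"],
    }


def _default_initial_probs() -> dict[str, float]:
    return {"liraglutide": 0.63, "semaglutide": 0.19, "other": 0.18}


def _default_switch_matrix() -> dict[str, dict[str, float]]:
    return {
        "liraglutide": {"semaglutide": 0.85, "other": 0.15},
        "semaglutide": {"liraglutide": 0.45, "other": 0.55},
        "other": {"semaglutide": 0.50, "liraglutide": 0.30, "other": 0.20},
    }


def _default_supply_days() -> dict[str, tuple[tuple[int, ...], tuple[float, ...]]]:
    # mostly ~3-month dispensations, as typical for maintenance drugs
    return {"default": ((30, 90, 98), (0.2, 0.6, 0.2))}


def _default_covariate_effects() -> dict[str, float]:
    # log sub-distribution hazard ratios on the latent discontinuation rate;
    # directions: men slightly less likely to discontinue, middle/old age and
    # higher BMI protective
    return {
        "male": math.log(0.95),
        "age_50_69": math.log(0.61),
        "age_ge70": math.log(0.65),
        "bmi_overweight": math.log(0.72),
        "bmi_obese1": math.log(0.65),
        "bmi_obese23": math.log(0.64),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic register.

    Hazards are per day; the default magnitudes put 1-year observed
    discontinuation in the 20-30% range and the population coverage near
    70-80%, the scale typical of maintenance glucose-lowering therapy.
    """

    n_patients: int = 4000
    entry_window: tuple[int, int] = (0, 1825)  # five entry years
    study_end_day: int = 2190  # one further year of follow-up
    drug_class: str = "GLP1"
    category_codes: dict[str, list[str]] = field(default_factory=_default_category_codes)
    initial_category_probs: dict[str, float] = field(default_factory=_default_initial_probs)
    switch_prob: float = 0.015  # per refill
    switch_matrix: dict[str, dict[str, float]] = field(default_factory=_default_switch_matrix)
    supply_days: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = field(
        default_factory=_default_supply_days
    )
    # refill gap (days between supply exhaustion and next fill): a mixture of
    # small jitter around on-time refilling and occasional long lapses
    gap_short_mean: float = -5.0
    gap_short_sd: float = 12.0
    gap_long_prob: float = 0.08
    gap_long_min: float = 20.0
    gap_long_scale: float = 75.0  # exponential tail beyond gap_long_min
    lambda_disc: float = 0.0006  # latent discontinuation hazard, per day
    lambda_reinit: float = 0.0013  # reinitiation hazard after discontinuation
    lambda_death: float = 3.5e-5
    lambda_emig: float = 1.0e-5
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    seed: int = 12345

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.entry_window[0] > self.entry_window[1]:
            raise ValueError("entry_window must be (first, last) with first <= last")
        if self.study_end_day < self.entry_window[1]:
            raise ValueError("study_end_day must not precede the entry window")
        for lam in (self.lambda_disc, self.lambda_reinit, self.lambda_death, self.lambda_emig):
            if lam < 0:
                raise ValueError("hazards must be non-negative")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in [0, 1]")
        for cat, (choices, probs) in self.supply_days.items():
            if len(choices) == 0 or any(c < 1 for c in choices):
                raise ValueError(f"supply_days for {cat!r} must be positive")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"supply probabilities for {cat!r} must sum to 1")
        if abs(sum(self.initial_category_probs.values()) - 1.0) > 1e-9:
            raise ValueError("initial_category_probs must sum to 1")
        for row, probs in self.switch_matrix.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"switch_matrix row {row!r} must sum to 1")

    def constant_hazard(self) -> bool:
        """True when the discontinuation hazard is the same for everyone."""
        return all(abs(v) < 1e-15 for v in self.covariate_effects.values())


@dataclass
class GroundTruthLog:
    """Latent per-patient event history behind the emitted fill stream."""

    patients: list[dict[str, Any]]

    @property
    def n_new_users(self) -> int:
        return sum(p["new_user"] for p in self.patients)

    @property
    def n_latent_discontinuations(self) -> int:
        return sum(len(p["disc_times"]) for p in self.patients)

    def to_dict(self) -> dict:
        return {"patients": self.patients}


_AGE_BANDS = (("lt50", 0.17, (25, 49)), ("50_69", 0.53, (50, 69)), ("ge70", 0.30, (70, 90)))
_BMI_CATS = (("normal", 0.06), ("overweight", 0.27), ("obese1", 0.34), ("obese23", 0.33))


def _draw_covariates(rng: np.random.Generator) -> dict[str, Any]:
    sex = "male" if rng.random() < 0.588 else "female"
    bands, probs, ranges = zip(*[(b, p, r) for b, p, r in _AGE_BANDS])
    band = bands[rng.choice(len(bands), p=np.array(probs) / sum(probs))]
    lo, hi = dict(zip(bands, ranges))[band]
    age = int(rng.integers(lo, hi + 1))
    cats, cprobs = zip(*_BMI_CATS)
    bmi = cats[rng.choice(len(cats), p=np.array(cprobs) / sum(cprobs))]
    return {
        "sex": sex,
        "age_band": band,
        "age_at_index": age,
        "bmi_category": bmi,
        "ascvd": bool(rng.random() < 0.23),
        "ckd": bool(rng.random() < 0.22),
        "hf": bool(rng.random() < 0.08),
    }


def _linear_predictor(cov: dict[str, Any], effects: dict[str, float]) -> float:
    indicators = {
        "male": cov["sex"] == "male",
        "age_50_69": cov["age_band"] == "50_69",
        "age_ge70": cov["age_band"] == "ge70",
        "bmi_overweight": cov["bmi_category"] == "overweight",
        "bmi_obese1": cov["bmi_category"] == "obese1",
        "bmi_obese23": cov["bmi_category"] == "obese23",
        "ascvd": cov["ascvd"],
        "ckd": cov["ckd"],
        "hf": cov["hf"],
    }
    return sum(b for name, b in effects.items() if indicators.get(name, False))


def _draw_gap(cfg: SimConfig, rng: np.random.Generator) -> int:
    if rng.random() < cfg.gap_long_prob:
        return int(round(cfg.gap_long_min + rng.exponential(cfg.gap_long_scale)))
    return int(round(rng.normal(cfg.gap_short_mean, cfg.gap_short_sd)))


def _draw_supply(cfg: SimConfig, category: str, rng: np.random.Generator) -> int:
    choices, probs = cfg.supply_days.get(category, cfg.supply_days["default"])
    return int(np.asarray(choices)[rng.choice(len(choices), p=np.asarray(probs))])


def _draw_exp(rate: float, rng: np.random.Generator) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else _INF


def _switch(cfg, category, code, rng):
    row = cfg.switch_matrix[category]
    cats = list(row)
    new_cat = cats[rng.choice(len(cats), p=np.array([row[c] for c in cats]))]
    options = [c for c in cfg.category_codes[new_cat] if c != code]
    if not options:  # single-code category, no distinct drug to switch to
        return category, code, False
    return new_cat, options[rng.choice(len(options))], True


def simulate_registry(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthLog]:
    """Generate (fills, persons, truth) tables from the behaviour model.

    Deterministic given the config (including its seed): identical configs
    produce identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fill_rows: list[tuple] = []
    person_rows: list[dict] = []
    truth: list[dict] = []
    cats = list(config.initial_category_probs)
    cat_probs = np.array([config.initial_category_probs[c] for c in cats])

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        cov = _draw_covariates(rng)
        lam_d = config.lambda_disc * math.exp(
            _linear_predictor(cov, config.covariate_effects)
        )
        index_day = int(rng.integers(config.entry_window[0], config.entry_window[1] + 1))
        death = index_day + _draw_exp(config.lambda_death, rng)
        emig = index_day + _draw_exp(config.lambda_emig, rng)
        death_day = int(math.ceil(death)) if death < _INF else None
        emig_day = int(math.ceil(emig)) if emig < _INF else None
        # fills may occur while alive, present and within the data period
        limit = min(
            death_day if death_day is not None else _INF,
            emig_day if emig_day is not None else _INF,
            config.study_end_day + 1,
        )
        category = cats[rng.choice(len(cats), p=cat_probs)]
        code = config.category_codes[category][
            rng.choice(len(config.category_codes[category]))
        ]
        log = {
            "person_id": pid,
            "new_user": True,
            "index_day": index_day,
            "initial_category": category,
            "death_day": death_day,
            "emigration_day": emig_day,
            "disc_times": [],
            "last_supply_ends": [],
            "reinit_days": [],
            "switch_days": [],
            "covariates": cov,
        }
        cycle_start = index_day
        first_fill = True
        pool_end = index_day  # supply on hand pools across cycles (stockpiling)
        while cycle_start < limit:
            disc_time = cycle_start + _draw_exp(lam_d, rng)
            t = cycle_start
            pool_end = max(pool_end, t)
            last_supply_end = None
            while t < disc_time and t < limit:
                if not first_fill and rng.random() < config.switch_prob:
                    new_cat, new_code, switched = _switch(config, category, code, rng)
                    if switched:
                        category, code = new_cat, new_code
                        log["switch_days"].append(int(t))
                supply = _draw_supply(config, category, rng)
                fill_rows.append(
                    (pid, config.drug_class, code, category, int(t), supply)
                )
                first_fill = False
                pool_end = max(pool_end, t) + supply
                last_supply_end = pool_end
                t = max(t + 1, pool_end + _draw_gap(config, rng))
            if t >= limit and t < disc_time:
                break  # censored while still adherent
            log["disc_times"].append(float(disc_time))
            log["last_supply_ends"].append(int(last_supply_end))
            reinit = disc_time + _draw_exp(config.lambda_reinit, rng)
            if reinit >= limit:
                break
            cycle_start = int(math.ceil(reinit))
            if cycle_start >= limit:
                break
            log["reinit_days"].append(cycle_start)
        person_rows.append(
            {
                "person_id": pid,
                "sex": cov["sex"],
                "birth_day": index_day - cov["age_at_index"] * 365
                - int(rng.integers(0, 365)),
                "death_day": death_day,
                "emigration_day": emig_day,
                "age_band": cov["age_band"],
                "bmi_category": cov["bmi_category"],
                "ascvd": cov["ascvd"],
                "ckd": cov["ckd"],
                "hf": cov["hf"],
            }
        )
        truth.append(log)

    fills = pd.DataFrame(
        fill_rows,
        columns=["person_id", "drug_class", "drug_code", "drug_category", "fill_day", "days_supply"],
    ).sort_values(["person_id", "fill_day"], ignore_index=True)
    persons = pd.DataFrame(person_rows)
    persons["death_day"] = persons["death_day"].astype("Float64")
    persons["emigration_day"] = persons["emigration_day"].astype("Float64")
    return fills, persons, GroundTruthLog(truth)


def ground_truth_cif(config: SimConfig, t: float, cause: str = "discontinuation") -> float:
    """Closed-form sub-distribution CIF under the constant-hazard configuration.

    With constant latent discontinuation hazard ``lambda_d`` and death hazard
    ``lambda_m``, the cumulative incidence of cause ``k`` is
    ``lambda_k / (lambda_d + lambda_m) * (1 - exp(-(lambda_d + lambda_m) t))``.
    Only valid when covariate effects are all zero (otherwise the population
    hazard is not constant and there is no closed form).
    """
    if not config.constant_hazard():
        raise ValueError("closed-form CIF requires zero covariate effects")
    if t < 0:
        raise ValueError("t must be non-negative")
    lam = {"discontinuation": config.lambda_disc, "death": config.lambda_death}
    if cause not in lam:
        raise ValueError("cause must be 'discontinuation' or 'death'")
    total = config.lambda_disc + config.lambda_death
    if total == 0:
        return 0.0
    return lam[cause] / total * (1.0 - math.exp(-total * t))


def simulate_competing_risks(
    n: int,
    lambda1: float,
    lambda2: float,
    admin_censor: float = _INF,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant cause-specific hazard competing-risks sample (time, event)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t1 = rng.exponential(1.0 / lambda1, n) if lambda1 > 0 else np.full(n, _INF)
    t2 = rng.exponential(1.0 / lambda2, n) if lambda2 > 0 else np.full(n, _INF)
    t = np.minimum(np.minimum(t1, t2), admin_censor)
    event = np.where(t == admin_censor, 0, np.where(t1 <= t2, 1, 2))
    return t, event


def simulate_fine_gray(
    n: int,
    beta: float | np.ndarray,
    p_base: float = 0.35,
    censor_low: float = 0.5,
    censor_high: float = 4.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (time, event, X) from a Fine–Gray sub-distribution model.

    The cause-1 sub-distribution is the unit-exponential mixture
    ``F1(t; x) = 1 - (1 - p_base (1 - exp(-t)))^exp(x'beta)``, so ``beta`` is
    exactly the log sub-distribution hazard ratio; covariates are independent
    Bernoulli(0.5).  Cause-2 times are unit exponentials and censoring is
    uniform on ``(censor_low, censor_high)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if not 0 < p_base < 1:
        raise ValueError("p_base must lie in (0, 1)")
    X = rng.integers(0, 2, size=(n, beta.size)).astype(float)
    eta = np.exp(X @ beta)
    p1 = 1.0 - (1.0 - p_base) ** eta  # P(cause 1 | x)
    cause1 = rng.random(n) < p1
    T = np.empty(n)
    v = rng.random(n)
    # invert F1 conditional on cause 1
    inner = (1.0 - v[cause1] * p1[cause1]) ** (1.0 / eta[cause1])
    T[cause1] = -np.log1p(-(1.0 - inner) / p_base)
    T[~cause1] = rng.exponential(1.0, (~cause1).sum())
    C = rng.uniform(censor_low, censor_high, n)
    time = np.minimum(T, C)
    event = np.where(T <= C, np.where(cause1, 1, 2), 0)
    return time, event, X
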