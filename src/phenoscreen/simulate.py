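"""Synthetic screening datasets with known ground truth.

Emulates the high-throughput phenotyping regime: a large control group
(hundreds of animals) accumulated across many measurement batches, and a
small mutant cohort — typically 7 animals per sex — concentrated in the
last few batches.  The continuous generator draws

    response = intercept + genotype + sex + genotype x sex
             + bodyweight slope x (weight - mean weight)
             + batch intercept (SD ``batch_sd``) + noise (SD ``resid_sd``)

with body weight simulated sex-dependently (so the bodyweight/sex
confounding seen in real screens is representable), optional missingness
per variable, and optional coarsening of the response onto a grid to
produce ties.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Any

import numpy as np
import pandas as pd

from .phen_data import ValidationError


@dataclass
class SimConfig:
    n_control: int = 400
    n_mutant_per_sex: int = 7
    n_batches: int = 20
    n_mutant_batches: int = 3      # mutants confined to the last few batches
    beta: dict[str, float] = field(default_factory=lambda: {
        "intercept": 10.0, "genotype": 0.0, "sex": 0.5,
        "interaction": 0.0, "bodyweight": 0.0})
    batch_sd: float = 0.5
    resid_sd: float = 1.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    tie_level: float = 0.0         # fraction of responses snapped to a grid
    tie_grid: float = 1.0
    categorical_rates: dict[str, list[float]] = field(default_factory=lambda: {
        "control": [0.95, 0.05], "mutant": [0.95, 0.05]})
    categories: list[str] = field(default_factory=lambda: ["normal", "abnormal"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_sd < 0 or self.resid_sd <= 0:
            raise ValidationError("batch_sd must be >= 0 and resid_sd > 0")
        if self.n_batches > self.n_control:
            raise ValidationError("infeasible: more batches than controls")
        if not (0.0 <= self.tie_level <= 1.0):
            raise ValidationError("tie_level must lie in [0, 1]")
        for g, probs in self.categorical_rates.items():
            p = np.asarray(probs, float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"categorical rates for {g!r} must be a probability vector")


def _batch_labels(n_batches: int) -> list[str]:
    start = date(2023, 1, 2)
    return [(start + timedelta(days=7 * i)).isoformat()
            for i in range(n_batches)]


def _specimen_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    labels = _batch_labels(cfg.n_batches)
    n_ctrl = cfg.n_control
    sex_ctrl = np.where(np.arange(n_ctrl) % 2 == 0, "Female", "Male")
    batch_ctrl = np.array(labels)[np.arange(n_ctrl) % cfg.n_batches]
    n_mut = 2 * cfg.n_mutant_per_sex
    sex_mut = np.array(["Female"] * cfg.n_mutant_per_sex
                       + ["Male"] * cfg.n_mutant_per_sex)
    mut_batches = labels[-min(cfg.n_mutant_batches, cfg.n_batches):]
    batch_mut = np.array(mut_batches)[np.arange(n_mut) % len(mut_batches)]
    df = pd.DataFrame({
        "Genotype": ["control"] * n_ctrl + ["mutant"] * n_mut,
        "Sex": np.concatenate([sex_ctrl, sex_mut]),
        "Batch": np.concatenate([batch_ctrl, batch_mut]),
    })
    male = (df["Sex"] == "Male").to_numpy()
    df["BodyWeight"] = np.where(male, 27.0, 22.0) + rng.normal(0.0, 1.5, len(df))
    return df


def _apply_missing(df: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    for col, rate in cfg.missing_rates.items():
        if col in df.columns and rate > 0:
            mask = rng.random(len(df)) < rate
            df.loc[mask, col] = np.nan
    return df


def gen_continuous_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    """A continuous-response screening dataset and its truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    df = _specimen_frame(cfg, rng)
    b = cfg.beta
    mut = (df["Genotype"] == "mutant").to_numpy(float)
    male = (df["Sex"] == "Male").to_numpy(float)
    batches = df["Batch"].unique()
    batch_eff = dict(zip(batches, rng.normal(0.0, cfg.batch_sd, len(batches))))
    centred_bw = df["BodyWeight"] - df["BodyWeight"].mean()
    resp = (b.get("intercept", 0.0)
            + b.get("genotype", 0.0) * mut
            + b.get("sex", 0.0) * male
            + b.get("interaction", 0.0) * mut * male
            + b.get("bodyweight", 0.0) * centred_bw.to_numpy()
            + df["Batch"].map(batch_eff).to_numpy()
            + rng.normal(0.0, cfg.resid_sd, len(df)))
    if cfg.tie_level > 0:
        snap = rng.random(len(df)) < cfg.tie_level
        resp = np.where(snap, np.round(resp / cfg.tie_grid) * cfg.tie_grid, resp)
    df["Response"] = resp
    df = _apply_missing(df, cfg, rng)
    truth = {
        "beta": dict(b), "batch_sd": cfg.batch_sd, "resid_sd": cfg.resid_sd,
        "batch_effects": {k: float(v) for k, v in batch_eff.items()},
        "n_control": cfg.n_control, "n_mutant": 2 * cfg.n_mutant_per_sex,
        "reference_genotype": "control", "seed": cfg.seed,
    }
    return df, truth


def gen_categorical_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    """A categorical-response screening dataset and its truth manifest."""
    firsts = [float(np.asarray(p, float)[0])
              for p in cfg.categorical_rates.values()]
    if firsts and all(f == 0.0 for f in firsts):
        raise ValidationError("reference category has zero probability everywhere")
    rng = np.random.default_rng(cfg.seed)
    df = _specimen_frame(cfg, rng)
    cats = np.asarray(cfg.categories, dtype=object)
    resp = np.empty(len(df), dtype=object)
    for geno, probs in cfg.categorical_rates.items():
        mask = (df["Genotype"] == geno).to_numpy()
        if mask.any():
            resp[mask] = rng.choice(cats, size=int(mask.sum()),
                                    p=np.asarray(probs, float))
    df = df.drop(columns=["BodyWeight"])
    df["Response"] = resp
    df = _apply_missing(df, cfg, rng)
    truth = {"categorical_rates": {k: list(map(float, v))
                                   for k, v in cfg.categorical_rates.items()},
             "categories": list(cfg.categories),
             "reference_genotype": "control", "seed": cfg.seed}
    return df, truth


def gen_edgecase_suite(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Deterministic degenerate-shape suite the pipeline must survive:
    single sex, single batch, >50%-missing body weight, fully tied
    response, right-skewed response, duplicated covariate column, and a
    ``gender``-labelled sex column."""
    rng = np.random.default_rng(seed)
    base_cfg = SimConfig(n_control=100, n_batches=5, seed=seed)
    base, _ = gen_continuous_dataset(base_cfg)
    suite: dict[str, pd.DataFrame] = {}

    single_sex = base.copy()
    single_sex = single_sex[single_sex["Sex"] == "Male"].reset_index(drop=True)
    suite["single-sex"] = single_sex

    single_batch = base.copy()
    single_batch["Batch"] = single_batch["Batch"].iloc[0]
    suite["single-batch"] = single_batch

    missing_weight = base.copy()
    idx = rng.choice(len(missing_weight), size=int(0.6 * len(missing_weight)),
                     replace=False)
    missing_weight.loc[missing_weight.index[idx], "BodyWeight"] = np.nan
    suite["missing-weight"] = missing_weight

    tied = base.copy()
    tied["Response"] = 7.0
    suite["tied"] = tied

    skewed = base.copy()
    skewed["Response"] = np.exp(rng.normal(0.0, 1.0, len(skewed)))
    suite["skewed"] = skewed

    duplicate = base.copy()
    duplicate["BodyWeight2"] = duplicate["BodyWeight"]
    suite["duplicate-column"] = duplicate

    gender = base.copy()
    gender = gender.rename(columns={"Sex": "gender"})
    gender["gender"] = gender["gender"].map({"Female": "f", "Male": "m"})
    suite["gender-column"] = gender

    return suite
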