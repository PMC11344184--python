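"""Synthetic respondents with random-coefficient preferences.

The generator reproduces the statistical structure the estimator assumes:
each respondent owns a coefficient vector drawn once from independent
normal distributions (the panel structure), answers the 8 tasks of a
randomly assigned questionnaire version, and picks the alternative with
the highest utility, where utility is coefficients · covariates plus
independent standard Gumbel (type-I extreme value) noise — the noise
under which argmax choice yields softmax (logit) choice probabilities.
The opt-out alternative has zero covariates, hence pure noise utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import LongChoiceTable, encode_profile
from .design import CONSTANT_NAME, OPTOUT_ID, ChoiceDesign, StudyDesignSpec
from .errors import InvalidSpecError
from .study import HZ_DEMOGRAPHIC_PROPORTIONS, HZ_N_RESPONDENTS


@dataclass(frozen=True)
class TrueParameters:
    """True preference distribution: Normal(mean, sd) per coefficient."""

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != (len(self.names),) or sds.shape != (len(self.names),):
            raise InvalidSpecError("means/sds must have one entry per coefficient name")
        if (sds < 0).any():
            raise InvalidSpecError("standard deviations must be non-negative")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)

    @property
    def n_coefficients(self) -> int:
        return len(self.names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "mean": self.means, "sd": self.sds})


def draw_population(params: TrueParameters, n: int, seed: int) -> np.ndarray:
    """Draw per-respondent coefficient vectors, shape (n, K).

    Coefficient k of respondent r is Normal(mean_k, sd_k), independent
    across respondents and coefficients; with all sds zero every
    respondent gets exactly the mean vector.
    """
    if n < 1:
        raise InvalidSpecError("need at least one respondent")
    rng = np.random.default_rng(seed)
    return rng.normal(params.means, params.sds, size=(n, params.n_coefficients))


def _design_tensors(design: ChoiceDesign, spec: StudyDesignSpec
                    ) -> dict[int, tuple[list[int], np.ndarray, list[str]]]:
    """Per block: (task ids, covariate tensor (T, A, K), alternative ids)."""
    coef_cols = spec.coefficient_columns()
    out = {}
    for b in design.block_ids:
        tasks = design.tasks_in_block(b)
        alt_ids = [f"designed-{j+1}" for j in range(spec.n_alternatives_per_task)]
        if spec.include_optout:
            alt_ids = alt_ids + [OPTOUT_ID]
        X = np.zeros((len(tasks), len(alt_ids), len(coef_cols)))
        for ti, t in enumerate(tasks):
            for j, p in enumerate(t.profiles):
                row = encode_profile(p, spec)
                row[CONSTANT_NAME] = 1.0
                X[ti, j] = [row[c] for c in coef_cols]
            # opt-out row stays all zero
        out[b] = ([t.task_id for t in tasks], X, alt_ids)
    return out


def simulate_choices(population: np.ndarray, design: ChoiceDesign,
                     spec: StudyDesignSpec, seed: int,
                     blocks: np.ndarray | None = None) -> LongChoiceTable:
    """Simulate each respondent's choices over their block's tasks.

    ``population`` is the (n, K) coefficient matrix from
    :func:`draw_population`.  Respondents are assigned to questionnaire
    versions uniformly at random (or per ``blocks``), utilities get
    independent standard Gumbel noise, and the argmax is marked chosen.
    """
    population = np.atleast_2d(np.asarray(population, dtype=float))
    n = population.shape[0]
    if n == 0:
        raise InvalidSpecError("population is empty")
    rng = np.random.default_rng(seed)
    block_ids = design.block_ids
    if blocks is None:
        blocks = np.asarray(block_ids)[rng.integers(0, len(block_ids), size=n)]
    else:
        blocks = np.asarray(blocks)

    tensors = _design_tensors(design, spec)
    coef_cols = spec.coefficient_columns()
    frames = []
    for b in block_ids:
        resp_idx = np.flatnonzero(blocks == b)
        if len(resp_idx) == 0:
            continue
        task_ids, X, alt_ids = tensors[b]
        T, A, K = X.shape
        V = population[resp_idx] @ X.reshape(T * A, K).T  # (n_b, T*A)
        V = V.reshape(len(resp_idx), T, A)
        V = V + rng.gumbel(size=V.shape)
        chosen_alt = V.argmax(axis=2)  # (n_b, T)

        n_b = len(resp_idx)
        df = pd.DataFrame({
            "respondent_id": np.repeat(resp_idx + 1, T * A),
            "block_id": b,
            "task_id": np.tile(np.repeat(task_ids, A), n_b),
            "alt_id": np.tile(alt_ids, n_b * T),
            "chosen": (np.tile(np.arange(A), n_b * T)
                       == np.repeat(chosen_alt.ravel(), A)).astype(int),
        })
        cov = np.tile(X.reshape(T * A, K), (n_b, 1))
        for k, c in enumerate(coef_cols):
            df[c] = cov[:, k]
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["respondent_id", "task_id"],
                            kind="stable").reset_index(drop=True)
    return LongChoiceTable(data, spec)


def generate_demographics(n: int, proportions: Mapping[str, Mapping[str, float]]
                          | None = None, seed: int = 12345) -> pd.DataFrame:
    """Sample respondent characteristics from configured category proportions."""
    if proportions is None:
        proportions = HZ_DEMOGRAPHIC_PROPORTIONS
    rng = np.random.default_rng(seed)
    out = {"respondent_id": np.arange(1, n + 1)}
    for char, props in proportions.items():
        cats = list(props.keys())
        p = np.array([props[c] for c in cats], dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise InvalidSpecError(
                f"proportions for {char!r} sum to {p.sum():.4f}, expected 1"
            )
        p = p / p.sum()
        draws = rng.choice(len(cats), size=n, p=p)
        out[char] = pd.Categorical.from_codes(draws, categories=cats)
    return pd.DataFrame(out)


@dataclass
class SyntheticStudyConfig:
    """Conditions of a synthetic study (defaults mirror the HZ survey)."""

    spec: StudyDesignSpec
    params: TrueParameters
    n_respondents: int = HZ_N_RESPONDENTS
    demographic_proportions: Mapping[str, Mapping[str, float]] | None = None
    design: ChoiceDesign | None = None
    seed: int = 12345

    def __post_init__(self):
        if self.n_respondents < 1:
            raise InvalidSpecError("n_respondents must be >= 1")


@dataclass
class SimulatedStudy:
    table: LongChoiceTable
    design: ChoiceDesign
    population: np.ndarray
    truth: dict


def simulate_study(config: SyntheticStudyConfig) -> SimulatedStudy:
    """Design (if needed), draw a population, simulate choices and demographics.

    Sub-seeds are derived from the config seed by fixed offsets so each
    stage is independently reproducible.
    """
    from .design import block_design, build_choice_design  # late import

    spec = config.spec
    design = config.design
    if design is None:
        design = build_choice_design(spec, run_size="auto", seed=config.seed + 1)
        design = block_design(design, spec.n_blocks, seed=config.seed + 2, spec=spec)
    population = draw_population(config.params, config.n_respondents, config.seed + 3)
    table = simulate_choices(population, design, spec, seed=config.seed + 4)
    table.demographics = generate_demographics(
        config.n_respondents, config.demographic_proportions, seed=config.seed + 5)
    truth = {
        "seed": config.seed,
        "n_respondents": config.n_respondents,
        "coefficients": {
            name: {"mean": float(m), "sd": float(s)}
            for name, m, s in zip(config.params.names, config.params.means,
                                  config.params.sds)
        },
        "design_provenance": design.provenance,
    }
    return SimulatedStudy(table, design, population, truth)
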