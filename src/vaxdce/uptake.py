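"""Predicted uptake of vaccination scenarios and tornado sensitivity.

Uptake is the probability of choosing a specified vaccine over the
opt-out under the logit choice rule, P = e^V / (e^V + 1), where V is the
scenario's deterministic utility.  The price attribute is excluded from
scenarios (uptake is reported free of hypothetical price levels).
Preference heterogeneity is integrated by Monte Carlo: coefficients are
drawn from Normal(mean, sd) using the fitted spreads and the softmax
probability is averaged over draws; with all spreads zero the plug-in
value is returned exactly.

Tornado analysis changes one attribute level at a time from a base case
(all reference levels) and reports the uptake delta in percentage points,
sorted by magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CATEGORICAL, CONSTANT_NAME, Profile, StudyDesignSpec
from .data import encode_profile
from .errors import InvalidSpecError, ScenarioError
from .mixlogit import EstimationResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UptakeScenario:
    """A vaccine profile over the non-price attributes."""

    levels: tuple[tuple[str, str], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "UptakeScenario":
        return cls(tuple((str(k), str(v)) for k, v in mapping.items()))

    def as_dict(self) -> dict[str, str]:
        return dict(self.levels)

    def replace(self, attribute: str, level: str) -> "UptakeScenario":
        d = self.as_dict()
        d[attribute] = level
        return UptakeScenario.from_mapping(d)


def base_case(spec: StudyDesignSpec) -> UptakeScenario:
    """The all-reference-levels scenario (price excluded)."""
    return UptakeScenario.from_mapping({
        a.name: a.reference_level for a in spec.attributes if a.coding == CATEGORICAL
    })


def _validate_scenario(scenario: UptakeScenario, spec: StudyDesignSpec) -> None:
    d = scenario.as_dict()
    for a in spec.attributes:
        if a.coding != CATEGORICAL:
            if a.name in d:
                raise ScenarioError(
                    f"scenario must not set the price attribute {a.name!r}; "
                    "uptake is computed with cost excluded")
            continue
        if a.name not in d:
            raise ScenarioError(f"scenario missing attribute {a.name!r}")
        if d[a.name] not in a.levels:
            raise ScenarioError(
                f"unknown level {d[a.name]!r} for attribute {a.name!r}")
    extra = set(d) - {a.name for a in spec.attributes}
    if extra:
        raise ScenarioError(f"scenario has unknown attributes {sorted(extra)}")


def _scenario_x(scenario: UptakeScenario, spec: StudyDesignSpec,
                coef_names: list[str]) -> np.ndarray:
    full = scenario.as_dict()
    for a in spec.attributes:  # price pinned to its zero/reference level
        if a.coding != CATEGORICAL:
            full[a.name] = a.levels[0]
    values = encode_profile(Profile.from_mapping(full), spec)
    values[CONSTANT_NAME] = 1.0
    for a in spec.attributes:
        if a.coding != CATEGORICAL:
            values[a.column_names()[0]] = 0.0
    return np.array([values[c] for c in coef_names])


@dataclass(frozen=True)
class UptakePrediction:
    probability: float
    delta_pp: float | None  # percentage points vs base case, None if no base
    mc_se: float
    n_draws: int
    seed: int | None
    scenario: UptakeScenario


def _full_sds(result: EstimationResult) -> np.ndarray:
    sds = np.zeros(len(result.coef_names))
    for name, s in zip(result.random_names, result.sds):
        sds[result.coef_names.index(name)] = s
    return sds


def predict_uptake(result: EstimationResult, scenario: UptakeScenario,
                   n_draws: int = 10000, seed: int = 12345,
                   spec: StudyDesignSpec | None = None,
                   _draws: np.ndarray | None = None) -> UptakePrediction:
    """Mean probability of choosing the scenario vaccine over opting out.

    Heterogeneity uses the fitted spread estimates; if the fit was a
    conditional logit (no random coefficients), the plug-in logit value is
    reported with a logged note.
    """
    spec = spec or result.study_spec
    if spec is None:
        raise InvalidSpecError("a StudyDesignSpec is required (none on the result)")
    _validate_scenario(scenario, spec)
    x = _scenario_x(scenario, spec, result.coef_names)
    sds = _full_sds(result)
    if not sds.any():
        if not result.random_names:
            logger.info("conditional logit fit: reporting the plug-in probability")
        v = float(result.means @ x)
        p = 1.0 / (1.0 + np.exp(-v))
        return UptakePrediction(float(p), None, 0.0, 1, None, scenario)
    if _draws is None:
        rng = np.random.default_rng(seed)
        _draws = rng.standard_normal((n_draws, len(result.coef_names)))
    beta = result.means + sds * _draws
    v = beta @ x
    p = 1.0 / (1.0 + np.exp(-v))
    return UptakePrediction(float(p.mean()), None,
                            float(p.std(ddof=1) / np.sqrt(len(p))),
                            len(p), seed, scenario)


def tornado_deltas(result: EstimationResult, base: UptakeScenario | None = None,
                   n_draws: int = 10000, seed: int = 12345,
                   spec: StudyDesignSpec | None = None) -> pd.DataFrame:
    """One-at-a-time level changes from the base case, as uptake deltas.

    Returns one row per non-reference level of each non-price attribute
    with the scenario probability and its delta versus the base case in
    percentage points, sorted by |delta| descending.  Common random
    numbers are shared across scenarios so deltas are not dominated by
    Monte-Carlo noise.
    """
    spec = spec or result.study_spec
    if spec is None:
        raise InvalidSpecError("a StudyDesignSpec is required (none on the result)")
    if base is None:
        base = base_case(spec)
    sds = _full_sds(result)
    draws = None
    if sds.any():
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_draws, len(result.coef_names)))
    pred_base = predict_uptake(result, base, n_draws, seed, spec, _draws=draws)

    rows = [{
        "attribute": "(base case)", "level": "", "probability": pred_base.probability,
        "delta_pp": 0.0, "mc_se": pred_base.mc_se,
    }]
    for a in spec.attributes:
        if a.coding != CATEGORICAL:
            continue
        for lv in a.levels:
            if lv == base.as_dict()[a.name]:
                continue
            pred = predict_uptake(result, base.replace(a.name, lv),
                                  n_draws, seed, spec, _draws=draws)
            rows.append({
                "attribute": a.name, "level": lv,
                "probability": pred.probability,
                "delta_pp": round(100.0 * (pred.probability - pred_base.probability), 2),
                "mc_se": pred.mc_se,
            })
    df = pd.DataFrame(rows)
    order = df["delta_pp"].abs().to_numpy()
    order[0] = np.inf  # keep the base case on top
    return df.iloc[np.argsort(-order, kind="stable")].reset_index(drop=True)


def plot_tornado(deltas: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of the tornado deltas (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = deltas[deltas["attribute"] != "(base case)"]
    labels = df["attribute"] + " = " + df["level"].astype(str)
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
    ax.barh(labels[::-1], df["delta_pp"][::-1],
            color=np.where(df["delta_pp"][::-1] >= 0, "#2b7bba", "#c23b22"))
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("change in predicted uptake vs base case (percentage points)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
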