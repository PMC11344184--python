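"""Willingness to pay (WTP) from fitted choice-model coefficients.

WTP for a one-level attribute change is the ratio of its utility
coefficient to the negative of the price coefficient,

    WTP_k = beta_k / (-beta_price)    [CN¥],

i.e. the money amount whose utility cost exactly offsets the attribute's
utility gain.  Ratios of means are used (the price coefficient held
fixed/non-random).  Confidence intervals come from bootstrapping:

* ``parametric`` (default): draw coefficient vectors from the asymptotic
  normal of the estimates (the Krinsky–Robb procedure) and take
  percentile bounds of the implied ratios;
* ``nonparametric``: resample respondents with replacement and refit the
  model — rigorous but slow; requires the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import LongChoiceTable
from .errors import InvalidSpecError, UndefinedWTPError
from .mixlogit import EstimationResult, ModelSpec, fit_mixed_logit

PRICE_NAME = "price"
CONSTANT_NAME = "const"


@dataclass
class WTPTable:
    """Per-level monetary values (CN¥) with optional CI bounds and metadata."""

    table: pd.DataFrame  # columns: term, wtp[, ci_low, ci_high]
    method: str = "point"
    replicates: int = 0
    seed: int | None = None

    def value(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term, "wtp"]
        if row.empty:
            raise KeyError(term)
        return float(row.iloc[0])

    def converted(self, rate: float) -> pd.DataFrame:
        """Display helper: the table with values multiplied by a user-supplied
        currency rate (e.g. CN¥ → US$)."""
        out = self.table.copy()
        for c in ("wtp", "ci_low", "ci_high"):
            if c in out.columns:
                out[c] = out[c] * rate
        return out


def _wtp_terms(coef_names: list[str], price_name: str) -> list[str]:
    return [c for c in coef_names if c not in (price_name, CONSTANT_NAME)]


def compute_wtp(result: EstimationResult, price_name: str = PRICE_NAME) -> WTPTable:
    """Point WTP per non-price attribute level: mean_k / (−mean_price)."""
    if price_name not in result.coef_names:
        raise InvalidSpecError(f"no coefficient named {price_name!r}")
    b_price = result.mean(price_name)
    if b_price == 0:
        raise UndefinedWTPError("price coefficient is zero; WTP undefined")
    if b_price > 0:
        warnings.warn("price coefficient is positive; WTP signs will be inverted",
                      stacklevel=2)
    terms = _wtp_terms(result.coef_names, price_name)
    wtp = [result.mean(t) / (-b_price) for t in terms]
    return WTPTable(pd.DataFrame({"term": terms, "wtp": wtp}))


def wtp_confidence_intervals(
    result: EstimationResult,
    method: str = "parametric",
    replicates: int = 1000,
    seed: int = 12345,
    data: LongChoiceTable | None = None,
    model: ModelSpec | None = None,
    price_name: str = PRICE_NAME,
    level: float = 0.95,
) -> WTPTable:
    """Bootstrap percentile CIs around the point WTP estimates."""
    if replicates < 100:
        warnings.warn(f"{replicates} bootstrap replicates is low; intervals "
                      "will be noisy", stacklevel=2)
    point = compute_wtp(result, price_name)
    terms = list(point.table["term"])
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0

    if method == "parametric":
        K = len(result.coef_names)
        cov = result.mean_vcov
        if not np.all(np.isfinite(cov)):
            raise InvalidSpecError("variance–covariance matrix contains non-finite values")
        draws = rng.multivariate_normal(result.means, cov, size=replicates,
                                        method="svd")
        ip = result.coef_names.index(price_name)
        idx = [result.coef_names.index(t) for t in terms]
        ratios = draws[:, idx] / (-draws[:, [ip]])
    elif method == "nonparametric":
        if data is None:
            raise InvalidSpecError("nonparametric bootstrap requires the data")
        model = model or result.model
        resp = data.data["respondent_id"].unique()
        ratios = np.empty((replicates, len(terms)))
        for b in range(replicates):
            sample = rng.choice(resp, size=len(resp), replace=True)
            parts = []
            for new_id, rid in enumerate(sample, start=1):
                grp = data.data[data.data["respondent_id"] == rid].copy()
                grp["respondent_id"] = new_id
                parts.append(grp)
            boot = LongChoiceTable(pd.concat(parts, ignore_index=True), data.spec)
            fit = fit_mixed_logit(boot, model)
            w = compute_wtp(fit, price_name)
            ratios[b] = [w.value(t) for t in terms]
    else:
        raise InvalidSpecError(f"unknown bootstrap method {method!r}")

    lo = np.quantile(ratios, alpha, axis=0)
    hi = np.quantile(ratios, 1 - alpha, axis=0)
    table = point.table.assign(ci_low=lo, ci_high=hi)
    return WTPTable(table, method=method, replicates=replicates, seed=seed)


def bundle_wtp(wtp: WTPTable, changes: Mapping[str, int]) -> float:
    """WTP of a bundle of attribute changes (linearity in the numerator).

    ``changes`` maps coefficient names to +1 (move from the reference
    level to this level) or −1 (move from this level back to the
    reference).  E.g. upgrading effectiveness to 90 while removing a
    20/100 side-effect risk sums ``{"effectiveness_90": +1,
    "skin_risk_20_100": -1}``.
    """
    return float(sum(sign * wtp.value(term) for term, sign in changes.items()))
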