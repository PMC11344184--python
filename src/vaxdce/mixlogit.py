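"""Panel mixed logit estimation by maximum simulated likelihood (MSL).

Model
-----
Respondent r's utility for alternative j in task t is

    U_rtj = beta_r' x_rtj + eps_rtj,

with eps iid standard Gumbel, so conditional on beta_r the choice
probabilities are softmax in the utilities.  Coefficients are random
across respondents, beta_r ~ Normal(b, diag(s^2)) (independent normals;
any subset may be held fixed, and with every coefficient fixed the model
is the conditional logit).  The panel simulated likelihood averages, over
draws of beta_r, the product over the respondent's tasks of the chosen
alternative's probability:

    SL_r = (1/D) sum_d prod_t P_rt(beta_rd),    LL = sum_r log SL_r.

Draws are scrambled Halton sequences by default (pseudo-random optional),
held fixed across optimizer iterations so the objective is smooth and the
fit is deterministic given the seed.  The optimizer is L-BFGS-B on the
negative simulated log-likelihood with an analytic gradient; standard
errors come from the inverse observed information (numerically
differentiated analytic score), with a respondent-clustered sandwich
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import norm, qmc

from .data import LongChoiceTable
from .design import StudyDesignSpec
from .errors import IdentifiabilityError, InvalidSpecError

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class ModelSpec:
    """Mixed logit configuration.

    ``random_coefficients`` is ``"all"`` (every coefficient random, the
    default), ``"none"``/empty (conditional logit), or an explicit list of
    coefficient names.  ``n_draws`` simulation draws per respondent are
    generated by ``draw_scheme`` (``"halton"`` scrambled low-discrepancy,
    or ``"pseudo"``) from ``seed``.
    """

    random_coefficients: str | tuple[str, ...] = "all"
    n_draws: int = 500
    draw_scheme: str = "halton"
    seed: int = 12345
    tol: float = 1e-6          # sup-norm gradient tolerance at the optimum
    maxiter: int = 2000
    robust_se: bool = False

    def __post_init__(self):
        if self.n_draws < 1:
            raise InvalidSpecError("n_draws must be >= 1")
        if self.draw_scheme not in ("halton", "pseudo"):
            raise InvalidSpecError(f"unknown draw scheme {self.draw_scheme!r}")
        if not isinstance(self.random_coefficients, str):
            object.__setattr__(self, "random_coefficients",
                               tuple(self.random_coefficients))

    def resolve_random(self, names: Sequence[str]) -> list[str]:
        if self.random_coefficients == "all":
            return list(names)
        if self.random_coefficients in ("none", ()):
            return []
        unknown = [c for c in self.random_coefficients if c not in names]
        if unknown:
            raise InvalidSpecError(f"unknown random coefficients {unknown}")
        return [c for c in names if c in self.random_coefficients]


CONDITIONAL_LOGIT = ModelSpec(random_coefficients=(), n_draws=1)


def choice_probabilities(utilities) -> np.ndarray:
    """Softmax choice probabilities, overflow-safe via max subtraction.

    Accepts a 1-D utility vector or an array whose last axis indexes
    alternatives; probabilities sum to 1 along that axis and are invariant
    to adding a constant to all utilities of a task.
    """
    v = np.asarray(utilities, dtype=float)
    if v.size == 0 or v.shape[-1] == 0:
        raise InvalidSpecError("need at least one alternative")
    if not np.all(np.isfinite(v)):
        raise InvalidSpecError("utilities must be finite")
    v = v - v.max(axis=-1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Panel tensors


@dataclass
class _Panel:
    X: np.ndarray          # (R, T, A, K) covariates; padded slots are zero
    chosen: np.ndarray     # (R, T) chosen alternative index (0 for padding)
    alt_mask: np.ndarray   # (R, T, A) True where the alternative exists
    coef_names: list[str]
    respondent_ids: np.ndarray
    n_tasks: int           # total observed tasks

    @property
    def R(self):
        return self.X.shape[0]

    @property
    def K(self):
        return self.X.shape[3]


def _build_panel(table: LongChoiceTable) -> _Panel:
    df = table.data
    coef_names = table.coefficient_columns
    r_codes, r_ids = pd.factorize(df["respondent_id"], sort=True)
    work = df.assign(_r=r_codes)
    # task index within respondent, alternative index within task
    t_codes = work.groupby("_r", sort=False)["task_id"].transform(
        lambda s: pd.factorize(s)[0])
    a_codes = work.groupby(["_r", "task_id"], sort=False).cumcount()
    R = len(r_ids)
    T = int(t_codes.max()) + 1
    A = int(a_codes.max()) + 1
    K = len(coef_names)

    X = np.zeros((R, T, A, K))
    alt_mask = np.zeros((R, T, A), dtype=bool)
    chosen = np.zeros((R, T), dtype=int)
    ri = work["_r"].to_numpy()
    ti = t_codes.to_numpy()
    ai = a_codes.to_numpy()
    X[ri, ti, ai] = work[coef_names].to_numpy(dtype=float)
    alt_mask[ri, ti, ai] = True
    ch = work["chosen"].to_numpy() == 1
    chosen[ri[ch], ti[ch]] = ai[ch]
    # padded tasks (respondent answered fewer than T): pretend a single
    # zero-covariate alternative was "chosen" — contributes log(1)=0 to the
    # likelihood and a zero score, so no special-casing downstream
    task_mask = alt_mask.any(axis=2)
    alt_mask[~task_mask, 0] = True
    n_tasks = int(task_mask.sum())
    return _Panel(X, chosen, alt_mask, list(coef_names), np.asarray(r_ids), n_tasks)


def _standard_draws(R: int, D: int, Kr: int, scheme: str, seed: int) -> np.ndarray:
    """Standard-normal mixing draws, shape (R, D, Kr), fixed for a fit."""
    if Kr == 0:
        return np.zeros((R, D, 0))
    if scheme == "halton":
        sampler = qmc.Halton(d=Kr, scramble=True, seed=seed)
        u = sampler.random(R * D)
    else:
        u = np.random.default_rng(seed).random((R * D, Kr))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return ndtri(u).reshape(R, D, Kr)


# ---------------------------------------------------------------------------
# Likelihood and gradient


def _loglik_parts(theta: np.ndarray, panel: _Panel, rand_idx: np.ndarray,
                  draws: np.ndarray, want_grad: bool):
    """Simulated log-likelihood; optionally its gradient and per-respondent scores."""
    R, T, A, K = panel.X.shape
    D = draws.shape[1]
    Kr = len(rand_idx)
    means = theta[:K]
    sds = theta[K:]

    beta = np.broadcast_to(means, (R, D, K)).copy()
    if Kr:
        beta[:, :, rand_idx] += sds * draws

    Xf = panel.X.reshape(R, T * A, K)
    V = np.matmul(beta, Xf.transpose(0, 2, 1)).reshape(R, D, T, A)
    V = np.where(panel.alt_mask[:, None, :, :], V, -np.inf)
    Vmax = V.max(axis=3, keepdims=True)
    E = np.exp(V - Vmax)
    denom = E.sum(axis=3)
    # log P(chosen): V_chosen - logsumexp
    idx_r = np.arange(R)[:, None, None]
    idx_t = np.arange(T)[None, None, :]
    v_chosen = V[idx_r, np.arange(D)[None, :, None], idx_t,
                 panel.chosen[:, None, :]]
    logp = v_chosen - (np.log(denom) + Vmax[..., 0])  # (R, D, T)
    ll_rd = logp.sum(axis=2)  # (R, D)

    m = ll_rd.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(ll_rd - m).sum(axis=1))
    ll = float(lse.sum() - R * np.log(D))
    if not want_grad:
        return ll, None, None

    w = np.exp(ll_rd - lse[:, None])  # (R, D), rows sum to 1
    P = E / denom[..., None]          # (R, D, T, A); zero on masked alts
    # score per (r, d): sum_t [x_chosen - E_P x]
    x_chosen = panel.X[np.arange(R)[:, None], np.arange(T)[None, :],
                       panel.chosen]                       # (R, T, K)
    s1 = x_chosen.sum(axis=1)                              # (R, K)
    s2 = np.matmul(P.reshape(R, D, T * A), Xf)             # (R, D, K)
    g = s1[:, None, :] - s2                                # (R, D, K)

    score_means = np.einsum("rd,rdk->rk", w, g)            # (R, K)
    parts = [score_means]
    if Kr:
        parts.append(np.einsum("rd,rdk->rk", w, g[:, :, rand_idx] * draws))
    scores = np.concatenate(parts, axis=1)                 # (R, K+Kr)
    return ll, scores.sum(axis=0), scores


def simulated_loglik(means, sds, data: LongChoiceTable,
                     model: ModelSpec = ModelSpec()) -> float:
    """Panel simulated log-likelihood at the given parameter values.

    ``means`` covers every coefficient (in ``data.coefficient_columns``
    order); ``sds`` covers the model's random coefficients (scalar or
    vector; ignored entries for fixed coefficients are not accepted).
    With all sds zero this equals the conditional logit log-likelihood
    exactly, for any draw count.
    """
    panel = _build_panel(data)
    means = np.asarray(means, dtype=float)
    if means.shape != (panel.K,):
        raise InvalidSpecError(
            f"means must have length {panel.K} (got {means.shape})")
    rand_names = model.resolve_random(panel.coef_names)
    rand_idx = np.array([panel.coef_names.index(c) for c in rand_names], dtype=int)
    sds = np.broadcast_to(np.asarray(sds, dtype=float), (len(rand_idx),))
    if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
        raise InvalidSpecError("parameters must be finite")
    draws = _standard_draws(panel.R, model.n_draws, len(rand_idx),
                            model.draw_scheme, model.seed)
    theta = np.concatenate([means, sds])
    ll, _, _ = _loglik_parts(theta, panel, rand_idx, draws, want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# Results


@dataclass
class EstimationResult:
    """Fitted mixed logit: means, spreads, uncertainty, fit metadata.

    ``param_names`` lists the estimated parameters in vcov order: the K
    coefficient means followed by ``sd:<name>`` for each random
    coefficient.  Spread estimates are reported as absolute values (the
    sign is unidentified under normal mixing).  Confidence intervals are
    the normal approximation, estimate ± 1.96·SE.
    """

    coef_names: list[str]
    random_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    se: np.ndarray            # aligned with param_names
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_respondents: int
    n_tasks: int
    n_rows: int
    model: ModelSpec
    study_spec: StudyDesignSpec | None = None
    message: str = ""

    @property
    def param_names(self) -> list[str]:
        return list(self.coef_names) + [f"sd:{c}" for c in self.random_names]

    @property
    def estimates(self) -> np.ndarray:
        return np.concatenate([self.means, self.sds])

    def mean(self, name: str) -> float:
        return float(self.means[self.coef_names.index(name)])

    def sd(self, name: str) -> float:
        return float(self.sds[self.random_names.index(name)])

    @property
    def mean_vcov(self) -> np.ndarray:
        """Variance–covariance of the coefficient means (the block used by WTP)."""
        K = len(self.coef_names)
        return self.vcov[:K, :K]

    def summary(self) -> pd.DataFrame:
        est = self.estimates
        z = np.divide(est, self.se, out=np.full_like(est, np.nan),
                      where=self.se > 0)
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.param_names,
            "estimate": est,
            "se": self.se,
            "ci_low": est - Z_95 * self.se,
            "ci_high": est + Z_95 * self.se,
            "p_value": p,
            "significant": p <= 0.05,
        })

    def to_dict(self) -> dict:
        return {
            "coef_names": list(self.coef_names),
            "random_names": list(self.random_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_respondents": self.n_respondents,
            "n_tasks": self.n_tasks,
            "n_rows": self.n_rows,
            "model": {
                "random_coefficients": list(self.random_names),
                "n_draws": self.model.n_draws,
                "draw_scheme": self.model.draw_scheme,
                "seed": self.model.seed,
            },
            "message": self.message,
        }


def _numeric_hessian(fun_grad, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    P = len(theta)
    H = np.zeros((P, P))
    for j in range(P):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (fun_grad(tp) - fun_grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_mixed_logit(data: LongChoiceTable,
                    model: ModelSpec = ModelSpec()) -> EstimationResult:
    """Fit the panel mixed logit (or conditional logit) to a choice table.

    Starting values are the conditional logit estimates for means and 0.1
    for spreads.  With the same data, model and seed two runs produce
    bit-identical results.  Raises :class:`IdentifiabilityError` if a
    covariate does not vary; non-convergence is flagged on the result, not
    silently ignored.
    """
    panel = _build_panel(data)
    obs = panel.X[panel.alt_mask]
    for k, name in enumerate(panel.coef_names):
        if np.ptp(obs[:, k]) == 0:
            raise IdentifiabilityError(
                f"covariate {name!r} does not vary in the data")

    # standardize columns internally: utility is invariant under x -> x/s,
    # beta -> beta*s, and the optimizer conditioning improves enormously
    # when price (hundreds of yuan) and 0/1 dummies share a scale
    col_scale = obs.std(axis=0)
    panel.X = panel.X / col_scale

    rand_names = model.resolve_random(panel.coef_names)
    rand_idx = np.array([panel.coef_names.index(c) for c in rand_names], dtype=int)
    K, Kr = panel.K, len(rand_names)

    # conditional logit (D=1, no spreads) for starting values / the CL path
    cl_draws = np.zeros((panel.R, 1, 0))
    no_rand = np.array([], dtype=int)

    def cl_negll(th):
        ll, g, _ = _loglik_parts(th, panel, no_rand, cl_draws, want_grad=True)
        return -ll, -g

    res_cl = optimize.minimize(cl_negll, np.zeros(K), jac=True, method="L-BFGS-B",
                               options={"maxiter": model.maxiter,
                                        "ftol": 1e-13, "gtol": model.tol})
    if Kr == 0:
        theta_hat = res_cl.x
        draws = cl_draws
        idx = no_rand
        res_opt = res_cl
    else:
        draws = _standard_draws(panel.R, model.n_draws, Kr,
                                model.draw_scheme, model.seed)
        idx = rand_idx
        theta0 = np.concatenate([res_cl.x, np.full(Kr, 0.1)])

        def negll(th):
            ll, g, _ = _loglik_parts(th, panel, idx, draws, want_grad=True)
            return -ll, -g

        res_opt = optimize.minimize(negll, theta0, jac=True, method="L-BFGS-B",
                                    options={"maxiter": model.maxiter,
                                             "ftol": 1e-11,
                                             "gtol": max(model.tol, 1e-5)})
        theta_hat = res_opt.x.copy()
        theta_hat[K:] = np.abs(theta_hat[K:])  # sign of sd unidentified

    ll_hat, grad_hat, scores = _loglik_parts(theta_hat, panel, idx, draws,
                                             want_grad=True)

    def grad_only(th):
        _, g, _ = _loglik_parts(th, panel, idx, draws, want_grad=True)
        return g

    H = _numeric_hessian(grad_only, theta_hat)  # Hessian of LL
    info = -H                                   # observed information
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular fits
        vcov = np.linalg.pinv(info)
    vcov = 0.5 * (vcov + vcov.T)
    if model.robust_se:
        meat = scores.T @ scores
        vcov = vcov @ meat @ vcov
        vcov = 0.5 * (vcov + vcov.T)

    # undo the internal column scaling: beta = beta_scaled / s
    theta_scale = np.concatenate([col_scale, col_scale[idx]]) if Kr else col_scale
    theta_hat = theta_hat / theta_scale
    vcov = vcov / np.outer(theta_scale, theta_scale)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    converged = bool(res_opt.success)
    if not converged:
        logger.warning("optimizer did not report convergence: %s",
                       res_opt.message)
    return EstimationResult(
        coef_names=list(panel.coef_names),
        random_names=list(rand_names),
        means=theta_hat[:K],
        sds=theta_hat[K:],
        se=se,
        vcov=vcov,
        loglik=float(ll_hat),
        converged=converged,
        n_respondents=panel.R,
        n_tasks=panel.n_tasks,
        n_rows=data.n_rows,
        model=model,
        study_spec=data.spec,
        message=str(res_opt.message),
    )
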