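"""Response model: arbitration, belief integration, choice and wager.

Arbitration weighs the two branches by their predicted level-1 precisions,
with the advice branch multiplied by the social bias ``zeta``:

    xi_a = zeta * pihat1_a / (zeta * pihat1_a + pihat1_c),   xi_c = 1 - xi_a

The integrated outcome belief is the convex combination of the advice-frame
probabilities of both branches; the probability of taking the advice is a
softmax of that belief with inverse temperature ``beta_ch``; and the log wager
is a linear function of belief uncertainty, arbitration, informational
uncertainty and environmental volatility of both branches, with Gaussian noise
of SD ``beta_wager`` on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .hgf import BranchTrajectory
from .params import ResponseParams

__all__ = [
    "arbitrate",
    "integrate_belief",
    "choice_probability",
    "wager_mean",
    "wager_loglik",
    "TrialPredictions",
    "predict_run",
    "choice_loglik",
    "data_loglik",
]

_PCLIP = 1e-9
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def arbitrate(pi1hat_a, pi1hat_c, zeta):
    """Arbitration weights (xi_a, xi_c) from level-1 predicted precisions.

    Accepts scalars or arrays. ``zeta = inf`` gives pure reliance on advice,
    ``zeta = 0`` pure reliance on the card branch.
    """
    pa = np.asarray(pi1hat_a, dtype=float)
    pc = np.asarray(pi1hat_c, dtype=float)
    if np.any(pa <= 0) or np.any(pc <= 0):
        if np.any((pa == 0) & (pc == 0)):
            raise ValueError("arbitration undefined: both precisions are zero")
        raise ValueError("predicted precisions must be positive")
    if zeta < 0:
        raise ValueError("zeta must be >= 0")
    if math.isinf(zeta):
        xi_a = np.ones_like(pa)
    else:
        xi_a = zeta * pa / (zeta * pa + pc)
    xi_c = 1.0 - xi_a
    if np.ndim(pi1hat_a) == 0 and np.ndim(pi1hat_c) == 0:
        return float(xi_a), float(xi_c)
    return xi_a, xi_c


def integrate_belief(xi_a, mu1hat_a, xi_c, mu1hat_c_adviceframe):
    """Precision-weighted integration of the two outcome predictions.

    Both probabilities must be expressed in the advice frame (probability that
    the advised color wins); ``mu1hat_c_adviceframe`` is the card-branch
    probability flipped to that frame where the advice points to the other
    color.
    """
    return xi_a * np.asarray(mu1hat_a) + xi_c * np.asarray(mu1hat_c_adviceframe)


def card_to_advice_frame(mu1hat_c, advice_color):
    """Re-express p(blue wins) as p(advised color wins)."""
    advice_color = np.asarray(advice_color)
    return np.where(advice_color == 1, mu1hat_c, 1.0 - mu1hat_c)


def choice_probability(mu1hat_b, beta_ch):
    """Softmax probability of taking the advice.

    p = mu^beta / (mu^beta + (1-mu)^beta), computed as a logistic of
    beta * logit(mu) for numerical stability.
    """
    if beta_ch <= 0:
        raise ValueError("beta_ch must be > 0")
    mu = np.clip(np.asarray(mu1hat_b, dtype=float), _PCLIP, 1.0 - _PCLIP)
    a = beta_ch * (np.log(mu) - np.log1p(-mu))
    p = expit(a)
    if np.ndim(mu1hat_b) == 0:
        return float(p)
    return p


def wager_mean(sigma_b_hat, xi_a, i2_a, i2_c, v3_a, v3_c, resp: ResponseParams):
    """Expected log wager: linear combination of the uncertainty read-outs."""
    return (resp.beta0
            + resp.beta1 * np.asarray(sigma_b_hat)
            + resp.beta2 * np.asarray(xi_a)
            + resp.beta3 * np.asarray(i2_a)
            + resp.beta4 * np.asarray(i2_c)
            + resp.beta5 * np.asarray(v3_a)
            + resp.beta6 * np.asarray(v3_c))


def wager_loglik(wager, wager_mean_log, beta_wager):
    """Gaussian log density of log(wager) around the predicted log wager.

    ``beta_wager`` is the SD of the log-wager noise. Wagers must be integers
    in [1, 10]; the density is continuous (no discretization correction).
    """
    w = np.asarray(wager)
    if np.any((w < 1) | (w > 10)):
        raise ValueError("wagers must lie in [1, 10]")
    if beta_wager <= 0:
        raise ValueError("beta_wager must be > 0")
    z = (np.log(w) - np.asarray(wager_mean_log)) / beta_wager
    # extreme optimizer excursions overflow to -inf log density; the MAP
    # objective converts that into its finite penalty, so only the warning
    # needs suppressing
    with np.errstate(over="ignore"):
        ll = -_LOG_SQRT_2PI - math.log(beta_wager) - 0.5 * z * z
    if np.ndim(wager) == 0 and np.ndim(wager_mean_log) == 0:
        return float(ll)
    return ll


@dataclass
class TrialPredictions:
    """Per-trial response-model quantities for one run."""

    xi_a: np.ndarray
    xi_c: np.ndarray
    mu1hat_b: np.ndarray        # integrated p(advised color wins)
    sigma_b_hat: np.ndarray     # irreducible belief uncertainty
    i2_a: np.ndarray            # informational uncertainty, advice
    i2_c: np.ndarray            # informational uncertainty, card
    v3_a: np.ndarray            # environmental volatility, advice
    v3_c: np.ndarray            # environmental volatility, card
    p_take_advice: np.ndarray
    wager_mean_log: np.ndarray

    def __len__(self) -> int:
        return len(self.xi_a)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "xi_a": self.xi_a, "xi_c": self.xi_c,
            "mu1hat_b": self.mu1hat_b, "sigma_b_hat": self.sigma_b_hat,
            "i2_a": self.i2_a, "i2_c": self.i2_c,
            "v3_a": self.v3_a, "v3_c": self.v3_c,
            "p_take_advice": self.p_take_advice,
            "wager_mean_log": self.wager_mean_log,
        })
        df.insert(0, "trial_index", np.arange(1, len(self) + 1))
        return df


def predict_run(traj_a: BranchTrajectory, traj_c: BranchTrajectory,
                advice_color: np.ndarray, resp: ResponseParams,
                response_variant: str = "arbitrated") -> TrialPredictions:
    """Compute all trial-wise response quantities for one run.

    ``advice_only`` and ``card_only`` are the zeta = inf and zeta = 0 limits
    of the arbitrated rule.
    """
    if len(traj_a) != len(traj_c) or len(traj_a) != len(advice_color):
        raise ValueError("trajectories and advice sequence are misaligned")

    if response_variant == "advice_only":
        zeta = math.inf
    elif response_variant == "card_only":
        zeta = 0.0
    elif response_variant == "arbitrated":
        zeta = resp.zeta
    else:
        raise ValueError(f"unknown response variant {response_variant!r}")

    xi_a, xi_c = arbitrate(traj_a.pi1hat, traj_c.pi1hat, zeta)
    mu_c_frame = card_to_advice_frame(traj_c.mu1hat, advice_color)
    mu_b = np.clip(integrate_belief(xi_a, traj_a.mu1hat, xi_c, mu_c_frame),
                   _PCLIP, 1.0 - _PCLIP)
    sigma_b_hat = mu_b * (1.0 - mu_b)

    var_a = traj_a.mu1hat * (1.0 - traj_a.mu1hat)
    var_c = traj_c.mu1hat * (1.0 - traj_c.mu1hat)
    i2_a = var_a * traj_a.sigma2hat
    i2_c = var_c * traj_c.sigma2hat
    v3_a = var_a * np.exp(np.clip(traj_a.mu3_prev, -700, 700))
    v3_c = var_c * np.exp(np.clip(traj_c.mu3_prev, -700, 700))

    p_take = choice_probability(mu_b, resp.beta_ch)
    wmean = wager_mean(sigma_b_hat, xi_a, i2_a, i2_c, v3_a, v3_c, resp)

    return TrialPredictions(xi_a=np.broadcast_to(np.asarray(xi_a, float), mu_b.shape).copy(),
                            xi_c=np.broadcast_to(np.asarray(xi_c, float), mu_b.shape).copy(),
                            mu1hat_b=mu_b, sigma_b_hat=sigma_b_hat,
                            i2_a=i2_a, i2_c=i2_c, v3_a=v3_a, v3_c=v3_c,
                            p_take_advice=np.asarray(p_take, float),
                            wager_mean_log=np.asarray(wmean, float))


def choice_loglik(choices: np.ndarray, mu1hat_b: np.ndarray, beta_ch: float) -> float:
    """Total Bernoulli log-likelihood of the advice-taking choices.

    Computed from the softmax argument directly so that extreme beliefs under
    a large inverse temperature do not underflow.
    """
    y = np.asarray(choices, dtype=float)
    mu = np.clip(np.asarray(mu1hat_b, dtype=float), _PCLIP, 1.0 - _PCLIP)
    a = beta_ch * (np.log(mu) - np.log1p(-mu))
    # log p(y=1) = -log(1+e^-a); log p(y=0) = -log(1+e^a)
    ll = -(np.logaddexp(0.0, -a) * y + np.logaddexp(0.0, a) * (1.0 - y))
    return float(np.sum(ll))


def data_loglik(choices: np.ndarray, wagers: np.ndarray,
                pred: TrialPredictions, resp: ResponseParams) -> float:
    """Joint log-likelihood of choices and wagers given trial predictions."""
    ll_choice = choice_loglik(choices, pred.mu1hat_b, resp.beta_ch)
    ll_wager = float(np.sum(wager_loglik(wagers, pred.wager_mean_log, resp.beta_wager)))
    return ll_choice + ll_wager
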