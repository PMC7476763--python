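"""Binary hierarchical Gaussian filter for one information branch.

The filter tracks three coupled hidden states of a binary input stream: the
trial outcome probability (level 1, a sigmoid read-out of level 2), the
tendency of the generating process (level 2, a Gaussian random walk whose step
size is controlled by level 3) and the log-volatility of that tendency
(level 3, a Gaussian random walk with meta-volatility ``theta``). Each trial
yields closed-form update equations in which belief means move by
precision-weighted prediction errors.

Both information branches of the task - the advice stream (input: was the
advice accurate?) and the card stream (input: was blue rewarded?) - use this
same code path with their own parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import PerceptualParams

__all__ = [
    "BranchTrajectory",
    "FilterDivergenceError",
    "predict_probability",
    "update_branch",
    "filter_sequence",
]

#: Overflow guard for exp() of log-volatility terms.
_EXP_CAP = 700.0


class FilterDivergenceError(FloatingPointError):
    """Raised when a trial update produces a non-positive precision."""

    def __init__(self, trial: int, message: str = "non-positive precision"):
        self.trial = trial
        super().__init__(f"filter diverged at trial {trial}: {message}")


def predict_probability(mu2_prev: float) -> float:
    """Predicted outcome probability: logistic sigmoid of the level-2 mean."""
    if mu2_prev >= 0:
        return 1.0 / (1.0 + math.exp(-min(mu2_prev, _EXP_CAP)))
    e = math.exp(max(mu2_prev, -_EXP_CAP))
    return e / (1.0 + e)


@dataclass
class BranchTrajectory:
    """Trial-wise belief states and prediction errors of one branch.

    All arrays have length T. ``mu1hat``, ``pi1hat``, ``pi2hat``, ``pi3hat``
    and ``sigma2hat`` are *predictions* (before seeing trial k's input);
    ``mu2``, ``pi2``, ``mu3``, ``pi3`` are posteriors after the update.
    ``mu3_prev`` is the level-3 mean the prediction was based on (the previous
    trial's posterior), needed by the volatility read-outs of the response
    model.
    """

    mu1hat: np.ndarray
    pi1hat: np.ndarray
    mu2: np.ndarray
    pi2: np.ndarray
    pi2hat: np.ndarray
    sigma2hat: np.ndarray
    mu3: np.ndarray
    pi3: np.ndarray
    pi3hat: np.ndarray
    mu3_prev: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    eps2: np.ndarray
    eps3: np.ndarray

    def __len__(self) -> int:
        return len(self.mu1hat)

    def to_frame(self, suffix: str = ""):
        """Export as a pandas DataFrame, one row per trial."""
        import pandas as pd

        cols = {
            f"mu1hat{suffix}": self.mu1hat,
            f"pi1hat{suffix}": self.pi1hat,
            f"mu2{suffix}": self.mu2,
            f"pi2{suffix}": self.pi2,
            f"pi2hat{suffix}": self.pi2hat,
            f"sigma2hat{suffix}": self.sigma2hat,
            f"mu3{suffix}": self.mu3,
            f"pi3{suffix}": self.pi3,
            f"pi3hat{suffix}": self.pi3hat,
            f"delta1{suffix}": self.delta1,
            f"delta2{suffix}": self.delta2,
            f"eps2{suffix}": self.eps2,
            f"eps3{suffix}": self.eps3,
        }
        df = pd.DataFrame(cols)
        df.insert(0, "trial_index", np.arange(1, len(self) + 1))
        return df


def update_branch(state: tuple[float, float, float, float], u: float,
                  kappa: float, theta: float, omega: float,
                  trial: int = 0) -> tuple[tuple[float, float, float, float], dict[str, float]]:
    """One full trial update of a branch.

    ``state`` is ``(mu2, sigma2, mu3, sigma3)`` from the previous trial;
    ``u`` is the binary input. Returns the new state and a record of all
    intermediate quantities.
    """
    mu2p, s2p, mu3p, s3p = state

    # prediction step
    muh1 = min(max(predict_probability(mu2p), 1e-13), 1.0 - 1e-13)
    pih1 = 1.0 / (muh1 * (1.0 - muh1))
    v = math.exp(min(kappa * mu3p + omega, _EXP_CAP))
    s2hat = s2p + v
    pih2 = 1.0 / s2hat
    pih3 = 1.0 / (s3p + theta)

    # level-2 update (outcome prediction error)
    d1 = u - muh1
    pi2 = pih2 + muh1 * (1.0 - muh1)
    dmu2 = d1 / pi2
    mu2 = mu2p + dmu2
    e2 = d1 / pi2

    # level-3 update (volatility prediction error)
    w2 = v * pih2
    d2 = (1.0 / pi2 + dmu2 * dmu2) * pih2 - 1.0
    pi3 = pih3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
    if pi3 <= 0.0 or not math.isfinite(pi3):
        raise FilterDivergenceError(trial)
    mu3 = mu3p + 0.5 * kappa * w2 * d2 / pi3
    e3 = d2 / pi3

    record = {
        "mu1hat": muh1, "pi1hat": pih1, "pi2hat": pih2, "sigma2hat": s2hat,
        "pi3hat": pih3, "mu2": mu2, "pi2": pi2, "mu3": mu3, "pi3": pi3,
        "mu3_prev": mu3p, "delta1": d1, "delta2": d2, "eps2": e2, "eps3": e3,
    }
    return (mu2, 1.0 / pi2, mu3, 1.0 / pi3), record


def _filter_kernel(u, kappa, theta, omega, mu2_0, sigma2_0, mu3_0, sigma3_0,
                   mu1hat, pi1hat, mu2, pi2, pi2hat, sigma2hat,
                   mu3, pi3, pi3hat, mu3_prev, delta1, delta2, eps2, eps3):
    """Sequential trial loop; returns 0 or the 1-based trial of divergence.

    Each trial depends on the previous posterior, so there is nothing to
    vectorize; the loop is written in scalar arithmetic so it can be JIT
    compiled (numba) and stays fast as the inner objective of the optimizer.
    """
    T = u.shape[0]
    mu2p = mu2_0
    s2p = sigma2_0
    mu3p = mu3_0
    s3p = sigma3_0
    cap = 700.0

    for k in range(T):
        x = mu2p
        if x >= 0:
            muh1 = 1.0 / (1.0 + math.exp(-x if x < cap else cap))
        else:
            e = math.exp(x if x > -cap else -cap)
            muh1 = e / (1.0 + e)
        # keep the prediction strictly inside (0, 1): a saturated sigmoid
        # would give zero first-level variance and infinite precision
        if muh1 < 1e-13:
            muh1 = 1e-13
        elif muh1 > 1.0 - 1e-13:
            muh1 = 1.0 - 1e-13
        var1 = muh1 * (1.0 - muh1)
        a = kappa * mu3p + omega
        v = math.exp(a if a < cap else cap)
        s2hat = s2p + v
        pih2 = 1.0 / s2hat
        pih3 = 1.0 / (s3p + theta)

        d1 = u[k] - muh1
        p2 = pih2 + var1
        dmu2 = d1 / p2
        m2 = mu2p + dmu2

        w2 = v * pih2
        d2 = (1.0 / p2 + dmu2 * dmu2) * pih2 - 1.0
        p3 = pih3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if p3 <= 0.0 or p3 != p3:
            return k + 1
        m3 = mu3p + 0.5 * kappa * w2 * d2 / p3

        mu1hat[k] = muh1
        pi1hat[k] = 1.0 / var1
        pi2hat[k] = pih2
        sigma2hat[k] = s2hat
        pi3hat[k] = pih3
        mu2[k] = m2
        pi2[k] = p2
        mu3[k] = m3
        pi3[k] = p3
        mu3_prev[k] = mu3p
        delta1[k] = d1
        delta2[k] = d2
        eps2[k] = d1 / p2
        eps3[k] = d2 / p3

        mu2p = m2
        s2p = 1.0 / p2
        mu3p = m3
        s3p = 1.0 / p3
    return 0


try:  # JIT compile when numba is available; the pure-Python loop is the fallback
    from numba import njit

    _filter_kernel = njit(cache=True, fastmath=False)(_filter_kernel)
except Exception:  # pragma: no cover - numba is an optional accelerator
    pass


def filter_sequence(inputs: np.ndarray, kappa: float, theta: float,
                    omega: float = -3.0, mu2_0: float = 0.0,
                    sigma2_0: float = 1.0, mu3_0: float = 1.0,
                    sigma3_0: float = 1.0) -> BranchTrajectory:
    """Filter a binary input sequence through the three-level model."""
    u = np.ascontiguousarray(inputs, dtype=float)
    if u.ndim != 1:
        raise ValueError("inputs must be a 1-D binary sequence")
    if not np.all((u == 0.0) | (u == 1.0)):
        raise ValueError("inputs must be binary (0/1)")
    T = len(u)

    arrays = [np.empty(T) for _ in range(14)]
    diverged = _filter_kernel(u, float(kappa), float(theta), float(omega),
                              float(mu2_0), float(sigma2_0), float(mu3_0),
                              float(sigma3_0), *arrays)
    if diverged:
        raise FilterDivergenceError(int(diverged))
    return BranchTrajectory(*arrays)


def filter_branches(u_advice: np.ndarray, u_card: np.ndarray,
                    perc: PerceptualParams) -> tuple[BranchTrajectory, BranchTrajectory]:
    """Run both branches of the two-branch filter with their own parameters."""
    traj_a = filter_sequence(u_advice, perc.kappa_a, perc.theta_a, perc.omega_a,
                             perc.mu2_0, perc.sigma2_0, perc.mu3_0, perc.sigma3_0)
    traj_c = filter_sequence(u_card, perc.kappa_c, perc.theta_c, perc.omega_c,
                             perc.mu2_0, perc.sigma2_0, perc.mu3_0, perc.sigma3_0)
    return traj_a, traj_c
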