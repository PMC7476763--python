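"""Synthetic task schedules and simulated agents for the advice-taking lottery.

The paradigm is a 160-trial binary card lottery with two independent
information sources. On each trial an advisor - privately informed about the
rewarded color with 80% accuracy - recommends a color, with helpful or
misleading intent that changes over the task; the participant also observes
the drawn card colors and can learn the color contingency. Both sources go
through stable phases (long runs of constant intent/contingency) and volatile
phases (rapid alternation), crossed in a 2x2 factorial design. On average the
advice is accurate on 56% of trials and blue is rewarded on 55% of trials.
Participants predict the color and wager 1-10 points, which are added to or
subtracted from a cumulative score.

Schedules are built by exact-count construction: per-phase counts of accurate
advice, advisor private-signal correctness, and blue outcomes are fixed by the
configured targets, and only their positions within phase runs are
randomized. Design-level statistics are therefore deterministic, and the
whole schedule is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .hgf import filter_branches
from .params import (ModelSpec, PerceptualParams, ResponseParams,
                     group_mean_perceptual, group_mean_response, model_by_name)
from .response import predict_run

__all__ = [
    "GeneratorConfig",
    "TaskSchedule",
    "SubjectData",
    "ConfigurationError",
    "generate_schedule",
    "simulate_agent",
    "score_run",
    "compare_volatility_tracking",
]


class ConfigurationError(ValueError):
    """Raised when a schedule configuration cannot realize its targets."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Design parameters of a synthetic schedule.

    Phases are given as ordered (label, length) runs per factor; their lengths
    must sum to ``n_trials`` and both labels must occur for each factor so the
    2x2 factorial structure is realized. Targets are enforced as exact trial
    counts (rounded to the nearest integer count).
    """

    n_trials: int = 160
    target_advice_accuracy: float = 0.56
    target_card_base_rate: float = 0.55
    advisor_info_accuracy: float = 0.80
    stable_contingency: float = 0.8
    advice_phases: tuple[tuple[str, int], ...] = (("stable", 64), ("volatile", 96))
    card_phases: tuple[tuple[str, int], ...] = (("stable", 32), ("volatile", 64), ("stable", 64))
    session_split: tuple[int, int] = (70, 90)
    seed: int = 0
    max_attempts: int = 200

    def validate(self) -> None:
        for name in ("target_advice_accuracy", "target_card_base_rate",
                     "advisor_info_accuracy", "stable_contingency"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in (0, 1)")
        if self.stable_contingency <= 0.5:
            raise ConfigurationError("stable_contingency must exceed 0.5")
        for factor, phases in (("advice", self.advice_phases), ("card", self.card_phases)):
            if sum(n for _, n in phases) != self.n_trials:
                raise ConfigurationError(f"{factor} phase lengths must sum to n_trials")
            labels = {lab for lab, _ in phases}
            if not labels <= {"stable", "volatile"}:
                raise ConfigurationError(f"unknown {factor} phase label in {labels}")
            if any(n <= 0 for _, n in phases):
                raise ConfigurationError(f"{factor} phase lengths must be positive")


@dataclass
class TaskSchedule:
    """Per-trial generative truth of one run (arrays of length T)."""

    trial_index: np.ndarray
    card_phase: np.ndarray      # "stable" / "volatile"
    advice_phase: np.ndarray
    p_blue: np.ndarray          # design probability that blue is rewarded
    outcome_color: np.ndarray   # 1 = blue rewarded
    advisor_info: np.ndarray    # advisor's private signal (a color)
    advice_color: np.ndarray    # recommended color
    advice_accurate: np.ndarray  # advice_color == outcome_color
    session_split: tuple[int, int] = (70, 90)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trial_index)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "trial_index": self.trial_index,
            "card_phase": self.card_phase,
            "advice_phase": self.advice_phase,
            "p_blue": self.p_blue,
            "outcome_color": self.outcome_color,
            "advisor_info": self.advisor_info,
            "advice_color": self.advice_color,
            "advice_accurate": self.advice_accurate,
        })


@dataclass
class SubjectData:
    """Choices and wagers aligned to a schedule.

    ``choice`` is 1 where the advice was taken (the advised color was
    predicted) and 0 otherwise; ``wager`` is an integer in [1, 10].
    """

    trial_index: np.ndarray
    choice: np.ndarray
    wager: np.ndarray

    def __len__(self) -> int:
        return len(self.trial_index)

    def predicted_color(self, schedule: TaskSchedule) -> np.ndarray:
        if len(self) != len(schedule):
            raise ValueError("responses are not aligned to the schedule")
        return np.where(self.choice == 1, schedule.advice_color,
                        1 - schedule.advice_color)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "trial_index": self.trial_index,
            "choice": self.choice,
            "wager": self.wager,
        })


def _largest_remainder(quotas: list[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` over runs with real-valued quotas."""
    floors = [math.floor(q) for q in quotas]
    short = total - sum(floors)
    if short < 0:  # all-floor already exceeds total: trim smallest remainders
        order = sorted(range(len(quotas)), key=lambda i: (quotas[i] - floors[i], i))
        for i in order[:(-short)]:
            floors[i] -= 1
    else:
        order = sorted(range(len(quotas)),
                       key=lambda i: (-(quotas[i] - floors[i]), i))
        for i in order[:short]:
            floors[i] += 1
    return floors


def _partition_lengths(total: int, rng: np.random.Generator,
                       lo: int = 8, hi: int = 12) -> list[int]:
    """Split ``total`` into sub-block lengths of roughly lo..hi trials."""
    if total <= hi:
        return [total]
    n = max(2, int(round(total / ((lo + hi) / 2))))
    base = total // n
    lengths = [base] * n
    for i in range(total - base * n):
        lengths[i % n] += 1
    # jitter while preserving the sum
    for _ in range(n):
        i, j = rng.integers(0, n, size=2)
        if i != j and lengths[i] > lo and lengths[j] < hi:
            lengths[i] -= 1
            lengths[j] += 1
    return lengths


def _phase_labels(phases: tuple[tuple[str, int], ...]) -> np.ndarray:
    out = []
    for lab, n in phases:
        out.extend([lab] * n)
    return np.array(out)


def _advice_intents(cfg: GeneratorConfig, rng: np.random.Generator,
                    n_accurate: int, n_correct: int) -> tuple[np.ndarray, int]:
    """Per-trial helpful (1) / misleading (0) intent and the required count of
    correct private signals among helpful trials."""
    n = cfg.n_trials
    intent = np.empty(n, dtype=int)
    pos = 0
    stable_len = sum(ln for lab, ln in cfg.advice_phases if lab == "stable")
    vol_len = n - stable_len

    # choose the volatile helpful count so that the accuracy identity
    #   n_accurate = c_h + (n_misleading - (n_correct - c_h))
    # admits an integer solution c_h within range.
    h_vol = int(round(vol_len / 3.0))
    for cand in (h_vol, h_vol + 1, h_vol - 1, h_vol + 2, h_vol - 2,
                 *range(0, vol_len + 1)):
        if cand < 0 or cand > vol_len:
            continue
        n_h = stable_len + cand
        num = n_accurate - cfg.n_trials + n_h + n_correct
        if num % 2 == 0:
            c_h = num // 2
            n_m = cfg.n_trials - n_h
            if 0 <= c_h <= min(n_h, n_correct) and 0 <= n_correct - c_h <= n_m:
                h_vol = cand
                break
    else:
        raise ConfigurationError(
            "advice targets are infeasible for this phase structure")

    # helpful/misleading sub-blocks in each volatile phase, misleading-leading
    vol_phase_sizes = [ln for lab, ln in cfg.advice_phases if lab == "volatile"]
    h_quota = _largest_remainder(
        [h_vol * s / vol_len for s in vol_phase_sizes], h_vol)

    qi = 0
    for lab, ln in cfg.advice_phases:
        if lab == "stable":
            intent[pos:pos + ln] = 1  # stable advice phases are helpful
            pos += ln
            continue
        h_here = h_quota[qi]
        qi += 1
        m_here = ln - h_here
        h_blocks = _partition_lengths(h_here, rng) if h_here else []
        m_blocks = _partition_lengths(m_here, rng) if m_here else []
        # interleave, starting with misleading
        seq: list[tuple[int, int]] = []
        for i in range(max(len(h_blocks), len(m_blocks))):
            if i < len(m_blocks):
                seq.append((0, m_blocks[i]))
            if i < len(h_blocks):
                seq.append((1, h_blocks[i]))
        for val, ln_b in seq:
            intent[pos:pos + ln_b] = val
            pos += ln_b
    assert pos == n
    return intent, c_h


def _card_design(cfg: GeneratorConfig, rng: np.random.Generator,
                 n_blue: int) -> np.ndarray:
    """Per-trial blue-favored (1) / green-favored (0) design sequence."""
    n = cfg.n_trials
    ps = cfg.stable_contingency
    # number of blue-favored trials consistent with the target base rate
    nb_exact = (n_blue - (1.0 - ps) * n) / (2.0 * ps - 1.0)
    n_b = int(round(nb_exact))
    if not 0 <= n_b <= n:
        raise ConfigurationError(
            "card base-rate target is infeasible at this contingency")

    vol_len = sum(ln for lab, ln in cfg.card_phases if lab == "volatile")
    stable_len = n - vol_len
    vb = int(round(vol_len * 3.0 / 8.0))  # green-leaning alternation
    stable_blue = n_b - vb
    if stable_blue < 0 or stable_blue > stable_len:
        vb = min(max(n_b - stable_len, 0), vol_len)
        stable_blue = n_b - vb
    if stable_blue < 0 or stable_blue > stable_len:
        raise ConfigurationError(
            "card base-rate target is infeasible for this phase structure")

    favored = np.empty(n, dtype=int)
    pos = 0
    vol_sizes = [ln for lab, ln in cfg.card_phases if lab == "volatile"]
    vb_quota = _largest_remainder([vb * s / vol_len for s in vol_sizes], vb) if vol_len else []
    stable_sizes = [ln for lab, ln in cfg.card_phases if lab == "stable"]
    sb_quota = _largest_remainder(
        [stable_blue * s / stable_len for s in stable_sizes], stable_blue)

    si = vi = 0
    for lab, ln in cfg.card_phases:
        if lab == "stable":
            blue_here = sb_quota[si]
            si += 1
            # a stable phase keeps one contingency, with at most one reversal
            # when the color budget requires a mixed block (green run first)
            favored[pos:pos + (ln - blue_here)] = 0
            favored[pos + (ln - blue_here):pos + ln] = 1
            pos += ln
            continue
        vb_here = vb_quota[vi]
        vi += 1
        vg_here = ln - vb_here
        b_blocks = _partition_lengths(vb_here, rng) if vb_here else []
        g_blocks = _partition_lengths(vg_here, rng) if vg_here else []
        seq: list[tuple[int, int]] = []
        for i in range(max(len(b_blocks), len(g_blocks))):
            if i < len(b_blocks):
                seq.append((1, b_blocks[i]))
            if i < len(g_blocks):
                seq.append((0, g_blocks[i]))
        for val, ln_b in seq:
            favored[pos:pos + ln_b] = val
            pos += ln_b
    assert pos == n
    return favored


def _place_counts(mask_runs: np.ndarray, p: np.ndarray, total: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw a 0/1 vector with exactly ``total`` ones, apportioned over maximal
    runs of constant ``p`` proportionally to p*len and placed uniformly within
    each run."""
    n = len(p)
    boundaries = [0] + [k for k in range(1, n) if p[k] != p[k - 1] or mask_runs[k] != mask_runs[k - 1]] + [n]
    runs = [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]
    quotas = [p[a] * (b - a) for a, b in runs]
    scale = total / sum(quotas) if sum(quotas) > 0 else 0.0
    counts = _largest_remainder([q * scale for q in quotas], total)
    out = np.zeros(n, dtype=int)
    for (a, b), c in zip(runs, counts):
        c = min(max(c, 0), b - a)
        idx = rng.permutation(b - a)[:c]
        out[a + idx] = 1
    # fix any clipping residue by flipping in the largest runs
    diff = total - int(out.sum())
    order = sorted(range(len(runs)), key=lambda i: -(runs[i][1] - runs[i][0]))
    for i in order:
        if diff == 0:
            break
        a, b = runs[i]
        if diff > 0:
            zeros = np.flatnonzero(out[a:b] == 0)
            take = min(diff, len(zeros))
            out[a + rng.permutation(zeros)[:take]] = 1
            diff -= take
        else:
            ones = np.flatnonzero(out[a:b] == 1)
            take = min(-diff, len(ones))
            out[a + rng.permutation(ones)[:take]] = 0
            diff += take
    return out


def generate_schedule(config: GeneratorConfig | None = None) -> TaskSchedule:
    """Generate a schedule realizing the configured design targets.

    Deterministic given ``config.seed``. The exact counts of accurate advice,
    correct private signals and blue outcomes are fixed by the targets; their
    positions are re-randomized (up to ``max_attempts`` seeded attempts) until
    the advice-accuracy and outcome sequences are approximately orthogonal
    (|r| <= 0.1), as in the factorial design.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    n = cfg.n_trials
    n_accurate = int(round(cfg.target_advice_accuracy * n))
    n_correct = int(round(cfg.advisor_info_accuracy * n))
    n_blue = int(round(cfg.target_card_base_rate * n))

    ss = np.random.SeedSequence(cfg.seed)
    for attempt, child in enumerate(ss.spawn(cfg.max_attempts)):
        rng = np.random.default_rng(child)
        intent, c_h = _advice_intents(cfg, rng, n_accurate, n_correct)
        favored = _card_design(cfg, rng, n_blue)
        ps = cfg.stable_contingency
        p_blue = np.where(favored == 1, ps, 1.0 - ps)

        outcome = _place_counts(favored, p_blue, n_blue, rng)

        # advisor private-signal correctness: exact counts within each intent
        helpful = intent == 1
        corr = np.zeros(n, dtype=int)
        h_idx = np.flatnonzero(helpful)
        m_idx = np.flatnonzero(~helpful)
        corr[h_idx[rng.permutation(len(h_idx))[:c_h]]] = 1
        corr[m_idx[rng.permutation(len(m_idx))[:n_correct - c_h]]] = 1

        info = np.where(corr == 1, outcome, 1 - outcome)
        advice = np.where(intent == 1, info, 1 - info)
        accurate = (advice == outcome).astype(int)

        if accurate.sum() != n_accurate:  # defensive; identity guarantees this
            continue
        sd_a = accurate.std()
        sd_o = outcome.std()
        if sd_a == 0 or sd_o == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(accurate, outcome)[0, 1])
        if abs(r) <= 0.1:
            return TaskSchedule(
                trial_index=np.arange(1, n + 1),
                card_phase=_phase_labels(cfg.card_phases),
                advice_phase=_phase_labels(cfg.advice_phases),
                p_blue=p_blue,
                outcome_color=outcome,
                advisor_info=info,
                advice_color=advice,
                advice_accurate=accurate,
                session_split=cfg.session_split,
                seed=cfg.seed,
            )
    raise ConfigurationError(
        "could not realize an orthogonal design within max_attempts")


def simulate_agent(schedule: TaskSchedule, perceptual: PerceptualParams,
                   response: ResponseParams, model: ModelSpec | str,
                   seed: int | np.random.SeedSequence = 0) -> SubjectData:
    """Simulate one agent's choices and wagers on a schedule.

    The agent filters the advice-accuracy and card-outcome sequences through
    the two-branch model, arbitrates, and samples a binary advice-taking
    choice from the softmax and an integer wager from the log-normal wager
    model (rounded and clipped to [1, 10]).
    """
    spec = model_by_name(model) if isinstance(model, str) else model
    perceptual.validate()
    response.validate()
    perc = _variant_perceptual(perceptual, spec.perceptual_variant)

    traj_a, traj_c = filter_branches(schedule.advice_accurate,
                                     schedule.outcome_color, perc)
    pred = predict_run(traj_a, traj_c, schedule.advice_color, response,
                       spec.response_variant)
    rng = np.random.default_rng(seed)
    choice = (rng.random(len(schedule)) < pred.p_take_advice).astype(int)
    log_w = pred.wager_mean_log + response.beta_wager * rng.standard_normal(len(schedule))
    wager = np.clip(np.rint(np.exp(np.clip(log_w, -20, 20))), 1, 10).astype(int)
    return SubjectData(trial_index=schedule.trial_index.copy(),
                       choice=choice, wager=wager)


def _variant_perceptual(perc: PerceptualParams, variant: str) -> PerceptualParams:
    """Pin parameters according to the perceptual variant."""
    from .params import TWO_LEVEL_THETA

    if variant == "three_level":
        return perc
    if variant == "normative":
        return replace(perc, kappa_a=0.5, kappa_c=0.5, theta_a=0.55, theta_c=0.55)
    if variant == "two_level":
        # no third level: the volatility state never influences learning
        # (kappa = 0) and never moves (theta pinned near zero)
        return replace(perc, kappa_a=0.0, kappa_c=0.0,
                       theta_a=TWO_LEVEL_THETA, theta_c=TWO_LEVEL_THETA)
    raise ValueError(f"unknown perceptual variant {variant!r}")


def score_run(schedule: TaskSchedule, responses: SubjectData) -> int:
    """Cumulative score: the wager is won on correct predictions, lost else."""
    if len(schedule) != len(responses):
        raise ValueError("responses are not aligned to the schedule")
    pred = responses.predicted_color(schedule)
    sign = np.where(pred == schedule.outcome_color, 1, -1)
    return int(np.sum(sign * responses.wager))


def compare_volatility_tracking(config: GeneratorConfig | None = None,
                                n_replicates: int = 1000,
                                seed: int | np.random.SeedSequence = 0,
                                perceptual: PerceptualParams | None = None,
                                response: ResponseParams | None = None,
                                ) -> dict[str, float | np.ndarray]:
    """Score advantage of volatility tracking.

    Simulates, on shared schedules, an arbitrated agent with the full
    three-level filter against an arbitrated agent whose volatility is fixed
    and low (two-level filter), both at group-mean response parameters, and
    returns the distribution of final-score differences (three-level minus
    two-level).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = config or GeneratorConfig()
    perc = perceptual or group_mean_perceptual()
    resp = response or group_mean_response()
    m3 = model_by_name("hgf3_arb")
    m2 = model_by_name("hgf2_arb")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    diffs = np.empty(n_replicates)
    for i, child in enumerate(ss.spawn(n_replicates)):
        s_sched, s3, s2 = child.spawn(3)
        sched_seed = int(s_sched.generate_state(1)[0] % (2**31 - 1))
        sched = generate_schedule(replace(cfg, seed=sched_seed))
        r3 = simulate_agent(sched, perc, resp, m3, seed=s3)
        r2 = simulate_agent(sched, perc, resp, m2, seed=s2)
        diffs[i] = score_run(sched, r3) - score_run(sched, r2)
    return {
        "mean_difference": float(diffs.mean()),
        "sd_difference": float(diffs.std(ddof=1)) if n_replicates > 1 else 0.0,
        "differences": diffs,
        "n_replicates": n_replicates,
    }
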