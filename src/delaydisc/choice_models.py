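"""Discount functions, the softmax choice rule, and choice-data likelihoods.

Intertemporal choice is modeled as a comparison of two options: a
smaller-sooner (SS) reward and a larger-later (LL) reward delivered after a
delay D. The delayed reward is devalued by a subject-specific discount rate
k, either hyperbolically,

    SV = A / (1 + k * D),

or exponentially,

    SV = A * exp(-k * D).

A softmax (logistic) choice rule with inverse temperature beta maps the
difference of subjective values to the probability of choosing LL:

    P(LL) = 1 / (1 + exp(-beta * (SV_LL - SV_SS))).

beta = 0 yields random choice (P = 0.5); large beta approaches deterministic
value maximization. k is estimated in log space and beta through an
exponential link (beta = exp(beta_raw)), so both parameters live on the real
line for sampling while remaining positive in the model.

Units: k is in 1 / delay-unit; a dataset's delay unit (seconds or days) is
carried as metadata and never mixed within a fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, log_expit

FAMILIES = ("hyperbolic", "exponential")

#: probabilities are clamped to [P_CLAMP, 1 - P_CLAMP] inside log-likelihoods
P_CLAMP = 1e-12
_LOG_P_MIN = math.log(P_CLAMP)


@dataclass(frozen=True)
class Trial:
    """One intertemporal decision.

    Amounts are in task-native currency units (cents or euros); delays share
    the dataset's delay unit, with 0 meaning "now". ``choice`` is 1 if the
    larger-later option was chosen, 0 for smaller-sooner, and ``None`` for
    design-only trials that have not been answered.
    """

    ss_amount: float
    ss_delay: float
    ll_amount: float
    ll_delay: float
    choice: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.ll_amount >= self.ss_amount >= 0):
            raise ValueError(
                f"require ll_amount >= ss_amount >= 0, got "
                f"ss={self.ss_amount}, ll={self.ll_amount}"
            )
        if not (self.ll_delay > self.ss_delay >= 0):
            raise ValueError(
                f"require ll_delay > ss_delay >= 0, got "
                f"ss_delay={self.ss_delay}, ll_delay={self.ll_delay}"
            )
        if self.choice is not None and self.choice not in (0, 1):
            raise ValueError(f"choice must be 0, 1 or None, got {self.choice}")


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level parameters in sampling space.

    ``log_k`` is the natural log of the discount rate; ``beta_raw`` maps to
    the softmax inverse temperature through beta = exp(beta_raw).
    """

    log_k: float
    beta_raw: float

    @property
    def k(self) -> float:
        return math.exp(self.log_k)

    @property
    def beta(self) -> float:
        return math.exp(self.beta_raw)


@dataclass(frozen=True)
class DiscountedTrial:
    """A trial evaluated under a parameter set: both subjective values and P(LL)."""

    sv_ss: float
    sv_ll: float
    p_ll: float


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown discount family {family!r}; expected one of {FAMILIES}")


def subjective_value(amount, delay, k, family: str):
    """Discounted value of ``amount`` delivered after ``delay``.

    Accepts scalars or numpy arrays (broadcast together). ``k`` must be
    nonnegative and carries units of 1/delay-unit; k = 0 returns the
    undiscounted amount for both families.
    """
    _check_family(family)
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(amount < 0):
        raise ValueError("amount must be nonnegative")
    if np.any(delay < 0):
        raise ValueError("delay must be nonnegative")
    if np.any(k < 0):
        raise ValueError("discount rate k must be nonnegative")
    if family == "hyperbolic":
        sv = amount / (1.0 + k * delay)
    else:
        sv = amount * np.exp(-k * delay)
    return sv if sv.ndim else float(sv)


def choice_probability(sv_ss, sv_ll, beta):
    """Softmax probability of choosing the larger-later option.

    Computed as a logistic of beta * (sv_ll - sv_ss), which is algebraically
    identical to the two-option softmax but immune to exp overflow.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("inverse temperature beta must be nonnegative")
    p = expit(beta * (np.asarray(sv_ll, float) - np.asarray(sv_ss, float)))
    return p if p.ndim else float(p)


def discount_trial(trial: Trial, params: SubjectParams, family: str) -> DiscountedTrial:
    """Evaluate one trial under subject parameters."""
    sv_ss = subjective_value(trial.ss_amount, trial.ss_delay, params.k, family)
    sv_ll = subjective_value(trial.ll_amount, trial.ll_delay, params.k, family)
    return DiscountedTrial(sv_ss=sv_ss, sv_ll=sv_ll, p_ll=choice_probability(sv_ss, sv_ll, params.beta))


def trials_to_arrays(trials: Sequence[Trial], require_choice: bool = True):
    """Columnar view of a trial list: (ss_amount, ss_delay, ll_amount, ll_delay, choice).

    choice is float NaN where absent (only allowed with require_choice=False).
    """
    n = len(trials)
    out = np.empty((5, n))
    for i, t in enumerate(trials):
        if require_choice and t.choice is None:
            raise ValueError(f"trial {i} has no recorded choice")
        out[:, i] = (
            t.ss_amount,
            t.ss_delay,
            t.ll_amount,
            t.ll_delay,
            np.nan if t.choice is None else t.choice,
        )
    return out[0], out[1], out[2], out[3], out[4]


def loglik_arrays(ss_amount, ss_delay, ll_amount, ll_delay, choice,
                  log_k, beta_raw, family: str):
    """Bernoulli log-likelihood of observed choices for vectorized inputs.

    The trailing trial axis is summed; leading axes of ``log_k``/``beta_raw``
    broadcast, so a (n_subjects, 1) parameter array against (n_subjects,
    n_trials) data yields per-subject log-likelihoods. Per-trial log
    probabilities are floored at log(P_CLAMP).
    """
    _check_family(family)
    k = np.exp(np.asarray(log_k, float))
    beta = np.exp(np.asarray(beta_raw, float))
    sv_ss = subjective_value(ss_amount, ss_delay, k, family)
    sv_ll = subjective_value(ll_amount, ll_delay, k, family)
    x = beta * (np.asarray(sv_ll) - np.asarray(sv_ss))
    sign = 2.0 * np.asarray(choice, float) - 1.0  # +1 for LL, -1 for SS
    logp = np.maximum(log_expit(sign * x), _LOG_P_MIN)
    return logp.sum(axis=-1)


def dataset_loglik(trials: Sequence[Trial], params: SubjectParams, family: str) -> float:
    """Sum of log P(observed choice) over trials; 0 for an empty sequence."""
    if len(trials) == 0:
        return 0.0
    arrays = trials_to_arrays(trials, require_choice=True)
    return float(loglik_arrays(*arrays, params.log_k, params.beta_raw, family))
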