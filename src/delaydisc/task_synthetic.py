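"""Task designs and synthetic two-group cohorts with known ground truth.

Two intertemporal-choice designs are emulated:

* ``adolescent_grid`` — an experiential task on a seconds timescale:
  smaller-sooner rewards of 0-4 cents available now versus a fixed
  larger-later reward of 5 cents after 10, 20, 30, 40 or 60 seconds. Each of
  the 25 (SS amount, delay) pairs appears twice, giving 50 trials and a
  maximum attainable payout of 250 cents.

* ``adult_pretest`` — a hypothetical task on a days timescale: 20 EUR now
  versus participant-specific larger-later amounts in [20.5, 80] EUR after
  1, 2, 7, 14, 30, 90 or 180 days. Half of the 140 trials space LL amounts
  uniformly over the range; the other half are centered on the per-delay
  hyperbolic indifference points 20*(1+k*D) implied by a short adaptive
  pretest of the participant. Delays whose indifference point exceeds the
  80 EUR ceiling fall back to uniform spacing.

Cohort simulation draws subject-level (log k, beta_raw) from group-level
normal distributions and fills in Bernoulli choices from the softmax rule,
so every downstream stage can be exercised against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .choice_models import (
    SubjectParams,
    Trial,
    choice_probability,
    subjective_value,
)

ADOLESCENT_SS_AMOUNTS = (0.0, 1.0, 2.0, 3.0, 4.0)  # cents
ADOLESCENT_LL_AMOUNT = 5.0  # cents
ADOLESCENT_DELAYS = (10.0, 20.0, 30.0, 40.0, 60.0)  # seconds

ADULT_SS_AMOUNT = 20.0  # euros, immediate
ADULT_DELAYS = (1.0, 2.0, 7.0, 14.0, 30.0, 90.0, 180.0)  # days
ADULT_LL_MIN = 20.5
ADULT_LL_MAX = 80.0
#: offsets (fractions of the indifference amount) for the targeted trial set
ADULT_INDIFF_OFFSETS = (-0.25, -0.20, -0.15, -0.10, -0.05, 0.05, 0.10, 0.15, 0.20, 0.25)
PRETEST_K_MIN = 1e-4  # 1/day
PRETEST_K_MAX = 3.0


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level normal hyperparameters for subject (log_k, beta_raw)."""

    mu_log_k: float
    sigma_log_k: float
    mu_beta_raw: float
    sigma_beta_raw: float

    def __post_init__(self) -> None:
        if self.sigma_log_k <= 0 or self.sigma_beta_raw <= 0:
            raise ValueError("group-level sigmas must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic two-group cohort; generation is a pure function of it."""

    n_per_group: int
    design: Literal["adolescent_grid", "adult_pretest"]
    group_hypers: Dict[str, GroupHyperParams]
    seed: int
    family: str = "hyperbolic"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.design not in ("adolescent_grid", "adult_pretest"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    trials: List[Trial]


@dataclass
class ChoiceDataset:
    """Multi-subject, multi-group collection of intertemporal choices."""

    subjects: List[SubjectRecord]
    delay_unit: Literal["seconds", "days"]
    currency_unit: Literal["cents", "euros"]
    ground_truth: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.delay_unit not in ("seconds", "days"):
            raise ValueError(f"unknown delay_unit {self.delay_unit!r}")
        if self.currency_unit not in ("cents", "euros"):
            raise ValueError(f"unknown currency_unit {self.currency_unit!r}")
        for s in self.subjects:
            if not s.trials:
                raise ValueError(f"subject {s.subject_id} has no trials")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def group_labels(self) -> List[str]:
        seen: List[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for i, t in enumerate(s.trials):
                rows.append(
                    (s.subject_id, s.group, i, t.ss_amount, t.ss_delay,
                     t.ll_amount, t.ll_delay, t.choice)
                )
        return pd.DataFrame(
            rows,
            columns=["subject_id", "group", "trial_index", "ss_amount",
                     "ss_delay", "ll_amount", "ll_delay", "choice"],
        )


def build_adolescent_design() -> List[Trial]:
    """The 50-trial seconds-scale grid: each (SS amount, delay) pair twice."""
    trials = []
    for _ in range(2):
        for ss in ADOLESCENT_SS_AMOUNTS:
            for d in ADOLESCENT_DELAYS:
                trials.append(Trial(ss_amount=ss, ss_delay=0.0,
                                    ll_amount=ADOLESCENT_LL_AMOUNT, ll_delay=d))
    return trials


def hyperbolic_indifference(k: float, delay: float, ss_amount: float = ADULT_SS_AMOUNT) -> float:
    """LL amount at which a hyperbolic discounter with rate k is indifferent
    to ``ss_amount`` now: A = SS * (1 + k * D)."""
    return ss_amount * (1.0 + k * delay)


def build_adult_design(pretest_k: float) -> List[Trial]:
    """140 participant-specific days-scale trials from a pretest discount rate.

    Per delay: 10 LL amounts uniformly spaced on [20.5, 80] EUR plus 10
    amounts at +/-5..25% of the hyperbolic indifference point 20*(1+k*D);
    delays whose indifference point exceeds 80 EUR use the uniform set twice.
    """
    if pretest_k <= 0:
        raise ValueError("pretest_k must be positive")
    uniform = np.linspace(ADULT_LL_MIN, ADULT_LL_MAX, 10)
    trials = []
    for d in ADULT_DELAYS:
        amounts = list(uniform)
        indiff = hyperbolic_indifference(pretest_k, d)
        if indiff > ADULT_LL_MAX:
            amounts += list(uniform)
        else:
            targeted = indiff * (1.0 + np.asarray(ADULT_INDIFF_OFFSETS))
            amounts += list(np.clip(targeted, ADULT_LL_MIN, ADULT_LL_MAX))
        for a in amounts:
            trials.append(Trial(ss_amount=ADULT_SS_AMOUNT, ss_delay=0.0,
                                ll_amount=float(a), ll_delay=d))
    return trials


def _agent_chooses_ll(ll_amount: float, delay: float, params: SubjectParams,
                      rng: np.random.Generator, family: str = "hyperbolic") -> bool:
    sv_ss = ADULT_SS_AMOUNT  # immediate
    sv_ll = subjective_value(ll_amount, delay, params.k, family)
    return bool(rng.random() < choice_probability(sv_ss, sv_ll, params.beta))


def simulate_pretest(true_params: SubjectParams, seed,
                     family: str = "hyperbolic") -> float:
    """Simulate the short adaptive pretest and return the estimated k (1/day).

    Per delay, a 5-step bisection on the LL amount in [20.5, 80] EUR brackets
    the agent's choice reversal. A delay where the agent accepts even the
    minimum LL amount contributes an indifference point at the SS amount (no
    measurable discounting there); a delay where even the maximum amount is
    rejected is censored and excluded. k is then the least-squares fit of
    20*(1+k*D) through the indifference points, clipped to [1e-4, 3].
    """
    rng = np.random.default_rng(seed)
    delays, indiffs = [], []
    for d in ADULT_DELAYS:
        if not _agent_chooses_ll(ADULT_LL_MAX, d, true_params, rng, family):
            continue  # censored above the amount ceiling
        if _agent_chooses_ll(ADULT_LL_MIN, d, true_params, rng, family):
            delays.append(d)
            indiffs.append(ADULT_SS_AMOUNT)
            continue
        lo, hi = ADULT_LL_MIN, ADULT_LL_MAX
        for _ in range(5):
            mid = 0.5 * (lo + hi)
            if _agent_chooses_ll(mid, d, true_params, rng, family):
                hi = mid
            else:
                lo = mid
        delays.append(d)
        indiffs.append(0.5 * (lo + hi))
    if not delays:
        return PRETEST_K_MAX
    d_arr = np.asarray(delays)
    y = np.asarray(indiffs) / ADULT_SS_AMOUNT - 1.0  # y = k * D under the model
    k_hat = float(np.dot(d_arr, y) / np.dot(d_arr, d_arr))
    return float(np.clip(k_hat, PRETEST_K_MIN, PRETEST_K_MAX))


def sample_subject_params(hypers: GroupHyperParams, n: int, seed) -> List[SubjectParams]:
    """Draw n subjects' (log_k, beta_raw) from the group-level normals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    log_k = rng.normal(hypers.mu_log_k, hypers.sigma_log_k, size=n)
    beta_raw = rng.normal(hypers.mu_beta_raw, hypers.sigma_beta_raw, size=n)
    return [SubjectParams(float(a), float(b)) for a, b in zip(log_k, beta_raw)]


def _simulate_choices(trials: Sequence[Trial], params: SubjectParams,
                      rng: np.random.Generator, family: str) -> List[Trial]:
    out = []
    for t in trials:
        sv_ss = subjective_value(t.ss_amount, t.ss_delay, params.k, family)
        sv_ll = subjective_value(t.ll_amount, t.ll_delay, params.k, family)
        p = choice_probability(sv_ss, sv_ll, params.beta)
        out.append(Trial(t.ss_amount, t.ss_delay, t.ll_amount, t.ll_delay,
                         int(rng.random() < p)))
    return out


def simulate_cohort(spec: CohortSpec) -> ChoiceDataset:
    """Generate a full two-group dataset with ground-truth parameters attached.

    Choices are Bernoulli draws from the softmax rule under each subject's
    true (k, beta); adult-design trial sets are built from that subject's own
    simulated pretest. Trial order is pseudorandomly permuted per subject.
    The result is a pure function of the spec (same spec, same dataset).
    """
    root = np.random.SeedSequence(spec.seed)
    group_seeds = root.spawn(len(spec.group_hypers))
    subjects: List[SubjectRecord] = []
    truth_rows = []
    for (label, hypers), gseed in zip(spec.group_hypers.items(), group_seeds):
        param_seed, *subject_seeds = gseed.spawn(spec.n_per_group + 1)
        params_list = sample_subject_params(hypers, spec.n_per_group, param_seed)
        for i, (params, sseed) in enumerate(zip(params_list, subject_seeds)):
            rng = np.random.default_rng(sseed)
            sid = f"{label}_{i + 1:02d}"
            pretest_k = float("nan")
            if spec.design == "adolescent_grid":
                design = build_adolescent_design()
            else:
                pretest_k = simulate_pretest(params, rng, family=spec.family)
                design = build_adult_design(pretest_k)
            order = rng.permutation(len(design))
            answered = _simulate_choices([design[j] for j in order], params, rng,
                                         spec.family)
            subjects.append(SubjectRecord(sid, label, answered))
            truth_rows.append((sid, label, params.log_k, params.beta_raw,
                               hypers.mu_log_k, hypers.mu_beta_raw, pretest_k))
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "group", "log_k", "beta_raw",
                 "true_mu_log_k", "true_mu_beta_raw", "pretest_k"],
    )
    if spec.design == "adolescent_grid":
        delay_unit, currency = "seconds", "cents"
    else:
        delay_unit, currency = "days", "euros"
    return ChoiceDataset(subjects=subjects, delay_unit=delay_unit,
                         currency_unit=currency, ground_truth=truth)
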