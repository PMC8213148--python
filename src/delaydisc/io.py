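"""File formats and run configuration.

Choice datasets travel as plain CSV with a small metadata header::

    # delaydisc-choice-data v1
    # delay_unit=seconds
    # currency_unit=cents
    subject_id,group,trial_index,ss_amount,ss_delay,ll_amount,ll_delay,choice

Choice coding is 1 = larger-later, 0 = smaller-sooner, empty = unanswered
design trial. Amounts are task-native (cents or euros); delays share the
dataset's single delay unit. Posterior draws are serialized long-form (one
row per chain x draw x parameter) and summaries wide-form, both CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .choice_models import Trial
from .hierarchical_inference import FitResult, MCMCConfig, PriorSpec, hdi
from .task_synthetic import ChoiceDataset, CohortSpec, GroupHyperParams, SubjectRecord

FORMAT_TAG = "delaydisc-choice-data v1"
COLUMNS = ["subject_id", "group", "trial_index", "ss_amount", "ss_delay",
           "ll_amount", "ll_delay", "choice"]


class ChoiceDataError(ValueError):
    """Parse/validation failure in a choice-data file, with line context."""


# ---------------------------------------------------------------------------
# dataset round trip

def write_choice_data(data: ChoiceDataset, path) -> None:
    path = Path(path)
    frame = data.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_TAG}\n")
        fh.write(f"# delay_unit={data.delay_unit}\n")
        fh.write(f"# currency_unit={data.currency_unit}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
    if data.ground_truth is not None:
        data.ground_truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def read_choice_data(path) -> ChoiceDataset:
    """Read and validate a choice-data CSV; errors name the offending line."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ChoiceDataError(f"{path}: empty file")
    lines = text.splitlines()
    meta: Dict[str, str] = {}
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    delay_unit = meta.get("delay_unit")
    currency_unit = meta.get("currency_unit")
    if delay_unit not in ("seconds", "days"):
        raise ChoiceDataError(f"{path}: missing or invalid delay_unit metadata header")
    if currency_unit not in ("cents", "euros"):
        raise ChoiceDataError(f"{path}: missing or invalid currency_unit metadata header")

    frame = pd.read_csv(path, comment="#")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ChoiceDataError(f"{path}: missing columns {missing}")

    truth_path = path.with_suffix(".truth.csv")
    truth = pd.read_csv(truth_path) if truth_path.exists() else None

    subjects: List[SubjectRecord] = []
    by_subject: Dict[str, SubjectRecord] = {}
    header_line = n_meta + 1  # 1-based line of the CSV header
    for pos, row in enumerate(frame.itertuples(index=False)):
        lineno = header_line + 1 + pos
        choice = row.choice
        if pd.isna(choice):
            choice = None
        elif float(choice) in (0.0, 1.0):
            choice = int(choice)
        else:
            raise ChoiceDataError(
                f"{path}, line {lineno}: choice must be 0, 1 or empty, got {row.choice!r}")
        try:
            trial = Trial(ss_amount=float(row.ss_amount), ss_delay=float(row.ss_delay),
                          ll_amount=float(row.ll_amount), ll_delay=float(row.ll_delay),
                          choice=choice)
        except ValueError as exc:
            raise ChoiceDataError(f"{path}, line {lineno}: {exc}") from exc
        sid = str(row.subject_id)
        rec = by_subject.get(sid)
        if rec is None:
            rec = SubjectRecord(subject_id=sid, group=str(row.group), trials=[])
            by_subject[sid] = rec
            subjects.append(rec)
        rec.trials.append(trial)
    if not subjects:
        raise ChoiceDataError(f"{path}: no data rows")
    return ChoiceDataset(subjects=subjects, delay_unit=delay_unit,
                         currency_unit=currency_unit, ground_truth=truth)


# ---------------------------------------------------------------------------
# posterior serialization

def fit_to_draws_frame(fit: FitResult) -> pd.DataFrame:
    """Long-form posterior draw table: chain, draw, parameter, value."""
    frames = []
    for name, arr in fit.samples.items():
        labels = fit.subject_ids if name in ("log_k", "beta_raw") else fit.group_labels
        n_chains, n_draws, _ = arr.shape
        for i, lab in enumerate(labels):
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "parameter": f"{name}[{lab}]",
                "value": arr[:, :, i].reshape(-1),
            }))
    return pd.concat(frames, ignore_index=True)


def fit_to_summary_frame(fit: FitResult) -> pd.DataFrame:
    """Wide posterior summary: mean, 85%/95% HDIs, R-hat per parameter."""
    rows = []
    for name, arr in fit.samples.items():
        labels = fit.subject_ids if name in ("log_k", "beta_raw") else fit.group_labels
        for i, lab in enumerate(labels):
            draws = arr[:, :, i].reshape(-1)
            lo85, hi85 = hdi(draws, 0.85)
            lo95, hi95 = hdi(draws, 0.95)
            key = f"{name}[{lab}]"
            rows.append((key, draws.mean(), lo85, hi85, lo95, hi95, fit.rhat[key]))
    return pd.DataFrame(rows, columns=["parameter", "mean", "hdi85_lo", "hdi85_hi",
                                       "hdi95_lo", "hdi95_hi", "rhat"])


def draws_frame_to_samples(frame: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Invert :func:`fit_to_draws_frame`: parameter name -> (n_chains, n_draws)."""
    out: Dict[str, np.ndarray] = {}
    for name, sub in frame.groupby("parameter", sort=False):
        piv = sub.pivot(index="chain", columns="draw", values="value")
        out[str(name)] = piv.to_numpy()
    return out


# ---------------------------------------------------------------------------
# run configuration

#: generator presets emulating the two study designs; hyperparameters are
#: the synthetic cohort's operating point (see docs/methods.md)
PRESETS: Dict[str, dict] = {
    "study1_adolescent": {
        "design": "adolescent_grid",
        "family": "hyperbolic",
        "n_per_group": 19,
        "group_hypers": {
            "patients": {"mu_log_k": math.log(0.03) - 1.0, "sigma_log_k": 1.0,
                         "mu_beta_raw": 1.0, "sigma_beta_raw": 0.5},
            "controls": {"mu_log_k": math.log(0.03), "sigma_log_k": 1.0,
                         "mu_beta_raw": 1.0, "sigma_beta_raw": 0.5},
        },
    },
    "study2_adult": {
        "design": "adult_pretest",
        "family": "hyperbolic",
        "n_per_group": 25,
        "group_hypers": {
            "patients": {"mu_log_k": math.log(0.01), "sigma_log_k": 1.0,
                         "mu_beta_raw": math.log(0.2), "sigma_beta_raw": 0.5},
            "controls": {"mu_log_k": math.log(0.01), "sigma_log_k": 1.0,
                         "mu_beta_raw": math.log(0.2), "sigma_beta_raw": 0.5},
        },
    },
}


@dataclass
class RunConfig:
    """Fully materialized pipeline configuration (no implicit defaults left)."""

    design: str = "adolescent_grid"
    family: str = "hyperbolic"
    n_per_group: int = 19
    group_hypers: Dict[str, GroupHyperParams] = field(default_factory=dict)
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_chains: int = 2
    n_iter: int = 20_000
    n_burnin: int = 10_000
    direction: str = "positive"
    seed: int = 0
    output_dir: str = "delaydisc_out"

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        return cls._from_dict({**PRESETS[name], **overrides})

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        preset = raw.pop("preset", None)
        if preset is not None:
            base = dict(PRESETS[preset])
            base.update(raw)
            raw = base
        raw.update(overrides)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        hypers = {label: GroupHyperParams(**params)
                  for label, params in raw.pop("group_hypers", {}).items()}
        priors = PriorSpec(**raw.pop("priors", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(group_hypers=hypers, priors=priors, **raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_per_group=self.n_per_group, design=self.design,
                          group_hypers=self.group_hypers, seed=self.seed,
                          family=self.family)

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                          n_burnin=self.n_burnin, base_seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def write_manifest(out_dir, config: RunConfig, extra: Optional[dict] = None) -> Path:
    """Record config hash, seed and versions so deterministic stages can be
    reproduced bit-for-bit."""
    import scipy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
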