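"""Synthetic cohorts of labeled CoP recordings.

No public dataset of elderly faller/non-faller statokinesigrams exists, so
this module simulates one.  Each subject's sway is a 2-D mean-reverting
(Ornstein-Uhlenbeck) process around the stance point, punctuated by
Poisson-timed ballistic repositioning jumps that the mean reversion pulls
back in — which is what gives the sway-density curve its peak structure.
Device realism: timestamps come at a nominal rate with multiplicative
log-normal jitter (irregular sampling), and the closed-eyes record amplifies
the diffusion noise, reflecting increased visual reliance.

The faller class is deliberately heterogeneous: one phenotype sways wide and
smooth (large statokinesigram, high AP variance, few repositionings), the
other narrow and jerky (tight trajectory, frequent repositionings), with
non-fallers in between on both axes.  Marginally, each descriptor therefore
discriminates poorly, while the joint structure is learnable — the premise
the scoring forest is meant to exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import SubjectRecord
from .signal import RawTrace

__all__ = ["PhenotypeParams", "CohortConfig", "simulate_trace",
           "simulate_subject", "simulate_cohort", "separable_features",
           "default_phenotypes"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Sway-process parameters for one postural phenotype.

    stiffness : 1/s — mean-reversion rate of the OU sway process.
    noise_ml, noise_ap : cm/sqrt(s) — diffusion scales per axis.
    jerk_rate : events/s — Poisson rate of ballistic repositioning jumps.
    jump_scale : cm — per-axis scale of a repositioning displacement.
    closed_eyes_gain : >= 1 — noise multiplier for the closed-eyes record.
    stance_offset_ml : cm — lateral offset of the stance point from the
        platform origin (real stances are off-center, keeping the raw ML
        percentiles away from zero).
    """

    stiffness: float = 1.0
    noise_ml: float = 0.3
    noise_ap: float = 0.4
    jerk_rate: float = 0.8
    jump_scale: float = 0.5
    closed_eyes_gain: float = 1.4
    stance_offset_ml: float = 2.0

    def __post_init__(self):
        if self.stiffness <= 0:
            raise ValueError("stiffness must be positive")
        if self.noise_ml <= 0 or self.noise_ap <= 0:
            raise ValueError("noise scales must be positive")
        if self.jerk_rate < 0:
            raise ValueError("jerk_rate must be non-negative")
        if self.closed_eyes_gain < 1:
            raise ValueError("closed_eyes_gain must be >= 1")


def default_phenotypes() -> dict:
    """The calibrated phenotype set behind the default "hard" cohort.

    Fallers split evenly between a wide-smooth and a narrow-jerky phenotype
    placed symmetrically (on a log scale) around the non-faller sway
    amplitude and repositioning rate, so that every single descriptor
    overlaps heavily across classes while the joint (amplitude, jerkiness)
    structure separates them.
    """
    # The stationary per-axis variance is (sigma^2 + lambda * s^2) / (2 theta)
    # (diffusion plus compound-Poisson jump input), so "amplitude" below means
    # that total, not the diffusion scale alone: the jerky phenotype keeps its
    # total amplitude below the non-fallers' despite its frequent jumps.
    return {
        "non_faller": PhenotypeParams(
            stiffness=1.0, noise_ml=0.30, noise_ap=0.40,
            jerk_rate=0.80, jump_scale=0.50,
            closed_eyes_gain=1.40, stance_offset_ml=2.0),
        "faller_wide_smooth": PhenotypeParams(
            stiffness=1.0, noise_ml=0.78, noise_ap=0.88,
            jerk_rate=0.38, jump_scale=0.50,
            closed_eyes_gain=1.40, stance_offset_ml=2.0),
        "faller_narrow_jerky": PhenotypeParams(
            stiffness=1.0, noise_ml=0.125, noise_ap=0.20,
            jerk_rate=1.90, jump_scale=0.235,
            closed_eyes_gain=1.40, stance_offset_ml=2.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-level simulation settings.

    Defaults mirror the study conditions: 25 s records per condition and a
    faller fraction of 24/84.  The device rate is nominally 60 Hz with 20%
    log-normal timestamp jitter, exercising the irregular-sampling path.
    """

    n_subjects: int = 84
    faller_fraction: float = 24.0 / 84.0
    record_seconds: float = 25.0
    nominal_device_rate: float = 60.0
    timestamp_jitter: float = 0.2
    phenotypes: dict = field(default_factory=default_phenotypes)
    faller_weights: tuple = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.faller_fraction < 1.0:
            raise ValueError("faller_fraction must lie in (0, 1)")
        if self.record_seconds <= 0:
            raise ValueError("record_seconds must be positive")
        if self.nominal_device_rate <= 0:
            raise ValueError("nominal_device_rate must be positive")
        names = set(self.phenotypes)
        if "non_faller" not in names:
            raise ValueError("phenotypes must include 'non_faller'")
        if len(self.faller_phenotype_names()) < 1:
            raise ValueError("at least one faller phenotype is required")
        w = np.asarray(self.faller_weights, dtype=float)
        if len(w) != len(self.faller_phenotype_names()) or w.sum() <= 0:
            raise ValueError("faller_weights must match the faller phenotypes")

    def faller_phenotype_names(self) -> list:
        return sorted(n for n in self.phenotypes if n != "non_faller")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["phenotypes"] = {k: asdict(v) for k, v in self.phenotypes.items()}
        d["faller_weights"] = list(self.faller_weights)
        return d


def _jittered_timestamps(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing device timestamps covering record_seconds."""
    base_dt = 1.0 / cfg.nominal_device_rate
    n_max = int(np.ceil(cfg.record_seconds / base_dt * 2)) + 2
    incr = base_dt * np.exp(rng.normal(0.0, cfg.timestamp_jitter, size=n_max))
    t = np.concatenate([[0.0], np.cumsum(incr)])
    return t[t <= cfg.record_seconds]


def simulate_trace(params: PhenotypeParams, condition: str, cfg: CohortConfig,
                   rng: np.random.Generator) -> RawTrace:
    """Simulate one raw irregularly-sampled CoP record.

    The OU state is advanced with the exact transition between consecutive
    (irregular) timestamps, starting from the stationary distribution;
    repositioning jumps falling in a step are added to the state before the
    step's mean reversion acts on them.
    """
    t = _jittered_timestamps(cfg, rng)
    n = len(t)
    gain = params.closed_eyes_gain if condition == "closed" else 1.0
    sig = np.array([params.noise_ml, params.noise_ap]) * gain
    theta = params.stiffness
    mean = np.array([params.stance_offset_ml, 0.0])

    n_jumps = rng.poisson(params.jerk_rate * cfg.record_seconds)
    jump_times = np.sort(rng.uniform(0.0, cfg.record_seconds, size=n_jumps))
    jump_disp = rng.normal(0.0, params.jump_scale, size=(n_jumps, 2))

    stat_sd = sig / np.sqrt(2.0 * theta)
    x = mean + stat_sd * rng.normal(size=2)
    noise = rng.normal(size=(n - 1, 2))

    out = np.empty((n, 2))
    out[0] = x
    j = 0
    for i in range(1, n):
        while j < n_jumps and jump_times[j] <= t[i]:
            x = x + jump_disp[j]
            j += 1
        dt = t[i] - t[i - 1]
        decay = np.exp(-theta * dt)
        sd = sig * np.sqrt((1.0 - decay * decay) / (2.0 * theta))
        x = mean + (x - mean) * decay + sd * noise[i - 1]
        out[i] = x
    return RawTrace(timestamps=t, ml=out[:, 0], ap=out[:, 1],
                    condition=condition)


def simulate_subject(subject_id: str, is_faller: bool, cfg: CohortConfig,
                     rng: np.random.Generator) -> SubjectRecord:
    """Draw a phenotype for the subject and simulate both eye conditions."""
    if is_faller:
        names = cfg.faller_phenotype_names()
        w = np.asarray(cfg.faller_weights, dtype=float)
        name = names[int(rng.choice(len(names), p=w / w.sum()))]
    else:
        name = "non_faller"
    params = cfg.phenotypes[name]
    open_trace = simulate_trace(params, "open", cfg, rng)
    closed_trace = simulate_trace(params, "closed", cfg, rng)
    return SubjectRecord(subject_id=subject_id, is_faller=is_faller,
                         open_trace=open_trace, closed_trace=closed_trace)


def simulate_cohort(cfg: CohortConfig = CohortConfig(),
                    out_dir: str | Path | None = None) -> list:
    """Simulate the labeled cohort; optionally write traces + manifest.

    Exactly ``round(faller_fraction * n_subjects)`` subjects are fallers.
    With ``out_dir`` set, one trace file per record, a manifest CSV and a
    JSON echo of the configuration are written (see :mod:`swayscore.io`).
    """
    rng = np.random.default_rng(cfg.seed)
    n_fallers = int(round(cfg.faller_fraction * cfg.n_subjects))
    labels = np.array([True] * n_fallers
                      + [False] * (cfg.n_subjects - n_fallers))
    rng.shuffle(labels)
    width = len(str(cfg.n_subjects))
    subjects = [
        simulate_subject(f"S{i:0{width}d}", bool(lab), cfg, rng)
        for i, lab in enumerate(labels)
    ]
    if out_dir is not None:
        from .io import write_cohort
        write_cohort(subjects, out_dir, config_echo=cfg.to_jsonable())
    return subjects


def separable_features(n: int = 200, faller_fraction: float = 24.0 / 84.0,
                       seed: int = 0):
    """A linearly separable feature-level cohort for sanity checks.

    Non-fallers and fallers are Gaussian clouds shifted well apart along the
    median-radius axis, with uninformative noise on the remaining
    descriptors.  Returns (X, is_faller).
    """
    rng = np.random.default_rng(seed)
    n_fall = int(round(faller_fraction * n))
    fall = np.zeros(n, dtype=bool)
    fall[:n_fall] = True
    rng.shuffle(fall)
    X = rng.normal(0.0, 1.0, size=(n, 5))
    for j in (0, 1, 2, 4):  # these descriptors are non-negative
        X[:, j] = np.abs(X[:, j]) + 0.1
    X[:, 0] += np.where(fall, 8.0, 0.0)  # fallers sway far wider: separable
    return X, fall
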