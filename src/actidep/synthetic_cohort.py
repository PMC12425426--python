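"""Synthetic circadian actigraphy cohorts with planted group effects.

The generator emulates the statistical structure that distinguishes the
clinical (condition) from the healthy (control) group in wrist actigraphy:
lower overall activity amplitude, smoother / more autocorrelated minute-to-
minute fluctuations, and shifted activity onset (either phase-delayed or
phase-advanced). Each participant gets a raised-cosine daily activity
profile — zero outside the active span, so onset/offset detection has an
exact ground truth — plus AR(1) Gaussian noise truncated at zero and rounded
to integer counts. MADRS severity scores are drawn from group-conditional
truncated normals (controls land in the normal band [0, 6], conditions in
the mild/moderate band [7, 34]); moderate cases receive a further amplitude
reduction and phase delay so the three-class task has learnable structure.

All randomness flows from the single config seed. Cohorts can be written in
the same CSV dialect that :mod:`actidep.cohort_io` reads, so the generator
doubles as a round-trip fixture for the ingestion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort_io import (
    ActivityRecording,
    Cohort,
    CohortMember,
    Group,
    ParticipantMetadata,
    ValidationError,
    write_cohort_dir,
)

import pandas as pd

__all__ = [
    "GroupProfile",
    "amplitude_dominant_config",
    "SyntheticCohortConfig",
    "generate_participant",
    "generate_cohort",
    "raised_cosine_template",
]

MINUTES_PER_DAY = 1440

#: default age-band categories (5-year bands) and sampling weights
DEFAULT_AGE_BANDS = (
    "20-24", "25-29", "30-34", "35-39", "40-44",
    "45-49", "50-54", "55-59", "60-64", "65-69",
)
DEFAULT_AGE_WEIGHTS = (1, 2, 3, 3, 3, 3, 2, 1, 1, 1)


@dataclass
class GroupProfile:
    """Per-group generative parameters.

    amplitude_mean/sd
        Mean and between-participant SD of the peak daily activity level
        (actigraph counts/min).
    onset_phase
        Mean activity onset in minutes-of-day; ``onset_jitter_sd`` is the
        between-participant spread and ``phase_shift`` an extra offset whose
        sign is randomised per participant when ``phase_shift_bimodal``
        (phase-delayed or phase-advanced rest-activity rhythm).
    active_span
        Width of the raised-cosine activity period in minutes.
    ar_coefficient
        Lag-1 coefficient of the AR(1) noise in [0, 1).
    madrs_mean/sd and madrs_range
        Truncated-normal MADRS distribution for the group.
    """

    amplitude_mean: float
    amplitude_sd: float
    onset_phase: float
    active_span: float
    ar_coefficient: float
    madrs_mean: float
    madrs_sd: float
    madrs_range: tuple[int, int]
    onset_jitter_sd: float = 25.0
    phase_shift: float = 0.0
    phase_shift_bimodal: bool = True
    span_jitter_sd: float = 50.0
    ar_jitter_sd: float = 0.08

    def validate(self) -> None:
        if self.amplitude_mean < 0 or self.amplitude_sd < 0:
            raise ValidationError("amplitude parameters must be non-negative")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValidationError("ar_coefficient must lie in [0, 1)")
        lo, hi = self.madrs_range
        if not (0 <= lo <= hi <= 34):
            raise ValidationError("madrs_range must lie within [0, 34]")


def _default_control() -> GroupProfile:
    return GroupProfile(
        amplitude_mean=300.0,
        amplitude_sd=75.0,
        onset_phase=390.0,          # 06:30
        active_span=960.0,          # 16 h of daytime activity
        ar_coefficient=0.35,
        madrs_mean=3.0,
        madrs_sd=2.0,
        madrs_range=(0, 6),
    )


def _default_condition() -> GroupProfile:
    return GroupProfile(
        amplitude_mean=240.0,       # blunted activity amplitude
        amplitude_sd=65.0,
        onset_phase=390.0,
        active_span=915.0,
        ar_coefficient=0.50,        # smoother, more rigid rhythm
        madrs_mean=16.0,
        madrs_sd=7.0,
        madrs_range=(7, 34),
        phase_shift=105.0,          # delayed OR advanced onset per participant
        phase_shift_bimodal=True,
    )


@dataclass
class SyntheticCohortConfig:
    """Cohort-level configuration; defaults emulate the study population.

    Group sizes default to 23 condition / 32 control (the class imbalance of
    the analysed dataset) with 13 days of recording per participant.
    Moderate-severity conditions (MADRS >= 20) receive a second increment:
    amplitude scaled by ``severity_amplitude_factor`` and onset shifted by
    ``severity_phase_increment`` minutes.
    """

    n_condition: int = 23
    n_control: int = 32
    days_per_participant: int = 13
    noise_scale: float = 60.0
    control: GroupProfile = field(default_factory=_default_control)
    condition: GroupProfile = field(default_factory=_default_condition)
    severity_amplitude_factor: float = 0.85
    severity_phase_increment: float = 30.0
    female_fraction: float = 0.5
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    age_weights: tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    start_date: str = "2026-01-05"
    seed: int = 0

    def validate(self) -> None:
        if self.n_condition < 0 or self.n_control < 0:
            raise ValidationError("group sizes must be non-negative")
        if self.n_condition + self.n_control == 0:
            raise ValidationError("at least one group must be non-empty")
        if self.days_per_participant < 1:
            raise ValidationError("days_per_participant must be >= 1")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be non-negative")
        if len(self.age_bands) != len(self.age_weights):
            raise ValidationError("age_bands and age_weights lengths differ")
        self.control.validate()
        self.condition.validate()

    def profile(self, group: Group) -> GroupProfile:
        return self.condition if group is Group.CONDITION else self.control

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticCohortConfig":
        raw = dict(raw)
        for grp, default in (("control", _default_control),
                             ("condition", _default_condition)):
            sub = raw.get(grp)
            if isinstance(sub, dict):
                merged = asdict(default())
                merged.update(sub)
                merged["madrs_range"] = tuple(merged["madrs_range"])
                raw[grp] = GroupProfile(**merged)
        for key in ("age_bands", "age_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def amplitude_dominant_config(
    n_per_group: int = 50, days: int = 5, seed: int = 0
) -> SyntheticCohortConfig:
    """Cohort variant with a single dominant planted axis.

    The condition group differs only in activity amplitude (200 vs 300
    counts) and AR(1) smoothness (0.65 vs 0.30) — no phase shift, equal
    active span — so the group signal concentrates on the overall-power
    proxies (PSD mean, mean activity) rather than on circadian timing.
    Used for attribution-recovery checks where the ground-truth driver
    must be unambiguous.
    """
    cfg = SyntheticCohortConfig(
        n_condition=n_per_group, n_control=n_per_group,
        days_per_participant=days, seed=seed,
    )
    cfg.condition.amplitude_mean = 200.0
    cfg.condition.amplitude_sd = 50.0
    cfg.condition.phase_shift = 0.0
    cfg.condition.active_span = cfg.control.active_span
    cfg.condition.ar_coefficient = 0.65
    cfg.control.ar_coefficient = 0.30
    return cfg


def raised_cosine_template(
    onset: float, span: float, minutes: Optional[np.ndarray] = None
) -> np.ndarray:
    """Day-periodic raised-cosine activity profile in [0, 1].

    Zero outside ``[onset, onset + span)`` (mod 1440), peaking at the span
    midpoint: ``0.5 * (1 - cos(2*pi*(t - onset)/span))``.
    """
    if minutes is None:
        minutes = np.arange(MINUTES_PER_DAY, dtype=float)
    rel = np.mod(minutes - onset, MINUTES_PER_DAY)
    tpl = np.where(rel < span, 0.5 * (1.0 - np.cos(2.0 * np.pi * rel / span)), 0.0)
    return tpl


def _ar1_noise(n: int, rho: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, scale, size=n)
    out = np.empty(n)
    # stationary start so the noise variance is homogeneous across the window
    out[0] = eps[0] / np.sqrt(1.0 - rho**2) if rho > 0 else eps[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def _truncated_normal_int(
    mean: float, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> int:
    """Rejection-sampled integer truncated normal on [lo, hi]."""
    if sd <= 0:
        return int(np.clip(round(mean), lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo - 0.5 <= v <= hi + 0.5:
            return int(np.clip(round(v), lo, hi))
    return int(np.clip(round(mean), lo, hi))


def generate_participant(
    config: SyntheticCohortConfig,
    group: Group,
    rng: np.random.Generator,
    index: int = 1,
) -> tuple[ActivityRecording, ParticipantMetadata]:
    """Simulate one participant's recording and metadata.

    Counts are ``max(0, round(A * template(t - phase) + ar1_noise))`` on a
    contiguous per-minute grid of ``days_per_participant`` days.
    """
    if group not in (Group.CONDITION, Group.CONTROL):
        raise ValidationError(f"cannot generate group {group!r}")
    config.validate()
    profile = config.profile(group)

    madrs = _truncated_normal_int(
        profile.madrs_mean, profile.madrs_sd, *profile.madrs_range, rng=rng
    )

    amplitude = max(0.0, rng.normal(profile.amplitude_mean, profile.amplitude_sd))
    onset = profile.onset_phase + rng.normal(0.0, profile.onset_jitter_sd)
    if profile.phase_shift:
        sign = rng.choice([-1.0, 1.0]) if profile.phase_shift_bimodal else 1.0
        onset += sign * profile.phase_shift
    span = max(120.0, rng.normal(profile.active_span, profile.span_jitter_sd))
    ar = float(np.clip(rng.normal(profile.ar_coefficient, profile.ar_jitter_sd),
                       0.0, 0.9))

    if group is Group.CONDITION and madrs >= 20:
        amplitude *= config.severity_amplitude_factor
        onset += config.severity_phase_increment
        ar = min(0.95, ar + 0.10)

    n = config.days_per_participant * MINUTES_PER_DAY
    minutes = np.arange(n, dtype=float) % MINUTES_PER_DAY
    signal = amplitude * raised_cosine_template(onset % MINUTES_PER_DAY,
                                                span, minutes)
    counts = np.maximum(0.0, np.round(signal + _ar1_noise(n, ar, config.noise_scale, rng)))

    pid = f"{group.value}_{index}"
    timestamps = pd.date_range(
        pd.Timestamp(config.start_date), periods=n, freq="min"
    )
    recording = ActivityRecording(
        participant_id=pid,
        group=group,
        timestamps=timestamps,
        counts=counts.astype(np.int64),
    )
    weights = np.asarray(config.age_weights, dtype=float)
    metadata = ParticipantMetadata(
        number=pid,
        days=config.days_per_participant,
        gender=1 if rng.random() < config.female_fraction else 2,
        age_band=str(rng.choice(config.age_bands, p=weights / weights.sum())),
        afftype=1 if group is Group.CONDITION else None,
        madrs1=madrs,
        madrs2=madrs,
    )
    return recording, metadata


def generate_cohort(
    config: SyntheticCohortConfig, out_dir: Optional[str | Path] = None
) -> Cohort:
    """Simulate a full cohort; optionally also write it in the CSV dialect."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    members: list[CohortMember] = []
    for i in range(config.n_condition):
        rec, meta = generate_participant(config, Group.CONDITION, rng, index=i + 1)
        members.append(CohortMember(recording=rec, metadata=meta))
    for i in range(config.n_control):
        rec, meta = generate_participant(config, Group.CONTROL, rng, index=i + 1)
        members.append(CohortMember(recording=rec, metadata=meta))
    cohort = Cohort(members=members, join_log=[])
    if out_dir is not None:
        write_cohort_dir(cohort, out_dir)
    return cohort
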