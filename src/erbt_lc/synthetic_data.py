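"""Synthetic procedure-log generator with a known learning structure.

Each simulated operator follows a :class:`LearningProfile`: procedure
time starts at ``time_initial_mean``, reaches ``time_plateau_mean``
after a true change point ``k*`` (``change_point``), with additive
Gaussian noise truncated below at one minute; the three binary outcomes
(perforation, piecemeal resection, absent detrusor muscle) are
independent Bernoulli draws whose probability drops from an initial to a
consolidation value at the same change point.

Three mean-curve shapes are available:

``step``
    constant at the initial level through ``k*``, then constant at the
    plateau — the change point is exactly the CUSUM peak, so this shape
    anchors exact recovery tests.
``linear_decay`` (default preset shape)
    linear decline from the initial level at procedure 1 toward the
    plateau across the initial phase, plateau thereafter — matches the
    gradual decline seen in real aggregated curves.
``exponential_decay``
    exponential relaxation toward the plateau, reaching within ~5% of it
    at the change point, plateau thereafter.

Default profiles (:func:`junior_profile`, :func:`senior_profile`,
:func:`default_cohort`) mimic the published regime for novice operators
learning en bloc bladder-tumor resection on an ex vivo model: two
seniority groups of four operators, 30 procedures each, initial/plateau
times of 52.61/26.36 min (junior, k*=16) and 46.35/23.41 min (senior,
k*=13), and phase-wise complication probabilities taken from the
corresponding observed rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .log_io import ProcedureLog, ProcedureRecord

SHAPES = ("step", "linear_decay", "exponential_decay")


@dataclass(frozen=True)
class LearningProfile:
    """Generative parameters for one simulated operator."""

    operator_id: str
    seniority: str
    n_procedures: int = 30
    change_point: int = 16
    time_initial_mean: float = 52.61
    time_plateau_mean: float = 26.36
    time_noise_sd: float = 9.0
    shape: str = "linear_decay"
    p_perforation: tuple[float, float] = (0.25, 0.018)
    p_piecemeal: tuple[float, float] = (0.156, 0.0)
    p_dm_absent: tuple[float, float] = (0.094, 0.0)

    def validate(self) -> None:
        """Raise ValueError naming the violated field."""
        if self.seniority not in ("junior", "senior"):
            raise ValueError(f"seniority: must be 'junior' or 'senior', got {self.seniority!r}")
        if self.n_procedures < 1:
            raise ValueError(f"n_procedures: must be positive, got {self.n_procedures}")
        if not (2 <= self.change_point <= self.n_procedures - 1):
            raise ValueError(
                f"change_point: must lie in [2, n_procedures-1]="
                f"[2, {self.n_procedures - 1}], got {self.change_point}"
            )
        if not self.time_initial_mean > 0:
            raise ValueError(f"time_initial_mean: must be > 0, got {self.time_initial_mean}")
        if not 0 < self.time_plateau_mean <= self.time_initial_mean:
            raise ValueError(
                "time_plateau_mean: must satisfy 0 < plateau <= initial, got "
                f"{self.time_plateau_mean} vs initial {self.time_initial_mean}"
            )
        if self.time_noise_sd < 0:
            raise ValueError(f"time_noise_sd: must be >= 0, got {self.time_noise_sd}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape: must be one of {SHAPES}, got {self.shape!r}")
        for name in ("p_perforation", "p_piecemeal", "p_dm_absent"):
            pair = getattr(self, name)
            if len(pair) != 2:
                raise ValueError(f"{name}: must be an (initial, consolidation) pair")
            init, cons = pair
            if not (0.0 <= init <= 1.0 and 0.0 <= cons <= 1.0):
                raise ValueError(f"{name}: probabilities must lie in [0, 1], got {pair}")
            if cons > init:
                raise ValueError(
                    f"{name}: consolidation probability must not exceed the initial one, got {pair}"
                )

    def expected_times(self) -> np.ndarray:
        """Noise-free mean procedure time at serial indices 1..n."""
        n, k = self.n_procedures, self.change_point
        t0, t1 = self.time_initial_mean, self.time_plateau_mean
        i = np.arange(1, n + 1, dtype=float)
        if self.shape == "step":
            mu = np.where(i <= k, t0, t1)
        elif self.shape == "linear_decay":
            mu = np.where(i <= k, t0 + (t1 - t0) * (i - 1) / k, t1)
        else:  # exponential_decay: within ~5% of plateau at i = k
            rate = 3.0 / max(k - 1, 1)
            mu = np.where(i <= k, t1 + (t0 - t1) * np.exp(-rate * (i - 1)), t1)
        return mu


def _rng_for(seed) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def simulate_operator(profile: LearningProfile, seed) -> list[ProcedureRecord]:
    """Simulate one operator's serial procedures.

    Returns exactly ``profile.n_procedures`` records with serial indices
    1..n. Times are the shape's expected mean plus independent N(0, sd)
    noise, truncated below at 1 minute and rounded to two decimals (the
    log's on-disk precision). Outcomes at index i use the initial-phase
    probability for i <= change_point and the consolidation one after.
    Identical ``(profile, seed)`` yield identical output.
    """
    profile.validate()
    rng = _rng_for(seed)
    n, k = profile.n_procedures, profile.change_point
    mu = profile.expected_times()
    times = mu + rng.normal(0.0, profile.time_noise_sd, size=n)
    times = np.round(np.maximum(times, 1.0), 2)

    idx = np.arange(1, n + 1)
    initial = idx <= k

    def draw(pair: tuple[float, float]) -> np.ndarray:
        p = np.where(initial, pair[0], pair[1])
        return rng.random(n) < p

    perforation = draw(profile.p_perforation)
    piecemeal = draw(profile.p_piecemeal)
    dm_absent = draw(profile.p_dm_absent)

    return [
        ProcedureRecord(
            operator_id=profile.operator_id,
            seniority=profile.seniority,
            serial_index=int(i),
            time_min=float(t),
            perforation=bool(pf),
            en_bloc=not bool(pm),
            dm_present=not bool(dm),
        )
        for i, t, pf, pm, dm in zip(idx, times, perforation, piecemeal, dm_absent)
    ]


def simulate_cohort(profiles: Sequence[LearningProfile], seed: int) -> ProcedureLog:
    """Simulate a cohort of independent operators.

    Operator sub-seeds are ``SeedSequence(seed, spawn_key=(i,))`` for the
    operator's position i in ``profiles``, so cohorts are reproducible
    and operators statistically independent. The returned log carries
    ``provenance="simulated"`` and the truth mapping operator_id ->
    profile.
    """
    ids = [p.operator_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"operator_id: duplicate ids {dupes}")
    records: list[ProcedureRecord] = []
    for i, profile in enumerate(profiles):
        sub = np.random.SeedSequence(int(seed), spawn_key=(i,))
        records.extend(simulate_operator(profile, sub))
    return ProcedureLog(
        records, provenance="simulated", truth={p.operator_id: p for p in profiles}
    )


def junior_profile(operator_id: str = "J1", shape: str = "linear_decay", **overrides) -> LearningProfile:
    """Preset mimicking the junior-group cell statistics (k*=16)."""
    base = LearningProfile(
        operator_id=operator_id,
        seniority="junior",
        change_point=16,
        time_initial_mean=52.61,
        time_plateau_mean=26.36,
        time_noise_sd=9.0,
        shape=shape,
        p_perforation=(0.25, 0.018),
        p_piecemeal=(0.156, 0.0),
        p_dm_absent=(0.094, 0.0),
    )
    return replace(base, **overrides) if overrides else base


def senior_profile(operator_id: str = "S1", shape: str = "linear_decay", **overrides) -> LearningProfile:
    """Preset mimicking the senior-group cell statistics (k*=13)."""
    base = LearningProfile(
        operator_id=operator_id,
        seniority="senior",
        change_point=13,
        time_initial_mean=46.35,
        time_plateau_mean=23.41,
        time_noise_sd=8.0,
        shape=shape,
        p_perforation=(0.173, 0.0),
        p_piecemeal=(0.115, 0.0),
        p_dm_absent=(0.115, 0.0),
    )
    return replace(base, **overrides) if overrides else base


def default_cohort(
    n_per_group: int = 4, shape: str = "linear_decay", **overrides
) -> list[LearningProfile]:
    """The study design: two seniority groups of four operators each."""
    profiles = [
        junior_profile(f"J{i + 1}", shape=shape, **overrides) for i in range(n_per_group)
    ] + [senior_profile(f"S{i + 1}", shape=shape, **overrides) for i in range(n_per_group)]
    return profiles
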