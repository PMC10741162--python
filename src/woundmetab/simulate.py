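"""Synthetic porcine burn-wound study generator.

Emulates the design of the source experiment: N pigs each carrying four
deep partial-thickness (DPT) wounds (two AFSG-treated, two FBD) and six
full-thickness (FT) wounds (two AFSG, two cadaver skin, two split-thickness
"sandwich" grafts), biopsied on days 7/14/21/28/60, injected in random
order on one LC-MS run with a pooled QC injected every ``qc_every``-th
position.

Per-feature intensity model (all effects multiplicative)::

    I = baseline * 2^(effect * z_traj(day))          # planted trajectory
          * 2^(day-7 treatment log2-FC, AFSG only)   # treatment effect
          * drift(injection order)                   # run-order drift
          * lognormal noise                          # CV = noise_cv

A pooled QC carries the mean linear abundance of all study samples of the
feature, times drift and noise; QC intensities therefore share the drift
signal that LOESS correction is meant to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    DAYS,
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    ValidationError,
)

#: the eight trajectory archetypes over the canonical day grid, as raw
#: profiles (centered and unit-scaled on construction).  Shapes encode the
#: timing narrative: U clusters cross their average early (U1, day 21) or
#: late (U2, day 28); D clusters fall below average by day 14 (D1), day 28
#: (D2) or only by day 60 (D3); P clusters peak at an interior day with a
#: Day-7 value above (P1), near (P2) or below (P3) average.  Within a
#: letter the raw shapes are kept angularly well separated (pairwise
#: cosine <~ 0.7) so planted trajectories are genuinely distinct.
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "U1": (-2.0, -0.3, 0.5, 0.7, 0.8),
    "U2": (-0.7, -0.6, -0.5, 0.2, 2.1),
    "D1": (2.0, -0.2, -0.5, -0.6, -0.7),
    "D2": (1.4, 1.0, 0.1, -1.2, -1.3),
    "D3": (0.6, 0.55, 0.5, 0.45, -2.1),
    "P1": (1.1, 2.0, -0.2, -1.3, -0.9),
    "P2": (0.3, 1.2, 1.6, 0.0, -1.3),
    "P3": (-1.0, -0.2, 0.8, 1.6, -1.2),
}

ARCHETYPES = tuple(ARCHETYPE_SHAPES)

_CANONICAL_DAYS = np.array(DAYS, dtype=float)


def trajectory_archetype(label: str, days=DAYS) -> np.ndarray:
    """Deterministic z-profile template for one archetype over a day grid.

    The canonical 5-point shape is linearly interpolated in normalized
    time onto ``days``, then centered (mean 0) and scaled (population
    sd 1) over the grid.
    """
    if label not in ARCHETYPE_SHAPES:
        raise ValidationError(f"unknown trajectory archetype {label!r}")
    days = np.asarray(days, dtype=float)
    if days.size < 2:
        raise ValidationError("day grid must have at least 2 points")
    t_canon = (_CANONICAL_DAYS - _CANONICAL_DAYS[0]) / (_CANONICAL_DAYS[-1] - _CANONICAL_DAYS[0])
    t = (days - days[0]) / (days[-1] - days[0])
    profile = np.interp(t, t_canon, ARCHETYPE_SHAPES[label])
    profile = profile - profile.mean()
    sd = profile.std()  # population sd
    if sd == 0:
        raise ValidationError(f"degenerate archetype profile for {label!r}")
    return profile / sd


@dataclass
class SimConfig:
    """Full parameterization of the synthetic study."""

    n_pigs: int = 6
    dpt_wounds_per_pig: int = 4      # split evenly AFSG / FBD
    ft_wounds_per_pig: int = 6       # split evenly AFSG / CS / STSG_sandwich
    days: tuple[int, ...] = DAYS
    n_features: int = 300
    frac_time_responsive: float = 0.25
    trajectory_mix: dict[str, float] = field(
        default_factory=lambda: {a: 1.0 / len(ARCHETYPES) for a in ARCHETYPES}
    )
    frac_day7_treatment_responsive: float = 0.3
    effect_size_log2: float = 1.0
    drift_amplitude: float = 0.2
    noise_cv: float = 0.1
    qc_every: int = 7
    missing_rate: float = 0.05
    frac_pos_mode: float = 0.74
    baseline_log10_range: tuple[float, float] = (4.0, 6.0)
    mz_catalog: tuple[tuple[float, str], ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_time_responsive", "frac_day7_treatment_responsive",
                     "missing_rate", "frac_pos_mode"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_features <= 0:
            raise ValidationError("n_features must be positive")
        if not self.days:
            raise ValidationError("day list must be nonempty")
        if self.qc_every < 2:
            raise ValidationError("qc_every must be >= 2")
        if self.effect_size_log2 <= 0:
            raise ValidationError("effect_size_log2 must be positive")
        if self.noise_cv < 0 or self.drift_amplitude < 0:
            raise ValidationError("noise_cv and drift_amplitude must be >= 0")
        total = sum(self.trajectory_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(f"trajectory_mix must sum to 1, got {total}")
        unknown = set(self.trajectory_mix) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes in trajectory_mix: {sorted(unknown)}")

    # -- design bookkeeping ----------------------------------------------
    @property
    def n_study_samples(self) -> int:
        return self.n_pigs * (self.dpt_wounds_per_pig + self.ft_wounds_per_pig) * len(self.days)

    @property
    def n_injections(self) -> int:
        """Total injections: study samples interleaved with QCs at every
        position that is a multiple of ``qc_every``."""
        n_study = self.n_study_samples
        n = n_study
        while n - n // self.qc_every < n_study:
            n += 1
        return n

    def to_dict(self) -> dict:
        return asdict(self)


def drift(injection_order: int, config: SimConfig) -> float:
    """Shared multiplicative run-order drift factor: 1 at the first
    injection, ``1 + drift_amplitude`` at the last, linear in between."""
    return drift_factor(injection_order, config.drift_amplitude, config.n_injections)


def drift_factor(injection_order, amplitude: float, n_injections: int):
    order = np.asarray(injection_order, dtype=float)
    if np.any(order < 1):
        raise ValidationError("injection_order must be >= 1")
    if n_injections <= 1:
        return np.ones_like(order) if order.ndim else 1.0
    out = 1.0 + amplitude * (order - 1.0) / (n_injections - 1.0)
    return out if out.ndim else float(out)


def _build_samples(config: SimConfig, rng: np.random.Generator) -> list[SampleMeta]:
    """Lay out the study design and randomize the injection order."""
    wounds: list[tuple[str, str, str]] = []  # (pig, wound_type, treatment)
    dpt_treatments = ["AFSG", "FBD"]
    ft_treatments = ["AFSG", "CS", "STSG_sandwich"]
    for p in range(1, config.n_pigs + 1):
        pig = f"P{p}"
        for w in range(config.dpt_wounds_per_pig):
            wounds.append((pig, "DPT", dpt_treatments[w % len(dpt_treatments)]))
        for w in range(config.ft_wounds_per_pig):
            wounds.append((pig, "FT", ft_treatments[w % len(ft_treatments)]))

    study: list[dict] = []
    for i, (pig, wtype, treat) in enumerate(wounds, start=1):
        for day in config.days:
            study.append({
                "sample_id": f"{pig}_{wtype}_W{i}_D{day}",
                "pig_id": pig, "wound_type": wtype, "treatment": treat, "day": day,
            })
    order = rng.permutation(len(study))

    n_total = config.n_injections
    qc_positions = [p for p in range(1, n_total + 1) if p % config.qc_every == 0]
    study_positions = [p for p in range(1, n_total + 1) if p % config.qc_every != 0]

    samples: list[SampleMeta] = []
    for qi, pos in enumerate(qc_positions, start=1):
        samples.append(SampleMeta(sample_id=f"QC{qi:02d}", injection_order=pos, kind="QC"))
    for rec, pos in zip((study[i] for i in order), study_positions):
        samples.append(SampleMeta(injection_order=pos, kind="study", **rec))
    samples.sort(key=lambda s: s.injection_order)
    return samples


def generate_study(config: SimConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate a feature table plus its ground truth.

    Returns ``(table, truth)`` where ``truth`` is a per-feature DataFrame
    with columns ``responsive``, ``trajectory``, ``treatment_responsive``
    and ``true_log2fc`` (Day-7 AFSG over comparator).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _build_samples(config, rng)
    n_s = len(samples)
    n_f = config.n_features
    day_index = {d: i for i, d in enumerate(config.days)}

    # feature metadata
    modes = np.where(rng.random(n_f) < config.frac_pos_mode, "pos", "neg")
    mzs = rng.uniform(60.0, 990.0, size=n_f)
    rts = rng.uniform(0.5, 9.5, size=n_f)
    if config.mz_catalog:
        for i, (mz, mode) in enumerate(config.mz_catalog[:n_f]):
            mzs[i] = mz
            modes[i] = mode
    features = [
        FeatureMeta(f"F{i + 1:04d}", float(mzs[i]), round(float(rts[i]), 3), str(modes[i]))
        for i in range(n_f)
    ]

    # ground truth
    responsive = rng.random(n_f) < config.frac_time_responsive
    mix_labels = [a for a in ARCHETYPES if config.trajectory_mix.get(a, 0.0) > 0]
    mix_weights = np.array([config.trajectory_mix[a] for a in mix_labels])
    mix_weights = mix_weights / mix_weights.sum()
    assigned = rng.choice(len(mix_labels), size=n_f, p=mix_weights)
    trajectory = np.where(responsive, [mix_labels[i] for i in assigned], "")
    treat_resp = rng.random(n_f) < config.frac_day7_treatment_responsive
    sign = rng.choice([-1.0, 1.0], size=n_f)
    true_log2fc = np.where(treat_resp, sign * config.effect_size_log2, 0.0)

    lo, hi = config.baseline_log10_range
    baseline = 10.0 ** rng.uniform(lo, hi, size=n_f)
    drift_sens = rng.uniform(0.8, 1.2, size=n_f)  # per-feature drift sensitivity

    profiles = {a: trajectory_archetype(a, config.days) for a in ARCHETYPES}
    day_z = np.zeros((n_f, len(config.days)))
    for i in range(n_f):
        if responsive[i]:
            day_z[i] = profiles[trajectory[i]]

    # expected log2 abundance of each study sample (before drift/noise)
    log2_expected = np.empty((n_f, n_s))
    study_cols = [j for j, s in enumerate(samples) if s.kind == "study"]
    log2_base = np.log2(baseline)
    for j, s in enumerate(samples):
        if s.kind != "study":
            continue
        col = log2_base + config.effect_size_log2 * day_z[:, day_index[s.day]]
        if s.day == config.days[0] and s.treatment == "AFSG":
            col = col + true_log2fc
        log2_expected[:, j] = col
    # pooled QC: mean linear abundance over study samples
    qc_expected = np.log2(np.mean(2.0 ** log2_expected[:, study_cols], axis=1))
    for j, s in enumerate(samples):
        if s.kind == "QC":
            log2_expected[:, j] = qc_expected

    orders = np.array([s.injection_order for s in samples], dtype=float)
    shared_drift = drift_factor(orders, config.drift_amplitude, config.n_injections)
    # per-feature amplitude jitter: drift_f = 1 + sens * amplitude * ramp
    ramp = (shared_drift - 1.0)
    drift_matrix = 1.0 + drift_sens[:, None] * ramp[None, :]

    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
    noise = np.exp(sigma * rng.standard_normal((n_f, n_s))) if sigma > 0 else 1.0

    intensities = 2.0 ** log2_expected * drift_matrix * noise
    if config.missing_rate > 0:
        mask = rng.random((n_f, n_s)) < config.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    table = FeatureTable(intensities, features, samples)
    truth = pd.DataFrame(
        {
            "responsive": responsive,
            "trajectory": trajectory,
            "treatment_responsive": treat_resp,
            "true_log2fc": true_log2fc,
            "mode": modes,
        },
        index=pd.Index([f.feature_id for f in features], name="feature_id"),
    )
    return table, truth
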