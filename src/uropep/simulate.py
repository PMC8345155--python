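"""Synthetic cohort generation with the statistical structure of urinary
CE-MS peptide profiles.

Amplitudes follow a zero-inflated log-normal: each peptide is detected in a
sample with a group-specific Bernoulli probability and, when detected, its
amplitude is log-normal.  Marker peptides get group-specific parameters
moment-matched to published per-group summary statistics
(:func:`model_from_marker_table`); background peptides are pure nulls whose
parameters are shared across groups, so selection specificity is testable.

The printed per-group summaries report the mean/SD over *all* samples with
the detection frequency listed separately; the default convention therefore
rescales them to the detected-only sub-population before moment matching
(``means_are="all"``; pass ``means_are="detected"`` to skip the rescale).

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import load_fixture
from .types import PeakMatrix, SampleRecord

#: Model groups: the non-cirrhotic pool (normal + NAFLD + NASH w/o LC),
#: liver cirrhosis, and HCC.
MODEL_GROUPS = ("NONLC", "LC", "HCC")

_GROUP_TO_MODEL = {
    "NORMAL": "NONLC",
    "NAFLD": "NONLC",
    "NASH": "NONLC",
    "OTHER": "NONLC",
    "LC": "LC",
    "HCC": "HCC",
}


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Natural-log-scale (mu, sigma) matching a target mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2);  mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class GroupAmplitudeModel:
    """Zero-inflated log-normal parameters for one peptide in one group."""

    freq: float
    mu: float = float("nan")
    sigma: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"detection frequency {self.freq} outside [0, 1]")
        if self.freq > 0 and (math.isnan(self.mu) or self.sigma < 0):
            raise ValueError("freq > 0 requires finite mu and sigma >= 0")


@dataclass(frozen=True)
class PeptideGroupModel:
    """Per-group amplitude model of one peptide (keys of ``by_group`` are
    ``NONLC``/``LC``/``HCC``)."""

    peptide_id: str
    by_group: Mapping[str, GroupAmplitudeModel]
    mass: float = float("nan")
    ce_time: float = float("nan")

    def group(self, clinical_group: str) -> GroupAmplitudeModel:
        return self.by_group[_GROUP_TO_MODEL[clinical_group]]


def _detected_moments(mean_all: float, sd_all: float, freq: float,
                      min_cv: float = 0.05) -> tuple[float, float]:
    """Convert all-sample moments of a zero-inflated variable to moments of
    the detected sub-population.

    With detection probability f and detected moments (m_d, s_d):
    E[X] = f*m_d and E[X^2] = f*(s_d^2 + m_d^2), hence
    m_d = m/f and s_d^2 = (s^2 + m^2)/f - m_d^2 (floored at (min_cv*m_d)^2).
    """
    m_det = mean_all / freq
    s2_det = (sd_all**2 + mean_all**2) / freq - m_det**2
    s2_det = max(s2_det, (min_cv * m_det) ** 2)
    return m_det, math.sqrt(s2_det)


def model_from_marker_table(
    marker_table: pd.DataFrame, means_are: str = "all"
) -> list[PeptideGroupModel]:
    """Moment-match a per-group marker statistics table to amplitude models.

    ``marker_table`` needs columns ``peptide_id`` and, per group suffix in
    ``{nonlc, lc, hcc}``: ``mean_<g>``, ``sd_<g>``, ``freq_<g>`` (frequency
    in percent).  ``means_are`` selects whether printed means/SDs cover all
    samples (``"all"``, the default convention; rescaled to the detected
    sub-population before matching) or detected samples only
    (``"detected"``).
    """
    if means_are not in ("all", "detected"):
        raise ValueError(f"means_are must be 'all' or 'detected', got {means_are!r}")
    models = []
    for _, row in marker_table.iterrows():
        by_group = {}
        for group, suffix in (("NONLC", "nonlc"), ("LC", "lc"), ("HCC", "hcc")):
            freq = float(row[f"freq_{suffix}"]) / 100.0
            mean = float(row[f"mean_{suffix}"])
            sd = float(row[f"sd_{suffix}"])
            if freq == 0.0:
                by_group[group] = GroupAmplitudeModel(freq=0.0)
                continue
            if mean <= 0:
                raise ValueError(
                    f"peptide {row['peptide_id']}, group {group}: detection "
                    f"frequency {freq:.2f} > 0 requires a positive mean amplitude"
                )
            if means_are == "all":
                mean, sd = _detected_moments(mean, sd, freq)
            mu, sigma = lognormal_from_moments(mean, sd)
            by_group[group] = GroupAmplitudeModel(freq=freq, mu=mu, sigma=sigma)
        models.append(
            PeptideGroupModel(
                peptide_id=str(row["peptide_id"]),
                by_group=by_group,
                mass=float(row.get("mass", float("nan"))),
                ce_time=float(row.get("ce_time", float("nan"))),
            )
        )
    return models


def table2_models(means_are: str = "all", mean_floor: float = 0.5) -> list[PeptideGroupModel]:
    """Amplitude models of the bundled 31-marker panel.

    Printed group means of 0 ion counts with a positive detection frequency
    are rounding artifacts of the source table; they are floored at
    ``mean_floor`` (half the printing unit) before moment matching.  Masses
    and CE times are attached from the bundled sequencing table where
    available.
    """
    stats = load_fixture("table2").copy()
    masses = load_fixture("table3").set_index("peptide_id")
    num_cols = [c for c in stats.columns if c != "peptide_id"]
    stats[num_cols] = stats[num_cols].astype(float)
    for g in ("nonlc", "lc", "hcc"):
        detected = stats[f"freq_{g}"] > 0
        stats.loc[detected, f"mean_{g}"] = stats.loc[detected, f"mean_{g}"].clip(lower=mean_floor)
        stats.loc[detected, f"sd_{g}"] = stats.loc[detected, f"sd_{g}"].clip(lower=mean_floor)
    stats["mass"] = stats["peptide_id"].map(masses["exp_mass"])
    stats["ce_time"] = stats["peptide_id"].map(masses["ce_time"])
    return model_from_marker_table(stats, means_are=means_are)


@dataclass(frozen=True)
class AgeModel:
    """Truncated-normal age model (years); SD defaults to range/4."""

    mean: float
    low: float
    high: float

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 4.0


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    Defaults reproduce the discovery-phase study conditions: group sizes
    9 normal / 9 NAFLD / 8 NASH / 25 LC / 18 HCC, demographic models from
    the published clinical table, administrative censoring at 500 days, and
    a baseline exponential hazard giving roughly 50% events within the
    follow-up horizon for test-negative patients when a hazard ratio is
    planted on test-positive ones.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"NORMAL": 9, "NAFLD": 9, "NASH": 8, "LC": 25, "HCC": 18}
    )
    n_background_peptides: int = 500
    seed: int = 0
    age_models: Mapping[str, AgeModel] = field(
        default_factory=lambda: {
            "HCC": AgeModel(58.0, 28.0, 76.0),
            "OTHER": AgeModel(52.0, 18.0, 82.0),
        }
    )
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HCC": 3 / 18, "OTHER": 20 / 51}
    )
    baseline_rate: float = math.log(2.0) / 500.0
    hazard_ratio: float = 4.1
    censor_days: float = 500.0
    n_internal_standards: int = 0
    # background-peptide population (group-invariant pure nulls)
    background_freq_range: tuple[float, float] = (0.2, 0.95)
    background_ln_mean: float = math.log(100.0)
    background_ln_mean_sd: float = 1.5
    background_sigma_range: tuple[float, float] = (0.6, 1.4)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        if self.censor_days <= 0:
            raise ValueError("censoring horizon must be > 0")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


def _background_models(design: CohortDesign, rng: np.random.Generator) -> list[PeptideGroupModel]:
    models = []
    lo_f, hi_f = design.background_freq_range
    lo_s, hi_s = design.background_sigma_range
    for i in range(design.n_background_peptides):
        freq = rng.uniform(lo_f, hi_f)
        mu = rng.normal(design.background_ln_mean, design.background_ln_mean_sd)
        sigma = rng.uniform(lo_s, hi_s)
        shared = GroupAmplitudeModel(freq=freq, mu=mu, sigma=sigma)
        models.append(
            PeptideGroupModel(
                peptide_id=f"BG{i:04d}",
                by_group={g: shared for g in MODEL_GROUPS},
                mass=rng.uniform(800.0, 3500.0),
                ce_time=rng.uniform(19.0, 45.0),
            )
        )
    return models


def _standard_models(design: CohortDesign, rng: np.random.Generator) -> list[PeptideGroupModel]:
    # ubiquitously detected, tight peptides usable as internal standards
    models = []
    for i in range(design.n_internal_standards):
        mu = rng.normal(math.log(2000.0), 0.5)
        shared = GroupAmplitudeModel(freq=1.0, mu=mu, sigma=0.15)
        models.append(
            PeptideGroupModel(
                peptide_id=f"IS{i:02d}",
                by_group={g: shared for g in MODEL_GROUPS},
                mass=rng.uniform(800.0, 3500.0),
                ce_time=rng.uniform(19.0, 45.0),
            )
        )
    return models


def simulate_cohort(
    design: CohortDesign, models: Sequence[PeptideGroupModel]
) -> tuple[PeakMatrix, list[SampleRecord]]:
    """Draw a cohort: amplitude matrix plus clinical metadata.

    Marker models in ``models`` get their group-specific parameters;
    ``design.n_background_peptides`` null peptides and (optionally)
    ``design.n_internal_standards`` ubiquitous standard peptides (ids
    prefixed ``BG``/``IS``) are appended.  Survival fields are left unset;
    use :func:`simulate_survival` once classifier flags exist.
    """
    rng = np.random.default_rng(design.seed)
    all_models = list(models) + _background_models(design, rng) + _standard_models(design, rng)

    known = ("NORMAL", "NAFLD", "NASH", "LC", "HCC")
    unknown = [g for g, n in design.group_sizes.items() if g not in known and n > 0]
    if unknown:
        raise ValueError(f"unknown group(s) {unknown} in design")

    records: list[SampleRecord] = []
    counter = 0
    for group in known:
        for _ in range(design.group_sizes.get(group, 0)):
            counter += 1
            key = "HCC" if group == "HCC" else "OTHER"
            am = design.age_models[key]
            age = float(np.clip(rng.normal(am.mean, am.sd), am.low, am.high))
            sex = "F" if rng.random() < design.female_fraction[key] else "M"
            records.append(
                SampleRecord(
                    sample_id=f"S{counter:04d}", group=group, age=round(age, 1), sex=sex
                )
            )

    n_samples = len(records)
    n_peptides = len(all_models)
    amp = np.zeros((n_samples, n_peptides))
    model_groups = [ _GROUP_TO_MODEL[r.group] for r in records ]
    for j, model in enumerate(all_models):
        gms = [model.by_group[g] for g in model_groups]
        freqs = np.array([gm.freq for gm in gms])
        mus = np.array([gm.mu if gm.freq > 0 else 0.0 for gm in gms])
        sigmas = np.array([gm.sigma if gm.freq > 0 else 0.0 for gm in gms])
        detected = rng.random(n_samples) < freqs
        values = np.exp(rng.normal(mus, sigmas))
        amp[:, j] = np.where(detected, values, 0.0)

    amplitudes = pd.DataFrame(
        amp,
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
        columns=[m.peptide_id for m in all_models],
    )
    info = pd.DataFrame(
        {
            "mass": [m.mass for m in all_models],
            "ce_time": [m.ce_time for m in all_models],
        },
        index=amplitudes.columns,
    )
    # peptides without curated mass/time get plausible drawn values
    missing = info["mass"].isna()
    info.loc[missing, "mass"] = rng.uniform(800.0, 3500.0, int(missing.sum()))
    missing_t = info["ce_time"].isna()
    info.loc[missing_t, "ce_time"] = rng.uniform(19.0, 45.0, int(missing_t.sum()))
    return PeakMatrix(amplitudes, info), records


def internal_standard_ids(peaks: PeakMatrix) -> list[str]:
    return [p for p in peaks.peptide_ids if str(p).startswith("IS")]


def simulate_survival(
    records: Sequence[SampleRecord],
    positive_flags: Sequence[bool],
    design: CohortDesign,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Plant exponential survival with a known hazard ratio.

    Event times are Exponential(rate * HR^flag), administratively censored
    at ``design.censor_days``; ``event`` records whether death occurred
    within the horizon.
    """
    if len(positive_flags) != len(records):
        raise ValueError("flags must align with records")
    if design.hazard_ratio <= 0:
        raise ValueError("hazard ratio must be > 0")
    if rng is None:
        rng = np.random.default_rng(design.seed + 104729)
    out = []
    for rec, flag in zip(records, positive_flags):
        rate = design.baseline_rate * (design.hazard_ratio if flag else 1.0)
        if rate <= 0:
            time, event = design.censor_days, False
        else:
            t = rng.exponential(1.0 / rate)
            event = t <= design.censor_days
            time = min(t, design.censor_days)
        out.append(
            SampleRecord(
                sample_id=rec.sample_id,
                group=rec.group,
                age=rec.age,
                sex=rec.sex,
                survival_days=float(time),
                event=bool(event),
            )
        )
    return out


def apply_dilution(peaks: PeakMatrix, factors: Sequence[float]) -> PeakMatrix:
    """Multiply every sample's amplitudes by a per-sample factor.

    Emulates urine-concentration/instrument-response differences; the
    normalization stage is expected to undo exactly this kind of distortion.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (peaks.shape[0],):
        raise ValueError("need one positive factor per sample")
    if (factors <= 0).any():
        raise ValueError("dilution factors must be positive")
    return peaks.with_amplitudes(peaks.amplitudes.mul(factors, axis=0))
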