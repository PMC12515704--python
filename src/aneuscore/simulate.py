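"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator produces every input the analysis consumes: healthy male
control arm-count profiles, patient cfDNA profiles that mix a tumor
arm-copy-number profile into a diploid male background at tumor fraction f,
matched tissue segment tables, dPCR wells whose AR/AGO1 ratio follows the
same mixture, and survival outcomes under a proportional-hazards model with
a treatment x GWA interaction.

Counts are Dirichlet-multinomial: the expected mass of arm a is
``w_a * ((1-f) * N_a + f * T_a)`` where ``w_a`` is the arm's amplicon-
abundance weight (default: arm length), ``N_a`` the normal male copy number
(2 autosomal, 1 for X and Y) and ``T_a`` the tumor copy number.  The
Dirichlet layer adds technical overdispersion on top of multinomial
sampling; at f = 0 the model reduces to the control generative model.

All randomness flows from one master seed; each component derives a child
generator deterministically, so identical configurations reproduce byte-
identical datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arms import (
    DEFAULT_MIN_READS,
    ArmCountProfile,
    ArmDefinition,
    arm_names,
    included_arms,
)
from .dpcr import DPCRWell
from .survival import ClinicalRecord
from .tissue import SegmentCN
from .gwa import classify_dynamics

#: Tumor fraction at or above which a sample is truly aneuploidy-detectable
#: (the conventional GWA>5 <-> f>10% correspondence).
TRUE_HIGH_FRACTION = 0.10

# Recurrent arm-level events of a high-aneuploidy mCRPC genome: classic
# 8p loss / 8q gain, AR-bearing Xq gain, chr7 and 1q/3q/9q gains, and the
# common losses (2q, 4p, 5q, 6q, 9p, 10q, 12p, 13q, 16q, 17p, 18q, 20p).
_PROSTATE_HIGH_CN = {
    "1q": 3, "3q": 3, "7p": 3, "7q": 3, "8q": 4, "9q": 3, "Xq": 3,
    "2q": 1, "4p": 1, "5q": 1, "6q": 1, "8p": 1, "9p": 1, "10q": 1,
    "12p": 1, "13q": 1, "16q": 1, "17p": 1, "18q": 1, "20p": 1,
}


def normal_male_cn(arm: ArmDefinition) -> int:
    """Expected germline copy number: 2 autosomal, 1 for X and Y arms."""
    return 1 if arm.chrom in ("X", "Y") else 2


@dataclass(frozen=True)
class TumorProfile:
    """Arm-level integer copy-number profile of a simulated tumor."""

    name: str
    arm_cn: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.arm_cn.values()):
            raise ValueError("copy numbers cannot be negative")

    def cn(self, arm: ArmDefinition) -> int:
        return self.arm_cn.get(arm.name, normal_male_cn(arm))


def tumor_preset(name: str, arms: Sequence[ArmDefinition]) -> TumorProfile:
    """Built-in tumor profiles: ``diploid`` (no alterations) and
    ``prostate_high`` (broadly aneuploid mCRPC-like genome)."""
    names = set(arm_names(arms, only_included=True))
    if name == "diploid":
        return TumorProfile(name="diploid", arm_cn={})
    if name == "prostate_high":
        cn = {k: v for k, v in _PROSTATE_HIGH_CN.items() if k in names}
        return TumorProfile(name="prostate_high", arm_cn=cn)
    raise ValueError(f"unknown tumor preset {name!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.

    ``concentration`` is the Dirichlet concentration of the count model
    (larger = closer to pure multinomial; ``None`` disables the Dirichlet
    layer entirely).  Survival effects are log hazard ratios on the
    indicators taxane, GWA-high (baseline truth) and their product, with an
    ARSI / GWA-low reference; the defaults reproduce the reported effect
    structure (taxane x high ~= no GWA effect, ARSI x high ~= HR 2.63).
    """

    n_controls: int = 17
    depth: int = 100_000
    concentration: Optional[float] = 200_000.0
    tumor_fraction: float = 0.0
    tissue_noise_sd: float = 0.1
    baseline_hazard: float = 1 / 400.0  # events per day
    beta_treatment: float = float(-np.log(2.36))
    beta_gwa: float = float(np.log(2.63))
    beta_interaction: float = float(-np.log(2.58))
    censoring: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 3:
            raise ValueError("n_controls must be >= 3")
        if self.depth <= 0 or self.baseline_hazard <= 0:
            raise ValueError("depth and baseline_hazard must be positive")
        if self.concentration is not None and self.concentration <= 0:
            raise ValueError("concentration must be positive or None")
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.tissue_noise_sd < 0 or not 0 <= self.censoring < 1:
            raise ValueError("invalid noise or censoring rate")


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-component generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def expected_arm_masses(
    profile: TumorProfile,
    arms: Sequence[ArmDefinition],
    tumor_fraction: float,
) -> np.ndarray:
    """Normalized expected count mass per arm (all arms, model order)."""
    mass = np.array(
        [
            a.weight * ((1 - tumor_fraction) * normal_male_cn(a)
                        + tumor_fraction * profile.cn(a))
            for a in arms
        ]
    )
    total = mass.sum()
    if total <= 0:
        raise ValueError("all arm masses are zero")
    return mass / total


def simulate_cfdna(
    profile: TumorProfile,
    config: SimulationConfig,
    arms: Sequence[ArmDefinition],
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    timepoint: str = "baseline",
) -> ArmCountProfile:
    """Draw one Dirichlet-multinomial arm-count profile."""
    if rng is None:
        rng = child_rng(config.seed, 0)
    mass = expected_arm_masses(profile, arms, config.tumor_fraction)
    if config.concentration is None:
        p = mass
    else:
        p = rng.dirichlet(config.concentration * mass)
    counts = rng.multinomial(config.depth, p)
    return ArmCountProfile.from_counts(
        sample_id,
        dict(zip([a.name for a in arms], counts.tolist())),
        arms,
        timepoint=timepoint,
    )


def make_control_cohort(
    config: SimulationConfig,
    arms: Sequence[ArmDefinition],
    rng: np.random.Generator | None = None,
) -> list[ArmCountProfile]:
    """Healthy male control cohort: ``n_controls`` profiles at f = 0."""
    if rng is None:
        rng = child_rng(config.seed, 1)
    if config.depth < DEFAULT_MIN_READS:
        warnings.warn(
            f"depth {config.depth} is below the QC minimum "
            f"{DEFAULT_MIN_READS}; control profiles will fail QC",
            stacklevel=2,
        )
    diploid = tumor_preset("diploid", arms)
    cfg = replace(config, tumor_fraction=0.0)
    return [
        simulate_cfdna(diploid, cfg, arms, rng, sample_id=f"control_{i + 1:02d}")
        for i in range(config.n_controls)
    ]


def simulate_tissue_segments(
    profile: TumorProfile,
    tissue_noise_sd: float,
    arms: Sequence[ArmDefinition],
    rng: np.random.Generator | int | None = None,
) -> list[SegmentCN]:
    """Segment table emulating purity-adjusted arm-level caller output.

    Each included arm is split into 1-3 segments at random internal
    breakpoints; each segment's copy number is the tumor arm CN plus
    Gaussian noise (truncated at 0).
    """
    if tissue_noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = child_rng(rng if rng is not None else 0, 2)
    segments = []
    for arm in included_arms(arms):
        k = int(rng.integers(1, 4))
        cuts = np.sort(rng.integers(arm.start + 1, arm.end, size=k - 1))
        bounds = [arm.start, *cuts.tolist(), arm.end]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            cn = max(0.0, profile.cn(arm) + float(rng.normal(0, tissue_noise_sd)))
            segments.append(SegmentCN(chrom=arm.chrom, start=lo, end=hi, cn=cn))
    return segments


# ---------------------------------------------------------------------------
# dPCR


def dpcr_true_ratio(profile: TumorProfile, arms: Sequence[ArmDefinition],
                    tumor_fraction: float) -> float:
    """DNA-level AR/AGO1 copy ratio implied by the cfDNA mixture.

    AR sits on Xq (one germline copy in males), AGO1 on 1p (two copies), so
    an unaltered sample has ratio 0.5; an Xq gain raises it.
    """
    by_name = {a.name: a for a in arms}
    xq, p1 = by_name["Xq"], by_name["1p"]
    ar = (1 - tumor_fraction) * normal_male_cn(xq) + tumor_fraction * profile.cn(xq)
    ago1 = (1 - tumor_fraction) * normal_male_cn(p1) + tumor_fraction * profile.cn(p1)
    return ar / ago1


def simulate_dpcr_wells(
    true_ratio: float,
    rng: np.random.Generator,
    n_partitions: int = 20_000,
    lambda_reference: float = 0.15,
    partition_volume: float = 0.85,
) -> tuple[DPCRWell, DPCRWell]:
    """Draw (target, reference) wells with a given true concentration ratio."""
    wells = []
    for name, lam in (("AR", true_ratio * lambda_reference),
                      ("AGO1", lambda_reference)):
        p_pos = 1.0 - np.exp(-lam)
        wells.append(
            DPCRWell(
                target_name=name,
                n_partitions=n_partitions,
                n_positive=int(rng.binomial(n_partitions, p_pos)),
                partition_volume=partition_volume,
            )
        )
    return wells[0], wells[1]


# ---------------------------------------------------------------------------
# Survival cohort


@dataclass
class CohortData:
    """One simulated patient cohort with its ground truth.

    ``truth`` holds per-patient tumor fractions, true GWA statuses and the
    generative log hazard ratios -- everything needed to score downstream
    estimates without inspecting generator internals.
    """

    profiles_bl: list[ArmCountProfile]
    profiles_et: list[ArmCountProfile]
    records: list[ClinicalRecord]
    truth: pd.DataFrame = field(repr=False)


def simulate_cohort(
    config: SimulationConfig,
    n_patients: int,
    treatment_mix: float = 154 / 196,
    preset: str = "prostate_high",
    arms: Sequence[ArmDefinition] | None = None,
    p_high: float = 0.48,
    p_responder: float = 0.5,
    make_profiles: bool = True,
) -> CohortData:
    """Simulate a two-timepoint treatment cohort with survival outcomes.

    Baseline tumor fraction is a two-component mixture (probability
    ``p_high`` of f ~ U(0.10, 0.40), else f ~ U(0, 0.05)), echoing the
    roughly half-and-half GWA-high prevalence seen at baseline in mCRPC.
    Responders (probability ``p_responder``) shrink f at the early timepoint
    by a U(0, 0.3) factor, producing the predominantly high-to-low switch
    group; non-responders keep their baseline fraction.  Event times are
    exponential with log-hazard ``b_trt*I[taxane] + b_gwa*I[high] +
    b_int*I[taxane]*I[high]`` on the *true* baseline status, censored
    administratively at the empirical (1 - censoring) quantile of the drawn
    event times.  ``treatment_mix`` is the ARSI share (default mirrors the
    154/42 ARSI/taxane split).
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    if arms is None:
        from .arms import grch38_arms

        arms = grch38_arms()
    profile = tumor_preset(preset, arms)
    rng = child_rng(config.seed, 3)

    treatments = np.where(rng.random(n_patients) < treatment_mix, "ARSI", "taxane")
    is_high = rng.random(n_patients) < p_high
    f_bl = np.where(
        is_high,
        rng.uniform(TRUE_HIGH_FRACTION, 0.40, n_patients),
        rng.uniform(0.0, 0.05, n_patients),
    )
    responder = rng.random(n_patients) < p_responder
    f_et = np.where(responder, f_bl * rng.uniform(0.0, 0.3, n_patients), f_bl)
    status_bl = np.where(f_bl >= TRUE_HIGH_FRACTION, "high", "low")
    status_et = np.where(f_et >= TRUE_HIGH_FRACTION, "high", "low")

    tax = (treatments == "taxane").astype(float)
    high = (status_bl == "high").astype(float)
    log_hr = (
        config.beta_treatment * tax
        + config.beta_gwa * high
        + config.beta_interaction * tax * high
    )
    hazard = config.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring > 0:
        tau = float(np.quantile(event_time, 1.0 - config.censoring))
        observed = np.minimum(event_time, tau)
        event = event_time <= tau
    else:
        observed, event = event_time, np.ones(n_patients, dtype=bool)
    observed = np.maximum(observed, 1e-9)

    records, profiles_bl, profiles_et = [], [], []
    for i in range(n_patients):
        pid = f"patient_{i + 1:03d}"
        records.append(
            ClinicalRecord(
                patient_id=pid,
                treatment=str(treatments[i]),
                time=float(observed[i]),
                event=bool(event[i]),
                status_bl=str(status_bl[i]),
                status_et=str(status_et[i]),
                dynamics=classify_dynamics(str(status_bl[i]), str(status_et[i])),
            )
        )
        if make_profiles:
            for tp, f, dest in (
                ("baseline", f_bl[i], profiles_bl),
                ("early", f_et[i], profiles_et),
            ):
                cfg = replace(config, tumor_fraction=float(f))
                dest.append(
                    simulate_cfdna(profile, cfg, arms, rng, sample_id=pid, timepoint=tp)
                )

    truth = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "treatment": treatments,
            "f_bl": f_bl,
            "f_et": f_et,
            "status_bl": status_bl,
            "status_et": status_et,
            "dynamics": [r.dynamics for r in records],
            "responder": responder,
            "event_time": event_time,
            "observed_time": observed,
            "event": event,
        }
    )
    truth.attrs["betas"] = {
        "treatment": config.beta_treatment,
        "gwa": config.beta_gwa,
        "interaction": config.beta_interaction,
    }
    return CohortData(
        profiles_bl=profiles_bl,
        profiles_et=profiles_et,
        records=records,
        truth=truth,
    )
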