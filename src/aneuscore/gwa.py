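"""Genome-wide aneuploidy (GWA) scoring of cfDNA arm-count profiles.

The score follows the aneuploidy-screening construction: per-sample arm read
counts are normalized to the included-arm library size, each arm fraction is
converted to a Z-score against a healthy-control reference, and the squared
Z-scores are summed over the 41 scored arms.  Because a raw sum of 41 squared
Z-scores has a null expectation near 41, the reported GWA score is by default
that sum re-standardized against the control distribution of sums (estimated
leave-one-out), which places the conventional decision threshold of 5 about
five null standard deviations above the control mean.  Samples with GWA >= 5
are called GWA-high, otherwise GWA-low.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arms import ArmCountProfile, ArmDefinition, arm_names

#: Conventional GWA-high decision threshold (standardized scale).
DEFAULT_THRESHOLD = 5.0

REFERENCE_FORMAT_VERSION = "aneuscore-reference-v1"


@dataclass(frozen=True)
class ControlReference:
    """Healthy-control summary statistics needed to score a new sample.

    ``arm_mean``/``arm_sd`` are the per-arm mean and SD of normalized
    fractions across controls (SD floored at ``sd_floor``); ``s_mean`` and
    ``s_sd`` summarize the control distribution of the sum of squared
    Z-scores, estimated leave-one-out so the spread is not optimistically
    shrunken by scoring controls against a reference that contains them.
    """

    arm_mean: dict[str, float]
    arm_sd: dict[str, float]
    n_controls: int
    s_mean: float
    s_sd: float
    sd_floor: float

    def __post_init__(self) -> None:
        if self.n_controls < 3:
            raise ValueError("a control reference requires at least 3 controls")
        if not self.sd_floor > 0:
            raise ValueError("sd_floor must be positive")
        if self.s_sd < 0:
            raise ValueError("s_sd cannot be negative")
        total = sum(self.arm_mean.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"arm means must sum to 1, got {total:.8f}")
        if any(sd < self.sd_floor for sd in self.arm_sd.values()):
            raise ValueError("every arm SD must be >= sd_floor")


@dataclass(frozen=True)
class ArmZProfile:
    """Per-arm Z-scores of one sample over the included arms."""

    sample_id: str
    z: dict[str, float]
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.z.values()))):
            raise ValueError("Z-scores must be finite")


@dataclass(frozen=True)
class GWAResult:
    """GWA score and dichotomized status for one sample/timepoint."""

    sample_id: str
    timepoint: str
    s_raw: float
    gwa: float
    status: str
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.s_raw < 0:
            raise ValueError("s_raw is a sum of squares and cannot be negative")
        expected = "high" if self.gwa >= self.threshold else "low"
        if self.status != expected:
            raise ValueError(f"status {self.status!r} inconsistent with gwa/threshold")


def normalize_counts(
    profile: ArmCountProfile, arms: Sequence[ArmDefinition]
) -> dict[str, float]:
    """Included-arm fractions p_a = count_a / sum of included counts.

    Excluded arms are dropped; the returned fractions sum to 1.
    """
    names = arm_names(arms, only_included=True)
    counts = np.array([profile.counts.get(n, 0) for n in names], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"empty profile: {profile.sample_id} has no included-arm reads")
    return dict(zip(names, counts / total))


def _mean_sd(fractions: np.ndarray, sd_floor: float | None) -> tuple[np.ndarray, np.ndarray, float]:
    """Column mean/SD (ddof=1) with the SD floor applied; returns the floor used.

    Default floor: 10% of the control mean fraction of the smallest arm.
    """
    mu = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=1)
    if sd_floor is None:
        sd_floor = 0.1 * float(mu.min())
    if not sd_floor > 0:
        raise ValueError("sd_floor must be positive")
    return mu, np.maximum(sd, sd_floor), sd_floor


def build_reference(
    controls: Sequence[ArmCountProfile],
    arms: Sequence[ArmDefinition],
    sd_floor: float | None = None,
) -> ControlReference:
    """Estimate the control reference from healthy-control count profiles.

    Per-arm means and SDs (sample SD, n-1 denominator) are computed across
    controls, with SDs floored at ``sd_floor``.  Each control's sum of
    squared Z-scores is computed leave-one-out (scored against a reference
    built from the remaining controls), and ``s_mean``/``s_sd`` summarize
    those values.

    Raises
    ------
    ValueError
        With fewer than 3 controls, or naming any control that fails QC.
    """
    if len(controls) < 3:
        raise ValueError(f"need at least 3 controls, got {len(controls)}")
    failing = [p.sample_id for p in controls if not p.qc_pass]
    if failing:
        raise ValueError(f"controls failing QC: {', '.join(failing)}")

    names = arm_names(arms, only_included=True)
    frac = np.array(
        [[normalize_counts(p, arms)[n] for n in names] for p in controls]
    )
    mu, sd, floor = _mean_sd(frac, sd_floor)

    n = len(controls)
    s_values = np.empty(n)
    for i in range(n):
        rest = np.delete(frac, i, axis=0)
        mu_i, sd_i, _ = _mean_sd(rest, sd_floor if sd_floor is not None else floor)
        z = (frac[i] - mu_i) / sd_i
        s_values[i] = float(np.sum(z**2))

    # A cohort of identical profiles yields s_sd = 0; the reference is still
    # constructible (raw-mode scoring works) but standardized scoring errors.
    s_sd = float(s_values.std(ddof=1))
    return ControlReference(
        arm_mean=dict(zip(names, mu)),
        arm_sd=dict(zip(names, sd)),
        n_controls=n,
        s_mean=float(s_values.mean()),
        s_sd=s_sd,
        sd_floor=floor,
    )


def arm_zscores(
    fractions: Mapping[str, float],
    ref: ControlReference,
    sample_id: str = "sample",
    timepoint: str = "baseline",
) -> ArmZProfile:
    """Z-score each included-arm fraction against the control reference."""
    z = {}
    for arm, mu in ref.arm_mean.items():
        if arm not in fractions:
            raise ValueError(f"arm {arm} missing from sample fractions")
        z[arm] = (fractions[arm] - mu) / ref.arm_sd[arm]
    return ArmZProfile(sample_id=sample_id, z=z, timepoint=timepoint)


def gwa_score(
    zprofile: ArmZProfile,
    ref: ControlReference,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "standardized",
) -> GWAResult:
    """Sum squared arm Z-scores and dichotomize.

    In ``standardized`` mode (default) the raw sum S is re-standardized as
    (S - s_mean) / s_sd against the control leave-one-out distribution; in
    ``raw`` mode the sum itself is reported.  A score exactly equal to the
    threshold is called high.
    """
    if mode not in ("standardized", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = set(ref.arm_mean) - set(zprofile.z)
    if missing:
        raise ValueError(f"Z-profile missing arms: {', '.join(sorted(missing))}")
    s_raw = float(sum(zprofile.z[a] ** 2 for a in ref.arm_mean))
    if mode == "standardized":
        if not ref.s_sd > 0:
            raise ValueError("degenerate control reference")
        gwa = (s_raw - ref.s_mean) / ref.s_sd
    else:
        gwa = s_raw
    return GWAResult(
        sample_id=zprofile.sample_id,
        timepoint=zprofile.timepoint,
        s_raw=s_raw,
        gwa=gwa,
        status="high" if gwa >= threshold else "low",
        threshold=threshold,
    )


def score_profile(
    profile: ArmCountProfile,
    ref: ControlReference,
    arms: Sequence[ArmDefinition],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "standardized",
) -> GWAResult:
    """Convenience: counts -> fractions -> Z-scores -> GWA in one call."""
    fractions = normalize_counts(profile, arms)
    zp = arm_zscores(fractions, ref, profile.sample_id, profile.timepoint)
    return gwa_score(zp, ref, threshold=threshold, mode=mode)


def classify_dynamics(status_bl: str, status_et: str) -> str:
    """Longitudinal GWA dynamics from baseline and early-timepoint statuses.

    low/low -> GWAlow, high/high -> GWAhigh, discordant -> GWAswitch.
    Missing statuses are an error; no imputation is performed.
    """
    valid = ("low", "high")
    if status_bl not in valid or status_et not in valid:
        raise ValueError(
            f"statuses must be 'low' or 'high', got ({status_bl!r}, {status_et!r})"
        )
    if status_bl == status_et:
        return "GWAlow" if status_bl == "low" else "GWAhigh"
    return "GWAswitch"


# ---------------------------------------------------------------------------
# Serialization

def write_reference(ref: ControlReference, path: str | Path) -> None:
    """Serialize a reference as a versioned key-value header + per-arm table."""
    with open(path, "w") as fh:
        fh.write(f"#format\t{REFERENCE_FORMAT_VERSION}\n")
        fh.write(f"#n_controls\t{ref.n_controls}\n")
        fh.write(f"#s_mean\t{float(ref.s_mean)!r}\n")
        fh.write(f"#s_sd\t{float(ref.s_sd)!r}\n")
        fh.write(f"#sd_floor\t{float(ref.sd_floor)!r}\n")
        fh.write("arm\tmean\tsd\n")
        for arm in ref.arm_mean:
            fh.write(f"{arm}\t{float(ref.arm_mean[arm])!r}\t{float(ref.arm_sd[arm])!r}\n")


def read_reference(path: str | Path) -> ControlReference:
    header: dict[str, str] = {}
    arm_mean: dict[str, float] = {}
    arm_sd: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, value = line[1:].split("\t")
                header[key] = value
            elif line and not line.startswith("arm\t"):
                arm, mean, sd = line.split("\t")
                arm_mean[arm] = float(mean)
                arm_sd[arm] = float(sd)
    if header.get("format") != REFERENCE_FORMAT_VERSION:
        raise ValueError(f"unrecognized reference format: {header.get('format')!r}")
    return ControlReference(
        arm_mean=arm_mean,
        arm_sd=arm_sd,
        n_controls=int(header["n_controls"]),
        s_mean=float(header["s_mean"]),
        s_sd=float(header["s_sd"]),
        sd_floor=float(header["sd_floor"]),
    )


def results_to_frame(results: Sequence[GWAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "timepoint": [r.timepoint for r in results],
            "s_raw": [r.s_raw for r in results],
            "gwa": [r.gwa for r in results],
            "status": [r.status for r in results],
        }
    )
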