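"""Arm-level aggregation of tissue copy-number segments and cfDNA concordance.

Purity-adjusted copy-number segments (as emitted by WGS arm-level CN callers)
are collapsed to one value per chromosome arm by a length-weighted mean over
the segment/arm intersections, expressed as a log2 deviation from the
expected normal copy number (2 for autosomes, 1 for chrX in males), and
compared per sample against the cfDNA arm Z-scores with a Spearman rank
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arms import ArmDefinition, included_arms
from .gwa import ArmZProfile

logger = logging.getLogger(__name__)

#: Lower bound on copy number before the log2 transform (handles cn=0).
DEFAULT_CN_FLOOR = 0.1

#: Minimum fraction of an arm that segments must cover for the arm to count.
DEFAULT_MIN_COVERAGE = 0.5

#: Minimum shared arms for a per-sample concordance estimate.
MIN_CONCORDANCE_ARMS = 10


@dataclass(frozen=True)
class SegmentCN:
    """One purity-adjusted copy-number segment (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    cn: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment start must be < end")
        if self.cn < 0:
            raise ValueError("copy number cannot be negative")


@dataclass(frozen=True)
class TissueArmCNA:
    """Per-arm log2 CN deviation of one tissue sample."""

    sample_id: str
    arm_log2: dict[str, float]
    expected_cn: dict[str, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.arm_log2.values()))):
            raise ValueError("arm log2 values must be finite")


def expected_normal_cn(
    arms: Sequence[ArmDefinition], male: bool = True
) -> dict[str, float]:
    """Expected copy number per included arm: 2 for autosomes, 1 for male X."""
    out = {}
    for a in included_arms(arms):
        if a.chrom == "X":
            out[a.name] = 1.0 if male else 2.0
        elif a.chrom == "Y":
            out[a.name] = 1.0
        else:
            out[a.name] = 2.0
    return out


def segments_to_arm_cn(
    segments: Sequence[SegmentCN],
    arms: Sequence[ArmDefinition],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict[str, float]:
    """Length-weighted mean copy number per included arm.

    Each segment contributes its intersection with the arm interval; arms
    whose covered fraction is below ``min_coverage`` are flagged missing
    (omitted from the result, with a warning logged) rather than estimated
    from too little data.
    """
    out: dict[str, float] = {}
    for arm in included_arms(arms):
        covered = 0.0
        weighted = 0.0
        for seg in segments:
            if seg.chrom != arm.chrom:
                continue
            lo = max(seg.start, arm.start)
            hi = min(seg.end, arm.end)
            if hi > lo:
                covered += hi - lo
                weighted += (hi - lo) * seg.cn
        if covered / arm.length < min_coverage:
            logger.warning(
                "arm %s covered %.1f%% (< %.0f%%); flagged missing",
                arm.name, 100 * covered / arm.length, 100 * min_coverage,
            )
            continue
        out[arm.name] = weighted / covered
    return out


def arm_log2_deviation(
    arm_cn: Mapping[str, float],
    expected_cn: Mapping[str, float],
    cn_floor: float = DEFAULT_CN_FLOOR,
    sample_id: str = "sample",
) -> TissueArmCNA:
    """log2(max(cn, cn_floor) / expected_cn) per arm.

    The floor bounds the transform for homozygous-deletion segments.
    """
    if not cn_floor > 0:
        raise ValueError("cn_floor must be positive")
    log2 = {}
    expected = {}
    for arm, cn in arm_cn.items():
        exp = expected_cn[arm]
        if not exp > 0:
            raise ValueError(f"expected copy number for {arm} must be positive")
        log2[arm] = float(np.log2(max(cn, cn_floor) / exp))
        expected[arm] = float(exp)
    return TissueArmCNA(sample_id=sample_id, arm_log2=log2, expected_cn=expected)


class ConcordanceResult(NamedTuple):
    rho: float
    p_value: float
    n_arms: int


def concordance(tissue: TissueArmCNA, zprofile: ArmZProfile) -> ConcordanceResult:
    """Spearman correlation between tissue arm log2 CNA and cfDNA arm Z-scores.

    Arms missing from either input are dropped pairwise; ties get average
    ranks (scipy default).  Fewer than 10 shared arms is an error.
    """
    shared = sorted(set(tissue.arm_log2) & set(zprofile.z))
    if len(shared) < MIN_CONCORDANCE_ARMS:
        raise ValueError(
            f"insufficient arms: {len(shared)} shared, "
            f"need >= {MIN_CONCORDANCE_ARMS}"
        )
    x = np.array([tissue.arm_log2[a] for a in shared])
    y = np.array([zprofile.z[a] for a in shared])
    res = stats.spearmanr(x, y)
    return ConcordanceResult(float(res.statistic), float(res.pvalue), len(shared))


# ---------------------------------------------------------------------------
# File formats


def read_segments(path: str | Path) -> list[SegmentCN]:
    """Read a segment TSV with columns (chromosome, start, end, copyNumber)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    chrom_col = cols.get("chromosome", cols.get("chrom"))
    cn_col = cols.get("copynumber", cols.get("cn"))
    if chrom_col is None or cn_col is None:
        raise ValueError("segment table needs chromosome and copyNumber columns")
    return [
        SegmentCN(
            chrom=str(row[chrom_col]).removeprefix("chr"),
            start=int(row[cols["start"]]),
            end=int(row[cols["end"]]),
            cn=float(row[cn_col]),
        )
        for _, row in df.iterrows()
    ]


def write_segments(segments: Sequence[SegmentCN], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chromosome": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "copyNumber": [s.cn for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)
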