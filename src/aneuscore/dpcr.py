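"""Digital-PCR copy-number ratios (AR target vs AGO1 reference).

Partition counts are Poisson-corrected: with a fraction q of positive
partitions, the mean occupancy is lambda = -ln(1 - q) copies per partition,
and the target/reference concentration ratio estimates the copy-number
ratio.  The AR gene sits on chrX and AGO1 on chromosome 1p34.3, so at the
DNA level an unamplified male sample has one AR copy against two AGO1 copies
(expected raw ratio ~0.5); the raw lambda ratio is reported without
renormalizing to that baseline.  CIs propagate the binomial uncertainty of
each positive fraction on the log-ratio scale (delta method).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwa import GWAResult


@dataclass(frozen=True)
class DPCRWell:
    """Summary of one dPCR well: partition counts for a single assay target."""

    target_name: str
    n_partitions: int
    n_positive: int
    partition_volume: float = 0.85  # nanoliters, instrument-typical default

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        if not 0 <= self.n_positive <= self.n_partitions:
            raise ValueError("n_positive must be in [0, n_partitions]")
        if not self.partition_volume > 0:
            raise ValueError("partition_volume must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_partitions


def poisson_lambda(well: DPCRWell) -> float:
    """Mean copies per partition, lambda = -ln(1 - positive fraction).

    A fully positive (saturated) well carries no concentration information
    and is an error; an all-negative well gives lambda = 0.
    """
    if well.n_positive == well.n_partitions:
        raise ValueError(f"saturated well for {well.target_name}: all partitions positive")
    return float(-np.log1p(-well.positive_fraction))


def poisson_concentration(well: DPCRWell) -> float:
    """Copies per nanoliter: lambda divided by the partition volume."""
    return poisson_lambda(well) / well.partition_volume


def _log_lambda_variance(well: DPCRWell) -> float:
    # delta method: Var(log lam) = q / (n (1-q) lam^2), q = positive fraction
    q = well.positive_fraction
    lam = poisson_lambda(well)
    if lam == 0:
        return float("inf")
    return q / (well.n_partitions * (1 - q) * lam**2)


class RatioResult(NamedTuple):
    ratio: float
    ci_low: float
    ci_high: float


def cn_ratio(
    target: DPCRWell, reference: DPCRWell, confidence: float = 0.95
) -> RatioResult:
    """Target/reference concentration ratio with a delta-method CI.

    With equal partition volumes this is the plain lambda ratio.  The CI is
    symmetric on the log-ratio scale.
    """
    lam_ref = poisson_lambda(reference)
    if lam_ref == 0:
        raise ValueError(f"reference not detected: {reference.target_name} has no positives")
    lam_t = poisson_lambda(target)
    ratio = (lam_t / target.partition_volume) / (lam_ref / reference.partition_volume)
    if lam_t == 0:
        return RatioResult(0.0, 0.0, float("nan"))
    z = stats.norm.ppf(0.5 + confidence / 2)
    se = float(np.sqrt(_log_lambda_variance(target) + _log_lambda_variance(reference)))
    return RatioResult(
        ratio=float(ratio),
        ci_low=float(ratio * np.exp(-z * se)),
        ci_high=float(ratio * np.exp(z * se)),
    )


@dataclass(frozen=True)
class RatioGWAReport:
    """Association of dPCR CN-ratios with GWA scores and Xq Z-scores."""

    pearson_r: float
    r_squared: float
    pearson_p: float
    ranksum_p: float  # ratios in GWA-high vs GWA-low samples
    xq_pearson_r: float
    n: int


def ratio_vs_gwa(
    ratios: Mapping[str, float],
    gwa: Mapping[str, GWAResult],
    xq_z: Mapping[str, float] | None = None,
) -> RatioGWAReport:
    """Correlate per-sample CN-ratios with GWA scores (paired by sample id).

    Reports Pearson r and R^2 between ratio and GWA score, a rank-sum
    (Mann-Whitney) comparison of ratios between GWA-high and GWA-low
    samples, and optionally the Pearson correlation with Xq Z-scores.
    """
    shared = sorted(set(ratios) & set(gwa))
    if len(shared) < 10:
        raise ValueError(f"need >= 10 paired samples, got {len(shared)}")
    r_vals = np.array([ratios[s] for s in shared])
    g_vals = np.array([gwa[s].gwa for s in shared])
    res = stats.pearsonr(r_vals, g_vals)
    high = r_vals[[gwa[s].status == "high" for s in shared]]
    low = r_vals[[gwa[s].status == "low" for s in shared]]
    if len(high) and len(low):
        ranksum_p = float(stats.mannwhitneyu(high, low, alternative="two-sided").pvalue)
    else:
        ranksum_p = float("nan")
    xq_r = float("nan")
    if xq_z is not None:
        xq_shared = [s for s in shared if s in xq_z]
        if len(xq_shared) >= 10:
            xq_r = float(
                stats.pearsonr(
                    [ratios[s] for s in xq_shared], [xq_z[s] for s in xq_shared]
                ).statistic
            )
    return RatioGWAReport(
        pearson_r=float(res.statistic),
        r_squared=float(res.statistic**2),
        pearson_p=float(res.pvalue),
        ranksum_p=ranksum_p,
        xq_pearson_r=xq_r,
        n=len(shared),
    )


# ---------------------------------------------------------------------------
# File formats


def read_wells(path) -> dict[str, dict[str, DPCRWell]]:
    """Read a well CSV (sample_id, target, n_partitions, n_positive,
    partition_volume_nl) into {sample_id: {target: well}}."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, DPCRWell]] = {}
    for _, row in df.iterrows():
        well = DPCRWell(
            target_name=str(row["target"]),
            n_partitions=int(row["n_partitions"]),
            n_positive=int(row["n_positive"]),
            partition_volume=float(row.get("partition_volume_nl", 0.85)),
        )
        out.setdefault(str(row["sample_id"]), {})[well.target_name] = well
    return out


def ratios_to_frame(
    wells: Mapping[str, Mapping[str, DPCRWell]],
    target: str = "AR",
    reference: str = "AGO1",
) -> pd.DataFrame:
    """Per-sample target/reference ratios with CIs from a well collection."""
    rows = []
    for sample, ws in wells.items():
        if target not in ws or reference not in ws:
            continue
        res = cn_ratio(ws[target], ws[reference])
        rows.append(
            {
                "sample_id": sample,
                "ratio": res.ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)
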