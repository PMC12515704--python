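"""Shared fixtures: arm models, cytoband fixture files, control references.

All fixture data are generated programmatically; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from aneuscore import SimulationConfig, build_reference, grch38_arms, make_control_cohort
from aneuscore.arms import _GRCH38_ARMS, ArmDefinition


@pytest.fixture(scope="session")
def arms():
    return grch38_arms()


@pytest.fixture(scope="session")
def toy_arms():
    """Two-chromosome toy arm model with simple round coordinates."""
    return [
        ArmDefinition("1", "p", 0, 50, True, 50.0),
        ArmDefinition("1", "q", 60, 100, True, 40.0),
        ArmDefinition("2", "p", 0, 30, True, 30.0),
        ArmDefinition("2", "q", 40, 100, True, 60.0),
    ]


@pytest.fixture()
def cytoband_file(tmp_path):
    """UCSC-style cytoband table generated from the built-in arm constants."""
    path = tmp_path / "cytoBand.txt"
    with open(path, "w") as fh:
        for chrom, acen_start, acen_end, length in _GRCH38_ARMS:
            mid = (acen_start + acen_end) // 2
            fh.write(f"chr{chrom}\t0\t{acen_start}\tp11\tgneg\n")
            fh.write(f"chr{chrom}\t{acen_start}\t{mid}\tp11.1\tacen\n")
            fh.write(f"chr{chrom}\t{mid}\t{acen_end}\tq11.1\tacen\n")
            fh.write(f"chr{chrom}\t{acen_end}\t{length}\tq11\tgneg\n")
    return path


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def control_reference(arms, default_config):
    """Reference built from the default synthetic 17-control cohort."""
    controls = make_control_cohort(default_config, arms)
    return build_reference(controls, arms)


# ---------------------------------------------------------------------------
# Independent survival oracles (hand-coded; never call lifelines)


def efron_log_partial_likelihood(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Explicit Cox log partial likelihood with Efron tie handling."""
    ll = 0.0
    for t in np.unique(times[events.astype(bool)]):
        dead = (times == t) & events.astype(bool)
        at_risk = times >= t
        d = int(dead.sum())
        risk_sum = float(np.sum(np.exp(beta * x[at_risk])))
        dead_sum = float(np.sum(np.exp(beta * x[dead])))
        ll += float(beta * x[dead].sum())
        for ell in range(d):
            ll -= np.log(risk_sum - (ell / d) * dead_sum)
    return ll


def grid_search_cox_mle(
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    lo: float = -4.0,
    hi: float = 4.0,
    step: float = 1e-4,
) -> float:
    """Brute-force maximizer of the Efron partial likelihood over a grid."""
    # coarse pass, then fine pass around the best coarse point
    coarse = np.arange(lo, hi + 1e-12, 0.01)
    ll = np.array([efron_log_partial_likelihood(b, times, events, x) for b in coarse])
    b0 = coarse[int(np.argmax(ll))]
    fine = np.arange(b0 - 0.02, b0 + 0.02 + 1e-12, step)
    ll = np.array([efron_log_partial_likelihood(b, times, events, x) for b in fine])
    return float(fine[int(np.argmax(ll))])


def cox_score_test_statistic(
    times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Squared, information-normalized Cox score at beta = 0 (binary x)."""
    score = 0.0
    info = 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        d = int(((times == t) & events.astype(bool)).sum())
        n = int(at_risk.sum())
        xbar = float(x[at_risk].mean())
        score += float(x[(times == t) & events.astype(bool)].sum()) - d * xbar
        info += d * float(np.mean((x[at_risk] - xbar) ** 2))
    return score**2 / info
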