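"""Monte-Carlo operating characteristics and type-I-error calibration.

``simulate`` runs many independent trials against a scenario and
aggregates the power for proof-of-concept, the probabilities of correctly
selecting the true MED and MUD, patient allocation, and early stopping.

``calibrate_cpoc`` determines the proof-of-concept cutoff: it simulates
the design on a flat null scenario, records each trial's final statistic
max_j Pr(mu_j > mu_1 | data), and returns the empirical (1 - alpha)
quantile, so that rejecting whenever the statistic exceeds the cutoff has
familywise type-I error approximately alpha under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
import warnings

import numpy as np
import pandas as pd

from .config import DesignConfig
from .trial_engine import TrialResult, run_trial

__all__ = ["OCSummary", "simulate", "calibrate_cpoc", "null_poc_statistics"]


@dataclass
class OCSummary:
    """Aggregated operating characteristics over simulated trials."""

    n_sim: int
    poc_rate: float
    pcs_med: float
    pcs_mud: float
    early_stop_rate: float
    mean_allocation: np.ndarray  # per-arm mean fraction of the planned sample size
    mean_enrolled: float
    med_selection: np.ndarray  # per-arm fraction of trials selecting arm as MED
    mud_selection: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_sim": self.n_sim,
            "poc_rate": self.poc_rate,
            "pcs_med": self.pcs_med,
            "pcs_mud": self.pcs_mud,
            "early_stop_rate": self.early_stop_rate,
            "mean_allocation": [float(v) for v in self.mean_allocation],
            "mean_enrolled": self.mean_enrolled,
            "med_selection": [float(v) for v in self.med_selection],
            "mud_selection": [float(v) for v in self.mud_selection],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self, scenario_name: str = "") -> pd.DataFrame:
        rows = [
            ("poc_rate", self.poc_rate),
            ("pcs_med", self.pcs_med),
            ("pcs_mud", self.pcs_mud),
            ("early_stop_rate", self.early_stop_rate),
            ("mean_enrolled", self.mean_enrolled),
        ]
        rows += [(f"allocation_arm{j + 1}", float(v)) for j, v in enumerate(self.mean_allocation)]
        rows += [(f"med_arm{j + 1}", float(v)) for j, v in enumerate(self.med_selection)]
        rows += [(f"mud_arm{j + 1}", float(v)) for j, v in enumerate(self.mud_selection)]
        df = pd.DataFrame(rows, columns=["metric", "value"])
        df.insert(0, "scenario", scenario_name)
        df.insert(2, "n_sim", self.n_sim)
        return df


def _trial_seeds(seed, n_sim: int) -> list[np.random.SeedSequence]:
    # one child SeedSequence per trial: order-independent and parallel-safe
    return np.random.SeedSequence(seed).spawn(n_sim)


def _run_all(scenario, config: DesignConfig, n_sim: int, seed) -> list[TrialResult]:
    return [run_trial(scenario, config, seed=ss) for ss in _trial_seeds(seed, n_sim)]


def simulate(scenario, config: DesignConfig, n_sim: int, seed=None) -> OCSummary:
    """Estimate operating characteristics from ``n_sim`` independent trials.

    Correct-selection rates use the scenario's ``true_med``/``true_mud``
    labels and count every simulated trial in the denominator: trials that
    stop early or fail to establish proof-of-concept select nothing and
    are therefore incorrect.
    """
    J = config.n_arms
    if n_sim == 0:
        z = np.zeros(J)
        return OCSummary(0, 0.0, 0.0, 0.0, 0.0, z, 0.0, z.copy(), z.copy())
    results = _run_all(scenario, config, n_sim, seed)
    return summarize(results, scenario, config)


def summarize(results: list[TrialResult], scenario, config: DesignConfig) -> OCSummary:
    n_sim = len(results)
    J = config.n_arms
    N = config.max_patients
    poc = np.array([r.poc_established for r in results])
    stopped = np.array([r.stopped_early for r in results])
    med = np.array([r.med if r.med is not None else 0 for r in results])
    mud = np.array([r.mud if r.mud is not None else 0 for r in results])
    alloc = np.stack([r.enrollment for r in results]) / N

    med_sel = np.array([(med == j + 1).mean() for j in range(J)])
    mud_sel = np.array([(mud == j + 1).mean() for j in range(J)])
    pcs_med = float((med == scenario.true_med).mean()) if scenario.true_med else 0.0
    pcs_mud = float((mud == scenario.true_mud).mean()) if scenario.true_mud else 0.0

    return OCSummary(
        n_sim=n_sim,
        poc_rate=float(poc.mean()),
        pcs_med=pcs_med,
        pcs_mud=pcs_mud,
        early_stop_rate=float(stopped.mean()),
        mean_allocation=alloc.mean(axis=0),
        mean_enrolled=float(np.stack([r.enrollment for r in results]).sum(axis=1).mean()),
        med_selection=med_sel,
        mud_selection=mud_sel,
    )


def null_poc_statistics(null_scenario, config: DesignConfig, n_sim: int, seed=None) -> np.ndarray:
    """Per-trial final PoC statistics under a null scenario.

    Early-stopped trials never reject; their statistic is recorded as 0.
    """
    results = _run_all(null_scenario, config, n_sim, seed)
    return np.array([r.poc_stat for r in results])


def calibrate_cpoc(
    null_scenario,
    config: DesignConfig,
    target_error: float = 0.05,
    n_sim: int = 2000,
    seed=None,
) -> float:
    """Calibrate the proof-of-concept cutoff to a familywise error level.

    Returns the empirical (1 - target_error) quantile of the per-trial
    statistic max_j Pr(mu_j > mu_1 | data) over ``n_sim`` simulated null
    trials.
    """
    if not 0.0 < target_error <= 1.0:
        raise ValueError("target_error must lie in (0, 1]")
    stats = null_poc_statistics(null_scenario, config, n_sim, seed)
    if np.ptp(stats) == 0:
        warnings.warn("all null PoC statistics identical; calibration is degenerate")
    return float(np.quantile(stats, 1.0 - target_error))
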