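"""Critical-mass model of scale-induced category convergence.

A label "reaches critical mass" in a population of N agents when at least a
fraction theta of them (default 25%) introduce it independently.  If each
individual introduces the label with probability p (infinite-population
reading), the number of introducers is Binomial(N, p); when K carriers exist
in a finite universe of M individuals from which the N agents are drawn, it
is Hypergeometric(M, K, N).  The tail probability
P[X >= ceil(theta * N)] rises with N for common labels (p > ~theta) and
falls with N for rare ones — the mechanism by which large populations
consistently amplify the same few labels while dyads latch onto idiosyncratic
ones.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .continuum import ContinuumSpec
from .simulate import GameParams, run_ensemble

__all__ = [
    "critical_mass_threshold",
    "critical_mass_prob_binomial",
    "critical_mass_prob_hypergeom",
    "critical_mass_scale_curve",
    "predict_convergence_curve",
]


def critical_mass_threshold(n_agents: int, theta: float = 0.25) -> int:
    """Minimum introducer count for critical mass: ceil(theta * N).

    "At least 25% of subjects" is read literally, so a dyad needs >= 1
    introducer.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    if n_agents < 1:
        raise ValueError("n_agents must be positive")
    return math.ceil(theta * n_agents)


def critical_mass_prob_binomial(p: float, n_agents: int, theta: float = 0.25) -> float:
    """P[X >= ceil(theta*N)] for X ~ Binomial(N, p).

    Computed through the survival function for stability at large N.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    k = critical_mass_threshold(n_agents, theta)
    return float(stats.binom.sf(k - 1, n_agents, p))


def critical_mass_prob_hypergeom(
    carriers_k: int, universe_m: int, n_agents: int, theta: float = 0.25
) -> float:
    """P[X >= ceil(theta*N)] for X ~ Hypergeometric(M, K, N): the chance that
    a sample of N from a universe of M containing K carriers holds a critical
    mass of carriers."""
    if not 0 <= carriers_k <= universe_m:
        raise ValueError("need 0 <= K <= M")
    if n_agents > universe_m:
        raise ValueError("sample size N cannot exceed universe size M")
    k = critical_mass_threshold(n_agents, theta)
    return float(stats.hypergeom.sf(k - 1, universe_m, carriers_k, n_agents))


def critical_mass_scale_curve(
    p: float, n_grid: Sequence[int], theta: float = 0.25
) -> pd.DataFrame:
    """Critical-mass probability as a function of population size.

    For p comfortably above theta the probability grows with N (common labels
    are reliably amplified); for rare p it shrinks (idiosyncratic labels are
    filtered out of large populations).
    """
    rows = [
        (int(n), critical_mass_prob_binomial(p, int(n), theta)) for n in n_grid
    ]
    return pd.DataFrame(rows, columns=["n_agents", "critical_mass_prob"])


def predict_convergence_curve(
    params: GameParams,
    n_grid: Sequence[int],
    n_trials: int,
    base_seed: int,
    spec: Optional[ContinuumSpec] = None,
) -> pd.DataFrame:
    """Model-predicted convergence curve: per population size, the mean
    within-size pairwise Jaccard similarity of emergent vocabularies and the
    mean label diversity, from an ensemble of simulated trials.

    The expectation under the critical-mass account is a Jaccard index
    nondecreasing in N across the grid.
    """
    from .analysis import convergence_report

    if n_trials < 2:
        raise ValueError("need at least 2 trials per size for pairwise Jaccard")
    rows = []
    for i, n in enumerate(n_grid):
        n = int(n)
        if n < 2 or n % 2:
            raise ValueError("population sizes must be even and >= 2")
        p = replace(
            params,
            n_agents=n,
            pairing_mode="fixed_partner" if n == 2 else "uniform_random",
        )
        logs = run_ensemble(p, n_trials, base_seed + i, spec)
        report = convergence_report(logs)
        rows.append(
            (n, float(np.mean(report.diversity)), report.mean_jaccard)
        )
    return pd.DataFrame(rows, columns=["n_agents", "diversity", "jaccard"])
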