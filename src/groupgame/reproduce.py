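"""Headline reproduction battery.

Recomputes, from fresh simulations at the default study conditions, the
package's headline quantities:

* mean pairwise vocabulary Jaccard across independent N = 50 populations;
* shared-label fraction across an ensemble of independent dyads;
* mean pairwise Jaccard across confederate-seeded N = 24 populations
  (9 of 24 agents immutably promoting rare labels) and across baseline
  N = 24 populations;
* the emergent-vocabulary size from the DBSCAN extraction on one N = 50
  trial.

All percentages are on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .analysis import (
    convergence_report,
    extract_category_system,
    shared_label_fraction,
)
from .continuum import ContinuumSpec
from .simulate import GameParams, default_confederate_mapping, run_ensemble, run_trial

__all__ = ["run_battery"]


def run_battery(seed: int, out_dir: Optional[str] = None) -> Dict[str, Dict]:
    """Run the full battery with seeds derived from ``seed``.

    Returns a mapping of quantity name to ``{"value": ..., "n": ...}`` and,
    when ``out_dir`` is given, writes the same table as CSV.
    """
    spec = ContinuumSpec()
    base = GameParams(n_agents=50)

    # scale-induced convergence: 15 independent N = 50 populations
    logs50 = run_ensemble(base, 15, seed, spec)
    rep50 = convergence_report(logs50)
    jaccard50 = 100.0 * rep50.mean_jaccard

    # dyad divergence: 80 independent fixed-partner dyads
    dyad = replace(base, n_agents=2, pairing_mode="fixed_partner")
    logs2 = run_ensemble(dyad, 80, seed + 1, spec)
    shared2 = 100.0 * shared_label_fraction(logs2)

    # confederate robustness: 9 of 24 agents push fixed rare labels
    conf = replace(
        base,
        n_agents=24,
        confederate_fraction=0.37,
        confederate_mapping=default_confederate_mapping(),
    )
    logs_conf = run_ensemble(conf, 6, seed + 2, spec)
    rep_conf = convergence_report(logs_conf, exclude_confederate_speakers=True)
    jaccard_conf = 100.0 * rep_conf.mean_jaccard

    # matched baseline: N = 24, no confederates
    base24 = replace(base, n_agents=24)
    logs24 = run_ensemble(base24, 15, seed + 3, spec)
    rep24 = convergence_report(logs24)
    jaccard24 = 100.0 * rep24.mean_jaccard

    # emergent-vocabulary size of one default N = 50 trial
    one = run_trial(replace(base, seed=seed + 4), spec, trial_id="single")
    n_emergent = len(extract_category_system(one).labels)

    results = {
        "jaccard_n50": {"value": round(jaccard50, 2), "n": 15},
        "dyad_shared_fraction": {"value": round(shared2, 2), "n": 80},
        "jaccard_confederate_n24": {"value": round(jaccard_conf, 2), "n": 6},
        "jaccard_baseline_n24": {"value": round(jaccard24, 2), "n": 15},
        "emergent_vocabulary_size": {"value": n_emergent, "n": 1},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(k, v["value"], v["n"]) for k, v in results.items()],
            columns=["quantity", "value", "n"],
        ).to_csv(out / "summary.csv", index=False)
    return results
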