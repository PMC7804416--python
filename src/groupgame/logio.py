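"""Interaction-log serialization, run configuration, and test fixtures.

Logs travel as CSV (one interaction per row, fixed header) or JSON-lines;
``write_log`` followed by ``read_log`` is the identity on valid logs.  The
reader validates the schema and the record invariants (topic and guess must
be scene stimuli; success must equal guess == topic), reporting offending
row numbers.  Extra columns are preserved so externally collected logs with
additional metadata can pass through the same reader.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .continuum import ContinuumSpec
from .simulate import (
    LOG_COLUMNS,
    GameParams,
    InteractionRecord,
    TrialLog,
    default_confederate_mapping,
)

__all__ = [
    "RunConfig",
    "read_log",
    "write_log",
    "make_fixture",
    "FIXTURES",
]


@dataclass
class RunConfig:
    """One reproducible run: continuum, game, analysis and ensemble settings.

    Defaults throughout are the headline study conditions (1500 slices,
    75-slice scene separation, 100 rounds, d_min = 0.01, pool 5000, b = 1,
    critical-mass threshold 25%, MinPts 3, 50 density bins).
    """

    continuum: ContinuumSpec = field(default_factory=ContinuumSpec)
    game: GameParams = field(default_factory=lambda: GameParams(n_agents=2))
    theta: float = 0.25
    min_pts: int = 3
    density_bins: int = 50
    n_trials: int = 15
    base_seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = {
            "continuum": asdict(self.continuum),
            "game": asdict(self.game),
            "analysis": {
                "theta": self.theta,
                "min_pts": self.min_pts,
                "density_bins": self.density_bins,
            },
            "ensemble": {"n_trials": self.n_trials, "base_seed": self.base_seed},
            "out_dir": self.out_dir,
        }
        cm = d["game"]["confederate_mapping"]
        if cm is not None:
            d["game"]["confederate_mapping"] = [list(r) for r in cm]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        game = dict(d.get("game", {}))
        if game.get("confederate_mapping"):
            game["confederate_mapping"] = tuple(
                (float(lo), float(hi), str(lab))
                for lo, hi, lab in game["confederate_mapping"]
            )
        analysis = d.get("analysis", {})
        ensemble = d.get("ensemble", {})
        return cls(
            continuum=ContinuumSpec(**d.get("continuum", {})),
            game=GameParams(**game) if game else GameParams(n_agents=2),
            theta=analysis.get("theta", 0.25),
            min_pts=analysis.get("min_pts", 3),
            density_bins=analysis.get("density_bins", 50),
            n_trials=ensemble.get("n_trials", 15),
            base_seed=ensemble.get("base_seed", 0),
            out_dir=d.get("out_dir", "."),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class LogSchemaError(ValueError):
    pass


def write_log(log: TrialLog, path) -> None:
    """Serialise a TrialLog as CSV (``.csv``) or JSON-lines (``.jsonl``)."""
    path = Path(path)
    df = log.to_dataframe()
    if path.suffix == ".jsonl":
        with path.open("w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        df.to_csv(path, index=False)


def _validate_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogSchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("success", "speaker_was_exposed", "speaker_is_confederate",
                "hearer_is_confederate"):
        df[col] = df[col].astype(bool)
    stim = df[["stim1", "stim2", "stim3"]].to_numpy()
    topic_ok = (stim == df["topic"].to_numpy()[:, None]).any(axis=1)
    guess_ok = (stim == df["guess"].to_numpy()[:, None]).any(axis=1)
    success_ok = df["success"].to_numpy() == (
        df["guess"].to_numpy() == df["topic"].to_numpy()
    )
    for name, ok in (
        ("topic not among stimuli", topic_ok),
        ("guess not among stimuli", guess_ok),
        ("success flag inconsistent with guess/topic", success_ok),
    ):
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0]) + 1
            raise LogSchemaError(f"{path}: {name} at data row {row}")
    return df


def read_log(path, params: Optional[GameParams] = None) -> TrialLog:
    """Read a CSV or JSON-lines interaction log into a TrialLog.

    Schema and invariant violations raise :class:`LogSchemaError` with the
    offending row number.  ``params`` attaches game parameters when known;
    otherwise a minimal GameParams is inferred from the log shape.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        rows = [json.loads(line) for line in path.read_text().splitlines() if line]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    df = _validate_frame(df, path)
    if params is None:
        agents = pd.concat([df["speaker_id"], df["hearer_id"]]).nunique()
        agents = max(2, agents + (agents % 2))
        rounds = int(df["round"].max()) if len(df) else 1
        params = GameParams(n_agents=int(agents), rounds=rounds)
    records = [
        InteractionRecord(
            trial_id=str(r.trial_id),
            round=int(r.round),
            speaker_id=int(r.speaker_id),
            hearer_id=int(r.hearer_id),
            stimuli=(int(r.stim1), int(r.stim2), int(r.stim3)),
            topic=int(r.topic),
            label=str(r.label),
            guess=int(r.guess),
            success=bool(r.success),
            speaker_was_exposed=bool(r.speaker_was_exposed),
            speaker_is_confederate=bool(r.speaker_is_confederate),
            hearer_is_confederate=bool(r.hearer_is_confederate),
        )
        for r in df.itertuples(index=False)
    ]
    trial_id = records[0].trial_id if records else "trial0"
    return TrialLog(params=params, records=records, trial_id=trial_id)


# ---------------------------------------------------------------------------
# hand-constructed fixtures
# ---------------------------------------------------------------------------

def _rec(rnd, sp, he, stimuli, topic, label, guess, exposed=False,
         sp_conf=False, he_conf=False, trial="fixture"):
    return InteractionRecord(
        trial_id=trial,
        round=rnd,
        speaker_id=sp,
        hearer_id=he,
        stimuli=stimuli,
        topic=topic,
        label=label,
        guess=guess,
        success=guess == topic,
        speaker_was_exposed=exposed,
        speaker_is_confederate=sp_conf,
        hearer_is_confederate=he_conf,
    )


def _exposure_trace() -> TrialLog:
    # Agents 0-5, three rounds of "fox": 0 introduces it (unexposed), 1
    # adopts it after hearing it in round 1, 2 introduces it independently.
    params = GameParams(n_agents=6, rounds=3)
    recs = [
        _rec(1, 0, 1, (0, 500, 1000), 0, "fox", 0),
        _rec(1, 2, 3, (100, 600, 1100), 600, "owl", 100),
        _rec(1, 4, 5, (200, 700, 1200), 1200, "elk", 1200),
        _rec(2, 1, 0, (300, 800, 1300), 300, "fox", 300, exposed=True),
        _rec(2, 3, 2, (50, 550, 1050), 550, "owl", 550, exposed=True),
        _rec(2, 5, 4, (250, 750, 1250), 750, "elk", 250, exposed=True),
        _rec(3, 2, 3, (400, 900, 1400), 400, "fox", 400),
        _rec(3, 0, 1, (150, 650, 1150), 1150, "owl", 1150, exposed=True),
        _rec(3, 4, 5, (350, 850, 1350), 850, "elk", 850, exposed=True),
    ]
    return TrialLog(params=params, records=recs, trial_id="fixture")


def _dominant4() -> TrialLog:
    # Four labels dominate successes and adopters across a 6-agent
    # population; a scatter of one-off failing labels forms the low-value
    # bulk, so the DBSCAN extraction must single out the dominant four.
    params = GameParams(n_agents=6, rounds=40)
    recs = []
    dominant = ["alpha", "beta", "gamma", "delta"]
    regions = [60, 440, 820, 1200]  # topic slices, one region per label
    rnd = 1
    s = 0
    for rep in range(8):
        for li, lab in enumerate(dominant):
            sp, he = (2 * (li % 3), 2 * (li % 3) + 1)
            topic = regions[li] + rep * 3
            recs.append(
                _rec(rnd, sp, he, (topic, topic + 100, topic + 200),
                     topic, lab, topic, exposed=rep > 0, trial="dominant4")
            )
            rnd += 1
    # rare one-shot failures
    for i in range(12):
        topic = 30 + i * 17
        recs.append(
            _rec(rnd, (2 * i) % 6, (2 * i + 1) % 6,
                 (topic, topic + 400, topic + 800), topic,
                 f"junk{i:02d}"[:6], topic + 400, trial="dominant4")
        )
        rnd += 1
    # renumber rounds so each agent appears at most once per round is NOT
    # enforced for fixtures; analysis only needs chronology
    return TrialLog(params=params, records=recs, trial_id="dominant4")


def _confederate_mini() -> TrialLog:
    # Two confederates (0, 1) pushing "sumo" against experimental subjects'
    # "crab"; used to test confederate filtering in the analyses.
    params = GameParams(n_agents=4, rounds=4)
    recs = [
        _rec(1, 0, 2, (0, 300, 600), 0, "sumo", 0, sp_conf=True, trial="confmini"),
        _rec(1, 3, 1, (100, 400, 700), 100, "crab", 100, he_conf=True, trial="confmini"),
        _rec(2, 2, 3, (50, 350, 650), 50, "sumo", 50, exposed=True, trial="confmini"),
        _rec(2, 0, 1, (150, 450, 750), 150, "sumo", 150, sp_conf=True,
             he_conf=True, trial="confmini"),
        _rec(3, 2, 3, (80, 380, 680), 80, "crab", 380, exposed=True, trial="confmini"),
        _rec(4, 3, 2, (120, 420, 720), 120, "sumo", 120, exposed=True, trial="confmini"),
    ]
    return TrialLog(params=params, records=recs, trial_id="confmini")


FIXTURES = {
    "exposure_trace": _exposure_trace,
    "dominant4": _dominant4,
    "confederate_mini": _confederate_mini,
}


def make_fixture(name: str) -> TrialLog:
    """Deterministic hand-constructed mini-logs used across the test suite."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
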