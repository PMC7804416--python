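"""Agent-based simulator of the Grouping Game.

Populations of agents play pairwise label-coordination rounds over a
continuum of ambiguous stimuli.  Each agent maintains a dynamic partition of
the normalised continuum [0, 1) into perceptual categories, with a per-category
label inventory, following the category-game family of models:

* the speaker refines its partition until the highlighted topic sits alone in
  a category (new boundaries at midpoints between topic and distractors),
  bounded below by the perceptual resolution ``d_min``;
* every agent arrives with a stable *private naming function*: a personal
  coarse partition of the continuum whose regions carry labels drawn from a
  shared, Zipf-weighted pool of candidate labels (rank-frequency exponent
  ``b``) — the model of wide individual variation in how people
  spontaneously categorise novel stimuli;
* the speaker transmits the topic category's most recently successful label
  (its *convention*), else its own most recent coinage for that category,
  else coins its private label for the region; conventions are inherited when
  a category splits, private coinages are looked up afresh;
* the hearer guesses among the scene stimuli whose categories know the label,
  either as a production label or from its memory of heard labels;
* on success both parties collapse the topic category's production inventory
  to the winning label; on failure the hearer files the heard label in the
  topic category's guessing memory (the payoff feedback reveals the topic).

The shared Zipf pool models the empirical fact that a few labels (e.g.
"crab", "bunny") are independently invented by many people while most labels
are idiosyncratic.  Because a label is only produced by its own coiners and
by agents it has already succeeded with, its rate of spread is proportional
to its number of independent introducers — the critical-mass engine of
scale-induced convergence.

Confederates are planted agents with an immutable mapping from continuum
regions to fixed labels; they never learn and always produce and interpret
labels through that mapping.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .continuum import ContinuumSpec, Scene, sample_scene

__all__ = [
    "GameParams",
    "LabelPool",
    "AgentState",
    "InteractionRecord",
    "TrialLog",
    "default_confederate_mapping",
    "init_population",
    "discriminate",
    "speak",
    "hear",
    "update_pair",
    "run_trial",
    "run_ensemble",
    "LOG_COLUMNS",
]

LOG_COLUMNS = [
    "trial_id",
    "round",
    "speaker_id",
    "hearer_id",
    "stim1",
    "stim2",
    "stim3",
    "topic",
    "label",
    "guess",
    "success",
    "speaker_was_exposed",
    "speaker_is_confederate",
    "hearer_is_confederate",
]

# Curated head of the label pool: short, plausible coinages.  The heavy Zipf
# head means these are the labels many individuals invent independently.
_HEAD_WORDS = [
    "crab", "bunny", "fish", "moth", "bird", "worm", "snake", "ghost",
    "star", "blob", "frog", "crown", "heart", "spike", "wave", "leaf",
    "hand", "claw", "horn", "tree", "boat", "hat", "dog", "cat",
    "bell", "key", "arrow", "cloud", "moon", "sun", "drop", "bone",
    "wing", "fork", "lamp", "ring", "shell", "kite", "spoon", "cone",
]

# A deliberately rare token, available for confederate seeding.
_SUMO_RANK = 2999


@dataclass(frozen=True)
class GameParams:
    """Full parameterisation of one simulated population.

    Defaults are the headline model conditions: 100 rounds per subject,
    perceptual resolution d_min = 0.01 on the normalised continuum, a shared
    pool of 5000 candidate labels with Zipf exponent b = 1.
    """

    n_agents: int
    rounds: int = 100
    d_min: float = 0.01
    pool_size: int = 5000
    zipf_b: float = 1.0
    pairing_mode: str = "uniform_random"  # or "fixed_partner"
    private_categories: int = 5  # regions in each agent's private naming function
    confederate_fraction: float = 0.0
    confederate_mapping: Optional[Tuple[Tuple[float, float, str], ...]] = None
    ablate_hearer_learning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2 or self.n_agents % 2:
            raise ValueError("n_agents must be a positive even integer")
        if self.rounds < 1:
            raise ValueError("rounds must be positive")
        if not 0.0 < self.d_min < 1.0:
            raise ValueError("d_min must lie in (0, 1)")
        if self.pool_size < 1:
            raise ValueError("pool_size must be positive")
        if self.zipf_b < 0:
            raise ValueError("zipf_b must be nonnegative")
        if self.private_categories < 1:
            raise ValueError("private_categories must be positive")
        if self.pairing_mode not in ("uniform_random", "fixed_partner"):
            raise ValueError(f"unknown pairing_mode {self.pairing_mode!r}")
        if self.pairing_mode == "fixed_partner" and self.n_agents != 2:
            raise ValueError("fixed_partner pairing requires n_agents = 2")
        if not 0.0 <= self.confederate_fraction < 1.0:
            raise ValueError("confederate_fraction must lie in [0, 1)")
        if self.confederate_fraction > 0 and self.confederate_mapping is None:
            raise ValueError(
                "confederate_fraction > 0 requires a confederate_mapping"
            )

    @property
    def n_confederates(self) -> int:
        # nearest-integer reading of a fractional confederate share
        # (a 37% minority of 24 agents means 9 confederates)
        return int(round(self.confederate_fraction * self.n_agents))


class LabelPool:
    """Shared pool of candidate labels with Zipf-distributed innovation weights.

    Rank r (1-based) is drawn with probability proportional to r ** -b,
    so for b = 1 the rank-1 label is drawn with probability 1/H_pool_size.
    All tokens are distinct and at most six characters long.
    """

    def __init__(self, labels: Sequence[str], zipf_b: float = 1.0):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("pool labels must be distinct")
        if any(len(t) > 6 for t in labels):
            raise ValueError("pool labels must be at most 6 characters")
        self.labels = labels
        self.zipf_b = float(zipf_b)
        ranks = np.arange(1, len(labels) + 1, dtype=float)
        w = ranks ** (-self.zipf_b)
        self.weights = w / w.sum()

    def __len__(self) -> int:
        return len(self.labels)

    def rank(self, label: str) -> int:
        """1-based rank of a label in the pool."""
        return self.labels.index(label) + 1

    def draw(self, rng: np.random.Generator) -> str:
        if not hasattr(self, "_cum"):
            self._cum = np.cumsum(self.weights)
        return self.labels[int(np.searchsorted(self._cum, rng.random()))]

    @classmethod
    def default(cls, pool_size: int = 5000, zipf_b: float = 1.0) -> "LabelPool":
        """Deterministic default pool: curated short words at the head,
        generated tokens in the tail, with 'sumo' parked at a rare rank."""
        labels: List[str] = []
        used = set()
        for w in _HEAD_WORDS:
            if len(labels) >= pool_size:
                break
            labels.append(w)
            used.add(w)
        i = 0
        while len(labels) < pool_size:
            tok = f"w{i:04d}"
            i += 1
            if tok in used:
                continue
            labels.append(tok)
            used.add(tok)
        if pool_size > _SUMO_RANK and "sumo" not in used:
            labels[_SUMO_RANK] = "sumo"
        return cls(labels, zipf_b)


@dataclass
class _Inventory:
    """Per-category label state.

    ``labels`` is the production inventory (the agent's own coinage and/or
    the locked-in convention); ``last_success`` marks the convention;
    ``heard`` is a guessing memory of labels heard for this region, which
    informs interpretation but is never produced until it wins a round.
    """

    labels: List[str] = field(default_factory=list)
    last_success: Optional[str] = None
    heard: set = field(default_factory=set)

    def knows(self, label: str) -> bool:
        return label in self.labels or label in self.heard

    def split_copy(self) -> "_Inventory":
        # a split creates a fresh perceptual category: the proven convention
        # and the heard-label memory carry over, private coinages do not
        kept = [self.last_success] if self.last_success in self.labels else []
        return _Inventory(kept, self.last_success, set(self.heard))


class AgentState:
    """One agent's perceptual partition and per-category label inventories.

    ``boundaries`` are strictly increasing cut-points in (0, 1); category i
    is the interval between boundary i-1 and boundary i, so there are
    ``len(boundaries) + 1`` categories and inventories.
    """

    def __init__(
        self,
        agent_id: int,
        is_confederate: bool = False,
        confederate_mapping: Optional[Sequence[Tuple[float, float, str]]] = None,
        private_boundaries: Optional[Sequence[float]] = None,
        private_labels: Optional[Sequence[str]] = None,
    ):
        self.agent_id = agent_id
        self.is_confederate = is_confederate
        self.boundaries: List[float] = []
        self.inventories: List[_Inventory] = [_Inventory()]
        self.exposure_set: set = set()
        self.seen_slices: set = set()
        # private naming function: the agent's idiosyncratic, game-stable way
        # of labelling the continuum, used when no convention exists
        self.private_boundaries: List[float] = list(private_boundaries or [])
        self.private_labels: List[str] = list(private_labels or [])
        if self.private_labels and (
            len(self.private_labels) != len(self.private_boundaries) + 1
        ):
            raise ValueError("private labels must tile the private partition")
        self._mapping: Optional[List[Tuple[float, float, str]]] = None
        if is_confederate:
            if not confederate_mapping:
                raise ValueError("confederate agents need a mapping")
            self._mapping = sorted(confederate_mapping)
            # fixed partition mirroring the mapped regions
            self.boundaries = [lo for lo, _, _ in self._mapping if lo > 0.0]
            self.inventories = []
            pos = 0.0
            for lo, hi, lab in self._mapping:
                inv = _Inventory([lab], lab)
                self.inventories.append(inv)
                pos = hi
            if len(self.inventories) != len(self.boundaries) + 1:
                raise ValueError("confederate mapping must tile [0, 1)")

    def category_of(self, x: float) -> int:
        return bisect.bisect_right(self.boundaries, x)

    def private_label(self, x: float) -> Optional[str]:
        """The agent's own spontaneous label for a continuum position."""
        if not self.private_labels:
            return None
        return self.private_labels[bisect.bisect_right(self.private_boundaries, x)]

    def mapped_label(self, x: float) -> str:
        assert self._mapping is not None
        for lo, hi, lab in self._mapping:
            if lo <= x < hi:
                return lab
        return self._mapping[-1][2]

    def insert_boundary(self, b: float, d_min: float) -> bool:
        """Insert a cut-point if it keeps all adjacent gaps >= d_min.

        Children inherit the parent category's inventory.  Returns whether
        the insertion happened (False = discrimination failure).
        """
        idx = bisect.bisect_right(self.boundaries, b)
        left = self.boundaries[idx - 1] if idx > 0 else 0.0
        right = self.boundaries[idx] if idx < len(self.boundaries) else 1.0
        if b - left < d_min or right - b < d_min:
            return False
        self.boundaries.insert(idx, b)
        self.inventories[idx] = self.inventories[idx].split_copy()
        self.inventories.insert(idx, self.inventories[idx].split_copy())
        return True


def default_confederate_mapping(
    n_regions: int = 4, pool: Optional[LabelPool] = None
) -> Tuple[Tuple[float, float, str], ...]:
    """Evenly tile [0, 1) with rare labels, 'sumo' on the first region.

    This is the confederate playbook of the robustness design: promote
    infrequent labels (those essentially never invented spontaneously) over
    the whole continuum.
    """
    pool = pool or LabelPool.default()
    rare = ["sumo"] + [
        lab
        for lab in pool.labels[3000:3000 + n_regions]
        if lab != "sumo"
    ][: n_regions - 1]
    edges = np.linspace(0.0, 1.0, n_regions + 1)
    return tuple(
        (float(lo), float(hi), lab)
        for lo, hi, lab in zip(edges[:-1], edges[1:], rare)
    )


@dataclass(frozen=True)
class InteractionRecord:
    trial_id: str
    round: int
    speaker_id: int
    hearer_id: int
    stimuli: Tuple[int, int, int]
    topic: int
    label: str
    guess: int
    success: bool
    speaker_was_exposed: bool
    speaker_is_confederate: bool
    hearer_is_confederate: bool

    def __post_init__(self) -> None:
        if self.topic not in self.stimuli or self.guess not in self.stimuli:
            raise ValueError("topic and guess must be scene stimuli")
        if self.success != (self.guess == self.topic):
            raise ValueError("success flag inconsistent with guess/topic")


@dataclass
class TrialLog:
    """Ordered interaction records for one population: N/2 records per round."""

    params: GameParams
    records: List[InteractionRecord]
    trial_id: str = "trial0"

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            (
                r.trial_id,
                r.round,
                r.speaker_id,
                r.hearer_id,
                r.stimuli[0],
                r.stimuli[1],
                r.stimuli[2],
                r.topic,
                r.label,
                r.guess,
                r.success,
                r.speaker_was_exposed,
                r.speaker_is_confederate,
                r.hearer_is_confederate,
            )
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _draw_private_partition(
    params: GameParams, pool: LabelPool, rng: np.random.Generator
) -> Tuple[List[float], List[str]]:
    k = params.private_categories
    while True:
        cuts = np.sort(rng.uniform(0.0, 1.0, size=k - 1))
        gaps = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
        if k == 1 or gaps.min() >= params.d_min:
            break
    labels = [pool.draw(rng) for _ in range(k)]
    return [float(c) for c in cuts], labels


def init_population(
    params: GameParams,
    rng: np.random.Generator,
    pool: Optional[LabelPool] = None,
) -> List[AgentState]:
    """Create the agents.

    Naive agents start with one perceptual category spanning [0, 1), an empty
    inventory, and a freshly drawn private naming function (uniform random
    region boundaries, Zipf-drawn labels).  The first ``n_confederates`` ids
    are confederates initialised from the confederate mapping.
    """
    pool = pool or LabelPool.default(params.pool_size, params.zipf_b)
    n_conf = params.n_confederates
    agents = []
    for i in range(params.n_agents):
        if i < n_conf:
            agents.append(AgentState(i, True, params.confederate_mapping))
        else:
            cuts, labels = _draw_private_partition(params, pool, rng)
            agents.append(
                AgentState(i, private_boundaries=cuts, private_labels=labels)
            )
    return agents


def discriminate(
    agent: AgentState, scene: Scene, spec: ContinuumSpec, d_min: float
) -> int:
    """Refine the agent's partition until the topic is alone in its category.

    New boundaries go at midpoints between the topic and each distractor that
    shares its category; children inherit the parent inventory.  A split that
    would create a category narrower than ``d_min`` is skipped (discrimination
    failure: the round proceeds with the unrefined category).  Returns the
    topic's category index.
    """
    if agent.is_confederate:
        return agent.category_of(spec.to_position(scene.topic))
    xt = spec.to_position(scene.topic)
    for s in scene.stimuli:
        if s == scene.topic:
            continue
        xs = spec.to_position(s)
        if agent.category_of(xs) == agent.category_of(xt):
            agent.insert_boundary((xt + xs) / 2.0, d_min)
    return agent.category_of(xt)


def _produce(
    agent: AgentState, category: int, pool: LabelPool, rng: np.random.Generator
) -> str:
    """Label choice for a category: the convention (last success), else the
    most recent coinage, else the agent's private label for the region
    (a one-off Zipf draw if the agent has no private naming function)."""
    inv = agent.inventories[category]
    if inv.last_success is not None and inv.last_success in inv.labels:
        return inv.last_success
    if inv.labels:
        return inv.labels[-1]
    lo = agent.boundaries[category - 1] if category > 0 else 0.0
    hi = agent.boundaries[category] if category < len(agent.boundaries) else 1.0
    label = agent.private_label((lo + hi) / 2.0)
    if label is None:
        label = pool.draw(rng)
    inv.labels.append(label)
    return label


def speak(
    agent: AgentState,
    category: int,
    pool: LabelPool,
    rng: np.random.Generator,
) -> str:
    """Produce a label for a category.

    Preference order: the category's most recently successful label, then its
    most recently coined label, then the agent's private label for the
    category's region (added to the inventory).  The label joins the agent's
    exposure set.
    """
    label = _produce(agent, category, pool, rng)
    agent.exposure_set.add(label)
    return label


def _interpret(
    agent: AgentState,
    scene: Scene,
    label: str,
    spec: ContinuumSpec,
    d_min: float,
    rng: np.random.Generator,
) -> Tuple[int, bool]:
    """Guess a stimulus for a label; also report whether the guess was
    *informed* (the label matched at least one candidate category) rather
    than a blind uniform pick."""
    if agent.is_confederate:
        candidates = [
            s
            for s in scene.stimuli
            if agent.mapped_label(spec.to_position(s)) == label
        ]
    else:
        # separate every pair of co-categorised stimuli at their midpoint
        for i, a in enumerate(scene.stimuli):
            for b in scene.stimuli[i + 1:]:
                xa, xb = spec.to_position(a), spec.to_position(b)
                if agent.category_of(xa) == agent.category_of(xb):
                    agent.insert_boundary((xa + xb) / 2.0, d_min)
        candidates = []
        for s in scene.stimuli:
            x = spec.to_position(s)
            if (
                agent.inventories[agent.category_of(x)].knows(label)
                or agent.private_label(x) == label
            ):
                candidates.append(s)
    if candidates:
        return int(candidates[int(rng.integers(len(candidates)))]), True
    return int(scene.stimuli[int(rng.integers(len(scene.stimuli)))]), False


def hear(
    agent: AgentState,
    scene: Scene,
    label: str,
    spec: ContinuumSpec,
    d_min: float,
    rng: np.random.Generator,
) -> int:
    """Interpret a label: guess which scene stimulus it names.

    A learning hearer first discriminates the scene (each stimulus into its
    own category, d_min permitting); candidate stimuli are those whose
    category knows the label (production inventory, heard memory, or the
    private naming function); the guess is uniform over candidates, or
    uniform over the whole scene when the label is unknown.
    """
    guess, _ = _interpret(agent, scene, label, spec, d_min, rng)
    return guess


def update_pair(
    speaker: AgentState,
    hearer: AgentState,
    scene: Scene,
    label: str,
    success: bool,
    spec: ContinuumSpec,
    informed: bool = True,
) -> None:
    """Apply the post-round learning rule.

    An *informed* success (the hearer recognised the label) is real
    coordination: both agents mark the label as the topic category's last
    success and delete all competing production labels.  A lucky success
    (blind guess that happened to land) locks only the speaker; for the
    hearer it is mere exposure, filed — like a failure — in the topic
    category's guessing memory (the payoff feedback reveals the topic either
    way).  Confederate state never changes.
    """
    xt = spec.to_position(scene.topic)
    if success:
        updaters = (speaker, hearer) if informed else (speaker,)
        for agent in updaters:
            if agent.is_confederate:
                continue
            inv = agent.inventories[agent.category_of(xt)]
            inv.labels = [label]
            inv.last_success = label
            inv.heard.discard(label)
        if not informed and not hearer.is_confederate:
            inv = hearer.inventories[hearer.category_of(xt)]
            if label not in inv.labels:
                inv.heard.add(label)
    else:
        if not hearer.is_confederate:
            inv = hearer.inventories[hearer.category_of(xt)]
            if label not in inv.labels:
                inv.heard.add(label)


def _make_pairs(
    params: GameParams, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    if params.pairing_mode == "fixed_partner":
        return [(0, 1)]
    order = rng.permutation(params.n_agents)
    return [
        (int(order[i]), int(order[i + 1])) for i in range(0, params.n_agents, 2)
    ]


def run_trial(
    params: GameParams,
    spec: Optional[ContinuumSpec] = None,
    trial_id: str = "trial0",
) -> TrialLog:
    """Simulate one full trial: ``rounds`` rounds of N/2 pairwise interactions.

    Every agent appears in exactly one record per round; pairings are uniform
    random (fixed partner for dyads); speaker/hearer roles are assigned
    uniformly within each pair.  Identical params and seed give identical logs.
    """
    spec = spec or ContinuumSpec()
    if spec.min_separation / spec.n_slices < params.d_min:
        raise ValueError(
            "scene separation below d_min: stimuli could be indiscriminable"
        )
    rng = np.random.default_rng(params.seed)
    pool = LabelPool.default(params.pool_size, params.zipf_b)
    agents = init_population(params, rng, pool)
    records: List[InteractionRecord] = []
    for rnd in range(1, params.rounds + 1):
        for a, b in _make_pairs(params, rng):
            if rng.integers(2):
                a, b = b, a
            speaker, hearer = agents[a], agents[b]
            shown = speaker.seen_slices | hearer.seen_slices
            scene = sample_scene(spec, shown, rng)
            speaker.seen_slices.update(scene.stimuli)
            hearer.seen_slices.update(scene.stimuli)

            if speaker.is_confederate:
                label = speaker.mapped_label(spec.to_position(scene.topic))
            else:
                category = discriminate(speaker, scene, spec, params.d_min)
                label = _produce(speaker, category, pool, rng)
            was_exposed = label in speaker.exposure_set
            speaker.exposure_set.add(label)

            if params.ablate_hearer_learning and not hearer.is_confederate:
                guess = int(scene.stimuli[int(rng.integers(len(scene.stimuli)))])
                informed = False
            else:
                guess, informed = _interpret(
                    hearer, scene, label, spec, params.d_min, rng
                )
            hearer.exposure_set.add(label)
            success = guess == scene.topic
            if not (params.ablate_hearer_learning and not hearer.is_confederate):
                update_pair(speaker, hearer, scene, label, success, spec, informed)
            elif success and not speaker.is_confederate:
                inv = speaker.inventories[speaker.category_of(spec.to_position(scene.topic))]
                inv.labels = [label]
                inv.last_success = label

            records.append(
                InteractionRecord(
                    trial_id=trial_id,
                    round=rnd,
                    speaker_id=speaker.agent_id,
                    hearer_id=hearer.agent_id,
                    stimuli=tuple(scene.stimuli),
                    topic=scene.topic,
                    label=label,
                    guess=guess,
                    success=success,
                    speaker_was_exposed=was_exposed,
                    speaker_is_confederate=speaker.is_confederate,
                    hearer_is_confederate=hearer.is_confederate,
                )
            )
    return TrialLog(params=params, records=records, trial_id=trial_id)


def run_ensemble(
    params: GameParams,
    n_trials: int,
    base_seed: int,
    spec: Optional[ContinuumSpec] = None,
) -> List[TrialLog]:
    """Run independent trials with per-trial seeds derived from ``base_seed``."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    seeds = np.random.SeedSequence(base_seed).spawn(n_trials)
    logs = []
    for i, ss in enumerate(seeds):
        trial_seed = int(ss.generate_state(1)[0] % (2**31))
        p = replace(params, seed=trial_seed)
        logs.append(run_trial(p, spec, trial_id=f"trial{i}"))
    return logs
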