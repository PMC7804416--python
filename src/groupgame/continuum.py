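"""Stimulus continuum and scene sampling.

The experiment presents shapes drawn from a one-dimensional perceptual
continuum divided into discrete slices (1500 in the original design).  Each
round a *scene* of three slices is shown, subject to two constraints: all
pairwise slice distances are at least ``min_separation`` (75 slices), and no
subject ever sees the same slice twice.  Slices are 0-based integers; when the
game dynamics need real-valued positions the continuum is normalised to
[0, 1) via ``x = slice / n_slices``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Set

import numpy as np

__all__ = [
    "ContinuumSpec",
    "Scene",
    "InfeasibleSpecError",
    "SceneExhaustionError",
    "sample_scene",
    "coverage_histogram",
]


class InfeasibleSpecError(ValueError):
    """The spec admits no valid scene at all."""


class SceneExhaustionError(RuntimeError):
    """No valid novel scene remains for this subject."""


@dataclass(frozen=True)
class ContinuumSpec:
    """Discrete stimulus continuum with scene constraints.

    Parameters
    ----------
    n_slices:
        Number of discrete stimuli along the continuum.
    min_separation:
        Minimum pairwise slice distance between stimuli in a scene.
    scene_size:
        Number of stimuli displayed per scene.
    """

    n_slices: int = 1500
    min_separation: int = 75
    scene_size: int = 3

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.min_separation < 1 or self.scene_size < 1:
            raise ValueError("all ContinuumSpec fields must be positive")
        if self.n_slices < self.scene_size:
            raise ValueError("n_slices must be at least scene_size")

    @property
    def feasible(self) -> bool:
        # scene_size stimuli pairwise >= min_separation apart need a span of
        # (scene_size - 1) * min_separation, which must fit inside the continuum
        return (self.scene_size - 1) * self.min_separation < self.n_slices

    def to_position(self, slice_index: int) -> float:
        """Normalised continuum position in [0, 1)."""
        return slice_index / self.n_slices


@dataclass(frozen=True)
class Scene:
    """Three (generally ``scene_size``) distinct slices plus a highlighted topic."""

    stimuli: tuple
    topic_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.topic_index < len(self.stimuli):
            raise ValueError("topic_index out of range")
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ValueError("scene stimuli must be distinct")

    @property
    def topic(self) -> int:
        return self.stimuli[self.topic_index]


def _separated(stimuli: Sequence[int], min_separation: int) -> bool:
    s = sorted(stimuli)
    return all(b - a >= min_separation for a, b in zip(s, s[1:]))


def _valid_scene_exists(spec: ContinuumSpec, shown: Set[int]) -> bool:
    """Greedy existence check on the sorted available slices.

    On a line, if any valid scene exists then the greedy scene (repeatedly
    take the smallest available slice at least min_separation beyond the
    previous pick) also exists, so greedy success is necessary and sufficient.
    """
    available = sorted(set(range(spec.n_slices)) - shown)
    picked = 0
    floor = -spec.min_separation
    for s in available:
        if s - floor >= spec.min_separation or picked == 0:
            picked += 1
            floor = s
            if picked == spec.scene_size:
                return True
    return False


def sample_scene(
    spec: ContinuumSpec,
    shown: Set[int],
    rng: np.random.Generator,
    max_rejects: int = 20_000,
) -> Scene:
    """Sample a scene uniformly (by rejection) under separation and novelty.

    Raises
    ------
    InfeasibleSpecError
        When no scene satisfies the separation constraint for *any* history.
    SceneExhaustionError
        When the subject's history leaves no valid novel scene.
    """
    if not spec.feasible:
        raise InfeasibleSpecError(
            f"no {spec.scene_size}-stimulus scene with pairwise separation "
            f">= {spec.min_separation} fits in {spec.n_slices} slices"
        )
    for _ in range(max_rejects):
        stimuli = rng.choice(spec.n_slices, size=spec.scene_size, replace=False)
        if any(int(s) in shown for s in stimuli):
            continue
        if _separated(stimuli, spec.min_separation):
            topic_index = int(rng.integers(spec.scene_size))
            return Scene(tuple(int(s) for s in stimuli), topic_index)
    # Rejection cap hit: decide between bad luck and genuine exhaustion.
    if not _valid_scene_exists(spec, shown):
        raise SceneExhaustionError(
            "no valid novel scene remains for this subject"
        )
    raise SceneExhaustionError(
        f"rejection sampling failed after {max_rejects} attempts although a "
        "valid scene exists; available slices are nearly exhausted"
    )


def coverage_histogram(
    scenes: Iterable[Scene], n_bins: int, n_slices: int = 1500
) -> np.ndarray:
    """Bin all displayed stimuli into equal-width bins over the continuum.

    Diagnostic for uniform coverage of the continuum: counts sum to
    ``scene_size * len(scenes)``.  An empty scene list yields all zeros.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    slices = [s for scene in scenes for s in scene.stimuli]
    counts, _ = np.histogram(slices, bins=n_bins, range=(0, n_slices))
    return counts
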