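"""Analysis pipeline: per-label statistics, emergent-category extraction, and
convergence metrics.

The pipeline mirrors how the experimental data are analysed:

1. per-label statistics — how many individuals introduced a label without
   prior exposure in the task (its *initial frequency*), how many produced it
   after exposure (*adopters*), and how many successful coordination events it
   carried;
2. emergent-category extraction — DBSCAN over the per-label
   (successes, cumulative adopters) feature plane, standardised per trial,
   with MinPts = 3 and the neighbourhood radius read off the knee of the
   sorted k-distance curve; the emergent vocabulary is the cluster with the
   highest feature values, and each emergent label is mapped to the continuum
   region(s) it successfully named;
3. convergence metrics — pairwise Jaccard similarity of emergent vocabularies
   across independent trials, per-subject label diversity, shared-label
   fractions, common/rare label classification (Tukey upper fence on initial
   frequency), critical-mass rates, and Zipf rank-frequency fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import DBSCAN as _SKDBSCAN
from sklearn.neighbors import NearestNeighbors

from .critical_mass import critical_mass_threshold
from .simulate import TrialLog

__all__ = [
    "LabelStats",
    "CategoryEntry",
    "CategorySystem",
    "ConvergenceReport",
    "label_statistics",
    "choose_eps",
    "dbscan",
    "extract_category_system",
    "jaccard_vocabulary",
    "convergence_report",
    "diversity",
    "shared_label_fraction",
    "classify_common_rare",
    "critical_mass_rate",
    "adoption_frequency_correlation",
    "zipf_fit",
    "cumulative_successful_uses",
]


# ---------------------------------------------------------------------------
# per-label statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelStats:
    """Counts for one label within one trial."""

    label: str
    initial_frequency: int  # individuals producing it with no prior exposure
    adopters: int           # individuals producing it after exposure
    successes: int          # successful coordination records carrying it


def _as_frame(log) -> pd.DataFrame:
    if isinstance(log, TrialLog):
        return log.to_dataframe()
    return log


def label_statistics(
    log, exclude_confederate_speakers: bool = False
) -> pd.DataFrame:
    """Per-label statistics from a chronological scan of an interaction log.

    A subject is *exposed* to a label the first time it hears or produces it;
    a production without prior exposure counts towards the label's initial
    frequency, a production with prior exposure counts the subject as an
    adopter.  Both counts are over distinct individuals.

    Returns a DataFrame with columns
    ``label, initial_frequency, adopters, successes`` (one row per distinct
    label produced, in order of first production).  With
    ``exclude_confederate_speakers`` the tallies only credit productions by
    experimental (non-confederate) subjects, though exposure still accrues
    from confederate speech.
    """
    df = _as_frame(log)
    exposure: Dict[int, set] = {}
    introducers: Dict[str, set] = {}
    adopters: Dict[str, set] = {}
    successes: Dict[str, int] = {}
    order: List[str] = []
    for row in df.itertuples(index=False):
        label = row.label
        if label not in successes:
            order.append(label)
            successes[label] = 0
            introducers[label] = set()
            adopters[label] = set()
        sp_exp = exposure.setdefault(row.speaker_id, set())
        he_exp = exposure.setdefault(row.hearer_id, set())
        count_speaker = not (
            exclude_confederate_speakers and row.speaker_is_confederate
        )
        if count_speaker:
            if label in sp_exp:
                adopters[label].add(row.speaker_id)
            else:
                introducers[label].add(row.speaker_id)
            if row.success:
                successes[label] += 1
        sp_exp.add(label)
        he_exp.add(label)
    rows = [
        (
            lab,
            len(introducers[lab]),
            len(adopters[lab]),
            successes[lab],
        )
        for lab in order
        if len(introducers[lab]) + len(adopters[lab]) + successes[lab] > 0
        or not exclude_confederate_speakers
    ]
    return pd.DataFrame(
        rows, columns=["label", "initial_frequency", "adopters", "successes"]
    )


# ---------------------------------------------------------------------------
# DBSCAN extraction
# ---------------------------------------------------------------------------

def choose_eps(points: np.ndarray, k: int) -> float:
    """Neighbourhood radius from the knee of the sorted k-distance curve.

    The k-distances (distance of each point to its k-th nearest neighbour)
    are sorted ascending; the knee is the point of maximum perpendicular
    distance from the chord joining the curve's endpoints.  When the curve is
    near-linear (no pronounced knee) the 90th-percentile k-distance is used
    instead.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k = {k} distances")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    kdist = np.sort(dist[:, k])
    if kdist[-1] == 0.0:
        warnings.warn("all k-distances are zero (degenerate input)")
        return 0.0
    x = np.arange(n, dtype=float)
    p0 = np.array([x[0], kdist[0]])
    p1 = np.array([x[-1], kdist[-1]])
    chord = p1 - p0
    chord_len = np.hypot(*chord)
    rel = np.stack([x - p0[0], kdist - p0[1]], axis=1)
    # perpendicular distance of each curve point from the chord
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / chord_len
    if perp.max() < 1e-3 * chord_len:
        return float(np.quantile(kdist, 0.9))
    return float(kdist[int(np.argmax(perp))])


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Density-based clustering with noise.

    Standard semantics: a core point has at least ``min_pts`` neighbours
    within ``eps`` (itself included); clusters are maximal density-connected
    sets; unassigned points are labelled -1 (noise).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) == 0:
        return np.array([], dtype=int)
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    if min_pts < 1:
        raise ValueError("min_pts must be at least 1")
    model = _SKDBSCAN(eps=max(eps, 1e-12), min_samples=min_pts)
    return model.fit_predict(points)


@dataclass(frozen=True)
class CategoryEntry:
    """One emergent label: its success density over continuum bins and the
    continuum region(s) it successfully named."""

    label: str
    density: np.ndarray            # per-bin successful-coordination counts
    support: Tuple[Tuple[int, int], ...]  # bin-index intervals with density > 0
    successes: int


@dataclass
class CategorySystem:
    """The emergent vocabulary of one trial.

    ``entries`` maps each emergent label to its continuum support and success
    density; ``region_winners`` assigns each continuum bin to the emergent
    label with the most successes there (ties to the higher total-success
    label), or None where no emergent label succeeded.
    """

    trial_id: str
    entries: Dict[str, CategoryEntry]
    n_bins: int
    n_slices: int

    @property
    def labels(self) -> FrozenSet[str]:
        return frozenset(self.entries)

    @property
    def region_winners(self) -> List[Optional[str]]:
        winners: List[Optional[str]] = []
        order = sorted(
            self.entries.values(), key=lambda e: e.successes, reverse=True
        )
        for b in range(self.n_bins):
            best, best_count = None, 0
            for e in order:  # ordered by total successes: ties go to the larger
                if e.density[b] > best_count:
                    best, best_count = e.label, e.density[b]
            winners.append(best)
        return winners


def _support_intervals(density: np.ndarray) -> Tuple[Tuple[int, int], ...]:
    nz = np.flatnonzero(density)
    if nz.size == 0:
        return ()
    intervals = []
    start = prev = int(nz[0])
    for b in nz[1:]:
        b = int(b)
        if b == prev + 1:
            prev = b
        else:
            intervals.append((start, prev))
            start = prev = b
    intervals.append((start, prev))
    return tuple(intervals)


def extract_category_system(
    log,
    min_pts: int = 3,
    n_bins: int = 50,
    n_slices: int = 1500,
    exclude_confederate_speakers: bool = False,
    fallback_m: int = 4,
) -> CategorySystem:
    """Extract the trial's emergent vocabulary by density clustering.

    Builds the per-label (successes, cumulative adopters) feature table,
    standardises both features (raw counts scale with population size, so
    clustering runs on z-scores per trial), chooses eps at the knee of the
    k-distance curve (k = MinPts) and runs DBSCAN with MinPts = 3.  The
    emergent vocabulary is the cluster with the highest mean standardised
    feature values (ties broken by total successes).  The selection is only
    meaningful when that cluster is a distinguished minority of high-value
    labels: when too few labels exist, when DBSCAN finds no cluster, when the
    best cluster holds a majority of all labels (the undifferentiated bulk),
    or when it fails to contain the top-ranked label, the extraction falls
    back to the top ``fallback_m`` labels by successes, with a warning.

    Each emergent label is then mapped to its continuum support: a histogram
    of topic slices over that label's successful records.
    """
    df = _as_frame(log)
    if len(df) == 0:
        raise ValueError("cannot extract categories from an empty log")
    trial_id = str(df["trial_id"].iloc[0])
    stats = label_statistics(df, exclude_confederate_speakers)
    if len(stats) == 0:
        raise ValueError("no label productions to cluster")

    X = stats[["successes", "adopters"]].to_numpy(dtype=float)
    selected: List[str]
    if len(stats) < min_pts + 1:
        warnings.warn(
            "too few distinct labels for density clustering; "
            f"falling back to top {fallback_m} by successes"
        )
        selected = list(
            stats.nlargest(fallback_m, "successes", keep="first")["label"]
        )
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        eps = choose_eps(Z, k=min_pts)
        assignment = dbscan(Z, eps, min_pts)
        clusters = sorted(set(assignment) - {-1})
        champion = int(np.argmax(Z.mean(axis=1)))
        selected = None
        if clusters:
            def score(c):
                mask = assignment == c
                return (
                    float(Z[mask].mean()),
                    float(X[mask, 0].sum()),  # tie-break: total raw successes
                )

            best = max(clusters, key=score)
            mask = assignment == best
            if mask.sum() <= len(stats) // 2 and mask[champion]:
                selected = list(stats["label"].to_numpy()[mask])
        if selected is None:
            warnings.warn(
                "DBSCAN found no distinguished high-value cluster; "
                f"falling back to top {fallback_m} by successes"
            )
            selected = list(
                stats.nlargest(fallback_m, "successes", keep="first")["label"]
            )

    n_emergent = len(selected)
    if not 3 <= n_emergent <= 5:
        warnings.warn(
            f"emergent vocabulary has {n_emergent} labels "
            "(3-5 expected in practice)"
        )

    if exclude_confederate_speakers:
        df = df[~df["speaker_is_confederate"]]
    ok = df[df["success"]]
    entries: Dict[str, CategoryEntry] = {}
    for lab in selected:
        topics = ok.loc[ok["label"] == lab, "topic"].to_numpy()
        density, _ = np.histogram(topics, bins=n_bins, range=(0, n_slices))
        entries[lab] = CategoryEntry(
            label=lab,
            density=density,
            support=_support_intervals(density),
            successes=int(density.sum()),
        )
    return CategorySystem(
        trial_id=trial_id, entries=entries, n_bins=n_bins, n_slices=n_slices
    )


# ---------------------------------------------------------------------------
# convergence metrics
# ---------------------------------------------------------------------------

def _label_set(v) -> FrozenSet[str]:
    if isinstance(v, CategorySystem):
        return v.labels
    return frozenset(v)


def jaccard_vocabulary(a, b) -> float:
    """Intersection-over-union of two vocabularies (CategorySystems or label
    sets); 1.0 by convention when both are empty (with a warning)."""
    sa, sb = _label_set(a), _label_set(b)
    union = sa | sb
    if not union:
        warnings.warn("Jaccard of two empty vocabularies defined as 1.0")
        return 1.0
    return len(sa & sb) / len(union)


def diversity(log) -> float:
    """Category diversity: the average number of unique labels each subject
    encounters (hears or produces) during the trial."""
    df = _as_frame(log)
    encountered: Dict[int, set] = {}
    for row in df.itertuples(index=False):
        encountered.setdefault(row.speaker_id, set()).add(row.label)
        encountered.setdefault(row.hearer_id, set()).add(row.label)
    if not encountered:
        return 0.0
    return float(np.mean([len(s) for s in encountered.values()]))


@dataclass
class ConvergenceReport:
    vocabularies: List[FrozenSet[str]]
    diversity: List[float]
    jaccard_matrix: np.ndarray
    mean_jaccard: float


def convergence_report(
    ensemble: Sequence, exclude_confederate_speakers: bool = False, **extract_kw
) -> ConvergenceReport:
    """Between-trial convergence of an ensemble: per-trial diversity, the full
    pairwise Jaccard matrix of extracted vocabularies, and its mean over all
    unordered trial pairs."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 trials for pairwise comparison")
    systems = [
        extract_category_system(
            log,
            exclude_confederate_speakers=exclude_confederate_speakers,
            **extract_kw,
        )
        for log in ensemble
    ]
    vocabs = [s.labels for s in systems]
    div = [diversity(log) for log in ensemble]
    n = len(vocabs)
    mat = np.ones((n, n))
    pair_vals = []
    for i in range(n):
        for j in range(i + 1, n):
            v = jaccard_vocabulary(vocabs[i], vocabs[j])
            mat[i, j] = mat[j, i] = v
            pair_vals.append(v)
    return ConvergenceReport(
        vocabularies=vocabs,
        diversity=div,
        jaccard_matrix=mat,
        mean_jaccard=float(np.mean(pair_vals)),
    )


def shared_label_fraction(ensemble: Sequence, **extract_kw) -> float:
    """Fraction of distinct emergent labels (union over the ensemble's
    extracted vocabularies) that appear in at least two trials."""
    if len(ensemble) < 2:
        raise ValueError("need at least 2 trials")
    vocabs = [
        v if isinstance(v, (set, frozenset)) else
        extract_category_system(v, **extract_kw).labels
        for v in ensemble
    ]
    counts: Dict[str, int] = {}
    for v in vocabs:
        for lab in v:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return 0.0
    shared = sum(1 for c in counts.values() if c >= 2)
    return shared / len(counts)


def classify_common_rare(stats_frames: Sequence[pd.DataFrame]) -> Dict[str, str]:
    """Classify labels as common or rare from their pooled initial frequency.

    Initial frequencies are summed per label across trials; common labels are
    the high outliers above the Tukey upper fence (Q3 + 1.5 IQR); everything
    else is rare.
    """
    pooled: Dict[str, int] = {}
    for frame in stats_frames:
        for row in frame.itertuples(index=False):
            pooled[row.label] = pooled.get(row.label, 0) + row.initial_frequency
    if len(pooled) < 4:
        raise ValueError("need at least 4 labels for quartile estimation")
    freqs = np.array(list(pooled.values()), dtype=float)
    q1, q3 = np.percentile(freqs, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    if freqs.max() == freqs.min():
        warnings.warn("degenerate all-equal frequencies; classifying all rare")
        return {lab: "rare" for lab in pooled}
    return {
        lab: ("common" if f > fence else "rare") for lab, f in pooled.items()
    }


def critical_mass_rate(
    ensemble: Sequence,
    classes: Mapping[str, str],
    label_class: str,
    theta: float = 0.25,
) -> float:
    """Proportion of trials in which any label of the given class reached
    critical mass (per-trial initial frequency >= ceil(theta * N))."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    hits = 0
    for log in ensemble:
        n_agents = (
            log.params.n_agents
            if isinstance(log, TrialLog)
            else int(
                pd.concat(
                    [
                        _as_frame(log)["speaker_id"],
                        _as_frame(log)["hearer_id"],
                    ]
                ).nunique()
            )
        )
        need = critical_mass_threshold(n_agents, theta) if theta > 0 else 0
        stats = label_statistics(log)
        reached = stats[
            (stats["initial_frequency"] >= need)
            & (stats["label"].map(classes.get) == label_class)
        ]
        if len(reached) > 0:
            hits += 1
    return hits / len(ensemble)


def adoption_frequency_correlation(log, n_agents: Optional[int] = None) -> float:
    """Pearson correlation between each label's initial frequency and the
    proportion of subjects who adopted it (produced it after exposure)."""
    df = _as_frame(log)
    if n_agents is None:
        n_agents = (
            log.params.n_agents
            if isinstance(log, TrialLog)
            else int(pd.concat([df["speaker_id"], df["hearer_id"]]).nunique())
        )
    stats = label_statistics(df)
    if len(stats) < 3:
        raise ValueError("need at least 3 labels")
    x = stats["initial_frequency"].to_numpy(dtype=float)
    y = stats["adopters"].to_numpy(dtype=float) / n_agents
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def zipf_fit(frequencies: Sequence[float]) -> Tuple[float, float]:
    """Least-squares Zipf fit on log-log rank-frequency coordinates.

    Frequencies are ranked in descending order; the slope of
    log(frequency) on log(rank) is estimated by OLS and the exponent is
    reported as the negated slope.  Returns ``(exponent, intercept)``.
    """
    f = np.asarray(sorted(frequencies, reverse=True), dtype=float)
    if len(f) < 3:
        raise ValueError("need at least 3 frequencies")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if f[0] == f[-1]:
        raise ValueError("need at least two distinct frequencies")
    ranks = np.arange(1, len(f) + 1, dtype=float)
    slope, intercept = np.polyfit(np.log(ranks), np.log(f), 1)
    return float(-slope), float(intercept)


def cumulative_successful_uses(
    log, label: str, experimental_only: bool = True
) -> np.ndarray:
    """Per-round cumulative count of successful uses of a label.

    With ``experimental_only`` (the confederate-trial convention), only
    productions by non-confederate speakers count, which also excludes all
    confederate-confederate interactions.
    """
    df = _as_frame(log)
    rounds = int(df["round"].max())
    mask = (df["label"] == label) & df["success"]
    if experimental_only:
        mask &= ~df["speaker_is_confederate"]
    per_round = (
        df.loc[mask, "round"].value_counts().reindex(
            range(1, rounds + 1), fill_value=0
        ).sort_index()
    )
    return per_round.cumsum().to_numpy()
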