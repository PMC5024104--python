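"""Two-stage winner-take-all clustering of turn conformations in dihedral space.

The procedure that discovered the four extended turn types.  It is a
self-organizing map without neighbourhood diffusion, operating on vectors of
four dihedral angles with all differences taken modulo 360 deg:

Stage one (unsupervised): the codebook is initialized with k quads drawn
from the data; for each presentation a random quad is drawn and the
codebook vector with minimal RMSDA (root mean square deviation on angular
values) is pulled toward it by the learning coefficient alpha.  One cycle
presents as many samples as there are data points (T); alpha decays as
alpha0 / cycle with alpha0 = 0.35, for 20 cycles.

Stage two (rule-constrained refinement): identical, restarting the alpha
schedule, except that the winning vector is only updated when the sample
satisfies the turn tolerance rule against it (at least three angles within
30 deg, the remaining one within 45 deg); otherwise the presentation is
skipped.  This anchors each codebook vector on a recurrent conformation and
stops diffuse, unclassifiable turns from dragging it.

Cluster "observed centers" are circular means of the member quads that
satisfy the tolerance rule against their winning vector; these are the
values reported and compared across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._angles import circular_mean, wrap_angle

__all__ = [
    "ClusteringConfig",
    "Codebook",
    "ClusterSummary",
    "rmsda",
    "update_winner",
    "train_stage_one",
    "train_stage_two",
    "train_two_stage",
    "rank_clusters",
    "match_codebooks",
]


def rmsda(v1, v2) -> float:
    """Root mean square deviation on angular values, degrees in [0, 180].

    Differences per angle are wrapped to the shortest arc; the mean square
    is taken over the four angles.
    """
    d = wrap_angle(np.asarray(v2, float) - np.asarray(v1, float))
    return float(np.sqrt(np.mean(d * d)))


def update_winner(winner, sample, alpha: float) -> np.ndarray:
    """Pull the winning vector toward the sample along the shortest arc.

    w' = wrap(w + alpha * delta) per angle, delta being the signed wrapped
    difference from winner to sample.
    """
    w = np.asarray(winner, float)
    delta = wrap_angle(np.asarray(sample, float) - w)
    return wrap_angle(w + alpha * delta)


@dataclass
class ClusteringConfig:
    """Training parameters; defaults are the published protocol."""

    k: int = 10
    alpha0: float = 0.35
    cycles_stage1: int = 20
    cycles_stage2: int = 20
    seed: int = 0
    tol_main: float = 30.0
    tol_loose: float = 45.0

    def __post_init__(self):
        if not (0.0 < self.alpha0 <= 1.0):
            raise ValueError("alpha0 must be in (0, 1]")
        if self.k < 1 or self.cycles_stage1 < 1 or self.cycles_stage2 < 1:
            raise ValueError("k and cycle counts must be >= 1")


@dataclass
class Codebook:
    """k cluster vectors of four wrapped angles each, plus provenance."""

    vectors: np.ndarray  # (k, 4)
    seed: int
    config: Optional[ClusteringConfig] = None
    stage: int = 0

    def __post_init__(self):
        self.vectors = wrap_angle(np.atleast_2d(np.asarray(self.vectors, float)))

    @property
    def k(self) -> int:
        return self.vectors.shape[0]


def _rule_ok(dev: np.ndarray, tol_main: float, tol_loose: float) -> bool:
    return bool((dev <= tol_main).sum() >= 3 and dev.max() <= tol_loose)


def _quads_array(dataset) -> np.ndarray:
    quads = getattr(dataset, "quads", dataset)
    arr = np.asarray(quads, float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("dataset must be a (T, 4) array of dihedral quads")
    return wrap_angle(arr)


def _train(data: np.ndarray, codebook: np.ndarray, cycles: int,
           config: ClusteringConfig, rng: np.random.Generator,
           rule_gated: bool, audit: Optional[list]) -> np.ndarray:
    T = len(data)
    cb = codebook.copy()
    for cycle in range(1, cycles + 1):
        alpha = config.alpha0 / cycle
        picks = rng.integers(0, T, size=T)
        for t in picks:
            sample = data[t]
            delta = wrap_angle(sample - cb)
            # ties in the winner search resolve to the lowest index (argmin)
            w = int(np.argmin((delta * delta).sum(axis=1)))
            if rule_gated:
                dev = np.abs(delta[w])
                accepted = _rule_ok(dev, config.tol_main, config.tol_loose)
                if audit is not None:
                    audit.append((sample.copy(), cb[w].copy(), accepted))
                if not accepted:
                    continue
            cb[w] = wrap_angle(cb[w] + alpha * delta[w])
    return cb


def train_stage_one(dataset, config: ClusteringConfig,
                    rng: Optional[np.random.Generator] = None) -> Codebook:
    """Unsupervised stage: init from k distinct data quads, RMSDA winner."""
    data = _quads_array(dataset)
    if len(data) < config.k:
        raise ValueError(f"need at least k={config.k} quads, got {len(data)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    init = data[rng.choice(len(data), size=config.k, replace=False)].copy()
    vectors = _train(data, init, config.cycles_stage1, config, rng,
                     rule_gated=False, audit=None)
    return Codebook(vectors, seed=config.seed, config=config, stage=1)


def train_stage_two(codebook: Codebook, dataset, config: ClusteringConfig,
                    rng: Optional[np.random.Generator] = None,
                    audit: Optional[list] = None) -> Codebook:
    """Rule-gated refinement stage; the alpha schedule restarts at alpha0."""
    data = _quads_array(dataset)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vectors = _train(data, codebook.vectors, config.cycles_stage2, config, rng,
                     rule_gated=True, audit=audit)
    return Codebook(vectors, seed=codebook.seed, config=config, stage=2)


def train_two_stage(dataset, config: ClusteringConfig) -> Codebook:
    """Both stages with a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    cb1 = train_stage_one(dataset, config, rng)
    return train_stage_two(cb1, dataset, config, rng)


@dataclass
class ClusterSummary:
    index: int
    count: int
    codebook_vector: np.ndarray
    observed_center: np.ndarray  # circular mean of rule-satisfying members
    rule_member_count: int


def assign_to_clusters(dataset, codebook: Codebook) -> np.ndarray:
    """Minimal-RMSDA cluster index per quad."""
    data = _quads_array(dataset)
    d = wrap_angle(data[:, None, :] - codebook.vectors[None, :, :])
    return (d * d).sum(axis=2).argmin(axis=1)


def rank_clusters(codebook: Codebook, dataset,
                  tol_main: float = 30.0,
                  tol_loose: float = 45.0) -> list[ClusterSummary]:
    """Clusters sorted by descending member count (counts sum to T).

    The observed center of a cluster is the per-angle circular mean of the
    members that satisfy the tolerance rule against its codebook vector
    (the conformations the cluster actually stands for); a cluster with no
    such members reports its codebook vector.
    """
    data = _quads_array(dataset)
    labels = assign_to_clusters(data, codebook)
    counts = np.bincount(labels, minlength=codebook.k)
    summaries = []
    for j in range(codebook.k):
        members = data[labels == j]
        center = codebook.vectors[j].copy()
        n_rule = 0
        if len(members):
            dev = np.abs(wrap_angle(members - codebook.vectors[j]))
            ok = ((dev <= tol_main).sum(axis=1) >= 3) & (dev.max(axis=1) <= tol_loose)
            n_rule = int(ok.sum())
            if n_rule:
                center = circular_mean(members[ok], axis=0)
        summaries.append(ClusterSummary(
            index=j, count=int(counts[j]),
            codebook_vector=codebook.vectors[j].copy(),
            observed_center=center, rule_member_count=n_rule,
        ))
    summaries.sort(key=lambda s: (-s.count, s.index))
    return summaries


def match_codebooks(ranked1: Sequence[ClusterSummary],
                    ranked2: Sequence[ClusterSummary],
                    top_n: int = 4):
    """Match the top_n largest clusters of two runs; report the deviation.

    Matching is the optimal one-to-one assignment minimizing total RMSDA
    between observed centers.  Returns (pairs, max_deviation) where pairs is
    a list of (summary1, summary2) and max_deviation the maximum wrapped
    absolute per-angle difference over all matched centers, in degrees.
    """
    for ranked in (ranked1, ranked2):
        nonempty = sum(1 for s in ranked if s.count > 0)
        if top_n > nonempty:
            raise ValueError(
                f"top_n={top_n} exceeds the {nonempty} nonempty clusters")
    a = list(ranked1)[:top_n]
    b = list(ranked2)[:top_n]
    cost = np.array([[rmsda(s1.observed_center, s2.observed_center)
                      for s2 in b] for s1 in a])
    rows, cols = linear_sum_assignment(cost)
    pairs = [(a[i], b[j]) for i, j in zip(rows, cols)]
    max_dev = max(
        float(np.abs(wrap_angle(s1.observed_center - s2.observed_center)).max())
        for s1, s2 in pairs)
    return pairs, max_dev
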