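"""Phase 3 - stepwise threshold clustering.

Reads are grouped by a quasi-Dirichlet ("Chinese restaurant") insertion
process: each focal read, drawn in random order, either joins the
existing cluster whose label sequence it most resembles - provided the
percent similarity reaches the round's threshold gamma - or opens a new
cluster.  Cluster labels track the current dominant (most frequent)
sequence after every insertion, and reads sharing a sequence always
co-cluster.  Because the insertion order is the only stochastic
element, each round is replicated (100x by default) and every sequence
is assigned to its modal cluster label.

Rounds sweep gamma upward (e.g. 60 %..97 %).  After each round clusters
are classified:

    GOOD       size >= theta x library and dominant/subdominant > delta
    SMALL      dominance holds, size fails
    AMBIGUOUS  dominance fails - likely two alleles; re-clustered at the
               next, stricter gamma

GOOD and SMALL clusters are exempt from further rounds.  Ambiguous
clusters that survive the final round are split into two sub-clusters
proportional to their top two correct-length sequences.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _align
from .seqprep import SampleLibrary

logger = logging.getLogger(__name__)

AUTO = "auto"
_EPS = 1e-9


class ClusterStatus(str, Enum):
    GOOD = "good"
    SMALL = "small"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class STCParams:
    """Tunable thresholds for one stepwise-clustering run.

    theta is the minimum fraction of the sample library a cluster must
    hold to be good; delta the minimum dominant/subdominant read-count
    ratio to escape ambiguity; epsilon the number of *other* samples in
    which a sequence must label a good cluster to rescue a small
    cluster in phase 4.
    """

    theta: float = 1 / 22
    delta: float = 4.0
    gamma_start: float | str = AUTO
    gamma_step: float = 1.0
    gamma_end: float = 97.0
    replicates: int = 100
    epsilon: int = 3
    min_dropped_reads: int = 3
    expected_len: int = 213
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta < 1):
            raise ValueError("theta must be in (0, 1)")
        if self.delta <= 1:
            raise ValueError("delta must exceed 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.gamma_end > 100:
            raise ValueError("gamma_end cannot exceed 100")
        if self.gamma_start != AUTO and self.gamma_start > self.gamma_end:
            raise ValueError("gamma_start must not exceed gamma_end")
        if self.gamma_step <= 0:
            raise ValueError("gamma_step must be positive")


def recommended_theta(max_alleles: int = 12, safety: float = 2.0) -> float:
    """Starting size threshold: 1 / (maximum expected allele number x a
    safety factor), e.g. 1/24 for 6 diploid loci."""
    return 1.0 / (max_alleles * safety)


def recommended_delta(error_free_fraction: float = 0.82) -> float:
    """Starting dominance threshold: error-free reads over errored reads
    (0.82/0.18 = 4.55 for pyrosequencing)."""
    return error_free_fraction / (1.0 - error_free_fraction)


@dataclass
class Cluster:
    """A group of sequences with read counts, labelled by its dominant
    sequence."""

    members: dict[str, int]
    formed_at_gamma: float
    status: ClusterStatus | None = None
    dominant_seq: str = field(init=False)
    dominant_count: int = field(init=False)
    subdominant_seq: str | None = field(init=False)
    subdominant_count: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster has no members")
        ranked = sorted(self.members.items(), key=lambda kv: (-kv[1], kv[0]))
        self.dominant_seq, self.dominant_count = ranked[0]
        if len(ranked) > 1:
            self.subdominant_seq, self.subdominant_count = ranked[1]
        else:
            self.subdominant_seq, self.subdominant_count = None, 0

    @property
    def label(self) -> str:
        return self.dominant_seq

    @property
    def total_reads(self) -> int:
        return sum(self.members.values())

    @property
    def dominance_ratio(self) -> float:
        if self.subdominant_count == 0:
            return float("inf")
        return self.dominant_count / self.subdominant_count


@dataclass(frozen=True)
class RoundLog:
    gamma: float
    n_good: int  # cumulative
    n_small: int  # cumulative
    n_ambiguous: int  # carried into the next round
    reads_left: int
    sequences_left: int


@dataclass
class ClusterSet:
    """Final phase-3 output for one sample: every input read sits in
    exactly one good or small cluster."""

    sample_id: str
    good: list[Cluster]
    small: list[Cluster]
    logs: list[RoundLog]
    library_size: int

    def round_log_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gamma\tgood\tsmall\tambiguous\treads_left\tsequences_left\n")
            for log in self.logs:
                fh.write(
                    f"{log.gamma:g}\t{log.n_good}\t{log.n_small}\t"
                    f"{log.n_ambiguous}\t{log.reads_left}\t{log.sequences_left}\n"
                )

    def cluster_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "label\tstatus\ttotal_reads\tdominant_count\t"
                "subdominant_count\tformed_at_gamma\n"
            )
            for c in self.good + self.small:
                fh.write(
                    f"{c.label}\t{c.status.value}\t{c.total_reads}\t"
                    f"{c.dominant_count}\t{c.subdominant_count}\t"
                    f"{c.formed_at_gamma:g}\n"
                )


# ---------------------------------------------------------------------------
# similarity


def similarity(a: str, b: str) -> float:
    """Percent of shared base pairs under the fixed global alignment;
    symmetric, 100 iff the sequences are identical."""
    return _align.percent_similarity(a, b)


def gamma_start_auto(lib: SampleLibrary, gamma_end: float = 97.0) -> float:
    """Floor of the minimum pairwise similarity among the library's
    unique sequences (the recommended starting gamma), clamped to
    gamma_end."""
    seqs = sorted(lib.counts)
    if len(seqs) < 2:
        return gamma_end
    S = _align.similarity_matrix(seqs)
    lo = float(np.floor(S[np.triu_indices(len(seqs), k=1)].min()))
    return min(lo, gamma_end)


# ---------------------------------------------------------------------------
# one clustering replicate (unique-sequence level)
#
# Focal reads are realised at the unique-sequence level: sequences are
# drawn without replacement with probability proportional to their
# remaining read counts, which reproduces uniform read-level draws
# exactly because same-sequence reads auto-join their sequence's
# cluster.


def _weighted_order(active: np.ndarray, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    keys = rng.exponential(size=active.size) / counts[active]
    return active[np.argsort(keys, kind="stable")]


def _replicate_idx(
    active: np.ndarray,
    counts: np.ndarray,
    S: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Cluster the active sequence indices once; returns seq idx ->
    final cluster label idx.  Sequence indices double as lexicographic
    ranks (the index order is sorted)."""
    order = _weighted_order(active, counts, rng)
    labels: list[int] = []
    totals: list[int] = []
    dom_counts: list[int] = []
    members: list[list[int]] = []
    for s in order:
        c_n = counts[s]
        best = -1
        best_sim = -1.0
        for ci in range(len(labels)):
            sim = S[s, labels[ci]]
            if sim > best_sim + _EPS:
                best, best_sim = ci, sim
            elif sim > best_sim - _EPS and best >= 0:
                # tie: larger cluster read total, then lexicographically
                # smallest label
                if totals[ci] > totals[best] or (
                    totals[ci] == totals[best] and labels[ci] < labels[best]
                ):
                    best = ci
        if best >= 0 and best_sim >= gamma - _EPS:
            members[best].append(s)
            totals[best] += c_n
            if c_n > dom_counts[best] or (
                c_n == dom_counts[best] and s < labels[best]
            ):
                labels[best] = s
                dom_counts[best] = c_n
        else:
            labels.append(s)
            totals.append(c_n)
            dom_counts.append(c_n)
            members.append([s])
    out: dict[int, int] = {}
    for ci, mem in enumerate(members):
        for s in mem:
            out[s] = labels[ci]
    return out


def cluster_replicate(
    seqs: Mapping[str, int],
    gamma: float,
    rng: np.random.Generator,
    sim: np.ndarray | None = None,
    order_index: Sequence[str] | None = None,
) -> dict[str, str]:
    """Run one insertion-order replicate; returns sequence -> cluster
    label (a member sequence).  ``sim``/``order_index`` allow reusing a
    precomputed similarity matrix."""
    if any(n <= 0 for n in seqs.values()):
        raise ValueError("all read counts must be positive")
    if order_index is None:
        order_index = sorted(seqs)
        sim = None
    index = {s: i for i, s in enumerate(order_index)}
    if sim is None:
        sim = _align.similarity_matrix(list(order_index))
    counts = np.zeros(len(order_index), dtype=np.int64)
    for s, n in seqs.items():
        counts[index[s]] = n
    active = np.array(sorted(index[s] for s in seqs), dtype=np.int64)
    assign = _replicate_idx(active, counts, sim, gamma, rng)
    return {order_index[s]: order_index[lab] for s, lab in assign.items()}


def modal_clusters(
    seqs: Mapping[str, int],
    gamma: float,
    replicates: int,
    seed: int,
    sim: np.ndarray | None = None,
    order_index: Sequence[str] | None = None,
) -> list[Cluster]:
    """Replicate the clustering and group sequences by their modal
    cluster label.

    Labels are treated as opaque group keys: sequences sharing a modal
    label form one cluster, with no transitive merging.  Deterministic
    for a fixed seed.
    """
    if order_index is None:
        order_index = sorted(seqs)
        sim = _align.similarity_matrix(list(order_index))
    index = {s: i for i, s in enumerate(order_index)}
    counts = np.zeros(len(order_index), dtype=np.int64)
    for s, n in seqs.items():
        counts[index[s]] = n
    active = np.array(sorted(index[s] for s in seqs), dtype=np.int64)
    votes: dict[int, Counter] = {int(s): Counter() for s in active}
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        assign = _replicate_idx(active, counts, sim, gamma, rng)
        for s, lab in assign.items():
            votes[s][lab] += 1
    groups: dict[int, list[int]] = {}
    for s, ctr in votes.items():
        # modal label; ties resolve to the lexicographically smallest label
        top = max(ctr.values())
        lab = min(l for l, n in ctr.items() if n == top)
        groups.setdefault(lab, []).append(s)
    clusters = []
    for lab in sorted(groups):
        mem = {order_index[s]: int(counts[s]) for s in groups[lab]}
        clusters.append(Cluster(mem, formed_at_gamma=gamma))
    return clusters


# ---------------------------------------------------------------------------
# classification and splitting


def classify_cluster(
    c: Cluster, library_size: int, theta: float, delta: float
) -> ClusterStatus:
    """Apply the size (>= theta) and dominance (> delta) criteria;
    single-sequence clusters pass dominance with an infinite ratio."""
    if library_size < c.total_reads:
        raise ValueError("library_size smaller than cluster")
    dominance_ok = c.dominance_ratio > delta
    size_ok = c.total_reads / library_size >= theta - _EPS
    if dominance_ok and size_ok:
        return ClusterStatus.GOOD
    if dominance_ok:
        return ClusterStatus.SMALL
    return ClusterStatus.AMBIGUOUS


def split_ambiguous(
    c: Cluster,
    library_size: int,
    theta: float,
    expected_len: int,
) -> list[Cluster]:
    """Split a residual ambiguous cluster into two sub-clusters sized in
    proportion to its two most frequent correct-length sequences.

    Wrong-length top sequences are skipped (the next most frequent
    correct-length sequence becomes the subdominant).  With fewer than
    two correct-length members the cluster is returned whole as SMALL.
    """
    ranked = sorted(c.members.items(), key=lambda kv: (-kv[1], kv[0]))
    correct = [(s, n) for s, n in ranked if len(s) == expected_len]
    total = c.total_reads
    if len(correct) < 2:
        logger.warning(
            "ambiguous cluster %s has <2 correct-length sequences; kept whole as small",
            c.label[:24],
        )
        whole = replace(c)
        whole.status = ClusterStatus.SMALL
        return [whole]
    (d_seq, d_n), (s_seq, s_n) = correct[0], correct[1]
    n1 = int(round(total * d_n / (d_n + s_n)))
    n2 = total - n1
    out = []
    for seq, n in ((d_seq, n1), (s_seq, n2)):
        sub = Cluster({seq: n}, formed_at_gamma=c.formed_at_gamma)
        sub.status = (
            ClusterStatus.GOOD
            if n / library_size >= theta - _EPS
            else ClusterStatus.SMALL
        )
        out.append(sub)
    return out


# ---------------------------------------------------------------------------
# the full stepwise run


def _gamma_schedule(start: float, step: float, end: float) -> list[float]:
    gammas = []
    g = start
    while g < end - _EPS:
        gammas.append(g)
        g += step
    gammas.append(end)
    return gammas


def run_stc(lib: SampleLibrary, params: STCParams) -> ClusterSet:
    """Run the full stepwise clustering for one (post-phase-2) sample
    library; fully deterministic for a given ``params.seed``."""
    if not lib.counts:
        return ClusterSet(lib.sample_id, [], [], [], 0)
    order_index = sorted(lib.counts)
    sim = _align.similarity_matrix(order_index)
    library_size = lib.library_size

    if params.gamma_start == AUTO:
        if len(order_index) < 2:
            gamma0 = params.gamma_end
        else:
            lo = sim[np.triu_indices(len(order_index), k=1)].min()
            gamma0 = min(float(np.floor(lo)), params.gamma_end)
    else:
        gamma0 = float(params.gamma_start)

    good: list[Cluster] = []
    small: list[Cluster] = []
    logs: list[RoundLog] = []
    active: dict[str, int] = dict(lib.counts)
    ambiguous: list[Cluster] = []

    for round_idx, gamma in enumerate(_gamma_schedule(gamma0, params.gamma_step, params.gamma_end)):
        if not active:
            break
        round_seed = int(
            np.random.SeedSequence([params.seed, round_idx]).generate_state(1)[0]
            % (2**31)
        )
        clusters = modal_clusters(
            active,
            gamma,
            params.replicates,
            round_seed,
            sim=sim,
            order_index=order_index,
        )
        ambiguous = []
        next_active: dict[str, int] = {}
        for c in clusters:
            status = classify_cluster(c, library_size, params.theta, params.delta)
            c.status = status
            if status is ClusterStatus.GOOD:
                good.append(c)
            elif status is ClusterStatus.SMALL:
                small.append(c)
            else:
                ambiguous.append(c)
                for s, n in c.members.items():
                    next_active[s] = next_active.get(s, 0) + n
        active = next_active
        logs.append(
            RoundLog(
                gamma=gamma,
                n_good=len(good),
                n_small=len(small),
                n_ambiguous=len(ambiguous),
                reads_left=sum(active.values()),
                sequences_left=len(active),
            )
        )

    # residual ambiguous clusters are split after the final round
    for c in ambiguous:
        for sub in split_ambiguous(c, library_size, params.theta, params.expected_len):
            (good if sub.status is ClusterStatus.GOOD else small).append(sub)

    return ClusterSet(lib.sample_id, good, small, logs, library_size)
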