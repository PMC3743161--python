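"""Train/test splitting: MACCS-fingerprint diversity clustering and
stratified random selection.

The diversity procedure clusters compounds by MACCS-key Tanimoto
similarity (sphere-exclusion leader clustering, default threshold 0.75)
and draws roughly 10% of each cluster of at least five members into the
test set, matching the cluster's active:inactive ratio; smaller clusters
go entirely to training.  The random procedure samples a fixed number of
actives and inactives (default 6 and 10, i.e. a 16-compound test set for
a 57:105 library) uniformly without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

DEFAULT_SIM_THRESHOLD = 0.75
DEFAULT_MIN_CLUSTER_SIZE = 5
DEFAULT_TEST_FRACTION = 0.1
DEFAULT_N_TEST_ACTIVE = 6
DEFAULT_N_TEST_INACTIVE = 10


@dataclass
class ClusterAssignment:
    """Cluster id per compound (every compound in exactly one cluster)."""

    cluster_ids: list[int]
    sim_threshold: float

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for idx, cid in enumerate(self.cluster_ids):
            out.setdefault(cid, []).append(idx)
        return out


@dataclass
class Split:
    """Disjoint train/test partition with per-class bookkeeping."""

    train: list[int]
    test: list[int]
    method: Literal["diversity", "random"]
    seed: int | None = None
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")

    def to_dict(self) -> dict:
        return {
            "train": self.train,
            "test": self.test,
            "method": self.method,
            "seed": self.seed,
            "class_counts": self.class_counts,
        }


def maccs_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """166-bit MACCS key vector (public key definitions, fixed bit order)."""
    if mol is None:
        raise ValueError("cannot fingerprint an unparsed molecule")
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(166, dtype=bool)
    for bit in bv.GetOnBits():
        if bit >= 1:  # RDKit bit 0 is a placeholder
            arr[bit - 1] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; 1.0 when both vectors are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def _similarity_matrix(fps: Sequence[np.ndarray]) -> np.ndarray:
    F = np.asarray(fps, dtype=bool).astype(np.int32)
    inter = F @ F.T
    pop = F.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def cluster_fingerprints(
    fps: Sequence[np.ndarray],
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> ClusterAssignment:
    """Sphere-exclusion (leader) clustering at a Tanimoto threshold.

    Centers are chosen in descending order of unassigned-neighbour count
    (ties broken by input index); each center absorbs all unassigned
    compounds with similarity >= the threshold.  Deterministic for a fixed
    input order; singletons allowed.
    """
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError("similarity threshold must be in (0, 1]")
    n = len(fps)
    if n == 0:
        raise ValueError("no fingerprints to cluster")
    sim = _similarity_matrix(fps)
    neighbor = sim >= sim_threshold
    np.fill_diagonal(neighbor, False)
    cluster_ids = np.full(n, -1, dtype=int)
    next_id = 0
    unassigned = np.ones(n, dtype=bool)
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = unassigned & neighbor[center]
        members[center] = True
        cluster_ids[members] = next_id
        unassigned[members] = False
        next_id += 1
    return ClusterAssignment(cluster_ids.tolist(), sim_threshold)


def _apportion(n_test: int, n_active: int, n_inactive: int) -> tuple[int, int]:
    """Largest-remainder split of test seats between the classes.

    Equal remainders award the seat to the active class first.
    """
    size = n_active + n_inactive
    qa = n_test * n_active / size
    qi = n_test * n_inactive / size
    fa, fi = int(qa), int(qi)
    remaining = n_test - fa - fi
    order = sorted(
        [(qa - fa, 0), (qi - fi, 1)], key=lambda t: (-t[0], t[1])
    )
    for _, cls in order[:remaining]:
        if cls == 0:
            fa += 1
        else:
            fi += 1
    fa = min(fa, n_active)
    fi = min(n_test - fa, n_inactive)
    return fa, fi


def diversity_split(
    clusters: ClusterAssignment,
    labels: Sequence[int],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    test_fraction: float = DEFAULT_TEST_FRACTION,
) -> Split:
    """Cluster-stratified test selection.

    For each cluster of at least ``min_cluster_size`` members,
    ``max(1, round(test_fraction * size))`` compounds (half-up rounding)
    go to the test set, apportioned between the classes by largest
    remainder and picked lowest-index-first within each class.  Smaller
    clusters go entirely to training.
    """
    labels = list(labels)
    if len(labels) != len(clusters.cluster_ids):
        raise ValueError("labels and cluster assignment are not aligned")
    test: list[int] = []
    for _, members in sorted(clusters.members().items()):
        size = len(members)
        if size < min_cluster_size:
            continue
        n_test = max(1, int(np.floor(test_fraction * size + 0.5)))
        actives = [i for i in members if labels[i] == 1]
        inactives = [i for i in members if labels[i] == 0]
        na, ni = _apportion(n_test, len(actives), len(inactives))
        test.extend(actives[:na])
        test.extend(inactives[:ni])
    if not test:
        raise ValueError(
            f"no cluster reaches {min_cluster_size} members; test set would be empty"
        )
    test_set = set(test)
    train = [i for i in range(len(labels)) if i not in test_set]
    if not {labels[i] for i in train} == {0, 1}:
        raise ValueError("training partition lost a class")
    return Split(
        train=train,
        test=sorted(test),
        method="diversity",
        class_counts=_class_counts(labels, train, sorted(test)),
    )


def random_split(
    labels: Sequence[int],
    n_test_active: int = DEFAULT_N_TEST_ACTIVE,
    n_test_inactive: int = DEFAULT_N_TEST_INACTIVE,
    seed: int = 1,
) -> Split:
    """Stratified random test selection, reproducible from the seed.

    Samples exactly ``n_test_active`` actives and ``n_test_inactive``
    inactives uniformly without replacement; the training set is the
    complement and must retain both classes.
    """
    labels = list(labels)
    actives = [i for i, v in enumerate(labels) if v == 1]
    inactives = [i for i, v in enumerate(labels) if v == 0]
    if len(actives) < n_test_active or len(inactives) < n_test_inactive:
        raise ValueError(
            f"requested {n_test_active}/{n_test_inactive} test compounds but only "
            f"{len(actives)} actives / {len(inactives)} inactives available"
        )
    if len(actives) == n_test_active or len(inactives) == n_test_inactive:
        raise ValueError("training partition would lose a class")
    rng = np.random.default_rng(seed)
    test = sorted(
        rng.choice(actives, size=n_test_active, replace=False).tolist()
        + rng.choice(inactives, size=n_test_inactive, replace=False).tolist()
    )
    test_set = set(test)
    train = [i for i in range(len(labels)) if i not in test_set]
    return Split(
        train=train,
        test=test,
        method="random",
        seed=seed,
        class_counts=_class_counts(labels, train, test),
    )


def _class_counts(labels: Sequence[int], train: Sequence[int], test: Sequence[int]):
    def cc(idx: Sequence[int]) -> dict[str, int]:
        return {
            "active": sum(1 for i in idx if labels[i] == 1),
            "inactive": sum(1 for i in idx if labels[i] == 0),
        }

    return {"train": cc(train), "test": cc(test)}
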