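"""Blocked, balanced BWS choice-set construction and diagnostics.

Designs are built by a randomized greedy swap optimizer: tasks are seeded
with random item triples, then single-item swaps are accepted whenever they
improve a lexicographic objective of (overall frequency balance,
within-version frequency balance, duplicate-triple count, D-efficiency of
the dummy-coded design matrix).  This mirrors the behaviour of commercial
MaxDiff designers — frequency balance first, information content as a
tiebreaker — without claiming to reproduce any proprietary algorithm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import OutcomeCatalog

#: Random designs used to normalize relative D-efficiency.
DEFAULT_RESTARTS = 50


@dataclass(frozen=True)
class ChoiceDesign:
    """A blocked BWS design: per-version lists of item index triples.

    ``tasks`` rows are ``(version_id, task_id, items)`` with ``items`` a
    tuple of distinct indices into ``catalog.outcomes``.
    """

    catalog: OutcomeCatalog
    n_versions: int
    tasks: tuple[tuple[int, int, tuple[int, ...]], ...]
    seed: int
    include_reference: bool = True

    def __post_init__(self) -> None:
        per_version: dict[int, int] = {}
        for version, _task, items in self.tasks:
            if len(set(items)) != len(items):
                raise ValueError("a task repeats an item")
            if any(i < 0 or i >= len(self.catalog) for i in items):
                raise ValueError("item index outside catalog")
            per_version[version] = per_version.get(version, 0) + 1
        if len(set(per_version.values())) > 1:
            raise ValueError("task count differs across versions")

    @property
    def items_per_task(self) -> int:
        return len(self.tasks[0][2])

    @property
    def tasks_per_version(self) -> int:
        return len(self.tasks) // self.n_versions

    def version_tasks(self, version: int) -> list[tuple[int, tuple[int, ...]]]:
        return [(t, items) for v, t, items in self.tasks if v == version]

    @property
    def item_pool(self) -> tuple[int, ...]:
        """Catalog indices eligible to appear in tasks."""
        ref = self.catalog.reference_index
        return tuple(
            i
            for i in range(len(self.catalog))
            if self.include_reference or i != ref
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            k = self.items_per_task
            writer.writerow(["version", "task"] + [f"item{j+1}" for j in range(k)])
            for version, task, items in self.tasks:
                writer.writerow(
                    [version, task] + [self.catalog.outcomes[i] for i in items]
                )

    @classmethod
    def from_csv(cls, path: str | Path, catalog: OutcomeCatalog) -> "ChoiceDesign":
        tasks = []
        ref_seen = False
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels = [v for k, v in row.items() if k.startswith("item")]
                items = tuple(catalog.index(lab) for lab in labels)
                ref_seen = ref_seen or catalog.reference_index in items
                tasks.append((int(row["version"]), int(row["task"]), items))
        n_versions = len({v for v, _, _ in tasks})
        return cls(catalog, n_versions, tuple(tasks), seed=-1,
                   include_reference=ref_seen)


@dataclass
class DesignDiagnostics:
    """Measured balance and efficiency properties of a design."""

    appearance_counts: dict[str, int]
    cooccurrence: np.ndarray  # (pool, pool), symmetric, zero diagonal
    pool_labels: tuple[str, ...]
    balance_score: int  # max - min appearance count
    d_efficiency: float  # relative, in (0, 1]
    n_restarts: int
    warnings: list[str] = field(default_factory=list)


def _counts(tasks: list[tuple[int, ...]], pool: tuple[int, ...]) -> np.ndarray:
    pos = {item: j for j, item in enumerate(pool)}
    c = np.zeros(len(pool), dtype=int)
    for items in tasks:
        for i in items:
            c[pos[i]] += 1
    return c


def _coded_matrix(tasks: list[tuple[int, ...]], pool: tuple[int, ...]) -> np.ndarray:
    """Dummy-coded (multi-hot), column-centered task x item matrix."""
    pos = {item: j for j, item in enumerate(pool)}
    x = np.zeros((len(tasks), len(pool)))
    for r, items in enumerate(tasks):
        for i in items:
            x[r, pos[i]] = 1.0
    return x - x.mean(axis=0)


def _d_criterion(tasks: list[tuple[int, ...]], pool: tuple[int, ...]) -> float:
    """det(X'X)^(1/p) / n of the centered coded matrix (drop one column)."""
    x = _coded_matrix(tasks, pool)[:, :-1]  # centered multi-hot is rank-deficient
    p = x.shape[1]
    sign, logdet = np.linalg.slogdet(x.T @ x)
    if sign <= 0:
        return 0.0
    return float(np.exp(logdet / p) / len(tasks))


def _objective(
    flat_tasks: list[tuple[int, ...]],
    version_of: list[int],
    n_versions: int,
    pool: tuple[int, ...],
) -> tuple[int, int, int, float]:
    overall = _counts(flat_tasks, pool)
    within = 0
    dupes = 0
    for v in range(n_versions):
        vt = [t for t, ver in zip(flat_tasks, version_of) if ver == v]
        cv = _counts(vt, pool)
        within += int(cv.max() - cv.min())
        seen = {tuple(sorted(t)) for t in vt}
        dupes += len(vt) - len(seen)
    # negate D so smaller tuples are better throughout
    return (
        int(overall.max() - overall.min()),
        within,
        dupes,
        -_d_criterion(flat_tasks, pool),
    )


def _random_tasks(
    rng: np.random.Generator,
    pool: tuple[int, ...],
    n_tasks: int,
    items_per_task: int,
) -> list[tuple[int, ...]]:
    pool_arr = np.asarray(pool)
    return [
        tuple(rng.choice(pool_arr, size=items_per_task, replace=False))
        for _ in range(n_tasks)
    ]


def _deal_balanced_version(
    rng: np.random.Generator,
    pool: tuple[int, ...],
    tasks_per_version: int,
    items_per_task: int,
    overall: dict[int, int],
) -> list[tuple[int, ...]]:
    """Deal a within-version-balanced item multiset into tasks.

    The version's slot multiset gives every pool item ``slots // n`` copies
    and hands the remainder to the items with the lowest running overall
    counts, which keeps the across-version totals within 1 of each other
    too.  Duplicate items inside a task are repaired by swapping slots
    between tasks.
    """
    slots = tasks_per_version * items_per_task
    n = len(pool)
    base, rem = divmod(slots, n)
    order = sorted(pool, key=lambda i: (overall[i], rng.random()))
    multiset: list[int] = []
    for item in pool:
        multiset.extend([item] * base)
    extras = order[:rem]
    multiset.extend(extras)
    for _attempt in range(200):
        rng.shuffle(multiset)
        tasks = [
            multiset[t * items_per_task:(t + 1) * items_per_task]
            for t in range(tasks_per_version)
        ]
        # repair within-task duplicates by cross-task slot swaps
        ok = True
        for _pass in range(50):
            dirty = [t for t in tasks if len(set(t)) < len(t)]
            if not dirty:
                break
            t = dirty[0]
            dup = next(x for x in t if t.count(x) > 1)
            fixed = False
            for u in tasks:
                if u is t:
                    continue
                for j, y in enumerate(u):
                    if y not in t and dup not in u:
                        t[t.index(dup)] = y
                        u[j] = dup
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                ok = False
                break
        else:
            ok = all(len(set(t)) == len(t) for t in tasks)
        if ok and all(len(set(t)) == len(t) for t in tasks):
            for item in extras:
                overall[item] += 0  # extras already in multiset; counted below
            for t in tasks:
                for i in t:
                    overall[i] += 1
            return [tuple(t) for t in tasks]
    raise RuntimeError("could not construct a duplicate-free balanced version")


def _greedy_improve(
    tasks: list[tuple[int, ...]],
    version_of: list[int],
    n_versions: int,
    pool: tuple[int, ...],
    max_passes: int = 30,
) -> list[tuple[int, ...]]:
    """First-improvement single-item swaps until a full pass stalls."""
    best = _objective(tasks, version_of, n_versions, pool)
    for _ in range(max_passes):
        improved = False
        for t_idx, items in enumerate(tasks):
            for slot in range(len(items)):
                for cand in pool:
                    if cand in items:
                        continue
                    trial = list(items)
                    trial[slot] = cand
                    tasks[t_idx] = tuple(trial)
                    score = _objective(tasks, version_of, n_versions, pool)
                    if score < best:
                        best = score
                        items = tasks[t_idx]
                        improved = True
                    else:
                        tasks[t_idx] = items
        if not improved:
            break
    return tasks


def generate_design(
    catalog: OutcomeCatalog,
    n_versions: int = 4,
    tasks_per_version: int = 10,
    items_per_task: int = 3,
    seed: int = 0,
    include_reference: bool = True,
) -> ChoiceDesign:
    """Construct a blocked, frequency-balanced BWS design.

    The item pool is the whole catalog (default) or the non-reference
    outcomes when ``include_reference=False``.  Including the reference
    level in the choice sets anchors the location of the utility scale
    during estimation; designs without it identify utilities only up to an
    additive constant.

    Deterministic given ``seed``.  Raises ``ValueError`` when the pool is
    smaller than ``items_per_task``.
    """
    if items_per_task < 2:
        raise ValueError("items_per_task must be >= 2")
    if n_versions < 1 or tasks_per_version < 1:
        raise ValueError("n_versions and tasks_per_version must be >= 1")
    ref = catalog.reference_index
    pool = tuple(
        i for i in range(len(catalog)) if include_reference or i != ref
    )
    if items_per_task > len(pool):
        raise ValueError(
            f"items_per_task={items_per_task} exceeds the {len(pool)}-item pool"
        )
    rng = np.random.default_rng(seed)
    n_tasks = n_versions * tasks_per_version
    version_of = [t // tasks_per_version for t in range(n_tasks)]
    overall = {i: 0 for i in pool}
    tasks: list[tuple[int, ...]] = []
    try:
        for _v in range(n_versions):
            tasks.extend(
                _deal_balanced_version(
                    rng, pool, tasks_per_version, items_per_task, overall
                )
            )
    except RuntimeError:
        # rare degenerate shapes: fall back to a purely random start
        tasks = _random_tasks(rng, pool, n_tasks, items_per_task)
    init_balance = _objective(tasks, version_of, n_versions, pool)[0]
    tasks = _greedy_improve(tasks, version_of, n_versions, pool)
    assert _objective(tasks, version_of, n_versions, pool)[0] <= init_balance
    rows = tuple(
        (version_of[t], t - version_of[t] * tasks_per_version, tasks[t])
        for t in range(n_tasks)
    )
    return ChoiceDesign(
        catalog=catalog,
        n_versions=n_versions,
        tasks=rows,
        seed=seed,
        include_reference=include_reference,
    )


def diagnose_design(
    design: ChoiceDesign,
    catalog: OutcomeCatalog | None = None,
    n_restarts: int = DEFAULT_RESTARTS,
) -> DesignDiagnostics:
    """Appearance counts, co-occurrence, balance, and relative D-efficiency.

    Relative D-efficiency normalizes the design's D-criterion against the
    best value found over ``n_restarts`` random designs of the same shape
    (the design itself included, so the result lies in (0, 1]).  The
    restart stream is internally seeded, so diagnostics are deterministic.
    """
    catalog = catalog or design.catalog
    pool = design.item_pool
    flat = [items for _, _, items in design.tasks]
    counts = _counts(flat, pool)
    n_pool = len(pool)
    pos = {item: j for j, item in enumerate(pool)}
    co = np.zeros((n_pool, n_pool), dtype=int)
    for items in flat:
        for a in items:
            for b in items:
                if a != b:
                    co[pos[a], pos[b]] += 1
    d_self = _d_criterion(flat, pool)
    rng = np.random.default_rng(12345)
    d_best = d_self
    for _ in range(n_restarts):
        rand = _random_tasks(rng, pool, len(flat), design.items_per_task)
        d_best = max(d_best, _d_criterion(rand, pool))
    warnings: list[str] = []
    balance = int(counts.max() - counts.min())
    slots = design.items_per_task * len(flat)
    if slots % n_pool != 0 and balance == 0:
        pass  # impossible; kept for clarity
    if balance > 1:
        warnings.append(
            f"appearance counts spread by {balance}; exact balance may be infeasible"
        )
    labels = tuple(catalog.outcomes[i] for i in pool)
    return DesignDiagnostics(
        appearance_counts={lab: int(c) for lab, c in zip(labels, counts)},
        cooccurrence=co,
        pool_labels=labels,
        balance_score=balance,
        d_efficiency=0.0 if d_best == 0 else d_self / d_best,
        n_restarts=n_restarts,
        warnings=warnings,
    )
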