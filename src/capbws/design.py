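"""Balanced incomplete block designs for object-case best-worst scaling tasks.

A BWS questionnaire version is a block design: ``n_tasks`` choice tasks (blocks)
each showing ``set_size`` of the ``n_items`` attributes.  Balance means every
item appears equally often (replication r = n_tasks * set_size / n_items) and,
in a strict BIBD, every unordered pair of items co-occurs equally often
(lambda = r * (set_size - 1) / (n_items - 1)).  For the OxCAP-MH configuration
(16 items, sets of 6, 16 tasks) r = 6 and lambda = 2, which is the parameter
set of the (16, 6, 2) biplane, so a perfectly pair-balanced version exists.

The generator runs a fixed number of random restarts of a swap-based hill
climb and keeps the best version found, ranking candidates lexicographically
by (item-frequency imbalance, pair-co-occurrence variance, display-position
imbalance).  Item frequencies are exact by construction, pair balance is
optimised, and position balance is polished last as a guard against
reading-order bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Design",
    "BalanceReport",
    "bibd_parameters",
    "generate_design",
    "validate_design",
]


@dataclass(frozen=True)
class Design:
    """A versioned set of BWS choice tasks.

    ``versions[v]`` is an integer array of shape (n_tasks, set_size) holding
    1-based item numbers; column order is the display position (1 = shown
    first).
    """

    n_items: int
    set_size: int
    versions: tuple[np.ndarray, ...]
    seed: int | None = None
    n_iterations: int | None = None

    @property
    def n_versions(self) -> int:
        return len(self.versions)

    @property
    def n_tasks(self) -> int:
        return self.versions[0].shape[0]

    @property
    def replication(self) -> int:
        """Appearances per item per version, r = n_tasks * set_size / n_items."""
        return self.n_tasks * self.set_size // self.n_items

    def tasks(self, version: int) -> np.ndarray:
        """Tasks of one version (1-based version index)."""
        return self.versions[version - 1]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Design):
            return NotImplemented
        return (
            self.n_items == other.n_items
            and self.set_size == other.set_size
            and len(self.versions) == len(other.versions)
            and all(np.array_equal(a, b) for a, b in zip(self.versions, other.versions))
        )


@dataclass(frozen=True)
class BalanceReport:
    """Exact balance bookkeeping for each version of a design.

    item_frequencies: (n_versions, n_items) appearance counts.
    pair_cooccurrence: (n_versions, n_items, n_items) symmetric co-occurrence
        counts with zero diagonal.
    positional_frequencies: (n_versions, n_items, set_size) counts of item k
        shown at display position p.
    is_bibd: per version, True iff item frequencies are constant and pair
        co-occurrences are constant.
    """

    item_frequencies: np.ndarray
    pair_cooccurrence: np.ndarray
    positional_frequencies: np.ndarray
    is_bibd: np.ndarray

    def pair_variance(self, version: int) -> float:
        """Population variance of the off-diagonal co-occurrence counts."""
        c = self.pair_cooccurrence[version - 1]
        iu = np.triu_indices_from(c, k=1)
        return float(np.var(c[iu]))


def bibd_parameters(n_items: int, set_size: int, n_tasks: int) -> dict:
    """Replication and pair-balance parameters implied by a block design.

    Returns r and lambda together with flags saying whether each is an
    integer, i.e. whether item balance / strict pair balance is arithmetically
    feasible at these sizes.  For (16, 6, 16): r = 6, lambda = 2, both feasible.
    """
    r = n_tasks * set_size / n_items
    lam = r * (set_size - 1) / (n_items - 1) if n_items > 1 else float("nan")
    return {
        "r": r,
        "lambda": lam,
        "r_integer": float(r).is_integer(),
        "lambda_integer": bool(np.isfinite(lam)) and float(lam).is_integer(),
    }


def _check_parameters(n_items, set_size, n_tasks, n_versions, n_iterations):
    if set_size > n_items:
        raise ValueError(
            f"set_size ({set_size}) cannot exceed n_items ({n_items})"
        )
    if min(n_items, set_size, n_tasks, n_versions) < 1 or n_iterations < 1:
        raise ValueError("all design parameters must be positive")
    if (n_tasks * set_size) % n_items != 0:
        raise ValueError(
            f"n_tasks * set_size = {n_tasks * set_size} is not divisible by "
            f"n_items = {n_items}: items cannot appear equally often"
        )


def _random_balanced_tasks(n_items, set_size, n_tasks, rng):
    """Random tasks with exact item frequencies r and no within-task duplicates."""
    r = n_tasks * set_size // n_items
    slots = np.repeat(np.arange(1, n_items + 1), r)
    while True:
        rng.shuffle(slots)
        tasks = slots.reshape(n_tasks, set_size).copy()
        # repair within-task duplicates by swapping occurrences across tasks
        for _ in range(200):
            dup = [
                t for t in range(n_tasks)
                if len(set(tasks[t])) < set_size
            ]
            if not dup:
                return tasks
            t = dup[0]
            vals, counts = np.unique(tasks[t], return_counts=True)
            x = vals[counts > 1][0]
            i = int(np.where(tasks[t] == x)[0][1])
            # find a partner slot whose item is absent from task t and vice versa
            order = rng.permutation(n_tasks)
            done = False
            for u in order:
                if u == t:
                    continue
                for j in rng.permutation(set_size):
                    y = tasks[u, j]
                    if y != x and y not in tasks[t] and x not in tasks[u]:
                        tasks[t, i], tasks[u, j] = y, x
                        done = True
                        break
                if done:
                    break
            if not done:
                break  # reshuffle from scratch


def _pair_counts(tasks, n_items):
    c = np.zeros((n_items, n_items), dtype=np.int64)
    for row in tasks:
        idx = row - 1
        for a, b in itertools.combinations(idx, 2):
            c[a, b] += 1
            c[b, a] += 1
    return c


def _pair_ss(c, lam_bar):
    iu = np.triu_indices_from(c, k=1)
    d = c[iu] - lam_bar
    return float(d @ d)


def _move_changes(row_t, row_u, x, y):
    """Net co-occurrence count changes from swapping x (in task t) with y (in u).

    Returned as {(i, j): delta} with i < j, 1-based items.  Using net changes
    keeps the accounting exact when the two tasks share items.
    """
    changes: dict[tuple[int, int], int] = {}

    def bump(a, b, d):
        key = (a, b) if a < b else (b, a)
        changes[key] = changes.get(key, 0) + d

    for a in row_t:
        if a != x:
            bump(x, a, -1)
            bump(y, a, +1)
    for b in row_u:
        if b != y:
            bump(y, b, -1)
            bump(x, b, +1)
    return changes


def move_delta(c, row_t, row_u, x, y, lam_bar=None):
    """Exact objective change of swapping x (task t) with y (task u).

    Because the co-occurrence mean is fixed, the quadratic terms telescope and
    the change of sum((C - mean)^2) is linear in row sums of C; net changes on
    items shared by both tasks cancel.  ``lam_bar`` is accepted for symmetry
    with the naive oracle but does not enter the result.
    """
    changes = _move_changes(row_t, row_u, x, y)
    delta = 0.0
    for (a, b), d in changes.items():
        cab = c[a - 1, b - 1]
        if lam_bar is None:
            delta += 2 * d * cab + d * d  # (c+d)^2 - c^2 with mean cancelled
        else:
            delta += (cab + d - lam_bar) ** 2 - (cab - lam_bar) ** 2
    return delta


def _hill_climb_pairs(tasks, n_items, rng, max_sweeps=40):
    """Best-improvement swaps of item occurrences between tasks.

    A move exchanges item x in task t with item y in task u (frequencies are
    preserved); it is admissible only if it creates no within-task duplicate.
    The objective is the sum of squared deviations of pair co-occurrence
    counts from their (fixed) mean; since that mean is constant, the change of
    a move reduces to a linear function of co-occurrence row sums, evaluated
    vectorised over all candidate swaps of a task pair:

        delta(x, y) = 2 * [(R_A[y] - R_B[y]) - (R_A[x] - R_B[x])
                           - 2 * C[x, y]] + 2 * (|A| + |B| - 2),

    where A and B are the items exclusive to tasks t and u and R_A, R_B are
    co-occurrence sums against those sets (shared items net out exactly).
    """
    n_tasks, set_size = tasks.shape
    c = _pair_counts(tasks, n_items)
    n_pairs_total = n_tasks * set_size * (set_size - 1) // 2
    lam_bar = n_pairs_total / (n_items * (n_items - 1) / 2)
    obj = _pair_ss(c, lam_bar)
    member = np.zeros((n_tasks, n_items + 1), dtype=bool)
    for t in range(n_tasks):
        member[t, tasks[t]] = True
    for _ in range(max_sweeps):
        if obj == 0.0:
            break
        best_delta, best_move = -1e-9, None
        for t in range(n_tasks - 1):
            row_t = tasks[t]
            for u in range(t + 1, n_tasks):
                row_u = tasks[u]
                a0 = row_t[~member[u, row_t]]  # candidates x: in t only
                b0 = row_u[~member[t, row_u]]  # candidates y: in u only
                if len(a0) == 0 or len(b0) == 0:
                    continue
                g = (c[:, a0 - 1].sum(axis=1) - c[:, b0 - 1].sum(axis=1))
                const = 2.0 * (len(a0) + len(b0) - 2)
                # delta matrix over (x in a0) x (y in b0)
                d = 2.0 * (g[b0 - 1][None, :] - g[a0 - 1][:, None]
                           - 2.0 * c[np.ix_(a0 - 1, b0 - 1)]) + const
                k = np.unravel_index(np.argmin(d), d.shape)
                if d[k] < best_delta:
                    best_delta = float(d[k])
                    best_move = (t, u, int(a0[k[0]]), int(b0[k[1]]))
        if best_move is None:
            break
        t, u, x, y = best_move
        for (a, b), dd in _move_changes(tasks[t], tasks[u], x, y).items():
            c[a - 1, b - 1] += dd
            c[b - 1, a - 1] += dd
        tasks[t, np.flatnonzero(tasks[t] == x)[0]] = y
        tasks[u, np.flatnonzero(tasks[u] == y)[0]] = x
        member[t, x] = member[u, y] = False
        member[t, y] = member[u, x] = True
        obj += best_delta
    return tasks, _pair_ss(c, lam_bar)


def _balance_positions(tasks, n_items, rng, max_sweeps=60):
    """Permute items within tasks to even out display-position counts."""
    n_tasks, set_size = tasks.shape
    for t in range(n_tasks):
        rng.shuffle(tasks[t])
    counts = np.zeros((n_items, set_size), dtype=np.int64)
    for row in tasks:
        for p, x in enumerate(row):
            counts[x - 1, p] += 1
    target = n_tasks * set_size / (n_items * set_size)

    def cell(x, p):
        return counts[x - 1, p] - target

    obj = float(np.sum((counts - target) ** 2))
    for _ in range(max_sweeps):
        improved = False
        for t in range(n_tasks):
            for p in range(set_size - 1):
                for q in range(p + 1, set_size):
                    x, y = tasks[t, p], tasks[t, q]
                    delta = (
                        (cell(x, q) + 1) ** 2 - cell(x, q) ** 2
                        + (cell(x, p) - 1) ** 2 - cell(x, p) ** 2
                        + (cell(y, p) + 1) ** 2 - cell(y, p) ** 2
                        + (cell(y, q) - 1) ** 2 - cell(y, q) ** 2
                    )
                    if delta < -1e-12:
                        counts[x - 1, p] -= 1
                        counts[x - 1, q] += 1
                        counts[y - 1, q] -= 1
                        counts[y - 1, p] += 1
                        tasks[t, p], tasks[t, q] = y, x
                        obj += delta
                        improved = True
        if not improved:
            break
    return tasks, obj


def generate_design(
    n_items: int,
    set_size: int,
    n_tasks: int,
    n_versions: int = 1,
    n_iterations: int = 1000,
    seed: int | None = None,
) -> Design:
    """Search for balanced BWS questionnaire versions.

    Each version is the best design over ``n_iterations`` random restarts of
    the swap-based hill climb; versions use independent seed streams spawned
    from ``seed`` so they differ in task composition while each satisfying
    per-version balance.  Deterministic for a fixed seed.
    """
    _check_parameters(n_items, set_size, n_tasks, n_versions, n_iterations)
    streams = np.random.SeedSequence(seed).spawn(n_versions)
    versions = []
    for v in range(n_versions):
        rng = np.random.default_rng(streams[v])
        best_tasks, best_key = None, None
        for _ in range(n_iterations):
            tasks = _random_balanced_tasks(n_items, set_size, n_tasks, rng)
            tasks, pair_obj = _hill_climb_pairs(tasks, n_items, rng)
            tasks, pos_obj = _balance_positions(tasks, n_items, rng)
            key = (pair_obj, pos_obj)
            if best_key is None or key < best_key:
                best_tasks, best_key = tasks.copy(), key
            if best_key == (0.0, 0.0):
                break
        best_tasks.setflags(write=False)
        versions.append(best_tasks)
    return Design(
        n_items=n_items,
        set_size=set_size,
        versions=tuple(versions),
        seed=seed,
        n_iterations=n_iterations,
    )


def validate_design(design: Design) -> BalanceReport:
    """Count item, pair and position frequencies and flag strict BIBDs.

    Raises ValueError when a task repeats an item or references an item
    outside 1..n_items, naming the offending version and task.
    """
    n_items, set_size = design.n_items, design.set_size
    n_versions, n_tasks = design.n_versions, design.n_tasks
    freq = np.zeros((n_versions, n_items), dtype=np.int64)
    pairs = np.zeros((n_versions, n_items, n_items), dtype=np.int64)
    pos = np.zeros((n_versions, n_items, set_size), dtype=np.int64)
    is_bibd = np.zeros(n_versions, dtype=bool)
    for v, tasks in enumerate(design.versions):
        if tasks.shape != (n_tasks, set_size):
            raise ValueError(
                f"version {v + 1} has shape {tasks.shape}, "
                f"expected {(n_tasks, set_size)}"
            )
        for t, row in enumerate(tasks):
            if np.any((row < 1) | (row > n_items)):
                raise ValueError(
                    f"version {v + 1}, task {t + 1}: item out of range 1..{n_items}"
                )
            if len(set(row.tolist())) != set_size:
                raise ValueError(
                    f"version {v + 1}, task {t + 1}: duplicate item in {row.tolist()}"
                )
            idx = row - 1
            for p, k in enumerate(idx):
                freq[v, k] += 1
                pos[v, k, p] += 1
            for a, b in itertools.combinations(idx, 2):
                pairs[v, a, b] += 1
                pairs[v, b, a] += 1
        iu = np.triu_indices(n_items, k=1)
        is_bibd[v] = (
            len(np.unique(freq[v])) == 1 and len(np.unique(pairs[v][iu])) == 1
        )
    return BalanceReport(
        item_frequencies=freq,
        pair_cooccurrence=pairs,
        positional_frequencies=pos,
        is_bibd=is_bibd,
    )
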