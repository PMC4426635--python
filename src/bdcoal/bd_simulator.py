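"""Exact forward simulation of the constant-rate birth-death process.

Event-driven (Gillespie) simulation from a single founder: with ``n`` alive,
the waiting time to the next event is exponential with rate
``n (lambda + mu)`` and the event is a birth with probability
``lambda / (lambda + mu)``.  Conditioning (survival to ``T``, or at least two
alive at ``T``) is implemented by rejection, which is exact; the acceptance
probability for survival is ``1 - p0(T)``.

Two levels of detail are produced:

* :class:`Trajectory` — event times and +/-1 population increments only;
  the input to the stochastic-coalescent sampler.
* :class:`SimulatedTree` — the full genealogy including extinct branches;
  sampling two random extant tips and reading off their divergence time
  (:func:`sample_pair_coalescence`) is the brute-force oracle for the
  analytic pairwise coalescent-time distribution.

Randomness: every public entry point takes one integer seed (or an existing
``numpy.random.Generator``); replicate ``k`` of an ensemble uses
``base_seed + k`` so that ensembles are reproducible bit for bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .params import BDParams

__all__ = [
    "Trajectory",
    "SimulatedTree",
    "simulate_trajectory",
    "simulate_trajectories",
    "simulate_tree",
    "sample_pair_coalescence",
]

CONDITIONS = ("none", "survival", "at_least_two_at_T")
_MAX_REJECTIONS = 10_000_000
_CHUNK = 4096


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _Draws:
    """Chunked standard-exponential and uniform draws from one generator."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._exp = rng.standard_exponential(_CHUNK)
        self._uni = rng.random(_CHUNK)
        self._i = 0

    def next_pair(self):
        if self._i == _CHUNK:
            self._exp = self.rng.standard_exponential(_CHUNK)
            self._uni = self.rng.random(_CHUNK)
            self._i = 0
        i = self._i
        self._i = i + 1
        return self._exp[i], self._uni[i]


@dataclass
class Trajectory:
    """One realized population-size path of the BD process on ``[0, T]``.

    Only event times and increments are stored; sizes are reconstructed by a
    cumulative scan (initial size 1 at ``t = 0``).
    """

    event_times: np.ndarray
    event_deltas: np.ndarray
    duration: float
    condition: str = "none"

    def sizes(self) -> np.ndarray:
        """Population size immediately after each event."""
        return 1 + np.cumsum(self.event_deltas, dtype=np.int64)

    @property
    def final_size(self) -> int:
        return int(1 + self.event_deltas.sum())

    def size_at(self, t) -> np.ndarray:
        """Piecewise-constant size at forward time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        sizes = np.concatenate(([1], self.sizes()))
        idx = np.searchsorted(self.event_times, t, side="right")
        out = sizes[idx]
        return out if out.ndim else int(out)

    def to_tsv(self, path_or_buf) -> None:
        """Write columns ``time, event, popsize_after`` as TSV."""
        sizes = self.sizes()
        own = isinstance(path_or_buf, str)
        buf = open(path_or_buf, "w") if own else path_or_buf
        try:
            buf.write("time\tevent\tpopsize_after\n")
            for t, d, n in zip(self.event_times, self.event_deltas, sizes):
                buf.write(f"{t:.12g}\t{'birth' if d > 0 else 'death'}\t{n}\n")
        finally:
            if own:
                buf.close()


@dataclass
class SimulatedTree:
    """Full BD genealogy, including extinct branches.

    Each node is a maximal unbranched lineage segment: created at
    ``birth_time`` (0 for the root), terminated at ``end_time`` by a split
    (two children), a death, or the present ``T``.  Extant tips are the
    leaves with ``end_time == T``.
    """

    parent: np.ndarray
    birth_time: np.ndarray
    end_time: np.ndarray
    duration: float
    extant: np.ndarray = field(repr=False)  # node indices of extant tips

    @property
    def n_extant(self) -> int:
        return len(self.extant)

    def children_lists(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def to_newick(self) -> str:
        """Serialize with branch lengths; extant tips labelled ``t1..tn``."""
        kids = self.children_lists()
        labels = {int(node): f"t{k + 1}" for k, node in enumerate(self.extant)}
        out = io.StringIO()
        # iterative post-order to avoid recursion limits on deep trees
        stack: list[tuple[int, bool]] = [(0, False)]
        while stack:
            node, done = stack.pop()
            if node == -1:  # comma marker between sibling subtrees
                out.write(",")
                continue
            blen = self.end_time[node] - self.birth_time[node]
            if not kids[node]:
                out.write(f"{labels.get(node, '')}:{blen:.12g}")
                continue
            if not done:
                out.write("(")
                stack.append((node, True))
                left, right = kids[node]
                # emit left first: push right then a comma marker then left
                stack.append((right, False))
                stack.append((-1, False))
                stack.append((left, False))
            else:
                out.write(f"):{blen:.12g}")
        return out.getvalue() + ";"


def _simulate_events(params: BDParams, draws: _Draws, track_tree: bool):
    """One unconditioned forward run; returns (times, deltas, tree arrays)."""
    lam, mu, T = params.birth_rate, params.death_rate, params.origin_time
    total = lam + mu
    p_birth = lam / total
    times: list[float] = []
    deltas: list[int] = []
    t, n = 0.0, 1
    if track_tree:
        parent = [-1]
        btime = [0.0]
        etime = [T]
        alive = [0]
    while n > 0:
        e, u = draws.next_pair()
        t += e / (n * total)
        if t > T:
            break
        if u < p_birth:
            times.append(t)
            deltas.append(1)
            if track_tree:
                i = int(u / p_birth * n)  # reuse u: uniform on [0, p_birth)
                i = min(i, n - 1)
                p = alive[i]
                etime[p] = t
                parent.append(p)
                btime.append(t)
                etime.append(T)
                a = len(parent) - 1
                parent.append(p)
                btime.append(t)
                etime.append(T)
                alive[i] = a
                alive.append(a + 1)
            n += 1
        else:
            times.append(t)
            deltas.append(-1)
            if track_tree:
                frac = (u - p_birth) / (1.0 - p_birth)
                i = min(int(frac * n), n - 1)
                etime[alive[i]] = t
                alive[i] = alive[-1]
                alive.pop()
            n -= 1
    tree = None
    if track_tree:
        tree = (parent, btime, etime, alive)
    return times, deltas, n, tree


def _accepted(n_final: int, condition: str) -> bool:
    if condition == "none":
        return True
    if condition == "survival":
        return n_final >= 1
    if condition == "at_least_two_at_T":
        return n_final >= 2
    raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


def simulate_trajectory(
    params: BDParams, condition: str = "survival", rng_seed=0
) -> Trajectory:
    """Simulate one trajectory satisfying ``condition`` (by rejection)."""
    _accepted(1, condition)  # validate condition string
    draws = _Draws(_as_rng(rng_seed))
    for _ in range(_MAX_REJECTIONS):
        times, deltas, n_final, _ = _simulate_events(params, draws, False)
        if _accepted(n_final, condition):
            return Trajectory(
                np.asarray(times), np.asarray(deltas, dtype=np.int8),
                params.origin_time, condition,
            )
    raise RuntimeError(
        f"rejection guard tripped after {_MAX_REJECTIONS} attempts "
        f"(condition={condition!r}, params={params})"
    )


def simulate_trajectories(
    params: BDParams, n: int, condition: str = "survival", rng_seed=0
):
    """Simulate ``n`` conditioned trajectories; returns ``(list, n_attempts)``.

    Replicate ``k`` is drawn from seed ``rng_seed + k`` when an integer seed
    is given, so ensembles are reproducible element-wise.
    """
    out = []
    attempts = 0
    for k in range(n):
        seed = rng_seed + k if isinstance(rng_seed, int) else rng_seed
        draws = _Draws(_as_rng(seed))
        for _ in range(_MAX_REJECTIONS):
            attempts += 1
            times, deltas, n_final, _ = _simulate_events(params, draws, False)
            if _accepted(n_final, condition):
                out.append(
                    Trajectory(
                        np.asarray(times), np.asarray(deltas, dtype=np.int8),
                        params.origin_time, condition,
                    )
                )
                break
        else:
            raise RuntimeError("rejection guard tripped")
    return out, attempts


def simulate_tree(
    params: BDParams, condition: str = "at_least_two_at_T", rng_seed=0
) -> SimulatedTree:
    """Simulate one full BD genealogy satisfying ``condition``."""
    _accepted(1, condition)
    draws = _Draws(_as_rng(rng_seed))
    for _ in range(_MAX_REJECTIONS):
        _times, _deltas, n_final, tree = _simulate_events(params, draws, True)
        if _accepted(n_final, condition):
            parent, btime, etime, alive = tree
            return SimulatedTree(
                np.asarray(parent, dtype=np.int64),
                np.asarray(btime),
                np.asarray(etime),
                params.origin_time,
                np.asarray(sorted(alive), dtype=np.int64),
            )
    raise RuntimeError(
        f"rejection guard tripped after {_MAX_REJECTIONS} attempts "
        f"(condition={condition!r}, params={params})"
    )


def sample_pair_coalescence(tree: SimulatedTree, rng_seed=0) -> float:
    """Backward coalescence time of two uniformly chosen extant tips.

    The divergence event of the pair is the split terminating their most
    recent common ancestral segment; the returned ``tau`` is ``T`` minus that
    forward split time, so ``tau`` lies in ``(0, T]``.
    """
    if tree.n_extant < 2:
        raise ValueError("need at least two extant tips to sample a pair")
    rng = _as_rng(rng_seed)
    i, j = rng.choice(tree.n_extant, size=2, replace=False)
    x, y = int(tree.extant[i]), int(tree.extant[j])
    ancestors = set()
    while x != -1:
        ancestors.add(x)
        x = int(tree.parent[x])
    while y not in ancestors:
        y = int(tree.parent[y])
    return tree.duration - float(tree.end_time[y])
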