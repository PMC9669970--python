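"""Network graphs: populations plus per-connection weighted synapse groups.

A :class:`NetworkGraph` is a list of named populations (each with its own
LIF constants and, optionally, ring coordinates) and a list of
:class:`ConnectionGroup` objects.  A connection group collects every
synapse of one type between one (pre, post) population pair, stored in a
CSR-like layout indexed by the local presynaptic neuron.  Per-connection
weights are realized (jittered) at build time, so a graph plus a seed is a
complete description of a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from zlib import crc32

import numpy as np

from .params import InvalidArgumentError, NeuronParams, SynapseSpec


def seed_for(master_seed: int, label: str) -> np.random.SeedSequence:
    """Derive a labeled, reproducible child seed from a master seed.

    Independent streams per label keep sub-experiments (each drive entry,
    each connectivity draw) individually reproducible under one master seed.
    """
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, crc32(label.encode())])


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(seed_for(master_seed, label))


@dataclass
class Population:
    name: str
    size: int
    params: NeuronParams
    start: int = 0  # global id offset, assigned by NetworkGraph
    coords: np.ndarray | None = None  # 0-based lattice coordinates, if any

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise InvalidArgumentError(f"population {self.name!r} must have size > 0")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if len(self.coords) != self.size:
                raise InvalidArgumentError("coords length must equal population size")
            if len(np.unique(self.coords)) != self.size:
                raise InvalidArgumentError("coords must be unique")

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def gids(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class ConnectionGroup:
    """All synapses of one type from population ``pre`` to ``post``.

    ``indptr``/``post_gids``/``weights`` form a CSR layout over the local
    presynaptic index: the targets of local neuron ``j`` are
    ``post_gids[indptr[j]:indptr[j+1]]`` with matching per-connection
    weights (pA).
    """

    name: str
    pre: str
    post: str
    indptr: np.ndarray
    post_gids: np.ndarray
    weights: np.ndarray
    spec: SynapseSpec

    @property
    def n_connections(self) -> int:
        return len(self.post_gids)

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def in_degrees(self, n_total: int) -> np.ndarray:
        return np.bincount(self.post_gids, minlength=n_total)


class NetworkGraph:
    """Populations plus realized connection groups."""

    def __init__(self) -> None:
        self.populations: dict[str, Population] = {}
        self.groups: list[ConnectionGroup] = []
        self._n = 0

    # -- construction -----------------------------------------------------
    def add_population(
        self,
        name: str,
        size: int,
        params: NeuronParams,
        coords: np.ndarray | None = None,
    ) -> Population:
        if name in self.populations:
            raise InvalidArgumentError(f"duplicate population {name!r}")
        pop = Population(name, size, params, start=self._n, coords=coords)
        self.populations[name] = pop
        self._n += size
        return pop

    def connect(
        self,
        name: str,
        pre: str,
        post: str,
        pre_local: np.ndarray,
        post_local: np.ndarray,
        weights: np.ndarray,
        spec: SynapseSpec,
    ) -> ConnectionGroup:
        """Register connections given as parallel (pre, post, weight) arrays.

        ``pre_local``/``post_local`` are local indices within the named
        populations.  Autapses are forbidden.
        """
        ppre, ppost = self.populations[pre], self.populations[post]
        pre_local = np.asarray(pre_local, dtype=np.int64)
        post_local = np.asarray(post_local, dtype=np.int64)
        weights = np.asarray(weights, dtype=np.float64)
        if not (len(pre_local) == len(post_local) == len(weights)):
            raise InvalidArgumentError("pre, post and weight arrays must align")
        if len(pre_local) and (
            pre_local.min() < 0
            or pre_local.max() >= ppre.size
            or post_local.min() < 0
            or post_local.max() >= ppost.size
        ):
            raise InvalidArgumentError(f"connection {name!r} references missing neurons")
        if pre == post and np.any(pre_local == post_local):
            raise InvalidArgumentError(f"autapses are not allowed (group {name!r})")
        order = np.argsort(pre_local, kind="stable")
        pre_local = pre_local[order]
        indptr = np.searchsorted(pre_local, np.arange(ppre.size + 1))
        group = ConnectionGroup(
            name=name,
            pre=pre,
            post=post,
            indptr=indptr.astype(np.int64),
            post_gids=(post_local[order] + ppost.start).astype(np.int32),
            weights=weights[order],
            spec=spec,
        )
        self.groups.append(group)
        return group

    # -- inspection -------------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self._n

    def population_of(self, gids: np.ndarray) -> np.ndarray:
        """Map global ids to population labels."""
        starts = np.array([p.start for p in self.populations.values()])
        names = np.array(list(self.populations.keys()))
        idx = np.searchsorted(starts, np.asarray(gids), side="right") - 1
        return names[idx]

    def group(self, name: str) -> ConnectionGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def groups_from(self, pre: str) -> list[ConnectionGroup]:
        return [g for g in self.groups if g.pre == pre]

    def summary(self) -> str:
        lines = [f"{self._n} neurons in {len(self.populations)} populations"]
        for p in self.populations.values():
            lines.append(f"  {p.name}: {p.size}")
        for g in self.groups:
            lines.append(f"  {g.name}: {g.n_connections} connections ({g.spec.kind})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Connectivity sampling helpers
# ---------------------------------------------------------------------------

def jittered_weights(rng: np.random.Generator, mean: float, n: int, sd_frac: float = 0.1) -> np.ndarray:
    """Gaussian per-connection weights, SD = ``sd_frac``·|mean|, sign-clipped.

    Excitatory weights are clipped below at 0, inhibitory above at 0, so a
    connection can never flip sign.
    """
    if sd_frac == 0 or mean == 0:
        return np.full(n, float(mean))
    w = rng.normal(mean, sd_frac * abs(mean), size=n)
    return np.clip(w, 0.0, None) if mean > 0 else np.clip(w, None, 0.0)


def bernoulli_pairs(
    rng: np.random.Generator,
    n_pre: int,
    n_post: int,
    p: float,
    no_autapse: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """All (pre, post) pairs kept independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise InvalidArgumentError(f"connection probability {p} outside [0, 1]")
    if p == 0.0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    if p == 1.0:
        pre = np.repeat(np.arange(n_pre), n_post)
        post = np.tile(np.arange(n_post), n_pre)
    else:
        # chunk over presynaptic neurons to bound memory
        pres, posts = [], []
        chunk = max(1, int(4e6) // max(n_post, 1))
        for lo in range(0, n_pre, chunk):
            hi = min(lo + chunk, n_pre)
            mask = rng.random((hi - lo, n_post)) < p
            i, j = np.nonzero(mask)
            pres.append(i + lo)
            posts.append(j)
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
    if no_autapse:
        keep = pre != post
        pre, post = pre[keep], post[keep]
    return pre, post


def fixed_indegree_pairs(
    rng: np.random.Generator,
    n_pre: int,
    n_post: int,
    k: int,
    no_autapse: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Each postsynaptic neuron draws ``k`` distinct presynaptic partners."""
    if k > n_pre:
        raise InvalidArgumentError(f"in-degree {k} exceeds source population size {n_pre}")
    if k == n_pre and not no_autapse:
        pre = np.tile(np.arange(n_pre), n_post)
        post = np.repeat(np.arange(n_post), k)
        return pre, post
    pres = np.empty((n_post, k), dtype=np.int64)
    for j in range(n_post):
        pool = rng.permutation(n_pre)
        if no_autapse and j < n_pre:
            pool = pool[pool != j]
        pres[j] = pool[:k]
    return pres.ravel(), np.repeat(np.arange(n_post), k)
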