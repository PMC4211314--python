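"""Hypernetwork data structures and incremental encoding.

A *hypernetwork* is a layered associative memory for multivariate categorical
events.  Each incoming event instance ``X = (x_0, ..., x_{d-1})`` is subsampled
into *hyperedges* — position-anchored subsets of ``k`` attribute–value pairs —
which are deduplicated against the store and connected to the edges at adjacent
anchors by *links*.  A link accumulates a co-occurrence count ``l`` that maps to
a weight through a half sigmoid

    phi(l) = 2 / (1 + exp(-l / C)) - 1  =  tanh(l / (2 C)),

so a never-seen pairing has weight 0, early co-occurrences are emphasised, and
the weight approaches (never reaches) 1.  ``C`` modulates the slope: a larger
``C`` slows saturation.

Edges never decay and links never lose count, which is what makes the model's
"no false negative" guarantee exact: anything encoded stays retrievable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "MISSING",
    "Token",
    "EventInstance",
    "EdgeConfig",
    "Hyperedge",
    "Link",
    "Hypernetwork",
    "EncodeReport",
    "CapacityReport",
    "sample_edges",
    "link_weight",
    "log_link_weight_complement",
    "encode",
    "connectivity",
    "capacity_bound",
]

#: Sentinel for a missing attribute value.  ``None`` never equals a category
#: token (tokens are ints or strings), so it is safe as the reserved sentinel.
MISSING = None

Token = Union[int, str]

RING = "ring"
LINE = "line"

FIXED = "fixed"
RANDOM_ORDER = "random_order"
RANDOM_COMBINATION = "random_combination"

_MODES = (FIXED, RANDOM_ORDER, RANDOM_COMBINATION)
_TOPOLOGIES = (RING, LINE)


class EventInstance(tuple):
    """One d-dimensional categorical event; entries may be :data:`MISSING`.

    A plain tuple subclass: instances hash and compare by value, so the
    exact-match registry and the truth labelling are set lookups.  Any plain
    tuple is accepted wherever an ``EventInstance`` is expected.
    """

    __slots__ = ()

    @property
    def d(self) -> int:
        return len(self)

    @property
    def is_complete(self) -> bool:
        return MISSING not in self

    def missing_indices(self) -> Tuple[int, ...]:
        return tuple(i for i, v in enumerate(self) if v is MISSING)


@dataclass(frozen=True)
class EdgeConfig:
    """How instances are subsampled into hyperedges.

    mode
        ``"fixed"``: every edge has order ``k`` and covers contiguous
        attributes from its anchor.  ``"random_order"``: the order ``k_t`` is
        drawn uniformly from ``order_range`` per anchor *on every sampling
        call* (this is what makes repeated encodings enrich the memory and
        repeated observations vary).  ``"random_combination"``: the anchor
        attribute plus ``k_t - 1`` attributes drawn without replacement from
        the rest.
    topology
        ``"ring"`` for contextual data (anchors wrap around the attribute
        circle), ``"line"`` for serial data (no wrap).
    repetitions
        Encoding passes per instance (the study-duration "repeated encoding").
    observation_count
        Default number of repeated judgments for one probe.
    """

    mode: str = FIXED
    k: Optional[int] = None
    order_range: Optional[Tuple[int, int]] = None
    topology: str = RING
    repetitions: int = 1
    observation_count: int = 1

    def validate(self, d: int) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown edge mode {self.mode!r}")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.observation_count < 1:
            raise ValueError("observation_count must be >= 1")
        if d < 3:
            raise ValueError("attribute dimension must be >= 3")
        if self.mode == FIXED:
            if self.k is None:
                raise ValueError("fixed mode requires k")
            if not 2 <= self.k <= d - 1:
                raise ValueError(f"order k={self.k} outside [2, {d - 1}]")
        else:
            if self.order_range is None:
                raise ValueError(f"{self.mode} mode requires order_range")
            r1, r2 = self.order_range
            if not 2 <= r1 <= r2 <= d - 1:
                raise ValueError(f"order_range {self.order_range} outside 2 <= r1 <= r2 <= {d - 1}")

    def with_repetitions(self, repetitions: int) -> "EdgeConfig":
        return replace(self, repetitions=repetitions)

    def with_observations(self, observation_count: int) -> "EdgeConfig":
        return replace(self, observation_count=observation_count)

    def label(self) -> str:
        if self.mode == FIXED:
            return f"fixed(k={self.k})"
        r1, r2 = self.order_range
        short = "rand_order" if self.mode == RANDOM_ORDER else "rand_comb"
        return f"{short}({r1},{r2})"


class Hyperedge(NamedTuple):
    """A position-anchored subset of attribute-value pairs.

    Identity is the full triple ``(anchor, attrs, vals)``: two edges with the
    same content at different anchors are distinct, because the network places
    edges in per-dimension layers.  ``attrs`` is sorted ascending and ``vals``
    aligned with it (canonical form, so equal content hashes equally).
    """

    anchor: int
    attrs: Tuple[int, ...]
    vals: Tuple[Token, ...]

    @property
    def order(self) -> int:
        return len(self.attrs)


class Link(NamedTuple):
    """A weighted co-occurrence connection between edges at adjacent anchors."""

    from_edge: Hyperedge
    to_edge: Hyperedge
    count: int
    weight: float


class EncodeReport(NamedTuple):
    new_edges: int
    new_links: int
    updated_links: int


class CapacityReport(NamedTuple):
    """Eq.-style scalability bound: possible edges vs possible instances."""

    edge_bound: int
    instance_count: int
    ratio: float


def link_weight(count: int, C: float) -> float:
    """Half-sigmoid link weight ``2/(1+exp(-count/C)) - 1`` in ``[0, 1)``.

    Strictly increasing in ``count`` with value 0 at count 0 and supremum 1.0;
    a larger ``C`` gives a smaller weight at fixed count.  Computed as
    ``tanh(count / 2C)`` (the same function, numerically stable).
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return math.tanh(count / (2.0 * C))


def log_link_weight_complement(count: int, C: float) -> float:
    """``log(1 - link_weight(count, C))``, evaluated in log-space.

    The weight saturates to 1.0 in double precision once ``count/C`` exceeds a
    few tens, so comparisons near the supremum are impossible on the raw
    values.  The log-complement ``log 2 - count/C - log(1 + exp(-count/C))``
    stays exact over the whole float range and is strictly decreasing wherever
    the weight is strictly increasing.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    x = count / C
    return math.log(2.0) - x - math.log1p(math.exp(-x))


def _draw_order(config: EdgeConfig, rng: np.random.Generator) -> int:
    r1, r2 = config.order_range
    if r1 == r2:
        return r1
    return int(rng.integers(r1, r2 + 1))


def sample_edges(
    instance: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Hyperedge]:
    """Subsample one instance into anchored hyperedges.

    Ring topology yields exactly ``d`` edges, one per anchor ``t``, covering
    attributes ``t .. t+k_t-1`` (mod d).  Line topology never wraps: fixed
    order ``k`` anchors ``t = 0 .. d-k``; random_order anchors ``t = 0 .. d-2``
    with the drawn order clamped to ``d - t``; random_combination anchors one
    edge per attribute like the ring.  Random draws are resampled on every
    call, so probes under random modes activate different edges each
    observation.

    ``instance`` may contain :data:`MISSING` (partial probes); encoding
    rejects those separately.
    """
    d = len(instance)
    config.validate(d)
    if config.mode != FIXED and rng is None:
        raise ValueError("random edge modes require an rng")
    ring = config.topology == RING

    edges: List[Hyperedge] = []
    if config.mode == FIXED:
        k = config.k
        anchors = range(d) if ring else range(d - k + 1)
        for t in anchors:
            if ring:
                attrs = tuple(sorted((t + i) % d for i in range(k)))
            else:
                attrs = tuple(range(t, t + k))
            edges.append(Hyperedge(t, attrs, tuple(instance[a] for a in attrs)))
    elif config.mode == RANDOM_ORDER:
        anchors = range(d) if ring else range(d - 1)
        for t in anchors:
            k = _draw_order(config, rng)
            if not ring:
                k = min(k, d - t)
            if ring:
                attrs = tuple(sorted((t + i) % d for i in range(k)))
            else:
                attrs = tuple(range(t, t + k))
            edges.append(Hyperedge(t, attrs, tuple(instance[a] for a in attrs)))
    else:  # RANDOM_COMBINATION — anchor attribute plus k-1 others, any position
        for t in range(d):
            k = _draw_order(config, rng)
            others = [a for a in range(d) if a != t]
            chosen = rng.choice(len(others), size=k - 1, replace=False)
            attrs = tuple(sorted([t] + [others[i] for i in chosen]))
            edges.append(Hyperedge(t, attrs, tuple(instance[a] for a in attrs)))
    return edges


class Hypernetwork:
    """The layered store of hyperedges and weighted links.

    Edges live in per-anchor layers; links connect edges at *adjacent* anchors
    (consecutive, plus the wrap pair anchor ``d-1 -> 0`` on a ring).  Only
    counts are stored — weights are derived state, recomputed from ``C`` on
    demand, so reloading a snapshot under a different ``C`` rescales every
    weight consistently.

    ``encoded_set`` is an exact-match registry of complete instances kept for
    ground-truth bookkeeping (hit/false-alarm labelling); judgment never
    consults it.
    """

    def __init__(
        self,
        d: int,
        topology: str = RING,
        C: float = 10.0,
        attribute_names: Optional[Sequence[str]] = None,
    ):
        if topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {topology!r}")
        if C <= 0:
            raise ValueError("C must be positive")
        if d < 3:
            raise ValueError("d must be >= 3")
        self.d = d
        self.topology = topology
        self.C = float(C)
        self.attribute_names = (
            list(attribute_names) if attribute_names is not None else [f"a{i}" for i in range(d)]
        )
        if len(self.attribute_names) != d:
            raise ValueError("attribute_names length must equal d")
        self._edges: List[set] = [set() for _ in range(d)]
        # (anchor, attr, val) -> list of edges containing that pair
        self._index: dict = {}
        # (anchor, v0, v1) -> edges whose first two window values are v0, v1;
        # kept only while every stored edge is a contiguous window, and used as
        # a fast activation path for contiguous probes
        self._prefix2: dict = {}
        self._contiguous_only = True
        # (edge_at_t, edge_at_next) -> count
        self._links: dict = {}
        # link adjacency lists, for route search
        self._succ: dict = {}
        self._pred: dict = {}
        self.n_encoded = 0
        self.encoded_set: set = set()
        self.observed_alphabets: List[set] = [set() for _ in range(d)]

    # -- scale ----------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._edges)

    @property
    def n_links(self) -> int:
        return len(self._links)

    def connectivity(self) -> float:
        n_e = self.n_edges
        return len(self._links) / n_e if n_e else 0.0

    def edges_at(self, anchor: int) -> frozenset:
        return frozenset(self._edges[anchor])

    def iter_links(self) -> Iterator[Link]:
        for (ea, eb), count in self._links.items():
            yield Link(ea, eb, count, link_weight(count, self.C))

    # -- mutation -------------------------------------------------------------

    def _window_attrs(self, anchor: int, order: int) -> Tuple[int, ...]:
        if self.topology == RING:
            return tuple(sorted((anchor + i) % self.d for i in range(order)))
        return tuple(range(anchor, anchor + order))

    def _add_edge(self, edge: Hyperedge) -> bool:
        layer = self._edges[edge.anchor]
        if edge in layer:
            return False
        layer.add(edge)
        for attr, val in zip(edge.attrs, edge.vals):
            self._index.setdefault((edge.anchor, attr, val), []).append(edge)
        if self._contiguous_only:
            if edge.attrs == self._window_attrs(edge.anchor, edge.order):
                at = dict(zip(edge.attrs, edge.vals))
                a0 = edge.anchor
                a1 = (edge.anchor + 1) % self.d if self.topology == RING else edge.anchor + 1
                self._prefix2.setdefault((edge.anchor, at[a0], at[a1]), []).append(edge)
            else:
                self._contiguous_only = False
                self._prefix2.clear()
        return True

    def _bump_link(self, ea: Hyperedge, eb: Hyperedge) -> bool:
        key = (ea, eb)
        new = key not in self._links
        if new:
            self._links[key] = 1
            self._succ.setdefault(ea, []).append(eb)
            self._pred.setdefault(eb, []).append(ea)
        else:
            self._links[key] += 1
        return new

    def encode(
        self,
        instance: Sequence[Token],
        config: EdgeConfig,
        rng: Optional[np.random.Generator] = None,
    ) -> EncodeReport:
        """Sample, deduplicate, connect, and weight one complete instance.

        Runs ``config.repetitions`` sampling passes.  Every pass increments the
        link count of each adjacent-anchor pair it samples (creating absent
        links at count 1), so re-encoding shifts weights up the sigmoid; the
        store never shrinks.
        """
        inst = tuple(instance)
        if len(inst) != self.d:
            raise ValueError(f"instance has {len(inst)} attributes, network expects {self.d}")
        if MISSING in inst:
            raise ValueError("cannot encode an instance with missing values")
        config.validate(self.d)
        if config.topology != self.topology:
            raise ValueError(
                f"config topology {config.topology!r} does not match network {self.topology!r}"
            )
        new_edges = new_links = updated = 0
        for _ in range(config.repetitions):
            edges = sample_edges(inst, config, rng)
            for e in edges:
                new_edges += self._add_edge(e)
            for ea, eb in _adjacent_pairs(edges, self.topology):
                if self._bump_link(ea, eb):
                    new_links += 1
                else:
                    updated += 1
        self.n_encoded += 1
        self.encoded_set.add(inst)
        for i, v in enumerate(inst):
            self.observed_alphabets[i].add(v)
        return EncodeReport(new_edges, new_links, updated)

    # -- lookup ---------------------------------------------------------------

    def has_link(self, ea: Hyperedge, eb: Hyperedge) -> bool:
        return (ea, eb) in self._links

    def link_count(self, ea: Hyperedge, eb: Hyperedge) -> int:
        return self._links.get((ea, eb), 0)

    def link_weight_between(self, ea: Hyperedge, eb: Hyperedge) -> float:
        count = self._links.get((ea, eb), 0)
        return link_weight(count, self.C) if count else 0.0

    def activated(self, probe_edge: Hyperedge, N_m: int = 0) -> List[Hyperedge]:
        """Memory edges at the probe edge's anchor that the probe activates.

        When every stored edge is a contiguous window and the probe edge is
        one too, candidates come from a single index lookup: every stored
        window at the anchor shares the probe's first one or two window
        positions, so the first-two-values bucket (both observed) or the
        first-observed-position list is a complete candidate superset.
        Otherwise candidates are the union over the probe's (attribute,
        value) pairs — activation needs at least one matched value, so any
        activated edge shares an indexed pair.  Candidates are then filtered
        by the full match/no-mismatch rule.
        """
        from .inference import activate  # local import to avoid a cycle

        anchor = probe_edge.anchor
        if self._contiguous_only and probe_edge.attrs == self._window_attrs(
            anchor, probe_edge.order
        ):
            at = dict(zip(probe_edge.attrs, probe_edge.vals))
            step = (lambda i: (anchor + i) % self.d) if self.topology == RING else (
                lambda i: anchor + i
            )
            v0, v1 = at[step(0)], at[step(1)]
            if v0 is not MISSING and v1 is not MISSING:
                cands = self._prefix2.get((anchor, v0, v1), ())
            else:
                cands = ()
                for i in range(probe_edge.order):
                    v = at[step(i)]
                    if v is not MISSING:
                        cands = self._index.get((anchor, step(i), v), ())
                        break
            return [e for e in cands if activate(probe_edge, e, N_m)]
        seen: dict = {}
        for attr, val in zip(probe_edge.attrs, probe_edge.vals):
            if val is MISSING:
                continue
            for e in self._index.get((anchor, attr, val), ()):
                seen[e] = None
        return [e for e in seen if activate(probe_edge, e, N_m)]

    # -- bookkeeping ----------------------------------------------------------

    def state_signature(self) -> Tuple[int, int, int, int]:
        """Cheap fingerprint of the store, for read-only-operation checks."""
        return (
            self.n_edges,
            len(self._links),
            sum(self._links.values()),
            hash(frozenset(self._links.items())),
        )

    def copy(self) -> "Hypernetwork":
        dup = Hypernetwork(self.d, self.topology, self.C, self.attribute_names)
        dup._edges = [set(s) for s in self._edges]
        dup._index = {k: list(v) for k, v in self._index.items()}
        dup._prefix2 = {k: list(v) for k, v in self._prefix2.items()}
        dup._contiguous_only = self._contiguous_only
        dup._links = dict(self._links)
        dup._succ = {k: list(v) for k, v in self._succ.items()}
        dup._pred = {k: list(v) for k, v in self._pred.items()}
        dup.n_encoded = self.n_encoded
        dup.encoded_set = set(self.encoded_set)
        dup.observed_alphabets = [set(s) for s in self.observed_alphabets]
        return dup


def _adjacent_pairs(edges: List[Hyperedge], topology: str) -> Iterator[Tuple[Hyperedge, Hyperedge]]:
    """Consecutive-anchor pairs of one sampling pass, plus the ring wrap pair."""
    ordered = sorted(edges, key=lambda e: e.anchor)
    for a, b in zip(ordered, ordered[1:]):
        yield a, b
    if topology == RING and len(ordered) > 2:
        yield ordered[-1], ordered[0]


def encode(
    network: Hypernetwork,
    instance: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
) -> EncodeReport:
    """Module-level alias of :meth:`Hypernetwork.encode`."""
    return network.encode(instance, config, rng)


def connectivity(network: Hypernetwork) -> float:
    """Total links over total edges (0 for an empty network)."""
    return network.connectivity()


def capacity_bound(category_counts: Sequence[int], k: int) -> CapacityReport:
    """Scalability of the edge store versus the instance space.

    With per-attribute alphabet sizes ``C_i`` and fixed order ``k``, the number
    of possible anchored contiguous edges is ``sum_t prod_{i=t..t+k-1} C_i``
    (ring indexing, mod d), against ``prod_i C_i`` possible instances.  In the
    uniform case the ratio equals ``d * C**(k-d)``, which is below 1 whenever
    ``k < d`` and ``C`` is appreciably larger than ``d`` — the memory's edge
    vocabulary grows far slower than the instance space it can represent.
    """
    d = len(category_counts)
    if not 1 <= k <= d:
        raise ValueError(f"order k={k} outside [1, {d}]")
    if any(c < 1 for c in category_counts):
        raise ValueError("category counts must be positive")
    edge_bound = 0
    for t in range(d):
        prod = 1
        for i in range(k):
            prod *= category_counts[(t + i) % d]
        edge_bound += prod
    instance_count = 1
    for c in category_counts:
        instance_count *= c
    return CapacityReport(edge_bound, instance_count, edge_bound / instance_count)
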