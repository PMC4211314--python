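"""Familiarity judgment and pattern completion over an encoded hypernetwork.

A complete probe is subsampled into edges exactly like an encoding pass, each
probe edge *activates* the memory edges at its anchor that share at least one
matched value and no mismatched value, and the probe is judged **old** iff one
activated edge can be selected per anchor such that every adjacent pair is
linked — a closed route on a ring, a full chain on a line.  Because edges and
links never decay, anything encoded always yields its own route: the model
permits false alarms (recombined routes) but no misses.

The weight-based side attaches a graded *similarity* ``S``: the maximum over
closed routes of the sum of link weights along the route, or — when no route
closes — the best partial-chain sum with inactivated adjacencies contributing
zero.  ``S`` drives the ROC analysis.

A partial probe (missing values) goes through the same machinery; each closed
route consistent with the observed values induces a completed instance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    MISSING,
    RING,
    EdgeConfig,
    Hyperedge,
    Hypernetwork,
    Token,
    sample_edges,
)

__all__ = [
    "JudgmentResult",
    "completion_flags",
    "CompletionResult",
    "activate",
    "find_routes",
    "judge",
    "similarity",
    "complete_pattern",
    "repeated_observation_judge",
    "DEFAULT_ROUTE_CAP",
]

#: Guard against pathological route explosions; hitting it logs a warning.
DEFAULT_ROUTE_CAP = 10_000

Route = Tuple[Hyperedge, ...]


@dataclass
class JudgmentResult:
    """Old/new verdict plus the weight-based similarity evidence.

    ``verdict == "old"`` iff ``closed_routes`` is non-empty; ``similarity`` is
    the max route similarity when old, otherwise the best open-chain score.
    """

    verdict: str
    similarity: float
    activated: Dict[int, List[Hyperedge]]
    closed_routes: List[Route]
    route_similarities: List[float]

    @property
    def is_old(self) -> bool:
        return self.verdict == "old"


@dataclass
class CompletionResult:
    """Completions of a partial probe, with completeness/expectation flags.

    ``complete`` — some consistent closed route exists (any completion).
    ``expected`` — the true original instance is among the completions (only
    meaningful when ground truth was supplied).
    """

    completions: FrozenSet[tuple]
    complete: bool
    expected: Optional[bool]
    n_routes: int


def activate(probe_edge: Hyperedge, memory_edge: Hyperedge, N_m: int = 0) -> int:
    """Edge activation: 1 iff matches > ``N_m`` and mismatches == 0.

    Only attributes present in *both* edges with a non-missing probe value are
    compared; attributes absent from one edge (different lengths or different
    combinations) and missing probe slots count as neither match nor mismatch.
    """
    if probe_edge.anchor != memory_edge.anchor:
        raise ValueError("activation compares edges at the same anchor")
    matched = 0
    pa, pv = probe_edge.attrs, probe_edge.vals
    ma, mv = memory_edge.attrs, memory_edge.vals
    i = j = 0
    while i < len(pa) and j < len(ma):
        if pa[i] == ma[j]:
            v = pv[i]
            if v is not MISSING:
                if v == mv[j]:
                    matched += 1
                else:
                    return 0
            i += 1
            j += 1
        elif pa[i] < ma[j]:
            i += 1
        else:
            j += 1
    return 1 if matched > N_m else 0


def _route_similarity(network: Hypernetwork, route: Route, ring: bool) -> float:
    s = 0.0
    for ea, eb in zip(route, route[1:]):
        s += network.link_weight_between(ea, eb)
    if ring and len(route) > 2:
        s += network.link_weight_between(route[-1], route[0])
    return s


def find_routes(
    network: Hypernetwork,
    activated: Dict[int, List[Hyperedge]],
    probe: Sequence[Token],
    cap: int = DEFAULT_ROUTE_CAP,
    *,
    require_total: bool = False,
    total_base: Optional[Sequence[int]] = None,
    max_routes: Optional[int] = None,
) -> List[Route]:
    """Enumerate closed routes through the activated edges.

    A route selects exactly one activated edge per surviving anchor such that
    every cyclically adjacent surviving anchor pair is linked and the selected
    edges are mutually consistent: any attribute covered by two of them
    carries the same value.  Anchors whose probe edge carries no observed
    value at all (possible only for partial probes) contribute no evidence and
    are skipped; an anchor with observed values but no activated edge aborts
    the search — its evidence contradicts the memory.  The consistency
    assignment is seeded with the probe's observed values — equivalent to the
    mutual rule, because every attribute's own anchor edge is
    activation-forced to match the probe there — which lets inconsistent
    candidates be pruned before the backtracking starts.  All complete routes
    are returned, up to ``cap``.

    ``activated`` maps surviving anchors to their activated edges; all-missing
    anchors must be left out of the map (``judge``/``complete_pattern`` do
    this).

    ``require_total`` keeps only routes that induce a complete instance: the
    attributes in ``total_base`` (default: the probe's observed attributes)
    plus the selected edges' attributes must cover every dimension.
    ``max_routes`` stops the search early.  Both are existence-check hooks
    used by the experiment harnesses.
    """
    anchors = sorted(activated)
    if not anchors:
        return []
    assignment: Dict[int, Token] = {
        i: v for i, v in enumerate(probe) if v is not MISSING
    }

    def agrees_seed(edge: Hyperedge) -> bool:
        for a, v in zip(edge.attrs, edge.vals):
            bound = assignment.get(a, MISSING)
            if bound is not MISSING and bound != v:
                return False
        return True

    cand_lists: Dict[int, List[Hyperedge]] = {}
    for a in anchors:
        cands = [e for e in activated[a] if agrees_seed(e)]
        if not cands:
            return []
        cand_lists[a] = cands
    cand_sets = {a: set(v) for a, v in cand_lists.items()}

    ring = network.topology == RING
    d = network.d
    arcs, circular = _split_arcs(anchors, d, ring)

    # Search plan: per arc, scan the anchor with the fewest candidates and
    # grow the chain along link successors/predecessors — link constraints are
    # then implicit in candidate generation instead of post-hoc filtering.
    plan: List[Tuple[int, str, Optional[int]]] = []  # (anchor, kind, source step)
    closures: List[Tuple[int, int]] = []
    pos_of: Dict[int, int] = {}
    for arc in sorted(arcs, key=lambda arc: min(len(cand_lists[a]) for a in arc)):
        pivot_idx = min(range(len(arc)), key=lambda i: len(cand_lists[arc[i]]))
        if circular:
            arc = arc[pivot_idx:] + arc[:pivot_idx]
            pivot_idx = 0
        plan.append((arc[pivot_idx], "scan", None))
        pos_of[arc[pivot_idx]] = len(plan) - 1
        for i in range(pivot_idx + 1, len(arc)):
            plan.append((arc[i], "succ", pos_of[arc[i - 1]]))
            pos_of[arc[i]] = len(plan) - 1
        for i in range(pivot_idx - 1, -1, -1):
            plan.append((arc[i], "pred", pos_of[arc[i + 1]]))
            pos_of[arc[i]] = len(plan) - 1
        if circular:
            closures.append((pos_of[arc[-1]], pos_of[arc[0]]))

    links = network._links
    succ = network._succ
    pred = network._pred
    routes: List[Route] = []
    chosen: List[Optional[Hyperedge]] = [None] * len(plan)
    anchor_of_step = [p[0] for p in plan]
    stop_at = cap if max_routes is None else min(cap, max_routes)
    if require_total and total_base is None:
        total_base = [i for i, v in enumerate(probe) if v is not MISSING]

    def backtrack(i: int) -> None:
        if len(routes) >= stop_at:
            return
        if i == len(plan):
            if require_total:
                cover = set(total_base)
                for e in chosen:
                    cover.update(e.attrs)
                if len(cover) < network.d:
                    return
            for x, y in closures:
                if (chosen[x], chosen[y]) not in links:
                    return
            by_anchor = sorted(zip(anchor_of_step, chosen))
            routes.append(tuple(e for _, e in by_anchor))
            return
        anchor, kind, src = plan[i]
        if kind == "scan":
            gen: Sequence[Hyperedge] = cand_lists[anchor]
        elif kind == "succ":
            pool = cand_sets[anchor]
            gen = [e for e in succ.get(chosen[src], ()) if e in pool]
        else:
            pool = cand_sets[anchor]
            gen = [e for e in pred.get(chosen[src], ()) if e in pool]
        for e in gen:
            newly: List[int] = []
            ok = True
            for a, v in zip(e.attrs, e.vals):
                bound = assignment.get(a, MISSING)
                if bound is MISSING:
                    assignment[a] = v
                    newly.append(a)
                elif bound != v:
                    ok = False
                    break
            if ok:
                chosen[i] = e
                backtrack(i + 1)
                chosen[i] = None
            for a in newly:
                del assignment[a]

    backtrack(0)
    if max_routes is None and len(routes) >= cap:
        warnings.warn(
            f"route enumeration hit the cap of {cap}; similarity and completions "
            "are computed over the enumerated subset",
            RuntimeWarning,
            stacklevel=2,
        )
    return routes


def _split_arcs(anchors: List[int], d: int, ring: bool) -> Tuple[List[List[int]], bool]:
    """Maximal runs of cyclically adjacent anchors; circular iff the full ring."""
    arcs: List[List[int]] = [[anchors[0]]]
    for a in anchors[1:]:
        if a == arcs[-1][-1] + 1:
            arcs[-1].append(a)
        else:
            arcs.append([a])
    if ring and len(arcs) == 1 and len(anchors) == d:
        return arcs, True
    if ring and len(arcs) > 1 and (arcs[-1][-1] + 1) % d == arcs[0][0]:
        arcs[0] = arcs.pop() + arcs[0]
    return arcs, False


def _best_open_chain(
    network: Hypernetwork, activated: Dict[int, List[Hyperedge]], ring: bool
) -> float:
    """Best activated-link weight sum when no route closes.

    Dynamic program over the anchor sequence selecting at most one activated
    edge per anchor: an adjacency with a stored link contributes its weight,
    an inactivated adjacency contributes zero (so the best selection may span
    breaks).  On a full ring the wrap adjacency also counts, handled by
    pinning each candidate at the smallest layer in turn.
    """
    anchors = sorted(activated)
    if not anchors:
        return 0.0
    pred = network._pred

    def sweep(seq, pinned):
        best = 0.0
        carry = 0.0  # best score of any selection ending at an earlier layer
        prev: Dict[Hyperedge, float] = {}
        last: Dict[Hyperedge, float] = {}
        for idx, a in enumerate(seq):
            layer = [pinned] if (idx == 0 and pinned is not None) else activated[a]
            cur: Dict[Hyperedge, float] = {}
            for e in layer:
                score = carry
                for pe in pred.get(e, ()):
                    s = prev.get(pe)
                    if s is not None:
                        cand = s + network.link_weight_between(pe, e)
                        if cand > score:
                            score = cand
                cur[e] = score
                if score > best:
                    best = score
            carry = max(carry, max(cur.values(), default=0.0))
            prev = cur
            last = cur
        return best, last

    full_ring = ring and len(anchors) == network.d and all(activated[a] for a in anchors)
    if not full_ring:
        return sweep(anchors, None)[0]
    start = min(range(len(anchors)), key=lambda i: len(activated[anchors[i]]))
    seq = anchors[start:] + anchors[:start]
    best = 0.0
    for e0 in activated[seq[0]]:
        run_best, last = sweep(seq, e0)
        wrap_best = max(
            (s + network.link_weight_between(e, e0) for e, s in last.items()),
            default=0.0,
        )
        best = max(best, run_best, wrap_best)
    return best


def similarity(
    network: Hypernetwork,
    probe: Sequence[Token],
    activated: Dict[int, List[Hyperedge]],
    routes: List[Route],
) -> float:
    """Weight-sum similarity ``S``: max over closed routes, else best open chain."""
    ring = network.topology == RING and len(activated) == network.d
    if routes:
        return max(_route_similarity(network, r, ring) for r in routes)
    return _best_open_chain(network, activated, ring)


def _activation_map(
    network: Hypernetwork, probe_edges: List[Hyperedge], N_m: int
) -> Dict[int, List[Hyperedge]]:
    """Activated edges per anchor, skipping evidence-free (all-missing) edges."""
    return {
        e.anchor: network.activated(e, N_m)
        for e in probe_edges
        if any(v is not MISSING for v in e.vals)
    }


def judge(
    network: Hypernetwork,
    probe: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    N_m: int = 0,
    route_cap: int = DEFAULT_ROUTE_CAP,
) -> JudgmentResult:
    """Old/new familiarity judgment of a complete probe.

    The probe is sampled with the same configuration as encoding (random modes
    re-draw orders), activated, and judged old iff a closed route exists.
    Judgment never mutates the network.
    """
    probe = tuple(probe)
    if len(probe) != network.d:
        raise ValueError(f"probe has {len(probe)} attributes, network expects {network.d}")
    if MISSING in probe:
        raise ValueError("probe has missing values; use complete_pattern for partial inputs")
    config.validate(network.d)
    probe_edges = sample_edges(probe, config, rng)
    activated = _activation_map(network, probe_edges, N_m)
    routes = find_routes(network, activated, probe, cap=route_cap)
    ring = network.topology == RING and len(activated) == network.d
    sims = [_route_similarity(network, r, ring) for r in routes]
    s = max(sims) if routes else _best_open_chain(network, activated, ring)
    return JudgmentResult("old" if routes else "new", s, activated, routes, sims)


def repeated_observation_judge(
    network: Hypernetwork,
    probe: Sequence[Token],
    config: EdgeConfig,
    count: int,
    rng: Optional[np.random.Generator] = None,
    *,
    N_m: int = 0,
    route_cap: int = DEFAULT_ROUTE_CAP,
) -> JudgmentResult:
    """Judge a probe up to ``count`` times; old only if every observation is old.

    Under random edge configurations each observation re-samples the probe, so
    a recombination false alarm can fail to close on a later draw — repeated
    observation corrects false alarms while a truly encoded probe stays old
    (its encoding-time route closes under every draw).  Observation stops at
    the first "new".  The reported similarity is the maximum over the
    observations performed.
    """
    if count < 1:
        raise ValueError("observation count must be >= 1")
    best_sim = 0.0
    res: Optional[JudgmentResult] = None
    for _ in range(count):
        res = judge(network, probe, config, rng, N_m=N_m, route_cap=route_cap)
        best_sim = max(best_sim, res.similarity)
        if res.verdict == "new":
            break
    return JudgmentResult(
        res.verdict, best_sim, res.activated, res.closed_routes, res.route_similarities
    )




def completion_flags(
    network: Hypernetwork,
    partial: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[Sequence[Token]] = None,
    *,
    N_m: int = 0,
) -> Tuple[bool, Optional[bool]]:
    """Completeness and expectation of a partial probe, by existence checks.

    Equivalent to running :func:`complete_pattern` and testing whether the
    completion set is non-empty / contains the truth, but each flag is a
    first-total-route existence search instead of a full enumeration: the
    expectation check seeds the route consistency with the *entire* true
    instance, so only truth-consistent edges survive pruning.  The probe is
    sampled once and both checks share its activation map.
    """
    partial = tuple(partial)
    if len(partial) != network.d:
        raise ValueError(f"input has {len(partial)} attributes, network expects {network.d}")
    missing = [i for i, v in enumerate(partial) if v is MISSING]
    if not missing or len(missing) == len(partial):
        raise ValueError("input must be partially (not fully) observed")
    config.validate(network.d)
    probe_edges = sample_edges(partial, config, rng)
    activated = _activation_map(network, probe_edges, N_m)
    observed = [i for i, v in enumerate(partial) if v is not MISSING]
    complete = bool(
        find_routes(network, activated, partial, require_total=True, max_routes=1)
    )
    expected: Optional[bool] = None
    if truth is not None:
        if not complete:
            expected = False
        else:
            expected = bool(
                find_routes(
                    network,
                    activated,
                    tuple(truth),
                    require_total=True,
                    total_base=observed,
                    max_routes=1,
                )
            )
    return complete, expected


def complete_pattern(
    network: Hypernetwork,
    partial: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[Sequence[Token]] = None,
    *,
    N_m: int = 0,
    route_cap: int = DEFAULT_ROUTE_CAP,
) -> CompletionResult:
    """Reconstruct complete instances from a partial probe.

    Probe edges carry the missing slots; activation uses the partial-data rule
    (at least one matched value, no mismatched value, missing slots neutral).
    Every consistent closed route induces a completion: the observed values
    plus the values read off the selected memory edges, which cover every
    attribute by construction of the anchoring.
    """
    partial = tuple(partial)
    if len(partial) != network.d:
        raise ValueError(f"input has {len(partial)} attributes, network expects {network.d}")
    missing = [i for i, v in enumerate(partial) if v is MISSING]
    if not missing:
        raise ValueError("input is fully observed; use judge for complete probes")
    if len(missing) == len(partial):
        raise ValueError("input is fully missing; nothing to anchor a completion on")
    config.validate(network.d)
    probe_edges = sample_edges(partial, config, rng)
    activated = _activation_map(network, probe_edges, N_m)
    routes = find_routes(network, activated, partial, cap=route_cap)
    completions = set()
    for route in routes:
        values: Dict[int, Token] = {i: v for i, v in enumerate(partial) if v is not MISSING}
        for e in route:
            for a, v in zip(e.attrs, e.vals):
                values[a] = v
        completion = tuple(values.get(i, MISSING) for i in range(network.d))
        if MISSING not in completion:
            completions.add(completion)
    expected = (tuple(truth) in completions) if truth is not None else None
    return CompletionResult(frozenset(completions), bool(completions), expected, len(routes))


def _judge_scored(
    network: Hypernetwork,
    probe: Sequence[Token],
    config: EdgeConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    N_m: int = 0,
) -> Tuple[bool, float]:
    """Verdict and exact similarity of a complete probe, without enumeration.

    For a complete probe, every route-eligible candidate agrees with the probe
    on all its attributes, so mutual consistency is automatic and the maximum
    closed-route weight sum is a layered dynamic program over the anchor
    sequence (per starting candidate on a ring).  Equivalent to
    :func:`judge` but exact even where route enumeration would hit its cap;
    used by the experiment harnesses.
    """
    probe = tuple(probe)
    if len(probe) != network.d:
        raise ValueError(f"probe has {len(probe)} attributes, network expects {network.d}")
    if MISSING in probe:
        raise ValueError("probe has missing values; use complete_pattern for partial inputs")
    config.validate(network.d)
    probe_edges = sample_edges(probe, config, rng)
    activated = _activation_map(network, probe_edges, N_m)
    anchors = sorted(activated)
    ring = network.topology == RING and len(anchors) == network.d

    def agrees(edge: Hyperedge) -> bool:
        for a, v in zip(edge.attrs, edge.vals):
            if probe[a] != v:
                return False
        return True

    cand: Dict[int, List[Hyperedge]] = {}
    for a in anchors:
        cand[a] = [e for e in activated[a] if agrees(e)]
        if not cand[a]:
            return False, _best_open_chain(network, activated, ring)
    pred = network._pred
    weight = network.link_weight_between

    def run(seq: List[int], starts: List[Hyperedge]) -> Optional[Dict[Hyperedge, float]]:
        prev: Dict[Hyperedge, float] = {e: 0.0 for e in starts}
        for a in seq[1:]:
            cur: Dict[Hyperedge, float] = {}
            for e in cand[a]:
                best = None
                for pe in pred.get(e, ()):
                    s = prev.get(pe)
                    if s is not None:
                        w = s + weight(pe, e)
                        if best is None or w > best:
                            best = w
                if best is not None:
                    cur[e] = best
            if not cur:
                return None
            prev = cur
        return prev

    if not ring:
        final = run(anchors, cand[anchors[0]])
        if final is None:
            return False, _best_open_chain(network, activated, ring)
        return True, max(final.values())
    start = min(range(len(anchors)), key=lambda i: len(cand[anchors[i]]))
    seq = anchors[start:] + anchors[:start]
    best_total: Optional[float] = None
    for e0 in cand[seq[0]]:
        final = run(seq, [e0])
        if final is None:
            continue
        for e, s in final.items():
            if network.has_link(e, e0):
                total = s + weight(e, e0)
                if best_total is None or total > best_total:
                    best_total = total
    if best_total is None:
        return False, _best_open_chain(network, activated, ring)
    return True, best_total
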