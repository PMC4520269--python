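"""Collision-calibrated merging of multi-tool SV call sets.

The problem: several callers report largely overlapping sets of insertions
and deletions, with breakpoint and length errors that depend on the
calling technique.  Two calls are *compatible* when their canonical
breakpoints lie within ``max_breakpoint_distance`` bp and their lengths
within ``max_length_deviation`` bp of each other.  Compatible calls form
the edges of a *call graph*; each maximal clique of that graph is a set of
calls that pairwise agree and is collapsed into one consensus call.

False-merge control
-------------------
Merging thresholds must be tight enough that unrelated calls rarely
collide by chance.  For two call sets of sizes ``K1`` and ``K2`` on a
genome of length ``G``, with a per-pair collision window of ``L`` bp, the
probability that *any* cross-set pair collides is

    P = 1 - (1 - L/G)^(K1*K2)  ~=  1 - exp(-K1*K2*L/G).

``random_merge_probability`` evaluates both forms (the exact one in log
space), ``calibrate_distance_threshold`` inverts the exact form to the
largest window with ``P <= alpha``, and ``empirical_collision_probability``
estimates the same quantity by Monte-Carlo placement for validation.

Window convention: the closed form charges each of the ``K1*K2`` pairs a
collision probability of ``L/G``, i.e. ``L`` is the *total width* of the
collision window.  A symmetric breakpoint-distance criterion ``|a-b| <= D``
on integer coordinates admits ``2*D + 1`` offsets, so the window matching a
criterion distance ``D`` is ``collision_window(D) = 2*D + 1``.  As a rule
of thumb, criteria of a few tens of bp keep ``P`` below 0.01 for realistic
call-set sizes on megabase-to-gigabase genomes.

Consensus rule: split-read callers place breakpoints far more accurately
than internal-segment callers, so the consensus coordinates are taken from
the clique member whose tool has the best (lowest) accuracy rank; among
equal-rank members the lower median is used.  Reciprocal overlap is
deliberately *not* offered as a merge criterion (see
:func:`svclique.model.max_offset_for_reciprocal_overlap` for why).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ConfigError, ConsistencyError
from .model import (
    DEFAULT_CRITERIA,
    MergeCriteria,
    SVCall,
    SVType,
    ToolProfile,
)
from .vcf_io import CallSet

__all__ = [
    "MergeNullModel",
    "CallGraph",
    "MergedCall",
    "collision_window",
    "random_merge_probability",
    "empirical_collision_probability",
    "calibrate_distance_threshold",
    "compatible",
    "pairwise_criteria",
    "build_call_graph",
    "enumerate_maximal_cliques",
    "merge_cliques",
    "merge_callsets",
    "merged_to_callset",
]


def collision_window(max_breakpoint_distance: int) -> int:
    """Total collision-window width ``L`` (in bp) corresponding to a
    symmetric breakpoint-distance criterion ``|a - b| <= D``."""
    return 2 * max_breakpoint_distance + 1


def random_merge_probability(
    k1: int, k2: int, genome_length: int, window: int, method: str = "exact"
) -> float:
    """Probability that any cross-pair from two random call sets collides.

    Parameters
    ----------
    k1, k2
        Sizes of the two call sets (calls within the size range under
        comparison).
    genome_length
        Total genome length ``G`` in bp (sum over contigs).
    window
        Collision-window width ``L`` in bp; for a symmetric distance
        criterion ``D`` use :func:`collision_window`.
    method
        ``"exact"`` evaluates ``1 - (1 - L/G)^(K1*K2)`` in log space;
        ``"approx"`` the exponential form ``1 - exp(-K1*K2*L/G)``.
    """
    if genome_length < 1:
        raise ValueError(f"genome_length must be >= 1, got {genome_length}")
    if not 0 <= window <= genome_length:
        raise ValueError(
            f"window must be in [0, genome_length], got {window}"
        )
    if k1 < 0 or k2 < 0:
        raise ValueError("call-set sizes must be >= 0")
    n_pairs = k1 * k2
    if n_pairs == 0 or window == 0:
        return 0.0
    x = window / genome_length
    if method == "exact":
        if x >= 1.0:
            return 1.0
        return -math.expm1(n_pairs * math.log1p(-x))
    if method == "approx":
        return -math.expm1(-n_pairs * x)
    raise ValueError(f"unknown method '{method}'")


def empirical_collision_probability(
    k1: int,
    k2: int,
    genome_length: int,
    max_breakpoint_distance: int,
    n_replicates: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> float:
    """Monte-Carlo estimate of the cross-set collision probability.

    Places ``k1`` and ``k2`` breakpoints independently and uniformly on
    ``[1, G]`` and tests whether any cross-set pair satisfies
    ``|a - b| <= D``.  The matching closed form is
    ``random_merge_probability(k1, k2, G, collision_window(D))``.
    """
    hits = 0
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        a = rng.integers(1, genome_length + 1, size=(m, k1))
        b = rng.integers(1, genome_length + 1, size=(m, k2))
        dist = np.abs(a[:, :, None] - b[:, None, :])
        hits += int((dist.min(axis=(1, 2)) <= max_breakpoint_distance).sum())
        done += m
    return hits / n_replicates


def calibrate_distance_threshold(
    k1: int, k2: int, genome_length: int, alpha: float
) -> int:
    """Largest integer window ``L`` with exact collision probability
    ``P(L) <= alpha`` (so ``P(L) <= alpha < P(L+1)`` unless ``L == G``)."""
    if alpha < 0 or alpha >= 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if k1 * k2 < 1:
        raise ValueError("k1*k2 must be >= 1 to calibrate a threshold")
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    n_pairs = k1 * k2
    # invert (1 - L/G)^n >= 1 - alpha  =>  L <= G * (1 - (1-alpha)^(1/n))
    window = int(math.floor(genome_length * -math.expm1(math.log1p(-alpha) / n_pairs)))
    window = max(0, min(window, genome_length))
    # float safety: nudge onto the exact boundary
    while window > 0 and random_merge_probability(k1, k2, genome_length, window) > alpha:
        window -= 1
    while (
        window < genome_length
        and random_merge_probability(k1, k2, genome_length, window + 1) <= alpha
    ):
        window += 1
    return window


@dataclass(frozen=True)
class MergeNullModel:
    """The symbols of the collision null model, bundled for reporting."""

    genome_length: int
    window: int
    k1: int
    k2: int

    @property
    def probability(self) -> float:
        return random_merge_probability(self.k1, self.k2, self.genome_length, self.window)


# ---------------------------------------------------------------------------
# compatibility and the call graph


def compatible(a: SVCall, b: SVCall, criteria: MergeCriteria) -> bool:
    """True iff two calls may describe the same event under ``criteria``.

    Requires same chromosome and type, breakpoints within
    ``max_breakpoint_distance``, and lengths within
    ``max_length_deviation``; a call with unknown length satisfies the
    length criterion vacuously.
    """
    if a.chrom != b.chrom or a.sv_type is not b.sv_type:
        return False
    if abs(a.breakpoint - b.breakpoint) > criteria.max_breakpoint_distance:
        return False
    if a.length is None or b.length is None:
        return True
    return abs(a.length - b.length) <= criteria.max_length_deviation


def pairwise_criteria(profile_a: ToolProfile, profile_b: ToolProfile) -> MergeCriteria:
    """Element-wise maximum of the two tools' thresholds: a pair is judged
    by the more permissive limit, so a split-read/IS pair inherits the IS
    tool's relaxed criteria."""
    ca, cb = profile_a.default_criteria, profile_b.default_criteria
    return MergeCriteria(
        max(ca.max_breakpoint_distance, cb.max_breakpoint_distance),
        max(ca.max_length_deviation, cb.max_length_deviation),
    )


@dataclass
class CallGraph:
    """Compatibility graph over calls.

    ``order`` lists node ids sorted by (chrom, breakpoint, id); ``adj`` is a
    symmetric adjacency map without self-loops.  Edges never join calls on
    different chromosomes or an INS to a DEL.
    """

    calls: dict[str, SVCall]
    order: list[str]
    adj: dict[str, set[str]]

    @classmethod
    def from_edges(
        cls, calls: Iterable[SVCall], edges: Iterable[tuple[str, str]]
    ) -> "CallGraph":
        """Build directly from an explicit edge list (used by tests)."""
        calls = {c.call_id: c for c in calls}
        adj: dict[str, set[str]] = {cid: set() for cid in calls}
        for u, v in edges:
            if u == v:
                continue
            adj[u].add(v)
            adj[v].add(u)
        order = sorted(calls, key=lambda cid: (calls[cid].chrom, calls[cid].breakpoint, cid))
        return cls(calls=calls, order=order, adj=adj)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adj.values()) // 2


def build_call_graph(
    callsets: Sequence[CallSet],
    profiles: Optional[dict[str, ToolProfile]] = None,
    global_criteria: Optional[MergeCriteria] = None,
    min_size: int = 20,
    allow_same_tool: bool = True,
) -> CallGraph:
    """Construct the call graph from one or more call sets.

    Per-pair thresholds come from :func:`pairwise_criteria` over the tools'
    profiles, unless ``global_criteria`` overrides them for every pair.
    Calls with a known length below ``min_size`` are excluded.  Pairs from
    the same tool are eligible by default (unifying a tool's duplicate or
    fragmented calls); set ``allow_same_tool=False`` to restrict edges to
    cross-tool pairs.

    Construction sweeps the breakpoint-sorted calls with a window of the
    widest applicable distance threshold, so runtime is near-linear for
    typical call densities.
    """
    if global_criteria is None:
        if profiles is None:
            raise ConfigError("either per-tool profiles or global_criteria required")
        for cs in callsets:
            if cs.tool_id not in profiles:
                raise ConfigError(f"no profile for tool '{cs.tool_id}'")

    calls: dict[str, SVCall] = {}
    for cs in callsets:
        for call in cs:
            if call.length is not None and call.length < min_size:
                continue
            node = call
            if node.call_id in calls:
                node = node.with_id(f"{node.tool_id}:{node.call_id}")
                if node.call_id in calls:
                    raise ConsistencyError(f"duplicate call id '{call.call_id}'")
            calls[node.call_id] = node

    def crit(a: SVCall, b: SVCall) -> MergeCriteria:
        if global_criteria is not None:
            return global_criteria
        return pairwise_criteria(profiles[a.tool_id], profiles[b.tool_id])

    if global_criteria is not None:
        max_dist = global_criteria.max_breakpoint_distance
    else:
        max_dist = max(
            (p.default_criteria.max_breakpoint_distance for p in profiles.values()),
            default=0,
        )

    order = sorted(calls, key=lambda cid: (calls[cid].chrom, calls[cid].breakpoint, cid))
    adj: dict[str, set[str]] = {cid: set() for cid in calls}

    # group sorted nodes by (chrom, sv_type) and sweep
    groups: dict[tuple[str, SVType], list[str]] = {}
    for cid in order:
        c = calls[cid]
        groups.setdefault((c.chrom, c.sv_type), []).append(cid)
    for members in groups.values():
        n = len(members)
        for i in range(n):
            a = calls[members[i]]
            for j in range(i + 1, n):
                b = calls[members[j]]
                if b.breakpoint - a.breakpoint > max_dist:
                    break
                if not allow_same_tool and a.tool_id == b.tool_id:
                    continue
                if compatible(a, b, crit(a, b)):
                    adj[a.call_id].add(b.call_id)
                    adj[b.call_id].add(a.call_id)
    return CallGraph(calls=calls, order=order, adj=adj)


# ---------------------------------------------------------------------------
# maximal cliques


def enumerate_maximal_cliques(graph: CallGraph) -> list[frozenset[str]]:
    """All maximal cliques of the call graph, deterministically ordered by
    (leftmost member, then sorted member ids).

    Bron-Kerbosch with pivoting; recursion depth is bounded by the largest
    clique, and the breakpoint-sorted, window-limited structure of call
    graphs keeps candidate sets small.
    """
    idx = {cid: i for i, cid in enumerate(graph.order)}
    adj = graph.adj
    out: list[frozenset[str]] = []

    def bk(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            out.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: (len(adj[u] & p), -idx[u]))
        for v in sorted(p - adj[pivot], key=idx.__getitem__):
            bk(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bk(set(), set(graph.order), set())
    out.sort(key=lambda c: (min(idx[m] for m in c), tuple(sorted(c))))
    return out


# ---------------------------------------------------------------------------
# clique -> consensus


@dataclass(frozen=True)
class MergedCall:
    """A maximal clique collapsed into one consensus call."""

    merge_id: str
    member_ids: tuple[str, ...]
    chrom: str
    sv_type: SVType
    consensus_breakpoint: int
    consensus_length: Optional[int]
    support: int
    representative_tool: str
    tools: tuple[str, ...]


def _lower_median(values: Sequence) -> object:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _consensus(members: list[SVCall], rank: dict[str, int]) -> tuple[int, Optional[int], str]:
    best = min(rank[m.tool_id] for m in members)
    cands = sorted(
        (m for m in members if rank[m.tool_id] == best),
        key=lambda m: (m.breakpoint, m.call_id),
    )
    rep = cands[(len(cands) - 1) // 2]
    lengths = [m.length for m in cands if m.length is not None]
    if rep.length is not None and len(cands) == 1:
        length: Optional[int] = rep.length
    elif lengths:
        length = _lower_median(lengths)
    else:
        # no best-rank member knows a length; fall back to any member
        lengths = [m.length for m in members if m.length is not None]
        length = _lower_median(lengths) if lengths else None
    return rep.breakpoint, length, rep.tool_id


def merge_cliques(
    cliques: Sequence[frozenset[str]],
    graph: CallGraph,
    profiles: Optional[dict[str, ToolProfile]] = None,
    policy: str = "greedy_disjoint",
) -> list[MergedCall]:
    """Collapse maximal cliques into consensus calls.

    Consensus coordinates come from the member whose tool has the best
    (lowest) accuracy rank; ties are broken by the lower median of the
    tied members' breakpoints/lengths.  Without profiles all tools rank
    equally, i.e. plain lower-median consensus.

    ``policy="greedy_disjoint"`` (default) processes cliques largest-first
    (ties: leftmost first) and removes already-consumed members, so every
    call contributes to at most one output; ``"all_cliques"`` emits every
    maximal clique as-is (a call shared by several cliques then appears in
    each).
    """
    if policy not in ("greedy_disjoint", "all_cliques"):
        raise ConfigError(f"unknown conflict policy '{policy}'")
    rank = {
        tid: (profiles[tid].accuracy_rank if profiles else 0)
        for tid in {c.tool_id for c in graph.calls.values()}
    }
    for cl in cliques:
        for cid in cl:
            if cid not in graph.calls:
                raise ConsistencyError(f"clique references unknown call '{cid}'")

    idx = {cid: i for i, cid in enumerate(graph.order)}
    member_sets: list[list[str]]
    if policy == "greedy_disjoint":
        ordered = sorted(
            cliques,
            key=lambda c: (-len(c), min(idx[m] for m in c), tuple(sorted(c))),
        )
        consumed: set[str] = set()
        member_sets = []
        for cl in ordered:
            remaining = [cid for cid in cl if cid not in consumed]
            if not remaining:
                continue
            consumed.update(remaining)
            member_sets.append(remaining)
    else:
        member_sets = [list(cl) for cl in cliques]

    merged: list[MergedCall] = []
    for ids in member_sets:
        members = [graph.calls[cid] for cid in ids]
        bp, length, rep_tool = _consensus(members, rank)
        merged.append(
            MergedCall(
                merge_id="",
                member_ids=tuple(sorted(ids, key=lambda cid: (idx[cid]))),
                chrom=members[0].chrom,
                sv_type=members[0].sv_type,
                consensus_breakpoint=bp,
                consensus_length=length,
                support=len(members),
                representative_tool=rep_tool,
                tools=tuple(sorted({m.tool_id for m in members})),
            )
        )
    merged.sort(key=lambda m: (m.chrom, m.consensus_breakpoint, m.member_ids))
    return [replace(m, merge_id=f"merged:{i}") for i, m in enumerate(merged)]


def merge_callsets(
    callsets: Sequence[CallSet],
    profiles: Optional[dict[str, ToolProfile]] = None,
    global_criteria: Optional[MergeCriteria] = DEFAULT_CRITERIA,
    min_size: int = 20,
    policy: str = "greedy_disjoint",
    allow_same_tool: bool = True,
) -> list[MergedCall]:
    """End-to-end convenience: graph, cliques, consensus.

    When ``profiles`` is given, per-tool criteria are used and
    ``global_criteria`` must be explicitly set to ``None`` (or it
    overrides them).
    """
    if profiles is not None and global_criteria is DEFAULT_CRITERIA:
        global_criteria = None
    graph = build_call_graph(
        callsets,
        profiles=profiles,
        global_criteria=global_criteria,
        min_size=min_size,
        allow_same_tool=allow_same_tool,
    )
    cliques = enumerate_maximal_cliques(graph)
    return merge_cliques(cliques, graph, profiles=profiles, policy=policy)


def merged_to_callset(merged: Sequence[MergedCall], tool_id: str = "merged") -> CallSet:
    """View merged calls as a CallSet (e.g. for benchmarking)."""
    calls = [
        SVCall(
            call_id=m.merge_id,
            tool_id=tool_id,
            chrom=m.chrom,
            sv_type=m.sv_type,
            breakpoint=m.consensus_breakpoint,
            length=m.consensus_length,
        )
        for m in merged
    ]
    return CallSet(tool_id=tool_id, calls=calls)
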