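"""Core domain types and breakpoint geometry for structural-variant calls.

Coordinate conventions
----------------------
All genomic coordinates are 1-based and inclusive (VCF-compatible).  A
deletion removing bases ``left .. right`` has ``length = right - left + 1``
and is anchored by a single canonical coordinate, its *center point*
``(left + right) // 2`` (floor of the arithmetic mean, so even spans round
down deterministically).  An insertion is anchored at the base position
after which the new sequence is inserted.  A center point plus a length
uniquely determines a deletion, which is why the pair (breakpoint, length)
is the canonical representation used everywhere downstream.

Events shorter than 20 bp are the territory of ordinary small-indel
pipelines; they are parsed but excluded from merging and evaluation by
default (callers pass ``min_size=0`` to retain them).  Events above 50 kb
fall outside the canonical size-class ladder and are reported in an
"above-range" bucket by the benchmark layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional


class SVType(str, enum.Enum):
    """Event type. Calls are INS or DEL; truth annotations may also be MIX
    (a substitution: ``del_len`` reference bases replaced by ``ins_len``
    new bases)."""

    INS = "INS"
    DEL = "DEL"
    MIX = "MIX"


class MethodClass(str, enum.Enum):
    """Breakpoint-accuracy family of an SV caller.

    Split-read methods align reads across the breakpoint and resolve it to
    base-pair precision; internal-segment (paired-end) methods infer events
    from insert-size deviations and place breakpoints imprecisely; hybrids
    sit in between.
    """

    SPLIT_READ = "split_read"
    INTERNAL_SEGMENT = "internal_segment"
    HYBRID = "hybrid"


def center_point(left: int, right: int) -> int:
    """Canonical single-coordinate anchor of the span ``[left, right]``.

    Returns ``floor((left + right) / 2)``; for even spans this rounds down,
    which keeps the result integral and deterministic.

    Raises
    ------
    ValueError
        If ``right < left``.
    """
    if right < left:
        raise ValueError(f"right ({right}) must be >= left ({left})")
    return (left + right) // 2


@dataclass(frozen=True)
class SizeClass:
    """One rung of the canonical event-size ladder (bp, both ends inclusive)."""

    lower: int
    upper: int
    label: str

    def __contains__(self, length: int) -> bool:
        return self.lower <= length <= self.upper


#: The canonical five-class ladder used for stratified reporting.
SIZE_CLASSES: tuple[SizeClass, ...] = (
    SizeClass(20, 49, "20-49"),
    SizeClass(50, 99, "50-99"),
    SizeClass(100, 249, "100-249"),
    SizeClass(250, 999, "250-999"),
    SizeClass(1000, 50000, "1000-50000"),
)

#: Bucket label for events above the ladder (retained in merging, reported
#: separately by the benchmark layer).
ABOVE_RANGE_LABEL = ">50000"
#: Bucket label for predictions whose length estimate is unknown.
UNSIZED_LABEL = "unsized"


def size_class_of(length: int) -> Optional[SizeClass]:
    """Map an event length to its size class.

    Returns ``None`` for lengths below 20 bp or above 50 kb (outside the
    ladder).  Raises ``ValueError`` for non-positive lengths.
    """
    if length < 1:
        raise ValueError(f"event length must be positive, got {length}")
    for cls in SIZE_CLASSES:
        if length in cls:
            return cls
    return None


def max_offset_for_reciprocal_overlap(
    len_a: int, len_b: int, fraction: float
) -> Optional[int]:
    """Largest start-coordinate offset ``d >= 0`` between two deletions of
    lengths ``len_a`` and ``len_b`` such that their overlap still covers at
    least ``fraction`` of *both* events.

    This utility exists to document why reciprocal overlap is a poor merge
    criterion: the tolerated breakpoint deviation scales with event length
    (5000 bp for two 10 kb deletions at 50% reciprocal overlap) instead of
    with the caller's actual breakpoint accuracy, and there is no overlap
    notion for insertions at all.  It is not used by the merge engine.

    Returns ``None`` when no non-negative offset achieves the required
    overlap (possible when the lengths are very different).
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("deletion lengths must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")

    eps = 1e-9

    def one_way(la: int, lb: int) -> Optional[int]:
        # interval a = [0, la), interval b = [d, d+lb), d >= 0
        need = fraction * max(la, lb)
        if min(la, lb) + eps < need:
            return None
        d = math.floor(la - need + eps)
        return d if d >= 0 else None

    candidates = [v for v in (one_way(len_a, len_b), one_way(len_b, len_a)) if v is not None]
    return max(candidates) if candidates else None


@dataclass(frozen=True)
class MergeCriteria:
    """Pairwise compatibility thresholds for two calls.

    ``max_breakpoint_distance`` bounds the distance between the calls'
    canonical breakpoints and ``max_length_deviation`` the difference of
    their predicted lengths.  The package defaults (50, 20) keep the
    probability of merging two random calls low for realistic call-set
    sizes and genome lengths (see :mod:`svclique.merge`).
    """

    max_breakpoint_distance: int = 50
    max_length_deviation: int = 20

    def __post_init__(self) -> None:
        if self.max_breakpoint_distance < 0 or self.max_length_deviation < 0:
            raise ValueError("merge criteria must be non-negative")


DEFAULT_CRITERIA = MergeCriteria(50, 20)

#: Recommended per-class criteria: tight for base-accurate split-read
#: callers, loose for internal-segment callers with fuzzy breakpoints.
METHOD_CLASS_CRITERIA: dict[MethodClass, MergeCriteria] = {
    MethodClass.SPLIT_READ: MergeCriteria(20, 10),
    MethodClass.HYBRID: MergeCriteria(50, 20),
    MethodClass.INTERNAL_SEGMENT: MergeCriteria(100, 100),
}

#: Default breakpoint-accuracy ranks (lower = more accurate).
METHOD_CLASS_RANK: dict[MethodClass, int] = {
    MethodClass.SPLIT_READ: 1,
    MethodClass.HYBRID: 2,
    MethodClass.INTERNAL_SEGMENT: 3,
}


@dataclass(frozen=True)
class ToolProfile:
    """Merging-relevant description of one SV caller."""

    tool_id: str
    method_class: MethodClass
    accuracy_rank: int
    default_criteria: MergeCriteria

    @classmethod
    def for_method(cls, tool_id: str, method_class: MethodClass) -> "ToolProfile":
        """Profile with the per-class default rank and criteria."""
        return cls(
            tool_id=tool_id,
            method_class=method_class,
            accuracy_rank=METHOD_CLASS_RANK[method_class],
            default_criteria=METHOD_CLASS_CRITERIA[method_class],
        )


@dataclass(frozen=True)
class SVCall:
    """One tool's predicted insertion or deletion.

    ``breakpoint`` is the canonical anchor: the insertion position for INS,
    the deletion center point for DEL.  ``left``/``right`` (DEL only) are
    the first and last deleted base when known.  ``length`` may be ``None``
    for callers that report insertions without a length estimate; such
    calls satisfy length criteria vacuously but never contribute a
    consensus length.
    """

    call_id: str
    tool_id: str
    chrom: str
    sv_type: SVType
    breakpoint: int
    length: Optional[int]
    left: Optional[int] = None
    right: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type not in (SVType.INS, SVType.DEL):
            raise ValueError(f"calls must be INS or DEL, got {self.sv_type}")
        if self.breakpoint < 1:
            raise ValueError(f"breakpoint must be >= 1, got {self.breakpoint}")
        if self.length is not None and self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.sv_type is SVType.INS and (self.left is not None or self.right is not None):
            raise ValueError("INS calls carry no left/right boundaries")
        if self.left is not None and self.right is not None:
            if self.length != self.right - self.left + 1:
                raise ValueError(
                    f"length {self.length} inconsistent with span "
                    f"[{self.left}, {self.right}]"
                )
            if self.breakpoint != center_point(self.left, self.right):
                raise ValueError(
                    f"breakpoint {self.breakpoint} is not the center of "
                    f"[{self.left}, {self.right}]"
                )

    @classmethod
    def deletion(
        cls, call_id: str, tool_id: str, chrom: str, left: int, right: int
    ) -> "SVCall":
        """Deletion from its boundary coordinates."""
        return cls(
            call_id=call_id,
            tool_id=tool_id,
            chrom=chrom,
            sv_type=SVType.DEL,
            breakpoint=center_point(left, right),
            length=right - left + 1,
            left=left,
            right=right,
        )

    @classmethod
    def insertion(
        cls, call_id: str, tool_id: str, chrom: str, position: int, length: Optional[int]
    ) -> "SVCall":
        """Insertion at ``position`` (base after which sequence is added)."""
        return cls(
            call_id=call_id,
            tool_id=tool_id,
            chrom=chrom,
            sv_type=SVType.INS,
            breakpoint=position,
            length=length,
        )

    def with_id(self, call_id: str) -> "SVCall":
        return replace(self, call_id=call_id)


def deletion_span(breakpoint: int, length: int) -> tuple[int, int]:
    """Invert the center-point convention: the unique ``(left, right)`` with
    ``right - left + 1 == length`` and ``(left + right) // 2 == breakpoint``."""
    left = breakpoint - (length - 1) // 2
    return left, left + length - 1


@dataclass(frozen=True)
class TruthEvent:
    """A validated/annotated event: insertion, deletion, or mixed
    (substitution) event.

    MIX events replace ``del_len`` reference bases with ``ins_len`` new
    bases; their *effective length* is the signed difference
    ``del_len - ins_len`` (positive = net deletion).  Callers confuse such
    events with plain indels of the same effective length, which is what
    the benchmark's mixed-event rescue accounts for.
    """

    event_id: str
    chrom: str
    ev_type: SVType
    breakpoint: int
    length: Optional[int] = None
    del_len: Optional[int] = None
    ins_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.breakpoint < 1:
            raise ValueError(f"breakpoint must be >= 1, got {self.breakpoint}")
        if self.ev_type is SVType.MIX:
            if self.del_len is None or self.ins_len is None:
                raise ValueError("MIX events need del_len and ins_len")
            if self.del_len < 0 or self.ins_len < 0:
                raise ValueError("del_len/ins_len must be >= 0")
            if self.del_len == 0 and self.ins_len == 0:
                raise ValueError("MIX event must delete or insert something")
        else:
            if self.length is None or self.length < 1:
                raise ValueError(f"{self.ev_type.value} truth events need length >= 1")

    @property
    def effective_length(self) -> Optional[int]:
        """Signed net length of a MIX event (positive = net deletion)."""
        if self.ev_type is not SVType.MIX:
            return None
        return self.del_len - self.ins_len  # type: ignore[operator]

    def ref_span(self) -> tuple[int, int]:
        """Reference bases occupied by the event (inclusive).

        Insertions (and MIX events with ``del_len == 0``) occupy the single
        anchor base."""
        if self.ev_type is SVType.DEL:
            return deletion_span(self.breakpoint, self.length)  # type: ignore[arg-type]
        if self.ev_type is SVType.MIX and self.del_len:
            return deletion_span(self.breakpoint, self.del_len)
        return self.breakpoint, self.breakpoint
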