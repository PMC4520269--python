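"""Synthetic references, truth SV sets, donor genomes, and virtual tools.

This module generates everything the merge and benchmark layers need
without external data: an i.i.d. random reference, a non-overlapping truth
set of insertions/deletions (and optional mixed events) across the
canonical size classes, a donor genome with those events implanted, and
"virtual tool" call sets that emulate the call-level behaviour of real SV
callers — split-read-like tools with near-base-pair breakpoint jitter,
internal-segment-like tools with coarse jitter, per-size-class detection
probabilities, and uniform random false positives.

Read-level simulation (read sampling, alignment, the callers themselves)
is intentionally not modelled: merging and benchmarking consume calls, so
the virtual-tool layer injects noise directly at the call level.  Every
operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, ConsistencyError
from .model import (
    SIZE_CLASSES,
    MethodClass,
    SVCall,
    SVType,
    SizeClass,
    ToolProfile,
    TruthEvent,
    center_point,
    deletion_span,
)
from .vcf_io import CallSet

__all__ = [
    "VirtualToolSpec",
    "DonorGenome",
    "generate_reference",
    "generate_truth",
    "implant_svs",
    "simulate_tool_calls",
    "benchmark_scenario",
]

_BASES = np.array(list("ACGT"))


def generate_reference(
    n_chroms: int,
    chrom_length: int,
    gc_fraction: float = 0.36,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. random reference sequences at the requested GC content.

    The default GC fraction of 0.36 is plant-like (Arabidopsis).  Output
    is a dict ``chrom name -> sequence`` and is deterministic per seed.
    """
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10000")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    probs = [at, gc, gc, at]
    return {
        f"chr{i + 1}": "".join(
            _BASES[rng.choice(4, size=chrom_length, p=probs)]
        )
        for i in range(n_chroms)
    }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def generate_truth(
    chrom_lengths: dict[str, int],
    counts: dict[tuple[str, str], int],
    min_gap: Optional[int] = None,
    seed: int = 0,
    mix_minor_range: tuple[int, int] = (10, 50),
    edge_margin: int = 500,
) -> list[TruthEvent]:
    """Non-overlapping truth events with per-class, per-type counts.

    ``counts`` maps ``(type, class label)`` to a count, where type is
    "INS", "DEL" or "MIX" and the label is one of the canonical ladder
    labels (for MIX the class constrains the magnitude of the effective
    length).  Events are placed uniformly subject to a minimum gap of
    ``min_gap`` bp between the reference footprints of consecutive events
    (default: twice the largest requested class upper bound, which makes
    truth matching unambiguous in tests).  Infeasible packing raises
    rather than silently truncating.

    MIX events pair a minor length drawn from ``mix_minor_range`` with a
    major length = minor + effective magnitude; the sign (net deletion vs
    net insertion) alternates deterministically.
    """
    classes = {c.label: c for c in SIZE_CLASSES}
    requested: list[tuple[str, SizeClass]] = []
    for (ev_type, label), n in sorted(counts.items()):
        if label not in classes:
            raise ConfigError(f"unknown size class label '{label}'")
        if ev_type not in ("INS", "DEL", "MIX"):
            raise ConfigError(f"unknown event type '{ev_type}'")
        if n < 0:
            raise ConfigError("counts must be >= 0")
        requested.extend([(ev_type, classes[label])] * n)
    if not requested:
        return []
    if min_gap is None:
        min_gap = 2 * max(cls.upper for _, cls in requested)

    rng = np.random.default_rng(seed)
    # place big-footprint events first: scattering hundreds of small events
    # beforehand would fragment the free space and starve the multi-kb ones
    order = sorted(
        range(len(requested)),
        key=lambda i: (-requested[i][1].upper, requested[i][0], i),
    )
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    events: list[TruthEvent] = []
    mix_sign = 1
    max_tries = 1000
    for k, i in enumerate(order):
        ev_type, cls = requested[i]
        length = int(rng.integers(cls.lower, cls.upper + 1))
        if ev_type == "MIX":
            minor = int(rng.integers(mix_minor_range[0], mix_minor_range[1] + 1))
            major = minor + length
            if mix_sign > 0:
                del_len, ins_len = major, minor
            else:
                del_len, ins_len = minor, major
            mix_sign = -mix_sign
            footprint = del_len if del_len > 0 else 1
        else:
            footprint = length if ev_type == "DEL" else 1

        placed = False
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            clen = chrom_lengths[chrom]
            lo = edge_margin + footprint
            hi = clen - edge_margin - footprint
            if hi <= lo:
                continue
            left = int(rng.integers(lo, hi))
            right = left + footprint - 1
            ok = all(
                left - min_gap > e or right + min_gap < s
                for s, e in occupied[chrom]
            )
            if not ok:
                continue
            occupied[chrom].append((left, right))
            bp = center_point(left, right)
            if ev_type == "DEL":
                events.append(TruthEvent(f"t{k}", chrom, SVType.DEL, bp, length))
            elif ev_type == "INS":
                events.append(TruthEvent(f"t{k}", chrom, SVType.INS, left, length))
            else:
                events.append(
                    TruthEvent(
                        f"t{k}", chrom, SVType.MIX, bp,
                        del_len=del_len, ins_len=ins_len,
                    )
                )
            placed = True
            break
        if not placed:
            raise ConfigError(
                f"cannot place event {k} ({ev_type}, {cls.label}) with "
                f"min_gap={min_gap}; packing infeasible"
            )
    events.sort(key=lambda e: (e.chrom, e.breakpoint, e.event_id))
    return events


@dataclass
class DonorGenome:
    """Reference with truth events applied, plus a liftover map.

    ``anchors[chrom]`` records, per event in reference order, the tuple
    ``(ref_pos, donor_pos, ref_skip, donor_insert)``: at reference
    coordinate ``ref_pos`` (1-based, first base of the event footprint)
    the donor skips ``ref_skip`` reference bases and inserts
    ``donor_insert`` new ones at donor coordinate ``donor_pos``.
    """

    sequences: dict[str, str]
    anchors: dict[str, list[tuple[int, int, int, int]]]
    truth: list[TruthEvent]

    def ref_to_donor(self, chrom: str, pos: int) -> Optional[int]:
        """Map a 1-based reference coordinate to the donor, or None if the
        base was deleted."""
        offset = 0
        for ref_pos, _donor_pos, ref_skip, donor_insert in self.anchors.get(chrom, []):
            if pos < ref_pos:
                break
            if pos < ref_pos + ref_skip:
                return None
            offset += donor_insert - ref_skip
        return pos + offset


def implant_svs(
    reference: dict[str, str],
    truth: Sequence[TruthEvent],
    seed: int = 0,
) -> DonorGenome:
    """Apply truth events to the reference, left to right, with cumulative
    offset tracking.

    DEL removes the event footprint; INS inserts a random (seeded)
    sequence after the breakpoint base; MIX replaces ``del_len`` bases by
    ``ins_len`` random bases.  Overlapping events or events beyond a
    chromosome end raise :class:`~svclique.errors.ConsistencyError`.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in truth:
        if ev.chrom not in reference:
            raise ConsistencyError(f"event {ev.event_id} on unknown chrom {ev.chrom}")
        by_chrom.setdefault(ev.chrom, []).append(ev)

    sequences: dict[str, str] = {}
    anchors: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, ref in reference.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda e: e.ref_span()[0])
        pieces: list[str] = []
        chrom_anchors: list[tuple[int, int, int, int]] = []
        cursor = 1  # next 1-based ref base to copy
        donor_len = 0
        prev_end = 0
        for ev in evs:
            start, end = ev.ref_span()
            if start <= prev_end:
                raise ConsistencyError(
                    f"event {ev.event_id} overlaps a previous event on {chrom}"
                )
            if end > len(ref) or start < 1:
                raise ConsistencyError(
                    f"event {ev.event_id} outside chromosome {chrom}"
                )
            if ev.ev_type is SVType.DEL:
                ref_skip, ins_seq = ev.length, ""
                anchor_ref = start
            elif ev.ev_type is SVType.INS:
                ref_skip, ins_seq = 0, _random_seq(rng, ev.length)
                anchor_ref = start + 1  # insert AFTER the breakpoint base
            else:  # MIX
                ref_skip = ev.del_len or 0
                ins_seq = _random_seq(rng, ev.ins_len or 0)
                anchor_ref = start if ref_skip else start + 1
            pieces.append(ref[cursor - 1 : anchor_ref - 1])
            donor_len += anchor_ref - cursor
            chrom_anchors.append((anchor_ref, donor_len + 1, ref_skip, len(ins_seq)))
            pieces.append(ins_seq)
            donor_len += len(ins_seq)
            cursor = anchor_ref + ref_skip
            prev_end = end
        pieces.append(ref[cursor - 1 :])
        sequences[chrom] = "".join(pieces)
        anchors[chrom] = chrom_anchors
    donor = DonorGenome(sequences=sequences, anchors=anchors, truth=list(truth))
    # conservation check: donor length = ref - sum(del) + sum(ins)
    for chrom, ref in reference.items():
        delta = sum(
            (ins - skip) for _, _, skip, ins in anchors[chrom]
        )
        if len(donor.sequences[chrom]) != len(ref) + delta:
            raise ConsistencyError(f"length bookkeeping failed on {chrom}")
    return donor


@dataclass(frozen=True)
class VirtualToolSpec:
    """Noise model of one virtual SV caller.

    ``detection_prob`` maps size-class labels to per-event emission
    probabilities (a plain float applies to every class).  Jitter is
    Gaussian, rounded to integers; false positives arrive as a Poisson
    process of ``fp_per_mb`` calls per megabase with lengths drawn
    log-uniformly (default) or uniformly on ``fp_length_range``.
    """

    tool_id: str
    method_class: MethodClass
    breakpoint_jitter_sd: float
    length_jitter_sd: float
    detection_prob: Union[float, dict[str, float]]
    fp_per_mb: float = 0.0
    fp_length_range: tuple[int, int] = (20, 50000)
    fp_length_dist: str = "loguniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breakpoint_jitter_sd < 0 or self.length_jitter_sd < 0:
            raise ConfigError("jitter sds must be >= 0")
        probs = (
            self.detection_prob.values()
            if isinstance(self.detection_prob, dict)
            else [self.detection_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("detection probabilities must be in [0, 1]")
        if self.fp_per_mb < 0:
            raise ConfigError("fp_per_mb must be >= 0")

    def detection_for(self, label: Optional[str]) -> float:
        if isinstance(self.detection_prob, dict):
            return self.detection_prob.get(label, 0.0) if label else 0.0
        return self.detection_prob

    def profile(self) -> ToolProfile:
        return ToolProfile.for_method(self.tool_id, self.method_class)


def _fp_length(spec: VirtualToolSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.fp_length_range
    if spec.fp_length_dist == "uniform":
        return int(rng.integers(lo, hi + 1))
    if spec.fp_length_dist == "loguniform":
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    raise ConfigError(f"unknown fp_length_dist '{spec.fp_length_dist}'")


def simulate_tool_calls(
    truth: Sequence[TruthEvent],
    spec: VirtualToolSpec,
    chrom_lengths: dict[str, int],
) -> CallSet:
    """Emit one virtual tool's call set for a truth set.

    Each INS/DEL truth event is emitted with its class's detection
    probability, with integer-rounded Gaussian jitter on breakpoint and
    length (length clamped to >= 20).  False positives are placed
    uniformly with lengths from the spec's FP length distribution.  Fully
    reproducible from ``spec.seed``.
    """
    from .benchmark import bucket_label  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    calls: list[SVCall] = []
    n = 0
    for ev in sorted(truth, key=lambda e: (e.chrom, e.breakpoint, e.event_id)):
        if ev.ev_type is SVType.MIX:
            continue
        p = spec.detection_for(bucket_label(ev.length))
        if rng.random() >= p:
            continue
        bp = ev.breakpoint + int(round(rng.normal(0, spec.breakpoint_jitter_sd)))
        length = ev.length + int(round(rng.normal(0, spec.length_jitter_sd)))
        length = max(length, 20)
        bp = max(bp, 1)
        if ev.ev_type is SVType.DEL:
            left, right = deletion_span(bp, length)
            if left < 1:
                left, right = 1, length
            calls.append(
                SVCall.deletion(f"{spec.tool_id}:{n}", spec.tool_id, ev.chrom, left, right)
            )
        else:
            calls.append(
                SVCall.insertion(f"{spec.tool_id}:{n}", spec.tool_id, ev.chrom, bp, length)
            )
        n += 1

    total_mb = sum(chrom_lengths.values()) / 1e6
    n_fp = int(rng.poisson(spec.fp_per_mb * total_mb))
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(n_fp):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = _fp_length(spec, rng)
        sv_type = SVType.DEL if rng.random() < 0.5 else SVType.INS
        bp = int(rng.integers(1 + length, chrom_lengths[chrom] - length))
        if sv_type is SVType.DEL:
            left, right = deletion_span(bp, length)
            calls.append(
                SVCall.deletion(f"{spec.tool_id}:{n}", spec.tool_id, chrom, left, right)
            )
        else:
            calls.append(
                SVCall.insertion(f"{spec.tool_id}:{n}", spec.tool_id, chrom, bp, length)
            )
        n += 1
    return CallSet(
        tool_id=spec.tool_id,
        calls=calls,
        genome_length=sum(chrom_lengths.values()),
    )


# ---------------------------------------------------------------------------
# the standard benchmark scenario


#: Per-class detection probabilities of the two virtual tool families.
SR_DETECTION = {"20-49": 0.95, "50-99": 0.90, "100-249": 0.85, "250-999": 0.80, "1000-50000": 0.70}
IS_DETECTION = {"20-49": 0.60, "50-99": 0.70, "100-249": 0.85, "250-999": 0.90, "1000-50000": 0.95}

#: Truth counts per (type, class) for the standard 2 Mb scenario (~600
#: events, skewed toward small classes as real validated SV sets are).
SCENARIO_COUNTS: dict[tuple[str, str], int] = {
    ("DEL", "20-49"): 150, ("DEL", "50-99"): 100, ("DEL", "100-249"): 80,
    ("DEL", "250-999"): 40, ("DEL", "1000-50000"): 10,
    ("INS", "20-49"): 120, ("INS", "50-99"): 60, ("INS", "100-249"): 30,
    ("INS", "250-999"): 8, ("INS", "1000-50000"): 2,
    ("MIX", "50-99"): 5, ("MIX", "100-249"): 5,
}


def benchmark_scenario(seed: int = 0, fp_per_mb: float = 5.0):
    """The package's standard synthetic study: 2 chromosomes x 1 Mb,
    ~600 truth events, four virtual tools (two split-read-like with
    breakpoint/length jitter sd 3/5 bp, two internal-segment-like with
    sd 25/40 bp), per-class detection 0.6-0.95, and ``fp_per_mb`` false
    positives per tool.

    Returns ``(chrom_lengths, truth, callsets, specs)``.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]
    chrom_lengths = {"chr1": 1_000_000, "chr2": 1_000_000}
    truth = generate_truth(
        chrom_lengths, SCENARIO_COUNTS, min_gap=300, seed=sub[0]
    )
    specs = [
        VirtualToolSpec(
            "sr1", MethodClass.SPLIT_READ, 3, 5, SR_DETECTION,
            fp_per_mb=fp_per_mb, seed=sub[1],
        ),
        VirtualToolSpec(
            "sr2", MethodClass.SPLIT_READ, 3, 5, SR_DETECTION,
            fp_per_mb=fp_per_mb, seed=sub[2],
        ),
        VirtualToolSpec(
            "is1", MethodClass.INTERNAL_SEGMENT, 25, 40, IS_DETECTION,
            fp_per_mb=fp_per_mb, seed=sub[3],
        ),
        VirtualToolSpec(
            "is2", MethodClass.INTERNAL_SEGMENT, 25, 40, IS_DETECTION,
            fp_per_mb=fp_per_mb, seed=sub[4],
        ),
    ]
    callsets = [simulate_tool_calls(truth, s, chrom_lengths) for s in specs]
    return chrom_lengths, truth, callsets, specs
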