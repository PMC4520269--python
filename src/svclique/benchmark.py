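"""Comparative evaluation of SV call sets against truth annotations.

A prediction matches a truth event of the same type when their center
points are within ``max_center_distance`` bp and their lengths within
``max_length_difference`` bp (``strict`` regime: 50/20; ``relaxed``:
100/100 — the relaxed regime credits tools that land near a true event
without hitting it).  Matching mirrors the merge compatibility criterion,
with the truth annotations playing the role of the second call set;
reciprocal overlap is deliberately not used.

Each prediction links to at most one truth event (nearest center; ties by
smaller length difference, then truth id), while several predictions may
spot the same truth event.  This realizes the asymmetric definitions:
*precision* is the percentage of predictions that match a true annotation,
*recall* the percentage of true events spotted, and the F-measure their
harmonic mean ``2pr/(p+r)``.

Unmatched predictions may still correspond to *mixed* (substitution)
events of similar signed effective length; such predictions are counted in
the ``Mix.`` percentage but never credited to precision.

Statistics are stratified by size class, with a matched pair classed by
the TRUTH length (keeping recall denominators aligned with the truth-set
counts) and an unmatched prediction by its own length.  Empty denominators
are reported as NA in tables and as 0 at radar vertices.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    ABOVE_RANGE_LABEL,
    SIZE_CLASSES,
    UNSIZED_LABEL,
    SVCall,
    SVType,
    TruthEvent,
)
from .vcf_io import CallSet

__all__ = [
    "MatchThresholds",
    "STRICT",
    "RELAXED",
    "MatchResult",
    "match_predictions",
    "mixed_event_rescue",
    "precision_recall",
    "f_measure",
    "evaluate",
    "EvaluationReport",
    "radar_data",
    "plot_radar",
]


@dataclass(frozen=True)
class MatchThresholds:
    max_center_distance: int
    max_length_difference: int
    regime_label: str = "custom"


STRICT = MatchThresholds(50, 20, "strict")
RELAXED = MatchThresholds(100, 100, "relaxed")

BELOW_RANGE_LABEL = "<20"
ALL_LABEL = "all"


def bucket_label(length: Optional[int]) -> str:
    """Size-class label of a length, incl. out-of-ladder buckets."""
    if length is None:
        return UNSIZED_LABEL
    if length < SIZE_CLASSES[0].lower:
        return BELOW_RANGE_LABEL
    for cls in SIZE_CLASSES:
        if length in cls:
            return cls.label
    return ABOVE_RANGE_LABEL


@dataclass
class MatchResult:
    """Outcome of matching predictions to truth under one regime."""

    links: dict[str, str]  # prediction call_id -> truth event_id
    center_dist: dict[str, int]
    length_diff: dict[str, Optional[int]]
    matched: list[SVCall]
    unmatched: list[SVCall]
    spotted: set[str]


def match_predictions(
    predictions: Sequence[SVCall],
    truth: Sequence[TruthEvent],
    thresholds: MatchThresholds,
) -> MatchResult:
    """Link predictions to INS/DEL truth events.

    A prediction with unknown length passes the length criterion
    vacuously (its length difference is recorded as None and excluded
    from averages).
    """
    by_group: dict[tuple[str, SVType], tuple[list[int], list[TruthEvent]]] = {}
    for ev in truth:
        if ev.ev_type is SVType.MIX:
            continue
        key = (ev.chrom, ev.ev_type)
        by_group.setdefault(key, ([], []))[1].append(ev)
    for bps, evs in by_group.values():
        evs.sort(key=lambda e: (e.breakpoint, e.event_id))
        bps.extend(e.breakpoint for e in evs)

    result = MatchResult({}, {}, {}, [], [], set())
    for pred in predictions:
        group = by_group.get((pred.chrom, pred.sv_type))
        best: Optional[tuple[int, int, str, TruthEvent]] = None
        if group is not None:
            bps, evs = group
            lo = bisect.bisect_left(bps, pred.breakpoint - thresholds.max_center_distance)
            hi = bisect.bisect_right(bps, pred.breakpoint + thresholds.max_center_distance)
            for ev in evs[lo:hi]:
                dist = abs(pred.breakpoint - ev.breakpoint)
                if pred.length is None:
                    ldiff = 0
                else:
                    ldiff = abs(pred.length - ev.length)
                    if ldiff > thresholds.max_length_difference:
                        continue
                key = (dist, ldiff, ev.event_id)
                if best is None or key < best[:3]:
                    best = (*key, ev)
        if best is None:
            result.unmatched.append(pred)
        else:
            dist, _, _, ev = best
            result.links[pred.call_id] = ev.event_id
            result.center_dist[pred.call_id] = dist
            result.length_diff[pred.call_id] = (
                None if pred.length is None else abs(pred.length - ev.length)
            )
            result.matched.append(pred)
            result.spotted.add(ev.event_id)
    return result


def mixed_event_rescue(
    unmatched_predictions: Sequence[SVCall],
    mix_truth: Sequence[TruthEvent],
    thresholds: MatchThresholds,
) -> set[str]:
    """Ids of unmatched predictions explained by a mixed event.

    A DEL prediction is rescued by a net-deletion MIX (``del_len >
    ins_len``) whose signed effective length matches the predicted length
    within the length threshold; an INS prediction symmetrically needs a
    net-insertion MIX.  Rescued predictions feed the Mix. column only.
    """
    mixes = [ev for ev in mix_truth if ev.ev_type is SVType.MIX]
    rescued: set[str] = set()
    for pred in unmatched_predictions:
        if pred.length is None:
            continue
        for ev in mixes:
            if ev.chrom != pred.chrom:
                continue
            if abs(pred.breakpoint - ev.breakpoint) > thresholds.max_center_distance:
                continue
            eff = ev.effective_length
            if pred.sv_type is SVType.DEL:
                if eff is None or eff <= 0:
                    continue
                if abs(pred.length - eff) <= thresholds.max_length_difference:
                    rescued.add(pred.call_id)
                    break
            else:
                if eff is None or eff >= 0:
                    continue
                if abs(pred.length - (-eff)) <= thresholds.max_length_difference:
                    rescued.add(pred.call_id)
                    break
    return rescued


def precision_recall(
    n_matched: int, n_predictions: int, n_spotted: int, n_truth: int
) -> tuple[Optional[float], Optional[float]]:
    """(precision %, recall %); NA (None) on an empty denominator."""
    precision = 100.0 * n_matched / n_predictions if n_predictions > 0 else None
    recall = 100.0 * n_spotted / n_truth if n_truth > 0 else None
    return precision, recall


def f_measure(precision: Optional[float], recall: Optional[float]) -> Optional[float]:
    """Harmonic mean of precision and recall on the ratio scale [0, 1]."""
    if precision is None or recall is None:
        return None
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """Stratified evaluation table plus the regimes that produced it.

    ``frame`` columns: sv_type, size_class, regime, n_calls, n_truth,
    n_matched, n_spotted, precision, recall, f_measure, mix_pct,
    avg_center_dist, avg_len_diff.  Percentages are on the 0-100 scale;
    f_measure is a ratio in [0, 1]; empty denominators are NaN.
    """

    frame: pd.DataFrame
    regimes: tuple[MatchThresholds, ...]

    TSV_COLUMNS = (
        "sv_type", "size_class", "regime", "n_calls", "n_truth",
        "n_matched", "n_spotted", "precision", "recall", "f_measure",
        "mix_pct", "avg_center_dist", "avg_len_diff",
    )

    def row(self, sv_type: str, size_class: str, regime: str) -> pd.Series:
        sel = self.frame[
            (self.frame.sv_type == sv_type)
            & (self.frame.size_class == size_class)
            & (self.frame.regime == regime)
        ]
        if len(sel) != 1:
            raise KeyError((sv_type, size_class, regime))
        return sel.iloc[0]

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")

    def to_json(self, path: Union[str, Path]) -> None:
        records = []
        for _, r in self.frame.iterrows():
            rec = {}
            for col in self.TSV_COLUMNS:
                v = r[col]
                if isinstance(v, float) and math.isnan(v):
                    v = None
                elif isinstance(v, (np.integer,)):
                    v = int(v)
                elif isinstance(v, (np.floating,)):
                    v = float(v)
                rec[col] = v
            records.append(rec)
        payload = {
            "regimes": [
                {
                    "label": t.regime_label,
                    "max_center_distance": t.max_center_distance,
                    "max_length_difference": t.max_length_difference,
                }
                for t in self.regimes
            ],
            "rows": records,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _as_calls(predictions: Union[CallSet, Iterable[SVCall]]) -> list[SVCall]:
    if isinstance(predictions, CallSet):
        return list(predictions)
    return list(predictions)


def evaluate(
    predictions: Union[CallSet, Iterable[SVCall]],
    truth: Sequence[TruthEvent],
    regimes: Sequence[MatchThresholds] = (STRICT, RELAXED),
    min_size: int = 20,
) -> EvaluationReport:
    """Full stratified evaluation of one call set.

    Predictions with a known length below ``min_size`` are excluded (as in
    merging); truth events are stratified by their own length.  Per regime
    and sv_type an ``all`` row aggregates over size classes.
    """
    labels = {t.regime_label for t in regimes}
    if len(labels) != len(regimes):
        raise ConfigError("regimes must have distinct labels")

    preds_all = [
        p for p in _as_calls(predictions)
        if p.length is None or p.length >= min_size
    ]
    indel_truth = [ev for ev in truth if ev.ev_type is not SVType.MIX]
    mix_truth = [ev for ev in truth if ev.ev_type is SVType.MIX]
    truth_by_id = {ev.event_id: ev for ev in indel_truth}

    rows = []
    for thr in regimes:
        res = match_predictions(preds_all, indel_truth, thr)
        rescued = mixed_event_rescue(res.unmatched, mix_truth, thr)
        for sv_type in (SVType.INS, SVType.DEL):
            # bucket assignment
            truth_events = [ev for ev in indel_truth if ev.ev_type is sv_type]
            n_truth: dict[str, int] = {}
            spotted: dict[str, int] = {}
            for ev in truth_events:
                lab = bucket_label(ev.length)
                n_truth[lab] = n_truth.get(lab, 0) + 1
                if ev.event_id in res.spotted:
                    spotted[lab] = spotted.get(lab, 0) + 1
            n_calls: dict[str, int] = {}
            n_matched: dict[str, int] = {}
            n_rescued: dict[str, int] = {}
            dists: dict[str, list[int]] = {}
            ldiffs: dict[str, list[int]] = {}
            for p in preds_all:
                if p.sv_type is not sv_type:
                    continue
                if p.call_id in res.links:
                    lab = bucket_label(truth_by_id[res.links[p.call_id]].length)
                    n_matched[lab] = n_matched.get(lab, 0) + 1
                    dists.setdefault(lab, []).append(res.center_dist[p.call_id])
                    ld = res.length_diff[p.call_id]
                    if ld is not None:
                        ldiffs.setdefault(lab, []).append(ld)
                else:
                    lab = bucket_label(p.length)
                    if p.call_id in rescued:
                        n_rescued[lab] = n_rescued.get(lab, 0) + 1
                n_calls[lab] = n_calls.get(lab, 0) + 1

            canonical = [c.label for c in SIZE_CLASSES]
            extra = sorted(
                (set(n_calls) | set(n_truth)) - set(canonical),
            )
            for lab in canonical + extra + [ALL_LABEL]:
                if lab == ALL_LABEL:
                    nc = sum(n_calls.values())
                    nt = sum(n_truth.values())
                    nm = sum(n_matched.values())
                    ns = sum(spotted.values())
                    nr = sum(n_rescued.values())
                    dd = [d for v in dists.values() for d in v]
                    ll = [d for v in ldiffs.values() for d in v]
                else:
                    nc = n_calls.get(lab, 0)
                    nt = n_truth.get(lab, 0)
                    nm = n_matched.get(lab, 0)
                    ns = spotted.get(lab, 0)
                    nr = n_rescued.get(lab, 0)
                    dd = dists.get(lab, [])
                    ll = ldiffs.get(lab, [])
                prec, rec = precision_recall(nm, nc, ns, nt)
                f_ratio = f_measure(
                    None if prec is None else prec / 100.0,
                    None if rec is None else rec / 100.0,
                )
                rows.append(
                    {
                        "sv_type": sv_type.value,
                        "size_class": lab,
                        "regime": thr.regime_label,
                        "n_calls": nc,
                        "n_truth": nt,
                        "n_matched": nm,
                        "n_spotted": ns,
                        "precision": np.nan if prec is None else prec,
                        "recall": np.nan if rec is None else rec,
                        "f_measure": np.nan if f_ratio is None else f_ratio,
                        "mix_pct": (100.0 * nr / nc) if nc > 0 else np.nan,
                        "avg_center_dist": float(np.mean(dd)) if dd else np.nan,
                        "avg_len_diff": float(np.mean(ll)) if ll else np.nan,
                    }
                )
    frame = pd.DataFrame(rows, columns=list(EvaluationReport.TSV_COLUMNS))
    return EvaluationReport(frame=frame, regimes=tuple(regimes))


def radar_data(
    report: EvaluationReport,
    metrics: Sequence[str] = ("recall", "precision", "f_measure"),
) -> dict[tuple[str, str], dict[str, list[float]]]:
    """Per-(sv_type, regime) pentagon vectors on [0, 1] over the five
    canonical size classes, in ladder order.  NA vertices are rendered as
    0.0 (tables keep the NA)."""
    out: dict[tuple[str, str], dict[str, list[float]]] = {}
    canonical = [c.label for c in SIZE_CLASSES]
    for thr in report.regimes:
        for sv_type in ("INS", "DEL"):
            vectors: dict[str, list[float]] = {}
            for metric in metrics:
                vec = []
                for lab in canonical:
                    v = report.row(sv_type, lab, thr.regime_label)[metric]
                    if isinstance(v, float) and math.isnan(v):
                        vec.append(0.0)
                    elif metric == "f_measure":
                        vec.append(float(v))
                    else:
                        vec.append(float(v) / 100.0)
                vectors[metric] = vec
            out[(sv_type, thr.regime_label)] = vectors
    return out


def plot_radar(
    radars: dict[str, dict[tuple[str, str], dict[str, list[float]]]],
    path: Union[str, Path],
    metric: str = "f_measure",
    regime: str = "strict",
) -> None:
    """Pentagon radar plot, one panel per SV type, one polygon per call
    set.  ``radars`` maps a call-set name to its :func:`radar_data`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [c.label for c in SIZE_CLASSES]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, axes = plt.subplots(
        1, 2, figsize=(10, 5), subplot_kw={"projection": "polar"}
    )
    for ax, sv_type in zip(axes, ("INS", "DEL")):
        for name, radar in radars.items():
            key = (sv_type, regime)
            if key not in radar:
                continue
            values = radar[key][metric]
            closed = np.concatenate([values, values[:1]])
            ax.plot(np.concatenate([angles, angles[:1]]), closed, label=name)
            ax.fill(np.concatenate([angles, angles[:1]]), closed, alpha=0.1)
        ax.set_xticks(angles)
        ax.set_xticklabels(labels, fontsize=8)
        ax.set_ylim(0, 1)
        ax.set_title(f"{sv_type} {metric} ({regime})")
    axes[-1].legend(loc="upper right", bbox_to_anchor=(1.4, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
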