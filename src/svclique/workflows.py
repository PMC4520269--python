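"""Merge-and-evaluate workflows behind the command line.

Each workflow echoes its fully-resolved configuration as JSON next to its
outputs, logs in/out counts at every stage, and is byte-reproducible from
that echoed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import benchmark as bm
from . import merge as mg
from .errors import ConfigError
from .model import (
    SIZE_CLASSES,
    MergeCriteria,
    MethodClass,
    ToolProfile,
)
from .vcf_io import CallSet, read_sv_vcf, read_truth, write_sv_vcf

log = logging.getLogger(__name__)

_ALLOWED_KEYS = {
    "tools", "policy", "min_size", "regimes", "genome_length", "seed",
    "log_level", "allow_same_tool", "global_criteria",
}
_ALLOWED_TOOL_KEYS = {"id", "method_class", "rank", "criteria"}
_ALLOWED_CRITERIA_KEYS = {"max_breakpoint_distance", "max_length_deviation"}

_REGIMES = {"strict": bm.STRICT, "relaxed": bm.RELAXED}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected)."""

    profiles: dict[str, ToolProfile] = dataclasses.field(default_factory=dict)
    policy: str = "greedy_disjoint"
    min_size: int = 20
    regimes: tuple[bm.MatchThresholds, ...] = (bm.STRICT, bm.RELAXED)
    genome_length: Optional[int] = None
    seed: int = 0
    log_level: str = "INFO"
    allow_same_tool: bool = True
    global_criteria: Optional[MergeCriteria] = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for entry in data.get("tools", []) or []:
            bad = set(entry) - _ALLOWED_TOOL_KEYS
            if bad:
                raise ConfigError(f"unknown tool keys: {sorted(bad)}")
            if "id" not in entry:
                raise ConfigError("each tool entry needs an 'id'")
            try:
                method = MethodClass(entry.get("method_class", "hybrid"))
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
            base = ToolProfile.for_method(entry["id"], method)
            criteria = base.default_criteria
            if "criteria" in entry:
                bad = set(entry["criteria"]) - _ALLOWED_CRITERIA_KEYS
                if bad:
                    raise ConfigError(f"unknown criteria keys: {sorted(bad)}")
                criteria = MergeCriteria(
                    entry["criteria"].get(
                        "max_breakpoint_distance", criteria.max_breakpoint_distance
                    ),
                    entry["criteria"].get(
                        "max_length_deviation", criteria.max_length_deviation
                    ),
                )
            cfg.profiles[entry["id"]] = ToolProfile(
                tool_id=entry["id"],
                method_class=method,
                accuracy_rank=entry.get("rank", base.accuracy_rank),
                default_criteria=criteria,
            )
        policy = data.get("policy", cfg.policy)
        policy = {"greedy": "greedy_disjoint", "all": "all_cliques"}.get(policy, policy)
        if policy not in ("greedy_disjoint", "all_cliques"):
            raise ConfigError(f"unknown policy '{policy}'")
        cfg.policy = policy
        cfg.min_size = int(data.get("min_size", cfg.min_size))
        if cfg.min_size < 0:
            raise ConfigError("min_size must be >= 0")
        if "regimes" in data:
            regimes = []
            for name in data["regimes"]:
                if name not in _REGIMES:
                    raise ConfigError(f"unknown regime '{name}'")
                regimes.append(_REGIMES[name])
            cfg.regimes = tuple(regimes)
        if data.get("genome_length") is not None:
            cfg.genome_length = int(data["genome_length"])
        cfg.seed = int(data.get("seed", cfg.seed))
        cfg.log_level = str(data.get("log_level", cfg.log_level))
        cfg.allow_same_tool = bool(data.get("allow_same_tool", cfg.allow_same_tool))
        if data.get("global_criteria") is not None:
            gc = data["global_criteria"]
            bad = set(gc) - _ALLOWED_CRITERIA_KEYS
            if bad:
                raise ConfigError(f"unknown criteria keys: {sorted(bad)}")
            cfg.global_criteria = MergeCriteria(
                gc.get("max_breakpoint_distance", 50),
                gc.get("max_length_deviation", 20),
            )
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config '{path}': {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config '{path}' must be a mapping")
        return cls.from_dict(data)

    def resolved(self) -> dict:
        return {
            "tools": [
                {
                    "id": p.tool_id,
                    "method_class": p.method_class.value,
                    "rank": p.accuracy_rank,
                    "criteria": {
                        "max_breakpoint_distance": p.default_criteria.max_breakpoint_distance,
                        "max_length_deviation": p.default_criteria.max_length_deviation,
                    },
                }
                for p in self.profiles.values()
            ],
            "policy": self.policy,
            "min_size": self.min_size,
            "regimes": [t.regime_label for t in self.regimes],
            "genome_length": self.genome_length,
            "seed": self.seed,
            "log_level": self.log_level,
            "allow_same_tool": self.allow_same_tool,
            "global_criteria": (
                None
                if self.global_criteria is None
                else {
                    "max_breakpoint_distance": self.global_criteria.max_breakpoint_distance,
                    "max_length_deviation": self.global_criteria.max_length_deviation,
                }
            ),
        }

    def echo(self, out_dir: Union[str, Path]) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "config.resolved.json"
        path.write_text(json.dumps(self.resolved(), indent=1, sort_keys=True))
        return path


def _load_callsets(config: RunConfig, vcfs: dict[str, Union[str, Path]]) -> list[CallSet]:
    callsets = []
    for tool_id, path in sorted(vcfs.items()):
        cs = read_sv_vcf(path, tool_id)
        log.info(
            "%s: parsed %d calls (%d records skipped)", tool_id, len(cs), cs.n_skipped
        )
        if tool_id not in config.profiles and config.global_criteria is None:
            # tools without explicit profiles fall back to hybrid defaults
            config.profiles[tool_id] = ToolProfile.for_method(tool_id, MethodClass.HYBRID)
        callsets.append(cs)
    return callsets


def merge_summary(
    callsets: Sequence[CallSet],
    merged: Sequence[mg.MergedCall],
    min_size: int,
) -> pd.DataFrame:
    """Per-size-class input/output counts, reduction %, support histogram."""
    from .benchmark import bucket_label

    rows = []
    labels = [c.label for c in SIZE_CLASSES] + ["all"]
    pooled = [
        c for cs in callsets for c in cs
        if c.length is None or c.length >= min_size
    ]
    for lab in labels:
        if lab == "all":
            n_in = len(pooled)
            sub = list(merged)
        else:
            n_in = sum(1 for c in pooled if bucket_label(c.length) == lab)
            sub = [m for m in merged if bucket_label(m.consensus_length) == lab]
        n_out = len(sub)
        hist: dict[int, int] = {}
        for m in sub:
            hist[m.support] = hist.get(m.support, 0) + 1
        rows.append(
            {
                "size_class": lab,
                "input_calls": n_in,
                "merged_calls": n_out,
                "reduction_pct": 100.0 * (1 - n_out / n_in) if n_in else float("nan"),
                "support_histogram": ",".join(
                    f"{k}:{v}" for k, v in sorted(hist.items())
                ),
            }
        )
    return pd.DataFrame(rows)


def run_merge_workflow(
    config: RunConfig,
    vcfs: dict[str, Union[str, Path]],
    out_vcf: Union[str, Path],
    report_path: Optional[Union[str, Path]] = None,
) -> tuple[list[mg.MergedCall], pd.DataFrame]:
    """Merge per-tool VCFs into one consensus VCF plus a stats table."""
    if not vcfs:
        raise ConfigError("at least one input VCF is required")
    callsets = _load_callsets(config, vcfs)
    merged = mg.merge_callsets(
        callsets,
        profiles=config.profiles or None,
        global_criteria=config.global_criteria,
        min_size=config.min_size,
        policy=config.policy,
        allow_same_tool=config.allow_same_tool,
    )
    log.info(
        "merged %d input calls into %d consensus calls",
        sum(len(cs) for cs in callsets), len(merged),
    )
    write_sv_vcf(merged, out_vcf)
    stats = merge_summary(callsets, merged, config.min_size)
    if report_path is not None:
        stats.to_csv(report_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    config.echo(Path(out_vcf).parent)
    return merged, stats


def run_benchmark_workflow(
    config: RunConfig,
    vcfs: dict[str, Union[str, Path]],
    truth_path: Union[str, Path],
    out_dir: Union[str, Path],
    include_merged: bool = False,
    radar: bool = False,
) -> dict[str, bm.EvaluationReport]:
    """Evaluate each call set (and optionally the merged set) against the
    truth annotations; writes ``<tool>.report.tsv/.json`` per call set."""
    truth = read_truth(truth_path)
    if not truth:
        raise ConfigError(f"truth set '{truth_path}' is empty")
    if not vcfs:
        raise ConfigError("at least one call set is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    callsets = _load_callsets(config, vcfs)
    reports: dict[str, bm.EvaluationReport] = {}
    for cs in callsets:
        reports[cs.tool_id] = bm.evaluate(
            cs, truth, regimes=config.regimes, min_size=config.min_size
        )
    if include_merged:
        merged = mg.merge_callsets(
            callsets,
            profiles=config.profiles or None,
            global_criteria=config.global_criteria,
            min_size=config.min_size,
            policy=config.policy,
            allow_same_tool=config.allow_same_tool,
        )
        reports["merged"] = bm.evaluate(
            mg.merged_to_callset(merged), truth,
            regimes=config.regimes, min_size=config.min_size,
        )
    for name, report in reports.items():
        report.to_tsv(out_dir / f"{name}.report.tsv")
        report.to_json(out_dir / f"{name}.report.json")
    if radar:
        radars = {name: bm.radar_data(rep) for name, rep in reports.items()}
        regime = config.regimes[0].regime_label
        bm.plot_radar(radars, out_dir / "radar.png", regime=regime)
    config.echo(out_dir)
    return reports
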