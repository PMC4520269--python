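"""Reading and writing SV call sets and truth annotations.

VCF handling goes through pysam.  Supported record shapes:

* symbolic alleles ``<DEL>``/``<INS>`` with INFO ``SVTYPE``/``SVLEN``/``END``;
* explicit REF/ALT indels (length = allele-length difference).

Conventions (standard VCF): POS of a deletion is the base *before* the
event, so the deleted span is ``left = POS + 1 .. right = END``; an
insertion sits after POS.  ``SVLEN`` is written negative for deletions and
positive for insertions; on input its absolute value is used, since tools
disagree on the sign.  Records that cannot yield a positive length are
skipped with a warning and counted in ``CallSet.n_skipped``.

Truth TSV dialect (whitespace-separated, ``#`` comments):

    chrom  DEL  <left> <right>
    chrom  DEL  breakpoint=<bp> length=<len>
    chrom  INS  <position> <length>
    chrom  MIX  <breakpoint> del_len=<d> ins_len=<i>

MIX (substitution) events exist only in the TSV dialect; VCF has no
first-class representation for them here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam

from .errors import InputParseError
from .model import SVCall, SVType, TruthEvent, center_point, deletion_span

log = logging.getLogger(__name__)


@dataclass
class CallSet:
    """All calls of one tool, sorted by (chrom, breakpoint, call_id)."""

    tool_id: str
    calls: list[SVCall]
    source_path: Optional[str] = None
    genome_length: Optional[int] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.calls = sorted(
            self.calls, key=lambda c: (c.chrom, c.breakpoint, c.call_id)
        )
        ids = [c.call_id for c in self.calls]
        if len(set(ids)) != len(ids):
            raise InputParseError(
                f"duplicate call ids in call set '{self.tool_id}'"
            )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)


def _parse_record(rec, tool_id: str, index: int) -> Optional[SVCall]:
    """One VCF record -> SVCall, or None if it is not a usable INS/DEL."""
    call_id = rec.id if rec.id not in (None, ".") else f"{tool_id}:{index}"
    pos = rec.pos  # 1-based
    alts = rec.alts or ()
    alt = alts[0] if alts else None
    svtype = rec.info.get("SVTYPE")
    svlen = rec.info.get("SVLEN")
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0] if svlen else None

    symbolic = alt is not None and alt.startswith("<")
    if symbolic:
        kind = alt.strip("<>").split(":")[0]
        if svtype is None:
            svtype = kind
        if svtype == "DEL":
            if svlen is not None and abs(int(svlen)) > 0:
                length = abs(int(svlen))
            elif rec.stop and rec.stop > pos:
                length = rec.stop - pos
            else:
                return None
            left = pos + 1
            right = left + length - 1
            return SVCall.deletion(call_id, tool_id, rec.chrom, left, right)
        if svtype == "INS":
            length = abs(int(svlen)) if svlen is not None else None
            if length == 0:
                length = None
            return SVCall.insertion(call_id, tool_id, rec.chrom, pos, length)
        return None

    if alt is None or rec.ref is None:
        return None
    # explicit alleles
    diff = len(rec.ref) - len(alt)
    if diff > 0:
        left = pos + 1
        right = left + diff - 1
        return SVCall.deletion(call_id, tool_id, rec.chrom, left, right)
    if diff < 0:
        return SVCall.insertion(call_id, tool_id, rec.chrom, pos, -diff)
    return None


def read_sv_vcf(path: Union[str, Path], tool_id: str) -> CallSet:
    """Load a VCF of insertion/deletion calls into a :class:`CallSet`.

    ``genome_length`` is the sum of contig lengths declared in the header
    (``None`` when the header carries no lengths); it feeds the merge
    engine's collision null model.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise InputParseError(f"cannot read VCF '{path}': {exc}") from exc

    contig_lengths = [
        c.length for c in vf.header.contigs.values() if c.length
    ]
    genome_length = sum(contig_lengths) if contig_lengths else None

    calls: list[SVCall] = []
    n_skipped = 0
    seen: set[str] = set()
    for i, rec in enumerate(vf):
        try:
            call = _parse_record(rec, tool_id, i)
        except (ValueError, KeyError) as exc:
            log.warning("%s: skipping record at %s:%s (%s)", path, rec.chrom, rec.pos, exc)
            n_skipped += 1
            continue
        if call is None:
            log.warning(
                "%s: skipping record at %s:%s (no usable INS/DEL length)",
                path, rec.chrom, rec.pos,
            )
            n_skipped += 1
            continue
        if call.call_id in seen:
            call = call.with_id(f"{call.call_id}.{i}")
        seen.add(call.call_id)
        calls.append(call)
    vf.close()
    return CallSet(
        tool_id=tool_id,
        calls=calls,
        source_path=path,
        genome_length=genome_length,
        n_skipped=n_skipped,
    )


def _build_header(
    chroms: Sequence[str],
    contig_lengths: Optional[dict[str, int]],
    merged: bool,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("source", "svclique")
    for line in (
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the event (DEL negative, INS positive)">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Last reference base of the event">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
    ):
        header.add_line(line)
    if merged:
        for line in (
            '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of member calls in the merged clique">',
            '##INFO=<ID=TOOLS,Number=.,Type=String,Description="Distinct tools contributing member calls">',
            '##INFO=<ID=REPR,Number=1,Type=String,Description="Tool whose breakpoint was adopted as consensus">',
            '##INFO=<ID=MEMBERS,Number=.,Type=String,Description="Member call ids">',
        ):
            header.add_line(line)
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom)
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    return header


def write_sv_vcf(
    calls: Iterable,
    path: Union[str, Path],
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write plain calls or merged calls to an uncompressed VCF 4.2 file.

    Accepts :class:`~svclique.model.SVCall` or
    :class:`~svclique.merge.MergedCall` objects (the latter additionally
    carry SUPPORT/TOOLS/REPR/MEMBERS INFO fields).
    """
    calls = list(calls)
    merged = any(hasattr(c, "support") for c in calls)
    chroms = sorted({c.chrom for c in calls} | set((contig_lengths or {}).keys()))
    header = _build_header(chroms, contig_lengths, merged)
    out = pysam.VariantFile(str(path), "w", header=header)
    for call in sorted(calls, key=_sort_key):
        sv_type = call.sv_type
        info: dict = {"SVTYPE": sv_type.value}
        if sv_type is SVType.DEL:
            length = _length_of(call)
            left, right = _span_of(call, length)
            start = max(left - 2, 0)  # VCF POS = base before the event
            stop = right
            alleles = ("N", "<DEL>")
            info["SVLEN"] = -length
        else:
            start = _breakpoint_of(call) - 1
            stop = _breakpoint_of(call)
            alleles = ("N", "<INS>")
            length = _length_of(call)
            if length is not None:
                info["SVLEN"] = length
        if hasattr(call, "support"):
            info["SUPPORT"] = call.support
            info["TOOLS"] = list(call.tools)
            info["REPR"] = call.representative_tool
            info["MEMBERS"] = list(call.member_ids)
        rec = out.new_record(
            contig=call.chrom,
            start=start,
            stop=stop,
            alleles=alleles,
            id=_id_of(call),
            info=info,
        )
        out.write(rec)
    out.close()


def _sort_key(call):
    return (call.chrom, _breakpoint_of(call), _id_of(call))


def _breakpoint_of(call):
    return getattr(call, "breakpoint", None) or call.consensus_breakpoint


def _length_of(call):
    if hasattr(call, "consensus_length"):
        return call.consensus_length
    return call.length


def _span_of(call, length):
    if getattr(call, "left", None) is not None:
        return call.left, call.right
    return deletion_span(_breakpoint_of(call), length)


def _id_of(call):
    if hasattr(call, "merge_id"):
        return call.merge_id
    return call.call_id


# ---------------------------------------------------------------------------
# truth sets


def read_truth(path: Union[str, Path]) -> list[TruthEvent]:
    """Load truth annotations from a VCF or the TSV dialect (see module
    docstring).  Dispatch is by file extension (.vcf -> VCF)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        callset = read_sv_vcf(path, tool_id="truth")
        return [
            TruthEvent(
                event_id=c.call_id,
                chrom=c.chrom,
                ev_type=c.sv_type,
                breakpoint=c.breakpoint,
                length=c.length,
            )
            for c in callset
        ]
    return _read_truth_tsv(path)


def _read_truth_tsv(path: Path) -> list[TruthEvent]:
    events: list[TruthEvent] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputParseError(f"cannot read truth file '{path}': {exc}") from exc
    n = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise InputParseError(f"{path}:{lineno}: expected at least 3 columns")
        chrom, kind = tokens[0], tokens[1].upper()
        kv = {
            k: int(v)
            for k, v in (t.split("=", 1) for t in tokens[2:] if "=" in t)
        }
        plain = [int(t) for t in tokens[2:] if "=" not in t]
        event_id = f"truth:{n}"
        try:
            if kind == "DEL":
                if "breakpoint" in kv and "length" in kv:
                    bp, length = kv["breakpoint"], kv["length"]
                elif len(plain) >= 2:
                    left, right = plain[0], plain[1]
                    bp, length = center_point(left, right), right - left + 1
                else:
                    raise InputParseError(
                        f"{path}:{lineno}: DEL needs left/right or breakpoint=/length="
                    )
                events.append(TruthEvent(event_id, chrom, SVType.DEL, bp, length))
            elif kind == "INS":
                if "breakpoint" in kv and "length" in kv:
                    bp, length = kv["breakpoint"], kv["length"]
                elif len(plain) >= 2:
                    bp, length = plain[0], plain[1]
                else:
                    raise InputParseError(
                        f"{path}:{lineno}: INS needs position and length"
                    )
                events.append(TruthEvent(event_id, chrom, SVType.INS, bp, length))
            elif kind == "MIX":
                if not plain or "del_len" not in kv or "ins_len" not in kv:
                    raise InputParseError(
                        f"{path}:{lineno}: MIX needs breakpoint, del_len= and ins_len="
                    )
                events.append(
                    TruthEvent(
                        event_id,
                        chrom,
                        SVType.MIX,
                        plain[0],
                        del_len=kv["del_len"],
                        ins_len=kv["ins_len"],
                    )
                )
            else:
                raise InputParseError(
                    f"{path}:{lineno}: unknown event type '{tokens[1]}'"
                )
        except ValueError as exc:
            raise InputParseError(f"{path}:{lineno}: {exc}") from exc
        n += 1
    return events


def write_truth_tsv(events: Iterable[TruthEvent], path: Union[str, Path]) -> None:
    """Write truth events in the TSV dialect (the only format carrying MIX)."""
    with open(path, "w") as fh:
        fh.write("# chrom type coordinates\n")
        for ev in sorted(events, key=lambda e: (e.chrom, e.breakpoint, e.event_id)):
            if ev.ev_type is SVType.DEL:
                left, right = ev.ref_span()
                fh.write(f"{ev.chrom}\tDEL\t{left}\t{right}\n")
            elif ev.ev_type is SVType.INS:
                fh.write(f"{ev.chrom}\tINS\t{ev.breakpoint}\t{ev.length}\n")
            else:
                fh.write(
                    f"{ev.chrom}\tMIX\t{ev.breakpoint}\t"
                    f"del_len={ev.del_len}\tins_len={ev.ins_len}\n"
                )


def write_truth_vcf(
    events: Iterable[TruthEvent],
    path: Union[str, Path],
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write INS/DEL truth events as a VCF (MIX events are TSV-only and are
    silently omitted here)."""
    calls = []
    for ev in events:
        if ev.ev_type is SVType.DEL:
            left, right = ev.ref_span()
            calls.append(SVCall.deletion(ev.event_id, "truth", ev.chrom, left, right))
        elif ev.ev_type is SVType.INS:
            calls.append(
                SVCall.insertion(ev.event_id, "truth", ev.chrom, ev.breakpoint, ev.length)
            )
    write_sv_vcf(calls, path, contig_lengths=contig_lengths)
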