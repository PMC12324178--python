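"""Segment aggregation, structural-grammar validation and concatemer calls.

Per-base label vectors are aggregated into maximal same-label segments,
lightly smoothed (sub-3 bp flickers sandwiched between two segments of one
label are absorbed), and matched against the layout grammar:

* a single canonical element order, forward or reversed, bracketed by
  optional terminal RANDOM flanks -> ``valid`` with an orientation;
* K >= 2 back-to-back canonical fragment orders, each independently
  oriented, with adjacent same-label junction segments shared between
  fragments (e.g. the merged ADAPTER3 run at a FWD/REV junction) and short
  RANDOM spacers tolerated at junctions -> ``concatemer`` with fragment
  count, orientation tally and sub-fragment spans;
* anything else -> ``invalid``.

``annotate_reads`` orchestrates model inference over a read store in the
hybrid (fast softmax model, CRF reprocessing of ambiguous reads) or
CRF-only mode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from seqgrammar.layout import LibraryLayout, RANDOM_LABEL
from seqgrammar.model.annotator import SequenceAnnotator


@dataclass
class Segment:
    """A maximal run of one label: 0-based, half-open coordinates."""

    label: str
    start: int
    end: int
    mean_confidence: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructuralCall:
    """Grammar verdict for one read."""

    status: str  # valid | invalid | concatemer
    orientation: str | None = None  # valid reads only
    fragment_count: int = 0
    orientation_counts: dict = field(default_factory=dict)
    sub_spans: tuple[tuple[int, int, str], ...] = ()

    def render(self) -> str:
        if self.status == "valid":
            return f"valid ({self.orientation})"
        if self.status == "invalid":
            return "invalid"
        parts = [
            f"{o}:{self.orientation_counts[o]}"
            for o in ("+", "-")
            if self.orientation_counts.get(o)
        ]
        return f"concatenated reads x{self.fragment_count} ({','.join(parts)})"


@dataclass
class AnnotatedRead:
    read_id: str
    segments: list[Segment]
    call: StructuralCall
    element_coords: dict = field(default_factory=dict)


def segments_from_labels(
    labels: np.ndarray,
    schema: Sequence[str],
    confidences: np.ndarray | None = None,
) -> list[Segment]:
    """Run-length encode a per-base label vector into ordered segments."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    segs = []
    for s, e in zip(starts, ends):
        conf = float(confidences[s:e].mean()) if confidences is not None else None
        segs.append(Segment(schema[labels[s]], int(s), int(e), conf))
    return segs


def smooth_segments(segments: list[Segment], min_len: int = 3) -> list[Segment]:
    """Absorb sub-``min_len`` flickers sandwiched between equal labels.

    A single left-to-right pass; the absorbed run's bases take the flanking
    label and the three segments merge.  Confidences merge length-weighted.
    """
    out: list[Segment] = []
    i = 0
    while i < len(segments):
        seg = segments[i]
        if (
            out
            and i + 1 < len(segments)
            and seg.length < min_len
            and out[-1].label == segments[i + 1].label
            and seg.label != out[-1].label
        ):
            left, right = out[-1], segments[i + 1]
            conf = None
            if left.mean_confidence is not None:
                total = left.length + seg.length + right.length
                conf = (
                    left.mean_confidence * left.length
                    + (seg.mean_confidence or 0.0) * seg.length
                    + (right.mean_confidence or 0.0) * right.length
                ) / total
            out[-1] = Segment(left.label, left.start, right.end, conf)
            i += 2
        else:
            if out and out[-1].label == seg.label:
                prev = out[-1]
                conf = None
                if prev.mean_confidence is not None and seg.mean_confidence is not None:
                    conf = (
                        prev.mean_confidence * prev.length
                        + seg.mean_confidence * seg.length
                    ) / (prev.length + seg.length)
                out[-1] = Segment(prev.label, prev.start, seg.end, conf)
            else:
                out.append(Segment(seg.label, seg.start, seg.end, seg.mean_confidence))
            i += 1
    return out


@dataclass(frozen=True)
class _Frag:
    start_seg: int
    end_seg: int  # exclusive
    orientation: str
    shared_start: bool


def _parse_fragments(
    labels: tuple[str, ...],
    seg_lengths: tuple[int, ...],
    fwd: tuple[str, ...],
    junction_tolerance: int,
) -> list[_Frag] | None:
    """DFS parse of a segment-label sequence into canonical fragments."""
    rev = tuple(reversed(fwd))
    n = len(labels)
    m = len(fwd)
    orders = [("+", fwd), ("-", rev)]

    def dfs(i: int, share_ok: bool) -> list[_Frag] | None:
        if i == n:
            return []
        for orientation, pat in orders:
            if labels[i : i + m] == pat:
                rest = dfs(i + m, True)
                if rest is not None:
                    return [_Frag(i, i + m, orientation, False)] + rest
            if (
                share_ok
                and m > 1
                and i > 0
                and labels[i - 1] == pat[0]
                and labels[i : i + m - 1] == pat[1:]
            ):
                rest = dfs(i + m - 1, True)
                if rest is not None:
                    return [_Frag(i - 1, i + m - 1, orientation, True)] + rest
        # short random spacer between fragments
        if (
            i > 0
            and labels[i] == RANDOM_LABEL
            and seg_lengths[i] <= junction_tolerance
        ):
            rest = dfs(i + 1, False)
            if rest is not None:
                return rest
        return None

    return dfs(0, False)


def _strip_flank_zones(segments: list[Segment], island_tolerance: int) -> list[Segment]:
    """Drop terminal flank zones, junk islands included.

    A flank zone is the largest terminal run whose innermost segment is
    RANDOM and whose non-RANDOM members are all at most ``island_tolerance``
    bp — flank bases are random, so short element calls inside them are
    classifier noise.  A long element adjacent to the flank (a real
    adapter) ends the zone and is preserved; so is any short element that
    borders the core directly rather than a RANDOM run.
    """

    def prefix_len(segs: list[Segment]) -> int:
        best = 0
        for k, seg in enumerate(segs, start=1):
            if seg.label == RANDOM_LABEL:
                best = k  # zone may extend to here
            elif seg.length > island_tolerance:
                break  # a real element ends the flank zone
        return best

    k = prefix_len(segments)
    segments = segments[k:]
    k = prefix_len(segments[::-1])
    return segments[: len(segments) - k] if k else segments


def validate_structure(
    segments: list[Segment],
    layout: LibraryLayout,
    junction_tolerance: int = 30,
    smooth: bool = True,
    island_tolerance: int = 25,
) -> StructuralCall:
    """Match a read's segment order against the layout grammar.

    Terminal RANDOM segments of any length are accepted as flanks; internal
    RANDOM segments are violations unless they sit at a concatemer junction
    and are at most ``junction_tolerance`` bp long.

    Before matching, same-label-sandwiched islands up to ``island_tolerance``
    bp are absorbed into their flanks (two passes).  In every legal structure
    the only same-label sandwich filling is a merged double-adapter junction
    run (>= ~44 bp for the 10x 3' adapters), so absorption below that scale
    only removes classifier hallucinations, never real elements.
    """
    if smooth:
        segments = smooth_segments(segments, min_len=island_tolerance)
        segments = smooth_segments(segments, min_len=island_tolerance)
    core = _strip_flank_zones(list(segments), island_tolerance)
    if not core:
        return StructuralCall(status="invalid")
    labels = tuple(s.label for s in core)
    lens = tuple(s.length for s in core)
    frags = _parse_fragments(labels, lens, layout.label_order, junction_tolerance)
    if frags is None:
        return StructuralCall(status="invalid")
    if len(frags) == 1:
        return StructuralCall(status="valid", orientation=frags[0].orientation)
    # coordinate spans; a shared junction segment is split at its midpoint
    spans: list[tuple[int, int, str]] = []
    for k, f in enumerate(frags):
        first = core[f.start_seg]
        start = (first.start + first.end) // 2 if f.shared_start else first.start
        last = core[f.end_seg - 1]
        if k + 1 < len(frags) and frags[k + 1].shared_start:
            end = (last.start + last.end) // 2
        else:
            end = last.end
        spans.append((start, end, f.orientation))
    counts = Counter(f.orientation for f in frags)
    return StructuralCall(
        status="concatemer",
        fragment_count=len(frags),
        orientation_counts=dict(counts),
        sub_spans=tuple(spans),
    )


def split_concatemer(
    sequence: str,
    call: StructuralCall,
    segments: list[Segment] | None = None,
    read_id: str = "read",
) -> list[dict]:
    """Cut a concatemer into sub-read records at its fragment boundaries.

    Each record carries the sub-sequence as sequenced (reverse fragments are
    not re-complemented; the orientation flag travels with them) and, when
    ``segments`` is given, the overlapping segments re-based to local
    coordinates.
    """
    if call.status != "concatemer":
        raise ValueError("split_concatemer requires a concatemer call")
    records = []
    for k, (start, end, orientation) in enumerate(call.sub_spans):
        rec = {
            "read_id": f"{read_id}/frag{k + 1}",
            "sequence": sequence[start:end],
            "orientation": orientation,
            "start": start,
            "end": end,
        }
        if segments is not None:
            local = []
            for s in segments:
                a, b = max(s.start, start), min(s.end, end)
                if a < b:
                    local.append(Segment(s.label, a - start, b - start, s.mean_confidence))
            rec["segments"] = local
        records.append(rec)
    return records


def _element_coords(segments: list[Segment], layout: LibraryLayout) -> dict:
    coords = {}
    for s in segments:
        if s.label in layout.label_order:
            coords[f"{s.label}_start"] = s.start
            coords[f"{s.label}_end"] = s.end
    return coords


def annotate_read(
    read_id: str,
    labels: np.ndarray,
    confidences: np.ndarray | None,
    layout: LibraryLayout,
    junction_tolerance: int = 30,
    island_tolerance: int = 25,
) -> AnnotatedRead:
    """Segments + structural call + element coordinates for one read."""
    segs = segments_from_labels(labels, layout.label_schema, confidences)
    segs = smooth_segments(segs, min_len=island_tolerance)
    segs = smooth_segments(segs, min_len=island_tolerance)
    call = validate_structure(segs, layout, junction_tolerance, smooth=False)
    coords = _element_coords(segs, layout) if call.status == "valid" else {}
    return AnnotatedRead(read_id, segs, call, coords)


def _min_confidence(segments: list[Segment]) -> float:
    vals = [s.mean_confidence for s in segments if s.mean_confidence is not None]
    return float(min(vals)) if vals else float("nan")


def annotate_reads(
    source,
    fast_model: SequenceAnnotator | None,
    crf_model: SequenceAnnotator | None,
    layout: LibraryLayout,
    mode: str = "HYB",
    ambiguity_threshold: float = 0.9,
    chunk_size: int = 300_000,
    token_budget: int = 300_000,
    junction_tolerance: int = 30,
    threads: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate all reads of a store (or (id, sequence) iterable).

    Mode ``CRF`` labels everything with the CRF model.  Mode ``HYB`` labels
    everything with the fast softmax model, then relabels with the CRF model
    those reads that are structurally invalid or whose least-confident
    segment falls below ``ambiguity_threshold``.  Returns the
    (valid, invalid) annotation tables; concatemers and other violations go
    to the invalid table with their call metadata.
    """
    if mode not in ("HYB", "CRF"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "HYB" and (fast_model is None or crf_model is None):
        raise ValueError("HYB mode needs both a fast and a CRF model")
    if mode == "CRF" and crf_model is None:
        raise ValueError("CRF mode needs a CRF model")
    primary = crf_model if mode == "CRF" else fast_model

    rows_valid: list[dict] = []
    rows_invalid: list[dict] = []
    for ids, seqs in _iter_chunks(source, chunk_size):
        preds = primary.predict(seqs, token_budget=token_budget)
        pending: list[int] = []
        annos: list[AnnotatedRead] = []
        min_confs: list[float] = []
        for i, (rid, (lab, conf)) in enumerate(zip(ids, preds)):
            anno = annotate_read(rid, lab, conf, layout, junction_tolerance)
            mc = _min_confidence(anno.segments)
            annos.append(anno)
            min_confs.append(mc)
            if mode == "HYB" and (
                anno.call.status == "invalid" or (mc == mc and mc < ambiguity_threshold)
            ):
                pending.append(i)
        if pending:
            repreds = crf_model.predict([seqs[i] for i in pending], token_budget=token_budget)
            for i, (lab, conf) in zip(pending, repreds):
                annos[i] = annotate_read(ids[i], lab, conf, layout, junction_tolerance)
                min_confs[i] = _min_confidence(annos[i].segments)
        for anno, mc, seq in zip(annos, min_confs, seqs):
            row = {
                "read_id": anno.read_id,
                "status": anno.call.status,
                "orientation": anno.call.orientation,
                "fragment_count": anno.call.fragment_count,
                "call": anno.call.render(),
                "min_confidence": mc,
                "read_length": len(seq),
            }
            if anno.call.status == "valid":
                row.update(anno.element_coords)
                rows_valid.append(row)
            else:
                if anno.call.status == "concatemer":
                    row["sub_spans"] = ";".join(
                        f"{s}-{e}:{o}" for s, e, o in anno.call.sub_spans
                    )
                rows_invalid.append(row)
    return pd.DataFrame(rows_valid), pd.DataFrame(rows_invalid)


def _iter_chunks(source, chunk_size: int):
    """Yield (ids, sequences) chunks from a BinStore or (id, seq) iterable."""
    if hasattr(source, "bin_ids"):
        for bin_id in source.bin_ids():
            table = source.read_bin(bin_id)
            ids, seqs = list(table["read_id"]), list(table["sequence"])
            for i in range(0, len(ids), chunk_size):
                yield ids[i : i + chunk_size], seqs[i : i + chunk_size]
    else:
        ids, seqs = [], []
        for rid, seq in source:
            ids.append(rid)
            seqs.append(seq)
            if len(ids) == chunk_size:
                yield ids, seqs
                ids, seqs = [], []
        if ids:
            yield ids, seqs
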