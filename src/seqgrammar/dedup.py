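"""PCR-duplicate marking by coordinate window and UMI edit distance.

Aligned, demultiplexed reads are partitioned by reference, strand and
(optionally) cell barcode; within a partition, reads whose start AND end
coordinates chain within a 10 bp window (single linkage) form candidate
sets, and inside each set UMIs are single-linkage clustered at Levenshtein
distance <= 2.  Every cluster of two or more reads keeps one representative
(highest mapping quality, then smallest start, then lexicographically
smallest read id); the rest are flagged with the standard duplicate flag
(0x400) and share a ``UG:i`` group tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from seqgrammar.demux import levenshtein

logger = logging.getLogger(__name__)

DUPLICATE_FLAG = 0x400


@dataclass(frozen=True)
class AlignedReadKey:
    """The dedup-relevant facts of one aligned read."""

    reference: str
    strand: str  # '+' or '-'
    cbc: str
    start: int  # leftmost aligned position
    end: int  # rightmost aligned position
    umi: str
    mapq: int
    read_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if not self.cbc or not self.umi:
            raise ValueError("empty CBC or UMI")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_candidates(
    keys: Sequence[AlignedReadKey],
    window: int = 10,
    per_cell: bool = True,
) -> list[list[AlignedReadKey]]:
    """Candidate duplicate sets (size >= 2) by coordinate-window chaining.

    Two reads chain when they share reference, strand (and CBC if
    ``per_cell``) and both |Δstart| <= window and |Δend| <= window; sets are
    the single-linkage closure of that relation.
    """
    parts: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        part = (k.reference, k.strand, k.cbc if per_cell else None)
        parts.setdefault(part, []).append(i)
    out: list[list[AlignedReadKey]] = []
    for idxs in parts.values():
        idxs.sort(key=lambda i: keys[i].start)
        uf = _UnionFind(len(idxs))
        for a in range(len(idxs)):
            ka = keys[idxs[a]]
            for b in range(a + 1, len(idxs)):
                kb = keys[idxs[b]]
                if kb.start - ka.start > window:
                    break
                if abs(kb.end - ka.end) <= window:
                    uf.union(a, b)
        clusters: dict[int, list[AlignedReadKey]] = {}
        for a in range(len(idxs)):
            clusters.setdefault(uf.find(a), []).append(keys[idxs[a]])
        out.extend(c for c in clusters.values() if len(c) >= 2)
    return out


def mark_duplicates(
    candidates: Iterable[Sequence[AlignedReadKey]],
    umi_threshold: int = 2,
    first_group_id: int = 0,
) -> dict[str, tuple[bool, int]]:
    """Flag duplicates inside candidate sets by UMI clustering.

    Returns ``read_id -> (is_duplicate, group_id)`` covering every read of
    every UMI cluster of size >= 2 (the representative is unflagged but
    carries the shared group id).
    """
    result: dict[str, tuple[bool, int]] = {}
    gid = first_group_id
    for cand in candidates:
        uf = _UnionFind(len(cand))
        for a in range(len(cand)):
            for b in range(a + 1, len(cand)):
                if levenshtein(cand[a].umi, cand[b].umi) <= umi_threshold:
                    uf.union(a, b)
        clusters: dict[int, list[AlignedReadKey]] = {}
        for a in range(len(cand)):
            clusters.setdefault(uf.find(a), []).append(cand[a])
        for cluster in clusters.values():
            if len(cluster) < 2:
                continue
            rep = min(cluster, key=lambda k: (-k.mapq, k.start, k.read_id))
            for k in cluster:
                result[k.read_id] = (k.read_id != rep.read_id, gid)
            gid += 1
    return result


def _key_from_alignment(aln: pysam.AlignedSegment) -> AlignedReadKey | None:
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        return None
    if not aln.has_tag("CB") or not aln.has_tag("UB"):
        logger.warning("read %s lacks CB/UB tags; excluded from dedup", aln.query_name)
        return None
    return AlignedReadKey(
        reference=aln.reference_name,
        strand="-" if aln.is_reverse else "+",
        cbc=aln.get_tag("CB"),
        start=aln.reference_start,
        end=aln.reference_end,
        umi=aln.get_tag("UB"),
        mapq=aln.mapping_quality,
        read_id=aln.query_name,
    )


def dedup_bam(
    in_bam: str | Path,
    out_bam: str | Path,
    window: int = 10,
    umi_threshold: int = 2,
    per_cell: bool = True,
    cores: int = 1,
) -> dict:
    """Duplicate-mark a coordinate-sorted BAM region by region.

    Reads without CB/UB tags are warned about and passed through unmarked.
    The output preserves input (coordinate) order and read count.  Returns
    summary counts.  Regions are independent; this implementation processes
    them sequentially (``cores`` accepted for interface stability).
    """
    in_bam, out_bam = str(in_bam), str(out_bam)
    with pysam.AlignmentFile(in_bam, "rb") as bam:
        so = dict(bam.header.get("HD", {})).get("SO", "")
        if so != "coordinate":
            raise ValueError(f"input BAM must be coordinate-sorted (SO={so or 'unknown'})")
        n_in = n_dup = 0
        with pysam.AlignmentFile(out_bam, "wb", template=bam) as out:
            gid = 0
            for ref in bam.references:
                alns = list(bam.fetch(ref))
                keys = [k for k in map(_key_from_alignment, alns) if k is not None]
                cands = group_candidates(keys, window=window, per_cell=per_cell)
                marks = mark_duplicates(cands, umi_threshold=umi_threshold, first_group_id=gid)
                gid += len({g for _, g in marks.values()})
                for aln in alns:
                    n_in += 1
                    mark = marks.get(aln.query_name)
                    if mark is not None:
                        is_dup, group = mark
                        aln.set_tag("UG", group, value_type="i")
                        if is_dup:
                            aln.flag |= DUPLICATE_FLAG
                            n_dup += 1
                        else:
                            aln.flag &= ~DUPLICATE_FLAG
                    out.write(aln)
    pysam.index(out_bam)
    return {"reads": n_in, "duplicates": n_dup}
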