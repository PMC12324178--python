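import itertools

import numpy as np
import pysam
import pytest

from seqgrammar.dedup import (
    AlignedReadKey,
    DUPLICATE_FLAG,
    dedup_bam,
    group_candidates,
    mark_duplicates,
)
from seqgrammar.demux import levenshtein


def key(rid, start, end, strand="+", cbc="AAAA", umi="ACGTAC", mapq=60, ref="chr1"):
    return AlignedReadKey(ref, strand, cbc, start, end, umi, mapq, rid)


def test_window_chaining_examples():
    pair = [key("a", 100, 600), key("b", 105, 608)]
    assert len(group_candidates(pair, window=10)) == 1
    assert group_candidates([key("a", 100, 600), key("b", 105, 620)], window=10) == []
    diff_cell = [key("a", 100, 600), key("b", 100, 600, cbc="TTTT")]
    assert group_candidates(diff_cell, window=10, per_cell=True) == []
    assert len(group_candidates(diff_cell, window=10, per_cell=False)) == 1
    diff_strand = [key("a", 100, 600), key("b", 100, 600, strand="-")]
    assert group_candidates(diff_strand, window=10) == []


def test_mark_duplicates_umi_clusters():
    cand = [
        key("a", 100, 600, umi="AAAAAA", mapq=50),
        key("b", 101, 601, umi="AAAAAT", mapq=60),
        key("c", 102, 602, umi="TTTTTT", mapq=60),
    ]
    marks = mark_duplicates([cand], umi_threshold=2)
    assert set(marks) == {"a", "b"}  # TTTTTT alone, unflagged, untagged
    assert marks["b"][0] is False  # higher MAPQ representative
    assert marks["a"][0] is True
    assert marks["a"][1] == marks["b"][1]
    # identical UMIs, threshold 0
    cand = [key(r, 100, 600, umi="ACGTAC", mapq=60) for r in "abc"]
    marks = mark_duplicates([cand], umi_threshold=0)
    assert sum(1 for d, _ in marks.values() if d) == 2
    reps = [r for r, (d, _) in marks.items() if not d]
    assert reps == ["a"]  # MAPQ tie -> smallest start -> lexicographic id


def brute_force_marks(keys, window=10, umi_threshold=2, per_cell=True):
    """All-pairs reference implementation via explicit graph closure."""
    n = len(keys)
    # stage 1: coordinate graph
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = keys[i], keys[j]
        if a.reference != b.reference or a.strand != b.strand:
            continue
        if per_cell and a.cbc != b.cbc:
            continue
        if abs(a.start - b.start) <= window and abs(a.end - b.end) <= window:
            adj[i].add(j)
            adj[j].add(i)

    def components(nodes, neighbours):
        seen, comps = set(), []
        for s in nodes:
            if s in seen:
                continue
            stack, comp = [s], []
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                comp.append(v)
                stack.extend(neighbours(v))
            comps.append(comp)
        return comps

    flagged = {}
    for comp in components(range(n), lambda v: adj[v]):
        if len(comp) < 2:
            continue
        # stage 2: UMI graph inside the candidate set
        uadj = {i: set() for i in comp}
        for i, j in itertools.combinations(comp, 2):
            if levenshtein(keys[i].umi, keys[j].umi) <= umi_threshold:
                uadj[i].add(j)
                uadj[j].add(i)
        for cluster in components(comp, lambda v: uadj[v]):
            if len(cluster) < 2:
                continue
            rep = min(
                cluster,
                key=lambda v: (-keys[v].mapq, keys[v].start, keys[v].read_id),
            )
            for v in cluster:
                flagged[keys[v].read_id] = v != rep
    return flagged


def jittered_keys(n, rng):
    """Simulated PCR duplicate families with <=10 bp jitter, <=2 UMI errors."""
    bases = "ACGT"
    keys = []
    i = 0
    while len(keys) < n:
        start = int(rng.integers(0, 5000))
        end = start + int(rng.integers(200, 600))
        cbc = "".join(rng.choice(list(bases)) for _ in range(8))
        umi = "".join(rng.choice(list(bases)) for _ in range(6))
        strand = "+" if rng.random() < 0.5 else "-"
        fam = int(rng.integers(1, 5))
        for _ in range(min(fam, n - len(keys))):
            u = list(umi)
            for _ in range(int(rng.integers(0, 3))):
                u[int(rng.integers(0, len(u)))] = rng.choice(list(bases))
            keys.append(
                AlignedReadKey(
                    "chr1",
                    strand,
                    cbc,
                    start + int(rng.integers(-5, 6)),
                    end + int(rng.integers(-5, 6)),
                    "".join(u),
                    int(rng.integers(10, 61)),
                    f"r{i}",
                )
            )
            i += 1
    return keys


def test_marks_equal_brute_force_oracle():
    rng = np.random.default_rng(0)
    keys = jittered_keys(400, rng)
    cands = group_candidates(keys, window=10, per_cell=True)
    marks = {r: d for r, (d, _) in mark_duplicates(cands, 2).items()}
    assert marks == brute_force_marks(keys, 10, 2, True)


def test_marks_independent_of_input_order():
    rng = np.random.default_rng(1)
    keys = jittered_keys(150, rng)
    marks1 = {r: d for r, (d, _) in mark_duplicates(group_candidates(keys), 2).items()}
    perm = [keys[i] for i in rng.permutation(len(keys))]
    marks2 = {r: d for r, (d, _) in mark_duplicates(group_candidates(perm), 2).items()}
    assert marks1 == marks2


def write_bam(path, rows, sort=True):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "queryname"},
        "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
    }
    rows = sorted(rows, key=lambda r: (r[1], r[2])) if sort else rows
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rid, ref, start, length, strand, cbc, umi, mapq in rows:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rid
            a.reference_name = ref
            a.reference_start = start
            a.query_sequence = "A" * length
            a.cigarstring = f"{length}M"
            a.mapping_quality = mapq
            a.flag = 16 if strand == "-" else 0
            if cbc:
                a.set_tag("CB", cbc)
                a.set_tag("UB", umi)
            bam.write(a)
    pysam.index(str(path))


def test_dedup_bam_flags_and_conservation(tmp_path):
    rows = [
        # one duplicate family of 3 on chr1
        ("d1", "chr1", 100, 500, "+", "AAAA", "ACGTAC", 60),
        ("d2", "chr1", 104, 498, "+", "AAAA", "ACGTAT", 50),
        ("d3", "chr1", 98, 505, "+", "AAAA", "ACGTAC", 55),
        # same window, different cell
        ("e1", "chr1", 100, 500, "+", "TTTT", "ACGTAC", 60),
        # far away
        ("f1", "chr1", 5000, 5400, "+", "AAAA", "ACGTAC", 60),
        # untagged read passes through
        ("g1", "chr2", 100, 400, "+", "", "", 60),
    ]
    src = tmp_path / "in.bam"
    out = tmp_path / "out.bam"
    write_bam(src, rows)
    stats = dedup_bam(src, out, window=10, umi_threshold=2, per_cell=True)
    assert stats == {"reads": 6, "duplicates": 2}
    with pysam.AlignmentFile(out) as bam:
        flags = {a.query_name: bool(a.flag & DUPLICATE_FLAG) for a in bam}
    assert flags == {"d1": False, "d2": True, "d3": True, "e1": False, "f1": False, "g1": False}
    with pysam.AlignmentFile(out) as bam:
        groups = {a.query_name: a.get_tag("UG") for a in bam if a.has_tag("UG")}
    assert groups["d1"] == groups["d2"] == groups["d3"]


def test_dedup_bam_rejects_unsorted(tmp_path):
    src = tmp_path / "u.bam"
    rows = [("a", "chr1", 100, 300, "+", "AAAA", "ACGTAC", 60)]
    write_bam(src, rows, sort=False)
    with pytest.raises(ValueError, match="coordinate-sorted"):
        dedup_bam(src, tmp_path / "o.bam")
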