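import numpy as np
import pytest

import seqgrammar as sg
from seqgrammar.annotate import (
    Segment,
    segments_from_labels,
    smooth_segments,
    validate_structure,
    split_concatemer,
    annotate_read,
)
from seqgrammar.simulate import ARTIFACT_PATTERNS, simulate_artifact_read, ErrorRates


def segs_from_names(names_lengths):
    segs, pos = [], 0
    for name, n in names_lengths:
        segs.append(Segment(name, pos, pos + n))
        pos += n
    return segs


def test_segments_are_maximal_runs():
    labels = np.array([2, 2, 2, 2, 3, 3, 3, 4, 4])
    schema = ("PAD", "RANDOM", "A", "B", "C")
    segs = segments_from_labels(labels, schema)
    assert [(s.label, s.start, s.end) for s in segs] == [
        ("A", 0, 4),
        ("B", 4, 7),
        ("C", 7, 9),
    ]
    single = segments_from_labels(np.array([3] * 5), schema)
    assert len(single) == 1 and single[0].end == 5


def test_segments_round_trip_random_vector():
    rng = np.random.default_rng(0)
    schema = tuple("PRABCDE")
    labels = rng.integers(0, 7, size=200)
    segs = segments_from_labels(labels, schema)
    rebuilt = np.concatenate(
        [np.full(s.length, schema.index(s.label)) for s in segs]
    )
    assert np.array_equal(rebuilt, labels)
    assert segs[0].start == 0 and segs[-1].end == 200
    for a, b in zip(segs, segs[1:]):
        assert a.end == b.start and a.label != b.label


def test_smoothing_absorbs_short_flicker():
    segs = segs_from_names([("CDNA", 50), ("UMI", 2), ("CDNA", 30)])
    out = smooth_segments(segs)
    assert [(s.label, s.start, s.end) for s in out] == [("CDNA", 0, 82)]
    # a 3bp run is kept
    segs = segs_from_names([("CDNA", 50), ("UMI", 3), ("CDNA", 30)])
    assert len(smooth_segments(segs)) == 3
    # differing flanks are kept
    segs = segs_from_names([("CDNA", 50), ("UMI", 2), ("POLYT", 30)])
    assert len(smooth_segments(segs)) == 3


def test_validate_forward_and_reverse_orders(layout):
    fwd = segs_from_names(
        [("ADAPTER5", 22), ("CBC", 16), ("UMI", 12), ("POLYT", 20), ("CDNA", 150), ("ADAPTER3", 30)]
    )
    call = validate_structure(fwd, layout)
    assert (call.status, call.orientation) == ("valid", "+")
    assert call.render() == "valid (+)"
    rev = segs_from_names(
        [("RANDOM", 10), ("ADAPTER3", 30), ("CDNA", 150), ("POLYT", 20), ("UMI", 12), ("CBC", 16), ("ADAPTER5", 22), ("RANDOM", 4)]
    )
    assert validate_structure(rev, layout).orientation == "-"


def test_validate_missing_element_is_invalid(layout):
    segs = segs_from_names(
        [("ADAPTER5", 22), ("CBC", 16), ("UMI", 12), ("CDNA", 150), ("ADAPTER3", 30)]
    )
    assert validate_structure(segs, layout).status == "invalid"
    # internal long RANDOM is a violation
    segs = segs_from_names(
        [("ADAPTER5", 22), ("CBC", 16), ("RANDOM", 50), ("UMI", 12), ("POLYT", 20), ("CDNA", 150), ("ADAPTER3", 30)]
    )
    assert validate_structure(segs, layout).status == "invalid"


def test_concatemer_x2_call_and_render(layout):
    one = [("ADAPTER5", 22), ("CBC", 16), ("UMI", 12), ("POLYT", 20), ("CDNA", 150), ("ADAPTER3", 30)]
    call = validate_structure(segs_from_names(one + one), layout)
    assert call.status == "concatemer"
    assert call.fragment_count == 2
    assert call.orientation_counts == {"+": 2}
    assert call.render() == "concatenated reads x2 (+:2)"
    assert len(call.sub_spans) == 2


def test_concatemer_shared_junction_segment(layout):
    """FWD_REV junctions merge the two ADAPTER3 runs into one segment."""
    fwd = [("ADAPTER5", 22), ("CBC", 16), ("UMI", 12), ("POLYT", 20), ("CDNA", 150)]
    merged = [("ADAPTER3", 60)]
    rev = [("CDNA", 140), ("POLYT", 18), ("UMI", 12), ("CBC", 16), ("ADAPTER5", 22)]
    call = validate_structure(segs_from_names(fwd + merged + rev), layout)
    assert call.status == "concatemer"
    assert call.fragment_count == 2
    assert tuple(o for _, _, o in call.sub_spans) == ("+", "-")
    assert call.render() == "concatenated reads x2 (+:1,-:1)"


@pytest.mark.parametrize("pattern", sorted(ARTIFACT_PATTERNS))
def test_all_artifact_patterns_parse_exactly(layout, whitelist, pattern):
    cfg = sg.SimulationConfig(
        layout=layout, whitelist=whitelist, error_rates=ErrorRates.zero(), seed=2
    )
    rng = np.random.default_rng(11)
    for _ in range(3):
        r = simulate_artifact_read(pattern, layout, cfg, rng)
        call = validate_structure(
            segments_from_labels(r.labels, layout.label_schema), layout
        )
        assert call.status == "concatemer"
        assert tuple(o for _, _, o in call.sub_spans) == ARTIFACT_PATTERNS[pattern]


def test_split_concatemer_subreads_revalidate(layout, whitelist):
    cfg = sg.SimulationConfig(
        layout=layout, whitelist=whitelist, error_rates=ErrorRates.zero(),
        flank_length_range=(0, 0), seed=4,
    )
    rng = np.random.default_rng(5)
    r = simulate_artifact_read("FWD_REV_FWD", layout, cfg, rng)
    segs = segments_from_labels(r.labels, layout.label_schema)
    call = validate_structure(segs, layout)
    recs = split_concatemer(r.sequence, call, segments=segs, read_id=r.read_id)
    assert [rec["orientation"] for rec in recs] == ["+", "-", "+"]
    assert sum(len(rec["sequence"]) for rec in recs) == len(r.sequence)
    for rec in recs:
        sub_call = validate_structure(rec["segments"], layout)
        assert sub_call.status == "valid"
        assert sub_call.orientation == rec["orientation"]
    with pytest.raises(ValueError):
        split_concatemer(r.sequence, sg.StructuralCall(status="valid"))


def test_annotation_mode_concordance(reference):
    """HYB and CRF modes agree on the valid/invalid verdict for >= 99% of
    default-error-rate reads."""
    from seqgrammar.annotate import annotate_reads
    from seqgrammar.simulate import simulate_reads

    lay, wl = reference["layout"], reference["whitelist"]
    reads = simulate_reads(
        sg.SimulationConfig(layout=lay, n_reads=5000, whitelist=wl, seed=404),
        artifact_fraction=0.1,
    )
    pairs = [(r.read_id, r.sequence) for r in reads]
    verdicts = {}
    for mode in ("HYB", "CRF"):
        valid, invalid = annotate_reads(
            iter(pairs), reference["fast"], reference["crf"], lay,
            mode=mode, token_budget=65_536,
        )
        assert len(valid) + len(invalid) == len(reads)  # conservation
        verdicts[mode] = {rid: True for rid in valid.read_id}
    agree = np.mean(
        [
            verdicts["HYB"].get(rid, False) == verdicts["CRF"].get(rid, False)
            for rid, _ in pairs
        ]
    )
    assert agree >= 0.99


def test_hybrid_dispatch_short_circuits(layout, clean_reads):
    """Confident, valid fast-model labels never reach the CRF model."""
    from seqgrammar.annotate import annotate_reads

    class PerfectModel:
        config = type("C", (), {"head": "softmax"})()

        def __init__(self, truth):
            self.truth = truth

        def predict(self, seqs, token_budget=0):
            return [
                (self.truth[s], np.ones(len(s))) for s in seqs
            ]

    class ExplodingModel:
        config = type("C", (), {"head": "crf"})()

        def predict(self, seqs, token_budget=0):
            raise AssertionError("CRF model should not be consulted")

    truth = {r.sequence: np.asarray(r.labels) for r in clean_reads}
    pairs = [(r.read_id, r.sequence) for r in clean_reads]
    valid, invalid = annotate_reads(
        iter(pairs), PerfectModel(truth), ExplodingModel(), layout, mode="HYB"
    )
    assert len(valid) == len(clean_reads) and len(invalid) == 0


def test_annotate_read_tiles_and_coords(clean_reads, layout):
    r = clean_reads[0]
    anno = annotate_read(r.read_id, r.labels, None, layout)
    assert anno.segments[0].start == 0
    assert anno.segments[-1].end == len(r.sequence)
    if anno.call.orientation == "+":
        cs, ce = anno.element_coords["CBC_start"], anno.element_coords["CBC_end"]
        assert r.sequence[cs:ce] == r.truth_cbc
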