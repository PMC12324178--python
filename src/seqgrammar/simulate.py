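"""Ground-truth read simulation with an ONT-like i.i.d. error model.

Reads are assembled by concatenating realized layout elements in canonical
order (or its reverse complement), bracketed by random flanking bases of
random length, and then corrupted base-by-base with independent
substitution / insertion / deletion events at configurable rates.  Every
simulated read carries a per-base ground-truth label vector, the true cell
barcode and UMI, and — for concatemer artifacts — the true sub-fragment
spans and orientations.  Defaults follow the benchmark conditions: 5%
substitutions, 5% insertions, 6.13% deletions, 0-70 bp flanks, 100-500 bp
inserts, cell barcodes drawn from a 6,500-entry whitelist.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from seqgrammar.layout import LibraryLayout, RANDOM_LABEL

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ErrorRates:
    """Per-base, independent error probabilities of the ONT-like model."""

    substitution: float = 0.05
    insertion: float = 0.05
    deletion: float = 0.0613

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate {v} outside [0, 1]")

    @classmethod
    def zero(cls) -> "ErrorRates":
        return cls(0.0, 0.0, 0.0)


#: The eight concatemer artifact patterns: name -> fragment orientations.
ARTIFACT_PATTERNS: dict[str, tuple[str, ...]] = {
    "FWD_FWD": ("+", "+"),
    "FWD_REV": ("+", "-"),
    "FWD_FWD_REV": ("+", "+", "-"),
    "FWD_REV_FWD": ("+", "-", "+"),
    "FWD_REV_REV": ("+", "-", "-"),
    "REV_FWD_FWD": ("-", "+", "+"),
    "REV_FWD_REV": ("-", "+", "-"),
    "REV_REV_FWD": ("-", "-", "+"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated dataset.

    ``n_cells`` barcodes are sampled from ``whitelist`` to form the cell
    pool from which every read's true CBC is drawn (``None``: use the whole
    whitelist, matching a 6,500-barcode pool).  ``orientation_mix`` is the
    fraction of reads emitted as the reverse-complemented strand.
    """

    layout: LibraryLayout
    n_reads: int = 1000
    whitelist: tuple[str, ...] = ()
    n_cells: int | None = None
    insert_length_range: tuple[int, int] = (100, 500)
    flank_length_range: tuple[int, int] = (0, 70)
    error_rates: ErrorRates = field(default_factory=ErrorRates)
    seed: int = 0
    orientation_mix: float = 0.5
    cbc_label: str = "CBC"
    umi_label: str = "UMI"

    def __post_init__(self) -> None:
        if self.n_cells is not None and self.n_cells > len(self.whitelist):
            raise ValueError("n_cells exceeds whitelist size")
        for lo, hi in (self.insert_length_range, self.flank_length_range):
            if lo < 0 or lo > hi:
                raise ValueError(f"degenerate range ({lo}, {hi})")

    def cell_pool(self, rng: np.random.Generator) -> tuple[str, ...]:
        if not self.whitelist:
            return ()
        if self.n_cells is None or self.n_cells == len(self.whitelist):
            return tuple(self.whitelist)
        idx = rng.choice(len(self.whitelist), size=self.n_cells, replace=False)
        return tuple(self.whitelist[i] for i in idx)


@dataclass
class SimulatedRead:
    """A simulated read with base-level ground truth."""

    read_id: str
    sequence: str
    labels: np.ndarray  # per-base label ids, len == len(sequence)
    truth_cbc: str | None
    truth_umi: str | None
    orientation: str  # '+' or '-' (canonical reads; first fragment for artifacts)
    artifact_pattern: str | None = None
    #: (start, end, orientation) of each true sub-fragment, flanks excluded.
    fragments: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels):
            raise ValueError("labels and sequence lengths differ")


def random_whitelist(
    n: int, length: int = 16, rng: np.random.Generator | int | None = None
) -> tuple[str, ...]:
    """``n`` unique uniform-random barcodes (synthetic whitelist stand-in).

    Real chemistries ship curated whitelists (e.g. the 10x 3M list); uniform
    random barcodes of the same length reproduce the pairwise-distance
    statistics that matter for correction benchmarks.
    """
    rng = np.random.default_rng(rng)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=(n - len(out), length))
        for row in codes:
            bc = _BASES[row].tobytes().decode()
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return tuple(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _realize_molecule(
    layout: LibraryLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    cell_pool: Sequence[str],
) -> tuple[str, np.ndarray, str | None, str | None]:
    """One error-free forward molecule (no flanks): sequence + labels."""
    parts: list[str] = []
    label_runs: list[tuple[int, int]] = []  # (label_id, length)
    cbc = umi = None
    for elem in layout.elements:
        lid = layout.label_id(elem.label)
        if elem.kind == "fixed_sequence":
            s = elem.sequence
        elif elem.kind == "random_fixed_length":
            if elem.label == config.cbc_label and cell_pool:
                s = cell_pool[rng.integers(0, len(cell_pool))]
                cbc = s
            else:
                s = _random_seq(rng, elem.length_min)
                if elem.label == config.umi_label:
                    umi = s
        elif elem.kind == "homopolymer":
            n = int(rng.integers(elem.length_min, elem.length_max + 1))
            s = elem.base * n
        elif elem.kind == "variable_length":
            lo, hi = elem.length_min, elem.length_max
            if elem.label.upper() in ("CDNA", "INSERT"):
                lo, hi = config.insert_length_range
            s = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        else:  # random_flank inside a layout
            s = _random_seq(rng, int(rng.integers(elem.length_min, elem.length_max + 1)))
        parts.append(s)
        label_runs.append((lid, len(s)))
    seq = "".join(parts)
    labels = np.repeat(
        np.array([l for l, _ in label_runs], dtype=np.uint8),
        np.array([n for _, n in label_runs], dtype=np.int64),
    )
    return seq, labels, cbc, umi


def sample_clean_read(
    layout: LibraryLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_id: str = "read",
    cell_pool: Sequence[str] | None = None,
) -> SimulatedRead:
    """One error-free canonical read: flank + molecule + flank, oriented."""
    if cell_pool is None:
        cell_pool = config.cell_pool(rng)
    seq, labels, cbc, umi = _realize_molecule(layout, config, rng, cell_pool)
    orientation = "-" if rng.random() < config.orientation_mix else "+"
    if orientation == "-":
        seq = reverse_complement(seq)
        labels = labels[::-1].copy()
    flo, fhi = config.flank_length_range
    left = int(rng.integers(flo, fhi + 1))
    right = int(rng.integers(flo, fhi + 1))
    rnd_id = layout.label_id(RANDOM_LABEL)
    full_seq = _random_seq(rng, left) + seq + _random_seq(rng, right)
    full_labels = np.concatenate(
        [
            np.full(left, rnd_id, dtype=np.uint8),
            labels,
            np.full(right, rnd_id, dtype=np.uint8),
        ]
    )
    return SimulatedRead(
        read_id=read_id,
        sequence=full_seq,
        labels=full_labels,
        truth_cbc=cbc,
        truth_umi=umi,
        orientation=orientation,
        fragments=((left, left + len(seq), orientation),),
    )


def simulate_artifact_read(
    pattern: str,
    layout: LibraryLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_id: str = "read",
    cell_pool: Sequence[str] | None = None,
) -> SimulatedRead:
    """A concatemer artifact: fragments joined end-to-end, flanked outside.

    ``pattern`` is a key of :data:`ARTIFACT_PATTERNS` (e.g. ``FWD_REV_FWD``).
    Each fragment is an independently sampled full canonical molecule; there
    is no spacer between fragments.
    """
    orientations = ARTIFACT_PATTERNS[pattern]
    if cell_pool is None:
        cell_pool = config.cell_pool(rng)
    rnd_id = layout.label_id(RANDOM_LABEL)
    flo, fhi = config.flank_length_range
    left = int(rng.integers(flo, fhi + 1))
    right = int(rng.integers(flo, fhi + 1))
    seqs: list[str] = [_random_seq(rng, left)]
    lab_parts: list[np.ndarray] = [np.full(left, rnd_id, dtype=np.uint8)]
    spans: list[tuple[int, int, str]] = []
    pos = left
    first_cbc = first_umi = None
    for o in orientations:
        seq, labels, cbc, umi = _realize_molecule(layout, config, rng, cell_pool)
        if o == "-":
            seq = reverse_complement(seq)
            labels = labels[::-1].copy()
        if first_cbc is None:
            first_cbc, first_umi = cbc, umi
        seqs.append(seq)
        lab_parts.append(labels)
        spans.append((pos, pos + len(seq), o))
        pos += len(seq)
    seqs.append(_random_seq(rng, right))
    lab_parts.append(np.full(right, rnd_id, dtype=np.uint8))
    return SimulatedRead(
        read_id=read_id,
        sequence="".join(seqs),
        labels=np.concatenate(lab_parts),
        truth_cbc=first_cbc,
        truth_umi=first_umi,
        orientation=orientations[0],
        artifact_pattern=pattern,
        fragments=tuple(spans),
    )


def inject_errors(
    sequence: str,
    labels: np.ndarray,
    rates: ErrorRates,
    rng: np.random.Generator,
    return_map: bool = False,
):
    """Apply i.i.d. per-base errors; labels follow their bases.

    Per input base, independently: with p_ins a uniform random base is
    inserted before it (inheriting its label, keeping label runs contiguous);
    the base itself is deleted with p_del, else substituted to a uniformly
    random *different* base with p_sub.

    With ``return_map`` a third value is returned: an int64 vector of length
    ``len(sequence) + 1`` mapping every input boundary coordinate to its
    output coordinate (used to carry truth spans through error injection).
    """
    if len(sequence) != len(labels):
        raise ValueError("labels and sequence lengths differ")
    L = len(sequence)
    if L == 0:
        empty_map = np.zeros(1, dtype=np.int64)
        return (sequence, labels[:0], empty_map) if return_map else (sequence, labels[:0])
    codes = _encode_acgt(sequence)
    ins = rng.random(L) < rates.insertion
    dele = rng.random(L) < rates.deletion
    sub = (rng.random(L) < rates.substitution) & ~dele
    # substitutions: shift by 1-3 mod 4 guarantees a different base
    codes = codes.copy()
    n_sub = int(sub.sum())
    if n_sub:
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=n_sub)) % 4
    keep = ~dele
    counts = ins.astype(np.int64) + keep.astype(np.int64)
    offsets = np.cumsum(counts) - counts
    out_len = int(counts.sum())
    out_codes = np.empty(out_len, dtype=np.uint8)
    out_labels = np.empty(out_len, dtype=np.uint8)
    ins_pos = offsets[ins]
    n_ins = len(ins_pos)
    if n_ins:
        out_codes[ins_pos] = rng.integers(0, 4, size=n_ins)
        out_labels[ins_pos] = labels[ins]
    keep_pos = offsets[keep] + ins[keep]
    out_codes[keep_pos] = codes[keep]
    out_labels[keep_pos] = labels[keep]
    out_seq = _BASES[out_codes].tobytes().decode()
    if return_map:
        coord_map = np.concatenate([offsets, [out_len]])
        return out_seq, out_labels, coord_map
    return out_seq, out_labels


def _encode_acgt(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    lut[ord("A")] = 0
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[raw]


def simulate_reads(
    config: SimulationConfig,
    artifact_fraction: float = 0.0,
    patterns: Sequence[str] | None = None,
) -> list[SimulatedRead]:
    """Simulate ``config.n_reads`` reads in memory (canonical + artifacts).

    Each read is an artifact with probability ``artifact_fraction``, its
    pattern drawn uniformly from ``patterns`` (default: all eight).  Errors
    are applied uniformly across the whole read, flanks included.
    """
    if not 0.0 <= artifact_fraction <= 1.0:
        raise ValueError("artifact_fraction outside [0, 1]")
    patterns = list(patterns if patterns is not None else ARTIFACT_PATTERNS)
    rng = np.random.default_rng(config.seed)
    cell_pool = config.cell_pool(rng)
    reads: list[SimulatedRead] = []
    for i in range(config.n_reads):
        rid = f"sim_{config.seed}_{i}"
        if artifact_fraction and rng.random() < artifact_fraction:
            pattern = patterns[rng.integers(0, len(patterns))]
            read = simulate_artifact_read(
                pattern, config.layout, config, rng, read_id=rid, cell_pool=cell_pool
            )
        else:
            read = sample_clean_read(
                config.layout, config, rng, read_id=rid, cell_pool=cell_pool
            )
        seq, labels, cmap = inject_errors(
            read.sequence, read.labels, config.error_rates, rng, return_map=True
        )
        read.sequence, read.labels = seq, labels
        read.fragments = tuple(
            (int(cmap[s]), int(cmap[e]), o) for s, e, o in read.fragments
        )
        reads.append(read)
    return reads


def _rle(labels: np.ndarray, schema: Sequence[str]) -> str:
    """Run-length encoding of a label vector, e.g. ``RANDOM:12;ADAPTER5:22``."""
    if len(labels) == 0:
        return ""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return ";".join(
        f"{schema[labels[s]]}:{e - s}" for s, e in zip(starts, ends)
    )


def simulate_dataset(
    config: SimulationConfig,
    out_fastq: str | Path,
    out_truth: str | Path,
    artifact_fraction: float = 0.0,
    patterns: Sequence[str] | None = None,
) -> list[SimulatedRead]:
    """Write a simulated dataset: FASTQ + tab-separated ground-truth table.

    The FASTQ uses a constant placeholder quality ('I'); annotation never
    consumes base qualities.  The truth table records read id, true CBC/UMI,
    orientation, artifact pattern, sub-fragment spans and the run-length
    encoded per-base label track.  Byte-identical across runs for a fixed
    config (seeded).
    """
    reads = simulate_reads(config, artifact_fraction, patterns)
    schema = config.layout.label_schema
    out_fastq, out_truth = Path(out_fastq), Path(out_truth)
    opener = gzip.open if out_fastq.suffix == ".gz" else open
    with opener(out_fastq, "wt") as fq, open(out_truth, "w") as tsv:
        tsv.write(
            "read_id\tcbc\tumi\torientation\tartifact_pattern\tfragments\tlabels_rle\n"
        )
        for r in reads:
            fq.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
            frags = ",".join(f"{s}-{e}:{o}" for s, e, o in r.fragments)
            tsv.write(
                f"{r.read_id}\t{r.truth_cbc or ''}\t{r.truth_umi or ''}\t"
                f"{r.orientation}\t{r.artifact_pattern or ''}\t{frags}\t"
                f"{_rle(r.labels, schema)}\n"
            )
    return reads
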