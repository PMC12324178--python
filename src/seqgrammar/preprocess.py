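"""Length-aware binning of reads into columnar (Parquet) files with an index.

Neural inference pads every batch to its longest read, so batching reads of
similar length minimizes wasted compute and memory.  ``bin_reads``
partitions input FASTQ/FASTA records into width-``bin_width`` length bins
(0-499, 500-999, ... for the default 500), writes one Parquet file per bin
with columns ``read_id, sequence, length``, and an index Parquet mapping
every read id to its (bin, row) for random access without scanning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pyarrow as pa
import pyarrow.parquet as pq
import pysam


class PreprocessError(ValueError):
    pass


def assign_bin(length: int, bin_width: int = 500) -> int:
    """Bin id of a read length: ``floor(length / bin_width)``."""
    if length < 1 or bin_width < 1:
        raise PreprocessError(f"length and bin_width must be >= 1, got {length}, {bin_width}")
    return length // bin_width


def bin_label(bin_id: int, bin_width: int = 500) -> str:
    lo = bin_id * bin_width
    return f"{lo}-{lo + bin_width - 1}"


@dataclass
class BinStore:
    """A directory of per-bin Parquet files plus a read-id index."""

    path: Path
    bin_width: int
    index: dict  # read_id -> (bin_id, row)

    @classmethod
    def open(cls, path: str | Path) -> "BinStore":
        path = Path(path)
        meta = json.loads((path / "store.json").read_text())
        tbl = pq.read_table(path / "index.parquet")
        ids = tbl["read_id"].to_pylist()
        bins = tbl["bin_id"].to_pylist()
        rows = tbl["row"].to_pylist()
        index = {r: (b, w) for r, b, w in zip(ids, bins, rows)}
        return cls(path=path, bin_width=meta["bin_width"], index=index)

    def bin_ids(self) -> list[int]:
        return sorted({b for b, _ in self.index.values()})

    def bin_path(self, bin_id: int) -> Path:
        return self.path / f"bin_{bin_id}.parquet"

    def read_bin(self, bin_id: int) -> dict[str, list]:
        tbl = pq.read_table(self.bin_path(bin_id))
        return {name: tbl[name].to_pylist() for name in tbl.column_names}

    def fetch_read(self, read_id: str) -> tuple[str, int, int]:
        """(sequence, length, bin_id) for one read via the index."""
        if read_id not in self.index:
            raise KeyError(f"read id {read_id!r} not in store index")
        bin_id, row = self.index[read_id]
        tbl = pq.read_table(self.bin_path(bin_id))
        seq = tbl["sequence"][row].as_py()
        return seq, len(seq), bin_id

    def __len__(self) -> int:
        return len(self.index)

    def iter_reads(self) -> Iterable[tuple[str, str]]:
        for bin_id in self.bin_ids():
            tbl = self.read_bin(bin_id)
            yield from zip(tbl["read_id"], tbl["sequence"])


def _iter_records(paths: Sequence[str | Path]):
    for p in paths:
        p = str(p)
        try:
            with pysam.FastxFile(p) as fh:
                for ordinal, rec in enumerate(fh):
                    yield rec.name, rec.sequence.upper()
        except Exception as exc:  # unparseable record/file
            raise PreprocessError(f"{p}: failed to parse ({exc})") from exc


def bin_reads(
    inputs: Sequence[str | Path] | str | Path,
    store_path: str | Path,
    bin_width: int = 500,
    threads: int = 1,
) -> BinStore:
    """Partition FASTQ/FASTA(.gz) records into length bins on disk.

    Every record lands in exactly one bin; the result is independent of
    ``threads`` up to within-bin row order (this implementation is
    single-process; the parameter is accepted for interface stability).
    Duplicate read ids are an error naming the id.
    """
    if isinstance(inputs, (str, Path)):
        inputs = [inputs]
    if bin_width < 1:
        raise PreprocessError("bin_width must be >= 1")
    store = Path(store_path)
    store.mkdir(parents=True, exist_ok=True)
    for old in store.glob("bin_*.parquet"):
        old.unlink()
    bins: dict[int, dict[str, list]] = {}
    index: dict[str, tuple[int, int]] = {}
    for read_id, seq in _iter_records(inputs):
        if read_id in index:
            raise PreprocessError(f"duplicate read id {read_id!r}")
        b = assign_bin(max(len(seq), 1), bin_width)
        slot = bins.setdefault(b, {"read_id": [], "sequence": [], "length": []})
        index[read_id] = (b, len(slot["read_id"]))
        slot["read_id"].append(read_id)
        slot["sequence"].append(seq)
        slot["length"].append(len(seq))
    for b, cols in bins.items():
        pq.write_table(pa.table(cols), store / f"bin_{b}.parquet")
    ids = list(index)
    pq.write_table(
        pa.table(
            {
                "read_id": ids,
                "bin_id": [index[r][0] for r in ids],
                "row": [index[r][1] for r in ids],
            }
        ),
        store / "index.parquet",
    )
    (store / "store.json").write_text(json.dumps({"bin_width": bin_width}))
    return BinStore(path=store, bin_width=bin_width, index=index)
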