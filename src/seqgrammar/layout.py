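"""Protocol read architectures (library layouts) and their label grammars.

A :class:`LibraryLayout` is the ordered list of structural elements a
sequencing library places on every molecule — e.g. for the 10x Genomics 3'
single-cell chemistry: 5' adapter, 16 bp cell barcode, 12 bp UMI, polyT
stretch, cDNA insert, 3' adapter.  The layout doubles as a grammar: a read is
structurally valid iff its per-base labels, aggregated into segments, follow
the layout's element order either forward or reversed (the molecule as
reverse-complemented by the sequencer), optionally flanked by runs of random
bases at the read termini.

Layout files are tab-delimited text with three columns::

    label <TAB> kind <TAB> spec

where ``kind`` is one of ``fixed_sequence``, ``random_fixed_length``,
``variable_length``, ``homopolymer``, ``random_flank`` and ``spec`` is,
respectively, a literal ACGT sequence, ``N{k}``, ``{min}-{max}``, a base
followed by a length range (``T 10-60``), or a length range.  Lines starting
with ``#`` are comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

#: Implicit label for random bases appended to read termini by library prep.
RANDOM_LABEL = "RANDOM"
#: Reserved label for batch padding positions (never a real base).
PAD_LABEL = "PAD"

KINDS = (
    "fixed_sequence",
    "random_fixed_length",
    "variable_length",
    "homopolymer",
    "random_flank",
)

_BASES = set("ACGT")


class LayoutError(ValueError):
    """Malformed or inconsistent layout definition."""


@dataclass(frozen=True)
class ElementSpec:
    """One structural element of a library layout.

    Parameters
    ----------
    label:
        Short identifier, unique within a layout (e.g. ``CBC``).
    kind:
        One of :data:`KINDS`.
    sequence:
        Literal nucleotide sequence; ``fixed_sequence`` only.
    length_min, length_max:
        Realized length range for the non-fixed kinds.
    base:
        Base identity for ``homopolymer`` elements.
    """

    label: str
    kind: str
    sequence: str = ""
    length_min: int = 0
    length_max: int = 0
    base: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise LayoutError(f"unknown element kind {self.kind!r}")
        if not self.label or any(c.isspace() for c in self.label):
            raise LayoutError(f"bad element label {self.label!r}")
        if self.kind == "fixed_sequence":
            if not self.sequence or set(self.sequence) - _BASES:
                raise LayoutError(
                    f"{self.label}: fixed_sequence needs a non-empty ACGT sequence"
                )
        else:
            if self.length_min < 0 or self.length_min > self.length_max:
                raise LayoutError(
                    f"{self.label}: invalid length range "
                    f"{self.length_min}-{self.length_max}"
                )
        if self.kind == "homopolymer" and self.base not in _BASES:
            raise LayoutError(f"{self.label}: homopolymer needs a single base identity")

    @property
    def spec_string(self) -> str:
        """Third-column representation used by :func:`serialize_layout`."""
        if self.kind == "fixed_sequence":
            return self.sequence
        if self.kind == "random_fixed_length":
            return f"N{{{self.length_min}}}"
        if self.kind == "homopolymer":
            return f"{self.base} {self.length_min}-{self.length_max}"
        return f"{self.length_min}-{self.length_max}"


@dataclass(frozen=True)
class LibraryLayout:
    """Ordered element schema of a library protocol."""

    name: str
    elements: tuple[ElementSpec, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.elements]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise LayoutError(f"duplicate element label(s): {', '.join(dup)}")
        for reserved in (RANDOM_LABEL, PAD_LABEL):
            if reserved in labels:
                raise LayoutError(f"label {reserved!r} is reserved")
        if not self.elements:
            raise LayoutError("layout has no elements")

    @property
    def label_order(self) -> tuple[str, ...]:
        """Element labels in layout (forward) order."""
        return tuple(e.label for e in self.elements)

    @property
    def label_schema(self) -> tuple[str, ...]:
        """All label names indexed by integer label id.

        Id 0 is reserved for padding, id 1 for terminal random flanks, then
        the layout elements in order.  This is the label binarizer shared by
        the simulator, the neural models and the grammar validator.
        """
        return (PAD_LABEL, RANDOM_LABEL) + self.label_order

    def label_id(self, label: str) -> int:
        return self.label_schema.index(label)

    def element(self, label: str) -> ElementSpec:
        for e in self.elements:
            if e.label == label:
                return e
        raise KeyError(label)


_NK_RE = re.compile(r"^N\{(\d+)\}$")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")
_HOMOPOLYMER_RE = re.compile(r"^([ACGT])\s+(\d+)-(\d+)$")


def _parse_spec(label: str, kind: str, spec: str, lineno: int) -> ElementSpec:
    if kind == "fixed_sequence":
        return ElementSpec(label, kind, sequence=spec.upper())
    if kind == "random_fixed_length":
        m = _NK_RE.match(spec)
        if not m:
            raise LayoutError(f"line {lineno}: expected N{{k}} spec, got {spec!r}")
        k = int(m.group(1))
        return ElementSpec(label, kind, length_min=k, length_max=k)
    if kind == "homopolymer":
        m = _HOMOPOLYMER_RE.match(spec)
        if not m:
            raise LayoutError(
                f"line {lineno}: expected 'BASE min-max' spec, got {spec!r}"
            )
        return ElementSpec(
            label,
            kind,
            base=m.group(1),
            length_min=int(m.group(2)),
            length_max=int(m.group(3)),
        )
    if kind in ("variable_length", "random_flank"):
        m = _RANGE_RE.match(spec)
        if not m:
            raise LayoutError(f"line {lineno}: expected min-max spec, got {spec!r}")
        return ElementSpec(
            label, kind, length_min=int(m.group(1)), length_max=int(m.group(2))
        )
    raise LayoutError(f"line {lineno}: unknown kind {kind!r}")


def parse_layout(path: str | Path, name: str | None = None) -> LibraryLayout:
    """Parse a tab-delimited layout file into a :class:`LibraryLayout`.

    Raises
    ------
    LayoutError
        On a malformed line (naming its line number), duplicate labels, or an
        empty file.
    """
    path = Path(path)
    elements: list[ElementSpec] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LayoutError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        label, kind, spec = (p.strip() for p in parts)
        elements.append(_parse_spec(label, kind, spec, lineno))
    if not elements:
        raise LayoutError(f"{path}: no layout elements found")
    return LibraryLayout(name or path.stem, tuple(elements))


def serialize_layout(layout: LibraryLayout) -> str:
    """Render a layout back to its tab-delimited file form (round-trippable)."""
    lines = [f"# layout: {layout.name}"]
    for e in layout.elements:
        lines.append(f"{e.label}\t{e.kind}\t{e.spec_string}")
    return "\n".join(lines) + "\n"


def canonical_orders(
    layout: LibraryLayout, allow_flanks: bool = True
) -> set[tuple[str, ...]]:
    """The label orders a structurally valid single-fragment read may show.

    Exactly two orders exist per layout: the forward element order and its
    reversal (the molecule read from the other strand; labels are unchanged
    because each element keeps its identity under reverse complement).  With
    ``allow_flanks`` each order is bracketed by the implicit terminal
    ``RANDOM`` label.
    """
    fwd = layout.label_order
    rev = tuple(reversed(fwd))
    if allow_flanks:
        fwd = (RANDOM_LABEL,) + fwd + (RANDOM_LABEL,)
        rev = (RANDOM_LABEL,) + rev + (RANDOM_LABEL,)
    return {fwd, rev}


def builtin_layout(name: str = "tenx_3prime_v3") -> LibraryLayout:
    """Load a layout shipped with the package (currently ``tenx_3prime_v3``)."""
    with resources.as_file(
        resources.files("seqgrammar.data").joinpath(f"{name}.tsv")
    ) as p:
        return parse_layout(p, name=name)
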