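"""Alignment container and I/O.

The :class:`Msa` is the universal substrate for the pipeline: an aligned,
region-annotated set of sequences over the alphabet ``{A,C,G,T,-,N}``.
Coordinates are 0-based and half-open everywhere.  Regions (introns, exons)
tile the alignment and may carry a codon reading frame; region maps are a
4-column TSV ``name<TAB>start<TAB>end<TAB>frame`` with ``NA`` for
non-coding regions.

``N`` is treated as missing data throughout the package: excluded from
distances, similarity windows, and parsimony state sets.  IUPAC ambiguity
codes other than N are mapped to N by default (or rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGT-N")
AMBIGUITY = set("RYSWKMBDHVU")

__all__ = ["Region", "Msa", "read_msa", "write_msa", "read_region_map",
           "write_region_map", "concatenate", "default_species"]


@dataclass(frozen=True)
class Region:
    """Half-open alignment interval, optionally with a codon frame.

    ``frame`` is the alignment column (within the region, 0-based) of the
    first complete codon's first position, or None for non-coding regions.
    """

    name: str
    start: int
    end: int
    frame: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def default_species(label: str) -> str:
    """Species tag from a sequence label: the prefix before the first '_'."""
    return label.split("_", 1)[0]


@dataclass
class Msa:
    labels: list[str]
    rows: list[str]
    regions: list[Region] = field(default_factory=list)
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: rows of unequal length")
        bad = set("".join(self.rows)) - ALPHABET
        if bad:
            raise ValueError(f"characters outside ACGT-N: {sorted(bad)}")
        if not self.species_of:
            self.species_of = {l: default_species(l) for l in self.labels}
        missing = [l for l in self.labels if l not in self.species_of]
        if missing:
            raise ValueError(f"labels without species tag: {missing}")
        self._check_regions()

    def _check_regions(self):
        if not self.regions:
            return
        pos = 0
        for r in self.regions:
            if r.start != pos:
                raise ValueError(
                    f"regions do not tile alignment: {r.name} starts at "
                    f"{r.start}, expected {pos}"
                )
            if r.end <= r.start:
                raise ValueError(f"empty or inverted region {r.name}")
            pos = r.end
        if pos != self.length:
            raise ValueError(
                f"regions cover [0, {pos}) but alignment length is {self.length}"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.labels)

    def array(self) -> np.ndarray:
        """(n, length) byte array view of the alignment."""
        return np.frombuffer(
            "".join(self.rows).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"no region named {name!r}")

    def slice(self, start: int, end: int, name: str | None = None) -> "Msa":
        """Sub-alignment over columns [start, end); regions are dropped
        unless the slice is exactly one declared region."""
        rows = [r[start:end] for r in self.rows]
        regions = []
        for r in self.regions:
            if r.start == start and r.end == end:
                regions = [Region(r.name, 0, end - start, r.frame)]
        return Msa(list(self.labels), rows, regions, dict(self.species_of))

    def subset(self, labels: list[str]) -> "Msa":
        rows = [self.row(l) for l in labels]
        return Msa(list(labels), rows, list(self.regions),
                   {l: self.species_of[l] for l in labels})

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _clean(seq: str, ambiguity: str) -> str:
    seq = seq.upper().replace(".", "-")
    chars = set(seq) - ALPHABET
    if chars:
        if ambiguity == "reject":
            raise ValueError(
                f"ambiguity codes present and ambiguity='reject': {sorted(chars)}"
            )
        unknown = chars - AMBIGUITY
        if unknown:
            raise ValueError(f"unrecognised characters: {sorted(unknown)}")
        for c in chars:
            seq = seq.replace(c, "N")
    return seq


def read_msa(path, region_map=None, species_of=None, ambiguity: str = "N") -> Msa:
    """Read an aligned FASTA (plus optional region-map TSV) into an Msa.

    ``ambiguity`` is ``"N"`` (map IUPAC codes to N, the default) or
    ``"reject"``.  Ragged alignments, duplicate labels, and region maps that
    do not tile the alignment are fatal.
    """
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(_clean(str(rec.seq), ambiguity))
    if not labels:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: rows of unequal length")
    regions = read_region_map(region_map) if region_map else []
    return Msa(labels, rows, regions, dict(species_of) if species_of else {})


def write_msa(msa: Msa, path, region_map=None) -> None:
    records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(msa.labels, msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta-2line")
    if region_map:
        write_region_map(msa.regions, region_map)


def read_region_map(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end, frame = line.split("\t")
            regions.append(
                Region(name, int(start), int(end),
                       None if frame == "NA" else int(frame))
            )
    return regions


def write_region_map(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            frame = "NA" if r.frame is None else str(r.frame)
            fh.write(f"{r.name}\t{r.start}\t{r.end}\t{frame}\n")


def concatenate(msas: list[Msa], names: list[str] | None = None) -> Msa:
    """Join per-region alignments into one, recording cumulative offsets.

    All inputs must share the same label set (order is taken from the first);
    a mismatch is fatal and reports the symmetric difference.
    """
    if not msas:
        raise ValueError("nothing to concatenate")
    first = msas[0]
    for m in msas[1:]:
        if set(m.labels) != set(first.labels):
            diff = sorted(set(m.labels) ^ set(first.labels))
            raise ValueError(f"label sets differ; symmetric difference: {diff}")
    if names is None:
        names = []
        for i, m in enumerate(msas):
            if len(m.regions) == 1:
                names.append(m.regions[0].name)
            else:
                names.append(f"region{i + 1}")
    rows = []
    for label in first.labels:
        rows.append("".join(m.row(label) for m in msas))
    regions, offset = [], 0
    for m, name in zip(msas, names):
        frame = m.regions[0].frame if len(m.regions) == 1 else None
        regions.append(Region(name, offset, offset + m.length, frame))
        offset += m.length
    return Msa(list(first.labels), rows, regions, dict(first.species_of))
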