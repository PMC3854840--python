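"""Circular mtDNA reference handling.

The human mitochondrial genome is a 16,569 bp circle conventionally numbered
by the revised Cambridge Reference Sequence (rCRS, NC_012920).  The CRS
origin sits inside the non-coding control region, which therefore appears
discontiguous (m.16024-16569 plus m.1-576) in CRS coordinates.  For junction
analysis it is convenient to rotate the circle so that base 1 is the first
base of MT-TF (CRS m.577), which makes the control region a single contiguous
block at the end of the sequence; we call this the ALT ("alternate")
numbering.  This module provides the circular-genome container, the
CRS<->ALT coordinate bijection, region/feature annotation lookup, and
direct-repeat search around rearrangement junctions.

All public coordinates are 1-based, fully closed, and modular: position
L + 1 is position 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

RCRS_LENGTH = 16569
DEFAULT_PIVOT = 577  # CRS position of ALT base 1 (first base of MT-TF)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; N stays N."""
    comp = np.where(codes < 4, 3 - codes, np.uint8(4)).astype(np.uint8)
    return comp[::-1] if comp.ndim == 1 else comp[:, ::-1]


def wrap_pos(pos: int, L: int) -> int:
    """Reduce any integer position to 1..L on a circle of length L."""
    return (int(pos) - 1) % L + 1


@dataclass
class CircularGenome:
    """A circular DNA reference with 1-based modular coordinates.

    Parameters
    ----------
    name : sequence identifier.
    sequence : upper-case DNA over {A, C, G, T, N}.
    numbering : "CRS" for the canonical origin, "ALT" for the rotated origin.
    """

    name: str
    sequence: str
    numbering: str = "CRS"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        self._codes: np.ndarray | None = None

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode_seq(self.sequence)
        return self._codes

    def base(self, pos: int) -> str:
        """Base at 1-based modular position."""
        return self.sequence[(pos - 1) % self.L]

    def fetch(self, start: int, end: int) -> str:
        """Closed-interval slice [start, end], wrapping the origin if needed.

        ``end`` may be numerically smaller than ``start``, in which case the
        interval crosses the origin (e.g. the CRS control region 16024..576).
        """
        L = self.L
        s = (start - 1) % L
        e = (end - 1) % L
        if s <= e:
            return self.sequence[s : e + 1]
        return self.sequence[s:] + self.sequence[: e + 1]

    def rotated(self, pivot: int = DEFAULT_PIVOT) -> "CircularGenome":
        """Return the genome renumbered so ``pivot`` becomes base 1 (ALT)."""
        p = (pivot - 1) % self.L
        return CircularGenome(
            name=self.name,
            sequence=self.sequence[p:] + self.sequence[:p],
            numbering="ALT" if self.numbering == "CRS" else "CRS",
        )

    @classmethod
    def from_fasta(cls, path: str | Path, numbering: str = "CRS") -> "CircularGenome":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single circular record, got {len(records)}")
        rec = records[0]
        return cls(name=rec.id, sequence=str(rec.seq), numbering=numbering)


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between CRS and ALT numbering on a circle of length L.

    ALT base 1 is CRS position ``pivot`` (default m.577, the first base of
    MT-TF), so that the control region m.16024-576 maps to the contiguous
    ALT block 15448..16569 when L = 16,569.
    """

    pivot: int = DEFAULT_PIVOT
    L: int = RCRS_LENGTH

    def _check(self, pos: int) -> None:
        if not 1 <= pos <= self.L:
            raise ValueError(f"position {pos} outside 1..{self.L}")

    def crs_to_alt(self, pos: int) -> int:
        self._check(pos)
        return (pos - self.pivot) % self.L + 1

    def alt_to_crs(self, pos: int) -> int:
        self._check(pos)
        return (pos - 1 + self.pivot - 1) % self.L + 1


def convert_coordinate(pos: int, direction: str, cmap: CoordinateMap) -> int:
    """Convert a 1-based position between CRS and ALT numbering.

    ``direction`` is ``"crs_to_alt"`` or ``"alt_to_crs"``.
    """
    if direction == "crs_to_alt":
        return cmap.crs_to_alt(pos)
    if direction == "alt_to_crs":
        return cmap.alt_to_crs(pos)
    raise ValueError(f"unknown direction {direction!r}")


class RegionAnnotation:
    """Interval annotation of a circular genome.

    Intervals carry a label, 1-based closed coordinates in a stated
    numbering, and a class in {control_region, rRNA, tRNA, protein_coding,
    feature}.  Gene/feature intervals may wrap the origin (start > end).
    The control region and its complement (the coding region) partition the
    genome.
    """

    GENE_CLASSES = ("rRNA", "tRNA", "protein_coding")

    def __init__(self, intervals: pd.DataFrame, L: int = RCRS_LENGTH):
        required = {"label", "start", "end", "numbering", "class"}
        if not required <= set(intervals.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        self.intervals = intervals.reset_index(drop=True)
        self.L = L
        self._build_lookup()

    @classmethod
    def from_tsv(cls, path: str | Path, L: int = RCRS_LENGTH) -> "RegionAnnotation":
        return cls(pd.read_csv(path, sep="\t"), L=L)

    def _interval_positions(self, s: int, e: int) -> np.ndarray:
        if s <= e:
            return np.arange(s, e + 1)
        return np.concatenate([np.arange(s, self.L + 1), np.arange(1, e + 1)])

    def _build_lookup(self) -> None:
        L = self.L
        self._is_control = np.zeros(L + 1, dtype=bool)
        self._gene_class = np.full(L + 1, "none", dtype=object)
        self._gene_label = np.full(L + 1, "", dtype=object)
        self._feature = np.full(L + 1, "", dtype=object)
        cols = self.intervals[["label", "start", "end", "class"]].itertuples(index=False)
        for label, start, end, cls in cols:
            pos = self._interval_positions(int(start), int(end))
            if cls == "control_region":
                self._is_control[pos] = True
            elif cls in self.GENE_CLASSES:
                unset = pos[self._gene_class[pos] == "none"]
                self._gene_class[unset] = cls
                self._gene_label[unset] = label
            elif cls == "feature":
                unset = pos[self._feature[pos] == ""]
                self._feature[unset] = label

    def region_of(self, pos: int | np.ndarray) -> np.ndarray | str:
        out = np.where(self._is_control[np.asarray(pos)], "control", "coding")
        return out if np.ndim(pos) else str(out)

    def region_length(self, region: str) -> int:
        n_control = int(self._is_control[1:].sum())
        if region == "control":
            return n_control
        if region == "coding":
            return self.L - n_control
        if region == "all":
            return self.L
        if region in self.GENE_CLASSES:
            return int((self._gene_class[1:] == region).sum())
        raise ValueError(f"unknown region {region!r}")

    def gene_at(self, pos: int) -> str:
        return str(self._gene_label[pos])

    def protein_coding_positions(self) -> np.ndarray:
        """1-based positions annotated as protein coding (unique)."""
        return np.flatnonzero(self._gene_class == "protein_coding")


def classify_position(pos: int, annot: RegionAnnotation) -> tuple[str, str, str | None]:
    """Region / gene-class / feature lookup for one position.

    Returns ``(region, gene_class, feature)`` with region in
    {"coding", "control"}, gene_class in {"rRNA", "tRNA", "protein_coding",
    "none"} and feature a label such as "CSBII" or None.
    """
    if not 1 <= pos <= annot.L:
        raise ValueError(f"position {pos} outside 1..{annot.L}")
    region = "control" if annot._is_control[pos] else "coding"
    gene_class = str(annot._gene_class[pos])
    feature = str(annot._feature[pos]) or None
    return region, gene_class, feature


@dataclass(frozen=True)
class DirectRepeat:
    """A perfect direct repeat flanking a junction.

    ``left_start``/``right_start`` are the 1-based starts of the two copies
    in the genome's numbering; ``length`` is the repeat length in bp.
    """

    left_start: int
    right_start: int
    length: int


def find_flanking_direct_repeat(
    genome: CircularGenome,
    b5: int,
    b3: int,
    min_len: int = 3,
    convention: str = "ambiguity",
) -> DirectRepeat | None:
    """Longest perfect direct repeat flanking the junction ...b5 | b3...

    The junction is given in non-overlapping form: the rearranged molecule
    reads the reference up to ``b5`` and resumes at ``b3`` (for a deletion,
    bases b5+1..b3-1 are deleted).  A flanking repeat makes the breakpoint
    position ambiguous: the junction can slide right while base b5+i equals
    base b3-1+i+1... and left while base b5-i equals base b3-1-i.

    ``convention`` selects what is reported:

    * ``"ambiguity"`` (default): the full slide window, i.e. the forward
      longest-common-prefix of the sequences starting at b5+1 and b3 plus
      the backward longest-common-suffix of the sequences ending at b5 and
      b3-1.  This is invariant to where inside the repeat the junction was
      assigned and reproduces the classic 13 bp common-deletion repeat from
      either endpoint convention.
    * ``"forward"``: the forward longest-common-prefix only (the repeat as
      seen when the junction is assigned leftmost).

    N bases never match and terminate a repeat.  Returns None when the
    repeat is shorter than ``min_len``.
    """
    L = genome.L
    seq = genome.sequence

    def at(p: int) -> str:
        return seq[(p - 1) % L]

    fwd = 0
    while fwd < L:
        a, b = at(b5 + 1 + fwd), at(b3 + fwd)
        if a != b or a == "N":
            break
        fwd += 1
    back = 0
    if convention == "ambiguity":
        while back < L:
            a, b = at(b5 - back), at(b3 - 1 - back)
            if a != b or a == "N":
                break
            back += 1
    elif convention != "forward":
        raise ValueError(f"unknown convention {convention!r}")

    length = fwd + back
    if length < min_len:
        return None
    return DirectRepeat(
        left_start=wrap_pos(b5 - back + 1, L),
        right_start=wrap_pos(b3 - back, L),
        length=length,
    )


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("mitospectra").joinpath("data", name))


def rcrs() -> CircularGenome:
    """The packaged rCRS (NC_012920.1) as a CircularGenome."""
    return CircularGenome.from_fasta(_data_path("NC_012920.fasta"))


def rcrs_annotation() -> RegionAnnotation:
    """Packaged rCRS region/gene/feature annotation (CRS coordinates)."""
    return RegionAnnotation.from_tsv(_data_path("rcrs_regions.tsv"))
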