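"""Circular-genome coordinate model for the E. coli chromosome.

The chromosome is a circle of ``length_bp`` bases with a replication origin
(oriC), named loci (dif, parS insertions, ...), and oriented Ter sites that
arrest a replication fork arriving from one direction only (the Tus/Ter
replication fork trap).  Coordinates are 0-based and arithmetic is modulo the
genome length; intervals are half-open.  Rearrangements (deletions,
inversions, insertions) derive new maps while keeping locus bookkeeping
consistent, which is how the engineered strains (terminus deletion, Ter
inversions, ectopic Ter insertion) are represented.

The module also provides sequence-level scanning: IUPAC motif matching on
both strands (KOPS ``GGGNAGGG``, Chi ``GCTGGTGG``), the orientation
convergence point of a set of oriented motif hits, and windowed GC skew with
its cumulative profile, whose maximum estimates the replichore junction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_SEQ_CHARS = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A position falls outside [0, length_bp)."""


class RearrangementError(ValueError):
    """A rearrangement is out of bounds or crosses the oriC cut."""


class MotifError(ValueError):
    """Invalid sequence or motif alphabet."""


class DegenerateOrientationError(ValueError):
    """Motif hits occur on one strand only; no convergence point exists."""


@dataclass(frozen=True)
class TerSite:
    """A Tus-bound replication arrest site blocking one fork direction."""

    name: str
    position: int
    blocks: str  # "clockwise" or "counterclockwise"
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.blocks not in (CLOCKWISE, COUNTERCLOCKWISE):
            raise ValueError(f"blocks must be clockwise/counterclockwise, got {self.blocks!r}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be in [0, 1], got {self.efficiency}")


@dataclass(frozen=True)
class Rearrangement:
    """A deletion, inversion, or insertion on the linearized map.

    ``start < end`` (half-open) on the representation linearized by cutting
    the circle at oriC; intervals containing oriC are rejected rather than
    silently rotated.  ``payload`` is the inserted length for insertions.
    """

    kind: str  # "deletion" | "inversion" | "insertion"
    start: int
    end: int
    payload: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "inversion", "insertion"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; position is the leftmost forward-strand base."""

    position: int
    strand: str  # "+" or "-"
    motif: str


@dataclass(frozen=True)
class ChromosomeMap:
    length_bp: int
    oriC: int
    loci: Mapping[str, int] = field(default_factory=dict)
    ter_sites: tuple[TerSite, ...] = ()
    rearrangements: tuple[Rearrangement, ...] = ()
    name: str = "chr"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        object.__setattr__(self, "loci", dict(self.loci))
        object.__setattr__(self, "ter_sites", tuple(self.ter_sites))
        object.__setattr__(self, "rearrangements", tuple(self.rearrangements))
        self._check_position(self.oriC)
        for pos in self.loci.values():
            self._check_position(pos)
        names = [t.name for t in self.ter_sites]
        if len(names) != len(set(names)):
            raise ValueError("Ter site names must be unique")
        if len(self.loci) != len(set(self.loci)):
            raise ValueError("locus names must be unique")
        for t in self.ter_sites:
            self._check_position(t.position)

    def _check_position(self, pos: int) -> None:
        if not 0 <= pos < self.length_bp:
            raise CoordinateError(f"position {pos} outside [0, {self.length_bp})")

    def offset(self, position: int) -> int:
        """Clockwise distance from oriC to ``position``."""
        self._check_position(position)
        return (position - self.oriC) % self.length_bp

    def position_at(self, offset: int) -> int:
        """Inverse of :meth:`offset`."""
        return (self.oriC + offset) % self.length_bp

    def antipode(self) -> int:
        """Position diametrically opposite oriC."""
        return (self.oriC + self.length_bp // 2) % self.length_bp

    def ter(self, name: str) -> TerSite:
        for t in self.ter_sites:
            if t.name == name:
                return t
        raise KeyError(name)


def circular_distance(a: int, b: int, map_or_length: ChromosomeMap | int) -> int:
    """Shortest arc length between two positions on the circle."""
    if isinstance(map_or_length, ChromosomeMap):
        length = map_or_length.length_bp
        map_or_length._check_position(a)
        map_or_length._check_position(b)
    else:
        length = int(map_or_length)
        for p in (a, b):
            if not 0 <= p < length:
                raise CoordinateError(f"position {p} outside [0, {length})")
    d = abs(a - b)
    return min(d, length - d)


def _shift_after_deletion(pos: int, start: int, end: int) -> int | None:
    if pos < start:
        return pos
    if pos < end:
        return None
    return pos - (end - start)


def apply_rearrangement(chrom: ChromosomeMap, r: Rearrangement) -> ChromosomeMap:
    """Derive a new map with ``r`` applied.

    Deletion removes loci in [start, end) and shifts downstream positions;
    inversion mirrors positions inside [start, end) and flips the blocking
    direction of inverted Ter sites; insertion shifts positions >= start by
    the payload length.  Intervals containing oriC are rejected (the map is
    linearized by cutting at oriC).
    """
    if not (0 <= r.start < r.end <= chrom.length_bp):
        raise RearrangementError(f"interval [{r.start}, {r.end}) out of bounds")
    if r.kind != "insertion" and r.start <= chrom.oriC < r.end:
        raise RearrangementError(
            "rearrangement spans oriC; rotate the linearization before applying"
        )

    if r.kind == "deletion":
        removed = r.end - r.start
        new_loci = {}
        for nm, pos in chrom.loci.items():
            new = _shift_after_deletion(pos, r.start, r.end)
            if new is not None:
                new_loci[nm] = new
        new_ters = []
        for t in chrom.ter_sites:
            new = _shift_after_deletion(t.position, r.start, r.end)
            if new is not None:
                new_ters.append(replace(t, position=new))
        new_ori = _shift_after_deletion(chrom.oriC, r.start, r.end)
        assert new_ori is not None  # oriC-in-interval rejected above
        return ChromosomeMap(
            length_bp=chrom.length_bp - removed,
            oriC=new_ori,
            loci=new_loci,
            ter_sites=tuple(new_ters),
            rearrangements=chrom.rearrangements + (r,),
            name=chrom.name,
        )

    if r.kind == "inversion":
        def mirror(pos: int) -> int:
            if r.start <= pos < r.end:
                return r.start + r.end - 1 - pos
            return pos

        new_loci = {nm: mirror(pos) for nm, pos in chrom.loci.items()}
        new_ters = []
        for t in chrom.ter_sites:
            if r.start <= t.position < r.end:
                flipped = CLOCKWISE if t.blocks == COUNTERCLOCKWISE else COUNTERCLOCKWISE
                new_ters.append(replace(t, position=mirror(t.position), blocks=flipped))
            else:
                new_ters.append(t)
        return ChromosomeMap(
            length_bp=chrom.length_bp,
            oriC=chrom.oriC,
            loci=new_loci,
            ter_sites=tuple(new_ters),
            rearrangements=chrom.rearrangements + (r,),
            name=chrom.name,
        )

    # insertion: payload bases inserted at start
    if r.payload is None or r.payload <= 0:
        raise RearrangementError("insertion requires a positive payload length")

    def shift(pos: int) -> int:
        return pos + r.payload if pos >= r.start else pos

    return ChromosomeMap(
        length_bp=chrom.length_bp + r.payload,
        oriC=shift(chrom.oriC),
        loci={nm: shift(pos) for nm, pos in chrom.loci.items()},
        ter_sites=tuple(replace(t, position=shift(t.position)) for t in chrom.ter_sites),
        rearrangements=chrom.rearrangements + (r,),
        name=chrom.name,
    )


def _motif_regex(motif: str) -> re.Pattern[str]:
    parts = []
    for ch in motif.upper():
        try:
            opts = _IUPAC[ch]
        except KeyError:
            raise MotifError(f"invalid IUPAC code {ch!r} in motif {motif!r}") from None
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_motif(sequence: str, motif: str, circular: bool = False) -> list[MotifHit]:
    """All occurrences of ``motif`` on both strands of ``sequence``.

    Positions are forward-strand coordinates of the leftmost base of the
    match for both strands, sorted by (position, strand).  With
    ``circular=True`` matches wrapping the origin are included.
    """
    seq = sequence.upper()
    if not seq:
        raise MotifError("empty sequence")
    bad = set(seq) - _SEQ_CHARS
    if bad:
        raise MotifError(f"invalid sequence characters: {sorted(bad)}")
    if not motif:
        raise MotifError("empty motif")
    n = len(seq)
    k = len(motif)
    scan_seq = seq + seq[: k - 1] if circular and k > 1 else seq
    hits: list[MotifHit] = []
    for strand, pat in (("+", motif.upper()), ("-", reverse_complement(motif.upper()))):
        rx = _motif_regex(pat)
        for m in rx.finditer(scan_seq):
            if m.start() < n:
                hits.append(MotifHit(position=m.start(), strand=strand, motif=motif.upper()))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def motif_convergence_point(hits: Sequence[MotifHit], chrom: ChromosomeMap) -> int:
    """Position maximizing the orientation-polarization score of the hits.

    The score of a candidate x is the number of '+' hits on the clockwise arc
    oriC -> x plus the number of '-' hits on the arc x -> oriC; for motifs
    like KOPS read toward the terminus on each replichore the maximum marks
    the convergence (dif-like) point.  Ties are broken by the smallest
    clockwise distance from the antipode of oriC.
    """
    plus = np.sort([chrom.offset(h.position) for h in hits if h.strand == "+"])
    minus = np.sort([chrom.offset(h.position) for h in hits if h.strand == "-"])
    if len(plus) == 0 or len(minus) == 0:
        raise DegenerateOrientationError("hits on one strand only")
    length = chrom.length_bp
    anti = length // 2  # offset of the antipode
    candidates = {0, anti}
    for off in itertools.chain(plus.tolist(), minus.tolist()):
        candidates.add((off + 1) % length)
    best_off = None
    best_key = None
    for off in candidates:
        score = int(np.searchsorted(plus, off, side="left")) + int(
            len(minus) - np.searchsorted(minus, off, side="left")
        )
        key = (-score, (off - anti) % length)
        if best_key is None or key < best_key:
            best_key = key
            best_off = off
    assert best_off is not None
    return chrom.position_at(best_off)


@dataclass(frozen=True)
class GcSkewProfile:
    """Windowed GC skew and its cumulative profile clockwise from an origin."""

    window_bp: int
    origin: int
    skew: np.ndarray  # (G-C)/(G+C) per window, 0 where G+C == 0
    cumulative: np.ndarray

    @property
    def convergence_position(self) -> int:
        """Boundary after the argmax of the cumulative skew (mod length)."""
        j = int(np.argmax(self.cumulative))
        length = len(self.skew) * self.window_bp
        # windows past the true sequence end (short final window) still use
        # nominal width; callers on exact-multiple sequences are unaffected
        return (self.origin + (j + 1) * self.window_bp) % max(length, 1)


def gc_skew_profile(sequence: str, window_bp: int, origin: int = 0) -> GcSkewProfile:
    """Per-window (G-C)/(G+C) and cumulative skew clockwise from ``origin``."""
    if not sequence:
        raise ValueError("empty sequence")
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    origin %= n
    rotated = seq[origin:] + seq[:origin]
    arr = np.frombuffer(rotated.encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    n_win = -(-n // window_bp)
    pad = n_win * window_bp - n
    if pad:
        is_g = np.concatenate([is_g, np.zeros(pad, dtype=np.int64)])
        is_c = np.concatenate([is_c, np.zeros(pad, dtype=np.int64)])
    g = is_g.reshape(n_win, window_bp).sum(axis=1)
    c = is_c.reshape(n_win, window_bp).sum(axis=1)
    denom = g + c
    skew = np.zeros(n_win, dtype=float)
    nz = denom > 0
    skew[nz] = (g[nz] - c[nz]) / denom[nz]
    return GcSkewProfile(
        window_bp=window_bp, origin=origin, skew=skew, cumulative=np.cumsum(skew)
    )
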