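"""Quadripartite plastome structure: inverted-repeat detection and summary.

Land-plant plastomes are circular molecules organised into a large
single-copy region (LSC), a small single-copy region (SSC) and two identical
inverted repeats (IRb, IRa).  This module finds the IR pair on a circular
sequence (exact-match seed-and-extend, k=25 seeds on the doubled sequence),
partitions the genome into the four regions with a canonical LSC-first
rotation, computes per-region GC content and reports the gene context at the
four region junctions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from ._util import complement_base, revcomp, round_half_up
from .io_formats import Annotation, PlastomeRecord

logger = logging.getLogger(__name__)

#: seed length for the inverted-repeat search
SEED_K = 25

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")

JUNCTION_NAMES = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


@dataclass
class QuadripartiteStructure:
    """Region coordinates on the canonically rotated (LSC-first) sequence.

    ``rotation_offset`` is the position on the *input* sequence where the LSC
    starts; ``rotate_sequence(seq, offset)`` reproduces the rotated frame.
    All coordinates are 0-based half-open and tile [0, total_length).
    """

    total_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    gc_total: float
    gc_by_region: dict[str, float]
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        regions = [self.lsc, self.irb, self.ssc, self.ira]
        if any(e <= s for s, e in regions):
            raise ValueError("all quadripartite regions must have positive length")
        if self.ir_length != self.ira[1] - self.ira[0]:
            raise ValueError("IRb and IRa lengths differ")
        # regions must tile the rotated sequence exactly once, in order
        expected_start = 0
        for (s, e) in regions:
            if s != expected_start:
                raise ValueError("quadripartite regions do not tile the sequence")
            expected_start = e
        if expected_start != self.total_length:
            raise ValueError("quadripartite regions do not tile the sequence")
        if self.lsc_length < self.ssc_length:
            raise ValueError("LSC must be at least as long as SSC")

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_coords(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, (s, e) in self.region_coords().items():
            rows.append(
                {
                    "region": name,
                    # reports are 1-based inclusive (GenBank convention)
                    "start": s + 1,
                    "end": e,
                    "length_bp": e - s,
                    "gc_pct": round_half_up(100.0 * self.gc_by_region[name], 2),
                }
            )
        rows.append(
            {
                "region": "total",
                "start": 1,
                "end": self.total_length,
                "length_bp": self.total_length,
                "gc_pct": round_half_up(100.0 * self.gc_total, 2),
            }
        )
        return pd.DataFrame(rows)


def rotate_sequence(seq: str, offset: int) -> str:
    """Rotate a circular sequence so position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def gc_content(sequence_slice: str) -> float:
    """(G+C) / (A+C+G+T); N and gaps are excluded from both counts.

    Returns NaN when the slice holds no unambiguous base (undefined signal).
    """
    if not sequence_slice:
        raise ValueError("empty sequence slice")
    s = sequence_slice.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def detect_inverted_repeat(
    record: PlastomeRecord | str, min_ir_length: int = 1000
) -> Optional[tuple[tuple[int, int], tuple[int, int]]]:
    """Find the longest disjoint reverse-complement segment pair on a circle.

    Returns two (start, end) segments in input-sequence coordinates, ordered
    by start; ``end`` may exceed the sequence length when the segment wraps
    the origin.  Returns None when no exact repeat of at least
    ``min_ir_length`` exists.  The search is exact-match seed-and-extend
    (seed k=25) on the doubled sequence, so circular placements are handled;
    ties on length resolve to the smallest start coordinate.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    if min_ir_length < 1:
        raise ValueError("min_ir_length must be >= 1")
    if "-" in seq:
        raise ValueError("inverted-repeat detection requires a gap-free sequence")
    L = len(seq)
    k = min(SEED_K, min_ir_length, L)
    if 2 * min_ir_length > L:
        return None

    doubled = seq + seq

    def char(p: int) -> str:
        return seq[p % L]

    # index seed k-mers by start position on the circle
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i : i + k], []).append(i)

    # maximal matches already found, keyed by the anti-diagonal invariant
    # i_start + j_end (constant along any one reverse-complement match)
    found: dict[int, list[tuple[int, int]]] = {}
    best: tuple[int, int, int, int, int] | None = None  # (len, i1, e1, j1, e2)

    max_len = L // 2  # two disjoint copies cannot each exceed half the circle

    for i in range(L):
        kmer = doubled[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        for j0 in index.get(rc, ()):
            j = j0 if j0 > i else j0 + L
            if j == i:
                continue
            # seg1 = [i, i+k), seg2 = [j, j+k) on the unrolled line, i < j
            e2 = j + k
            diag = i + e2
            if any(a <= i < b for a, b in found.get(diag % (2 * L), ())):
                continue
            i1, e1, j1 = i, i + k, j
            # extend right of seg1 / left of seg2 (disjointness: e1 <= j1)
            while (
                e1 < j1
                and e1 - i1 < max_len
                and char(e1) == complement_base(char(j1 - 1))
            ):
                e1 += 1
                j1 -= 1
            # extend left of seg1 / right of seg2 (seg2 must not wrap into seg1)
            while (
                e2 < i1 + L
                and e1 - i1 < max_len
                and char(i1 - 1) == complement_base(char(e2))
            ):
                i1 -= 1
                e2 += 1
            length = e1 - i1
            found.setdefault(diag % (2 * L), []).append((i1, e1))
            if length >= min_ir_length:
                cand = (length, i1 % L)
                if best is None or (cand[0], -cand[1]) > (best[0], -(best[1] % L)):
                    best = (length, i1, e1, j1, e2)

    if best is None:
        return None
    _, i1, e1, j1, e2 = best
    seg1 = (i1 % L, i1 % L + (e1 - i1))
    seg2 = (j1 % L, j1 % L + (e2 - j1))
    if seg1[0] > seg2[0]:
        seg1, seg2 = seg2, seg1
    if _segments_overlap(seg1, seg2, L):
        raise ValueError("best inverted-repeat pair overlaps itself")
    return seg1, seg2


def _segments_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    cover_a = {p % L for p in range(a[0], a[1])}
    cover_b = {p % L for p in range(b[0], b[1])}
    return bool(cover_a & cover_b)


def partition_quadripartite(
    record: PlastomeRecord | str,
    irb: tuple[int, int],
    ira: tuple[int, int],
) -> QuadripartiteStructure:
    """Label LSC/IRb/SSC/IRa from an IR pair and canonically rotate.

    The longer single-copy stretch is the LSC; on a tie the single-copy
    region that *follows* IRb in sequence order is the SSC (deterministic
    rule).  The returned structure is expressed on the sequence rotated so
    that the LSC starts at position 0 (region order LSC, IRb, SSC, IRa);
    ``rotation_offset`` records the rotation.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    L = len(seq)
    if _segments_overlap(irb, ira, L):
        raise ValueError("IR segments overlap")
    seg_a, seg_b = sorted([irb, ira])
    len_a = seg_a[1] - seg_a[0]
    len_b = seg_b[1] - seg_b[0]
    if len_a != len_b:
        raise ValueError("IR segments have unequal lengths")

    # the two single-copy gaps, walking the circle: after seg_a and after seg_b
    gap1 = (seg_a[1] % L, (seg_a[1] % L) + (seg_b[0] - seg_a[1]) % L)  # between a and b
    gap2 = (seg_b[1] % L, (seg_b[1] % L) + (seg_a[0] - (seg_b[1] % L)) % L)
    g1 = gap1[1] - gap1[0]
    g2 = gap2[1] - gap2[0]
    if g1 <= 0 or g2 <= 0:
        raise ValueError("IR segments leave no single-copy region between them")

    # LSC = the longer gap; tie -> the gap starting at the smaller coordinate
    if (g1, -(gap1[0] % L)) >= (g2, -(gap2[0] % L)):
        lsc_gap, ssc_gap, ir_after_lsc, ir_after_ssc = gap1, gap2, seg_b, seg_a
    else:
        lsc_gap, ssc_gap, ir_after_lsc, ir_after_ssc = gap2, gap1, seg_a, seg_b

    offset = lsc_gap[0] % L
    rotated = rotate_sequence(seq, offset)
    lsc_len = lsc_gap[1] - lsc_gap[0]
    ir_len = len_a
    ssc_len = ssc_gap[1] - ssc_gap[0]
    lsc = (0, lsc_len)
    irb_r = (lsc_len, lsc_len + ir_len)
    ssc = (irb_r[1], irb_r[1] + ssc_len)
    ira_r = (ssc[1], ssc[1] + ir_len)
    if ira_r[1] != L:
        raise ValueError("quadripartite regions do not tile the sequence")

    gc_by_region = {
        "LSC": gc_content(rotated[lsc[0] : lsc[1]]),
        "IRb": gc_content(rotated[irb_r[0] : irb_r[1]]),
        "SSC": gc_content(rotated[ssc[0] : ssc[1]]),
        "IRa": gc_content(rotated[ira_r[0] : ira_r[1]]),
    }
    return QuadripartiteStructure(
        total_length=L,
        lsc=lsc,
        irb=irb_r,
        ssc=ssc,
        ira=ira_r,
        gc_total=gc_content(rotated),
        gc_by_region=gc_by_region,
        rotation_offset=offset,
    )


def analyze_structure(
    record: PlastomeRecord | str, min_ir_length: int = 1000
) -> Optional[QuadripartiteStructure]:
    """detect_inverted_repeat + partition_quadripartite; None if no IR."""
    pair = detect_inverted_repeat(record, min_ir_length=min_ir_length)
    if pair is None:
        return None
    return partition_quadripartite(record, *pair)


@dataclass(frozen=True)
class JunctionContext:
    junction: str
    feature: str
    bp_inside_ir: int


def junction_report(
    structure: QuadripartiteStructure, annotations: Sequence[Annotation]
) -> list[JunctionContext]:
    """Gene context at the four region junctions.

    Annotations must be in the rotated (LSC-first) coordinate frame.  For a
    gene spanning a junction into an IR the number of bp inside the IR is
    reported; junctions falling between genes report the flanking pair as
    "left-right".
    """
    L = structure.total_length
    for ann in annotations:
        if ann.end > L:
            raise ValueError(
                f"annotation {ann.name!r} ({ann.start}:{ann.end}) outside sequence of length {L}"
            )
    ir_spans = {"LSC/IRb": structure.irb, "IRb/SSC": structure.irb,
                "SSC/IRa": structure.ira, "IRa/LSC": structure.ira}
    points = {
        "LSC/IRb": structure.irb[0],
        "IRb/SSC": structure.ssc[0],
        "SSC/IRa": structure.ira[0],
        "IRa/LSC": structure.ira[1] % L,  # the circular origin of the rotated frame
    }
    out = []
    for name in JUNCTION_NAMES:
        p = points[name]
        spanning = [a for a in annotations if a.start < p < a.end]
        if spanning:
            ann = max(spanning, key=len)
            ir_s, ir_e = ir_spans[name]
            bp_in_ir = max(0, min(ann.end, ir_e) - max(ann.start, ir_s))
            out.append(JunctionContext(name, ann.name, bp_in_ir))
            continue
        # intergenic junction: nearest feature ending at/before p (circularly)
        # and nearest feature starting at/after p
        left = min(
            annotations, key=lambda a: ((p - a.end) % L, a.name), default=None
        ) if annotations else None
        right = min(
            annotations, key=lambda a: ((a.start - p) % L, a.name), default=None
        ) if annotations else None
        if left is None or right is None:
            feature = "(no annotation)"
        elif left.name == right.name:
            feature = left.name
        else:
            feature = f"{left.name}-{right.name}"
        out.append(JunctionContext(name, feature, 0))
    return out


def junctions_to_frame(contexts: Sequence[JunctionContext]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"junction": c.junction, "feature": c.feature, "bp_inside_IR": c.bp_inside_ir}
            for c in contexts
        ]
    )
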