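"""Alignment-based variation statistics.

Polymorphic-site counting, pairwise p-distances with pairwise deletion
(MEGA-style), Nei-Li nucleotide diversity (Pi), sliding-window Pi profiles
(DnaSP-style, window 1000 / step 300 defaults), hyper-variable region
extraction (Pi > 0.003 default), region slicing and inverted-repeat
de-duplication.

Conventions (documented, not options unless noted):

* Columns containing a gap or N are excluded entirely from polymorphic-site
  counting by default; ``count_gapped_columns=True`` flips this so such
  columns count when they still show >= 2 distinct A/C/G/T bases.
* Pairwise statistics use pairwise deletion: only sites where *both*
  sequences show an unambiguous base are retained for that pair.
* "Nucleotide differences" count substitutions only, never indels.
* Percentages are rounded half-up to 2 decimals; window coordinates are
  alignment coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .io_formats import Annotation, PlastomeRecord, read_fasta

logger = logging.getLogger(__name__)

_BASES = [b"A", b"C", b"G", b"T"]


@dataclass
class MultipleAlignment:
    """Equal-length sequence matrix over {A,C,G,T,N,-} with accession ids."""

    ids: list[str]
    matrix: np.ndarray  # shape (n_seq, n_col), dtype 'S1'
    region_name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        if self.matrix.shape[0] < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if self.matrix.shape[1] == 0:
            raise ValueError("zero-length alignment")

    @classmethod
    def from_sequences(
        cls, ids: Sequence[str], sequences: Sequence[str], region_name: str = ""
    ) -> "MultipleAlignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences must share one length, got {sorted(lengths)}")
        matrix = np.array([list(s.upper()) for s in sequences], dtype="S1")
        return cls(ids=list(ids), matrix=matrix, region_name=region_name)

    @classmethod
    def from_records(
        cls, records: Sequence[PlastomeRecord], region_name: str = ""
    ) -> "MultipleAlignment":
        return cls.from_sequences(
            [r.accession_id for r in records], [r.sequence for r in records], region_name
        )

    @classmethod
    def from_fasta(cls, path, region_name: str = "") -> "MultipleAlignment":
        return cls.from_records(read_fasta(path), region_name=region_name)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, accession_id: str) -> str:
        try:
            row = self.ids.index(accession_id)
        except ValueError:
            raise KeyError(f"accession {accession_id!r} not in alignment") from None
        return self.matrix[row].tobytes().decode()

    def sequences(self) -> list[str]:
        return [self.matrix[i].tobytes().decode() for i in range(self.n_sequences)]

    def to_records(self) -> list[PlastomeRecord]:
        return [
            PlastomeRecord(accession_id=i, sequence=s)
            for i, s in zip(self.ids, self.sequences())
        ]

    def to_fasta(self, path) -> None:
        from .io_formats import write_fasta

        write_fasta(self.to_records(), path)


@dataclass
class DistanceMatrix:
    """Pairwise p-distances (fractions) and substitution counts."""

    ids: list[str]
    p: np.ndarray  # float, NaN where undefined (no retained sites)
    diff_counts: np.ndarray  # int
    retained_sites: np.ndarray  # int, sites surviving pairwise deletion

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name, m in (("p", self.p), ("diff_counts", self.diff_counts)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(np.nan_to_num(self.p), np.nan_to_num(self.p.T)):
            raise ValueError("p-distance matrix must be symmetric")

    def pair(self, a: str, b: str) -> tuple[float, int]:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.p[i, j]), int(self.diff_counts[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.ids, columns=self.ids)

    def mega_style_frame(self) -> pd.DataFrame:
        """Upper triangle: nucleotide differences; lower triangle: p-distances."""
        n = len(self.ids)
        out = np.full((n, n), np.nan, dtype=object)
        for i in range(n):
            for j in range(n):
                if i < j:
                    out[i, j] = int(self.diff_counts[i, j])
                elif i > j:
                    out[i, j] = float(self.p[i, j])
                else:
                    out[i, j] = 0
        return pd.DataFrame(out, index=self.ids, columns=self.ids)


@dataclass
class SlidingWindowProfile:
    """Ordered (start, end, pi) windows on alignment coordinates."""

    window_length: int
    step: int
    windows: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [w[0] for w in self.windows]
        if starts != sorted(starts):
            raise ValueError("windows must be ordered by start")

    def max_pi(self) -> float:
        return max((w[2] for w in self.windows), default=float("nan"))

    def argmax_window(self) -> tuple[int, int, float]:
        return max(self.windows, key=lambda w: w[2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"start": s + 1, "end": e, "pi": pi}  # 1-based inclusive in reports
                for s, e, pi in self.windows
            ]
        )


_VALID = {b"A", b"C", b"G", b"T"}


def _canonical_mask(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of cells holding an unambiguous base."""
    mask = np.zeros(matrix.shape, dtype=bool)
    for b in _BASES:
        mask |= matrix == b
    return mask


def count_polymorphic_sites(
    alignment: MultipleAlignment, count_gapped_columns: bool = False
) -> tuple[int, float]:
    """Number (and percent of alignment length) of polymorphic columns.

    A column is polymorphic when it holds >= 2 distinct bases among A/C/G/T.
    By default, columns containing any gap or N are excluded entirely; with
    ``count_gapped_columns=True`` they still count if the unambiguous bases
    present are >= 2 distinct.  Percent = 100 * count / alignment length,
    rounded half-up to 2 decimals.
    """
    m = alignment.matrix
    canonical = _canonical_mask(m)
    distinct = np.zeros(m.shape[1], dtype=np.int16)
    for b in _BASES:
        distinct += (m == b).any(axis=0)
    polymorphic = distinct >= 2
    if not count_gapped_columns:
        polymorphic &= canonical.all(axis=0)
    count = int(polymorphic.sum())
    percent = round_half_up(100.0 * count / alignment.length, 2)
    return count, percent


def pairwise_divergence(alignment: MultipleAlignment) -> DistanceMatrix:
    """p-distances and substitution counts under pairwise deletion.

    For each pair, sites with a gap/N in either sequence are excluded; the
    p-distance is differing retained sites / retained sites (NaN when no
    site is retained).
    """
    m = alignment.matrix
    canonical = _canonical_mask(m)
    n = alignment.n_sequences
    p = np.zeros((n, n))
    diffs = np.zeros((n, n), dtype=np.int64)
    retained = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        retained[i, i] = int(canonical[i].sum())
        for j in range(i + 1, n):
            both = canonical[i] & canonical[j]
            nret = int(both.sum())
            ndiff = int((both & (m[i] != m[j])).sum())
            retained[i, j] = retained[j, i] = nret
            diffs[i, j] = diffs[j, i] = ndiff
            if nret == 0:
                p[i, j] = p[j, i] = np.nan
            else:
                p[i, j] = p[j, i] = ndiff / nret
    return DistanceMatrix(ids=list(alignment.ids), p=p, diff_counts=diffs, retained_sites=retained)


def nucleotide_diversity(alignment: MultipleAlignment) -> float:
    """Nucleotide diversity Pi: mean pairwise p-distance over all pairs.

    Each sequence counts once (Nei-Li diversity of the sample); pairs with
    no retained sites are excluded from the mean.  Returns NaN when every
    pair is undefined.
    """
    dm = pairwise_divergence(alignment)
    n = len(dm.ids)
    iu = np.triu_indices(n, k=1)
    vals = dm.p[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def _window_spans(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if window > length:
        warnings.warn(
            f"window ({window}) exceeds alignment length ({length}); "
            "using a single whole-alignment window",
            stacklevel=3,
        )
        return [(0, length)]
    spans: list[tuple[int, int]] = []
    start = 0
    while start < length:
        end = min(start + window, length)
        if end - start == window:
            spans.append((start, end))
        else:
            # final partial window kept only when at least one step wide
            if end - start >= step:
                spans.append((start, end))
            break
        start += step
    return spans


def sliding_window_pi(
    alignment: MultipleAlignment, window: int = 1000, step: int = 300
) -> SlidingWindowProfile:
    """Pi per sliding window (window/step defaults 1000/300).

    Windows start at 0, step, 2*step, ...; a final partial window is kept
    when it spans at least ``step`` columns.  Per-window Pi is the mean
    pairwise p-distance with pairwise deletion, computed exactly as
    ``nucleotide_diversity`` on that column slice (cumulative sums make the
    scan linear in alignment length).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    m = alignment.matrix
    length = alignment.length
    spans = _window_spans(length, window, step)

    canonical = _canonical_mask(m)
    n = alignment.n_sequences
    nwin = len(spans)
    p_sum = np.zeros(nwin)
    p_count = np.zeros(nwin, dtype=np.int64)
    starts = np.array([s for s, _ in spans])
    ends = np.array([e for _, e in spans])
    for i in range(n):
        for j in range(i + 1, n):
            both = canonical[i] & canonical[j]
            diff = both & (m[i] != m[j])
            cboth = np.concatenate(([0], np.cumsum(both)))
            cdiff = np.concatenate(([0], np.cumsum(diff)))
            ret = cboth[ends] - cboth[starts]
            dif = cdiff[ends] - cdiff[starts]
            ok = ret > 0
            p_sum[ok] += dif[ok] / ret[ok]
            p_count += ok
    windows = []
    for k, (s, e) in enumerate(spans):
        pi = p_sum[k] / p_count[k] if p_count[k] else float("nan")
        windows.append((s, e, float(pi)))
    return SlidingWindowProfile(window_length=window, step=step, windows=windows)


def extract_hypervariable_regions(
    profile: SlidingWindowProfile, threshold: float = 0.003
) -> list[tuple[int, int, float]]:
    """Merge windows with Pi > threshold into maximal (start, end, peak_pi) regions.

    Overlapping or bookended selected windows merge; the default threshold
    0.003 nominates hyper-variable candidate barcodes.
    """
    if not profile.windows:
        raise ValueError("empty sliding-window profile")
    selected = [(s, e, pi) for s, e, pi in profile.windows if pi > threshold]
    regions: list[list[float]] = []
    for s, e, pi in selected:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], e)
            regions[-1][2] = max(regions[-1][2], pi)
        else:
            regions.append([s, e, pi])
    return [(int(s), int(e), float(pi)) for s, e, pi in regions]


def slice_region(
    alignment: MultipleAlignment,
    region: Annotation | tuple[int, int],
    name: str | None = None,
) -> MultipleAlignment:
    """Column slice of an alignment, ids preserved, region_name set."""
    if isinstance(region, Annotation):
        start, end, region_name = region.start, region.end, region.name
    else:
        start, end = region
        region_name = name or alignment.region_name
    if start < 0 or end > alignment.length:
        raise ValueError(
            f"slice {start}:{end} outside alignment of length {alignment.length}"
        )
    if end <= start:
        raise ValueError(f"empty or reversed slice {start}:{end}")
    return MultipleAlignment(
        ids=list(alignment.ids),
        matrix=alignment.matrix[:, start:end].copy(),
        region_name=name if name is not None else region_name,
    )


def remove_one_ir(target, structure) -> "MultipleAlignment | PlastomeRecord":
    """Drop the IRa so each repeat is represented once (LSC+IRb+SSC kept).

    ``target`` is a MultipleAlignment whose columns are in the structure's
    rotated frame, or a single PlastomeRecord (rotated internally).  Errors
    when the structure does not tile the target's length.
    """
    ira_s, ira_e = structure.ira
    if isinstance(target, MultipleAlignment):
        if structure.total_length != target.length:
            raise ValueError(
                f"structure (total {structure.total_length}) does not tile the "
                f"alignment ({target.length} columns)"
            )
        kept = np.concatenate(
            [target.matrix[:, : ira_s], target.matrix[:, ira_e :]], axis=1
        )
        return MultipleAlignment(
            ids=list(target.ids), matrix=kept, region_name=target.region_name
        )
    if isinstance(target, PlastomeRecord):
        if structure.total_length != len(target.sequence):
            raise ValueError(
                f"structure (total {structure.total_length}) does not tile the "
                f"record ({len(target.sequence)} bp)"
            )
        from .structure import rotate_sequence

        seq = rotate_sequence(target.sequence, structure.rotation_offset)
        return PlastomeRecord(
            accession_id=target.accession_id,
            sequence=seq[:ira_s] + seq[ira_e:],
            species=target.species,
        )
    raise TypeError(f"cannot remove IR from {type(target).__name__}")


def concatenate_alignments(
    alignments: Iterable[MultipleAlignment], region_name: str = ""
) -> MultipleAlignment:
    """Column-wise concatenation matched by accession id.

    Accessions missing from any member alignment are dropped with a warning
    (complete matrices pass through unchanged).
    """
    alns = list(alignments)
    if not alns:
        raise ValueError("no alignments to concatenate")
    common = set(alns[0].ids)
    for a in alns[1:]:
        common &= set(a.ids)
    dropped = sorted(set().union(*(a.ids for a in alns)) - common)
    if dropped:
        logger.warning("concatenation drops accessions missing from some barcode: %s", dropped)
    if len(common) < 2:
        raise ValueError("fewer than 2 accessions shared across alignments")
    ids = [i for i in alns[0].ids if i in common]
    blocks = []
    for a in alns:
        rows = [a.ids.index(i) for i in ids]
        blocks.append(a.matrix[rows])
    return MultipleAlignment(
        ids=ids,
        matrix=np.concatenate(blocks, axis=1),
        region_name=region_name or "+".join(a.region_name or "?" for a in alns),
    )
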