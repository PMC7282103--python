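"""Tree-based species discrimination by reciprocal monophyly.

A species is successfully identified when all of its sampled accessions form
an exclusive clade (some edge of the unrooted tree bipartitions the tips
into exactly that accession set versus everything else).  Only species with
>= 2 accessions enter the success rate; branch support at the clade's edge
is recorded but never thresholded.  The barcode-evaluation harness scores a
set of candidate barcode alignments (and their concatenated combinations)
the same way, yielding per-barcode rows of length, polymorphic sites and
species-identification rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from ._util import round_half_up
from .io_formats import SampleTable
from .phylo import TreeBuilder, bipartitions, edge_support, p_distance_nj, tip_labels
from .variation import MultipleAlignment, concatenate_alignments, count_polymorphic_sites

logger = logging.getLogger(__name__)


@dataclass
class SpeciesVerdict:
    species: str
    n_accessions: int
    monophyletic: bool
    support: Optional[float]
    counted: bool
    nearest: str = ""  # descriptive placement for singletons


@dataclass
class DiscriminationReport:
    rows: list[SpeciesVerdict]
    n_multi: int
    n_success: int
    success_rate_pct: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": r.species,
                    "n_accessions": r.n_accessions,
                    "monophyletic": r.monophyletic,
                    "support": r.support,
                    "counted": r.counted,
                    "nearest": r.nearest,
                }
                for r in self.rows
            ]
        )


@dataclass
class BarcodeEvaluation:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "barcode",
                "length",
                "polymorphic_sites",
                "polymorphic_pct",
                "species_identified",
                "success_rate_pct",
            ],
        )


def is_monophyletic(
    tree: dendropy.Tree, tip_set: Iterable[str]
) -> tuple[bool, Optional[float]]:
    """Does some edge separate exactly ``tip_set`` from the rest?

    Returns (verdict, support of that edge).  The full tip set is not
    monophyletic by convention (no separating edge exists); supports are
    returned as recorded on the tree, never fabricated.
    """
    tips = frozenset(tip_set)
    all_tips = frozenset(tip_labels(tree))
    unknown = tips - all_tips
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if tips == all_tips:
        return False, None
    if len(tips) == 1:
        return True, None  # a single accession is trivially exclusive
    key = frozenset({tips, all_tips - tips})
    bips = bipartitions(tree)
    if key in bips:
        return True, edge_support(bips[key])
    return False, None


def _sister_species(
    tree: dendropy.Tree, accession: str, species_of: Mapping[str, str]
) -> str:
    """Species of the smallest clade containing the accession's nearest tips."""
    leaf = next(
        (l for l in tree.leaf_node_iter() if l.taxon.label == accession), None
    )
    if leaf is None or leaf.parent_node is None:
        return ""
    node = leaf.parent_node
    while node is not None:
        others = {
            species_of.get(l.taxon.label, "?")
            for l in node.leaf_iter()
            if l.taxon.label != accession
        }
        if others:
            return ",".join(sorted(others))
        node = node.parent_node
    return ""


def assess_discrimination(
    tree: dendropy.Tree, sample_table: SampleTable
) -> DiscriminationReport:
    """Reciprocal-monophyly verdict per species and the overall success rate.

    Singleton species are excluded from the rate (their nearest-neighbour
    placement is reported descriptively); the rate is
    round(100 * successes / multi-accession species) to the nearest integer.
    Raises no error when no species has >= 2 accessions: the rate is None
    (undefined signal).
    """
    tips = set(tip_labels(tree))
    missing = tips - set(sample_table.accessions)
    if missing:
        raise ValueError(f"tree tips absent from sample table: {sorted(missing)}")
    groups = sample_table.species_to_accessions()
    species_of = {
        acc: sp for sp, accs in groups.items() for acc in accs
    }
    rows: list[SpeciesVerdict] = []
    n_multi = 0
    n_success = 0
    for species in sorted(groups):
        accs = [a for a in groups[species] if a in tips]
        if not accs:
            continue
        counted = len(accs) >= 2
        if counted:
            mono, support = is_monophyletic(tree, accs)
            n_multi += 1
            n_success += int(mono)
            nearest = ""
        else:
            mono, support = True, None
            nearest = _sister_species(tree, accs[0], species_of)
        rows.append(
            SpeciesVerdict(
                species=species,
                n_accessions=len(accs),
                monophyletic=mono,
                support=support,
                counted=counted,
                nearest=nearest,
            )
        )
    rate = round_half_up(100.0 * n_success / n_multi) if n_multi else None
    if n_multi == 0:
        logger.warning("no species with >= 2 accessions; success rate undefined")
    return DiscriminationReport(
        rows=rows, n_multi=n_multi, n_success=n_success, success_rate_pct=rate
    )


def evaluate_barcodes(
    alignments_by_name: Mapping[str, MultipleAlignment],
    sample_table: SampleTable,
    tree_builder: TreeBuilder | None = None,
    combinations: Sequence[Sequence[str]] = (),
) -> BarcodeEvaluation:
    """Table-style evaluation of single barcodes and their combinations.

    One row per barcode (input order) and per requested combination:
    aligned length, polymorphic sites and percent, species identified, and
    the monophyly success rate from a tree built by ``tree_builder``
    (default: NJ on p-distances).  Combinations concatenate member barcodes
    column-wise by accession id.
    """
    builder = tree_builder or p_distance_nj
    evaluation = BarcodeEvaluation()

    def one_row(name: str, aln: MultipleAlignment) -> dict:
        count, pct = count_polymorphic_sites(aln)
        report = assess_discrimination(builder(aln), sample_table)
        return {
            "barcode": name,
            "length": aln.length,
            "polymorphic_sites": count,
            "polymorphic_pct": pct,
            "species_identified": report.n_success,
            "success_rate_pct": report.success_rate_pct,
        }

    for name, aln in alignments_by_name.items():
        evaluation.rows.append(one_row(name, aln))
    for combo in combinations:
        missing = [b for b in combo if b not in alignments_by_name]
        if missing:
            raise ValueError(f"combination references unknown barcodes: {missing}")
        name = "+".join(combo)
        aln = concatenate_alignments(
            [alignments_by_name[b] for b in combo], region_name=name
        )
        evaluation.rows.append(one_row(name, aln))
    return evaluation
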