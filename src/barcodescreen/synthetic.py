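"""Synthetic plastome/phylogeny generator.

Emulates the statistical structure the analysis assumes so every stage is
testable without downloads: a Yule species tree over 21 species (nine of
them with 2-3 accessions, 32 tips total), low intraspecific versus higher
interspecific divergence, Jukes-Cantor site evolution with per-locus rate
multipliers that create a few Pi-elevated windows, an IRa generated as the
reverse complement of the IRb of each genome, optional plastome capture
(one species' accession carries another species' plastid haplotype) and
optional large intergenic insertions in one taxon.

All randomness flows from one seeded ``numpy`` generator passed explicitly;
alongside every alignment a *truth record* stores what the generator
guarantees (locus map, expected per-locus divergence, which species are
monophyletic by construction), so tests never re-derive expectations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .io_formats import Annotation, PlastomeRecord, SampleTable
from .variation import MultipleAlignment

# base coding A=0 C=1 G=2 T=3; complement is 3 - code
_LOOKUP = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
#: root base composition giving the plastome-typical 37.5% GC
_BASE_FREQS = np.array([0.3125, 0.1875, 0.1875, 0.3125])

#: default per-locus mutation-rate multipliers (the screened hyper-variable loci)
DEFAULT_MULTIPLIERS = {
    "ndhF": 4.0,
    "trnS-G": 4.0,
    "trnC-petN": 4.0,
    "ndhF-rpl32": 4.0,
    "rpl32-trnL": 4.0,
    "trnE-T": 2.0,
    "trnT-L": 2.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate the sampling design the analysis targets: 21 species,
    nine with multiple accessions (7x2 + 2x3 = 32 tips), template region
    lengths near a real plastome (87 kb / 30.5 kb / 13.4 kb), a mean
    interspecific p-distance of 1.5e-3 (pairwise extremes then fall near
    3-4e-3) and intraspecific divergence of 4e-4 (observed intraspecific
    p-distances span 0.2-8.5e-4).
    """

    n_species: int = 21
    n_multi_accession: int = 9
    accessions_per_multi: tuple[int, ...] = (3, 3, 2, 2, 2, 2, 2, 2, 2)
    lsc_length: int = 87_000
    ir_length: int = 30_500
    ssc_length: int = 13_400
    interspecific_scale: float = 0.0015  # mean pairwise species-tree p-distance
    intraspecific_scale: float = 0.0004  # expected within-species p-distance
    region_rate_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    capture_events: list[tuple[str, str]] = field(default_factory=list)
    insertion_events: list[tuple[str, str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not self.intraspecific_scale < self.interspecific_scale:
            raise ValueError("intraspecific scale must be below interspecific scale")
        if any(m <= 0 for m in self.region_rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")
        if len(self.accessions_per_multi) != self.n_multi_accession:
            raise ValueError("accessions_per_multi length must equal n_multi_accession")

    @classmethod
    def scaled_down(cls, seed: int, **overrides) -> "SimulationConfig":
        """Desk-scale preset: template lengths divided by 10."""
        defaults = dict(lsc_length=8_700, ir_length=3_050, ssc_length=1_340, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def total_length(self) -> int:
        return self.lsc_length + 2 * self.ir_length + self.ssc_length

    @property
    def n_accessions(self) -> int:
        return (self.n_species - self.n_multi_accession) + sum(self.accessions_per_multi)


@dataclass(frozen=True)
class Locus:
    name: str
    start: int
    end: int
    region: str  # LSC / IRb / SSC / IRa
    multiplier: float = 1.0
    intergenic: bool = False

    def __len__(self) -> int:
        return self.end - self.start


# full-scale named locus templates: (name, length at 87 kb LSC, intergenic)
_LSC_TEMPLATE = [
    ("lsc-f1", 3000, True),
    ("trnH-psbA", 400, True),
    ("lsc-f2", 2000, True),
    ("matK", 1500, False),
    ("rps16-trnQ", 800, True),
    ("lsc-f3", 4000, True),
    ("trnC-petN", 900, True),
    ("petN-psbM", 500, True),
    ("lsc-f4", 6000, True),
    ("trnS-G", 1200, True),
    ("lsc-f5", 5000, True),
    ("trnE-T", 1000, True),
    ("trnT-L", 1000, True),
    ("lsc-f6", 8000, True),
    ("rbcL", 1400, False),
]
_SSC_TEMPLATE = [
    ("ndhF", 2200, False),
    ("ndhF-rpl32", 1000, True),
    ("rpl32-trnL", 650, True),
]

#: names usable as barcode regions in evaluation harnesses
BARCODE_LOCI = (
    "matK", "rbcL", "trnH-psbA", "ndhF", "trnS-G", "trnC-petN",
    "ndhF-rpl32", "rpl32-trnL", "trnE-T", "trnT-L",
)


def default_locus_map(config: SimulationConfig) -> list[Locus]:
    """Partition the template into named loci covering LSC/IRb/SSC/IRa.

    Named locus lengths scale with the LSC so the scaled-down preset keeps
    proportions; each region ends with a filler locus absorbing the
    remainder.
    """
    factor = config.lsc_length / 87_000.0
    loci: list[Locus] = []
    pos = 0

    def emit(name: str, length: int, region: str, intergenic: bool) -> None:
        nonlocal pos
        if length <= 0:
            raise ValueError(f"locus {name!r} would have non-positive length")
        mult = config.region_rate_multipliers.get(name, 1.0)
        loci.append(Locus(name, pos, pos + length, region, mult, intergenic))
        pos += length

    used = 0
    for name, base_len, intergenic in _LSC_TEMPLATE:
        length = max(1, round(base_len * factor))
        emit(name, length, "LSC", intergenic)
        used += length
    if used >= config.lsc_length:
        raise ValueError("LSC template loci exceed the configured LSC length")
    emit("lsc-f7", config.lsc_length - used, "LSC", True)

    emit("IRb", config.ir_length, "IRb", False)

    used = 0
    for name, base_len, intergenic in _SSC_TEMPLATE:
        length = max(1, round(base_len * factor))
        emit(name, length, "SSC", intergenic)
        used += length
    if used >= config.ssc_length:
        raise ValueError("SSC template loci exceed the configured SSC length")
    emit("ssc-f1", config.ssc_length - used, "SSC", True)

    emit("IRa", config.ir_length, "IRa", False)
    return loci


def locus_annotations(loci: Sequence[Locus]) -> list[Annotation]:
    return [Annotation(name=l.name, start=l.start, end=l.end) for l in loci]


def simulate_species_tree(config: SimulationConfig) -> dendropy.Tree:
    """Yule species tree with accession tips attached at shallow depth.

    Branch lengths are scaled so the mean pairwise tip-to-tip species
    distance equals ``interspecific_scale``; each multi-accession species
    leaf is replaced by a shallow clade of 2-3 accession tips whose pendant
    edges are ``intraspecific_scale / 2``.  Tip labels are accession ids
    "<species>_a<i>"; seeded and deterministic.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species

    # forward Yule: split a uniformly chosen active lineage at each event,
    # waiting Exp(k) between events with k active lineages
    root = dendropy.Node()
    root.depth = 0.0
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        parent = active.pop(int(rng.integers(0, k)))
        parent.depth = t
        for _ in range(2):
            child = dendropy.Node()
            active.append(child)
        for child in active[-2:]:
            parent.add_child(child)
    t += rng.exponential(1.0 / n)
    for leaf in active:
        leaf.depth = t

    def set_edges(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            child.edge.length = child.depth - node.depth
            set_edges(child)

    set_edges(root)

    # mean pairwise tip distance on an ultrametric tree = 2 * mean TMRCA depth
    # measured from the tips; compute exactly and rescale
    leaves = active
    total = 0.0
    npairs = 0
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            a, b = leaves[i], leaves[j]
            ancestors_a = set()
            node = a
            while node is not None:
                ancestors_a.add(id(node))
                node = node.parent_node
            node = b
            while id(node) not in ancestors_a:
                node = node.parent_node
            total += 2.0 * (t - node.depth)
            npairs += 1
    mean_pairwise = total / npairs
    scale = config.interspecific_scale / mean_pairwise

    def rescale(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            child.edge.length *= scale
            rescale(child)

    rescale(root)

    species = [f"sp{i + 1:02d}" for i in range(n)]
    # multi-accession species must be separated from their sister by more
    # than the intraspecific noise, or "monophyletic by construction" would
    # be vacuous: sample them among leaves whose terminal branch is at least
    # 3x the intraspecific scale, topping up from the longest branches
    pendants = np.array([leaf.edge.length for leaf in leaves])
    qualifying = [i for i in range(n) if pendants[i] >= 3.0 * config.intraspecific_scale]
    k = config.n_multi_accession
    if len(qualifying) >= k:
        multi = sorted(rng.choice(qualifying, size=k, replace=False).tolist())
    else:
        by_length = sorted(range(n), key=lambda i: (-pendants[i], i))
        multi = sorted(set(qualifying) | set(by_length[: k]))[:k]
    counts = {species[m]: c for m, c in zip(multi, config.accessions_per_multi)}

    labels: list[str] = []
    for leaf, sp in zip(leaves, species):
        k = counts.get(sp, 1)
        if k == 1:
            leaf.label = f"{sp}_a1"
            labels.append(leaf.label)
            continue
        for i in range(k):
            tip = dendropy.Node()
            tip.label = f"{sp}_a{i + 1}"
            leaf.add_child(tip)
            tip.edge.length = config.intraspecific_scale / 2.0
            labels.append(tip.label)

    tns = dendropy.TaxonNamespace(labels)
    for node in root.preorder_iter():
        if not node.child_nodes():
            node.taxon = tns.get_taxon(node.label)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    tree.species_names = species
    tree.multi_accession_species = sorted(counts)
    return tree


def species_of_accession(accession_id: str) -> str:
    return accession_id.rsplit("_a", 1)[0]


def sample_table_for(alignment_ids: Sequence[str]) -> SampleTable:
    return SampleTable.from_pairs(
        [(acc, species_of_accession(acc)) for acc in alignment_ids]
    )


def _mutate(seq: np.ndarray, distance: float, rates: np.ndarray, rng) -> np.ndarray:
    """One Jukes-Cantor branch step; per-site distance = branch * multiplier."""
    p_change = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * distance * rates))
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def evolve_alignment(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[MultipleAlignment, dict]:
    """Jukes-Cantor site evolution along the tree over the locus template.

    The core (LSC + IRb + SSC) evolves site-by-site with per-locus rate
    multipliers; each genome's IRa is then appended as the reverse
    complement of its own IRb, so the alignment is gap-free with homology
    known by construction.  Returns the alignment and the truth record.
    """
    rng = np.random.default_rng(config.seed + 1)
    loci = default_locus_map(config)
    core_len = config.lsc_length + config.ir_length + config.ssc_length

    rates = np.ones(core_len)
    for locus in loci:
        if locus.region == "IRa":
            continue
        rates[locus.start : locus.end] = locus.multiplier

    # pin the four junction-adjacent single-copy sites to A and hold them
    # invariant: a maximal exact reverse-complement repeat then ends exactly
    # at the planted IR boundaries in every genome (A is never complementary
    # to A), so the structure stage recovers template region lengths exactly
    ssc_start = config.lsc_length + config.ir_length
    pinned = [0, config.lsc_length - 1, ssc_start, ssc_start + config.ssc_length - 1]
    rates[pinned] = 0.0

    root_seq = rng.choice(4, size=core_len, p=_BASE_FREQS).astype(np.int8)
    root_seq[pinned] = 0
    tree.seed_node.sim_seq = root_seq
    leaf_seqs: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            d = node.edge.length or 0.0
            node.sim_seq = _mutate(node.parent_node.sim_seq, d, rates, rng)
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = node.sim_seq
    for node in tree.preorder_node_iter():  # free intermediate sequences
        if not node.is_leaf():
            del node.sim_seq

    irb = next(l for l in loci if l.name == "IRb")
    ids = sorted(leaf_seqs)
    rows = []
    for acc in ids:
        core = leaf_seqs[acc]
        ira = (3 - core[irb.start : irb.end])[::-1]  # reverse complement
        rows.append(np.concatenate([core, ira]))
    matrix = _LOOKUP[np.stack(rows)]
    alignment = MultipleAlignment(ids=ids, matrix=matrix, region_name="plastome")

    multi = sorted(getattr(tree, "multi_accession_species", []))
    truth = {
        "seed": config.seed,
        "config": _config_dict(config),
        "locus_map": [
            {
                "name": l.name,
                "start": l.start,
                "end": l.end,
                "region": l.region,
                "multiplier": l.multiplier,
                "intergenic": l.intergenic,
            }
            for l in loci
        ],
        "multi_accession_species": multi,
        "monophyletic_species": list(multi),
        "captures": [],
        "per_locus_expected_divergence": {
            l.name: config.interspecific_scale * l.multiplier for l in loci
        },
    }
    _set_expected_rate(truth)
    return alignment, truth


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["accessions_per_multi"] = list(d["accessions_per_multi"])
    return d


def _set_expected_rate(truth: dict) -> None:
    from ._util import round_half_up

    n_multi = len(truth["multi_accession_species"])
    k = len(truth["monophyletic_species"])
    truth["expected_rate_pct"] = round_half_up(100.0 * k / n_multi) if n_multi else None


def inject_plastome_capture(
    alignment: MultipleAlignment,
    truth: dict,
    recipient: str,
    donor: str,
    seed: int,
) -> tuple[MultipleAlignment, dict]:
    """Replace one recipient accession's plastome by a near-copy of a donor
    haplotype (donor-level intraspecific noise applied), emulating plastid
    introgression.

    The truth record drops the recipient (and, when the donor itself has
    multiple accessions, the donor) from the monophyletic set.
    """
    if recipient == donor:
        raise ValueError("capture recipient and donor must differ")
    groups: dict[str, list[str]] = {}
    for acc in alignment.ids:
        groups.setdefault(species_of_accession(acc), []).append(acc)
    if recipient not in groups or donor not in groups:
        raise ValueError(f"unknown species in capture event: {recipient!r} or {donor!r}")
    if len(groups[recipient]) < 2:
        raise ValueError(f"capture recipient {recipient!r} needs >= 2 accessions")

    rng = np.random.default_rng(seed)
    target_acc = groups[recipient][0]
    donor_acc = groups[donor][0]
    ti = alignment.ids.index(target_acc)
    di = alignment.ids.index(donor_acc)

    codes = np.searchsorted(_LOOKUP, alignment.matrix[di])
    intra = truth["config"]["intraspecific_scale"]
    noisy = _mutate(codes.astype(np.int8), intra, np.ones(codes.size), rng)
    matrix = alignment.matrix.copy()
    matrix[ti] = _LOOKUP[noisy]

    new_truth = json.loads(json.dumps(truth))
    mono = set(new_truth["monophyletic_species"])
    mono.discard(recipient)
    if len(groups[donor]) >= 2:
        mono.discard(donor)
    new_truth["monophyletic_species"] = sorted(mono)
    new_truth["captures"].append({"recipient": recipient, "donor": donor,
                                  "replaced_accession": target_acc})
    _set_expected_rate(new_truth)
    return (
        MultipleAlignment(ids=list(alignment.ids), matrix=matrix,
                          region_name=alignment.region_name),
        new_truth,
    )


def inject_insertion(
    records: Sequence[PlastomeRecord],
    species: str,
    locus_name: str,
    length: int,
    seed: int,
    loci: Sequence[Locus],
) -> list[PlastomeRecord]:
    """Insert a random sequence into one species' unaligned genomes.

    The insertion point is the midpoint of the named intergenic locus, which
    must lie in a single-copy region (inserting into an IR would desynchronise
    the two repeat copies).  All accessions of the species grow by ``length``;
    other records pass through unchanged.  ``length = 0`` is the identity.
    """
    locus = next((l for l in loci if l.name == locus_name), None)
    if locus is None:
        raise ValueError(f"unknown locus {locus_name!r}")
    if locus.region in {"IRb", "IRa"}:
        raise ValueError(f"cannot insert into inverted repeat locus {locus_name!r}")
    if not locus.intergenic:
        raise ValueError(f"insertion target {locus_name!r} is not intergenic")
    if length < 0:
        raise ValueError("insertion length must be >= 0")
    if length == 0:
        return list(records)
    rng = np.random.default_rng(seed)
    insert = "".join("ACGT"[b] for b in rng.choice(4, size=length, p=_BASE_FREQS))
    point = (locus.start + locus.end) // 2
    out = []
    for rec in records:
        if (rec.species or species_of_accession(rec.accession_id)) == species:
            seq = rec.sequence[:point] + insert + rec.sequence[point:]
            out.append(PlastomeRecord(rec.accession_id, seq, rec.species))
        else:
            out.append(rec)
    return out


@dataclass
class SyntheticDataset:
    """One generated study: tree, gap-free alignment, samples, truth record."""

    tree: dendropy.Tree
    alignment: MultipleAlignment
    sample_table: SampleTable
    truth: dict
    loci: list[Locus]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Species tree + alignment + sample table, with configured capture events."""
    tree = simulate_species_tree(config)
    alignment, truth = evolve_alignment(tree, config)
    for k, (recipient, donor) in enumerate(config.capture_events):
        alignment, truth = inject_plastome_capture(
            alignment, truth, recipient, donor, seed=config.seed + 100 + k
        )
    return SyntheticDataset(
        tree=tree,
        alignment=alignment,
        sample_table=sample_table_for(alignment.ids),
        truth=truth,
        loci=default_locus_map(config),
    )


def evolve_codon_alignment(
    n_codons: int, divergence: float, omega: float, seed: int, gene_name: str = "sim"
):
    """Fixed-omega codon-pair generator for the dN/dS screen's tests.

    An ancestral sequence of random sense codons receives
    ``divergence * 3 * n_codons`` proposed single-nucleotide changes at
    uniformly random sites; proposals creating stops are rejected,
    synonymous proposals are always accepted and nonsynonymous ones are
    accepted with probability ``omega`` — so the generating dN/dS ratio is
    ``omega`` by construction.
    """
    from .selection import CODON_TO_AA, STOP_CODONS, CodonAlignment

    rng = np.random.default_rng(seed)
    sense = sorted(set(CODON_TO_AA) - STOP_CODONS)
    anc = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    der = list(anc)
    n_proposals = int(round(divergence * 3 * n_codons))
    for _ in range(n_proposals):
        site = int(rng.integers(0, 3 * n_codons))
        k, pos = divmod(site, 3)
        codon = der[k]
        choices = [b for b in "ACGT" if b != codon[pos]]
        new = codon[:pos] + choices[int(rng.integers(0, 3))] + codon[pos + 1 :]
        if new in STOP_CODONS:
            continue
        if CODON_TO_AA[new] != CODON_TO_AA[codon] and rng.random() >= omega:
            continue
        der[k] = new
    return CodonAlignment(
        ids=["ancestral", "derived"],
        sequences=["".join(anc), "".join(der)],
        gene_name=gene_name,
    )
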