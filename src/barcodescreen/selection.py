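"""Per-gene dN/dS screening with Nei-Gojobori (1986) counting.

For each protein-coding gene alignment the method counts synonymous (S) and
nonsynonymous (N) *sites* by enumerating the three single-nucleotide mutants
of every codon (mutants creating stop codons are excluded, so a codon
contributes S + N = 3 minus the excluded fraction), and synonymous (Sd) and
nonsynonymous (Nd) *differences* per codon pair, averaging over all mutation
orderings for multi-hit codons (pathways passing through a stop codon are
discarded).  Proportions pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS.

This is a counting screen: adequate to band genes into purifying /
near-neutral / candidate-positive classes, not a maximum-likelihood
estimate.  The standard genetic code is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .variation import MultipleAlignment

_BASES = "ACGT"

#: codon -> amino acid, '*' for stops (standard code)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass
class CodonAlignment:
    """In-frame codon alignment for one gene (length divisible by 3)."""

    ids: list[str]
    sequences: list[str]
    gene_name: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("codon alignment rows must share one length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"codon alignment length {length} is not divisible by 3")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("codon alignment ids must be unique")
        self.sequences = [s.upper() for s in self.sequences]
        for sid, seq in zip(self.ids, self.sequences):
            for k in range(0, length - 3, 3):  # terminal stop is allowed
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"{self.gene_name or 'gene'}/{sid}: internal stop codon "
                        f"{codon} at nucleotide {k}"
                    )

    @classmethod
    def from_alignment(cls, aln: MultipleAlignment, gene_name: str = "") -> "CodonAlignment":
        return cls(ids=list(aln.ids), sequences=aln.sequences(),
                   gene_name=gene_name or aln.region_name)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon(self, row: int, k: int) -> str:
        return self.sequences[row][3 * k : 3 * k + 3]


@dataclass
class SelectionResult:
    gene_name: str
    dn: Optional[float]
    ds: Optional[float]
    omega: Optional[float]
    reliability_flag: bool
    n_pairs_used: int = 0

    def to_row(self) -> dict:
        return {
            "gene": self.gene_name,
            "dN": self.dn,
            "dS": self.ds,
            "omega": self.omega,
            "reliable": self.reliability_flag,
        }


def codon_site_counts(codon: str) -> Optional[tuple[float, float]]:
    """(synonymous sites, nonsynonymous sites) for one sense codon.

    Per position, each of the 3 single-nucleotide mutants contributes 1/3
    site: synonymous mutants to S, nonsynonymous to N, and mutants creating
    a stop codon to neither (so S + N = 3 minus the excluded fraction).
    Returns None for codons with ambiguous characters (skip signal); raises
    for stop codons.
    """
    codon = codon.upper()
    if any(b not in _BASES for b in codon):
        return None
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    syn = 0.0
    nonsyn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            maa = CODON_TO_AA[mutant]
            if maa == "*":
                continue  # excluded
            if maa == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def _pathway_differences(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Multi-hit codons average over all orderings of the changed positions;
    orderings passing through a stop codon are discarded.  None when no
    stop-free pathway exists.
    """
    changed = [i for i in range(3) if c1[i] != c2[i]]
    if not changed:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    valid = 0
    for order in permutations(changed):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            valid += 1
            syn_total += syn
            non_total += non
    if valid == 0:
        return None
    return syn_total / valid, non_total / valid


def jukes_cantor(p: float) -> Optional[float]:
    """d = -(3/4) ln(1 - (4/3) p); None when p >= 3/4 (undefined)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def pair_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """Pre-correction NG86 counts (S, N, Sd, Nd) for one sequence pair.

    Site counts are averaged across the two sequences; difference counts
    average over mutation pathways.  Codons with ambiguity/gaps, stop codons
    and codon pairs with no stop-free pathway are skipped.
    """
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3], seq2[k : k + 3]
        counts1 = codon_site_counts(c1) if c1 not in STOP_CODONS else None
        counts2 = codon_site_counts(c2) if c2 not in STOP_CODONS else None
        if counts1 is None or counts2 is None:
            continue  # ambiguous/gapped/terminal-stop codon: skipped
        path = _pathway_differences(c1, c2)
        if path is None:
            continue
        s_sites += (counts1[0] + counts2[0]) / 2.0
        n_sites += (counts1[1] + counts2[1]) / 2.0
        sd += path[0]
        nd += path[1]
    return s_sites, n_sites, sd, nd


def _pair_dn_ds(seq1: str, seq2: str) -> Optional[tuple[float, float]]:
    """Jukes-Cantor-corrected (dN, dS) for one sequence pair, or None."""
    s_sites, n_sites, sd, nd = pair_counts(seq1, seq2)
    if s_sites == 0 or n_sites == 0:
        return None
    ds = jukes_cantor(sd / s_sites)
    dn = jukes_cantor(nd / n_sites)
    if ds is None or dn is None:
        return None
    return dn, ds


def ng86_dn_ds(codon_alignment: CodonAlignment) -> SelectionResult:
    """Gene-level NG86 dN, dS and omega, averaged over all sequence pairs.

    Pairs whose correction is undefined (p >= 3/4) or that retain no
    comparable codons are dropped and clear the reliability flag; omega is
    None when dS = 0 (identical sequences at synonymous sites).
    """
    n = len(codon_alignment.ids)
    if n < 2:
        raise ValueError("dN/dS needs at least 2 sequences")
    dns: list[float] = []
    dss: list[float] = []
    all_defined = True
    for i, j in combinations(range(n), 2):
        pair = _pair_dn_ds(codon_alignment.sequences[i], codon_alignment.sequences[j])
        if pair is None:
            all_defined = False
            continue
        dns.append(pair[0])
        dss.append(pair[1])
    if not dns:
        return SelectionResult(codon_alignment.gene_name, None, None, None, False, 0)
    dn = sum(dns) / len(dns)
    ds = sum(dss) / len(dss)
    omega = dn / ds if ds > 0 else None
    return SelectionResult(
        gene_name=codon_alignment.gene_name,
        dn=dn,
        ds=ds,
        omega=omega,
        reliability_flag=all_defined and omega is not None,
        n_pairs_used=len(dns),
    )


def classify_selection(result: SelectionResult, total_ds: float) -> str:
    """Band a gene by omega; candidate-positive additionally needs tree-wide dS > 0.5.

    Labels: 'purifying' (omega < 0.5), 'relaxed/near-neutral'
    (0.5 <= omega <= 1), 'candidate-positive' (omega > 1 and total_dS > 0.5),
    'unreliable' (omega > 1 with total_dS <= 0.5, or omega undefined).
    """
    if result.omega is None:
        return "unreliable"
    if result.omega < 0.5:
        return "purifying"
    if result.omega <= 1.0:
        return "relaxed/near-neutral"
    return "candidate-positive" if total_ds > 0.5 else "unreliable"


def screen_genes(
    gene_alignments: Sequence[CodonAlignment],
) -> "pd.DataFrame":
    """NG86 screen over a set of gene alignments -> tidy result table."""
    import pandas as pd

    rows = []
    for gene in gene_alignments:
        res = ng86_dn_ds(gene)
        total_ds = (res.ds or 0.0) * max(res.n_pairs_used, 1)
        rows.append({**res.to_row(), "class": classify_selection(res, total_ds)})
    return pd.DataFrame(rows)
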