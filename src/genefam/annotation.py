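"""Chromosome distribution, tandem gene clusters, and promoter cis-element
scanning.

A gene cluster is a run of consecutive family members on one chromosome
whose span (first member's start to last member's end) stays below a
threshold — 200 kb with at least two genes by default, the criterion
commonly used in plant gene-family surveys.  Promoter scanning matches an
editable dictionary of IUPAC consensus strings (PlantCARE-style element
names, split into phytohormone-responsive and abiotic-stress categories)
on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .core_io import DATA_DIR, GeneRecord, reverse_complement

__all__ = [
    "GeneCluster",
    "CisElement",
    "CisElementHit",
    "chromosome_distribution",
    "detect_clusters",
    "load_element_dictionary",
    "default_element_dictionary",
    "scan_cis_elements",
    "summarize_elements",
    "WHEAT_CHROMOSOMES",
]

# hexaploid wheat: chromosome groups 1-7 across the A, B and D subgenomes
WHEAT_CHROMOSOMES = [f"{i}{g}" for i in range(1, 8) for g in "ABD"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class GeneCluster:
    chromosome: str
    members: list[str]          # gene ids ordered by start
    span: int                   # bp, first start to last end


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str               # "phytohormone" | "abiotic"


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element_name: str
    category: str
    position: int               # 1-based on the + strand of the promoter
    strand: str                 # "+" | "-"


# ---------------------------------------------------------------------------
# chromosome distribution and clusters
# ---------------------------------------------------------------------------

def chromosome_distribution(
    genes: list[GeneRecord], chromosomes: list[str] | None = None
) -> dict[str, int]:
    """Gene counts per chromosome, zeros included for empty chromosomes."""
    if chromosomes is None:
        chromosomes = sorted({g.chromosome for g in genes})
    counts = {c: 0 for c in chromosomes}
    for g in genes:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    return counts


def detect_clusters(
    genes: list[GeneRecord], max_span: int = 200_000, min_genes: int = 2
) -> list[GeneCluster]:
    """Greedy maximal runs of consecutive genes within ``max_span`` bp.

    Per chromosome, genes are sorted by start; a run grows while the span
    from its first member's start to the candidate's end stays below
    ``max_span``.  Runs of at least ``min_genes`` are reported; members are
    disjoint across clusters.  Input order does not matter.
    """
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        i = 0
        while i < len(ordered):
            j = i
            while (
                j + 1 < len(ordered)
                and ordered[j + 1].end - ordered[i].start < max_span
            ):
                j += 1
            if j - i + 1 >= min_genes:
                run = ordered[i : j + 1]
                clusters.append(
                    GeneCluster(
                        chromosome=chrom,
                        members=[g.gene_id for g in run],
                        span=run[-1].end - run[0].start,
                    )
                )
            i = j + 1
    return clusters


# ---------------------------------------------------------------------------
# cis-element scanning
# ---------------------------------------------------------------------------

def load_element_dictionary(path: str | Path) -> list[CisElement]:
    out: list[CisElement] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            consensus = p[idx["consensus"]].upper()
            bad = set(consensus) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"element {p[idx['element']]!r}: non-IUPAC {sorted(bad)}"
                )
            out.append(
                CisElement(p[idx["element"]], consensus, p[idx["category"]])
            )
    return out


def default_element_dictionary() -> list[CisElement]:
    return load_element_dictionary(DATA_DIR / "cis_elements.tsv")


def _iupac_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(IUPAC[c] for c in consensus))


def scan_cis_elements(
    promoter: str,
    dictionary: list[CisElement] | None = None,
    gene_id: str = "",
) -> list[CisElementHit]:
    """Every exact occurrence of every dictionary consensus on both strands.

    Occurrences may overlap.  Minus-strand matches are reported at the
    1-based plus-strand coordinate of their leftmost base.
    """
    if dictionary is None:
        dictionary = default_element_dictionary()
    promoter = promoter.upper()
    hits: list[CisElementHit] = []
    for element in dictionary:
        fwd = _iupac_regex(element.consensus)
        rev = _iupac_regex(reverse_complement(element.consensus))
        for pattern, strand in ((fwd, "+"), (rev, "-")):
            pos = 0
            while True:
                m = pattern.search(promoter, pos)
                if m is None:
                    break
                hits.append(
                    CisElementHit(
                        gene_id=gene_id,
                        element_name=element.name,
                        category=element.category,
                        position=m.start() + 1,
                        strand=strand,
                    )
                )
                pos = m.start() + 1  # allow overlapping occurrences
    hits.sort(key=lambda h: (h.position, h.element_name, h.strand))
    return hits


def summarize_elements(
    hits: list[CisElementHit],
) -> tuple[dict[str, float], dict[str, float]]:
    """(per-element, per-category) percentages of all hits; element
    percentages sum to 100."""
    if not hits:
        raise ValueError("empty hit list")
    total = len(hits)
    per_element: dict[str, int] = {}
    per_category: dict[str, int] = {}
    for h in hits:
        per_element[h.element_name] = per_element.get(h.element_name, 0) + 1
        per_category[h.category] = per_category.get(h.category, 0) + 1
    return (
        {k: 100.0 * v / total for k, v in sorted(per_element.items())},
        {k: 100.0 * v / total for k, v in sorted(per_category.items())},
    )
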