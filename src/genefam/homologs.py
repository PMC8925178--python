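"""Paralog/ortholog pair detection by exact local alignment.

At family scale (dozens of genes) exact Smith–Waterman with affine gaps is
affordable, so pairs are detected by optimal local alignment rather than
heuristic seeding.  A pair is reported when both percent identity (over
aligned columns) and coverage (aligned span over the shorter sequence) meet
their thresholds; pairs within one species are paralogs, across species
orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .core_io import DATA_DIR, SequenceSet

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "HomologPair",
    "local_align",
    "find_homolog_pairs",
    "split_species_tag",
    "read_pair_table",
    "bundled_pair_table",
    "pair_counts",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring: a gap of length k costs open + k*extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


@dataclass
class LocalAlignment:
    score: float
    identity: float       # percent of matched columns over aligned columns
    coverage: float       # percent of the shorter sequence inside the span
    a_start: int          # 1-based inclusive span on sequence a (0 if empty)
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    kind: str             # "paralog" | "ortholog"
    identity: float
    coverage: float
    score: float


def local_align(
    a: str, b: str, scoring: ScoringScheme = ScoringScheme()
) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment with affine gaps.

    Traceback is deterministic: on ties, diagonal beats a gap in ``b``
    (up) beats a gap in ``a`` (left).  If no positive-scoring alignment
    exists the result has score 0 and an empty span.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    la, lb = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend
    NEG = float("-inf")
    # H: best ending at (i,j); E: gap in b (vertical); F: gap in a (horizontal)
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, la + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        ai = a[i - 1]
        for j in range(1, lb + 1):
            Ei[j] = max(Hi1[j] - go - ge, Ei1[j] - ge)
            Fi[j] = max(Hi[j - 1] - go - ge, Fi[j - 1] - ge)
            s = scoring.match if ai == b[j - 1] else scoring.mismatch
            h = max(0.0, Hi1[j - 1] + s, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best == 0.0:
        return LocalAlignment(0.0, 0.0, 0.0, 0, 0, 0, 0, "", "")
    # traceback from (bi, bj)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0 and not (state == "H" and H[i][j] == 0.0):
        if state == "H":
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            out_a.append(a[i - 1])
            out_b.append("-")
            closed = H[i - 1][j] - go - ge == E[i][j]
            i -= 1
            if closed:
                state = "H"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            closed = H[i][j - 1] - go - ge == F[i][j]
            j -= 1
            if closed:
                state = "H"
    out_a.reverse()
    out_b.reverse()
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    cols = len(aligned_a)
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y)
    identity = 100.0 * matches / cols if cols else 0.0
    short_len = min(la, lb)
    span_a = bi - i
    span_b = bj - j
    span_short = span_a if la <= lb else span_b
    coverage = 100.0 * span_short / short_len
    return LocalAlignment(
        score=best, identity=identity, coverage=coverage,
        a_start=i + 1, a_end=bi, b_start=j + 1, b_end=bj,
        aligned_a=aligned_a, aligned_b=aligned_b,
    )


def split_species_tag(name: str) -> tuple[str, str]:
    """Split a ``species|gene_id`` FASTA id; missing tag is an error."""
    if "|" not in name:
        raise ValueError(f"sequence id {name!r} lacks a 'species|gene' tag")
    species, gene = name.split("|", 1)
    return species, gene


def find_homolog_pairs(
    genes: SequenceSet,
    min_identity: float = 75.0,
    min_coverage: float = 75.0,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[HomologPair]:
    """All unordered gene pairs passing both thresholds.

    Sequence ids carry species tags (``species|gene``); output order is
    lexicographic by (gene_a, gene_b).
    """
    names = list(genes.records)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    tags = {n: split_species_tag(n) for n in names}
    pairs: list[HomologPair] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            na, nb = sorted((names[i], names[j]))
            aln = local_align(genes[na], genes[nb], scoring)
            if aln.identity >= min_identity and aln.coverage >= min_coverage:
                kind = (
                    "paralog" if tags[na][0] == tags[nb][0] else "ortholog"
                )
                pairs.append(
                    HomologPair(
                        gene_a=na, gene_b=nb, kind=kind,
                        identity=aln.identity, coverage=aln.coverage,
                        score=aln.score,
                    )
                )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


# ---------------------------------------------------------------------------
# curated pair tables
# ---------------------------------------------------------------------------

def read_pair_table(path: str | Path) -> list[HomologPair]:
    """Read a curated pair table (gene_a, gene_b, kind); similarity fields
    are not part of such tables and are set to NaN."""
    out: list[HomologPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            out.append(
                HomologPair(
                    gene_a=p[idx["gene_a"]], gene_b=p[idx["gene_b"]],
                    kind=p[idx["kind"]],
                    identity=float("nan"), coverage=float("nan"),
                    score=float("nan"),
                )
            )
    return out


def bundled_pair_table() -> list[HomologPair]:
    """The bundled wheat/rice/maize VQ homolog pair list (84 pairs)."""
    return read_pair_table(DATA_DIR / "homolog_pairs.tsv")


def pair_counts(pairs: list[HomologPair]) -> dict[str, int]:
    """Pair counts keyed by species combination (e.g. Ta/Ta, Ta/Os)."""
    counts: dict[str, int] = {}

    def species_of(gene: str) -> str:
        if "|" in gene:
            return gene.split("|", 1)[0]
        # curated ids like TaVQ1 / OsVQ8 / ZmVQ14 carry a 2-letter prefix
        return gene[:2]

    for p in pairs:
        key = "/".join(sorted((species_of(p.gene_a), species_of(p.gene_b))))
        counts[key] = counts.get(key, 0) + 1
    return counts
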