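"""Nei–Gojobori (1986) Ka/Ks estimation, sliding-window profiles, selection
classification, and molecular-clock divergence dating.

The NG86 counting method works codon by codon: each codon contributes a
fractional number of synonymous sites (the fraction of one-step nucleotide
changes that leave the amino acid unchanged, summed over its three
positions), differences between codons are classified by averaging over all
minimal substitution pathways with equal weights (pathways passing through
a stop codon are excluded), and the raw proportions pS = Sd/S and pN = Nd/N
are corrected for multiple hits with the Jukes–Cantor formula
K = -(3/4)·ln(1 - (4/3)p).  The correction is undefined for p >= 3/4, in
which case the corresponding rate is reported as missing (None).

Divergence dates follow the synonymous molecular clock T = Ks/(2λ), with a
default rate λ = 6.5e-9 synonymous substitutions per site per year (a value
commonly applied to grass nuclear genes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

from .core_io import DATA_DIR, Alignment, SequenceSet

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "ClockConfig",
    "back_translate",
    "nei_gojobori",
    "kaks_classify",
    "sliding_window_kaks",
    "divergence_time",
    "summarize_selection",
    "SelectionSummary",
    "read_kaks_table",
    "bundled_kaks_table",
]

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Codon-level alignment: gaps only in whole-codon triplets."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("unequal row lengths")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("row length not divisible by 3")
        for rid, seq in self.rows:
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"{rid}: partial-codon gap at nt {i + 1} ({codon!r})"
                    )


@dataclass
class KaKsResult:
    """NG86 output for one sequence pair.  ``None`` marks undefined values
    (Jukes–Cantor correction out of domain, or a zero/missing Ks for the
    ratio)."""

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None
    selection_class: str = "NA"


@dataclass(frozen=True)
class ClockConfig:
    """Synonymous molecular clock: substitutions per site per year."""

    lambda_rate: float = 6.5e-9

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")


# ---------------------------------------------------------------------------
# codon bookkeeping
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str) -> float:
    """Fractional synonymous sites of one codon: per position, the share of
    the three possible nucleotide changes that are synonymous.  Changes to
    stop codons count as nonsynonymous."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES: dict[str, float] = {c: _syn_site_fraction(c) for c in CODON_TO_AA}


def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weights over all minimal substitution pathways.  Pathways
    passing through a stop codon are dropped; if every pathway does, all are
    kept (the standard fallback so counts remain defined)."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                nd += 1.0
            elif cur in STOP_CODONS:
                through_stop = True
                nd += 1.0
            elif CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (fallback if through_stop else pathways).append((sd, nd))
    chosen = pathways or fallback
    sd = sum(p[0] for p in chosen) / len(chosen)
    nd = sum(p[1] for p in chosen) / len(chosen)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` outside its domain (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


# ---------------------------------------------------------------------------
# core estimator
# ---------------------------------------------------------------------------

def _comparable(codon: str) -> bool:
    return (
        len(codon) == 3
        and set(codon) <= set(_BASES)
        and codon not in STOP_CODONS
    )


def nei_gojobori(row_a: str, row_b: str) -> KaKsResult:
    """NG86 Ka/Ks between two aligned codon sequences.

    Codon pairs where either side has a gap, an ambiguity character, or a
    stop codon are excluded pairwise.  Symmetric in its two arguments.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal length")
    if len(row_a) % 3:
        raise ValueError("length not divisible by 3")
    row_a, row_b = row_a.upper(), row_b.upper()
    s_sites = n_sites = sd = nd = 0.0
    compared = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if not (_comparable(ca) and _comparable(cb)):
            continue
        compared += 1
        s_sites += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        d = _pathway_diffs(ca, cb)
        sd += d[0]
        nd += d[1]
    if compared == 0:
        raise ValueError("no comparable codons")
    n_sites = 3.0 * compared - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ka is None or ks is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks
    result = KaKsResult(
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        ps=ps, pn=pn, ks=ks, ka=ka, ratio=ratio,
    )
    result.selection_class = kaks_classify(result)
    return result


def kaks_classify(result: KaKsResult | float | None) -> str:
    """Selection class from the Ka/Ks ratio: >1 positive, <1 purifying,
    =1 (within 1e-9) neutral, undefined -> NA."""
    ratio = result.ratio if isinstance(result, KaKsResult) else result
    if ratio is None:
        return "NA"
    if abs(ratio - 1.0) <= 1e-9:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


def sliding_window_kaks(
    row_a: str, row_b: str, window: int = 30, step: int = 3
) -> list[tuple[int, float | None, float | None, float | None]]:
    """Per-window NG86 profile along a pair of aligned codon sequences.

    Returns (1-based start codon, ka, ks, ratio) per window; window count is
    floor((L - window)/step) + 1.  Windows with no comparable codons yield
    all-None entries.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n_codons = len(row_a) // 3
    if window > n_codons:
        raise ValueError(f"window {window} exceeds {n_codons} aligned codons")
    out = []
    for start in range(0, n_codons - window + 1, step):
        a = row_a[start * 3 : (start + window) * 3]
        b = row_b[start * 3 : (start + window) * 3]
        try:
            r = nei_gojobori(a, b)
            out.append((start + 1, r.ka, r.ks, r.ratio))
        except ValueError:
            out.append((start + 1, None, None, None))
    return out


def divergence_time(
    ks: float | None, clock: ClockConfig = ClockConfig()
) -> float | None:
    """Synonymous-clock divergence date in million years: T = Ks/(2λ)·1e-6."""
    if ks is None:
        return None
    if ks < 0:
        raise ValueError("negative Ks")
    return ks / (2.0 * clock.lambda_rate) * 1e-6


# ---------------------------------------------------------------------------
# back-translation
# ---------------------------------------------------------------------------

def back_translate(
    protein_alignment: Alignment, cds: SequenceSet
) -> CodonAlignment:
    """Thread each CDS through its aligned protein row: one codon per
    residue, ``---`` per protein gap.  The CDS (minus any terminal stop)
    must translate to the ungapped protein row."""
    from .core_io import translate_cds

    rows: list[tuple[str, str]] = []
    for rid, gapped in protein_alignment.rows:
        if rid not in cds:
            raise KeyError(f"no CDS for {rid!r}")
        seq = cds[rid]
        prot = translate_cds(seq, permissive=True)
        ungapped = gapped.replace("-", "")
        if prot != ungapped:
            mism = next(
                (k for k, (x, y) in enumerate(zip(prot, ungapped)) if x != y),
                min(len(prot), len(ungapped)),
            )
            raise ValueError(
                f"{rid}: CDS translation differs from aligned protein "
                f"at residue {mism + 1}"
            )
        out = []
        k = 0
        for aa in gapped:
            if aa == "-":
                out.append("---")
            else:
                out.append(seq[3 * k : 3 * k + 3])
                k += 1
        rows.append((rid, "".join(out)))
    return CodonAlignment(rows)


# ---------------------------------------------------------------------------
# summaries and the bundled pair table
# ---------------------------------------------------------------------------

@dataclass
class SelectionSummary:
    counts: dict[str, int]
    ks_min: float | None
    ks_max: float | None
    date_min: float | None
    date_max: float | None


def summarize_selection(
    results: Iterable[tuple[str, KaKsResult]],
    clock: ClockConfig = ClockConfig(),
) -> SelectionSummary:
    """Counts per selection class plus the Ks range and its clock dates."""
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    counts = {"positive": 0, "purifying": 0, "neutral": 0, "NA": 0}
    ks_values = []
    for _, r in results:
        counts[kaks_classify(r)] += 1
        if r.ks is not None:
            ks_values.append(r.ks)
    ks_min = min(ks_values) if ks_values else None
    ks_max = max(ks_values) if ks_values else None
    return SelectionSummary(
        counts=counts,
        ks_min=ks_min,
        ks_max=ks_max,
        date_min=divergence_time(ks_min, clock),
        date_max=divergence_time(ks_max, clock),
    )


def read_kaks_table(path: str | Path) -> list[tuple[str, KaKsResult]]:
    """Read a published-style Ka/Ks pair table (pair, ka, ks, ka_ks, date)."""
    out: list[tuple[str, KaKsResult]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ka = float(parts[idx["ka"]])
            ks = float(parts[idx["ks"]])
            ratio = float(parts[idx["ka_ks"]])
            r = KaKsResult(
                s_sites=float("nan"), n_sites=float("nan"),
                sd=float("nan"), nd=float("nan"),
                ps=float("nan"), pn=float("nan"),
                ks=ks, ka=ka, ratio=ratio,
            )
            r.selection_class = kaks_classify(r)
            out.append((parts[idx["pair"]], r))
    return out


def bundled_kaks_table() -> list[tuple[str, KaKsResult]]:
    """The bundled wheat/rice/maize VQ homolog-pair Ka/Ks table (84 pairs)."""
    return read_kaks_table(DATA_DIR / "kaks_pairs.tsv")
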