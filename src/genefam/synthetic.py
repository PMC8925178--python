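"""Seeded synthetic-data generators with recorded ground truth.

Every pipeline stage can be exercised on generated inputs whose true
planted structure (motif positions, substitution counts, element
placements, expression directions) is recorded alongside, so downstream
recovery can be scored exactly.  All generators are deterministic given
(parameters, seed).

These generators emulate the *shape* of real gene-family data — not real
genome composition: backgrounds are i.i.d. uniform nucleotides or residues,
with no codon-usage bias and no homoeologous subgenome structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CisElement, IUPAC, default_element_dictionary, scan_cis_elements
from .core_io import SequenceSet, reverse_complement
from .dormancy import ExpressionMatrix, GerminationRecord
from .evolution import CODON_TO_AA, STOP_CODONS, _SYN_SITES
from .family_scan import DEFAULT_PATTERN, MotifPattern, scan_vq_motif

__all__ = [
    "SyntheticTruth",
    "simulate_proteome",
    "evolve_codon_pair",
    "simulate_promoters",
    "simulate_germination",
    "simulate_expression",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SENSE_CODONS = sorted(CODON_TO_AA)


@dataclass
class SyntheticTruth:
    """What a generator planted, keyed so the downstream stage can be
    scored without re-deriving anything."""

    generator: str
    seed: int
    facts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# proteomes with planted VQ motifs
# ---------------------------------------------------------------------------

def _motif_free_protein(
    rng: np.random.Generator, length: int, pattern: MotifPattern
) -> str:
    while True:
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        if not scan_vq_motif(seq, mode="relaxed", pattern=pattern):
            return seq


def simulate_proteome(
    n_decoys: int,
    n_motif_proteins: int,
    length_range: tuple[int, int] = (127, 723),
    seed: int = 0,
    domain_types: Sequence[str] = ("LTG", "FTG", "ITG"),
    pattern: MotifPattern = DEFAULT_PATTERN,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Decoy proteins guaranteed motif-free plus proteins carrying exactly
    one planted VQ core of a recorded domain type at a recorded position.

    The default length range (127–723 aa) matches the span observed in the
    wheat VQ family.
    """
    if n_decoys < 0 or n_motif_proteins < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = length_range
    if lo < 10 or hi < lo:
        raise ValueError(f"impossible length range {length_range}")
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    planted: dict[str, dict] = {}
    for i in range(n_decoys):
        length = int(rng.integers(lo, hi + 1))
        records[f"decoy{i + 1}"] = _motif_free_protein(rng, length, pattern)
    for i in range(n_motif_proteins):
        name = f"vq{i + 1}"
        dtype = domain_types[i % len(domain_types)]
        length = int(rng.integers(lo, hi + 1))
        while True:
            background = _motif_free_protein(rng, length, pattern)
            pos = int(rng.integers(0, length - 10 + 1))
            core = (
                "F"
                + "".join(rng.choice(list(_AMINO_ACIDS), size=3))
                + "VQ"
                + str(rng.choice(list(_AMINO_ACIDS)))
                + dtype
            )
            seq = background[:pos] + core + background[pos + 10 :]
            hits = scan_vq_motif(seq, mode="relaxed", pattern=pattern)
            if len(hits) == 1 and hits[0].position == pos + 1:
                break
        records[name] = seq
        planted[name] = {"position": pos + 1, "matched": core,
                         "domain_type": dtype}
    truth = SyntheticTruth(
        generator="simulate_proteome", seed=seed, facts={"planted": planted}
    )
    return SequenceSet(records, "protein"), truth


# ---------------------------------------------------------------------------
# codon pairs diverged at target Ka/Ks
# ---------------------------------------------------------------------------

def _invert_jc(k: float) -> float:
    """Expected raw proportion p for a Jukes–Cantor distance K."""
    if k < 0:
        raise ValueError("negative target rate")
    p = 0.75 * (1.0 - np.exp(-4.0 * k / 3.0))
    if p >= 0.75:
        raise ValueError(f"target rate {k} outside the invertible JC range")
    return float(p)


def evolve_codon_pair(
    n_codons: int, target_ks: float, target_ka: float, seed: int = 0
) -> tuple[str, str, SyntheticTruth]:
    """A stop-free ancestral CDS and a derived copy carrying Poisson numbers
    of synonymous and nonsynonymous one-step substitutions.

    Expected difference counts are pS·S and pN·N with pS, pN the
    JC-inverted target proportions; each substituted codon receives a
    single one-step change, keeping the NG86 counting assumptions exact at
    low divergence (multiple hits per codon are not simulated).
    """
    if n_codons < 1:
        raise ValueError("need at least one codon")
    ps, pn = _invert_jc(target_ks), _invert_jc(target_ka)
    rng = np.random.default_rng(seed)
    codons = [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons)]
    s_sites = sum(_SYN_SITES[c] for c in codons)
    n_sites = 3.0 * n_codons - s_sites

    def one_step(codon: str, synonymous: bool) -> list[str]:
        aa = CODON_TO_AA[codon]
        out = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                if (CODON_TO_AA[alt] == aa) == synonymous:
                    out.append(alt)
        return out

    n_syn = int(rng.poisson(ps * s_sites))
    n_non = int(rng.poisson(pn * n_sites))
    derived = list(codons)
    available = list(range(n_codons))
    rng.shuffle(available)
    realized_syn = realized_non = 0
    pool = iter(available)
    for synonymous, want in ((True, n_syn), (False, n_non)):
        done = 0
        while done < want:
            try:
                idx = next(pool)
            except StopIteration:
                raise ValueError(
                    f"{n_codons} codons too short for the requested divergence"
                ) from None
            options = one_step(derived[idx], synonymous)
            if not options:
                continue
            derived[idx] = str(rng.choice(options))
            done += 1
        if synonymous:
            realized_syn = done
        else:
            realized_non = done
    truth = SyntheticTruth(
        generator="evolve_codon_pair", seed=seed,
        facts={
            "target_ks": target_ks, "target_ka": target_ka,
            "syn_substitutions": realized_syn,
            "nonsyn_substitutions": realized_non,
            "s_sites_ancestor": s_sites, "n_sites_ancestor": n_sites,
        },
    )
    return "".join(codons), "".join(derived), truth


# ---------------------------------------------------------------------------
# promoters with planted cis-elements
# ---------------------------------------------------------------------------

def _concretize(consensus: str, rng: np.random.Generator) -> str:
    out = []
    for c in consensus:
        choices = IUPAC[c].strip("[]")
        out.append(str(rng.choice(list(choices))))
    return "".join(out)


def _element_free_background(
    rng: np.random.Generator, length: int, dictionary: list[CisElement]
) -> str:
    seq = list(rng.choice(list("ACGT"), size=length))
    for _ in range(200):
        hits = scan_cis_elements("".join(seq), dictionary)
        if not hits:
            return "".join(seq)
        for h in hits:
            width = len(
                next(e.consensus for e in dictionary if e.name == h.element_name)
            )
            for k in range(h.position - 1, h.position - 1 + width):
                seq[k] = str(rng.choice(list("ACGT")))
    raise RuntimeError("could not generate an element-free background")


def simulate_promoters(
    n: int,
    element_counts: dict[str, int],
    length: int = 1500,
    seed: int = 0,
    dictionary: list[CisElement] | None = None,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Element-free background promoters with the requested total number of
    each element planted at recorded non-overlapping positions on random
    strands, spread across the n promoters."""
    if dictionary is None:
        dictionary = default_element_dictionary()
    by_name = {e.name: e for e in dictionary}
    unknown = set(element_counts) - set(by_name)
    if unknown:
        raise ValueError(f"elements not in dictionary: {sorted(unknown)}")
    total_planted_len = sum(
        len(by_name[e].consensus) * c for e, c in element_counts.items()
    )
    if total_planted_len > n * length // 2:
        raise ValueError("too many plantings for the requested promoter space")
    rng = np.random.default_rng(seed)
    jobs = [
        name for name, count in sorted(element_counts.items())
        for _ in range(count)
    ]
    assignment = [int(rng.integers(0, n)) for _ in jobs]
    records: dict[str, str] = {}
    planted: dict[str, list[dict]] = {f"promoter{i + 1}": [] for i in range(n)}
    for i in range(n):
        my_jobs = [jobs[k] for k in range(len(jobs)) if assignment[k] == i]
        name = f"promoter{i + 1}"
        for _attempt in range(100):
            seq = _element_free_background(rng, length, dictionary)
            placements: list[tuple[int, int, str, str]] = []
            occupied: list[tuple[int, int]] = []
            ok = True
            for elem in my_jobs:
                width = len(by_name[elem].consensus)
                for _ in range(500):
                    pos = int(rng.integers(0, length - width + 1))
                    if all(
                        pos + width <= s or pos >= s + w for s, w in occupied
                    ):
                        break
                else:
                    ok = False
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                instance = _concretize(by_name[elem].consensus, rng)
                if strand == "-":
                    instance = reverse_complement(instance)
                seq = seq[:pos] + instance + seq[pos + width :]
                occupied.append((pos, width))
                placements.append((pos + 1, width, elem, strand))
            if not ok:
                continue
            hits = scan_cis_elements(seq, dictionary)
            want = sorted((p, e) for p, _, e, _ in placements)
            got = sorted((h.position, h.element_name) for h in hits)
            if want == got:
                break
        else:
            raise RuntimeError(f"could not plant elements in {name}")
        records[name] = seq
        planted[name] = [
            {"position": p, "element": e, "strand": s}
            for p, _, e, s in placements
        ]
    truth = SyntheticTruth(
        generator="simulate_promoters", seed=seed,
        facts={"planted": planted, "element_counts": dict(element_counts)},
    )
    return SequenceSet(records, "nucleotide"), truth


# ---------------------------------------------------------------------------
# germination assays
# ---------------------------------------------------------------------------

DEFAULT_DAY_PROBS = {
    # low dormancy germinates early and nearly completely (GI ~0.9, GR ~98%);
    # high dormancy barely germinates in 3 days (GI ~0.07, GR ~10%)
    "low": (0.80, 0.12, 0.06),
    "high": (0.04, 0.03, 0.03),
}


def simulate_germination(
    varieties: list[tuple[str, str]],
    N: int = 50,
    day_probs: dict[str, tuple[float, float, float]] | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[GerminationRecord], SyntheticTruth]:
    """Multinomial 3-day germination counts for each (variety, dormancy
    class), three replicates of 50 seeds by default."""
    probs = day_probs or DEFAULT_DAY_PROBS
    for cls, p in probs.items():
        if min(p) < 0 or sum(p) > 1.0 + 1e-12:
            raise ValueError(f"invalid day probabilities for class {cls!r}")
    rng = np.random.default_rng(seed)
    records: list[GerminationRecord] = []
    for variety, cls in varieties:
        p1, p2, p3 = probs[cls]
        pvec = [p1, p2, p3, 1.0 - p1 - p2 - p3]
        for rep in range(1, replicates + 1):
            n1, n2, n3, _ = rng.multinomial(N, pvec)
            records.append(
                GerminationRecord(
                    variety=variety, replicate=rep,
                    n1=int(n1), n2=int(n2), n3=int(n3), N=N,
                )
            )
    truth = SyntheticTruth(
        generator="simulate_germination", seed=seed,
        facts={
            "classes": dict(varieties),
            "expected_gi": {
                cls: (3 * p[0] + 2 * p[1] + p[2]) / 3.0
                for cls, p in probs.items()
            },
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# grouped expression matrices
# ---------------------------------------------------------------------------

DEFAULT_VARIETIES = [
    ("J411", "low"), ("ZY9507", "low"), ("ZM895", "low"),
    ("HMC21", "high"), ("YXM", "high"), ("SNTT", "high"),
]


def simulate_expression(
    n_genes: int = 65,
    varieties: list[tuple[str, str]] | None = None,
    timepoints: Sequence[float] = (0, 6, 10),
    n_low_direction: int = 13,
    n_high_direction: int = 8,
    effect: float = 4.0,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-normal baseline expression with direction genes shifted by a
    fold effect in one dormancy class at every timepoint.

    Defaults mirror a six-variety (three per dormancy class), three
    timepoint imbibition design with 13 genes up in low-dormancy varieties
    and 8 up in high-dormancy ones.
    """
    if n_low_direction + n_high_direction > n_genes:
        raise ValueError("direction gene counts exceed total genes")
    varieties = varieties or DEFAULT_VARIETIES
    if len({cls for _, cls in varieties}) < 2:
        raise ValueError("need varieties of both dormancy classes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    idx = rng.permutation(n_genes)
    low_set = {genes[i] for i in idx[:n_low_direction]}
    high_set = {
        genes[i] for i in idx[n_low_direction : n_low_direction + n_high_direction]
    }
    baseline = np.exp(rng.normal(np.log(10.0), 1.0, size=n_genes))
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for variety, cls in varieties:
        for tp in timepoints:
            for rep in range(1, replicates + 1):
                sample = f"{variety}_T{tp}_r{rep}"
                fold = np.ones(n_genes)
                for g_i, g in enumerate(genes):
                    if (g in low_set and cls == "low") or (
                        g in high_set and cls == "high"
                    ):
                        fold[g_i] = effect
                noise = np.exp(rng.normal(0.0, noise_sd, size=n_genes))
                columns[sample] = baseline * fold * noise
                meta_rows.append(
                    {"sample": sample, "variety": variety, "timepoint": tp,
                     "dormancy_class": cls, "replicate": rep}
                )
    values = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    directions = {
        g: (
            "higher_in_low_dormancy" if g in low_set
            else "higher_in_high_dormancy" if g in high_set
            else "none"
        )
        for g in genes
    }
    truth = SyntheticTruth(
        generator="simulate_expression", seed=seed,
        facts={"directions": directions},
    )
    return ExpressionMatrix(values=values, metadata=metadata), truth
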