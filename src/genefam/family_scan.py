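"""VQ-family identification and protein physicochemical properties.

The VQ motif is a short plant-specific domain with the conserved core
``FxxxVQxLTG`` (x = any residue).  The terminal triplet varies between
lineages (LTG most common; FTG, ITG, LTA, VTG elsewhere), and in several
grasses the VQ dipeptide itself has mutated to VH.  Family members are
identified here by deterministic consensus-pattern scanning rather than a
profile HMM: every conserved position of the core is known, so an explicit
pattern is reproducible and needs no external profile database.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .core_io import DATA_DIR, SequenceSet

__all__ = [
    "VqDomainHit",
    "ProteinProperties",
    "MotifPattern",
    "DEFAULT_PATTERN",
    "scan_vq_motif",
    "scan_sequence_set",
    "classify_domain_type",
    "compute_mw",
    "net_charge",
    "compute_pi",
    "protein_properties",
]


@dataclass(frozen=True)
class VqDomainHit:
    """One matched VQ core: 1-based position of the F, the 10-mer, its type."""

    gene_id: str
    position: int
    matched: str
    domain_type: Literal["LTG", "FTG", "ITG", "OTHER"]
    vh_variant: bool
    mode: Literal["strict", "relaxed"]


@dataclass(frozen=True)
class ProteinProperties:
    length_aa: int
    mw: float
    pi: float


@dataclass(frozen=True)
class MotifPattern:
    """Residue classes for the 10 positions of the VQ core.

    ``position8`` is the variable residue before the terminal TG/TA
    (observed L/F/I in wheat plus V elsewhere); ``position10`` admits the
    G->A variant.  ``None`` entries match any residue including X.
    """

    position8: str = "LFIV"
    position10: str = "GA"

    def regex(self, mode: Literal["strict", "relaxed"]) -> re.Pattern:
        q = "Q" if mode == "strict" else "QH"
        return re.compile(
            f"F[A-Z]{{3}}V[{q}][A-Z][{self.position8}]T[{self.position10}]"
        )


DEFAULT_PATTERN = MotifPattern()


def scan_vq_motif(
    protein: str,
    mode: Literal["strict", "relaxed"] = "strict",
    gene_id: str = "",
    pattern: MotifPattern = DEFAULT_PATTERN,
) -> list[VqDomainHit]:
    """All non-overlapping left-to-right VQ-core matches in a protein.

    Strict mode requires the conserved VQ dipeptide; relaxed mode also
    accepts the VH variant seen in some grass VQ proteins.  X never matches
    a conserved position (the classes are explicit); an empty protein gives
    an empty list.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    hits = []
    for m in pattern.regex(mode).finditer(protein.upper()):
        ten = m.group(0)
        hits.append(
            VqDomainHit(
                gene_id=gene_id,
                position=m.start() + 1,
                matched=ten,
                domain_type=classify_domain_type(ten),
                vh_variant=ten[5] == "H",
                mode=mode,
            )
        )
    return hits


def scan_sequence_set(
    proteins: SequenceSet,
    mode: Literal["strict", "relaxed"] = "strict",
    pattern: MotifPattern = DEFAULT_PATTERN,
) -> list[VqDomainHit]:
    hits: list[VqDomainHit] = []
    for name, seq in proteins.items():
        hits.extend(scan_vq_motif(seq, mode=mode, gene_id=name, pattern=pattern))
    return hits


def classify_domain_type(matched: str | VqDomainHit) -> str:
    """Domain type from the terminal triplet of the matched 10-mer."""
    ten = matched.matched if isinstance(matched, VqDomainHit) else matched
    tail = ten[7:10]
    return tail if tail in ("LTG", "FTG", "ITG") else "OTHER"


# ---------------------------------------------------------------------------
# physicochemical properties
# ---------------------------------------------------------------------------

# average (not monoisotopic) residue masses, Da, as used by ExPASy-style tools
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


def compute_mw(protein: str) -> float:
    """Average-isotopic molecular weight in Da, rounded to 2 decimals."""
    if not protein:
        raise ValueError("empty protein")
    mass = WATER_MASS
    for aa in protein.upper():
        try:
            mass += _RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return round(mass, 2)


def _load_pka(path: str | Path | None = None) -> dict:
    with open(path or DATA_DIR / "pka_bjellqvist.json") as fh:
        return json.load(fh)


_PKA = _load_pka()


def net_charge(protein: str, ph: float, pka: dict | None = None) -> float:
    """Henderson–Hasselbalch net charge of a peptide at the given pH.

    Termini plus D/E/C/Y (acidic) and H/K/R (basic) side chains contribute;
    unknown residues (e.g. X) carry no charge.
    """
    table = pka or _PKA
    protein = protein.upper()

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - ph))

    nterm_pk = table["n_terminus"].get(protein[0], table["n_terminus_default"])
    charge = pos(nterm_pk) + neg(table["c_terminus"])
    for aa in protein:
        if aa in table["sidechain_acidic"]:
            charge += neg(table["sidechain_acidic"][aa])
        elif aa in table["sidechain_basic"]:
            charge += pos(table["sidechain_basic"][aa])
    return charge


def compute_pi(protein: str, pka: dict | None = None, tol: float = 1e-3) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection on [0, 14]."""
    if not protein:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 3)


def protein_properties(protein: str) -> ProteinProperties:
    clean = protein.replace("-", "").upper()
    return ProteinProperties(
        length_aa=len(clean), mw=compute_mw(clean), pi=compute_pi(clean)
    )
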