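"""Seed dormancy and germination analysis: germination statistics,
2^-ΔΔCt relative expression, heatmap preparation, and the
contrasting-variety candidate-gene classifier.

The germination index over a 3-day assay weights early germination more
heavily, GI = (3·n1 + 2·n2 + 1·n3)/(3·N), so GI = 1 when every seed
germinates on day 1 and 0 when none germinate; the germination rate is the
cumulative percentage GR = (n1+n2+n3)/N·100.  Low GI/GR marks strong
dormancy (and hence pre-harvest-sprouting resistance).

Candidate dormancy genes are called from an expression matrix over
varieties of contrasting dormancy class: a gene is "higher in low-dormancy"
when at every shared timepoint the lowest replicate-mean among low-dormancy
varieties strictly exceeds the highest among high-dormancy varieties
(symmetrically for the opposite direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GerminationRecord",
    "ExpressionMatrix",
    "CandidateCall",
    "HeatmapResult",
    "germination_index",
    "germination_rate",
    "read_germination_table",
    "ddct_relative_expression",
    "ddct_mean_se",
    "prepare_heatmap",
    "classify_candidates",
]


# ---------------------------------------------------------------------------
# germination statistics
# ---------------------------------------------------------------------------

def _check_counts(n1: int, n2: int, n3: int, N: int) -> None:
    if N <= 0:
        raise ValueError("total seed count N must be positive")
    if min(n1, n2, n3) < 0:
        raise ValueError("negative germination count")
    if n1 + n2 + n3 > N:
        raise ValueError(f"germinated {n1 + n2 + n3} exceeds total {N}")


def germination_index(n1: int, n2: int, n3: int, N: int) -> float:
    """Day-weighted germination index (3·n1 + 2·n2 + 1·n3)/(3·N) in [0, 1]."""
    _check_counts(n1, n2, n3, N)
    return (3 * n1 + 2 * n2 + 1 * n3) / (3 * N)


def germination_rate(n1: int, n2: int, n3: int, N: int) -> float:
    """Cumulative 3-day germination percentage (n1+n2+n3)/N × 100."""
    _check_counts(n1, n2, n3, N)
    return (n1 + n2 + n3) / N * 100.0


@dataclass(frozen=True)
class GerminationRecord:
    variety: str
    replicate: int
    n1: int
    n2: int
    n3: int
    N: int

    @property
    def gi(self) -> float:
        return germination_index(self.n1, self.n2, self.n3, self.N)

    @property
    def gr(self) -> float:
        return germination_rate(self.n1, self.n2, self.n3, self.N)


def read_germination_table(path: str | Path) -> list[GerminationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        GerminationRecord(
            variety=str(r["variety"]), replicate=int(r["replicate"]),
            n1=int(r["n1"]), n2=int(r["n2"]), n3=int(r["n3"]), N=int(r["N"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# qRT-PCR relative expression
# ---------------------------------------------------------------------------

def ddct_relative_expression(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """2^-ΔΔCt fold change of a target gene against a reference gene
    (e.g. TaActin) and a calibrator sample."""
    for v in (ct_target, ct_reference, ct_target_cal, ct_reference_cal):
        if v is None or not math.isfinite(v):
            raise ValueError("missing or non-finite Ct value")
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return 2.0 ** (-ddct)


def ddct_mean_se(
    ct_targets: Sequence[float],
    ct_references: Sequence[float],
    ct_target_cal: float,
    ct_reference_cal: float,
) -> tuple[float, float]:
    """Replicate 2^-ΔΔCt fold changes reduced to (mean, standard error)."""
    if len(ct_targets) != len(ct_references) or not ct_targets:
        raise ValueError("replicate Ct lists must be non-empty, equal length")
    folds = [
        ddct_relative_expression(t, r, ct_target_cal, ct_reference_cal)
        for t, r in zip(ct_targets, ct_references)
    ]
    mean = float(np.mean(folds))
    se = float(np.std(folds, ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else 0.0
    return mean, se


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """genes × samples non-negative expression values plus per-sample
    metadata (variety, timepoint, dormancy_class, replicate)."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        needed = {"variety", "timepoint", "dormancy_class", "replicate"}
        absent = needed - set(self.metadata.columns)
        if absent:
            raise ValueError(f"metadata lacks columns: {sorted(absent)}")


@dataclass(frozen=True)
class CandidateCall:
    gene_id: str
    direction: Literal[
        "higher_in_low_dormancy", "higher_in_high_dormancy", "none"
    ]


@dataclass
class HeatmapResult:
    values: pd.DataFrame          # log2(x+1), per-gene z-scored
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def prepare_heatmap(matrix: ExpressionMatrix) -> HeatmapResult:
    """log2(x+1) transform, per-gene z-score (constant rows to zero), and
    average-linkage Euclidean clustering of rows and columns.

    Rows/columns are pre-sorted by label so leaf orders are deterministic
    and ties break lexicographically.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import pdist

    df = matrix.values.sort_index(axis=0).sort_index(axis=1)
    logged = np.log2(df + 1.0)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    z = logged.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)

    def order(frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        if len(frame) < 2:
            return list(frame.index), np.empty((0, 4))
        link = linkage(pdist(frame.values), method="average")
        return [frame.index[k] for k in leaves_list(link)], link

    row_order, row_link = order(z)
    col_order, col_link = order(z.T)
    return HeatmapResult(
        values=z, row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
    )


def classify_candidates(
    matrix: ExpressionMatrix,
    rule: Literal["strict_minmax", "mean_difference"] = "strict_minmax",
) -> list[CandidateCall]:
    """Direction calls for every gene from contrasting dormancy classes.

    ``strict_minmax``: a gene is higher in the low-dormancy class when at
    *every* shared timepoint the minimum replicate-mean over low-dormancy
    varieties strictly exceeds the maximum over high-dormancy varieties
    (and symmetrically).  ``mean_difference`` relaxes this to comparing the
    class means at every shared timepoint.
    """
    meta = matrix.metadata.loc[list(matrix.values.columns)]
    classes = set(meta["dormancy_class"])
    if not {"high", "low"} <= classes:
        raise ValueError(f"need both dormancy classes, got {sorted(classes)}")
    tp_low = set(meta.loc[meta["dormancy_class"] == "low", "timepoint"])
    tp_high = set(meta.loc[meta["dormancy_class"] == "high", "timepoint"])
    shared = sorted(tp_low & tp_high)
    if not shared:
        raise ValueError("no shared timepoints between dormancy classes")

    # replicate means per (variety, timepoint)
    grouped = matrix.values.T.groupby(
        [meta["variety"], meta["timepoint"]]
    ).mean()  # rows: (variety, timepoint), columns: genes
    cls_of = meta.drop_duplicates("variety").set_index("variety")[
        "dormancy_class"
    ]

    calls: list[CandidateCall] = []
    for gene in matrix.values.index:
        col = grouped[gene]
        low_wins = high_wins = True
        for tp in shared:
            at_tp = col.xs(tp, level=1)
            low = at_tp[[v for v in at_tp.index if cls_of[v] == "low"]]
            high = at_tp[[v for v in at_tp.index if cls_of[v] == "high"]]
            if rule == "strict_minmax":
                low_wins &= low.min() > high.max()
                high_wins &= high.min() > low.max()
            else:
                low_wins &= low.mean() > high.mean()
                high_wins &= high.mean() > low.mean()
        if low_wins:
            direction = "higher_in_low_dormancy"
        elif high_wins:
            direction = "higher_in_high_dormancy"
        else:
            direction = "none"
        calls.append(CandidateCall(gene_id=gene, direction=direction))
    return calls
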