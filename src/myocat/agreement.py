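"""Rater-vs-gold-standard agreement on the four surgical categories.

Agreement between a comparator (the automated model or a doctor) and the
gold standard is summarised by the 4x4 confusion matrix (rows = gold
standard, columns = comparator, categories ordered 0,1,2,3), the percent
consistency (share of eyes on the diagonal), and unweighted Cohen's kappa

    kappa = (po - pe) / (1 - pe),

where po is the observed agreement fraction and pe the chance agreement
from the marginal products.  Because kappa depends on the table only
through its marginals and its trace, it can be reconstructed exactly from
published per-category counts plus the agreement count, without the raw
per-eye pairings — :func:`kappa_from_marginals` does exactly that.

Special cases are eyes whose gold-standard decision is "no surgery",
"retinal surgery" or "combined surgery" (categories 0, 2, 3) — the
non-routine calls where rater skill differs most.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .engine import DecisionCategory, EyeRecord

__all__ = [
    "ConfusionMatrix",
    "AgreementResult",
    "build_confusion",
    "cohen_kappa",
    "kappa_from_marginals",
    "consistency",
    "Consistency",
    "special_case_subset",
    "heatmap_export",
    "round_half_up",
]

K_CATEGORIES = 4

SPECIAL_CATEGORIES = frozenset(
    {
        DecisionCategory.NO_SURGERY,
        DecisionCategory.RETINAL_SURGERY,
        DecisionCategory.COMBINED_SURGERY,
    }
)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (0.8115 -> 0.812), matching clinical reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K cross-tabulation; rows = gold standard, columns = comparator."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"confusion matrix must be square, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def agree_count(self) -> int:
        return int(np.trace(self.counts))

    @property
    def gold_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def comparator_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class AgreementResult:
    """Observed/chance agreement and Cohen's kappa for one rater pairing.

    ``kappa`` is the raw value; ``kappa_reported`` rounds half-up to three
    decimals for presentation.  ``kappa`` is None when both raters are
    constant on the same category (pe = 1, agreement is vacuous).
    """

    po: float
    pe: float
    kappa: float | None
    agree_count: int
    n: int

    @property
    def consistency_pct(self) -> float:
        return 100.0 * self.po

    @property
    def kappa_reported(self) -> float | None:
        return None if self.kappa is None else round_half_up(self.kappa, 3)


def build_confusion(
    gold: Sequence[DecisionCategory | int],
    comparator: Sequence[DecisionCategory | int],
    k: int = K_CATEGORIES,
) -> ConfusionMatrix:
    """Tally paired decisions into a K x K matrix (rows = gold)."""
    g = np.asarray(gold, dtype=int)
    c = np.asarray(comparator, dtype=int)
    if g.shape != c.shape or g.ndim != 1:
        raise ValueError("gold and comparator decision lists must be equal-length 1-D")
    if g.size == 0:
        raise ValueError("cannot build a confusion matrix from no decisions")
    if ((g < 0) | (g >= k) | (c < 0) | (c >= k)).any():
        raise ValueError(f"decision categories must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (g, c), 1)
    return ConfusionMatrix(counts=counts)


def _agreement(gold_marg: np.ndarray, comp_marg: np.ndarray, agree: int, n: int) -> AgreementResult:
    po = agree / n
    pe = float((gold_marg * comp_marg).sum()) / n**2
    kappa = None if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return AgreementResult(po=po, pe=pe, kappa=kappa, agree_count=int(agree), n=int(n))


def cohen_kappa(matrix: ConfusionMatrix) -> AgreementResult:
    """Unweighted Cohen's kappa from a full confusion matrix."""
    if matrix.n == 0:
        raise ValueError("kappa undefined for an empty confusion matrix")
    return _agreement(
        matrix.gold_marginals, matrix.comparator_marginals, matrix.agree_count, matrix.n
    )


def kappa_from_marginals(
    gold_marginals: Sequence[int],
    comparator_marginals: Sequence[int],
    agree_count: int,
    n: int,
) -> AgreementResult:
    """Cohen's kappa reconstructed from marginal counts and the agreement count.

    Kappa is a function of the confusion matrix only through its row sums,
    column sums and trace, so published per-category counts plus a
    consistency numerator reconstruct it exactly.
    """
    g = np.asarray(gold_marginals, dtype=float)
    c = np.asarray(comparator_marginals, dtype=float)
    if g.shape != c.shape or g.ndim != 1:
        raise ValueError("marginal vectors must be equal-length 1-D")
    if not (g.sum() == n and c.sum() == n):
        raise ValueError(
            f"marginals must each sum to n={n}, got {g.sum():.0f} and {c.sum():.0f}"
        )
    if not (0 <= agree_count <= n):
        raise ValueError(f"agree_count {agree_count} outside [0, {n}]")
    return _agreement(g, c, agree_count, n)


@dataclass(frozen=True)
class Consistency:
    """Percent agreement with its numerator/denominator kept explicit."""

    agree_count: int
    n: int

    @property
    def pct(self) -> float:
        return 100.0 * self.agree_count / self.n

    def __str__(self) -> str:  # e.g. "96.26% (103/107)"
        return f"{self.pct:.2f}% ({self.agree_count}/{self.n})"


def consistency(
    dec_a: Sequence[DecisionCategory | int], dec_b: Sequence[DecisionCategory | int]
) -> Consistency:
    """Percentage of eyes on which two decision lists agree."""
    a = np.asarray(dec_a, dtype=int)
    b = np.asarray(dec_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("decision lists must be equal-length 1-D")
    if a.size == 0:
        raise ValueError("consistency undefined for empty decision lists")
    return Consistency(agree_count=int((a == b).sum()), n=int(a.size))


def special_case_subset(
    records: Iterable[EyeRecord], gold_rater: str = "gold"
) -> list[EyeRecord]:
    """Eyes whose gold-standard decision is 0, 2 or 3 (non-routine calls).

    Downstream consistency/kappa on this subset still uses the full
    four-category table; the comparator may answer category 1.
    """
    out = []
    for rec in records:
        if gold_rater not in rec.decisions:
            raise ValueError(f"eye {rec.eye_id}: missing decision from {gold_rater!r}")
        if DecisionCategory(rec.decisions[gold_rater]) in SPECIAL_CATEGORIES:
            out.append(rec)
    return out


def heatmap_export(
    matrix: ConfusionMatrix,
    path: str | Path,
    title: str | None = None,
    gold_label: str = "gold standard",
    comparator_label: str = "comparator",
) -> tuple[Path, Path]:
    """Write an annotated count heatmap (PNG/SVG) plus the counts as CSV.

    Returns ``(image_path, csv_path)``.  The CSV round-trips: reading it
    back with ``numpy.loadtxt`` (skipping the header row/column) recovers
    the matrix exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    k = matrix.counts.shape[0]
    cats = list(range(k))

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(matrix.counts, cmap="Blues")
    for i in range(k):
        for j in range(k):
            v = matrix.counts[i, j]
            ax.text(
                j, i, str(v), ha="center", va="center",
                color="white" if v > matrix.counts.max() / 2 else "black",
            )
    ax.set_xticks(cats)
    ax.set_yticks(cats)
    ax.set_xlabel(comparator_label)
    ax.set_ylabel(gold_label)
    ax.set_title(title or f"decision agreement (n={matrix.n})")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gold\\comparator"] + [str(c) for c in cats])
        for i in cats:
            w.writerow([str(i)] + [str(int(v)) for v in matrix.counts[i]])
    return path, csv_path


def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Read back a confusion-matrix CSV written by :func:`heatmap_export`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    counts = np.array([[int(v) for v in row[1:]] for row in rows[1:]], dtype=int)
    return ConfusionMatrix(counts=counts)
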