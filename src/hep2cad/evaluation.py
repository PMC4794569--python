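"""Reader-agreement and classifier-performance statistics.

The metric vocabulary is the standard one for multi-class reader studies:

* per-class correct classification rate ``CCR_k = T_k / N_k`` — the
  diagonal count for class k over its reference-row total;
* Accuracy — the class-size-weighted mean of the CCRs, identically equal
  to trace/N of the confusion matrix;
* Mean Class Accuracy (MAC) — the unweighted mean of the CCRs over the
  classes actually present (classes with no reference examples are
  excluded and reported);
* Cohen's kappa for chance-corrected two-reader agreement;
* Pearson's chi-square for independence of two labelings; and
* McNemar's test (exact binomial or continuity-corrected chi-square) for
  paired proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "ccr",
    "accuracy",
    "mean_class_accuracy",
    "cohens_kappa",
    "mcnemar_test",
    "chi_square_independence",
    "AgreementReport",
    "agreement_report",
    "reader_with_cad",
    "CAD_POLICIES",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """A labeled square count matrix: rows = reference, columns = prediction.

    For a two-reader agreement table the rows are reader A and the
    columns reader B; the statistics are the same.
    """

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def index_of(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(
    ref_labels: Sequence[str],
    pred_labels: Sequence[str],
    classes: Sequence[str],
) -> ConfusionMatrix:
    """Tally paired labels into a ConfusionMatrix over ``classes``."""
    if len(ref_labels) != len(pred_labels):
        raise ValueError("label lists must have equal length")
    classes = tuple(str(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for ref, pred in zip(ref_labels, pred_labels):
        ref, pred = str(ref), str(pred)
        if ref not in index:
            raise ValueError(f"unknown reference label {ref!r}")
        if pred not in index:
            raise ValueError(f"unknown predicted label {pred!r}")
        counts[index[ref], index[pred]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def ccr(cm: ConfusionMatrix, class_k: str) -> float:
    """Correct classification rate of one class: T_k / N_k."""
    i = cm.index_of(str(class_k))
    n_k = int(cm.row_totals()[i])
    if n_k == 0:
        raise ValueError(f"CCR undefined for class {class_k!r}: no reference examples")
    return float(cm.counts[i, i]) / n_k


def accuracy(cm: ConfusionMatrix) -> float:
    """Class-size-weighted mean of CCRs; algebraically trace/N."""
    if cm.n == 0:
        raise ValueError("accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts)) / cm.n


def mean_class_accuracy(
    cm_or_rates: ConfusionMatrix | Sequence[float],
) -> float:
    """Unweighted mean of per-class rates (MAC).

    Accepts either a confusion matrix (classes with zero reference
    examples are excluded) or a sequence of per-class rates directly.
    """
    if isinstance(cm_or_rates, ConfusionMatrix):
        cm = cm_or_rates
        totals = cm.row_totals()
        rates = [
            ccr(cm, cm.classes[i]) for i in range(len(cm.classes)) if totals[i] > 0
        ]
    else:
        rates = [float(r) for r in cm_or_rates]
    if not rates:
        raise ValueError("MAC undefined: no class with reference examples")
    return float(np.mean(rates))


def excluded_classes(cm: ConfusionMatrix) -> list[str]:
    """Classes excluded from MAC because they have no reference examples."""
    totals = cm.row_totals()
    return [c for c, t in zip(cm.classes, totals) if t == 0]


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    if cm.n == 0:
        raise ValueError("kappa undefined for an empty matrix")
    n = cm.n
    p_o = float(np.trace(cm.counts)) / n
    p_e = float((cm.row_totals() * cm.col_totals()).sum()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float | None
    p_value: float
    mode: str


def mcnemar_test(
    n_discordant_ab: int, n_discordant_ba: int, mode: str = "auto"
) -> McNemarResult:
    """McNemar's test for paired proportions from the two discordant counts.

    ``exact`` uses the two-sided binomial(b, b+c, 1/2) tail; ``corrected``
    the continuity-corrected chi-square (|b-c|-1)^2/(b+c). ``auto`` picks
    exact when b+c < 25. Zero discordance yields p = 1 by convention.
    """
    b, c = int(n_discordant_ab), int(n_discordant_ba)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(statistic=None, p_value=1.0, mode="degenerate")
    if mode == "auto":
        mode = "exact" if n < 25 else "corrected"
    if mode == "exact":
        p = float(stats.binomtest(b, n, 0.5, alternative="two-sided").pvalue)
        return McNemarResult(statistic=None, p_value=min(p, 1.0), mode="exact")
    if mode == "corrected":
        statistic = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        return McNemarResult(statistic=statistic, p_value=p, mode="corrected")
    raise ValueError(f"unknown McNemar mode {mode!r}")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    dropped_rows: tuple[str, ...]
    dropped_cols: tuple[str, ...]


def chi_square_independence(cm: ConfusionMatrix) -> ChiSquareResult:
    """Pearson chi-square for independence of the two labelings.

    Rows/columns with zero totals are dropped first (and reported).
    """
    if cm.n == 0:
        raise ValueError("chi-square undefined for an empty matrix")
    row_keep = cm.row_totals() > 0
    col_keep = cm.col_totals() > 0
    dropped_rows = tuple(c for c, k in zip(cm.classes, row_keep) if not k)
    dropped_cols = tuple(c for c, k in zip(cm.classes, col_keep) if not k)
    table = cm.counts[np.ix_(row_keep, col_keep)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi-square requires at least 2 non-empty rows and columns")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


@dataclass
class AgreementReport:
    """Two-reader agreement summary around one confusion matrix."""

    confusion: ConfusionMatrix
    observed_agreement: float
    kappa: float
    per_class_ccr_rows: dict[str, float]
    per_class_ccr_cols: dict[str, float]
    chi_square: ChiSquareResult
    n: int

    def to_text(self) -> str:
        """Render a concordance table in the conventional layout."""
        frame = self.confusion.to_frame()
        frame["TOT"] = self.confusion.row_totals()
        totals = list(self.confusion.col_totals()) + [self.n]
        frame.loc["TOT"] = totals
        lines = [frame.to_string()]
        lines.append("")
        lines.append(f"N = {self.n}")
        lines.append(f"observed agreement = {100 * self.observed_agreement:.1f}%")
        lines.append(f"Cohen's kappa = {self.kappa:.2f}")
        lines.append(
            f"chi-square = {self.chi_square.statistic:.1f} "
            f"(df={self.chi_square.df}, p={self.chi_square.p_value:.3g})"
        )
        return "\n".join(lines)


def agreement_report(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    classes: Sequence[str],
) -> AgreementReport:
    """Full agreement analysis of two paired label lists."""
    cm = confusion_matrix(labels_a, labels_b, classes)
    obs = accuracy(cm)
    kappa = cohens_kappa(cm)
    rows = {c: ccr(cm, c) for i, c in enumerate(cm.classes) if cm.row_totals()[i] > 0}
    # CCR in the other direction: treat columns as the reference axis
    cm_t = ConfusionMatrix(classes=cm.classes, counts=cm.counts.T)
    cols = {c: ccr(cm_t, c) for i, c in enumerate(cm.classes) if cm.col_totals()[i] > 0}
    chi = chi_square_independence(cm)
    return AgreementReport(
        confusion=cm,
        observed_agreement=obs,
        kappa=kappa,
        per_class_ccr_rows=rows,
        per_class_ccr_cols=cols,
        chi_square=chi,
        n=cm.n,
    )


# ---------------------------------------------------------------------------
# second-reader (reader + CAD) combination


def _policy_never(reader: str, cad: str, confidence: float, threshold: float) -> str:
    return reader


def _policy_always(reader: str, cad: str, confidence: float, threshold: float) -> str:
    return cad


def _policy_confidence(reader: str, cad: str, confidence: float, threshold: float) -> str:
    if cad != reader and confidence >= threshold:
        return cad
    return reader


CAD_POLICIES: dict[str, Callable[[str, str, float, float], str]] = {
    "never": _policy_never,
    "always": _policy_always,
    "confidence": _policy_confidence,
}


@dataclass
class ReaderWithCadResult:
    assisted_labels: list[str]
    before: dict[str, float]
    after: dict[str, float]


def reader_with_cad(
    reader_labels: Sequence[str],
    cad_labels: Sequence[str],
    gold_labels: Sequence[str],
    policy: str = "confidence",
    cad_confidences: Sequence[float] | None = None,
    confidence_threshold: float = 0.5,
    classes: Sequence[str] | None = None,
) -> ReaderWithCadResult:
    """Simulate a reader using the CAD as a second reader.

    Applies the configured combination policy per case and recomputes
    Accuracy, MAC and kappa against the gold labels before and after.
    """
    if not (len(reader_labels) == len(cad_labels) == len(gold_labels)):
        raise ValueError("reader, CAD and gold label lists must have equal length")
    if policy not in CAD_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {sorted(CAD_POLICIES)}")
    if cad_confidences is None:
        cad_confidences = [1.0] * len(cad_labels)
    if classes is None:
        classes = sorted(set(map(str, reader_labels)) | set(map(str, cad_labels)) | set(map(str, gold_labels)))
    fn = CAD_POLICIES[policy]
    assisted = [
        fn(str(r), str(c), float(conf), confidence_threshold)
        for r, c, conf in zip(reader_labels, cad_labels, cad_confidences)
    ]

    def metrics(pred: Sequence[str]) -> dict[str, float]:
        cm = confusion_matrix(gold_labels, pred, classes)
        return {
            "accuracy": accuracy(cm),
            "mac": mean_class_accuracy(cm),
            "kappa": cohens_kappa(cm),
        }

    return ReaderWithCadResult(
        assisted_labels=assisted,
        before=metrics(list(map(str, reader_labels))),
        after=metrics(assisted),
    )
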