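"""Agreement statistics between two artifact label vectors.

The reference vector is the live annotation; the test vector is the
retrospective annotation or a model's predictions. Statistics follow the
usual diagnostic-test conventions: sensitivity = TP/(TP+FN), specificity
= TN/(TN+FP), PPV = TP/(TP+FP), plus Cohen's kappa, which corrects raw
agreement for chance and is the meaningful summary when artifacts are
rare (a trivial all-clean rater already achieves ~98% raw agreement at a
2% incidence).

Internal values are never rounded; ``round_half_up`` is the display rule
(2 decimals for proportions, 1 decimal for percentages).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding: .005 always rounds away from zero."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: rows = test (retrospective/model), columns = reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.n == 0:
            raise ValueError("contingency table must have n > 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of reference and test rater."""
        return ContingencyTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


@dataclass(frozen=True)
class AgreementStats:
    """Diagnostic statistics; None where a denominator was zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    kappa: float
    incidence_ref: float
    incidence_test: float

    def rounded(self) -> dict[str, float | None]:
        out = {}
        for k in ("sensitivity", "specificity", "ppv", "kappa"):
            v = getattr(self, k)
            out[k] = None if v is None else round_half_up(v, 2)
        for k in ("incidence_ref", "incidence_test"):
            out[k + "_pct"] = round_half_up(100.0 * getattr(self, k), 1)
        return out


def contingency(ref, test) -> ContingencyTable:
    """Tabulate two boolean vectors; ``ref`` is the positive-truth axis.

    Pairs where either label is missing (NaN) are excluded pairwise.
    """
    ref = np.asarray(ref)
    test = np.asarray(test)
    if ref.shape != test.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {test.shape}")
    if ref.dtype != bool or test.dtype != bool:
        reff = ref.astype(float)
        testf = test.astype(float)
        keep = ~(np.isnan(reff) | np.isnan(testf))
        ref = reff[keep] > 0
        test = testf[keep] > 0
    return ContingencyTable(
        tp=int(np.sum(test & ref)),
        fp=int(np.sum(test & ~ref)),
        fn=int(np.sum(~test & ref)),
        tn=int(np.sum(~test & ~ref)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostics(t: ContingencyTable) -> AgreementStats:
    """Sensitivity, specificity, PPV, kappa and both incidences."""
    return AgreementStats(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        kappa=cohen_kappa(t),
        incidence_ref=(t.tp + t.fn) / t.n,
        incidence_test=(t.tp + t.fp) / t.n,
    )


def cohen_kappa(t: ContingencyTable) -> float:
    """Chance-corrected agreement (p_o − p_e) / (1 − p_e).

    p_o is raw agreement; p_e the agreement expected if both raters
    labelled independently with their observed marginal rates. A
    degenerate table with p_e = 1 (both raters single-class) returns 0.
    """
    n = t.n
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def incidence(labels) -> float:
    """Fraction of positive labels (display as a percentage at 1 decimal)."""
    labels = np.asarray(labels, dtype=float)
    labels = labels[~np.isnan(labels)]
    if labels.size == 0:
        raise ValueError("incidence of an empty label vector is undefined")
    return float(np.mean(labels > 0))
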