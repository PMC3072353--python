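"""The two-gene ratio score and its one-dimensional discriminant.

The classifying feature is the dimensionless score

    x = log10(CCND1 expression / CDKN2A expression).

High CCND1 relative to CDKN2A indicates functional RB1 (cyclin D1 drives
RB1 phosphorylation in RB1-competent cells, while CDKN2A accumulates by
feedback when RB1 is lost), so the positive class sits at higher x and
that orientation is enforced, never inferred.

Two measurement paths produce the same x:

* microarray — both genes are measured as log10 ratios versus a common
  reference RNA, so ``x = log10r_CCND1 - log10r_CDKN2A`` (the reference
  cancels);
* qPCR — with amplification efficiency E per cycle, expression is
  proportional to ``E ** -Ct``, so
  ``x = (mean Ct_CDKN2A - mean Ct_CCND1) * log10(E)`` over the replicate
  wells. No housekeeping gene enters: the two-target ratio cancels the
  loading term.

Classification is a threshold on x. A model trained here is a 1-D Fisher
discriminant with equal priors and pooled variance, whose decision point
is the midpoint of the class means. A published reference model with the
fixed cutoff x0 = 0.404 is packaged for use without training data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateStatisticsError,
    DomainError,
    InsufficientDataError,
    OrientationError,
    ValidationError,
)
from .io import CtTable, ExpressionMatrix, PhenotypeLabels

__all__ = [
    "RatioScore",
    "DiscriminantModel",
    "Prediction",
    "ratio_from_log_expression",
    "ratio_from_ct",
    "scores_from_expression",
    "scores_from_ct_table",
    "train_discriminant",
    "published_model",
    "classify",
    "save_model",
    "load_model",
    "read_scores",
    "write_scores",
]

#: coefficients of the published discriminant Y = a*x + b and its operative
#: decision cutoff on the x scale. The printed coefficient pair does not
#: zero-cross at 0.404; the cutoff is the constant actually used to call
#: samples, so it is stored as authoritative and the coefficients ride
#: along as metadata.
PUBLISHED_SLOPE = 0.54
PUBLISHED_INTERCEPT = -2.051094
PUBLISHED_THRESHOLD = 0.404


@dataclass(frozen=True)
class RatioScore:
    sample_id: str
    x: float  # log10(CCND1/CDKN2A)
    platform: str = "microarray"  # or "qpcr"

    def __post_init__(self) -> None:
        if not math.isfinite(self.x):
            raise ValidationError(f"ratio score for {self.sample_id!r} is not finite")
        if self.platform not in ("microarray", "qpcr"):
            raise ValidationError(f"unknown platform {self.platform!r}")


@dataclass(frozen=True)
class DiscriminantModel:
    """Threshold classifier Y = slope * x + intercept, decided at x >= threshold.

    For trained models the threshold is the zero-crossing -intercept/slope;
    preset models may carry an independently fixed threshold with the
    coefficients as metadata only.
    """

    slope: float
    intercept: float
    threshold: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValidationError(f"slope must be > 0, got {self.slope}")
        if not math.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")
        if self.provenance.get("source") == "trained":
            x0 = -self.intercept / self.slope
            if abs(x0 - self.threshold) > 1e-9:
                raise ValidationError(
                    f"trained model threshold {self.threshold} is not the "
                    f"zero-crossing {-self.intercept / self.slope}"
                )

    def decision_value(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    x: float
    call: str  # "positive" | "negative"
    margin: float  # x - threshold

    def __post_init__(self) -> None:
        expected = "positive" if self.margin >= 0 else "negative"
        if self.call != expected:
            raise ValidationError("call and margin disagree")


def ratio_from_log_expression(ccnd1_log10: float, cdkn2a_log10: float) -> float:
    """x from two log10 ratios against the same common reference."""
    if not (math.isfinite(ccnd1_log10) and math.isfinite(cdkn2a_log10)):
        raise DomainError("log10 expression values must be finite")
    return float(ccnd1_log10 - cdkn2a_log10)


def ratio_from_ct(
    ct_ccnd1: Sequence[float],
    ct_cdkn2a: Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """x from replicate Ct values of the two genes.

    ``x = (mean(Ct_CDKN2A) - mean(Ct_CCND1)) * log10(efficiency)``; the
    default efficiency of 2 assumes perfect doubling per cycle.
    """
    a = np.asarray(ct_ccnd1, dtype=float)
    b = np.asarray(ct_cdkn2a, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("need at least one replicate per gene")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("Ct values must be finite")
    if np.any(a <= 0) or np.any(a >= 50) or np.any(b <= 0) or np.any(b >= 50):
        raise DomainError("Ct values must lie in (0, 50) cycles")
    if not (efficiency > 1):
        raise DomainError(f"amplification efficiency must exceed 1, got {efficiency}")
    return float((b.mean() - a.mean()) * math.log10(efficiency))


def scores_from_expression(
    matrix: ExpressionMatrix,
    ccnd1_symbol: str = "CCND1",
    cdkn2a_symbol: str = "CDKN2A",
) -> list[RatioScore]:
    """Per-sample scores from a log10-ratio expression matrix."""
    c1 = matrix.gene_values(ccnd1_symbol)
    c2 = matrix.gene_values(cdkn2a_symbol)
    return [
        RatioScore(s, ratio_from_log_expression(a, b), "microarray")
        for s, a, b in zip(matrix.sample_ids, c1, c2)
    ]


def scores_from_ct_table(
    table: CtTable,
    ccnd1_symbol: str = "CCND1",
    cdkn2a_symbol: str = "CDKN2A",
    efficiency: float = 2.0,
) -> list[RatioScore]:
    """Per-sample scores from a replicate Ct table."""
    scores = []
    for sid in table.sample_ids:
        a = table.replicates(sid, ccnd1_symbol)
        b = table.replicates(sid, cdkn2a_symbol)
        if a.size == 0 or b.size == 0:
            missing = ccnd1_symbol if a.size == 0 else cdkn2a_symbol
            raise ValidationError(f"sample {sid!r} has no Ct wells for {missing!r}")
        scores.append(RatioScore(sid, ratio_from_ct(a, b, efficiency), "qpcr"))
    return scores


def train_discriminant(
    scores: Iterable[RatioScore], labels: PhenotypeLabels
) -> DiscriminantModel:
    """Fit the 1-D Fisher discriminant (equal priors, pooled variance).

    The decision point is the midpoint of the class means on x; the slope
    is 1/pooled_sd so the decision value Y is a z-like margin. The positive
    class must have the higher mean — an inverted panel raises
    :class:`OrientationError` rather than silently flipping the rule.
    """
    scores = list(scores)
    x = np.array([s.x for s in scores])
    y = np.array([labels[s.sample_id] for s in scores])
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticsError("training needs both classes present")
    if n_pos < 2 or n_neg < 2:
        raise InsufficientDataError("training needs at least 2 samples per class")
    xp, xn = x[y == 1], x[y == 0]
    mean_pos, mean_neg = float(xp.mean()), float(xn.mean())
    pooled_var = (
        (n_pos - 1) * float(np.var(xp, ddof=1)) + (n_neg - 1) * float(np.var(xn, ddof=1))
    ) / (n_pos + n_neg - 2)
    if pooled_var <= 0:
        raise DegenerateStatisticsError("pooled within-class variance is zero")
    if mean_pos <= mean_neg:
        raise OrientationError(
            f"positive-class mean ({mean_pos:.4g}) must exceed negative-class "
            f"mean ({mean_neg:.4g}); high CCND1/CDKN2A marks RB1-positive"
        )
    x0 = (mean_pos + mean_neg) / 2.0
    a = 1.0 / math.sqrt(pooled_var)
    b = -a * x0
    model = DiscriminantModel(
        slope=a,
        intercept=b,
        threshold=x0,
        provenance={
            "source": "trained",
            "n_pos": n_pos,
            "n_neg": n_neg,
            "mean_pos": mean_pos,
            "mean_neg": mean_neg,
            "pooled_sd": math.sqrt(pooled_var),
        },
    )
    preds = classify(scores, model)
    correct = sum(
        1 for p in preds if (p.call == "positive") == (labels[p.sample_id] == 1)
    )
    prov = dict(model.provenance)
    prov["training_accuracy"] = correct / len(preds)
    return DiscriminantModel(model.slope, model.intercept, model.threshold, prov)


def published_model() -> DiscriminantModel:
    """The published reference discriminant for this assay.

    Threshold 0.404 on x = log10(CCND1/CDKN2A); the published coefficient
    pair (0.54, -2.051094) is retained as metadata.
    """
    return DiscriminantModel(
        slope=PUBLISHED_SLOPE,
        intercept=PUBLISHED_INTERCEPT,
        threshold=PUBLISHED_THRESHOLD,
        provenance={"source": "published-preset"},
    )


def classify(scores: Iterable[RatioScore], model: DiscriminantModel) -> list[Prediction]:
    """Threshold each score: x >= threshold calls positive (boundary convention)."""
    preds = []
    for s in scores:
        margin = s.x - model.threshold
        call = "positive" if margin >= 0 else "negative"
        preds.append(Prediction(s.sample_id, s.x, call, margin))
    return preds


# ---------------------------------------------------------------------------
# persistence

def save_model(model: DiscriminantModel, path: str | Path) -> None:
    payload = {
        "slope": model.slope,
        "intercept": model.intercept,
        "threshold": model.threshold,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> DiscriminantModel:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid model JSON: {exc}") from None
    missing = {"slope", "intercept", "threshold"} - set(payload)
    if missing:
        raise ValidationError(f"{path}: model JSON missing {sorted(missing)}")
    prov = payload.get("provenance", {})
    if isinstance(prov, str):
        prov = {"source": prov}
    return DiscriminantModel(
        slope=float(payload["slope"]),
        intercept=float(payload["intercept"]),
        threshold=float(payload["threshold"]),
        provenance=prov,
    )


def write_scores(scores: Iterable[RatioScore], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tx\tplatform\n")
        for s in scores:
            fh.write(f"{s.sample_id}\t{s.x!r}\t{s.platform}\n")


def read_scores(path: str | Path) -> list[RatioScore]:
    scores = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "x"]:
            raise ValidationError(f"{path}: expected header sample_id<TAB>x[<TAB>platform]")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected at least 2 fields")
            platform = fields[2] if len(fields) > 2 else "microarray"
            try:
                x = float(fields[1])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: x {fields[1]!r} is not numeric") from None
            scores.append(RatioScore(fields[0], x, platform))
    return scores
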