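"""Active/decoy validation bookkeeping and the eight-metric suite.

A screen of a labelled test set yields a 2x2 confusion matrix per target
kinase; matrices are summed across targets (never averaged as metrics) and
scored with:

    Se  = TP / (TP + FN)                sensitivity (recall)
    Sp  = TN / (TN + FP)                specificity
    Ya  = TP / (TP + FP)                yield of actives (precision)
    E   = Ya * N / A                    enrichment over random picking
    Acc = (TP + TN) / N                 accuracy
    DR  = Se / Sp                       discrimination ratio
    F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with A = TP + FN actives, D = TN + FP decoys, N = A + D. All ratios are
computed in exact rational arithmetic before any rounding; reported values
use half-up rounding at the conventional precisions (3 decimals, except F1
and MCC at 4). Metrics whose denominator vanishes are flagged undefined,
never silently zeroed.

``back_solve_counts`` inverts rounded (Se, Ya) back to the integer confusion
matrix by exhaustive search — the tool used to cross-validate every row of a
printed metrics table against an integer-consistent confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import LabelError, MetricsError, NoConsistentCountsError

__all__ = [
    "Label",
    "TestSetLabel",
    "ConfusionCounts",
    "MetricsReport",
    "compile_test_set",
    "confusion_from_screen",
    "aggregate_counts",
    "compute_metrics",
    "rank_models",
    "back_solve_counts",
    "consistent_counts_for_row",
    "load_reference_table",
    "load_test_set_composition",
    "METRIC_DECIMALS",
]

#: Printed precision per metric (half-up rounding).
METRIC_DECIMALS = {
    "se": 3,
    "sp": 3,
    "ya": 3,
    "e": 3,
    "acc": 3,
    "dr": 3,
    "f1": 4,
    "mcc": 4,
}


class Label(str, Enum):
    ACTIVE = "ACTIVE"
    DECOY = "DECOY"


@dataclass(frozen=True)
class TestSetLabel:
    __test__ = False  # not a pytest class, despite the name

    compound_id: str
    target: str
    label: Label


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with the derived totals A (actives), D (decoys), N."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise MetricsError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def actives(self) -> int:
        return self.tp + self.fn

    @property
    def decoys(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.actives + self.decoys

    @property
    def hits(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """The eight metrics for one model; ``None`` marks an undefined entry."""

    se: float | None
    sp: float | None
    ya: float | None
    e: float | None
    acc: float | None
    dr: float | None
    f1: float | None
    mcc: float | None

    @property
    def undefined(self) -> frozenset[str]:
        return frozenset(k for k in METRIC_DECIMALS if getattr(self, k) is None)

    def rounded(self) -> dict[str, float | None]:
        """Report-precision values (half-up; 3 decimals, F1/MCC 4)."""
        out = {}
        for k, nd in METRIC_DECIMALS.items():
            v = getattr(self, k)
            out[k] = None if v is None else round_half_up(v, nd)
        return out


def round_half_up(x: float | Fraction, ndigits: int) -> float:
    """Decimal half-up rounding (0.5 rounds away from zero at the last digit)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Test-set handling
# ---------------------------------------------------------------------------


def compile_test_set(path) -> tuple[list[TestSetLabel], pd.DataFrame]:
    """Read a labels CSV (compound_id, target, label) and summarise per target.

    Returns the label list and a per-target summary frame with columns
    ``actives`` and ``decoys`` (indexed by target).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise LabelError(f"{path}: empty labels file") from exc
    required = {"compound_id", "target", "label"}
    if not required <= set(df.columns):
        raise LabelError(f"{path}: labels CSV needs columns {sorted(required)}")
    if df.empty:
        raise LabelError(f"{path}: labels CSV has no rows")
    dupes = df.duplicated(subset=["compound_id", "target"])
    if dupes.any():
        bad = df.loc[dupes, ["compound_id", "target"]].head(5).to_records(index=False)
        raise LabelError(f"{path}: duplicate (compound_id, target) rows, e.g. {list(bad)}")
    labels = []
    for row in df.itertuples(index=False):
        try:
            lab = Label(row.label.strip().upper())
        except (ValueError, AttributeError):
            raise LabelError(f"{path}: unknown label value {row.label!r}") from None
        labels.append(TestSetLabel(str(row.compound_id), str(row.target), lab))
    summary = (
        pd.DataFrame(
            {
                "target": [l.target for l in labels],
                "is_active": [l.label == Label.ACTIVE for l in labels],
            }
        )
        .groupby("target", sort=True)["is_active"]
        .agg(actives="sum", decoys=lambda s: int((~s).sum()))
    )
    summary["actives"] = summary["actives"].astype(int)
    return labels, summary


def confusion_from_screen(report, labels: Sequence[TestSetLabel]) -> ConfusionCounts:
    """Confusion counts of a screen against one target's label set.

    Every labelled compound must have been screened; a compound absent from
    the hit list but present in the screen's universe is a non-hit.
    """
    missing = sorted({l.compound_id for l in labels} - set(report.results))
    if missing:
        raise LabelError(
            f"labelled compounds never screened: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    tp = fp = tn = fn = 0
    for lab in labels:
        hit = report.results[lab.compound_id].hit
        if lab.label == Label.ACTIVE:
            tp, fn = (tp + 1, fn) if hit else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if hit else (fp, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def aggregate_counts(per_target: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Field-wise integer sum of per-target confusion matrices."""
    if not per_target:
        raise MetricsError("aggregate_counts needs a non-empty list")
    return ConfusionCounts(
        tp=sum(c.tp for c in per_target),
        fp=sum(c.fp for c in per_target),
        tn=sum(c.tn for c in per_target),
        fn=sum(c.fn for c in per_target),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Exact-arithmetic metric suite for one confusion matrix."""
    A, D, N = c.actives, c.decoys, c.total
    if A < 1 or D < 1:
        raise MetricsError(f"need at least one active and one decoy (A={A}, D={D})")
    se = Fraction(c.tp, A)
    sp = Fraction(c.tn, D)
    acc = Fraction(c.tp + c.tn, N)
    hits = c.tp + c.fp
    ya = Fraction(c.tp, hits) if hits > 0 else None
    e = ya * Fraction(N, A) if ya is not None else None
    dr = se / sp if sp > 0 else None
    # F1 is the harmonic mean of Se and Ya: undefined whenever Ya is
    f1 = Fraction(2 * c.tp, 2 * c.tp + c.fp + c.fn) if ya is not None else None
    mcc_prod = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_prod) if mcc_prod > 0 else None
    )
    as_float = lambda v: None if v is None else float(v)
    return MetricsReport(
        se=as_float(se),
        sp=as_float(sp),
        ya=as_float(ya),
        e=as_float(e),
        acc=as_float(acc),
        dr=as_float(dr),
        f1=as_float(f1),
        mcc=mcc,
    )


def rank_models(
    rows: Iterable[tuple[str, MetricsReport]], key: str = "mcc"
) -> list[tuple[str, MetricsReport]]:
    """Sort models descending by ``key`` (ties alphabetical by name)."""
    rows = list(rows)
    if key not in METRIC_DECIMALS:
        raise MetricsError(f"unknown metric {key!r}")
    for name, rep in rows:
        if getattr(rep, key) is None:
            raise MetricsError(f"metric {key!r} undefined for model {name!r}")
    return sorted(rows, key=lambda nr: (-getattr(nr[1], key), nr[0]))


# ---------------------------------------------------------------------------
# Back-solving integer counts from rounded metrics
# ---------------------------------------------------------------------------


def _rounds_to(fr: Fraction, printed: float, ndigits: int) -> bool:
    return round_half_up(fr, ndigits) == round(printed, ndigits)


def back_solve_counts(
    se_printed: float,
    ya_printed: float,
    actives: int,
    decoys: int,
    se_decimals: int = 3,
    ya_decimals: int = 3,
) -> list[ConfusionCounts]:
    """Integer confusion matrices whose exact Se and Ya round to the inputs.

    Exhaustive search over tp in [0, A] and hits in [max(tp, 1), tp + D].
    Returns all candidates (a single element when unique); raises
    ``NoConsistentCountsError`` when no integer solution exists.
    """
    if not (0 <= se_printed <= 1 and 0 <= ya_printed <= 1):
        raise MetricsError("printed Se and Ya must lie in [0, 1]")
    if actives < 1 or decoys < 1:
        raise MetricsError("need at least one active and one decoy")
    out = []
    for tp in range(actives + 1):
        if not _rounds_to(Fraction(tp, actives), se_printed, se_decimals):
            continue
        for hits in range(max(tp, 1), tp + decoys + 1):
            if not _rounds_to(Fraction(tp, hits), ya_printed, ya_decimals):
                continue
            fp = hits - tp
            out.append(ConfusionCounts(tp=tp, fp=fp, tn=decoys - fp, fn=actives - tp))
    if not out:
        raise NoConsistentCountsError(
            f"no integer counts reproduce Se={se_printed}, Ya={ya_printed} "
            f"with A={actives}, D={decoys}"
        )
    return out


def consistent_counts_for_row(
    row: dict[str, float], actives: int, decoys: int
) -> list[ConfusionCounts]:
    """Candidates from (Se, Ya) whose *eight* rounded metrics match the row."""
    try:
        candidates = back_solve_counts(row["se"], row["ya"], actives, decoys)
    except NoConsistentCountsError:
        return []
    keep = []
    for c in candidates:
        rounded = compute_metrics(c).rounded()
        if all(rounded[k] == round(row[k], METRIC_DECIMALS[k]) for k in METRIC_DECIMALS):
            keep.append(c)
    return keep


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("ph4screen").joinpath("data", name))


def load_reference_table() -> pd.DataFrame:
    """The 17-model published metrics table (printed precision), as a frame."""
    return pd.read_csv(_data_path("reference_model_metrics.csv"))


def load_test_set_composition() -> pd.DataFrame:
    """Per-kinase active/decoy counts of the published test set."""
    return pd.read_csv(_data_path("test_set_composition.csv"))
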