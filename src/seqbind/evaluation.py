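"""Confusion-matrix metrics, Z-scores, residue preferences, random baseline.

Per-target metrics follow the CASP function-prediction conventions:
sensitivity, specificity, accuracy, precision and F1 are reported as
percentages, the Matthews correlation coefficient (MCC) on its natural
[-1, 1] scale.  Degenerate denominators (no predicted positives, a zero
factor under the MCC root) resolve to 0, the standard convention for
sparse binding-site predictions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._alphabet import CANONICAL_AA
from .datasets import ChainAnnotation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Sen/Spe/Acc/Prec/F1 in percent, MCC in [-1, 1]."""

    sen: float
    spe: float
    acc: float
    prec: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sen": self.sen, "spe": self.spe, "acc": self.acc,
            "prec": self.prec, "f1": self.f1, "mcc": self.mcc,
        }


@dataclass
class TargetResult:
    target_id: str
    pdb_id: str
    chemical_class: str  # metal | non-metal | hybrid
    metrics: MetricsReport
    binding_ratio: float
    n_residues: int = 0

    def __post_init__(self):
        if self.chemical_class not in ("metal", "non-metal", "hybrid"):
            raise ValueError(f"unknown chemical class {self.chemical_class!r}")


# ---------------------------------------------------------------------------
# metrics


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Sen, Spe, Acc, Prec, F1 (percent) and MCC from explicit counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (fp + tn) if fp + tn else 0.0
    acc = (tp + tn) / c.total if c.total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sen / (prec + sen) if prec + sen else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(
        sen=100 * sen, spe=100 * spe, acc=100 * acc, prec=100 * prec, f1=100 * f1, mcc=mcc
    )


def compute_metrics(pred, true) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and metrics for one prediction-truth label pair."""
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: pred {pred.shape}, truth {true.shape}")
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )
    return counts, metrics_from_counts(counts)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_from_summary(
    n_residues: int, ratio_pct: float, sen_pct: float, prec_pct: float,
    tolerance_pct: float = 0.5,
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from a per-target summary row.

    Given the residue count, the binding ratio, sensitivity and precision
    (all as printed percentages), recovers the unique consistent integer
    confusion matrix: P = round(ratio*n), TP = round(sen*P), FN = P - TP,
    TP+FP = round(TP/prec), TN = n - TP - FP - FN.  The result is validated
    by recomputing Sen/Prec, which must match within ``tolerance_pct``.
    """
    if not (0 <= ratio_pct <= 100 and 0 <= sen_pct <= 100):
        raise ValueError("ratio and sensitivity must lie in [0, 100]")
    if prec_pct <= 0:
        raise ValueError("precision must be positive for reconstruction")
    p = _round_half_up(ratio_pct * n_residues / 100.0)
    tp = _round_half_up(sen_pct * p / 100.0)
    fn = p - tp
    if tp > 0:
        pred_pos = _round_half_up(tp * 100.0 / prec_pct)
    else:
        pred_pos = 0
    fp = pred_pos - tp
    tn = n_residues - tp - fp - fn
    for name, val in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if val < 0:
            raise ValueError(f"inconsistent summary: reconstructed {name} = {val} < 0")
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    rep = metrics_from_counts(counts)
    if tp > 0 and (abs(rep.sen - sen_pct) > tolerance_pct or abs(rep.prec - prec_pct) > tolerance_pct):
        raise ValueError(
            "round-trip failed: reconstructed counts give "
            f"Sen {rep.sen:.2f} / Prec {rep.prec:.2f}, expected {sen_pct} / {prec_pct}"
        )
    return counts


def macro_average(
    results: Sequence[TargetResult], group: str | None = None
) -> MetricsReport:
    """Unweighted arithmetic mean of each metric over targets.

    ``group`` filters by chemical class before averaging.
    """
    picked = [r for r in results if group is None or r.chemical_class == group]
    if not picked:
        raise ValueError(f"no targets in group {group!r}")
    arr = np.array([[r.metrics.sen, r.metrics.spe, r.metrics.acc,
                     r.metrics.prec, r.metrics.f1, r.metrics.mcc] for r in picked])
    m = arr.mean(axis=0)
    return MetricsReport(sen=m[0], spe=m[1], acc=m[2], prec=m[3], f1=m[4], mcc=m[5])


def pooled_metrics(pairs: Iterable[tuple[np.ndarray, np.ndarray]]) -> tuple[ConfusionCounts, MetricsReport]:
    """Micro average: pool residues of all targets into one confusion matrix."""
    tp = fp = tn = fn = 0
    for pred, true in pairs:
        c, _ = compute_metrics(pred, true)
        tp, fp, tn, fn = tp + c.tp, fp + c.fp, tn + c.tn, fn + c.fn
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, metrics_from_counts(counts)


# ---------------------------------------------------------------------------
# Z-scores


def zscores(mcc_table: pd.DataFrame, ddof: int = 0) -> tuple[pd.Series, pd.DataFrame]:
    """Standardize per-target MCCs across predictors; average per predictor.

    ``mcc_table`` is predictors x targets, NaN where a predictor skipped a
    target.  For each target with >= 2 values and non-zero spread,
    Z = (MCC - target mean) / target std (population by default).  Returns
    (per-predictor mean Z over attempted targets, the Z matrix).
    """
    z = pd.DataFrame(np.nan, index=mcc_table.index, columns=mcc_table.columns)
    for col in mcc_table.columns:
        vals = mcc_table[col].dropna()
        if len(vals) < 2:
            warnings.warn(f"target {col}: fewer than 2 predictors, skipped")
            continue
        sigma = vals.std(ddof=ddof)
        if sigma == 0:
            warnings.warn(f"target {col}: zero MCC spread, skipped")
            continue
        z[col] = (mcc_table[col] - vals.mean()) / sigma
    return z.mean(axis=1), z


# ---------------------------------------------------------------------------
# amino-acid preferences


def aa_preferences(annotations: Sequence[ChainAnnotation]) -> pd.DataFrame:
    """Amino-acid frequencies among binding vs non-binding residues.

    Returns one row per canonical amino acid with the frequency in each
    class (each column sums to 1) and the raw positive/negative count ratio
    (inf where an amino acid never occurs in a negative position).
    """
    pos_counts = dict.fromkeys(CANONICAL_AA, 0)
    neg_counts = dict.fromkeys(CANONICAL_AA, 0)
    for ann in annotations:
        for aa, lab in zip(ann.sequence, ann.labels):
            if aa not in pos_counts:
                continue
            (pos_counts if lab else neg_counts)[aa] += 1
    n_pos = sum(pos_counts.values())
    n_neg = sum(neg_counts.values())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative residue")
    rows = []
    for aa in CANONICAL_AA:
        p, n = pos_counts[aa], neg_counts[aa]
        ratio = p / n if n else (math.inf if p else 0.0)
        rows.append({"aa": aa, "freq_pos": p / n_pos, "freq_neg": n / n_neg, "ratio": ratio})
    return pd.DataFrame(rows).set_index("aa")


# ---------------------------------------------------------------------------
# random baseline


def random_baseline(
    labels: np.ndarray,
    positive_rate: float | None = None,
    n_runs: int = 100,
    seed: int = 0,
) -> MetricsReport:
    """Metrics of a Bernoulli predictor, averaged over ``n_runs`` draws.

    Each run predicts "binding" independently with probability
    ``positive_rate`` (default: the empirical positive rate of ``labels``).
    The expected MCC is ~0; this is the chance floor all real predictors
    are compared against.
    """
    labels = np.asarray(labels, dtype=int)
    rate = positive_rate if positive_rate is not None else labels.mean()
    if not 0 < rate <= 1:
        raise ValueError(f"positive rate must be in (0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_runs):
        pred = (rng.random(labels.shape[0]) < rate).astype(int)
        _, rep = compute_metrics(pred, labels)
        reports.append(rep)
    arr = np.array([[r.sen, r.spe, r.acc, r.prec, r.f1, r.mcc] for r in reports])
    m = arr.mean(axis=0)
    return MetricsReport(sen=m[0], spe=m[1], acc=m[2], prec=m[3], f1=m[4], mcc=m[5])


# ---------------------------------------------------------------------------
# bundled benchmark summaries


def load_casp_targets(dataset: str) -> pd.DataFrame:
    """Per-target summary table from the CASP8/CASP9 community assessments.

    Columns: target, pdb_id, n_residues, chemical_class, sen_pct, prec_pct,
    mcc, ratio_pct.  These printed summaries are the inputs for the
    confusion-matrix reconstruction worked examples.
    """
    if dataset not in ("casp8", "casp9"):
        raise ValueError("dataset must be 'casp8' or 'casp9'")
    with resources.files("seqbind.data").joinpath(f"{dataset}_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def target_results_from_table(df: pd.DataFrame) -> list[TargetResult]:
    """Build TargetResults from a printed summary table (Sen/Prec/MCC only;
    unavailable metrics are set to NaN)."""
    out = []
    for _, row in df.iterrows():
        rep = MetricsReport(
            sen=float(row["sen_pct"]), spe=math.nan, acc=math.nan,
            prec=float(row["prec_pct"]), f1=math.nan, mcc=float(row["mcc"]),
        )
        out.append(
            TargetResult(
                target_id=str(row["target"]),
                pdb_id=str(row["pdb_id"]),
                chemical_class=str(row["chemical_class"]),
                metrics=rep,
                binding_ratio=float(row["ratio_pct"]),
                n_residues=int(row["n_residues"]),
            )
        )
    return out
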