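"""Reliability analysis: join responses with unsealed provenance.

Everything the blinded experiment was designed to measure is computed
here:

* per-source agreement breakdowns (inter-observer view),
* DSC between source pairs stratified by whether the validator gave both
  sources the same binary judgment,
* intra-observer consistency from the covert repeats: k×k and binary
  confusion matrices (rows = first evaluation, columns = second) and the
  derived metrics — accuracy with a Wilson score interval, Cohen's
  kappa, balanced accuracy, F1, precision, recall,
* order-of-appearance effects (does agreement depend on whether a
  source's mask was the first, second, or third version of the image the
  validator saw),
* session analytics (a break of more than one hour starts a new session).

First-pass (replicate-1) responses feed the inter-observer analyses;
the covert repeats feed only the intra-observer analysis.  This split is
what makes the denominators per source equal the image count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .design import ProvenanceRecord, SchedulePlan, order_ranks
from .errors import AnalysisError, IncompleteLogError
from .masks import DscSummary, summarize_dsc
from .responses import LabelScheme, ResponseLog, collapse_binary

__all__ = [
    "ConfusionMatrix",
    "RaterMetrics",
    "RepeatTables",
    "StratifiedDscRow",
    "wilson_ci",
    "cohen_kappa",
    "agreement_by_source",
    "confusion_from_repeats",
    "rater_metrics",
    "stratified_dsc",
    "order_effect",
    "detect_sessions",
    "build_report",
]

BINARY_LABELS = ("agree", "disagree")


@dataclass(frozen=True)
class ConfusionMatrix:
    """k×k counts; rows index the first evaluation, columns the second."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if arr.shape != (k, k):
            raise AnalysisError(f"confusion matrix must be {k}x{k}, got {arr.shape}")
        if (arr < 0).any():
            raise AnalysisError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_discordant(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


@dataclass(frozen=True)
class RaterMetrics:
    """Reliability metrics of a 2×2 repeat-judgment matrix.

    ``kappa`` is None when chance agreement is exactly 1 (all mass in one
    cell of the marginals), where the statistic is undefined.
    """

    accuracy: float
    acc_ci_low: float
    acc_ci_high: float
    kappa: float | None
    balanced_accuracy: float
    f1: float
    precision: float
    recall: float
    n: int


def wilson_ci(successes: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise AnalysisError("wilson_ci requires n >= 1")
    if not 0 <= successes <= n:
        raise AnalysisError(f"successes {successes} outside [0, {n}]")
    if not 0.0 < conf_level < 1.0:
        raise AnalysisError("conf_level must lie in (0, 1)")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - conf_level, method="wilson")
    return float(lo), float(hi)


def cohen_kappa(cm: ConfusionMatrix) -> float | None:
    """Chance-corrected agreement (p_o − p_e) / (1 − p_e); None if p_e = 1."""
    n = cm.total
    if n == 0:
        raise AnalysisError("kappa undefined on an empty matrix")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if math.isclose(p_e, 1.0):
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def rater_metrics(binary: ConfusionMatrix, conf_level: float = 0.95) -> RaterMetrics:
    """Derive the reliability metrics from a 2×2 repeat matrix.

    The first evaluation (rows) is the reference and the second (columns)
    the prediction; the positive class is "agree".  Accuracy gets a
    Wilson interval; kappa, balanced accuracy, F1, precision and recall
    follow the usual binary definitions.
    """
    if binary.labels != BINARY_LABELS:
        raise AnalysisError(f"expected binary labels {BINARY_LABELS}, got {binary.labels}")
    n = binary.total
    if n < 1:
        raise AnalysisError("rater_metrics requires at least one pair")
    tp, fn = int(binary.counts[0, 0]), int(binary.counts[0, 1])
    fp, tn = int(binary.counts[1, 0]), int(binary.counts[1, 1])
    correct = tp + tn
    accuracy = correct / n
    lo, hi = wilson_ci(correct, n, conf_level)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    balanced = (recall + specificity) / 2.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    return RaterMetrics(
        accuracy=accuracy, acc_ci_low=lo, acc_ci_high=hi,
        kappa=cohen_kappa(binary), balanced_accuracy=balanced,
        f1=f1, precision=precision, recall=recall, n=n,
    )


# ---------------------------------------------------------------------------
# joining the log with provenance

def _first_pass(log: ResponseLog, prov: ProvenanceRecord) -> dict[tuple[str, str], str]:
    """(image, source) → label for replicate-1 responses."""
    out = {}
    for r in log:
        img, src, rep = prov[r.presentation_id]
        if rep == 1:
            out[(img, src)] = r.label
    return out


def _require_complete_first_pass(
    log: ResponseLog, prov: ProvenanceRecord
) -> dict[tuple[str, str], str]:
    labels = _first_pass(log, prov)
    expected = {(i, s) for (i, s, r) in (prov[pid] for pid in prov) if r == 1}
    missing = sorted(expected - set(labels))
    if missing:
        raise IncompleteLogError(
            f"{len(missing)} first-pass responses missing (e.g. {missing[:3]})",
            missing=[f"{i}/{s}" for i, s in missing],
        )
    return labels


def agreement_by_source(
    log: ResponseLog, prov: ProvenanceRecord, scheme: LabelScheme
) -> pd.DataFrame:
    """Per-source label counts and percent agreement (first pass only).

    Returns a DataFrame indexed by source_id with one column per label
    category, plus ``total`` and ``percent_agree`` (0–100).  Covert
    repeats are excluded, so each source's denominator is the image count.
    """
    labels = _require_complete_first_pass(log, prov)
    sources = sorted({s for (_, s) in labels})
    rows = []
    for src in sources:
        src_labels = [lab for (i, s), lab in labels.items() if s == src]
        counts = {cat: src_labels.count(cat) for cat in scheme.categories}
        agree = sum(counts[c] for c in scheme.agree)
        rows.append({"source_id": src, **counts, "total": len(src_labels),
                     "percent_agree": 100.0 * agree / len(src_labels)})
    return pd.DataFrame(rows).set_index("source_id")


@dataclass(frozen=True)
class RepeatTables:
    """Confusion matrices from the covert repeats, overall and per source."""

    overall: ConfusionMatrix
    overall_binary: ConfusionMatrix
    per_source: dict[str, tuple[ConfusionMatrix, ConfusionMatrix]]


def confusion_from_repeats(
    log: ResponseLog, prov: ProvenanceRecord, scheme: LabelScheme
) -> RepeatTables:
    """Pair each duplicated item's two judgments into confusion matrices.

    Rows are the replicate-1 label, columns the replicate-2 label; the
    binary matrices collapse both axes through the scheme.  Every
    duplicated (image, source) must have both responses.
    """
    by_rep: dict[tuple[str, str], dict[int, str]] = {}
    for r in log:
        img, src, rep = prov[r.presentation_id]
        by_rep.setdefault((img, src), {})[rep] = r.label
    duplicated = {(i, s) for pid in prov for (i, s, rep) in [prov[pid]] if rep == 2}
    pairs = {k: by_rep.get(k, {}) for k in duplicated}
    unpaired = sorted(k for k, v in pairs.items() if 1 not in v or 2 not in v)
    if unpaired:
        raise IncompleteLogError(
            f"{len(unpaired)} duplicated items lack one of their two responses "
            f"(e.g. {unpaired[:3]})",
            missing=[f"{i}/{s}" for i, s in unpaired],
        )

    cats = scheme.categories
    idx = {c: i for i, c in enumerate(cats)}
    bidx = {b: i for i, b in enumerate(BINARY_LABELS)}

    def _tally(keys):
        k = np.zeros((len(cats), len(cats)), dtype=np.int64)
        b = np.zeros((2, 2), dtype=np.int64)
        for key in keys:
            l1, l2 = pairs[key][1], pairs[key][2]
            k[idx[l1], idx[l2]] += 1
            b[bidx[collapse_binary(l1, scheme)], bidx[collapse_binary(l2, scheme)]] += 1
        return (ConfusionMatrix(cats, k), ConfusionMatrix(BINARY_LABELS, b))

    overall_k, overall_b = _tally(pairs)
    per_source = {}
    for src in sorted({s for (_, s) in pairs}):
        per_source[src] = _tally([k for k in pairs if k[1] == src])
    return RepeatTables(overall=overall_k, overall_binary=overall_b,
                        per_source=per_source)


@dataclass(frozen=True)
class StratifiedDscRow:
    """DSC summary for one stratum of a source pair.

    ``same_label`` is True for images where the validator's binary
    judgment agreed across the two sources.  ``ci_flagged`` marks strata
    too small (n < 2) for a confidence interval.
    """

    source_a: str
    source_b: str
    same_label: bool
    summary: DscSummary

    @property
    def n(self) -> int:
        return self.summary.n

    @property
    def ci_flagged(self) -> bool:
        return self.summary.ci_low is None


def stratified_dsc(
    log: ResponseLog,
    prov: ProvenanceRecord,
    dsc_by_image: Mapping[str, float],
    pair: tuple[str, str],
    scheme: LabelScheme,
    conf_level: float = 0.95,
) -> list[StratifiedDscRow]:
    """Split a pair's per-image DSC by validator-judgment concordance.

    ``dsc_by_image`` maps image_id → DSC between the two sources of
    ``pair``.  Images are split by whether the validator's binary label
    was the same for both sources; each stratum is summarised as
    mean ± sd with a t-interval.  An empty stratum is omitted; a
    singleton stratum is emitted without a CI and flagged.
    """
    src_a, src_b = pair
    labels = _require_complete_first_pass(log, prov)
    strata: dict[bool, list[float]] = {True: [], False: []}
    for img in dsc_by_image:
        la = collapse_binary(labels[(img, src_a)], scheme)
        lb = collapse_binary(labels[(img, src_b)], scheme)
        strata[la == lb].append(float(dsc_by_image[img]))
    rows = []
    for same in (False, True):
        vals = strata[same]
        if not vals:
            continue
        rows.append(StratifiedDscRow(
            source_a=src_a, source_b=src_b, same_label=same,
            summary=summarize_dsc(vals, conf_level),
        ))
    return rows


def order_effect(
    log: ResponseLog,
    prov: ProvenanceRecord,
    plan: SchedulePlan,
    scheme: LabelScheme,
) -> pd.DataFrame:
    """Percent agreement per (source, order-of-appearance rank).

    Rank r means the source's mask was the r-th version of its image the
    validator saw (covert repeats excluded from ranking).  Returns a
    DataFrame with columns source_id, rank, n, percent_agree; for each
    source the n over ranks sum to the image count.
    """
    labels = _require_complete_first_pass(log, prov)
    ranks = order_ranks(plan, prov)
    rows: dict[tuple[str, int], list[str]] = {}
    for (img, src), lab in labels.items():
        rows.setdefault((src, ranks[(img, src)]), []).append(lab)
    out = []
    for (src, rank), labs in sorted(rows.items()):
        agree = sum(1 for l in labs if collapse_binary(l, scheme) == "agree")
        out.append({"source_id": src, "rank": rank, "n": len(labs),
                    "percent_agree": 100.0 * agree / len(labs)})
    return pd.DataFrame(out)


def detect_sessions(
    log: ResponseLog,
    scheme: LabelScheme,
    gap_threshold: float = 3600.0,
) -> pd.DataFrame:
    """Segment the log into review sessions separated by long breaks.

    Responses are ordered by answer time; a new session starts when the
    next item was shown more than ``gap_threshold`` seconds (default one
    hour) after the previous answer — a gap of exactly the threshold does
    not split.  Per session: start, end, item count, items per hour
    (single-item sessions use their own shown→answered span as duration)
    and percent agreement.
    """
    if len(log) == 0:
        raise AnalysisError("cannot sessionize an empty log")
    resp = sorted(log, key=lambda r: r.answered_at)
    for r in resp:
        for ts in (r.shown_at, r.answered_at):
            if ts is None or pd.isna(ts):
                raise AnalysisError("non-finite timestamp in response log")
    sessions: list[list] = [[resp[0]]]
    for prev, cur in zip(resp, resp[1:]):
        gap = (cur.shown_at - prev.answered_at).total_seconds()
        if gap > gap_threshold:
            sessions.append([cur])
        else:
            sessions[-1].append(cur)
    rows = []
    for i, ses in enumerate(sessions, start=1):
        start, end = ses[0].shown_at, ses[-1].answered_at
        duration_s = (end - start).total_seconds()
        agree = sum(1 for r in ses if collapse_binary(r.label, scheme) == "agree")
        rows.append({
            "session": i,
            "start": start,
            "end": end,
            "n_items": len(ses),
            "duration_s": duration_s,
            "items_per_hour": (len(ses) / (duration_s / 3600.0)
                               if duration_s > 0 else float("nan")),
            "percent_agree": 100.0 * agree / len(ses),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report bundle

def _metrics_row(name: str, m: RaterMetrics) -> dict:
    return {
        "scope": name, "n": m.n, "accuracy": m.accuracy,
        "acc_ci_low": m.acc_ci_low, "acc_ci_high": m.acc_ci_high,
        "kappa": m.kappa if m.kappa is not None else float("nan"),
        "kappa_undefined": m.kappa is None,
        "balanced_accuracy": m.balanced_accuracy, "f1": m.f1,
        "precision": m.precision, "recall": m.recall,
    }


def build_report(
    outdir: str | Path,
    *,
    agreement: pd.DataFrame,
    repeats: RepeatTables | None = None,
    strata: Sequence[StratifiedDscRow] = (),
    order: pd.DataFrame | None = None,
    sessions: pd.DataFrame | None = None,
    conf_level: float = 0.95,
) -> Path:
    """Write the analysis as a directory of deterministic CSV tables.

    Emits agreement_by_source.csv always, plus (when the corresponding
    analysis is provided) stratified_dsc.csv, confusion_overall.csv,
    confusion_binary.csv, confusion_by_source.csv, rater_metrics.csv,
    order_effect.csv, sessions.csv.  Numbers are written at 6 decimals
    so regenerating from identical inputs yields byte-identical files;
    the headline tables are conventionally read at 3 decimals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, name: str, index=False):
        df.to_csv(outdir / name, index=index, float_format="%.6f")

    _write(agreement.reset_index(), "agreement_by_source.csv")

    if strata:
        _write(pd.DataFrame([{
            "source_a": r.source_a, "source_b": r.source_b,
            "same_label": r.same_label, "n": r.n,
            "dsc_mean": r.summary.mean, "dsc_sd": r.summary.sd,
            "ci_low": (r.summary.ci_low if r.summary.ci_low is not None else float("nan")),
            "ci_high": (r.summary.ci_high if r.summary.ci_high is not None else float("nan")),
            "ci_flagged": r.ci_flagged,
        } for r in strata]), "stratified_dsc.csv")

    if repeats is not None:
        _write(repeats.overall.to_frame(), "confusion_overall.csv", index=True)
        _write(repeats.overall_binary.to_frame(), "confusion_binary.csv", index=True)
        per_src = []
        for src, (kmat, _b) in sorted(repeats.per_source.items()):
            df = kmat.to_frame()
            for first in df.index:
                for second in df.columns:
                    per_src.append({"source_id": src, "first": first,
                                    "second": second, "count": int(df.loc[first, second])})
        _write(pd.DataFrame(per_src), "confusion_by_source.csv")
        mrows = [_metrics_row("overall", rater_metrics(repeats.overall_binary, conf_level))]
        for src, (_k, b) in sorted(repeats.per_source.items()):
            mrows.append(_metrics_row(src, rater_metrics(b, conf_level)))
        _write(pd.DataFrame(mrows), "rater_metrics.csv")

    if order is not None:
        _write(order, "order_effect.csv")
    if sessions is not None:
        ses = sessions.copy()
        for col in ("start", "end"):
            ses[col] = ses[col].map(lambda t: t.strftime("%Y-%m-%dT%H:%M:%S%z"))
        _write(ses, "sessions.csv")
    return outdir
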