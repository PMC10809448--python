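"""Proficiency scoring of query batches against reference datasets.

Three complementary metrics per batch:

* **SNR** — reference-free discriminability of the four Quartet groups
  (see :mod:`quartetqc.qc_metrics`);
* **RC (relative correlation)** — Pearson correlation between the batch's
  measured log2 ratios to D6 and the consensus reference values, pooled
  over the three sample pairs;
* **recall** — the fraction of reference DAMs the batch also calls
  differentially abundant (p < alpha).

Each metric is min–max scaled to [0, 10] across the scored cohort and the
total score is their mean; batches are ranked by total score and binned
into four levels (Great/Good/Fair/Bad) at the cohort quartiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DAMTable, dam_test
from .errors import (
    DegenerateInputError,
    InsufficientFeaturesError,
    NotEvaluableError,
    ValidationError,
)
from .profiles_io import BatchProfile
from .qc_metrics import FilterCriteria, snr
from .reference_builder import ReferenceDataset

logger = logging.getLogger(__name__)

LEVELS = ("Great", "Good", "Fair", "Bad")
METRICS = ("snr_db", "rc", "recall")


def recall(query_dams: Mapping[tuple[str, str], DAMTable],
           references: Mapping[tuple[str, str], ReferenceDataset],
           scope: str = "detected") -> float:
    """Fraction of reference DAMs that the query batch also calls.

    Pooled over the sample pairs.  Under the default ``detected`` scope
    the denominator is restricted to reference DAMs the query measured
    (present in its DAM table for that pair), so the metric reads as
    calling sensitivity rather than panel coverage; ``scope='all'`` uses
    every reference DAM.
    """
    if scope not in ("detected", "all"):
        raise ValidationError(f"unknown recall scope {scope!r}")
    if not references or all(len(r.table) == 0 for r in references.values()):
        raise ValidationError("reference datasets are empty")
    num = den = 0
    for pair, ref in references.items():
        if pair not in query_dams:
            if scope == "all":
                den += len(ref.metabolites)
            continue
        table = query_dams[pair]
        measured = set(table.table.index)
        eligible = ref.metabolites if scope == "all" \
            else ref.metabolites & measured
        den += len(eligible)
        num += len(eligible & table.dams)
    if den == 0:
        raise NotEvaluableError(
            "no reference DAM was detected by the query; recall not evaluable")
    return num / den


def relative_correlation(
        profile: BatchProfile,
        references: Mapping[tuple[str, str], ReferenceDataset],
        min_points: int = 3) -> float:
    """Pearson correlation of measured vs reference log2 ratios.

    Per pair, the measured value of a metabolite is its mean log2
    abundance in the numerator group minus that in the denominator group;
    points from all pairs are pooled before the correlation.
    """
    from .ratio_transform import to_ratio

    measured, expected = [], []
    ratio_cache: dict[str, pd.DataFrame] = {}
    for pair, ref in references.items():
        num, den = pair
        # measured log2 ratio = mean over the numerator group's ratio-to-den
        # values; division-first ratios keep this batch-effect-invariant
        if den not in ratio_cache:
            ratio_cache[den] = to_ratio(profile, ref_group=den).data
        rdata = ratio_cache[den]
        num_cols = [c for c in rdata.columns if c.startswith(f"{num}-")]
        if not num_cols:
            continue
        diff = rdata[num_cols].mean(axis=1, skipna=True)
        for key in ref.metabolites:
            if key in diff.index and np.isfinite(diff.loc[key]):
                measured.append(float(diff.loc[key]))
                expected.append(ref.value_of(key))
    if len(measured) < min_points:
        raise InsufficientFeaturesError(
            f"RC needs >= {min_points} overlapping points, got {len(measured)}")
    r, _ = stats.pearsonr(measured, expected)
    return float(r)


@dataclass
class ProficiencyReport:
    """Scored cohort: per-batch metrics, scaled scores, ranks and levels."""

    table: pd.DataFrame       # index batch_id; metrics, scaled_*, total_score,
                              # rank, level
    anchors: dict             # per metric: (min, max) used for scaling
    thresholds: dict          # level cut points (cohort quartiles)


def _minmax_scale(col: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    vals = col.astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    if not np.isfinite(lo) or not np.isfinite(hi):
        return pd.Series(np.nan, index=col.index), (np.nan, np.nan)
    if hi == lo:
        logger.info("metric constant across cohort; scaled to 10 for all")
        return pd.Series(10.0, index=col.index).where(vals.notna()), (lo, hi)
    # ratio first so the cohort maximum scales to exactly 10.0
    return 10.0 * ((vals - lo) / (hi - lo)), (lo, hi)


def total_score(metrics: pd.DataFrame) -> ProficiencyReport:
    """Scale SNR, RC and recall to [0, 10], average, rank, and assign levels.

    ``metrics`` is indexed by batch id with columns ``snr_db``, ``rc``,
    ``recall`` (NaN allowed for a missing metric — the total then averages
    the available ones and the batch is flagged).  Levels follow cohort
    quartiles of the total score, top quartile "Great" down to "Bad".
    """
    missing_cols = [c for c in METRICS if c not in metrics.columns]
    if missing_cols:
        raise ValidationError(f"metrics table missing columns {missing_cols}")
    if len(metrics) < 2:
        raise DegenerateInputError(
            "scoring needs a cohort of >=2 batches; report raw metrics only")
    out = metrics[list(METRICS)].astype(float).copy()
    anchors = {}
    for m in METRICS:
        scaled, anchors[m] = _minmax_scale(out[m])
        out[f"scaled_{m}"] = scaled
    scaled_cols = [f"scaled_{m}" for m in METRICS]
    out["n_metrics"] = out[scaled_cols].notna().sum(axis=1)
    out["incomplete"] = out["n_metrics"] < len(METRICS)
    out["total_score"] = out[scaled_cols].mean(axis=1, skipna=True)
    order = out.sort_values(["total_score"], ascending=False, kind="stable")
    # deterministic tie-break: batch_id lexicographic within equal totals
    order = order.loc[sorted(order.index,
                             key=lambda b: (-order.loc[b, "total_score"], b))]
    out = out.loc[order.index]
    out["rank"] = np.arange(1, len(out) + 1)
    q25, q50, q75 = np.percentile(out["total_score"], [25, 50, 75])
    def level_of(t: float) -> str:
        if t >= q75:
            return "Great"
        if t >= q50:
            return "Good"
        if t >= q25:
            return "Fair"
        return "Bad"
    out["level"] = [level_of(t) for t in out["total_score"]]
    return ProficiencyReport(
        table=out, anchors=anchors,
        thresholds={"q25": float(q25), "q50": float(q50), "q75": float(q75)})


def score_batches(batches: Sequence[BatchProfile],
                  references: Mapping[tuple[str, str], ReferenceDataset],
                  alpha: float = 0.05,
                  criteria: Optional[FilterCriteria] = None,
                  recall_scope: str = "detected") -> ProficiencyReport:
    """End-to-end proficiency run: compute SNR, RC and recall per batch,
    then scale, rank and classify the cohort."""
    rows = {}
    for b in batches:
        vals: dict[str, float] = {}
        try:
            vals["snr_db"] = snr(b, criteria=criteria).snr_db
        except Exception as exc:  # metric missing, not fatal for the cohort
            logger.warning("batch %s: SNR not evaluable (%s)", b.batch_id, exc)
            vals["snr_db"] = np.nan
        try:
            vals["rc"] = relative_correlation(b, references)
        except Exception as exc:
            logger.warning("batch %s: RC not evaluable (%s)", b.batch_id, exc)
            vals["rc"] = np.nan
        try:
            dams = {pair: dam_test(b, pair, alpha=alpha)
                    for pair in references}
            vals["recall"] = recall(dams, references, scope=recall_scope)
        except Exception as exc:
            logger.warning("batch %s: recall not evaluable (%s)",
                           b.batch_id, exc)
            vals["recall"] = np.nan
        rows[b.batch_id] = vals
    return total_score(pd.DataFrame.from_dict(rows, orient="index"))
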