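"""Differentially abundant metabolite (DAM) calling and Levey–Jennings
longitudinal monitoring.

DAMs between two Quartet groups are called by a two-sided t-test on log2
replicate abundances (Welch by default — safer at n = 3 — pooled-variance
Student available), with raw p < alpha as the criterion.  An optional
Benjamini–Hochberg column is emitted for information only.

Levey–Jennings monitoring tracks each metabolite's per-run mean (log2
abundance per group, or log2 ratio per sample pair) across runs and flags
runs deviating from the across-run mean by more than k standard deviations
(k = 3 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .profiles_io import (
    GROUPS,
    REPLICATES,
    BatchProfile,
    MetaboliteKey,
)
from .ratio_transform import RatioProfile

logger = logging.getLogger(__name__)

CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("D5", "D6"), ("F7", "D6"), ("M8", "D6"))


@dataclass
class DAMTable:
    """Per-metabolite log2 fold change and t-test p for one sample pair."""

    batch_id: str
    pair: tuple[str, str]            # (numerator, denominator)
    alpha: float
    table: pd.DataFrame              # index MetaboliteKey; log2_fc, p_value,
                                     # dam_flag, p_bh

    @property
    def dams(self) -> set[MetaboliteKey]:
        return set(self.table.index[self.table["dam_flag"]])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _group_log2(profile: Union[BatchProfile, RatioProfile],
                group: str) -> pd.DataFrame:
    cols = [f"{group}-{r}" for r in REPLICATES
            if f"{group}-{r}" in profile.data.columns]
    block = profile.data[cols]
    if isinstance(profile, RatioProfile):
        return block  # already log2
    return np.log2(block)


def dam_test(profile: BatchProfile, pair: tuple[str, str],
             alpha: float = 0.05, variant: str = "welch") -> DAMTable:
    """Call DAMs for an ordered (numerator, denominator) group pair.

    Per metabolite: log2 fold change = mean log2 numerator replicates −
    mean log2 denominator replicates; p from a two-sided t-test on the
    log2 replicate values.  Metabolites with fewer than 2 replicates in
    either group are omitted with a logged reason.
    """
    num, den = pair
    if num not in GROUPS or den not in GROUPS or num == den:
        raise ValidationError(f"invalid sample pair {pair!r}")
    if variant not in ("welch", "pooled"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    a = _group_log2(profile, num)
    b = _group_log2(profile, den)
    n_a = a.notna().sum(axis=1)
    n_b = b.notna().sum(axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info("batch %s %s/%s: %d metabolites untestable (<2 replicates)",
                    profile.batch_id, num, den, n_skip)
    if not testable.any():
        logger.warning("batch %s %s/%s: no testable metabolites",
                       profile.batch_id, num, den)
    mask = testable.to_numpy()
    keys = list(profile.data.index[mask])
    A = a.to_numpy(dtype=float)[mask]
    B = b.to_numpy(dtype=float)[mask]
    if keys:
        fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance rows handled below
            res = stats.ttest_ind(A, B, axis=1, nan_policy="omit",
                                  equal_var=(variant == "pooled"))
            p = np.asarray(res.pvalue, dtype=float)
        # degenerate t: replicates exactly constant in both groups
        degenerate = (np.nanvar(A, axis=1, ddof=1) == 0.0) & \
                     (np.nanvar(B, axis=1, ddof=1) == 0.0)
        p[degenerate] = np.where(fc[degenerate] == 0.0, 1.0, 0.0)
    else:
        fc = np.empty(0)
        p = np.empty(0)
    table = pd.DataFrame({"log2_fc": fc, "p_value": p}, index=keys)
    table["dam_flag"] = table["p_value"] < alpha
    table["p_bh"] = _bh_adjust(table["p_value"].to_numpy()) \
        if len(table) else np.nan
    return DAMTable(profile.batch_id, (num, den), alpha, table)


def volcano_table(dam: DAMTable) -> pd.DataFrame:
    """Volcano-plot rows: log2 fold change, −log10 p and call direction
    (``up``/``down`` for significant increases/decreases, else ``ns``)."""
    t = dam.table
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(t["p_value"].to_numpy(dtype=float))
    direction = np.where(~t["dam_flag"], "ns",
                         np.where(t["log2_fc"] > 0, "up", "down"))
    return pd.DataFrame({
        "log2_fc": t["log2_fc"],
        "neg_log10_p": neg_log10_p,
        "direction": direction,
    }, index=t.index)


@dataclass
class LeveyJenningsFlags:
    """Control-chart result for one laboratory's run series."""

    level: str                       # absolute | ratio
    k_sd: float
    records: pd.DataFrame            # metabolite, series, run_id, run_mean,
                                     # z, flag, constant
    deviated: pd.DataFrame           # metabolite, series, deviated_flag
    deviated_counts: dict[str, int]  # series -> number of deviated metabolites


def levey_jennings(runs: Sequence[Union[BatchProfile, RatioProfile]],
                   level: str = "absolute", k_sd: float = 3.0,
                   min_runs: int = 3) -> LeveyJenningsFlags:
    """Flag runs whose per-metabolite mean deviates beyond ±k SD.

    The monitored quantity is the mean over a run's replicates: log2
    abundance per sample group at the absolute level, log2 ratio per
    sample pair at the ratio level (reference-group series are identically
    zero and skipped).  A series needs ``min_runs`` runs with data; a
    series with zero across-run SD is marked constant and never flagged.
    """
    if level not in ("absolute", "ratio"):
        raise ValidationError(f"unknown level {level!r}")
    if len(runs) < 3:
        raise ValidationError("Levey–Jennings monitoring needs >=3 runs")
    if level == "ratio":
        ref = runs[0].ref_group if isinstance(runs[0], RatioProfile) else "D6"
        series_groups = [g for g in GROUPS if g != ref]
    else:
        ref = None
        series_groups = list(GROUPS)

    def series_name(g: str) -> str:
        return f"{g}/{ref}" if level == "ratio" else g

    # per-run mean per (metabolite, group): long frame runs x series
    per_run: dict[str, pd.DataFrame] = {}
    for g in series_groups:
        cols = {}
        for run in runs:
            block = _group_log2(run, g)
            cols[run.batch_id] = block.mean(axis=1, skipna=True)
        per_run[g] = pd.DataFrame(cols)  # metabolite x run

    records, deviated_rows = [], []
    counts = {series_name(g): 0 for g in series_groups}
    for g in series_groups:
        frame = per_run[g]
        sname = series_name(g)
        for key, row in frame.iterrows():
            vals = row.dropna()
            if len(vals) < min_runs:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            # rounding in the across-run mean leaves identical series with
            # an SD of a few ulp; treat those as constant too
            constant = sd <= 1e-12 * max(abs(mean), 1.0)
            any_flag = False
            for run_id, v in vals.items():
                z = 0.0 if constant else (v - mean) / sd
                flag = (not constant) and abs(v - mean) > k_sd * sd
                any_flag |= flag
                records.append((key, sname, run_id, float(v), z, flag,
                                constant))
            deviated_rows.append((key, sname, any_flag))
            counts[sname] += int(any_flag)
    return LeveyJenningsFlags(
        level=level, k_sd=k_sd,
        records=pd.DataFrame(records, columns=[
            "metabolite", "series", "run_id", "run_mean", "z", "flag",
            "constant"]),
        deviated=pd.DataFrame(deviated_rows, columns=[
            "metabolite", "series", "deviated_flag"]),
        deviated_counts=counts,
    )
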