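"""Ratio-based profiling: scaling absolute profiles to a common reference.

Each batch measures the same four Quartet reference materials, so any
per-batch, per-metabolite multiplicative effect (ionisation efficiency,
calibration, instrument response) is shared by all 12 samples of the batch.
Dividing every sample's abundance by that of a concurrently measured
reference group (D6 by default), metabolite by metabolite, cancels such
batch effects exactly.  Output is stored as log2 ratios: symmetric in
up/down direction and directly comparable to reference datasets.

Also provides the cross-batch integration matrices (absolute and ratio
level) used to assess integration quality by PCA/HCA/silhouette.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingDataError, ValidationError
from .profiles_io import (
    GROUPS,
    REPLICATES,
    SAMPLE_COLUMNS,
    BatchProfile,
    MetaboliteKey,
    MultiBatchCollection,
    complete_case_metabolites,
    group_of,
)

logger = logging.getLogger(__name__)

PAIRINGS = ("mean_denominator", "replicate_paired")


def geometric_mean(values: Iterable[float]) -> float:
    """Geometric mean of positive reals, computed in log space."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of an empty sequence")
    if np.any(~(arr > 0)):
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class RatioProfile:
    """A batch re-expressed as log2 ratios to a reference sample group."""

    batch_id: str
    data: pd.DataFrame          # metabolite x sample label, log2 ratios
    ref_group: str = "D6"
    pairing: str = "mean_denominator"

    def __post_init__(self):
        if self.ref_group not in GROUPS:
            raise ValidationError(f"unknown reference group {self.ref_group!r}")
        if self.pairing not in PAIRINGS:
            raise ValidationError(f"unknown pairing {self.pairing!r}")


def to_ratio(profile: BatchProfile, ref_group: str = "D6",
             pairing: str = "mean_denominator") -> RatioProfile:
    """Convert absolute abundances to log2 ratios to ``ref_group``.

    ``mean_denominator`` (default): each value divided by the geometric
    mean of the reference group's replicates of that metabolite, so the
    reference samples average to log2 ratio 0.  ``replicate_paired``:
    replicate i divided by reference replicate i (matched acquisition
    round).  Metabolites with no usable reference measurement are dropped
    with a logged reason.
    """
    if pairing not in PAIRINGS:
        raise ValidationError(f"unknown pairing {pairing!r}")
    ref_cols = [f"{ref_group}-{r}" for r in REPLICATES]
    present_ref = [c for c in ref_cols if c in profile.data.columns]
    if not present_ref:
        raise MissingDataError(
            f"batch {profile.batch_id!r}: reference group {ref_group} absent")
    vals = profile.data.to_numpy(dtype=float)
    # Ratios are formed by dividing raw values *before* the log: a shared
    # multiplicative batch factor then cancels in the division itself, so
    # power-of-two factors cancel bit-exactly and arbitrary ones to an ulp.
    if pairing == "mean_denominator":
        # log2(v / geometric mean of refs) == mean_i log2(v / ref_i)
        stack = np.stack([
            np.log2(vals / profile.data[c].to_numpy(dtype=float)[:, None])
            for c in present_ref])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out_vals = np.nanmean(stack, axis=0)
        out = pd.DataFrame(out_vals, index=profile.data.index,
                           columns=profile.data.columns)
        usable = profile.data[present_ref].notna().any(axis=1)
        reason = f"without {ref_group} values"
    else:
        out = pd.DataFrame(np.nan, index=profile.data.index,
                           columns=profile.data.columns)
        for col in profile.data.columns:
            rep = col.split("-")[1]
            ref_col = f"{ref_group}-{rep}"
            if ref_col in profile.data.columns:
                out[col] = np.log2(profile.data[col] / profile.data[ref_col])
        usable = out.notna().any(axis=1)
        reason = f"without matched {ref_group} replicates"
    if (~usable).any():
        logger.info("batch %s: dropping %d metabolites %s",
                    profile.batch_id, int((~usable).sum()), reason)
    return RatioProfile(profile.batch_id, out.loc[usable],
                        ref_group=ref_group, pairing=pairing)


def write_ratio_profile(rp: RatioProfile, path: Union[str, Path]) -> None:
    """Wide TSV/CSV of log2 ratios; reference group in a comment header."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta = pd.DataFrame({
        "hmdb_id": [k.hmdb_id or "" for k in rp.data.index],
        "name": [k.name for k in rp.data.index],
    })
    out = pd.concat([meta, rp.data.reset_index(drop=True)], axis=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ref_group={rp.ref_group}\n# pairing={rp.pairing}\n")
        out.to_csv(fh, sep=sep, index=False, na_rep="",
                   float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# cross-batch integration matrices
# ---------------------------------------------------------------------------

def integrated_matrix(collection: MultiBatchCollection,
                      level: str = "absolute", ref_group: str = "D6",
                      pairing: str = "mean_denominator",
                      ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Stack batches into one samples-x-metabolites matrix.

    Uses the complete-case intersection of metabolites across batches.
    ``level='absolute'`` stacks log2 abundances; ``level='ratio'`` stacks
    log2 ratios to ``ref_group``.  Returns (matrix, batch labels, group
    labels) with sample index ``"<batch>:<group>-<replicate>"``.
    """
    if level not in ("absolute", "ratio"):
        raise ValidationError(f"unknown level {level!r}")
    if len(collection.batches) < 2:
        raise ValidationError("integration needs at least 2 batches")
    shared: Optional[set[MetaboliteKey]] = None
    for b in collection.batches:
        cc = complete_case_metabolites(b)
        shared = cc if shared is None else shared & cc
    if not shared:
        raise DegenerateInputError(
            "no metabolite is complete in every batch; nothing to integrate")
    first = collection.batches[0]
    order = [k for k in first.data.index if k in shared]
    blocks, batch_labels, group_labels, sample_index = [], [], [], []
    for b in collection.batches:
        if level == "absolute":
            block = np.log2(b.data.loc[order, list(SAMPLE_COLUMNS)])
        else:
            rp = to_ratio(b, ref_group=ref_group, pairing=pairing)
            block = rp.data.loc[order, list(SAMPLE_COLUMNS)]
        blocks.append(block.T)  # samples x metabolites
        for col in SAMPLE_COLUMNS:
            batch_labels.append(b.batch_id)
            group_labels.append(group_of(col))
            sample_index.append(f"{b.batch_id}:{col}")
    mat = pd.DataFrame(np.vstack([blk.to_numpy() for blk in blocks]),
                       index=sample_index,
                       columns=order)
    return mat, batch_labels, group_labels


def silhouette_by(matrix: pd.DataFrame, labels: Sequence[str]) -> float:
    """Mean silhouette coefficient of the samples under a labelling."""
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(np.asarray(matrix, dtype=float),
                                  np.asarray(labels)))


def hca_linkage(matrix: pd.DataFrame, method: str = "ward"):
    """Hierarchical clustering (scipy linkage) of samples on Euclidean
    distances; returns (linkage matrix, leaf order)."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    Z = linkage(np.asarray(matrix, dtype=float), method=method)
    return Z, list(leaves_list(Z))
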