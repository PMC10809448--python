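"""Consensus construction of ratio-based metabolite reference datasets.

The workflow distils many laboratory batches of the four Quartet reference
materials into high-confidence per-metabolite log2 ratio reference values
for each sample pair (D5/D6, F7/D6, M8/D6):

1. *detected*: a metabolite counts as detected in a group when all three
   replicates are measured;
2. *reproducible*: detected in all four groups of the same batch, in at
   least two batches;
3. *consensus DAMs*: called differentially abundant (t-test p < alpha)
   for the pair in at least two batches;
4. *reference value*: the geometric mean of the replicate-level fold
   changes pooled across all supporting batches, stored as a log2 ratio.

Because every fold change is a within-batch ratio, per-batch multiplicative
effects cancel exactly and never move a reference value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .differential import CANONICAL_PAIRS, DAMTable, dam_test
from .errors import DegenerateInputError, FormatError
from .profiles_io import (
    GROUPS,
    REPLICATES,
    BatchProfile,
    MetaboliteKey,
    MultiBatchCollection,
)
from .qc_metrics import FilterCriteria, filter_metabolites

logger = logging.getLogger(__name__)


@dataclass
class ReferenceDataset:
    """Consensus log2 ratio reference values for one sample pair."""

    pair: tuple[str, str]
    version: str
    table: pd.DataFrame          # index MetaboliteKey; ref_log2_ratio,
                                 # n_supporting_datasets, per_dataset_log2_fcs
    provenance: dict = field(default_factory=dict)

    @property
    def metabolites(self) -> set[MetaboliteKey]:
        return set(self.table.index)

    def value_of(self, key: MetaboliteKey) -> float:
        return float(self.table.loc[key, "ref_log2_ratio"])


def detected_metabolites(profile: BatchProfile) -> dict[str, set[MetaboliteKey]]:
    """Per-group sets of metabolites measured in all three replicates."""
    out: dict[str, set[MetaboliteKey]] = {}
    for g in GROUPS:
        cols = [f"{g}-{r}" for r in REPLICATES]
        if set(cols) - set(profile.data.columns):
            out[g] = set()
            continue
        mask = profile.data[cols].notna().all(axis=1)
        out[g] = set(profile.data.index[mask])
    return out


def union_detected(collection: MultiBatchCollection,
                   ) -> dict[str, set[MetaboliteKey]]:
    """Per-group union of detected metabolites over all batches."""
    out: dict[str, set[MetaboliteKey]] = {g: set() for g in GROUPS}
    for b in collection.batches:
        per_batch = detected_metabolites(b)
        for g in GROUPS:
            out[g] |= per_batch[g]
    return out


def reproducible_set(collection: MultiBatchCollection,
                     min_batches: int = 2) -> set[MetaboliteKey]:
    """Metabolites detected in all four groups of >= ``min_batches`` batches.

    Detection follows the all-three-replicates rule, evaluated within each
    batch separately.
    """
    counts: dict[MetaboliteKey, int] = {}
    for b in collection.batches:
        per_group = detected_metabolites(b)
        full = set.intersection(*(per_group[g] for g in GROUPS))
        for key in full:
            counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= min_batches}


def per_batch_dams(collection: MultiBatchCollection, pair: tuple[str, str],
                   alpha: float = 0.05,
                   scope: Optional[set[MetaboliteKey]] = None,
                   ) -> dict[str, DAMTable]:
    """DAM tables for every batch, optionally restricted to a scope."""
    out = {}
    for b in collection.batches:
        if scope is not None:
            keep = [k for k in b.data.index if k in scope]
            b = BatchProfile(b.batch_id, b.data.loc[keep],
                             strategy=b.strategy, scale=b.scale)
        out[b.batch_id] = dam_test(b, pair, alpha=alpha)
    return out


def consensus_dams(collection: MultiBatchCollection, pair: tuple[str, str],
                   alpha: float = 0.05, min_batches: int = 2,
                   scope: Optional[set[MetaboliteKey]] = None,
                   ) -> set[MetaboliteKey]:
    """Metabolites called DAM for the pair in >= ``min_batches`` batches,
    within the reproducible set (or an explicit scope)."""
    if scope is None:
        scope = reproducible_set(collection, min_batches=min_batches)
    tables = per_batch_dams(collection, pair, alpha=alpha, scope=scope)
    counts: dict[MetaboliteKey, int] = {}
    for t in tables.values():
        for key in t.dams:
            counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= min_batches}


def _replicate_fold_changes(profile: BatchProfile, key: MetaboliteKey,
                            pair: tuple[str, str]) -> tuple[list[float], bool]:
    """Matched-index replicate-level log2 fold changes for one metabolite.

    Falls back to the single mean-based fold change (difference of mean
    log2 abundances) when no replicate index has both measurements; the
    second element reports whether the fallback was used.
    """
    num, den = pair
    row = profile.data.loc[key]
    # division before log2: a shared multiplicative batch factor cancels
    # inside the quotient, keeping reference values batch-effect-free
    fcs = []
    for r in REPLICATES:
        a, b = row.get(f"{num}-{r}"), row.get(f"{den}-{r}")
        if a is not None and b is not None and np.isfinite(a) and np.isfinite(b):
            fcs.append(float(np.log2(a / b)))
    if fcs:
        return fcs, False
    num_vals = [v for r in REPLICATES
                if np.isfinite(v := row.get(f"{num}-{r}", np.nan))]
    den_vals = [v for r in REPLICATES
                if np.isfinite(v := row.get(f"{den}-{r}", np.nan))]
    if not num_vals or not den_vals:
        return [], False
    # all-pairs mean of log2 quotients == difference of mean log2 abundances
    fc = float(np.mean([np.log2(a / b) for a in num_vals for b in den_vals]))
    return [fc], True


def build_reference(collection: MultiBatchCollection, pair: tuple[str, str],
                    alpha: float = 0.05, min_batches: int = 2,
                    version: str = "v1.0",
                    filter_criteria: Optional[FilterCriteria] = None,
                    ) -> ReferenceDataset:
    """Build the consensus reference dataset for one sample pair.

    For each consensus DAM the replicate-level fold changes of every
    supporting batch (a batch that called it a DAM) are pooled flat, and
    the reference value is the mean of their log2 values — the log-space
    geometric mean of the fold changes.  ``filter_criteria`` optionally
    applies CV/ICC filtering before the detection rule (off by default).
    """
    scope = reproducible_set(collection, min_batches=min_batches)
    if filter_criteria is not None:
        allowed: set[MetaboliteKey] = set()
        for b in collection.batches:
            allowed |= filter_metabolites(b, filter_criteria)
        scope &= allowed
    tables = per_batch_dams(collection, pair, alpha=alpha, scope=scope)
    counts: dict[MetaboliteKey, int] = {}
    for t in tables.values():
        for key in t.dams:
            counts[key] = counts.get(key, 0) + 1
    consensus = {k for k, c in counts.items() if c >= min_batches}
    if not consensus:
        raise DegenerateInputError(
            f"no consensus DAM for pair {pair[0]}/{pair[1]}")
    ordered = sorted(collection.batches, key=lambda b: b.batch_id)
    rows = []
    for key in sorted(consensus):
        pooled: list[float] = []
        per_dataset: list[str] = []
        n_support = 0
        # canonical batch order keeps the pooled mean independent of the
        # order in which batches were supplied
        for b in ordered:
            if key not in tables[b.batch_id].dams:
                continue
            fcs, fallback = _replicate_fold_changes(b, key, pair)
            if not fcs:
                continue
            if fallback:
                logger.info("batch %s: no matched replicates for %r; "
                            "using mean-based fold change", b.batch_id, key)
            pooled.extend(fcs)
            per_dataset.append(
                f"{b.batch_id}:" + ",".join(f"{v:.6g}" for v in fcs))
            n_support += 1
        rows.append((key, float(np.mean(pooled)), n_support,
                     ";".join(per_dataset)))
    table = pd.DataFrame(rows, columns=[
        "metabolite", "ref_log2_ratio", "n_supporting_datasets",
        "per_dataset_log2_fcs"]).set_index("metabolite")
    table.index.name = None
    return ReferenceDataset(
        pair=pair, version=version, table=table,
        provenance={
            "alpha": alpha, "min_batches": min_batches,
            "n_batches": len(collection.batches),
            "n_reproducible": len(scope),
            "filtered": filter_criteria is not None,
        })


def build_all_references(collection: MultiBatchCollection,
                         pairs: Sequence[tuple[str, str]] = CANONICAL_PAIRS,
                         **kwargs) -> dict[tuple[str, str], ReferenceDataset]:
    return {pair: build_reference(collection, pair, **kwargs)
            for pair in pairs}


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_reference(ref: ReferenceDataset, path: Union[str, Path]) -> None:
    """One TSV per pair: hmdb_id, name, ref_log2_ratio, support columns."""
    path = Path(path)
    idx = ref.table.index
    out = pd.DataFrame({
        "hmdb_id": [k.hmdb_id or "" for k in idx],
        "name": [k.name for k in idx],
        "ref_log2_ratio": ref.table["ref_log2_ratio"].to_numpy(),
        "n_supporting_datasets":
            ref.table["n_supporting_datasets"].to_numpy(),
        "per_dataset_log2_fcs":
            ref.table["per_dataset_log2_fcs"].to_numpy(),
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pair={ref.pair[0]}/{ref.pair[1]}\n")
        fh.write(f"# version={ref.version}\n")
        for k, v in sorted(ref.provenance.items()):
            fh.write(f"# {k}={v}\n")
        out.to_csv(fh, sep="\t", index=False,
                   float_format=lambda v: repr(float(v)))


def read_reference(path: Union[str, Path]) -> ReferenceDataset:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    if "pair" not in meta:
        raise FormatError(f"{path}: missing '# pair=' header")
    num, den = meta["pair"].split("/")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     dtype=str, keep_default_na=False)
    for c in ("hmdb_id", "name", "ref_log2_ratio", "n_supporting_datasets"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    keys = [MetaboliteKey(h or None, n)
            for h, n in zip(df["hmdb_id"], df["name"])]
    table = pd.DataFrame({
        "ref_log2_ratio": [float(v) for v in df["ref_log2_ratio"]],
        "n_supporting_datasets":
            pd.to_numeric(df["n_supporting_datasets"]).astype(int),
        "per_dataset_log2_fcs": df.get(
            "per_dataset_log2_fcs", pd.Series([""] * len(df))),
    })
    table.index = keys
    provenance = {k: v for k, v in meta.items() if k not in ("pair", "version")}
    return ReferenceDataset(pair=(num, den), version=meta.get("version", ""),
                            table=table, provenance=provenance)
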