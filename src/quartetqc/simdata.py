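"""Synthetic multi-laboratory Quartet-style data with known ground truth.

The generator emulates the structure that drives the QC suite: several
laboratories each measure the same four reference materials (D5, D6, F7,
M8) in triplicate.  On the log2 scale,

    value(lab, metabolite k, group s, replicate r)
        = baseline_k + effect_{k,s} + batch_offset_{lab,k} + noise

with per-metabolite baselines, per-(metabolite, group) biological effects
(a random component for every metabolite plus planted fold changes versus
D6 for a DAM fraction), per-lab-x-metabolite additive batch offsets shared
by all 12 samples of a batch (exactly the structure ratio scaling cancels),
iid replicate noise, and missing-completely-at-random dropout per
(metabolite, lab) — whole-metabolite by default, mirroring panel
selectivity across laboratories; a per-cell mode exists for complete-case
tests.  A misspecification mode adds group-dependent batch effects, which
ratio scaling does not fully cancel.

One integer seed drives a single documented numpy Generator stream with
per-lab substreams spawned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import CANONICAL_PAIRS
from .errors import ValidationError
from .profiles_io import (
    GROUPS,
    SAMPLE_COLUMNS,
    BatchProfile,
    MetaboliteKey,
    MultiBatchCollection,
    harmonize,
)
from .reference_builder import ReferenceDataset

REF_GROUP = "D6"
NONREF_GROUPS = tuple(g for g in GROUPS if g != REF_GROUP)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic multi-laboratory experiment.

    Defaults emulate the cross-laboratory study setting: 7 laboratories,
    200-metabolite panels, a quarter of the panel carrying planted
    |log2 FC| in [1, 3] versus D6, 0.2 log2 replicate noise (roughly a 15%
    CV), lab-dominating batch offsets (SD 1.0 log2), and 10%
    whole-metabolite dropout per laboratory.
    """

    n_metabolites: int = 200
    n_labs: int = 7
    n_runs_per_lab: int = 1
    group_effect_sd: float = 0.5
    frac_dam: float = 0.25
    dam_log2fc_range: tuple[float, float] = (1.0, 3.0)
    batch_effect_sd: float = 1.0
    replicate_sd: float = 0.2
    dropout_prob: float = 0.1
    dropout_mode: str = "metabolite"       # or "cell"
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    group_dependent_batch_effects: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.dam_log2fc_range
        if not (0 < lo <= hi):
            raise ValidationError("dam_log2fc_range needs 0 < lo <= hi")
        for name in ("group_effect_sd", "batch_effect_sd", "replicate_sd",
                     "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.frac_dam <= 1 or not 0 <= self.dropout_prob <= 1:
            raise ValidationError("fractions must lie in [0, 1]")
        if self.dropout_mode not in ("metabolite", "cell"):
            raise ValidationError(f"unknown dropout mode {self.dropout_mode!r}")
        if self.n_metabolites < 1 or self.n_labs < 1 or self.n_runs_per_lab < 1:
            raise ValidationError("counts must be positive")


@dataclass
class SimTruth:
    """Ground truth behind one simulated collection."""

    keys: list[MetaboliteKey]
    baseline: np.ndarray                  # (n_metabolites,)
    group_effects: pd.DataFrame           # metabolite x group, log2
    dam_mask: np.ndarray                  # planted-DAM indicator
    batch_offsets: pd.DataFrame           # metabolite x batch_id, log2
    dropout: pd.DataFrame                 # metabolite x batch_id, bool
    config: SimConfig

    def true_log2fc(self, pair: tuple[str, str]) -> pd.Series:
        """Exact log2 fold change effect(A) − effect(B) per metabolite."""
        num, den = pair
        return self.group_effects[num] - self.group_effects[den]

    def dam_status(self, pair: tuple[str, str]) -> pd.Series:
        """Planted-DAM indicator for a canonical pair versus D6."""
        fc = self.true_log2fc(pair)
        planted = pd.Series(self.dam_mask, index=self.group_effects.index)
        return planted & (fc.abs() > 0)


def simulate(config: SimConfig) -> tuple[MultiBatchCollection, SimTruth]:
    """Draw one synthetic multi-laboratory collection plus its truth.

    The same seed always yields bit-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    global_ss, labs_ss = root.spawn(2)
    rng = np.random.default_rng(global_ss)
    nm = config.n_metabolites
    keys = [MetaboliteKey(f"HMDB{k + 1:07d}", f"metabolite_{k + 1:04d}")
            for k in range(nm)]
    baseline = rng.normal(config.baseline_log2_mean,
                          config.baseline_log2_sd, size=nm)
    effects = rng.normal(0.0, config.group_effect_sd, size=(nm, len(GROUPS)))
    dam_mask = rng.random(nm) < config.frac_dam
    lo, hi = config.dam_log2fc_range
    for gi, g in enumerate(GROUPS):
        if g == REF_GROUP:
            continue
        magnitude = rng.uniform(lo, hi, size=nm)
        sign = rng.choice([-1.0, 1.0], size=nm)
        effects[:, gi] += np.where(dam_mask, sign * magnitude, 0.0)
    group_effects = pd.DataFrame(effects, index=keys, columns=list(GROUPS))

    batch_ids = []
    batches = []
    offsets = {}
    dropout_cols = {}
    lab_streams = labs_ss.spawn(config.n_labs)
    for li, lab_ss in enumerate(lab_streams):
        lab_rng = np.random.default_rng(lab_ss)
        offset = lab_rng.normal(0.0, config.batch_effect_sd, size=nm)
        group_offset = (
            lab_rng.normal(0.0, config.batch_effect_sd,
                           size=(nm, len(GROUPS)))
            if config.group_dependent_batch_effects else None)
        for run in range(config.n_runs_per_lab):
            batch_id = (f"L{li + 1}" if config.n_runs_per_lab == 1
                        else f"L{li + 1}_run{run + 1:02d}")
            batch_ids.append(batch_id)
            offsets[batch_id] = offset
            log2vals = np.empty((nm, len(SAMPLE_COLUMNS)))
            for ci, col in enumerate(SAMPLE_COLUMNS):
                g = col.split("-")[0]
                gi = GROUPS.index(g)
                noise = lab_rng.normal(0.0, config.replicate_sd, size=nm)
                log2vals[:, ci] = (baseline + effects[:, gi] + offset + noise)
                if group_offset is not None:
                    log2vals[:, ci] += group_offset[:, gi]
            values = np.exp2(log2vals)
            if config.dropout_mode == "metabolite":
                drop = lab_rng.random(nm) < config.dropout_prob
                values[drop, :] = np.nan
            else:
                drop_cells = lab_rng.random(values.shape) < config.dropout_prob
                values[drop_cells] = np.nan
                drop = np.isnan(values).all(axis=1)
            dropout_cols[batch_id] = drop
            df = pd.DataFrame(values, index=list(keys),
                              columns=list(SAMPLE_COLUMNS))
            batches.append(BatchProfile(batch_id, df))
    truth = SimTruth(
        keys=keys,
        baseline=baseline,
        group_effects=group_effects,
        dam_mask=dam_mask,
        batch_offsets=pd.DataFrame(offsets, index=keys),
        dropout=pd.DataFrame(dropout_cols, index=keys),
        config=config,
    )
    return harmonize(batches), truth


def plant_reference(truth: SimTruth, version: str = "truth",
                    ) -> dict[tuple[str, str], ReferenceDataset]:
    """Reference datasets holding the planted fold changes of the truth.

    One dataset per canonical pair, rows exactly the planted DAMs with
    their true log2 fold changes — the oracle for recall/RC recovery.
    """
    out = {}
    for pair in CANONICAL_PAIRS:
        status = truth.dam_status(pair)
        fc = truth.true_log2fc(pair)
        keys = [k for k in truth.keys if status.loc[k]]
        table = pd.DataFrame({
            "ref_log2_ratio": [float(fc.loc[k]) for k in keys],
            "n_supporting_datasets": truth.config.n_labs,
            "per_dataset_log2_fcs": "",
        }, index=keys)
        out[pair] = ReferenceDataset(pair=pair, version=version, table=table,
                                     provenance={"source": "synthetic truth"})
    return out
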