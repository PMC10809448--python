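"""Data model and I/O for Quartet reference-material metabolite profiles.

A *batch* is one laboratory run of the four Quartet reference materials
(D5, D6 = monozygotic twin daughters; F7 = father; M8 = mother), each
measured in triplicate, giving at most 12 samples per batch.  Profiles are
held as a pandas DataFrame with :class:`MetaboliteKey` rows and sample
columns named ``"<group>-<replicate>"`` (``D5-1`` … ``M8-3``); missing
measurements are NaN.  Zero and negative abundances are coerced to missing:
MS intensities are positive, and exported zeros conventionally encode
non-detection.

Cross-batch harmonisation merges metabolites first by normalised HMDB
accession and, for entries without an accession, by case-folded
whitespace-collapsed name.  No fuzzy matching is attempted — a false merge
is worse for QC than a false split.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ValidationError

GROUPS: tuple[str, ...] = ("D5", "D6", "F7", "M8")
REPLICATES: tuple[int, ...] = (1, 2, 3)

#: Canonical sample labels in acquisition (run) order: one replicate of each
#: material, then the next replicate round.
SAMPLE_COLUMNS: tuple[str, ...] = tuple(
    f"{g}-{r}" for r in REPLICATES for g in GROUPS
)

_HMDB_RE = re.compile(r"^HMDB(\d+)$")
_SAMPLE_RE = re.compile(r"^([A-Za-z0-9]+)-(\d+)$")


def normalize_hmdb_id(raw: str) -> str:
    """Normalise an HMDB accession to the canonical 7-digit form.

    Accepts legacy 5-digit and current 7-digit accessions; whitespace is
    stripped and case ignored.  ``HMDB123`` -> ``HMDB0000123``.
    """
    s = str(raw).strip().upper()
    m = _HMDB_RE.match(s)
    if m is None:
        raise ValidationError(f"not a valid HMDB accession: {raw!r}")
    return f"HMDB{int(m.group(1)):07d}"


def _fold_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


class MetaboliteKey:
    """Identity of one metabolite: HMDB accession and/or free-text name.

    Equality and hashing use the *merge identity*: the normalised HMDB ID
    when present, otherwise the case-folded, whitespace-collapsed name.
    The display name and HMDB class annotation are metadata and do not
    participate in comparisons, so harmonised namespaces are invariant to
    batch order.
    """

    __slots__ = ("hmdb_id", "name", "class_label")

    def __init__(self, hmdb_id: Optional[str] = None, name: str = "",
                 class_label: str = ""):
        hmdb = normalize_hmdb_id(hmdb_id) if hmdb_id else None
        name = str(name).strip() if name is not None else ""
        if not hmdb and not name:
            raise ValidationError(
                "a metabolite needs an HMDB accession or a name")
        object.__setattr__(self, "hmdb_id", hmdb)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "class_label", class_label or "")

    def __setattr__(self, *_):  # immutable; keys index DataFrames
        raise AttributeError("MetaboliteKey is immutable")

    @property
    def identity(self) -> tuple[str, str]:
        if self.hmdb_id:
            return ("hmdb", self.hmdb_id)
        return ("name", _fold_name(self.name))

    def with_class(self, class_label: str) -> "MetaboliteKey":
        return MetaboliteKey(self.hmdb_id, self.name, class_label)

    def __eq__(self, other):
        return (isinstance(other, MetaboliteKey)
                and self.identity == other.identity)

    def __hash__(self):
        return hash(self.identity)

    def __lt__(self, other: "MetaboliteKey"):
        return self.identity < other.identity

    def __repr__(self):
        return f"MetaboliteKey({self.hmdb_id!r}, {self.name!r})"


@dataclass(frozen=True)
class SampleKey:
    """One of the 12 canonical samples: Quartet group x replicate index."""

    group: str
    replicate: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown Quartet group {self.group!r}; expected one of {GROUPS}")
        if self.replicate not in REPLICATES:
            raise ValidationError(
                f"replicate must be one of {REPLICATES}, got {self.replicate}")

    @property
    def label(self) -> str:
        return f"{self.group}-{self.replicate}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        m = _SAMPLE_RE.match(str(label).strip())
        if m is None:
            raise FormatError(f"malformed sample column {label!r}; "
                              "expected '<group>-<replicate>'")
        return cls(m.group(1), int(m.group(2)))


def group_of(label: str) -> str:
    return SampleKey.from_label(label).group


@dataclass
class BatchProfile:
    """One laboratory batch: metabolite x (group, replicate) abundances.

    ``data`` rows are :class:`MetaboliteKey`, columns a subset of the 12
    canonical sample labels; NaN marks missing measurements.  All present
    values are strictly positive.
    """

    batch_id: str
    data: pd.DataFrame
    strategy: str = "targeted"
    scale: str = "raw_abundance"

    def __post_init__(self):
        if self.strategy not in ("targeted", "untargeted"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.scale not in ("raw_abundance", "concentration"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        df = self.data.copy()
        for col in df.columns:
            SampleKey.from_label(col)  # validates group & replicate
        order = [c for c in SAMPLE_COLUMNS if c in df.columns]
        df = df[order]
        vals = df.to_numpy(dtype=float, copy=True)
        vals[~(vals > 0)] = np.nan  # zero/negative -> missing
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
        dup = pd.Index(df.index).duplicated()
        if dup.any():
            bad = [repr(k) for k, d in zip(df.index, dup) if d]
            raise IntegrityError(
                f"batch {self.batch_id!r}: duplicate metabolites {bad}")
        self.data = df

    @property
    def metabolites(self) -> list[MetaboliteKey]:
        return list(self.data.index)

    def detected_any(self) -> set[MetaboliteKey]:
        """Metabolites with at least one non-missing value."""
        mask = self.data.notna().any(axis=1)
        return set(self.data.index[mask])


@dataclass
class MultiBatchCollection:
    """Batches sharing one harmonised metabolite namespace."""

    batches: list[BatchProfile]
    synonyms: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.batches)

    def __len__(self):
        return len(self.batches)

    @property
    def metabolites(self) -> set[MetaboliteKey]:
        out: set[MetaboliteKey] = set()
        for b in self.batches:
            out.update(b.data.index)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("hmdb_id", "name", "group", "replicate", "value")


def _delimiter_for(path: Union[str, Path]) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _float_repr(v) -> str:
    # shortest decimal string that round-trips to the same binary64
    return repr(float(v))


def _parse_float(s) -> float:
    try:
        return float(s)
    except (TypeError, ValueError):
        return float("nan")


def _to_positive(series: pd.Series) -> np.ndarray:
    # float() is correctly rounded, so written values round-trip bit-exactly
    vals = np.array([_parse_float(x) for x in series], dtype=float)
    vals[~(vals > 0)] = np.nan
    return vals


def read_profile(path: Union[str, Path], dialect: str, *,
                 batch_id: Optional[str] = None, strategy: str = "targeted",
                 scale: str = "raw_abundance") -> BatchProfile:
    """Read a long or wide CSV/TSV metabolite table into a BatchProfile.

    Long dialect columns: hmdb_id, name, group, replicate, value.
    Wide dialect columns: hmdb_id, name, then sample columns ``D5-1``…``M8-3``.
    Blank, non-numeric and non-positive cells are recorded as missing.
    """
    path = Path(path)
    if batch_id is None:
        batch_id = path.stem
    sep = _delimiter_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if dialect == "long":
        missing = [c for c in _LONG_COLUMNS if c not in raw.columns]
        if missing:
            raise FormatError(f"long table missing column(s) {missing}")
        keys, labels = [], []
        for _, row in raw.iterrows():
            keys.append(MetaboliteKey(row["hmdb_id"] or None, row["name"]))
            try:
                rep = int(row["replicate"])
            except ValueError as exc:
                raise FormatError(
                    f"non-integer replicate {row['replicate']!r}") from exc
            labels.append(SampleKey(str(row["group"]).strip(), rep).label)
        cells = pd.DataFrame({
            "key": keys, "label": labels, "value": _to_positive(raw["value"]),
        })
        dup = cells.duplicated(subset=["key", "label"])
        if dup.any():
            first = cells[dup].iloc[0]
            raise IntegrityError(
                f"duplicate cell for {first['key']!r} / {first['label']}")
        wide = cells.pivot(index="key", columns="label", values="value")
        wide.index.name = None
        wide.columns.name = None
        return BatchProfile(batch_id, wide, strategy=strategy, scale=scale)
    if dialect == "wide":
        for c in ("hmdb_id", "name"):
            if c not in raw.columns:
                raise FormatError(f"wide table missing column {c!r}")
        sample_cols = [c for c in raw.columns if c not in ("hmdb_id", "name")]
        for c in sample_cols:
            SampleKey.from_label(c)  # FormatError / ValidationError
        keys = [MetaboliteKey(row["hmdb_id"] or None, row["name"])
                for _, row in raw.iterrows()]
        data = pd.DataFrame(
            {c: _to_positive(raw[c]) for c in sample_cols},
            index=keys)
        return BatchProfile(batch_id, data, strategy=strategy, scale=scale)
    raise ValidationError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def write_profile(profile: BatchProfile, path: Union[str, Path],
                  dialect: str = "wide") -> None:
    """Write a profile as UTF-8 CSV/TSV; missing values become empty cells."""
    path = Path(path)
    sep = _delimiter_for(path)
    idx = profile.data.index
    meta = pd.DataFrame({
        "hmdb_id": [k.hmdb_id or "" for k in idx],
        "name": [k.name for k in idx],
    })
    if dialect == "wide":
        body = profile.data.reset_index(drop=True)
        out = pd.concat([meta, body], axis=1)
        out.to_csv(path, sep=sep, index=False, na_rep="", encoding="utf-8",
                   float_format=_float_repr)
        return
    if dialect == "long":
        rows = []
        for key, series in profile.data.iterrows():
            for label, val in series.items():
                sk = SampleKey.from_label(label)
                rows.append((key.hmdb_id or "", key.name, sk.group,
                             sk.replicate,
                             "" if pd.isna(val) else _float_repr(val)))
        pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(
            path, sep=sep, index=False, na_rep="", encoding="utf-8")
        return
    raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def harmonize(batches: Sequence[BatchProfile]) -> MultiBatchCollection:
    """Merge metabolite namespaces across batches.

    Metabolites sharing a normalised HMDB accession become one key; the
    remainder merge by case-folded name.  The merge never collapses two
    distinct metabolites within one batch.  The resulting namespace is
    invariant to batch order (display names are first-seen; all synonyms
    are kept as collection metadata).
    """
    if not batches:
        raise ValidationError("harmonize needs at least one batch")
    canonical: dict[tuple[str, str], MetaboliteKey] = {}
    names: dict[tuple[str, str], set[str]] = {}
    for b in batches:
        seen: dict[tuple[str, str], MetaboliteKey] = {}
        for key in b.data.index:
            ident = key.identity
            if ident in seen:
                raise IntegrityError(
                    f"batch {b.batch_id!r}: {seen[ident]!r} and {key!r} "
                    "map to the same harmonised key")
            seen[ident] = key
            if ident not in canonical:
                canonical[ident] = key
            elif not canonical[ident].class_label and key.class_label:
                canonical[ident] = canonical[ident].with_class(key.class_label)
            names.setdefault(ident, set()).add(key.name)
    out = []
    for b in batches:
        new_index = [canonical[k.identity] for k in b.data.index]
        df = b.data.copy()
        df.index = new_index
        out.append(BatchProfile(b.batch_id, df, strategy=b.strategy,
                                scale=b.scale))
    synonyms = {ident: tuple(sorted(v)) for ident, v in names.items()}
    return MultiBatchCollection(out, synonyms)


def complete_case_metabolites(profile: BatchProfile) -> set[MetaboliteKey]:
    """Metabolites measured in all 12 samples of the batch."""
    df = profile.data
    if set(SAMPLE_COLUMNS) - set(df.columns):
        return set()
    mask = df[list(SAMPLE_COLUMNS)].notna().all(axis=1)
    return set(df.index[mask])


def annotate_classes(collection: MultiBatchCollection,
                     table: Union[str, Path, pd.DataFrame],
                     ) -> MultiBatchCollection:
    """Attach HMDB taxonomy classes from an annotation table.

    The table needs columns ``hmdb_id`` and ``class_label``; metabolites
    without a matching accession keep an empty class.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=_delimiter_for(table), dtype=str,
                            keep_default_na=False)
    for c in ("hmdb_id", "class_label"):
        if c not in table.columns:
            raise FormatError(f"annotation table missing column {c!r}")
    mapping: dict[str, str] = {}
    for _, row in table.iterrows():
        hid = normalize_hmdb_id(row["hmdb_id"])
        cls = str(row["class_label"]).strip()
        if hid in mapping and mapping[hid] != cls:
            raise IntegrityError(
                f"conflicting class annotations for {hid}: "
                f"{mapping[hid]!r} vs {cls!r}")
        mapping[hid] = cls
    def _annot(key: MetaboliteKey) -> MetaboliteKey:
        if key.hmdb_id and key.hmdb_id in mapping:
            return key.with_class(mapping[key.hmdb_id])
        return key.with_class("")
    out = []
    for b in collection.batches:
        df = b.data.copy()
        df.index = [_annot(k) for k in df.index]
        out.append(BatchProfile(b.batch_id, df, strategy=b.strategy,
                                scale=b.scale))
    return MultiBatchCollection(out, dict(collection.synonyms))
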