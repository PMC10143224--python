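"""Core data containers: compound records and activity classes.

An *activity class* is the set of compounds with measured potency (pIC50,
the negative decadic logarithm of the IC50 in mol/L) against one protein
target. Classes carry a provenance tag so that modified variants (potency
balanced, nearest-neighbor depleted, randomly reduced) remain
distinguishable from the original sets they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

PROVENANCES = ("original", "balanced", "nn_removed", "random_reduced")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier, structure, potency and optional annotations.

    ``potency`` is a pIC50; after curation it lies in [5, 11] and
    ``structure`` is a parseable SMILES. ``series_id`` is a ground-truth
    analog-series label available for synthetic data only; predictors never
    see it.
    """

    compound_id: str
    class_id: str
    structure: str
    potency: float
    mw: float | None = None
    relation: str | None = None
    flags: frozenset[str] = frozenset()
    series_id: str | None = None


@dataclass
class ActivityClass:
    """A named, ordered set of compound records with a provenance tag."""

    class_id: str
    records: list[CompoundRecord]
    provenance: str = "original"
    lineage: str = "original"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"activity class {self.class_id!r} is empty")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate compound_ids in class {self.class_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def potencies(self) -> list[float]:
        return [r.potency for r in self.records]

    def subset(self, ids: Iterable[str], provenance: str, lineage: str) -> "ActivityClass":
        """New class containing the records with the given ids, input order kept."""
        wanted = set(ids)
        kept = [r for r in self.records if r.compound_id in wanted]
        return ActivityClass(self.class_id, kept, provenance=provenance, lineage=lineage)


_CSV_COLUMNS = ("compound_id", "class_id", "smiles", "pIC50", "mw", "relation", "flags", "series_id")


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = [
        {
            "compound_id": r.compound_id,
            "class_id": r.class_id,
            "smiles": r.structure,
            "pIC50": r.potency,
            "mw": r.mw,
            "relation": r.relation,
            "flags": ";".join(sorted(r.flags)) if r.flags else "",
            "series_id": r.series_id,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CompoundRecord]:
    records = []
    for row in df.itertuples(index=False):
        flags = getattr(row, "flags", None)
        flags = frozenset(str(flags).split(";")) if isinstance(flags, str) and flags else frozenset()
        mw = getattr(row, "mw", None)
        relation = getattr(row, "relation", None)
        series_id = getattr(row, "series_id", None)
        records.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                class_id=str(row.class_id),
                structure=str(row.smiles),
                potency=float(row.pIC50),
                mw=None if mw is None or pd.isna(mw) else float(mw),
                relation=None if relation is None or pd.isna(relation) else str(relation),
                flags=flags,
                series_id=None if series_id is None or pd.isna(series_id) else str(series_id),
            )
        )
    return records


def write_records_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (compound_id, class_id, smiles, pIC50[, ...])."""
    df = pd.read_csv(path)
    missing = {"compound_id", "class_id", "smiles", "pIC50"} - set(df.columns)
    if missing:
        raise ValueError(f"input CSV missing required columns: {sorted(missing)}")
    return frame_to_records(df)


def write_classes_csv(classes: Sequence[ActivityClass], path: str | Path) -> None:
    records = [r for cls in classes for r in cls.records]
    write_records_csv(records, path)


def classes_from_records(records: Sequence[CompoundRecord]) -> list[ActivityClass]:
    """Group records by class_id, preserving record order within each class."""
    by_class: dict[str, list[CompoundRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_id, []).append(r)
    return [ActivityClass(cid, recs) for cid, recs in by_class.items()]
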