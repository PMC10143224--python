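"""Record-level curation of compound activity tables.

Mirrors the standard high-confidence selection protocol for bioactivity
data: compounds below a molecular-weight cap, with exact potency
measurements (relation "="), pIC50 inside a fixed support, no suspect
annotation flags, and parseable structures; classes must reach a minimum
size. Database-specific pre-extraction requirements (e.g. direct target
relationship, maximum assay confidence, IC50 as the standard type when
exporting from ChEMBL) are expectations on how the input CSV was built and
are documented rather than re-checked here, keeping the pipeline
source-agnostic.

Filter rules are applied in a fixed, documented order; the audit counts a
record only under the first rule it fails, so the audit is a partition of
the input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Callable, Sequence

from rdkit import Chem

from .containers import ActivityClass, CompoundRecord

#: Rule order for the audit; a record failing several rules counts under the first.
RULE_ORDER = ("structure", "relation", "mw", "potency_range", "flags", "interference")

DEFAULT_EXCLUDED_FLAGS = frozenset(
    {"potential transcription error", "potential author error"}
)


@dataclass(frozen=True)
class CurationConfig:
    """Curation rules.

    ``max_mw`` is exclusive ("less than 1000 Da"); ``potency_range`` is the
    closed pIC50 interval kept; ``interference_filter`` is an optional hook
    for substructure-based assay-interference screens (a callable mapping a
    SMILES to True when the compound should be rejected).
    """

    max_mw: float = 1000.0
    potency_range: tuple[float, float] = (5.0, 11.0)
    required_relation: str = "="
    excluded_flags: frozenset[str] = DEFAULT_EXCLUDED_FLAGS
    min_class_size: int = 50
    interference_filter: Callable[[str], bool] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.potency_range
        if not (0.0 < lo < hi < 14.0):
            raise ValueError("potency_range must lie within (0, 14)")
        if self.min_class_size < 2:
            raise ValueError("min_class_size must be >= 2")


def _first_failing_rule(record: CompoundRecord, config: CurationConfig) -> str | None:
    if Chem.MolFromSmiles(record.structure) is None:
        return "structure"
    if record.relation is not None and record.relation != config.required_relation:
        return "relation"
    if record.mw is not None and record.mw >= config.max_mw:
        return "mw"
    lo, hi = config.potency_range
    if not (lo <= record.potency <= hi):
        return "potency_range"
    if record.flags & config.excluded_flags:
        return "flags"
    if config.interference_filter is not None and config.interference_filter(record.structure):
        return "interference"
    return None


def apply_filters(
    records: Sequence[CompoundRecord], config: CurationConfig | None = None
) -> tuple[list[CompoundRecord], dict[str, int]]:
    """Apply all curation rules, preserving record order.

    Returns the kept records and an audit of per-rule rejection counts
    (plus a ``kept`` entry); the counts partition the input. Idempotent:
    re-filtering the kept records changes nothing.
    """
    config = config or CurationConfig()
    audit = {rule: 0 for rule in RULE_ORDER}
    kept: list[CompoundRecord] = []
    for record in records:
        rule = _first_failing_rule(record, config)
        if rule is None:
            kept.append(record)
        else:
            audit[rule] += 1
    audit["kept"] = len(kept)
    return kept, audit


def _collapse_duplicates(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Merge repeated compound_ids into one record with the median potency."""
    by_id: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.compound_id not in by_id:
            order.append(r.compound_id)
        by_id.setdefault(r.compound_id, []).append(r)
    out = []
    for cid in order:
        group = by_id[cid]
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(replace(group[0], potency=float(median(r.potency for r in group))))
    return out


def assemble_classes(
    records: Sequence[CompoundRecord], min_class_size: int = 50
) -> list[ActivityClass]:
    """Group curated records into activity classes of at least ``min_class_size``.

    Within a class, repeated compound_ids (multiple measurements) collapse
    to a single record carrying the median pIC50. Classes are returned
    sorted by descending size, ties broken by class_id.
    """
    by_class: dict[str, list[CompoundRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_id, []).append(r)
    classes = []
    for cid, recs in by_class.items():
        collapsed = _collapse_duplicates(recs)
        if len(collapsed) >= min_class_size:
            classes.append(ActivityClass(cid, collapsed, provenance="original", lineage="curated"))
    classes.sort(key=lambda c: (-len(c), c.class_id))
    return classes


def curate(
    records: Sequence[CompoundRecord], config: CurationConfig | None = None
) -> tuple[list[ActivityClass], dict[str, int]]:
    """Filter records and assemble qualifying activity classes."""
    config = config or CurationConfig()
    kept, audit = apply_filters(records, config)
    return assemble_classes(kept, config.min_class_size), audit
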