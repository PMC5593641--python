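"""Fuzzy-logic tissue-level diagnosis from per-cell classifications.

The per-cell classifiers say nothing about the specimen; the bridge is a
deliberately simple fuzzy rule: the share of each class among a specimen's
classified cells is read as the probability of that tissue-level diagnosis,
and the largest share is the reported diagnosis. A specimen with 80% normal
cells is "80% probably normal, 20% probably malignant".

Abstained cells are excluded from the denominator but always reported, so
accuracy statements can be read as "of the cells the classifier committed
to". Display percentages are rounded half-away-from-zero to two decimals;
machine outputs keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import DefinitionError
from .knn import ABSTAIN

__all__ = [
    "SEVERITY_PATHOLOGY",
    "SEVERITY_GLEASON",
    "TissueComposition",
    "compose",
    "compositions_by_specimen",
    "majority_diagnosis",
    "composition_table",
    "deterministic_call",
    "round_half_away",
]

#: Severity orders used for conservative (toward-malignancy) tie-breaking.
SEVERITY_PATHOLOGY = ("B", "ASAP", "AC", "LAC", "StageII", "StageIII")
SEVERITY_GLEASON = ("B", "G33", "G34", "G43")

INDETERMINATE = "indeterminate"


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TissueComposition:
    """Class counts/fractions of one specimen's classified cells.

    ``majority_fraction`` is interpreted as the probability of the
    tissue-level diagnosis ``majority_label``. ``status`` is 'ok' or
    'indeterminate' (zero classified cells).
    """

    specimen_id: str
    counts: dict[str, int]
    fractions: dict[str, float]
    majority_label: str | None
    majority_fraction: float | None
    n_cells: int
    n_abstained: int
    status: str
    tie: bool

    @property
    def n_classified(self) -> int:
        return self.n_cells - self.n_abstained


def _severity_order(labels: Iterable[str], severity: Sequence[str] | None) -> list[str]:
    if severity is not None:
        return list(severity)
    labels = set(labels)
    for order in (SEVERITY_PATHOLOGY, SEVERITY_GLEASON):
        if labels <= set(order):
            return list(order)
    # fall back to binary normal/aberrant or alphabetical order
    if labels <= {"normal", "aberrant"}:
        return ["normal", "aberrant"]
    return sorted(labels)


def compose(
    cell_labels: Sequence[str],
    specimen_id: str = "",
    severity: Sequence[str] | None = None,
) -> TissueComposition:
    """Aggregate one specimen's cell labels into a tissue composition.

    Abstentions (ABSTAIN) are excluded from the fractions and counted
    separately. Zero classified cells yields an explicit indeterminate
    composition rather than an exception. Order-invariant by construction.
    """
    labels = np.asarray(list(cell_labels), dtype=object)
    n_cells = len(labels)
    if n_cells == 0:
        raise DefinitionError("specimen has no cells")
    classified = labels[labels != ABSTAIN]
    n_abstained = n_cells - len(classified)
    if len(classified) == 0:
        return TissueComposition(
            specimen_id=specimen_id,
            counts={},
            fractions={},
            majority_label=None,
            majority_fraction=None,
            n_cells=n_cells,
            n_abstained=n_abstained,
            status=INDETERMINATE,
            tie=False,
        )
    order = _severity_order(classified, severity)
    unknown = set(classified) - set(order)
    if unknown:
        raise DefinitionError(f"labels outside severity order: {sorted(unknown)}")
    counts = {cls: int((classified == cls).sum()) for cls in order}
    total = len(classified)
    fractions = {cls: c / total for cls, c in counts.items()}
    comp = TissueComposition(
        specimen_id=specimen_id,
        counts=counts,
        fractions=fractions,
        majority_label=None,
        majority_fraction=None,
        n_cells=n_cells,
        n_abstained=n_abstained,
        status="ok",
        tie=False,
    )
    label, frac, tie = majority_diagnosis(comp, severity=order)
    comp.majority_label = label
    comp.majority_fraction = frac
    comp.tie = tie
    return comp


def majority_diagnosis(
    composition: TissueComposition,
    severity: Sequence[str] | None = None,
) -> tuple[str | None, float | None, bool]:
    """Largest-share diagnosis with its probability (the share itself).

    An exact tie is resolved toward the more severe class under the severity
    order (conservative toward malignancy) and flagged. Indeterminate
    compositions propagate as (None, None, False).
    """
    if composition.status == INDETERMINATE:
        return None, None, False
    order = _severity_order(composition.counts, severity)
    best = max(composition.counts.values())
    winners = [cls for cls in order if composition.counts.get(cls, 0) == best]
    tie = len(winners) > 1
    label = winners[-1]  # most severe among tied classes
    return label, composition.fractions[label], tie


def composition_table(
    compositions: Sequence[TissueComposition],
    class_order: Sequence[str],
) -> pd.DataFrame:
    """Report table: one count row and one percentage row per specimen.

    Percentages are shares of classified cells rounded half-away-from-zero to
    two decimals; the Total column shows the exact classified count on count
    rows and 100.0 on percentage rows.
    """
    class_order = list(class_order)
    rows = []
    index = []
    for comp in compositions:
        unknown = {c for c, n in comp.counts.items() if n > 0} - set(class_order)
        if unknown:
            raise DefinitionError(f"classes outside class_order: {sorted(unknown)}")
        counts = [comp.counts.get(cls, 0) for cls in class_order]
        total = sum(counts)
        rows.append(counts + [total])
        index.append(comp.specimen_id)
        if total > 0:
            pct = [round_half_away(100.0 * c / total) for c in counts]
        else:
            pct = [np.nan] * len(class_order)
        rows.append(pct + [100.0 if total > 0 else np.nan])
        index.append("%")
    return pd.DataFrame(rows, index=index, columns=class_order + ["Total"])


def deterministic_call(
    composition: TissueComposition,
    aberrant_threshold: float,
    aberrant_classes: Sequence[str] = ("aberrant",),
) -> str:
    """Hard malignant/benign call from the aberrant cell share.

    The fuzzy rule deliberately reports a probability; where a deterministic
    outcome is required, the caller must supply the decision threshold on the
    aberrant fraction explicitly — no validated default exists, so none is
    shipped.
    """
    if not 0.0 < aberrant_threshold <= 1.0:
        raise DefinitionError("aberrant_threshold must be in (0, 1]")
    if composition.status == INDETERMINATE:
        return INDETERMINATE
    aberrant = sum(composition.fractions.get(c, 0.0) for c in aberrant_classes)
    return "malignant" if aberrant >= aberrant_threshold else "benign"


def compositions_by_specimen(
    labels: Sequence[str],
    specimen_ids: Sequence[str],
    severity: Sequence[str] | None = None,
) -> list[TissueComposition]:
    """Group per-cell labels by specimen id and compose each group."""
    labels = np.asarray(list(labels), dtype=object)
    specimen_ids = np.asarray(list(specimen_ids), dtype=object)
    if labels.shape != specimen_ids.shape:
        raise DefinitionError("labels and specimen_ids must have equal length")
    out = []
    for spec in pd.unique(specimen_ids):
        out.append(compose(labels[specimen_ids == spec], str(spec), severity=severity))
    return out
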