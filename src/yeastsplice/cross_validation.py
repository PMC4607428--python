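"""Confirmation of predicted introns in an independent alignment dataset.

A predicted intron is validated when split reads with exactly the same
junction coordinates are found in the second dataset.  Support values from
the two datasets can be correlated per AS class (log1p-scaled, product-
moment correlation) to gauge reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intron_filtering import PredictedIntron
from .io_models import GenomicInterval
from .splitread_extraction import (
    PotentialIntron,
    SplitReadAlignment,
    call_potential_introns,
)

DEFAULT_MIN_SECONDARY_SUPPORT = 1


@dataclass
class ValidationRecord:
    intron: GenomicInterval
    support_primary: int
    support_secondary: int
    validated: bool


def _secondary_support_index(secondary) -> dict[tuple[str, int, int], int]:
    items = list(secondary)
    if items and isinstance(items[0], SplitReadAlignment):
        items = call_potential_introns(items)
    index: dict[tuple[str, int, int], int] = {}
    for pi in items:
        if not isinstance(pi, PotentialIntron):
            raise TypeError(
                "secondary dataset must contain SplitReadAlignment or PotentialIntron"
            )
        index[pi.interval.key] = pi.read_support
    return index


def validate_in_dataset(
    predicted_introns: Sequence[PredictedIntron],
    secondary: Iterable,
    min_secondary_support: int = DEFAULT_MIN_SECONDARY_SUPPORT,
    secondary_chromosomes: Iterable[str] | None = None,
) -> list[ValidationRecord]:
    """Exact-coordinate validation of predicted introns in a second dataset.

    ``secondary`` is a collection of split reads or potential introns from
    the independent dataset.  When ``secondary_chromosomes`` (e.g. the SAM
    header names) is given, predicted introns on chromosomes unknown to the
    second dataset raise an error listing the unmatched names — both
    datasets must be mapped to the same genome build.
    """
    if secondary_chromosomes is not None:
        known = set(secondary_chromosomes)
        unmatched = sorted(
            {p.interval.chrom for p in predicted_introns} - known
        )
        if unmatched:
            raise ValueError(
                "chromosome names absent from secondary dataset: "
                + ", ".join(unmatched)
            )
    index = _secondary_support_index(secondary)
    records = []
    for p in predicted_introns:
        support2 = index.get(p.interval.key, 0)
        records.append(
            ValidationRecord(
                intron=p.interval,
                support_primary=p.read_support,
                support_secondary=support2,
                validated=support2 >= min_secondary_support,
            )
        )
    return records


def support_correlation(
    records: Sequence[ValidationRecord],
    class_labels: Sequence[str],
) -> dict[str, float | None]:
    """Per-class correlation of log1p read support across the two datasets.

    Classes with fewer than 3 records are skipped; zero-variance classes
    report ``None`` (correlation undefined).
    """
    if len(records) != len(class_labels):
        raise ValueError("records and class_labels must align")
    grouped: dict[str, list[ValidationRecord]] = {}
    for rec, label in zip(records, class_labels):
        grouped.setdefault(label, []).append(rec)
    out: dict[str, float | None] = {}
    for label, recs in sorted(grouped.items()):
        if len(recs) < 3:
            continue
        x = np.log1p([r.support_primary for r in recs])
        y = np.log1p([r.support_secondary for r in recs])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[label] = None
            continue
        rho = stats.pearsonr(x, y).statistic
        out[label] = None if math.isnan(rho) else float(rho)
    return out
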