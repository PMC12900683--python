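"""PANAS scoring, depression screening, and change scores.

The 20-item Positive and Negative Affect Schedule (PANAS) splits into
two 10-item dimensions (positive affect PA, negative affect NA), each
rated 1–5, so each dimension totals 10–50.  Screening uses the study's
thresholds: CES-D ≥ 20 together with PHQ-9 ≥ 10 defines the subclinical
depression (ScD) group; both strictly below threshold defines healthy
controls (HC).  The published rule covers only ScD — the HC criterion
here is the natural complement, and score profiles meeting one threshold
but not the other are flagged ``indeterminate`` rather than forced into
a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DataError

__all__ = [
    "PanasResponse",
    "ScreeningRecord",
    "DEFAULT_PA_ITEMS",
    "DEFAULT_NA_ITEMS",
    "score_panas",
    "screen_group",
    "change_scores",
]

# Standard PANAS item→dimension assignment (1-based item numbers).
DEFAULT_PA_ITEMS: tuple[int, ...] = (1, 3, 5, 9, 10, 12, 14, 16, 17, 19)
DEFAULT_NA_ITEMS: tuple[int, ...] = (2, 4, 6, 7, 8, 11, 13, 15, 18, 20)


@dataclass
class PanasResponse:
    """One subject's 20 PANAS item ratings (integers 1–5)."""

    items: Sequence[int]
    pa_items: Sequence[int] = DEFAULT_PA_ITEMS
    na_items: Sequence[int] = DEFAULT_NA_ITEMS

    def __post_init__(self) -> None:
        self.items = list(self.items)
        if len(self.items) != 20:
            raise DataError(f"PANAS has 20 items, got {len(self.items)}")
        for v in self.items:
            if v not in (1, 2, 3, 4, 5):
                raise DataError(f"item rating {v!r} outside 1–5")
        pa, na = set(self.pa_items), set(self.na_items)
        if len(pa) != 10 or len(na) != 10 or pa & na or (pa | na) != set(range(1, 21)):
            raise DataError("pa_items and na_items must partition items 1..20")


def score_panas(resp: PanasResponse) -> tuple[int, int]:
    """Sum the PA and NA items; each total lies in [10, 50]."""
    pa = sum(resp.items[i - 1] for i in resp.pa_items)
    na = sum(resp.items[i - 1] for i in resp.na_items)
    return int(pa), int(na)


@dataclass
class ScreeningRecord:
    """CES-D (0–60) and PHQ-9 (0–27) totals for one participant."""

    cesd_total: int
    phq9_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.cesd_total <= 60:
            raise DataError(f"CES-D total {self.cesd_total} outside 0–60")
        if not 0 <= self.phq9_total <= 27:
            raise DataError(f"PHQ-9 total {self.phq9_total} outside 0–27")


#: Screening thresholds: CES-D ≥ 20 and PHQ-9 ≥ 10 jointly define ScD.
CESD_THRESHOLD = 20
PHQ9_THRESHOLD = 10


def screen_group(rec: ScreeningRecord) -> str:
    """Assign ``"ScD"``, ``"HC"`` or ``"indeterminate"`` from screening scores."""
    high_cesd = rec.cesd_total >= CESD_THRESHOLD
    high_phq = rec.phq9_total >= PHQ9_THRESHOLD
    if high_cesd and high_phq:
        return "ScD"
    if not high_cesd and not high_phq:
        return "HC"
    return "indeterminate"


def change_scores(pre_table: pd.DataFrame, post_table: pd.DataFrame,
                  keys: Sequence[str] = ("subject_id",),
                  ) -> tuple[pd.DataFrame, list]:
    """Per-subject post − pre deltas for every shared numeric column.

    Rows are aligned on ``keys``; subjects present in only one table are
    reported in the second return value, not silently dropped.  Duplicate
    keys in either table are an error.
    """
    keys = list(keys)
    for name, tab in (("pre", pre_table), ("post", post_table)):
        if tab.duplicated(subset=keys).any():
            raise DataError(f"duplicate keys in {name} table")
    pre = pre_table.set_index(keys)
    post = post_table.set_index(keys)
    shared = pre.index.intersection(post.index)
    missing = sorted(pre.index.symmetric_difference(post.index).tolist())
    num_cols = [c for c in pre.columns
                if c in post.columns and np.issubdtype(pre[c].dtype, np.number)]
    delta = (post.loc[shared, num_cols] - pre.loc[shared, num_cols]).reset_index()
    return delta, missing
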