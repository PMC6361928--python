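"""Questionnaire-derived measures: SLE decomposition, GHQ, PHQ, proxy cases.

Stressful-life-event (SLE) instruments based on the 12-item list of
threatening experiences are decomposed into a total count (TSLE) and two
subscales: events potentially dependent on the respondent's own behaviour
(DSLE, items 6-11 by default) and independent events (ISLE, items 1-5
with the pregnancy item removed).  Item 12 belongs to neither subscale by
default.  Missing item responses count as "no" (and as 0 for GHQ items);
callers needing a different rule should pre-impute.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

YES, NO, MISSING = "yes", "no", "missing"


class ItemClass(str, Enum):
    INDEPENDENT = "independent"
    DEPENDENT = "dependent"
    EXCLUDED = "excluded_from_subscales"


#: default 12-item classification: items 1-5 independent, 6-11 dependent,
#: item 12 outside both subscales; pregnancy item index 4 (0-based item 5).
DEFAULT_ITEM_CLASSES = (
    [ItemClass.INDEPENDENT] * 5 + [ItemClass.DEPENDENT] * 6 + [ItemClass.EXCLUDED]
)
DEFAULT_PREGNANCY_ITEM = 4


def score_sle(
    responses,
    item_classes=None,
    pregnancy_item_index: int | None = DEFAULT_PREGNANCY_ITEM,
) -> tuple[int, int, int]:
    """Return (tsle, dsle, isle) counts for one respondent.

    tsle counts every "yes"; dsle counts "yes" on dependent items; isle
    counts "yes" on independent items excluding the pregnancy item.
    Missing responses count as "no".
    """
    responses = list(responses)
    if item_classes is None:
        if len(responses) != len(DEFAULT_ITEM_CLASSES):
            raise ValueError(
                f"default classification covers {len(DEFAULT_ITEM_CLASSES)} items, "
                f"got {len(responses)} responses"
            )
        item_classes = DEFAULT_ITEM_CLASSES
    item_classes = [ItemClass(c) for c in item_classes]
    if len(item_classes) != len(responses):
        raise ValueError("item_classes must cover all items")

    tsle = dsle = isle = 0
    for i, resp in enumerate(responses):
        if resp not in (YES, NO, MISSING):
            raise ValueError(f"unknown response code {resp!r} at item {i}")
        if resp != YES:
            continue
        tsle += 1
        if item_classes[i] is ItemClass.DEPENDENT:
            dsle += 1
        elif item_classes[i] is ItemClass.INDEPENDENT and i != pregnancy_item_index:
            isle += 1
    return tsle, dsle, isle


def score_sle_table(
    responses: pd.DataFrame,
    item_classes=None,
    pregnancy_item_index: int | None = DEFAULT_PREGNANCY_ITEM,
) -> pd.DataFrame:
    """Vectorised :func:`score_sle` over a per-sample response table."""
    out = [
        score_sle(row, item_classes, pregnancy_item_index)
        for row in responses.to_numpy()
    ]
    return pd.DataFrame(out, columns=["TSLE", "DSLE", "ISLE"], index=responses.index)


def transform_ghq(item_scores, binary_scoring: bool = False) -> float:
    """Log-transformed 28-item GHQ total.

    Items are scored 0-3 on the four-point Likert scale (or 0-0-1-1 with
    ``binary_scoring``); the result is ``log(1 + sum)`` with natural log.
    The +1 offset keeps the all-zero questionnaire finite; any monotone
    base gives identical downstream rank behaviour.  Missing (nan) items
    count as 0.
    """
    scores = np.asarray(item_scores, dtype=float)
    if scores.shape != (28,):
        raise ValueError(f"expected 28 GHQ items, got shape {scores.shape}")
    finite = scores[np.isfinite(scores)]
    if not np.isin(finite, (0.0, 1.0, 2.0, 3.0)).all():
        raise ValueError("GHQ items must be in {0, 1, 2, 3}")
    scores = np.nan_to_num(scores)
    if binary_scoring:
        scores = (scores >= 2).astype(float)
    return float(np.log1p(scores.sum()))


def bin_phq(raw_sum: int) -> int:
    """Four-point PHQ category: 0 -> 0; 1-2 -> 1; 3-5 -> 2; >=6 -> 3."""
    raw_sum = int(raw_sum)
    if raw_sum < 0:
        raise ValueError(f"PHQ raw sum must be non-negative, got {raw_sum}")
    if raw_sum == 0:
        return 0
    if raw_sum <= 2:
        return 1
    if raw_sum <= 5:
        return 2
    return 3


@dataclass
class ProxyCaseLabel:
    sample_id: str
    status: str  # case | proxy_case | control
    source: str  # self_report | first_degree_relative


def map_proxy_cases(
    case_status: dict[str, bool],
    relatives: list[tuple[str, str]],
) -> pd.DataFrame:
    """Label unaffected first-degree relatives of cases as proxy cases.

    Cases stay cases (self-report takes precedence); non-cases with at
    least one first-degree case relative become ``proxy_case``; everyone
    else is a control.  The analysis case group is cases + proxy cases,
    so the case-group size never shrinks.
    """
    neighbours: dict[str, set[str]] = {s: set() for s in case_status}
    for a, b in relatives:
        if a == b:
            raise ValueError(f"sample {a!r} listed as its own relative")
        if a not in case_status or b not in case_status:
            raise ValueError(f"relative pair ({a!r}, {b!r}) references unknown samples")
        neighbours[a].add(b)
        neighbours[b].add(a)

    rows = []
    for sample, is_case in case_status.items():
        if is_case:
            rows.append(ProxyCaseLabel(sample, "case", "self_report"))
        elif any(case_status[r] for r in neighbours[sample]):
            rows.append(ProxyCaseLabel(sample, "proxy_case", "first_degree_relative"))
        else:
            rows.append(ProxyCaseLabel(sample, "control", "self_report"))
    return pd.DataFrame([vars(r) for r in rows])
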