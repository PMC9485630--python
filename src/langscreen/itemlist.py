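"""Word-list reduction for building a short expressive-vocabulary screen.

Starting from a long parent-reported word checklist, items are dropped
when (a) too few children use the word (low usage gives the item no
discriminating range at this age) or (b) *not* producing the word,
taken as a one-item screen, has a poor positive predictive value for
the deficit outcome.  A per-item audit table records every decision.

A third criterion sometimes applied in instrument construction --
marked age heterogeneity of item usage within the screening window --
has no agreed quantitative definition; the audit table reports the
endorsement spread across age months as information only, and no item
is dropped for it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reduce_word_list"]


def reduce_word_list(
    items,
    outcome,
    usage_min: float = 0.25,
    item_ppv_min: float = 0.50,
    age_months=None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the usage and single-item-PPV retention rules.

    Parameters
    ----------
    items : DataFrame or ItemMatrix
        Binary responses, one 0/1 column per item.
    outcome : array-like of bool
        Deficit outcome aligned with the rows of ``items``.
    usage_min : float
        Items endorsed by fewer than this fraction of children are
        dropped.
    item_ppv_min : float
        Treating "word not produced" as a positive one-item screen,
        items whose PPV for the outcome falls below this are dropped.
        With no non-endorsers the PPV is undefined and the rule is
        skipped (the item is retained).
    age_months : array-like of int, optional
        If given, the audit table reports each item's endorsement
        spread across age months (max - min rate); informational only.

    Returns
    -------
    (retained, audit) : retained item labels, and a per-item DataFrame
    with usage, non-endorser count, single-item PPV, the decision and
    its reason.
    """
    responses = getattr(items, "responses", items)
    if getattr(items, "age_months", None) is not None and age_months is None:
        age_months = items.age_months
    if responses.shape[0] == 0 or responses.shape[1] == 0:
        raise ValueError("empty item matrix")
    y = np.asarray(outcome).astype(bool)
    if len(y) != responses.shape[0]:
        raise ValueError("items and outcome must be aligned")

    R = responses.to_numpy(dtype=int)
    usage = R.mean(axis=0)
    non_endorsed = R == 0
    n_non = non_endorsed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(n_non > 0, (non_endorsed & y[:, None]).sum(axis=0) / n_non, np.nan)

    age_spread = np.full(responses.shape[1], np.nan)
    if age_months is not None:
        ages = np.asarray(age_months)
        rates_by_age = np.array(
            [R[ages == a].mean(axis=0) for a in np.unique(ages) if (ages == a).any()]
        )
        if len(rates_by_age):
            age_spread = rates_by_age.max(axis=0) - rates_by_age.min(axis=0)

    rows = []
    retained = []
    for j, label in enumerate(responses.columns):
        if usage[j] < usage_min:
            decision, reason = "dropped", f"usage {usage[j]:.3f} < {usage_min}"
        elif n_non[j] > 0 and ppv[j] < item_ppv_min:
            decision, reason = "dropped", f"single-item PPV {ppv[j]:.3f} < {item_ppv_min}"
        elif n_non[j] == 0:
            decision, reason = "retained", "PPV rule skipped: no non-endorsers"
            retained.append(label)
        else:
            decision, reason = "retained", "passes usage and PPV rules"
            retained.append(label)
        rows.append(
            {
                "item": label,
                "usage": usage[j],
                "n_non_endorsed": int(n_non[j]),
                "single_item_ppv": ppv[j],
                "age_spread": age_spread[j],
                "decision": decision,
                "reason": reason,
            }
        )
    return retained, pd.DataFrame(rows)
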