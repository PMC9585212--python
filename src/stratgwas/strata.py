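"""Assignment of individuals to age quantile strata (Q1 = youngest).

Cut points are nearest-rank (type-1) empirical quantiles of the age vector,
and individuals are assigned by age *value*, so everyone sharing an age
lands in one stratum. With integer ages this makes stratum sizes only
approximately equal — the price of never splitting an age across strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .errors import StratificationError


@dataclass
class StratumAssignment:
    """Mapping from individual id to stratum label plus per-stratum age summary."""

    assignments: pd.Series  # index: individual id, values: "Q1".."Qk"
    labels: list[str]  # ordered youngest -> oldest
    summary: pd.DataFrame  # per-stratum n, min/mean/max age

    def ids_in(self, label: str) -> list[str]:
        return list(self.assignments.index[self.assignments == label])

    def label_index(self, label: str) -> int:
        return self.labels.index(label)


def assign_age_quartiles(ages, ids=None, k: int = 4) -> StratumAssignment:
    """Partition a cohort into ``k`` age strata Q1 (youngest) .. Qk (oldest).

    Parameters
    ----------
    ages
        Age per individual (years).
    ids
        Individual identifiers aligned with ``ages``; defaults to the
        integer position as a string.
    k
        Number of strata (quartiles by default).

    Raises
    ------
    StratificationError
        If there are fewer than ``k`` distinct age values.
    """
    ages = np.asarray(ages)
    if ids is None:
        ids = [str(i) for i in range(len(ages))]
    if len(ids) != len(ages):
        raise StratificationError(f"{len(ids)} ids for {len(ages)} ages")
    if len(np.unique(ages)) < k:
        raise StratificationError(
            f"need at least {k} distinct age values to form {k} strata, "
            f"got {len(np.unique(ages))}"
        )
    n = len(ages)
    srt = np.sort(ages)
    # type-1 (nearest-rank) quantiles at i/k, i = 1..k-1
    cuts = [srt[ceil(n * i / k) - 1] for i in range(1, k)]
    stratum_idx = np.sum(ages[:, None] > np.asarray(cuts)[None, :], axis=1)
    labels = [f"Q{i + 1}" for i in range(k)]
    assignments = pd.Series(
        [labels[i] for i in stratum_idx], index=pd.Index(ids, name="IID"), name="stratum"
    )
    rows = []
    for i, lab in enumerate(labels):
        in_s = ages[stratum_idx == i]
        rows.append(
            {
                "stratum": lab,
                "n": int(in_s.size),
                "age_min": float(in_s.min()) if in_s.size else np.nan,
                "age_mean": float(in_s.mean()) if in_s.size else np.nan,
                "age_max": float(in_s.max()) if in_s.size else np.nan,
            }
        )
    return StratumAssignment(assignments, labels, pd.DataFrame(rows))
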