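"""Hybridization design: one two-color array per (group, replicate) against a
common reference, with alternating dye swaps within each group."""

from __future__ import annotations

import pandas as pd


def build_design(
    groups: tuple[str, ...] | list[str],
    replicates_per_group: int,
    reference: str = "VO",
) -> pd.DataFrame:
    """One array per (treatment group, biological replicate).

    Each array co-hybridizes one treatment replicate with one reference
    replicate; dye-swap flags alternate within each group's replicate series,
    so the array count is len(groups) * replicates_per_group.
    """
    if replicates_per_group < 1:
        raise ValueError("replicates_per_group must be >= 1")
    if reference in groups:
        raise ValueError(f"reference {reference!r} must not be a treatment group")
    rows = []
    for group in groups:
        for rep in range(1, replicates_per_group + 1):
            rows.append(
                {
                    "array_id": f"{group}_rep{rep}",
                    "group": group,
                    "replicate": rep,
                    "reference": reference,
                    "reference_replicate": rep,
                    "dye_swapped": (rep % 2 == 0),
                }
            )
    return pd.DataFrame(rows)
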