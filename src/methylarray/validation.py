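"""Validation-arm analytics: bisulfite clone scoring and qPCR 2^-ddCt.

Bisulfite conversion deaminates unmethylated cytosines to uracil (read as T)
while methylated CpG cytosines stay C. A sequenced clone is scored at every
CpG position of its reference amplicon (C = methylated, T = unmethylated,
anything else ambiguous); the fraction of non-CpG cytosines read as T is the
clone's conversion rate, and clones below the conversion threshold are
discarded before per-site methylation percentages are computed.

Relative qPCR expression uses the comparative Ct method: dCt = target -
normalizer per replicate, ddCt = mean dCt(group) - mean dCt(calibrator), and
relative expression = 2^-ddCt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BisulfiteAmplicon:
    amplicon_id: str
    reference: str
    cpg_positions: tuple[int, ...]
    non_cpg_c_positions: tuple[int, ...]

    @classmethod
    def from_reference(cls, amplicon_id: str, reference: str) -> "BisulfiteAmplicon":
        ref = reference.upper()
        cpg, non_cpg = [], []
        for i, base in enumerate(ref):
            if base != "C":
                continue
            if i + 1 < len(ref) and ref[i + 1] == "G":
                cpg.append(i)
            else:
                non_cpg.append(i)
        return cls(amplicon_id, ref, tuple(cpg), tuple(non_cpg))


@dataclass(frozen=True)
class CloneCall:
    clone_id: str
    #: per-CpG call in reference order: 'methylated'/'unmethylated'/'ambiguous'
    calls: tuple[str, ...]
    conversion_rate: float


def score_clone(amplicon: BisulfiteAmplicon, clone_id: str, seq: str) -> CloneCall:
    """Exact-position scoring of one equal-length clone against the reference."""
    seq = seq.upper()
    if len(seq) != len(amplicon.reference):
        raise ValueError(
            f"clone {clone_id!r} length {len(seq)} != reference "
            f"{len(amplicon.reference)}"
        )
    calls = []
    for pos in amplicon.cpg_positions:
        base = seq[pos]
        if base == "C":
            calls.append("methylated")
        elif base == "T":
            calls.append("unmethylated")
        else:
            calls.append("ambiguous")
    if amplicon.non_cpg_c_positions:
        converted = sum(
            1 for pos in amplicon.non_cpg_c_positions if seq[pos] == "T"
        )
        conversion = converted / len(amplicon.non_cpg_c_positions)
    else:
        conversion = 1.0
    return CloneCall(clone_id, tuple(calls), conversion)


def score_bisulfite_clones(
    amplicon: BisulfiteAmplicon,
    clones: list[tuple[str, str]],
    conversion_threshold: float = 0.95,
) -> tuple[list[CloneCall], pd.DataFrame]:
    """Score clones and compute per-CpG-site methylation percentages.

    Length-mismatched clones are flagged, excluded and logged; clones with a
    conversion rate below the threshold are discarded before the site
    percentages. Ambiguous calls drop out of that site's denominator. The
    profile row per CpG site reports percent methylated across retained
    clones and the retained-clone count.
    """
    calls: list[CloneCall] = []
    for clone_id, seq in clones:
        try:
            calls.append(score_clone(amplicon, clone_id, seq))
        except ValueError as exc:
            log.warning("excluding clone: %s", exc)
    retained = [c for c in calls if c.conversion_rate >= conversion_threshold]
    if len(retained) < len(calls):
        log.info(
            "discarded %d/%d clones below conversion threshold %.2f",
            len(calls) - len(retained), len(calls), conversion_threshold,
        )
    rows = []
    for site_idx, pos in enumerate(amplicon.cpg_positions):
        site_calls = [c.calls[site_idx] for c in retained]
        n_meth = sum(1 for c in site_calls if c == "methylated")
        n_unmeth = sum(1 for c in site_calls if c == "unmethylated")
        denom = n_meth + n_unmeth
        rows.append(
            {
                "site": site_idx,
                "position": pos,
                "n_methylated": n_meth,
                "n_unmethylated": n_unmeth,
                "n_retained_clones": len(retained),
                "percent_methylated": 100.0 * n_meth / denom if denom else np.nan,
            }
        )
    return calls, pd.DataFrame(rows)


def mean_methylation_percent(profile: pd.DataFrame) -> float:
    """Group-level summary: the average of the per-CpG-site percentages."""
    return float(profile["percent_methylated"].mean())


def ddct_expression(
    measurements: pd.DataFrame, calibrator: str
) -> pd.DataFrame:
    """Relative expression per group by the comparative Ct method.

    ``measurements`` needs columns group, replicate, target_ct,
    normalizer_ct; every replicate must carry both Ct values.
    """
    needed = {"group", "replicate", "target_ct", "normalizer_ct"}
    if not needed <= set(measurements.columns):
        raise ValueError(f"Ct table missing columns {needed - set(measurements.columns)}")
    if measurements[["target_ct", "normalizer_ct"]].isna().any().any():
        raise ValueError("missing Ct value (normalizer or target)")
    if (measurements[["target_ct", "normalizer_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be > 0")
    df = measurements.copy()
    df["dct"] = df["target_ct"] - df["normalizer_ct"]
    group_dct = df.groupby("group")["dct"].mean()
    if calibrator not in group_dct.index:
        raise ValueError(f"calibrator group {calibrator!r} not in measurements")
    ddct = group_dct - group_dct[calibrator]
    out = pd.DataFrame(
        {
            "group": group_dct.index,
            "mean_dct": group_dct.to_numpy(),
            "ddct": ddct.to_numpy(),
            "relative_expression": 2.0 ** (-ddct.to_numpy()),
        }
    ).reset_index(drop=True)
    return out
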