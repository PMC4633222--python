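"""Two-color array preprocessing.

Pipeline order matches common two-color practice: background detection
against negative controls (mean + k*SD cutoff), within-array loess
normalization of M on A, then inter-array quantile scale normalization of the
normalized M values over the commonly detected probe set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


@dataclass
class ArraySet:
    """Per-array two-channel intensity tables plus array metadata.

    ``intensities`` is long-form (probe_id, array_id, channel1, channel2,
    is_negative_control); ``metadata`` has one row per array (array_id,
    group, replicate, dye_swapped).
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"probe_id", "array_id", "channel1", "channel2",
                  "is_negative_control"}
        if not needed <= set(self.intensities.columns):
            raise ValueError(f"intensity table missing {needed - set(self.intensities.columns)}")
        if not {"array_id", "group", "replicate", "dye_swapped"} <= set(
            self.metadata.columns
        ):
            raise ValueError("metadata must have array_id, group, replicate, dye_swapped")

    @property
    def array_ids(self) -> list[str]:
        return list(self.metadata["array_id"])

    def array_table(self, array_id: str) -> pd.DataFrame:
        return self.intensities[self.intensities["array_id"] == array_id]

    def is_swapped(self, array_id: str) -> bool:
        row = self.metadata.loc[self.metadata["array_id"] == array_id]
        return bool(row["dye_swapped"].iloc[0])


def detection_call(
    array_table: pd.DataFrame, sd_multiplier: float = 4.0
) -> set[str]:
    """Probes whose signal rises above the negative-control background.

    The per-probe signal is the mean of the two channels on the natural
    scale; the cutoff is mean + sd_multiplier * sample SD (ddof=1) of the
    negative controls. Detection requires strictly exceeding the cutoff.
    """
    negatives = array_table[array_table["is_negative_control"]]
    if len(negatives) < 2:
        raise ValueError(
            f"need >= 2 negative controls to estimate background SD, got {len(negatives)}"
        )
    neg_signal = (negatives["channel1"] + negatives["channel2"]) / 2.0
    cutoff = neg_signal.mean() + sd_multiplier * neg_signal.std(ddof=1)
    real = array_table[~array_table["is_negative_control"]]
    signal = (real["channel1"] + real["channel2"]) / 2.0
    return set(real.loc[signal > cutoff, "probe_id"])


def detection_masks(
    arrays: ArraySet, sd_multiplier: float = 4.0
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-array detection sets and their intersection (detected in all)."""
    per_array = {
        aid: detection_call(arrays.array_table(aid), sd_multiplier)
        for aid in arrays.array_ids
    }
    common = set.intersection(*per_array.values()) if per_array else set()
    return per_array, common


def compute_ma(
    array_table: pd.DataFrame,
    dye_swapped: bool = False,
    floor: float = 0.5,
) -> pd.DataFrame:
    """M/A transform with treatment-over-reference orientation.

    The treatment sample sits in channel2 (Cy5) by convention; dye-swapped
    arrays carry it in channel1, so channels are logically re-labeled before
    the ratio and M keeps the same orientation on every array.
    """
    real = array_table[~array_table["is_negative_control"]]
    c1 = np.maximum(real["channel1"].to_numpy(float), floor)
    c2 = np.maximum(real["channel2"].to_numpy(float), floor)
    treatment, reference = (c1, c2) if dye_swapped else (c2, c1)
    m = np.log2(treatment / reference)
    a = 0.5 * np.log2(treatment * reference)
    return pd.DataFrame({"probe_id": real["probe_id"].to_numpy(), "M": m, "A": a})


def loess_normalize(
    ma: pd.DataFrame, span: float = 0.3, iterations: int = 3
) -> pd.DataFrame:
    """Remove the intensity-dependent M trend by locally weighted regression.

    M is replaced by the residual from a robust loess fit of M on A; A is
    untouched. Degenerate A (all values equal) falls back to subtracting the
    global mean, with a warning.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if len(ma) < 50:
        raise ValueError(f"need >= 50 probes for loess, got {len(ma)}")
    out = ma.copy()
    a = ma["A"].to_numpy(float)
    m = ma["M"].to_numpy(float)
    if np.ptp(a) == 0:
        warnings.warn("degenerate A values (all equal); subtracting global mean")
        out["M"] = m - m.mean()
        return out
    delta = 0.005 * np.ptp(a)
    fitted = lowess(
        m, a, frac=span, it=iterations, delta=delta, return_sorted=False
    )
    out["M"] = m - fitted
    return out


def quantile_normalize(m_matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every array's M distribution onto the across-array mean quantile
    function; within-array ranks are preserved."""
    if m_matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 arrays")
    values = m_matrix.to_numpy(float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    mean_quantiles = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[order[:, j], j] = mean_quantiles
    return pd.DataFrame(out, index=m_matrix.index, columns=m_matrix.columns)


def mad_scale_normalize(m_matrix: pd.DataFrame) -> pd.DataFrame:
    """Alternative inter-array scaling: match median absolute deviations."""
    mads = (m_matrix - m_matrix.median()).abs().median()
    target = float(np.exp(np.log(mads[mads > 0]).mean())) if (mads > 0).any() else 0.0
    scaled = m_matrix.copy()
    for col in m_matrix.columns:
        if mads[col] > 0 and target > 0:
            scaled[col] = (m_matrix[col] - m_matrix[col].median()) * (
                target / mads[col]
            ) + m_matrix[col].median()
    return scaled


def preprocess_arrays(
    arrays: ArraySet,
    *,
    sd_multiplier: float = 4.0,
    floor: float = 0.5,
    span: float = 0.3,
    quantile_mode: str = "quantile",
) -> tuple[pd.DataFrame, set[str]]:
    """Full preprocessing: detection -> MA -> loess -> inter-array scaling.

    Returns the normalized M matrix (probes x arrays, restricted to probes
    detected on every array) and the commonly detected probe set.
    """
    _per_array, common = detection_masks(arrays, sd_multiplier)
    if not common:
        raise ValueError("no probe detected on all arrays")
    m_cols = {}
    for aid in arrays.array_ids:
        ma = compute_ma(arrays.array_table(aid), arrays.is_swapped(aid), floor)
        ma = ma[ma["probe_id"].isin(common)]
        norm = loess_normalize(ma, span=span)
        m_cols[aid] = norm.set_index("probe_id")["M"]
    m_matrix = pd.DataFrame(m_cols)
    if m_matrix.isna().any().any():
        dropped = int(m_matrix.isna().any(axis=1).sum())
        log.info("dropping %d probes missing on some array", dropped)
        m_matrix = m_matrix.dropna()
    if quantile_mode == "quantile":
        m_matrix = quantile_normalize(m_matrix)
    elif quantile_mode == "mad":
        m_matrix = mad_scale_normalize(m_matrix)
    elif quantile_mode != "none":
        raise ValueError(f"unknown quantile_mode {quantile_mode!r}")
    return m_matrix, common
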