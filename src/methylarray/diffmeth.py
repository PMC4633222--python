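"""Per-probe moderated linear models and DMR calling.

Each probe's replicate M values for one group-vs-reference contrast are fit
with a one-sample linear model (beta = mean M). Residual variances are then
shrunk towards a common prior by empirical Bayes: the prior degrees of
freedom d0 and prior variance s0^2 are estimated by the method of moments on
log variances (the digamma/trigamma system), the moderated variance is the
weighted average

    s2_tilde = (d0 * s0^2 + df * s2) / (d0 + df)

and the moderated t-statistic beta / sqrt(s2_tilde / n) is referred to a t
distribution with d0 + df degrees of freedom. With d0 = 0 this reduces to the
ordinary one-sample t-test; with d0 -> infinity every probe is tested against
the pooled variance.

A probe is called a differentially methylated region (DMR) when p < 0.05 and
|log2 fold-change| >= log2(1.5); on this platform fold-changes are indicative
of higher or lower odds of methylation rather than quantitative, so no
multiple-testing correction is applied to the DMR calls (an FDR column is
emitted for transparency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

#: Sentinel prior df meaning "effectively infinite shrinkage".
D0_CAP = 1e8


@dataclass(frozen=True)
class EBHyperparams:
    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_2 <= 0:
            raise ValueError("require d0 >= 0 and s0_2 > 0")


def fit_probe_model(m_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-probe mean, sample variance and residual df across replicates.

    ``m_matrix`` is probes x replicate arrays for a single contrast (dye
    orientation already corrected upstream). Missing replicates reduce the
    per-probe df. Raises when no probe has >= 2 observations.
    """
    values = m_matrix.to_numpy(float)
    n_obs = np.sum(~np.isnan(values), axis=1)
    if values.shape[1] < 2 or (n_obs < 2).all():
        raise ValueError("need >= 2 replicate arrays to estimate a variance")
    with np.errstate(invalid="ignore"):
        beta = np.nanmean(values, axis=1)
        s2 = np.nanvar(values, axis=1, ddof=1)
    df = n_obs - 1
    out = pd.DataFrame(
        {"beta": beta, "s2": s2, "df": df, "n": n_obs}, index=m_matrix.index
    )
    return out[out["df"] >= 1]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_eb_hyperparams(fit: pd.DataFrame) -> EBHyperparams:
    """Method-of-moments estimation of the variance prior on log variances.

    Under the scaled chi-square sampling model, log s2 has mean
    log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2) and variance
    psi'(df/2) + psi'(d0/2). When the observed spread of log s2 does not
    exceed the theoretical sampling floor psi'(df/2), d0 is capped at a large
    sentinel and s0^2 set to the mean variance.
    """
    ok = fit["s2"] > 0
    if int(ok.sum()) < 100:
        raise ValueError(
            f"need >= 100 probes with positive variance, got {int(ok.sum())}"
        )
    s2 = fit.loc[ok, "s2"].to_numpy(float)
    df = fit.loc[ok, "df"].to_numpy(float)
    z = np.log(s2)
    e = z - special.psi(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    floor = float(np.mean(special.polygamma(1, df / 2.0)))
    excess = e_var - floor
    if excess <= 0:
        return EBHyperparams(D0_CAP, float(s2.mean()))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.psi(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBHyperparams(d0, s0_2)


def moderated_test(fit: pd.DataFrame, hyper: EBHyperparams) -> pd.DataFrame:
    """Complete the per-probe statistics with moderated variance, t and p."""
    s2 = fit["s2"].to_numpy(float)
    df = fit["df"].to_numpy(float)
    n = fit["n"].to_numpy(float)
    beta = fit["beta"].to_numpy(float)
    d0, s0_2 = hyper.d0, hyper.s0_2
    if d0 >= D0_CAP:
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.full_like(df, D0_CAP)
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_tilde / n)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    out = fit.copy()
    out["s2_tilde"] = s2_tilde
    out["t"] = np.where(np.isnan(t), 0.0, t)
    out["p"] = np.clip(p, 0.0, 1.0)
    return out


def call_dmrs(
    stats_df: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    *,
    threshold_is_log2: bool = False,
) -> pd.DataFrame:
    """Filter probe statistics to DMRs and attach the direction.

    Default reading: |log2FC| >= log2(fc_threshold). The alternative literal
    reading |log2FC| >= fc_threshold is available via ``threshold_is_log2``.
    An unadjusted-p rule is used; a Benjamini-Hochberg FDR column is emitted
    alongside for transparency.
    """
    log2_cutoff = fc_threshold if threshold_is_log2 else math.log2(fc_threshold)
    out = stats_df.copy()
    if "beta" in out.columns and "log2fc" not in out.columns:
        out = out.rename(columns={"beta": "log2fc"})
    fdr = _benjamini_hochberg(out["p"].to_numpy(float))
    out["fdr"] = fdr
    keep = (out["p"] < p_threshold) & (out["log2fc"].abs() >= log2_cutoff)
    dmrs = out[keep].copy()
    dmrs["direction"] = np.where(dmrs["log2fc"] > 0, "hyper", "hypo")
    assert (dmrs["p"] < p_threshold).all()
    assert (dmrs["log2fc"].abs() >= log2_cutoff).all()
    return dmrs


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def fit_contrast(m_matrix: pd.DataFrame) -> pd.DataFrame:
    """Convenience: fit, estimate the prior, and moderate in one call."""
    fit = fit_probe_model(m_matrix)
    hyper = estimate_eb_hyperparams(fit)
    return moderated_test(fit, hyper)


@dataclass
class DMRSetComparison:
    """Venn partition of per-group DMR id sets."""

    groups: tuple[str, ...]
    #: frozenset of group names -> set of DMR ids present in exactly those
    cells: dict[frozenset, set]

    @property
    def union(self) -> set:
        out: set = set()
        for members in self.cells.values():
            out |= members
        return out

    def specific(self, group: str) -> set:
        return set(self.cells.get(frozenset([group]), set()))

    def stable(self, group: str) -> set:
        """DMRs of ``group`` shared with at least one other group."""
        out: set = set()
        for key, members in self.cells.items():
            if group in key and len(key) >= 2:
                out |= members
        return out

    def counts(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(key)), len(members))
            for key, members in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["cell", "n"])


def partition_dmr_sets(group_sets: dict[str, set]) -> DMRSetComparison:
    """Assign every DMR id to exactly one Venn cell (its membership pattern)."""
    if len(group_sets) < 2:
        raise ValueError("need >= 2 groups to partition")
    cells: dict[frozenset, set] = {}
    universe = set().union(*group_sets.values())
    for dmr in universe:
        key = frozenset(g for g, ids in group_sets.items() if dmr in ids)
        cells.setdefault(key, set()).add(dmr)
    return DMRSetComparison(tuple(group_sets), cells)
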