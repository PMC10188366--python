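"""Statistical post-processing of mutation counts.

Stages, in the order a run applies them:

* batch-effect screen: one-way ANOVA of per-member mutation frequencies
  across batches at a Bonferroni-corrected family-wise level of 0.005
  (flagged hypotheses are reported, not removed, by default);
* two-replicate sequencing-noise filter: a mutation is kept iff the product
  of upper-tail binomial probabilities P(X_i >= k_i), X_i ~ Binomial(n_i, p)
  with p = 1e-3 (Q30), is below 0.05 - i.e. the observation is less than 5%
  likely to be sequencing noise in both replicates jointly;
* replicate pooling: efficiency = sum(k_i) / sum(n_i), the maximum-likelihood
  rate of the underlying Bernoulli;
* position-wise profiles, the >= 30%-of-peak editing window, the
  geometric-mean C->T : A->G selectivity over the window, read-level average
  editing efficiency, conditional co-editing and the A->G : C->T ratio.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assign import AssignmentResult
from .library import A_TO_G, C_TO_T, WINDOW_POSITIONS

logger = logging.getLogger(__name__)

_COUNT_KEY = ["member_id", "position", "ref_base", "alt_base"]


@dataclass(frozen=True)
class NoiseFilterConfig:
    error_rate: float = 1e-3
    keep_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0, 1)")
        if not 0 < self.keep_threshold < 1:
            raise ValueError("keep_threshold must be in (0, 1)")


@dataclass(frozen=True)
class AnovaConfig:
    family_alpha: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.family_alpha < 1:
            raise ValueError("family_alpha must be in (0, 1)")


@dataclass(frozen=True)
class WindowConfig:
    peak_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.peak_fraction <= 1:
            raise ValueError("peak_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# noise filter
# ---------------------------------------------------------------------------


def noise_probability(
    k1: int, n1: int, k2: int, n2: int, config: NoiseFilterConfig | None = None
) -> float:
    """Joint probability that counts this large arise from sequencing noise.

    Returns P(X1 >= k1) * P(X2 >= k2) with X_i ~ Binomial(n_i, error_rate).
    The mutation is retained downstream iff this probability is below
    ``keep_threshold``; a mutation present at low counts in *both* replicates
    can therefore survive even when each replicate alone would not.
    """
    if config is None:
        config = NoiseFilterConfig()
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    p = config.error_rate
    return float(stats.binom.sf(k1 - 1, n1, p) * stats.binom.sf(k2 - 1, n2, p))


def apply_noise_filter(
    counts: pd.DataFrame, config: NoiseFilterConfig | None = None
) -> pd.DataFrame:
    """Per-mutation keep decisions from replicate-level counts.

    Returns one row per (member_id, position, ref_base, alt_base) with the
    joint noise probability (product of per-replicate binomial upper tails)
    and a boolean ``keep``.
    """
    if config is None:
        config = NoiseFilterConfig()
    tails = stats.binom.sf(
        counts["edited_reads"].to_numpy() - 1,
        counts["total_reads"].to_numpy(),
        config.error_rate,
    )
    probs = (
        counts.assign(_tail=tails)
        .groupby(_COUNT_KEY, sort=True)["_tail"]
        .prod()
        .rename("noise_probability")
        .reset_index()
    )
    probs["keep"] = probs["noise_probability"] < config.keep_threshold
    return probs


# ---------------------------------------------------------------------------
# batch-effect ANOVA
# ---------------------------------------------------------------------------


def batch_anova(
    counts: pd.DataFrame, config: AnovaConfig | None = None
) -> pd.DataFrame:
    """One-way ANOVA of per-member mutation frequencies across batches.

    For each (position, ref, alt) hypothesis the groups are the batch
    (replicate) labels and the observations are per-member frequencies
    k/n.  Hypotheses with fewer than 2 groups of >= 2 observations are
    reported as untestable; groups of identical constant values return
    p = 1 by convention.  ``flagged`` marks p < family_alpha / m with m the
    number of testable hypotheses.
    """
    if config is None:
        config = AnovaConfig()
    df = counts[counts["total_reads"] > 0].copy()
    df["freq"] = df["edited_reads"] / df["total_reads"]

    rows = []
    for (pos, ref, alt), grp in df.groupby(["position", "ref_base", "alt_base"]):
        groups = [g["freq"].to_numpy() for _, g in grp.groupby("replicate")]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            rows.append((pos, ref, alt, np.nan, np.nan, False))
            continue
        pooled = np.concatenate(groups)
        if np.allclose(pooled, pooled[0]):
            rows.append((pos, ref, alt, 0.0, 1.0, True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, pval = stats.f_oneway(*groups)
        if not np.isfinite(pval):
            # identical within-group values but different means
            pval = 0.0
        rows.append((pos, ref, alt, float(f), float(pval), True))
    out = pd.DataFrame(
        rows,
        columns=["position", "ref_base", "alt_base", "F", "p_value", "testable"],
    )
    m = int(out["testable"].sum())
    out["flagged"] = out["testable"] & (out["p_value"] < config.family_alpha / max(m, 1))
    out.attrs["n_testable"] = m
    return out


# ---------------------------------------------------------------------------
# pooling and profiles
# ---------------------------------------------------------------------------


def pool_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Pool replicate counts: efficiency = sum(k) / sum(n) per mutation.

    Zero pooled coverage yields a missing (NaN) efficiency, never 0.
    """
    pooled = (
        counts.groupby(_COUNT_KEY, sort=True)[["edited_reads", "total_reads"]]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled["efficiency"] = np.where(
            pooled["total_reads"] > 0,
            pooled["edited_reads"] / pooled["total_reads"],
            np.nan,
        )
    return pooled


def position_profile(pooled: pd.DataFrame) -> pd.DataFrame:
    """Per-position, per-class profile: unweighted mean over members.

    Only members with pooled coverage at the position contribute.  Columns:
    position, ref_base, alt_base, efficiency, n_members, total_reads.
    """
    df = pooled[pooled["total_reads"] > 0]
    prof = (
        df.groupby(["position", "ref_base", "alt_base"], sort=True)
        .agg(
            efficiency=("efficiency", "mean"),
            n_members=("member_id", "nunique"),
            total_reads=("total_reads", "sum"),
        )
        .reset_index()
    )
    return prof


def class_profile(profile: pd.DataFrame, mutation: tuple[str, str]) -> dict[int, float]:
    ref, alt = mutation
    sel = profile[(profile["ref_base"] == ref) & (profile["alt_base"] == alt)]
    return dict(zip(sel["position"].astype(int), sel["efficiency"].astype(float)))


def editing_window(
    profile_by_pos: dict[int, float], config: WindowConfig | None = None
) -> set[int]:
    """Positions whose efficiency is >= peak_fraction of the peak efficiency.

    The window need not be contiguous and is reported as-is; an all-zero
    profile yields an empty window with a warning.
    """
    if config is None:
        config = WindowConfig()
    if not profile_by_pos:
        raise ValueError("profile has no positions with defined efficiency")
    finite = {p: e for p, e in profile_by_pos.items() if np.isfinite(e)}
    if not finite:
        raise ValueError("profile has no positions with defined efficiency")
    peak = max(finite.values())
    if peak <= 0:
        logger.warning("all efficiencies are zero; editing window is empty")
        return set()
    threshold = config.peak_fraction * peak
    return {pos for pos, eff in finite.items() if eff >= threshold}


def selectivity(
    c_profile: dict[int, float],
    a_profile: dict[int, float],
    window: set[int],
) -> float:
    """Geometric mean over window positions of the C->T : A->G ratio.

    Positions where the A->G efficiency is zero or undefined are excluded
    with a warning (the log-ratio is undefined there); if no usable position
    remains the selectivity is NaN.
    """
    if not window:
        raise ValueError("editing window is empty")
    logs = []
    for pos in sorted(window):
        c = c_profile.get(pos, np.nan)
        a = a_profile.get(pos, np.nan)
        if not np.isfinite(c) or not np.isfinite(a) or a <= 0 or c <= 0:
            logger.warning(
                "position %d excluded from selectivity (C->T=%s, A->G=%s)",
                pos, c, a,
            )
            continue
        logs.append(math.log(c / a))
    if not logs:
        return float("nan")
    return float(math.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# read-level statistics
# ---------------------------------------------------------------------------


def _read_flags(
    calls: pd.DataFrame,
    keep: pd.DataFrame | None,
    window: set[int] | None,
) -> pd.DataFrame:
    """Per-read booleans: carries >= 1 retained C->T / A->G call."""
    df = calls
    if window is not None:
        df = df[df["position"].isin(window)]
    if keep is not None:
        kept = keep[keep["keep"]][_COUNT_KEY]
        df = df.merge(kept, on=_COUNT_KEY, how="inner")
    if df.empty:
        return pd.DataFrame(
            columns=["replicate", "member_id", "read_index", "c2t", "a2g"]
        )
    df = df.assign(
        c2t=(df["ref_base"] == "C") & (df["alt_base"] == "T"),
        a2g=(df["ref_base"] == "A") & (df["alt_base"] == "G"),
    )
    return (
        df.groupby(["replicate", "member_id", "read_index"], sort=False)[["c2t", "a2g"]]
        .any()
        .reset_index()
    )


def average_editing_efficiency(
    calls: pd.DataFrame,
    reads_per_member: pd.DataFrame,
    mutation: tuple[str, str] = C_TO_T,
    keep: pd.DataFrame | None = None,
    window: set[int] | None = None,
) -> tuple[float, pd.Series]:
    """Average fraction of reads with >= 1 retained edit of ``mutation``.

    Per member, the fraction of genotyped reads (pooled across replicates)
    carrying at least one retained call of the class within the window; the
    headline value is the unweighted mean over members with >= 1 read.
    Returns ``(mean, per-member series)``.
    """
    ref, alt = mutation
    df = calls[(calls["ref_base"] == ref) & (calls["alt_base"] == alt)]
    if window is not None:
        df = df[df["position"].isin(window)]
    if keep is not None:
        kept = keep[keep["keep"]][_COUNT_KEY]
        df = df.merge(kept, on=_COUNT_KEY, how="inner")
    edited = (
        df.drop_duplicates(["replicate", "member_id", "read_index"])
        .groupby("member_id")
        .size()
    )
    totals = reads_per_member.groupby("member_id")["n_reads"].sum()
    totals = totals[totals > 0]
    if totals.empty:
        return float("nan"), pd.Series(dtype=float)
    frac = edited.reindex(totals.index, fill_value=0) / totals
    return float(frac.mean()), frac


def conditional_coediting(
    calls: pd.DataFrame,
    keep: pd.DataFrame | None = None,
    window: set[int] | None = None,
) -> float:
    """P(read has >= 1 A->G call | read has >= 1 C->T call)."""
    flags = _read_flags(calls, keep, window)
    n_ct = int(flags["c2t"].sum())
    if n_ct == 0:
        return float("nan")
    n_both = int((flags["c2t"] & flags["a2g"]).sum())
    return n_both / n_ct


def abe_cbe_ratio(avg_a2g: float, avg_c2t: float) -> float:
    """Average A->G efficiency divided by average C->T efficiency."""
    if not np.isfinite(avg_c2t) or avg_c2t == 0:
        return float("nan")
    return avg_a2g / avg_c2t


# ---------------------------------------------------------------------------
# one-call quantification of an assignment result
# ---------------------------------------------------------------------------


@dataclass
class QuantConfig:
    noise: NoiseFilterConfig = field(default_factory=NoiseFilterConfig)
    anova: AnovaConfig = field(default_factory=AnovaConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    drop_flagged: bool = False


@dataclass
class QuantResults:
    """Pooled profiles and headline statistics for one editor run."""

    profile: pd.DataFrame
    pooled: pd.DataFrame
    noise_keep: pd.DataFrame
    anova: pd.DataFrame
    window: set[int]
    selectivity: float
    average_efficiency: dict[str, float]
    per_member_efficiency: dict[str, pd.Series]
    conditional_coediting: float
    abe_cbe_ratio: float
    report: dict[str, dict[str, int]]

    @property
    def peak_position(self) -> int:
        prof = class_profile(self.profile, C_TO_T)
        return max(prof, key=prof.get)

    @property
    def peak_efficiency(self) -> float:
        prof = class_profile(self.profile, C_TO_T)
        return max(prof.values())

    def summary(self) -> str:
        window = sorted(self.window)
        lines = [
            "Base-editing library quantification",
            "===================================",
            f"members quantified        {self.pooled['member_id'].nunique()}",
            f"peak C>T position         {self.peak_position}",
            f"peak C>T efficiency       {self.peak_efficiency:.3f}",
            f"editing window (>=30%)    {window[0]}..{window[-1]}"
            if window else "editing window (>=30%)    (empty)",
            f"C>T : A>G selectivity     {self.selectivity:.1f}",
            f"avg C>T efficiency        {self.average_efficiency['C2T']:.3f}",
            f"avg A>G efficiency        {self.average_efficiency['A2G']:.3f}",
            f"A>G : C>T ratio           {self.abe_cbe_ratio:.2f}",
            f"P(A>G | C>T) per read     {self.conditional_coediting:.3f}",
            f"batch-effect hypotheses   {int(self.anova['testable'].sum())} tested, "
            f"{int(self.anova['flagged'].sum())} flagged",
        ]
        return "\n".join(lines)


def quantify(
    assignment: AssignmentResult, config: QuantConfig | None = None
) -> QuantResults:
    """Run the full statistical post-processing on an assignment result."""
    if config is None:
        config = QuantConfig()
    counts = assignment.counts
    anova = batch_anova(counts, config.anova)
    if config.drop_flagged and anova["flagged"].any():
        flagged = anova[anova["flagged"]][["position", "ref_base", "alt_base"]]
        counts = counts.merge(
            flagged.assign(_drop=True),
            on=["position", "ref_base", "alt_base"],
            how="left",
        )
        counts = counts[counts["_drop"].isna()].drop(columns="_drop")
    keep = apply_noise_filter(counts, config.noise)
    pooled = pool_replicates(counts)
    # zero out mutations attributed to sequencing noise, keep denominators
    pooled = pooled.merge(keep[_COUNT_KEY + ["keep"]], on=_COUNT_KEY, how="left")
    pooled["edited_reads"] = np.where(pooled["keep"], pooled["edited_reads"], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled["efficiency"] = np.where(
            pooled["total_reads"] > 0,
            pooled["edited_reads"] / pooled["total_reads"],
            np.nan,
        )
    profile = position_profile(pooled)
    c_prof = class_profile(profile, C_TO_T)
    a_prof = class_profile(profile, A_TO_G)
    window = editing_window(c_prof, config.window)
    sel = selectivity(c_prof, a_prof, window) if window else float("nan")
    avg_c, per_c = average_editing_efficiency(
        assignment.calls, assignment.reads_per_member, C_TO_T, keep=keep
    )
    avg_a, per_a = average_editing_efficiency(
        assignment.calls, assignment.reads_per_member, A_TO_G, keep=keep
    )
    cond = conditional_coediting(assignment.calls, keep=keep)
    return QuantResults(
        profile=profile,
        pooled=pooled,
        noise_keep=keep,
        anova=anova,
        window=window,
        selectivity=sel,
        average_efficiency={"C2T": avg_c, "A2G": avg_a},
        per_member_efficiency={"C2T": per_c, "A2G": per_a},
        conditional_coediting=cond,
        abe_cbe_ratio=abe_cbe_ratio(avg_a, avg_c),
        report=assignment.report,
    )
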