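"""Trophic-mode group statistics.

Strain-level metrics (total GC content, gene density, region GC) are
compared across the three nutritional modes — phototroph, mixotroph,
heterotroph — with classical fixed-effects one-way ANOVA, a Tukey HSD (or
Holm-adjusted pairwise-t) posthoc, paired t-tests between genomic regions of
the same strains, and Pearson/Spearman correlation screens. All functions
are pure: no randomness, no hidden state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StrainObservation:
    strain: str
    species: str
    mode: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for strain {self.strain!r}")


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]


def _to_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations
    else:
        df = pd.DataFrame([o.__dict__ for o in observations])
    if "mode" not in df.columns or "value" not in df.columns:
        raise ValueError("observations need 'mode' and 'value' columns")
    return df


def group_means(observations, round_to: int | None = 1) -> dict[str, float]:
    """Arithmetic mean per trophic mode, rounded for reporting."""
    df = _to_frame(observations)
    means = df.groupby("mode")["value"].mean()
    if round_to is not None:
        means = means.round(round_to)
    return means.to_dict()


def one_way_anova(observations) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA (F = MSB/MSW) across modes."""
    df = _to_frame(observations)
    groups = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("mode")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n = sum(len(g) for g in groups)
    df_between = len(groups) - 1
    df_within = n - len(groups)
    if df_within < 1:
        raise ValueError("ANOVA needs residual degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        f_stat, p = (0.0, 1.0) if ssb == 0.0 else (math.inf, 0.0)
    else:
        f_stat = (ssb / df_between) / (ssw / df_within)
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(f_stat=float(f_stat), df_between=df_between, df_within=df_within,
                       p_value=p, group_means=group_means(df, round_to=None))


def posthoc_pairwise(observations, method: str = "tukey_hsd") -> dict[tuple[str, str], float]:
    """Family-wise-adjusted pairwise p-values between all mode pairs.

    ``tukey_hsd`` (default) uses the studentized-range distribution;
    ``holm_t`` runs two-sample pooled-variance t-tests with Holm step-down
    adjustment.
    """
    df = _to_frame(observations)
    names = sorted(df["mode"].unique())
    groups = {m: df.loc[df["mode"] == m, "value"].to_numpy(dtype=float) for m in names}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        return {pair: 1.0 for pair in pairs}
    if method == "tukey_hsd":
        res = sps.tukey_hsd(*(groups[m] for m in names))
        return {(a, b): float(res.pvalue[names.index(a), names.index(b)]) for a, b in pairs}
    if method == "holm_t":
        raw = []
        for a, b in pairs:
            _, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
            raw.append(float(p))
        order = np.argsort(raw)
        adj = [0.0] * len(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(raw) - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        return {pair: adj[i] for i, pair in enumerate(pairs)}
    raise ValueError(f"unknown posthoc method {method!r}")


REGION_PAIRS = (("coding", "intron"), ("coding", "intergenic"), ("intron", "intergenic"))


def region_gc_tests(region_table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Paired t-tests between region GC values of the same strains.

    ``region_table`` has one row per strain and columns coding, intron,
    intergenic; strains with a missing region are dropped with a warning.
    The regions belong to the same genomes, hence pairing by strain. P-values
    are reported raw (unadjusted).
    """
    cols = [c for pair in REGION_PAIRS for c in pair]
    missing_cols = [c for c in set(cols) if c not in region_table.columns]
    if missing_cols:
        raise ValueError(f"region table lacks column(s) {sorted(missing_cols)}")
    complete = region_table.dropna(subset=["coding", "intron", "intergenic"])
    if len(complete) < len(region_table):
        warnings.warn(f"dropped {len(region_table) - len(complete)} strain(s) with missing regions")
    if len(complete) < 3:
        raise ValueError("paired region tests need at least 3 complete strains")
    out = {}
    for a, b in REGION_PAIRS:
        diff = complete[a].to_numpy(dtype=float) - complete[b].to_numpy(dtype=float)
        if np.all(diff == 0.0):
            out[(a, b)] = 1.0
            continue
        _, p = sps.ttest_rel(complete[a], complete[b])
        out[(a, b)] = float(p)
    return out


def correlation_screen(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p; (nan, nan) on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)
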