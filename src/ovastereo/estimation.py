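"""Fractionator scale-up and study-level summaries.

The fractionator estimate of the total follicle number in an ovary is

    N_hat = sum(Q) / (f1 * f2 * f3)

where sum(Q) is the raw count over the sampled sections and f1, f2, f3 are
the realized sampling fractions (tissue available, slabs selected,
sections sampled).  Because every counting unit is examined with
probability f1*f2*f3 under systematic uniform random sampling, N_hat is
design-unbiased; realized rather than nominal fractions are always used
(the nominal 1/3 is only approximate whenever the slab count is not a
multiple of the interval).

Study summaries follow the cohort workflow: the two ovaries of a bilateral
donor are averaged at the N_hat level first, then subjects are binned into
age groups (default 35-39, 40-44, 45-49, 50-52 years) and group arithmetic
means are reported per stage, together with the primary:primordial ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountResult
from .synthetic_ovary import STAGES

__all__ = [
    "OvaryEstimate",
    "StudySummary",
    "DEFAULT_AGE_BINS",
    "estimate_total",
    "estimates_from_counts",
    "ratio_primary_to_primordial",
    "summarize_groups",
]

#: The study's age bins (inclusive bounds, years).
DEFAULT_AGE_BINS = ((35, 39), (40, 44), (45, 49), (50, 52))


@dataclass(frozen=True)
class OvaryEstimate:
    """Scaled-up total for one stage in one ovary."""

    ovary_id: str
    stage: str
    N_hat: float
    sum_Q: int
    f1: float
    f2: float
    f3: float


@dataclass
class StudySummary:
    """Group-level summary: per-stage group means and primary:primordial
    ratios, after bilateral averaging (two ovaries of one subject are
    averaged before any group mean)."""

    group_means: pd.DataFrame     # columns: group, stage, mean_N_hat, n_subjects
    ratios: pd.DataFrame          # columns: group, ratio_primary_to_primordial
    bilateral_averaged: bool = True


def estimate_total(sum_Q: float, f1: float, f2: float, f3: float) -> float:
    """N_hat = sum(Q) / (f1*f2*f3); fractions must lie in (0, 1]."""
    for name, f in (("f1", f1), ("f2", f2), ("f3", f3)):
        if not (0.0 < f <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {f}")
    if sum_Q < 0:
        raise ValueError(f"sum_Q must be >= 0, got {sum_Q}")
    return sum_Q / (f1 * f2 * f3)


def estimates_from_counts(counts, mode: str = "nucleolus_gated"
                          ) -> list[OvaryEstimate]:
    """Scale up a CountResult (or list of them, or a counts table as written
    by :func:`ovastereo.counting.write_counts`) into per-stage estimates."""
    if isinstance(counts, CountResult):
        counts = [counts]
    out: list[OvaryEstimate] = []
    if isinstance(counts, pd.DataFrame):
        sub = counts[counts["mode"] == mode]
        for row in sub.itertuples(index=False):
            out.append(OvaryEstimate(
                ovary_id=str(row.ovary_id), stage=str(row.stage),
                N_hat=estimate_total(row.sum_Q, row.f1, row.f2, row.f3),
                sum_Q=int(row.sum_Q), f1=row.f1, f2=row.f2, f3=row.f3))
        return out
    for cr in counts:
        if cr.counting_mode != mode:
            continue
        for stage in STAGES:
            q = cr.counts_by_stage.get(stage, 0)
            out.append(OvaryEstimate(
                ovary_id=cr.ovary_id, stage=stage,
                N_hat=estimate_total(q, cr.realized_f1, cr.realized_f2,
                                     cr.realized_f3),
                sum_Q=int(q), f1=cr.realized_f1, f2=cr.realized_f2,
                f3=cr.realized_f3))
    return out


def ratio_primary_to_primordial(estimates: list[OvaryEstimate]) -> float:
    """N_hat(primary) / N_hat(primordial); NaN flags an undefined ratio
    (primordial estimate zero or either stage absent)."""
    prim = [e.N_hat for e in estimates if e.stage == "primordial"]
    pri = [e.N_hat for e in estimates if e.stage == "primary"]
    if not prim or not pri:
        return math.nan
    denom = sum(prim)
    if denom == 0:
        return math.nan
    return sum(pri) / denom


def estimates_table(estimates: list[OvaryEstimate]) -> pd.DataFrame:
    rows = [(e.ovary_id, e.stage, e.N_hat, e.sum_Q, e.f1, e.f2, e.f3)
            for e in estimates]
    return pd.DataFrame(rows, columns=["ovary_id", "stage", "N_hat", "sum_Q",
                                       "f1", "f2", "f3"])


def summarize_groups(estimates: list[OvaryEstimate] | pd.DataFrame,
                     ages: pd.DataFrame,
                     bins=DEFAULT_AGE_BINS) -> StudySummary:
    """Bilateral-average then group-average the estimates.

    ``ages`` maps ovaries to donors: columns ovary_id, subject_id, age.
    ``bins`` is a sequence of inclusive (lo, hi) age bounds; an age falling
    outside every bin raises, naming the offending ovaries.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_table(estimates)
    need = {"ovary_id", "subject_id", "age"}
    if not need.issubset(ages.columns):
        raise ValueError(f"ages table must have columns {sorted(need)}")
    merged = df.merge(ages[["ovary_id", "subject_id", "age"]], on="ovary_id",
                      how="left")
    if merged["subject_id"].isna().any():
        lost = sorted(merged.loc[merged["subject_id"].isna(), "ovary_id"].unique())
        raise ValueError(f"ovaries missing from ages table: {lost}")

    def to_group(age):
        for lo, hi in bins:
            if lo <= age <= hi:
                return f"{lo}-{hi}"
        return None

    merged["group"] = merged["age"].map(to_group)
    if merged["group"].isna().any():
        lost = sorted(merged.loc[merged["group"].isna(), "ovary_id"].unique())
        raise ValueError(f"age outside all bins for ovaries: {lost}")

    # bilateral mean first, then group mean
    per_subject = (merged.groupby(["group", "subject_id", "stage"], sort=True)
                   ["N_hat"].mean().reset_index())
    gm = (per_subject.groupby(["group", "stage"], sort=True)
          .agg(mean_N_hat=("N_hat", "mean"), n_subjects=("subject_id", "nunique"))
          .reset_index())

    wide = gm.pivot(index="group", columns="stage", values="mean_N_hat")
    ratios = []
    for group in wide.index:
        prim = wide.get("primordial", pd.Series(dtype=float)).get(group, np.nan)
        pri = wide.get("primary", pd.Series(dtype=float)).get(group, np.nan)
        r = math.nan if (pd.isna(prim) or pd.isna(pri) or prim == 0) else pri / prim
        ratios.append((group, r))
    ratios_df = pd.DataFrame(ratios, columns=["group", "ratio_primary_to_primordial"])
    return StudySummary(group_means=gm, ratios=ratios_df, bilateral_averaged=True)
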