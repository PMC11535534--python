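"""Counting rules applied to section observations.

The counting unit for primordial and primary follicles is the oocyte
nucleolus: a follicle enters the raw count Q only in a section where its
nucleolus is visible, and once counted it is excluded from all subsequent
adjacent sections of the same serial run (so a nucleolus spanning several
sections is still counted exactly once).  ``profile_presence`` mode -- a
follicle counted in every sampled section showing any oocyte profile -- is
deliberately naive; it exists to quantify the size-dependent overcounting
that motivates treating large (secondary+) follicles with a separate
relative scheme rather than the fractionator.

Also provided: the secondary-follicle relative count (1-of-50 sections,
no scale-up, for between-ovary comparison only), the per-section growing-
follicle raw count (whole-section profile counts at 50-section intervals),
and primordial profile-diameter morphometry measured in the section where
each follicle was counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sectioning import SectioningResult, SectionObservation, OBSERVATION_COLUMNS
from .synthetic_ovary import STAGES, GROWING_STAGES

__all__ = [
    "CountResult",
    "COUNTING_MODES",
    "apply_counting_rule",
    "count_secondary_relative",
    "count_growing_raw",
    "measure_primordial_diameters",
    "write_counts",
    "read_counts",
]

COUNTING_MODES = ("nucleolus_gated", "profile_presence")


@dataclass
class CountResult:
    """Per-stage raw counts with the realized sampling fractions.

    ``counts_by_stage`` maps every stage to its raw count sum(Q); the
    fractions are what the fractionator scale-up divides by.  ``counted``
    (nucleolus-gated mode) keeps the observation row in which each follicle
    was counted, for downstream morphometry.
    """

    counts_by_stage: dict[str, int]
    realized_f1: float
    realized_f2: float
    realized_f3: float
    counting_mode: str
    ovary_id: str = "ovary"
    counted: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts_by_stage.values())


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------

def _as_frame(observations) -> tuple[pd.DataFrame, SectioningResult | None]:
    """Accept a SectioningResult, an observations DataFrame, or a list of
    SectionObservation; return (long-format DataFrame, result-or-None)."""
    if isinstance(observations, SectioningResult):
        return observations.observations, observations
    if isinstance(observations, pd.DataFrame):
        return observations, None
    rows = []
    for so in observations:
        if not isinstance(so, SectionObservation):
            raise TypeError(f"unsupported observation type {type(so)!r}")
        for p in so.profiles:
            rows.append({
                "slab_index": so.frame.slab_index,
                "section_index": so.frame.section_index_in_slab,
                "z_lo": so.frame.z_lo, "z_hi": so.frame.z_hi,
                "sampled": so.frame.sampled,
                "follicle_id": p["follicle_id"], "stage": p["stage"],
                "oocyte_profile": p["oocyte_profile_diameter"],
                "nucleus_profile": p["nucleus_profile_diameter"],
                "nucleolus_visible": p["nucleolus_visible"],
                "nucleolus_chord": p["nucleolus_chord"],
            })
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS), None


def _check_ordered(obs: pd.DataFrame) -> None:
    key = obs["slab_index"].to_numpy(float) * 2**32 + obs["section_index"].to_numpy(float)
    if np.any(np.diff(key) < 0):
        raise ValueError("observations must be ordered by (slab_index, section_index)")


def _run_ids(obs: pd.DataFrame) -> pd.Series:
    """Serial-run id per observation row.

    Sections adjacent in z (each starting where the previous one ended)
    form one run -- including across a slab boundary under exhaustive
    sampling, where the last section of one slab physically abuts the
    first of the next; any z gap starts a new run.
    """
    frames = obs[["slab_index", "section_index", "z_lo", "z_hi"]] \
        .drop_duplicates(subset=["slab_index", "section_index"]) \
        .sort_values(["slab_index", "section_index"])
    z_lo = frames["z_lo"].to_numpy(float)
    z_hi = frames["z_hi"].to_numpy(float)
    new_run = np.ones(len(frames), dtype=bool)
    if len(frames) > 1:
        thickness = z_hi[0] - z_lo[0]
        new_run[1:] = np.abs(z_lo[1:] - z_hi[:-1]) > 1e-6 * thickness
    frames = frames.assign(_run=np.cumsum(new_run) - 1)
    merged = obs.merge(frames[["slab_index", "section_index", "_run"]],
                       on=["slab_index", "section_index"], how="left")
    return merged["_run"]


def _gated_events(obs: pd.DataFrame) -> pd.DataFrame:
    """First visible observation of each follicle per serial run (the
    sections in which follicles are actually counted)."""
    samp = obs[obs["sampled"]].copy()
    if len(samp) == 0:
        return samp
    samp["_run"] = _run_ids(samp).to_numpy()
    vis = samp[samp["nucleolus_visible"].astype(bool)]
    # obs is ordered by section, so the first row per (run, follicle) is the
    # first section where the nucleolus shows; later rows of the run are the
    # adjacent-section exclusions.
    return vis.drop_duplicates(subset=["_run", "follicle_id"], keep="first")


# ---------------------------------------------------------------------------
# counting operations
# ---------------------------------------------------------------------------

def apply_counting_rule(observations, mode: str = "nucleolus_gated", *,
                        fractions: tuple[float, float, float] | None = None,
                        ovary_id: str = "ovary") -> CountResult:
    """Accumulate per-stage raw counts sum(Q) under a counting rule.

    ``observations`` may be a :class:`SectioningResult` (fractions are taken
    from it), an observations DataFrame, or a list of
    :class:`SectionObservation` (then ``fractions`` must be supplied or
    defaults to all 1).
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    obs, res = _as_frame(observations)
    _check_ordered(obs)
    bad = set(obs["stage"].unique()) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    if fractions is None:
        fractions = ((res.realized_f1, res.realized_f2, res.realized_f3)
                     if res is not None else (1.0, 1.0, 1.0))
    f1, f2, f3 = fractions

    counted = None
    if mode == "nucleolus_gated":
        events = _gated_events(obs)
        vc = events["stage"].value_counts() if len(events) else pd.Series(dtype=int)
        counted = events
    else:
        samp = obs[obs["sampled"]]
        vc = samp["stage"].value_counts() if len(samp) else pd.Series(dtype=int)
    counts = {s: int(vc.get(s, 0)) for s in STAGES}
    return CountResult(counts_by_stage=counts, realized_f1=float(f1),
                       realized_f2=float(f2), realized_f3=float(f3),
                       counting_mode=mode, ovary_id=ovary_id, counted=counted)


def count_secondary_relative(observations) -> int:
    """Raw nucleolus-gated secondary-follicle count, no fractionator scale-up.

    Valid only for a 1-of-50 single-section plan (run_length = 1): sampled
    sections must be isolated, never adjacent.  Intended for between-ovary
    comparison of secondary follicles, whose size makes the fractionator
    scheme used for small follicles overcount them.
    """
    obs, res = _as_frame(observations)
    if res is not None and res.plan.run_length != 1:
        raise ValueError(
            f"secondary relative counting requires run_length = 1, got "
            f"{res.plan.run_length}")
    samp = obs[obs["sampled"]]
    if len(samp):
        frames = samp[["slab_index", "section_index"]].drop_duplicates().sort_values(
            ["slab_index", "section_index"]).to_numpy()
        adjacent = (len(frames) > 1 and np.any(
            (frames[1:, 0] == frames[:-1, 0]) & (frames[1:, 1] == frames[:-1, 1] + 1)))
        if adjacent:
            raise ValueError("sampled sections are adjacent; plan is not 1-of-50")
    events = _gated_events(obs)
    if len(events) == 0:
        return 0
    return int((events["stage"] == "secondary").sum())


def count_growing_raw(observations) -> pd.DataFrame:
    """Whole-section raw counts of growing follicles per sampled section.

    Counts every growing follicle (primary, secondary, antral) showing any
    oocyte profile -- no nucleolus gate, no scale-up; mirrors per-section
    growing-follicle counts taken at 50-section intervals.  Returns one row
    per sampled section: slab_index, section_index, n_growing.
    """
    obs, res = _as_frame(observations)
    samp = obs[obs["sampled"]]
    growing = samp[samp["stage"].isin(GROWING_STAGES)]
    counts = (growing.groupby(["slab_index", "section_index"])["follicle_id"]
              .nunique().rename("n_growing"))
    if res is not None:
        idx = res.frames[res.frames["sampled"]][["slab_index", "section_index"]]
    else:
        idx = samp[["slab_index", "section_index"]].drop_duplicates()
    out = idx.drop_duplicates().sort_values(["slab_index", "section_index"])
    out = out.merge(counts, on=["slab_index", "section_index"], how="left")
    out["n_growing"] = out["n_growing"].fillna(0).astype(int)
    return out.reset_index(drop=True)


def measure_primordial_diameters(observations) -> dict:
    """Mean oocyte and nucleus profile diameters of counted primordial
    follicles, measured in the section where each was counted.

    Returns {'mean_oocyte_diameter', 'mean_nucleus_diameter', 'n'}; the
    means are NaN when no primordial follicle was counted (n = 0).
    """
    obs, _ = _as_frame(observations)
    events = _gated_events(obs)
    prim = events[events["stage"] == "primordial"] if len(events) else events
    n = int(len(prim))
    if n == 0:
        return {"mean_oocyte_diameter": float("nan"),
                "mean_nucleus_diameter": float("nan"), "n": 0}
    return {"mean_oocyte_diameter": float(prim["oocyte_profile"].mean()),
            "mean_nucleus_diameter": float(prim["nucleus_profile"].mean()),
            "n": n}


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_counts(results: list[CountResult] | CountResult, path) -> None:
    """Write counts as a tidy table: ovary_id, stage, mode, sum_Q, f1, f2, f3."""
    if isinstance(results, CountResult):
        results = [results]
    rows = []
    for r in results:
        for stage in STAGES:
            rows.append((r.ovary_id, stage, r.counting_mode,
                         r.counts_by_stage.get(stage, 0),
                         r.realized_f1, r.realized_f2, r.realized_f3))
    pd.DataFrame(rows, columns=["ovary_id", "stage", "mode", "sum_Q",
                                "f1", "f2", "f3"]).to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ["ovary_id", "stage", "mode", "sum_Q", "f1", "f2", "f3"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    return df
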