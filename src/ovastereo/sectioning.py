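"""Virtual microtomy: slabs, systematic slab sampling, serial-section runs,
and sphere-section intersection geometry.

The physical design mirrors routine ovarian stereology: the ovary is cut
into 1-mm slabs perpendicular to its long axis; a systematic random third
of the slabs is selected (fixed interval, uniformly random start); each
selected slab is cut into 5-um sections, and within every group of 50
consecutive sections a serial run of 5 sections is collected.  Sections
are 3D slices with thickness, not planes; every z interval is half-open
[lo, hi) with z measured from the ovary's lower pole, so frames tile a
slab exactly and no structure can be attributed to two sections.

What the virtual histologist records on a section: for every follicle
whose oocyte sphere intersects the section, the oocyte and nucleus chord
(profile) diameters at the section mid-plane, and whether the oocyte
nucleolus is visible in the section.  Nucleolus visibility is governed by
``nucleolus_visibility`` in [0, 1], the fraction of the true nucleolus
diameter the in-section chord must reach.  The default 1.0 is the
classical in-focus convention -- the nucleolus counts only in the section
containing its center, so the counting gate fires in exactly one section
and the fractionator is unbiased.  0.0 is the permissive any-intersection
reading, under which a nucleolus spanning a section boundary is seen
twice; the resulting overcount is quantified in :mod:`ovastereo.mc_study`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_ovary import OvaryModel

__all__ = [
    "SamplingPlan",
    "SectionFrame",
    "SectionObservation",
    "SectioningResult",
    "OBSERVATION_COLUMNS",
    "cut_slabs",
    "select_slabs",
    "select_serial_runs",
    "observe_frames",
    "observe_section",
    "section_ovary",
    "write_observations",
    "read_observations",
]

#: Column schema of the observations table.
OBSERVATION_COLUMNS = [
    "slab_index", "section_index", "z_lo", "z_hi", "sampled",
    "follicle_id", "stage", "oocyte_profile", "nucleus_profile",
    "nucleolus_visible", "nucleolus_chord",
]


@dataclass(frozen=True)
class SamplingPlan:
    """The sampling design (defaults: 1-mm slabs, 1-in-3 slab sampling,
    5-um sections, 5-of-50 serial runs).

    ``slab_start`` (1-based, in [1, slab_interval]) and ``run_start``
    (1-based, in [1, group_size - run_length + 1]) may be "random", in which
    case a single uniformly random start is drawn per ovary.  With
    ``per_slab_run_start`` the serial-run offset is re-drawn for every slab
    instead of reused across the whole ovary.
    """

    slab_thickness: float = 1000.0
    slab_interval: int = 3
    slab_start: int | str = "random"
    section_thickness: float = 5.0
    group_size: int = 50
    run_length: int = 5
    run_start: int | str = "random"
    per_slab_run_start: bool = False

    def __post_init__(self):
        if self.slab_thickness <= 0 or self.section_thickness <= 0:
            raise ValueError("slab and section thickness must be > 0")
        if self.slab_interval < 1:
            raise ValueError("slab_interval must be >= 1")
        if not (1 <= self.run_length <= self.group_size):
            raise ValueError("need 1 <= run_length <= group_size")
        if self.slab_start != "random" and not (1 <= int(self.slab_start) <= self.slab_interval):
            raise ValueError("slab_start must be 'random' or in [1, slab_interval]")
        max_start = self.group_size - self.run_length + 1
        if self.run_start != "random" and not (1 <= int(self.run_start) <= max_start):
            raise ValueError(f"run_start must be 'random' or in [1, {max_start}]")

    @property
    def sections_per_slab(self) -> int:
        """Sections obtainable from a full slab (floor division)."""
        return int(self.slab_thickness // self.section_thickness)

    @classmethod
    def exhaustive(cls, **kw) -> "SamplingPlan":
        """Plan that keeps every slab and samples every section (f2=f3=1)."""
        kw.setdefault("slab_interval", 1)
        kw.setdefault("slab_start", 1)
        gs = kw.setdefault("group_size", 50)
        kw.setdefault("run_length", gs)
        kw.setdefault("run_start", 1)
        return cls(**kw)


@dataclass(frozen=True)
class SectionFrame:
    """One section's z-interval [z_lo, z_hi), with its sampling flag."""

    slab_index: int
    section_index_in_slab: int
    z_lo: float
    z_hi: float
    sampled: bool = True


@dataclass
class SectionObservation:
    """What is recorded on one section: per-follicle profile rows."""

    frame: SectionFrame
    profiles: list[dict]


@dataclass
class SectioningResult:
    """Full output of sectioning one ovary.

    ``observations`` has one row per (sampled section, intersecting
    follicle); ``frames`` lists every section of every selected slab with
    its ``sampled`` flag.  Realized fractions are the bookkeeping the
    fractionator divides by: f1 = kept/total follicles after tissue
    thinning, f2 = selected/total slabs, f3 = sampled/total sections over
    the selected slabs.
    """

    observations: pd.DataFrame
    frames: pd.DataFrame
    selected_slabs: list[int]
    n_slabs_total: int
    realized_f1: float
    realized_f2: float
    realized_f3: float
    plan: SamplingPlan
    seed: int | None = None
    nucleolus_visibility: float = 1.0


# ---------------------------------------------------------------------------
# slabs and sections
# ---------------------------------------------------------------------------

def cut_slabs(model: OvaryModel | float, plan: SamplingPlan) -> list[tuple[float, float]]:
    """Cut the long-axis extent into contiguous half-open slabs.

    Returns ceil(extent / slab_thickness) intervals; the terminal partial
    slab is kept.  A degenerate extent of 0 returns an empty list.
    """
    extent = model.extent if isinstance(model, OvaryModel) else float(model)
    if extent <= 0:
        return []
    n = int(np.ceil(extent / plan.slab_thickness - 1e-12))
    edges = [min(i * plan.slab_thickness, extent) for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n)]


def select_slabs(slabs: list[tuple[float, float]], plan: SamplingPlan,
                 seed_or_rng=None) -> tuple[list[int], float]:
    """Systematic random slab sampling: fixed interval, random start.

    Selected indices are {start-1, start-1+interval, ...} (0-based); the
    realized fraction selected/total -- not the nominal 1/interval -- is
    what the estimator must divide by.
    """
    n = len(slabs)
    if n == 0:
        return [], 1.0
    if plan.slab_start == "random":
        rng = np.random.default_rng(seed_or_rng) if not isinstance(
            seed_or_rng, np.random.Generator) else seed_or_rng
        start = int(rng.integers(1, plan.slab_interval + 1))
    else:
        start = int(plan.slab_start)
    if plan.slab_interval > n:
        warnings.warn(
            f"slab_interval {plan.slab_interval} exceeds slab count {n}; "
            "at most one slab selected", stacklevel=2)
    idx = list(range(start - 1, n, plan.slab_interval))
    return idx, len(idx) / n


def select_serial_runs(slab: tuple[float, float], plan: SamplingPlan,
                       seed_or_rng=None, slab_index: int = 0,
                       run_start: int | None = None
                       ) -> tuple[pd.DataFrame, float]:
    """Enumerate a slab's sections and flag the serial runs as sampled.

    Sections of ``section_thickness`` tile the slab from its lower face
    (floor count; a terminal sliver thinner than one section is not cut,
    as on a real microtome).  Within each consecutive group of
    ``group_size`` sections, the run of ``run_length`` sections starting at
    ``run_start`` (1-based within the group) is sampled; a run overhanging
    a partial terminal group is truncated to the sections that exist, and
    the realized fraction reflects that.

    Returns (frames table, realized_f3 = sampled/total sections in slab).
    """
    z0, z1 = float(slab[0]), float(slab[1])
    width = z1 - z0
    if width < plan.section_thickness:
        raise ValueError(f"slab width {width} below section thickness")
    n_sec = int(width // plan.section_thickness * (1 + 1e-15))
    if run_start is None:
        if plan.run_start == "random":
            rng = np.random.default_rng(seed_or_rng) if not isinstance(
                seed_or_rng, np.random.Generator) else seed_or_rng
            run_start = int(rng.integers(1, plan.group_size - plan.run_length + 2))
        else:
            run_start = int(plan.run_start)
    sec = np.arange(n_sec)
    pos_in_group = sec % plan.group_size
    sampled = (pos_in_group >= run_start - 1) & (pos_in_group < run_start - 1 + plan.run_length)
    z_lo = z0 + sec * plan.section_thickness
    frames = pd.DataFrame({
        "slab_index": slab_index,
        "section_index": sec,
        "z_lo": z_lo,
        "z_hi": z_lo + plan.section_thickness,
        "sampled": sampled,
    })
    return frames, float(sampled.sum()) / n_sec


# ---------------------------------------------------------------------------
# observation geometry
# ---------------------------------------------------------------------------

def _chord(diam: np.ndarray, dz: np.ndarray) -> np.ndarray:
    """Chord diameter of a sphere of diameter ``diam`` cut ``dz`` from its
    center: 2*sqrt(max(0, (d/2)^2 - dz^2))."""
    r = diam / 2.0
    return 2.0 * np.sqrt(np.maximum(0.0, r * r - dz * dz))


def observe_frames(model: OvaryModel, frames: pd.DataFrame,
                   nucleolus_visibility: float = 1.0,
                   sampled_only: bool = True,
                   max_pairs: int = 5_000_000) -> pd.DataFrame:
    """Vectorized observation of many section frames.

    Emits one row per (frame, follicle) pair whose oocyte sphere intersects
    the frame's half-open z-interval.  Oocyte and nucleus profile diameters
    are chords at the section mid-plane; the nucleolus is tested against
    the full section thickness, with its chord evaluated at the in-section
    plane nearest its center (= the full diameter when the center lies in
    the section).  Work is chunked so the frames x follicles broadcast
    never materializes more than ``max_pairs`` pairs at once.
    """
    if not (0.0 <= nucleolus_visibility <= 1.0):
        raise ValueError("nucleolus_visibility must be in [0, 1]")
    fr = frames[frames["sampled"]] if sampled_only else frames
    foll = model.follicles
    if len(fr) == 0 or len(foll) == 0:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)

    cz = foll["cz"].to_numpy(float)
    d_oo = foll["d_oocyte"].to_numpy(float)
    d_nu = foll["d_nucleus"].to_numpy(float)
    d_no = foll["d_nucleolus"].to_numpy(float)
    z_no = cz + foll["off_z"].to_numpy(float)
    fid = foll["id"].to_numpy()
    stage = foll["stage"].to_numpy()

    z_lo_all = fr["z_lo"].to_numpy(float)
    z_hi_all = fr["z_hi"].to_numpy(float)
    meta = fr[["slab_index", "section_index"]].to_numpy()
    sampled_flag = fr["sampled"].to_numpy(bool)

    nf = len(foll)
    chunk = max(1, max_pairs // nf)
    pieces = []
    for lo in range(0, len(fr), chunk):
        zl = z_lo_all[lo:lo + chunk, None]
        zh = z_hi_all[lo:lo + chunk, None]
        zm = 0.5 * (zl + zh)
        hit = (cz[None, :] - d_oo[None, :] / 2 < zh) & (cz[None, :] + d_oo[None, :] / 2 > zl)
        if not hit.any():
            continue
        i_fr, i_fo = np.nonzero(hit)
        zm_h = zm[i_fr, 0]
        zl_h = zl[i_fr, 0]
        zh_h = zh[i_fr, 0]
        oo = _chord(d_oo[i_fo], cz[i_fo] - zm_h)
        nu = _chord(d_nu[i_fo], cz[i_fo] - zm_h)
        zn = z_no[i_fo]
        rn = d_no[i_fo] / 2.0
        present = (zn - rn < zh_h) & (zn + rn > zl_h)
        in_center = (zl_h <= zn) & (zn < zh_h)
        z_eval = np.clip(zn, zl_h, zh_h)
        chord = np.where(present, _chord(d_no[i_fo], zn - z_eval), 0.0)
        if nucleolus_visibility >= 1.0:
            visible = in_center
        else:
            visible = present & (chord >= nucleolus_visibility * d_no[i_fo])
        pieces.append(pd.DataFrame({
            "slab_index": meta[lo + i_fr, 0],
            "section_index": meta[lo + i_fr, 1],
            "z_lo": zl_h, "z_hi": zh_h,
            "sampled": sampled_flag[lo + i_fr],
            "follicle_id": fid[i_fo], "stage": stage[i_fo],
            "oocyte_profile": oo, "nucleus_profile": nu,
            "nucleolus_visible": visible, "nucleolus_chord": chord,
        }))
    if not pieces:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    obs = pd.concat(pieces, ignore_index=True)
    obs.sort_values(["slab_index", "section_index", "follicle_id"],
                    inplace=True, kind="mergesort")
    return obs.reset_index(drop=True)


def observe_section(model: OvaryModel, frame: SectionFrame,
                    nucleolus_visibility: float = 1.0) -> SectionObservation:
    """Observe a single section (thin wrapper over :func:`observe_frames`)."""
    if frame.z_hi <= frame.z_lo:
        raise ValueError("frame must have positive thickness")
    df = pd.DataFrame({
        "slab_index": [frame.slab_index],
        "section_index": [frame.section_index_in_slab],
        "z_lo": [frame.z_lo], "z_hi": [frame.z_hi], "sampled": [True],
    })
    obs = observe_frames(model, df, nucleolus_visibility)
    profiles = [
        {"follicle_id": int(r.follicle_id), "stage": r.stage,
         "oocyte_profile_diameter": float(r.oocyte_profile),
         "nucleus_profile_diameter": float(r.nucleus_profile),
         "nucleolus_visible": bool(r.nucleolus_visible),
         "nucleolus_chord": float(r.nucleolus_chord)}
        for r in obs.itertuples(index=False)
    ]
    return SectionObservation(frame=frame, profiles=profiles)


# ---------------------------------------------------------------------------
# whole-ovary pipeline
# ---------------------------------------------------------------------------

def section_ovary(model: OvaryModel, plan: SamplingPlan, seed: int | None = None,
                  nucleolus_visibility: float = 1.0) -> SectioningResult:
    """Run the full physical sampling design on one ovary.

    Draw order from the seeded generator: (1) f1 tissue thinning -- each
    follicle is independently deleted with probability 1 - f1, mimicking
    removal of a wedge for pathology, and the realized kept/total fraction
    is recorded (the analog of weighing the removed tissue); (2) the slab
    start; (3) the serial-run start (one per ovary, or per slab when the
    plan says so).
    """
    rng = np.random.default_rng(seed)
    foll = model.follicles
    f1 = model.available_fraction_f1
    realized_f1 = f1  # nominal fallback (exact when f1 == 1 or the ovary is empty)
    if f1 < 1.0 and len(foll):
        keep = rng.uniform(size=len(foll)) < f1
        realized_f1 = float(keep.mean()) if keep.any() else f1
        foll = foll[keep].reset_index(drop=True)
    thinned = OvaryModel(model.semi_axes, model.cortex_thickness, foll,
                         available_fraction_f1=f1, seed=model.seed)

    slabs = cut_slabs(model, plan)
    sel, f2 = select_slabs(slabs, plan, rng)

    run_start = None
    if not plan.per_slab_run_start:
        if plan.run_start == "random":
            run_start = int(rng.integers(1, plan.group_size - plan.run_length + 2))
        else:
            run_start = int(plan.run_start)

    frame_tables, tot, samp = [], 0, 0
    for si in sel:
        fr, _ = select_serial_runs(slabs[si], plan, rng, slab_index=si,
                                   run_start=run_start)
        frame_tables.append(fr)
        tot += len(fr)
        samp += int(fr["sampled"].sum())
    frames = (pd.concat(frame_tables, ignore_index=True) if frame_tables
              else pd.DataFrame(columns=["slab_index", "section_index",
                                         "z_lo", "z_hi", "sampled"]))
    f3 = samp / tot if tot else 1.0
    obs = observe_frames(thinned, frames, nucleolus_visibility)
    return SectioningResult(observations=obs, frames=frames,
                            selected_slabs=list(sel), n_slabs_total=len(slabs),
                            realized_f1=float(realized_f1), realized_f2=float(f2),
                            realized_f3=float(f3), plan=plan, seed=seed,
                            nucleolus_visibility=nucleolus_visibility)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_observations(result: SectioningResult, path, meta_path=None) -> None:
    """Write the observations table (CSV) and, optionally, a JSON sidecar
    with the realized fractions and design metadata."""
    result.observations.to_csv(path, index=False)
    if meta_path is not None:
        import json
        meta = {
            "realized_f1": result.realized_f1,
            "realized_f2": result.realized_f2,
            "realized_f3": result.realized_f3,
            "selected_slabs": result.selected_slabs,
            "n_slabs_total": result.n_slabs_total,
            "seed": result.seed,
            "nucleolus_visibility": result.nucleolus_visibility,
            "plan": {k: v for k, v in vars(result.plan).items()},
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_observations(path, meta_path=None):
    """Read an observations table (and metadata sidecar if given).

    Returns the DataFrame alone, or (DataFrame, meta dict).
    """
    obs = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observations table missing columns: {missing}")
    if meta_path is None:
        return obs
    import json
    with open(meta_path) as fh:
        meta = json.load(fh)
    return obs, meta
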