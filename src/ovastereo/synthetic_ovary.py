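"""Synthetic 3D ovaries with staged follicle populations.

The generator produces a ground-truth ovary for the virtual sectioning and
counting pipeline: a prolate ellipsoid whose long axis is the sectioning
(z) axis, carrying a list of follicles.  Each follicle is a nest of
concentric spheres -- follicle > oocyte > nucleus -- plus a nucleolus
sphere placed at a uniform random offset strictly inside the nucleus.
Follicle centers are placed uniformly at random in a cortical shell
(primordial follicles live in the ovarian cortex), with the whole follicle
sphere required to fit inside the ovary.

All stochastic draws come from a single ``numpy.random.Generator`` seeded
per ovary, in a fixed documented order (per stage: sizes, then nucleolus
offsets, then center placement), so identical seeds give field-for-field
identical follicle tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGES",
    "GROWING_STAGES",
    "FOLLICLE_COLUMNS",
    "SizeDist",
    "StageConfig",
    "OvaryConfig",
    "FollicleSpec",
    "OvaryModel",
    "PlacementError",
    "ConfigError",
    "generate_ovary",
    "validate_ovary",
    "ellipsoid_max_scaled",
    "write_follicles",
    "read_follicles",
]

#: Follicle stages, in generation order (also the canonical table order).
STAGES = ("primordial", "primary", "secondary", "antral")

#: Stages counted as "growing follicles" (everything past primordial).
GROWING_STAGES = ("primary", "secondary", "antral")

#: Column schema of the follicle table (units: micrometres).
FOLLICLE_COLUMNS = [
    "id", "stage", "cx", "cy", "cz",
    "d_follicle", "d_oocyte", "d_nucleus", "d_nucleolus",
    "off_x", "off_y", "off_z",
]


class ConfigError(ValueError):
    """Invalid generation configuration."""


class PlacementError(RuntimeError):
    """Could not place a follicle within the attempt budget."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeDist:
    """Truncated-normal diameter distribution (micrometres).

    ``sd == 0`` degenerates to the constant ``mean``.  Bounds default to
    mean +/- 3 sd, floored at a small positive value so diameters stay > 0.
    """

    mean: float
    sd: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def bounds(self) -> tuple[float, float]:
        lo = self.lower if self.lower is not None else self.mean - 3.0 * self.sd
        hi = self.upper if self.upper is not None else self.mean + 3.0 * self.sd
        return (max(lo, 1e-6), max(hi, 1e-6))

    def validate(self, name: str = "size") -> None:
        if not (self.mean > 0):
            raise ConfigError(f"{name}: mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ConfigError(f"{name}: sd must be >= 0, got {self.sd}")
        lo, hi = self.bounds()
        if lo > hi:
            raise ConfigError(f"{name}: lower bound {lo} exceeds upper bound {hi}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(n, float(self.mean))
        lo, hi = self.bounds()
        a, b = (lo - self.mean) / self.sd, (hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class StageConfig:
    """Requested population and size distributions for one follicle stage."""

    count: int = 0
    follicle: SizeDist = SizeDist(35.0)
    oocyte: SizeDist = SizeDist(30.0)
    nucleus: SizeDist = SizeDist(18.0)
    nucleolus: SizeDist = SizeDist(3.0)

    def validate(self, stage: str) -> None:
        if self.count < 0:
            raise ConfigError(f"{stage}: count must be >= 0, got {self.count}")
        for name in ("follicle", "oocyte", "nucleus", "nucleolus"):
            getattr(self, name).validate(f"{stage}.{name}")


def _default_stages() -> dict[str, StageConfig]:
    """Literature-informed simulator defaults (not study-measured values).

    Means: primordial follicle 35 um (oocyte 30, nucleus 18, nucleolus 3);
    primary 60 um; secondary 150 um; antral 1000 um.  Dispersions are mild
    truncated normals.  Default population sizes sketch a mid-perimenopausal
    ovary at a scale that sections in well under a second; every value is a
    simulator parameter and overridable.
    """
    return {
        "primordial": StageConfig(1000, SizeDist(35, 3), SizeDist(30, 2.5),
                                  SizeDist(18, 1.5), SizeDist(3, 0.3)),
        "primary": StageConfig(100, SizeDist(60, 6), SizeDist(40, 3),
                               SizeDist(20, 1.5), SizeDist(3.5, 0.3)),
        "secondary": StageConfig(20, SizeDist(150, 15), SizeDist(60, 5),
                                 SizeDist(25, 2), SizeDist(4, 0.4)),
        "antral": StageConfig(3, SizeDist(1000, 100), SizeDist(100, 8),
                              SizeDist(30, 2.5), SizeDist(5, 0.5)),
    }


@dataclass
class OvaryConfig:
    """Generation configuration for one synthetic ovary.

    ``semi_axes`` is (ax, ay, az) in micrometres with the z semi-axis the
    longest: sectioning proceeds perpendicular to the long axis, so z is
    the sectioning axis and the long-axis extent is ``2*az``.  The default
    30 mm long axis cuts into exactly 30 slabs of 1 mm, each of which
    yields exactly 200 sections of 5 um (four full 50-section groups), so
    the default geometry has no partial slabs or groups.
    """

    semi_axes: tuple[float, float, float] = (7500.0, 10000.0, 15000.0)
    cortex_thickness: float = 1500.0
    f1: float = 1.0
    stages: dict[str, StageConfig] = field(default_factory=_default_stages)
    whole_ovary: bool = False
    overlap_allowed: bool = True
    max_attempts: int = 1000

    def validate(self) -> None:
        s = np.asarray(self.semi_axes, dtype=float)
        if s.shape != (3,) or not np.all(s > 0):
            raise ConfigError(f"semi_axes must be 3 positive lengths, got {self.semi_axes}")
        if s[2] < max(s[0], s[1]):
            raise ConfigError("the z semi-axis must be the longest (sectioning axis)")
        if not (0 < self.f1 <= 1):
            raise ConfigError(f"f1 must be in (0, 1], got {self.f1}")
        if self.cortex_thickness <= 0 or self.cortex_thickness > s.min():
            raise ConfigError("cortex_thickness must be in (0, min semi-axis]")
        for stage, sc in self.stages.items():
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
            sc.validate(stage)
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollicleSpec:
    """One follicle: nested spheres plus the nucleolus offset (um).

    ``center`` uses the ovary frame: x, y about the ovary midline, z from
    the lower pole (z in [0, 2*az]).  ``nucleolus_offset`` is the nucleolus
    center relative to the oocyte center.
    """

    id: int
    stage: str
    center: tuple[float, float, float]
    follicle_diameter: float
    oocyte_diameter: float
    nucleus_diameter: float
    nucleolus_diameter: float
    nucleolus_offset: tuple[float, float, float]


@dataclass
class OvaryModel:
    """Ground-truth ovary: geometry, follicle table and available fraction f1."""

    semi_axes: tuple[float, float, float]
    cortex_thickness: float
    follicles: pd.DataFrame
    available_fraction_f1: float = 1.0
    seed: int | None = None

    @property
    def extent(self) -> float:
        """Length of the long (sectioning) axis, um."""
        return 2.0 * float(self.semi_axes[2])

    def count_by_stage(self) -> dict[str, int]:
        vc = self.follicles["stage"].value_counts()
        return {s: int(vc.get(s, 0)) for s in STAGES}

    def follicle_specs(self) -> list[FollicleSpec]:
        out = []
        for row in self.follicles.itertuples(index=False):
            out.append(FollicleSpec(
                id=int(row.id), stage=str(row.stage),
                center=(row.cx, row.cy, row.cz),
                follicle_diameter=row.d_follicle, oocyte_diameter=row.d_oocyte,
                nucleus_diameter=row.d_nucleus, nucleolus_diameter=row.d_nucleolus,
                nucleolus_offset=(row.off_x, row.off_y, row.off_z)))
        return out


def follicles_from_specs(specs: list[FollicleSpec]) -> pd.DataFrame:
    """Build a follicle table from hand-written specs (test/validation aid)."""
    rows = [
        (f.id, f.stage, *f.center, f.follicle_diameter, f.oocyte_diameter,
         f.nucleus_diameter, f.nucleolus_diameter, *f.nucleolus_offset)
        for f in specs
    ]
    return pd.DataFrame(rows, columns=FOLLICLE_COLUMNS)


# ---------------------------------------------------------------------------
# ellipsoid geometry
# ---------------------------------------------------------------------------

def _scaled_sq(p: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    """sum((p_i/s_i)^2) for centered coordinates p, vectorized over rows."""
    return np.sum((p / semi_axes) ** 2, axis=-1)


def ellipsoid_max_scaled(points: np.ndarray, radii, semi_axes) -> np.ndarray:
    """Exact max of g(x)=sum((x_i/s_i)^2) over balls |x - p| <= r.

    ``g <= 1`` on the whole ball iff the returned value is <= 1, i.e. the
    sphere lies inside the ellipsoid.  This is the trust-region maximization
    of a convex quadratic over a ball, solved per point by bisection on the
    Lagrange multiplier; the "hard case" (center on the plane orthogonal to
    the shortest axis) is handled explicitly.  Coordinates are ellipsoid-
    centered.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    n = p.shape[0]
    r = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).astype(float)
    s = np.asarray(semi_axes, dtype=float)
    A = 1.0 / s ** 2                       # (3,)
    Amax = A.max()
    is_max = np.isclose(A, Amax, rtol=1e-12)
    q = A * p                              # (n, 3)

    val = np.empty(n)
    zero_r = r <= 0
    if np.any(zero_r):
        val[zero_r] = _scaled_sq(p[zero_r], s)
    idx = np.where(~zero_r)[0]
    if idx.size == 0:
        return val if points.ndim > 1 else val[0]

    pi, qi, ri = p[idx], q[idx], r[idx]
    # phi at mu -> Amax+ using only non-max axes; infinite if q has any
    # component along a max-A (shortest) axis.
    denom0 = Amax - A[~is_max]
    phi0 = np.sum(qi[:, ~is_max] ** 2 / denom0 ** 2, axis=1) if denom0.size else np.zeros(len(idx))
    qmax_sq = np.sum(qi[:, is_max] ** 2, axis=1)
    hard = (qmax_sq <= (1e-14 * Amax) ** 2) & (phi0 < ri ** 2)

    # --- regular case: bisect phi(mu) = r^2 on (Amax, Amax + |q|/r] --------
    reg = ~hard
    if np.any(reg):
        qr, rr, pr = qi[reg], ri[reg], pi[reg]
        B = np.sqrt(np.sum(qr ** 2, axis=1))
        lo = np.full(len(rr), Amax * (1 + 1e-15))
        hi = Amax + B / rr + 1e-30
        for _ in range(120):
            mid = 0.5 * (lo + hi)
            phi = np.sum(qr ** 2 / (mid[:, None] - A) ** 2, axis=1)
            take_hi = phi > rr ** 2
            lo = np.where(take_hi, mid, lo)
            hi = np.where(take_hi, hi, mid)
        mu = 0.5 * (lo + hi)
        d = qr / (mu[:, None] - A)
        val[idx[reg]] = _scaled_sq(pr + d, s)

    # --- hard case: mu = Amax, spare norm goes along a shortest axis -------
    if np.any(hard):
        qh, rh, ph = qi[hard], ri[hard], pi[hard]
        d = np.zeros_like(ph)
        d[:, ~is_max] = qh[:, ~is_max] / (Amax - A[~is_max])
        rem = np.sqrt(np.maximum(rh ** 2 - np.sum(d ** 2, axis=1), 0.0))
        pmax = np.sqrt(np.sum(ph[:, is_max] ** 2, axis=1))
        base = np.sum(A[~is_max] * (ph[:, ~is_max] + d[:, ~is_max]) ** 2, axis=1)
        val[idx[hard]] = base + Amax * (pmax + rem) ** 2

    return val if np.asarray(points).ndim > 1 else val[0]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_sizes(sc: StageConfig, n: int, rng: np.random.Generator,
                stage: str, max_rounds: int = 1000) -> np.ndarray:
    """Draw (n, 4) diameters obeying nucleolus <= nucleus <= oocyte <= follicle."""
    d = np.column_stack([sc.follicle.draw(n, rng), sc.oocyte.draw(n, rng),
                         sc.nucleus.draw(n, rng), sc.nucleolus.draw(n, rng)])
    for _ in range(max_rounds):
        bad = ~((d[:, 3] <= d[:, 2]) & (d[:, 2] <= d[:, 1]) & (d[:, 1] <= d[:, 0]))
        if not bad.any():
            return d
        m = int(bad.sum())
        d[bad] = np.column_stack([sc.follicle.draw(m, rng), sc.oocyte.draw(m, rng),
                                  sc.nucleus.draw(m, rng), sc.nucleolus.draw(m, rng)])
    raise ConfigError(
        f"{stage}: could not draw nested diameters after {max_rounds} rounds; "
        "size distributions overlap too strongly")


def _uniform_in_ball(n: int, radii: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
    u = rng.uniform(size=n) ** (1.0 / 3.0)
    return v * (radii * u)[:, None]


def _accept_centers(centered: np.ndarray, radii: np.ndarray,
                    cfg: OvaryConfig) -> np.ndarray:
    """Placement predicate: center in the cortical shell (unless whole-ovary
    placement) and the follicle sphere entirely inside the ovary."""
    s = np.asarray(cfg.semi_axes, dtype=float)
    # sqrt(g) is (1/s_min)-Lipschitz, giving a cheap sufficient certificate;
    # only the thin borderline band needs the exact trust-region solve.
    sg = np.sqrt(_scaled_sq(centered, s))
    ok = sg <= 1.0 - radii / s.min()
    border = ~ok & (sg <= 1.0)
    if np.any(border):
        ok[border] = ellipsoid_max_scaled(centered[border], radii[border], s) <= 1.0
    if not cfg.whole_ovary:
        inner = s - cfg.cortex_thickness
        if np.all(inner > 0):
            ok &= _scaled_sq(centered, inner) >= 1.0
    return ok


def _place_stage(n: int, radii: np.ndarray, cfg: OvaryConfig,
                 rng: np.random.Generator, stage: str,
                 placed_centers: list[np.ndarray],
                 placed_radii: list[np.ndarray]) -> np.ndarray:
    """Rejection-sample n centers (ellipsoid-centered frame).

    ``placed_centers``/``placed_radii`` accumulate accepted follicles across
    stages when non-overlap mode is on; they are mutated in place.
    """
    centers = np.empty((n, 3))
    remaining = np.arange(n)
    attempts = np.zeros(n, dtype=int)
    s = np.asarray(cfg.semi_axes, dtype=float)
    while remaining.size:
        m = remaining.size
        cand = rng.uniform(-s, s, size=(m, 3))
        ok = _accept_centers(cand, radii[remaining], cfg)
        if not cfg.overlap_allowed:
            ok &= _no_overlap(cand, radii[remaining], ok,
                              placed_centers, placed_radii)
        newly = remaining[ok]
        centers[newly] = cand[ok]
        if not cfg.overlap_allowed and newly.size:
            placed_centers.append(cand[ok])
            placed_radii.append(radii[newly])
        attempts[remaining] += 1
        remaining = remaining[~ok]
        if remaining.size and attempts[remaining].max() >= cfg.max_attempts:
            raise PlacementError(
                f"failed to place a {stage} follicle within "
                f"max_attempts={cfg.max_attempts} attempts")
    return centers


def _no_overlap(cand: np.ndarray, cand_r: np.ndarray, geom_ok: np.ndarray,
                placed_centers: list[np.ndarray],
                placed_radii: list[np.ndarray]) -> np.ndarray:
    """Greedy sequential overlap filter: a candidate passes if it clears all
    previously placed follicles and all earlier accepted candidates in this
    batch (so the batch itself stays overlap-free)."""
    ok = np.zeros(len(cand), dtype=bool)
    allc = np.vstack(placed_centers) if placed_centers else np.empty((0, 3))
    allr = np.concatenate(placed_radii) if placed_radii else np.empty(0)
    acc_c: list[np.ndarray] = []
    acc_r: list[float] = []
    for i in range(len(cand)):
        if not geom_ok[i]:
            continue
        if allc.shape[0]:
            if np.any(np.linalg.norm(allc - cand[i], axis=1) < allr + cand_r[i]):
                continue
        if acc_c and np.any(np.linalg.norm(np.vstack(acc_c) - cand[i], axis=1)
                            < np.asarray(acc_r) + cand_r[i]):
            continue
        ok[i] = True
        acc_c.append(cand[i][None, :])
        acc_r.append(cand_r[i])
    return ok


def generate_ovary(params: OvaryConfig, seed: int) -> OvaryModel:
    """Generate a ground-truth ovary; deterministic given ``seed``.

    Per stage (in STAGES order): draw the four diameters, the nucleolus
    offset (uniform in the ball of radius (d_nucleus - d_nucleolus)/2), then
    rejection-sample centers uniformly in the placement region.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 0
    placed_centers: list[np.ndarray] = []
    placed_radii: list[np.ndarray] = []
    for stage in STAGES:
        sc = params.stages.get(stage)
        if sc is None or sc.count == 0:
            continue
        n = sc.count
        d = _draw_sizes(sc, n, rng, stage)
        off = _uniform_in_ball(n, (d[:, 2] - d[:, 3]) / 2.0, rng)
        centered = _place_stage(n, d[:, 0] / 2.0, params, rng, stage,
                                placed_centers if not params.overlap_allowed else [],
                                placed_radii if not params.overlap_allowed else [])
        az = params.semi_axes[2]
        df = pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "stage": stage,
            "cx": centered[:, 0], "cy": centered[:, 1], "cz": centered[:, 2] + az,
            "d_follicle": d[:, 0], "d_oocyte": d[:, 1],
            "d_nucleus": d[:, 2], "d_nucleolus": d[:, 3],
            "off_x": off[:, 0], "off_y": off[:, 1], "off_z": off[:, 2],
        })
        frames.append(df)
        next_id += n
    follicles = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=FOLLICLE_COLUMNS))
    return OvaryModel(semi_axes=tuple(float(x) for x in params.semi_axes),
                      cortex_thickness=float(params.cortex_thickness),
                      follicles=follicles,
                      available_fraction_f1=float(params.f1), seed=seed)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-invariant pass/fail with offending follicle ids."""

    checks: dict[str, tuple[bool, list[int]]]

    @property
    def ok(self) -> bool:
        return all(passed for passed, _ in self.checks.values())


def validate_ovary(model: OvaryModel, rtol: float = 1e-9) -> ValidationReport:
    """Check every structural invariant of an :class:`OvaryModel`.

    Reporting only -- never raises.  Checks: f1 range; positive, nested
    diameters; nucleolus strictly inside the nucleus; follicle sphere inside
    the ovary ellipsoid.
    """
    f = model.follicles
    checks: dict[str, tuple[bool, list[int]]] = {}

    ok_f1 = 0 < model.available_fraction_f1 <= 1
    checks["f1_in_range"] = (ok_f1, [])

    if len(f) == 0:
        for name in ("diameters_positive_nested", "nucleolus_inside_nucleus",
                     "follicle_inside_ovary"):
            checks[name] = (True, [])
        return ValidationReport(checks)

    ids = f["id"].to_numpy()
    d = f[["d_follicle", "d_oocyte", "d_nucleus", "d_nucleolus"]].to_numpy(float)
    nested = (d > 0).all(axis=1) & (d[:, 3] <= d[:, 2]) & (d[:, 2] <= d[:, 1]) \
        & (d[:, 1] <= d[:, 0])
    checks["diameters_positive_nested"] = (bool(nested.all()),
                                           [int(i) for i in ids[~nested]])

    off = np.linalg.norm(f[["off_x", "off_y", "off_z"]].to_numpy(float), axis=1)
    inside_nuc = off + d[:, 3] / 2.0 <= d[:, 2] / 2.0 * (1 + rtol)
    checks["nucleolus_inside_nucleus"] = (bool(inside_nuc.all()),
                                          [int(i) for i in ids[~inside_nuc]])

    az = model.semi_axes[2]
    centered = f[["cx", "cy", "cz"]].to_numpy(float) - np.array([0.0, 0.0, az])
    gmax = ellipsoid_max_scaled(centered, d[:, 0] / 2.0, model.semi_axes)
    inside = gmax <= 1 + rtol
    checks["follicle_inside_ovary"] = (bool(inside.all()),
                                       [int(i) for i in ids[~inside]])
    return ValidationReport(checks)


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_follicles(model: OvaryModel, path) -> None:
    """Serialize the follicle table as CSV (header mandatory, um units)."""
    model.follicles.to_csv(path, index=False)


def read_follicles(path, *, semi_axes=(7500.0, 10000.0, 15000.0),
                   cortex_thickness: float = 1500.0, f1: float = 1.0,
                   seed: int | None = None) -> OvaryModel:
    """Load a follicle table; geometry metadata is supplied by the caller
    (typically from the same config that generated the table)."""
    df = pd.read_csv(path)
    missing = [c for c in FOLLICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"follicle table missing columns: {missing}")
    return OvaryModel(semi_axes=tuple(float(x) for x in semi_axes),
                      cortex_thickness=float(cortex_thickness),
                      follicles=df[FOLLICLE_COLUMNS],
                      available_fraction_f1=float(f1), seed=seed)


def config_fingerprint(*objs) -> str:
    """Short stable hash of dataclass configs (for MC provenance)."""
    import hashlib
    import json

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps([enc(o) for o in objs], sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
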