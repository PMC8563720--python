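"""Synthetic nucleus phantoms and the TCSPC forward model.

Stands in for unavailable raw FLIM acquisitions: generates nuclei with
S-phase-specific replication-labeling geometry (many scattered foci in early
S; fewer, clustered, rim-hugging foci in mid/late S), assigns each labeled
pixel a ground-truth refractive index and decay, and renders the result into
a Poisson-sampled photon-count cube.

Ground-truth lifetimes are derived from the refractive-index map through the
inverse-quadratic lifetime-RI relation, so the per-stage RI defaults are the
values that place the stage mean lifetimes at the configured references
(late > mid > early in RI, hence early > mid > late in lifetime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
from scipy import ndimage

from .io import TcspcCube, config_digest, write_float_map
from .models import (
    AcquisitionConfig,
    BiDecayParams,
    Irf,
    MonoDecayParams,
    strickler_berg_lifetime,
)

__all__ = [
    "LABEL_OUTSIDE",
    "LABEL_NUCLEOPLASM",
    "LABEL_NUCLEOLUS",
    "LABEL_FOCUS",
    "STAGES",
    "PhantomConfig",
    "NucleusPhantom",
    "PhantomError",
    "generate_phantom",
    "generate_fret_phantom",
    "simulate_cube",
    "export_phantom",
]

LABEL_OUTSIDE = 0
LABEL_NUCLEOPLASM = 1
LABEL_NUCLEOLUS = 2
LABEL_FOCUS = 3

STAGES = ("early", "mid", "late")


class PhantomError(RuntimeError):
    """Raised when a phantom cannot be generated from the given config."""


def _default_n_foci() -> dict[str, int]:
    return {"early": 300, "mid": 60, "late": 40}


def _default_focus_radius() -> dict[str, tuple[float, float]]:
    return {"early": (1.0, 2.0), "mid": (2.0, 4.0), "late": (2.5, 4.5)}


def _default_stage_lifetimes() -> dict[str, float]:
    # per-stage mean lifetime references (ns), early > mid > late
    return {"early": 2.46, "mid": 2.37, "late": 2.23}


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic nucleus generator.

    ``stage_lifetimes_ns`` are the target ground-truth mean lifetimes per
    S-phase stage; the per-stage refractive index is derived from them via the
    inverse-quadratic relation anchored at (``tau_ref``, ``n_ref``) unless
    ``ri_by_class`` overrides it.  ``cycles_per_pixel`` is the number of
    excitation cycles a pixel is exposed to and feeds the pile-up check.
    """

    image_size: tuple[int, int] = (256, 256)
    n_foci: dict[str, int] = field(default_factory=_default_n_foci)
    focus_radius_px: dict[str, tuple[float, float]] = field(
        default_factory=_default_focus_radius
    )
    peripheral_fraction: float = 0.7
    rim_width_px: float = 5.0
    n_clusters: int = 6
    cluster_sigma_px: float = 6.0
    stage_lifetimes_ns: dict[str, float] = field(
        default_factory=_default_stage_lifetimes
    )
    ri_by_class: Optional[dict[str, float]] = None
    n_ref: float = 1.38
    tau_ref: float = 2.47
    ri_jitter: float = 0.002
    ri_outside: float = 1.33
    ri_nucleoplasm: float = 1.37
    ri_nucleolus: float = 1.39
    photons_per_pixel: float = 2000.0
    background_rate: float = 0.0
    fret_fraction: float = 0.5
    fret_efficiency: float = 1.0 - 2.01 / 2.47
    cycles_per_pixel: float = 200_000.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if not (0.0 <= self.peripheral_fraction <= 1.0):
            raise ValueError("peripheral_fraction must be in [0, 1]")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if not (0.0 <= self.fret_fraction <= 1.0):
            raise ValueError("fret_fraction must be in [0, 1]")
        if not (0.0 <= self.fret_efficiency < 1.0):
            raise ValueError("fret_efficiency must be in [0, 1)")

    def stage_ri(self, stage: str) -> float:
        """Refractive index whose derived lifetime hits the stage reference."""
        if self.ri_by_class is not None:
            return self.ri_by_class[stage]
        tau = self.stage_lifetimes_ns[stage]
        return self.n_ref * float(np.sqrt(self.tau_ref / tau))


@dataclass
class NucleusPhantom:
    """Synthetic nucleus with per-pixel ground truth.

    ``tau_map`` holds the (slow / donor) lifetime on labeled-focus pixels and
    NaN elsewhere.  For FRET phantoms ``a1_frac_map`` > 0 marks pixels whose
    decay is a two-component mixture with fast lifetime ``tau_fret_map``;
    ``efficiency_map`` stores the ground-truth FRET efficiency (0 on pure
    donor foci pixels).
    """

    labels: np.ndarray
    ri_map: np.ndarray
    tau_map: np.ndarray
    a1_frac_map: np.ndarray
    tau_fret_map: np.ndarray
    efficiency_map: np.ndarray
    amp_map: np.ndarray
    focus_id_map: np.ndarray
    foci: list[dict[str, Any]]
    stage: str
    seed: int
    config: PhantomConfig
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def focus_mask(self) -> np.ndarray:
        return self.labels == LABEL_FOCUS

    @property
    def nucleus_mask(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE

    @property
    def is_fret(self) -> bool:
        return bool(np.any(self.a1_frac_map > 0))

    def truth_params(self, row: int, col: int):
        """Ground-truth decay parameters of one pixel."""
        if self.labels[row, col] != LABEL_FOCUS:
            raise ValueError(f"pixel ({row}, {col}) is not a labeled focus")
        amp = float(self.amp_map[row, col])
        f = float(self.a1_frac_map[row, col])
        tau0 = float(self.tau_map[row, col])
        if f > 0:
            return BiDecayParams(
                a1=f * amp,
                a2=(1 - f) * amp,
                tau_fret=float(self.tau_fret_map[row, col]),
                tau0=tau0,
            )
        return MonoDecayParams(amplitude=amp, tau=tau0)

    def truth_mean_tau(self) -> float:
        """Mean ground-truth (slow) lifetime over labeled foci pixels."""
        return float(np.nanmean(self.tau_map[self.focus_mask]))


def _nucleus_geometry(
    shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Label image with an irregular elliptical nucleus and 2-3 nucleoli."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    a = 0.40 * w * rng.uniform(0.92, 1.0)
    b = 0.31 * h * rng.uniform(0.92, 1.0)
    angle = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # low-frequency radial jitter of the boundary
    theta = np.arctan2(v, u)
    jitter = np.ones_like(theta)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.015)
        phase = rng.uniform(0, 2 * np.pi)
        jitter += amp * np.cos(k * theta + phase)
    labels = np.where(rho < jitter, LABEL_NUCLEOPLASM, LABEL_OUTSIDE).astype(np.uint8)

    n_nucleoli = int(rng.integers(2, 4))
    for _ in range(n_nucleoli):
        for _try in range(40):
            ny = cy + rng.uniform(-0.45, 0.45) * b
            nx = cx + rng.uniform(-0.45, 0.45) * a
            ra = rng.uniform(0.05, 0.09) * min(h, w)
            rb = ra * rng.uniform(0.7, 1.0)
            ell = ((yy - ny) / ra) ** 2 + ((xx - nx) / rb) ** 2 < 1.0
            if np.all(labels[ell] != LABEL_OUTSIDE) and ell.any():
                labels[ell] = LABEL_NUCLEOLUS
                break
    return labels


def _rim_band(labels: np.ndarray, width: float) -> np.ndarray:
    """Nucleoplasm pixels within ``width`` px of the nuclear or nucleolar edge."""
    nucleoplasm = labels == LABEL_NUCLEOPLASM
    inside = labels != LABEL_OUTSIDE
    d_outer = ndimage.distance_transform_edt(inside)
    not_nucleolus = labels != LABEL_NUCLEOLUS
    d_nucleolus = ndimage.distance_transform_edt(not_nucleolus)
    band = (d_outer <= width) | (d_nucleolus <= width)
    return band & nucleoplasm


def _place_foci(
    labels: np.ndarray,
    stage: str,
    cfg: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Choose focus centers/radii per stage and stamp them into an id map."""
    h, w = labels.shape
    nucleoplasm = labels == LABEL_NUCLEOPLASM
    n = cfg.n_foci[stage]
    r_lo, r_hi = cfg.focus_radius_px[stage]
    area_needed = n * np.pi * r_hi**2
    if area_needed > 0.8 * nucleoplasm.sum():
        raise PhantomError(
            f"{n} foci of radius <= {r_hi} px need ~{area_needed:.0f} px^2 "
            f"but the nucleoplasm has only {nucleoplasm.sum()} px"
        )

    cand = np.argwhere(nucleoplasm)
    if cand.size == 0:
        raise PhantomError("empty nucleoplasm; cannot place foci")

    centers: list[tuple[float, float]] = []
    if stage == "early":
        picks = cand[rng.choice(len(cand), size=n, replace=False)]
        centers = [tuple(p) for p in picks]
    else:
        rim = _rim_band(labels, cfg.rim_width_px)
        rim_cand = np.argwhere(rim)
        if len(rim_cand) == 0:
            raise PhantomError("rim band is empty; cannot place peripheral foci")
        n_rim = int(round(cfg.peripheral_fraction * n))
        picks = rim_cand[rng.choice(len(rim_cand), size=n_rim, replace=n_rim > len(rim_cand))]
        centers.extend(tuple(p) for p in picks)
        # remaining foci form a few interior clusters
        n_int = n - n_rim
        if n_int > 0:
            seeds = cand[rng.choice(len(cand), size=cfg.n_clusters, replace=False)]
            for _ in range(n_int):
                sy, sx = seeds[rng.integers(cfg.n_clusters)]
                for _try in range(50):
                    y = sy + rng.normal(0, cfg.cluster_sigma_px)
                    x = sx + rng.normal(0, cfg.cluster_sigma_px)
                    iy, ix = int(round(y)), int(round(x))
                    if 0 <= iy < h and 0 <= ix < w and nucleoplasm[iy, ix]:
                        centers.append((iy, ix))
                        break
                else:
                    centers.append((int(sy), int(sx)))

    yy, xx = np.mgrid[0:h, 0:w]
    focus_id = np.full((h, w), -1, dtype=np.int32)
    foci = []
    inside_nucleus = labels != LABEL_OUTSIDE
    for i, (cy, cx) in enumerate(centers):
        r = rng.uniform(r_lo, r_hi)
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) & inside_nucleus
        focus_id[disk] = i
        foci.append({"id": i, "center": (float(cy), float(cx)), "radius": float(r)})
    return focus_id, foci


def generate_phantom(
    stage: str,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    *,
    ri_override: float | None = None,
) -> NucleusPhantom:
    """Build a donor-only (mono-exponential truth) nucleus phantom.

    ``ri_override`` pins the foci refractive index to a fixed value instead of
    the stage default; FRET phantoms use this to anchor the donor reference
    lifetime at the configured photophysics rather than a stage mean.
    Identical (stage, cfg, seed) always yields a bit-identical phantom.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    cfg = cfg or PhantomConfig()
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_foci, rng_ri = (np.random.default_rng(s) for s in ss.spawn(3))

    labels = _nucleus_geometry(cfg.image_size, rng_geom)
    focus_id, foci = _place_foci(labels, stage, cfg, rng_foci)
    focus_mask = focus_id >= 0
    labels = labels.copy()
    labels[focus_mask] = LABEL_FOCUS

    ri = np.full(cfg.image_size, cfg.ri_outside, dtype=float)
    ri[labels == LABEL_NUCLEOPLASM] = cfg.ri_nucleoplasm
    ri[labels == LABEL_NUCLEOLUS] = cfg.ri_nucleolus
    ri_focus = ri_override if ri_override is not None else cfg.stage_ri(stage)
    jitter = rng_ri.normal(0.0, cfg.ri_jitter, size=int(focus_mask.sum()))
    ri[focus_mask] = ri_focus + jitter
    np.maximum(ri, 1.0, out=ri)

    tau = np.full(cfg.image_size, np.nan)
    tau[focus_mask] = strickler_berg_lifetime(
        ri[focus_mask], tau_ref=cfg.tau_ref, n_ref=cfg.n_ref
    )
    amp = np.zeros(cfg.image_size)
    amp[focus_mask] = cfg.photons_per_pixel

    return NucleusPhantom(
        labels=labels,
        ri_map=ri,
        tau_map=tau,
        a1_frac_map=np.zeros(cfg.image_size),
        tau_fret_map=np.full(cfg.image_size, np.nan),
        efficiency_map=np.where(focus_mask, 0.0, np.nan),
        amp_map=amp,
        focus_id_map=focus_id,
        foci=foci,
        stage=stage,
        seed=seed,
        config=cfg,
        meta={"ri_focus": float(ri_focus)},
    )


def generate_fret_phantom(
    stage_donor: str,
    stage_acceptor: str,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    *,
    mode: str = "simultaneous",
    proximity_fraction: float = 0.3,
) -> NucleusPhantom:
    """Donor phantom with two-component (FRET) truth on acceptor-proximal foci.

    ``simultaneous`` labeling puts every donor focus in acceptor proximity;
    ``sequential`` labeling marks each focus proximal independently with
    probability ``proximity_fraction``.  Foci pixels use the donor reference
    refractive index (``cfg.n_ref``), so the slow component sits at
    ``cfg.tau_ref``; proximal pixels get an amplitude fraction
    ``cfg.fret_fraction`` of a fast component at efficiency
    ``cfg.fret_efficiency``.
    """
    if mode not in ("simultaneous", "sequential"):
        raise ValueError(f"mode must be simultaneous|sequential, got {mode!r}")
    if stage_acceptor not in STAGES:
        raise ValueError(f"stage_acceptor must be one of {STAGES}")
    cfg = cfg or PhantomConfig()
    ph = generate_phantom(stage_donor, cfg, seed, ri_override=cfg.n_ref)

    rng = np.random.default_rng([seed, 0xF4E7])
    n_foci = len(ph.foci)
    if mode == "simultaneous":
        proximal = np.ones(n_foci, dtype=bool)
    else:
        proximal = rng.random(n_foci) < proximity_fraction
    for f, prox in zip(ph.foci, proximal):
        f["acceptor_proximal"] = bool(prox)

    if cfg.fret_fraction > 0 and proximal.any():
        prox_px = ph.focus_mask & np.isin(ph.focus_id_map, np.flatnonzero(proximal))
        ph.a1_frac_map[prox_px] = cfg.fret_fraction
        ph.tau_fret_map[prox_px] = ph.tau_map[prox_px] * (1.0 - cfg.fret_efficiency)
        ph.efficiency_map[prox_px] = cfg.fret_efficiency
    ph.meta.update(
        {
            "mode": mode,
            "stage_acceptor": stage_acceptor,
            "proximity_fraction": proximity_fraction,
        }
    )
    return ph


def _unit_shapes(
    taus: np.ndarray, irf: Irf, acq: AcquisitionConfig
) -> np.ndarray:
    """Normalized expected decay shapes, one row per lifetime."""
    m = acq.n_period_bins
    w = acq.bin_width
    k = np.arange(m)[None, :]
    e = np.exp(-w / np.asarray(taus, dtype=float))[:, None]
    d = (1.0 - e) * e**k
    d /= d.sum(axis=1, keepdims=True)
    h = np.zeros(m)
    h[: irf.weights.size] = irf.weights
    s = np.fft.irfft(np.fft.rfft(d, axis=1) * np.fft.rfft(h)[None, :], m, axis=1)
    s = s[:, : acq.n_bins]
    np.maximum(s, 0.0, out=s)
    s /= s.sum(axis=1, keepdims=True)
    return s


def simulate_cube(
    phantom: NucleusPhantom,
    irf: Irf,
    acq: AcquisitionConfig,
    seed: int = 0,
    *,
    photons_per_pixel: float | None = None,
) -> TcspcCube:
    """Render a phantom into a Poisson-sampled TCSPC photon cube.

    Each labeled pixel's expected decay is its ground-truth mixture of
    IRF-convolved shapes scaled to the photon budget; background counts are
    added uniformly over bins inside the nucleus.  The pile-up check compares
    the brightest pixel's photons-per-excitation-cycle against
    ``acq.pileup_budget`` and records (but does not correct) violations.
    """
    cfg = phantom.config
    h, w = phantom.labels.shape
    expected = np.zeros((acq.n_bins, h, w), dtype=np.float32)

    focus = phantom.focus_mask
    idx = np.argwhere(focus)
    if len(idx):
        rows, cols = idx[:, 0], idx[:, 1]
        budget = photons_per_pixel if photons_per_pixel is not None else None
        amps = (
            np.full(len(rows), float(budget))
            if budget is not None
            else phantom.amp_map[rows, cols]
        )
        tau0 = phantom.tau_map[rows, cols]
        f = phantom.a1_frac_map[rows, cols]
        tauf = np.where(f > 0, phantom.tau_fret_map[rows, cols], tau0)
        # photon (intensity) fraction of the fast component
        q = np.where(f > 0, f * tauf / (f * tauf + (1 - f) * tau0), 0.0)
        s_slow = _unit_shapes(tau0, irf, acq)
        s_fast = _unit_shapes(tauf, irf, acq)
        mix = (q[:, None] * s_fast + (1 - q)[:, None] * s_slow) * amps[:, None]
        expected[:, rows, cols] = mix.T.astype(np.float32)

    if cfg.background_rate > 0:
        expected[:, phantom.nucleus_mask] += cfg.background_rate

    totals = expected.sum(axis=0, dtype=np.float64)
    peak_ratio = float(totals.max() / cfg.cycles_per_pixel)
    pileup_ok = peak_ratio <= acq.pileup_budget
    if not pileup_ok:
        warnings.warn(
            f"pile-up budget exceeded: peak count rate is {peak_ratio:.1%} of "
            f"the excitation rate (budget {acq.pileup_budget:.0%})",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected.astype(np.float64))
    dtype = np.uint16 if counts.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    provenance = {
        "generator": "flimfret.phantom.simulate_cube",
        "seed": int(seed),
        "phantom_seed": int(phantom.seed),
        "stage": phantom.stage,
        "config_digest": config_digest(cfg),
        "pileup_ratio": peak_ratio,
        "pileup_ok": pileup_ok,
    }
    return TcspcCube(counts=counts.astype(dtype), acq=acq, provenance=provenance)


def export_phantom(phantom: NucleusPhantom, outdir: str | Path) -> dict[str, Path]:
    """Write label mask, RI map and ground-truth maps as TIFFs + config JSON."""
    import json

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    labels_path = outdir / "labels.tif"
    tifffile.imwrite(labels_path, phantom.labels.astype(np.uint8))
    paths["labels"] = labels_path
    for name, arr in [
        ("ri", phantom.ri_map),
        ("truth_tau", phantom.tau_map),
        ("truth_a1_frac", phantom.a1_frac_map),
        ("truth_efficiency", phantom.efficiency_map),
    ]:
        paths[name] = write_float_map(arr, outdir / f"{name}.tif")
    cfg_path = outdir / "phantom_config.json"
    cfg_path.write_text(
        json.dumps(
            {
                "stage": phantom.stage,
                "seed": phantom.seed,
                "meta": phantom.meta,
                "config": {
                    k: getattr(phantom.config, k)
                    for k in phantom.config.__dataclass_fields__
                },
                "n_foci": len(phantom.foci),
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    paths["config"] = cfg_path
    return paths
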