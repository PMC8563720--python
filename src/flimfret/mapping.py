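"""Lifetime and FRET maps, segmentation, histograms and summary tables.

Segmentation uses half-open intervals ``[low, high)`` everywhere; values
below the first edge or at/above the last edge fall into explicit ``under`` /
``over`` overflow classes rather than being clipped.  The built-in schemes
are the three-band lifetime coloring (short 2.1-2.35 ns red, intermediate
2.35-2.55 ns green, long 2.55-2.75 ns blue) and the FRET-efficiency bands
(low < 50 %, intermediate 50-70 %, high >= 70 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import BiFitImage, LifetimeMap

__all__ = [
    "SegmentationScheme",
    "ClassMap",
    "FretMap",
    "LIFETIME_SCHEME",
    "FRET_SCHEME",
    "MASKED",
    "segment_map",
    "compute_fret_map",
    "histogram",
    "summarize_by_group",
    "render_class_map",
]

MASKED = -1  # class code for pixels outside the validity mask


@dataclass(frozen=True)
class SegmentationScheme:
    """Ordered class boundaries with names and display colors.

    ``boundaries`` has one more entry than ``labels``; class ``i`` covers
    ``[boundaries[i], boundaries[i+1])``.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    colors: tuple[str, ...]
    under_color: str = "dimgray"
    over_color: str = "white"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing, length >= 2")
        if len(self.labels) != len(b) - 1:
            raise ValueError("need exactly one label per interval")
        if len(self.colors) != len(self.labels):
            raise ValueError("need exactly one color per label")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    @property
    def under_code(self) -> int:
        return self.n_classes

    @property
    def over_code(self) -> int:
        return self.n_classes + 1

    def all_labels(self) -> list[str]:
        return list(self.labels) + ["under", "over"]


LIFETIME_SCHEME = SegmentationScheme(
    boundaries=(2.1, 2.35, 2.55, 2.75),
    labels=("short", "intermediate", "long"),
    colors=("red", "green", "blue"),
)

FRET_SCHEME = SegmentationScheme(
    boundaries=(0.0, 0.5, 0.7, 1.0),
    labels=("low", "intermediate", "high"),
    colors=("blue", "green", "red"),
)


@dataclass
class ClassMap:
    """Integer class codes per pixel plus the scheme that produced them."""

    codes: np.ndarray
    scheme: SegmentationScheme

    def class_counts(self) -> dict[str, int]:
        """Pixel count per class, including the overflow classes."""
        out = {}
        for code, label in enumerate(self.scheme.all_labels()):
            out[label] = int(np.count_nonzero(self.codes == code))
        return out

    @property
    def mask(self) -> np.ndarray:
        return self.codes != MASKED


@dataclass
class FretMap:
    """Per-pixel FRET efficiency with class labels; E defined iff mask."""

    efficiency_map: np.ndarray
    class_map: ClassMap
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(np.isfinite(self.efficiency_map), self.mask):
            raise ValueError("efficiency must be finite exactly on masked-in pixels")

    def mean_efficiency(self) -> float:
        return float(np.nanmean(self.efficiency_map[self.mask]))


def segment_map(
    values: np.ndarray,
    scheme: SegmentationScheme,
    mask: Optional[np.ndarray] = None,
) -> ClassMap:
    """Assign each unmasked pixel the class of its half-open interval.

    Out-of-range values go to the ``under`` / ``over`` overflow classes;
    masked or non-finite pixels get the ``MASKED`` code.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    codes = np.full(values.shape, MASKED, dtype=np.int16)
    b = np.asarray(scheme.boundaries)
    # np.digitize(right=False): value in [b[i-1], b[i]) -> i
    dig = np.digitize(values[mask], b, right=False)
    cls = np.where(
        dig == 0,
        scheme.under_code,
        np.where(dig == len(b), scheme.over_code, dig - 1),
    )
    codes[mask] = cls
    return ClassMap(codes=codes, scheme=scheme)


def compute_fret_map(
    bi_fits: BiFitImage,
    tau0_ref: Optional[float] = None,
    scheme: SegmentationScheme = FRET_SCHEME,
    min_fret_fraction: float = 0.05,
    lrt_threshold: float = 4.0,
) -> FretMap:
    """Per-pixel FRET efficiency ``E = 1 - tau_fret/tau0`` from bi-fit maps.

    ``tau0_ref`` overrides the per-pixel slow lifetime (donor-only control
    mode).  Pixels where the two-component model is not supported — fast
    amplitude fraction below ``min_fret_fraction``, or objective improvement
    over the single-exponential fit below ``lrt_threshold`` — carry no FRET
    signal and are reported as E = 0 (low class) via the donor-only path,
    instead of trusting an unidentifiable fast lifetime.  Collapsed
    two-component fits are masked out.
    """
    if tau0_ref is not None and tau0_ref <= 0:
        raise ValueError("tau0_ref must be positive")
    base = bi_fits.mask.copy()
    frac = bi_fits.a1_fraction_map()
    with np.errstate(invalid="ignore"):
        no_fret = base & (frac < min_fret_fraction)
        if bi_fits.delta_nll_map is not None:
            no_fret |= base & (bi_fits.delta_nll_map < lrt_threshold)
    valid = base & ~no_fret & ~bi_fits.collapsed

    tau0 = np.full(bi_fits.tau0_map.shape, tau0_ref) if tau0_ref else bi_fits.tau0_map
    with np.errstate(invalid="ignore", divide="ignore"):
        e = 1.0 - bi_fits.tau_fret_map / tau0
    eff = np.full(bi_fits.tau0_map.shape, np.nan)
    eff[valid] = np.clip(e[valid], 0.0, 1.0)
    eff[no_fret] = 0.0
    mask = valid | no_fret
    cmap = segment_map(eff, scheme, mask=mask)
    return FretMap(efficiency_map=eff, class_map=cmap, mask=mask)


def histogram(
    values: np.ndarray,
    bin_width: float,
    mask: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Histogram of a scalar map with edges aligned to multiples of bin_width.

    Returns a table of (bin_center, count); counts sum to the number of
    unmasked pixels.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    v = values[mask]
    if v.size == 0:
        raise ValueError("histogram needs at least one unmasked pixel")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = (np.floor(v.max() / bin_width) + 1) * bin_width
    n = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return pd.DataFrame({"bin_center": centers, "count": counts})


def summarize_by_group(
    lifetime_map: LifetimeMap,
    groups: np.ndarray,
    efficiency_map: Optional[np.ndarray] = None,
    weighting: str = "intensity",
    pairwise: bool = True,
) -> pd.DataFrame:
    """Per-group lifetime statistics, plus pairwise mean differences in ps.

    ``groups`` is a per-pixel label array covering the unmasked pixels.
    The mean is intensity-weighted (per-pixel photon totals) by default.
    Difference rows are labeled ``"A-B"`` and report ``(mean_A - mean_B)``
    in picoseconds in the ``diff_ps`` column.
    """
    if weighting not in ("intensity", "none"):
        raise ValueError("weighting must be 'intensity' or 'none'")
    groups = np.asarray(groups)
    mask = lifetime_map.mask
    rows = []
    means: dict[str, float] = {}
    uniq = [g for g in pd.unique(groups.ravel()) if g is not None and g == g]
    for g in uniq:
        sel = mask & (groups == g)
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"group {g!r} has no unmasked pixels; omitted", stacklevel=2)
            continue
        tau = lifetime_map.tau_map[sel]
        wts = (
            lifetime_map.intensity_map[sel].astype(float)
            if weighting == "intensity"
            else np.ones(n)
        )
        if wts.sum() <= 0:
            wts = np.ones(n)
        mean = float(np.average(tau, weights=wts))
        sd = float(np.sqrt(np.average((tau - mean) ** 2, weights=wts)))
        mean_e = (
            float(np.nanmean(efficiency_map[sel]))
            if efficiency_map is not None
            else np.nan
        )
        means[str(g)] = mean
        rows.append(
            {
                "group": str(g),
                "n_pixels": n,
                "mean_tau_ns": mean,
                "sd_tau_ns": sd,
                "mean_E": mean_e,
                "diff_ps": np.nan,
            }
        )
    if pairwise and len(rows) > 1:
        names = [r["group"] for r in rows]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rows.append(
                    {
                        "group": f"{a}-{b}",
                        "n_pixels": rows[i]["n_pixels"],
                        "mean_tau_ns": np.nan,
                        "sd_tau_ns": np.nan,
                        "mean_E": np.nan,
                        "diff_ps": (means[a] - means[b]) * 1000.0,
                    }
                )
    return pd.DataFrame(rows)


def render_class_map(
    class_map: ClassMap,
    scheme: Optional[SegmentationScheme] = None,
) -> tuple[np.ndarray, dict[str, str]]:
    """Render class codes to an RGB uint8 image plus a label→color legend.

    Masked pixels are black; overflow classes use the scheme's under/over
    colors.
    """
    from matplotlib.colors import to_rgb

    scheme = scheme or class_map.scheme
    palette = list(scheme.colors) + [scheme.under_color, scheme.over_color]
    rgb = np.zeros(class_map.codes.shape + (3,), dtype=np.uint8)
    legend = {"masked": "black"}
    for code, (label, color) in enumerate(zip(scheme.all_labels(), palette)):
        rgb[class_map.codes == code] = np.round(
            np.array(to_rgb(color)) * 255
        ).astype(np.uint8)
        legend[label] = color
    return rgb, legend
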