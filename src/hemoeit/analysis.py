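"""Hemorrhage quantification: ROI thresholding, the regional impedance
variation (RIV) statistic, group ANOVA across injected volumes, and the
RIV-versus-volume linear regression.

RIV is the area-weighted sum of the reconstructed impedance change over
the hemorrhage region of interest, normalized by the total imaging area:

    RIV = sum_{e in ROI} drho_e * area_e / sum_{all e} area_e.

The ROI contains every element whose hemorrhage-signed magnitude
(-drho, blood lowers impedance) exceeds a fraction (default 10%) of the
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mesh import Mesh
from .reconstruct import EitImage, ImageSeries

__all__ = [
    "NoAnomalyError",
    "RoiDefinition",
    "RivSeries",
    "GroupComparison",
    "RegressionResult",
    "derive_roi",
    "compute_riv",
    "riv_trajectory",
    "anova_oneway",
    "compare_groups",
    "regress_riv_volume",
]

DEFAULT_ROI_FRACTION = 0.10
DEFAULT_MILESTONES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


class NoAnomalyError(ValueError):
    """No impedance-reduction anomaly present; the ROI is undefined."""


@dataclass
class RoiDefinition:
    elements: np.ndarray  # indices into the inverse mesh elements
    fraction: float
    source: str = ""


@dataclass
class RivSeries:
    times: np.ndarray
    riv: np.ndarray
    volumes_ml: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.riv) == len(self.volumes_ml)):
            raise ValueError("times, riv and volumes must have equal length")
        if np.any(np.diff(self.volumes_ml) < 0):
            raise ValueError("injected volumes must be non-decreasing")


@dataclass
class GroupComparison:
    labels: list
    samples: list
    f_stat: float
    p_omnibus: float
    posthoc_p: dict  # label -> adjusted p vs baseline (Tukey HSD)


@dataclass
class RegressionResult:
    slope: float  # RIV per ml
    intercept: float
    r_squared: float
    p_value: float  # F test of the linear fit
    n: int
    label: str = ""


def _image_values(image) -> np.ndarray:
    if isinstance(image, EitImage):
        return image.values
    return np.asarray(image, dtype=float)


def derive_roi(image, fraction: float = DEFAULT_ROI_FRACTION,
               source: str = "") -> RoiDefinition:
    """Elements whose hemorrhage-signed value exceeds ``fraction`` of the max.

    With m = max(-drho), the ROI is {e : -drho_e > fraction * m}; the
    argmax element is always included.  Raises if the image contains no
    impedance reduction at all.
    """
    if not 0 < fraction < 1:
        raise ValueError("threshold fraction must be in (0, 1)")
    values = _image_values(image)
    mag = -values
    m = mag.max()
    if not np.isfinite(m) or m <= 0:
        raise NoAnomalyError("image contains no impedance reduction; ROI undefined")
    elements = np.flatnonzero(mag > fraction * m)
    return RoiDefinition(elements=elements, fraction=float(fraction),
                         source=source)


def compute_riv(image, roi: RoiDefinition, mesh: Mesh) -> float:
    """Area-weighted ROI sum of the image, normalized by total mesh area."""
    values = _image_values(image)
    if len(values) != mesh.n_elements:
        raise ValueError("image length does not match mesh element count")
    if len(roi.elements) == 0:
        raise ValueError("ROI is empty")
    return float(
        np.dot(values[roi.elements], mesh.areas[roi.elements])
        / mesh.areas.sum()
    )


def riv_trajectory(
    images: ImageSeries,
    mesh: Mesh,
    volumes_ml: np.ndarray,
    roi_policy: str = "final-frame",
    fraction: float = DEFAULT_ROI_FRACTION,
) -> RivSeries:
    """RIV per image, with volumes aligned by time.

    With the default ``final-frame`` policy the ROI is derived once from
    the last image (largest hemorrhage) and applied to every frame,
    mirroring one fixed ROI per subject; ``per-frame`` re-derives it for
    each image.
    """
    if len(images) == 0:
        raise ValueError("empty image sequence")
    volumes_ml = np.asarray(volumes_ml, dtype=float)
    if roi_policy == "final-frame":
        roi = derive_roi(images.values[-1], fraction, source="final-frame")
        riv = images.values[:, roi.elements] @ mesh.areas[roi.elements]
        riv = riv / mesh.areas.sum()
    elif roi_policy == "per-frame":
        riv = np.empty(len(images))
        for i in range(len(images)):
            roi_i = derive_roi(images.values[i], fraction, source=f"frame {i}")
            riv[i] = compute_riv(images.values[i], roi_i, mesh)
    else:
        raise ValueError("roi_policy must be 'final-frame' or 'per-frame'")
    return RivSeries(times=images.times, riv=np.asarray(riv, dtype=float),
                     volumes_ml=volumes_ml)


def anova_oneway(groups) -> tuple:
    """One-way ANOVA (F, p) with explicit degenerate handling.

    Identical constant groups have zero between-group variation and
    return F = 0, p = 1; perfectly separated constant groups return
    F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def compare_groups(
    series: RivSeries,
    milestones=DEFAULT_MILESTONES,
    window_s: float = 30.0,
    baseline_label: str = "baseline",
) -> GroupComparison:
    """Compare baseline RIV against volume-milestone RIV groups.

    The baseline group holds every pre-injection frame; each milestone
    group holds the frames within ``window_s`` seconds of the instant the
    milestone volume was reached.  Omnibus one-way ANOVA plus Tukey HSD
    post hoc comparisons of each milestone against baseline.
    """
    baseline = series.riv[series.volumes_ml == 0]
    labels = [baseline_label]
    samples = [baseline]
    for m in milestones:
        if m > series.volumes_ml.max():
            raise ValueError(f"milestone {m} ml exceeds the injected volume")
        t_m = series.times[np.searchsorted(series.volumes_ml, m)]
        mask = (np.abs(series.times - t_m) <= window_s) & (series.volumes_ml > 0)
        group = series.riv[mask]
        labels.append(f"{m:g} ml")
        samples.append(group)
    if any(len(g) < 2 for g in samples):
        raise ValueError("every group needs at least 2 RIV samples")
    f, p = anova_oneway(samples)
    tukey = stats.tukey_hsd(*samples)
    posthoc = {
        labels[k]: float(tukey.pvalue[0, k]) for k in range(1, len(labels))
    }
    return GroupComparison(labels=labels, samples=samples, f_stat=f,
                           p_omnibus=p, posthoc_p=posthoc)


def regress_riv_volume(series: RivSeries, label: str = "") -> RegressionResult:
    """OLS regression of RIV on injected volume over the injection frames.

    For a simple linear regression the F test of the fit coincides with
    the two-sided t test on the slope reported by ``linregress``.
    """
    mask = series.volumes_ml > 0
    x = series.volumes_ml[mask]
    y = series.riv[mask]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct injected volumes to regress")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(len(x)),
        label=label,
    )
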