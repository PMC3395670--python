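"""Cross-assay same-scale correction.

Multi-color cytometry intensities of different epitopes are not mutually
comparable: each conjugate/detector pair carries its own arbitrary gain.
When the same epitopes are also measured in single-color indirect assays
sharing one secondary antibody, those assays *are* on one common scale.
DNA content, measured with high precision in every file, is the
correlating variable: after stretching each file's DNA axis so the G1 and
G2 modes land on channels 350 and 700, identical S-phase windows can be
placed in every file.  Regressing single-color against multi-color cyclin
medians within those windows yields an affine map per epitope onto the
common secondary-antibody scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy import stats as sstats

from .events_io import EventTable

__all__ = [
    "DnaRescale",
    "EquivalentGates",
    "ScalingMap",
    "find_dna_modes",
    "rescale_dna",
    "build_equivalent_gates",
    "gate_medians",
    "derive_scaling",
    "apply_scaling",
]

TARGET_G1 = 350.0
TARGET_G2 = 700.0


@dataclass
class DnaRescale:
    """Exact two-point linear map placing the DNA modes on target channels."""

    g1_mode: float
    g2_mode: float
    target_g1: float = TARGET_G1
    target_g2: float = TARGET_G2

    def __post_init__(self) -> None:
        if self.g2_mode <= self.g1_mode:
            raise ValueError("G2 mode must exceed G1 mode")
        self.a = (self.target_g2 - self.target_g1) / (self.g2_mode - self.g1_mode)
        self.b = self.target_g1 - self.a * self.g1_mode
        assert self.a > 0

    def __call__(self, values) -> np.ndarray:
        return self.a * np.asarray(values, dtype=float) + self.b


@dataclass
class EquivalentGates:
    """Contiguous equal-width DNA intervals centred on mid-S.

    The gates expand outward from the S-phase midpoint of the rescaled DNA
    axis (channel 525 under the default 350/700 anchors) and must stay
    within the open (G1, G2) modal interval.
    """

    intervals: list

    def __post_init__(self) -> None:
        iv = [tuple(map(float, p)) for p in self.intervals]
        widths = [b - a for a, b in iv]
        if any(w <= 0 for w in widths):
            raise ValueError("gate intervals must have positive width")
        if not np.allclose(widths, widths[0]):
            raise ValueError("gate intervals must be equal width")
        for (a0, b0), (a1, b1) in zip(iv[:-1], iv[1:]):
            if not np.isclose(b0, a1):
                raise ValueError("gate intervals must be contiguous")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def center(self) -> float:
        return 0.5 * (self.intervals[0][0] + self.intervals[-1][1])

    def membership(self, values) -> np.ndarray:
        """Gate index per value (-1 outside all gates); upper edge of the
        last gate is inclusive."""
        values = np.asarray(values, dtype=float)
        out = np.full(values.shape, -1, dtype=int)
        for k, (lo, hi) in enumerate(self.intervals):
            last = k == len(self.intervals) - 1
            sel = (values >= lo) & ((values <= hi) if last else (values < hi))
            out[sel] = k
        return out


@dataclass
class ScalingMap:
    """Affine map multi-color -> single-color (common secondary) scale."""

    slope: float
    intercept: float
    r2: float = float("nan")
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    epitope: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("scaling slope must be positive")

    def __call__(self, values):
        return self.slope * np.asarray(values, dtype=float) + self.intercept

    @property
    def rmse(self) -> float:
        if self.residuals.size == 0:
            return float("nan")
        return float(np.sqrt(np.mean(self.residuals ** 2)))


def find_dna_modes(table_or_values, bins: int = 512, smooth_bins: float = 3.0,
                   ratio_bounds: tuple = (1.8, 2.2)) -> tuple[float, float]:
    """Locate the G1 and G2 modal channels of a bimodal DNA histogram.

    Uses a 512-bin histogram with Gaussian kernel smoothing (bandwidth 3
    bins) and peak detection; the two most prominent peaks are returned in
    ascending order, ties broken toward the lower channel.  A mode ratio
    outside ``ratio_bounds`` triggers a warning; fewer than two detected
    peaks raises ``ValueError``.
    """
    if isinstance(table_or_values, EventTable):
        values = table_or_values[table_or_values.dna_channel]
    else:
        values = np.asarray(table_or_values, dtype=float)
    values = values[np.isfinite(values) & (values > 0)]
    if values.size < 10:
        raise ValueError("too few DNA values for mode detection")
    lo, hi = np.percentile(values, [0.5, 99.9])
    pad = 0.05 * max(hi - lo, 1e-9)   # modes at the range edge stay detectable
    lo, hi = lo - pad, hi + pad
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), smooth_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(smooth, prominence=0.05 * smooth.max(),
                              distance=max(bins // 16, 1))
    if len(peaks) < 2:
        raise ValueError("DNA histogram is not bimodal (fewer than two peaks)")
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(peaks[order[:2]])
    g1, g2 = float(centers[top2[0]]), float(centers[top2[1]])
    ratio = g2 / g1
    if ratio < 1.3:
        # two local bumps on one mound, not a 2C/4C pair
        raise ValueError("DNA histogram is not bimodal (no separated G2 peak)")
    if not ratio_bounds[0] <= ratio <= ratio_bounds[1]:
        warnings.warn(f"G2/G1 mode ratio {ratio:.3f} outside {ratio_bounds}",
                      stacklevel=2)
    return g1, g2


def rescale_dna(table: EventTable, rescale: DnaRescale) -> EventTable:
    """Apply the two-point modal DNA stretch to the table's DNA channel."""
    data = table.data.copy()
    ch = table.dna_channel
    data[ch] = rescale(data[ch].to_numpy())
    out = table.with_data(data)
    out.log("samescale.rescale_dna", a=rescale.a, b=rescale.b,
            targets=[rescale.target_g1, rescale.target_g2])
    return out


def build_equivalent_gates(n_gates: int = 7, width: float = 40.0,
                           center: float = 0.5 * (TARGET_G1 + TARGET_G2),
                           bounds: tuple = (TARGET_G1, TARGET_G2)
                           ) -> EquivalentGates:
    """Equal-width contiguous DNA gates expanding outward from mid-S."""
    if n_gates < 1:
        raise ValueError("n_gates must be >= 1")
    lo = center - n_gates * width / 2.0
    edges = lo + width * np.arange(n_gates + 1)
    if edges[0] <= bounds[0] or edges[-1] >= bounds[1]:
        raise ValueError(
            f"gate union [{edges[0]}, {edges[-1]}] exceeds the open modal "
            f"interval {bounds}")
    return EquivalentGates([(edges[k], edges[k + 1]) for k in range(n_gates)])


def gate_medians(table: EventTable, gates: EquivalentGates,
                 epitope: str) -> np.ndarray:
    """Per-gate median epitope intensity on a DNA-rescaled table.

    Empty gates yield NaN and a warning.
    """
    dna = table[table.dna_channel]
    values = table[epitope]
    member = gates.membership(dna)
    out = np.full(len(gates), np.nan)
    for k in range(len(gates)):
        sel = member == k
        if sel.any():
            out[k] = float(np.median(values[sel]))
    if np.isnan(out).any():
        warnings.warn(f"{int(np.isnan(out).sum())} equivalent gate(s) empty",
                      stacklevel=2)
    return out


def derive_scaling(multi_medians, single_medians, epitope: str = "") -> ScalingMap:
    """OLS line single = a * multi + b over paired equivalent-gate medians.

    Background subtraction should force b toward 0; the intercept is left
    free so that assumption is testable rather than imposed.
    """
    x = np.asarray(multi_medians, dtype=float)
    y = np.asarray(single_medians, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired finite medians for scaling regression")
    res = sstats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError("non-positive scaling slope: assays are inconsistent")
    fitted = res.slope * x + res.intercept
    return ScalingMap(float(res.slope), float(res.intercept),
                      r2=float(res.rvalue ** 2), residuals=y - fitted,
                      epitope=epitope)


def apply_scaling(profile, mapping: ScalingMap):
    """Map a profile's y values onto the common single-color scale.

    Accepts an :class:`cytocycle.profiles.ExpressionProfile` (returns a new
    profile with provenance note) or a bare array of y values.
    """
    from .profiles import ExpressionProfile

    if isinstance(profile, ExpressionProfile):
        return profile.transform_y(mapping, scale="samescale")
    return mapping(np.asarray(profile, dtype=float))
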