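"""Expression-profile synthesis.

Every region or fitted component along the cell-cycle traversal owns a
frequency of events proportional to the time the average cell spends in
that state.  Converting the per-step summaries into profiles takes four
moves:

1. cumulative positioning — step k sits at the midpoint of its event
   mass, x_k = sum_{j<k} f_j + f_k / 2;
2. piecewise-linear synthesis — knots (x_i, y_i) joined by the two-point
   line y = [(y_{i+1}-y_i)/(x_{i+1}-x_i)] x + y_i - [(y_{i+1}-y_i)/(x_{i+1}-x_i)] x_i;
3. boundary heuristics — duplicate the G1 value at x = 0, extrapolate a
   zero-crossing knot at the G1/S boundary for markers absent in G1, and
   optionally zero the endpoints for epitopes known to be below detection
   at birth and division;
4. frequency -> time — under the ideal exponential age distribution of an
   asynchronous population, t = 1 - log2(2 - F), the inverse of
   F = 2 - 2**(1-t).

:func:`profile_pipeline` chains preprocessing, gating, deconvolution,
same-scale correction and profile synthesis end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events_io import EventTable

__all__ = [
    "ExpressionPoint",
    "ExpressionProfile",
    "cumulative_positions",
    "frequency_to_time",
    "time_to_frequency",
    "assemble_profile",
    "apply_boundary_heuristics",
    "PipelineConfig",
    "profile_pipeline",
]


@dataclass
class ExpressionPoint:
    """One profile knot: x is cumulative frequency or cell-cycle time."""

    x: float
    y: float
    source: str = "region_median"
    phase: str = ""

    def __post_init__(self) -> None:
        if -1e-9 <= self.x < 0.0:
            self.x = 0.0
        elif 1.0 < self.x <= 1.0 + 1e-9:
            self.x = 1.0
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"knot x={self.x} outside [0, 1]")
        if not np.isfinite(self.y):
            raise ValueError("knot y must be finite")


@dataclass
class ExpressionProfile:
    """Ordered knots with piecewise-linear evaluation.

    ``axis_kind`` is ``frequency`` or ``time``; evaluation is defined on
    [x_first, x_last] (and linearly extrapolated outside, for trajectory
    use).
    """

    points: list
    axis_kind: str = "frequency"
    marker: str = ""
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.x)
        xs = self.x
        if len(xs) < 2:
            raise ValueError("profile needs >= 2 points")
        if np.any(np.diff(xs) <= 0):
            raise ValueError("profile x values must be strictly increasing")
        if self.axis_kind not in ("frequency", "time"):
            raise ValueError("axis_kind must be 'frequency' or 'time'")

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p.y for p in self.points])

    def __call__(self, x) -> np.ndarray:
        """Piecewise-linear evaluation with linear end-extrapolation."""
        x = np.asarray(x, dtype=float)
        xs, ys = self.x, self.y
        out = np.interp(x, xs, ys)
        # linear extrapolation beyond the knot range
        lo = x < xs[0]
        hi = x > xs[-1]
        if lo.any():
            m = (ys[1] - ys[0]) / (xs[1] - xs[0])
            out = np.where(lo, ys[0] + m * (x - xs[0]), out)
        if hi.any():
            m = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            out = np.where(hi, ys[-1] + m * (x - xs[-1]), out)
        return out

    def resample(self, n: int) -> "ExpressionProfile":
        """Uniformly interpolated copy with ``n`` points (point-to-point
        connections are preserved exactly at the original knots)."""
        xs = np.linspace(self.x[0], self.x[-1], n)
        xs = np.unique(np.concatenate([xs, self.x]))
        pts = [ExpressionPoint(float(x), float(self(x)), "interpolated")
               for x in xs]
        return ExpressionProfile(pts, self.axis_kind, self.marker, self.scale)

    def transform_y(self, func, scale: str | None = None) -> "ExpressionProfile":
        pts = [replace(p, y=float(func(p.y))) for p in self.points]
        return ExpressionProfile(pts, self.axis_kind, self.marker,
                                 scale or self.scale)

    def peak(self) -> tuple[float, float]:
        i = int(np.argmax(self.y))
        return float(self.x[i]), float(self.y[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker,
            "x": self.x, "y": self.y,
            "source": [p.source for p in self.points],
            "phase": [p.phase for p in self.points],
        })


def cumulative_positions(frequencies) -> np.ndarray:
    """Midpoint-of-mass x positions: x_k = sum_{j<k} f_j + f_k / 2.

    Zero-frequency steps are dropped with a warning.  Frequencies may come
    from region counts or from fitted component weights.
    """
    f = np.asarray(frequencies, dtype=float)
    if (f < 0).any():
        raise ValueError("frequencies must be nonnegative")
    if f.sum() > 1.0 + 1e-9:
        raise ValueError("frequencies must sum to at most 1")
    if (f == 0).any():
        warnings.warn(f"{int((f == 0).sum())} zero-frequency step(s) dropped",
                      stacklevel=2)
    cum = np.concatenate([[0.0], np.cumsum(f)])[:-1]
    x = cum + f / 2.0
    return x[f > 0]


def frequency_to_time(F):
    """Map cumulative frequency to cell-cycle time, t = 1 - log2(2 - F).

    Corrects for the exponential age distribution of an asynchronous
    population (a factor-of-2 decline across the cycle); a monotone
    bijection of [0, 1] onto itself.
    """
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("cumulative frequency must lie in [0, 1]")
    return 1.0 - np.log2(2.0 - F)


def time_to_frequency(t):
    """Inverse of :func:`frequency_to_time`: F = 2 - 2**(1-t)."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("cell-cycle time must lie in [0, 1]")
    return 2.0 - 2.0 ** (1.0 - t)


def assemble_profile(points, axis_kind: str = "frequency", marker: str = "",
                     scale: str = "raw") -> ExpressionProfile:
    """Build a profile from (x, y) pairs or :class:`ExpressionPoint` s."""
    pts = [p if isinstance(p, ExpressionPoint)
           else ExpressionPoint(float(p[0]), float(p[1]))
           for p in points]
    xs = sorted(p.x for p in pts)
    if np.any(np.diff(xs) == 0):
        raise ValueError("duplicate x values in profile points")
    return ExpressionProfile(pts, axis_kind, marker, scale)


def apply_boundary_heuristics(profile: ExpressionProfile,
                              zero_endpoints: bool = False,
                              extrapolate_zero_onset: bool = False
                              ) -> ExpressionProfile:
    """Improve profile boundaries where region centres leave them sparse.

    * The first G1 knot's value also holds at x = 0, so it is duplicated
      there.
    * For a marker absent in G1 (``extrapolate_zero_onset``), a line
      through the first three S knots is extended back to its y = 0
      crossing and a knot inserted there — if the crossing falls inside
      the G1-to-S gap; an inadmissible crossing is skipped with a warning
      (the shape of that transition is then left unimproved).
    * The last knot's value is duplicated at x = 1.
    * With ``zero_endpoints`` the y values at x = 0 and x = 1 are set to
      exactly 0, encoding below-detection levels at birth and division.
    """
    pts = list(profile.points)
    phases = [p.phase for p in pts]
    if pts[0].x > 0:
        first_g1 = next((p for p in pts if p.phase in ("", "g1")), pts[0])
        pts.insert(0, ExpressionPoint(0.0, first_g1.y, "heuristic", "g1"))
    if extrapolate_zero_onset:
        s_pts = [p for p in pts if p.phase == "s"][:3]
        if len(s_pts) == 3:
            coef = np.polyfit([p.x for p in s_pts], [p.y for p in s_pts], 1)
            if abs(coef[0]) > 1e-12:
                x0 = -coef[1] / coef[0]
                g1_x = max((p.x for p in pts if p.phase == "g1"), default=0.0)
                s_x = s_pts[0].x
                if g1_x < x0 < s_x and not any(np.isclose(x0, p.x) for p in pts):
                    pts.append(ExpressionPoint(float(x0), 0.0, "heuristic", "s"))
                elif not g1_x < x0 < s_x:
                    warnings.warn(
                        "zero-onset extrapolation falls outside the G1-S gap; "
                        "transition left unimproved", stacklevel=2)
    pts.sort(key=lambda p: p.x)
    if pts[-1].x < 1:
        pts.append(ExpressionPoint(1.0, pts[-1].y, "heuristic", pts[-1].phase or "m"))
    if zero_endpoints:
        pts[0] = replace(pts[0], y=0.0, source="heuristic")
        pts[-1] = replace(pts[-1], y=0.0, source="heuristic")
    return ExpressionProfile(pts, profile.axis_kind, profile.marker,
                             profile.scale)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Knobs for the end-to-end profile pipeline.

    ``compensation`` lists (source, target, coefficient) spillover terms
    for the multi-color file.  ``lam`` weights the amplitude-continuity
    penalty in the phase deconvolutions.  ``zero_endpoint_markers`` names
    epitopes known to be below detection at birth and division (degraded
    cyclins); their profiles are pinned to 0 at x = 0 and 1.
    """

    compensation: list = field(default_factory=list)
    n_segments: int = 12
    min_events: int = 300
    lam: float = 1.0
    n_gates: int = 7
    gate_width: float = 40.0
    zero_endpoint_markers: tuple = ("cyca2", "cycb1")
    seed: int = 0


def _preprocess_table(table, compensation=None):
    from . import preprocess as pp

    if compensation:
        table = pp.compensate(table, compensation)
    table = pp.exclude_debris_aggregates(table)
    table, anchor = pp.subtract_background(table)
    return table, anchor


def _phase_points(marker, y_values, freqs, phases, sources):
    pts = []
    for y, f_x, ph, src in zip(y_values, freqs, phases, sources):
        if np.isfinite(y):
            pts.append(ExpressionPoint(float(f_x), float(y), src, ph))
    return pts


def _component_points(fit, f_start, f_span, phase, y_offset=0.0):
    """(F, linear-mean) knots from a phase deconvolution's components.

    Components are ordered by mean and assigned sequential frequency mass
    proportional to their weights; ``y_offset`` converts raw-scale means
    back to background-subtracted units.
    """
    comps = sorted(fit.components, key=lambda c: c.mean)
    w = np.array([c.weight for c in comps])
    if w.sum() <= 0:
        return []
    w = w / w.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])[:-1]
    pts = []
    for c, cw, cc in zip(comps, w, cum):
        if cw < 1e-6:
            continue  # a massless component carries no profile time
        x = f_start + f_span * (cc + cw / 2.0)
        pts.append(ExpressionPoint(float(x), float(10.0 ** c.mean - y_offset),
                                   "component_mean", phase))
    return pts


def profile_pipeline(multi: EventTable, single_a: EventTable,
                     single_b: EventTable,
                     config: PipelineConfig | None = None) -> dict:
    """Run the full static-to-dynamic conversion on one assay triple.

    Returns a dict with per-marker knot tables (``profiles``), time-domain
    same-scale :class:`ExpressionProfile` objects (``expression``) and fit
    and scaling diagnostics (``diagnostics``).  DNA is reported in genome
    units (G1 mode anchored at 2 genomes); pHH3 stays on its own relative
    scale (ratio to its G1 level).
    """
    from . import gating, mixture, samescale

    cfg = config or PipelineConfig()
    diagnostics: dict = {}

    multi_pp, anchor = _preprocess_table(multi, cfg.compensation)
    single_a_pp, _ = _preprocess_table(single_a)
    single_b_pp, _ = _preprocess_table(single_b)

    inter, mito = gating.split_interphase_mitosis(multi_pp)
    from .preprocess import stemline_gate

    inter = stemline_gate(inter)
    n_total = len(inter) + len(mito)

    chain = gating.auto_segment_s(inter, cfg.n_segments, cfg.min_events,
                                  adapt=True)
    stats = gating.chain_stats(inter, chain)
    by_id = {s.step_id: s for s in stats}
    inter_scale = len(inter) / n_total

    mchain = gating.build_mitosis_chain(mito)
    mstats = gating.chain_stats(mito, mchain) if mchain.steps else []
    mito_scale = len(mito) / n_total

    # frequency layout over the whole gated population
    f_g1 = by_id["G1"].frequency * inter_scale
    s_ids = [s.id for s in chain.steps if s.role == "segment"]
    f_s = np.array([by_id[i].frequency for i in s_ids]) * inter_scale
    f_g2 = by_id["G2"].frequency * inter_scale
    f_m = np.array([s.frequency for s in mstats]) * mito_scale
    f_s_start = f_g1
    f_g2_start = f_g1 + f_s.sum()
    f_m_start = f_g2_start + f_g2
    x_s = f_s_start + np.concatenate([[0.0], np.cumsum(f_s)])[:-1] + f_s / 2.0
    x_m = f_m_start + np.concatenate([[0.0], np.cumsum(f_m)])[:-1] + f_m / 2.0

    # S-phase trajectories (for the continuity penalty), per cyclin
    def s_trajectory(marker):
        ys = np.array([by_id[i].medians[marker] for i in s_ids])
        pts = [ExpressionPoint(float(x), float(y), "region_median", "s")
               for x, y in zip(x_s, ys)]
        return ExpressionProfile(pts, "frequency", marker)

    traj_a2 = s_trajectory("cyca2")
    traj_b1 = s_trajectory("cycb1")

    # anchors and phase deconvolutions.  Fitting works in log10 of the
    # *raw-scale* (offset-restored) intensities: background subtraction
    # centres negative cells on zero, which a log transform cannot
    # represent; adding the measured G1 background back recovers a strictly
    # positive scale, and component means are converted back afterwards.
    off_a2 = anchor.offsets.get("cyca2", 0.0)
    off_b1 = anchor.offsets.get("cycb1", 0.0)
    g1s_oval = chain.step("G1/S").indices
    sg2_oval = chain.step("S/G2").indices
    a2_entry = mixture.fit_anchor(inter["cyca2"][sg2_oval] + off_a2)
    b1_entry = mixture.fit_anchor(inter["cycb1"][sg2_oval] + off_b1)
    b1_g1_exit = mixture.fit_anchor(inter["cycb1"][g1s_oval] + off_b1)
    a2_exit_vals = gating.g2_exit_values(mito, mchain, "cyca2")
    b1_exit_vals = gating.g2_exit_values(mito, mchain, "cycb1")
    a2_exit = (mixture.fit_anchor(a2_exit_vals + off_a2)
               if a2_exit_vals.size >= 50 else a2_entry)
    b1_exit = (mixture.fit_anchor(b1_exit_vals + off_b1)
               if b1_exit_vals.size >= 50 else b1_entry)

    g2_a2 = inter["cyca2"][chain.step("G2").indices] + off_a2
    g2_b1 = inter["cycb1"][chain.step("G2").indices] + off_b1
    g1_b1 = inter["cycb1"][chain.step("G1").indices] + off_b1
    traj_a2_raw = lambda F: traj_a2(F) + off_a2
    traj_b1_raw = lambda F: traj_b1(F) + off_b1
    fit_a2_g2 = mixture.fit_g2(g2_a2, a2_entry, a2_exit, traj_a2_raw, cfg.lam,
                               f_start=f_g2_start, f_span=f_g2, seed=cfg.seed)
    fit_b1_g2 = mixture.fit_g2(g2_b1, b1_entry, b1_exit, traj_b1_raw, cfg.lam,
                               f_start=f_g2_start, f_span=f_g2,
                               seed=cfg.seed + 1)
    fit_b1_g1 = mixture.fit_g1_cyclinB(g1_b1, b1_g1_exit, traj_b1_raw, cfg.lam,
                                       f_start=0.0, f_span=f_g1,
                                       seed=cfg.seed + 2)
    diagnostics["fits"] = {
        "cyca2_g2": fit_a2_g2, "cycb1_g2": fit_b1_g2, "cycb1_g1": fit_b1_g1}
    diagnostics["anchors"] = {
        "cyca2_entry": a2_entry, "cyca2_exit": a2_exit,
        "cycb1_entry": b1_entry, "cycb1_exit": b1_exit,
        "cycb1_g1_exit": b1_g1_exit}

    # raw frequency-domain profiles -------------------------------------
    def m_points(marker):
        return _phase_points(marker,
                             [s.medians[marker] for s in mstats],
                             x_m, ["m"] * len(mstats),
                             ["region_median"] * len(mstats))

    def s_points(marker):
        return _phase_points(marker,
                             [by_id[i].medians[marker] for i in s_ids],
                             x_s, ["s"] * len(s_ids),
                             ["region_median"] * len(s_ids))

    profiles_raw: dict[str, ExpressionProfile] = {}
    # cyclin A2: single G1 point (background ~0), G2 deconvolved
    a2_pts = ([ExpressionPoint(float(f_g1 / 2.0),
                               float(by_id["G1"].medians["cyca2"]),
                               "region_median", "g1")]
              + s_points("cyca2")
              + _component_points(fit_a2_g2, f_g2_start, f_g2, "g2", off_a2)
              + m_points("cyca2"))
    profiles_raw["cyca2"] = ExpressionProfile(a2_pts, "frequency", "cyca2")
    # cyclin B1: both G1 and G2 deconvolved
    b1_pts = (_component_points(fit_b1_g1, 0.0, f_g1, "g1", off_b1)
              + s_points("cycb1")
              + _component_points(fit_b1_g2, f_g2_start, f_g2, "g2", off_b1)
              + m_points("cycb1"))
    profiles_raw["cycb1"] = ExpressionProfile(b1_pts, "frequency", "cycb1")
    # context: DNA (genome units) and pHH3 (own relative scale)
    g1_dna_mode, _ = samescale.find_dna_modes(multi_pp)
    dna_pts = ([ExpressionPoint(float(f_g1 / 2.0), by_id["G1"].medians["dna"],
                                "region_median", "g1")]
               + s_points("dna")
               + [ExpressionPoint(float(f_g2_start + f_g2 / 2.0),
                                  by_id["G2"].medians["dna"],
                                  "region_median", "g2")]
               + m_points("dna"))
    dna_prof = ExpressionProfile(dna_pts, "frequency", "dna")
    profiles_raw["dna"] = dna_prof.transform_y(
        lambda y: 2.0 * y / g1_dna_mode, scale="genomes")
    # pHH3 relative scale: ratio to its own interphase G1 level, which is
    # the pre-subtraction background anchor (interphase pHH3 is not zero)
    off_p = anchor.offsets.get("phh3", 0.0)
    phh3_g1 = by_id["G1"].medians["phh3"]
    phh3_pts = ([ExpressionPoint(float(f_g1 / 2.0), phh3_g1,
                                 "region_median", "g1")]
                + s_points("phh3")
                + [ExpressionPoint(float(f_g2_start + f_g2 / 2.0),
                                   by_id["G2"].medians["phh3"],
                                   "region_median", "g2")]
                + m_points("phh3"))
    phh3_prof = ExpressionProfile(phh3_pts, "frequency", "phh3")
    ref = (phh3_g1 + off_p) if (phh3_g1 + off_p) > 0 else 1.0
    profiles_raw["phh3"] = phh3_prof.transform_y(
        lambda y: (y + off_p) / ref, scale="relative")

    # boundary heuristics -------------------------------------------------
    heur: dict[str, ExpressionProfile] = {}
    for marker, prof in profiles_raw.items():
        heur[marker] = apply_boundary_heuristics(
            prof,
            zero_endpoints=marker in cfg.zero_endpoint_markers,
            extrapolate_zero_onset=(marker == "cyca2"),
        )

    # same-scale correction ----------------------------------------------
    gates = samescale.build_equivalent_gates(cfg.n_gates, cfg.gate_width)
    maps: dict[str, samescale.ScalingMap] = {}
    for marker, single in (("cyca2", single_a_pp), ("cycb1", single_b_pp)):
        multi_rs = samescale.rescale_dna(
            multi_pp, samescale.DnaRescale(*samescale.find_dna_modes(multi_pp)))
        single_rs = samescale.rescale_dna(
            single, samescale.DnaRescale(*samescale.find_dna_modes(single)))
        mm = samescale.gate_medians(multi_rs, gates, marker)
        sm = samescale.gate_medians(single_rs, gates, marker)
        maps[marker] = samescale.derive_scaling(mm, sm, marker)
    diagnostics["scaling"] = maps

    # final frames ---------------------------------------------------------
    out_profiles: dict[str, pd.DataFrame] = {}
    expression: dict[str, ExpressionProfile] = {}
    for marker, prof in heur.items():
        if marker in maps:
            scaled = prof.transform_y(maps[marker], scale="samescale")
            # zeroed endpoints stay exactly zero on the common scale
            if marker in cfg.zero_endpoint_markers:
                pts = list(scaled.points)
                pts[0] = replace(pts[0], y=0.0)
                pts[-1] = replace(pts[-1], y=0.0)
                scaled = ExpressionProfile(pts, scaled.axis_kind, marker,
                                           "samescale")
            y_scaled = scaled.y
        else:
            scaled = prof
            y_scaled = prof.y
        xf = prof.x
        xt = frequency_to_time(xf)
        out_profiles[marker] = pd.DataFrame({
            "marker": marker,
            "x_frequency": xf,
            "x_time": xt,
            "y_raw": prof.y,
            "y_samescale": y_scaled,
            "source": [p.source for p in prof.points],
            "phase": [p.phase for p in prof.points],
        })
        tpts = [ExpressionPoint(float(t), float(y), p.source, p.phase)
                for t, y, p in zip(xt, y_scaled, prof.points)]
        expression[marker] = ExpressionProfile(tpts, "time", marker,
                                               scaled.scale)

    diagnostics["frequencies"] = {
        "g1": float(f_g1), "s": float(f_s.sum()), "g2": float(f_g2),
        "m": float(f_m.sum())}
    diagnostics["n_events"] = {"interphase": len(inter), "mitosis": len(mito)}
    return {"profiles": out_profiles, "expression": expression,
            "diagnostics": diagnostics}
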