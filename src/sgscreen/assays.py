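"""Quantitative validation-assay calculations for resistance follow-up.

Covers the arithmetic that turns raw bench measurements into the numbers a
resistance study reports: four-parameter logistic (4PL) dose-response fits
and IC50 fold-resistance, caliper tumor volume and treatment percent
change, comet-assay tail-DNA percentage, DSB-reporter repair efficiency,
DNA-fiber IdU/CldU ratios, and the two-group statistical tests these data
are conventionally analyzed with (exact Mann-Whitney for per-cell/per-fiber
distributions, Welch's t for summary comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """4PL fit of viability vs concentration.

    ``ic50`` is the inflection concentration of the fitted curve (relative
    IC50). ``converged`` is False — never an exception — when the data are
    too flat to define a curve.
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool


def _four_pl(logc: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    # Decreasing logistic in log10 concentration; v(ic50) = (top+bottom)/2.
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_dose_response(
    concentrations: np.ndarray,
    viability: np.ndarray,
    fix_bottom: float | None = None,
    fix_top: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration.

    ``concentrations`` (uM, > 0) and ``viability`` (fraction of untreated
    control, in [0, 1.5]) are parallel arrays; replicates appear as repeated
    concentrations. Requires >= 4 distinct concentrations. The optimizer is
    multi-started from a deterministic grid of IC50 and Hill-slope guesses,
    so identical input always yields the identical fit.

    ``fix_bottom``/``fix_top`` pin the corresponding asymptote instead of
    fitting it. Because viability here is normalized to untreated control,
    ``fix_top=1`` (and ``fix_bottom=0`` for a fully cytotoxic drug) is the
    usual normalized-response model; constraining the asymptotes roughly
    halves the sampling error of the IC50 at bench-typical noise.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(viability, dtype=float)
    if c.shape != v.shape or c.ndim != 1:
        raise ValueError("concentrations and viability must be parallel 1-D arrays")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 (log scale)")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(v < 0) or np.any(v > 1.5):
        raise ValueError("viability must lie in [0, 1.5]")

    logc = np.log10(c)
    lo, hi = logc.min(), logc.max()

    free = [i for i, fx in enumerate((fix_bottom, fix_top)) if fx is None]
    lower = [-0.5] * len(free) + [lo - 3.0, 0.01]
    upper = [1.6] * len(free) + [hi + 3.0, 10.0]

    def unpack(theta):
        it = iter(theta)
        bottom = fix_bottom if fix_bottom is not None else next(it)
        top = fix_top if fix_top is not None else next(it)
        return bottom, top, *it

    def residuals(theta):
        return _four_pl(logc, *unpack(theta)) - v

    vmin, vmax = float(v.min()), float(v.max())
    asym0 = [x for x, fx in (((vmin, fix_bottom)), ((vmax, fix_top))) if fx is None]
    best = None
    for lic in np.linspace(lo, hi, 7):
        for hill in (0.5, 1.0, 2.0, 4.0):
            x0 = np.array(asym0 + [lic, hill])
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            if best is None or res.cost < best.cost:
                best = res

    bottom, top, log_ic50, hill = unpack(best.x)
    rss = float(2 * best.cost)
    # A flat curve cannot localize an IC50: require a minimal dynamic range.
    converged = bool(best.success and (top - bottom) > 0.1)
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(10.0**log_ic50),
        hill=float(hill),
        rss=rss,
        converged=converged,
    )


def viability_fractions(counts: np.ndarray, untreated_mean: float) -> np.ndarray:
    """Normalize raw viable-cell counts to fractions of the untreated mean."""
    if untreated_mean <= 0:
        raise ValueError("untreated_mean must be > 0")
    return np.asarray(counts, dtype=float) / untreated_mean


def fold_resistance(ic50_test: float, ic50_reference: float) -> float:
    """IC50 ratio of a test line over its parental reference (> 1 = resistant)."""
    if ic50_test <= 0 or ic50_reference <= 0:
        raise ValueError("IC50 values must be > 0")
    return ic50_test / ic50_reference


# ---------------------------------------------------------------------------
# In vivo and cell-based readouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement: L = largest diameter (mm), W = perpendicular
    diameter (mm), at a study day."""

    L: float
    W: float
    day: int = 0

    def __post_init__(self) -> None:
        if not self.W > 0:
            raise ValueError("W must be > 0")
        if self.L < self.W:
            raise ValueError("L is the largest diameter; require L >= W")


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-style caliper volume V = L * W^2 * 0.5, in mm^3."""
    return m.L * m.W**2 * 0.5


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Percent reduction of a treated group mean relative to control;
    negative when the treated mean exceeds control."""
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 100.0 * (control_mean - treated_mean) / control_mean


@dataclass
class CometProfile:
    """Comet-assay intensity profile along the electrophoresis axis with an
    externally supplied head/tail boundary index (segmentation happens
    upstream, in the imaging software)."""

    intensities: np.ndarray
    head_boundary: int

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be 1-D")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if not 0 <= self.head_boundary <= len(self.intensities):
            raise ValueError("head_boundary out of range")


def tail_dna_percent(p: CometProfile) -> float:
    """Percent of total comet intensity beyond the head boundary — the
    per-cell double-strand-break proxy."""
    total = float(p.intensities.sum())
    if total <= 0:
        raise ValueError("total intensity must be > 0")
    return 100.0 * float(p.intensities[p.head_boundary :].sum()) / total


@dataclass(frozen=True)
class ReporterCounts:
    """DSB-repair reporter readout: GFP-restored cells over transfection-
    marker-positive (mCherry/BFP) cells."""

    gfp_positive: int
    transfection_positive: int

    def __post_init__(self) -> None:
        if self.gfp_positive < 0:
            raise ValueError("gfp_positive must be >= 0")
        if self.transfection_positive < 1:
            raise ValueError("transfection_positive must be >= 1")


def repair_efficiency(r: ReporterCounts) -> float:
    """Fraction of transfected cells with a restored GFP reporter."""
    return r.gfp_positive / r.transfection_positive


@dataclass(frozen=True)
class FiberMeasurement:
    """One DNA fiber: first-label (CldU) and second-label (IdU) tract
    lengths in any consistent unit — the ratio is unit-free."""

    cldu_length: float
    idu_length: float

    def __post_init__(self) -> None:
        if self.cldu_length <= 0 or self.idu_length <= 0:
            raise ValueError("tract lengths must be > 0")


def fiber_ratio(f: FiberMeasurement) -> float:
    """IdU/CldU tract-length ratio: ~1 for protected forks, < 1 when the
    nascent strand is degraded after stalling."""
    return f.idu_length / f.cldu_length


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    test: str
    method: str


def compare_groups(
    a: np.ndarray, b: np.ndarray, test: str = "mann_whitney"
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``mann_whitney`` uses the exact null distribution when both groups have
    n <= 20 and the pooled data are tie-free (the regime of per-cell comet
    and per-fiber measurements), otherwise the tie-corrected normal
    approximation. ``welch_t`` is the unequal-variance t-test used for
    summary-level comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        exact_ok = len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
        method = "exact" if exact_ok else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparison(float(res.statistic), float(res.pvalue), test, method)
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(float(res.statistic), float(res.pvalue), test, "welch")
    raise ValueError(f"unknown test {test!r}; use 'mann_whitney' or 'welch_t'")
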