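"""Single-probe peak detection for DNA methylation beta values.

Across a cohort, the beta values at one CpG probe usually pile up in a
single mode.  Genetic variation under the probe — most prominently a SNP
at the CpG site itself, which splits samples into three genotype
clusters — or technical artifacts such as cross-hybridization produce
two or more modes.  This module implements the per-probe detector:

1. Gaussian kernel density smoothing of the empirical beta distribution
   (rule-of-thumb ``nrd0`` bandwidth, 512-point grid extended three
   bandwidths past the data range, mirroring the base-R density
   contract).
2. Stationary-point detection from the sign pattern of first
   differences of the fitted density.
3. A two-parameter noise filter: a candidate peak capturing less than
   ``proportion_sample`` of the cohort *and* bounded by a zero-density
   minimum is discarded.
4. Merging of adjacent maxima whose apexes lie within ``peak_distance``
   of each other (they represent the same mode), followed by a
   re-application of the proportion floor.
5. The final unimodal/multimodal call.

Everything here is deterministic: the same beta vector and parameters
always yield the same call, byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionError",
    "TooFewObservationsError",
    "DegenerateInputError",
    "DetectionParams",
    "DensityCurve",
    "Peak",
    "ModalityCall",
    "MIN_OBS",
    "rule_of_thumb_bandwidth",
    "estimate_density",
    "find_stationary_points",
    "assign_candidate_peaks",
    "filter_noise_peaks",
    "merge_close_peaks",
    "refilter_merged_peaks",
    "classify_probe",
]

#: Minimum number of non-missing beta values required to attempt detection.
MIN_OBS = 10


class DetectionError(ValueError):
    """Base class for per-probe detection failures."""


class TooFewObservationsError(DetectionError):
    """Fewer non-missing beta values than the detection minimum."""


class DegenerateInputError(DetectionError):
    """Zero-spread input: both SD and IQR are zero, so no bandwidth exists."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the peak detector.

    Parameters
    ----------
    peak_distance:
        Minimum beta-scale distance required between the apexes of two
        adjacent peaks; closer apexes are treated as one mode and
        merged.  Default 0.10.
    proportion_sample:
        Minimum fraction of the cohort a peak must capture between its
        bounding minima.  Default 0.01.
    grid_size:
        Number of equally spaced density evaluation points.  Default 512.
    bandwidth_rule:
        ``"rule-of-thumb"`` (the nrd0 rule, default) or ``"fixed"``
        with ``fixed_bandwidth`` supplied.
    fixed_bandwidth:
        Positive bandwidth used when ``bandwidth_rule == "fixed"``.
    grid_cut:
        The evaluation grid extends this many bandwidths beyond the
        observed data range on each side.  Default 3.
    zero_density_tol:
        Density values at or below this threshold count as "zero" for
        the noise filter.  ``None`` (default) resolves, per curve, to
        1e-4 times the curve's maximum density — a Gaussian KDE is never
        exactly zero in exact arithmetic, so an absolute zero test would
        depend on floating-point underflow.
    secondary_peak_min:
        Post-hoc filter: a multimodal call whose secondary peak (the
        second-largest sample proportion) falls below this fraction is
        flagged as likely noise.  Default 0.04.
    hypo_mean_max, hyper_mean_min:
        Probe-level mean-beta thresholds for the hypo-/hyper-methylation
        flags.  Defaults 0.1 and 0.9.
    extreme_var_max:
        Optional probe-level variance ceiling additionally required for
        the hypo/hyper flags; ``None`` means mean-only flags.
    """

    peak_distance: float = 0.10
    proportion_sample: float = 0.01
    grid_size: int = 512
    bandwidth_rule: str = "rule-of-thumb"
    fixed_bandwidth: float | None = None
    grid_cut: float = 3.0
    zero_density_tol: float | None = None
    secondary_peak_min: float = 0.04
    hypo_mean_max: float = 0.1
    hyper_mean_min: float = 0.9
    extreme_var_max: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.proportion_sample < 1.0:
            raise ValueError("proportion_sample must lie in (0, 1)")
        if not 0.0 < self.peak_distance <= 1.0:
            raise ValueError("peak_distance must lie in (0, 1]")
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8")
        if self.bandwidth_rule not in ("rule-of-thumb", "fixed"):
            raise ValueError(f"unknown bandwidth_rule {self.bandwidth_rule!r}")
        if self.bandwidth_rule == "fixed":
            if self.fixed_bandwidth is None or self.fixed_bandwidth <= 0:
                raise ValueError("fixed bandwidth_rule requires fixed_bandwidth > 0")
        if self.grid_cut < 0:
            raise ValueError("grid_cut must be nonnegative")
        if self.zero_density_tol is not None and self.zero_density_tol < 0:
            raise ValueError("zero_density_tol must be nonnegative")
        if not 0.0 <= self.secondary_peak_min < 1.0:
            raise ValueError("secondary_peak_min must lie in [0, 1)")
        if not self.hypo_mean_max < self.hyper_mean_min:
            raise ValueError("hypo_mean_max must be below hyper_mean_min")
        if self.extreme_var_max is not None and self.extreme_var_max <= 0:
            raise ValueError("extreme_var_max must be positive when set")


@dataclass(frozen=True)
class DensityCurve:
    """Smoothed density estimate for one probe.

    ``grid`` is a strictly ascending, uniformly spaced sequence of
    beta-scale evaluation points; ``density`` the matching nonnegative
    density values; ``bandwidth`` the kernel standard deviation used;
    ``n_obs`` the count of non-missing beta values behind the fit.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_obs: int

    def zero_tolerance(self, params: DetectionParams) -> float:
        """Resolve the effective zero-density threshold for this curve."""
        if params.zero_density_tol is not None:
            return params.zero_density_tol
        return 1e-4 * float(self.density.max())


@dataclass(frozen=True)
class Peak:
    """One detected mode.

    Boundaries are the bounding density minima; the outermost peaks use
    -inf/+inf sentinels so that the peak intervals partition the beta
    line.  ``proportion`` is the fraction of non-missing samples whose
    beta falls in ``[left_bound, right_bound)`` (ties on a boundary go
    to the right-hand peak); ``variance`` is the sample variance of
    those betas (0 when fewer than two samples fall inside).
    ``left_density``/``right_density`` record the fitted density at the
    bounding minima (0 for the sentinels) and drive the noise filter.
    """

    apex_beta: float
    apex_density: float
    left_bound: float
    right_bound: float
    proportion: float
    variance: float
    merged_from: int = 1
    left_density: float = 0.0
    right_density: float = 0.0


@dataclass(frozen=True)
class ModalityCall:
    """Final modality classification for one probe."""

    label: str  # "unimodal" | "multimodal"
    peaks: tuple[Peak, ...]
    fallback: bool = False  # True when filtering removed every candidate

    def __post_init__(self) -> None:
        if self.label not in ("unimodal", "multimodal"):
            raise ValueError(f"unknown modality label {self.label!r}")
        if (self.label == "unimodal") != (len(self.peaks) == 1):
            raise ValueError("unimodal iff exactly one peak")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# density estimation


def _drop_missing(betas) -> np.ndarray:
    x = np.asarray(betas, dtype=float).ravel()
    return x[~np.isnan(x)]


def rule_of_thumb_bandwidth(x: np.ndarray) -> float:
    """Silverman-style rule-of-thumb (nrd0) bandwidth.

    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)`` with linear-interpolation
    quartiles; when the IQR is zero the SD takes its place.  Raises
    :class:`DegenerateInputError` when both are zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd
    if lo == 0.0:
        raise DegenerateInputError(
            "all beta values identical: SD and IQR are both zero"
        )
    return 0.9 * lo * n ** (-0.2)


def estimate_density(betas, params: DetectionParams) -> DensityCurve:
    """Gaussian-kernel density estimate of one probe's beta values.

    Missing values are dropped silently; ``n_obs`` on the returned
    curve records the count actually used.  The grid spans
    ``[min - grid_cut*bw, max + grid_cut*bw]`` with ``grid_size``
    equally spaced points.

    Raises
    ------
    TooFewObservationsError
        Fewer than :data:`MIN_OBS` non-missing values.
    DegenerateInputError
        All values identical under the rule-of-thumb bandwidth.
    """
    x = _drop_missing(betas)
    if x.size < MIN_OBS:
        raise TooFewObservationsError(
            f"{x.size} non-missing beta values; at least {MIN_OBS} required"
        )
    if x.max() == x.min():
        # np.std of identical values can be a nonzero rounding residue,
        # so test degeneracy on the range rather than the bandwidth.
        raise DegenerateInputError("all beta values identical")
    if params.bandwidth_rule == "fixed":
        bw = float(params.fixed_bandwidth)
    else:
        bw = rule_of_thumb_bandwidth(x)
    lo = x.min() - params.grid_cut * bw
    hi = x.max() + params.grid_cut * bw
    grid = np.linspace(lo, hi, params.grid_size)
    # Exact Gaussian kernel sum (no FFT binning): mean of N(x_j, bw) pdfs.
    z = (grid[:, None] - x[None, :]) / bw
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * math.sqrt(2.0 * math.pi))
    return DensityCurve(grid=grid, density=density, bandwidth=bw, n_obs=int(x.size))


# ---------------------------------------------------------------------------
# stationary points


def find_stationary_points(curve: DensityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Locate local maxima and minima from first differences.

    The slope is approximated by first differences of the density; the
    logical vector ``slope > 0`` is scanned for switches.  A TRUE→FALSE
    switch marks a maximum, FALSE→TRUE a minimum.  Zero slopes fall on
    the FALSE branch, so a flat-topped peak reports its first plateau
    index.  Returns ``(maxima_indices, minima_indices)``; the two sets
    strictly interleave.
    """
    density = np.asarray(curve.density, dtype=float)
    if density.size < 3:
        raise ValueError("curve must have at least 3 grid points")
    rising = np.diff(density) > 0
    switch = np.flatnonzero(rising[:-1] != rising[1:])
    maxima = switch[rising[switch]] + 1
    minima = switch[~rising[switch]] + 1
    return maxima, minima


# ---------------------------------------------------------------------------
# candidate peaks


def _interval_stats(x_sorted: np.ndarray, bounds: np.ndarray, n_obs: int):
    """Counts and variances of sorted betas partitioned at ``bounds``.

    Intervals are half-open ``[b_i, b_{i+1})`` — a beta exactly on a
    boundary belongs to the right-hand interval — with the outermost
    intervals unbounded.
    """
    idx = np.searchsorted(bounds, x_sorted, side="right")
    n_int = bounds.size + 1
    counts = np.bincount(idx, minlength=n_int)
    variances = np.zeros(n_int)
    start = 0
    for k in range(n_int):
        stop = start + counts[k]
        if counts[k] >= 2:
            variances[k] = float(np.var(x_sorted[start:stop], ddof=1))
        start = stop
    return counts / n_obs, variances


def assign_candidate_peaks(
    curve: DensityCurve,
    maxima: np.ndarray,
    minima: np.ndarray,
    betas,
) -> list[Peak]:
    """Turn detected maxima into candidate peaks with boundaries.

    Each maximum's boundaries are its adjacent minima; the leftmost and
    rightmost peaks use -inf/+inf sentinels, so the candidate peaks
    partition the beta line and their sample proportions sum to one.
    """
    maxima = np.asarray(maxima, dtype=int)
    if maxima.size == 0:
        raise ValueError("no maxima to assign")
    x = np.sort(_drop_missing(betas))
    n_obs = x.size
    # Only minima lying strictly between the first and last maximum bound
    # peaks; interleaving guarantees exactly one per consecutive pair.
    inner = np.asarray(
        [m for m in np.asarray(minima, dtype=int) if maxima[0] < m < maxima[-1]],
        dtype=int,
    )
    if inner.size != maxima.size - 1:
        raise ValueError("maxima and minima do not interleave")
    inner_beta = curve.grid[inner]
    proportions, variances = _interval_stats(x, inner_beta, n_obs)
    bounds = np.concatenate(([-np.inf], inner_beta, [np.inf]))
    bound_density = np.concatenate(([0.0], curve.density[inner], [0.0]))
    peaks = []
    for i, m in enumerate(maxima):
        peaks.append(
            Peak(
                apex_beta=float(curve.grid[m]),
                apex_density=float(curve.density[m]),
                left_bound=float(bounds[i]),
                right_bound=float(bounds[i + 1]),
                proportion=float(proportions[i]),
                variance=float(variances[i]),
                merged_from=1,
                left_density=float(bound_density[i]),
                right_density=float(bound_density[i + 1]),
            )
        )
    return peaks


# ---------------------------------------------------------------------------
# filtering and merging


def filter_noise_peaks(
    peaks: list[Peak], curve: DensityCurve, params: DetectionParams
) -> list[Peak]:
    """Drop candidate peaks that are both small and zero-bounded.

    A peak is noise when its proportion is strictly below
    ``proportion_sample`` *and* at least one bounding minimum has
    density at or below the zero tolerance.  The outermost sentinel
    boundaries count as zero-density minima.  Survivors keep their
    boundaries unchanged.
    """
    tol = curve.zero_tolerance(params)
    return [
        p
        for p in peaks
        if not (
            p.proportion < params.proportion_sample
            and (p.left_density <= tol or p.right_density <= tol)
        )
    ]


def merge_close_peaks(peaks: list[Peak], params: DetectionParams, betas) -> list[Peak]:
    """Merge adjacent peaks whose apexes lie within ``peak_distance``.

    A single left-to-right pass chains consecutive peaks with apex
    separation strictly below ``peak_distance`` into one group (the
    closure is transitive).  The merged peak takes the group member's
    apex with the highest density, the outermost group boundaries, and
    proportion/variance recomputed from the betas inside those
    boundaries; ``merged_from`` records the group size.
    """
    if len(peaks) <= 1:
        return list(peaks)
    x = np.sort(_drop_missing(betas))
    n_obs = x.size
    groups: list[list[Peak]] = [[peaks[0]]]
    for p in peaks[1:]:
        if p.apex_beta - groups[-1][-1].apex_beta < params.peak_distance:
            groups[-1].append(p)
        else:
            groups.append([p])
    merged = []
    for g in groups:
        if len(g) == 1:
            merged.append(g[0])
            continue
        best = max(g, key=lambda p: p.apex_density)
        left, right = g[0].left_bound, g[-1].right_bound
        inside = x[(x >= left) & (x < right)]
        var = float(np.var(inside, ddof=1)) if inside.size >= 2 else 0.0
        merged.append(
            Peak(
                apex_beta=best.apex_beta,
                apex_density=best.apex_density,
                left_bound=left,
                right_bound=right,
                proportion=inside.size / n_obs,
                variance=var,
                merged_from=sum(p.merged_from for p in g),
                left_density=g[0].left_density,
                right_density=g[-1].right_density,
            )
        )
    return merged


def refilter_merged_peaks(peaks: list[Peak], params: DetectionParams) -> list[Peak]:
    """Drop merged peaks whose proportion is strictly below the floor.

    No zero-density condition applies at this stage; a peak sitting
    exactly at ``proportion_sample`` survives.
    """
    return [p for p in peaks if p.proportion >= params.proportion_sample]


# ---------------------------------------------------------------------------
# orchestration


def _whole_line_peak(curve: DensityCurve) -> Peak:
    # Degenerate guard: a monotone-free curve with no detected maximum
    # (possible only for pathological fixed-bandwidth settings).
    m = int(np.argmax(curve.density))
    return Peak(
        apex_beta=float(curve.grid[m]),
        apex_density=float(curve.density[m]),
        left_bound=-np.inf,
        right_bound=np.inf,
        proportion=1.0,
        variance=0.0,
    )


def classify_probe(betas, params: DetectionParams | None = None) -> ModalityCall:
    """Run the full detector on one probe and call its modality.

    Pipeline: density estimation → stationary points → candidate peaks
    (short-circuit to unimodal when only one candidate exists) → noise
    filter → merge → proportion re-filter → label.  If filtering ever
    removes every peak, the largest-proportion candidate is restored and
    the probe is called unimodal with ``fallback=True``.

    Deterministic: a pure function of ``(betas, params)``.
    """
    if params is None:
        params = DetectionParams()
    x = _drop_missing(betas)
    curve = estimate_density(x, params)
    maxima, minima = find_stationary_points(curve)
    if maxima.size == 0:
        return ModalityCall(label="unimodal", peaks=(_whole_line_peak(curve),))
    candidates = assign_candidate_peaks(curve, maxima, minima, x)
    if len(candidates) == 1:
        return ModalityCall(label="unimodal", peaks=tuple(candidates))
    kept = filter_noise_peaks(candidates, curve, params)
    if not kept:
        best = max(candidates, key=lambda p: p.proportion)
        return ModalityCall(label="unimodal", peaks=(best,), fallback=True)
    merged = merge_close_peaks(kept, params, x)
    final = refilter_merged_peaks(merged, params)
    if not final:
        best = max(merged, key=lambda p: p.proportion)
        return ModalityCall(label="unimodal", peaks=(best,), fallback=True)
    label = "unimodal" if len(final) == 1 else "multimodal"
    return ModalityCall(label=label, peaks=tuple(final))
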