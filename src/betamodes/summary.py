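"""Per-probe result records, extreme-methylation flags, and the
secondary-peak confidence filter.

The secondary peak of a multimodal probe is the final peak with the
*second-largest* sample proportion.  A probe whose secondary peak holds
a substantial share of the cohort is unambiguously multimodal; one
whose secondary peak is tiny may be noise.  The post-hoc filter
annotates (never deletes) records below a secondary-proportion cutoff,
and the same quantity ranks probes by confidence in multimodality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detection import (
    DetectionError,
    DetectionParams,
    ModalityCall,
    TooFewObservationsError,
    classify_probe,
    _drop_missing,
)

__all__ = [
    "ProbeResult",
    "summarize_probe",
    "failed_probe_result",
    "flag_methylation_extremes",
    "apply_secondary_peak_filter",
    "rank_by_secondary_proportion",
    "analyze_probe",
]

#: Probe status codes.
STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_obs"
STATUS_DEGENERATE = "degenerate"
STATUS_FALLBACK = "fallback_unimodal"


@dataclass(frozen=True)
class ProbeResult:
    """One output record per probe.

    Peak vectors are ordered by apex location.  ``proportion_sample_2``
    is the second-largest peak proportion (0 for unimodal probes) and
    drives both the post-hoc filter and confidence ranking.
    """

    probe_id: str
    n_obs: int
    mean_beta: float
    var_beta: float
    modality: ModalityCall | None
    peak_locations: tuple[float, ...]
    peak_proportions: tuple[float, ...]
    peak_variances: tuple[float, ...]
    proportion_sample_2: float
    hypo_flag: bool = False
    hyper_flag: bool = False
    passed_secondary_filter: bool = True
    status: str = STATUS_OK

    @property
    def n_peaks(self) -> int:
        return len(self.peak_locations)

    @property
    def is_multimodal(self) -> bool:
        return self.modality is not None and self.modality.label == "multimodal"


def summarize_probe(
    probe_id: str, betas, call: ModalityCall, params: DetectionParams
) -> ProbeResult:
    """Build the output record for one classified probe."""
    x = _drop_missing(betas)
    proportions = [p.proportion for p in call.peaks]
    if call.n_peaks >= 2:
        secondary = float(sorted(proportions, reverse=True)[1])
    else:
        secondary = 0.0
    return ProbeResult(
        probe_id=probe_id,
        n_obs=int(x.size),
        mean_beta=float(np.mean(x)),
        var_beta=float(np.var(x, ddof=1)) if x.size >= 2 else 0.0,
        modality=call,
        peak_locations=tuple(p.apex_beta for p in call.peaks),
        peak_proportions=tuple(proportions),
        peak_variances=tuple(p.variance for p in call.peaks),
        proportion_sample_2=secondary,
        status=STATUS_FALLBACK if call.fallback else STATUS_OK,
    )


def failed_probe_result(probe_id: str, betas, status: str) -> ProbeResult:
    """Error-status record for a probe the detector could not process."""
    x = _drop_missing(betas)
    return ProbeResult(
        probe_id=probe_id,
        n_obs=int(x.size),
        mean_beta=float(np.mean(x)) if x.size else float("nan"),
        var_beta=float(np.var(x, ddof=1)) if x.size >= 2 else 0.0,
        modality=None,
        peak_locations=(),
        peak_proportions=(),
        peak_variances=(),
        proportion_sample_2=0.0,
        status=status,
    )


def flag_methylation_extremes(
    result: ProbeResult, params: DetectionParams
) -> ProbeResult:
    """Set the hypo-/hyper-methylation flags from probe-level mean (and,
    when ``extreme_var_max`` is set, variance)."""
    var_ok = params.extreme_var_max is None or result.var_beta < params.extreme_var_max
    hypo = bool(result.mean_beta < params.hypo_mean_max and var_ok)
    hyper = bool(result.mean_beta > params.hyper_mean_min and var_ok)
    return replace(result, hypo_flag=hypo, hyper_flag=hyper)


def apply_secondary_peak_filter(
    results: list[ProbeResult], min_secondary: float
) -> list[ProbeResult]:
    """Annotate multimodal records whose secondary peak is too small.

    Records are never deleted here — ``passed_secondary_filter`` is set
    to False when a multimodal probe's secondary proportion falls
    strictly below ``min_secondary``; unimodal records always pass.
    The exclusion decision itself is left to the investigator.
    """
    out = []
    for r in results:
        fails = r.is_multimodal and r.proportion_sample_2 < min_secondary
        out.append(replace(r, passed_secondary_filter=not fails))
    return out


def rank_by_secondary_proportion(results: list[ProbeResult]) -> list[ProbeResult]:
    """Order records by confidence in multimodality.

    Multimodal records first, sorted by secondary-peak proportion
    descending (ties broken by probe ID); unimodal and error records
    follow, by probe ID.
    """
    multi = [r for r in results if r.is_multimodal]
    rest = [r for r in results if not r.is_multimodal]
    multi.sort(key=lambda r: (-r.proportion_sample_2, r.probe_id))
    rest.sort(key=lambda r: r.probe_id)
    return multi + rest


def analyze_probe(probe_id: str, betas, params: DetectionParams) -> ProbeResult:
    """Classify, summarize and flag one probe, mapping detection errors
    to status rows instead of raising."""
    try:
        call = classify_probe(betas, params)
    except TooFewObservationsError:
        return failed_probe_result(probe_id, betas, STATUS_TOO_FEW)
    except DetectionError:
        return failed_probe_result(probe_id, betas, STATUS_DEGENERATE)
    result = summarize_probe(probe_id, betas, call, params)
    return flag_methylation_extremes(result, params)
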