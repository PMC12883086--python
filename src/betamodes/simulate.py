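"""Synthetic beta matrices with known modality truth.

Methylation arrays show three recurring per-probe shapes: a single
tight cluster (most probes), the three genotype clusters produced by a
SNP at the CpG site — with Hardy–Weinberg weights (1-q)^2, 2q(1-q),
q^2 for minor allele frequency q — and subtler two-cluster patterns of
the kind mQTLs produce.  This module simulates all three as beta
mixtures: each sample draws a component by weight, then a beta value
from a (mean, precision)-parameterized Beta distribution, giving the
tight, bounded clusters real arrays show.

Every probe's stream is seeded deterministically from a master seed
plus the probe index, so a fixture is byte-identical across runs and
any single probe can be replayed from its recorded seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = [
    "ProbeSpec",
    "simulate_probe",
    "generate_fixture_dataset",
    "DEFAULT_PRECISION",
    "DEFAULT_TRIMODAL_MEANS",
    "DEFAULT_BIMODAL_MEANS",
    "DEFAULT_BIMODAL_WEIGHTS",
]

#: Default per-component concentration; at mean 0.5 this gives a
#: within-cluster SD of ~0.05, tightening toward the boundaries
#: (~0.02 at mean 0.05) like real genotype clusters.
DEFAULT_PRECISION = 100.0

#: Genotype cluster means for a SNP at the CpG site.
DEFAULT_TRIMODAL_MEANS = (0.05, 0.50, 0.95)

#: Subtle mQTL-style pattern: close components, small minor weight,
#: exercising the merge/noise-filter path.
DEFAULT_BIMODAL_MEANS = (0.30, 0.55)
DEFAULT_BIMODAL_WEIGHTS = (0.90, 0.10)

_CLAMP = 1e-6


@dataclass(frozen=True)
class ProbeSpec:
    """Generative description of one probe.

    ``component_means`` must be strictly increasing in (0, 1);
    ``component_weights`` nonnegative and summing to 1.  ``precision``
    is the Beta concentration per component (scalar broadcast or one
    value per component); cluster SD is
    ``sqrt(m*(1-m)/(precision+1))``.  ``maf`` is recorded for
    SNP-trimodal probes, whose weights are the Hardy–Weinberg triple.
    """

    probe_id: str
    kind: str  # unimodal | bimodal | snp_trimodal
    component_means: tuple[float, ...]
    component_weights: tuple[float, ...]
    precision: tuple[float, ...] = ()
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("unimodal", "bimodal", "snp_trimodal"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        means = np.asarray(self.component_means, dtype=float)
        weights = np.asarray(self.component_weights, dtype=float)
        if means.size != weights.size or means.size == 0:
            raise ValueError("means and weights must match and be nonempty")
        if not np.all((means > 0) & (means < 1)):
            raise ValueError("component means must lie strictly in (0, 1)")
        if not np.all(np.diff(means) > 0):
            raise ValueError("component means must be strictly increasing")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")
        prec = self.precision or (DEFAULT_PRECISION,) * means.size
        if len(prec) == 1:
            prec = prec * means.size
        if len(prec) != means.size or any(p <= 0 for p in prec):
            raise ValueError("precision must be positive, one per component")
        object.__setattr__(self, "precision", tuple(float(p) for p in prec))
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if self.kind == "snp_trimodal":
            if self.maf is None:
                raise ValueError("snp_trimodal requires maf")
            q = self.maf
            hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
            if not np.allclose(weights, hwe, atol=1e-12):
                raise ValueError("snp_trimodal weights must be the HWE triple")

    # -- constructors -------------------------------------------------

    @classmethod
    def unimodal(
        cls, probe_id: str, mean: float = 0.5, precision: float = DEFAULT_PRECISION
    ) -> "ProbeSpec":
        return cls(probe_id, "unimodal", (mean,), (1.0,), (precision,))

    @classmethod
    def bimodal(
        cls,
        probe_id: str,
        means: tuple[float, float] = DEFAULT_BIMODAL_MEANS,
        weights: tuple[float, float] = DEFAULT_BIMODAL_WEIGHTS,
        precision: float = DEFAULT_PRECISION,
    ) -> "ProbeSpec":
        return cls(probe_id, "bimodal", tuple(means), tuple(weights), (precision,))

    @classmethod
    def snp_trimodal(
        cls,
        probe_id: str,
        maf: float,
        means: tuple[float, float, float] = DEFAULT_TRIMODAL_MEANS,
        precision: float = DEFAULT_PRECISION,
    ) -> "ProbeSpec":
        """Three genotype clusters under Hardy–Weinberg equilibrium.

        Means are ordered (major-homozygote, heterozygote,
        minor-homozygote); ``maf=0`` collapses to a single occupied
        component and is recorded as truly unimodal.
        """
        q = float(maf)
        weights = ((1 - q) ** 2, 2 * q * (1 - q), q * q)
        kind = "unimodal" if q == 0.0 else "snp_trimodal"
        if kind == "unimodal":
            return cls(probe_id, kind, (means[0],), (1.0,), (precision,))
        return cls(probe_id, kind, tuple(means), weights, (precision,), maf=q)


def probe_seed(master_seed: int, probe_index: int) -> int:
    """Deterministic 31-bit per-probe seed from (master seed, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(probe_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_probe(spec: ProbeSpec, n_samples: int, seed: int) -> np.ndarray:
    """Draw one probe's beta vector from its mixture spec.

    Each sample picks a component by weight, then draws
    ``Beta(m*k, (1-m)*k)`` for that component's mean ``m`` and
    precision ``k``; values are clamped to ``[1e-6, 1-1e-6]``.
    Reproducible given the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    means = np.asarray(spec.component_means)
    prec = np.asarray(spec.precision)
    comp = rng.choice(means.size, size=n_samples, p=np.asarray(spec.component_weights))
    a = means[comp] * prec[comp]
    b = (1.0 - means[comp]) * prec[comp]
    betas = rng.beta(a, b)
    return np.clip(betas, _CLAMP, 1.0 - _CLAMP)


def generate_fixture_dataset(
    n_unimodal: int = 50,
    n_bimodal: int = 25,
    n_trimodal: int = 25,
    n_samples: int = 500,
    seed: int = 1234,
    unimodal_mean_range: tuple[float, float] = (0.15, 0.85),
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Generate a labelled beta matrix for pipeline testing.

    Probe order is unimodal, then bimodal, then SNP-trimodal.
    Unimodal cluster means are drawn uniformly from
    ``unimodal_mean_range`` and trimodal minor allele frequencies from
    ``maf_range``; both draws and every probe's data stream derive
    deterministically from ``seed``.  Returns the matrix and a truth
    table (one row per probe: probe_id, kind, means, weights, maf,
    seed) that allows exact replay of any probe.
    """
    total = n_unimodal + n_bimodal + n_trimodal
    if min(n_unimodal, n_bimodal, n_trimodal) < 0 or total == 0:
        raise ValueError("probe counts must be nonnegative with at least one probe")
    param_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A]))
    specs: list[ProbeSpec] = []
    for i in range(total):
        pid = f"cg{i:08d}"
        if i < n_unimodal:
            mean = float(param_rng.uniform(*unimodal_mean_range))
            specs.append(ProbeSpec.unimodal(pid, mean=mean))
        elif i < n_unimodal + n_bimodal:
            param_rng.uniform()  # keep the parameter stream aligned per probe
            specs.append(ProbeSpec.bimodal(pid))
        else:
            maf = float(param_rng.uniform(*maf_range))
            specs.append(ProbeSpec.snp_trimodal(pid, maf=maf))
    values = np.empty((total, n_samples))
    truth_rows = []
    for i, spec in enumerate(specs):
        s = probe_seed(seed, i)
        values[i] = simulate_probe(spec, n_samples, s)
        truth_rows.append(
            {
                "probe_id": spec.probe_id,
                "kind": spec.kind,
                "component_means": ";".join(f"{m:.6f}" for m in spec.component_means),
                "component_weights": ";".join(
                    f"{w:.6f}" for w in spec.component_weights
                ),
                "maf": spec.maf if spec.maf is not None else "",
                "seed": s,
            }
        )
    matrix = BetaMatrix(
        probe_ids=[s.probe_id for s in specs],
        sample_ids=[f"sample_{j:04d}" for j in range(n_samples)],
        values=values,
    )
    return matrix, pd.DataFrame(truth_rows)
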