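"""Monte Carlo propagation of measurement noise.

Two stages, mirroring the manual workflow:

1. **Classical parameters.**  The corrected spectrum is cloned many times;
   each clone perturbs every ordinate by a normal draw whose standard
   deviation is ``sqrt(|y|)`` (the Poisson-counting noise model customary in
   EPR, extended with an absolute value because derivative ordinates are
   signed), optionally floored by a constant.  (App, DeltaBpp, Bres) are
   re-extracted from every clone, giving empirical distributions whose
   normality is reported — never enforced.
2. **R10.**  Parameter triples are drawn from independent normals with the
   means and standard deviations found in stage 1, and R10 is recomputed on
   the *fixed* corrected spectrum for each draw.  The spread of the resulting
   R10 samples is the propagated uncertainty.

Everything is reproducible bit-for-bit from ``MCConfig.seed``; the input
spectrum is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
from scipy import stats

from .errors import MonteCarloError
from .preprocessing import ClassicalParams, extract_classical_params
from .r10 import DEFAULT_X_LIMIT, r10_spectrum
from .errors import EPRShapeError
from .spectra_io import Spectrum

__all__ = [
    "MCConfig",
    "ParamDistributions",
    "R10Distribution",
    "NormalitySummary",
    "perturb_spectrum",
    "mc_classical_params",
    "mc_r10",
    "normality_summary",
]

# fixed sub-stream tag so parameter draws never reuse clone-noise streams
_R10_STREAM = 104_729


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: iteration count, seed, optional noise floor."""

    n_iterations: int = 1000
    seed: int = 0
    noise_floor: float = 0.0

    def __post_init__(self):
        if self.n_iterations < 2:
            raise MonteCarloError(
                f"n_iterations must be >= 2, got {self.n_iterations}"
            )
        if self.noise_floor < 0:
            raise MonteCarloError(
                f"noise_floor must be >= 0, got {self.noise_floor}"
            )


@dataclass(frozen=True)
class NormalitySummary:
    """D'Agostino-Pearson normality check plus histogram-ready counts."""

    statistic: Optional[float]
    pvalue: Optional[float]
    bin_edges: np.ndarray
    counts: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class ParamDistributions:
    """MC samples and summaries of the three classical parameters."""

    samples_App: np.ndarray
    samples_DeltaBpp: np.ndarray
    samples_Bres: np.ndarray
    mean_App: float
    sd_App: float
    mean_DeltaBpp: float
    sd_DeltaBpp: float
    mean_Bres: float
    sd_Bres: float
    normality: Dict[str, Optional[NormalitySummary]] = field(default_factory=dict)


@dataclass(frozen=True)
class R10Distribution:
    """MC samples of R10 under parameter uncertainty."""

    samples: np.ndarray
    mean: float
    sd: float
    source_params: ParamDistributions
    n_rejected: int = 0


def perturb_spectrum(spectrum: Spectrum, config: MCConfig, draw_index: int) -> Spectrum:
    """One noisy clone: ordinates -> N(y_i, max(sqrt(|y_i|), noise_floor)).

    Reproducible given ``(config.seed, draw_index)``; the field axis and the
    original spectrum are untouched.
    """
    rng = np.random.default_rng([int(config.seed), int(draw_index)])
    sd = np.maximum(np.sqrt(np.abs(spectrum.intensity)), config.noise_floor)
    return replace(spectrum, intensity=rng.normal(spectrum.intensity, sd))


def normality_summary(samples, bins: str | int = "auto") -> NormalitySummary:
    """Normality statistic, p-value and binned counts for one sample set.

    Interpretation is left to the caller: the pipeline proceeds whatever the
    p-value, it only surfaces it.  Constant samples are flagged degenerate
    (no test is defined for them).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 20:
        raise MonteCarloError(
            f"normality check needs >= 20 samples, got {samples.size}"
        )
    if np.ptp(samples) == 0.0:
        edges = np.array([samples[0] - 0.5, samples[0] + 0.5])
        return NormalitySummary(
            statistic=None,
            pvalue=None,
            bin_edges=edges,
            counts=np.array([samples.size]),
            degenerate=True,
        )
    stat, pval = stats.normaltest(samples)
    counts, edges = np.histogram(samples, bins=bins)
    return NormalitySummary(
        statistic=float(stat), pvalue=float(pval), bin_edges=edges, counts=counts
    )


def mc_classical_params(spectrum: Spectrum, config: MCConfig) -> ParamDistributions:
    """Distributions of (App, DeltaBpp, Bres) over noisy clones.

    Clones whose extraction fails (noise destroyed the derivative-line
    structure) are redrawn with fresh draw indices so the sample count always
    equals ``n_iterations``; once failures exceed 10% of ``n_iterations`` the
    spectrum is deemed too noisy for this pipeline and an error is raised.
    """
    if not spectrum.baseline_corrected:
        raise MonteCarloError("Monte Carlo runs on the baseline-corrected spectrum")
    n = config.n_iterations
    max_failures = int(np.ceil(0.1 * n))
    apps, widths, centers = [], [], []
    failures = 0
    draw_index = 0
    while len(apps) < n:
        clone = perturb_spectrum(spectrum, config, draw_index)
        draw_index += 1
        try:
            p = extract_classical_params(clone)
        except EPRShapeError:
            failures += 1
            if failures > max_failures:
                raise MonteCarloError(
                    f"parameter extraction failed on {failures} clones "
                    f"(> 10% of {n}): spectrum too noisy for this pipeline"
                )
            continue
        apps.append(p.App)
        widths.append(p.DeltaBpp)
        centers.append(p.Bres)
    apps = np.array(apps)
    widths = np.array(widths)
    centers = np.array(centers)
    normality: Dict[str, Optional[NormalitySummary]] = {}
    for name, arr in (("App", apps), ("DeltaBpp", widths), ("Bres", centers)):
        normality[name] = normality_summary(arr) if n >= 20 else None
    return ParamDistributions(
        samples_App=apps,
        samples_DeltaBpp=widths,
        samples_Bres=centers,
        mean_App=float(apps.mean()),
        sd_App=float(apps.std(ddof=1)),
        mean_DeltaBpp=float(widths.mean()),
        sd_DeltaBpp=float(widths.std(ddof=1)),
        mean_Bres=float(centers.mean()),
        sd_Bres=float(centers.std(ddof=1)),
        normality=normality,
    )


def mc_r10(
    spectrum: Spectrum,
    params: ClassicalParams,
    dists: ParamDistributions,
    config: MCConfig,
    x_limit: float = DEFAULT_X_LIMIT,
) -> R10Distribution:
    """Distribution of R10 under the classical-parameter uncertainty.

    Each iteration draws (App', DeltaBpp', Bres') from independent normals
    with the means/sds of ``dists`` and recomputes R10 on the fixed corrected
    spectrum.  Draws on which the transform is undefined (e.g. a non-positive
    width) are rejected and redrawn, with a hard cap of 10 * n_iterations
    total attempts.
    """
    if not spectrum.baseline_corrected:
        raise MonteCarloError("Monte Carlo runs on the baseline-corrected spectrum")
    rng = np.random.default_rng([int(config.seed), _R10_STREAM])
    n = config.n_iterations
    samples = []
    attempts = 0
    rejected = 0
    while len(samples) < n:
        if attempts >= 10 * n:
            raise MonteCarloError(
                f"R10 Monte Carlo rejected {rejected} of {attempts} draws; "
                "parameter distributions are incompatible with the spectrum"
            )
        attempts += 1
        app = rng.normal(dists.mean_App, dists.sd_App)
        width = rng.normal(dists.mean_DeltaBpp, dists.sd_DeltaBpp)
        center = rng.normal(dists.mean_Bres, dists.sd_Bres)
        try:
            drawn = ClassicalParams(App=app, DeltaBpp=width, Bres=center)
            samples.append(r10_spectrum(spectrum, drawn, x_limit).r10)
        except EPRShapeError:
            rejected += 1
            continue
    samples = np.array(samples)
    return R10Distribution(
        samples=samples,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
        source_params=dists,
        n_rejected=rejected,
    )
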