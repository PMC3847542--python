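"""End-to-end pipeline: read -> baseline -> params -> R10 -> Monte Carlo."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

from . import __version__
from .errors import EPRShapeError, PipelineError
from .montecarlo import MCConfig, mc_classical_params, mc_r10
from .preprocessing import (
    ClassicalParams,
    correct_baseline,
    extract_classical_params,
    fit_baseline,
)
from .r10 import DEFAULT_X_LIMIT, R10Result, r10_spectrum
from .spectra_io import read_spectrum

__all__ = ["RunReport", "MCSummary", "run_full_pipeline"]

log = logging.getLogger("eprshape")


@dataclass(frozen=True)
class MCSummary:
    """Scalar summaries of the Monte Carlo distributions."""

    n_iterations: int
    mean_App: float
    sd_App: float
    mean_DeltaBpp: float
    sd_DeltaBpp: float
    mean_Bres: float
    sd_Bres: float
    normality_pvalues: Tuple[Optional[float], Optional[float], Optional[float]]
    r10_mean: float
    r10_sd: float


@dataclass(frozen=True)
class RunReport:
    """Everything one pipeline run produced; serializes losslessly to JSON."""

    input_path: str
    baseline_coefficients: Tuple[float, float, float, float]
    tail_fraction: float
    params: ClassicalParams
    r10: R10Result
    mc: Optional[MCSummary]
    version: str
    seed: Optional[int]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        d = dict(d)
        d["baseline_coefficients"] = tuple(d["baseline_coefficients"])
        d["params"] = ClassicalParams(**d["params"])
        d["r10"] = R10Result(**d["r10"])
        if d["mc"] is not None:
            mc = dict(d["mc"])
            mc["normality_pvalues"] = tuple(mc["normality_pvalues"])
            d["mc"] = MCSummary(**mc)
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, EPRShapeError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_full_pipeline(
    path,
    config: Optional[MCConfig] = None,
    tail_fraction: float = 0.10,
    x_limit: float = DEFAULT_X_LIMIT,
) -> RunReport:
    """Run the stages in order and collect every intermediate result.

    ``config=None`` skips the Monte Carlo stages (point estimates only).
    Stage failures surface as :class:`PipelineError` naming the stage; a
    report is only returned when the whole pipeline completed.
    """
    with _stage("spectra_io"):
        raw = read_spectrum(path)
    with _stage("baseline"):
        model = fit_baseline(raw, tail_fraction)
        corrected = correct_baseline(raw, model)
    with _stage("classical_params"):
        params = extract_classical_params(corrected)
    with _stage("r10"):
        result = r10_spectrum(corrected, params, x_limit)
    mc_summary = None
    if config is not None:
        with _stage("montecarlo"):
            dists = mc_classical_params(corrected, config)
            r10_dist = mc_r10(corrected, params, dists, config, x_limit)
        pvals = tuple(
            (dists.normality[k].pvalue if dists.normality.get(k) else None)
            for k in ("App", "DeltaBpp", "Bres")
        )
        mc_summary = MCSummary(
            n_iterations=config.n_iterations,
            mean_App=dists.mean_App,
            sd_App=dists.sd_App,
            mean_DeltaBpp=dists.mean_DeltaBpp,
            sd_DeltaBpp=dists.sd_DeltaBpp,
            mean_Bres=dists.mean_Bres,
            sd_Bres=dists.sd_Bres,
            normality_pvalues=pvals,
            r10_mean=r10_dist.mean,
            r10_sd=r10_dist.sd,
        )
    return RunReport(
        input_path=str(path),
        baseline_coefficients=tuple(model.coefficients),
        tail_fraction=float(tail_fraction),
        params=params,
        r10=result,
        mc=mc_summary,
        version=__version__,
        seed=None if config is None else config.seed,
    )
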