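"""Configuration and the reproducible simulate→fit→report pipeline.

A single YAML file configures every stage; unknown keys are rejected up
front so that typos fail before any stage runs.  Each run writes its
artifacts together with a manifest carrying the seed, a hash of the
resolved configuration, stage timings and flag counts — identical
config + seed reproduces byte-identical numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .binding import fit_binding
from .loading import LoadingSystem, load as solve_loading
from .spectra import pick_peak, second_derivative
from .synthetic import (
    SpectrumGroundTruth,
    TitrationGroundTruth,
    UptakeGroundTruth,
    generate_spectrum_series,
    generate_titration,
    generate_uptake,
)
from .uptake import enhancement_percent, mass_balance, retention_ratio, summarize

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("mannoload")


class PipelineError(RuntimeError):
    """A stage failed; carries a machine-readable error record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


@dataclass(frozen=True)
class LoadingSpec:
    neg_lg_kd: float
    n_sites: float
    c_ligand: float = 1e-4
    c_drug: float = 1e-3
    m_drug: float = 401.4
    m_ligand: float = 2100.0
    label: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the full pipeline."""

    seed: int = 0
    outdir: str = "mannoload_out"
    # spectral analytical signal: native or second_derivative spectra,
    # read out as peak intensity or peak position
    signal_kind: str = "second_derivative"
    signal_readout: str = "intensity"
    peak_region: tuple[float, float] = (1600.0, 1700.0)
    # Hill fit options
    clip: tuple[float, float] = (0.01, 0.99)
    # stage inputs
    titration: TitrationGroundTruth = field(default_factory=TitrationGroundTruth)
    spectra: SpectrumGroundTruth = field(default_factory=SpectrumGroundTruth)
    uptake: UptakeGroundTruth = field(default_factory=UptakeGroundTruth)
    loading: tuple[LoadingSpec, ...] = ()
    uptake_balance_tol: float = 0.10

    def __post_init__(self) -> None:
        if self.signal_kind not in ("native", "second_derivative"):
            raise ValueError("signal_kind must be 'native' or 'second_derivative'")
        if self.signal_readout not in ("intensity", "position"):
            raise ValueError("signal_readout must be 'intensity' or 'position'")

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, raw: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**raw)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    for key, cls in (
        ("titration", TitrationGroundTruth),
        ("spectra", SpectrumGroundTruth),
        ("uptake", UptakeGroundTruth),
    ):
        if key in raw:
            raw[key] = _build(cls, dict(raw[key]), key)
    if "loading" in raw:
        raw["loading"] = tuple(
            _build(LoadingSpec, dict(item), f"loading[{i}]")
            for i, item in enumerate(raw["loading"])
        )
    for tup_key in ("peak_region", "clip"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    return _build(PipelineConfig, raw, "config")


def _reseed(gt, seed: int):
    return dataclasses.replace(gt, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate → preprocess → fit → load-calc → uptake-report.

    Returns the report bundle (also written to <outdir>/report.json).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            report["stages"][name] = {
                "elapsed_s": round(time.perf_counter() - t0, 4),
                **result,
            }
            log.info("stage %s done in %.3fs", name, report["stages"][name]["elapsed_s"])
            return result

        return wrap

    @stage("simulate_titration")
    def _sim_titr():
        series = generate_titration(_reseed(config.titration, config.seed))
        mio.write_titration_csv(series, outdir / "titration.csv")
        return {"points": len(series)}

    @stage("simulate_spectra")
    def _sim_spec():
        thetas = np.linspace(0.0, 1.0, 10)
        spectra = generate_spectrum_series(
            _reseed(config.spectra, config.seed + 1), thetas
        )
        mio.write_spectrum_series_csv(
            spectra, outdir / "spectra.csv",
            labels=[f"theta_{t:.2f}" for t in thetas],
        )
        return {"levels": len(spectra)}

    @stage("preprocess")
    def _preprocess():
        spectra = mio.read_spectrum_series_csv(outdir / "spectra.csv")
        readings = []
        flagged = 0
        for s in spectra:
            if config.signal_kind == "second_derivative":
                s = second_derivative(s)
                kind = "minimum"  # absorption maxima are d2 minima
            else:
                kind = "maximum"
            peak = pick_peak(s, config.peak_region, kind)
            flagged += int(peak.on_boundary)
            readings.append(
                peak.intensity if config.signal_readout == "intensity"
                else peak.position
            )
        (outdir / "xi_series.json").write_text(
            json.dumps({"xi": readings}, indent=1)
        )
        return {"readings": len(readings), "boundary_flags": flagged}

    @stage("fit_binding")
    def _fit():
        series = mio.read_titration_csv(outdir / "titration.csv")
        res = fit_binding(series, clip=config.clip)
        rec = {
            "n": res.n, "neg_lg_Kd": res.neg_lg_Kd,
            "stderr_n": res.stderr_n, "stderr_neg_lg_Kd": res.stderr_neg_lg_Kd,
            "r_squared": res.r_squared, "points_used": res.points_used,
            "transition_bracketed": res.transition_bracketed,
        }
        (outdir / "binding_fit.json").write_text(json.dumps(rec, indent=1))
        return rec

    @stage("load_calc")
    def _load():
        rows = []
        for specn in config.loading:
            sys = LoadingSystem.from_neg_lg_kd(
                specn.neg_lg_kd, N=specn.n_sites,
                c_ligand_total=specn.c_ligand, c_drug_total=specn.c_drug,
                m_drug=specn.m_drug, m_ligand=specn.m_ligand,
            )
            res = solve_loading(sys)
            rows.append(
                {"label": specn.label, "neg_lg_kd": specn.neg_lg_kd,
                 "N": specn.n_sites, "c_bound_M": res.c_bound,
                 "ee_percent": res.ee_percent, "lc_percent": res.lc_percent}
            )
        (outdir / "loading.json").write_text(json.dumps(rows, indent=1))
        return {"systems": len(rows), "rows": rows}

    @stage("uptake_report")
    def _uptake():
        control = generate_uptake(config.uptake, with_adjuvant=False)
        treated = generate_uptake(config.uptake, with_adjuvant=True)
        mio.write_uptake_csv(control, outdir / "uptake_control.csv")
        mio.write_uptake_csv(treated, outdir / "uptake_adjuvant.csv")
        analyte = control.analytes[0]
        stats_c = summarize(control, analyte, tol=config.uptake_balance_tol)
        stats_t = summarize(treated, analyte, tol=config.uptake_balance_tol)
        flags = int(
            mass_balance(control, analyte, config.uptake_balance_tol)["flagged"].sum()
            + mass_balance(treated, analyte, config.uptake_balance_tol)["flagged"].sum()
        )
        rr = retention_ratio(treated, control, analyte)
        rec = {
            "peak_control": stats_c.peak_absorbed,
            "peak_control_time_min": stats_c.peak_time_min,
            "peak_adjuvant": stats_t.peak_absorbed,
            "peak_adjuvant_time_min": stats_t.peak_time_min,
            "enhancement_percent": enhancement_percent(treated, control, analyte),
            "retention_ratio_final": float(rr["ratio"].iloc[-1]),
            "balance_flags": flags,
        }
        (outdir / "uptake_report.json").write_text(json.dumps(rec, indent=1))
        return rec

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
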