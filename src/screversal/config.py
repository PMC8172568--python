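"""Pipeline configuration: YAML with nested sections, strictly validated.

Unknown keys are an error (listed explicitly), so a typo in a threshold
never silently falls back to a default. The parsed object echoes every
effective value into the run manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .preprocess import QCThresholds
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config", "demo_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with the study defaults.

    The fixed analysis constants (3000 HVGs, 30 PCs, SNN k=20, clustering
    resolution 1.4, DEG threshold q < 0.05, top-500 fold-change ranking,
    24 bins / 100 controls for signature scoring) live here and are echoed
    into the run manifest of every run.
    """

    seed: int = 0
    outdir: str = "screversal_out"
    simulation: SimulationConfig | None = None
    input: dict | None = None  # matrix/genes/barcodes/metadata paths
    qc: QCThresholds = field(default_factory=QCThresholds)
    mito_prefix: str = "mt-"
    n_hvg: int = 3000
    n_pcs: int = 30
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolution: float = 1.4
    alpha: float = 0.05
    min_detection_fraction: float = 0.1
    min_abs_lnfc_prefilter: float = 0.0
    de_covariates: tuple = ()
    rank_limit: int = 500
    marker_gmt: str | None = None
    z_threshold: float = 0.5
    signature_gmt: str | None = None
    score_cell_type: str | None = None
    nbins: int = 24
    nctrl: int = 100
    enrich_gmt: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.input is None:
            raise ConfigError("config needs either a 'simulation' or an 'input' section")
        if self.simulation is not None and self.input is not None:
            raise ConfigError("'simulation' and 'input' sections are exclusive")
        if self.input is not None:
            required = {"matrix", "genes", "barcodes", "metadata"}
            missing = required - set(self.input)
            if missing:
                raise ConfigError(f"input section missing keys: {sorted(missing)}")
            unknown = set(self.input) - required
            if unknown:
                raise ConfigError(f"unknown input keys: {sorted(unknown)}")

    def manifest_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["simulation"] = asdict(self.simulation) if self.simulation else None
        return d


def _check_unknown(section: dict, allowed, where: str) -> None:
    unknown = sorted(set(section) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {unknown}")


def load_config(path=None, data: dict | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or a raw mapping.

    ``overrides`` (e.g. CLI --seed/--outdir) replace top-level values.
    """
    if data is None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    data = dict(data)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    top_allowed = {f.name for f in fields(PipelineConfig)}
    _check_unknown(data, top_allowed, "config")

    sim = data.get("simulation")
    if sim is not None and not isinstance(sim, SimulationConfig):
        sim_allowed = {f.name for f in fields(SimulationConfig)}
        _check_unknown(sim, sim_allowed, "simulation section")
        if "groups" in sim:
            sim["groups"] = tuple(sim["groups"])
        if "rho" in sim and isinstance(sim["rho"], list):
            sim["rho"] = tuple(sim["rho"])
        sim = SimulationConfig(**sim)
    qc = data.get("qc", {})
    if not isinstance(qc, QCThresholds):
        qc_allowed = {f.name for f in fields(QCThresholds)}
        _check_unknown(qc, qc_allowed, "qc section")
        qc = QCThresholds(**qc)
    kwargs = {
        k: v for k, v in data.items() if k not in ("simulation", "qc")
    }
    if "de_covariates" in kwargs and kwargs["de_covariates"] is not None:
        kwargs["de_covariates"] = tuple(kwargs["de_covariates"])
    return PipelineConfig(simulation=sim, qc=qc, **kwargs)


def demo_config(seed: int = 0, outdir: str = "demo_out") -> PipelineConfig:
    """Small self-contained demo: simulated data, full pipeline, minutes of CPU.

    Two cell types — one with strong treatment reversal (rho = 0.8) and one
    untreated-control-like type with rho = 0 — so the output shows the
    reversed-vs-flat contrast side by side.
    """
    sim = SimulationConfig(
        n_genes=700,
        n_cell_types=2,
        cells_per_sample_per_type=50,
        samples_per_group=3,
        groups=("young", "aged", "treated"),
        f_de=0.12,
        rho=(0.8, 0.0),
        p_rev=0.9,
        signature_size=40,
        signature_shift_ln=0.5,
        seed=seed,
    )
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        simulation=sim,
        n_hvg=300,
        n_pcs=20,
        snn_k=15,
    )
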