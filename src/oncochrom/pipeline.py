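"""End-to-end orchestration: synthetic (or file-based) inputs through domain
calling, clustering, dependency-model fitting, expression integration and
ploidy estimation, emitting one machine-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, dependency_model, domain_calling, expression, ploidy
from .errors import ConfigurationError, StageError, ValidationError
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate_dataset, read_assembly_tsv
from .track_io import read_bedgraph, rebin, smooth

log = logging.getLogger("oncochrom")

STAGES = ("domains", "clustering", "fit", "integration", "ploidy")


@dataclass(frozen=True)
class StageParams:
    tau: float = 0.0
    min_domain_bins: int = 5
    max_gap_bins: int = 2
    smooth_window: int = 5
    cluster_bin_size: int = 10_000
    cluster_k: int = 6
    degree: int = 7
    body_slots: int = 100
    flank_bp: int = 500
    n_permutations: int = 999
    pseudocount: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # synthetic | files
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    paths: dict = field(default_factory=dict)  # file mode: assembly/wt/onco/mut/genes/dapi
    stages: tuple[str, ...] = STAGES
    params: StageParams = field(default_factory=StageParams)
    bin_size: int = 1_000  # file mode grid

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.mode == "files":
            required = {"assembly", "wt", "onco", "mut"}
            missing = required - set(self.paths)
            if missing:
                raise ConfigurationError(f"file mode needs paths for {sorted(missing)}")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(f"path for {key!r} does not exist: {p}")

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["stages"] = list(self.stages)
        d["paths"] = {k: str(v) for k, v in self.paths.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(d.get("synthetic"), dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if isinstance(d.get("params"), dict):
            punknown = set(d["params"]) - {f.name for f in dataclasses.fields(StageParams)}
            if punknown:
                raise ConfigurationError(f"unknown stage parameters: {sorted(punknown)}")
            d["params"] = StageParams(**d["params"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _load_inputs(config: RunConfig) -> SyntheticDataset | dict:
    if config.mode == "synthetic":
        return generate_dataset(config.synthetic)
    assembly = read_assembly_tsv(config.paths["assembly"])
    data = {
        "assembly": assembly,
        "wt": read_bedgraph(config.paths["wt"], assembly, config.bin_size, state="logratio"),
        "onco": read_bedgraph(config.paths["onco"], assembly, config.bin_size, state="logratio"),
        "mut": read_bedgraph(config.paths["mut"], assembly, config.bin_size, state="logratio"),
        "genes": pd.read_csv(config.paths["genes"], sep="\t") if "genes" in config.paths else None,
        "dapi": pd.read_csv(config.paths["dapi"], sep="\t") if "dapi" in config.paths else None,
    }
    return data


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the report.

    Identical config (seed included) gives an identical report; timestamps are
    deliberately excluded. Stage failures abort the run, naming the stage.
    """
    p = config.params
    report: dict = {
        "seed": config.seed,
        "config_hash": config.synthetic.config_hash(),
        "versions": {
            "oncochrom": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    inputs = _load_inputs(config)
    if isinstance(inputs, SyntheticDataset):
        wt, onco, mut = inputs.wt_k27me3, inputs.oncohistone, inputs.mut_k27me3
        genes, dapi = inputs.genes, inputs.dapi
    else:
        wt, onco, mut = inputs["wt"], inputs["onco"], inputs["mut"]
        genes, dapi = inputs["genes"], inputs["dapi"]
    report["stages"]["synthetic"] = {
        "n_bins": wt.total_bins,
        "bin_size": wt.bin_size,
        "chromosomes": [
            {"name": c.name, "length": c.length, "chrom_class": c.chrom_class}
            for c in wt.assembly
        ],
    }
    log.info("inputs: %d bins at %d bp over %d chromosomes",
             wt.total_bins, wt.bin_size, len(wt.assembly.chromosomes))

    if "domains" in config.stages:
        try:
            wt_s = smooth(wt, p.smooth_window)
            mut_s = smooth(mut, p.smooth_window)
            domains = domain_calling.call_domains(
                wt_s, mut_s, tau=p.tau,
                min_domain_bins=p.min_domain_bins, max_gap_bins=p.max_gap_bins,
            )
            summary = domain_calling.domain_summary(
                {"wt_k27me3": wt, "oncohistone": onco, "mut_k27me3": mut}, domains
            )
            report["stages"]["domains"] = {
                "counts": domains.category_counts(),
                "summary": summary.to_dict(orient="records"),
            }
            log.info("domains: %d intervals over %d bins",
                     len(domains.intervals), domains.total_bins)
        except Exception as exc:
            raise StageError("domains", exc) from exc

    if "clustering" in config.stages:
        try:
            wt_c = rebin(wt, p.cluster_bin_size)
            onco_c = rebin(onco, p.cluster_bin_size)
            mut_c = rebin(mut, p.cluster_bin_size)
            cluster_out = {}
            for partition in clustering.PARTITIONS:
                matrix = clustering.build_matrix(wt_c, onco_c, mut_c, partition)
                k = min(p.cluster_k, matrix.n_rows)
                result = clustering.cluster_bins(matrix, k=k)
                summ = clustering.cluster_summary(matrix, result.labels)
                cluster_out[partition] = summ.to_dict(orient="records")
                log.info("clustering %s: %d rows -> %d clusters",
                         partition, matrix.n_rows, k)
            report["stages"]["clustering"] = {
                "autosomes": cluster_out["autosomes"], "X": cluster_out["X"],
            }
        except Exception as exc:
            raise StageError("clustering", exc) from exc

    if "fit" in config.stages:
        try:
            x, y, z = wt.flatten(), onco.flatten(), mut.flatten()
            result = dependency_model.fit(x, y, z, degree=p.degree)
            report["stages"]["fit"] = {
                "coefficients": result.model.to_dict(),
                "r_squared": result.r_squared,
                "sse": result.sse,
                "n_bins": result.n_bins,
            }
            log.info("fit: n=%d r2=%.4f", result.n_bins, result.r_squared)
        except Exception as exc:
            raise StageError("fit", exc) from exc

    if "integration" in config.stages:
        if genes is None:
            raise StageError("integration", ValidationError("no gene table provided"))
        try:
            table = expression.de_filter(genes)
            table = expression.assign_quintiles(table)
            delta = expression.delta_k27me3(wt, mut, table)
            table = table.assign(delta_k27me3=table["gene_id"].map(delta))
            de = table[table["de_status"] != expression.DE_NS]
            if len(de) >= 3:
                corr = expression.correlate_changes(
                    de["log2_fc"], de["delta_k27me3"],
                    n_permutations=p.n_permutations, seed=config.seed,
                )
                corr_out = {"spearman": corr.spearman, "pearson": corr.pearson,
                            "p_spearman": corr.p_spearman}
            else:
                corr_out = {"spearman": float("nan"), "pearson": float("nan"),
                            "p_spearman": float("nan")}
            fractions = expression.quintile_fractions(table)
            if "germline_specific" in table.columns:
                germline = table.loc[table["germline_specific"].astype(bool), "gene_id"]
            else:
                germline = pd.Series([], dtype=object)
            overlap = expression.gene_set_overlap(de["gene_id"], germline)
            report["stages"]["integration"] = {
                **corr_out,
                "n_de": int(len(de)),
                "quintile_fractions": {
                    q: (None if pd.isna(v) else float(v))
                    for q, v in fractions.fractions.items()
                },
                "overlap": {"only_de": overlap.only_a,
                            "intersection": overlap.intersection,
                            "only_reference": overlap.only_b},
            }
            log.info("integration: %d DE genes, spearman=%s",
                     len(de), corr_out["spearman"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("integration", exc) from exc

    if "ploidy" in config.stages:
        if dapi is None:
            raise StageError("ploidy", ValidationError("no DAPI table provided"))
        try:
            cal = ploidy.calibrate(dapi)
            contents = dapi.assign(
                content=ploidy.estimate_content(dapi["intensity"].to_numpy(), cal)
            )
            rel = ploidy.relative_content_report(contents[["population", "content"]])
            report["stages"]["ploidy"] = {
                "slope": cal.slope,
                "intercept": cal.intercept,
                "relative_content": rel.to_dict(orient="records"),
            }
            log.info("ploidy: slope=%.3f intercept=%.3f over %d nuclei",
                     cal.slope, cal.intercept, len(dapi))
        except Exception as exc:
            raise StageError("ploidy", exc) from exc

    validate_report(report)
    return report


# ---------------------------------------------------------------------------
# minimal schema validation (packaged schema, no external validator required)


def load_report_schema() -> dict:
    text = resources.files("oncochrom.data").joinpath("run_report.schema.json").read_text()
    return json.loads(text)


def _check(node, schema, path):
    t = schema.get("type")
    if t == "object":
        if not isinstance(node, dict):
            raise ValidationError(f"{path}: expected object")
        for key in schema.get("required", []):
            if key not in node:
                raise ValidationError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}")
    elif t == "array":
        if not isinstance(node, list):
            raise ValidationError(f"{path}: expected array")
    elif t == "integer":
        if not isinstance(node, int) or isinstance(node, bool):
            raise ValidationError(f"{path}: expected integer, got {type(node).__name__}")
    elif t == "number":
        if not isinstance(node, (int, float)) or isinstance(node, bool):
            raise ValidationError(f"{path}: expected number, got {type(node).__name__}")
    elif t == "string":
        if not isinstance(node, str):
            raise ValidationError(f"{path}: expected string")


def validate_report(report: dict, schema: dict | None = None) -> None:
    _check(report, schema or load_report_schema(), "$")
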