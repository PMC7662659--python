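"""Config-driven orchestration: trim -> denoise -> split -> select -> train -> evaluate.

A :class:`PipelineConfig` (buildable from YAML or JSON) names the input —
a wide-CSV file or a synthetic-generator spec — the preprocessing, the
selection methods, the classifiers and the tasks.  ``run_pipeline``
executes the stages in order, fits each wavelength selection once per
(task, method) on the training rows and shares it across classifiers,
writes the report tables plus a machine-readable manifest (config hash,
seeds, versions), and is deterministic given the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import ClassifierSpec
from .evaluation import (TaskConfig, build_report_tables, report_markdown,
                         run_task)
from .preprocess import WaveletConfig
from .spectra_io import read_dataset, stratified_split
from .synthetic_data import SyntheticSpec, default_spec, generate, train_sizes
from .variable_selection import GAPLSConfig

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("walnutmir")


@dataclass
class PipelineConfig:
    input: str | None = None            # wide-CSV path; None -> synthetic
    input_format: str = "wide_csv"
    synthetic: SyntheticSpec | None = None
    trim: tuple[float, float] | None = (700.0, 3450.0)
    wavelet: WaveletConfig | None = field(default_factory=WaveletConfig)
    selections: tuple[str, ...] = ("full", "uve_spa", "ga_pls")
    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec("ELM", 40), ClassifierSpec("RF", 40),
        ClassifierSpec("RBF", 20), ClassifierSpec("PLSDA", 8),
        ClassifierSpec("BPNN", 10))
    tasks: tuple[str, ...] = ("origins", "varieties_within", "all_varieties")
    partition_seed: int = 0
    ga_config: GAPLSConfig = field(default_factory=lambda: GAPLSConfig(n_runs=10))
    uve_params: dict = field(default_factory=dict)
    spa_params: dict = field(default_factory=dict)
    outdir: str = "pipeline_out"

    def validate(self) -> None:
        if self.input is None and self.synthetic is None:
            raise ValueError("config needs either an input path or a "
                             "synthetic spec")
        if self.input is not None and not Path(self.input).exists():
            raise ValueError(f"input path {self.input} does not exist")
        for t in self.tasks:
            if t not in ("origins", "varieties_within", "all_varieties"):
                raise ValueError(f"unknown task {t!r}")
        for s in self.selections:
            if s not in ("full", "uve_spa", "ga_pls"):
                raise ValueError(f"unknown selection {s!r}")
        for c in self.classifiers:
            if c.kind == "BPNN" and "full" in self.selections and \
                    len(self.selections) == 1:
                raise ValueError(
                    "BPNN cannot be evaluated on the full spectral range; "
                    "add a selection method or drop BPNN")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(
                d["synthetic"], SyntheticSpec):
            syn = d["synthetic"]
            d["synthetic"] = default_spec(**syn) if isinstance(syn, dict) \
                else default_spec()
        if d.get("wavelet") is not None and isinstance(d["wavelet"], dict):
            d["wavelet"] = WaveletConfig(**d["wavelet"])
        if d.get("ga_config") is not None and isinstance(d["ga_config"], dict):
            d["ga_config"] = GAPLSConfig(**d["ga_config"])
        if "classifiers" in d:
            d["classifiers"] = tuple(
                c if isinstance(c, ClassifierSpec) else ClassifierSpec(**c)
                for c in d["classifiers"])
        for k in ("selections", "tasks"):
            if k in d:
                d[k] = tuple(d[k])
        if d.get("trim") is not None:
            d["trim"] = tuple(d["trim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def canonical_json(self) -> str:
        def enc(o):
            if isinstance(o, (SyntheticSpec, WaveletConfig, GAPLSConfig,
                              ClassifierSpec)):
                return asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        return json.dumps(asdict(self), default=enc, sort_keys=True)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured workflow; returns {reports, table, manifest}."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.input is not None:
        log.info("reading dataset from %s", cfg.input)
        ds = read_dataset(cfg.input, format=cfg.input_format)
        sizes = None
    else:
        log.info("generating synthetic dataset (seed=%d)", cfg.synthetic.seed)
        ds = generate(cfg.synthetic)
        sizes = train_sizes(cfg.synthetic)
    partition = stratified_split(ds, seed=cfg.partition_seed,
                                 train_sizes=sizes)
    partition.to_json(out / "partition.json")
    task_cfg = TaskConfig(trim=cfg.trim, wavelet=cfg.wavelet,
                          uve_params=cfg.uve_params, spa_params=cfg.spa_params,
                          ga_config=cfg.ga_config)
    origins = sorted(set(map(str, ds.origin)))
    cells: list[tuple[str, str | None]] = []
    for t in cfg.tasks:
        if t == "varieties_within":
            cells.extend((t, o) for o in origins)
        else:
            cells.append((t, None))
    reports = []
    for task, origin in cells:
        for vi in cfg.selections:
            for spec in cfg.classifiers:
                if spec.kind == "BPNN" and vi == "full":
                    log.info("skipping BPNN on full spectrum (%s)", task)
                    continue
                try:
                    r = run_task(ds, task, vi, spec, partition, task_cfg,
                                 origin=origin)
                except Exception:
                    log.error("stage failed: task=%s origin=%s input=%s "
                              "classifier=%s", task, origin, vi, spec.kind)
                    raise
                log.info("%s/%s %s %s -> overall %.2f%%", task, origin or "-",
                         vi, spec.kind, r.overall_acc)
                reports.append(r)
    table = build_report_tables(reports)
    table.to_csv(out / "report.csv", index=False)
    (out / "report.md").write_text(report_markdown(table))
    manifest = {
        "config_sha256": hashlib.sha256(
            cfg.canonical_json().encode()).hexdigest(),
        "partition_seed": cfg.partition_seed,
        "synthetic_seed": None if cfg.synthetic is None else cfg.synthetic.seed,
        "ga_seed": cfg.ga_config.seed,
        "walnutmir_version": __version__,
        "numpy_version": np.__version__,
        "n_reports": len(reports),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"reports": reports, "table": table, "manifest": manifest,
            "partition": partition}
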