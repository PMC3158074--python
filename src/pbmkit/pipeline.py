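"""End-to-end orchestration of the PBM analysis stages.

A single YAML config drives the run: simulate (or load) spot-level arrays,
normalize, call bound / differentially bound sequences, scan with PWMs,
and compare sets — every stage's parameters, seeds and outputs recorded in a
JSON run manifest so a rerun with the same config is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comparison import cv_summary, overlap_sets, random_split_comparison
from .differential_binding import (
    DesignSpec,
    differential_pipeline,
    select_bound,
    select_differential,
)
from .errors import ConfigurationError, PbmkitError
from .io_formats import (
    ArraySet,
    Slide,
    read_fasta,
    read_gpr,
    read_pwm,
    write_table,
)
from .motif_scan import scan_all, write_bed
from .normalization import normalize_arrayset
from .synthetic_data import PbmSimConfig, simulate_pbm_experiment, write_experiment

log = logging.getLogger("pbmkit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig:
    """Validated pipeline configuration loaded from a YAML mapping."""

    def __init__(self, raw: dict, base_dir: Path | None = None):
        if not isinstance(raw, dict):
            raise ConfigurationError("pipeline config must be a mapping")
        self.raw = raw
        self.base_dir = base_dir or Path.cwd()
        self.simulate = raw.get("simulate")
        self.arrays = raw.get("arrays")
        if self.simulate is None and self.arrays is None:
            raise ConfigurationError("config needs either 'simulate' or 'arrays'")
        self.normalize = raw.get("normalize", {})
        self.diffbind = raw.get("diffbind", {})
        self.scan = raw.get("scan")
        self.compare = raw.get("compare", {})
        self.outdir = Path(raw.get("outdir", "pbmkit_run"))
        paths: list = []
        if self.arrays is not None:
            paths += [entry["path"] for entry in self.arrays]
        if self.scan is not None:
            paths += [self.scan["fasta"], *self.scan.get("pwms", [])]
        for p in paths:
            p = self.base_dir / p
            if not p.exists():
                raise ConfigurationError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {}, base_dir=path.parent)


def _load_arrays(cfg: PipelineConfig) -> ArraySet:
    arrays = ArraySet()
    for entry in cfg.arrays:
        path = cfg.base_dir / entry["path"]
        spots = read_gpr(path)
        arrays.slides.append(
            Slide(slide_id=spots[0].slide_id, group=entry.get("group", ""), spots=spots)
        )
    return arrays


def run_pipeline(config: PipelineConfig | dict | str | Path, outdir=None) -> dict:
    """Run all configured stages; return the manifest (also written as JSON).

    A stage failure aborts the run with the failing stage named; outputs of
    earlier stages are preserved on disk.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    outdir = Path(outdir) if outdir is not None else config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pbmkit_version": __version__,
        "stages": [],
        "parameters": config.raw,
        "outputs": {},
    }

    def _stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    def _fail(name: str, exc: Exception):
        manifest["outputs"]["failed_stage"] = name
        _write_manifest(manifest, outdir)
        raise PbmkitError(f"stage '{name}' failed: {exc}") from exc

    truth = None
    try:
        _stage("load")
        if config.simulate is not None:
            sim_cfg = PbmSimConfig(**config.simulate)
            arrays, truth = simulate_pbm_experiment(sim_cfg)
            sim_manifest = write_experiment(arrays, truth, outdir / "simulated")
            manifest["outputs"]["simulated"] = sim_manifest
            manifest["seeds"] = {"simulate": sim_cfg.seed}
        else:
            arrays = _load_arrays(config)
    except PbmkitError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _fail("load", exc)

    try:
        _stage("normalize")
        binding, cv = normalize_arrayset(
            arrays,
            span=config.normalize.get("span", 0.3),
            quantile=config.normalize.get("quantile", "ratio"),
            aggregate=config.normalize.get("aggregate", "median"),
        )
        binding_path = outdir / "binding_matrix.tsv"
        write_table(binding.rename_axis("sequence_id").reset_index(), binding_path)
        cv_path = outdir / "replicate_cv.tsv"
        write_table(cv, cv_path)
        cdf, _ = cv_summary(cv)
        write_table(cdf, outdir / "cv_summary.tsv")
        manifest["outputs"]["binding_matrix"] = str(binding_path)
        manifest["outputs"]["replicate_cv"] = str(cv_path)
    except Exception as exc:
        _fail("normalize", exc)

    groups = tuple(arrays.groups)
    diff_cfg = config.diffbind
    alpha = diff_cfg.get("alpha", 0.05)
    m_cutoff = diff_cfg.get("m_cutoff", 1.0)
    use_adjusted = diff_cfg.get("adjusted", True)
    contrast = diff_cfg.get("contrast")
    if isinstance(contrast, str):
        contrast = tuple(contrast.split(":"))
    try:
        _stage("diffbind")
        # one-group binding call on every slide (is M above the DNA baseline?)
        bound_records = differential_pipeline(binding, DesignSpec(groups=groups))
        bound = select_bound(bound_records, alpha=alpha, use_adjusted=use_adjusted)
        out = bound_records.rename_axis("sequence_id").reset_index()
        out["selected_bound"] = out["sequence_id"].isin(bound)
        write_table(out, outdir / "bound_table.tsv")
        _write_ids(sorted(bound), outdir / "bound_ids.txt")
        manifest["outputs"]["bound_table"] = str(outdir / "bound_table.tsv")
        manifest["outputs"]["n_bound"] = len(bound)

        differential: set[str] = set()
        if contrast is not None:
            diff_records = differential_pipeline(
                binding, DesignSpec(groups=groups, contrast=tuple(contrast))
            )
            differential, fold_only = select_differential(
                diff_records, m_cutoff=m_cutoff, alpha=alpha, use_adjusted=use_adjusted
            )
            out = diff_records.rename_axis("sequence_id").reset_index()
            out["selected_differential"] = out["sequence_id"].isin(differential)
            out["passes_fold_cutoff"] = out["sequence_id"].isin(fold_only)
            write_table(out, outdir / "differential_table.tsv")
            _write_ids(sorted(differential), outdir / "differential_ids.txt")
            manifest["outputs"]["differential_table"] = str(outdir / "differential_table.tsv")
            manifest["outputs"]["n_differential"] = len(differential)
    except Exception as exc:
        _fail("diffbind", exc)

    if config.scan is not None:
        try:
            _stage("scan")
            sequences = read_fasta(config.base_dir / config.scan["fasta"])
            for pwm_path in config.scan.get("pwms", []):
                pwm = read_pwm(config.base_dir / pwm_path)
                hits = scan_all(pwm, sequences)
                bed_path = outdir / f"hits_{pwm.name}.bed"
                write_bed(hits, bed_path, width=pwm.width)
                manifest["outputs"][f"hits_{pwm.name}"] = str(bed_path)
        except Exception as exc:
            _fail("scan", exc)

    if config.compare:
        try:
            _stage("compare")
            split_cfg = config.compare.get("split")
            if split_cfg is not None:
                results = random_split_comparison(
                    binding,
                    groups,
                    group=split_cfg["group"],
                    n_per_side=split_cfg.get("n", 4),
                    seed=split_cfg.get("seed", 0),
                    m_cutoff=m_cutoff,
                    alpha=alpha,
                    use_adjusted=use_adjusted,
                    true_contrast=tuple(contrast) if contrast else None,
                    replicates=split_cfg.get("replicates", 1),
                )
                payload = [
                    {
                        "side_a": list(r.side_a),
                        "side_b": list(r.side_b),
                        "split_count": r.split_count,
                        "true_count": r.true_count,
                    }
                    for r in results
                ]
                (outdir / "split_noise.json").write_text(json.dumps(payload, indent=2))
                manifest["outputs"]["split_noise"] = str(outdir / "split_noise.json")
            sets_cfg = config.compare.get("overlap")
            if sets_cfg:
                named = {
                    name: set(pd.read_csv(config.base_dir / p, header=None)[0].astype(str))
                    for name, p in sets_cfg.items()
                }
                result = overlap_sets(named)
                (outdir / "overlap.json").write_text(
                    json.dumps(result.to_json_dict(), indent=2)
                )
                manifest["outputs"]["overlap"] = str(outdir / "overlap.json")
        except Exception as exc:
            _fail("compare", exc)

    if truth is not None:
        manifest["outputs"]["ground_truth"] = str(outdir / "simulated" / "ground_truth.tsv")
    _write_manifest(manifest, outdir)
    return manifest


def _write_ids(ids, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
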