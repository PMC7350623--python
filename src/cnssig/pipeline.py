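"""End-to-end reproducible runs: simulate -> discover -> normalize ->
classify -> evaluate, with a manifest of content digests.

A run is driven by a single config dict (or YAML file) with per-stage
sections and explicit seeds. Stages execute in order and fail fast; on a
stage error the partial outputs are retained next to a ``<stage>.failed``
marker. Identical config + seeds produce identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classification import call_groups, calls_to_frame, hierarchical_cluster
from .discovery import (
    DiscoveryParams,
    log2_and_variance_filter,
    quantile_normalize,
    rank_and_select,
    resampled_marker_stats,
    stats_to_frame,
)
from .errors import ConfigurationError, PipelineError
from .evaluation import auc_table
from .normalization import hybridization_report, normalize_cohort
from .rcc import CodeSet, default_codeset, write_rcc
from .synthetic import (
    CohortConfig,
    DiscoveryConfig,
    default_infratentorial_config,
    default_supratentorial_config,
    generate_discovery_dataset,
    generate_nanostring_cohort,
    reference_map,
)


@dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds, and per-output digests."""

    config_hash: str
    seed: int | None
    package_version: str = __version__
    stages: list[dict] = field(default_factory=list)
    created: str = ""

    def add_stage(self, name: str, outputs: dict[str, str], elapsed_s: float):
        self.stages.append(
            {"name": name, "outputs": outputs, "elapsed_s": round(elapsed_s, 4)}
        )

    def output_digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for stage in self.stages:
            out.update(stage["outputs"])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "package_version": self.package_version,
                "created": self.created,
                "stages": self.stages,
            },
            indent=2,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def default_run_config(seed: int = 0) -> dict:
    """A complete demo configuration exercising every stage."""
    return {
        "seed": seed,
        "codeset": "default",
        "discovery": {
            "classes": {"ENTITY": 12, "HGG": 20, "EPN": 20, "MB": 16},
            "n_probes": 400,
            "planted": {"ENTITY": [["P00000", 4.0], ["P00001", 5.0], ["P00002", 4.5]]},
            "params": {"n_reps": 100, "top_n": 100, "fold_threshold": 10.0},
        },
        "cohorts": ["supratentorial", "infratentorial"],
        "tau": 2.0,
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("run config must be a mapping")
    return config


def _resolve_codeset(spec) -> CodeSet:
    if spec in (None, "default"):
        return default_codeset()
    path = Path(spec)
    if not path.exists():
        raise ConfigurationError(f"CodeSet file not found: {path}")
    return CodeSet.from_yaml(path)


def _cohort_config(name_or_map, seed: int) -> CohortConfig:
    if name_or_map == "supratentorial":
        return default_supratentorial_config(seed=seed)
    if name_or_map == "infratentorial":
        return default_infratentorial_config(seed=seed)
    if isinstance(name_or_map, dict):
        return CohortConfig(**{**name_or_map, "seed": name_or_map.get("seed", seed)})
    raise ConfigurationError(f"unknown cohort spec {name_or_map!r}")


class _StageRunner:
    def __init__(self, manifest: RunManifest, out_dir: Path, log_path: Path):
        self.manifest = manifest
        self.out_dir = out_dir
        self.log_path = log_path

    def run(self, name: str, fn):
        start = time.perf_counter()
        try:
            outputs = fn()
        except Exception as err:
            (self.out_dir / f"{name}.failed").write_text(f"{type(err).__name__}: {err}\n")
            self._log(name, "failed", error=str(err))
            raise PipelineError(f"stage {name!r} failed: {err}") from err
        elapsed = time.perf_counter() - start
        digests = {
            str(p.relative_to(self.out_dir)): _sha256(p) for p in sorted(outputs)
        }
        self.manifest.add_stage(name, digests, elapsed)
        self._log(name, "ok", elapsed_s=round(elapsed, 4), n_outputs=len(outputs))
        return outputs

    def _log(self, stage: str, status: str, **extra):
        rec = {"stage": stage, "status": status, **extra}
        with self.log_path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_pipeline(config, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full synthetic-cohort diagnostic workflow.

    Returns the :class:`RunManifest`; also written to
    ``out_dir/manifest.json`` alongside per-stage outputs and a JSON-lines
    stage log.
    """
    config = _load_config(config)
    # validate before any compute: config errors must precede stage work
    codeset = _resolve_codeset(config.get("codeset"))
    if seed is None:
        seed = int(config.get("seed", 0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_digest_config(config), seed=seed)
    manifest.created = time.strftime("%Y-%m-%dT%H:%M:%S")
    log_path = out_dir / "log.jsonl"
    log_path.write_text("")
    runner = _StageRunner(manifest, out_dir, log_path)
    tau = float(config.get("tau", 2.0))

    if "discovery" in config:
        runner.run("discovery", lambda: _discovery_stage(config, seed, out_dir))

    for cohort_spec in config.get("cohorts", []):
        name = cohort_spec if isinstance(cohort_spec, str) else cohort_spec.get(
            "compartment", "cohort"
        )
        runner.run(
            f"cohort-{name}",
            lambda spec=cohort_spec: _cohort_stage(
                spec, codeset, seed, tau, out_dir
            ),
        )

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest


def _discovery_stage(config: dict, seed: int, out_dir: Path) -> list[Path]:
    section = config["discovery"]
    planted = {
        cls: [(p, float(e)) for p, e in markers]
        for cls, markers in section.get("planted", {}).items()
    }
    dconf = DiscoveryConfig(
        classes=dict(section["classes"]),
        n_probes=int(section["n_probes"]),
        planted_markers=planted,
        seed=seed,
    )
    params = DiscoveryParams(**section.get("params", {}), seed=seed)
    matrix = generate_discovery_dataset(dconf)
    log2 = log2_and_variance_filter(quantile_normalize(matrix), params)
    outputs = []
    stage_dir = out_dir / "discovery"
    stage_dir.mkdir(exist_ok=True)
    matrix_path = stage_dir / "matrix.tsv"
    matrix.to_tsv(matrix_path)
    outputs.append(matrix_path)
    for cls in planted:
        stats = resampled_marker_stats(log2, cls, params)
        panel = rank_and_select(stats, params)
        path = stage_dir / f"panel_{cls}.tsv"
        stats_to_frame(panel).to_csv(path, sep="\t", index=False)
        outputs.append(path)
    return outputs


def _cohort_stage(
    cohort_spec, codeset: CodeSet, seed: int, tau: float, out_dir: Path
) -> list[Path]:
    cconf = _cohort_config(cohort_spec, seed)
    samples, truth = generate_nanostring_cohort(cconf, codeset)
    stage_dir = out_dir / f"cohort_{cconf.compartment}"
    rcc_dir = stage_dir / "rcc"
    rcc_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for s in samples:
        path = rcc_dir / f"{s.sample_id}.rcc"
        write_rcc(s, path)
        outputs.append(path)
    truth_path = stage_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    outputs.append(truth_path)

    norm = normalize_cohort(samples, codeset)
    norm_path = stage_dir / "normalized.tsv"
    norm.values.to_csv(norm_path, sep="\t", index_label="probe_id")
    outputs.append(norm_path)

    refs = reference_map(truth)
    analysis = norm.restrict(codeset.analysis_probes(cconf.compartment))
    tree = hierarchical_cluster(analysis)
    newick_path = stage_dir / "dendrogram.nwk"
    newick_path.write_text(tree.to_newick() + "\n")
    outputs.append(newick_path)

    calls = call_groups(
        norm, codeset, cconf.compartment, refs, tau=tau, dendrogram=tree
    )
    calls_path = stage_dir / "calls.tsv"
    calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    outputs.append(calls_path)

    qc = hybridization_report(norm, codeset, refs, cconf.compartment)
    qc_path = stage_dir / "hybridization_qc.tsv"
    qc.to_csv(qc_path, sep="\t", index=False)
    outputs.append(qc_path)

    if truth["entity"].ne("").any():
        aucs = auc_table(norm, codeset, truth, cconf.compartment)
        auc_path = stage_dir / "auc.tsv"
        aucs.to_csv(auc_path, sep="\t", index=False)
        outputs.append(auc_path)
    return outputs
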