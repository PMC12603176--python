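"""End-to-end workflow: ingest/simulate -> QC -> residualize -> select ->
evaluate -> PCA, with one output namespace per comparison and a JSON
manifest that records the config, every derived seed and every artifact, so
any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import fit_and_residualize
from .boruta import BorutaParams
from .evaluation import evaluate_comparison
from .io import read_panel, write_panel, write_table
from .panel import ComparisonSpec, MetabolitePanel
from .pca import run_pca
from .qc import QCThresholds, apply_filters
from .simulate import SimConfig, generate_panel
from .stability import (
    MODERATELY_RELIABLE,
    ReliabilityThresholds,
    StabilityReport,
    run_validation,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML or JSON."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # input: either a panel file (+ optional metabolite sidecar) ...
    panel_path: str | None = None
    metabolite_meta_path: str | None = None
    # ... or a simulation config
    sim: SimConfig | None = None

    qc: QCThresholds = field(default_factory=QCThresholds)
    boruta: BorutaParams = field(default_factory=BorutaParams)
    n_seeds: int = 5
    reliability: ReliabilityThresholds = field(default_factory=ReliabilityThresholds)
    # each entry: list of group names (2 = pairwise, >2 = multiclass),
    # or the string "all_pairwise" / "multiclass"
    comparisons: list = field(default_factory=lambda: ["all_pairwise", "multiclass"])
    evaluation_alpha: float = 0.05
    evaluation_n_trees: int = 1000
    selection_category: str = MODERATELY_RELIABLE
    log10_adjust: bool = False

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValueError("comparisons must be non-empty")
        if self.panel_path is None and self.sim is None:
            raise ValueError("either panel_path or sim must be given")

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = {k: tuple(v) if isinstance(v, list) else v for k, v in d["sim"].items()}
            d["sim"] = SimConfig(**sim)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "boruta" in d and isinstance(d["boruta"], dict):
            d["boruta"] = BorutaParams(**d["boruta"])
        if "reliability" in d and isinstance(d["reliability"], dict):
            d["reliability"] = ReliabilityThresholds(**d["reliability"])
        return PipelineConfig(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def resolve_comparisons(config: PipelineConfig, panel: MetabolitePanel) -> list[ComparisonSpec]:
    groups = panel.groups()
    specs: list[ComparisonSpec] = []
    for entry in config.comparisons:
        if entry == "all_pairwise":
            specs.extend(
                ComparisonSpec.pairwise(a, b)
                for i, a in enumerate(groups)
                for b in groups[i + 1:]
            )
        elif entry == "multiclass":
            if len(groups) >= 3:
                specs.append(ComparisonSpec.multiclass(groups))
        else:
            names = list(entry)
            spec = (
                ComparisonSpec.pairwise(*names)
                if len(names) == 2
                else ComparisonSpec.multiclass(names)
            )
            specs.append(spec)
    for spec in specs:
        spec.check_against(panel)
    return specs


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every configured comparison.

    Returns (and writes as ``manifest.json``) a manifest of artifacts,
    seeds, configuration hash and headline counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest: dict = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "base_seed": config.seed,
        "artifacts": {},
        "comparisons": {},
    }

    # ingest / simulate ----------------------------------------------------
    truth = None
    if config.sim is not None:
        panel, truth = _simulate(config)
        write_panel(panel, out / "panel.tsv", meta_path=out / "metabolites.tsv")
        truth.to_json(out / "truth.json")
        manifest["artifacts"]["panel"] = "panel.tsv"
        manifest["artifacts"]["truth"] = "truth.json"
    else:
        panel = _ingest(config)
        manifest["artifacts"]["panel"] = str(config.panel_path)

    # QC -------------------------------------------------------------------
    clean, report = _qc(panel, config)
    qc_table = report.metabolites.reset_index()
    write_table(qc_table, out / "qc_report.tsv", sort_by=["metabolite"])
    write_panel(clean, out / "clean.tsv", meta_path=out / "clean.tsv.metabolites.tsv")
    manifest["artifacts"]["qc_report"] = "qc_report.tsv"
    manifest["artifacts"]["clean_panel"] = "clean.tsv"
    manifest["qc"] = {
        "n_input_metabolites": int(len(panel.metabolites)),
        "n_retained": report.n_retained,
        "exclusion_reasons": report.reason_counts(),
        "outlier_samples": [
            {k: (str(v) if k == "sample_id" else float(v)) for k, v in f.items() if k != "reason"}
            for f in report.outlier_samples
        ],
    }

    # residualization ------------------------------------------------------
    residuals = _adjust(clean, config)
    res_table = residuals.residuals.reset_index()
    write_table(res_table, out / "residuals.tsv", sort_by=["sample_id"])
    coef = residuals.coefficients.reset_index(names="metabolite")
    write_table(coef, out / "coefficients.tsv", sort_by=["metabolite"])
    manifest["artifacts"]["residuals"] = "residuals.tsv"
    manifest["artifacts"]["coefficients"] = "coefficients.tsv"
    manifest["sex_coding"] = residuals.sex_coding

    # PCA on the full cleaned panel ---------------------------------------
    pca_before = run_pca(residuals.residuals)
    _write_pca(pca_before, out, "pca_full")
    manifest["pca_full_pc1_frac"] = float(pca_before.explained_variance_frac[0])

    # selection + evaluation per comparison --------------------------------
    n_tests = len(clean.metabolites)
    for spec in resolve_comparisons(config, panel):
        cdir = out / spec.label.replace("/", "_")
        cdir.mkdir(exist_ok=True)
        centry: dict = {"mode": spec.mode, "groups": list(spec.groups)}

        stab = _select(residuals, spec, config)
        counts = stab.counts.reset_index(names="metabolite")
        write_table(counts, cdir / "stability.tsv", sort_by=["metabolite"])
        write_table(stab.run_log, cdir / "runs.tsv",
                    sort_by=["seed_index", "held_out_sample"])
        selected = stab.selected(config.selection_category)
        centry.update(
            total_runs=stab.total_runs,
            skipped_runs=stab.skipped_runs,
            selected=sorted(selected),
            highly_reliable=sorted(stab.selected("highly_reliable")),
        )

        if selected:
            ev = _evaluate(panel, residuals, spec, selected, n_tests, config)
            etable = ev.metabolites.reset_index()
            write_table(etable, cdir / "evaluation.tsv", sort_by=["metabolite"])
            centry["oob_error"] = ev.oob_error
            centry["misclassified"] = sorted(map(str, ev.misclassified))
            pca_after = run_pca(
                residuals.subset_groups(spec.groups).residuals, selected
            )
            _write_pca(pca_after, cdir, "pca_selected")
            centry["pca_selected_pc1_frac"] = float(pca_after.explained_variance_frac[0])
        manifest["comparisons"][spec.label] = centry

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest


@_stage("simulate")
def _simulate(config: PipelineConfig):
    sim = dataclasses.replace(config.sim)
    return generate_panel(sim)


@_stage("ingest")
def _ingest(config: PipelineConfig) -> MetabolitePanel:
    return read_panel(config.panel_path, meta_path=config.metabolite_meta_path)


@_stage("qc")
def _qc(panel, config):
    return apply_filters(panel, config.qc)


@_stage("adjust")
def _adjust(clean, config):
    return fit_and_residualize(clean, log10_transform=config.log10_adjust)


@_stage("select")
def _select(residuals, spec, config) -> StabilityReport:
    params = dataclasses.replace(config.boruta, seed=config.seed)
    return run_validation(
        residuals, spec, params,
        n_seeds=config.n_seeds, thresholds=config.reliability,
    )


@_stage("evaluate")
def _evaluate(panel, residuals, spec, selected, n_tests, config):
    return evaluate_comparison(
        panel, residuals, spec, selected, n_tests,
        alpha=config.evaluation_alpha,
        n_trees=config.evaluation_n_trees,
        seed=config.seed,
    )


def _write_pca(result, out_dir: Path, stem: str) -> None:
    scores = result.scores.iloc[:, : min(2, result.n_components)].reset_index()
    scores = scores.rename(columns={scores.columns[0]: "sample_id"})
    write_table(scores, out_dir / f"{stem}_scores.tsv", sort_by=["sample_id"])
    var = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(result.n_components)],
            "explained_variance_frac": result.explained_variance_frac,
        }
    )
    write_table(var, out_dir / f"{stem}_variance.tsv")


# ---------------------------------------------------------------------------

def load_manifest(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    return json.loads(Path(path_or_dict).read_text())


def compare_runs(manifest_a, manifest_b) -> dict:
    """Overlap of selected metabolites between two pipeline runs.

    For every comparison label present in both manifests, reports the two
    selected sets, their intersection and the run-specific remainders
    (replication analysis).
    """
    ma, mb = load_manifest(manifest_a), load_manifest(manifest_b)
    common = sorted(set(ma["comparisons"]) & set(mb["comparisons"]))
    if not common:
        raise ValueError("manifests share no comparison label")
    report: dict = {}
    for label in common:
        sa = set(ma["comparisons"][label].get("selected", []))
        sb = set(mb["comparisons"][label].get("selected", []))
        report[label] = {
            "n_a": len(sa),
            "n_b": len(sb),
            "intersection": sorted(sa & sb),
            "only_a": sorted(sa - sb),
            "only_b": sorted(sb - sa),
            "union_size": len(sa | sb),
        }
    return report
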