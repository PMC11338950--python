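"""End-to-end pipeline orchestration.

Runs filter -> normalize -> calibrate -> differential -> protein aggregation
-> kinase enrichment -> ORA in order, writing every stage output as TSV plus
a JSON summary and a manifest embedding the resolved configuration, so a run
is reproducible from its own output directory. Per-stage log lines carry
record counts in and out, so the site funnel (total -> class I -> p<0.05 ->
FC-filtered) is reconstructable from the logs of any dataset.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .diffstats import (
    DifferentialResults,
    SiteDifferentialModel,
    overlap_fraction,
)
from .enrich import ora_frame, ora_test
from .kinase import KinaseEnrichmentModel
from .preprocess import pca_project, preprocess_experiment, sample_correlation

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    sites: str
    proteins: str
    design: str
    kinases: str | None = None
    gmt: str | None = None
    outdir: str = "run"
    group_a: str | None = None  # default: first group in the design
    group_b: str | None = None  # default: last group in the design
    loc_threshold: float = 0.75
    strict_threshold: bool = False
    alpha: float = 0.05
    fc_threshold: float = 1.5
    log_scale: bool = True
    fpr: float = 0.02
    matrix: str = "BLOSUM62"
    n_background: int = 1000
    pca_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate_paths(self) -> None:
        for name in ("sites", "proteins", "design", "kinases", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to outdir)."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}, "summary": {}}

    def _out(name: str, fname: str) -> Path:
        path = outdir / fname
        manifest["outputs"][name] = str(path)
        return path

    stage = "read_inputs"
    try:
        design = pio.read_design(config.design)
        sites = pio.read_site_table(config.sites, design)
        proteins = pio.read_protein_table(config.proteins, design)
        group_a = config.group_a or design.groups[0]
        group_b = config.group_b or design.groups[-1]

        stage = "preprocess"
        pre = preprocess_experiment(
            sites,
            proteins,
            design,
            loc_threshold=config.loc_threshold,
            strict_threshold=config.strict_threshold,
        )
        calibrated = pre["calibrated"]
        calibrated.data.rename_axis("site_id").to_csv(_out("calibrated", "calibrated.tsv"), sep="\t")
        pd.DataFrame(
            {
                "site_id": [f.site_id for f in pre["flags"]],
                "protein_quantified": [f.protein_quantified for f in pre["flags"]],
            }
        ).to_csv(_out("flags", "calibration_flags.tsv"), sep="\t", index=False)

        stage = "qc"
        corr = sample_correlation(calibrated)
        corr.rename_axis("channel").to_csv(_out("correlation", "correlation.tsv"), sep="\t")
        scores, varexp = pca_project(calibrated, config.pca_components)
        scores.assign(group=[design.group_of[c] for c in scores.index]).rename_axis(
            "channel"
        ).to_csv(_out("pca", "pca_scores.tsv"), sep="\t")
        manifest["summary"]["pca_variance_explained"] = [round(float(v), 6) for v in varexp]

        stage = "differential"
        model = SiteDifferentialModel(
            calibrated, design, group_a, group_b, log_scale=config.log_scale
        )
        diff = model.fit(alpha=config.alpha, fc_threshold=config.fc_threshold)
        diff.frame.to_csv(_out("diff", "diff.tsv"), sep="\t", index=False)

        stage = "aggregate_proteins"
        prot_summary = diff.aggregate_proteins(pre["parent_of"])
        pd.DataFrame(
            {
                "protein_accession": [p.protein_accession for p in prot_summary],
                "n_up_sites": [p.n_up_sites for p in prot_summary],
                "n_down_sites": [p.n_down_sites for p in prot_summary],
                "category": [p.category for p in prot_summary],
            }
        ).to_csv(_out("proteins_direction", "proteins_direction.tsv"), sep="\t", index=False)

        summary = {
            "groups": {"a": group_a, "b": group_b},
            "sites_total": pre["counts"]["sites_total"],
            "class1": pre["counts"]["class1"],
            "protein_fallback": pre["counts"]["protein_fallback"],
            "tested": diff.n_tested,
            "significant_p": int((diff.frame["p_value"] < config.alpha).sum()),
            "up_p_only": len(diff.p_only_ids("up")),
            "down_p_only": len(diff.p_only_ids("down")),
            "up": diff.n_up,
            "down": diff.n_down,
            "ns": diff.n_ns,
            "proteins_up_only": sum(p.category == "up-only" for p in prot_summary),
            "proteins_down_only": sum(p.category == "down-only" for p in prot_summary),
            "proteins_both": sum(p.category == "both" for p in prot_summary),
        }

        if config.kinases:
            stage = "kinase_enrichment"
            kin_specs = pio.read_kinase_reference(config.kinases)
            kmodel = KinaseEnrichmentModel(
                pre["class1_sites"],
                kin_specs,
                diff.direction_ids("up"),
                diff.direction_ids("down"),
                fpr=config.fpr,
                substitution_matrix=config.matrix,
                n_background=config.n_background,
                seed=config.seed,
            )
            kres = kmodel.fit(alpha=config.alpha)
            kres.frame.to_csv(_out("kinase", "kinase_enrichment.tsv"), sep="\t", index=False)
            kres.family_summary().to_csv(
                _out("family", "kinase_family_summary.tsv"), sep="\t", index=False
            )
            summary["top_kinases_up"] = [
                [r.kinase, round(float(r.p_value), 10)]
                for r in kres.top(5, "up").itertuples(index=False)
            ]
            summary["top_kinases_down"] = [
                [r.kinase, round(float(r.p_value), 10)]
                for r in kres.top(5, "down").itertuples(index=False)
            ]

        if config.gmt:
            stage = "ora"
            gene_sets = pio.read_gmt(config.gmt)
            parent_of = pre["parent_of"]
            background = frozenset(parent_of[s] for s in diff.tested_ids() if s in parent_of)
            hits = frozenset(
                parent_of[s]
                for s in (diff.direction_ids("up") | diff.direction_ids("down"))
                if s in parent_of
            )
            results = ora_test(hits, background, gene_sets)
            ora_frame(results).to_csv(_out("ora", "ora.tsv"), sep="\t", index=False)
            summary["ora_hits"] = sorted(
                r.set_name for r in results if r.q_value < config.alpha
            )

        manifest["summary"] = {**manifest["summary"], **summary}
        pio.write_json(manifest["summary"], _out("summary", "summary.json"))
        pio.write_json(manifest, outdir / "manifest.json")
        manifest["outputs"]["manifest"] = str(outdir / "manifest.json")
    except Exception as e:  # noqa: BLE001 - annotate with the failing stage
        pio.write_json(
            {"failed_stage": stage, "error": str(e), "config": config.to_dict()},
            outdir / "FAILED.json",
        )
        raise StageError(stage, e) from e
    return manifest


def run_inhibitor_comparison(
    maturation_diff: DifferentialResults | pd.DataFrame,
    inhibitor_diff: DifferentialResults | pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Overlap of maturation-upregulated sites with inhibitor-downregulated sites.

    Both sets are defined by p < alpha only (no fold-change filter), matching
    how inhibitor-responsive site sets are conventionally reported. Returns
    the two set sizes, the intersection, and the overlap percentage of the
    maturation-up set.
    """
    mat_up = _p_only_set(maturation_diff, "up", alpha)
    inh_down = _p_only_set(inhibitor_diff, "down", alpha)
    if not mat_up:
        raise ValueError("maturation-up set is empty")
    count, frac, pct = overlap_fraction(mat_up, inh_down)
    return {
        "alpha": alpha,
        "maturation_up": len(mat_up),
        "inhibitor_down": len(inh_down),
        "intersection": count,
        "fraction": frac,
        "percent": pct,
    }


def _p_only_set(diff, direction: str, alpha: float) -> frozenset[str]:
    if isinstance(diff, DifferentialResults):
        return diff.p_only_ids(direction, alpha)
    f = diff
    sig = f["p_value"].notna() & (f["p_value"] < alpha)
    mask = sig & ((f["fold_change"] > 1) if direction == "up" else (f["fold_change"] < 1))
    return frozenset(f.loc[mask, "site_id"])
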