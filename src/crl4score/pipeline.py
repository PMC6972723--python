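"""End-to-end orchestration: annotate -> score -> heatmap -> burden ->
comparisons -> association, with a checksummed run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cohort_stats, data_io, rubric_scoring
from .cohort_stats import OVERALL, GroupComparison
from .rubric_scoring import Rubric

log = logging.getLogger(__name__)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    version: str = __version__
    seed: int | None = None
    started: str = ""
    finished: str = ""
    status: str = "running"
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineResult:
    out_dir: Path
    scores: pd.DataFrame
    heatmap: pd.DataFrame
    burden: pd.DataFrame
    comparisons: list[GroupComparison]
    associations: list[GroupComparison]
    manifest: RunManifest


def run_pipeline(
    vcf: str | Path,
    gene_models: str | Path,
    phenotypes: str | Path,
    annotations: str | Path,
    out_dir: str | Path,
    rubric: str | Path | None = None,
    threshold: int = 10,
    weighting: str = "carrier",
    reference_location_counts: str | Path | None = None,
    plots: bool = False,
) -> PipelineResult:
    """Run every analysis stage and write the result artefacts.

    Outputs under ``out_dir``: scored_variants.tsv, heatmap.tsv, per-gene
    genotype_heatmap_<gene>.tsv, burden.tsv, comparisons.tsv,
    associations.tsv, location_counts.tsv and manifest.json.  Raises on a
    missing or unparseable input before any computation; the manifest marks
    failures of later stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(started=_now())
    inputs = {
        "vcf": Path(vcf), "gene_models": Path(gene_models),
        "phenotypes": Path(phenotypes), "annotations": Path(annotations),
    }
    if rubric is not None:
        inputs["rubric"] = Path(rubric)
    if reference_location_counts is not None:
        inputs["reference_location_counts"] = Path(reference_location_counts)
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")
    for name, p in inputs.items():
        manifest.inputs[str(p)] = sha256_of(p)

    try:
        result = _run_stages(inputs, out, manifest, threshold, weighting, plots)
    except Exception:
        manifest.status = "failed"
        manifest.finished = _now()
        manifest.write(out / "manifest.json")
        raise
    manifest.status = "ok"
    manifest.finished = _now()
    for p in sorted(out.glob("*.tsv")):
        manifest.outputs[p.name] = sha256_of(p)
    manifest.write(out / "manifest.json")
    result.manifest = manifest
    return result


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def _run_stages(inputs, out: Path, manifest: RunManifest, threshold, weighting, plots) -> PipelineResult:
    # stage 1: annotate (read + classify)
    variants, gmatrix = data_io.read_vcf(inputs["vcf"])
    models = data_io.read_gene_models(inputs["gene_models"])
    phenotypes = data_io.read_phenotypes(inputs["phenotypes"])
    pheno_ids = set(phenotypes["individual"])
    extra = set(gmatrix.individuals) - pheno_ids
    if extra:
        raise ValueError(f"VCF samples missing from phenotype table: {sorted(extra)[:5]}")
    log.info("annotate: %d variants, %d individuals", len(variants), len(gmatrix.individuals))
    manifest.counts["variants"] = len(variants)
    manifest.counts["individuals"] = len(gmatrix.individuals)

    dist = data_io.location_counts(variants, models) if variants else None
    if dist is not None:
        rows = [{"category": c, "count": dist.counts.get(c, 0), "percent": dist.percentages().get(c, 0.0)}
                for c in (*data_io.PANEL_CATEGORIES, data_io.Location.OUT_OF_PANEL.value)]
        pd.DataFrame(rows).to_csv(out / "location_counts.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=["category", "count", "percent"]).to_csv(
            out / "location_counts.tsv", sep="\t", index=False
        )

    # stage 2: score
    rubric = Rubric.from_yaml(inputs["rubric"]) if "rubric" in inputs else Rubric.default()
    raw = rubric_scoring.read_annotations(inputs["annotations"])
    consolidated = rubric_scoring.consolidate_annotations(raw)
    scores = rubric_scoring.score_variants(variants, models, consolidated, rubric)
    scores.to_csv(out / "scored_variants.tsv", sep="\t")
    manifest.counts["scored_variants"] = len(scores)

    # stage 3: heatmaps
    heatmap = rubric_scoring.build_heatmap(scores, threshold=threshold) if len(scores) else scores
    heatmap.to_csv(out / "heatmap.tsv", sep="\t")
    manifest.counts["heatmap_variants"] = len(heatmap)
    if plots and len(heatmap):
        rubric_scoring.plot_heatmap(heatmap, out / "heatmap.png")
    for gene in sorted(models):
        if any(v.gene == gene for v in variants):
            labels, counts = cohort_stats.genotype_heatmap(gmatrix, variants, gene)
            labels.to_csv(out / f"genotype_heatmap_{gene}.tsv", sep="\t")
            counts.to_frame().to_csv(out / f"genotype_counts_{gene}.tsv", sep="\t")

    # stage 4: burden
    score_map = scores["total"].to_dict() if len(scores) else {}
    gene_map = {v.vid: v.gene for v in variants}
    burden = cohort_stats.individual_burden(gmatrix, score_map, gene_map, weighting=weighting)
    burden = burden.merge(phenotypes, on="individual", how="left")
    burden.to_csv(out / "burden.tsv", sep="\t", index=False)

    # stage 5: comparisons
    comparisons: list[GroupComparison] = []
    cases = phenotypes.loc[phenotypes["cohort"] == "case", "individual"].tolist()
    refs = phenotypes.loc[phenotypes["cohort"] == "reference", "individual"].tolist()
    subgroups = {
        label: phenotypes.loc[phenotypes["endophenotype"] == label, "individual"].tolist()
        for label in ("pre_axial_longitudinal", "intercalary_transverse")
    }
    genes_present = sorted({v.gene for v in variants})
    if variants and len(cases) >= 2 and len(refs) >= 2:
        for by in ("count", "score"):
            for gene in [OVERALL, *genes_present]:
                comparisons.append(
                    cohort_stats.compare_burden(
                        burden, {"case": cases, "reference": refs}, by=by, gene=gene
                    )
                )
        if all(len(ids) >= 2 for ids in subgroups.values()):
            comparisons.append(
                cohort_stats.compare_burden(
                    burden,
                    {k: v for k, v in subgroups.items()},
                    by="score",
                    gene=OVERALL,
                )
            )
            comparisons.append(
                cohort_stats.anova_burden(
                    burden, {**subgroups, "reference": refs}, by="score", gene=OVERALL
                )
            )
    if dist is not None and "reference_location_counts" in inputs:
        reference = data_io.read_location_counts(inputs["reference_location_counts"])
        comparisons.append(cohort_stats.compare_location_distribution(dist, reference))
    cohort_stats.comparisons_frame(comparisons).to_csv(out / "comparisons.tsv", sep="\t", index=False)

    # stage 6: genotype-endophenotype association for heatmap variants
    associations: list[GroupComparison] = []
    if len(heatmap) and all(len(ids) >= 2 for ids in subgroups.values()):
        for vid in heatmap.index:
            associations.extend(
                cohort_stats.genotype_phenotype_test(vid, gmatrix, subgroups, mode="carrier")
            )
    cohort_stats.comparisons_frame(associations).to_csv(out / "associations.tsv", sep="\t", index=False)
    manifest.counts["comparisons"] = len(comparisons)
    manifest.counts["associations"] = len(associations)

    return PipelineResult(
        out_dir=out,
        scores=scores,
        heatmap=heatmap,
        burden=burden,
        comparisons=comparisons,
        associations=associations,
        manifest=manifest,
    )
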