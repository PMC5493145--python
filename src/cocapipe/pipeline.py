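"""End-to-end run orchestration.

A YAML configuration names either a synthetic cohort specification or paths
to on-disk inputs, plus the list of stages to execute.  Stages run in
declared order; every output lands in the run directory and is listed in a
manifest with provenance (config hash, seed, package version).  A failing
stage aborts with the stage name; outputs of earlier stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_formats
from . import __version__
from .integrate import coca, consensus_cluster, select_cancer_cpgs, select_recurrent_scna
from .matrices import ValidationError
from .reports import summarize_cohort
from .scores import score_signatures
from .silencing import fit_signature_exposures, intersect_hyper_down
from .stromal import derive_tissue_specific_genes, filter_genes
from .subtypes import discriminant_genes, pca_cluster, select_top_variable
from .synthetic import CohortConfig, SubtypeSpec, generate_cohort, liver_compendium

__all__ = ["ConfigurationError", "STAGES", "run_pipeline"]

log = logging.getLogger("cocapipe")

STAGES = (
    "generate", "filter", "subtype", "score", "cluster",
    "coca", "silencing", "signatures", "summarize",
)

_REQUIRES = {
    "filter": ("expression",),
    "subtype": ("expression",),
    "score": ("expression",),
    "cluster": ("copy_number", "methylation"),
    "coca": ("expression", "copy_number", "methylation"),
    "silencing": ("methylation", "expression"),
    "signatures": ("mutations",),
    "summarize": ("mutations",),
}


class ConfigurationError(ValueError):
    pass


def _cohort_from_config(config: dict):
    if "synthetic" in config:
        spec = dict(config["synthetic"])
        subtypes = [SubtypeSpec(**s) for s in spec.pop("subtypes", [])]
        cfg = CohortConfig(subtypes=subtypes, seed=int(config.get("seed", 0)), **spec)
        return generate_cohort(cfg)
    if "inputs" in config:
        paths = config["inputs"]
        from .synthetic import OmicsCohort  # assembled, not generated

        return OmicsCohort(
            expression=io_formats.read_matrix(paths["expression"], "expression"),
            methylation=io_formats.read_matrix(
                paths["methylation"], "methylation", paths["probe_annotation"]
            ),
            copy_number=io_formats.read_matrix(paths["copy_number"], "copy_number"),
            mutations=io_formats.read_mutations(paths["mutations"]),
            samples=pd.read_csv(paths["samples"], sep="\t", index_col=0),
            truth={},
        )
    raise ConfigurationError("config must provide a 'synthetic' spec or 'inputs' paths")


def _validate(config: dict, stages: list[str]) -> None:
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    has_data = "synthetic" in config or "inputs" in config
    for stage in stages:
        if stage == "generate":
            if "synthetic" not in config:
                raise ConfigurationError("stage 'generate' needs a 'synthetic' spec")
            continue
        if _REQUIRES.get(stage) and not has_data:
            raise ConfigurationError(
                f"stage {stage!r} requires {_REQUIRES[stage]} but the config names "
                "neither a synthetic spec nor input paths"
            )
        if _REQUIRES.get(stage) and "inputs" in config:
            missing = [r for r in _REQUIRES[stage] if r not in config["inputs"]]
            if missing:
                raise ConfigurationError(
                    f"stage {stage!r} requires inputs {missing} not named in config"
                )


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Execute the configured stages and write outputs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    _validate(config, stages)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": stages,
        "outputs": {},
    }

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, []).append(str(path.relative_to(outdir)))

    cohort = None
    filtered = None
    assignments = []

    def need_cohort():
        nonlocal cohort
        if cohort is None:
            cohort = _cohort_from_config(config)
        return cohort

    for stage in stages:
        log.info("stage %s", stage)
        try:
            if stage == "generate":
                ch = need_cohort()
                io_formats.write_matrix(ch.expression, outdir / "expression.tsv")
                io_formats.write_matrix(
                    ch.methylation, outdir / "methylation.tsv",
                    annotation_path=outdir / "probe_annotation.tsv",
                )
                io_formats.write_matrix(ch.copy_number, outdir / "copy_number.tsv")
                io_formats.write_mutations(ch.mutations, outdir / "mutations.maf.tsv")
                ch.samples.to_csv(outdir / "samples.tsv", sep="\t")
                with open(outdir / "truth.json", "w") as fh:
                    json.dump(ch.truth, fh, indent=2, default=str)
                for f in ("expression.tsv", "methylation.tsv", "probe_annotation.tsv",
                          "copy_number.tsv", "mutations.maf.tsv", "samples.tsv",
                          "truth.json"):
                    emit(stage, f, outdir / f)
            elif stage == "filter":
                ch = need_cohort()
                opts = config.get("filter", {})
                comp = liver_compendium(ch, seed=seed) if ch.truth else None
                if comp is None:
                    raise ConfigurationError("filter stage needs a tissue compendium")
                gene_list = derive_tissue_specific_genes(
                    comp, opts.get("tissue", "liver"),
                    min_fold=opts.get("min_fold", 50.0),
                    min_level=opts.get("min_level", 1.0),
                )
                filtered = filter_genes(ch.expression, gene_list)
                gene_list.to_frame().to_csv(outdir / "tissue_genes.tsv", sep="\t", index=False)
                io_formats.write_matrix(filtered, outdir / "expression.filtered.tsv")
                emit(stage, "tissue_genes.tsv", outdir / "tissue_genes.tsv")
                emit(stage, "expression.filtered.tsv", outdir / "expression.filtered.tsv")
            elif stage == "subtype":
                ch = need_cohort()
                opts = config.get("subtype", {})
                expr = filtered if filtered is not None else ch.expression
                top = select_top_variable(expr, opts.get("fraction", 0.02))
                _, assign = pca_cluster(
                    top, n_components=opts.get("n_components", 5), k=opts.get("k", 3)
                )
                assignments.append(assign)
                io_formats.write_assignment(assign, outdir / "mrna_clusters.tsv")
                emit(stage, "mrna_clusters.tsv", outdir / "mrna_clusters.tsv")
                disc = discriminant_genes(
                    expr, assign.labels,
                    selection_rule=("top", opts.get("n_discriminant", 200)),
                )
                disc.to_frame().to_csv(outdir / "discriminant_genes.tsv", sep="\t", index=False)
                emit(stage, "discriminant_genes.tsv", outdir / "discriminant_genes.tsv")
            elif stage == "score":
                ch = need_cohort()
                opts = config.get("score", {})
                genesets = (
                    io_formats.read_genesets(opts["genesets"])
                    if "genesets" in opts
                    else {"planted_up": list(ch.truth.get("diff_genes", {}).get(
                        next(iter(ch.truth.get("diff_genes", {})), ""), {}))}
                )
                genesets = {k: v for k, v in genesets.items() if v}
                if genesets:
                    table = score_signatures(ch.expression, genesets)
                    table.to_csv(outdir / "signature_scores.tsv", sep="\t")
                    emit(stage, "signature_scores.tsv", outdir / "signature_scores.tsv")
            elif stage == "cluster":
                ch = need_cohort()
                opts = config.get("cluster", {})
                scna = select_recurrent_scna(ch.copy_number, seed=seed)
                scna.table.to_csv(outdir / "recurrent_scna.tsv", sep="\t", index=False)
                emit(stage, "recurrent_scna.tsv", outdir / "recurrent_scna.tsv")
                loci = scna.loci or list(ch.copy_number.loci)
                cn_assign, cn_cons = consensus_cluster(
                    ch.copy_number.values.loc[loci],
                    k_range=opts.get("k_range", (2, 3, 4)),
                    n_reps=opts.get("n_reps", 50),
                    seed=seed, platform="copy_number",
                )
                assignments.append(cn_assign)
                io_formats.write_assignment(cn_assign, outdir / "cn_clusters.tsv")
                cn_cons.to_csv(outdir / "cn_consensus.tsv", sep="\t")
                emit(stage, "cn_clusters.tsv", outdir / "cn_clusters.tsv")
                emit(stage, "cn_consensus.tsv", outdir / "cn_consensus.tsv")
                if ch.normal_methylation is not None:
                    cpgs = select_cancer_cpgs(ch.methylation, ch.normal_methylation)
                    probe_sel = cpgs.probes or list(ch.methylation.probes)
                else:
                    probe_sel = list(ch.methylation.probes)
                meth_assign, meth_cons = consensus_cluster(
                    ch.methylation.betas.loc[probe_sel],
                    k_range=opts.get("k_range", (2, 3, 4)),
                    n_reps=opts.get("n_reps", 50),
                    seed=seed, platform="methylation",
                )
                assignments.append(meth_assign)
                io_formats.write_assignment(meth_assign, outdir / "meth_clusters.tsv")
                meth_cons.to_csv(outdir / "meth_consensus.tsv", sep="\t")
                emit(stage, "meth_clusters.tsv", outdir / "meth_clusters.tsv")
                emit(stage, "meth_consensus.tsv", outdir / "meth_consensus.tsv")
            elif stage == "coca":
                if len(assignments) < 2:
                    for name in ("mrna_clusters.tsv", "cn_clusters.tsv", "meth_clusters.tsv"):
                        if (outdir / name).exists():
                            assignments.append(io_formats.read_assignment(outdir / name))
                if len(assignments) < 2:
                    raise ConfigurationError(
                        "coca requires the subtype and cluster stages to run first "
                        "(in this run or in the same output directory)"
                    )
                opts = config.get("coca", {})
                result = coca(
                    assignments,
                    k_range=opts.get("k_range", (2, 3, 4, 5)),
                    n_reps=opts.get("n_reps", 50),
                    seed=seed,
                )
                io_formats.write_assignment(result, outdir / "coca_clusters.tsv")
                emit(stage, "coca_clusters.tsv", outdir / "coca_clusters.tsv")
            elif stage == "silencing":
                ch = need_cohort()
                opts = config.get("silencing", {})
                group_col = opts.get("group_column", "subtype")
                group_value = opts.get("group_value")
                if group_value is None:
                    group_value = sorted(ch.samples[group_col].unique())[0]
                mask = ch.samples[group_col] == group_value
                result = intersect_hyper_down(
                    ch.methylation, ch.expression, mask,
                    purity=ch.samples.get("purity"),
                    purity_cutoff=opts.get("purity_cutoff", 0.65),
                    delta_beta_min=opts.get("delta_beta_min", 0.2),
                    q_max=opts.get("q_max", 0.05),
                    rho_max=opts.get("rho_max", -0.3),
                )
                result.table.to_csv(outdir / "silenced_genes.tsv", sep="\t")
                emit(stage, "silenced_genes.tsv", outdir / "silenced_genes.tsv")
            elif stage == "signatures":
                ch = need_cohort()
                sig_path = config.get("signatures", {}).get("matrix")
                if sig_path:
                    sig = pd.read_csv(sig_path, sep="\t", index_col=0)
                else:
                    from .synthetic import example_signature_matrix

                    sig = example_signature_matrix()
                est = fit_signature_exposures(ch.mutations, sig)
                est.exposures.rename("exposure").to_frame().assign(
                    enriched=est.enriched
                ).to_csv(outdir / "signature_exposures.tsv", sep="\t")
                emit(stage, "signature_exposures.tsv", outdir / "signature_exposures.tsv")
            elif stage == "summarize":
                ch = need_cohort()
                opts = config.get("summarize", {})
                summary = summarize_cohort(
                    ch,
                    features_of_interest=opts.get("features"),
                    callable_mb=opts.get("callable_mb"),
                )
                summary.prevalences.to_csv(outdir / "cohort_summary.tsv", sep="\t")
                emit(stage, "cohort_summary.tsv", outdir / "cohort_summary.tsv")
        except (ValidationError, ConfigurationError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    io_formats.write_manifest(outdir, manifest)
    return outdir
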