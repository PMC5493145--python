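"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates a small tumor cohort profiled on four platforms — log2 expression,
CpG methylation betas, copy-number log-ratios, and MAF-like somatic
mutations — with the statistical structure the downstream analyses assume:

* planted sample subtypes, each with subtype-specific differential genes,
  promoter-hypermethylated probes (coupled to downregulation of their target
  genes), copy-number events, and driver-mutation probabilities;
* a set of stromal (normal liver) genes expressed orders of magnitude higher
  in normal tissue than in tumor cells, mixed into each sample in linear
  space according to a per-sample contamination fraction — the confound that
  dominates naive most-variable-gene clustering;
* per-sample tumor purity, distinct from contamination (DNA purity does not
  capture stromal admixture of the transcriptome);
* trinucleotide mutation spectra drawn from a known mixture of mutational
  signatures.

Every planted effect is recorded in a truth ledger so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import (
    CopyNumberMatrix,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    ValidationError,
)

__all__ = [
    "SubtypeSpec",
    "CohortConfig",
    "OmicsCohort",
    "generate_cohort",
    "generate_mutations",
    "liver_compendium",
    "trinucleotide_contexts",
    "example_signature_matrix",
]


def trinucleotide_contexts() -> list[str]:
    """The 96 pyrimidine-centred trinucleotide substitution contexts."""
    subs = [("C", alt) for alt in "AGT"] + [("T", alt) for alt in "ACG"]
    return [
        f"{five}[{ref}>{alt}]{three}"
        for ref, alt in subs
        for five in "ACGT"
        for three in "ACGT"
    ]


def example_signature_matrix() -> pd.DataFrame:
    """A small column-stochastic context x signature matrix.

    Three stylized processes: spontaneous deamination at CpG sites
    (C>T in a NpCpG context), a flat clock-like background, and a
    C>A-dominated process.
    """
    contexts = trinucleotide_contexts()
    n = len(contexts)
    sigs = pd.DataFrame(0.0, index=contexts, columns=["cpg_ct", "flat", "c_to_a"])
    cpg = [c for c in contexts if "[C>T]G" in c]
    sigs.loc[cpg, "cpg_ct"] = 0.8 / len(cpg)
    sigs["cpg_ct"] += 0.2 / n
    sigs["flat"] = 1.0 / n
    c_to_a = [c for c in contexts if "[C>A]" in c]
    sigs.loc[c_to_a, "c_to_a"] = 0.9 / len(c_to_a)
    sigs["c_to_a"] += 0.1 / n
    return sigs / sigs.sum(axis=0)


@dataclass
class SubtypeSpec:
    """Planted effects defining one sample subtype."""

    name: str
    proportion: float
    n_diff_genes: int = 40
    expr_log2_effect: float = 2.0
    n_silenced_genes: int = 0       # genes with coupled hypermethylation + downregulation
    probes_per_silenced_gene: int = 2
    n_hyper_probes: int = 40        # additional subtype-specific hypermethylated probes
    beta_shift: float = 0.3
    n_cn_loci: int = 20
    cn_log_ratio: float = 0.0       # signed; 0 disables the event
    driver_genes: dict[str, float] = field(default_factory=dict)  # gene -> P(mutated)
    mtdna_mean: float = 200.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Distributions are given as ``("uniform", lo, hi)``, ``("constant", v)``
    or ``("beta", a, b)`` tuples; contamination and purity are fractions in
    [0, 1].  ``stromal_fold_range`` is the linear-scale fold by which stromal
    genes are higher in normal tissue than in tumor cells.
    """

    n_samples: int = 38
    n_genes: int = 2000
    n_probes: int = 600
    n_loci: int = 200
    subtypes: list[SubtypeSpec] = field(default_factory=list)
    n_stromal_genes: int = 200
    stromal_fold_range: tuple[float, float] = (1_000.0, 20_000.0)
    contamination: tuple = ("uniform", 0.0, 0.3)
    purity: tuple = ("uniform", 0.55, 0.95)
    noise_sd: float = 0.5
    beta_concentration: float = 60.0   # Beta-distribution dispersion knob
    promoter_fraction: float = 0.3     # promoter rate among unplanted probes
    mean_mutations: float = 49.0
    nonsilent_fraction: float = 0.66
    signature_matrix: pd.DataFrame | None = None
    exposures: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.subtypes:
            self.subtypes = [
                SubtypeSpec("idh_like", 0.2, n_silenced_genes=6, n_cn_loci=20,
                            cn_log_ratio=-1.0, driver_genes={"IDH1": 0.9},
                            mtdna_mean=350.0),
                SubtypeSpec("ecc_like", 0.3, n_cn_loci=20, cn_log_ratio=0.0,
                            driver_genes={"TP53": 0.4}),
                SubtypeSpec("fgfr2_like", 0.5, n_cn_loci=20, cn_log_ratio=1.0,
                            driver_genes={"FGFR2": 0.5}, mtdna_mean=120.0),
            ]
        if self.signature_matrix is None:
            self.signature_matrix = example_signature_matrix()
        if self.exposures is None:
            k = self.signature_matrix.shape[1]
            self.exposures = np.full(k, 1.0 / k)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.validate()

    def validate(self) -> None:
        props = np.array([s.proportion for s in self.subtypes], dtype=float)
        if (props <= 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"subtype proportions must be positive and sum to 1, got {props.tolist()}"
            )
        lo, hi = self.stromal_fold_range
        if not (1.0 <= lo <= hi <= 1e6):
            raise ValidationError(f"stromal_fold_range {self.stromal_fold_range} outside [1, 1e6]")
        if (self.exposures < 0).any() or abs(self.exposures.sum() - 1.0) > 1e-9:
            raise ValidationError("exposure vector must be non-negative and sum to 1")
        if len(self.exposures) != self.signature_matrix.shape[1]:
            raise ValidationError(
                f"{len(self.exposures)} exposures for "
                f"{self.signature_matrix.shape[1]} signature columns"
            )
        colsums = self.signature_matrix.sum(axis=0).to_numpy()
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValidationError("signature matrix columns must sum to 1")
        need_probes = sum(
            s.n_silenced_genes * s.probes_per_silenced_gene + s.n_hyper_probes
            for s in self.subtypes
        )
        if need_probes > self.n_probes:
            raise ValidationError(
                f"planted effects need {need_probes} probes but n_probes={self.n_probes}"
            )
        drivers = {g for s in self.subtypes for g in s.driver_genes}
        need_genes = len(drivers) + self.n_stromal_genes + sum(
            s.n_diff_genes + s.n_silenced_genes for s in self.subtypes
        )
        if need_genes > self.n_genes:
            raise ValidationError(
                f"planted effects need {need_genes} genes but n_genes={self.n_genes}"
            )
        need_loci = sum(s.n_cn_loci for s in self.subtypes)
        if need_loci > self.n_loci:
            raise ValidationError(
                f"planted events need {need_loci} loci but n_loci={self.n_loci}"
            )


@dataclass
class OmicsCohort:
    """One generated cohort: per-platform matrices, annotations, truth ledger."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    copy_number: CopyNumberMatrix
    mutations: MutationTable
    samples: pd.DataFrame
    truth: dict
    normal_methylation: MethylationMatrix | None = None

    def __post_init__(self) -> None:
        ids = list(self.samples.index)
        for mat, name in [
            (self.expression.samples, "expression"),
            (self.methylation.samples, "methylation"),
            (self.copy_number.samples, "copy number"),
        ]:
            if list(mat) != ids:
                raise ValidationError(f"{name} matrix sample set differs from annotation")


def _draw(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        return np.full(n, float(dist[1]))
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=n)
    raise ValidationError(f"unknown distribution {dist!r}")


def _subtype_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact largest-remainder allocation of samples to subtypes, shuffled."""
    props = np.array([s.proportion for s in config.subtypes])
    raw = props * config.n_samples
    counts = np.floor(raw).astype(int)
    remainder = config.n_samples - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat([s.name for s in config.subtypes], counts)
    return rng.permutation(labels)


def generate_cohort(config: CohortConfig) -> OmicsCohort:
    """Generate a full multi-omics cohort; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    driver_universe = sorted({g for s in config.subtypes for g in s.driver_genes})
    genes = driver_universe + genes[: config.n_genes - len(driver_universe)]
    probes = [f"cg{i:05d}" for i in range(config.n_probes)]
    loci = [f"L{i:04d}" for i in range(config.n_loci)]

    subtype = _subtype_labels(config, rng)
    contamination = _draw(config.contamination, config.n_samples, rng)
    purity = _draw(config.purity, config.n_samples, rng)

    # ---- gene bookkeeping: stromal genes, then disjoint per-subtype blocks
    non_driver = [g for g in genes if g not in driver_universe]
    shuffled = list(rng.permutation(non_driver))
    stromal_genes = shuffled[: config.n_stromal_genes]
    cursor = config.n_stromal_genes
    diff_genes: dict[str, dict[str, float]] = {}
    silenced_genes: dict[str, list[str]] = {}
    for spec in config.subtypes:
        block = shuffled[cursor: cursor + spec.n_diff_genes]
        cursor += spec.n_diff_genes
        signs = rng.choice([-1.0, 1.0], size=len(block))
        diff_genes[spec.name] = {g: s * spec.expr_log2_effect for g, s in zip(block, signs)}
        sil = shuffled[cursor: cursor + spec.n_silenced_genes]
        cursor += spec.n_silenced_genes
        silenced_genes[spec.name] = sil
    if cursor > len(shuffled):
        raise ValidationError("n_genes too small for the planted effects requested")

    # ---- expression: linear-space mixture of tumor signal and stromal signal
    base_log2 = rng.uniform(3.0, 8.0, size=len(genes))
    base = pd.Series(base_log2, index=genes)
    folds = pd.Series(
        rng.uniform(*config.stromal_fold_range, size=len(stromal_genes)),
        index=stromal_genes,
    )
    # Planted subtype effects are applied on the observed log2 scale, after
    # the stromal mixture, so a planted effect is realized as the stated
    # group difference in the delivered matrix.
    effect_log2 = pd.DataFrame(0.0, index=genes, columns=samples)
    silencing_latent = pd.Series(0.0, index=samples)
    for spec in config.subtypes:
        members = [s for s, lab in zip(samples, subtype) if lab == spec.name]
        for g, eff in diff_genes[spec.name].items():
            effect_log2.loc[g, members] += eff
        if spec.n_silenced_genes:
            # per-sample silencing dose (mean 1) couples the methylation gain
            # to the expression loss without biasing the planted effect size
            latent = rng.uniform(0.85, 1.15, size=len(members))
            silencing_latent.loc[members] = latent
            for g in silenced_genes[spec.name]:
                effect_log2.loc[g, members] -= spec.expr_log2_effect * latent
    tumor_lin = np.power(2.0, np.tile(base.to_numpy()[:, None], (1, config.n_samples)))
    normal_lin = np.power(2.0, base.to_numpy())[:, None] * np.ones((1, config.n_samples))
    stromal_idx = [genes.index(g) for g in stromal_genes]
    normal_lin[stromal_idx, :] *= folds.to_numpy()[:, None]
    mix = tumor_lin * (1.0 - contamination)[None, :] + normal_lin * contamination[None, :]
    expr_values = (
        np.log2(mix + 1.0)
        + effect_log2.to_numpy()
        + rng.normal(0.0, config.noise_sd, size=mix.shape)
    )
    expression = ExpressionMatrix(pd.DataFrame(expr_values, index=genes, columns=samples))

    # ---- methylation: Beta-distributed betas around planted means.
    # Betas are purity-adjusted (tumor-cell scale), so a planted shift is
    # realized as the stated group difference in the observed matrix.
    probe_base = rng.uniform(0.05, 0.4, size=config.n_probes)
    unplanted = shuffled[cursor:] or shuffled
    probe_gene = list(rng.choice(unplanted, size=config.n_probes))
    promoter = rng.random(config.n_probes) < config.promoter_fraction
    mu = np.tile(probe_base[:, None], (1, config.n_samples))
    pcursor = 0
    hyper_probes: dict[str, list[str]] = {}
    silenced_probe_map: dict[str, list[str]] = {}
    for spec in config.subtypes:
        member_mask = subtype == spec.name
        assigned: list[str] = []
        for g in silenced_genes[spec.name]:
            for _ in range(spec.probes_per_silenced_gene):
                probe_gene[pcursor] = g
                promoter[pcursor] = True
                mu[pcursor, member_mask] += spec.beta_shift * silencing_latent.loc[
                    np.array(samples)[member_mask]
                ].to_numpy()
                silenced_probe_map.setdefault(g, []).append(probes[pcursor])
                assigned.append(probes[pcursor])
                pcursor += 1
        # additional subtype-wide hypermethylation is planted outside
        # promoters (CIMP-like body/intergenic methylation); only the
        # silencing probes above carry promoter hypermethylation
        block = list(range(pcursor, pcursor + spec.n_hyper_probes))
        pcursor += spec.n_hyper_probes
        for j in block:
            promoter[j] = False
            mu[j, member_mask] += spec.beta_shift
            assigned.append(probes[j])
        hyper_probes[spec.name] = assigned
    if pcursor > config.n_probes:
        raise ValidationError("n_probes too small for the planted effects requested")
    mu = np.clip(mu, 0.02, 0.98)
    nu = config.beta_concentration
    betas = rng.beta(mu * nu, (1.0 - mu) * nu)
    betas = np.clip(betas, 0.0, 1.0)
    annotation = pd.DataFrame(
        {
            "gene": probe_gene,
            "promoter": promoter,
            "chrom": [f"chr{1 + i % 22}" for i in range(config.n_probes)],
            "pos": np.arange(config.n_probes) * 1000,
        },
        index=pd.Index(probes, name="probe"),
    )
    methylation = MethylationMatrix(pd.DataFrame(betas, index=probes, columns=samples), annotation)
    normal_mu = np.clip(probe_base, 0.02, 0.98)
    n_normals = max(8, config.n_samples // 4)
    normal_betas = rng.beta(
        np.tile(normal_mu[:, None], (1, n_normals)) * nu,
        np.tile((1.0 - normal_mu)[:, None], (1, n_normals)) * nu,
    )
    normal_methylation = MethylationMatrix(
        pd.DataFrame(normal_betas, index=probes,
                     columns=[f"N{i:03d}" for i in range(n_normals)]),
        annotation,
    )

    # ---- copy number: planted subtype events over diploid noise
    cn = rng.normal(0.0, 0.15, size=(config.n_loci, config.n_samples))
    lcursor = 0
    cn_loci: dict[str, list[str]] = {}
    for spec in config.subtypes:
        block = loci[lcursor: lcursor + spec.n_cn_loci]
        lcursor += spec.n_cn_loci
        cn_loci[spec.name] = block
        if spec.cn_log_ratio:
            member_mask = subtype == spec.name
            rows = slice(lcursor - spec.n_cn_loci, lcursor)
            cn[rows, member_mask] += spec.cn_log_ratio * purity[member_mask]
    copy_number = CopyNumberMatrix(pd.DataFrame(cn, index=loci, columns=samples))

    # ---- mutations and per-sample annotations
    mutations = generate_mutations(
        config, rng=rng, samples=samples, subtype_of=dict(zip(samples, subtype)),
        gene_universe=non_driver[: max(50, len(non_driver) // 4)],
    )
    mtdna = np.empty(config.n_samples)
    driver_status = pd.DataFrame(False, index=samples, columns=driver_universe or ["none"])
    if not driver_universe:
        driver_status = driver_status.drop(columns=["none"])
    for i, spec in enumerate(config.subtypes):
        member_mask = subtype == spec.name
        mtdna[member_mask] = rng.normal(spec.mtdna_mean, 30.0, size=member_mask.sum())
    for g in driver_universe:
        hit = mutations.records.query("gene == @g and effect_class == 'non-silent'")["sample"]
        driver_status.loc[driver_status.index.isin(set(hit)), g] = True
    annotations = pd.DataFrame(
        {
            "subtype": subtype,
            "purity": purity,
            "contamination": contamination,
            "mtdna_copies": np.clip(mtdna, 10.0, None),
        },
        index=pd.Index(samples, name="sample"),
    )
    for g in driver_universe:
        annotations[f"{g}_mutant"] = driver_status[g].to_numpy()

    truth = {
        "stromal_genes": list(stromal_genes),
        "stromal_folds": folds.to_dict(),
        "diff_genes": diff_genes,
        "silenced_genes": silenced_genes,
        "silenced_probes": silenced_probe_map,
        "hyper_probes": hyper_probes,
        "cn_loci": cn_loci,
        "subtype_of": dict(zip(samples, subtype)),
        "exposures": dict(zip(config.signature_matrix.columns, config.exposures)),
        "base_log2": base.to_dict(),
    }
    return OmicsCohort(
        expression=expression,
        methylation=methylation,
        copy_number=copy_number,
        mutations=mutations,
        samples=annotations,
        truth=truth,
        normal_methylation=normal_methylation,
    )


def generate_mutations(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
    subtype_of: dict[str, str] | None = None,
    gene_universe: list[str] | None = None,
) -> MutationTable:
    """Draw a MAF-like mutation table from the configured signature mixture.

    Per-sample mutation counts are Poisson with mean ``config.mean_mutations``;
    trinucleotide contexts follow the mixture ``signature_matrix @ exposures``;
    a ``nonsilent_fraction`` of records are coding-relevant.  When a subtype
    map is supplied, subtype driver genes acquire hotspot non-silent
    mutations with their configured probabilities.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if samples is None:
        samples = [f"S{i:03d}" for i in range(config.n_samples)]
    if gene_universe is None:
        gene_universe = [f"G{i:04d}" for i in range(min(500, config.n_genes))]
    contexts = list(config.signature_matrix.index)
    p = config.signature_matrix.to_numpy() @ config.exposures
    p = p / p.sum()

    rows: list[dict] = []
    for s in samples:
        n = rng.poisson(config.mean_mutations)
        if n:
            ctx = rng.choice(contexts, size=n, p=p)
            gidx = rng.integers(0, len(gene_universe), size=n)
            nonsilent = rng.random(n) < config.nonsilent_fraction
            for j in range(n):
                rows.append(
                    {
                        "sample": s,
                        "gene": gene_universe[gidx[j]],
                        "protein_change": f"p.X{int(rng.integers(1, 900))}Y",
                        "effect_class": "non-silent" if nonsilent[j] else "silent",
                        "context": ctx[j],
                        "hotspot": False,
                    }
                )
        if subtype_of is not None:
            spec = next(t for t in config.subtypes if t.name == subtype_of[s])
            for gene, prob in spec.driver_genes.items():
                if rng.random() < prob:
                    rows.append(
                        {
                            "sample": s,
                            "gene": gene,
                            "protein_change": "p.R132C",
                            "effect_class": "non-silent",
                            "context": str(rng.choice(contexts, p=p)),
                            "hotspot": True,
                        }
                    )
    columns = ["sample", "gene", "protein_change", "effect_class", "context", "hotspot"]
    return MutationTable(pd.DataFrame(rows, columns=columns))


def liver_compendium(
    cohort: OmicsCohort,
    tissues: tuple[str, ...] = ("liver", "lung", "kidney", "colon", "breast", "brain"),
    jitter_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a normal-tissue median-expression compendium consistent with the
    cohort's planted stromal genes.

    Every gene sits near its tumor baseline in every tissue; the planted
    stromal genes additionally carry their true linear fold in the liver
    column.  Returned as a gene x tissue log2 DataFrame, the input shape the
    tissue-specific gene derivation expects.
    """
    rng = np.random.default_rng(seed)
    base = pd.Series(cohort.truth["base_log2"])
    comp = pd.DataFrame(
        {t: base + rng.normal(0.0, jitter_sd, size=len(base)) for t in tissues},
        index=base.index,
    )
    folds = pd.Series(cohort.truth["stromal_folds"])
    comp.loc[folds.index, "liver"] = base.loc[folds.index] + np.log2(folds)
    return comp
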