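"""Synthetic postmortem-cohort generator.

Emulates the statistical structure of a multi-study case/control brain
RNA-seq compendium: negative-binomial counts with library-size variation,
nuisance covariates (source dataset, sex, age, postmortem interval, brain
region), a small set of condition-associated genes sharing downregulation
across a subset of regions (a hub transcription factor plus an
immediate-early-gene block), latent-factor co-expression modules whose
activity shifts with condition, and a gene-set collection in which only a
few pathways carry label information.

Every draw flows from a single root seed through per-operation child
streams, so pathways, metadata and counts can be regenerated independently
and reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from mddpipe.io import GeneSetCollection

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DEGeneSpec",
    "ModuleSpec",
    "PathwaySpec",
    "scaled_default_config",
    "generate_pathways",
    "generate_metadata",
    "generate_counts",
    "generate_null_cohort",
]

REGIONS = ("AnCg", "aINS", "Cg25", "DLPFC", "nACC", "OFC", "vSUB")

#: (n_control, n_case) per region, mirroring the published cohort's
#: distribution of 216 control / 241 case samples over seven regions.
DEFAULT_REGION_SIZES: dict[str, tuple[int, int]] = {
    "AnCg": (24, 23),
    "aINS": (22, 26),
    "Cg25": (15, 13),
    "DLPFC": (71, 79),
    "nACC": (43, 51),
    "OFC": (22, 25),
    "vSUB": (19, 24),
}

CTRL, CASE = "CTRL", "CASE"

# Demographics: (mean, sd) of age in years and PMI in hours, and the female
# fraction, per condition — cosmetic realism for the nuisance covariates.
_AGE = {CTRL: (47.66, 15.18), CASE: (46.78, 15.21)}
_PMI = {CTRL: (24.08, 16.22), CASE: (26.32, 16.24)}
_FEMALE_FRAC = {CTRL: 62 / 216, CASE: 103 / 241}

# child-stream indices off the root seed
_STREAM_PATHWAYS, _STREAM_METADATA, _STREAM_COUNTS = 0, 1, 2


@dataclass(frozen=True)
class DEGeneSpec:
    """A gene planted differentially expressed in a subset of regions.

    ``base_log2`` optionally pins the gene's baseline log2 abundance
    (condition-associated genes in the emulated study are well expressed;
    a gene drawn at the detection floor could never be the finding).
    """

    gene: str
    log2fc: float
    regions: tuple[str, ...]
    base_log2: float | None = None


@dataclass(frozen=True)
class ModuleSpec:
    """A latent-factor co-expression module.

    Member genes load (uniform loadings in [0.6, 1]) on a per-sample factor
    f_s ~ Normal(condition_shift * 1[case in shift_regions], latent_sd), on
    the log2 scale.  ``shift_regions=None`` applies the condition shift in
    every region; the latent (co-expression) part is always global.
    """

    genes: tuple[str, ...]
    latent_sd: float = 1.2
    condition_shift: float = -0.6
    shift_regions: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PathwaySpec:
    """Gene-set collection layout and which sets carry label signal.

    Genes belonging to the informative pathways receive an additional
    ``informative_effect`` log2 shift in case samples (all regions).
    """

    n_pathways: int = 30
    genes_per_pathway: int = 20
    informative_pathway_ids: tuple[int, ...] = (0, 1, 2)
    #: per-gene log2 case shift: weak enough that individual genes rarely
    #: clear per-region DE thresholds, while the grouped signal remains
    #: learnable by the pathway-kernel classifier
    informative_effect: float = -0.3


def _default_de_genes() -> tuple[DEGeneSpec, ...]:
    common3 = ("DLPFC", "nACC", "vSUB")
    # the hub: a well-expressed activity-dependent transcription factor
    specs = [DEGeneSpec("G0000", -1.0, common3, base_log2=7.0)]
    # immediate-early-gene block: co-downregulated, but not in all three
    specs += [DEGeneSpec(f"G{i:04d}", -0.8, ("DLPFC", "nACC")) for i in range(1, 5)]
    dlpfc_lfcs = [-2.0, -1.5, -1.2, -1.0, -0.8, -0.6, 0.6, 0.8, 1.0, 1.2, -0.7, -0.9]
    specs += [
        DEGeneSpec(f"G{i + 5:04d}", lfc, ("DLPFC",)) for i, lfc in enumerate(dlpfc_lfcs)
    ]
    specs += [DEGeneSpec("G0017", -0.9, ("nACC",)), DEGeneSpec("G0018", 0.8, ("nACC",))]
    specs += [DEGeneSpec("G0019", -1.2, ("vSUB",))]
    return tuple(specs)


def _default_modules() -> tuple[ModuleSpec, ...]:
    # condition shift confined to the three affected regions, matching the
    # emulated finding that module activity differs only where the hub does;
    # sizes mirror the two modules of the emulated study (128 and 60 genes)
    affected = ("DLPFC", "nACC", "vSUB")
    m1 = tuple(f"G{i:04d}" for i in range(100, 228))
    m2 = tuple(f"G{i:04d}" for i in range(300, 360))
    # shift -0.35: strong enough for class-labelled enrichment over the
    # pooled affected regions, weak enough that individual module genes
    # rarely clear per-region DE thresholds in the smaller regions (the
    # hub stays the sole three-region gene)
    return (
        ModuleSpec(m1, latent_sd=1.2, condition_shift=-0.35,
                   shift_regions=affected),
        ModuleSpec(m2, latent_sd=1.2, condition_shift=-0.35,
                   shift_regions=affected),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generative configuration; defaults encode the emulated study design."""

    n_genes: int = 1000
    samples_per_region: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SIZES)
    )
    n_datasets: int = 3
    de_genes: tuple[DEGeneSpec, ...] = field(default_factory=_default_de_genes)
    module_specs: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    pathway_specs: PathwaySpec = field(default_factory=PathwaySpec)
    nb_dispersion: float = 0.1
    libsize_log_sd: float = 0.3
    base_log2_mean: float = 5.0
    base_log2_sd: float = 2.0
    covariate_effect_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "dataset": 0.10,
            "sex": 0.05,
            "age": 0.05,
            "pmi": 0.05,
            "region": 0.10,
        }
    )
    seed: int = 0

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.samples_per_region)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_datasets <= 0:
            raise ValueError("n_datasets must be positive")
        for region, (nc, nm) in self.samples_per_region.items():
            if nc <= 0 or nm <= 0:
                raise ValueError(f"region {region!r}: sample counts must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be non-negative")
        universe = set(self.gene_ids)
        regions = set(self.regions)
        for spec in self.de_genes:
            if spec.gene not in universe:
                raise ValueError(f"de gene {spec.gene!r} outside gene universe")
            if not set(spec.regions) <= regions:
                raise ValueError(f"de gene {spec.gene!r}: unknown region")
            if not np.isfinite(spec.log2fc):
                raise ValueError(f"de gene {spec.gene!r}: non-finite log2fc")
        for spec in self.module_specs:
            if not set(spec.genes) <= universe:
                raise ValueError("module gene outside gene universe")
            if spec.shift_regions is not None and not set(spec.shift_regions) <= regions:
                raise ValueError("module shift_regions outside region set")
        ps = self.pathway_specs
        if ps.n_pathways < 0 or ps.genes_per_pathway < 0:
            raise ValueError("pathway counts must be non-negative")
        if ps.n_pathways and ps.genes_per_pathway > self.n_genes:
            raise ValueError("genes_per_pathway exceeds n_genes")
        if not set(ps.informative_pathway_ids) <= set(range(max(ps.n_pathways, 1))):
            raise ValueError("informative_pathway_ids out of range")

    def zeroed(self) -> "SimConfig":
        """Copy with all condition-linked effects removed (null conditions)."""
        return replace(
            self,
            de_genes=(),
            module_specs=tuple(
                replace(m, condition_shift=0.0) for m in self.module_specs
            ),
            pathway_specs=replace(self.pathway_specs, informative_effect=0.0),
        )


@dataclass
class GroundTruth:
    """Record of all planted structure, for recovery oracles."""

    true_de: list[tuple[str, str, float]]  # (gene, region, log2fc)
    true_modules: list[set[str]]
    informative_pathways: set[str]
    sample_labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "true_de": [list(t) for t in self.true_de],
            "true_modules": [sorted(m) for m in self.true_modules],
            "informative_pathways": sorted(self.informative_pathways),
            "sample_labels": self.sample_labels,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            true_de=[tuple(t) for t in obj["true_de"]],
            true_modules=[set(m) for m in obj["true_modules"]],
            informative_pathways=set(obj["informative_pathways"]),
            sample_labels=obj["sample_labels"],
        )


def scaled_default_config(n_genes: int = 1000, seed: int = 0) -> SimConfig:
    """Default study structure rescaled to a smaller/larger gene universe.

    Planted DE genes keep their identities (they occupy the first 20
    slots); module sizes scale with the universe (12.8% and 6%, the
    proportions of the default 1000-gene layout) and pathway sizes shrink
    on tiny universes.
    """
    if n_genes >= 400:
        base = SimConfig(n_genes=n_genes, seed=seed)
        if n_genes == 1000:
            return base
    if n_genes < 40:
        raise ValueError("scaled default config needs at least 40 genes")
    m1_size = max(10, round(0.128 * n_genes))
    m2_size = max(8, round(0.06 * n_genes))
    m1_start = max(20, round(0.10 * n_genes))
    m2_start = m1_start + m1_size + max(5, round(0.05 * n_genes))
    if m2_start + m2_size > n_genes:
        raise ValueError("gene universe too small for the default modules")
    affected = ("DLPFC", "nACC", "vSUB")
    modules = (
        ModuleSpec(tuple(f"G{i:04d}" for i in range(m1_start, m1_start + m1_size)),
                   latent_sd=1.2, shift_regions=affected),
        ModuleSpec(tuple(f"G{i:04d}" for i in range(m2_start, m2_start + m2_size)),
                   latent_sd=1.2, shift_regions=affected),
    )
    pathways = PathwaySpec(genes_per_pathway=min(20, max(5, n_genes // 10)))
    return SimConfig(
        n_genes=n_genes, seed=seed, module_specs=modules, pathway_specs=pathways
    )


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def pathway_name(i: int) -> str:
    return f"PW{i:03d}"


def generate_pathways(config: SimConfig) -> GeneSetCollection:
    """Draw the gene-set collection (KEGG-pathway stand-ins).

    Informative pathways are drawn first from the full gene universe; decoy
    pathways are drawn from the remaining genes so that the planted label
    signal stays attributable to the informative sets.  Decoys may overlap
    each other.
    """
    config.validate()
    rng = _rng(config, _STREAM_PATHWAYS)
    ps = config.pathway_specs
    genes = np.asarray(config.gene_ids)
    coll = GeneSetCollection()
    if ps.n_pathways == 0:
        return coll
    informative = set(ps.informative_pathway_ids)
    informative_members: set[str] = set()
    members: dict[int, list[str]] = {}
    for i in sorted(informative):
        chosen = rng.choice(genes, size=ps.genes_per_pathway, replace=False)
        members[i] = [str(g) for g in chosen]
        informative_members.update(members[i])
    decoy_pool = np.asarray([g for g in genes if g not in informative_members])
    for i in range(ps.n_pathways):
        if i in members:
            continue
        pool = decoy_pool if len(decoy_pool) >= ps.genes_per_pathway else genes
        chosen = rng.choice(pool, size=ps.genes_per_pathway, replace=False)
        members[i] = [str(g) for g in chosen]
    for i in range(ps.n_pathways):
        desc = "informative" if i in informative else "decoy"
        coll.add(pathway_name(i), members[i], desc)
    return coll


def generate_metadata(config: SimConfig) -> pd.DataFrame:
    """Per-sample condition labels and nuisance covariates.

    Case/control counts per region are exact (stratification is
    deterministic); ages, PMIs, sexes and dataset assignments are seeded
    draws around the cohort demographics.
    """
    config.validate()
    rng = _rng(config, _STREAM_METADATA)
    rows = []
    idx = 0
    for region, (n_ctrl, n_case) in config.samples_per_region.items():
        for condition, n in ((CTRL, n_ctrl), (CASE, n_case)):
            for _ in range(n):
                age_mu, age_sd = _AGE[condition]
                pmi_mu, pmi_sd = _PMI[condition]
                age = stats.truncnorm.rvs(
                    -age_mu / age_sd, np.inf, loc=age_mu, scale=age_sd, random_state=rng
                )
                pmi = stats.truncnorm.rvs(
                    -pmi_mu / pmi_sd, np.inf, loc=pmi_mu, scale=pmi_sd, random_state=rng
                )
                sex = "F" if rng.random() < _FEMALE_FRAC[condition] else "M"
                dataset = f"D{rng.integers(config.n_datasets)}"
                rows.append(
                    {
                        "sample_id": f"S{idx:04d}",
                        "condition": condition,
                        "dataset": dataset,
                        "sex": sex,
                        "age": round(float(age), 2),
                        "pmi": round(float(pmi), 2),
                        "region": region,
                    }
                )
                idx += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(
    config: SimConfig,
    metadata: pd.DataFrame,
    pathways: GeneSetCollection | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw NB counts for the configured cohort.

    The log2 mean for gene g in sample s is

        a_g + log2(s_s) + x_s . beta_g + case_s * (lfc_{g,region} + inf_g)
            + sum_m loading_{g,m} * f_{s,m}

    with a_g a baseline abundance, s_s a lognormal library factor, beta_g
    per-gene nuisance covariate effects, planted region-specific condition
    effects, informative-pathway shifts, and latent module factors.  Counts
    are NB with Var = mu + alpha * mu^2.
    """
    config.validate()
    if len(metadata) == 0:
        raise ValueError("metadata is empty")
    rng = _rng(config, _STREAM_COUNTS)
    genes = config.gene_ids
    G, n = len(genes), len(metadata)
    gene_index = {g: i for i, g in enumerate(genes)}

    a = rng.normal(config.base_log2_mean, config.base_log2_sd, size=G)
    for spec in config.de_genes:
        if spec.base_log2 is not None:
            a[gene_index[spec.gene]] = spec.base_log2
    log2mu = np.tile(a[:, None], (1, n)).astype(np.float64)

    # library sizes (lognormal, natural-log sd)
    libsize = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))
    log2mu += np.log2(libsize)[None, :]

    sds = config.covariate_effect_sds
    case = (metadata["condition"] == CASE).to_numpy()

    # categorical nuisance effects: per (gene, level), reference level 0
    for col in ("dataset", "sex", "region"):
        sd = float(sds.get(col, 0.0))
        levels = sorted(metadata[col].unique())
        for level in levels[1:]:
            beta = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)
            mask = (metadata[col] == level).to_numpy()
            log2mu[:, mask] += beta[:, None]

    # numeric nuisance effects on standardized covariates
    for col in ("age", "pmi"):
        sd = float(sds.get(col, 0.0))
        x = metadata[col].to_numpy(dtype=float)
        xz = (x - x.mean()) / (x.std() + 1e-12)
        beta = rng.normal(0.0, sd, size=G) if sd > 0 else np.zeros(G)
        log2mu += beta[:, None] * xz[None, :]

    # planted condition effects per (gene, region)
    true_de: list[tuple[str, str, float]] = []
    for spec in config.de_genes:
        gi = gene_index[spec.gene]
        for region in spec.regions:
            mask = case & (metadata["region"] == region).to_numpy()
            log2mu[gi, mask] += spec.log2fc
            true_de.append((spec.gene, region, spec.log2fc))

    # informative-pathway shift (all regions)
    ps = config.pathway_specs
    informative_names = {pathway_name(i) for i in ps.informative_pathway_ids}
    if pathways is not None and ps.informative_effect != 0.0:
        inf_genes = set()
        for name in informative_names & set(pathways.names()):
            inf_genes.update(pathways[name])
        for g in inf_genes:
            if g in gene_index:
                log2mu[gene_index[g], case] += ps.informative_effect

    # latent module factors
    true_modules: list[set[str]] = []
    region_arr = metadata["region"].to_numpy()
    for spec in config.module_specs:
        loadings = rng.uniform(0.6, 1.0, size=len(spec.genes))
        if spec.shift_regions is None:
            shifted = case
        else:
            shifted = case & np.isin(region_arr, list(spec.shift_regions))
        f = rng.normal(0.0, spec.latent_sd, size=n) + spec.condition_shift * shifted
        for g, l in zip(spec.genes, loadings):
            log2mu[gene_index[g]] += l * f
        true_modules.append(set(spec.genes))

    if not np.all(np.isfinite(log2mu)) or np.max(log2mu) > 40:
        raise ValueError("non-finite or overflowing NB mean; check effect sizes")

    mu = np.exp2(log2mu)
    alpha = config.nb_dispersion
    if alpha < 1e-10:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(genes, name="gene_id"),
        columns=metadata.index,
    )
    truth = GroundTruth(
        true_de=true_de,
        true_modules=true_modules,
        informative_pathways=informative_names
        if (pathways is not None and ps.informative_effect != 0.0)
        else set(),
        sample_labels=metadata["condition"].to_dict(),
    )
    return counts_df, truth


def generate_null_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection, GroundTruth]:
    """Full cohort with every condition-linked effect zeroed.

    Nuisance structure (covariates, library sizes, latent module
    correlation) is retained; the labels carry no signal.
    """
    null_config = config.zeroed()
    pathways = generate_pathways(null_config)
    metadata = generate_metadata(null_config)
    counts, truth = generate_counts(null_config, metadata, pathways)
    return counts, metadata, pathways, truth
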