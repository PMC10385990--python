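"""Synthetic multi-species study generator with planted ground truth.

Every downstream stage of the pipeline is testable offline against studies
produced here: negative-binomial count matrices for two-group contrasts in
several species, ortholog tables into a common reference gene space, gene
set collections with planted enriched sets, and a paired
transcriptome/metabolome reference with planted gene–metabolite
correlations.

Gene identifier scheme (auditable by construction): species-level genes are
``<SPECIES>_g<k>`` and map to reference gene ``G<k>``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigmeta import io

DEFAULT_SPECIES = (
    "hsapiens",
    "mmusculus",
    "celegans",
    "drerio",
    "gmorhua",
    "msalmoides",
    "ppromelas",
)

# 30+25+15+10+10+10+10 = 110 contrasts, mirroring the uneven species
# representation of a realistic multi-study corpus.
DEFAULT_CONTRASTS = (30, 25, 15, 10, 10, 10, 10)

_TISSUES = ("liver", "ovary", "embryo", "blood", "whole_body")
_COMPOUNDS = ("PFOA", "PFOS", "PFNA", "PFBS", "HFPO-DA")

# Baseline expression model: gene means are log-normal, log-mean 5 /
# log-sd 1.5 (natural log) — standard RNA-seq-like marginal behaviour.
_BASELINE_LOG_MEAN = 5.0
_BASELINE_LOG_SD = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic multi-species study."""

    species_list: tuple[str, ...] = DEFAULT_SPECIES
    contrasts_per_species: tuple[int, ...] = DEFAULT_CONTRASTS
    genes_per_species: int = 2000
    n_replicates: int = 5
    n_conserved_up: int = 50
    n_conserved_down: int = 50
    effect_logfc: float = 2.0
    dispersion: float = 0.1
    ortholog_coverage: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species_list) != len(self.contrasts_per_species):
            raise ValueError("species_list and contrasts_per_species must align")
        if len(set(self.species_list)) != len(self.species_list):
            raise ValueError("species labels must be unique")
        if any(c < 1 for c in self.contrasts_per_species):
            raise ValueError("every species needs at least one contrast")
        if self.n_replicates < 3:
            raise ValueError(
                "n_replicates must be >= 3: contrasts require a balanced "
                "design with at least three replicates per group"
            )
        if self.genes_per_species < 1:
            raise ValueError("genes_per_species must be positive")
        n_ortho = self.n_orthologous_genes
        if self.n_conserved_up + self.n_conserved_down > n_ortho:
            raise ValueError(
                "more planted genes than orthologous genes "
                f"({self.n_conserved_up}+{self.n_conserved_down} > {n_ortho})"
            )
        if self.effect_logfc <= 0:
            raise ValueError("effect_logfc must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 < self.ortholog_coverage <= 1:
            raise ValueError("ortholog_coverage must be in (0, 1]")

    @property
    def n_orthologous_genes(self) -> int:
        """Number of genes guaranteed an ortholog in every species."""
        return int(round(self.ortholog_coverage * self.genes_per_species))

    @property
    def n_contrasts(self) -> int:
        return int(sum(self.contrasts_per_species))


@dataclass
class ContrastData:
    """One two-group contrast: counts, group labels, annotation."""

    contrast_id: str
    species: str
    tissue: str
    compound: str
    counts: pd.DataFrame  # genes × samples, nonnegative ints
    groups: pd.Series  # sample -> {"control", "treated"}


@dataclass
class SyntheticStudy:
    """A full synthetic corpus plus its planted truth."""

    config: SimulationConfig
    contrasts: list[ContrastData]
    orthologs: dict[str, pd.DataFrame]  # species -> (source_gene, target_gene, score)
    truth: pd.Series  # reference gene -> {"up", "down", "null"}

    @property
    def contrast_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [c.species for c in self.contrasts],
                "tissue": [c.tissue for c in self.contrasts],
                "compound": [c.compound for c in self.contrasts],
            },
            index=pd.Index([c.contrast_id for c in self.contrasts], name="contrast_id"),
        )

    def planted_genes(self, direction: str) -> list[str]:
        return sorted(self.truth.index[self.truth == direction])


@dataclass
class GeneSetCollection:
    """Named gene sets over reference identifiers, with optional truth."""

    sets: dict[str, tuple[str, ...]]
    source: str | None = None
    truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PairedReference:
    """Expression and metabolite matrices over the same ordered samples."""

    expression: pd.DataFrame  # genes × samples (log-scale)
    metabolites: pd.DataFrame  # metabolites × samples
    truth: dict[str, dict[str, int]]  # metabolite -> {gene: sign}

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.metabolites.columns):
            raise ValueError("expression and metabolite samples must match in order")
        if self.expression.shape[1] < 10:
            raise ValueError("paired reference requires at least 10 samples")


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, n: int
) -> np.ndarray:
    """Negative-binomial draws: mean ``mu``, variance ``mu + d*mu^2``."""
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p[:, None], size=(mu.size, n))


def generate_multispecies_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate count matrices, ortholog tables and a planted truth table.

    Planted "up"/"down" genes are shifted by ``±effect_logfc`` (log2) in the
    treated group of *every* contrast, consistently on the reference-gene
    side of the ortholog map; all other genes have zero expected log fold
    change.  Identical config (including seed) reproduces the study
    bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.genes_per_species
    ref_genes = np.array([f"G{i + 1}" for i in range(n_genes)])

    # Orthologous genes are a fixed prefix-independent random subset shared
    # in index by all species; planted genes are drawn from it so every
    # planted reference gene is reachable from every species.
    ortho_idx = np.sort(
        rng.choice(n_genes, size=config.n_orthologous_genes, replace=False)
    )
    planted_idx = rng.choice(
        ortho_idx,
        size=config.n_conserved_up + config.n_conserved_down,
        replace=False,
    )
    up_idx = np.sort(planted_idx[: config.n_conserved_up])
    down_idx = np.sort(planted_idx[config.n_conserved_up :])

    truth = pd.Series("null", index=pd.Index(ref_genes, name="gene"), dtype=object)
    truth.iloc[up_idx] = "up"
    truth.iloc[down_idx] = "down"

    log2_shift = np.zeros(n_genes)
    log2_shift[up_idx] = config.effect_logfc
    log2_shift[down_idx] = -config.effect_logfc

    contrasts: list[ContrastData] = []
    orthologs: dict[str, pd.DataFrame] = {}
    n_rep = config.n_replicates

    for species, n_contrasts in zip(config.species_list, config.contrasts_per_species):
        gene_ids = np.array([f"{species}_g{i + 1}" for i in range(n_genes)])
        orthologs[species] = pd.DataFrame(
            {
                "source_gene": gene_ids[ortho_idx],
                "target_gene": ref_genes[ortho_idx],
                "score": np.round(rng.uniform(1.0, 15.0, size=ortho_idx.size), 3),
            }
        )
        baseline = rng.lognormal(_BASELINE_LOG_MEAN, _BASELINE_LOG_SD, size=n_genes)
        mu_treated = baseline * np.exp2(log2_shift)

        for j in range(n_contrasts):
            cid = f"{species}_c{j + 1}"
            tissue = _TISSUES[rng.integers(len(_TISSUES))]
            compound = _COMPOUNDS[rng.integers(len(_COMPOUNDS))]
            ctrl = _nb_counts(rng, baseline, config.dispersion, n_rep)
            trt = _nb_counts(rng, mu_treated, config.dispersion, n_rep)
            samples = [f"{cid}_ctrl{r + 1}" for r in range(n_rep)] + [
                f"{cid}_trt{r + 1}" for r in range(n_rep)
            ]
            counts = pd.DataFrame(
                np.hstack([ctrl, trt]),
                index=pd.Index(gene_ids, name="gene"),
                columns=samples,
            )
            groups = pd.Series(
                ["control"] * n_rep + ["treated"] * n_rep,
                index=counts.columns,
                name="group",
            )
            contrasts.append(
                ContrastData(cid, species, tissue, compound, counts, groups)
            )

    return SyntheticStudy(config, contrasts, orthologs, truth)


def generate_gene_sets(
    study: SyntheticStudy,
    n_sets: int,
    set_size: int,
    n_enriched: int,
    seed: int,
    enriched_fraction: float = 0.8,
) -> GeneSetCollection:
    """Build a gene set collection with ``n_enriched`` planted-enriched sets.

    Enriched sets draw at least ``enriched_fraction`` of their members from
    the planted up- (even sets) or down- (odd sets) regulated genes; the
    remaining sets are uniform random draws over reference genes.  The
    ``truth`` attribute records the planted direction per enriched set.
    """
    if n_enriched > n_sets:
        raise ValueError(f"n_enriched ({n_enriched}) exceeds n_sets ({n_sets})")
    ref_genes = np.asarray(study.truth.index)
    if set_size > ref_genes.size:
        raise ValueError("set_size exceeds the number of reference genes")

    rng = np.random.default_rng(seed)
    up = np.asarray(study.planted_genes("up"))
    down = np.asarray(study.planted_genes("down"))
    null = np.asarray(sorted(study.truth.index[study.truth == "null"]))

    sets: dict[str, tuple[str, ...]] = {}
    truth: dict[str, str] = {}
    n_core = math.ceil(enriched_fraction * set_size)
    for i in range(n_enriched):
        direction = "up" if i % 2 == 0 else "down"
        pool = up if direction == "up" else down
        if n_core > pool.size:
            raise ValueError(
                f"not enough planted {direction} genes ({pool.size}) for a "
                f"{n_core}-gene enriched core"
            )
        core = rng.choice(pool, size=n_core, replace=False)
        filler = rng.choice(null, size=set_size - n_core, replace=False)
        name = f"SET_{direction.upper()}_{i + 1}"
        sets[name] = tuple(np.concatenate([core, filler]))
        truth[name] = direction
    for i in range(n_sets - n_enriched):
        name = f"SET_RANDOM_{i + 1}"
        sets[name] = tuple(rng.choice(ref_genes, size=set_size, replace=False))

    return GeneSetCollection(sets=sets, source="synthetic", truth=truth)


def generate_reference_paired_dataset(
    n_genes: int,
    n_metabolites: int,
    n_samples: int,
    genes_per_metabolite: int,
    rho: float,
    seed: int,
) -> PairedReference:
    """Generate a paired transcriptome/metabolome reference.

    Each metabolite gets a disjoint block of ``genes_per_metabolite``
    reference genes whose expression correlates with it at expected
    |Spearman| ≈ ``rho``; every other gene is independent of it.  Gene
    identifiers live in the reference space (``G<k>``) so fitted models
    apply directly to mapped signatures.
    """
    if n_samples < 10:
        raise ValueError(
            "n_samples must be >= 10: correlation estimates are unstable below this"
        )
    if genes_per_metabolite > n_genes:
        raise ValueError("genes_per_metabolite exceeds n_genes")
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if n_metabolites * genes_per_metabolite > n_genes:
        raise ValueError("planted gene blocks exceed the gene universe")

    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    metabolites = [f"M{i + 1}" for i in range(n_metabolites)]

    latent = rng.standard_normal((n_metabolites, n_samples))
    expr = rng.standard_normal((n_genes, n_samples))
    truth: dict[str, dict[str, int]] = {}
    for m in range(n_metabolites):
        block = slice(m * genes_per_metabolite, (m + 1) * genes_per_metabolite)
        noise = rng.standard_normal((genes_per_metabolite, n_samples))
        expr[block] = rho * latent[m] + math.sqrt(1.0 - rho**2) * noise
        truth[metabolites[m]] = {genes[g]: +1 for g in range(*block.indices(n_genes))}

    expression = pd.DataFrame(
        expr + 8.0, index=pd.Index(genes, name="gene"), columns=samples
    )
    metab = pd.DataFrame(
        3.0 * latent + 10.0,
        index=pd.Index(metabolites, name="metabolite"),
        columns=samples,
    )
    return PairedReference(expression=expression, metabolites=metab, truth=truth)


# ---------------------------------------------------------------------------
# serialization


def write_study(study: SyntheticStudy, outdir: str | os.PathLike) -> None:
    """Write a study as plain TSV files (counts, metadata, orthologs, truth)."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    meta_rows = []
    for contrast in study.contrasts:
        io.write_tsv(
            contrast.counts, os.path.join(outdir, f"counts_{contrast.contrast_id}.tsv")
        )
        for sample in contrast.counts.columns:
            meta_rows.append(
                {
                    "contrast_id": contrast.contrast_id,
                    "species": contrast.species,
                    "tissue": contrast.tissue,
                    "compound": contrast.compound,
                    "sample": sample,
                    "group": contrast.groups[sample],
                }
            )
    io.write_tsv(
        pd.DataFrame(meta_rows), os.path.join(outdir, "metadata.tsv"), index=False
    )
    for species, table in study.orthologs.items():
        io.write_tsv(
            table, os.path.join(outdir, f"orthologs_{species}.tsv"), index=False
        )
    io.write_tsv(study.truth.to_frame("direction"), os.path.join(outdir, "truth.tsv"))


def write_paired_reference(
    ref: PairedReference, expression_path: str | os.PathLike,
    metabolite_path: str | os.PathLike,
) -> None:
    io.write_tsv(ref.expression, expression_path)
    io.write_tsv(ref.metabolites, metabolite_path)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    """Write a GeneSetCollection in standard GMT format."""
    desc = collection.source or "na"
    io.write_lines(
        ("\t".join([name, desc, *genes]) for name, genes in collection.sets.items()),
        path,
    )
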