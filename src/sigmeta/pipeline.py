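"""Config-driven orchestration of the full analysis.

Stages run in dependency order: simulate/load → differential expression →
signatures → ortholog mapping → signature matrix → correlation →
gene-level integration → pathway enrichment → metabolite prediction.
Every output is a TSV with a '#' metadata header naming the parameters;
identical config + seed reproduces every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from sigmeta import __version__, designature, enrich, integrate, io, metabopredict
from sigmeta import orthomap as om
from sigmeta import simmatrix, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; mirrors the CLI flags and YAML keys."""

    outdir: str = "sigmeta_out"
    seed: int = 0

    # input routes; when counts_dir is None the synthetic generator is used
    counts_dir: str | None = None
    gmt: str | None = None
    reference_expression: str | None = None
    reference_metabolites: str | None = None

    # synthetic-data parameters (used when simulating)
    simulate: dict = field(default_factory=dict)
    n_sets: int = 60
    set_size: int = 20
    n_enriched: int = 4
    n_metabolites: int = 40
    genes_per_metabolite: int = 10
    reference_samples: int = 120
    reference_rho: float = 0.7

    # stage toggles
    run_correlation: bool = True
    run_enrichment: bool = True
    run_metabolites: bool = True

    # numeric parameters
    min_overlap: int = simmatrix.DEFAULT_MIN_OVERLAP
    min_species: int = integrate.DEFAULT_MIN_SPECIES
    z_hi: float = integrate.DEFAULT_Z_HI
    z_lo: float = integrate.DEFAULT_Z_LO
    sd_cut: float = integrate.DEFAULT_SD_CUT
    n_perm: int = 1000
    k: int = metabopredict.DEFAULT_K
    min_set_size: int = enrich.DEFAULT_MIN_SIZE
    max_set_size: int = enrich.DEFAULT_MAX_SIZE
    evalue_cutoff: float = om.DEFAULT_EVALUE_CUTOFF
    metabolite_species: str | None = None  # None = reference species only

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for path in (
            self.counts_dir,
            self.gmt,
            self.reference_expression,
            self.reference_metabolites,
        ):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"configured path does not exist: {path}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")

    def parameter_hash(self) -> str:
        params = dataclasses.asdict(self)
        params.pop("outdir")  # location does not affect results
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    signature_matrix: designature.SignatureMatrix
    correlation: simmatrix.CorrelationMatrix | None
    integrated_genes: pd.DataFrame
    integrated_pathways: pd.DataFrame | None
    enrichment_tables: dict[str, pd.DataFrame]
    metabolite_predictions: pd.DataFrame | None
    integrated_metabolites: pd.DataFrame | None
    qc: pd.DataFrame
    mapping_report: pd.DataFrame
    manifest: dict


def qc_report(de_tables: dict[str, pd.DataFrame], threshold: int = 10) -> pd.DataFrame:
    """Per-contrast count of genes significant at p <= 0.05.

    Contrasts with ``threshold`` or fewer significant genes are flagged:
    a usable contrast is expected to yield more than 10 differentially
    expressed genes.
    """
    rows = []
    for cid, de in de_tables.items():
        n_sig = int((de["pvalue"] <= 0.05).sum()) if len(de) else 0
        rows.append(
            {"contrast_id": cid, "n_significant": n_sig, "flagged": n_sig <= threshold}
        )
    return pd.DataFrame(rows).set_index("contrast_id")


def _stage(name: str):
    """Log stage timing and re-raise failures naming the stage."""

    class _StageContext:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - self.t0)
            return False

    return _StageContext()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all enabled stages and write result tables under outdir."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    meta_header = {
        "sigmeta_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
    }
    logger.info("run: seed=%d hash=%s", config.seed, config.parameter_hash())
    seeds = np.random.SeedSequence(config.seed).spawn(4)

    def child_seed(seq: np.random.SeedSequence) -> int:
        return int(seq.generate_state(1)[0])

    with _stage("inputs"):
        study, contrasts, ortho_tables, gene_sets, paired = _load_inputs(
            config, child_seed(seeds[0])
        )

    with _stage("differential_expression"):
        de_tables = {
            c.contrast_id: designature.compute_differential_expression(
                c.counts, c.groups
            )
            for c in contrasts
        }
        qc = qc_report(de_tables)

    with _stage("signatures"):
        signatures = [
            designature.signature_from_de(
                de_tables[c.contrast_id],
                contrast_id=c.contrast_id,
                species=c.species,
                tissue=c.tissue,
                compound=c.compound,
            )
            for c in contrasts
        ]

    with _stage("ortholog_mapping"):
        mapped, reports = [], []
        for sig in signatures:
            table = ortho_tables[sig.species]
            ref_sig, report = om.map_signature_to_reference(sig, table)
            mapped.append(ref_sig)
            reports.append(report.to_dict())
        mapping_report = pd.DataFrame(reports).set_index("contrast_id")

    with _stage("signature_matrix"):
        matrix = designature.build_signature_matrix(mapped)
        weights = integrate.species_balanced_weights(matrix.meta)

    correlation = None
    if config.run_correlation:
        with _stage("correlation"):
            correlation = simmatrix.pairwise_correlation(
                matrix, min_overlap=config.min_overlap
            )

    with _stage("gene_integration"):
        integrated_genes = integrate.integrate_signature_matrix(
            matrix,
            weights=weights,
            min_species=config.min_species,
            z_hi=config.z_hi,
            z_lo=config.z_lo,
            sd_cut=config.sd_cut,
        )

    enrichment_tables: dict[str, pd.DataFrame] = {}
    integrated_pathways = None
    if config.run_enrichment and gene_sets is not None:
        with _stage("enrichment"):
            gsea_seed = child_seed(seeds[1])
            for sig in mapped:
                enrichment_tables[sig.contrast_id] = enrich.gsea_contrast(
                    sig,
                    gene_sets,
                    n_perm=config.n_perm,
                    min_size=config.min_set_size,
                    max_size=config.max_set_size,
                    seed=gsea_seed,
                )
            integrated_pathways = enrich.integrate_pathways(
                enrichment_tables, weights
            )

    metabolite_predictions = None
    integrated_metabolites = None
    if config.run_metabolites and paired is not None:
        with _stage("metabolites"):
            model = metabopredict.fit_metabolite_model(paired, k=config.k)
            target_species = config.metabolite_species or _reference_species(matrix)
            msigs = [s for s in mapped if s.species == target_species]
            if not msigs:
                raise ValueError(
                    f"no contrasts for metabolite species {target_species!r}"
                )
            met_seed = child_seed(seeds[2])
            preds = {
                s.contrast_id: metabopredict.predict_metabolites(
                    s, model, n_perm=config.n_perm, seed=met_seed
                )
                for s in msigs
            }
            metabolite_predictions = pd.DataFrame(preds)
            met_weights = weights.reindex(metabolite_predictions.columns)
            integrated_metabolites = metabopredict.integrate_metabolites(
                preds, met_weights
            )

    manifest = {
        **meta_header,
        "n_contrasts": len(contrasts),
        "n_genes_integrated": len(integrated_genes),
        "config": dataclasses.asdict(config),
    }

    result = PipelineResult(
        signature_matrix=matrix,
        correlation=correlation,
        integrated_genes=integrated_genes,
        integrated_pathways=integrated_pathways,
        enrichment_tables=enrichment_tables,
        metabolite_predictions=metabolite_predictions,
        integrated_metabolites=integrated_metabolites,
        qc=qc,
        mapping_report=mapping_report,
        manifest=manifest,
    )
    with _stage("write_outputs"):
        _write_outputs(result, config, meta_header, study)
    return result


def _reference_species(matrix: designature.SignatureMatrix) -> str:
    """Default metabolite-stage species: the first listed (reference) one."""
    return matrix.meta["species"].iloc[0]


def _load_inputs(config: PipelineConfig, sim_seed: int):
    """Either simulate a study or load user-provided inputs."""
    if config.counts_dir is None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        for key in ("species_list", "contrasts_per_species"):
            if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_config = simulate.SimulationConfig(**sim_kwargs)
        study = simulate.generate_multispecies_study(sim_config)
        contrasts = study.contrasts
        ortho_tables = study.orthologs
        if config.gmt is not None:
            gene_sets = enrich.parse_gmt(config.gmt)
        else:
            gene_sets = simulate.generate_gene_sets(
                study,
                n_sets=config.n_sets,
                set_size=config.set_size,
                n_enriched=config.n_enriched,
                seed=sim_seed,
            )
        if config.reference_expression and config.reference_metabolites:
            paired = _load_paired(config)
        else:
            paired = simulate.generate_reference_paired_dataset(
                n_genes=sim_config.genes_per_species,
                n_metabolites=config.n_metabolites,
                n_samples=config.reference_samples,
                genes_per_metabolite=config.genes_per_metabolite,
                rho=config.reference_rho,
                seed=sim_seed + 1,
            )
        return study, contrasts, ortho_tables, gene_sets, paired

    meta = io.read_metadata(os.path.join(config.counts_dir, "metadata.tsv"))
    contrasts = []
    ortho_tables = {}
    for cid, rows in meta.groupby("contrast_id", sort=True):
        counts = io.read_counts(os.path.join(config.counts_dir, f"counts_{cid}.tsv"))
        first = rows.iloc[0]
        contrasts.append(
            simulate.ContrastData(
                contrast_id=cid,
                species=first["species"],
                tissue=first["tissue"],
                compound=first["compound"],
                counts=counts,
                groups=rows.set_index("sample")["group"].reindex(counts.columns),
            )
        )
    for species in meta["species"].unique():
        path = os.path.join(config.counts_dir, f"orthologs_{species}.tsv")
        ortho_tables[species] = om.load_ortholog_table(path)
    gene_sets = enrich.parse_gmt(config.gmt) if config.gmt else None
    paired = (
        _load_paired(config)
        if config.reference_expression and config.reference_metabolites
        else None
    )
    return None, contrasts, ortho_tables, gene_sets, paired


def _load_paired(config: PipelineConfig) -> simulate.PairedReference:
    expr = io.read_tsv(config.reference_expression, index_col=0)
    metab = io.read_tsv(config.reference_metabolites, index_col=0)
    shared = [s for s in expr.columns if s in set(metab.columns)]
    return simulate.PairedReference(
        expression=expr[shared], metabolites=metab[shared], truth={}
    )


def _write_outputs(result, config, meta_header, study) -> None:
    out = config.outdir
    io.write_tsv(
        result.signature_matrix.values,
        os.path.join(out, "signature_matrix.tsv"),
        metadata=meta_header,
    )
    io.write_tsv(
        result.signature_matrix.meta,
        os.path.join(out, "contrast_metadata.tsv"),
        metadata=meta_header,
    )
    io.write_tsv(
        result.integrated_genes,
        os.path.join(out, "integrated_genes.tsv"),
        metadata={
            **meta_header,
            "z_hi": config.z_hi,
            "z_lo": config.z_lo,
            "sd_cut": config.sd_cut,
            "min_species": config.min_species,
        },
    )
    io.write_tsv(result.qc, os.path.join(out, "qc_report.tsv"), metadata=meta_header)
    io.write_tsv(
        result.mapping_report,
        os.path.join(out, "mapping_report.tsv"),
        metadata=meta_header,
    )
    if result.correlation is not None:
        io.write_tsv(
            result.correlation.r,
            os.path.join(out, "correlation_matrix.tsv"),
            metadata={**meta_header, "min_overlap": config.min_overlap},
        )
        io.write_tsv(
            result.correlation.to_long(),
            os.path.join(out, "correlation_long.tsv"),
            metadata={**meta_header, "min_overlap": config.min_overlap},
            index=False,
        )
    if result.integrated_pathways is not None:
        io.write_tsv(
            result.integrated_pathways,
            os.path.join(out, "integrated_pathways.tsv"),
            metadata={**meta_header, "n_perm": config.n_perm},
        )
        long = pd.concat(
            {cid: t for cid, t in result.enrichment_tables.items()},
            names=["contrast_id", "set"],
        )
        io.write_tsv(
            long, os.path.join(out, "enrichment_per_contrast.tsv"), metadata=meta_header
        )
    if result.integrated_metabolites is not None:
        io.write_tsv(
            result.metabolite_predictions,
            os.path.join(out, "metabolite_predictions.tsv"),
            metadata=meta_header,
        )
        io.write_tsv(
            result.integrated_metabolites,
            os.path.join(out, "integrated_metabolites.tsv"),
            metadata=meta_header,
        )
    if study is not None:
        io.write_tsv(
            study.truth.to_frame("direction"),
            os.path.join(out, "simulation_truth.tsv"),
            metadata=meta_header,
        )
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
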