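"""Shared fixtures: small synthetic studies and derived signature matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigmeta import designature, orthomap, simulate


def study_signatures(study: simulate.SyntheticStudy) -> list:
    """DE → signature → ortholog mapping for every contrast of a study."""
    sigs = []
    for c in study.contrasts:
        de = designature.compute_differential_expression(c.counts, c.groups)
        sig = designature.signature_from_de(
            de,
            contrast_id=c.contrast_id,
            species=c.species,
            tissue=c.tissue,
            compound=c.compound,
        )
        mapped, _ = orthomap.map_signature_to_reference(sig, study.orthologs[c.species])
        sigs.append(mapped)
    return sigs


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        species_list=("alpha", "beta", "gamma"),
        contrasts_per_species=(2, 2, 2),
        genes_per_species=300,
        n_replicates=5,
        n_conserved_up=20,
        n_conserved_down=20,
        effect_logfc=2.0,
        dispersion=0.1,
        ortholog_coverage=0.95,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> simulate.SyntheticStudy:
    return simulate.generate_multispecies_study(small_config)


@pytest.fixture(scope="session")
def small_signatures(small_study):
    return study_signatures(small_study)


@pytest.fixture(scope="session")
def small_matrix(small_signatures) -> designature.SignatureMatrix:
    return designature.build_signature_matrix(small_signatures)


@pytest.fixture(scope="session")
def null_study() -> simulate.SyntheticStudy:
    config = simulate.SimulationConfig(
        species_list=("alpha", "beta"),
        contrasts_per_species=(3, 3),
        genes_per_species=400,
        n_conserved_up=0,
        n_conserved_down=0,
        seed=202,
    )
    return simulate.generate_multispecies_study(config)


@pytest.fixture(scope="session")
def null_matrix(null_study) -> designature.SignatureMatrix:
    return designature.build_signature_matrix(study_signatures(null_study))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_signature(
    scores: dict[str, float] | pd.Series, contrast_id: str = "c1", **meta
) -> designature.ContrastSignature:
    if isinstance(scores, dict):
        scores = pd.Series(scores)
    return designature.ContrastSignature(
        scores=scores.astype(float), contrast_id=contrast_id, **meta
    )
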