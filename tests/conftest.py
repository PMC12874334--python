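"""Shared fixtures: one full-size synthetic study and one light study per
session, plus a written-to-disk copy for file-round-trip tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lungomics import expression as ex
from lungomics import integration as ig
from lungomics import methylation as mm
from lungomics.simulate import SimulationConfig, simulate_study, write_study

LIGHT_KWARGS = dict(
    n_mutations_per_sample=10,
    n_decoys_per_sample=2,
    n_dbs_per_sample=2,
    n_indels_per_sample=2,
    n_germline_sites=2,
    n_shared_artifacts=2,
    n_clustered_artifacts=1,
)


def light_config(seed: int, **overrides) -> SimulationConfig:
    kwargs = {**LIGHT_KWARGS, **overrides}
    return SimulationConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def study():
    """Full default-size synthetic study (default mutation counts)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def light_study():
    """Light synthetic study for expression/methylation/integration tests."""
    return simulate_study(light_config(seed=11))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    """The full study written to disk (VCFs, matrices, truth)."""
    outdir = tmp_path_factory.mktemp("study")
    paths = write_study(study, outdir)
    return outdir, paths


def run_integration_chain(bundle):
    """The pipeline's integration path as composed stage calls.

    simulate -> DE (normal) -> site differential (normal) -> promoter map ->
    DMG derivation -> quadrants -> inverse-correlation screen.  Returns the
    integration record table.
    """
    design = bundle.design
    filtered = ex.filter_low_counts(bundle.counts)
    de = ex.nb_wald_de(filtered, design, "normal")
    sd = mm.site_differential(bundle.beta, design, "normal")
    pmap = ig.build_promoter_map(
        bundle.annotation, {c: len(s) for c, s in bundle.reference.items()}
    )
    dmgs = ig.derive_dmgs(sd, bundle.cpg_coords, pmap)
    rec = ig.classify_quadrants(dmgs, de)
    pbeta = ig.promoter_beta_from_sites(bundle.beta, sd, bundle.cpg_coords, pmap)
    tmm = ex.tmm_factors(filtered)
    lib = filtered.sum(axis=0)
    norm_expr = np.log2(filtered / (lib * tmm) * 1e6 + 1.0)
    hdm = design.index[
        (design["tissue"] == "normal") & (design["treatment"] == "HDM")
    ]
    return ig.inverse_correlation_filter(rec, pbeta, norm_expr, hdm)
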