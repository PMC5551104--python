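"""Shared fixtures: a small synthetic landscape and fitted models.

Everything is generated at test time from fixed seeds; no stored data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coarsesdm import (EnvStack, GridSpec, MaxentModel, VirtualSpecies,
                       build_all_treatments, derive_bioclim, filter_records,
                       fit_pca, generate_counties, generate_monthly_climate,
                       normalize_layers, sample_background,
                       sample_occurrences, select_components,
                       true_suitability)


@pytest.fixture(scope="session")
def landscape():
    """A 60x60 synthetic landscape with counties, bioclim, PCA, components."""
    spec = GridSpec(60, 60)
    monthly = generate_monthly_climate(spec, seed=101)
    partition = generate_counties(spec, split_x=30.0, mean_area_small=16,
                                  mean_area_large=160, seed=102)
    env = derive_bioclim(monthly)
    normalized, normalizer = normalize_layers(env)
    pca = fit_pca(normalized)
    components = select_components(pca, normalized)
    return {
        "spec": spec, "monthly": monthly, "partition": partition,
        "env": env, "normalized": normalized, "normalizer": normalizer,
        "pca": pca, "components": components,
    }


@pytest.fixture(scope="session")
def species_env(landscape):
    """3-layer niche space: the leading components of the landscape."""
    comps = landscape["components"]
    return EnvStack(spec=landscape["spec"], layers=comps.layers[:3],
                    layer_names=comps.layer_names[:3], mask=comps.mask)


@pytest.fixture(scope="session")
def background(landscape):
    return sample_background(landscape["components"], n_bg=800, seed=103)


@pytest.fixture(scope="session")
def fitted_models(landscape, species_env, background):
    """MaxEnt models for all five treatments of one virtual species.

    Returns (models, training_sets): the shared pool used by the KKT,
    threshold, and prediction-contract checks.
    """
    comps = landscape["components"]
    partition = landscape["partition"]
    sds = species_env.masked_matrix().std(axis=0)
    M = species_env.masked_matrix()
    center = M[np.random.default_rng(104).integers(M.shape[0])]
    vs = VirtualSpecies("fixture_species", center, 0.8 * sds, seed=105)
    occ = sample_occurrences(vs, species_env, partition, n=120, seed=106)
    occ = occ[~occ.duplicated(subset="county_id", keep="first")].head(25)
    occ = filter_records(occ.reset_index(drop=True), partition, min_records=10)
    assert len(occ) >= 10
    sets = build_all_treatments(occ, partition, comps, seed=107)
    models = {}
    for name, ts in sets.items():
        X = np.vstack([ts.X, background.X])
        y = np.r_[np.ones(ts.n), np.zeros(background.n)]
        models[name] = MaxentModel().fit(X, y)
    return models, sets
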