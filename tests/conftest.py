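from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netprox import (
    SyntheticScenario,
    build_interactome,
    lcc_zscore,
    make_degree_bins,
    proximity_zscore,
    rank_compounds,
    roc_auc,
    score_pairs,
)
from netprox.proximity import distance_matrix
from netprox.synthetic import generate_bundle

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def path_graph(*nodes):
    return build_interactome([(a, b) for a, b in zip(nodes, nodes[1:])])


def star_graph(center, leaves):
    return build_interactome([(center, leaf) for leaf in leaves])


@pytest.fixture(scope="session")
def toy_path():
    return path_graph("A", "B", "C", "D")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scenario synthetic bundle shared by cheap tests."""
    return generate_bundle(SyntheticScenario(seed=42))


@pytest.fixture(scope="session")
def default_screen():
    """Full proximity screen of the default scenario over 50 seeds.

    Per seed: z_closest for every compound, planted labels, and the top-8
    ranking.  Shared by the null-self-consistency and planted-recovery
    checks so the expensive part runs once.
    """
    out = []
    for seed in range(50):
        bundle = generate_bundle(SyntheticScenario(seed=seed))
        dmat = distance_matrix(bundle.interactome, sorted(bundle.disease.members))
        results = [
            proximity_zscore(
                bundle.interactome, ts, bundle.disease, bundle.bins,
                metric="closest", n_reps=1000, seed=1000 * seed + i, _dmat=dmat,
            )
            for i, ts in enumerate(bundle.compounds)
        ]
        out.append(
            {
                "z": {r.compound: r.z_closest for r in results},
                "labels": {name: t["label"] for name, t in bundle.truth["compounds"].items()},
                "top": [r.compound for r in rank_compounds(results, k=8)],
            }
        )
    return out


@pytest.fixture(scope="session")
def e2e_validation_aucs():
    """Pooled proximity-vs-indication ROC AUC of the default scenario,
    one AUC per seed for 20 seeds."""
    aucs = []
    for seed in range(20):
        bundle = generate_bundle(SyntheticScenario(seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = score_pairs(
                bundle.interactome,
                {c.name: c for c in bundle.compounds},
                bundle.disease_sets,
                bundle.associations,
                bundle.bins,
                n_reps=1000,
                seed=seed + 77,
            )
        labelled = [
            (scores[(c, d)], label == "therapeutic")
            for c, d, label in bundle.associations.rows
            if (c, d) in scores
        ]
        aucs.append(roc_auc([s for s, _ in labelled], [l for _, l in labelled]).auc)
    return aucs
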