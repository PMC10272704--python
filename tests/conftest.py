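"""Shared fixtures: small synthetic inputs and the two full study regimes.

The heavy session fixtures (`separable_runs`, `similar_runs`) each run the
complete method — simulate, preprocess, consensus, GCN training, baselines —
for five seeds under one differential-expression magnitude, and are shared
by several acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sclabelprop as slp
from sclabelprop.consensus import max_consensus
from sclabelprop.neighbor_majority import (
    propagate_neighbor_majority,
    select_neighbor_params,
)

SEEDS = (1, 2, 3, 4, 5)


def make_embedding(coords: np.ndarray) -> slp.PCAEmbedding:
    """Wrap raw coordinates as a PCAEmbedding (identity gene map)."""
    coords = np.asarray(coords, dtype=np.float64)
    d = coords.shape[1]
    return slp.PCAEmbedding(
        coords=coords,
        components=np.eye(d),
        gene_means=np.zeros(d),
        d=d,
    )


def full_run(de_facscale: float, seed: int, epochs: int = 150) -> dict:
    """One complete pass of the method on a fresh simulated dataset."""
    bench = slp.make_benchmark(slp.SimParams(de_facscale=de_facscale, seed=seed))
    filtered, cell_idx, gene_idx = slp.filter_counts(bench.sim.counts)
    norm = slp.lognormalize(filtered)
    emb = slp.pca_project(norm, 500, seed=seed)
    preds = bench.predictions.subset_cells(cell_idx)
    votes = slp.encode_votes(preds, bench.cell_types)
    labels = slp.confident_labels(votes)
    truth = bench.sim.true_labels[cell_idx]
    model, log = slp.train_gcn(
        emb, labels, slp.GCNConfig(epochs=epochs, seed=seed)
    )
    pred, _ = slp.predict_labels(model, emb)
    return {
        "bench": bench,
        "cell_idx": cell_idx,
        "truth": truth,
        "votes": votes,
        "labels": labels,
        "norm": norm,
        "embedding": emb,
        "model": model,
        "gcn_pred": pred,
        "max_consensus": max_consensus(votes),
        "seed": seed,
    }


@pytest.fixture(scope="session")
def separable_runs() -> list[dict]:
    """Five seeds in the well-separated regime (de_facscale = 2.0)."""
    runs = []
    for seed in SEEDS:
        run = full_run(2.0, seed)
        _, val_mask = slp.split_validation(run["labels"], 0.20, seed)
        k, _, _ = select_neighbor_params(
            run["embedding"], run["labels"], val_mask,
            strategies=("until_labeled",), seed=seed,
        )
        nm = propagate_neighbor_majority(
            run["embedding"], run["labels"], k, "until_labeled", seed=seed
        )
        run["nm_pred"] = nm.labels
        runs.append(run)
    return runs


@pytest.fixture(scope="session")
def similar_runs() -> list[dict]:
    """Five seeds in the transcriptionally similar regime (de_facscale = 0.4)."""
    runs = []
    for seed in SEEDS:
        run = full_run(0.4, seed)
        _, val_mask = slp.split_validation(run["labels"], 0.20, seed)
        k, strategy, _ = select_neighbor_params(
            run["embedding"], run["labels"], val_mask, seed=seed
        )
        nm = propagate_neighbor_majority(
            run["embedding"], run["labels"], k, strategy, seed=seed
        )
        run["nm_pred"] = nm.labels
        runs.append(run)
    return runs


@pytest.fixture()
def small_benchmark(tmp_path):
    """A small on-disk benchmark bundle for pipeline tests."""
    params = slp.SimParams(
        n_cells=120, n_genes=300, de_facscale=1.5, seed=7
    )
    bench = slp.make_benchmark(params)
    outdir = tmp_path / "bundle"
    slp.write_benchmark(bench, outdir)
    return bench, outdir
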