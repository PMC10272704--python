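"""Gamma-Poisson scRNA-seq simulation with known groups, DE genes and a
noisy annotation-tool ensemble.

The count model follows the Splat recipe in outline: gamma-distributed base
gene means, per-group log-normal differential-expression factors applied to
a random subset of genes, log-normal library sizes, and Poisson sampling
with gamma overdispersion governed by a biological coefficient of variation
(BCV). It is deliberately a simplified cousin of the full Splat model — no
dropout layer, no trajectories, a single dispersion parameter — because its
job is to provide group-structured overdispersed counts with a known ground
truth, not to replicate any particular tissue.

The key separability dial is ``de_facscale``, the log-normal sigma of the DE
factors: larger values make the groups more transcriptionally distinct. An
optional reference dataset re-draws counts under independent per-gene batch
factors (sigma ``batch_facscale``). Tool predictions are simulated directly
from the true labels with per-tool accuracy and abstention rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .consensus import ABSTAIN, PredictionTable
from .io_prep import RawCountMatrix

__all__ = [
    "SimParams",
    "ToolProfile",
    "SimulatedDataset",
    "Benchmark",
    "simulate_counts",
    "select_markers",
    "simulate_predictions",
    "make_benchmark",
    "default_tool_profiles",
    "write_benchmark",
]


@dataclass
class SimParams:
    """Simulation settings; defaults give a desk-scale 4-group dataset."""

    n_cells: int = 1000
    n_genes: int = 2000
    n_groups: int = 4
    de_prob: float = 0.1  # fraction of genes DE per group
    de_facscale: float = 0.7  # log-normal sigma of DE factors
    batch_facscale: float = 0.5  # log-normal sigma of reference batch factors
    lib_size_median: float = 5000.0  # median library size (counts per cell)
    lib_size_sigma: float = 0.2  # sdlog of the library-size log-normal
    gene_mean_shape: float = 0.6  # gamma shape of base gene means
    gene_mean_rate: float = 0.3  # gamma rate of base gene means
    bcv: float = 0.2  # biological coefficient of variation
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells",
            "n_genes",
            "n_groups",
            "de_prob",
            "de_facscale",
            "lib_size_median",
            "lib_size_sigma",
            "gene_mean_shape",
            "gene_mean_rate",
        ):
            if getattr(self, name) <= 0 and name not in ("de_facscale",):
                raise ValueError(f"{name} must be positive")
        if self.de_facscale < 0 or self.batch_facscale < 0 or self.bcv < 0:
            raise ValueError("scale parameters must be non-negative")


@dataclass
class ToolProfile:
    """Error model of one simulated annotation tool."""

    accuracy: float
    abstain_rate: float = 0.0
    confusion: str = "uniform"  # or "neighbor": errors go to the next group

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.abstain_rate <= 1.0):
            raise ValueError("accuracy and abstain_rate must lie in [0, 1]")
        if self.confusion not in ("uniform", "neighbor"):
            raise ValueError(f"unknown confusion mode {self.confusion!r}")


@dataclass
class SimulatedDataset:
    counts: RawCountMatrix
    true_labels: np.ndarray
    de_factors: np.ndarray  # (n_groups, n_genes), 1.0 for non-DE genes
    base_means: np.ndarray  # (n_genes,) gamma base expression means
    group_names: list[str]
    params: SimParams
    reference: RawCountMatrix | None = None
    reference_labels: np.ndarray | None = None


@dataclass
class Benchmark:
    sim: SimulatedDataset
    predictions: PredictionTable
    markers: dict[str, list[str]]

    @property
    def cell_types(self) -> list[str]:
        return self.sim.group_names


def default_tool_profiles() -> list[ToolProfile]:
    """Five-tool ensemble whose 0.51-majority coverage lands near 85%."""
    return [
        ToolProfile(accuracy=a, abstain_rate=0.05)
        for a in (0.75, 0.73, 0.72, 0.70, 0.68)
    ]


def _draw_counts(mu: np.ndarray, bcv: float, rng: np.random.Generator) -> np.ndarray:
    if bcv == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / (bcv * bcv)
    lam = rng.gamma(shape, mu * (bcv * bcv))
    return rng.poisson(lam)


def simulate_counts(params: SimParams) -> SimulatedDataset:
    """Generate one dataset (and an optional batch-shifted reference).

    Cells are split as evenly as possible between the groups and shuffled.
    Per group, a ``de_prob`` fraction of genes receives a multiplicative DE
    factor ``exp(N(0, de_facscale))`` (the random sign of the log-factor
    makes genes up- or down-regulated); all other factors are exactly 1.
    """
    rng = np.random.default_rng(params.seed)
    n, g, k = params.n_cells, params.n_genes, params.n_groups

    base_means = rng.gamma(params.gene_mean_shape, 1.0 / params.gene_mean_rate, size=g)
    base_means = np.maximum(base_means, 1e-8)

    n_de = int(round(params.de_prob * g))
    if n_de < 10:
        warnings.warn(
            "fewer than 10 DE genes per group; marker selection pool is short",
            stacklevel=2,
        )
    de_factors = np.ones((k, g))
    for grp in range(k):
        idx = rng.choice(g, size=n_de, replace=False)
        de_factors[grp, idx] = np.exp(rng.normal(0.0, params.de_facscale, size=n_de))

    labels = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(labels)

    def _sample(base: np.ndarray, labs: np.ndarray) -> np.ndarray:
        lib = rng.lognormal(np.log(params.lib_size_median), params.lib_size_sigma, labs.size)
        means = base * de_factors[labs]  # (n, g)
        props = means / means.sum(axis=1, keepdims=True)
        return _draw_counts(lib[:, None] * props, params.bcv, rng)

    counts = _sample(base_means, labels)
    dataset = RawCountMatrix(
        counts,
        [f"Gene{j + 1}" for j in range(g)],
        [f"Cell{i + 1}" for i in range(n)],
    )

    batch_factors = np.exp(rng.normal(0.0, params.batch_facscale, size=g))
    ref_labels = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(ref_labels)
    ref_counts = _sample(base_means * batch_factors, ref_labels)
    reference = RawCountMatrix(
        ref_counts,
        [f"Gene{j + 1}" for j in range(g)],
        [f"Ref{i + 1}" for i in range(n)],
    )

    return SimulatedDataset(
        counts=dataset,
        true_labels=labels,
        de_factors=de_factors,
        base_means=base_means,
        group_names=[f"Group{j + 1}" for j in range(k)],
        params=params,
        reference=reference,
        reference_labels=ref_labels,
    )


def select_markers(
    sim: SimulatedDataset, n_markers: int = 5, seed: int = 0
) -> dict[str, list[str]]:
    """Sample ``n_markers`` marker genes per group from its top-10 DE pool.

    Genes are ranked per group by log DE factor (most up-regulated first);
    the markers are drawn uniformly without replacement from the top ten.
    Marker sets of different groups are not guaranteed disjoint.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(sim.counts.gene_names)
    markers: dict[str, list[str]] = {}
    for grp, name in enumerate(sim.group_names):
        logf = np.log(sim.de_factors[grp])
        pool_size = int(np.count_nonzero(logf != 0.0))
        if pool_size < 10:
            warnings.warn(
                f"group {name} has only {pool_size} DE genes; using full pool",
                stacklevel=2,
            )
        order = np.argsort(-logf, kind="stable")
        pool = order[: min(10, max(pool_size, 1))]
        take = min(n_markers, pool.size)
        chosen = rng.choice(pool, size=take, replace=False)
        markers[name] = genes[np.sort(chosen)].tolist()
    return markers


def simulate_predictions(
    true_labels: np.ndarray,
    tool_profiles: list[ToolProfile],
    group_names: list[str],
    seed: int = 0,
) -> PredictionTable:
    """Simulate the cells x tools prediction table from the true labels.

    Per tool and cell: abstain with the tool's abstention rate; otherwise
    predict the true label with the tool's accuracy; otherwise an incorrect
    label, drawn uniformly over the other groups or, in ``"neighbor"``
    confusion mode, deterministically the next group (a designated
    transcriptionally similar type).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(true_labels, dtype=np.int64)
    n, k = labels.size, len(group_names)
    preds = np.empty((n, len(tool_profiles)), dtype=object)
    for j, prof in enumerate(tool_profiles):
        u = rng.random(n)
        abstain = u < prof.abstain_rate
        correct = ~abstain & (rng.random(n) < prof.accuracy)
        wrong = ~abstain & ~correct
        out = labels.copy()
        if prof.confusion == "uniform":
            shift = rng.integers(1, k, size=n)
            out[wrong] = (labels[wrong] + shift[wrong]) % k
        else:
            out[wrong] = (labels[wrong] + 1) % k
        col = np.array([group_names[v] for v in out], dtype=object)
        col[abstain] = ABSTAIN
        preds[:, j] = col
    return PredictionTable(
        preds,
        [f"tool{j + 1}" for j in range(len(tool_profiles))],
        [f"Cell{i + 1}" for i in range(n)],
    )


def make_benchmark(
    params: SimParams | None = None,
    tool_profiles: list[ToolProfile] | None = None,
    seed: int | None = None,
    n_markers: int = 5,
) -> Benchmark:
    """Compose counts, truth, tool predictions and markers into one bundle."""
    if params is None:
        params = SimParams()
    if seed is not None:
        params = SimParams(**{**asdict(params), "seed": seed})
    if tool_profiles is None:
        tool_profiles = default_tool_profiles()
    sim = simulate_counts(params)
    predictions = simulate_predictions(
        sim.true_labels, tool_profiles, sim.group_names, seed=params.seed + 1
    )
    markers = select_markers(sim, n_markers=n_markers, seed=params.seed + 2)
    return Benchmark(sim=sim, predictions=predictions, markers=markers)


def _write_mtx_triplet(counts: RawCountMatrix, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    # 10x convention: genes as rows, cells as columns.
    mmwrite(str(outdir / "matrix.mtx"), coo_matrix(counts.counts.T))
    pd.Series(counts.gene_names).to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.cell_ids).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Write counts (MatrixMarket triplet + dense CSV), predictions, truth,
    markers, and a provenance JSON of the parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = bench.sim
    _write_mtx_triplet(sim.counts, outdir / "mtx")
    pd.DataFrame(
        sim.counts.counts, index=sim.counts.cell_ids, columns=sim.counts.gene_names
    ).to_csv(outdir / "counts.csv")
    pred_df = pd.DataFrame(
        bench.predictions.preds,
        index=bench.predictions.cell_ids,
        columns=bench.predictions.tool_names,
    ).replace(ABSTAIN, "unknown")
    pred_df.to_csv(outdir / "predictions.csv")
    pd.DataFrame(
        {
            "cell_id": sim.counts.cell_ids,
            "true_label": [sim.group_names[v] for v in sim.true_labels],
        }
    ).to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "markers.json", "w") as fh:
        json.dump(bench.markers, fh, indent=2, sort_keys=True)
    with open(outdir / "params.json", "w") as fh:
        json.dump(asdict(sim.params), fh, indent=2, sort_keys=True)
    if sim.reference is not None:
        pd.DataFrame(
            sim.reference.counts,
            index=sim.reference.cell_ids,
            columns=sim.reference.gene_names,
        ).to_csv(outdir / "reference_counts.csv")
        pd.DataFrame(
            {
                "cell_id": sim.reference.cell_ids,
                "true_label": [sim.group_names[v] for v in sim.reference_labels],
            }
        ).to_csv(outdir / "reference_truth.csv", index=False)
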