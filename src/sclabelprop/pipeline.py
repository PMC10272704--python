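"""End-to-end orchestration: prep -> consensus -> grid search -> multi-seed
GCN -> neighbor-majority comparison -> interpretation.

Every run writes its resolved configuration, all stage artifacts, a
``manifest.json`` of SHA-256 checksums, and a ``report.json``. Ground-truth
labels, when supplied, are used exclusively for reporting accuracy — never
for training, hyperparameter selection or any other decision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import gcn, interpretation, io_prep, neighbor_majority

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; defaults follow the method's
    published recipe (0.51 consensus threshold, 500 PCs, 150 epochs, learning
    rate 1e-4, five random initializations, 20% validation fraction)."""

    counts_path: str = ""
    counts_format: str = "csv"
    predictions_path: str = ""
    markers_path: str | None = None
    truth_path: str | None = None
    out_dir: str = "run_output"
    threshold: float = 0.51
    pcs: int = 500
    min_genes: int = 200
    min_cells: int = 3
    epochs: int = 150
    learning_rate: float = 1e-4
    runs: int = 5
    validation_fraction: float = 0.20
    grid: str | list = "default"
    nm_ks: list = field(default_factory=lambda: [2, 5, 10, 25, 50])
    nm_batch_size: int = 1000
    top_n: int = 5
    n_add: int = 3
    inference_batch: int | None = None
    seed: int = 0


def _resolve_grid(config: RunConfig) -> list[gcn.GCNConfig]:
    common = dict(epochs=config.epochs, learning_rate=config.learning_rate)
    if config.grid == "default":
        return gcn.default_grid(**common)
    if config.grid == "single":
        return [gcn.GCNConfig(batch_size=20, n_neighbors=2, n_layers=2, embed_dim=25, **common)]
    if isinstance(config.grid, list):
        return [gcn.GCNConfig(**{**common, **entry}) for entry in config.grid]
    raise ValueError(f"unrecognized grid specification: {config.grid!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_markers(path: str) -> dict[str, list[str]]:
    p = Path(path)
    if p.suffix.lower() == ".json":
        with open(p) as fh:
            return {str(k): [str(g) for g in v] for k, v in json.load(fh).items()}
    df = pd.read_csv(p)  # columns = cell types, rows = marker genes
    return {
        str(col): [str(g) for g in df[col].dropna() if str(g).strip()]
        for col in df.columns
    }


def _load_truth(path: str, cell_ids: list[str], cell_types: list[str]) -> np.ndarray:
    df = pd.read_csv(path, dtype=str)
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [cid for cid in cell_ids if cid not in mapping]
    if missing:
        raise ValueError(f"truth file is missing {len(missing)} cell ids, e.g. {missing[:5]}")
    index = {t: i for i, t in enumerate(cell_types)}
    try:
        return np.array([index[mapping[cid]] for cid in cell_ids], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"truth label outside cell-type vocabulary: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the report dict (also written to disk)."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def _write_json(name: str, obj) -> None:
        path = outdir / name
        _json_dump(obj, path)
        artifacts.append(path)

    _write_json("config.json", asdict(config))

    # --- stage: prep ------------------------------------------------------
    try:
        raw = io_prep.read_counts(config.counts_path, config.counts_format)
        filtered, cell_idx, _ = io_prep.filter_counts(
            raw, config.min_genes, config.min_cells
        )
        normalized = io_prep.lognormalize(filtered)
        embedding = io_prep.pca_project(normalized, d=config.pcs, seed=config.seed)
    except (OSError, ValueError) as exc:
        raise PipelineError("prep", str(exc)) from exc

    # --- stage: consensus -------------------------------------------------
    try:
        preds = cons.read_predictions(config.predictions_path)
        pred_index = {cid: i for i, cid in enumerate(preds.cell_ids)}
        missing = [cid for cid in filtered.cell_ids if cid not in pred_index]
        if missing:
            raise ValueError(
                f"{len(missing)} filtered cells have no prediction row, "
                f"e.g. {missing[:5]}"
            )
        preds = preds.subset_cells(
            np.array([pred_index[cid] for cid in filtered.cell_ids])
        )
        markers = _load_markers(config.markers_path) if config.markers_path else None
        if markers:
            cell_types = list(markers.keys())
            extra = sorted(set(cons.infer_cell_types(preds)) - set(cell_types))
            cell_types += extra
        else:
            cell_types = cons.infer_cell_types(preds)
        votes = cons.encode_votes(preds, cell_types)
        labels = cons.confident_labels(votes, config.threshold)
        max_cons = cons.max_consensus(votes)
        summary = cons.consensus_summary(labels)
    except (OSError, ValueError) as exc:
        raise PipelineError("consensus", str(exc)) from exc

    cast = votes.votes.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_i = np.where(cast > 0, votes.votes.max(axis=1) / cast, 0.0)
    labels_df = pd.DataFrame(
        {
            "cell_id": filtered.cell_ids,
            "consensus_label": [
                cell_types[v] if v >= 0 else "unconfident" for v in labels.labels
            ],
            "max_consensus_label": [
                cell_types[v] if v >= 0 else "unknown" for v in max_cons
            ],
            "m_i": np.round(m_i, 6),
        }
    )
    for j, t in enumerate(cell_types):
        labels_df[f"votes_{t}"] = votes.votes[:, j]
    labels_path = outdir / "labels.csv"
    labels_df.to_csv(labels_path, index=False)
    artifacts.append(labels_path)

    # --- stage: propagate (grid search + multi-seed GCN) -------------------
    try:
        train_mask, val_mask = gcn.split_validation(
            labels, config.validation_fraction, config.seed
        )
        grid = _resolve_grid(config)
        best_config, grid_results = gcn.grid_search(
            embedding, labels, grid, seed=config.seed,
            train_mask=train_mask, val_mask=val_mask,
        )
        report_runs = gcn.multi_seed_report(
            embedding,
            labels,
            best_config,
            truth=None,
            n_runs=config.runs,
            base_seed=config.seed,
        )
        final_model = report_runs["models"][0]
        gcn_pred = report_runs["predictions"][0]
        _, gcn_scores = gcn.predict_labels(
            final_model, embedding, config.inference_batch
        )
    except ValueError as exc:
        raise PipelineError("propagate", str(exc)) from exc

    pred_df = pd.DataFrame(
        {
            "cell_id": filtered.cell_ids,
            "predicted_label": [cell_types[v] for v in gcn_pred],
        }
    )
    for j, t in enumerate(cell_types):
        pred_df[f"score_{t}"] = np.round(gcn_scores[:, j], 6)
    pred_path = outdir / "predictions.csv"
    pred_df.to_csv(pred_path, index=False)
    artifacts.append(pred_path)
    model_path = outdir / "model.npz"
    final_model.save(model_path)

    # --- stage: neighbor majority ------------------------------------------
    try:
        nm_k, nm_strategy, nm_sweep = neighbor_majority.select_neighbor_params(
            embedding,
            labels,
            val_mask,
            ks=tuple(k for k in config.nm_ks if k < filtered.n_cells),
            batch_size=config.nm_batch_size,
            seed=config.seed,
        )
        nm_result = neighbor_majority.propagate_neighbor_majority(
            embedding, labels, nm_k, nm_strategy,
            batch_size=config.nm_batch_size, seed=config.seed,
        )
    except ValueError as exc:
        raise PipelineError("neighbor_majority", str(exc)) from exc

    nm_df = pd.DataFrame(
        {
            "cell_id": filtered.cell_ids,
            "predicted_label": [
                cell_types[v] if v >= 0 else "unlabeled" for v in nm_result.labels
            ],
        }
    )
    nm_path = outdir / "neighbor_majority.csv"
    nm_df.to_csv(nm_path, index=False)
    artifacts.append(nm_path)

    # --- stage: interpret ---------------------------------------------------
    try:
        attributions = interpretation.deeplift_attribute(
            final_model, embedding, normalized, gcn_pred, config.inference_batch
        )
        importance = interpretation.aggregate_importance(
            attributions, gcn_pred, cell_types
        )
        top = interpretation.top_genes(importance, config.top_n)
        augmented = None
        if markers:
            # marker genes that the gene filter removed cannot be augmented
            vocab = set(importance.gene_names)
            markers_in_vocab = {
                t: [g for g in genes if g in vocab] for t, genes in markers.items()
            }
            augmented = interpretation.augment_markers(
                markers_in_vocab, importance, config.n_add
            )
    except ValueError as exc:
        raise PipelineError("interpret", str(exc)) from exc

    imp_path = outdir / "importance.csv"
    pd.DataFrame(
        np.round(importance.importance, 6),
        index=importance.cell_types,
        columns=importance.gene_names,
    ).to_csv(imp_path)
    artifacts.append(imp_path)
    top_path = outdir / "top_genes.csv"
    pd.DataFrame(
        [
            {"cell_type": t, "rank": r + 1, "gene": g}
            for t, genes in top.items()
            for r, g in enumerate(genes)
        ]
    ).to_csv(top_path, index=False)
    artifacts.append(top_path)
    # Long-format importance table, ready for heatmap plotting.
    heat_rows = []
    top_union = sorted({g for genes in top.values() for g in genes})
    gene_pos = {g: i for i, g in enumerate(importance.gene_names)}
    for t_idx, t in enumerate(importance.cell_types):
        for g in top_union:
            heat_rows.append(
                {
                    "cell_type": t,
                    "gene": g,
                    "importance": round(float(importance.importance[t_idx, gene_pos[g]]), 6),
                }
            )
    heat_path = outdir / "importance_long.csv"
    pd.DataFrame(heat_rows).to_csv(heat_path, index=False)
    artifacts.append(heat_path)
    if augmented is not None:
        _write_json("augmented_markers.json", augmented)

    # --- report -------------------------------------------------------------
    report: dict = {
        "consensus": summary,
        "cell_types": cell_types,
        "n_cells_filtered": filtered.n_cells,
        "n_genes_filtered": filtered.n_genes,
        "pca_dim": embedding.d,
        "best_config": asdict(best_config),
        "grid": [
            {**asdict(r["config"]), "val_accuracy": round(r["val_accuracy"], 6)}
            for r in grid_results
        ],
        "gcn_seeds": report_runs["seeds"],
        "neighbor_majority": {
            "k": nm_k,
            "strategy": nm_strategy,
            "epochs": nm_result.epochs,
            "n_unlabeled": int(np.count_nonzero(nm_result.labels < 0)),
            "sweep": [
                {**row, "val_accuracy": round(row["val_accuracy"], 6)}
                for row in nm_sweep
            ],
        },
        "degenerate_importance_rows": importance.degenerate,
    }

    if config.truth_path:
        try:
            truth = _load_truth(config.truth_path, filtered.cell_ids, cell_types)
        except (OSError, ValueError) as exc:
            raise PipelineError("report", str(exc)) from exc
        unconf = labels.labels < 0
        gcn_total = [
            gcn.evaluate_accuracy(p, truth) for p in report_runs["predictions"]
        ]
        gcn_unconf = (
            [
                gcn.evaluate_accuracy(p, truth, unconf)
                for p in report_runs["predictions"]
            ]
            if unconf.any()
            else []
        )

        def _ms(vals):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                return {"mean": None, "sd": None}
            return {
                "mean": round(float(arr.mean()), 6),
                "sd": round(float(arr.std(ddof=0)), 6),
            }

        tool_acc = {}
        for j, tool in enumerate(preds.tool_names):
            col = preds.preds[:, j]
            tool_pred = np.array(
                [cell_types.index(v) if v != cons.ABSTAIN else -1 for v in col]
            )
            tool_acc[tool] = {
                "total": round(gcn.evaluate_accuracy(tool_pred, truth), 6),
                "unconfident": (
                    round(gcn.evaluate_accuracy(tool_pred, truth, unconf), 6)
                    if unconf.any()
                    else None
                ),
            }
        report["accuracy"] = {
            "gcn": {"total": _ms(gcn_total), "unconfident": _ms(gcn_unconf)},
            "max_consensus": {
                "total": round(gcn.evaluate_accuracy(max_cons, truth), 6),
                "unconfident": (
                    round(gcn.evaluate_accuracy(max_cons, truth, unconf), 6)
                    if unconf.any()
                    else None
                ),
            },
            "neighbor_majority": {
                "total": round(gcn.evaluate_accuracy(nm_result.labels, truth), 6),
                "unconfident": (
                    round(gcn.evaluate_accuracy(nm_result.labels, truth, unconf), 6)
                    if unconf.any()
                    else None
                ),
            },
            "tools": tool_acc,
        }

    _write_json("report.json", report)
    # config.json echoes run-local paths, so it stays out of the checksums
    manifest = {
        p.name: _sha256(p)
        for p in sorted(artifacts, key=lambda p: p.name)
        if p.name != "config.json"
    }
    _json_dump(manifest, outdir / "manifest.json")
    return report
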