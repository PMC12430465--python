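"""Readers/writers, run configuration and the end-to-end pipeline driver."""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffstats import anova_tukey
from .preprocess import FeatureTable, SampleMeta
from .split import RecursiveOPLSDA, SplitConfig, SplitNode, SplitTree

logger = logging.getLogger(__name__)

VALID_SPECIES = ("MD", "MH", "MR", "MS")
VALID_REGIONS = ("north", "south")


@dataclass
class RunConfig:
    """Full run configuration: split thresholds plus paths and toggles."""

    input_path: str = ""
    meta_path: str = ""
    out_dir: str = "results"
    plot: bool = False
    split: SplitConfig = field(default_factory=SplitConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        split = d.pop("split", {})
        return cls(split=SplitConfig(**split), **d)


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_feature_table(path) -> FeatureTable:
    """Load a delimited feature table: first column sample ids, header features.

    Non-numeric cells are rejected with the offending row/column named;
    missing values are imputed with half the feature's minimum positive value
    (count reported through the log).
    """
    df = _read_delimited(path)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip().str.upper()
                                                  .isin(["NA", "NAN", ""]) == False)
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric value {df.loc[row, col]!r} "
                             f"at sample {row!r}, feature {col!r}")
        df[col] = coerced
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("%s: imputing %d missing value(s) with half the feature "
                    "minimum positive value", path, n_missing)
        for col in df.columns[df.isna().any()]:
            positive = df[col][df[col] > 0]
            fill = positive.min() / 2.0 if len(positive) else 0.0
            df[col] = df[col].fillna(fill)
    return FeatureTable(list(df.index.astype(str)), list(df.columns.astype(str)),
                        df.to_numpy(dtype=float), "raw")


def read_metadata(path) -> SampleMeta:
    """Load the sample metadata CSV (columns sample_id, species, region)."""
    df = pd.read_csv(path)
    required = {"sample_id", "species", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {sorted(missing)}")
    return SampleMeta(df["sample_id"].astype(str).tolist(),
                      df["species"].astype(str).tolist(),
                      df["region"].astype(str).tolist())


# ---------------------------------------------------------------------------
# tree serialization


def _node_to_dict(node: SplitNode) -> dict:
    d = {
        "node_id": node.node_id,
        "depth": node.depth,
        "sample_ids": list(node.sample_ids),
        "silhouette": node.silhouette,
        "rejection_reason": node.rejection_reason,
        "report": node.report.to_dict() if node.report else None,
        "n_significant_markers": len(node.significant_markers()),
        "children": [ _node_to_dict(c) for c in node.children ] if node.children else None,
    }
    if node.child_assignment is not None:
        d["child_assignment"] = [int(x) for x in node.child_assignment]
    return d


def write_tree(tree: SplitTree, path) -> None:
    """Serialize a fitted tree (nodes, metrics, rejection reasons) to JSON."""
    payload = {
        "seed": tree.seed,
        "config": tree.config.to_dict(),
        "n_accepted_splits": tree.n_accepted,
        "accepted_node_ids": [n.node_id for n in tree.accepted_splits],
        "root": _node_to_dict(tree.root),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def validate_tree_payload(payload: dict) -> None:
    """Structural check of a serialized tree (raises ValueError on problems)."""
    for key in ("seed", "config", "n_accepted_splits", "root"):
        if key not in payload:
            raise ValueError(f"tree payload missing key {key!r}")

    def visit(node, seen):
        for key in ("node_id", "sample_ids", "rejection_reason"):
            if key not in node:
                raise ValueError(f"tree node missing key {key!r}")
        if node["rejection_reason"] not in ("none", "too_small",
                                            "low_silhouette", "not_significant"):
            raise ValueError(f"unknown rejection reason {node['rejection_reason']!r}")
        children = node.get("children")
        if children:
            ids = [set(c["sample_ids"]) for c in children]
            if ids[0] & ids[1] or ids[0] | ids[1] != set(node["sample_ids"]):
                raise ValueError(f"children of node {node['node_id']} do not "
                                 "partition the parent")
            for c in children:
                visit(c, seen)
        else:
            dup = seen & set(node["sample_ids"])
            if dup:
                raise ValueError(f"sample(s) {sorted(dup)[:3]} appear in "
                                 "multiple leaves")
            seen |= set(node["sample_ids"])

    visit(payload["root"], set())


def read_tree(path) -> dict:
    """Read and validate a serialized tree; returns the JSON payload.

    The leaf partition is exactly recoverable from the nested ``sample_ids``.
    """
    payload = json.loads(Path(path).read_text())
    validate_tree_payload(payload)
    return payload


def tree_leaf_partition(payload: dict) -> list[list]:
    """Leaf sample-id sets from a serialized tree payload."""
    leaves = []

    def visit(node):
        if not node.get("children"):
            leaves.append(list(node["sample_ids"]))
        else:
            for c in node["children"]:
                visit(c)

    visit(payload["root"])
    return leaves


def write_markers(tree: SplitTree, out_dir: Path) -> None:
    for k, node in enumerate(tree.accepted_splits, start=1):
        rows = [m.to_dict() for m in node.markers]
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / f"split{k}_markers.tsv", sep="\t", index=False)
        df[["feature_id", "s_cov", "s_corr", "significant"]].to_csv(
            out_dir / f"split{k}_splot.tsv", sep="\t", index=False)


def write_split_stats(tree: SplitTree, logged: FeatureTable, out_dir: Path) -> None:
    """Per accepted split: ANOVA/Tukey + effect-size table for significant markers."""
    fid_index = {f: j for j, f in enumerate(logged.feature_ids)}
    for k, node in enumerate(tree.accepted_splits, start=1):
        idx = node.sample_indices
        labels = node.child_assignment
        rows = []
        for m in node.significant_markers():
            j = fid_index[m.feature_id]
            vals = logged.values[idx, j]
            cmp = anova_tukey({"cluster_a": vals[labels == 0],
                               "cluster_b": vals[labels == 1]}, feature_id=m.feature_id)
            rows.append({
                "feature_id": m.feature_id,
                "mean_a": cmp.group_means["cluster_a"],
                "mean_b": cmp.group_means["cluster_b"],
                "sd_a": cmp.group_sds["cluster_a"],
                "sd_b": cmp.group_sds["cluster_b"],
                "anova_p": cmp.anova_p,
                "cohens_d": cmp.effect.d,
                "abs_d": abs(cmp.effect.d),
                "d_category": cmp.effect.category,
                "stars": cmp.stars,
            })
        pd.DataFrame(rows).to_csv(out_dir / f"split{k}_diffstats.tsv",
                                  sep="\t", index=False)


def render_boxplots(tree: SplitTree, logged: FeatureTable, out_dir: Path,
                    top_n: int = 8) -> None:
    """Boxplots of the top markers per accepted split (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fid_index = {f: j for j, f in enumerate(logged.feature_ids)}
    for k, node in enumerate(tree.accepted_splits, start=1):
        markers = node.significant_markers()[:top_n]
        if not markers:
            continue
        idx = node.sample_indices
        labels = node.child_assignment
        ncol = min(4, len(markers))
        nrow = -(-len(markers) // ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow),
                                 squeeze=False)
        for ax, m in zip(axes.flat, markers):
            vals = logged.values[idx, fid_index[m.feature_id]]
            ax.boxplot([vals[labels == 0], vals[labels == 1]],
                       tick_labels=["cluster A", "cluster B"])
            ax.set_title(m.feature_id, fontsize=8)
        for ax in axes.flat[len(markers):]:
            ax.set_visible(False)
        fig.tight_layout()
        fig.savefig(out_dir / f"split{k}_boxplots.png", dpi=100)
        plt.close(fig)


def run_pipeline(config: RunConfig, table: FeatureTable | None = None) -> SplitTree:
    """Preprocess, grow the recursive hierarchy, write all artifacts.

    On any stage error, partial outputs under ``out_dir`` are removed and the
    exception propagates (the CLI maps it to a nonzero exit code).
    """
    from .preprocess import log_transform

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    pkg_logger = logging.getLogger("roplsda")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(logging.INFO)
    try:
        if table is None:
            table = read_feature_table(config.input_path)
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
        est = RecursiveOPLSDA(**config.split.to_dict())
        est.fit(table)
        tree = est.tree_
        write_tree(tree, out_dir / "tree.json")
        write_markers(tree, out_dir)
        logged = log_transform(table)
        write_split_stats(tree, logged, out_dir)
        if config.plot:
            render_boxplots(tree, logged, out_dir)
        leaf_df = pd.DataFrame({"sample_id": table.sample_ids,
                                "leaf": est.labels_})
        leaf_df.to_csv(out_dir / "leaf_assignments.tsv", sep="\t", index=False)
        logger.info("run complete: %d accepted split(s), outputs in %s",
                    tree.n_accepted, out_dir)
        return tree
    except Exception:
        logger.exception("pipeline failed; removing partial outputs")
        handler.close()
        pkg_logger.removeHandler(handler)
        shutil.rmtree(out_dir, ignore_errors=True)
        raise
    finally:
        if handler in pkg_logger.handlers:
            handler.close()
            pkg_logger.removeHandler(handler)
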