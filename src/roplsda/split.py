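"""Recursive divisive classification by embedding, clustering and OPLS-DA.

Each node of the hierarchy is processed the same way: project the node's
samples into three t-SNE dimensions, propose a binary partition with k-means,
gate the proposal on its silhouette score, then validate the surviving
partition with a permutation-tested OPLS-DA. Accepted splits recurse into
both children (a homogeneous child self-terminates at the silhouette or
significance gate); every rejection is recorded with its reason so a run is
fully auditable. A one-vs-one pairwise OPLS-DA grid over predefined class
labels is provided as the conventional baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .diffstats import cohens_d
from .opls import (MarkerRecord, OPLSDA, ValidationReport, permutation_test,
                   s_plot, select_markers, vip_scores)
from .preprocess import FeatureTable, log_transform, pareto_scale, univariate_screen

logger = logging.getLogger(__name__)

REJECTION_REASONS = ("none", "too_small", "low_silhouette", "not_significant")


@dataclass
class SplitConfig:
    """Tunable thresholds for the recursive engine.

    Defaults follow standard practice for this pipeline: silhouette gate at
    0.5, permutation alpha 0.05, VIP threshold 1, 3-D t-SNE capped at 10,000
    iterations, k-means with 25 restarts, and a minimum node size of 12 so a
    proposed split can still support stratified cross-validation.
    """

    silhouette_threshold: float = 0.5
    alpha: float = 0.05
    vip_threshold: float = 1.0
    tsne_dims: int = 3
    tsne_max_iter: int = 10000
    tsne_perplexity: float | str = "auto"
    kmeans_restarts: int = 25
    tsne_restarts: int = 3
    n_perm: int = 999
    n_folds: int = 10
    n_ortho: int | str = "auto"
    min_node: int = 12
    max_depth: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.min_node < 6:
            raise ValueError("min_node must be >= 6")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.silhouette_threshold <= 1:
            raise ValueError("silhouette_threshold must be in [-1, 1]")
        if self.n_perm < 19:
            raise ValueError("n_perm must be >= 19")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitNode:
    """One node of the divisive hierarchy."""

    node_id: int
    sample_ids: list
    sample_indices: np.ndarray
    depth: int = 0
    silhouette: float | None = None
    child_assignment: np.ndarray | None = None
    report: ValidationReport | None = None
    markers: list = field(default_factory=list)
    children: tuple | None = None
    rejection_reason: str = "none"

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def significant_markers(self) -> list[MarkerRecord]:
        return [m for m in self.markers if m.significant]


@dataclass
class SplitTree:
    """The fitted hierarchy: root node plus accepted splits in discovery order."""

    root: SplitNode
    accepted_splits: list
    config: SplitConfig
    seed: int

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.children:
                stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_splits)

    def leaf_labels(self, n_samples: int) -> np.ndarray:
        """Leaf index per sample (leaves enumerated in traversal order)."""
        labels = np.full(n_samples, -1, dtype=int)
        for k, leaf in enumerate(self.leaves()):
            labels[leaf.sample_indices] = k
        if (labels < 0).any():
            raise AssertionError("leaves do not cover every sample")
        return labels


# ---------------------------------------------------------------------------
# node-level operations


#: auto perplexity cap; small enough that t-SNE emphasizes local cluster
#: structure, which is what makes the embedding a usable split-proposal space
_PERPLEXITY_CAP = 8


def _auto_perplexity(n: int) -> int:
    return min(_PERPLEXITY_CAP, (n - 1) // 3)


def embed(X, cfg: SplitConfig, seed: int | None = None,
          perplexity: float | None = None) -> np.ndarray:
    """3-D t-SNE embedding of one node's (scaled) samples.

    Perplexity "auto" is min(8, floor((n-1)/3)); a fixed seed with PCA
    initialization makes the embedding deterministic. An explicit
    ``perplexity`` overrides the configured one (the engine's retry ladder
    probes a smaller neighborhood scale).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if perplexity is not None:
        perplexity = min(float(perplexity), (n - 1) / 3)
    elif cfg.tsne_perplexity == "auto":
        perplexity = _auto_perplexity(n)
    else:
        perplexity = min(float(cfg.tsne_perplexity), (n - 1) / 3)
    if perplexity < 1:
        raise ValueError(f"node of {n} samples is too small for any valid perplexity")
    tsne = TSNE(
        n_components=cfg.tsne_dims,
        perplexity=perplexity,
        max_iter=cfg.tsne_max_iter,
        init="pca",
        random_state=cfg.seed if seed is None else seed,
    )
    return tsne.fit_transform(X)


def propose_split(embedding, cfg: SplitConfig, seed: int | None = None,
                  X_scaled=None):
    """Binary partition of a node with its silhouette score.

    k-means (k=2) restarts on the t-SNE embedding generate candidate cuts;
    each candidate is scored by its silhouette, evaluated both in the
    embedding and — when the node's Pareto-scaled matrix ``X_scaled`` is
    supplied — in feature space, keeping the larger of the two. The
    best-scoring cut is returned. The two spaces are complementary: t-SNE
    tends to equalize the magnitude of between-cluster gaps, so when a node
    holds more than two subgroups the feature-space silhouette restores the
    gap hierarchy and the most distinct group is peeled first; conversely,
    overlapping groups that are only separable through local neighborhood
    structure score higher in the embedding.

    Returns (labels in {0,1}, silhouette). All-identical points make the
    silhouette undefined and are reported as silhouette -1 (always gated out).
    """
    E = np.asarray(embedding, dtype=float)
    n = E.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to propose a split")
    if np.allclose(E, E[0]):
        return np.zeros(n, dtype=int), -1.0

    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    def score(labels):
        sil_e = float(silhouette_score(E, labels))
        if X_scaled is None:
            return sil_e, sil_e
        sil_x = float(silhouette_score(X_scaled, labels))
        return (sil_e + sil_x) / 2.0, max(sil_e, sil_x)

    # primary proposal: plain binary k-means, best inertia over restarts
    km2 = KMeans(n_clusters=2, n_init=cfg.kmeans_restarts,
                 random_state=int(rng.integers(2**31 - 1)))
    primary = km2.fit_predict(E).astype(int)
    if len(np.unique(primary)) == 2:
        _, sil = score(primary)
        if sil > cfg.silhouette_threshold:
            return primary, sil
    else:
        primary = None

    # fallback: when the balanced k-means cut fails the gate, the node may
    # still hold one distinct lobe among several (t-SNE equalizes gap sizes,
    # and k-means inertia then favors balanced unions of lobes); offer
    # one-vs-rest merges of finer k-means clusterings as candidate cuts,
    # ranked by the mean of the embedding- and feature-space silhouettes (a
    # genuine split carries support in both views) and gated on the max
    candidates = []
    seen = set()

    def consider(labels):
        labels = np.asarray(labels, dtype=int)
        counts = np.bincount(labels, minlength=2)
        # tiny clusters get inflated silhouettes (an isolated outlier scores
        # near 1) and could never be validated anyway
        if counts.min() < min(3, n - 1):
            return
        if labels[0] == 1:
            labels = 1 - labels  # canonical polarity for dedup
        key = labels.tobytes()
        if key in seen:
            return
        seen.add(key)
        candidates.append(labels)

    if primary is not None:
        consider(primary)
    k_max = min(5, n // 3)
    for k in range(3, k_max + 1):
        km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts,
                    random_state=int(rng.integers(2**31 - 1)))
        fine = km.fit_predict(E)
        present = np.unique(fine)
        for mask_bits in range(1, 2 ** (len(present) - 1)):
            side = {c for i, c in enumerate(present) if mask_bits >> i & 1}
            consider(np.isin(fine, list(side)).astype(int))

    best_labels, best_rank, best_sil = None, -np.inf, -1.0
    for labels in candidates:
        rank, sil = score(labels)
        if rank > best_rank:
            best_labels, best_rank, best_sil = labels, rank, sil
    if best_labels is None:
        return np.zeros(n, dtype=int), -1.0
    return best_labels, best_sil


def validate_split(X_logged, labels, cfg: SplitConfig, seed: int | None = None,
                   feature_ids=None, X_raw=None):
    """OPLS-DA validation of a proposed binary partition, with markers.

    Fits an OPLS-DA (Pareto scaling estimated inside the model) on the
    cluster labels, computes the permutation p-value of the cross-validated
    Q2, and assembles marker records: VIP from the model, BH-adjusted Welch
    t-test p between the clusters, S-plot coordinates, and Cohen's d on the
    logged abundances.
    """
    X_logged = np.asarray(X_logged, dtype=float)
    labels = np.asarray(labels)
    n, d = X_logged.shape
    if feature_ids is None:
        feature_ids = [f"F{j}" for j in range(d)]
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < 3:
        raise ValueError("both clusters need >= 3 samples to validate")

    seed = cfg.seed if seed is None else seed
    model = OPLSDA(n_ortho=cfg.n_ortho, scale="pareto", n_folds=cfg.n_folds,
                   random_state=seed).fit(X_logged, labels)
    report = permutation_test(X_logged, labels, n_perm=cfg.n_perm, seed=seed,
                              n_folds=cfg.n_folds, n_ortho=model.n_ortho_,
                              scale="pareto")
    report.r2y = model.r2y_

    if X_raw is not None:
        screen_table = FeatureTable([f"s{i}" for i in range(n)], list(feature_ids),
                                    np.asarray(X_raw, dtype=float), "raw")
    else:
        screen_table = FeatureTable([f"s{i}" for i in range(n)], list(feature_ids),
                                    X_logged, "logged")
    screen = univariate_screen(screen_table, labels)
    q = np.array([r.q for r in screen])

    vips = vip_scores(model)
    s_cov, s_corr = s_plot(model, X_logged)
    mask0 = labels == np.unique(labels)[0]
    d_list, cat_list = [], []
    for j in range(d):
        eff = cohens_d(X_logged[mask0, j], X_logged[~mask0, j])
        d_list.append(eff.d)
        cat_list.append(eff.category)
    markers = select_markers(feature_ids, vips, q, (s_cov, s_corr),
                             (np.array(d_list), cat_list),
                             vip_threshold=cfg.vip_threshold, alpha=0.05)
    return report, markers


# ---------------------------------------------------------------------------
# recursive engine


class RecursiveOPLSDA(BaseEstimator, ClusterMixin):
    """Divisive hierarchical classifier over an abundance feature table.

    ``fit`` takes a raw (non-negative) samples x features matrix or
    :class:`FeatureTable`, applies log10 + Pareto preprocessing, and grows the
    split hierarchy. The fitted attributes are ``tree_`` (a
    :class:`SplitTree`) and ``labels_`` (leaf index per sample).

    Parameters mirror :class:`SplitConfig`; a single ``seed`` fans out
    deterministically to t-SNE, k-means, cross-validation folds and the
    permutation tests of every node.
    """

    def __init__(self, silhouette_threshold=0.5, alpha=0.05, vip_threshold=1.0,
                 tsne_dims=3, tsne_max_iter=10000, tsne_perplexity="auto",
                 kmeans_restarts=25, tsne_restarts=3, n_perm=999, n_folds=10,
                 n_ortho="auto", min_node=12, max_depth=10, seed=0):
        self.silhouette_threshold = silhouette_threshold
        self.alpha = alpha
        self.vip_threshold = vip_threshold
        self.tsne_dims = tsne_dims
        self.tsne_max_iter = tsne_max_iter
        self.tsne_perplexity = tsne_perplexity
        self.kmeans_restarts = kmeans_restarts
        self.tsne_restarts = tsne_restarts
        self.n_perm = n_perm
        self.n_folds = n_folds
        self.n_ortho = n_ortho
        self.min_node = min_node
        self.max_depth = max_depth
        self.seed = seed

    def _config(self) -> SplitConfig:
        return SplitConfig(**{k: getattr(self, k) for k in SplitConfig.__dataclass_fields__})

    @staticmethod
    def _reference_silhouette(X, cfg, perp, tsne_seed, km_seed) -> float:
        """Best split silhouette of a covariance-matched Gaussian reference.

        The reference reproduces the node's sample covariance (Gaussian with
        the same principal axes and spreads) but has no cluster structure by
        construction; embedding and clustering it identically yields the
        silhouette a homogeneous cloud of this shape earns at this scale.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rng = np.random.default_rng(tsne_seed)
        best = -1.0
        for _ in range(2):  # max of two draws: one is too noisy a floor
            G = rng.standard_normal((n, len(s)))
            ref = G @ np.diag(s / np.sqrt(max(n - 1, 1))) @ Vt
            ref_seed = int(rng.integers(2**31 - 1))
            E_ref = embed(ref, cfg, seed=ref_seed, perplexity=perp)
            _, sil = propose_split(E_ref, cfg, seed=km_seed, X_scaled=ref)
            best = max(best, sil)
        return best

    @staticmethod
    def _node_seeds(base_seed: int, node_id: int, attempt: int = 0) -> dict:
        ss = np.random.SeedSequence([int(base_seed), int(node_id), int(attempt)])
        tsne_s, km_s, perm_s = (int(s) for s in ss.generate_state(3) % (2**31 - 1))
        return {"tsne": tsne_s, "kmeans": km_s, "perm": perm_s}

    def fit(self, X, y=None):
        cfg = self._config()
        if isinstance(X, FeatureTable):
            table = X
        else:
            X = np.asarray(X, dtype=float)
            table = FeatureTable([f"s{i}" for i in range(X.shape[0])],
                                 [f"F{j}" for j in range(X.shape[1])], X, "raw")
        if table.state == "raw":
            logged = log_transform(table)
        elif table.state == "logged":
            logged = table
        else:
            raise ValueError("fit expects a raw or logged table")
        scaled = pareto_scale(logged)
        raw_values = table.values if table.state == "raw" else None

        self._n_opls_fits = 0
        self._next_id = 0
        self._sample_id_list = list(table.sample_ids)
        root = self._make_node(np.arange(table.n_samples), depth=0)
        accepted: list[SplitNode] = []
        self._grow(root, scaled.values, logged.values, raw_values,
                   table.feature_ids, cfg, accepted)

        self.tree_ = SplitTree(root=root, accepted_splits=accepted,
                               config=cfg, seed=cfg.seed)
        self.labels_ = self.tree_.leaf_labels(table.n_samples)
        self.feature_ids_ = list(table.feature_ids)
        self.sample_ids_ = list(table.sample_ids)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _make_node(self, indices, depth) -> SplitNode:
        node = SplitNode(
            node_id=self._next_id,
            sample_ids=[self._sample_id_list[i] for i in indices],
            sample_indices=np.asarray(indices, dtype=int),
            depth=depth,
        )
        self._next_id += 1
        return node

    def _grow(self, node, X_scaled, X_logged, X_raw, feature_ids, cfg, accepted):
        idx = node.sample_indices
        n = len(idx)
        if n < cfg.min_node or node.depth >= cfg.max_depth:
            node.rejection_reason = "too_small"
            logger.info("node %d (n=%d, depth=%d): rejected too_small",
                        node.node_id, n, node.depth)
            return

        # separability at the detection margin depends on the neighborhood
        # scale t-SNE resolves: a gap invisible at the default perplexity can
        # be decisive at a smaller one. On gate failure, retry the proposal
        # down a perplexity ladder (with fresh seeds). Small perplexities
        # also manufacture density sub-lobes out of genuinely homogeneous
        # low-dimensional clouds, so a retry proposal only counts if its
        # silhouette clearly beats a covariance-matched Gaussian reference
        # put through the identical embed/cluster procedure (gap-statistic
        # reasoning, applied in the embedding). Nodes passing at the default
        # scale are unaffected.
        perp_ladder = [None, 5.0, 7.0][:max(1, cfg.tsne_restarts)]
        labels, sil = None, -1.0
        for attempt, perp in enumerate(perp_ladder):
            seeds = self._node_seeds(cfg.seed, node.node_id, attempt)
            try:
                E = embed(X_scaled[idx], cfg, seed=seeds["tsne"], perplexity=perp)
            except ValueError:
                node.rejection_reason = "too_small"
                logger.info("node %d (n=%d): too small to embed", node.node_id, n)
                return
            labels_a, sil_a = propose_split(E, cfg, seed=seeds["kmeans"],
                                            X_scaled=X_scaled[idx])
            if attempt > 0 and sil_a > cfg.silhouette_threshold:
                ref_sil = self._reference_silhouette(
                    X_scaled[idx], cfg, perp, seeds["tsne"] ^ 0x5EED,
                    seeds["kmeans"])
                logger.info("node %d: retry perp=%s sil=%.3f vs reference %.3f",
                            node.node_id, perp, sil_a, ref_sil)
                if sil_a <= ref_sil + 0.15:
                    sil_a = min(sil_a, cfg.silhouette_threshold)
            if sil_a > sil:
                labels, sil = labels_a, sil_a
            if sil > cfg.silhouette_threshold:
                break
        node.silhouette = sil
        if sil <= cfg.silhouette_threshold:
            node.rejection_reason = "low_silhouette"
            logger.info("node %d (n=%d): rejected low_silhouette (%.3f)",
                        node.node_id, n, sil)
            return

        counts = np.bincount(labels, minlength=2)
        if counts.min() < 3:  # smaller cluster must support >= 3 stratified folds
            node.rejection_reason = "too_small"
            logger.info("node %d (n=%d): cluster sizes %s too small to validate",
                        node.node_id, n, counts.tolist())
            return

        # refine boundary assignments with the supervised view: embedding
        # k-means can misplace an isolated boundary sample that the
        # whole-feature-space classifier places unambiguously; only a small
        # minority of samples may flip, and never below the size floor
        refine = OPLSDA(n_ortho=cfg.n_ortho, scale="pareto",
                        n_folds=cfg.n_folds,
                        random_state=seeds["perm"]).fit(X_logged[idx], labels)
        pred = (refine.predict(X_logged[idx]) == refine.classes_[1]).astype(int)
        flips = int((pred != labels).sum())
        if 0 < flips <= max(1, int(0.02 * n)) and 3 <= pred.sum() <= n - 3:
            logger.info("node %d: %d boundary sample(s) reassigned by the "
                        "supervised refinement", node.node_id, flips)
            labels = pred

        self._n_opls_fits += 1
        report, markers = validate_split(
            X_logged[idx], labels, cfg, seed=seeds["perm"],
            feature_ids=feature_ids,
            X_raw=None if X_raw is None else X_raw[idx],
        )
        node.report = report
        if report.p_perm >= cfg.alpha:
            node.rejection_reason = "not_significant"
            logger.info("node %d (n=%d): rejected not_significant "
                        "(p=%.4f, Q2=%.3f)", node.node_id, n, report.p_perm, report.q2)
            return

        node.child_assignment = labels
        node.markers = markers
        node.rejection_reason = "none"
        accepted.append(node)
        logger.info("node %d (n=%d): ACCEPTED split %d (sil=%.3f, p=%.4f, "
                    "R2Y=%.3f, Q2=%.3f, %d significant markers)",
                    node.node_id, n, len(accepted), sil, report.p_perm,
                    report.r2y, report.q2, len(node.significant_markers()))

        idx_a = idx[labels == 0]
        idx_b = idx[labels == 1]
        if len(idx_b) > len(idx_a):
            idx_a, idx_b = idx_b, idx_a  # larger child first
        child_a = self._make_node(idx_a, node.depth + 1)
        child_b = self._make_node(idx_b, node.depth + 1)
        node.children = (child_a, child_b)
        for child in node.children:
            self._grow(child, X_scaled, X_logged, X_raw, feature_ids, cfg, accepted)


def recursive_fit(table, cfg: SplitConfig | None = None, **overrides) -> SplitTree:
    """Run the full divisive hierarchy on a raw feature table.

    Thin functional wrapper over :class:`RecursiveOPLSDA`; ``overrides``
    update individual :class:`SplitConfig` fields.
    """
    cfg = cfg or SplitConfig()
    if overrides:
        cfg = SplitConfig(**{**cfg.to_dict(), **overrides})
    est = RecursiveOPLSDA(**cfg.to_dict())
    est.fit(table)
    return est.tree_


def pairwise_grid(table, class_labels, cfg: SplitConfig | None = None) -> dict:
    """One-vs-one OPLS-DA baseline over all unordered class pairs.

    Each pair of predefined classes gets its own validated model (same Q2 +
    permutation machinery as the recursive engine); pairs involving a class
    with fewer than 3 samples are skipped with a warning. Returns a dict
    mapping (class_a, class_b) -> :class:`ValidationReport` (or None for a
    skipped pair).
    """
    cfg = cfg or SplitConfig()
    if isinstance(table, FeatureTable):
        logged = log_transform(table) if table.state == "raw" else table
        X = logged.values
    else:
        X = np.log10(np.asarray(table, dtype=float) + 1e-9)
    labels = np.asarray(class_labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    grid: dict = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            mask = (labels == a) | (labels == b)
            sub_y = labels[mask]
            if min((sub_y == a).sum(), (sub_y == b).sum()) < 3:
                logger.warning("pair (%s, %s) skipped: a class has < 3 samples", a, b)
                grid[(a, b)] = None
                continue
            seed = int(np.random.SeedSequence(
                [cfg.seed, classes.index(a), classes.index(b)]).generate_state(1)[0]
                % (2**31 - 1))
            model = OPLSDA(n_ortho=cfg.n_ortho, scale="pareto",
                           n_folds=cfg.n_folds, random_state=seed).fit(X[mask], sub_y)
            grid[(a, b)] = permutation_test(
                X[mask], sub_y, n_perm=cfg.n_perm, seed=seed,
                n_folds=cfg.n_folds, n_ortho=model.n_ortho_, scale="pareto")
    return grid
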