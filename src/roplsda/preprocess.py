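"""Normalization and univariate screening for abundance feature tables.

The pipeline's standard metabolomics preprocessing: a log10 transform with a
small offset so zero abundances stay finite, Pareto scaling (column centering
and division by the square root of the standard deviation), and a univariate
screen combining fold change with Welch t-tests under Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Fold-change screen threshold: |log2 FC| must exceed this (strict).
FC_THRESHOLD = 2.0
#: FDR threshold for the q-value screen (strict <).
Q_THRESHOLD = 0.05


@dataclass
class FeatureTable:
    """A samples x features abundance matrix with identifiers and a state flag.

    Parameters
    ----------
    sample_ids : list of str
        Row identifiers, unique and ordered.
    feature_ids : list of str
        Column identifiers, unique and ordered.
    values : ndarray of shape (n_samples, n_features)
        Abundances. Non-negative while ``state == "raw"``; any real after
        transformation.
    state : {"raw", "logged", "pareto_scaled"}
        Tracks which preprocessing stages have been applied.
    """

    sample_ids: list
    feature_ids: list
    values: np.ndarray
    state: str = "raw"

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample ids")
        if len(set(self.feature_ids)) != d:
            raise ValueError("duplicated feature ids")
        if self.state not in ("raw", "logged", "pareto_scaled"):
            raise ValueError(f"unknown state {self.state!r}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in table; resolve them at load time")
        if self.state == "raw" and (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"raw table contains a negative value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: str = "raw") -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), state)

    def subset(self, sample_indices) -> "FeatureTable":
        idx = np.asarray(sample_indices)
        return FeatureTable(
            [self.sample_ids[i] for i in idx], self.feature_ids,
            self.values[idx], self.state,
        )


@dataclass
class SampleMeta:
    """Per-sample species/region metadata; class label = species + "_" + region."""

    sample_ids: list
    species: list
    region: list

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.species = list(self.species)
        self.region = list(self.region)
        if not (len(self.sample_ids) == len(self.species) == len(self.region)):
            raise ValueError("metadata columns differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids in metadata")

    @property
    def class_labels(self) -> list:
        return [f"{s}_{r}" for s, r in zip(self.species, self.region)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "species": self.species,
             "region": self.region, "class": self.class_labels}
        )


@dataclass
class UnivariateResult:
    """Per-feature fold-change and Welch t-test screen result."""

    feature_id: str
    log2_fc: float
    t_p: float
    q: float
    passes_fc: bool = field(init=False)
    passes_q: bool = field(init=False)

    def __post_init__(self):
        self.passes_fc = bool(abs(self.log2_fc) > FC_THRESHOLD)
        self.passes_q = bool(self.q < Q_THRESHOLD)


def _log_offset(values: np.ndarray) -> float:
    """Half the smallest strictly positive value; 0.5 if none exist."""
    positive = values[values > 0]
    return float(positive.min()) / 2.0 if positive.size else 0.5


def log_transform(table: FeatureTable, base: float = 10.0,
                  offset: float | None = None) -> FeatureTable:
    """Log-transform a raw abundance table: x -> log_base(x + eps).

    ``eps`` defaults to half the smallest strictly positive value in the
    table, keeping zeros finite while preserving the ordering of entries.
    """
    if table.state != "raw":
        raise ValueError(f"log_transform expects a raw table, got state={table.state!r}")
    eps = _log_offset(table.values) if offset is None else float(offset)
    logged = np.log(table.values + eps) / np.log(base)
    return replace(table, values=logged, state="logged")


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Pareto-scale a logged table: center each column, divide by sqrt(sd).

    Zero-variance columns are centered and left unscaled (divisor 1) so that
    feature indices stay aligned downstream; their count is logged.
    """
    if table.state != "logged":
        raise ValueError(f"pareto_scale expects a logged table, got state={table.state!r}")
    values, _, _ = pareto_scale_matrix(table.values)
    return replace(table, values=values, state="pareto_scaled")


def pareto_scale_matrix(X: np.ndarray):
    """Center and Pareto-scale a plain matrix; returns (scaled, means, divisors)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero_var = sd <= 0
    if zero_var.any():
        logger.info("pareto scaling: %d zero-variance column(s) left unscaled",
                    int(zero_var.sum()))
    divisors = np.where(zero_var, 1.0, np.sqrt(np.where(zero_var, 1.0, sd)))
    return (X - means) / divisors, means, divisors


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def univariate_screen(table: FeatureTable, labels: Sequence) -> list[UnivariateResult]:
    """Fold-change + Welch t-test screen between two groups of samples.

    log2 fold changes are computed on raw-scale group means (a fold change on
    logged data is not a fold change); the t-tests run on logged values. BH
    adjustment is applied jointly over all features. A feature with zero
    variance in both groups gets p = 1 when the means agree and p = 0 when
    they differ.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n_samples:
        raise ValueError("labels length does not match sample count")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    mask_a = labels == groups[0]
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    if table.state == "raw":
        raw = table.values
        logged = log_transform(table).values
    elif table.state == "logged":
        logged = table.values
        raw = None
    else:
        raise ValueError("univariate_screen expects a raw or logged table")

    if raw is not None:
        eps = _log_offset(raw)
        # eps floors all-zero group means only; positive means stay exact
        mean_a = np.maximum(raw[mask_a].mean(axis=0), eps)
        mean_b = np.maximum(raw[mask_b].mean(axis=0), eps)
        log2_fc = np.log2(mean_a / mean_b)
    else:
        # logged input: raw-scale means unavailable; fall back to difference of
        # logged means converted to base 2 (exact when within-group spread is 0)
        base_factor = np.log2(10.0)
        log2_fc = (logged[mask_a].mean(axis=0) - logged[mask_b].mean(axis=0)) * base_factor

    a, b = logged[mask_a], logged[mask_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(a, b, equal_var=False, axis=0)
        pvals = np.asarray(t_res.pvalue, dtype=float)
    degenerate = np.isnan(pvals)
    if degenerate.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        pvals[degenerate] = np.where(same_mean[degenerate], 1.0, 0.0)
    qvals = bh_adjust(pvals)

    return [
        UnivariateResult(fid, float(fc), float(p), float(q))
        for fid, fc, p, q in zip(table.feature_ids, log2_fc, pvals, qvals)
    ]
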