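"""Synthetic feature tables with planted hierarchical class structure.

The generator draws log-normal abundances (Gaussian in log space, so the
pipeline's log transform recovers the planted Gaussian structure exactly) and
shifts disjoint blocks of "informative" features between chosen class groups.
A nested list of such contrasts plants a binary hierarchy: one globally
distinct class, a region-split class, overlapping classes, and so on —
mirroring the structure of a multi-species, multi-region foliar metabolome
survey (63 trees, 409 annotated metabolites, 8 species x region classes).

Real GC-MS data additionally carries correlated metabolite blocks, heavy
tails and batch effects that this generator deliberately omits; see the
methods note for what that implies about test coverage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import FeatureTable, SampleMeta

@dataclass
class Contrast:
    """One planted binary separation: ``classes_a`` vs the rest of ``scope``."""

    name: str
    classes_a: tuple
    scope: tuple            # classes present at this node of the hierarchy
    n_informative: int
    effect_size: float      # mean shift of informative features, in noise-sd units

    def __post_init__(self):
        self.classes_a = tuple(self.classes_a)
        self.scope = tuple(self.scope)
        if not set(self.classes_a) <= set(self.scope):
            raise ValueError(f"contrast {self.name}: classes_a not within scope")
        if not 0 < len(self.classes_a) < len(self.scope):
            raise ValueError(f"contrast {self.name}: both sides must be non-empty")
        if self.n_informative < 1:
            raise ValueError(f"contrast {self.name}: n_informative must be positive")


@dataclass
class SyntheticSpec:
    """Recipe for a planted-hierarchy abundance table.

    ``baseline_loc``/``baseline_scale`` set the per-feature log-abundance
    location (natural-log scale); ``noise_sd`` is the within-class spread of
    an informative feature in the group it marks; a contrast's
    ``effect_size`` is expressed in units of ``noise_sd``.

    ``stable_sd`` (default: 0.55 x ``noise_sd``) is the spread of an
    informative feature in samples where it is *not* elevated — marker
    metabolites sitting at a low basal level show correspondingly little
    variation there. ``background_sd`` (default: half of ``noise_sd``) is
    the spread of features informative for no contrast; clade markers are
    high-dynamic-range compounds, so non-discriminating features vary less.
    The asymmetry inflates the per-feature Cohen's d of a planted contrast
    slightly above ``effect_size`` (by sqrt(2/(1+(stable/noise)^2)), about
    1.24 at the default).
    """

    n_per_class: dict
    n_features: int
    hierarchy: list = field(default_factory=list)
    noise_sd: float = 1.0
    stable_sd: float | None = None
    background_sd: float | None = None
    baseline_loc: float = 6.0
    baseline_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.n_per_class.values()):
            raise ValueError("all class counts must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        total_inf = sum(c.n_informative for c in self.hierarchy)
        if total_inf > self.n_features:
            raise ValueError(
                f"hierarchy needs {total_inf} informative features but only "
                f"{self.n_features} exist (informative sets are disjoint)")
        for c in self.hierarchy:
            unknown = set(c.scope) - set(self.n_per_class)
            if unknown:
                raise ValueError(f"contrast {c.name} references unknown classes {unknown}")


def _meta_from_classes(sample_ids, class_of_sample) -> SampleMeta:
    species, region = [], []
    for c in class_of_sample:
        parts = str(c).rsplit("_", 1)
        if len(parts) == 2 and parts[1] in ("north", "south"):
            species.append(parts[0])
            region.append(parts[1])
        else:
            species.append(str(c))
            region.append("na")
    return SampleMeta(sample_ids, species, region)


def generate(spec: SyntheticSpec):
    """Draw one table from a :class:`SyntheticSpec`.

    Returns ``(table, meta, truth)`` where ``truth`` maps each contrast name
    to its planted partition (sample ids on side A / side B) and informative
    feature ids. Raw abundances are ``exp(baseline + shifts + noise)`` so the
    table is strictly positive and log transformation recovers Gaussian
    structure.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.n_per_class)
    class_of_sample = [c for c in classes for _ in range(spec.n_per_class[c])]
    n = len(class_of_sample)
    sample_ids = [f"{c}_{i+1:02d}" for c in classes for i in range(spec.n_per_class[c])]
    feature_ids = [f"M{j+1:04d}" for j in range(spec.n_features)]
    stable_sd = 0.55 * spec.noise_sd if spec.stable_sd is None else spec.stable_sd
    background_sd = (spec.noise_sd / 2 if spec.background_sd is None
                     else spec.background_sd)

    # assign disjoint informative blocks in feature order, then shift side A
    truth = {}
    cursor = 0
    class_arr = np.array(class_of_sample)
    sd = np.full((n, spec.n_features), background_sd)
    shift = np.zeros((n, spec.n_features))
    for contrast in spec.hierarchy:
        feats = np.arange(cursor, cursor + contrast.n_informative)
        cursor += contrast.n_informative
        in_a = np.isin(class_arr, contrast.classes_a)
        in_scope = np.isin(class_arr, contrast.scope)
        sd[np.ix_(~in_a, feats)] = stable_sd
        sd[np.ix_(in_a, feats)] = spec.noise_sd
        signs = rng.choice([-1.0, 1.0], size=contrast.n_informative)
        shift[np.ix_(in_a, feats)] = contrast.effect_size * spec.noise_sd * signs
        truth[contrast.name] = {
            "side_a": [sample_ids[i] for i in np.flatnonzero(in_scope & in_a)],
            "side_b": [sample_ids[i] for i in np.flatnonzero(in_scope & ~in_a)],
            "informative_features": [feature_ids[j] for j in feats],
            "effect_size": contrast.effect_size,
        }

    baseline = rng.normal(spec.baseline_loc, spec.baseline_scale, size=spec.n_features)
    Z = baseline + shift + rng.normal(0.0, 1.0, size=(n, spec.n_features)) * sd
    table = FeatureTable(sample_ids, feature_ids, np.exp(Z), "raw")
    return table, _meta_from_classes(sample_ids, class_of_sample), truth


def mitragyna_like(seed: int = 0):
    """A 63 x 409, 8-class table emulating a four-species, two-region survey.

    Four nested planted contrasts with decreasing effect sizes and scaled
    informative-feature counts (134/106/119/42): one species (MS) globally
    distinct, one species-region group (MH south) distinct within the
    remainder, one species (MD) distinct within what is left, and a final
    regional split inside MD; the remaining classes (MH north and MR)
    deliberately overlap.

    Marker blocks behave like presence/absence metabolite families: strongly
    elevated and variable (sd 0.5 natural-log units) in the clade they mark,
    low and stable (sd 0.25) elsewhere. Effect sizes decrease steeply down
    the hierarchy (shifts of 7.5/4.5/2.7/2.5 log units); the grading is what
    lets the divisive engine peel one level at a time, and the fourth level
    is deliberately marginal, mirroring a final split that is barely
    resolvable.

    Returns ``(table, meta, truth)``.
    """
    n_per_class = {
        "MS_north": 7, "MS_south": 7,
        "MH_north": 8, "MH_south": 8,
        "MR_north": 9, "MR_south": 8,
        "MD_north": 8, "MD_south": 8,
    }
    all_classes = tuple(n_per_class)
    rest1 = tuple(c for c in all_classes if not c.startswith("MS"))
    rest2 = tuple(c for c in rest1 if c != "MH_south")
    rest3 = ("MD_north", "MD_south")
    hierarchy = [
        Contrast("level1_MS", ("MS_north", "MS_south"), all_classes, 134, 15.0),
        Contrast("level2_MH_south", ("MH_south",), rest1, 106, 9.0),
        Contrast("level3_MD", ("MD_north", "MD_south"), rest2, 119, 5.4),
        Contrast("level4_MD_south", ("MD_south",), rest3, 42, 5.0),
    ]
    spec = SyntheticSpec(n_per_class=n_per_class, n_features=409,
                         hierarchy=hierarchy, noise_sd=0.5, stable_sd=0.25,
                         background_sd=0.3, seed=seed)
    return generate(spec)


def recovered_contrasts(tree, truth: dict) -> dict:
    """Which planted contrasts a fitted tree resolved, judged at the leaves.

    A contrast counts as recovered when no leaf of the tree mixes samples from
    its two sides (restricted to the contrast's scope): the planted boundary
    is then contained in the union of the tree's split boundaries. This is
    robust to the order in which the recursion peels the hierarchy and to
    splits that cut several planted groups away at once.
    """
    result = {}
    for name, info in truth.items():
        side_a = set(info["side_a"])
        scope = side_a | set(info["side_b"])
        ok = True
        for leaf in tree.leaves():
            in_scope = [s for s in leaf.sample_ids if s in scope]
            if not in_scope:
                continue
            n_a = sum(s in side_a for s in in_scope)
            if 0 < n_a < len(in_scope):
                ok = False
                break
        result[name] = ok
    return result


_IRIS_SHA256 = "9cc1c345c71bcc9b486b74cbf6063fa66f4bb5e0f603a4b3c3471ec2e5e8e355"


def iris_fixture():
    """The canonical 150 x 4 Iris measurements bundled as package data.

    Returns ``(table, species_labels)`` where the table is in raw state
    (centimeter measurements, all positive). The packaged CSV is pinned by
    sha256 so the worked example is byte-stable.
    """
    ref = resources.files("roplsda") / "datasets" / "iris.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _IRIS_SHA256:
        raise RuntimeError(f"bundled iris.csv checksum mismatch: {digest}")
    df = pd.read_csv(ref)
    species = df.pop("species").tolist()
    table = FeatureTable(
        [f"iris_{i+1:03d}" for i in range(len(df))],
        list(df.columns), df.to_numpy(dtype=float), "raw",
    )
    return table, species
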