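"""Semi-automated mapping suggestions for unlabeled data columns.

Lab feeds frequently arrive under non-informative test codes, so the values
themselves must carry the signal.  Each column is summarized as a feature
vector combining (i) distribution moments — mean, standard deviation,
skewness, excess kurtosis — (ii) comparative statistics against every entry
of a curated reference panel — Welch t statistic, F variance ratio,
two-sample Kolmogorov–Smirnov statistic, interquartile-range ratio — and
(iii) a Bloom-filter bit vector over lowercased tokens of the field name
and (for mostly non-numeric columns) the categorical values.  A k-nearest-
neighbor search over labeled reference columns then ranks candidate codes;
returning the top k rather than a single class lets a data manager pick
among likely alternatives.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import PanelError, ParameterError

#: Sentinel for ratios whose reference denominator is degenerate (zero
#: spread); large but finite so distances stay usable.
RATIO_SENTINEL = 1e6

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class BloomParams:
    """Bloom-filter geometry: m bits, k independent hashes per token."""

    m: int = 256
    k: int = 3


@dataclass
class ColumnProfile:
    """Raw view of one data column: the field name and its string values."""

    field_name: str
    values: list[str]
    numeric: np.ndarray = field(init=False, repr=False)
    n_total: int = field(init=False)
    n_numeric: int = field(init=False)
    n_missing: int = field(init=False)
    categorical: list[str] = field(init=False, repr=False)

    def __post_init__(self):
        numeric, categorical, missing = [], [], 0
        for v in self.values:
            text = "" if v is None else str(v).strip()
            if text == "":
                missing += 1
                continue
            try:
                numeric.append(float(text))
            except ValueError:
                categorical.append(text)
        self.numeric = np.asarray(numeric, dtype=float)
        self.categorical = categorical
        self.n_total = len(self.values)
        self.n_numeric = len(numeric)
        self.n_missing = missing


@dataclass
class ReferencePanel:
    """Curated labeled reference columns: (code, numeric sample) entries."""

    entries: list[tuple[str, np.ndarray]]

    def __post_init__(self):
        codes = [c for c, _ in self.entries]
        if len(set(codes)) != len(codes):
            raise PanelError("panel codes must be unique")
        self.entries = [(c, np.asarray(s, dtype=float)) for c, s in self.entries]
        for code, sample in self.entries:
            if sample.size < 2:
                raise PanelError(f"panel entry {code!r} needs >= 2 numeric values")

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.entries]


@dataclass
class ColumnFeature:
    """Featurized column: numeric block + Bloom text bits."""

    field_name: str
    moments: np.ndarray          # mean, sd, skewness, excess kurtosis
    comparative: np.ndarray      # per panel entry: t, F, KS, IQR ratio
    text_bits: np.ndarray        # boolean, length m

    @property
    def numeric_vector(self) -> np.ndarray:
        return np.concatenate([self.moments, self.comparative])


@dataclass(frozen=True)
class Suggestion:
    code: str
    rank: int
    distance: float


# -- featurization ---------------------------------------------------------

def bloom_bits(tokens, params: BloomParams = BloomParams()) -> np.ndarray:
    """Hash each token k ways into an m-bit vector (stable across runs)."""
    bits = np.zeros(params.m, dtype=bool)
    for token in tokens:
        for i in range(params.k):
            digest = hashlib.sha256(f"{i}:{token}".encode()).digest()
            bits[int.from_bytes(digest[:8], "big") % params.m] = True
    return bits


def tokenize(text: str) -> list[str]:
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def _safe_ratio(num: float, den: float) -> float:
    if den == 0.0:
        return 1.0 if num == 0.0 else RATIO_SENTINEL
    return num / den


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    t = stats.ttest_ind(a, b, equal_var=False).statistic
    if np.isfinite(t):
        return float(t)
    # zero pooled variance: identical means -> 0, else signed sentinel
    diff = float(np.mean(a) - np.mean(b))
    return 0.0 if diff == 0.0 else float(np.sign(diff)) * RATIO_SENTINEL


def featurize(profile: ColumnProfile, panel: ReferencePanel,
              bloom: BloomParams = BloomParams(),
              use_field_name: bool = True) -> ColumnFeature:
    """Build the feature vector for one column against a reference panel.

    Distributional blocks require at least two numeric values; below that
    they are imputed (moments 0; t/KS 0; F and IQR ratio 1) and only the
    text block is informative.  ``use_field_name=False`` reproduces the
    values-only configuration appropriate when field names are opaque codes.
    """
    if not panel.entries:
        raise PanelError("reference panel is empty")

    x = profile.numeric
    if x.size >= 2:
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
        if not np.isfinite(skew):
            skew = 0.0
        if not np.isfinite(kurt):
            kurt = 0.0
        moments = np.array([mean, sd, skew, kurt])
        comparative = []
        for _, ref in panel.entries:
            t = _welch_t(x, ref)
            f = _safe_ratio(float(np.var(x, ddof=1)), float(np.var(ref, ddof=1)))
            ks = float(stats.ks_2samp(x, ref).statistic)
            iqr_ratio = _safe_ratio(float(stats.iqr(x)), float(stats.iqr(ref)))
            comparative.extend([t, f, ks, iqr_ratio])
        comparative = np.asarray(comparative)
    else:
        moments = np.zeros(4)
        comparative = np.tile([0.0, 1.0, 0.0, 1.0], len(panel.entries))

    tokens: list[str] = []
    if use_field_name:
        tokens.extend(tokenize(profile.field_name))
    if profile.n_total and profile.n_numeric / profile.n_total < 0.5:
        for v in profile.categorical:
            tokens.extend(tokenize(v))
    bits = bloom_bits(tokens, bloom)

    return ColumnFeature(field_name=profile.field_name, moments=moments,
                         comparative=comparative, text_bits=bits)


# -- KNN suggestion --------------------------------------------------------

def _jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


def feature_distances(feature: ColumnFeature,
                      training: list[tuple[str, ColumnFeature]],
                      text_weight: float = 1.0) -> np.ndarray:
    """Combined distance to every training column: Euclidean on the numeric
    block standardized per-dimension over the training set, plus
    ``text_weight`` times Jaccard distance on the Bloom bits.

    The variance-ratio (F) and IQR-ratio families are normalized by
    1/sqrt(panel size) per dimension.  Unlike the t and KS statistics, which
    are genuinely pairwise two-sample comparisons, each ratio is the query
    column's own dispersion divided by a fixed per-entry constant — the
    family is rank-one, so repeating it once per panel entry multiplies its
    perfectly correlated sampling noise by the panel size.  The
    normalization keeps each ratio family's total contribution independent
    of how large the panel is.
    """
    train_matrix = np.vstack([f.numeric_vector for _, f in training])
    mu = train_matrix.mean(axis=0)
    sigma = train_matrix.std(axis=0)
    sigma[sigma == 0] = 1.0
    weights = np.ones_like(mu)
    n_panel = (feature.numeric_vector.size - 4) // 4
    if n_panel > 0:
        ratio_scale = 1.0 / np.sqrt(n_panel)
        for j in range(n_panel):
            weights[5 + 4 * j] = ratio_scale  # F variance ratio
            weights[7 + 4 * j] = ratio_scale  # IQR ratio
    q = (feature.numeric_vector - mu) / sigma * weights
    z = (train_matrix - mu) / sigma * weights
    euclid = np.sqrt(((z - q) ** 2).sum(axis=1))
    jac = np.array([_jaccard_distance(feature.text_bits, f.text_bits)
                    for _, f in training])
    return euclid + text_weight * jac


def knn_suggest(feature: ColumnFeature,
                training: list[tuple[str, ColumnFeature]],
                k: int = 5, text_weight: float = 1.0) -> list[Suggestion]:
    """Top-k candidate codes by ascending combined distance; duplicate codes
    collapse to their best-ranked occurrence."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if not training:
        raise ParameterError("training set is empty")
    dists = feature_distances(feature, training, text_weight)
    order = np.lexsort((np.array([c for c, _ in training]), dists))
    suggestions: list[Suggestion] = []
    seen: set[str] = set()
    for idx in order:
        code = training[idx][0]
        if code in seen:
            continue
        seen.add(code)
        suggestions.append(Suggestion(code=code, rank=len(suggestions) + 1,
                                      distance=float(dists[idx])))
        if len(suggestions) == k:
            break
    return suggestions


def panel_training_features(panel: ReferencePanel,
                            bloom: BloomParams = BloomParams(),
                            use_field_name: bool = False,
                            ) -> list[tuple[str, ColumnFeature]]:
    """Featurize each panel entry against the panel itself, producing the
    labeled training set for :func:`knn_suggest`."""
    out = []
    for code, sample in panel.entries:
        profile = ColumnProfile(field_name=code if use_field_name else "",
                                values=[repr(float(v)) for v in sample])
        out.append((code, featurize(profile, panel, bloom, use_field_name)))
    return out
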