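"""Correlation analysis, redundancy-based feature selection, risk banding,
residue-level regression mapping, and a PCA overview.

These are the descriptive-statistics stages that sit between descriptor
extraction and model building: a Pearson/Spearman correlation matrix over
descriptors and condition covariates, a greedy redundancy filter that drops
the member of each highly correlated feature pair with the weaker link to
the response, a three-band aggregation-risk classifier driven by a single
descriptor threshold, and per-residue fluctuation-vs-rate regressions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "BandedClassification",
    "correlation_matrix",
    "select_nonredundant",
    "banded_classifier",
    "residue_level_r2",
    "pca_overview",
]


@dataclass
class CorrelationMatrix:
    """A symmetric correlation matrix with labelled variables."""

    labels: list[str]
    r: pd.DataFrame
    method: str
    zero_variance: list[str] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.r.loc[pair[0], pair[1]])


def correlation_matrix(table: pd.DataFrame, method: str = "pearson"
                       ) -> CorrelationMatrix:
    """Pairwise correlation over the numeric columns of ``table``.

    Pearson is covariance over the product of standard deviations; Spearman
    is Pearson on average-ranked data.  Rows with missing values are handled
    pairwise-complete.  Zero-variance columns yield undefined (NaN)
    coefficients and are reported, never silently set to 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    zero_var = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    if zero_var:
        logger.warning("zero-variance columns (coefficients undefined): %s",
                       zero_var)
    r = num.corr(method=method)
    # pandas fills the diagonal of a zero-variance column with 1; mark the
    # whole row/column undefined instead, keeping the valid diagonal at 1
    for c in zero_var:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    return CorrelationMatrix(labels=list(num.columns), r=r, method=method,
                             zero_variance=zero_var)


def select_nonredundant(corr: CorrelationMatrix | pd.DataFrame,
                        target_corr: pd.Series,
                        threshold: float = 0.8,
                        keep: list[str] | None = None
                        ) -> tuple[list[str], list[dict]]:
    """Drop the weaker member of every feature pair correlated above
    ``threshold``.

    Pairs with |r| > threshold are processed in descending |r|; at each, the
    feature with the smaller |correlation with the response| is removed
    (ties drop the later column, logged).  Features already removed are
    skipped, so the procedure is deterministic given the column order.
    ``keep`` lists features exempt from removal regardless of redundancy
    (retention-by-judgment, e.g. features suspected of a nonlinear link to
    the response).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    r = corr.r if isinstance(corr, CorrelationMatrix) else corr
    features = list(r.columns)
    missing = [f for f in features if f not in target_corr.index]
    if missing:
        raise ValueError(f"target_corr lacks features: {missing}")
    keep = keep or []

    pairs = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            rv = r.loc[a, b]
            if np.isfinite(rv) and abs(rv) > threshold:
                pairs.append((abs(rv), a, b))
    pairs.sort(key=lambda t: (-t[0], features.index(t[1]), features.index(t[2])))

    removed: set[str] = set()
    log: list[dict] = []
    for absr, a, b in pairs:
        if a in removed or b in removed:
            continue
        ta, tb = abs(target_corr[a]), abs(target_corr[b])
        if ta > tb:
            drop, kept_one = b, a
        elif tb > ta:
            drop, kept_one = a, b
        else:
            # tie: drop the later column
            drop, kept_one = (b, a) if features.index(a) < features.index(b) \
                else (a, b)
            logger.info("redundancy tie between %s and %s; dropping %s",
                        a, b, drop)
        entry = {"pair": (a, b), "abs_r": float(absr), "dropped": drop,
                 "kept": kept_one, "tie": bool(ta == tb)}
        if drop in keep:
            entry["dropped"] = None
            entry["kept"] = f"{a},{b} (keep-list)"
            log.append(entry)
            continue
        removed.add(drop)
        log.append(entry)
    retained = [f for f in features if f not in removed]
    return retained, log


@dataclass
class BandedClassification:
    """Outcome of the single-feature three-band aggregation classifier.

    Bands are assigned from the response ln(v): high strictly above the
    upper edge, low strictly below the lower edge, medium otherwise
    (values exactly at an edge fall in the middle band).  The confusion
    counts treat the high band as the positive class.
    """

    n: int
    low: int
    medium: int
    high: int
    tp: int
    fp: int
    fn: int
    tn: int
    feature_threshold: float
    direction: str
    band_edges: tuple[float, float]

    @property
    def precision(self) -> float | None:
        """Percent of flagged conditions truly in the high band (None when
        nothing is flagged)."""
        if self.tp + self.fp == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fp)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "low": self.low, "medium": self.medium,
            "high": self.high, "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "tn": self.tn, "precision_pct": self.precision,
            "feature_threshold": self.feature_threshold,
            "direction": self.direction,
            "band_edges": list(self.band_edges),
        }


def banded_classifier(feature_values, ln_v, feature_threshold: float,
                      direction: str = "below_flags_high",
                      band_edges: tuple[float, float] = (0.0, 4.0)
                      ) -> BandedClassification:
    """Classify conditions into low/medium/high aggregation bands and score a
    single-feature "high risk" flag.

    ``direction`` states which side of ``feature_threshold`` flags high risk:
    for the native-contact fraction small values indicate disrupted structure,
    so ``below_flags_high`` with threshold 0.814 reproduces the canonical
    screen.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(ln_v, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature_values and ln_v must be equal-length 1-D")
    if x.size < 1:
        raise ValueError("need at least one condition")
    if not np.isfinite(feature_threshold):
        raise ValueError("feature_threshold must be finite")
    if direction not in ("below_flags_high", "above_flags_high"):
        raise ValueError(f"unknown direction {direction!r}")
    lo, hi = band_edges
    if not lo < hi:
        raise ValueError("band_edges must be increasing")
    high = y > hi
    low = y < lo
    medium = ~high & ~low
    flagged = x < feature_threshold if direction == "below_flags_high" \
        else x > feature_threshold
    tp = int(np.sum(flagged & high))
    fp = int(np.sum(flagged & ~high))
    fn = int(np.sum(~flagged & high))
    tn = int(np.sum(~flagged & ~high))
    return BandedClassification(
        n=x.size, low=int(low.sum()), medium=int(medium.sum()),
        high=int(high.sum()), tp=tp, fp=fp, fn=fn, tn=tn,
        feature_threshold=float(feature_threshold), direction=direction,
        band_edges=(float(lo), float(hi)),
    )


def residue_level_r2(rmsf_matrix: pd.DataFrame, ln_v: pd.Series) -> pd.Series:
    """Squared Pearson correlation between each residue's fluctuation and the
    aggregation rate across conditions.

    ``rmsf_matrix`` has one row per condition and one column per residue.
    Equivalent to the R^2 of a simple OLS of ln(v) on each residue's RMSF.
    Zero-variance residue columns yield NaN.
    """
    if rmsf_matrix.shape[0] < 3:
        raise ValueError("need at least 3 conditions")
    y = ln_v.reindex(rmsf_matrix.index)
    if y.isna().any():
        raise ValueError("ln_v missing for some conditions")
    r = rmsf_matrix.apply(lambda col: col.corr(y))
    zero_var = rmsf_matrix.std(ddof=0) == 0
    r[zero_var] = np.nan
    out = r ** 2
    out.name = "r2"
    return out


def pca_overview(table: pd.DataFrame, standardize: bool = True
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component overview of a numeric table.

    Columns are z-scored (population sd) when ``standardize`` is set, then
    decomposed by SVD.  Returns the loadings (columns PC1..PCk, sign-fixed
    so each component's largest-magnitude loading is positive) and the
    variance-explained fractions (summing to 1).
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] < 2 or num.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows and 2 columns")
    X = num.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(num.columns, sd) if s == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    frac = s ** 2 / np.sum(s ** 2)
    loadings = vt.T
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return pd.DataFrame(loadings, index=num.columns, columns=cols), frac
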