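"""Model-agnostic Shapley feature attribution.

Attribution uses the interventional (marginal) value function: the value of
a coalition S for an explained row x is the model output averaged over a
background sample in which the features in S take x's values and the rest
keep the background row's values.  Exact enumeration over all 2^p
coalitions is available for small p; a seeded permutation-sampling Monte
Carlo estimator with standard errors covers larger feature sets.  Global
importance ranks features by the mean absolute attribution over explained
rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ShapleyResult",
    "shapley_exact",
    "shapley_permutation",
    "explain_rows",
    "global_importance",
    "EXACT_LIMIT",
]

#: Largest feature count for which 2^p enumeration is attempted.
EXACT_LIMIT = 15


@dataclass
class ShapleyResult:
    """Per-row attributions plus the estimator's metadata.

    ``phi`` has one row per explained sample, one column per feature;
    ``base_value`` is the mean model output over the background, so
    efficiency reads: phi.sum(axis=1) + base_value == model(x_row).
    """

    phi: pd.DataFrame
    base_value: float
    method: str                     # "exact" | "permutation"
    n_permutations: int | None = None
    seed: int | None = None
    standard_errors: pd.DataFrame | None = None


def _prepare(x_row, background, feature_names):
    x = np.asarray(x_row, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a nonempty 2-D array")
    if bg.shape[1] != x.shape[0]:
        raise ValueError("x_row and background feature counts differ")
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(x.shape[0])]
    return x, bg, list(feature_names)


def shapley_exact(model_fn, x_row, background,
                  feature_names=None) -> pd.Series:
    """Exact Shapley values of one row by full coalition enumeration.

    ``model_fn`` maps an (m, p) array to m outputs.  The coalition value
    v(S) is the background-mean of the model on rows that take x's values
    on S; phi_i sums the weighted marginals v(S+i) - v(S) with the classic
    kernel |S|! (p-|S|-1)! / p!.  Requires p <= 15.
    """
    x, bg, names = _prepare(x_row, background, feature_names)
    p = x.shape[0]
    if p > EXACT_LIMIT:
        raise ValueError(
            f"p={p} exceeds the exact-enumeration limit ({EXACT_LIMIT}); "
            "use shapley_permutation"
        )
    n_subsets = 1 << p
    B = bg.shape[0]
    # evaluate v(S) for every coalition in one batched model call
    composites = np.empty((n_subsets * B, p))
    for s in range(n_subsets):
        rows = bg.copy()
        mask = np.array([(s >> j) & 1 for j in range(p)], dtype=bool)
        rows[:, mask] = x[mask]
        composites[s * B:(s + 1) * B] = rows
    outputs = np.asarray(model_fn(composites), dtype=float).reshape(n_subsets, B)
    v = outputs.mean(axis=1)

    w = np.array([factorial(s) * factorial(p - s - 1) / factorial(p)
                  for s in range(p)])
    phi = np.zeros(p)
    for s in range(n_subsets):
        size = bin(s).count("1")
        for i in range(p):
            if not (s >> i) & 1:
                phi[i] += w[size] * (v[s | (1 << i)] - v[s])
    return pd.Series(phi, index=names, name="phi")


def shapley_permutation(model_fn, x_row, background, n_permutations: int,
                        seed: int, feature_names=None
                        ) -> tuple[pd.Series, pd.Series]:
    """Monte-Carlo Shapley estimates by averaging marginal contributions over
    seeded random feature orderings.

    Returns the estimates and their standard errors (between-permutation
    standard deviation over sqrt(n_permutations)).
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    x, bg, names = _prepare(x_row, background, feature_names)
    p = x.shape[0]
    B = bg.shape[0]
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, p))
    for t in range(n_permutations):
        order = rng.permutation(p)
        # p+1 coalition states along the ordering, evaluated in one batch
        rows = np.tile(bg, (p + 1, 1))
        mask = np.zeros(p, dtype=bool)
        for step, j in enumerate(order, start=1):
            mask[j] = True
            block = rows[step * B:(step + 1) * B]
            block[:, mask] = x[mask]
        out = np.asarray(model_fn(rows), dtype=float).reshape(p + 1, B).mean(axis=1)
        contrib[t, order] = np.diff(out)
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return (pd.Series(phi, index=names, name="phi"),
            pd.Series(se, index=names, name="se"))


def explain_rows(model_fn, X, background, method: str = "exact",
                 n_permutations: int = 500, seed: int = 0,
                 feature_names=None) -> ShapleyResult:
    """Attribute the model output for every row of ``X``."""
    Xm = np.asarray(X, dtype=float)
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    bg = np.asarray(background, dtype=float)
    base = float(np.mean(np.asarray(model_fn(bg), dtype=float)))
    phis, ses = [], []
    for row in Xm:
        if method == "exact":
            phis.append(shapley_exact(model_fn, row, bg, feature_names))
        elif method == "permutation":
            phi, se = shapley_permutation(model_fn, row, bg, n_permutations,
                                          seed, feature_names)
            phis.append(phi)
            ses.append(se)
        else:
            raise ValueError(f"unknown method {method!r}")
    phi_df = pd.DataFrame(phis).reset_index(drop=True)
    se_df = pd.DataFrame(ses).reset_index(drop=True) if ses else None
    return ShapleyResult(phi=phi_df, base_value=base, method=method,
                         n_permutations=(n_permutations
                                         if method == "permutation" else None),
                         seed=seed if method == "permutation" else None,
                         standard_errors=se_df)


def global_importance(result: ShapleyResult | pd.DataFrame) -> pd.DataFrame:
    """Rank features by mean |phi| over all explained rows (descending).

    All-zero attributions are flagged degenerate and left in input order.
    """
    phi = result.phi if isinstance(result, ShapleyResult) else result
    if phi.shape[0] < 1:
        raise ValueError("need at least one explained row")
    imp = phi.abs().mean(axis=0)
    degenerate = bool((imp == 0).all())
    if degenerate:
        logger.warning("all attributions are zero; ranking is degenerate")
        ranked = imp
    else:
        ranked = imp.sort_values(ascending=False, kind="stable")
    out = pd.DataFrame({"feature": ranked.index,
                        "mean_abs_phi": ranked.to_numpy()})
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["degenerate"] = degenerate
    return out
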