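"""Identification of discriminatory chromatin contacts.

Three complementary views of which contact pairs separate two sample
classes:

* class-averaged IF maps and their difference (with per-cell standard
  errors of the mean);
* information gain of each contact: the reduction in class-label entropy
  after discretizing the IF values by Fayyad-Irani MDL recursive binary
  partitioning (a feature the MDL criterion refuses to cut carries 0 bits);
* a per-contact two-sample t-test (Welch by default, pooled-variance
  optional), two-sided, filtered at P < alpha with no multiple-testing
  correction.

"Informative" contacts are those that both pass the t-test filter and
have positive information gain, ranked by gain.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ContactMatrix, FeatureIndex, SamplePanel, build_feature_index, panel_feature_matrix
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# class-averaged maps


def class_mean_maps(
    panel: SamplePanel, label_field: str
) -> tuple[dict[str, ContactMatrix], dict[str, ContactMatrix], ContactMatrix]:
    """Cell-wise class means, standard errors, and the difference map.

    Returns ``(means, sems, difference)`` where the difference is
    first-class mean minus second-class mean in sorted label order.  A cell
    unmeasured in every sample of a class is unmeasured in that class's
    output (and in the difference).
    """
    labels = panel.labels(label_field)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"difference map needs a binary label, got {classes}")
    means: dict[str, ContactMatrix] = {}
    sems: dict[str, ContactMatrix] = {}
    for c in classes:
        stack = np.array(
            [s.matrix.values for s in panel if s.label(label_field) == c], dtype=float
        )
        if stack.shape[0] == 0:
            raise DegenerateDataError(f"class {c!r} has no samples")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            mean = np.nanmean(stack, axis=0)
            count = np.sum(np.isfinite(stack), axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(count > 1, sd / np.sqrt(np.maximum(count, 1)), np.nan)
        means[c] = ContactMatrix.from_dense(mean)
        sems[c] = ContactMatrix.from_dense(np.where(count > 0, sem, np.nan))
    diff = means[classes[0]].values - means[classes[1]].values
    return means, sems, ContactMatrix.from_dense(diff, signed=True)


# ---------------------------------------------------------------------------
# supervised discretization + information gain


def _entropy_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _label_counts(codes: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(codes, minlength=k)


def _mdl_accepts(
    n: int, k: int, k1: int, k2: int, ent: float, ent1: float, ent2: float, gain: float
) -> bool:
    """Fayyad-Irani MDL stopping rule: accept a cut only when the gain pays
    for encoding the partition."""
    delta = math.log2(3**k - 2) - (k * ent - k1 * ent1 - k2 * ent2)
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _best_cut(values: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, int] | None:
    """Best boundary (by class-entropy) between sorted distinct values;
    returns (gain-maximizing cut point, split position) or None."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    v = values[order]
    c = codes[order]
    # candidate cuts between distinct adjacent values
    best = None
    best_ent = np.inf
    left = np.zeros(k, dtype=int)
    right = _label_counts(c, k).astype(int)
    for pos in range(1, n):
        left[c[pos - 1]] += 1
        right[c[pos - 1]] -= 1
        if v[pos] == v[pos - 1]:
            continue
        w_ent = (pos / n) * _entropy_counts(left) + ((n - pos) / n) * _entropy_counts(right)
        if w_ent < best_ent - 1e-12:
            best_ent = w_ent
            best = ((v[pos - 1] + v[pos]) / 2.0, pos)
    return best


def _mdl_cuts(values: np.ndarray, codes: np.ndarray, k: int) -> list[float]:
    n = len(values)
    if n < 2:
        return []
    counts = _label_counts(codes, k)
    ent = _entropy_counts(counts)
    if ent == 0.0:
        return []
    found = _best_cut(values, codes, k)
    if found is None:
        return []
    cut, _pos = found
    sel = values <= cut
    c1, c2 = codes[sel], codes[~sel]
    n1, n2 = len(c1), len(c2)
    ent1 = _entropy_counts(_label_counts(c1, k))
    ent2 = _entropy_counts(_label_counts(c2, k))
    gain = ent - (n1 / n) * ent1 - (n2 / n) * ent2
    k_here = int(np.sum(counts > 0))
    k1 = int(np.sum(_label_counts(c1, k) > 0))
    k2 = int(np.sum(_label_counts(c2, k) > 0))
    if gain <= 0 or not _mdl_accepts(n, k_here, k1, k2, ent, ent1, ent2, gain):
        return []
    left_cuts = _mdl_cuts(values[sel], c1, k)
    right_cuts = _mdl_cuts(values[~sel], c2, k)
    return sorted(left_cuts + [cut] + right_cuts)


def discretize_supervised(values, labels) -> list[float]:
    """Fayyad-Irani MDL recursive binary discretization.

    Returns the accepted cut points (possibly none: a feature whose
    ordering carries no class information stays undiscretized).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValidationError("values and labels differ in length")
    if len(values) < 2:
        return []
    classes, codes = np.unique(labels, return_inverse=True)
    return _mdl_cuts(values, codes, len(classes))


def information_gain(values, labels) -> float:
    """Class-entropy reduction (bits, base 2) of a feature after MDL
    discretization; 0 when no cut is accepted."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    k = len(classes)
    cuts = _mdl_cuts(values, codes, k)
    if not cuts:
        return 0.0
    h0 = _entropy_counts(_label_counts(codes, k))
    bins = np.digitize(values, cuts, right=True)
    h_cond = 0.0
    n = len(values)
    for b in np.unique(bins):
        sel = bins == b
        h_cond += (sel.sum() / n) * _entropy_counts(_label_counts(codes[sel], k))
    return float(h0 - h_cond)


# ---------------------------------------------------------------------------
# per-contact t-tests and the score table


def _welch_or_student(
    A: np.ndarray, B: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t per column; the degenerate zero-variance case
    is resolved by the documented convention (equal means -> P=1, unequal
    -> P->0 with a warning)."""
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(degenerate):
        delta = A.mean(axis=0) - B.mean(axis=0)
        mean_eq = np.isclose(delta, 0.0)
        n_deg = int(np.sum(degenerate & ~mean_eq))
        if n_deg:
            logger.warning(
                "%d features have zero variance but unequal means; P set to 0", n_deg
            )
        with np.errstate(invalid="ignore"):
            t_inf = np.where(mean_eq, 0.0, np.sign(delta) * np.inf)
        t = np.where(degenerate, t_inf, t)
        p = np.where(degenerate, np.where(mean_eq, 1.0, 0.0), p)
    bad = ~np.isfinite(p)
    if np.any(bad):  # residual NaNs from near-degenerate inputs
        p = np.where(bad, 1.0, p)
        t = np.where(bad, 0.0, t)
    return t, p


def ttest_contacts(
    panel: SamplePanel,
    label_field: str,
    alpha: float = 0.01,
    equal_var: bool = False,
    index: FeatureIndex | None = None,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-contact two-sample t-test score table.

    One row per feature-index pair with class means/SEMs, the mean
    difference, t statistic, two-sided P value and the ``passes`` flag
    (P < alpha).  No multiple-testing correction is applied by default;
    ``correction="benjamini-hochberg"`` switches ``passes`` to an FDR
    criterion and is clearly a deviation from the default analysis.
    """
    labels = np.asarray(panel.labels(label_field))
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"t-test filtering needs a binary label, got {classes}")
    if index is None:
        index = build_feature_index(panel)
    X = panel_feature_matrix(panel, index).to_numpy()
    A = X[labels == classes[0]]
    B = X[labels == classes[1]]
    if len(A) < 2 or len(B) < 2:
        raise DegenerateDataError("need >= 2 samples per class for a t-test")
    t, p = _welch_or_student(A, B, equal_var)
    passes = p < alpha
    if correction == "benjamini-hochberg":
        passes = _bh_reject(p, alpha)
    pairs = np.asarray(index.pairs, dtype=int)
    df = pd.DataFrame(
        {
            "frag_i": pairs[:, 0],
            "frag_j": pairs[:, 1],
            f"mean_{classes[0]}": A.mean(axis=0),
            f"mean_{classes[1]}": B.mean(axis=0),
            f"sem_{classes[0]}": A.std(axis=0, ddof=1) / np.sqrt(len(A)),
            f"sem_{classes[1]}": B.std(axis=0, ddof=1) / np.sqrt(len(B)),
            "diff": A.mean(axis=0) - B.mean(axis=0),
            "t_stat": t,
            "p_value": p,
            "passes": passes,
        }
    )
    df.attrs["classes"] = classes
    df.attrs["alpha"] = alpha
    return df


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    below = np.where(p[order] <= (np.arange(m) + 1) / m * alpha)[0]
    reject = np.zeros(m, dtype=bool)
    if len(below):
        reject[order[: below.max() + 1]] = True
    return reject


def rank_informative_contacts(
    panel: SamplePanel,
    label_field: str,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Join information gain with the t-test filter and rank.

    Adds ``info_gain_bits`` and ``informative`` (t-test pass AND gain > 0)
    to the t-test table; rows sorted by descending gain, ties by (i, j).
    """
    index = build_feature_index(panel)
    df = ttest_contacts(panel, label_field, alpha=alpha, equal_var=equal_var, index=index)
    labels = np.asarray(panel.labels(label_field))
    X = panel_feature_matrix(panel, index).to_numpy()
    gains = np.array([information_gain(X[:, j], labels) for j in range(X.shape[1])])
    df["info_gain_bits"] = gains
    df["informative"] = df["passes"] & (gains > 0)
    df = df.sort_values(
        ["info_gain_bits", "frag_i", "frag_j"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# heatmap rendering (reporting convenience)


def plot_contact_heatmap(
    matrix: ContactMatrix | np.ndarray,
    path,
    title: str = "",
    symmetric: bool = False,
) -> None:
    """Render a contact map as a PNG/SVG heatmap; with ``symmetric=True``
    the colour scale is centred on zero (for difference maps)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values if isinstance(matrix, ContactMatrix) else np.asarray(matrix)
    fig, ax = plt.subplots(figsize=(6, 5))
    if symmetric:
        vmax = np.nanmax(np.abs(values))
        im = ax.imshow(values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(values, cmap="YlOrRd")
    ax.set_xlabel("fragment")
    ax.set_ylabel("fragment")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scores_to_matrix(df: pd.DataFrame, n_fragments: int, column: str = "info_gain_bits") -> np.ndarray:
    """Place a score-table column back onto a symmetric fragment grid."""
    out = np.full((n_fragments, n_fragments), np.nan)
    for _, row in df.iterrows():
        i, j = int(row["frag_i"]) - 1, int(row["frag_j"]) - 1
        out[i, j] = out[j, i] = row[column]
    return out
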