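"""Permutational multivariate statistics for scenario analysis.

The scenario engine produces community matrices (replicate runs x state
variables). This module implements the analysis chain applied to them:
column normalisation, Euclidean distances, crossed-design PERMANOVA with
permutation of residuals under a reduced model, a posteriori pairwise
tests, PERMDISP (homogeneity of multivariate dispersions), CAP (canonical
analysis of principal coordinates), non-metric MDS, mean-distance effect
sizes and classification of stressor interactions.

PERMANOVA follows Anderson's distance-based partitioning: the total sum of
squares is the sum of squared inter-point distances divided by n, and term
sums of squares come from orthogonal effect projectors of the balanced
factorial design applied in principal-coordinate space. Significance uses
the Freedman-Lane scheme: for each term, the residuals of the model
excluding that term are permuted, the term's pseudo-F is recomputed, and
p = (exceedances + 1) / (n_perm + 1).

Principal-coordinate decompositions keep negative-eigenvalue axes in a
separate block and subtract their squared contributions (Anderson's
corrected distances); with Euclidean input distances — the only distance
used in this package — the negative block is empty up to rounding.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.manifold import MDS

__all__ = [
    "DistanceMatrix",
    "drop_constant_columns",
    "PermanovaResult",
    "DispersionResult",
    "OrdinationResult",
    "normalise",
    "distance_matrix",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "cap",
    "nmds",
    "effect_size",
    "classify_interaction",
    "axis_correlations",
]

_EIG_TOL = 1e-8


class DegenerateDistanceError(ValueError):
    """Raised when a test is undefined (e.g. all points identical)."""


# --------------------------------------------------------------------------
# normalisation and distances


def normalise(matrix):
    """Z-score every column (mean 0, sd 1 with denominator n-1).

    Accepts a :class:`~reefcast.scenarios.CommunityMatrix` (returns a new
    one flagged as normalised) or a plain DataFrame/array. Constant columns
    are rejected: drop the variable (e.g. urchins at sites without urchins)
    before normalising.
    """
    from .scenarios import CommunityMatrix  # local import to avoid a cycle

    if isinstance(matrix, CommunityMatrix):
        data = normalise(matrix.data)
        return CommunityMatrix(
            data=data,
            groups=matrix.groups.copy(),
            year=matrix.year,
            site_label=matrix.site_label,
            normalised=True,
        )

    df = pd.DataFrame(matrix)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to normalise")
    sd = df.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(
            f"constant column(s) {constant}: drop the variable before normalising"
        )
    out = (df - df.mean(axis=0)) / sd
    if isinstance(matrix, np.ndarray):
        return out.to_numpy()
    return out


def drop_constant_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove zero-variance variables (e.g. the decoupled urchin stock,
    identical across runs) ahead of normalisation; returns the reduced
    frame and the dropped column names."""
    sd = df.std(axis=0, ddof=1)
    dropped = sd[sd == 0].index.tolist()
    return df.drop(columns=dropped), dropped


@dataclass
class DistanceMatrix:
    """Square symmetric Euclidean distance matrix with factor labels."""

    values: np.ndarray
    labels: pd.DataFrame | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        labels = None if self.labels is None else self.labels.iloc[idx].reset_index(drop=True)
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels)


def distance_matrix(matrix) -> DistanceMatrix:
    """Euclidean distance matrix of a (normalised) community matrix."""
    from .scenarios import CommunityMatrix

    if isinstance(matrix, CommunityMatrix):
        d = squareform(pdist(matrix.data.to_numpy(), metric="euclidean"))
        return DistanceMatrix(d, matrix.groups.copy())
    arr = np.asarray(pd.DataFrame(matrix), dtype=float)
    return DistanceMatrix(squareform(pdist(arr, metric="euclidean")))


# --------------------------------------------------------------------------
# principal coordinates


def _gower(dist: np.ndarray) -> np.ndarray:
    a = -0.5 * dist**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _pcoa(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates: (positive-axis scores, negative-axis scores).

    Axes with |eigenvalue| below a relative tolerance are discarded; the
    negative block holds the imaginary-axis magnitudes used for corrected
    centroid distances.
    """
    g = _gower(dist)
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    scale = max(abs(lam[0]), abs(lam[-1]), 1.0)
    pos = lam > _EIG_TOL * scale
    neg = lam < -_EIG_TOL * scale
    y_pos = vec[:, pos] * np.sqrt(lam[pos])
    y_neg = vec[:, neg] * np.sqrt(-lam[neg])
    return y_pos, y_neg


# --------------------------------------------------------------------------
# balanced factorial machinery


def _cell_codes(design: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    key = design[list(cols)].astype(str).agg("|".join, axis=1)
    return pd.factorize(key)[0]


def _averaging_projector(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    h = np.zeros((n, n))
    for c in np.unique(codes):
        idx = np.where(codes == c)[0]
        h[np.ix_(idx, idx)] = 1.0 / len(idx)
    return h


def _effect_projectors(design: pd.DataFrame) -> tuple[dict, np.ndarray, int]:
    """Orthogonal effect projectors for every term of the crossed design.

    Returns ({term: (projector, df)}, residual projector, residual df) via
    the Moebius (inclusion-exclusion) expansion over averaging projectors,
    which is exact for balanced designs.
    """
    factors = list(design.columns)
    n = len(design)

    # balance check: full crossing must have equal cell sizes
    full_codes = _cell_codes(design, tuple(factors))
    counts = np.bincount(full_codes)
    if counts.min() != counts.max():
        raise ValueError(
            "unbalanced design: all cells of the full crossing must have "
            f"equal replicate counts (got {sorted(set(counts))})"
        )

    averaging = {(): np.full((n, n), 1.0 / n)}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            averaging[combo] = _averaging_projector(_cell_codes(design, combo))

    terms: dict[tuple[str, ...], tuple[np.ndarray, int]] = {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            e = np.zeros((n, n))
            for k in range(0, r + 1):
                sign = (-1) ** (r - k)
                for sub in itertools.combinations(combo, k):
                    e += sign * averaging[sub]
            df = 1
            for f in combo:
                df *= design[f].nunique() - 1
            terms[combo] = (e, df)

    residual = np.eye(n) - averaging[tuple(factors)]
    df_res = n - int(np.prod([design[f].nunique() for f in factors]))
    return terms, residual, df_res


def _orthonormal_basis(projector: np.ndarray, rank: int) -> np.ndarray:
    lam, vec = np.linalg.eigh(projector)
    idx = np.argsort(lam)[::-1][:rank]
    return vec[:, idx]


def _term_label(combo: tuple[str, ...]) -> str:
    return " x ".join(combo)


@dataclass
class PermanovaResult:
    """Distance-based factorial ANOVA table.

    ``table`` rows: one per term plus Residual and Total, with columns
    df, SS, MS, pseudo_F and p_perm. ``degenerate`` flags a zero total sum
    of squares (all points identical), in which case no p is emitted.
    """

    table: pd.DataFrame
    n_perm: int
    scheme: str = "permutation of residuals under a reduced model"
    degenerate: bool = False


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame | list[str] | np.ndarray,
    n_perm: int = 4999,
    seed: int | None = None,
) -> PermanovaResult:
    """Crossed fixed-factor PERMANOVA on a distance matrix.

    ``design`` holds one column per factor (a single list/array is treated
    as a one-factor design). The design must be balanced. Term sums of
    squares come from orthogonal effect projectors in principal-coordinate
    space; each term's p-value uses Freedman-Lane permutation of the
    residuals of the model that excludes the term.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    if isinstance(design, (list, np.ndarray, pd.Series)):
        design = pd.DataFrame({"factor": np.asarray(design)})
    design = design.reset_index(drop=True)
    n = len(dist)
    if len(design) != n:
        raise ValueError("design length must match distance matrix size")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    terms, resid_proj, df_res = _effect_projectors(design)
    y_pos, y_neg = _pcoa(dist.values)
    sign = np.concatenate([np.ones(y_pos.shape[1]), -np.ones(y_neg.shape[1])])
    y = np.hstack([y_pos, y_neg])  # grand-mean centred by construction

    def ss(x: np.ndarray) -> float | np.ndarray:
        return (x**2 * sign).sum(axis=(-2, -1))

    ss_total = float(ss(y))
    if ss_total <= 1e-12 * n:
        rows = [
            {"term": _term_label(c), "df": df, "SS": 0.0, "MS": 0.0,
             "pseudo_F": np.nan, "p_perm": np.nan}
            for c, (_, df) in terms.items()
        ]
        rows.append({"term": "Residual", "df": df_res, "SS": 0.0, "MS": 0.0,
                     "pseudo_F": np.nan, "p_perm": np.nan})
        rows.append({"term": "Total", "df": n - 1, "SS": 0.0, "MS": np.nan,
                     "pseudo_F": np.nan, "p_perm": np.nan})
        return PermanovaResult(pd.DataFrame(rows).set_index("term"),
                               n_perm=n_perm, degenerate=True)

    bases = {c: _orthonormal_basis(p, df) for c, (p, df) in terms.items()}
    ss_terms = {c: float(ss(b.T @ y)) for c, b in bases.items()}
    ss_res = ss_total - sum(ss_terms.values())
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    rows = []
    for combo, (proj, df) in terms.items():
        f_obs = (ss_terms[combo] / df) / ms_res
        # reduced model: every term except this one
        h_red = np.full((n, n), 1.0 / n)
        for other, (p_other, _) in terms.items():
            if other != combo:
                h_red = h_red + p_other
        fitted = h_red @ y
        resid = y - fitted

        exceed = 0
        chunk = max(1, min(n_perm, int(2e7 // (n * max(y.shape[1], 1)))))
        u_term = bases[combo]
        u_all = np.hstack(list(bases.values()))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perms = np.array([rng.permutation(n) for _ in range(m)])
            y_star = fitted[None, :, :] + resid[perms]
            ss_t = ((u_term.T @ y_star) ** 2 * sign).sum(axis=(-2, -1))
            ss_model = ((u_all.T @ y_star) ** 2 * sign).sum(axis=(-2, -1))
            ss_tot_star = (y_star**2 * sign).sum(axis=(-2, -1))
            ss_res_star = np.maximum(ss_tot_star - ss_model, 1e-300)
            f_star = (ss_t / df) / (ss_res_star / df_res)
            exceed += int(np.sum(f_star >= f_obs - 1e-12))
            done += m
        p = (exceed + 1) / (n_perm + 1)
        rows.append({"term": _term_label(combo), "df": df, "SS": ss_terms[combo],
                     "MS": ss_terms[combo] / df, "pseudo_F": f_obs, "p_perm": p})

    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "MS": ms_res,
                 "pseudo_F": np.nan, "p_perm": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "MS": np.nan,
                 "pseudo_F": np.nan, "p_perm": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm=n_perm)


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: np.ndarray | pd.Series | list,
    n_perm: int = 4999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way PERMANOVA between every unordered pair of groups.

    Reports both the pseudo-F and the pseudo-t (= sqrt F) statistic with
    an unadjusted permutation p-value per comparison — no multiplicity
    correction is applied, following the source analysis convention.
    Groups with fewer than two members are skipped with a warning.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    groups = np.asarray(groups)
    if len(groups) != len(dist):
        raise ValueError("group labels must match distance matrix size")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        idx = np.where((groups == a) | (groups == b))[0]
        if np.sum(groups == a) < 2 or np.sum(groups == b) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): group with < 2 members")
            continue
        sub = dist.submatrix(idx)
        res = permanova(
            sub,
            pd.DataFrame({"group": groups[idx]}),
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        f = res.table.loc["group", "pseudo_F"]
        rows.append({
            "group_a": a, "group_b": b,
            "pseudo_F": f, "pseudo_t": np.sqrt(f) if np.isfinite(f) else np.nan,
            "p_perm": res.table.loc["group", "p_perm"],
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionResult:
    """PERMDISP output: per-group mean distance-to-centroid and the
    permutation test for homogeneity of dispersions."""

    group_means: pd.Series
    distances: pd.Series
    f_statistic: float
    p_perm: float
    n_perm: int


def _centroid_distances(dist: DistanceMatrix, groups: np.ndarray) -> np.ndarray:
    y_pos, y_neg = _pcoa(dist.values)
    z = np.empty(len(groups), dtype=float)
    for g in pd.unique(groups):
        idx = np.where(groups == g)[0]
        c_pos = y_pos[idx].mean(axis=0)
        c_neg = y_neg[idx].mean(axis=0) if y_neg.size else np.zeros(0)
        d2 = ((y_pos[idx] - c_pos) ** 2).sum(axis=1)
        if y_neg.size:
            d2 = d2 - ((y_neg[idx] - c_neg) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for c in range(k):
        grp = values[codes == c]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
        ss_within += ((grp - grp.mean()) ** 2).sum()
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permdisp(
    dist: DistanceMatrix,
    groups: np.ndarray | pd.Series | list,
    n_perm: int = 4999,
    seed: int | None = None,
) -> DispersionResult:
    """Test for homogeneity of multivariate dispersions.

    Distances to group centroids are computed in principal-coordinate
    space (with the negative-axis correction); the F statistic of a
    one-way ANOVA on those distances is assessed by permuting the
    least-squares residuals of the distances across groups.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if np.sum(groups == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    codes = pd.Categorical(groups, categories=levels).codes
    k = len(levels)
    z = _centroid_distances(dist, groups)
    f_obs = _anova_f(z, codes, k)

    group_means = pd.Series({g: z[groups == g].mean() for g in levels})
    means_per_point = group_means.to_numpy()[codes]
    resid = z - means_per_point

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_star = _anova_f(resid[rng.permutation(len(z))], codes, k)
        if f_star >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return DispersionResult(
        group_means=group_means,
        distances=pd.Series(z),
        f_statistic=f_obs,
        p_perm=p,
        n_perm=n_perm,
    )


# --------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    """Ordination coordinates plus method-specific diagnostics."""

    method: str
    coordinates: np.ndarray
    stress: float | None = None
    canonical_correlations: np.ndarray | None = None
    allocation_success: float | None = None
    m_axes: int | None = None
    variable_correlations: pd.DataFrame | None = None


def _cap_axes(q_m: np.ndarray, codes: np.ndarray, k: int):
    """Canonical eigen-analysis of Q'HQ for the group projector H."""
    n = len(codes)
    x = np.zeros((n, k))
    x[np.arange(n), codes] = 1.0
    x = x - x.mean(axis=0)
    # projector onto centred group space via least squares
    gram = x.T @ x
    h_qx = q_m.T @ x            # m x k
    mat = h_qx @ np.linalg.pinv(gram) @ h_qx.T
    lam, vec = np.linalg.eigh(mat)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, 1.0)
    vec = vec[:, order]
    n_axes = min(k - 1, q_m.shape[1])
    return lam[:n_axes], vec[:, :n_axes]


def _loo_success(q_m: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Leave-one-out allocation success (%) of nearest-centroid
    classification in canonical space, refitting the axes per left-out
    observation on fixed principal coordinates."""
    n = len(codes)
    correct = 0
    all_idx = np.arange(n)
    for i in range(n):
        rest = all_idx != i
        _, w = _cap_axes(q_m[rest], codes[rest], k)
        scores = q_m[rest] @ w
        centroids = np.vstack([
            scores[codes[rest] == c].mean(axis=0) for c in range(k)
        ])
        s_i = q_m[i] @ w
        if int(np.argmin(((centroids - s_i) ** 2).sum(axis=1))) == codes[i]:
            correct += 1
    return 100.0 * correct / n


def cap(
    dist: DistanceMatrix,
    groups: np.ndarray | pd.Series | list,
    m_axes: int | str = "auto",
) -> OrdinationResult:
    """Canonical analysis of principal coordinates.

    Principal coordinates are truncated to ``m_axes`` orthonormal axes and
    canonical discriminant axes maximising between-group separation
    relative to within-group dispersion are extracted. With
    ``m_axes="auto"`` the number of axes minimising leave-one-out
    misclassification is chosen (ties resolved toward fewer axes).
    Reports canonical correlations and the leave-one-out allocation
    success of nearest-centroid classification.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    codes = pd.Categorical(groups, categories=levels).codes

    y_pos, _ = _pcoa(dist.values)
    # orthonormal principal-coordinate axes (unit-scaled)
    norms = np.linalg.norm(y_pos, axis=0)
    q = y_pos / norms
    max_m = q.shape[1]
    if max_m == 0:
        raise DegenerateDistanceError("no positive principal-coordinate axes")

    if m_axes == "auto":
        candidates = range(1, min(max_m, len(groups) - 2) + 1)
        best_m, best_success = None, -1.0
        for m in candidates:
            success = _loo_success(q[:, :m], codes, k)
            if success > best_success + 1e-12:
                best_m, best_success = m, success
        m = best_m
        success = best_success
    else:
        m = int(m_axes)
        if not 1 <= m <= max_m:
            raise ValueError(f"m_axes must be in [1, {max_m}]")
        success = _loo_success(q[:, :m], codes, k)

    lam, w = _cap_axes(q[:, :m], codes, k)
    scores = q[:, :m] @ w
    return OrdinationResult(
        method="CAP",
        coordinates=scores,
        canonical_correlations=np.sqrt(lam),
        allocation_success=success,
        m_axes=m,
    )


def nmds(
    dist: DistanceMatrix,
    k_dims: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling (Kruskal stress-1).

    SMACOF with isotonic (monotone) regression over ``n_restarts`` random
    starts; the lowest-stress configuration is returned. Stress is the
    normalised Kruskal stress-1 (0.09 means a good 2-D representation).
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    n = len(dist)
    if k_dims < 1:
        raise ValueError("k_dims must be >= 1")
    if k_dims >= n - 1:
        raise ValueError(f"k_dims must be < n - 1 = {n - 1}")
    import inspect

    kwargs = dict(
        n_components=k_dims,
        n_init=n_restarts,
        max_iter=500,
        eps=1e-9,
        normalized_stress=True,
        random_state=None if seed is None else int(seed),
    )
    sig = inspect.signature(MDS).parameters
    if "metric_mds" in sig:  # sklearn >= 1.9 parameter names
        kwargs.update(metric="precomputed", metric_mds=False, init="random")
    else:
        kwargs.update(metric=False, dissimilarity="precomputed")
    model = MDS(**kwargs)
    coords = model.fit_transform(dist.values)
    return OrdinationResult(method="nMDS", coordinates=coords,
                            stress=float(model.stress_))


def axis_correlations(
    variables: pd.DataFrame, coordinates: np.ndarray, threshold: float = 0.0
) -> pd.DataFrame:
    """Spearman rank correlations between variables and ordination axes.

    Rows below ``threshold`` in absolute value on every axis are dropped
    (the conventional display cut-off for vector overlays is |r| > 0.20).
    """
    coords = np.asarray(coordinates)
    rows = {}
    for name in variables.columns:
        rows[name] = [
            spearmanr(variables[name], coords[:, j]).statistic
            for j in range(coords.shape[1])
        ]
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"axis_{j + 1}" for j in range(coords.shape[1])],
    )
    if threshold > 0:
        out = out[(out.abs() > threshold).any(axis=1)]
    return out


# --------------------------------------------------------------------------
# effect sizes and interaction classification


def effect_size(
    dist: DistanceMatrix,
    groups: np.ndarray | pd.Series | list,
    group_a,
    group_b,
) -> float:
    """Mean Euclidean distance between all cross-group pairs of points."""
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))
    groups = np.asarray(groups)
    idx_a = np.where(groups == group_a)[0]
    idx_b = np.where(groups == group_b)[0]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be non-empty")
    return float(dist.values[np.ix_(idx_a, idx_b)].mean())


def classify_interaction(
    effect_a: float, effect_b: float, effect_ab: float, tolerance: float = 0.0
) -> str:
    """Classify a two-stressor interaction against additivity.

    The combined effect is compared with the sum of the single-stressor
    effects: smaller by more than ``tolerance`` is antagonistic, larger is
    synergistic, otherwise additive.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if effect_a < 0 or effect_b < 0 or effect_ab < 0:
        raise ValueError("effect sizes must be >= 0")
    total = effect_a + effect_b
    if effect_ab < total - tolerance:
        return "antagonistic"
    if effect_ab > total + tolerance:
        return "synergistic"
    return "additive"
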