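"""Community ecology statistics: Shannon diversity, Bray-Curtis
dissimilarity, non-metric MDS, PERMANOVA, Mantel tests, two-way ANOVA with
Tukey HSD, and a REML random-intercept linear mixed model.

These are self-contained implementations so that every permutation scheme,
tie rule, and degrees-of-freedom convention is explicit and testable; the
test suite cross-checks them against independent reference implementations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.optimize import isotonic_regression

logger = logging.getLogger("rhizovir")


# ---------------------------------------------------------------------------
# diversity and dissimilarity
# ---------------------------------------------------------------------------

def shannon_diversity(profile: np.ndarray | pd.Series) -> float:
    """Shannon's H on a nonnegative abundance profile, natural log."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("abundance profile must be nonnegative")
    total = p.sum()
    if total <= 0:
        logger.warning("all-zero profile: Shannon H undefined")
        return float("nan")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class DistanceMatrix:
    """Square symmetric sample distance matrix with a transform tag."""

    values: pd.DataFrame
    transform: str = "none"

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def condensed(self) -> np.ndarray:
        arr = self.to_numpy()
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]


def bray_curtis(
    matrix: pd.DataFrame, transform: str | None = "sqrt"
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    matrix is sample x taxon, nonnegative. The default square-root transform
    is applied before computing d(s, t) = sum|x - y| / sum(x + y). Pairs of
    all-zero profiles get distance 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundance matrix must be nonnegative")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform not in (None, "none"):
        raise ValueError(f"unknown transform: {transform}")
    # pairwise |x-y| sums via broadcasting; n is small (samples)
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    if ((tot == 0) & ~np.eye(len(x), dtype=bool)).any():
        logger.warning("pair(s) of all-zero profiles: distance set to 0")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(
        pd.DataFrame(d, index=matrix.index, columns=matrix.index),
        transform=transform or "none",
    )


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    seed: int
    converged: bool = True
    #: stress-1 values recorded per iteration for the best start
    stress_history: list[float] = field(default_factory=list)


def _config_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _stress_and_disparities(
    dist_flat: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and monotone disparities for one configuration.

    dist_flat holds configuration distances for the upper-triangle pairs;
    order sorts pairs by ascending dissimilarity. Disparities are the
    isotonic (pool-adjacent-violators) fit of distances in that order.
    """
    dhat = np.empty_like(dist_flat)
    dhat[order] = isotonic_regression(dist_flat[order]).x
    denom = (dist_flat**2).sum()
    if denom <= 0:
        return 0.0, dhat
    stress = math.sqrt(((dist_flat - dhat) ** 2).sum() / denom)
    return stress, dhat


def nmds(
    distance: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """NMDS by SMACOF-style majorization with isotonic regression.

    Minimizes Kruskal stress-1. The first start is initialized from
    classical (metric) MDS of the dissimilarities; remaining starts are
    random. Within a start the recorded stress sequence is non-increasing:
    an iteration that would raise stress reverts and terminates the start.
    """
    d = distance.to_numpy()
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    iu = np.triu_indices(n, k=1)
    diss_flat = d[iu]
    order = np.argsort(diss_flat, kind="stable")
    rng = np.random.default_rng(seed)

    best_stress, best_coords, any_converged = np.inf, None, False
    best_history: list[float] = []
    for start in range(max(1, n_starts)):
        if start == 0:
            coords = _classical_mds(d, k)
        else:
            coords = rng.standard_normal((n, k))
        prev_stress = np.inf
        converged = False
        history: list[float] = []
        for _ in range(max_iter):
            dist = _config_distances(coords)
            dist_flat = dist[iu]
            stress, dhat_flat = _stress_and_disparities(dist_flat, order)
            if stress > prev_stress + 1e-12:
                break  # majorization overshoot: keep previous configuration
            history.append(stress)
            if prev_stress - stress < tol:
                prev_stress = stress
                prev_coords = coords
                converged = True
                break
            prev_stress, prev_coords = stress, coords
            # Guttman transform using the disparities
            dhat = np.zeros((n, n))
            dhat[iu] = dhat_flat
            dhat = dhat + dhat.T
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(dist > 0, dhat / np.where(dist > 0, dist, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            coords = b @ coords / n
        else:
            prev_coords = coords
        if prev_stress < best_stress:
            best_stress, best_coords = prev_stress, prev_coords
            best_history = history
            any_converged = converged
    if not any_converged:
        logger.warning("NMDS did not converge within max_iter; best-so-far returned")
    best_coords = best_coords - best_coords.mean(axis=0)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            best_coords,
            index=distance.sample_ids,
            columns=[f"NMDS{i + 1}" for i in range(k)],
        ),
        stress=float(best_stress),
        n_starts=n_starts,
        seed=seed,
        converged=any_converged,
        stress_history=best_history,
    )


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    idx = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals_k)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    term: str
    statistic: float
    effect_size: float | None
    p_value: float
    n_permutations: int
    seed: int
    df: int | None = None
    extra: dict = field(default_factory=dict)


def _dummy_matrix(levels: list[str]) -> np.ndarray:
    uniq = sorted(set(levels))
    return np.column_stack([[1.0 if v == u else 0.0 for v in levels] for u in uniq])


def _column_space_projector(m: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of m, and its rank."""
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def _term_columns(term: str, factors: dict[str, list[str]]) -> np.ndarray:
    """Dummy columns for a main effect or an 'a:b' interaction term."""
    parts = term.split(":")
    levels = [
        "|".join(vals)
        for vals in zip(*[factors[p] for p in parts])
    ]
    return _dummy_matrix(levels)


def permanova(
    distance: DistanceMatrix,
    factors: dict[str, list[str]],
    terms: list[str] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[PermutationTestResult]:
    """Sequential (type-I) PERMANOVA on a distance matrix.

    factors maps factor name to a per-sample level list aligned with the
    distance matrix; terms default to all factors in insertion order and may
    include 'a:b' interactions. Variance is partitioned via the
    Gower-centered inner-product matrix G = -1/2 J D^2 J and nested
    projection matrices; p-values come from free permutation of sample
    labels with the add-one rule. With exhaustive=True all n! permutations
    are enumerated instead (identity included; no add-one correction, since
    the identity permutation already keeps p strictly positive).
    """
    if terms is None:
        terms = list(factors)
    d = distance.to_numpy()
    n = d.shape[0]
    for name in {p for t in terms for p in t.split(":")}:
        if len(factors[name]) != n:
            raise ValueError(f"factor {name}: length mismatch with distance matrix")
        if len(set(factors[name])) < 2:
            raise ValueError(f"factor {name} has a single level")

    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    ss_total = float(np.trace(g))

    # nested projectors: intercept, then adding one term at a time
    design_cols = [np.ones((n, 1))]
    projectors, ranks = [], []
    h_prev, rank_prev = _column_space_projector(np.ones((n, 1)))
    for term in terms:
        design_cols.append(_term_columns(term, factors))
        h, rank = _column_space_projector(np.hstack(design_cols))
        projectors.append((h_prev, h))
        ranks.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    resid_proj = np.eye(n) - h_prev

    def _stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_resid = float(np.sum(resid_proj * gmat))
        ss_terms = np.array(
            [float(np.sum(h * gmat) - np.sum(h0 * gmat)) for h0, h in projectors]
        )
        ms_resid = ss_resid / df_resid
        with np.errstate(invalid="ignore", divide="ignore"):
            f_vals = (ss_terms / np.array(ranks)) / ms_resid if ms_resid > 0 else (
                np.zeros(len(ss_terms))
            )
        return f_vals, ss_resid

    f_obs, _ = _stats(g)
    ss_terms_obs = np.array(
        [float(np.sum(h * g) - np.sum(h0 * g)) for h0, h in projectors]
    )

    exceed = np.zeros(len(terms))
    if exhaustive:
        n_done = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            f_perm, _ = _stats(gp)
            exceed += f_perm >= f_obs - 1e-12
            n_done += 1
        n_permutations = n_done
        p_values = exceed / n_done
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            f_perm, _ = _stats(gp)
            exceed += f_perm >= f_obs
        p_values = (1.0 + exceed) / (1.0 + n_permutations)

    return [
        PermutationTestResult(
            term=term,
            statistic=float(f_obs[i]),
            effect_size=float(ss_terms_obs[i] / ss_total) if ss_total > 0 else 0.0,
            p_value=float(p_values[i]),
            n_permutations=n_permutations,
            seed=seed,
            df=ranks[i],
            extra={"ss": float(ss_terms_obs[i]), "ss_total": ss_total,
                   "df_resid": df_resid},
        )
        for i, term in enumerate(terms)
    ]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of distance matrices, permutation p.

    One matrix's rows/columns are permuted simultaneously; the add-one rule
    keeps p strictly positive. A constant upper triangle makes r undefined
    (NaN statistic, flagged in extra). With exhaustive=True all n!
    permutations are enumerated (identity included, no add-one).
    """
    a = d1.to_numpy()
    b = d2.to_numpy()
    if a.shape != b.shape:
        raise ValueError("distance matrices differ in size")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    if np.ptp(x) == 0 or np.ptp(b[iu]) == 0:
        logger.warning("constant upper triangle: Mantel r undefined")
        return PermutationTestResult(
            term="mantel", statistic=float("nan"), effect_size=None,
            p_value=float("nan"), n_permutations=n_permutations, seed=seed,
            extra={"undefined": True},
        )

    def _r(mat_b: np.ndarray) -> float:
        y = mat_b[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = _r(b)
    exceed = 0
    if exhaustive:
        n_done = 0
        for perm in itertools.permutations(range(n)):
            if _r(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
                exceed += 1
            n_done += 1
        n_permutations = n_done
        p = exceed / n_done
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            if _r(b[np.ix_(perm, perm)]) >= r_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermutationTestResult(
        term="mantel", statistic=r_obs, effect_size=None, p_value=p,
        n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    terms: pd.DataFrame  # term, ss, df, f, p
    tukey: dict[str, pd.DataFrame]  # per-factor pairwise comparisons


def two_way_anova(
    response: np.ndarray | pd.Series,
    factor_a: list[str],
    factor_b: list[str],
    interaction: bool = False,
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Sequential two-way ANOVA with Tukey HSD pairwise tables per factor.

    Crossed cells must all be populated when the interaction is requested.
    A constant response yields F = 0, p = 1 for every term.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if len(factor_a) != n or len(factor_b) != n:
        raise ValueError("factor lengths must match the response")
    if interaction:
        cells = set(zip(factor_a, factor_b))
        missing = [
            (a, b)
            for a in sorted(set(factor_a))
            for b in sorted(set(factor_b))
            if (a, b) not in cells
        ]
        if missing:
            raise ValueError(f"empty cell(s) in crossed design: {missing}")

    factors = {factor_names[0]: list(factor_a), factor_names[1]: list(factor_b)}
    terms = list(factor_names)
    if interaction:
        terms.append(f"{factor_names[0]}:{factor_names[1]}")

    design_cols = [np.ones((n, 1))]
    rows = []
    h_prev, rank_prev = _column_space_projector(np.ones((n, 1)))
    ss_prev = float(y @ h_prev @ y)
    for term in terms:
        design_cols.append(_term_columns(term, factors))
        h, rank = _column_space_projector(np.hstack(design_cols))
        ss_fit = float(y @ h @ y)
        rows.append({"term": term, "ss": ss_fit - ss_prev, "df": rank - rank_prev})
        h_prev, rank_prev, ss_prev = h, rank, ss_fit
    ss_resid = float(y @ y) - ss_prev
    df_resid = n - rank_prev
    ss_total = float(((y - y.mean()) ** 2).sum())

    for row in rows:
        if row["df"] == 0:  # factor collapsed to a single level
            row["f"], row["p"] = float("nan"), float("nan")
        elif ss_total <= 1e-300:
            row["f"], row["p"] = 0.0, 1.0
        elif df_resid <= 0 or ss_resid / max(df_resid, 1) <= 0:
            row["f"], row["p"] = float("inf"), 0.0
        else:
            mse = ss_resid / df_resid
            f_val = (row["ss"] / row["df"]) / mse
            row["f"] = f_val
            row["p"] = float(stats.f.sf(f_val, row["df"], df_resid))
    table = pd.DataFrame(rows)

    mse = ss_resid / df_resid if df_resid > 0 else float("nan")
    tukey = {
        factor_names[0]: _tukey_hsd(y, factor_a, mse, df_resid),
        factor_names[1]: _tukey_hsd(y, factor_b, mse, df_resid),
    }
    return AnovaTable(terms=table, tukey=tukey)


def _tukey_hsd(
    y: np.ndarray, factor: list[str], mse: float, df_resid: int
) -> pd.DataFrame:
    levels = sorted(set(factor))
    k = len(levels)
    groups = {lv: y[np.asarray(factor) == lv] for lv in levels}
    rows = []
    for lv1, lv2 in itertools.combinations(levels, 2):
        g1, g2 = groups[lv1], groups[lv2]
        diff = float(g1.mean() - g2.mean())
        if df_resid <= 0 or not np.isfinite(mse) or mse <= 0:
            q = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(mse / 2.0 * (1.0 / len(g1) + 1.0 / len(g2)))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append(
            {"level_1": lv1, "level_2": lv2, "mean_diff": diff, "q": q, "p_adj": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (REML)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    intercept: float
    slope: float | None
    slope_se: float | None
    slope_df: float | None
    slope_p: float | None
    group_variance: float
    residual_variance: float
    grouping_factor: str = "group"
    converged: bool = True


def fit_random_intercept_lmm(
    y: np.ndarray | pd.Series,
    x: np.ndarray | pd.Series | None,
    group: list | np.ndarray | pd.Series,
    grouping_factor: str = "group",
) -> MixedModelResult:
    """REML fit of y = b0 + b1*x + u_group + e with a random intercept.

    The variance ratio lambda = var(u)/var(e) is profiled out and optimized
    by 1-D bounded search. The slope test uses a Satterthwaite-approximate
    t distribution; when the group variance collapses to zero the fit
    reduces to ordinary least squares with residual degrees of freedom.
    Pass x=None for an intercept-only (variance components) model.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    group = np.asarray(group)
    levels, group_idx = np.unique(group, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x is None:
        xmat = np.ones((n, 1))
    else:
        x = np.asarray(x, dtype=float)
        xmat = np.column_stack([np.ones(n), x])
    p = xmat.shape[1]
    if np.linalg.matrix_rank(xmat) < p:
        raise ValueError("singular fixed-effects design")
    z = np.zeros((n, len(levels)))
    z[np.arange(n), group_idx] = 1.0
    zzt = z @ z.T

    def _gls(lam: float):
        v = np.eye(n) + lam * zzt
        vinv = np.linalg.inv(v)
        xtvx = xmat.T @ vinv @ xmat
        beta = np.linalg.solve(xtvx, xmat.T @ vinv @ y)
        r = y - xmat @ beta
        quad = float(r @ vinv @ r)
        sigma2 = quad / (n - p)
        sign_v, logdet_v = np.linalg.slogdet(v)
        sign_x, logdet_x = np.linalg.slogdet(xtvx)
        return beta, sigma2, vinv, xtvx, logdet_v, logdet_x

    def _reml_criterion(lam: float) -> float:
        _, sigma2, _, _, logdet_v, logdet_x = _gls(lam)
        if sigma2 <= 0:
            return np.inf
        return (n - p) * math.log(sigma2) + logdet_v + logdet_x

    # optimize on log-scale plus explicit boundary check at lambda = 0
    res = optimize.minimize_scalar(
        lambda t: _reml_criterion(math.exp(t)), bounds=(-12.0, 12.0), method="bounded"
    )
    lam_hat = math.exp(res.x)
    if _reml_criterion(0.0) <= _reml_criterion(lam_hat) + 1e-10:
        lam_hat = 0.0

    beta, sigma2_e, vinv, xtvx, _, _ = _gls(lam_hat)
    sigma2_u = lam_hat * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(xtvx)

    intercept = float(beta[0])
    if x is None:
        return MixedModelResult(
            intercept=intercept, slope=None, slope_se=None, slope_df=None,
            slope_p=None, group_variance=sigma2_u, residual_variance=sigma2_e,
            grouping_factor=grouping_factor, converged=bool(res.success),
        )

    slope = float(beta[1])
    slope_var = float(cov_beta[1, 1])
    slope_se = math.sqrt(slope_var)

    if lam_hat == 0.0:
        df = float(n - p)
    else:
        df = _satterthwaite_df(
            np.array([sigma2_u, sigma2_e]), xmat, zzt, y, n, p
        )
        df = float(np.clip(df, 1.0, n - p))
    t_stat = slope / slope_se if slope_se > 0 else float("inf")
    slope_p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return MixedModelResult(
        intercept=intercept, slope=slope, slope_se=slope_se, slope_df=df,
        slope_p=slope_p, group_variance=sigma2_u, residual_variance=sigma2_e,
        grouping_factor=grouping_factor, converged=bool(res.success),
    )


def _satterthwaite_df(
    theta: np.ndarray, xmat: np.ndarray, zzt: np.ndarray, y: np.ndarray,
    n: int, p: int,
) -> float:
    """Satterthwaite df for the slope: 2*C^2 / (g' A g) with g the gradient
    of C(theta) = Var(slope) and A the inverse REML information."""

    def _slope_var(th: np.ndarray) -> float:
        s2u, s2e = th
        v = s2e * np.eye(n) + s2u * zzt
        vinv = np.linalg.inv(v)
        return float(np.linalg.inv(xmat.T @ vinv @ xmat)[1, 1])

    def _neg_reml_ll(th: np.ndarray) -> float:
        s2u, s2e = th
        if s2e <= 0 or s2u < 0:
            return np.inf
        v = s2e * np.eye(n) + s2u * zzt
        vinv = np.linalg.inv(v)
        xtvx = xmat.T @ vinv @ xmat
        beta = np.linalg.solve(xtvx, xmat.T @ vinv @ y)
        r = y - xmat @ beta
        _, logdet_v = np.linalg.slogdet(v)
        _, logdet_x = np.linalg.slogdet(xtvx)
        return 0.5 * (logdet_v + logdet_x + float(r @ vinv @ r))

    c_hat = _slope_var(theta)
    h = np.maximum(np.abs(theta), 1e-8) * 1e-4
    grad = np.zeros(2)
    hess = np.zeros((2, 2))
    for i in range(2):
        e_i = np.zeros(2)
        e_i[i] = h[i]
        grad[i] = (_slope_var(theta + e_i) - _slope_var(theta - e_i)) / (2 * h[i])
    for i in range(2):
        for j in range(2):
            e_i = np.zeros(2)
            e_j = np.zeros(2)
            e_i[i] = h[i]
            e_j[j] = h[j]
            hess[i, j] = (
                _neg_reml_ll(theta + e_i + e_j)
                - _neg_reml_ll(theta + e_i - e_j)
                - _neg_reml_ll(theta - e_i + e_j)
                + _neg_reml_ll(theta - e_i - e_j)
            ) / (4 * h[i] * h[j])
    try:
        a = np.linalg.inv(hess)
        denom = float(grad @ a @ grad)
    except np.linalg.LinAlgError:
        denom = 0.0
    if denom <= 0:
        return float(len(y) - p)
    return 2.0 * c_hat**2 / denom
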