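"""Community-composition analysis: dissimilarities, NMDS, vector fitting,
indicator genera, and SD-ellipse areas.

NMDS minimizes Kruskal's stress-1,

    stress = sqrt( Σ (d_hat_ij − f(d_ij))² / Σ d_hat_ij² ),

over k-dimensional configurations, where f is fit by monotone (isotonic)
regression of configuration distances on observed dissimilarity ranks
(primary/weak tie treatment). The optimizer alternates the Guttman
majorizing transform with pooled-adjacent-violators isotonic regression;
the best of a classical-scaling start plus seeded random starts is kept,
and the final configuration is centred and rotated to its principal axes
with a deterministic sign convention, so identical seeds reproduce the
scores bit for bit.

Vector fitting regresses each genus' abundance on the score axes
(envfit-style), and indicator analysis computes IndVal = sqrt(A·B) over
groups and group combinations; both use add-one permutation p-values,
which are therefore never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .metrics import CommunityProfile


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class DissimilarityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # square symmetric, zero diagonal, entries in [0, 1]
    method: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise OrdinationError("matrix shape does not match ids")
        if not np.allclose(np.diag(v), 0.0):
            raise OrdinationError("nonzero diagonal")
        if not np.allclose(v, v.T, equal_nan=True):
            raise OrdinationError("matrix not symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise OrdinationError("entries outside [0, 1]")


def profiles_to_matrix(profiles: Sequence[CommunityProfile]) -> pd.DataFrame:
    """Plot × genus abundance matrix over the common genus universe."""
    genera = sorted({g for p in profiles for g in p.abundance})
    data = np.zeros((len(profiles), len(genera)))
    for i, p in enumerate(profiles):
        for j, g in enumerate(genera):
            data[i, j] = p.abundance.get(g, 0.0)
    return pd.DataFrame(data, index=[p.plot_id for p in profiles], columns=genera)


def dissimilarity_matrix(
    community: pd.DataFrame | Sequence[CommunityProfile], method: str = "bray-curtis"
) -> DissimilarityMatrix:
    """Bray–Curtis (abundance) or Jaccard (presence–absence) dissimilarities.

    Pairs of all-zero profiles have no defined dissimilarity and are
    flagged NaN.
    """
    if not isinstance(community, pd.DataFrame):
        community = profiles_to_matrix(list(community))
    if community.shape[0] < 2:
        raise OrdinationError("need at least two profiles")
    x = community.to_numpy(dtype=float)
    if method in ("bray-curtis", "bray"):
        d = squareform(pdist(x, metric="braycurtis"))
    elif method == "jaccard":
        d = squareform(pdist(x > 0, metric="jaccard"))
    else:
        raise OrdinationError(f"unknown method {method!r}")
    empty = ~(x > 0).any(axis=1)
    if empty.any():
        d[np.ix_(empty, empty)] = np.nan
        np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(community.index), d, method)


@dataclass(frozen=True)
class OrdinationResult:
    ids: tuple[str, ...]
    scores: np.ndarray  # plots × k, centred, principal-axis rotated
    stress: float
    converged: bool
    n_starts: int

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.ids, columns=cols)


def _stress1(config_d: np.ndarray, dhat: np.ndarray) -> float:
    # Kruskal stress-1: residual sum of squares of configuration distances
    # about the monotone disparities, normalized by the configuration SS
    denom = float((config_d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((config_d - dhat) ** 2).sum() / denom))


def _classical_start(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling start: eigendecomposition of −½ J D² J."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def _principal_rotate(x: np.ndarray) -> np.ndarray:
    """Centre, rotate to principal axes, fix signs deterministically."""
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    rot = x @ vt.T
    for j in range(rot.shape[1]):
        i = int(np.argmax(np.abs(rot[:, j])))
        if rot[i, j] < 0:
            rot[:, j] = -rot[:, j]
    return rot


def nmds(
    dissim: DissimilarityMatrix,
    k: int = 3,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling by majorization + isotonic regression."""
    if k < 1:
        raise OrdinationError("k must be at least 1")
    d = dissim.values
    if np.isnan(d).any():
        raise OrdinationError("dissimilarity matrix contains undefined entries")
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    order = np.argsort(dv, kind="stable")
    iso = IsotonicRegression(increasing=True)

    rng = np.random.default_rng(seed)
    best_x: np.ndarray | None = None
    best_stress = np.inf
    best_converged = False

    starts: list[np.ndarray] = [_classical_start(d, k)]
    scale = np.nanmax(dv) if dv.size else 1.0
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.normal(0.0, scale, size=(n, k)))

    for x in starts:
        x = x - x.mean(axis=0)
        prev_stress = np.inf
        converged = False
        stress = np.inf
        for _ in range(max_iter):
            delta = squareform(pdist(x))
            dconf = delta[iu]
            if (dconf**2).sum() <= 1e-300:  # fully collapsed configuration
                stress = 1.0
                break
            # monotone fit of configuration distances on dissimilarity ranks
            fitted = np.empty_like(dconf)
            fitted[order] = iso.fit_transform(dv[order], dconf[order])
            stress = _stress1(dconf, fitted)
            if prev_stress - stress < tol:
                converged = True
                break
            prev_stress = stress
            # Guttman transform; disparities renormalized to the configuration
            # scale so the update cannot shrink the solution towards collapse
            ss = (fitted**2).sum()
            if ss > 0:
                fitted = fitted * np.sqrt((dconf**2).sum() / ss)
            dhat = np.zeros_like(delta)
            dhat[iu] = fitted
            dhat += dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(delta > 0, dhat / np.where(delta > 0, delta, 1.0), 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
            x = x - x.mean(axis=0)
        # pin the (stress-invariant) configuration scale to the data scale:
        # rms configuration distance = rms observed dissimilarity
        dconf = pdist(x)
        rms = np.sqrt((dconf**2).mean())
        if rms > 0 and dv.size:
            x = x * (np.sqrt((dv**2).mean()) / rms)
        if stress < best_stress:
            best_stress = stress
            best_x = x
            best_converged = converged

    assert best_x is not None
    return OrdinationResult(
        ids=dissim.ids,
        scores=_principal_rotate(best_x),
        stress=best_stress,
        converged=best_converged,
        n_starts=len(starts),
    )


@dataclass(frozen=True)
class VectorFit:
    """Per-genus least-squares fit of abundance on the ordination axes."""

    table: pd.DataFrame  # index genus; direction cosines per axis, r2, p


def fit_genus_vectors(
    result: OrdinationResult,
    community: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> VectorFit:
    """envfit-style vector fitting with add-one permutation p-values.

    For each genus the abundance vector is regressed on all score axes;
    r² is the fraction of (centred) variance explained, the direction is
    the unit coefficient vector, and p = (1 + #{perm r² ≥ observed}) /
    (1 + n_perm) from random row permutations.
    """
    ids = list(result.ids)
    y_all = community.loc[ids].to_numpy(dtype=float)
    x = result.scores
    n, k = x.shape
    xc = x - x.mean(axis=0)
    # hat matrix of the centred axes (orthogonal after principal rotation,
    # but solve generally)
    h = xc @ np.linalg.solve(xc.T @ xc, xc.T)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for j, genus in enumerate(community.columns):
        y = y_all[:, j]
        yc = y - y.mean()
        ss = float(yc @ yc)
        if ss == 0:
            coef = np.zeros(k)
            r2 = 0.0
            p = 1.0
        else:
            coef = np.linalg.solve(xc.T @ xc, xc.T @ yc)
            r2 = float(yc @ h @ yc / ss)
            yp = yc[perms]  # n_perm × n
            fit_ss = np.einsum("ij,ij->i", yp @ h, yp)
            r2_perm = fit_ss / ss
            p = (1 + int((r2_perm >= r2 - 1e-12).sum())) / (1 + n_perm)
        norm = np.linalg.norm(coef)
        cosines = coef / norm if norm > 0 else coef
        row = {"genus": genus, "r2": r2, "p": p}
        for a in range(k):
            row[f"NMDS{a + 1}"] = cosines[a]
        rows.append(row)
    return VectorFit(pd.DataFrame(rows).set_index("genus"))


@dataclass(frozen=True)
class IndicatorResult:
    """Best group (or combination) per genus with IndVal components."""

    table: pd.DataFrame  # index genus; columns group, A, B, stat, p


def _group_combinations(levels: Sequence, max_order: int | None = None):
    from itertools import combinations

    levels = list(levels)
    if max_order is None:
        max_order = len(levels) - 1  # all proper, non-empty combinations
    for r in range(1, max_order + 1):
        yield from combinations(levels, r)


def _indval_best(
    y: np.ndarray, groups: np.ndarray, levels: list, combos: list[tuple]
) -> tuple[tuple, float, float, float]:
    """Best (combo, A, B, stat) for one genus abundance vector."""
    means = {g: y[groups == g].mean() for g in levels}
    total_mean = sum(means.values())
    best = (combos[0], 0.0, 0.0, -1.0)
    for combo in combos:
        mask = np.isin(groups, combo)
        in_mean = y[mask].mean()
        out_sum = sum(means[g] for g in levels if g not in combo)
        denom = in_mean + out_sum
        a = in_mean / denom if denom > 0 else 0.0
        b = float((y[mask] > 0).mean())
        stat = float(np.sqrt(a * b))
        if stat > best[3]:
            best = (combo, a, b, stat)
    return best


def indicator_analysis(
    community: pd.DataFrame,
    groups: Mapping[str, object] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    max_order: int | None = None,
) -> IndicatorResult:
    """IndVal over groups and group combinations (multipatt-style).

    A (specificity) = mean abundance within the group set over the sum of
    per-group means; B (fidelity) = occurrence frequency within the group
    set; statistic = sqrt(A·B). The best group set per genus is reported
    with an add-one permutation p-value (group labels permuted, the
    best-combination statistic recomputed each time). Genera absent
    everywhere are excluded.
    """
    g = pd.Series(groups).loc[community.index].to_numpy()
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise OrdinationError("need at least two groups")
    combos = list(_group_combinations(levels, max_order))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(g)) for _ in range(n_perm)]

    rows = []
    for genus in community.columns:
        y = community[genus].to_numpy(dtype=float)
        if not (y > 0).any():
            continue
        combo, a, b, stat = _indval_best(y, g, levels, combos)
        exceed = 0
        for p_idx in perms:
            _, _, _, stat_p = _indval_best(y, g[p_idx], levels, combos)
            if stat_p >= stat - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {
                "genus": genus,
                "group": "+".join(str(c) for c in combo),
                "A": a,
                "B": b,
                "stat": stat,
                "p": p,
            }
        )
    return IndicatorResult(pd.DataFrame(rows).set_index("genus"))


def sd_ellipse_area(
    result: OrdinationResult, groups: Mapping[str, object] | pd.Series
) -> pd.Series:
    """SD-ellipse area per group on ordination axes 1–2.

    area = π·s₁·s₂ with s₁, s₂ the standard deviations along the
    principal axes of the group's 2-D score covariance (square roots of
    its eigenvalues). Degenerate (collinear) groups get area 0.
    """
    g = pd.Series(groups).loc[list(result.ids)]
    xy = result.scores[:, :2]
    out = {}
    for level in sorted(pd.unique(g).tolist()):
        pts = xy[(g == level).to_numpy()]
        if pts.shape[0] < 3:
            raise OrdinationError(f"group {level!r} has fewer than 3 plots")
        cov = np.cov(pts.T)
        eigvals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        out[level] = float(np.pi * np.sqrt(eigvals[0] * eigvals[1]))
    return pd.Series(out, name="ellipse_area")
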