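"""Mixed-model richness tests, Tukey comparisons, the D_max deviation test,
and piecewise structural equation modelling with d-separation and Fisher's C.

All mixed models carry crossed random intercepts for block and mixture
identity (the specific plant species combination; a monoculture's mixture
identity is its species name) and are fit by maximum likelihood, so that
likelihood-ratio tests across fixed-effect structures are valid. The
likelihood is maximized by Powell search followed by L-BFGS refinement,
which reproduces lme4 ML log-likelihoods to ~1e-6 on this design.

Piecewise SEM: each endogenous variable gets a mixed-effects component
model on its parents; overall fit is judged by Fisher's C over the DAG's
d-separation basis set — the non-adjacent variable pairs, conditioned on
the union of both members' parents — with C = −2 Σ ln p ~ χ²(2k) when
every independence claim holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dfield
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transformation ledger

#: Response-name → variance-stabilizing transformation used throughout the
#: richness-model battery. Abundances of bacterial feeders, fungal feeders
#: and omnivores+predators, the predator–prey ratio and the c–p 1+2 and
#: c–p 4 abundances are log-transformed; fungal-feeder genus richness and
#: the c–p 3 and c–p 5 abundances are square-root-transformed; everything
#: else (including plant-feeder abundance) is analysed untransformed.
TRANSFORM_LEDGER: Mapping[str, str] = {
    "bf_abund": "log",
    "ff_abund": "log",
    "ompr_abund": "log",
    "predator_prey": "log",
    "cp12": "log",
    "cp4": "log",
    "ff_richness": "sqrt",
    "cp3": "sqrt",
    "cp5": "sqrt",
}


def transform_response(
    name: str, values: pd.Series | np.ndarray, tag: str | None = None
) -> np.ndarray:
    """Apply the ledger transformation (or an explicit *tag*) to a response.

    Raises a descriptive error naming the offending plots when a log is
    requested for non-positive values.
    """
    if tag is None:
        tag = TRANSFORM_LEDGER.get(name, "identity")
    v = np.asarray(values, dtype=float)
    if tag == "identity":
        return v
    if tag == "sqrt":
        if (v < 0).any():
            raise InferenceError(f"{name}: negative values under sqrt transform")
        return np.sqrt(v)
    if tag == "log1p":
        if (v < 0).any():
            raise InferenceError(f"{name}: negative values under log1p transform")
        return np.log1p(v)
    if tag == "log":
        bad = ~(v > 0)
        if bad.any():
            idx = (
                list(values.index[bad])
                if isinstance(values, pd.Series)
                else list(np.nonzero(bad)[0])
            )
            raise InferenceError(
                f"{name}: non-positive values under log transform at {idx[:5]}"
            )
        return np.log(v)
    raise InferenceError(f"unknown transformation {tag!r}")


# ---------------------------------------------------------------------------
# mixed-model machinery


def _dummy(codes: pd.Series | np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    u, inv = np.unique(codes, return_inverse=True)
    m = np.zeros((codes.size, u.size))
    m[np.arange(codes.size), inv] = 1.0
    return m


@dataclass
class LmmResult:
    """A fitted mixed model: fixed effects, variance components, likelihood."""

    params: pd.Series
    pvalues: pd.Series  # Wald z reference
    bse: pd.Series
    llf: float
    scale: float  # residual variance
    vcomp: pd.Series  # block / mixture variances
    fitted_fixed: np.ndarray
    singular: bool
    df_resid: int  # conservative inner-stratum residual df

    def pvalues_t(self) -> pd.Series:
        """Wald p-values against a t reference with inner-stratum df.

        The denominator df counts every random-intercept level against
        the residual stratum (nlme-style), which is conservative for
        plot-level predictors and avoids the anti-conservatism of the
        normal reference in moderate samples.
        """
        t = self.params / self.bse
        return pd.Series(
            2.0 * stats.t.sf(np.abs(t.to_numpy()), self.df_resid), index=t.index
        )


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str] = (),
    block: str = "block",
    mixture: str = "mixture",
    reml: bool = False,
) -> LmmResult:
    """Linear mixed model with crossed block and mixture random intercepts.

    *fixed* lists data columns entering as fixed effects (an intercept is
    always included). ML by default so model pairs differing in fixed
    effects have comparable likelihoods.
    """
    y = data[response].to_numpy(dtype=float)
    n = y.size
    cols = ["Intercept", *fixed]
    x = np.column_stack([np.ones(n)] + [data[c].to_numpy(dtype=float) for c in fixed])
    vcs = VCSpec(
        names=["block", "mixture"],
        colnames=[[["b"]], [["m"]]],
        mats=[[_dummy(data[block])], [_dummy(data[mixture])]],
    )
    groups = np.zeros(n, dtype=int)
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, x, groups=groups, exog_re=np.zeros((n, 0)), exog_vc=vcs)
        res = model.fit(reml=reml, method="powell", maxiter=1000)
        try:
            res2 = model.fit(
                reml=reml, method="lbfgs", start_params=res.params_object, maxiter=200
            )
            if res2.llf > res.llf:
                res = res2
        except (np.linalg.LinAlgError, ValueError):  # refinement is best-effort
            pass
        singular = any("singular" in str(w.message).lower() for w in caught)
    params = pd.Series(res.fe_params, index=cols)
    n_levels = sum(m[0].shape[1] for m in vcs.mats)
    df_resid = max(n - len(cols) - n_levels + 2, 4)
    return LmmResult(
        params=params,
        pvalues=pd.Series(np.asarray(res.pvalues)[: len(cols)], index=cols),
        bse=pd.Series(np.asarray(res.bse)[: len(cols)], index=cols),
        llf=float(res.llf),
        scale=float(res.scale),
        vcomp=pd.Series(res.vcomp, index=["block", "mixture"]),
        fitted_fixed=x @ params.to_numpy(),
        singular=singular,
        df_resid=df_resid,
    )


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    singular: bool = False


def lrt_richness(
    data: pd.DataFrame,
    response: str,
    predictor: str = "sown",
    transform: str | None = None,
    log_realized: bool = False,
) -> LRTResult:
    """Likelihood-ratio test of a richness effect on one response.

    The null model carries the crossed random intercepts only; the full
    model adds sown richness as a log-linear term (``predictor="sown"``)
    or realized richness (untransformed by default; ``log_realized``
    switches to its log). The response transformation follows the ledger
    unless *transform* overrides it. df = 1 (one added fixed effect).
    """
    df = data.copy()
    df["_y"] = transform_response(response, data[response], transform)
    if predictor == "sown":
        df["_x"] = np.log(df["sown_richness"].to_numpy(dtype=float))
    elif predictor == "realized":
        x = df["realized_richness"].to_numpy(dtype=float)
        df["_x"] = np.log(x) if log_realized else x
    else:
        raise InferenceError(f"predictor must be 'sown' or 'realized', got {predictor!r}")
    df = df.dropna(subset=["_y", "_x"])
    null = fit_lmm(df, "_y", fixed=())
    full = fit_lmm(df, "_y", fixed=("_x",))
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    return LRTResult(
        chi2=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        singular=null.singular or full.singular,
    )


def tukey_groups(
    values: Sequence[float] | pd.Series,
    groups: Sequence | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of group means (studentized range).

    Groups with fewer than two observations are excluded with a warning.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups), index=v.index)
    sizes = g.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 observations: {small}")
        keep = ~g.isin(small)
        v, g = v[keep], g[keep]
    if g.nunique() < 2:
        raise InferenceError("need at least two groups with >= 2 observations")
    res = pairwise_tukeyhsd(v.to_numpy(), g.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return frame.astype(
        {"meandiff": float, "p-adj": float, "lower": float, "upper": float}
    )


@dataclass(frozen=True)
class DmaxTest:
    grand_mean: float
    F: float
    df_num: int
    df_den: int
    p: float
    n_mixtures: int


def dmax_deviation_test(records: pd.DataFrame) -> DmaxTest:
    """Test whether mixtures' D_max deviates from zero on average.

    Replicate plots of a mixture (which sit in different blocks) are
    averaged, and the mixture means are regressed on centred ln(sown
    richness); the intercept of this parameterization is the grand mean,
    and its squared t statistic is the reported F with 1 and
    (n_mixtures − 2) degrees of freedom.
    """
    if not {"dmax", "mixture", "sown_richness"} <= set(records.columns):
        raise InferenceError("records need columns dmax, mixture, sown_richness")
    agg = records.groupby("mixture").agg(
        dmax=("dmax", "mean"), sown_richness=("sown_richness", "first")
    )
    n = len(agg)
    if n < 3:
        raise InferenceError("need at least 3 mixtures")
    y = agg["dmax"].to_numpy()
    x = np.log(agg["sown_richness"].to_numpy(dtype=float))
    xc = x - x.mean()
    df_den = n - 2
    sxx = float(xc @ xc)
    slope = float(xc @ y / sxx) if sxx > 0 else 0.0
    intercept = float(y.mean())
    resid = y - intercept - slope * xc
    s2 = float(resid @ resid) / df_den
    if s2 == 0.0:
        if intercept == 0.0:
            return DmaxTest(0.0, 0.0, 1, df_den, 1.0, n)
        return DmaxTest(intercept, math.inf, 1, df_den, 0.0, n)
    se = math.sqrt(s2 / n)
    F = (intercept / se) ** 2
    return DmaxTest(
        grand_mean=intercept,
        F=F,
        df_num=1,
        df_den=df_den,
        p=float(stats.f.sf(F, 1, df_den)),
        n_mixtures=n,
    )


# ---------------------------------------------------------------------------
# piecewise SEM


@dataclass(frozen=True)
class Claim:
    """One d-separation independence claim: x ⟂ response | conditioning."""

    response: str
    x: str
    conditioning: tuple[str, ...]


@dataclass
class SemModel:
    """DAG over named variables with per-variable transformation tags.

    ``transforms`` maps variable → {identity, log, sqrt}; variables enter
    every component model (as response or predictor) on that scale.
    ``design_vars`` are experimental design variables (e.g. the richness
    gradient) that never serve as the response of a d-separation claim.
    ``correlated_errors`` pairs are exempt from the basis set.
    """

    edges: list[tuple[str, str]]
    transforms: Mapping[str, str] = dfield(default_factory=dict)
    correlated_errors: list[tuple[str, str]] = dfield(default_factory=list)
    design_vars: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise InferenceError("SEM graph is cyclic")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._graph))

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.nodes if self._graph.in_degree(v) > 0]

    def parents(self, v: str) -> list[str]:
        return sorted(self._graph.predecessors(v))


def basis_set(model: SemModel) -> list[Claim]:
    """Union basis set of d-separation claims for the model's DAG.

    One claim per non-adjacent pair, conditioned on the parents of both
    members; pairs declared as correlated errors are exempt. The claim
    is directed at the member later in (lexicographical) topological
    order, never at a design variable.
    """
    g = model.graph
    order = {v: i for i, v in enumerate(model.nodes)}
    exempt = {frozenset(p) for p in model.correlated_errors}
    claims: list[Claim] = []
    nodes = model.nodes
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            if frozenset((u, v)) in exempt:
                continue
            pair = sorted((u, v), key=lambda w: order[w])
            candidates = [w for w in pair if w not in model.design_vars]
            if not candidates:
                continue  # independence of two design variables is fixed by design
            response = candidates[-1]
            x = pair[0] if response == pair[1] else pair[1]
            cond = (set(g.predecessors(u)) | set(g.predecessors(v))) - {u, v}
            claims.append(Claim(response=response, x=x, conditioning=tuple(sorted(cond))))
    return claims


def fisher_c(pvalues: Iterable[float]) -> tuple[float, int, float]:
    """Fisher's C = −2 Σ ln p over k independence claims; C ~ χ²(2k) under fit.

    An empty claim set (saturated model) gives C = 0 with fit p = 1.
    """
    ps = list(pvalues)
    for p in ps:
        if not 0 < p <= 1:
            raise InferenceError(f"claim p-value {p} outside (0, 1]")
    c = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    p_fit = float(stats.chi2.sf(c, df)) if ps else 1.0
    return c, df, p_fit


@dataclass
class SemFit:
    """A fitted piecewise SEM."""

    paths: pd.DataFrame  # response, predictor, coef, std_coef, p
    r2: pd.DataFrame  # response, marginal, conditional
    claims: pd.DataFrame  # response, x, conditioning, p
    fisher_c: float
    c_df: int
    c_p: float
    n_obs: int
    n_dropped: int


def _apply_transforms(data: pd.DataFrame, model: SemModel) -> pd.DataFrame:
    out = pd.DataFrame(index=data.index)
    for v in model.nodes:
        if v not in data.columns:
            raise InferenceError(f"SEM variable {v!r} missing from data")
        out[v] = transform_response(v, data[v], model.transforms.get(v, "identity"))
    for aux in ("block", "mixture"):
        if aux not in data.columns:
            raise InferenceError(f"data lacks grouping column {aux!r}")
        out[aux] = data[aux].to_numpy()
    return out


_P_FLOOR = 1e-300  # claims cannot contribute p = 0 to Fisher's C


def fit_piecewise_sem(model: SemModel, data: pd.DataFrame) -> SemFit:
    """Fit every component model and score the d-separation basis set.

    Rows with missing values in any model variable are dropped (their
    count is reported, mirroring designs where some plots lack root
    measurements). Path coefficients are standardized as b·SD(x)/SD(y)
    on the transformed scales; marginal R² is the fixed-effects variance
    share, conditional R² adds the random-intercept variances.
    """
    n_before = len(data)
    needed = [v for v in model.nodes]
    frame = data.dropna(subset=[c for c in needed if c in data.columns])
    n_obs = len(frame)
    tf = _apply_transforms(frame, model)
    sds = tf[model.nodes].std(ddof=1)

    path_rows = []
    r2_rows = []
    for resp in model.endogenous:
        parents = model.parents(resp)
        fit = fit_lmm(tf, resp, fixed=tuple(parents), reml=True)
        pvals_t = fit.pvalues_t()
        for p_name in parents:
            b = fit.params[p_name]
            path_rows.append(
                {
                    "response": resp,
                    "predictor": p_name,
                    "coef": b,
                    "std_coef": b * sds[p_name] / sds[resp] if sds[resp] > 0 else np.nan,
                    "p": pvals_t[p_name],
                }
            )
        var_f = float(np.var(fit.fitted_fixed, ddof=0))
        var_re = float(fit.vcomp.sum())
        denom = var_f + var_re + fit.scale
        r2_rows.append(
            {
                "response": resp,
                "marginal": var_f / denom,
                "conditional": (var_f + var_re) / denom,
            }
        )

    claim_rows = []
    for claim in basis_set(model):
        fit = fit_lmm(
            tf, claim.response, fixed=tuple(claim.conditioning) + (claim.x,), reml=True
        )
        p = float(fit.pvalues_t()[claim.x])
        claim_rows.append(
            {
                "response": claim.response,
                "x": claim.x,
                "conditioning": "+".join(claim.conditioning),
                "p": max(p, _P_FLOOR) if math.isfinite(p) else 1.0,
            }
        )
    claims_df = pd.DataFrame(
        claim_rows, columns=["response", "x", "conditioning", "p"]
    )
    if len(claims_df):
        c, c_df, c_p = fisher_c(claims_df["p"])
    else:
        c, c_df, c_p = 0.0, 0, 1.0
    return SemFit(
        paths=pd.DataFrame(
            path_rows, columns=["response", "predictor", "coef", "std_coef", "p"]
        ),
        r2=pd.DataFrame(r2_rows, columns=["response", "marginal", "conditional"]),
        claims=claims_df,
        fisher_c=c,
        c_df=c_df,
        c_p=c_p,
        n_obs=n_obs,
        n_dropped=n_before - n_obs,
    )


def default_abundance_sem() -> SemModel:
    """The trophic-group-abundance SEM over the generator's causal structure.

    Sown richness (log-linear) drives the plant and soil covariates;
    bacterial feeders respond to soil organic carbon, plant feeders to
    leaf C/N and shoot mass, omnivores+predators to their prey groups,
    and fungal feeders have no drivers. Abundances are log-scale.
    """
    covariates = ["root_mass", "srl", "shoot_mass", "cn_leaf", "soil_corg"]
    edges = [("ln_richness", c) for c in covariates]
    edges += [
        ("soil_corg", "bf_abund"),
        ("cn_leaf", "pf_abund"),
        ("shoot_mass", "pf_abund"),
        ("bf_abund", "ompr_abund"),
        ("pf_abund", "ompr_abund"),
    ]
    # ff_abund participates in the basis set as a driverless response.
    # Correlated errors among trophic-group abundances not linked by a
    # directed path: every group's abundance is estimated from the same
    # <=100-individual identified subsample, so their measurement errors
    # are (negatively) coupled by construction.
    model = SemModel(
        edges=edges,
        correlated_errors=[
            ("bf_abund", "pf_abund"),
            ("bf_abund", "ff_abund"),
            ("pf_abund", "ff_abund"),
            ("ff_abund", "ompr_abund"),
        ],
        # covariates are right-skewed, multiplicative quantities: log them so
        # component models are linear and homoscedastic; abundances use log1p
        # rather than strict log because a subsample with no individual of a
        # group yields an estimated abundance of exactly 0, and the unit
        # offset is immaterial at per-100 g abundances of order 10^2-10^3
        transforms={
            "root_mass": "log",
            "srl": "log",
            "shoot_mass": "log",
            "cn_leaf": "log",
            "soil_corg": "log",
            "bf_abund": "log1p",
            "pf_abund": "log1p",
            "ff_abund": "log1p",
            "ompr_abund": "log1p",
        },
        design_vars=frozenset({"ln_richness"}),
    )
    model._graph.add_node("ff_abund")
    return model


def sem_frame(covariates: pd.DataFrame, indices: pd.DataFrame) -> pd.DataFrame:
    """Merge covariates and index tables into a SEM/LRT analysis frame.

    Adds ``ln_richness`` (log sown richness) and ``mixture`` (the sorted
    species composition string, i.e. mixture identity).
    """
    df = covariates.merge(indices, on="plot_id", how="inner").copy()
    df["ln_richness"] = np.log(df["sown_richness"].to_numpy(dtype=float))
    df["mixture"] = df["species"]
    return df
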