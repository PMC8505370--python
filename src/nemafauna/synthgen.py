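"""Synthetic covariates and nematode samples over the dominance-experiment roster.

The generator emulates the study conditions end to end so that every
downstream stage (indices, ordination, mixed models, piecewise SEM) can
be exercised and calibrated without the deposited field data:

* plant/soil covariates follow log-linear links in ln(sown richness)
  with block effects and lognormal noise — positive slopes for shoot
  mass, root mass and soil C_org, a small negative slope for specific
  root length, none for the community-weighted leaf C/N ratio; soil N
  is generated to correlate with soil C_org (target r ≈ 0.866);
* realized richness is obtained by thinning legume (and, weakly, herb)
  presence, emulating the legume extinctions observed in the field;
* trophic-group abundances per 100 g dry soil follow the causal
  structure assumed by the structural equation models: bacterial
  feeders respond to soil C_org, plant feeders to leaf C/N (+) and
  shoot mass (−), omnivores+predators to realized bacterial- and
  plant-feeder abundance (prey), fungal feeders are flat;
* counts are negative binomial (overdispersion typical of nematode
  counts; Poisson as the no-dispersion limit), allocated to genera by a
  geometric rank–abundance series within each trophic group, and
  thinned to an identified subsample of at most ``cap`` individuals by
  a multivariate hypergeometric draw — mirroring the "identify up to
  100 individuals" protocol;
* root-derived measurements (root mass, SRL, RLD) are flagged missing
  on the second monoculture replicate of each species, leaving 86 of
  the 93 plots with complete data, as in the field campaign.

A fixed seed reproduces the entire dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, default_annotations, genera_by_trophic
from .design import LEGUMES, HERBS, Roster, build_dominance_roster
from .metrics import NematodeSample


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class CovariateLink:
    """Lognormal covariate: exp(alpha + beta·ln(sown richness) + block + noise)."""

    alpha: float
    beta: float
    sigma: float


# Default covariate scales: shoot mass in g m^-2, root mass in g cm^-3,
# SRL in m g^-1, leaf C/N dimensionless, soil C_org in mg g^-1.
_DEFAULT_COVARIATES: Mapping[str, CovariateLink] = {
    "shoot_mass": CovariateLink(alpha=math.log(220.0), beta=0.35, sigma=0.30),
    "root_mass": CovariateLink(alpha=math.log(0.0018), beta=0.20, sigma=0.30),
    "srl": CovariateLink(alpha=math.log(100.0), beta=-0.08, sigma=0.22),
    "cn_leaf": CovariateLink(alpha=math.log(19.0), beta=0.0, sigma=0.10),
    "soil_corg": CovariateLink(alpha=math.log(20.0), beta=0.15, sigma=0.12),
}


@dataclass(frozen=True)
class TrophicLinks:
    """Log-linear links from covariates to expected per-100 g group abundances.

    Intercepts are the log expected abundance at the reference covariate
    values (the ``*_ref`` fields); slopes are per covariate unit.
    Omnivores+predators respond to the *realized* (noise-included)
    abundances of their prey groups.
    """

    bf_intercept: float = math.log(228.0)
    bf_on_corg: float = 0.05
    corg_ref: float = 20.0

    pf_intercept: float = math.log(1180.0)
    pf_on_cn: float = 0.08
    pf_on_shoot: float = -0.0015
    cn_ref: float = 19.0
    shoot_ref: float = 260.0

    ff_intercept: float = math.log(240.0)

    # elasticities: response of log Om+Pr to log prey abundance (numerical
    # response of predators to prey density is multiplicative)
    ompr_intercept: float = math.log(208.0)
    ompr_on_bf: float = 0.6
    ompr_on_pf: float = 0.5
    bf_ref: float = 228.0
    pf_ref: float = 1180.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that parameterizes a synthetic dataset."""

    seed: int = 0
    covariates: Mapping[str, CovariateLink] = dfield(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    links: TrophicLinks = dfield(default_factory=TrophicLinks)
    block_sd: float = 0.08
    corg_n_rho: float = 0.866
    soil_n_alpha: float = math.log(1.7)
    soil_n_sigma: float = 0.15
    rld_sigma: float = 0.05
    legume_extinction: float = 0.35
    herb_extinction: float = 0.15
    nb_dispersion: float | None = 8.0  # None = Poisson
    cap: int = 100
    fresh_mass: float = 25.0  # g fresh soil extracted (documentation value)
    dry_mass_mean: float = 22.0
    dry_mass_sd: float = 1.5
    dry_mass_min: float = 10.0
    genus_geometric_ratio: float = 0.55

    def __post_init__(self) -> None:
        for name, link in self.covariates.items():
            for v in (link.alpha, link.beta, link.sigma):
                if not math.isfinite(v):
                    raise ConfigError(f"non-finite coefficient in covariate {name!r}")
            if link.sigma < 0:
                raise ConfigError(f"negative noise scale for covariate {name!r}")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ConfigError("negative-binomial dispersion must be positive")
        if self.cap < 1:
            raise ConfigError("subsample cap must be at least 1")
        if not 0 <= self.corg_n_rho <= 1:
            raise ConfigError("soil C_org / N correlation must lie in [0, 1]")


def zero_effect_config(seed: int = 0) -> SyntheticConfig:
    """All richness slopes and all causal path coefficients set to zero.

    Used for null calibration: under this configuration no response has
    any true association with richness or with any covariate.
    """
    cov = {
        name: replace(link, beta=0.0) for name, link in _DEFAULT_COVARIATES.items()
    }
    links = TrophicLinks(
        bf_on_corg=0.0, pf_on_cn=0.0, pf_on_shoot=0.0, ompr_on_bf=0.0, ompr_on_pf=0.0
    )
    return SyntheticConfig(seed=seed, covariates=cov, links=links)


def generate_covariates(
    cfg: SyntheticConfig, roster: Roster, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-plot measurements over *roster*; one row per plot.

    Columns: plot_id, block, sown_richness, replicate, species,
    realized_richness, the five lognormal covariates, rld (derived from
    root mass × SRL), soil_n (correlated with soil C_org), and a
    root_data flag (False on the second monoculture replicates, whose
    root-derived columns are set to NaN).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = len(roster)
    ln_s = np.log([p.sown_richness for p in roster])
    blocks = np.array([p.block for p in roster])

    out = roster.to_frame()

    # block effects: one log-scale intercept shift per covariate × block
    for name, link in cfg.covariates.items():
        block_eff = rng.normal(0.0, cfg.block_sd, size=4)
        eps = rng.normal(0.0, link.sigma, size=n)
        out[name] = np.exp(link.alpha + link.beta * ln_s + block_eff[blocks - 1] + eps)

    # root length density: root length / soil volume = root mass × SRL
    # (unit conversion m g^-1 × g cm^-3 → ×100 cm cm^-3), small extra noise
    out["rld"] = (
        out["root_mass"]
        * out["srl"]
        * 100.0
        * np.exp(rng.normal(0.0, cfg.rld_sigma, size=n))
    )

    # soil N built from the standardized log soil C_org so the realized
    # correlation matches the configured value
    ln_corg = np.log(out["soil_corg"].to_numpy())
    sd = ln_corg.std()
    z = (ln_corg - ln_corg.mean()) / sd if sd > 0 else np.zeros(n)
    w = rng.normal(0.0, 1.0, size=n)
    rho = cfg.corg_n_rho
    out["soil_n"] = np.exp(
        cfg.soil_n_alpha
        + cfg.soil_n_sigma * (rho * z + math.sqrt(max(0.0, 1 - rho**2)) * w)
    )

    # realized richness: thin legume/herb presence in mixtures
    realized = []
    for p in roster:
        if p.sown_richness == 1:
            realized.append(1)
            continue
        alive = 0
        for sp in p.species:
            if sp in LEGUMES:
                dead = rng.random() < cfg.legume_extinction
            elif sp in HERBS:
                dead = rng.random() < cfg.herb_extinction
            else:
                dead = False
            alive += 0 if dead else 1
        realized.append(max(1, alive))
    out["realized_richness"] = realized

    # root campaign skipped the second monoculture replicate of each species
    no_root = (out["sown_richness"] == 1) & (out["replicate"] == 2)
    out["root_data"] = ~no_root
    out.loc[no_root, ["root_mass", "srl", "rld"]] = np.nan
    return out


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    """Negative binomial with mean/dispersion parameterization; Poisson when None."""
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # Gamma–Poisson mixture: var = mean + mean^2 / dispersion
    lam = rng.gamma(dispersion, mean / dispersion)
    return int(rng.poisson(lam))


def group_expectations(
    cfg: SyntheticConfig,
    soil_corg: float,
    cn_leaf: float,
    shoot_mass: float,
) -> dict[str, float]:
    """Expected per-100 g abundances of BF, PF and FF given covariates."""
    L = cfg.links
    return {
        "BF": math.exp(L.bf_intercept + L.bf_on_corg * (soil_corg - L.corg_ref)),
        "PF": math.exp(
            L.pf_intercept
            + L.pf_on_cn * (cn_leaf - L.cn_ref)
            + L.pf_on_shoot * (shoot_mass - L.shoot_ref)
        ),
        "FF": math.exp(L.ff_intercept),
    }


def _genus_probs(genera: list[str], ratio: float) -> np.ndarray:
    """Geometric rank–abundance series over alphabetically ordered genera."""
    w = np.array([ratio**i for i in range(len(genera))], dtype=float)
    return w / w.sum()


def generate_nematode_sample(
    cfg: SyntheticConfig,
    plot_id: str,
    measurements: Mapping[str, float],
    aset: AnnotationSet | None = None,
    rng: np.random.Generator | None = None,
) -> NematodeSample:
    """One plot's raw nematode sample from its covariates.

    *measurements* must provide ``soil_corg``, ``cn_leaf`` and
    ``shoot_mass``. Counts are realized at the sample scale (expected
    per-100 g abundance × dry mass / 100), omnivores+predators respond
    to the realized prey abundances, and identification is a
    multivariate hypergeometric subsample of at most ``cap`` animals.
    """
    if aset is None:
        aset = default_annotations()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    by_trophic = genera_by_trophic(aset)
    for required in ("BF", "PF", "FF", "Om", "Pr"):
        if not by_trophic[required]:
            raise ConfigError(f"annotation table has no {required} genera")

    dry_mass = float(
        np.clip(
            rng.normal(cfg.dry_mass_mean, cfg.dry_mass_sd), cfg.dry_mass_min, None
        )
    )
    scale = dry_mass / 100.0

    mu = group_expectations(
        cfg,
        float(measurements["soil_corg"]),
        float(measurements["cn_leaf"]),
        float(measurements["shoot_mass"]),
    )
    counts: dict[str, int] = {}
    realized_100g: dict[str, float] = {}
    for grp in ("BF", "PF", "FF"):
        c = _nb_draw(rng, mu[grp] * scale, cfg.nb_dispersion)
        counts[grp] = c
        realized_100g[grp] = c / scale

    L = cfg.links
    # log-log (elasticity) links to realized prey abundance; prey-free plots
    # contribute through a half-animal floor to keep the log finite
    ln_bf = math.log(max(realized_100g["BF"], 0.5 / scale))
    ln_pf = math.log(max(realized_100g["PF"], 0.5 / scale))
    mu_ompr = math.exp(
        L.ompr_intercept
        + L.ompr_on_bf * (ln_bf - math.log(L.bf_ref))
        + L.ompr_on_pf * (ln_pf - math.log(L.pf_ref))
    )
    counts["OmPr"] = _nb_draw(rng, mu_ompr * scale, cfg.nb_dispersion)

    # allocate group counts to genera: geometric series over alphabetical order
    genus_names: list[str] = []
    genus_counts: list[int] = []
    group_members = {
        "BF": by_trophic["BF"],
        "PF": by_trophic["PF"],
        "FF": by_trophic["FF"],
        "OmPr": sorted(by_trophic["Om"] + by_trophic["Pr"]),
    }
    for grp, members in group_members.items():
        if counts[grp] == 0:
            continue
        probs = _genus_probs(members, cfg.genus_geometric_ratio)
        alloc = rng.multinomial(counts[grp], probs)
        for g, c in zip(members, alloc):
            if c > 0:
                genus_names.append(g)
                genus_counts.append(int(c))

    counted_total = int(sum(genus_counts))
    n_identify = min(counted_total, cfg.cap)
    if counted_total > 0 and n_identify > 0:
        picked = rng.multivariate_hypergeometric(genus_counts, n_identify)
        identified = {
            g: int(c) for g, c in zip(genus_names, picked) if c > 0
        }
    else:
        identified = {}
    return NematodeSample(
        plot_id=plot_id,
        dry_mass=dry_mass,
        counted_total=counted_total,
        identified=identified,
    )


@dataclass
class SyntheticDataset:
    """Complete synthetic study: roster, covariates and nematode samples."""

    roster: Roster
    covariates: pd.DataFrame
    samples: list[NematodeSample]

    @property
    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [s.plot_id for s in self.samples],
                "dry_mass": [s.dry_mass for s in self.samples],
                "counted_total": [s.counted_total for s in self.samples],
            }
        )

    @property
    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {"plot_id": s.plot_id, "genus": g, "identified_count": c}
            for s in self.samples
            for g, c in sorted(s.identified.items())
        ]
        return pd.DataFrame(rows, columns=["plot_id", "genus", "identified_count"])

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.roster.to_frame().to_csv(out / "plots.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.counts_frame.to_csv(out / "nematode_counts.csv", index=False)
        self.samples_frame.to_csv(out / "samples.csv", index=False)


def generate_dataset(
    cfg: SyntheticConfig | None = None,
    seed: int | None = None,
    roster: Roster | None = None,
    aset: AnnotationSet | None = None,
) -> SyntheticDataset:
    """End-to-end synthetic dataset over the 93-plot roster.

    *seed* overrides ``cfg.seed`` when given; the same seed yields an
    identical dataset bit for bit.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if roster is None:
        roster = build_dominance_roster()
    if aset is None:
        aset = default_annotations()
    rng = np.random.default_rng(cfg.seed)
    covariates = generate_covariates(cfg, roster, rng)
    samples = [
        generate_nematode_sample(cfg, row.plot_id, row._asdict(), aset, rng)
        for row in covariates.itertuples(index=False)
    ]
    return SyntheticDataset(roster=roster, covariates=covariates, samples=samples)
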