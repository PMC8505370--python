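"""Per-plot nematode community metrics.

From a raw sample (total count in the dried soil subsample plus a
genus-identified subsample of at most ``cap`` individuals) the module
derives abundances per 100 g dry soil and the standard faunal metrics:

* genus richness and Shannon–Wiener diversity (natural log),
* trophic-group abundances and genus richness (PF, BF, FF, Pr, Om, and
  the grouped Om+Pr),
* predator–prey ratio (Pr+Om)/PF, channel ratio FF/(FF+BF), and the
  grazing-pressure ratio log(PF / root mass),
* c–p class abundances (c–p 1+2 pooled, 3, 4, 5) over free-living
  (non-plant-feeding) genera,
* Maturity Index (c–p-weighted mean over free-living genera),
* Enrichment and Structure indices from guild-weighted components,
* community-weighted means of plant traits, and the transgressive-
  overyielding statistic D_max against the best constituent monoculture.

Undefined metrics propagate as NaN, never as zero — zero is a legal
metric value and must not be conflated with "not computable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, GuildWeightTable


class MetricError(ValueError):
    """Raised for inconsistent samples or inputs outside a metric's domain."""


@dataclass(frozen=True)
class NematodeSample:
    """Raw counts for one plot.

    counted_total is every animal counted in the extracted subsample;
    ``identified`` maps genus to counts in the microscopy subsample
    (at most ``cap`` individuals, all of them when fewer were present).
    dry_mass is the dried remaining soil in grams.
    """

    plot_id: str
    dry_mass: float
    counted_total: int
    identified: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.counted_total < 0:
            raise MetricError(f"{self.plot_id}: negative counted_total")
        if any(c < 0 for c in self.identified.values()):
            raise MetricError(f"{self.plot_id}: negative identified count")
        n_ident = sum(self.identified.values())
        if n_ident > 0 and self.counted_total == 0:
            raise MetricError(
                f"{self.plot_id}: identified individuals but counted_total = 0"
            )
        if n_ident > self.counted_total:
            raise MetricError(
                f"{self.plot_id}: identified ({n_ident}) exceeds counted_total "
                f"({self.counted_total})"
            )


@dataclass(frozen=True)
class CommunityProfile:
    """Genus abundances extrapolated to individuals per 100 g dry soil."""

    plot_id: str
    abundance: Mapping[str, float]
    total_per_100g: float

    def __post_init__(self) -> None:
        s = float(sum(self.abundance.values()))
        if not math.isclose(s, self.total_per_100g, rel_tol=1e-9, abs_tol=1e-9):
            raise MetricError(
                f"{self.plot_id}: abundances sum to {s}, not {self.total_per_100g}"
            )

    @property
    def genera(self) -> list[str]:
        return [g for g, a in self.abundance.items() if a > 0]


def abundance_per_100g(sample: NematodeSample) -> float:
    """Total nematodes per 100 g dry soil: counted_total × 100 / dry_mass."""
    if sample.dry_mass <= 0:
        raise MetricError(f"{sample.plot_id}: dry mass must be positive")
    return sample.counted_total * 100.0 / sample.dry_mass


def genus_profile(sample: NematodeSample) -> CommunityProfile:
    """Allocate the per-100 g total to genera by their identified shares."""
    total = abundance_per_100g(sample)
    n_ident = sum(sample.identified.values())
    if sample.counted_total == 0:
        return CommunityProfile(sample.plot_id, {}, 0.0)
    if n_ident == 0:
        raise MetricError(
            f"{sample.plot_id}: counted {sample.counted_total} but none identified"
        )
    abund = {
        g: c / n_ident * total for g, c in sample.identified.items() if c > 0
    }
    return CommunityProfile(sample.plot_id, abund, total)


def diversity_metrics(profile: CommunityProfile) -> tuple[int, float]:
    """(genus richness, Shannon–Wiener H' in nats); H' is NaN for empty profiles."""
    abund = np.array([a for a in profile.abundance.values() if a > 0], dtype=float)
    richness = int(abund.size)
    if richness == 0:
        return 0, float("nan")
    q = abund / abund.sum()
    return richness, float(-(q * np.log(q)).sum())


@dataclass(frozen=True)
class TrophicSummary:
    """Abundance and genus richness per trophic group (per 100 g dry soil)."""

    abundance: Mapping[str, float]  # keys PF, BF, FF, Pr, Om
    richness: Mapping[str, int]

    @property
    def ompr_abundance(self) -> float:
        return self.abundance["Om"] + self.abundance["Pr"]

    @property
    def ompr_richness(self) -> int:
        return self.richness["Om"] + self.richness["Pr"]


def trophic_summary(profile: CommunityProfile, aset: AnnotationSet) -> TrophicSummary:
    missing = aset.missing(profile.genera)
    if missing:
        raise MetricError(f"unannotated genera: {missing}")
    abund = {t: 0.0 for t in ("PF", "BF", "FF", "Pr", "Om")}
    rich = {t: 0 for t in ("PF", "BF", "FF", "Pr", "Om")}
    for g, a in profile.abundance.items():
        if a <= 0:
            continue
        t = aset.trophic(g)
        abund[t] += a
        rich[t] += 1
    return TrophicSummary(abund, rich)


def trophic_ratios(
    summary: TrophicSummary,
    root_mass: float | None = None,
    log_base: float = math.e,
) -> tuple[float, float, float]:
    """(predator–prey, channel, grazing-pressure) ratios; NaN where undefined.

    predator–prey = (Pr+Om)/PF; channel = FF/(FF+BF);
    grazing pressure = log(PF/root mass), natural log by default.
    """
    pf = summary.abundance["PF"]
    ff = summary.abundance["FF"]
    bf = summary.abundance["BF"]
    pred_prey = summary.ompr_abundance / pf if pf > 0 else float("nan")
    channel = ff / (ff + bf) if (ff + bf) > 0 else float("nan")
    if pf > 0 and root_mass is not None and root_mass > 0:
        grazing = math.log(pf / root_mass) / math.log(log_base)
    else:
        grazing = float("nan")
    return pred_prey, channel, grazing


def cp_class_abundances(
    profile: CommunityProfile, aset: AnnotationSet
) -> tuple[float, float, float, float]:
    """(c–p 1+2, c–p 3, c–p 4, c–p 5) abundances over non-plant-feeding genera.

    Plant feeders are excluded: they respond to nutrient availability
    unlike the free-living c–p groups.
    """
    missing = aset.missing(profile.genera)
    if missing:
        raise MetricError(f"unannotated genera: {missing}")
    sums = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0}
    for g, a in profile.abundance.items():
        if a <= 0 or aset.trophic(g) == "PF":
            continue
        sums[aset.cp(g)] += a
    return sums[1] + sums[2], sums[3], sums[4], sums[5]


def maturity_index(
    profile: CommunityProfile, aset: AnnotationSet, exclude_pf: bool = True
) -> float:
    """MI = Σ v_g q_g: c–p-weighted mean of relative abundances.

    By default computed within the free-living (non-PF) community; set
    ``exclude_pf=False`` to weight over all taxa instead. NaN when no
    eligible individuals are present.
    """
    missing = aset.missing(profile.genera)
    if missing:
        raise MetricError(f"unannotated genera: {missing}")
    num = 0.0
    den = 0.0
    for g, a in profile.abundance.items():
        if a <= 0:
            continue
        if exclude_pf and aset.trophic(g) == "PF":
            continue
        num += aset.cp(g) * a
        den += a
    return num / den if den > 0 else float("nan")


def enrichment_structure_indices(
    profile: CommunityProfile, aset: AnnotationSet, weights: GuildWeightTable
) -> tuple[float, float]:
    """(EI, SI) on the 0–100 scale from weighted guild components.

    With e, b, s the weighted sums over enrichment, basal and structure
    guilds: EI = 100·e/(e+b), SI = 100·s/(s+b). NaN where the respective
    denominator is zero.
    """
    missing = aset.missing(profile.genera)
    if missing:
        raise MetricError(f"unannotated genera: {missing}")
    e = b = s = 0.0
    for g, a in profile.abundance.items():
        if a <= 0:
            continue
        guild = aset.guild(g)
        e += weights.weight(guild, "enrichment") * a
        b += weights.weight(guild, "basal") * a
        s += weights.weight(guild, "structure") * a
    ei = 100.0 * e / (e + b) if (e + b) > 0 else float("nan")
    si = 100.0 * s / (s + b) if (s + b) > 0 else float("nan")
    return ei, si


def community_weighted_mean(
    proportions: Sequence[float], traits: Sequence[float], tol: float = 1e-8
) -> float:
    """CWM = Σ p_i t_i with p the species biomass proportions (Σp = 1)."""
    p = np.asarray(proportions, dtype=float)
    t = np.asarray(traits, dtype=float)
    if p.shape != t.shape:
        raise MetricError("proportions and traits differ in length")
    if (p < 0).any():
        raise MetricError("negative biomass proportion")
    if abs(p.sum() - 1.0) > tol:
        raise MetricError(f"biomass proportions sum to {p.sum()}, not 1")
    return float(p @ t)


@dataclass(frozen=True)
class DmaxRecord:
    """Transgressive overyielding of one mixture against its best monoculture."""

    mixture_value: float  # O_T
    benchmark: float  # M_Max: best (max or min) constituent monoculture
    dmax: float


def dmax(
    mixture_value: float,
    mono_values: Sequence[float],
    direction: str = "max",
) -> DmaxRecord:
    """D_max = (O_T − M_Max)/M_Max.

    ``direction="max"`` benchmarks against the highest constituent
    monoculture (variables expected to increase with richness);
    ``direction="min"`` against the lowest (variables expected to
    decrease, e.g. channel and grazing-pressure ratios).
    """
    vals = [v for v in mono_values if not math.isnan(v)]
    if not vals:
        raise MetricError("no monoculture values supplied")
    if direction not in ("max", "min"):
        raise MetricError(f"direction must be 'max' or 'min', got {direction!r}")
    bench = max(vals) if direction == "max" else min(vals)
    if bench == 0:
        return DmaxRecord(mixture_value, bench, float("nan"))
    return DmaxRecord(mixture_value, bench, (mixture_value - bench) / bench)


@dataclass(frozen=True)
class IndexSet:
    """All per-plot community metrics."""

    plot_id: str
    total_per_100g: float
    genus_richness: int
    shannon: float
    pf_abund: float
    bf_abund: float
    ff_abund: float
    ompr_abund: float
    pf_richness: int
    bf_richness: int
    ff_richness: int
    ompr_richness: int
    predator_prey: float
    channel: float
    grazing_pressure: float
    cp12: float
    cp3: float
    cp4: float
    cp5: float
    mi: float
    ei: float
    si: float


def compute_indices(
    sample: NematodeSample,
    aset: AnnotationSet,
    weights: GuildWeightTable,
    root_mass: float | None = None,
) -> IndexSet:
    """Full :class:`IndexSet` for one plot."""
    profile = genus_profile(sample)
    richness, shannon = diversity_metrics(profile)
    troph = trophic_summary(profile, aset)
    pred_prey, channel, grazing = trophic_ratios(troph, root_mass)
    cp12, cp3, cp4, cp5 = cp_class_abundances(profile, aset)
    mi = maturity_index(profile, aset)
    ei, si = enrichment_structure_indices(profile, aset, weights)
    return IndexSet(
        plot_id=sample.plot_id,
        total_per_100g=profile.total_per_100g,
        genus_richness=richness,
        shannon=shannon,
        pf_abund=troph.abundance["PF"],
        bf_abund=troph.abundance["BF"],
        ff_abund=troph.abundance["FF"],
        ompr_abund=troph.ompr_abundance,
        pf_richness=troph.richness["PF"],
        bf_richness=troph.richness["BF"],
        ff_richness=troph.richness["FF"],
        ompr_richness=troph.ompr_richness,
        predator_prey=pred_prey,
        channel=channel,
        grazing_pressure=grazing,
        cp12=cp12,
        cp3=cp3,
        cp4=cp4,
        cp5=cp5,
        mi=mi,
        ei=ei,
        si=si,
    )


def indices_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    aset: AnnotationSet,
    weights: GuildWeightTable,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One :class:`IndexSet` row per plot from long-format tables.

    *counts* needs columns ``plot_id, genus, identified_count``; *samples*
    needs ``plot_id, dry_mass, counted_total``. Root mass (for the
    grazing-pressure ratio) is taken from *covariates* (``plot_id,
    root_mass``) when given.
    """
    root = {}
    if covariates is not None and "root_mass" in covariates.columns:
        root = dict(zip(covariates["plot_id"], covariates["root_mass"]))
    by_plot = {
        pid: dict(zip(sub["genus"], sub["identified_count"].astype(int)))
        for pid, sub in counts.groupby("plot_id")
    }
    rows = []
    for r in samples.itertuples():
        sample = NematodeSample(
            plot_id=str(r.plot_id),
            dry_mass=float(r.dry_mass),
            counted_total=int(r.counted_total),
            identified=by_plot.get(str(r.plot_id), {}),
        )
        rm = root.get(str(r.plot_id))
        rm = None if rm is None or (isinstance(rm, float) and math.isnan(rm)) else float(rm)
        idx = compute_indices(sample, aset, weights, root_mass=rm)
        rows.append({f.name: getattr(idx, f.name) for f in fields(IndexSet)})
    return pd.DataFrame(rows)


def dmax_table(
    indices: pd.DataFrame,
    roster_frame: pd.DataFrame,
    response: str,
    direction: str = "max",
) -> pd.DataFrame:
    """D_max per mixture plot for one response column of an indices table.

    The benchmark for each mixture is the best (per *direction*) of the
    constituent species' monoculture means, averaging the available
    monoculture replicates of each species. Mixtures whose benchmark is
    undefined (all constituent monocultures missing) are dropped.
    """
    df = roster_frame.merge(indices, on="plot_id", how="inner")
    monos = df[df["sown_richness"] == 1]
    mono_mean = monos.groupby("species")[response].mean()

    rows = []
    for r in df[df["sown_richness"] > 1].itertuples():
        species = str(r.species).split(";")
        vals = [mono_mean.get(s, float("nan")) for s in species]
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        o_t = getattr(r, response)
        if not vals or (isinstance(o_t, float) and math.isnan(o_t)):
            continue
        rec = dmax(float(o_t), vals, direction=direction)
        if math.isnan(rec.dmax):
            continue
        rows.append(
            {
                "plot_id": r.plot_id,
                "block": r.block,
                "sown_richness": r.sown_richness,
                "mixture": r.species,
                "dmax": rec.dmax,
            }
        )
    return pd.DataFrame(rows)


def merge_identical_genera(
    profile: CommunityProfile, aset: AnnotationSet
) -> CommunityProfile:
    """Collapse genera sharing an identical annotation into one pseudo-genus.

    Trophic and c–p metrics are invariant under this merge; richness and
    Shannon diversity can only decrease.
    """
    representative: dict[str, str] = {}
    merged: dict[str, float] = {}
    for g in sorted(profile.abundance):
        ann = aset.get(g)
        key = representative.setdefault(ann.guild, g)
        merged[key] = merged.get(key, 0.0) + profile.abundance[g]
    return CommunityProfile(profile.plot_id, merged, profile.total_per_100g)
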