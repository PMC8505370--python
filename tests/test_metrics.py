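import math

import numpy as np
import pytest

from nemafauna.annotations import AnnotationSet, GenusAnnotation
from nemafauna.metrics import (
    CommunityProfile,
    MetricError,
    NematodeSample,
    abundance_per_100g,
    community_weighted_mean,
    compute_indices,
    cp_class_abundances,
    diversity_metrics,
    dmax,
    enrichment_structure_indices,
    genus_profile,
    maturity_index,
    merge_identical_genera,
    trophic_ratios,
    trophic_summary,
)


def profile(abund: dict, plot="p1") -> CommunityProfile:
    return CommunityProfile(plot, abund, float(sum(abund.values())))


class TestAbundanceScaling:
    def test_counted_400_dry_25_gives_1600(self):
        s = NematodeSample("p", 25.0, 400, {"Plectus": 100})
        assert abundance_per_100g(s) == pytest.approx(1600.0)

    def test_empty_sample_is_zero(self):
        assert abundance_per_100g(NematodeSample("p", 25.0, 0, {})) == 0.0

    def test_dry_mass_100_is_identity(self):
        s = NematodeSample("p", 100.0, 321, {"Plectus": 100})
        assert abundance_per_100g(s) == pytest.approx(321.0)

    def test_nonpositive_dry_mass_rejected(self):
        with pytest.raises(MetricError, match="dry mass"):
            abundance_per_100g(NematodeSample("p", 0.0, 10, {"Plectus": 5}))


class TestGenusProfile:
    def test_proportional_allocation(self):
        s = NematodeSample("p", 20.0, 400, {"A": 60, "B": 40})  # total/100 g = 2000
        p = genus_profile(s)
        assert p.abundance["A"] == pytest.approx(1200.0)
        assert p.abundance["B"] == pytest.approx(800.0)

    def test_fully_identified_sample_needs_no_correction(self):
        s = NematodeSample("p", 50.0, 37, {"A": 30, "B": 7})
        p = genus_profile(s)
        assert p.abundance["A"] == pytest.approx(30 * 100 / 50.0)

    def test_single_genus_carries_total(self):
        p = genus_profile(NematodeSample("p", 25.0, 250, {"A": 100}))
        assert p.abundance == {"A": pytest.approx(1000.0)}

    def test_identified_without_counts_is_inconsistent(self):
        with pytest.raises(MetricError):
            NematodeSample("p", 25.0, 0, {"A": 3})


class TestDiversity:
    def test_hand_computed_shannon(self):
        rich, h = diversity_metrics(profile({"a": 50.0, "b": 30.0, "c": 20.0}))
        assert rich == 3
        assert h == pytest.approx(1.0297, abs=1e-4)

    def test_uniform_profile_reaches_max_entropy(self):
        _, h = diversity_metrics(profile({g: 5.0 for g in "abcd"}))
        assert h == pytest.approx(math.log(4))

    def test_single_genus_has_zero_entropy(self):
        rich, h = diversity_metrics(profile({"a": 10.0}))
        assert (rich, h) == (1, 0.0)

    def test_empty_profile_flagged_missing(self):
        rich, h = diversity_metrics(CommunityProfile("p", {}, 0.0))
        assert rich == 0 and math.isnan(h)


class TestTrophicAndCp:
    def test_group_sums_with_named_genera(self, aset):
        t = trophic_summary(
            profile({"Helicotylenchus": 100.0, "Plectus": 50.0, "Aphelenchus": 50.0}),
            aset,
        )
        assert t.abundance["PF"] == 100.0
        assert t.abundance["BF"] == 50.0
        assert t.abundance["FF"] == 50.0
        assert t.richness["BF"] == 1

    def test_unannotated_genus_is_named_in_error(self, aset):
        with pytest.raises(MetricError, match="Xenogenus"):
            trophic_summary(profile({"Xenogenus": 1.0}), aset)

    def test_ratios(self, aset):
        t = trophic_summary(
            profile({"Helicotylenchus": 60.0, "Clarkus": 20.0, "Prodorylaimus": 10.0}),
            aset,
        )
        pred_prey, channel, grazing = trophic_ratios(t, root_mass=None)
        assert pred_prey == pytest.approx(0.5)
        assert math.isnan(channel)  # no microbial feeders present
        assert math.isnan(grazing)  # no root mass supplied

    def test_channel_ratio(self, aset):
        t = trophic_summary(profile({"Aphelenchus": 50.0, "Plectus": 150.0}), aset)
        assert trophic_ratios(t)[1] == pytest.approx(0.25)

    def test_grazing_pressure_natural_log(self, aset):
        t = trophic_summary(profile({"Helicotylenchus": 100.0}), aset)
        assert trophic_ratios(t, root_mass=0.01)[2] == pytest.approx(
            math.log(10000), abs=1e-4
        )

    def test_cp_classes_exclude_plant_feeders(self, aset):
        p = profile(
            {
                "Protorhabditis": 10.0,  # BF1
                "Plectus": 20.0,  # BF2
                "Prodesmodora": 5.0,  # BF3
                "Clarkus": 3.0,  # Pr4
                "Prodorylaimus": 2.0,  # Om5
                "Helicotylenchus": 50.0,  # PF3 - excluded
            }
        )
        assert cp_class_abundances(p, aset) == pytest.approx((30.0, 5.0, 3.0, 2.0))

    def test_all_plant_feeder_profile_has_empty_cp_classes(self, aset):
        p = profile({"Helicotylenchus": 9.0, "Lelenchus": 1.0})
        assert cp_class_abundances(p, aset) == (0.0, 0.0, 0.0, 0.0)


class TestMaturityIndex:
    def test_weighted_mean_hand_value(self, aset):
        p = profile(
            {
                "Protorhabditis": 10.0,
                "Plectus": 20.0,
                "Prodesmodora": 5.0,
                "Clarkus": 3.0,
                "Prodorylaimus": 2.0,
            }
        )
        assert maturity_index(p, aset) == pytest.approx(2.175)

    def test_constant_class_community(self, aset):
        assert maturity_index(profile({"Plectus": 7.0, "Wilsonema": 3.0}), aset) == 2.0

    def test_upper_bound_community(self, aset):
        p = profile({"Prodorylaimus": 1.0, "Aporcelaimellus": 4.0})
        assert maturity_index(p, aset) == 5.0

    def test_pf_only_profile_is_undefined(self, aset):
        assert math.isnan(maturity_index(profile({"Helicotylenchus": 3.0}), aset))


class TestEnrichmentStructure:
    @pytest.fixture()
    def bf_guild_set(self):
        return AnnotationSet(
            [
                GenusAnnotation("Alpha", "BF", 1),
                GenusAnnotation("Beta", "BF", 2),
                GenusAnnotation("Gamma", "BF", 5),
            ]
        )

    def test_enrichment_only_community(self, aset, weights):
        ei, si = enrichment_structure_indices(
            profile({"Protorhabditis": 10.0}), aset, weights
        )
        assert ei == pytest.approx(100.0)

    def test_basal_only_community(self, aset, weights):
        ei, si = enrichment_structure_indices(profile({"Plectus": 10.0}), aset, weights)
        assert (ei, si) == (0.0, 0.0)

    def test_weighted_quotients(self, bf_guild_set, weights):
        # e = 3.2*10 = 32, b = 0.8*10 = 8, s = 5.0*10 = 50
        p = profile({"Alpha": 10.0, "Beta": 10.0, "Gamma": 10.0})
        ei, si = enrichment_structure_indices(p, bf_guild_set, weights)
        assert ei == pytest.approx(80.0)
        assert si == pytest.approx(100 * 50 / 58, abs=1e-2)


class TestCwmAndDmax:
    @pytest.mark.parametrize(
        "p,t,expected",
        [((0.5, 0.5), (20, 30), 25.0), ((1.0,), (17,), 17.0), ((0.25, 0.75), (12, 20), 18.0)],
    )
    def test_cwm(self, p, t, expected):
        assert community_weighted_mean(p, t) == pytest.approx(expected)

    def test_cwm_rejects_non_normalized_proportions(self):
        with pytest.raises(MetricError, match="sum"):
            community_weighted_mean((0.5, 0.4), (1.0, 2.0))

    def test_dmax_zero_when_mixture_equals_best(self):
        assert dmax(10.0, [10.0, 8.0]).dmax == 0.0

    def test_dmax_max_benchmark(self):
        assert dmax(15.0, [10.0, 8.0], "max").dmax == pytest.approx(0.5)

    def test_dmax_min_benchmark(self):
        assert dmax(4.0, [10.0, 5.0], "min").dmax == pytest.approx(-0.2)

    def test_dmax_empty_monocultures_rejected(self):
        with pytest.raises(MetricError):
            dmax(1.0, [])


# ---------------------------------------------------------------------------
# independent naive-loop oracle


def oracle_metrics(abund, ann, w):
    """Brute-force re-computation of every IndexSet metric with plain loops."""
    total = sum(abund.values())
    present = {g: a for g, a in abund.items() if a > 0}
    rich = len(present)
    h = 0.0
    for a in present.values():
        q = a / total
        h -= q * math.log(q)
    groups = {t: 0.0 for t in ("PF", "BF", "FF", "Pr", "Om")}
    grich = {t: 0 for t in groups}
    for g, a in present.items():
        groups[ann[g][0]] += a
        grich[ann[g][0]] += 1
    pf, bf, ff = groups["PF"], groups["BF"], groups["FF"]
    ompr = groups["Om"] + groups["Pr"]
    pred_prey = ompr / pf if pf > 0 else float("nan")
    channel = ff / (ff + bf) if ff + bf > 0 else float("nan")
    cp = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0}
    mi_num = mi_den = 0.0
    for g, a in present.items():
        trophic, c = ann[g]
        if trophic == "PF":
            continue
        cp[c] += a
        mi_num += c * a
        mi_den += a
    mi = mi_num / mi_den if mi_den > 0 else float("nan")
    e = b = s = 0.0
    for g, a in present.items():
        guild = f"{ann[g][0]}{ann[g][1]}"
        e += w.get((guild, "enrichment"), 0.0) * a
        b += w.get((guild, "basal"), 0.0) * a
        s += w.get((guild, "structure"), 0.0) * a
    ei = 100 * e / (e + b) if e + b > 0 else float("nan")
    si = 100 * s / (s + b) if s + b > 0 else float("nan")
    return {
        "genus_richness": rich,
        "shannon": h,
        "pf_abund": pf,
        "bf_abund": bf,
        "ff_abund": ff,
        "ompr_abund": ompr,
        "predator_prey": pred_prey,
        "channel": channel,
        "cp12": cp[1] + cp[2],
        "cp3": cp[3],
        "cp4": cp[4],
        "cp5": cp[5],
        "mi": mi,
        "ei": ei,
        "si": si,
    }


def _annotation_lookup(aset):
    return {a.genus: (a.trophic, a.cp) for a in aset}


def _weight_lookup(weights):
    return {
        (r.guild, r.component): r.weight
        for r in weights.to_frame().itertuples()
        if r.component != "excluded"
    }


class TestOracleEquivalence:
    def test_random_profiles_match_naive_oracle(self, aset, weights, rng):
        ann = _annotation_lookup(aset)
        w = _weight_lookup(weights)
        genera = sorted(ann)
        for _ in range(200):
            k = rng.integers(2, 25)
            chosen = rng.choice(genera, size=k, replace=False)
            counts = rng.integers(1, 40, size=k)
            dry = float(rng.uniform(15, 30))
            sample = NematodeSample(
                "p", dry, int(counts.sum()), dict(zip(chosen, counts.tolist()))
            )
            got = compute_indices(sample, aset, weights)
            expected = oracle_metrics(
                genus_profile(sample).abundance, ann, w
            )
            for key, exp in expected.items():
                val = getattr(got, key)
                if isinstance(exp, float) and math.isnan(exp):
                    assert math.isnan(val), key
                else:
                    assert val == pytest.approx(exp, rel=1e-12), key

    def test_scale_invariance(self, aset, weights, rng):
        """Scaling abundances leaves composition metrics unchanged."""
        genera = ["Plectus", "Aphelenchus", "Helicotylenchus", "Clarkus", "Protorhabditis"]
        base = {g: float(a) for g, a in zip(genera, rng.uniform(1, 50, 5))}
        for c in (0.1, 7.3):
            scaled = profile({g: a * c for g, a in base.items()})
            orig = profile(dict(base))
            assert diversity_metrics(scaled)[1] == pytest.approx(
                diversity_metrics(orig)[1], rel=1e-12
            )
            t_o = trophic_summary(orig, aset)
            t_s = trophic_summary(scaled, aset)
            for i in range(2):
                a, b = trophic_ratios(t_o)[i], trophic_ratios(t_s)[i]
                assert a == pytest.approx(b, rel=1e-12)
            assert maturity_index(scaled, aset) == pytest.approx(
                maturity_index(orig, aset), rel=1e-12
            )
            assert enrichment_structure_indices(scaled, aset, weights) == pytest.approx(
                enrichment_structure_indices(orig, aset, weights), rel=1e-12
            )

    def test_merging_identically_annotated_genera(self, aset, weights):
        """Merging same-guild genera preserves trophic/c-p metrics and can
        only decrease richness and Shannon diversity."""
        p = profile(
            {"Plectus": 30.0, "Wilsonema": 20.0, "Eucephalobus": 10.0, "Clarkus": 5.0}
        )
        merged = merge_identical_genera(p, aset)
        assert len(merged.abundance) == 2  # three BF2 genera collapse
        assert maturity_index(merged, aset) == pytest.approx(maturity_index(p, aset))
        t_p, t_m = trophic_summary(p, aset), trophic_summary(merged, aset)
        assert t_p.abundance == t_m.abundance
        assert enrichment_structure_indices(merged, aset, weights) == pytest.approx(
            enrichment_structure_indices(p, aset, weights)
        )
        assert diversity_metrics(merged)[0] <= diversity_metrics(p)[0]
        assert diversity_metrics(merged)[1] <= diversity_metrics(p)[1]
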