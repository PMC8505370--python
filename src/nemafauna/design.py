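"""Reconstruction of the sampled plot roster of a nine-species dominance experiment.

The design uses nine potentially dominant grassland species — five grasses,
two legumes, two herbs — sown at richness levels 1, 2, 6 and 9 across four
blocks. Two of the nine (Phleum pratense and Anthriscus sylvestris) were
nearly extinct at sampling and serve only as partners, never as targets.
The sampled roster comprises 93 plots:

* 14 monocultures (two replicates of each of the 7 target species),
* 47 two-species plots (all target pairs in two replicates, with single
  replicates where legumes had gone extinct, plus single-replicate pairs
  with the two non-target species, with stated exceptions),
* 24 six-species plots (12 compositions × 2 replicates, each target
  occurring 16 times),
* 8 nine-species plots (all nine species).

The reconstruction is deterministic and matches every printed margin of
the design summary table.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import pandas as pd

GRASSES = (
    "Alopecurus pratensis",
    "Arrhenatherum elatius",
    "Dactylis glomerata",
    "Phleum pratense",
    "Poa trivialis",
)
LEGUMES = ("Trifolium pratense", "Trifolium repens")
HERBS = ("Anthriscus sylvestris", "Geranium pratense")

ALL_SPECIES = tuple(sorted(GRASSES + LEGUMES + HERBS))

#: Species not used as targets (almost extinct at sampling).
NON_TARGETS = ("Phleum pratense", "Anthriscus sylvestris")
TARGET_SPECIES = tuple(s for s in ALL_SPECIES if s not in NON_TARGETS)

_AE = "Arrhenatherum elatius"
_AP = "Alopecurus pratensis"
_DG = "Dactylis glomerata"
_PT = "Poa trivialis"
_GP = "Geranium pratense"
_TP = "Trifolium pratense"
_TR = "Trifolium repens"
_AS = "Anthriscus sylvestris"
_PP = "Phleum pratense"

N_BLOCKS = 4
RICHNESS_LEVELS = (1, 2, 6, 9)


@dataclass(frozen=True)
class PlotSpec:
    """One experimental plot: sown composition, block and replicate."""

    plot_id: str
    block: int
    sown_richness: int
    species: frozenset[str]
    replicate: int

    def __post_init__(self) -> None:
        if len(self.species) != self.sown_richness:
            raise ValueError(
                f"{self.plot_id}: |species| = {len(self.species)} != sown richness "
                f"{self.sown_richness}"
            )
        unknown = self.species - set(ALL_SPECIES)
        if unknown:
            raise ValueError(f"{self.plot_id}: unknown species {sorted(unknown)}")
        if not 1 <= self.block <= N_BLOCKS:
            raise ValueError(f"{self.plot_id}: block {self.block} outside 1..{N_BLOCKS}")


def composition_key(species: frozenset[str]) -> str:
    """Deterministic 8-hex-digit hash of a sorted species composition."""
    joined = "|".join(sorted(species))
    return f"{zlib.crc32(joined.encode()):08x}"


@dataclass
class Roster:
    """Ordered collection of :class:`PlotSpec` with block assignments."""

    plots: list[PlotSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.plots)

    def __iter__(self):
        return iter(self.plots)

    def at_richness(self, k: int) -> list[PlotSpec]:
        return [p for p in self.plots if p.sown_richness == k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "block": [p.block for p in self.plots],
                "sown_richness": [p.sown_richness for p in self.plots],
                "species": [";".join(sorted(p.species)) for p in self.plots],
                "replicate": [p.replicate for p in self.plots],
            }
        )

    def validate(self) -> None:
        """Check the roster invariants; raises ValueError on violation."""
        seen: dict[tuple[frozenset[str], int], str] = {}
        by_comp: dict[frozenset[str], list[PlotSpec]] = {}
        for p in self.plots:
            key = (p.species, p.replicate)
            if key in seen:
                raise ValueError(f"duplicate composition/replicate: {p.plot_id}")
            seen[key] = p.plot_id
            by_comp.setdefault(p.species, []).append(p)
        for comp, plots in by_comp.items():
            blocks = [p.block for p in plots]
            if len(blocks) <= N_BLOCKS:
                if len(blocks) != len(set(blocks)):
                    raise ValueError(
                        f"replicates of {sorted(comp)} share a block: {blocks}"
                    )
            else:
                # more replicates than blocks (the nine-species community):
                # spread as evenly as divisibility allows
                per = [blocks.count(b) for b in range(1, N_BLOCKS + 1)]
                if max(per) - min(per) > 1:
                    raise ValueError(
                        f"replicates of {sorted(comp)} unbalanced over blocks: {blocks}"
                    )


def _two_species_compositions() -> list[tuple[frozenset[str], int]]:
    """(composition, n_replicates) for the 47 two-species plots."""
    single_rep_target_pairs = {
        frozenset({_TP, _AE}),
        frozenset({_TP, _AP}),
        frozenset({_TP, _DG}),
        frozenset({_TR, _AE}),
        frozenset({_TR, _AP}),
        frozenset({_TR, _DG}),
        frozenset({_TP, _TR}),
    }
    out: list[tuple[frozenset[str], int]] = []
    for a, b in itertools.combinations(TARGET_SPECIES, 2):
        comp = frozenset({a, b})
        out.append((comp, 1 if comp in single_rep_target_pairs else 2))
    # pairs of each target with the two non-target species, one replicate,
    # except the stated exclusions and the doubled T. pratense–A. sylvestris pair
    excluded = {
        frozenset({_GP, _AS}),
        frozenset({_GP, _PP}),
        frozenset({_TR, _AS}),
    }
    for t in TARGET_SPECIES:
        for nt in (_AS, _PP):
            comp = frozenset({t, nt})
            if comp in excluded:
                continue
            reps = 2 if comp == frozenset({_TP, _AS}) else 1
            out.append((comp, reps))
    return out


def _six_species_compositions() -> list[frozenset[str]]:
    """12 distinct 6-subsets of the nine species, each species in exactly 8.

    Equivalently: 12 distinct 3-subsets (the omitted species), each species
    omitted exactly 4 times. Found by exhaustive lexicographic backtracking
    — deterministic and independent of any seed.
    """
    n = len(ALL_SPECIES)
    triples = list(itertools.combinations(range(n), 3))
    target_omissions = 4
    n_comps = 12

    counts = [0] * n
    chosen: list[tuple[int, int, int]] = []

    def dfs(start: int) -> bool:
        if len(chosen) == n_comps:
            return all(c == target_omissions for c in counts)
        # the lexicographically first species still under quota must appear
        # in the next triple — prunes the search to well under a millisecond
        first_open = min(i for i in range(n) if counts[i] < target_omissions)
        for idx in range(start, len(triples)):
            t = triples[idx]
            if first_open not in t:
                continue
            if any(counts[i] >= target_omissions for i in t):
                continue
            chosen.append(t)
            for i in t:
                counts[i] += 1
            if dfs(idx + 1):
                return True
            for i in t:
                counts[i] -= 1
            chosen.pop()
        return False

    if not dfs(0):  # pragma: no cover - design is known feasible
        raise RuntimeError("no balanced six-species design found")
    full = set(range(n))
    return [
        frozenset(ALL_SPECIES[i] for i in full - set(t)) for t in chosen
    ]


def build_dominance_roster() -> Roster:
    """Deterministically reconstruct the 93-plot sampled roster.

    Blocks are assigned by cycling blocks 1–4 within each richness level,
    honouring the constraint that replicates of an identical composition
    lie in different blocks. The published design does not print the full
    block layout; no downstream statistic on synthetic data depends on
    which block a composition landed in.
    """
    compositions: list[tuple[int, frozenset[str], int]] = []  # (richness, comp, reps)
    for t in TARGET_SPECIES:
        compositions.append((1, frozenset({t}), 2))
    for comp, reps in _two_species_compositions():
        compositions.append((2, comp, reps))
    for comp in _six_species_compositions():
        compositions.append((6, comp, 2))
    compositions.append((9, frozenset(ALL_SPECIES), 8))

    plots: list[PlotSpec] = []
    for richness in RICHNESS_LEVELS:
        level = [(c, r) for (k, c, r) in compositions if k == richness]
        level.sort(key=lambda cr: tuple(sorted(cr[0])))
        cursor = 0
        for comp, reps in level:
            used: set[int] = set()
            for rep in range(1, reps + 1):
                block = cursor % N_BLOCKS + 1
                # replicates must differ in block, as far as divisibility allows
                while block in used and len(used) < N_BLOCKS:
                    cursor += 1
                    block = cursor % N_BLOCKS + 1
                if len(used) == N_BLOCKS:
                    used.clear()
                used.add(block)
                cursor += 1
                plots.append(
                    PlotSpec(
                        plot_id=f"SR{richness}_{composition_key(comp)}_r{rep}",
                        block=block,
                        sown_richness=richness,
                        species=comp,
                        replicate=rep,
                    )
                )
    roster = Roster(plots)
    roster.validate()
    return roster


def summarize_roster(roster: Roster) -> pd.DataFrame:
    """Occurrence counts per species × richness level, plus community totals.

    Mirrors the printed design summary: species rows give how often each
    species occurred in plots of that richness level; the final row gives
    the total number of communities.
    """
    levels = sorted({p.sown_richness for p in roster})
    rows = {}
    for sp in ALL_SPECIES:
        rows[sp] = [
            sum(1 for p in roster.at_richness(k) if sp in p.species) for k in levels
        ]
    rows["Total no. of communities"] = [len(roster.at_richness(k)) for k in levels]
    return pd.DataFrame(rows, index=levels).T.rename_axis(columns="sown_richness")
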