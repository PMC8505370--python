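"""Genus-level reference tables for nematode faunal analysis.

Two tables drive every community metric:

* a genus annotation table assigning each genus a trophic group — plant
  feeder (PF), bacterial feeder (BF), fungal feeder (FF), predator (Pr),
  omnivore (Om) — and a colonizer–persister (c–p) life-history class from
  1 (fast, disturbance-tolerant) to 5 (slow, sensitive);
* a functional-guild weight table mapping guild codes (trophic × c–p,
  e.g. ``BF1``) to the enrichment / basal / structure components used by
  the Enrichment and Structure indices, with their weights.

Both ship as editable TSV files under ``nemafauna/data`` so alternative
published weightings or classifications can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TROPHIC_GROUPS = ("PF", "BF", "FF", "Pr", "Om")
CP_CLASSES = (1, 2, 3, 4, 5)
GUILD_COMPONENTS = ("enrichment", "basal", "structure", "excluded")


class AnnotationError(ValueError):
    """Raised when an annotation or guild-weight table fails validation."""


def _norm(genus: str) -> str:
    """Normalization key for genus matching: trimmed, case-insensitive."""
    return genus.strip().casefold()


@dataclass(frozen=True)
class GenusAnnotation:
    """Trophic group and c–p class of one nematode genus."""

    genus: str
    trophic: str
    cp: int

    def __post_init__(self) -> None:
        if self.trophic not in TROPHIC_GROUPS:
            raise AnnotationError(
                f"{self.genus}: trophic group {self.trophic!r} not one of {TROPHIC_GROUPS}"
            )
        if self.cp not in CP_CLASSES:
            raise AnnotationError(
                f"{self.genus}: c-p class {self.cp!r} outside 1..5"
            )

    @property
    def guild(self) -> str:
        """Functional guild code: trophic abbreviation + c–p digit, e.g. ``BF1``."""
        return f"{self.trophic}{self.cp}"


def guild_code(a: GenusAnnotation) -> str:
    return a.guild


class AnnotationSet:
    """Validated collection of :class:`GenusAnnotation`, unique per genus.

    Lookup is case-insensitive after trimming, since field data tables
    vary in capitalization.
    """

    def __init__(self, annotations: Iterable[GenusAnnotation]):
        self._by_key: dict[str, GenusAnnotation] = {}
        dupes = []
        for a in annotations:
            key = _norm(a.genus)
            if key in self._by_key:
                dupes.append(a.genus)
            self._by_key[key] = a
        if dupes:
            raise AnnotationError(f"duplicate genus names: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, genus: str) -> bool:
        return _norm(genus) in self._by_key

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, genus: str) -> GenusAnnotation:
        try:
            return self._by_key[_norm(genus)]
        except KeyError:
            raise AnnotationError(f"genus {genus!r} not in annotation table") from None

    def trophic(self, genus: str) -> str:
        return self.get(genus).trophic

    def cp(self, genus: str) -> int:
        return self.get(genus).cp

    def guild(self, genus: str) -> str:
        return self.get(genus).guild

    def missing(self, genera: Iterable[str]) -> list[str]:
        """Genera present in a profile but absent from this table (sorted)."""
        return sorted({g for g in genera if _norm(g) not in self._by_key})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.genus, a.trophic, a.cp) for a in self],
            columns=["genus", "trophic", "cp"],
        )

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def load_annotation_table(path: str | Path, sep: str | None = None) -> AnnotationSet:
    """Read a genus annotation table (columns ``genus, trophic, cp``).

    The delimiter is sniffed when *sep* is None; extra columns (e.g. a
    provenance/source column) are ignored.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"genus", "trophic", "cp"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing_cols)}")
    annotations = [
        GenusAnnotation(str(r.genus).strip(), str(r.trophic).strip(), int(r.cp))
        for r in df.itertuples()
    ]
    return AnnotationSet(annotations)


def validate_annotation_table(aset: AnnotationSet, genera: Iterable[str]) -> list[str]:
    """Coverage report: genera in *genera* lacking an annotation (empty = full coverage)."""
    return aset.missing(genera)


class GuildWeightTable:
    """Weights of functional guilds in the enrichment/basal/structure components.

    A guild may appear in more than one component (classically, FF2
    contributes to both the enrichment and the basal component), but at
    most once per component. Every non-PF trophic × c–p combination must
    be covered; PF guilds are always excluded.
    """

    def __init__(self, rows: Iterable[tuple[str, str, float]]):
        self._rows: list[tuple[str, str, float]] = []
        seen: set[tuple[str, str]] = set()
        for guild, component, weight in rows:
            guild = guild.strip()
            component = component.strip()
            if component not in GUILD_COMPONENTS:
                raise AnnotationError(f"unknown component {component!r} for guild {guild}")
            w = float(weight)
            if w < 0:
                raise AnnotationError(f"negative weight for guild {guild}")
            if (guild, component) in seen:
                raise AnnotationError(f"duplicate entry for ({guild}, {component})")
            seen.add((guild, component))
            self._rows.append((guild, component, w))
        self._validate_coverage()

    def _validate_coverage(self) -> None:
        covered = {g for g, _, _ in self._rows}
        for trophic in ("BF", "FF", "Om", "Pr"):
            for cp in CP_CLASSES:
                if f"{trophic}{cp}" not in covered:
                    raise AnnotationError(f"guild {trophic}{cp} has no weight entry")
        for g, comp, _ in self._rows:
            if g.startswith("PF") and comp != "excluded":
                raise AnnotationError(f"plant-feeder guild {g} must be excluded")

    def weight(self, guild: str, component: str) -> float:
        """Weight of *guild* in *component*; 0 when the guild is not a member."""
        for g, c, w in self._rows:
            if g == guild and c == component:
                return w
        return 0.0

    def members(self, component: str) -> dict[str, float]:
        return {g: w for g, c, w in self._rows if c == component}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=["guild", "component", "weight"])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def load_guild_weights(path: str | Path, sep: str | None = None) -> GuildWeightTable:
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"guild", "component", "weight"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise AnnotationError(f"guild weight table missing columns: {sorted(missing_cols)}")
    return GuildWeightTable(
        (str(r.guild), str(r.component), float(r.weight)) for r in df.itertuples()
    )


def _data_path(name: str) -> Path:
    return Path(str(resources.files("nemafauna").joinpath("data").joinpath(name)))


def default_annotations() -> AnnotationSet:
    """The shipped 51-genus annotation table (grassland soil nematodes)."""
    return load_annotation_table(_data_path("genus_annotations.tsv"), sep="\t")


def default_guild_weights() -> GuildWeightTable:
    """The shipped enrichment/basal/structure guild weighting."""
    return load_guild_weights(_data_path("guild_weights.tsv"), sep="\t")


def genera_by_trophic(aset: AnnotationSet) -> Mapping[str, list[str]]:
    """Alphabetical genus lists per trophic group."""
    out: dict[str, list[str]] = {t: [] for t in TROPHIC_GROUPS}
    for a in aset:
        out[a.trophic].append(a.genus)
    for t in out:
        out[t].sort()
    return out
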