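"""Binary longevity trait map (LONG / SHORT) with optional max lifespan."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ValidationError
from .tree import Phylogeny

LONG = "LONG"
SHORT = "SHORT"
CLASSES = (LONG, SHORT)


@dataclass
class TraitMap:
    """tip label -> class in {LONG, SHORT}, plus optional lifespan (years)."""

    classes: dict[str, str]
    lifespan: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for sp, cls in self.classes.items():
            if cls not in CLASSES:
                raise ValidationError(f"unknown class {cls!r} for species {sp!r}")
        for sp, yrs in self.lifespan.items():
            if not yrs > 0:
                raise ValidationError(f"non-positive lifespan for {sp!r}: {yrs}")

    def __getitem__(self, tip: str) -> str:
        return self.classes[tip]

    def __contains__(self, tip: str) -> bool:
        return tip in self.classes

    def __iter__(self) -> Iterator[str]:
        return iter(self.classes)

    def tips_of(self, cls: str) -> list[str]:
        return [t for t, c in self.classes.items() if c == cls]

    @property
    def long_tips(self) -> list[str]:
        return self.tips_of(LONG)

    @property
    def short_tips(self) -> list[str]:
        return self.tips_of(SHORT)

    def check_against_tree(self, tree: Phylogeny, require_both: bool = True) -> None:
        tips = set(tree.tip_labels)
        stray = [t for t in self.classes if t not in tips]
        if stray:
            raise ValidationError(f"trait species not in tree: {sorted(stray)}")
        if require_both and (not self.long_tips or not self.short_tips):
            raise ValidationError("need at least one tip in each class")

    def swapped(self) -> "TraitMap":
        """Exchange the two class labels (used by antisymmetry checks)."""
        inv = {LONG: SHORT, SHORT: LONG}
        return TraitMap({t: inv[c] for t, c in self.classes.items()}, dict(self.lifespan))

    def restricted(self, tips: Iterable[str]) -> "TraitMap":
        keep = set(tips)
        return TraitMap(
            {t: c for t, c in self.classes.items() if t in keep},
            {t: v for t, v in self.lifespan.items() if t in keep},
        )

    # -- I/O ----------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "TraitMap":
        """Read a tab-delimited table: species, class[, max_lifespan_years]."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"species": str})
        required = {"species", "class"}
        if not required.issubset(df.columns):
            raise ValidationError(f"trait TSV must have columns {sorted(required)}")
        for i, cls_token in enumerate(df["class"]):
            if cls_token not in CLASSES:
                raise ValidationError(
                    f"unknown class token {cls_token!r} at row {i + 2}"
                )
        classes = dict(zip(df["species"], df["class"]))
        if len(classes) != len(df):
            raise ValidationError("duplicate species in trait TSV")
        lifespan = {}
        if "max_lifespan_years" in df.columns:
            sub = df.dropna(subset=["max_lifespan_years"])
            lifespan = dict(zip(sub["species"], sub["max_lifespan_years"].astype(float)))
        return cls(classes, lifespan)

    def to_tsv(self, path) -> None:
        rows = [
            {
                "species": sp,
                "class": cls,
                "max_lifespan_years": self.lifespan.get(sp, ""),
            }
            for sp, cls in self.classes.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def trait_series(traits: TraitMap | Mapping[str, str]) -> pd.Series:
    mapping = traits.classes if isinstance(traits, TraitMap) else dict(traits)
    return pd.Series(mapping, name="class")
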