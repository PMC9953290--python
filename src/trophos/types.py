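"""Core record types for the dual stomach-content / stable-isotope workflow.

The study system is a community of four mid-trophic ("ancillary") pelagic
fishes sampled across three geographic areas and two depth strata.  Every
analysis downstream consumes one or more of the record types defined here:

* :class:`Specimen` — one fish with its factor levels and morphometrics,
* :class:`PreyRecord` / :class:`StomachSample` — the gut content of a fish,
* :class:`IsotopeSample` — its muscle δ13C/δ15N measurement.

Records are plain dataclasses; tabular converters to/from :mod:`pandas` are
provided for CSV interchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DomainError

#: The four study species (two mackerels, two horse mackerels).
SPECIES = ("S. colias", "S. scombrus", "T. mediterraneus", "T. trachurus")

#: Geographic sub-basins, north to south.
AREAS = ("North", "Central", "South")

#: Depth strata: inshore hauls (<40 m, daytime) vs offshore (>=40 m, night).
STRATA = ("inshore", "offshore")

#: Sex determination: male, female, or undetermined (juveniles).
SEXES = ("M", "F", "ND")

#: Length categories used throughout: small (<12 cm TL),
#: medium (12.1–24 cm TL), large (>=24 cm TL).
SIZE_CLASSES = ("small", "medium", "large")

#: A stomach whose fullness falls below this percentage counts as empty.
EMPTY_FULLNESS_THRESHOLD = 0.5


def size_class_of(tl_cm: float) -> str:
    """Assign the size class for a total length in cm.

    Small is <12 cm, large is >=24 cm, medium is everything in between
    (the nominal band is 12.1–24 cm; lengths in the measurement gap
    12.0–12.1 are classed as medium).
    """
    if tl_cm <= 0 or not math.isfinite(tl_cm):
        raise DomainError(f"total length must be positive and finite, got {tl_cm}")
    if tl_cm < 12.0:
        return "small"
    if tl_cm >= 24.0:
        return "large"
    return "medium"


@dataclass(frozen=True)
class Specimen:
    """One fish: identity, factor levels, and morphometrics."""

    id: str
    species: str
    area: str
    stratum: str
    sex: str
    tl_cm: float
    ww_g: float
    size_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DomainError(f"unknown species {self.species!r}")
        if self.area not in AREAS:
            raise DomainError(f"unknown area {self.area!r}")
        if self.stratum not in STRATA:
            raise DomainError(f"unknown stratum {self.stratum!r}")
        if self.sex not in SEXES:
            raise DomainError(f"unknown sex {self.sex!r}")
        if self.tl_cm <= 0 or self.ww_g <= 0:
            raise DomainError("TL and WW must be positive")
        expected = size_class_of(self.tl_cm)
        if not self.size_class:
            object.__setattr__(self, "size_class", expected)
        elif self.size_class != expected:
            raise DomainError(
                f"size_class {self.size_class!r} inconsistent with TL {self.tl_cm} cm"
            )


@dataclass(frozen=True)
class PreyRecord:
    """One prey taxon inside one stomach.

    ``is_other`` flags non-prey material (fish scales, parasites,
    unidentifiable digested matter) that diet-composition analyses exclude.
    ``digestion`` grades the state of the item from 0 (undigested) to
    3 (highly digested).
    """

    taxon: str
    count: int
    weight_g: float
    digestion: int
    is_other: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DomainError("prey count must be >= 0")
        if self.weight_g < 0:
            raise DomainError("prey weight must be >= 0")
        if self.digestion not in (0, 1, 2, 3):
            raise DomainError("digestion grade must be in {0, 1, 2, 3}")


@dataclass(frozen=True)
class StomachSample:
    """Gut record of one specimen.

    ``fullness`` is stomach content weight as a percentage of body weight;
    a stomach with fullness below :data:`EMPTY_FULLNESS_THRESHOLD` is
    flagged ``empty``.  Use :meth:`build` to derive both consistently.
    """

    specimen_id: str
    content_weight_g: float
    prey: tuple[PreyRecord, ...]
    fullness: float
    empty: bool

    @classmethod
    def build(
        cls,
        specimen_id: str,
        content_weight_g: float,
        body_weight_g: float,
        prey: tuple[PreyRecord, ...] = (),
    ) -> "StomachSample":
        from .diet_indices import stomach_fullness

        f = stomach_fullness(content_weight_g, body_weight_g)
        return cls(
            specimen_id=specimen_id,
            content_weight_g=content_weight_g,
            prey=tuple(prey),
            fullness=f,
            empty=f < EMPTY_FULLNESS_THRESHOLD,
        )


@dataclass(frozen=True)
class IsotopeSample:
    """Muscle stable-isotope measurement of one specimen.

    δ values are per-mil deviations from international standards (PeeDee
    Belemnite for carbon, atmospheric N2 for nitrogen).  ``d13c_corrected``
    is the lipid-normalized carbon value used by all downstream analyses;
    it equals ``d13c_raw`` unless the C/N ratio exceeded the lipid gate
    (``corrected_flag``).
    """

    specimen_id: str
    d13c_raw: float
    d15n: float
    cn_ratio: float
    d13c_corrected: float | None = None
    corrected_flag: bool = False


# ---------------------------------------------------------------------------
# tabular converters


def specimens_to_frame(specimens: list[Specimen]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "species": s.species,
                "area": s.area,
                "stratum": s.stratum,
                "sex": s.sex,
                "tl_cm": s.tl_cm,
                "ww_g": s.ww_g,
                "size_class": s.size_class,
            }
            for s in specimens
        ]
    )


def specimens_from_frame(df: pd.DataFrame) -> list[Specimen]:
    return [
        Specimen(
            id=str(r.id),
            species=r.species,
            area=r.area,
            stratum=r.stratum,
            sex=r.sex,
            tl_cm=float(r.tl_cm),
            ww_g=float(r.ww_g),
            size_class=str(r.size_class),
        )
        for r in df.itertuples()
    ]


def stomachs_to_frame(stomachs: list[StomachSample]) -> pd.DataFrame:
    """Long format: one row per prey record; empty stomachs keep one row
    with a blank taxon so the round trip preserves them."""
    rows = []
    for st in stomachs:
        base = {
            "specimen_id": st.specimen_id,
            "content_weight_g": st.content_weight_g,
            "fullness_pct": st.fullness,
            "empty": st.empty,
        }
        if not st.prey:
            rows.append({**base, "taxon": "", "count": 0, "weight_g": 0.0,
                         "digestion": -1, "is_other": False})
        for p in st.prey:
            rows.append(
                {**base, "taxon": p.taxon, "count": p.count,
                 "weight_g": p.weight_g, "digestion": p.digestion,
                 "is_other": p.is_other}
            )
    return pd.DataFrame(rows)


def stomachs_from_frame(df: pd.DataFrame) -> list[StomachSample]:
    out: list[StomachSample] = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        first = grp.iloc[0]
        prey = tuple(
            PreyRecord(
                taxon=r.taxon,
                count=int(r.count),
                weight_g=float(r.weight_g),
                digestion=int(r.digestion),
                is_other=bool(r.is_other),
            )
            for r in grp.itertuples()
            if isinstance(r.taxon, str) and r.taxon != ""
        )
        out.append(
            StomachSample(
                specimen_id=str(sid),
                content_weight_g=float(first.content_weight_g),
                prey=prey,
                fullness=float(first.fullness_pct),
                empty=bool(first.empty),
            )
        )
    return out


def isotopes_to_frame(isotopes: list[IsotopeSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen_id": i.specimen_id,
                "d13c_raw": i.d13c_raw,
                "d15n": i.d15n,
                "cn_ratio": i.cn_ratio,
                "d13c_corrected": i.d13c_corrected,
                "corrected_flag": i.corrected_flag,
            }
            for i in isotopes
        ]
    )


def isotopes_from_frame(df: pd.DataFrame) -> list[IsotopeSample]:
    out = []
    for r in df.itertuples():
        corr = getattr(r, "d13c_corrected", None)
        out.append(
            IsotopeSample(
                specimen_id=str(r.specimen_id),
                d13c_raw=float(r.d13c_raw),
                d15n=float(r.d15n),
                cn_ratio=float(r.cn_ratio),
                d13c_corrected=None if corr is None or pd.isna(corr) else float(corr),
                corrected_flag=bool(getattr(r, "corrected_flag", False)),
            )
        )
    return out
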