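"""Lateralized brain-region atlas and per-animal c-Fos density tables.

The unit of observation is one animal; the unit of measurement is the
density of c-Fos-positive cells (cells/mm^2) in one brain region of one
hemisphere.  A cohort is the animals x regions density matrix for a single
experimental condition, and is the input to all downstream network
inference.

The default atlas holds 30 regions: 15 bilateral areas ordered frontal to
caudal, each present in the left (ipsilateral to the stimulated left ear)
and right (contralateral) hemisphere.  Region codes are ``"<Name>-<L|R>"``,
e.g. ``"PrL-L"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cfosnet")

__all__ = [
    "Region",
    "Atlas",
    "CohortTable",
    "compute_density",
    "default_atlas",
    "load_atlas",
    "read_cohort",
    "write_cohort",
    "CohortLoadError",
]

NA_TOKEN = "NA"

HEMISPHERES = ("L", "R")
HEMISPHERE_NAMES = {"L": "left", "R": "right"}

#: display groups used for plotting / presentation (5 anatomical systems)
DISPLAY_GROUPS = ("cortical", "hippocampal", "amygdalar", "thalamic", "brainstem")

#: area groups used for the hemispheric edge-count summary table
AREA_GROUPS = ("frontal", "hippocampal", "amygdalar", "brainstem", "other")


class CohortLoadError(ValueError):
    """Raised when a cohort file fails validation against the atlas."""


@dataclass(frozen=True)
class Region:
    """One lateralized brain area - a node of the functional network.

    Parameters
    ----------
    code : str
        Short unique label, ``"<Name>-<L|R>"`` (e.g. ``"LC-L"``).
    name : str
        Full anatomical name.
    hemisphere : str
        ``"left"`` or ``"right"``.  Left is ipsilateral to the stimulation
        site (left ear).
    display_group : str
        One of ``cortical, hippocampal, amygdalar, thalamic, brainstem``.
    area_group : str
        Grouping used by the hemispheric edge-count table: one of
        ``frontal, hippocampal, amygdalar, brainstem, other``.
    bregma_range : tuple of float, optional
        (min, max) anterioposterior coordinate in mm relative to Bregma.
        Metadata only; never used in computation.
    """

    code: str
    name: str
    hemisphere: str
    display_group: str
    area_group: str
    bregma_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if self.display_group not in DISPLAY_GROUPS:
            raise ValueError(f"unknown display_group {self.display_group!r}")
        if self.area_group not in AREA_GROUPS:
            raise ValueError(f"unknown area_group {self.area_group!r}")


@dataclass(frozen=True)
class Atlas:
    """Ordered collection of :class:`Region`, frontal to caudal, paired L/R."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        codes = [r.code for r in self.regions]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate region codes in atlas: {dupes}")
        for hemi in ("left", "right"):
            names = [r.name for r in self.regions if r.hemisphere == hemi]
            if len(set(names)) != len(names):
                raise ValueError(f"region name repeated within {hemi} hemisphere")

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, code: str) -> Region:
        for r in self.regions:
            if r.code == code:
                return r
        raise KeyError(code)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def hemisphere_codes(self, hemisphere: str) -> list[str]:
        return [r.code for r in self.regions if r.hemisphere == hemisphere]

    def group_codes(self, area_group: str) -> list[str]:
        """Codes of all regions (both hemispheres) in an area group."""
        return [r.code for r in self.regions if r.area_group == area_group]

    def mirror_code(self, code: str) -> str:
        """Code of the homotopic region in the opposite hemisphere."""
        region = self[code]
        suffix = "-R" if region.hemisphere == "left" else "-L"
        return code[: code.rfind("-")] + suffix

    def n_pairs(self) -> int:
        n = len(self)
        return n * (n - 1) // 2

    def pair_codes(self) -> list[tuple[str, str]]:
        """All unordered region pairs in atlas (upper-triangle) order."""
        codes = self.codes
        return [
            (codes[i], codes[j])
            for i in range(len(codes))
            for j in range(i + 1, len(codes))
        ]


# ---------------------------------------------------------------------------
# Default atlas: 15 bilateral areas, frontal -> caudal
# ---------------------------------------------------------------------------

# name, full name, display group, area group, bregma range (mm)
_DEFAULT_AREAS: list[tuple[str, str, str, str, tuple[float, float]]] = [
    ("Cg", "cingulate cortex", "cortical", "frontal", (1.54, 1.94)),
    ("PrL", "prelimbic cortex", "cortical", "frontal", (1.54, 1.94)),
    ("IL", "infralimbic cortex", "cortical", "frontal", (1.54, 1.94)),
    ("DG", "dentate gyrus", "hippocampal", "hippocampal", (-1.82, -1.46)),
    ("CA1", "CA1 field of hippocampus", "hippocampal", "hippocampal", (-1.82, -1.46)),
    ("CA3", "CA3 field of hippocampus", "hippocampal", "hippocampal", (-1.82, -1.46)),
    ("BLA", "basolateral amygdala", "amygdalar", "amygdalar", (-1.82, -1.46)),
    ("LA", "lateral amygdala", "amygdalar", "amygdalar", (-1.82, -1.46)),
    ("CeA", "central amygdala", "amygdalar", "amygdalar", (-1.82, -1.46)),
    ("PVT", "paraventricular nucleus of the thalamus", "thalamic", "other", (-1.82, -1.46)),
    ("RSP", "anterior retrosplenial cortex", "cortical", "other", (-2.92, -1.46)),
    ("pRSP", "posterior retrosplenial cortex", "cortical", "other", (-2.92, -1.46)),
    ("LC", "locus coeruleus", "brainstem", "brainstem", (-5.68, -5.34)),
    ("NTS", "nucleus of the solitary tract", "brainstem", "brainstem", (-7.64, -7.32)),
    ("DMX", "dorsal vagal nucleus", "brainstem", "brainstem", (-7.64, -7.32)),
]


def default_atlas() -> Atlas:
    """The 30-region bilateral atlas (15 areas x left/right).

    Regions are ordered frontal to caudal with hemispheres paired (L then R
    for each area).  Deterministic and order-stable across calls.
    """
    regions = []
    for name, full, disp, area, bregma in _DEFAULT_AREAS:
        for hemi in HEMISPHERES:
            regions.append(
                Region(
                    code=f"{name}-{hemi}",
                    name=full,
                    hemisphere=HEMISPHERE_NAMES[hemi],
                    display_group=disp,
                    area_group=area,
                    bregma_range=bregma,
                )
            )
    return Atlas(regions=tuple(regions))


def load_atlas(path: str | Path) -> Atlas:
    """Load an atlas override from a YAML (or JSON) file.

    The file holds a list of mappings with the :class:`Region` fields
    (``code, name, hemisphere, display_group, area_group`` and optional
    ``bregma_range`` as a two-element list).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"atlas file {path} must contain a list of regions")
    regions = []
    for entry in raw:
        bregma = entry.get("bregma_range")
        regions.append(
            Region(
                code=entry["code"],
                name=entry["name"],
                hemisphere=entry["hemisphere"],
                display_group=entry["display_group"],
                area_group=entry["area_group"],
                bregma_range=tuple(bregma) if bregma is not None else None,
            )
        )
    return Atlas(regions=tuple(regions))


# ---------------------------------------------------------------------------
# Density computation
# ---------------------------------------------------------------------------


def compute_density(counts: Sequence[float], area: float) -> float:
    """Regional c-Fos density from repeated counts of positive cells.

    Several independent determinations (sections) are counted per region and
    hemisphere; the density is their mean divided by the counted area:

        density = mean(counts) / area          [cells / mm^2]

    Parameters
    ----------
    counts : sequence of int
        Non-negative cell counts, one per determination.  The number of
        determinations is not fixed.
    area : float
        Area of the counting region in mm^2 (> 0); assumed identical across
        determinations.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(counts < 0) or np.any(~np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    if not np.isfinite(area) or area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    return float(counts.mean() / area)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Animals x regions density matrix for one experimental condition.

    Attributes
    ----------
    condition : str
        Condition label (e.g. ``"no_stimulation"``).
    data : pandas.DataFrame
        Index = animal IDs (strings, unique), columns = atlas region codes
        in atlas order, values = densities in cells/mm^2.  Missing values
        are ``NaN``.
    atlas : Atlas
        The region atlas the columns are validated against.
    """

    condition: str
    data: pd.DataFrame
    atlas: Atlas = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1:
            raise ValueError("cohort must contain at least one animal")
        if list(self.data.columns) != self.atlas.codes:
            unknown = [c for c in self.data.columns if c not in self.atlas.codes]
            missing = [c for c in self.atlas.codes if c not in self.data.columns]
            raise CohortLoadError(
                f"cohort columns do not match atlas: unknown={unknown}, missing={missing}"
            )
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise CohortLoadError(f"duplicate animal IDs: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] < 0):
            raise ValueError("densities must be non-negative")
        self.data = self.data.astype(float)

    @property
    def animals(self) -> list[str]:
        return [str(a) for a in self.data.index]

    @property
    def n_animals(self) -> int:
        return self.data.shape[0]

    @property
    def densities(self) -> np.ndarray:
        """Animals x regions matrix (float, NaN for missing)."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


def read_cohort(path: str | Path, atlas: Atlas | None = None) -> CohortTable:
    """Read a cohort density table from delimited text.

    Expected layout: header ``animal_id,<sep>condition,<sep><region codes...>``,
    one row per animal, densities in cells/mm^2, missing cells as ``NA``.
    Tab-separated files are recognised by a ``.tsv`` extension.

    Raises
    ------
    CohortLoadError
        On unknown/missing columns, non-numeric densities, duplicate animal
        IDs, or multiple condition labels in one file.
    """
    atlas = atlas if atlas is not None else default_atlas()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(
        path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False,
        dtype={"animal_id": str}, float_precision="round_trip",
    )
    for required in ("animal_id", "condition"):
        if required not in frame.columns:
            raise CohortLoadError(f"{path}: missing required column {required!r}")
    region_cols = [c for c in frame.columns if c not in ("animal_id", "condition")]
    unknown = [c for c in region_cols if c not in atlas.codes]
    if unknown:
        raise CohortLoadError(f"{path}: unknown region column(s) {unknown}")
    missing_cols = [c for c in atlas.codes if c not in region_cols]
    if missing_cols:
        raise CohortLoadError(f"{path}: missing region column(s) {missing_cols}")
    conditions = frame["condition"].unique()
    if len(conditions) != 1:
        raise CohortLoadError(
            f"{path}: expected a single condition label, found {sorted(map(str, conditions))}"
        )
    data = frame.set_index("animal_id")[atlas.codes]
    try:
        data = data.astype(float)
    except (TypeError, ValueError) as exc:
        raise CohortLoadError(f"{path}: non-numeric density value ({exc})") from exc
    n_missing = int(data.isna().to_numpy().sum())
    if n_missing:
        logger.info("%s: %d missing density value(s) flagged", path, n_missing)
    return CohortTable(condition=str(conditions[0]), data=data, atlas=atlas)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort as delimited text; loss-free round trip with
    :func:`read_cohort` (full float precision, column order preserved)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out = cohort.data.copy()
    out.insert(0, "condition", cohort.condition)
    out.index.name = "animal_id"
    # repr-based float formatting round-trips exactly through read_cohort
    out.to_csv(path, sep=sep, na_rep=NA_TOKEN, float_format=lambda v: repr(float(v)))
    return path
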