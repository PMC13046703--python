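"""Packaged reference statistics for the 70 measured chemical components.

The package ships, as plain CSV fixtures, the published per-country summary
statistics of the 70 chemical components quantified in flue-cured tobacco
leaves (routine components, inorganic ions, polyphenols, organic/fatty acids,
free amino acids, Amadori compounds and a few physical indices), together
with the 13-origin sampling plan (9 Chinese provinces + 4 other countries,
1,717 samples in total) and the handful of per-province means that were
reported individually.  These fixtures parameterise the synthetic-data
generator in :mod:`chemorigin.synthesis`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ComponentRegistry",
    "ClassProfile",
    "load_component_registry",
    "load_country_profiles",
    "load_region_counts",
    "load_region_mean_overrides",
]

#: category -> expected number of components
CATEGORY_COUNTS = {
    "Routine chemical components": 5,
    "Cations and anions": 6,
    "Polyphenols": 5,
    "Polyacids and higher fatty acids": 12,
    "Amino acids": 21,
    "Amadori compounds": 17,
    "Others": 4,
}

N_COMPONENTS = 70


def _fixture_path(name: str) -> Path:
    path = resources.files("chemorigin").joinpath("data", name)
    if not path.is_file():
        raise FileNotFoundError(f"packaged fixture {name!r} not found at {path}")
    return Path(str(path))


@dataclass(frozen=True)
class ComponentRegistry:
    """Ordered catalogue of the 70 components: name, chemical category, units."""

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(names) != N_COMPONENTS:
            raise ValueError(f"expected {N_COMPONENTS} components, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        counts: dict[str, int] = {}
        for _, cat, _ in self.entries:
            counts[cat] = counts.get(cat, 0) + 1
        if counts != CATEGORY_COUNTS:
            raise ValueError(f"category counts {counts} do not match expected {CATEGORY_COUNTS}")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def units(self) -> dict[str, str]:
        return {name: units for name, _, units in self.entries}

    @property
    def categories(self) -> dict[str, str]:
        return {name: cat for name, cat, _ in self.entries}

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}") from None


@dataclass(frozen=True)
class ClassProfile:
    """Per-class marginal summary: sample count plus mean/SD per component."""

    class_label: str
    n: int
    mean: np.ndarray
    sd: np.ndarray
    component_names: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.n <= 0:
            raise ValueError(f"profile {self.class_label!r}: n must be positive, got {self.n}")
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError(f"profile {self.class_label!r}: mean/sd must be equal-length vectors")
        if np.any(self.sd < 0):
            raise ValueError(f"profile {self.class_label!r}: sd must be non-negative")
        if self.component_names and len(self.component_names) != self.mean.size:
            raise ValueError(f"profile {self.class_label!r}: component_names length mismatch")


def _read_profiles_frame() -> pd.DataFrame:
    path = _fixture_path("country_profiles.csv")
    df = pd.read_csv(path)
    required = {"component", "category", "units", "country", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"fixture {path.name} is corrupt: missing columns {required - set(df.columns)}")
    return df


def load_component_registry() -> ComponentRegistry:
    """Load the 70-component catalogue (name, category, units) from the fixture."""
    df = _read_profiles_frame()
    sub = df.drop_duplicates("component", keep="first")
    return ComponentRegistry(tuple(zip(sub["component"], sub["category"], sub["units"])))


def load_country_profiles() -> list[ClassProfile]:
    """Per-country mean/SD profiles over all 70 components, at the published n.

    Returns the five country profiles in publication order
    (China n=1269, United States n=64, Brazil n=129, Zimbabwe n=154,
    Zambia n=101), each carrying 70 mean/SD pairs.
    """
    df = _read_profiles_frame()
    registry = load_component_registry()
    counts = load_region_counts()
    country_n: dict[str, int] = {}
    for region, (country, n) in counts.items():
        country_n[country] = country_n.get(country, 0) + n

    profiles = []
    for country in df["country"].drop_duplicates():
        sub = df[df["country"] == country].set_index("component")
        sub = sub.reindex(registry.names)
        if sub[["mean", "sd"]].isna().any().any():
            raise ValueError(f"fixture country_profiles.csv is corrupt for country {country!r}")
        profiles.append(
            ClassProfile(
                class_label=str(country),
                n=country_n[str(country)],
                mean=sub["mean"].to_numpy(),
                sd=sub["sd"].to_numpy(),
                component_names=tuple(registry.names),
            )
        )
    return profiles


def load_region_counts() -> dict[str, tuple[str, int]]:
    """Sampling plan: region -> (country, number of samples); 13 origins, Σn = 1717."""
    path = _fixture_path("region_counts.csv")
    df = pd.read_csv(path)
    if not {"region", "country", "n"}.issubset(df.columns):
        raise ValueError(f"fixture {path.name} is corrupt")
    return {str(r.region): (str(r.country), int(r.n)) for r in df.itertuples()}


def load_region_mean_overrides() -> dict[tuple[str, str], float]:
    """The individually published per-province means, keyed by (region, component).

    Only a handful of within-China province means were reported (e.g. Hunan
    total alkaloids 3.10 %, Heilongjiang 1.19 %); everything else inherits the
    country-level mean.  Used to derive default region offsets for synthesis.
    """
    path = _fixture_path("region_means.csv")
    df = pd.read_csv(path)
    return {(str(r.region), str(r.component)): float(r.mean) for r in df.itertuples()}
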