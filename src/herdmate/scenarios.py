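"""Experiment configuration: recessive-locus tables and scenario presets.

A :class:`Scenario` bundles everything one simulation run needs: the set of
recessive loci segregating in the population, population sizes and caps, the
lifecycle parameters (maximum ages, culling rates), and the mate-allocation
scheme with its knobs (inbreeding-depression cost ``lambda_inbreeding``,
per-bull mating cap, herd-sire sampling rule).

Presets reproduce the published study conditions: the 12-locus US Holstein
panel (fertility haplotypes HH1–HH5, BLAD, CVM, DUMPS, brachyspina, mulefoot,
horned, and red coat color), single hypothetical lethal loci on a 3×2 grid of
initial frequency × economic value, and randomized many-locus panels.
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "RecessiveLocus",
    "Scenario",
    "SCHEMES",
    "holstein_scenario",
    "hypothetical_scenario",
    "horned_scenario",
    "many_loci_scenario",
    "load_locus_table",
    "loci_from_rows",
    "load_scenario_config",
    "save_scenario_config",
    "preset",
    "PRESETS",
]

SCHEMES = ("random", "truncation", "pryce", "modified_pryce")


@dataclass(frozen=True)
class RecessiveLocus:
    """One biallelic recessive locus.

    ``maf`` is the frequency of the minor (recessive) allele. ``value`` is the
    economic cost in dollars of producing a homozygous-recessive calf:
    positive values are undesirable (penalized in the modified allocation
    scheme), negative values are desirable (rewarded, e.g. red coat color).
    ``lethal`` marks loci whose homozygous calves die at birth.
    """

    name: str
    maf: float
    value: float
    lethal: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(
                f"locus {self.name!r}: maf must be in [0, 1], got {self.maf}"
            )


@dataclass(frozen=True)
class Scenario:
    """Full configuration of one breeding-program experiment."""

    loci: tuple[RecessiveLocus, ...] = ()
    name: str = "custom"
    n_base_bulls: int = 350
    n_base_cows: int = 35_000
    n_herds: int = 200
    max_bulls: int = 500
    max_cows: int = 100_000
    max_matings_per_bull: int = 5_000
    years: int = 20
    replicates: int = 10
    scheme: str = "random"
    lambda_inbreeding: float = 25.0  # $ per 1 % increase in calf inbreeding
    trunc_fraction: float = 0.10
    herd_sample_fraction: float = 0.20
    n_herd_sires: int = 50
    bull_max_age: int = 10
    cow_max_age: int = 5
    bull_min_breeding_age: int = 1
    cow_min_breeding_age: int = 2
    involuntary_cull_rate: float = 0.0
    genetic_sd: float = 200.0
    bull_tbv_mean: float = 300.0
    additive_variance: float = 40_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not 0.0 < self.trunc_fraction <= 1.0:
            raise ValueError("trunc_fraction must be in (0, 1]")
        if not 0.0 < self.herd_sample_fraction <= 1.0:
            raise ValueError("herd_sample_fraction must be in (0, 1]")
        if not 0.0 <= self.involuntary_cull_rate <= 1.0:
            raise ValueError("involuntary_cull_rate must be in [0, 1]")
        for fld in (
            "n_base_bulls", "n_base_cows", "n_herds", "max_bulls", "max_cows",
            "max_matings_per_bull", "years", "replicates", "n_herd_sires",
            "bull_max_age", "cow_max_age",
        ):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if self.max_bulls < self.n_base_bulls:
            raise ValueError("max_bulls must be >= n_base_bulls")
        if self.max_cows < self.n_base_cows:
            raise ValueError("max_cows must be >= n_base_cows")
        if abs(self.additive_variance - self.genetic_sd**2) > 1e-6 * self.additive_variance:
            raise ValueError("additive_variance must equal genetic_sd**2")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique within a scenario")
        # loci may arrive as a list; freeze it
        object.__setattr__(self, "loci", tuple(self.loci))

    # -- convenience -------------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def lethal_mask(self) -> np.ndarray:
        return np.array([loc.lethal for loc in self.loci], dtype=bool)

    @property
    def maf_array(self) -> np.ndarray:
        return np.array([loc.maf for loc in self.loci], dtype=float)

    @property
    def value_array(self) -> np.ndarray:
        return np.array([loc.value for loc in self.loci], dtype=float)

    def with_(self, **overrides) -> "Scenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def reduced(self, **overrides) -> "Scenario":
        """Return a desk-scale variant of this scenario.

        The base population shrinks to 50 bulls / 2,000 cows / 20 herds and
        the caps shrink by the same factors (71 bulls, 5,714 cows, 300 matings
        per bull), preserving the structure of the full-scale program while
        keeping runs to seconds per simulated year. Defaults to 10 years and
        3 replicates.
        """
        params = dict(
            n_base_bulls=50,
            n_base_cows=2_000,
            n_herds=20,
            max_bulls=71,
            max_cows=5_714,
            max_matings_per_bull=300,
            years=10,
            replicates=3,
        )
        params.update(overrides)
        return replace(self, **params)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _packaged_holstein_loci() -> list[RecessiveLocus]:
    text = resources.files("herdmate.data").joinpath("holstein_loci.csv").read_text()
    return _parse_locus_rows(io.StringIO(text), source="packaged holstein table")


def holstein_scenario(high_cost: bool = False, **overrides) -> Scenario:
    """The 12-locus US Holstein panel.

    With ``high_cost=True`` every economic value is multiplied by three
    (a sensitivity variant probing how allocation responds to locus prices);
    frequencies and lethality are unchanged.
    """
    loci = _packaged_holstein_loci()
    if high_cost:
        loci = [replace(loc, value=3 * loc.value) for loc in loci]
    name = "holstein_high_cost" if high_cost else "holstein"
    return Scenario(loci=tuple(loci), name=name, **overrides)


_FREQ_LEVELS = {"low": 0.01, "medium": 0.50, "high": 0.90}
_VALUE_LEVELS = {"low": 20.0, "high": 200.0}


def hypothetical_scenario(freq_level: str, value_level: str, **overrides) -> Scenario:
    """A single hypothetical lethal recessive.

    ``freq_level`` ∈ {low: 0.01, medium: 0.50, high: 0.90};
    ``value_level`` ∈ {low: $20, high: $200}.
    """
    try:
        maf = _FREQ_LEVELS[freq_level]
        value = _VALUE_LEVELS[value_level]
    except KeyError as exc:
        raise ValueError(f"unknown level {exc.args[0]!r}") from exc
    locus = RecessiveLocus(f"{freq_level.capitalize()}, {value_level}", maf, value, True)
    return Scenario(
        loci=(locus,), name=f"hypothetical_{freq_level}_{value_level}", **overrides
    )


def horned_scenario(high_value: bool = False, **overrides) -> Scenario:
    """The horned locus alone.

    The recessive *horned* allele sits at frequency 0.9929 (polled is the
    rare dominant allele); the cost of a horned calf is $40, or $400 in the
    high-value variant.
    """
    value = 400.0 if high_value else 40.0
    locus = RecessiveLocus("Horned", 0.9929, value, False)
    name = "horned_high_value" if high_value else "horned"
    return Scenario(loci=(locus,), name=name, **overrides)


def many_loci_scenario(
    n_loci: int,
    rng_seed: int,
    literal_negative_values: bool = False,
    **overrides,
) -> Scenario:
    """A panel of ``n_loci`` lethal recessives with randomized properties.

    Initial minor-allele frequencies are sampled from U[0.01, 0.10] and
    economic-value magnitudes from U[$10, $50]. By default the values are
    positive (costs, consistent with the convention that positive values are
    undesirable); ``literal_negative_values=True`` flips the sign to negative.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    rng = np.random.default_rng(rng_seed)
    mafs = rng.uniform(0.01, 0.10, size=n_loci)
    values = rng.uniform(10.0, 50.0, size=n_loci)
    if literal_negative_values:
        values = -values
    loci = tuple(
        RecessiveLocus(f"L{i + 1:04d}", float(mafs[i]), float(values[i]), True)
        for i in range(n_loci)
    )
    return Scenario(loci=loci, name=f"many_{n_loci}", **overrides)


def _hypothetical_all_loci() -> tuple[RecessiveLocus, ...]:
    return tuple(
        RecessiveLocus(f"{f.capitalize()}, {v}", _FREQ_LEVELS[f], _VALUE_LEVELS[v], True)
        for f in ("high", "medium", "low")
        for v in ("low", "high")
    )


PRESETS = {
    "holstein": lambda **kw: holstein_scenario(False, **kw),
    "holstein_high_cost": lambda **kw: holstein_scenario(True, **kw),
    "hypothetical_all": lambda **kw: Scenario(
        loci=_hypothetical_all_loci(), name="hypothetical_all", **kw
    ),
    "horned": lambda **kw: horned_scenario(False, **kw),
    "horned_high_value": lambda **kw: horned_scenario(True, **kw),
    "many_100": lambda **kw: many_loci_scenario(100, rng_seed=kw.pop("rng_seed", 2015), **kw),
    "many_1000": lambda **kw: many_loci_scenario(1000, rng_seed=kw.pop("rng_seed", 2015), **kw),
}
for _f in ("low", "medium", "high"):
    for _v in ("low", "high"):
        PRESETS[f"hypothetical_{_f}_{_v}"] = (
            lambda _f=_f, _v=_v, **kw: hypothetical_scenario(_f, _v, **kw)
        )


def preset(name: str, **overrides) -> Scenario:
    """Build a packaged preset scenario by name."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return factory(**overrides)


# ---------------------------------------------------------------------------
# Locus-table and config I/O
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_locus_rows(handle, source: str) -> list[RecessiveLocus]:
    reader = csv.DictReader(handle)
    required = {"name", "maf", "value", "lethal"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"{source}: header must contain columns {sorted(required)}")
    loci: list[RecessiveLocus] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):  # data starts at line 2
        try:
            name = row["name"].strip()
            maf = float(row["maf"])
            value = float(row["value"])
            lethal = _BOOL[row["lethal"].strip().lower()]
        except (KeyError, TypeError, ValueError, AttributeError) as exc:
            raise ValueError(f"{source}: malformed row at line {i}: {row}") from exc
        if name in seen:
            raise ValueError(f"{source}: duplicate locus name {name!r} at line {i}")
        seen.add(name)
        try:
            loci.append(RecessiveLocus(name, maf, value, lethal))
        except ValueError as exc:
            raise ValueError(f"{source}: line {i}: {exc}") from exc
    return loci


def load_locus_table(path: str | Path) -> list[RecessiveLocus]:
    """Read a locus table from a CSV with columns name,maf,value,lethal."""
    path = Path(path)
    with path.open(newline="") as handle:
        return _parse_locus_rows(handle, source=str(path))


def loci_from_rows(rows: Iterable[Sequence]) -> tuple[RecessiveLocus, ...]:
    """Build loci from (name, maf, value, lethal) tuples."""
    return tuple(RecessiveLocus(str(n), float(m), float(v), bool(l)) for n, m, v, l in rows)


def save_scenario_config(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as a flat YAML document (loci inline as a list)."""
    doc = dataclasses.asdict(scenario)
    doc["loci"] = [dataclasses.asdict(loc) for loc in scenario.loci]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario_config(path: str | Path, **overrides) -> Scenario:
    """Read a scenario config written by :func:`save_scenario_config`.

    The document may instead name a preset (``scenario: holstein``) and list
    only the fields that deviate from the preset's defaults.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    doc.update(overrides)
    preset_name = doc.pop("scenario", None)
    if "loci" in doc:
        doc["loci"] = tuple(RecessiveLocus(**loc) for loc in doc["loci"])
    if preset_name is not None:
        return preset(preset_name, **doc)
    return Scenario(**doc)
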