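"""Population-level paternity records: reading, validation, clustering, pooling.

The unit of analysis is a *population*: one row summarising a published
paternity study — how many broods (or litters) were genotyped, the mean brood
size k̄, the mean number of sires per brood s̄, and the proportion of broods
with more than one sire (the observed probability of multiple paternity, p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PopulationRecord",
    "Violation",
    "BROOD_SIZE_CLUSTERS",
    "read_population_table",
    "write_population_table",
    "validate_record",
    "assign_brood_size_cluster",
    "pool_species",
]

CLADES = {"bird", "mammal"}
TECHNIQUES = {"microsatellite", "fingerprint"}
MATING_SYSTEMS = {"monogamous", "other", "unknown"}

#: Mean-brood-size clusters: (lower, upper]; the first is open below, the last
#: open above.  Broods of at most 2.5 share one cluster, above 6.5 another.
BROOD_SIZE_CLUSTERS: tuple[tuple[float, float], ...] = (
    (-math.inf, 2.5),
    (2.5, 3.5),
    (3.5, 4.5),
    (4.5, 5.5),
    (5.5, 6.5),
    (6.5, math.inf),
)


@dataclass(frozen=True)
class PopulationRecord:
    """Observed summaries for one studied population.

    Attributes
    ----------
    species_name, population_id : str
        Species (binomial) and a unique population label.
    clade : str
        ``"bird"`` or ``"mammal"``.
    technique : str
        Molecular technique, ``"microsatellite"`` or ``"fingerprint"``.
    mating_system : str
        ``"monogamous"``, ``"other"`` or ``"unknown"``.
    n_broods : int
        Number of broods/litters genotyped (>= 1).
    mean_brood_size : float
        Offspring per brood, k̄ (>= 1).
    mean_n_sires : float
        Sires per brood, s̄ (>= 1).
    prop_mp : float
        Proportion of broods with more than one sire, p in [0, 1].
    body_mass : float | None
        Optional adult body mass in grams.
    """

    species_name: str
    population_id: str
    clade: str
    technique: str
    mating_system: str
    n_broods: int
    mean_brood_size: float
    mean_n_sires: float
    prop_mp: float
    body_mass: float | None = None


@dataclass(frozen=True)
class Violation:
    """One failed record invariant: which rule, and the offending values."""

    invariant: str
    message: str


_MANDATORY = (
    "species_name",
    "population_id",
    "clade",
    "technique",
    "mating_system",
    "n_broods",
    "mean_brood_size",
    "mean_n_sires",
    "prop_mp",
)
_OPTIONAL = ("body_mass",)


def _coerce_row(row: pd.Series, idx: int) -> PopulationRecord:
    def num(field: str, caster):
        raw = row[field]
        try:
            return caster(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"row {idx}: cannot parse {field}={raw!r} as a number"
            ) from exc

    mass = None
    if "body_mass" in row.index and pd.notna(row["body_mass"]) and row["body_mass"] != "":
        mass = num("body_mass", float)
    return PopulationRecord(
        species_name=str(row["species_name"]),
        population_id=str(row["population_id"]),
        clade=str(row["clade"]).strip().lower(),
        technique=str(row["technique"]).strip().lower(),
        mating_system=str(row["mating_system"]).strip().lower(),
        n_broods=num("n_broods", int),
        mean_brood_size=num("mean_brood_size", float),
        mean_n_sires=num("mean_n_sires", float),
        prop_mp=num("prop_mp", float),
        body_mass=mass,
    )


def read_population_table(
    path,
    delimiter: str | None = None,
    column_map: dict[str, str] | None = None,
) -> list[PopulationRecord]:
    """Read a delimited population table into records, in file order.

    Parameters
    ----------
    path : path-like
        Delimited text file with one header row; comma by default, tab
        accepted (``delimiter=None`` sniffs between the two).
    delimiter : str, optional
        Explicit field delimiter.
    column_map : dict, optional
        Mapping from file column names to canonical field names, for tables
        whose headers differ from the canonical ones.  Matching is
        case-insensitive.

    Raises
    ------
    ValueError
        If a mandatory column is missing (the error names it) or a numeric
        cell fails to parse (the error names the row).
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    rename = {c: c.strip().lower() for c in df.columns}
    if column_map:
        lowered = {k.strip().lower(): v for k, v in column_map.items()}
        rename = {c: lowered.get(r, r) for c, r in rename.items()}
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    return [_coerce_row(row, i) for i, (_, row) in enumerate(df.iterrows())]


def write_population_table(records: Iterable[PopulationRecord], path, delimiter: str = ",") -> None:
    """Write records back to the canonical delimited format (round-trips)."""
    df = pd.DataFrame([vars(r) for r in records], columns=_MANDATORY + _OPTIONAL)
    df.to_csv(path, sep=delimiter, index=False)


def validate_record(r: PopulationRecord) -> list[Violation]:
    """Check every record invariant; returns one entry per failure.

    Validation reports rather than raises: inconsistent literature values are
    a finding, not a crash.  Integer-consistency of ``prop_mp * n_broods`` is
    reported as a violation only when the product is further than 0.51 from an
    integer (published proportions are rounded).
    """
    v: list[Violation] = []

    def bad(name: str, msg: str) -> None:
        v.append(Violation(name, msg))

    if r.clade not in CLADES:
        bad("clade", f"clade {r.clade!r} not in {sorted(CLADES)}")
    if r.technique not in TECHNIQUES:
        bad("technique", f"technique {r.technique!r} not in {sorted(TECHNIQUES)}")
    if r.mating_system not in MATING_SYSTEMS:
        bad("mating_system", f"mating_system {r.mating_system!r} not recognised")
    if r.n_broods < 1:
        bad("n_broods >= 1", f"n_broods = {r.n_broods}")
    if r.mean_brood_size < 1:
        bad("mean_brood_size >= 1", f"k̄ = {r.mean_brood_size}")
    if r.mean_n_sires < 1:
        bad("mean_n_sires >= 1", f"s̄ = {r.mean_n_sires}")
    if not 0.0 <= r.prop_mp <= 1.0:
        bad("0 <= prop_mp <= 1", f"p = {r.prop_mp}")
        return v  # remaining cross-checks assume a sane p
    # Each multiply-sired brood contributes at least one extra sire.
    if 1.0 + r.prop_mp > r.mean_n_sires + 1e-9:
        bad("1 + p <= s̄", f"1 + {r.prop_mp} = {1 + r.prop_mp} > s̄ = {r.mean_n_sires}")
    if r.mean_n_sires > r.mean_brood_size + 1e-9:
        bad("s̄ <= k̄", f"s̄ = {r.mean_n_sires} > k̄ = {r.mean_brood_size}")
    if r.prop_mp == 0.0 and r.mean_n_sires != 1.0:
        bad("p = 0 iff s̄ = 1", f"p = 0 but s̄ = {r.mean_n_sires}")
    if r.mean_n_sires == 1.0 and r.prop_mp != 0.0:
        bad("p = 0 iff s̄ = 1", f"s̄ = 1 but p = {r.prop_mp}")
    count = r.prop_mp * r.n_broods
    if abs(count - round(count)) >= 0.51:
        bad(
            "p * n integer-consistent",
            f"p*n = {count:.3f} is not within 0.51 of an integer",
        )
    if r.body_mass is not None and r.body_mass <= 0:
        bad("body_mass > 0", f"body_mass = {r.body_mass}")
    return v


def assign_brood_size_cluster(mean_brood_size: float) -> int:
    """Map a mean brood size onto the six-cluster partition (1-based).

    Values of at most 2.5 form cluster 1; greater than 6.5 form cluster 6;
    between those, integer-centred bins (2.5, 3.5], (3.5, 4.5], ...
    """
    k = float(mean_brood_size)
    if k < 1:
        raise ValueError(f"mean brood size must be >= 1, got {k}")
    for idx, (lo, hi) in enumerate(BROOD_SIZE_CLUSTERS, start=1):
        if lo < k <= hi:
            return idx
    return len(BROOD_SIZE_CLUSTERS)  # k > 6.5 handled by the open last bin


def pool_species(
    records: Sequence[PopulationRecord],
    strategy: str = "n_weighted",
) -> list[PopulationRecord]:
    """Collapse multiple populations of a species into one species record.

    With ``strategy="n_weighted"`` the summaries k̄, s̄, p are means weighted
    by the number of broods and ``n_broods`` sums; ``"unweighted"`` takes
    plain means and sums broods.  Single-population species pass through
    unchanged.  Categorical fields are taken from the first population; body
    mass is the mean of the non-missing values.
    """
    if strategy not in {"n_weighted", "unweighted"}:
        raise ValueError(f"unknown pooling strategy {strategy!r}")
    by_species: dict[str, list[PopulationRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_name, []).append(r)
    pooled: list[PopulationRecord] = []
    for species, group in by_species.items():
        if len(group) == 1:
            pooled.append(group[0])
            continue
        n_total = sum(r.n_broods for r in group)
        if strategy == "n_weighted":
            w = [r.n_broods / n_total for r in group]
        else:
            w = [1.0 / len(group)] * len(group)
        masses = [r.body_mass for r in group if r.body_mass is not None]
        pooled.append(
            replace(
                group[0],
                population_id=f"{species}/pooled",
                n_broods=n_total,
                mean_brood_size=sum(wi * r.mean_brood_size for wi, r in zip(w, group)),
                mean_n_sires=sum(wi * r.mean_n_sires for wi, r in zip(w, group)),
                prop_mp=sum(wi * r.prop_mp for wi, r in zip(w, group)),
                body_mass=sum(masses) / len(masses) if masses else None,
            )
        )
    return pooled
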