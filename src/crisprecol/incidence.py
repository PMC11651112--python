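"""Aggregate strain-level CRISPR annotations into taxon-level incidence.

CRISPR carriage is annotated per sequenced strain as an evidence level
from 0 (no array detected) to 4 (highest-confidence array).  A strain
counts as a CRISPR carrier when its best array reaches a minimum
evidence level (default 4, the highest confidence tier).  Species-level
CRISPR incidence is the proportion of carrier strains among the
sequenced strains of that species; genus-level incidence is the
*unweighted* arithmetic mean of the species-level incidences, so that
heavily sequenced species do not dominate their genus.

Taxon labels are matched case-sensitively after whitespace stripping;
no fuzzy matching is attempted.  Strains with an unknown evidence level
are treated as non-carriers (level 0) but still count in the
denominator.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "StrainAnnotation",
    "IncidenceMap",
    "species_incidence",
    "genus_incidence",
    "read_strain_table",
    "write_incidence_csv",
    "read_incidence_csv",
]

EVIDENCE_LEVELS = frozenset(range(5))


@dataclass(frozen=True)
class StrainAnnotation:
    """One sequenced strain with taxonomy and CRISPR evidence level.

    Parameters
    ----------
    strain_id : str
        Opaque identifier, unique within a table.
    species, genus : str
        Taxon labels; surrounding whitespace is stripped on construction.
    evidence_level : int
        Maximum evidence level of any CRISPR array detected in the
        strain, in {0, 1, 2, 3, 4}; 0 means no array detected.
    """

    strain_id: str
    species: str
    genus: str
    evidence_level: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_id", str(self.strain_id).strip())
        object.__setattr__(self, "species", str(self.species).strip())
        object.__setattr__(self, "genus", str(self.genus).strip())
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        if not self.species or not self.genus:
            raise ValueError(
                f"strain {self.strain_id!r}: species and genus must be non-empty"
            )
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise ValueError(
                f"strain {self.strain_id!r}: evidence_level must be in 0..4, "
                f"got {self.evidence_level!r}"
            )


@dataclass
class IncidenceMap:
    """Taxon label -> CRISPR incidence (a fraction in [0, 1]).

    Attributes
    ----------
    level : {"species", "genus"}
        Taxonomic level the values refer to.
    values : dict
        Taxon label -> incidence.
    support : dict
        Taxon label -> number of underlying records (strains for the
        species level, species for the genus level).
    """

    level: str
    values: dict[str, float] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("species", "genus"):
            raise ValueError(f"level must be 'species' or 'genus', got {self.level!r}")
        for taxon, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"incidence for {taxon!r} outside [0, 1]: {v}")
        for taxon, n in self.support.items():
            if n < 1:
                raise ValueError(f"support for {taxon!r} must be >= 1, got {n}")
        if set(self.values) != set(self.support):
            raise ValueError("values and support must cover the same taxa")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.values

    def __getitem__(self, taxon: str) -> float:
        return self.values[taxon]

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as columns ``taxon, level, incidence, support``."""
        taxa = sorted(self.values)
        return pd.DataFrame(
            {
                "taxon": taxa,
                "level": self.level,
                "incidence": [self.values[t] for t in taxa],
                "support": [self.support[t] for t in taxa],
            }
        )


def species_incidence(
    strains: Iterable[StrainAnnotation], min_evidence: int = 4
) -> IncidenceMap:
    """Fraction of CRISPR-carrying strains per species.

    A strain carries CRISPR when ``evidence_level >= min_evidence``.
    Incidence for a species is ``carriers / total strains`` of that
    species; support is the strain count.

    Raises
    ------
    ValueError
        If the input is empty, a strain_id occurs twice, or
        ``min_evidence`` is not in 1..4.
    """
    strains = list(strains)
    if not strains:
        raise ValueError("species_incidence requires at least one strain")
    if min_evidence not in (1, 2, 3, 4):
        raise ValueError(f"min_evidence must be in 1..4, got {min_evidence!r}")
    dup = [s for s, n in Counter(s.strain_id for s in strains).items() if n > 1]
    if dup:
        raise ValueError(f"duplicate strain_id(s): {sorted(dup)}")

    totals: Counter[str] = Counter()
    carriers: Counter[str] = Counter()
    for s in strains:
        totals[s.species] += 1
        if s.evidence_level >= min_evidence:
            carriers[s.species] += 1
    values = {sp: carriers[sp] / n for sp, n in totals.items()}
    return IncidenceMap(level="species", values=values, support=dict(totals))


def genus_incidence(
    species_map: IncidenceMap, species_to_genus: Mapping[str, str]
) -> IncidenceMap:
    """Unweighted mean of species-level incidences within each genus.

    Every species in ``species_map`` must have a genus assignment;
    support is the number of species per genus.

    Raises
    ------
    KeyError
        If a species has no genus assignment (the species is named in
        the message).
    """
    if species_map.level != "species":
        raise ValueError("genus_incidence expects a species-level IncidenceMap")
    lookup = {str(k).strip(): str(v).strip() for k, v in species_to_genus.items()}
    per_genus: dict[str, list[float]] = defaultdict(list)
    for sp, inc in species_map.values.items():
        if sp not in lookup:
            raise KeyError(f"species {sp!r} has no genus assignment")
        per_genus[lookup[sp]].append(inc)
    values = {g: sum(v) / len(v) for g, v in per_genus.items()}
    support = {g: len(v) for g, v in per_genus.items()}
    return IncidenceMap(level="genus", values=values, support=support)


def strains_species_to_genus(
    strains: Iterable[StrainAnnotation],
) -> dict[str, str]:
    """Extract the species -> genus mapping implied by a strain table."""
    mapping: dict[str, str] = {}
    for s in strains:
        prev = mapping.setdefault(s.species, s.genus)
        if prev != s.genus:
            raise ValueError(
                f"species {s.species!r} assigned to two genera: {prev!r}, {s.genus!r}"
            )
    return mapping


def read_strain_table(path: str | Path) -> list[StrainAnnotation]:
    """Read a strain annotation CSV with header ``strain_id,species,genus,evidence_level``.

    A missing evidence level is treated as 0 (no array detected).
    """
    df = pd.read_csv(path, dtype={"strain_id": str, "species": str, "genus": str})
    required = {"strain_id", "species", "genus", "evidence_level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    ev = pd.to_numeric(df["evidence_level"], errors="raise").fillna(0).astype(int)
    return [
        StrainAnnotation(row.strain_id, row.species, row.genus, int(level))
        for row, level in zip(df.itertuples(index=False), ev)
    ]


def write_incidence_csv(imap: IncidenceMap, path: str | Path) -> None:
    imap.to_frame().to_csv(path, index=False)


def read_incidence_csv(path: str | Path) -> IncidenceMap:
    """Read an incidence CSV as written by :func:`write_incidence_csv`."""
    df = pd.read_csv(path, dtype={"taxon": str, "level": str})
    levels = set(df["level"].unique())
    if len(levels) != 1:
        raise ValueError(f"{path}: expected a single taxonomic level, got {levels}")
    return IncidenceMap(
        level=levels.pop(),
        values=dict(zip(df["taxon"], df["incidence"].astype(float))),
        support=dict(zip(df["taxon"], df["support"].astype(int))),
    )
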