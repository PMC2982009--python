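"""Abundance matrices and their plumbing.

The universal currency of every analysis stage is a species x years table of
non-negative abundances over strictly consecutive years.  Empirical tables
hold integer counts; simulated tables may hold real values.  The on-disk
format is a wide CSV: first column the species label, remaining column
headers the (integer) years.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SpeciesProfile",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "species_profiles",
    "select_core",
    "ever_present",
]


class ValidationError(ValueError):
    """An abundance table violates a structural invariant."""


class AbundanceMatrix:
    """Species x consecutive-years table of non-negative abundances.

    Parameters
    ----------
    species_ids
        Unique species labels, one per row.
    years
        Strictly consecutive, increasing integer year labels, one per column.
    values
        Array of shape ``(n_species, n_years)``; every entry finite and >= 0.
    """

    __slots__ = ("species_ids", "years", "values")

    def __init__(
        self,
        species_ids: Sequence[str],
        years: Sequence[int],
        values: np.ndarray,
    ) -> None:
        species_ids = [str(s) for s in species_ids]
        years = [int(y) for y in years]
        values = np.asarray(values, dtype=float)

        if len(species_ids) == 0:
            raise ValidationError("abundance matrix needs at least one species")
        if len(set(species_ids)) != len(species_ids):
            dupes = sorted({s for s in species_ids if species_ids.count(s) > 1})
            raise ValidationError(f"duplicate species labels: {dupes}")
        if len(years) < 2:
            raise ValidationError("abundance matrix needs at least two years")
        diffs = np.diff(years)
        if np.any(diffs != 1):
            raise ValidationError(
                f"year labels must be consecutive and increasing, got {years}"
            )
        if values.shape != (len(species_ids), len(years)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(species_ids)} species x {len(years)} years"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance for species {species_ids[i]!r}, year {years[j]}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[i, j]} for species "
                f"{species_ids[i]!r}, year {years[j]}"
            )

        self.species_ids = species_ids
        self.years = years
        self.values = values

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: index = species, columns = years."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.species_ids, name="species"),
            columns=self.years,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceMatrix":
        return cls(list(frame.index), [int(c) for c in frame.columns], frame.to_numpy())

    def subset(self, species: Sequence[str]) -> "AbundanceMatrix":
        """Row subset preserving this matrix's species order."""
        wanted = set(species)
        missing = wanted - set(self.species_ids)
        if missing:
            raise KeyError(f"unknown species: {sorted(missing)}")
        keep = [i for i, s in enumerate(self.species_ids) if s in wanted]
        return AbundanceMatrix(
            [self.species_ids[i] for i in keep], self.years, self.values[keep]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.species_ids == other.species_ids
            and self.years == other.years
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceMatrix({self.n_species} species, years "
            f"{self.years[0]}..{self.years[-1]})"
        )


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species summary over all years of the series (zeros included).

    ``mean`` and ``sd`` (sample standard deviation, n-1 denominator)
    parameterize the AR(1) turnover simulator; ``occupancy`` is the fraction
    of years with positive abundance.
    """

    species_id: str
    mean: float
    sd: float
    occupancy: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValidationError("mean and sd must be non-negative")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy must lie in [0, 1]")


def read_abundance_table(source) -> AbundanceMatrix:
    """Read a wide CSV (first column species, remaining columns years).

    Year columns are normalized to ascending order; values are validated
    (non-negative, finite, consecutive years).
    """
    frame = pd.read_csv(source, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.index.name = "species"

    try:
        years = [int(c) for c in frame.columns]
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"column headers must be integer years: {exc}") from exc

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna() | frame.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric or missing value for species {frame.index[i]!r}, "
            f"year {years[j]}"
        )

    order = np.argsort(years)
    years = [years[k] for k in order]
    values = numeric.to_numpy()[:, order]
    return AbundanceMatrix(list(frame.index), years, values)


def write_abundance_table(matrix: AbundanceMatrix, sink) -> None:
    """Write the wide CSV; round-trips with :func:`read_abundance_table`.

    Integer-valued matrices (counts) are written as integers so the
    round-trip is bit-exact; real-valued (simulated) matrices use full
    ``repr`` precision.
    """
    frame = matrix.to_frame()
    if np.all(matrix.values == np.round(matrix.values)):
        frame = frame.astype(int)
    frame.to_csv(sink)


def species_profiles(matrix: AbundanceMatrix) -> list[SpeciesProfile]:
    """Per-species mean, sample s.d. and occupancy over all years."""
    if matrix.n_years < 2:
        raise ValidationError("species profiles need at least two years (sd undefined)")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    occs = (matrix.values > 0).mean(axis=1)
    return [
        SpeciesProfile(s, float(m), float(sd), float(o))
        for s, m, sd, o in zip(matrix.species_ids, means, sds, occs)
    ]


def select_core(
    matrix: AbundanceMatrix, occupancy_threshold: float = 0.5
) -> AbundanceMatrix:
    """Retain species present in a (strict) majority of years.

    A species is core when its occupancy is strictly greater than
    ``occupancy_threshold``; the default 0.5 selects species present in a
    majority of years.  The year set is unchanged.
    """
    if not 0 < occupancy_threshold <= 1:
        raise ValueError("occupancy_threshold must lie in (0, 1]")
    occ = (matrix.values > 0).mean(axis=1)
    keep = occ > occupancy_threshold
    if not keep.any():
        raise ValidationError(
            f"no species exceed occupancy {occupancy_threshold}; lower the threshold"
        )
    return AbundanceMatrix(
        [s for s, k in zip(matrix.species_ids, keep) if k],
        matrix.years,
        matrix.values[keep],
    )


def ever_present(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Convenience preset: the species present in every year (occupancy 1)."""
    occ = (matrix.values > 0).all(axis=1)
    if not occ.any():
        raise ValidationError("no species are present in every year")
    return AbundanceMatrix(
        [s for s, k in zip(matrix.species_ids, occ) if k],
        matrix.years,
        matrix.values[occ],
    )
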