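"""Core data containers and delimited-text readers.

Genetic data are population x allele count tables (the ``genpop`` role of
adegenet): one row per population, one pair of columns per biallelic locus
named ``<locus>.A`` / ``<locus>.B``, plus an implied per-population sample
size ``N`` (total alleles sampled, constant across loci).  Individual-level
tables (the ``genind`` role) carry per-individual allele dosages and can be
aggregated to the population table.  Environmental tables hold one climate
(baseline or changed) and must list populations in exactly the same order as
the genetic table -- row alignment is a hard contract, checked by
:func:`check_datasets`, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountTable",
    "IndividualAlleleTable",
    "EnvTable",
    "GeoTable",
    "AlignmentReport",
    "FormatError",
    "ValidationError",
    "load_counts_table",
    "write_counts_table",
    "load_env_table",
    "load_geo_table",
    "check_datasets",
    "counts_to_frequencies",
    "minor_alleles",
]


class FormatError(ValueError):
    """A delimited file does not follow the expected layout."""


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


def _split_locus_columns(columns: Iterable[str]) -> list[str]:
    """Return locus ids from paired ``<locus>.A``/``<locus>.B`` columns.

    Raises :class:`FormatError` on unpaired or unrecognised columns.
    """
    a_cols = []
    b_cols = []
    for c in columns:
        if c.endswith(".A"):
            a_cols.append(c[:-2])
        elif c.endswith(".B"):
            b_cols.append(c[:-2])
        else:
            raise FormatError(f"column {c!r} is not a '<locus>.A' or '<locus>.B' pair member")
    if set(a_cols) != set(b_cols):
        odd = sorted(set(a_cols) ^ set(b_cols))
        raise FormatError(f"unpaired allele columns for loci: {odd}")
    if len(a_cols) != len(set(a_cols)):
        raise FormatError("duplicated locus columns")
    return a_cols  # preserves file order of the .A columns


@dataclass
class AlleleCountTable:
    """Population x allele counts for biallelic loci.

    ``counts`` columns are ``<locus>.A`` / ``<locus>.B`` pairs; the index
    holds unique population ids.  ``N(p) = A + B`` must be identical across
    loci for each population (no missing genotypes).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = pd.DataFrame(self.counts)
        if counts.index.has_duplicates:
            raise ValidationError("population ids are not unique")
        loci = _split_locus_columns(counts.columns)
        # canonical column order: locus by locus, A before B
        counts = counts[[f"{l}.{al}" for l in loci for al in ("A", "B")]]
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("allele counts must be numeric")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError("allele counts must be finite and nonnegative")
        if np.any(arr != np.round(arr)):
            raise ValidationError("allele counts must be integers")
        counts = counts.astype(np.int64)
        self.counts = counts
        self._loci = loci
        n_ref = None
        for locus in loci:
            n = counts[f"{locus}.A"] + counts[f"{locus}.B"]
            if n_ref is None:
                n_ref = n
            else:
                bad = n_ref != n
                if bad.any():
                    pop = counts.index[bad.to_numpy().nonzero()[0][0]]
                    raise ValidationError(
                        f"allele counts of population {pop!r} at locus {locus!r} "
                        f"sum to {int(n[pop])}, expected N={int(n_ref[pop])}"
                    )
        assert n_ref is not None
        if (n_ref < 1).any():
            pop = counts.index[(n_ref < 1).to_numpy().nonzero()[0][0]]
            raise ValidationError(f"population {pop!r} has N < 1 alleles sampled")
        self._N = n_ref.rename("N")

    @property
    def population_ids(self) -> list:
        return list(self.counts.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self._loci)

    @property
    def N(self) -> pd.Series:
        """Total alleles sampled per population."""
        return self._N

    def allele_counts(self, locus: str, allele: str) -> pd.Series:
        return self.counts[f"{locus}.{allele}"]

    @classmethod
    def from_frequencies(cls, freq_a: pd.DataFrame, n: pd.Series) -> "AlleleCountTable":
        """Build a table from per-locus A-allele frequencies and sample sizes.

        Counts are rounded to the nearest integer; B receives the remainder.
        """
        cols = {}
        n = pd.Series(n, index=freq_a.index)
        for locus in freq_a.columns:
            a = np.round(freq_a[locus].to_numpy() * n.to_numpy()).astype(np.int64)
            cols[f"{locus}.A"] = a
            cols[f"{locus}.B"] = n.to_numpy().astype(np.int64) - a
        return cls(pd.DataFrame(cols, index=freq_a.index))


@dataclass
class IndividualAlleleTable:
    """Individual x allele dosages (the genind role).

    ``dosages`` columns are ``<locus>.A``/``<locus>.B`` pairs summing to
    ``ploidy`` per individual and locus; ``population_of`` maps each
    individual id to its population label.
    """

    dosages: pd.DataFrame
    population_of: pd.Series
    ploidy: int = 2

    def __post_init__(self) -> None:
        dosages = pd.DataFrame(self.dosages)
        loci = _split_locus_columns(dosages.columns)
        self.dosages = dosages[[f"{l}.{al}" for l in loci for al in ("A", "B")]].astype(np.int64)
        self._loci = loci
        self.population_of = pd.Series(self.population_of).reindex(self.dosages.index)
        if self.population_of.isna().any():
            missing = self.dosages.index[self.population_of.isna()][0]
            raise ValidationError(f"individual {missing!r} has no population assignment")
        for locus in loci:
            tot = self.dosages[f"{locus}.A"] + self.dosages[f"{locus}.B"]
            bad = tot != self.ploidy
            if bad.any():
                ind = self.dosages.index[bad.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"individual {ind!r} at locus {locus!r} has allele dosage "
                    f"{int(tot[ind])}, expected ploidy {self.ploidy}"
                )

    @property
    def individual_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self._loci)

    def to_population_table(self, population_order: list | None = None) -> AlleleCountTable:
        """Aggregate individuals to a population allele-count table."""
        grouped = self.dosages.groupby(self.population_of, sort=False).sum()
        if population_order is not None:
            grouped = grouped.reindex(population_order)
        return AlleleCountTable(grouped)

    def allele_matrix(self) -> pd.DataFrame:
        """Individual x allele dosage matrix (all .A/.B columns)."""
        return self.dosages.copy()


@dataclass
class EnvTable:
    """Population x environmental variables for one climate."""

    values: pd.DataFrame
    climate_tag: str = "baseline"

    def __post_init__(self) -> None:
        values = pd.DataFrame(self.values).astype(float)
        if values.isna().any().any():
            col = values.columns[values.isna().any().to_numpy().nonzero()[0][0]]
            raise ValidationError(f"environmental variable {col!r} contains missing values")
        if values.index.has_duplicates:
            raise ValidationError("population ids are not unique")
        self.values = values

    @property
    def population_ids(self) -> list:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeoTable:
    """Population longitude/latitude in decimal degrees."""

    coords: pd.DataFrame

    def __post_init__(self) -> None:
        coords = pd.DataFrame(self.coords)
        missing = [c for c in ("longitude", "latitude") if c not in coords.columns]
        if missing:
            raise FormatError(f"geographic table lacks columns {missing}")
        coords = coords[["longitude", "latitude"]].astype(float)
        if (coords["longitude"].abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        if (coords["latitude"].abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        self.coords = coords

    @property
    def population_ids(self) -> list:
        return list(self.coords.index)


# ---------------------------------------------------------------------------
# delimited readers / writers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _write_delimited(frame: pd.DataFrame, path: str | Path, index_label: str) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame.to_csv(path, sep=sep, index_label=index_label)


def _load_genalex(path: Path) -> AlleleCountTable:
    """Aggregate a GenAlEx-style codominant CSV to population counts.

    Layout: two metadata rows, then a header row (individual, population,
    one locus name spanning two allele columns), then one row per
    individual.  Allele labels per locus are ordered alphabetically; the
    first maps to ``.A``.
    """
    raw = pd.read_csv(path, header=None, skiprows=2, dtype=str)
    header = raw.iloc[0]
    body = raw.iloc[1:]
    locus_names = []
    for j in range(2, raw.shape[1], 2):
        name = header.iloc[j]
        if pd.isna(name) or not str(name).strip():
            raise FormatError(f"GenAlEx header misses a locus name in column {j}")
        locus_names.append(str(name).strip())
    if raw.shape[1] != 2 + 2 * len(locus_names):
        raise FormatError("GenAlEx file must carry two allele columns per locus")
    pops = body.iloc[:, 1].astype(str)
    rows: dict[str, dict[str, int]] = {}
    for j, locus in enumerate(locus_names):
        cols = body.iloc[:, [2 + 2 * j, 3 + 2 * j]]
        labels = sorted(set(cols.to_numpy().ravel().astype(str)))
        if len(labels) > 2:
            raise FormatError(f"locus {locus!r} has more than two allele labels: {labels}")
        allele_a = labels[0]
        for pop in pops.unique():
            sub = cols[pops.to_numpy() == pop].to_numpy().astype(str)
            rows.setdefault(pop, {})[f"{locus}.A"] = int((sub == allele_a).sum())
            rows[pop][f"{locus}.B"] = int((sub != allele_a).sum())
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "population"
    return AlleleCountTable(frame)


def load_counts_table(path: str | Path, dialect: str = "plain") -> AlleleCountTable:
    """Read an allele-count table from delimited text.

    ``plain``: first column population id, then ``<locus>.A``/``<locus>.B``
    column pairs.  ``genalex``: GenAlEx-style individual CSV aggregated to
    population counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain":
        return AlleleCountTable(_read_delimited(path))
    if dialect == "genalex":
        return _load_genalex(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_counts_table(table: AlleleCountTable, path: str | Path) -> None:
    _write_delimited(table.counts, path, index_label="population")


def load_env_table(path: str | Path, climate_tag: str = "baseline") -> EnvTable:
    return EnvTable(_read_delimited(path), climate_tag=climate_tag)


def load_geo_table(path: str | Path) -> GeoTable:
    return GeoTable(_read_delimited(path))


def load_individual_table(path: str | Path, ploidy: int = 2) -> IndividualAlleleTable:
    """Read an individual dosage table: first column individual id, then a
    ``population`` column, then ``<locus>.A``/``<locus>.B`` dosage pairs."""
    frame = _read_delimited(path)
    if "population" not in frame.columns:
        raise FormatError("individual table needs a 'population' column")
    pops = frame["population"]
    return IndividualAlleleTable(frame.drop(columns=["population"]), pops, ploidy=ploidy)


def write_individual_table(table: IndividualAlleleTable, path: str | Path) -> None:
    frame = table.dosages.copy()
    frame.insert(0, "population", table.population_of)
    _write_delimited(frame, path, index_label="individual")


# ---------------------------------------------------------------------------
# alignment & frequencies


@dataclass
class AlignmentReport:
    """Result of the population-sequence alignment check."""

    passed: bool
    mismatches: list[tuple[int, object, object]] = field(default_factory=list)
    missing_from_env: list = field(default_factory=list)
    missing_from_genetic: list = field(default_factory=list)

    def message(self) -> str:
        if self.passed:
            return "population sequences identical"
        parts = []
        if self.mismatches:
            i, g, e = self.mismatches[0]
            parts.append(f"first divergence at index {i}: genetic={g!r} vs env={e!r}")
        if self.missing_from_env:
            parts.append(f"missing from env: {self.missing_from_env}")
        if self.missing_from_genetic:
            parts.append(f"missing from genetic: {self.missing_from_genetic}")
        return "; ".join(parts)

    def raise_if_failed(self) -> None:
        if not self.passed:
            raise ValidationError(f"population sequences differ ({self.message()})")


def check_datasets(genetic: AlleleCountTable, env: EnvTable) -> AlignmentReport:
    """Check that genetic and environmental tables list the same populations
    in the same order (labels and order both part of the contract)."""
    g = genetic.population_ids
    e = env.population_ids
    if g == e:
        return AlignmentReport(passed=True)
    mism = [(i, a, b) for i, (a, b) in enumerate(zip(g, e)) if a != b]
    extra_g = min(len(g), len(e))
    mism += [(i, g[i], None) for i in range(extra_g, len(g))]
    mism += [(i, None, e[i]) for i in range(extra_g, len(e))]
    return AlignmentReport(
        passed=False,
        mismatches=mism,
        missing_from_env=sorted(set(g) - set(e)),
        missing_from_genetic=sorted(set(e) - set(g)),
    )


def minor_alleles(table: AlleleCountTable) -> Mapping[str, str]:
    """Per locus, the allele (A or B) with the smaller total count across
    populations; ties go to A."""
    out = {}
    for locus in table.locus_ids:
        tot_a = int(table.allele_counts(locus, "A").sum())
        tot_b = int(table.allele_counts(locus, "B").sum())
        out[locus] = "A" if tot_a <= tot_b else "B"
    return out


def counts_to_frequencies(table: AlleleCountTable, which: str = "minor") -> pd.DataFrame:
    """Population x locus allele frequencies.

    ``which`` selects the A allele, the B allele, or per-locus the minor
    allele (smaller summed count across populations, tie -> A).
    """
    if which not in {"A", "B", "minor"}:
        raise ValueError("which must be 'A', 'B' or 'minor'")
    minors = minor_alleles(table) if which == "minor" else None
    n = table.N.to_numpy().astype(float)
    data = {}
    for locus in table.locus_ids:
        allele = minors[locus] if minors else which
        data[locus] = table.allele_counts(locus, allele).to_numpy() / n
    return pd.DataFrame(data, index=table.counts.index)
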