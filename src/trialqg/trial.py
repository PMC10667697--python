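"""Trial data model: design description and tidy phenotype tables.

The canonical substrate for every analysis in this package is a *long*
(tidy) phenotype table with one row per plot measurement and the six
columns ``genotype, year, regime, block, trait, value``.  This mirrors
how multi-environment RCBD (randomized complete block design) trials
are recorded: every genotype appears once per block, blocks are nested
in irrigation regime, and the whole layout is repeated across years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import DataError, FormatError

REQUIRED_COLUMNS = ("genotype", "year", "regime", "block", "trait", "value")
KEY_COLUMNS = ("genotype", "year", "regime", "block", "trait")


@dataclass(frozen=True)
class TrialDesign:
    """Dimensions and factor levels of a multi-environment RCBD trial.

    Parameters
    ----------
    n_genotypes :
        Number of genotypes (accessions) ``g``; at least 2.
    n_blocks :
        Number of complete blocks (replicates) ``r`` per regime; at least 2.
    years, regimes, traits :
        Factor level labels.  ``regimes`` should include a control and at
        least one stress level for reduction statistics to be meaningful.
    """

    n_genotypes: int
    n_blocks: int
    years: tuple = ("2018", "2019")
    regimes: tuple = ("control", "drought")
    traits: tuple = ("FY",)

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("a trial needs at least 2 genotypes")
        if self.n_blocks < 2:
            raise ValueError("a trial needs at least 2 blocks")
        if not self.years or not self.regimes:
            raise ValueError("at least one year and one regime required")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("trait names must be unique")
        object.__setattr__(self, "years", tuple(str(y) for y in self.years))
        object.__setattr__(self, "regimes", tuple(self.regimes))
        object.__setattr__(self, "traits", tuple(self.traits))

    @property
    def genotype_labels(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    @property
    def block_labels(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_blocks)]

    def n_cells(self) -> int:
        return (
            self.n_genotypes
            * self.n_blocks
            * len(self.years)
            * len(self.regimes)
            * len(self.traits)
        )


@dataclass
class PhenotypeTable:
    """A validated tidy phenotype table plus its balance status.

    ``data`` always carries the six canonical columns; ``balanced`` is
    evaluated against ``design`` when one is supplied, otherwise against
    the full cross of the levels observed in the data.
    """

    data: pd.DataFrame
    design: TrialDesign | None = None
    balanced: bool = True
    missing_cells: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)
        self.balanced, self.missing_cells = _balance_status(self.data, self.design)
        if not self.balanced:
            preview = ", ".join(map(str, self.missing_cells[:5]))
            warnings.warn(
                f"phenotype table is unbalanced: {len(self.missing_cells)} "
                f"missing cell(s), e.g. {preview}",
                stacklevel=3,
            )

    # -- convenience -------------------------------------------------
    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def years(self) -> list[str]:
        return sorted(self.data["year"].unique())

    @property
    def regimes(self) -> list[str]:
        return sorted(self.data["regime"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def n_blocks(self) -> int:
        return self.data["block"].nunique()

    def subset(self, trait=None, year=None, regime=None) -> pd.DataFrame:
        """Rows matching the given factor levels (None = all)."""
        d = self.data
        if trait is not None:
            d = d[d["trait"] == trait]
        if year is not None:
            d = d[d["year"] == str(year)]
        if regime is not None:
            d = d[d["regime"] == regime]
        return d

    def genotype_means(self, regime=None, year=None) -> pd.DataFrame:
        """Genotype × trait matrix of means over blocks (and unfixed factors)."""
        d = self.data
        if regime is not None:
            d = d[d["regime"] == regime]
        if year is not None:
            d = d[d["year"] == str(year)]
        return d.pivot_table(
            index="genotype", columns="trait", values="value", aggfunc="mean"
        )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for c in KEY_COLUMNS:
        df[c] = df[c].astype(str)
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].iloc[0]
        raise DataError(
            f"non-numeric or missing value at key "
            f"{tuple(bad[list(KEY_COLUMNS)])!r}"
        )
    df["value"] = values.astype(float)
    dup = df.duplicated(list(KEY_COLUMNS), keep=False)
    if dup.any():
        key = tuple(df.loc[dup].iloc[0][list(KEY_COLUMNS)])
        raise DataError(f"duplicate observation for key {key!r}")
    return df.reset_index(drop=True)


def _balance_status(
    df: pd.DataFrame, design: TrialDesign | None
) -> tuple[bool, list[tuple]]:
    if design is not None:
        levels = [
            design.genotype_labels,
            [str(y) for y in design.years],
            list(design.regimes),
            design.block_labels,
            list(design.traits),
        ]
    else:
        levels = [sorted(df[c].unique()) for c in KEY_COLUMNS]
    expected = set(product(*levels))
    present = set(map(tuple, df[list(KEY_COLUMNS)].itertuples(index=False)))
    missing = sorted(expected - present)
    return (not missing, missing)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_phenotypes(
    path: str | Path,
    design: TrialDesign | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a long-format phenotype table from CSV or TSV.

    The header must declare the six canonical columns (order free).  The
    result is validated against the invariants of :class:`PhenotypeTable`;
    an unbalanced table loads with a warning listing missing cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    return PhenotypeTable(df, design=design)


def read_phenotypes_wide(
    path: str | Path,
    trait_columns: Sequence[str] | None = None,
    design: TrialDesign | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a wide table (one column per trait) and normalise to long form."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    id_cols = ["genotype", "year", "regime", "block"]
    missing = [c for c in id_cols if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c not in id_cols]
    long = df.melt(
        id_vars=id_cols, value_vars=list(trait_columns),
        var_name="trait", value_name="value",
    )
    return PhenotypeTable(long, design=design)


def write_phenotypes(table: PhenotypeTable, path: str | Path, sep: str | None = None) -> Path:
    """Write the canonical long-format CSV/TSV. Round-trips bit-exactly."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (design sizes, trait list, stage knobs)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config file must contain a mapping")
    return cfg
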