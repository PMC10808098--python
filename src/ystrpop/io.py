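"""Reading, validation and normalization of haplotype and rate tables.

The canonical on-disk layout is a UTF-8, tab-delimited table with header

    SampleID<TAB>Population<TAB><locus><TAB><locus>...

one row per individual, integer repeat counts, missing cells encoded by
an explicit sentinel (empty, ``NA``, ``na``, ``.`` or ``-``) — never 0,
which is not a possible repeat count. A column-mapping option
accommodates tables whose identifier columns are named differently.

Panel normalization applies the two standard conventions for diversity
work on Yfiler data: DYS385a/b are dropped (copies indistinguishable)
and DYS389II is replaced by DYS389II − DYS389I. Normalization is
recorded on the table and guarded against double application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParseError, StateError, ValidationError
from .loci import MAX_REPEAT, MIN_REPEAT, MULTICOPY, PANEL_15

logger = logging.getLogger(__name__)

#: Tokens accepted as "missing" in input cells.
MISSING_TOKENS = {"", "NA", "na", "N/A", ".", "-", "nan", "NaN"}

_ID_COL = "SampleID"
_POP_COL = "Population"


@dataclass
class HaplotypeTable:
    """Individuals × loci integer repeat counts, with population labels.

    Attributes
    ----------
    data : pandas.DataFrame
        Index = sample IDs; columns = ``Population`` followed by one
        nullable-integer (``Int64``) column per locus.
    panel : tuple of str
        Ordered locus names (the data columns).
    normalized : bool
        True once DYS389II has been adjusted and DYS385a/b dropped.
    """

    data: pd.DataFrame
    panel: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        missing_cols = [l for l in self.panel if l not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"panel loci absent from data: {missing_cols}")
        if _POP_COL not in self.data.columns:
            raise ValidationError("data must carry a Population column")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        if len(set(self.panel)) != len(self.panel):
            raise ValidationError("panel contains duplicate locus names")

    # ------------------------------------------------------------------
    # basic views
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def populations(self) -> pd.Series:
        """Population label per sample (index = sample ID)."""
        return self.data[_POP_COL]

    @property
    def population_names(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.data[_POP_COL]))

    def repeats(self) -> pd.DataFrame:
        """Locus columns only, nullable Int64."""
        return self.data[list(self.panel)]

    def matrix(self) -> np.ndarray:
        """Dense int array of repeat counts; raises if any value missing."""
        block = self.repeats()
        if block.isna().any().any():
            raise ValidationError(
                "table has missing repeat values; call filter_complete() first"
            )
        return block.to_numpy(dtype=np.int64)

    def for_population(self, population: str) -> "HaplotypeTable":
        """Sub-table restricted to one population label."""
        mask = self.data[_POP_COL] == population
        if not mask.any():
            raise ValidationError(f"no records for population {population!r}")
        return replace(self, data=self.data.loc[mask].copy())

    def copy(self) -> "HaplotypeTable":
        return replace(self, data=self.data.copy())

    # ------------------------------------------------------------------
    # normalization pipeline
    # ------------------------------------------------------------------
    def normalize(self) -> "HaplotypeTable":
        """Return a 15-locus normalized copy (see :func:`normalize_panel`)."""
        return normalize_panel(self)

    def complete(self) -> "HaplotypeTable":
        """Return only records with no missing loci (see :func:`filter_complete`)."""
        return filter_complete(self)

    def require_normalized(self, operation: str = "this operation") -> None:
        if not self.normalized:
            raise StateError(f"{operation} requires a normalized (15-locus) table")

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str, dict[str, int | None]]],
        panel: tuple[str, ...],
        normalized: bool = False,
    ) -> "HaplotypeTable":
        """Build a table from (sample_id, population, {locus: repeat}) triples."""
        rows = {}
        for sample_id, population, repeats in records:
            extra = set(repeats) - set(panel)
            if extra:
                raise ValidationError(
                    f"record {sample_id}: loci not in panel: {sorted(extra)}"
                )
            rows[sample_id] = {_POP_COL: population, **repeats}
        data = pd.DataFrame.from_dict(rows, orient="index")
        data.index.name = _ID_COL
        for locus in panel:
            if locus not in data.columns:
                data[locus] = pd.NA
            data[locus] = _validate_repeat_column(data[locus], locus)
        data = data[[_POP_COL, *panel]]
        return cls(data=data, panel=tuple(panel), normalized=normalized)

    @classmethod
    def from_arrays(
        cls,
        repeats: np.ndarray,
        panel: tuple[str, ...],
        populations,
        sample_ids=None,
        normalized: bool = True,
    ) -> "HaplotypeTable":
        """Build a complete table from an (n, L) integer array.

        Convenience constructor used by the simulator; ``normalized``
        defaults to True because simulated panels are 15-locus panels.
        """
        repeats = np.asarray(repeats)
        n = repeats.shape[0]
        if repeats.ndim != 2 or repeats.shape[1] != len(panel):
            raise ValidationError("repeats must be (n_samples, n_loci)")
        if sample_ids is None:
            sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        if isinstance(populations, str):
            populations = [populations] * n
        data = pd.DataFrame(repeats, columns=list(panel), index=list(sample_ids))
        data = data.astype("Int64")
        data.insert(0, _POP_COL, list(populations))
        data.index.name = _ID_COL
        return cls(data=data, panel=tuple(panel), normalized=normalized)

    # ------------------------------------------------------------------
    # io
    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        write_haplotype_table(self, path)


def _validate_repeat_column(col: pd.Series, locus: str) -> pd.Series:
    """Coerce a raw column to nullable Int64, rejecting out-of-range values."""
    col = col.astype("Int64")
    present = col.dropna()
    bad = present[(present < MIN_REPEAT) | (present > MAX_REPEAT)]
    if len(bad):
        raise ValidationError(
            f"locus {locus}: repeat counts outside [{MIN_REPEAT}, {MAX_REPEAT}] "
            f"for samples {list(bad.index)}"
        )
    return col


def read_haplotype_table(
    path,
    delimiter: str | None = None,
    sample_col: str = _ID_COL,
    population_col: str = _POP_COL,
    drop_intermediate: bool = False,
) -> HaplotypeTable:
    """Read a haplotype TSV/CSV into an un-normalized :class:`HaplotypeTable`.

    Parameters
    ----------
    path : path-like
        Header-first delimited text file.
    delimiter : str, optional
        Field delimiter; autodetected (tab, then comma) when omitted.
    sample_col, population_col : str
        Names of the identifier columns in the file; mapped onto the
        canonical ``SampleID``/``Population`` names.
    drop_intermediate : bool
        If True, records carrying intermediate (non-integer) alleles such
        as ``13.2`` are dropped with a warning instead of raising.

    Missing cells (``NA``, empty, ``.``, ``-``) are preserved as missing,
    never coerced to 0.
    """
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    raw.columns = [c.strip() for c in raw.columns]
    for col in (sample_col, population_col):
        if col not in raw.columns:
            raise ParseError(f"required column {col!r} missing from header")
    loci = tuple(c for c in raw.columns if c not in (sample_col, population_col))
    if not loci:
        raise ParseError("no locus columns found in header")

    parsed: dict[str, list[object]] = {l: [] for l in loci}
    keep_rows: list[bool] = []
    for row_idx, row in raw.iterrows():
        row_ok = True
        row_vals: dict[str, object] = {}
        for locus in loci:
            token = str(row[locus]).strip()
            if token in MISSING_TOKENS:
                row_vals[locus] = pd.NA
                continue
            try:
                value = int(token)
            except ValueError:
                msg = (
                    f"row {row_idx + 2} (sample {row[sample_col]!r}), column "
                    f"{locus}: non-integer repeat {token!r}"
                )
                if drop_intermediate:
                    logger.warning("%s — record dropped", msg)
                    row_ok = False
                    break
                raise ParseError(msg) from None
            row_vals[locus] = value
        keep_rows.append(row_ok)
        if row_ok:
            for locus in loci:
                parsed[locus].append(row_vals[locus])

    kept = raw.loc[keep_rows]
    data = pd.DataFrame(index=kept[sample_col].str.strip())
    data.index.name = _ID_COL
    data[_POP_COL] = kept[population_col].str.strip().to_numpy()
    for locus in loci:
        data[locus] = _validate_repeat_column(
            pd.Series(parsed[locus], index=data.index, dtype="object"), locus
        )
    if data.index.has_duplicates:
        dups = sorted(set(data.index[data.index.duplicated()]))
        raise ValidationError(f"duplicate sample IDs: {dups}")
    return HaplotypeTable(data=data, panel=loci, normalized=False)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    """Write the canonical tab-delimited layout (UTF-8, header first)."""
    out = table.data.copy()
    out.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")


def normalize_panel(table: HaplotypeTable) -> HaplotypeTable:
    """Apply the 15-locus panel conventions.

    DYS389II is replaced by DYS389II − DYS389I (the II amplicon contains
    the I stretch) and the indistinguishable DYS385a/b columns are
    dropped. Normalizing an already-normalized table is a state error;
    a record with DYS389II ≤ DYS389I is biologically impossible and
    rejected.
    """
    if table.normalized:
        raise StateError("table is already normalized")
    for required in ("DYS389I", "DYS389II"):
        if required not in table.panel:
            raise ValidationError(f"normalization requires column {required}")
    data = table.data.copy()
    both = data["DYS389I"].notna() & data["DYS389II"].notna()
    bad = data.loc[both & (data["DYS389II"] <= data["DYS389I"])]
    if len(bad):
        raise ValidationError(
            "DYS389II must exceed DYS389I (the II amplicon contains the I "
            f"stretch); violated by samples {list(bad.index)}"
        )
    adjusted = data["DYS389II"] - data["DYS389I"]
    # a record missing DYS389I cannot be adjusted: its DYS389II becomes missing
    adjusted[~both] = pd.NA
    data["DYS389II"] = adjusted.astype("Int64")
    drop = [l for l in MULTICOPY if l in data.columns]
    data = data.drop(columns=drop)
    panel = tuple(l for l in table.panel if l not in MULTICOPY)
    return HaplotypeTable(data=data, panel=panel, normalized=True)


def filter_complete(table: HaplotypeTable) -> HaplotypeTable:
    """Keep only records typed at every locus of the normalized panel.

    The input must be normalized; the original table is untouched. An
    all-incomplete input yields an empty table with a logged warning.
    """
    table.require_normalized("filter_complete")
    mask = table.repeats().notna().all(axis=1)
    if not mask.any():
        logger.warning("no complete haplotypes remain after filtering")
    return replace(table, data=table.data.loc[mask].copy())


@dataclass
class MutationRateTable:
    """Per-locus per-generation mutation rates with provenance.

    Rates are strictly positive; the table must cover every locus of the
    panel it is used with for dating (checked at use time by
    :meth:`for_panel`).
    """

    rates: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        for locus, rate in self.rates.items():
            if not np.isfinite(rate) or rate <= 0:
                raise ValidationError(
                    f"mutation rate for {locus} must be strictly positive, got {rate}"
                )

    def for_panel(self, panel) -> np.ndarray:
        """Rate vector ordered like ``panel``; missing locus → LookupError."""
        missing = [l for l in panel if l not in self.rates]
        if missing:
            raise LookupError(f"no mutation rate for loci: {missing}")
        return np.array([self.rates[l] for l in panel], dtype=float)

    @property
    def total(self) -> float:
        return float(sum(self.rates.values()))

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Locus\tRate\n")
            for locus, rate in self.rates.items():
                fh.write(f"{locus}\t{rate:.6g}\n")


def read_mutation_rates(path, source_label: str | None = None) -> MutationRateTable:
    """Read a two-column ``locus<TAB>rate`` file (header optional)."""
    rates: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t" if "\t" in line else None)
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected 'locus rate', got {line!r}")
            locus, token = parts[0].strip(), parts[1].strip()
            if lineno == 1 and locus.lower() in {"locus", "marker"}:
                continue
            try:
                rate = float(token)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric rate {token!r} for {locus}"
                ) from None
            if locus in rates:
                raise ValidationError(f"duplicate rate for locus {locus}")
            rates[locus] = rate
    if source_label is None:
        source_label = f"read from {path}"
    return MutationRateTable(rates=rates, source_label=source_label)


__all__ = [
    "HaplotypeTable",
    "MutationRateTable",
    "read_haplotype_table",
    "write_haplotype_table",
    "normalize_panel",
    "filter_complete",
    "read_mutation_rates",
    "MISSING_TOKENS",
    "PANEL_15",
]
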