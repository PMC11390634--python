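"""Readers and writers for GWAS summary statistics and pipeline artifacts.

All tabular artifacts are plain TSV (optionally gzipped, by file extension);
configuration files (drug-class → gene map, outcome panel, column maps) are
YAML.  Summary statistics are held in memory as :class:`pandas.DataFrame`
objects with a fixed canonical column set; column names on disk are mapped
through a *dialect* (a ``canonical field -> file column`` mapping), with
shipped presets for a canonical dialect and a FinnGen-like dialect
(``rsids``/``#chrom``/``alt``/``ref``/``af_alt``/``beta``/``sebeta``/``pval``).

Genomic coordinates are 1-based inclusive in memory regardless of the on-disk
convention; BED gene-region input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical column order of an in-memory summary-statistic table
SUMSTAT_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
#: fields that must be present and non-missing in every row
REQUIRED_FIELDS = tuple(f for f in SUMSTAT_FIELDS if f != "eaf")
#: numeric fields (coerced and checked row-wise on read)
_NUMERIC_FIELDS = ("pos", "eaf", "beta", "se", "pval", "n")

CANONICAL_DIALECT: dict[str, str] = {f: f for f in SUMSTAT_FIELDS}
FINNGEN_DIALECT: dict[str, str] = {
    "variant_id": "rsids",
    "chrom": "#chrom",
    "pos": "pos",
    "effect_allele": "alt",
    "other_allele": "ref",
    "eaf": "af_alt",
    "beta": "beta",
    "se": "sebeta",
    "pval": "pval",
    "n": "n",
}
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": CANONICAL_DIALECT,
    "finngen": FINNGEN_DIALECT,
}

#: stable column order of a results table (one row per drug-class x outcome)
RESULT_COLUMNS = (
    "class",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "q_pval",
    "egger_intercept_pval",
    "presso_global_pval",
    "steiger_direction",
    "steiger_pval",
    "tier",
)

_FLOAT_FMT = "%.12g"


class SumstatsFormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class SumstatsValidationError(ValueError):
    """A row violates a summary-statistic invariant (e.g. se <= 0)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the effect per unit of trait on the effect-allele dose scale
    (exposure: per 1 mmHg SBP increase; binary outcomes: log odds per unit
    exposure).  ``eaf`` may be ``None`` on outcome tables that do not report
    allele frequency.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene footprint, 1-based inclusive coordinates."""

    gene_symbol: str
    chrom: str
    start: int
    end: int


def _resolve_dialect(column_map: str | Mapping[str, str] | None) -> dict[str, str]:
    if column_map is None:
        return dict(CANONICAL_DIALECT)
    if isinstance(column_map, str):
        try:
            return dict(DIALECTS[column_map])
        except KeyError:
            raise SumstatsFormatError(
                f"unknown dialect {column_map!r}; known: {sorted(DIALECTS)}"
            ) from None
    return dict(column_map)


def validate_sumstats(df: pd.DataFrame, *, source: str = "<table>") -> pd.DataFrame:
    """Validate (and normalise) a canonical summary-statistic frame in place.

    Alleles are upper-cased; every invariant of :class:`SummaryStatRecord`
    is checked.  ``eaf`` may be missing (NaN) but, where present, must lie
    strictly in (0, 1).  Raises :class:`SumstatsValidationError` naming the
    first offending row (1-based data-row number).
    """
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    def _fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            i = int(np.flatnonzero(mask.to_numpy())[0])
            vid = df["variant_id"].iloc[i]
            raise SumstatsValidationError(
                f"{source}: row {i + 1} ({vid}): {message}"
            )

    for col in REQUIRED_FIELDS:
        _fail(df[col].isna(), f"missing value in required column {col!r}")
    _fail(~df["effect_allele"].isin(VALID_ALLELES), "effect_allele not one of A/C/G/T")
    _fail(~df["other_allele"].isin(VALID_ALLELES), "other_allele not one of A/C/G/T")
    _fail(df["effect_allele"] == df["other_allele"], "effect_allele == other_allele")
    _fail(df["pos"] < 1, "pos < 1")
    _fail(df["se"] <= 0, "se <= 0")
    _fail((df["pval"] <= 0) | (df["pval"] > 1), "pval outside (0, 1]")
    _fail(df["n"] <= 0, "n <= 0")
    eaf = df["eaf"]
    _fail(eaf.notna() & ((eaf <= 0) | (eaf >= 1)), "eaf outside (0, 1)")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_sumstats(
    path: str | Path,
    column_map: str | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV into the canonical frame.

    Parameters
    ----------
    path
        TSV file, optionally gzip-compressed (``.gz``).
    column_map
        Dialect name (``"canonical"``, ``"finngen"``) or an explicit mapping
        of canonical field name to file column name.  ``eaf`` may be omitted
        from the mapping / file; it is then NaN in memory.

    Row order is preserved; alleles are upper-cased; unknown extra columns are
    ignored with a logged warning.
    """
    path = Path(path)
    dialect = _resolve_dialect(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [
        f for f in REQUIRED_FIELDS
        if dialect.get(f) is None or dialect[f] not in raw.columns
    ]
    if missing:
        raise SumstatsFormatError(
            f"{path}: missing required column(s) "
            + ", ".join(f"{f!r} (mapped to {dialect.get(f)!r})" for f in missing)
        )
    mapped_cols = {dialect[f] for f in SUMSTAT_FIELDS if dialect.get(f) in raw.columns}
    extra = [c for c in raw.columns if c not in mapped_cols]
    if extra:
        logger.warning("%s: ignoring unmapped column(s): %s", path, ", ".join(extra))

    df = pd.DataFrame(index=raw.index)
    for field in SUMSTAT_FIELDS:
        col = dialect.get(field)
        if col is not None and col in raw.columns:
            df[field] = raw[col]
        elif field == "eaf":
            df[field] = np.nan
        else:  # pragma: no cover - guarded above
            raise SumstatsFormatError(f"{path}: missing required column {field!r}")

    # numeric coercion with row-level diagnostics (header is line 1)
    for field in _NUMERIC_FIELDS:
        original = df[field]
        coerced = pd.to_numeric(original, errors="coerce")
        bad = coerced.isna() & pd.Series(original).notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SumstatsFormatError(
                f"{path}: line {i + 2}: non-numeric value {original.iloc[i]!r} "
                f"in column {field!r}"
            )
        df[field] = coerced

    df = validate_sumstats(df, source=str(path))
    logger.info("%s: read %d records", path, len(df))
    return df.reset_index(drop=True)


def write_sumstats(
    df: pd.DataFrame,
    path: str | Path,
    column_map: str | Mapping[str, str] | None = None,
) -> None:
    """Write a canonical summary-statistic frame as TSV in the given dialect."""
    dialect = _resolve_dialect(column_map)
    out = df.loc[:, list(SUMSTAT_FIELDS)].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def iter_records(df: pd.DataFrame) -> Iterable[SummaryStatRecord]:
    """Yield rows of a canonical frame as :class:`SummaryStatRecord`."""
    for row in df.itertuples(index=False):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        yield SummaryStatRecord(
            variant_id=str(row.variant_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            eaf=eaf,
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=float(row.n),
        )


# ---------------------------------------------------------------------------
# gene regions


def read_gene_regions(path: str | Path, dialect: str = "bed") -> pd.DataFrame:
    """Read gene regions as a frame (gene_symbol, chrom, start, end).

    ``dialect="bed"``: 4-column headerless BED (chrom, start, end, name),
    0-based half-open on disk, converted to 1-based inclusive.
    ``dialect="tsv"``: 4-column TSV with header (chrom, start, end,
    gene_symbol), already 1-based inclusive.
    """
    path = Path(path)
    if dialect == "bed":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "gene_symbol"],
            dtype={"chrom": str, "gene_symbol": str},
        )
        df["start"] = df["start"].astype(np.int64) + 1  # 0-based -> 1-based
        df["end"] = df["end"].astype(np.int64)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_symbol": str})
        required = {"chrom", "start", "end", "gene_symbol"}
        if not required.issubset(df.columns):
            raise SumstatsFormatError(
                f"{path}: gene-region TSV needs columns {sorted(required)}"
            )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    else:
        raise SumstatsFormatError(f"unknown gene-region dialect {dialect!r}")

    bad = df["start"] > df["end"]
    if bad.any():
        sym = df.loc[bad, "gene_symbol"].iloc[0]
        raise SumstatsValidationError(f"{path}: region {sym}: start > end")
    dup = df["gene_symbol"][df["gene_symbol"].duplicated()].unique()
    if len(dup):
        raise SumstatsValidationError(
            f"{path}: duplicate gene_symbol(s): {', '.join(sorted(dup))}"
        )
    out = df.loc[:, ["gene_symbol", "chrom", "start", "end"]].reset_index(drop=True)
    logger.info("%s: read %d gene regions", path, len(out))
    return out


def write_gene_regions(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write gene regions in the given dialect (see :func:`read_gene_regions`)."""
    if dialect == "tsv":
        df.loc[:, ["chrom", "start", "end", "gene_symbol"]].to_csv(
            path, sep="\t", index=False
        )
    elif dialect == "bed":
        out = df.loc[:, ["chrom", "start", "end", "gene_symbol"]].copy()
        out["start"] = out["start"] - 1
        out.to_csv(path, sep="\t", index=False, header=False)
    else:
        raise SumstatsFormatError(f"unknown gene-region dialect {dialect!r}")


# ---------------------------------------------------------------------------
# LD table


class LDTable:
    """Symmetric lookup of pairwise r² between variants.

    Pairs absent from the table have *unknown* LD; selection logic treats
    unknown pairs as unlinked (r² = 0) and a self pair as r² = 1.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._adj: dict[str, dict[str, float]] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise SumstatsValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            if r2 != 1.0:
                raise SumstatsValidationError(f"r2({a},{a}) must be 1, got {r2}")
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float | None:
        """r² for a pair, 1.0 for a self pair, ``None`` if unknown."""
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b)

    def neighbors(self, a: str) -> dict[str, float]:
        """All variants with a known r² to ``a`` (possibly empty)."""
        return dict(self._adj.get(a, {}))

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (a, b, r2)
            for a, nbrs in self._adj.items()
            for b, r2 in nbrs.items()
            if a < b
        )
        return pd.DataFrame(rows, columns=["variant_id_a", "variant_id_b", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDTable":
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(row.variant_id_a), str(row.variant_id_b), float(row.r2))
        return table


def read_ld_table(path: str | Path) -> LDTable:
    """Read a 3-column TSV (variant_id_a, variant_id_b, r2) with header."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id_a": str, "variant_id_b": str})
    required = {"variant_id_a", "variant_id_b", "r2"}
    if not required.issubset(df.columns):
        raise SumstatsFormatError(f"{path}: LD table needs columns {sorted(required)}")
    table = LDTable.from_frame(df)
    logger.info("%s: read %d LD pairs", path, len(table))
    return table


def write_ld_table(table: LDTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# blocklist and configs


def read_blocklist(path: str | Path) -> pd.DataFrame:
    """Read a confounder blocklist: 2-column TSV (variant_id, confounder)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "confounder"}
    if not required.issubset(df.columns):
        raise SumstatsFormatError(f"{path}: blocklist needs columns {sorted(required)}")
    return df.loc[:, ["variant_id", "confounder"]]


def read_drug_classes(path: str | Path | None = None) -> dict[str, list[str]]:
    """Drug-class → target-gene map from YAML (shipped default if no path).

    The shipped map covers the twelve antihypertensive classes of the British
    National Formulary with DrugBank-style target genes.
    """
    if path is None:
        from importlib.resources import files

        text = files("dtmr.data").joinpath("drug_classes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SumstatsFormatError("drug-class map must be a YAML mapping")
    classes: dict[str, list[str]] = {}
    for name, genes in raw.items():
        if not genes:
            raise SumstatsValidationError(f"drug class {name!r} has no target genes")
        classes[str(name)] = [str(g) for g in genes]
    return classes


def read_outcome_panel(path: str | Path | None = None) -> dict[str, str | None]:
    """Outcome panel from YAML: list of names, or mapping name → sumstat path."""
    if path is None:
        from importlib.resources import files

        text = files("dtmr.data").joinpath("outcome_panel.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if isinstance(raw, Mapping):
        return {str(k): (None if v is None else str(v)) for k, v in raw.items()}
    if isinstance(raw, list):
        return {str(name): None for name in raw}
    raise SumstatsFormatError("outcome panel must be a YAML list or mapping")


# ---------------------------------------------------------------------------
# results


def write_results(rows: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write scan results as TSV with the stable :data:`RESULT_COLUMNS` order.

    ``rows`` may be a frame, an iterable of mappings, or objects exposing
    ``to_row()``.  Floats survive a round trip to 10 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in rows]
        df = pd.DataFrame(dicts, columns=list(RESULT_COLUMNS))
    df = df.reindex(columns=list(RESULT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back with :data:`RESULT_COLUMNS` columns."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "class": str,
            "outcome": str,
            "method": str,
            "steiger_direction": str,
            "tier": str,
        },
    )
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SumstatsFormatError(f"{path}: missing result column(s) {sorted(missing)}")
    return df.loc[:, list(RESULT_COLUMNS)]
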