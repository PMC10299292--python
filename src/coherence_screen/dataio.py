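"""Plain tab-delimited I/O for expression matrices, phenotype tables, and
result tables, with validation on ingest.

All files are UTF-8 TSV with '.' decimal separators.  Lines starting with
``#`` are provenance comments and are ignored on read.  Ingest never silently
drops rows: every rejection raises a named error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Case-insensitive aliases for phenotype group labels (GEO-style tables vary).
GROUP_ALIASES: Mapping[str, str] = {
    "case": "case",
    "ad": "case",
    "patient": "case",
    "disease": "case",
    "control": "control",
    "normal": "control",
    "healthy": "control",
}

SEVERITY_ALIASES: Mapping[str, str] = {
    "incipient": "mild",
    "mild": "mild",
    "moderate": "moderate",
    "severe": "severe",
}

PHENOTYPE_COLUMNS = ("sample_id", "group", "severity", "mmse", "nft")


class DataIOError(ValueError):
    """Raised for any ingest/validation failure in this module."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2 expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.ndim != 2:
            raise DataIOError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataIOError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataIOError(
                f"non-finite expression value at gene "
                f"'{self.gene_ids[bad[0]]}', sample '{self.sample_ids[bad[1]]}'"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise DataIOError(f"gene '{gene_id}' not present in matrix") from None

    def gene_values(self, gene_id: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Expression vector of one gene over ``sample_ids`` (default: all)."""
        row = self.values[self.gene_index(gene_id)]
        if sample_ids is None:
            return row.copy()
        idx = [self._sample_index(s) for s in sample_ids]
        return row[idx]

    def subset(
        self,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        genes = list(gene_ids) if gene_ids is not None else self.gene_ids
        samples = list(sample_ids) if sample_ids is not None else self.sample_ids
        gi = [self.gene_index(g) for g in genes]
        si = [self._sample_index(s) for s in samples]
        return ExpressionMatrix(genes, samples, self.values[np.ix_(gi, si)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def _sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DataIOError(f"sample '{sample_id}' not present in matrix") from None


@dataclass
class PhenotypeTable:
    """Per-sample phenotype: group label plus optional severity/MMSE/NFT."""

    sample_ids: list[str]
    group: list[str]
    severity: list[str | None] = field(default_factory=list)
    mmse: list[float | None] = field(default_factory=list)
    nft: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        if not self.severity:
            self.severity = [None] * n
        if not self.mmse:
            self.mmse = [None] * n
        if not self.nft:
            self.nft = [None] * n
        for name, col in (("group", self.group), ("severity", self.severity),
                          ("mmse", self.mmse), ("nft", self.nft)):
            if len(col) != n:
                raise DataIOError(f"phenotype column '{name}' has length "
                                  f"{len(col)}, expected {n}")
        self.group = [_canonical_group(g) for g in self.group]
        self.severity = [_canonical_severity(s) for s in self.severity]
        for s, v in zip(self.sample_ids, self.mmse):
            if v is not None and not (0.0 <= v <= 30.0):
                raise DataIOError(f"MMSE {v} for sample '{s}' outside [0, 30]")
        for s, v in zip(self.sample_ids, self.nft):
            if v is not None and v < 0.0:
                raise DataIOError(f"NFT {v} for sample '{s}' is negative")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == group]

    @property
    def case_ids(self) -> list[str]:
        return self.samples_in_group("case")

    @property
    def control_ids(self) -> list[str]:
        return self.samples_in_group("control")

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.sample_ids, self.group))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise DataIOError(f"samples missing from phenotype table: {missing[:5]}")
        return np.array([lut[s] for s in sample_ids])

    def score_for(self, sample_ids: Sequence[str], endpoint: str) -> np.ndarray:
        """Clinical score values (NaN where absent) for the given endpoint."""
        if endpoint not in ("mmse", "nft"):
            raise DataIOError(f"unknown clinical endpoint '{endpoint}'")
        col = self.mmse if endpoint == "mmse" else self.nft
        lut = dict(zip(self.sample_ids, col))
        return np.array([np.nan if lut[s] is None else float(lut[s])
                         for s in sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "group": self.group,
            "severity": [s if s is not None else "" for s in self.severity],
            "mmse": [v if v is not None else np.nan for v in self.mmse],
            "nft": [v if v is not None else np.nan for v in self.nft],
        })


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise DataIOError(f"duplicate {kind} identifiers: {sorted(set(dupes))}")


def _canonical_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in GROUP_ALIASES:
        raise DataIOError(
            f"unknown group label '{label}' (accepted: {sorted(GROUP_ALIASES)})"
        )
    return GROUP_ALIASES[key]


def _canonical_severity(label: str | None) -> str | None:
    if label is None:
        return None
    key = str(label).strip().lower()
    if key in ("", "na", "nan", "none"):
        return None
    if key not in SEVERITY_ALIASES:
        raise DataIOError(
            f"unknown severity label '{label}' (accepted: {sorted(SEVERITY_ALIASES)})"
        )
    return SEVERITY_ALIASES[key]


def _provenance_header(seed: int | None = None) -> str:
    from coherence_screen import __version__

    parts = [f"# coherence-screen v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression(path: str | Path, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    Missing values are rejected unless ``impute_missing`` is set, in which
    case each missing cell is replaced by its row median (logged).
    """
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"expression file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataIOError(f"expression file is empty: {path}") from None
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise DataIOError(f"expression file has no data rows/columns: {path}")
    _check_unique(list(df.index.astype(str)), "gene")
    _check_unique(list(df.columns.astype(str)), "sample")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's strtod is correctly rounded -> exact round trips
            values[:, j] = df[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & ~df[col].isna()
            gene = df.index[bad.argmax()] if bad.any() else df.index[0]
            raise DataIOError(
                f"non-numeric expression value at gene '{gene}', sample '{col}'"
            ) from None
    if np.isnan(values).any():
        if not impute_missing:
            gi, sj = np.argwhere(np.isnan(values))[0]
            raise DataIOError(
                f"missing expression value at gene '{df.index[gi]}', "
                f"sample '{df.columns[sj]}' (pass impute_missing=True to "
                f"impute row medians)"
            )
        n_missing = int(np.isnan(values).sum())
        row_med = np.nanmedian(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), row_med, values)
        logger.info("imputed %d missing cells with row medians", n_missing)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, seed: int | None = None
) -> Path:
    """Write a matrix as TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# phenotype table I/O


def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample_id, group[, severity, mmse, nft]."""
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"phenotype file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataIOError(f"phenotype file is empty: {path}") from None
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample_id", "group"):
        if required not in cols:
            raise DataIOError(f"phenotype file missing column '{required}'")

    def _num(colname: str) -> list[float | None]:
        if colname not in cols:
            return []
        parsed = pd.to_numeric(df[cols[colname]], errors="coerce")
        raw_na = df[cols[colname]].isna() | df[cols[colname]].astype(str).str.strip().isin(
            ["", "na", "NA", "NaN", "nan"]
        )
        bad = parsed.isna() & ~raw_na
        if bad.any():
            sample = df[cols["sample_id"]][bad.argmax()]
            raise DataIOError(
                f"non-numeric {colname} value for sample '{sample}'"
            )
        return [None if pd.isna(v) else float(v) for v in parsed]

    return PhenotypeTable(
        sample_ids=list(df[cols["sample_id"]].astype(str)),
        group=list(df[cols["group"]].astype(str)),
        severity=(
            [None if pd.isna(v) else str(v) for v in df[cols["severity"]]]
            if "severity" in cols else []
        ),
        mmse=_num("mmse"),
        nft=_num("nft"),
    )


def write_phenotype(
    table: PhenotypeTable, path: str | Path, seed: int | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")
    return path


def write_table(
    records: Iterable[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
    seed: int | None = None,
) -> Path:
    """Serialize result records (DEGs, frequencies, fits, CV AUCs) as TSV.

    Column order is ``columns`` if given, otherwise the order of keys in the
    first record; stable across runs.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if columns is not None:
        df = df.reindex(columns=list(columns))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_table`."""
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")
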