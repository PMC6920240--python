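"""Readers and writers for the pipeline's external formats.

All tabular formats are plain delimited text. Genomic coordinates are
stored 0-based half-open (BED convention) internally regardless of the
input dialect; gene identity is by upper-cased symbol, with Entrez IDs
carried as advisory metadata only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tfsigkit")


class ConfigurationError(ValueError):
    """A reader or operation was configured inconsistently."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class Direction(str, Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class GeneId:
    """A gene identified by its (upper-cased) symbol.

    Equality and hashing use the normalized symbol only; the optional
    Entrez ID travels along but never participates in matching.
    """

    symbol: str
    entrez: int | None = None

    def __post_init__(self):
        sym = self.symbol.strip().upper()
        if not sym:
            raise ValidationError("gene symbol is empty")
        if self.entrez is not None and self.entrez < 1:
            raise ValidationError(f"Entrez ID must be >= 1, got {self.entrez}")
        object.__setattr__(self, "symbol", sym)

    def __eq__(self, other):
        if not isinstance(other, GeneId):
            return NotImplemented
        return self.symbol == other.symbol

    def __hash__(self):
        return hash(self.symbol)


@dataclass(frozen=True)
class SignatureRecord:
    gene: GeneId
    direction: Direction
    injury: bool


@dataclass
class SignatureTable:
    """A directional, injury-annotated gene list.

    ``d_up`` / ``d_down`` are the per-direction sizes (the D of the
    representation-factor statistic).
    """

    records: list[SignatureRecord]

    def __post_init__(self):
        seen: set[str] = set()
        dups: list[str] = []
        for rec in self.records:
            if rec.gene.symbol in seen:
                dups.append(rec.gene.symbol)
            seen.add(rec.gene.symbol)
        if dups:
            raise ValidationError(f"duplicate genes in signature: {sorted(set(dups))}")

    def __len__(self):
        return len(self.records)

    @property
    def d_up(self) -> int:
        return sum(1 for r in self.records if r.direction is Direction.UP)

    @property
    def d_down(self) -> int:
        return sum(1 for r in self.records if r.direction is Direction.DOWN)

    @property
    def genes(self) -> list[GeneId]:
        return [r.gene for r in self.records]

    def symbols(self, direction: Direction | None = None) -> set[str]:
        return {
            r.gene.symbol
            for r in self.records
            if direction is None or r.direction is direction
        }

    def injury_symbols(self) -> set[str]:
        return {r.gene.symbol for r in self.records if r.injury}

    def __getitem__(self, symbol: str) -> SignatureRecord:
        for r in self.records:
            if r.gene.symbol == symbol.upper():
                return r
        raise KeyError(symbol)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[GeneId, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    @property
    def member_symbols(self) -> set[str]:
        return {g.symbol for g in self.members}


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style).

    For TF-target databases the set id encodes the TF plus an experiment
    label, delimiter-separated; :meth:`tf_of` recovers the TF symbol.
    """

    sets: list[GeneSet]
    tf_delimiter: str = "_"

    def __post_init__(self):
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate set ids: {dup}")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def tf_of(self, set_id: str) -> str:
        """TF symbol encoded in a target-database set id (leading field)."""
        return set_id.split(self.tf_delimiter, 1)[0].upper()

    def union_symbols(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.member_symbols
        return out


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    intensity: float
    study_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.intensity < 0:
            raise ValidationError(f"negative intensity {self.intensity}")
        if not self.study_id:
            raise ValidationError("study_id is empty")


@dataclass
class PeakSet:
    """ChIP-seq peaks from one study; coordinates 0-based half-open."""

    peaks: list[Peak]
    study_id: str

    def __post_init__(self):
        for p in self.peaks:
            if p.study_id != self.study_id:
                raise ValidationError(
                    f"peak study_id {p.study_id!r} != set study_id {self.study_id!r}"
                )

    def __len__(self):
        return len(self.peaks)


@dataclass(frozen=True)
class GeneAnnotation:
    gene: GeneId
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty/inverted gene interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneAnnotationTable:
    records: list[GeneAnnotation]

    def __post_init__(self):
        syms = [r.gene.symbol for r in self.records]
        if len(syms) != len(set(syms)):
            dup = sorted({s for s in syms if syms.count(s) > 1})
            raise ValidationError(f"multiple annotation records for genes: {dup}")
        self._by_symbol = {r.gene.symbol: r for r in self.records}

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self._by_symbol

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        return self._by_symbol[symbol.upper()]


CT_MIN, CT_MAX = 0.0, 45.0
MISSING_CT_TOKENS = {"undetermined", "na", "nan", ""}


@dataclass
class CtMatrix:
    """qPCR cycle-threshold values, samples x assays, with factorial metadata.

    ``values`` holds Ct in cycles with NaN for undetermined reactions.
    ``metadata`` is indexed by sample with columns genotype (WT/KO),
    treatment (PBS/DCVC) and timepoint. ``roles`` maps each assay to
    "target_gene" or "housekeeping".
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self):
        v = self.values
        bad = v[(v < CT_MIN) | (v > CT_MAX)]
        n_bad = int(bad.notna().sum().sum())
        if n_bad:
            logger.warning("masking %d Ct values outside [%g, %g]", n_bad, CT_MIN, CT_MAX)
            self.values = v.mask((v < CT_MIN) | (v > CT_MAX))
        missing_meta = set(v.index) - set(self.metadata.index)
        extra_meta = set(self.metadata.index) - set(v.index)
        if missing_meta or extra_meta:
            raise ValidationError(
                "sample mismatch between Ct matrix and metadata: "
                f"missing metadata for {sorted(missing_meta)}, "
                f"metadata without Ct for {sorted(extra_meta)}"
            )
        for col in ("genotype", "treatment", "timepoint"):
            if col not in self.metadata.columns:
                raise ConfigurationError(f"metadata lacks required column {col!r}")
            if self.metadata[col].isna().any():
                bad_s = list(self.metadata.index[self.metadata[col].isna()])
                raise ValidationError(f"missing {col} for samples {bad_s}")
        unknown = set(self.roles) - set(v.columns)
        if unknown:
            raise ConfigurationError(f"roles declared for unknown assays: {sorted(unknown)}")

    @property
    def housekeeping_assays(self) -> list[str]:
        return [a for a in self.values.columns if self.roles.get(a) == "housekeeping"]

    @property
    def target_assays(self) -> list[str]:
        return [a for a in self.values.columns if self.roles.get(a, "target_gene") == "target_gene"]


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

DEFAULT_SIGNATURE_DIALECT = {
    "symbol": "symbol",
    "direction": "direction",
    "injury": "injury",
    "entrez": "entrez",
    "one_based": False,
}

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


def _parse_bool(token: str, row: int) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValidationError(f"row {row}: unrecognized boolean token {token!r}")


def read_signature(path: str | Path, dialect: Mapping[str, object] | None = None) -> SignatureTable:
    """Read a directional gene-signature table from delimited text.

    ``dialect`` maps the logical columns (symbol, direction, injury,
    optionally entrez) to the file's column names.
    """
    d = dict(DEFAULT_SIGNATURE_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("symbol", "direction", "injury"):
        if d[key] not in df.columns:
            raise ConfigurationError(
                f"signature file {path} lacks column {d[key]!r} (mapped from {key!r})"
            )
    has_entrez = d.get("entrez") in df.columns
    records: list[SignatureRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        raw_dir = str(row[d["direction"]]).strip().lower()
        try:
            direction = Direction(raw_dir)
        except ValueError:
            raise ValidationError(f"row {i}: unknown direction token {raw_dir!r}") from None
        entrez = None
        if has_entrez and not pd.isna(row[d["entrez"]]) and str(row[d["entrez"]]).strip():
            entrez = int(float(row[d["entrez"]]))
        records.append(
            SignatureRecord(
                gene=GeneId(str(row[d["symbol"]]), entrez),
                direction=direction,
                injury=_parse_bool(row[d["injury"]], i),
            )
        )
    table = SignatureTable(records)
    logger.info("read_signature: %d genes (up=%d, down=%d) from %s",
                len(table), table.d_up, table.d_down, path)
    return table


def write_signature(table: SignatureTable, path: str | Path) -> None:
    rows = [
        {
            "symbol": r.gene.symbol,
            "entrez": "" if r.gene.entrez is None else r.gene.entrez,
            "direction": r.direction.value,
            "injury": int(r.injury),
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["symbol", "entrez", "direction", "injury"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path, tf_delimiter: str = "_") -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            members: list[GeneId] = []
            seen: set[str] = set()
            for tok in fields[2:]:
                tok = tok.strip()
                if not tok:
                    continue
                g = GeneId(tok)
                if g.symbol not in seen:
                    seen.add(g.symbol)
                    members.append(g)
            sets.append(GeneSet(name, desc, tuple(members)))
    coll = GeneSetCollection(sets, tf_delimiter=tf_delimiter)
    logger.info("read_gmt: %d sets from %s", len(coll), path)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, s.description, *(g.symbol for g in s.members)]) + "\n")


def read_peaks(
    path: str | Path,
    study_id: str,
    intensity_column: int = 4,
    one_based: bool = False,
) -> PeakSet:
    """Read a BED-like peak file.

    ``intensity_column`` is the 0-based index of the intensity field
    (default 4 — the BED score slot). ``one_based`` converts 1-based
    closed input coordinates to the internal 0-based half-open form.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= intensity_column:
                raise ParseError(
                    f"{path}:{lineno}: {len(fields)} fields, intensity column "
                    f"{intensity_column + 1} absent"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from None
            try:
                intensity = float(fields[intensity_column])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric intensity") from None
            if one_based:
                start -= 1
            try:
                peaks.append(Peak(fields[0], start, end, intensity, study_id))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    ps = PeakSet(peaks, study_id)
    logger.info("read_peaks: %d peaks for study %s from %s", len(ps), study_id, path)
    return ps


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpk{i}\t{_fmt(p.intensity)}\n")


def read_annotation(path: str | Path, one_based: bool = False) -> GeneAnnotationTable:
    """Read a gene annotation table (symbol, chrom, strand, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    for col in ("symbol", "chrom", "strand", "start", "end"):
        if col not in df.columns:
            raise ConfigurationError(f"annotation file {path} lacks column {col!r}")
    records = [
        GeneAnnotation(
            gene=GeneId(str(row.symbol)),
            chrom=str(row.chrom),
            strand=str(row.strand),
            start=int(row.start) - (1 if one_based else 0),
            end=int(row.end),
        )
        for row in df.itertuples(index=False)
    ]
    return GeneAnnotationTable(records)


def write_annotation(table: GeneAnnotationTable, path: str | Path) -> None:
    rows = [
        {"symbol": r.gene.symbol, "chrom": r.chrom, "strand": r.strand,
         "start": r.start, "end": r.end}
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_ct(
    path: str | Path,
    metadata_path: str | Path,
    housekeeping: Sequence[str] = (),
) -> CtMatrix:
    """Read a Ct matrix (samples x assays) and its sample-metadata sidecar.

    Tokens like "Undetermined"/"NA" and values outside [0, 45] become
    missing. The metadata file needs columns sample, genotype, treatment,
    timepoint, and optionally a ``role`` declaration per assay via a
    ``housekeeping`` argument.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    def _to_ct(tok):
        if pd.isna(tok) or str(tok).strip().lower() in MISSING_CT_TOKENS:
            return np.nan
        return float(tok)

    values = raw.map(_to_ct).astype(float)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ConfigurationError(f"metadata file {metadata_path} lacks column 'sample'")
    meta = meta.set_index("sample")
    hk = {h.strip() for h in housekeeping if h.strip()}
    missing_hk = hk - set(values.columns)
    if missing_hk:
        raise ConfigurationError(f"housekeeping assays absent from Ct matrix: {sorted(missing_hk)}")
    roles = {a: ("housekeeping" if a in hk else "target_gene") for a in values.columns}
    return CtMatrix(values=values, metadata=meta, roles=roles)


def write_ct(matrix: CtMatrix, ct_path: str | Path, metadata_path: str | Path) -> None:
    out = matrix.values.map(lambda v: "" if pd.isna(v) else _fmt(v))
    out.index.name = "sample"
    out.to_csv(ct_path, sep="\t")
    meta = matrix.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


# --------------------------------------------------------------------------
# Generic table writer
# --------------------------------------------------------------------------

def _fmt(v) -> str:
    """Render a float with 6 significant digits, ints untouched."""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_table(rows: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as TSV: header line, deterministic order,
    floats at 6 significant digits. ``sort_by`` names the primary sort
    keys; omitted means the incoming order is already canonical."""
    df = rows.copy()
    if sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    rendered = df.map(_fmt)
    rendered.to_csv(path, sep="\t", index=False)
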