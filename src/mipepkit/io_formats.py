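"""Tabular and sequence I/O for protein-level quantification data.

The central container is :class:`ProteinQuantTable`: a protein × sample table
of label-free intensities (with explicit missingness) plus an optional block
of spectral counts, where every sample column carries a condition label
(``bait``/``control`` for IP experiments, ``conditionA``/``conditionB`` for
two-condition proteomes) and a replicate index.

Conventions
-----------
* An intensity of 0 or an empty cell means "not detected" (the MaxQuant LFQ
  convention) and is stored as ``NaN``.
* Contaminant and decoy rows (ids prefixed ``CON__`` / ``REV__``) are dropped
  on read and counted in :attr:`ProteinQuantTable.n_dropped`.
* FASTA records are amino-acid sequences over the 20-letter alphabet plus
  ``X``, stored uppercase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONDITIONS = ("bait", "control", "conditionA", "conditionB")
CONTAMINANT_PREFIXES = ("CON__", "REV__")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class SequenceRecordError(ValueError):
    """Raised for malformed sequence records (illegal residues, duplicates)."""


class TableFormatError(ValueError):
    """Raised for malformed quantification tables."""


class SeqEntry(NamedTuple):
    """A named amino-acid sequence; residues are uppercase."""

    id: str
    seq: str


@dataclass
class ProteinQuantTable:
    """Protein × sample quantification table.

    Parameters
    ----------
    intensities:
        DataFrame indexed by unique protein id, one column per sample;
        missing values are NaN, observed values are > 0.
    samples:
        DataFrame indexed by sample name with columns ``condition`` (one of
        :data:`CONDITIONS`) and ``replicate`` (int).
    spectral_counts:
        Optional DataFrame with the same index/columns as ``intensities``
        holding non-negative integer spectral counts.
    source:
        Provenance string (file the table was read from, or the simulator).
    n_dropped:
        Number of contaminant/decoy rows removed on read.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    spectral_counts: pd.DataFrame | None = None
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise TableFormatError(f"duplicate protein ids: {sorted(set(dupes))}")
        if list(self.samples.index) != list(self.intensities.columns):
            raise TableFormatError("sample metadata does not match intensity columns")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise TableFormatError(f"unknown condition labels: {sorted(bad)}")
        vals = self.intensities.to_numpy(dtype=float)
        if (vals[~pd.isna(vals)] <= 0).any():
            raise TableFormatError("observed intensities must be > 0")
        if self.spectral_counts is not None:
            sc = self.spectral_counts
            if list(sc.columns) != list(self.intensities.columns) or not sc.index.equals(
                self.intensities.index
            ):
                raise TableFormatError("spectral-count block must mirror the intensity block")
            if (sc.to_numpy() < 0).any():
                raise TableFormatError("spectral counts must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    def condition_columns(self, condition: str) -> list[str]:
        """Sample column names carrying the given condition label."""
        return list(self.samples.index[self.samples["condition"] == condition])

    def conditions(self) -> list[str]:
        """Distinct condition labels, in first-appearance order."""
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen


def _to_missing(series: pd.Series) -> pd.Series:
    """Map the 0 / empty-cell encoding to NaN."""
    s = pd.to_numeric(series, errors="coerce")
    return s.mask(s == 0)


def read_protein_groups(
    path: str | Path,
    column_map: Mapping[str, tuple[str, str, int]],
) -> ProteinQuantTable:
    """Read a MaxQuant-proteinGroups-style TSV into a :class:`ProteinQuantTable`.

    ``column_map`` maps a header name to ``(kind, condition, replicate)`` where
    ``kind`` is ``"intensity"`` or ``"sc"``. Contaminant/decoy rows (ids
    prefixed ``CON__``/``REV__``) are dropped and counted; intensity 0 becomes
    missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    missing_cols = [c for c in column_map if c not in df.columns]
    if missing_cols:
        raise TableFormatError(f"mapped columns absent from {path}: {missing_cols}")

    keep = ~df[id_col].str.startswith(CONTAMINANT_PREFIXES)
    n_dropped = int((~keep).sum())
    df = df[keep]
    ids = pd.Index(df[id_col], name="protein_id")
    if ids.duplicated().any():
        raise TableFormatError(f"duplicate protein ids in {path}")

    samples: dict[str, tuple[str, int]] = {}
    intens: dict[str, pd.Series] = {}
    counts: dict[str, pd.Series] = {}
    for col, (kind, condition, rep) in column_map.items():
        name = f"{condition}_{rep}"
        samples.setdefault(name, (condition, rep))
        if kind == "intensity":
            intens[name] = _to_missing(df[col])
        elif kind == "sc":
            counts[name] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
        else:
            raise TableFormatError(f"unknown column kind {kind!r} for {col!r}")

    order = list(intens)
    sample_df = pd.DataFrame(
        {"condition": [samples[s][0] for s in order], "replicate": [samples[s][1] for s in order]},
        index=pd.Index(order, name="sample"),
    )
    imat = pd.DataFrame({s: intens[s].to_numpy() for s in order}, index=ids)
    sc_mat = None
    if counts:
        if set(counts) != set(order):
            raise TableFormatError("spectral-count columns must cover the same samples")
        sc_mat = pd.DataFrame({s: counts[s].to_numpy() for s in order}, index=ids)
    return ProteinQuantTable(imat, sample_df, sc_mat, source=str(path), n_dropped=n_dropped)


def read_intensity_matrix(
    path: str | Path,
    condition_map: Mapping[str, tuple[str, int]],
) -> ProteinQuantTable:
    """Read a DIANN-style protein × sample intensity matrix (no spectral counts).

    ``condition_map`` maps a header name to ``(condition, replicate)``.
    """
    column_map = {col: ("intensity", cond, rep) for col, (cond, rep) in condition_map.items()}
    table = read_protein_groups(path, column_map)
    return table


def write_quant_table(table: ProteinQuantTable, path: str | Path) -> None:
    """Write a table as TSV with ``intensity.<condition>.<rep>`` (and
    ``sc.<condition>.<rep>``) columns; missing intensities become 0."""
    out = pd.DataFrame(index=table.intensities.index)
    for s in table.intensities.columns:
        cond = table.samples.loc[s, "condition"]
        rep = table.samples.loc[s, "replicate"]
        col = table.intensities[s].fillna(0.0)
        out[f"intensity.{cond}.{rep}"] = col
    if table.spectral_counts is not None:
        for s in table.spectral_counts.columns:
            cond = table.samples.loc[s, "condition"]
            rep = table.samples.loc[s, "replicate"]
            out[f"sc.{cond}.{rep}"] = table.spectral_counts[s]
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def read_quant_table(path: str | Path) -> ProteinQuantTable:
    """Read back a TSV written by :func:`write_quant_table`."""
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    column_map: dict[str, tuple[str, str, int]] = {}
    for col in header[1:]:
        kind, cond, rep = col.split(".")
        column_map[col] = ("intensity" if kind == "intensity" else "sc", cond, int(rep))
    table = read_protein_groups(path, column_map)
    return table


def _validate_residues(seq: str, seq_id: str) -> str:
    up = seq.upper()
    for pos, ch in enumerate(up, start=1):
        if ch not in AA_ALPHABET:
            raise SequenceRecordError(
                f"illegal residue {ch!r} at position {pos} in sequence {seq_id!r}"
            )
    return up


def read_fasta(path: str | Path) -> list[SeqEntry]:
    """Read amino-acid FASTA; sequences validated and uppercased, ids unique."""
    records: list[SeqEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceRecordError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqEntry(rec.id, _validate_residues(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Iterable[SeqEntry], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(_validate_residues(r.seq, r.id)), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
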