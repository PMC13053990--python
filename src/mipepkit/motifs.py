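"""SLiM scanning, motif mutagenesis and motif→domain partner inference.

Short linear motifs (SLiMs) are short amino-acid patterns, usually inside
intrinsically disordered regions, that mediate transient protein–protein
interactions. They are catalogued as regular-expression classes (ELM-style
ids such as ``MOD_Plk1``). This module provides:

* :func:`scan_motifs` — exhaustive, overlap-aware scanning of a sequence
  against a motif library, with optional restriction to disordered regions;
* :func:`mutate_motif` — in-silico alanine (or other residue) replacement of
  a matched motif, the computational analogue of a SLiM-mutant construct;
* :func:`infer_partners` — interaction inference: a protein is a candidate
  partner when it carries a domain listed as a template partner of a matched
  motif class;
* :func:`overlap_predicted_experimental` — intersection of predicted and
  experimentally called interactor sets.

All residue coordinates are 1-based and inclusive. Patterns anchored with
``re`` semantics are matched at every start position independently, so
overlapping occurrences are all reported (a plain ``finditer`` would miss
them).

The real ELM regexes are curated data and are not bundled; the library ships
as a user-editable TSV plus a small synthetic toy library for tests and
demos.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SeqEntry


class MotifLibraryError(ValueError):
    """Raised for malformed motif libraries or unknown class ids."""


@dataclass
class MotifClass:
    """A motif class: ELM-style id, regex pattern, and interaction templates.

    ``partner_domain_ids`` lists the domain signatures (e.g. Pfam/InterPro
    accessions) whose carriers are candidate binding partners of the motif.
    ``taxon_validated`` marks classes with true-positive instances reported in
    the organism under study; inference can be restricted to those.
    """

    class_id: str
    pattern: str
    requires_disorder: bool = False
    taxon_validated: bool = True
    partner_domain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        try:
            self._regex = re.compile(self.pattern)
        except re.error as exc:
            raise MotifLibraryError(f"pattern of {self.class_id!r} does not compile: {exc}")

    @property
    def regex(self) -> re.Pattern:
        return self._regex


@dataclass(frozen=True)
class MotifMatch:
    """A motif occurrence; ``start``/``end`` are 1-based inclusive."""

    sequence_id: str
    class_id: str
    start: int
    end: int
    matched: str
    in_disorder: bool


@dataclass(frozen=True)
class DomainAnnotation:
    """Domain signatures carried by one protein."""

    protein_id: str
    domain_ids: frozenset[str]


def _check_unique(library: Sequence[MotifClass]) -> None:
    ids = [m.class_id for m in library]
    if len(set(ids)) != len(ids):
        raise MotifLibraryError("motif class ids must be unique")


def scan_motifs(
    record: SeqEntry,
    library: Sequence[MotifClass],
    disorder_regions: Sequence[tuple[int, int]] = (),
) -> list[MotifMatch]:
    """Report every occurrence of every library pattern in the sequence.

    Each start position is scanned independently so overlapping matches are
    all found. A match is ``in_disorder`` when it lies wholly inside one of
    the given (1-based inclusive) disordered regions; classes flagged
    ``requires_disorder`` only report matches inside disorder.
    """
    _check_unique(library)
    seq = record.seq
    matches: list[MotifMatch] = []
    for cls in library:
        for pos in range(len(seq)):
            m = cls.regex.match(seq, pos)
            if m is None or m.end() == pos:
                continue
            start, end = pos + 1, m.end()  # to 1-based inclusive
            in_dis = any(ds <= start and end <= de for ds, de in disorder_regions)
            if cls.requires_disorder and not in_dis:
                continue
            matches.append(
                MotifMatch(record.id, cls.class_id, start, end, seq[pos : m.end()], in_dis)
            )
    matches.sort(key=lambda m: (m.start, m.end, m.class_id))
    return matches


def mutate_motif(
    record: SeqEntry,
    match: MotifMatch,
    replacement_residue: str = "A",
) -> SeqEntry:
    """Replace the matched span by a run of ``replacement_residue``.

    Length and all residues outside the span are preserved — the in-silico
    counterpart of replacing a motif by an alanine stretch in a mutant
    construct.
    """
    if len(replacement_residue) != 1:
        raise ValueError("replacement_residue must be a single letter")
    if match.sequence_id != record.id:
        raise ValueError(f"match belongs to {match.sequence_id!r}, not {record.id!r}")
    if not (1 <= match.start <= match.end <= len(record.seq)):
        raise ValueError(f"match span {match.start}..{match.end} out of bounds")
    if record.seq[match.start - 1 : match.end] != match.matched:
        raise ValueError("match subsequence does not agree with the sequence")
    mutated = (
        record.seq[: match.start - 1]
        + replacement_residue.upper() * (match.end - match.start + 1)
        + record.seq[match.end :]
    )
    return SeqEntry(record.id, mutated)


def infer_partners(
    matches: Sequence[MotifMatch],
    library: Sequence[MotifClass],
    annotations: Sequence[DomainAnnotation],
    taxon_validated_only: bool = False,
) -> dict[str, set[tuple[str, str]]]:
    """Predict partner proteins from motif→domain interaction templates.

    A protein is predicted iff it carries at least one domain signature listed
    as a template partner of at least one matched motif class. Returns
    ``{protein id: {(motif class id, domain id), ...}}`` with every supporting
    pair. Unknown matched class ids raise :class:`MotifLibraryError`.
    """
    _check_unique(library)
    by_id = {m.class_id: m for m in library}
    matched_classes: list[MotifClass] = []
    seen: set[str] = set()
    for match in matches:
        if match.class_id not in by_id:
            raise MotifLibraryError(f"matched class {match.class_id!r} not in library")
        cls = by_id[match.class_id]
        if taxon_validated_only and not cls.taxon_validated:
            continue
        if cls.class_id not in seen:
            seen.add(cls.class_id)
            matched_classes.append(cls)

    predictions: dict[str, set[tuple[str, str]]] = {}
    for ann in annotations:
        support = {
            (cls.class_id, dom)
            for cls in matched_classes
            for dom in cls.partner_domain_ids
            if dom in ann.domain_ids
        }
        if support:
            predictions.setdefault(ann.protein_id, set()).update(support)
    return predictions


def overlap_predicted_experimental(
    predicted: Iterable[str],
    experimental: Iterable[str],
) -> list[str]:
    """Sorted intersection of predicted and experimentally called interactors."""
    return sorted(set(predicted) & set(experimental))


# ---------------------------------------------------------------------------
# Library I/O and the bundled toy library
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ["class_id", "pattern", "requires_disorder", "taxon_validated", "partner_domains"]


def read_motif_library(path: str | Path) -> list[MotifClass]:
    """Read a motif library TSV (class_id, pattern, requires_disorder,
    taxon_validated, partner_domains separated by ';')."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_LIB_COLUMNS) - set(df.columns)
    if missing:
        raise MotifLibraryError(f"library missing columns: {sorted(missing)}")
    library = [
        MotifClass(
            class_id=row.class_id,
            pattern=row.pattern,
            requires_disorder=row.requires_disorder.strip().lower() in ("1", "true", "yes"),
            taxon_validated=row.taxon_validated.strip().lower() in ("1", "true", "yes"),
            partner_domain_ids=[d for d in row.partner_domains.split(";") if d],
        )
        for row in df.itertuples()
    ]
    _check_unique(library)
    return library


def write_motif_library(library: Sequence[MotifClass], path: str | Path) -> None:
    rows = [
        {
            "class_id": m.class_id,
            "pattern": m.pattern,
            "requires_disorder": str(m.requires_disorder).lower(),
            "taxon_validated": str(m.taxon_validated).lower(),
            "partner_domains": ";".join(m.partner_domain_ids),
        }
        for m in library
    ]
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, sep="\t", index=False)


def toy_motif_library() -> list[MotifClass]:
    """Small synthetic motif library for tests and demonstrations.

    The patterns are invented stand-ins, not curated ELM regexes: a
    polo-like-kinase-style phospho-motif class that matches the literal
    ``REKSIL``, and a LIR-like (Atg8-interacting) class. Partner-domain ids
    use Pfam-style accessions (PF00069: protein kinase domain; PF02991:
    Atg8/ubiquitin-like domain).
    """
    return [
        MotifClass(
            class_id="MOD_PLK_TOY",
            pattern="[RK].KS.[LIVM]",
            requires_disorder=False,
            taxon_validated=True,
            partner_domain_ids=["PF00069"],
        ),
        MotifClass(
            class_id="LIG_LIR_TOY",
            pattern="[WFY]..[LIV]",
            requires_disorder=True,
            taxon_validated=True,
            partner_domain_ids=["PF02991"],
        ),
        MotifClass(
            class_id="DOC_UNVALIDATED_TOY",
            pattern="PP.Y",
            requires_disorder=False,
            taxon_validated=False,
            partner_domain_ids=["PF00397"],
        ),
    ]
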