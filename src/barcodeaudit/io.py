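"""Reading, writing and sequence-level QC for barcode libraries.

A barcode library couples an aligned set of COI sequences (FASTA) with a
specimen table (TSV) carrying the morphological species label and the
geographic (FAO) division of every individual.  QC screens translated
reading frames for stop codons — the classic test for NUMTs and sequencing
artefacts in protein-coding barcodes — and summarises nucleotide
composition.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

#: genetic-code ids accepted by QC, mapped to NCBI table names
GENETIC_CODES = {
    "vertebrate-mito": "Vertebrate Mitochondrial",
    "standard": "Standard",
    "invertebrate-mito": "Invertebrate Mitochondrial",
}


class LibraryError(ValueError):
    """Raised for malformed input libraries (duplicate ids, ragged lengths...)."""


@dataclass
class SpecimenRecord:
    """One barcoded individual: sequence plus field metadata."""

    specimen_id: str
    sequence: str = ""
    morph_label: str = ""
    division: str = ""
    accession: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise LibraryError("specimen_id must be non-empty")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise LibraryError(
                f"specimen {self.specimen_id!r}: non-IUPAC symbols {sorted(bad)}"
            )


@dataclass
class BarcodeLibrary:
    """An ordered collection of specimens sharing one alignment length."""

    records: list[SpecimenRecord]
    alignment_length: int

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise LibraryError(f"duplicate specimen ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def labels(self) -> dict[str, str]:
        """specimen_id -> morphological species label."""
        return {r.specimen_id: r.morph_label for r in self.records}

    def divisions(self) -> dict[str, str]:
        return {r.specimen_id: r.division for r in self.records}

    def subset(self, keep: Iterable[str]) -> "BarcodeLibrary":
        keep = set(keep)
        return BarcodeLibrary(
            [r for r in self.records if r.specimen_id in keep], self.alignment_length
        )

    def relabelled(self, new_labels: dict[str, str]) -> "BarcodeLibrary":
        """Copy with morph labels replaced where new_labels provides one."""
        recs = [
            replace(r, morph_label=new_labels.get(r.specimen_id, r.morph_label))
            for r in self.records
        ]
        return BarcodeLibrary(recs, self.alignment_length)


@dataclass
class QcReport:
    n_input: int
    n_passed: int
    excluded: list[tuple[str, str]] = field(default_factory=list)
    frame_used: Optional[int] = None
    composition: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_passed + len(self.excluded) != self.n_input:
            raise LibraryError("QC accounting mismatch: passed + excluded != input")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_passed": self.n_passed,
                "excluded": [list(e) for e in self.excluded],
                "frame_used": self.frame_used,
                "composition": self.composition,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# readers / writers


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{id: sequence}`` mapping.

    Ids are the header token before the first whitespace; sequences are
    upper-cased with U mapped to T.  Duplicate ids are a hard error; ragged
    lengths are accepted here and rejected later by
    :func:`validate_alignment`.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise LibraryError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = _clean(str(rec.seq))
    if not seqs:
        raise LibraryError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(library: BarcodeLibrary, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in library:
            fh.write(f">{r.specimen_id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


MANDATORY_COLUMNS = ("specimen_id", "morph_label")


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read the tab-delimited specimen table (metadata only, no sequences).

    Mandatory columns: specimen_id, morph_label.  division and accession are
    optional; any further columns are preserved verbatim in ``notes``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise LibraryError(
                f"specimen table {path} lacks mandatory column(s) {missing}; "
                f"header found: {header}"
            )
        known = {"specimen_id", "morph_label", "division", "accession"}
        extra_cols = [c for c in header if c not in known]
        records = []
        for row in reader:
            notes = (
                "; ".join(f"{c}={row[c]}" for c in extra_cols if row.get(c))
                or None
            )
            records.append(
                SpecimenRecord(
                    specimen_id=row["specimen_id"],
                    morph_label=row["morph_label"],
                    division=row.get("division") or "",
                    accession=row.get("accession") or None,
                    notes=notes,
                )
            )
    return records


def write_specimen_table(library: BarcodeLibrary, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["specimen_id", "morph_label", "division", "accession"])
        for r in library:
            w.writerow([r.specimen_id, r.morph_label, r.division, r.accession or ""])


def load_library(fasta_path, table_path) -> BarcodeLibrary:
    """Join sequences and metadata by specimen_id into a validated library."""
    seqs = read_fasta(fasta_path)
    meta = {r.specimen_id: r for r in read_specimen_table(table_path)}
    records = []
    for sid, seq in seqs.items():
        m = meta.get(sid)
        if m is None:
            raise LibraryError(f"sequence {sid!r} has no row in the specimen table")
        records.append(replace(m, sequence=seq))
    lib = BarcodeLibrary(records, alignment_length=len(records[0].sequence))
    return validate_alignment(lib)


# ---------------------------------------------------------------------------
# validation & QC


def validate_alignment(library: BarcodeLibrary) -> BarcodeLibrary:
    """Assert all sequences share the library alignment length."""
    if not library.records:
        raise LibraryError("no records in library")
    bad = [
        (r.specimen_id, len(r.sequence))
        for r in library
        if len(r.sequence) != library.alignment_length
    ]
    if bad:
        raise LibraryError(
            f"ragged alignment (expected length {library.alignment_length}): {bad}"
        )
    return library


def _stop_codons(code: str) -> frozenset[str]:
    try:
        table = CodonTable.unambiguous_dna_by_name[GENETIC_CODES[code]]
    except KeyError as e:
        raise LibraryError(f"unknown genetic code {code!r}") from e
    return frozenset(table.stop_codons)


def count_stops(sequence: str, frame: int, stops: frozenset[str]) -> int:
    """In-frame stop codons; codons touching any non-ACGT symbol are skipped."""
    n = 0
    for i in range(frame - 1, len(sequence) - 2, 3):
        codon = sequence[i : i + 3]
        if set(codon) <= UNAMBIGUOUS and codon in stops:
            n += 1
    return n


def screen_stop_codons(
    library: BarcodeLibrary,
    code: str = "vertebrate-mito",
    frame: Optional[int] = None,
) -> tuple[BarcodeLibrary, QcReport]:
    """Exclude records carrying in-frame stop codons.

    When ``frame`` is None the reading frame is auto-detected as the frame in
    {1,2,3} minimising the library-wide stop-codon total (ties broken toward
    the lowest frame).  Gaps and ambiguity codes make a codon untranslatable
    and can therefore never register as stops — conservative QC.
    """
    validate_alignment(library)
    stops = _stop_codons(code)
    if frame is None:
        totals = {
            f: sum(count_stops(r.sequence, f, stops) for r in library)
            for f in (1, 2, 3)
        }
        frame = min((1, 2, 3), key=lambda f: (totals[f], f))
    elif frame not in (1, 2, 3):
        raise LibraryError(f"frame must be 1, 2 or 3, got {frame}")

    excluded = [
        (r.specimen_id, "stop_codon")
        for r in library
        if count_stops(r.sequence, frame, stops) > 0
    ]
    excluded_ids = {sid for sid, _ in excluded}
    passed = library.subset(set(library.ids()) - excluded_ids)
    report = QcReport(
        n_input=len(library),
        n_passed=len(passed),
        excluded=excluded,
        frame_used=frame,
    )
    return passed, report


def composition_summary(library: BarcodeLibrary) -> dict:
    """Nucleotide frequencies over unambiguous sites, pooled across records.

    Returns per-base fractions, pooled GC, and (secondary) the mean of
    per-sequence GC fractions.
    """
    pooled = Counter()
    per_seq_gc = []
    for r in library:
        c = Counter(ch for ch in r.sequence if ch in UNAMBIGUOUS)
        if sum(c.values()):
            per_seq_gc.append((c["G"] + c["C"]) / sum(c.values()))
        pooled.update(c)
    total = sum(pooled.values())
    if total == 0:
        raise LibraryError("library contains no unambiguous A/C/G/T bases")
    freqs = {b: pooled[b] / total for b in "ACGT"}
    return {
        **freqs,
        "gc_pooled": freqs["G"] + freqs["C"],
        "gc_mean_per_sequence": sum(per_seq_gc) / len(per_seq_gc),
        "n_unambiguous_sites": total,
    }
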