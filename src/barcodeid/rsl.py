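"""Reference Sequences Library (RSL) handling.

An RSL is a curated multi-FASTA of single-marker sequences, one uniquely
identified sequence per described or candidate species. Identifiers encode
the taxon; the lineage (species-level name) is derived from the identifier
by a configurable parsing convention. The RSL also backs the local
nucleotide search database built with ``makeblastdb``.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdentifierError,
    EmptyLibraryError,
    ExternalToolError,
    InvalidSequenceError,
    LineageParseError,
    MissingInputError,
)

# IUPAC nucleotide codes, ambiguity codes included.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")

#: Lineage-parsing conventions. "binomial" joins the first two
#: underscore-separated tokens (Genus_species); "full" uses the whole
#: identifier; any other string is treated as a user regex whose first
#: capture group (or whole match) is the lineage.
LineageConvention = Union[str, Callable[[str], str]]


def parse_lineage(seq_id: str, convention: LineageConvention = "binomial") -> str:
    """Derive the species-level lineage name from a sequence identifier.

    Parameters
    ----------
    seq_id
        FASTA header token, e.g. ``"Mantella_aurantiaca_MRSN1234"``.
    convention
        ``"binomial"`` (default): first two underscore-separated tokens
        joined by an underscore. ``"full"``: the identifier itself. Any
        other string: a regular expression applied with ``re.search``;
        group 1 if present, else the whole match. A callable is applied
        directly.

    Raises
    ------
    LineageParseError
        If the identifier yields an empty lineage under the convention.
    """
    if not seq_id:
        raise LineageParseError("empty sequence identifier")
    if callable(convention):
        lineage = convention(seq_id)
    elif convention == "binomial":
        parts = seq_id.split("_")
        head = parts[:2]
        # an empty token (e.g. "_x" or "_") means the binomial is incomplete
        lineage = "" if any(p == "" for p in head) else "_".join(head)
    elif convention == "full":
        lineage = seq_id
    else:
        m = re.search(convention, seq_id)
        if m is None:
            lineage = ""
        else:
            lineage = m.group(1) if m.groups() else m.group(0)
    if not lineage:
        raise LineageParseError(
            f"identifier {seq_id!r} yields an empty lineage under "
            f"convention {convention!r}"
        )
    return lineage


@dataclass(frozen=True)
class RSLRecord:
    """One reference sequence: identifier, derived lineage, nucleotides."""

    seq_id: str
    lineage: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise InvalidSequenceError("reference record with empty identifier")
        if not self.lineage:
            raise LineageParseError(f"record {self.seq_id!r} has empty lineage")
        if not self.sequence:
            raise InvalidSequenceError(f"record {self.seq_id!r} has empty sequence")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise InvalidSequenceError(
                f"record {self.seq_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )


@dataclass
class RSL:
    """An ordered reference library plus the set of distinct lineages."""

    records: list[RSLRecord] = field(default_factory=list)

    @property
    def lineages(self) -> list[str]:
        """Distinct lineage names, in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.lineage, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.records)

    def lineage_of(self, seq_id: str) -> str | None:
        """Lineage for a reference identifier, or None if unknown."""
        return self._index().get(seq_id)

    def _index(self) -> dict[str, str]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.seq_id: r.lineage for r in self.records}
        return self._idx

    def to_fasta(self, path: str | Path) -> Path:
        """Write the library back to multi-FASTA (one line per sequence)."""
        path = Path(path)
        seqs = [
            SeqRecord(Seq(r.sequence), id=r.seq_id, description="")
            for r in self.records
        ]
        with open(path, "w") as fh:
            SeqIO.write(seqs, fh, "fasta-2line")
        return path


def load_rsl(
    path: str | Path, convention: LineageConvention = "binomial"
) -> RSL:
    """Load and validate a Reference Sequences Library from multi-FASTA.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T`` so the
    library is always in DNA space. Duplicate identifiers, empty files and
    non-IUPAC characters are rejected with distinct errors.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"reference library not found: {path}")
    records: list[RSLRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdentifierError(
                f"duplicate identifier {rec.id!r} in {path}"
            )
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(
            RSLRecord(seq_id=rec.id, lineage=parse_lineage(rec.id, convention), sequence=seq)
        )
    if not records:
        raise EmptyLibraryError(f"no sequences found in {path}")
    return RSL(records=records)


@dataclass(frozen=True)
class SearchDatabase:
    """Handle to a built nucleotide search database (index file paths)."""

    prefix: Path
    files: tuple[Path, ...]


def _db_index_files(prefix: Path) -> list[Path]:
    return sorted(prefix.parent.glob(prefix.name + ".n*"))


def build_search_db(
    rsl_fasta: str | Path,
    out_prefix: str | Path,
    makeblastdb_exe: str = "makeblastdb",
) -> SearchDatabase:
    """Build the local nucleotide database from an RSL FASTA.

    Thin adapter over ``makeblastdb -in <fasta> -dbtype nucl -out <prefix>``.
    Idempotent: rebuilding over an existing prefix replaces the index. On
    failure no partial index files are left behind.
    """
    rsl_fasta = Path(rsl_fasta)
    out_prefix = Path(out_prefix)
    if not rsl_fasta.exists():
        raise MissingInputError(f"reference library not found: {rsl_fasta}")
    if shutil.which(makeblastdb_exe) is None:
        raise ExternalToolError(
            f"{makeblastdb_exe!r} not found on PATH; install NCBI BLAST+ "
            "(https://blast.ncbi.nlm.nih.gov) or run in hit-table mode"
        )
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    cmd = [
        makeblastdb_exe,
        "-in", str(rsl_fasta),
        "-dbtype", "nucl",
        "-out", str(out_prefix),
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        for leftover in _db_index_files(out_prefix):
            leftover.unlink(missing_ok=True)
        raise ExternalToolError(
            f"makeblastdb exited with status {proc.returncode}: "
            f"{proc.stderr.strip()}"
        )
    files = tuple(_db_index_files(out_prefix))
    if not files:
        raise ExternalToolError(
            f"makeblastdb reported success but produced no index at {out_prefix}"
        )
    return SearchDatabase(prefix=out_prefix, files=files)
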