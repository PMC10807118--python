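"""Local BLAST invocation and extended tabular hit-table I/O.

The aligner is run with the 12 standard tabular fields plus ``qlen``,
``slen``, ``gaps`` and ``qcovs`` appended, in that order. The same
tab-separated dialect is read and written here so pre-computed hit files
(from any source honouring the format) can feed the pipeline without the
aligner installed.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    ExternalToolError,
    HitTableFormatError,
    MissingInputError,
    ParameterError,
)
from .rsl import SearchDatabase

#: Tabular output columns, matching the aligner's -outfmt specification.
OUTFMT_FIELDS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "qlen", "slen", "gaps", "qcovs",
)

OUTFMT_SPEC = "6 " + " ".join(OUTFMT_FIELDS)


@dataclass(frozen=True)
class HitRecord:
    """One row of the 16-field extended tabular alignment output."""

    qseqid: str
    sseqid: str
    pident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int
    gaps: int
    qcovs: float

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise HitTableFormatError(
                f"hit {self.qseqid}->{self.sseqid}: query coordinates "
                f"qstart={self.qstart}, qend={self.qend} violate "
                f"1 <= qstart <= qend <= qlen={self.qlen}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise HitTableFormatError(
                f"hit {self.qseqid}->{self.sseqid}: pident {self.pident} "
                "outside [0, 100]"
            )
        if self.aln_len < 1:
            raise HitTableFormatError(
                f"hit {self.qseqid}->{self.sseqid}: alignment length "
                f"{self.aln_len} < 1"
            )
        # subject coordinates may be reversed (minus strand) but must lie
        # within the subject
        lo, hi = sorted((self.sstart, self.send))
        if not (1 <= lo and hi <= self.slen):
            raise HitTableFormatError(
                f"hit {self.qseqid}->{self.sseqid}: subject coordinates "
                f"[{self.sstart}, {self.send}] outside [1, slen={self.slen}]"
            )
        if self.evalue < 0 or self.bitscore < 0:
            raise HitTableFormatError(
                f"hit {self.qseqid}->{self.sseqid}: negative evalue/bitscore"
            )


def _fmt_float(x: float) -> str:
    """Lossless compact float formatting: integers without a decimal point."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _format_row(hit: HitRecord) -> str:
    vals = [
        hit.qseqid,
        hit.sseqid,
        f"{hit.pident:.3f}",
        str(hit.aln_len), str(hit.mismatch), str(hit.gapopen),
        str(hit.qstart), str(hit.qend), str(hit.sstart), str(hit.send),
        _fmt_float(hit.evalue),
        _fmt_float(hit.bitscore),
        str(hit.qlen), str(hit.slen), str(hit.gaps),
        _fmt_float(hit.qcovs),
    ]
    return "\t".join(vals)


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> Path:
    """Write hits as tab-separated extended tabular rows (no header).

    ``pident`` is written with 3 decimals (the aligner's precision); other
    reals round-trip losslessly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(_format_row(hit) + "\n")
    return path


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse an extended tabular hit file into validated HitRecords.

    Comment lines starting with ``#`` are skipped; row order is preserved.
    Errors name the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"hit table not found: {path}")
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(OUTFMT_FIELDS):
                raise HitTableFormatError(
                    f"{path}:{lineno}: expected {len(OUTFMT_FIELDS)} "
                    f"tab-separated fields, got {len(cols)}"
                )
            try:
                hits.append(HitRecord(
                    qseqid=cols[0], sseqid=cols[1],
                    pident=float(cols[2]), aln_len=int(cols[3]),
                    mismatch=int(cols[4]), gapopen=int(cols[5]),
                    qstart=int(cols[6]), qend=int(cols[7]),
                    sstart=int(cols[8]), send=int(cols[9]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                    qlen=int(cols[12]), slen=int(cols[13]),
                    gaps=int(cols[14]), qcovs=float(cols[15]),
                ))
            except ValueError as exc:
                raise HitTableFormatError(
                    f"{path}:{lineno}: unparseable numeric field ({exc})"
                ) from exc
    return hits


def run_local_blast(
    query_fasta: str | Path,
    db: SearchDatabase,
    cutoff_pident: float,
    out_path: str | Path,
    blastn_exe: str = "blastn",
    extra_args: Sequence[str] = (),
) -> Path:
    """Run the local nucleotide aligner with the extended tabular format.

    The identity cutoff is enforced at the aligner (``-perc_identity``) and
    re-checked when the table is consumed downstream. An empty query file
    yields an empty result file and success.
    """
    query_fasta = Path(query_fasta)
    out_path = Path(out_path)
    if not (0.0 <= cutoff_pident <= 100.0):
        raise ParameterError(
            f"cutoff_pident must be in [0, 100], got {cutoff_pident}"
        )
    if not query_fasta.exists():
        raise MissingInputError(f"query file not found: {query_fasta}")
    if shutil.which(blastn_exe) is None:
        raise ExternalToolError(
            f"{blastn_exe!r} not found on PATH; install NCBI BLAST+ or "
            "supply a pre-computed hit table"
        )
    cmd = [
        blastn_exe,
        "-query", str(query_fasta),
        "-db", str(db.prefix),
        "-perc_identity", str(cutoff_pident),
        "-outfmt", OUTFMT_SPEC,
        "-out", str(out_path),
        *extra_args,
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError(
            f"blastn exited with status {proc.returncode}: "
            f"{proc.stderr.strip()}"
        )
    return out_path
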