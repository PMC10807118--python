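"""Synthetic reference libraries, query sets and hit tables.

The generator emulates a single-marker barcoding study: a reference
library with one random sequence per lineage, in-group queries derived
from references by a fixed number of point substitutions (no indels, so
percent identity is exact by construction: ``100 * (1 - subs/L)``), and
unrelated outgroup queries with no acceptable match. A companion hit-table
generator stands in for the aligner so the filtering/reporting core is
testable offline.

Defaults reproduce a small frog-barcoding benchmark: a 25-lineage library,
nine in-group queries spread over seven lineages — three of them divergent
enough (4–6%) to fall below a 97% similarity threshold while staying above
a 90% identity cutoff — and one outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .blast_io import HitRecord, write_hit_table
from .errors import ParameterError
from .rsl import RSL, load_rsl

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_lineages: int = 25
    ref_length: int = 500
    n_matched_lineages: int = 7
    per_query_divergence: tuple[float, ...] = (
        0.0, 0.0, 0.0, 1.0, 1.0, 2.0, 4.0, 5.0, 6.0,
    )
    n_outgroups: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_matched_lineages > self.n_lineages:
            raise ParameterError(
                f"n_matched_lineages={self.n_matched_lineages} exceeds "
                f"n_lineages={self.n_lineages}"
            )
        if any(not (0.0 <= d < 100.0) for d in self.per_query_divergence):
            raise ParameterError("divergences must lie in [0, 100)")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one query: its source reference (None for
    outgroups), the exact substitution count, and the implied identity."""

    query_id: str
    source_seq_id: str | None
    source_lineage: str | None
    n_substitutions: int
    expected_pident: float  # 100 * (1 - subs / qlen); NaN-free, outgroups 0
    qlen: int
    seed: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_rsl(spec: FixtureSpec) -> str:
    """Generate the reference-library FASTA text.

    Headers follow ``Genus{i}_species{i}_V{i}`` so the default binomial
    lineage convention yields one lineage per record. Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    chunks = []
    for i in range(1, spec.n_lineages + 1):
        chunks.append(f">Genus{i}_species{i}_V{i}\n"
                      f"{_random_seq(rng, spec.ref_length)}\n")
    return "".join(chunks)


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions, each to a
    base different from the original.

    Positions avoid the terminal ~5% of the sequence when there is room:
    a local aligner trims alignments ending in mismatches, which would
    break the closed-form identity the fixtures guarantee.
    """
    arr = np.array(list(seq))
    margin = min(25, len(arr) // 10)
    lo, hi = margin, len(arr) - margin
    if hi - lo < n_subs:
        lo, hi = 0, len(arr)
    positions = lo + rng.choice(hi - lo, size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(len(choices))]
    return "".join(arr)


def make_queries(rsl: RSL, spec: FixtureSpec) -> tuple[str, list[TruthRow]]:
    """Generate query FASTA text plus the ground-truth table.

    Query *j* derives from matched lineage ``j % n_matched_lineages`` with
    ``round(d * L / 100)`` substitutions for divergence *d*; outgroups are
    fresh random sequences unrelated to the library.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fasta_chunks: list[str] = []
    truth: list[TruthRow] = []
    for j, d in enumerate(spec.per_query_divergence):
        ref = rsl.records[j % spec.n_matched_lineages]
        L = len(ref.sequence)
        n_subs = int(round(d * L / 100.0))
        if n_subs > L:
            raise ParameterError(
                f"divergence {d}% implies more substitutions than length {L}"
            )
        qid = f"Q{j + 1}_{ref.lineage}"
        fasta_chunks.append(f">{qid}\n{_substitute(rng, ref.sequence, n_subs)}\n")
        truth.append(TruthRow(
            query_id=qid,
            source_seq_id=ref.seq_id,
            source_lineage=ref.lineage,
            n_substitutions=n_subs,
            expected_pident=100.0 * (1.0 - n_subs / L),
            qlen=L,
            seed=spec.seed,
        ))
    for k in range(1, spec.n_outgroups + 1):
        qid = f"OUT{k}"
        fasta_chunks.append(f">{qid}\n{_random_seq(rng, spec.ref_length)}\n")
        truth.append(TruthRow(
            query_id=qid,
            source_seq_id=None,
            source_lineage=None,
            n_substitutions=0,
            expected_pident=0.0,
            qlen=spec.ref_length,
            seed=spec.seed,
        ))
    return "".join(fasta_chunks), truth


def make_hit_table(
    truth: Sequence[TruthRow],
    spec: FixtureSpec,
    n_decoys_per_query: int = 0,
) -> list[HitRecord]:
    """Build the extended tabular hits the aligner would report.

    Each in-group query gets one full-length hit against its source
    reference (identity from the truth table, alignment spanning the whole
    query and subject); outgroups get no rows. Optional decoy rows per
    in-group query have half-length alignments (50% coverage) so the
    coverage filter has something to remove.
    """
    hits: list[HitRecord] = []
    for row in truth:
        if row.source_seq_id is None:
            continue
        L = row.qlen
        pident = round(row.expected_pident, 3)
        hits.append(HitRecord(
            qseqid=row.query_id, sseqid=row.source_seq_id,
            pident=pident, aln_len=L,
            mismatch=row.n_substitutions, gapopen=0,
            qstart=1, qend=L, sstart=1, send=L,
            evalue=1e-50, bitscore=round(2.0 * L * pident / 100.0, 1),
            qlen=L, slen=L, gaps=0, qcovs=100.0,
        ))
        for _ in range(n_decoys_per_query):
            half = L // 2
            hits.append(HitRecord(
                qseqid=row.query_id, sseqid=row.source_seq_id,
                pident=pident, aln_len=half,
                mismatch=0, gapopen=0,
                qstart=1, qend=half, sstart=1, send=half,
                evalue=1e-10, bitscore=round(1.0 * half, 1),
                qlen=L, slen=L, gaps=0, qcovs=100.0,
            ))
    return hits


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path,
                      n_decoys_per_query: int = 0) -> dict[str, Path]:
    """Materialize a complete fixture set (RSL, queries, hit table, truth
    TSV) into a directory; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rsl_path = out_dir / "rsl.fasta"
    rsl_path.write_text(make_rsl(spec))
    rsl = load_rsl(rsl_path)
    query_text, truth = make_queries(rsl, spec)
    query_path = out_dir / "queries.fasta"
    query_path.write_text(query_text)
    hits_path = out_dir / "hits.tsv"
    write_hit_table(make_hit_table(truth, spec, n_decoys_per_query), hits_path)
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("query_id\tsource_seq_id\tsource_lineage\t"
                 "n_substitutions\texpected_pident\tqlen\tseed\n")
        for row in truth:
            fh.write(f"{row.query_id}\t{row.source_seq_id or ''}\t"
                     f"{row.source_lineage or ''}\t{row.n_substitutions}\t"
                     f"{row.expected_pident!r}\t{row.qlen}\t{row.seed}\n")
    return {"rsl": rsl_path, "queries": query_path,
            "hits": hits_path, "truth": truth_path}
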