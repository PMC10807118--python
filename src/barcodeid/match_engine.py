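"""Hit filtering, best-match selection, tagging and summary statistics.

This is the computational core of the identification workflow:

* query coverage is computed from alignment coordinates as
  ``qcov = 100 * (qend - qstart + 1) / qlen`` — deliberately not the
  aligner's per-subject ``qcovs`` column, which merges HSPs;
* hits are discarded when ``qcov < 75`` or when the alignment spans less
  than 90% of the subject length, removing high-identity matches that rest
  on short alignments;
* per query, the retained hit with the highest percent identity is the
  best match; ties break deterministically on bitscore, alignment length,
  then subject id;
* matches below the similarity threshold ``100 - intersp_div`` or with
  coverage below 75% are flagged for further checking, as are matches
  whose subject identifier carries a user-supplied taxa warning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .blast_io import HitRecord
from .errors import CheckTagError, ParameterError, PipelineInternalError
from .rsl import RSL

#: Minimum query coverage (percent) for a hit to be retained, and below
#: which a best match is coverage-flagged.
QCOV_MIN = 75.0

#: Minimum alignment length as a fraction of the subject length.
SUBJECT_SPAN_MIN = 0.90

# float guard so aln_len == 0.90 * slen is never rejected by representation
# error (the 90% boundary itself is retained)
_EPS = 1e-9


def compute_qcov(qstart: int, qend: int, qlen: int) -> float:
    """Percent of the query spanned by an alignment, on 1-based inclusive
    coordinates: ``100 * (qend - qstart + 1) / qlen``. Not rounded."""
    if not (1 <= qstart <= qend <= qlen):
        raise ParameterError(
            f"invalid coordinates: need 1 <= qstart <= qend <= qlen, "
            f"got qstart={qstart}, qend={qend}, qlen={qlen}"
        )
    return 100.0 * (qend - qstart + 1) / qlen


def similarity_threshold(intersp_div: float) -> float:
    """Similarity threshold (percent identity) for confident identification:
    ``100 - intersp_div``."""
    if not (0.0 <= intersp_div < 100.0):
        raise ParameterError(
            f"intersp_div must be in [0, 100), got {intersp_div}"
        )
    return 100.0 - intersp_div


@dataclass(frozen=True)
class EvaluatedHit:
    """A hit annotated with computed query coverage and filter outcomes."""

    hit: HitRecord
    qcov: float
    passes_qcov_filter: bool
    passes_length_filter: bool

    @property
    def retained(self) -> bool:
        return self.passes_qcov_filter and self.passes_length_filter


def evaluate_hit(hit: HitRecord) -> EvaluatedHit:
    qcov = compute_qcov(hit.qstart, hit.qend, hit.qlen)
    return EvaluatedHit(
        hit=hit,
        qcov=qcov,
        passes_qcov_filter=qcov >= QCOV_MIN,
        passes_length_filter=hit.aln_len >= SUBJECT_SPAN_MIN * hit.slen - _EPS,
    )


def filter_hits(hits: Iterable[HitRecord]) -> list[EvaluatedHit]:
    """Evaluate and keep only hits passing both filters, preserving order.

    A hit survives iff its computed query coverage is >= 75% and its
    alignment length is >= 90% of the subject length (both boundaries
    inclusive: the filters remove strictly-below values).
    """
    return [ev for ev in map(evaluate_hit, hits) if ev.retained]


@dataclass
class BestMatch:
    """The top retained hit for one query, with check flags and notes."""

    qseqid: str
    sseqid: str
    lineage: str
    pident: float
    qcov: float
    qlen: int
    slen: int
    aln_len: int
    evalue: float
    bitscore: float
    check_identity: bool
    check_coverage: bool
    notes: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        """True when the match needs further checking by the user."""
        return self.check_identity or self.check_coverage or bool(self.notes)


def _better(a: EvaluatedHit, b: EvaluatedHit) -> bool:
    """True if a outranks b: pident desc, bitscore desc, aln_len desc,
    then sseqid ascending for full determinism."""
    ka = (a.hit.pident, a.hit.bitscore, a.hit.aln_len)
    kb = (b.hit.pident, b.hit.bitscore, b.hit.aln_len)
    if ka != kb:
        return ka > kb
    return a.hit.sseqid < b.hit.sseqid


def best_match_per_query(
    evaluated: Iterable[EvaluatedHit],
    rsl: RSL,
    threshold: float,
) -> list[BestMatch]:
    """Select the best retained hit for each query.

    One BestMatch per query with at least one retained hit, in first-
    appearance order of the queries. ``check_identity`` is set when pident
    is strictly below the similarity threshold; ``check_coverage`` when the
    computed coverage is strictly below 75%. Subject ids not found in the
    reference library keep the id itself as lineage and gain a warning note.
    """
    best: dict[str, EvaluatedHit] = {}
    order: list[str] = []
    for ev in evaluated:
        if not ev.retained:
            continue
        q = ev.hit.qseqid
        if q not in best:
            best[q] = ev
            order.append(q)
        elif _better(ev, best[q]):
            best[q] = ev
    matches: list[BestMatch] = []
    for q in order:
        ev = best[q]
        hit = ev.hit
        lineage = rsl.lineage_of(hit.sseqid)
        notes: list[str] = []
        if lineage is None:
            lineage = hit.sseqid
            notes.append(
                f"subject {hit.sseqid!r} not found in the reference library"
            )
        matches.append(BestMatch(
            qseqid=q,
            sseqid=hit.sseqid,
            lineage=lineage,
            pident=hit.pident,
            qcov=ev.qcov,
            qlen=hit.qlen,
            slen=hit.slen,
            aln_len=hit.aln_len,
            evalue=hit.evalue,
            bitscore=hit.bitscore,
            check_identity=hit.pident < threshold,
            check_coverage=ev.qcov < QCOV_MIN,
            notes=notes,
        ))
    return matches


@dataclass(frozen=True)
class CheckTag:
    """User-supplied taxa warning: substring pattern + message."""

    pattern: str
    message: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise CheckTagError("check tag with empty pattern")


def load_check_tags(path: str | Path | None) -> list[CheckTag]:
    """Load the optional 2-column taxa-warning CSV (pattern, message).

    A missing file (or None) is not an error — the feature is optional and
    yields an empty tag list. A header row ``pattern,message`` is detected
    and skipped. Empty patterns are rejected, naming the row.
    """
    if path is None:
        return []
    path = Path(path)
    if not path.exists():
        return []
    tags: list[CheckTag] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rowno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            if len(row) != 2:
                raise CheckTagError(
                    f"{path}: row {rowno}: expected 2 columns "
                    f"(pattern, message), got {len(row)}"
                )
            pattern, message = row[0].strip(), row[1].strip()
            if rowno == 1 and pattern.lower() == "pattern" \
                    and message.lower() == "message":
                continue
            if not pattern:
                raise CheckTagError(f"{path}: row {rowno}: empty pattern")
            tags.append(CheckTag(pattern=pattern, message=message))
    return tags


def apply_tags(
    matches: Sequence[BestMatch],
    tags: Sequence[CheckTag],
    case_sensitive: bool = True,
    match_lineage: bool = False,
) -> list[BestMatch]:
    """Append each tag's message to every match whose subject id contains
    the tag's pattern (substring match, case-sensitive by default).

    With ``match_lineage`` the lineage name is searched instead of the full
    subject identifier. Matches gaining a note join the further-checking set.
    """
    out: list[BestMatch] = []
    for m in matches:
        target = m.lineage if match_lineage else m.sseqid
        haystack = target if case_sensitive else target.lower()
        extra = [
            t.message
            for t in tags
            if (t.pattern if case_sensitive else t.pattern.lower()) in haystack
        ]
        out.append(replace(m, notes=list(m.notes) + extra) if extra else m)
    return out


@dataclass
class LineageRollup:
    """Per-lineage query assignment plus the below-cutoff pool."""

    by_lineage: dict[str, list[str]]
    below_cutoff: list[str]


def aggregate_by_lineage(
    matches: Sequence[BestMatch],
    rsl: RSL,
    all_query_ids: Sequence[str],
) -> LineageRollup:
    """Roll matches up by reference lineage.

    Every library lineage appears (possibly empty); every matched query is
    listed under exactly one lineage; queries with no retained hit go to
    the below-cutoff pool (the "outgroups"), preserving input order.
    """
    by_lineage: dict[str, list[str]] = {lin: [] for lin in rsl.lineages}
    matched_ids = set()
    for m in matches:
        by_lineage.setdefault(m.lineage, []).append(m.qseqid)
        matched_ids.add(m.qseqid)
    below = [q for q in all_query_ids if q not in matched_ids]
    return LineageRollup(by_lineage=by_lineage, below_cutoff=below)


@dataclass(frozen=True)
class SummaryStats:
    """Run-level statistics for the report's final sheet."""

    total_lineages: int
    taxonomic_coverage: float
    taxa_without_sample: int
    total_queries: int
    percent_processed: float
    n_below_cutoff: int


def format_percent(x: float) -> str:
    """Integer when whole, else one decimal (``28`` / ``97.5`` style)."""
    return str(int(round(x))) if abs(x - round(x)) < 1e-9 else f"{x:.1f}"


def compute_summary(
    rsl: RSL,
    matches: Sequence[BestMatch],
    below_cutoff: Sequence[str],
    total_queries: int,
) -> SummaryStats:
    """Aggregate the summary statistics.

    ``taxonomic_coverage`` is the percent of library lineages matched by at
    least one query; ``percent_processed`` is 100 exactly when every input
    query landed in the best-match set or the below-cutoff pool.
    """
    if len(matches) + len(below_cutoff) > total_queries:
        raise PipelineInternalError(
            f"{len(matches)} matches + {len(below_cutoff)} below-cutoff "
            f"exceeds {total_queries} input queries"
        )
    lineage_set = set(rsl.lineages)
    matched_lineages = {m.lineage for m in matches} & lineage_set
    total = len(lineage_set)
    coverage = 100.0 * len(matched_lineages) / total if total else 0.0
    processed = (
        100.0 * (len(matches) + len(below_cutoff)) / total_queries
        if total_queries else 100.0
    )
    return SummaryStats(
        total_lineages=total,
        taxonomic_coverage=coverage,
        taxa_without_sample=total - len(matched_lineages),
        total_queries=total_queries,
        percent_processed=processed,
        n_below_cutoff=len(below_cutoff),
    )
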