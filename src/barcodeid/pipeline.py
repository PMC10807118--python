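"""End-to-end orchestration of the five identification steps.

1. build the local search database from the reference library;
2. run the local aligner at the identity cutoff (or consume a
   pre-computed extended tabular hit file — the aligner-free seam);
3. compute query coverage, filter hits, select the best match per query;
4. flag matches below the similarity threshold or coverage floor and
   attach user-supplied taxa warnings;
5. assemble and write the four-sheet report.

Empty results are a valid outcome, never an error.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .blast_io import read_hit_table, run_local_blast
from .errors import MissingInputError, ParameterError
from .match_engine import (
    aggregate_by_lineage,
    apply_tags,
    best_match_per_query,
    compute_summary,
    filter_hits,
    load_check_tags,
    similarity_threshold,
)
from .report_writer import ReportBundle, build_report, write_spreadsheet, write_tsv
from .rsl import LineageConvention, build_search_db, load_rsl

logger = logging.getLogger("barcodeid")


@dataclass
class RunConfig:
    """Configuration of one identification run."""

    rsl_path: Path
    query_path: Path
    cutoff_pident: float = 90.0
    intersp_div: float = 3.0
    tags_path: Path | None = None
    hit_table_path: Path | None = None  # bypasses the aligner when set
    output_path: Path | None = None
    output_mode: str = "xlsx"  # "xlsx" or "tsv"
    lineage_convention: LineageConvention = "binomial"
    tags_case_sensitive: bool = True
    tags_match_lineage: bool = False
    db_prefix: Path | None = None  # reuse an existing database

    def __post_init__(self) -> None:
        self.rsl_path = Path(self.rsl_path)
        self.query_path = Path(self.query_path)
        if not (0.0 <= self.cutoff_pident <= 100.0):
            raise ParameterError(
                f"cutoff_pident must be in [0, 100], got {self.cutoff_pident}"
            )
        if not (0.0 <= self.intersp_div < 100.0):
            raise ParameterError(
                f"intersp_div must be in [0, 100), got {self.intersp_div}"
            )
        if self.output_mode not in ("xlsx", "tsv"):
            raise ParameterError(
                f"output_mode must be 'xlsx' or 'tsv', got {self.output_mode!r}"
            )


def _query_ids(query_path: Path) -> list[str]:
    if not query_path.exists():
        raise MissingInputError(f"query file not found: {query_path}")
    return [rec.id for rec in SeqIO.parse(str(query_path), "fasta")]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full workflow and (optionally) write the report.

    Returns the assembled ReportBundle; writes XLSX or TSV when
    ``config.output_path`` is set.
    """
    rsl = load_rsl(config.rsl_path, config.lineage_convention)
    logger.info("step 1: loaded reference library: %d records, %d lineages",
                len(rsl), len(rsl.lineages))

    query_ids = _query_ids(config.query_path)

    if config.hit_table_path is not None:
        raw_hits = read_hit_table(config.hit_table_path)
        # pre-computed tables obey the same contract as aligner output
        hits = [h for h in raw_hits if h.pident >= config.cutoff_pident]
        logger.info(
            "step 2: hit-table mode: %d rows read, %d at or above "
            "cutoff_pident=%g", len(raw_hits), len(hits), config.cutoff_pident)
    else:
        db = (build_search_db(config.rsl_path, config.db_prefix)
              if config.db_prefix is not None
              else build_search_db(
                  config.rsl_path,
                  Path(tempfile.mkdtemp(prefix="barcodeid_db_")) / "rsl_db"))
        logger.info("step 1: search database at %s", db.prefix)
        with tempfile.NamedTemporaryFile(
                suffix=".tsv", delete=False) as tmp:
            out = Path(tmp.name)
        run_local_blast(config.query_path, db, config.cutoff_pident, out)
        hits = [h for h in read_hit_table(out)
                if h.pident >= config.cutoff_pident]
        logger.info("step 2: aligner mode: %d hits at or above "
                    "cutoff_pident=%g", len(hits), config.cutoff_pident)

    retained = filter_hits(hits)
    logger.info("step 3: %d of %d hits pass the coverage and "
                "subject-span filters", len(retained), len(hits))

    threshold = similarity_threshold(config.intersp_div)
    logger.info("step 4: similarity threshold = 100 - %g = %g",
                config.intersp_div, threshold)
    matches = best_match_per_query(retained, rsl, threshold)
    tags = load_check_tags(config.tags_path)
    matches = apply_tags(matches, tags,
                         case_sensitive=config.tags_case_sensitive,
                         match_lineage=config.tags_match_lineage)
    n_flagged = sum(m.flagged for m in matches)
    logger.info("step 4: %d best matches, %d flagged for checking "
                "(%d taxa warnings loaded)", len(matches), n_flagged, len(tags))

    rollup = aggregate_by_lineage(matches, rsl, query_ids)
    stats = compute_summary(rsl, matches, rollup.below_cutoff, len(query_ids))
    flagged_qids = {m.qseqid for m in matches if m.flagged}
    flagged_hits = [ev for ev in retained if ev.hit.qseqid in flagged_qids]
    bundle = build_report(matches, flagged_hits, rollup, stats)
    logger.info("step 5: report assembled: %d matched, %d below cutoff, "
                "taxonomic coverage %.1f%%", len(matches),
                stats.n_below_cutoff, stats.taxonomic_coverage)

    if config.output_path is not None:
        if config.output_mode == "tsv":
            write_tsv(bundle, config.output_path)
        else:
            write_spreadsheet(bundle, config.output_path)
        logger.info("step 5: report written to %s (%s)",
                    config.output_path, config.output_mode)
    return bundle
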