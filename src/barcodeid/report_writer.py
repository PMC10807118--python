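"""Four-sheet result report: assembly, XLSX output with flag colouring,
and a TSV-per-sheet fallback for diffable, byte-stable output.

Sheet layout:

1. ``BestMatches`` — one row per query with a retained hit: best-match
   subject, lineage, %id, %qcov, alignment geometry, e-value, notes, and a
   machine-readable ``flag`` column (so the TSV fallback loses nothing).
2. ``ToCheck`` — every retained hit for the flagged queries, ordered by
   %id descending.
3. ``Lineages`` — the full library lineage list with the query ids
   assigned to each, plus the pooled below-cutoff ("outgroup") queries.
4. ``Summary`` — run-level statistics.

Identity-flagged rows are styled red, coverage-flagged rows amber;
tag-only flags are carried in the ``flag``/``notes`` columns unstyled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from openpyxl import Workbook
from openpyxl.styles import Font, PatternFill

from .errors import PipelineInternalError
from .match_engine import (
    BestMatch,
    EvaluatedHit,
    LineageRollup,
    SummaryStats,
    format_percent,
)

SHEET_NAMES = ("BestMatches", "ToCheck", "Lineages", "Summary")

BEST_MATCH_COLUMNS = (
    "qseqid", "sseqid", "lineage", "%id", "%qcov",
    "qlen", "slen", "aln_len", "evalue", "notes", "flag",
)
TO_CHECK_COLUMNS = (
    "qseqid", "sseqid", "%id", "%qcov", "qlen", "slen", "aln_len", "evalue",
)
LINEAGE_COLUMNS = ("lineage", "query_ids")
SUMMARY_COLUMNS = ("statistic", "value")

#: Label of the pooled below-cutoff row on the Lineages sheet.
BELOW_CUTOFF_LABEL = "[below cutoff_pident]"

_RED = PatternFill("solid", fgColor="FFC7CE")
_AMBER = PatternFill("solid", fgColor="FFEB9C")


@dataclass
class ReportBundle:
    """The four report sheets as DataFrames, in output order."""

    best_matches: pd.DataFrame
    to_check: pd.DataFrame
    lineages: pd.DataFrame
    summary: pd.DataFrame

    @property
    def sheets(self) -> dict[str, pd.DataFrame]:
        return dict(zip(SHEET_NAMES, (
            self.best_matches, self.to_check, self.lineages, self.summary)))


def _flag_string(m: BestMatch) -> str:
    parts = []
    if m.check_identity:
        parts.append("identity")
    if m.check_coverage:
        parts.append("coverage")
    if m.notes:
        parts.append("tag")
    return ";".join(parts)


def build_report(
    matches: Sequence[BestMatch],
    flagged_hits: Sequence[EvaluatedHit],
    rollup: LineageRollup,
    stats: SummaryStats,
) -> ReportBundle:
    """Assemble the four sheets and check their structural invariants."""
    flagged_qids = {m.qseqid for m in matches if m.flagged}
    extraneous = {ev.hit.qseqid for ev in flagged_hits} - flagged_qids
    if extraneous:
        raise PipelineInternalError(
            f"ToCheck sheet contains hits for unflagged queries: "
            f"{sorted(extraneous)}"
        )
    if len(matches) + len(rollup.below_cutoff) != stats.total_queries:
        raise PipelineInternalError(
            f"{len(matches)} best matches + {len(rollup.below_cutoff)} "
            f"below-cutoff queries != {stats.total_queries} input queries"
        )

    best = pd.DataFrame(
        [
            (m.qseqid, m.sseqid, m.lineage, m.pident, m.qcov,
             m.qlen, m.slen, m.aln_len, m.evalue,
             "; ".join(m.notes), _flag_string(m))
            for m in matches
        ],
        columns=list(BEST_MATCH_COLUMNS),
    )

    ordered = sorted(
        flagged_hits,
        key=lambda ev: (-ev.hit.pident, -ev.hit.bitscore,
                        ev.hit.qseqid, ev.hit.sseqid),
    )
    check = pd.DataFrame(
        [
            (ev.hit.qseqid, ev.hit.sseqid, ev.hit.pident, ev.qcov,
             ev.hit.qlen, ev.hit.slen, ev.hit.aln_len, ev.hit.evalue)
            for ev in ordered
        ],
        columns=list(TO_CHECK_COLUMNS),
    )

    lineage_rows = [
        (lin, ";".join(qids)) for lin, qids in rollup.by_lineage.items()
    ]
    lineage_rows.append((BELOW_CUTOFF_LABEL, ";".join(rollup.below_cutoff)))
    lineages = pd.DataFrame(lineage_rows, columns=list(LINEAGE_COLUMNS))

    summary = pd.DataFrame(
        [
            ("total lineages in RSL", str(stats.total_lineages)),
            ("taxonomic coverage (%)",
             format_percent(stats.taxonomic_coverage)),
            ("taxa without a sample", str(stats.taxa_without_sample)),
            ("total input sequences", str(stats.total_queries)),
            ("sequences processed (%)",
             format_percent(stats.percent_processed)),
            ("results below cutoff_pident", str(stats.n_below_cutoff)),
        ],
        columns=list(SUMMARY_COLUMNS),
    )
    return ReportBundle(best, check, lineages, summary)


def write_spreadsheet(bundle: ReportBundle, path: str | Path) -> Path:
    """Write the bundle as one XLSX workbook with four named sheets.

    Identity-flagged rows get a red fill, coverage-only flags amber; the
    header row is bold and frozen on every sheet.
    """
    path = Path(path)
    wb = Workbook()
    wb.remove(wb.active)
    for name, df in bundle.sheets.items():
        ws = wb.create_sheet(title=name)
        ws.append(list(df.columns))
        for cell in ws[1]:
            cell.font = Font(bold=True)
        ws.freeze_panes = "A2"
        for _, row in df.iterrows():
            ws.append(list(row))
        if name == "BestMatches" and len(df):
            flag_col = list(df.columns).index("flag")
            for i, flag in enumerate(df["flag"], start=2):
                fill = None
                if "identity" in flag:
                    fill = _RED
                elif "coverage" in flag:
                    fill = _AMBER
                if fill is not None:
                    for cell in ws[i]:
                        cell.fill = fill
    wb.save(path)
    return path


def write_tsv(bundle: ReportBundle, base_path: str | Path) -> list[Path]:
    """Write one TSV per sheet, suffixed with the sheet name.

    Output is byte-identical across runs for identical inputs.
    """
    base_path = Path(base_path)
    stem = base_path.with_suffix("") if base_path.suffix else base_path
    paths = []
    for name, df in bundle.sheets.items():
        out = stem.parent / f"{stem.name}_{name}.tsv"
        df.to_csv(out, sep="\t", index=False, lineterminator="\n")
        paths.append(out)
    return paths
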