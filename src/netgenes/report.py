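"""Prediction tables: genes whose predicted essentiality probability reaches
the 70% threshold, scored on a 70.0–100.0 scale (probability × 100, one
decimal), annotated and written as per-organism CSV files.
"""

from __future__ import annotations

import csv
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .io import AnnotationTable

logger = logging.getLogger("netgenes")

DEFAULT_THRESHOLD = 0.70

CSV_HEADER = ("gene_id", "preferred_name", "function", "essentiality_score")


@dataclass
class PredictionRow:
    gene_id: str
    preferred_name: str
    function: str
    essentiality_score: float


@dataclass
class PredictionTable:
    organism: str
    rows: list[PredictionRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def validate(self) -> None:
        seen = set()
        prev = None
        for row in self.rows:
            if not 70.0 <= row.essentiality_score <= 100.0:
                raise ValueError(
                    f"score {row.essentiality_score} outside [70.0, 100.0]"
                )
            if row.gene_id in seen:
                raise ValueError(f"duplicate gene {row.gene_id}")
            seen.add(row.gene_id)
            key = (-row.essentiality_score, row.gene_id)
            if prev is not None and key < prev:
                raise ValueError("rows not sorted by descending score, then gene id")
            prev = key


def classify_and_score(
    probs: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    organism: str = "",
    annotations: AnnotationTable | None = None,
) -> PredictionTable:
    """Keep genes with probability >= threshold (inclusive) and convert to
    essentiality scores.

    The score is the probability times 100, rounded to one decimal, so the
    emitted range is [100*threshold, 100.0].
    """
    ann = annotations or AnnotationTable()
    rows = []
    for gene, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} for {gene} outside [0, 1]")
        if p >= threshold:
            name, function = ann.lookup(gene)
            rows.append(
                PredictionRow(
                    gene_id=gene,
                    preferred_name=name,
                    function=function,
                    essentiality_score=round(p * 100.0, 1),
                )
            )
    rows.sort(key=lambda r: (-r.essentiality_score, r.gene_id))
    table = PredictionTable(organism=organism, rows=rows)
    logger.info(
        "%s: %d of %d genes at or above threshold %.2f",
        organism or "<unnamed>", len(rows), len(probs), threshold,
    )
    return table


def write_predictions_csv(
    table: PredictionTable,
    path: str | Path,
    annotations: AnnotationTable | None = None,
) -> None:
    """Write the table as ``gene_id,preferred_name,function,essentiality_score``.

    If ``annotations`` is given, names/functions are (re-)resolved through
    it; unannotated genes fall back to the gene id and ``"NA"``.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for row in table.rows:
            name, function = row.preferred_name, row.function
            if annotations is not None:
                name, function = annotations.lookup(row.gene_id)
            writer.writerow([row.gene_id, name, function, f"{row.essentiality_score:.1f}"])


def read_predictions_csv(path: str | Path, organism: str = "") -> PredictionTable:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != CSV_HEADER:
            raise ValueError(f"unexpected header {header}")
        for rec in reader:
            rows.append(
                PredictionRow(
                    gene_id=rec[0],
                    preferred_name=rec[1],
                    function=rec[2],
                    essentiality_score=float(rec[3]),
                )
            )
    return PredictionTable(organism=organism or Path(path).stem, rows=rows)


def bundle_zip(csv_paths: list[str | Path], zip_path: str | Path) -> None:
    """Bundle per-organism prediction CSVs into one downloadable archive."""
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for p in csv_paths:
            zf.write(p, arcname=Path(p).name)
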