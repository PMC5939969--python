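"""File formats: FASTA sequences, delimited datasets, prediction tables.

Datasets are comma-separated with a header row and required columns
``id``, ``sequence``, ``experimental_pi`` plus optional ``fraction`` and
``modifications`` (the ``phospho@3;acetyl@nterm`` dialect).  Rows whose
experimental pI is null or non-numeric are dropped with a logged count —
silent nulls are a classic way to corrupt a benchmark.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataFileError, SchemaError, SequenceError
from .modifications import ModifiedSequence, parse_annotations
from .records import DatasetRecord, PredictionRecord

logger = logging.getLogger("ampholyte")

REQUIRED_COLUMNS = ("id", "sequence", "experimental_pi")


def read_fasta(path: str | Path) -> list[tuple[str, ModifiedSequence]]:
    """Parse FASTA; id = header token before the first whitespace.

    Sequences are uppercased and alphabet-validated; duplicate ids and
    empty (header-only) records are rejected, naming the offending record.
    """
    path = Path(path)
    out: list[tuple[str, ModifiedSequence]] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise DataFileError(f"{path}: record {i} has an empty header")
        if rec.id in seen:
            raise DataFileError(f"{path}: duplicate id {rec.id!r} (record {i})")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise DataFileError(
                f"{path}: record {i} ({rec.id!r}) is header-only (no sequence)"
            )
        try:
            out.append((rec.id, ModifiedSequence(raw)))
        except SequenceError as exc:
            raise DataFileError(f"{path}: record {i} ({rec.id!r}): {exc}") from exc
    if not out:
        raise DataFileError(f"{path}: no FASTA records found")
    return out


def write_fasta(pairs: Iterable[tuple[str, ModifiedSequence]], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(mseq.residues), id=str(sid), description="")
        for sid, mseq in pairs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_dataset(path: str | Path, delimiter: str = ",") -> list[DatasetRecord]:
    """Read a benchmark dataset table, dropping null experimental values.

    The dropped-row count is logged at INFO level (null-value detection);
    a missing required column raises :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    pis = pd.to_numeric(df["experimental_pi"], errors="coerce")
    keep = pis.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) with null/non-numeric experimental pI",
                    path, n_dropped)
    records: list[DatasetRecord] = []
    for idx in df.index[keep]:
        row = df.loc[idx]
        mods = row.get("modifications") if "modifications" in df.columns else None
        mseq = parse_annotations(str(row["sequence"]), mods if pd.notna(mods) else None)
        frac = row.get("fraction") if "fraction" in df.columns else None
        records.append(
            DatasetRecord(
                id=str(row["id"]),
                sequence=mseq,
                experimental_pi=float(pis.loc[idx]),
                fraction=str(frac) if frac is not None and pd.notna(frac) else None,
                source=None,
            )
        )
    return records


def write_dataset(records: Sequence[DatasetRecord], path: str | Path,
                  fasta_path: str | Path | None = None) -> None:
    """Write records in the same dialect ``read_dataset`` reads.

    Optionally writes the sequences as FASTA alongside.
    """
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "sequence": r.sequence.residues,
                "experimental_pi": r.experimental_pi,
                "fraction": r.fraction if r.fraction is not None else "",
                "modifications": r.sequence.annotation_string(),
                "source": r.source if r.source is not None else "",
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    if fasta_path is not None:
        # one FASTA entry per unique id (proteins may repeat across rows)
        seen: dict[str, ModifiedSequence] = {}
        for r in records:
            seen.setdefault(r.id, r.sequence)
        write_fasta(seen.items(), fasta_path)


def write_predictions(records: Sequence[PredictionRecord], path: str | Path,
                      full_precision: bool = False) -> None:
    """One row per input sequence; failures are rows with a reason, not gaps.

    pIs print to 2 decimals by default (full precision via flag); internal
    computation always keeps full precision.
    """
    rows = []
    for r in records:
        pi = r.predicted_pi
        if pi is not None and not full_precision:
            pi = round(pi, 2)
        rows.append(
            {
                "id": r.id,
                "method": r.method,
                "pka_set_or_variant": r.pka_set_or_variant,
                "predicted_pi": pi if pi is not None else "",
                "failure_reason": r.failure_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
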