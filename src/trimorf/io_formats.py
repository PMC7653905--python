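"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text. Coordinates in every file (and in every
error message) are 1-based with inclusive interval ends.

Formats
-------
* FASTA — sequences (via Bio.SeqIO).
* Annotation TSV — columns ``seq_id``, ``start``, ``end``; one row per
  MoRF interval.
* Native structural TSV — header ``index  aa  <channel> ...`` with one
  row per residue; channel names from :data:`trimorf.types.CHANNELS`.
* SPIDER2-style table — best-effort column mapping of SPIDER2 ``.spd3``
  + HSE output headers onto the native channel names (see
  ``SPIDER2_COLUMN_MAP``). SPIDER2 ships its predictions across
  several files whose exact concatenation varies between releases, so
  this dialect accepts any whitespace-separated headered table whose
  column names appear in the map.
* Score-track TSV — columns ``seq_id``, ``position``, ``residue``,
  ``score`` (6 decimals), ``stage``.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import CHANNELS, VALID_RESIDUES, AnnotatedSequence, ScoreTrack, StructuralTrace


class ParseError(ValueError):
    """A file failed validation; the message names the record/row."""


#: Best-effort mapping of SPIDER2 output column headers to native
#: channel names.  Keys are matched case-insensitively after stripping
#: a leading '#'.
SPIDER2_COLUMN_MAP = {
    "p(h)": "SS_H",
    "p(e)": "SS_E",
    "p(c)": "SS_C",
    "asa": "ASA",
    "phi": "PHI",
    "psi": "PSI",
    "theta": "THETA",
    "theta(i-1=>i+1)": "THETA",
    "tau": "TAU",
    "tau(i-2=>i+2)": "TAU",
    "hseu": "HSEa_up",
    "hsed": "HSEa_dn",
    "hsea_up": "HSEa_up",
    "hsea_down": "HSEa_dn",
    "hseau": "HSEa_up",
    "hsead": "HSEa_dn",
    "hseb_up": "HSEb_up",
    "hseb_down": "HSEb_dn",
    "hsebu": "HSEb_up",
    "hsebd": "HSEb_dn",
    "cn": "CN",
}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, residues)`` pairs in file order.

    Residues are upper-cased and whitespace is stripped.  Raises
    :class:`ParseError` for an empty file, duplicate ids, or characters
    outside the 20-letter amino-acid alphabet plus X.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).strip().upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in VALID_RESIDUES:
                raise ParseError(
                    f"{path}: record {rec.id!r} position {pos}: "
                    f"invalid residue {ch!r}"
                )
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, seq))
    return out


def write_fasta(pairs: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in pairs:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MoRF annotations


def read_morf_annotations(
    path: str | os.PathLike,
    sequences: Sequence[tuple[str, str]],
) -> list[AnnotatedSequence]:
    """Apply an interval annotation table to sequences.

    The table is a TSV with columns ``seq_id``, ``start``, ``end``
    (1-based, inclusive).  Sequences with no rows get all-false labels.
    Out-of-bounds or overlapping intervals and unknown ids raise
    :class:`ParseError`.
    """
    table = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    required = {"seq_id", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    lengths = {sid: len(seq) for sid, seq in sequences}
    labels = {sid: np.zeros(n, dtype=bool) for sid, n in lengths.items()}
    for row in table.itertuples(index=False):
        sid, start, end = str(row.seq_id), int(row.start), int(row.end)
        if sid not in lengths:
            raise ParseError(f"{path}: unknown seq_id {sid!r}")
        n = lengths[sid]
        if not 1 <= start <= end <= n:
            raise ParseError(
                f"{path}: interval [{start}, {end}] out of bounds for "
                f"{sid!r} (length {n})"
            )
        span = labels[sid][start - 1:end]
        if span.any():
            raise ParseError(
                f"{path}: overlapping intervals on {sid!r} near "
                f"[{start}, {end}]"
            )
        span[:] = True
    return [
        AnnotatedSequence(id=sid, residues=seq, labels=labels[sid])
        for sid, seq in sequences
    ]


def write_morf_annotations(
    annotated: Iterable[AnnotatedSequence], path: str | os.PathLike
) -> None:
    """Write MoRF runs as a seq_id/start/end TSV (1-based inclusive)."""
    rows = []
    for seq in annotated:
        for start, end in seq.morf_runs():
            rows.append((seq.id, start, end))
    pd.DataFrame(rows, columns=["seq_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Structural tables


def read_structural_table(
    path: str | os.PathLike,
    dialect: str = "native",
    seq_id: str | None = None,
    sequence: str | None = None,
) -> StructuralTrace:
    """Read a per-residue structural-attribute table.

    ``native`` expects a tab-separated file with header columns
    ``index``, ``aa`` and channel names; ``spider2`` accepts any
    whitespace-separated headered table and maps recognised SPIDER2
    column names onto channels (best effort — see module docstring).

    If ``sequence`` is given, the table's amino-acid column is checked
    against it row by row.
    """
    if dialect not in ("native", "spider2"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "native":
        table = pd.read_csv(path, sep="\t")
        colmap = {c: c for c in table.columns if c in CHANNELS}
    else:
        with open(path) as fh:
            text = fh.read()
        lines = text.splitlines()
        if lines and lines[0].lstrip().startswith("#"):
            lines[0] = lines[0].lstrip().lstrip("#")
        table = pd.read_csv(io.StringIO("\n".join(lines)), sep=r"\s+")
        colmap = {}
        for col in table.columns:
            target = SPIDER2_COLUMN_MAP.get(col.strip().lower())
            if target is not None and target not in colmap.values():
                colmap[col] = target

    if not colmap:
        raise ParseError(f"{path}: no recognised channel columns")

    aa_col = next(
        (c for c in table.columns if c.strip().lower() in ("aa", "amino_acid", "seq")),
        None,
    )
    if sequence is not None and aa_col is not None:
        if len(table) != len(sequence):
            raise ParseError(
                f"{path}: {len(table)} rows for sequence of length "
                f"{len(sequence)}"
            )
        for i, (a, b) in enumerate(zip(table[aa_col].astype(str), sequence), start=1):
            if a.upper() != b.upper():
                raise ParseError(
                    f"{path}: amino acid mismatch at row {i}: "
                    f"table has {a!r}, sequence has {b!r}"
                )
    elif sequence is not None and len(table) != len(sequence):
        raise ParseError(
            f"{path}: {len(table)} rows for sequence of length {len(sequence)}"
        )

    # fixed canonical channel order regardless of file column order
    channels = tuple(c for c in CHANNELS if c in colmap.values())
    inverse = {v: k for k, v in colmap.items()}
    columns = []
    for ch in channels:
        col = pd.to_numeric(table[inverse[ch]], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric value in column {inverse[ch]!r} "
                f"at row {bad[0] + 1}"
            )
        columns.append(col)
    sid = seq_id if seq_id is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return StructuralTrace(seq_id=sid, channels=channels,
                           values=np.column_stack(columns))


def write_structural_table(
    trace: StructuralTrace, path: str | os.PathLike, sequence: str | None = None
) -> None:
    """Write a trace in the native TSV dialect (values to 6 decimals)."""
    n = len(trace)
    aa = list(sequence) if sequence is not None else ["X"] * n
    if len(aa) != n:
        raise ValueError("sequence length does not match trace rows")
    frame = pd.DataFrame({"index": np.arange(1, n + 1), "aa": aa})
    for j, ch in enumerate(trace.channels):
        frame[ch] = trace.values[:, j]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Score tracks


def write_score_track(track: ScoreTrack, path: str | os.PathLike,
                      mode: str = "w") -> None:
    """Write one score track as TSV (see module docstring for columns)."""
    n = len(track)
    residues = track.residues if track.residues is not None else "X" * n
    frame = pd.DataFrame({
        "seq_id": track.seq_id,
        "position": np.arange(1, n + 1),
        "residue": list(residues),
        "score": track.scores,
        "stage": track.stage,
    })
    header = mode == "w" or not (os.path.exists(path) and os.path.getsize(path))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f",
                 mode=mode, header=header)


def read_score_track(path: str | os.PathLike) -> list[ScoreTrack]:
    """Read a score-track TSV; returns one track per seq_id, file order."""
    table = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "residue": str})
    required = {"seq_id", "position", "residue", "score", "stage"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if table.empty:
        raise ParseError(f"{path}: score-track file has no rows")
    tracks = []
    for sid, group in table.groupby("seq_id", sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_numpy(int)
        if not np.array_equal(positions, np.arange(1, len(group) + 1)):
            raise ParseError(f"{path}: positions for {sid!r} are not 1..n")
        stages = group["stage"].unique()
        if len(stages) != 1:
            raise ParseError(f"{path}: mixed stages for {sid!r}")
        tracks.append(ScoreTrack(
            seq_id=str(sid),
            scores=group["score"].to_numpy(float),
            stage=str(stages[0]),
            residues="".join(group["residue"].astype(str)),
        ))
    return tracks
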