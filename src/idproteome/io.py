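"""Readers and writers for the pipeline's three file kinds.

Formats
-------
FASTA
    Standard multi-line FASTA; the first whitespace-delimited token of a
    ``>`` header is the protein id.  Read/written through ``Bio.SeqIO``.
Score-track TSV
    Tab-separated columns ``protein_id  predictor  residue_index  score``
    with ``#`` comment lines ignored.  Residue indices are 1-based in files
    and must form a contiguous run 1..L per (protein, predictor); scores
    lie in [0, 1].  Internally tracks are 0-based numpy arrays.
Expression TSV
    Two metadata header lines ``#pool_id=<id>`` and ``#mean_age=<years>``
    followed by ``protein_id  abundance`` rows.

Ambiguous residues (B, Z, X, U, O and anything else non-canonical) are
handled per a configurable policy, since upstream proteome sets routinely
contain them:

* ``strict`` — raise;
* ``drop_ambiguous`` (default) — remove them with a logged warning;
* ``map_to_nearest`` — B→N, Z→Q, U→C, O→K, and drop X.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    CANONICAL_RESIDUES,
    DisorderTrack,
    ExpressionTable,
    ProteinRecord,
    ProteomeGroup,
    ValidationError,
)

logger = logging.getLogger(__name__)

AmbiguousPolicy = Literal["strict", "drop_ambiguous", "map_to_nearest"]

_NEAREST = {"B": "N", "Z": "Q", "U": "C", "O": "K"}


def normalize_sequence(
    raw: str, policy: AmbiguousPolicy = "drop_ambiguous", label: str = "?"
) -> str:
    """Uppercase a raw sequence and resolve non-canonical letters.

    ``label`` only decorates log/error messages.
    """
    if policy not in ("strict", "drop_ambiguous", "map_to_nearest"):
        raise ValueError(f"unknown ambiguous-residue policy {policy!r}")
    seq = raw.upper().replace("*", "").replace("-", "")
    bad = sorted(set(seq) - set(CANONICAL_RESIDUES))
    if not bad:
        return seq
    if policy == "strict":
        raise ValidationError(f"{label}: non-canonical residues {bad} (strict policy)")
    if policy == "drop_ambiguous":
        logger.warning("%s: dropping %d non-canonical residue(s) %s",
                       label, sum(seq.count(c) for c in bad), bad)
        return "".join(c for c in seq if c in CANONICAL_RESIDUES)
    if policy == "map_to_nearest":
        mapped = "".join(_NEAREST.get(c, c) for c in seq)
        dropped = sorted(set(mapped) - set(CANONICAL_RESIDUES))
        if dropped:
            logger.warning("%s: dropping unmappable residue(s) %s", label, dropped)
        return "".join(c for c in mapped if c in CANONICAL_RESIDUES)
    raise AssertionError("unreachable")


def read_fasta(
    path: str | Path,
    name: str | None = None,
    policy: AmbiguousPolicy = "drop_ambiguous",
) -> ProteomeGroup:
    """Read a FASTA file into a :class:`ProteomeGroup`.

    The group name defaults to the file stem.  Duplicate ids, empty files
    and (under ``strict``) non-canonical residues raise ``ValidationError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValidationError(f"{path}: duplicate id {pid!r}")
        seen.add(pid)
        seq = normalize_sequence(str(rec.seq), policy, label=pid)
        if not seq:
            raise ValidationError(f"{path}: record {pid!r} empty after normalization")
        records.append(ProteinRecord(id=pid, sequence=seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return ProteomeGroup(name=name or path.stem, records=records)


def write_fasta(group: ProteomeGroup, path: str | Path, width: int = 60) -> None:
    """Write a proteome group as wrapped FASTA."""
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in group]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_score_tracks(path: str | Path) -> list[DisorderTrack]:
    """Read a score-track TSV into per-(protein, predictor) tracks.

    Verifies residue contiguity 1..L and score bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["protein_id", "predictor", "residue_index", "score"],
        dtype={"protein_id": str, "predictor": str},
    )
    if df.empty:
        raise ValidationError(f"{path}: no score rows")
    if df["score"].isna().any() or df["residue_index"].isna().any():
        raise ValidationError(f"{path}: non-numeric score or index")
    tracks: list[DisorderTrack] = []
    for (pid, pred), sub in df.groupby(["protein_id", "predictor"], sort=False):
        sub = sub.sort_values("residue_index")
        idx = sub["residue_index"].to_numpy(dtype=int)
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(idx, expected):
            raise ValidationError(
                f"{path}: {pid}/{pred}: residue indices not contiguous 1..L "
                f"(got {idx.min()}..{idx.max()}, n={len(idx)})"
            )
        scores = sub["score"].to_numpy(dtype=float)
        if scores.min() < 0 or scores.max() > 1:
            raise ValidationError(f"{path}: {pid}/{pred}: score outside [0, 1]")
        tracks.append(DisorderTrack(protein_id=pid, predictor=pred, scores=scores))
    return tracks


def write_score_tracks(tracks: Iterable[DisorderTrack], path: str | Path) -> None:
    """Write tracks in the TSV dialect :func:`read_score_tracks` reads."""
    with open(path, "w") as fh:
        fh.write("# protein_id\tpredictor\tresidue_index\tscore\n")
        for t in tracks:
            for i, s in enumerate(t.scores, start=1):
                fh.write(f"{t.protein_id}\t{t.predictor}\t{i}\t{s:.6f}\n")


def check_track_lengths(
    group: ProteomeGroup, tracks: Iterable[DisorderTrack]
) -> None:
    """Raise if any track length disagrees with its protein's sequence length.

    A mismatch is an error, never a truncation: silently clipping a track
    would corrupt every downstream average.
    """
    lengths = {r.id: len(r) for r in group}
    for t in tracks:
        L = lengths.get(t.protein_id)
        if L is not None and L != len(t):
            raise ValidationError(
                f"{t.protein_id}/{t.predictor}: track length {len(t)} != "
                f"sequence length {L}"
            )


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read one pool's expression TSV (see module docstring for the dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pool_id: str | None = None
    mean_age: float | None = None
    abundance: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("pool_id="):
                    pool_id = body.split("=", 1)[1].strip()
                elif body.startswith("mean_age="):
                    mean_age = float(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            pid, raw = parts
            try:
                a = float(raw)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric abundance") from exc
            if pid in abundance:
                raise ValidationError(f"{path}:{lineno}: duplicate protein {pid!r}")
            abundance[pid] = a
    if pool_id is None or mean_age is None:
        raise ValidationError(
            f"{path}: malformed header — '#pool_id=' and '#mean_age=' lines required"
        )
    if not abundance:
        raise ValidationError(f"{path}: no proteins in pool")
    return ExpressionTable(pool_id=pool_id, mean_age=mean_age, abundance=abundance)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#pool_id={table.pool_id}\n")
        fh.write(f"#mean_age={table.mean_age}\n")
        for pid, a in table.abundance.items():
            fh.write(f"{pid}\t{a:.6g}\n")
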