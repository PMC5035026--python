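"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* multi-record FASTA (wrapped lines, ``>`` headers) for protein sequences;
* the PSI-BLAST ``-out_ascii_pssm`` dialect for per-protein profiles;
* FASTA-like annotation files carrying secondary-structure strings (H/E/C)
  or per-residue relative-solvent-accessibility fractions;
* comma-delimited feature tables with a name/group schema;
* a flat key-value model manifest.

All 20-wide structures use one canonical alphabetical amino-acid ordering
(:data:`AMINO_ACIDS`); PSSM columns are re-mapped to it at parse time so a
column index always means the same residue everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

#: Canonical alphabetical ordering of the 20 standard amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: The three secondary-structure states: helix, strand, coil.
SS_STATES: str = "HEC"

#: Feature group tags, in vector order.
FEATURE_GROUPS: tuple[str, ...] = ("SSI", "RSA", "CTD", "PSSM")


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: identifier plus validated amino-acid sequence.

    The sequence must have length >= 2 and contain only the 20 standard
    uppercase amino-acid letters; lowercase input is uppercased first.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise FormatError(f"record {self.id!r}: sequence length {len(seq)} < 2")
        for pos, letter in enumerate(seq, start=1):
            if letter not in AA_INDEX:
                raise FormatError(
                    f"record {self.id!r}: non-standard residue {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SsAnnotation:
    """Per-residue three-state secondary structure, a string over {H,E,C}."""

    elements: str

    def __post_init__(self) -> None:
        for pos, s in enumerate(self.elements, start=1):
            if s not in SS_STATES:
                raise FormatError(
                    f"secondary-structure letter {s!r} at position {pos} not in {{H,E,C}}"
                )

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class RsaAnnotation:
    """Per-residue relative solvent accessibility, fractions in [0, 1].

    The binary buried/exposed state is derived downstream from ``threshold``
    (a residue is exposed iff its value >= threshold); only the real-valued
    trace is stored because the encoders need both the scores and the states.
    """

    values: tuple[float, ...]
    threshold: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not 0.0 < self.threshold < 1.0:
            raise FormatError(f"RSA threshold {self.threshold} not in (0, 1)")
        for pos, v in enumerate(self.values, start=1):
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"RSA value {v} at position {pos} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PssmMatrix:
    """An L x 20 position-specific scoring matrix in canonical column order.

    ``scores[i, j]`` is the log-odds of residue i substituting to amino acid
    ``AMINO_ACIDS[j]``.
    """

    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.int64)
        if arr.ndim != 2 or arr.shape != (len(self.residues), 20):
            raise FormatError(
                f"PSSM shape {arr.shape} does not match sequence length "
                f"{len(self.residues)} x 20"
            )
        object.__setattr__(self, "scores", arr)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FeatureTable:
    """n_samples x n_features matrix with a name/group schema and optional labels."""

    values: np.ndarray
    feature_names: list[str]
    group_tags: list[str]
    ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("feature table values must be 2-D")
        n, d = self.values.shape
        if not (len(self.feature_names) == len(self.group_tags) == d):
            raise FormatError(
                f"schema mismatch: {d} columns, {len(self.feature_names)} names, "
                f"{len(self.group_tags)} group tags"
            )
        if len(self.ids) != n:
            raise FormatError(f"{n} rows but {len(self.ids)} ids")
        bad = set(self.group_tags) - set(FEATURE_GROUPS)
        if bad:
            raise FormatError(f"unknown group tags {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("feature table contains NaN/Inf entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise FormatError("labels length does not match row count")
            if not np.isin(self.labels, [0, 1]).all():
                raise FormatError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices belonging to one feature group (SSI/RSA/CTD/PSSM)."""
        return np.flatnonzero(np.asarray(self.group_tags) == np.asarray(group))


@dataclass
class ReadReport:
    """Bookkeeping for lenient reads: skipped records and deduplicated ids."""

    skipped: list[tuple[str, str]] = field(default_factory=list)
    renamed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.skipped) + len(self.renamed)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _iter_fasta(handle: Iterable[str]):
    header: str | None = None
    chunks: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            chunks = []
        else:
            if header is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path, strict: bool = True) -> tuple[list[ProteinRecord], ReadReport]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` s.

    With ``strict`` on, any record containing a non-standard letter raises
    :class:`FormatError` naming the residue and position; with ``strict`` off
    such records are skipped and counted in the returned report.  Duplicate
    identifiers are suffix-deduplicated (``id.2``, ``id.3``, ...) and reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    report = ReadReport()
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        entries = list(_iter_fasta(fh))
    if not entries:
        raise FormatError(f"empty FASTA file: {path}")
    for rid, seq in entries:
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.{seen[rid]}"
            report.renamed.append((rid, new_id))
            rid = new_id
        else:
            seen[rid] = 1
        try:
            records.append(ProteinRecord(rid, seq))
        except FormatError as exc:
            if strict:
                raise
            report.skipped.append((rid, str(exc)))
    return records, report


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(path: str | Path, record: ProteinRecord) -> PssmMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file aligned to ``record``.

    The dialect has two blank/header lines, a column-header line listing the
    20 amino acids (once for the 20-column log-odds dialect, twice when the
    weighted-percentage block is also present), then one row per residue:
    position index, residue letter, and >= 20 integer score columns.  Only
    the first 20 columns (the log-odds block) are retained, re-mapped from
    file column order to the canonical alphabetical ordering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSSM file not found: {path}")
    lines = path.read_text().splitlines()

    header_order: list[str] | None = None
    rows: list[tuple[int, str, list[int]]] = []
    for line in lines:
        toks = line.split()
        if not toks:
            continue
        if header_order is None:
            # column-header line: >= 20 single amino-acid letters
            letters = [t for t in toks if len(t) == 1 and t in AA_INDEX]
            if len(letters) >= 20:
                header_order = letters[:20]
            continue
        if toks[0].isdigit() and len(toks) >= 22 and toks[1] in AA_INDEX:
            try:
                scores = [int(t) for t in toks[2:22]]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: non-integer score cell in row {toks[0]}: {exc}"
                ) from None
            rows.append((int(toks[0]), toks[1], scores))
    if header_order is None:
        raise FormatError(f"{path.name}: no PSSM column-header line found")
    if sorted(header_order) != list(AMINO_ACIDS):
        raise FormatError(f"{path.name}: header is not a permutation of the 20 amino acids")
    if len(rows) != len(record):
        raise FormatError(
            f"{path.name}: {len(rows)} PSSM rows but record {record.id!r} "
            f"has length {len(record)}"
        )
    residues = "".join(r[1] for r in rows)
    for pos, (got, expected) in enumerate(zip(residues, record.sequence), start=1):
        if got != expected:
            raise FormatError(
                f"{path.name}: residue mismatch for record {record.id!r} at "
                f"position {pos}: PSSM has {got!r}, sequence has {expected!r}"
            )
    raw = np.array([r[2] for r in rows], dtype=np.int64)
    # re-map file column order -> canonical alphabetical order
    perm = [header_order.index(a) for a in AMINO_ACIDS]
    return PssmMatrix(residues=residues, scores=raw[:, perm])


def write_pssm_ascii(pssm: PssmMatrix, path: str | Path, record_id: str = "") -> None:
    """Write a PSSM in the PSI-BLAST ASCII log-odds dialect (20 columns)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(AMINO_ACIDS) + "\n")
        for i, (res, row) in enumerate(zip(pssm.residues, pssm.scores), start=1):
            cells = " ".join(f"{v:4d}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")


# ---------------------------------------------------------------------------
# SS / RSA annotations (FASTA-like, keyed by record id)
# ---------------------------------------------------------------------------

def _read_fasta_like(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    with open(path) as fh:
        return {rid: payload for rid, payload in _iter_fasta_payload(fh)}


def _iter_fasta_payload(handle: Iterable[str]):
    header: str | None = None
    chunks: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                yield header, " ".join(chunks)
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            chunks = []
        elif line.strip():
            if header is None:
                raise FormatError("payload before first header in annotation file")
            chunks.append(line.strip())
    if header is not None:
        yield header, " ".join(chunks)


def read_annotation(
    path: str | Path,
    kind: Literal["ss", "rsa"],
    record: ProteinRecord,
    threshold: float = 0.25,
) -> SsAnnotation | RsaAnnotation:
    """Read one record's SS or RSA annotation from a FASTA-like file.

    SS payloads are H/E/C strings (wrapped lines concatenated); RSA payloads
    are whitespace-separated reals in [0, 1].  Length is checked against the
    record.
    """
    entries = _read_fasta_like(path)
    if record.id not in entries:
        raise FormatError(f"record {record.id!r} not found in {Path(path).name}")
    payload = entries[record.id]
    if kind == "ss":
        ss = payload.replace(" ", "")
        if len(ss) != len(record):
            raise FormatError(
                f"record {record.id!r}: SS length {len(ss)} != sequence length {len(record)}"
            )
        return SsAnnotation(ss)
    if kind == "rsa":
        try:
            vals = [float(t) for t in payload.split()]
        except ValueError:
            raise FormatError(f"record {record.id!r}: non-numeric RSA value") from None
        if len(vals) != len(record):
            raise FormatError(
                f"record {record.id!r}: RSA length {len(vals)} != sequence length {len(record)}"
            )
        return RsaAnnotation(tuple(vals), threshold=threshold)
    raise ValueError(f"unknown annotation kind {kind!r}")


def write_annotation(
    entries: dict[str, str | Sequence[float]], path: str | Path, kind: Literal["ss", "rsa"]
) -> None:
    """Write SS strings or RSA traces as a FASTA-like annotation file."""
    with open(path, "w") as fh:
        for rid, payload in entries.items():
            fh.write(f">{rid}\n")
            if kind == "ss":
                fh.write(str(payload) + "\n")
            else:
                fh.write(" ".join(f"{float(v):.17g}" for v in payload) + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_ID_COL = "id"
_LABEL_COL = "label"
_GROUP_SEP = "|"


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as comma-delimited text.

    Header cells encode ``group|name`` so the schema round-trips; values are
    written with 17 significant digits (lossless for float64).
    """
    cols = [f"{g}{_GROUP_SEP}{n}" for g, n in zip(table.group_tags, table.feature_names)]
    df = pd.DataFrame(table.values, columns=cols)
    df.insert(0, _ID_COL, table.ids)
    if table.labels is not None:
        df[_LABEL_COL] = table.labels
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read back a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if _ID_COL not in df.columns:
        raise FormatError(f"{path.name}: missing {_ID_COL!r} column")
    labels = None
    if _LABEL_COL in df.columns:
        labels = df.pop(_LABEL_COL).to_numpy()
    ids = df.pop(_ID_COL).astype(str).tolist()
    groups: list[str] = []
    names: list[str] = []
    for col in df.columns:
        if _GROUP_SEP not in col:
            raise FormatError(f"{path.name}: column {col!r} lacks a group tag")
        g, n = col.split(_GROUP_SEP, 1)
        groups.append(g)
        names.append(n)
    values = df.to_numpy(dtype=float) if len(df) else np.empty((0, len(names)))
    return FeatureTable(values, names, groups, ids, labels)


# ---------------------------------------------------------------------------
# Model manifest (flat key-value text)
# ---------------------------------------------------------------------------

def write_manifest(entries: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}\t{value}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        out[key] = value
    return out
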