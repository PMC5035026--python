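"""Hybrid feature encoders for antioxidant-protein prediction.

Each annotated protein is mapped to a fixed 759-dimensional vector:

* 21 secondary-structure (SSI) descriptors — per-state content, all 9 ordered
  state-pair transition frequencies, average and normalized-maximal segment
  lengths, and position-order statistics;
* 28 relative-solvent-accessibility (RSA) descriptors — global mean/std,
  buried/exposed segment counts and extremal lengths, per-amino-acid means;
* 310 composition/transition/distribution (CTD) descriptors over the raw
  amino-acid alphabet;
* 400 PSSM descriptors — the L x 20 profile collapsed to 20 x 20 by summing
  rows that share a residue identity.

Conventions applied uniformly: positions are 1-based, every statistic over an
empty set (no run of a state, amino acid absent from the sequence) is 0 so
vectors are always finite and fixed-length, and compositions are fractions in
[0, 1] rather than percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    AA_INDEX,
    FeatureTable,
    ProteinRecord,
    PssmMatrix,
    RsaAnnotation,
    SsAnnotation,
)

SS_STATES = "HEC"

SSI_DIM = 21
RSA_DIM = 28
CTD_DIM = 310
PSSM_DIM = 400
HYBRID_DIM = SSI_DIM + RSA_DIM + CTD_DIM + PSSM_DIM


@dataclass(frozen=True)
class FeatureVector:
    """A named feature vector with one group tag per entry."""

    values: np.ndarray
    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.names),) or len(self.names) != len(self.groups):
            raise ValueError("feature vector / schema length mismatch")
        if not np.all(np.isfinite(vals)):
            raise ValueError("feature vector contains NaN/Inf")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.names)


def segments(states: str) -> list[tuple[str, int, int]]:
    """Maximal runs of a state string as (state, 1-based start, length) triples.

    Runs tile the string exactly and adjacent runs carry different states.
    """
    runs: list[tuple[str, int, int]] = []
    if not states:
        return runs
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start + 1, i - start))
            start = i
    return runs


# ---------------------------------------------------------------------------
# SSI: 21 features
# ---------------------------------------------------------------------------

_SSI_NAMES = (
    tuple(f"ssi.content.{s}" for s in SS_STATES)
    + tuple(f"ssi.trans.{a}{b}" for a in SS_STATES for b in SS_STATES)
    + tuple(f"ssi.avgseg.{s}" for s in SS_STATES)
    + tuple(f"ssi.nmaxseg.{s}" for s in SS_STATES)
    + tuple(f"ssi.order.{s}" for s in SS_STATES)
)


def encode_ssi(ss: SsAnnotation) -> FeatureVector:
    """Encode a three-state secondary-structure string into 21 descriptors.

    Blocks, in order:

    * content ``F_j = N_j / L`` for j in (H, E, C);
    * transitions ``T_{i,j} = N_{i,j} / (L - 1)`` over all 9 ordered pairs,
      where ``N_{i,j}`` counts adjacent positions (s_k = i, s_{k+1} = j);
    * ``AvgSeg_i`` = total length of i-runs / number of i-runs (0 if none)
      and ``NMaxSeg_i`` = longest i-run / L (0 if none);
    * order ``F_i = (sum_j p_{i,j}) / (L (L - 1))`` with ``p_{i,j}`` the
      1-based position of the j-th occurrence of state i.
    """
    s = ss.elements
    L = len(s)
    if L < 2:
        raise ValueError(f"SS string of length {L} < 2: transition denominator undefined")

    content = [s.count(st) / L for st in SS_STATES]
    trans = [
        sum(1 for k in range(L - 1) if s[k] == a and s[k + 1] == b) / (L - 1)
        for a in SS_STATES
        for b in SS_STATES
    ]
    runs = segments(s)
    avgseg, nmaxseg = [], []
    for st in SS_STATES:
        lens = [length for state, _, length in runs if state == st]
        avgseg.append(sum(lens) / len(lens) if lens else 0.0)
        nmaxseg.append(max(lens) / L if lens else 0.0)
    order = [
        sum(k for k in range(1, L + 1) if s[k - 1] == st) / (L * (L - 1))
        for st in SS_STATES
    ]
    values = np.array(content + trans + avgseg + nmaxseg + order)
    return FeatureVector(values, _SSI_NAMES, ("SSI",) * SSI_DIM)


# ---------------------------------------------------------------------------
# RSA: 28 features
# ---------------------------------------------------------------------------

_RSA_NAMES = (
    "rsa.mean",
    "rsa.std",
    "rsa.nseg.buried",
    "rsa.nseg.exposed",
    "rsa.minseg.buried",
    "rsa.maxseg.buried",
    "rsa.minseg.exposed",
    "rsa.maxseg.exposed",
) + tuple(f"rsa.aamean.{a}" for a in AMINO_ACIDS)


def encode_rsa(rsa: RsaAnnotation, record: ProteinRecord) -> FeatureVector:
    """Encode an RSA trace into 28 descriptors.

    A residue is exposed iff its value >= the annotation's threshold.  The
    standard deviation is the population form (divide by L): the vector
    describes the whole chain, not a sample estimate.  Min/max run lengths of
    a state with no runs are 0, as is the mean RSA of an absent amino acid.
    """
    if len(rsa) != len(record):
        raise ValueError(
            f"record {record.id!r}: RSA length {len(rsa)} != sequence length {len(record)}"
        )
    vals = np.asarray(rsa.values)
    states = "".join("E" if v >= rsa.threshold else "B" for v in vals)
    runs = segments(states)

    out = [float(vals.mean()), float(vals.std())]  # population std
    for st in "BE":
        out.append(float(sum(1 for state, _, _ in runs if state == st)))
    for st in "BE":
        lens = [length for state, _, length in runs if state == st]
        out.append(float(min(lens)) if lens else 0.0)
        out.append(float(max(lens)) if lens else 0.0)
    for a in AMINO_ACIDS:
        mask = np.frombuffer(record.sequence.encode(), dtype=np.uint8) == ord(a)
        out.append(float(vals[mask].mean()) if mask.any() else 0.0)
    return FeatureVector(np.array(out), _RSA_NAMES, ("RSA",) * RSA_DIM)


# ---------------------------------------------------------------------------
# CTD: 310 features
# ---------------------------------------------------------------------------

_CTD_PAIRS = tuple(combinations(AMINO_ACIDS, 2))  # 190 unordered pairs, lexicographic
_CTD_QUANTILES = ("p0", "p25", "p50", "p75", "p100")
_CTD_NAMES = (
    tuple(f"ctd.c.{a}" for a in AMINO_ACIDS)
    + tuple(f"ctd.t.{a}{b}" for a, b in _CTD_PAIRS)
    + tuple(f"ctd.d.{a}.{q}" for a in AMINO_ACIDS for q in _CTD_QUANTILES)
)


def encode_ctd(record: ProteinRecord) -> FeatureVector:
    """Composition/transition/distribution descriptors over the 20-letter alphabet.

    * C (20): fraction ``n_a / L`` of each amino acid.
    * T (190): for each unordered pair {a, b}, adjacent ab plus ba occurrences
      divided by L - 1, pairs in canonical lexicographic order.
    * D (100): for each amino acid present, the 1-based positions of its 1st,
      ceil(0.25 n_a)-th, ceil(0.50 n_a)-th, ceil(0.75 n_a)-th and n_a-th
      occurrence, each divided by L; all five 0 for an absent amino acid.
    """
    seq = record.sequence
    L = len(seq)
    comp = [seq.count(a) / L for a in AMINO_ACIDS]
    trans = []
    for a, b in _CTD_PAIRS:
        n = sum(
            1
            for k in range(L - 1)
            if (seq[k] == a and seq[k + 1] == b) or (seq[k] == b and seq[k + 1] == a)
        )
        trans.append(n / (L - 1))
    dist: list[float] = []
    for a in AMINO_ACIDS:
        positions = [k + 1 for k in range(L) if seq[k] == a]
        if not positions:
            dist.extend([0.0] * 5)
            continue
        n_a = len(positions)
        for q in (0.0, 0.25, 0.50, 0.75, 1.0):
            idx = max(1, ceil(q * n_a))  # 1-based occurrence index
            dist.append(positions[idx - 1] / L)
    values = np.array(comp + trans + dist)
    return FeatureVector(values, _CTD_NAMES, ("CTD",) * CTD_DIM)


# ---------------------------------------------------------------------------
# PSSM: 400 features
# ---------------------------------------------------------------------------

_PSSM_NAMES = tuple(f"pssm.{a}.{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)


def encode_pssm400(pssm: PssmMatrix) -> FeatureVector:
    """Collapse an L x 20 profile to 20 x 20 by summing rows per residue.

    ``M[a][b]`` is the sum over sequence positions carrying residue ``a`` of
    that position's log-odds toward amino acid ``b``; rows for amino acids
    absent from the sequence are all-zero.  Flattened row-major in canonical
    alphabetical order.  Sums are of raw log-odds (no sigmoid, no length
    normalization); scale is handled by downstream standardization.
    """
    M = np.zeros((20, 20))
    for res, row in zip(pssm.residues, pssm.scores):
        M[AA_INDEX[res]] += row
    return FeatureVector(M.ravel(), _PSSM_NAMES, ("PSSM",) * PSSM_DIM)


# ---------------------------------------------------------------------------
# Hybrid
# ---------------------------------------------------------------------------

def encode_hybrid(
    record: ProteinRecord,
    ss: SsAnnotation,
    rsa: RsaAnnotation,
    pssm: PssmMatrix,
) -> FeatureVector:
    """Concatenate SSI(21) | RSA(28) | CTD(310) | PSSM(400) -> 759 dims."""
    if not (len(ss) == len(rsa) == len(pssm) == len(record)):
        raise ValueError(f"record {record.id!r}: annotation channels not aligned to sequence")
    try:
        parts = [encode_ssi(ss), encode_rsa(rsa, record), encode_ctd(record), encode_pssm400(pssm)]
    except ValueError as exc:
        raise ValueError(f"record {record.id!r}: {exc}") from exc
    values = np.concatenate([p.values for p in parts])
    names = tuple(n for p in parts for n in p.names)
    groups = tuple(g for p in parts for g in p.groups)
    return FeatureVector(values, names, groups)


def build_feature_table(
    records,
    ss_by_id: dict,
    rsa_by_id: dict,
    pssm_by_id: dict,
    labels: dict | None = None,
) -> FeatureTable:
    """Encode a collection of annotated records into one FeatureTable."""
    rows, ids = [], []
    names: tuple[str, ...] | None = None
    groups: tuple[str, ...] | None = None
    for rec in records:
        fv = encode_hybrid(rec, ss_by_id[rec.id], rsa_by_id[rec.id], pssm_by_id[rec.id])
        rows.append(fv.values)
        ids.append(rec.id)
        names, groups = fv.names, fv.groups
    y = None
    if labels is not None:
        y = np.array([labels[i] for i in ids], dtype=int)
    return FeatureTable(np.vstack(rows), list(names), list(groups), ids, y)
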