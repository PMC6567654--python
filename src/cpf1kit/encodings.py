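"""Binary one-hot encodings of Cpf1 target sequences.

Two encoding schemes are used throughout the package:

* **order-k** — a window of k nucleotides slides over the 27-nt target
  (4-nt TTTN PAM + 23-nt protospacer) with step 1; each window position
  becomes one column of a ``4**k x (L-k+1)`` binary matrix with a single 1
  in the row of the observed k-mer.  The default order-2 encoding of a
  27-nt target is a 16 x 26 matrix.
* **mismatch** — a guide/target pair of equal length 27 becomes a 12 x 27
  matrix: each position is a twelve-dimensional binary vector over the 12
  ordered base substitutions (guide base -> target base); matched positions
  are all-zero columns, so the matrix total equals the Hamming distance.

Position 1 is the 5'-most base of the PAM and maps to the leftmost column.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "MISMATCH_TYPES",
    "OneHotMatrix",
    "TargetRecord",
    "MismatchRecord",
    "reverse_complement",
    "encode_order_k",
    "encode_mismatch_pair",
    "permute_rows",
    "extract_context_window",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: The 12 ordered substitution types (guide base > target base), lexicographic.
MISMATCH_TYPES: tuple[str, ...] = tuple(
    f"{g}>{t}" for g in BASES for t in BASES if g != t
)
_MISMATCH_ROW = {pair: i for i, pair in enumerate(MISMATCH_TYPES)}

#: Context window layout: 7 nt upstream of the PAM, 27-nt site, 6 nt downstream.
CONTEXT_UPSTREAM = 7
CONTEXT_DOWNSTREAM = 6
SITE_LEN = 27
CONTEXT_LEN = CONTEXT_UPSTREAM + SITE_LEN + CONTEXT_DOWNSTREAM  # 40


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str, *, name: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in _BASE_INDEX:
            raise ValueError(
                f"{name} contains non-ACGT character {ch!r} at position {i + 1}"
            )


def seq_to_ints(seq: str, *, name: str = "sequence") -> np.ndarray:
    """Map an ACGT string to integer codes 0..3, validating the alphabet."""
    _validate_sequence(seq, name=name)
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)


@dataclass(frozen=True)
class OneHotMatrix:
    """A binary category x position matrix.

    Attributes
    ----------
    entries : ndarray of 0/1, shape (n_rows, n_cols)
    scheme : one of ``order1``, ``order2``, ``order3``, ``mismatch``
    row_labels : ordered category names (k-mers, or ordered substitutions
        such as ``"A>C"`` for the mismatch scheme)
    """

    entries: np.ndarray
    scheme: str
    row_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if e.ndim != 2:
            raise ValueError("entries must be a 2-D matrix")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("entries must be binary")
        if len(self.row_labels) != e.shape[0]:
            raise ValueError("row_labels length must match row count")
        object.__setattr__(self, "entries", e.astype(np.uint8))

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_cols(self) -> int:
        return self.entries.shape[1]

    def to_text(self) -> str:
        """Dense TSV rendering: header of position columns, one row per category."""
        lines = ["\t".join(["category"] + [str(j + 1) for j in range(self.n_cols)])]
        for label, row in zip(self.row_labels, self.entries):
            lines.append("\t".join([label] + [str(int(v)) for v in row]))
        return "\n".join(lines) + "\n"


def _kmer_labels(k: int) -> tuple[str, ...]:
    return tuple("".join(p) for p in itertools.product(BASES, repeat=k))


def encode_order_k(seq: str, k: int = 2) -> OneHotMatrix:
    """Encode a DNA sequence as an order-k one-hot matrix.

    A window of ``k`` nucleotides slides along ``seq`` with step 1; column
    ``j`` carries a single 1 in the row of the k-mer ``seq[j:j+k]``.  Rows
    are ordered lexicographically over {A,C,G,T} (AA, AC, AG, AT, CA, ...
    for k=2).  A 27-nt target yields 4x27 (k=1), 16x26 (k=2) or 64x25 (k=3).
    """
    if k not in (1, 2, 3):
        raise ValueError(f"order k must be 1, 2 or 3, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} is shorter than order {k}")
    codes = seq_to_ints(seq)
    n_cols = len(seq) - k + 1
    # lexicographic k-mer index = base-4 number of the window
    idx = np.zeros(n_cols, dtype=np.int64)
    for t in range(k):
        idx = idx * 4 + codes[t : t + n_cols]
    entries = np.zeros((4**k, n_cols), dtype=np.uint8)
    entries[idx, np.arange(n_cols)] = 1
    return OneHotMatrix(entries, scheme=f"order{k}", row_labels=_kmer_labels(k))


def encode_mismatch_pair(guide: str, target: str) -> OneHotMatrix:
    """Encode a guide/target pair as a 12 x L mismatch matrix (L = 27).

    Matched positions give all-zero columns; a mismatch with guide base g
    and target base t at position p sets a single 1 at (row of ordered pair
    g>t, column p-1).  The matrix total therefore equals the Hamming
    distance of the pair.
    """
    if len(guide) != len(target):
        raise ValueError(
            f"guide (len {len(guide)}) and target (len {len(target)}) differ in length"
        )
    _validate_sequence(guide, name="guide")
    _validate_sequence(target, name="target")
    entries = np.zeros((len(MISMATCH_TYPES), len(guide)), dtype=np.uint8)
    for p, (g, t) in enumerate(zip(guide, target)):
        if g != t:
            entries[_MISMATCH_ROW[f"{g}>{t}"], p] = 1
    return OneHotMatrix(entries, scheme="mismatch", row_labels=MISMATCH_TYPES)


def permute_rows(m: OneHotMatrix, seed: int) -> OneHotMatrix:
    """Permute the category rows of a matrix with a seeded uniform permutation.

    Column sums are unchanged and the same seed reproduces the same
    permutation bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_rows)
    return OneHotMatrix(
        m.entries[perm], scheme=m.scheme, row_labels=tuple(m.row_labels[i] for i in perm)
    )


def extract_context_window(genome: str, site_start: int, strand: str) -> str:
    """Extract the 40-nt context window around a 27-nt site, PAM-first.

    ``site_start`` is the 0-based forward-strand offset of the 27-nt site.
    The window spans 7 nt upstream of the PAM and 6 nt downstream of the
    protospacer in the site's own orientation; minus-strand sites are
    reverse-complemented so the PAM again reads left-to-right.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    n = len(genome)
    if strand == "+":
        lo, hi = site_start - CONTEXT_UPSTREAM, site_start + SITE_LEN + CONTEXT_DOWNSTREAM
    else:
        lo, hi = site_start - CONTEXT_DOWNSTREAM, site_start + SITE_LEN + CONTEXT_UPSTREAM
    if lo < 0 or hi > n:
        raise ValueError(
            f"context window [{lo}, {hi}) out of bounds for sequence of length {n}"
        )
    window = genome[lo:hi]
    if strand == "-":
        window = reverse_complement(window)
    return window


@dataclass(frozen=True)
class TargetRecord:
    """One matched 27-nt target (TTTN PAM + 23-nt protospacer) with its
    measured indel frequency in percent; optionally a 40-nt context window."""

    sequence: str
    indel_frequency: float
    context: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != SITE_LEN:
            raise ValueError(
                f"target sequence must be {SITE_LEN} nt, got {len(self.sequence)}"
            )
        _validate_sequence(self.sequence)
        if not 0.0 <= self.indel_frequency <= 100.0:
            raise ValueError(
                f"indel_frequency must be in [0, 100], got {self.indel_frequency}"
            )
        if self.context is not None:
            if len(self.context) != CONTEXT_LEN:
                raise ValueError(
                    f"context must be {CONTEXT_LEN} nt, got {len(self.context)}"
                )
            _validate_sequence(self.context, name="context")
            if self.context[CONTEXT_UPSTREAM : CONTEXT_UPSTREAM + SITE_LEN] != self.sequence:
                raise ValueError(
                    f"context must contain the site at offset {CONTEXT_UPSTREAM}"
                )

    @property
    def pam(self) -> str:
        return self.sequence[:4]

    @property
    def protospacer(self) -> str:
        return self.sequence[4:]


@dataclass(frozen=True)
class MismatchRecord:
    """A guide/target pair of 27-nt sequences with the measured indel
    frequency at the (possibly mismatched) target site."""

    guide: str
    target: str
    indel_frequency: float

    def __post_init__(self) -> None:
        if len(self.guide) != len(self.target):
            raise ValueError("guide and target must have equal length")
        if len(self.guide) != SITE_LEN:
            raise ValueError(f"guide must be {SITE_LEN} nt, got {len(self.guide)}")
        _validate_sequence(self.guide, name="guide")
        _validate_sequence(self.target, name="target")
        if not 0.0 <= self.indel_frequency <= 100.0:
            raise ValueError(
                f"indel_frequency must be in [0, 100], got {self.indel_frequency}"
            )

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        """1-based positions where guide and target disagree."""
        return tuple(
            i + 1 for i, (g, t) in enumerate(zip(self.guide, self.target)) if g != t
        )

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)
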