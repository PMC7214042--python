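"""Alignment I/O (Stockholm 1.0, aligned FASTA) and WUSS structure parsing.

Residue conventions
-------------------
Sequences are stored exactly as read (case preserved).  For statistics,
residues are normalised on access: T/t -> U, gaps ('-', '.', '_', '~') to
``GAP``, anything that is not A/C/G/U to ``MISSING``.  Comparison is
case-insensitive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, StructureError

GAP = "-"
MISSING = "N"
GAP_CHARS = frozenset("-._~")
ALPHABET = "ACGU"

#: integer codes used in the packed residue matrix
CODE_A, CODE_C, CODE_G, CODE_U, CODE_GAP, CODE_MISSING = 0, 1, 2, 3, 4, 5

_CODE_OF = {}
for _i, _r in enumerate(ALPHABET):
    _CODE_OF[_r] = _i
    _CODE_OF[_r.lower()] = _i
_CODE_OF["T"] = CODE_U
_CODE_OF["t"] = CODE_U
for _g in GAP_CHARS:
    _CODE_OF[_g] = CODE_GAP


def normalize_residue(ch: str) -> str:
    """Map a raw alignment character to A/C/G/U, GAP or MISSING."""
    code = _CODE_OF.get(ch, CODE_MISSING)
    if code == CODE_GAP:
        return GAP
    if code == CODE_MISSING:
        return MISSING
    return ALPHABET[code]


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with optional SS_cons annotation."""

    names: list[str]
    rows: list[str]
    ss_cons: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise FormatError("names and rows must have equal length")
        if not self.rows:
            return
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.L < 1:
            raise FormatError("alignment must have at least one column")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise FormatError(f"duplicate sequence names: {dup}")
        if any(not n for n in self.names):
            raise FormatError("empty sequence name")
        if self.ss_cons is not None and len(self.ss_cons) != self.L:
            raise FormatError(
                f"SS_cons length {len(self.ss_cons)} != alignment length {self.L}"
            )

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codes(self) -> np.ndarray:
        """(n_seqs, L) int8 matrix of residue codes (see CODE_* constants)."""
        mat = np.full((self.n_seqs, self.L), CODE_MISSING, dtype=np.int8)
        for r, row in enumerate(self.rows):
            mat[r] = [_CODE_OF.get(ch, CODE_MISSING) for ch in row]
        return mat

    def column(self, i: int) -> list[str]:
        """Normalised residues of column *i*."""
        return [normalize_residue(row[i]) for row in self.rows]

    def structure(self) -> "SecondaryStructure | None":
        if self.ss_cons is None:
            return None
        return pairs_from_wuss(self.ss_cons)


@dataclass
class SecondaryStructure:
    """A set of basepairs given as 0-based column-index pairs (i < j)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise StructureError(f"pair ({i}, {j}) must satisfy i < j")
            if i < 0:
                raise StructureError(f"negative column index in pair ({i}, {j})")
            for k in (i, j):
                if k in seen:
                    raise StructureError(f"column {k} appears in more than one pair")
                seen.add(k)
        self.pairs = sorted(self.pairs)

    @property
    def B(self) -> int:
        return len(self.pairs)

    def paired_columns(self) -> set[int]:
        return {k for p in self.pairs for k in p}


# ---------------------------------------------------------------------------
# Stockholm / FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def _from_biopython(msa: MultipleSeqAlignment) -> Alignment:
    names = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    ss = msa.column_annotations.get("secondary_structure")
    meta = {}
    if getattr(msa, "annotations", None):
        meta.update({str(k): str(v) for k, v in msa.annotations.items()})
    return Alignment(names=names, rows=rows, ss_cons=ss, metadata=meta)


def read_stockholm(path: str) -> Alignment:
    """Read a (possibly interleaved) Stockholm 1.0 file into an Alignment.

    Sequence blocks are concatenated; per-block ``#=GC SS_cons`` segments are
    concatenated into a single ss_cons string.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# STOCKHOLM 1.0"):
            raise FormatError(f"{path}: missing '# STOCKHOLM 1.0' header")
        fh.seek(0)
        try:
            msa = AlignIO.read(fh, "stockholm")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    aln = _from_biopython(msa)
    if aln.n_seqs == 0:
        raise FormatError(f"{path}: no sequences")
    return aln


def write_stockholm(aln: Alignment, path: str) -> None:
    """Write a single-block Stockholm 1.0 file (with SS_cons if present)."""
    if aln.n_seqs == 0:
        raise FormatError("cannot write an empty alignment")
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    msa = MultipleSeqAlignment(records)
    if aln.ss_cons is not None:
        msa.column_annotations["secondary_structure"] = aln.ss_cons
    buf = io.StringIO()
    AlignIO.write(msa, buf, "stockholm")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_fasta(path: str) -> Alignment:
    """Read an aligned (gapped) FASTA file."""
    try:
        msa = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return _from_biopython(msa)


# ---------------------------------------------------------------------------
# WUSS secondary-structure notation
# ---------------------------------------------------------------------------

_OPEN_OF = {">": "<", ")": "(", "]": "[", "}": "{"}
_BRACKET_OPENS = frozenset("<([{")
_UNPAIRED = frozenset(".,_-:~")


def pairs_from_wuss(ss: str) -> SecondaryStructure:
    """Extract basepairs from a WUSS/dot-bracket consensus structure string.

    Bracket families <>, (), [], {} nest independently; uppercase letters
    open and lowercase letters close pseudoknot families (Aa, Bb, ...).
    """
    if not ss:
        raise StructureError("empty structure string")
    stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    for col, ch in enumerate(ss):
        if ch in _UNPAIRED:
            continue
        if ch in _BRACKET_OPENS:
            stacks.setdefault(ch, []).append(col)
        elif ch in _OPEN_OF:
            stack = stacks.get(_OPEN_OF[ch], [])
            if not stack:
                raise StructureError(f"unbalanced '{ch}' at column {col + 1}")
            pairs.append((stack.pop(), col))
        elif ch.isalpha() and ch.isupper():
            stacks.setdefault(ch, []).append(col)
        elif ch.isalpha() and ch.islower():
            stack = stacks.get(ch.upper(), [])
            if not stack:
                raise StructureError(
                    f"unmatched pseudoknot letter '{ch}' at column {col + 1}"
                )
            pairs.append((stack.pop(), col))
        else:
            raise StructureError(f"unknown WUSS character '{ch}' at column {col + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced '{opener}' opened at column {stack[-1] + 1}"
            )
    return SecondaryStructure(pairs=pairs)


def wuss_from_pairs(struct: SecondaryStructure, L: int) -> str:
    """Render a pair set as WUSS: nested pairs with <>, crossing pairs with
    pseudoknot letter families assigned greedily."""
    for i, j in struct.pairs:
        if j >= L:
            raise StructureError(f"pair ({i}, {j}) outside alignment length {L}")

    def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
        (i, j), (k, l) = a, b
        return (i < k < j < l) or (k < i < l < j)

    families: list[list[tuple[int, int]]] = []
    for pair in sorted(struct.pairs):
        for fam in families:
            if not any(crosses(pair, q) for q in fam):
                fam.append(pair)
                break
        else:
            families.append([pair])
    if len(families) > 27:
        raise StructureError(
            f"{len(families) - 1} crossing pseudoknot families exceed the 26 "
            "letter families supported by WUSS"
        )
    out = ["."] * L
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for f, fam in enumerate(families):
        if f == 0:
            op, cl = "<", ">"
        else:
            op, cl = letters[f - 1], letters[f - 1].lower()
        for i, j in fam:
            out[i], out[j] = op, cl
    return "".join(out)
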