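"""Reference-genome handling and cytosine context classification.

Plant DNA methylation is context specific: a cytosine is classified by the
two bases immediately 3' of it on its own strand as CG, CHG or CHH (H = A,
C or T).  Positions are 1-based at the cytosine itself; a minus-strand call
at position p refers to the G at p on the plus strand.

Edge behaviour: CG needs only one downstream base, CHG/CHH need two; any N
(or running off the sequence end) in the needed window yields ``ambiguous``,
and ambiguous sites are excluded from every downstream statistic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

CONTEXTS = ("CG", "CHG", "CHH")
AMBIGUOUS = "ambiguous"


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named nucleotide sequences, upper-cased, alphabet {A,C,G,T,N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            norm = _NON_ACGTN.sub("N", seq.upper())
            self.sequences[name] = norm

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def reverse_complement(self) -> "Genome":
        return Genome({name: revcomp(seq) for name, seq in self.sequences.items()})


class ContextCall(NamedTuple):
    chrom: str
    pos: int  # 1-based position of the cytosine (G on + strand for '-' calls)
    strand: str  # '+' or '-'
    context: str  # 'CG', 'CHG', 'CHH' or 'ambiguous'


def load_genome(path) -> Genome:
    """Read a (multi-record, wrapped) FASTA into a :class:`Genome`.

    Sequences are upper-cased; soft-masked lower case is kept as the plain
    base; anything outside {A,C,G,T,N} becomes N.  Duplicate record names
    are a fatal format error.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def classify_context(genome: Genome, chrom: str, pos: int, strand: str) -> ContextCall:
    """Classify the cytosine at (chrom, pos, strand).

    Raises ValueError unless the base there is a cytosine on the given
    strand (C on '+', G on the plus strand for '-').
    """
    seq = genome[chrom]
    n = len(seq)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside {chrom} (length {n})")
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[i]}, not C")
        d1 = seq[i + 1] if i + 1 < n else None
        d2 = seq[i + 2] if i + 2 < n else None
    elif strand == "-":
        if seq[i] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[i]} on +, not G")
        d1 = seq[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else None
        d2 = seq[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    if d1 == "G":
        context = "CG"
    elif d1 is None or d1 == "N":
        context = AMBIGUOUS
    elif d2 == "G":
        context = "CHG"
    elif d2 is None or d2 == "N":
        context = AMBIGUOUS
    else:
        context = "CHH"
    return ContextCall(chrom, pos, strand, context)


def _context_codes(is_g_next: np.ndarray, is_n_next: np.ndarray,
                   is_g_next2: np.ndarray, is_n_next2: np.ndarray) -> np.ndarray:
    """Vectorised context decision: 0=CG, 1=CHG, 2=CHH, 3=ambiguous."""
    return np.select(
        [is_g_next, is_n_next, is_g_next2, is_n_next2],
        [0, 3, 1, 3],
        default=2,
    )


def chromosome_cytosines(seq: str) -> pd.DataFrame:
    """All cytosines of one chromosome, both strands, as a DataFrame.

    Columns: pos (1-based), strand, context.  Sorted by (pos, strand) with
    '+' before '-' at equal positions.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)

    # '+' strand: C at i, downstream bases at i+1, i+2 (pad with N = absent)
    padded = np.concatenate([arr, np.array([b"N", b"N"], dtype="S1")])
    plus_idx = np.flatnonzero(arr == b"C")
    d1 = padded[plus_idx + 1]
    d2 = padded[plus_idx + 2]
    plus_ctx = _context_codes(d1 == b"G", d1 == b"N", d2 == b"G", d2 == b"N")

    # '-' strand: G at i on +; downstream on '-' are complements of i-1, i-2.
    # complement == 'G' iff plus base == 'C'; N maps to N.
    lpad = np.concatenate([np.array([b"N", b"N"], dtype="S1"), arr])
    minus_idx = np.flatnonzero(arr == b"G")
    u1 = lpad[minus_idx + 1]  # plus base at i-1
    u2 = lpad[minus_idx]      # plus base at i-2
    minus_ctx = _context_codes(u1 == b"C", u1 == b"N", u2 == b"C", u2 == b"N")

    pos = np.concatenate([plus_idx + 1, minus_idx + 1])
    strand = np.concatenate([np.zeros(len(plus_idx), dtype=np.int8),
                             np.ones(len(minus_idx), dtype=np.int8)])
    ctx = np.concatenate([plus_ctx, minus_ctx])
    order = np.lexsort((strand, pos))

    labels = np.array(["CG", "CHG", "CHH", AMBIGUOUS])
    df = pd.DataFrame({
        "pos": pos[order].astype(np.int64),
        "strand": pd.Categorical.from_codes(strand[order], categories=["+", "-"]),
        "context": pd.Categorical.from_codes(ctx[order].astype(np.int8),
                                             categories=list(labels)),
    })
    assert n == 0 or df.shape[0] == int((arr == b"C").sum() + (arr == b"G").sum())
    return df


def cytosine_table(genome: Genome) -> pd.DataFrame:
    """Every cytosine of the genome: chrom, pos, strand, context."""
    frames = []
    for chrom, seq in genome.sequences.items():
        df = chromosome_cytosines(seq)
        df.insert(0, "chrom", chrom)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    return pd.concat(frames, ignore_index=True)


def enumerate_cytosines(genome: Genome) -> Iterator[ContextCall]:
    """Yield every +/− strand cytosine in coordinate order ('+' first at ties)."""
    for chrom, seq in genome.sequences.items():
        df = chromosome_cytosines(seq)
        for pos, strand, context in zip(df["pos"], df["strand"], df["context"]):
            yield ContextCall(chrom, int(pos), str(strand), str(context))


def write_context_table(genome: Genome, path) -> None:
    """Tab-separated chrom, pos, strand, context for the whole genome."""
    cytosine_table(genome).to_csv(path, sep="\t", header=False, index=False)
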