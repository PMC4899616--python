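"""Locus-specific clone-based bisulfite sequencing analysis.

After bisulfite treatment, PCR and cloning, each sequenced clone reports
one molecule: at every reference cytosine a clone base C means the site was
methylated (protected from conversion) and T means unmethylated.  Only the
top strand of the amplicon is modelled — bisulfite PCR is strand specific —
so bottom-strand loci are handled by reverse-complementing the reference
before analysis.

Levels are summarised separately for CG, CHG and CHH columns with explicit
denominators, and a per-clone non-CG (CHH) methylation fraction serves as
an advisory conversion-efficiency proxy; no clone is dropped automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CONTEXTS, Genome, chromosome_cytosines

METHYLATED, UNMETHYLATED, MISSING = "M", "U", "."


@dataclass
class AmpliconReference:
    """Top-strand amplicon sequence with its cytosine positions and contexts."""

    name: str
    sequence: str
    cytosines: pd.DataFrame = field(default=None, repr=False)  # pos, context

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty amplicon sequence")
        self.sequence = Genome({self.name: self.sequence})[self.name]
        if self.cytosines is None:
            table = chromosome_cytosines(self.sequence)
            table = table[table["strand"] == "+"]
            self.cytosines = table[["pos", "context"]].reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.cytosines)


@dataclass
class CloneCallMatrix:
    """Rows = clones, columns = reference cytosines; entries M/U/missing."""

    reference: AmpliconReference
    calls: pd.DataFrame = field(repr=False)  # index clone names, cols positions

    def __post_init__(self) -> None:
        if self.calls.shape[1] != self.reference.n_sites:
            raise ValueError("call matrix columns != reference cytosines")


def call_clones(reference: AmpliconReference,
                clones: Sequence[str] | dict[str, str]) -> CloneCallMatrix:
    """Score each clone at every reference cytosine (C -> M, T -> U, else missing).

    Clones must already be aligned end-to-end to the reference (equal
    length); gapped alignments must be resolved upstream.
    """
    if not isinstance(clones, dict):
        clones = {f"clone_{i}": s for i, s in enumerate(clones, start=1)}
    positions = reference.cytosines["pos"].tolist()
    rows = {}
    for name, seq in clones.items():
        seq = seq.upper()
        if len(seq) != len(reference.sequence):
            raise ValueError(
                f"{name}: length {len(seq)} != reference "
                f"{len(reference.sequence)}; align before calling")
        calls = []
        for pos in positions:
            base = seq[pos - 1]
            calls.append(METHYLATED if base == "C"
                         else UNMETHYLATED if base == "T" else MISSING)
        rows[name] = calls
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=positions)
    return CloneCallMatrix(reference, matrix)


def summarize_clones(matrix: CloneCallMatrix) -> pd.DataFrame:
    """Per-context methylation levels with explicit denominators.

    Level = methylated calls / (methylated + unmethylated calls); missing
    calls are excluded.  Returns one row per context plus a 'all' row.
    """
    ctx = matrix.reference.cytosines["context"].to_numpy()
    calls = matrix.calls.to_numpy()
    rows = []
    for context in list(CONTEXTS) + ["all"]:
        cols = np.isin(ctx, list(CONTEXTS)) if context == "all" \
            else np.isin(ctx, [context])
        sub = calls[:, cols]
        n_m = int((sub == METHYLATED).sum())
        n_u = int((sub == UNMETHYLATED).sum())
        rows.append({
            "context": context,
            "n_sites": int(cols.sum()),
            "n_methylated": n_m,
            "n_unmethylated": n_u,
            "level": n_m / (n_m + n_u) if n_m + n_u else nan,
        })
    return pd.DataFrame(rows)


def per_site_levels(matrix: CloneCallMatrix) -> pd.DataFrame:
    """Columnwise methylation fraction across clones (lollipop-style table)."""
    calls = matrix.calls
    n_m = (calls == METHYLATED).sum(axis=0)
    n_u = (calls == UNMETHYLATED).sum(axis=0)
    with np.errstate(invalid="ignore"):
        level = n_m / (n_m + n_u).replace(0, np.nan)
    return pd.DataFrame({
        "pos": matrix.reference.cytosines["pos"].to_numpy(),
        "context": matrix.reference.cytosines["context"].to_numpy(),
        "n_methylated": n_m.to_numpy(),
        "n_unmethylated": n_u.to_numpy(),
        "level": level.to_numpy(),
    })


def conversion_check(matrix: CloneCallMatrix,
                     flag_threshold: float = 0.9) -> pd.DataFrame:
    """Per-clone CHH methylation fraction as a conversion-failure proxy.

    A fully unconverted clone scores 1.0.  Clones at or above the flag
    threshold are marked, but nothing is dropped.
    """
    ctx = matrix.reference.cytosines["context"].to_numpy()
    chh = ctx == "CHH"
    rows = []
    for name, calls in zip(matrix.calls.index, matrix.calls.to_numpy()):
        sub = calls[chh]
        n_m = int((sub == METHYLATED).sum())
        n_u = int((sub == UNMETHYLATED).sum())
        frac = n_m / (n_m + n_u) if n_m + n_u else nan
        rows.append({"clone": name, "chh_meth_fraction": frac,
                     "flagged": bool(frac >= flag_threshold)
                     if n_m + n_u else False})
    return pd.DataFrame(rows)


def duplicate_clones(matrix: CloneCallMatrix) -> list[tuple[str, str]]:
    """Advisory: pairs of clones with identical call patterns."""
    seen: dict[tuple, str] = {}
    dups = []
    for name, calls in zip(matrix.calls.index, matrix.calls.to_numpy()):
        key = tuple(calls)
        if key in seen:
            dups.append((seen[key], name))
        else:
            seen[key] = name
    return dups


def simulate_clones(reference: AmpliconReference, m_per_site: np.ndarray,
                    n_clones: int,
                    rng: np.random.Generator) -> dict[str, str]:
    """Draw clone sequences from a known per-site methylation vector.

    Each clone methylates cytosine i with probability m_per_site[i]
    (independent Bernoulli); unmethylated cytosines read as T after
    conversion, all other bases copy the reference.
    """
    m_per_site = np.asarray(m_per_site, dtype=float)
    if len(m_per_site) != reference.n_sites:
        raise ValueError("methylation vector length != number of cytosines")
    positions = reference.cytosines["pos"].to_numpy()
    clones = {}
    for i in range(n_clones):
        seq = list(reference.sequence)
        keep = rng.random(len(positions)) < m_per_site
        for pos, methylated in zip(positions, keep):
            if not methylated:
                seq[pos - 1] = "T"
        clones[f"sim_clone_{i + 1}"] = "".join(seq)
    return clones


def read_fasta_clones(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
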