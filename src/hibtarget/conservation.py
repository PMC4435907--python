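"""Amino-acid alignment conservation summaries.

A column is *identical* when every non-gap residue in it agrees across all
taxa.  Group-contrast classification finds columns conserved within one
group (e.g. hibernators) but variable — or fixed for a different residue —
within the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence


@dataclass
class ConservationSummary:
    region: tuple[int, int]  # 1-based inclusive column range
    n_columns: int
    n_identical: int
    n_variable: int
    percent_identity: float
    # 1-based column numbers (within the full alignment)
    conserved_in_a_diff_in_b: list[int]
    conserved_in_b_diff_in_a: list[int]


def _column_residues(seqs: Sequence[str], col0: int) -> list[str]:
    return [s[col0] for s in seqs]


def _is_identical(residues: Sequence[str]) -> bool:
    nz = {r for r in residues if r not in "-.X"}
    return len(nz) <= 1


def _group_state(residues: Sequence[str]) -> str | None:
    """The single residue the group is fixed for, or None when variable."""
    nz = {r for r in residues if r not in "-.X"}
    if len(nz) == 1:
        return next(iter(nz))
    if len(nz) == 0:
        return ""  # all gap: treated as (vacuously) conserved
    return None


def conservation_summary(
    alignment: Mapping[str, str],
    region: tuple[int, int] | None = None,
    groups: tuple[Sequence[str], Sequence[str]] | None = None,
) -> ConservationSummary:
    """Identity and group-contrast statistics over an alignment column range.

    ``region`` is a 1-based inclusive column range (defaults to the whole
    alignment).  ``groups`` is an optional (A, B) partition of the taxa;
    a column is "conserved in A but different/divergent in B" when A is
    fixed for one residue and B is either variable or fixed for another.
    """
    taxa = list(alignment)
    if not taxa:
        raise ValueError("empty alignment")
    seqs = [alignment[t] for t in taxa]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("alignment rows differ in length")
    if region is None:
        region = (1, L)
    lo, hi = region
    if not (1 <= lo <= hi <= L):
        raise ValueError(f"region {region} outside alignment of {L} columns")

    idx_a = idx_b = None
    if groups is not None:
        a, b = groups
        if not a or not b:
            raise ValueError("both groups must be non-empty")
        missing = (set(a) | set(b)) - set(taxa)
        if missing:
            raise ValueError(f"group taxa absent from alignment: {sorted(missing)}")
        row = {t: i for i, t in enumerate(taxa)}
        idx_a = [row[t] for t in a]
        idx_b = [row[t] for t in b]

    n_identical = 0
    a_not_b: list[int] = []
    b_not_a: list[int] = []
    for col in range(lo - 1, hi):
        residues = _column_residues(seqs, col)
        if _is_identical(residues):
            n_identical += 1
            continue
        if idx_a is not None:
            res_a = _group_state([residues[i] for i in idx_a])
            res_b = _group_state([residues[i] for i in idx_b])
            if res_a is not None and (res_b is None or res_b != res_a):
                a_not_b.append(col + 1)
            if res_b is not None and (res_a is None or res_a != res_b):
                b_not_a.append(col + 1)
    n_columns = hi - lo + 1
    return ConservationSummary(
        region=region,
        n_columns=n_columns,
        n_identical=n_identical,
        n_variable=n_columns - n_identical,
        percent_identity=100.0 * n_identical / n_columns,
        conserved_in_a_diff_in_b=a_not_b,
        conserved_in_b_diff_in_a=b_not_a,
    )
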