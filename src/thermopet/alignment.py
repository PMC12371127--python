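"""Residue frequencies of engineered mutations among aligned homologs.

Given a multiple sequence alignment that contains the engineered enzyme
as a designated reference row, this module maps positions in the
ungapped reference sequence onto alignment columns and tallies how often
each queried mutant residue occurs among the homologs.  A mutation that
is common in natural homologs is evolutionarily sanctioned; one that is
absent is a genuine departure from the family consensus.

Counting conventions: the reference row is excluded; gaps count in the
denominator but never as matches (a gap-excluded frequency is reported
alongside); parsing is case-insensitive; non-standard residues (X, B, Z,
...) are never matches and are tallied separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AlignedHomologSet",
    "MutationQuery",
    "SiteFrequencyTable",
    "map_reference_positions",
    "site_frequencies",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
#: Tolerated ambiguity codes; counted as non-matches, tallied separately.
EXTENDED = set("XBZJUO*")


@dataclass(frozen=True)
class AlignedHomologSet:
    """Equal-length gapped sequences with a designated reference row."""

    records: Tuple[Tuple[str, str], ...]
    reference_id: str

    def __post_init__(self) -> None:
        recs = tuple((rid, seq.upper()) for rid, seq in self.records)
        object.__setattr__(self, "records", recs)
        if not recs:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in recs}
        if len(lengths) != 1:
            raise ValueError("all gapped sequences must have equal length")
        ids = [rid for rid, _ in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids")
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        allowed = AMINO_ACIDS | EXTENDED | {GAP}
        for rid, seq in recs:
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"record {rid!r} has invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    @property
    def reference_seq(self) -> str:
        return dict(self.records)[self.reference_id]

    @property
    def homolog_records(self) -> List[Tuple[str, str]]:
        return [(rid, seq) for rid, seq in self.records if rid != self.reference_id]

    @property
    def n_homologs(self) -> int:
        return len(self.records) - 1

    @classmethod
    def from_fasta(cls, path, reference_id: str) -> "AlignedHomologSet":
        """Read an aligned FASTA file."""
        from Bio import SeqIO

        records = tuple(
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        )
        return cls(records=records, reference_id=reference_id)


@dataclass(frozen=True)
class MutationQuery:
    """Mutations as (1-based ungapped reference position, ref_aa, mut_aa)."""

    entries: Tuple[Tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        entries = tuple(
            (int(p), ra.upper(), ma.upper()) for p, ra, ma in self.entries
        )
        object.__setattr__(self, "entries", entries)
        for pos, ra, ma in entries:
            if pos < 1:
                raise ValueError("positions are 1-based (>= 1)")
            if ra not in AMINO_ACIDS or ma not in AMINO_ACIDS:
                raise ValueError(f"invalid residue in entry ({pos}, {ra}, {ma})")

    def validate_against(self, aln: AlignedHomologSet) -> None:
        """Check every ref_aa matches the reference sequence."""
        ungapped = aln.reference_seq.replace(GAP, "")
        for pos, ra, _ in self.entries:
            if pos > len(ungapped):
                raise ValueError(
                    f"position {pos} beyond reference length {len(ungapped)}"
                )
            if ungapped[pos - 1] != ra:
                raise ValueError(
                    f"reference has {ungapped[pos - 1]} at {pos}, query says {ra}"
                )

    @property
    def positions(self) -> List[int]:
        return [p for p, _, _ in self.entries]


def map_reference_positions(
    aln: AlignedHomologSet, positions: Sequence[int]
) -> np.ndarray:
    """Map 1-based ungapped reference positions to 0-based alignment columns.

    The mapping is a bijection onto the columns where the reference row
    carries a residue; ungapping the reference at the returned columns
    reproduces the queried residues.
    """
    ref = aln.reference_seq
    residue_cols = np.flatnonzero(np.frombuffer(ref.encode(), dtype="S1") != GAP.encode())
    n_res = residue_cols.size
    out = np.empty(len(positions), dtype=int)
    for i, pos in enumerate(positions):
        if not (1 <= pos <= n_res):
            raise ValueError(f"position {pos} beyond reference length {n_res}")
        out[i] = residue_cols[pos - 1]
    return out


@dataclass(frozen=True)
class SiteFrequencyTable:
    """Per-site mutation frequencies plus full residue distributions.

    ``table`` columns: position, ref_aa, mut_aa, column (0-based),
    n_homologs, mut_count, mut_freq_pct (gaps in the denominator),
    mut_freq_pct_gap_excluded, gap_pct, nonstandard_pct.
    ``distributions`` maps each queried position to its full residue ->
    percent distribution over the homologs (including the gap symbol).
    """

    table: pd.DataFrame
    distributions: Dict[int, Dict[str, float]]


def site_frequencies(aln: AlignedHomologSet, query: MutationQuery) -> SiteFrequencyTable:
    """Frequency of each queried mutant residue among the homologs.

    Frequencies are percentages of the non-reference records (gap rows
    included in the denominator); a gap-excluded percentage and the gap
    share are reported alongside, together with the full residue
    distribution per site.  Invariant under record reordering/renaming.
    """
    if aln.n_homologs == 0:
        raise ValueError("alignment holds only the reference; no homologs to count")
    query.validate_against(aln)
    columns = map_reference_positions(aln, query.positions)
    homolog_seqs = [seq for _, seq in aln.homolog_records]
    n = len(homolog_seqs)
    rows = []
    distributions: Dict[int, Dict[str, float]] = {}
    for (pos, ref_aa, mut_aa), col in zip(query.entries, columns):
        counts = Counter(seq[col] for seq in homolog_seqs)
        gap_n = counts.get(GAP, 0)
        nonstd_n = sum(c for sym, c in counts.items() if sym in EXTENDED)
        mut_n = counts.get(mut_aa, 0)
        non_gap = n - gap_n
        rows.append(
            {
                "position": pos,
                "ref_aa": ref_aa,
                "mut_aa": mut_aa,
                "column": int(col),
                "n_homologs": n,
                "mut_count": mut_n,
                "mut_freq_pct": 100.0 * mut_n / n,
                "mut_freq_pct_gap_excluded": (
                    100.0 * mut_n / non_gap if non_gap else float("nan")
                ),
                "gap_pct": 100.0 * gap_n / n,
                "nonstandard_pct": 100.0 * nonstd_n / n,
            }
        )
        distributions[pos] = {sym: 100.0 * c / n for sym, c in sorted(counts.items())}
    return SiteFrequencyTable(table=pd.DataFrame(rows), distributions=distributions)
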