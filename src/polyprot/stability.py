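"""Dipeptide instability index, saturation-mutagenesis scanning, variant design.

The instability index of a protein sequence s of length L is

    II(s) = (10 / L) * sum_{i=1}^{L-1} DIWV(s_i, s_{i+1})

where DIWV is the published 20x20 dipeptide instability weight table
(Guruprasad et al.; the table used by the ExPASy ProtParam calculator).
Sequences with II below 40 are classified stable, at or above 40 unstable
(the boundary value itself counts as unstable).

The saturation scan replaces every position with each of the other 19
standard residues.  Because a substitution at position i only changes the
(i-1, i) and (i, i+1) dipeptides, each variant's index is evaluated
incrementally from the wild-type dipeptide sum; the test suite proves the
incremental evaluation exactly equal to full recomputation.  Positions are
ranked as instability hotspots by the most negative achievable delta-II
(ties broken by ascending position) — the procedure that identified H507 and
S584 in PFV PR-RT and led to the stabilised triple mutant C280S/H507D/S584K.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from ._diwv import DIWV, DIWV_SHA256, checksum

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STABILITY_THRESHOLD = 40.0

__all__ = [
    "DIWV",
    "DIWV_SHA256",
    "checksum",
    "instability_index",
    "classify_stability",
    "saturation_scan",
    "apply_variants",
    "ScanResult",
]


class NonStandardResidueError(ValueError):
    """Raised when a sequence contains a residue outside the standard 20."""


def _validate(sequence: str) -> str:
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_AA:
            raise NonStandardResidueError(
                f"non-standard residue {aa!r} at position {i}"
            )
    return sequence


def _dipeptide_sum(sequence: str) -> float:
    return sum(DIWV[a][b] for a, b in zip(sequence, sequence[1:]))


def instability_index(sequence: str) -> float:
    """Instability index (10/L × Σ dipeptide weights); 0 for length-1 input."""
    sequence = _validate(sequence)
    return 10.0 / len(sequence) * _dipeptide_sum(sequence)


def classify_stability(ii: float) -> str:
    """'stable' for II < 40, 'unstable' otherwise (boundary 40 → unstable)."""
    if not pd.notna(ii) or ii in (float("inf"), float("-inf")):
        raise ValueError(f"instability index must be finite, got {ii}")
    return "stable" if ii < STABILITY_THRESHOLD else "unstable"


@dataclass
class ScanResult:
    """Exhaustive single-substitution scan of one sequence.

    ``records`` holds all L×19 variants with columns position (1-based),
    wild, substitution, ii_variant, delta_ii; ``hotspots`` ranks positions by
    their best (most negative) achievable delta_ii, ties by position.
    """

    sequence: str
    ii_wild: float
    records: pd.DataFrame
    hotspots: pd.DataFrame

    def top_hotspots(self, n: int = 10) -> pd.DataFrame:
        return self.hotspots.head(n)

    def best_at(self, position: int) -> pd.Series:
        sub = self.records[self.records.position == position]
        return sub.loc[sub.delta_ii.idxmin()]


def saturation_scan(sequence: str) -> ScanResult:
    """Evaluate all 19 substitutions at every position of ``sequence``.

    Incremental evaluation: each variant re-scores only the one or two
    dipeptides overlapping the substituted position.
    """
    sequence = _validate(sequence)
    L = len(sequence)
    base_sum = _dipeptide_sum(sequence)
    ii_wild = 10.0 / L * base_sum

    positions, wilds, subs, iis, deltas = [], [], [], [], []
    for i, wild in enumerate(sequence):
        left = sequence[i - 1] if i > 0 else None
        right = sequence[i + 1] if i < L - 1 else None
        wild_local = (DIWV[left][wild] if left else 0.0) + (DIWV[wild][right] if right else 0.0)
        for sub in STANDARD_AA:
            if sub == wild:
                continue
            var_local = (DIWV[left][sub] if left else 0.0) + (DIWV[sub][right] if right else 0.0)
            ii_var = 10.0 / L * (base_sum - wild_local + var_local)
            positions.append(i + 1)
            wilds.append(wild)
            subs.append(sub)
            iis.append(ii_var)
            deltas.append(ii_var - ii_wild)

    records = pd.DataFrame(
        {
            "position": positions,
            "wild": wilds,
            "substitution": subs,
            "ii_variant": iis,
            "delta_ii": deltas,
        }
    )
    best = (
        records.groupby("position", sort=True)
        .agg(wild=("wild", "first"), best_delta_ii=("delta_ii", "min"))
        .reset_index()
    )
    best["best_substitution"] = [
        records[(records.position == p)].sort_values(["delta_ii", "substitution"]).iloc[0].substitution
        for p in best.position
    ]
    hotspots = best.sort_values(
        ["best_delta_ii", "position"], kind="mergesort"
    ).reset_index(drop=True)
    hotspots.insert(0, "rank", range(1, len(hotspots) + 1))
    return ScanResult(sequence=sequence, ii_wild=ii_wild, records=records, hotspots=hotspots)


_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def apply_variants(sequence: str, variants: list[str] | str) -> str:
    """Apply substitutions like ``"C280S"`` (1-based positions) to a sequence.

    The stated wild-type residue must match the sequence; on mismatch the
    error quotes expectation vs observation.
    """
    sequence = _validate(sequence)
    if isinstance(variants, str):
        variants = [v for v in re.split(r"[/,\s]+", variants) if v]
    seq = list(sequence)
    for v in variants:
        m = _VARIANT_RE.match(v.strip().upper())
        if not m:
            raise ValueError(f"cannot parse variant {v!r} (expected e.g. 'C280S')")
        wild, pos, sub = m.group(1), int(m.group(2)), m.group(3)
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"variant {v!r}: position outside 1..{len(seq)}")
        if seq[pos - 1] != wild:
            raise ValueError(
                f"variant {v!r}: expected {wild} at position {pos}, observed {seq[pos - 1]}"
            )
        if sub not in STANDARD_AA:
            raise NonStandardResidueError(f"variant {v!r}: {sub} is not a standard residue")
        seq[pos - 1] = sub
    return "".join(seq)


def read_fasta_sequence(path) -> str:
    """First sequence of a FASTA file (plain text), uppercased."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
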