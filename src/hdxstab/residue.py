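"""Peptide-level %D projected onto single-residue alignment coordinates.

Light chains of different sequence are compared on a shared master
alignment: each protein's sequential numbering maps to alignment columns
through its gapped alignment row.  Peptide-level percent deuteration is
reduced to residue level either by a coverage-weighted average (default,
transparent and deterministic) or by bounded least squares (nnls), and
conditions are compared cell-wise as difference maps.  A per-protein scalar
stability summary integrates %D over log10(time) per residue (trapezoids)
and sums over the residues covered in every compared experiment.  Both
protomers of a light-chain dimer are assumed equivalent and share one map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .errors import UsageError, ValidationError
from .exchange import FLAG_OK, compute_percent_d, reporter_residues
from .io import ProteinEntry, StateTable

__all__ = [
    "AlignmentMap",
    "ResidueExchangeMap",
    "DifferenceMap",
    "build_alignment_map",
    "map_interval",
    "reduce_to_residues",
    "difference_map",
    "exchange_auc",
]


@dataclass
class AlignmentMap:
    """Bidirectional map between sequential and alignment coordinates.

    Both coordinate systems are 1-based; gap columns map to nothing.
    """

    protein: str
    seq_to_aln: dict[int, int]
    aln_to_seq: dict[int, int]
    alignment_length: int

    def to_alignment(self, position: int) -> int:
        if position not in self.seq_to_aln:
            raise ValidationError(
                f"{self.protein}: sequential position {position} out of range"
            )
        return self.seq_to_aln[position]

    def to_sequential(self, position: int) -> int | None:
        """Sequential position at an alignment column; None at a gap."""
        if not 1 <= position <= self.alignment_length:
            raise ValidationError(
                f"{self.protein}: alignment position {position} out of range"
            )
        return self.aln_to_seq.get(position)


def build_alignment_map(entry: ProteinEntry) -> AlignmentMap:
    """Coordinate maps from a protein's gapped alignment row.

    A protein without an alignment row gets the identity map over its own
    sequence (sequential numbering doubles as alignment numbering).
    """
    if entry.alignment_row is None:
        n = len(entry.sequence)
        ident = {i: i for i in range(1, n + 1)}
        return AlignmentMap(entry.name, dict(ident), dict(ident), n)
    seq_to_aln: dict[int, int] = {}
    aln_to_seq: dict[int, int] = {}
    seq_pos = 0
    for col, char in enumerate(entry.alignment_row, start=1):
        if char == "-":
            continue
        seq_pos += 1
        seq_to_aln[seq_pos] = col
        aln_to_seq[col] = seq_pos
    if seq_pos != len(entry.sequence):
        raise ValidationError(f"{entry.name}: alignment row inconsistent with sequence")
    return AlignmentMap(entry.name, seq_to_aln, aln_to_seq, len(entry.alignment_row))


def map_interval(
    amap: AlignmentMap, start: int, end: int, direction: str
) -> tuple[int, int] | None:
    """Map an inclusive interval between coordinate systems.

    ``direction="seq_to_aln"`` may return a longer interval (interior gaps
    are legal); ``"aln_to_seq"`` drops gap columns and returns None when the
    interval covers only gaps for this protein.
    """
    if end < start:
        raise UsageError("interval end before start")
    if direction == "seq_to_aln":
        return amap.to_alignment(start), amap.to_alignment(end)
    if direction == "aln_to_seq":
        positions = [
            p
            for col in range(start, end + 1)
            if (p := amap.to_sequential(col)) is not None
        ]
        if not positions:
            return None
        return min(positions), max(positions)
    raise UsageError(f"unknown direction {direction!r}")


@dataclass
class ResidueExchangeMap:
    """Per-residue %D by condition and exposure on alignment coordinates."""

    protein: str
    positions: list[int]
    conditions: list[str]
    times: list[float]
    # indexed (position, condition, time) -> percent_d; absence = uncovered
    values: dict[tuple[int, str, float], float] = field(default_factory=dict)

    def value(self, position: int, condition: str, time: float) -> float | None:
        return self.values.get((position, condition, time))

    def covered(self, position: int, condition: str, time: float) -> bool:
        return (position, condition, time) in self.values

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            for cond in self.conditions:
                for t in self.times:
                    v = self.values.get((pos, cond, t))
                    rows.append(
                        {
                            "position": pos,
                            "condition": cond,
                            "exposure": t,
                            "percent_d": np.nan if v is None else v,
                            "covered": v is not None,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class DifferenceMap:
    """Cell-wise %D(A) - %D(B); stabilizer protection shows as negative values."""

    protein: str
    condition_a: str
    condition_b: str
    positions: list[int]
    times: list[float]
    delta: dict[tuple[int, float], float] = field(default_factory=dict)

    def value(self, position: int, time: float) -> float | None:
        return self.delta.get((position, time))


def _collect_percent_d(
    table: StateTable,
) -> tuple[list[tuple], dict]:
    """Mean ok-flagged %D per (peptide, condition, time), with reporter sets."""
    groups: dict[tuple, list[float]] = {}
    meta: dict[tuple, tuple] = {}
    for rec in table.records:
        uv = compute_percent_d(rec)
        if uv.flag != FLAG_OK or uv.percent_d is None:
            continue
        key = (rec.protein, rec.start, rec.end, rec.condition, rec.exposure)
        groups.setdefault(key, []).append(uv.percent_d)
        meta[key] = (rec.sequence,)
    out = []
    for key, vals in groups.items():
        (sequence,) = meta[key]
        reporters = reporter_residues(sequence, key[1])
        if reporters:
            out.append((key, float(np.mean(vals)), reporters))
    return out, meta


def reduce_to_residues(
    table: StateTable, method: str = "weighted_average"
) -> dict[str, ResidueExchangeMap]:
    """Reduce peptide %D to single-residue level, one map per protein.

    weighted_average: each residue's value is the mean of the %D of the
    peptides in which it is an exchangeable reporter, weighted by
    1/(number of reporters in the peptide) so short (more informative)
    peptides count more.

    nnls: per condition/time, solves the bounded linear system
    %D(peptide) = mean over its reporters of the residue values, with every
    residue constrained to [0, 100], minimizing the squared residual.

    Residue positions are alignment coordinates when the protein entry
    carries an alignment row, sequential positions otherwise.  Residues with
    no reporting peptide are uncovered.
    """
    if method not in ("weighted_average", "nnls"):
        raise UsageError(f"unknown reduction method {method!r}")
    peptide_values, _ = _collect_percent_d(table)
    if not peptide_values:
        raise UsageError("no usable %D values in the state table")

    amaps = {p.name: build_alignment_map(p) for p in table.proteins}

    # organize per protein
    by_protein: dict[str, list] = {}
    for key, pct, reporters in peptide_values:
        by_protein.setdefault(key[0], []).append((key, pct, reporters))

    out: dict[str, ResidueExchangeMap] = {}
    for protein, items in by_protein.items():
        amap = amaps.get(protein)
        conditions = sorted({k[3] for k, _, _ in items})
        times = sorted({k[4] for k, _, _ in items})
        all_residues = sorted({r for _, _, reps in items for r in reps})
        values: dict[tuple[int, str, float], float] = {}
        for cond in conditions:
            for t in times:
                sel = [
                    (pct, reps)
                    for (k, pct, reps) in items
                    if k[3] == cond and k[4] == t
                ]
                if not sel:
                    continue
                residues = sorted({r for _, reps in sel for r in reps})
                index = {r: i for i, r in enumerate(residues)}
                if method == "weighted_average":
                    num = np.zeros(len(residues))
                    den = np.zeros(len(residues))
                    for pct, reps in sel:
                        w = 1.0 / len(reps)
                        for r in reps:
                            num[index[r]] += w * pct
                            den[index[r]] += w
                    solved = num / den
                else:
                    A = np.zeros((len(sel), len(residues)))
                    b = np.zeros(len(sel))
                    for row, (pct, reps) in enumerate(sel):
                        for r in reps:
                            A[row, index[r]] = 1.0 / len(reps)
                        b[row] = pct
                    res = lsq_linear(A, b, bounds=(0.0, 100.0), method="bvls")
                    solved = res.x
                for r, v in zip(residues, solved):
                    pos = amap.to_alignment(r) if amap is not None else r
                    values[(pos, cond, float(t))] = float(v)
        if amap is not None:
            positions = sorted(
                {amap.to_alignment(r) for r in all_residues}
            )
        else:
            positions = all_residues
        out[protein] = ResidueExchangeMap(
            protein=protein,
            positions=positions,
            conditions=conditions,
            times=[float(t) for t in times],
            values=values,
        )
    return out


def difference_map(
    residue_map: ResidueExchangeMap, condition_a: str, condition_b: str
) -> DifferenceMap:
    """Cell-wise %D(A) - %D(B), defined only where both conditions are covered."""
    for cond in (condition_a, condition_b):
        if cond not in residue_map.conditions:
            raise UsageError(f"unknown condition label {cond!r}")
    delta: dict[tuple[int, float], float] = {}
    for pos in residue_map.positions:
        for t in residue_map.times:
            a = residue_map.value(pos, condition_a, t)
            b = residue_map.value(pos, condition_b, t)
            if a is not None and b is not None:
                delta[(pos, t)] = a - b
    return DifferenceMap(
        protein=residue_map.protein,
        condition_a=condition_a,
        condition_b=condition_b,
        positions=list(residue_map.positions),
        times=list(residue_map.times),
        delta=delta,
    )


def common_coverage(
    maps: Sequence[ResidueExchangeMap],
) -> list[int]:
    """Alignment positions covered at every condition and time of every map."""
    sets = []
    for m in maps:
        covered = {
            pos
            for pos in m.positions
            if all(
                m.covered(pos, cond, t) for cond in m.conditions for t in m.times
            )
        }
        sets.append(covered)
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)


def exchange_auc(
    residue_map: ResidueExchangeMap,
    condition: str,
    residues: Sequence[int] | None = None,
    time_axis: str = "log10",
) -> float:
    """Scalar exchange summary: trapezoidal AUC of %D over time, summed.

    Per residue, %D is integrated over log10(seconds) by default (the
    labeling grid is log-spaced, and a linear axis would be dominated by the
    longest time); per-residue areas are then summed over ``residues`` —
    normally the common-coverage set of the comparison group (see
    :func:`common_coverage`), by default every residue fully covered in this
    condition.
    """
    if condition not in residue_map.conditions:
        raise UsageError(f"unknown condition label {condition!r}")
    if len(residue_map.times) < 2:
        raise UsageError("need at least 2 timepoints for an exchange AUC")
    if time_axis == "log10":
        axis = np.log10(residue_map.times)
    elif time_axis == "linear":
        axis = np.asarray(residue_map.times, dtype=float)
    else:
        raise UsageError(f"unknown time axis {time_axis!r}")
    if residues is None:
        residues = [
            pos
            for pos in residue_map.positions
            if all(residue_map.covered(pos, condition, t) for t in residue_map.times)
        ]
    total = 0.0
    for pos in residues:
        vals = [residue_map.value(pos, condition, t) for t in residue_map.times]
        if any(v is None for v in vals):
            raise ValidationError(
                f"residue {pos} not covered at every time in {condition!r}"
            )
        order = np.argsort(axis)
        total += float(np.trapezoid(np.asarray(vals)[order], axis[order]))
    return total
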