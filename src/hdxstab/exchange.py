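"""Centroid masses to back-exchange-corrected deuterium uptake.

The observables per peptide are three centroid masses: the undeuterated
centroid ``m0``, the centroid after a labeling time ``mt``, and the centroid
of a maximally deuterated (maxD) control ``mmaxD``.  Deuterium uptake is
``mt - m0`` (Da) and the back-exchange-corrected percent deuteration is

    %D = 100 * (mt - m0) / (mmaxD - m0)

Because label loss during analysis scales ``mt - m0`` and ``mmaxD - m0`` by
the same retention factor, the ratio cancels back exchange exactly; this is
the central normalization the rest of the pipeline relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import UsageError, ValidationError

PROTON_MASS = 1.007276466  # Da
DEUTERON_MASS_SHIFT = 1.00627675  # Da, mass difference H -> D

#: %D outside this window is flagged out_of_range and excluded from residue
#: reduction by default (centroid noise on small maxD denominators can push
#: values slightly past the physical [0, 100] limits).
PERCENT_D_TOLERANCE = (-5.0, 105.0)

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_OUT_OF_RANGE = "out_of_range"


@dataclass
class PeptideUptakeRecord:
    """One peptide x condition x exposure observation.

    ``start``/``end`` are 1-based inclusive positions in the protein's own
    (sequential) numbering.  Centroids may be ``None`` when the peptide was
    not detected at that timepoint; such records are retained, flagged
    missing, and never imputed.
    """

    protein: str
    start: int
    end: int
    sequence: str
    condition: str
    exposure: float  # seconds
    m0: float | None = None
    mt: float | None = None
    mmaxD: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start + 2:
            raise ValidationError(
                f"peptide {self.protein} {self.start}-{self.end}: too short "
                "(no exchangeable reporters after N-terminal exclusion)"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.protein} {self.start}-{self.end}: sequence "
                f"length {len(self.sequence)} does not match interval"
            )
        if self.exposure < 0:
            raise ValidationError("exposure must be non-negative")
        if self.m0 is not None and self.mmaxD is not None and self.mmaxD <= self.m0:
            raise ValidationError(
                f"peptide {self.protein} {self.start}-{self.end}: maxD centroid "
                f"{self.mmaxD} not above undeuterated centroid {self.m0}"
            )

    @property
    def is_missing(self) -> bool:
        return self.mt is None or self.m0 is None


@dataclass
class UptakeValue:
    """Deuterium uptake for one record, with the %D level when computable."""

    uptake: float | None
    percent_d: float | None = None
    flag: str = FLAG_OK


@dataclass
class ReplicateSummary:
    """Mean and dispersion of replicate uptake measurements.

    Dispersion is reported as the range (max - min), matching how duplicate
    HDX measurements are usually displayed; the SD is added when n >= 3.
    """

    mean: float
    range: float
    n: int
    sd: float | None = None


def reporter_residues(sequence: str, start: int, protein_nterm: int = 1) -> list[int]:
    """Sequential positions in a peptide that report on exchange.

    The first two residues of every peptide are excluded (their amide
    deuterons back-exchange too fast to be retained through analysis),
    prolines carry no backbone amide, and the protein's N-terminal residue
    has no peptide-bond amide at all.
    """
    out = []
    for offset, aa in enumerate(sequence):
        pos = start + offset
        if offset < 2:
            continue
        if aa == "P":
            continue
        if pos == protein_nterm:
            continue
        out.append(pos)
    return out


def compute_uptake(record: PeptideUptakeRecord) -> UptakeValue:
    """Deuterium uptake mt - m0 in Da; missing centroids flag, not raise."""
    if record.mt is None or record.m0 is None:
        return UptakeValue(uptake=None, flag=FLAG_MISSING)
    return UptakeValue(uptake=record.mt - record.m0)


def compute_percent_d(record: PeptideUptakeRecord) -> UptakeValue:
    """Back-exchange-corrected percent deuteration.

    %D = 100 (mt - m0) / (mmaxD - m0).  Values slightly outside [0, 100]
    (instrument noise) are preserved; beyond ``PERCENT_D_TOLERANCE`` the
    value is flagged ``out_of_range``.
    """
    if record.mt is None or record.m0 is None or record.mmaxD is None:
        return UptakeValue(uptake=None, flag=FLAG_MISSING)
    if record.mmaxD <= record.m0:
        raise ValidationError(
            f"degenerate maxD control for {record.protein} "
            f"{record.start}-{record.end}: mmaxD <= m0"
        )
    uptake = record.mt - record.m0
    pct = 100.0 * uptake / (record.mmaxD - record.m0)
    flag = FLAG_OK
    lo, hi = PERCENT_D_TOLERANCE
    if not (lo <= pct <= hi):
        flag = FLAG_OUT_OF_RANGE
    return UptakeValue(uptake=uptake, percent_d=pct, flag=flag)


def aggregate_replicates(records: Sequence[PeptideUptakeRecord]) -> ReplicateSummary:
    """Mean uptake and range over replicates of one peptide/condition/time."""
    if not records:
        raise UsageError("aggregate_replicates: empty record list")
    values = [compute_uptake(r).uptake for r in records]
    values = [v for v in values if v is not None]
    if not values:
        raise UsageError("aggregate_replicates: all replicates missing")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 3 else None
    return ReplicateSummary(
        mean=float(arr.mean()),
        range=float(arr.max() - arr.min()),
        n=arr.size,
        sd=sd,
    )


def centroid_mass(peaks: Iterable[tuple[float, float]], charge: int) -> float:
    """Neutral centroid mass from an (m/z, intensity) peak list.

    The centroid is the intensity-weighted mean m/z; the neutral mass is
    recovered as ``centroid_mz * z - z * m_proton``.
    """
    if charge <= 0:
        raise ValidationError("charge must be a positive integer")
    peaks = list(peaks)
    if not peaks:
        raise ValidationError("empty peak list")
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    total = inten.sum()
    if total <= 0 or not math.isfinite(total):
        raise ValidationError("peak list has no positive total intensity")
    centroid_mz = float((mz * inten).sum() / total)
    return centroid_mz * charge - charge * PROTON_MASS
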