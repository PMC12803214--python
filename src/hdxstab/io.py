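"""Readers and writers for the tabular and sequence formats in the pipeline.

Formats handled: FASTA (protein sequences and gapped alignment rows),
peptide state tables (DynamX-style or the package's native CSV), long-format
residue tables, JSON reports, and a YAML run configuration.

Conventions: sequential protein numbering is 1-based with inclusive
intervals; alignment numbering is 1-based over the master alignment columns;
exposure times are stored in seconds.  Missing centroids (peptide not
detected at a timepoint) are kept as flagged-missing records, never imputed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

from Bio import SeqIO

from .errors import FormatError, UsageError, ValidationError
from .exchange import PeptideUptakeRecord


@dataclass
class ProteinEntry:
    """A protein with optional master-alignment row and region annotations.

    ``alignment_row`` is the gapped string over the master alignment
    (gap character '-'); stripping gaps must reproduce ``sequence``.
    ``domain_boundary`` is the alignment position separating the variable
    domain (columns 1..boundary) from the constant domain.
    ``region_annotations`` are (label, alignment_start, alignment_end)
    triples for framework and CDR regions.
    """

    name: str
    sequence: str
    alignment_row: str | None = None
    domain_boundary: int | None = None
    region_annotations: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alignment_row is not None:
            ungapped = self.alignment_row.replace("-", "")
            if ungapped != self.sequence:
                raise ValidationError(
                    f"{self.name}: ungapped alignment row does not equal sequence"
                )
            if self.domain_boundary is not None and not (
                1 <= self.domain_boundary <= len(self.alignment_row)
            ):
                raise ValidationError(
                    f"{self.name}: domain boundary outside alignment length"
                )


@dataclass
class StateTable:
    """Peptide-level HDX observations plus the proteins they refer to."""

    records: list[PeptideUptakeRecord]
    proteins: list[ProteinEntry] = field(default_factory=list)

    def protein(self, name: str) -> ProteinEntry:
        for p in self.proteins:
            if p.name == name:
                return p
        raise UsageError(f"unknown protein {name!r}")

    def validate_against_proteins(self) -> None:
        """Check every record's peptide against its protein sequence."""
        by_name = {p.name: p for p in self.proteins}
        for i, rec in enumerate(self.records):
            prot = by_name.get(rec.protein)
            if prot is None:
                continue
            segment = prot.sequence[rec.start - 1 : rec.end]
            if segment != rec.sequence:
                raise ValidationError(
                    f"row {i + 1}: peptide {rec.sequence!r} does not match "
                    f"{rec.protein} residues {rec.start}-{rec.end} ({segment!r})"
                )


_EXPOSURE_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*([a-zA-Z]*)\s*$")
_UNIT_SECONDS = {
    "": 1.0,
    "s": 1.0,
    "sec": 1.0,
    "secs": 1.0,
    "second": 1.0,
    "seconds": 1.0,
    "m": 60.0,
    "min": 60.0,
    "mins": 60.0,
    "minute": 60.0,
    "minutes": 60.0,
    "h": 3600.0,
    "hr": 3600.0,
    "hrs": 3600.0,
    "hour": 3600.0,
    "hours": 3600.0,
}


def parse_exposure(token: str | float | int) -> float:
    """Parse an exposure token ("10 s", "1 min", "16 h", bare seconds) to seconds."""
    if isinstance(token, (int, float)):
        value = float(token)
    else:
        m = _EXPOSURE_RE.match(str(token))
        if m is None:
            raise FormatError(f"cannot parse exposure token {token!r}")
        unit = m.group(2).lower()
        if unit not in _UNIT_SECONDS:
            raise FormatError(f"unknown exposure unit {unit!r} in {token!r}")
        value = float(m.group(1)) * _UNIT_SECONDS[unit]
    if value < 0:
        raise ValidationError("exposure must be non-negative")
    return value


_NATIVE_COLUMNS = [
    "protein",
    "start",
    "end",
    "sequence",
    "condition",
    "exposure_s",
    "replicate",
    "m0",
    "mt",
    "mmaxD",
]

_DYNAMX_REQUIRED = ["protein", "start", "end", "sequence", "state", "exposure", "center"]


def _opt_float(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


def read_peptide_state_table(
    path: str | Path,
    dialect: str = "native",
    proteins: Sequence[ProteinEntry] | None = None,
) -> StateTable:
    """Read a peptide-level state table.

    ``dialect="native"`` expects the package's own long CSV with explicit
    m0/mt/mmaxD columns.  ``dialect="dynamx_state"`` (alias "dynax_state")
    expects a DynamX-style state-data export with one centroid column:
    rows at exposure 0 supply m0 and rows whose state is "maxD" supply the
    maximally deuterated control, both joined per peptide.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file (no header row)")
        header = {c.strip().lower(): c for c in reader.fieldnames}
        rows = list(reader)

    def col(row: dict, name: str) -> str:
        return row[header[name]]

    if dialect == "native":
        missing = [c for c in _NATIVE_COLUMNS if c.lower() not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        records = []
        for i, row in enumerate(rows):
            try:
                records.append(
                    PeptideUptakeRecord(
                        protein=col(row, "protein"),
                        start=int(col(row, "start")),
                        end=int(col(row, "end")),
                        sequence=col(row, "sequence"),
                        condition=col(row, "condition"),
                        exposure=parse_exposure(col(row, "exposure_s")),
                        replicate=int(col(row, "replicate")),
                        m0=_opt_float(col(row, "m0")),
                        mt=_opt_float(col(row, "mt")),
                        mmaxD=_opt_float(col(row, "mmaxd")),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    elif dialect in ("dynamx_state", "dynax_state"):
        missing = [c for c in _DYNAMX_REQUIRED if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        # first pass: undeuterated and maxD controls per peptide
        m0_by_pep: dict[tuple, float] = {}
        maxd_by_pep: dict[tuple, float] = {}
        for row in rows:
            key = (col(row, "protein"), int(col(row, "start")), int(col(row, "end")))
            center = _opt_float(col(row, "center"))
            if center is None:
                continue
            state = col(row, "state").strip().lower()
            if state in ("maxd", "fd", "max"):
                maxd_by_pep[key] = center
            elif parse_exposure(col(row, "exposure")) == 0.0:
                m0_by_pep.setdefault(key, center)
        records = []
        replicate_counter: dict[tuple, int] = {}
        for i, row in enumerate(rows):
            state = col(row, "state").strip()
            if state.lower() in ("maxd", "fd", "max"):
                continue
            exposure = parse_exposure(col(row, "exposure"))
            if exposure == 0.0:
                continue
            key = (col(row, "protein"), int(col(row, "start")), int(col(row, "end")))
            rep_key = key + (state, exposure)
            replicate_counter[rep_key] = replicate_counter.get(rep_key, 0) + 1
            try:
                records.append(
                    PeptideUptakeRecord(
                        protein=key[0],
                        start=key[1],
                        end=key[2],
                        sequence=col(row, "sequence"),
                        condition=state,
                        exposure=exposure,
                        replicate=replicate_counter[rep_key],
                        m0=m0_by_pep.get(key),
                        mt=_opt_float(col(row, "center")),
                        mmaxD=maxd_by_pep.get(key),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    else:
        raise UsageError(f"unknown state-table dialect {dialect!r}")

    table = StateTable(records=records, proteins=list(proteins or []))
    if proteins:
        table.validate_against_proteins()
    return table


def write_peptide_state_table(table: StateTable, path: str | Path) -> None:
    """Write a StateTable as native-dialect CSV (round-trips losslessly)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_NATIVE_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.protein,
                    rec.start,
                    rec.end,
                    rec.sequence,
                    rec.condition,
                    repr(rec.exposure),
                    rec.replicate,
                    "" if rec.m0 is None else repr(rec.m0),
                    "" if rec.mt is None else repr(rec.mt),
                    "" if rec.mmaxD is None else repr(rec.mmaxD),
                ]
            )


_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read protein sequences from FASTA; names from headers, '*' stripped."""
    path = Path(path)
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        bad = set(seq) - _AA_CODES
        if bad:
            raise ValidationError(
                f"{path}: {rec.id}: non-amino-acid characters {sorted(bad)}"
            )
        entries.append(ProteinEntry(name=rec.id, sequence=seq))
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")
    return entries


def read_alignment_table(path: str | Path) -> list[ProteinEntry]:
    """Read a gapped alignment (aligned FASTA, or CSV with name,alignment_row)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with path.open() as fh:
        first = fh.readline()
    if first.startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            rows.append((rec.id, str(rec.seq).upper()))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "name",
                "alignment_row",
            } <= {c.strip().lower() for c in reader.fieldnames}:
                raise FormatError(
                    f"{path}: expected aligned FASTA or CSV with "
                    "'name' and 'alignment_row' columns"
                )
            header = {c.strip().lower(): c for c in reader.fieldnames}
            for row in reader:
                rows.append(
                    (row[header["name"]], row[header["alignment_row"]].upper())
                )
    if not rows:
        raise FormatError(f"{path}: no alignment rows found")
    lengths = {len(r[1]) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: alignment rows have unequal lengths {sorted(lengths)}")
    return [
        ProteinEntry(name=name, sequence=row.replace("-", ""), alignment_row=row)
        for name, row in rows
    ]


def write_residue_table(residue_map: "Any", path: str | Path) -> None:
    """Write a ResidueExchangeMap as long CSV (one row per cell).

    Uncovered cells are emitted with covered=false and an empty %D field so
    coverage gaps survive a round trip.
    """
    path = Path(path)
    frame = residue_map.to_frame()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein", "alignment_position", "condition", "exposure_s", "percentD", "covered"]
        )
        for row in frame.itertuples(index=False):
            writer.writerow(
                [
                    residue_map.protein,
                    row.position,
                    row.condition,
                    repr(float(row.exposure)),
                    "" if not row.covered else repr(float(row.percent_d)),
                    "true" if row.covered else "false",
                ]
            )


def read_residue_table(path: str | Path) -> "Any":
    """Read a long-format residue CSV back into a ResidueExchangeMap.

    Inverse of :func:`write_residue_table`; uncovered cells (covered=false)
    come back as coverage gaps.
    """
    from .residue import ResidueExchangeMap

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"protein", "alignment_position", "condition", "exposure_s",
                    "percentD", "covered"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: missing residue-table column(s)")
        rows = list(reader)
    if not rows:
        raise FormatError(f"{path}: empty residue table")
    protein = rows[0]["protein"]
    positions, conditions, times = set(), set(), set()
    values: dict[tuple[int, str, float], float] = {}
    for row in rows:
        pos = int(row["alignment_position"])
        cond = row["condition"]
        t = float(row["exposure_s"])
        positions.add(pos)
        conditions.add(cond)
        times.add(t)
        if row["covered"].strip().lower() == "true":
            values[(pos, cond, t)] = float(row["percentD"])
    return ResidueExchangeMap(
        protein=protein,
        positions=sorted(positions),
        conditions=sorted(conditions),
        times=sorted(times),
        values=values,
    )


REPORT_SCHEMA_VERSION = "1"


def _jsonable(obj: Any) -> Any:
    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(
    results: Any,
    path: str | Path,
    parameters: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write any pipeline product as deterministic, schema-versioned JSON."""
    from .plimstex import BindingFit, TitrationSeries
    from .proteolysis import DecayFit, ProteolysisTimecourse, StabilityComparison
    from .exchange import ReplicateSummary, UptakeValue

    known = (
        BindingFit,
        TitrationSeries,
        DecayFit,
        ProteolysisTimecourse,
        StabilityComparison,
        ReplicateSummary,
        UptakeValue,
        dict,
        list,
    )
    if not isinstance(results, known):
        raise UsageError(f"cannot report object of type {type(results).__name__}")
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "result_type": type(results).__name__,
        "parameters": _jsonable(parameters or {}),
        "seed": seed,
        "results": _jsonable(results),
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


DEFAULT_CONFIG = {
    "labeling_times_s": [10.0, 60.0, 600.0, 3600.0, 14400.0, 57600.0],
    "label_fraction": 0.9,
    "noise_sd_da": 0.20,
    "deuteron_mass_da": 1.00627675,
    "plimstex_exposure_s": 5400.0,
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """Load the YAML run configuration, filling defaults for absent keys."""
    import yaml

    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise UsageError(f"unknown config key(s): {sorted(unknown)}")
        config.update(loaded)
    return config
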