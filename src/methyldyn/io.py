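"""Readers and writers for the tabular formats, and PDB methyl extraction.

All tables are TSV, UTF-8, one header row, ``#`` comment lines. Reads are
lossless round-trips of the corresponding writes at full float precision.
A :class:`ColumnMap` dialect maps this package's canonical column names onto
whatever headers a file actually uses; nothing is ever guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .exceptions import MethylDynError, TableFormatError
from .probes import (
    BuildupSeries,
    MethylProbe,
    OrderParameterEntry,
    OrderParameterSet,
    RelaxationRecord,
)

# ---------------------------------------------------------------------------
# generic TSV plumbing


@dataclass
class ColumnMap:
    """Maps canonical column names to the headers used in a file."""

    mapping: dict = dc_field(default_factory=dict)

    def resolve(self, canonical: str) -> str:
        return self.mapping.get(canonical, canonical)


def _read_tsv_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(line_number, fields), ...]) skipping comments/blanks."""
    header = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip() for h in fields]
            else:
                rows.append((lineno, fields))
    return header, rows


def _index_columns(header, canonical_names, dialect, path):
    dialect = dialect or ColumnMap()
    idx = {}
    missing = []
    for name in canonical_names:
        col = dialect.resolve(name)
        if col in header:
            idx[name] = header.index(col)
        else:
            missing.append(col)
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s) {missing}; header was {header}"
        )
    return idx


def _parse_float(value: str) -> float:
    return float(value)


# ---------------------------------------------------------------------------
# relaxation tables

RELAXATION_COLUMNS = (
    "residue_number",
    "R1",
    "R1_err",
    "R2",
    "R2_err",
    "field_MHz",
    "temperature_K",
)


def read_relaxation_table(path, dialect: ColumnMap | None = None) -> list[RelaxationRecord]:
    """Read per-residue ¹⁵N R1/R2 records from a TSV file.

    Malformed rows are reported collectively in a :class:`TableFormatError`
    carrying ``(line_number, detail)`` tuples.
    """
    header, rows = _read_tsv_rows(path)
    if header is None:
        warnings.warn(f"{path}: empty relaxation table", stacklevel=2)
        return []
    idx = _index_columns(header, RELAXATION_COLUMNS, dialect, path)
    records, bad = [], []
    for lineno, fields in rows:
        try:
            records.append(
                RelaxationRecord(
                    residue_number=int(fields[idx["residue_number"]]),
                    R1=_parse_float(fields[idx["R1"]]),
                    R1_err=_parse_float(fields[idx["R1_err"]]),
                    R2=_parse_float(fields[idx["R2"]]),
                    R2_err=_parse_float(fields[idx["R2_err"]]),
                    field_MHz=_parse_float(fields[idx["field_MHz"]]),
                    temperature_K=_parse_float(fields[idx["temperature_K"]]),
                )
            )
        except (ValueError, IndexError, MethylDynError) as exc:
            bad.append((lineno, f"{exc} in row {fields!r}"))
    if bad:
        raise TableFormatError(
            f"{path}: {len(bad)} malformed row(s), first at line {bad[0][0]}: "
            f"{bad[0][1]}",
            rows=bad,
        )
    if not records:
        warnings.warn(f"{path}: relaxation table contains no data rows", stacklevel=2)
    return records


def write_relaxation_table(records: Sequence[RelaxationRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RELAXATION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        str(r.residue_number),
                        repr(float(r.R1)),
                        repr(float(r.R1_err)),
                        repr(float(r.R2)),
                        repr(float(r.R2_err)),
                        repr(float(r.field_MHz)),
                        repr(float(r.temperature_K)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# order-parameter tables

ORDER_PARAMETER_COLUMNS = (
    "chain",
    "residue_number",
    "residue_type",
    "methyl_id",
    "O2_axis",
    "error",
    "temperature_K",
    "environment",
    "tau_m_ns",
)


def write_order_parameter_table(opset: OrderParameterSet, path) -> None:
    """Write an :class:`OrderParameterSet` as a fixed-column TSV.

    The set's invariants (probe uniqueness) are enforced at construction,
    so any set reaching this point is writable; read-back reproduces it
    exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ORDER_PARAMETER_COLUMNS) + "\n")
        for e in opset.entries:
            p = e.probe
            fh.write(
                "\t".join(
                    [
                        p.chain_id,
                        str(p.residue_number),
                        p.residue_type,
                        p.methyl_id,
                        repr(float(e.O2_axis)),
                        repr(float(e.error)),
                        repr(float(e.temperature_K)),
                        e.environment,
                        repr(float(opset.tau_m_ns)),
                    ]
                )
                + "\n"
            )


def read_order_parameter_table(path, dialect: ColumnMap | None = None) -> OrderParameterSet:
    header, rows = _read_tsv_rows(path)
    if header is None:
        warnings.warn(f"{path}: empty order-parameter table", stacklevel=2)
        return OrderParameterSet([])
    idx = _index_columns(header, ORDER_PARAMETER_COLUMNS, dialect, path)
    entries, bad = [], []
    tau_m_ns = float("nan")
    for lineno, fields in rows:
        try:
            probe = MethylProbe(
                residue_number=int(fields[idx["residue_number"]]),
                residue_type=fields[idx["residue_type"]],
                methyl_id=fields[idx["methyl_id"]],
                chain_id=fields[idx["chain"]],
            )
            entries.append(
                OrderParameterEntry(
                    probe=probe,
                    O2_axis=_parse_float(fields[idx["O2_axis"]]),
                    error=_parse_float(fields[idx["error"]]),
                    temperature_K=_parse_float(fields[idx["temperature_K"]]),
                    environment=fields[idx["environment"]],
                )
            )
            tau_m_ns = _parse_float(fields[idx["tau_m_ns"]])
        except (ValueError, IndexError, MethylDynError) as exc:
            bad.append((lineno, str(exc)))
    if bad:
        raise TableFormatError(
            f"{path}: {len(bad)} malformed row(s), first at line {bad[0][0]}: {bad[0][1]}",
            rows=bad,
        )
    return OrderParameterSet(entries, tau_m_ns=tau_m_ns)


# ---------------------------------------------------------------------------
# build-up series tables

BUILDUP_COLUMNS = (
    "chain",
    "residue_number",
    "residue_type",
    "methyl_id",
    "delay_s",
    "ratio",
    "ratio_err",
    "temperature_K",
)


def write_buildup_table(series_list: Sequence[BuildupSeries], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(BUILDUP_COLUMNS) + "\n")
        for s in series_list:
            p = s.probe
            for t, r, e in zip(s.delays, s.ratios, s.ratio_errs):
                fh.write(
                    "\t".join(
                        [
                            p.chain_id,
                            str(p.residue_number),
                            p.residue_type,
                            p.methyl_id,
                            repr(float(t)),
                            repr(float(r)),
                            repr(float(e)),
                            repr(float(s.temperature_K)),
                        ]
                    )
                    + "\n"
                )


def read_buildup_table(path, dialect: ColumnMap | None = None) -> list[BuildupSeries]:
    header, rows = _read_tsv_rows(path)
    if header is None:
        warnings.warn(f"{path}: empty build-up table", stacklevel=2)
        return []
    idx = _index_columns(header, BUILDUP_COLUMNS, dialect, path)
    grouped: dict = {}
    order: list = []
    bad = []
    for lineno, fields in rows:
        try:
            probe = MethylProbe(
                residue_number=int(fields[idx["residue_number"]]),
                residue_type=fields[idx["residue_type"]],
                methyl_id=fields[idx["methyl_id"]],
                chain_id=fields[idx["chain"]],
            )
            key = probe.key
            if key not in grouped:
                grouped[key] = {
                    "probe": probe,
                    "delays": [],
                    "ratios": [],
                    "errs": [],
                    "temperature_K": _parse_float(fields[idx["temperature_K"]]),
                }
                order.append(key)
            g = grouped[key]
            g["delays"].append(_parse_float(fields[idx["delay_s"]]))
            g["ratios"].append(_parse_float(fields[idx["ratio"]]))
            g["errs"].append(_parse_float(fields[idx["ratio_err"]]))
        except (ValueError, IndexError, MethylDynError) as exc:
            bad.append((lineno, str(exc)))
    if bad:
        raise TableFormatError(
            f"{path}: {len(bad)} malformed row(s), first at line {bad[0][0]}: {bad[0][1]}",
            rows=bad,
        )
    series = []
    for key in order:
        g = grouped[key]
        pts = sorted(zip(g["delays"], g["ratios"], g["errs"]))
        series.append(
            BuildupSeries(
                probe=g["probe"],
                delays=tuple(p[0] for p in pts),
                ratios=tuple(p[1] for p in pts),
                ratio_errs=tuple(p[2] for p in pts),
                temperature_K=g["temperature_K"],
            )
        )
    return series


# ---------------------------------------------------------------------------
# PDB methyl extraction

#: methyl carbon atom per residue type -> methyl label
METHYL_ATOMS = {
    "ILE": (("CD1", "d1"),),
    "LEU": (("CD1", "d1"), ("CD2", "d2")),
    "VAL": (("CG1", "g1"), ("CG2", "g2")),
    "MET": (("CE", "e"),),
}


def extract_methyl_probes(path, chain: str) -> list[tuple[MethylProbe, np.ndarray]]:
    """Extract ILVM methyl carbons from a PDB file.

    Uses the first model and author residue numbering; altloc '' or 'A'
    only. Returns ``(probe, carbon_position_Å)`` tuples. Residues whose
    expected methyl carbon is absent from the model are skipped with a
    warning.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise TableFormatError(f"{path}: cannot parse structure: {exc}") from exc
    if len(structure) == 0:
        raise TableFormatError(f"{path}: structure contains no models")
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise MethylDynError(
            f"{path}: chain {chain!r} not found (have "
            f"{[c.name for c in model]})"
        )
    out = []
    for residue in ch:
        spec = METHYL_ATOMS.get(residue.name)
        if spec is None:
            continue
        for atom_name, methyl_id in spec:
            atom = None
            for a in residue:
                if a.name == atom_name and a.altloc in ("\0", "", "A"):
                    atom = a
                    break
            if atom is None:
                warnings.warn(
                    f"{residue.name}{residue.seqid.num} chain {chain}: "
                    f"methyl carbon {atom_name} missing; probe skipped",
                    stacklevel=2,
                )
                continue
            probe = MethylProbe(
                residue_number=residue.seqid.num,
                residue_type=residue.name,
                methyl_id=methyl_id,
                chain_id=chain,
            )
            out.append((probe, np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    if not out:
        warnings.warn(f"{path} chain {chain}: no ILVM methyl probes found", stacklevel=2)
    return out
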