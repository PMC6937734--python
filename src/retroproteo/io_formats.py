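"""Readers and writers for the file dialects the pipeline touches.

All parsing is isolated here; computation modules only ever see the parsed
domain objects.  Supported formats:

* multi-line FASTA ('>' headers) via Biopython,
* MGF peak lists (``BEGIN IONS``/``END IONS``) via pyteomics,
* a simplified tab-separated PSM report dialect (one row per
  peptide-spectrum match; see :func:`read_psm_table` for the columns),
* MaxQuant ``proteinGroups``-style intensity TSVs with ``LFQ intensity <sample>``
  columns and '+'-flagged ``Reverse`` / ``Potential contaminant`` rows.

Missing intensities are encoded as 0 on disk (the MaxQuant convention) and
converted to an explicit mask immediately downstream; no computation module
ever tests for 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .fragment_annotation import PSMRecord, Spectrum

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the documented dialect."""


@dataclass
class SequenceEntry:
    """One FASTA record.

    ``identifier`` is the header token up to the first whitespace,
    ``description`` the remainder of the header line.  Residues are
    uppercased on parse; '*' stop symbols are stripped from protein
    sequences with a logged note.
    """

    identifier: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier!r}")


@dataclass
class PSMTable:
    """Container for one sample's PSM rows."""

    rows: list[PSMRecord]
    source_label: str = ""


@dataclass
class RawIntensityTable:
    """MaxQuant-style protein-by-sample intensity matrix, pre-masking.

    ``values`` holds non-negative reals with 0 meaning "not quantified".
    Flags are derived only from '+' markers in the ``Reverse`` /
    ``Potential contaminant`` columns.
    """

    protein_ids: list[str]
    sample_columns: list[str]
    values: np.ndarray
    reverse_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    contaminant_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.protein_ids)
        if self.values.shape != (n, len(self.sample_columns)):
            raise ValueError("values matrix does not match protein_ids x sample_columns")
        if (self.values < 0).any():
            raise ValueError("negative intensities are not allowed")
        if self.reverse_flags is None:
            self.reverse_flags = np.zeros(n, dtype=bool)
        if self.contaminant_flags is None:
            self.contaminant_flags = np.zeros(n, dtype=bool)
        self.reverse_flags = np.asarray(self.reverse_flags, dtype=bool)
        self.contaminant_flags = np.asarray(self.contaminant_flags, dtype=bool)
        if len(self.reverse_flags) != n or len(self.contaminant_flags) != n:
            raise ValueError("flag vectors must match protein_ids")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceEntry]:
    """Read a FASTA file into :class:`SequenceEntry` objects.

    Line breaks inside sequences are joined; residues are uppercased and
    '*' symbols stripped (logged).  Duplicate identifiers raise
    :class:`FormatError` naming the duplicate.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    entries: list[SequenceEntry] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if "*" in residues:
            logger.info("stripping %d stop symbol(s) from %s", residues.count("*"), rec.id)
            residues = residues.replace("*", "")
        description = rec.description[len(rec.id):].strip()
        entries.append(SequenceEntry(rec.id, description, residues))
    return entries


def write_fasta(entries: Iterable[SequenceEntry], path: str | Path, width: int = 60) -> None:
    """Write entries as wrapped FASTA (default 60-column lines)."""
    records = []
    for e in entries:
        rec = SeqRecord(Seq(e.residues), id=e.identifier, description=e.description)
        records.append(rec)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PSM tables

_PSM_COLUMNS = ("spectrum", "peptide", "prev_aa", "next_aa", "proteins", "evalue", "modifications")

#: Monoisotopic mass shifts for modification names accepted in PSM tables.
NAMED_MODIFICATIONS = {
    "deamidation": 0.984016,
    "oxidation": 15.994915,
    "dioxidation": 31.989829,
    "carbamidomethyl": 57.021464,
    "acetyl": 42.010565,
    "phospho": 79.966331,
}


def _parse_modifications(cell: str, line_no: int) -> list[tuple[int, float, str]]:
    mods: list[tuple[int, float, str]] = []
    cell = cell.strip()
    if not cell:
        return mods
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            pos_str, value = token.split(":", 1)
            pos = int(pos_str)
        except ValueError as exc:
            raise FormatError(f"line {line_no}: bad modification token {token!r}") from exc
        try:
            mods.append((pos, float(value), ""))
        except ValueError:
            name = value.strip().lower()
            if name not in NAMED_MODIFICATIONS:
                raise FormatError(
                    f"line {line_no}: unknown modification name {value!r}"
                ) from None
            mods.append((pos, NAMED_MODIFICATIONS[name], name))
    return mods


def read_psm_table(path: str | Path, source_label: str | None = None) -> PSMTable:
    """Read the simplified tab-separated PSM dialect.

    The header must name at least the columns ``spectrum``, ``peptide``,
    ``prev_aa``, ``next_aa``, ``proteins``, ``evalue`` and
    ``modifications``.  ``proteins`` is ';'-separated; ``modifications``
    holds ``position:mass-or-name`` tokens joined by ';' (1-based residue
    positions); '-' in ``prev_aa``/``next_aa`` marks a protein terminus.
    An optional ``sample`` column attaches a per-row sample label.
    """
    path = Path(path)
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        header = [h.strip() for h in header_line.rstrip("\n").split("\t")]
        missing = [c for c in _PSM_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        rows: list[PSMRecord] = []
        for line_no, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < len(header):
                cells += [""] * (len(header) - len(cells))
            try:
                evalue = float(cells[idx["evalue"]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {line_no}: unparsable e-value {cells[idx['evalue']]!r}"
                ) from exc
            peptide = cells[idx["peptide"]].strip().upper()
            if not peptide:
                raise FormatError(f"{path}: line {line_no}: empty peptide")
            rows.append(
                PSMRecord(
                    spectrum_id=cells[idx["spectrum"]].strip(),
                    peptide=peptide,
                    modifications=_parse_modifications(cells[idx["modifications"]], line_no),
                    prev_aa=cells[idx["prev_aa"]].strip() or "-",
                    next_aa=cells[idx["next_aa"]].strip() or "-",
                    assignments=[p.strip() for p in cells[idx["proteins"]].split(";") if p.strip()],
                    evalue=evalue,
                    sample=cells[idx["sample"]].strip() if "sample" in idx else "",
                )
            )
    return PSMTable(rows=rows, source_label=source_label or path.stem)


def write_psm_table(table: PSMTable, path: str | Path) -> None:
    """Write a :class:`PSMTable` back to the simplified TSV dialect."""
    with open(path, "w") as handle:
        handle.write("\t".join(_PSM_COLUMNS + ("sample",)) + "\n")
        for r in table.rows:
            mods = ";".join(
                f"{pos}:{name or mass:g}" if not name else f"{pos}:{name}"
                for pos, mass, name in r.modifications
            )
            handle.write(
                "\t".join(
                    [
                        r.spectrum_id,
                        r.peptide,
                        r.prev_aa,
                        r.next_aa,
                        ";".join(r.assignments),
                        f"{r.evalue:g}",
                        mods,
                        r.sample,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Intensity tables

_LFQ_PREFIX = "LFQ intensity "


def read_intensity_table(path: str | Path) -> RawIntensityTable:
    """Read a MaxQuant ``proteinGroups``-style TSV.

    Requires a ``Protein IDs`` column and at least one ``LFQ intensity X``
    column; sample names are the ``X`` suffixes.  Empty cells read as 0
    (missing).  '+' in ``Reverse`` / ``Potential contaminant`` sets the
    corresponding flag.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "Protein IDs" not in df.columns:
        raise FormatError(f"{path}: missing 'Protein IDs' column")
    lfq_cols = [c for c in df.columns if c.startswith(_LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(f"{path}: no 'LFQ intensity' columns found")
    samples = [c[len(_LFQ_PREFIX):] for c in lfq_cols]
    values = (
        df[lfq_cols]
        .replace("", "0")
        .apply(lambda col: col.astype(float))
        .to_numpy()
    )

    def flags(col: str) -> np.ndarray:
        if col in df.columns:
            return (df[col].str.strip() == "+").to_numpy()
        return np.zeros(len(df), dtype=bool)

    return RawIntensityTable(
        protein_ids=df["Protein IDs"].tolist(),
        sample_columns=samples,
        values=values,
        reverse_flags=flags("Reverse"),
        contaminant_flags=flags("Potential contaminant"),
    )


def write_intensity_table(table: RawIntensityTable, path: str | Path) -> None:
    """Write a :class:`RawIntensityTable` as a MaxQuant-style TSV."""
    import pandas as pd

    data = {"Protein IDs": table.protein_ids}
    for j, s in enumerate(table.sample_columns):
        data[_LFQ_PREFIX + s] = table.values[:, j]
    data["Reverse"] = ["+" if f else "" for f in table.reverse_flags]
    data["Potential contaminant"] = ["+" if f else "" for f in table.contaminant_flags]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    Peaks are sorted ascending by m/z; ``PEPMASS`` and ``CHARGE`` are
    captured when present.  Spectra are returned in file order.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            precursor_mz = float(pepmass[0]) if pepmass else None
            charge = params.get("charge")
            precursor_charge = int(charge[0]) if charge else None
            spectra.append(
                Spectrum(
                    peaks=list(zip(mz[order].tolist(), inten[order].tolist())),
                    precursor_mz=precursor_mz,
                    precursor_charge=precursor_charge,
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF blocks in order."""
    entries = []
    for i, s in enumerate(spectra):
        params: dict = {"title": s.title or f"spectrum_{i}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "params": params,
                "m/z array": np.array([p[0] for p in s.peaks]),
                "intensity array": np.array([p[1] for p in s.peaks]),
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
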