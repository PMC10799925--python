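"""Readers and writers for every external representation the pipeline touches.

Sequences travel as FASTA, structures as PDB CA traces (the B-factor column
is interpreted as per-residue pLDDT when it lies in [0, 100]), and tabular
annotations (domain hits, defense systems, screen reports) as tab-delimited
UTF-8 text with a header row and '.'-decimal numbers.

Genomic coordinates are 1-based and inclusive in every file and in every
in-memory record (the GFF convention); all interval arithmetic in the
package works directly in these units.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """An identified amino-acid sequence with optional genomic coordinates.

    Coordinates, when present, are 1-based inclusive basepair positions on
    ``contig_id``.
    """

    protein_id: str
    sequence: str
    genome_id: str | None = None
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"protein {self.protein_id!r}: invalid residue "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"protein {self.protein_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"protein {self.protein_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class StructureModel:
    """Ordered CA coordinates (Å) with residue codes; the unit of structural
    comparison. ``plddt`` holds optional per-residue model confidence."""

    protein_id: str
    coords: np.ndarray  # (n, 3) float64, Å
    residues: str
    plddt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.coords) != len(self.residues):
            raise ValueError("coords and residues must be index-aligned")
        if len(self.coords) < 3:
            raise ValueError(
                f"structure {self.protein_id!r}: fewer than 3 residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"structure {self.protein_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    """A conserved-domain hit for one protein (stand-in for a CDD search row)."""

    protein_id: str
    domain_id: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(
                f"domain hit {self.protein_id}/{self.domain_id}: negative evalue"
            )


@dataclass
class DefenseSystemAnnotation:
    """A located multi- or single-gene anti-phage defense system on a contig."""

    genome_id: str
    contig_id: str
    system_name: str
    start: int
    end: int
    strand: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"system {self.system_name} on {self.contig_id}: "
                f"start {self.start} > end {self.end}"
            )
        if not self.gene_ids:
            raise ValueError(f"system {self.system_name}: empty gene_ids")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; a single terminal ``*`` (gene-caller stop) is
    stripped. The record id is the first whitespace-delimited header token.
    Raises ``ValueError`` on an empty sequence or on residues outside the
    one-letter alphabet (plus X).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty sequence under header {rec.id!r}")
        records.append(ProteinRecord(protein_id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA. Duplicate ids are an error."""
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    seen: set[str] = set()
    for r in records:
        if r.protein_id in seen:
            raise ValueError(f"duplicate protein_id {r.protein_id!r}")
        seen.add(r.protein_id)
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# PDB CA traces

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_ca_trace(path: str | Path) -> StructureModel:
    """Read the CA trace of a single-chain PDB model.

    Policy for arbitrary files: first MODEL only, first chain encountered,
    altloc blank or 'A' only; residues ordered by residue sequence number.
    Residues lacking a CA atom are skipped with a warning. The B-factor is
    stored as pLDDT when every value lies in [0, 100].
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    if len(model) == 0:
        raise ValueError(f"{path}: model has no chains")
    chain = model[0]
    rows: list[tuple[int, str, np.ndarray, float]] = []
    for residue in chain:
        ca = None
        for atom in residue:
            if atom.name == "CA" and atom.altloc in ("", "A", "\x00"):
                ca = atom
                break
        if ca is None:
            if residue.name in _THREE_TO_ONE:
                logger.warning(
                    "%s: residue %s %s has no CA atom; skipped",
                    path, residue.name, residue.seqid.num,
                )
            continue
        code = _THREE_TO_ONE.get(residue.name, "X")
        rows.append(
            (residue.seqid.num, code,
             np.array([ca.pos.x, ca.pos.y, ca.pos.z]), ca.b_iso)
        )
    if not rows:
        raise ValueError(f"{path}: no CA atoms found")
    if len(rows) < 3:
        raise ValueError(f"{path}: fewer than 3 CA residues; superposition undefined")
    rows.sort(key=lambda r: r[0])
    coords = np.stack([r[2] for r in rows])
    residues = "".join(r[1] for r in rows)
    bvals = np.array([r[3] for r in rows])
    plddt = bvals if np.all((bvals >= 0) & (bvals <= 100)) else None
    return StructureModel(
        protein_id=Path(path).stem, coords=coords, residues=residues, plddt=plddt
    )


def write_ca_trace(model: StructureModel, path: str | Path) -> None:
    """Write a CA-only PDB file (one chain A, pLDDT in the B-factor column)."""
    plddt = model.plddt if model.plddt is not None else np.zeros(len(model))
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
    with open(path, "w") as fh:
        for i, (xyz, res) in enumerate(zip(model.coords, model.residues)):
            name3 = one_to_three.get(res, "UNK")
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {name3} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{plddt[i]:6.2f}"
                f"           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Annotation tables (TSV)

_DEFENSE_COLUMNS = ["genome_id", "contig_id", "system_name", "start", "end",
                    "strand", "gene_ids"]


def read_defense_table(path: str | Path) -> list[DefenseSystemAnnotation]:
    """Read a defense-system annotation TSV (one row per located system).

    Required columns: genome_id, contig_id, system_name, start, end, strand,
    gene_ids (comma-joined member protein ids). Coordinates are 1-based
    inclusive; rows with start > end are rejected.
    """
    out: list[DefenseSystemAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fieldnames = reader.fieldnames or []
        for col in _DEFENSE_COLUMNS:
            if col not in fieldnames:
                raise ValueError(f"defense table {path}: missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError:
                raise ValueError(
                    f"defense table {path} row {lineno}: non-integer coordinates"
                ) from None
            out.append(DefenseSystemAnnotation(
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                system_name=row["system_name"],
                start=start,
                end=end,
                strand=row["strand"],
                gene_ids=[g for g in row["gene_ids"].split(",") if g],
            ))
    return out


def write_defense_table(systems: Iterable[DefenseSystemAnnotation],
                        path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DEFENSE_COLUMNS)
        for s in systems:
            w.writerow([s.genome_id, s.contig_id, s.system_name, s.start, s.end,
                        s.strand, ",".join(s.gene_ids)])


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a domain-hit TSV (columns protein_id, domain_id, evalue).

    A protein may carry zero or many rows; a negative evalue is an error.
    """
    out: list[DomainAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fieldnames = reader.fieldnames or []
        for col in ("protein_id", "domain_id", "evalue"):
            if col not in fieldnames:
                raise ValueError(f"domain table {path}: missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            ev = float(row["evalue"])
            if ev < 0:
                raise ValueError(
                    f"domain table {path} row {lineno}: negative evalue {ev}"
                )
            out.append(DomainAnnotation(row["protein_id"], row["domain_id"], ev))
    return out


def write_domain_table(domains: Iterable[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "domain_id", "evalue"])
        for d in domains:
            w.writerow([d.protein_id, d.domain_id, repr(d.evalue)])


# ---------------------------------------------------------------------------
# Candidate reports

REPORT_COLUMNS = ["candidate_id", "reference_id", "tm_query", "tm_target",
                  "tm_shorter", "rmsd", "identity", "filters_passed"]


def write_report(rows, path: str | Path) -> None:
    """Write candidate reports as TSV, one row per candidate x reference hit.

    Rows are sorted by candidate_id then descending tm_shorter; numeric
    values carry 4 decimals. Candidates with no reference hits are omitted
    (the funnel TSV accounts for them).
    """
    flat: list[tuple] = []
    for report in rows:
        passed = ";".join(
            name for name, ok, _ in report.stage_verdicts if ok
        )
        for hit in report.reference_hits:
            flat.append((
                report.candidate_id, hit.reference_id,
                hit.tm_query, hit.tm_target, hit.tm_shorter,
                hit.rmsd, hit.identity, passed,
            ))
    flat.sort(key=lambda r: (r[0], -r[4]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for row in flat:
            w.writerow([row[0], row[1],
                        f"{row[2]:.4f}", f"{row[3]:.4f}", f"{row[4]:.4f}",
                        f"{row[5]:.4f}", f"{row[6]:.4f}", row[7]])


def read_report(path: str | Path):
    """Read a report TSV back as a pandas DataFrame (round-trip helper)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")
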