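"""PDB and FASTA input/output.

PDB support is a dedicated fixed-column reader/writer because the package
uses a PQR-style dialect: with ``dialect="pqr"`` partial charges and
intrinsic radii are carried in the occupancy and B-factor columns.  The
reader validates record geometry and reports the line number of any
malformed ATOM/HETATM record.  Multi-model files round-trip as snapshot
lists.  Coordinates survive a write/read cycle at PDB precision (1e-3 A).

Bead models are exported as one pseudo-atom per bead (residue TUA for
alpha monomers, TUB for beta, one residue per dimer).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .lattice import ALPHA, BeadModel
from .structure import AtomicStructure

__all__ = [
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "write_pdb_models",
    "write_bead_pdb",
    "read_fasta",
    "write_fasta",
]


class PDBFormatError(ValueError):
    pass


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line.rstrip("\n")) < 54:
        raise PDBFormatError(
            f"line {lineno}: truncated ATOM/HETATM record "
            f"({len(line.rstrip())} columns, need at least 54)"
        )
    try:
        return {
            "name": line[12:16].strip(),
            "res_name": line[17:20].strip(),
            "chain": line[21].strip() or "A",
            "res_id": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occ": line[54:60],
            "b": line[60:66],
            "element": line[76:78].strip(),
        }
    except ValueError as exc:
        raise PDBFormatError(
            f"line {lineno}: malformed ATOM/HETATM record: {exc}"
        ) from None


def _records_to_structure(records: list, dialect: str) -> AtomicStructure:
    n = len(records)
    charges = radii = None
    if dialect == "pqr":
        try:
            charges = np.array([float(r["occ"]) for r in records])
            radii = np.array([float(r["b"]) for r in records])
        except ValueError:
            raise PDBFormatError(
                "pqr dialect requires numeric occupancy/B columns"
            ) from None
    elements = [
        r["element"] or (r["name"][:1] if r["name"] else "X") for r in records
    ]
    return AtomicStructure(
        names=np.array([r["name"] for r in records]),
        res_names=np.array([r["res_name"] for r in records]),
        res_ids=np.array([r["res_id"] for r in records]),
        chains=np.array([r["chain"] for r in records]),
        elements=np.array(elements),
        coords=np.array([[r["x"], r["y"], r["z"]] for r in records]),
        charges=charges,
        radii=radii,
        backbone=np.array([r["name"] == "CA" for r in records]),
    )


def read_pdb_models(path, dialect: str = "pdb") -> list:
    """All models of a (possibly multi-model) PDB file."""
    models: list[AtomicStructure] = []
    records: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6].strip()
            if tag in ("ATOM", "HETATM"):
                records.append(_parse_atom_line(line, lineno))
            elif tag == "ENDMDL":
                if records:
                    models.append(_records_to_structure(records, dialect))
                    records = []
    if records:
        models.append(_records_to_structure(records, dialect))
    if not models:
        raise PDBFormatError(f"{path}: no ATOM records found")
    return models


def read_pdb(path, dialect: str = "pdb") -> AtomicStructure:
    """First (or only) model of a PDB file."""
    return read_pdb_models(path, dialect)[0]


def _format_atom(i, name, res_name, chain, res_id, xyz, occ, b, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {i % 100000:5d} {name_field}"
        f" {res_name:<3s} {chain[:1]}{res_id % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}\n"
    )


def _structure_lines(structure: AtomicStructure, dialect: str) -> list:
    lines = []
    for i in range(len(structure)):
        if dialect == "pqr":
            occ = float(structure.charges[i]) if (
                structure.charges is not None
            ) else 0.0
            b = float(structure.radii[i]) if (
                structure.radii is not None
            ) else 0.0
        else:
            occ, b = 1.0, 0.0
        lines.append(
            _format_atom(
                i + 1,
                structure.names[i],
                structure.res_names[i],
                str(structure.chains[i]),
                int(structure.res_ids[i]),
                structure.coords[i],
                occ,
                b,
                str(structure.elements[i]),
            )
        )
    return lines


def write_pdb(structure: AtomicStructure, path, dialect: str = "pdb") -> None:
    with open(path, "w") as fh:
        fh.writelines(_structure_lines(structure, dialect))
        fh.write("END\n")


def write_pdb_models(models, path, dialect: str = "pdb") -> None:
    """Write an ordered snapshot set as a multi-model PDB file."""
    with open(path, "w") as fh:
        for i, m in enumerate(models, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            fh.writelines(_structure_lines(m, dialect))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_bead_pdb(model: BeadModel, path) -> None:
    """Export a bead model as pseudo-atoms (CA in residue TUA/TUB, one
    residue per dimer, 1-based residue numbering in the output)."""
    with open(path, "w") as fh:
        for i in range(len(model)):
            res = "TUA" if model.kinds[i] == ALPHA else "TUB"
            fh.write(
                _format_atom(
                    i + 1,
                    "CA",
                    res,
                    "A",
                    int(model.dimer_index[i]) + 1,
                    model.positions[i],
                    1.0,
                    0.0,
                    "C",
                )
            )
        fh.write("END\n")


# -- FASTA ---------------------------------------------------------------


def read_fasta(path) -> dict:
    """Sequences keyed by record id (Biopython-backed; wrapped lines fine)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
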