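"""Readers and writers for the formats the pipeline touches.

FASTA sequence files are read through Biopython, PDB coordinate files
through gemmi, tabular inputs (2-DE spot volumes, isotherm points)
through pandas.  Everything is converted into the small domain types
used by the rest of the package: :class:`ProteinRecord`,
:class:`Structure`, :class:`SpotTable` and :class:`IsothermData`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {one: three for three, one in AA3_TO_1.items()}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The sequence is restricted to the 20 standard one-letter codes;
    construction fails otherwise so every downstream composition
    fraction has a well-defined denominator.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = sorted(set(self.sequence) - set(AMINO_ACIDS))
        if bad:
            raise ValueError(
                f"protein {self.id!r}: characters outside the 20-letter "
                f"alphabet: {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Atom:
    """One ATOM record: name, parent residue, Cartesian coordinates in A."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_seq: int
    coords: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass
class Structure:
    """A single-chain protein structure as an ordered list of atoms."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain, residue_seq), in file order."""
        groups: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault((atom.chain, atom.residue_seq), []).append(atom)
        return groups

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class SpotTable:
    """Per-protein 2-DE spot volumes for one gel."""

    gel_id: str
    protein_ids: list[str]
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.protein_ids) != len(self.volumes):
            raise ValueError("protein_ids and volumes differ in length")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = sorted(
                pid for pid in set(self.protein_ids)
                if self.protein_ids.count(pid) > 1
            )
            raise ValueError(f"gel {self.gel_id!r}: duplicate protein ids {dupes}")
        if np.any(self.volumes < 0):
            raise ValueError(f"gel {self.gel_id!r}: negative spot volume")
        if len(self.volumes) == 0 or self.volumes.sum() <= 0:
            raise ValueError(f"gel {self.gel_id!r}: total volume must be > 0")

    @property
    def total(self) -> float:
        return float(self.volumes.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.volumes, index=pd.Index(self.protein_ids, name="protein_id"))


@dataclass
class IsothermData:
    """Adsorption isotherm points: equilibrium concentration (g/L) vs
    adsorbed amount (mg/m^2)."""

    c_eq: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.c_eq = np.asarray(self.c_eq, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.c_eq.shape != self.gamma.shape or self.c_eq.ndim != 1:
            raise ValueError("c_eq and gamma must be 1-D arrays of equal length")
        if np.any(self.c_eq < 0) or np.any(self.gamma < 0):
            raise ValueError("isotherm values must be non-negative")

    def __len__(self) -> int:
        return len(self.c_eq)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, policy: str = "reject") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path:
        FASTA file path.
    policy:
        How to handle characters outside the 20-letter alphabet:
        ``"reject"`` (default) raises naming the offending characters;
        ``"drop"`` removes them and logs the count.
    """
    if policy not in ("reject", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    records: list[ProteinRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq) - set(AMINO_ACIDS))
        if bad:
            if policy == "reject":
                raise ValueError(
                    f"protein {rec.id!r}: illegal characters {''.join(bad)!r}"
                )
            n_dropped += sum(seq.count(c) for c in bad)
            seq = "".join(c for c in seq if c in AMINO_ACIDS)
        records.append(ProteinRecord(rec.id, seq))
    if n_dropped:
        logger.info("read_fasta: dropped %d non-standard residues", n_dropped)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path: str | Path, chain: str | None = None) -> Structure:
    """Read a PDB file into a single-chain :class:`Structure`.

    Only the first MODEL is used.  HETATM records, waters, altlocs other
    than blank/'A' and non-standard residues are dropped.  If *chain* is
    None the first chain encountered is kept (the monomer rule);
    otherwise the named chain is selected.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    chain_names = [ch.name for ch in model]
    if not chain_names:
        raise ValueError(f"{path}: no ATOM records")
    if chain is None:
        selected = chain_names[0]
    else:
        if chain not in chain_names:
            raise ValueError(f"{path}: chain {chain!r} not found (have {chain_names})")
        selected = chain
    atoms: list[Atom] = []
    n_nonstandard = 0
    for ch in model:
        if ch.name != selected:
            continue
        for res in ch:
            if res.het_flag == "H" or res.name == "HOH":
                continue
            if res.name not in AA3_TO_1:
                n_nonstandard += 1
                continue
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    residue_name=res.name,
                    chain=ch.name,
                    residue_seq=res.seqid.num,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    element=at.element.name,
                ))
    if n_nonstandard:
        logger.info("read_pdb: dropped %d non-standard residues", n_nonstandard)
    if not atoms:
        raise ValueError(f"{path}: no standard-residue ATOM records in chain {selected!r}")
    return Structure(id=Path(path).stem, atoms=atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB v3.3 ATOM records (plus END)."""
    lines = []
    for atom in structure.atoms:
        name = atom.name
        # PDB atom-name column convention: 1-letter elements start in col 14
        if len(name) < 4 and len(atom.element) == 1:
            name = f" {name}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {atom.serial:5d} {name:<4s} {atom.residue_name:<3s} "
            f"{atom.chain:1s}{atom.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tables

def read_spot_table(path: str | Path, gel_id: str | None = None) -> SpotTable:
    """Read a TSV with columns ``protein_id`` and ``volume`` into a SpotTable."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "volume"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty data section")
    return SpotTable(
        gel_id=gel_id or Path(path).stem,
        protein_ids=[str(p) for p in df["protein_id"]],
        volumes=df["volume"].to_numpy(dtype=float),
    )


def write_spot_table(table: SpotTable, path: str | Path) -> None:
    pd.DataFrame({"protein_id": table.protein_ids, "volume": table.volumes}).to_csv(
        path, sep="\t", index=False
    )


def read_isotherm_table(path: str | Path) -> IsothermData:
    """Read a TSV with columns ``c_eq`` (g/L) and ``gamma`` (mg/m^2)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("c_eq", "gamma"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return IsothermData(df["c_eq"].to_numpy(float), df["gamma"].to_numpy(float))
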