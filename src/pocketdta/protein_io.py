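"""Residue-level protein structure I/O.

Proteins enter the pipeline as clouds of alpha-carbon positions, one per
residue, each carrying the smoothing radius of its residue type.  The
per-type radii are the empirical residue radius statistics used to define
the smooth distance function of the surface sampler.  Binary pocket
labels ride alongside as a dense 0/1 vector aligned to cloud order.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "RESIDUE_RADII", "DEFAULT_UNKNOWN_RADIUS", "ResidueCloud", "PocketLabels",
    "parse_pdb", "residue_radius", "read_pocket_labels",
    "write_pdb", "write_pocket_labels",
]

#: Mean radius (Å) of each of the 20 standard residue types, used as the
#: per-residue smoothing length sigma_k of the smooth distance function.
RESIDUE_RADII: dict[str, float] = {
    "GLY": 1.46, "ALA": 1.54, "THR": 1.61, "SER": 1.64, "CYS": 1.80,
    "ASN": 1.83, "ASP": 1.88, "PRO": 1.88, "GLN": 1.96, "VAL": 1.99,
    "ILE": 1.99, "LEU": 2.02, "HIS": 2.02, "MET": 2.05, "GLU": 2.07,
    "LYS": 2.17, "ARG": 2.17, "PHE": 2.18, "TYR": 2.19, "TRP": 2.38,
}

#: Fallback radius (Å) for non-canonical residues (MSE, UNK, ...):
#: the median of the 20-entry table.
DEFAULT_UNKNOWN_RADIUS: float = 1.99


class UnknownResidueError(KeyError):
    """Raised for residue codes outside the 20-entry radius table."""


def residue_radius(code: str) -> float:
    """Radius (Å) of a 3-letter residue code from the 20-entry table.

    Raises :class:`UnknownResidueError` for codes outside the table;
    callers that want to keep non-canonical chains usable may substitute
    :data:`DEFAULT_UNKNOWN_RADIUS`.
    """
    try:
        return RESIDUE_RADII[code.upper()]
    except KeyError:
        raise UnknownResidueError(
            f"residue code {code!r} is not one of the 20 standard residues"
        ) from None


@dataclass
class ResidueCloud:
    """One protein as residue identities + alpha-carbon coordinates.

    ``seq_index`` keeps the author residue numbering of the source file;
    array positions are the internal 0-based indexing used everywhere
    downstream.
    """

    residue_names: list[str]
    coords: np.ndarray            # (n, 3) float, Å
    radii: np.ndarray             # (n,) float, Å, all > 0
    chain_ids: list[str]
    seq_index: np.ndarray         # (n,) int, author numbering
    skipped: int = 0              # residues dropped for lacking a CA atom
    unknown_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.seq_index = np.asarray(self.seq_index, dtype=int).ravel()
        n = len(self.residue_names)
        if not (self.coords.shape[0] == n == len(self.radii)
                == len(self.chain_ids) == len(self.seq_index)):
            raise ValueError("ResidueCloud field lengths disagree")
        if np.any(self.radii <= 0):
            raise ValueError("all residue radii must be positive")
        if self.unknown_mask is None:
            self.unknown_mask = np.array(
                [name.upper() not in RESIDUE_RADII for name in self.residue_names]
            )

    def __len__(self) -> int:
        return len(self.residue_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def sequence_key(self) -> str:
        """Canonical string key for this protein (for embedding providers)."""
        return "-".join(self.residue_names)


@dataclass
class PocketLabels:
    """Dense binary pocket membership aligned to a :class:`ResidueCloud`."""

    labels: np.ndarray  # (n,) int in {0, 1}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("pocket labels must be 0/1")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def parse_pdb(path: str | os.PathLike,
              unknown_radius: float = DEFAULT_UNKNOWN_RADIUS) -> ResidueCloud:
    """Parse a PDB file into a residue cloud (one entry per CA-bearing residue).

    Residues without an alpha carbon are skipped and counted in
    ``ResidueCloud.skipped``.  Duplicate CA records (altloc) keep the
    highest-occupancy copy (ties: first) with a warning.  Output order is
    (chain id, author residue number).
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        atoms = pdb_file.get_structure(
            model=1, altloc="all", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise ValueError(f"could not parse ATOM records from {path}: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path} contains no ATOM records")

    residues: dict[tuple[str, int], dict] = {}
    ca_dup_keys = []
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]))
        rec = residues.setdefault(key, {"name": str(atoms.res_name[i]), "ca": None})
        if atoms.atom_name[i] == "CA" and atoms.element[i] != "CA":
            occ = float(atoms.occupancy[i])
            if rec["ca"] is None:
                rec["ca"] = (occ, atoms.coord[i])
            else:
                ca_dup_keys.append(key)
                if occ > rec["ca"][0]:
                    rec["ca"] = (occ, atoms.coord[i])
    if ca_dup_keys:
        warnings.warn(
            f"duplicate CA (altloc) for {len(set(ca_dup_keys))} residue(s); "
            "kept highest occupancy", stacklevel=2,
        )

    names, coords, radii, chains, seq_idx = [], [], [], [], []
    skipped = 0
    unknown_names = set()
    for (chain, resi) in sorted(residues):
        rec = residues[(chain, resi)]
        if rec["ca"] is None:
            skipped += 1
            continue
        name = rec["name"].upper()
        try:
            r = residue_radius(name)
        except UnknownResidueError:
            r = unknown_radius
            unknown_names.add(name)
        names.append(name)
        coords.append(rec["ca"][1])
        radii.append(r)
        chains.append(chain)
        seq_idx.append(resi)
    if unknown_names:
        warnings.warn(
            f"non-standard residue(s) {sorted(unknown_names)} assigned "
            f"default radius {unknown_radius} Å", stacklevel=2,
        )
    if not names:
        raise ValueError(f"{path}: no residue in the file has a CA atom")
    return ResidueCloud(names, np.array(coords), np.array(radii),
                        chains, np.array(seq_idx), skipped=skipped)


def write_pdb(cloud: ResidueCloud, path: str | os.PathLike) -> None:
    """Write the cloud as a CA-only PDB file (inverse of :func:`parse_pdb`)."""
    n = len(cloud)
    arr = struc.AtomArray(n)
    arr.coord = cloud.coords.astype(np.float32)
    arr.chain_id = np.array(cloud.chain_ids, dtype="U4")
    arr.res_id = cloud.seq_index.astype(int)
    arr.res_name = np.array(cloud.residue_names, dtype="U5")
    arr.atom_name = np.array(["CA"] * n, dtype="U6")
    arr.element = np.array(["C"] * n, dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Pocket label TSV  (chain <tab> resi <tab> {0,1})
# ---------------------------------------------------------------------------

def read_pocket_labels(path: str | os.PathLike, cloud: ResidueCloud) -> PocketLabels:
    """Read a (chain, resi, label) TSV into a dense 0/1 vector in cloud order.

    Unlisted residues default to 0.  Keys absent from the cloud raise with
    the list of orphans.
    """
    index = {(c, int(s)): i
             for i, (c, s) in enumerate(zip(cloud.chain_ids, cloud.seq_index))}
    labels = np.zeros(len(cloud), dtype=int)
    orphans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "chain":
                continue  # optional header row
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            chain, resi, lab = parts[0], int(parts[1]), int(parts[2])
            key = (chain, resi)
            if key not in index:
                orphans.append(key)
                continue
            labels[index[key]] = lab
    if orphans:
        raise KeyError(f"label rows not present in structure: {orphans}")
    return PocketLabels(labels)


def write_pocket_labels(labels: PocketLabels, cloud: ResidueCloud,
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresi\tlabel\n")
        for c, s, y in zip(cloud.chain_ids, cloud.seq_index, labels.labels):
            fh.write(f"{c}\t{s}\t{y}\n")
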