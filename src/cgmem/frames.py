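"""Shared frame data model and structure-format I/O.

A :class:`CGFrame` is one coarse-grained snapshot: bead coordinates (Å),
per-bead chemical classes (:class:`~cgmem.beads.BeadClass`), residue/chain
identity, a lipid grouping, and the orthorhombic periodic box.  GRO and PDB
files are read and written through MDAnalysis; GRO coordinates (nm) are
converted to Å on read and back on write.

Lipids are grouped by (residue_name, residue_index): CG coordinate formats
carry no bond information, so molecule identity follows residue identity.
Chain identifiers are taken from the file where the format records them
(PDB); GRO carries none, and all beads fall in chain "A".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beads import BeadClass, LIPID_CLASSES, classify_bead
from .errors import ClassificationError, FrameParseError

__all__ = [
    "CGFrame",
    "ChainSequence",
    "frame_from_arrays",
    "read_frame",
    "read_frames",
    "write_frame",
    "read_fasta",
    "write_fasta",
    "write_contact_table",
    "read_contact_table",
]


@dataclass
class CGFrame:
    """One coarse-grained snapshot."""

    coordinates: np.ndarray  # (N, 3), Å
    bead_class: np.ndarray  # (N,), BeadClass values as ints
    bead_name: np.ndarray  # (N,), str
    residue_name: np.ndarray  # (N,), str
    residue_index: np.ndarray  # (N,), 1-based int
    chain_id: np.ndarray  # (N,), str
    lipid_id: np.ndarray  # (N,), int; -1 for non-lipid beads
    box: np.ndarray  # (3,), Å, orthorhombic edges
    frame_time: float = 0.0  # ns

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.bead_class = np.asarray(self.bead_class, np.int8)
        self.box = np.asarray(self.box, float)
        self.validate()

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths (Å)")
        lip = self.lipid_id >= 0
        bad = lip & ~np.isin(
            self.bead_class, [int(c) for c in LIPID_CLASSES]
        )
        if np.any(bad):
            raise ValueError("lipid-grouped beads must carry lipid bead classes")
        if np.any(lip):
            phos = self.bead_class == int(BeadClass.PHOSPHATE)
            per_lipid = np.bincount(
                self.lipid_id[lip], weights=phos[lip].astype(float)
            )
            if np.any(per_lipid != 1):
                raise ValueError("every lipid must have exactly one phosphate bead")

    def select(self, mask: np.ndarray) -> "CGFrame":
        """Sub-frame of the beads selected by a boolean mask (lipid ids kept)."""
        return CGFrame(
            coordinates=self.coordinates[mask],
            bead_class=self.bead_class[mask],
            bead_name=self.bead_name[mask],
            residue_name=self.residue_name[mask],
            residue_index=self.residue_index[mask],
            chain_id=self.chain_id[mask],
            lipid_id=self.lipid_id[mask],
            box=self.box.copy(),
            frame_time=self.frame_time,
        )

    def class_mask(self, *classes: BeadClass) -> np.ndarray:
        return np.isin(self.bead_class, [int(c) for c in classes])

    def phosphate_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(lipid_ids, coordinates) of all phosphate beads, ordered by lipid id."""
        m = self.class_mask(BeadClass.PHOSPHATE)
        order = np.argsort(self.lipid_id[m], kind="stable")
        return self.lipid_id[m][order], self.coordinates[m][order]

    def protein_residues(self) -> pd.DataFrame:
        """Per-residue table for protein beads.

        One row per (chain_id, residue_index): residue_name and the residue
        position x/y/z — the backbone (BB) bead when present, otherwise the
        centroid of the residue's beads.
        """
        m = self.bead_class == int(BeadClass.PROTEIN)
        if not np.any(m):
            return pd.DataFrame(
                columns=["chain_id", "residue_index", "residue_name", "x", "y", "z"]
            )
        df = pd.DataFrame(
            {
                "chain_id": self.chain_id[m],
                "residue_index": self.residue_index[m],
                "residue_name": self.residue_name[m],
                "bead_name": self.bead_name[m],
                "x": self.coordinates[m, 0],
                "y": self.coordinates[m, 1],
                "z": self.coordinates[m, 2],
            }
        )
        rows = []
        for (chain, resid), grp in df.groupby(["chain_id", "residue_index"], sort=True):
            bb = grp[grp["bead_name"] == "BB"]
            src = bb if len(bb) else grp
            rows.append(
                {
                    "chain_id": chain,
                    "residue_index": int(resid),
                    "residue_name": grp["residue_name"].iloc[0],
                    "x": float(src["x"].mean()),
                    "y": float(src["y"].mean()),
                    "z": float(src["z"].mean()),
                }
            )
        return pd.DataFrame(rows)

    def translated(self, shift) -> "CGFrame":
        out = self.select(np.ones(self.n_beads, bool))
        out.coordinates = out.coordinates + np.asarray(shift, float)
        return out


@dataclass
class ChainSequence:
    """One protein chain: sequence and optional secondary-structure string."""

    chain_id: str
    sequence: str
    ss: str | None = None

    def __post_init__(self):
        if self.ss is not None:
            if len(self.ss) != len(self.sequence):
                raise ValueError(
                    f"chain {self.chain_id}: ss length {len(self.ss)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if set(self.ss) - set("HEC"):
                raise ValueError("ss must be over the alphabet {H, E, C}")


def _assign_lipid_ids(
    bead_class: np.ndarray, residue_name: np.ndarray, residue_index: np.ndarray
) -> np.ndarray:
    """Group lipid beads into molecules by (residue_name, residue_index)."""
    lipid_id = np.full(len(bead_class), -1, dtype=int)
    is_lip = np.isin(bead_class, [int(c) for c in LIPID_CLASSES])
    keys = {}
    for i in np.flatnonzero(is_lip):
        key = (residue_name[i], int(residue_index[i]))
        lipid_id[i] = keys.setdefault(key, len(keys))
    return lipid_id


def frame_from_arrays(
    coordinates,
    bead_names,
    residue_names,
    residue_indices,
    box,
    chain_ids=None,
    frame_time: float = 0.0,
    table=None,
) -> CGFrame:
    """Build a classified :class:`CGFrame` from raw per-bead arrays (Å)."""
    coordinates = np.asarray(coordinates, float)
    bead_names = np.asarray(bead_names, dtype=object)
    residue_names = np.asarray(residue_names, dtype=object)
    residue_indices = np.asarray(residue_indices, int)
    n = len(coordinates)
    if chain_ids is None:
        chain_ids = np.full(n, "A", dtype=object)
    else:
        chain_ids = np.asarray(chain_ids, dtype=object)

    classes = np.empty(n, np.int8)
    bad = []
    for i in range(n):
        try:
            classes[i] = int(classify_bead(residue_names[i], bead_names[i], table))
        except ClassificationError:
            bad.append((residue_names[i], bead_names[i]))
    if bad:
        raise ClassificationError(bad)

    lipid_id = _assign_lipid_ids(classes, residue_names, residue_indices)
    return CGFrame(
        coordinates=coordinates,
        bead_class=classes,
        bead_name=bead_names,
        residue_name=residue_names,
        residue_index=residue_indices,
        chain_id=chain_ids,
        lipid_id=lipid_id,
        box=np.asarray(box, float),
        frame_time=frame_time,
    )


def _check_gro_shape(path: Path) -> None:
    """Cheap structural validation so malformed GRO files fail with a line number."""
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FrameParseError(f"{path}: truncated GRO file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise FrameParseError(f"{path}, line 2: atom count is not an integer") from None
    if len(lines) < n_atoms + 3:
        raise FrameParseError(
            f"{path}: header declares {n_atoms} atoms but only "
            f"{len(lines) - 3} coordinate lines follow"
        )
    for ln in range(2, 2 + n_atoms):
        rec = lines[ln]
        if len(rec) < 44:
            raise FrameParseError(f"{path}, line {ln + 1}: record too short for GRO")
        for col in (rec[20:28], rec[28:36], rec[36:44]):
            try:
                float(col)
            except ValueError:
                raise FrameParseError(
                    f"{path}, line {ln + 1}: malformed coordinate field {col!r}"
                ) from None
    box_line = lines[2 + n_atoms].split()
    if len(box_line) < 3:
        raise FrameParseError(f"{path}, line {3 + n_atoms}: missing box vector")


def _universe(path: Path, fmt: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), format=fmt)
        except FrameParseError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap as parse error
            raise FrameParseError(f"{path}: {exc}") from exc


def _frame_from_universe(u, frame_time: float, table) -> CGFrame:
    dims = u.dimensions
    if dims is None or np.any(np.asarray(dims[:3]) <= 0):
        raise FrameParseError("missing or degenerate periodic box")
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise FrameParseError(
            f"triclinic box (angles {tuple(dims[3:6])}) is unsupported; "
            "only orthorhombic boxes are handled"
        )
    atoms = u.atoms
    try:
        chains = np.asarray(atoms.chainIDs, dtype=object)
        chains = np.where(chains == "", "A", chains)
    except Exception:  # noqa: BLE001 - GRO has no chain IDs
        chains = np.full(len(atoms), "A", dtype=object)
    return frame_from_arrays(
        coordinates=atoms.positions.astype(float),  # MDAnalysis is Å-native
        bead_names=np.asarray(atoms.names, dtype=object),
        residue_names=np.asarray(atoms.resnames, dtype=object),
        residue_indices=np.asarray(atoms.resids, int),
        chain_ids=chains,
        box=np.asarray(dims[:3], float),
        frame_time=frame_time,
        table=table,
    )


def read_frame(path, format: str | None = None, table=None) -> CGFrame:
    """Read one snapshot from a GRO or PDB file.

    ``format`` defaults to the file suffix.  GRO nm coordinates arrive in Å
    (×10, done by the reader).  Raises :class:`FrameParseError` on malformed
    records (with a line number for GRO) and :class:`ClassificationError`
    when a residue/bead pair is not in the classification table.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"gro", "pdb"}:
        raise FrameParseError(f"{path}: unsupported format {fmt!r}")
    if fmt == "gro":
        _check_gro_shape(path)
    u = _universe(path, fmt.upper())
    return _frame_from_universe(u, frame_time=0.0, table=table)


def read_frames(paths, format: str | None = None, table=None) -> list[CGFrame]:
    """Read an ordered sequence of snapshots.

    Accepts a list of single-frame files, or a single multi-model PDB.
    Frame times are the file order (index) unless encoded elsewhere.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        fmt = (format or path.suffix.lstrip(".")).lower()
        if fmt == "pdb":
            u = _universe(path, "PDB")
            frames = []
            for i, _ts in enumerate(u.trajectory):
                frames.append(_frame_from_universe(u, frame_time=float(i), table=table))
            return frames
        return [read_frame(path, format=fmt, table=table)]
    out = []
    for i, p in enumerate(paths):
        fr = read_frame(p, format=format, table=table)
        fr.frame_time = float(i)
        out.append(fr)
    return out


def write_frame(frame: CGFrame, path, format: str | None = None) -> None:
    """Write a snapshot as GRO (nm) or PDB (Å)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in {"gro", "pdb"}:
        raise FrameParseError(f"{path}: unsupported format {fmt!r}")

    # residues = runs of constant (residue_index, chain_id, residue_name)
    keys = list(
        zip(frame.residue_index.tolist(), frame.chain_id.tolist(),
            frame.residue_name.tolist())
    )
    resindex = np.empty(frame.n_beads, int)
    res_keys = []
    for i, key in enumerate(keys):
        if not res_keys or key != res_keys[-1]:
            res_keys.append(key)
        resindex[i] = len(res_keys) - 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=frame.n_beads,
            n_residues=len(res_keys),
            atom_resindex=resindex,
            residue_segindex=np.zeros(len(res_keys), int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(frame.bead_name))
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[0] for k in res_keys])
        u.add_TopologyAttr("segids", ["SYS"])
        if fmt == "pdb":
            u.add_TopologyAttr("chainIDs", list(frame.chain_id))
        u.atoms.positions = frame.coordinates
        u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def read_fasta(path) -> list[ChainSequence]:
    """Chains from a FASTA file; record ids are chain identifiers."""
    from Bio import SeqIO

    return [
        ChainSequence(chain_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(chains: list[ChainSequence], path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(f">{ch.chain_id}\n{ch.sequence}\n")


CONTACT_TABLE_COLUMNS = [
    "chain_id", "residue_index", "residue_name",
    "choline", "phosphate", "glycerol",
    "tail_1", "tail_2", "tail_3", "tail_4",
    "water", "ion", "flip_lipid",
    "head_count", "tail_count", "solvent_count",
    "head_fraction", "tail_fraction", "solvent_fraction",
    "frames_analysed",
]


def write_contact_table(profile, path) -> None:
    """Residue contact profile as CSV (fixed, documented column order)."""
    df = profile.as_table()
    df.to_csv(path, index=False, columns=CONTACT_TABLE_COLUMNS)


def read_contact_table(path):
    """Inverse of :func:`write_contact_table`."""
    from .contacts import ResidueContactProfile

    df = pd.read_csv(path)
    frames = int(df["frames_analysed"].iloc[0]) if len(df) else 1
    return ResidueContactProfile.from_table(df, frames_analysed=frames)


def center_midplane(frame: CGFrame) -> float:
    """z of the bilayer midplane, estimated as the mean phosphate z."""
    m = frame.class_mask(BeadClass.PHOSPHATE)
    if not np.any(m):
        raise ValueError("frame has no phosphate beads")
    return float(frame.coordinates[m, 2].mean())
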