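"""Protein-lipid/solvent contact counting and residue environment labels.

A contact is a protein bead-other bead pair within a cutoff (default 6 Å,
the common CG bead-contact convention), minimum-imaged laterally.  Counting
is per bead pair: a lipid touching a residue through three beads contributes
three counts, split by bead class.  Head = choline + phosphate + glycerol,
tail = the four acyl beads, solvent = water + ions (kept distinct in the
counts, merged in the fractions).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from ._geom import distance_matrix
from .beads import BeadClass
from .bilayer import FlipFlopEvent
from .frames import CGFrame, ChainSequence

__all__ = [
    "ResidueContactProfile",
    "EnvironmentLabel",
    "count_contacts",
    "classify_environment",
    "sequence_tracks",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 6.0  # Å

_CLASS_COLUMNS = {
    BeadClass.CHOLINE: "choline",
    BeadClass.PHOSPHATE: "phosphate",
    BeadClass.GLYCEROL: "glycerol",
    BeadClass.TAIL_1: "tail_1",
    BeadClass.TAIL_2: "tail_2",
    BeadClass.TAIL_3: "tail_3",
    BeadClass.TAIL_4: "tail_4",
    BeadClass.WATER: "water",
    BeadClass.ION: "ion",
}
HEAD_COLUMNS = ["choline", "phosphate", "glycerol"]
TAIL_COLUMNS = ["tail_1", "tail_2", "tail_3", "tail_4"]
SOLVENT_COLUMNS = ["water", "ion"]
COUNT_COLUMNS = HEAD_COLUMNS + TAIL_COLUMNS + SOLVENT_COLUMNS + ["flip_lipid"]


class EnvironmentLabel(str, Enum):
    HEADGROUP = "HEADGROUP"
    ACYL_TAIL = "ACYL_TAIL"
    SOLVENT = "SOLVENT"
    BURIED = "BURIED"


@dataclass
class ResidueContactProfile:
    """Per-residue contact counts against each bead class, plus fractions.

    ``counts`` is indexed by (chain_id, residue_index) with residue_name and
    one column per bead class, water, ion and flip-lipid contacts, summed
    over all analysed frames.  Fractions (head/tail/solvent) are defined for
    residues with at least one contact and sum to 1 there.
    """

    counts: pd.DataFrame
    frames_analysed: int

    def head_tail_solvent(self) -> pd.DataFrame:
        df = pd.DataFrame(index=self.counts.index)
        df["head_count"] = self.counts[HEAD_COLUMNS].sum(axis=1)
        df["tail_count"] = self.counts[TAIL_COLUMNS].sum(axis=1)
        df["solvent_count"] = self.counts[SOLVENT_COLUMNS].sum(axis=1)
        total = df.sum(axis=1)
        for part in ("head", "tail", "solvent"):
            df[f"{part}_fraction"] = np.where(
                total > 0, df[f"{part}_count"] / total.where(total > 0, 1), np.nan
            )
        return df

    def as_table(self) -> pd.DataFrame:
        """Flat CSV-ready table: counts, group sums, fractions, frame count."""
        df = pd.concat([self.counts, self.head_tail_solvent()], axis=1)
        df = df.reset_index()
        df["frames_analysed"] = self.frames_analysed
        return df

    @classmethod
    def from_table(cls, df: pd.DataFrame, frames_analysed: int):
        counts = df.set_index(["chain_id", "residue_index"])[
            ["residue_name"] + COUNT_COLUMNS
        ]
        return cls(counts=counts, frames_analysed=frames_analysed)

    def merged_with(self, other: "ResidueContactProfile") -> "ResidueContactProfile":
        """Additivity over frame subsets: element-wise sum of counts."""
        if not self.counts.index.equals(other.counts.index):
            raise ValueError("profiles cover different residue sets")
        counts = self.counts.copy()
        counts[COUNT_COLUMNS] = (
            counts[COUNT_COLUMNS] + other.counts[COUNT_COLUMNS]
        )
        return ResidueContactProfile(
            counts=counts,
            frames_analysed=self.frames_analysed + other.frames_analysed,
        )


def count_contacts(
    frames: list[CGFrame],
    cutoff: float = DEFAULT_CUTOFF,
    flip_events: list[FlipFlopEvent] | None = None,
) -> ResidueContactProfile:
    """Accumulate per-residue contact counts over the supplied frames.

    ``flip_events``: contacts with a lipid that has a flip-flop event
    overlapping the analysed frame window additionally increment that
    residue's ``flip_lipid`` count.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = frames[0].box
    if cutoff > min(box[0], box[1], box[2]) / 2:
        raise ValueError("cutoff exceeds half the smallest box edge")

    frame_ids = [int(round(f.frame_time)) for f in frames]
    flip_lipids: set[int] = set()
    if flip_events:
        lo, hi = min(frame_ids), max(frame_ids)
        flip_lipids = {
            ev.lipid_id for ev in flip_events if ev.overlaps(lo, hi)
        }

    ref = frames[0].protein_residues()
    res_index = pd.MultiIndex.from_arrays(
        [ref["chain_id"], ref["residue_index"]], names=["chain_id", "residue_index"]
    )
    key_to_row = {k: i for i, k in enumerate(res_index)}
    n_res = len(res_index)
    acc = np.zeros((n_res, len(COUNT_COLUMNS)), dtype=np.int64)
    col_of_class = {
        int(c): COUNT_COLUMNS.index(name) for c, name in _CLASS_COLUMNS.items()
    }
    flip_col = COUNT_COLUMNS.index("flip_lipid")

    for frame in frames:
        pmask = frame.bead_class == int(BeadClass.PROTEIN)
        prot = frame.coordinates[pmask]
        other = ~pmask
        ocoord = frame.coordinates[other]
        oclass = frame.bead_class[other]
        olip = frame.lipid_id[other]
        rows = np.array(
            [
                key_to_row[(c, int(r))]
                for c, r in zip(frame.chain_id[pmask], frame.residue_index[pmask])
            ]
        )
        d = distance_matrix(prot, ocoord, frame.box)
        ii, jj = np.nonzero(d < cutoff)
        cols = np.array([col_of_class[int(c)] for c in oclass[jj]], dtype=int)
        np.add.at(acc, (rows[ii], cols), 1)
        if flip_lipids:
            is_flip = np.isin(olip[jj], list(flip_lipids))
            np.add.at(acc, (rows[ii][is_flip], flip_col), 1)

    counts = pd.DataFrame(acc, index=res_index, columns=COUNT_COLUMNS)
    counts.insert(0, "residue_name", ref["residue_name"].to_numpy())
    return ResidueContactProfile(counts=counts, frames_analysed=len(frames))


def classify_environment(profile: ResidueContactProfile) -> pd.Series:
    """Dominant surface environment per residue.

    argmax of (head, tail, solvent) summed counts; zero contacts -> BURIED;
    ties broken HEADGROUP > ACYL_TAIL > SOLVENT.
    """
    hts = profile.head_tail_solvent()
    arr = hts[["head_count", "tail_count", "solvent_count"]].to_numpy()
    order = [EnvironmentLabel.HEADGROUP, EnvironmentLabel.ACYL_TAIL,
             EnvironmentLabel.SOLVENT]
    labels = []
    for row in arr:
        if row.sum() == 0:
            labels.append(EnvironmentLabel.BURIED)
        else:
            labels.append(order[int(np.argmax(row))])  # argmax takes first on ties
    return pd.Series(labels, index=profile.counts.index, name="environment")


def sequence_tracks(
    profile: ResidueContactProfile,
    per_residue_depth: pd.DataFrame,
    chain: ChainSequence,
) -> pd.DataFrame:
    """Per-residue sequence-viewer table for one chain.

    Rows follow the chain sequence; columns: flip-lipid contacts, water+ion
    contacts, per-bead-class contacts ordered choline -> phosphate ->
    glycerol -> tail_1..tail_4, stacked head/tail/solvent fractions, depth
    and local membrane thickness, secondary structure and amino acid.
    """
    counts = profile.counts[profile.counts.index.get_level_values(0) == chain.chain_id]
    n = len(chain.sequence)
    if len(counts) != n:
        raise ValueError(
            f"chain {chain.chain_id}: sequence has {n} residues but profile has "
            f"{len(counts)}"
        )
    depth = per_residue_depth[per_residue_depth["chain_id"] == chain.chain_id]
    depth = depth.set_index("residue_index")
    missing = [
        int(r) for r in counts.index.get_level_values(1) if int(r) not in depth.index
    ]
    if missing:
        raise ValueError(f"residues missing from depth table: {missing}")

    hts = profile.head_tail_solvent().loc[counts.index]
    resids = counts.index.get_level_values(1).to_numpy()
    out = pd.DataFrame(
        {
            "residue_index": resids,
            "amino_acid": list(chain.sequence),
            "ss": list(chain.ss) if chain.ss else ["C"] * n,
            "flip_lipid": counts["flip_lipid"].to_numpy(),
            "water_ion": counts[SOLVENT_COLUMNS].sum(axis=1).to_numpy(),
            "choline": counts["choline"].to_numpy(),
            "phosphate": counts["phosphate"].to_numpy(),
            "glycerol": counts["glycerol"].to_numpy(),
            "tail_1": counts["tail_1"].to_numpy(),
            "tail_2": counts["tail_2"].to_numpy(),
            "tail_3": counts["tail_3"].to_numpy(),
            "tail_4": counts["tail_4"].to_numpy(),
            "head_fraction": hts["head_fraction"].to_numpy(),
            "tail_fraction": hts["tail_fraction"].to_numpy(),
            "solvent_fraction": hts["solvent_fraction"].to_numpy(),
            "depth": depth.loc[resids, "depth"].to_numpy(),
            "local_thickness": depth.loc[resids, "local_thickness"].to_numpy(),
        }
    )
    return out
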