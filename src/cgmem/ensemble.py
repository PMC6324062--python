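"""Cross-structure aggregation: sequence-aligned contact profiles, the
amino-acid lipid-contact propensity scale, depth distributions along the
membrane normal, and per-class thickness summaries.

The propensity scale follows the published convention: per amino acid type
the unbiased probability of a contact with lipid head-groups, acyl tails or
solvent is the fraction of surface residues (>= 1 non-protein contact) of
that type with >= 1 contact in the category; the normalized value anchors
glycine at 0 and the maximum at 100.  Depth coordinates are normalized so
the leaflet phosphate surfaces sit at ±1 (z' = 2 * depth / local thickness),
removing membrane-thickness variation between structures.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon

from .beads import AMINO_ACIDS_3
from .contacts import (
    HEAD_COLUMNS,
    SOLVENT_COLUMNS,
    TAIL_COLUMNS,
    ResidueContactProfile,
)
from .frames import ChainSequence

__all__ = [
    "ProgressiveAligner",
    "CommandAligner",
    "align_members",
    "EnsembleProfile",
    "aggregate_profiles",
    "PropensityScale",
    "contact_propensity_scale",
    "DepthDistribution",
    "depth_distributions",
    "thickness_summary",
]

AA_ORDER = sorted(set(AMINO_ACIDS_3.values()))
GAP = "-"
CATEGORIES = ("head", "tail", "solvent")
THICKNESS_CLASSES = ("alpha_helical", "beta_barrel")


# ---------------------------------------------------------------------------
# multiple sequence alignment


def _blosum_column_matrix() -> tuple[np.ndarray, dict[str, int]]:
    """21x21 scoring matrix over AA_ORDER + gap (gap rows/cols are 0)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    idx = {aa: i for i, aa in enumerate(AA_ORDER)}
    idx[GAP] = len(AA_ORDER)
    S = np.zeros((21, 21))
    for a in AA_ORDER:
        for b in AA_ORDER:
            S[idx[a], idx[b]] = blosum[a][b]
    return S, idx


class ProgressiveAligner:
    """Dependency-free progressive MSA.

    Pairwise global alignments (BLOSUM62, gap open -10, extend -0.5) give a
    percent-identity distance matrix; a neighbour-joining guide tree orders
    profile-profile merges; profiles are aligned with an affine-gap Gotoh DP
    whose column score is the composition-averaged BLOSUM62 score (residue
    vs gap scores 0).
    """

    def __init__(self, gap_open: float = -10.0, gap_extend: float = -0.5):
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._S, self._idx = _blosum_column_matrix()

    # -- pairwise identity ---------------------------------------------------
    def _identity(self, a: str, b: str) -> float:
        from Bio.Align import PairwiseAligner, substitution_matrices

        al = PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        aln = al.align(a, b)[0]
        sa, sb = str(aln[0]), str(aln[1])
        matches = sum(1 for x, y in zip(sa, sb) if x == y and x != GAP)
        return matches / max(len(sa), 1)

    # -- profile-profile Gotoh ----------------------------------------------
    def _composition(self, profile: list[str]) -> np.ndarray:
        L = len(profile[0])
        C = np.zeros((L, 21))
        for row in profile:
            for j, ch in enumerate(row):
                C[j, self._idx.get(ch, self._idx[GAP])] += 1
        return C

    def _align_profiles(self, pa: list[str], pb: list[str]):
        CA = self._composition(pa)
        CB = self._composition(pb)
        # residue-only normalisation; gap column entries score 0 via S
        score = (CA @ self._S @ CB.T) / (len(pa) * len(pb))
        la, lb = len(CA), len(CB)
        go, ge = self.gap_open, self.gap_extend
        NEG = -1e18
        M = np.full((la + 1, lb + 1), NEG)
        X = np.full((la + 1, lb + 1), NEG)  # gap in profile B (consume A)
        Y = np.full((la + 1, lb + 1), NEG)  # gap in profile A (consume B)
        M[0, 0] = 0.0
        for i in range(1, la + 1):
            X[i, 0] = go + ge * (i - 1)
        for j in range(1, lb + 1):
            Y[0, j] = go + ge * (j - 1)
        for i in range(1, la + 1):
            prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
            Mi, Xi, Yi = M[i], X[i], Y[i]
            for j in range(1, lb + 1):
                best = max(prevM[j - 1], prevX[j - 1], prevY[j - 1])
                Mi[j] = best + score[i - 1, j - 1]
                Xi[j] = max(prevM[j] + go, prevX[j] + ge, prevY[j] + go)
                Yi[j] = max(Mi[j - 1] + go, Yi[j - 1] + ge, Xi[j - 1] + go)
        # traceback
        i, j = la, lb
        state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
        ops = []
        while i > 0 or j > 0:
            if state == 0 and i > 0 and j > 0:
                ops.append("M")
                cand = [M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]]
                target = M[i][j] - score[i - 1, j - 1]
                state = int(np.argmax(np.isclose(cand, target, atol=1e-9)))
                i, j = i - 1, j - 1
            elif state == 1 and i > 0:
                ops.append("X")
                cands = [M[i - 1][j] + self.gap_open, X[i - 1][j] + self.gap_extend,
                         Y[i - 1][j] + self.gap_open]
                state = int(np.argmax(np.isclose(cands, X[i][j], atol=1e-9)))
                i -= 1
            elif state == 2 and j > 0:
                ops.append("Y")
                cands = [M[i][j - 1] + self.gap_open, Y[i][j - 1] + self.gap_extend,
                         X[i][j - 1] + self.gap_open]
                order = [0, 2, 1]  # candidates map to states M, Y, X
                state = order[int(np.argmax(np.isclose(cands, Y[i][j], atol=1e-9)))]
                j -= 1
            elif i > 0:
                ops.append("X")
                i -= 1
            else:
                ops.append("Y")
                j -= 1
        ops.reverse()
        out_a = ["" for _ in pa]
        out_b = ["" for _ in pb]
        ia = ib = 0
        for op in ops:
            if op in ("M", "X"):
                for k, row in enumerate(pa):
                    out_a[k] += row[ia]
                ia += 1
            else:
                for k in range(len(pa)):
                    out_a[k] += GAP
            if op in ("M", "Y"):
                for k, row in enumerate(pb):
                    out_b[k] += row[ib]
                ib += 1
            else:
                for k in range(len(pb)):
                    out_b[k] += GAP
        return out_a, out_b

    def _guide_groups(self, sequences: list[str]) -> list:
        """Nested merge order from an NJ tree on 1 - identity."""
        n = len(sequences)
        if n == 2:
            return [[0], [1]]
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - self._identity(sequences[i], sequences[j])
                dm[i, j] = dm[j, i] = d
        from skbio import DistanceMatrix
        from skbio.tree import nj

        ids = [f"s{i}" for i in range(n)]
        tree = nj(DistanceMatrix(dm, ids))

        def flat_min(g):
            return g if isinstance(g, int) else min(flat_min(x) for x in g)

        def rec(node):
            if node.is_tip():
                return [int(node.name[1:])]
            groups = [rec(ch) for ch in node.children]
            groups.sort(key=flat_min)
            return groups

        return rec(tree.root())

    def align(self, sequences: list[str]) -> list[str]:
        if any(not s for s in sequences):
            raise ValueError("empty sequence in alignment input")
        if len(sequences) < 2:
            raise ValueError("need >= 2 sequences")

        def build(group):
            if isinstance(group, list) and len(group) == 1 and isinstance(
                group[0], int
            ):
                return [group[0]], [sequences[group[0]]]
            if isinstance(group, int):
                return [group], [sequences[group]]
            members, profile = build(group[0])
            for sub in group[1:]:
                m2, p2 = build(sub)
                profile, p2 = self._align_profiles(profile, p2)
                members, profile = members + m2, profile + p2
            return members, profile

        members, profile = build(self._guide_groups(sequences))
        out = [None] * len(sequences)
        for m, row in zip(members, profile):
            out[m] = row
        return out


class CommandAligner:
    """Adapter running an external MSA tool (e.g. ``mafft``) on a FASTA."""

    def __init__(self, command: list[str] | None = None):
        self.command = command or ["mafft", "--auto", "--quiet"]

    def align(self, sequences: list[str]) -> list[str]:
        from Bio import SeqIO

        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "in.fasta"
            with open(fasta, "w") as fh:
                for i, s in enumerate(sequences):
                    fh.write(f">s{i}\n{s}\n")
            res = subprocess.run(
                [*self.command, str(fasta)], capture_output=True, text=True,
                check=True,
            )
            out_path = Path(tmp) / "out.fasta"
            out_path.write_text(res.stdout)
            rows = {rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(out_path), "fasta")}
        return [rows[f"s{i}"] for i in range(len(sequences))]


def align_members(
    sequences: list[ChainSequence], aligner=None
) -> list[ChainSequence]:
    """Multiple alignment of member chains; returns gapped copies."""
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences to align")
    aligner = aligner or ProgressiveAligner()
    rows = aligner.align([c.sequence for c in sequences])
    return [
        ChainSequence(chain_id=c.chain_id, sequence=row)
        for c, row in zip(sequences, rows)
    ]


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class EnsembleProfile:
    """Alignment-column-indexed aggregation across member structures."""

    member_ids: list[str]
    alignment: list[str]  # gapped rows, one per member
    head_fraction: np.ndarray  # (n_members, n_columns), NaN at gaps
    tail_fraction: np.ndarray
    solvent_fraction: np.ndarray
    depth: np.ndarray
    ss: np.ndarray  # (n_members, n_columns) chars, '-' at gaps
    consensus_ss: np.ndarray  # (n_columns,)
    conservation: np.ndarray  # modal SS fraction per column, in [0, 1]
    coverage: np.ndarray  # fraction of members with a residue, in (0, 1]

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0])

    def column_table(self) -> pd.DataFrame:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return pd.DataFrame(
                {
                    "column": np.arange(self.n_columns),
                    "coverage": self.coverage,
                    "consensus_ss": self.consensus_ss,
                    "conservation": self.conservation,
                    "mean_head_fraction": np.nanmean(self.head_fraction, axis=0),
                    "mean_tail_fraction": np.nanmean(self.tail_fraction, axis=0),
                    "mean_solvent_fraction": np.nanmean(self.solvent_fraction, axis=0),
                    "mean_depth": np.nanmean(self.depth, axis=0),
                }
            )


def aggregate_profiles(
    alignment: list[ChainSequence],
    member_ids: list[str],
    member_tables: list[pd.DataFrame],
) -> EnsembleProfile:
    """Carry per-residue metrics onto alignment columns.

    Each member table has one row per residue in sequence order, with
    columns ``head_fraction``, ``tail_fraction``, ``solvent_fraction``,
    ``depth`` and ``ss``.  Gap cells are marked missing (NaN / '-').
    """
    n = len(alignment)
    if not (n == len(member_ids) == len(member_tables)):
        raise ValueError("alignment, ids and tables must have equal length")
    L = len(alignment[0].sequence)
    if any(len(c.sequence) != L for c in alignment):
        raise ValueError("alignment rows differ in length")

    fields = {
        k: np.full((n, L), np.nan)
        for k in ("head_fraction", "tail_fraction", "solvent_fraction", "depth")
    }
    ss = np.full((n, L), GAP, dtype="<U1")
    for m, (chain, table) in enumerate(zip(alignment, member_tables)):
        residues = [j for j, ch in enumerate(chain.sequence) if ch != GAP]
        if len(residues) != len(table):
            raise ValueError(
                f"member {member_ids[m]!r}: profile has {len(table)} residues "
                f"but alignment row has {len(residues)}"
            )
        for r, (_, row) in enumerate(table.iterrows()):
            col = residues[r]
            for k in fields:
                fields[k][m, col] = row[k]
            ss[m, col] = row["ss"]

    coverage = (ss != GAP).mean(axis=0)
    consensus = np.empty(L, dtype="<U1")
    conservation = np.zeros(L)
    for j in range(L):
        present = ss[:, j][ss[:, j] != GAP]
        if len(present) == 0:
            consensus[j] = GAP
            continue
        vals, counts = np.unique(present, return_counts=True)
        k = int(np.argmax(counts))
        consensus[j] = vals[k]
        conservation[j] = counts[k] / len(present)
    return EnsembleProfile(
        member_ids=list(member_ids),
        alignment=[c.sequence for c in alignment],
        head_fraction=fields["head_fraction"],
        tail_fraction=fields["tail_fraction"],
        solvent_fraction=fields["solvent_fraction"],
        depth=fields["depth"],
        ss=ss,
        consensus_ss=consensus,
        conservation=conservation,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# propensity scale


@dataclass
class PropensityScale:
    """Raw contact probabilities p and normalized values s per amino acid.

    s anchors glycine at 0 and the maximum at 100 in every category; amino
    acids with p below glycine's take negative values.
    """

    table: pd.DataFrame  # index: one-letter aa; columns p_/s_ per category
    mode: str = "incidence"
    missing_types: list[str] = field(default_factory=list)


def _aa1(resname: str) -> str | None:
    return AMINO_ACIDS_3.get(resname)


def normalize_scale(p: pd.Series) -> pd.Series:
    """Anchor raw contact probabilities: glycine -> 0, maximum -> 100.

    s(aa) = 100 * (p(aa) - p(Gly)) / (max p - p(Gly)); amino acids less
    contact-prone than glycine take negative values.  Raises when the
    maximum equals glycine's probability (zero denominator).
    """
    p_gly = p.loc["G"]
    p_max = p.max()
    if np.isclose(p_max, p_gly):
        raise ValueError("degenerate scale: max probability equals glycine's")
    return 100.0 * (p - p_gly) / (p_max - p_gly)


def contact_propensity_scale(
    profiles: list[ResidueContactProfile] | ResidueContactProfile,
    mode: str = "incidence",
) -> PropensityScale:
    """Normalized lipid/solvent contact propensities over a profile collection.

    ``incidence`` (default): p(aa, cat) is the fraction of surface residues
    (>= 1 non-protein contact) of type aa with >= 1 contact in the category,
    so abundant residue types do not dominate.  ``count_share``: p is the
    category's share of the type's total contacts.
    """
    if isinstance(profiles, ResidueContactProfile):
        profiles = [profiles]
    if mode not in ("incidence", "count_share"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = pd.concat([p.counts for p in profiles], axis=0)
    aa = counts["residue_name"].map(_aa1)
    counts = counts[aa.notna()].copy()
    counts["aa"] = aa[aa.notna()]

    head = counts[HEAD_COLUMNS].sum(axis=1)
    tail = counts[TAIL_COLUMNS].sum(axis=1)
    solv = counts[SOLVENT_COLUMNS].sum(axis=1)
    total = head + tail + solv
    surface = total > 0

    rows = {}
    for aa_type, grp in counts.groupby("aa"):
        sel = surface.loc[grp.index]
        n_surf = int(sel.sum())
        if n_surf == 0:
            continue
        if mode == "incidence":
            p = [
                float((cat.loc[grp.index][sel] > 0).mean())
                for cat in (head, tail, solv)
            ]
        else:
            tot = float(total.loc[grp.index][sel].sum())
            p = [float(cat.loc[grp.index][sel].sum()) / tot for cat in
                 (head, tail, solv)]
        rows[aa_type] = p
    missing = [a for a in AA_ORDER if a not in rows]
    if "G" not in rows:
        raise ValueError("collection has no surface glycine; scale is undefined")

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p_{c}" for c in CATEGORIES]
    ).sort_index()
    for cat in CATEGORIES:
        try:
            table[f"s_{cat}"] = normalize_scale(table[f"p_{cat}"])
        except ValueError as exc:
            raise ValueError(f"category {cat!r}: {exc}") from None
    return PropensityScale(table=table, mode=mode, missing_types=missing)


# ---------------------------------------------------------------------------
# depth distributions


@dataclass
class DepthDistribution:
    """Per-amino-acid histograms over the normalized depth z'."""

    bin_edges: np.ndarray  # z' in [-2, 2], width 0.1
    histograms: pd.DataFrame  # index aa, one column per bin
    mode: str  # absolute | relative
    cluster_labels: dict[str, int]
    empty_types: list[str] = field(default_factory=list)
    n_excluded_pore: int = 0


def _inside_hull(points_xy: np.ndarray, hull_xy: np.ndarray) -> np.ndarray:
    from scipy.spatial import Delaunay, QhullError

    if hull_xy is None or len(hull_xy) < 3:
        return np.zeros(len(points_xy), bool)
    try:
        tri = Delaunay(hull_xy)
    except QhullError:
        return np.zeros(len(points_xy), bool)
    return tri.find_simplex(points_xy) >= 0


def depth_distributions(
    residue_table: pd.DataFrame,
    mode: str = "relative",
    n_clusters: int = 4,
    tm_axes_xy: np.ndarray | None = None,
    exclude_pore: bool = True,
    pore_z_limit: float = 0.8,
) -> DepthDistribution:
    """Distribution of each amino acid type along the normalized membrane normal.

    ``residue_table`` needs columns ``residue_name`` (or ``amino_acid``),
    ``depth``, ``local_thickness``, and, for pore exclusion, ``solvent_count``
    plus lateral ``x``/``y``.  z' = 2 * depth / local_thickness puts the
    phosphate surfaces at ±1.  Pore-inner residues — solvent-contacting,
    |z'| < ``pore_z_limit`` and laterally inside the convex hull of the TM
    segment axes (``tm_axes_xy``) — are discounted.  Relative mode normalizes
    each type's histogram to sum to 1.  Types are clustered by average-linkage
    on the Jensen-Shannon distance between relative histograms (lexicographic
    amino-acid order fixes tie-breaking).
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    df = residue_table.copy()
    if "amino_acid" not in df:
        df["amino_acid"] = df["residue_name"].map(_aa1)
    df = df[df["amino_acid"].notna()]
    zp = 2.0 * df["depth"].to_numpy() / df["local_thickness"].to_numpy()
    df["zprime"] = zp

    n_excl = 0
    if exclude_pore and tm_axes_xy is not None and {"solvent_count", "x", "y"} <= set(
        df.columns
    ):
        inside = _inside_hull(df[["x", "y"]].to_numpy(), np.asarray(tm_axes_xy))
        pore = (
            (df["solvent_count"].to_numpy() > 0)
            & (np.abs(df["zprime"].to_numpy()) < pore_z_limit)
            & inside
        )
        n_excl = int(pore.sum())
        df = df[~pore]

    edges = np.round(np.arange(-2.0, 2.0 + 0.05, 0.1), 10)
    hists = {}
    empty = []
    for aa in AA_ORDER:
        vals = df.loc[df["amino_acid"] == aa, "zprime"].to_numpy()
        h, _ = np.histogram(vals, bins=edges)
        if h.sum() == 0:
            empty.append(aa)
            hists[aa] = h.astype(float)
        elif mode == "relative":
            hists[aa] = h / h.sum()
        else:
            hists[aa] = h.astype(float)
    table = pd.DataFrame.from_dict(hists, orient="index").sort_index()

    # cluster on relative histograms (deterministic: lexicographic aa order)
    present = [a for a in table.index if a not in empty]
    labels: dict[str, int] = {}
    if len(present) >= 2:
        rel = table.loc[present].to_numpy().astype(float)
        rel = rel / rel.sum(axis=1, keepdims=True)
        from scipy.spatial.distance import pdist

        dm = pdist(rel, metric=jensenshannon)
        dm = np.nan_to_num(dm, nan=0.0)
        Z = linkage(dm, method="average")
        k = min(n_clusters, len(present))
        fl = fcluster(Z, t=k, criterion="maxclust")
        labels = {aa: int(c) for aa, c in zip(present, fl)}
    return DepthDistribution(
        bin_edges=edges,
        histograms=table,
        mode=mode,
        cluster_labels=labels,
        empty_types=empty,
        n_excluded_pore=n_excl,
    )


# ---------------------------------------------------------------------------
# thickness summary


def thickness_summary(members: list[tuple[float, str]]) -> pd.DataFrame:
    """Per-class mean ± sd of bulk membrane thickness.

    ``members``: (bulk thickness Å, class label) pairs; labels must be
    ``alpha_helical`` or ``beta_barrel``.  sd uses the population convention
    (a single member gives sd 0).
    """
    rows = []
    for value, label in members:
        if label not in THICKNESS_CLASSES:
            raise ValueError(f"unknown class label {label!r}")
        thick = value.bulk_thickness if hasattr(value, "bulk_thickness") else value
        rows.append({"class": label, "thickness": float(thick)})
    if not rows:
        raise ValueError("need at least one member")
    df = pd.DataFrame(rows)
    out = df.groupby("class")["thickness"].agg(
        mean="mean", sd=lambda s: float(np.std(s, ddof=0)), n="count"
    )
    return out.reset_index()
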