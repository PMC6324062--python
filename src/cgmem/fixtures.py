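"""Synthetic coarse-grained membrane systems with planted ground truth.

Systems emulate the post-assembly snapshots the analysis pipeline consumes:
DPPC lipids on a jittered lattice (12 beads each, NC3 outermost, PO4 at the
planted phosphate plane, GL1/GL2, two 4-bead tails toward the midplane), an
optional idealised protein (TM helix bundle or strand barrel traced by
backbone beads), an optional smooth radial thinning of both leaflets,
planted flip-flops (a lipid mirrored through the midplane at a stated
frame), and water/ion beads filling the remaining volume.  Every generated
frame classifies cleanly through the frames module, and the planted truth
(leaflet labels, flips, analytic surfaces, TM counts, residue environment
bands) is emitted alongside.

Defaults describe a typical fluid-phase PC bilayer: 64 Å² per lipid,
1 Å lattice jitter / bead noise, 37 Å phosphate-plane separation (the
class-typical value for membranes around α-helical proteins; 33 Å is the
β-barrel counterpart).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beads import AMINO_ACIDS_1
from .contacts import COUNT_COLUMNS, ResidueContactProfile
from .frames import CGFrame, ChainSequence, frame_from_arrays, write_fasta, write_frame

__all__ = [
    "HelixBundleSpec",
    "BarrelSpec",
    "RadialDeformation",
    "FixtureSpec",
    "GroundTruth",
    "generate",
    "generate_cohort",
    "write_fixture",
]

ALPHA_HELICAL_THICKNESS = 37.0  # Å, class-typical phosphate-to-phosphate
BETA_BARREL_THICKNESS = 33.0  # Å

# z-offsets of the 12 DPPC beads relative to the phosphate plane, toward the
# bilayer exterior (positive = outward).  Tail beads step 3.1 Å toward the
# midplane per position.
_DPPC_OFFSETS = [("NC3", 3.0), ("PO4", 0.0), ("GL1", -3.0), ("GL2", -3.0)]
for _k in range(1, 5):
    _DPPC_OFFSETS.append((f"C{_k}A", -3.0 - 3.1 * _k))
    _DPPC_OFFSETS.append((f"C{_k}B", -3.0 - 3.1 * _k))
_DPPC_LATERAL = {"GL2": (1.5, 0.0)}
for _k in range(1, 5):
    _DPPC_LATERAL[f"C{_k}A"] = (0.8, 0.0)
    _DPPC_LATERAL[f"C{_k}B"] = (-0.8, 0.0)

_TM_CORE = "LVIAFLIVGA"
_TM_INTERFACE = "WYFTS"
_TM_OUTER = "RKQN"
_LOOP = "GSNQ"
_STRAND = "LSVTFA"


@dataclass
class HelixBundleSpec:
    """Idealised TM α-helix bundle (GPCR-like at the defaults: 7 helices)."""

    n_helices: int = 7
    bundle_radius: float = 12.0  # Å, helix axes on this circle
    kink_angle: float = 0.0  # degrees, planted mid-helix axis bend
    residues_per_helix: int = 34
    helix_radius: float = 2.3  # Å, backbone about the axis
    rise: float = 1.5  # Å per residue along the axis
    twist: float = 100.0  # degrees per residue
    loop_length: int = 4


@dataclass
class BarrelSpec:
    """Idealised TM β-strand barrel."""

    n_strands: int = 8
    radius: float = 8.0
    residues_per_strand: int = 12
    rise: float = 3.3
    loop_length: int = 3


@dataclass
class RadialDeformation:
    """Plateau-shaped radial thinning about the box centre axis.

    Local thinning d(r) = depth * exp(-(r / range_)^6): approximately
    ``depth`` inside ``range_``, decaying smoothly outside.  Each leaflet is
    displaced by d/2 toward the midplane.  The flat top keeps the planted
    depth recoverable through the kernel-smoothed surface estimator, which
    attenuates features narrower than its bandwidth.
    """

    depth: float = 6.0
    range_: float = 12.0

    def thinning(self, r):
        return self.depth * np.exp(-((np.asarray(r, float) / self.range_) ** 6))


@dataclass
class FixtureSpec:
    lipids_per_leaflet: int = 256
    area_per_lipid: float = 64.0  # Å²
    phosphate_plane_separation: float = ALPHA_HELICAL_THICKNESS  # Å
    protein: HelixBundleSpec | BarrelSpec | None = None
    deformation: RadialDeformation | None = None
    planted_flips: list[tuple[int, int, str]] = field(default_factory=list)
    n_frames: int = 1
    noise_sd: float = 1.0  # Å, lattice jitter and per-frame bead noise
    water: bool = True
    water_spacing: float = 5.0
    water_depth: float = 20.0  # Å of solvent beyond each phosphate plane
    n_ions: int = 10  # per species
    seed: int = 0

    @classmethod
    def gpcr_default(cls, seed: int = 1) -> "FixtureSpec":
        """The documented GPCR-like worked example: a 7-TM helix bundle in a
        37 Å bilayer."""
        return cls(
            lipids_per_leaflet=128,
            protein=HelixBundleSpec(),
            n_frames=3,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted truth emitted with every generated fixture."""

    box: list[float]
    midplane_z: float
    bulk_thickness: float
    leaflet_labels: list[dict[int, str]]  # per frame: lipid_id -> UPPER/LOWER
    flips: list[dict]  # lipid_id, frame, direction
    deformation: dict | None  # depth, range, centre (x, y)
    tm_helix_count: int
    tm_strand_count: int
    chains: list[ChainSequence]
    environment: dict[int, str | None]  # residue_index -> planted band label

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["chains"] = [dataclasses.asdict(c) for c in self.chains]
        d["leaflet_labels"] = [
            {str(k): v for k, v in lab.items()} for lab in self.leaflet_labels
        ]
        d["environment"] = {str(k): v for k, v in self.environment.items()}
        return json.dumps(d, indent=1)


def _tm_residue_name(dz: float, half_sep: float) -> str:
    if abs(dz) < half_sep - 6.5:
        pool = _TM_CORE
    elif abs(dz) < half_sep + 1.0:
        pool = _TM_INTERFACE
    else:
        pool = _TM_OUTER
    return pool


def _build_helix_bundle(spec: HelixBundleSpec, centre, half_sep, rng):
    """Backbone traces for the bundle; returns per-residue name/pos/ss lists."""
    names, pos, ss = [], [], []
    span = spec.rise * (spec.residues_per_helix - 1)
    kink = np.deg2rad(spec.kink_angle)
    seq_counters = {}
    for h in range(spec.n_helices):
        theta = 2 * np.pi * h / spec.n_helices
        axis_xy = centre[:2] + spec.bundle_radius * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        direction = 1 if h % 2 == 0 else -1
        # axis point per residue, with an optional planted kink at mid-helix
        mid = spec.residues_per_helix // 2
        for i in range(spec.residues_per_helix):
            t = i * spec.rise - span / 2
            axis = np.array([axis_xy[0], axis_xy[1], centre[2] + direction * t])
            if spec.kink_angle and i > mid:
                s = (i - mid) * spec.rise
                axis[0] += direction * s * np.sin(kink)
                axis[2] = centre[2] + direction * (mid * spec.rise - span / 2
                                                   + s * np.cos(kink))
            phi = np.deg2rad(spec.twist * i) + theta
            p = axis + spec.helix_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
            dz = p[2] - centre[2]
            pool = _tm_residue_name(dz, half_sep)
            k = seq_counters.setdefault(pool, 0)
            names.append(AMINO_ACIDS_1[pool[k % len(pool)]])
            seq_counters[pool] = k + 1
            pos.append(p)
            ss.append("H")
        # connecting loop above/below the membrane
        if h < spec.n_helices - 1:
            next_theta = 2 * np.pi * (h + 1) / spec.n_helices
            next_xy = centre[:2] + spec.bundle_radius * np.array(
                [np.cos(next_theta), np.sin(next_theta)]
            )
            loop_z = centre[2] + direction * (span / 2 + 3.0)
            a = np.array([axis_xy[0], axis_xy[1], loop_z])
            b = np.array([next_xy[0], next_xy[1], loop_z])
            for j in range(spec.loop_length):
                f = (j + 1) / (spec.loop_length + 1)
                p = a + f * (b - a)
                p[2] += 2.0  # arc slightly away from the membrane
                names.append(AMINO_ACIDS_1[_LOOP[j % len(_LOOP)]])
                pos.append(p)
                ss.append("C")
    return names, np.array(pos), "".join(ss)


def _build_barrel(spec: BarrelSpec, centre, rng):
    names, pos, ss = [], [], []
    span = spec.rise * (spec.residues_per_strand - 1)
    for s in range(spec.n_strands):
        theta = 2 * np.pi * s / spec.n_strands
        axis_xy = centre[:2] + spec.radius * np.array([np.cos(theta), np.sin(theta)])
        direction = 1 if s % 2 == 0 else -1
        for i in range(spec.residues_per_strand):
            t = i * spec.rise - span / 2
            # slight zig-zag normal to the barrel wall
            wob = 0.6 * (1 if i % 2 == 0 else -1)
            p = np.array(
                [
                    axis_xy[0] + wob * np.cos(theta),
                    axis_xy[1] + wob * np.sin(theta),
                    centre[2] + direction * t,
                ]
            )
            names.append(AMINO_ACIDS_1[_STRAND[i % len(_STRAND)]])
            pos.append(p)
            ss.append("E")
        if s < spec.n_strands - 1:
            next_theta = 2 * np.pi * (s + 1) / spec.n_strands
            next_xy = centre[:2] + spec.radius * np.array(
                [np.cos(next_theta), np.sin(next_theta)]
            )
            loop_z = centre[2] + direction * (span / 2 + 3.0)
            for j in range(spec.loop_length):
                f = (j + 1) / (spec.loop_length + 1)
                xy = axis_xy + f * (next_xy - axis_xy)
                names.append(AMINO_ACIDS_1[_LOOP[j % len(_LOOP)]])
                pos.append(np.array([xy[0], xy[1], loop_z + 2.0]))
                ss.append("C")
    return names, np.array(pos), "".join(ss)


def _environment_truth(
    dz: np.ndarray, half_sep: float, outward: np.ndarray
) -> list[str | None]:
    """Planted residue environment bands.

    None marks residues with no unambiguous planted label: transition zones
    between bands, and membrane-depth residues facing the bundle/barrel
    interior (those are buried, not lipid-exposed).
    """
    out = []
    for z, facing_out in zip(np.abs(dz), outward):
        if z >= half_sep + 7.0:
            out.append("SOLVENT")  # extramembrane loops see solvent either way
        elif not facing_out:
            out.append(None)
        elif z <= half_sep - 6.0:
            out.append("ACYL_TAIL")
        elif half_sep - 3.0 <= z <= half_sep + 2.0:
            out.append("HEADGROUP")
        else:
            out.append(None)
    return out


def generate(spec: FixtureSpec) -> tuple[list[CGFrame], GroundTruth]:
    """Build the frame sequence and its planted ground truth.

    Deterministic under a fixed seed (identical seeds give bitwise-identical
    GRO output through :func:`write_fixture`).
    """
    rng = np.random.default_rng(spec.seed)
    sep = spec.phosphate_plane_separation
    half = sep / 2.0

    L = np.sqrt(spec.lipids_per_leaflet * spec.area_per_lipid)
    Lz = sep + 2 * spec.water_depth
    box = np.array([L, L, Lz])
    centre = np.array([L / 2, L / 2, Lz / 2])

    # protein
    prot_names: list[str] = []
    prot_pos = np.empty((0, 3))
    prot_ss = ""
    tm_helices = tm_strands = 0
    excl_radius = 0.0
    if isinstance(spec.protein, HelixBundleSpec):
        if spec.protein.bundle_radius + 6 > L / 2:
            raise ValueError("protein radius exceeds the box")
        prot_names, prot_pos, prot_ss = _build_helix_bundle(
            spec.protein, centre, half, rng
        )
        tm_helices = spec.protein.n_helices
        excl_radius = spec.protein.bundle_radius + spec.protein.helix_radius + 1.0
    elif isinstance(spec.protein, BarrelSpec):
        if spec.protein.radius + 6 > L / 2:
            raise ValueError("protein radius exceeds the box")
        prot_names, prot_pos, prot_ss = _build_barrel(spec.protein, centre, rng)
        tm_strands = spec.protein.n_strands
        excl_radius = spec.protein.radius + 4.0

    # lipid lattice (leaflet-symmetric), excluding sites under the protein
    n_side = int(np.ceil(np.sqrt(spec.lipids_per_leaflet)))
    pitch = L / n_side
    sites = []
    for ix in range(n_side):
        for iy in range(n_side):
            if len(sites) >= spec.lipids_per_leaflet:
                break
            sites.append(((ix + 0.5) * pitch, (iy + 0.5) * pitch))
    sites = np.array(sites)
    jitter = rng.normal(0.0, spec.noise_sd, size=sites.shape)
    sites = sites + jitter
    if excl_radius > 0:
        # explicit annular ring so the first lipid shell around the protein
        # is continuous (the jittered lattice alone leaves angular gaps)
        r_ring = excl_radius + 1.0
        keep = np.hypot(sites[:, 0] - centre[0], sites[:, 1] - centre[1]) > r_ring + 4.0
        sites = sites[keep]
        n_ring = max(6, int(round(2 * np.pi * r_ring / 7.0)))
        angles = 2 * np.pi * np.arange(n_ring) / n_ring
        angles = angles + rng.normal(0.0, 0.02, n_ring)
        ring = centre[:2] + r_ring * np.column_stack([np.cos(angles), np.sin(angles)])
        sites = np.vstack([sites, ring])
    n_per_leaflet = len(sites)

    # static reference geometry: lipid ordinal -> (site, leaflet)
    lipid_sites = np.vstack([sites, sites])
    lipid_leaflet = np.array([1] * n_per_leaflet + [-1] * n_per_leaflet)  # +1 upper

    deform = spec.deformation

    def leaflet_shift(xy):
        if deform is None:
            return 0.0
        r = np.hypot(xy[0] - centre[0], xy[1] - centre[1])
        return 0.5 * deform.thinning(r)

    # solvent lattice
    water_xyz = []
    if spec.water:
        nw = int(L // spec.water_spacing)
        nz = int(Lz // spec.water_spacing)
        for ix in range(nw):
            for iy in range(nw):
                for iz in range(nz):
                    p = np.array(
                        [
                            (ix + 0.5) * spec.water_spacing,
                            (iy + 0.5) * spec.water_spacing,
                            (iz + 0.5) * spec.water_spacing,
                        ]
                    )
                    if abs(p[2] - centre[2]) < half + 5.0:
                        continue
                    water_xyz.append(p)
    water_xyz = np.array(water_xyz) if water_xyz else np.empty((0, 3))
    n_ions = min(spec.n_ions, len(water_xyz) // 2) if len(water_xyz) else 0
    ion_idx = (
        rng.choice(len(water_xyz), size=2 * n_ions, replace=False)
        if n_ions
        else np.array([], int)
    )
    ion_set = set(ion_idx.tolist())

    flips_by_frame: dict[int, list[tuple[int, str]]] = {}
    for ordinal, fr, direction in spec.planted_flips:
        if not (0 <= ordinal < len(lipid_sites)) or not (0 <= fr < spec.n_frames):
            raise ValueError(f"planted flip ({ordinal}, {fr}) out of range")
        flips_by_frame.setdefault(fr, []).append((ordinal, direction))

    frames: list[CGFrame] = []
    leaflet_truth: list[dict[int, str]] = []
    flipped = np.zeros(len(lipid_sites), bool)
    flip_records = [
        {"lipid_id": int(o), "frame": int(f), "direction": d}
        for o, f, d in spec.planted_flips
    ]

    n_res_prot = len(prot_names)
    for fi in range(spec.n_frames):
        for ordinal, _ in flips_by_frame.get(fi, []):
            flipped[ordinal] = True
        signs = np.where(flipped, -lipid_leaflet, lipid_leaflet)

        names, resnames, resids, coords = [], [], [], []
        # protein (chain A, residues 1..n, one BB bead each)
        for i, (nm, p) in enumerate(zip(prot_names, prot_pos)):
            names.append("BB")
            resnames.append(nm)
            resids.append(i + 1)
            coords.append(p)
        # lipids
        resid0 = n_res_prot
        for ordinal in range(len(lipid_sites)):
            xy = lipid_sites[ordinal]
            sign = signs[ordinal]
            z_po4 = centre[2] + sign * (half - leaflet_shift(xy))
            for bead, dz in _DPPC_OFFSETS:
                lx, ly = _DPPC_LATERAL.get(bead, (0.0, 0.0))
                names.append(bead)
                resnames.append("DPPC")
                resids.append(resid0 + ordinal + 1)
                coords.append([xy[0] + lx, xy[1] + ly, z_po4 + sign * dz])
        # solvent
        resid0 = n_res_prot + len(lipid_sites)
        for wi, p in enumerate(water_xyz):
            if wi in ion_set:
                continue
            names.append("W")
            resnames.append("W")
            resids.append(resid0 + wi + 1)
            coords.append(p)
        for k, wi in enumerate(ion_idx):
            ion = "NA+" if k < n_ions else "CL-"
            names.append(ion)
            resnames.append(ion)
            resids.append(resid0 + len(water_xyz) + k + 1)
            coords.append(water_xyz[wi])

        coords = np.asarray(coords, float)
        coords = coords + rng.normal(0.0, spec.noise_sd * 0.3, size=coords.shape)
        frames.append(
            frame_from_arrays(
                coordinates=coords,
                bead_names=names,
                residue_names=resnames,
                residue_indices=resids,
                box=box,
                frame_time=float(fi),
            )
        )
        leaflet_truth.append(
            {
                int(o): ("UPPER" if signs[o] > 0 else "LOWER")
                for o in range(len(lipid_sites))
            }
        )

    dz = prot_pos[:, 2] - centre[2] if len(prot_pos) else np.empty(0)
    if len(prot_pos):
        r_lat = np.hypot(prot_pos[:, 0] - centre[0], prot_pos[:, 1] - centre[1])
        if isinstance(spec.protein, HelixBundleSpec):
            outward = r_lat >= spec.protein.bundle_radius + 1.5
        elif isinstance(spec.protein, BarrelSpec):
            outward = r_lat >= spec.protein.radius
        else:
            outward = np.ones(len(prot_pos), bool)
    else:
        outward = np.empty(0, bool)
    env = {
        i + 1: lab for i, lab in enumerate(_environment_truth(dz, half, outward))
    }
    chains = []
    if prot_names:
        seq = "".join(
            {v: k for k, v in AMINO_ACIDS_1.items()}[nm] for nm in prot_names
        )
        chains = [ChainSequence(chain_id="A", sequence=seq, ss=prot_ss)]

    truth = GroundTruth(
        box=box.tolist(),
        midplane_z=float(centre[2]),
        bulk_thickness=float(sep),
        leaflet_labels=leaflet_truth,
        flips=flip_records,
        deformation=(
            None
            if deform is None
            else {
                "depth": deform.depth,
                "range": deform.range_,
                "centre": [float(centre[0]), float(centre[1])],
            }
        ),
        tm_helix_count=tm_helices,
        tm_strand_count=tm_strands,
        chains=chains,
        environment=env,
    )
    return frames, truth


def analytic_surfaces(truth: GroundTruth):
    """Planted upper/lower surface z as callables of (x, y)."""
    half = truth.bulk_thickness / 2.0
    mid = truth.midplane_z

    def thinning(x, y):
        if truth.deformation is None:
            return np.zeros_like(np.asarray(x, float))
        cx, cy = truth.deformation["centre"]
        r = np.hypot(np.asarray(x, float) - cx, np.asarray(y, float) - cy)
        return truth.deformation["depth"] * np.exp(
            -((r / truth.deformation["range"]) ** 2)
        )

    def upper(x, y):
        return mid + half - 0.5 * thinning(x, y)

    def lower(x, y):
        return mid - half + 0.5 * thinning(x, y)

    return upper, lower


def write_fixture(frames: list[CGFrame], truth: GroundTruth, outdir) -> dict:
    """Write GRO frames, the chain FASTA and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"frames": []}
    for i, frame in enumerate(frames):
        p = outdir / f"frame_{i:04d}.gro"
        write_frame(frame, p)
        paths["frames"].append(str(p))
    if truth.chains:
        write_fasta(truth.chains, outdir / "protein.fasta")
        with open(outdir / "protein.ss", "w") as fh:
            for ch in truth.chains:
                fh.write(f">{ch.chain_id}\n{ch.ss}\n")
        paths["fasta"] = str(outdir / "protein.fasta")
        paths["ss"] = str(outdir / "protein.ss")
    (outdir / "truth.json").write_text(truth.to_json())
    paths["truth"] = str(outdir / "truth.json")
    return paths


def generate_cohort(
    probabilities: dict[str, tuple[float, float, float]],
    n_residues_per_type: int = 500,
    seed: int = 1,
    ensure_surface: bool = True,
) -> ResidueContactProfile:
    """Sample residue-level contact incidences with known probabilities.

    ``probabilities`` maps one-letter amino acid codes to Bernoulli
    probabilities of a (head, tail, solvent) contact.  Head incidence is
    recorded as one phosphate contact, tail as one first-tail-bead contact,
    solvent as one water contact.  With ``ensure_surface`` (default) a
    residue that drew no contact receives a single water contact, so every
    residue counts toward the propensity denominator; solvent incidence then
    follows p_s + (1 - p_s)(1 - p_h)(1 - p_t).
    """
    rng = np.random.default_rng(seed)
    rows = []
    resid = 0
    for aa in sorted(probabilities):
        p_h, p_t, p_s = probabilities[aa]
        for p in (p_h, p_t, p_s):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        draws = rng.random((n_residues_per_type, 3)) < (p_h, p_t, p_s)
        for k in range(n_residues_per_type):
            resid += 1
            h, t, s = draws[k]
            if ensure_surface and not (h or t or s):
                s = True
            row = {c: 0 for c in COUNT_COLUMNS}
            row.update(
                chain_id="A",
                residue_index=resid,
                residue_name=AMINO_ACIDS_1[aa],
                phosphate=int(h),
                tail_1=int(t),
                water=int(s),
            )
            rows.append(row)
    df = pd.DataFrame(rows).set_index(["chain_id", "residue_index"])
    df = df[["residue_name"] + COUNT_COLUMNS]
    return ResidueContactProfile(counts=df, frames_analysed=1)
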