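import numpy as np
import pandas as pd
import pytest

from cgmem.beads import AMINO_ACIDS_1, AMINO_ACIDS_3
from cgmem.contacts import COUNT_COLUMNS, ResidueContactProfile
from cgmem.ensemble import (
    AA_ORDER,
    CommandAligner,
    ProgressiveAligner,
    aggregate_profiles,
    align_members,
    contact_propensity_scale,
    depth_distributions,
    thickness_summary,
)
from cgmem.fixtures import generate_cohort
from cgmem.frames import ChainSequence


# ---------------------------------------------------------------------------
# alignment


def test_identical_sequences_align_gapless():
    rows = ProgressiveAligner().align(["MKTAYIAKQR"] * 3)
    assert rows == ["MKTAYIAKQR"] * 3


def test_single_deletion_gap_sits_opposite_the_missing_residue():
    rows = ProgressiveAligner().align(["ACDEFG", "ACEFG"])
    assert rows[0] == "ACDEFG"
    assert rows[1] == "AC-EFG"


def test_pairwise_score_matches_biopython_oracle():
    """Our profile DP reduces to pairwise global alignment for 2 sequences;
    its score must match an independent dynamic-programming implementation."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    a, b = "MKTAYIAKQRQISFVKSHFSRQ", "MKTAYIAKQISFVKSHFS"
    rows = ProgressiveAligner().align([a, b])

    blosum = substitution_matrices.load("BLOSUM62")
    score = 0.0
    in_gap = False
    for x, y in zip(rows[0], rows[1]):
        if x == "-" or y == "-":
            score += -0.5 if in_gap else -10.0
            in_gap = True
        else:
            score += blosum[x][y]
            in_gap = False

    oracle = PairwiseAligner()
    oracle.mode = "global"
    oracle.substitution_matrix = blosum
    oracle.open_gap_score = -10.0
    oracle.extend_gap_score = -0.5
    assert score == pytest.approx(oracle.score(a, b))


def test_alignment_length_at_least_longest_input():
    seqs = ["ACDEFGHIKL", "ACDEGHIKL", "CDEFGHIKLM", "ACDEFGHIK"]
    rows = ProgressiveAligner().align(seqs)
    L = len(rows[0])
    assert all(len(r) == L for r in rows)
    assert L >= max(len(s) for s in seqs)
    for r, s in zip(rows, seqs):
        assert r.replace("-", "") == s


def test_empty_sequence_is_error():
    with pytest.raises(ValueError):
        ProgressiveAligner().align(["ACDE", ""])


def test_mafft_command_adapter_agrees_on_trivial_case():
    rows = CommandAligner().align(["ACDEFG", "ACDEFG"])
    assert rows == ["ACDEFG", "ACDEFG"]


# ---------------------------------------------------------------------------
# aggregation


def _member_table(seq, depth0=0.0):
    n = len(seq)
    return pd.DataFrame(
        {
            "head_fraction": np.linspace(0, 1, n),
            "tail_fraction": np.linspace(1, 0, n),
            "solvent_fraction": np.zeros(n),
            "depth": np.full(n, depth0),
            "ss": ["H"] * n,
        }
    )


def test_identical_members_aggregate_to_single_profile():
    seq = "MKTAYIAKQR"
    chains = [ChainSequence(chain_id=f"m{i}", sequence=seq) for i in range(3)]
    aligned = align_members(chains)
    tables = [_member_table(seq) for _ in range(3)]
    ens = aggregate_profiles(aligned, [c.chain_id for c in chains], tables)
    assert (ens.conservation == 1.0).all()
    assert (ens.coverage == 1.0).all()
    np.testing.assert_allclose(ens.head_fraction[0], tables[0]["head_fraction"])
    np.testing.assert_allclose(
        np.nanmean(ens.head_fraction, axis=0), tables[0]["head_fraction"]
    )


def test_gap_column_coverage_arithmetic():
    chains = [
        ChainSequence(chain_id="m0", sequence="ACDEFG"),
        ChainSequence(chain_id="m1", sequence="ACEFG"),
        ChainSequence(chain_id="m2", sequence="ACDEFG"),
    ]
    aligned = align_members(chains)
    tables = [_member_table(c.sequence) for c in chains]
    ens = aggregate_profiles(aligned, [c.chain_id for c in chains], tables)
    gap_col = aligned[1].sequence.index("-")
    assert ens.coverage[gap_col] == pytest.approx(2.0 / 3.0)
    assert np.isnan(ens.head_fraction[1, gap_col])


def test_column_means_match_direct_recomputation():
    chains = [
        ChainSequence(chain_id="m0", sequence="ACDEFGHIKL"),
        ChainSequence(chain_id="m1", sequence="ACDEGHIKL"),
    ]
    aligned = align_members(chains)
    tables = [_member_table(c.sequence, depth0=i) for i, c in enumerate(chains)]
    ens = aggregate_profiles(aligned, ["m0", "m1"], tables)
    table = ens.column_table()
    for j in range(ens.n_columns):
        vals = []
        for m, chain in enumerate(aligned):
            if chain.sequence[j] == "-":
                continue
            r = len(chain.sequence[:j].replace("-", ""))
            vals.append(tables[m]["head_fraction"].iloc[r])
        assert table["mean_head_fraction"].iloc[j] == pytest.approx(
            np.mean(vals)
        )


def test_profile_length_mismatch_is_error():
    chains = [
        ChainSequence(chain_id="m0", sequence="ACDEFG"),
        ChainSequence(chain_id="m1", sequence="ACDEFG"),
    ]
    aligned = align_members(chains)
    with pytest.raises(ValueError, match="m1"):
        aggregate_profiles(aligned, ["m0", "m1"],
                           [_member_table("ACDEFG"), _member_table("ACDE")])


# ---------------------------------------------------------------------------
# propensity scale


def _incidence_profile(p_by_aa, n=10):
    """Profile with exact planted per-category incidence fractions.

    ``p_by_aa`` maps aa -> (p_head, p_tail, p_solvent); head goes to the
    first residues, tail to the last (prefix + suffix cover every residue so
    all are surface residues), solvent to the first few.
    """
    rows = []
    resid = 0
    for aa, (p_h, p_t, p_s) in p_by_aa.items():
        k_h, k_t, k_s = (int(round(p * n)) for p in (p_h, p_t, p_s))
        assert k_h + k_t >= n, "union must cover all residues"
        for i in range(n):
            resid += 1
            row = {c: 0 for c in COUNT_COLUMNS}
            row.update(chain_id="A", residue_index=resid,
                       residue_name=AMINO_ACIDS_1[aa],
                       phosphate=int(i < k_h),
                       tail_1=int(i >= n - k_t),
                       water=int(i < k_s))
            rows.append(row)
    df = pd.DataFrame(rows).set_index(["chain_id", "residue_index"])
    return ResidueContactProfile(counts=df[["residue_name"] + COUNT_COLUMNS],
                                 frames_analysed=1)


def test_hand_set_probabilities_give_affine_scale():
    from cgmem.ensemble import normalize_scale

    p = pd.Series({"G": 0.2, "L": 0.8, "R": 0.5})
    s = normalize_scale(p)
    assert s["G"] == pytest.approx(0.0)
    assert s["L"] == pytest.approx(100.0)
    assert s["R"] == pytest.approx(50.0)


def test_planted_head_incidence_recovered_exactly():
    profile = _incidence_profile(
        {"G": (0.2, 0.8, 0.2), "L": (0.8, 0.9, 0.6), "R": (0.5, 0.7, 0.4)}
    )
    scale = contact_propensity_scale(profile)
    assert scale.table.loc["G", "p_head"] == pytest.approx(0.2)
    assert scale.table.loc["L", "p_head"] == pytest.approx(0.8)
    assert scale.table.loc["R", "s_head"] == pytest.approx(50.0)
    assert set(scale.missing_types) == set(AA_ORDER) - {"G", "L", "R"}


def test_scale_anchors_on_any_cohort():
    probs = {aa: (0.1 + 0.8 * i / 19, 0.5, 0.3)
             for i, aa in enumerate(AA_ORDER)}
    scale = contact_propensity_scale(generate_cohort(probs, 200, seed=3))
    for cat in ("head", "tail", "solvent"):
        assert scale.table.loc["G", f"s_{cat}"] == pytest.approx(0.0)
        assert scale.table[f"s_{cat}"].max() == pytest.approx(100.0)


def test_scale_invariant_under_collection_duplication():
    probs = {aa: (0.3, 0.6, 0.9) if aa != "G" else (0.1, 0.2, 0.5)
             for aa in AA_ORDER}
    cohort = generate_cohort(probs, 100, seed=4)
    once = contact_propensity_scale([cohort])
    twice = contact_propensity_scale([cohort, cohort])
    pd.testing.assert_frame_equal(once.table, twice.table)


def test_probability_recovery_at_n2000():
    """Recovered incidence probabilities converge to the generating ones."""
    rng = np.random.default_rng(5)
    probs = {aa: tuple(rng.uniform(0.1, 0.9, 3)) for aa in AA_ORDER}
    cohort = generate_cohort(probs, 2000, seed=6)
    scale = contact_propensity_scale(cohort)
    for aa in AA_ORDER:
        p_h, p_t, p_s = probs[aa]
        assert abs(scale.table.loc[aa, "p_head"] - p_h) < 0.05
        assert abs(scale.table.loc[aa, "p_tail"] - p_t) < 0.05
        # ensure_surface adds a water contact when nothing was drawn
        p_s_eff = p_s + (1 - p_s) * (1 - p_h) * (1 - p_t)
        assert abs(scale.table.loc[aa, "p_solvent"] - p_s_eff) < 0.05


def test_degenerate_scale_is_error():
    profile = _incidence_profile({"G": (0.5, 0.5, 0.2), "L": (0.5, 0.5, 0.2)})
    with pytest.raises(ValueError, match="degenerate"):
        contact_propensity_scale(profile)


# ---------------------------------------------------------------------------
# depth distributions


def _depth_table(spec, n=300, seed=8):
    rng = np.random.default_rng(seed)
    rows = []
    for aa, mu, sd in spec:
        for z in rng.normal(mu, sd, n):
            rows.append(
                {"residue_name": AMINO_ACIDS_1[aa], "depth": z * 18.5,
                 "local_thickness": 37.0}
            )
    return pd.DataFrame(rows)


def test_relative_histograms_sum_to_one():
    table = _depth_table([("L", 0.0, 0.3), ("R", 1.0, 0.1)])
    dist = depth_distributions(table, mode="relative", n_clusters=2)
    sums = dist.histograms.loc[["L", "R"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_separated_types_fall_in_different_clusters():
    table = _depth_table([("L", 0.0, 0.25), ("R", 1.0, 0.05)])
    dist = depth_distributions(table, mode="relative", n_clusters=2)
    assert dist.cluster_labels["L"] != dist.cluster_labels["R"]


def test_identical_types_share_a_cluster():
    rng = np.random.default_rng(9)
    core = rng.normal(0, 0.25, 300)
    rows = []
    for aa in ("I", "L"):  # identical planted distributions
        for z in core:
            rows.append({"residue_name": AMINO_ACIDS_1[aa], "depth": z * 18.5,
                         "local_thickness": 37.0})
    for aa, mu in (("R", 1.0), ("W", 0.8), ("Q", 1.5)):
        for z in rng.normal(mu, 0.05, 300):
            rows.append({"residue_name": AMINO_ACIDS_1[aa], "depth": z * 18.5,
                         "local_thickness": 37.0})
    dist = depth_distributions(pd.DataFrame(rows), n_clusters=4)
    assert dist.cluster_labels["I"] == dist.cluster_labels["L"]


def test_pore_residues_are_discounted():
    table = _depth_table([("L", 0.0, 0.2)], n=100)
    table["x"] = 0.0
    table["y"] = 0.0
    table["solvent_count"] = 5
    hull = np.array([[-10.0, -10.0], [10.0, -10.0], [0.0, 10.0]])
    dist = depth_distributions(table, tm_axes_xy=hull)
    assert dist.n_excluded_pore > 0
    assert "L" in dist.empty_types or dist.histograms.loc["L"].sum() in (0.0, 1.0)


def test_empty_type_flagged():
    table = _depth_table([("L", 0.0, 0.2)], n=50)
    dist = depth_distributions(table)
    assert "R" in dist.empty_types


# ---------------------------------------------------------------------------
# thickness summary


def test_class_means_recover_planted_thicknesses():
    members = [(37.1, "alpha_helical"), (36.9, "alpha_helical"),
               (33.2, "beta_barrel"), (32.8, "beta_barrel")]
    out = thickness_summary(members).set_index("class")
    assert abs(out.loc["alpha_helical", "mean"] - 37.0) < 0.5
    assert abs(out.loc["beta_barrel", "mean"] - 33.0) < 0.5


def test_single_member_class_has_zero_sd():
    out = thickness_summary([(37.0, "alpha_helical")]).set_index("class")
    assert out.loc["alpha_helical", "sd"] == 0.0


def test_summary_invariant_under_member_reordering():
    members = [(37.1, "alpha_helical"), (33.0, "beta_barrel"),
               (36.5, "alpha_helical")]
    a = thickness_summary(members)
    b = thickness_summary(members[::-1])
    pd.testing.assert_frame_equal(a, b)


def test_unknown_class_label_is_error():
    with pytest.raises(ValueError, match="unknown class"):
        thickness_summary([(37.0, "green")])
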