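"""dN/dS counting (NG86, TN93-weighted variant) and TN93 estimation."""
import itertools
import math

import numpy as np
import pytest

from mitocomp.composition import MITO_STOP_CODONS, SENSE_CODONS, VERTEBRATE_MITO_CODE
from mitocomp.selection import (
    CodonAlignment,
    SubstitutionModel,
    classify_selection_value,
    estimate_tn93,
    myn_pairwise,
    ng86_pairwise,
)
from mitocomp import simulate as sim
from mitocomp.divergence import jc_divergence


# --- independent oracle for tiny inputs ------------------------------------
def oracle_site_count(codon):
    """Synonymous sites of one codon by direct enumeration (equal weights)."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in MITO_STOP_CODONS:
                continue
            valid += 1
            if VERTEBRATE_MITO_CODE[alt] == VERTEBRATE_MITO_CODE[codon]:
                syn += 1
        if valid:
            total += syn / valid
    return total


def oracle_pair_diffs(c1, c2):
    """(Sd, Nd) averaged over stop-free orderings of the changed positions."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    sds = []
    for order in itertools.permutations(diff):
        cur, sd, ok = c1, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in MITO_STOP_CODONS:
                ok = False
                break
            if VERTEBRATE_MITO_CODE[cur] == VERTEBRATE_MITO_CODE[nxt]:
                sd += 1
            cur = nxt
        if ok:
            sds.append(sd)
    if not sds:
        return None
    sd = sum(sds) / len(sds)
    return sd, len(diff) - sd


def two_codon_alignment(c1a, c2a, c1b, c2b):
    return CodonAlignment({"A": c1a + c2a, "B": c1b + c2b}, gene="toy")


class TestNG86:
    def test_identical_sequences(self):
        aln = two_codon_alignment("ATG", "AAA", "ATG", "AAA")
        r = ng86_pairwise(aln, ("A", "B"))
        assert r.dN == 0.0 and r.dS == 0.0
        assert r.omega is None
        assert r.category == "undetermined"

    def test_single_synonymous_change_matches_oracle(self):
        aln = two_codon_alignment("ATG", "AAA", "ATG", "AAG")  # Lys AAA->AAG
        r = ng86_pairwise(aln, ("A", "B"))
        assert r.Sd == 1.0 and r.Nd == 0.0
        S_exp = 0.5 * (oracle_site_count("ATG") + oracle_site_count("ATG")) \
            + 0.5 * (oracle_site_count("AAA") + oracle_site_count("AAG"))
        assert r.S == pytest.approx(S_exp, abs=1e-12)
        # only 2/3 synonymous sites here, so pS = 1.5 is beyond JC saturation
        assert r.pS == pytest.approx(1.0 / S_exp, abs=1e-12)
        assert r.saturated and r.omega is None
        assert r.dN == 0.0

    def test_single_synonymous_change_ds_from_jc_on_longer_gene(self):
        a = "ATG" + "AAA" * 10
        b = "ATG" + "AAA" * 9 + "AAG"
        aln = CodonAlignment({"A": a, "B": b})
        r = ng86_pairwise(aln, ("A", "B"))
        S_exp = sum(0.5 * (oracle_site_count(a[i:i + 3])
                           + oracle_site_count(b[i:i + 3]))
                    for i in range(0, len(a), 3))
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert r.dS == pytest.approx(jc_divergence(1.0 / S_exp), abs=1e-12)
        assert r.dN == 0.0

    @pytest.mark.parametrize("c1,c2", [
        ("AAA", "AAG"), ("TTT", "TTC"), ("ATG", "ACG"), ("CTT", "GAG"),
        ("GGG", "CCC"), ("ATA", "TTG"), ("CAT", "CGC"),
    ])
    def test_pairwise_counts_match_enumeration_oracle(self, c1, c2):
        aln = two_codon_alignment("ATG", c1, "ATG", c2)
        r = ng86_pairwise(aln, ("A", "B"))
        sd, nd = oracle_pair_diffs(c1, c2)
        assert r.Sd == pytest.approx(sd, abs=1e-12)
        assert r.Nd == pytest.approx(nd, abs=1e-12)

    def test_blocked_pathway_pair_uses_detour_but_keeps_difference_count(self):
        # AAA <-> TGA: both 2-step direct pathways cross a stop codon
        assert oracle_pair_diffs("AAA", "TGA") is None
        aln = two_codon_alignment("ATG", "AAA", "ATG", "TGA")
        r = ng86_pairwise(aln, ("A", "B"))
        assert r.Sd + r.Nd == pytest.approx(2.0, abs=1e-12)
        assert r.Sd >= 0 and r.Nd >= 0

    def test_site_conservation_on_random_alignments(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            codons_a = rng.choice(SENSE_CODONS, size=30)
            codons_b = rng.choice(SENSE_CODONS, size=30)
            aln = CodonAlignment({"A": "".join(codons_a), "B": "".join(codons_b)})
            r = ng86_pairwise(aln, ("A", "B"))
            assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-6)
            ndiff = sum(a != b for a, b in zip(aln.sequences["A"],
                                              aln.sequences["B"]))
            assert r.Sd + r.Nd == pytest.approx(ndiff, abs=1e-9)

    def test_gapped_codons_skipped(self):
        aln = CodonAlignment({"A": "ATGAAATTT", "B": "ATG---TTT"})
        r = ng86_pairwise(aln, ("A", "B"))
        assert r.n_codons == 2


class TestCodonAlignmentValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            CodonAlignment({"A": "ATGAAA", "B": "ATG"})

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="whole codons"):
            CodonAlignment({"A": "ATGAAA", "B": "AT-AAA"})

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            CodonAlignment({"A": "ATGTAAAAA", "B": "ATGAAAAAA"})

    def test_from_cds_set_completes_and_strips_stops(self):
        aln = CodonAlignment.from_cds_set({"A": "ATGAAATA", "B": "ATGAAGTA"})
        # TA + A-padding -> TAA stop, stripped
        assert all(len(s) == 6 for s in aln.sequences.values())


class TestTN93Estimation:
    def test_recovers_simulated_rate_ratios(self):
        truth = sim.SimTruth(
            tree_newick="(A:0.1,B:0.1);",
            model=SubstitutionModel(4.0, 8.0,
                                    {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}),
            seed=7)
        rng = np.random.default_rng(7)
        root = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3],
                                  size=50000))
        tips = sim.evolve_along_tree(root, truth)["tips"]
        m = estimate_tn93(tips)
        assert m.kappa_R == pytest.approx(4.0, rel=0.10)
        assert m.kappa_Y == pytest.approx(8.0, rel=0.10)

    def test_jc_data_gives_unit_ratios(self):
        truth = sim.SimTruth(tree_newick="(A:0.1,B:0.1);", seed=11)
        rng = np.random.default_rng(11)
        root = "".join(rng.choice(list("ACGT"), size=50000))
        tips = sim.evolve_along_tree(root, truth)["tips"]
        m = estimate_tn93(tips)
        assert m.kappa_R == pytest.approx(1.0, abs=0.15)
        assert m.kappa_Y == pytest.approx(1.0, abs=0.15)

    def test_transversion_only_data_hits_lower_bound_with_warning(self):
        # 20% of sites differ, every difference a transversion (A<->C)
        a = "A" * 80 + "G" * 10 + "T" * 10
        b = "C" * 20 + "A" * 60 + "G" * 10 + "T" * 10
        with pytest.warns(UserWarning):
            m = estimate_tn93({"A": a, "B": b})
        assert m.kappa_R <= 1e-3 + 1e-12 and m.kappa_Y <= 1e-3 + 1e-12
        assert m.notes

    def test_saturated_transversions_fall_back_to_unit_ratios(self):
        with pytest.warns(UserWarning, match="saturation"):
            m = estimate_tn93({"A": "AAACCC" * 50, "B": "CCCAAA" * 50})
        assert m.kappa_R == 1.0 and m.kappa_Y == 1.0


class TestMYN:
    def test_collapse_identity_on_random_alignments(self):
        jc = SubstitutionModel.jukes_cantor()
        rng = np.random.default_rng(13)
        for _ in range(20):
            codons_a = rng.choice(SENSE_CODONS, size=40)
            codons_b = [c if rng.random() < 0.8
                        else str(rng.choice(SENSE_CODONS)) for c in codons_a]
            aln = CodonAlignment({"A": "".join(codons_a),
                                  "B": "".join(codons_b)})
            r_ng = ng86_pairwise(aln, ("A", "B"))
            r_myn = myn_pairwise(aln, ("A", "B"), model=jc)
            assert r_myn.S == pytest.approx(r_ng.S, abs=1e-6)
            assert r_myn.Sd == pytest.approx(r_ng.Sd, abs=1e-6)
            if not (math.isnan(r_ng.dS) or math.isnan(r_myn.dS)):
                assert r_myn.dS == pytest.approx(r_ng.dS, abs=1e-6)
                assert r_myn.dN == pytest.approx(r_ng.dN, abs=1e-6)

    def test_purifying_omega_recovered(self):
        truth = sim.SimTruth(tree_newick="(A:0.15,B:0.15);",
                             omega={"g": 0.2}, seed=3)
        tips = sim.evolve_codons(None, truth, gene="g", n_codons=5000)["tips"]
        aln = CodonAlignment(tips, gene="g")
        for estimator in (ng86_pairwise, myn_pairwise):
            r = estimator(aln, ("A", "B"))
            assert r.omega == pytest.approx(0.2, abs=0.1)
            assert r.category == "negative"

    def test_neutral_omega_recovered(self):
        truth = sim.SimTruth(tree_newick="(A:0.15,B:0.15);",
                             omega={"g": 1.0}, seed=17)
        tips = sim.evolve_codons(None, truth, gene="g", n_codons=5000)["tips"]
        aln = CodonAlignment(tips, gene="g")
        for estimator in (ng86_pairwise, myn_pairwise):
            r = estimator(aln, ("A", "B"))
            assert r.omega == pytest.approx(1.0, abs=0.15)

    def test_saturated_pair_flagged(self):
        rng = np.random.default_rng(19)
        a = rng.choice(SENSE_CODONS, size=200)
        b = rng.choice(SENSE_CODONS, size=200)
        aln = CodonAlignment({"A": "".join(a), "B": "".join(b)})
        r = ng86_pairwise(aln, ("A", "B"))
        assert r.saturated
        assert r.omega is None


@pytest.mark.parametrize("omega,expected", [
    (0.1, "negative"),
    (0.94, "negative"),
    (1.0, "neutral"),
    (1.04, "neutral"),
    (1.2, "positive"),
    (None, "undetermined"),
])
def test_selection_categories(omega, expected):
    assert classify_selection_value(omega) == expected
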