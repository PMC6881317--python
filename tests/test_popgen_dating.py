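"""Tajima's D, NG86 Ka/Ks, Ks dating, and the cohort enrichment test."""

import itertools
import math

import numpy as np
import pytest

from retrosel.genetic_code import STOP_CODONS, translate_codon
from retrosel.popgen_dating import (
    SaturationError,
    age_from_ks,
    enrichment_test,
    harmonic_a1,
    jukes_cantor,
    ks_confidence,
    ng86,
    tajima_d,
    watterson_theta,
)
from retrosel.seq_tree_io import PhyloTree
from retrosel.synthetic_data import SimulationConfig, simulate_alignment


# ---------------------------------------------------------------------------
# independent oracles, written from the original formulas
# ---------------------------------------------------------------------------


def tajima_oracle(seqs):
    """Direct transcription of the D statistic: enumerate all pairs,
    apply the a1..e2 variance construction."""
    m = len(seqs)
    n = len(seqs[0])
    S = sum(1 for j in range(n) if len({s[j] for s in seqs}) > 1)
    diffs = [
        sum(a[j] != b[j] for j in range(n))
        for a, b in itertools.combinations(seqs, 2)
    ]
    k_bar = sum(diffs) / len(diffs)
    a1 = sum(1 / i for i in range(1, m))
    a2 = sum(1 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m * m + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def ng86_oracle(seq_a, seq_b):
    """Step-by-step pathway enumeration for NG86 counts (no caching,
    explicit loops), returning (Ka, Ks)."""

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut not in STOP_CODONS and translate_codon(mut) == translate_codon(codon):
                    syn += 1 / 3
        return syn

    s_sites = n_sites = s_diff = n_diff = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        s_sites += (sites(ca) + sites(cb)) / 2
        n_sites += 3 - (sites(ca) + sites(cb)) / 2
        pos = [p for p in range(3) if ca[p] != cb[p]]
        if not pos:
            continue
        paths = []
        for order in itertools.permutations(pos):
            cur, steps, bad = ca, [], False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if nxt in STOP_CODONS:
                    bad = True
                steps.append((cur, nxt))
                cur = nxt
            paths.append((bad, steps))
        good = [st for bad, st in paths if not bad] or [st for _, st in paths]
        sd = nd = 0.0
        for steps in good:
            for a, b in steps:
                if (
                    translate_codon(a) == translate_codon(b)
                    and "*" not in (translate_codon(a), translate_codon(b))
                ):
                    sd += 1
                else:
                    nd += 1
        s_diff += sd / len(good)
        n_diff += nd / len(good)
    ka = -0.75 * math.log(1 - 4 * (n_diff / n_sites) / 3)
    ks = -0.75 * math.log(1 - 4 * (s_diff / s_sites) / 3)
    return ka, ks


def random_coding_pair(rng, n_codons, mut_prob):
    from retrosel.genetic_code import SENSE_CODONS

    a = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    b = list(a)
    for i in range(len(b)):
        if rng.random() < mut_prob:
            b[i] = str(rng.choice(list("ACGT")))
    # repair stops introduced by mutation
    out = []
    for i in range(0, len(b), 3):
        codon = "".join(b[i : i + 3])
        out.append(codon if codon not in STOP_CODONS else a[i : i + 3])
    return a, "".join(out)


class TestTajima:
    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for seed in range(8):
            m = int(rng.integers(4, 9))
            n = int(rng.integers(20, 100))
            seqs = ["".join(rng.choice(list("ACGT"), size=n)) for _ in range(m)]
            if all(len({s[j] for s in seqs}) == 1 for j in range(n)):
                continue
            res = tajima_d(seqs)
            assert res.D == pytest.approx(tajima_oracle(seqs), abs=1e-9)

    def test_matches_dendropy_popgenstat(self):
        import dendropy
        from dendropy.calculate import popgenstat

        rng = np.random.default_rng(33)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(6)]
        res = tajima_d(seqs)
        mat = dendropy.DnaCharacterMatrix.get(
            data="".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)),
            schema="fasta",
        )
        assert res.D == pytest.approx(popgenstat.tajimas_d(mat), abs=1e-9)

    def test_theta_from_printed_table_rows(self):
        assert watterson_theta(0.570, 16) == pytest.approx(0.172, abs=5e-4)
        assert watterson_theta(0.357, 4) == pytest.approx(0.195, abs=5e-4)

    def test_identical_sequences_have_undefined_d(self):
        res = tajima_d(["ACGTAC"] * 4)
        assert res.S == 0
        assert res.D is None
        assert "undefined" in res.note

    def test_complete_deletion_of_gapped_columns(self):
        seqs = ["AC-TAC", "ACGTAC", "ACGTAT", "ACGTAA"]
        res = tajima_d(seqs)
        assert res.n_sites == 5  # gapped column dropped

    def test_theta_identity(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
        res = tajima_d(seqs)
        assert res.theta == pytest.approx(res.ps / harmonic_a1(res.m), abs=1e-12)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            tajima_d(["ACG", "ACG", "ACG"])


class TestNg86:
    def test_identical_sequences(self):
        ka, ks, ratio = ng86("ATGAAATTT", "ATGAAATTT")
        assert ka == 0.0 and ks == 0.0
        assert math.isnan(ratio)

    def test_synonymous_single_change(self):
        # uncorrected proportions: a lone codon saturates Jukes-Cantor
        ka, ks, _ = ng86("TTT", "TTC", correction=False)
        assert ka == 0.0
        assert ks > 0.0

    def test_nonsynonymous_single_change(self):
        ka, ks, _ = ng86("TTT", "TTA", correction=False)  # Phe -> Leu
        assert ka > 0.0
        assert ks == 0.0

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            a, b = random_coding_pair(rng, 100, 0.05)
            ka, ks, _ = ng86(a, b)
            oka, oks = ng86_oracle(a, b)
            assert ka == pytest.approx(oka, abs=1e-12)
            assert ks == pytest.approx(oks, abs=1e-12)

    def test_neutral_simulation_gives_unit_ratio(self):
        tree = PhyloTree.from_newick("(a:0.15,b:0.15);")
        aln, _ = simulate_alignment(
            SimulationConfig(
                tree=tree,
                n_codons=1000,
                omega_scheme={"type": "one_ratio", "omega": 1.0},
                seed=5,
            )
        )
        ka, ks, ratio = ng86(aln.sequence("a"), aln.sequence("b"))
        assert ratio == pytest.approx(1.0, rel=0.10)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)


class TestDating:
    @pytest.mark.parametrize(
        "ks,expected", [(0.041, 3.15), (0.090, 6.92), (0.192, 14.77), (0.0, 0.0)]
    )
    def test_age_from_printed_ks(self, ks, expected):
        assert round(age_from_ks(ks), 2) == expected

    def test_zero_divergence_interval(self):
        seq = "ATGAAATTTGGGCCC" * 10
        ks, ci, info = ks_confidence(seq, seq, n_boot=100, seed=1)
        assert ks == 0.0 and ci == 0.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        a, b = random_coding_pair(rng, 120, 0.08)
        assert ks_confidence(a, b, n_boot=200, seed=9) == ks_confidence(
            a, b, n_boot=200, seed=9
        )

    def test_interval_narrows_with_length(self):
        # doubling the number of codons shrinks the CI roughly by sqrt(2)
        tree = PhyloTree.from_newick("(a:0.2,b:0.2);")
        aln, _ = simulate_alignment(
            SimulationConfig(tree=tree, n_codons=1600,
                             omega_scheme={"type": "one_ratio", "omega": 0.3},
                             seed=21)
        )
        sa, sb = aln.sequence("a"), aln.sequence("b")
        _, ci_short, _ = ks_confidence(sa[: 800 * 3], sb[: 800 * 3], n_boot=400, seed=3)
        _, ci_long, _ = ks_confidence(sa, sb, n_boot=400, seed=3)
        assert ci_long / ci_short == pytest.approx(1 / math.sqrt(2), rel=0.25)

    def test_bootstrap_interval_coverage(self):
        # population Ks from one long simulation; 20 short replicates
        cfg_kwargs = dict(
            omega_scheme={"type": "one_ratio", "omega": 0.3}, kappa=2.0
        )
        tree = PhyloTree.from_newick("(a:0.15,b:0.15);")
        big, _ = simulate_alignment(
            SimulationConfig(tree=tree, n_codons=30_000, seed=99, **cfg_kwargs)
        )
        _, true_ks, _ = ng86(big.sequence("a"), big.sequence("b"))
        covered = 0
        for seed in range(20):
            aln, _ = simulate_alignment(
                SimulationConfig(tree=tree, n_codons=300, seed=600 + seed, **cfg_kwargs)
            )
            ks, ci, _ = ks_confidence(
                aln.sequence("a"), aln.sequence("b"), n_boot=300, seed=seed
            )
            covered += abs(ks - true_ks) <= max(ci, 1e-9)
        assert covered >= 18  # >= 90% coverage

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            ks_confidence("ATG" * 10, "ATG" * 10)


class TestEnrichment:
    def test_identical_proportions(self):
        odds, p = enrichment_test(1, 10, 0.10, 100)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_table_matches_hypergeometric_enumeration(self):
        # [[5,0],[0,5]]: both extreme tables have probability 1/C(10,5)
        _, p = enrichment_test(5, 5, 0.0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_cohort_against_genomic_baseline(self):
        _, p = enrichment_test(7, 24, 0.10, 1000)
        assert p < 0.05

    def test_zero_margin_convention(self):
        _, p = enrichment_test(0, 10, 0.0, 100)
        assert p == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enrichment_test(11, 10, 0.1, 100)
        with pytest.raises(ValueError):
            enrichment_test(1, 10, 1.5, 100)
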