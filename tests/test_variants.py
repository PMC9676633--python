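import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cladediv.variants import (
    VariantRecord,
    build_consensus,
    classify_sites,
    filter_variants,
    gene_variant_stats,
    ng86_dnds,
    snp_per_base,
    tajimas_d,
    translate_codon,
)
from oracles import oracle_ng86, oracle_tajima_d

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]


def rec(pos, ref="A", alt="G", depth=30, qual=500.0, gene="g"):
    return VariantRecord(gene, pos, ref, alt, depth, qual)


class TestFilterVariants:
    def test_depth_inclusive_and_qual_strict_boundaries(self):
        kept = filter_variants([
            rec(1, depth=10, qual=201.0),   # kept: depth boundary inclusive
            rec(2, depth=10, qual=200.0),   # removed: QUAL must be > 200
            rec(3, depth=9, qual=500.0),    # removed: below depth
        ])
        assert [r.position for r in kept] == [1]

    def test_one_point_mutation_per_position(self):
        kept = filter_variants([
            rec(57, alt="G", qual=250.0),
            rec(57, alt="T", qual=230.0),
        ])
        assert len(kept) == 1 and kept[0].qual == 250.0
        # qual tie -> higher depth; full tie -> lexicographic alt
        kept = filter_variants([
            rec(5, alt="T", depth=40, qual=300.0),
            rec(5, alt="G", depth=20, qual=300.0),
        ])
        assert kept[0].depth == 40
        kept = filter_variants([
            rec(5, alt="T", depth=40, qual=300.0),
            rec(5, alt="C", depth=40, qual=300.0),
        ])
        assert kept[0].alt == "C"

    def test_idempotent_and_order_invariant(self):
        records = [rec(3), rec(1, alt="C"), rec(3, alt="T", qual=600.0), rec(2)]
        once = filter_variants(records)
        assert filter_variants(once) == once
        assert filter_variants(records[::-1]) == once

    def test_malformed_record_rejected_with_context(self):
        with pytest.raises(ValueError, match="g:4"):
            VariantRecord("g", 4, "A", "A", 30, 500.0)
        with pytest.raises(ValueError, match="SNV"):
            VariantRecord("g", 4, "AT", "A", 30, 500.0)


class TestSnpPerBase:
    def test_forced_arithmetic(self):
        assert snp_per_base([rec(i) for i in (1, 5, 9, 20, 777)], 1000) == 0.005
        assert snp_per_base([], 1000) == 0.0
        assert snp_per_base([rec(i) for i in range(1, 31)], 30) == 1.0

    def test_position_beyond_gene_is_an_error(self):
        with pytest.raises(ValueError, match="beyond"):
            snp_per_base([rec(31)], 30)


class TestConsensus:
    def test_substitution_and_identity(self):
        ref = "ATGGCATAA"
        assert build_consensus(ref, []) == ref
        out = build_consensus(ref, [rec(3, ref="G", alt="T")])
        assert out == "ATTGCATAA" and len(out) == len(ref)

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_consensus("ATG", [rec(3, ref="A", alt="C")])


class TestClassifySites:
    def test_phenylalanine_third_position(self):
        # TTT: only TTC is synonymous among the three third-position changes
        assert classify_sites("TTT")[2] == pytest.approx(1 / 3)

    def test_fourfold_degenerate_site(self):
        assert classify_sites("GGG")[2] == 1.0  # glycine GGN

    @pytest.mark.parametrize("codon", ["TTT", "GGG", "ATG", "TGG", "CGA", "TAT"])
    def test_sites_partition_to_three_per_codon(self, codon):
        frac = classify_sites(codon)
        s = frac.sum()
        assert 0 <= s <= 3
        # S + N = 3 by construction: N = 3 - S
        assert (3 - s) + s == pytest.approx(3)

    def test_matches_enumeration_oracle_on_all_sense_codons(self):
        from oracles import oracle_codon_sites

        for codon in SENSE_CODONS:
            assert classify_sites(codon).sum() == pytest.approx(
                oracle_codon_sites(codon), abs=1e-12
            )

    def test_internal_stop_is_an_error(self):
        with pytest.raises(ValueError, match="stop"):
            classify_sites("TAAGGG")


class TestNG86:
    def test_identical_sequences_invalid_omega(self):
        res = ng86_dnds("ATGGCA", "ATGGCA")
        assert res.dn == 0 and res.ds == 0 and not res.omega_valid
        assert res.reason == "ds_below_min"

    def test_single_synonymous_change_gives_omega_zero(self):
        ref = "GGT" * 100
        alt = "GGC" + "GGT" * 99
        res = ng86_dnds(ref, alt)
        assert res.dn == 0.0 and res.ds > 0
        assert res.omega_valid and res.omega == 0.0
        dn_o, ds_o = oracle_ng86(ref, alt)
        assert res.dn == pytest.approx(dn_o, abs=1e-9)
        assert res.ds == pytest.approx(ds_o, abs=1e-9)

    def test_equivalence_with_pathway_enumeration_oracle(self):
        """Every codon pair differing at <= 2 positions, embedded in a neutral
        context, agrees with the independent oracle to 1e-9."""
        context = "GCT" * 40  # alanine padding keeps dS inside the window
        rng = np.random.default_rng(0)
        pairs = []
        for c1 in SENSE_CODONS:
            for pos1 in range(3):
                for b1 in "ACGT":
                    if b1 == c1[pos1]:
                        continue
                    c2 = c1[:pos1] + b1 + c1[pos1 + 1:]
                    pairs.append((c1, c2))
        # add two-position differences (sampled exhaustively per codon)
        for c1 in SENSE_CODONS:
            for p1, p2 in ((0, 1), (0, 2), (1, 2)):
                for b1 in "ACGT":
                    for b2 in "ACGT":
                        if b1 == c1[p1] or b2 == c1[p2]:
                            continue
                        c2 = list(c1)
                        c2[p1], c2[p2] = b1, b2
                        pairs.append((c1, "".join(c2)))
        for c1, c2 in pairs:
            res = ng86_dnds(c1 + context, c2 + context, ds_min=0.0, ds_max=100.0)
            dn_o, ds_o = oracle_ng86(c1 + context, c2 + context)
            assert res.dn == pytest.approx(dn_o, abs=1e-9), (c1, c2)
            assert res.ds == pytest.approx(ds_o, abs=1e-9), (c1, c2)

    def test_symmetry_under_sequence_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s1 = "".join(rng.choice(SENSE_CODONS, 30))
            s2 = "".join(rng.choice(SENSE_CODONS, 30))
            a = ng86_dnds(s1, s2, ds_min=0.0, ds_max=100.0)
            # swapped comparison requires s2 to be a valid reference too
            try:
                b = ng86_dnds(s2, s1, ds_min=0.0, ds_max=100.0)
            except ValueError:
                continue
            assert a.dn == pytest.approx(b.dn, abs=1e-12, nan_ok=True)
            assert a.ds == pytest.approx(b.ds, abs=1e-12, nan_ok=True)

    def test_fourfold_third_position_mutations_give_dn_zero(self):
        rng = np.random.default_rng(7)
        fourfold = ["GC", "GG", "CC", "CG", "CT", "GT", "TC", "AC", "CG"]
        ref_codons = [rng.choice(fourfold) + rng.choice(list("ACGT")) for _ in range(60)]
        alt_codons = []
        for c in ref_codons:
            third = rng.choice([b for b in "ACGT" if b != c[2]])
            alt_codons.append(c[:2] + third)
        res = ng86_dnds("".join(ref_codons), "".join(alt_codons),
                        ds_min=0.0, ds_max=100.0)
        assert res.dn == 0.0

    def test_saturated_pair_is_flagged(self):
        ref = "GGT" * 50
        alt = "GGA GGC GGG".replace(" ", "") * 16 + "GGC" * 2
        # force very high synonymous divergence: every codon differs
        alt = "".join("GGC" if c == "GGT" else c for c in [ref[i:i+3] for i in range(0, len(ref), 3)])
        res = ng86_dnds(ref, alt)
        assert not res.omega_valid
        assert res.reason in ("ds_above_max", "jukes_cantor_saturated")

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATGGCA", "ATG")

    def test_matches_biopython_ng86(self):
        """Cross-check against an independent published implementation."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(20):
            ref = list(rng.choice(SENSE_CODONS, 50))
            alt = ref.copy()
            for i in rng.choice(50, size=4, replace=False):
                options = [c for c in SENSE_CODONS
                           if sum(x != y for x, y in zip(c, alt[i])) == 1]
                alt[i] = options[int(rng.integers(len(options)))]
            s1, s2 = "".join(ref), "".join(alt)
            dn_bio, ds_bio = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            res = ng86_dnds(s1, s2, ds_min=0.0, ds_max=100.0)
            if math.isnan(dn_bio) or math.isnan(res.dn):
                continue
            assert res.dn == pytest.approx(dn_bio, abs=5e-3)
            assert res.ds == pytest.approx(ds_bio, abs=5e-3)
            checked += 1
        assert checked >= 10


def make_alignment(n, length, n_sites, pattern, seed=0):
    """Alignments with planted segregating sites; pattern 'singleton' puts the
    derived allele in one sequence, 'balanced' in half of them."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), length))
    seqs = [list(base) for _ in range(n)]
    sites = rng.choice(length, size=n_sites, replace=False)
    for k, pos in enumerate(sites):
        ref = base[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        carriers = [k % n] if pattern == "singleton" else list(range(n // 2))
        for i in carriers:
            seqs[i][pos] = alt
    return ["".join(s) for s in seqs]


class TestTajimasD:
    def test_harmonic_constants(self):
        from cladediv.variants import _tajima_constants

        # a1(n=5) = 1 + 1/2 + 1/3 + 1/4 = 25/12
        a1 = sum(1 / i for i in range(1, 5))
        assert a1 == pytest.approx(25 / 12)
        e1, e2 = _tajima_constants(5)
        assert e1 > 0 and e2 > 0

    def test_no_segregating_sites_is_undefined(self):
        res = tajimas_d(["ACGT"] * 5)
        assert not res.defined and math.isnan(res.D)

    def test_fewer_than_three_sequences_is_an_error(self):
        with pytest.raises(ValueError):
            tajimas_d(["ACGT", "ACGT"])

    def test_unequal_lengths_are_an_error(self):
        with pytest.raises(ValueError):
            tajimas_d(["ACGT", "ACG", "ACGT"])

    def test_singleton_alignment_negative_balanced_positive(self):
        sing = make_alignment(10, 300, 20, "singleton", seed=1)
        bal = make_alignment(10, 300, 20, "balanced", seed=2)
        assert tajimas_d(sing).D < 0
        assert tajimas_d(bal).D > 0

    def test_matches_independent_oracle_on_random_alignments(self):
        rng = np.random.default_rng(3)
        checked = 0
        for trial in range(100):
            n = int(rng.integers(4, 12))
            aln = make_alignment(
                n, 90, int(rng.integers(1, 25)),
                "singleton" if trial % 2 else "balanced", seed=trial,
            )
            expected = oracle_tajima_d(aln)
            res = tajimas_d(aln)
            if expected is None:
                assert not res.defined
                continue
            assert res.D == pytest.approx(expected, abs=1e-9)
            checked += 1
        assert checked >= 90

    def test_synonymous_mask_restricts_sites(self):
        # GGT*30 reference: third positions are 4-fold degenerate
        ref = "GGT" * 30
        seqs = [list(ref) for _ in range(5)]
        seqs[0][2] = "C"   # synonymous (GGT->GGC)
        seqs[1][0] = "T"   # non-synonymous (GGT->TGT, Gly->Cys)
        aln = ["".join(s) for s in seqs]
        res_all = tajimas_d(aln)
        res_syn = tajimas_d(aln, synonymous=True, ref_seq=ref)
        assert res_all.S == 2
        assert res_syn.S == 1
        assert res_syn.total_sites == pytest.approx(classify_sites(ref).sum())


class TestGeneVariantStats:
    def test_zero_variants_zero_rate_invalid_omega(self):
        ref = "GGT" * 20
        s = gene_variant_stats("s1", "g", [], ref)
        assert s.snp_per_base == 0 and not s.omega_valid

    def test_synonymous_only_variants_give_omega_zero(self):
        ref = "GGT" * 100
        records = [
            VariantRecord("g", 3 * i + 3, "T", "C", 30, 500.0) for i in range(8)
        ]
        s = gene_variant_stats("s1", "g", records, ref)
        assert s.snp_per_base == pytest.approx(8 / 300)
        assert s.omega_valid and s.omega == 0.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(1, 60), st.integers(0, 60), st.floats(0, 1000)),
        min_size=0, max_size=30,
    )
)
def test_filter_variants_idempotence_property(entries):
    records = []
    for pos, depth, qual in entries:
        records.append(VariantRecord("g", pos, "A", "G", depth, qual))
    once = filter_variants(records)
    assert filter_variants(once) == once
    positions = [r.position for r in once]
    assert len(positions) == len(set(positions))
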