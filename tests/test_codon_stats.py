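import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from cpcub.codon_stats import (
    CodonCountTable,
    cai,
    composition,
    count_codons,
    enc,
    enc_expected,
    pool_counts,
    pr2_coordinates,
    rscu,
)
from cpcub.sequence_io import CodingSequence


def _table(counts, **kw):
    return CodonCountTable(counts=dict(counts), **kw)


class TestCountCodons:
    def test_stop_tally_separate(self):
        t = count_codons(CodingSequence("g", "t", "ATGAAATAA"))
        assert t.counts == {"ATG": 1, "AAA": 1}
        assert t.stop_counts == {"TAA": 1}

    def test_ambiguous_codon_skipped(self):
        t = count_codons(CodingSequence("g", "t", "ATGANATAA"))
        assert t.counts == {"ATG": 1}
        assert t.total == 1

    def test_pooled_total_matches_manifest_arithmetic(self, small_cds_set):
        genes, manifest = small_cds_set
        pool = pool_counts([count_codons(g) for g in genes], "fix")
        expected = sum(
            int(manifest[f"gene.{g.gene_id}.length_nt"]) // 3 - 1 for g in genes
        )
        assert pool.total == expected


class TestComposition:
    def test_hand_arithmetic(self):
        prof = composition(_table({"ATG": 1, "GCC": 1}))
        assert prof.gc1 == pytest.approx(0.5)
        assert prof.gc2 == pytest.approx(0.5)
        # third bases are G and C, so gc3 is 1.0 (consistent with gc_total=4/6)
        assert prof.gc3 == pytest.approx(1.0)
        assert prof.gc_total == pytest.approx(4 / 6)
        assert prof.gc3s == pytest.approx(1.0)  # only GCC eligible

    def test_gc3s_undefined_when_only_singletons(self):
        prof = composition(_table({"ATG": 1, "TGG": 1}))
        assert math.isnan(prof.gc3s)

    def test_position_fractions_sum_to_one(self, rng):
        from conftest import random_count_table

        prof = composition(random_count_table(rng))
        for pos in range(3):
            assert sum(prof.position_fractions[pos].values()) == pytest.approx(1.0, abs=1e-12)

    def test_mutation_pressure_recovered(self):
        from cpcub import synthetic_data as sd

        genes, manifest = sd.generate_mutation_driven(
            1, (4500, 4500), (0.3, 0.3), seed=5, taxon="p"
        )
        prof = composition(count_codons(genes[0]))
        # ~1500 draws/position: allow 4 binomial sigmas around 0.30
        sigma = 4 * math.sqrt(0.3 * 0.7 / 1500)
        for value in (prof.gc1, prof.gc2, prof.gc3):
            assert abs(value - 0.30) < sigma + 0.01

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            composition(_table({}))


class TestRSCU:
    def test_no_preference_is_one(self):
        table = rscu(_table({"TTT": 5, "TTC": 5}))
        assert table["TTT"] == table["TTC"] == pytest.approx(1.0)

    def test_forced_by_formula(self):
        table = rscu(_table({"TTT": 3, "TTC": 1}))
        assert table["TTT"] == pytest.approx(1.5)
        assert table["TTC"] == pytest.approx(0.5)

    def test_absent_family_nan_and_singleton_one(self):
        table = rscu(_table({"ATG": 2}))
        assert table["ATG"] == 1.0
        assert math.isnan(table["TTT"])

    @given(seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_family_sums_equal_family_size(self, seed, code):
        from conftest import random_count_table

        table = rscu(random_count_table(np.random.default_rng(seed)))
        for aa, fam in code.families().items():
            assert sum(table[c] for c in fam) == pytest.approx(len(fam), abs=1e-9)


class TestENc:
    def test_one_codon_per_aa_gives_20(self, code):
        counts = {fam[0]: 1000 for fam in code.families().values()}
        assert enc(_table(counts)) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self, code):
        counts = {}
        for fam in code.families().values():
            per = 6000 // len(fam)
            for c in fam:
                counts[c] = per
        value = enc(_table(counts))
        assert value > 60.9
        assert value == pytest.approx(61.0, abs=0.1)

    def test_oracle_equivalence_random_tables(self, rng):
        from conftest import random_count_table

        for _ in range(50):
            t = random_count_table(rng)
            assert enc(t) == pytest.approx(oracles.enc_brute(t.counts), abs=1e-9)

    def test_range_or_nan_property(self, rng):
        from conftest import random_count_table

        for _ in range(20):
            t = random_count_table(rng, max_count=4)
            value = enc(t)
            assert math.isnan(value) or 20.0 <= value <= 61.0

    def test_undefined_on_tiny_table(self):
        assert math.isnan(enc(_table({"TTT": 1})))

    def test_threefold_imputation(self, code):
        # all families well sampled except Ile (absent): ENc still defined
        counts = {}
        for aa, fam in code.families().items():
            if aa == "I":
                continue
            for c in fam:
                counts[c] = 100
        assert not math.isnan(enc(_table(counts)))


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_maximal_at_half_but_not_symmetric(self):
        grid = np.linspace(0, 1, 101)
        values = [enc_expected(s) for s in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5)
        # the linear +s term breaks symmetry
        assert enc_expected(0.3) != pytest.approx(enc_expected(0.7))
        assert enc_expected(0.7) - enc_expected(0.3) == pytest.approx(0.4)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)


class TestCAI:
    def _reference(self):
        # every family: one major codon (count 2) and minors (count 1) -> w_minor = 0.5
        from cpcub.sequence_io import DEFAULT_CODE

        counts = {}
        for fam in DEFAULT_CODE.families().values():
            counts[fam[0]] = 2
            for c in fam[1:]:
                counts[c] = 1
        return rscu(_table(counts))

    def test_all_maximal_codons_gives_one(self):
        ref = self._reference()
        from cpcub.sequence_io import DEFAULT_CODE

        gene = _table({fam[0]: 10 for fam in DEFAULT_CODE.families().values()})
        assert cai(gene, ref) == pytest.approx(1.0)

    def test_constant_w_half(self):
        ref = self._reference()
        from cpcub.sequence_io import DEFAULT_CODE

        gene = _table(
            {fam[1]: 10 for fam in DEFAULT_CODE.families().values() if len(fam) > 1}
        )
        assert cai(gene, ref) == pytest.approx(0.5)

    def test_log_domain_oracle(self, rng):
        from conftest import random_count_table

        ref = rscu(random_count_table(rng))
        for _ in range(20):
            t = random_count_table(rng)
            expected = oracles.cai_brute(t.counts, ref)
            assert math.log(cai(t, ref)) == pytest.approx(math.log(expected), abs=1e-12)

    def test_scale_invariance(self, rng):
        from conftest import random_count_table

        t = random_count_table(rng)
        ref = rscu(t)
        assert cai(t.scaled(10), ref) == pytest.approx(cai(t, ref), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            cai(_table({"ATG": 5}), self._reference())  # no eligible codons
        with pytest.raises(ValueError):
            cai(_table({"TTT": 5}), {})


class TestPR2:
    def test_center(self):
        x, y = pr2_coordinates(_table({"GGA": 1, "GGT": 1, "GGG": 1, "GGC": 1}))
        assert (x, y) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_zero_a3(self):
        _, y = pr2_coordinates(_table({"GGT": 3, "GGC": 1, "GGG": 1}))
        assert y == 0.0

    def test_zero_denominator_flagged(self):
        x, y = pr2_coordinates(_table({"GGA": 1, "GGT": 1}))
        assert y == pytest.approx(0.5)
        assert math.isnan(x)

    def test_fourfold_scope_restricts(self):
        # TTT (2-fold family) ignored under fourfold scope
        t = _table({"TTT": 100, "GGA": 1, "GGT": 1, "GGG": 2, "GGC": 2})
        x_all, y_all = pr2_coordinates(t, family_scope="all")
        x_ff, y_ff = pr2_coordinates(t, family_scope="fourfold")
        assert y_ff == pytest.approx(0.5)
        assert y_all < y_ff

    def test_mutation_model_near_center(self, mutation_records):
        dists = [
            math.hypot(r.pr2_x - 0.5, r.pr2_y - 0.5)
            for r in mutation_records
        ]
        assert np.mean(dists) < 0.05

    def test_bad_scope(self):
        with pytest.raises(ValueError):
            pr2_coordinates(_table({"GGA": 1}), family_scope="sixfold")
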