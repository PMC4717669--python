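import pytest
from hypothesis import given, settings, strategies as st

from chromorr.model import (Chromosome, ChromosomeStructure, Dialect,
                            GeneToken, ParseError, Pattern, WeightScheme,
                            parse_structure, validate_weights,
                            write_structure, CIRCULAR_DEFAULT_WEIGHTS,
                            LINEAR_DEFAULT_WEIGHTS, UNIT_WEIGHTS)
from conftest import ACONOIDASIDA_ROWS


class TestParsing:
    def test_table_dialect_orientations(self):
        s = parse_structure("cox1 *cox3 ls1 *ls3 *cytb *ls5 ls4 (L)", "table1")
        (chrom,) = s.chromosomes
        assert not chrom.circular
        assert [g.orient for g in chrom.genes] == [1, -1, 1, -1, -1, -1, 1]

    def test_grimm_minimal_circle(self):
        s = parse_structure("g1 g2 @")
        (chrom,) = s.chromosomes
        assert chrom.circular and len(chrom) == 2

    def test_multi_chromosome_table_line(self):
        s = parse_structure("a b (C) | *c (L)", "table1")
        assert sorted(c.circular for c in s.chromosomes) == [False, True]

    @pytest.mark.parametrize("bad", [
        "g1 g2",              # missing terminator
        "g1 g!2 $",           # malformed token
        "g1 g1 $",            # duplicate gene
        "x.1 x.1 $",          # duplicate paralog
    ])
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            parse_structure(bad)

    def test_paralog_token(self):
        s = parse_structure("cox1.2 -cox1.1 $")
        genes = s.chromosomes[0].genes
        assert genes[0].paralog == 2 and genes[1].orient == -1


class TestCanonical:
    def test_rotation_invariance(self):
        assert parse_structure("g1 g2 @") == parse_structure("g2 g1 @")

    def test_reversal_invariance_linear(self):
        assert parse_structure("g1 -g2 g3 $") == parse_structure("-g3 g2 -g1 $")

    def test_canonicalization_idempotent(self):
        s = parse_structure("g3 -g1 g2 @\n-g4 $").canonical()
        assert s.canonical().canonical_key == s.canonical_key

    def test_roundtrip_all_printed_rows(self):
        for name, topo, genes in ACONOIDASIDA_ROWS:
            text = f"{genes} ({topo})"
            s = parse_structure(text, "table1", name=name)
            for dialect in (Dialect.GRIMM, Dialect.TABLE1):
                assert parse_structure(write_structure(s, dialect),
                                       dialect) == s

    def test_babesia_reemits_identically(self):
        row = "cox1 *ls2 *ls3 *cytb *ls4 ls5 (L)"
        s = parse_structure(row, "table1")
        assert write_structure(s, "table1") == row

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_roundtrip_random(self, data):
        n = data.draw(st.integers(1, 5))
        orients = data.draw(st.lists(st.sampled_from([1, -1]),
                                     min_size=n, max_size=n))
        circular = data.draw(st.booleans())
        genes = tuple(GeneToken(f"g{i}", None, o)
                      for i, o in enumerate(orients))
        s = ChromosomeStructure((Chromosome(genes, circular),))
        for dialect in (Dialect.GRIMM, Dialect.TABLE1):
            assert parse_structure(write_structure(s, dialect), dialect) == s


class TestWeights:
    def test_default_patterns_valid(self):
        assert validate_weights(CIRCULAR_DEFAULT_WEIGHTS) == []
        assert validate_weights(LINEAR_DEFAULT_WEIGHTS) == []

    def test_equal_weights_valid_for_both_patterns(self):
        for pattern in (Pattern.CIRCULAR, Pattern.LINEAR):
            w = WeightScheme(1, 1, 1, 1, 1, 1, pattern)
            assert validate_weights(w) == []
            assert w.is_case2

    def test_case2_boundary(self):
        assert WeightScheme(1, 1, 1, 1, 1, 2).is_case2          # c = 2d
        assert not WeightScheme(1, 1, 1, 1, 1, "5/2").is_case2  # c > 2d
        assert not WeightScheme(1, 1, 1, 1, 1, "1/2").is_case2  # c < d

    def test_violations_reported(self):
        w = WeightScheme(double=2, sesqui=1, cut=1, join=1, delete=1,
                         insert=1, pattern=Pattern.CIRCULAR)
        assert any("double" in v for v in validate_weights(w))

    def test_nonpositive_weight(self):
        w = WeightScheme(0, 1, 1, 1, 1, 1)
        assert validate_weights(w)
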