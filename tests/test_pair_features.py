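"""Pair featurization: symmetry, pair-level primitives, completeness."""

from __future__ import annotations

import math
import random

import numpy as np
import pandas as pd
import pytest

from ppipred.io_formats import FeatureTable
from ppipred.pair_features import (
    SUPERSLIM_FALLBACK,
    SUPERSLIM_PRIORITY,
    PairFeaturizer,
    assemble_pair_vector,
    assign_superslim,
    chromosomal_pair_features,
    colocalization_index,
    expression_correlation,
    filter_complete,
)
from ppipred.pairs import MISSING, PairKey, is_missing


@pytest.fixture()
def expr():
    return pd.DataFrame(
        {
            "c1": [1.0, 2.0, 1.0, 5.0],
            "c2": [2.0, 1.0, 2.0, 5.0],
            "c3": [3.0, 4.0, 3.0, 5.0],
            "c4": [4.0, 3.0, 4.0, 5.0],
        },
        index=["A", "B", "C", "K"],
    )


class TestExpressionCorrelation:
    def test_identical_profiles_give_one(self, expr):
        assert expression_correlation(expr, PairKey.of("A", "C")) == pytest.approx(1.0)

    def test_antilinear_profiles_give_minus_one(self, expr):
        anti = expr.copy()
        anti.loc["B"] = -expr.loc["A"] + 10.0
        assert expression_correlation(anti, PairKey.of("A", "B")) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, expr):
        x = expr.loc["A"].to_numpy()
        y = expr.loc["B"].to_numpy()
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert expression_correlation(expr, PairKey.of("A", "B")) == pytest.approx(r_oracle)

    def test_fewer_than_three_shared_conditions_is_missing(self, expr):
        holey = expr.copy()
        holey.loc["B", ["c1", "c2"]] = np.nan
        assert is_missing(expression_correlation(holey, PairKey.of("A", "B")))

    def test_zero_variance_profile_is_missing(self, expr):
        assert is_missing(expression_correlation(expr, PairKey.of("A", "K")))

    def test_affine_invariance(self, expr):
        scaled = expr.copy()
        scaled.loc["A"] = 3.0 * expr.loc["A"] - 7.0
        base = expression_correlation(expr, PairKey.of("A", "B"))
        assert expression_correlation(scaled, PairKey.of("A", "B")) == pytest.approx(base)


class TestColocalization:
    LOC = {
        "A": frozenset({"nucleus", "cytoplasm"}),
        "B": frozenset({"nucleus"}),
        "C": frozenset({"vacuole"}),
    }

    def test_identical_sets_give_one(self):
        loc = {"A": frozenset({"nucleus"}), "B": frozenset({"nucleus"})}
        assert colocalization_index(loc, PairKey.of("A", "B")) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert colocalization_index(self.LOC, PairKey.of("A", "C")) == 0.0

    def test_jaccard_by_hand(self):
        assert colocalization_index(self.LOC, PairKey.of("A", "B")) == pytest.approx(0.5)

    def test_missing_annotation_is_missing(self):
        assert is_missing(colocalization_index(self.LOC, PairKey.of("A", "Z")))


class TestChromosomalFeatures:
    POS = pd.DataFrame(
        {
            "chromosome": ["I", "I", "II"],
            "strand": ["+", "-", "+"],
            "start": [500, 4500, 100],
            "end": [1500, 5500, 900],
        },
        index=["A", "B", "C"],
    )

    def test_same_gene_coordinates(self):
        pos = self.POS.copy()
        pos.loc["B"] = pos.loc["A"]
        assert chromosomal_pair_features(pos, PairKey.of("A", "B")) == (1.0, 1.0, 0.0)

    def test_cross_chromosome_distance_is_missing(self):
        same_strand, same_chrom, dist = chromosomal_pair_features(self.POS, PairKey.of("A", "C"))
        assert (same_strand, same_chrom) == (1.0, 0.0)
        assert is_missing(dist)

    def test_midpoint_distance(self):
        # midpoints 1000 and 5000 on chromosome I
        _, _, dist = chromosomal_pair_features(self.POS, PairKey.of("A", "B"))
        assert dist == 4000.0


class TestSuperslim:
    def test_priority_order_transport_before_primary_metabolism(self):
        assert assign_superslim({"GO:0006810", "GO:0044238"}) == "GO:0006810"

    def test_unannotated_falls_back_to_biological_process(self):
        assert assign_superslim(set()) == SUPERSLIM_FALLBACK

    def test_every_protein_gets_exactly_one_term(self, sim_dataset):
        for terms in sim_dataset.go_annotations.values():
            label = assign_superslim(terms)
            assert label in SUPERSLIM_PRIORITY


def _oracle_vector(featurizer, table, pair):
    """Independent concatenate-then-sort construction of the numeric block."""
    out = []
    for f, kind in table.kinds.items():
        if kind == "categorical":
            continue
        a = table.data.at[pair.first, f]
        b = table.data.at[pair.second, f]
        if is_missing(a) or is_missing(b):
            out.extend([MISSING, MISSING])
        else:
            out.extend(sorted([float(a), float(b)]))
    return out


class TestAssemble:
    def test_swap_gives_bit_identical_vector(self, featurizer, sim_dataset):
        rng = random.Random(1)
        ids = sim_dataset.features.protein_ids
        for _ in range(200):
            a, b = rng.sample(ids, 2)
            va = featurizer.vector(PairKey(a, b) if a < b else PairKey(b, a)).values
            vb = featurizer.vector(PairKey.of(b, a)).values
            np.testing.assert_array_equal(va, vb)

    def test_numeric_block_matches_min_max_oracle(self, featurizer, sim_dataset):
        rng = random.Random(2)
        ids = sim_dataset.features.protein_ids
        n_num = sum(1 for k in sim_dataset.features.kinds.values() if k != "categorical")
        for _ in range(50):
            a, b = rng.sample(ids, 2)
            vec = featurizer.vector(PairKey.of(a, b))
            oracle = _oracle_vector(featurizer, sim_dataset.features, PairKey.of(a, b))
            np.testing.assert_allclose(
                vec.values[: 2 * n_num], oracle, rtol=1e-12, equal_nan=True
            )

    def test_identical_feature_values_give_min_equal_max(self):
        table = FeatureTable(
            data=pd.DataFrame({"f": [3.0, 3.0]}, index=["A", "B"]),
            kinds={"f": "numeric"},
        )
        vec = assemble_pair_vector(table, None, None, None, set(), PairKey.of("A", "B"))
        assert vec.values[0] == vec.values[1] == 3.0

    def test_unknown_protein_raises(self, featurizer):
        with pytest.raises(KeyError):
            featurizer.vector(PairKey.of("nope1", "nope2"))

    def test_missing_propagates_and_sets_incomplete(self):
        table = FeatureTable(
            data=pd.DataFrame({"f": [1.0, np.nan]}, index=["A", "B"]),
            kinds={"f": "numeric"},
        )
        vec = assemble_pair_vector(table, None, None, None, set(), PairKey.of("A", "B"))
        assert not vec.complete
        assert is_missing(vec.values[0]) and is_missing(vec.values[1])

    def test_categorical_encoding_is_order_free(self):
        table = FeatureTable(
            data=pd.DataFrame({"cat": ["x", "y", "x"]}, index=["A", "B", "C"]),
            kinds={"cat": "categorical"},
            levels={"cat": ["x", "y"]},
        )
        fz = PairFeaturizer(features=table)
        v_ab = fz.vector(PairKey.of("A", "B")).values
        same, nx_, ny = v_ab[0], v_ab[1], v_ab[2]
        assert (same, nx_, ny) == (0.0, 1.0, 1.0)
        v_ac = fz.vector(PairKey.of("A", "C")).values
        assert (v_ac[0], v_ac[1], v_ac[2]) == (1.0, 2.0, 0.0)

    def test_per_protein_mode_is_still_symmetric(self, sim_dataset):
        fz = PairFeaturizer(features=sim_dataset.features, symmetric_mode="per_protein")
        rng = random.Random(3)
        ids = sim_dataset.features.protein_ids
        for _ in range(50):
            a, b = rng.sample(ids, 2)
            np.testing.assert_array_equal(
                fz.vector(PairKey.of(a, b)).values, fz.vector(PairKey.of(b, a)).values
            )

    def test_layout_is_stable_across_instances(self, sim_dataset):
        fz1 = PairFeaturizer(features=sim_dataset.features,
                             expression=sim_dataset.expression,
                             localization=sim_dataset.localization,
                             positions=sim_dataset.positions)
        fz2 = PairFeaturizer(features=sim_dataset.features,
                             expression=sim_dataset.expression,
                             localization=sim_dataset.localization,
                             positions=sim_dataset.positions)
        assert fz1.layout == fz2.layout

    def test_cross_chromosome_modes(self, sim_dataset):
        strict = PairFeaturizer(features=sim_dataset.features,
                                positions=sim_dataset.positions,
                                cross_chromosome_distance="missing")
        relaxed = PairFeaturizer(features=sim_dataset.features,
                                 positions=sim_dataset.positions,
                                 cross_chromosome_distance="max")
        pos = sim_dataset.positions
        a = pos.index[pos["chromosome"] == "I"][0]
        b = pos.index[pos["chromosome"] == "II"][0]
        i = strict.layout.index("chromosome_distance")
        assert is_missing(strict.vector(PairKey.of(a, b)).values[i])
        assert relaxed.vector(PairKey.of(a, b)).values[i] > 0


class TestFilterComplete:
    def test_counts(self, featurizer, sim_dataset):
        rng = random.Random(4)
        ids = sim_dataset.features.protein_ids
        vectors = [featurizer.vector(PairKey.of(*rng.sample(ids, 2))) for _ in range(100)]
        kept = filter_complete(vectors)
        assert len(kept) == sum(v.complete for v in vectors)
        assert all(not np.isnan(v.values).any() for v in kept)

    def test_all_complete_is_identity(self):
        table = FeatureTable(
            data=pd.DataFrame({"f": [1.0, 2.0]}, index=["A", "B"]),
            kinds={"f": "numeric"},
        )
        vecs = [assemble_pair_vector(table, None, None, None, set(), PairKey.of("A", "B"))]
        assert filter_complete(vecs) == vecs
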