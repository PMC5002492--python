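"""Compositional geometry: closure, filling value, SBP, ilr and inverses."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skbio.stats.composition import clr, ilr as skbio_ilr

import nutribalance as nb
from nutribalance.composition import SbpTable
from tests.conftest import random_compositions


class TestClose:
    @pytest.mark.parametrize(
        "values, scale, expected",
        [
            ((1, 1, 1, 1), 1.0, (0.25, 0.25, 0.25, 0.25)),
            ((12.2, 987.8), 1000.0, (12.2, 987.8)),
            ((2, 3, 5), 100.0, (20.0, 30.0, 50.0)),
        ],
    )
    def test_proportional_rescaling(self, values, scale, expected):
        profile = nb.close(values, scale=scale)
        assert profile.values == pytest.approx(expected)
        assert profile.values.sum() == pytest.approx(scale, rel=1e-12)

    def test_rejects_nonpositive_naming_part(self):
        with pytest.raises(ValueError, match="'P'"):
            nb.close([1.0, 0.0], parts=["N", "P"])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            nb.close([])


class TestFillingValue:
    def test_dry_waste_means(self):
        # B arrives in mg/kg and must be converted before the subtraction
        profile = nb.filling_value(
            {"N": 12.2, "P": 2.2, "K": 2.42, "Ca": 0.86, "Mg": 0.96,
             "S": 1.26, "B": 10.8}
        )
        assert profile["Fv"] == pytest.approx(1000.0 - 19.9108, abs=1e-9)
        assert profile["B"] == pytest.approx(0.0108)
        # measured values are not rescaled
        assert profile["N"] == pytest.approx(12.2)

    def test_single_part(self):
        assert nb.filling_value({"x": 400.0})["Fv"] == pytest.approx(600.0)

    def test_rejects_sum_at_or_above_scale(self):
        with pytest.raises(ValueError, match="units"):
            nb.filling_value({"a": 600.0, "b": 400.5}, mg_parts=())


class TestSbp:
    def test_two_part_basis(self):
        basis = nb.sbp_to_basis(SbpTable(("a", "b"), [[-1, +1]]))
        assert basis.matrix[0] == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_normalization_coefficient_four_vs_one(self, basis):
        # [S | N,P,K,Mg]: 4 numerator parts against 1 denominator part
        j = basis.labels.index("[S | N,P,K,Mg]")
        assert basis.coefficients[j] == pytest.approx(np.sqrt(4 / 5), abs=5e-5)

    def test_default_design_is_orthonormal(self, basis):
        gram = basis.matrix @ basis.matrix.T
        assert np.abs(gram - np.eye(7)).max() < 1e-10
        assert np.abs(basis.matrix.sum(axis=1)).max() < 1e-10

    def test_partial_design_accepted_but_incomplete(self, partial_basis):
        assert partial_basis.n_balances == 6
        assert not partial_basis.is_complete
        with pytest.raises(ValueError, match="complete"):
            nb.inverse_ilr(np.zeros(6), partial_basis)

    def test_rejects_straddling_row(self):
        # {b, c} straddles the split {a | b} ∪ {c, d}
        with pytest.raises(ValueError):
            SbpTable(("a", "b", "c", "d"),
                     [[+1, -1, 0, 0], [0, +1, -1, 0]])

    def test_rejects_one_sided_row(self):
        with pytest.raises(ValueError, match="row 1"):
            SbpTable(("a", "b"), [[+1, +1]])

    def test_frame_round_trip(self, tmp_path):
        sbp = nb.default_sbp()
        again = SbpTable.from_frame(sbp.to_frame())
        assert again.labels == sbp.labels
        assert (again.codes == sbp.codes).all()


class TestIlr:
    def test_pair_balance_hand_value(self):
        basis = nb.sbp_to_basis(SbpTable(("N", "P"), [[+1, -1]]))
        profile = nb.close([12.2, 2.2], ["N", "P"], 1000.0)
        coord = nb.ilr(profile, basis).coordinates[0]
        assert coord == pytest.approx(np.sqrt(0.5) * np.log(12.2 / 2.2))
        assert coord == pytest.approx(1.2113, abs=5e-5)

    def test_equal_parts_balance_is_zero(self, basis):
        profile = nb.close(np.full(8, 1.0), basis.parts)
        assert nb.ilr(profile, basis).coordinates == pytest.approx(np.zeros(7))

    @pytest.mark.parametrize("scale", [1.0, 100.0, 1000.0])
    def test_scale_invariance(self, basis, rng, scale):
        raw = rng.uniform(0.5, 20.0, size=8)
        ref = nb.ilr(nb.close(raw, basis.parts, 1000.0), basis).coordinates
        other = nb.ilr(nb.close(raw, basis.parts, scale), basis).coordinates
        assert other == pytest.approx(ref, rel=1e-12)

    def test_missing_part_rejected(self, basis):
        with pytest.raises(ValueError, match="'Fv'"):
            nb.ilr({p: 1.0 for p in basis.parts[:-1]}, basis)

    def test_matches_skbio_given_same_basis(self, basis, rng):
        x = random_compositions(rng, 20, 8)
        ours = nb.ilr_transform(x, basis).to_numpy()
        theirs = skbio_ilr(x / x.sum(axis=1, keepdims=True), basis=basis.matrix)
        assert np.abs(ours - theirs).max() < 1e-10


class TestInverseIlr:
    def test_zero_vector_gives_uniform(self, basis):
        profile = nb.inverse_ilr(np.zeros(7), basis, 1000.0)
        assert profile.values == pytest.approx(np.full(8, 125.0))

    def test_two_part_inverse_recovers_ratio(self):
        basis = nb.sbp_to_basis(SbpTable(("N", "P"), [[+1, -1]]))
        profile = nb.inverse_ilr([np.sqrt(0.5) * np.log(12.2 / 2.2)],
                                 basis, 1000.0)
        assert profile["N"] / profile["P"] == pytest.approx(12.2 / 2.2)

    def test_round_trip_bulk(self, basis, rng):
        x = random_compositions(rng, 1000, 8)
        coords = nb.ilr_transform(x, basis)
        back = nb.inverse_ilr_transform(coords, basis, 1000.0).to_numpy()
        assert np.abs(back / x - 1.0).max() < 1e-8

    @given(st.lists(st.floats(0.01, 100.0), min_size=8, max_size=8))
    def test_round_trip_property(self, values):
        basis = nb.default_basis()
        profile = nb.close(values, basis.parts, 1000.0)
        back = nb.inverse_ilr(nb.ilr(profile, basis), basis, 1000.0)
        assert back.values == pytest.approx(profile.values, rel=1e-8)


def _pivot_basis(parts):
    """Alternative complete SBP: part j against all later parts."""
    d = len(parts)
    codes = np.zeros((d - 1, d), dtype=int)
    for j in range(d - 1):
        codes[j, j] = +1
        codes[j, j + 1:] = -1
    return nb.sbp_to_basis(SbpTable(tuple(parts), codes))


class TestMeanAndDistance:
    def test_mean_of_identical_profiles(self, basis):
        x = nb.close([21, 1.6, 14, 9, 3.7, 3, 0.02, 947.68], basis.parts)
        mean = nb.compositional_mean([x, x, x], basis)
        assert mean.values == pytest.approx(x.values, rel=1e-12)

    def test_mean_symmetry_two_parts(self):
        basis = nb.sbp_to_basis(SbpTable(("a", "b"), [[+1, -1]]))
        p = nb.close([0.2, 0.8], ["a", "b"], 1.0)
        q = nb.close([0.8, 0.2], ["a", "b"], 1.0)
        assert nb.compositional_mean([p, q], basis, 1.0).values == pytest.approx(
            [0.5, 0.5])

    def test_mean_equals_closed_geometric_mean(self, basis, rng):
        x = random_compositions(rng, 50, 8)
        mean = nb.compositional_mean(
            nb.ilr_transform(x, basis).pipe(
                lambda c: nb.inverse_ilr_transform(c, basis)),
            basis).values
        gm = np.exp(np.log(x).mean(axis=0))
        gm = gm / gm.sum() * 1000.0
        assert np.abs(mean - gm).max() < 1e-10

    def test_distance_axioms_and_clr_oracle(self, basis, rng):
        x = random_compositions(rng, 10, 8)
        p = nb.close(x[0], basis.parts)
        q = nb.close(x[1], basis.parts)
        assert nb.aitchison_distance(p, p, basis) == 0.0
        assert nb.aitchison_distance(p, q, basis) == pytest.approx(
            nb.aitchison_distance(q, p, basis))
        # oracle: clr-based distance
        d_clr = np.linalg.norm(clr(p.values / 1000.0) - clr(q.values / 1000.0))
        assert nb.aitchison_distance(p, q, basis) == pytest.approx(d_clr,
                                                                   abs=1e-10)

    def test_distance_isometric_across_sbps(self, basis, rng):
        other = _pivot_basis(basis.parts)
        x = random_compositions(rng, 6, 8)
        for i in range(0, 6, 2):
            p = nb.close(x[i], basis.parts)
            q = nb.close(x[i + 1], basis.parts)
            assert nb.aitchison_distance(p, q, basis) == pytest.approx(
                nb.aitchison_distance(p, q, other), abs=1e-10)


def brute_force_sbp_count(n_parts: int) -> int:
    """Enumerate ordered SBP row sequences (as pairwise merge orders)."""

    def merges(groups: frozenset) -> int:
        if len(groups) == 1:
            return 1
        total = 0
        members = sorted(groups, key=sorted)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                merged = (groups - {members[i], members[j]}) | {
                    members[i] | members[j]}
                total += merges(frozenset(merged))
        return total

    singletons = frozenset(frozenset([i]) for i in range(n_parts))
    return merges(singletons)


class TestCountSbps:
    @pytest.mark.parametrize("d, expected", [(2, 1), (3, 3), (4, 18), (5, 180)])
    def test_matches_enumeration(self, d, expected):
        assert brute_force_sbp_count(d) == expected
        assert nb.count_sbps(d) == expected

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            nb.count_sbps(1)
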