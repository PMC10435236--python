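"""Morphology parsing, measurement, inflation, editing, and axon delays."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbcsim import morphology as mor
from gbcsim import synthetic as syn
from gbcsim.morphology import Tag

SWC_MINIMAL = """\
# soma root plus two children
1 1 0 0 0 5 -1
2 1 10 0 0 5 1
3 1 20 0 0 4 2
"""


def _cylinder(r=1.0, L=1.0, tag=Tag.SOMA, sid=0, parent=None, x0=0.0):
    pts = np.array([[x0, 0.0, 0.0, r], [x0 + L, 0.0, 0.0, r]])
    return mor.Section(id=sid, parent_id=parent, tag=tag, points=pts)


class TestParseSWC:
    def test_minimal_tree(self, tmp_path):
        p = tmp_path / "m.swc"
        p.write_text(SWC_MINIMAL)
        m = mor.parse_swc(p)
        assert len(m.sections) == 1
        assert m.root.tag is Tag.SOMA
        assert len(m.root.points) == 3  # two frustums

    def test_round_trip_identity(self, tmp_path):
        cell = syn.make_toy_cell(syn.CellTemplate(), seed=3)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        mor.write_swc(cell, p1)
        m1 = mor.parse_swc(p1)
        mor.write_swc(m1, p2)
        m2 = mor.parse_swc(p2)
        assert len(m1.sections) == len(m2.sections)
        tags1 = sorted((s.tag, len(s.points)) for s in m1.sections)
        tags2 = sorted((s.tag, len(s.points)) for s in m2.sections)
        assert tags1 == tags2
        assert mor.surface_area(m1) == pytest.approx(mor.surface_area(m2), rel=1e-12)
        # SWC text carries 6 decimals, hence the slightly relaxed tolerance
        assert mor.surface_area(m1) == pytest.approx(mor.surface_area(cell), rel=1e-5)
        for tag in Tag:
            assert mor.surface_area(m1, {tag}) == pytest.approx(
                mor.surface_area(cell, {tag}), rel=1e-5
            ), tag

    def test_swelling_tag_usable_by_area_filter(self, tmp_path):
        p = tmp_path / "s.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 1 10 0 0 5 1\n3 6 10 5 0 2 2\n4 6 10 9 0 2 3\n")
        m = mor.parse_swc(p)
        swell = [s for s in m.sections if s.tag is Tag.SWELLING]
        assert len(swell) == 1
        assert mor.surface_area(m, {Tag.SWELLING}) > 0

    def test_unknown_code_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 99 0 0 0 5 -1\n")
        with pytest.raises(mor.MorphologyError, match="type code"):
            mor.parse_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "two.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 1 9 0 0 5 -1\n")
        with pytest.raises(mor.MorphologyError, match="root"):
            mor.parse_swc(p)

    def test_duplicate_points_merged(self, tmp_path):
        p = tmp_path / "dup.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 1 0 0 0 5 1\n3 1 10 0 0 5 2\n")
        m = mor.parse_swc(p)
        assert len(m.root.points) == 2


class TestSurfaceArea:
    def test_cylinder_closed_form(self):
        m = mor.Morphology([_cylinder(r=1.0, L=1.0)])
        assert mor.surface_area(m) == pytest.approx(2 * math.pi, rel=1e-12)

    def test_cone_closed_form(self):
        pts = np.array([[0, 0, 0, 1.0], [1.0, 0, 0, 1e-9]])
        m = mor.Morphology([mor.Section(0, None, Tag.SOMA, pts)])
        assert mor.surface_area(m) == pytest.approx(math.pi * math.sqrt(2.0), rel=1e-6)

    def test_matches_numeric_quadrature(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 3.0, 20))])
        r = rng.uniform(0.5, 3.0, 21)
        pts = np.column_stack([x, np.zeros(21), np.zeros(21), r])
        m = mor.Morphology([mor.Section(0, None, Tag.SOMA, pts)])
        # quadrature of the surface of revolution: dA = 2 pi r sqrt(1+r'^2) dx
        total = 0.0
        for i in range(20):
            xs = np.linspace(x[i], x[i + 1], 20001)
            rs = np.interp(xs, x[i: i + 2], r[i: i + 2])
            drdx = (r[i + 1] - r[i]) / (x[i + 1] - x[i])
            total += np.trapezoid(2 * np.pi * rs * math.sqrt(1 + drdx**2), xs)
        assert mor.surface_area(m) == pytest.approx(total, rel=1e-6)

    def test_empty_tag_selection_warns_and_returns_zero(self):
        m = mor.Morphology([_cylinder()])
        with pytest.warns(UserWarning):
            assert mor.surface_area(m, set()) == 0.0


class TestInflate:
    def test_identity_targets(self, toy_cell):
        soma = mor.surface_area(toy_cell, {Tag.SOMA})
        dend = mor.surface_area(toy_cell, mor.DENDRITE_TAGS)
        out, res = mor.inflate(toy_cell, soma, dend)
        assert res.soma_factor == pytest.approx(1.0, abs=1e-9)
        assert res.dendrite_factor == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("factor", [1.486, 0.5])
    def test_linear_scaling(self, toy_cell, factor):
        soma = mor.surface_area(toy_cell, {Tag.SOMA})
        dend = mor.surface_area(toy_cell, mor.DENDRITE_TAGS)
        out, res = mor.inflate(toy_cell, factor * soma, factor * dend)
        assert res.achieved_soma_area == pytest.approx(factor * soma, rel=1e-3)
        assert res.achieved_dendrite_area == pytest.approx(factor * dend, rel=1e-3)
        # frustum lateral area is linear in radius at fixed length
        assert res.soma_factor == pytest.approx(factor, rel=1e-6)
        assert res.dendrite_factor == pytest.approx(factor, rel=1e-6)
        # lengths unchanged
        assert out.total_length() == pytest.approx(toy_cell.total_length(), rel=1e-12)

    @given(st.floats(min_value=0.3, max_value=3.0))
    def test_factor_equals_area_ratio(self, factor):
        cell = syn.make_toy_cell(syn.CellTemplate(), seed=5)
        soma = mor.surface_area(cell, {Tag.SOMA})
        dend = mor.surface_area(cell, mor.DENDRITE_TAGS)
        _out, res = mor.inflate(cell, factor * soma, factor * dend)
        assert res.soma_factor == pytest.approx(factor, rel=1e-6)


class TestPrune:
    def test_empty_set_is_identity(self, toy_cell):
        out = mor.prune(toy_cell, set())
        assert mor.surface_area(out) == pytest.approx(mor.surface_area(toy_cell))
        assert len(out.sections) == len(toy_cell.sections)

    def test_terminal_branch_area_bookkeeping(self, toy_cell):
        terminal = next(
            s for s in toy_cell.sections
            if not toy_cell.children(s.id) and s.tag is not Tag.SOMA
        )
        out = mor.prune(toy_cell, {terminal.id})
        assert mor.surface_area(toy_cell) - mor.surface_area(out) == pytest.approx(
            terminal.area, rel=1e-12
        )

    def test_subtree_removed(self, toy_cell):
        hub = next(s for s in toy_cell.sections if s.tag is Tag.HUB)
        doomed = toy_cell.subtree_ids(hub.id)
        out = mor.prune(toy_cell, {hub.id})
        assert {s.id for s in out.sections}.isdisjoint(doomed)
        assert mor.surface_area(out) < mor.surface_area(toy_cell)

    def test_refuses_root(self, toy_cell):
        with pytest.raises(mor.MorphologyError, match="root"):
            mor.prune(toy_cell, {toy_cell.root.id})


class TestStandardAxon:
    def test_graft_sets_ais_length(self, toy_cell):
        frag = syn.make_standard_axon(hillock_length=2.3, ais_length=16.8)
        out = mor.substitute_standard_axon(toy_cell, frag)
        assert out.total_length({Tag.AIS}) == pytest.approx(16.8, rel=1e-9)
        assert {s.tag for s in out.sections} >= set(mor.AXON_TAGS)

    def test_double_substitution_idempotent(self, toy_cell):
        frag = syn.make_standard_axon(ais_length=20.0)
        once = mor.substitute_standard_axon(toy_cell, frag)
        twice = mor.substitute_standard_axon(once, frag)
        assert mor.surface_area(twice) == pytest.approx(mor.surface_area(once))
        assert twice.total_length({Tag.AIS}) == pytest.approx(20.0, rel=1e-9)


class TestBranchDelay:
    def test_en_passant_zero(self):
        assert mor.branch_delay(mor.AxonBranch(0.0, 1.4)) == 0.0

    def test_arithmetic_oracle(self):
        b = mor.AxonBranch(length=100.0, axon_diameter=2.7, g_ratio=0.76)
        cv = 4.6 * 2.7 / 0.76  # m/s
        assert cv == pytest.approx(16.34, abs=0.005)
        base = mor.branch_delay(b, ld_slowing_k=0.0)
        assert base == pytest.approx(100.0 / cv, rel=1e-12)
        assert base == pytest.approx(6.12, abs=0.005)

    def test_monotone_in_length(self):
        delays = [
            mor.branch_delay(mor.AxonBranch(L, 1.4)) for L in (5.0, 20.0, 80.0, 133.0)
        ]
        assert all(d2 > d1 for d1, d2 in zip(delays, delays[1:]))

    def test_short_branch_slowing(self):
        short = mor.AxonBranch(5.0, 1.4)
        # the L/d correction multiplies delay by >= 1, more for short branches
        assert mor.branch_delay(short) > mor.branch_delay(short, ld_slowing_k=0.0)

    def test_fiber_diameter(self):
        b = mor.AxonBranch(10.0, 2.7, g_ratio=0.76)
        assert b.fiber_diameter == pytest.approx(2.7 / 0.76)
        with pytest.raises(ValueError):
            mor.AxonBranch(10.0, 1.0, g_ratio=1.2)
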