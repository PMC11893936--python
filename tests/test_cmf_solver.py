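"""Continuous max-flow solver: energies, projection, thresholding,
oracle equivalence with a discrete min-cut."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from cmflv import (
    CapacityField,
    CMFConfig,
    LabelField,
    chambolle_project,
    primal_energy,
    solve_cmf,
    threshold_label,
)
from cmflv.core_grid_io import VectorField


def discrete_mincut_oracle(Cs, Ct, C, spacing=(1.0, 1.0, 1.0), scale=10**6):
    """Min-cut on the 4/6-connected grid graph, independent of the CMF path.

    Integer-scaled capacities through scipy's max-flow, cut extracted by
    BFS on the residual graph.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_flow

    shape = Cs.shape
    nvox = Cs.size
    src, snk = nvox, nvox + 1
    rows, cols, caps = [], [], []

    def add(u, v, c):
        rows.append(u)
        cols.append(v)
        caps.append(int(round(c * scale)))

    strides = (shape[1] * shape[2], shape[2], 1)
    for i, j, k in product(*(range(s) for s in shape)):
        n = i * strides[0] + j * strides[1] + k
        add(src, n, Cs[i, j, k])
        add(n, snk, Ct[i, j, k])
        for ax, (di, dj, dk) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
            ii, jj, kk = i + di, j + dj, k + dk
            if ii < shape[0] and jj < shape[1] and kk < shape[2]:
                w = 0.5 * (C[i, j, k] + C[ii, jj, kk]) / spacing[ax]
                n2 = ii * strides[0] + jj * strides[1] + kk
                add(n, n2, w)
                add(n2, n, w)

    g = csr_matrix((caps, (rows, cols)), shape=(nvox + 2, nvox + 2))
    residual = (g - maximum_flow(g, src, snk).flow).tocsr()
    seen = np.zeros(nvox + 2, bool)
    seen[src] = True
    dq = deque([src])
    while dq:
        u = dq.popleft()
        for e in range(residual.indptr[u], residual.indptr[u + 1]):
            v = residual.indices[e]
            if residual.data[e] > 0 and not seen[v]:
                seen[v] = True
                dq.append(v)
    return seen[:nvox].reshape(shape).astype(np.uint8)


class TestPrimalEnergy:
    def test_all_background_pays_source(self, rng):
        Cs, Ct = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        cap = CapacityField(Cs, Ct, 0.3, spacing=(2.0, 1.0, 1.0))
        e = primal_energy(LabelField(np.zeros((4, 4, 4)), cap.spacing), cap)
        assert e == pytest.approx(Cs.sum() * 2.0)

    def test_all_foreground_pays_sink(self, rng):
        Cs, Ct = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        cap = CapacityField(Cs, Ct, 0.3)
        e = primal_energy(LabelField(np.ones((4, 4, 4))), cap)
        assert e == pytest.approx(Ct.sum())

    def test_matches_term_by_term_oracle(self, rng):
        lam = rng.random((5, 4, 3))
        Cs, Ct = rng.random((5, 4, 3)), rng.random((5, 4, 3))
        C = rng.random((5, 4, 3))
        sp = (1.5, 0.9, 2.0)
        cap = CapacityField(Cs, Ct, C, sp)
        # literal re-computation, scalar loops
        vol = sp[0] * sp[1] * sp[2]
        total = 0.0
        for i, j, k in product(range(5), range(4), range(3)):
            gx = (lam[i + 1, j, k] - lam[i, j, k]) / sp[0] if i + 1 < 5 else 0.0
            gy = (lam[i, j + 1, k] - lam[i, j, k]) / sp[1] if j + 1 < 4 else 0.0
            gz = (lam[i, j, k + 1] - lam[i, j, k]) / sp[2] if k + 1 < 3 else 0.0
            total += (
                (1 - lam[i, j, k]) * Cs[i, j, k]
                + lam[i, j, k] * Ct[i, j, k]
                + C[i, j, k] * np.sqrt(gx**2 + gy**2 + gz**2)
            ) * vol
        assert primal_energy(LabelField(lam, sp), cap) == pytest.approx(total)


class TestChambolleProjection:
    def test_feasible_field_unchanged(self, rng):
        p = VectorField(*(0.1 * rng.standard_normal((3, 4, 4, 4))))
        q = chambolle_project(p, np.ones((4, 4, 4)))
        np.testing.assert_array_equal(q.px, p.px)

    def test_rescales_to_ball(self):
        px = np.zeros((2, 2, 2))
        py = np.zeros((2, 2, 2))
        px[0, 0, 0], py[0, 0, 0] = 3.0, 4.0
        q = chambolle_project(VectorField(px, py, np.zeros((2, 2, 2))),
                              np.ones((2, 2, 2)))
        assert q.px[0, 0, 0] == pytest.approx(0.6)
        assert q.py[0, 0, 0] == pytest.approx(0.8)

    def test_idempotent_and_feasible(self, rng):
        C = rng.random((4, 4, 4)) * 2
        p = VectorField(*rng.standard_normal((3, 4, 4, 4)))
        q = chambolle_project(p, C)
        assert np.all(q.norm() <= C * (1 + 1e-12))
        qq = chambolle_project(q, C)
        np.testing.assert_allclose(qq.px, q.px, atol=1e-14)

    def test_negative_capacity_rejected(self, rng):
        p = VectorField.zeros((3, 3, 3))
        with pytest.raises(ValueError):
            chambolle_project(p, -np.ones((3, 3, 3)))


class TestThreshold:
    def test_examples(self):
        lam = LabelField(np.full((3, 3, 3), 1.0))
        assert threshold_label(lam, 0.5).mask.all()
        vals = np.where(np.arange(27).reshape(3, 3, 3) % 2 == 0, 0.2, 0.8)
        m = threshold_label(LabelField(vals), 0.5).mask
        np.testing.assert_array_equal(m, (vals == 0.8))

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.5, 2.0])
    def test_threshold_domain(self, t):
        with pytest.raises(ValueError):
            threshold_label(LabelField(np.zeros((3, 3, 3))), t)


class TestSolveCMF:
    def test_cheap_source_gives_all_foreground(self):
        cap = CapacityField(np.ones((6, 6, 6)), np.zeros((6, 6, 6)), 0.2)
        st = solve_cmf(cap)
        assert st.converged
        assert threshold_label(st.lam).mask.all()

    def test_step_edge_matches_exhaustive_cut_search(self):
        # 1-D two-segment signal: compare against brute force over every
        # single-threshold labeling
        N = 16
        I = np.zeros((N, 1, 1))
        I[9:] = 1.0
        Cs, Ct = I**2, (I - 1) ** 2
        cap = CapacityField(Cs, Ct, 0.3)
        st = solve_cmf(cap, CMFConfig(max_iter=800, tol=1e-6))
        got = threshold_label(st.lam).mask.ravel()

        def cut_energy(c):  # labels 1 from c onward
            m = np.zeros(N)
            m[c:] = 1
            lf = LabelField(m[:, None, None])
            return primal_energy(lf, cap)

        best = min(range(N + 1), key=cut_energy)
        expect = np.zeros(N, dtype=np.uint8)
        expect[best:] = 1
        np.testing.assert_array_equal(got, expect)

    def test_agrees_with_discrete_mincut(self, rng):
        agree, total = 0, 0
        for trial in range(6):
            shape = (8, 8, 1) if trial % 2 == 0 else (6, 6, 6)
            Cs, Ct = rng.random(shape), rng.random(shape)
            C = np.full(shape, 0.01)
            st = solve_cmf(CapacityField(Cs, Ct, C),
                           CMFConfig(max_iter=5000, tol=1e-8))
            m = threshold_label(st.lam).mask
            mo = discrete_mincut_oracle(Cs, Ct, C)
            agree += int((m == mo).sum())
            total += m.size
        assert agree / total >= 0.99

    def test_truncation_property_approximate(self, rng):
        # thresholding a converged relaxed solution at any cut level costs
        # almost nothing: the residual is the relaxation gap of the
        # isotropic discretization, well under 1% of the energy
        Cs, Ct = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        cap = CapacityField(Cs, Ct, 0.05)
        st = solve_cmf(cap, CMFConfig(max_iter=5000, tol=1e-8))
        assert st.converged
        e_relaxed = primal_energy(st.lam, cap)
        for t in np.arange(0.1, 0.95, 0.1):
            lf = LabelField(threshold_label(st.lam, float(t)).mask.astype(float))
            assert primal_energy(lf, cap) <= e_relaxed * 1.01

    def test_truncation_exact_on_binary_optimum(self):
        # when the relaxed optimum is itself binary (clean two-level data)
        # thresholding is exactly energy-neutral at every cut level
        I = np.zeros((8, 8, 2))
        I[3:6, 2:7] = 1.0
        cap = CapacityField(I**2, (I - 1) ** 2, 1e-3)
        st = solve_cmf(cap, CMFConfig(max_iter=3000, tol=1e-9))
        e_relaxed = primal_energy(st.lam, cap)
        for t in (0.1, 0.5, 0.9):
            lf = LabelField(threshold_label(st.lam, t).mask.astype(float))
            assert primal_energy(lf, cap) <= e_relaxed + 1e-6 * max(e_relaxed, 1)

    def test_label_stays_in_unit_interval_and_residual_small(self, rng):
        Cs, Ct = rng.random((8, 8, 4)), rng.random((8, 8, 4))
        cfg = CMFConfig(max_iter=2000, tol=1e-6)
        st = solve_cmf(CapacityField(Cs, Ct, 0.1), cfg)
        assert st.lam.lam.min() >= 0 and st.lam.lam.max() <= 1
        assert st.converged
        scale = np.mean(Cs + Ct)
        assert st.residuals[-1] < cfg.tol * scale
        # residuals trend downward: final well below the early iterates
        assert st.residuals[-1] < 0.1 * max(st.residuals[:10])

    def test_nonconvergence_returns_best_iterate(self, rng):
        Cs, Ct = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        st = solve_cmf(CapacityField(Cs, Ct, 0.1), CMFConfig(max_iter=3))
        assert not st.converged
        assert st.iterations == 3

    def test_flow_capacity_constraints_hold(self, rng):
        Cs, Ct = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        C = np.full((6, 6, 6), 0.2)
        st = solve_cmf(CapacityField(Cs, Ct, C), CMFConfig(max_iter=2000, tol=1e-6))
        assert np.all(st.ps <= Cs + 1e-9)
        assert np.all(st.pt <= Ct + 1e-9)
        assert np.all(st.p.norm() <= C + 1e-9)


class TestConfigValidation:
    def test_bad_penalty(self):
        with pytest.raises(ValueError):
            CMFConfig(c=0.0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            CMFConfig(threshold=1.0)

    def test_negative_capacity_rejected(self):
        with pytest.raises(Exception):
            CapacityField(-np.ones((3, 3, 3)), np.ones((3, 3, 3)), 0.1)
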