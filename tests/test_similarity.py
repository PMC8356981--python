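"""Partition similarity: NMI, cover NMI, resampling significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbncomm import (
    SoftCover,
    bootstrap_nmi_pvalue,
    group_between_scan_agreement,
    nmi_cover,
    nmi_hard,
)


def _contingency_nmi_oracle(a, b):
    """Independent hand oracle: 2 I(a;b) / (H(a) + H(b)) from the table."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    table = np.zeros((a.max(), b.max()))
    for x, y in zip(a, b):
        table[x - 1, y - 1] += 1
    p = table / n
    px, py = p.sum(1), p.sum(0)

    def H(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    mask = p > 0
    I = (p[mask] * np.log(p[mask] / np.outer(px, py)[mask])).sum()
    denom = H(px) + H(py)
    return 1.0 if denom == 0 else 2 * I / denom


class TestHardNmi:
    def test_identity_and_permutation_invariance(self):
        a = np.repeat([1, 2, 3, 4], 10)
        assert nmi_hard(a, a) == 1.0
        relabeled = np.array([5 - x for x in a])  # bijective relabeling
        assert nmi_hard(a, relabeled) == pytest.approx(1.0)

    def test_orthogonal_partitions_share_no_information(self):
        assert nmi_hard([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_both_trivial_partitions_defined_as_one(self):
        assert nmi_hard([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi_hard([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_hand_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        a = rng.integers(1, 4, n)
        b = rng.integers(1, 4, n)
        a[0], b[0] = 1, 1  # keep labels 1-based contiguous enough for the oracle
        assert nmi_hard(a, b) == pytest.approx(_contingency_nmi_oracle(a, b), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        v1, v2 = nmi_hard(a, b), nmi_hard(b, a)
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert -1e-12 <= v1 <= 1 + 1e-12


def _as_cover(labels) -> SoftCover:
    labels = np.asarray(labels)
    k = labels.max()
    M = np.zeros((labels.size, k), dtype=int)
    M[np.arange(labels.size), labels - 1] = 1
    return SoftCover(M)


class TestCoverNmi:
    def test_identical_covers_are_one(self):
        c = _as_cover(np.repeat([1, 2, 3], 5))
        assert nmi_cover(c, c) == 1.0

    def test_column_permutation_invariance(self):
        labels = np.repeat([1, 2, 3], 5)
        a = _as_cover(labels)
        b = SoftCover(a.membership[:, ::-1])
        assert nmi_cover(a, b) == 1.0

    def test_orthogonal_hard_partitions_score_zero(self):
        assert nmi_cover(_as_cover([1, 1, 2, 2]), _as_cover([1, 2, 1, 2])) == pytest.approx(0.0)

    def test_close_to_hard_nmi_on_embedded_partitions(self):
        # the LFK and contingency normalisations differ, but agree closely
        # for similar partitions; fixture pairs span exact and near matches
        base = np.repeat([1, 2, 3, 4], 10)
        moved = base.copy()
        moved[0] = 2
        for other in (base, moved):
            hard = nmi_hard(base, other)
            soft = nmi_cover(_as_cover(base), _as_cover(other))
            assert abs(hard - soft) < 0.05
        # the gap widens as partitions diverge, but both orderings agree
        rough = base.copy()
        rough[[0, 10, 20]] = [2, 3, 4]
        assert nmi_cover(_as_cover(base), _as_cover(rough)) < nmi_cover(
            _as_cover(base), _as_cover(moved)
        )
        assert nmi_hard(base, rough) < nmi_hard(base, moved)

    def test_overlapping_node_improves_on_wrong_assignment(self):
        # node 4 genuinely in both communities: the overlap cover should
        # score at least as high as either hard alternative
        M = np.zeros((9, 2), dtype=int)
        M[:5, 0] = 1
        M[4:, 1] = 1
        overlap = SoftCover(M)
        hard = _as_cover([1, 1, 1, 1, 1, 2, 2, 2, 2])
        assert nmi_cover(overlap, overlap) == 1.0
        assert 0 < nmi_cover(overlap, hard) < 1

    def test_empty_cover_rejected(self):
        with pytest.raises(ValueError):
            nmi_cover(SoftCover(np.ones((3, 1))), SoftCover(np.ones((0, 1))))


class TestBootstrapPvalue:
    def test_identical_nontrivial_partitions_minimal_pvalue(self):
        labels = np.repeat([1, 2, 3, 4], 10)
        res = bootstrap_nmi_pvalue(labels, labels, n_resamples=999, seed=0)
        assert res.nmi == 1.0
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_calibration_under_random_relabeling(self):
        # p-values from the exact permutation null: rejection at p <= .05
        # should occur for ~5% of random pairs
        rng = np.random.default_rng(42)
        base = np.repeat([1, 2, 3, 4], 10)
        rejections = 0
        n_pairs = 200
        for i in range(n_pairs):
            shuffled = rng.permutation(base)
            res = bootstrap_nmi_pvalue(base, shuffled, n_resamples=199, seed=5000 + i)
            rejections += res.p_value <= 0.05
        assert abs(rejections / n_pairs - 0.05) <= 0.02

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_nmi_pvalue([1, 2], [1, 2], n_resamples=10)


class TestGroupAgreement:
    def test_identical_sessions_give_one(self):
        parts = {(s, ses): [1, 1, 2, 2] for s in (1, 2, 3) for ses in (1, 2)}
        assert group_between_scan_agreement(parts) == 1.0

    def test_mean_over_subjects(self):
        parts = {
            (1, 1): [1, 1, 2, 2], (1, 2): [1, 1, 2, 2],  # NMI 1
            (2, 1): [1, 1, 2, 2], (2, 2): [1, 2, 1, 2],  # NMI 0
        }
        assert group_between_scan_agreement(parts) == pytest.approx(0.5)

    def test_missing_session_names_subject(self):
        with pytest.raises(ValueError, match="2"):
            group_between_scan_agreement({(1, 1): [1, 2], (1, 2): [1, 2], (2, 1): [1, 2]})
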