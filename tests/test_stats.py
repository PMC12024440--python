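import numpy as np
import pandas as pd
import pytest

from edgefc import (
    SubjectTable,
    bonferroni,
    chi_square_counts,
    compare_groups,
    residualize,
    two_sample_t,
)


def subjects_frame(n1=6, n2=6, seed=0, **covs):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    data = {
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["g1"] * n1 + ["g2"] * n2,
    }
    for name, spec in covs.items():
        data[name] = spec if hasattr(spec, "__len__") else rng.normal(size=n)
    return SubjectTable(frame=pd.DataFrame(data))


class TestResidualize:
    def test_no_covariates_demeans(self):
        subj = subjects_frame()
        y = np.arange(12.0)
        r = residualize(y, subj, [])
        assert np.allclose(r, y - y.mean())

    def test_exact_linear_fit_gives_zero(self):
        x = np.linspace(0, 10, 12)
        subj = subjects_frame(education=x)
        y = 3.0 + 0.5 * x
        r = residualize(y, subj, ["education"])
        assert np.abs(r).max() < 1e-10

    def test_rank_deficient_named(self):
        x = np.linspace(0, 10, 12)
        subj = subjects_frame(a=x, b=2 * x)
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.arange(12.0), subj, ["a", "b"])

    def test_recovers_planted_group_effect(self):
        rng = np.random.default_rng(42)
        n1 = n2 = 60
        edu = rng.normal(12, 3, n1 + n2)
        effect = 1.0
        y = (
            effect * np.r_[np.zeros(n1), np.ones(n2)]
            + 0.5 * edu
            + rng.normal(0, 0.5, n1 + n2)
        )
        subj = subjects_frame(n1, n2, education=edu)
        r = residualize(y, subj, ["education"])
        mask = subj.group_mask()
        est = r[mask].mean() - r[~mask].mean()
        # CI half-width ~ 2 * 0.5 * sqrt(2/60) ~ 0.18
        assert abs(est - effect) < 0.3

    def test_affine_covariate_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1 = residualize(y, subjects_frame(c=x), ["c"])
        r2 = residualize(y, subjects_frame(c=5 * x + 7), ["c"])
        assert np.allclose(r1, r2, atol=1e-10)


class TestTwoSampleT:
    def test_identical_groups(self):
        y = np.r_[np.arange(6.0), np.arange(6.0)]
        t, df, p = two_sample_t(y, np.r_[np.zeros(6), np.ones(6)].astype(bool))
        assert t == 0.0
        assert p == 1.0
        assert df == 10

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=13)
        mask = rng.random(13) < 0.5
        mask[:2], mask[-2:] = False, True
        t1, _, p1 = two_sample_t(y, mask)
        t2, _, p2 = two_sample_t(y, ~mask)
        assert np.isclose(t1, -t2)
        assert np.isclose(p1, p2)

    def test_matches_textbook_formula(self):
        """Pooled-variance t computed independently from the definition."""
        a = np.array([2.1, 3.4, 2.8, 3.9, 2.2, 3.0])  # group2
        b = np.array([1.1, 1.9, 2.5, 1.4, 2.0, 1.7])  # group1
        n1, n2 = len(b), len(a)
        sp2 = ((n1 - 1) * b.var(ddof=1) + (n2 - 1) * a.var(ddof=1)) / (n1 + n2 - 2)
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        y = np.r_[b, a]
        mask = np.r_[np.zeros(n1), np.ones(n2)].astype(bool)
        t, df, p = two_sample_t(y, mask)
        assert abs(t - t_expected) < 1e-12
        assert df == n1 + n2 - 2

    def test_welch_option(self):
        rng = np.random.default_rng(5)
        y = np.r_[rng.normal(0, 1, 10), rng.normal(0, 5, 8)]
        mask = np.r_[np.zeros(10), np.ones(8)].astype(bool)
        t_eq, df_eq, _ = two_sample_t(y, mask, equal_var=True)
        t_w, df_w, _ = two_sample_t(y, mask, equal_var=False)
        assert df_w < df_eq

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(np.arange(4.0), np.array([True, False, False, False]))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 16, 0.003125), (0.05, 1, 0.05), (0.05, 9, 0.05 / 9)],
    )
    def test_threshold(self, alpha, n, expected):
        assert np.isclose(bonferroni(alpha, n), expected)

    def test_zero_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)


class TestChiSquare:
    def test_proportional_table(self):
        chi2, p = chi_square_counts(np.array([[10, 20], [5, 10]]))
        assert np.isclose(chi2, 0.0)
        assert np.isclose(p, 1.0)

    def test_perfect_association(self):
        chi2, _ = chi_square_counts(np.array([[10, 0], [0, 10]]))
        assert np.isclose(chi2, 20.0)  # n*(ad-bc)^2 / (row*col products)

    def test_cohort_sex_table_nonsignificant(self):
        # 24M/9F vs 24M/20F: qualitatively non-significant
        chi2, p = chi_square_counts(np.array([[24, 9], [24, 20]]))
        assert 0.05 <= p <= 0.2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_counts(np.array([[0, 0], [5, 10]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_square_counts(np.array([[1.5, 2], [3, 4]]))


def entropy_frame(values_by_unit, subject_ids, level="network", k=2):
    rows = []
    for unit, values in values_by_unit.items():
        for sid, v in zip(subject_ids, values):
            rows.append(
                {"subject_id": sid, "level": level, "unit": unit, "k": k,
                 "entropy": v}
            )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_trivially_separated_single_unit(self):
        subj = subjects_frame(5, 5)
        ids = subj.subject_ids
        ent = entropy_frame({"netA": np.r_[np.zeros(5), np.ones(5)]}, ids)
        res = compare_groups(ent, subj, level="network", k=2)
        assert res.family_size == 1
        assert res.significant_units == ["netA"]
        row = res.table.iloc[0]
        assert row["t"] > 0 and row["direction"] == "g2>g1"

    def test_direction_bookkeeping_roundtrip(self, tmp_path):
        subj = subjects_frame(5, 5)
        ids = subj.subject_ids
        ent = entropy_frame({"netA": np.r_[np.ones(5), np.zeros(5)]}, ids)
        res = compare_groups(ent, subj, level="network", k=2)
        row = res.table.iloc[0]
        assert row["t"] < 0 and row["direction"] == "g1>g2"
        out = tmp_path / "stats.tsv"
        res.table.to_csv(out, sep="\t", index=False)
        back = pd.read_csv(out, sep="\t")
        assert back.loc[0, "direction"] == "g1>g2"
        assert bool(back.loc[0, "significant"]) == bool(row["significant"])

    def test_family_size_sets_threshold(self):
        rng = np.random.default_rng(0)
        subj = subjects_frame(6, 6)
        ids = subj.subject_ids
        units = {f"net{i}": rng.normal(size=12) for i in range(16)}
        res = compare_groups(entropy_frame(units, ids), subj, level="network", k=2)
        assert res.family_size == 16
        assert np.isclose(res.threshold, 0.05 / 16)
        assert (res.table["threshold"] == res.threshold).all()
        # significance flag <=> p < threshold
        assert (
            (res.table["p_raw"] < res.threshold) == res.table["significant"]
        ).all()

    def test_missing_subject_rejected(self):
        subj = subjects_frame(3, 3)
        ent = entropy_frame({"n": np.zeros(5)}, subj.subject_ids[:5])
        with pytest.raises(ValueError, match="missing entropy"):
            compare_groups(ent, subj, level="network", k=2)

    def test_covariate_adjustment_changes_result(self):
        rng = np.random.default_rng(7)
        subj = subjects_frame(20, 20, education=np.r_[
            rng.normal(10, 1, 20), rng.normal(14, 1, 20)])
        edu = subj.frame["education"].to_numpy()
        # entropy driven entirely by education, not by group
        ent = entropy_frame({"netA": 0.05 * edu + rng.normal(0, 0.01, 40)},
                            subj.subject_ids)
        raw = compare_groups(ent, subj, level="network", k=2)
        adj = compare_groups(ent, subj, level="network", k=2,
                             covariates=["education"])
        assert raw.table.loc[0, "p_raw"] < 0.001  # confounded
        assert adj.table.loc[0, "p_raw"] > 0.01  # adjusted away
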