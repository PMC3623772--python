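"""Tag-SNP classification, PCA, within-group diversity, concordance."""

import numpy as np
import pytest

from balsel import haplogroups, popstats, synthdata
from balsel.haplogroups import NE1, NON_NE1, UNCLASSIFIED, TagSnpPanel
from balsel.hapio import _loose_matrix


def make_panel(k=6):
    return TagSnpPanel(
        snp_ids=[f"t{i}" for i in range(k)],
        positions=np.arange(1, k + 1) * 100,
        consensus_ne1=np.ones(k, dtype=np.int8),
        consensus_non_ne1=np.zeros(k, dtype=np.int8),
    )


def matrix_from_rows(rows, positions):
    rows = np.asarray(rows, dtype=np.int8)
    ids = [f"h{i}" for i in range(rows.shape[0])]
    return _loose_matrix(rows, np.asarray(positions), "c", ids, {})


class TestClassifyByTagSnps:
    def test_exact_consensus_match(self):
        panel = make_panel()
        m = matrix_from_rows([[1] * 6, [0] * 6], panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel)
        assert [c.label for c in calls] == [NE1, NON_NE1]
        assert [c.mismatches for c in calls] == [0, 0]

    def test_singleton_haplotypes_unclassified_at_zero_mismatch(self):
        # analog of the two reference-panel singletons matching neither
        # 6-SNP consensus exactly: with max_mismatch=0 they stay unassigned
        panel = make_panel(6)
        singletons = [[1, 1, 0, 1, 1, 1], [0, 1, 0, 0, 0, 0]]
        m = matrix_from_rows(singletons, panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel)  # default 0 for 6-SNP
        assert all(c.label == UNCLASSIFIED for c in calls)

    def test_one_mismatch_assigned_with_tolerance(self):
        panel = make_panel(6)
        m = matrix_from_rows([[1, 1, 0, 1, 1, 1]], panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel, max_mismatch=1)
        assert calls[0].label == NE1 and calls[0].mismatches == 1

    def test_tie_stays_unclassified(self):
        panel = make_panel(6)
        m = matrix_from_rows([[1, 1, 1, 0, 0, 0]], panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel, max_mismatch=6)
        assert calls[0].label == UNCLASSIFIED

    def test_missing_tag_position_raises(self):
        panel = make_panel(6)
        m = matrix_from_rows([[1] * 5], panel.positions[:5])
        with pytest.raises(KeyError, match="t5"):
            haplogroups.classify_by_tag_snps(m, panel)

    def test_permutation_equivariance(self, rng):
        panel = make_panel(6)
        rows = rng.integers(0, 2, size=(12, 6))
        m = matrix_from_rows(rows, panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel, max_mismatch=1)
        perm = rng.permutation(12)
        m2 = matrix_from_rows(rows[perm], panel.positions)
        calls2 = haplogroups.classify_by_tag_snps(m2, panel, max_mismatch=1)
        assert [calls[i].label for i in perm] == [c.label for c in calls2]


def test_scenario_tag_classification_matches_deletion_carriage(default_scenario):
    """Tag SNPs and the deletion are in perfect LD with clade membership."""
    _, m, truth = default_scenario
    calls = haplogroups.classify_by_tag_snps(m, truth.tag_panel())
    for i, c in enumerate(calls):
        assert c.label == truth.clade_of[i]
        assert (c.label == NE1) == bool(truth.deletion_carriers[i])


def test_haplogroup_frequency_table_conserves_counts(default_scenario):
    _, m, truth = default_scenario
    calls = haplogroups.classify_by_tag_snps(m, truth.tag_panel())
    table = haplogroups.haplogroup_frequencies(m, calls)
    assert int(table.sum().sum()) == m.n_haplotypes


class TestWithinGroupDiversity:
    def test_identical_group_zero_pi(self):
        panel = make_panel(2)
        rows = [[1, 1]] * 4 + [[0, 0]] * 4
        m = matrix_from_rows(rows, panel.positions)
        calls = haplogroups.classify_by_tag_snps(m, panel)
        div = haplogroups.within_group_diversity(m, calls)
        assert (div["pi_total"] == 0).all()

    def test_all_in_one_group_equals_unrestricted(self, rng):
        panel = make_panel(2)
        extra = rng.integers(0, 2, size=(6, 4))
        rows = np.column_stack([np.ones((6, 2), dtype=np.int8), extra])
        m = matrix_from_rows(rows, [100, 200, 300, 400, 500, 600])
        calls = haplogroups.classify_by_tag_snps(m, panel)
        div = haplogroups.within_group_diversity(m, calls)
        want = popstats.nucleotide_diversity(rows).pi_total
        assert div.loc[div["label"] == NE1, "pi_total"].iloc[0] == pytest.approx(want)

    def test_deep_african_clade_has_higher_ne1_diversity(self):
        cfg = synthdata.SubstructureConfig(
            ne1_freq={"AFR": 0.2, "EUR": 0.5},
            pop_time_scale={"AFR": 3.0, "EUR": 1.0},
            seed=77,
        )
        m, truth = synthdata.simulate_substructure_locus(cfg)
        calls = haplogroups.classify_by_tag_snps(m, truth.tag_panel())
        afr = haplogroups.group_pairwise_distances(m, calls, NE1, "AFR")
        eur = haplogroups.group_pairwise_distances(m, calls, NE1, "EUR")
        assert afr.mean() > eur.mean()
        _, p = popstats.mann_whitney_u(afr, eur)
        assert p < 0.01


class TestHaplotypePca:
    def test_two_clusters_separate_on_pc1(self):
        rows = np.array([[1, 1, 1, 1]] * 5 + [[0, 0, 0, 0]] * 5, dtype=np.int8)
        res = haplogroups.haplotype_pca(rows, k=2)
        pc1 = res.coordinates[:, 0]
        gap = abs(pc1[:5].mean() - pc1[5:].mean())
        within = max(pc1[:5].std(), pc1[5:].std())
        assert gap > 10 * (within + 1e-12)

    def test_order_permutation_invariance_up_to_sign(self, rng):
        rows = rng.integers(0, 2, size=(15, 10)).astype(np.int8)
        res = haplogroups.haplotype_pca(rows, k=2)
        perm = rng.permutation(15)
        res2 = haplogroups.haplotype_pca(rows[perm], k=2)
        for j in range(2):
            a, b = res.coordinates[perm, j], res2.coordinates[:, j]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_scenario_pc1_separates_haplogroups(self, default_scenario):
        _, m, truth = default_scenario
        res = haplogroups.haplotype_pca(m, k=2)
        pc1 = res.coordinates[:, 0]
        is_ne1 = truth.clade_of == NE1
        thresh = (pc1[is_ne1].mean() + pc1[~is_ne1].mean()) / 2
        sign = 1 if pc1[is_ne1].mean() > thresh else -1
        pred = sign * pc1 > sign * thresh
        accuracy = max((pred == is_ne1).mean(), (pred == ~is_ne1).mean())
        assert accuracy >= 0.99

    def test_rank_truncation(self):
        rows = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
        res = haplogroups.haplotype_pca(rows, k=5)
        assert res.k <= 2


class TestGenotypeConcordance:
    def test_identical_and_partial(self):
        a = {f"s{i}": i % 3 for i in range(10)}
        assert haplogroups.genotype_concordance(a, dict(a)) == 1.0
        b = dict(a)
        b["s0"] = (b["s0"] + 1) % 3
        assert haplogroups.genotype_concordance(a, b) == pytest.approx(0.9)

    def test_no_shared_samples_raises(self):
        with pytest.raises(ValueError):
            haplogroups.genotype_concordance({"a": 0}, {"b": 1})

    def test_random_perturbation_rate(self, rng):
        q = 0.05
        a = {f"s{i}": int(rng.integers(0, 3)) for i in range(1_000)}
        b = {
            s: (g + 1) % 3 if rng.random() < q else g
            for s, g in a.items()
        }
        conc = haplogroups.genotype_concordance(a, b)
        assert conc == pytest.approx(1 - q, abs=0.03)
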