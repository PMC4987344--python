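"""Clustering workflow: z-scores, Ward oracle, cuts, benchmarks, stages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apcphys import cluster as clu
from apcphys.features import FEATURE_NAMES, SUBTHRESHOLD_FEATURES


def _fm(X, names=None):
    X = np.asarray(X, float)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return clu.FeatureMatrix([f"c{i}" for i in range(X.shape[0])], list(names), X)


# ---------------------------------------------------------------------------
# brute-force Ward oracle: at each step merge the pair whose union minimises
# the increase in total within-cluster sum of squares
# ---------------------------------------------------------------------------


def brute_force_ward(X):
    X = np.asarray(X, float)
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = X[clusters[i]], X[clusters[j]]
                na, nb = len(a), len(b)
                d2 = np.sum((a.mean(0) - b.mean(0)) ** 2)
                cost = na * nb / (na + nb) * d2
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        # scipy reports sqrt(2 * increase) as the Ward merge height
        merges.append((np.sqrt(2.0 * cost), [frozenset(c) for c in clusters]))
    return merges


def _partitions_from_linkage(Z, n):
    from scipy.cluster import hierarchy

    parts = []
    for k in range(n - 1, 0, -1):
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        groups = {}
        for i, l in enumerate(flat):
            groups.setdefault(l, []).append(i)
        parts.append({frozenset(g) for g in groups.values()})
    return parts


class TestStandardize:
    def test_two_point_column(self):
        out = clu.standardize(_fm([[1.0], [3.0]]))
        assert np.allclose(out.X.ravel(), [-0.7071067, 0.7071067], atol=1e-6)

    def test_idempotent_on_zscores(self):
        rng = np.random.default_rng(0)
        z = clu.standardize(_fm(rng.normal(size=(20, 4))))
        z2 = clu.standardize(z)
        assert np.allclose(z.X, z2.X, atol=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_columns_zero_mean_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        out = clu.standardize(_fm(rng.normal(2.0, 5.0, size=(12, 3))))
        assert np.allclose(out.X.mean(0), 0.0, atol=1e-9)
        assert np.allclose(out.X.std(0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_named_in_error(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.raises(ValueError, match="tau_m"):
            clu.standardize(_fm(X, names=["r_in", "tau_m"]))


class TestWardLinkage:
    def test_identical_points_merge_at_zero(self):
        d = clu.ward_linkage(_fm([[1.0, 2.0], [1.0, 2.0]]))
        assert d.heights[0] == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_bruteforce_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        X = rng.normal(size=(n, 3))
        dend = clu.ward_linkage(_fm(X))
        oracle = brute_force_ward(X)
        assert np.allclose(
            sorted(dend.heights), sorted(m[0] for m in oracle), rtol=1e-8
        )
        parts = _partitions_from_linkage(dend.linkage, n)
        for (_h, part_oracle), part_scipy in zip(oracle, parts):
            assert set(part_oracle) == part_scipy

    def test_heights_monotone(self):
        rng = np.random.default_rng(3)
        d = clu.ward_linkage(_fm(rng.normal(size=(30, 5))))
        assert np.all(np.diff(d.heights) >= -1e-9)

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        perm = rng.permutation(15)
        a = clu.cut(clu.ward_linkage(_fm(X)), 3)
        fmp = clu.FeatureMatrix(
            [f"c{i}" for i in perm], [f"f{j}" for j in range(4)], X[perm]
        )
        b = clu.cut(clu.ward_linkage(fmp), 3)
        part_a = {frozenset(a.members(c)) for c in set(a.labels.values())}
        part_b = {frozenset(b.members(c)) for c in set(b.labels.values())}
        assert part_a == part_b

    def test_newick_export_parses(self):
        rng = np.random.default_rng(1)
        d = clu.ward_linkage(_fm(rng.normal(size=(6, 2))))
        nwk = d.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 5
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert tree.count_terminals() == 6


class TestCut:
    def test_k_one_and_k_n(self):
        rng = np.random.default_rng(2)
        d = clu.ward_linkage(_fm(rng.normal(size=(8, 2))))
        assert len(set(clu.cut(d, 1).labels.values())) == 1
        assert len(set(clu.cut(d, 8).labels.values())) == 8

    def test_invalid_k(self):
        d = clu.ward_linkage(_fm(np.random.default_rng(0).normal(size=(5, 2))))
        for k in (0, 6):
            with pytest.raises(ValueError):
                clu.cut(d, k)

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal(0, 0.1, size=(10, 3)), rng.normal(8, 0.1, size=(12, 3))]
        )
        truth = {f"c{i}": ("A" if i < 10 else "B") for i in range(22)}
        a = clu.cut(clu.ward_linkage(clu.standardize(_fm(X))), 2)
        n_mis, _ = clu.count_misclassified(a, truth)
        assert n_mis == 0


class TestBenchmarks:
    def _assignment(self):
        labels = {"b1": 1, "b2": 1, "x1": 1, "x2": 2, "b3": 2}
        return clu.ClusterAssignment(labels=labels, k=2)

    def test_majority_naming(self):
        out = clu.benchmark_assign(self._assignment(), {"b1": "PV", "b2": "PV"})
        assert out.cluster_names[1] == "pPV"

    def test_stray_benchmark_flagged(self):
        out = clu.benchmark_assign(
            self._assignment(), {"b1": "PV", "b2": "PV", "b3": "PV"}
        )
        assert "b3" in out.misclassified

    def test_tie_raises(self):
        with pytest.raises(clu.BenchmarkTieError):
            clu.benchmark_assign(self._assignment(), {"b1": "PV", "x1": "SST"})

    def test_misclassification_equals_confusion_oracle(self):
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(0, 1.0, size=(12, 2)), rng.normal(3, 1.0, size=(12, 2))]
        )
        truth = {f"c{i}": ("A" if i < 12 else "B") for i in range(24)}
        a = clu.cut(clu.ward_linkage(clu.standardize(_fm(X))), 2)
        n_mis, mis = clu.count_misclassified(a, truth)
        # oracle: best of the two cluster<->class mappings on the 2x2 table
        conf = np.zeros((2, 2), int)
        clusters = sorted(set(a.labels.values()))
        for cid, cl in a.labels.items():
            conf[clusters.index(cl), 0 if truth[cid] == "A" else 1] += 1
        best = min(conf[0, 1] + conf[1, 0], conf[0, 0] + conf[1, 1])
        assert n_mis == best
        assert len(mis) == n_mis


class TestSequentialClustering:
    def test_single_stage_equals_direct_pipeline(self, target_cohort_frame):
        df = target_cohort_frame
        stage = clu.StagePlan(feature_names=tuple(FEATURE_NAMES), k=2)
        (got_stage, got), = clu.sequential_cluster(df, [stage])
        fm = clu.FeatureMatrix.from_frame(df, FEATURE_NAMES)
        want = clu.cut(clu.ward_linkage(clu.standardize(fm)), 2)
        assert got.labels == want.labels

    def test_excluding_all_cells_raises(self, target_cohort_frame):
        stage = clu.StagePlan(exclude_groups=("FS-SST", "FS-PV"), k=2)
        with pytest.raises(ValueError):
            clu.sequential_cluster(target_cohort_frame, [stage])

    def test_staged_workflow_isolates_distinct_class_then_separates(self):
        """A G42-like cluster is isolated at the first cut; after removal the
        two FS lines separate at the final subthreshold-only stage."""
        from apcphys.synth import _draw_targets, _spec_for

        rng = np.random.default_rng(4)
        rows = {}
        for preset, line, n in [
            ("FS-SST-tonic", "FS-SST", 10),
            ("FS-PV-tonic", "FS-PV", 10),
            ("G42-APC", "G42", 8),
        ]:
            spec = _spec_for(preset)
            for _ in range(n):
                t = _draw_targets(spec, rng, 0.5)
                rows[f"{line}-{len(rows)}"] = t | {"group": line}
        df = pd.DataFrame.from_dict(rows, orient="index")

        stage1 = clu.StagePlan(feature_names=tuple(FEATURE_NAMES), k=2)
        stage2 = clu.StagePlan(
            feature_names=tuple(SUBTHRESHOLD_FEATURES),
            exclude_groups=("G42",),
            k=2,
        )
        trail = clu.sequential_cluster(df, [stage1, stage2])
        # stage 1: G42 cells form one pure branch
        a1 = trail[0][1]
        g42_clusters = {a1.labels[c] for c in a1.labels if c.startswith("G42")}
        assert len(g42_clusters) == 1
        # stage 2: FS lines separate with few errors at halved spread
        a2 = trail[1][1]
        truth = {c: df.loc[c, "group"] for c in a2.labels}
        n_mis, _ = clu.count_misclassified(a2, truth)
        assert n_mis <= 3
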