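"""End-to-end study workflows composed from the library modules.

These are the benchmark experiments the package reproduces on synthetic
cohorts: the fast-spiking two-line clustering comparison (eight features vs
the subthreshold trio), per-preset feature-recovery runs, the three-condition
gabazine decomposition on pyramidal cells, and reporter-line co-labeling
sections.
"""

from __future__ import annotations

import numpy as np

from . import anatomy, cluster as clu, features as feat, ipsc, synth

__all__ = [
    "extract_cohort_features",
    "fs_cohort_misclassification",
    "fs_clustering_medians",
    "feature_recovery_mean",
    "pooled_fs_max_rate",
    "ipsc_decomposition_experiment",
    "colabel_experiment",
]


def extract_cohort_features(cohort):
    """Run feature extraction over (CellRecord, sweeps) pairs in place."""
    for rec, sweeps in cohort:
        rec.features = feat.extract_features(
            sweeps.get("subthreshold"), sweeps.get("suprathreshold")
        )
    return [rec for rec, _ in cohort]


def fs_cohort_misclassification(seed: int, n_sst: int = 14, n_pv: int = 11):
    """(8-feature misclassified, subthreshold-trio misclassified SST cells).

    Simulates the two-line fast-spiking cohort, extracts the eight features,
    z-scores, Ward-clusters, cuts at k=2, and counts confusion-matrix
    off-diagonal cells against the line labels — once with all eight features
    and once with the subthreshold trio (R_in, tau_m, sag), where only
    misclassified SST-like cells are counted.
    """
    cohort = synth.simulate_fs_cohort(seed=seed, n_sst=n_sst, n_pv=n_pv)
    records = extract_cohort_features(cohort)
    ids = [r.cell_id for r in records]
    truth = {r.cell_id: r.label for r in records}
    X = np.array([r.features.to_array() for r in records])
    fm = clu.FeatureMatrix(ids, list(feat.FEATURE_NAMES), X)

    a8 = clu.cut(clu.ward_linkage(clu.standardize(fm)), 2)
    n8, _ = clu.count_misclassified(a8, truth)

    fm3 = fm.select(list(feat.SUBTHRESHOLD_FEATURES))
    a3 = clu.cut(clu.ward_linkage(clu.standardize(fm3)), 2)
    _, mis3 = clu.count_misclassified(a3, truth)
    n3_sst = sum(1 for c in mis3 if truth[c] == "FS-SST")
    return n8, n3_sst


def fs_clustering_medians(seed: int, n_seeds: int = 100):
    """Median misclassification over ``n_seeds`` independent cohorts."""
    root = np.random.SeedSequence(seed)
    sub = [int(s) % (2**31) for s in root.generate_state(n_seeds)]
    results = [fs_cohort_misclassification(s) for s in sub]
    m8 = float(np.median([r[0] for r in results]))
    m3 = float(np.median([r[1] for r in results]))
    return m8, m3


def feature_recovery_mean(
    preset: str, feature: str, n: int = 50, seed: int = 0
) -> float:
    """Population mean of one extracted feature over ``n`` simulated cells."""
    cells = synth.simulate_population(preset, n, seed=seed)
    records = extract_cohort_features(cells)
    vals = np.array([getattr(r.features, feature) for r in records])
    return float(np.nanmean(vals))


def pooled_fs_max_rate(n: int = 50, seed: int = 0) -> float:
    """Mean maximum firing rate over a pooled FS-SST / FS-PV population."""
    cohort = synth.simulate_fs_cohort(seed=seed, n_sst=n // 2, n_pv=n - n // 2)
    records = extract_cohort_features(cohort)
    vals = np.array([r.features.max_firing_rate for r in records])
    return float(np.nanmean(vals))


def ipsc_decomposition_experiment(
    n_cells: int = 6, seed: int = 0, heterogeneous: bool = False
):
    """Per-cell gabazine decompositions for ``n_cells`` simulated experiments.

    By default every cell runs the *default* pyramidal-cell scenario (trial
    noise only), the benchmark configuration; ``heterogeneous=True`` draws
    per-cell scenarios around it instead.
    """
    if heterogeneous:
        scenarios = synth.sample_pc_scenarios(n_cells, seed=seed)
    else:
        scenarios = [synth.default_pc_scenario()] * n_cells
    sub = np.random.SeedSequence(seed).generate_state(n_cells + 1)[1:]
    out = []
    for scen, s in zip(scenarios, sub):
        trials = synth.simulate_ipsc_experiment(scen, seed=int(s) % (2**31))
        t = scen.time()
        q = {
            cond: ipsc.average_trials(arr, t, condition=cond).charge
            for cond, arr in trials.items()
        }
        out.append(ipsc.decompose(q["baseline"], q["GZ-soma"], q["GZ-both"]))
    return out


def colabel_experiment(
    line: str = "PV-line",
    marker: str = "PV+",
    n_sections: int = 10,
    roi_area_mm2: float = 0.83,
    seed: int = 0,
) -> float:
    """Mean co-labeling percentage (reporter denominator) over sections."""
    preset = synth.ANATOMY_PRESETS[line]
    sub = np.random.SeedSequence(seed).generate_state(n_sections)
    vals = []
    for s in sub:
        pat = synth.generate_point_pattern(
            roi_area_mm2, preset["density"], preset["colabel"],
            seed=int(s) % (2**31),
        )
        vals.append(anatomy.colabel_percent_pattern(pat, "tdTom", marker, "tdTom"))
    return float(np.mean(vals))
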