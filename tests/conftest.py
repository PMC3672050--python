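import numpy as np
import pytest

import gapwave as gw


def small_sim_config(seed: int = 42) -> gw.SimConfig:
    """Scaled-down study: same archetypes, fewer transcripts (fast tests)."""
    counts = {"spermatogonia": 12, "spermatocytes": 15, "early_spermatids": 20,
              "late_spermatids": 22, "somatic": 18}
    arch = []
    for a in gw.default_archetypes():
        arch.append(gw.ArchetypeSpec(a.name, a.trough_or_peak_day, a.depth,
                                     a.width_days, counts[a.name],
                                     direction=a.direction, recovery_day=a.recovery_day))
    return gw.SimConfig(archetypes=arch, n_noise_transcripts=300, rng_seed=seed)


def run_expression_pipeline(cfg: gw.SimConfig):
    """simulate -> normalise -> collapse -> select -> cluster -> annotate."""
    ds = gw.simulate_expression(cfg)
    norm = gw.quantile_normalize(ds.probe_matrix)
    collapsed = gw.collapse_probes_median(norm, ds.annotation)
    selection = gw.select_transcripts(
        collapsed, gw.SelectionConfig(rng_seed=cfg.rng_seed))
    ids = selection.selected_ids
    idx = [collapsed.matrix.row_ids.index(t) for t in ids]
    sub = gw.ExpressionMatrix(collapsed.matrix.values[idx], ids,
                              collapsed.matrix.col_days, "linear").to_log2()
    clusters = gw.cluster_transcripts(sub, k="auto")
    evidence, missing = gw.map_markers(gw.MarkerTable.load_packaged(), clusters.labels)
    assignment = gw.assign_cell_types(clusters.median_z_profiles, evidence)
    return {
        "dataset": ds,
        "collapsed": collapsed,
        "selection": selection,
        "clusters": clusters,
        "assignment": assignment,
        "missing_markers": missing,
    }


@pytest.fixture(scope="session")
def default_run():
    """The full pipeline on the default study conditions (seed 42)."""
    return run_expression_pipeline(gw.SimConfig(rng_seed=42))


@pytest.fixture(scope="session")
def small_run():
    return run_expression_pipeline(small_sim_config())


def write_sim_inputs(ds: gw.SimulatedDataset, out_dir):
    """Write a simulated dataset to TSV files; returns the three paths."""
    probes = out_dir / "probes.tsv"
    ann = out_dir / "annotation.tsv"
    truth = out_dir / "truth.tsv"
    ds.probe_matrix.write_tsv(probes)
    ds.annotation.write_tsv(ann)
    ds.truth.to_csv(truth, sep="\t", index=False)
    return probes, ann, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
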