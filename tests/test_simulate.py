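"""Synthetic panel generator: marginals, dependence, determinism, configs."""

import numpy as np
import pytest

import consilico as c


def _single_gene_config(**kwargs):
    defaults = dict(
        genes={"G": c.GeneComposition(200, 200)},
        tools={
            "A": c.ToolProfile(0.9, 0.8),
            "B": c.ToolProfile(0.8, 0.7, polarity=c.LOW_IS_DAMAGING),
        },
        seed=100,
        rho=0.0,
    )
    defaults.update(kwargs)
    return c.SimulationConfig(**defaults)


def test_perfect_tools_reproduce_truth():
    config = _single_gene_config(
        tools={"A": c.ToolProfile(1.0, 1.0)}, genes={"G": c.GeneComposition(50, 50)}
    )
    panel = c.generate_panel(config)
    for variant, row in zip(panel.variants, panel.calls):
        expected = c.DAMAGING if variant.truth == c.PATHOGENIC else c.TOLERATED
        assert row[0].call == expected


def test_same_seed_same_panel_different_seed_differs():
    config = _single_gene_config(seed=42)
    p1, p2 = c.generate_panel(config), c.generate_panel(config)
    assert p1.variants == p2.variants and p1.calls == p2.calls
    p3 = c.generate_panel(_single_gene_config(seed=43))
    assert p3.calls != p1.calls


def test_marginal_rates_recovered_within_binomial_bounds():
    """Configured sensitivity/specificity are the marginal correctness
    rates; check 3-sigma binomial recovery at n=2000 per class."""
    config = c.SimulationConfig(
        genes={"G": c.GeneComposition(2000, 2000)},
        tools={"A": c.ToolProfile(0.9, 0.8)},
        seed=7,
        rho=0.0,
    )
    panel = c.generate_panel(config)
    truths = np.array(panel.truths())
    calls = np.array([row[0].call for row in panel.calls])
    sens = np.mean(calls[truths == c.PATHOGENIC] == c.DAMAGING)
    spec = np.mean(calls[truths == c.BENIGN] == c.TOLERATED)
    assert abs(sens - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / 2000)
    assert abs(spec - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / 2000)


def test_dependence_knob_raises_inter_tool_phi():
    """Mean pairwise phi grows with the latent correlation rho."""
    def mean_phi(rho, reps=20):
        vals = []
        for r in range(reps):
            config = c.SimulationConfig(
                genes={"G": c.GeneComposition(150, 150)},
                tools={t: c.ToolProfile(0.85, 0.75) for t in "ABCD"},
                seed=1000 + r,
                rho=rho,
            )
            mat = c.association_matrix(c.generate_panel(config))
            off = mat.values[~np.eye(4, dtype=bool)]
            vals.append(np.nanmean(off))
        return np.mean(vals)

    assert mean_phi(0.6) > mean_phi(0.0)


def test_score_auc_increases_with_separation():
    aucs = []
    for sep in (0.5, 1.5, 3.0):
        config = c.SimulationConfig(
            genes={"G": c.GeneComposition(300, 300)},
            tools={"A": c.ToolProfile(0.85, 0.75, separation=sep)},
            seed=21,
        )
        panel = c.generate_panel(config)
        res = c.analyze_scores(
            panel.scores_frame()["A"].to_numpy(), panel.truths(),
            direction=panel.polarity("A"),
        )
        aucs.append(res.auc)
    assert aucs[0] < aucs[1] < aucs[2]


def test_low_polarity_tool_scores_run_backwards():
    """A low-is-damaging tool's raw scores anticorrelate with pathogenicity,
    and fixed-polarity orientation recovers the signal."""
    config = _single_gene_config(seed=5)
    panel = c.generate_panel(config)
    scores_b = panel.scores_frame()["B"].to_numpy()
    raw = c.roc_curve(scores_b, panel.truths(), direction="high_is_damaging")
    oriented = c.roc_curve(scores_b, panel.truths(), direction="low_is_damaging")
    assert raw.auc < 0.5 < oriented.auc


def test_missing_rate_masks_cells():
    config = _single_gene_config(missing_rate=0.3, seed=9)
    panel = c.generate_panel(config)
    frac = np.mean(panel.calls_frame().to_numpy() == c.MISSING)
    assert 0.2 < frac < 0.4


def test_generated_panel_passes_filter_and_round_trips(tmp_path):
    panel = c.generate_panel(c.lqts_benchmark_config(seed=77))
    kept, rejected = c.apply_inclusion_filter(panel.variants)
    assert rejected == [] and len(kept) == panel.n_variants
    schema = c.default_schema(panel.tools)
    out = tmp_path / "panel.tsv"
    c.write_panel(panel, out, schema)
    again = c.read_panel(out, schema)
    assert again.variants == panel.variants
    assert again.calls_frame().equals(panel.calls_frame())
    np.testing.assert_allclose(
        again.scores_frame().to_numpy(), panel.scores_frame().to_numpy()
    )
    assert again.metaservers == panel.metaservers


def test_benchmark_config_composition():
    config = c.lqts_benchmark_config()
    assert config.total_variants() == 312
    assert (config.genes["KCNQ1"].n_pathogenic, config.genes["KCNQ1"].n_benign) == (101, 8)
    assert (config.genes["KCNH2"].n_pathogenic, config.genes["KCNH2"].n_benign) == (82, 8)
    assert (config.genes["SCN5A"].n_pathogenic, config.genes["SCN5A"].n_benign) == (99, 14)
    assert set(config.tools) == {
        "PolyPhen-2", "SNPs&GO", "SIFT", "PROVEAN", "SNAP", "Meta-SNP", "PredictSNP",
    }
    assert sum(p.metaserver for p in config.tools.values()) == 2
    # SCN5A gets real region annotations for the two-group sub-analysis
    panel = c.generate_panel(config)
    scn5a_regions = {v.region for v in panel.variants if v.gene == "SCN5A"}
    assert "loop" in scn5a_regions and scn5a_regions & {"n_term", "transmembrane", "c_term"}


def test_config_validation_and_yaml_round_trip(tmp_path):
    with pytest.raises(ValueError, match="rho"):
        _single_gene_config(rho=1.0)
    with pytest.raises(ValueError, match="sensitivity"):
        c.ToolProfile(1.2, 0.5)
    with pytest.raises(ValueError, match="sum to 1"):
        c.GeneComposition(5, 5, region_probs=(("loop", 0.5),))
    config = c.lqts_benchmark_config(seed=3)
    path = tmp_path / "config.yaml"
    c.save_sim_config(config, path)
    loaded = c.load_sim_config(path)
    assert loaded == config
    assert c.generate_panel(loaded).calls == c.generate_panel(config).calls
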