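import pytest

import consilico as c


@pytest.fixture(scope="session")
def lqts_panel():
    """One draw of the default three-gene benchmark panel."""
    return c.generate_panel(c.lqts_benchmark_config(seed=20240))


@pytest.fixture()
def toy_schema():
    """Two-tool schema with opposite score polarities."""
    return c.default_schema(["SIFT", "PolyPhen-2"])


@pytest.fixture()
def toy_panel_path(tmp_path, toy_schema):
    """Three-variant, two-tool fixture TSV with one missing SIFT cell."""
    lines = [
        "variant_id\tgene\ttruth\tevidence\tallele_frequency\tregion\t"
        "SIFT_call\tSIFT_score\tPolyPhen-2_call\tPolyPhen-2_score",
        "KCNQ1:p.R190Q\tKCNQ1\tpathogenic\tfunctional\t.\tunassigned\t"
        "Damaging\t0.01\tProbably damaging\t0.98",
        "KCNQ1:p.P448R\tKCNQ1\tbenign\tallele_frequency\t0.02\tunassigned\t"
        "Tolerated\t0.4\tBenign\t0.03",
        "KCNH2:p.G628S\tKCNH2\tpathogenic\tcosegregation\t.\tunassigned\t"
        ".\t.\tPossibly damaging\t0.62",
    ]
    path = tmp_path / "toy_panel.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
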